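"""Cohort statistics: per-technique pre/post summaries and the pairwise
between-technique significance matrix.

Every comparison is made on the same feet, so the paired two-tailed
Student t-test is the default for both the pre-vs-post column and the
between-technique matrix; an unpaired variant is available behind a flag.
Raw p-values are reported (no multiple-testing correction by default).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

SIGNIFICANCE_ALPHA = 0.05
COHORT_COLUMNS = ("subject_id", "session", "technique", "angle_deg")
SESSIONS = ("pre", "post")


class CohortError(Exception):
    pass


# ---------------------------------------------------------------------------
# cohort table I/O and validation

def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise CohortError(f"cohort table missing columns: {missing}")
    t = table.loc[:, list(COHORT_COLUMNS)].copy()
    bad_session = ~t["session"].isin(SESSIONS)
    if bad_session.any():
        row = int(np.flatnonzero(bad_session.to_numpy())[0])
        raise CohortError(f"row {row}: session must be one of {SESSIONS}, "
                          f"got {t['session'].iloc[row]!r}")
    angles = pd.to_numeric(t["angle_deg"], errors="coerce")
    if angles.isna().any():
        row = int(np.flatnonzero(angles.isna().to_numpy())[0])
        raise CohortError(f"row {row}: angle_deg {t['angle_deg'].iloc[row]!r} "
                          "is not numeric")
    if not np.all(np.isfinite(angles)):
        raise CohortError("cohort table contains non-finite angles")
    t["angle_deg"] = angles.astype(float)
    dup = t.duplicated(subset=["subject_id", "session", "technique"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise CohortError(f"row {row}: duplicate (subject, session, technique)")
    return t


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path))


def write_cohort_csv(table: pd.DataFrame, path: str | Path) -> None:
    out = table.copy()
    out["angle_deg"] = out["angle_deg"].map(lambda x: f"{x:.6f}")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# tests

def paired_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-tailed paired Student t-test.

    Returns (t, p) with t = mean(d) / (sd(d)/sqrt(n)) for d = x - y, sd
    with n-1 denominator, and p from Student's t with n-1 degrees of
    freedom.  All-zero differences give (0, 1); zero variance with a
    nonzero mean gives p = 0 with a warning.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = len(x)
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = x - y
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0
        logger.warning("degenerate variance in paired t-test "
                       "(all differences equal %.6g); p set to 0", mean)
        return float(np.sign(mean) * np.inf), 0.0
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), n - 1))
    return float(t), p


def unpaired_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-tailed two-sample Student t-test with pooled variance."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("unpaired t-test needs at least 2 samples per group")
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return float(np.sign(x.mean() - y.mean()) * np.inf), 0.0
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * float(sps.t.sf(abs(t), n1 + n2 - 2))
    return float(t), p


# ---------------------------------------------------------------------------
# summaries

def _paired_frame(table: pd.DataFrame, technique: str) -> pd.DataFrame:
    sub = table[table["technique"] == technique]
    wide = sub.pivot(index="subject_id", columns="session", values="angle_deg")
    for s in SESSIONS:
        if s not in wide.columns:
            wide[s] = np.nan
    return wide


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-technique pre/post means, STDs, pre mean-to-STD ratio and the
    paired pre-vs-post p-value.

    Subjects missing one session are included in the marginal means but
    excluded from the paired test (with a log note).
    """
    table = validate_cohort(table)
    rows = []
    for tech in table["technique"].unique():
        wide = _paired_frame(table, tech)
        pre = wide["pre"].dropna()
        post = wide["post"].dropna()
        if len(pre) == 0 or len(post) == 0:
            raise CohortError(f"technique {tech!r} has an empty session column")
        complete = wide.dropna(subset=list(SESSIONS))
        n_excluded = len(wide) - len(complete)
        if n_excluded:
            logger.info("technique %s: %d subjects missing a session were "
                        "excluded from the paired test", tech, n_excluded)
        if len(complete) >= 2:
            t, p = paired_t_test(complete["pre"].to_numpy(),
                                 complete["post"].to_numpy())
        else:
            t, p = np.nan, np.nan
        pre_std = pre.std(ddof=1)
        ratio = pre.mean() / pre_std if pre_std > 0 else np.inf
        rows.append({
            "technique": tech,
            "pre_mean": pre.mean(), "pre_std": pre_std,
            "post_mean": post.mean(), "post_std": post.std(ddof=1),
            "mean_to_std_ratio_pre": ratio,
            "t_pre_vs_post": t, "p_pre_vs_post": p,
            "n_paired": len(complete),
        })
    return pd.DataFrame(rows).set_index("technique")


def pairwise_matrix(table: pd.DataFrame, session: str,
                    paired: bool = True) -> pd.DataFrame:
    """Symmetric technique x technique matrix of two-tailed p-values within
    one session (diagonal NaN)."""
    table = validate_cohort(table)
    if session not in SESSIONS:
        raise CohortError(f"session must be one of {SESSIONS}")
    sub = table[table["session"] == session]
    wide = sub.pivot(index="subject_id", columns="technique",
                     values="angle_deg")
    techs = [t for t in table["technique"].unique() if t in wide.columns]
    if len(techs) < 2 or len(wide) < 2:
        raise CohortError("pairwise matrix needs >= 2 techniques and "
                          ">= 2 subjects")
    mat = pd.DataFrame(np.nan, index=techs, columns=techs, dtype=float)
    for i, a in enumerate(techs):
        for b in techs[i + 1:]:
            pair = wide[[a, b]].dropna()
            if paired:
                _, p = paired_t_test(pair[a].to_numpy(), pair[b].to_numpy())
            else:
                _, p = unpaired_t_test(wide[a].dropna().to_numpy(),
                                       wide[b].dropna().to_numpy())
            mat.loc[a, b] = p
            mat.loc[b, a] = p
    return mat


def count_significant(matrix: pd.DataFrame,
                      alpha: float = SIGNIFICANCE_ALPHA) -> int:
    """Number of significant unordered pairs in a p-value matrix."""
    vals = matrix.to_numpy()
    iu = np.triu_indices(len(matrix), k=1)
    upper = vals[iu]
    return int(np.count_nonzero(upper[~np.isnan(upper)] < alpha))


def holm_bonferroni(matrix: pd.DataFrame) -> pd.DataFrame:
    """Holm step-down adjusted p-values for the unordered pairs (optional;
    raw p-values are the default presentation)."""
    out = matrix.copy()
    iu = np.triu_indices(len(matrix), k=1)
    raw = matrix.to_numpy()[iu]
    mask = ~np.isnan(raw)
    p = raw[mask]
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    filled = raw.copy()
    filled[mask] = adj
    arr = out.to_numpy()
    arr[iu] = filled
    arr[(iu[1], iu[0])] = filled
    return pd.DataFrame(arr, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# report

def format_report(summary: pd.DataFrame,
                  matrices: dict[str, pd.DataFrame],
                  alpha: float = SIGNIFICANCE_ALPHA) -> str:
    """Plain-text report: summary table plus per-session pairwise matrices
    with significant cells starred."""
    lines = ["Hindfoot alignment angle cohort report",
             "=" * 40, "",
             "Per-technique summary (degrees):", ""]
    fmt = summary.copy()
    for col in fmt.columns:
        if col != "n_paired":
            fmt[col] = fmt[col].map(lambda x: f"{x:.2f}"
                                    if np.isfinite(x) else "inf")
    lines.append(fmt.to_string())
    lines.append("")
    for session, mat in matrices.items():
        n_sig = count_significant(mat, alpha)
        n_tot = len(mat) * (len(mat) - 1) // 2
        lines.append(f"Pairwise p-values, session '{session}' "
                     f"({n_sig} of {n_tot} comparisons significant at "
                     f"alpha = {alpha}):")
        cells = mat.copy()
        for col in cells.columns:
            cells[col] = mat[col].map(
                lambda p: "" if np.isnan(p)
                else (f"{p:.4f}*" if p < alpha else f"{p:.4f}"))
        lines.append(cells.to_string())
        lines.append("")
    return "\n".join(lines)


def boxplot_figure(table: pd.DataFrame, path: str | Path) -> None:
    """Per-session box plots of the angles by technique (PNG/SVG by
    file extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = validate_cohort(table)
    techs = list(table["technique"].unique())
    fig, axes = plt.subplots(2, 1, figsize=(1.2 * len(techs) + 2, 8),
                             sharex=True)
    for ax, session in zip(axes, SESSIONS):
        sub = table[table["session"] == session]
        data = [sub.loc[sub["technique"] == t, "angle_deg"].to_numpy()
                for t in techs]
        ax.boxplot(data, tick_labels=techs)
        ax.set_ylabel("angle (deg)")
        ax.set_title(f"{session}-op")
        ax.axhline(0.0, color="grey", lw=0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
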