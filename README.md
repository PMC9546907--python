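# haa3d

3D measurement of the hindfoot alignment angle (HAA) from weight-bearing-CT
bone meshes, with a synthetic foot-phantom oracle and cohort statistics.

Given segmented STL surfaces of the distal tibia, calcaneus and (optionally)
talus, ground plane and second metatarsal, the package builds a whole-foot
anatomical frame (dorsal axis normal to the ground, anterior axis from the
calcaneal most-plantar point to the second metatarsal head) and computes the
signed frontal-plane angle (degrees, valgus positive) between the projected
tibial axis and a hindfoot vertical axis defined by six techniques:

| technique | hindfoot vertical axis |
|---|---|
| `A` | vertical principal axis of the whole calcaneal surface (area-weighted PCA) |
| `B1` | most-plantar calcaneal point → talus volume centroid |
| `B2` | most-plantar calcaneal point → talar middle-facet centre (landmark) |
| `C` | bisector of the medial and lateral frontal-silhouette contour segments |
| `D10/D15/D20` | vertical PCA axis of the posterior 10/15/20 % calcaneal slab |
| `E` | as D, with the slab grown until the most plantar point is enclosed |

Left feet are handled by flipping the medial axis (valgus stays positive);
all principal axes are treated as undirected lines and sign-normalized
dorsal-positive.

## CLI

```sh
# generate a synthetic foot with known angles (truth.json)
haa3d phantom --body-valgus 10 --tuberosity-valgus 5 --out scratch/ph

# measure all techniques for one foot
haa3d measure --tibia scratch/ph/tibia.stl --calcaneus scratch/ph/calcaneus.stl \
    --talus scratch/ph/talus.stl --ground scratch/ph/ground.stl \
    --metatarsal scratch/ph/metatarsal2.stl --landmarks scratch/ph/landmarks.json \
    --side right --out scratch/res

# simulate a pre/post cohort and run the statistics
haa3d cohort-sim --n-subjects 10 --rho 0.7 --seed 1 --out scratch/cohort.csv
haa3d stats  --cohort scratch/cohort.csv --out scratch/stats
haa3d report --cohort scratch/cohort.csv --out scratch/report   # + box plot
```

`measure` accepts a TOML config mirroring its flags (`--config run.toml`;
explicit flags win).  Without a ground mesh the plane z = 0 is assumed; the
second metatarsal head may come from a mesh or from the landmark file
(JSON mapping `second_met_head_plantar` / `talus_middle_facet_center` to
`[x, y, z]` in mm).  Outputs are deterministic: identical inputs and seeds
give byte-identical STL/CSV/JSON.

`stats` reports per-technique pre/post means and STDs, the pre mean-to-STD
ratio, paired two-tailed pre-vs-post t-tests, and the symmetric pairwise
between-technique p-value matrix per session (unpaired tests behind
`--unpaired`, Holm adjustment behind `--holm`).

## Phantom

The phantom (`haa3d phantom`, `haa3d.phantom.generate_phantom`) builds
watertight solids whose expected angle under every technique is analytic:
a cross-section-profiled calcaneus with independently tiltable posterior
tuberosity and a plantar apex, an ellipsoidal talus at a configured
(medial, dorsal) offset, a capped-cylinder tibia, a metatarsal-head sphere
and a ground slab.  `truth.json` records the expected angles; with a tilted
tuberosity the `A`/`C` truths describe only the bone body (the silhouette
then mixes both tilts).

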