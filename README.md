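# vasodose

Multiscale liver-vasculature dosimetry toolkit: synthetic macroscale vessel
trees inside an organ boundary, a stylized hexagonal-prism lobule model of the
liver microanatomy, labeled tetrahedral-mesh sampling, a desk-scale particle
transport surrogate, and the mathematical machinery that couples macroscale
and microscale absorbed fractions into blood/parenchyma specific absorbed
fractions and radionuclide S-values.

## Layout

| module                | what it does |
|-----------------------|--------------|
| `vasodose.masses`     | reference mass ledger (liver / blood / parenchyma at two scales), elemental-composition subtraction and mixing, blood-partition bookkeeping |
| `vasodose.tree`       | seeded constructive growth of vascular centerline trees (power-law bifurcation radii, volume-minimizing attachment, intersection avoidance), endpoint triplet matching |
| `vasodose.surface`    | triangle meshes: Rodrigues cylinder instancing, watertight offset wrapping, boolean union via signed-distance extraction, OBJ/PLY/STL I/O |
| `vasodose.lobule`     | hexagonal lobule (central vein, portal triads, sinusoids, Space of Disse, bile channels, Kupffer cells) built from exact convex polytopes, plus the mirror-symmetric rectangular tiling crop |
| `vasodose.tetmesh`    | TetGen-dialect node/ele I/O, determinant tet volumes, volume-weighted barycentric point sampling |
| `vasodose.transport`  | toy Monte Carlo on voxelized labels: straight constant-LET charged tracks, Woodcock photon tracking, reflective or escaping boundaries, absorbed-fraction CSV tables |
| `vasodose.coupling`   | macro/micro absorbed-fraction coupling, whole-organ sums, macroscale-only comparator, photon volume-fraction substitution |
| `vasodose.dosimetry`  | shape-preserving SAF interpolation, per-radiation-class S-values, activity partitioning and parenchyma dose rate |

## CLI

```bash
vasodose gen-tree --config growth.json --seed 3 --out tree.json
vasodose mesh-tree --tree tree.json --offset 0.01 --out vessels.obj
vasodose build-lobule --out lobule_dir/           # one OBJ per component + manifest
vasodose tetsample --node m.node --ele m.ele --region 1 --n 100000 --seed 1 --out pts.txt
vasodose transport --node m.node --ele m.ele --particle alpha --energy 5.87 \
    --mode reflective --source 1 --n 100000 --seed 1 --out af.json
vasodose couple --macro macro_af.csv --micro micro_af.csv --out coupled.csv
vasodose svalue --saf coupled.csv --decay y90.csv --out svalues.csv
```

A growth config is JSON, e.g.

```json
{"boundary": {"type": "sphere", "radius": 1.0},
 "n_terminals": 50, "root_position": [0, 0, 1.0],
 "root_radius": 0.12, "min_radius": 0.01}
```

## Notes

* The transport module is a deliberately simplified surrogate (constant-LET
  straight charged tracks, kerma-style photons, no secondaries): it exists to
  exercise and validate the coupling mathematics end-to-end. Absorbed-fraction
  tables from production Monte Carlo codes can be imported through the same
  CSV schema (`scale,source,target,particle,energy_MeV,af,rel_err`).
* Mesh wrapping and booleans use signed-distance-field iso-surface extraction
  rather than exact-kernel geometry; outputs are watertight and
  offset-compensated, with volumes within ~2% of analytic references at
  default resolutions.
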