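# sdsl

In silico spin labeling of protein structures: attach weighted rotamer
ensembles of spin labels to protein sites, score and trim them against the
local environment, and derive experimental observables — inter-label
distance distributions (DEER-style), spin centroids and membrane depths.
Higher-level protocols built on these primitives: two-state site-pair
screening, portable rotamer-library archives, Markov-chain Monte Carlo side
chain repacking, and rigid-body membrane docking from depth restraints.

## Test

```sh
python -m pytest -q tests/
```

The suite is fully self-contained: all inputs (ideal helices, a toy
nitroxide-like label library, a two-state hinge protein, synthetic depth
tables) are generated by `sdsl.fixtures` at test time. The optional
replication test on maltose binding protein runs only if you place a copy
of the PDB entry 1OMP at `tests/data/1OMP.pdb` (no network access is ever
attempted).

## Library overview

| module            | contents |
| ----------------- | -------- |
| `structure_io`    | PDB read/write (multistate, pseudo-atoms), a small selection grammar, site mutation |
| `rotamer_core`    | `RotamerLibrary` / `RotamerEnsemble` / `SpinLabel`, dihedral geometry, bisect & least-squares backbone superposition, attachment, off-rotamer sampling |
| `energetics`      | flat-top repulsive Lennard-Jones clash score (forgive factor + cap), Boltzmann reweighting, trimming, Shrake-Rupley SASA, SASA-augmented score, pluggable energy-function contract |
| `observables`     | spin centers/centroids, distance distributions, 1-D Wasserstein (earth-mover's) distance, solvent-exposed site-pair screening |
| `library_builder` | create/validate/save/load `.rotlib.zip` archives from multistate conformer PDBs |
| `repack`          | MCMC repacking of labels + neighboring side chains, ensemble extraction from trajectories |
| `docking`         | membrane pose (z + Z-Y-Z Euler angles) least-squares fit from per-site depth data |
| `fixtures`        | deterministic synthetic inputs, incl. an idealized R1-like nitroxide library |

Quick start:

```python
import sdsl
from sdsl.fixtures import make_helix, make_toy_label_library

protein = make_helix(16)                      # or sdsl.read_pdb("file.pdb")
library = make_toy_label_library()            # or sdsl.load_library("x.rotlib.zip")
l1 = sdsl.attach(library, protein, "A", 4)    # clash-aware by default
l2 = sdsl.attach(library, protein, "A", 12)
dist = sdsl.distance_distribution([l1, l2])
print(dist.mode, dist.mean)
sdsl.write_ensemble_pdb("labeled.pdb", protein, [l1, l2])
```

## CLI

Installed as `sdsl`. Subcommands: `attach`, `distances`, `screen`,
`repack`, `dock`, `rotlib {create,validate,info}`, `fixtures make`.

```sh
sdsl fixtures make helix --n-res 16 --out helix.pdb
sdsl attach helix.pdb A:8 --out labeled.pdb
sdsl distances helix.pdb A:4 A:12 --out pr.tsv --plot pr.png
sdsl fixtures make depths --n-res 16 --z 5 --beta 30 --out depths.txt
sdsl dock helix.pdb depths.txt --out pose.json --out-pdb docked.pdb
```

Defaults (forgive factor 0.9, cap 10 kcal/mol, cutoff 10 Å, kT 0.593
kcal/mol, trim tolerance 0.005) can be overridden per flag or via
`--config file` (keys: `forgive`, `cap`, `cutoff`, `kT`, `trim_tol`,
`lj_table_path`, `sasa.probe`, `sasa.n_points`); precedence is
CLI flag > config file > built-in default. Exit codes: 0 ok, 2 usage,
3 data error, 4 degenerate result.

## File formats

* **Rotamer library archives** (`.rotlib.zip`): ZIP containing
  `manifest.json` (names, elements, dihedral quadruplets, spin atoms and
  weights, shapes, SHA-256 checksums) plus raw little-endian float64
  arrays `coords.f64`, `weights.f64`, `dihedrals.f64` (row-major).
* **Ensemble PDB**: the unaltered protein, then one MODEL block per
  rotamer with the rotamer weight in the occupancy column, then `NEN`
  (residue `SCN`) HETATM pseudo-atoms at the rotamer spin centers.
* **Depth tables**: whitespace-delimited `chain resnum depth [sigma]`
  with `#` comments; depths in Å relative to the phosphate plane
  (z = 0, positive into the hydrocarbon core).
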