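# flexgen

Distance-geometry generation of protein conformational ensembles from two
input structures, with perturbation-based prediction of allosteric pockets.

Given two conformations of the same protein, flexgen:

1. classifies every atom pair into one of 15 interaction types (covalent,
   bond-angle, ring, 1–4 dihedral classes, secondary structure, salt bridge,
   hydrogen bond, hydrophobic shells, generic) and derives lower/upper
   distance bounds with a global tolerance weight `wb`;
2. combines the bounds from both structures so every constraint covers both
   observed distances, and subsamples the generic pairs to ~20 per atom;
3. generates structures by stochastic proximity embedding (SPE): random
   coordinates are annealed by repeatedly correcting randomly drawn violated
   constraints under a decaying learning rate; mirror-image solutions are
   fixed, over-generated candidates are filtered by a constraint-violation
   error score (ratio 1.5);
4. auto-selects `wb` by scanning 1.0 → 0.0 in 0.1 steps until an ensemble's
   spread fraction F — the share of models strictly closer (by TM-score) to
   both inputs than the inputs are to each other — reaches 0.9;
5. analyses ensembles: reference-free iterative alignment, average
   structures, Cα covariance PCA with projections, per-residue mean square
   fluctuations and ratios;
6. ranks candidate pockets by simulating a bound modulator: 120 pocket
   points become pseudo-atoms tethered (±0.1 Å) to all protein atoms within
   7 Å, the ensemble is regenerated, and pockets are ordered by the Cα RMSD
   shift of the ensemble average (volume > 13 Å³, at most 8 pockets, 6 Å
   center-to-modulator validation rule).

A synthetic fixture generator (`flexgen.fixtures`) builds an idealized
two-state hinged peptide with realistic covalent geometry, synthetic pockets
and a fake modulator, so the entire pipeline runs and is tested without any
external downloads.

## CLI

```bash
flexgen fixtures --out fx --seed 1                 # synthetic two-state peptide + pockets
flexgen param     --structure-a fx/state_a.pdb --structure-b fx/state_b.pdb \
                  --out run                         # (wb, F) search trace
flexgen generate  --structure-a fx/state_a.pdb --structure-b fx/state_b.pdb \
                  --n-models 50 --wb auto --seed 1 --out run
flexgen allostery --structure-a fx/state_a.pdb --structure-b fx/state_b.pdb \
                  --pockets fx/pockets.tsv --modulator fx/modulator.tsv \
                  --n-models 20 --wb 0.0 --seed 1 --out run
flexgen perturb   --structure-a ... --structure-b ... --pockets fx/pockets.tsv \
                  --pocket-id 1 --out run           # one perturbed ensemble
flexgen msf       --reference run/ensemble.pdb --ensemble other/ensemble.pdb \
                  --out run                         # MSF tables + ratios
```

Options can also come from a YAML config (`--config run.yaml`); flags
override config values. Every run writes `manifest.json` with the resolved
configuration and seed so outputs reproduce bit-for-bit.

Structure inputs are PDB files; DSSP files supply secondary structure when
available (`--dssp`), otherwise a deterministic φ/ψ-window fallback is used.
Pocket points are accepted as TSV (`x y z pocket_id volume`) or PDB-like
point files from any grid pocket finder.

## Layout

| module | contents |
|---|---|
| `flexgen.structure_io` | PDB/ensemble I/O, atom intersection, secondary structure |
| `flexgen.constraints` | interaction classification, bounds, combination, subsampling |
| `flexgen.spe` | SPE engine (numba), chirality fix, error score, ensemble generation |
| `flexgen.autoparam` | TM-score, spread fraction F, automatic `wb` selection |
| `flexgen.analysis` | Kabsch, iterative alignment, PCA, MSF, RMSD |
| `flexgen.perturbation` | pocket filtering/sampling, modulator constraints, ranking |
| `flexgen.fixtures` | synthetic hinged-peptide test protein, pockets, modulator |
| `flexgen.cli` | `flexgen` command-line entry point |
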