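# cdftkit

Conceptual-DFT (CDFT) reactivity descriptors for peptide-sized molecules,
computed from quantum-chemistry *outputs* rather than wavefunctions. The
toolkit parses Gaussian-style text logs (orbital-eigenvalue listings,
Mulliken charge / charges-and-spin-densities blocks) and cube-format
density grids, and derives:

- **Global descriptors** from frontier-orbital energies in the
  Koopmans-type identification I = −εHOMO, A = −εLUMO:
  electronegativity χ = (I+A)/2, hardness η = I−A, electrophilicity
  ω = χ²/2η, electrodonating/accepting powers ω∓ = (3I+A)²/16η and
  (I+3A)²/16η, and net electrophilicity Δω± = ω− + ω+.
- **λmax** from the gap proxy λ = hc/η (hc = 1239.84193 eV·nm).
- **pKa** from the linear hardness relation pKa = 16.3088 − 0.8268 η
  (coefficients overridable).
- **Local descriptors**: condensed Fukui functions from 0/+1/−1
  Mulliken charges (f−ₖ = qₖ(N−1) − qₖ(N), f+ₖ = qₖ(N) − qₖ(N+1)),
  the condensed dual descriptor Δfₖ = f+ₖ − f−ₖ (reported ×100), Parr
  functions from radical-ion spin densities, deterministic
  reactive-site ranking, and volumetric Fukui fields as cube-grid
  density differences.
- A **ΔSCF consistency check** (`kid_deviation`) comparing frontier
  eigenvalues against total-energy differences.

A packaged fixture bundle ships the five virotoxin peptides
(alaviroidin, viroisin, deoxoviroisin, viroidin, deoxoviroidin) with
their published frontier energies and reference descriptor values, and a
synthetic module generates seed-deterministic mock logs and cube triples
with planted ground truth for offline testing.

## CLI

```bash
# global descriptors from JSON records (or QC logs with --format log)
cdftkit fixtures --out fx/
cdftkit global --input fx/records.json --out report.csv

# condensed site analysis from three charge-state logs (+ optional cubes)
cdftkit mock --seed 7 --atoms 10 --out mock/
cdftkit local --neutral mock/neutral.log --cation mock/cation.log \
              --anion mock/anion.log --cubes mock/rho_n.cube \
              mock/rho_nm1.cube mock/rho_np1.cube --out sites.csv
```

`global` accepts a JSON config (`--config cfg.json`) overriding
`pka_intercept`, `pka_slope`, `hc_ev_nm`, `hartree_to_ev` and the report
precisions; flags win over the file. Results go to stdout/files,
diagnostics to stderr (`-v` to raise verbosity). Every constant applied
is recorded in the report metadata.

Reporting rounds half-to-even at the printed precisions (3 d.p. for
descriptors, 2 d.p. for pKa, integer nm for λmax); the reported net
electrophilicity is the sum of the reported (rounded) powers so the
printed columns stay internally consistent. Stored values are always
full precision.

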