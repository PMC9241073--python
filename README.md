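# ticycle

Thermodynamic-integration analysis of **relative binding free energies**
(ΔΔG_b) for single-point protein mutations, built around the CDC42/PAK1
interface mutant panel.

Mutating an interface residue changes how tightly a GTPase binds its
effector kinase. Alchemical free energy calculations quantify that change by
transforming the wild-type residue into the mutant along a coupling
parameter λ, once in the effector-bound complex and once in the unbound
(apo) protein. `ticycle` provides the full *analysis* side of that workflow
for anyone running (or teaching) such calculations:

* **TI estimation** — ΔG = ∫₀¹ ⟨∂V/∂λ⟩ dλ ≈ Σᵢ wᵢ⟨∂V/∂λ⟩ᵢ over an n-point
  Gauss–Legendre λ schedule (the 12-window production rule starts at
  λ = 0.00922 and never touches the endpoints).
* **Uncertainty** — per-window equilibration discard (default first 10 %),
  statistical inefficiency g = 1 + 2ΣC(t) from the autocovariance,
  uncorrelated subsampling, SEM, and forward/reverse convergence profiles.
* **Thermodynamic cycle** — ΔΔG_b = ΔG(complex) − ΔG(apo) with errors
  combined in quadrature, plus co-ion bookkeeping (Na⁺ ↔ water) for
  charge-changing mutations such as D38A, K135Q and Y32K.
* **Atom mapping** — backbone-only (`default`) and maximal-common-
  substructure (`mcs`) partitions into linearly-transformed core atoms and
  softcore unique atoms; the `mcs` scheme reproduces the refined THR→SER
  (−CβHOH common) and PHE↔TYR (ring common, −OH vs −H softcore) mappings.
* **Conformational states** — histogram-based state splitting of a
  side-chain descriptor series (distance or periodic dihedral), occupancy
  reporting and representative-frame selection for choosing the starting
  structure of a transformation.
* **Kd benchmark** — ΔG_b = RT·ln K_d conversion of the experimental mutant
  panel (wild-type K_d = 20 ± 4 nM), with MAE and Pearson-r scoring of any
  computed ΔΔG_b column; the panel table ships as a packaged CSV.
* **Synthetic data** — generators with known ground truth (polynomial
  ∂V/∂λ profiles with AR(1) noise, Metropolis-sampled harmonic and softcore
  Lennard-Jones toy systems, hidden-Markov two-state descriptor series) so
  the whole pipeline is validated end-to-end against closed forms.

## Worked example

Score the computed alchemical estimates against the experimental K_d panel
(conversion at 298.15 K, wild-type self-row excluded):

```console
$ ticycle benchmark --table src/ticycle/data/table1.csv --temperature 298.15
alchemical/all: n=16  MAE=0.4 kcal/mol  r=0.90
(full precision: MAE 0.3606 kcal/mol, r 0.9030)
```

The 16 mutations' computed ΔΔG_b deviate from the K_d-derived experimental
values by 0.36 kcal/mol on average, with a correlation of 0.90 — chemical
accuracy for ranking interface mutations. The alanine subset scores 0.3
kcal/mol for the alchemical route versus 2.7 kcal/mol for MM/GBSA alanine
scanning (`--subset alanine --method alanine_scan`).

Inspect the refined atom mapping that keeps a Thr hydroxyl's interactions
intact while it becomes a Ser:

```console
$ ticycle map --from THR --to SER --scheme mcs
THR → SER  [mcs]
paired:        N↔N, CA↔CA, C↔C, O↔O, H↔H, HA↔HA, CB↔CB, OG1↔OG, HB↔HB2, HG1↔HG
unique source: CG2, HG21, HG22, HG23
unique target: HB3
```

Only the Thr methyl group (CG2 + three hydrogens) and one Ser β-hydrogen
are created/annihilated via softcore; the shared −CβHOH group transforms
linearly.

End-to-end with synthetic data and known truth:

```bash
ticycle simulate harmonic --k0 1 --k1 4 --kt 1 --seed 1 --out-dir sim/
ticycle estimate --manifest cycle.yaml --out result.json
```

where `cycle.yaml` lists the two legs' schedule and window files; the
harmonic system's exact ΔG = (kT/2)·ln(k₁/k₀) = 0.6931 is written to
`sim/ground_truth.json` for comparison.

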