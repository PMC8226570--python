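# porinperm

Scoring compound permeability through bacterial porins, and relating it to
whole-cell accumulation in Gram-negative bacteria.

## The problem

Most polar antibacterials enter Gram-negative bacteria such as *E. coli*
through general porins (OmpF/OmpC) in the outer membrane. Whether a
compound permeates well is governed by a small set of physical
descriptors of the molecule–pore interaction: its **net charge** *Q*
(cation-selective porins have a negative internal potential), the
**transversal component of its dipole moment** *D* (the part
perpendicular to the molecule's main inertia axis, which couples to the
pore's transversal electric field), and its **minimal projection area**
(MPA) — the smallest shadow the molecule can cast — together with the MPA
fluctuation across conformers, which measures flexibility against the
pore's hourglass-shaped constriction.

`porinperm` computes these descriptors from conformer ensembles, scores
log-permeability through a configurable porin with the linear
interaction-based scoring function

```
P = α·U_steric + β·Q·V_pore + γ·D·E_pore + δ
U_steric = ln Φ( (A_pore − MPA) / sqrt(σ_pore² + σ_MPA² + ε²) )
```

(Φ the standard normal CDF), expresses scores as a percentage of
glycine's permeability (`100·exp(P − P_glycine)`), and reproduces the
accumulation analysis: discard compounds below the assay detection limit
(45 nmol per 10¹² CFUs) and non-porin permeants (alogP > 2.9), categorise
both axes, and regress ln(accumulation) on ln(percent permeability).

It is written for computational chemists and medicinal chemists screening
compound series for Gram-negative uptake, in scikit-learn style:
`PorinPermeabilityModel` is a fit/predict estimator (OLS coefficient
calibration, linear scoring) and `ConformerDescriptorCalculator` a
transformer, so both compose with sklearn pipelines.

Because the underlying experimental accumulation table is not
redistributable and the trained coefficients are unpublished, the package
ships a first-class synthetic-data generator that emulates the dataset's
structure (189 compounds, charges −2..+2, ~13% high accumulators, a
log-linear permeability–accumulation link with noise calibrated to a
target Pearson R = 0.74) plus clearly-labelled illustrative pore/
coefficient configs, and a `calibrate` command to fit coefficients to
your own reference permeabilities.

## Worked example

```sh
porinperm simulate --out table.csv --seed 42
porinperm pipeline --in table.csv \
    --config src/porinperm/data/ompf_example.yaml --out-dir run42
```

prints

```
wrote 189 rows to table.csv (+table.params.json)
n=137  R=0.783  p=1.29e-29
report written to run42/report.json
```

The generator drew 189 compounds of which 35 fall below the 45 nmol per
10¹² CFUs detection cutoff and 18 are non-polar (alogP > 2.9), with one
compound failing both rules, leaving 137 analysed compounds
(`report.json` → `filter_audit: {total: 189, low_accumulation: 35,
nonpolar: 18, overlap: 1, kept: 137}`). On those 137, the correlation
between ln(accumulation) and ln(predicted percent permeability) is
R = 0.783 for this seed (the generator's planted target is 0.74; single
tables scatter around it), with a vanishing p-value. The report also
contains the accumulation category counts (here 79 low / 42 accumulator /
16 good / 0 excellent) and the permeability × accumulation
cross-tabulation.

The same analysis from Python:

```python
from porinperm import GeneratorConfig, generate_table, run_pipeline

cfg = GeneratorConfig()
table, params = generate_table(cfg, seed=42)
per_compound, report = run_pipeline(table, cfg.pore, cfg.true_coefficients)
print(report["regression"])   # {'n': 137, 'r': 0.783, ...}
```

Real structures enter through `porinperm descriptors --in compounds.sdf
--charges charges.csv --alogp alogp.csv --out descriptors.csv` (or a
SMILES file with seeded conformer embedding), after which `score` and
`pipeline` operate on the descriptor CSV.

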