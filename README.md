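# qaffp

**QSAR-predicted affinity fingerprints with conformal applicability domains.**

`qaffp` describes a small molecule not by its substructures but by its
*predicted biological activities* across a reference panel of protein-target
assays.  For each assay in a curated activity table it trains a random-forest
QSAR regression model on 1024-bit Morgan2 (ECFP4-equivalent) fingerprints,
admits the model to the panel only if it passes a quality gate
(cross-validated q² ≥ 0.5 and test-set R'₀² ≥ 0.6, where R'₀² is the
determination coefficient of the predicted-vs-observed fit through the
origin, slope k' = Σyŷ/Σŷ²), and wraps it in a normalized conformal
regressor whose prediction-interval width defines the model's applicability
domain (AD): the nonconformity score is α = |y − ŷ|/λ with λ an
error-forest's predicted absolute residual, and a prediction is in-domain
when its interval at confidence 0.90 is narrower than 4.0 log units.

Any molecule can then be fingerprinted:

* **rv-fingerprint** — the vector of predicted activities (−log10 M;
  5 = 10 µM, 6 = 1 µM, 7 = 100 nM, 8 = 10 nM), optionally imputing
  out-of-domain components by the molecule's mean reliable prediction;
* **b-fingerprint** — the same vector binarized at an activity cutoff
  (default 5), with out-of-domain components set to 0 (a compound outside a
  model's domain is more likely inactive than active).

Evaluation harnesses for the three standard ligand-based virtual-screening
tasks are included: similarity searching (MAX group fusion, Rogot-Goldberg
index for binary affinity fingerprints, Tanimoto for Morgan2), bioactivity
classification (balanced random forests, 5-fold CV × 10), and scaffold
hopping (retrieval of unseen cyclic skeletons, the all-carbon single-bond
reduction of Bemis-Murcko scaffolds).  Scheme comparisons use an exact
Wilcoxon paired signed-rank test.  A synthetic-data module generates assay
and benchmark sets with planted, fully known structure-activity signal and
scaffold families, so the whole pipeline is testable without any download.

The intended audience is cheminformaticians studying biological (rather than
structural) similarity: affinity fingerprints excel precisely where
structural fingerprints cannot — finding actives whose chemotype differs
from everything in the query set.

## Worked example

Build a panel from synthetic assays, fingerprint two molecules, and run a
benchmark:

```bash
qaffp synth assay --out data --seed 1 --n-assays 3 --n-compounds 100 --noise-sigma 0.1
# -> wrote 300 activity records for 3 assays to data/activities.csv

qaffp build --activities data/activities.csv --out panel --seed 7 --cv-repeats 1
# -> panel of 2 gated assays written to panel

printf 'c1ccc2nc(CCO)ccc2c1\nCC1CCC(N)CC1\n' > query.smi
qaffp fingerprint --panel panel --smiles query.smi --mode rv --out fp.csv
# -> wrote 2 rv fingerprints of length 2 to fp.csv
cat fp.csv
# smiles,SYN001:IC50,SYN002:IC50
# OCCc1ccc2ccccc2n1,4.46458,7.13671
# CC1CCC(N)CC1,5.84662,7.32068
```

One of the three assays failed the quality gate (its q² fell below 0.5 on
this small synthetic set), so the panel — and every fingerprint — has two
positions.  Each column is one panel assay; the numbers are predicted
activities on the −log10 M scale, so 7.14 means the first molecule is
predicted to act on assay `SYN002:IC50` at about 70 nM potency, while 4.46
on `SYN001:IC50` is weaker than 10 µM, i.e. effectively inactive.  With
`--mode b` the same values are binarized at the cutoff (default 5 = 10 µM)
with out-of-domain predictions zeroed.  `panel/build_report.json` records
each assay's q², R'₀² and gate decision.

Benchmark sets live one-per-directory (`actives.smi`, `inactives.smi`,
`manifest.json`; `qaffp synth classset` writes them):

```bash
qaffp bench sim hop --panel panel --sets sets/ --out results --seed 5 --fp morgan2 --fp b
```

writes one tidy CSV of per-repetition AUC/EF5 per task plus a
`summary.json` with per-scheme means and exact-Wilcoxon scheme comparisons.

The same API is available from Python (`qaffp.pipeline.run_build`,
`qaffp.fingerprint.rv_qaffp`, `qaffp.benchmarks.run_similarity_benchmark`,
...); see `docs/methods.md` for the model details and every tunable.

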