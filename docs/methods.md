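# Methods

## The affinity-fingerprint model

A structural fingerprint describes a molecule by the substructures it
contains; an *affinity fingerprint* describes it by how strongly it is
predicted to act on a reference panel of protein-target assays.  This package
builds such panels from curated dose-response data and emits two fingerprint
variants per molecule:

* **rv** (real-valued): the vector of point predictions, one per panel assay,
  on the -log10 molar (pChEMBL-like) scale where 5 = 10 uM, 6 = 1 uM,
  7 = 100 nM and 8 = 10 nM;
* **b** (binary): the rv vector thresholded at an activity cutoff
  (default 5), with components whose conformal prediction interval is too
  wide set to 0 on the grounds that a compound outside a model's
  applicability domain is more likely to be inactive than active.

## Curation

An *assay* is one organism/target/activity-type combination.  Records are
kept when the activity type is IC50, EC50, Ki or Kd, the relation is exactly
"=", and the provenance confidence score is 7 or 9.  Replicate measurements
of one compound-assay pair are averaged only when their sample standard
deviation is below 0.5 log units; discordant pairs are discarded outright
(per pair — the compound survives in other assays).  Assays enter QSAR
modeling only with strictly more than 50 distinct compounds.  Input
activities must be on the -log10 M scale; a logged converter from molar
concentration units is provided.  Inputs are assumed pre-standardized; the
parser's only salt handling is keeping the largest covalent fragment, with a
warning.

## Per-assay QSAR models and the quality gate

Molecules are encoded as 1024-bit Morgan fingerprints of radius 2 (the ECFP4
equivalent).  Each assay gets a 100-tree random-forest regressor with every
feature considered at each split.  Ligand sets are split 80:20 into training
and test portions, stratified on activity: compounds are sorted by activity,
cut into consecutive blocks (size 5 for an 80:20 split; size k for k folds),
and dealt randomly within each block.  This block scheme is our convention
for stratifying a continuous response; it guarantees both portions span the
activity range and that fold sizes differ by at most one.

Internal fit is measured by q², the coefficient of determination of k-fold
cross-validation (k = 10, repeated 10 times by default; the statistic is the
mean of per-fold q² values, not a pooled-prediction q²).  External
predictivity is measured on the held-out test set by R'₀², the determination
coefficient of the predicted-vs-observed regression forced through the
origin with slope k' = Σyŷ / Σŷ².  A model joins the panel only when
q² ≥ 0.5 **and** R'₀² ≥ 0.6, both inclusive.

## Conformal applicability domain

Around each point model sits a normalized conformal regressor.  A second
random forest, the *error model*, predicts the expected absolute residual
λ(x); the nonconformity score of a compound is α = |y − ŷ| / λ.  The error
model's training targets are the point forest's out-of-bag residuals: each
tree's OOB sample never trained that tree, so these are out-of-fold
predictions obtained without extra model fits, avoiding the optimism of
in-sample residuals.  λ is floored at 0.01 log units to keep the score
finite.

Two calibration regimes are implemented.  **ICP** holds out a single
calibration split (default 30% of the training portion).  **CCP** rotates
the calibration role over k = 10 folds, pools all scores into one table, and
refits the point and error models on the full data.  For a new compound the
interval at confidence 1 − ε is ŷ ± λ(x)·α*, where α* is the
⌈(1 − ε)(n + 1)⌉-th smallest calibration score (the standard finite-sample
order-statistic convention; the interval is infinite when the index exceeds
n).  A prediction is *in-domain* when the interval width 2·λ·α* does not
exceed 4.0 log units (± 2.0) at confidence 0.90.

Open choices we fixed: the error-model target is the *absolute* residual
(it scales an absolute-value score); CCP pools scores rather than
aggregating per-fold intervals.

## Fingerprint emission

The panel is the ordered (by assay id) collection of gate-passing conformal
bundles; its order defines fingerprint positions and is persisted with the
panel.  rv components may optionally be imputed: an out-of-domain component
is replaced by the mean of that molecule's in-domain components (per
molecule, across assays — the per-assay alternative would make single-
molecule fingerprinting impossible).  Recommended defaults follow the
package's own evaluations: rv with raw values and no AD handling; b with
cutoff 5, ICP AD at confidence 0.90, maximum width 4.0 and out-of-domain
bits zeroed.  Assays overlapping a benchmark's target can be masked from the
panel to avoid leakage.  Z-standardization of rv matrices (population SD;
constant columns zeroed with a warning) is available but optional.

## Evaluation harnesses

*Similarity searching* ranks a test pool by its maximum Rogot-Goldberg
(binary affinity fingerprints) or Tanimoto (Morgan2) similarity to a set of
query actives — MAX group fusion.  Heterogeneous (HET) sets run 50
repetitions of 10 random query actives with 20% of inactives withheld;
homogeneous (HOM) sets run once with a configurable query fraction (default
half the actives) and 10% of inactives withheld, optionally capping the
number of test actives.  The Rogot-Goldberg index
a/(2a+b+c) + d/(2d+b+c) credits shared off-bits as well as shared on-bits,
which matters for binary affinity fingerprints where inactivity is as
informative as activity; a term with zero denominator contributes 0.

*Classification* uses balanced random forests (each tree grown on an
equal-size bootstrap from each class, GINI criterion, 100 trees) under
5-fold cross-validation repeated 10 times.  CLASS-style sets require
strictly more than 60 actives and 60 inactives, with labels from the
activity rule ≤ 5 inactive / ≥ 6 active (the gap between 5 and 6 is
unlabeled).  The balanced forest is implemented in-package
(`qaffp.ensemble`) as per-tree equal-size class bootstraps over scikit-learn
decision trees.

*Scaffold hopping* reduces every active to its cyclic skeleton (CSK): the
Bemis-Murcko scaffold with all heavy atoms converted to carbon and all bonds
to single order.  Exocyclic atoms double-bonded to the scaffold are retained
by the extractor before reduction (a documented convention).  CSKs with at
least five active members (RACSKs) each seed a training set of that CSK's
actives plus all inactives; a balanced forest classifies the remaining
actives at probability threshold 0.5, and the CSKs of predicted actives are
unioned over all training sets.  Pooling two schemes' results is a set
union.

Performance is summarized by ROC AUC (Mann-Whitney form, ties credited 1/2)
and the enrichment factor in the top χ = 5% of the ranked list, with
N_χ = ⌈χ·N⌉ and boundary ties broken by a seeded pre-shuffle before a stable
sort so the value is order-independent.  Scheme comparisons use the exact
Wilcoxon paired signed-rank test — the null distribution of the
positive-rank sum is enumerated exactly over all 2ⁿ sign assignments (as a
convolution equivalent to the explicit enumeration; midranks handle ties,
zero differences are dropped with a logged count, and n > 25 is refused in
favor of a normal approximation) — and the signed-rank-inverted
(Hodges-Lehmann) confidence interval over Walsh averages.

## Synthetic data: what it emulates and what it does not

The generator enumerates ~6000 valid molecules from a fragment grammar of
ring cores grouped into seven CSK families (six-membered rings, five-
membered rings, fused 6-6, biphenyl-like, fused 6-5, diarylmethane, seven-
membered rings) crossed with small substituents.  Assay-level sets assign
activity = offset + sparse linear function of fingerprint bits + Gaussian
noise, clipped to [3, 11]; signal bits are drawn among bits present in
10-90% of the library so every signal bit varies.  CLASS-style sets plant
actives across a chosen number of CSK families (one family always has ≥ 5
members, guaranteeing a RACSK) and attach a shared sulfonamide "marker"
substituent to actives with probability `hop_signal`, making cross-scaffold
generalization possible exactly to a known extent; a manifest records the
true family memberships for oracle checks.

This emulates the *structure* of real assay data — controllable
signal-to-noise, scaffold families, class imbalance — but not its chemistry:
real structure-activity landscapes are not linear in fingerprint bits, real
scaffold families are not marked by a single substituent, and the library's
property distributions are far narrower than a screening deck's.  Passing
tests therefore demonstrate that the machinery is correct and recovers
planted signal, not that any particular real-world retrieval rate will be
achieved.

## Numerical choices and problem sizes

* Master seed: every stochastic choice (splits, folds, bootstraps, query
  sampling, tie-breaks) derives from one integer via a stable mixing
  function, so equal configurations give byte-identical outputs.
* Conformal validity study (`qaffp.validation.icp_coverage_study`): 3
  independent replicates of a 5050-compound synthetic assay (noise σ = 0.4),
  each split 600 proper-training / 2500 calibration / 1950 test, pooling
  ~5850 intervals at confidences 0.80/0.90/0.95.  Pooling over replicates
  measures the *marginal* coverage guarantee rather than the coverage of one
  calibration draw.  Forests use 50 trees here; coverage is guaranteed
  regardless of model quality.
* Desk-scale study conditions elsewhere: ligand sets of 100-400 compounds
  (the package's choice of a realistic small-assay size), gating studies
  with one cross-validation repeat, and a 20-assay end-to-end panel.
* Degenerate inputs: constant observed activities make q²/R'₀² undefined
  (explicit error); all-zero predictions make the origin slope undefined;
  folds with constant activity are excluded from q² with a warning; two
  all-zero vectors have Tanimoto 0 (warning) and Rogot-Goldberg terms with
  empty denominators contribute 0.

## Known limitations

* The balanced forest supports binary classification only.
* The exact Wilcoxon test is limited to 25 informative pairs; larger samples
  need a normal-approximation test not provided here.
* No tautomer handling, stereochemistry-aware scaffolds, or 3D structure.
* Panel composition is taken as given; no optimization of which assays make
  the most informative fingerprint.
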