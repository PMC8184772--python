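# Methods

`cytogravity` re-implements, as a tested pipeline, a single-cell
mass-cytometry analysis of how simulated microgravity (sµG, produced by
a rotating wall vessel) reshapes human peripheral immune function. The
design it emulates: PBMCs from 8 healthy donors, exposed 18 h to 1G or
sµG, analyzed unstimulated (0 h) and after ConA/anti-CD28 stimulation
(4 h; a 1.5 h timepoint is generator-supported but unused by default),
on a 41-channel panel (21 surface, 14 functional, 6 Pd barcode).

## Synthetic-data generator

No public machine-readable accession exists for the original raw events,
so the package's canonical input is synthetic, with ground truth carried
alongside. Per cell:

* subset membership is multinomial over the 18 gating-tree leaves with
  PBMC-realistic default proportions (e.g. CD4 T 30%, cMC 12%, NK
  CD56dim 10%, Tregs 5%, pDC 1%);
* surface markers are Gaussian on the arcsinh scale around a low band
  (mean 0.6) or high band (mean 3.5), SD 0.35, according to the leaf's
  phenotype as implied by its gating path; markers off the path are
  negative;
* functional markers are Gaussian (SD 0.3) around
  `base (1.0) + donor intercept + stimulation response + condition shifts`;
* arcsinh draws are inverse-transformed (`sinh(z) * cofactor`, cofactor
  5) and floored at 0, so raw intensities are nonnegative ion-count-like
  values.

Donor structure has two components, both shared across a donor's four
samples: an additive intercept per (donor, marker) (SD 0.2) that makes
the paired design non-trivial, and a per-(donor, marker) random
stimulation-response slope (SD 0.15) modeling inter-donor differences in
pathway responsiveness. The slope is what gives real-data-like
inter-correlation of same-marker response features across subsets —
without it the correlation network is essentially edgeless and the
elastic net faces an unrealistically easy independent-features problem.

Condition effects (`EffectSpec`) act on three axes: stimulation (shifts
in all stimulated samples), gravity (basal sµG shifts, present in
stimulated and unstimulated samples, hence cancelling out of response
features), and gravity x stimulation (sµG shifts of the stimulation
response). The default spec encodes the qualitative sµG phenotype the
package is built around: pSTAT5 response increased in naive and memory
Tregs (+1.0 arcsinh unit); CD25 response decreased in CD8 T subsets and
CD56dim NK cells; CD69 decreased in CD4 and CD8 T subsets; pSTAT1
decreased in CD8 T subsets (all -1.0); plus basal-tone decreases (-0.5)
for Treg pSTAT5 and mDC MyD88-pathway markers.

What the generator does **not** model: instrument artifacts (doublets,
bead-normalization drift, spillover), cell-cell heterogeneity beyond a
single Gaussian band per (subset, marker), non-Gaussian tails, and
subset-specific stimulation kinetics. Passing tests therefore show the
analysis machinery is correct and calibrated under a plausible
generative model — not that the biology of any real dataset is
reproduced.

## Barcoding

Samples are keyed by exactly-3-of-6 palladium combinations (C(6,3) = 20
keys, lexicographic). Simulated barcode channels are two Gaussian bands
on the arcsinh scale separated by 3.0 units (SD 0.3). Debarcoding
assigns an event to a key iff its 3 brightest barcode channels equal the
key's positive set and the gap between dimmest-positive and
brightest-negative exceeds a margin (default 1.0 arcsinh unit); ties or
insufficient separation leave the event unassigned. Accuracy approaches
100% at the default separation and collapses to near-zero assignment as
separation goes to 0.

## Gating and features

Gating is a deterministic tree of 1-D threshold rules on arcsinh-scale
surface intensities (positive: value > threshold; negative: <=). The
default 18 leaves are: cMC, intermediate MC, ncMC, mDC, pDC, B naive,
B memory, NK CD56dim CD16+, NK CD56bright CD16-, NKT, gdT, CD4/CD8 T
naive and memory, Treg naive/memory, and a Lin- remainder. A single
default threshold (2.05) sits midway between the generator's bands;
real data would supply a custom tree with per-marker thresholds. Events
stopping at an internal node are unassigned.

Features per (subset, marker): **response** = arcsinh-scale median in
the 4 h stimulated sample minus the 0 h unstimulated median (the asinh
ratio; 18 x 14 = 252 features), **basal** = unstimulated medians,
**abundance** = gated leaf frequencies. Medians (not means) are used
throughout. A feature needs >= 20 cells in the subset (min_cells,
configurable); otherwise it is NaN, and the elastic-net stage imputes
per-column medians while reporting which columns were imputed.

## Elastic net

The model minimizes `|Y - Xb|^2 + l1*|b|_1 + l2*|b|_2^2` with Y in
{-1 (1G), +1 (sµG)} — a squared-error fit to the binary outcome, not
logistic regression. The ridge term is squared; the unsquared-norm
variant of the objective is available for reporting only. Cyclic
coordinate descent with exact soft-threshold updates runs on internally
standardized features (Gram formulation, numba-accelerated inner loop
with a pure-numpy fallback); the objective is non-increasing per sweep
and non-convergence is flagged, never silent. Penalties are
parametrized as l1 = a*l, l2 = (1-a)*l with mixing a = 0.5 and a
50-point log grid spanning 4 decades down from the data-derived
l_max = 2*max|x_j'(Y - Ybar)| / a.

Cross-validation is leave-one-donor-out with both of a donor's rows held
out together and per-fold standardization, preventing donor leakage in
the paired design. The per-lambda error is the paired sign error of
pair-centered out-of-fold scores (ties count 1/2). Both lambda_min
(largest lambda attaining the minimal error — note that in strongly
separable synthetic data the error curve hits 0 over a wide range, so
this tie-break matters) and lambda_1se are reported; lambda_1se is the
default reported model.

**Model significance.** The naive construction — Wilcoxon signed-rank on
per-donor out-of-fold score differences at the CV-chosen lambda — is
anti-conservative: lambda is selected on the very fold scores being
tested. The pipeline instead uses nested cross-validation
(`nested_model_significance`): for each held-out donor, lambda is chosen
by an inner leave-one-donor-out CV on the remaining donors only, a model
is refit on them at that lambda, and the held-out pair is scored. The
per-donor differences then go to the exact Wilcoxon signed-rank test
(complete sign-assignment distribution, midranks for ties, zeros
dropped; normal approximation with tie correction beyond n = 25). With 8
donors the smallest attainable two-sided p is 2/256 = 0.0078125; a
claimed paired p of order 1e-4 is not attainable from an exact
8-pair test. Residual cross-donor dependence of CV scores can still
inflate the test slightly when features are very noisy; at the problem
sizes used here the measured null rate is consistent with the exact
discrete level.

## Univariate screen and FDR

Each response feature is tested by the exact paired Wilcoxon on
per-donor (sµG - 1G) differences, then screened by the two-stage
adaptive linear step-up FDR procedure at q = 0.01: stage 1 at
q' = q/(1+q) giving r1 rejections; m0 = m - r1; stage 2 at q*m/m0
(stage-1 outcomes of 0 or m are final). Note the structural consequence
of exactness at n = 8: with a p-floor of 0.0078 no feature can clear a
q = 0.01 step-up threshold over 252 tests, so the default screen
reports zero discoveries at desk scale — the multivariate model and its
nested significance, not the univariate q-values, carry the inference.
The same screen runs on the 18 abundance features (where no effect is
injected, and none is expected).

## Correlation network

Spearman correlations are computed between all response-feature pairs
over all sample rows (both gravity conditions pooled). An edge requires
raw p * C(n_nodes, 2) < 0.05 (Bonferroni). Pair p-values use the exact
permutation null of S = sum of squared rank differences whenever the
pair is tie-free and 4 <= n_rows <= 16 (precomputed by a bitmask dynamic
program, shipped as package data, verified against full enumeration for
n <= 8; n <= 13 computed on demand); otherwise the t approximation. The
exact tail matters: at n = 16 the t approximation is about twice as
liberal at family-wise thresholds, which visibly inflates the number of
false edges in null data. Communities are greedy-modularity partitions
of the |rho|-weighted significant-edge graph (isolated nodes become
singletons), each annotated by its most frequent functional marker (ties
alphabetical, flagged). The 2-D layout is t-SNE on the 1 - |rho|
distance with perplexity min(30, (n-1)/3) and a fixed seed. The number
of communities is a data-dependent observation, not a contract.

## Pipeline, determinism, problem sizes

`run_pipeline` executes simulate → gate → features (response, basal,
abundance) → paired screens → elastic nets (response and basal) →
network, writing CSV/TSV/GraphML/JSON artifacts; every randomized stage
derives its seed from the global seed plus a fixed per-stage offset, so
identical config + seed reproduce byte-identical outputs and any stage
can be re-run in isolation from saved artifacts. qPCR
relative quantification (2^-ddCt) is provided as a small utility.

Default problem sizes were chosen to keep full runs at interactive
speed: 8 donors x 5000 cells/sample for headline runs and recovery
replicates; 1000 cells/sample with a 15-point lambda grid for the
200-replicate null-calibration studies; smaller fixtures in unit tests.
The methods and conclusions do not depend on these sizes; they only set
Monte-Carlo precision.

## Known limitations

* Real-data input is CSV event tables with JSON metadata; FCS files are
  not parsed.
* Rectangular 1-D gates only; no polygons, back-gating, or automated
  population discovery.
* The exact-S network tail requires tie-free ranks and n <= 16 rows;
  otherwise the liberal t approximation is used and Bonferroni edges
  should be read accordingly.
* The univariate q-value screen is structurally powerless at n = 8 with
  exact tests (see above); it is retained for fidelity and for larger
  designs.
* `model_significance` (single-layer) is retained for interface
  completeness but is optimistically biased; prefer the nested variant.
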