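# Methods

This note documents the models implemented in `grainfill`, the assumptions
behind them, the parameters that matter, and what the synthetic-study
generator does and does not emulate.

## Study design

The reference design is a balanced complete factorial over three barley
genotypes (the mother line Bomi, the high-lysine mutant *lys3.a*, the
high-β-glucan / low-starch mutant *lys5.f*), two growth temperatures (LT =
15 °C, HT = 25 °C) and eight grain-filling sampling days (9, 13, 16, 20, 23,
30, 39, 47 days after flowering), with two biological replicates per cell:
96 samples. Balance is not cosmetic: it is what makes the ASCA effect
matrices mutually orthogonal, so each term's share of the total sum of
squares is unambiguous. Unbalanced designs are rejected rather than
approximated.

## Synthetic-data generator

The generator is the package's substitute for field and instrument work; its
defaults define the study conditions every test and the acceptance script
run under.

**Concentration model.** Per-seed concentration of metabolite *k* in sample
*i* is

    conc(i,k) = baseline · trend_k(DAF_i) · (1 + δ·membership) · exp(ε),
    ε ~ N(0, noise_sd²)

* Trends are logistic in DAF (accumulation rising, depletion falling,
  midpoint 20 DAF, rate 5 days) or a Gaussian bump peaking at 23 DAF
  (σ = 6 days) for the transient class; flat metabolites have no trend.
  These smooth monotone/unimodal forms are the simplest shapes consistent
  with the three observed developmental patterns.
* Replicate noise is multiplicative log-normal: peak areas are positive and
  right-skewed, and between-plant variation scales with abundance.
* Default allocation at 247 variables: 136 accumulating, 28 depleting,
  10 transient, 73 flat; 72 genotype markers (27 Bomi / 21 lys3.a /
  24 lys5.f, δ_GT = 0.55), 14 temperature markers (9 LT / 5 HT,
  δ_TEMP = 0.15), and 18 metabolites per genotype with a mean-free
  genotype-specific DAF modulation (δ_GT×DAF = 0.8). Effect magnitudes are
  free parameters of the generator — the study system reports which effects
  exist and how much variance each explains, not per-metabolite sizes — and
  were fixed once so that the default study's ASCA partition has the
  realistic structure: DAF ≈ 29 %, GT×DAF ≈ 11 %, GT ≈ 7 %, TEMP ≈ 0.9 %,
  residual ≈ 45 %. The planted temperature effect is deliberately the
  smallest term and sits at the edge of permutation detectability.

**Measurement model.** The detector sees a fixed flour mass, so the injected
area of every metabolite is diluted by seed dry matter (logistic growth from
5 to 45 mg per seed, midpoint 22 DAF — the closure effect driven by starch
accumulation) and multiplied by an injection/extraction factor shared with
the internal standard (log-normal, CV = 10 %):

    area(i,k) = conc(i,k) · (w_ref / seed_weight_i) · inj(i)
    IS(i) = IS_baseline · inj(i)

Dividing by IS removes `inj`; multiplying by seed weight removes the
dilution. The pipeline's `Xi = X/IS` then `Xs = Xi × Seed` recovers `conc`
up to a constant, which is the property the closure tests check.

**Chromatographic rendering.** Each metabolite occupies one elution-time
interval (default geometry 4800 points × 450 m/z channels in 121 intervals;
tests use smaller cubes of identical structure), with a Gaussian elution
profile (σ = 3 points) normalised to unit time integral, a fixed sparse
non-negative unit-norm spectrum (~4 % occupied channels), a flat baseline
and truncated-Gaussian detector noise (intensities stay non-negative). The
internal standard gets an interval of its own, and its interval/apex are
recorded in the cube metadata — the synthetic analogue of knowing the spiked
standard's retention time. Retention drift is drawn per sample *per
interval* and shared by all compounds eluting there (rigid local drift,
truncated at ±3σ so peaks stay inside their interval). This is the
physically sensible model of slow drift, and it is also what keeps the
cross-products of co-eluting elution profiles constant across samples —
independent per-compound shifts would place the truth outside the PARAFAC2
model class entirely.

**What the generator does not emulate:** derivatization chemistry, realistic
EI fragmentation patterns, retention-index calibration, peak tailing or
saturation, missing values, and drift in spectral response. Passing tests
therefore demonstrate that the chain recovers planted structure under
idealised chromatography with realistic design-level noise, not that it is
robust to every artefact of real instruments.

## PARAFAC2 deconvolution

Sample slabs of one interval are modelled as `X_k ≈ P_k B diag(c_k) Aᵀ`
with `P_k` (time × R) orthonormal, `B` (R × R), `A` (m/z × R); the
orthonormality of `P_k` enforces the constant cross-product constraint
`(P_k B)ᵀ(P_k B) = BᵀB` that lets elution profiles shift per sample while
the decomposition stays identifiable. The solver is direct-fit alternating
least squares: orthogonal-Procrustes update of every `P_k` (batched SVD),
then one CP-ALS sweep on the rotated slabs `Y_k = P_kᵀX_k`. The loss is
monotone non-increasing; iteration stops when its relative change drops
below 1e−8 (cap 2000 iterations; hitting the cap flags `converged=False`
but is not an error). Initialisation is deterministic — `A` from the top
eigenvectors of `Σ_k X_kᵀX_k`, `B = I`, `c_k = 1` — so identical data yield
identical models and no RNG is involved.

Scale/sign indeterminacy is fixed by normalising the columns of `A` and `B`
to unit norm, pushing magnitude into `C`, flipping `A` columns so spectra
are non-negative-dominant, and flipping `B` so concentrations come out
positive-dominant. No non-negativity constraint is imposed during ALS;
instead each component must pass validation: spectral negativity fraction
≤ 10 % (entries below −1 % of the spectral maximum), apex strictly inside
the interval, and median signal-to-noise ≥ 5 across samples. The rank of
each interval is the largest R (up to `R_max`) for which every component
validates and each added component improves the fit by at least 1
percentage point; pure-noise intervals get R = 0. All validation thresholds
are configurable (`ValidationRules`) because published validation practice
varies between laboratories.

Before fitting, each sample's per-channel median over time is subtracted
(flat-baseline correction); without it the baseline itself appears as a
spurious low-SNR component.

## Preprocessing

The stage order raw → Xi → Xs → scaled is enforced by the
`MetaboliteTable` object: the transforms do not commute and downstream
statistics are defined on `Xs`. Scaling defaults to autoscaling (columns
centred, unit sample SD); Pareto and centre-only are selectable since the
choice of scaling is a study-level decision. Zero-variance columns are
centred, flagged and excluded from VIP ranking rather than dropped.

## ASCA

Main-effect rows are level means minus the grand mean; interaction rows are
cell means minus both level means plus the grand mean; the residual absorbs
replicates and higher-order structure. Six terms are always reported (three
mains, three two-factor interactions). Permutation tests use the term's SSQ
as the statistic: main effects permute the factor's labels over rows;
interactions first remove both observed main effects and then permute the
cell labels of the residualised data. p-values use the add-one convention
`(1 + #{perm ≥ obs})/(1 + n_perm)`, so the attainable floor at 1999
permutations is 5e−4 and p = 0 never occurs. PCA of an effect matrix
defaults to the pure (level-constant) matrix; an `augment_with_residual`
mode projects effect + residual onto the effect's loadings to show
replicate dispersion around level means — both are exposed because either
convention is found in practice.

## PLS-DA, double cross-validation, markers

Multiclass discrimination uses a single PLS2 model against the one-hot
class matrix with arg-max prediction (binary one-vs-rest is the degenerate
case). Model complexity is never chosen on the data that scores it: an
inner stratified k-fold (default 7) picks the number of latent variables
from 1–10 by minimum inner-CV error, an outer stratified k-fold (default 8)
supplies pooled unbiased misclassification and one-vs-rest AUC; regression
(DAF prediction) stratifies folds by the discrete sampling days and reports
r² (squared Pearson correlation of the prediction plot) and RMSEP.

VIP uses the standard weighted-weights formula; `mean(VIP²) = 1` holds
identically. A variable becomes a marker when VIP > 1.0 and its regression
coefficient keeps the same sign in ≥ 80 % of outer folds; it is assigned to
the class where its coefficient is largest (markers are "elevated in" their
class, and per-class sets stay disjoint). Because outer training sets
overlap, fold coefficients are correlated and the VIP/stability rule alone
passes a large fraction of noise variables on null data; selection is
therefore gated on the cross-validated model beating chance (one-sided
binomial test, α = 0.05). A model that does not validate yields an empty,
flagged marker report. The VIP threshold, stability fraction and gate are
all configurable — none has a canonical published value.

## Trends and univariate testing

Per metabolite, the replicate-averaged DAF profile (on `Xs`, not scaled
data) is labelled by Spearman correlation with DAF: ≥ 0.6 accumulation,
≤ −0.6 depletion. The transient label additionally requires an interior
maximum exceeding both endpoints by ≥ 20 % of the profile range *and*
monotone rank behaviour on each side of the peak (segment Spearman ≥ 0.6 up,
≤ −0.6 down) — without the segment condition, replicate noise on flat
profiles routinely fakes an interior maximum. One-way ANOVA per metabolite
and factor is computed by a vectorised F-test; p-values are reported raw
(α = 0.05 convention), with Benjamini–Hochberg columns available by flag
since the error-rate philosophy is a study-level choice.

## Correlation fingerprints

Profiles are replicate means over the eight DAF levels per genotype ×
temperature group (a 16-point replicate-resolved mode exists behind a
flag). Significance of a Pearson coefficient at n profile points uses the
exact t threshold `|r|crit = t_{1−α/2,n−2}/√(n−2+t²)`; for n = 8, α = 0.05
this is 0.70673. Within-group counts scan unique off-diagonal pairs;
between-group matrices are not symmetric and all K² entries count.
Zero-variance profiles yield NaN entries that are excluded from counts and
histograms, which conserve totals by construction. No multiplicity
correction is applied to correlation counts — they are descriptive
fingerprints, not hypothesis tests.

## Pipeline and reproducibility

The CLI pipeline executes simulate → deconvolve → preprocess → asca →
markers → trends → correlate → report in fixed order; each stage reads only
prior-stage files, and a manifest records the configuration hash and
SHA-256 digest of every output. All randomness (generator, permutations,
CV folds) is pinned by explicit seeds in the configuration — a config
without seeds is rejected before execution — so identical configurations
reproduce deterministic-stage digests bit for bit. The bundled small
configuration (24 samples, 40 metabolites, 20-interval cubes of 800 × 60
points) exercises every stage in about half a minute; the statistical
stages of the acceptance script run at the full 96 × 247 scale, with only
the chromatographic rendering reduced (a 4800 × 450 × 96 cube is ~1.6 GB of
float64 and adds nothing statistically to the recovery measurement).

## Known limitations

* PARAFAC2 rank scanning is greedy (stops at the first stalled or invalid
  rank) and can under-split heavily overlapped triplets at low SNR.
* The interaction permutation scheme is approximate (residualised-data
  permutation), as is standard; its type-I error is checked empirically for
  main effects only.
* Marker assignment by largest coefficient forces disjoint per-class sets;
  a metabolite genuinely elevated in two classes is assigned to one.
* The trend classifier assumes a single interior maximum; oscillating
  profiles land in `none`.
* Correlation significance assumes bivariate normality of 8-point profiles;
  with so few points the threshold is best read as a descriptive cutoff.
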