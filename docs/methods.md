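# Methods

## Model

Each pathway assay is a two-layer Bayesian network shaped as a tree. The
root `TF` is a latent binary variable (transcription factor complex
active/inactive). Each curated direct target gene *g* has a latent binary
transcription state `TG_g` (up/down) depending on `TF`, and each
measurement probe/assay *p* of that gene has an observed binary node
(high/low, the measured value dichotomized at a per-probe threshold `t_p`)
depending on `TG_g`. Probes of one gene are conditionally independent given
the gene state, and genes are conditionally independent given `TF` — the
usual naive-Bayes-with-one-extra-layer structure. Measurement platform
(log2 microarray intensity, or ΔCq-normalized qPCR) enters only through
thresholds and emission probabilities; the graph is identical.

Inference marginalizes every `TG_g` analytically, so the posterior log2
odds of activation decompose as the prior log2 odds plus one additive term
per gene:

    L = log2 p/(1-p) + Σ_g log2 [ (a_g·U_g + (1-a_g)·D_g) / (b_g·U_g + (1-b_g)·D_g) ]

with `a_g = P(TG=up|active)`, `b_g = P(TG=up|inactive)`, and `U_g`, `D_g`
the products of the probe-evidence likelihoods under the up and down state.
A `brute_force_infer` oracle recomputes L by summing the full joint over
all latent gene-state configurations (refused above 16 genes); the test
suite holds the two routes to within 1e-9 across random models.

Assumptions worth stating: the panel genes are genuinely *direct* targets
(specificity lives in the panel, not the model); one sample is scored
independently of all others; binary TF and TG states (no graded
activation); and dichotomized measurements (a continuous emission model is
a possible extension, deliberately not implemented).

### Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| `p_tf_active` | prior P(TF active) | 0.5 | makes L = 0 the neutral point |
| `p_up_given_active/inactive` | first-layer coupling | 0.95 / 0.05 | strong but non-degenerate regulation of a curated direct target; swapped for repressed (−1) genes |
| `threshold t_p` | dichotomization cut, measurement units (log2) | calibrated | midpoint of class-conditional medians |
| `p_high_given_up/down` | emission probabilities | calibrated | Laplace-smoothed class frequencies |
| `smoothing_alpha` | pseudo-count | 1 | keeps probabilities strictly inside (0,1) and likelihood ratios finite on small calibration sets |
| `cq_max` | no-amplification cap, cycles | 40 | conventional qPCR cutoff |
| `q` | reference percentile | 95 | upper bound of normal |

Repressed target genes are handled by swapping the first-layer
conditionals, never by negating measurements: the emission layer stays a
pure description of measurement behavior, and one calibration code path
serves both directions.

### Score normalization

The published read-outs are on a 0–100 scale but the mapping from log2
odds is not public, so this package pins its own: `l_min`/`l_max` are the
extreme achievable L over all complete evidence assignments (computable
per gene because the model factorizes; per-gene extremes found by
enumerating that gene's probe states), and
`S = 100·(L − l_min)/(l_max − l_min)` clamped to [0,100]. This makes S
model-intrinsic, deterministic, and attains 0/100 at maximal evidence.
Under the symmetric defaults `l_min = −l_max` exactly and S = 50 at L = 0.
The ratio is computed before multiplying by 100 so the symmetric anchors
(50, 100) are floating-point exact. A fully uninformative model
(`l_max = l_min`) reports the neutral score 50. Comparisons with published
score values are therefore qualitative; rankings and threshold calls, not
absolute scores, are the transferable quantities.

### Missing data

A missing measurement (NA, absent probe, Cq past `cq_max`) contributes a
likelihood factor of exactly 1: the gene term of a fully missing gene is 0.
This is deliberate — an unexpressed or dropped-out target gene should pull
the sample toward "no information", not toward "pathway off". A sample with
*no* observed probe at all raises an explicit no-evidence error rather than
silently reporting the prior; the brute-force oracle, by contrast, returns
the degenerate posterior (L = prior log2 odds) for empty evidence, which is
also the documented analytic anchor.

## Calibration

Ground-truth samples (known active/inactive status) calibrate the second
layer only; the first layer is a fixed knowledge prior. The scheme is
deterministic hard assignment, not EM:

1. `t_p` = midpoint of the class-conditional medians of probe *p* (medians
   for outlier robustness; ties at the threshold read "high" — a stated,
   testable convention).
2. Each calibration sample's gene state is deduced from its label and the
   gene's direction (active ⇒ up for induced genes, down for repressed).
3. `p_high|up = (n_high_in_up + α)/(n_up + 2α)`, α = 1, NaN measurements
   excluded from both counts; both classes must have at least
   `min_samples_per_class` (default 2) samples.

EM over latent gene states was considered and rejected: the hard scheme is
auditable, reproducible, and matches the idea that typical measurement
levels in the active and inactive condition are what the ground-truth sets
define. The cost is a small bias when the first layer is genuinely
stochastic: the estimator measures P(high | label-deduced state), which
leaks (1 − 0.95) of the other state's emission probability. The
generative-consistency checks therefore generate with label-determined
states (`simulate_from_model(..., hard_states=True)`), i.e. under the same
assumption the calibration makes; with `hard_states=False` the recovered
probabilities are biased by up to ~0.045 at the default coupling, which is
a property of hard-assignment calibration generally, not of this
implementation.

Platform porting re-runs steps 1–3 on the same calibration samples
re-measured on the new platform (optionally on a reduced gene subset),
retaining priors and directions and updating the platform tag. Any constant
offset between platforms (e.g. reference-minus-target ΔCq baselines) is
absorbed by the re-derived thresholds.

### ΔCq normalization

qPCR expression is `mean(Cq of reference genes) − Cq(target)`, so higher =
more transcript, matching the intensity orientation. Cq above `cq_max` or
missing is treated as no amplification → missing expression. Samples with
no valid reference gene are dropped and recorded. The scheme is invariant
to a global per-sample Cq shift. Amplification efficiency is assumed to be
exactly 2.0 (one cycle per doubling); no efficiency correction is applied —
a known limitation.

## Reference ranges and reports

The healthy-score threshold is the q-th percentile (default 95) by linear
interpolation between order statistics at rank `h = 1 + (n−1)·q/100`,
computed as written (multiply before dividing) so round thresholds such as
95.5 for scores 10..100 are exact to the last bit; this matches numpy's
"linear" percentile up to floating-point rounding. At least 5 reference
scores are required. A score strictly above the threshold is called
above-threshold / potentially tumor driving; a score exactly at the
threshold is within normal. Only the upper tail is thresholded: loss of
activity (e.g. of tumor-suppressive TGFβ signaling) is pathway-dependent
and reported descriptively, not called. For FOXO-based models the result
carries an annotation that PI3K activity is read as the inverse of measured
FOXO activity — a reporting convention only; no numeric inversion is
applied. One source describes the normal bound as a 95% confidence interval
in a figure caption and as the 95th percentile in the text; this package
implements the percentile reading.

## Synthetic data

The cohort generator mirrors the model's causal story: label → gene state
(first-layer conditionals, direction-aware) → Gaussian measurement on the
log2 scale around class-conditional means. Defaults: means 8 (up) vs 5
(down), sd 1 — a clearly responsive target gene with ~3 log2 units of
dynamic range; cohorts of 50 active + 50 inactive samples. "Conflicting"
genes are emulated by flipping the drawn state of a fixed rounded fraction
of genes, chosen uniformly per sample. qPCR re-measurement regenerates the
same latent samples from the same seed and converts expression to cycles
(`Cq = base − expression + N(0, sd_cq)`, sd_cq 0.2) with its own noise
stream, so intensity and qPCR matrices are paired measurements of
identical samples — the porting scenario. Low-input degradation is
missing-at-random dropout per measurement plus extra Gaussian noise, and on
the Cq scale additionally a global upward shift interacting with the
`cq_max` censor (dilution regime with reference genes near Cq 33).

What the generator does *not* emulate: correlated biological noise across
genes, batch/platform effects beyond a constant offset, structured
(expression-dependent) dropout, pre-amplification primer bias, or
cell-mixture composition. Passing tests therefore demonstrate correctness
and robustness of the inference/calibration machinery under the model's
own assumptions, not clinical performance on real tissue.

## Numerical and design notes

- All randomness flows from explicit integer seeds via
  `numpy.random.default_rng`; identical spec + seed is bit-identical.
- Score-bound enumeration caps at 12 probes per gene (2^k states); the
  brute-force oracle caps at 16 genes. Both refuse loudly, never truncate.
- Probabilities are validated strictly inside (0,1) at construction;
  smoothing guarantees calibrated values comply.
- Model files are versioned JSON (`pathsig-model/1`) with probabilities as
  plain decimals for auditability; loading recomputes the score bounds and
  rejects files whose stored bounds disagree, and rejects other major
  versions explicitly.
- Permutation controls: a single label permutation can still produce an
  extreme held-out AUC, because the residual emission differences of all
  genes share the same permuted labels and are therefore correlated; the
  AUC is scale-invariant and amplifies that tiny coherent signal. The
  permutation *expectation* is 0.5, and the suite estimates it over 200
  permutations.
- Problem sizes in the test and acceptance runs — 12-gene panels, 50+50
  calibration and held-out cohorts, 500/class for parameter recovery,
  200 oracle trials, 1000 monotonicity trials — were chosen as the
  package's standard study conditions; the full suite runs in well under a
  minute.

## Known limitations

- Dichotomized evidence discards within-class magnitude information; a
  continuous emission model would use it.
- Hard-assignment calibration is biased when the first layer is truly
  stochastic (quantified above).
- No amplification-efficiency correction and no batch-effect handling.
- Pathways are scored independently; crosstalk is not modeled.
- The 0–100 mapping is model-intrinsic; absolute scores are not comparable
  to other implementations of the same idea, only orderings and
  reference-relative calls are.
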