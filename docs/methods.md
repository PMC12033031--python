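# Methods

## Problem and estimand

We estimate the average treatment effect (ATE) `E[Y₁ − Y₀]` of a binary
treatment from longitudinal claims records under the usual identification
assumptions (consistency, positivity, no unmeasured confounding given the
record history). The estimator is inverse probability of treatment
weighting in Horvitz–Thompson form with divisor `N` (the sample count, not
the weight sum); no stabilization or Hájek normalization is applied, and
no doubly-robust augmentation — the scientific question here is purely how
propensity-score *estimation quality* propagates into the weighted
estimate. Trimming treats the retention band `[α, 1−α]` as closed and
renormalizes by the retained count: dividing the trimmed sum by the
original `N` would estimate no population quantity. Default `α = 0.05`.

## Synthetic confounded data

The generator emulates claims sequences in which the confounder is a
*temporal pattern*, not a marginal covariate:

- `T ~ Poisson(λ=10)`, redrawn when 0 (a patient must have a record).
- Static matrix `B`: one `Uniform(0.5, 1.5)` draw per code, broadcast over
  time — intrinsic characteristics. Dynamic matrix `C`: initial row
  `Uniform(15, 40)`, then `C_tk = C_{t−1,k}·exp(η)`, `η ~ N(0, 0.1²)` — a
  positive log-scale random walk for slowly drifting factors. These ranges
  put the background per-record occurrence probability
  `E[B/(B+C)] ≈ 0.037`, i.e. ~35–40 total code occurrences per patient at
  `d_x = 100` — sparse, short records.
- `P_tk ~ Beta(B_tk, C_tk)`, `X_tk ~ Bernoulli(P_tk)`. Empty records are
  legal and retained (they contribute a zero row / no tokens).
- Scenario statistic `s`: longest consecutive run of a target code;
  `max(0, d_cap − d_min)` for the record-wise distance between two target
  codes (0 when either is absent — the saturating form keeps the statistic
  bounded and "closer ⇒ higher propensity"); or the count of target-code
  records among the last `w = 5` records (window anchored at the end of
  the sequence, which forces genuinely temporal modeling).
- Propensity `e = σ(β₀ + β₁ s)` with `β₀ = −1.5`, `β₁ = 0.7` (0.6 for the
  distance scenario); outcome `y₀ = γ s + ε`, `ε ~ N(0,1)`, `γ = 5`;
  homogeneous additive effect `y₁ = y₀ + τ`, `τ = 20`.

**Target-code calibration.** Target codes draw their initial dynamic
parameter from `Uniform(1, 3)` instead of `Uniform(15, 40)`, giving them a
mean per-record occurrence probability near 1/3. This is the one place the
generator deviates from the background calibration, and it is load-bearing:
at the background rate the scenario statistics would be ~0 for almost every
patient, propensities would be nearly constant, and there would be no
confounding to adjust for. With it, propensities span ≈ (0.18, 0.88),
treated fractions sit near 0.45, and the naive difference-in-means is
biased upward by ≈ 4–5 outcome units — large relative to the ATE-error
scale of the benchmark. The logistic link and the linear outcome are
design choices exposed in `SimulatorConfig`; alternates can be swapped
without code changes.

What the generator does **not** emulate: code–code interactions
(disease–disease, drug–disease), calendar-time irregularity (time is
ordinal), multiple or sequential treatments, and any dependence of later
records on treatment. Passing benchmarks here therefore says nothing about
feedback-type time-varying confounding (the g-methods setting) — only
about confounding through pre-treatment temporal patterns.

### Semi-synthetic variant

The Synthea adapter groups same-date condition events into one ordinal
record per visit and injects occurrence-distance confounding between two
named codes (defaults: *chronic sinusitis* vs *viral sinusitis*), resolved
by case-insensitive description matching because Synthea's numeric code
assignments vary across versions. Tests use a *synthetic* fixture
generator that mimics the `conditions.csv` shape with controllable carrier
fractions and forced inter-code distances, so nothing is downloaded.

## Propensity models

- **Baselines.** Per-code record counts; standardization uses
  whole-dataset mean/SD (population convention, zero-SD columns map to 0),
  matching the convention of computing feature moments on the full cohort;
  the label-using ranking step (below) is fit per training fold only.
  HDPS recurrence indicators per code — *once* (count ≥ 1), *sporadic*
  (≥ carrier median), *frequent* (≥ carrier upper quartile, linear
  interpolation) — ranked by `|log BiasM|`,
  `BiasM = (P_C1(RR−1)+1)/(P_C0(RR−1)+1)`, with the risk ratio computed on
  the outcome dichotomized at its median (the outcome is continuous; the
  bias formula needs a binary one), symmetrized as `max(RR, 1/RR)`, 0.1
  continuity correction on zero cells, ties broken by feature index.
  Default `top_k = 100` — the classical 500 is oversized for a
  100-code vocabulary. "Counts+recurrence" (no selection) and
  "hdps_selected" (counts + top-k recurrence) are both available.
  Estimators are scikit-learn logistic regression (lbfgs, L2) and an MLP
  (ReLU, Adam). The MLP stops on training-loss convergence rather than
  accuracy-based validation stopping, which freezes probabilities as soon
  as a small validation split is perfectly classified.
- **Sequence models.** Embedding dimension 64 (32 in tests), LSTM hidden
  64, BERT 2 layers × 4 heads, feed-forward 128, dropout 0.1, Adam at
  1e-3 without scheduling, early stopping on the cross-entropy of a 10%
  validation split carved from the training folds, best-validation
  checkpoint restored. Within-record token order for BERT_code is
  ascending vocabulary index: records are bags and all codes of a record
  share one positional encoding, so the order carries no information and a
  deterministic convention makes runs reproducible. Empty records
  contribute a zero token in LSTM/BERT_record and no token (position
  still advances) in BERT_code.

### Numerical engine

The models run on a tape-based reverse-mode autodiff over float64 numpy
(`seqiptw.nn`): broadcasted arithmetic, batched matmul (operands forced
contiguous — transposed-view matmuls are pathologically slow), masked
softmax, layer norm, dropout, and a fused stable binary cross-entropy on
logits. Gradients are verified against central finite differences in the
test suite. Attention maps are stored only outside training. BERT_code
batches are capped at 32 sequences because its attention tensors grow with
the square of total code count; LSTM and BERT_record use batch 128.
Everything is seeded through `numpy.random.Generator`; a CRC32 rule fans a
single experiment seed out to per-stage child seeds so any cell of a
benchmark grid reruns in isolation, bit-for-bit.

## Evaluation

Per held-out fold: propensity MAE `(1/M)Σ|e−ê|`; weighted propensity MAE
`(1/M)Σ e·|e−ê|` (divisor `M`, not the weight sum — weights `e ≤ 1` make
it a lower bound of the unweighted MAE) emphasizing strongly confounded
patients; and `|Δ̂ − τ|` for the raw, trimmed and clipped IPTW estimators,
computed on the held-out fold's patients (fold-wise estimates are what the
fold CIs describe). Across-fold means carry 95% Student-t intervals with
`k−1` degrees of freedom. Defaults: 10-fold on synthetic data, 5-fold on
semi-synthetic.

## Problem sizes in the test suite

The suite favors many small, deep checks over few large ones; simulation
scales are package choices made for desk-scale replication:

- estimator unbiasedness: 500 replicates at N = 2000 using the
  marginalized (targets-only) generator path — background codes are
  independent of `(s, e, A, Y)`, so their simulation is skipped in
  replicate studies of the estimator itself;
- LSTM-vs-logistic ordering under window confounding: N = 3000, 2-fold
  CV, 2 seeded repetitions, reduced model (embed 32, ≤ 15 epochs);
- attention-concentration check: BERT_code trained on N = 1200 of the
  window scenario, attention summarized on 300 held-out patients;
- the full-size reference (N = 12 000, 10-fold logistic regression) runs
  both in the suite and in `scripts/acceptance.py`.

## Known limitations

- The trimmed estimator's renormalization changes the estimand to the
  overlap subpopulation; with a homogeneous effect this is immaterial,
  which is precisely why the benchmark can compare all three variants.
- Attention means are head-averaged uniformly (per-head rows are exposed);
  patient-level group means are averaged across patients, with patients
  lacking any confounder token excluded from that group's mean.
  Whether "all other" should include empty-record tokens is a convention;
  they are included, padding is not.
- Count-feature baselines see exactly the information summation preserves;
  their failure on window confounding is a property of the featurization,
  not of the optimizer.
- The numpy engine is CPU-bound and single-threaded; it is built for
  reproducibility at benchmark scale, not for large-vocabulary production
  training.
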