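# Methods

This note records the models, defaults and design choices behind
`paddygrade`, and what the synthetic experiments do and do not demonstrate.

## Synthetic monitoring campaigns

**Growth law.** Toxin accumulation in a bin held at a fixed storage condition
is modelled as logistic growth,

    x(t) = K / (1 + ((K − x0)/x0) · e^{−r t}),

multiplied by lognormal noise `exp(σ ε_t)`, ε_t ~ N(0,1).  Logistic growth is
a modelling choice, not a fitted mechanism: it reproduces the three
qualitative features the analysis depends on — slow accumulation in cool/dry
bins, fast accumulation in warm/humid ones, and saturation at a finite
ceiling — without a mechanistic fungal-ecology model (no colony counts, lag
phases, or AFB1–DON interaction).

**Rate response.** The per-day rate is
`r = r_max · g_T(T) · g_a(a_w)` with Gaussian-bell factors
`g_T = exp(−((T−30)/s_T)²)` and `g_a = exp(−((a_w−0.98)/s_a)²)` centred at
the warm/humid corner of the legal domain (10–30 °C, a_w 0.92–0.98).  Both
factors are strictly increasing over the domain and equal 1 at (30 °C,
0.98), so the rate is maximal there by construction.  Defaults
`s_T = 20 °C`, `s_a = 0.05` put the cold/dry corner at roughly 9% of the
maximal rate — slow but nonzero growth.

**Defaults and why.**

| parameter | AFB1 | DON | rationale |
|---|---|---|---|
| initial level x0 | 0.5 µg/kg | 60 µg/kg | well below limits at intake |
| carrying capacity K | 20 µg/kg | 2500 µg/kg | 2× the regulatory limit (10 / 1250 µg/kg), so warm/humid trajectories cross the limit mid-campaign and grading is nontrivial |
| max rate r_max | 0.25 /day | 0.25 /day | limit crossing near day 15 at the optimum |
| noise σ | 5% | 5% | typical relative assay repeatability; multiplicative because concentrations are positive and variance grows with level |
| design | 9 bins × 11 points × 30 days | | 99 series, 2970 records; daily sampling |

Bins take conditions from a 3 × 3 grid (T ∈ {10, 20, 30} °C × a_w ∈ {0.92,
0.95, 0.98}), cycled bin by bin; sampling points within a bin share the
condition and differ only in noise realization.  Noise medians at the
noiseless curve (`exp(σε)` has median 1), so the noiseless trajectory is the
median trajectory, not the mean.

**What the generator does not emulate:** sensor drift and missing values,
within-bin spatial gradients, condition changes over time, toxin
co-occurrence structure, and seasonal ambient cycles.  Tests passing on this
generator show the pipeline's arithmetic and recovery properties under its
stated assumptions; they say nothing about real monitoring noise spectra.

## Containers and the split

Series are stored long-form
(`sample_id,bin,point,day,temperature_C,water_activity,afb1_ug_kg,don_ug_kg`),
days 1-based, values serialized with 17 significant digits so a CSV
roundtrip is bit-exact.

The 70/20/10 split operates on records but is **time-blocked within each
series**: the earliest block of each series goes to train, the middle to
test, the latest to validation, so no model trains on the future of a series
it is evaluated on.  Per series, test and validation get
`floor(fraction × length)` records and train the remainder; for the
canonical 99 × 30-day campaign this gives exactly 2079/594/297.  Evaluation
windows slide over the full series but score only target days inside the
evaluation block (partition blocks are shorter than the forecast horizon, so
unmasked windows would leak across partitions).

Normalization is per toxin channel (mean/sd), fitted on training records
only.  A constant channel is a domain error when fitting strictly; the
training entry point fits non-strictly (sd 0 → 1) so degenerate inputs such
as a constant series fed to the persistence baseline still pass through.

## Seasonal–trend decomposition

The trend is a convex combination of centred moving averages at odd window
lengths (default 5, 9, 13 days — sub-monthly structure on a 30-day grid),
with softmax mixing weights; the seasonal part is the residual, so
`S + T = x` holds exactly in exact arithmetic and to ~1 ulp in float64.
Sequence ends are padded by edge replication (the decomposition literature's
convention).  Two weight granularities exist: fixed per-kernel logits
(default for the standalone function; equal weights when unset) and, inside
the forecaster, a learnable linear map producing one logit per kernel *per
time step*.  Inside the network the filters are applied as dense L×L
matrices so they participate in reverse-mode differentiation.

## Frequency-domain operators

Sequences use the real-input DFT (`rfft`, L//2+1 bins).  A **mode
selection** fixes, at model construction, which frequency indices a block
retains: policy `random-fixed` (drawn once from a seeded generator,
M = min(8, bins)) or `lowest` (indices 0…M−1, used by deterministic tests).

**FEB** computes `idft(pad(select(dft(W x)) ⊙ R))`: an input projection `W`,
truncation to the selected modes, multiplication by learnable complex
weights `R` (one per retained mode per channel pair), zero-padding of the
unselected modes, inverse transform.  `R` is stored as paired real/imaginary
arrays so the in-package real-valued autodiff engine can train it.  FEB is
linear in its input for fixed weights.

**FEA** projects query (decoder) and key/value (encoder) streams, truncates
each spectrum to its own fixed selection, forms the score `Q′·K′ᴴ`, applies
an activation σ, multiplies by `V′`, pads back into the query spectrum and
inverse-transforms to the query's length.  σ defaults to tanh applied
independently to the real and imaginary parts; a softmax-over-modes
alternative on score magnitudes is available in the config.  Multi-head
operation splits the model width into head blocks.

Inside the network the transforms are applied as fixed cosine/sine matrices
(`dft_matrices`/`idft_matrices`), verified against `rfft`/`irfft`, which
keeps every frequency operation a real linear map with trivial adjoints.

## Forecaster

Architecture per forward pass (widths: model width w = 64 default):

- **Embedding.** Per day: the two normalized toxin channels, scaled
  temperature and water activity, and three day-index features (d/30,
  sin(2πd/30), cos(2πd/30)), mapped linearly to width w.
- **Encoder** (2 layers default): x → FEB + residual → decompose (keep
  seasonal) → feed-forward + residual → decompose (keep seasonal).  Trends
  are discarded.
- **Decoder warm start.** The last `label_len` days of the encoder window
  are decomposed with equal weights; the seasonal part is extended with
  `pred_len` zeros, the trend part with `pred_len` copies of the window
  mean.
- **Decoder** (1 layer default): FEB + residual → decompose; FEA between the
  decoder seasonal stream (query) and the layer-normalized encoder output
  (key/value), + residual → decompose; feed-forward + residual → decompose.
  The three extracted trends each pass through their own linear map to the
  output width and are summed onto the warm-start trend.
- **Output.** Forecast = linear(final seasonal) + accumulated trend, so the
  seasonal/trend split of every prediction is available and sums to the
  prediction exactly.

**Training.** Masked MSE on normalized values, Adam, learning rate 1e-4,
full-batch, 30 epochs default; the parameters with the best validation loss
are kept.  Window sizes default to seq_len 14 / label_len 7 / pred_len 7 —
sized so a 21-day training block hosts exactly one window per series on the
30-day campaign.  Fixed seed ⇒ bit-reproducible loss histories on a given
BLAS backend (float64 throughout, single-threaded NumPy).

**Baselines.** Persistence (repeat last value); RNN/GRU/LSTM encoders
(hidden 32) and a single-layer time-domain Transformer, each with a direct
multi-step linear head, all trained by the same loop.  A contiguous-fold
cross-validation harness reports mean ± sd of each metric.

## Error metrics

MAPE, MSE, RMSE, MAE, SMAPE, MSPE with the standard definitions;
percentages on the 0–100 scale.  SMAPE uses the symmetric denominator
`(|y′| + |y|)/2`; MSPE is `100²/n · Σ((y′−y)/y)²`.  Zero denominators are
domain errors, not silently clipped.  The silhouette coefficient is computed
by definition (per point `(b−a)/max(a,b)`; singleton clusters and zero
distances score 0) and is cross-checked in tests against a brute-force O(N²)
oracle and scikit-learn.

## Grading

The evaluation index at day j is `P = (x̄_past, x_j, x̄_future)` with window
n = 7 days by default (one forecast horizon; configurable).  Days lacking n
observed days of history or a full forecast horizon are reported as skipped,
never silently dropped.  P points are pooled over all (sample, day) pairs
and clustered **per toxin** — AFB1 and DON scales differ by two orders of
magnitude, so cross-toxin pooling would let DON dominate every distance.

**k-medoids** is the randomized-swap greedy: seeded random initial medoids;
propose swapping a random medoid with a random non-medoid; keep the swap iff
the summed point-to-nearest-medoid Euclidean distance strictly decreases;
stop after k·N consecutive non-improving proposals or 300 iterations.  Ten
seeded restarts are run and the best cost kept — on all N ≤ 8, k = 2
instances tested this matches exhaustive search.  Nearest-medoid ties break
to the lowest medoid index.  The k-means comparator is seeded Lloyd from
random data points, also best-of-10 restarts.

The cluster count is scanned over k = 3…7 and selected by mean silhouette
(ties → smaller k).  The three clusters are mapped to quality levels 1–3 by
sorting their centers' Euclidean distances from the origin of P-space;
grading therefore only requires that "worse" means "farther from zero toxin
everywhere", which holds by construction of P.

## Numerical choices

- float64 everywhere; no GPU, no thread-level nondeterminism.
- Decomposition and forecast reconstruction identities hold to ~1 ulp
  (asserted at 1e-12 absolute).
- DFT roundtrips asserted at 1e-9 relative.
- Softmax computed with a detached max-shift; layer norm with ε = 1e-6.
- Seeds fan out through `numpy.random.SeedSequence`; all derived seeds stay
  below 2³¹.

## Problem sizes used by the tests and the acceptance script

Unit and property tests run on toy lengths (8–64) and the 6-series campaign.
The acceptance script uses the full 99-series campaign for arithmetic and
grading (1683 P points per toxin), 100 random instances for k-medoids
optimality, 150 planted points for selection/recovery, and a 200-day
noiseless sinusoid+ramp series (seq 48 / pred 12, width 64, 100 epochs) for
forecast recovery.

## Known limitations

- On the 30-day logistic campaign itself the frequency model does **not**
  beat persistence: the time-blocked split trains on the early growth phase
  and evaluates on the saturating phase, a deliberate distribution shift
  under which repeating the last observation is a strong predictor at 5%
  noise.  Forecast skill is demonstrated on the longer periodic benchmark,
  where the model reaches held-out MAPE < 10% against ~19% for persistence.
- The silhouette scan compares k = 3…7 only; it cannot conclude that three
  regimes exist, only that 3 is the best of the scanned counts.
- The randomized-swap k-medoids is a greedy local search; optimality is
  verified exhaustively only at small N, and relied on via restarts
  elsewhere.
- Grading quality inherits forecast quality: with a poor forecaster the
  future-mean component of P degrades toward a persistence estimate.
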