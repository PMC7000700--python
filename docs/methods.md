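# Methods

This note documents the models, defaults and numerical choices behind
`ryrpipe`, what the synthetic-data generators do and do not emulate, and
the known limitations.

## Lifetime fitting (`ryrpipe.waveform`)

Each well's decay is modeled as a pure exponential over a flat
background, `y(t) = b + A·exp(−t/τ)`, with a delta instrument-response
function. Real plate readers convolve the decay with a finite IRF and
the underlying photophysics is multi-component; the screen, however,
consumes only *relative* lifetime changes between wells on the same
plate, for which the mono-exponential effective lifetime is the
appropriate summary. No IRF model is shipped because the analysis never
depends on absolute lifetimes.

Fitting is bounded least squares (`scipy.optimize.least_squares`, TRF)
with a deterministic start: the background is the mean of the last 10%
of bins, and τ and A come from a log-linear regression of the
background-subtracted counts. Three weighting modes reflect
photon-counting statistics:

- `mle` (default): Poisson maximum likelihood via signed deviance
  residuals, `sign(y−m)·sqrt(2(m − y + y·log(y/m)))`. At 10⁵ photons per
  well the Monte-Carlo bias of τ is below 0.3% (a suite invariant).
- `neyman`: classic observed-count weights `1/max(y,1)`. Kept as an
  option, but at 10⁵ photons it biases τ low by roughly 0.5% (small
  observed counts in the tail get over-weighted), which is why it is not
  the default.
- `none`: unweighted; unbiased but noisier.

Non-convergence is reported (`converged=False`), never raised; an
all-zero waveform is an error because no lifetime is defined.

FRET efficiency `E = 1 − τ_DA/τ_D` is left unclipped: values below 0
(τ_DA > τ_D) are physically odd but diagnostically useful, and the
artifact filters — not the arithmetic — decide what to exclude.

## Plate screen (`ryrpipe.screen`)

Default layout: 32 rows × 48 columns; compounds in columns 3–22 and
27–46 (1280 wells), DMSO controls in columns 1–2, 23–26 and 47–48
(256 wells). Three companion plates per run share the layout:
donor-acceptor (FRET), donor-only (τ_D control), unlabeled (spectral
intensity control).

Choices where the procedure admitted more than one reading:

- τ_D per plate is the donor-only plate's DMSO-well mean. The companion
  plates are physically distinct, so no well-to-well pairing exists.
- The hit statistic is the deviation of E/E₀ in units of the per-plate
  DMSO E/E₀ SD (not pooled across runs); a raw-E mode would behave
  identically up to the E₀ scale since both are per-plate affine maps.
- The 4-SD boundary is a strict inequality: exactly 4.0 SD is not a hit.
- Reproducibility requires the same sign in ≥ 2 runs; opposite-direction
  flags are treated as artifacts, not reproduced biology.
- All reads are stored; the analysis uses one chosen read, by default
  the latest (compound effects grow with incubation time; the default
  read in the generated data is 120 min).
- The Gaussian QC fit has a robust mode (trim |z| > 4 on median/MAD
  scale before the ML fit) so genuine hits do not inflate the width
  estimate; `analyze_screen` uses it by default.

The false-positive behavior of the 4-SD rule follows from the plug-in
control SD: with m = 256 control wells the null deviation statistic is
t-distributed, giving `p = 2·P(t_{m−1} > 4/√(1+1/m)) ≈ 8.3·10⁻⁵` per
well — slightly above the idealized `2Φ(−4) = 6.3·10⁻⁵`. The test suite
checks the simulated rate against the exact form.

No spatial plate-effect correction (B-score, edge effects) is applied
anywhere; that is a deliberate non-feature of this analysis.

## Dose-response (`ryrpipe.dose`)

The four-parameter Hill model is fit on log₁₀ concentration with
`lmfit`; initialization is deterministic (plateaus from the extreme-
concentration means, IC50 from the midpoint crossing, h = 1). A fitted
negative slope is canonicalized by swapping the plateaus, so `hill > 0`
always. A 3-parameter variant fixes h = 1. Standard errors come from
the fit covariance; since the study's own uncertainty convention is not
recoverable from fit files, the covariance SE is what is reported, and a
relative IC50 SE above 1 raises a `poorly_constrained` flag (typical of
monotone data with no lower plateau).

Biphasic detection compares the best monotone shape against the best
rise-then-fall / fall-then-rise shape over the concentration means
(pool-adjacent-violators on each arm, scanning all interior turning
points), in units of the replicate pure-error variance. The scan makes
the null distribution of the improvement statistic grow with the number
of concentrations, so no fixed χ² cut holds a stated specificity; the
threshold is instead the Monte-Carlo null quantile for the series'
replicate-count pattern (500 draws, fixed internal seed, cached), giving
~95% specificity at the default `alpha = 0.05`.

Per-dose significance stars on dose-response figures are plain two-sided
t-tests; call `scipy.stats.ttest_ind` — the package deliberately adds no
multiple-testing machinery.

## Free calcium (`ryrpipe.buffers`)

Single-ligand 1:1 Ca–EGTA equilibrium; the free concentration is the
non-negative root of `x² + (Kd + EGTA − Ca)x − Kd·Ca = 0`, evaluated in
the conjugate form when `b ≥ 0` to avoid catastrophic cancellation at
free ≪ total. The apparent Kd is a parameter, not a constant: full
chelator calculators fold pH, ionic strength, temperature and competing
ions into the apparent constant, and the two buffer conditions used in
the assays imply slightly different values (≈431.5 nM from the 65 μM →
30 nM condition; ≈303 nM from the 1.02 mM → 30 μM condition). The
default is 431.5 nM (`KD_APP_DEFAULT`), with `KD_APP_HIGH_CA` provided
for the high-calcium regime. Mg²⁺/ATP competition is out of scope;
solutions containing ATP are not recomputed.

## Fiber calcium (`ryrpipe.fiber`)

The rhod-5N conversion `[Ca²⁺] = Kd(F − F_min)/(F_max − F)` uses
Kd = 0.8 mM. F_min/F_max are per-fiber anchors: they may be supplied
explicitly, or taken from trace features (the caffeine-depleted floor
approximates F_min); the generator knows its own calibration, so
round-trip tests are exact.

Plateau extraction averages the final 20% of each inter-event window
(configurable) and flags non-plateau segments when
|slope|·window > 2% of the trace range. Both defaults are honest
summaries of "value at plateau" for traces that have settled ≥ 5 time
constants; the drift check is what protects against traces that have
not.

Leak is reported per trace as
`(ss_drug − ss_tetracaine)/(ss_control − ss_tetracaine)`; negative
values are kept and flagged `beyond_tetracaine`, since a drug pushing
t-system calcium below the full-block floor indicates an off-target
effect (e.g. on t-system uptake), not a measurement error. Pooling
across fibers is left to the user: within-fiber repeat structure varies
between experiments and no single pooling rule is defensible in-package.

Transient analysis uses a 100 ms post-stimulus peak window and a 200 ms
pre-stimulus baseline; at 1 Hz pacing and ≤ 10 ms sampling these windows
cannot overlap adjacent stimuli.

## Synthetic data (`ryrpipe.synth`)

The screen generator works at the lifetime level: a well's normalized
FRET ratio is drawn and mapped to τ_DA = τ_D(1 − E), with
τ_D = 4.0 ns (typical of the green donor dye) and a baseline control
FRET E₀ = 0.3 (sub-saturating acceptor). DMSO wells draw their ratio
from N(1, σ); null compound wells from N(μ₀, σ) with μ₀ = 1.004 and
σ = 0.016 — the observed compound-vs-control offset and width of the
null screen distribution. μ₀ is deliberately applied to compound wells
relative to the DMSO mean: normalization divides by the measured DMSO
mean, so an offset drawn identically by both groups would cancel and be
unrecoverable. Companion plates get an instrument CV of 0.5% on
donor-only lifetimes and 1% on intensities; at these values simulated
DMSO-vs-suramin plates give Z′ ≈ 0.9, the quality class of the real
assay. Two reads (20 and 120 min) are emitted, with effects attenuated
to 50% at the early read.

Effects are per-compound E/E₀ shifts, scalar (identical across runs,
with independent noise redraws — the simplest model consistent with
multi-run reproducibility screening) or per-run sequences. The shipped
demo scenario spikes 17 strong modulators at 10σ in every run and 5
marginal ones at 6σ in two runs and 0.5σ in the third (rotating). The
per-run marginal design is intentional: with identical marginal effects
near the threshold, whether a marginal lands in all three runs would be
a coin flip, and the demo is meant to reproduce the structure
17-in-all-three / ~22-in-at-least-two deterministically (up to ~10⁻³
tail events). Per-run compound-effect correlation in real screens is
unknown; independence is an assumption, flagged here.

The dose generator adds iid Gaussian noise (SD 0.03, n = 4 replicates)
to an exact Hill curve; the fiber generator produces piecewise
single-exponential approaches to per-solution steady states
(control 0.6 mM, tetracaine floor 0.2 mM, caffeine-depleted 0.01 mM by
default) encoded through the inverse rhod-5N calibration. Kinetic time
constants are plumbing: the analysis consumes plateaus only.

What the generators do **not** emulate: spatial plate effects (edge
evaporation, dispenser gradients), read-to-read drift, compound
fluorescence interacting with the donor channel beyond an intensity
shift, photobleaching, multi-exponential decay physics, SOCE kinetics,
or fiber-to-fiber calibration variability. Passing round-trip tests
therefore demonstrates correctness of the analysis chain under the
stated statistical model, not robustness to these real-data features.

## Problem sizes in tests

Monte-Carlo checks use 200 replicates (lifetime bias, IC50 recovery
bias), 100–200 simulations (biphasic specificity, median fit error) and
~10⁵ simulated wells (4-SD null tail), sizes at which the binomial or
Monte-Carlo error of each check is several times smaller than the
tolerance it enforces. The acceptance script reports IC50s as the
median over 9 independently simulated replicate experiments of the
standard design, shrinking simulation scatter around an estimator whose
bias is separately verified to be under 5%.

## Known limitations

- Delta-IRF lifetime model; absolute lifetimes from real instruments
  will differ from fitted effective lifetimes.
- Single-ligand buffer model; no proton/Mg/ATP competition.
- The Hill fit reports covariance SEs only.
- Per-trace fiber metrics; no cross-fiber pooling or statistics.
- No spatial normalization of plates (by design).
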