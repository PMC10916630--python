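# Methods

## Scope and data model

The package analyses accelerated storage tests of a beverage: a set of
quality indices measured repeatedly over storage time at several constant
temperatures, plus a panel sensory score. The unit of analysis is the
`StorageSeries` — one index at one temperature, times in days (strictly
increasing, ≥ 2 points), temperature in kelvin. Replicate bottles are
averaged before fitting; the generator can emit either raw replicates or
means, but every fit consumes a single complete series. Missing values are
rejected rather than imputed, because all downstream fits assume a complete
design.

## Kinetic fitting

Both kinetic orders are fit by OLS on the linearised form: C on t for order
0, ln C on t for order 1. The linearised route (rather than nonlinear least
squares on the exponential) was chosen deliberately: the reported rate
constants in this literature are produced that way, and it keeps the fit a
closed-form, assumption-transparent regression. Consequences: for order 1
the implicit error model is multiplicative lognormal, which is also what the
synthetic generator produces.

`k` is reported as a magnitude with a separate ±1 direction flag, because
the same first-order form ln(C0/C) = kt is applied to indices that grow
(CSR, particle size) and decay (viscosity, sensory score) without a sign
convention. The free-intercept fit is the default (C0 estimated); `fix_C0`
pins the intercept to the first observation and refits the slope through it,
reproducing the convention in which C0 is treated as known.

Order selection runs both fits and keeps the higher linearised r²; a tie
closer than 1e-9 resolves to first order, the form storage stability of
protein beverages is generally found to follow. A constant series is a
perfect k = 0 fit under either order (r² defined as 1 when the response has
zero variance, since the zero-slope model is exact there).

## Arrhenius and transition-state analysis

Activation energy comes from OLS of ln k on 1/T (Ea = −slope·R); no
weighting is applied, as the inputs are three to four rate constants of
comparable precision. Duplicate temperatures collapse to the geometric mean
of their rates (the mean on the ln k scale the regression works in), with a
warning. Identical rates at all temperatures give Ea = 0 with r² = 1.

Transition-state parameters are computed row-wise from (T, k, Ea):
ΔH* = Ea − RT, ΔS* = R(ln k′ − ln(k_b/h) − ln T − 1) + Ea/T,
ΔG* = ΔH* − TΔS*. Ea is an *input* here, not recomputed from the rates, so
a published table can be reproduced from its own printed activation
energies independently of how they were estimated.

**Rate-unit convention.** The Eyring expression pairs k with k_b/h in SI,
so k strictly belongs in s⁻¹. The storage-stability literature, however,
inserts the numeric value of k in d⁻¹ directly, and published ΔS*/ΔG*
tables are only reproducible that way. The default `per_day_numeric` mode
follows that practice; `per_second_SI` (k/86 400) gives the dimensionally
consistent analysis, shifting ΔS* by −R·ln(86 400) ≈ −94.4 J/(mol·K) and
ΔG* correspondingly. The mode is stamped into every output row, and the
two modes satisfy the same exact round-trip identity
k = (k_b T/h)·e^{ΔS*/R}·e^{−ΔH*/(RT)}.

The ΔG*–temperature regression is fit in kJ/mol (the unit the quantity is
tabulated in); the shelf-life module multiplies by 1000 internally to pair
with R in J/(mol·K).

Known inconsistencies in the reference parameter set are handled by using
printed values verbatim and row-wise only: the viscosity rate constant at
298.15 K (0.0630 d⁻¹) is non-monotone against the higher temperatures and
incompatible with the printed Ea = 10.56 kJ/mol, so the viscosity Arrhenius
fit has r² ≈ 0.3 and its ΔG*(T) regression is meaningful only as a
reproduction of the published one. Likewise, OLS over the three CSR rate
constants yields Ea ≈ 40.1 kJ/mol against a published 40.8; the published
estimation procedure is unstated, so the package documents the ~2 % gap and
treats printed Ea values as authoritative inputs where a table is being
reproduced.

## Shelf-life model

The combined model is generalised from the CSR special case to any
(sensory link, ΔG*–T fit, C0, direction) quadruple. Solvability requires
the sensory score to decline with storage (link slope × index direction
< 0), which is validated at construction. The shelf life is closed-form:

t = ln((SS_lim − β)/(α·C0)) / (±k(T)),

with a domain error when the threshold exceeds SS(0) (product already
unacceptable) or lies at/below the model's asymptote (a decaying-index
model approaches SS → β and may never reach the threshold). The threshold
defaults to 80 points but is configurable, since published shelf lives are
sometimes quoted against unstated criteria. No numeric root-finding is
used; the exponential form makes the inversion exact.

The sensory link is fit with all temperatures pooled — one equation per
index, matching how such links are reported — and the key index is the one
with the highest link r², ties broken lexicographically for determinism.

Validation statistics: Se = √(Σ(yᵢ−ŷᵢ)²/(n−k−1)) with k the number of
prediction factors, Ve = 100·Se/ȳ, adequate below 15 %. The observed
shelf-life times published for the reference study (90/120/150 days)
cannot be reconciled with its printed model constants and an 80-point
threshold (the closed form gives ~19 days at 25 °C), and the predicted
values behind its Ve = 10.78 % are not printed; the package therefore
exposes the validation operations but makes no claim to reproduce that
figure.

## Synthetic data generator

The generator emulates the reference study design: indices CSR
(C0 = 0.82 %), particle size (0.545 μm) and viscosity (5.82 mPa·s), first
order with the published rate constants at 298.15/308.15/318.15 K; 6
parallel replicates per sampling point; and a schedule of 11 points. The
default schedule spans 0–20 days at 2-day intervals: the published
sampling-interval description is ambiguous about which interval belongs to
which temperature, and a 20-day span is the one that keeps every noiseless
trajectory inside its reported index range (e.g. CSR reaching ≈ 1.7 % at
25 °C). Schedules are plain tuples and meant to be overridden when a
different design is wanted.

Noise is multiplicative lognormal on index values (σ = 0.05 by default;
keeps values positive and matches the log-linear fitting assumption) and
additive Gaussian on sensory points (σ = 0.5 points), clipped to the 0–100
panel scale. No published noise model exists for these data; these choices
are the package's own, sized to the reported mean ± SD figures' visual
scatter. The sensory score is a single observable generated from one
designated source index's link (CSR by default) — not one score per index.

Determinism: every (index, temperature) group and the sensory stream draw
from sub-streams of a `numpy` SeedSequence keyed on the config seed and the
group labels, so identical configs give identical data, replicates are
independent, and adding an index does not perturb the others' draws.

What the generator does **not** emulate: panel-level rubric structure
(color/flavor/taste/stability sub-scores), autocorrelated drift within a
bottle, batch effects between replicates, and any departure of the true
trajectories from exact kinetics. Passing recovery tests therefore show
that the estimation chain inverts its own assumed data-generating process —
not that real storage data meet those assumptions.

## Numerical choices and problem sizes

All regressions are `scipy.stats.linregress` or closed-form fixed-intercept
OLS; r² values are clipped into [0, 1] only where a fixed intercept can
make the usual formula marginally negative. Results CSVs are written with
10 significant digits and deterministic row order, so reruns are
byte-identical and round-trips preserve values to ≤ 1e-9 relative.

The stochastic test-suite workloads are sized to run in seconds: 1000
replications for the single-series rate-recovery rate check, 200 for the
full-fixture recovery harness; the recovery harness reports median and 95th
percentile relative errors (typical: median |k̂−k|/k ≈ 1.7 % at σ = 0.05
with 6 replicates).

## Known limitations

* The first-order + Arrhenius + linear-ΔG*(T) chain is a local empirical
  description; extrapolating far outside the fitted 25–45 °C window has no
  support.
* The linear sensory link is pooled across temperatures; if the true link
  were temperature-dependent, the single-equation model would hide it.
* `per_day_numeric` reproduces published tables but is dimensionally
  inconsistent; quantitative ΔS* comparisons across studies should use
  `per_second_SI`.
* Microbiological spoilage, Q10 shortcuts, and non-exponential sensory
  failure models are out of scope.
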