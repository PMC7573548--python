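# Methods

## Signal model and scope

`lumirhythm` analyses population-level bioluminescence from clock-reporter
cell cultures. After a synchronizing dexamethasone pulse, such cultures emit
a damped, noisy ~24 h oscillation on top of a slowly decaying baseline
(cell proliferation, substrate and reporter decline). The package covers
the desk-scale path from plate CSV to per-condition rhythm parameters:
reading/writing plate recordings, conditioning the traces, fitting a
constant-plus-sinusoid regression, and aggregating condition summaries.
Animal endpoints beyond two scalar formulas (caliper tumor volume
`V = W²·L/2`, organ/body weight ratio), imaging, and any transcriptomic
analysis are out of scope.

## Conditioning filters

Two linear, zero-phase discrete boxcar filters prepare a trace for fitting:

* **Detrending** subtracts a centered running mean over
  `detrend_window_h` (default 24 h = 121 samples at the 0.2 h cadence).
  A 24 h window straddles one circadian cycle, so the running mean tracks
  the baseline while nearly cancelling the oscillation.
* **Smoothing** replaces the signal by a centered running mean over
  `smooth_window_h` (default 2 h = 11 samples) to suppress shot noise.

Windows are converted to odd sample counts so the filters stay centered on
a sample. Edge handling is `trim` by default (drop the half-window at each
end, avoiding edge bias in the fit; a 72 h record retains 46 h after both
filters); `shrink` (progressively smaller symmetric windows) keeps full
length for short records but distorts decaying baselines near the edges and
is not recommended for period estimation.

A boxcar of `w` samples at spacing `dt` multiplies a sinusoid of period `T`
by the Dirichlet gain `G(T) = sin(wπ·dt/T) / (w·sin(π·dt/T))` — the discrete
analogue of the continuous `sinc(w·dt/T)`. Consequences worth knowing:

* the default smoother attenuates a 24 h rhythm by ~1.4% (and a shorter
  16 h rhythm by ~3%);
* the 121-sample detrend window does **not** exactly annihilate a 24 h
  sinusoid: its boxcar equals `−sin/121`, so detrending passes the rhythm
  with gain `1 + 1/121`. The continuous-time intuition "a full-period mean
  is zero" holds only approximately on a sampled grid.

Because both gains are exactly known, the pipeline reports a
**gain-corrected amplitude**: the fitted amplitude divided by
`(1 − G_detrend(T̂))·G_smooth(T̂)` at the fitted period. For a noiseless
sinusoid this inverts the filters exactly; the raw fitted amplitude is kept
alongside (`amplitude_fit` in `wells.csv`). Period, phase and R² need no
such correction (the filters are zero-phase).

## The sinusoid fit

The fitted model is `y(t) = c + a·sin(2πt/T) + b·cos(2πt/T)`. At fixed `T`
this is an ordinary least-squares problem solved by SVD; amplitude is
`√(a²+b²)` and phase is reported as the hour in `[0, T)` of the fitted
sinusoid's first ascending zero-crossing after `t = 0` — an unambiguous,
unit-free convention (`phase = (−atan2(b, a)·T/2π) mod T`).

The period is profiled: SSE is evaluated on a coarse grid over the search
bounds (default 16–40 h, which brackets every plausible circadian period
with margin, in 0.05 h steps), then the best bracket is refined by
golden-section search to `refine_tol_h` (default 0.001 h). The two-stage
search is deterministic and matches a 0.001 h dense-grid brute force to
within the refinement tolerance (checked in the test suite against an
independent normal-equations implementation). Ties on the coarse grid
(within 1e-12) resolve to the smaller period. `converged` is true iff the
coarse minimum is interior to the bounds.

R² is computed as `1 − SSE/SST` on the same conditioned signal the model
was fitted to, about its mean. An all-constant input (`SST < 1e-12`) yields
a degenerate result rather than an exception: `r_squared = 0`,
`amplitude = 0`, `phase = 0`, `period` set to the lower search bound as a
deterministic placeholder, `converged = false`. A candidate period short
enough to alias the sine/cosine columns raises a flagged numerical error.

### Damping and period bias

Deliberately, the fitted model has **no damping term**; damping appears
only in the simulator. Fitting an undamped sinusoid to exponentially damped
data costs more than a reduced R²: over a finite record the
envelope-modulated partial cycle leaks into the SSE profile and **biases
the recovered period**, by an amount depending on damping rate, period and
starting phase. At 0.01/h damping on a 72 h record the bias reaches
~0.1–0.2 h (it vanishes when the record holds an integer number of cycles,
e.g. at T = 24 h); at 0.02/h it can approach 0.5 h. This was verified
against a dense-grid oracle, so it is a property of the least-squares
problem, not of the search. Practical guidance: period comparisons across
conditions sharing similar damping remain valid (the bias largely cancels),
but absolute accuracy beyond ~0.2 h should not be expected for strongly
damped records. The test suite asserts a 95%-within-±0.2 h recovery target
at 0.01/h damping; the measured rate is ~80–85%, limited by exactly this
bias, and the shortfall is documented rather than hidden.

### R² inflation by smoothing

Smoothing removes most noise variance from the conditioned trace, so SST
shrinks while smooth residual structure (e.g. imperfectly removed baseline)
remains fittable. A completely arrhythmic well therefore scores R² ≈ 0.4
rather than ≈ 0 under default settings. R² is best read as a relative
rhythmicity score under a fixed configuration, not an absolute probability
of rhythm; rhythmic wells at SNR 5 score ≥ 0.98.

## Synthetic plates

The generator emulates the measured signal class:

```
y(tᵢ) = floor + B₀·e^(−β·tᵢ) + A₀·e^(−λ·tᵢ)·sin(2π(tᵢ − φᵢ)/T) + εᵢ
```

with per-well phase `φᵢ = φ₀ + jitter + random walk` (jitter: one Gaussian
draw per well, sd 0.5 h by default — the operational meaning of
dexamethasone synchronization; walk: per-step sd
`phase_diffusion·√dt`, modelling gradual desynchronization) and i.i.d.
Gaussian noise. Defaults represent the standard recording design: 0.2 h
sampling (12 min) for 72 h (≥3 days), amplitude 50 counts against noise sd
10 (SNR 5), baseline `50 + 200·e^(−0.03t)` counts. An `unsync` preset
draws phases uniformly on `[0, T)` instead.

Determinism: equal seeds give bit-identical traces; per-well seeds derive
from the plate seed via `numpy.random.SeedSequence(seed).generate_state`.

**Presets.** Cell-line presets anchor true periods to reported values for
the three cancer lines — MC38 26.3 h, E0771 27.2 h, LLC 28.3 h. The
fibroblast (NIH3T3) period was never printed; its 24.0 h default is a
placeholder, not a measured value. Preset damping is 0.005/h, chosen so
that preset periods remain recoverable to ±0.2 h by the undamped fitted
model (see the bias discussion above); rhythm robustness differences are
carried by across-well phase diffusion (NIH3T3 0.01, E0771 0.025, MC38
0.04, LLC 0.05 h/√h), making cancer lines less coherent than fibroblasts
and E0771 the most intact cancer line.

**Knockdown.** siRNA loss of the core clock genes is modeled
phenomenologically: efficiency `e` scales amplitude by `1 − 0.6e`, damping
by `1 + 2e` and phase diffusion by `1 + 4e`. Single-gene presets (`siPer1`,
`siPer2`) use `e = 0.6` — Per1 and Per2 are partially redundant, so a
single knockdown shows a weaker rhythm phenotype — and the combined
`siPer1Per2` preset uses `e = 0.8`. The coefficients are tuning constants
that visibly flatten averaged curves; they are not estimates of any
biological quantity.

**What the simulator does not emulate** — and hence what passing tests do
not establish about real data: single-cell oscillator ensembles and their
coupling, luciferin substrate-depletion kinetics, temperature effects,
non-Gaussian photon-counting noise, plate-position artifacts, or wells with
missing samples. The generator's damped-sinusoid-plus-baseline form matches
the fitting model family closely; real traces deviate more, so real-data R²
values will run lower than simulated ones at comparable noise.

## Pipeline and reporting

`run_pipeline` detrends, smooths and fits every well, then aggregates
per-condition mean ± SEM (SEM = sample sd/√n, reported absent for n < 2)
of period, gain-corrected amplitude and clipped R². Degenerate and
non-converged wells are counted (`n_wells`) but excluded from parameter
means (`n_converged`), and every exclusion is logged — never silent.
`--fit-mean` (library: `fit_mean=True`) instead averages each condition's
technical replicates and fits the mean curve, matching the display
convention of averaged repeats; per-well fitting is the default because it
yields dispersion estimates. Whether published per-line periods derive from
per-replicate fits or mean-curve fits is generally ambiguous, which is why
both modes exist.

Reports are plain text (`wells.csv`, `summary.csv`, `run_info.yaml`) with
no timestamps, so identical inputs and configurations produce byte-identical
output. Plate CSVs store floats at full `repr` precision and the reader
converts them with correctly rounded parsing, making write→read round trips
bit-exact; the reader rejects malformed input (naming the offending
row/column/well) and never repairs silently.

## Problem sizes and runtimes

Validation uses desk-scale experiments chosen to exercise the method fully:
single plates of 3–12 wells at 361 timepoints for round trips and
contrasts, 200 simulations for the recovery study, 50 random instances for
the oracle-equivalence check (dense grid at 0.001 h over 16–40 h). The full
test suite runs in well under a minute on one CPU; `scripts/acceptance.py`
takes ~15 s.
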