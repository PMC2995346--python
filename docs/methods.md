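# Methods

## Model structure and assumptions

The model is a 1-D opponent motion-energy model. The 2-D annular display is
mapped to translation along a single spatial axis: a +90° phase step is a
quarter-period displacement toward +x, and the clockwise/counter-clockwise
distinction reduces to ±x. Absolute luminance never enters the computation —
stimuli are stored as luminance contrast about the mean-grey background
(coded 0), and the model output is contrast-invariant by construction.

Stimuli are x–t matrices covering 8° × 1.5 s, sampled at 0.05° and 5 ms.
The two-stroke cycle is seven epochs (`G1–ISI–G2–G1–ISI–G2–G1`) with 40 ms
grating frames and ISIs from {0, 40, 85, 125, 165, 200, 240, 285, 315} ms.
For direction discrimination a single cycle is centred in the 1.5 s window
(an odd padding sample goes after the sequence, so onset is rounded earlier);
where exactly the cycle sits is immaterial at the level of pooled energies,
which is testable by shifting the onset. The MAE adaptor tiles the cycle from
t = 0, truncating the final partial cycle. Epoch boundaries are rounded to the
nearest sample; with the default grid 40 ms is exactly 8 samples, so no
rounding drift occurs.

Four sensors are assembled as sums of outer products of the spatial quadrature
pair (even/odd Gabor, f = 1.1 cpd, σ = 0.5°, 4° support) and the fast/slow
biphasic temporal filters (n = 6 and 9, β = 0.9, 0.5 s support):
R1 = SE⊗TF + SO⊗TS, R2 = SO⊗TF − SE⊗TS, and the L pair with the TS-bearing
signs flipped. The combination signs are a convention; the suite pins it with
a calibration stimulus (a grating drifting toward +x must yield NE > 0).
Because the fast/slow temporal filters are only an approximate quadrature
pair, direction selectivity is imperfect: the bank's maximum NE for a 1.1 cpd
drifting grating is ≈ 0.92, reached near 8 Hz — above the ≈ 5.3 Hz peak of
the slow filter's own amplitude spectrum, because the opponent readout
combines both temporal filters.

Filtering is 2-D cross-correlation with zero-padded boundaries at 'same'
output size. Energies are squared and pooled over all space–time positions
and over each quadrature pair before the ratio NE = (E_R − E_L)/(E_R + E_L)
is taken: one scalar per stimulus. Pooling first is algebraically identical
to flicker-weighted pointwise normalisation; an unweighted pointwise variant
would be a different model and is not implemented. A blank stimulus (flicker
below 1e−12) returns NE = 0 with a warning rather than an error, keeping
ISI curves total.

Adaptation is not modelled. MAE predictions use the response to the adaptor
as a proxy for adaptation strength, on the view that adaptation scales with
the activation the adaptor produces.

## Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| k | temporal scale factor; sets filter centre frequency | fitted (grid 20–200, step 5) | s⁻¹ |
| n | temporal filter order | 6 fast / 9 slow | — |
| β | negative-lobe weight | 0.9 | — |
| f, σ | Gabor carrier and envelope | 1.1 cpd, 0.5° | |
| frame, ISI set | stimulus timing | 40 ms; 0–315 ms | s |
| sf, contrast | stimulus grating | 1.6 cpd, 0.5 | |

The stimulus spatial frequency for the model defaults to the psychophysical
1.6 cpd; nothing in the model pins it, and it is configurable. The k grid
bounds and 5-unit step reflect the granularity at which fitted values are
reported; ties in RMS (which do not occur for clean data on this grid) break
toward smaller k, making fits deterministic.

As printed, the Gabor envelope would read exp(+(x/σ)²), which diverges; the
implementation uses the Gaussian exp(−(x/σ)²), the only reading consistent
with a Gabor filter. Factorials are evaluated as log-gamma so large orders
cannot overflow.

## Centre frequency

The centre frequency of a temporal filter is the peak of its amplitude
spectrum. Two routes are provided: an FFT of the sampled impulse response
(zero-padded to ≤ 0.01 Hz resolution; the window auto-extends with a warning
when a slow filter has not decayed within 0.5 s) and a closed-form maximiser
of |F(ω)| = |kⁿ/(k+iω)ⁿ⁺¹|·|1 − βk²/(k+iω)²|, used as an independent oracle.
Both exploit nothing of each other and agree to well under 1%. Since R
depends on t only through kt, the peak scales linearly: f_peak ≈ 0.04786·k Hz
for the slow filter (reduced peak ω/k ≈ 0.3007) and ≈ 0.0566·k for the fast
one, i.e. ≈ 5.3 and 6.2 Hz at k = 110. Frequencies are reported raw and
rounded to 0.5 Hz.

## Synthetic observers

The generator emulates the statistical structure of the psychophysical
procedure, not idiosyncrasies of real observers. Direction discrimination:
80 Bernoulli trials per ISI (40 per direction, collapsed), with success
probability (1 − 2λ)(0.5 + NE/2) + λ and lapse rate λ = 0.02 — the simplest
observer consistent with near-ceiling plateaus. MAE: four repeats per ISI of
max(0, g·max(0, NE) + ε), ε ~ N(0, σ²), with gain g = 15 s per unit NE and
σ = 3 s (20% of the gain), chosen to give durations in the 0–20 s range
typical of MAE reports; "no after-effect" responses are the zero floor. The
default dataset is 5 observers × 2 conditions × 2 tasks × 9 ISIs with
per-condition true k of 110/90 (photopic dd/MAE) and 47/56 (scotopic),
matching the group-level pattern the pipeline is meant to detect. All
randomness flows through per-observer seeds spawned from one master seed.

What passing tests do not show: real observers differ in lapse rate, gain,
and criterion, show adaptation and learning across sessions, and are
correlated across conditions. The generator models none of that, so recovery
results speak to the identifiability of k under idealised noise, not to the
analysis of any particular dataset.

## Identifiability of k from the dd task

A caveat the simulations expose: for high k the dd curve saturates — curves
for k = 105–115 differ by an RMS of only ≈ 0.006 on the rescaled scale, while
binomial noise at 80 trials contributes ≈ 0.05 per point. Noise-free data
refit exactly, and the photopic/scotopic ordering of fitted k is preserved
under noise, but the median |k̂ − k_true| for noisy dd observers at
k_true = 110 is ≈ 10 (two grid steps), not one. The MAE task, whose curve
retains shape throughout the ISI range, recovers k to within one grid step at
the default noise level. Group comparisons (paired t-tests across conditions)
remain decisively significant either way because the photopic–scotopic
separation is an order of magnitude larger than the recovery error.

## Numerical choices

Problem sizes are the native ones throughout: 160 × 300 stimulus matrices,
80 × 100 sensor kernels, 37-point k grids; model curves are memoised per
(task, k, ISI set, configuration), so fitting many observers costs one grid
sweep. Recovery simulations in the suite use 100 synthetic observers per
task. Exact symmetries (time reversal, matrix mirror) hold to ≈ 1e−10; the
±90° phase-step negation holds to ≈ 1e−3 only, because the spatial window is
not a whole number of grating periods at 1.6 cpd and 'same'-size edge
cropping is not shift-invariant — the residual is boundary, not model.

## Known limitations

1-D only; no adaptation dynamics, so MAE durations are predicted up to a
monotone map of adaptor response; no fitting of β, n, f or σ; the dd/k
identifiability ceiling above; and centre frequencies are reported from the
analytic spectrum of the impulse response — any convention that rescales the
frequency axis would rescale them proportionally (the fast/slow ratio is
convention-free).
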