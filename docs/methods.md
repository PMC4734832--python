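# Methods

## Signal model and synthetic sessions

The generator produces the statistical structure the analysis assumes, not a
biophysical simulation. A single coupled channel is

    x(t) = A_θ sin(2π f_θ t)
         + A_γ [ (1 − c) + c (1 + cos(2π f_θ t + φ₀)) / 2 ] sin(2π f_γ t)
         + σ_n · pink(t),

with coupling strength c ∈ [0, 1]: the gamma envelope is constant at c = 0
and fully theta-locked at c = 1 (vanishing where the modulating cosine is
−1, peaking at A_γ where it is +1). φ₀ defaults to 0. `pink(t)` is unit-RMS
1/f^α noise synthesized by spectral shaping of white noise, α = 1.5 by
default (a typical broadband LFP floor).

Two variants exist deliberately:

- `generate_coupled_signal` — the closed form above with a deterministic
  sinusoidal theta. Used for analytic checks (envelope endpoints, PSD peaks,
  comodulogram argmax).
- `generate_coupled_process` — theta is a *stochastic* narrowband process
  (white noise bandpassed to f_θ ± 1 Hz, default), whose phase drifts as
  in-vivo theta does. This is the variant for surrogate-based significance:
  a strictly periodic signal retains its phase–amplitude coupling under any
  circular time shift (the shift only rotates the preferred phase, to which
  the entropy-based MI is blind), so time-shift surrogates can only null
  coupling when theta decorrelates over the shift. With a 2 Hz bandwidth the
  theta coherence time is ~0.5 s, well under the ≥ 1 s minimum shift.

Sessions concatenate segments — pre-maze baseline (60 s), per-trial swim
(12 s default), per-trial platform (15 s) — each with its own coupling
parameters. Defaults encode the study conditions used throughout the tests:
maze segments carry 2× the baseline theta amplitude, the strongest coupling
(c = 0.8 vs 0.4 at baseline), and a theta-coherence target 0.3 above
baseline (0.8 vs 0.5; platform 0.7, c = 0.6, 1.2× amplitude). Amplitudes
are arbitrary units (A_θ = 1, A_γ = 0.5, σ_n = 0.5); in-vivo amplitudes and
SNR for this preparation are not published, so these are free parameters
chosen to give a realistic theta-dominated spectrum over a 1/f floor, and
they are not tuned per test.

Between-channel theta coherence is controlled by mixing a shared and a
per-channel independent narrowband theta: θ_i = √λ·s + √(1−λ)·n_i (all unit
power). Ignoring the noise floor the theta-band coherence is λ²; the
implementation inverts the full expression λ² (P_θ/(P_θ+N))², with N the
1/f noise power inside the theta band computed from the synthesis weights,
and clamps λ ≤ 1. A target of 1.0 therefore measures ≈ 0.99, limited by the
independent broadband noise.

Artifacts emulate the rat shaking or hitting the maze wall: Poisson onsets
(`rate`/s), Gamma(shape 4) durations with mean `duration_mean` (shape 4
keeps the total artifact time stable enough for Monte-Carlo validation
while remaining right-skewed), Tukey-tapered sinusoidal bursts at
`burst_freq` (15 Hz default) with peak amplitude `burst_amp_factor` × the
channel's clean RMS. A shake hits the whole headstage, so events are shared
across channels. Ground-truth intervals are returned merged.

What the generator does *not* emulate: non-sinusoidal theta waveform
asymmetry, volume conduction, spike leakage, electrode drift,
non-stationary noise floors, or behavior-locked gamma bursts. Passing tests
therefore demonstrate estimator correctness under the assumed model, not
robustness to every property of real LFP.

## Epoching and scrubbing

Epochs are half-open [t_start, t_end) in seconds; sample conversion is
floor(t·fs), 0-based, so re-assembled epochs never duplicate samples. The
maze epoch is the 4 s before each platform-reach; trials reaching the
platform sooner are kept but flagged short and excluded from spectral
averaging (a shorter window would change the spectral resolution).
Platform epochs are clipped to the recording end with a warning.

Artifact detection scans 0.25 s windows with a 0.125 s step (50% overlap so
bursts straddling a boundary are caught). A window is flagged when its RMS
— or the RMS of the > 15 Hz highpassed signal — exceeds
median + k·1.4826·MAD (k = 6 default) of that statistic over the epoch.
Both thresholds are relative, making detection invariant to global
amplitude scaling; a degenerate spread (MAD ≈ 0, e.g. constant or zero
signal) flags nothing. Adjacent flagged windows merge; interval edges are
then tightened to the supra-threshold extent of a 0.1 s moving-RMS envelope
±50 ms. Without this refinement each burst is over-flagged by up to one
window per side, which at ~20 bursts/100 s biases the recovered fraction by
several percent. Flagged-and-adjacent 2 s analysis windows are *excluded*
rather than the signal spliced: concatenation across cut points would
manufacture spectral discontinuities. The scrub report is
recovered = clean/total duration per channel.

The free parameter k has no in-vivo calibration — the original removal this
automates was manual — so no claim is made of matching any particular
recovered-percentage figure on real data; on synthetic data the detector is
validated against ground truth (false-positive rate ≤ 2% on clean signals,
≥ 90% recall on 10× bursts, recovered ≈ 1 − injected fraction ± 0.03).

## Spectral estimation

Multitaper PSD: 2 s windows, 1 s overlap, K = 3 DPSS tapers. The
time-bandwidth is NW = 2, the smallest standard choice admitting exactly
3 leakage-optimal tapers (K ≤ 2NW − 1). Tapers are unit-energy; per-window
per-taper one-sided periodograms (units²/Hz) are averaged over tapers then
windows; FFT length equals the window (0.5 Hz grid, no padding). The raw
PSD integrates to the signal variance (Parseval, checked to 10%).
Epoch PSDs are divided by the RMS of the epoch's clean samples; per-epoch
normalized spectra are averaged across trials within a phase before any
between-phase statistics. Coherence pools all window-taper cross/auto
spectra: |⟨S_xy⟩|²/(⟨S_xx⟩⟨S_yy⟩); RMS normalization cancels in the ratio
and is not applied. Band peaks take the maximum over the closed 5–12 Hz
band, ties resolved to the lowest frequency.

## Cross-frequency coupling

Filters are windowed-sinc (Hamming) FIR band-passes applied forward and
backward (zero net phase; squared magnitude response), computed with
FFT-based convolution. The number of taps is set by a transition width of
20% of the passband width, floored at 3 cycles of the low cutoff and capped
at a third of the signal length — a 2 Hz-wide theta band at 1 kHz gets a
~8 s kernel, which is why convolution is FFT-based. Phase and envelope come
from the analytic signal (Hilbert transform); the phase convention is the
analytic-signal angle: 0 at the peak of a cosine-aligned band signal, ±π at
its trough (fixed by test).

Scan grid defaults: theta centers 2–12 Hz step 1 Hz, ±1 Hz bands; gamma
centers 20–120 Hz step 5 Hz, **±10 Hz** bands. The gamma bandwidth must
exceed the modulating frequency: an envelope modulated at 8 Hz puts
sidebands ±8 Hz around the carrier, and a ±5 Hz filter removes them,
flattening the recovered envelope and destroying the very coupling being
measured. ±10 Hz keeps first-order sidebands for theta up to ~10 Hz; the
cost is overlapping gamma bands (adjacent cells share signal), which
spreads a strong peak across neighbors but does not move the argmax in the
validated strong-coupling regime. Low gamma centers' bands reach below the
theta range; only the band *centers* are required to sit above the theta
bands.

The 18 × 20° binning and the ln 18 normalization are fixed by the MI
definition; the log base cancels. Samples with phase exactly +π wrap to bin
0. Artifact-masked samples are dropped from the histogram (filtering runs
on the continuous signal first); at least 10 cycles of the lowest theta
band must survive masking.

Surrogates circularly shift each gamma envelope by one offset per
surrogate, drawn uniformly from [1 s, T − 1 s] from a seeded generator (one
offset shared across cells keeps surrogates comparable across the grid and
halves the cost; cells are standardized independently anyway). Circular
shifting preserves both marginals and the sample count. z = (MI − μ)/σ over
100 surrogates; a zero surrogate spread yields z = 0 with a warning. Null
calibration on uncoupled signals gives ~5% of cells beyond |z| = 1.96.

## Group statistics

ANOVA is fixed-effects and computed from explicit sums of squares (the only
scipy dependency is the F tail), so tests can check it against independent
oracles (statsmodels, residual-based brute force) to 1e-10. The two-way
design must be balanced and complete with ≥ 2 replicates per cell —
anything else is rejected with an explicit message rather than silently
reweighted. Repeated-measures structure (trials within rat) is deliberately
ignored: the unit of observation is whatever rows the caller supplies.
Pairwise follow-ups are pooled-variance two-sample t tests with
p_adj = min(m·p, 1); degenerate zero-within-variance cases pin F at 0 or ∞
with p = 1 or 0.

## Behavior

Errors are scored from the ordered zone-entry sequence: initial = number of
distinct error zones entered (≤ 5 by construction), repetitive = total
error-zone entries − initial. Consecutive duplicate entries collapse only
when their timestamps are identical (double-logged lines); otherwise each
entry counts. The five error-zone identities are configuration, not
constants. Latencies are differences from the trial start; a platform time
before the goal-arm time is physically impossible in this maze and raises.
The trial-log simulator draws error counts from a Poisson with a mean
decaying geometrically across sessions and lognormal-noised latencies
decaying toward a floor, identically for both groups, so the
training-session effect is real and the group effect is null by
construction.

## Pipeline and problem sizes

`run_pipeline` chains decimation (optional) → epoching → scrubbing →
per-phase spectra and coherence → optional comodulograms/z matrices for the
four channel pairings → report; it is deterministic given config and seed.
The single pre-maze epoch is split into 15 s pseudo-trials so the baseline
contributes several observations per session, matching the per-trial maze
and platform epochs. Cohort-level phase contrasts
(`phase_contrast_cohort`) analyze 5–6 sessions of ~168 s each (60 s
baseline, 4 × 12 s trials, 4 × 15 s platforms at 1 kHz); coupling recovery
uses 60 s single-channel signals at 1 kHz with 100 surrogates; scrub
validation uses 10 × 100 s signals with ~15% contamination. These sizes
give stable Monte-Carlo behavior (e.g. the Poisson spread of total artifact
time averages out over 10 seeds) while keeping a full test run to about a
minute.

## Known limitations

- Surrogate significance is only meaningful for signals whose slow rhythm
  decorrelates over ≥ 1 s; purely periodic inputs are, correctly, never
  significant.
- Coherence targets are met at the theta band only; broadband coherence is
  not controlled.
- The artifact detector assumes bursts are *loud* (several × RMS) and
  broadband; low-amplitude or purely low-frequency artifacts will pass.
- ANOVA ignores within-animal correlation; with few animals and many trials
  the reported p-values are anti-conservative in the same way pooled
  designs always are.
- Decimation requires integer factors (staged ≤ 10); arbitrary resampling
  is out of scope.
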