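# Methods

This note documents the generative models, the extraction procedures, the
numerical choices, and what the synthetic validation does and does not
establish. All times are milliseconds, amplitudes microvolts, and windows
half-open `[start, end)` on a 500 Hz sample grid (2 ms resolution).

## Task simulation (independent horse race)

Each session is 450 trials with stop probability 0.24. Go finishing times
are ex-Gaussian (defaults mu = 380, sigma = 50, tau = 70); stop-process
latencies are Gaussian (defaults mu_s = 160, sigma_s = 25). A stop trial
produces a response iff the go process finishes before `SSD + T_stop`
(independent race on the *central* finishing time). The overt keypress adds
a fixed motor conduction delay (50 ms), so the recorded go RT averages
380 + 70 + 50 = 500 ms and the ground-truth behavioral SSRT — what any
RT-based estimator can see — is mu_s + 50 = 210 ms. This coupling is the
package's model of the marker ladder: the stop process reaches the muscle
at ~160 ms (the prEMG decline point), while behavioral estimates absorb the
motor delay and land at ~210 ms.

The SSD staircase starts at 200 ms, moves +50 after each successful stop
and −50 after each failed one, clipped to [50, 900]. One-up/one-down
tracking converges on P(respond | stop) = 0.5; simulated grand-mean stop
accuracy sits slightly above 50% (~50.8%) because go omissions (1%) and
responses slower than the 1000 ms response window count as successful
stops regardless of the race. Performance feedback is evaluated every 75
trials (mean goRT > 600 ms -> "faster"; stop accuracy < 0.40 -> "more
accurate") and logged only — no strategic-adjustment model is simulated.
Trigger failures are available (`p_trigger_failure`) but default to 0.

Degenerate and edge conditions: latency parameters must be positive
(stop_mu may be 0), omission probability below 5%, and a session with no
responded go trial is rejected downstream.

## Synthetic EMG

Traces are go-locked (−200…+1600) and already rectified: tonic activity is
|N(0, 10 µV)| noise; responded trials add a 200 ms Hann burst (100 µV)
peaking 30 ms before the keypress; successful stop trials contain, with
probability 0.30, a partial burst — an asymmetric triangle rising over
80 ms to 60 µV and collapsing over 50 ms — whose apex sits at
`SSD + suppression_lag` (default lag 160, tied to the participant's stop
latency in cohort simulations). The incidence parameter is the detection
calibration: at the default signal-to-noise ratio the 1.2-z detector finds
essentially every partial burst and no noise-only trial, so the detection
rate reproduces the ~30% incidence reported for real recordings.

The extraction pipeline is staged and state-checked (`raw -> rms -> ratio
-> z`): a 25 ms centered moving RMS (edge-truncated windows; the window
width is a free parameter), division by each trial's mean baseline RMS
(−200…0), then z-scoring against the pooled mean/SD of all trials and
samples. Applying a stage out of order raises; z-scoring twice is therefore
impossible by construction. Trials whose mean rectified baseline exceeds
100 µV (strict) are rejected beforehand; "exceeds" is read strictly for
both the artifact gate and the 1.2 detection threshold. Detection operates
on per-trial z traces between go onset (exclusive) and the response-window
offset (inclusive). Detected trials are re-epoched to stop onset
(stop-locked time = go-locked time − SSD, rounded to the sample grid;
trials whose window falls outside the source epoch are dropped with a
warning), averaged, and the peak is the argmax on [0, SSRT]. A maximum on
the boundary sample is flagged, never silently returned.

## Synthetic EEG and stop-P3 extraction

Stop-locked epochs (−200…+800) of successful stop trials contain a
triangular P3: rising from `2*onset − peak` to `amp` (8 µV) at `peak`
(374), decaying over 150 ms — so the half-amplitude onset equals `onset`
(302) in closed form. Background noise is Gaussian shaped by a 25 ms Hann
FIR kernel with unit power (marginal SD preserved, default 5 µV); the
band-limited spectrum emulates the residual of a low-pass-filtered
recording, which is what any real epoch set would look like by this stage.

Extraction: per-trial baseline correction (−200…0; the epoch start is the
only pre-stimulus span available), ±120 µV absolute-amplitude rejection
(warning when more than half the trials drop), pointwise averaging, and
optionally a centered moving average on the averaged waveform (the cohort
pipeline uses 20 ms) standing in for the pre-extraction low-pass of real
pipelines. The peak is the largest strict local maximum in 250–500 ms
(plateaus take their earliest sample); if the window contains no interior
local maximum the window max is returned with a boundary flag. The onset
walks backward from the peak and stops at the first sample at or below
half-amplitude — no gap-jumping across non-monotone flanks — and returns
the sample after it. No sub-sample interpolation anywhere: both latencies
are quantized at 2 ms, which is the precision floor quoted for recovery.
Latencies are computed on per-participant averages (no jackknife).

## Cohort structure

The default study is 18 participants x {IFG, VC, SHAM} x {pre, peri,
post}. Participant-level parameters are Gaussian jitter around the cohort
means (stop_mu SD 15, go_mu SD 25, suppression SD 5, P3-onset SD 10,
P3-rise SD 8); the suppression point tracks the participant's stop latency
and the P3 onset shifts 0.9 ms per ms of stop-latency shift. The coupling
is deliberate: a shared latent inhibitory speed is the simplest mechanism
that makes the markers correlate across participants, as they do in real
cohorts. No between-cell (session) jitter is added by default; injected
effects are per-cell additive shifts declared in the config, and a
`stop_mu` shift moves the suppression point with it. Cell seeds derive
from `SeedSequence([master, participant, condition, time])`, so runs are
bit-reproducible and cells are independent.

Go-RT means use correct responses only (wrong-hand responses excluded);
the integration-method go distribution keeps wrong-hand responses (the go
process did finish) and replaces omissions with the maximum observed go
RT. The quantile is the 1-based rank `ceil(p * n_go)` with no
interpolation. The mean method sits above the integration method by the
mean-median gap of the skewed go distribution (~16 ms at the defaults);
the two agree for symmetric go distributions, which is how the estimator
pair is unit-tested.

## Inference layer

- Pearson r per cell after a single-pass Cook's-d screen: simple
  regression of the second-named measure on the first-named one, all
  points with d > 1 removed simultaneously (no iteration; removing more
  than ceil(n/10) points warns).
- Grid pooling: Fisher z = atanh(r), weighted mean with weights n − 3
  (inverse asymptotic variance of z), back-transformed with tanh. The
  one-sample JZS t-test of the unweighted z values supplies the Bayes
  factor. The 95% interval on the mean z is the central posterior interval
  under the JZS model (Cauchy(0, r·sigma) prior on the mean, Jeffreys on
  sigma), computed by 2-D grid integration over (mu, log sigma) on an
  801 x 241 grid spanning ±10 SE and ±3 log-units; a frequentist
  t-interval is available as `ci_method="t"`. The two constructions agree
  to ~0.01 on the r scale for 9-cell grids. Identical cells pool exactly
  with a degenerate (NaN) test.
- JZS Bayes factor: the Cauchy prior is expanded as a normal scale mixture
  with InvGamma(1/2, 1/2) mixing, giving a 1-D integral over g evaluated
  by adaptive quadrature on u = g/(1+g) with the central-t kernel divided
  out inside the log-space integrand (the integrand is then on the scale
  of the Bayes factor, avoiding underflow at large |t| or n; relative
  tolerance 1e-10, hard failure rather than a silent wrong value if the
  quadrature does not converge). Tests cross-check against a separate
  fixed-grid Gauss-Legendre brute force to 4+ significant figures.
- rmANOVA: F table from statsmodels' AnovaRM; Greenhouse-Geisser epsilon
  `tr(S)^2 / (d * tr(S^2))` and Mauchly's W (chi-square approximation)
  from the covariance of orthonormal Helmert contrasts (Kronecker products
  for the interaction), epsilon clipped to [1/d, 1]; corrected df are
  (eps*df1, eps*df2) with the corrected p from the F survival function.
  epsilon matches pingouin's implementation to machine precision in tests.
  A fully Bayesian rmANOVA (multivariate Cauchy priors) is out of scope;
  the frequentist GG-corrected ANOVA plus JZS t-tests stand in.
- Univariate outlier screen: |z| > 3.5 with population-SD z-scores.

## What the synthetic validation shows — and not

Recovery tests demonstrate that the estimators are unbiased to within a
few ms under the generator's assumptions: cohort-mean integration-SSRT
bias ≲ 3 ms (bound 10), prEMG peak within 2 samples at SNR 3, P3 onset
within 6 ms at SNR ≥ 4 with ≥ 40 trials. The generator does not emulate:
filtering artifacts, line noise, ocular components or ICA residue;
non-stationary or autocorrelated EMG baselines; RT sequential effects,
fatigue or strategic slowing after stop trials; P3 amplitude/latency
single-trial variability (the component is trial-constant within a cell);
or any between-subject covariance beyond the single latent-speed factor.
Passing recovery here therefore validates the *estimators and their
implementation*, not the claim that real data meet these assumptions.
Problem sizes in the shipped tests (25–120 replicates, 100-participant
recovery cohorts, 400-session staircase runs) were chosen so Monte-Carlo
error is small against each tolerance.

## Known limitations

- The integration estimator is undefined at stop accuracy 0 or 1; such
  cells surface as NaN and are excluded from ANOVAs by the caller.
- The prEMG peak bound [0, SSRT] inherits the SSRT estimate's noise; with
  very noisy SSRTs the bound can clip the true peak (boundary flags make
  this visible).
- Epoch files are float32 on disk (`.npy` + JSON sidecar); round-tripping
  loses ~1e-7 relative precision, irrelevant at physiological scales.
- The moving-RMS window (25 ms) and the averaged-ERP smoothing (20 ms) are
  conventions, exposed as parameters; latency estimates shift by a sample
  or two under reasonable alternatives.
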