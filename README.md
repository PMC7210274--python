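# stopmark

Simulation and analysis of **stopping latency** in the stop-signal task
(SST), for cognitive neurophysiologists who want to compare the different
markers that are claimed to time response inhibition:

- **SSRT** — the stop-signal reaction time, inferred from behavior under the
  independent horse-race model;
- **prEMG peak latency** — the moment partial muscle activity in successful
  stop trials starts to decline, i.e. when inhibition reaches the periphery;
- **stop-P3 peak and onset latency** — the timing of the centro-parietal P3
  deflection after the stop signal.

Because raw recordings for this kind of study are rarely shareable, the
package ships a first-class synthetic-data generator with known ground
truth: trial-level task behavior under the race model with an adaptive
stop-signal-delay (SSD) staircase, rectified EMG epochs containing full and
partial response bursts, and stop-locked EEG epochs containing a P3-like
component. Every synthesized latency is retrievable, so the complete
extraction pipeline can be validated by parameter recovery.

## The models in brief

**Race model.** On every trial a go process with ex-Gaussian finishing time
$T_{go} \sim \mu + \sigma Z + \mathrm{Exp}(\tau)$ races; on stop trials a
stop process $T_{stop} \sim \mathcal N(\mu_s, \sigma_s)$ launched at the SSD
races it, and a response is emitted iff $T_{go} < \mathrm{SSD} + T_{stop}$.
The keypress lags the central finishing time by a motor delay $\delta$, so
the ground-truth behavioral SSRT is $\mu_s + \delta$ (210 ms at the
defaults). The SSD moves +50 ms after each successful stop and −50 ms after
each failed one, holding stop accuracy near 50%.

**Integration SSRT.** With $p = P(\mathrm{respond}\mid\mathrm{stop})$, the
estimate is the $\lceil p \cdot n_{go}\rceil$-th smallest go RT (omissions
replaced by the maximum go RT) minus the mean SSD; the mean method uses the
mean go RT instead of the quantile.

**prEMG.** EMG epochs are moving-RMS transformed, expressed as a ratio to
each trial's pre-go baseline RMS, and z-scored against the pooled activity
of all trials. A partial response is detected in a successful stop trial
when any z-value before the response-window offset exceeds 1.2; its peak
latency is the argmax of the averaged stop-locked trace in [0, SSRT].

**stop-P3.** Artifact-free (±120 µV) baseline-corrected epochs are
averaged; the peak is the largest local maximum in 250–500 ms post-stop and
the onset is the half-amplitude latency found tracking backward from the
peak.

**Inference.** Pearson correlations per condition × time cell with Cook's-d
(> 1) bivariate outlier removal, pooled on the Fisher-z scale with $n-3$
weights and back-transformed ($M_r = \tanh \bar z$); one-sample/paired JZS
Bayes-factor t-tests with a Cauchy(0, r = 0.707) prior; and two-way
repeated-measures ANOVA with Mauchly's W and Greenhouse-Geisser-corrected
degrees of freedom.

## Worked example

```python
from stopmark import RaceModelParams, simulate_session, BehavioralDataset, summarize

session = simulate_session(RaceModelParams(seed=7))
s = summarize(BehavioralDataset(list(session)))
print(f"goRT  {s.goRT_mean:6.1f} ms   USRT {s.USRT_mean:6.1f} ms")
print(f"SSD   {s.SSD_mean:6.1f} ms   SSRT (integration) {s.SSRT_integration:6.1f} ms")
print(f"stop accuracy {s.stop_accuracy:.1%}   go omissions {s.go_omission_rate:.1%}")
```

prints

```
goRT   494.2 ms   USRT  456.8 ms
SSD    300.4 ms   SSRT (integration)  179.2 ms
stop accuracy 50.9%   go omissions 1.2%
```

The staircase has converged (stop accuracy ≈ 50%), unsuccessful-stop RTs
are faster than go RTs as the race model demands, and this particular
session's integration SSRT lands below the generative 210 ms — single-run
estimates scatter by some ±25 ms; the cohort mean is unbiased to within a
few ms (see the recovery table below).

The full 18-participant × 3-condition × 3-time-point study, with marker
extraction, rmANOVAs, pooled correlation grids and a parameter-recovery
report:

```bash
stopmark report --seed 1 --out out/
stopmark recovery --seed 1 --participants 8 --out out/
# staged alternatives: stopmark simulate / extract / stats / reproduce-table2
```

A typical recovery table (8 participants, seed 3):

```
             marker  bias_ms  rmse_ms
ssrt_integration_ms    -1.9     11.5
      premg_peak_ms    -2.2      2.5
        p3_onset_ms     0.8      9.6
         p3_peak_ms     1.6      7.8
```

Pooling the packaged grid of printed per-cell correlations:

```bash
stopmark reproduce-table2
```

```
         pair   m_r  m_r_printed  recovered
 SSRT - P3 ol  0.43         0.44       True
 SSRT - P3 pl  0.20         0.20       True
 SSRT - prEMG  0.69         0.69       True
prEMG - P3 ol  0.46         0.48      False
...
```

(The `recovered` flag marks agreement within ±0.01; a minority of rows
cannot be recovered exactly from two-decimal inputs and are reported with
the flag unset.)

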