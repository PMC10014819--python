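# warpkit

Perceptual warping in speech categorization: when listeners label sounds
from an acoustic continuum, the category boundary is not fixed — presenting
the continuum *serially* (stepping from one endpoint to the other) shifts
the boundary relative to random presentation, often as hysteresis: the
current percept lags the stimulus change. `warpkit` implements, end to end,
the paradigm used to study how this warping interacts with noise-degraded
listening: a synthetic /u/–/a/ vowel continuum with a speech-shaped masker,
a two-alternative mouse-tracking identification task, and the analyses that
quantify warping from both the button-level and the movement-level data.

It is aimed at auditory psychophysicists who want a reproducible reference
implementation of the full measurement chain — and, because no public
dataset accompanies the paradigm, a parametric synthetic observer whose
generative structure the analyses can be validated against.

## The models in brief

**Identification.** Per subject and condition, the proportion of /a/
responses over the 7-token continuum is fit with the two-parameter logistic

    P(x) = 1 / (1 + exp(−β₁ (x − β₀)))

where β₀ is the category boundary (the 50% point) and β₁ the slope.
Warping is the boundary displacement Δβ₀ between serial and random order.

**Stimuli.** Cascade (Klatt-style) formant synthesis: F1 in 7 equal steps
from 430 to 730 Hz; F0 = 100, F2 = 1090, F3 = 2350 Hz; 100 ms tokens,
10 ms raised-cosine ramps, 48,828 Hz. The masker is seeded Gaussian noise
shaped to the 1/3-octave-smoothed long-term power spectrum of the vowel
set, mixed at an exact SNR (the noise condition uses 0 dB).

**Mouse tracking.** 100 Hz cursor paths, normalized to the unit screen and
T = 101 normalized-time points, mirrored onto a common target. Curvature
is the area between the path and its start–end chord (shoelace a.u.c.);
attraction to the category is the proximity curve 1 − d/max(d). Condition
curves are compared with a running paired t-test (p < 0.01 per sample).

**Statistics.** Repeated-measures ANOVA on subject × condition cell means
with partial η², Holm-corrected contrasts, and Pearson correlations linking
each subject's |Δβ₀| to the change in their trajectory curvature, per SNR.

## Worked example

```python
import numpy as np
from warpkit import ContinuumSpec, synthesize_vowel, token_f1
from warpkit.acoustics import estimate_formants, estimate_f0
from warpkit.experiment import DesignSpec
from warpkit.observer import PopulationParams, simulate_experiment
from warpkit.psychometrics import fit_conditions

spec = ContinuumSpec()
tok1 = synthesize_vowel(spec, 1)
print(f"token 1: F1 target {token_f1(spec, 1):.0f} Hz, "
      f"LPC estimate {estimate_formants(tok1)[0]:.1f} Hz, "
      f"F0 {estimate_f0(tok1):.2f} Hz")

log = simulate_experiment(DesignSpec(), PopulationParams(), 8, seed=7,
                          include_trajectories=False)
fits = fit_conditions(log)
cell = fits[fits["order"].isin(["random", "serial"])]
print(cell.groupby(["snr", "order"], observed=True)[["beta0", "beta1"]]
      .mean().round(3))

fwd = fits[fits["order"] == "forward"].set_index("subject_id")["beta0"]
rnd = fits[fits["order"] == "random"].groupby(
    "subject_id", observed=True)["beta0"].mean()
print(f"mean |forward - random| boundary shift: "
      f"{np.abs(fwd - rnd).mean():.3f} tokens")
```

prints

```
token 1: F1 target 430 Hz, LPC estimate 420.4 Hz, F0 100.00 Hz
              beta0  beta1
snr   order
0dB   random  4.156  1.733
      serial  4.168  1.069
clean random  4.164  1.565
      serial  4.105  1.126
mean |forward - random| boundary shift: 0.932 tokens
```

Read: the synthesized endpoint token measures within 10 Hz of its F1
target; pooling forward and reverse blocks cancels the signed warp, so the
pooled-serial boundary barely moves while the pooled-serial *slope*
flattens (two opposed shifted sigmoids averaged); the per-direction shift
recovers the generating warp of 1.0 tokens (here 0.93 from eight
simulated listeners at 30 trials/token).

The full pipeline — stimuli, simulation, fits, trajectory geometry,
ANOVA/correlations, figures and a markdown report — runs from the shell:

```bash
warpkit run --out results/run1 --seed 7 --subjects 29
# or per-stage subcommands:
warpkit synth --out stimuli/ --seed 1
warpkit simulate --subjects 29 --seed 7 --out trials.csv
warpkit psychometrics --trials trials.csv --out fits.csv
warpkit mousetrack --trials trials.csv --out geom/
```

(`warpkit --help` lists the exact options; every stochastic stage takes a
seed and identical configs regenerate identical outputs.)

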