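"""Parametric synthetic listener: responses, reaction times, cursor paths.

The observer embodies the statistical structure the analysis chain assumes:

* identification follows a logistic in token index with subject-specific
  boundary (beta0) and slope (beta1);
* serial presentation displaces the effective boundary by a signed,
  subject-specific ``warp`` in the direction of the pass (hysteresis when
  positive) — large between-subject variability, fixed within subject;
* median reaction time has an inverted-V token profile peaking at the
  boundary, with serial-order facilitation and a small speed-up in noise,
  under multiplicative lognormal trial noise;
* 100 Hz cursor paths start at bottom-center on the invisible threshold
  line, rise vertically while the decision is ambiguous, then curve into the
  chosen response box; lateral hesitation grows with category ambiguity and
  shrinks under serial order in noise.

Responses are drawn from the warped boundary; trajectory curvature is driven
by ambiguity relative to the observer's *nominal* boundary, so stimulus
order reshapes cursor geometry only through the explicit serial-in-noise
reduction, keeping the generative roles of the two effects separable.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
import json

import numpy as np
import pandas as pd
from scipy.special import expit

from .experiment import (
    DesignSpec,
    Trajectory,
    TARGET_CENTERS,
    RESPONSE_SIDE,
    START_THRESHOLD_Y,
    SAMPLE_DT_MS,
    make_trial_sequence,
    block_conditions,
)

__all__ = [
    "ObserverParams",
    "PopulationParams",
    "effective_boundary",
    "simulate_response",
    "simulate_rt",
    "simulate_trajectory",
    "simulate_experiment",
]


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one synthetic listener.

    Units: ``beta0``/``warp`` in token units, ``beta1`` per token, RT terms
    in ms, trajectory terms dimensionless on the unit screen.
    """

    beta0: float = 4.0
    beta1: float = 1.5
    warp: float = 1.0                 # signed boundary lag per pass direction
    rt_base: float = 700.0
    rt_ambiguity_gain: float = 300.0  # peak slowing at the boundary
    rt_serial_facilitation: float = 80.0
    rt_noise_speedup: float = 40.0
    rt_sigma: float = 0.25            # lognormal dispersion of trial RTs
    traj_attraction: float = 10.0     # 1/s pull toward the chosen target
    traj_curvature_gain: float = 0.6  # ambiguity -> hesitation-phase length
    traj_deviation: float = 0.35      # max lateral excursion at full ambiguity
    traj_jitter: float = 0.004        # per-sample positional noise (screen units)
    curvature_noise_reduction_serial: float = 0.5  # in [0, 1]

    def __post_init__(self) -> None:
        if self.beta1 <= 0:
            raise ValueError("beta1 must be positive")
        for name in ("rt_base", "rt_ambiguity_gain", "rt_serial_facilitation",
                     "rt_noise_speedup", "rt_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.curvature_noise_reduction_serial <= 1:
            raise ValueError("curvature_noise_reduction_serial must be in [0,1]")


@dataclass(frozen=True)
class PopulationParams:
    """Distribution over ObserverParams: normal per-subject draws of beta0,
    beta1 and warp around the template; everything else is shared."""

    template: ObserverParams = ObserverParams()
    beta0_sd: float = 0.4
    beta1_sd: float = 0.3
    warp_sd_between: float = 0.75

    def sample(self, rng: np.random.Generator) -> ObserverParams:
        t = self.template
        beta0 = float(np.clip(rng.normal(t.beta0, self.beta0_sd), 1.5, 6.5))
        beta1 = float(np.clip(rng.normal(t.beta1, self.beta1_sd), 0.4, 20.0))
        warp = float(rng.normal(t.warp, self.warp_sd_between))
        return replace(t, beta0=beta0, beta1=beta1, warp=warp)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PopulationParams":
        d = json.loads(text)
        if "template" in d:
            d["template"] = ObserverParams(**d["template"])
        return cls(**d)


def _direction(order: str) -> float:
    return {"forward": 1.0, "reverse": -1.0}.get(order, 0.0)


def effective_boundary(params: ObserverParams, order: str) -> float:
    """Boundary used for responses: beta0, displaced by warp on serial passes."""
    return params.beta0 + params.warp * _direction(order)


def simulate_response(params: ObserverParams, token: int, order: str,
                      snr: str, rng: np.random.Generator,
                      prev_token: int | None = None) -> tuple[str, float]:
    """Draw one binary identification; returns (response, p_a).

    ``p_a`` is the probability of the /a/ label (token 7 endpoint):
    ``1/(1+exp(-beta1*(token - b_eff)))`` with the order-dependent boundary.
    ``prev_token`` is accepted for log compatibility; the model conditions on
    pass direction, not response history.
    """
    b_eff = effective_boundary(params, order)
    p_a = float(expit(params.beta1 * (token - b_eff)))
    response = "a" if rng.random() < p_a else "u"
    return response, p_a


def rt_location(params: ObserverParams, token: int, order: str,
                snr: str) -> float:
    """Deterministic (median) RT structure in ms: inverted-V over tokens,
    peaking at the effective boundary, minus condition facilitations."""
    b_eff = effective_boundary(params, order)
    bump = np.exp(-params.beta1**2 * (token - b_eff) ** 2 / 2.0)
    loc = params.rt_base + params.rt_ambiguity_gain * bump
    if order in ("forward", "reverse"):
        loc -= params.rt_serial_facilitation
    if snr != "clean":
        loc -= params.rt_noise_speedup
    return float(loc)


def simulate_rt(params: ObserverParams, token: int, order: str, snr: str,
                rng: np.random.Generator) -> float:
    """One trial RT: the median structure times lognormal(0, rt_sigma) noise,
    clipped to stay positive (>= 1 ms)."""
    loc = rt_location(params, token, order, snr)
    rt = loc * rng.lognormal(0.0, params.rt_sigma) if params.rt_sigma > 0 else loc
    return float(max(rt, 1.0))


def simulate_trajectory(params: ObserverParams, p_a: float, response: str,
                        rt_ms: float, rng: np.random.Generator,
                        serial_in_noise: bool = False) -> Trajectory:
    """One 100 Hz cursor path from the start threshold into the response box.

    The path follows the straight chord to the chosen target at constant
    speed plus a lateral hesitation excursion toward the competing side:
    amplitude and duration both grow with ambiguity ``h = 1 - |2 p_a - 1|``
    (hesitation-phase length ``traj_curvature_gain * h`` of the trial), and
    the excursion then decays at ``traj_attraction`` per unit of normalized
    trial time, so path geometry is invariant to trial duration (movement
    shape scales with movement time; RT effects and geometry effects stay
    separable in the generative model).  Under serial order in noise the
    effective ambiguity is shrunk by ``curvature_noise_reduction_serial``.
    Smooth (band-limited) seeded jitter perturbs interior samples; endpoints
    are exact.
    """
    if not 0.0 <= p_a <= 1.0:
        raise ValueError("p_a must lie in [0, 1]")
    n = int(round(rt_ms / SAMPLE_DT_MS)) + 1
    if n < 2:
        raise ValueError("rt too short for two cursor samples")

    side = RESPONSE_SIDE[response]
    target = np.array(TARGET_CENTERS[side])
    start = np.array([0.5, START_THRESHOLD_Y])

    h = 1.0 - abs(2.0 * p_a - 1.0)
    if serial_in_noise:
        h *= 1.0 - params.curvature_noise_reduction_serial

    chord = target - start
    length = np.hypot(*chord)
    u = chord / length
    normal = np.array([-u[1], u[0]])
    if np.dot(normal, np.array([0.5, 0.5]) - start) < 0:
        normal = -normal  # lateral excursion bows toward screen center

    s = np.linspace(0.0, 1.0, n)

    frac = min(0.85, params.traj_curvature_gain * h)
    profile = np.zeros(n)  # hesitation bump: linear rise then decay
    if frac > 0:
        rise = s < frac
        profile[rise] = s[rise] / frac
        profile[~rise] = np.exp(-params.traj_attraction * (s[~rise] - frac))
    dev = params.traj_deviation * h * profile
    # while hesitating the cursor also falls behind the constant-speed
    # schedule along the chord (vertical rise instead of diagonal progress),
    # which is what depresses proximity-to-target mid-trial
    progress = s - 0.5 * frac * profile
    base = start[None, :] + progress[:, None] * chord[None, :]

    pos = base + dev[:, None] * normal[None, :]
    if params.traj_jitter > 0 and n > 2:
        pos[1:-1] += _smooth_jitter(rng, n - 2, params.traj_jitter)
    pos[-1] = target
    pos = np.clip(pos, 0.0, 1.0)

    t_ms = np.arange(n, dtype=float) * SAMPLE_DT_MS
    return Trajectory(t_ms=t_ms, x=pos[:, 0], y=pos[:, 1], target_side=side)


#: Hann smoothing window for cursor jitter: ~110 ms at 100 Hz.  Hand tremor
#: is band-limited; unsmoothed sample-wise noise would tie measured path
#: area to the sampling count (and hence to RT), an artifact.
_JITTER_WINDOW = np.hanning(11)
_JITTER_WINDOW /= _JITTER_WINDOW.sum()
_JITTER_GAIN = 1.0 / np.sqrt(np.sum(_JITTER_WINDOW**2))


def _smooth_jitter(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """(n, 2) band-limited positional noise with per-sample SD ``sd``."""
    white = rng.normal(0.0, sd * _JITTER_GAIN, size=(n + 10, 2))
    out = np.empty((n, 2))
    for k in range(2):
        out[:, k] = np.convolve(white[:, k], _JITTER_WINDOW, "valid")
    return out


def _nominal_p_a(params: ObserverParams, token: int) -> float:
    return float(expit(params.beta1 * (token - params.beta0)))


def simulate_experiment(
    design: DesignSpec,
    population: PopulationParams | ObserverParams,
    n_subjects: int,
    seed: int = 0,
    return_params: bool = False,
    include_trajectories: bool = True,
):
    """Simulate the full six-block experiment for ``n_subjects`` listeners.

    Returns the long-format trial log (one row per cursor sample); with
    ``return_params`` also a DataFrame of each subject's generating
    parameters.  All randomness flows from ``seed`` through per-subject
    spawned substreams, so a subject's data are reproducible independent of
    ``n_subjects`` ordering.

    ``include_trajectories=False`` logs a single start-position row per
    trial — responses and RTs are drawn from the identical random stream,
    at a fraction of the memory, for analyses that never touch the cursor.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if isinstance(population, ObserverParams):
        population = PopulationParams(template=population,
                                      beta0_sd=0.0, beta1_sd=0.0,
                                      warp_sd_between=0.0)
    root = np.random.SeedSequence(seed)
    subject_seeds = root.spawn(n_subjects)

    cols: dict[str, list] = {
        "subject_id": [], "block_id": [], "trial_index": [], "token": [],
        "order": [], "snr": [], "response": [], "rt_ms": [],
        "sample_t_ms": [], "sample_x": [], "sample_y": []}
    param_rows = []
    for i, sseq in enumerate(subject_seeds):
        behav_seq, traj_seq = sseq.spawn(2)
        rng = np.random.default_rng(behav_seq)
        # separate substream: cursor noise never perturbs the response/RT
        # stream, so trajectory-free logs reproduce the same behavior
        traj_rng = np.random.default_rng(traj_seq)
        params = population.sample(rng)
        sid = f"S{i + 1:03d}"
        param_rows.append({"subject_id": sid, **asdict(params)})

        for b, (order, snr) in enumerate(
                block_conditions(design, seed=int(rng.integers(2**31)))):
            tokens = make_trial_sequence(design, order, seed=rng)
            block_id = f"B{b + 1}_{order}_{snr}"
            serial_in_noise = order in ("forward", "reverse") and snr != "clean"
            prev_token = None
            for j, token in enumerate(tokens):
                token = int(token)
                response, p_a = simulate_response(
                    params, token, order, snr, rng, prev_token=prev_token)
                rt = max(simulate_rt(params, token, order, snr, rng), 20.0)
                if include_trajectories:
                    traj = simulate_trajectory(
                        params, _nominal_p_a(params, token), response, rt,
                        traj_rng, serial_in_noise=serial_in_noise)
                    t_arr, x_arr, y_arr = traj.t_ms, traj.x, traj.y
                else:
                    t_arr = np.array([0.0])
                    x_arr = np.array([0.5])
                    y_arr = np.array([START_THRESHOLD_Y])
                m = len(t_arr)
                cols["subject_id"].append(np.repeat(sid, m))
                cols["block_id"].append(np.repeat(block_id, m))
                cols["trial_index"].append(np.full(m, j, dtype=np.int64))
                cols["token"].append(np.full(m, token, dtype=np.int64))
                cols["order"].append(np.repeat(order, m))
                cols["snr"].append(np.repeat(snr, m))
                cols["response"].append(np.repeat(response, m))
                cols["rt_ms"].append(np.full(m, rt))
                cols["sample_t_ms"].append(t_arr)
                cols["sample_x"].append(x_arr)
                cols["sample_y"].append(y_arr)
                prev_token = token

    log = pd.DataFrame({c: np.concatenate(v) for c, v in cols.items()})
    for c in ("subject_id", "block_id", "order", "snr", "response"):
        log[c] = log[c].astype("category")
    if return_params:
        return log, pd.DataFrame(param_rows)
    return log
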