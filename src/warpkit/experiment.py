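"""Experiment design space and the canonical long-format trial log.

The design fully crosses masking (clean vs speech-shaped noise at 0 dB SNR)
with presentation order (random, forward Tk1->Tk7, reverse Tk7->Tk1): six
blocks, 30 trials per token per block (210 trials/block with the 7-token
continuum).  Trial logs are stored long-format, one CSV row per 100 Hz
cursor sample, the schema shared by the simulator and every analysis stage.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "ORDERS",
    "SNRS",
    "DesignSpec",
    "Trajectory",
    "TrialRecord",
    "make_trial_sequence",
    "block_conditions",
    "write_trial_log",
    "read_trial_log",
    "records_to_frame",
    "frame_to_records",
    "TrialLogError",
]

ORDERS = ("random", "forward", "reverse")
SNRS = ("clean", "0dB")

#: Long-format CSV schema: one row per cursor sample.
LOG_COLUMNS = [
    "subject_id", "block_id", "trial_index", "token", "order", "snr",
    "response", "rt_ms", "sample_t_ms", "sample_x", "sample_y",
]

START_THRESHOLD_Y = 1.0 / 8.0  # invisible start line: 1/8 of screen height
SAMPLE_DT_MS = 10.0            # cursor sampled at 100 Hz

#: Response boxes are the top corners, each 15% x 15% of the screen;
#: "u" is fixed on the left, "a" on the right.
BOX_SIZE = 0.15
TARGET_CENTERS = {"left": (BOX_SIZE / 2, 1 - BOX_SIZE / 2),
                  "right": (1 - BOX_SIZE / 2, 1 - BOX_SIZE / 2)}
RESPONSE_SIDE = {"u": "left", "a": "right"}


class TrialLogError(ValueError):
    """Raised when a trial-log CSV violates the long-format schema."""


@dataclass(frozen=True)
class DesignSpec:
    """The six-block (order x SNR) within-subject design."""

    snr_conditions: tuple[str, ...] = SNRS
    order_conditions: tuple[str, ...] = ORDERS
    trials_per_token: int = 30
    n_tokens: int = 7
    block_order_seed: int = 0

    def __post_init__(self) -> None:
        for o in self.order_conditions:
            if o not in ORDERS:
                raise ValueError(f"unknown order condition {o!r}")
        for s in self.snr_conditions:
            if s not in SNRS:
                raise ValueError(f"unknown snr condition {s!r}")
        if self.trials_per_token < 1 or self.n_tokens < 2:
            raise ValueError("need >= 1 trial per token and >= 2 tokens")

    @property
    def trials_per_block(self) -> int:
        return self.trials_per_token * self.n_tokens

    @property
    def n_blocks(self) -> int:
        return len(self.snr_conditions) * len(self.order_conditions)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "DesignSpec":
        d = json.loads(text)
        for k in ("snr_conditions", "order_conditions"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class Trajectory:
    """100 Hz cursor samples in normalized screen coordinates (y up).

    Analysis starts at the crossing of the invisible threshold line
    (y = 1/8 screen height) and ends when the cursor enters the selected
    response box.
    """

    t_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    target_side: str
    start_threshold_y: float = START_THRESHOLD_Y

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=np.float64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if not len(self.t_ms) == len(self.x) == len(self.y):
            raise ValueError("t, x, y must have equal length")
        if self.target_side not in ("left", "right"):
            raise ValueError("target_side must be 'left' or 'right'")

    def __len__(self) -> int:
        return len(self.t_ms)


@dataclass
class TrialRecord:
    """One categorization trial with its full cursor trace."""

    subject_id: str
    block_id: str
    trial_index: int
    token: int
    order: str
    snr: str
    response: str
    rt_ms: float
    trajectory: Trajectory

    def __post_init__(self) -> None:
        if self.rt_ms <= 0:
            raise ValueError("rt_ms must be positive")
        if self.response not in RESPONSE_SIDE:
            raise ValueError("response must be 'u' or 'a'")


def make_trial_sequence(design: DesignSpec, order: str,
                        seed: int | np.random.Generator = 0) -> np.ndarray:
    """Token sequence (1-based) for one block.

    Serial orders are ``trials_per_token`` concatenated monotone passes
    (forward 1..n, reverse n..1).  Random order draws one balanced
    permutation of 1..n per pass, guaranteeing exactly ``trials_per_token``
    occurrences of every token.
    """
    if order not in ORDERS:
        raise ValueError(f"unknown order {order!r}")
    tokens = np.arange(1, design.n_tokens + 1)
    if order == "forward":
        return np.tile(tokens, design.trials_per_token)
    if order == "reverse":
        return np.tile(tokens[::-1], design.trials_per_token)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    return np.concatenate(
        [rng.permutation(tokens) for _ in range(design.trials_per_token)])


def block_conditions(design: DesignSpec,
                     seed: int | None = None) -> list[tuple[str, str]]:
    """The (order, snr) pairs of the design's blocks, shuffled per subject.

    ``seed=None`` uses ``design.block_order_seed``.
    """
    pairs = [(o, s) for s in design.snr_conditions
             for o in design.order_conditions]
    rng = np.random.default_rng(
        design.block_order_seed if seed is None else seed)
    rng.shuffle(pairs)
    return pairs


def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    """Flatten trial records to the long-format schema (one row per sample)."""
    if not records:
        return pd.DataFrame({c: [] for c in LOG_COLUMNS})
    rows = {c: [] for c in LOG_COLUMNS}
    for r in records:
        n = len(r.trajectory)
        rows["subject_id"].append(np.repeat(r.subject_id, n))
        rows["block_id"].append(np.repeat(r.block_id, n))
        rows["trial_index"].append(np.repeat(r.trial_index, n))
        rows["token"].append(np.repeat(r.token, n))
        rows["order"].append(np.repeat(r.order, n))
        rows["snr"].append(np.repeat(r.snr, n))
        rows["response"].append(np.repeat(r.response, n))
        rows["rt_ms"].append(np.repeat(r.rt_ms, n))
        rows["sample_t_ms"].append(r.trajectory.t_ms)
        rows["sample_x"].append(r.trajectory.x)
        rows["sample_y"].append(r.trajectory.y)
    return pd.DataFrame({c: np.concatenate(v) for c, v in rows.items()})


def frame_to_records(df: pd.DataFrame) -> list[TrialRecord]:
    """Reassemble TrialRecords from a long-format frame, validating sampling."""
    records: list[TrialRecord] = []
    if df.empty:
        return records
    for (sid, bid, idx), g in df.groupby(
            ["subject_id", "block_id", "trial_index"], sort=True,
            observed=True):
        g = g.sort_values("sample_t_ms")
        t = g["sample_t_ms"].to_numpy(dtype=float)
        if len(t) > 1:
            dt = np.diff(t)
            if not np.allclose(dt, SAMPLE_DT_MS, atol=1e-6):
                warnings.warn(
                    f"trial {sid}/{bid}/{idx}: non-uniform sampling "
                    f"(dt range {dt.min():.3f}-{dt.max():.3f} ms)")
        response = str(g["response"].iloc[0])
        traj = Trajectory(
            t_ms=t,
            x=g["sample_x"].to_numpy(dtype=float),
            y=g["sample_y"].to_numpy(dtype=float),
            target_side=RESPONSE_SIDE[response],
        )
        records.append(TrialRecord(
            subject_id=str(sid), block_id=str(bid), trial_index=int(idx),
            token=int(g["token"].iloc[0]), order=str(g["order"].iloc[0]),
            snr=str(g["snr"].iloc[0]), response=response,
            rt_ms=float(g["rt_ms"].iloc[0]), trajectory=traj))
    return records


def validate_trial_frame(df: pd.DataFrame) -> None:
    """Schema check; raises TrialLogError naming the offending column/row."""
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise TrialLogError(f"missing columns: {missing}")
    if df.empty:
        return
    for col in ("token", "rt_ms", "sample_t_ms", "sample_x", "sample_y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = int(df.index[coerced.isna()][0])
            raise TrialLogError(f"column {col!r} non-numeric at row {row}")
    bad_order = set(df["order"].unique()) - set(ORDERS)
    if bad_order:
        raise TrialLogError(f"unknown order labels {sorted(bad_order)}")
    bad_snr = set(df["snr"].unique()) - set(SNRS)
    if bad_snr:
        raise TrialLogError(f"unknown snr labels {sorted(bad_snr)}")


def write_trial_log(records_or_frame, path) -> None:
    """Write a trial log CSV (long format, one row per cursor sample)."""
    df = (records_or_frame if isinstance(records_or_frame, pd.DataFrame)
          else records_to_frame(records_or_frame))
    df.to_csv(path, index=False, float_format="%.10g")


def read_trial_log(path, as_records: bool = False):
    """Read and validate a trial log CSV.

    Returns the long-format DataFrame, or TrialRecords if ``as_records``.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "block_id": str})
    if df.empty:
        df = pd.DataFrame({c: [] for c in LOG_COLUMNS})
    validate_trial_frame(df)
    return frame_to_records(df) if as_records else df
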