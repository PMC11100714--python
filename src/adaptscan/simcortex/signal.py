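"""Voxel-level BOLD simulation with category tuning and repetition fatigue.

Each voxel carries a baseline, a nonnegative selectivity weight per stimulus
category, and a multiplicative *fatigue* factor applied to repeated
presentations of the same exemplar — the generative stand-in for repetition
suppression (fewer neurons respond, or responding neurons enter a refractory
state, when an exemplar repeats).  The neural drive is convolved with a
hemodynamic response and sampled at the TR, with AR(1) Gaussian noise and
smooth random-walk motion traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .. import glm as _glm
from .designs import ExperimentDesign

__all__ = [
    "VoxelTuningParams",
    "TimeSeriesDataset",
    "event_fatigue_exponents",
    "expected_condition_attenuation",
    "simulate_timeseries",
    "simulate_motion",
]


@dataclass(frozen=True)
class VoxelTuningParams:
    """Generative tuning of one voxel (or one homogeneous voxel population)."""

    baseline: float = 1000.0
    selectivity: Mapping[str, float] = field(default_factory=dict)
    fatigue: float = 1.0  # response factor per repeat; 1 = no suppression
    noise_sd: float = 0.0
    ar1: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.fatigue <= 1.0):
            raise ValueError("fatigue must lie in (0, 1]")
        for cat, w in self.selectivity.items():
            if not np.isfinite(w) or w < 0:
                raise ValueError(f"selectivity[{cat!r}] must be finite and >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.ar1 < 1.0):
            raise ValueError("ar1 must lie in [0, 1)")


@dataclass
class TimeSeriesDataset:
    """Simulated voxel x volume signal plus nuisance traces and labels."""

    signal: np.ndarray
    design: ExperimentDesign
    motion: np.ndarray | None = None
    voxel_labels: pd.DataFrame | None = None
    grid_shape: tuple[int, ...] | None = None
    ground_truth: Sequence[VoxelTuningParams] | None = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2 or self.signal.shape[1] != self.design.n_volumes:
            raise ValueError("signal must be voxels x n_volumes")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")
        if self.motion is not None and self.motion.shape[0] != self.design.n_volumes:
            raise ValueError("motion trace length must equal n_volumes")
        if self.voxel_labels is not None and len(self.voxel_labels) != self.signal.shape[0]:
            raise ValueError("voxel label count must equal the number of voxels")

    @property
    def n_voxels(self) -> int:
        return self.signal.shape[0]


def event_fatigue_exponents(
    design: ExperimentDesign, mode: str = "exemplar_memory"
) -> dict[str, list[int]]:
    """Fatigue exponent k for each event, grouped by condition label.

    ``exemplar_memory`` (default): k counts prior occurrences of the event's
    exemplar within the current block, so alternating blocks attenuate less
    than same blocks but more than different blocks.  ``immediate``: k counts
    only the immediately preceding consecutive run of the same exemplar, so
    alternating blocks incur no attenuation.
    """
    if mode not in ("exemplar_memory", "immediate"):
        raise ValueError(f"unknown fatigue mode: {mode!r}")
    out: dict[str, list[int]] = {}
    block_counts: dict[str, int] = {}
    prev_end, prev_label, prev_ex, run_len = -np.inf, None, None, 0
    for ev in design.events:
        gap = ev.onset - prev_end
        new_block = ev.trial_type != prev_label or gap > ev.duration + 0.5
        if new_block:
            block_counts = {}
            run_len = 0
            prev_ex = None
        if mode == "exemplar_memory":
            k = block_counts.get(ev.exemplar_id, 0)
            block_counts[ev.exemplar_id] = k + 1
        else:
            run_len = run_len + 1 if ev.exemplar_id == prev_ex else 0
            k = run_len
        out.setdefault(ev.trial_type, []).append(k)
        prev_end, prev_label, prev_ex = ev.onset + ev.duration, ev.trial_type, ev.exemplar_id
    return out


def expected_condition_attenuation(
    condition: str, n_stims: int = 12, fatigue: float = 1.0, mode: str = "exemplar_memory"
) -> float:
    """Mean per-event response factor for one block of a given condition.

    This is the generator's contract for the expected block response: e.g. a
    same block attenuates to ``sum(f**k for k in range(n)) / n``.
    """
    f = float(fatigue)
    if condition == "different" or mode == "immediate" and condition == "alternating":
        reps = [0] * n_stims
    elif condition == "alternating":
        reps = [i // 2 for i in range(n_stims)]
    elif condition == "same":
        reps = list(range(n_stims))
    else:
        raise ValueError(f"unknown condition: {condition!r}")
    return float(np.mean([f**k for k in reps]))


def simulate_motion(n_volumes: int, rng: np.random.Generator, step_sd: float = 0.02) -> np.ndarray:
    """Six smooth random-walk motion traces (translations + rotations)."""
    steps = rng.normal(0.0, step_sd, size=(n_volumes + 4, 6))
    walk = np.cumsum(steps, axis=0)
    kernel = np.ones(5) / 5.0
    smooth = np.column_stack(
        [np.convolve(walk[:, j], kernel, mode="valid") for j in range(6)]
    )
    return smooth[:n_volumes]


def simulate_timeseries(
    design: ExperimentDesign,
    tuning: Sequence[VoxelTuningParams],
    hrf_kind: str | None = None,
    seed: int = 0,
    dt: float = 0.05,
    fatigue_mode: str = "exemplar_memory",
    within_block: str = "distributed",
    voxel_labels: pd.DataFrame | None = None,
    grid_shape: tuple[int, ...] | None = None,
) -> TimeSeriesDataset:
    """Simulate one run of BOLD data for a list of voxel tuning parameters.

    Each event drives a voxel with amplitude ``selectivity[category] *
    fatigue**k`` (k per ``fatigue_mode``).  With ``within_block="distributed"``
    (default) a block's total drive is spread uniformly over its events, so
    the noiseless signal is an exact linear combination of the unit condition
    regressors; ``"event"`` places each amplitude at its own event.
    """
    if not tuning:
        raise ValueError("tuning list must be non-empty")
    if within_block not in ("distributed", "event"):
        raise ValueError(f"unknown within_block mode: {within_block!r}")
    kind = hrf_kind or ("gamma" if design.paradigm == "adaptation" else "double_gamma")
    _ = _glm.hrf(kind, 1.0)  # validates hrf kind eagerly
    exponents = event_fatigue_exponents(design, fatigue_mode)

    # per (label, fatigue value): the convolved fatigue-profile regressor
    n_vox = len(tuning)
    n_vol = design.n_volumes
    signal = np.zeros((n_vox, n_vol))
    unique_f = sorted({tp.fatigue for tp in tuning})
    for label, ks in exponents.items():
        cat = label.split("_")[0]
        sels = np.array([tp.selectivity.get(cat, 0.0) for tp in tuning])
        if not np.any(sels):
            continue
        for f in unique_f:
            idx = [v for v in range(n_vox) if tuning[v].fatigue == f and sels[v] > 0]
            if not idx:
                continue
            w = np.asarray([f**k for k in ks], dtype=float)
            if within_block == "distributed":
                # uniform redistribution of each block's summed drive; blocks
                # are contiguous runs of matching events in schedule order
                w = _distribute_block_means(design, label, w)
            reg = _glm.task_regressor(design, label, kind, dt=dt, weights=w)
            for v in idx:
                signal[v] += sels[v] * reg

    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    baselines = np.array([tp.baseline for tp in tuning])
    sds = np.array([tp.noise_sd for tp in tuning])
    ars = np.array([tp.ar1 for tp in tuning])
    signal += baselines[:, None]
    if np.any(sds > 0):
        innov = sds * np.sqrt(1.0 - ars**2)
        eps = rng.normal(size=(n_vox, n_vol)) * innov[:, None]
        acc = rng.normal(size=n_vox) * sds  # stationary start
        for t in range(n_vol):
            acc = ars * acc + eps[:, t]
            signal[:, t] += acc
    motion = simulate_motion(n_vol, rng)
    return TimeSeriesDataset(
        signal=signal,
        design=design,
        motion=motion,
        voxel_labels=voxel_labels,
        grid_shape=grid_shape,
        ground_truth=tuple(tuning),
    )


def _distribute_block_means(
    design: ExperimentDesign, label: str, weights: np.ndarray
) -> np.ndarray:
    """Replace per-event weights by their within-block mean."""
    events = [ev for ev in design.events if ev.trial_type == label]
    out = weights.astype(float).copy()
    start = 0
    for i in range(1, len(events) + 1):
        boundary = i == len(events) or (
            events[i].onset - (events[i - 1].onset + events[i - 1].duration)
            > events[i - 1].duration + 0.5
        )
        if boundary:
            out[start:i] = out[start:i].mean()
            start = i
    return out
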