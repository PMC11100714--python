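"""Voxelwise general linear modelling of (simulated) BOLD time series.

The localizer paradigm is modelled with stimulus boxcars convolved with a
canonical double-gamma HRF; the adaptation paradigm's short mini-blocks use a
single-gamma basis (``(t/(p*q))**p * exp(p - t/q)`` with p = 8.6, q = 0.547).
Time series are scaled to a run mean of 100 per voxel (so β-weights are in
percent of mean signal), volumes with excessive motion or widespread
intensity outliers are censored, and ordinary least squares (optionally with
AR(1) prewhitening) yields per-voxel condition βs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import TYPE_CHECKING, Sequence

import numpy as np
from numpy.polynomial import legendre
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from .simcortex.designs import ExperimentDesign
    from .simcortex.signal import TimeSeriesDataset

__all__ = [
    "hrf",
    "task_regressor",
    "DesignMatrix",
    "build_design_matrix",
    "CensorMask",
    "scale_and_censor",
    "BetaMap",
    "fit_glm",
    "contrast_map",
]

_HRF_SPAN = 32.0  # seconds of HRF support retained


@lru_cache(maxsize=8)
def _double_gamma_norm(peak: float, undershoot: float, ratio: float) -> float:
    tt = np.arange(0.0, _HRF_SPAN, 0.01)
    return float(np.max(_double_gamma_raw(tt, peak, undershoot, ratio)))


def _double_gamma_raw(t: np.ndarray, peak: float, undershoot: float, ratio: float):
    # shape/scale chosen so each gamma density has its mode at `peak`/`undershoot`
    d1 = stats.gamma.pdf(t, peak + 1.0, scale=1.0)
    d2 = stats.gamma.pdf(t, undershoot + 1.0, scale=1.0)
    return d1 - ratio * d2


def hrf(
    kind: str,
    t: float | np.ndarray,
    peak: float = 6.0,
    undershoot: float = 16.0,
    ratio: float = 1.0 / 6.0,
    p: float = 8.6,
    q: float = 0.547,
) -> float | np.ndarray:
    """Hemodynamic response at time ``t`` (seconds) since stimulus onset.

    ``double_gamma`` is the canonical difference-of-gamma-densities response
    (peak 6 s, undershoot 16 s, undershoot ratio 1/6) normalised to unit peak;
    ``gamma`` is the single-gamma basis with unit peak at ``p*q`` seconds.
    Both are 0 at ``t = 0`` and for ``t < 0``.
    """
    tt = np.asarray(t, dtype=float)
    scalar = tt.ndim == 0
    tt = np.atleast_1d(tt)
    if kind == "double_gamma":
        out = np.where(
            tt > 0,
            _double_gamma_raw(np.maximum(tt, 0.0), peak, undershoot, ratio)
            / _double_gamma_norm(peak, undershoot, ratio),
            0.0,
        )
    elif kind == "gamma":
        safe = np.maximum(tt, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(
                tt > 0, (safe / (p * q)) ** p * np.exp(p - safe / q), 0.0
            )
    else:
        raise ValueError(f"unknown hrf kind: {kind!r}")
    return float(out[0]) if scalar else out


def _default_hrf_kind(paradigm: str) -> str:
    return "gamma" if paradigm == "adaptation" else "double_gamma"


def task_regressor(
    design: "ExperimentDesign",
    label: str,
    hrf_kind: str | None = None,
    dt: float = 0.05,
    weights: Sequence[float] | None = None,
) -> np.ndarray:
    """HRF-convolved regressor for one condition label, sampled at the TR.

    The neural drive is a boxcar of each event's duration (unit height, or
    ``weights[i]`` for the i-th matching event); convolution is computed on a
    fine ``dt`` grid and sampled at volume onsets.  With ``weights=None`` this
    is the design-matrix regressor; the simulator reuses the same routine with
    per-event amplitudes so that simulated signal lies in the model's span.
    """
    kind = hrf_kind or _default_hrf_kind(design.paradigm)
    n_grid = int(np.ceil(design.duration / dt)) + 1
    neural = np.zeros(n_grid)
    matches = [ev for ev in design.events if ev.trial_type == label]
    if weights is not None and len(weights) != len(matches):
        raise ValueError("weights length must equal the number of matching events")
    for i, ev in enumerate(matches):
        w = 1.0 if weights is None else float(weights[i])
        a = int(round(ev.onset / dt))
        b = max(a + 1, int(round((ev.onset + ev.duration) / dt)))
        neural[a : min(b, n_grid)] += w
    kernel = hrf(kind, np.arange(0.0, _HRF_SPAN, dt))
    conv = np.convolve(neural, kernel)[:n_grid] * dt
    vol_idx = np.minimum(
        np.round(np.arange(design.n_volumes) * design.tr / dt).astype(int), n_grid - 1
    )
    return conv[vol_idx]


@dataclass(frozen=True)
class DesignMatrix:
    """Volume x regressor matrix with named, typed columns."""

    matrix: np.ndarray
    names: tuple[str, ...]
    kinds: tuple[str, ...]  # per column: {"task", "motion", "drift"}

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.names) or len(self.names) != len(self.kinds):
            raise ValueError("inconsistent design-matrix metadata")

    @property
    def task_indices(self) -> np.ndarray:
        return np.array([i for i, k in enumerate(self.kinds) if k == "task"])

    @property
    def task_names(self) -> tuple[str, ...]:
        return tuple(self.names[i] for i in self.task_indices)

    def check_rank(self, rows: np.ndarray | None = None) -> None:
        m = self.matrix if rows is None else self.matrix[rows]
        if m.shape[0] < m.shape[1] or np.linalg.matrix_rank(m) < m.shape[1]:
            # name the columns implicated in the deficiency via the QR diagonal
            _, r = np.linalg.qr(m)
            d = np.abs(np.diag(r))
            bad = [self.names[j] for j in np.where(d < 1e-8 * max(d.max(), 1e-30))[0]]
            raise np.linalg.LinAlgError(
                f"design matrix is rank deficient (columns: {bad or self.names})"
            )


def default_drift_order(duration: float) -> int:
    """Legendre drift order: 1 + floor(run duration / 150 s)."""
    return 1 + int(duration // 150.0)


def build_design_matrix(
    design: "ExperimentDesign",
    basis_kind: str | None = None,
    motion: np.ndarray | None = None,
    drift_order: int | None = None,
    dt: float = 0.05,
) -> DesignMatrix:
    """Task + motion + Legendre-drift design matrix for one run.

    One task regressor per condition label (5 categories for the localizer, 9
    block types for adaptation), six motion columns when motion traces are
    supplied, and drift polynomials up to ``drift_order`` (default
    ``1 + floor(duration/150 s)``), including the constant.
    """
    labels = [
        lab
        for lab in design.condition_labels
        if any(ev.trial_type == lab for ev in design.events)
    ]
    cols: list[np.ndarray] = []
    names: list[str] = []
    kinds: list[str] = []
    for lab in labels:
        cols.append(task_regressor(design, lab, basis_kind, dt=dt))
        names.append(lab)
        kinds.append("task")
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != design.n_volumes:
            raise ValueError("motion trace length must equal n_volumes")
        mc = motion - motion.mean(axis=0)
        for j in range(mc.shape[1]):
            cols.append(mc[:, j])
            names.append(f"motion_{'xyzprw'[j] if j < 6 else j}")
            kinds.append("motion")
    order = default_drift_order(design.duration) if drift_order is None else drift_order
    x = np.linspace(-1.0, 1.0, design.n_volumes)
    for d in range(order + 1):
        coef = np.zeros(d + 1)
        coef[d] = 1.0
        cols.append(legendre.legval(x, coef))
        names.append(f"drift_{d}")
        kinds.append("drift")
    dm = DesignMatrix(np.column_stack(cols), tuple(names), tuple(kinds))
    dm.check_rank()
    return dm


@dataclass(frozen=True)
class CensorMask:
    """Per-volume keep flags with a reason for every dropped volume."""

    keep: np.ndarray
    reasons: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i in self.reasons:
            if self.keep[i]:
                raise ValueError("reason recorded for a kept volume")

    @property
    def n_kept(self) -> int:
        return int(np.sum(self.keep))


def scale_and_censor(
    data: "TimeSeriesDataset",
    motion_threshold: float = 1.0,
    mad_k: float = 5.5,
    outlier_frac: float = 0.10,
) -> tuple["TimeSeriesDataset", CensorMask]:
    """Scale each voxel's series to a run mean of 100 and flag bad volumes.

    Volumes are censored when the Euclidean norm of the motion derivative
    exceeds ``motion_threshold`` (in the trace's native units) or when more
    than ``outlier_frac`` of voxels deviate from their run median by more than
    ``mad_k`` median absolute deviations.
    """
    sig = np.asarray(data.signal, dtype=float)
    means = sig.mean(axis=1)
    bad = np.where(means <= 0)[0]
    if bad.size:
        raise ValueError(f"non-positive mean signal in voxels {bad.tolist()}")
    scaled = sig * (100.0 / means)[:, None]

    n_vol = sig.shape[1]
    keep = np.ones(n_vol, dtype=bool)
    reasons: dict[int, str] = {}
    if data.motion is not None:
        deriv = np.diff(np.asarray(data.motion, dtype=float), axis=0, prepend=data.motion[:1])
        enorm = np.sqrt((deriv**2).sum(axis=1))
        for i in np.where(enorm > motion_threshold)[0]:
            keep[i] = False
            reasons[int(i)] = "motion"
    med = np.median(scaled, axis=1, keepdims=True)
    mad = np.median(np.abs(scaled - med), axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        out = np.abs(scaled - med) > mad_k * np.where(mad > 0, mad, np.inf)
    frac = out.mean(axis=0)
    for i in np.where(frac > outlier_frac)[0]:
        if keep[i]:
            keep[i] = False
            reasons[int(i)] = "outlier"
    return replace(data, signal=scaled), CensorMask(keep, reasons)


@dataclass
class BetaMap:
    """Per-voxel condition β-weights with the metadata needed for inference.

    ``betas`` is voxel x condition (percent of mean signal after scaling);
    ``cov_task`` is ``(X' V^-1 X)^-1`` restricted to the task columns (shared
    across voxels, or per-voxel when prewhitening coefficients differ), so a
    contrast t-statistic is ``c'β / sqrt(resid_var * c' cov_task c)``.
    """

    betas: np.ndarray
    conditions: tuple[str, ...]
    resid_var: np.ndarray
    df: int
    cov_task: np.ndarray
    voxel_coords: np.ndarray | None = None
    grid_shape: tuple[int, ...] | None = None
    voxel_info: object | None = None  # pandas DataFrame of labels, optional
    runs: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be unique")
        if not np.all(np.isfinite(self.betas)):
            raise ValueError("non-finite β values")

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[0]

    def beta(self, condition: str) -> np.ndarray:
        return self.betas[:, self.conditions.index(condition)]

    def contrast(
        self, target: str, baselines: Sequence[str] | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Balanced contrast (target minus mean of baselines) and its t-stat."""
        if baselines is None:
            baselines = [c for c in self.conditions if c != target]
        baselines = list(baselines)
        if not baselines:
            raise ValueError("empty baseline set")
        if target in baselines:
            raise ValueError("target cannot appear in the baseline set")
        c = np.zeros(len(self.conditions))
        c[self.conditions.index(target)] = 1.0
        for b in baselines:
            c[self.conditions.index(b)] -= 1.0 / len(baselines)
        con = self.betas @ c
        if self.cov_task.ndim == 2:
            cnorm = float(c @ self.cov_task @ c)
            var = self.resid_var * cnorm
        else:
            var = self.resid_var * np.einsum("i,vij,j->v", c, self.cov_task, c)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(var > 0, con / np.sqrt(np.maximum(var, 1e-300)), 0.0)
        return con, t


def _ar1_whiten(rows: np.ndarray, rho: float) -> np.ndarray:
    out = rows.copy()
    out[1:] = rows[1:] - rho * rows[:-1]
    out[0] = rows[0] * np.sqrt(max(1.0 - rho**2, 1e-12))
    return out


def fit_glm(
    data: "TimeSeriesDataset",
    X: DesignMatrix,
    mask: CensorMask | None = None,
    prewhiten: bool = False,
    ar1: float | None = None,
) -> BetaMap:
    """Ordinary least squares per voxel on the kept volumes.

    Nuisance (motion, drift) regressors are estimated jointly and dropped;
    only task βs are returned.  With ``prewhiten=True`` an AR(1) transform is
    applied before fitting, using ``ar1`` if given or a per-voxel lag-1
    autocorrelation estimated from OLS residuals.
    """
    y = np.asarray(data.signal, dtype=float).T  # volumes x voxels
    keep = mask.keep if mask is not None else np.ones(y.shape[0], dtype=bool)
    Xm_full = X.matrix
    if keep.sum() < Xm_full.shape[1] + 1:
        raise ValueError("too few volumes remain after censoring")
    X.check_rank(keep)
    task_idx = X.task_indices
    p = Xm_full.shape[1]

    def _solve(Xw: np.ndarray, yw: np.ndarray):
        Xk, yk = Xw[keep], yw[keep]
        beta, _, _, _ = np.linalg.lstsq(Xk, yk, rcond=None)
        resid = yk - Xk @ beta
        dof = Xk.shape[0] - p
        rvar = (resid**2).sum(axis=0) / dof
        cov = np.linalg.inv(Xk.T @ Xk)
        return beta, rvar, dof, cov[np.ix_(task_idx, task_idx)]

    if not prewhiten and ar1 is None:
        beta, rvar, dof, cov_task = _solve(Xm_full, y)
    elif ar1 is not None:
        beta, rvar, dof, cov_task = _solve(_ar1_whiten(Xm_full, ar1), _ar1_whiten(y, ar1))
    else:
        beta0, _, _, _ = _solve(Xm_full, y)
        resid = y[keep] - Xm_full[keep] @ beta0
        num = (resid[1:] * resid[:-1]).sum(axis=0)
        den = (resid**2).sum(axis=0)
        rhos = np.clip(np.where(den > 0, num / den, 0.0), -0.98, 0.98)
        n_vox = y.shape[1]
        beta = np.empty((p, n_vox))
        rvar = np.empty(n_vox)
        cov_task = np.empty((n_vox, len(task_idx), len(task_idx)))
        for v in range(n_vox):
            b, r, dof, c = _solve(_ar1_whiten(Xm_full, rhos[v]), _ar1_whiten(y[:, [v]], rhos[v]))
            beta[:, v] = b[:, 0]
            rvar[v] = r[0]
            cov_task[v] = c

    info = getattr(data, "voxel_labels", None)
    coords = None
    grid = getattr(data, "grid_shape", None)
    if info is not None and all(c in getattr(info, "columns", []) for c in ("i", "j", "k")):
        coords = info[["i", "j", "k"]].to_numpy()
    return BetaMap(
        betas=beta[task_idx].T,
        conditions=X.task_names,
        resid_var=np.atleast_1d(rvar),
        df=dof,
        cov_task=cov_task,
        voxel_coords=coords,
        grid_shape=grid,
        voxel_info=info,
        runs=(data.design.run_index,) if getattr(data, "design", None) is not None else (),
    )


def contrast_map(
    betas: BetaMap, target_category: str, baseline_categories: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel balanced contrast value and t-statistic (thin wrapper)."""
    return betas.contrast(target_category, baseline_categories)
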