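"""Representational similarity analysis over the nine adaptation block types.

Activation RDMs are 9x9 Pearson-correlation matrices between block-type
voxel patterns over the ventral mask (similarity convention; dissimilarity
views are 1 − r for display).  Three theoretical models are fit by Spearman
correlation over the 36 lower-triangle entries: category selectivity only
(CS), repetition suppression only (RS), and their combination (CS-RS, the
generative structure under which suppression occurs within but not across
categories).  Group-average RDMs use Fisher-z averaging, and groups are
compared by Kendall τ-b with a group-label permutation envelope.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from .glm import BetaMap
from .simcortex.designs import (
    ADAPTATION_BLOCK_TYPES,
    ADAPTATION_CONDITIONS,
)

__all__ = [
    "RDM",
    "RSAFit",
    "GroupRDMComparison",
    "activation_rdm",
    "model_rdm",
    "fit_rdm_model",
    "group_average_rdm",
    "group_rdm_permutation",
]

MODEL_KINDS = ("CS", "RS", "CS_RS")
#: pinned condition-pair similarities of the RS pattern: identical conditions
#: are maximally similar, one-step pairs intermediate, same-vs-different low
_RS_VALUES = {0: 1.0, 1: 0.5, 2: 0.0}
_ATANH_CLIP = 1.0 - 1e-12


@dataclass(frozen=True)
class RDM:
    """Symmetric matrix of pairwise block-type similarities (Pearson r)."""

    values: np.ndarray
    labels: tuple[str, ...] = ADAPTATION_BLOCK_TYPES
    source: str = "activation"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("RDM shape must match its labels")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-8):
            raise ValueError("RDM diagonal must be 1")
        if not self.source.startswith("model") and (
            v.min() < -1 - 1e-9 or v.max() > 1 + 1e-9
        ):
            raise ValueError("correlations must lie in [-1, 1]")

    def lower_triangle(self) -> np.ndarray:
        """The 36 below-diagonal entries in row-major order."""
        idx = np.tril_indices(len(self.labels), k=-1)
        return np.asarray(self.values)[idx]

    def dissimilarity(self) -> np.ndarray:
        """1 − r view, for display."""
        return 1.0 - np.asarray(self.values)


@dataclass(frozen=True)
class RSAFit:
    """Spearman fit of one activation RDM to one model RDM."""

    participant_id: str
    hemisphere: str
    model_kind: str
    spearman_rho: float
    fisher_z: float


@dataclass(frozen=True)
class GroupRDMComparison:
    """Observed pairwise Kendall τ between group-average RDMs, with a
    permutation envelope of group-average RDMs under label shuffling."""

    group_names: tuple[str, ...]
    observed_tau: dict[tuple[str, str], float]
    lower_envelope: dict[str, np.ndarray]
    upper_envelope: dict[str, np.ndarray]
    within_envelope: dict[tuple[str, str], bool]
    n_iter: int
    seed: int


def activation_rdm(
    adapt_betas: BetaMap | np.ndarray, mask_rows: np.ndarray | None = None
) -> RDM:
    """Pearson-correlation RDM between block-type patterns over mask voxels."""
    if isinstance(adapt_betas, BetaMap):
        order = [adapt_betas.conditions.index(bt) for bt in ADAPTATION_BLOCK_TYPES]
        pat = adapt_betas.betas[:, order]
    else:
        pat = np.asarray(adapt_betas, dtype=float)
    if mask_rows is not None:
        pat = pat[np.asarray(mask_rows)]
    if pat.shape[0] < 3:
        raise ValueError("need at least 3 mask voxels")
    sds = pat.std(axis=0)
    flat = np.where(sds <= 0)[0]
    if flat.size:
        names = [ADAPTATION_BLOCK_TYPES[i] for i in flat]
        raise ValueError(f"zero-variance pattern for block type(s) {names}")
    r = np.corrcoef(pat.T)
    np.fill_diagonal(r, 1.0)
    return RDM(values=np.clip(r, -1.0, 1.0), source="activation")


def model_rdm(kind: str) -> RDM:
    """Theoretical similarity structure: CS, RS or CS_RS.

    CS: 1 within category, 0 across.  RS: depends only on the condition pair
    (1 / 0.5 / 0 for condition distance 0 / 1 / 2, regardless of category).
    CS_RS: the RS values within a category, 0 across categories.
    """
    if kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind: {kind!r}")
    n = len(ADAPTATION_BLOCK_TYPES)
    m = np.zeros((n, n))
    for a in range(n):
        cat_a, cond_a = ADAPTATION_BLOCK_TYPES[a].rsplit("_", 1)
        for b in range(n):
            cat_b, cond_b = ADAPTATION_BLOCK_TYPES[b].rsplit("_", 1)
            dist = abs(
                ADAPTATION_CONDITIONS.index(cond_a)
                - ADAPTATION_CONDITIONS.index(cond_b)
            )
            if kind == "CS":
                m[a, b] = 1.0 if cat_a == cat_b else 0.0
            elif kind == "RS":
                m[a, b] = _RS_VALUES[dist]
            else:
                m[a, b] = _RS_VALUES[dist] if cat_a == cat_b else 0.0
    np.fill_diagonal(m, 1.0)
    return RDM(values=m, source=f"model:{kind}")


def fit_rdm_model(
    activation: RDM, model: RDM, participant_id: str = "", hemisphere: str = ""
) -> RSAFit:
    """Spearman correlation (average-rank ties) over the lower triangles."""
    if activation.labels != model.labels:
        raise ValueError("activation and model RDMs must share labels")
    x = activation.lower_triangle()
    y = model.lower_triangle()
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        raise ValueError("constant RDM vector: Spearman correlation undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    z = float(np.arctanh(np.clip(rho, -_ATANH_CLIP, _ATANH_CLIP)))
    kind = model.source.split(":", 1)[1] if model.source.startswith("model:") else ""
    return RSAFit(
        participant_id=participant_id,
        hemisphere=hemisphere,
        model_kind=kind,
        spearman_rho=rho,
        fisher_z=z,
    )


def group_average_rdm(rdms: Sequence[RDM]) -> RDM:
    """Entrywise tanh(mean(atanh(r))) across participants."""
    if not rdms:
        raise ValueError("need at least one RDM")
    labels = rdms[0].labels
    if any(r.labels != labels for r in rdms):
        raise ValueError("RDMs must share labels")
    stack = np.stack([np.asarray(r.values) for r in rdms])
    z = np.arctanh(np.clip(stack, -_ATANH_CLIP, _ATANH_CLIP))
    avg = np.tanh(z.mean(axis=0))
    np.fill_diagonal(avg, 1.0)
    return RDM(values=avg, labels=labels, source="group_average")


def _pair_tau(a: RDM, b: RDM) -> float:
    """Kendall τ-b between two RDMs' lower triangles (tie-corrected)."""
    return float(stats.kendalltau(a.lower_triangle(), b.lower_triangle()).statistic)


def group_rdm_permutation(
    rdms: Sequence[RDM],
    groups: Sequence[str],
    n_iter: int = 5000,
    seed: int = 0,
) -> GroupRDMComparison:
    """Compare group-average RDMs under group-label shuffling.

    Returns the observed pairwise Kendall τ-b, the elementwise min/max
    envelope of permuted group-average RDMs per group, and whether each
    observed group-average matrix lies within its own permutation envelope.
    With ``n_iter=0`` only the observed statistics are computed.
    """
    groups = list(groups)
    names = tuple(dict.fromkeys(groups))
    if len(names) < 2:
        raise ValueError("need at least two groups")
    by_group = {g: [r for r, gg in zip(rdms, groups) if gg == g] for g in names}
    observed_avg = {g: group_average_rdm(by_group[g]) for g in names}
    observed_tau = {
        (a, b): _pair_tau(observed_avg[a], observed_avg[b])
        for a, b in combinations(names, 2)
    }
    lower = {g: np.full_like(np.asarray(observed_avg[g].values), np.inf) for g in names}
    upper = {g: np.full_like(np.asarray(observed_avg[g].values), -np.inf) for g in names}
    rng = np.random.default_rng(seed)
    labels = np.asarray(groups)
    for _ in range(n_iter):
        for _retry in range(100):
            perm = labels[rng.permutation(len(labels))]
            if all((perm == g).any() for g in names):
                break
        else:  # pragma: no cover - unreachable for label permutations
            raise RuntimeError("permutation emptied a group repeatedly")
        for g in names:
            avg = group_average_rdm([r for r, gg in zip(rdms, perm) if gg == g])
            v = np.asarray(avg.values)
            lower[g] = np.minimum(lower[g], v)
            upper[g] = np.maximum(upper[g], v)
    within = {}
    for a, b in observed_tau:
        if n_iter == 0:
            within[(a, b)] = True
            continue
        ok = True
        for g in (a, b):
            v = np.asarray(observed_avg[g].values)
            ok &= bool(np.all(v >= lower[g] - 1e-12) and np.all(v <= upper[g] + 1e-12))
        within[(a, b)] = ok
    return GroupRDMComparison(
        group_names=names,
        observed_tau=observed_tau,
        lower_envelope={g: lower[g] for g in names} if n_iter else {},
        upper_envelope={g: upper[g] for g in names} if n_iter else {},
        within_envelope=within,
        n_iter=n_iter,
        seed=seed,
    )
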