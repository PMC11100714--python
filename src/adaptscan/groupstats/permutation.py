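"""Participant-level permutation tests for group effects.

The group factor varies between participants, so exchangeability holds at
the participant level: a permutation reassigns whole participants to groups,
keeping every within-participant observation together.  The default scheme
shuffles the observed label vector (each permutation preserves the group
sizes); ``mode="resample"`` instead draws labels with replacement, which
breaks the size constraint and is provided as a sensitivity variant.

The test statistic is the joint Wald χ² of every fixed-effects term
involving the permuted factor, recomputed from a full mixed-model refit per
permutation.  The reported p-value is the plain proportion of permuted
statistics at or above the observed one; the add-one smoothed version
(b+1)/(m+1) is also recorded.

``demographic_matching`` checks group/covariate balance with a multinomial
logit likelihood-ratio statistic calibrated by permuting the covariate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .._seeds import derive_rng
from .design import FixedEffectsEncoder, ModelSpec
from .inference import bh_adjust
from .lmm import fit_lmem, profile_ml

__all__ = [
    "PermutationResult",
    "MatchingResult",
    "permute_group_effect",
    "pairwise_group_permutations",
    "demographic_matching",
]


@dataclass(frozen=True)
class PermutationResult:
    factor: str
    statistic: float
    df: int
    p: float
    p_smoothed: float
    n_iter: int
    n_at_or_above: int
    seed: int


@dataclass(frozen=True)
class MatchingResult:
    covariate: str
    statistic: float
    p: float
    p_smoothed: float
    n_iter: int
    seed: int


def _factor_chisq(encoder: FixedEffectsEncoder, factor: str, beta, cov) -> tuple[float, int]:
    idx = [
        j
        for term, cols in encoder.term_columns.items()
        if factor in term
        for j in cols
    ]
    b = beta[idx]
    c = cov[np.ix_(idx, idx)]
    return float(b @ np.linalg.solve(c, b)), len(idx)


def permute_group_effect(
    spec: ModelSpec,
    measures: pd.DataFrame,
    factor: str = "group",
    n_iter: int = 1000,
    seed: int = 0,
    mode: str = "shuffle",
) -> PermutationResult:
    """Participant-level permutation test of ``factor`` under ``spec``.

    Labels travel with participants; the mixed model is refit for every
    permutation and the observed joint Wald χ² for the factor is compared to
    the permuted distribution.
    """
    if factor not in spec.factors:
        raise ValueError(f"{factor!r} is not a factor of the model")
    if mode not in ("shuffle", "resample"):
        raise ValueError(f"unknown permutation mode: {mode!r}")
    # ML on both sides: the observed and permuted statistics must be computed
    # identically for the permutation distribution to be exchangeable
    obs_fit = fit_lmem(spec, measures, method="ml")
    df_obs = _rows_in_fit_order(spec, measures)
    encoder = obs_fit.encoder
    stat_obs, df_stat = _factor_chisq(encoder, factor, obs_fit.params, obs_fit.cov)

    starts, sizes = obs_fit.group_starts, obs_fit.group_sizes
    y = obs_fit.y
    part_labels = df_obs[factor].to_numpy()[starts]  # one label per participant
    rng = derive_rng(seed, "permutation", factor, spec.response)
    names = np.unique(part_labels)
    work = df_obs.copy()
    count = 0
    for _ in range(n_iter):
        if mode == "shuffle":
            perm = part_labels[rng.permutation(len(part_labels))]
        else:
            for _retry in range(1000):
                perm = rng.choice(part_labels, size=len(part_labels), replace=True)
                if np.isin(names, perm).all():
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise RuntimeError("resampling repeatedly emptied a group")
        work[factor] = np.repeat(perm, sizes)
        X = encoder.transform(work)
        _, beta, _, _, cov, _ = profile_ml(X, y, starts, sizes)
        stat_perm, _ = _factor_chisq(encoder, factor, beta, cov)
        if stat_perm >= stat_obs:
            count += 1
    return PermutationResult(
        factor=factor,
        statistic=stat_obs,
        df=df_stat,
        p=count / n_iter if n_iter else float("nan"),
        p_smoothed=(count + 1) / (n_iter + 1),
        n_iter=n_iter,
        n_at_or_above=count,
        seed=seed,
    )


def _rows_in_fit_order(spec: ModelSpec, measures: pd.DataFrame) -> pd.DataFrame:
    """Reproduce the row filtering/sorting that ``fit_lmem`` applies."""
    from .lmm import _prepare

    df, _ = _prepare(spec, measures)
    codes, _levels = pd.factorize(df[spec.random], sort=True)
    order = np.argsort(codes, kind="stable")
    return df.iloc[order].reset_index(drop=True)


def pairwise_group_permutations(
    spec: ModelSpec,
    measures: pd.DataFrame,
    factor: str = "group",
    n_iter: int = 1000,
    seed: int = 0,
    mode: str = "shuffle",
) -> pd.DataFrame:
    """Post-hoc two-group permutation tests with BH correction."""
    levels = sorted(measures[factor].dropna().unique())
    rows = []
    for a, b in combinations(levels, 2):
        sub = measures[measures[factor].isin([a, b])]
        res = permute_group_effect(
            spec, sub, factor=factor, n_iter=n_iter,
            seed=int(np.abs(hash((a, b))) % 2**16 + seed), mode=mode,
        )
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "statistic": res.statistic,
                "p_raw": res.p,
                "p_smoothed": res.p_smoothed,
            }
        )
    out = pd.DataFrame(rows)
    out["p_bh"] = bh_adjust(out["p_raw"].to_numpy())
    return out


def demographic_matching(
    records: pd.DataFrame,
    covariate: str = "age",
    group_col: str = "group",
    n_iter: int = 1000,
    seed: int = 0,
) -> MatchingResult:
    """Multinomial-logit balance check of a covariate across groups.

    The statistic is the likelihood-ratio χ² of ``group ~ covariate`` against
    the intercept-only multinomial model; its null distribution is obtained
    by permuting the covariate across participants.  Large p-values indicate
    the groups are not distinguishable by the covariate.
    """
    import statsmodels.api as sm

    df = records.dropna(subset=[covariate, group_col]).reset_index(drop=True)
    codes, names = pd.factorize(df[group_col], sort=True)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    x = pd.to_numeric(df[covariate]).to_numpy(dtype=float)
    # standardise for optimiser stability; the LR statistic is invariant
    if x.std() > 0:
        x = (x - x.mean()) / x.std()

    def lr_stat(xs: np.ndarray) -> float:
        # small cohorts can separate perfectly: the MLE diverges and the LR
        # statistic approaches its ceiling, so treat a non-finite fit as
        # maximal evidence rather than an error (symmetric under permutation)
        import warnings as _warnings

        exog = sm.add_constant(xs)
        with _warnings.catch_warnings(), np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            _warnings.simplefilter("ignore")
            try:
                fit = sm.MNLogit(codes, exog).fit(disp=0, maxiter=200)
                llr = float(fit.llr)
            except Exception:
                return float("inf")
        return llr if np.isfinite(llr) else float("inf")

    stat_obs = lr_stat(x)
    rng = derive_rng(seed, "matching", covariate)
    count = 0
    for _ in range(n_iter):
        if lr_stat(x[rng.permutation(len(x))]) >= stat_obs:
            count += 1
    return MatchingResult(
        covariate=covariate,
        statistic=stat_obs,
        p=count / n_iter if n_iter else float("nan"),
        p_smoothed=(count + 1) / (n_iter + 1),
        n_iter=n_iter,
        seed=seed,
    )
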