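"""Backward model selection over the fixed-effects term ladder.

Starting from the full factorial model, candidate terms (those not contained
in any retained higher-order term) are tested one at a time with ML
likelihood-ratio tests against the current model.  The least useful
non-significant term is removed and the search repeats; a term whose removal
is significant at ``alpha`` — or raises the AIC when ``require_aic`` is set —
is kept.  Covariates are eligible for removal only when ``drop_covariates``
is set.  The full trail of comparisons is returned for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

from .design import ModelSpec
from .lmm import LMEMFit, fit_lmem

__all__ = ["SelectionStep", "SelectionResult", "lrt", "select_model"]


@dataclass(frozen=True)
class SelectionStep:
    term: tuple[str, ...]
    chi_sq: float
    df: int
    p: float
    aic_full: float
    aic_reduced: float
    removed: bool


@dataclass(frozen=True)
class SelectionResult:
    fit: LMEMFit
    trail: tuple[SelectionStep, ...]

    def trail_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "term": ":".join(s.term),
                    "chi_sq": s.chi_sq,
                    "df": s.df,
                    "p": s.p,
                    "aic_full": s.aic_full,
                    "aic_reduced": s.aic_reduced,
                    "removed": s.removed,
                }
                for s in self.trail
            ]
        )


def lrt(full: LMEMFit, reduced: LMEMFit) -> tuple[float, int, float]:
    """ML likelihood-ratio test of nested fixed-effects models."""
    if full.method != "ml" or reduced.method != "ml":
        raise ValueError("likelihood-ratio tests require ML fits")
    df = full.X.shape[1] - reduced.X.shape[1]
    if df <= 0:
        raise ValueError("models are not nested in the expected direction")
    if full.n_obs != reduced.n_obs:
        raise ValueError("LRT requires fits on identical rows")
    chi = max(2.0 * (full.loglik - reduced.loglik), 0.0)
    return chi, df, float(stats.chi2.sf(chi, df))


def _removable(spec: ModelSpec, drop_covariates: bool) -> list[tuple[str, ...]]:
    terms = spec.expanded_terms()
    out = []
    for term in terms:
        if not drop_covariates and all(f in spec.covariates for f in term):
            continue
        # marginality: keep any term contained in a retained higher-order term
        if any(t != term and set(term) < set(t) for t in terms):
            continue
        out.append(term)
    return out


def select_model(
    spec: ModelSpec,
    measures: pd.DataFrame,
    alpha: float = 0.05,
    drop_covariates: bool = False,
    require_aic: bool = True,
) -> SelectionResult:
    """Backward LRT/AIC selection from the full model given by ``spec``."""
    current_spec = spec.with_terms(spec.expanded_terms())
    current = fit_lmem(current_spec, measures, method="ml")
    trail: list[SelectionStep] = []
    while True:
        candidates = _removable(current.spec, drop_covariates)
        if not candidates:
            break
        steps = []
        for term in candidates:
            reduced = fit_lmem(current.spec.drop_term(term), measures, method="ml")
            chi, df, p = lrt(current, reduced)
            steps.append((p, term, chi, df, reduced))
        steps.sort(key=lambda s: (-s[0], s[1]))
        p, term, chi, df, reduced = steps[0]
        removable = p >= alpha and (not require_aic or reduced.aic <= current.aic)
        trail.append(
            SelectionStep(
                term=term,
                chi_sq=chi,
                df=df,
                p=p,
                aic_full=current.aic,
                aic_reduced=reduced.aic,
                removed=removable,
            )
        )
        if not removable:
            break
        current = reduced
    # the selected structure is refit by REML for downstream estimation
    final = fit_lmem(current.spec, measures, method="reml")
    return SelectionResult(fit=final, trail=tuple(trail))
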