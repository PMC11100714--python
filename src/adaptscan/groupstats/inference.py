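"""Wald tests, BIC Bayes factors and estimated marginal means for LMEM fits.

Wald χ² tests are Type II by default (marginality-respecting: a term is
tested with its higher-order relatives orthogonalised against it in the
whitened model, so the test is unaffected by those relatives); when a term
has no higher-order relatives in the model this reduces to the joint test of
its coefficients.  Bayes factors use the BIC approximation, oriented as BF01
so that values above 3 support the model *lacking* the term.  EMMs are
computed on an equal-weight reference grid with covariates at their means,
with pairwise asymptotic-z contrasts and Benjamini-Hochberg correction
within each contrast family.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .lmm import LMEMFit

__all__ = [
    "WaldResult",
    "BayesFactorResult",
    "wald_terms",
    "bic_bayes_factor",
    "emmeans_contrasts",
    "bh_adjust",
]


@dataclass(frozen=True)
class WaldResult:
    term: tuple[str, ...]
    chi_sq: float
    df: int
    p: float


@dataclass(frozen=True)
class BayesFactorResult:
    term: tuple[str, ...]
    bf01: float


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _block_chisq(beta: np.ndarray, cov: np.ndarray, idx: list[int]) -> tuple[float, int]:
    b = beta[idx]
    c = cov[np.ix_(idx, idx)]
    chi = float(b @ np.linalg.solve(c, b))
    return max(chi, 0.0), len(idx)


def _type2_chisq(fit: LMEMFit, term: tuple[str, ...], relatives) -> tuple[float, int]:
    # whiten, reorder [others | term | residualised relatives], OLS, test term
    Xw = fit.whiten(fit.X)
    yw = fit.whiten(fit.y)
    t_idx = fit.term_indices(term)
    r_idx = [j for rel in relatives for j in fit.term_indices(rel)]
    o_idx = [j for j in range(fit.X.shape[1]) if j not in t_idx and j not in r_idx]
    Xo, Xt, Xr = Xw[:, o_idx], Xw[:, t_idx], Xw[:, r_idx]
    base = np.column_stack([Xo, Xt])
    # residualise the relatives against [others, term]
    coef, *_ = np.linalg.lstsq(base, Xr, rcond=None)
    Xr_res = Xr - base @ coef
    M = np.column_stack([base, Xr_res])
    MtM = M.T @ M
    beta = np.linalg.solve(MtM, M.T @ yw)
    cov = fit.sigma2 * np.linalg.inv(MtM)
    block = list(range(Xo.shape[1], Xo.shape[1] + Xt.shape[1]))
    return _block_chisq(beta, cov, block)


def wald_terms(fit: LMEMFit, kind: str = "II") -> list[WaldResult]:
    """Wald χ² per model term (Type II default; Type III behind ``kind``)."""
    if not fit.converged:
        raise ValueError("Wald tests require a converged fit")
    terms = fit.spec.expanded_terms()
    out = []
    for term in terms:
        idx = fit.term_indices(term)
        relatives = [t for t in terms if t != term and set(term) < set(t)]
        if kind == "III" or not relatives:
            chi, df = _block_chisq(fit.params, fit.cov, idx)
        elif kind == "II":
            chi, df = _type2_chisq(fit, term, relatives)
        else:
            raise ValueError(f"unknown Wald test kind: {kind!r}")
        if not np.isfinite(chi):
            raise np.linalg.LinAlgError(f"singular covariance for term {term}")
        out.append(WaldResult(term=term, chi_sq=chi, df=df, p=float(stats.chi2.sf(chi, df))))
    return out


def wald_for_term(fit: LMEMFit, term: tuple[str, ...], kind: str = "II") -> WaldResult:
    for res in wald_terms(fit, kind):
        if res.term == term:
            return res
    raise ValueError(f"term {term} not in model")


def bic_bayes_factor(fit_with: LMEMFit, fit_without: LMEMFit, term=None) -> BayesFactorResult:
    """BF01 = exp((BIC_with − BIC_without)/2): evidence for the simpler model.

    Both fits must be ML fits on identical observations.
    """
    if fit_with.method != "ml" or fit_without.method != "ml":
        raise ValueError("BIC Bayes factors require ML fits")
    if fit_with.n_obs != fit_without.n_obs:
        raise ValueError("Bayes factor requires fits on identical rows")
    bf01 = float(np.exp((fit_with.bic - fit_without.bic) / 2.0))
    if term is None:
        with_terms = set(fit_with.spec.expanded_terms())
        without_terms = set(fit_without.spec.expanded_terms())
        diff = tuple(sorted(with_terms - without_terms))
        term = diff[0] if len(diff) == 1 else tuple(diff)
    return BayesFactorResult(term=term, bf01=bf01)


def emmeans_contrasts(
    fit: LMEMFit, factors: Sequence[str], alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """EMMs for the cells of ``factors`` plus BH-corrected pairwise contrasts.

    Cells are averaged over the equal-weight reference grid of the remaining
    factors with covariates at their means.  Cells with no observed data are
    flagged and their contrasts dropped.
    """
    for f in factors:
        if f not in fit.encoder.levels:
            raise ValueError(f"factor {f!r} not in the fitted model")
    grid = fit.encoder.grid()
    rows = np.stack([fit.encoder.row_for(dict(r)) for _, r in grid.iterrows()])
    cells = (
        grid[list(factors)].drop_duplicates().reset_index(drop=True)
        if factors
        else pd.DataFrame([{}])
    )
    L = np.zeros((len(cells), fit.X.shape[1]))
    observed = []
    data_cells = _observed_cells(fit, factors)
    for i, (_, cell) in enumerate(cells.iterrows()):
        match = np.ones(len(grid), dtype=bool)
        for f in factors:
            match &= grid[f].to_numpy() == cell[f]
        L[i] = rows[match].mean(axis=0)
        observed.append(tuple(cell[f] for f in factors) in data_cells)
    emm = L @ fit.params
    var = np.einsum("ij,jk,ik->i", L, fit.cov, L)
    se = np.sqrt(np.maximum(var, 0.0))
    zc = stats.norm.ppf(1.0 - alpha / 2.0)
    cells_out = cells.copy()
    cells_out["emm"] = emm
    cells_out["se"] = se
    cells_out["ci_lo"] = emm - zc * se
    cells_out["ci_hi"] = emm + zc * se
    cells_out["observed"] = observed

    pairs = []
    for a, b in combinations(range(len(cells)), 2):
        if not (observed[a] and observed[b]):
            continue
        d = L[a] - L[b]
        sed = float(np.sqrt(max(d @ fit.cov @ d, 0.0)))
        z = (emm[a] - emm[b]) / sed if sed > 0 else 0.0
        pairs.append(
            {
                "cell_a": " ".join(str(cells.iloc[a][f]) for f in factors),
                "cell_b": " ".join(str(cells.iloc[b][f]) for f in factors),
                "estimate": emm[a] - emm[b],
                "se": sed,
                "z": z,
                "p_raw": float(2.0 * stats.norm.sf(abs(z))) if sed > 0 else 1.0,
            }
        )
    contrasts = pd.DataFrame(pairs)
    if not contrasts.empty:
        contrasts["p_bh"] = bh_adjust(contrasts["p_raw"].to_numpy())
    return cells_out, contrasts


def _observed_cells(fit: LMEMFit, factors: Sequence[str]) -> set:
    if not factors:
        return {()}
    # reconstruct observed factor combinations from the design columns is
    # fragile; use the encoder's levels crossed with whether any row matches
    cols = {}
    for f in factors:
        levs = fit.encoder.levels[f]
        mat = np.zeros((fit.X.shape[0], len(levs)))
        idx = fit.encoder.term_columns.get((f,))
        # level of each row: reference unless its indicator column is 1
        for j, lev in enumerate(levs[1:]):
            mat[:, j + 1] = fit.X[:, idx[j]]
        mat[:, 0] = 1.0 - mat[:, 1:].sum(axis=1)
        cols[f] = np.array(levs)[mat.argmax(axis=1)]
    seen = set()
    for i in range(fit.X.shape[0]):
        seen.add(tuple(cols[f][i] for f in factors))
    return seen
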