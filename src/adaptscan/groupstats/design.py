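"""Fixed-effects design construction for the mixed-model analyses.

Factors are treatment-coded against explicit reference levels; interaction
terms are products of the component indicator columns.  The encoder exposes
the term-to-column mapping needed for Wald tests and the cell-row builder
needed for estimated marginal means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations, product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["ModelSpec", "FixedEffectsEncoder", "DEFAULT_REFERENCES"]

DEFAULT_REFERENCES = {
    "group": "TD",
    "hemisphere": "LH",
    "category": "faces",
    "condition": "same",
    "model_kind": "CS",
}


@dataclass(frozen=True)
class ModelSpec:
    """Response, fixed factors (with interaction order), covariates and the
    random-intercept grouping of one mixed model."""

    response: str
    factors: tuple[str, ...]
    max_order: int | None = None
    covariates: tuple[str, ...] = ("age",)
    random: str = "participant_id"
    references: Mapping[str, str] = field(default_factory=dict)
    terms: tuple[tuple[str, ...], ...] | None = None  # explicit override

    def expanded_terms(self) -> tuple[tuple[str, ...], ...]:
        """All factor interaction terms up to max_order, plus covariates."""
        if self.terms is not None:
            return self.terms
        order = self.max_order or len(self.factors)
        terms: list[tuple[str, ...]] = []
        for k in range(1, min(order, len(self.factors)) + 1):
            terms.extend(combinations(self.factors, k))
        terms.extend((c,) for c in self.covariates)
        return tuple(terms)

    def with_terms(self, terms: Sequence[tuple[str, ...]]) -> "ModelSpec":
        return replace(self, terms=tuple(terms))

    def drop_term(self, term: tuple[str, ...]) -> "ModelSpec":
        return self.with_terms([t for t in self.expanded_terms() if t != term])

    def reference_for(self, factor: str) -> str | None:
        return self.references.get(factor, DEFAULT_REFERENCES.get(factor))


class FixedEffectsEncoder:
    """Treatment-coded design matrix builder tied to one dataset's levels."""

    def __init__(self, spec: ModelSpec, data: pd.DataFrame) -> None:
        self.spec = spec
        self.terms = spec.expanded_terms()
        self.levels: dict[str, list[str]] = {}
        for f in spec.factors:
            obs = [str(v) for v in pd.unique(data[f].dropna())]
            ref = spec.reference_for(f)
            if ref is not None and ref in obs:
                ordered = [ref] + sorted(v for v in obs if v != ref)
            else:
                ordered = sorted(obs)
            if len(ordered) < 2:
                raise ValueError(f"factor {f!r} needs >= 2 observed levels")
            self.levels[f] = ordered
        self.covariate_means = {
            c: float(pd.to_numeric(data[c]).mean()) for c in spec.covariates
        }
        self.names: list[str] = ["Intercept"]
        self.term_columns: dict[tuple[str, ...], list[int]] = {}
        for term in self.terms:
            cols = []
            for combo in self._term_level_combos(term):
                cols.append(len(self.names))
                self.names.append(self._column_name(term, combo))
            self.term_columns[term] = cols

    def _term_level_combos(self, term: tuple[str, ...]):
        parts = []
        for f in term:
            if f in self.levels:
                parts.append([(f, lev) for lev in self.levels[f][1:]])
            else:  # covariate
                parts.append([(f, None)])
        return list(product(*parts))

    @staticmethod
    def _column_name(term, combo) -> str:
        bits = []
        for f, lev in combo:
            bits.append(f if lev is None else f"{f}[{lev}]")
        return ":".join(bits)

    @property
    def n_columns(self) -> int:
        return len(self.names)

    def transform(self, data: pd.DataFrame) -> np.ndarray:
        n = len(data)
        cols = {("Intercept",): np.ones(n)}
        base: dict[tuple[str, str], np.ndarray] = {}
        for f, levs in self.levels.items():
            vals = data[f].astype(str).to_numpy()
            for lev in levs[1:]:
                base[(f, lev)] = (vals == lev).astype(float)
        for c in self.spec.covariates:
            base[(c, None)] = (
                pd.to_numeric(data[c]).to_numpy(dtype=float) - self.covariate_means[c]
            )
        X = np.empty((n, self.n_columns))
        X[:, 0] = 1.0
        j = 1
        for term in self.terms:
            for combo in self._term_level_combos(term):
                col = np.ones(n)
                for key in combo:
                    col = col * base[key]
                X[:, j] = col
                j += 1
        return X

    def row_for(self, cell: Mapping[str, str], covariate_values=None) -> np.ndarray:
        """Design row for one full grid cell (covariates at their means)."""
        data = {f: [cell[f]] for f in self.levels}
        for c in self.spec.covariates:
            v = (covariate_values or {}).get(c, self.covariate_means[c])
            data[c] = [v]
        return self.transform(pd.DataFrame(data))[0]

    def grid(self) -> pd.DataFrame:
        """Equal-weight reference grid over all factor-level combinations."""
        factors = list(self.levels)
        rows = [
            dict(zip(factors, combo))
            for combo in product(*(self.levels[f] for f in factors))
        ]
        return pd.DataFrame(rows)
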