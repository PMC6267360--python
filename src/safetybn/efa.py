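"""Exploratory factor analysis and item reduction.

Extraction is principal-axis factoring followed by an oblique promax
rotation (correlated safety-climate constructs are expected; an orthogonal
varimax rotation is available for comparison), via
``statsmodels.multivariate.factor``.  The item-reduction rule is two-staged:
items whose maximal absolute loading falls below a threshold (default 0.4)
are dropped first, then factors left with fewer than a minimum number of
items (default 3) are removed together with their items.  Internal
consistency of the retained item sets is quantified by Cronbach's alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .survey import ItemSpec, SurveyDataset, cronbach_alpha

logger = logging.getLogger(__name__)


@dataclass
class FactorModel:
    """Loadings, item assignment, and reliability of an EFA solution."""

    loadings: pd.DataFrame  # items x factors
    factor_names: list[str]
    assignment: dict[str, str]  # item -> factor, by max |loading|
    explained_variance_ratio: float
    alpha_overall: float | None = None
    alpha_per_factor: dict[str, float] = field(default_factory=dict)
    dropped_items: list[str] = field(default_factory=list)
    dropped_factors: list[str] = field(default_factory=list)

    def items_of(self, factor: str) -> list[str]:
        return [i for i, f in self.assignment.items() if f == factor]

    def report(self) -> dict:
        """JSON-serializable reduction report."""
        return {
            "factors": list(self.factor_names),
            "assignment": dict(self.assignment),
            "loadings": {i: {f: float(v) for f, v in row.items()}
                         for i, row in self.loadings.iterrows()},
            "explained_variance_ratio": float(self.explained_variance_ratio),
            "alpha_overall": self.alpha_overall,
            "alpha_per_factor": dict(self.alpha_per_factor),
            "dropped_items": list(self.dropped_items),
            "dropped_factors": list(self.dropped_factors),
        }


def _as_item_frame(data) -> pd.DataFrame:
    if isinstance(data, SurveyDataset):
        return data.likert
    return pd.DataFrame(data)


def kaiser_factor_count(data) -> int:
    """Number of correlation-matrix eigenvalues exceeding one."""
    X = _as_item_frame(data)
    ev = np.linalg.eigvalsh(np.corrcoef(X.to_numpy(), rowvar=False))
    return int((ev > 1.0).sum())


def extract_factors(data, n_factors: int | None = None,
                    rotation: str = "promax") -> FactorModel:
    """Principal-axis EFA with promax (or varimax / no) rotation.

    ``data`` is a SurveyDataset (its Likert matrix is used) or any
    item-per-column matrix.  With ``n_factors=None`` the Kaiser
    eigenvalue-greater-than-one rule chooses the count (and logs it).
    """
    from statsmodels.multivariate.factor import Factor as _SmFactor

    X = _as_item_frame(data)
    n, p = X.shape
    if n_factors is None:
        n_factors = kaiser_factor_count(X)
        logger.info("Kaiser eigenvalue>1 rule selected %d factors "
                    "(%d items, n=%d)", n_factors, p, n)
    if not (1 <= n_factors < p):
        raise ValueError(
            f"n_factors must be in [1, {p - 1}], got {n_factors}")
    if n < 3 * n_factors:
        raise ValueError(
            f"need at least 3x more respondents ({n}) than factors "
            f"({n_factors})")
    if rotation not in ("promax", "varimax", "none"):
        raise ValueError(f"unknown rotation {rotation!r}")
    try:
        res = _SmFactor(X.to_numpy(dtype=float), n_factor=n_factors,
                        method="pa").fit()
    except np.linalg.LinAlgError as e:
        raise ValueError(
            "singular item correlation matrix; consider pruning collinear "
            "or constant items") from e
    unrotated = np.asarray(res.loadings)
    evr = float((unrotated ** 2).sum() / p)
    if rotation != "none":
        res.rotate(rotation)
    L = np.asarray(res.loadings, dtype=float)
    # column sign convention: make each factor's dominant direction positive
    for j in range(L.shape[1]):
        if L[:, j].sum() < 0:
            L[:, j] = -L[:, j]
    factor_names = [f"F{j + 1}" for j in range(n_factors)]
    loadings = pd.DataFrame(L, index=list(X.columns), columns=factor_names)
    assignment = {item: loadings.loc[item].abs().idxmax()
                  for item in loadings.index}
    fm = FactorModel(loadings=loadings, factor_names=factor_names,
                     assignment=assignment, explained_variance_ratio=evr)
    fm.alpha_overall = cronbach_alpha(X) if p >= 2 else None
    return fm


def reduce_items(fm: FactorModel, loading_threshold: float = 0.4,
                 min_items_per_factor: int = 3) -> FactorModel:
    """Two-stage item reduction; returns a reduced model with a removal log.

    Stage 1 drops items whose maximal absolute loading is below
    ``loading_threshold``; stage 2 drops factors retaining fewer than
    ``min_items_per_factor`` items, together with those items.
    """
    L = fm.loadings
    max_abs = L.abs().max(axis=1)
    stage1_dropped = [i for i in L.index if max_abs[i] < loading_threshold]
    kept_items = [i for i in L.index if i not in stage1_dropped]

    per_factor = {f: [i for i in kept_items if fm.assignment[i] == f]
                  for f in fm.factor_names}
    stage2_factors = [f for f, its in per_factor.items()
                      if len(its) < min_items_per_factor]
    stage2_items = [i for f in stage2_factors for i in per_factor[f]]
    kept_items = [i for i in kept_items if i not in stage2_items]
    kept_factors = [f for f in fm.factor_names if f not in stage2_factors]
    if not kept_factors:
        raise ValueError("item reduction removed every factor")
    logger.info("reduction: dropped %d low-loading items, %d undersized "
                "factors (%d items); %d factors / %d items retained",
                len(stage1_dropped), len(stage2_factors), len(stage2_items),
                len(kept_factors), len(kept_items))
    reduced = replace(
        fm,
        loadings=fm.loadings.loc[kept_items, kept_factors],
        factor_names=list(kept_factors),
        assignment={i: fm.assignment[i] for i in kept_items},
        dropped_items=list(fm.dropped_items) + stage1_dropped + stage2_items,
        dropped_factors=list(fm.dropped_factors) + stage2_factors,
        alpha_per_factor={},
    )
    return reduced


def rename_factors(fm: FactorModel, items: Sequence[ItemSpec]) -> FactorModel:
    """Rename factors to construct names by plurality of item hints.

    Each retained factor takes the ``factor_hint`` shared by most of its
    assigned items; a factor whose items carry no hints keeps its generic
    name.  If two factors claim the same hint, the one with more hinted
    items wins and the other keeps its generic name.
    """
    hints = {s.item_id: s.factor_hint for s in items}
    claims: list[tuple[int, str, str]] = []
    for f in fm.factor_names:
        counts: dict[str, int] = {}
        for i in fm.items_of(f):
            h = hints.get(i)
            if h:
                counts[h] = counts.get(h, 0) + 1
        if counts:
            best = max(sorted(counts), key=lambda h: counts[h])
            claims.append((counts[best], f, best))
    mapping: dict[str, str] = {}
    taken: set[str] = set()
    for cnt, f, hint in sorted(claims, reverse=True):
        if hint not in taken:
            mapping[f] = hint
            taken.add(hint)
    new_names = [mapping.get(f, f) for f in fm.factor_names]
    return replace(
        fm,
        loadings=fm.loadings.rename(columns=mapping),
        factor_names=new_names,
        assignment={i: mapping.get(f, f) for i, f in fm.assignment.items()},
        alpha_per_factor={mapping.get(f, f): a
                          for f, a in fm.alpha_per_factor.items()},
    )


def run_reduction(data: SurveyDataset, items: Sequence[ItemSpec],
                  n_factors: int | None = None,
                  loading_threshold: float = 0.4,
                  min_items_per_factor: int = 3,
                  rotation: str = "promax"
                  ) -> tuple[FactorModel, SurveyDataset]:
    """Full item-reduction stage: reverse-code, extract, reduce, name, rate.

    Returns the reduced, construct-named factor model and the reverse-coded
    dataset ready for scoring.
    """
    from .survey import reverse_code

    coded = data if data.reverse_coded else reverse_code(data, items)
    fm = extract_factors(coded, n_factors=n_factors, rotation=rotation)
    fm = reduce_items(fm, loading_threshold, min_items_per_factor)
    fm = rename_factors(fm, items)
    fm.alpha_overall = cronbach_alpha(coded.likert[list(fm.assignment)])
    fm.alpha_per_factor = {
        f: cronbach_alpha(coded.likert[fm.items_of(f)])
        for f in fm.factor_names if len(fm.items_of(f)) >= 2
    }
    return fm, coded
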