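"""CPT estimation from discretized records, plus consistency diagnostics.

Estimation is per-node counting over complete records with an optional
Dirichlet (Laplace) smoothing pseudo-count.  The default pseudo-count of one
is not cosmetic: the outcome node conditions on seven ternary parents (2187
configurations), far more than any realistic survey can populate, so
unsmoothed maximum likelihood is undefined on most rows.  A sparsity report
of unobserved parent configurations is logged on every fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .inference import DiscreteDistribution, posterior_by_elimination
from .network import (BayesianNetwork, ConditionalProbabilityTable,
                      resolve_state, validate_network)

logger = logging.getLogger(__name__)

#: A fully discretized respondent: node name -> state label.
DiscretizedRecord = Mapping[str, str]


@dataclass(frozen=True)
class SmoothingPrior:
    """Pseudo-count added to every (parent configuration, child state) cell."""

    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")


def records_to_frame(records: Sequence[DiscretizedRecord],
                     bn: BayesianNetwork) -> pd.DataFrame:
    """Validate records against ``bn`` and return a node-per-column frame."""
    if not len(records):
        raise ValueError("no records supplied")
    df = pd.DataFrame(list(records))
    missing = [n for n in bn.nodes if n not in df.columns]
    if missing:
        raise ValueError(f"records missing nodes: {missing}")
    for node in bn.nodes:
        spec = bn.nodes[node]
        col = df[node]
        for i, v in enumerate(col):
            try:
                resolve_state(spec, v)
            except ValueError as e:
                raise ValueError(f"record {i}, node {node!r}: {e}") from e
        df[node] = [resolve_state(spec, v) for v in col]
    return df[list(bn.nodes)]


def estimate_cpts(records: Sequence[DiscretizedRecord], bn: BayesianNetwork,
                  prior: SmoothingPrior | float = SmoothingPrior(1.0)
                  ) -> BayesianNetwork:
    """Fit every CPT of ``bn`` by (smoothed) counting over ``records``.

    Each cell becomes ``(count + alpha) / (row_total + alpha * n_states)``.
    With ``alpha == 0``, rows with no observations fall back to the uniform
    distribution; all unsupported rows are reported via the module logger.
    """
    if isinstance(prior, (int, float)):
        prior = SmoothingPrior(float(prior))
    df = records_to_frame(records, bn)
    n = len(df)
    codes = {
        node: pd.Categorical(df[node], categories=bn.nodes[node].states).codes
        for node in bn.nodes
    }
    new = bn.copy()
    for node in bn.nodes:
        spec = bn.nodes[node]
        configs = bn.parent_configurations(node)
        n_rows, k = len(configs), spec.n_states
        row_idx = np.zeros(n, dtype=np.int64)
        for p in spec.parents:
            row_idx = row_idx * bn.nodes[p].n_states + codes[p]
        counts = np.zeros((n_rows, k))
        np.add.at(counts, (row_idx, codes[node]), 1.0)
        empty = np.where(counts.sum(axis=1) == 0)[0]
        if empty.size:
            logger.info(
                "sparsity: node %r has %d of %d parent configurations "
                "with zero observations (n=%d records)",
                node, empty.size, n_rows, n)
        if prior.alpha > 0:
            probs = (counts + prior.alpha) / (
                counts.sum(axis=1, keepdims=True) + prior.alpha * k)
        else:
            totals = counts.sum(axis=1, keepdims=True)
            with np.errstate(invalid="ignore"):
                probs = counts / totals
            probs[empty] = 1.0 / k
        new.cpts[node] = ConditionalProbabilityTable(node, tuple(configs), probs)
    violations = validate_network(new)
    if violations:  # pragma: no cover - defensive
        raise RuntimeError("estimated network invalid: " + "; ".join(violations))
    return new


def sparsity_report(records: Sequence[DiscretizedRecord],
                    bn: BayesianNetwork) -> dict[str, list[tuple[str, ...]]]:
    """Parent configurations of each node with zero observations."""
    df = records_to_frame(records, bn)
    out: dict[str, list[tuple[str, ...]]] = {}
    for node in bn.nodes:
        spec = bn.nodes[node]
        seen = set(map(tuple, df[list(spec.parents)].itertuples(index=False))) \
            if spec.parents else {()}
        out[node] = [c for c in bn.parent_configurations(node) if c not in seen]
    return out


def node_marginals(bn: BayesianNetwork) -> dict[str, DiscreteDistribution]:
    """No-evidence posterior of every node (each sums to one)."""
    return {node: posterior_by_elimination(bn, node, {}) for node in bn.nodes}


def solve_consistent_root_marginal(
        cpt: ConditionalProbabilityTable,
        known_parent_marginal: DiscreteDistribution,
        child_marginal: DiscreteDistribution,
        unknown_name: str = "unknown_parent",
) -> tuple[DiscreteDistribution, float]:
    """Infer the marginal of one root parent from a two-parent CPT.

    Given P(child | A, B) with independent root parents, a known marginal for
    one parent and a target marginal for the child, find the simplex point p
    for the other parent minimizing the L2 distance between the implied
    mixture ``sum_ij e_i p_j CPT(i, j, .)`` and the target child marginal.
    Returns the minimizing distribution and the residual distance.  A child
    marginal outside the convex hull of the mixture columns simply yields a
    positive residual.
    """
    axes_labels: list[tuple[str, ...]] = []
    for ax in range(2):
        labels = []
        for cfg in cpt.parent_states:
            if len(cfg) != 2:
                raise ValueError("CPT must have exactly two parents")
            if cfg[ax] not in labels:
                labels.append(cfg[ax])
        axes_labels.append(tuple(labels))
    known_states = tuple(known_parent_marginal.states)
    if axes_labels[0] == known_states:
        known_ax = 0
    elif axes_labels[1] == known_states:
        known_ax = 1
    else:
        raise ValueError("known parent's states match neither CPT parent axis")
    c1, c2 = len(axes_labels[0]), len(axes_labels[1])
    k = cpt.probabilities.shape[1]
    T = cpt.probabilities.reshape(c1, c2, k)
    e = np.asarray(known_parent_marginal.probabilities, dtype=float)
    child = np.asarray(child_marginal.probabilities, dtype=float)
    if child.shape != (k,):
        raise ValueError("child marginal length does not match CPT columns")
    # mixture matrix M: unknown-parent state j -> child distribution
    M = np.einsum("i,ijk->jk", e, T) if known_ax == 0 \
        else np.einsum("j,ijk->ik", e, T)
    m = M.shape[0]

    def objective(p: np.ndarray) -> float:
        return float(np.sum((p @ M - child) ** 2))

    res = minimize(objective, np.full(m, 1.0 / m), method="SLSQP",
                   bounds=[(0.0, 1.0)] * m,
                   constraints=[{"type": "eq",
                                 "fun": lambda p: float(p.sum() - 1.0)}],
                   options={"ftol": 1e-14, "maxiter": 500})
    p = np.clip(res.x, 0.0, 1.0)
    p = p / p.sum()
    residual = float(np.linalg.norm(p @ M - child))
    unknown_states = axes_labels[1 - known_ax]
    return DiscreteDistribution(unknown_name, unknown_states, p), residual


# ---------------------------------------------------------------------------
# Record CSV I/O: one column per node, header = node names.

def save_records(records: Sequence[DiscretizedRecord], bn: BayesianNetwork,
                 path: str | Path) -> Path:
    path = Path(path)
    records_to_frame(records, bn).to_csv(path, index=False)
    return path


def load_records(path: str | Path, bn: BayesianNetwork
                 ) -> list[dict[str, str]]:
    df = pd.read_csv(path, dtype=str)
    recs = df.to_dict(orient="records")
    records_to_frame(recs, bn)  # validates
    return recs
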