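"""Intervention-strategy evaluation and the diminishing-returns curve.

A strategy fixes one or more controllable nodes at their best states
(Good / Positive / Long / Not smoking / Not drinking) and measures how far
the posterior probability of a High number of accidents falls.  Sensitivity
is the absolute drop (baseline minus new value); the improvement percentage
is the relative drop between successive strategy sizes.  Exhaustive search
over all C(9, k) best-state subsets is the default (nine controllable nodes
is small); a greedy forward search is available and is what produces a
monotone returns curve on realistic networks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

import pandas as pd

from .inference import accident_probability
from .network import BEST_STATE, OUTCOME_NODE, BayesianNetwork

SENSITIVITY_IDENTITY_TOL = 1e-12


@dataclass(frozen=True)
class StrategyResult:
    """One evidence set and its effect on P(accidents = High)."""

    evidence: dict[str, str]
    p_high_baseline: float
    p_high_new: float

    def __post_init__(self) -> None:
        for p in (self.p_high_baseline, self.p_high_new):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")

    @property
    def sensitivity(self) -> float:
        return self.p_high_baseline - self.p_high_new

    @property
    def k(self) -> int:
        return len(self.evidence)

    @property
    def factors(self) -> tuple[str, ...]:
        return tuple(sorted(self.evidence))


@dataclass
class ReturnsCurve:
    """Best strategy per size k with stepwise improvement percentages."""

    entries: list[tuple[int, StrategyResult, float]]

    def p_high_sequence(self) -> list[float]:
        return [r.p_high_new for _, r, _ in self.entries]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, r, imp in self.entries:
            rows.append({
                "k": k,
                "factors": " + ".join(r.factors),
                "p_high": r.p_high_new,
                "p_high_pct": present_percent(r.p_high_new),
                "improvement_percent": imp,
                "improvement_pct": round_half_up(imp, 2),
            })
        return pd.DataFrame(rows)


def round_half_up(x: float, digits: int = 2) -> float:
    """Presentation rounding (half away from zero), applied only at output."""
    q = Decimal(10) ** -digits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def present_percent(p: float, digits: int = 2) -> float:
    """A probability as a percentage, presentation-rounded."""
    return round_half_up(100.0 * p, digits)


def _controllable(bn: BayesianNetwork) -> list[str]:
    return [n for n in bn.nodes if n != OUTCOME_NODE]


def _strategy_evidence(bn: BayesianNetwork,
                       factors: Iterable[str]) -> dict[str, str]:
    ev = {}
    for f in factors:
        if f == OUTCOME_NODE:
            raise ValueError(f"{OUTCOME_NODE!r} cannot be a strategy factor")
        if f not in bn.nodes:
            raise KeyError(f"unknown factor {f!r}")
        ev[f] = BEST_STATE[f]
    return ev


def joint_sensitivity(bn: BayesianNetwork, factors: Iterable[str],
                      mode: str = "condition",
                      baseline: float | None = None) -> StrategyResult:
    """Fix every named factor at its best state simultaneously."""
    factors = list(factors)
    if not factors:
        raise ValueError("empty strategy")
    ev = _strategy_evidence(bn, factors)
    if baseline is None:
        baseline = accident_probability(bn, {}, mode=mode)
    p_new = accident_probability(bn, ev, mode=mode)
    return StrategyResult(ev, baseline, p_new)


def single_factor_sensitivity(bn: BayesianNetwork, factor: str,
                              mode: str = "condition",
                              baseline: float | None = None) -> StrategyResult:
    """Sensitivity of the outcome to improving one factor to its best state."""
    return joint_sensitivity(bn, [factor], mode=mode, baseline=baseline)


def rank_single_strategies(bn: BayesianNetwork,
                           mode: str = "condition") -> list[StrategyResult]:
    """All nine single-factor strategies, by sensitivity descending.

    Ties are broken lexicographically by node name.
    """
    baseline = accident_probability(bn, {}, mode=mode)
    results = [single_factor_sensitivity(bn, f, mode=mode, baseline=baseline)
               for f in _controllable(bn)]
    return sorted(results, key=lambda r: (-r.sensitivity, r.factors))


def improvement_percentage(p_prev: float, p_curr: float) -> float:
    """Relative reduction 100 * (p_prev - p_curr) / p_prev, full precision.

    Use :func:`round_half_up` for two-decimal presentation.
    """
    if p_prev <= 0:
        raise ValueError("previous probability must be positive")
    return 100.0 * (p_prev - p_curr) / p_prev


def best_k_strategy(bn: BayesianNetwork, k: int, mode: str = "exhaustive",
                    inference_mode: str = "condition") -> StrategyResult:
    """The best-state evidence set of size k minimizing P(High).

    ``mode='exhaustive'`` searches all C(9, k) subsets (ties resolved toward
    the lexicographically smallest factor set); ``mode='greedy'`` extends the
    best (k-1)-set by the factor with the largest marginal gain.
    """
    nodes = _controllable(bn)
    if not (1 <= k <= len(nodes)):
        raise ValueError(f"k must be in [1, {len(nodes)}], got {k}")
    baseline = accident_probability(bn, {}, mode=inference_mode)
    if mode == "exhaustive":
        best: StrategyResult | None = None
        for combo in itertools.combinations(sorted(nodes), k):
            r = joint_sensitivity(bn, combo, mode=inference_mode,
                                  baseline=baseline)
            if best is None or r.p_high_new < best.p_high_new - SENSITIVITY_IDENTITY_TOL \
                    or (abs(r.p_high_new - best.p_high_new) <= SENSITIVITY_IDENTITY_TOL
                        and r.factors < best.factors):
                best = r
        return best
    if mode == "greedy":
        chosen: list[str] = []
        result: StrategyResult | None = None
        for _ in range(k):
            candidates = [
                joint_sensitivity(bn, chosen + [f], mode=inference_mode,
                                  baseline=baseline)
                for f in sorted(set(nodes) - set(chosen))
            ]
            result = min(candidates, key=lambda r: (r.p_high_new, r.factors))
            chosen = list(result.factors)
        return result
    raise ValueError(f"unknown search mode {mode!r}")


def diminishing_returns_curve(bn: BayesianNetwork, mode: str = "exhaustive",
                              inference_mode: str = "condition"
                              ) -> ReturnsCurve:
    """Best achievable P(High) under a budget of k = 0..9 factor improvements.

    Each entry carries the improvement percentage relative to the previous
    k.  Greedy mode grows a nested factor set, adding the factor with the
    largest marginal gain — but a budget is not an obligation: if every
    remaining factor would *raise* the predicted risk (which happens on
    sparse smoothed tables), the incumbent set is kept and the curve
    flattens with 0% improvement, so the greedy sequence is non-increasing
    by construction.
    """
    nodes = _controllable(bn)
    baseline = accident_probability(bn, {}, mode=inference_mode)
    entries: list[tuple[int, StrategyResult, float]] = [
        (0, StrategyResult({}, baseline, baseline), 0.0)]
    if mode == "greedy":
        chosen: list[str] = []
        for k in range(1, len(nodes) + 1):
            candidates = [
                joint_sensitivity(bn, chosen + [f], mode=inference_mode,
                                  baseline=baseline)
                for f in sorted(set(nodes) - set(chosen))
            ]
            r = min(candidates, key=lambda c: (c.p_high_new, c.factors))
            prev = entries[-1][1].p_high_new
            if r.p_high_new <= prev + SENSITIVITY_IDENTITY_TOL:
                chosen = list(r.factors)
                entries.append(
                    (k, r, max(0.0, improvement_percentage(prev, r.p_high_new))))
            else:  # no remaining factor helps; keep the incumbent set
                entries.append((k, entries[-1][1], 0.0))
    elif mode == "exhaustive":
        for k in range(1, len(nodes) + 1):
            r = best_k_strategy(bn, k, mode="exhaustive",
                                inference_mode=inference_mode)
            prev = entries[-1][1].p_high_new
            entries.append((k, r, improvement_percentage(prev, r.p_high_new)))
    else:
        raise ValueError(f"unknown search mode {mode!r}")
    return ReturnsCurve(entries)


# ---------------------------------------------------------------------------
# Report tables (full precision plus presentation-rounded columns).

def single_strategy_table(bn: BayesianNetwork,
                          mode: str = "condition") -> pd.DataFrame:
    rows = []
    for r in rank_single_strategies(bn, mode=mode):
        rows.append({
            "factor": r.factors[0],
            "p_high_baseline": r.p_high_baseline,
            "p_high_new": r.p_high_new,
            "sensitivity": r.sensitivity,
            "baseline_pct": present_percent(r.p_high_baseline),
            "new_pct": present_percent(r.p_high_new),
            "sensitivity_pct": present_percent(r.sensitivity),
        })
    return pd.DataFrame(rows)


def joint_strategy_table(bn: BayesianNetwork, k: int = 2, top: int = 3,
                         mode: str = "condition") -> pd.DataFrame:
    baseline = accident_probability(bn, {}, mode=mode)
    results = [
        joint_sensitivity(bn, combo, mode=mode, baseline=baseline)
        for combo in itertools.combinations(sorted(_controllable(bn)), k)
    ]
    results.sort(key=lambda r: (r.p_high_new, r.factors))
    rows = []
    for r in results[:top]:
        rows.append({
            "strategy": " + ".join(f"{f}={BEST_STATE[f]}" for f in r.factors),
            "p_high_baseline": r.p_high_baseline,
            "p_high_new": r.p_high_new,
            "sensitivity": r.sensitivity,
            "baseline_pct": present_percent(r.p_high_baseline),
            "new_pct": present_percent(r.p_high_new),
            "sensitivity_pct": present_percent(r.sensitivity),
        })
    return pd.DataFrame(rows)
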