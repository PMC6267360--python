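"""Synthetic survey generation with the statistical structure the pipeline assumes.

The generator emulates the study conditions of the source survey: 155
respondents, a 38-item safety-climate instrument (28 items loading on six
constructs, a 2-item and a 1-item nuisance construct, seven noise items),
three personal fields, and four accident-count questions whose High/Low
split is driven by a ground-truth Bayesian network.

Ground-truth parameters: the safety-attitude CPT and the working-experience
root marginal are the published reference values; the workmate-influences
root uses the consistency-solver estimate (0.644, 0.336, 0.020); everything
else is synthetic — a documented graded-interpolation scheme in which each
child's distribution moves linearly from a "good" profile to a "poor"
profile as a weighted badness score of its parents increases.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .network import (NODE_STATES, OUTCOME_NODE, BayesianNetwork,
                      ConditionalProbabilityTable, build_accident_network,
                      cpt_from_function, set_cpt)
from .reference import WORKING_EXPERIENCE_MARGINAL, safety_attitude_reference_cpt
from .survey import (ACCIDENT_COLUMNS, CLIMATE_FACTORS, ItemSpec,
                     SurveyDataset, default_item_specs, save_item_specs,
                     save_survey)

#: Workmate-influences root marginal (Positive, Neutral, Negative), the
#: simplex point most consistent with the published safety-attitude CPT and
#: the published experience / attitude marginals.  Synthetic (not published).
WORKMATE_MARGINAL_SYNTHETIC = (0.644, 0.336, 0.020)

#: Badness weights of the outcome node's seven parents, ordered so that the
#: intended influence ranking (attitude and procedures dominant) holds.
#: Synthetic.
ACCIDENT_WEIGHTS = {
    "safety_attitude": 0.24,
    "safety_procedures": 0.22,
    "management_commitment": 0.16,
    "understanding_of_work_risk": 0.13,
    "smoking_habit": 0.11,
    "safety_resources_equipment": 0.08,
    "drinking_habit": 0.06,
}
ACCIDENT_P_HIGH_RANGE = (0.08, 0.62)


def state_badness(node: str, state: str) -> float:
    """0 for the node's best state, 1 for its worst, 0.5 in between."""
    states = NODE_STATES[node]
    idx = states.index(state)
    if node == "working_experience":  # ordered short -> long; long is best
        idx = len(states) - 1 - idx
    return idx / (len(states) - 1)


def _graded(bn: BayesianNetwork, node: str, weights: Mapping[str, float],
            good_profile: Sequence[float], poor_profile: Sequence[float]
            ) -> ConditionalProbabilityTable:
    """CPT interpolating good->poor profiles by weighted parent badness."""
    parents = bn.nodes[node].parents
    w = np.array([weights[p] for p in parents])
    w = w / w.sum()
    good = np.asarray(good_profile, dtype=float)
    poor = np.asarray(poor_profile, dtype=float)

    def fn(config):
        b = float(w @ [state_badness(p, s) for p, s in zip(parents, config)])
        return (1 - b) * good + b * poor

    return cpt_from_function(bn, node, fn)


def default_ground_truth(
        root_marginals: Mapping[str, Sequence[float]] | None = None
) -> BayesianNetwork:
    """The generator's ground-truth network.

    ``root_marginals`` overrides the root CPTs (e.g. uniform roots for
    parameter-recovery fixtures, where every parent configuration needs
    ample sampling support).
    """
    bn = build_accident_network()
    roots = {
        "working_experience": tuple(WORKING_EXPERIENCE_MARGINAL),
        "workmate_influences": WORKMATE_MARGINAL_SYNTHETIC,
        "management_commitment": (1 / 3, 1 / 3, 1 / 3),
    }
    if root_marginals:
        roots.update({k: tuple(v) for k, v in root_marginals.items()})
    for node, marg in roots.items():
        bn = set_cpt(bn, node, ConditionalProbabilityTable(
            node, ((),), np.asarray([marg], dtype=float)))
    bn = set_cpt(bn, "safety_attitude", safety_attitude_reference_cpt(bn))
    # Moderate good->poor gradients: steep profiles would make the latent
    # factors nearly collinear, which no oblique factor analysis could
    # separate; the instrument this emulates presupposes correlated but
    # distinct constructs.
    bn = set_cpt(bn, "understanding_of_work_risk", _graded(
        bn, "understanding_of_work_risk",
        {"working_experience": 0.4, "safety_attitude": 0.6},
        (0.65, 0.25, 0.10), (0.25, 0.35, 0.40)))
    bn = set_cpt(bn, "safety_resources_equipment", _graded(
        bn, "safety_resources_equipment", {"management_commitment": 1.0},
        (0.60, 0.28, 0.12), (0.25, 0.35, 0.40)))
    bn = set_cpt(bn, "safety_procedures", _graded(
        bn, "safety_procedures",
        {"management_commitment": 0.5, "safety_resources_equipment": 0.5},
        (0.60, 0.28, 0.12), (0.22, 0.33, 0.45)))
    bn = set_cpt(bn, "smoking_habit", _graded(
        bn, "smoking_habit", {"workmate_influences": 1.0},
        (0.60, 0.30, 0.10), (0.20, 0.30, 0.50)))
    bn = set_cpt(bn, "drinking_habit", _graded(
        bn, "drinking_habit", {"workmate_influences": 1.0},
        (0.65, 0.25, 0.10), (0.25, 0.35, 0.40)))

    lo, hi = ACCIDENT_P_HIGH_RANGE
    parents = bn.nodes[OUTCOME_NODE].parents
    w = np.array([ACCIDENT_WEIGHTS[p] for p in parents])
    w = w / w.sum()

    def accidents(config):
        b = float(w @ [state_badness(p, s) for p, s in zip(parents, config)])
        p_high = lo + (hi - lo) * b
        return (p_high, 1.0 - p_high)

    bn = set_cpt(bn, OUTCOME_NODE, cpt_from_function(bn, OUTCOME_NODE, accidents))
    return bn


def uniform_root_ground_truth() -> BayesianNetwork:
    """Ground-truth variant with uniform root marginals.

    A recovery fixture: uniform roots maximize the minimum expected support
    per parent configuration, so CPT estimates from moderate samples are
    tight for every row.  Synthetic, like the default it derives from.
    """
    u = (1 / 3, 1 / 3, 1 / 3)
    return default_ground_truth(root_marginals={
        "working_experience": u, "workmate_influences": u,
        "management_commitment": u})


@dataclass
class GeneratorConfig:
    """Study conditions of the synthetic survey."""

    n_respondents: int = 155
    seed: int = 0
    ground_truth: BayesianNetwork | None = None
    item_specs: list[ItemSpec] | None = None
    loading_strength: float = 0.7  # fraction of responses driven by the state
    likert_noise: float = 0.1  # chance of a +/-1 spillover on a driven response
    accident_rate_map: dict[str, dict[int, float]] | None = None
    accident_split: tuple[float, ...] = (0.5, 0.3, 0.15, 0.05)
    experience_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"Short": (0, 5), "Medium": (6, 10),
                                 "Long": (11, 40)})

    def __post_init__(self) -> None:
        if not (0 < self.loading_strength <= 1):
            raise ValueError("loading_strength must be in (0, 1]")
        if not (0 <= self.likert_noise < 1):
            raise ValueError("likert_noise must be in [0, 1)")
        if self.n_respondents < 0:
            raise ValueError("n_respondents must be non-negative")
        if self.ground_truth is None:
            self.ground_truth = default_ground_truth()
        if self.item_specs is None:
            self.item_specs = default_item_specs()
        if self.accident_rate_map is None:
            self.accident_rate_map = {
                "Low": {0: 0.6, 1: 0.4},
                "High": {2: 0.5, 3: 0.3, 4: 0.15, 5: 0.05},
            }
        for state, dist in self.accident_rate_map.items():
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"accident_rate_map[{state!r}] does not sum to 1")
            if state == "Low" and any(t >= 2 for t in dist):
                raise ValueError("Low totals must be < 2")
            if state == "High" and any(t < 2 for t in dist):
                raise ValueError("High totals must be >= 2")


def sample_states(config: GeneratorConfig) -> list[dict[str, str]]:
    """Ancestral sampling of all ten node states for each respondent."""
    bn = config.ground_truth
    n = config.n_respondents
    rng = np.random.default_rng((int(config.seed), 0))
    codes: dict[str, np.ndarray] = {}
    for node in bn.topological_order():
        spec = bn.nodes[node]
        rows = np.zeros(n, dtype=np.int64)
        for p in spec.parents:
            rows = rows * bn.nodes[p].n_states + codes[p]
        P = bn.cpts[node].probabilities
        cum = np.cumsum(P, axis=1)
        u = rng.random(n)
        codes[node] = (u[:, None] > cum[rows]).sum(axis=1)
    return [
        {node: bn.nodes[node].states[codes[node][i]] for node in bn.nodes}
        for i in range(n)
    ]


def _signal_fraction(class_probs: np.ndarray, loading: float,
                     spill: float) -> float:
    """Signal fraction q achieving a target standardized loading.

    Items are a mixture: with probability q the response is driven by the
    latent state (class 0 -> {4, 5}, class 1 -> {3}, class 2 -> {1, 2},
    plus +/-1 spillover with probability ``spill``), otherwise uniform on
    1..5.  Two same-factor items then correlate as
    ``rho = q^2 Vb / Vmix(q)`` with loading ``sqrt(rho)``, where Vb is the
    between-class variance of the driven mean and Vmix the mixture variance.
    Solving ``loading^2 = q^2 Vb / Vmix(q)`` for q is a quadratic; the
    positive root is clipped to 1 (a loading of 1 is unattainable because of
    the within-class coin flip, so loading_strength = 1 degenerates to a
    fully driven item, which is what the zero-noise round-trip identity
    needs).  Spillover clipping at the scale ends makes this calibration
    approximate to a few hundredths.
    """
    p = np.asarray(class_probs, dtype=float)
    means = np.array([4.5, 3.0, 1.5])
    mu_s = float(p @ means)
    vb = float(p @ (means - mu_s) ** 2)
    vw = float((p[0] + p[2]) * 0.25 + 0.8 * spill)
    vs = vb + vw
    vu, dmu2 = 2.0, (mu_s - 3.0) ** 2
    lam2 = loading ** 2
    a = vb / lam2 + dmu2
    b = -(vs - vu + dmu2)
    c = -vu
    q = (-b + np.sqrt(b * b - 4 * a * c)) / (2 * a)
    return float(min(1.0, max(q, 0.0)))


def _emit_item_levels(classes: np.ndarray, q: float, config: GeneratorConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Likert levels for one item given per-respondent state classes.

    Class 0 (best state) draws from {4, 5}, class 1 from {3}, class 2 from
    {1, 2}.  A fraction 1 - q of responses ignores the state (uniform 1-5);
    driven responses spill over to an adjacent level with probability
    likert_noise.
    """
    n = classes.shape[0]
    base = np.empty(n, dtype=np.int64)
    coin = rng.integers(0, 2, size=n)
    base[classes == 0] = 4 + coin[classes == 0]
    base[classes == 1] = 3
    base[classes == 2] = 1 + coin[classes == 2]
    signal = rng.random(n) < q
    background = rng.integers(1, 6, size=n)
    level = np.where(signal, base, background)
    spill = signal & (rng.random(n) < config.likert_noise)
    delta = rng.choice((-1, 1), size=n)
    level = np.where(spill, np.clip(level + delta, 1, 5), level)
    return level


def emit_survey(records: Sequence[Mapping[str, str]],
                config: GeneratorConfig) -> SurveyDataset:
    """Render sampled states as a raw survey dataset."""
    n = len(records)
    rng = np.random.default_rng((int(config.seed), 1))
    state_class: dict[str, np.ndarray] = {}
    for node in CLIMATE_FACTORS:
        states = NODE_STATES[node]
        state_class[node] = np.array(
            [states.index(r[node]) for r in records], dtype=np.int64)
    nuisance = sorted({s.factor_hint for s in config.item_specs
                       if s.factor_hint and s.factor_hint not in CLIMATE_FACTORS})
    for hint in nuisance:
        state_class[hint] = rng.integers(0, 3, size=n)

    signal_fraction = {}
    for hint, classes in state_class.items():
        freq = np.bincount(classes, minlength=3) / max(n, 1) if n else \
            np.full(3, 1 / 3)
        signal_fraction[hint] = _signal_fraction(
            freq, config.loading_strength, config.likert_noise)

    likert = {}
    for spec in config.item_specs:
        if spec.factor_hint is None:
            level = rng.integers(1, 6, size=n)
        else:
            level = _emit_item_levels(state_class[spec.factor_hint],
                                      signal_fraction[spec.factor_hint],
                                      config, rng)
        if spec.reverse_coded:
            level = 6 - level
        likert[spec.item_id] = level
    likert_df = pd.DataFrame(likert)

    exp_years = np.empty(n, dtype=np.int64)
    for state, (lo, hi) in config.experience_ranges.items():
        mask = np.array([r["working_experience"] == state for r in records])
        exp_years[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))

    totals = np.empty(n, dtype=np.int64)
    for state, dist in config.accident_rate_map.items():
        mask = np.array([r[OUTCOME_NODE] == state for r in records])
        vals = np.array(sorted(dist))
        probs = np.array([dist[v] for v in vals])
        totals[mask] = rng.choice(vals, size=int(mask.sum()), p=probs)
    split = np.asarray(config.accident_split, dtype=float)
    counts = np.array([rng.multinomial(t, split) for t in totals]) \
        if n else np.zeros((0, 4), dtype=np.int64)

    data = SurveyDataset(
        likert=likert_df,
        experience_years=pd.Series(exp_years, dtype=float),
        smoking=pd.Series([r["smoking_habit"] for r in records], dtype=object),
        drinking=pd.Series([r["drinking_habit"] for r in records], dtype=object),
        accidents=pd.DataFrame(counts, columns=list(ACCIDENT_COLUMNS)),
    )
    data.validate()
    return data


def build_dataset(config: GeneratorConfig
                  ) -> tuple[list[dict[str, str]], SurveyDataset]:
    """Sample states and render the survey in one call (no disk I/O)."""
    records = sample_states(config)
    return records, emit_survey(records, config)


def _config_fingerprint(config: GeneratorConfig) -> str:
    from .network import network_to_dict

    doc = {
        "n_respondents": config.n_respondents,
        "seed": int(config.seed),
        "loading_strength": config.loading_strength,
        "likert_noise": config.likert_noise,
        "accident_rate_map": {k: {str(t): p for t, p in v.items()}
                              for k, v in config.accident_rate_map.items()},
        "accident_split": list(config.accident_split),
        "experience_ranges": {k: list(v)
                              for k, v in config.experience_ranges.items()},
        "items": [s.__dict__ for s in config.item_specs],
        "ground_truth": network_to_dict(config.ground_truth),
    }
    blob = json.dumps(doc, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def generate(config: GeneratorConfig, outdir: str | Path) -> dict[str, Path]:
    """Write survey CSV, item specs, ground-truth model, and a manifest."""
    from .network import save_network

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, data = build_dataset(config)
    paths = {
        "survey": save_survey(data, outdir / "survey.csv"),
        "items": save_item_specs(config.item_specs, outdir / "items.json"),
        "model": save_network(config.ground_truth, outdir / "model.json"),
    }
    manifest = {
        "seed": int(config.seed),
        "n_respondents": config.n_respondents,
        "config_hash": _config_fingerprint(config),
        "safetybn_version": __version__,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    paths["manifest"] = manifest_path
    return paths
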