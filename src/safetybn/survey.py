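"""Survey ingestion, scoring, and discretization.

Raw input is a 38-item safety-climate questionnaire on a five-point Likert
scale (1 = strongly disagree ... 5 = strongly agree), three personal fields
(years of working experience, smoking and drinking categories) and four
accident-count questions covering the past twelve months.  The pipeline
reverse-codes negatively worded items, aggregates retained items to factor
scores (unweighted means), collapses the five Likert levels to three states
(Good / Average / Poor), bins the personal fields, dichotomizes the accident
counts, and emits one fully discretized record per respondent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .network import (NODE_STATES, OUTCOME_NODE, NodeSpec, resolve_state)

ACCIDENT_COLUMNS = ("near_miss", "no_absence", "absence_le3", "absence_gt3")
PERSONAL_COLUMNS = ("experience_years", "smoking", "drinking")

CLIMATE_FACTORS = (
    "safety_attitude",
    "understanding_of_work_risk",
    "management_commitment",
    "safety_resources_equipment",
    "safety_procedures",
    "workmate_influences",
)

#: Items per climate factor in the default 38-item design: 28 strong items
#: across the six factors, one 2-item and one 1-item nuisance construct, and
#: seven free-standing noise items.
FACTOR_ITEM_COUNTS = {
    "safety_attitude": 4,
    "understanding_of_work_risk": 3,
    "management_commitment": 5,
    "safety_resources_equipment": 3,
    "safety_procedures": 9,
    "workmate_influences": 4,
}

_FACTOR_PREFIX = {
    "safety_attitude": "sa",
    "understanding_of_work_risk": "ur",
    "management_commitment": "mc",
    "safety_resources_equipment": "re",
    "safety_procedures": "sp",
    "workmate_influences": "wi",
}

#: Default reverse-coded items: negatively worded statements whose raw level
#: runs opposite to "higher = safer" (attitude items 1-3, understanding item
#: 3, procedures items 2-7, workmate item 4).  Fully configurable.
DEFAULT_REVERSE_CODED = frozenset(
    {"sa1", "sa2", "sa3", "ur3", "sp2", "sp3", "sp4", "sp5", "sp6", "sp7",
     "wi4"})


@dataclass(frozen=True)
class ItemSpec:
    """One questionnaire item: identity, construct hint, coding direction."""

    item_id: str
    factor_hint: str | None = None
    reverse_coded: bool = False
    text: str | None = None


def default_item_specs() -> list[ItemSpec]:
    """The default 38-item design (28 strong, 3 nuisance, 7 noise items)."""
    specs: list[ItemSpec] = []
    for factor, count in FACTOR_ITEM_COUNTS.items():
        prefix = _FACTOR_PREFIX[factor]
        for i in range(1, count + 1):
            iid = f"{prefix}{i}"
            specs.append(ItemSpec(iid, factor, iid in DEFAULT_REVERSE_CODED))
    specs.append(ItemSpec("nxa1", "nuisance_a"))
    specs.append(ItemSpec("nxa2", "nuisance_a"))
    specs.append(ItemSpec("nxb1", "nuisance_b"))
    for i in range(1, 8):
        specs.append(ItemSpec(f"nz{i}", None))
    assert len(specs) == 38
    return specs


def save_item_specs(specs: Sequence[ItemSpec], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps([spec.__dict__ for spec in specs], indent=1))
    return path


def load_item_specs(path: str | Path) -> list[ItemSpec]:
    doc = json.loads(Path(path).read_text())
    return [ItemSpec(**d) for d in doc]


@dataclass
class SurveyDataset:
    """Respondent-level raw survey data.

    ``likert`` holds one integer column (1-5) per item; ``accidents`` holds
    the four count questions of :data:`ACCIDENT_COLUMNS`.
    """

    likert: pd.DataFrame
    experience_years: pd.Series
    smoking: pd.Series
    drinking: pd.Series
    accidents: pd.DataFrame
    reverse_coded: bool = False

    @property
    def n_respondents(self) -> int:
        return len(self.likert)

    def validate(self) -> None:
        lik = self.likert
        if not np.issubdtype(np.asarray(lik).dtype, np.integer):
            bad = lik.apply(lambda c: c != c.astype(int))
            if bad.any().any():
                raise ValueError("non-integer Likert responses present")
        arr = lik.to_numpy()
        out = np.argwhere((arr < 1) | (arr > 5))
        if out.size:
            r, c = out[0]
            raise ValueError(
                f"Likert value {arr[r, c]} out of range 1-5 at row {r}, "
                f"column {lik.columns[c]!r}")
        if (np.asarray(self.experience_years) < 0).any():
            raise ValueError("negative experience_years")
        acc = self.accidents.to_numpy()
        neg = np.argwhere(acc < 0)
        if neg.size:
            r, c = neg[0]
            raise ValueError(f"negative accident count at row {r}, column "
                             f"{self.accidents.columns[c]!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [self.likert.reset_index(drop=True),
             pd.DataFrame({
                 "experience_years": np.asarray(self.experience_years),
                 "smoking": np.asarray(self.smoking, dtype=object),
                 "drinking": np.asarray(self.drinking, dtype=object)}),
             self.accidents.reset_index(drop=True)], axis=1)


def save_survey(data: SurveyDataset, path: str | Path) -> Path:
    path = Path(path)
    data.to_frame().to_csv(path, index=False)
    return path


def load_survey(path: str | Path,
                item_ids: Sequence[str] | None = None) -> SurveyDataset:
    """Read a survey CSV and validate its schema and value ranges."""
    df = pd.read_csv(path)
    non_item = set(PERSONAL_COLUMNS) | set(ACCIDENT_COLUMNS)
    missing = [c for c in non_item if c not in df.columns]
    if missing:
        raise ValueError(f"survey file {path} missing columns: {sorted(missing)}")
    if item_ids is None:
        item_ids = [c for c in df.columns if c not in non_item]
    else:
        absent = [c for c in item_ids if c not in df.columns]
        if absent:
            raise ValueError(f"survey file missing item columns: {absent}")
    likert = df[list(item_ids)]
    try:
        likert = likert.astype(np.int64)
    except (ValueError, TypeError) as e:
        raise ValueError(f"non-integer Likert responses: {e}") from e
    if not (df[list(item_ids)].to_numpy() == likert.to_numpy()).all():
        raise ValueError("non-integer Likert responses present")
    data = SurveyDataset(
        likert=likert,
        experience_years=df["experience_years"].astype(float),
        smoking=df["smoking"].astype(str),
        drinking=df["drinking"].astype(str),
        accidents=df[list(ACCIDENT_COLUMNS)].astype(np.int64),
    )
    data.validate()
    return data


def reverse_code(data: SurveyDataset,
                 items: Sequence[ItemSpec]) -> SurveyDataset:
    """Flip flagged items (x -> 6 - x).  Guarded against double application."""
    if data.reverse_coded:
        raise ValueError("dataset already reverse-coded")
    lik = data.likert.copy()
    for spec in items:
        if spec.reverse_coded and spec.item_id in lik.columns:
            lik[spec.item_id] = 6 - lik[spec.item_id]
    return replace(data, likert=lik, reverse_coded=True)


def cronbach_alpha(matrix) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum(item variances)/var(item sum)).

    Sample (ddof=1) variances.  Requires at least two items and two
    respondents and a non-degenerate total score.
    """
    X = np.asarray(pd.DataFrame(matrix), dtype=float)
    n, k = X.shape
    if k < 2:
        raise ValueError("Cronbach's alpha requires at least two items")
    if n < 2:
        raise ValueError("Cronbach's alpha requires at least two respondents")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total score has zero variance; alpha undefined")
    item_var = X.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def factor_scores(data: SurveyDataset, fm) -> pd.DataFrame:
    """Unweighted per-factor mean of each respondent's retained items."""
    if not data.reverse_coded:
        raise ValueError("apply reverse_code before scoring")
    cols = {}
    for factor in fm.factor_names:
        items = [i for i, f in fm.assignment.items() if f == factor]
        if not items:
            raise ValueError(f"factor {factor!r} has no retained items")
        absent = [i for i in items if i not in data.likert.columns]
        if absent:
            raise ValueError(f"retained items missing from data: {absent}")
        cols[factor] = data.likert[items].mean(axis=1)
    return pd.DataFrame(cols)


def discretize_score(score: float) -> str:
    """Collapse a mean Likert score in [1, 5] to Good / Average / Poor.

    Bands: >= 3.5 Good, [2.5, 3.5) Average, < 2.5 Poor (upper-inclusive
    boundary convention; the integer levels map 4-5 -> Good, 3 -> Average,
    1-2 -> Poor).
    """
    s = float(score)
    if not (1.0 <= s <= 5.0):
        raise ValueError(f"score {s} outside [1, 5]")
    if s >= 3.5:
        return "Good"
    if s >= 2.5:
        return "Average"
    return "Poor"


def discretize_personal(experience_years: float, smoking: str,
                        drinking: str) -> tuple[str, str, str]:
    """Bin experience years and validate habit categories.

    Experience: > 10 years Long, > 5 years Medium (closing the (5, 6) gap
    deterministically), otherwise Short.
    """
    y = float(experience_years)
    if y < 0:
        raise ValueError("experience_years must be non-negative")
    if y > 10:
        exp = "Long"
    elif y > 5:
        exp = "Medium"
    else:
        exp = "Short"
    smoke = resolve_state(NodeSpec("smoking_habit",
                                   NODE_STATES["smoking_habit"]), smoking)
    drink = resolve_state(NodeSpec("drinking_habit",
                                   NODE_STATES["drinking_habit"]), drinking)
    return exp, smoke, drink


def dichotomize_accidents(counts: Sequence[int]) -> str:
    """High iff the four accident questions total two or more events."""
    c = [int(v) for v in counts]
    if any(v < 0 for v in c):
        raise ValueError("accident counts must be non-negative")
    return "High" if sum(c) >= 2 else "Low"


def build_records(data: SurveyDataset, fm,
                  items: Sequence[ItemSpec] | None = None
                  ) -> list[dict[str, str]]:
    """Compose scoring and discretization into one record per respondent.

    ``data`` may be raw (then ``items`` must carry the reverse-coding flags)
    or already reverse-coded.
    """
    if data.n_respondents == 0:
        raise ValueError("empty survey dataset")
    if not data.reverse_coded:
        if items is None:
            raise ValueError("raw dataset: pass item specs for reverse coding")
        data = reverse_code(data, items)
    missing = [f for f in CLIMATE_FACTORS if f not in fm.factor_names]
    if missing:
        raise ValueError(f"factor model does not cover climate factors: {missing}")
    scores = factor_scores(data, fm)
    records: list[dict[str, str]] = []
    exp_years = np.asarray(data.experience_years, dtype=float)
    smoking = np.asarray(data.smoking, dtype=object)
    drinking = np.asarray(data.drinking, dtype=object)
    acc = data.accidents.to_numpy()
    for i in range(data.n_respondents):
        exp, smoke, drink = discretize_personal(exp_years[i], smoking[i],
                                                drinking[i])
        rec = {
            "working_experience": exp,
            "smoking_habit": smoke,
            "drinking_habit": drink,
            OUTCOME_NODE: dichotomize_accidents(acc[i]),
        }
        for factor in CLIMATE_FACTORS:
            band = ("Good", "Average", "Poor").index(
                discretize_score(scores[factor].iloc[i]))
            # each climate node's states are ordered best -> worst, so the
            # band indexes directly into its own labels (e.g. Positive /
            # Neutral / Negative for workmate influences)
            rec[factor] = NODE_STATES[factor][band]
        records.append(rec)
    return records
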