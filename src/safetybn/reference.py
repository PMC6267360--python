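"""Reference probabilities from the source field survey.

The underlying study surveyed 155 Hong Kong E&M repair-and-maintenance
practitioners.  Its published results include one full conditional
probability table — safety attitude given working experience and workmate
influences — and the marginal distributions of working experience and safety
attitude.  Those numbers are kept here verbatim so they can be installed as
fixtures, used as ground truth for sampling checks, and cross-checked for
internal consistency.  Every other table in this package is synthetic and
lives in :mod:`safetybn.synthetic`.
"""

from __future__ import annotations

import numpy as np

from .network import (BayesianNetwork, ConditionalProbabilityTable,
                      cpt_from_rows)

#: P(safety_attitude | working_experience, workmate_influences), as published.
#: Keys are (working_experience, workmate_influences); values are
#: (Good, Average, Poor) probabilities.  "Poor" is labeled "Bad" in some
#: renderings of the instrument; the alias table maps between the two.
SAFETY_ATTITUDE_CPT_ROWS: dict[tuple[str, str], tuple[float, float, float]] = {
    ("Short", "Positive"): (0.54, 0.32, 0.14),
    ("Short", "Neutral"): (0.45, 0.48, 0.07),
    ("Short", "Negative"): (0.34, 0.33, 0.33),
    ("Medium", "Positive"): (0.79, 0.08, 0.13),
    ("Medium", "Neutral"): (0.58, 0.33, 0.09),
    ("Medium", "Negative"): (0.50, 0.25, 0.25),
    ("Long", "Positive"): (0.69, 0.20, 0.10),  # published row sums to 0.99
    ("Long", "Neutral"): (0.61, 0.33, 0.06),
    ("Long", "Negative"): (0.40, 0.20, 0.40),
}

#: Published marginal of working experience (Short, Medium, Long).
WORKING_EXPERIENCE_MARGINAL = np.array([0.329, 0.203, 0.468])

#: Published marginal of safety attitude (Good, Average, Poor).
SAFETY_ATTITUDE_MARGINAL = np.array([0.62, 0.272, 0.108])


def safety_attitude_reference_cpt(bn: BayesianNetwork,
                                  renormalize: bool = True
                                  ) -> ConditionalProbabilityTable:
    """The published safety-attitude CPT, as a table for ``bn``.

    One published row (Long, Positive) sums to 0.99 as printed; with
    ``renormalize`` (default) it is rescaled to sum to one, otherwise the
    printed values are kept verbatim.
    """
    rows = SAFETY_ATTITUDE_CPT_ROWS
    if renormalize:
        rows = {k: tuple(np.asarray(v) / np.sum(v)) for k, v in rows.items()}
    return cpt_from_rows(bn, "safety_attitude", rows)
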