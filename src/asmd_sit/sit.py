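"""The deployed suspicion-index calculator.

The tool wraps the fitted multinomial model with its audience contract:
hepatosplenomegaly is a prerequisite — patients without simultaneous liver
and spleen enlargement are not scored at all (the tool declines rather than
emitting a probability). For gated-in patients the three remaining inputs
(thrombocytopenia with bleeding tendencies, interstitial lung disease, mixed
dyslipidemia with low HDL-C) are entered as 0/1 and the model returns the
probability of being an ASMD case, a control (phenotypically similar
lysosomal disease) or a non-case. A probability of case at or above the
cutoff (default 0.50, the median case score of the development workflow)
flags high risk.

The prerequisite stays in the fitted model as a predictor fixed at 1 during
scoring; this keeps the model fittable on full cohorts while matching the
deployment gate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cohort import Cohort
from .multinomial import (CLASS_ORDER, ModelSpec, MultinomialSymptomResults,
                          fit_multinomial)

DEFAULT_PREREQUISITE = "hepatosplenomegaly"
DEFAULT_INPUTS = (
    "thrombocytopenia_bleeding",
    "interstitial_lung_disease",
    "mixed_dyslipidemia_low_hdl",
)


@dataclass(frozen=True)
class SITModel:
    """Prerequisite-gated suspicion index over a fitted multinomial model."""

    model: MultinomialSymptomResults
    prerequisite: str = DEFAULT_PREREQUISITE
    inputs: tuple[str, ...] = DEFAULT_INPUTS
    cutoff: float = 0.50

    def __post_init__(self) -> None:
        if self.prerequisite in self.inputs:
            raise ValueError("prerequisite must not appear among the inputs")
        spec_vars = set(self.model.spec.variables)
        if spec_vars != {self.prerequisite, *self.inputs}:
            raise ValueError(
                "model variables must equal {prerequisite} | inputs; "
                f"got {sorted(spec_vars)}")
        if not 0 < self.cutoff < 1:
            raise ValueError("cutoff must be in (0,1)")


@dataclass(frozen=True)
class SITResult:
    gated: bool
    probability_case: float | None
    probability_control: float | None
    probability_non_case: float | None
    high_risk: bool | None

    def to_dict(self) -> dict:
        return {
            "gated": self.gated,
            "probability_case": self.probability_case,
            "probability_control": self.probability_control,
            "probability_non_case": self.probability_non_case,
            "high_risk": self.high_risk,
        }


def _check_binary(name: str, value) -> int:
    if value not in (0, 1, 0.0, 1.0, False, True):
        raise ValueError(f"field {name!r} must be 0 or 1, got {value!r}")
    return int(value)


def score(model: SITModel, pattern: dict) -> SITResult:
    """Score one symptom pattern.

    ``pattern`` must supply 0/1 for the prerequisite and every input. When
    the prerequisite is absent the tool declines (gated result, no
    probabilities emitted).
    """
    for name in (model.prerequisite, *model.inputs):
        if name not in pattern:
            raise KeyError(f"pattern lacks required field {name!r}")
        _check_binary(name, pattern[name])
    if int(pattern[model.prerequisite]) == 0:
        return SITResult(True, None, None, None, None)
    full = {model.prerequisite: 1}
    full.update({k: int(pattern[k]) for k in model.inputs})
    probs = model.model.predict_proba(full)
    p_case = float(probs[CLASS_ORDER.index("case")])
    return SITResult(
        gated=False,
        probability_case=p_case,
        probability_control=float(probs[CLASS_ORDER.index("control")]),
        probability_non_case=float(probs[CLASS_ORDER.index("non_case")]),
        high_risk=bool(p_case >= model.cutoff),
    )


def probability_table(model: SITModel) -> pd.DataFrame:
    """All 2^k input patterns (prerequisite fixed present) with probabilities.

    Rows are enumerated in canonical binary order of the inputs (first input
    is the least-significant bit).
    """
    k = len(model.inputs)
    rows = []
    for code in range(1 << k):
        pattern = {model.prerequisite: 1}
        for j, name in enumerate(model.inputs):
            pattern[name] = (code >> j) & 1
        res = score(model, pattern)
        row = {name: pattern[name] for name in model.inputs}
        row.update({
            "probability_case": res.probability_case,
            "probability_control": res.probability_control,
            "probability_non_case": res.probability_non_case,
            "high_risk": res.high_risk,
        })
        rows.append(row)
    return pd.DataFrame(rows)


def derive_cutoff(model: SITModel, cohort: Cohort) -> float:
    """Median case-probability over the cohort's gated-in cases.

    The development workflow assigns the high-risk cutoff as the median total
    risk prediction score of the ASMD cases that pass the prerequisite gate.
    """
    df = cohort.frame
    cases = df[(df["group"] == "case") & (df[model.prerequisite] == 1)]
    if len(cases) == 0:
        raise ValueError("no cases pass the prerequisite gate")
    variables = list(model.model.spec.variables)
    sub = cases[variables].dropna()
    if len(sub) == 0:
        raise ValueError("no gated-in case has complete tool inputs")
    probs = model.model.predict_proba(sub)
    probs = np.atleast_2d(probs)
    return float(np.median(probs[:, CLASS_ORDER.index("case")]))


def with_derived_cutoff(model: SITModel, cohort: Cohort) -> SITModel:
    return replace(model, cutoff=derive_cutoff(model, cohort))


def build_sit(cohort: Cohort,
              prerequisite: str = DEFAULT_PREREQUISITE,
              inputs: tuple[str, ...] = DEFAULT_INPUTS,
              ridge_penalty: float = 1e-2,
              derive_cutoff_from_cohort: bool = True) -> SITModel:
    """Fit the suspicion index on a cohort (prerequisite + inputs model)."""
    spec = ModelSpec(variables=(prerequisite, *inputs), ridge_penalty=ridge_penalty)
    fitted = fit_multinomial(cohort, spec)
    sit = SITModel(model=fitted, prerequisite=prerequisite, inputs=inputs)
    if derive_cutoff_from_cohort:
        sit = with_derived_cutoff(sit, cohort)
    return sit
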