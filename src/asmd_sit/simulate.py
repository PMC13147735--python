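"""Seeded synthetic-cohort generator.

Emulates the statistical structure the suspicion-index analysis assumes:
three patient groups (case / control / non_case) with specified per-group
symptom prevalences, demographics, and configurable within-patient symptom
dependence. Defaults reproduce the development cohort's published margins
(group sizes 48/52/808, the per-group symptom counts, and the per-group
age means/SDs).

Dependence model
----------------
One standard-normal latent severity factor ``z`` per patient. Symptom ``j``
in group ``g`` is Bernoulli with conditional probability
``expit(alpha_gj + dependence * z)``; for ``dependence > 0`` the intercept
``alpha_gj`` is recalibrated by Gauss-Hermite quadrature so the marginal
prevalence stays at the configured value. ``dependence = 0`` gives mutually
independent symptoms. The shared factor induces positive within-group
pairwise association between all non-degenerate symptoms, which is the
qualitative co-occurrence pattern of real chart data (e.g. isolated
hepatomegaly without splenomegaly is rare in ASMD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import truncnorm

from . import reference
from .catalog import DEFAULT_CATALOG, SymptomCatalog
from .cohort import GROUPS, Cohort

_HERM_NODES, _HERM_WEIGHTS = np.polynomial.hermite_e.hermegauss(80)
_HERM_WEIGHTS = _HERM_WEIGHTS / np.sqrt(2.0 * np.pi)  # E[f(Z)], Z ~ N(0,1)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    prevalence maps ``(group, symptom_id)`` to a probability; ``age_params``
    maps group to (onset mean, onset SD, current mean, current SD) in years.
    """

    group_sizes: dict[str, int]
    prevalence: dict[tuple[str, str], float]
    dependence: float = 0.0
    age_params: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)
    sex_male_rate: dict[str, float] = field(default_factory=dict)
    family_history_rate: dict[str, float] = field(default_factory=dict)
    case_subtype_probs: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n <= 0:
                raise ValueError(f"group size for {g!r} must be positive, got {n}")
        for (g, s), p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence[{g},{s}] = {p} outside [0,1]")
        if self.dependence < 0:
            raise ValueError("dependence must be non-negative")
        for g, (m1, s1, m2, s2) in self.age_params.items():
            if s1 < 0 or s2 < 0:
                raise ValueError(f"negative age SD for group {g!r}")
        for d in (self.sex_male_rate, self.family_history_rate):
            for g, p in d.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"rate {p} for {g!r} outside [0,1]")

    # -- YAML round-trip ---------------------------------------------------
    def to_yaml(self, path) -> None:
        doc = {
            "group_sizes": dict(self.group_sizes),
            "prevalence": {f"{g}:{s}": float(p) for (g, s), p in self.prevalence.items()},
            "dependence": float(self.dependence),
            "age_params": {g: list(map(float, v)) for g, v in self.age_params.items()},
            "sex_male_rate": {g: float(v) for g, v in self.sex_male_rate.items()},
            "family_history_rate": {g: float(v) for g, v in self.family_history_rate.items()},
            "case_subtype_probs": {k: float(v) for k, v in self.case_subtype_probs.items()},
            "seed": int(self.seed),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        prev = {}
        for key, p in doc.get("prevalence", {}).items():
            g, s = key.split(":", 1)
            prev[(g, s)] = float(p)
        return cls(
            group_sizes={g: int(n) for g, n in doc["group_sizes"].items()},
            prevalence=prev,
            dependence=float(doc.get("dependence", 0.0)),
            age_params={g: tuple(v) for g, v in doc.get("age_params", {}).items()},
            sex_male_rate=doc.get("sex_male_rate", {}),
            family_history_rate=doc.get("family_history_rate", {}),
            case_subtype_probs=doc.get("case_subtype_probs", {}),
            seed=int(doc.get("seed", 0)),
        )


def default_study_config(scale: int = 1, dependence: float = 1.0, seed: int = 0,
                         catalog: SymptomCatalog = DEFAULT_CATALOG) -> GeneratorConfig:
    """The packaged study configuration.

    Group sizes 48/52/808 (times ``scale``), symptom prevalences equal to the
    development cohort's observed count/denominator ratios, demographics from
    the published per-group means/SDs, family-history rate 10/48 for cases and
    0 elsewhere. ``dependence`` defaults to 1.0 so that the strong visceral
    co-occurrence pattern of real charts is qualitatively reproduced; pass 0
    for mutually independent symptoms.
    """
    prevalence = {}
    for sid in catalog.symptom_ids:
        counts = reference.SYMPTOM_COUNTS.get(sid)
        for gi, g in enumerate(GROUPS):
            if sid == "family_history_asmd":
                continue  # handled via family_history_rate
            p = 0.0 if counts is None else counts[gi] / reference.GROUP_SIZES[g]
            prevalence[(g, sid)] = p
    total_cases = sum(reference.CASE_SUBTYPE_COUNTS.values())
    return GeneratorConfig(
        group_sizes={g: reference.GROUP_SIZES[g] * scale for g in GROUPS},
        prevalence=prevalence,
        dependence=dependence,
        age_params=dict(reference.AGE_PARAMS),
        sex_male_rate={
            g: reference.MALE_COUNTS[g] / reference.GROUP_SIZES[g] for g in GROUPS
        },
        family_history_rate={
            g: reference.FAMILY_HISTORY_COUNTS[g] / reference.GROUP_SIZES[g]
            for g in GROUPS
        },
        case_subtype_probs={
            k: v / total_cases for k, v in reference.CASE_SUBTYPE_COUNTS.items()
        },
        seed=seed,
    )


def _recalibrated_intercept(p: float, dependence: float) -> float:
    """Intercept alpha with E[expit(alpha + dependence*Z)] = p, Z ~ N(0,1)."""
    if p <= 0.0 or p >= 1.0 or dependence == 0.0:
        return logit(min(max(p, 1e-300), 1 - 1e-16)) if 0 < p < 1 else (np.inf if p >= 1 else -np.inf)

    def marginal_minus_p(alpha: float) -> float:
        return float(_HERM_WEIGHTS @ expit(alpha + dependence * _HERM_NODES)) - p

    lo, hi = -60.0, 60.0
    return brentq(marginal_minus_p, lo, hi, xtol=1e-12, rtol=1e-14)


def _truncated_normal_ages(rng, n, onset_mu, onset_sd, cur_mu, cur_sd,
                           max_rounds: int = 200):
    """Ages from normals truncated at 0 with onset <= current enforced by
    resampling the offending pairs (clamped after max_rounds)."""
    def draw(k, mu, sd):
        if sd == 0:
            return np.full(k, mu)
        a = (0.0 - mu) / sd
        return truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=k, random_state=rng)

    onset = draw(n, onset_mu, onset_sd)
    current = draw(n, cur_mu, cur_sd)
    for _ in range(max_rounds):
        bad = onset > current
        k = int(bad.sum())
        if k == 0:
            break
        onset[bad] = draw(k, onset_mu, onset_sd)
        current[bad] = draw(k, cur_mu, cur_sd)
    else:
        bad = onset > current
        onset[bad] = current[bad]
    return onset, current


def generate(config: GeneratorConfig,
             catalog: SymptomCatalog = DEFAULT_CATALOG) -> Cohort:
    """Generate a synthetic cohort; deterministic given ``config.seed``.

    Each group draws from its own seed substream (derived from the root seed
    and a fixed per-group key), so changing one group's size does not perturb
    the other groups' draws.
    """
    config.validate()
    lam = config.dependence
    frames = []
    for gi, g in enumerate(GROUPS):
        n = config.group_sizes.get(g, 0)
        if n == 0:
            continue
        rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(gi,)))
        z = rng.standard_normal(n) if lam > 0 else None
        data: dict[str, object] = {}
        data["patient_id"] = [f"{g}-{i + 1:06d}" for i in range(n)]
        data["group"] = g
        if g == "case" and config.case_subtype_probs:
            subtypes = sorted(config.case_subtype_probs)
            probs = np.array([config.case_subtype_probs[s] for s in subtypes])
            probs = probs / probs.sum()
            data["subtype"] = rng.choice(subtypes, size=n, p=probs)
        else:
            data["subtype"] = "none"
        male_rate = config.sex_male_rate.get(g, 0.5)
        data["sex"] = np.where(rng.random(n) < male_rate, "male", "female")
        if g in config.age_params:
            m1, s1, m2, s2 = config.age_params[g]
            onset, current = _truncated_normal_ages(rng, n, m1, s1, m2, s2)
            data["age_onset_years"] = onset
            data["age_current_years"] = current
        else:
            data["age_onset_years"] = np.nan
            data["age_current_years"] = np.nan
        for sid in catalog.symptom_ids:
            if sid == "family_history_asmd" and config.family_history_rate:
                p = config.family_history_rate.get(g, 0.0)
            else:
                p = config.prevalence.get((g, sid), 0.0)
            u = rng.random(n)
            if lam > 0 and 0.0 < p < 1.0:
                alpha = _recalibrated_intercept(p, lam)
                cond = expit(alpha + lam * z)
                x = u < cond
            else:
                x = u < p
            data[sid] = pd.array(x.astype("int8"), dtype="Int8")
        frames.append(pd.DataFrame(data))
    if not frames:
        raise ValueError("all group sizes are zero")
    df = pd.concat(frames, ignore_index=True)
    return Cohort(df, catalog)


def prevalence_table(cohort: Cohort) -> pd.DataFrame:
    """Per (group, symptom) counts of ``present`` over non-unknown denominators.

    Returns a DataFrame indexed by (group, symptom_id) with columns
    ``count``, ``denominator``, ``proportion``; a zero denominator (symptom
    entirely unknown in a group) yields proportion NaN.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    df = cohort.frame
    rows = []
    for g in GROUPS:
        sub = df[df["group"] == g]
        for sid in cohort.catalog.symptom_ids:
            col = sub[sid]
            denom = int(col.notna().sum())
            count = int((col == 1).sum())
            rows.append({
                "group": g,
                "symptom_id": sid,
                "count": count,
                "denominator": denom,
                "proportion": count / denom if denom else np.nan,
            })
    return pd.DataFrame(rows).set_index(["group", "symptom_id"])
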