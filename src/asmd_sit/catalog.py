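"""Symptom catalogue for the ASMD suspicion index.

The default catalogue lists the 27 chart-review signs and symptoms observed in
more than 5% of confirmed ASMD cases, grouped by organ system (neurological,
visceral, skeletal), plus a positive family history of ASMD ("other").
Symptom identifiers are lower_snake_case slugs and are the stable join keys
used by every other module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

ORGAN_SYSTEMS = ("neurological", "visceral", "skeletal", "other")


@dataclass(frozen=True)
class SymptomEntry:
    symptom_id: str
    display_name: str
    organ_system: str

    def __post_init__(self) -> None:
        if self.organ_system not in ORGAN_SYSTEMS:
            raise ValueError(
                f"unknown organ system {self.organ_system!r} for {self.symptom_id!r}"
            )


@dataclass(frozen=True)
class SymptomCatalog:
    """Ordered collection of symptoms with unique identifiers."""

    entries: tuple[SymptomEntry, ...]
    _index: dict[str, SymptomEntry] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        seen: dict[str, SymptomEntry] = {}
        for e in self.entries:
            if e.symptom_id in seen:
                raise ValueError(f"duplicate symptom_id {e.symptom_id!r}")
            seen[e.symptom_id] = e
        object.__setattr__(self, "_index", seen)

    @property
    def symptom_ids(self) -> list[str]:
        return [e.symptom_id for e in self.entries]

    def organ_system(self, symptom_id: str) -> str:
        return self._index[symptom_id].organ_system

    def display_name(self, symptom_id: str) -> str:
        return self._index[symptom_id].display_name

    def __contains__(self, symptom_id: str) -> bool:
        return symptom_id in self._index

    def __len__(self) -> int:
        return len(self.entries)

    def with_entry(self, entry: SymptomEntry, after: str | None = None) -> "SymptomCatalog":
        """Return a new catalogue with *entry* appended (or inserted after a given id)."""
        if entry.symptom_id in self._index:
            raise ValueError(f"symptom {entry.symptom_id!r} already in catalog")
        entries = list(self.entries)
        if after is None:
            entries.append(entry)
        else:
            pos = [i for i, e in enumerate(entries) if e.symptom_id == after]
            if not pos:
                raise KeyError(after)
            entries.insert(pos[0] + 1, entry)
        return SymptomCatalog(tuple(entries))


_DEFAULT_ENTRIES = [
    # neurological
    ("learning_disability", "Learning disability", "neurological"),
    ("muscular_hypotonia", "Muscular hypotonia", "neurological"),
    ("peripheral_neuropathy", "Peripheral neuropathy", "neurological"),
    ("loss_of_deep_tendon_reflexes", "Loss of deep tendon reflexes", "neurological"),
    ("macular_halo", "Macular halo", "neurological"),
    ("loss_of_skills", "Loss of skills", "neurological"),
    ("cherry_red_spot", 'Ocular "cherry red spot"', "neurological"),
    ("ataxia", "Ataxia", "neurological"),
    ("psychiatric_symptoms", "Psychiatric symptoms", "neurological"),
    ("dysphagia", "Dysphagia", "neurological"),
    # visceral
    ("splenomegaly", "Splenomegaly", "visceral"),
    ("hepatomegaly", "Hepatomegaly", "visceral"),
    ("interstitial_lung_disease", "Interstitial lung disease", "visceral"),
    ("thrombocytopenia_bleeding", "Thrombocytopenia (with bleeding tendencies)", "visceral"),
    ("mixed_dyslipidemia_low_hdl", "Mixed dyslipidemia with low HDL-C", "visceral"),
    ("recurrent_respiratory_infections", "Recurrent respiratory tract infections", "visceral"),
    ("abnormal_liver_function_test", "Abnormal liver function test", "visceral"),
    ("diarrhea", "Diarrhea", "visceral"),
    ("cholestatic_jaundice", "Cholestatic jaundice", "visceral"),
    ("portal_hypertension", "Portal hypertension", "visceral"),
    ("aspiration_pneumonia", "Aspiration pneumonia", "visceral"),
    ("liver_fibrosis", "Liver fibrosis", "visceral"),
    ("feeding_difficulties", "Feeding difficulties", "visceral"),
    ("cardiac_valve_disease", "Cardiac valve disease", "visceral"),
    # skeletal
    ("growth_retardation", "Growth retardation in childhood", "skeletal"),
    ("reduced_bone_density", "Reduced bone density (with pathologic fractures)", "skeletal"),
    ("bone_and_joint_pain", "Bone and joint pain", "skeletal"),
    # other
    ("family_history_asmd", "Family history of ASMD", "other"),
]

DEFAULT_CATALOG = SymptomCatalog(
    tuple(SymptomEntry(sid, name, org) for sid, name, org in _DEFAULT_ENTRIES)
)
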