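"""Diagnosis keyword vocabulary: BI-RADS assessment categories, lesion morphology,
and histology terms (benign / high-risk / malignant groups).

Keywords are the head items of mined rules and the labels attached to training
images; every keyword appearing in an input must belong to this vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

BIRADS_CATEGORIES: dict[str, str] = {
    "BI-RADS 0": "Need additional imaging evaluation.",
    "BI-RADS 1": "Negative.",
    "BI-RADS 2": "Benign finding.",
    "BI-RADS 3": "Probably benign finding; short interval follow-up suggested.",
    "BI-RADS 4": "Suspicious abnormality; biopsy should be considered.",
    "BI-RADS 5": "Highly suggestive of malignancy; appropriate action should be taken.",
}

MORPHOLOGY_TERMS: tuple[str, ...] = (
    "Circum",        # circumscribed mass
    "Indist",        # indistinct mass
    "Spicul",        # spiculated mass
    "Arch Dist",     # architectural distortion
    "Asym Dens",     # asymmetric density
    "Calc Amorph",
    "Calc Pleomorph",
    "Calc Linear",
    "Calc Benign",
)

HISTOLOGY_BENIGN: tuple[str, ...] = (
    "Normal", "Benign", "Breast tissue", "Cyst", "Calcifications",
    "Ductal hyperplasia", "Fibrosis", "Fibroadenoma", "Fatty tissue",
    "Hematoma", "Hamartoma", "Lymphangioma", "Lymphatic node", "Mastitis",
    "Mastopathia", "Papilloma", "Sclerosing adenosis", "Scar",
)

HISTOLOGY_HIGH_RISK: tuple[str, ...] = (
    "Atypical ductal hyperplasia", "LCIS", "Phyllodes tumor", "Radial scar",
)

HISTOLOGY_MALIGNANT: tuple[str, ...] = (
    "Malignant", "DCIS", "IDC", "ILC", "Invasive tubular cancer", "Mucinous cancer",
)


@dataclass(frozen=True)
class KeywordVocabulary:
    """The closed set of diagnosis keywords accepted by the pipeline."""

    birads: dict[str, str] = field(default_factory=lambda: dict(BIRADS_CATEGORIES))
    morphology: tuple[str, ...] = MORPHOLOGY_TERMS
    histology_benign: tuple[str, ...] = HISTOLOGY_BENIGN
    histology_high_risk: tuple[str, ...] = HISTOLOGY_HIGH_RISK
    histology_malignant: tuple[str, ...] = HISTOLOGY_MALIGNANT

    def terms(self) -> frozenset[str]:
        return frozenset(self.birads) | frozenset(
            self.morphology + self.histology_benign
            + self.histology_high_risk + self.histology_malignant
        )

    def __contains__(self, keyword: str) -> bool:
        return keyword in self.terms()

    def validate(self, keywords) -> None:
        unknown = set(keywords) - self.terms()
        if unknown:
            raise ValueError(f"unknown diagnosis keywords: {sorted(unknown)}")


DEFAULT_VOCABULARY = KeywordVocabulary()
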