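"""Radiation-protection quantities: equivalent and effective dose.

Equivalent dose [mSv] = absorbed dose [mGy] x radiation weighting factor
(1.0 for photons). The effective dose aggregates tissue equivalent doses
with the ICRP Publication 103 tissue weighting factors; the 13 remainder
tissues share w_T = 0.12 via the arithmetic-mean rule. Because the
synthetic head phantom supplies only head/neck organs, the module reports
explicit weight-coverage bookkeeping and labels the result a *partial*
effective dose whenever the covered weight is below ~1. The eye lens has
no tissue weighting factor and never enters the effective dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TissueWeightTable",
    "EffectiveDoseResult",
    "icrp103_weights",
    "equivalent_dose",
    "effective_dose",
    "PHANTOM_TISSUE_MAP",
]

# ICRP Publication 103, Table 3 tissue weighting factors.
_ICRP103_NAMED = {
    "red_bone_marrow": 0.12,
    "colon": 0.12,
    "lung": 0.12,
    "stomach": 0.12,
    "breast": 0.12,
    "gonads": 0.08,
    "bladder": 0.04,
    "oesophagus": 0.04,
    "liver": 0.04,
    "thyroid": 0.04,
    "bone_surface": 0.01,
    "brain": 0.01,
    "salivary_glands": 0.01,
    "skin": 0.01,
}
_ICRP103_REMAINDER_WT = 0.12
_ICRP103_REMAINDER = (
    "adrenals", "extrathoracic_region", "gall_bladder", "heart", "kidneys",
    "lymphatic_nodes", "muscle", "oral_mucosa", "pancreas",
    "prostate_or_uterus", "small_intestine", "spleen", "thymus",
)

# Mapping from phantom organ labels to ICRP tissue names (lens and eyeball
# carry no tissue weighting factor).
PHANTOM_TISSUE_MAP = {
    "brain": "brain",
    "salivary_glands": "salivary_glands",
    "skin": "skin",
    "thyroid": "thyroid",
    "oral_mucosa": "oral_mucosa",
}


@dataclass
class TissueWeightTable:
    """ICRP-103 tissue weighting factors with the remainder rule."""

    named: dict  # tissue -> w_T
    remainder_weight: float
    remainder_tissues: tuple
    version: str = "ICRP-103"

    def __post_init__(self):
        total = sum(self.named.values()) + self.remainder_weight
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"tissue weights sum to {total}, must be 1.0")

    def all_tissues(self):
        return tuple(self.named) + self.remainder_tissues


def icrp103_weights() -> TissueWeightTable:
    return TissueWeightTable(dict(_ICRP103_NAMED), _ICRP103_REMAINDER_WT,
                             _ICRP103_REMAINDER)


def equivalent_dose(absorbed_mGy: float, w_R: float = 1.0) -> float:
    """Equivalent dose [mSv] = absorbed dose [mGy] x w_R (1.0 for photons)."""
    if np.any(np.asarray(absorbed_mGy) < 0):
        raise ValueError("absorbed dose must be >= 0")
    return absorbed_mGy * w_R


@dataclass
class EffectiveDoseResult:
    """Effective dose with explicit coverage of the weight table."""

    equivalent_doses_mSv: dict
    E_eff_mSv: float
    covered_weight: float
    missing_tissues: list
    partial: bool = field(init=False)
    label: str = field(init=False)

    def __post_init__(self):
        self.partial = self.covered_weight < 0.999
        self.label = ("partial effective dose" if self.partial
                      else "effective dose")


def effective_dose(equivalent_doses: dict,
                   weights: TissueWeightTable | None = None
                   ) -> EffectiveDoseResult:
    """E = sum_T w_T H_T over supplied tissues.

    The remainder contribution is the remainder weight times the arithmetic
    mean of the supplied remainder-tissue doses. Tissues absent from the
    input contribute zero and are listed as missing; the covered weight
    counts named weights of supplied tissues plus the remainder weight
    scaled by the supplied fraction of remainder tissues.
    """
    if weights is None:
        weights = icrp103_weights()
    if not equivalent_doses:
        raise ValueError("at least one tissue dose required")
    for t in equivalent_doses:
        if t not in weights.named and t not in weights.remainder_tissues:
            raise KeyError(f"tissue {t!r} not in the weight table")
    e = 0.0
    covered = 0.0
    for t, w in weights.named.items():
        if t in equivalent_doses:
            e += w * float(equivalent_doses[t])
            covered += w
    rem_supplied = [t for t in weights.remainder_tissues
                    if t in equivalent_doses]
    if rem_supplied:
        rem_mean = float(np.mean([equivalent_doses[t] for t in rem_supplied]))
        e += weights.remainder_weight * rem_mean
        covered += weights.remainder_weight * \
            len(rem_supplied) / len(weights.remainder_tissues)
    missing = [t for t in weights.all_tissues() if t not in equivalent_doses]
    return EffectiveDoseResult(
        equivalent_doses_mSv=dict(equivalent_doses),
        E_eff_mSv=e, covered_weight=covered, missing_tissues=missing)
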