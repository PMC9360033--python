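"""Risk stratification: the ELN2017 reference and the class-based 3-tier score.

The proposed score maps each of the 16 molecular classes onto one of three
strata (Favorable^P, Intermediate^P, Adverse^P) and then applies two
FLT3-ITD shift rules, each moving exactly one tier downward:

* NPM1 class (Favorable^P) with FLT3-ITD → Intermediate^P;
* any class whose base stratum is Intermediate^P with FLT3-ITD → Adverse^P.

The shifts are independent of the ITD allelic ratio.  The ELN2017 reference
implementation does consult the ratio (high = ratio ≥ 0.5; an ITD with a
missing ratio is treated as high).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .classify import AmlClass, ClassAssignment, derived_karyotype_features
from .cohort import LesionProfile


class Eln2017(str, enum.Enum):
    FAVORABLE = "favorable"
    INTERMEDIATE = "intermediate"
    ADVERSE = "adverse"


class ProposedRisk(str, enum.Enum):
    FAVORABLE = "favorable_p"
    INTERMEDIATE = "intermediate_p"
    ADVERSE = "adverse_p"


class Shift(str, enum.Enum):
    NONE = "none"
    NPM1_ITD_DOWN = "npm1_itd_down"
    ITD_DOWN = "itd_down"


@dataclass(frozen=True)
class RiskAssignment:
    patient_id: str
    eln2017: Eln2017
    proposed: ProposedRisk
    shift_applied: Shift


#: Base stratum for each class, before any FLT3-ITD shift.
DEFAULT_BASE_STRATA: Mapping[AmlClass, ProposedRisk] = {
    AmlClass.APL_t15_17: ProposedRisk.FAVORABLE,
    AmlClass.inv16: ProposedRisk.FAVORABLE,
    AmlClass.t8_21: ProposedRisk.FAVORABLE,
    AmlClass.biCEBPA: ProposedRisk.FAVORABLE,
    AmlClass.NPM1: ProposedRisk.FAVORABLE,
    AmlClass.no_events: ProposedRisk.FAVORABLE,
    AmlClass.sAML1: ProposedRisk.INTERMEDIATE,
    AmlClass.trisomies: ProposedRisk.INTERMEDIATE,
    AmlClass.WT1: ProposedRisk.INTERMEDIATE,
    AmlClass.DNMT3A_IDH: ProposedRisk.INTERMEDIATE,
    AmlClass.t6_9: ProposedRisk.INTERMEDIATE,
    AmlClass.mNOS: ProposedRisk.INTERMEDIATE,
    AmlClass.KMT2A_t11x: ProposedRisk.INTERMEDIATE,
    AmlClass.sAML2: ProposedRisk.ADVERSE,
    AmlClass.TP53_complex: ProposedRisk.ADVERSE,
    AmlClass.inv3: ProposedRisk.ADVERSE,
}

_ELN_ADVERSE_LESIONS = {"t(6;9)", "t(11;x)", "inv(3)", "-7", "del(5q)", "del(17p)", "-17"}
_ELN_FAVORABLE_FUSIONS = {"t(8;21)", "inv(16)"}


def _itd_high(profile: LesionProfile) -> bool:
    if not profile.flt3_itd:
        return False
    # missing ratio with an ITD present is treated as high (conservative)
    return profile.flt3_itd_ratio is None or profile.flt3_itd_ratio >= 0.5


def eln2017_stratify(profile: LesionProfile) -> Eln2017:
    """ELN2017 genetic risk (three tiers), the reference standard.

    Adverse cytogenetics (t(6;9), non-t(9;11) KMT2A fusions, inv(3),
    -5/del(5q), -7, -17/abn(17p), complex or monosomal karyotype), TP53,
    and RUNX1/ASXL1 outside favorable subtypes are adverse; CBF fusions,
    NPM1 without high-ratio FLT3-ITD and biallelic CEBPA are favorable;
    everything else intermediate.  t(15;17) (APL, formally outside the
    ELN2017 table) is reported favorable.  The single t(11;x) token cannot
    isolate t(9;11) and is treated as adverse.
    """
    codes = profile.lesion_codes()
    genes = profile.genes()
    if "t(15;17)" in codes:
        return Eln2017.FAVORABLE
    if codes & _ELN_FAVORABLE_FUSIONS:
        return Eln2017.FAVORABLE
    feats = derived_karyotype_features(profile)
    if codes & _ELN_ADVERSE_LESIONS or feats.is_complex or feats.is_monosomal:
        return Eln2017.ADVERSE
    if "TP53" in genes:
        return Eln2017.ADVERSE
    if profile.npm1:
        return Eln2017.INTERMEDIATE if _itd_high(profile) else Eln2017.FAVORABLE
    n_cebpa = sum(
        1 for m in profile.mutations if m.gene == "CEBPA" and m.oncogenic
    )
    if n_cebpa >= 2:
        return Eln2017.FAVORABLE
    if genes & {"RUNX1", "ASXL1"}:
        return Eln2017.ADVERSE
    return Eln2017.INTERMEDIATE


def proposed_stratify(
    assignment: ClassAssignment,
    profile: LesionProfile,
    base_strata: Mapping[AmlClass, ProposedRisk] | None = None,
) -> RiskAssignment:
    """Class-based 3-tier score with the FLT3-ITD shift rules.

    Pure function of (class, ITD status); the ITD allelic ratio never
    changes the result.
    """
    strata = base_strata or DEFAULT_BASE_STRATA
    base = strata[assignment.aml_class]
    proposed, shift = base, Shift.NONE
    if profile.flt3_itd:
        if assignment.aml_class is AmlClass.NPM1 and base is ProposedRisk.FAVORABLE:
            proposed, shift = ProposedRisk.INTERMEDIATE, Shift.NPM1_ITD_DOWN
        elif base is ProposedRisk.INTERMEDIATE:
            proposed, shift = ProposedRisk.ADVERSE, Shift.ITD_DOWN
    return RiskAssignment(
        patient_id=assignment.patient_id,
        eln2017=eln2017_stratify(profile),
        proposed=proposed,
        shift_applied=shift,
    )


def restratification_table(
    eln: Sequence[Eln2017], proposed: Sequence[ProposedRisk]
) -> tuple[pd.DataFrame, float]:
    """3x3 cross-tabulation of ELN2017 vs proposed strata and the fraction
    of patients whose tier changed (off-diagonal share)."""
    if len(eln) != len(proposed):
        raise ValueError(
            f"stratum vectors differ in length: {len(eln)} vs {len(proposed)}"
        )
    eln_order = [e.value for e in Eln2017]
    prop_order = [p.value for p in ProposedRisk]
    tab = pd.crosstab(
        pd.Categorical([e.value for e in eln], categories=eln_order),
        pd.Categorical([p.value for p in proposed], categories=prop_order),
        dropna=False,
    )
    tab = tab.reindex(index=eln_order, columns=prop_order, fill_value=0)
    n = len(eln)
    diagonal = sum(tab.iloc[i, i] for i in range(3))
    fraction = (n - diagonal) / n if n else 0.0
    return tab, fraction


def stratify_cohort(
    assignments: Sequence[ClassAssignment],
    profiles: Sequence[LesionProfile],
    base_strata: Mapping[AmlClass, ProposedRisk] | None = None,
) -> pd.DataFrame:
    """Per-patient ELN2017 + proposed risk for matched assignment/profile
    sequences."""
    if len(assignments) != len(profiles):
        raise ValueError("assignments and profiles must align")
    rows = []
    for a, p in zip(assignments, profiles):
        if a.patient_id != p.patient_id:
            raise ValueError(
                f"patient order mismatch: {a.patient_id} vs {p.patient_id}"
            )
        r = proposed_stratify(a, p, base_strata)
        rows.append({
            "patient_id": r.patient_id,
            "eln2017": r.eln2017.value,
            "proposed": r.proposed.value,
            "shift_applied": r.shift_applied.value,
        })
    return pd.DataFrame(
        rows, columns=["patient_id", "eln2017", "proposed", "shift_applied"]
    )
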