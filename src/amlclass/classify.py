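"""Deterministic hierarchical assignment to one of 16 molecular classes.

Every patient is assigned to exactly one class by walking an ordered rule
list and returning the first rule whose predicate holds.  The final two
rules — mNOS ("molecularly not otherwise specified": at least one driver
left but no class rule fired) and no_events (nothing detected) — make the
hierarchy total.  FLT3-ITD is never class defining: it is risk modifying
only, and toggling it can never change the assigned class.
"""

from __future__ import annotations

import enum
import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, NamedTuple, Sequence

import pandas as pd
import yaml

from .cohort import Consequence, GenePanel, LesionProfile, MutationCall, load_panel
from .vocab import (
    AUTOSOMAL_MONOSOMIES,
    LesionCategory,
    LesionCode,
    TP53_LOCUS_LOSS,
)

MLL_PTD_FEATURE = "MLL-PTD"


class AmlClass(str, enum.Enum):
    APL_t15_17 = "APL_t15_17"
    inv16 = "inv16"
    t8_21 = "t8_21"
    KMT2A_t11x = "KMT2A_t11x"
    t6_9 = "t6_9"
    inv3 = "inv3"
    TP53_complex = "TP53_complex"
    trisomies = "trisomies"
    sAML2 = "sAML2"
    biCEBPA = "biCEBPA"
    NPM1 = "NPM1"
    sAML1 = "sAML1"
    DNMT3A_IDH = "DNMT3A_IDH"
    WT1 = "WT1"
    mNOS = "mNOS"
    no_events = "no_events"


@dataclass(frozen=True)
class ClassAssignment:
    patient_id: str
    aml_class: AmlClass
    rule_rank: int  # 1-based position of the rule that fired
    evidence: frozenset[str]  # lesion codes / gene symbols satisfying the rule


class KaryotypeFeatures(NamedTuple):
    n_unbalanced: int
    n_trisomies: int
    has_deletion: bool
    is_complex: bool
    is_monosomal: bool


def derived_karyotype_features(profile: LesionProfile) -> KaryotypeFeatures:
    """Summarise a coded karyotype.

    - ``n_unbalanced``: count of unbalanced lesions (what the complex-
      karyotype rule counts).
    - ``n_trisomies``: count of whole-chromosome gains.
    - ``has_deletion``: any segmental deletion or whole-chromosome loss.
    - ``is_complex``: ≥3 unbalanced abnormalities, excluding pure-gain
      karyotypes (≥3 trisomies with nothing else belong to the trisomy
      class, not complex).
    - ``is_monosomal``: ≥2 autosomal monosomies, or one autosomal monosomy
      plus ≥1 structural abnormality (deletion or other unbalanced
      structural change).
    """
    lesions = profile.cytogenetics
    unbalanced = [l for l in lesions if l.unbalanced]
    n_unbalanced = len(unbalanced)
    n_trisomies = sum(1 for l in lesions if l.category is LesionCategory.GAIN)
    has_deletion = any(
        l.category in (LesionCategory.DELETION, LesionCategory.LOSS)
        for l in lesions
    )
    pure_gain = n_unbalanced > 0 and all(
        l.category is LesionCategory.GAIN for l in unbalanced
    )
    is_complex = n_unbalanced >= 3 and not pure_gain
    n_auto_monosomies = sum(1 for l in lesions if l.code in AUTOSOMAL_MONOSOMIES)
    n_structural = sum(
        1
        for l in lesions
        if l.category is LesionCategory.DELETION
        or (l.category is LesionCategory.OTHER and l.unbalanced)
    )
    is_monosomal = n_auto_monosomies >= 2 or (
        n_auto_monosomies == 1 and n_structural >= 1
    )
    return KaryotypeFeatures(
        n_unbalanced, n_trisomies, has_deletion, is_complex, is_monosomal
    )


class Tp53State(str, enum.Enum):
    WILD_TYPE = "wild_type"
    MONO_ALLELIC = "mono_allelic"
    MULTI_HIT = "multi_hit"


def tp53_allelic_state(
    mutations: Iterable[MutationCall],
    cytogenetics: Iterable[LesionCode] = (),
) -> Tp53State:
    """Annotate the TP53 allelic state.

    Multi-hit requires one of: ≥2 TP53 mutations; ≥1 TP53 mutation with a
    concomitant 17p/chromosome-17 deletion; or ≥1 TP53 mutation at
    VAF > 65% (loss of heterozygosity).  Exactly one mutation with no
    other criterion is mono-allelic; otherwise wild type.
    """
    tp53 = [m for m in mutations if m.gene == "TP53"]
    if not tp53:
        return Tp53State.WILD_TYPE
    locus_loss = any(l.code in TP53_LOCUS_LOSS for l in cytogenetics)
    high_vaf = any(m.vaf is not None and m.vaf > 0.65 for m in tp53)
    if len(tp53) >= 2 or locus_loss or high_vaf:
        return Tp53State.MULTI_HIT
    return Tp53State.MONO_ALLELIC


# ---------------------------------------------------------------------------
# hierarchy rules

def _saml_features(profile: LesionProfile, panel: GenePanel) -> frozenset[str]:
    """sAML class-defining features present: the flagged gene symbols with
    an oncogenic call, plus MLL-PTD when an MLL ptd call is present."""
    present: set[str] = set()
    for m in profile.mutations:
        if not m.oncogenic:
            continue
        if m.gene == "MLL":
            if (
                m.consequence is Consequence.PTD
                and MLL_PTD_FEATURE in panel.saml_class_defining
            ):
                present.add(MLL_PTD_FEATURE)
        elif m.gene in panel.saml_class_defining:
            present.add(m.gene)
    return frozenset(present)


def _oncogenic_genes(profile: LesionProfile) -> frozenset[str]:
    return frozenset(m.gene for m in profile.mutations if m.oncogenic)


def _has_gene(profile: LesionProfile, gene: str) -> bool:
    return any(m.gene == gene and m.oncogenic for m in profile.mutations)


def _fusion_rule(code: str) -> Callable:
    def rule(profile: LesionProfile, panel: GenePanel) -> frozenset[str] | None:
        if profile.has_lesion(code):
            return frozenset({code})
        return None

    return rule


def _tp53_complex_rule(profile: LesionProfile, panel: GenePanel):
    evidence: set[str] = set()
    if _has_gene(profile, "TP53"):
        evidence.add("TP53")
    feats = derived_karyotype_features(profile)
    if feats.is_complex:
        evidence.update(l.code for l in profile.cytogenetics if l.unbalanced)
    return frozenset(evidence) or None


def _trisomy_rule(profile: LesionProfile, panel: GenePanel):
    feats = derived_karyotype_features(profile)
    if feats.n_trisomies >= 1 and not feats.has_deletion:
        return frozenset(
            l.code
            for l in profile.cytogenetics
            if l.category is LesionCategory.GAIN
        )
    return None


def _saml2_rule(profile: LesionProfile, panel: GenePanel):
    feats = _saml_features(profile, panel)
    return feats if len(feats) >= 2 else None


def _saml1_rule(profile: LesionProfile, panel: GenePanel):
    feats = _saml_features(profile, panel)
    return feats if len(feats) >= 1 else None


def _bicebpa_rule(profile: LesionProfile, panel: GenePanel):
    calls = [m for m in profile.mutations if m.gene == "CEBPA" and m.oncogenic]
    return frozenset({"CEBPA"}) if len(calls) >= 2 else None


def _npm1_rule(profile: LesionProfile, panel: GenePanel):
    return frozenset({"NPM1"}) if _has_gene(profile, "NPM1") else None


def _dnmt3a_idh_rule(profile: LesionProfile, panel: GenePanel):
    if _has_gene(profile, "DNMT3A") and (
        _has_gene(profile, "IDH1") or _has_gene(profile, "IDH2")
    ):
        genes = {"DNMT3A"} | (
            {g for g in ("IDH1", "IDH2") if _has_gene(profile, g)}
        )
        return frozenset(genes)
    return None


def _wt1_rule(profile: LesionProfile, panel: GenePanel):
    return frozenset({"WT1"}) if _has_gene(profile, "WT1") else None


def _mnos_rule(profile: LesionProfile, panel: GenePanel):
    # FLT3-ITD is not class defining anywhere in the hierarchy, including
    # here: a lone ITD leaves the patient in no_events.
    drivers = {
        m.gene
        for m in profile.mutations
        if m.oncogenic
        and not (m.gene == "FLT3" and m.consequence is Consequence.ITD)
    }
    evidence = frozenset(drivers) | profile.lesion_codes()
    return evidence or None


def _no_events_rule(profile: LesionProfile, panel: GenePanel):
    return frozenset()


_RULES: dict[AmlClass, Callable] = {
    AmlClass.APL_t15_17: _fusion_rule("t(15;17)"),
    AmlClass.inv16: _fusion_rule("inv(16)"),
    AmlClass.t8_21: _fusion_rule("t(8;21)"),
    AmlClass.KMT2A_t11x: _fusion_rule("t(11;x)"),
    AmlClass.t6_9: _fusion_rule("t(6;9)"),
    AmlClass.inv3: _fusion_rule("inv(3)"),
    AmlClass.TP53_complex: _tp53_complex_rule,
    AmlClass.trisomies: _trisomy_rule,
    AmlClass.sAML2: _saml2_rule,
    AmlClass.biCEBPA: _bicebpa_rule,
    AmlClass.NPM1: _npm1_rule,
    AmlClass.sAML1: _saml1_rule,
    AmlClass.DNMT3A_IDH: _dnmt3a_idh_rule,
    AmlClass.WT1: _wt1_rule,
    AmlClass.mNOS: _mnos_rule,
    AmlClass.no_events: _no_events_rule,
}


def load_hierarchy(path: str | Path | None = None) -> tuple[AmlClass, ...]:
    """Load the ordered rule list (bundled default when ``path`` is None).

    The order must list all 16 classes exactly once, ending with mNOS and
    no_events (which guarantee totality).
    """
    if path is None:
        ref = importlib.resources.files("amlclass") / "data" / "hierarchy.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    order = tuple(AmlClass(name) for name in raw["order"])
    if sorted(order, key=lambda c: c.value) != sorted(AmlClass, key=lambda c: c.value):
        raise ValueError("hierarchy must list each of the 16 classes exactly once")
    if order[-2:] != (AmlClass.mNOS, AmlClass.no_events):
        raise ValueError("hierarchy must end with mNOS then no_events")
    return order


DEFAULT_HIERARCHY: tuple[AmlClass, ...] = load_hierarchy()


def classify_patient(
    profile: LesionProfile,
    panel: GenePanel | None = None,
    hierarchy: Sequence[AmlClass] | None = None,
) -> ClassAssignment:
    """Assign a patient to the first class in the hierarchy whose rule fires.

    Total by construction: the no_events rule always matches.
    """
    panel = panel or _default_panel()
    hierarchy = hierarchy or DEFAULT_HIERARCHY
    for rank, aml_class in enumerate(hierarchy, start=1):
        evidence = _RULES[aml_class](profile, panel)
        if evidence is not None:
            return ClassAssignment(
                patient_id=profile.patient_id,
                aml_class=aml_class,
                rule_rank=rank,
                evidence=evidence,
            )
    raise AssertionError("unreachable: no_events always matches")


_PANEL_CACHE: list[GenePanel] = []


def _default_panel() -> GenePanel:
    if not _PANEL_CACHE:
        _PANEL_CACHE.append(load_panel())
    return _PANEL_CACHE[0]


def classify_cohort(
    profiles: Iterable[LesionProfile],
    panel: GenePanel | None = None,
    hierarchy: Sequence[AmlClass] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify a cohort; returns (per-patient table, class-frequency summary).

    The summary has one row per class (including empty ones) with counts
    and fractions; fractions sum to 1 on a non-empty cohort.
    """
    panel = panel or _default_panel()
    hierarchy = hierarchy or DEFAULT_HIERARCHY
    rows = []
    for profile in profiles:
        a = classify_patient(profile, panel, hierarchy)
        rows.append({
            "patient_id": a.patient_id,
            "class": a.aml_class.value,
            "rule_rank": a.rule_rank,
            "evidence": ";".join(sorted(a.evidence)),
        })
    table = pd.DataFrame(rows, columns=["patient_id", "class", "rule_rank", "evidence"])
    counts = table["class"].value_counts() if len(table) else pd.Series(dtype=int)
    summary = pd.DataFrame({
        "class": [c.value for c in hierarchy],
        "count": [int(counts.get(c.value, 0)) for c in hierarchy],
    })
    total = summary["count"].sum()
    summary["fraction"] = summary["count"] / total if total else 0.0
    return table, summary
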