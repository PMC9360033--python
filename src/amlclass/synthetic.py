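"""Synthetic AML cohort generator with known ground truth.

Patients are drawn class-first: a molecular class label, then
class-conditional genotypes (class-defining lesions, passenger mutations,
FLT3-ITD status), class-conditional clinical covariates (age, blood
counts, antecedent hematologic disorder), and finally a six-state event
trajectory with transition-specific exponential hazards scaled by
covariate/risk log-hazard effects, with right censoring.

Two modes:

* ``strict`` — class-defining lesions are emitted deterministically and no
  lesion from an earlier hierarchy rank can contaminate the profile, so
  re-classification recovers the truth label for every patient (exact
  round-trip tests);
* ``noisy`` — with probability ``epsilon`` per patient a contaminating
  lesion from another class's defining set is added (robustness tests).

Default class prevalences and emission rates follow the published cohort
make-up where stated (e.g. TP53 mutated in 65% of complex-karyotype
patients, FLT3-ITD in 72% of t(6;9), antecedent hematologic disorder in
32% of secondary-AML-like vs 11.4% of other patients); the remaining
rates are set to representative values for adult AML.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import AmlClass
from .cohort import (
    ClinicalRecord,
    Consequence,
    DiseaseType,
    LesionProfile,
    MutationCall,
    OutcomeRecord,
    PatientRecord,
    Sex,
)
from .risk import DEFAULT_BASE_STRATA, ProposedRisk

#: Default class prevalences (sum to 1).  Where the source cohort printed a
#: class share it is used (complex karyotype 10.3%, trisomies 11.2%, sAML1
#: 4.7%, sAML2 23.7%, WT1 2%, DNMT3A/IDH 1%, mNOS 6%, no events 2%); the
#: remaining classes carry representative adult-AML frequencies.
DEFAULT_PREVALENCES: dict[AmlClass, float] = {
    AmlClass.APL_t15_17: 0.050,
    AmlClass.inv16: 0.040,
    AmlClass.t8_21: 0.050,
    AmlClass.KMT2A_t11x: 0.020,
    AmlClass.t6_9: 0.010,
    AmlClass.inv3: 0.010,
    AmlClass.TP53_complex: 0.103,
    AmlClass.trisomies: 0.112,
    AmlClass.sAML2: 0.237,
    AmlClass.biCEBPA: 0.020,
    AmlClass.NPM1: 0.191,
    AmlClass.sAML1: 0.047,
    AmlClass.DNMT3A_IDH: 0.010,
    AmlClass.WT1: 0.020,
    AmlClass.mNOS: 0.060,
    AmlClass.no_events: 0.020,
}

#: FLT3-ITD rate per class (non-class-defining, risk-modifying only).
DEFAULT_ITD_RATES: dict[AmlClass, float] = {
    AmlClass.APL_t15_17: 0.15,
    AmlClass.inv16: 0.05,
    AmlClass.t8_21: 0.05,
    AmlClass.KMT2A_t11x: 0.05,
    AmlClass.t6_9: 0.72,
    AmlClass.inv3: 0.10,
    AmlClass.TP53_complex: 0.03,
    AmlClass.trisomies: 0.10,
    AmlClass.sAML2: 0.12,
    AmlClass.biCEBPA: 0.10,
    AmlClass.NPM1: 0.40,
    AmlClass.sAML1: 0.15,
    AmlClass.DNMT3A_IDH: 0.25,
    AmlClass.WT1: 0.40,
    AmlClass.mNOS: 0.10,
    AmlClass.no_events: 0.00,
}

#: median diagnostic age per class (complex karyotype 62, sAML 65.5, WT1 41;
#: 56 elsewhere) and AHD rates (32% sAML-like vs 11.4% other).
_AGE_MEDIAN = {
    AmlClass.TP53_complex: 62.0,
    AmlClass.sAML1: 65.5,
    AmlClass.sAML2: 65.5,
    AmlClass.WT1: 41.0,
    AmlClass.APL_t15_17: 45.0,
}
_AHD_RATE = {AmlClass.sAML1: 0.32, AmlClass.sAML2: 0.32}
_BLAST_MEDIAN = {AmlClass.sAML1: 51.0, AmlClass.sAML2: 51.0}
_WBC_MEDIAN = {AmlClass.WT1: 60.0, AmlClass.NPM1: 35.0}

_SAML_FEATURES = (
    "SRSF2", "SF3B1", "U2AF1", "ZRSR2", "ASXL1", "EZH2", "BCOR",
    "STAG2", "RUNX1", "SETBP1", "MLL-PTD",
)
_PASSENGER_GENES = (
    "TET2", "NRAS", "KRAS", "PTPN11", "KIT", "JAK2", "CBL", "GATA2",
    "PHF6", "ETV6", "NF1", "CSF3R",
)


@dataclass(frozen=True)
class TransitionHazard:
    """Exponential baseline rate (events / person-year) plus log-hazard
    effects of covariate columns for one transition."""

    baseline_rate: float
    betas: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be nonnegative")


#: Default transition hazards on covariates risk_intermediate/risk_adverse
#: (proposed-stratum indicators) and age_decades (age − 55 in decades).
DEFAULT_HAZARDS: dict[tuple[int, int], TransitionHazard] = {
    (1, 2): TransitionHazard(2.5, {"risk_intermediate": -0.3, "risk_adverse": -0.8}),
    (1, 4): TransitionHazard(0.45, {"risk_intermediate": 0.5, "risk_adverse": 1.1,
                                    "age_decades": 0.2}),
    (2, 3): TransitionHazard(0.35, {"risk_intermediate": 0.5, "risk_adverse": 1.0}),
    (2, 5): TransitionHazard(0.08, {"risk_intermediate": 0.3, "risk_adverse": 0.6,
                                    "age_decades": 0.25}),
    (3, 6): TransitionHazard(0.9, {"risk_intermediate": 0.3, "risk_adverse": 0.7,
                                   "age_decades": 0.2}),
}


@dataclass(frozen=True)
class GeneratorConfig:
    n_patients: int = 500
    seed: int = 0
    mode: str = "strict"  # or "noisy"
    epsilon: float = 0.0  # contamination probability in noisy mode
    class_prevalences: Mapping[AmlClass, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    itd_rates: Mapping[AmlClass, float] = field(
        default_factory=lambda: dict(DEFAULT_ITD_RATES)
    )
    hazards: Mapping[tuple[int, int], TransitionHazard] = field(
        default_factory=lambda: dict(DEFAULT_HAZARDS)
    )
    censoring_window: tuple[float, float] = (3.0, 8.0)  # admin censoring, years

    def __post_init__(self) -> None:
        total = sum(self.class_prevalences.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class prevalences must sum to 1, got {total}")
        if any(p < 0 for p in self.class_prevalences.values()):
            raise ValueError("prevalences must be nonnegative")
        if self.mode not in {"strict", "noisy"}:
            raise ValueError("mode must be 'strict' or 'noisy'")


@dataclass
class SyntheticCohort:
    records: list[PatientRecord]
    truth: pd.Series  # patient_id -> true class label
    covariates: pd.DataFrame  # indexed by patient_id

    @property
    def profiles(self) -> list[LesionProfile]:
        return [r.profile for r in self.records]

    @property
    def outcomes(self) -> list[OutcomeRecord]:
        return [r.outcome for r in self.records]


def _mut(gene: str, rng, consequence=Consequence.SUBSTITUTION, vaf=None) -> MutationCall:
    if vaf is None:
        vaf = float(np.round(rng.uniform(0.2, 0.5), 3))
    return MutationCall(gene=gene, consequence=consequence, vaf=vaf)


def _saml_call(feature: str, rng) -> MutationCall:
    if feature == "MLL-PTD":
        return _mut("MLL", rng, consequence=Consequence.PTD)
    return _mut(feature, rng)


def _emit_genotype(
    label: AmlClass, rng: np.random.Generator
) -> tuple[set[MutationCall], set[str]]:
    """Class-conditional lesions and mutations (before ITD)."""
    muts: set[MutationCall] = set()
    lesions: set[str] = set()
    if label is AmlClass.APL_t15_17:
        lesions.add("t(15;17)")
    elif label is AmlClass.inv16:
        lesions.add("inv(16)")
        if rng.random() < 0.4:
            muts.add(_mut("KIT", rng))
    elif label is AmlClass.t8_21:
        lesions.add("t(8;21)")
        if rng.random() < 0.25:
            muts.add(_mut("KIT", rng))
    elif label is AmlClass.KMT2A_t11x:
        lesions.add("t(11;x)")
    elif label is AmlClass.t6_9:
        lesions.add("t(6;9)")
    elif label is AmlClass.inv3:
        lesions.add("inv(3)")
        if rng.random() < 0.4:
            lesions.add("-7")
    elif label is AmlClass.TP53_complex:
        lesions.update({"del(5q)", "-7", "del(17p)"})
        if rng.random() < 0.4:
            lesions.add("other_unbalanced")
        if rng.random() < 0.65:  # TP53 mutated in 65% of complex karyotypes
            muts.add(_mut("TP53", rng, vaf=float(np.round(rng.uniform(0.3, 0.9), 3))))
    elif label is AmlClass.trisomies:
        gains = rng.choice(["+8", "+11", "+13", "+21", "+22"],
                           size=rng.integers(1, 4), replace=False)
        lesions.update(gains)
        if rng.random() < 0.3:
            muts.add(_mut("TET2", rng))
    elif label is AmlClass.sAML2:
        k = int(rng.integers(2, 5))
        feats = rng.choice(_SAML_FEATURES, size=k, replace=False)
        muts.update(_saml_call(f, rng) for f in feats)
    elif label is AmlClass.biCEBPA:
        muts.add(_mut("CEBPA", rng, consequence=Consequence.SUBSTITUTION))
        muts.add(_mut("CEBPA", rng, consequence=Consequence.INDEL))
    elif label is AmlClass.NPM1:
        muts.add(_mut("NPM1", rng, consequence=Consequence.INDEL))
        if rng.random() < 0.5:
            muts.add(_mut("DNMT3A", rng))
        if rng.random() < 0.3:  # one sAML gene never re-routes an NPM1 patient
            muts.add(_saml_call(str(rng.choice(_SAML_FEATURES[:2])), rng))
    elif label is AmlClass.sAML1:
        muts.add(_saml_call(str(rng.choice(_SAML_FEATURES)), rng))
        if rng.random() < 0.3:
            muts.add(_mut("TET2", rng))
    elif label is AmlClass.DNMT3A_IDH:
        muts.add(_mut("DNMT3A", rng))
        muts.add(_mut(str(rng.choice(["IDH1", "IDH2"])), rng))
    elif label is AmlClass.WT1:
        muts.add(_mut("WT1", rng))
    elif label is AmlClass.mNOS:
        k = int(rng.integers(1, 3))
        for g in rng.choice(_PASSENGER_GENES, size=k, replace=False):
            muts.add(_mut(str(g), rng))
    # no_events: nothing
    return muts, lesions


_CONTAMINANTS: tuple[str, ...] = (
    "t(15;17)", "inv(16)", "t(8;21)", "t(11;x)", "t(6;9)", "inv(3)",
    "del(5q)", "-7", "del(17p)", "+8",
)


def _emit_clinical(pid: str, label: AmlClass, rng) -> ClinicalRecord:
    age = float(np.clip(rng.normal(_AGE_MEDIAN.get(label, 56.0), 12.0), 18, 90))
    ahd_rate = _AHD_RATE.get(label, 0.114)
    ahd = bool(rng.random() < ahd_rate)
    wbc = float(np.round(rng.lognormal(np.log(_WBC_MEDIAN.get(label, 15.0)), 0.9), 2))
    blasts = float(np.clip(rng.normal(_BLAST_MEDIAN.get(label, 65.0), 20.0), 1, 100))
    return ClinicalRecord(
        patient_id=pid,
        age_years=round(age, 1),
        sex=Sex.MALE if rng.random() < 0.5 else Sex.FEMALE,
        wbc=wbc,
        hb=float(np.round(np.clip(rng.normal(9.5, 1.6), 4, 17), 1)),
        platelets=float(np.round(rng.lognormal(np.log(60.0), 0.7), 1)),
        bm_blast_pct=round(blasts, 1),
        ahd=ahd,
        performance_status=int(rng.choice([0, 1, 2], p=[0.55, 0.35, 0.10])),
        disease_type=DiseaseType.SECONDARY if ahd else DiseaseType.DE_NOVO,
    )


def simulate_trajectories(
    covariates: pd.DataFrame,
    hazards: Mapping[tuple[int, int], TransitionHazard] | None = None,
    censoring_window: tuple[float, float] = (3.0, 8.0),
    seed: int = 0,
) -> list[OutcomeRecord]:
    """Draw six-state event trajectories for each covariate row.

    Competing transitions out of a state are resolved by the first drawn
    exponential event time (rates scaled by exp(beta'z)); the trajectory is
    right-censored at an administrative time drawn uniformly from
    ``censoring_window``.  A zero baseline rate disables a transition.
    """
    hazards = dict(hazards) if hazards is not None else dict(DEFAULT_HAZARDS)
    rng = np.random.default_rng(seed)

    def rate(key: tuple[int, int], row: pd.Series) -> float:
        h = hazards[key]
        lin = sum(b * float(row.get(c, 0.0)) for c, b in h.betas.items())
        return h.baseline_rate * float(np.exp(lin))

    def draw(r: float) -> float:
        return float(rng.exponential(1.0 / r)) if r > 0 else np.inf

    outcomes = []
    for pid, row in covariates.iterrows():
        censor = float(rng.uniform(*censoring_window))
        t12 = draw(rate((1, 2), row))
        t14 = draw(rate((1, 4), row))
        t_cr = t_relapse = None
        if t12 < t14 and t12 < censor:  # reached CR
            t_cr = t12
            t23 = t_cr + draw(rate((2, 3), row))
            t25 = t_cr + draw(rate((2, 5), row))
            if t23 < t25 and t23 < censor:  # relapsed
                t_relapse = t23
                t36 = t_relapse + draw(rate((3, 6), row))
                dead = t36 < censor
                t_last = min(t36, censor)
            else:
                dead = t25 < censor and t25 < t23
                t_last = min(t25, censor) if dead else censor
        else:
            dead = t14 < censor and t14 < t12
            t_last = min(t14, censor) if dead else censor
        outcomes.append(
            OutcomeRecord(
                patient_id=str(pid),
                t_cr=round(t_cr, 6) if t_cr is not None else None,
                t_relapse=round(t_relapse, 6) if t_relapse is not None else None,
                t_last=round(float(t_last), 6),
                dead=bool(dead),
            )
        )
    return outcomes


def generate_cohort(config: GeneratorConfig | None = None) -> SyntheticCohort:
    """Generate a full synthetic cohort: genotypes, clinical covariates and
    outcome trajectories, with the true class label per patient."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    labels = list(config.class_prevalences.keys())
    probs = np.array([config.class_prevalences[l] for l in labels], float)
    drawn = rng.choice(len(labels), size=config.n_patients, p=probs / probs.sum())

    profiles: list[LesionProfile] = []
    clinicals: list[ClinicalRecord] = []
    truth = {}
    cov_rows = []
    for i, li in enumerate(drawn):
        label = labels[int(li)]
        pid = f"SYN{i:05d}"
        truth[pid] = label.value
        muts, lesions = _emit_genotype(label, rng)
        if config.mode == "noisy" and rng.random() < config.epsilon:
            lesions.add(str(rng.choice(_CONTAMINANTS)))
        itd_ratio = None
        if rng.random() < config.itd_rates.get(label, 0.0):
            itd_ratio = float(np.round(rng.uniform(0.1, 1.5), 3))
            muts.add(
                MutationCall("FLT3", consequence=Consequence.ITD,
                             vaf=float(np.round(rng.uniform(0.1, 0.5), 3)))
            )
        profile = LesionProfile.build(
            pid, mutations=muts, cytogenetics=lesions, flt3_itd_ratio=itd_ratio
        )
        profiles.append(profile)
        clinical = _emit_clinical(pid, label, rng)
        clinicals.append(clinical)
        base = DEFAULT_BASE_STRATA[label]
        stratum = base
        if profile.flt3_itd:
            if label is AmlClass.NPM1:
                stratum = ProposedRisk.INTERMEDIATE
            elif base is ProposedRisk.INTERMEDIATE:
                stratum = ProposedRisk.ADVERSE
        cov_rows.append({
            "patient_id": pid,
            "risk_intermediate": float(stratum is ProposedRisk.INTERMEDIATE),
            "risk_adverse": float(stratum is ProposedRisk.ADVERSE),
            "age_decades": (clinical.age_years - 55.0) / 10.0,
            "flt3_itd": float(profile.flt3_itd),
            "ahd": float(clinical.ahd),
        })
    covariates = pd.DataFrame(cov_rows).set_index("patient_id")
    outcomes = simulate_trajectories(
        covariates, config.hazards, config.censoring_window,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    records = [
        PatientRecord(p, c, o) for p, c, o in zip(profiles, clinicals, outcomes)
    ]
    return SyntheticCohort(
        records=records,
        truth=pd.Series(truth, name="true_class"),
        covariates=covariates,
    )


def lesion_matrix(profiles: Sequence[LesionProfile]) -> pd.DataFrame:
    """Binary patient-by-feature matrix (cytogenetic tokens + mutated
    genes, MLL-PTD as its own feature) for the clustering module."""
    rows = []
    for p in profiles:
        row: dict[str, int] = {}
        for code in p.lesion_codes():
            row[code] = 1
        for m in p.mutations:
            if m.gene == "MLL" and m.consequence is Consequence.PTD:
                row["MLL-PTD"] = 1
            elif m.gene == "FLT3" and m.consequence is Consequence.ITD:
                row["FLT3-ITD"] = 1
            else:
                row[m.gene] = 1
        rows.append(row)
    df = pd.DataFrame(rows, index=[p.patient_id for p in profiles]).fillna(0).astype(int)
    return df.reindex(sorted(df.columns), axis=1)
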