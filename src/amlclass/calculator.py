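"""Patient-level risk calculator: the offline composite report.

Given one patient's genotype and clinical presentation plus a trained
multi-state model bundle, the calculator returns the molecular class, the
ELN2017 and proposed risk strata, state-occupancy curves (from diagnosis
or from attainment of CR), per-transition contributing factors and
outlier warnings.  All 32 panel genes and all cytogenetic findings are
assumed wild type / absent unless specified; clinical covariates left
unspecified are imputed at the training-cohort medians (and therefore
contribute exactly zero to every transition's log-hazard).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .classify import AmlClass, ClassAssignment, classify_patient
from .cohort import Consequence, LesionProfile, MutationCall
from .multistate import State, TransitionModel, contributing_factors, predict_state_occupancy
from .risk import ProposedRisk, RiskAssignment, proposed_stratify


class RequestValidationError(ValueError):
    """Malformed calculator request; ``fields`` lists the offenders."""

    def __init__(self, fields: Sequence[str]):
        self.fields = list(fields)
        super().__init__(f"invalid request fields: {self.fields}")


@dataclass(frozen=True)
class CalculatorRequest:
    """One patient's inputs.  ``mutations`` are (gene, consequence, vaf)
    triples — anything not listed is wild type; ``clinical`` maps clinical
    covariate names to values — anything missing is median-imputed."""

    mutations: tuple[MutationCall, ...] = ()
    cytogenetics: tuple[str, ...] = ()
    karyotype_available: bool = True
    flt3_itd_ratio: float | None = None
    clinical: Mapping[str, float] = field(default_factory=dict)
    start: str = "diagnosis"  # or "cr"
    horizon_years: float = 5.0

    def __post_init__(self) -> None:
        bad = []
        if self.start not in {"diagnosis", "cr"}:
            bad.append("start")
        if self.horizon_years <= 0:
            bad.append("horizon_years")
        for k, v in self.clinical.items():
            if v is not None and not np.isfinite(v):
                bad.append(f"clinical.{k}")
        if bad:
            raise RequestValidationError(bad)


def risk_covariates(
    assignment: ClassAssignment,
    risk: RiskAssignment,
    clinical: Mapping[str, float],
) -> dict[str, float]:
    """Model covariates derived from the classification and clinical input:
    proposed-stratum indicators plus any clinical covariates supplied
    (age as decades from 55)."""
    z: dict[str, float] = {
        "risk_intermediate": float(risk.proposed is ProposedRisk.INTERMEDIATE),
        "risk_adverse": float(risk.proposed is ProposedRisk.ADVERSE),
    }
    if "age_years" in clinical and clinical["age_years"] is not None:
        z["age_decades"] = (float(clinical["age_years"]) - 55.0) / 10.0
    for k, v in clinical.items():
        if k != "age_years" and v is not None:
            z[k] = float(v)
    return z


def calculate(
    request: CalculatorRequest,
    model: TransitionModel,
    panel=None,
    hierarchy=None,
) -> dict:
    """Run the full pipeline for one patient and assemble the report."""
    profile = LesionProfile.build(
        "calculator",
        mutations=request.mutations,
        cytogenetics=request.cytogenetics,
        karyotype_available=request.karyotype_available,
        flt3_itd_ratio=request.flt3_itd_ratio,
    )
    assignment = classify_patient(profile, panel, hierarchy)
    risk = proposed_stratify(assignment, profile)
    z = risk_covariates(assignment, risk, request.clinical)
    # drop covariates the model was not trained on
    trained = set()
    for f in model.fits.values():
        trained.update(f.covariates)
    z = {k: v for k, v in z.items() if k in trained}
    start = State.ALIVE_CR if request.start == "cr" else State.ALIVE_INDUCTION
    pred = predict_state_occupancy(model, z, start=start)
    occ = pred.occupancy[pred.occupancy["time"] <= request.horizon_years]
    factors = {}
    for key, f in model.fits.items():
        if not f.estimable:
            continue
        zk = {c: z[c] for c in f.covariates if c in z}
        factors[f"{key[0]}->{key[1]}"] = contributing_factors(model, zk, key)
    return {
        "class": assignment.aml_class.value,
        "rule_rank": assignment.rule_rank,
        "evidence": sorted(assignment.evidence),
        "eln2017": risk.eln2017.value,
        "proposed_risk": risk.proposed.value,
        "shift_applied": risk.shift_applied.value,
        "covariates_used": z,
        "occupancy": occ.to_dict(orient="list"),
        "contributing_factors": factors,
        "outlier_warnings": pred.outlier_warnings,
    }
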