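"""Classify a handful of patients and stratify their risk.

Builds four genotype profiles by hand, assigns each to one of the 16
molecular classes, and prints the ELN2017 reference stratum next to the
proposed class-based stratum (with any FLT3-ITD shift).
"""

from amlclass import (
    LesionProfile,
    MutationCall,
    classify_patient,
    proposed_stratify,
)
from amlclass.cohort import Consequence

itd = MutationCall("FLT3", consequence=Consequence.ITD)

patients = {
    # the published worked example: 63y, normal karyotype, BCOR + SF3B1
    "PD25176a-like": LesionProfile.build(
        "PD25176a-like",
        mutations=[MutationCall("BCOR", vaf=0.35), MutationCall("SF3B1", vaf=0.42)],
    ),
    "NPM1 + FLT3-ITD": LesionProfile.build(
        "NPM1 + FLT3-ITD", mutations=[MutationCall("NPM1"), itd]
    ),
    "complex karyotype": LesionProfile.build(
        "complex karyotype",
        mutations=[MutationCall("TP53", vaf=0.78)],
        cytogenetics=["del(5q)", "-7", "del(17p)"],
    ),
    "triple trisomy": LesionProfile.build(
        "triple trisomy", cytogenetics=["+8", "+13", "+21"]
    ),
}

print(f"{'patient':<20}{'class':<14}{'ELN2017':<14}{'proposed':<16}shift")
for name, profile in patients.items():
    assignment = classify_patient(profile)
    risk = proposed_stratify(assignment, profile)
    print(
        f"{name:<20}{assignment.aml_class.value:<14}"
        f"{risk.eln2017.value:<14}{risk.proposed.value:<16}"
        f"{risk.shift_applied.value}"
    )

# The proposed stratum follows class membership alone, except that FLT3-ITD
# demotes NPM1-class patients one tier (favorable -> intermediate) and any
# intermediate-class patient to adverse.
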