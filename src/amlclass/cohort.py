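"""Domain types and readers/writers for per-patient cohort tables.

A cohort is carried in three tab-separated tables:

``mutations.tsv``
    one row per oncogenic-annotated mutation call:
    ``patient_id  gene  vaf  consequence  oncogenic  [itd_ratio]``
    (``vaf`` may be empty; ``consequence`` one of substitution / indel /
    splice / itd / ptd; ``itd_ratio`` is the FLT3-ITD allelic ratio and is
    only meaningful on FLT3 itd rows).

``cytogenetics.tsv``
    one row per patient: ``patient_id  karyotype_available  lesions`` where
    ``lesions`` is a comma-separated list of controlled-vocabulary tokens
    (empty for a normal karyotype).

``clinical.tsv``
    one row per patient with demographics, blood counts and outcome
    timepoints: ``patient_id  age_years  sex  wbc  hb  platelets
    bm_blast_pct  ahd  performance_status  disease_type  t_cr  t_relapse
    t_last  dead``.  Times are years from diagnosis.

The joined record per patient is (:class:`LesionProfile`,
:class:`ClinicalRecord`, :class:`OutcomeRecord`).
"""

from __future__ import annotations

import enum
import importlib.resources
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .vocab import LesionCode, get_lesion

MLL_PTD_FEATURE = "MLL-PTD"


class SchemaError(ValueError):
    """A cohort table does not match its documented column schema."""


class CohortIntegrityError(ValueError):
    """Cross-table consistency violated (e.g. duplicated patient_id)."""


class Consequence(str, enum.Enum):
    SUBSTITUTION = "substitution"
    INDEL = "indel"
    SPLICE = "splice"
    ITD = "itd"
    PTD = "ptd"


@dataclass(frozen=True)
class MutationCall:
    """A single mutation call in a panel gene.

    ``vaf`` is the variant allele fraction in [0, 1] and may be ``None``
    when not reported (the TP53 VAF-based multi-hit criterion then simply
    cannot fire).
    """

    gene: str
    consequence: Consequence = Consequence.SUBSTITUTION
    vaf: float | None = None
    oncogenic: bool = True

    def __post_init__(self) -> None:
        if self.vaf is not None and not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"vaf must be in [0, 1], got {self.vaf}")


@dataclass(frozen=True)
class GenePanel:
    """The configured gene panel and its sAML class-defining subset.

    ``saml_class_defining`` holds the 11 secondary-AML-like features
    (SRSF2, SF3B1, U2AF1, ZRSR2, ASXL1, EZH2, BCOR, STAG2, RUNX1, SETBP1
    and MLL-PTD).  MLL-PTD is a feature, not a gene symbol: it corresponds
    to an MLL call with consequence ``ptd``.
    """

    genes: tuple[str, ...]
    saml_class_defining: frozenset[str]

    def __post_init__(self) -> None:
        gene_set = set(self.genes)
        for feature in self.saml_class_defining:
            gene = "MLL" if feature == MLL_PTD_FEATURE else feature
            if gene not in gene_set:
                raise SchemaError(
                    f"sAML class-defining feature {feature!r} not in panel"
                )

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


def load_panel(path: str | Path | None = None) -> GenePanel:
    """Load a gene panel from YAML; with no path, the bundled 32-gene panel."""
    if path is None:
        ref = importlib.resources.files("amlclass") / "data" / "panel.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    try:
        genes = tuple(raw["genes"])
        subset = frozenset(raw["saml_class_defining"])
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"panel config missing key: {exc}") from exc
    return GenePanel(genes=genes, saml_class_defining=subset)


@dataclass(frozen=True)
class LesionProfile:
    """One patient's genotype: mutation calls plus coded cytogenetics.

    ``flt3_itd`` / ``npm1`` are derived flags kept consistent with the
    mutation set; construct through :meth:`build` unless you are writing
    tests for the consistency invariant itself.
    """

    patient_id: str
    mutations: frozenset[MutationCall] = frozenset()
    cytogenetics: frozenset[LesionCode] = frozenset()
    karyotype_available: bool = True
    flt3_itd: bool = False
    flt3_itd_ratio: float | None = None
    npm1: bool = False

    @classmethod
    def build(
        cls,
        patient_id: str,
        mutations: Iterable[MutationCall] = (),
        cytogenetics: Iterable[LesionCode | str] = (),
        karyotype_available: bool = True,
        flt3_itd_ratio: float | None = None,
    ) -> "LesionProfile":
        muts = frozenset(mutations)
        lesions = frozenset(
            get_lesion(c) if isinstance(c, str) else c for c in cytogenetics
        )
        return cls(
            patient_id=patient_id,
            mutations=muts,
            cytogenetics=lesions,
            karyotype_available=karyotype_available,
            flt3_itd=any(
                m.gene == "FLT3" and m.consequence is Consequence.ITD
                for m in muts
            ),
            flt3_itd_ratio=flt3_itd_ratio,
            npm1=any(m.gene == "NPM1" and m.oncogenic for m in muts),
        )

    def genes(self, oncogenic_only: bool = True) -> frozenset[str]:
        return frozenset(
            m.gene for m in self.mutations if m.oncogenic or not oncogenic_only
        )

    def lesion_codes(self) -> frozenset[str]:
        return frozenset(l.code for l in self.cytogenetics)

    def has_lesion(self, code: str) -> bool:
        return any(l.code == code for l in self.cytogenetics)


class Sex(str, enum.Enum):
    FEMALE = "F"
    MALE = "M"


class DiseaseType(str, enum.Enum):
    DE_NOVO = "de_novo"
    SECONDARY = "sAML"
    THERAPY_RELATED = "tAML"


@dataclass(frozen=True)
class ClinicalRecord:
    """Diagnostic demographics and blood counts.

    Units: age in years, WBC and platelets in 1e9/L, Hb in g/dL, marrow
    blasts in percent.  ``ahd`` flags an antecedent hematologic disorder.
    """

    patient_id: str
    age_years: float
    sex: Sex = Sex.FEMALE
    wbc: float | None = None
    hb: float | None = None
    platelets: float | None = None
    bm_blast_pct: float | None = None
    ahd: bool = False
    performance_status: int = 0
    disease_type: DiseaseType = DiseaseType.DE_NOVO

    def __post_init__(self) -> None:
        if self.bm_blast_pct is not None and not (0 <= self.bm_blast_pct <= 100):
            raise ValueError("bm_blast_pct must be in [0, 100]")
        for name in ("wbc", "hb", "platelets"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class OutcomeRecord:
    """Outcome timepoints in years from diagnosis.

    ``t_cr``: complete remission (missing if never attained);
    ``t_relapse``: relapse (requires CR first); ``t_last``: last follow-up
    or death; ``dead``: vital status at ``t_last``.
    """

    patient_id: str
    t_last: float
    dead: bool
    t_cr: float | None = None
    t_relapse: float | None = None

    def __post_init__(self) -> None:
        times = [t for t in (self.t_cr, self.t_relapse, self.t_last) if t is not None]
        if any(t < 0 for t in times):
            raise ValueError("times must be nonnegative")

    def is_consistent(self) -> bool:
        """True when timepoints are mutually orderable (CR before relapse
        before last follow-up, and relapse never without CR)."""
        if self.t_relapse is not None and self.t_cr is None:
            return False
        if self.t_cr is not None and self.t_cr > self.t_last:
            return False
        if self.t_relapse is not None and (
            self.t_relapse < self.t_cr or self.t_relapse > self.t_last
        ):
            return False
        return True


@dataclass(frozen=True)
class PatientRecord:
    profile: LesionProfile
    clinical: ClinicalRecord
    outcome: OutcomeRecord

    @property
    def patient_id(self) -> str:
        return self.profile.patient_id


# ---------------------------------------------------------------------------
# table I/O

_MUTATION_COLS = ["patient_id", "gene", "vaf", "consequence", "oncogenic"]
_CYTO_COLS = ["patient_id", "karyotype_available", "lesions"]
_CLINICAL_COLS = [
    "patient_id", "age_years", "sex", "wbc", "hb", "platelets",
    "bm_blast_pct", "ahd", "performance_status", "disease_type",
    "t_cr", "t_relapse", "t_last", "dead",
]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table missing required columns: {missing}")


def _check_unique(ids: pd.Series, what: str) -> None:
    dup = ids[ids.duplicated()]
    if len(dup):
        raise CohortIntegrityError(
            f"duplicate patient_id in {what} table: {sorted(set(dup))}"
        )


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return float(value)


def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in {"1", "true", "yes", "y"}
    return bool(value)


def read_cohort(
    mutations_path: str | Path,
    cytogenetics_path: str | Path,
    clinical_path: str | Path,
    panel: GenePanel | None = None,
) -> list[PatientRecord]:
    """Read and join the three cohort tables into one record per patient.

    The clinical table defines cohort membership: patients absent from the
    mutation or cytogenetics tables get empty mutation sets / no-karyotype
    profiles.  Mutation rows whose gene is not in the panel are skipped
    with a warning; unknown cytogenetic tokens raise, identifying the
    offending patient.
    """
    panel = panel or load_panel()
    mut = pd.read_csv(mutations_path, sep="\t", dtype={"patient_id": str})
    cyt = pd.read_csv(cytogenetics_path, sep="\t", dtype=str)
    cli = pd.read_csv(clinical_path, sep="\t", dtype={"patient_id": str})
    _require_columns(mut, _MUTATION_COLS, "mutations")
    _require_columns(cyt, _CYTO_COLS, "cytogenetics")
    _require_columns(cli, _CLINICAL_COLS, "clinical")
    _check_unique(cyt["patient_id"], "cytogenetics")
    _check_unique(cli["patient_id"], "clinical")

    calls: dict[str, set[MutationCall]] = {}
    ratios: dict[str, float] = {}
    for row in mut.itertuples(index=False):
        if row.gene not in panel:
            warnings.warn(
                f"skipping mutation row for patient {row.patient_id}: "
                f"gene {row.gene!r} not in panel",
                stacklevel=2,
            )
            continue
        call = MutationCall(
            gene=row.gene,
            consequence=Consequence(row.consequence),
            vaf=_opt_float(row.vaf),
            oncogenic=_as_bool(row.oncogenic),
        )
        calls.setdefault(row.patient_id, set()).add(call)
        if call.gene == "FLT3" and call.consequence is Consequence.ITD:
            r = _opt_float(getattr(row, "itd_ratio", None))
            if r is not None:
                ratios[row.patient_id] = r

    cyto: dict[str, tuple[bool, frozenset[LesionCode]]] = {}
    for row in cyt.itertuples(index=False):
        tokens = [
            t.strip()
            for t in str(row.lesions).split(",")
            if t.strip() and str(row.lesions) not in ("nan", "None")
        ]
        try:
            lesions = frozenset(get_lesion(t) for t in tokens)
        except ValueError as exc:
            raise SchemaError(
                f"cytogenetics row for patient {row.patient_id}: {exc}"
            ) from exc
        cyto[row.patient_id] = (_as_bool(row.karyotype_available), lesions)

    records: list[PatientRecord] = []
    for row in cli.itertuples(index=False):
        pid = row.patient_id
        karyotype_available, lesions = cyto.get(pid, (False, frozenset()))
        profile = LesionProfile.build(
            pid,
            mutations=calls.get(pid, ()),
            cytogenetics=lesions,
            karyotype_available=karyotype_available,
            flt3_itd_ratio=ratios.get(pid),
        )
        clinical = ClinicalRecord(
            patient_id=pid,
            age_years=float(row.age_years),
            sex=Sex(row.sex),
            wbc=_opt_float(row.wbc),
            hb=_opt_float(row.hb),
            platelets=_opt_float(row.platelets),
            bm_blast_pct=_opt_float(row.bm_blast_pct),
            ahd=_as_bool(row.ahd),
            performance_status=int(row.performance_status),
            disease_type=DiseaseType(row.disease_type),
        )
        outcome = OutcomeRecord(
            patient_id=pid,
            t_cr=_opt_float(row.t_cr),
            t_relapse=_opt_float(row.t_relapse),
            t_last=float(row.t_last),
            dead=_as_bool(row.dead),
        )
        records.append(PatientRecord(profile, clinical, outcome))
    return records


def read_profiles(
    mutations_path: str | Path,
    cytogenetics_path: str | Path,
    panel: GenePanel | None = None,
) -> list[LesionProfile]:
    """Read lesion profiles only (no clinical table); cohort membership is
    the union of patient ids across the two tables."""
    panel = panel or load_panel()
    mut = pd.read_csv(mutations_path, sep="\t", dtype={"patient_id": str})
    cyt = pd.read_csv(cytogenetics_path, sep="\t", dtype=str)
    _require_columns(mut, _MUTATION_COLS, "mutations")
    _require_columns(cyt, _CYTO_COLS, "cytogenetics")
    _check_unique(cyt["patient_id"], "cytogenetics")

    calls: dict[str, set[MutationCall]] = {}
    ratios: dict[str, float] = {}
    for row in mut.itertuples(index=False):
        if row.gene not in panel:
            warnings.warn(
                f"skipping mutation row for patient {row.patient_id}: "
                f"gene {row.gene!r} not in panel",
                stacklevel=2,
            )
            continue
        call = MutationCall(
            gene=row.gene,
            consequence=Consequence(row.consequence),
            vaf=_opt_float(row.vaf),
            oncogenic=_as_bool(row.oncogenic),
        )
        calls.setdefault(row.patient_id, set()).add(call)
        if call.gene == "FLT3" and call.consequence is Consequence.ITD:
            r = _opt_float(getattr(row, "itd_ratio", None))
            if r is not None:
                ratios[row.patient_id] = r
    cyto: dict[str, tuple[bool, frozenset[LesionCode]]] = {}
    for row in cyt.itertuples(index=False):
        tokens = [
            t.strip()
            for t in str(row.lesions).split(",")
            if t.strip() and str(row.lesions) not in ("nan", "None")
        ]
        lesions = frozenset(get_lesion(t) for t in tokens)
        cyto[row.patient_id] = (_as_bool(row.karyotype_available), lesions)
    pids = sorted(set(calls) | set(cyto))
    profiles = []
    for pid in pids:
        karyotype_available, lesions = cyto.get(pid, (False, frozenset()))
        profiles.append(
            LesionProfile.build(
                pid,
                mutations=calls.get(pid, ()),
                cytogenetics=lesions,
                karyotype_available=karyotype_available,
                flt3_itd_ratio=ratios.get(pid),
            )
        )
    return profiles


def write_cohort(
    records: Sequence[PatientRecord],
    mutations_path: str | Path,
    cytogenetics_path: str | Path,
    clinical_path: str | Path,
) -> None:
    """Write records back to the three-table layout read by
    :func:`read_cohort` (round-trip safe for lesion and mutation sets)."""
    mut_rows, cyt_rows, cli_rows = [], [], []
    for rec in records:
        p, c, o = rec.profile, rec.clinical, rec.outcome
        for m in sorted(p.mutations, key=lambda m: (m.gene, m.consequence.value)):
            mut_rows.append({
                "patient_id": p.patient_id,
                "gene": m.gene,
                "vaf": m.vaf,
                "consequence": m.consequence.value,
                "oncogenic": m.oncogenic,
                "itd_ratio": p.flt3_itd_ratio
                if (m.gene == "FLT3" and m.consequence is Consequence.ITD)
                else None,
            })
        cyt_rows.append({
            "patient_id": p.patient_id,
            "karyotype_available": p.karyotype_available,
            "lesions": ",".join(sorted(p.lesion_codes())),
        })
        cli_rows.append({
            "patient_id": p.patient_id,
            "age_years": c.age_years,
            "sex": c.sex.value,
            "wbc": c.wbc,
            "hb": c.hb,
            "platelets": c.platelets,
            "bm_blast_pct": c.bm_blast_pct,
            "ahd": c.ahd,
            "performance_status": c.performance_status,
            "disease_type": c.disease_type.value,
            "t_cr": o.t_cr,
            "t_relapse": o.t_relapse,
            "t_last": o.t_last,
            "dead": o.dead,
        })
    cols = _MUTATION_COLS + ["itd_ratio"]
    pd.DataFrame(mut_rows, columns=cols).to_csv(mutations_path, sep="\t", index=False)
    pd.DataFrame(cyt_rows, columns=_CYTO_COLS).to_csv(
        cytogenetics_path, sep="\t", index=False
    )
    pd.DataFrame(cli_rows, columns=_CLINICAL_COLS).to_csv(
        clinical_path, sep="\t", index=False
    )


def export_json(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Export joined records as a JSON array (one object per patient)."""
    payload = []
    for rec in records:
        p, c, o = rec.profile, rec.clinical, rec.outcome
        payload.append({
            "patient_id": p.patient_id,
            "mutations": [
                {
                    "gene": m.gene,
                    "consequence": m.consequence.value,
                    "vaf": m.vaf,
                    "oncogenic": m.oncogenic,
                }
                for m in sorted(p.mutations, key=lambda m: (m.gene, m.consequence.value))
            ],
            "cytogenetics": sorted(p.lesion_codes()),
            "karyotype_available": p.karyotype_available,
            "flt3_itd": p.flt3_itd,
            "flt3_itd_ratio": p.flt3_itd_ratio,
            "npm1": p.npm1,
            "clinical": {
                "age_years": c.age_years,
                "sex": c.sex.value,
                "wbc": c.wbc,
                "hb": c.hb,
                "platelets": c.platelets,
                "bm_blast_pct": c.bm_blast_pct,
                "ahd": c.ahd,
                "performance_status": c.performance_status,
                "disease_type": c.disease_type.value,
            },
            "outcome": {
                "t_cr": o.t_cr,
                "t_relapse": o.t_relapse,
                "t_last": o.t_last,
                "dead": o.dead,
            },
        })
    Path(path).write_text(json.dumps(payload, indent=2))
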