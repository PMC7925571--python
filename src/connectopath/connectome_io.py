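"""Readers, writers and boundary validation for connectivity matrices,
the parcellation atlas and the cohort phenotype table.

All structural invariants (symmetry, non-negativity, zero diagonal, atlas
consistency, symptom-score ranges) are enforced here so that downstream
modules can assume clean inputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: closed set of admissible network labels (seven cortical systems + subcortex)
NETWORK_LABELS = frozenset(
    {
        "visual",
        "somatomotor",
        "dorsal_attention",
        "ventral_attention",
        "limbic",
        "frontoparietal",
        "default_mode",
        "subcortical",
    }
)

HEMISPHERES = frozenset({"left", "right"})

#: tolerance used when symmetrizing loaded matrices
SYMMETRY_TOL = 1e-9

ADHD_RS_ITEMS = 18
ADHD_RS_TOTAL_MAX = 54  # 18 items x 0-3
ADHD_RS_SUBSCALE_MAX = 27  # 9 items x 0-3


class ValidationError(ValueError):
    """Raised when an input file violates a structural invariant."""


# ---------------------------------------------------------------------------
# Parcellation atlas
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParcellationAtlas:
    """Ordered region table: name, hemisphere, network label."""

    names: tuple[str, ...]
    hemispheres: tuple[str, ...]
    networks: tuple[str, ...]

    def __post_init__(self) -> None:
        if not (len(self.names) == len(self.hemispheres) == len(self.networks)):
            raise ValidationError("atlas columns have unequal lengths")
        if len(set(self.names)) != len(self.names):
            dupes = sorted({n for n in self.names if list(self.names).count(n) > 1})
            raise ValidationError(f"duplicate region names in atlas: {dupes}")
        for h in self.hemispheres:
            if h not in HEMISPHERES:
                raise ValidationError(f"unknown hemisphere label: {h!r}")
        for net in self.networks:
            if net not in NETWORK_LABELS:
                raise ValidationError(f"unknown network label: {net!r}")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, region: str) -> int:
        try:
            return self.names.index(region)
        except ValueError:
            raise KeyError(f"unknown region: {region!r}") from None

    def network_of(self, region: str) -> str:
        return self.networks[self.index(region)]

    def hemisphere_of(self, region: str) -> str:
        return self.hemispheres[self.index(region)]

    def network_census(self) -> dict[str, int]:
        census: dict[str, int] = {}
        for net in self.networks:
            census[net] = census.get(net, 0) + 1
        return census

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"name": self.names, "hemisphere": self.hemispheres, "network": self.networks}
        )


def load_atlas(path: str | Path) -> ParcellationAtlas:
    """Load a delimited atlas table with columns ``name, hemisphere, network``."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = {"name", "hemisphere", "network"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"atlas file missing columns: {sorted(missing)}")
    return ParcellationAtlas(
        names=tuple(df["name"]),
        hemispheres=tuple(df["hemisphere"]),
        networks=tuple(df["network"]),
    )


def default_atlas() -> ParcellationAtlas:
    """The bundled 82-region atlas: 68 cortical (34/hemisphere) + 14 subcortical."""
    ref = resources.files("connectopath.data").joinpath("atlas_82.tsv")
    with resources.as_file(ref) as path:
        atlas = load_atlas(path)
    if len(atlas) != 82:
        raise ValidationError("bundled atlas must have exactly 82 regions")
    return atlas


# ---------------------------------------------------------------------------
# Connectivity matrices
# ---------------------------------------------------------------------------


@dataclass
class ConnectivityMatrix:
    """One subject's symmetric, non-negative weighted adjacency matrix."""

    subject_id: str
    regions: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        n = len(self.regions)
        if w.shape != (n, n):
            raise ValidationError(
                f"weights shape {w.shape} does not match {n} regions"
            )
        if not np.all(np.isfinite(w)):
            raise ValidationError("non-finite entries in connectivity matrix")
        if np.any(w < 0):
            raise ValidationError("negative weight in connectivity matrix")
        asym = np.max(np.abs(w - w.T)) if n else 0.0
        if asym > SYMMETRY_TOL:
            raise ValidationError(
                f"asymmetry {asym:.3g} exceeds tolerance {SYMMETRY_TOL:g}"
            )
        w = (w + w.T) / 2.0
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n(self) -> int:
        return len(self.regions)


def _read_delimited_matrix(path: Path) -> tuple[Optional[list[str]], np.ndarray]:
    """Return (header or None, values) from a comma/tab-delimited matrix file."""
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValidationError(f"empty matrix file: {path}")
    delim = "\t" if lines[0].count("\t") >= lines[0].count(",") and "\t" in lines[0] else ","
    first = [tok.strip() for tok in lines[0].split(delim)]

    def _numeric(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    header: Optional[list[str]] = None
    body = lines
    if not all(_numeric(tok) for tok in first):
        header = first
        body = lines[1:]
    rows = []
    for ln in body:
        toks = [tok.strip() for tok in ln.split(delim)]
        try:
            rows.append([float(tok) for tok in toks])
        except ValueError as exc:
            raise ValidationError(f"non-numeric entry in {path}: {exc}") from None
    values = np.asarray(rows, dtype=float)
    return header, values


def load_matrix(path: str | Path, atlas: ParcellationAtlas) -> ConnectivityMatrix:
    """Load and validate one subject's delimited connectivity matrix.

    The file must be an n x n numeric table (comma- or tab-delimited,
    auto-detected) with an optional header row of region names whose order
    must match the atlas exactly. Subject id is taken from the file stem.
    """
    path = Path(path)
    header, values = _read_delimited_matrix(path)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValidationError(f"matrix in {path} is not square: shape {values.shape}")
    if values.shape[0] != len(atlas):
        raise ValidationError(
            f"matrix dimension {values.shape[0]} does not match atlas length {len(atlas)}"
        )
    if header is not None and tuple(header) != atlas.names:
        raise ValidationError(f"header region order in {path} does not match atlas")
    return ConnectivityMatrix(
        subject_id=path.stem, regions=atlas.names, weights=values
    )


def write_matrix(
    m: ConnectivityMatrix, path: str | Path, header: bool = True
) -> None:
    """Write a matrix as delimited text at 12 significant digits.

    Delimiter follows the extension (``.tsv`` -> tab, otherwise comma), so a
    round-trip through :func:`load_matrix` reproduces weights to 1e-9.
    """
    path = Path(path)
    delim = "\t" if path.suffix == ".tsv" else ","
    with path.open("w") as fh:
        if header:
            fh.write(delim.join(m.regions) + "\n")
        for row in m.weights:
            fh.write(delim.join(f"{v:.12g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# Subjects and cohort
# ---------------------------------------------------------------------------


@dataclass
class SubjectRecord:
    """Phenotypes, covariates and outcomes for one subject."""

    subject_id: str
    group: str  # "ADHD" | "TDC"
    age: float
    gender: str
    adhd_subtype: Optional[str] = None
    mph_dose_mg_per_kg: Optional[float] = None
    prior_stimulant_6mo: Optional[bool] = None
    prior_stimulant_duration: Optional[float] = None
    adhdrs_total_w0: int = 0
    adhdrs_inatt_w0: int = 0
    adhdrs_hyper_w0: int = 0
    adhdrs_total_w6: Optional[int] = None
    adhdrs_inatt_w6: Optional[int] = None
    adhdrs_hyper_w6: Optional[int] = None

    def __post_init__(self) -> None:
        if self.group not in ("ADHD", "TDC"):
            raise ValidationError(f"unknown group: {self.group!r}")
        self._check_scores(
            self.adhdrs_total_w0, self.adhdrs_inatt_w0, self.adhdrs_hyper_w0, "w0"
        )
        has_w6 = any(
            v is not None
            for v in (self.adhdrs_total_w6, self.adhdrs_inatt_w6, self.adhdrs_hyper_w6)
        )
        if has_w6 and self.group == "TDC":
            raise ValidationError(
                f"TDC subject {self.subject_id} must not carry week-6 scores"
            )
        if has_w6:
            self._check_scores(
                self.adhdrs_total_w6, self.adhdrs_inatt_w6, self.adhdrs_hyper_w6, "w6"
            )

    def _check_scores(self, total, inatt, hyper, label: str) -> None:
        if total is None or inatt is None or hyper is None:
            raise ValidationError(
                f"{self.subject_id}: incomplete {label} scores"
            )
        if not 0 <= total <= ADHD_RS_TOTAL_MAX:
            raise ValidationError(
                f"{self.subject_id}: {label} total score {total} out of range [0, 54]"
            )
        for name, sub in (("inattention", inatt), ("hyperactivity", hyper)):
            if not 0 <= sub <= ADHD_RS_SUBSCALE_MAX:
                raise ValidationError(
                    f"{self.subject_id}: {label} {name} subscale {sub} out of range [0, 27]"
                )

    @property
    def has_week6(self) -> bool:
        return self.adhdrs_total_w6 is not None


@dataclass
class CohortTable:
    """Subjects joined to their connectivity matrices."""

    subjects: list[SubjectRecord]
    matrices: dict[str, ConnectivityMatrix] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate subject ids in cohort")
        for sid in ids:
            if sid not in self.matrices:
                raise ValidationError(f"subject {sid} has no connectivity matrix")

    def group(self, label: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == label]

    @property
    def n(self) -> int:
        return len(self.subjects)

    def treatment_subjects(self) -> list[SubjectRecord]:
        """ADHD subjects with complete week-6 outcomes (treatment analyses)."""
        return [s for s in self.group("ADHD") if s.has_week6]


_PHENO_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "gender",
    "adhd_subtype",
    "mph_dose_mg_per_kg",
    "prior_stimulant_6mo",
    "prior_stimulant_duration",
    "adhdrs_total_w0",
    "adhdrs_inatt_w0",
    "adhdrs_hyper_w0",
    "adhdrs_total_w6",
    "adhdrs_inatt_w6",
    "adhdrs_hyper_w6",
]


def _opt_float(v) -> Optional[float]:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return float(v)


def _opt_int(v) -> Optional[int]:
    f = _opt_float(v)
    return None if f is None else int(round(f))


def _opt_bool(v) -> Optional[bool]:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    if isinstance(v, str):
        return v.strip().lower() in ("true", "1", "yes")
    return bool(v)


def _opt_str(v) -> Optional[str]:
    if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
        return None
    return str(v)


def record_from_row(row: dict) -> SubjectRecord:
    return SubjectRecord(
        subject_id=str(row["subject_id"]),
        group=str(row["group"]),
        age=float(row["age"]),
        gender=str(row["gender"]),
        adhd_subtype=_opt_str(row.get("adhd_subtype")),
        mph_dose_mg_per_kg=_opt_float(row.get("mph_dose_mg_per_kg")),
        prior_stimulant_6mo=_opt_bool(row.get("prior_stimulant_6mo")),
        prior_stimulant_duration=_opt_float(row.get("prior_stimulant_duration")),
        adhdrs_total_w0=_opt_int(row.get("adhdrs_total_w0")),
        adhdrs_inatt_w0=_opt_int(row.get("adhdrs_inatt_w0")),
        adhdrs_hyper_w0=_opt_int(row.get("adhdrs_hyper_w0")),
        adhdrs_total_w6=_opt_int(row.get("adhdrs_total_w6")),
        adhdrs_inatt_w6=_opt_int(row.get("adhdrs_inatt_w6")),
        adhdrs_hyper_w6=_opt_int(row.get("adhdrs_hyper_w6")),
    )


def load_cohort(
    pheno_path: str | Path, matrix_dir: str | Path, atlas: ParcellationAtlas
) -> CohortTable:
    """Load the phenotype CSV plus one matrix file per subject.

    ADHD subjects lacking week-6 scores are retained (they still enter the
    diagnostic analyses) but a warning is logged; treatment-response analyses
    pick complete cases through :meth:`CohortTable.treatment_subjects`.
    """
    pheno_path = Path(pheno_path)
    matrix_dir = Path(matrix_dir)
    df = pd.read_csv(pheno_path)
    subjects = [record_from_row(row) for row in df.to_dict("records")]
    matrices: dict[str, ConnectivityMatrix] = {}
    for s in subjects:
        candidates = [matrix_dir / f"{s.subject_id}.csv", matrix_dir / f"{s.subject_id}.tsv"]
        found = next((p for p in candidates if p.exists()), None)
        if found is None:
            raise ValidationError(f"missing matrix file for subject {s.subject_id}")
        matrices[s.subject_id] = load_matrix(found, atlas)
        if s.group == "ADHD" and not s.has_week6:
            logger.warning(
                "ADHD subject %s lacks week-6 scores; excluded from treatment analyses",
                s.subject_id,
            )
    cohort = CohortTable(subjects=subjects, matrices=matrices)
    n_adhd = len(cohort.group("ADHD"))
    n_tdc = len(cohort.group("TDC"))
    logger.info("loaded cohort: %d ADHD, %d TDC", n_adhd, n_tdc)
    return cohort


def write_cohort_phenotypes(subjects: list[SubjectRecord], path: str | Path) -> None:
    """Write the phenotype table as CSV, one row per subject."""
    rows = []
    for s in subjects:
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "age": s.age,
                "gender": s.gender,
                "adhd_subtype": s.adhd_subtype,
                "mph_dose_mg_per_kg": s.mph_dose_mg_per_kg,
                "prior_stimulant_6mo": s.prior_stimulant_6mo,
                "prior_stimulant_duration": s.prior_stimulant_duration,
                "adhdrs_total_w0": s.adhdrs_total_w0,
                "adhdrs_inatt_w0": s.adhdrs_inatt_w0,
                "adhdrs_hyper_w0": s.adhdrs_hyper_w0,
                "adhdrs_total_w6": s.adhdrs_total_w6,
                "adhdrs_inatt_w6": s.adhdrs_inatt_w6,
                "adhdrs_hyper_w6": s.adhdrs_hyper_w6,
            }
        )
    pd.DataFrame(rows, columns=_PHENO_COLUMNS).to_csv(path, index=False)
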