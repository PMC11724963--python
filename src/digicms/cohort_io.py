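"""Reading and writing of on-disk cohort artefacts.

A cohort lives in a directory holding one YAML manifest, one clinical CSV,
one feature store per slide (compressed ``.npz`` with patch coordinates and a
K x 1024 embedding matrix, emulating the output of a histology foundation
model) and optional nuclei stores (JSON in a HoverNet-style dialect, one per
detector vocabulary).  All paths in the manifest are relative to the manifest
file, so a cohort directory is relocatable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

FEATURE_DIM = 1024

#: 5-class vocabulary of a PanNuke-trained nuclei classifier.
V5 = frozenset({"neoplastic", "inflammatory", "connective", "necrosis", "non-neoplastic"})
#: 6-class vocabulary of a CoNIC-trained nuclei classifier.
V6 = frozenset({"neutrophil", "epithelial", "lymphocyte", "plasma", "eosinophil", "connective"})

VOCABULARIES: dict[str, frozenset[str]] = {"V5": V5, "V6": V6}

#: Column names of the clinical CSV.
CLINICAL_COLUMNS = [
    "patient_id", "cms_label", "dss_time", "dss_event", "dfs_time", "dfs_event",
    "hpv_type", "stage", "age", "treatment", "hiv_status",
]


class SchemaError(ValueError):
    """An on-disk artefact does not match its documented schema."""


@dataclass
class SlideEntry:
    slide_id: str
    features_path: str
    nuclei_paths: dict[str, str] = field(default_factory=dict)  # vocabulary -> path


@dataclass
class PatientEntry:
    patient_id: str
    slides: list[SlideEntry]

    @property
    def slide_ids(self) -> list[str]:
        return [s.slide_id for s in self.slides]


@dataclass
class CohortManifest:
    """One cohort: unique patients, each with >= 1 slide, plus a clinical table."""

    cohort_id: str
    patients: list[PatientEntry]
    clinical_path: str | None = None
    root: Path = field(default_factory=Path)
    #: paths referenced by the manifest that could not be resolved at load time
    missing_paths: list[str] = field(default_factory=list)
    #: patient ids present but without a CMS label in the clinical table
    unlabeled_patients: list[str] = field(default_factory=list)

    def resolve(self, relpath: str) -> Path:
        return (Path(self.root) / relpath).resolve()

    def patient(self, patient_id: str) -> PatientEntry:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)


@dataclass
class FeatureStore:
    """Patch embeddings of one slide: K coords (x, y, w, h) and a K x 1024 matrix.

    Coordinates are 0-based, half-open, in level-0 pixels; ``mpp`` is the
    microns-per-pixel of the patch plane.
    """

    slide_id: str
    coords: np.ndarray  # (K, 4) int
    features: np.ndarray  # (K, 1024) float32
    mpp: float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64)
        self.features = np.asarray(self.features, dtype=np.float32)
        if self.features.ndim != 2 or self.features.shape[1] != FEATURE_DIM:
            raise SchemaError(
                f"feature matrix of slide {self.slide_id!r} has dimension "
                f"{self.features.shape[-1] if self.features.ndim == 2 else self.features.shape}; "
                f"expected {FEATURE_DIM}"
            )
        if self.features.shape[0] < 1:
            raise SchemaError(f"feature store of slide {self.slide_id!r} is empty")
        if len(self.coords) != len(self.features):
            raise SchemaError(
                f"slide {self.slide_id!r}: {len(self.coords)} coords vs "
                f"{len(self.features)} feature rows"
            )

    @property
    def n_patches(self) -> int:
        return int(self.features.shape[0])


@dataclass
class NucleusRecord:
    """One detected nucleus: class label, contour polygon and centroid in pixels."""

    nucleus_id: int
    class_label: str
    contour: np.ndarray  # (n, 2) pixel vertices, closed implicitly
    centroid: tuple[float, float]
    mpp: float

    def __post_init__(self) -> None:
        self.contour = np.asarray(self.contour, dtype=float)


@dataclass
class NucleiStore:
    """Nuclei of one slide/region under one declared vocabulary.

    Iterable over its :class:`NucleusRecord` list; exclusion counters record
    records dropped at read time (degenerate contours, unknown labels).
    """

    vocabulary: str
    mpp: float
    records: list[NucleusRecord]
    n_excluded_degenerate: int = 0
    n_excluded_unknown: int = 0

    def __iter__(self) -> Iterator[NucleusRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def label_histogram(self) -> dict[str, int]:
        hist: dict[str, int] = {}
        for r in self.records:
            hist[r.class_label] = hist.get(r.class_label, 0) + 1
        return dict(sorted(hist.items()))


def polygon_area(contour: np.ndarray) -> float:
    """Unsigned polygon area (shoelace formula), in squared contour units."""
    c = np.asarray(contour, dtype=float)
    x, y = c[:, 0], c[:, 1]
    return abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))) / 2.0


# ---------------------------------------------------------------------------
# manifest

def load_cohort(manifest_path: str | Path) -> CohortManifest:
    """Load and validate a cohort manifest (YAML).

    Missing referenced files are recorded in ``missing_paths`` rather than
    raising; duplicate patient ids raise :class:`SchemaError`.  Patients whose
    clinical row lacks a CMS label are listed in ``unlabeled_patients``.
    """
    manifest_path = Path(manifest_path)
    try:
        raw = yaml.safe_load(manifest_path.read_text())
    except yaml.YAMLError as exc:  # pragma: no cover - message passthrough
        raise SchemaError(f"manifest {manifest_path} is not valid YAML: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise SchemaError(f"manifest {manifest_path}: top level must be a mapping")
    for key in ("cohort_id", "patients"):
        if key not in raw:
            raise SchemaError(f"manifest {manifest_path}: missing field {key!r}")

    patients: list[PatientEntry] = []
    seen: set[str] = set()
    for i, p in enumerate(raw["patients"]):
        if "patient_id" not in p:
            raise SchemaError(f"patient entry {i}: missing field 'patient_id'")
        pid = str(p["patient_id"])
        if pid in seen:
            raise SchemaError(f"duplicate patient_id {pid!r} in cohort {raw['cohort_id']!r}")
        seen.add(pid)
        slides = []
        for s in p.get("slides", []):
            if "slide_id" not in s or "features" not in s:
                raise SchemaError(f"patient {pid!r}: slide entry missing 'slide_id' or 'features'")
            slides.append(SlideEntry(
                slide_id=str(s["slide_id"]),
                features_path=str(s["features"]),
                nuclei_paths={str(k): str(v) for k, v in (s.get("nuclei") or {}).items()},
            ))
        patients.append(PatientEntry(patient_id=pid, slides=slides))

    manifest = CohortManifest(
        cohort_id=str(raw["cohort_id"]),
        patients=patients,
        clinical_path=raw.get("clinical"),
        root=manifest_path.parent,
    )
    # resolve every referenced path
    for p in manifest.patients:
        for s in p.slides:
            for rel in [s.features_path, *s.nuclei_paths.values()]:
                if not manifest.resolve(rel).exists():
                    manifest.missing_paths.append(rel)
    if manifest.clinical_path is not None:
        clin_file = manifest.resolve(manifest.clinical_path)
        if not clin_file.exists():
            manifest.missing_paths.append(manifest.clinical_path)
        else:
            clinical = read_clinical_table(clin_file)
            labelled = set(clinical.loc[clinical["cms_label"].notna(), "patient_id"])
            manifest.unlabeled_patients = [
                p.patient_id for p in manifest.patients if p.patient_id not in labelled
            ]
    return manifest


def save_cohort(manifest: CohortManifest, manifest_path: str | Path) -> Path:
    """Write the manifest as YAML; paths are kept as stored (relative)."""
    manifest_path = Path(manifest_path)
    doc = {
        "cohort_id": manifest.cohort_id,
        "clinical": manifest.clinical_path,
        "patients": [
            {
                "patient_id": p.patient_id,
                "slides": [
                    {
                        "slide_id": s.slide_id,
                        "features": s.features_path,
                        **({"nuclei": s.nuclei_paths} if s.nuclei_paths else {}),
                    }
                    for s in p.slides
                ],
            }
            for p in manifest.patients
        ],
    }
    manifest_path.parent.mkdir(parents=True, exist_ok=True)
    manifest_path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return manifest_path


# ---------------------------------------------------------------------------
# feature stores

def write_feature_store(store: FeatureStore, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path,
        slide_id=np.asarray(store.slide_id),
        coords=store.coords,
        features=store.features,
        mpp=np.asarray(store.mpp, dtype=float),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def read_feature_store(path: str | Path) -> FeatureStore:
    with np.load(Path(path), allow_pickle=False) as npz:
        for key in ("coords", "features", "mpp"):
            if key not in npz:
                raise SchemaError(f"feature store {path}: missing array {key!r}")
        return FeatureStore(
            slide_id=str(npz["slide_id"]) if "slide_id" in npz else Path(path).stem,
            coords=npz["coords"],
            features=npz["features"],
            mpp=float(npz["mpp"]),
        )


# ---------------------------------------------------------------------------
# nuclei stores

def write_nuclei_store(store: NucleiStore, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "vocabulary": store.vocabulary,
        "mpp": store.mpp,
        "nuclei": {
            str(r.nucleus_id): {
                "type": r.class_label,
                "contour": np.asarray(r.contour, dtype=float).round(3).tolist(),
                "centroid": [round(float(r.centroid[0]), 3), round(float(r.centroid[1]), 3)],
            }
            for r in store.records
        },
    }
    path.write_text(json.dumps(doc))
    return path


def read_nuclei_store(path: str | Path, vocabulary: str, strict: bool = False) -> NucleiStore:
    """Read a nuclei JSON store and validate against a declared vocabulary.

    Records with degenerate contours (< 3 vertices or zero area) are excluded
    with a warning; records whose label is outside the requested vocabulary are
    excluded (or raise, under ``strict=True``).  Exclusion counts are reported
    on the returned :class:`NucleiStore`.
    """
    if vocabulary not in VOCABULARIES:
        raise ValueError(f"unknown vocabulary {vocabulary!r}; expected one of {sorted(VOCABULARIES)}")
    allowed = VOCABULARIES[vocabulary]
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"nuclei store {path} is not valid JSON: {exc}") from exc
    if "nuclei" not in doc:
        raise SchemaError(f"nuclei store {path}: missing field 'nuclei'")
    declared = doc.get("vocabulary")
    if declared is not None and declared != vocabulary:
        raise SchemaError(
            f"nuclei store {path} declares vocabulary {declared!r}, requested {vocabulary!r}"
        )
    mpp = float(doc.get("mpp", 0.5))

    records: list[NucleusRecord] = []
    n_degenerate = n_unknown = 0
    for key, rec in doc["nuclei"].items():
        label = rec.get("type")
        if label not in allowed:
            if strict:
                raise SchemaError(f"nucleus {key}: label {label!r} not in vocabulary {vocabulary}")
            n_unknown += 1
            continue
        contour = np.asarray(rec.get("contour", []), dtype=float)
        if contour.ndim != 2 or len(contour) < 3 or polygon_area(contour) <= 0.0:
            n_degenerate += 1
            continue
        centroid = rec.get("centroid")
        if centroid is None:
            centroid = contour.mean(axis=0)
        records.append(NucleusRecord(
            nucleus_id=int(key),
            class_label=str(label),
            contour=contour,
            centroid=(float(centroid[0]), float(centroid[1])),
            mpp=mpp,
        ))
    if n_degenerate:
        warnings.warn(
            f"nuclei store {path}: excluded {n_degenerate} record(s) with degenerate contours",
            stacklevel=2,
        )
    return NucleiStore(
        vocabulary=vocabulary, mpp=mpp, records=records,
        n_excluded_degenerate=n_degenerate, n_excluded_unknown=n_unknown,
    )


# ---------------------------------------------------------------------------
# clinical tables and score tables

def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read and validate the clinical CSV.

    Required: ``patient_id``.  ``cms_label`` (0 = C1, 1 = C2) may be missing
    per patient.  Times must be >= 0 and events in {0, 1} where present.
    """
    df = pd.read_csv(path)
    if "patient_id" not in df.columns:
        raise SchemaError(f"clinical table {path}: missing column 'patient_id'")
    df["patient_id"] = df["patient_id"].astype(str)
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise SchemaError(f"clinical table {path}: duplicate patient_id {dup!r}")
    for col in CLINICAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    for col in ("dss_time", "dfs_time"):
        if (pd.to_numeric(df[col], errors="coerce").dropna() < 0).any():
            raise SchemaError(f"clinical table {path}: negative values in {col!r}")
    for col in ("dss_event", "dfs_event", "cms_label", "hiv_status"):
        vals = pd.to_numeric(df[col], errors="coerce").dropna()
        if not vals.isin([0, 1]).all():
            raise SchemaError(f"clinical table {path}: {col!r} must be 0/1")
    return df[CLINICAL_COLUMNS + [c for c in df.columns if c not in CLINICAL_COLUMNS]]


def write_clinical_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def write_score_table(scores: pd.DataFrame, path: str | Path) -> Path:
    """Write a digital-CMS score table (patient_id, cohort, score, predicted class)."""
    required = {"patient_id", "cohort", "digital_cms_score"}
    missing = required - set(scores.columns)
    if missing:
        raise SchemaError(f"score table missing columns {sorted(missing)}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    scores.to_csv(path, index=False)
    return path


def read_score_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "digital_cms_score" not in df.columns:
        raise SchemaError(f"score table {path}: missing column 'digital_cms_score'")
    df["patient_id"] = df["patient_id"].astype(str)
    return df
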