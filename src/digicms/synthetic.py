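"""Synthetic cohort generation.

Every downstream stage of the pipeline consumes outputs of external tools
(a patch-embedding foundation model, HoverNet-style nuclei detectors, a slide
scanner).  This module emulates those outputs with controllable
class-conditional structure, so the full pipeline — multiple-instance
training, survival stratification, exemplar mining, tumour-microenvironment
profiling and CD8 scoring — is testable end to end on a laptop with no slide
data:

* **feature bags** — background patches are standard normal in 1024
  dimensions; in C2 bags a known fraction of patches is shifted by
  ``effect_size`` (in units of the feature SD) along one fixed random unit
  vector.  The indices of the shifted ("signal") patches are recorded as
  ground truth, which is what lets tests verify that the learner localises
  class-informative regions.
* **survival** — exponential event times whose hazard for C2 is
  ``survival_hazard_ratio`` times the C1 baseline, with independent
  exponential censoring calibrated to the requested censoring fraction
  (closed-form expectations make test oracles exact).
* **nuclei records** — Poisson counts per cell type with class-conditional
  rates and jittered regular-polygon contours with class-conditional radius
  distributions.  The default profiles encode the directions of the tumour
  microenvironment differences between the subtypes: more lymphocytes in C1,
  a higher neutrophil ratio / NLR and larger, more variable neoplastic
  nuclei in C2.
* **IHC tiles** — haematoxylin-coloured tissue with a DAB-brown region of
  known area fraction, built by inverting the H-DAB stain matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.color import rgb_from_hdx

from .cohort_io import (
    CLINICAL_COLUMNS,
    FEATURE_DIM,
    CohortManifest,
    FeatureStore,
    NucleiStore,
    NucleusRecord,
    PatientEntry,
    SlideEntry,
    save_cohort,
    write_clinical_table,
    write_feature_store,
    write_nuclei_store,
)

__all__ = [
    "SyntheticSpec",
    "SyntheticCohort",
    "generate_cohort",
    "generate_nuclei",
    "generate_ihc_tile",
    "write_cohort",
    "DEFAULT_NUCLEI_PROFILES",
]


#: Per-class, per-vocabulary cell-type profiles.  ``density`` is the Poisson
#: rate in nuclei per square micron (tumour tissue carries a few thousand
#: nuclei per mm^2, i.e. densities of order 1e-3 um^-2); ``radius_um`` and
#: ``radius_sd_um`` parameterise the nucleus radius distribution in microns.
DEFAULT_NUCLEI_PROFILES: dict[int, dict[str, dict[str, dict[str, float]]]] = {
    0: {  # C1: higher cellularity, more lymphocytes, regular nuclei
        "V5": {
            "neoplastic": {"density": 4.0e-3, "radius_um": 3.5, "radius_sd_um": 0.4},
            "inflammatory": {"density": 1.5e-3, "radius_um": 2.5, "radius_sd_um": 0.25},
            "connective": {"density": 1.0e-3, "radius_um": 3.0, "radius_sd_um": 0.3},
            "necrosis": {"density": 1.0e-4, "radius_um": 3.0, "radius_sd_um": 0.5},
            "non-neoplastic": {"density": 5.0e-4, "radius_um": 3.0, "radius_sd_um": 0.3},
        },
        "V6": {
            "epithelial": {"density": 3.0e-3, "radius_um": 3.5, "radius_sd_um": 0.4},
            "lymphocyte": {"density": 1.2e-3, "radius_um": 2.4, "radius_sd_um": 0.2},
            "neutrophil": {"density": 1.0e-4, "radius_um": 2.6, "radius_sd_um": 0.2},
            "plasma": {"density": 3.0e-4, "radius_um": 2.8, "radius_sd_um": 0.25},
            "eosinophil": {"density": 5.0e-5, "radius_um": 2.8, "radius_sd_um": 0.25},
            "connective": {"density": 1.0e-3, "radius_um": 3.0, "radius_sd_um": 0.3},
        },
    },
    1: {  # C2: fewer immune cells, more neutrophils, pleomorphic nuclei
        "V5": {
            "neoplastic": {"density": 3.0e-3, "radius_um": 4.3, "radius_sd_um": 0.9},
            "inflammatory": {"density": 5.0e-4, "radius_um": 2.5, "radius_sd_um": 0.25},
            "connective": {"density": 1.0e-3, "radius_um": 3.0, "radius_sd_um": 0.3},
            "necrosis": {"density": 3.0e-4, "radius_um": 3.0, "radius_sd_um": 0.5},
            "non-neoplastic": {"density": 5.0e-4, "radius_um": 3.0, "radius_sd_um": 0.3},
        },
        "V6": {
            "epithelial": {"density": 3.0e-3, "radius_um": 4.3, "radius_sd_um": 0.9},
            "lymphocyte": {"density": 4.0e-4, "radius_um": 2.4, "radius_sd_um": 0.2},
            "neutrophil": {"density": 3.0e-4, "radius_um": 2.6, "radius_sd_um": 0.2},
            "plasma": {"density": 1.0e-4, "radius_um": 2.8, "radius_sd_um": 0.25},
            "eosinophil": {"density": 5.0e-5, "radius_um": 2.8, "radius_sd_um": 0.25},
            "connective": {"density": 1.0e-3, "radius_um": 3.0, "radius_sd_um": 0.3},
        },
    },
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    ``effect_size`` is the mean shift of signal patches along the latent class
    direction, in units of the per-feature SD; ``signal_fraction`` the fraction
    of patches per C2 bag carrying that shift.  ``baseline_hazard`` is the C1
    event hazard per day (default gives a median disease-specific survival of
    about five years); C2's hazard is multiplied by ``survival_hazard_ratio``.
    """

    n_patients_per_class: int = 40
    patches_per_bag: tuple[int, int] = (96, 160)
    signal_fraction: float = 0.3
    effect_size: float = 2.0
    feature_dim: int = FEATURE_DIM
    survival_hazard_ratio: float = 2.0
    censoring_rate: float = 0.3
    baseline_hazard: float = np.log(2) / 1825.0
    dfs_hazard_factor: float = 1.3
    mpp: float = 0.5
    patch_size_px: int = 256
    nuclei_profiles: Mapping[int, Mapping[str, Mapping[str, Mapping[str, float]]]] = field(
        default_factory=lambda: DEFAULT_NUCLEI_PROFILES
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.signal_fraction <= 1.0:
            raise ValueError("signal_fraction must lie in (0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.survival_hazard_ratio <= 0:
            raise ValueError("survival_hazard_ratio must be > 0")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if self.n_patients_per_class < 1:
            raise ValueError("n_patients_per_class must be >= 1")
        lo, hi = self.patches_per_bag
        if not 1 <= lo <= hi:
            raise ValueError("patches_per_bag must be a (lo, hi) range with 1 <= lo <= hi")
        for cls, vocabs in self.nuclei_profiles.items():
            for vocab, types in vocabs.items():
                for ct, pars in types.items():
                    if pars["density"] < 0:
                        raise ValueError(f"negative density for {ct!r} (class {cls}, {vocab})")


@dataclass
class SyntheticCohort:
    """In-memory synthetic cohort with its generation ground truth."""

    cohort_id: str
    spec: SyntheticSpec
    feature_stores: dict[str, FeatureStore]  # patient_id -> store (one slide/patient)
    clinical: pd.DataFrame
    #: patient_id -> indices of the patches drawn from the shifted distribution
    signal_indices: dict[str, np.ndarray]
    #: the fixed unit vector along which signal patches are shifted
    signal_direction: np.ndarray

    @property
    def patient_ids(self) -> list[str]:
        return list(self.feature_stores)

    def labels(self) -> dict[str, int]:
        return dict(zip(self.clinical["patient_id"], self.clinical["cms_label"].astype(int)))


def _signal_direction(spec: SyntheticSpec) -> np.ndarray:
    # One fixed latent axis shared by all generated cohorts, so cross-cohort
    # experiments see the same class signal in every cohort.
    rng = np.random.default_rng(987654321)
    v = rng.standard_normal(spec.feature_dim)
    return (v / np.linalg.norm(v)).astype(np.float64)


def generate_cohort(spec: SyntheticSpec, cohort_id: str = "synth") -> SyntheticCohort:
    """Generate one cohort of labelled feature bags plus a clinical table.

    Deterministic given ``spec.seed``.  C1 bags are pure background noise;
    each C2 bag has ``ceil(signal_fraction * K)`` patches shifted by
    ``effect_size`` along the latent direction, with their indices recorded.
    """
    rng = np.random.default_rng(spec.seed)
    direction = _signal_direction(spec)
    lo, hi = spec.patches_per_bag

    stores: dict[str, FeatureStore] = {}
    signal_indices: dict[str, np.ndarray] = {}
    rows = []
    for label in (0, 1):
        for i in range(spec.n_patients_per_class):
            pid = f"{cohort_id}-{'C1' if label == 0 else 'C2'}-{i:03d}"
            k = int(rng.integers(lo, hi + 1))
            feats = rng.standard_normal((k, spec.feature_dim))
            if label == 1:
                n_sig = max(1, int(np.ceil(spec.signal_fraction * k)))
                sig_idx = rng.choice(k, size=n_sig, replace=False)
                feats[sig_idx] += spec.effect_size * direction
            else:
                sig_idx = np.empty(0, dtype=np.int64)
            signal_indices[pid] = np.sort(sig_idx)
            # lay patches on a square-ish non-overlapping grid
            ncol = int(np.ceil(np.sqrt(k)))
            idx = np.arange(k)
            coords = np.stack(
                [
                    (idx % ncol) * spec.patch_size_px,
                    (idx // ncol) * spec.patch_size_px,
                    np.full(k, spec.patch_size_px),
                    np.full(k, spec.patch_size_px),
                ],
                axis=1,
            )
            stores[pid] = FeatureStore(
                slide_id=f"{pid}-S1", coords=coords,
                features=feats.astype(np.float32), mpp=spec.mpp,
            )
            rows.append(_clinical_row(pid, label, spec, rng))
    clinical = pd.DataFrame(rows, columns=CLINICAL_COLUMNS)
    clinical["cohort"] = cohort_id
    return SyntheticCohort(
        cohort_id=cohort_id, spec=spec, feature_stores=stores,
        clinical=clinical, signal_indices=signal_indices, signal_direction=direction,
    )


def _survival_pair(hazard: float, censoring_rate: float, rng: np.random.Generator) -> tuple[float, int]:
    event_time = rng.exponential(1.0 / hazard)
    if censoring_rate == 0.0:
        return float(event_time), 1
    # independent exponential censoring with P(censored) = censoring_rate
    cens_hazard = hazard * censoring_rate / (1.0 - censoring_rate)
    cens_time = rng.exponential(1.0 / cens_hazard)
    if event_time <= cens_time:
        return float(event_time), 1
    return float(cens_time), 0


def _clinical_row(pid: str, label: int, spec: SyntheticSpec, rng: np.random.Generator) -> dict:
    haz = spec.baseline_hazard * (spec.survival_hazard_ratio if label == 1 else 1.0)
    dss_time, dss_event = _survival_pair(haz, spec.censoring_rate, rng)
    dfs_time, dfs_event = _survival_pair(haz * spec.dfs_hazard_factor, spec.censoring_rate, rng)
    return {
        "patient_id": pid,
        "cms_label": label,
        "dss_time": round(dss_time, 1),
        "dss_event": dss_event,
        "dfs_time": round(dfs_time, 1),
        "dfs_event": dfs_event,
        "hpv_type": rng.choice(["HPV16", "HPV18", "other"], p=[0.6, 0.2, 0.2]),
        "stage": rng.choice(["I", "II", "III", "IV"], p=[0.35, 0.3, 0.25, 0.1]),
        "age": int(np.clip(rng.normal(50, 11), 21, 85)),
        "treatment": rng.choice(["surgery", "RT", "CRT"], p=[0.3, 0.3, 0.4]),
        "hiv_status": int(rng.random() < 0.1),
    }


# ---------------------------------------------------------------------------
# nuclei

def _polygon_contour(cx: float, cy: float, radius_px: float, rng: np.random.Generator,
                     n_vertices: int = 12, jitter: float = 0.12) -> np.ndarray:
    angles = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    radii = radius_px * (1.0 + jitter * rng.uniform(-1.0, 1.0, n_vertices))
    radii = np.maximum(radii, 0.3)
    return np.stack([cx + radii * np.cos(angles), cy + radii * np.sin(angles)], axis=1)


def generate_nuclei(
    spec: SyntheticSpec,
    class_label: int,
    vocabulary: str,
    region_size_px: tuple[int, int] = (256, 256),
    mpp: float | None = None,
    rng: np.random.Generator | None = None,
) -> NucleiStore:
    """Generate detector-style nuclei records for one region of one class.

    Counts per cell type are Poisson with the class-conditional density of the
    spec's profile; contours are 12-gons with per-vertex radius jitter around a
    truncated-normal radius.  Centroids are unique (duplicates are re-jittered).
    """
    w, h = region_size_px
    if w <= 0 or h <= 0:
        raise ValueError("region dimensions must be positive")
    mpp = spec.mpp if mpp is None else mpp
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    profile = spec.nuclei_profiles[class_label][vocabulary]
    area_um2 = w * h * mpp * mpp

    records: list[NucleusRecord] = []
    seen: set[tuple[float, float]] = set()
    nid = 0
    for cell_type, pars in profile.items():
        n = int(rng.poisson(pars["density"] * area_um2))
        for _ in range(n):
            cx, cy = rng.uniform(0, w), rng.uniform(0, h)
            while (round(cx, 3), round(cy, 3)) in seen:
                cx, cy = rng.uniform(0, w), rng.uniform(0, h)
            seen.add((round(cx, 3), round(cy, 3)))
            radius_um = max(float(rng.normal(pars["radius_um"], pars["radius_sd_um"])), 0.5)
            contour = _polygon_contour(cx, cy, radius_um / mpp, rng)
            records.append(NucleusRecord(
                nucleus_id=nid, class_label=cell_type, contour=contour,
                centroid=(cx, cy), mpp=mpp,
            ))
            nid += 1
    return NucleiStore(vocabulary=vocabulary, mpp=mpp, records=records)


# ---------------------------------------------------------------------------
# IHC tiles

# Stain concentrations in OD10 units: every tissue pixel carries haematoxylin;
# positive pixels add a strong DAB component (well above the 0.15 OD default
# segmentation threshold).
_HEMA_C = 0.6
_DAB_C = 0.9


def generate_ihc_tile(
    positive_fraction: float,
    size_px: int = 256,
    rng: np.random.Generator | None = None,
    noise: float = 0.03,
) -> tuple[np.ndarray, float]:
    """Synthetic CD8 IHC tile: haematoxylin tissue with a DAB-positive band.

    Returns ``(rgb uint8 image, achieved_fraction)`` where the achieved
    fraction is the exact share of tissue pixels painted with DAB (it can
    differ from the request by pixel quantisation only).
    """
    if not 0.0 <= positive_fraction <= 1.0:
        raise ValueError("positive_fraction must lie in [0, 1]")
    rng = np.random.default_rng(0) if rng is None else rng
    n_pos_rows = int(round(positive_fraction * size_px))
    stains = np.zeros((size_px, size_px, 3))
    stains[..., 0] = _HEMA_C * (1.0 + noise * rng.standard_normal((size_px, size_px)))
    stains[:n_pos_rows, :, 1] = _DAB_C * (
        1.0 + noise * rng.standard_normal((n_pos_rows, size_px))
    )
    od = stains @ rgb_from_hdx
    rgb = np.clip(np.power(10.0, -od), 0.0, 1.0)
    image = (rgb * 255.0).round().astype(np.uint8)
    return image, n_pos_rows / size_px


# ---------------------------------------------------------------------------
# on-disk emission

def write_cohort(cohort: SyntheticCohort, outdir: str | Path,
                 nuclei_regions: bool = False) -> Path:
    """Write a synthetic cohort as a runnable cohort directory.

    Emits one feature store per patient, the clinical CSV and the YAML
    manifest; with ``nuclei_regions=True`` also one V5 + one V6 nuclei store
    per patient.  Returns the manifest path.
    """
    outdir = Path(outdir)
    (outdir / "features").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cohort.spec.seed + 1)
    labels = cohort.labels()

    patients = []
    for pid, store in cohort.feature_stores.items():
        rel_feat = f"features/{pid}.npz"
        write_feature_store(store, outdir / rel_feat)
        nuclei_paths = {}
        if nuclei_regions:
            for vocab in ("V5", "V6"):
                rel_nuc = f"nuclei/{pid}.{vocab}.json"
                ns = generate_nuclei(cohort.spec, labels[pid], vocab, rng=rng)
                write_nuclei_store(ns, outdir / rel_nuc)
                nuclei_paths[vocab] = rel_nuc
        patients.append(PatientEntry(
            patient_id=pid,
            slides=[SlideEntry(slide_id=store.slide_id, features_path=rel_feat,
                               nuclei_paths=nuclei_paths)],
        ))
    write_clinical_table(cohort.clinical, outdir / "clinical.csv")
    manifest = CohortManifest(
        cohort_id=cohort.cohort_id, patients=patients,
        clinical_path="clinical.csv", root=outdir,
    )
    return save_cohort(manifest, outdir / "manifest.yaml")


def spec_for_seed(spec: SyntheticSpec, seed: int) -> SyntheticSpec:
    """The same study conditions under a different random seed."""
    return replace(spec, seed=seed)
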