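"""Tumour-microenvironment profiling from nuclei-detection records.

Given per-region nuclei records (class label + contour polygon at a known
resolution), this module computes cellular-composition and morphology
features and the group statistics used to contrast the two molecular
subtypes:

* per cell type: count N, density rho = N / A with the region area A in
  square microns, ln density, and the ratio of the type among all detected
  cells;
* the neutrophil-to-lymphocyte ratio (NLR) from the 6-class vocabulary;
* per-nucleus morphology (polygon area in um^2 via the shoelace formula,
  perimeter in um via summed edge lengths) summarised as mean/median/SD per
  type;
* lymphocyte density restricted to tumour-rich regions (128 x 128 um^2
  patches holding more than 50 neoplastic nuclei);
* C1-vs-C2 comparisons: Welch two-tailed t-test, Mann-Whitney U, Cliff's
  delta, Benjamini-Hochberg correction across the feature family;
* Spearman correlation of a biological feature with the digital-CMS score;
* CD8+ IHC scoring: H-DAB colour deconvolution, threshold segmentation of
  the DAB channel, positive-area fraction over the tissue mask.

Missing-value policy: ln density with zero cells, NLR with zero lymphocytes
and morphology of an absent cell type are *missing* (NaN), never zero or
infinity — samples lacking a cell type drop out of that feature's test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage.color import hdx_from_rgb, separate_stains
from statsmodels.stats.multitest import multipletests

from .cohort_io import VOCABULARIES, NucleusRecord
from .preprocess import compute_tissue_mask

__all__ = [
    "RegionProfile",
    "profile_region",
    "profiles_to_frame",
    "tumour_rich_lymphocyte_density",
    "compare_groups",
    "cliffs_delta",
    "bh_adjust",
    "correlate_scores",
    "cd8_area_fraction",
]


def polygon_area_um2(contour: np.ndarray, mpp: float) -> float:
    """Unsigned shoelace area of a pixel-space polygon, in square microns."""
    c = np.asarray(contour, dtype=float)
    x, y = c[:, 0], c[:, 1]
    return abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))) / 2.0 * mpp * mpp


def polygon_perimeter_um(contour: np.ndarray, mpp: float) -> float:
    """Closed-polygon perimeter (summed edge lengths), in microns."""
    c = np.asarray(contour, dtype=float)
    return float(np.linalg.norm(np.roll(c, -1, axis=0) - c, axis=1).sum()) * mpp


@dataclass
class RegionProfile:
    """Cellular composition and morphology of one region under one vocabulary."""

    region_id: str
    vocabulary: str
    area_um2: float
    counts: dict[str, int]
    density: dict[str, float]  # um^-2, exactly N / area
    ln_density: dict[str, float]  # NaN when N = 0
    ratio: dict[str, float]  # NaN when total = 0
    nlr: float  # NaN unless V6 with lymphocytes present
    morphology: dict[str, dict[str, float]]  # type -> stat name -> value (um / um^2)

    def features(self) -> dict[str, float]:
        """Flat feature dictionary for group comparisons."""
        out: dict[str, float] = {}
        for ct in self.counts:
            out[f"{ct}_density"] = self.density[ct]
            out[f"{ct}_ln_density"] = self.ln_density[ct]
            out[f"{ct}_ratio"] = self.ratio[ct]
            for stat_name, value in self.morphology[ct].items():
                out[f"{ct}_{stat_name}"] = value
        if self.vocabulary == "V6":
            out["nlr"] = self.nlr
        return out


_MORPH_STATS = ("area_mean", "area_median", "area_sd", "perimeter_mean",
                "perimeter_median", "perimeter_sd")


def profile_region(
    nuclei: Iterable[NucleusRecord],
    region_area_px: float,
    mpp: float,
    vocabulary: str,
    region_id: str = "region",
) -> RegionProfile:
    """Compute the composition/morphology profile of one region.

    ``region_area_px`` is the region area in pixels at resolution ``mpp``;
    all records must share that resolution and belong to the declared
    vocabulary (mixing vocabularies in one call is an error).
    """
    if region_area_px <= 0:
        raise ValueError("region area must be positive")
    allowed = VOCABULARIES[vocabulary]
    area_um2 = float(region_area_px) * mpp * mpp

    by_type: dict[str, list[NucleusRecord]] = {ct: [] for ct in sorted(allowed)}
    for rec in nuclei:
        if rec.class_label not in allowed:
            raise ValueError(
                f"nucleus {rec.nucleus_id} has label {rec.class_label!r} outside "
                f"vocabulary {vocabulary}: vocabularies must not be mixed"
            )
        if abs(rec.mpp - mpp) > 1e-9:
            raise ValueError("inconsistent mpp across nucleus records")
        by_type[rec.class_label].append(rec)

    counts = {ct: len(records) for ct, records in by_type.items()}
    total = sum(counts.values())
    density = {ct: n / area_um2 for ct, n in counts.items()}
    ln_density = {ct: (np.log(d) if counts[ct] > 0 else np.nan) for ct, d in density.items()}
    ratio = {ct: (n / total if total > 0 else np.nan) for ct, n in counts.items()}

    morphology: dict[str, dict[str, float]] = {}
    for ct, records in by_type.items():
        if not records:
            morphology[ct] = {s: np.nan for s in _MORPH_STATS}
            continue
        areas = np.array([polygon_area_um2(r.contour, r.mpp) for r in records])
        perims = np.array([polygon_perimeter_um(r.contour, r.mpp) for r in records])
        morphology[ct] = {
            "area_mean": float(areas.mean()),
            "area_median": float(np.median(areas)),
            "area_sd": float(areas.std(ddof=1)) if len(areas) > 1 else np.nan,
            "perimeter_mean": float(perims.mean()),
            "perimeter_median": float(np.median(perims)),
            "perimeter_sd": float(perims.std(ddof=1)) if len(perims) > 1 else np.nan,
        }

    if vocabulary == "V6" and counts.get("lymphocyte", 0) > 0:
        nlr = counts.get("neutrophil", 0) / counts["lymphocyte"]
    else:
        nlr = np.nan
    return RegionProfile(
        region_id=region_id, vocabulary=vocabulary, area_um2=area_um2,
        counts=counts, density=density, ln_density=ln_density,
        ratio=ratio, nlr=float(nlr), morphology=morphology,
    )


def profiles_to_frame(profiles: Sequence[RegionProfile]) -> pd.DataFrame:
    """One row per region, one column per flat feature."""
    rows = [{"region_id": p.region_id, **p.features()} for p in profiles]
    return pd.DataFrame(rows).set_index("region_id")


# ---------------------------------------------------------------------------
# tumour-rich lymphocyte density

TUMOUR_RICH_PATCH_UM = 128.0
TUMOUR_RICH_MIN_NEOPLASTIC = 50


def tumour_rich_lymphocyte_density(
    neoplastic_nuclei: Iterable[NucleusRecord],
    lymphocyte_nuclei: Iterable[NucleusRecord],
    mpp: float,
    patch_um: float = TUMOUR_RICH_PATCH_UM,
    min_neoplastic: int = TUMOUR_RICH_MIN_NEOPLASTIC,
) -> float:
    """ln lymphocyte density pooled over tumour-rich patches; NaN if none.

    Nuclei from the 5-class detector (neoplastic) and the 6-class detector
    (lymphocyte) are joined spatially onto a ``patch_um`` x ``patch_um``
    grid by centroid membership (half-open bins).  A patch qualifies as
    tumour-rich when it holds strictly more than ``min_neoplastic``
    neoplastic nuclei; the returned value is ln of (total lymphocytes in
    qualifying patches) / (qualifying patch count x patch area).  Zero
    qualifying patches — or zero lymphocytes within them — yield NaN
    (a missing value, never zero).
    """

    def bins(records: Iterable[NucleusRecord]) -> dict[tuple[int, int], int]:
        acc: dict[tuple[int, int], int] = {}
        for r in records:
            key = (int(r.centroid[0] * mpp // patch_um), int(r.centroid[1] * mpp // patch_um))
            acc[key] = acc.get(key, 0) + 1
        return acc

    neo = bins(neoplastic_nuclei)
    lym = bins(lymphocyte_nuclei)
    qualifying = [key for key, n in neo.items() if n > min_neoplastic]
    if not qualifying:
        return float("nan")
    n_lym = sum(lym.get(key, 0) for key in qualifying)
    if n_lym == 0:
        return float("nan")
    density = n_lym / (len(qualifying) * patch_um * patch_um)
    return float(np.log(density))


# ---------------------------------------------------------------------------
# group statistics

def cliffs_delta(x, y) -> float:
    """Cliff's delta = (#(x > y) - #(x < y)) / (n_x * n_y), in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("Cliff's delta needs non-empty samples")
    # O((n+m) log m): per x, count y's strictly below / strictly above
    ys = np.sort(y)
    greater = np.searchsorted(ys, x, side="left").sum()
    less = (len(y) - np.searchsorted(ys, x, side="right")).sum()
    return float((greater - less) / (len(x) * len(y)))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def compare_groups(
    profiles_c1: pd.DataFrame | Sequence[RegionProfile],
    profiles_c2: pd.DataFrame | Sequence[RegionProfile],
    features: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature C1-vs-C2 comparison with multiple-testing correction.

    Per feature: Welch two-tailed t-test, Mann-Whitney U (normal
    approximation with tie correction), Cliff's delta (positive = larger in
    C1), then Benjamini-Hochberg across the tested features separately for
    the t and U p-values.  ``significant`` flags BH-adjusted t-test p below
    ``alpha``.  Missing values are dropped per feature; features with fewer
    than two non-missing values in either group are reported untestable.
    """
    df1 = profiles_c1 if isinstance(profiles_c1, pd.DataFrame) else profiles_to_frame(profiles_c1)
    df2 = profiles_c2 if isinstance(profiles_c2, pd.DataFrame) else profiles_to_frame(profiles_c2)
    if features is None:
        features = [c for c in df1.columns if c in df2.columns and c != "region_id"]

    rows = []
    for feat in features:
        x = df1[feat].dropna().to_numpy(dtype=float) if feat in df1 else np.empty(0)
        y = df2[feat].dropna().to_numpy(dtype=float) if feat in df2 else np.empty(0)
        row: dict = {
            "feature": feat,
            "n_c1": len(x), "n_c2": len(y),
            "mean_c1": x.mean() if len(x) else np.nan,
            "mean_c2": y.mean() if len(y) else np.nan,
            "median_c1": np.median(x) if len(x) else np.nan,
            "median_c2": np.median(y) if len(y) else np.nan,
        }
        if len(x) < 2 or len(y) < 2:
            row.update(testable=False, t=np.nan, t_p=np.nan, mwu=np.nan,
                       mwu_p=np.nan, cliffs_delta=np.nan)
        else:
            t_stat, t_p = stats.ttest_ind(x, y, equal_var=False)
            if np.ptp(np.concatenate([x, y])) == 0:
                # identical constant groups: no evidence of difference
                t_stat, t_p = 0.0, 1.0
                u_stat, u_p = len(x) * len(y) / 2.0, 1.0
            else:
                u_stat, u_p = stats.mannwhitneyu(x, y, alternative="two-sided",
                                                 method="asymptotic")
            row.update(testable=True, t=float(t_stat), t_p=float(t_p),
                       mwu=float(u_stat), mwu_p=float(u_p),
                       cliffs_delta=cliffs_delta(x, y))
        rows.append(row)
    out = pd.DataFrame(rows)
    testable = out["testable"].fillna(False).to_numpy(dtype=bool)
    out["t_p_adj"] = np.nan
    out["mwu_p_adj"] = np.nan
    if testable.any():
        out.loc[testable, "t_p_adj"] = bh_adjust(out.loc[testable, "t_p"])
        out.loc[testable, "mwu_p_adj"] = bh_adjust(out.loc[testable, "mwu_p"])
    out["significant"] = out["t_p_adj"] < alpha
    return out


def correlate_scores(digital_cms_scores, feature_values) -> dict[str, float]:
    """Spearman correlation of a biological feature with the digital-CMS score.

    Pairs with a missing value on either side are dropped; returns
    ``{"rho", "p", "n"}`` with NaN rho/p when either vector is constant.
    """
    x = np.asarray(digital_cms_scores, dtype=float)
    y = np.asarray(feature_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors required")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        raise ValueError(f"Spearman correlation needs >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"rho": float("nan"), "p": float("nan"), "n": n}
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p), "n": n}


# ---------------------------------------------------------------------------
# CD8+ IHC scoring

#: skimage's separate_stains works on a ln(1e-6) basis; this factor converts
#: its output back to optical density in log10 units.
_OD10_RESCALE = -np.log(1e-6) / np.log(10.0)

DAB_OD_THRESHOLD = 0.15


def cd8_area_fraction(
    rgb_image: np.ndarray,
    dab_threshold: float = DAB_OD_THRESHOLD,
    tissue_mask: np.ndarray | None = None,
) -> float:
    """CD8-positive area fraction of an H-DAB-stained IHC tile.

    The image is colour-deconvolved with the standard H-DAB stain vectors,
    the DAB channel (in OD10 units) is thresholded at ``dab_threshold``, and
    the fraction of DAB-positive pixels over tissue pixels is returned.  The
    tissue mask defaults to :func:`digicms.preprocess.compute_tissue_mask`;
    an empty mask is an error (no denominator).
    """
    img = np.asarray(rgb_image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {img.shape}")
    if tissue_mask is None:
        tissue_mask = compute_tissue_mask(img)
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if not tissue_mask.any():
        raise ValueError("empty tissue mask: CD8 area fraction undefined")
    imgf = img.astype(np.float64) / 255.0 if img.dtype != np.float64 else img
    dab = separate_stains(imgf, hdx_from_rgb)[..., 1] * _OD10_RESCALE
    positive = (dab > dab_threshold) & tissue_mask
    return float(positive.sum() / tissue_mask.sum())
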