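"""Histogram, GLCM texture and volumetric features per habitat ROI.

For each of the ten habitat ROIs and each of the six maps (post-contrast T1w,
T2w, MD, FA, relative CBV and CBF) the extractor computes four first-order
histogram statistics (mean, sample SD, moment skewness g1, excess kurtosis
g2) and four gray-level co-occurrence matrix (GLCM) texture features
(contrast, correlation, energy, homogeneity), giving the fused
10 x 6 x 8 = 480-column cohort feature table.

GLCM convention: ROI intensities are quantized to 32 equal-width gray levels
over the ROI's own range; co-occurrences are accumulated over all axial
slices and four in-plane unit offsets, with both pixels required inside the
ROI, counted symmetrically (each pair in both directions), pooled into a
single matrix and normalized to sum 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .habitats import ROICatalog, ROI_NAMES, normalize_rcbv
from .phantom import SubjectVolumes

#: maps as they enter the feature table (CBV enters NAWM-normalized)
FEATURE_MAP_NAMES: Tuple[str, ...] = ("t1c", "t2", "md", "fa", "rcbv", "cbf")

FEATURE_KINDS: Tuple[str, ...] = (
    "mean", "sd", "skewness", "kurtosis",
    "glcm_contrast", "glcm_correlation", "glcm_energy", "glcm_homogeneity",
)

DEFAULT_OFFSETS: Tuple[Tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))
DEFAULT_N_LEVELS = 32

#: number of columns of the default fused feature table
N_FEATURES = len(ROI_NAMES) * len(FEATURE_MAP_NAMES) * len(FEATURE_KINDS)


class RadiomicsError(RuntimeError):
    pass


@dataclass(frozen=True)
class HistogramStats:
    mean: float
    sd: float
    skewness: float
    kurtosis: float


@dataclass(frozen=True)
class GlcmFeatures:
    contrast: float
    correlation: float
    energy: float
    homogeneity: float


@dataclass
class RadiomicsConfig:
    n_levels: int = DEFAULT_N_LEVELS
    offsets: Tuple[Tuple[int, int], ...] = DEFAULT_OFFSETS


def feature_names() -> List[str]:
    """The 480 canonical column names, ``{roi}__{map}__{feature}``."""
    return [f"{roi}__{m}__{k}" for roi in ROI_NAMES
            for m in FEATURE_MAP_NAMES for k in FEATURE_KINDS]


def histogram_stats(values: Sequence[float]) -> HistogramStats:
    """First-order statistics of a voxel sample.

    SD is the sample SD (n-1); skewness and kurtosis are the moment
    coefficients g1 = m3/m2^1.5 and g2 = m4/m2^2 - 3 built from biased
    central moments.  With fewer than 3 voxels or zero variance the shape
    statistics are NaN (imputed downstream); an empty sample is all-NaN.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    n = v.size
    if n == 0:
        return HistogramStats(np.nan, np.nan, np.nan, np.nan)
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if n >= 2 else np.nan
    c = v - mean
    m2 = float(np.mean(c ** 2))
    if n < 3 or m2 <= 0:
        return HistogramStats(mean, sd, np.nan, np.nan)
    g1 = float(np.mean(c ** 3)) / m2 ** 1.5
    g2 = float(np.mean(c ** 4)) / m2 ** 2 - 3.0
    return HistogramStats(mean, sd, g1, g2)


def quantize_roi(values: Sequence[float], n_levels: int = DEFAULT_N_LEVELS,
                 ) -> np.ndarray:
    """Quantize a voxel sample to integer levels ``1..n_levels`` using
    equal-width bins over the sample's own [min, max]; a degenerate range
    maps every voxel to level 1."""
    if n_levels < 2:
        raise RadiomicsError("n_levels must be >= 2")
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise RadiomicsError("cannot quantize an empty sample")
    vmin, vmax = float(v.min()), float(v.max())
    if vmax <= vmin:
        return np.ones(v.shape, dtype=np.int64)
    idx = ((v - vmin) / (vmax - vmin) * n_levels).astype(np.int64)
    idx[idx == n_levels] = n_levels - 1
    return idx + 1


def glcm_matrix(levels: np.ndarray, mask: np.ndarray, n_levels: int,
                offsets: Sequence[Tuple[int, int]] = DEFAULT_OFFSETS,
                ) -> Optional[np.ndarray]:
    """Pooled symmetric normalized co-occurrence matrix.

    ``levels`` holds gray levels 1..n_levels wherever ``mask`` is True; the
    array is 2-D (one slice) or 3-D, in which case axes (0, 1) are in-plane
    and pairs are accumulated over every slice along axis 2.  Returns None if
    no valid in-mask pair exists for any offset.
    """
    if levels.shape != mask.shape:
        raise RadiomicsError("levels and mask shapes differ")
    lv = np.asarray(levels, dtype=np.int64)
    if lv.ndim == 2:
        lv = lv[:, :, None]
        mask = mask[:, :, None]
    counts = np.zeros(n_levels * n_levels, dtype=np.float64)
    nr, nc = lv.shape[0], lv.shape[1]
    for dr, dc in offsets:
        if abs(dr) >= nr or abs(dc) >= nc:
            continue
        r0a, r1a = max(0, -dr), min(nr, nr - dr)
        c0a, c1a = max(0, -dc), min(nc, nc - dc)
        a = lv[r0a:r1a, c0a:c1a, :]
        b = lv[r0a + dr:r1a + dr, c0a + dc:c1a + dc, :]
        ma = mask[r0a:r1a, c0a:c1a, :]
        mb = mask[r0a + dr:r1a + dr, c0a + dc:c1a + dc, :]
        valid = ma & mb
        if not valid.any():
            continue
        i = a[valid] - 1
        j = b[valid] - 1
        counts += np.bincount(i * n_levels + j,
                              minlength=n_levels * n_levels)
        counts += np.bincount(j * n_levels + i,
                              minlength=n_levels * n_levels)
    total = counts.sum()
    if total == 0:
        return None
    return (counts / total).reshape(n_levels, n_levels)


def glcm_features(levels: np.ndarray, mask: np.ndarray, n_levels: int,
                  offsets: Sequence[Tuple[int, int]] = DEFAULT_OFFSETS,
                  ) -> GlcmFeatures:
    """Contrast, correlation, energy and homogeneity of the pooled GLCM.

    When either marginal SD is zero the correlation is defined as 0; with no
    valid pixel pair at all, every feature is NaN.
    """
    p = glcm_matrix(levels, mask, n_levels, offsets)
    if p is None:
        return GlcmFeatures(np.nan, np.nan, np.nan, np.nan)
    idx = np.arange(1, n_levels + 1, dtype=np.float64)
    ii = idx[:, None]
    jj = idx[None, :]
    contrast = float(np.sum(p * (ii - jj) ** 2))
    energy = float(np.sum(p ** 2))
    homogeneity = float(np.sum(p / (1.0 + np.abs(ii - jj))))
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float(np.sum(idx * pi))
    mu_j = float(np.sum(idx * pj))
    var_i = float(np.sum(pi * (idx - mu_i) ** 2))
    var_j = float(np.sum(pj * (idx - mu_j) ** 2))
    if var_i * var_j <= 0:
        corr = 0.0
    else:
        corr = float(np.sum(p * (ii - mu_i) * (jj - mu_j))
                     / np.sqrt(var_i * var_j))
    return GlcmFeatures(contrast, corr, energy, homogeneity)


def roi_volumes(catalog: ROICatalog, tumor_mask: np.ndarray,
                voxel_size: Sequence[float]) -> pd.DataFrame:
    """Absolute (cm^3) and relative (fraction of tumor) ROI volumes.

    Includes a ``tumor`` row and the whole-tumor low-diffusivity
    low-perfusion habitat (``lmd_lrcbv`` = LMD ∩ LrCBV), the quantity the
    published group comparison reports.
    """
    n_tumor = int(tumor_mask.sum())
    if n_tumor == 0:
        raise RadiomicsError("empty tumor mask")
    voxel_cm3 = float(np.prod(voxel_size)) / 1000.0
    tumor_cm3 = n_tumor * voxel_cm3
    rows = {}
    for name in ROI_NAMES:
        cm3 = int(catalog.masks[name].sum()) * voxel_cm3
        rows[name] = (cm3, cm3 / tumor_cm3)
    ll = int((catalog.masks["LMD"] & catalog.masks["LrCBV"]).sum()) * voxel_cm3
    rows["lmd_lrcbv"] = (ll, ll / tumor_cm3)
    rows["tumor"] = (tumor_cm3, 1.0)
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=["absolute_cm3", "relative"])


def _bbox(mask: np.ndarray) -> Tuple[slice, slice, slice]:
    idx = np.argwhere(mask)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    return tuple(slice(l, h) for l, h in zip(lo, hi))


def extract_subject_features(volumes: SubjectVolumes, catalog: ROICatalog,
                             config: Optional[RadiomicsConfig] = None,
                             ) -> pd.Series:
    """One subject's fused feature vector (480 named values).

    Empty ROIs yield NaN for their 48 features; those are imputed at cohort
    assembly time.
    """
    config = config or RadiomicsConfig()
    missing_maps = [m for m in ("t1c", "t2", "md", "fa", "cbv", "cbf")
                    if m not in volumes.maps]
    if missing_maps:
        raise RadiomicsError(f"missing maps: {', '.join(missing_maps)}")
    missing_rois = [r for r in ROI_NAMES if r not in catalog.masks]
    if missing_rois:
        raise RadiomicsError(f"missing ROIs: {', '.join(missing_rois)}")

    fmaps = {m: np.asarray(volumes.maps[m], dtype=np.float64)
             for m in ("t1c", "t2", "md", "fa", "cbf")}
    fmaps["rcbv"] = normalize_rcbv(volumes.maps["cbv"], volumes.nawm_mask)

    out: Dict[str, float] = {}
    for roi in ROI_NAMES:
        mask = catalog.masks[roi]
        empty = not mask.any()
        box = None if empty else _bbox(mask)
        for m in FEATURE_MAP_NAMES:
            prefix = f"{roi}__{m}__"
            if empty:
                for k in FEATURE_KINDS:
                    out[prefix + k] = np.nan
                continue
            arr = fmaps[m]
            vals = arr[mask]
            hs = histogram_stats(vals)
            out[prefix + "mean"] = hs.mean
            out[prefix + "sd"] = hs.sd
            out[prefix + "skewness"] = hs.skewness
            out[prefix + "kurtosis"] = hs.kurtosis
            sub_mask = mask[box]
            levels = np.zeros(sub_mask.shape, dtype=np.int64)
            levels[sub_mask] = quantize_roi(vals, config.n_levels)
            gf = glcm_features(levels, sub_mask, config.n_levels,
                               config.offsets)
            out[prefix + "glcm_contrast"] = gf.contrast
            out[prefix + "glcm_correlation"] = gf.correlation
            out[prefix + "glcm_energy"] = gf.energy
            out[prefix + "glcm_homogeneity"] = gf.homogeneity
    return pd.Series(out, index=feature_names(), dtype=np.float64)


@dataclass
class FeatureTable:
    """Cohort feature matrix plus survival labels.

    ``features`` is the cohort-imputed, column-standardized matrix written to
    disk; ``raw`` keeps the pre-imputation values so cross-validation can
    refit imputation and standardization on training folds only.
    """

    features: pd.DataFrame
    raw: pd.DataFrame
    labels: pd.Series
    provenance: Dict[str, object] = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def y01(self, positive: str = "short") -> np.ndarray:
        """Binary labels with the clinically urgent class as positive."""
        return (self.labels.to_numpy() == positive).astype(np.int64)

    def to_csv(self, path) -> None:
        df = self.features.copy()
        df["label"] = self.labels.to_numpy()
        df.to_csv(path, index_label="subject_id", float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, index_col="subject_id")
        labels = df.pop("label")
        return cls(features=df, raw=df.copy(), labels=labels,
                   provenance={"source": str(path)})


def assemble_feature_table(vectors: Sequence[pd.Series],
                           labels: Sequence[str],
                           subject_ids: Optional[Sequence[str]] = None,
                           provenance: Optional[Dict[str, object]] = None,
                           ) -> FeatureTable:
    """Fuse per-subject vectors into the cohort table.

    Missing cells are imputed by the per-column cohort median; columns that
    are missing for every subject are dropped with a warning; every surviving
    column is then z-scored (mean 0, SD 1 over the cohort).
    """
    if len(vectors) != len(labels):
        raise RadiomicsError("one label per subject is required")
    if any(lb is None or (isinstance(lb, float) and np.isnan(lb))
           for lb in labels):
        raise RadiomicsError("every subject needs a survival label")
    classes = sorted(set(labels))
    if len(classes) > 2:
        raise RadiomicsError(f"labels must be binary, got {classes}")
    names = list(vectors[0].index)
    for v in vectors[1:]:
        if list(v.index) != names:
            raise RadiomicsError("feature vectors have inconsistent names")
    if subject_ids is None:
        subject_ids = [f"S{i + 1:03d}" for i in range(len(vectors))]
    raw = pd.DataFrame([v.to_numpy() for v in vectors], columns=names,
                       index=list(subject_ids))
    all_nan = raw.columns[raw.isna().all(axis=0)]
    if len(all_nan):
        warnings.warn(
            f"dropping {len(all_nan)} all-missing feature columns",
            stacklevel=2)
        raw = raw.drop(columns=all_nan)
    filled = raw.fillna(raw.median())
    mean = filled.mean(axis=0)
    sd = filled.std(axis=0, ddof=0).replace(0.0, 1.0)
    features = (filled - mean) / sd
    return FeatureTable(features=features, raw=raw,
                        labels=pd.Series(list(labels), index=raw.index,
                                         name="label"),
                        provenance=dict(provenance or {}))
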