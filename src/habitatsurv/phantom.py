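"""Synthetic co-registered multimodal tumor phantoms with known ground truth.

Each phantom subject carries six aligned 3-D maps (post-contrast T1w, T2w,
mean diffusivity, fractional anisotropy, cerebral blood volume and flow) on a
common voxel grid, plus a binary tumor mask and a contralateral
normal-appearing white matter (NAWM) mask.  The tumor is an ellipsoid with a
necrotic core, a contrast-enhancing (CE) shell and a non-enhancing outer
margin; diffusion and perfusion sub-habitats are placed inside those
compartments by seeded region growing so that every ground-truth volume is an
exact voxel count.

The default group models encode the published cohort statistics of the
glioblastoma study this generator emulates: two survival groups (16 short-term
and 13 long-term survivors, dichotomized at 15 months) whose habitat volumes
follow the reported group means and SDs, and whose intensity contrasts follow
the reported effect directions (short-term survivors: higher relative CBV and
lower MD in the low-diffusivity/low-perfusion habitat, larger LMD-LrCBV
volume; long-term survivors: larger necrosis and HMD-LrCBV volumes).

Because the published per-group volume statistics are marginal summaries, they
are mutually infeasible as independent draws under the containment constraints
(sub-habitat inside parent compartment, compartments inside the tumor).  The
generator therefore draws sub-habitats that must nest as Beta-distributed
fractions of their parent (with the Beta moments solved so the *marginal*
mean/SD still match the published rows) and draws the whole-tumor volume from
a moment-matched lognormal redrawn until it contains the habitats.  See
docs/methods.md for the consequences.
"""

from __future__ import annotations

import gzip
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

MAP_NAMES: Tuple[str, ...] = ("t1c", "t2", "md", "fa", "cbv", "cbf")
GROUPS: Tuple[str, str] = ("short", "long")

#: keys of the per-group volume distributions (cm^3), in reporting order
VOLUME_KEYS: Tuple[str, ...] = (
    "en", "nec", "lmd_lrcbv", "hmd_lrcbv", "en_hrcbv", "tumor"
)

#: names used for ground-truth volumes; aligned with the habitat ROI catalog
TRUTH_VOLUME_KEYS: Tuple[str, ...] = (
    "tumor", "CE", "necrotic", "non_en", "lmd_lrcbv",
    "LMD_LrCBV_CE", "LMD_LrCBV_nec", "HMD_LrCBV_nec", "En_HrCBV",
)

_MAX_TRIES = 200
_MIN_COMPARTMENT_CM3 = 0.10   # floor for En / Nec draws
_MIN_LL_CM3 = 0.05            # floor for the LMD-LrCBV draw
_NONEN_MARGIN_CM3 = 0.20      # guaranteed non-enhancing slack around habitats
_MAX_TUMOR_FRACTION = 0.115   # of the grid volume; keeps the ellipsoid inside

# geometry (fractions of the grid): tumor in one hemisphere, NAWM contralateral
_TUMOR_CENTER_FRAC = (0.34, 0.50, 0.50)
_NAWM_CENTER_FRAC = (0.78, 0.50, 0.50)
_NAWM_RADIUS_FRAC = 0.09
_BRAIN_SEMI_FRAC = 0.47
_NAWM_MARGIN_VOX = 3


class PhantomError(RuntimeError):
    """Raised when a phantom cannot be generated under its constraints."""


@dataclass(frozen=True)
class VolumeParams:
    """Mean and SD of a true ROI volume in cm^3."""
    mean: float
    sd: float


@dataclass(frozen=True)
class RegionSignal:
    """Per-region signal model: group-level mean and between-subject SD."""
    mean: float
    between_sd: float


@dataclass
class GroupModel:
    """Distributional description of one survival group.

    ``volume_params`` holds the per-ROI mean/SD of the true habitat volumes
    (defaults are the published group rows); ``intensity_params`` holds, per
    map and per region, the plateau mean and the between-subject SD of the
    plateau; ``noise_sd`` is the additive voxel noise per map.
    """

    group_name: str
    volume_params: Dict[str, VolumeParams]
    intensity_params: Dict[str, Dict[str, RegionSignal]]
    noise_sd: Dict[str, float]
    survival_cutoff_months: float = 15.0

    def validate(self) -> None:
        if self.group_name not in GROUPS:
            raise PhantomError(f"unknown group name {self.group_name!r}")
        if self.survival_cutoff_months <= 0:
            raise PhantomError("survival cutoff must be positive")
        for key in VOLUME_KEYS:
            if key not in self.volume_params:
                raise PhantomError(f"volume_params missing {key!r}")
            vp = self.volume_params[key]
            if vp.sd < 0:
                raise PhantomError(f"volume SD for {key!r} must be >= 0")
            if vp.mean <= 0:
                raise PhantomError(f"volume mean for {key!r} must be > 0")
        # sub-habitat means must nest inside their parent compartment means
        pairs = (("hmd_lrcbv", "nec"), ("en_hrcbv", "en"),
                 ("lmd_lrcbv", "tumor"))
        for child, parent in pairs:
            if self.volume_params[child].mean > self.volume_params[parent].mean:
                raise PhantomError(
                    f"mean volume of {child!r} exceeds its parent {parent!r}")
        for name in MAP_NAMES:
            if name not in self.intensity_params:
                raise PhantomError(f"intensity_params missing map {name!r}")
            if self.noise_sd.get(name, -1.0) < 0:
                raise PhantomError(f"noise_sd for map {name!r} must be >= 0")
            for rs in self.intensity_params[name].values():
                if rs.between_sd < 0:
                    raise PhantomError("between-subject SD must be >= 0")


_DEFAULT_VOLUMES = {
    "short": {
        "en": (1.51, 0.45), "nec": (2.07, 0.59), "lmd_lrcbv": (3.20, 0.73),
        "hmd_lrcbv": (1.01, 0.49), "en_hrcbv": (0.65, 0.37),
        "tumor": (6.02, 5.1),
    },
    "long": {
        "en": (1.26, 0.41), "nec": (2.64, 0.65), "lmd_lrcbv": (2.47, 0.88),
        "hmd_lrcbv": (1.95, 0.77), "en_hrcbv": (0.42, 0.23),
        "tumor": (6.07, 5.4),
    },
}

# Plateau intensities (arbitrary units except MD in um^2/ms and CBV on a
# NAWM-relative scale).  Ordered so the k-means naming conventions hold
# (T1c: necrotic < non-enhancing < CE; MD: LMD < HMD; CBV: LrCBV < HrCBV)
# and so the group contrasts point in the reported effect directions.
_DEFAULT_INTENSITY = {
    "short": {
        "t1c": {"necrotic": (20.0, 3.0), "non_en": (50.0, 3.0), "ce": (80.0, 3.0)},
        "t2": {"necrotic": (130.0, 4.0), "non_en": (95.0, 4.0), "ce": (80.0, 4.0)},
        "md": {"lmd": (0.70, 0.05), "hmd": (1.40, 0.05)},
        "fa": {"necrotic": (0.10, 0.02), "non_en": (0.28, 0.02), "ce": (0.22, 0.02)},
        "cbv": {"lrcbv": (1.60, 0.15), "hrcbv": (4.50, 0.15)},
        "cbf": {"necrotic": (30.0, 4.0), "non_en": (55.0, 4.0), "ce": (70.0, 4.0)},
    },
    "long": {
        "t1c": {"necrotic": (20.0, 3.0), "non_en": (50.0, 3.0), "ce": (80.0, 3.0)},
        "t2": {"necrotic": (120.0, 4.0), "non_en": (90.0, 4.0), "ce": (78.0, 4.0)},
        "md": {"lmd": (0.90, 0.05), "hmd": (1.50, 0.05)},
        "fa": {"necrotic": (0.10, 0.02), "non_en": (0.28, 0.02), "ce": (0.22, 0.02)},
        "cbv": {"lrcbv": (1.10, 0.15), "hrcbv": (4.00, 0.15)},
        "cbf": {"necrotic": (22.0, 4.0), "non_en": (50.0, 4.0), "ce": (65.0, 4.0)},
    },
}

_DEFAULT_NOISE = {"t1c": 5.0, "t2": 6.0, "md": 0.10, "fa": 0.04,
                  "cbv": 0.25, "cbf": 5.0}

# healthy-tissue baselines (no group dependence)
_BASELINE = {
    "t1c": {"brain": 42.0, "nawm": 40.0},
    "t2": {"brain": 75.0, "nawm": 70.0},
    "md": {"brain": 0.80, "nawm": 0.75},
    "fa": {"brain": 0.35, "nawm": 0.45},
    "cbv": {"brain": 1.00, "nawm": 1.00},
    "cbf": {"brain": 25.0, "nawm": 22.0},
}


def default_group_model(group: str) -> GroupModel:
    """Return the built-in :class:`GroupModel` for ``"short"`` or ``"long"``."""
    if group not in GROUPS:
        raise PhantomError(f"unknown group {group!r}")
    vols = {k: VolumeParams(*v) for k, v in _DEFAULT_VOLUMES[group].items()}
    intens = {m: {r: RegionSignal(*v) for r, v in regs.items()}
              for m, regs in _DEFAULT_INTENSITY[group].items()}
    gm = GroupModel(group_name=group, volume_params=vols,
                    intensity_params=intens, noise_sd=dict(_DEFAULT_NOISE))
    gm.validate()
    return gm


@dataclass
class PhantomSpec:
    """Cohort-level generation settings."""

    grid_shape: Tuple[int, int, int] = (64, 64, 64)
    voxel_size: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_short: int = 16
    n_long: int = 13
    seed: int = 0
    group_models: Optional[Dict[str, GroupModel]] = None

    def __post_init__(self) -> None:
        if self.group_models is None:
            self.group_models = {g: default_group_model(g) for g in GROUPS}

    @property
    def voxel_cm3(self) -> float:
        return float(np.prod(self.voxel_size)) / 1000.0

    def validate(self) -> None:
        if self.n_short + self.n_long < 1:
            raise PhantomError("cohort must contain at least one subject")
        if self.n_short < 0 or self.n_long < 0:
            raise PhantomError("group sizes must be non-negative")
        if any(v <= 0 for v in self.voxel_size):
            raise PhantomError("voxel_size must be strictly positive")
        if any(s < 32 for s in self.grid_shape):
            raise PhantomError("grid_shape must be at least 32 voxels per axis")
        for gm in self.group_models.values():
            gm.validate()
        cap = self.max_tumor_cm3()
        for g, gm in self.group_models.items():
            if gm.volume_params["tumor"].mean > cap:
                raise PhantomError(
                    f"grid too small: mean tumor volume of group {g!r} "
                    f"exceeds the grid capacity of {cap:.1f} cm^3")

    def max_tumor_cm3(self) -> float:
        grid_cm3 = float(np.prod(self.grid_shape)) * self.voxel_cm3
        return _MAX_TUMOR_FRACTION * grid_cm3


@dataclass
class SubjectVolumes:
    """Six aligned scalar maps plus tumor and NAWM masks for one subject."""

    maps: Dict[str, np.ndarray]
    tumor_mask: np.ndarray
    nawm_mask: np.ndarray
    voxel_size: Tuple[float, float, float]

    def validate(self) -> None:
        shape = self.tumor_mask.shape
        if self.nawm_mask.shape != shape:
            raise PhantomError("mask shapes differ")
        for name in MAP_NAMES:
            if name not in self.maps:
                raise PhantomError(f"missing map {name!r}")
            if self.maps[name].shape != shape:
                raise PhantomError(f"map {name!r} shape differs from masks")
            if not np.all(np.isfinite(self.maps[name])):
                raise PhantomError(f"map {name!r} contains non-finite values")
        if not self.tumor_mask.any() or not self.nawm_mask.any():
            raise PhantomError("tumor and NAWM masks must be non-empty")
        if np.any(self.tumor_mask & self.nawm_mask):
            raise PhantomError("tumor and NAWM masks overlap")


@dataclass
class GroundTruth:
    """Known compartments, habitat masks and exact volumes for one subject.

    ``compartment_labels``: 0 background, 1 necrotic, 2 non-enhancing, 3 CE.
    ``md_low_mask`` / ``cbv_low_mask`` are the true LMD and LrCBV habitats
    (kept so segmentation output can be scored voxel-wise).
    """

    compartment_labels: np.ndarray
    md_low_mask: np.ndarray
    cbv_low_mask: np.ndarray
    subhabitat_masks: Dict[str, np.ndarray]
    true_volumes: Dict[str, float]
    survival_class: str


def _trunc_normal(rng: np.random.Generator, vp: VolumeParams,
                  low: float, high: float = np.inf) -> float:
    for _ in range(_MAX_TRIES):
        x = rng.normal(vp.mean, vp.sd)
        if low <= x <= high:
            return float(x)
    raise PhantomError(
        f"could not draw a volume in [{low}, {high}] from "
        f"N({vp.mean}, {vp.sd}) after {_MAX_TRIES} tries")


def _beta_fraction(rng: np.random.Generator, child: VolumeParams,
                   parent: VolumeParams) -> float:
    """Draw child/parent volume fraction with moments matched to the child.

    If ``F ~ Beta`` independent of the parent volume ``P``, then ``FP`` has
    mean ``E[F]E[P]`` and variance ``v_F v_P + v_F m_P^2 + m_F^2 v_P``.
    Solving for the Beta moments makes the *marginal* child volume match its
    published mean/SD while containment (child <= parent) holds surely.
    """
    m_f = child.mean / parent.mean
    if not 0 < m_f < 1:
        raise PhantomError("child mean must be inside (0, parent mean)")
    v_f = (child.sd ** 2 - m_f ** 2 * parent.sd ** 2) / \
          (parent.sd ** 2 + parent.mean ** 2)
    if v_f <= 1e-12:
        return m_f
    if v_f >= m_f * (1 - m_f):
        raise PhantomError(
            "child volume SD too large for a Beta fraction of its parent")
    kappa = m_f * (1 - m_f) / v_f - 1.0
    return float(rng.beta(m_f * kappa, (1 - m_f) * kappa))


def _lognormal_volume(rng: np.random.Generator, vp: VolumeParams) -> float:
    sigma2 = np.log1p((vp.sd / vp.mean) ** 2)
    mu = np.log(vp.mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def draw_volumes(group_model: GroupModel, rng: np.random.Generator,
                 max_tumor_cm3: float = np.inf) -> Dict[str, float]:
    """Draw one subject's target volumes (cm^3) under the nesting constraints.

    Returns every compartment and habitat volume needed to voxelize the
    subject; all values are strictly positive and mutually consistent.
    """
    vp = group_model.volume_params
    en = _trunc_normal(rng, vp["en"], low=_MIN_COMPARTMENT_CM3)
    nec = _trunc_normal(rng, vp["nec"], low=_MIN_COMPARTMENT_CM3)
    hmd_nec = _beta_fraction(rng, vp["hmd_lrcbv"], vp["nec"]) * nec
    en_hr = _beta_fraction(rng, vp["en_hrcbv"], vp["en"]) * en
    lmd_nec = nec - hmd_nec          # necrotic low-MD tissue
    ll = _trunc_normal(rng, vp["lmd_lrcbv"], low=_MIN_LL_CM3)
    # When the drawn LMD-LrCBV volume is smaller than the necrotic low-MD
    # share, the surplus becomes a high-perfusion necrotic focus (necrotic
    # rCBV is reported as non-zero) instead of redrawing, which would bias
    # the LMD-LrCBV marginal.
    ll_nec = min(ll, lmd_nec)
    nec_hr = lmd_nec - ll_nec
    rest = ll - ll_nec
    lmd_ce = min(rest, en - en_hr)
    lmd_nonen = rest - lmd_ce
    required = en + nec + lmd_nonen + _NONEN_MARGIN_CM3
    if required > max_tumor_cm3:
        raise PhantomError("grid too small for the drawn habitat volumes")
    for _ in range(_MAX_TRIES):
        tumor = _lognormal_volume(rng, vp["tumor"])
        if required <= tumor <= max_tumor_cm3:
            break
    else:
        raise PhantomError(
            f"could not draw a whole-tumor volume in "
            f"[{required:.2f}, {max_tumor_cm3:.2f}] cm^3 after "
            f"{_MAX_TRIES} tries")
    return {
        "en": en, "nec": nec, "tumor": tumor, "non_en": tumor - en - nec,
        "hmd_nec": hmd_nec, "en_hr": en_hr, "nec_hr": nec_hr,
        "lmd_ce": lmd_ce, "lmd_nonen": lmd_nonen, "lmd_lrcbv": ll,
    }


def _grow_region(parent: np.ndarray, n_target: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Seeded region growing: a connected-ish blob of exactly ``n_target``
    voxels inside ``parent`` (restarting from a fresh seed if a component is
    exhausted, so the exact count is always reached)."""
    if n_target <= 0:
        return np.zeros_like(parent, dtype=bool)
    coords = np.argwhere(parent)
    if n_target > len(coords):
        raise PhantomError("region-growing target exceeds parent size")
    shape = parent.shape
    selected = np.zeros(shape, dtype=bool)
    order = rng.permutation(len(coords))
    restart_ptr = 0
    frontier: List[Tuple[int, int, int]] = []
    n_sel = 0
    while n_sel < n_target:
        if not frontier:
            while restart_ptr < len(coords):
                c = tuple(coords[order[restart_ptr]])
                restart_ptr += 1
                if not selected[c]:
                    frontier.append(c)
                    break
            else:  # pragma: no cover - guarded by the size check above
                raise PhantomError("region growing exhausted its parent")
            continue
        j = int(rng.integers(len(frontier)))
        frontier[j], frontier[-1] = frontier[-1], frontier[j]
        x, y, z = frontier.pop()
        if selected[x, y, z]:
            continue
        selected[x, y, z] = True
        n_sel += 1
        for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                           (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            nx, ny, nz = x + dx, y + dy, z + dz
            if (0 <= nx < shape[0] and 0 <= ny < shape[1]
                    and 0 <= nz < shape[2] and parent[nx, ny, nz]
                    and not selected[nx, ny, nz]):
                frontier.append((nx, ny, nz))
    return selected


def _ellipsoid_mask(shape: Sequence[int], center: Sequence[float],
                    semi_axes: Sequence[float]) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return d2 <= 1.0


def _nawm_mask(shape: Sequence[int]) -> np.ndarray:
    center = [f * s for f, s in zip(_NAWM_CENTER_FRAC, shape)]
    r = _NAWM_RADIUS_FRAC * min(shape)
    return _ellipsoid_mask(shape, center, (r, r, r))


def _brain_mask(shape: Sequence[int]) -> np.ndarray:
    center = [s / 2.0 for s in shape]
    semi = [_BRAIN_SEMI_FRAC * s for s in shape]
    return _ellipsoid_mask(shape, center, semi)


def generate_ground_truth(spec: PhantomSpec, group_model: GroupModel,
                          rng: np.random.Generator) -> GroundTruth:
    """Draw volumes and voxelize the compartment/habitat geometry."""
    shape = spec.grid_shape
    voxel_cm3 = spec.voxel_cm3
    vols = draw_volumes(group_model, rng, max_tumor_cm3=spec.max_tumor_cm3())

    def n_vox(cm3: float) -> int:
        return int(round(cm3 / voxel_cm3))

    n_tumor = n_vox(vols["tumor"])
    n_nec = n_vox(vols["nec"])
    n_en = n_vox(vols["en"])

    # anisotropically weighted distance; smallest-distance voxels form the
    # tumor, radial ordering gives core (necrotic), shell (CE), margin
    center = [f * s for f, s in zip(_TUMOR_CENTER_FRAC, shape)]
    wx = rng.uniform(1.30, 1.45)
    wy = rng.uniform(0.85, 1.10)
    wz = rng.uniform(0.85, 1.10)
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d = np.sqrt(((grids[0] - center[0]) * wx) ** 2
                + ((grids[1] - center[1]) * wy) ** 2
                + ((grids[2] - center[2]) * wz) ** 2)

    candidates = np.ones(shape, dtype=bool)
    candidates[[0, -1], :, :] = False
    candidates[:, [0, -1], :] = False
    candidates[:, :, [0, -1]] = False
    nawm = _nawm_mask(shape)
    nawm_center = [f * s for f, s in zip(_NAWM_CENTER_FRAC, shape)]
    r_excl = _NAWM_RADIUS_FRAC * min(shape) + _NAWM_MARGIN_VOX
    candidates &= ~_ellipsoid_mask(shape, nawm_center,
                                   (r_excl, r_excl, r_excl))
    flat_d = np.where(candidates, d, np.inf).ravel()
    if n_tumor >= int(candidates.sum()):
        raise PhantomError("grid too small for the drawn tumor volume")
    tumor_flat = np.argpartition(flat_d, n_tumor)[:n_tumor]
    tumor_flat = tumor_flat[np.argsort(flat_d[tumor_flat])]

    labels = np.zeros(shape, dtype=np.uint8).ravel()
    labels[tumor_flat[:n_nec]] = 1                       # necrotic core
    labels[tumor_flat[n_nec:n_nec + n_en]] = 3           # CE shell
    labels[tumor_flat[n_nec + n_en:]] = 2                # non-enhancing margin
    labels = labels.reshape(shape)
    tumor_mask = labels > 0

    nec_mask = labels == 1
    ce_mask = labels == 3
    nonen_mask = labels == 2

    # high-perfusion tissue: a blob inside CE (the En-HrCBV habitat) and,
    # when the drawn LMD-LrCBV volume is below the necrotic low-MD share,
    # a high-perfusion focus inside the necrotic low-MD tissue
    en_hr = _grow_region(ce_mask, min(n_vox(vols["en_hr"]),
                                      int(ce_mask.sum())), rng)

    # diffusion habitat: the necrotic remainder is low-MD; further low-MD
    # tissue is grown in CE-LrCBV and the non-enhancing margin so the
    # LMD ∩ LrCBV total hits the drawn LMD-LrCBV volume
    hmd_nec = _grow_region(nec_mask, min(n_vox(vols["hmd_nec"]),
                                         int(nec_mask.sum())), rng)
    lmd_nec = nec_mask & ~hmd_nec
    nec_hr = _grow_region(lmd_nec, min(n_vox(vols["nec_hr"]),
                                       int(lmd_nec.sum())), rng)
    lrcbv = tumor_mask & ~en_hr & ~nec_hr
    ce_lr = ce_mask & ~en_hr
    n_lmd_ce = min(n_vox(vols["lmd_ce"]), int(ce_lr.sum()))
    if n_lmd_ce >= int(ce_lr.sum()):
        lmd_ce = ce_lr.copy()
    else:
        lmd_ce = _grow_region(ce_lr, n_lmd_ce, rng)
    lmd_nonen = _grow_region(nonen_mask, min(n_vox(vols["lmd_nonen"]),
                                             int(nonen_mask.sum())), rng)
    lmd = lmd_nec | lmd_ce | lmd_nonen | en_hr

    sub = {
        "LMD_LrCBV_CE": lmd_ce,
        "LMD_LrCBV_nec": lmd_nec & lrcbv,
        "HMD_LrCBV_nec": hmd_nec,
        "En_HrCBV": en_hr,
    }
    true_volumes = {
        "tumor": tumor_mask.sum() * voxel_cm3,
        "CE": ce_mask.sum() * voxel_cm3,
        "necrotic": nec_mask.sum() * voxel_cm3,
        "non_en": nonen_mask.sum() * voxel_cm3,
        "lmd_lrcbv": (lmd & lrcbv).sum() * voxel_cm3,
    }
    for name, mask in sub.items():
        true_volumes[name] = mask.sum() * voxel_cm3
    return GroundTruth(
        compartment_labels=labels,
        md_low_mask=lmd,
        cbv_low_mask=lrcbv,
        subhabitat_masks=sub,
        true_volumes={k: float(v) for k, v in true_volumes.items()},
        survival_class=group_model.group_name,
    )


def _synthesize_maps(spec: PhantomSpec, group_model: GroupModel,
                     truth: GroundTruth,
                     rng: np.random.Generator) -> SubjectVolumes:
    shape = spec.grid_shape
    labels = truth.compartment_labels
    brain = _brain_mask(shape)
    nawm = _nawm_mask(shape)
    tumor = labels > 0
    brain_only = brain & ~tumor & ~nawm
    head = brain | nawm | tumor

    region_masks_by_map = {
        "compartment": {"necrotic": labels == 1, "non_en": labels == 2,
                        "ce": labels == 3},
        "md": {"lmd": truth.md_low_mask, "hmd": tumor & ~truth.md_low_mask},
        "cbv": {"lrcbv": truth.cbv_low_mask,
                "hrcbv": tumor & ~truth.cbv_low_mask},
    }

    maps: Dict[str, np.ndarray] = {}
    for name in MAP_NAMES:
        regions = group_model.intensity_params[name]
        kind = "md" if name == "md" else ("cbv" if name == "cbv"
                                          else "compartment")
        vol = np.zeros(shape, dtype=np.float64)
        vol[brain_only] = _BASELINE[name]["brain"]
        vol[nawm] = _BASELINE[name]["nawm"]
        for region_name, rs in regions.items():
            plateau = rs.mean + rng.normal(0.0, rs.between_sd)
            vol[region_masks_by_map[kind][region_name]] = plateau
        sd = group_model.noise_sd[name]
        if sd > 0:
            noise = rng.normal(0.0, sd, size=shape)
            vol[head] += noise[head]
        else:
            # keep the stream position independent of the noise level
            rng.normal(0.0, 1.0, size=shape)
        maps[name] = vol.astype(np.float32)
    return SubjectVolumes(maps=maps, tumor_mask=tumor, nawm_mask=nawm,
                          voxel_size=tuple(spec.voxel_size))


def generate_subject(spec: PhantomSpec, group_model: GroupModel,
                     subject_seed: int, with_maps: bool = True,
                     ) -> Tuple[Optional[SubjectVolumes], GroundTruth]:
    """Generate one phantom subject.

    Identical ``(spec, group_model, subject_seed)`` yields bitwise-identical
    maps and masks.  ``with_maps=False`` skips map synthesis (geometry and
    true volumes only), which is much faster for calibration studies.
    """
    spec.validate()
    group_model.validate()
    rng = np.random.default_rng(subject_seed)
    truth = generate_ground_truth(spec, group_model, rng)
    if not with_maps:
        return None, truth
    volumes = _synthesize_maps(spec, group_model, truth, rng)
    volumes.validate()
    return volumes, truth


def subject_seeds(spec: PhantomSpec, n: int) -> np.ndarray:
    """Deterministic per-subject seeds derived from ``spec.seed``."""
    return np.random.default_rng(spec.seed).integers(0, 2 ** 31 - 1, size=n)


def generate_cohort(spec: PhantomSpec, with_maps: bool = True,
                    ) -> Tuple[List[Tuple[Optional[SubjectVolumes], GroundTruth]],
                               pd.DataFrame]:
    """Generate the full two-group cohort plus its manifest.

    The manifest has one row per subject: id, group, survival class and every
    true ROI volume in cm^3.
    """
    spec.validate()
    n = spec.n_short + spec.n_long
    if n < 1:
        raise PhantomError("empty cohort requested")
    seeds = subject_seeds(spec, n)
    groups = ["short"] * spec.n_short + ["long"] * spec.n_long
    subjects = []
    rows = []
    for i, (grp, seed) in enumerate(zip(groups, seeds)):
        sid = f"S{i + 1:03d}"
        try:
            vols, truth = generate_subject(spec, spec.group_models[grp],
                                           int(seed), with_maps=with_maps)
        except PhantomError as err:
            raise PhantomError(f"subject {sid}: {err}") from err
        subjects.append((vols, truth))
        row = {"subject_id": sid, "group": grp,
               "survival_class": truth.survival_class,
               "subject_seed": int(seed)}
        row.update({f"vol_{k}_cm3": truth.true_volumes[k]
                    for k in TRUTH_VOLUME_KEYS})
        rows.append(row)
    manifest = pd.DataFrame(rows)
    return subjects, manifest


# ---------------------------------------------------------------------------
# NIfTI / JSON output
# ---------------------------------------------------------------------------

def save_nifti(path: Path, data: np.ndarray,
               voxel_size: Sequence[float]) -> None:
    """Write a (optionally gzipped) NIfTI volume with deterministic bytes.

    The gzip member is written with ``mtime=0`` so rerunning a pipeline at the
    same seed produces bit-identical files.
    """
    path = Path(path)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    affine = np.diag([*voxel_size, 1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    raw = img.to_bytes()
    if path.suffix == ".gz":
        with open(path, "wb") as fh:
            # filename="" keeps the basename out of the gzip header so the
            # bytes depend only on the payload
            with gzip.GzipFile(filename="", fileobj=fh, mode="wb",
                               mtime=0) as gz:
                gz.write(raw)
    else:
        path.write_bytes(raw)


def load_nifti(path: Path) -> Tuple[np.ndarray, Tuple[float, ...]]:
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), zooms


def write_subject(out_dir: Path, subject_id: str, volumes: SubjectVolumes,
                  truth: Optional[GroundTruth] = None) -> Path:
    """Write one subject's maps, masks and (optionally) ground truth."""
    sdir = Path(out_dir) / subject_id
    sdir.mkdir(parents=True, exist_ok=True)
    vs = volumes.voxel_size
    for name in MAP_NAMES:
        save_nifti(sdir / f"{name}.nii.gz",
                   volumes.maps[name].astype(np.float32), vs)
    save_nifti(sdir / "tumor_mask.nii.gz", volumes.tumor_mask, vs)
    save_nifti(sdir / "nawm_mask.nii.gz", volumes.nawm_mask, vs)
    if truth is not None:
        save_nifti(sdir / "truth_compartments.nii.gz",
                   truth.compartment_labels.astype(np.uint8), vs)
        save_nifti(sdir / "truth_md_low.nii.gz", truth.md_low_mask, vs)
        save_nifti(sdir / "truth_cbv_low.nii.gz", truth.cbv_low_mask, vs)
        for name, mask in truth.subhabitat_masks.items():
            save_nifti(sdir / f"truth_{name}.nii.gz", mask, vs)
        payload = {"survival_class": truth.survival_class,
                   "true_volumes_cm3": truth.true_volumes}
        (sdir / "truth.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True))
    return sdir


def read_subject(subject_dir: Path
                 ) -> Tuple[SubjectVolumes, Optional[GroundTruth]]:
    """Load a subject written by :func:`write_subject`."""
    sdir = Path(subject_dir)
    maps = {}
    vs: Tuple[float, ...] = (1.0, 1.0, 1.0)
    for name in MAP_NAMES:
        arr, vs = load_nifti(sdir / f"{name}.nii.gz")
        maps[name] = np.asarray(arr, dtype=np.float64)
    tumor, _ = load_nifti(sdir / "tumor_mask.nii.gz")
    nawm, _ = load_nifti(sdir / "nawm_mask.nii.gz")
    volumes = SubjectVolumes(maps=maps, tumor_mask=tumor.astype(bool),
                             nawm_mask=nawm.astype(bool), voxel_size=vs)
    truth = None
    truth_json = sdir / "truth.json"
    if truth_json.exists():
        meta = json.loads(truth_json.read_text())
        labels, _ = load_nifti(sdir / "truth_compartments.nii.gz")
        md_low, _ = load_nifti(sdir / "truth_md_low.nii.gz")
        cbv_low, _ = load_nifti(sdir / "truth_cbv_low.nii.gz")
        sub = {}
        for name in ("LMD_LrCBV_CE", "LMD_LrCBV_nec",
                     "HMD_LrCBV_nec", "En_HrCBV"):
            m, _ = load_nifti(sdir / f"truth_{name}.nii.gz")
            sub[name] = m.astype(bool)
        truth = GroundTruth(
            compartment_labels=labels.astype(np.uint8),
            md_low_mask=md_low.astype(bool),
            cbv_low_mask=cbv_low.astype(bool),
            subhabitat_masks=sub,
            true_volumes=meta["true_volumes_cm3"],
            survival_class=meta["survival_class"],
        )
    return volumes, truth


def write_cohort(out_dir: Path, spec: PhantomSpec) -> pd.DataFrame:
    """Generate the cohort and write every subject plus ``manifest.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    subjects, manifest = generate_cohort(spec)
    for (vols, truth), sid in zip(subjects, manifest["subject_id"]):
        write_subject(out_dir, sid, vols, truth)
    manifest.to_csv(out_dir / "manifest.csv", index=False,
                    float_format="%.6f")
    return manifest
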