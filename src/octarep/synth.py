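"""Synthetic widefield en-face angiogram generator with known ground truth.

Real widefield OCTA cohorts are rarely shareable, so the pipeline is
exercised on synthetic scenes that emulate the geometry and appearance of
a 15 x 9-mm scan sampled at 800 x 534 pixels:

* retinal-plexus scenes — a branching bright large-vessel tree over a
  thresholded correlated-noise capillary texture, with multiplicative
  radial vignetting and speckle noise;
* choriocapillaris scenes — a stationary granular texture with dark
  elliptical flow voids covering a controllable area fraction;
* two-visit pairs sharing one anatomy but differing in speckle
  realization, a small global gain perturbation, and an optional
  sub-pixel shift;
* cohorts with controlled between-subject and within-subject variance
  components, so the implied true inter-visit ICC b²/(b²+w²) is known.

Every generator is a pure function of (spec, params, seed): identical
inputs reproduce images bit-for-bit. Each call splits its seed into named
substreams (anatomy, noise, visit, cohort) so visit pairs share anatomy
deterministically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import (
    DEFAULT_HEIGHT_PX,
    DEFAULT_PITCH_X_UM,
    DEFAULT_PITCH_Y_UM,
    DEFAULT_WIDTH_PX,
    EnFaceAngiogram,
)

__all__ = [
    "SceneSpec",
    "RetinaSceneParams",
    "ChoriocapillarisSceneParams",
    "CohortSpec",
    "GroundTruth",
    "CohortDataset",
    "generate_retina_scene",
    "generate_cc_scene",
    "generate_visit_pair",
    "generate_latent_cohort",
    "generate_cohort",
]

_STREAM = {"anatomy": 0, "noise": 1, "visit": 2, "cohort": 3}

# appearance constants (intensity levels in [0, 1])
_VESSEL_LEVEL = 0.90
_CAPILLARY_LEVEL = 0.55
_CC_TEXTURE_MEAN = 0.55
_CC_TEXTURE_SD = 0.08
_CC_VOID_LEVEL = 0.15
_CC_EDGE_SIGMA_PX = 0.8   # soft void edges: higher thresholds erode voids
_LARGE_VESSEL_MIN_UM = 30.0  # taper floor: below this a branch stops


def _rng(seed: int, stream: str, *extra: int) -> np.random.Generator:
    if seed < 0:
        raise ValueError("seed must be non-negative")
    return np.random.default_rng(np.random.SeedSequence([seed, _STREAM[stream], *extra]))


# --------------------------------------------------------------------------
# Specs
# --------------------------------------------------------------------------

@dataclass
class SceneSpec:
    """Scan geometry: grid size, physical pitch, landmark positions, seed."""

    width_px: int = DEFAULT_WIDTH_PX
    height_px: int = DEFAULT_HEIGHT_PX
    pitch_x_um: float = DEFAULT_PITCH_X_UM
    pitch_y_um: float = DEFAULT_PITCH_Y_UM
    fovea_center_px: Optional[tuple[float, float]] = None  # (row, col); None -> centre
    disc_center_px: Optional[tuple[float, float]] = None
    disc_radius_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px < 64 or self.height_px < 64:
            raise ValueError("scene must be at least 64 x 64 px")
        if self.pitch_x_um <= 0 or self.pitch_y_um <= 0:
            raise ValueError("pitch must be positive")
        if self.fovea_center_px is None:
            self.fovea_center_px = ((self.height_px - 1) / 2.0, (self.width_px - 1) / 2.0)
        fr, fc = self.fovea_center_px
        if not (0 <= fr < self.height_px and 0 <= fc < self.width_px):
            raise ValueError("fovea centre outside image bounds")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height_px, self.width_px)


@dataclass
class RetinaSceneParams:
    """Appearance of a retinal-plexus slab.

    Widths are physical (µm); ``capillary_density_target`` is the fraction
    of the field covered by the capillary texture; ``vignetting_strength``
    is the relative signal loss at the field corner; ``speckle_sigma`` the
    noise scale of the multiplicative+additive speckle model.
    """

    large_vessel_count: int = 4
    large_vessel_width_um: tuple[float, float] = (60.0, 180.0)
    capillary_density_target: float = 0.30
    capillary_width_um: float = 20.0
    vignetting_strength: float = 0.25
    speckle_sigma: float = 0.05
    background_level: float = 0.15

    def __post_init__(self) -> None:
        if self.large_vessel_count < 0:
            raise ValueError("large_vessel_count must be non-negative")
        lo, hi = self.large_vessel_width_um
        if lo > hi:
            raise ValueError("width range min must be <= max")
        if not (0.0 <= self.capillary_density_target <= 1.0):
            raise ValueError("capillary_density_target must be in [0, 1]")
        if self.large_vessel_count and not (self.capillary_width_um < lo):
            raise ValueError("capillary width must be below the large-vessel minimum")
        if not (0.0 <= self.vignetting_strength < 1.0):
            raise ValueError("vignetting_strength must be in [0, 1)")
        if self.speckle_sigma < 0:
            raise ValueError("speckle_sigma must be non-negative")
        if not (0.0 <= self.background_level <= 1.0):
            raise ValueError("background_level must be in [0, 1]")


@dataclass
class ChoriocapillarisSceneParams:
    """Appearance of a choriocapillaris slab."""

    texture_correlation_um: float = 30.0
    void_fraction_target: float = 0.12
    void_size_um2_mean: float = 1500.0
    speckle_sigma: float = 0.04

    def __post_init__(self) -> None:
        if self.texture_correlation_um <= 0:
            raise ValueError("texture_correlation_um must be positive")
        if not (0.0 <= self.void_fraction_target <= 1.0):
            raise ValueError("void_fraction_target must be in [0, 1]")
        if self.void_size_um2_mean <= 0:
            raise ValueError("void_size_um2_mean must be positive")
        if self.speckle_sigma < 0:
            raise ValueError("speckle_sigma must be non-negative")


@dataclass
class GroundTruth:
    """Exact rasterized truth carried alongside a synthetic scene."""

    large_vessel_mask: Optional[np.ndarray] = None
    capillary_mask: Optional[np.ndarray] = None
    void_mask: Optional[np.ndarray] = None
    true_pd_percent: Optional[float] = None
    true_void_fraction: Optional[float] = None

    @property
    def union_vessel_mask(self) -> Optional[np.ndarray]:
        masks = [m for m in (self.large_vessel_mask, self.capillary_mask) if m is not None]
        if not masks:
            return None
        out = masks[0].copy()
        for m in masks[1:]:
            out |= m
        return out


# --------------------------------------------------------------------------
# Rasterization helpers
# --------------------------------------------------------------------------

def _ellipse_footprint(shape: tuple[int, int], row: float, col: float,
                       ry: float, rx: float, phi: float = 0.0):
    """Boolean footprint of a rotated ellipse inside its bounding box.

    Returns ``(r0, r1, c0, c1, local)`` with pixel-centre inclusion, or
    ``None`` when the ellipse misses the grid entirely.
    """
    h, w = shape
    rmax = max(ry, rx)
    r0, r1 = max(0, int(np.floor(row - rmax))), min(h, int(np.ceil(row + rmax)) + 1)
    c0, c1 = max(0, int(np.floor(col - rmax))), min(w, int(np.ceil(col + rmax)) + 1)
    if r0 >= r1 or c0 >= c1:
        return None
    rr, cc = np.ogrid[r0:r1, c0:c1]
    dy, dx = rr - row, cc - col
    u = dx * np.cos(phi) + dy * np.sin(phi)
    v = -dx * np.sin(phi) + dy * np.cos(phi)
    return r0, r1, c0, c1, (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _stamp_ellipse(mask: np.ndarray, row: float, col: float,
                   ry: float, rx: float, phi: float = 0.0) -> None:
    """Set the pixels inside a rotated ellipse (pixel-centre inclusion)."""
    fp = _ellipse_footprint(mask.shape, row, col, ry, rx, phi)
    if fp is None:
        return
    r0, r1, c0, c1, local = fp
    mask[r0:r1, c0:c1] |= local


def _vessel_tree_mask(spec: SceneSpec, params: RetinaSceneParams,
                      rng: np.random.Generator) -> np.ndarray:
    """Rasterize a stochastic branching walk of bright large vessels."""
    h, w = spec.shape
    mask = np.zeros((h, w), bool)
    lo, hi = params.large_vessel_width_um
    # roots alternate left/right edges at staggered heights, heading across
    # the field like the temporal arcades; gentle curvature, sparse branching
    queue: list[tuple[float, float, float, float, int]] = []
    n = params.large_vessel_count
    for i in range(n):
        side = i % 2  # 0 = left edge, 1 = right edge
        frac = (i + 0.5) / n + rng.uniform(-0.3, 0.3) / n
        row = float(np.clip(frac, 0.05, 0.95)) * h
        col = 0.0 if side == 0 else w - 1.0
        heading = rng.normal(0.0 if side == 0 else np.pi, 0.2)
        width = rng.uniform(lo, hi)
        queue.append((row, col, heading, width, 0))

    step_px = 2.0
    max_steps = 900
    while queue:
        row, col, heading, width_um, depth = queue.pop()
        base_heading = heading
        for _ in range(max_steps):
            ry = width_um / 2.0 / spec.pitch_y_um
            rx = width_um / 2.0 / spec.pitch_x_um
            _stamp_ellipse(mask, row, col, ry, rx)
            row += step_px * np.sin(heading)
            col += step_px * np.cos(heading)
            # mean-reverting heading keeps arcades crossing the field
            heading += rng.normal(0.0, 0.06) - 0.02 * (heading - base_heading)
            width_um *= 0.999
            if width_um < _LARGE_VESSEL_MIN_UM:
                break
            if not (-2 <= row < h + 2 and -2 <= col < w + 2):
                break
            if depth < 2 and rng.random() < 0.004:
                sign = 1.0 if rng.random() < 0.5 else -1.0
                queue.append(
                    (row, col, heading + sign * rng.uniform(0.4, 0.9),
                     width_um * 0.7, depth + 1)
                )
    return mask


def _capillary_mask(spec: SceneSpec, params: RetinaSceneParams,
                    rng: np.random.Generator) -> np.ndarray:
    """Thresholded correlated field covering ~capillary_density_target."""
    target = params.capillary_density_target
    if target <= 0:
        return np.zeros(spec.shape, bool)
    if target >= 1:
        return np.ones(spec.shape, bool)
    sig_y = max(params.capillary_width_um / (2.0 * spec.pitch_y_um), 0.3)
    sig_x = max(params.capillary_width_um / (2.0 * spec.pitch_x_um), 0.3)
    fld = ndimage.gaussian_filter(rng.standard_normal(spec.shape), (sig_y, sig_x))
    cut = np.quantile(fld, 1.0 - target)
    return fld > cut


def _vignette(spec: SceneSpec, strength: float) -> np.ndarray:
    if strength == 0:
        return np.ones(spec.shape)
    h, w = spec.shape
    rr, cc = np.ogrid[:h, :w]
    dy = (rr - (h - 1) / 2.0) * spec.pitch_y_um
    dx = (cc - (w - 1) / 2.0) * spec.pitch_x_um
    d2 = dy**2 + dx**2
    return 1.0 - strength * d2 / d2.max()


def _apply_speckle(px: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Two-component speckle: image x (1 + N(0, s)) + N(0, s/2), clipped."""
    if sigma == 0:
        return np.clip(px, 0.0, 1.0)
    mult = rng.standard_normal(px.shape)
    add = rng.standard_normal(px.shape)
    return np.clip(px * (1.0 + sigma * mult) + 0.5 * sigma * add, 0.0, 1.0)


# --------------------------------------------------------------------------
# Scene generators
# --------------------------------------------------------------------------

# memo for the deterministic anatomy stage, so the two visits of a pair
# (same spec/params, different noise) rasterize the scene only once
_CLEAN_CACHE: dict[tuple, tuple[np.ndarray, GroundTruth]] = {}
_CLEAN_CACHE_MAX = 4


def _memo_clean(kind: str, spec, params, builder):
    key = (kind, repr(spec), repr(params))
    if key not in _CLEAN_CACHE:
        if len(_CLEAN_CACHE) >= _CLEAN_CACHE_MAX:
            _CLEAN_CACHE.pop(next(iter(_CLEAN_CACHE)))
        _CLEAN_CACHE[key] = builder(spec, params)
    return _CLEAN_CACHE[key]


def _retina_clean(spec: SceneSpec, params: RetinaSceneParams
                  ) -> tuple[np.ndarray, GroundTruth]:
    """Noise-free retinal scene (anatomy substream only)."""
    anat = _rng(spec.seed, "anatomy")
    large = (_vessel_tree_mask(spec, params, anat)
             if params.large_vessel_count else np.zeros(spec.shape, bool))
    caps = _capillary_mask(spec, params, anat)
    union = large | caps
    px = np.full(spec.shape, params.background_level)
    px[caps] = _CAPILLARY_LEVEL
    px[large] = _VESSEL_LEVEL
    px *= _vignette(spec, params.vignetting_strength)
    truth = GroundTruth(
        large_vessel_mask=large,
        capillary_mask=caps,
        true_pd_percent=100.0 * union.sum() / union.size,
    )
    return px, truth


def generate_retina_scene(
    spec: SceneSpec,
    params: Optional[RetinaSceneParams] = None,
    _noise_rng: Optional[np.random.Generator] = None,
) -> tuple[EnFaceAngiogram, GroundTruth]:
    """Generate a retinal-plexus scene with exact vessel-mask ground truth.

    ``true_pd_percent`` is 100 x (union vessel-mask area / image area).
    Deterministic for fixed (spec, params).
    """
    params = params or RetinaSceneParams()
    clean, truth = _memo_clean("retina", spec, params, _retina_clean)
    noise = _noise_rng if _noise_rng is not None else _rng(spec.seed, "noise")
    px = _apply_speckle(clean, params.speckle_sigma, noise)
    img = EnFaceAngiogram(px, spec.pitch_x_um, spec.pitch_y_um, slab="SCP")
    return img, truth


def _cc_clean(spec: SceneSpec, params: ChoriocapillarisSceneParams
              ) -> tuple[np.ndarray, GroundTruth]:
    anat = _rng(spec.seed, "anatomy")
    sig_y = max(params.texture_correlation_um / (2.0 * spec.pitch_y_um), 0.3)
    sig_x = max(params.texture_correlation_um / (2.0 * spec.pitch_x_um), 0.3)
    fld = ndimage.gaussian_filter(anat.standard_normal(spec.shape), (sig_y, sig_x))
    fld_sd = fld.std()
    texture = _CC_TEXTURE_MEAN + (_CC_TEXTURE_SD / fld_sd if fld_sd else 0.0) * fld

    void_mask = np.zeros(spec.shape, bool)
    target = params.void_fraction_target
    if target > 0:
        h, w = spec.shape
        px_area_um2 = spec.pitch_x_um * spec.pitch_y_um
        expected_n = max(int(target * h * w * px_area_um2 / params.void_size_um2_mean), 1)
        max_attempts = 60 * expected_n
        total_px = h * w
        need_px = target * total_px
        # lognormal sizes with mean = void_size_um2_mean
        ln_sigma = 0.5
        ln_mu = np.log(params.void_size_um2_mean) - 0.5 * ln_sigma**2
        placed_px = 0
        attempts = 0
        # dense targets approach the packing limit of separated ellipses:
        # when a whole draw chunk makes <0.5% progress, relax the
        # separation in stages so the target fraction always wins
        sep_levels = iter([2.0, 1.0, 0.0])
        sep = next(sep_levels)
        pitch = 0.5 * (spec.pitch_x_um + spec.pitch_y_um)
        chunk = 4096
        draws = None
        draw_i = chunk
        chunk_start_px = 0
        while placed_px < need_px and attempts < max_attempts:
            if draw_i >= chunk:  # batch the random draws
                if draws is not None and placed_px - chunk_start_px < 0.005 * need_px:
                    nxt = next(sep_levels, None)
                    if nxt is None:
                        break
                    sep = nxt
                chunk_start_px = placed_px
                draws = (
                    np.exp(anat.normal(ln_mu, ln_sigma, chunk)),
                    anat.uniform(0.5, 1.0, chunk),
                    anat.uniform(0.0, np.pi, chunk),
                    anat.uniform(0, h - 1, chunk),
                    anat.uniform(0, w - 1, chunk),
                )
                draw_i = 0
            area_um2, aspect, phi, row, col = (d[draw_i] for d in draws)
            draw_i += 1
            attempts += 1
            a_um = np.sqrt(area_um2 / (np.pi * aspect))
            # per-axis px radii (mean pitch is used for the rotated stamp)
            ra = max(a_um / pitch, 0.6)
            rb = max(aspect * a_um / pitch, 0.6)
            # enforce a >= 2 px separation so true voids stay distinct
            # components: one local grid serves both the dilated probe and
            # the core stamp
            cp, sp = np.cos(phi), np.sin(phi)
            # tight bounding box of the rotated, separation-dilated ellipse;
            # an occupied box rejects the candidate (conservative but cheap)
            ex = np.sqrt((ra * cp) ** 2 + (rb * sp) ** 2) + sep
            ey = np.sqrt((ra * sp) ** 2 + (rb * cp) ** 2) + sep
            r0, r1 = max(0, int(row - ey)), min(h, int(row + ey) + 2)
            c0, c1 = max(0, int(col - ex)), min(w, int(col + ex) + 2)
            if r0 >= r1 or c0 >= c1:
                continue
            box = void_mask[r0:r1, c0:c1]
            if sep > 0 and box.any():
                continue
            dy = np.arange(r0, r1, dtype=np.float64)[:, None] - row
            dx = np.arange(c0, c1, dtype=np.float64)[None, :] - col
            u = dx * cp + dy * sp
            v = -dx * sp + dy * cp
            core = (u / ra) ** 2 + (v / rb) ** 2 <= 1.0
            prev = int(box.sum()) if sep == 0 else 0
            box |= core
            placed_px += int(box.sum()) - prev if sep == 0 else int(core.sum())

    soft = ndimage.gaussian_filter(void_mask.astype(np.float64), _CC_EDGE_SIGMA_PX)
    soft = np.clip(soft * 1.4, 0.0, 1.0)
    px = texture * (1.0 - soft) + _CC_VOID_LEVEL * soft
    px = np.clip(px, 0.0, 1.0)
    truth = GroundTruth(
        void_mask=void_mask,
        true_void_fraction=float(void_mask.sum()) / void_mask.size,
    )
    return px, truth


def generate_cc_scene(
    spec: SceneSpec,
    params: Optional[ChoriocapillarisSceneParams] = None,
    _noise_rng: Optional[np.random.Generator] = None,
) -> tuple[EnFaceAngiogram, GroundTruth]:
    """Generate a choriocapillaris scene with exact void-mask ground truth.

    Dark elliptical voids are placed with a ~2 px separation (dart throwing
    with rejection) until the rasterized fraction reaches the target, so
    the true void count equals the number placed.
    """
    params = params or ChoriocapillarisSceneParams()
    clean, truth = _memo_clean("cc", spec, params, _cc_clean)
    noise = _noise_rng if _noise_rng is not None else _rng(spec.seed, "noise")
    px = _apply_speckle(clean, params.speckle_sigma, noise)
    img = EnFaceAngiogram(px, spec.pitch_x_um, spec.pitch_y_um, slab="CC")
    return img, truth


def generate_visit_pair(
    scene_op: Callable,
    spec: SceneSpec,
    params,
    within_subject_sd: float = 0.0,
    share_noise: bool = False,
    shift_px: float = 0.0,
) -> tuple[tuple[EnFaceAngiogram, EnFaceAngiogram], GroundTruth]:
    """Two visits of one anatomy: re-sampled speckle, a global gain drawn
    with scale ``within_subject_sd``, and an optional sub-pixel shift.

    With ``within_subject_sd = 0`` and ``share_noise = True`` the two
    visits are identical.
    """
    if within_subject_sd < 0:
        raise ValueError("within_subject_sd must be non-negative")
    visit_rng = _rng(spec.seed, "visit")
    gains = 1.0 + within_subject_sd * visit_rng.standard_normal(2)
    shifts = visit_rng.uniform(-shift_px, shift_px, 2) if shift_px > 0 else (0.0, 0.0)

    img1, truth = scene_op(spec, params, _noise_rng=_rng(spec.seed, "noise", 1))
    img2, _ = scene_op(
        spec, params,
        _noise_rng=_rng(spec.seed, "noise", 1 if share_noise else 2),
    )
    px1 = np.clip(img1.pixels * gains[0], 0.0, 1.0)
    px2 = img2.pixels * gains[1]
    if shift_px > 0:
        px2 = ndimage.shift(px2, shifts, order=1, mode="reflect")
    px2 = np.clip(px2, 0.0, 1.0)
    v1 = replace(img1, pixels=px1, visit=1)
    v2 = replace(img2, pixels=px2, visit=2)
    return (v1, v2), truth


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """A two-visit cohort with controlled variance components.

    ``between_subject_sd`` (b) and ``within_subject_sd`` (w) act on the
    latent metric (capillary density fraction for retinal scenes, void
    fraction for choriocapillaris scenes); the implied true inter-visit
    ICC is b² / (b² + w²). Defaults mirror a 14-subject, two-visit design.
    """

    n_subjects: int = 14
    n_visits: int = 2
    between_subject_sd: float = 0.03
    within_subject_sd: float = 0.01
    base_scene: SceneSpec = field(default_factory=SceneSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.n_visits < 2:
            raise ValueError("need at least 2 visits")
        if self.between_subject_sd < 0 or self.within_subject_sd < 0:
            raise ValueError("variance components must be non-negative")
        if self.between_subject_sd == 0 and self.within_subject_sd == 0:
            raise ValueError("at least one variance component must be positive")

    @property
    def implied_true_icc(self) -> float:
        b2 = self.between_subject_sd**2
        w2 = self.within_subject_sd**2
        return b2 / (b2 + w2)


@dataclass
class CohortDataset:
    """Outputs of a cohort generation run."""

    latent: pd.DataFrame            # subject_id, visit, latent value
    manifest: Optional[pd.DataFrame] = None
    out_dir: Optional[Path] = None
    truths: dict = field(default_factory=dict)


def generate_latent_cohort(cohort: CohortSpec, base_value: float = 0.0) -> pd.DataFrame:
    """Latent metric table y_ij = base + b_i + w_ij (no images).

    b_i ~ N(0, between_subject_sd) per subject, w_ij ~ N(0,
    within_subject_sd) per subject-visit; the sample SDs of the two
    components recover (b, w) at large n.
    """
    rng = _rng(cohort.seed, "cohort")
    b = rng.normal(0.0, cohort.between_subject_sd, cohort.n_subjects)
    w = rng.normal(0.0, cohort.within_subject_sd, (cohort.n_subjects, cohort.n_visits))
    rows = [
        {"subject_id": f"S{i + 1:03d}", "visit": j + 1,
         "value": base_value + b[i] + w[i, j]}
        for i in range(cohort.n_subjects)
        for j in range(cohort.n_visits)
    ]
    return pd.DataFrame(rows)


def generate_cohort(
    cohort: CohortSpec,
    scene_kind: str = "retina",
    out_dir: Optional[Path] = None,
    retina_params: Optional[RetinaSceneParams] = None,
    cc_params: Optional[ChoriocapillarisSceneParams] = None,
) -> CohortDataset:
    """Generate a cohort; when ``out_dir`` is given, write images + manifest.

    The subject effect b_i perturbs the scene's latent density target; the
    visit effect w_ij is realized as a global gain perturbation (relative
    scale) plus a fresh speckle realization. ``scene_kind`` is ``"retina"``,
    ``"cc"``, or ``"all"`` (SCP + DCP retinal slabs plus a CC slab).
    """
    if scene_kind not in ("retina", "cc", "all"):
        raise ValueError(f"unknown scene_kind {scene_kind!r}")
    if cohort.n_visits != 2:
        raise ValueError("image cohorts use the two-visit study design")
    latent = generate_latent_cohort(cohort)
    ds = CohortDataset(latent=latent)
    if out_dir is None:
        return ds

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from .io import write_image, write_truth  # local import to avoid cycle

    retina_params = retina_params or RetinaSceneParams()
    cc_params = cc_params or ChoriocapillarisSceneParams()
    base = cohort.base_scene
    rng = _rng(cohort.seed, "cohort", 1)
    b = rng.normal(0.0, cohort.between_subject_sd, cohort.n_subjects)
    w = rng.normal(0.0, cohort.within_subject_sd, (cohort.n_subjects, 2))

    slabs = {"retina": ["SCP"], "cc": ["CC"], "all": ["SCP", "DCP", "CC"]}[scene_kind]
    rows = []
    for i in range(cohort.n_subjects):
        sid = f"S{i + 1:03d}"
        subj_seed = int(np.random.SeedSequence([cohort.seed, 7, i]).generate_state(1)[0] % 2**31)
        for slab in slabs:
            spec = replace(base, seed=int(np.random.SeedSequence(
                [subj_seed, {"SCP": 0, "DCP": 1, "CC": 2}[slab]]).generate_state(1)[0] % 2**31))
            if slab == "CC":
                params = replace(
                    cc_params,
                    void_fraction_target=float(np.clip(
                        cc_params.void_fraction_target + b[i], 0.02, 0.5)),
                )
                op = generate_cc_scene
            else:
                density = retina_params.capillary_density_target + b[i]
                params = replace(
                    retina_params,
                    capillary_density_target=float(np.clip(density, 0.05, 0.6)),
                    # the deep plexus is a denser pure-capillary network
                    large_vessel_count=(retina_params.large_vessel_count
                                        if slab == "SCP" else 0),
                )
                if slab == "DCP":
                    params = replace(params, capillary_density_target=float(
                        np.clip(density + 0.05, 0.05, 0.65)))
                op = generate_retina_scene
            (v1, v2), truth = generate_visit_pair(
                op, spec, params, within_subject_sd=cohort.within_subject_sd
            )
            for visit, img in ((1, v1), (2, v2)):
                img = replace(img, slab=slab, subject_id=sid, visit=visit, eye="OD")
                fname = f"{sid}_v{visit}_{slab}.tiff"
                write_image(out_dir / fname, img)
                rows.append({
                    "subject_id": sid, "visit": visit, "eye": "OD", "slab": slab,
                    "image_path": fname,
                    "pitch_x_um": base.pitch_x_um, "pitch_y_um": base.pitch_y_um,
                    "fovea_row": spec.fovea_center_px[0],
                    "fovea_col": spec.fovea_center_px[1],
                })
            key = (sid, slab)
            ds.truths[key] = truth
            truth_path = out_dir / f"{sid}_{slab}_truth.json"
            write_truth(truth_path, {
                "subject_id": sid, "slab": slab,
                "true_pd_percent": truth.true_pd_percent,
                "true_void_fraction": truth.true_void_fraction,
            })
    manifest = pd.DataFrame(rows)
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False, lineterminator="\n")
    ds.manifest = manifest
    ds.out_dir = out_dir
    return ds
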