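"""Synthetic stained-slice image generator with ground truth.

No raw photographs from potato-model electroporation experiments are
publicly deposited, so every downstream stage (scale calibration,
segmentation, statistics) is exercised on seeded synthetic images whose
ground truth is known exactly.  The generator emulates the two readouts
used in the field:

* **TTC staining** — the irreversibly electroporated (IRE) core stays
  white (dead tissue does not reduce the tetrazolium dye) and is
  surrounded by a deep-red annulus attributed to reversible
  electroporation (RE).  The red annulus fades exponentially with the
  delay between pulsing and staining, vanishing by ~21 h.
* **Melanin accumulation** — damaged tissue blackens by polyphenol
  oxidation; the blackened area grows with a saturating-exponential time
  course and converges to the TTC white area by 48 h.  The melanin
  readout is distorted into a star shape by the heterogeneous inner
  medullar tissue; TTC is much less affected.

Replicate-to-replicate variation is modelled as multiplicative lognormal
jitter on the zone areas.  Everything is driven by per-item seeds derived
from a single master seed, so a whole experiment regenerates
byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from ._seeds import derive_seed
from .field_model import (
    AblationZones,
    ElectrodeConfig,
    FieldMap,
    GridSpec,
    field_magnitude,
    predict_zones,
    solve_laplace,
)

__all__ = [
    "RenderParams",
    "KineticsParams",
    "StarParams",
    "RulerSpec",
    "StainImageBundle",
    "ExperimentBundle",
    "melanin_area_at",
    "red_area_at",
    "apply_star_distortion",
    "render_ttc",
    "render_melanin",
    "generate_experiment",
    "generate_measurement_table",
    "default_conditions",
    "DEFAULT_VOLTAGES",
]

#: Field-strength settings of the standard protocol, V/cm (1-cm gap, so the
#: numeric applied voltage equals the setting).
DEFAULT_VOLTAGES = (300.0, 600.0, 900.0, 1200.0, 1500.0)

#: Staining delay used for the standard TTC condition: staining performed
#: within 5 min of pulsing.
TTC_DEFAULT_DELAY_H = 5.0 / 60.0

#: Standard melanin readout time, h.
MELANIN_DEFAULT_TIME_H = 48.0


@dataclass(frozen=True)
class RulerSpec:
    """Millimetre ruler drawn into the frame for scale calibration."""

    band_height_px: int = 12
    tick_spacing_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.band_height_px < 3:
            raise ValueError("ruler band must be at least 3 px tall")
        if self.tick_spacing_mm <= 0:
            raise ValueError("tick spacing must be positive")


@dataclass(frozen=True)
class RenderParams:
    """Rendering palette, scale and noise for synthetic slice photographs.

    Colors were chosen for clean segmentability and are stated explicitly
    for reproducibility: tan tuber background, near-white dead core,
    formazan deep red, melanin near-black.
    """

    pixels_per_mm: float = 10.0
    background_color: tuple[int, int, int] = (210, 190, 150)
    white_core_color: tuple[int, int, int] = (245, 243, 238)
    deep_red_color: tuple[int, int, int] = (150, 30, 40)
    melanin_color: tuple[int, int, int] = (40, 35, 30)
    noise_sigma: float = 8.0
    ruler: RulerSpec | None = field(default_factory=RulerSpec)

    def __post_init__(self) -> None:
        if self.pixels_per_mm <= 0:
            raise ValueError("pixels_per_mm must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        colors = [
            self.background_color,
            self.white_core_color,
            self.deep_red_color,
            self.melanin_color,
        ]
        for i, ci in enumerate(colors):
            for cj in colors[i + 1 :]:
                dist = max(abs(a - b) for a, b in zip(ci, cj))
                if dist < 30:
                    raise ValueError(
                        "palette colors too close for well-posed segmentation"
                    )


@dataclass(frozen=True)
class KineticsParams:
    """Time constants of the two staining readouts.

    melanin_tau_h / melanin_onset_h
        Saturating-exponential growth of the blackened area toward the
        final (TTC-equivalent) area, with a lag before any blackening is
        visible (only slight changes are seen 3 h after pulsing).
    red_decay_tau_h
        Exponential decay of the deep-red annulus with staining delay;
        the default 6 h leaves < 5% of the initial area at a 21-h delay,
        emulating its observed disappearance.
    rep_noise_cv
        Coefficient of variation of the multiplicative lognormal jitter
        applied to replicate areas.
    """

    melanin_tau_h: float = 12.0
    melanin_onset_h: float = 2.0
    red_decay_tau_h: float = 6.0
    rep_noise_cv: float = 0.08

    def __post_init__(self) -> None:
        for name in ("melanin_tau_h", "melanin_onset_h", "red_decay_tau_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.rep_noise_cv < 0.5:
            raise ValueError("rep_noise_cv must lie in [0, 0.5)")


@dataclass(frozen=True)
class StarParams:
    """Star-shaped boundary modulation from the inner medullar tissue."""

    amplitude: float = 0.25
    lobes: int = 5

    def __post_init__(self) -> None:
        if not 0 <= self.amplitude < 1:
            raise ValueError("amplitude must lie in [0, 1)")
        if self.lobes < 3:
            raise ValueError("lobes must be >= 3")


#: Default star artifact strength per modality: pronounced for melanin,
#: absent for TTC (the white TTC core is much less affected).
DEFAULT_MELANIN_STAR = StarParams(amplitude=0.25, lobes=5)
DEFAULT_TTC_STAR: StarParams | None = None


@dataclass
class StainImageBundle:
    """One rendered slice photograph plus its exact ground truth."""

    image: np.ndarray  # uint8 (H, W, 3)
    truth_masks: dict[str, np.ndarray]  # class name -> bool (H, W)
    truth_areas: dict[str, float]  # class name -> cm^2
    pixels_per_mm: float
    seed: int
    condition: tuple[float, str, float]  # (voltage V/cm, modality, time_h)


@dataclass
class ExperimentBundle:
    """A full synthetic experiment: images plus truth and electrical tables."""

    bundles: list[StainImageBundle]
    truth_table: pd.DataFrame
    electrical_table: pd.DataFrame
    master_seed: int


# --------------------------------------------------------------------------
# kinetics
# --------------------------------------------------------------------------

def melanin_area_at(final_area: float, time_h: float, kin: KineticsParams) -> float:
    """Blackened area (cm^2) at ``time_h`` hours after pulsing.

    Saturating exponential with onset lag:
    ``A(t) = A_final * (1 - exp(-(t - onset)/tau))`` for ``t > onset``,
    zero before onset.
    """
    if final_area < 0:
        raise ValueError("final_area must be non-negative")
    if time_h < 0:
        raise ValueError("time must be non-negative")
    dt = time_h - kin.melanin_onset_h
    if dt <= 0:
        return 0.0
    return final_area * (1.0 - np.exp(-dt / kin.melanin_tau_h))


def red_area_at(initial_red_area: float, staining_delay_h: float,
                kin: KineticsParams) -> float:
    """Deep-red annulus area (cm^2) after a staining delay.

    Exponential decay toward zero, emulating membrane resealing:
    ``A(d) = A_0 * exp(-d / tau_r)``.
    """
    if initial_red_area < 0:
        raise ValueError("initial_red_area must be non-negative")
    if staining_delay_h < 0:
        raise ValueError("staining delay must be non-negative")
    return initial_red_area * float(np.exp(-staining_delay_h / kin.red_decay_tau_h))


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Multiplicative jitter with unit mean and the given cv."""
    if cv == 0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))


# --------------------------------------------------------------------------
# mask geometry
# --------------------------------------------------------------------------

def rasterize_zone_mask(mask: np.ndarray, grid: GridSpec,
                        pixels_per_mm: float) -> np.ndarray:
    """Sample a field-grid boolean mask onto the image pixel lattice.

    Pixel (r, c) takes the value of the nearest grid node to its centre;
    image row 0 is the top of the frame (y = +height/2).
    """
    npx_x = int(round(grid.width * pixels_per_mm))
    npx_y = int(round(grid.height * pixels_per_mm))
    xs = -grid.width / 2 + (np.arange(npx_x) + 0.5) / pixels_per_mm
    ys = grid.height / 2 - (np.arange(npx_y) + 0.5) / pixels_per_mm
    jx = np.clip(np.round((xs - grid.x[0]) / grid.spacing_h).astype(int), 0, grid.nx - 1)
    iy = np.clip(np.round((ys - grid.y[0]) / grid.spacing_h).astype(int), 0, grid.ny - 1)
    return mask[np.ix_(iy, jx)]


def resize_mask_to_area(mask: np.ndarray, target_px: int,
                        allowed: np.ndarray | None = None) -> np.ndarray:
    """Morphologically shrink or grow a region to an exact pixel count.

    Pixels are ranked by signed Euclidean distance to the region boundary
    (positive inside, negative outside) and the top ``target_px`` are
    kept — equivalent to erosion/dilation by the disk radius that hits the
    target area, with deterministic raster-order tie-breaking.
    """
    n_on = int(mask.sum())
    if target_px <= 0:
        return np.zeros_like(mask)
    if target_px == n_on:
        return mask.copy()
    d = ndimage.distance_transform_edt(mask).astype(np.float64)
    d -= ndimage.distance_transform_edt(~mask)
    if allowed is not None:
        d[~allowed] = -np.inf
    flat = d.ravel()
    order = np.lexsort((np.arange(flat.size), -flat))
    out = np.zeros(flat.size, dtype=bool)
    out[order[:target_px]] = True
    return out.reshape(mask.shape)


def apply_star_distortion(mask: np.ndarray, amplitude: float, lobes: int,
                          seed: int) -> np.ndarray:
    """Modulate a region boundary into a star shape, preserving area.

    The boundary radius about the region centroid is remapped as
    ``r(theta) * (1 + amplitude * cos(lobes * theta + phase))`` with the
    phase drawn from the seed; the mean radius is renormalised by
    ``1/sqrt(1 + amplitude^2/2)`` so the enclosed area is preserved to
    within a few percent.  The region must be star-convex about its
    centroid (true for the convex-ish ablation zones this models).
    """
    if not 0 <= amplitude < 1:
        raise ValueError("amplitude must lie in [0, 1)")
    if lobes < 3:
        raise ValueError("lobes must be >= 3")
    if amplitude == 0 or not mask.any():
        return mask.copy()

    rng = np.random.default_rng(seed)
    phase = float(rng.uniform(0, 2 * np.pi))

    # distort each connected component about its own centroid: at low
    # field settings the zone splits into a lobe around each needle, and
    # a single radial map about the joint centroid would fill the gap
    labels, n_comp = ndimage.label(mask)
    if n_comp > 1:
        out = np.zeros_like(mask)
        for lab in range(1, n_comp + 1):
            out |= _star_distort_component(labels == lab, amplitude, lobes, phase)
        return out
    return _star_distort_component(mask, amplitude, lobes, phase)


def _star_distort_component(mask: np.ndarray, amplitude: float, lobes: int,
                            phase: float) -> np.ndarray:
    rows, cols = np.nonzero(mask)
    cy, cx = rows.mean(), cols.mean()
    ny, nx = mask.shape
    Y, X = np.ogrid[:ny, :nx]
    dy = Y - cy
    dx = X - cx
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)

    # radial extent of the original region per angular bin; the bin count
    # adapts to the region size so every bin sees ~1 px of boundary arc
    r_max = float(np.hypot(rows - cy, cols - cx).max())
    nbins = int(np.clip(2 * np.pi * r_max, 36, 720))
    bins = ((theta + np.pi) / (2 * np.pi) * nbins).astype(int) % nbins
    r_pix = np.hypot(rows - cy, cols - cx)
    theta_pix = np.arctan2(rows - cy, cols - cx)
    bin_pix = ((theta_pix + np.pi) / (2 * np.pi) * nbins).astype(int) % nbins
    radius_of = np.zeros(nbins)
    np.maximum.at(radius_of, bin_pix, r_pix)
    # fill empty bins by circular interpolation from occupied neighbours
    occupied = radius_of > 0
    if not occupied.all():
        idx = np.arange(nbins)
        radius_of = np.interp(
            idx, idx[occupied], radius_of[occupied], period=nbins
        )

    norm = 1.0 / np.sqrt(1.0 + amplitude * amplitude / 2.0)
    modulation = norm * (1.0 + amplitude * np.cos(lobes * theta + phase))
    return r <= (radius_of[bins] + 0.5) * modulation


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

def _blank_frame(grid: GridSpec, params: RenderParams) -> tuple[np.ndarray, np.ndarray]:
    """Background-filled float frame and the boolean tissue-region mask."""
    npx_x = int(round(grid.width * params.pixels_per_mm))
    npx_y = int(round(grid.height * params.pixels_per_mm))
    img = np.empty((npx_y, npx_x, 3), dtype=np.float64)
    img[:] = params.background_color
    tissue = np.ones((npx_y, npx_x), dtype=bool)
    if params.ruler is not None:
        tissue[-params.ruler.band_height_px :, :] = False
    return img, tissue


def _draw_ruler(img: np.ndarray, params: RenderParams) -> None:
    """White band with black millimetre ticks along the bottom of the frame."""
    spec = params.ruler
    if spec is None:
        return
    band = img[-spec.band_height_px :, :, :]
    band[:] = (250, 250, 250)
    npx_x = img.shape[1]
    pitch = spec.tick_spacing_mm * params.pixels_per_mm
    k = 1
    while True:
        col = int(round(k * pitch))
        if col >= npx_x - 1:
            break
        band[:, col, :] = (10, 10, 10)
        k += 1


def _finalize(img: np.ndarray, params: RenderParams,
              rng: np.random.Generator) -> np.ndarray:
    """Add i.i.d. Gaussian channel noise and quantise to uint8."""
    if params.noise_sigma > 0:
        img = img + rng.normal(0.0, params.noise_sigma, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _px_area_cm2(count: int, pixels_per_mm: float) -> float:
    return count / (pixels_per_mm**2) / 100.0


def render_ttc(
    zones: AblationZones,
    params: RenderParams | None = None,
    star: StarParams | None = DEFAULT_TTC_STAR,
    seed: int = 0,
    staining_delay_h: float = TTC_DEFAULT_DELAY_H,
    kin: KineticsParams | None = None,
    area_jitter: tuple[float, float] = (1.0, 1.0),
) -> StainImageBundle:
    """Render a TTC-stained slice: white IRE core, deep-red RE annulus.

    The zone masks are rasterized at ``params.pixels_per_mm``, optionally
    star-distorted, the red annulus is shrunk according to the staining
    delay (:func:`red_area_at`), replicate jitter rescales both regions,
    and seeded Gaussian noise is added after the ground truth is frozen.

    ``area_jitter`` gives the multiplicative factors for (IRE area, outer
    = IRE + RE area); :func:`generate_experiment` draws them from the
    replicate-noise model.
    """
    params = params or RenderParams()
    kin = kin or KineticsParams()
    rng = np.random.default_rng(seed)

    ire_px = rasterize_zone_mask(zones.ire_mask, zones.grid, params.pixels_per_mm)
    outer_px = rasterize_zone_mask(zones.ire_mask | zones.re_mask, zones.grid,
                                   params.pixels_per_mm)
    img, tissue = _blank_frame(zones.grid, params)
    if ire_px.shape != img.shape[:2]:
        raise ValueError("zone masks larger than the rendered frame")
    ire_px &= tissue
    outer_px &= tissue

    if star is not None and star.amplitude > 0:
        star_seed = derive_seed(seed, "star")
        ire_px = apply_star_distortion(ire_px, star.amplitude, star.lobes, star_seed) & tissue
        outer_px = apply_star_distortion(outer_px, star.amplitude, star.lobes, star_seed) & tissue
        outer_px |= ire_px

    f_ire, f_outer = area_jitter
    ire_target = int(round(ire_px.sum() * f_ire))
    ire_px = resize_mask_to_area(ire_px, ire_target, allowed=tissue)
    red_initial = max(int(round(outer_px.sum() * f_outer)) - ire_target, 0)
    red_target = int(round(
        red_initial * np.exp(-staining_delay_h / kin.red_decay_tau_h)
    ))
    # membrane resealing proceeds from the annulus rim inward: keep the
    # red pixels closest to the white core until the target count is met
    red_full = (outer_px | ire_px) & ~ire_px
    n_red_full = int(red_full.sum())
    if red_target >= n_red_full:
        red_px = red_full
    elif red_target <= 0:
        red_px = np.zeros_like(red_full)
    elif ire_px.any():
        d_core = ndimage.distance_transform_edt(~ire_px)
        flat = np.where(red_full.ravel(), d_core.ravel(), np.inf)
        order = np.lexsort((np.arange(flat.size), flat))
        red_px = np.zeros(flat.size, dtype=bool)
        red_px[order[:red_target]] = True
        red_px = red_px.reshape(red_full.shape)
    else:
        red_px = resize_mask_to_area(red_full, red_target, allowed=tissue)

    img[red_px] = params.deep_red_color
    img[ire_px] = params.white_core_color
    _draw_ruler(img, params)

    truth_masks = {"white": ire_px, "red": red_px}
    truth_areas = {
        "white": _px_area_cm2(int(ire_px.sum()), params.pixels_per_mm),
        "red": _px_area_cm2(int(red_px.sum()), params.pixels_per_mm),
    }
    return StainImageBundle(
        image=_finalize(img, params, rng),
        truth_masks=truth_masks,
        truth_areas=truth_areas,
        pixels_per_mm=params.pixels_per_mm,
        seed=seed,
        condition=(zones.voltage, "ttc", staining_delay_h),
    )


def render_melanin(
    zones: AblationZones,
    time_h: float,
    params: RenderParams | None = None,
    kin: KineticsParams | None = None,
    star: StarParams | None = DEFAULT_MELANIN_STAR,
    seed: int = 0,
    area_jitter: float = 1.0,
) -> StainImageBundle:
    """Render a melanin-accumulation slice ``time_h`` hours after pulsing.

    The blackened region is the (optionally star-distorted) IRE mask
    shrunk so its area equals :func:`melanin_area_at`; its darkness ramps
    with the same kinetics, so early timepoints are both smaller and
    fainter.  No red annulus exists in this modality.
    """
    if time_h < 0:
        raise ValueError("time must be non-negative")
    params = params or RenderParams()
    kin = kin or KineticsParams()
    rng = np.random.default_rng(seed)

    ire_px = rasterize_zone_mask(zones.ire_mask, zones.grid, params.pixels_per_mm)
    img, tissue = _blank_frame(zones.grid, params)
    if ire_px.shape != img.shape[:2]:
        raise ValueError("zone masks larger than the rendered frame")
    ire_px &= tissue

    if star is not None and star.amplitude > 0:
        star_seed = derive_seed(seed, "star")
        ire_px = apply_star_distortion(ire_px, star.amplitude, star.lobes, star_seed) & tissue

    final_px = int(round(ire_px.sum() * area_jitter))
    final_area = _px_area_cm2(final_px, params.pixels_per_mm)
    target_area = melanin_area_at(final_area, time_h, kin)
    target_px = int(round(target_area * 100.0 * params.pixels_per_mm**2))
    mel_px = resize_mask_to_area(ire_px, target_px, allowed=tissue)

    # darkness follows the same saturation curve as the area
    alpha = 0.0 if final_area == 0 else target_area / final_area
    bg = np.array(params.background_color, dtype=float)
    mel = np.array(params.melanin_color, dtype=float)
    img[mel_px] = (1 - alpha) * bg + alpha * mel
    _draw_ruler(img, params)

    truth_masks = {"melanin": mel_px}
    truth_areas = {"melanin": _px_area_cm2(int(mel_px.sum()), params.pixels_per_mm)}
    return StainImageBundle(
        image=_finalize(img, params, rng),
        truth_masks=truth_masks,
        truth_areas=truth_areas,
        pixels_per_mm=params.pixels_per_mm,
        seed=seed,
        condition=(zones.voltage, "melanin", time_h),
    )


# --------------------------------------------------------------------------
# whole-experiment generation
# --------------------------------------------------------------------------

def default_conditions(
    voltages: Sequence[float] = DEFAULT_VOLTAGES,
) -> list[tuple[float, str, float]]:
    """Standard condition grid: TTC at a 5-min delay and melanin at 48 h."""
    conditions = [(float(v), "ttc", TTC_DEFAULT_DELAY_H) for v in voltages]
    conditions += [(float(v), "melanin", MELANIN_DEFAULT_TIME_H) for v in voltages]
    return conditions


def condition_id(voltage: float, modality: str, time_h: float) -> str:
    return f"{voltage:g}Vcm-{modality}-{time_h:g}h"


def solve_zones_by_voltage(
    voltages: Sequence[float],
    grid: GridSpec | None = None,
    electrode: ElectrodeConfig | None = None,
    ire_threshold: float = 250.0,
    re_threshold: float = 100.0,
) -> dict[float, AblationZones]:
    """Predict ablation zones for each voltage with a single linear solve.

    The potential problem is linear in the applied voltage, so the field
    is solved once at the highest setting and rescaled.
    """
    voltages = sorted({float(v) for v in voltages})
    if not voltages:
        raise ValueError("voltage list must be non-empty")
    grid = grid or GridSpec()
    ref_v = voltages[-1]
    base = electrode or ElectrodeConfig(applied_voltage_V0=ref_v)
    if base.applied_voltage_V0 != ref_v:
        base = replace(base, applied_voltage_V0=ref_v)
    fm_ref = field_magnitude(solve_laplace(base, grid))
    return {
        v: predict_zones(fm_ref.rescaled(v), ire_threshold, re_threshold)
        for v in voltages
    }


def _replicate_jitter(seed: int, cv: float) -> tuple[float, float]:
    """(IRE factor, outer factor) lognormal jitter for one replicate."""
    rng = np.random.default_rng(seed)
    return _lognormal_factor(rng, cv), _lognormal_factor(rng, cv)


def generate_experiment(
    conditions: Sequence[tuple[float, str, float]] | None = None,
    reps: int = 3,
    kin: KineticsParams | None = None,
    params: RenderParams | None = None,
    electrical_params=None,
    master_seed: int = 0,
    grid: GridSpec | None = None,
    electrode: ElectrodeConfig | None = None,
    ire_threshold: float = 250.0,
    re_threshold: float = 100.0,
    zones_by_voltage: dict[float, AblationZones] | None = None,
    melanin_star: StarParams | None = DEFAULT_MELANIN_STAR,
    ttc_star: StarParams | None = DEFAULT_TTC_STAR,
) -> ExperimentBundle:
    """Generate a complete seeded experiment: images, truth and electrical data.

    For every condition x replicate the field is solved (one linear solve,
    cached across voltages), zones predicted, replicate area jitter drawn,
    the slice image rendered, and matching electrical records generated.
    Electrical records are shared between the two modalities of the same
    (voltage, replicate) — one pulsing treats both slice halves.
    """
    from . import electrical as elec_mod

    if conditions is None:
        conditions = default_conditions()
    if len(conditions) == 0:
        raise ValueError("condition list must be non-empty")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    kin = kin or KineticsParams()
    params = params or RenderParams()
    eparams = electrical_params or elec_mod.ElectricalParams()
    grid = grid or GridSpec()

    if zones_by_voltage is None:
        zones_by_voltage = solve_zones_by_voltage(
            [v for v, _, _ in conditions], grid, electrode,
            ire_threshold, re_threshold,
        )

    bundles: list[StainImageBundle] = []
    truth_rows = []
    elec_rows = []
    elec_cache: dict[tuple[float, int], dict] = {}

    for voltage, modality, time_h in conditions:
        zones = zones_by_voltage[float(voltage)]
        cid = condition_id(voltage, modality, time_h)
        for rep in range(1, reps + 1):
            item_seed = derive_seed(master_seed, cid, rep)
            # jitter is drawn per modality: the two readouts come from
            # different halves of the slice, so their replicate noise is
            # independent
            f_ire, f_outer = _replicate_jitter(
                derive_seed(master_seed, f"{voltage:g}Vcm-{modality}-area", rep),
                kin.rep_noise_cv,
            )
            key = (float(voltage), rep)
            if key not in elec_cache:
                eseed = derive_seed(master_seed, f"{voltage:g}Vcm-elec", rep)
                trace = elec_mod.simulate_current_train(
                    elec_mod.PulseProtocol(field_setting=voltage), eparams, eseed
                )
                cond = elec_mod.generate_conductivity(
                    voltage, eparams, derive_seed(eseed, "sigma")
                )
                elec_cache[key] = {
                    "voltage_vcm": voltage,
                    "rep": rep,
                    "i_first_A": trace.per_pulse_amplitude[0],
                    "i_last_A": trace.per_pulse_amplitude[-1],
                    "sigma_before": cond.sigma_before,
                    "sigma_after": cond.sigma_after,
                    "ratio": cond.ratio,
                    "seed": eseed,
                }
                elec_rows.append(elec_cache[key])
            erec = elec_cache[key]

            if modality == "ttc":
                bundle = render_ttc(
                    zones, params, star=ttc_star, seed=item_seed,
                    staining_delay_h=time_h, kin=kin,
                    area_jitter=(f_ire, f_outer),
                )
                ire_cm2 = bundle.truth_areas["white"]
                re_cm2 = bundle.truth_areas["red"]
            elif modality == "melanin":
                bundle = render_melanin(
                    zones, time_h, params, kin, star=melanin_star,
                    seed=item_seed, area_jitter=f_ire,
                )
                ire_cm2 = bundle.truth_areas["melanin"]
                re_cm2 = 0.0
            else:
                raise ValueError(f"unknown modality: {modality!r}")

            bundles.append(bundle)
            truth_rows.append({
                "condition_id": cid,
                "voltage_vcm": voltage,
                "modality": modality,
                "time_h": time_h,
                "rep": rep,
                "truth_ire_cm2": ire_cm2,
                "truth_re_cm2": re_cm2,
                "current_A": erec["i_last_A"],
                "conductivity_ratio": erec["ratio"],
                "seed": item_seed,
            })

    return ExperimentBundle(
        bundles=bundles,
        truth_table=pd.DataFrame(truth_rows),
        electrical_table=pd.DataFrame(elec_rows),
        master_seed=master_seed,
    )


def generate_measurement_table(
    voltages: Sequence[float] = DEFAULT_VOLTAGES,
    reps: int = 3,
    kin: KineticsParams | None = None,
    electrical_params=None,
    master_seed: int = 0,
    zones_by_voltage: dict[float, AblationZones] | None = None,
    grid: GridSpec | None = None,
    melanin_time_h: float = MELANIN_DEFAULT_TIME_H,
    ttc_delay_h: float = TTC_DEFAULT_DELAY_H,
) -> pd.DataFrame:
    """Ground-truth measurement table without rendering any images.

    One row per (voltage, replicate) with the melanin, TTC-white and
    TTC-red areas plus matched electrical observables — the wide-format
    input of the statistics layer.  Uses the same per-item seeds and
    jitter draws as :func:`generate_experiment`, so the scalar truth
    matches the rendered truth up to pixel quantisation.
    """
    from . import electrical as elec_mod

    kin = kin or KineticsParams()
    eparams = electrical_params or elec_mod.ElectricalParams()
    if zones_by_voltage is None:
        zones_by_voltage = solve_zones_by_voltage(voltages, grid)

    rows = []
    for voltage in sorted({float(v) for v in voltages}):
        zones = zones_by_voltage[voltage]
        for rep in range(1, reps + 1):
            f_ire, f_outer = _replicate_jitter(
                derive_seed(master_seed, f"{voltage:g}Vcm-ttc-area", rep),
                kin.rep_noise_cv,
            )
            f_mel, _ = _replicate_jitter(
                derive_seed(master_seed, f"{voltage:g}Vcm-melanin-area", rep),
                kin.rep_noise_cv,
            )
            white = zones.ire_area * f_ire
            red_initial = max((zones.ire_area + zones.re_area) * f_outer - white, 0.0)
            red = red_area_at(red_initial, ttc_delay_h, kin)
            melanin = melanin_area_at(zones.ire_area * f_mel, melanin_time_h, kin)

            eseed = derive_seed(master_seed, f"{voltage:g}Vcm-elec", rep)
            trace = elec_mod.simulate_current_train(
                elec_mod.PulseProtocol(field_setting=voltage), eparams, eseed
            )
            cond = elec_mod.generate_conductivity(
                voltage, eparams, derive_seed(eseed, "sigma")
            )
            rows.append({
                "condition_id": f"{voltage:g}Vcm",
                "voltage_vcm": voltage,
                "rep": rep,
                "melanin_area_cm2": melanin,
                "ttc_white_area_cm2": white,
                "ttc_red_area_cm2": red,
                "current_A": trace.per_pulse_amplitude[-1],
                "conductivity_ratio": cond.ratio,
            })
    return pd.DataFrame(rows)
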