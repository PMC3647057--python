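"""Digital kidney phantoms: a 2D longitudinal section with four nested compartments.

The phantom is a labelled 256x128 grid (100x50 mm field of view by default,
0.39 mm nominal pixels) partitioned into cortex (CTX), outer stripe (OS) and
inner stripe (IS) of the outer medulla, and inner medulla (IM), modelled as
concentric elliptical bands. Each compartment carries scalar ground-truth T2*
(ms) and ADC (10^-3 mm^2/s) drawn from a condition preset, plus an optional
red-cell-congestion (RCC) mask of blob-like lesions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .presets import COMPARTMENTS, ConditionPreset, GaussianParam

LABELS = {"CTX": 1, "OS": 2, "IS": 3, "IM": 4}
LABEL_NAMES = {v: k for k, v in LABELS.items()}

# Cumulative kidney-area fractions from the innermost band outward
# (IM:IS:OS:CTX = 30:15:15:40). An elliptical band at normalized radius t
# encloses area fraction t^2, so band edges sit at sqrt of the cumulative
# fractions.
_AREA_CUM = {"IM": 0.30, "IS": 0.45, "OS": 0.60, "CTX": 1.00}

DEFAULT_GRID = (256, 128)
DEFAULT_FOV_MM = (100.0, 50.0)
DEFAULT_S0 = 1000.0


@dataclass
class KidneyPhantom:
    """Label map plus per-compartment ground-truth parameter fields.

    label_map: 0=background, 1=CTX, 2=OS, 3=IS, 4=IM. t2star_map in ms,
    adc_map in 10^-3 mm^2/s (== 10^-9 m^2/s), s0_map in arbitrary units.
    """

    label_map: np.ndarray
    s0_map: np.ndarray
    t2star_map: np.ndarray
    adc_map: np.ndarray
    rcc_mask: np.ndarray
    pixel_size: tuple[float, float]
    seed: int
    condition: str = "CD0h"
    perfusion: str = "none"
    compartment_values: dict = field(default_factory=dict)

    @property
    def kidney_mask(self) -> np.ndarray:
        return self.label_map > 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_map.shape

    def validate(self) -> None:
        """Raise AssertionError if any structural invariant is violated."""
        kid = self.kidney_mask
        labels = np.unique(self.label_map[kid])
        assert np.all((labels >= 1) & (labels <= 4)), "kidney labels outside 1..4"
        assert not np.any(self.rcc_mask & ~kid), "RCC mask leaks outside kidney"
        assert np.all(self.t2star_map[kid] > 0), "non-positive T2* in kidney"
        assert np.all(self.adc_map[kid] >= 0), "negative ADC in kidney"


def _elliptical_radius(shape: tuple[int, int]) -> np.ndarray:
    """Normalized elliptical radius of each pixel center (kidney boundary at 1)."""
    n0, n1 = shape
    i, j = np.ogrid[:n0, :n1]
    c0, c1 = (n0 - 1) / 2.0, (n1 - 1) / 2.0
    a, b = 0.46 * n0, 0.42 * n1  # kidney semi-axes in pixels
    return np.sqrt(((i - c0) / a) ** 2 + ((j - c1) / b) ** 2)


def make_label_map(shape: tuple[int, int] = DEFAULT_GRID) -> np.ndarray:
    """Concentric four-band compartment labelling of an elliptical kidney."""
    r = _elliptical_radius(shape)
    label = np.zeros(shape, dtype=np.int8)
    kid = r <= 1.0
    label[kid] = LABELS["CTX"]
    label[r <= np.sqrt(_AREA_CUM["OS"])] = LABELS["OS"]
    label[r <= np.sqrt(_AREA_CUM["IS"])] = LABELS["IS"]
    label[r <= np.sqrt(_AREA_CUM["IM"])] = LABELS["IM"]
    label[~kid] = 0
    return label


def _blobby_mask(
    region: np.ndarray, fraction: float, rng: np.random.Generator, smooth_sigma: float = 2.0
) -> np.ndarray:
    """Select ~fraction of region's pixels as contiguous blobs.

    Thresholds a smoothed Gaussian random field at the exact count quantile,
    so the realized fraction matches the request to the nearest pixel.
    """
    mask = np.zeros(region.shape, dtype=bool)
    n = int(region.sum())
    k = int(round(fraction * n))
    if k == 0:
        return mask
    feld = gaussian_filter(rng.standard_normal(region.shape), smooth_sigma)
    vals = feld[region]
    # top-k pixels of the smooth field inside the region
    cutoff = np.partition(vals, n - k)[n - k]
    sel = region & (feld >= cutoff)
    # ties at the cutoff can overshoot by a pixel or two; trim deterministically
    extra = int(sel.sum()) - k
    if extra > 0:
        idx = np.flatnonzero(sel.ravel() & (feld.ravel() == cutoff))[:extra]
        flat = sel.ravel()
        flat[idx] = False
        sel = flat.reshape(region.shape)
    mask |= sel
    return mask


def _sample_positive(rng: np.random.Generator, p: GaussianParam) -> float:
    """Draw Normal(mean, sd) truncated to positive values (resampling)."""
    if p.sd == 0:
        return p.mean
    for _ in range(1000):
        v = rng.normal(p.mean, p.sd)
        if v > 0:
            return float(v)
    raise RuntimeError("could not draw a positive parameter value")


def make_kidney_phantom(
    grid: tuple[int, int] = DEFAULT_GRID,
    fov_mm: tuple[float, float] = DEFAULT_FOV_MM,
    preset: ConditionPreset | None = None,
    seed: int = 0,
    s0: float = DEFAULT_S0,
) -> KidneyPhantom:
    """Build one kidney phantom from a condition preset.

    Per-compartment T2*/ADC values are drawn once per phantom from the preset
    (mean, SD); with zero SDs the maps carry the preset means exactly. The RCC
    mask covers preset.rcc_severity of each compartment's pixels as blobs, and
    T2* inside the mask is multiplied by preset.rcc_t2star_factor.
    """
    if len(grid) != 2 or min(grid) < 32:
        raise ValueError(f"matrix dims must be >= 32x32, got {grid}")
    if min(fov_mm) <= 0:
        raise ValueError(f"FOV must be positive, got {fov_mm}")
    if preset is None:
        from .presets import table_preset

        preset = table_preset("CD0h")

    rng = np.random.default_rng(seed)
    label = make_label_map(tuple(grid))
    kid = label > 0

    t2star = np.zeros(label.shape, dtype=np.float64)
    adc = np.zeros(label.shape, dtype=np.float64)
    s0_map = np.where(kid, float(s0), 0.0)
    rcc = np.zeros(label.shape, dtype=bool)

    comp_values: dict[str, dict[str, float]] = {}
    for comp in COMPARTMENTS:
        region = label == LABELS[comp]
        t2_val = _sample_positive(rng, preset.t2star[comp])
        adc_val = max(0.0, _sample_positive(rng, preset.adc[comp]))
        t2star[region] = t2_val
        adc[region] = adc_val
        comp_values[comp] = {"t2star_ms": t2_val, "adc_e3mm2s": adc_val}
        sev = preset.rcc_severity.get(comp, 0.0)
        if sev > 0:
            rcc |= _blobby_mask(region, sev, rng)

    t2star[rcc] *= preset.rcc_t2star_factor

    phantom = KidneyPhantom(
        label_map=label,
        s0_map=s0_map,
        t2star_map=t2star,
        adc_map=adc,
        rcc_mask=rcc,
        pixel_size=(fov_mm[0] / grid[0], fov_mm[1] / grid[1]),
        seed=seed,
        condition=preset.condition,
        perfusion=preset.perfusion,
        compartment_values=comp_values,
    )
    phantom.validate()
    return phantom


def make_cohort(
    design: list[tuple[ConditionPreset, int]],
    seed: int = 0,
    grid: tuple[int, int] = DEFAULT_GRID,
    fov_mm: tuple[float, float] = DEFAULT_FOV_MM,
) -> list[KidneyPhantom]:
    """Generate a cohort: n_kidneys phantoms per preset, independently sampled.

    Deterministic given seed; each kidney gets its own child seed so cohorts
    are reproducible regardless of design order within a preset.
    """
    if not design:
        raise ValueError("empty cohort design")
    for preset, n in design:
        if n < 1:
            raise ValueError(f"n_kidneys must be >= 1, got {n} for {preset.condition}")
    ss = np.random.SeedSequence(seed)
    child_seeds = iter(ss.generate_state(sum(n for _, n in design)))
    cohort = []
    for preset, n in design:
        for _ in range(n):
            kid_seed = int(next(child_seeds)) % (2**31)
            cohort.append(make_kidney_phantom(grid, fov_mm, preset, seed=kid_seed))
    return cohort


# ---------------------------------------------------------------------------
# Synthetic eosin histology
# ---------------------------------------------------------------------------

@dataclass
class HistologySample:
    """Synthetic eosin-stained section with known congestion ground truth."""

    rgb_image: np.ndarray  # uint8, H x W x 3
    compartment_map: np.ndarray
    rcc_truth: np.ndarray
    stain_params: dict

    def validate(self) -> None:
        assert self.rgb_image.ndim == 3 and self.rgb_image.shape[2] == 3
        assert not np.any(self.rcc_truth & (self.compartment_map == 0)), (
            "congestion truth outside tissue"
        )


# Eosin-like rendering: pale pink tissue, saturated bright red for trapped
# erythrocytes (strongly eosinophilic), near-white lumen/background.
DEFAULT_STAIN = {
    "tissue_rgb": (225.0, 170.0, 190.0),
    "rcc_rgb": (240.0, 50.0, 60.0),
    "background_rgb": (248.0, 248.0, 248.0),
    "noise_sd": 6.0,
}


def make_histology_sample(
    compartment_map: np.ndarray,
    rcc_fraction: dict[str, float],
    seed: int = 0,
    stain_params: dict | None = None,
) -> HistologySample:
    """Render a synthetic eosin section with per-compartment congested fractions.

    The realized congested pixel fraction per compartment matches the request
    to the nearest pixel (well within 1% for compartments of >= 1000 pixels).
    """
    for comp, frac in rcc_fraction.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"rcc_fraction[{comp}] = {frac} outside [0, 1]")
    stain = dict(DEFAULT_STAIN)
    if stain_params:
        stain.update(stain_params)

    rng = np.random.default_rng(seed)
    truth = np.zeros(compartment_map.shape, dtype=bool)
    for comp, frac in rcc_fraction.items():
        if frac == 0:
            continue
        region = compartment_map == LABELS[comp]
        truth |= _blobby_mask(region, frac, rng)

    tissue = compartment_map > 0
    img = np.empty(compartment_map.shape + (3,), dtype=np.float64)
    img[...] = stain["background_rgb"]
    img[tissue] = stain["tissue_rgb"]
    img[truth] = stain["rcc_rgb"]
    img += rng.normal(0.0, stain["noise_sd"], size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    sample = HistologySample(
        rgb_image=img, compartment_map=compartment_map, rcc_truth=truth, stain_params=stain
    )
    sample.validate()
    return sample
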