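"""Parameter mapping: per-pixel T2* and ADC estimation, and the SI-ratio statistic.

T2* comes from a log-linear least-squares fit of monoexponential decay across
echoes; ADC from the standard two-point formula ln(S_low/S_high)/(b_high-b_low).
Non-physical estimates (non-positive signal, negative ADC, non-positive T2*)
are masked invalid rather than clipped, so downstream region statistics can
exclude and count them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal import ImageStack

MAP_KINDS = ("t2star_ms", "adc_e3mm2s", "si_au", "si_ratio")


@dataclass
class ParameterMap:
    """2D quantitative map with per-pixel validity.

    kind: t2star_ms | adc_e3mm2s | si_au | si_ratio. Invalid pixels hold NaN
    in `values`; `diagnostics` may carry the unmasked estimate (e.g. negative
    ADC) for QC.
    """

    values: np.ndarray
    kind: str
    valid_mask: np.ndarray
    diagnostics: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in MAP_KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}")
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values/valid_mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def fit_t2star(stack: ImageStack) -> ParameterMap:
    """Per-pixel monoexponential T2* by least squares on log-signal.

    ln S = ln S0 - TE/T2*; the slope over >= 2 distinct echoes gives
    T2* = -1/slope. Exact on noiseless data. Pixels with any non-positive
    signal, or with a non-negative fitted slope (T2* <= 0), are invalid.
    """
    te = stack.contrast_axis
    if stack.kind != "gre":
        raise ValueError(f"expected a gradient-echo stack, got kind {stack.kind!r}")
    if te.size < 2 or np.unique(te).size < 2:
        raise ValueError(
            "T2* fitting needs >= 2 distinct echo times; with a single echo use "
            "signal-intensity (SI) analysis instead"
        )
    positive = np.all(stack.data > 0, axis=0)
    log_s = np.where(stack.data > 0, np.log(np.where(stack.data > 0, stack.data, 1.0)), 0.0)
    te_c = te - te.mean()
    denom = float(np.sum(te_c**2))
    slope = np.tensordot(te_c, log_s - log_s.mean(axis=0), axes=(0, 0)) / denom
    with np.errstate(divide="ignore", invalid="ignore"):
        t2star = -1.0 / slope
    valid = positive & (slope < 0)
    values = np.where(valid, t2star, np.nan)
    return ParameterMap(values=values, kind="t2star_ms", valid_mask=valid, diagnostics=t2star)


def compute_adc_map(stack: ImageStack, b_low: float = 0.0, b_high: float = 134.0) -> ParameterMap:
    """Two-point ADC map in 10^-3 mm^2/s: ln(S_low/S_high)/(b_high - b_low).

    Pixels where either signal is non-positive are invalid; pixels where
    S_high > S_low (negative ADC, unphysical for pure diffusion) are invalid
    but keep their raw estimate in the diagnostics channel.
    """
    if stack.kind != "dwi":
        raise ValueError(f"expected a diffusion-weighted stack, got kind {stack.kind!r}")
    if b_high <= b_low:
        raise ValueError("b_high must exceed b_low")
    s_low = stack.frame_at(b_low)
    s_high = stack.frame_at(b_high)
    positive = (s_low > 0) & (s_high > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        adc_mm2s = np.log(np.where(positive, s_low, 1.0) / np.where(positive, s_high, 1.0)) / (
            b_high - b_low
        )
    adc = adc_mm2s * 1e3  # report in 10^-3 mm^2/s
    valid = positive & (adc >= 0)
    values = np.where(valid, adc, np.nan)
    diagnostics = np.where(positive, adc, np.nan)
    return ParameterMap(values=values, kind="adc_e3mm2s", valid_mask=valid, diagnostics=diagnostics)


def compute_si_map(stack: ImageStack, te_ms: float | None = None) -> ParameterMap:
    """Single-echo T2*-weighted signal-intensity map (arbitrary units)."""
    if stack.kind != "gre":
        raise ValueError(f"expected a gradient-echo stack, got kind {stack.kind!r}")
    frame = stack.frame_at(te_ms) if te_ms is not None else stack.data[0]
    valid = np.isfinite(frame)
    return ParameterMap(values=frame.copy(), kind="si_au", valid_mask=valid)


def compute_si_ratio(
    group_values: np.ndarray | list[float], reference_values: np.ndarray | list[float]
) -> np.ndarray:
    """Per-kidney SI ratio: each kidney's compartment SI divided by the mean
    compartment SI of the reference (CD0h) group.

    Inputs are per-kidney compartment mean signal intensities for one
    compartment; returns one ratio per kidney in `group_values`.
    """
    ref = np.asarray(reference_values, dtype=float)
    if ref.size == 0:
        raise ValueError("reference group is empty")
    ref_mean = ref.mean()
    if ref_mean == 0 or not np.isfinite(ref_mean):
        raise ValueError("reference group mean is zero or non-finite")
    return np.asarray(group_values, dtype=float) / ref_mean
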