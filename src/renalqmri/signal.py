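"""Forward MR signal models: multi-echo gradient echo (BOLD) and two-point DWI.

Gradient-echo magnitude signal follows monoexponential T2* decay,
S(TE) = S0_eff * exp(-TE / T2*), with proton density and steady-state
(TR / flip-angle) weighting folded into the single multiplicative field
S0_eff — the analyses of interest are T2*- and diffusion-driven, and each
sequence is acquired at one TR/flip setting. Diffusion-weighted signal is
S(b) = S0_eff * exp(-b * ADC).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import KidneyPhantom

NOISE_MODELS = ("none", "gaussian", "rician")


@dataclass(frozen=True)
class AcquisitionConfig:
    """Sequence settings; defaults match a gradient-echo BOLD protocol
    (TR 30 ms, TE 10 ms, flip 13 deg, 256x128 over 100x50 mm, 1 mm slice,
    two averages)."""

    tr_ms: float = 30.0
    te_list_ms: tuple[float, ...] = (10.0,)
    flip_angle_deg: float = 13.0
    b_values: tuple[float, ...] = (0.0, 134.0)
    matrix: tuple[int, int] = (256, 128)
    fov_mm: tuple[float, float] = (100.0, 50.0)
    slice_thickness_mm: float = 1.0
    n_averages: int = 2
    noise_sigma: float = 0.0
    noise_model: str = "rician"
    seed: int = 0

    def __post_init__(self) -> None:
        te = np.asarray(self.te_list_ms, dtype=float)
        if te.size < 1 or np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ValueError("te_list_ms must be positive and strictly increasing")
        b = np.asarray(self.b_values, dtype=float)
        if np.any(b < 0):
            raise ValueError("b_values must be non-negative")
        if self.n_averages < 1:
            raise ValueError("n_averages must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"unknown noise model {self.noise_model!r}")


@dataclass
class ImageStack:
    """Multi-contrast image series: data[frame, row, col] with the TE (ms) or
    b-value (s/mm^2) of each frame on contrast_axis."""

    data: np.ndarray
    contrast_axis: np.ndarray
    contrast_unit: str  # "ms" or "s/mm^2"
    kind: str  # "gre" | "dwi"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.contrast_axis = np.asarray(self.contrast_axis, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("ImageStack data must be 3D (contrast, rows, cols)")
        if self.data.shape[0] != self.contrast_axis.size:
            raise ValueError("frame count does not match contrast_axis length")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def frame_at(self, value: float) -> np.ndarray:
        """Frame whose contrast value equals `value` (exact match)."""
        idx = np.flatnonzero(np.isclose(self.contrast_axis, value))
        if idx.size == 0:
            raise KeyError(f"no frame at contrast value {value}")
        return self.data[idx[0]]


def _check_grid(phantom: KidneyPhantom, acq: AcquisitionConfig) -> None:
    if tuple(phantom.shape) != tuple(acq.matrix):
        raise ValueError(
            f"phantom grid {phantom.shape} does not match acquisition matrix {acq.matrix}"
        )


def simulate_gre(phantom: KidneyPhantom, acq: AcquisitionConfig) -> ImageStack:
    """Noiseless multi-echo gradient-echo stack: S0_eff * exp(-TE/T2*).

    The phantom's t2star_map already carries any congestion-related reduction;
    background pixels stay zero. Apply measurement noise separately with
    add_noise.
    """
    _check_grid(phantom, acq)
    te = np.asarray(acq.te_list_ms, dtype=float)
    kid = phantom.kidney_mask
    data = np.zeros((te.size,) + phantom.shape)
    with np.errstate(divide="ignore"):
        inv_t2 = np.where(kid, 1.0 / np.where(kid, phantom.t2star_map, 1.0), 0.0)
    for i, t in enumerate(te):
        data[i] = phantom.s0_map * np.exp(-t * inv_t2)
        data[i][~kid] = 0.0
    return ImageStack(data=data, contrast_axis=te, contrast_unit="ms", kind="gre")


def simulate_dwi(phantom: KidneyPhantom, acq: AcquisitionConfig) -> ImageStack:
    """Noiseless diffusion-weighted stack: S0_eff * exp(-b * ADC).

    ADC maps are stored in 10^-3 mm^2/s, so the exponent uses adc_map * 1e-3
    with b in s/mm^2. Requires at least two b-values including b=0.
    """
    _check_grid(phantom, acq)
    b = np.asarray(acq.b_values, dtype=float)
    if b.size < 2 or not np.any(b == 0):
        raise ValueError("DWI simulation needs >= 2 b-values including 0")
    if np.any(b < 0):
        raise ValueError("b_values must be non-negative")
    adc_mm2s = phantom.adc_map * 1e-3
    data = np.stack([phantom.s0_map * np.exp(-bv * adc_mm2s) for bv in b])
    data[:, ~phantom.kidney_mask] = 0.0
    return ImageStack(data=data, contrast_axis=b, contrast_unit="s/mm^2", kind="dwi")


def add_noise(
    stack: ImageStack,
    sigma: float,
    model: str = "rician",
    seed: int = 0,
    n_averages: int = 1,
) -> ImageStack:
    """Noisy copy of a stack; n_averages independent acquisitions are averaged
    (Gaussian noise SD then scales as sigma/sqrt(n)).

    gaussian: S + N(0, sigma). rician: magnitude reconstruction
    sqrt((S + e1)^2 + e2^2), e1, e2 ~ N(0, sigma) — the correct model for
    magnitude MR images, with Rayleigh-distributed background.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if n_averages < 1:
        raise ValueError("n_averages must be >= 1")
    if model not in NOISE_MODELS:
        raise ValueError(f"unknown noise model {model!r}; expected one of {NOISE_MODELS}")
    if sigma == 0 or model == "none":
        return ImageStack(
            data=stack.data.copy(),
            contrast_axis=stack.contrast_axis.copy(),
            contrast_unit=stack.contrast_unit,
            kind=stack.kind,
        )
    rng = np.random.default_rng(seed)
    acc = np.zeros_like(stack.data)
    for _ in range(n_averages):
        if model == "gaussian":
            acc += stack.data + rng.normal(0.0, sigma, size=stack.data.shape)
        else:  # rician
            e1 = rng.normal(0.0, sigma, size=stack.data.shape)
            e2 = rng.normal(0.0, sigma, size=stack.data.shape)
            acc += np.sqrt((stack.data + e1) ** 2 + e2**2)
    return ImageStack(
        data=acc / n_averages,
        contrast_axis=stack.contrast_axis.copy(),
        contrast_unit=stack.contrast_unit,
        kind=stack.kind,
    )
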