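"""Readers/writers: image stacks and parameter maps as multi-page TIFF with a
JSON sidecar or as NIfTI, plus condition presets from INI-style config files.

TIFF pages (or the NIfTI 3rd dimension) hold one frame per contrast value;
the sidecar carries the contrast axis, its unit and the stack kind so a
round-trip is lossless for both pixels and metadata.
"""

from __future__ import annotations

import configparser
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from .mapping import ParameterMap
from .phantom import KidneyPhantom
from .presets import COMPARTMENTS, ConditionPreset, GaussianParam
from .signal import ImageStack

FORMATS = ("tiff", "nifti")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ImageStack, path: str | Path, format: str = "tiff") -> Path:
    """Serialize an ImageStack; returns the primary file path."""
    path = Path(path)
    meta = {
        "contrast_axis": [float(v) for v in stack.contrast_axis],
        "contrast_unit": stack.contrast_unit,
        "kind": stack.kind,
    }
    if format == "tiff":
        tifffile.imwrite(path, stack.data, photometric="minisblack")
    elif format == "nifti":
        # rows x cols x frames, contrast on the 3rd axis
        nib.save(nib.Nifti1Image(np.moveaxis(stack.data, 0, -1), affine=np.eye(4)), path)
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_stack(path: str | Path, format: str = "tiff") -> ImageStack:
    """Load an ImageStack written by write_stack (data + sidecar metadata)."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sidecar}")
    try:
        meta = json.loads(sidecar.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt sidecar {sidecar}: {exc}") from exc
    if format == "tiff":
        try:
            data = tifffile.imread(path)
        except Exception as exc:
            raise ValueError(f"cannot parse TIFF stack {path}: {exc}") from exc
    elif format == "nifti":
        try:
            data = np.moveaxis(np.asarray(nib.load(path).get_fdata()), -1, 0)
        except Exception as exc:
            raise ValueError(f"cannot parse NIfTI stack {path}: {exc}") from exc
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    data = np.atleast_3d(data)
    if data.shape[0] != len(meta["contrast_axis"]):
        raise ValueError("frame count disagrees with sidecar contrast_axis")
    return ImageStack(
        data=np.asarray(data, dtype=np.float64),
        contrast_axis=np.asarray(meta["contrast_axis"], dtype=float),
        contrast_unit=meta["contrast_unit"],
        kind=meta["kind"],
    )


def write_parameter_map(pmap: ParameterMap, path: str | Path, format: str = "tiff") -> Path:
    """32-bit float map plus companion 8-bit validity mask (``*_mask``)."""
    path = Path(path)
    values = pmap.values.astype(np.float32)
    mask = pmap.valid_mask.astype(np.uint8) * 255
    mask_path = path.with_name(path.stem + "_mask" + path.suffix)
    if format == "tiff":
        tifffile.imwrite(path, values, photometric="minisblack")
        tifffile.imwrite(mask_path, mask, photometric="minisblack")
    elif format == "nifti":
        nib.save(nib.Nifti1Image(values, affine=np.eye(4)), path)
        nib.save(nib.Nifti1Image(mask, affine=np.eye(4)), mask_path)
    else:
        raise ValueError(f"unknown format {format!r}")
    _sidecar_path(path).write_text(json.dumps({"kind": pmap.kind}, indent=1))
    return path


def save_phantom(phantom: KidneyPhantom, path: str | Path, format: str = "tiff") -> Path:
    """Phantom fields as a multi-page stack: label, S0, T2*, ADC, RCC mask."""
    path = Path(path)
    pages = np.stack(
        [
            phantom.label_map.astype(np.float32),
            phantom.s0_map.astype(np.float32),
            phantom.t2star_map.astype(np.float32),
            phantom.adc_map.astype(np.float32),
            phantom.rcc_mask.astype(np.float32),
        ]
    )
    meta = {
        "pages": ["label", "s0", "t2star_ms", "adc_e3mm2s", "rcc_mask"],
        "pixel_size_mm": list(phantom.pixel_size),
        "condition": phantom.condition,
        "perfusion": phantom.perfusion,
        "seed": phantom.seed,
    }
    if format == "tiff":
        tifffile.imwrite(path, pages, photometric="minisblack")
    elif format == "nifti":
        nib.save(nib.Nifti1Image(np.moveaxis(pages, 0, -1), affine=np.eye(4)), path)
    else:
        raise ValueError(f"unknown format {format!r}")
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_presets(path: str | Path) -> dict[str, ConditionPreset]:
    """Condition presets from an INI file, one section per condition.

    Section example::

        [CD0h]
        perfusion = none
        rcc_t2star_factor = 1.0
        t2star_ctx = 146.7, 10.8
        adc_ctx = 0.626, 0.043
        rcc_ctx = 0.01
        ... (os / is / im keys likewise)
    """
    cp = configparser.ConfigParser()
    read = cp.read(path)
    if not read:
        raise FileNotFoundError(path)
    presets = {}
    for section in cp.sections():
        sec = cp[section]
        t2star, adc, sev = {}, {}, {}
        for comp in COMPARTMENTS:
            key = comp.lower()
            m, s = (float(x) for x in sec[f"t2star_{key}"].split(","))
            t2star[comp] = GaussianParam(m, s)
            m, s = (float(x) for x in sec[f"adc_{key}"].split(","))
            adc[comp] = GaussianParam(m, s)
            sev[comp] = float(sec.get(f"rcc_{key}", "0"))
        presets[section] = ConditionPreset(
            condition=section,
            perfusion=sec.get("perfusion", "none"),
            t2star=t2star,
            adc=adc,
            rcc_severity=sev,
            rcc_t2star_factor=float(sec.get("rcc_t2star_factor", "1.0")),
        )
    return presets
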