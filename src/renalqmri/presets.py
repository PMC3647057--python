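"""Condition presets: per-compartment ground-truth parameters for each study arm.

Each preset couples a cardiac-death condition (CD0h/CD1h/CD2h: graft harvested
0, 1 or 2 hours after donor cardiac death) and a perfusion state with the
per-compartment (mean, SD) of T2* (ms) and ADC (10^-3 mm^2/s, numerically equal
to 10^-9 m^2/s) plus a red-cell-congestion severity per compartment. The means
and SDs are measured compartment averages (n = 3 kidneys per arm), so the T2*
values already reflect any congestion present; table-derived presets therefore
apply no additional T2* reduction inside the RCC mask (``rcc_t2star_factor=1``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

COMPARTMENTS = ("CTX", "OS", "IS", "IM")

CONDITIONS = ("CD0h", "CD1h", "CD2h")

PERFUSION_STATES = ("none", "uw_perfused", "uw_incubated")


@dataclass(frozen=True)
class GaussianParam:
    """(mean, SD) pair for one compartment parameter."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ValueError(f"parameter mean must be non-negative, got {self.mean}")
        if self.sd < 0:
            raise ValueError(f"parameter SD must be non-negative, got {self.sd}")


@dataclass(frozen=True)
class ConditionPreset:
    """Ground truth for one condition x perfusion arm.

    t2star/adc map compartment name -> (mean, SD); rcc_severity maps
    compartment name -> fraction of pixels congested, in [0, 1].
    rcc_t2star_factor multiplies T2* inside the RCC mask (1.0 = values
    already include congestion, as for measured-table presets; <1 models
    deoxyhemoglobin-driven signal loss mechanistically).
    """

    condition: str
    perfusion: str
    t2star: dict[str, GaussianParam]
    adc: dict[str, GaussianParam]
    rcc_severity: dict[str, float] = field(
        default_factory=lambda: {c: 0.0 for c in COMPARTMENTS}
    )
    rcc_t2star_factor: float = 0.35

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.perfusion not in PERFUSION_STATES:
            raise ValueError(f"unknown perfusion state {self.perfusion!r}")
        for table, unit in ((self.t2star, "T2*"), (self.adc, "ADC")):
            missing = set(COMPARTMENTS) - set(table)
            if missing:
                raise ValueError(f"{unit} preset missing compartments {sorted(missing)}")
        if any(p.mean <= 0 for p in self.t2star.values()):
            raise ValueError("T2* means must be positive")
        for comp, sev in self.rcc_severity.items():
            if not 0.0 <= sev <= 1.0:
                raise ValueError(f"rcc_severity[{comp}] = {sev} outside [0, 1]")
        if not 0.0 < self.rcc_t2star_factor <= 1.0:
            raise ValueError("rcc_t2star_factor must be in (0, 1]")

    def with_zero_sd(self) -> "ConditionPreset":
        """Copy of the preset with all biological SDs set to zero."""
        return replace(
            self,
            t2star={c: GaussianParam(p.mean, 0.0) for c, p in self.t2star.items()},
            adc={c: GaussianParam(p.mean, 0.0) for c, p in self.adc.items()},
        )


def _params(d: dict[str, tuple[float, float]]) -> dict[str, GaussianParam]:
    return {c: GaussianParam(*d[c]) for c in COMPARTMENTS}


# --- Measured compartment averages, unperfused grafts (n = 3 kidneys) ---
# T2* in ms; ADC in 10^-3 mm^2/s.

T2STAR_UNPERFUSED = {
    "CD0h": {"CTX": (146.7, 10.8), "OS": (133.5, 3.8), "IS": (146.1, 14.1), "IM": (218.1, 10.3)},
    "CD1h": {"CTX": (70.4, 1.4), "OS": (56.8, 5.2), "IS": (42.3, 5.8), "IM": (90.1, 4.0)},
    "CD2h": {"CTX": (69.9, 1.3), "OS": (58.7, 2.1), "IS": (51.3, 0.6), "IM": (84.8, 3.6)},
}

ADC_UNPERFUSED = {
    "CD0h": {"CTX": (0.626, 0.043), "OS": (0.793, 0.066), "IS": (0.665, 0.073), "IM": (0.985, 0.029)},
    "CD1h": {"CTX": (0.743, 0.070), "OS": (0.676, 0.120), "IS": (0.773, 0.067), "IM": (0.783, 0.097)},
    "CD2h": {"CTX": (0.667, 0.054), "OS": (0.558, 0.068), "IS": (0.833, 0.030), "IM": (0.840, 0.120)},
}

# --- After perfusion with University of Wisconsin (UW) solution ---

T2STAR_UW_PERFUSED = {
    "CD0h": {"CTX": (187.3, 6.6), "OS": (182.9, 13.1), "IS": (177.9, 16.5), "IM": (222.4, 9.3)},
    "CD1h": {"CTX": (140.7, 3.0), "OS": (148.5, 1.0), "IS": (143.0, 6.6), "IM": (168.7, 12.4)},
    "CD2h": {"CTX": (80.2, 5.7), "OS": (77.1, 5.0), "IS": (63.6, 2.1), "IM": (95.9, 4.0)},
}

ADC_UW_PERFUSED = {
    "CD0h": {"CTX": (0.568, 0.060), "OS": (0.543, 0.028), "IS": (0.557, 0.011), "IM": (0.983, 0.013)},
    "CD1h": {"CTX": (0.621, 0.091), "OS": (0.486, 0.068), "IS": (0.528, 0.054), "IM": (0.810, 0.060)},
    "CD2h": {"CTX": (0.897, 0.094), "OS": (0.774, 0.008), "IS": (0.671, 0.053), "IM": (0.843, 0.064)},
}

# --- CD0h graft before/after 3 h incubation in UW solution ---

T2STAR_CD0H_UW_INCUBATED = {"CTX": (87.3, 7.8), "OS": (81.4, 4.9), "IS": (87.9, 9.0), "IM": (137.6, 6.5)}
ADC_CD0H_UW_INCUBATED = {"CTX": (0.677, 0.033), "OS": (0.750, 0.057), "IS": (0.517, 0.013), "IM": (0.871, 0.011)}

# RCC pixel-fraction severities per condition (pre-transplant pattern: congestion
# concentrated in the IS for CD1h/CD2h, mild elsewhere). The source figures are
# not numeric, so these are package defaults chosen for plausible lesion loads.
RCC_SEVERITY = {
    "CD0h": {"CTX": 0.01, "OS": 0.02, "IS": 0.03, "IM": 0.02},
    "CD1h": {"CTX": 0.02, "OS": 0.04, "IS": 0.35, "IM": 0.04},
    "CD2h": {"CTX": 0.03, "OS": 0.06, "IS": 0.40, "IM": 0.06},
}

# Partial IS washout for CD1h after UW perfusion; CD2h congestion persists.
RCC_SEVERITY_UW_PERFUSED = {
    "CD0h": {"CTX": 0.01, "OS": 0.01, "IS": 0.02, "IM": 0.01},
    "CD1h": {"CTX": 0.01, "OS": 0.02, "IS": 0.12, "IM": 0.02},
    "CD2h": {"CTX": 0.02, "OS": 0.05, "IS": 0.38, "IM": 0.05},
}


def table_preset(condition: str, perfusion: str = "none") -> ConditionPreset:
    """Preset whose compartment means/SDs are the measured table values.

    Measured T2* already includes congestion, so rcc_t2star_factor is 1.0.
    """
    if perfusion == "none":
        t2, adc, sev = T2STAR_UNPERFUSED, ADC_UNPERFUSED, RCC_SEVERITY
    elif perfusion == "uw_perfused":
        t2, adc, sev = T2STAR_UW_PERFUSED, ADC_UW_PERFUSED, RCC_SEVERITY_UW_PERFUSED
    elif perfusion == "uw_incubated":
        if condition != "CD0h":
            raise ValueError("UW-incubation measurements exist only for CD0h")
        return ConditionPreset(
            condition="CD0h",
            perfusion="uw_incubated",
            t2star=_params(T2STAR_CD0H_UW_INCUBATED),
            adc=_params(ADC_CD0H_UW_INCUBATED),
            rcc_severity=dict(RCC_SEVERITY["CD0h"]),
            rcc_t2star_factor=1.0,
        )
    else:
        raise ValueError(f"unknown perfusion state {perfusion!r}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    return ConditionPreset(
        condition=condition,
        perfusion=perfusion,
        t2star=_params(t2[condition]),
        adc=_params(adc[condition]),
        rcc_severity=dict(sev[condition]),
        rcc_t2star_factor=1.0,
    )
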