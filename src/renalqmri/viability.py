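"""Graft-viability classification from the congestion/edema imaging pattern.

A graft is called non-functioning when three findings co-occur relative to a
healthy (CD0h) reference: depressed T2*-weighted SI ratio in the inner stripe
(prolonged red-cell congestion), decreased ADC in the outer stripe (cellular
edema) and increased ADC in the inner stripe (interstitial edema). Each flag
fires when the metric deviates from the reference mean by more than a margin
of `margin_sd` reference SDs in the indicated direction; comparisons are
strict, so a metric exactly on the boundary does not fire. The conjunction is
the default rule but any boolean expression over the three flags can be
configured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .roi import GroupSummary

FLAG_NAMES = ("is_si_depressed", "os_adc_decreased", "is_adc_increased")

DEFAULT_RULE = "is_si_depressed and os_adc_decreased and is_adc_increased"

# Condition -> post-transplant outcome used as ground truth when scoring the
# classifier: grafts harvested 0 or 1 h after cardiac death function, 2 h
# grafts do not.
CONDITION_OUTCOME = {"CD0h": "functioning", "CD1h": "functioning", "CD2h": "non_functioning"}


@dataclass
class ViabilityCall:
    label: str
    flags: dict[str, bool]
    thresholds: dict[str, float]
    metrics: dict[str, float]
    rule: str


@dataclass
class ViabilityReference:
    """CD0h reference statistics the thresholds are anchored to.

    is_si_ratio: SI-ratio of the reference group itself (mean 1 by
    construction when ratios are taken against the same group; its SD is the
    group's coefficient of variation). os_adc / is_adc in 10^-3 mm^2/s.
    """

    is_si_ratio: GroupSummary
    os_adc: GroupSummary
    is_adc: GroupSummary


def _eval_rule(rule: str, flags: dict[str, bool]) -> bool:
    allowed = dict(flags)
    code = compile(rule, "<viability-rule>", "eval")
    for name in code.co_names:
        if name not in allowed and name not in ("and", "or", "not", "True", "False"):
            raise ValueError(f"rule references unknown flag {name!r}")
    return bool(eval(code, {"__builtins__": {}}, allowed))


def classify_graft(
    metrics: dict[str, float],
    reference: ViabilityReference,
    margin_sd: float = 2.0,
    rule: str = DEFAULT_RULE,
) -> ViabilityCall:
    """Classify one kidney from its IS SI-ratio, OS ADC and IS ADC.

    metrics keys: 'is_si_ratio', 'os_adc', 'is_adc'. Flags use strict
    inequalities against reference mean -/+ margin_sd * reference SD.
    """
    for key in ("is_si_ratio", "os_adc", "is_adc"):
        if key not in metrics or not np.isfinite(metrics[key]):
            raise ValueError(f"missing or non-finite metric {key!r}")
    thr = {
        "is_si_ratio_low": float(reference.is_si_ratio.mean - margin_sd * reference.is_si_ratio.sd),
        "os_adc_low": float(reference.os_adc.mean - margin_sd * reference.os_adc.sd),
        "is_adc_high": float(reference.is_adc.mean + margin_sd * reference.is_adc.sd),
    }
    flags = {
        "is_si_depressed": bool(metrics["is_si_ratio"] < thr["is_si_ratio_low"]),
        "os_adc_decreased": bool(metrics["os_adc"] < thr["os_adc_low"]),
        "is_adc_increased": bool(metrics["is_adc"] > thr["is_adc_high"]),
    }
    label = "non_functioning" if _eval_rule(rule, flags) else "functioning"
    return ViabilityCall(
        label=label, flags=flags, thresholds=thr,
        metrics={k: float(v) for k, v in metrics.items()}, rule=rule,
    )


def reference_from_groups(
    si_ratio: GroupSummary, os_adc: GroupSummary, is_adc: GroupSummary
) -> ViabilityReference:
    return ViabilityReference(is_si_ratio=si_ratio, os_adc=os_adc, is_adc=is_adc)


def reference_from_preset(preset, si_te_ms: float = 10.0, n: int = 3) -> ViabilityReference:
    """Threshold anchor built from a CD0h condition preset's (mean, SD) table.

    ADC references are the preset values verbatim. The IS SI-ratio reference
    has mean 1 (the group is its own denominator); its SD is the group's
    coefficient of variation of SI = S0*exp(-TE/T2*), obtained from the T2*
    spread by first-order propagation: CV_SI = (TE / T2*^2) * SD_T2*.
    """
    if preset.condition != "CD0h":
        raise ValueError("the viability reference is anchored to the CD0h arm")
    t2 = preset.t2star["IS"]
    cv_si = si_te_ms / t2.mean**2 * t2.sd
    return ViabilityReference(
        is_si_ratio=GroupSummary("CD0h", 1.0, float(cv_si), n),
        os_adc=GroupSummary("CD0h", preset.adc["OS"].mean, preset.adc["OS"].sd, n),
        is_adc=GroupSummary("CD0h", preset.adc["IS"].mean, preset.adc["IS"].sd, n),
    )


def evaluate_rule(
    kidney_metrics: list[tuple[str, dict[str, float]]],
    reference: ViabilityReference,
    margin_sd: float = 2.0,
    rule: str = DEFAULT_RULE,
) -> dict:
    """Score classify_graft against condition-derived outcomes.

    kidney_metrics: (condition_label, metrics) per kidney, conditions in
    CD0h/CD1h/CD2h. Returns confusion counts, accuracy and the per-kidney
    calls.
    """
    if not kidney_metrics:
        raise ValueError("empty cohort")
    confusion = {
        ("functioning", "functioning"): 0,
        ("functioning", "non_functioning"): 0,
        ("non_functioning", "functioning"): 0,
        ("non_functioning", "non_functioning"): 0,
    }
    calls = []
    n_correct = 0
    for condition, metrics in kidney_metrics:
        if condition not in CONDITION_OUTCOME:
            raise ValueError(f"unlabeled or unknown condition {condition!r}")
        truth = CONDITION_OUTCOME[condition]
        call = classify_graft(metrics, reference, margin_sd=margin_sd, rule=rule)
        confusion[(truth, call.label)] += 1
        n_correct += truth == call.label
        calls.append((condition, call))
    return {
        "confusion": confusion,
        "accuracy": n_correct / len(kidney_metrics),
        "n": len(kidney_metrics),
        "calls": calls,
    }
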