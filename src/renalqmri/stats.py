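"""Small-sample group comparisons: pooled-variance t-tests (from summaries or
raw samples), paired t-tests, and one-way ANOVA with Tukey's HSD.

Designed around the (mean, SD, n) triples that published compartment tables
report, so every printed comparison can be recomputed without raw data.
All p-values are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .roi import GroupSummary


@dataclass
class TestResult:
    method: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    pairwise: dict[tuple[str, str], float] | None = None
    degenerate: bool = False


def _as_summary(g) -> GroupSummary:
    if isinstance(g, GroupSummary):
        return g
    if isinstance(g, (tuple, list)) and len(g) in (3, 4):
        if len(g) == 3:
            return GroupSummary(label="", mean=float(g[0]), sd=float(g[1]), n=int(g[2]))
        return GroupSummary(label=str(g[0]), mean=float(g[1]), sd=float(g[2]), n=int(g[3]))
    arr = np.asarray(g, dtype=float)
    if arr.ndim == 1 and arr.size >= 2:
        return GroupSummary(label="", mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=arr.size)
    raise TypeError(f"cannot interpret {g!r} as a group summary or raw sample")


def unpaired_t_from_summary(a, b) -> TestResult:
    """Equal-variance (pooled) two-sample t-test from (mean, SD, n) summaries.

    s_p^2 = ((n_a-1)SD_a^2 + (n_b-1)SD_b^2) / (n_a+n_b-2);
    t = (m_a-m_b) / sqrt(s_p^2 (1/n_a + 1/n_b)), df = n_a+n_b-2.
    Accepts GroupSummary, (mean, sd, n) triples, or raw 1D samples.
    Degenerate zero-variance cases: equal means -> t=0, p=1; unequal means ->
    p=0, flagged.
    """
    a, b = _as_summary(a), _as_summary(b)
    if a.n < 2 or b.n < 2:
        raise ValueError("both groups need n >= 2")
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    if sp2 == 0:
        if a.mean == b.mean:
            return TestResult("unpaired_t_pooled", 0.0, df, 1.0, degenerate=True)
        return TestResult(
            "unpaired_t_pooled", float(np.sign(a.mean - b.mean)) * np.inf, df, 0.0, degenerate=True
        )
    t = (a.mean - b.mean) / np.sqrt(sp2 * (1.0 / a.n + 1.0 / b.n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult("unpaired_t_pooled", float(t), df, float(p))


def paired_t(differences) -> TestResult:
    """One-sample two-sided t-test on per-subject paired differences."""
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError("paired test needs >= 2 pairs")
    df = d.size - 1
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return TestResult("paired_t", 0.0, df, 1.0, degenerate=True)
        return TestResult("paired_t", float(np.sign(d.mean())) * np.inf, df, 0.0, degenerate=True)
    t = d.mean() / (sd / np.sqrt(d.size))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult("paired_t", float(t), df, float(p))


def one_way_anova_tukey(groups) -> TestResult:
    """One-way ANOVA F-test plus Tukey-Kramer adjusted pairwise p-values.

    groups: >= 3 entries, each a GroupSummary, a (mean, sd, n) triple or a raw
    sample. F has (k-1, N-k) df; each pairwise comparison uses the studentized
    range with parameters (k, N-k):
    q_ij = |m_i - m_j| / sqrt(MSW/2 * (1/n_i + 1/n_j)).
    """
    gs = [_as_summary(g) for g in groups]
    k = len(gs)
    if k < 3:
        raise ValueError("ANOVA/Tukey here is for >= 3 groups; use unpaired_t_from_summary")
    if any(g.n < 2 for g in gs):
        raise ValueError("every group needs n >= 2")
    labels = [g.label or f"g{i}" for i, g in enumerate(gs)]
    ns = np.array([g.n for g in gs], dtype=float)
    means = np.array([g.mean for g in gs])
    sds = np.array([g.sd for g in gs])
    n_tot = ns.sum()
    grand = float((ns * means).sum() / n_tot)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df_b, df_w = k - 1, n_tot - k
    msw = ss_within / df_w
    if msw == 0:
        f_stat = 0.0 if ss_between == 0 else np.inf
        p = 1.0 if ss_between == 0 else 0.0
    else:
        f_stat = (ss_between / df_b) / msw
        p = float(sps.f.sf(f_stat, df_b, df_w))
    pairwise: dict[tuple[str, str], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            if msw == 0:
                pairwise[(labels[i], labels[j])] = 1.0 if means[i] == means[j] else 0.0
                continue
            q = abs(means[i] - means[j]) / np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            pairwise[(labels[i], labels[j])] = float(
                sps.studentized_range.sf(q, k, df_w)
            )
    return TestResult(
        "anova_tukey", float(f_stat), (float(df_b), float(df_w)), float(p),
        pairwise=pairwise, degenerate=(msw == 0),
    )
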