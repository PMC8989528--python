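"""Bypass efficiency and cross-group statistics.

Bypass efficiency follows the competitive replication of adduct bypass
(CRAB) logic on read counts: with an equimolar input mix of a lesion-bearing
and a control genome, the post-replication lesion:control ratio of validated
sequencing reads directly estimates the fraction of lesion genomes whose
replication succeeded; a ratio of 1 is 100% bypass.  A seeded bootstrap CI
over read resampling quantifies counting uncertainty, which the wet-lab
ratio alone does not provide.

Group comparisons (mutation frequency across genotypes or sequence
contexts) use one-way fixed-effects ANOVA computed from the definitional
between/within sums of squares, followed by the Tukey HSD post-hoc test via
the studentized range distribution at family-wise alpha = 0.05.  Responses
are untransformed replicate frequencies.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .extract import PASS

__all__ = ["BypassEstimate", "bypass_efficiency", "equal_coverage_test",
           "AnovaResult", "anova_tukey"]


@dataclass
class BypassEstimate:
    """Normalised lesion:control read-count ratio with a bootstrap CI."""

    lesion_reads: int
    control_reads: int
    input_molar_ratio: float
    bypass_ratio: float
    bypass_percent: float
    ci_low_percent: float
    ci_high_percent: float
    ci_level: float
    n_boot: int
    seed: int

    def to_dict(self) -> dict:
        return dict(vars(self))


def _pass_counts(observations: pd.DataFrame, construct_id: str) -> int:
    sel = ((observations["status"] == PASS)
           & (observations["construct_id"] == construct_id))
    return int(sel.sum())


def bypass_efficiency(observations: pd.DataFrame | None = None,
                      *, lesion_id: str, control_id: str,
                      input_molar_ratio: float = 1.0,
                      counts: tuple[int, int] | None = None,
                      n_boot: int = 10_000,
                      ci_level: float = 0.95,
                      seed: int = 0) -> BypassEstimate:
    """Estimate lesion bypass efficiency from validated read counts.

    Either pass an observation table (PASS counts are taken per construct)
    or explicit ``counts=(lesion_reads, control_reads)``.  The estimate is
    ``(lesion/control) / input_molar_ratio``; the percentile CI resamples
    the construct-of-origin of the pooled reads (binomial bootstrap).
    """
    if counts is None:
        if observations is None:
            raise ValueError("need an observation table or explicit counts")
        counts = (_pass_counts(observations, lesion_id),
                  _pass_counts(observations, control_id))
    lesion_reads, control_reads = counts
    if control_reads <= 0:
        raise ValueError(
            f"bypass ratio undefined: control group {control_id!r} has "
            f"{control_reads} validated reads")
    if lesion_reads <= 0:
        raise ValueError(
            f"bypass ratio undefined: lesion group {lesion_id!r} has "
            f"{lesion_reads} validated reads")
    if input_molar_ratio <= 0:
        raise ValueError("input_molar_ratio must be positive")
    ratio = (lesion_reads / control_reads) / input_molar_ratio

    if not 0.0 < ci_level < 1.0:
        raise ValueError("ci_level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n = lesion_reads + control_reads
    draws = rng.binomial(n, lesion_reads / n, size=n_boot)
    with np.errstate(divide="ignore"):
        boot = draws / (n - draws) / input_molar_ratio
    tail = 100.0 * (1.0 - ci_level) / 2.0
    lo, hi = np.percentile(boot, [tail, 100.0 - tail])
    return BypassEstimate(
        lesion_reads=lesion_reads, control_reads=control_reads,
        input_molar_ratio=input_molar_ratio, bypass_ratio=ratio,
        bypass_percent=100.0 * ratio, ci_low_percent=100.0 * float(lo),
        ci_high_percent=100.0 * float(hi), ci_level=ci_level,
        n_boot=n_boot, seed=seed)


def equal_coverage_test(lesion_reads: int, control_reads: int,
                        input_molar_ratio: float = 1.0) -> tuple[float, float]:
    """Normal-approximation test that lesion and control coverage agree
    with the input molar ratio.  Returns (z, two-sided p)."""
    n = lesion_reads + control_reads
    p0 = input_molar_ratio / (1.0 + input_molar_ratio)
    z = (lesion_reads - n * p0) / math.sqrt(n * p0 * (1 - p0))
    return z, 2.0 * float(sps.norm.sf(abs(z)))


@dataclass
class AnovaResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons."""

    factor: str
    group_names: list[str]
    group_n: dict[str, int]
    group_means: dict[str, float]
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    ms_within: float
    tukey: pd.DataFrame = field(repr=False)
    alpha: float = 0.05

    @property
    def significant_pairs(self) -> list[tuple[str, str]]:
        sig = self.tukey[self.tukey["significant"]]
        return list(zip(sig["group1"], sig["group2"]))


def _coerce_groups(data, factor: str, value: str
                   ) -> dict[str, np.ndarray]:
    if isinstance(data, pd.DataFrame):
        return {str(g): np.asarray(sub[value], dtype=float)
                for g, sub in data.groupby(factor, sort=True)}
    if isinstance(data, Mapping):
        return {str(g): np.asarray(v, dtype=float)
                for g, v in data.items()}
    raise TypeError("data must be a DataFrame or a mapping group -> values")


def anova_tukey(data: pd.DataFrame | Mapping[str, Sequence[float]],
                *, factor: str = "group", value: str = "mutation_frequency",
                alpha: float = 0.05) -> AnovaResult:
    """One-way fixed-effects ANOVA plus Tukey HSD.

    ``data`` is either a long-format frame with ``factor`` and ``value``
    columns (e.g. replicate mutation frequencies per genotype) or a mapping
    from group name to replicate values.  The F statistic comes from the
    definitional sums of squares; Tukey adjusted p-values use the
    studentized range distribution with the Tukey-Kramer standard error for
    unequal group sizes.  With exactly two groups the Tukey adjusted p
    equals the ANOVA p.
    """
    groups = _coerce_groups(data, factor, value)
    k = len(groups)
    if k < 2:
        raise ValueError(f"ANOVA needs at least 2 groups, got {k}")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(
                f"group {name!r} has {len(vals)} replicate(s); at least 2 "
                f"are required")
    names = list(groups)
    all_vals = np.concatenate([groups[g] for g in names])
    n_total = len(all_vals)
    grand = float(all_vals.mean())
    means = {g: float(groups[g].mean()) for g in names}
    ns = {g: len(groups[g]) for g in names}

    ss_between = sum(ns[g] * (means[g] - grand) ** 2 for g in names)
    ss_within = sum(float(((groups[g] - means[g]) ** 2).sum()) for g in names)
    df_b = k - 1
    df_w = n_total - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w

    if ms_w == 0.0:
        warnings.warn("zero within-group variance: all replicates tie "
                      "exactly; F reported as infinite")
        f_stat = math.inf if ss_between > 0 else 0.0
        p_val = 0.0 if ss_between > 0 else 1.0
    else:
        f_stat = ms_b / ms_w
        p_val = float(sps.f.sf(f_stat, df_b, df_w))

    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            g1, g2 = names[i], names[j]
            diff = means[g2] - means[g1]
            if ms_w == 0.0:
                q = math.inf if diff != 0 else 0.0
                p_adj = 0.0 if diff != 0 else 1.0
            else:
                se = math.sqrt(ms_w / 2.0 * (1.0 / ns[g1] + 1.0 / ns[g2]))
                q = abs(diff) / se
                p_adj = float(sps.studentized_range.sf(q, k, df_w))
            rows.append({"group1": g1, "group2": g2, "difference": diff,
                         "q_statistic": q, "p_adjusted": p_adj,
                         "significant": p_adj < alpha})
    tukey = pd.DataFrame(rows, columns=["group1", "group2", "difference",
                                        "q_statistic", "p_adjusted",
                                        "significant"])
    return AnovaResult(
        factor=factor if isinstance(data, pd.DataFrame) else "group",
        group_names=names, group_n=ns, group_means=means,
        f_statistic=f_stat, p_value=p_val, df_between=df_b, df_within=df_w,
        ms_within=ms_w, tukey=tukey, alpha=alpha)
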