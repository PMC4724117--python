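"""Group comparisons: Mann–Whitney U tests and pooled two-proportion Z-tests.

The distributional comparisons between SSD and WGD groups are two-tailed
Mann–Whitney U tests (rank-based location tests); group means are reported
alongside for display. Essentiality and disease enrichment are compared with
the pooled two-sample Z-test on proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .assembly import DEFAULT_DN_BINS, DnBin, assign_dn_bin
from .errors import DegenerateProportionsError
from .model import SSD, WGD, PairScore

#: Samples up to this combined size (without ties) use the exact U null
#: distribution; larger or tied samples use the normal approximation with
#: tie and continuity corrections.
EXACT_LIMIT = 12


def mann_whitney_two_tailed(x, y) -> tuple[float, float]:
    """Two-tailed Mann–Whitney U test; returns (U of x, p).

    U is the rank-sum statistic with midrank tie handling. The p-value is by
    exact enumeration when |x|+|y| <= 12 with no ties, otherwise the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("Mann-Whitney requires non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_LIMIT and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class ProportionTestResult:
    """Pooled two-sample Z-test on proportions."""

    p1: float
    n1: int
    p2: float
    n2: int
    pooled_p: float
    z_statistic: float
    p_two_tailed: float
    confidence_level: float = 0.99


def two_proportion_z(
    p1: float, n1: int, p2: float, n2: int, confidence_level: float = 0.99
) -> ProportionTestResult:
    """Pooled two-sample Z-test comparing two proportions.

    z = (p1 − p2) / sqrt(p̄(1−p̄)(1/n1 + 1/n2)) with p̄ the pooled proportion.
    Accepts the (possibly rounded) proportions directly; see
    :func:`two_proportion_z_from_counts` for count input.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise ValueError("proportions must lie in [0, 1]")
    pooled = (p1 * n1 + p2 * n2) / (n1 + n2)
    if pooled <= 0.0 or pooled >= 1.0:
        raise DegenerateProportionsError(
            f"pooled proportion {pooled} leaves zero variance"
        )
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    p = 2.0 * sps.norm.sf(abs(z))
    return ProportionTestResult(
        p1=p1, n1=n1, p2=p2, n2=n2, pooled_p=pooled,
        z_statistic=z, p_two_tailed=float(min(p, 1.0)),
        confidence_level=confidence_level,
    )


def two_proportion_z_from_counts(
    k1: int, n1: int, k2: int, n2: int, confidence_level: float = 0.99
) -> ProportionTestResult:
    """Same test with integer success counts converted to proportions."""
    return two_proportion_z(k1 / n1, n1, k2 / n2, n2, confidence_level)


@dataclass
class BinnedComparisonRow:
    """One SSD-vs-WGD comparison within a dN stratum (or overall)."""

    bin_label: str
    metric: str
    mean_ssd: float | None
    n_ssd: int
    mean_wgd: float | None
    n_wgd: int
    u_statistic: float | None
    p_two_tailed: float | None
    applicable: bool = True


def binned_metric_comparison(
    pair_scores: list[PairScore],
    bins: tuple[DnBin, ...] = DEFAULT_DN_BINS,
) -> list[BinnedComparisonRow]:
    """Compare SSD vs WGD score distributions per dN bin and overall.

    One row per (metric, bin) plus an "overall" row per metric. A bin where
    either group is empty is still emitted, with the test marked
    not-applicable. Scores without a dN contribute to "overall" only.
    """
    by_metric: dict[str, list[PairScore]] = {}
    for s in pair_scores:
        by_metric.setdefault(s.metric, []).append(s)

    rows: list[BinnedComparisonRow] = []
    for metric in sorted(by_metric):
        scores = by_metric[metric]
        groups: dict[str, dict[str, list[float]]] = {"overall": {SSD: [], WGD: []}}
        for b in bins:
            groups[b.label] = {SSD: [], WGD: []}
        for s in scores:
            if s.origin not in (SSD, WGD):
                continue
            groups["overall"][s.origin].append(s.value)
            if s.dn is not None:
                groups[assign_dn_bin(s.dn, bins)][s.origin].append(s.value)
        for label in ["overall"] + [b.label for b in bins]:
            ssd_vals = groups[label][SSD]
            wgd_vals = groups[label][WGD]
            applicable = bool(ssd_vals) and bool(wgd_vals)
            u = p = None
            if applicable:
                u, p = mann_whitney_two_tailed(ssd_vals, wgd_vals)
            rows.append(BinnedComparisonRow(
                bin_label=label, metric=metric,
                mean_ssd=float(np.mean(ssd_vals)) if ssd_vals else None,
                n_ssd=len(ssd_vals),
                mean_wgd=float(np.mean(wgd_vals)) if wgd_vals else None,
                n_wgd=len(wgd_vals),
                u_statistic=u, p_two_tailed=p, applicable=applicable,
            ))
    return rows


def format_p(p: float | None, floor: float = 1e-6) -> str:
    """Display convention: report very small p-values as "<floor"."""
    if p is None:
        return "NA"
    if p < floor:
        return f"<{floor:g}"
    return f"{p:.3g}"
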