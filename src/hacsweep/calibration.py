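"""Critical-value calibration and detection-power estimation.

The Svd neutrality test rejects when Svd exceeds a critical value ``c``
calibrated on *matched* neutral simulations: replicates generated under
identical parameters — demography, recombination map, ascertainment,
windowing — except that the selection coefficient is set to zero.  The
critical value is chosen so that the proportion of null values greater than
or equal to ``c`` is the nominal level ``p`` (0.05 throughout the original
study); detection power is the proportion of sweep-replicate values
*strictly* greater than ``c``.  Undefined statistic values (either allele
class smaller than two haplotypes) are dropped from both distributions and
counted, never treated as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as _dc_replace
from typing import Sequence

import numpy as np

from .simulate import ScenarioConfig

__all__ = [
    "NullDistribution",
    "PowerResult",
    "MatchedNullError",
    "critical_value",
    "make_null_distribution",
    "detection_power",
    "power_fdr_curve",
    "power_at_fdr",
    "assert_matched_null",
]


class MatchedNullError(ValueError):
    """Null and alternative scenario configs differ in more than s (and seed)."""


@dataclass(frozen=True)
class NullDistribution:
    """Calibrated null distribution of a statistic at the evaluated site."""

    statistic: str
    values: np.ndarray
    p: float
    c: float
    achieved: float  # proportion of values >= c (on the 1/n grid)
    n_undefined: int = 0


@dataclass(frozen=True)
class PowerResult:
    """Monte Carlo power estimate with its binomial standard error."""

    scenario: str
    power: float
    n_alt: int
    se: float
    n_undefined: int = 0


def _finite(values: Sequence[float]) -> tuple[np.ndarray, int]:
    arr = np.asarray(
        [v for v in values if v is not None], dtype=float
    )
    n_undef = len(values) - arr.size
    keep = np.isfinite(arr)
    n_undef += int((~keep).sum())
    return arr[keep], n_undef


def critical_value(null_values: Sequence[float], p: float = 0.05) -> tuple[float, float]:
    """Smallest observed value c with proportion(values >= c) <= p.

    Returns ``(c, achieved)``; the achieved proportion lies on the 1/N grid
    of the empirical distribution, matching the `exactly 0.05` construction
    at N a multiple of 1/p.  Degenerate inputs (all values equal) yield that
    value with achieved proportion 1.
    """
    vals, _ = _finite(null_values)
    if vals.size < 20:
        raise ValueError(f"need at least 20 defined null values, got {vals.size}")
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0,1)")
    srt = np.sort(vals)
    N = srt.size
    if srt[0] == srt[-1]:
        return float(srt[0]), 1.0
    # proportion >= srt[j] is (N - first_index_of(srt[j])) / N
    first_idx = np.searchsorted(srt, srt, side="left")
    prop_ge = (N - first_idx) / N
    ok = np.flatnonzero(prop_ge <= p)
    if ok.size == 0:
        # even the maximum is too frequent (massive ties); use the maximum
        return float(srt[-1]), float(prop_ge[-1])
    j = ok[0]
    return float(srt[j]), float(prop_ge[j])


def make_null_distribution(
    statistic: str, values: Sequence[float], p: float = 0.05
) -> NullDistribution:
    vals, n_undef = _finite(values)
    c, achieved = critical_value(vals, p)
    return NullDistribution(
        statistic=statistic, values=vals, p=p, c=c, achieved=achieved, n_undefined=n_undef
    )


def detection_power(
    alt_values: Sequence[float], c: float, scenario: str = ""
) -> PowerResult:
    """Proportion of alternative values strictly greater than c."""
    vals, n_undef = _finite(alt_values)
    if vals.size < 20:
        raise ValueError(f"need at least 20 defined alternative values, got {vals.size}")
    power = float(np.mean(vals > c))
    se = math.sqrt(power * (1.0 - power) / vals.size)
    return PowerResult(
        scenario=scenario, power=power, n_alt=int(vals.size), se=se, n_undefined=n_undef
    )


def power_fdr_curve(
    null_values: Sequence[float], alt_values: Sequence[float]
) -> list[tuple[float, float]]:
    """(FDR, power) pairs sweeping the decision threshold over pooled values.

    At each achievable threshold t, FDR = (#null >= t) / (#null >= t +
    #alt >= t) and power = proportion of alternative values >= t.  Assumes
    the null and alternative pools play equal prior weight, as in a
    half-null/half-sweep benchmark panel.
    """
    null_arr, _ = _finite(null_values)
    alt_arr, _ = _finite(alt_values)
    if null_arr.size == 0 or alt_arr.size == 0:
        raise ValueError("need nonempty null and alternative value sets")
    thresholds = np.unique(np.concatenate([null_arr, alt_arr]))[::-1]
    null_sorted = np.sort(null_arr)
    alt_sorted = np.sort(alt_arr)
    out: list[tuple[float, float]] = []
    for t in thresholds:
        n_null = null_arr.size - np.searchsorted(null_sorted, t, side="left")
        n_alt = alt_arr.size - np.searchsorted(alt_sorted, t, side="left")
        total = n_null + n_alt
        if total == 0:
            continue
        fdr = n_null / total
        power = n_alt / alt_arr.size
        out.append((float(fdr), float(power)))
    return out


def power_at_fdr(
    null_values: Sequence[float], alt_values: Sequence[float], fdr: float = 0.1
) -> float:
    """Power at the largest achievable FDR not exceeding ``fdr``.

    Walks the threshold sweep of :func:`power_fdr_curve` and returns the
    highest power whose operating FDR is <= the requested level.
    """
    curve = power_fdr_curve(null_values, alt_values)
    feasible = [pw for f, pw in curve if f <= fdr]
    if not feasible:
        return 0.0
    return max(feasible)


def assert_matched_null(null_config: ScenarioConfig, alt_config: ScenarioConfig) -> None:
    """Enforce the matched-null rule structurally.

    The null config must equal the alternative in every field except the
    selection coefficient (which must be absent or zero) and the seed.
    """
    ns, als = null_config.selection, alt_config.selection
    if ns is not None and ns.s != 0:
        raise MatchedNullError("null scenario has a nonzero selection coefficient")
    if (ns is None) != (als is None):
        raise MatchedNullError(
            "null must keep the alternative's frequency conditioning (s=0, same f)"
        )
    if ns is not None and als is not None and ns.f != als.f:
        raise MatchedNullError(
            f"evaluated-allele frequency differs between null ({ns.f}) and "
            f"alternative ({als.f})"
        )
    stripped_null = _dc_replace(null_config, selection=None, seed=0)
    stripped_alt = _dc_replace(alt_config, selection=None, seed=0)
    if stripped_null != stripped_alt:
        raise MatchedNullError(
            "null and alternative configs differ in more than the selection "
            f"coefficient: {stripped_null} vs {stripped_alt}"
        )
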