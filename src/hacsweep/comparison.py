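"""Comparison neutrality statistics: Tajima's D, normalized Fay & Wu's H,
and the unstandardized iHS.

These are the three statistics against which the HAC-based Svd test is
benchmarked.  D and H summarise the site frequency spectrum of a window; the
unstandardized iHS contrasts extended haplotype homozygosity (EHH) decay
around a core SNP between its ancestral- and derived-allele carriers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import HaplotypeWindow

__all__ = ["StatResult", "tajima_d", "fay_wu_h_normalized", "ihs_unstandardized"]

EHH_TRUNCATION = 0.05  # stop integrating iHH once EHH decays below this


@dataclass(frozen=True)
class StatResult:
    name: str
    value: float | None
    defined: bool


def _undefined(name: str) -> StatResult:
    return StatResult(name=name, value=None, defined=False)


def _spectrum(window: HaplotypeWindow) -> tuple[int, np.ndarray]:
    """(n, xi) with xi[i] = number of sites at derived count i, i = 1..n−1."""
    n = window.n
    d = window.alleles.sum(axis=0).astype(int)
    seg = (d > 0) & (d < n)
    xi = np.bincount(d[seg], minlength=n)[: n]
    return n, xi


def tajima_d(window: HaplotypeWindow) -> StatResult:
    """Tajima's D = (π − θ_W) / sd, with the 1989 variance constants.

    π is the mean pairwise difference count, θ_W = S/a1 Watterson's
    estimator.  Undefined for fewer than one segregating site.
    """
    n, xi = _spectrum(window)
    i = np.arange(1, n)
    S = int(xi[1:].sum())
    if S < 1 or n < 4:
        return _undefined("tajima_d")
    pi = float(np.sum(2.0 * xi[1:] * i * (n - i)) / (n * (n - 1)))
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return _undefined("tajima_d")
    return StatResult("tajima_d", float((pi - S / a1) / np.sqrt(var)), True)


def fay_wu_h_normalized(window: HaplotypeWindow) -> StatResult:
    """Normalized Fay & Wu's H from the unfolded frequency spectrum.

    H = π − θ_H with θ_H = Σ 2 S_i i² / (n(n−1)); equivalently
    π − θ_H = 2(π − θ_L), standardised by the variance of (π − θ_L) with θ
    and θ² estimated by the usual unbiased moment estimators (Zeng et al.
    normalisation).  Requires ancestral/derived polarisation, which the 0/1
    coding of :class:`HaplotypeWindow` guarantees.
    """
    n, xi = _spectrum(window)
    i = np.arange(1, n)
    S = int(xi[1:].sum())
    if S < 1 or n < 3:
        return _undefined("fay_wu_h")
    pi = float(np.sum(2.0 * xi[1:] * i * (n - i)) / (n * (n - 1)))
    theta_l = float(np.sum(xi[1:] * i) / (n - 1))
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    bn1 = a2 + 1.0 / n**2  # Σ_{i=1..n} 1/i²
    theta_w = S / a1
    theta_sq = S * (S - 1.0) / (a1**2 + a2)
    var = (
        theta_w * (n - 2.0) / (6.0 * (n - 1.0))
        + theta_sq
        * (
            18.0 * n**2 * (3.0 * n + 2.0) * bn1
            - (88.0 * n**3 + 9.0 * n**2 - 13.0 * n + 6.0)
        )
        / (9.0 * n * (n - 1.0) ** 2)
    )
    if var <= 0:
        return _undefined("fay_wu_h")
    return StatResult("fay_wu_h", float(2.0 * (pi - theta_l) / np.sqrt(var)), True)


def _ehh(rows: np.ndarray, core: int, stop: int, step: int) -> tuple[list[int], list[float]]:
    """EHH of `rows` extending from the core column towards `stop`.

    Returns site indices (starting at the core) and the EHH value once the
    haplotype is extended to each of them.  EHH at the core itself is 1 by
    construction (all rows share the core allele).
    """
    n = rows.shape[0]
    pairs = n * (n - 1) / 2.0
    idx = [core]
    ehh = [1.0]
    # group haplotypes by identity over the growing interval
    keys = np.zeros(n, dtype=np.int64)
    j = core
    while j != stop:
        j += step
        # refine grouping by the allele at column j
        keys = keys * 2 + rows[:, j]
        _, counts = np.unique(keys, return_counts=True)
        hom = float(np.sum(counts * (counts - 1) / 2.0) / pairs)
        idx.append(j)
        ehh.append(hom)
        if hom < EHH_TRUNCATION:
            break
        if keys.max() > 2**61:  # re-index groups to avoid overflow
            _, keys = np.unique(keys, return_inverse=True)
    return idx, ehh


def _ihh_one_side(rows: np.ndarray, positions: np.ndarray, core: int, stop: int, step: int) -> float:
    idx, ehh = _ehh(rows, core, stop, step)
    pos = positions[idx]
    return float(abs(np.trapezoid(ehh, pos)))


def ihs_unstandardized(window: HaplotypeWindow, k: int | None = None) -> StatResult:
    """Unstandardized iHS = ln(iHH_A / iHH_D) at core SNP k.

    iHH is the trapezoidal integral of EHH against physical position, run
    separately over ancestral-core and derived-core haplotypes, out to the
    window edge or to EHH < 0.05, whichever comes first.  Sweeps on derived
    alleles give extended derived haplotype homozygosity, hence large iHH_D
    and *negative* unstandardized iHS; the selection-appropriate tail is the
    lower one (or use |iHS|).
    """
    if k is None:
        k = window.evaluated_index
    if k is None:
        raise ValueError("no core site: set evaluated_index or pass k")
    if window.S < 2:
        return _undefined("ihs")
    col = window.alleles[:, k]
    derived = window.alleles[col == 1]
    ancestral = window.alleles[col == 0]
    if derived.shape[0] < 2 or ancestral.shape[0] < 2:
        return _undefined("ihs")
    ihh = {}
    for name, rows in (("A", ancestral), ("D", derived)):
        left = _ihh_one_side(rows, window.positions, k, 0, -1)
        right = _ihh_one_side(rows, window.positions, k, window.S - 1, +1)
        ihh[name] = left + right
    if ihh["A"] <= 0 or ihh["D"] <= 0:
        return _undefined("ihs")
    return StatResult("ihs", float(np.log(ihh["A"] / ihh["D"])), True)
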