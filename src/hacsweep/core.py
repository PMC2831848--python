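"""Haplotype allelic classes (HAC) and the Svd statistic.

A haplotype allelic class is the Hamming distance between a haplotype and a
chosen reference haplotype over a window of S biallelic SNPs.  Against the
major-allele reference haplotype (MARH) — the artificial haplotype carrying
the majority allele at every SNP — the HAC of a haplotype is the number of
minor alleles it carries.  An ongoing selective sweep drags a cluster of
haplotypes toward the MARH, so at the selected SNP the carriers of the
(major, selected) allele form a tight, low-variance HAC distribution while
the remaining haplotypes stay dispersed.

Per evaluated SNP ``k`` the sample is split into ``R_k`` (haplotypes carrying
the allele present on the MARH at ``k``) and ``r_k`` (the rest), and

    vd_k  = V̂(r_k) − V̂(R_k)
    Svd_k = f_d,k · vd_k / S

where ``V̂`` is the sample variance of HAC values, ``f_d,k`` the derived
allele frequency at ``k`` and ``S`` the window size.  The division by ``S``
normalises out the (at most linear) growth of the HAC variance with window
size; the ``f_d,k`` weight focuses the statistic on sweeps that carried a
*derived* allele to high frequency.  Large positive Svd indicates an ongoing
sweep; under neutrality Svd is near zero or negative.

Everything in this module is pure in-memory computation on
:class:`HaplotypeWindow` objects produced by :mod:`hacsweep.io` or
:mod:`hacsweep.simulate`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SiteAnnotation",
    "HaplotypeWindow",
    "ReferenceHaplotype",
    "HacDistribution",
    "SiteSvd",
    "MalformedInputError",
    "encode_window",
    "build_marh",
    "hac_distance",
    "hac_distribution",
    "hac_variance",
    "split_by_allele",
    "vd_at_site",
    "svd_at_site",
    "extract_centered_window",
]


class MalformedInputError(ValueError):
    """Raised when raw input violates the biallelic/ancestral-call contract."""


@dataclass(frozen=True)
class SiteAnnotation:
    """Per-SNP annotation: alleles, ancestral state and sample frequencies.

    ``derived_freq`` is the frequency of the derived allele among exactly the
    ``n`` haplotypes of the enclosing window.
    """

    site_id: str
    position: float
    ancestral_allele: str
    derived_allele: str
    derived_freq: float

    @property
    def minor_allele_freq(self) -> float:
        return min(self.derived_freq, 1.0 - self.derived_freq)


@dataclass
class HaplotypeWindow:
    """An n × S matrix of phased alleles coded 0 = ancestral, 1 = derived.

    ``positions`` are strictly increasing physical (bp) or relative
    coordinates.  ``evaluated_index`` optionally marks the SNP under
    evaluation (the selected site in simulated sweep replicates, or the
    window centre in a scan).
    """

    alleles: np.ndarray
    positions: np.ndarray
    site_ids: Sequence[str] | None = None
    ancestral_alleles: Sequence[str] | None = None
    derived_alleles: Sequence[str] | None = None
    evaluated_index: int | None = None

    def __post_init__(self) -> None:
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.alleles.ndim != 2:
            raise MalformedInputError("allele matrix must be 2-dimensional")
        if self.positions.shape != (self.alleles.shape[1],):
            raise MalformedInputError("positions length must equal site count")
        if self.alleles.shape[1] > 1 and not np.all(np.diff(self.positions) > 0):
            raise MalformedInputError("site positions must be strictly increasing")
        if self.evaluated_index is not None and not (
            0 <= self.evaluated_index < self.alleles.shape[1]
        ):
            raise MalformedInputError("evaluated_index out of range")

    @property
    def n(self) -> int:
        return self.alleles.shape[0]

    @property
    def S(self) -> int:
        return self.alleles.shape[1]

    def derived_freq(self) -> np.ndarray:
        """Derived-allele frequency per site over the window's n haplotypes."""
        return self.alleles.mean(axis=0)

    def minor_count(self) -> np.ndarray:
        """Minor-allele count per site over the window's n haplotypes."""
        d = self.alleles.sum(axis=0)
        return np.minimum(d, self.n - d)

    def site(self, k: int) -> SiteAnnotation:
        sid = self.site_ids[k] if self.site_ids is not None else f"site_{k}"
        anc = self.ancestral_alleles[k] if self.ancestral_alleles is not None else "0"
        der = self.derived_alleles[k] if self.derived_alleles is not None else "1"
        return SiteAnnotation(
            site_id=sid,
            position=float(self.positions[k]),
            ancestral_allele=anc,
            derived_allele=der,
            derived_freq=float(self.alleles[:, k].mean()),
        )

    @property
    def sites(self) -> list[SiteAnnotation]:
        return [self.site(k) for k in range(self.S)]

    def take_sites(self, index: np.ndarray) -> "HaplotypeWindow":
        """Restrict to a subset of sites (sorted index array); the
        evaluated_index is remapped, or dropped if the site was removed."""
        index = np.asarray(index, dtype=int)
        new_eval = None
        if self.evaluated_index is not None:
            hits = np.flatnonzero(index == self.evaluated_index)
            new_eval = int(hits[0]) if hits.size else None
        return HaplotypeWindow(
            alleles=self.alleles[:, index],
            positions=self.positions[index],
            site_ids=[self.site_ids[i] for i in index] if self.site_ids is not None else None,
            ancestral_alleles=(
                [self.ancestral_alleles[i] for i in index]
                if self.ancestral_alleles is not None
                else None
            ),
            derived_alleles=(
                [self.derived_alleles[i] for i in index]
                if self.derived_alleles is not None
                else None
            ),
            evaluated_index=new_eval,
        )


@dataclass(frozen=True)
class ReferenceHaplotype:
    """A length-S reference haplotype; ``tie_sites`` lists indices where both
    alleles had frequency exactly 0.5 and the tie rule decided the call."""

    alleles: np.ndarray
    tie_sites: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "alleles", np.ascontiguousarray(self.alleles, dtype=np.uint8)
        )

    @property
    def S(self) -> int:
        return self.alleles.shape[0]


@dataclass(frozen=True)
class HacDistribution:
    """Counts of haplotypes per HAC class 0..S, with mean and variance."""

    counts: np.ndarray
    size: int
    mean: float
    variance: float | None  # None when size < 2


@dataclass(frozen=True)
class SiteSvd:
    """Svd decomposition at one evaluated SNP.

    ``defined`` is False when either allele class has fewer than two
    haplotypes; such sites are reported as missing, never as zero.
    """

    k: int
    n_major: int
    n_minor: int
    var_major: float | None
    var_minor: float | None
    vd: float | None
    svd: float | None
    defined: bool


def encode_window(
    raw_alleles: Sequence[Sequence[str]] | np.ndarray,
    annotations: Iterable[SiteAnnotation],
) -> HaplotypeWindow:
    """Recode a symbolic n × S allele matrix to 0 = ancestral / 1 = derived.

    Every symbol must match the site's annotated ancestral or derived allele,
    and every site must be segregating within the matrix.
    """
    raw = np.asarray(raw_alleles, dtype=object)
    ann = list(annotations)
    if raw.ndim != 2 or raw.shape[1] != len(ann):
        raise MalformedInputError("annotation count must match matrix columns")
    n, S = raw.shape
    coded = np.empty((n, S), dtype=np.uint8)
    for k, a in enumerate(ann):
        col = raw[:, k]
        is_anc = col == a.ancestral_allele
        is_der = col == a.derived_allele
        bad = ~(is_anc | is_der)
        if bad.any():
            raise MalformedInputError(
                f"site {a.site_id}: allele {col[bad][0]!r} matches neither "
                f"{a.ancestral_allele!r} nor {a.derived_allele!r}"
            )
        coded[:, k] = is_der
        d = int(coded[:, k].sum())
        if d == 0 or d == n:
            raise MalformedInputError(f"site {a.site_id}: not segregating in matrix")
    # frequencies are recomputed from the matrix, not trusted from input
    return HaplotypeWindow(
        alleles=coded,
        positions=np.array([a.position for a in ann], dtype=float),
        site_ids=[a.site_id for a in ann],
        ancestral_alleles=[a.ancestral_allele for a in ann],
        derived_alleles=[a.derived_allele for a in ann],
    )


def build_marh(window: HaplotypeWindow) -> ReferenceHaplotype:
    """Build the major-allele reference haplotype of a window.

    At each site the reference carries the allele with frequency > 0.5.  At
    an exact 50/50 tie the ancestral allele (code 0) is chosen — a
    deterministic rule; the site index is recorded in ``tie_sites``.
    """
    if window.n == 0 or window.S == 0:
        raise MalformedInputError("cannot build a reference from an empty window")
    dcount = window.alleles.sum(axis=0)
    ref = (2 * dcount > window.n).astype(np.uint8)  # ties (2d == n) -> ancestral
    ties = frozenset(int(i) for i in np.flatnonzero(2 * dcount == window.n))
    return ReferenceHaplotype(alleles=ref, tie_sites=ties)


def hac_distance(haplotype: np.ndarray, reference: ReferenceHaplotype | np.ndarray) -> int:
    """Hamming distance between one haplotype and a reference (its HAC)."""
    ref = reference.alleles if isinstance(reference, ReferenceHaplotype) else np.asarray(reference)
    hap = np.asarray(haplotype)
    if hap.shape != ref.shape:
        raise ValueError(f"length mismatch: haplotype {hap.shape} vs reference {ref.shape}")
    return int(np.count_nonzero(hap != ref))


def _hac_values(rows: np.ndarray, reference: ReferenceHaplotype) -> np.ndarray:
    return np.count_nonzero(rows != reference.alleles[None, :], axis=1)


def hac_variance(hac_values: Sequence[int] | np.ndarray, ddof: int = 1) -> float:
    """Sample variance of HAC values (default: unbiased, denominator n−1).

    Raises on fewer than two values: the variance is then undefined and
    callers must flag the statistic as missing rather than substitute zero.
    """
    h = np.asarray(hac_values, dtype=float)
    if h.size < 2:
        raise ValueError("HAC variance undefined for fewer than 2 values")
    return float(np.var(h, ddof=ddof))


def hac_distribution(
    haplotypes: np.ndarray, reference: ReferenceHaplotype, ddof: int = 1
) -> HacDistribution:
    """HAC class counts (0..S), mean and variance for a set of haplotypes."""
    rows = np.atleast_2d(np.asarray(haplotypes))
    if rows.shape[0] == 0:
        raise ValueError("empty haplotype set")
    h = _hac_values(rows, reference)
    counts = np.bincount(h, minlength=reference.S + 1)
    var = hac_variance(h, ddof=ddof) if h.size >= 2 else None
    return HacDistribution(counts=counts, size=int(h.size), mean=float(h.mean()), variance=var)


def split_by_allele(
    window: HaplotypeWindow, k: int, reference: ReferenceHaplotype
) -> tuple[np.ndarray, np.ndarray]:
    """Partition window rows at SNP k into (R_k, r_k).

    R_k holds the haplotypes carrying the allele present on the reference at
    k (the major allele for a MARH); r_k holds the rest.
    """
    if not 0 <= k < window.S:
        raise IndexError(f"site index {k} out of range for S={window.S}")
    in_major = window.alleles[:, k] == reference.alleles[k]
    return window.alleles[in_major], window.alleles[~in_major]


def vd_at_site(
    window: HaplotypeWindow,
    k: int,
    reference: ReferenceHaplotype | None = None,
    *,
    include_evaluated: bool = True,
    ddof: int = 1,
) -> SiteSvd:
    """HAC variance difference vd_k = V̂(r_k) − V̂(R_k) at SNP k.

    HAC distances are computed over the full window; ``include_evaluated``
    controls whether SNP k's own column contributes to them (default: it
    does, being part of the S-SNP haplotype).  When either subsample has
    fewer than two haplotypes the result is flagged undefined.
    """
    if reference is None:
        reference = build_marh(window)
    major_rows, minor_rows = split_by_allele(window, k, reference)
    n_major, n_minor = major_rows.shape[0], minor_rows.shape[0]
    if n_major < 2 or n_minor < 2:
        return SiteSvd(k, n_major, n_minor, None, None, None, None, defined=False)
    if include_evaluated:
        ref = reference
        maj, mino = major_rows, minor_rows
    else:
        keep = np.arange(window.S) != k
        ref = ReferenceHaplotype(alleles=reference.alleles[keep])
        maj, mino = major_rows[:, keep], minor_rows[:, keep]
    var_major = hac_variance(_hac_values(maj, ref), ddof=ddof)
    var_minor = hac_variance(_hac_values(mino, ref), ddof=ddof)
    return SiteSvd(
        k=k,
        n_major=n_major,
        n_minor=n_minor,
        var_major=var_major,
        var_minor=var_minor,
        vd=var_minor - var_major,
        svd=None,
        defined=True,
    )


def svd_at_site(
    window: HaplotypeWindow,
    k: int,
    reference: ReferenceHaplotype | None = None,
    *,
    include_evaluated: bool = True,
    ddof: int = 1,
) -> SiteSvd:
    """Svd_k = f_d,k · vd_k / S at SNP k (undefined propagates).

    f_d,k is the derived-allele frequency within the analysed window of n
    haplotypes; S is the window's SNP count, normalising out the O(S) growth
    of the HAC variance.
    """
    res = vd_at_site(
        window, k, reference, include_evaluated=include_evaluated, ddof=ddof
    )
    if not res.defined:
        return res
    f_d = float(window.alleles[:, k].mean())
    return replace(res, svd=f_d * res.vd / window.S)


def extract_centered_window(
    window: HaplotypeWindow, S: int, center: int | None = None
) -> HaplotypeWindow:
    """Take the S SNPs centred on ``center`` (default: evaluated_index).

    The centre lands at index ⌊S/2⌋ of the result.  Raises if the window
    does not extend at least ⌊S/2⌋ SNPs left and S − ⌊S/2⌋ − 1 SNPs right of
    the centre, keeping S constant so the /S normalisation is comparable.
    """
    if center is None:
        center = window.evaluated_index
    if center is None:
        raise ValueError("no centre site: set evaluated_index or pass center")
    half = S // 2
    lo, hi = center - half, center - half + S
    if lo < 0 or hi > window.S:
        raise ValueError(
            f"cannot centre a window of S={S} on site {center} (have {window.S} sites)"
        )
    sub = window.take_sites(np.arange(lo, hi))
    sub.evaluated_index = half
    return sub
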