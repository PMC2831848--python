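"""SNP-ascertainment emulation and diploidization.

Genotyping datasets rarely contain every segregating site: rare variants are
filtered out (MAF thresholds), SNPs are discovered in small sequencing
panels before being typed in the full sample, and array content is chosen to
match a target frequency spectrum.  Each scheme here removes (or re-weights)
sites from a simulated replicate without ever altering allele codes at the
sites it keeps, so the downstream Svd pipeline sees data shaped like the
ascertained real data it will be applied to.

``diploidize`` is the hook for phasing experiments: it collapses the phased
haplotypes into unphased genotypes so an external phaser can be run and the
reconstructed haplotypes re-imported (statistical phasing itself is out of
scope here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import HaplotypeWindow

__all__ = [
    "AscertainmentScheme",
    "filter_by_maf",
    "panel_ascertain",
    "spectrum_rejection_sample",
    "diploidize",
    "DEFAULT_SPECTRUM_BINS",
]

DEFAULT_SPECTRUM_BINS = 25


@dataclass(frozen=True)
class AscertainmentScheme:
    """Declarative description of one scheme, for configs and reports.

    kind: 'maf_filter' (min_minor_count), 'panel' (m chromosomes) or
    'spectrum_match' (target derived-frequency histogram).
    """

    kind: str
    min_minor_count: int = 0
    m: int = 0
    target_spectrum: tuple[float, ...] = ()
    seed: int = 0

    def apply(self, window: HaplotypeWindow, seed: int | None = None) -> HaplotypeWindow:
        seed = self.seed if seed is None else seed
        if self.kind == "maf_filter":
            return filter_by_maf(window, self.min_minor_count)
        if self.kind == "panel":
            return panel_ascertain(window, self.m, seed)
        if self.kind == "spectrum_match":
            return spectrum_rejection_sample(window, np.asarray(self.target_spectrum), seed)
        raise ValueError(f"unknown ascertainment kind {self.kind!r}")


def filter_by_maf(
    window: HaplotypeWindow, min_minor_count: int, strict: bool = False
) -> HaplotypeWindow:
    """Drop sites whose minor-allele count is below ``min_minor_count``.

    With n = 50, ``min_minor_count = 3`` removes singletons and doubletons
    (MAF < 0.05).  The evaluated site is never removed — it is the site
    under test; if it fails the filter a warning is issued (or an error when
    ``strict``).
    """
    if min_minor_count < 0:
        raise ValueError("min_minor_count must be >= 0")
    if min_minor_count == 0:
        return window
    keep = window.minor_count() >= min_minor_count
    if window.evaluated_index is not None and not keep[window.evaluated_index]:
        if strict:
            raise ValueError("evaluated site fails the MAF filter")
        import warnings

        warnings.warn("evaluated site fails the MAF filter; kept anyway")
        keep[window.evaluated_index] = True
    return window.take_sites(np.flatnonzero(keep))


def panel_ascertain(window: HaplotypeWindow, m: int, seed: int) -> HaplotypeWindow:
    """Keep only sites segregating within a random discovery panel of m rows.

    Emulates discovering SNPs by sequencing m chromosomes and genotyping
    them in the full sample of n: sites monomorphic within the panel are
    never discovered.  At m = n there is no ascertainment bias.
    """
    if not 2 <= m <= window.n:
        raise ValueError(f"panel size m={m} must be in [2, n={window.n}]")
    rng = np.random.default_rng(seed)
    panel = rng.choice(window.n, size=m, replace=False)
    counts = window.alleles[panel].sum(axis=0)
    keep = (counts > 0) & (counts < m)
    return window.take_sites(np.flatnonzero(keep))


def spectrum_rejection_sample(
    window: HaplotypeWindow,
    target_spectrum: np.ndarray,
    seed: int,
    n_bins: int | None = None,
) -> HaplotypeWindow:
    """Thin sites so the derived-frequency spectrum approaches a target.

    Voight-style rejection sampling: a site in derived-frequency bin b is
    accepted with probability proportional to target(b)/source(b), ratios
    rescaled so that the best-represented bin is accepted with probability
    one.  The target is a histogram over equal-width derived-frequency bins
    on (0, 1); it is renormalised internally.
    """
    target = np.asarray(target_spectrum, dtype=float)
    if target.ndim != 1 or target.size < 2 or np.any(target < 0) or target.sum() == 0:
        raise ValueError("target spectrum must be a nonnegative histogram over (0,1)")
    n_bins = target.size if n_bins is None else n_bins
    if n_bins != target.size:
        raise ValueError("n_bins must match the target histogram length")
    rng = np.random.default_rng(seed)
    freqs = window.derived_freq()
    bins = np.clip((freqs * n_bins).astype(int), 0, n_bins - 1)
    source = np.bincount(bins, minlength=n_bins).astype(float)
    target = target / target.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(source > 0, target / np.maximum(source / source.sum(), 1e-300), 0.0)
    if ratio.max() == 0:
        raise ValueError("no overlap between source sites and target spectrum")
    accept = ratio / ratio.max()
    keep = rng.random(window.S) < accept[bins]
    if window.evaluated_index is not None:
        keep[window.evaluated_index] = True  # the tested site always survives
    return window.take_sites(np.flatnonzero(keep))


def diploidize(
    replicate: HaplotypeWindow, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly pair the n haplotypes into n/2 unphased diploid genotypes.

    Returns ``(genotypes, pairing)``: genotypes is an (n/2) × S matrix of
    derived-allele dosages {0,1,2}; pairing is an (n/2, 2) array of row
    indices so the assignment can be audited or re-summed exactly.
    """
    if replicate.n % 2:
        raise ValueError("diploidization needs an even number of haplotypes")
    rng = np.random.default_rng(seed)
    order = rng.permutation(replicate.n)
    pairing = order.reshape(-1, 2)
    genotypes = (
        replicate.alleles[pairing[:, 0]].astype(np.int16)
        + replicate.alleles[pairing[:, 1]]
    ).astype(np.uint8)
    return genotypes, pairing
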