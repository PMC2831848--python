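"""Replicate simulation under neutral and selective-sweep scenarios.

Scenarios follow the validation design of the Svd study: samples of
``n = 50`` haplotypes at population mutation rate ``Θ = 223`` (≈1,000 SNPs
per replicate), with optional recombination (constant rate or hotspots),
demographic change (bottleneck, expansion) and an ongoing selective sweep
that has carried the selected allele to current frequency ``f`` under
selection coefficient ``s``.

Neutral replicates are generated with msprime (standard coalescent,
infinite-sites binary mutations on a continuous genome); sweep replicates
use the in-package structured-coalescent engine (:mod:`hacsweep._engine`)
conditioned on a selected-allele frequency trajectory.  All time scaling is
in generations with a diploid effective size ``Ne`` (default 1,000); Θ and ρ
are the usual population-scaled rates 4Ne·μ and 4Ne·r per locus, held fixed
when Ne is varied so that Ne enters only through the sweep dynamics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import msprime
import numpy as np

from ._engine import RecombinationMap, simulate_sweep_replicate
from .core import HaplotypeWindow

__all__ = [
    "Selection",
    "Demography",
    "Constant",
    "Bottleneck",
    "Expansion",
    "ScenarioConfig",
    "ReplicateSet",
    "simulate_neutral",
    "simulate_sweep",
    "simulate_scenario",
    "scenario_grid",
    "watterson_expected_sites",
    "DEFAULT_THETA",
    "DEFAULT_N",
    "DEFAULT_NE",
]

DEFAULT_THETA = 223.0
DEFAULT_N = 50
DEFAULT_NE = 1000.0


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class Selection:
    """Ongoing sweep: selection coefficient s, current allele frequency f."""

    s: float
    f: float
    stochastic_trajectory: bool = True

    def __post_init__(self):
        if not 0.0 < self.f < 1.0:
            raise ConfigError("selected-allele frequency f must be in (0,1)")
        if self.s < 0:
            raise ConfigError("selection coefficient s must be >= 0")


@dataclass(frozen=True)
class Demography:
    kind: str = "constant"


@dataclass(frozen=True)
class Constant(Demography):
    kind: str = "constant"


@dataclass(frozen=True)
class Bottleneck(Demography):
    """Size reduction starting ``t_start`` generations ago (forward sense),
    lasting ``duration`` generations, at fractional ``reduction``."""

    kind: str = "bottleneck"
    t_start: float = 340.0
    duration: float = 80.0
    reduction: float = 0.95

    def __post_init__(self):
        if not 0.0 < self.reduction < 1.0:
            raise ConfigError("bottleneck reduction must be in (0,1)")
        if self.duration <= 0 or self.t_start < self.duration:
            raise ConfigError("need 0 < duration <= t_start")


@dataclass(frozen=True)
class Expansion(Demography):
    """Growth from ``ne_from`` to ``ne_to`` over the last ``duration``
    generations (exponential)."""

    kind: str = "expansion"
    ne_from: float = 500.0
    ne_to: float = 1000.0
    duration: float = 300.0

    def __post_init__(self):
        if self.ne_from <= 0 or self.ne_to <= 0 or self.duration <= 0:
            raise ConfigError("expansion sizes and duration must be positive")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of one simulation scenario.

    ``hotspots`` holds (start_bp, multiplier) pairs on the physical locus of
    ``locus_length`` bp; multipliers scale the background per-bp rate
    ``rho_background/(4·Ne·L)`` over a ``hotspot_width`` interval.
    """

    n: int = DEFAULT_N
    theta: float = DEFAULT_THETA
    rho_background: float = 0.0
    hotspots: tuple[tuple[float, float], ...] = ()
    ne: float = DEFAULT_NE
    demography: Demography = field(default_factory=Constant)
    selection: Selection | None = None
    locus_length: float = 50_000.0
    hotspot_width: float = 2_000.0
    seed: int = 0

    def __post_init__(self):
        if self.n < 2:
            raise ConfigError("sample size n must be >= 2")
        if self.theta <= 0:
            raise ConfigError("theta must be > 0")
        if self.rho_background < 0:
            raise ConfigError("rho must be >= 0")
        for _, mult in self.hotspots:
            if mult < 1:
                raise ConfigError("hotspot multipliers must be >= 1")

    def matched_null(self, seed: int | None = None) -> "ScenarioConfig":
        """The scenario with the selection coefficient set to zero.

        Every other parameter is kept — including the current frequency f of
        the evaluated allele, so that the null is the frequency-conditioned
        neutral model and the calibrated test contrasts selection, not
        allele frequency.
        """
        null_sel = (
            None
            if self.selection is None
            else dataclasses.replace(self.selection, s=0.0)
        )
        return dataclasses.replace(
            self,
            selection=null_sel,
            seed=self.seed + 1_000_003 if seed is None else seed,
        )

    def recombination_map(self) -> RecombinationMap:
        return RecombinationMap.uniform_with_hotspots(
            self.rho_background,
            self.ne,
            self.locus_length,
            self.hotspots,
            self.hotspot_width,
        )


@dataclass
class ReplicateSet:
    """Simulated replicates plus the scenario and seeds that regenerate them.

    ``scenario`` is None for replicate sets parsed from external files.
    """

    replicates: list[HaplotypeWindow]
    scenario: ScenarioConfig | None
    n_regenerated: int = 0

    @property
    def n_reps(self) -> int:
        return len(self.replicates)


def _msprime_demography(config: ScenarioConfig) -> msprime.Demography:
    # haploid samples (ploidy=1): hand msprime 2·Ne genomes so that the
    # pairwise coalescence rate is the diploid 1/(2·Ne) per generation
    demo = msprime.Demography()
    d = config.demography
    if d.kind == "constant":
        demo.add_population(initial_size=2 * config.ne)
    elif d.kind == "bottleneck":
        demo.add_population(initial_size=2 * config.ne)
        # backwards: [0, t_start-duration) full size, then reduced, then full
        demo.add_population_parameters_change(
            time=d.t_start - d.duration,
            initial_size=2 * config.ne * (1.0 - d.reduction),
        )
        demo.add_population_parameters_change(time=d.t_start, initial_size=2 * config.ne)
    elif d.kind == "expansion":
        rate = np.log(d.ne_to / d.ne_from) / d.duration
        demo.add_population(initial_size=2 * d.ne_to, growth_rate=rate)
        demo.add_population_parameters_change(
            time=d.duration, initial_size=2 * d.ne_from, growth_rate=0.0
        )
    else:
        raise ConfigError(f"unknown demography kind {d.kind!r}")
    return demo


def _msprime_rate_map(config: ScenarioConfig) -> msprime.RateMap | float:
    rm = config.recombination_map()
    if rm.total == 0:
        return 0.0
    return msprime.RateMap(position=rm.breaks, rate=rm.rates)


def _ts_to_window(ts, center_bp: float) -> HaplotypeWindow:
    positions = np.array([s.position for s in ts.sites()])
    alleles = np.ascontiguousarray(ts.genotype_matrix().T.astype(np.uint8))
    if positions.size == 0:
        raise RuntimeError("replicate has no segregating sites")
    evaluated = int(np.argmin(np.abs(positions - center_bp)))
    return HaplotypeWindow(
        alleles=alleles, positions=positions, evaluated_index=evaluated
    )


def _neutral_replicate(config: ScenarioConfig, seed: int) -> HaplotypeWindow:
    mu_bp = config.theta / (4.0 * config.ne * config.locus_length)
    ts = msprime.sim_ancestry(
        samples=config.n,
        ploidy=1,
        sequence_length=config.locus_length,
        recombination_rate=_msprime_rate_map(config),
        demography=_msprime_demography(config),
        random_seed=seed,
    )
    ts = msprime.sim_mutations(
        ts,
        rate=mu_bp,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        random_seed=seed,
    )
    return _ts_to_window(ts, config.locus_length / 2.0)


def _sweep_replicate(config: ScenarioConfig, seed: int) -> HaplotypeWindow:
    sel = config.selection
    rng = np.random.default_rng(seed)
    # sample count of the selected allele: binomial draw at the population
    # frequency, conditioned on both allele classes having >= 2 copies
    while True:
        n_derived = int(rng.binomial(config.n, sel.f))
        if 2 <= n_derived <= config.n - 2:
            break
    positions, alleles, sel_index = simulate_sweep_replicate(
        rng,
        n=config.n,
        n_derived=n_derived,
        N=config.ne,
        s=sel.s,
        f=sel.f,
        theta=config.theta,
        recomb_map=config.recombination_map(),
        L=config.locus_length,
        p_sel=config.locus_length / 2.0,
        stochastic_trajectory=sel.stochastic_trajectory,
    )
    perm = rng.permutation(config.n)
    return HaplotypeWindow(
        alleles=np.ascontiguousarray(alleles[perm]),
        positions=positions,
        evaluated_index=sel_index,
    )


def _replicate_seeds(config: ScenarioConfig, n_reps: int, stream: int) -> np.ndarray:
    ss = np.random.SeedSequence([int(config.seed) % 2**31, stream])
    return ss.generate_state(2 * n_reps + 64) % (2**31 - 1) + 1


def _simulate(
    config: ScenarioConfig,
    n_reps: int,
    make_one,
    stream: int,
    min_flank: int | None,
) -> ReplicateSet:
    seeds = _replicate_seeds(config, n_reps, stream)
    reps: list[HaplotypeWindow] = []
    spare = n_reps  # index of the next regeneration seed
    regenerated = 0
    for i in range(n_reps):
        seed = int(seeds[i])
        while True:
            win = make_one(config, seed)
            if min_flank is None:
                break
            k = win.evaluated_index
            if k >= min_flank and win.S - 1 - k >= min_flank:
                break
            regenerated += 1
            if spare >= seeds.size:
                seeds = np.concatenate(
                    [seeds, _replicate_seeds(config, n_reps, stream + 7919)]
                )
            seed = int(seeds[spare])
            spare += 1
        reps.append(win)
    return ReplicateSet(replicates=reps, scenario=config, n_regenerated=regenerated)


def simulate_neutral(
    config: ScenarioConfig, n_reps: int, min_flank: int | None = None
) -> ReplicateSet:
    """Neutral replicates (selection must be unset).

    ``min_flank``: minimum SNP count required on each side of the evaluated
    (central) site; replicates failing it are regenerated with a fresh seed
    and counted in ``n_regenerated``.
    """
    if config.selection is not None:
        raise ConfigError("simulate_neutral requires a config without selection")
    return _simulate(config, n_reps, _neutral_replicate, stream=1, min_flank=min_flank)


def simulate_sweep(
    config: ScenarioConfig, n_reps: int, min_flank: int | None = None
) -> ReplicateSet:
    """Replicates under an ongoing sweep conditioned on current frequency f.

    The selected site sits at the locus centre and is marked as each
    replicate's ``evaluated_index``.  With ``s = 0`` this degrades to a
    frequency-conditioned neutral simulation (documented behaviour, not an
    error).  Demographic change combined with selection is not supported.
    """
    if config.selection is None:
        raise ConfigError("simulate_sweep requires selection parameters")
    if config.demography.kind != "constant":
        raise ConfigError("sweep simulation supports constant population size only")
    return _simulate(config, n_reps, _sweep_replicate, stream=2, min_flank=min_flank)


def simulate_scenario(
    config: ScenarioConfig, n_reps: int, min_flank: int | None = None
) -> ReplicateSet:
    """Dispatch on whether the scenario carries selection."""
    if config.selection is None:
        return simulate_neutral(config, n_reps, min_flank)
    return simulate_sweep(config, n_reps, min_flank)


def scenario_grid(
    base: ScenarioConfig, f_values: list[float], s_values: list[float]
) -> list[ScenarioConfig]:
    """Cartesian grid of sweep configs over (f, s), with distinct seeds."""
    out = []
    for i, f in enumerate(f_values):
        for j, s in enumerate(s_values):
            seed = int(
                np.random.SeedSequence([base.seed % 2**31, i, j]).generate_state(1)[0]
                % (2**31 - 1)
            )
            out.append(
                dataclasses.replace(base, selection=Selection(s=s, f=f), seed=seed)
            )
    return out


def watterson_expected_sites(n: int, theta: float) -> float:
    """Closed-form expected segregating-site count Θ·Σ_{i=1}^{n-1} 1/i."""
    return float(theta * np.sum(1.0 / np.arange(1, n)))
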