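"""The standard validation suite: Table-1-style power studies at desk scale.

One function per study block, plus :func:`validation_suite`, which runs the
whole set with seeds derived from one master seed and returns a flat dict of
named quantities:

``power_S26 / power_S51 / power_S201``
    Default selection scenario (n=50, Θ=223, ρ=0, s=0.15, f=0.75), critical
    value calibrated at p=0.05 on the matched frequency-conditioned null,
    windows of 26/51/201 SNPs cut from one shared replicate pool.
``power_ne500 / power_ne2000``
    Same protocol with diploid effective size 500 / 2000.
``power_rho_constant / power_hotspot_weak / power_hotspot_strong``
    Constant ρ=Θ/2, and 10×/100× hotspots 2 kb downstream of the selected
    site.
``power_maf_filtered``
    Default scenario after removing singletons and doubletons (minor count
    < 3) from every replicate, null and alternative alike, with c
    recalibrated on the filtered null.
``power_at_fdr_10``
    Sensitivity at the FDR = 0.1 operating point on the default pool.
``mean_segregating_sites``
    Plain neutral standard scenario, cross-checked against Watterson's
    closed form in the acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pipeline import PowerStudy, run_power_study
from .simulate import (
    ReplicateSet,
    ScenarioConfig,
    Selection,
    simulate_neutral,
    simulate_sweep,
)

__all__ = ["ValidationSuite", "default_pool", "validation_suite"]

DEFAULT_SELECTION = Selection(s=0.15, f=0.75)
HOTSPOT_OFFSET = 2_000.0  # bp downstream of the evaluated site
MAX_WINDOW = 201


def _seed(master: int, label: str) -> int:
    import zlib

    h = np.random.SeedSequence([master % 2**31, zlib.crc32(label.encode())])
    return int(h.generate_state(1)[0] % (2**31 - 1)) + 1


def _scenario(master: int, label: str, **kw) -> ScenarioConfig:
    return ScenarioConfig(selection=DEFAULT_SELECTION, seed=_seed(master, label), **kw)


def default_pool(
    master_seed: int, n_reps: int = 1000, max_window: int = MAX_WINDOW
) -> tuple[ReplicateSet, ReplicateSet]:
    """Matched (null, alternative) pools for the default selection scenario,
    wide enough to cut windows up to ``max_window`` SNPs."""
    alt_cfg = _scenario(master_seed, "default-alt")
    null_cfg = alt_cfg.matched_null(seed=_seed(master_seed, "default-null"))
    flank = max_window // 2 + 1
    null = simulate_sweep(null_cfg, n_reps, min_flank=flank)
    alt = simulate_sweep(alt_cfg, n_reps, min_flank=flank)
    return null, alt


@dataclass
class ValidationSuite:
    values: dict[str, float] = field(default_factory=dict)
    sizes: dict[str, int] = field(default_factory=dict)
    studies: dict[str, PowerStudy] = field(default_factory=dict)

    def record(self, name: str, study: PowerStudy) -> None:
        self.values[name] = study.power
        self.sizes[name] = study.result.n_alt
        self.studies[name] = study


def validation_suite(
    master_seed: int = 1,
    n_default: int = 1000,
    n_recomb: int = 500,
    include_recombination: bool = True,
) -> ValidationSuite:
    """Run the full validation battery.

    ``n_default`` replicates (null and alternative each) for the ρ=0
    scenarios; ``n_recomb`` for the recombination scenarios, whose sweep
    genealogies are much heavier to simulate.
    """
    suite = ValidationSuite()

    # --- default scenario: one pool shared by S, filtering and FDR studies
    null, alt = default_pool(master_seed, n_default)
    for S in (26, 51, 201):
        study = run_power_study(
            alt.scenario, S=S, null_reps=null, alt_reps=alt,
            scenario_label=f"default S={S}",
        )
        suite.record(f"power_S{S}", study)
    study = run_power_study(
        alt.scenario, S=51, min_minor_count=3, null_reps=null, alt_reps=alt,
        scenario_label="default S=51, singletons+doubletons removed",
    )
    suite.record("power_maf_filtered", study)
    suite.values["power_at_fdr_10"] = suite.studies["power_S51"].power_at_fdr(0.1)
    suite.sizes["power_at_fdr_10"] = suite.sizes["power_S51"]

    # --- population-size scenarios
    for ne, name in ((500.0, "power_ne500"), (2000.0, "power_ne2000")):
        cfg = _scenario(master_seed, name, ne=ne)
        study = run_power_study(
            cfg, n_reps=n_default, S=51, scenario_label=f"Ne={ne:g}"
        )
        suite.record(name, study)

    # --- recombination scenarios
    if include_recombination:
        rho = 223.0 / 2.0
        hotspot_start = 25_000.0 + HOTSPOT_OFFSET
        recomb = {
            "power_rho_constant": dict(rho_background=rho),
            "power_hotspot_weak": dict(
                rho_background=rho, hotspots=((hotspot_start, 10.0),)
            ),
            "power_hotspot_strong": dict(
                rho_background=rho, hotspots=((hotspot_start, 100.0),)
            ),
        }
        for name, kw in recomb.items():
            cfg = _scenario(master_seed, name, **kw)
            study = run_power_study(
                cfg, n_reps=n_recomb, S=51, scenario_label=name
            )
            suite.record(name, study)

    # --- simulator sanity: plain neutral segregating sites
    neutral = simulate_neutral(
        ScenarioConfig(seed=_seed(master_seed, "plain-neutral")), n_default
    )
    counts = np.array([w.S for w in neutral.replicates], dtype=float)
    suite.values["mean_segregating_sites"] = float(counts.mean())
    suite.sizes["mean_segregating_sites"] = int(counts.size)
    return suite
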