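"""End-to-end power studies: simulate → ascertain → window → statistic → power.

This is the validation harness of the Svd test.  For a sweep scenario it
simulates matched null (s = 0, same frequency conditioning and the same
ascertainment/windowing) and alternative replicate sets, computes the chosen
statistic at the evaluated site of the S-SNP centred window of every
replicate, calibrates the critical value on the null at nominal level p and
reports the detection power on the alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ascertainment import filter_by_maf
from .calibration import (
    NullDistribution,
    PowerResult,
    assert_matched_null,
    detection_power,
    make_null_distribution,
    power_at_fdr,
)
from .comparison import fay_wu_h_normalized, ihs_unstandardized, tajima_d
from .core import HaplotypeWindow, extract_centered_window, svd_at_site
from .simulate import ReplicateSet, ScenarioConfig, simulate_scenario

__all__ = [
    "STATISTICS",
    "DEFAULT_TAILS",
    "PowerStudy",
    "statistic_at_center",
    "replicate_values",
    "run_power_study",
    "power_surface",
]

#: selection-appropriate tails: a sweep inflates Svd, deflates D and H, and
#: drives the unstandardized iHS negative (extended derived homozygosity)
DEFAULT_TAILS = {"svd": "upper", "tajima_d": "lower", "fay_wu_h": "lower", "ihs": "lower"}
STATISTICS = tuple(DEFAULT_TAILS)


def statistic_at_center(
    window: HaplotypeWindow,
    statistic: str = "svd",
    *,
    include_evaluated: bool = True,
    ddof: int = 1,
) -> float | None:
    """Evaluate one statistic at the window's evaluated site (None if
    undefined there)."""
    k = window.evaluated_index
    if statistic == "svd":
        res = svd_at_site(window, k, include_evaluated=include_evaluated, ddof=ddof)
        return res.svd if res.defined else None
    if statistic == "tajima_d":
        res = tajima_d(window)
    elif statistic == "fay_wu_h":
        res = fay_wu_h_normalized(window)
    elif statistic == "ihs":
        res = ihs_unstandardized(window, k)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    return res.value if res.defined else None


def replicate_values(
    reps: ReplicateSet,
    S: int,
    statistic: str = "svd",
    *,
    min_minor_count: int = 0,
    include_evaluated: bool = True,
    ddof: int = 1,
) -> list[float | None]:
    """Per-replicate statistic at the centre of the S-SNP window.

    Ascertainment (minor-allele-count filtering) is applied to the full
    replicate before window extraction, exactly as it would be to real
    genotyping data; replicates left without a full centred window after
    filtering yield None.
    """
    out: list[float | None] = []
    for rep in reps.replicates:
        win = rep
        if min_minor_count > 0:
            win = filter_by_maf(win, min_minor_count)
        try:
            win = extract_centered_window(win, S)
        except ValueError:
            out.append(None)
            continue
        out.append(
            statistic_at_center(
                win, statistic, include_evaluated=include_evaluated, ddof=ddof
            )
        )
    return out


def _oriented(values: list[float | None], tail: str) -> list[float | None]:
    if tail == "upper":
        return values
    if tail == "lower":
        return [None if v is None else -v for v in values]
    if tail == "abs":
        return [None if v is None else abs(v) for v in values]
    raise ValueError(f"unknown tail {tail!r}")


@dataclass
class PowerStudy:
    """Everything one calibrated power estimate rests on."""

    statistic: str
    S: int
    tail: str
    null_config: ScenarioConfig
    alt_config: ScenarioConfig
    null: NullDistribution
    result: PowerResult
    null_values: list[float | None]
    alt_values: list[float | None]

    @property
    def power(self) -> float:
        return self.result.power

    def power_at_fdr(self, fdr: float = 0.1) -> float:
        return power_at_fdr(
            _oriented(self.null_values, self.tail),
            _oriented(self.alt_values, self.tail),
            fdr,
        )


def run_power_study(
    alt_config: ScenarioConfig,
    n_reps: int = 1000,
    S: int = 51,
    statistic: str = "svd",
    *,
    p: float = 0.05,
    min_minor_count: int = 0,
    tail: str | None = None,
    null_config: ScenarioConfig | None = None,
    null_reps: ReplicateSet | None = None,
    alt_reps: ReplicateSet | None = None,
    include_evaluated: bool = True,
    scenario_label: str = "",
) -> PowerStudy:
    """Calibrate on the matched null and estimate power for one scenario.

    The null is ``alt_config.matched_null()`` unless given explicitly; it is
    always checked against the structural matched-null rule (identical in
    everything but the selection coefficient and seed).  Pre-simulated
    replicate sets may be passed to share them across window sizes or
    ascertainment settings.
    """
    if null_config is None:
        null_config = (
            null_reps.scenario if null_reps is not None else alt_config.matched_null()
        )
    assert_matched_null(null_config, alt_config)
    tail = DEFAULT_TAILS[statistic] if tail is None else tail
    min_flank = S // 2 + 1
    if null_reps is None:
        null_reps = simulate_scenario(null_config, n_reps, min_flank=min_flank)
    if alt_reps is None:
        alt_reps = simulate_scenario(alt_config, n_reps, min_flank=min_flank)
    kwargs = dict(
        min_minor_count=min_minor_count, include_evaluated=include_evaluated
    )
    null_values = replicate_values(null_reps, S, statistic, **kwargs)
    alt_values = replicate_values(alt_reps, S, statistic, **kwargs)
    null = make_null_distribution(statistic, _oriented(null_values, tail), p=p)
    result = detection_power(
        _oriented(alt_values, tail), null.c, scenario=scenario_label or statistic
    )
    return PowerStudy(
        statistic=statistic,
        S=S,
        tail=tail,
        null_config=null_config,
        alt_config=alt_config,
        null=null,
        result=result,
        null_values=null_values,
        alt_values=alt_values,
    )


def power_surface(
    grid: list[ScenarioConfig],
    statistic: str = "svd",
    S: int = 51,
    n_reps: int = 200,
    **kwargs,
) -> pd.DataFrame:
    """One calibrated PowerResult per grid scenario, as a tidy table."""
    rows = []
    for cfg in grid:
        sel = cfg.selection
        study = run_power_study(cfg, n_reps=n_reps, S=S, statistic=statistic, **kwargs)
        rows.append(
            {
                "s": sel.s if sel else 0.0,
                "f": sel.f if sel else np.nan,
                "S": S,
                "statistic": statistic,
                "power": study.power,
                "se": study.result.se,
                "c": study.null.c,
                "n_alt": study.result.n_alt,
            }
        )
    return pd.DataFrame(rows)
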