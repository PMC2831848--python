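"""Sliding-window Svd scan along a chromosome.

The window of fixed length S slides one SNP at a time; at each evaluable
SNP the S-SNP window centred on it is rebuilt, its own (window-local) MARH
constructed, and Svd computed there.  SNPs without a full centred window
(closer than ⌊S/2⌋ to either chromosome end) are skipped rather than given
truncated windows, keeping the /S normalisation comparable along the track.
Empirical p-values come from the chromosome-wide distribution of defined
Svd values; candidate loci get simulation-matched p-values against
replicates tailored to the locus (frequency of the putative selected
allele, ascertainment, SNP count and target index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import HaplotypeWindow, extract_centered_window, svd_at_site
from .simulate import ReplicateSet

__all__ = [
    "ScanTrack",
    "CandidateReport",
    "sliding_scan",
    "empirical_pvalues",
    "flagged_clusters",
    "candidate_pvalues",
]


@dataclass
class ScanTrack:
    """Per-SNP scan results as a tidy DataFrame.

    Columns: site_id, position, S, svd, defined, empirical_p,
    top_percentile_flag.  SNPs too close to a chromosome end carry
    defined=False and no p-value.
    """

    table: pd.DataFrame
    S: int

    def defined_values(self) -> np.ndarray:
        t = self.table
        return t.loc[t.defined, "svd"].to_numpy(dtype=float)


@dataclass
class CandidateReport:
    """Per-SNP simulation-matched p-values for a candidate locus."""

    table: pd.DataFrame
    n_replicates: int
    locus_S: int


def sliding_scan(
    chromosome: HaplotypeWindow,
    S: int,
    *,
    include_evaluated: bool = True,
    ddof: int = 1,
) -> ScanTrack:
    """Svd at every SNP of a chromosome using S-SNP centred windows."""
    if S > chromosome.S:
        raise ValueError(f"window S={S} exceeds chromosome SNP count {chromosome.S}")
    half = S // 2
    n_sites = chromosome.S
    svd = np.full(n_sites, np.nan)
    defined = np.zeros(n_sites, dtype=bool)
    for k in range(half, n_sites - (S - half) + 1):
        win = extract_centered_window(chromosome, S, center=k)
        res = svd_at_site(
            win, win.evaluated_index, include_evaluated=include_evaluated, ddof=ddof
        )
        if res.defined:
            svd[k] = res.svd
            defined[k] = True
    ids = (
        list(chromosome.site_ids)
        if chromosome.site_ids is not None
        else [f"site_{k}" for k in range(n_sites)]
    )
    table = pd.DataFrame(
        {
            "site_id": ids,
            "position": chromosome.positions,
            "S": S,
            "svd": svd,
            "defined": defined,
            "empirical_p": np.nan,
            "top_percentile_flag": False,
        }
    )
    return ScanTrack(table=table, S=S)


def empirical_pvalues(track: ScanTrack, top_quantile: float = 0.99) -> ScanTrack:
    """Assign upper-tail empirical p-values from the chromosome-wide
    distribution of defined Svd values; ties share the larger p.

    ``top_percentile_flag`` marks SNPs with Svd > 0 in the top (1 −
    top_quantile) share of the *positive* values, the convention used to
    plot genome-scan signals.
    """
    t = track.table
    vals = track.defined_values()
    if vals.size < 100:
        raise ValueError(f"need >= 100 defined Svd values, got {vals.size}")
    srt = np.sort(vals)
    N = srt.size
    def_idx = np.flatnonzero(t.defined.to_numpy())
    # p = proportion of all defined values >= this one (ties inclusive)
    ranks = np.searchsorted(srt, vals, side="left")
    pvals = (N - ranks) / N
    t.loc[t.index[def_idx], "empirical_p"] = pvals
    pos = srt[srt > 0]
    if pos.size:
        cut = np.quantile(pos, top_quantile)
        flag = np.zeros(len(t), dtype=bool)
        flag[def_idx] = (vals > 0) & (vals >= cut)
        t["top_percentile_flag"] = flag
    return track


def flagged_clusters(track: ScanTrack, max_gap: int = 20) -> pd.DataFrame:
    """Merge runs of flagged SNPs separated by at most ``max_gap`` SNPs into
    reported intervals (BED-style 0-based half-open bp coordinates)."""
    t = track.table
    idx = np.flatnonzero(t.top_percentile_flag.to_numpy())
    rows = []
    if idx.size:
        start = prev = idx[0]
        for i in idx[1:]:
            if i - prev > max_gap:
                rows.append((start, prev))
                start = i
            prev = i
        rows.append((start, prev))
    return pd.DataFrame(
        [
            {
                "start_bp": int(np.floor(t.position.iloc[a])),
                "end_bp": int(np.floor(t.position.iloc[b])) + 1,
                "first_snp": t.site_id.iloc[a],
                "last_snp": t.site_id.iloc[b],
                "n_snps": int(t.top_percentile_flag.iloc[a : b + 1].sum()),
                "max_svd": float(t.svd.iloc[a : b + 1].max()),
            }
            for a, b in rows
        ],
        columns=["start_bp", "end_bp", "first_snp", "last_snp", "n_snps", "max_svd"],
    )


def candidate_pvalues(
    locus: HaplotypeWindow,
    matched: ReplicateSet,
    target_index: int | None = None,
    *,
    include_evaluated: bool = True,
) -> CandidateReport:
    """Simulation-matched per-SNP p-values for a candidate locus.

    Each matched replicate is trimmed to the locus's SNP count with the
    simulated selected SNP at ``target_index`` (the locus's putative target,
    default: the locus's evaluated_index).  For every locus SNP j, the
    observed Svd (computed in the context of the full locus window) is
    compared with the simulated Svd distribution at the same column, and
    p_sim(j) is the exceedance proportion.
    """
    S = locus.S
    if target_index is None:
        target_index = locus.evaluated_index
    if target_index is None:
        raise ValueError("no target index: set locus.evaluated_index or pass one")
    sim_svd: list[np.ndarray] = []
    for rep in matched.replicates:
        k = rep.evaluated_index
        if k is None:
            raise ValueError("matched replicate lacks a selected-site index")
        lo = k - target_index
        hi = lo + S
        if lo < 0 or hi > rep.S:
            raise ValueError(
                "matched replicate too short to align its selected SNP with "
                f"locus index {target_index} over {S} SNPs"
            )
        win = rep.take_sites(np.arange(lo, hi))
        row = np.full(S, np.nan)
        for j in range(S):
            res = svd_at_site(win, j, include_evaluated=include_evaluated)
            if res.defined:
                row[j] = res.svd
        sim_svd.append(row)
    sim = np.asarray(sim_svd)
    obs = np.full(S, np.nan)
    for j in range(S):
        res = svd_at_site(locus, j, include_evaluated=include_evaluated)
        if res.defined:
            obs[j] = res.svd
    pvals = np.full(S, np.nan)
    for j in range(S):
        col = sim[:, j]
        col = col[np.isfinite(col)]
        if col.size and np.isfinite(obs[j]):
            pvals[j] = np.mean(col >= obs[j])
    ids = (
        list(locus.site_ids)
        if locus.site_ids is not None
        else [f"site_{k}" for k in range(S)]
    )
    table = pd.DataFrame(
        {
            "site_id": ids,
            "position": locus.positions,
            "svd_observed": obs,
            "p_sim": pvals,
        }
    )
    return CandidateReport(table=table, n_replicates=matched.n_reps, locus_S=S)
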