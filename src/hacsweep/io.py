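"""Readers and writers for the formats the tool touches.

ms-format text (``segsites:``/``positions:`` blocks of 0/1 rows, replicates
separated by ``//``) for interoperability with external coalescent
simulators; phased VCF plus a tab-delimited ancestral-allele table for real
data; minimal unphased VCF export for external phasing tools; and a
deterministic fixture generator for tests and demos.

Coordinates are 0-based half-open internally; VCF's 1-based positions are
converted at the boundary.  Ancestral alleles are assumed to be reported on
the same strand as REF/ALT; sites whose ancestral call matches neither
allele are dropped and counted, never strand-flipped.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import HaplotypeWindow, build_marh, svd_at_site
from .simulate import ReplicateSet, ScenarioConfig, Selection, simulate_neutral, simulate_sweep

__all__ = [
    "AncestralTable",
    "MsParseError",
    "read_ms",
    "write_ms",
    "read_ancestral_table",
    "write_ancestral_table",
    "read_phased",
    "write_genotype_vcf",
    "make_fixture",
]


class MsParseError(ValueError):
    pass


@dataclass
class AncestralTable:
    """site_id → ancestral allele, with a provenance tag (e.g. outgroup name).

    Sites absent from the table cannot be polarised and are excluded from
    analysis by the readers.
    """

    alleles: dict[str, str] = field(default_factory=dict)
    provenance: str = ""

    def __contains__(self, site_id: str) -> bool:
        return site_id in self.alleles

    def __getitem__(self, site_id: str) -> str:
        return self.alleles[site_id]

    def __len__(self) -> int:
        return len(self.alleles)


def read_ancestral_table(path) -> AncestralTable:
    """Tab-delimited ``site_id<TAB>ancestral_allele`` with optional
    ``#provenance=`` header line."""
    table = AncestralTable()
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#provenance="):
                    table.provenance = line.split("=", 1)[1]
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise MsParseError(f"{path}:{line_no}: expected two tab-separated fields")
            table.alleles[parts[0]] = parts[1]
    return table


def write_ancestral_table(path, table: AncestralTable) -> None:
    with open(path, "w") as fh:
        if table.provenance:
            fh.write(f"#provenance={table.provenance}\n")
        for sid, allele in table.alleles.items():
            fh.write(f"{sid}\t{allele}\n")


def read_ms(path_or_buffer) -> ReplicateSet:
    """Parse ms-style output into one HaplotypeWindow per replicate.

    Allele 0 maps to ancestral, 1 to derived (the ms convention); positions
    are the relative coordinates of the positions line.  Malformed input —
    row length disagreeing with segsites, missing positions line, truncated
    replicates — raises :class:`MsParseError` with a line number.
    """
    if hasattr(path_or_buffer, "read"):
        lines = path_or_buffer.read().splitlines()
    else:
        lines = Path(path_or_buffer).read_text().splitlines()
    reps: list[HaplotypeWindow] = []
    i = 0
    # skip any header (command line, seeds) up to the first replicate
    while i < len(lines) and lines[i].strip() != "//":
        i += 1
    while i < len(lines):
        assert lines[i].strip() == "//"
        i += 1
        while i < len(lines) and not lines[i].strip():
            i += 1
        if i >= len(lines) or not lines[i].startswith("segsites:"):
            raise MsParseError(f"line {i + 1}: expected 'segsites:' after '//'")
        segsites = int(lines[i].split(":")[1])
        i += 1
        if segsites == 0:
            reps.append(
                HaplotypeWindow(
                    alleles=np.zeros((0, 0), dtype=np.uint8), positions=np.array([])
                )
            )
            while i < len(lines) and lines[i].strip() != "//":
                i += 1
            continue
        if i >= len(lines) or not lines[i].startswith("positions:"):
            raise MsParseError(f"line {i + 1}: expected 'positions:' line")
        positions = np.array([float(x) for x in lines[i].split(":")[1].split()])
        if positions.size != segsites:
            raise MsParseError(f"line {i + 1}: {positions.size} positions != segsites {segsites}")
        i += 1
        rows = []
        while i < len(lines) and lines[i].strip() and lines[i].strip() != "//":
            row = lines[i].strip()
            if set(row) - {"0", "1"}:
                raise MsParseError(f"line {i + 1}: non-binary haplotype row")
            if len(row) != segsites:
                raise MsParseError(
                    f"line {i + 1}: row length {len(row)} != segsites {segsites}"
                )
            rows.append(np.frombuffer(row.encode(), dtype=np.uint8) - ord("0"))
            i += 1
        if not rows:
            raise MsParseError(f"line {i + 1}: replicate has no haplotype rows")
        # strictly increasing positions: nudge exact duplicates (ms prints
        # rounded coordinates)
        pos = positions.copy()
        for j in range(1, pos.size):
            if pos[j] <= pos[j - 1]:
                pos[j] = pos[j - 1] + 1e-9
        reps.append(HaplotypeWindow(alleles=np.vstack(rows), positions=pos))
        while i < len(lines) and lines[i].strip() != "//":
            if lines[i].strip():
                raise MsParseError(f"line {i + 1}: unexpected content between replicates")
            i += 1
    if not reps:
        raise MsParseError("no replicates found (missing '//' separators?)")
    return ReplicateSet(replicates=reps, scenario=None)


def write_ms(path_or_buffer, replicates: list[HaplotypeWindow] | ReplicateSet, header: str = "ms") -> None:
    """Write replicates as ms-format text (positions on their native scale
    divided by the maximum to stay in [0,1) if needed)."""
    if isinstance(replicates, ReplicateSet):
        replicates = replicates.replicates
    own = not hasattr(path_or_buffer, "write")
    fh = open(path_or_buffer, "w") if own else path_or_buffer
    try:
        fh.write(f"{header}\n\n")
        for rep in replicates:
            fh.write("//\n")
            fh.write(f"segsites: {rep.S}\n")
            pos = rep.positions
            if pos.size and pos.max() > 1.0:
                pos = pos / (pos.max() * (1.0 + 1e-9))
            fh.write("positions: " + " ".join(f"{p:.9f}" for p in pos) + "\n")
            for row in rep.alleles:
                fh.write("".join("1" if a else "0" for a in row) + "\n")
            fh.write("\n")
    finally:
        if own:
            fh.close()


def ms_roundtrip_string(replicates) -> str:
    buf = _io.StringIO()
    write_ms(buf, replicates)
    return buf.getvalue()


def read_phased(path_vcf, ancestral: AncestralTable) -> tuple[HaplotypeWindow, dict]:
    """Read phased biallelic VCF records into a chromosome-scale window.

    Each diploid sample contributes two haplotypes.  Sites are polarised
    with the ancestral table: records whose ancestral allele matches neither
    REF nor ALT, or that are absent from the table, are dropped and counted
    in the returned stats dict.  Unphased genotypes raise; multi-allelic
    sites are skipped with a count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path_vcf))
    haps: list[np.ndarray] = []
    positions: list[float] = []
    ids: list[str] = []
    anc_syms: list[str] = []
    der_syms: list[str] = []
    stats = {"no_ancestral": 0, "ancestral_mismatch": 0, "multiallelic": 0, "monomorphic": 0}
    for rec in vcf:
        sid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        if len(rec.ALT) != 1:
            stats["multiallelic"] += 1
            continue
        if sid not in ancestral:
            stats["no_ancestral"] += 1
            continue
        anc = ancestral[sid]
        ref, alt = rec.REF, rec.ALT[0]
        if anc == ref:
            der = alt
        elif anc == alt:
            der = ref
        else:
            stats["ancestral_mismatch"] += 1
            continue
        col = []
        for g in rec.genotypes:  # [a0, a1, phased]
            if len(g) < 3 or not g[2]:
                raise MsParseError(f"unphased genotype at {sid}")
            for a in g[:2]:
                if a < 0:
                    raise MsParseError(f"missing allele at {sid}")
                sym = ref if a == 0 else alt
                col.append(1 if sym == der else 0)
        col = np.asarray(col, dtype=np.uint8)
        if col.min() == col.max():
            stats["monomorphic"] += 1
            continue
        haps.append(col)
        positions.append(float(rec.POS - 1))  # to 0-based
        ids.append(sid)
        anc_syms.append(anc)
        der_syms.append(der)
    if not haps:
        import warnings

        warnings.warn("no usable sites read from VCF (empty ancestral table?)")
        return (
            HaplotypeWindow(alleles=np.zeros((0, 0), np.uint8), positions=np.array([])),
            stats,
        )
    alleles = np.column_stack(haps)
    order = np.argsort(positions)
    win = HaplotypeWindow(
        alleles=alleles[:, order],
        positions=np.asarray(positions)[order],
        site_ids=[ids[i] for i in order],
        ancestral_alleles=[anc_syms[i] for i in order],
        derived_alleles=[der_syms[i] for i in order],
    )
    return win, stats


def write_genotype_vcf(
    path,
    genotypes: np.ndarray,
    positions: np.ndarray,
    site_ids=None,
    chrom: str = "1",
    ref_alt=None,
) -> None:
    """Write an unphased genotype dosage matrix (n_ind × S of {0,1,2}) as a
    minimal VCF, the handoff format for external phasing tools."""
    genotypes = np.asarray(genotypes)
    n_ind, S = genotypes.shape
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(f"ind{i}" for i in range(n_ind))
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for j in range(S):
            sid = site_ids[j] if site_ids is not None else f"snp{j}"
            ref, alt = ref_alt[j] if ref_alt is not None else ("A", "G")
            pos1 = int(np.floor(positions[j])) + 1  # back to 1-based
            gts = "\t".join(gt_map[int(g)] for g in genotypes[:, j])
            fh.write(f"{chrom}\t{pos1}\t{sid}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def _brute_force_variance(values) -> float:
    values = list(values)
    mean = sum(values) / len(values)
    return sum((v - mean) ** 2 for v in values) / (len(values) - 1)


def make_fixture(out_dir, seed: int = 0) -> dict:
    """Write a small deterministic set of test inputs under ``out_dir``.

    (a) a 50-haplotype neutral ms file (small Θ so files stay tiny);
    (b) a sweep ms file (s = 0.15, f = 0.75) with the selected site central;
    (c) a 4-sample toy phased VCF plus ancestral table;
    (d) a JSON manifest of expected Svd values computed by an independent
        brute-force variance oracle.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    theta = 20.0
    neutral_cfg = ScenarioConfig(n=50, theta=theta, seed=seed)
    sweep_cfg = ScenarioConfig(
        n=50, theta=theta, seed=seed + 1, selection=Selection(s=0.15, f=0.75)
    )
    neutral = simulate_neutral(neutral_cfg, 3, min_flank=5)
    sweep = simulate_sweep(sweep_cfg, 3, min_flank=5)
    write_ms(out / "neutral.ms", neutral, header="hacsweep-fixture neutral")
    write_ms(out / "sweep.ms", sweep, header="hacsweep-fixture sweep")

    rng = np.random.default_rng(seed)
    n_sites = 3
    vcf_positions = np.array([99.0, 199.0, 299.0])
    ref_alt = [("A", "G"), ("C", "T"), ("G", "A")]
    while True:
        hap = rng.integers(0, 2, size=(8, n_sites))
        d = hap.sum(axis=0)
        if np.all((d > 0) & (d < 8)):
            break
    table = AncestralTable(provenance="toy_outgroup")
    lines = []
    for j in range(n_sites):
        ref, alt = ref_alt[j]
        table.alleles[f"rs{j}"] = ref  # ancestral = REF in the toy data
    with open(out / "toy_phased.vcf", "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(f"s{i}" for i in range(4))
            + "\n"
        )
        for j in range(n_sites):
            ref, alt = ref_alt[j]
            gts = "\t".join(
                f"{hap[2 * i, j]}|{hap[2 * i + 1, j]}" for i in range(4)
            )
            fh.write(
                f"1\t{int(vcf_positions[j]) + 1}\trs{j}\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )
    write_ancestral_table(out / "ancestral.tsv", table)

    manifest = {"seed": seed, "svd": []}
    for label, reps in (("neutral", neutral), ("sweep", sweep)):
        for r, rep in enumerate(reps.replicates):
            k = rep.evaluated_index
            ref = build_marh(rep)
            res = svd_at_site(rep, k, ref)
            entry = {"file": f"{label}.ms", "replicate": r, "k": int(k)}
            if res.defined:
                # cross-check against the brute-force oracle before freezing
                h = np.count_nonzero(rep.alleles != ref.alleles[None, :], axis=1)
                major = h[rep.alleles[:, k] == ref.alleles[k]]
                minor = h[rep.alleles[:, k] != ref.alleles[k]]
                vd = _brute_force_variance(minor) - _brute_force_variance(major)
                f_d = rep.alleles[:, k].mean()
                expect = f_d * vd / rep.S
                assert abs(expect - res.svd) < 1e-9
                entry["svd"] = res.svd
            else:
                entry["svd"] = None
            manifest["svd"].append(entry)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
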