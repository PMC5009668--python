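"""Plain-text interchange: TSV tables, phased VCF panels, SAM ingestion.

All tabular formats are tab-separated with a header row.  Coordinates in
the region dialect are 1-based inclusive.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .genealogy import HaplotypePanel
from .insert_model import InsertObservation, InsertSizeDistribution, STRRegion
from .pipeline import AlignedPairRecord

log = logging.getLogger(__name__)

__all__ = [
    "read_observations_tsv",
    "write_observations_tsv",
    "read_region_tsv",
    "write_region_tsv",
    "read_insert_distribution_tsv",
    "write_insert_distribution_tsv",
    "read_truth_tsv",
    "write_truth_tsv",
    "write_calls_tsv",
    "read_calls_tsv",
    "write_scores_tsv",
    "write_panel_vcf",
    "read_panel_vcf",
    "read_sam_pairs",
    "write_sam_fixture",
]


# -- TSV tables -------------------------------------------------------------


def read_observations_tsv(path) -> dict[str, list[InsertObservation]]:
    """Observations TSV with columns ``sample_id``, ``s``, ``e``."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "s", "e"):
        if col not in df.columns:
            raise ValueError(f"observations TSV missing column {col!r}")
    out: dict[str, list[InsertObservation]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.sample_id, []).append(InsertObservation(int(row.s), int(row.e)))
    return out


def write_observations_tsv(obs_by_sample: dict[str, list[InsertObservation]], path) -> None:
    rows = [(s, ob.s, ob.e) for s, obs in obs_by_sample.items() for ob in obs]
    pd.DataFrame(rows, columns=["sample_id", "s", "e"]).to_csv(path, sep="\t", index=False)


def read_region_tsv(path) -> list[STRRegion]:
    """BED-like region TSV: chrom, start, end, unit, ref_repeat, id
    (start/end 1-based inclusive in this dialect)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
    return [
        STRRegion(r.chrom, int(r.start), int(r.end), int(r.unit), int(r.ref_repeat),
                  id=str(r.id))
        for r in df.itertuples(index=False)
    ]


def write_region_tsv(regions: list[STRRegion], path) -> None:
    rows = [(r.chrom, r.start, r.end, r.unit, r.ref_repeat, r.id) for r in regions]
    pd.DataFrame(rows, columns=["chrom", "start", "end", "unit", "ref_repeat", "id"]
                 ).to_csv(path, sep="\t", index=False)


def read_insert_distribution_tsv(path, K: int = 2000) -> InsertSizeDistribution:
    """Two-column TSV (length, probability)."""
    df = pd.read_csv(path, sep="\t")
    pmf = {int(l): float(p) for l, p in zip(df.iloc[:, 0], df.iloc[:, 1])}
    return InsertSizeDistribution(pmf, K=K)


def write_insert_distribution_tsv(dist: InsertSizeDistribution, path) -> None:
    lengths = np.flatnonzero(dist.p)
    pd.DataFrame({"length": lengths, "probability": dist.p[lengths]}
                 ).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> dict[str, tuple[int, int]]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return {r.sample_id: (int(r.n1), int(r.n2)) for r in df.itertuples(index=False)}


def write_truth_tsv(truth: dict[str, tuple[int, int]], path) -> None:
    rows = [(s, n1, n2) for s, (n1, n2) in truth.items()]
    pd.DataFrame(rows, columns=["sample_id", "n1", "n2"]).to_csv(path, sep="\t", index=False)


def write_calls_tsv(calls: dict[str, tuple[int, int]], path,
                    beliefs: dict[str, np.ndarray] | None = None,
                    mu_s: float | None = None) -> None:
    rows = []
    for s, (n1, n2) in calls.items():
        belief_max = ""
        if beliefs:
            b1 = beliefs.get(f"{s}_1")
            b2 = beliefs.get(f"{s}_2")
            if b1 is not None and b2 is not None:
                belief_max = f"{min(b1.max(), b2.max()):.6g}"
        rows.append((s, n1, n2, belief_max, "" if mu_s is None else f"{mu_s:g}"))
    pd.DataFrame(rows, columns=["sample_id", "n_hat_1", "n_hat_2", "belief_max",
                                "mu_s_selected"]).to_csv(path, sep="\t", index=False)


def read_calls_tsv(path) -> dict[str, tuple[int, int]]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return {r.sample_id: (int(r.n_hat_1), int(r.n_hat_2)) for r in df.itertuples(index=False)}


def write_scores_tsv(scores, path) -> None:
    rows = [(rs.mu_s, rs.score) for rs in scores]
    pd.DataFrame(rows, columns=["mu_s", "score"]).to_csv(path, sep="\t", index=False)


# -- VCF --------------------------------------------------------------------


def write_panel_vcf(panel: HaplotypePanel, chrom: str, path) -> None:
    """Minimal phased VCF 4.2 for a biallelic haplotype panel."""
    samples = []
    for lab in panel.labels[0::2]:
        if not lab.endswith("_1"):
            raise ValueError(f"unexpected haplotype label {lab!r}")
        samples.append(lab[:-2])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for j, pos in enumerate(panel.positions):
            gts = [
                f"{panel.alleles[2 * i, j]}|{panel.alleles[2 * i + 1, j]}"
                for i in range(len(samples))
            ]
            fh.write(f"{chrom}\t{pos}\t.\tA\tC\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n")


def read_panel_vcf(path, window: tuple[int, int] | None = None) -> HaplotypePanel:
    """Phased biallelic SNVs from a VCF into a haplotype panel.

    Unphased, multiallelic or non-SNV records are skipped (count logged).
    ``window`` restricts to positions within ``[lo, hi]`` inclusive.
    """
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        positions: list[int] = []
        rows: list[list[int]] = []
        skipped = 0
        for rec in vf:
            if window and not (window[0] <= rec.pos <= window[1]):
                continue
            if rec.alts is None or len(rec.alts) != 1:
                skipped += 1
                continue
            if len(rec.ref) != 1 or len(rec.alts[0]) != 1:
                skipped += 1
                continue
            gts = [rec.samples[s] for s in samples]
            if any(not g.phased or None in g["GT"] for g in gts):
                skipped += 1
                continue
            positions.append(rec.pos)
            row: list[int] = []
            for g in gts:
                row.extend(int(a) for a in g["GT"])
            rows.append(row)
    if skipped:
        log.info("read_panel_vcf: skipped %d unphased/non-biallelic records", skipped)
    if not rows:
        raise ValueError("no usable phased biallelic SNVs in VCF")
    from .genealogy import haplotype_labels

    alleles = np.array(rows, dtype=np.uint8).T
    return HaplotypePanel(np.array(positions), alleles, haplotype_labels(samples))


# -- SAM --------------------------------------------------------------------


def read_sam_pairs(path, sample_id: str = "sample", mapq_min: int = 20) -> list[AlignedPairRecord]:
    """Aligned pairs from a SAM/BAM file for spanning-pair extraction.

    Mates are joined by query name; both must be mapped to the same
    reference with MAPQ >= ``mapq_min`` and FR orientation.
    """
    mates: dict[str, list] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for read in fh:
            if (read.is_unmapped or read.mate_is_unmapped or read.is_secondary
                    or read.is_supplementary or read.mapping_quality < mapq_min):
                continue
            mates.setdefault(read.query_name, []).append(
                (read.reference_id, read.is_reverse, read.reference_start + 1,
                 read.reference_end, read.template_length)
            )
    records = []
    dropped = 0
    for qname, pair in mates.items():
        if len(pair) != 2 or pair[0][0] != pair[1][0]:
            dropped += 1
            continue
        fwd = [p for p in pair if not p[1]]
        rev = [p for p in pair if p[1]]
        if len(fwd) != 1 or len(rev) != 1:
            dropped += 1
            continue
        records.append(AlignedPairRecord(
            sample_id, fwd_start=fwd[0][2], rev_end=rev[0][3],
            fwd_strand="+", rev_strand="-", tlen=abs(fwd[0][4]),
        ))
    if dropped:
        log.info("read_sam_pairs: dropped %d incomplete/discordant pairs", dropped)
    return records


def write_sam_fixture(obs: list[InsertObservation], region: STRRegion, path,
                      read_len: int = 100, chrom_len: int = 300_000_000) -> None:
    """Write a minimal plain-text SAM encoding observations as proper pairs.

    For testing ingestion round trips only: each observation becomes a
    99/147 flag pair with ``read_len``-M CIGARs placed so the forward read
    starts at ``s`` and the reverse read ends at ``e``.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{region.chrom}\tLN:{chrom_len}\n")
        seq = "A" * read_len
        qual = "I" * read_len
        for j, ob in enumerate(sorted(obs, key=lambda o: o.s)):
            rev_start = ob.e - read_len + 1
            tlen = ob.e - ob.s + 1
            fh.write(f"pair{j}\t99\t{region.chrom}\t{ob.s}\t60\t{read_len}M\t=\t"
                     f"{rev_start}\t{tlen}\t{seq}\t{qual}\n")
            fh.write(f"pair{j}\t147\t{region.chrom}\t{rev_start}\t60\t{read_len}M\t=\t"
                     f"{ob.s}\t{-tlen}\t{seq}\t{qual}\n")
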