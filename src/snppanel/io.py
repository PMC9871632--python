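"""Readers/writers for the standard formats the toolkit touches.

VCF 4.x (GT required) via cyvcf2, FASTA via pyfaidx, GFF3 via gffutils,
plus the panel-manifest TSV/BED and the sample->group table. Everything is
translated into the internal :class:`~snppanel.containers.GenotypeMatrix`
/ :class:`~snppanel.containers.MarkerRecord` containers at the boundary.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, MarkerRecord, PanelManifest


class VcfParseError(ValueError):
    pass


class ReferenceLookupError(KeyError):
    pass


# --------------------------------------------------------------------------
# VCF
# --------------------------------------------------------------------------

def read_vcf(path: str | Path, groups: dict[str, str] | None = None) -> GenotypeMatrix:
    """Read a VCF into an ALT-dosage matrix.

    Dosage counts non-reference alleles; any genotype containing a missing
    allele (``./.`` and half-missing ``0/.`` alike) becomes the missing
    sentinel. Multiallelic records are retained and flagged for the
    downstream biallelic filter. Phasing is ignored.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    markers: list[MarkerRecord] = []
    columns: list[np.ndarray] = []
    for i, v in enumerate(vcf):
        if not v.ALT:
            continue  # monomorphic reference records carry no marker
        alt = ",".join(v.ALT)
        mid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}"
        markers.append(
            MarkerRecord(
                id=mid,
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alt=alt,
                multiallelic=len(v.ALT) > 1,
            )
        )
        col = np.full(len(samples), MISSING, dtype=np.int16)
        if samples:
            for s, gt in enumerate(v.genotypes):
                alleles = gt[:-1]  # last element is the phasing flag
                if len(alleles) == 0 or any(a < 0 for a in alleles):
                    continue
                col[s] = sum(1 for a in alleles if a > 0)
        columns.append(col)

    dosage = (
        np.column_stack(columns)
        if columns
        else np.empty((len(samples), 0), dtype=np.int16)
    )
    if groups is not None:
        groups = {s: g for s, g in groups.items() if s in set(samples)}
    return GenotypeMatrix(samples, markers, dosage, groups)


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT fields (round-trips with read_vcf)."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = []
        for m in matrix.markers:
            if m.chrom not in chroms:
                chroms.append(m.chrom)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if matrix.samples:
            header += ["FORMAT"] + matrix.samples
        fh.write("\t".join(header) + "\n")
        order = sorted(
            range(matrix.n_markers),
            key=lambda j: (matrix.markers[j].chrom, matrix.markers[j].pos),
        )
        for j in order:
            m = matrix.markers[j]
            row = [m.chrom, str(m.pos), m.id, m.ref, m.alt, ".", "PASS", "."]
            if matrix.samples:
                row.append("GT")
                row.extend(gt_map[int(d)] for d in matrix.column(j))
            fh.write("\t".join(row) + "\n")


# --------------------------------------------------------------------------
# FASTA flanks
# --------------------------------------------------------------------------

def extract_flanks(
    markers: Sequence[MarkerRecord], fasta_path: str | Path, flank_size: int = 50
) -> list[MarkerRecord]:
    """Populate left/right flanks of exactly ``flank_size`` bases.

    Flanks are truncated at contig edges; truncation is flagged on the
    record so the specificity stage can reject short probes.
    """
    from pyfaidx import Fasta

    if flank_size < 1:
        raise ValueError("flank_size must be >= 1")
    fa = Fasta(str(fasta_path))
    missing_chroms = sorted({m.chrom for m in markers} - set(fa.keys()))
    if missing_chroms:
        raise ReferenceLookupError(
            f"chromosome(s) absent from FASTA: {missing_chroms}"
        )
    out = []
    for m in markers:
        seq = fa[m.chrom]
        left_start = max(0, m.pos - 1 - flank_size)
        left = str(seq[left_start : m.pos - 1])
        right = str(seq[m.pos : m.pos + flank_size])
        out.append(
            MarkerRecord(
                id=m.id,
                chrom=m.chrom,
                pos=m.pos,
                ref=m.ref,
                alt=m.alt,
                left_flank=left,
                right_flank=right,
                region=m.region,
                multiallelic=m.multiallelic,
                flank_truncated=len(left) < flank_size or len(right) < flank_size,
            )
        )
    return out


# --------------------------------------------------------------------------
# GFF3 region classification
# --------------------------------------------------------------------------

def classify_region(
    markers: Sequence[MarkerRecord],
    gff_path: str | Path,
    promoter_window_bp: int = 5000,
) -> list[MarkerRecord]:
    """Assign each marker exactly one region label from gene annotation.

    Precedence: exon > intron > upstream > downstream > intergenic.
    Upstream/downstream are strand-aware windows of ``promoter_window_bp``
    beyond the gene boundaries (for a minus-strand gene, upstream lies past
    its rightmost coordinate). A feature-free GFF leaves all markers
    ``unknown`` with a warning.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            str(gff_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        genes = list(db.features_of_type("gene"))
        exons = list(db.features_of_type("exon"))
    except (ValueError, gffutils.exceptions.EmptyInputError):
        # gffutils rejects feature-free files outright
        genes, exons = [], []
    if not genes and not exons:
        warnings.warn("GFF contains no gene/exon features; all regions unknown")
        return [
            MarkerRecord(
                id=m.id, chrom=m.chrom, pos=m.pos, ref=m.ref, alt=m.alt,
                left_flank=m.left_flank, right_flank=m.right_flank,
                region="unknown", multiallelic=m.multiallelic,
                flank_truncated=m.flank_truncated,
            )
            for m in markers
        ]

    exon_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for e in exons:
        exon_by_chrom.setdefault(e.seqid, []).append((e.start, e.end))
    gene_by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for g in genes:
        gene_by_chrom.setdefault(g.seqid, []).append((g.start, g.end, g.strand))

    out = []
    for m in markers:
        region = "intergenic"
        if any(s <= m.pos <= e for s, e in exon_by_chrom.get(m.chrom, ())):
            region = "exon"
        elif any(s <= m.pos <= e for s, e, _ in gene_by_chrom.get(m.chrom, ())):
            region = "intron"
        else:
            up = down = False
            for s, e, strand in gene_by_chrom.get(m.chrom, ()):
                if strand == "-":
                    up = up or e < m.pos <= e + promoter_window_bp
                    down = down or s - promoter_window_bp <= m.pos < s
                else:
                    up = up or s - promoter_window_bp <= m.pos < s
                    down = down or e < m.pos <= e + promoter_window_bp
            if up:
                region = "upstream"
            elif down:
                region = "downstream"
        out.append(
            MarkerRecord(
                id=m.id, chrom=m.chrom, pos=m.pos, ref=m.ref, alt=m.alt,
                left_flank=m.left_flank, right_flank=m.right_flank,
                region=region, multiallelic=m.multiallelic,
                flank_truncated=m.flank_truncated,
            )
        )
    return out


# --------------------------------------------------------------------------
# Panel manifest + group table
# --------------------------------------------------------------------------

def write_panel_manifest(
    manifest: PanelManifest, path: str | Path, bed_path: str | Path | None = None
) -> None:
    manifest.table.to_csv(path, sep="\t", index=False)
    if bed_path is not None:
        manifest.to_bed().to_csv(bed_path, sep="\t", index=False, header=False)


def read_panel_manifest(path: str | Path) -> PanelManifest:
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str, "id": str})
    return PanelManifest(table)  # duplicate (chrom,pos) rejected in validation


def read_groups(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample, group) TSV, with or without a header."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if list(df.iloc[0]) == ["sample", "group"]:
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_groups(groups: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for s, g in groups.items():
            fh.write(f"{s}\t{g}\n")
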