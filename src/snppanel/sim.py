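"""Synthetic two-population inbred genotype datasets.

Emulates the study design the toolkit targets: two differentiated breeding
pools (seed-parent "B" and restorer "R" lines) of highly homozygous
inbreds, genotyped at biallelic SNPs. Differentiation follows the
Balding–Nichols model — subpopulation ALT frequencies are Beta-distributed
around an ancestral frequency with a single drift parameter F (an FST
analog) — and inbreeding enters as a within-individual Hardy–Weinberg
departure: P(het) = 2p(1-p)(1-f).

The generator also fabricates a matching reference FASTA and GFF3 gene
annotation, with optional *injected defects* (flanking SSR tracts,
duplicated probe segments, nearby decoy variants, non-exonic placement)
whose positions are logged in a truth record, so every stage of the mining
cascade can be audited against ground truth without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .containers import MISSING, GenotypeMatrix, MarkerRecord

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study-condition defaults: 195 B-lines + 182 R-lines, 7 chromosomes,
    inbreeding high enough that Ho/He sits near the observed 0.03/0.29."""

    n_per_group: tuple[int, int] = (195, 182)
    group_names: tuple[str, str] = ("B", "R")
    n_markers: int = 1000
    fst: float = 0.15  # Balding–Nichols differentiation F in [0, 1)
    inbreeding: float = 0.90  # within-individual f in [0, 1]
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.05
    missing_beta_concentration: float | None = None  # per-marker Beta rates
    n_chromosomes: int = 7
    marker_spacing_bp: int = 200  # leaves 50bp flanks + 50bp windows clear
    exon_fraction: float = 0.6
    intron_fraction: float = 0.2
    ssr_inject_fraction: float = 0.0
    dup_inject_fraction: float = 0.0
    near_variant_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "fst",
            "inbreeding",
            "missing_rate",
            "exon_fraction",
            "intron_fraction",
            "ssr_inject_fraction",
            "dup_inject_fraction",
            "near_variant_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.fst >= 1.0:
            raise ValueError("fst must be < 1")
        lo, hi = self.ancestral_maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("ancestral_maf_range must satisfy 0 < lo <= hi <= 0.5")


@dataclass
class SyntheticDataset:
    matrix: GenotypeMatrix
    truth: dict
    fasta: dict[str, str] | None = None
    gff: str | None = None
    config: SimConfig | None = None

    def all_variant_sites(self) -> list[tuple[str, int]]:
        """Every raw site in the dataset (candidates and decoys alike)."""
        return [(m.chrom, m.pos) for m in self.matrix.markers]


# --------------------------------------------------------------------------
# Genotypes
# --------------------------------------------------------------------------

def _draw_subpop_freq(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    if F == 0.0:
        return p.copy()  # no-drift limit, not a Beta with infinite parameters
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    return rng.beta(a, b)


def _sample_genotypes(
    rng: np.random.Generator, p: np.ndarray, f: float, n: int
) -> np.ndarray:
    """Dosages for n individuals at len(p) markers with inbreeding f."""
    q = 1.0 - p
    p_het = 2.0 * p * q * (1.0 - f)
    p_alt = p * p + f * p * q
    u = rng.random((n, p.size))
    g = np.zeros((n, p.size), dtype=np.int16)
    g[u < p_alt] = 2
    g[(u >= p_alt) & (u < p_alt + p_het)] = 1
    return g


def simulate_genotypes(config: SimConfig) -> SyntheticDataset:
    """Two-pool Balding–Nichols genotype matrix with truth record.

    The truth record stores ancestral and per-pool allele frequencies and
    per-marker defect flags (filled in later by
    :func:`build_reference_and_annotation`), enough to verify every filter
    decision downstream.
    """
    rng = np.random.default_rng(config.seed)
    m = config.n_markers

    p_anc = rng.uniform(*config.ancestral_maf_range, size=m)
    flip = rng.random(m) < 0.5  # ALT may be the major allele
    p_anc = np.where(flip, 1.0 - p_anc, p_anc)

    p_groups = [
        _draw_subpop_freq(rng, p_anc, config.fst) for _ in config.n_per_group
    ]

    blocks = [
        _sample_genotypes(rng, p_g, config.inbreeding, n_g)
        for p_g, n_g in zip(p_groups, config.n_per_group)
    ]
    dosage = np.vstack(blocks)

    # missingness, i.i.d. or long-tailed per-marker
    if config.missing_beta_concentration is not None and config.missing_rate > 0:
        c = config.missing_beta_concentration
        rates = rng.beta(config.missing_rate * c, (1 - config.missing_rate) * c, size=m)
    else:
        rates = np.full(m, config.missing_rate)
    miss = rng.random(dosage.shape) < rates[None, :]
    dosage[miss] = MISSING

    samples = []
    groups = {}
    for name, n_g in zip(config.group_names, config.n_per_group):
        for i in range(n_g):
            s = f"{name}{i + 1:04d}"
            samples.append(s)
            groups[s] = name

    # marker placement: round-robin over chromosomes, fixed spacing + jitter
    chrom_of = [f"chr{(j % config.n_chromosomes) + 1}" for j in range(m)]
    rank_on_chrom = [j // config.n_chromosomes for j in range(m)]
    jitter = rng.integers(0, config.marker_spacing_bp // 4, size=m)
    positions = [
        200 + r * config.marker_spacing_bp + int(h)
        for r, h in zip(rank_on_chrom, jitter)
    ]
    ref_idx = rng.integers(0, 4, size=m)
    alt_shift = rng.integers(1, 4, size=m)
    markers = [
        MarkerRecord(
            id=f"snp{j + 1:05d}",
            chrom=chrom_of[j],
            pos=positions[j],
            ref=str(_BASES[ref_idx[j]]),
            alt=str(_BASES[(ref_idx[j] + alt_shift[j]) % 4]),
        )
        for j in range(m)
    ]

    truth = {
        "config": asdict(config),
        "markers": {
            markers[j].id: {
                "chrom": markers[j].chrom,
                "pos": positions[j],
                "p_ancestral": float(p_anc[j]),
                "p_by_group": {
                    g: float(p_groups[gi][j])
                    for gi, g in enumerate(config.group_names)
                },
                "missing_rate": float(rates[j]),
                "region": None,
                "ssr_inject": False,
                "dup_inject": False,
                "near_variant": False,
                "decoy": False,
            }
            for j in range(m)
        },
    }
    matrix = GenotypeMatrix(samples, markers, dosage, groups)
    return SyntheticDataset(matrix=matrix, truth=truth, config=config)


# --------------------------------------------------------------------------
# Reference + annotation + injected defects
# --------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def build_reference_and_annotation(dataset: SyntheticDataset) -> SyntheticDataset:
    """Fabricate chromosomes and gene models around the simulated markers.

    A configurable fraction of markers land inside exons (single-exon
    genes), a fraction inside introns (two-exon genes straddling the SNP),
    the rest stay non-genic. Defect injection per the config fractions:

    * ``ssr_inject`` — a 14 bp AT tract written into the left flank;
    * ``dup_inject`` — the 101 bp probe copied to a decoy region, breaking
      exact-match uniqueness;
    * ``near_variant`` — a decoy variant record placed 10–40 bp away.

    Every injection is logged in the truth record. Defect sets are
    disjoint so each marker has exactly one expected drop reason.
    """
    config = dataset.config
    if config is None:
        raise ValueError("dataset carries no SimConfig")
    rng = np.random.default_rng(config.seed + 1)
    matrix = dataset.matrix
    m = matrix.n_markers

    order = rng.permutation(m)
    n_ssr = int(round(config.ssr_inject_fraction * m))
    n_dup = int(round(config.dup_inject_fraction * m))
    n_near = int(round(config.near_variant_fraction * m))
    ssr_set = set(order[:n_ssr].tolist())
    dup_set = set(order[n_ssr : n_ssr + n_dup].tolist())
    near_set = set(order[n_ssr + n_dup : n_ssr + n_dup + n_near].tolist())

    # chromosome scaffolds sized to fit the densest chromosome plus a tail
    # region reserved for duplicated-probe decoys
    by_chrom: dict[str, list[int]] = {}
    for j, mk in enumerate(matrix.markers):
        by_chrom.setdefault(mk.chrom, []).append(j)
    seqs: dict[str, np.ndarray] = {}
    dup_tail: dict[str, int] = {}
    for chrom, idx in by_chrom.items():
        max_pos = max(matrix.markers[j].pos for j in idx)
        length = max_pos + 200 + 150 * (len(dup_set) + 1)
        seqs[chrom] = _random_seq(rng, length)
        dup_tail[chrom] = max_pos + 300
    for j, mk in enumerate(matrix.markers):
        seqs[mk.chrom][mk.pos - 1] = mk.ref

    # SSR tracts: 14bp AT repeat ending 8bp left of the SNP
    for j in sorted(ssr_set):
        mk = matrix.markers[j]
        start = mk.pos - 1 - 8 - 14
        if start < 0:
            continue
        tract = np.array(list("AT" * 7))
        seqs[mk.chrom][start : start + 14] = tract

    # scrub chance tandem tracts from the flanks of non-flagged markers so
    # the truth record fully determines every SSR-filter decision
    from .design import detect_ssr

    for j, mk in enumerate(matrix.markers):
        if j in ssr_set:
            continue
        seq = seqs[mk.chrom]
        for lo, hi in ((max(mk.pos - 1 - 50, 0), mk.pos - 1),
                       (mk.pos, min(mk.pos + 50, len(seq)))):
            for _ in range(20):
                tracts = detect_ssr("".join(seq[lo:hi]))
                if not tracts:
                    break
                for _, _, s, length in tracts:
                    seq[lo + s : lo + s + length] = _random_seq(rng, length)

    # duplicated probes: copy the 101bp window into the reserved tail
    for j in sorted(dup_set):
        mk = matrix.markers[j]
        lo = mk.pos - 1 - 50
        hi = mk.pos + 50
        if lo < 0:
            continue
        probe = seqs[mk.chrom][lo:hi].copy()
        t = dup_tail[mk.chrom]
        seqs[mk.chrom][t : t + probe.size] = probe
        dup_tail[mk.chrom] = t + probe.size + 40

    # decoy variants near chosen candidates (extra raw sites in the VCF)
    decoy_markers: list[MarkerRecord] = []
    decoy_cols: list[np.ndarray] = []
    for k, j in enumerate(sorted(near_set)):
        mk = matrix.markers[j]
        offset = int(rng.integers(10, 41)) * (1 if rng.random() < 0.5 else -1)
        pos = max(2, mk.pos + offset)
        ref = str(seqs[mk.chrom][pos - 1])
        alt = "ACGT".replace(ref, "")[int(rng.integers(0, 3))]
        col = np.zeros(matrix.n_samples, dtype=np.int16)
        col[int(rng.integers(0, matrix.n_samples))] = 1  # one het: maf < floor
        decoy_markers.append(
            MarkerRecord(
                id=f"decoy{k + 1:04d}", chrom=mk.chrom, pos=pos, ref=ref, alt=alt
            )
        )
        decoy_cols.append(col)

    # gene models
    region_of: dict[int, str] = {}
    gff_lines = ["##gff-version 3"]
    gene_n = 0
    for j, mk in enumerate(matrix.markers):
        u = rng.random()
        strand = "+" if rng.random() < 0.5 else "-"
        if u < config.exon_fraction:
            gene_n += 1
            s, e = mk.pos - 30, mk.pos + 30
            gff_lines += [
                f"{mk.chrom}\tsim\tgene\t{s}\t{e}\t.\t{strand}\t.\tID=gene{gene_n}",
                f"{mk.chrom}\tsim\tmRNA\t{s}\t{e}\t.\t{strand}\t.\t"
                f"ID=mrna{gene_n};Parent=gene{gene_n}",
                f"{mk.chrom}\tsim\texon\t{s}\t{e}\t.\t{strand}\t.\t"
                f"ID=exon{gene_n};Parent=mrna{gene_n}",
            ]
            region_of[j] = "exon"
        elif u < config.exon_fraction + config.intron_fraction:
            gene_n += 1
            s, e = mk.pos - 60, mk.pos + 60
            gff_lines += [
                f"{mk.chrom}\tsim\tgene\t{s}\t{e}\t.\t{strand}\t.\tID=gene{gene_n}",
                f"{mk.chrom}\tsim\tmRNA\t{s}\t{e}\t.\t{strand}\t.\t"
                f"ID=mrna{gene_n};Parent=gene{gene_n}",
                f"{mk.chrom}\tsim\texon\t{s}\t{mk.pos - 20}\t.\t{strand}\t.\t"
                f"ID=exon{gene_n}a;Parent=mrna{gene_n}",
                f"{mk.chrom}\tsim\texon\t{mk.pos + 20}\t{e}\t.\t{strand}\t.\t"
                f"ID=exon{gene_n}b;Parent=mrna{gene_n}",
            ]
            region_of[j] = "intron"
        else:
            region_of[j] = "nongenic"

    # assemble extended matrix (candidates + decoys) and truth
    all_markers = list(matrix.markers) + decoy_markers
    if decoy_cols:
        dosage = np.hstack([matrix.dosage] + [c[:, None] for c in decoy_cols])
    else:
        dosage = matrix.dosage
    # VCF convention: records sorted by position within chromosome
    order2 = sorted(
        range(len(all_markers)), key=lambda j: (all_markers[j].chrom, all_markers[j].pos)
    )
    new_matrix = GenotypeMatrix(
        matrix.samples,
        [all_markers[j] for j in order2],
        dosage[:, order2],
        matrix.groups,
    )

    truth = dataset.truth
    for j, mk in enumerate(matrix.markers):
        rec = truth["markers"][mk.id]
        rec["region"] = region_of[j]
        rec["ssr_inject"] = j in ssr_set
        rec["dup_inject"] = j in dup_set
        rec["near_variant"] = j in near_set
    for k, dm in enumerate(decoy_markers):
        truth["markers"][dm.id] = {
            "chrom": dm.chrom,
            "pos": dm.pos,
            "p_ancestral": None,
            "p_by_group": None,
            "missing_rate": 0.0,
            "region": "nongenic",
            "ssr_inject": False,
            "dup_inject": False,
            "near_variant": False,
            "decoy": True,
        }

    return SyntheticDataset(
        matrix=new_matrix,
        truth=truth,
        fasta={c: "".join(s) for c, s in sorted(seqs.items())},
        gff="\n".join(gff_lines) + "\n",
        config=config,
    )


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Genotypes + reference + annotation in one call."""
    return build_reference_and_annotation(simulate_genotypes(config))


# --------------------------------------------------------------------------
# Writing
# --------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write VCF + FASTA + GFF3 + groups TSV + truth JSON.

    Output is byte-identical for a fixed seed and config; re-reading the
    VCF through :func:`snppanel.io.read_vcf` reproduces the dosage matrix
    exactly.
    """
    from .io import write_vcf, write_groups

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "fasta": out / "reference.fa",
        "gff": out / "annotation.gff3",
        "groups": out / "groups.tsv",
        "truth": out / "truth.json",
    }
    write_vcf(dataset.matrix, paths["vcf"])
    write_groups(dataset.matrix.groups, paths["groups"])
    if dataset.fasta is not None:
        with open(paths["fasta"], "w") as fh:
            for chrom, seq in dataset.fasta.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
    if dataset.gff is not None:
        paths["gff"].write_text(dataset.gff)
    with open(paths["truth"], "w") as fh:
        json.dump(dataset.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
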