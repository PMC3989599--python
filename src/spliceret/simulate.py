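"""Seeded synthetic worlds: genome, gene models, expression, alignments.

A world is generated from a :class:`SimConfig` and a seed.  Gene structure
and expression come from a *structure* RNG stream (``structure_seed``,
defaulting to ``seed``); fragment draws come from the *read* stream
(``seed``), so re-seeding reads leaves gene models untouched.

Per boundary, each simulated fragment comes from the intron-retaining
precursor with probability ``p`` (the boundary's truth retention), else
from the spliced isoform, of which a fraction ``mis_splice_rate`` is
re-routed to a wrong acceptor (mis-spliced).  Fragment starts are uniform
over a window around the junction *in the coordinates of the generating
isoform*, which makes the informative-read probability identical across
isoforms (so downstream retention estimates are unbiased) while leaving
informativeness itself emergent.

Draw order (one documented pass): structure stream — gene plans, layout,
genome bases, splice-site dinucleotides, expression values, per-boundary
truth retention and mis-splice acceptor shifts; read stream — per
boundary, per fragment: isoform, fragment length, start.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .annotation import GeneModel, GeneModelSet, revcomp
from .expression import (
    EARLY_ZYGOTIC,
    EXCLUDED_HIGH,
    MATERNAL,
    UNCLASSIFIED,
    ExpressionRecord,
)

BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    n_maternal: int = 14
    n_early_zygotic: int = 14
    n_excluded_high: int = 4
    n_unclassified: int = 4
    intronless_fraction: float = 0.15
    introns_per_gene: tuple[int, int] = (1, 3)
    exon_len_range: tuple[int, int] = (150, 400)
    intron_len_bins: tuple[tuple[int, int], ...] = ((60, 99), (100, 500), (501, 1200))
    intron_bin_weights: tuple[float, ...] = (1.0, 1.0, 1.0)
    retention_levels: tuple[float, ...] = (0.0, 0.1, 0.3, 0.5, 0.9)
    class_retention: dict | None = None  # optional per-class retention levels
    mis_splice_rate: float = 0.05
    noncanonical_fraction: float = 0.0
    read_len: int = 100
    frag_len_mean: float = 250.0
    frag_len_sd: float = 30.0
    fragments_per_boundary: int = 120
    window_pad: int = 60
    min_overlap: int = 10
    nested_pairs: int = 1
    alt_transcripts: bool = True
    force_intronless_last: bool = False
    intergenic_gap: int = 500
    chrom_name: str = "chrS"
    seed: int = 1
    structure_seed: int | None = None

    def validate(self) -> None:
        if self.read_len < 2 * self.min_overlap:
            raise ConfigError(
                f"read_len {self.read_len} shorter than 2*min_overlap "
                f"({2 * self.min_overlap}); fragments could never be informative"
            )
        if self.frag_len_mean < self.read_len:
            raise ConfigError("frag_len_mean must be >= read_len")
        for p in self.retention_levels:
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"retention level {p} outside [0,1]")
        if not 0.0 <= self.mis_splice_rate <= 1.0:
            raise ConfigError("mis_splice_rate outside [0,1]")
        if min(self.exon_len_range) <= 0 or any(
            lo <= 0 for lo, _ in self.intron_len_bins
        ):
            raise ConfigError("lengths must be positive")


def recovery_config(
    retention_levels: Sequence[float] = (0.0, 0.1, 0.3, 0.5, 0.9),
    boundaries_per_level: int = 50,
    fragments_per_boundary: int = 500,
    seed: int = 1,
) -> SimConfig:
    """Config tuned for unbiased truth-retention recovery.

    Single-intron genes (no cross-boundary read contamination) with exons
    long enough that the fragment-start window never truncates, so the
    informative probability is exactly equal across isoforms.
    """
    n = boundaries_per_level * len(retention_levels)
    return SimConfig(
        n_maternal=n // 2,
        n_early_zygotic=n - n // 2,
        n_excluded_high=0,
        n_unclassified=0,
        intronless_fraction=0.0,
        introns_per_gene=(1, 1),
        exon_len_range=(620, 720),
        intron_len_bins=((60, 99), (100, 500), (501, 900)),
        retention_levels=tuple(retention_levels),
        mis_splice_rate=0.0,
        frag_len_mean=180.0,
        frag_len_sd=15.0,
        fragments_per_boundary=fragments_per_boundary,
        nested_pairs=0,
        alt_transcripts=False,
        seed=seed,
    )


@dataclass
class BoundaryTruth:
    chrom: str
    intron_start: int
    intron_end: int
    strand: str
    gene_id: str
    p: float
    mis_rate: float
    mis_shift: int
    canonical: bool = True
    unsafe: bool = False  # True when overlapped by another exon by design
    n_retained: int = 0
    n_spliced: int = 0
    n_mis: int = 0

    @property
    def key(self) -> tuple:
        return (self.chrom, self.intron_start, self.intron_end, self.strand)


@dataclass
class TruthTable:
    gene_class: dict[str, str] = field(default_factory=dict)
    boundaries: list[BoundaryTruth] = field(default_factory=list)
    fragment_isoform: dict[str, str] = field(default_factory=dict)


@dataclass
class SamRecord:
    qname: str
    flag: int
    chrom: str
    pos: int  # 0-based leftmost
    cigar: str
    pnext: int
    tlen: int
    seq: str

    def to_line(self) -> str:
        qual = "I" * len(self.seq)
        return (
            f"{self.qname}\t{self.flag}\t{self.chrom}\t{self.pos + 1}\t60\t"
            f"{self.cigar}\t=\t{self.pnext + 1}\t{self.tlen}\t{self.seq}\t{qual}"
        )


@dataclass
class World:
    config: SimConfig
    genome: dict[str, str]
    models: GeneModelSet
    expression: list[ExpressionRecord]
    sam_records: list[SamRecord]
    truth: TruthTable

    def write(self, outdir: str) -> dict[str, str]:
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "genome": os.path.join(outdir, "genome.fa"),
            "annotation": os.path.join(outdir, "annotation.gtf"),
            "expression": os.path.join(outdir, "expression.tsv"),
            "alignments": os.path.join(outdir, "alignments.sam"),
            "truth_genes": os.path.join(outdir, "truth_genes.tsv"),
            "truth_boundaries": os.path.join(outdir, "truth_boundaries.tsv"),
            "truth_fragments": os.path.join(outdir, "truth_fragments.tsv"),
            "config": os.path.join(outdir, "sim_config.json"),
        }
        write_fasta(self.genome, paths["genome"])
        write_gtf(self.models, paths["annotation"])
        with open(paths["expression"], "w") as fh:
            fh.write("gene_id\texpr_0_2\texpr_2_4\n")
            for rec in self.expression:
                fh.write(f"{rec.gene_id}\t{rec.expr_0_2:.3f}\t{rec.expr_2_4:.3f}\n")
        write_sam(self.genome, self.sam_records, paths["alignments"])
        with open(paths["truth_genes"], "w") as fh:
            fh.write("gene_id\tclass\n")
            for gene_id in sorted(self.truth.gene_class):
                fh.write(f"{gene_id}\t{self.truth.gene_class[gene_id]}\n")
        with open(paths["truth_boundaries"], "w") as fh:
            fh.write(
                "chrom\tintron_start\tintron_end\tstrand\tgene_id\tp\tmis_rate\t"
                "mis_shift\tcanonical\tunsafe\tn_retained\tn_spliced\tn_mis\n"
            )
            for bt in self.truth.boundaries:
                fh.write(
                    f"{bt.chrom}\t{bt.intron_start}\t{bt.intron_end}\t{bt.strand}\t"
                    f"{bt.gene_id}\t{bt.p:.4f}\t{bt.mis_rate:.4f}\t{bt.mis_shift}\t"
                    f"{int(bt.canonical)}\t{int(bt.unsafe)}\t"
                    f"{bt.n_retained}\t{bt.n_spliced}\t{bt.n_mis}\n"
                )
        with open(paths["truth_fragments"], "w") as fh:
            fh.write("read_id\tisoform\n")
            for read_id in sorted(self.truth.fragment_isoform):
                fh.write(f"{read_id}\t{self.truth.fragment_isoform[read_id]}\n")
        with open(paths["config"], "w") as fh:
            json.dump(dataclasses.asdict(self.config), fh, indent=2, default=list)
            fh.write("\n")
        return paths


# ---------------------------------------------------------------------------
# plumbing: standard-format writers

def write_fasta(genome: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def load_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_gtf(models: GeneModelSet, path: str) -> None:
    with open(path, "w") as fh:
        for gene in models.genes:
            for tid in sorted(gene.transcripts):
                for start, end in gene.transcripts[tid]:
                    attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tid}";'
                    fh.write(
                        f"{gene.chrom}\tsim\texon\t{start + 1}\t{end}\t.\t"
                        f"{gene.strand}\t.\t{attrs}\n"
                    )


def write_sam(genome: dict[str, str], records: Sequence[SamRecord], path: str) -> None:
    recs = sorted(records, key=lambda r: (r.chrom, r.pos, r.qname, r.flag))
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name in sorted(genome):
            fh.write(f"@SQ\tSN:{name}\tLN:{len(genome[name])}\n")
        for rec in recs:
            fh.write(rec.to_line() + "\n")


# ---------------------------------------------------------------------------
# isoform geometry

def _transcript_order(blocks: list[tuple[int, int]], strand: str) -> list[tuple[int, int]]:
    return blocks if strand == "+" else list(reversed(blocks))


def _isoform_blocks(
    exons: list[tuple[int, int]], strand: str, kind: str, k: int, shift: int = 0
) -> list[tuple[int, int]]:
    """Genomic blocks (ascending) of one isoform around intron ``k``.

    ``spliced``: the exons as annotated.  ``retained``: exons with intron k
    kept (flanking exons merged across it).  ``mis``: intron k's removed
    gap extended ``shift`` nt into the transcript-sense downstream exon.
    """
    if kind == "spliced":
        return list(exons)
    if kind == "retained":
        out = list(exons)
        merged = (out[k][0], out[k + 1][1])
        return out[:k] + [merged] + out[k + 2 :]
    if kind == "mis":
        out = list(exons)
        if strand == "+":
            s, e = out[k + 1]
            out[k + 1] = (s + shift, e)
        else:
            s, e = out[k]
            out[k] = (s, e - shift)
        return out
    raise ValueError(kind)


def _junction_offset(
    blocks: list[tuple[int, int]], strand: str, intron_start: int, intron_end: int
) -> int:
    """Transcript coordinate of the donor junction within an isoform."""
    j = 0
    for s, e in blocks:
        if strand == "+":
            j += max(0, min(e, intron_start) - s)
        else:
            j += max(0, e - max(s, intron_end))
    return j


def _map_interval(
    blocks: list[tuple[int, int]], strand: str, t0: int, t1: int
) -> list[tuple[int, int]]:
    """Map transcript-coordinate interval [t0, t1) to genomic blocks."""
    out: list[tuple[int, int]] = []
    acc = 0
    for s, e in _transcript_order(blocks, strand):
        length = e - s
        a = max(t0, acc)
        b = min(t1, acc + length)
        if a < b:
            if strand == "+":
                out.append((s + (a - acc), s + (b - acc)))
            else:
                out.append((e - (b - acc), e - (a - acc)))
        acc += length
    out.sort()
    merged: list[tuple[int, int]] = []
    for s, e in out:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _cigar(blocks: list[tuple[int, int]]) -> str:
    parts = []
    for i, (s, e) in enumerate(blocks):
        if i:
            parts.append(f"{s - blocks[i - 1][1]}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


# ---------------------------------------------------------------------------
# world generation

@dataclass
class _GenePlan:
    gene_id: str
    label: str
    strand: str
    exon_lens: list[int]
    intron_lens: list[int]
    exons: list[tuple[int, int]] = field(default_factory=list)
    alt_exons: list[tuple[int, int]] | None = None

    @property
    def intronless(self) -> bool:
        return not self.intron_lens


def _plan_genes(cfg: SimConfig, rng: np.random.Generator) -> list[_GenePlan]:
    class_counts = [
        (EARLY_ZYGOTIC, cfg.n_early_zygotic),
        (MATERNAL, cfg.n_maternal),
        (EXCLUDED_HIGH, cfg.n_excluded_high),
        (UNCLASSIFIED, cfg.n_unclassified),
    ]
    weights = np.asarray(cfg.intron_bin_weights, dtype=float)
    weights = weights / weights.sum()
    plans: list[_GenePlan] = []
    idx = 0
    for label, count in class_counts:
        for _ in range(count):
            gene_id = f"g{idx:04d}_{label[:3]}"
            idx += 1
            strand = "+" if rng.random() < 0.5 else "-"
            intronless = rng.random() < cfg.intronless_fraction
            if intronless:
                n_introns = 0
            else:
                lo, hi = cfg.introns_per_gene
                n_introns = int(rng.integers(lo, hi + 1))
            exon_lens = [
                int(rng.integers(cfg.exon_len_range[0], cfg.exon_len_range[1] + 1))
                for _ in range(n_introns + 1)
            ]
            intron_lens = []
            for _ in range(n_introns):
                b = int(rng.choice(len(cfg.intron_len_bins), p=weights))
                lo_i, hi_i = cfg.intron_len_bins[b]
                intron_lens.append(int(rng.integers(lo_i, hi_i + 1)))
            plans.append(_GenePlan(gene_id, label, strand, exon_lens, intron_lens))
    want_one = cfg.force_intronless_last or cfg.intronless_fraction > 0.0
    if plans and want_one and all(not p.intronless for p in plans):
        last = plans[-1]
        last.exon_lens = [sum(last.exon_lens) + sum(last.intron_lens)]
        last.intron_lens = []
    return plans


def _draw_expression(label: str, rng: np.random.Generator) -> tuple[float, float]:
    """Class-conditional expression units, drawn away from every threshold."""
    if label == EARLY_ZYGOTIC:
        e02 = float(rng.uniform(0.0, 2.0))
        e24 = float(rng.uniform(30.0, 500.0))
    elif label == MATERNAL:
        e02 = float(rng.uniform(80.0, 900.0))
        e24 = float(rng.uniform(0.0, min(2.0 * e02, 950.0)))
    elif label == EXCLUDED_HIGH:
        e02 = float(rng.uniform(1100.0, 5000.0))
        e24 = float(rng.uniform(0.0, 500.0))
    else:
        e02 = float(rng.uniform(0.0, 40.0))
        e24 = float(rng.uniform(0.0, 8.0))
    return e02, e24


def generate_world(cfg: SimConfig) -> World:
    cfg.validate()
    rng_struct = np.random.default_rng(
        cfg.seed if cfg.structure_seed is None else cfg.structure_seed
    )
    rng_reads = np.random.default_rng(cfg.seed)

    plans = _plan_genes(cfg, rng_struct)
    if not plans:
        raise ConfigError("config yields zero genes")

    # layout on one chromosome
    cursor = 100
    for plan in plans:
        exons = []
        pos = cursor
        for i, elen in enumerate(plan.exon_lens):
            exons.append((pos, pos + elen))
            pos += elen
            if i < len(plan.intron_lens):
                pos += plan.intron_lens[i]
        plan.exons = exons
        cursor = pos + cfg.intergenic_gap

    truth = TruthTable()
    genes: list[GeneModel] = []
    for plan in plans:
        truth.gene_class[plan.gene_id] = plan.label
        genes.append(
            GeneModel(
                plan.gene_id,
                cfg.chrom_name,
                plan.strand,
                {"t1": list(plan.exons)},
            )
        )

    unsafe_keys: set[tuple] = set()

    # alternative transcripts: one identical duplicate (dedup case) and one
    # with an exon extended into its first intron (overlap case)
    if cfg.alt_transcripts:
        dup_done = ext_done = False
        for plan, gene in zip(plans, genes):
            if not dup_done and len(plan.intron_lens) >= 2:
                gene.transcripts["t2"] = list(plan.exons)
                dup_done = True
            elif not ext_done and plan.intron_lens and plan.intron_lens[0] > 40:
                delta = 20
                alt = list(plan.exons)
                s0, e0 = alt[0]
                alt[0] = (s0, e0 + delta)
                gene.transcripts["t2"] = alt
                plan.alt_exons = alt
                unsafe_keys.add((cfg.chrom_name, e0, alt[1][0], plan.strand))
                ext_done = True
            if dup_done and ext_done:
                break

    # nested intronless genes inside large introns
    placed = 0
    for plan in plans:
        if placed >= cfg.nested_pairs:
            break
        big = [
            (i, ilen)
            for i, ilen in enumerate(plan.intron_lens)
            if ilen >= 400 and not plan.alt_exons
        ]
        if not big:
            continue
        i, ilen = big[0]
        istart = plan.exons[i][1]
        iend = plan.exons[i + 1][0]
        nest_len = min(200, ilen - 120)
        nest_start = istart + 60
        gene_id = f"nested{placed:02d}"
        nest_strand = "-" if plan.strand == "+" else "+"
        genes.append(
            GeneModel(
                gene_id,
                cfg.chrom_name,
                nest_strand,
                {"t1": [(nest_start, nest_start + nest_len)]},
            )
        )
        truth.gene_class[gene_id] = MATERNAL
        unsafe_keys.add((cfg.chrom_name, istart, iend, plan.strand))
        placed += 1

    models = GeneModelSet(genes)
    models.validate()

    # genome bases, then splice-site dinucleotides
    seq = rng_struct.choice(BASES, size=cursor)
    all_introns: list[tuple[int, int, str, str, bool]] = []  # start, end, strand, gene, primary
    for plan in plans:
        for i in range(len(plan.intron_lens)):
            istart = plan.exons[i][1]
            iend = plan.exons[i + 1][0]
            all_introns.append((istart, iend, plan.strand, plan.gene_id, True))
        if plan.alt_exons:
            all_introns.append(
                (plan.alt_exons[0][1], plan.alt_exons[1][0], plan.strand, plan.gene_id, False)
            )
    canonical_flags: dict[tuple, bool] = {}
    for istart, iend, strand, gene_id, primary in all_introns:
        canonical = not (primary and rng_struct.random() < cfg.noncanonical_fraction)
        donor_dinuc = "GT" if canonical else "CA"
        if strand == "+":
            seq[istart : istart + 2] = list(donor_dinuc)
            seq[iend - 2 : iend] = list("AG")
        else:
            seq[iend - 2 : iend] = list(revcomp(donor_dinuc))
            seq[istart : istart + 2] = list("CT")  # revcomp of AG
        canonical_flags[(istart, iend, strand)] = canonical
    genome = {cfg.chrom_name: "".join(seq)}

    # expression table
    expression = [
        ExpressionRecord(gene_id, *_draw_expression(truth.gene_class[gene_id], rng_struct))
        for gene_id in sorted(truth.gene_class)
    ]

    # per-boundary truth retention (round-robin over levels for even counts)
    level_idx = 0
    boundary_truths: list[BoundaryTruth] = []
    for plan in plans:
        for i in range(len(plan.intron_lens)):
            istart = plan.exons[i][1]
            iend = plan.exons[i + 1][0]
            if cfg.class_retention and plan.label in cfg.class_retention:
                levels = tuple(cfg.class_retention[plan.label])
            else:
                levels = cfg.retention_levels
            p = float(levels[level_idx % len(levels)])
            level_idx += 1
            down_len = (
                plan.exon_lens[i + 1] if plan.strand == "+" else plan.exon_lens[i]
            )
            shift = int(rng_struct.integers(4, min(16, max(5, down_len - 2 * cfg.min_overlap))))
            bt = BoundaryTruth(
                chrom=cfg.chrom_name,
                intron_start=istart,
                intron_end=iend,
                strand=plan.strand,
                gene_id=plan.gene_id,
                p=p,
                mis_rate=cfg.mis_splice_rate,
                mis_shift=shift,
                canonical=canonical_flags[(istart, iend, plan.strand)],
                unsafe=(cfg.chrom_name, istart, iend, plan.strand) in unsafe_keys,
            )
            boundary_truths.append(bt)
    truth.boundaries = boundary_truths

    # fragments
    sam_records: list[SamRecord] = []
    chrom_seq = genome[cfg.chrom_name]
    by_gene = {plan.gene_id: plan for plan in plans}
    for bt in boundary_truths:
        plan = by_gene[bt.gene_id]
        k = next(
            i
            for i in range(len(plan.intron_lens))
            if plan.exons[i][1] == bt.intron_start
        )
        templates = {}
        for kind in ("spliced", "retained", "mis"):
            blocks = _isoform_blocks(plan.exons, plan.strand, kind, k, bt.mis_shift)
            j = _junction_offset(blocks, plan.strand, bt.intron_start, bt.intron_end)
            tlen = sum(e - s for s, e in blocks)
            templates[kind] = (blocks, j, tlen)
        for fi in range(cfg.fragments_per_boundary):
            u = rng_reads.random()
            if u < bt.p:
                kind = "retained"
                bt.n_retained += 1
            elif u < bt.p + (1.0 - bt.p) * bt.mis_rate:
                kind = "mis"
                bt.n_mis += 1
            else:
                kind = "spliced"
                bt.n_spliced += 1
            blocks, j, tlen = templates[kind]
            flen = int(round(rng_reads.normal(cfg.frag_len_mean, cfg.frag_len_sd)))
            flen = max(cfg.read_len, min(flen, tlen))
            wmax = cfg.window_pad + flen
            lo = max(0, j - wmax)
            hi = min(tlen - flen, j + wmax)
            if hi < lo:
                continue
            t0 = int(rng_reads.integers(lo, hi + 1))
            read_id = f"frag_{bt.gene_id}_i{k}_{fi:05d}"
            truth.fragment_isoform[read_id] = kind
            m1 = _map_interval(blocks, plan.strand, t0, t0 + cfg.read_len)
            m2 = _map_interval(blocks, plan.strand, t0 + flen - cfg.read_len, t0 + flen)
            if plan.strand == "+":
                f1, f2 = 99, 147  # paired, proper; mate1 fwd, mate2 rev
            else:
                f1, f2 = 83, 163
            p1, p2 = m1[0][0], m2[0][0]
            left = min(p1, p2)
            right = max(m1[-1][1], m2[-1][1])
            span = right - left
            for mate_blocks, flag, pos, pnext in (
                (m1, f1, p1, p2),
                (m2, f2, p2, p1),
            ):
                tl = span if pos == left else -span
                mate_seq = "".join(chrom_seq[s:e] for s, e in mate_blocks)
                sam_records.append(
                    SamRecord(
                        qname=read_id,
                        flag=flag,
                        chrom=cfg.chrom_name,
                        pos=pos,
                        cigar=_cigar(mate_blocks),
                        pnext=pnext,
                        tlen=tl,
                        seq=mate_seq,
                    )
                )

    return World(
        config=cfg,
        genome=genome,
        models=models,
        expression=expression,
        sam_records=sam_records,
        truth=truth,
    )


def intronless_gene_set(
    n_genes: int = 100, min_len: int = 1000, max_len: int = 3000, seed: int = 0
) -> GeneModelSet:
    """Single-exon genes spanning their whole body (structure-profile limit case)."""
    rng = np.random.default_rng(seed)
    genes = [
        GeneModel(
            f"il{i:04d}",
            "chrI",
            "+",
            {"t1": [(0, int(rng.integers(min_len, max_len + 1)))]},
        )
        for i in range(n_genes)
    ]
    return GeneModelSet(genes)


def bernoulli_segment_gene_set(
    n_genes: int = 2000, n_segments: int = 1000, prob: float = 0.5, seed: int = 0
) -> GeneModelSet:
    """Null-model genes: one base per segment, exonic with probability ``prob``.

    Gene length equals ``n_segments`` so each profile segment is exactly one
    base and segment presence equals the Bernoulli draw.  The first and last
    bases are forced exonic to pin the gene span (only the two terminal
    segments are perturbed).
    """
    rng = np.random.default_rng(seed)
    genes = []
    for i in range(n_genes):
        draws = rng.random(n_segments) < prob
        draws[0] = draws[-1] = True
        idx = np.flatnonzero(draws)
        runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        exons = [(int(r[0]), int(r[-1]) + 1) for r in runs]
        genes.append(GeneModel(f"bn{i:04d}", "chrB", "+", {"t1": exons}))
    return GeneModelSet(genes)


def worked_fixture_config(read_seed: int = 7) -> SimConfig:
    """Miniature deterministic world: 3 genes, 4 boundaries, ~200 reads."""
    return SimConfig(
        n_maternal=2,
        n_early_zygotic=1,
        n_excluded_high=0,
        n_unclassified=0,
        intronless_fraction=0.0,
        introns_per_gene=(2, 2),
        exon_len_range=(150, 300),
        intron_len_bins=((60, 99), (100, 400), (401, 600)),
        retention_levels=(0.0, 0.5),
        mis_splice_rate=0.0,
        frag_len_mean=200.0,
        frag_len_sd=20.0,
        fragments_per_boundary=25,
        nested_pairs=0,
        alt_transcripts=False,
        force_intronless_last=True,
        seed=read_seed,
        structure_seed=20240214,
    )


def emit_worked_fixture(outdir: str, read_seed: int = 7) -> dict[str, str]:
    """Generate and write the hand-checkable miniature world.

    3 genes (one intronless), 4 boundaries, 100 fragments (200 reads).
    The structure seed is pinned, so changing ``read_seed`` changes the
    reads but not the gene models, genome or expression table.
    """
    world = generate_world(worked_fixture_config(read_seed))
    return world.write(outdir)
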