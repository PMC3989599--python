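"""Gene models, exon-intron boundaries, structure profiles and splice motifs.

Coordinates are 0-based half-open internally.  GTF input is 1-based
inclusive and converted on parse.  A :class:`SpliceBoundary` is one unique
intron; its ``donor_pos`` is the first intronic base in transcript sense and
``acceptor_pos`` the first exonic base after the intron, so that
``abs(acceptor_pos - donor_pos) == intron_len`` on either strand.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence, TextIO

import numpy as np

log = logging.getLogger(__name__)

STRANDS = ("+", "-")


class GtfParseError(ValueError):
    """A malformed GTF line; carries the 1-based line number."""


@dataclass
class GeneModel:
    """One gene: ordered exon intervals per transcript, on one chromosome."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def validate(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"{self.gene_id}: invalid strand {self.strand!r}")
        for tid, exons in self.transcripts.items():
            prev_end = None
            for start, end in exons:
                if end <= start:
                    raise ValueError(
                        f"{self.gene_id}/{tid}: exon ({start},{end}) has end <= start"
                    )
                if prev_end is not None and start < prev_end:
                    raise ValueError(
                        f"{self.gene_id}/{tid}: exons overlap or are unsorted"
                    )
                prev_end = end

    def span(self) -> tuple[int, int]:
        """Genomic extent covered by any exon of any transcript."""
        starts = [e[0] for ex in self.transcripts.values() for e in ex]
        ends = [e[1] for ex in self.transcripts.values() for e in ex]
        return min(starts), max(ends)


@dataclass
class GeneModelSet:
    genes: list[GeneModel] = field(default_factory=list)

    def validate(self) -> None:
        for g in self.genes:
            g.validate()

    def by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    def all_exons(self) -> Iterator[tuple[str, int, int]]:
        """Yield (chrom, start, end) for every exon of every transcript."""
        for g in self.genes:
            for exons in g.transcripts.values():
                for start, end in exons:
                    yield g.chrom, start, end

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class SpliceBoundary:
    """One unique intron keyed by (chrom, intron_start, intron_end, strand)."""

    chrom: str
    strand: str
    intron_start: int  # genomic, 0-based half-open
    intron_end: int
    gene_id: str
    upstream_exon_len: int
    downstream_exon_len: int
    safe: bool = False

    def __post_init__(self) -> None:
        if self.intron_end <= self.intron_start:
            raise ValueError("intron_end must exceed intron_start")
        if self.upstream_exon_len <= 0 or self.downstream_exon_len <= 0:
            raise ValueError("flanking exon lengths must be positive")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def intron_len(self) -> int:
        return self.intron_end - self.intron_start

    @property
    def donor_pos(self) -> int:
        """First intronic base in transcript sense (genomic coordinate)."""
        return self.intron_start if self.strand == "+" else self.intron_end - 1

    @property
    def acceptor_pos(self) -> int:
        """First exonic base after the intron in transcript sense."""
        return self.intron_end if self.strand == "+" else self.intron_start - 1

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.chrom, self.intron_start, self.intron_end, self.strand)

    def key_str(self) -> str:
        return f"{self.chrom}:{self.intron_start}-{self.intron_end}:{self.strand}"


@dataclass
class StructureProfile:
    """Per-segment exon-presence frequency (percent) over a gene set."""

    n_segments: int
    freq: np.ndarray  # length n_segments, values in [0, 100]
    n_genes: int
    n_skipped: int = 0


@dataclass
class MotifMatrix:
    """Position base-count matrix around a splice junction.

    Rows are A, C, G, T; ``info_content`` is 2 - Shannon entropy (bits),
    without small-sample correction.
    """

    window: tuple[int, int]  # (left flank nt, right flank nt)
    counts: np.ndarray  # shape (4, left+right), nonnegative ints
    n_sequences: int
    n_dropped: int = 0

    ALPHABET = "ACGT"

    @property
    def freq(self) -> np.ndarray:
        total = self.counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, self.counts / total, 0.0)

    @property
    def info_content(self) -> np.ndarray:
        f = self.freq
        with np.errstate(invalid="ignore", divide="ignore"):
            plogp = np.where(f > 0, f * np.log2(f), 0.0)
        entropy = -plogp.sum(axis=0)
        return np.clip(2.0 - entropy, 0.0, 2.0)


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(attr_field))


def parse_gene_models(source: str | TextIO | Iterable[str]) -> GeneModelSet:
    """Parse exon features from GTF text into a :class:`GeneModelSet`.

    ``source`` may be a path, an open text handle, or an iterable of lines.
    GTF coordinates (1-based inclusive) are converted to 0-based half-open;
    duplicate exon lines within a transcript are collapsed.
    """
    close = False
    if isinstance(source, str):
        handle: Iterable[str] = open(source)
        close = True
    else:
        handle = source
    genes: dict[str, GeneModel] = {}
    exon_sets: dict[tuple[str, str], set[tuple[int, int]]] = {}
    try:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _src, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise GtfParseError(f"line {lineno}: end < start ({end1} < {start1})")
            if strand not in STRANDS:
                raise GtfParseError(f"line {lineno}: invalid strand {strand!r}")
            attr = _parse_attributes(attrs)
            gene_id = attr.get("gene_id")
            tx_id = attr.get("transcript_id")
            if not gene_id or not tx_id:
                raise GtfParseError(
                    f"line {lineno}: exon lacks gene_id or transcript_id attribute"
                )
            gene = genes.get(gene_id)
            if gene is None:
                gene = genes[gene_id] = GeneModel(gene_id, chrom, strand)
            elif gene.chrom != chrom or gene.strand != strand:
                raise GtfParseError(
                    f"line {lineno}: gene {gene_id} switches chromosome or strand"
                )
            exon_sets.setdefault((gene_id, tx_id), set()).add((start1 - 1, end1))
    finally:
        if close:
            handle.close()  # type: ignore[union-attr]

    for (gene_id, tx_id), exons in exon_sets.items():
        genes[gene_id].transcripts[tx_id] = sorted(exons)
    models = GeneModelSet(list(genes.values()))
    models.validate()
    return models


def extract_boundaries(models: GeneModelSet) -> list[SpliceBoundary]:
    """All unique introns across every transcript of every gene.

    Introns are gaps between consecutive exons of a transcript; intronless
    transcripts contribute nothing.  Boundaries sharing the same
    (chrom, intron_start, intron_end, strand) are merged, and flanking exon
    lengths are the minimum over the sharing transcripts.
    """
    acc: dict[tuple[str, int, int, str], dict] = {}
    for gene in models.genes:
        for exons in gene.transcripts.values():
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if s2 == e1:  # abutting exons: no intron
                    continue
                key = (gene.chrom, e1, s2, gene.strand)
                # transcript-sense upstream exon: left one on +, right one on -
                if gene.strand == "+":
                    up, down = e1 - s1, e2 - s2
                else:
                    up, down = e2 - s2, e1 - s1
                rec = acc.get(key)
                if rec is None:
                    acc[key] = {"gene_id": gene.gene_id, "up": up, "down": down}
                else:
                    rec["up"] = min(rec["up"], up)
                    rec["down"] = min(rec["down"], down)
    out = [
        SpliceBoundary(
            chrom=chrom,
            strand=strand,
            intron_start=istart,
            intron_end=iend,
            gene_id=rec["gene_id"],
            upstream_exon_len=rec["up"],
            downstream_exon_len=rec["down"],
        )
        for (chrom, istart, iend, strand), rec in acc.items()
    ]
    out.sort(key=lambda b: b.key)
    return out


def filter_safe(
    boundaries: Sequence[SpliceBoundary], models: GeneModelSet
) -> list[SpliceBoundary]:
    """Drop boundaries whose intron interval overlaps any annotated exon.

    Exons of any transcript of any gene count, on either strand.  Surviving
    boundaries are returned flagged ``safe=True``.
    """
    exon_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    tmp: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in models.all_exons():
        tmp.setdefault(chrom, []).append((start, end))
    for chrom, ivals in tmp.items():
        arr = np.asarray(ivals)
        exon_by_chrom[chrom] = (arr[:, 0], arr[:, 1])

    out: list[SpliceBoundary] = []
    for b in boundaries:
        starts_ends = exon_by_chrom.get(b.chrom)
        if starts_ends is None:
            out.append(dataclasses.replace(b, safe=True))
            continue
        starts, ends = starts_ends
        overlapping = bool(
            np.any((starts < b.intron_end) & (ends > b.intron_start))
        )
        if not overlapping:
            out.append(dataclasses.replace(b, safe=True))
    return out


def filter_min_flank(
    boundaries: Sequence[SpliceBoundary], min_len: int = 50
) -> list[SpliceBoundary]:
    """Keep boundaries whose intron and both flanking exons are >= min_len nt."""
    return [
        b
        for b in boundaries
        if b.intron_len >= min_len
        and b.upstream_exon_len >= min_len
        and b.downstream_exon_len >= min_len
    ]


def structure_profile(models: GeneModelSet, n_segments: int = 1000) -> StructureProfile:
    """Exon-presence frequency over ``n_segments`` equal gene segments.

    Each gene span is cut into ``n_segments`` equal segments; a segment
    counts as exonic if any exon of any transcript of the gene covers at
    least one base assigned to it (base i belongs to segment
    ``i * n_segments // L``).  Minus-strand genes are flipped so segment 0
    is the transcript 5' end.  Genes shorter than ``n_segments`` nt are
    skipped with a warning.  Frequencies are percentages of non-skipped
    genes.
    """
    if not models.genes:
        raise ValueError("empty gene model set")
    presence_sum = np.zeros(n_segments, dtype=np.int64)
    n_used = 0
    n_skipped = 0
    for gene in models.genes:
        span_start, span_end = gene.span()
        length = span_end - span_start
        if length < n_segments:
            log.warning(
                "structure_profile: skipping %s (span %d nt < %d segments)",
                gene.gene_id,
                length,
                n_segments,
            )
            n_skipped += 1
            continue
        base_cov = np.zeros(length, dtype=bool)
        for exons in gene.transcripts.values():
            for s, e in exons:
                base_cov[s - span_start : e - span_start] = True
        if gene.strand == "-":
            base_cov = base_cov[::-1]
        # first base index of each segment; strictly increasing since L >= n
        seg_starts = -(-(np.arange(n_segments, dtype=np.int64) * length) // n_segments)
        seg_any = np.maximum.reduceat(base_cov.astype(np.int8), seg_starts)
        presence_sum += seg_any
        n_used += 1
    if n_used == 0:
        raise ValueError("no gene long enough for the requested segment count")
    freq = 100.0 * presence_sum / n_used
    return StructureProfile(n_segments=n_segments, freq=freq, n_genes=n_used, n_skipped=n_skipped)


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class MissingChromosomeError(KeyError):
    pass


def _fetch(genome: Mapping[str, str], chrom: str, start: int, end: int) -> str | None:
    if chrom not in genome:
        raise MissingChromosomeError(f"chromosome {chrom!r} absent from genome")
    seq = genome[chrom]
    if start < 0 or end > len(seq):
        return None
    return seq[start:end].upper()


def boundary_motifs(
    genome: Mapping[str, str],
    boundaries: Sequence[SpliceBoundary],
    left_flank: int = 3,
    right_flank: int = 6,
) -> tuple[MotifMatrix, MotifMatrix]:
    """Donor- and acceptor-side base-count matrices in transcript sense.

    The donor window is ``left_flank`` exonic + ``right_flank`` intronic nt
    around the 5' splice site; the acceptor window mirrors it
    (``right_flank`` intronic + ``left_flank`` exonic).  Sequences with
    non-ACGT symbols (or running off the chromosome) are dropped and
    counted.
    """
    width = left_flank + right_flank
    donor_counts = np.zeros((4, width), dtype=np.int64)
    acceptor_counts = np.zeros((4, width), dtype=np.int64)
    idx = {c: i for i, c in enumerate(MotifMatrix.ALPHABET)}
    n_seq = 0
    n_dropped = 0
    for b in boundaries:
        if b.strand == "+":
            donor_seq = _fetch(genome, b.chrom, b.intron_start - left_flank, b.intron_start + right_flank)
            acceptor_seq = _fetch(genome, b.chrom, b.intron_end - right_flank, b.intron_end + left_flank)
        else:
            raw_d = _fetch(genome, b.chrom, b.intron_end - right_flank, b.intron_end + left_flank)
            raw_a = _fetch(genome, b.chrom, b.intron_start - left_flank, b.intron_start + right_flank)
            donor_seq = revcomp(raw_d) if raw_d is not None else None
            acceptor_seq = revcomp(raw_a) if raw_a is not None else None
        if (
            donor_seq is None
            or acceptor_seq is None
            or any(c not in idx for c in donor_seq)
            or any(c not in idx for c in acceptor_seq)
        ):
            n_dropped += 1
            continue
        for pos, c in enumerate(donor_seq):
            donor_counts[idx[c], pos] += 1
        for pos, c in enumerate(acceptor_seq):
            acceptor_counts[idx[c], pos] += 1
        n_seq += 1
    donor = MotifMatrix((left_flank, right_flank), donor_counts, n_seq, n_dropped)
    acceptor = MotifMatrix((right_flank, left_flank), acceptor_counts, n_seq, n_dropped)
    return donor, acceptor


# ---------------------------------------------------------------------------
# tabular output

def write_boundaries_tsv(boundaries: Sequence[SpliceBoundary], path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tintron_start\tintron_end\tstrand\tgene_id\tintron_len\t"
            "upstream_exon_len\tdownstream_exon_len\tsafe\n"
        )
        for b in boundaries:
            fh.write(
                f"{b.chrom}\t{b.intron_start}\t{b.intron_end}\t{b.strand}\t"
                f"{b.gene_id}\t{b.intron_len}\t{b.upstream_exon_len}\t"
                f"{b.downstream_exon_len}\t{int(b.safe)}\n"
            )


def read_boundaries_tsv(path: str) -> list[SpliceBoundary]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                SpliceBoundary(
                    chrom=f[col["chrom"]],
                    intron_start=int(f[col["intron_start"]]),
                    intron_end=int(f[col["intron_end"]]),
                    strand=f[col["strand"]],
                    gene_id=f[col["gene_id"]],
                    upstream_exon_len=int(f[col["upstream_exon_len"]]),
                    downstream_exon_len=int(f[col["downstream_exon_len"]]),
                    safe=bool(int(f[col["safe"]])),
                )
            )
    return out


def write_structure_tsv(profile: StructureProfile, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("segment\tfreq\n")
        for s, v in enumerate(profile.freq):
            fh.write(f"{s}\t{v:.6f}\n")


def write_motif_tsv(matrix: MotifMatrix, path: str) -> None:
    ic = matrix.info_content
    with open(path, "w") as fh:
        fh.write("position\tA\tC\tG\tT\tIC\n")
        left, _right = matrix.window
        for j in range(matrix.counts.shape[1]):
            pos = j - left  # 0 = first base after the junction
            a, c, g, t = matrix.counts[:, j]
            fh.write(f"{pos}\t{a}\t{c}\t{g}\t{t}\t{ic[j]:.6f}\n")
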