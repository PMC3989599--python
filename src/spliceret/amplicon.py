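"""In-silico RT-PCR product sizes on spliced vs intron-retained templates.

A template is an ordered list of exon/intron segments.  Primer
hybridization is positional (no sequence or thermodynamics): a primer
occupies an interval inside one segment, the forward primer on the sense
strand and the reverse primer on the antisense strand.  A primer pair
yields a product on an isoform only when both host segments are present
and the reverse primer's 5' end lies at or downstream of the forward
primer's 5' end; the product size is the inclusive distance between the
two primer 5' ends on the isoform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Collection, Sequence

EXON = "exon"
INTRON = "intron"

NO_PRODUCT = None


@dataclass(frozen=True)
class Segment:
    id: str
    kind: str  # exon | intron
    length: int

    def __post_init__(self) -> None:
        if self.kind not in (EXON, INTRON):
            raise ValueError(f"segment {self.id}: kind must be exon or intron")
        if self.length <= 0:
            raise ValueError(f"segment {self.id}: length must be positive")


@dataclass
class TranscriptTemplate:
    segments: list[Segment]

    def __post_init__(self) -> None:
        ids = [s.id for s in self.segments]
        if len(set(ids)) != len(ids):
            raise ValueError("segment ids must be unique")

    def segment(self, seg_id: str) -> Segment:
        for s in self.segments:
            if s.id == seg_id:
                return s
        raise KeyError(seg_id)

    def intron_ids(self) -> list[str]:
        return [s.id for s in self.segments if s.kind == INTRON]

    def isoform_segments(self, retained: Collection[str]) -> list[Segment]:
        """Segments of the isoform keeping exactly ``retained`` introns."""
        unknown = set(retained) - set(self.intron_ids())
        if unknown:
            raise ValueError(f"retained ids are not introns of this template: {sorted(unknown)}")
        return [
            s
            for s in self.segments
            if s.kind == EXON or s.id in retained
        ]


@dataclass(frozen=True)
class PrimerSite:
    segment_id: str
    offset: int  # 0-based offset of the primer's leftmost (sense) base
    length: int

    def __post_init__(self) -> None:
        if self.offset < 0 or self.length <= 0:
            raise ValueError("primer offset must be >= 0 and length > 0")


@dataclass(frozen=True)
class PrimerPair:
    pair_id: str
    forward: PrimerSite
    reverse: PrimerSite


def _validate_site(t: TranscriptTemplate, site: PrimerSite) -> Segment:
    seg = t.segment(site.segment_id)
    if site.offset + site.length > seg.length:
        raise ValueError(
            f"primer exceeds segment {seg.id} (offset {site.offset} + "
            f"len {site.length} > {seg.length})"
        )
    return seg


def classify_primer_pair(t: TranscriptTemplate, p: PrimerPair) -> str:
    """Label the pair by host-segment kinds: e-e, e-i, i-e or i-i."""
    fwd = _validate_site(t, p.forward)
    rev = _validate_site(t, p.reverse)
    code = {EXON: "e", INTRON: "i"}
    return f"{code[fwd.kind]}-{code[rev.kind]}"


def product_size(
    t: TranscriptTemplate, p: PrimerPair, retained: Collection[str] = ()
) -> int | None:
    """Amplicon size on the isoform retaining ``retained`` introns.

    Returns None (no product) when either primer's host segment is absent
    from the isoform or the reverse primer lies upstream of the forward
    one on it.
    """
    _validate_site(t, p.forward)
    _validate_site(t, p.reverse)
    iso = t.isoform_segments(retained)
    offsets: dict[str, int] = {}
    pos = 0
    for seg in iso:
        offsets[seg.id] = pos
        pos += seg.length
    if p.forward.segment_id not in offsets or p.reverse.segment_id not in offsets:
        return NO_PRODUCT
    fwd_5p = offsets[p.forward.segment_id] + p.forward.offset
    rev_5p = offsets[p.reverse.segment_id] + p.reverse.offset + p.reverse.length - 1
    if rev_5p < fwd_5p:
        return NO_PRODUCT
    return rev_5p - fwd_5p + 1


def introns_between(t: TranscriptTemplate, p: PrimerPair) -> list[str]:
    """Intron ids lying strictly between the two primer host segments."""
    ids = [s.id for s in t.segments]
    i = ids.index(p.forward.segment_id)
    j = ids.index(p.reverse.segment_id)
    if i > j:
        i, j = j, i
    return [s.id for s in t.segments[i + 1 : j] if s.kind == INTRON]


# ---------------------------------------------------------------------------
# config I/O for the CLI

def load_amplicon_config(path: str) -> tuple[TranscriptTemplate, list[PrimerPair], dict[str, list[str]]]:
    """Load template, primer pairs and named isoforms from a JSON config.

    Schema::

        {"segments": [{"id", "kind", "length"}, ...],
         "primer_pairs": [{"id", "forward": {"segment_id", "offset", "length"},
                           "reverse": {...}}, ...],
         "isoforms": {"name": [retained intron ids], ...}}

    An isoforms entry of ``"all"`` retains every intron.
    """
    with open(path) as fh:
        cfg = json.load(fh)
    template = TranscriptTemplate(
        [Segment(s["id"], s["kind"], int(s["length"])) for s in cfg["segments"]]
    )
    pairs = [
        PrimerPair(
            pair_id=pp["id"],
            forward=PrimerSite(**pp["forward"]),
            reverse=PrimerSite(**pp["reverse"]),
        )
        for pp in cfg["primer_pairs"]
    ]
    isoforms: dict[str, list[str]] = {}
    for name, retained in cfg.get("isoforms", {"spliced": [], "retained": "all"}).items():
        if retained == "all":
            retained = template.intron_ids()
        isoforms[name] = list(retained)
    return template, pairs, isoforms


def amplicon_table(
    t: TranscriptTemplate,
    pairs: Sequence[PrimerPair],
    isoforms: dict[str, list[str]],
):
    """Rows of (pair, isoform, pair class, product size) for a report TSV."""
    import pandas as pd

    rows = []
    for p in pairs:
        klass = classify_primer_pair(t, p)
        for name, retained in isoforms.items():
            size = product_size(t, p, retained)
            rows.append(
                {
                    "pair_id": p.pair_id,
                    "pair_class": klass,
                    "isoform": name,
                    "product_size": "no_product" if size is None else size,
                }
            )
    return pd.DataFrame(rows, columns=["pair_id", "pair_class", "isoform", "product_size"])
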