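"""Normalized per-base coverage profiles around 5' splice sites.

For each boundary, every base within ``halfwidth`` nt either side of the
donor junction gets the number of reads covering it, divided by the total
number of reads whose aligned footprint intersects the window at all
(reads only partially overlapping the window still count in the
denominator).  Profiles with fewer than ``min_reads`` window reads are
excluded.  Positions run -halfwidth..halfwidth-1 in transcript sense
(exon side negative); a split read covers only its aligned blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import SpliceBoundary
from .retention import AlignmentIndex, five_number_summary, sense_blocks

log = logging.getLogger(__name__)


@dataclass
class CoverageProfile:
    boundary_key: tuple
    gene_id: str
    values: np.ndarray  # length 2*halfwidth, each in [0, 1]
    n_window_reads: int
    halfwidth: int = 50


def coverage_profile(
    index: AlignmentIndex,
    b: SpliceBoundary,
    halfwidth: int = 50,
    min_reads: int = 50,
) -> CoverageProfile | None:
    """Per-base normalized coverage in the window around b's donor junction.

    Returns None (and logs) when fewer than ``min_reads`` reads intersect
    the window.
    """
    width = 2 * halfwidth
    # genomic interval containing every sense position in [-halfwidth, halfwidth)
    if b.strand == "+":
        g_start, g_end = b.intron_start - halfwidth, b.intron_start + halfwidth
    else:
        g_start, g_end = b.intron_end - halfwidth, b.intron_end + halfwidth
    counts = np.zeros(width, dtype=np.int64)
    n_window = 0
    for aln in index.overlapping(b.chrom, g_start, g_end):
        sblocks = sense_blocks(aln.blocks, b)
        in_window = False
        for s, e in sblocks:
            lo = max(s, -halfwidth)
            hi = min(e, halfwidth)
            if lo < hi:
                in_window = True
                counts[lo + halfwidth : hi + halfwidth] += 1
        if in_window:
            n_window += 1
    if n_window < min_reads:
        log.debug(
            "boundary %s: %d window reads < %d, profile excluded",
            b.key_str(),
            n_window,
            min_reads,
        )
        return None
    return CoverageProfile(
        boundary_key=b.key,
        gene_id=b.gene_id,
        values=counts / n_window,
        n_window_reads=n_window,
        halfwidth=halfwidth,
    )


def aggregate_profiles(
    profiles: Sequence[CoverageProfile],
    gene_classes: Mapping[str, str],
) -> pd.DataFrame:
    """Per-position five-number summaries across boundaries, by gene class.

    Classes with no profiles simply contribute no rows (a warning is
    emitted for classes requested via ``gene_classes`` values but empty).
    """
    by_class: dict[str, list[CoverageProfile]] = {}
    for p in profiles:
        cls = gene_classes.get(p.gene_id, "unclassified")
        by_class.setdefault(cls, []).append(p)
    for cls in set(gene_classes.values()) - set(by_class):
        log.warning("gene class %s has no defined coverage profiles", cls)
    rows = []
    for cls in sorted(by_class):
        plist = by_class[cls]
        halfwidth = plist[0].halfwidth
        mat = np.vstack([p.values for p in plist])
        for j in range(mat.shape[1]):
            summary = five_number_summary(mat[:, j])
            rows.append({"gene_class": cls, "position": j - halfwidth, **summary})
    return pd.DataFrame(
        rows, columns=["gene_class", "position", "lo", "q1", "median", "q3", "hi", "n"]
    )


def profiles_long_table(profiles: Sequence[CoverageProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        key = f"{p.boundary_key[0]}:{p.boundary_key[1]}-{p.boundary_key[2]}:{p.boundary_key[3]}"
        for j, v in enumerate(p.values):
            rows.append(
                {
                    "boundary": key,
                    "gene_id": p.gene_id,
                    "position": j - p.halfwidth,
                    "value": v,
                    "n_window_reads": p.n_window_reads,
                }
            )
    return pd.DataFrame(
        rows, columns=["boundary", "gene_id", "position", "value", "n_window_reads"]
    )
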