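"""Maternal / early-zygotic gene classification from stage expression units.

A gene is *early zygotic* when its 2-4 hr expression exceeds a floor
(strictly more than 10 units) and is at least 5x its 0-2 hr expression,
irrespective of the 0-2 hr value.  A gene that is not early zygotic but has
strictly more than 50 units at 0-2 hr is *maternal*.  Genes with extremely
high expression (strictly more than 1000 units at either stage) are
excluded outright, before either rule.  Everything else is unclassified.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

EARLY_ZYGOTIC = "early_zygotic"
MATERNAL = "maternal"
EXCLUDED_HIGH = "excluded_high"
UNCLASSIFIED = "unclassified"
LABELS = (EARLY_ZYGOTIC, MATERNAL, EXCLUDED_HIGH, UNCLASSIFIED)


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    expr_0_2: float
    expr_2_4: float

    def __post_init__(self) -> None:
        for name, v in (("expr_0_2", self.expr_0_2), ("expr_2_4", self.expr_2_4)):
            if not math.isfinite(v) or v < 0:
                raise ValueError(
                    f"{self.gene_id}: {name} must be finite and nonnegative, got {v!r}"
                )


@dataclass(frozen=True)
class ClassifierParams:
    zygotic_min_units: float = 10.0
    zygotic_fold: float = 5.0
    maternal_min_units: float = 50.0
    exclusion_max_units: float = 1000.0

    def __post_init__(self) -> None:
        if min(self.zygotic_min_units, self.maternal_min_units, self.exclusion_max_units) <= 0:
            raise ValueError("thresholds must be positive")
        if self.zygotic_fold <= 1:
            raise ValueError("zygotic_fold must exceed 1")


def classify_gene(rec: ExpressionRecord, params: ClassifierParams = ClassifierParams()) -> str:
    """Return exactly one of the four class labels for one gene."""
    if max(rec.expr_0_2, rec.expr_2_4) > params.exclusion_max_units:
        return EXCLUDED_HIGH
    if rec.expr_2_4 > params.zygotic_min_units and rec.expr_2_4 >= params.zygotic_fold * rec.expr_0_2:
        return EARLY_ZYGOTIC
    if rec.expr_0_2 > params.maternal_min_units:
        return MATERNAL
    return UNCLASSIFIED


def classify_table(
    records: Sequence[ExpressionRecord],
    params: ClassifierParams = ClassifierParams(),
) -> tuple[dict[str, str], Counter]:
    """Classify every record; returns (gene_id -> label, per-label counts).

    Raises on duplicate gene_ids, listing the offenders.
    """
    seen: set[str] = set()
    dups: list[str] = []
    for r in records:
        if r.gene_id in seen:
            dups.append(r.gene_id)
        seen.add(r.gene_id)
    if dups:
        raise ValueError(f"duplicate gene_ids: {sorted(set(dups))}")
    labels = {r.gene_id: classify_gene(r, params) for r in records}
    counts = Counter({label: 0 for label in LABELS})
    counts.update(labels.values())
    return labels, counts


def read_expression_tsv(path: str) -> list[ExpressionRecord]:
    """Read a headered TSV with gene_id, expr_0_2, expr_2_4 columns.

    Extra columns are permitted and ignored.
    """
    out: list[ExpressionRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            col = {k: header.index(k) for k in ("gene_id", "expr_0_2", "expr_2_4")}
        except ValueError as exc:
            raise ValueError(
                f"{path}: header must contain gene_id, expr_0_2, expr_2_4"
            ) from exc
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                ExpressionRecord(
                    gene_id=f[col["gene_id"]],
                    expr_0_2=float(f[col["expr_0_2"]]),
                    expr_2_4=float(f[col["expr_2_4"]]),
                )
            )
    return out


def write_classes_tsv(labels: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tclass\n")
        for gene_id in sorted(labels):
            fh.write(f"{gene_id}\t{labels[gene_id]}\n")


def read_classes_tsv(path: str) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            gene_id, label = line.rstrip("\n").split("\t")
            out[gene_id] = label
    return out


def write_summary_json(counts: Counter, path: str) -> None:
    with open(path, "w") as fh:
        json.dump({label: counts.get(label, 0) for label in LABELS}, fh, indent=2)
        fh.write("\n")
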