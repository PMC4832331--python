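"""Classify lysine decarboxylase genes by their genetic environment.

In E. coli the acid-stress-inducible gene (ldcI/cadA) sits in an operon
with the cadB lysine–cadaverine antiporter, while the constitutive
paralogue ldcC lies between accA and yaeR. Those two arrangements are
used as classification rules for ldc genes of other enterobacteria, and
stated database annotations are audited against the rule-based call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Default gene-family synonym lists (case-insensitive exact match).
DEFAULT_SYNONYMS: dict[str, set[str]] = {
    "cadB": {"cadb"},
    "accA": {"acca"},
    "yaeR": {"yaer"},
}

#: Stated annotations mapped to the group they claim.
_STATED_GROUP = {"ldci": "ldcI-like", "cada": "ldcI-like", "ldcc": "ldcC-like"}

VALID_ANNOTATIONS = {"ldcI", "ldcC", "cadA", "unannotated"}


class ContextError(ValueError):
    pass


@dataclass
class Neighbor:
    gene_name: str
    strand: str
    same_operon: bool = False


@dataclass
class NeighborhoodRecord:
    """An ldc gene with its ordered (5'->3') stranded flanking genes."""

    gene_id: str
    taxon: str
    strand: str
    neighbors: list[Neighbor] = field(default_factory=list)
    stated_annotation: str = "unannotated"

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ContextError(f"strand must be +/- for {self.gene_id!r}")
        if self.stated_annotation not in VALID_ANNOTATIONS:
            raise ContextError(
                f"stated_annotation {self.stated_annotation!r} invalid "
                f"for {self.gene_id!r}"
            )
        for nb in self.neighbors:
            if nb.strand not in {"+", "-"}:
                raise ContextError(f"neighbor strand must be +/- in {self.gene_id!r}")


@dataclass
class ContextCall:
    gene_id: str
    call: str  # ldcI-like | ldcC-like | unknown
    evidence: str
    conflict_with_stated: bool = False


def _matches(name: str, family: str, synonyms: dict[str, set[str]]) -> bool:
    return name.lower() in synonyms[family]


def classify_by_context(
    record: NeighborhoodRecord,
    synonyms: dict[str, set[str]] | None = None,
) -> ContextCall:
    """Apply the two E. coli context rules to one neighborhood record.

    Rule 1 (ldcI-like): a cadB-family antiporter gene adjacent and in
    the same operon. Rule 2 (ldcC-like): flanked by an accA-family and
    a yaeR-family gene (either order). Both firing is reported as
    ambiguous; neither as unknown.
    """
    syn = synonyms or DEFAULT_SYNONYMS
    if not record.neighbors:
        return _with_conflict(record, ContextCall(record.gene_id, "unknown", "no-context"))

    cadb_operon = any(
        _matches(nb.gene_name, "cadB", syn)
        and nb.strand == record.strand
        and nb.same_operon
        for nb in record.neighbors
    )
    has_acca = any(_matches(nb.gene_name, "accA", syn) for nb in record.neighbors)
    has_yaer = any(_matches(nb.gene_name, "yaeR", syn) for nb in record.neighbors)
    flanked = has_acca and has_yaer

    if cadb_operon and flanked:
        call = ContextCall(record.gene_id, "unknown", "ambiguous")
    elif cadb_operon:
        call = ContextCall(record.gene_id, "ldcI-like", "cadB-operon")
    elif flanked:
        call = ContextCall(record.gene_id, "ldcC-like", "accA-yaeR-flanks")
    else:
        call = ContextCall(record.gene_id, "unknown", "no-rule-matched")
    return _with_conflict(record, call)


def _with_conflict(record: NeighborhoodRecord, call: ContextCall) -> ContextCall:
    stated = _STATED_GROUP.get(record.stated_annotation.lower())
    call.conflict_with_stated = (
        stated is not None
        and call.call in {"ldcI-like", "ldcC-like"}
        and stated != call.call
    )
    return call


def audit_annotations(
    records: list[NeighborhoodRecord],
    synonyms: dict[str, set[str]] | None = None,
) -> list[ContextCall]:
    """One ContextCall per record, with annotation conflicts flagged."""
    seen: set[str] = set()
    for rec in records:
        if rec.gene_id in seen:
            raise ContextError(f"duplicate gene_id {rec.gene_id!r}")
        seen.add(rec.gene_id)
    return [classify_by_context(rec, synonyms) for rec in records]


def audit_summary(
    records: list[NeighborhoodRecord], calls: list[ContextCall]
) -> pd.DataFrame:
    """Cross-tab of stated annotation vs context call."""
    stated = [r.stated_annotation for r in records]
    called = [c.call for c in calls]
    return pd.crosstab(
        pd.Series(stated, name="stated"), pd.Series(called, name="called")
    )


# ---------------------------------------------------------------------------
# TSV round-trip (format shared with the synthetic generator)

TSV_COLUMNS = [
    "gene_id",
    "taxon",
    "strand",
    "upstream_gene",
    "upstream_strand",
    "downstream_gene",
    "downstream_strand",
    "same_operon_flag",
    "stated_annotation",
]


def records_to_frame(records: list[NeighborhoodRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        up = r.neighbors[0] if r.neighbors else Neighbor("", "+")
        down = r.neighbors[1] if len(r.neighbors) > 1 else Neighbor("", "+")
        rows.append(
            dict(
                gene_id=r.gene_id,
                taxon=r.taxon,
                strand=r.strand,
                upstream_gene=up.gene_name,
                upstream_strand=up.strand,
                downstream_gene=down.gene_name,
                downstream_strand=down.strand,
                same_operon_flag=int(up.same_operon or down.same_operon),
                stated_annotation=r.stated_annotation,
            )
        )
    return pd.DataFrame(rows, columns=TSV_COLUMNS)


def write_tsv(records: list[NeighborhoodRecord], path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_tsv(path) -> list[NeighborhoodRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        operonic = str(row.same_operon_flag) in {"1", "True", "true"}
        neighbors = []
        if row.upstream_gene:
            neighbors.append(
                Neighbor(row.upstream_gene, row.upstream_strand,
                         operonic and row.upstream_strand == row.strand)
            )
        if row.downstream_gene:
            neighbors.append(
                Neighbor(row.downstream_gene, row.downstream_strand,
                         operonic and row.downstream_strand == row.strand)
            )
        records.append(
            NeighborhoodRecord(
                row.gene_id, row.taxon, row.strand, neighbors,
                row.stated_annotation or "unannotated",
            )
        )
    return records
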