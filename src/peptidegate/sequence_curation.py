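"""Pre-analysis sequence curation: length windowing and redundancy collapse.

Mirrors the curation applied to large channel-superfamily alignments before
a comparative screen: sequences shorter than 300 or longer than 1000
residues (fragments and fusions/mispredictions) are dropped, and near-exact
duplicates (>90% pairwise identity on the alignment) are collapsed to a
single representative so no clade is overweighted by redundant database
entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .physchem import GAP

__all__ = [
    "SequenceRecord",
    "CurationConfig",
    "filter_by_length",
    "pairwise_identity",
    "collapse_redundant",
    "mask_high_gap_columns",
    "curate",
]


@dataclass(frozen=True)
class SequenceRecord:
    """One amino-acid sequence; ``residues`` may contain '-' when aligned."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    @property
    def ungapped_length(self) -> int:
        return len(self.ungapped)


@dataclass(frozen=True)
class CurationConfig:
    min_length: int = 300
    max_length: int = 1000
    identity_threshold: float = 0.90

    def __post_init__(self) -> None:
        if not 0 < self.min_length <= self.max_length:
            raise ValueError("require 0 < min_length <= max_length")
        if not 0 < self.identity_threshold <= 1:
            raise ValueError("identity_threshold must be in (0, 1]")


def filter_by_length(
    records: list[SequenceRecord], config: CurationConfig = CurationConfig()
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Partition records into (kept, removed) by gap-stripped length.

    Bounds are inclusive: a sequence of exactly ``min_length`` or exactly
    ``max_length`` residues is kept. Input order is preserved in both
    partitions.
    """
    if not records:
        raise ValueError("filter_by_length: empty input")
    kept, removed = [], []
    for rec in records:
        n = rec.ungapped_length
        (kept if config.min_length <= n <= config.max_length else removed).append(rec)
    return kept, removed


def pairwise_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Fraction of identical residues over columns where neither row is gapped.

    Requires pre-aligned (equal-length) sequences; columns with a gap in
    either member contribute to neither numerator nor denominator.
    """
    if len(a.residues) != len(b.residues):
        raise ValueError(
            f"pairwise_identity requires aligned sequences of equal length "
            f"({a.id}: {len(a.residues)}, {b.id}: {len(b.residues)})"
        )
    matches = comparable = 0
    for x, y in zip(a.residues, b.residues):
        if x == GAP or y == GAP:
            continue
        comparable += 1
        if x == y:
            matches += 1
    if comparable == 0:
        raise ValueError(f"no comparable (mutually ungapped) columns between {a.id} and {b.id}")
    return matches / comparable


def collapse_redundant(
    records: list[SequenceRecord], config: CurationConfig = CurationConfig()
) -> tuple[list[SequenceRecord], list[SequenceRecord], dict[str, str]]:
    """Greedy redundancy collapse on an aligned set.

    Sweeps records in input order; a record is removed iff its identity to
    some already-kept record strictly exceeds ``identity_threshold`` (">90%"
    is strict: a pair at exactly the threshold survives). Returns
    (kept, removed, mapping) where ``mapping`` sends each removed id to the
    kept id that absorbed it. The representative chosen depends on input
    order, but the guarantee "no kept pair exceeds the threshold" does not.
    """
    kept: list[SequenceRecord] = []
    removed: list[SequenceRecord] = []
    mapping: dict[str, str] = {}
    for rec in records:
        absorbed_by = None
        for rep in kept:
            if pairwise_identity(rec, rep) > config.identity_threshold:
                absorbed_by = rep.id
                break
        if absorbed_by is None:
            kept.append(rec)
        else:
            removed.append(rec)
            mapping[rec.id] = absorbed_by
    return kept, removed, mapping


def mask_high_gap_columns(
    records: list[SequenceRecord], max_gap_fraction: float = 0.5
) -> tuple[list[SequenceRecord], list[int]]:
    """Drop alignment columns gapped in more than ``max_gap_fraction`` of rows.

    This is an optional, approximate stand-in for manual removal of
    poor-aligning segments; it is NOT part of the default curation path.
    Returns the masked records and the 1-based indices of dropped columns.
    """
    if not records:
        raise ValueError("mask_high_gap_columns: empty input")
    ncol = len(records[0].residues)
    if any(len(r.residues) != ncol for r in records):
        raise ValueError("records must be aligned (equal lengths)")
    n = len(records)
    dropped = [
        c
        for c in range(ncol)
        if sum(r.residues[c] == GAP for r in records) / n > max_gap_fraction
    ]
    dropset = set(dropped)
    masked = [
        SequenceRecord(
            r.id,
            "".join(ch for c, ch in enumerate(r.residues) if c not in dropset),
            r.description,
        )
        for r in records
    ]
    return masked, [c + 1 for c in dropped]


@dataclass
class CurationReport:
    kept: list[SequenceRecord]
    removed_length: list[SequenceRecord]
    removed_redundant: list[SequenceRecord]
    redundancy_mapping: dict[str, str] = field(default_factory=dict)

    def removal_rows(self) -> list[tuple[str, str, str]]:
        """(id, reason, detail) rows for the TSV removal report."""
        rows = [
            (r.id, "length", f"{r.ungapped_length} aa outside window")
            for r in self.removed_length
        ]
        rows += [
            (r.id, "redundant", f"absorbed by {self.redundancy_mapping[r.id]}")
            for r in self.removed_redundant
        ]
        return rows


def curate(
    records: list[SequenceRecord], config: CurationConfig = CurationConfig()
) -> CurationReport:
    """Length filter followed by redundancy collapse; idempotent."""
    by_length, removed_length = filter_by_length(records, config)
    kept, removed_red, mapping = collapse_redundant(by_length, config)
    return CurationReport(kept, removed_length, removed_red, mapping)
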