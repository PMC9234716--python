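"""Clade-contrast screen for specificity-determining alignment columns.

Given a clade-labeled multiple sequence alignment (a foreground clade of
peptide-gated channels against the rest of the superfamily as background),
every column is scored for foreground conservation — complete identity or
shared physicochemical class — versus divergence in the background. Columns
that clear both thresholds become candidate residues, reported in the
ungapped numbering of a chosen reference sequence, each with a proposed
mutation: swap to the background consensus residue where one exists, or to
alanine where the background is too heterogeneous to name an "equivalent"
residue.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .physchem import AMBIGUOUS, GAP, residue_class
from .sequence_curation import SequenceRecord

logger = logging.getLogger(__name__)

__all__ = [
    "CladeLabeledAlignment",
    "ScanConfig",
    "CandidateResidue",
    "column_conservation",
    "scan",
    "column_to_ref",
    "ref_to_column",
    "propose_mutation",
    "group_vicinal",
    "map_equivalent_residue",
    "GAPPED",
]

FOREGROUND = "foreground"
BACKGROUND = "background"
EXCLUDED = "excluded"
LABELS = frozenset({FOREGROUND, BACKGROUND, EXCLUDED})

#: sentinel returned by map_equivalent_residue when the target row is gapped
GAPPED = "gapped"


@dataclass
class CladeLabeledAlignment:
    """Equal-length gapped records plus an id -> clade-label partition."""

    records: list[SequenceRecord]
    partition: dict[str, str]

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("alignment is empty")
        ncol = len(self.records[0].residues)
        for r in self.records:
            if len(r.residues) != ncol:
                raise ValueError(f"row {r.id} length {len(r.residues)} != {ncol}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in alignment")
        for r in self.records:
            label = self.partition.get(r.id)
            if label is None:
                raise ValueError(f"row {r.id} has no clade label")
            if label not in LABELS:
                raise ValueError(f"row {r.id}: unknown label {label!r}")
        if len(self.rows_with_label(FOREGROUND)) < 2:
            raise ValueError("need at least 2 foreground rows")
        if len(self.rows_with_label(BACKGROUND)) < 2:
            raise ValueError("need at least 2 background rows")

    @property
    def n_columns(self) -> int:
        return len(self.records[0].residues)

    def rows_with_label(self, label: str) -> list[SequenceRecord]:
        return [r for r in self.records if self.partition[r.id] == label]

    def record(self, seq_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(f"sequence {seq_id!r} not in alignment")

    def column(self, column: int, label: str | None = None) -> list[str]:
        """Characters of a 1-based column, optionally restricted to a label."""
        if not 1 <= column <= self.n_columns:
            raise IndexError(f"column {column} outside [1, {self.n_columns}]")
        rows = self.records if label is None else self.rows_with_label(label)
        return [r.residues[column - 1] for r in rows]


@dataclass(frozen=True)
class ScanConfig:
    """Thresholds operationalizing "conserved in the foreground, divergent outside".

    The source screen gives no numeric thresholds, so these defaults are the
    package's operating point and every one is exposed. ``mode`` "either"
    accepts a column conserved at the identity level OR at the class level.
    """

    reference_id: str = ""
    fg_conservation_min: float = 0.90
    bg_match_max: float = 0.20
    mode: str = "either"  # identity | class | either
    fg_gap_max: float = 0.50
    region_of_interest: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        for name in ("fg_conservation_min", "bg_match_max", "fg_gap_max"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.mode not in ("identity", "class", "either"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class CandidateResidue:
    column: int
    ref_number: int
    ref_residue: str
    fg_consensus: str
    fg_class: str | None
    fg_conservation: float
    bg_match_fraction: float
    matched_mode: str
    proposed_mutation: str = ""


def _ungapped(chars: list[str]) -> list[str]:
    return [c for c in chars if c != GAP]


def column_conservation(
    alignment: CladeLabeledAlignment,
    column: int,
    label: str,
    mode: str = "identity",
) -> tuple[str, float]:
    """Consensus and conservation score of one column within one clade label.

    Identity mode returns (modal residue, modal count / ungapped count);
    class mode returns (modal class label, modal-class count / ungapped
    count). Gaps are excluded from both numerator and denominator; the
    ambiguity code X counts toward the denominator but can never be the
    consensus.
    """
    chars = _ungapped(alignment.column(column, label))
    if not chars:
        raise ValueError(f"column {column} is all-gap for label {label!r}")
    n = len(chars)
    if mode == "identity":
        counts = Counter(c for c in chars if c != AMBIGUOUS)
        if not counts:
            raise ValueError(f"column {column}: only ambiguity codes for {label!r}")
        consensus, top = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
        return consensus, top / n
    if mode == "class":
        classes = Counter(
            cls for c in chars if (cls := residue_class(c)) is not None
        )
        if not classes:
            raise ValueError(f"column {column}: no classifiable residue for {label!r}")
        consensus, top = max(classes.items(), key=lambda kv: (kv[1], kv[0]))
        return consensus, top / n
    raise ValueError(f"unknown mode {mode!r}")


def _bg_match_fraction(
    alignment: CladeLabeledAlignment, column: int, consensus: str, mode: str
) -> float:
    """Fraction of ungapped background residues matching the foreground consensus."""
    chars = _ungapped(alignment.column(column, BACKGROUND))
    if not chars:
        raise ValueError(f"column {column} is all-gap in the background")
    if mode == "identity":
        hits = sum(c == consensus and c != AMBIGUOUS for c in chars)
    else:
        hits = sum(residue_class(c) == consensus for c in chars)
    return hits / len(chars)


def column_to_ref(
    alignment: CladeLabeledAlignment, column: int, reference_id: str
) -> int:
    """Ungapped reference position at a 1-based alignment column."""
    ref = alignment.record(reference_id).residues
    if not 1 <= column <= len(ref):
        raise IndexError(f"column {column} outside alignment")
    if ref[column - 1] == GAP:
        raise ValueError(f"reference {reference_id} is gapped at column {column}")
    return column - ref[:column].count(GAP)


def ref_to_column(
    alignment: CladeLabeledAlignment, ref_number: int, reference_id: str
) -> int:
    """Alignment column of a 1-based ungapped reference position."""
    ref = alignment.record(reference_id).residues
    seen = 0
    for i, c in enumerate(ref):
        if c != GAP:
            seen += 1
            if seen == ref_number:
                return i + 1
    raise IndexError(
        f"position {ref_number} beyond reference {reference_id} length {seen}"
    )


def _column_verdict(
    alignment: CladeLabeledAlignment, column: int, config: ScanConfig
) -> tuple[str, str, float, float] | None:
    """(mode, consensus, fg_score, bg_match) of the passing mode, or None.

    Mode "either" evaluates the full identity criterion and the full class
    criterion independently and accepts if either accepts (identity
    preferred when both do).
    """
    modes = [config.mode] if config.mode != "either" else ["identity", "class"]
    for mode in modes:
        try:
            consensus, score = column_conservation(alignment, column, FOREGROUND, mode)
        except ValueError:
            # only gaps/X (identity) or no classifiable residue (class):
            # the column cannot exhibit foreground conservation in this mode
            continue
        if score < config.fg_conservation_min:
            continue
        try:
            bg = _bg_match_fraction(alignment, column, consensus, mode)
        except ValueError:
            # no ungapped background residue: divergence cannot be assessed
            continue
        if bg <= config.bg_match_max:
            return mode, consensus, score, bg
    return None


def scan(
    alignment: CladeLabeledAlignment, config: ScanConfig
) -> list[CandidateResidue]:
    """Screen every column for foreground conservation vs background divergence.

    A column is a candidate iff its foreground gap fraction is at most
    ``fg_gap_max``, its foreground conservation reaches
    ``fg_conservation_min`` in the configured mode, at most ``bg_match_max``
    of ungapped background residues match the foreground consensus, the
    reference row is ungapped there, and (if a region of interest is set)
    the reference position falls inside it. Output is sorted by reference
    position; ``proposed_mutation`` is filled in.
    """
    if not config.reference_id:
        raise ValueError("ScanConfig.reference_id must be set for a scan")
    ref = alignment.record(config.reference_id)  # raises if absent
    fg_rows = alignment.rows_with_label(FOREGROUND)
    n_fg = len(fg_rows)

    out: list[CandidateResidue] = []
    for col in range(1, alignment.n_columns + 1):
        fg_chars = [r.residues[col - 1] for r in fg_rows]
        gap_frac = fg_chars.count(GAP) / n_fg
        if gap_frac > config.fg_gap_max or gap_frac == 1.0:
            continue
        verdict = _column_verdict(alignment, col, config)
        if verdict is None:
            continue
        mode, consensus, score, bg = verdict
        if ref.residues[col - 1] == GAP:
            logger.warning(
                "column %d passes the contrast thresholds but the reference "
                "%s is gapped there; candidate dropped",
                col,
                config.reference_id,
            )
            continue
        ref_number = column_to_ref(alignment, col, config.reference_id)
        if config.region_of_interest is not None and not any(
            lo <= ref_number <= hi for lo, hi in config.region_of_interest
        ):
            continue
        if mode == "identity":
            fg_consensus, fg_class = consensus, residue_class(consensus)
        else:
            # class-level pass: report the modal residue as consensus
            fg_consensus, _ = column_conservation(alignment, col, FOREGROUND, "identity")
            fg_class = consensus
        cand = CandidateResidue(
            column=col,
            ref_number=ref_number,
            ref_residue=ref.residues[col - 1],
            fg_consensus=fg_consensus,
            fg_class=fg_class,
            fg_conservation=score,
            bg_match_fraction=bg,
            matched_mode=mode,
        )
        out.append(
            CandidateResidue(
                **{**cand.__dict__, "proposed_mutation": propose_mutation(cand, alignment)}
            )
        )
    out.sort(key=lambda c: c.ref_number)
    return out


def propose_mutation(
    candidate: CandidateResidue, alignment: CladeLabeledAlignment
) -> str:
    """Mutation string for a candidate: to the background consensus, else alanine.

    The target is the modal background residue if it reaches frequency 0.5
    among ungapped background residues — the "equivalent residue from
    channels outside the foreground clade". If the background is too
    heterogeneous to name one, or the nominal target equals the reference
    residue, alanine is substituted instead.
    """
    chars = [
        c
        for c in _ungapped(alignment.column(candidate.column, BACKGROUND))
        if c != AMBIGUOUS
    ]
    target = "A"
    if chars:
        modal, count = max(Counter(chars).items(), key=lambda kv: (kv[1], kv[0]))
        if count / len(chars) >= 0.5:
            target = modal
    if target == candidate.ref_residue:
        target = "A"
    return f"{candidate.ref_residue}{candidate.ref_number}{target}"


def group_vicinal(
    candidates: list[CandidateResidue], max_gap: int = 2
) -> list[list[CandidateResidue]]:
    """Group candidates whose reference positions sit within ``max_gap`` residues.

    Single-linkage runs are formed first, then split greedily left-to-right
    into groups of at most three, matching the practice of mutating one to
    three vicinal residues together.
    """
    if not candidates:
        return []
    ordered = sorted(candidates, key=lambda c: c.ref_number)
    runs: list[list[CandidateResidue]] = [[ordered[0]]]
    for cand in ordered[1:]:
        if cand.ref_number - runs[-1][-1].ref_number <= max_gap:
            runs[-1].append(cand)
        else:
            runs.append([cand])
    groups: list[list[CandidateResidue]] = []
    for run in runs:
        for i in range(0, len(run), 3):
            groups.append(run[i : i + 3])
    return groups


def map_equivalent_residue(
    alignment: CladeLabeledAlignment, from_id: str, ref_number: int, to_id: str
) -> int | str:
    """Ungapped position in ``to_id`` aligned with ``ref_number`` of ``from_id``.

    Returns the sentinel :data:`GAPPED` if the target row is gapped at that
    column — positions are never silently renumbered.
    """
    col = ref_to_column(alignment, ref_number, from_id)
    target = alignment.record(to_id)
    if target.residues[col - 1] == GAP:
        return GAPPED
    return column_to_ref(alignment, col, to_id)
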