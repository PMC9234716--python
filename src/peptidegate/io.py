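"""File formats: FASTA alignments, clade tables, newick trees, traces, peaks.

FASTA goes through Biopython; newick through dendropy. Traces are plain TSV
(time_s, current_uA) with a JSON sidecar holding application windows and
holding potential, so raw recordings stay greppable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .sequence_curation import SequenceRecord
from .clade_contrast import (
    BACKGROUND,
    FOREGROUND,
    LABELS,
    CladeLabeledAlignment,
    CandidateResidue,
)
from .ephys_stats import ApplicationWindow, CurrentTrace, DoseResponseSet

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_clades_tsv",
    "write_clades_tsv",
    "clades_from_tree",
    "read_alignment",
    "write_candidates_tsv",
    "candidates_to_json",
    "read_trace",
    "write_trace",
    "read_dose_response",
    "write_dose_response",
]


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    records = [
        SequenceRecord(rec.id, str(rec.seq).upper(), rec.description)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    bio = [
        BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_clades_tsv(path: str | Path) -> dict[str, str]:
    """Two-column TSV: sequence id, label in {foreground, background, excluded}."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "label"], comment="#")
    partition = {}
    for _, row in df.iterrows():
        label = str(row["label"]).strip()
        if label not in LABELS:
            raise ValueError(f"unknown clade label {label!r} for {row['id']!r}")
        partition[str(row["id"]).strip()] = label
    return partition


def write_clades_tsv(partition: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid in partition:
            fh.write(f"{sid}\t{partition[sid]}\n")


def clades_from_tree(
    newick_path: str | Path, foreground_node: str, all_ids: list[str] | None = None
) -> dict[str, str]:
    """Partition from a newick tree: leaves under a named internal node are
    foreground, every other leaf background."""
    tree = dendropy.Tree.get(path=str(newick_path), schema="newick")
    node = None
    for nd in tree.preorder_node_iter():
        if nd.label == foreground_node or (
            nd.taxon is not None and nd.taxon.label == foreground_node
        ):
            node = nd
            break
    if node is None:
        raise ValueError(f"no node labeled {foreground_node!r} in {newick_path}")
    fg = {leaf.taxon.label for leaf in node.leaf_iter()}
    leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    partition = {leaf: (FOREGROUND if leaf in fg else BACKGROUND) for leaf in leaves}
    if all_ids is not None:
        for sid in all_ids:
            partition.setdefault(sid, "excluded")
    return partition


def read_alignment(
    fasta_path: str | Path, clades_path: str | Path
) -> CladeLabeledAlignment:
    return CladeLabeledAlignment(read_fasta(fasta_path), read_clades_tsv(clades_path))


def write_candidates_tsv(candidates: list[CandidateResidue], path: str | Path) -> None:
    pd.DataFrame([c.__dict__ for c in candidates]).to_csv(path, sep="\t", index=False)


def candidates_to_json(candidates: list[CandidateResidue]) -> list[dict]:
    return [dict(c.__dict__) for c in candidates]


# ---------------------------------------------------------------------------
# Traces


def write_trace(trace: CurrentTrace, path: str | Path) -> None:
    """TSV (time_s, current_uA) plus a <name>.json sidecar with metadata."""
    path = Path(path)
    pd.DataFrame({"time_s": trace.time, "current_uA": trace.current}).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
    sidecar = {
        "holding_potential_mv": trace.holding_potential_mv,
        "application_windows": [
            {
                "start_s": w.start,
                "end_s": w.end,
                "ligand": w.ligand,
                "concentration_M": None if np.isnan(w.concentration) else w.concentration,
            }
            for w in trace.application_windows
        ],
        "metadata": trace.metadata,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_trace(path: str | Path) -> CurrentTrace:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    windows = [
        ApplicationWindow(
            w["start_s"],
            w["end_s"],
            w.get("ligand", ""),
            float("nan") if w.get("concentration_M") is None else w["concentration_M"],
        )
        for w in sidecar.get("application_windows", [])
    ]
    return CurrentTrace(
        df["time_s"].to_numpy(),
        df["current_uA"].to_numpy(),
        windows,
        sidecar.get("holding_potential_mv", -60.0),
        sidecar.get("metadata", {}),
    )


def write_dose_response(ds: DoseResponseSet, path: str | Path) -> None:
    ds.table.to_csv(path, sep="\t", index=False)


def read_dose_response(path: str | Path, construct: str = "", ligand: str = "") -> DoseResponseSet:
    df = pd.read_csv(path, sep="\t")
    return DoseResponseSet(df, construct=construct, ligand=ligand)
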