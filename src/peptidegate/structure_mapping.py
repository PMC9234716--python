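"""Map candidate residues onto a trimeric channel structure.

DEG/ENaC channels are homotrimers, and a ligand site may sit at the seam
between two subunits rather than inside one. This module measures, for each
candidate residue, the minimum distance from its atoms to any atom of a
different chain, flags residues within a cutoff as interfacial, and groups
interfacial residues into spatial pockets by single-linkage clustering of
Cα positions.

The default atom mode is Cα: side-chain placement in low-identity homology
models is unreliable, while backbone positions are comparatively robust, so
an 8 Å Cα cutoff is used rather than a 5 Å heavy-atom contact criterion
(both are available).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

import biotite.structure as struc
import biotite.structure.io.pdb as pdb

__all__ = [
    "TrimerStructure",
    "InterfaceHit",
    "PocketReport",
    "min_interchain_distance",
    "detect_interface_residues",
    "cluster_pockets",
    "DEFAULT_CUTOFF",
]

#: default interface cutoffs in Å by atom mode
DEFAULT_CUTOFF = {"CA": 8.0, "heavy": 5.0}


@dataclass
class TrimerStructure:
    """Exactly three chains of residues with atomic coordinates (Å)."""

    atoms: struc.AtomArray

    def __post_init__(self) -> None:
        chains = self.chain_ids
        if len(chains) != 3:
            raise ValueError(f"expected exactly 3 chains, found {sorted(chains)}")
        if not np.all(np.isfinite(self.atoms.coord)):
            raise ValueError("non-finite coordinates in structure")

    @property
    def chain_ids(self) -> list[str]:
        return sorted(set(self.atoms.chain_id))

    @classmethod
    def from_pdb(cls, path: str) -> "TrimerStructure":
        """Read the first model; altloc 'A'/blank only; insertion codes rejected."""
        f = pdb.PDBFile.read(path)
        arr = f.get_structure(model=1, altloc="first")
        if np.any(arr.ins_code != ""):
            raise ValueError(
                "structure contains insertion codes; renumber before mapping"
            )
        return cls(arr)

    def to_pdb(self, path: str) -> None:
        f = pdb.PDBFile()
        f.set_structure(self.atoms)
        f.write(path)

    def select(
        self, chain: str | None = None, res_id: int | None = None, atom_mode: str = "CA"
    ) -> struc.AtomArray:
        mask = np.ones(self.atoms.array_length(), dtype=bool)
        if chain is not None:
            mask &= self.atoms.chain_id == chain
        if res_id is not None:
            mask &= self.atoms.res_id == res_id
        if atom_mode == "CA":
            mask &= self.atoms.atom_name == "CA"
        elif atom_mode == "heavy":
            mask &= self.atoms.element != "H"
        else:
            raise ValueError(f"unknown atom_mode {atom_mode!r}")
        return self.atoms[mask]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TrimerStructure":
        """Rigid-body copy: coords @ R.T + t."""
        arr = self.atoms.copy()
        arr.coord = arr.coord @ np.asarray(rotation).T + np.asarray(translation)
        return TrimerStructure(arr)


@dataclass(frozen=True)
class InterfaceHit:
    chain: str
    res_id: int
    distance: float
    partner_chain: str
    interfacial: bool


@dataclass
class PocketReport:
    """Interface flags per candidate plus single-linkage pocket clusters."""

    interfacial: list[InterfaceHit]
    non_interfacial: list[InterfaceHit]
    unresolved: list[int]
    pockets: list[dict] = field(default_factory=list)
    cutoff: float = 0.0
    atom_mode: str = "CA"

    @property
    def flagged_res_ids(self) -> list[int]:
        return sorted({h.res_id for h in self.interfacial})


def min_interchain_distance(
    structure: TrimerStructure, chain: str, res_id: int, atom_mode: str = "CA"
) -> tuple[float, str]:
    """Minimum distance (Å) from a residue's atoms to any atom of another chain.

    Returns the distance and the chain achieving it. Raises if the residue
    or its atoms in the selected mode are absent, or if no other chain
    exists.
    """
    own = structure.select(chain=chain, res_id=res_id, atom_mode=atom_mode)
    if own.array_length() == 0:
        raise ValueError(f"residue {chain}/{res_id} has no {atom_mode} atoms")
    others = [c for c in structure.chain_ids if c != chain]
    if not others:
        raise ValueError("structure has a single chain; no partner exists")
    best, partner = np.inf, others[0]
    for other in others:
        coords = structure.select(chain=other, atom_mode=atom_mode).coord
        if len(coords) == 0:
            continue
        d = cKDTree(coords).query(own.coord, k=1)[0].min()
        if d < best:
            best, partner = float(d), other
    return best, partner


def _min_interchain_distance_bruteforce(
    structure: TrimerStructure, chain: str, res_id: int, atom_mode: str = "CA"
) -> float:
    """All-pairs oracle for the KD-tree path; used in tests only."""
    own = structure.select(chain=chain, res_id=res_id, atom_mode=atom_mode).coord
    best = np.inf
    for other in structure.chain_ids:
        if other == chain:
            continue
        coords = structure.select(chain=other, atom_mode=atom_mode).coord
        if len(coords):
            diff = own[:, None, :] - coords[None, :, :]
            best = min(best, float(np.sqrt((diff**2).sum(-1)).min()))
    return best


def detect_interface_residues(
    structure: TrimerStructure,
    candidates: list[int],
    cutoff: float | None = None,
    atom_mode: str = "CA",
) -> PocketReport:
    """Flag candidate residues lying within ``cutoff`` of a different chain.

    Candidates are residue numbers in the reference (chain) numbering and
    are evaluated on every chain. Candidates absent from the structure
    (e.g. unmodeled loops) are recorded as unresolved, not raised.
    """
    if cutoff is None:
        cutoff = DEFAULT_CUTOFF[atom_mode]
    hits, misses, unresolved = [], [], []
    for res_id in candidates:
        present = False
        for chain in structure.chain_ids:
            if structure.select(chain=chain, res_id=res_id, atom_mode=atom_mode).array_length() == 0:
                continue
            present = True
            d, partner = min_interchain_distance(structure, chain, res_id, atom_mode)
            hit = InterfaceHit(chain, res_id, d, partner, d <= cutoff)
            (hits if hit.interfacial else misses).append(hit)
        if not present:
            unresolved.append(res_id)
    report = PocketReport(
        interfacial=hits,
        non_interfacial=misses,
        unresolved=unresolved,
        cutoff=cutoff,
        atom_mode=atom_mode,
    )
    report.pockets = cluster_pockets(structure, hits)
    return report


def cluster_pockets(
    structure: TrimerStructure,
    interfacial: list[InterfaceHit],
    linkage_cutoff: float = 12.0,
) -> list[dict]:
    """Single-linkage clusters of interfacial residues under Cα distance.

    Each cluster is reported as a sorted set of residue numbers (chain
    copies of the same pocket merge) with its linkage diameter, the maximum
    pairwise Cα distance inside the cluster.
    """
    if not interfacial:
        return []
    coords = []
    keys = []
    for hit in interfacial:
        ca = structure.select(chain=hit.chain, res_id=hit.res_id, atom_mode="CA")
        if ca.array_length() == 0:
            raise ValueError(f"no Cα for {hit.chain}/{hit.res_id}")
        coords.append(ca.coord[0])
        keys.append((hit.chain, hit.res_id))
    coords = np.asarray(coords)
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    adjacency = csr_matrix(dist <= linkage_cutoff)
    n_comp, labels = connected_components(adjacency, directed=False)
    pockets = []
    for comp in range(n_comp):
        idx = np.flatnonzero(labels == comp)
        members = sorted({keys[i][1] for i in idx})
        diameter = float(dist[np.ix_(idx, idx)].max())
        pockets.append({"residues": members, "diameter": diameter, "size": len(idx)})
    pockets.sort(key=lambda p: (-p["size"], p["residues"]))
    return pockets
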