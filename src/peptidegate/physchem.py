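"""Fixed six-class physicochemical grouping of the 20 standard amino acids.

This scheme is the single source of truth used both by the synthetic
alignment generator (to plant class-conserved columns) and by the
clade-contrast scan (to score class-level conservation). Histidine is
grouped with the positives, cysteine with the aliphatics, and glycine and
proline are isolated as a "special" class because their backbone behaviour
resembles no side-chain group.
"""

from __future__ import annotations

CLASSES: dict[str, str] = {
    "aliphatic": "AVLIMC",
    "aromatic": "FWY",
    "positive": "KRH",
    "negative": "DE",
    "polar": "STNQ",
    "special": "GP",
}

#: residue -> class label; residues outside the 20-letter alphabet (X, gaps)
#: have no class and never match anything.
CLASS_OF: dict[str, str] = {
    aa: name for name, members in CLASSES.items() for aa in members
}

AMINO_ACIDS: str = "".join(sorted(CLASS_OF))

GAP = "-"
AMBIGUOUS = "X"


def residue_class(residue: str) -> str | None:
    """Class label of a residue, or ``None`` for gaps, X, or non-standard codes."""
    return CLASS_OF.get(residue.upper())


def same_class(a: str, b: str) -> bool:
    """True iff both residues are standard and share a physicochemical class."""
    ca = residue_class(a)
    return ca is not None and ca == residue_class(b)


def class_members(label: str) -> str:
    """Residues belonging to a class label."""
    return CLASSES[label]
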