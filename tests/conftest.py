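import numpy as np
import pytest

from peptidegate.clade_contrast import CladeLabeledAlignment
from peptidegate.sequence_curation import SequenceRecord
from peptidegate.synthetic_data import simulate_trimer


def make_alignment(fg_rows, bg_rows, excluded_rows=()):
    """Build a CladeLabeledAlignment from plain residue strings."""
    records, partition = [], {}
    for i, seq in enumerate(fg_rows):
        rid = f"fg{i + 1}"
        records.append(SequenceRecord(rid, seq))
        partition[rid] = "foreground"
    for i, seq in enumerate(bg_rows):
        rid = f"bg{i + 1}"
        records.append(SequenceRecord(rid, seq))
        partition[rid] = "background"
    for i, seq in enumerate(excluded_rows):
        rid = f"ex{i + 1}"
        records.append(SequenceRecord(rid, seq))
        partition[rid] = "excluded"
    return CladeLabeledAlignment(records, partition)


@pytest.fixture
def contrast_alignment():
    """Six-row alignment with a hand-designed candidate at column 2.

    Column 2: foreground all R, background all Q (maximal contrast).
    Column 4: foreground F/F/Y (class-conserved aromatic), background D/E/K.
    Column 1: M everywhere (conserved in both clades -> not a candidate).
    """
    return make_alignment(
        fg_rows=["MRAFG", "MRCFG", "MRDYG"],
        bg_rows=["MQADG", "MQCEG", "MQDKG"],
    )


@pytest.fixture(scope="session")
def toy_trimer():
    structure, truth = simulate_trimer(
        60, pocket_residues=[10, 20, 30], interface_radius=5.0, seed=11
    )
    return structure, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
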