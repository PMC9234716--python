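"""Column scoring, candidate scanning, numbering, mutation proposals."""

from collections import Counter

import numpy as np
import pytest

from peptidegate.physchem import CLASS_OF, CLASSES, residue_class
from peptidegate.clade_contrast import (
    GAPPED,
    CandidateResidue,
    ScanConfig,
    column_conservation,
    column_to_ref,
    group_vicinal,
    map_equivalent_residue,
    propose_mutation,
    ref_to_column,
    scan,
)
from peptidegate.sequence_curation import SequenceRecord

from conftest import make_alignment


def test_physchem_classes_partition_the_alphabet():
    members = "".join(CLASSES.values())
    assert len(members) == 20 and len(set(members)) == 20
    assert residue_class("X") is None and residue_class("-") is None


class TestColumnConservation:
    def test_fully_conserved_identity(self):
        aln = make_alignment(["F", "F", "F"], ["A", "A"])
        assert column_conservation(aln, 1, "foreground", "identity") == ("F", 1.0)

    def test_class_conservation_exceeds_identity(self):
        aln = make_alignment(["F", "F", "F", "F", "Y"], ["A", "A"])
        assert column_conservation(aln, 1, "foreground", "class") == ("aromatic", 1.0)
        cons, score = column_conservation(aln, 1, "foreground", "identity")
        assert (cons, score) == ("F", pytest.approx(0.8))

    def test_gaps_excluded_from_both_counts(self):
        aln = make_alignment(["F", "-", "F", "-", "F"], ["A", "A"])
        assert column_conservation(aln, 1, "foreground", "identity") == ("F", 1.0)

    def test_all_gap_column_is_an_error_not_zero(self):
        aln = make_alignment(["-A", "-A"], ["AA", "AA"])
        with pytest.raises(ValueError):
            column_conservation(aln, 1, "foreground", "identity")

    def test_x_never_forms_consensus(self):
        aln = make_alignment(["X", "X", "F"], ["A", "A"])
        cons, score = column_conservation(aln, 1, "foreground", "identity")
        assert cons == "F" and score == pytest.approx(1 / 3)


class TestScan:
    def test_maximal_contrast_column(self, contrast_alignment):
        cands = scan(contrast_alignment, ScanConfig(reference_id="fg1"))
        by_col = {c.column: c for c in cands}
        assert 2 in by_col
        assert by_col[2].fg_conservation == 1.0
        assert by_col[2].bg_match_fraction == 0.0
        assert 1 not in by_col  # conserved in both clades

    def test_class_mode_catches_aromatic_column(self, contrast_alignment):
        cands = scan(contrast_alignment, ScanConfig(reference_id="fg1", mode="class"))
        assert 4 in {c.column for c in cands}
        cands_id = scan(
            contrast_alignment, ScanConfig(reference_id="fg1", mode="identity")
        )
        assert 4 not in {c.column for c in cands_id}  # F/F/Y fails identity 0.9

    def test_background_match_threshold(self):
        # foreground all A; background 50% A -> rejected at bg_match_max 0.20
        aln = make_alignment(["A", "A", "A"], ["A", "A", "D", "E"])
        assert scan(aln, ScanConfig(reference_id="fg1")) == []
        relaxed = ScanConfig(reference_id="fg1", bg_match_max=0.5)
        assert [c.column for c in scan(aln, relaxed)] == [1]

    def test_region_of_interest_restricts_output(self, contrast_alignment):
        cfg = ScanConfig(reference_id="fg1", region_of_interest=((3, 5),))
        assert all(c.ref_number >= 3 for c in scan(contrast_alignment, cfg))

    def test_row_permutation_and_renaming_invariance(self, contrast_alignment):
        from peptidegate.clade_contrast import CladeLabeledAlignment

        base = scan(contrast_alignment, ScanConfig(reference_id="fg1"))
        recs = list(reversed(contrast_alignment.records))
        perm = CladeLabeledAlignment(recs, contrast_alignment.partition)
        assert scan(perm, ScanConfig(reference_id="fg1")) == base
        renamed_recs = [
            SequenceRecord("z" + r.id, r.residues) for r in contrast_alignment.records
        ]
        renamed = CladeLabeledAlignment(
            renamed_recs,
            {"z" + k: v for k, v in contrast_alignment.partition.items()},
        )
        renamed_out = scan(renamed, ScanConfig(reference_id="zfg1"))
        assert [(c.column, c.fg_conservation) for c in renamed_out] == [
            (c.column, c.fg_conservation) for c in base
        ]

    def test_monotone_in_thresholds(self, rng):
        aln = _random_alignment(rng, 6, 10)
        base = {c.column for c in scan(aln, ScanConfig(reference_id="fg1",
                                                       fg_conservation_min=0.6,
                                                       bg_match_max=0.5))}
        for fg_min, bg_max in [(0.8, 0.5), (0.6, 0.3), (0.9, 0.1)]:
            tighter = {
                c.column
                for c in scan(
                    aln,
                    ScanConfig(reference_id="fg1", fg_conservation_min=fg_min,
                               bg_match_max=bg_max),
                )
            }
            assert tighter <= base


def _random_alignment(rng, n_rows, n_cols):
    alphabet = list("ACDEFGHIKLMNPQRSTVWY-")
    weights = np.array([1.0] * 20 + [4.0])
    weights /= weights.sum()
    n_fg = n_rows // 2
    rows = []
    for _ in range(n_rows):
        rows.append("".join(rng.choice(alphabet, size=n_cols, p=weights)))
    # reference must have at least one residue; force ungapped reference
    rows[0] = "".join(rng.choice(alphabet[:-1], size=n_cols))
    return make_alignment(rows[:n_fg], rows[n_fg:])


def _brute_force_candidate_columns(aln, config):
    """Independent per-column recount with plain loops and Counters."""
    ref = aln.record(config.reference_id)
    fg_rows = [r for r in aln.records if aln.partition[r.id] == "foreground"]
    bg_rows = [r for r in aln.records if aln.partition[r.id] == "background"]
    out = []
    for col in range(1, aln.n_columns + 1):
        fg = [r.residues[col - 1] for r in fg_rows]
        bg = [r.residues[col - 1] for r in bg_rows]
        if fg.count("-") / len(fg) > config.fg_gap_max:
            continue
        fg_ng = [c for c in fg if c != "-"]
        bg_ng = [c for c in bg if c != "-"]
        if not fg_ng or not bg_ng:
            continue
        passed = False
        modes = (
            ["identity", "class"] if config.mode == "either" else [config.mode]
        )
        for mode in modes:
            if mode == "identity":
                counts = Counter(c for c in fg_ng if c != "X")
                if not counts:
                    continue
                cons, top = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
                score = top / len(fg_ng)
                bg_match = sum(c == cons and c != "X" for c in bg_ng) / len(bg_ng)
            else:
                counts = Counter(
                    CLASS_OF[c] for c in fg_ng if c in CLASS_OF
                )
                if not counts:
                    continue
                cons, top = max(counts.items(), key=lambda kv: (kv[1], kv[0]))
                score = top / len(fg_ng)
                bg_match = sum(CLASS_OF.get(c) == cons for c in bg_ng) / len(bg_ng)
            if score >= config.fg_conservation_min and bg_match <= config.bg_match_max:
                passed = True
                break
        if passed and ref.residues[col - 1] != "-":
            out.append(col)
    return out


@pytest.mark.parametrize("trial", range(30))
@pytest.mark.parametrize("mode", ["identity", "class", "either"])
def test_scan_agrees_with_brute_force_recount(trial, mode):
    rng = np.random.default_rng(1000 + trial)
    n_rows = int(rng.integers(4, 7))
    n_cols = int(rng.integers(3, 11))
    aln = _random_alignment(rng, n_rows, n_cols)
    cfg = ScanConfig(
        reference_id="fg1",
        fg_conservation_min=float(rng.choice([0.5, 0.7, 0.9])),
        bg_match_max=float(rng.choice([0.0, 0.2, 0.4])),
        mode=mode,
    )
    assert [c.column for c in scan(aln, cfg)] == _brute_force_candidate_columns(aln, cfg)


class TestNumbering:
    def test_gapped_reference_hand_count(self):
        aln = make_alignment(["M-KL", "M-KL"], ["MAKL", "MAKL"])
        assert column_to_ref(aln, 3, "fg1") == 2
        assert ref_to_column(aln, 2, "fg1") == 3

    def test_ungapped_reference_is_identity(self):
        aln = make_alignment(["MAKL", "MAKL"], ["MAKL", "MAKL"])
        for col in range(1, 5):
            assert column_to_ref(aln, col, "fg1") == col

    def test_round_trip(self):
        aln = make_alignment(["M--KLV-W", "MAAKLVAW"], ["MAAKLVAW", "MAAKLVAW"])
        for col in (1, 4, 5, 6, 8):
            assert ref_to_column(aln, column_to_ref(aln, col, "fg1"), "fg1") == col

    def test_gapped_column_is_an_error(self):
        aln = make_alignment(["M-KL", "M-KL"], ["MAKL", "MAKL"])
        with pytest.raises(ValueError):
            column_to_ref(aln, 2, "fg1")


class TestProposeMutation:
    def _candidate(self, aln, col):
        return CandidateResidue(
            column=col,
            ref_number=column_to_ref(aln, col, "fg1"),
            ref_residue=aln.record("fg1").residues[col - 1],
            fg_consensus=aln.record("fg1").residues[col - 1],
            fg_class=None,
            fg_conservation=1.0,
            bg_match_fraction=0.0,
            matched_mode="identity",
        )

    def test_background_consensus_target(self):
        aln = make_alignment(["A", "A"], ["Q", "Q", "Q", "D"])
        assert propose_mutation(self._candidate(aln, 1), aln) == "A1Q"

    def test_heterogeneous_background_falls_back_to_alanine(self):
        aln = make_alignment(["R", "R"], ["Q", "D", "K", "E", "S"])
        assert propose_mutation(self._candidate(aln, 1), aln) == "R1A"

    def test_background_equal_to_foreground_falls_back_to_alanine(self):
        aln = make_alignment(["R", "R"], ["R", "R", "R"])
        assert propose_mutation(self._candidate(aln, 1), aln) == "R1A"


class TestGroupVicinal:
    def _cands(self, positions):
        return [
            CandidateResidue(p, p, "A", "A", None, 1.0, 0.0, "identity")
            for p in positions
        ]

    def test_vicinal_pair_groups_together(self):
        groups = group_vicinal(self._cands([270, 272]))
        assert [[c.ref_number for c in g] for g in groups] == [[270, 272]]

    def test_distant_positions_stay_separate(self):
        groups = group_vicinal(self._cands([100, 200]))
        assert [[c.ref_number for c in g] for g in groups] == [[100], [200]]

    def test_long_run_splits_greedily_at_three(self):
        groups = group_vicinal(self._cands([10, 11, 12, 13]))
        assert [[c.ref_number for c in g] for g in groups] == [[10, 11, 12], [13]]


class TestEquivalentResidue:
    def test_direct_equivalence(self):
        aln = make_alignment(["MKRF", "MKRF"], ["MQRF", "MQRF"])
        assert map_equivalent_residue(aln, "fg1", 2, "bg1") == 2

    def test_gap_yields_sentinel_never_a_shifted_number(self):
        aln = make_alignment(["MKRF", "MKRF"], ["M-RF", "M-RF"])
        assert map_equivalent_residue(aln, "fg1", 2, "bg1") == GAPPED
        assert map_equivalent_residue(aln, "fg1", 3, "bg1") == 2

    def test_source_gap_is_an_error(self):
        aln = make_alignment(["M-RF", "MKRF"], ["MKRF", "MKRF"])
        with pytest.raises(IndexError):
            map_equivalent_residue(aln, "fg1", 4, "bg1")
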