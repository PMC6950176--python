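"""Folding engine: trivial structures, oracle equivalence, tree parsing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ltrmir.fold import (FoldSizeError, ScanFolder, brute_force_fold,
                         energy_of_structure, fold_mfe, fold_vienna,
                         pair_code, parse_structure, _pairs_from_dotbracket,
                         encode)


@pytest.mark.parametrize("seq,db,mfe", [
    ("AAAAAA", "......", 0.0),  # no legal pair
    ("A", ".", 0.0),
    ("GCGC", "....", 0.0),  # lone pair would close an illegal 2-loop
    ("GGGGAAAACCCC", "((((....))))", None),  # mfe checked against oracle
])
def test_folds_constrained_cases(seq, db, mfe):
    result = fold_mfe(seq)
    assert result.dot_bracket == db
    if mfe is not None:
        assert result.mfe == mfe
    assert result.mfe == brute_force_fold(seq).mfe


def test_rejects_empty_and_oversized():
    with pytest.raises(FoldSizeError):
        fold_mfe("")
    with pytest.raises(FoldSizeError):
        fold_mfe("A" * 501)
    with pytest.raises(FoldSizeError):
        brute_force_fold("A" * 25)


def test_dna_input_is_transcribed():
    result = fold_mfe("GGGGAAAACCCC".replace("U", "T"))
    assert "T" not in result.seq and result.seq.startswith("GGGG")


def test_oracle_equivalence_energy_and_tiebreak():
    """DP fold equals exhaustive enumeration, including the lexicographic
    co-optimal tie-break, on seeded random sequences."""
    rng = np.random.default_rng(42)
    for _ in range(60):
        n = int(rng.integers(10, 21))
        seq = "".join(rng.choice(list("ACGU"), size=n))
        dp, brute = fold_mfe(seq), brute_force_fold(seq)
        assert dp.mfe == brute.mfe
        assert dp.dot_bracket == brute.dot_bracket


def test_reported_energy_matches_structure_evaluation():
    rng = np.random.default_rng(7)
    for _ in range(10):
        seq = "".join(rng.choice(list("ACGU"), size=60))
        result = fold_mfe(seq)
        assert energy_of_structure(seq, result.dot_bracket) == result.mfe


def test_unpairable_tail_leaves_mfe_unchanged():
    """Exterior unpaired bases are free: a C-run appended to a G-free
    sequence cannot change the minimum."""
    rng = np.random.default_rng(3)
    for _ in range(5):
        seq = "".join(rng.choice(list("ACU"), size=40))
        assert fold_mfe(seq + "CCCCCC").mfe == fold_mfe(seq).mfe


def test_n_bases_never_pair():
    rng = np.random.default_rng(11)
    for _ in range(10):
        seq = "".join(rng.choice(list("ACGUN"), size=40, p=[.2, .2, .2, .2, .2]))
        enc = encode(seq)
        for (i, j) in fold_mfe(seq).pairs:
            assert enc[i] != 4 and enc[j] != 4
            assert pair_code(enc[i], enc[j]) != 0


def test_scanfolder_windows_match_standalone_folds():
    rng = np.random.default_rng(19)
    seq = "".join(rng.choice(list("ACGU"), size=200))
    folder = ScanFolder(seq, max_span=80)
    for s, e in [(0, 60), (40, 120), (100, 180), (17, 90)]:
        assert folder.fold_window(s, e).mfe == fold_mfe(seq[s:e]).mfe


# -- dot-bracket tree ------------------------------------------------------


@pytest.mark.parametrize("db,n_hairpins,n_multiloops,top_branches", [
    ("(((...)))", 1, 0, 1),
    ("(((((((...))))..((((...)))))))", 2, 1, 1),
    ("((...))((...))", 2, 0, 2),
    ("......", 0, 0, 0),
])
def test_tree_counts(db, n_hairpins, n_multiloops, top_branches):
    tree = parse_structure(db)
    assert tree.n_hairpins == n_hairpins
    assert tree.n_multiloops == n_multiloops
    assert len(tree.root.branches) == top_branches
    assert tree.serialize() == db


def test_basal_helix_and_helix_lengths():
    tree = parse_structure("(((((((...))))..((((...)))))))")
    assert sorted(tree.helix_lengths) == [3, 4, 4]


@pytest.mark.parametrize("bad,pos", [("(()", 0), ("())", 2), ("(.x)", 2)])
def test_unbalanced_or_invalid_reports_position(bad, pos):
    with pytest.raises(ValueError, match=f"position {pos}"):
        _pairs_from_dotbracket(bad)


@st.composite
def balanced_dotbracket(draw, max_leaves=5):
    def grow(depth):
        kind = draw(st.integers(0, 2 if depth < 4 else 1))
        if kind == 0:
            return "." * draw(st.integers(0, 4))
        if kind == 1:
            return "(" + ("." * draw(st.integers(3, 6))) + ")"
        return "(" + grow(depth + 1) + grow(depth + 1) + "..." + ")"
    return grow(0) + ("." * draw(st.integers(0, 3)))


@given(balanced_dotbracket())
@settings(max_examples=200, derandomize=True)
def test_parse_serialize_roundtrip(db):
    assert parse_structure(db).serialize() == db


def test_vienna_backend_agrees_on_dumbbell_classification(small_dataset):
    """Both folding backends call a planted precursor a two-hairpin
    structure (energies differ; topology must not)."""
    from ltrmir.dumbbell import TopologyConfig, classify_dumbbell
    from ltrmir.seqio import SeqRegion

    records, truth = small_dataset
    row = truth.iloc[0]
    rec = next(r for r in records if r.id == row.genome_id)
    window = SeqRegion(rec.id, int(row.dumbbell_start), int(row.dumbbell_end))
    sub = rec.seq[window.start:window.end]
    for result in (fold_mfe(sub), fold_vienna(sub)):
        call = classify_dumbbell(result, window, TopologyConfig())
        assert call.n_hairpins == 2
        assert call.passes_topology and call.passes_energy
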