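"""Synthetic fixture generator: determinism, planted-structure guarantees."""

import numpy as np
import pytest

from ltrmir.dumbbell import TopologyConfig, classify_dumbbell
from ltrmir.fold import fold_mfe, parse_structure
from ltrmir.scan import ScanConfig, scan_record
from ltrmir.seqio import SeqRecordT, SeqRegion
from ltrmir.synth import (SPAN_MAX, SPAN_MIN, PlantSpec, make_dataset,
                          make_records, plant_cassette, random_background)


def test_background_basics():
    assert random_background(0, 0.5, 1) == ""
    assert random_background(50, 0.4, 9) == random_background(50, 0.4, 9)
    with pytest.raises(ValueError):
        random_background(10, 1.5, 0)


def test_background_gc_within_binomial_bound():
    seq = random_background(10000, 0.4, rng_seed=7)
    gc = sum(c in "GC" for c in seq) / len(seq)
    sigma = (0.4 * 0.6 / 10000) ** 0.5
    assert abs(gc - 0.4) < 3 * sigma


def test_default_span_inside_reported_envelope():
    spec = PlantSpec()
    assert SPAN_MIN <= spec.span <= SPAN_MAX
    with pytest.raises(ValueError):
        plant_cassette("A" * 800, 300, PlantSpec(arm1_stem_bp=30, arm2_stem_bp=30))


def test_planted_dumbbell_folds_as_designed():
    """Isolated planted precursors reach two hairpins and <= -30 kcal/mol
    under the built-in model (the generation-time guarantee)."""
    bg = random_background(800, 0.4, rng_seed=2)
    for seed in (0, 1, 2):
        seq, truth = plant_cassette(bg, 300, PlantSpec(rng_seed=seed))
        db = seq[truth.dumbbell_start:truth.dumbbell_end]
        result = fold_mfe(db)
        tree = parse_structure(result.dot_bracket)
        assert tree.n_hairpins == 2
        assert result.mfe <= -30.0
        assert tree.paired_span == (0, len(db))
        assert truth.span == truth.dumbbell_end - truth.dumbbell_start


def test_planted_cassette_recovered_end_to_end():
    bg = random_background(800, 0.4, rng_seed=4)
    seq, truth = plant_cassette(bg, 300, PlantSpec(rng_seed=5))
    summary = scan_record(SeqRecordT(id="g", seq=seq), ScanConfig())
    assert summary.n_cassettes == 1
    cas = summary.cassettes[0]
    overlap = (min(cas.dumbbell.trim_end, truth.dumbbell_end)
               - max(cas.dumbbell.trim_start, truth.dumbbell_start))
    assert overlap >= 0.5 * truth.span
    assert cas.terminator.region.start >= cas.dumbbell.trim_end


def test_no_terminator_means_no_cassette():
    bg = random_background(800, 0.4, rng_seed=4)
    seq, truth = plant_cassette(bg, 300, PlantSpec(rng_seed=5,
                                                   with_terminator=False))
    # remove chance T-runs downstream so only the planted context matters
    chars = list(seq)
    for i in range(truth.dumbbell_end, min(len(seq), truth.dumbbell_end + 30)):
        if chars[i] == "T":
            chars[i] = "C"
    summary = scan_record(SeqRecordT(id="g", seq="".join(chars)), ScanConfig())
    assert summary.n_cassettes == 0


def test_planted_boxes_are_detected():
    bg = random_background(800, 0.4, rng_seed=8)
    seq, truth = plant_cassette(bg, 300, PlantSpec(rng_seed=9, with_bbox=True))
    assert truth.has_boxes and truth.bbox_start > 0
    summary = scan_record(SeqRecordT(id="g", seq=seq), ScanConfig())
    assert summary.n_cassettes == 1
    assert summary.cassettes[0].has_internal_boxes
    assert summary.n_box_cassettes == 1


def test_dataset_counts_and_determinism(tmp_path):
    records, truth = make_records(5, 1.0, rng_seed=17)
    assert len(records) == 5
    assert len(truth) >= 5
    _, truth_none = make_records(3, 0.0, rng_seed=1)
    assert len(truth_none) == 0
    f1, t1 = make_dataset(4, 1.0, rng_seed=17, out_dir=tmp_path / "a")
    f2, t2 = make_dataset(4, 1.0, rng_seed=17, out_dir=tmp_path / "b")
    assert f1.read_text() == f2.read_text()
    assert t1.read_text() == t2.read_text()


def test_truth_coordinates_consistent_with_sequence():
    records, truth = make_records(3, 1.0, rng_seed=23)
    by_id = {r.id: r for r in records}
    for _, row in truth.iterrows():
        seq = by_id[row.genome_id].seq
        assert seq[row.term_start:row.term_start + 5] == "TTTTT"
        assert seq[row.tata_start:row.tata_start + 7] == "TATAAAA"
        db = seq[row.dumbbell_start:row.dumbbell_end]
        call = classify_dumbbell(fold_mfe(db),
                                 SeqRegion(row.genome_id, int(row.dumbbell_start),
                                           int(row.dumbbell_end)),
                                 TopologyConfig())
        assert call.passes_topology and call.passes_energy
        assert (call.arm_regions[0].start, call.arm_regions[0].end) == \
            (row.arm1_start, row.arm1_end)
        assert (call.arm_regions[1].start, call.arm_regions[1].end) == \
            (row.arm2_start, row.arm2_end)
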