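"""Window sweep, deduplication, cassette assembly, genome summaries."""

import pytest

from ltrmir.dumbbell import DumbbellCall, dumbbell_span
from ltrmir.fold import FoldResult
from ltrmir.motifs import MotifHit
from ltrmir.scan import (Cassette, ScanConfig, assemble_cassettes,
                         generate_windows, merge_overlapping, scan_record,
                         scan_region, summarize_genome)
from ltrmir.seqio import SeqRecordT, SeqRegion
from ltrmir.synth import random_background


def _cfg(**kw):
    return ScanConfig().with_overrides(**kw)


# -- window generation -----------------------------------------------------


def test_single_exact_window():
    cfg = _cfg(window_min=100, window_max=100, window_step=5)
    wins = generate_windows(SeqRegion("s", 0, 100), cfg)
    assert wins == [SeqRegion("s", 0, 100)]


def test_region_shorter_than_window_min_gives_no_windows():
    cfg = _cfg(window_min=100)
    assert generate_windows(SeqRegion("s", 0, 99), cfg) == []


def test_window_sweep_matches_enumeration():
    cfg = _cfg(window_min=100, window_max=140, window_step=20)
    region = SeqRegion("s", 0, 150)
    wins = generate_windows(region, cfg)
    expected = [(i, i + w)
                for i in range(0, 151 - 100, 20)
                for w in (100, 120, 140) if i + w <= 150]
    expected.sort()
    assert [(w.start, w.end) for w in wins] == expected


# -- dedup ------------------------------------------------------------------


def _call(ts, te, mfe, seq_id="s", width=None):
    width = width or (te - ts + 10)
    window = SeqRegion(seq_id, max(0, ts - 5), max(0, ts - 5) + width)
    fold = FoldResult("A" * width, "." * width, mfe)
    return DumbbellCall(window=window, fold=fold, n_hairpins=2,
                        basal_helix_bp=2, arm_regions=(), loop_sizes=(2, 2),
                        passes_energy=True, passes_topology=True,
                        trim_start=ts, trim_end=te)


def test_merge_keeps_best_of_identical_spans():
    kept = merge_overlapping([_call(10, 100, -38.0), _call(10, 100, -45.0)])
    assert [c.mfe for c in kept] == [-45.0]


def test_merge_keeps_disjoint_calls():
    kept = merge_overlapping([_call(10, 100, -38.0), _call(200, 300, -45.0)])
    assert len(kept) == 2
    assert [c.trim_start for c in kept] == [10, 200]


def test_merge_chain_selects_outer_pair():
    """A-B-C where B overlaps both, A and C disjoint, MFE(A)<MFE(C)<MFE(B):
    the greedy rule keeps A and C."""
    a, b, c = _call(0, 100, -50.0), _call(80, 180, -35.0), _call(150, 250, -40.0)
    kept = merge_overlapping([b, a, c])
    assert [(k.trim_start, k.mfe) for k in kept] == [(0, -50.0), (150, -40.0)]


# -- assembly ---------------------------------------------------------------


def _hit(name, start, end, matched="X"):
    return MotifHit(name, SeqRegion("s", start, end), matched)


def test_assembly_requires_terminator_within_window():
    cfg = ScanConfig()
    call = _call(100, 220, -50.0)
    near = [_hit("TERM", 230, 235, "TTTTT"), _hit("TATA", 75, 82)]
    far = [_hit("TERM", 246, 251, "TTTTT"), _hit("TATA", 75, 82)]
    assert len(assemble_cassettes("", [call], near, cfg)) == 1
    assert assemble_cassettes("", [call], far, cfg) == []


def test_assembly_promoter_tata_or_internal_box():
    cfg = ScanConfig()
    call = _call(100, 220, -50.0)
    term = _hit("TERM", 225, 230, "TTTT")
    tata_ok = _hit("TATA", 75, 82)  # 25 nt upstream
    tata_close = _hit("TATA", 95, 102)  # 5 nt: below the 15 nt minimum
    bbox_in = _hit("BBOX", 150, 159)
    bbox_out = _hit("BBOX", 50, 59)
    assert len(assemble_cassettes("", [call], [term, tata_ok], cfg)) == 1
    assert assemble_cassettes("", [call], [term, tata_close], cfg) == []
    assert assemble_cassettes("", [call], [term], cfg) == []
    (cas,) = assemble_cassettes("", [call], [term, bbox_in], cfg)
    assert cas.has_internal_boxes and cas.n_internal_boxes == 1
    assert assemble_cassettes("", [call], [term, bbox_out], cfg) == []


def test_assembly_cassette_region_and_nearest_terminator():
    cfg = ScanConfig()
    call = _call(100, 220, -50.0)
    hits = [_hit("TATA", 75, 82), _hit("TERM", 240, 244, "TTTT"),
            _hit("TERM", 228, 233, "TTTTT")]
    (cas,) = assemble_cassettes("", [call], hits, cfg)
    assert cas.terminator.region.start == 228
    assert (cas.cassette_region.start, cas.cassette_region.end) == (75, 233)
    assert not cas.has_internal_boxes
    assert cas.score == -50.0


def test_summarize_counts_and_box_modes():
    def cas(n_boxes):
        c = _call(0, 100, -40.0)
        return Cassette(c, (), None, SeqRegion("s", 0, 100), n_boxes > 0,
                        n_boxes, -40.0)
    cassettes = [cas(0), cas(2), cas(1), cas(0)]
    s = summarize_genome("acc", cassettes)
    assert (s.n_cassettes, s.n_box_cassettes) == (4, 2)
    assert summarize_genome("acc", cassettes, "boxes").n_box_cassettes == 3
    empty = summarize_genome("acc", [])
    assert (empty.n_cassettes, empty.n_box_cassettes) == (0, 0)


# -- region/genome scans -----------------------------------------------------


def test_scan_region_finds_planted_dumbbell(small_dataset):
    records, truth = small_dataset
    row = truth.iloc[0]
    rec = next(r for r in records if r.id == row.genome_id)
    region = SeqRegion(rec.id, 0, len(rec.seq))
    calls = scan_region(rec.seq, region, ScanConfig())
    assert any(c.trim_start < row.dumbbell_end and row.dumbbell_start < c.trim_end
               for c in calls)
    mfes = [c.mfe for c in calls]
    assert all(m <= -30.0 for m in mfes)
    assert all(c.n_hairpins == 2 for c in calls)


def test_background_only_yields_no_cassettes():
    seq = random_background(600, 0.4, rng_seed=101)
    rec = SeqRecordT(id="bg", seq=seq)
    summary = scan_record(rec, ScanConfig())
    assert summary.n_cassettes == 0


def test_scan_is_deterministic(small_dataset):
    records, _ = small_dataset
    rec = records[0]
    s1 = scan_record(rec, ScanConfig())
    s2 = scan_record(rec, ScanConfig())
    key = lambda s: [(c.cassette_region.start, c.cassette_region.end, c.score,
                      c.dumbbell.fold.dot_bracket) for c in s.cassettes]
    assert key(s1) == key(s2)


def test_relaxing_energy_threshold_never_loses_cassettes(small_dataset):
    records, _ = small_dataset
    rec = records[1]
    strict = scan_record(rec, _cfg(mfe_max=-60.0))
    loose = scan_record(rec, _cfg(mfe_max=-30.0))
    assert loose.n_cassettes >= strict.n_cassettes


def test_ltr_features_restrict_scan(small_dataset):
    records, truth = small_dataset
    rec = records[0]
    rows = truth[truth.genome_id == rec.id]
    first = rows.iloc[0]
    # annotate only the first cassette's neighbourhood as the LTR
    lo = max(0, int(first.dumbbell_start) - 60)
    hi = min(len(rec.seq), int(first.dumbbell_end) + 40)
    annotated = SeqRecordT(id=rec.id, seq=rec.seq,
                           features=[("LTR", SeqRegion(rec.id, lo, hi))])
    summary = scan_record(annotated, ScanConfig())
    assert summary.n_cassettes == 1
    cas = summary.cassettes[0]
    assert lo <= cas.dumbbell.trim_start and cas.dumbbell.trim_end <= hi


def test_minus_strand_scan_mirrors_plus(small_dataset):
    from ltrmir.seqio import revcomp
    records, _ = small_dataset
    rec = records[2]
    plus = scan_record(rec, _cfg(strand="+"))
    flipped = SeqRecordT(id=rec.id, seq=revcomp(rec.seq))
    minus = scan_record(flipped, _cfg(strand="-"))
    L = len(rec.seq)
    mirrored = sorted((L - c.dumbbell.trim_end, L - c.dumbbell.trim_start,
                       round(c.score, 2)) for c in minus.cassettes)
    direct = sorted((c.dumbbell.trim_start, c.dumbbell.trim_end,
                     round(c.score, 2)) for c in plus.cassettes)
    assert mirrored == direct


def test_identical_ltr_copies_deduplicated(small_dataset):
    """A provirus carries the cassette in both LTR copies; the genome-wide
    count reports it once by default, twice when dedup is off."""
    records, truth = small_dataset
    rec = records[0]
    row = truth[truth.genome_id == rec.id].iloc[0]
    unit = rec.seq[:int(row.dumbbell_end) + 60]
    spacer = random_background(300, 0.4, rng_seed=55)
    provirus = SeqRecordT(id="prov", seq=unit + spacer + unit)
    dedup = scan_record(provirus, ScanConfig())
    full = scan_record(provirus, _cfg(dedup_identical=False))
    assert full.n_cassettes == 2 * dedup.n_cassettes


def test_config_file_and_overrides(tmp_path):
    p = tmp_path / "scan.cfg"
    p.write_text("mfe_max = -35\nwindow_step = 10\nbbox_max_mismatch = 0\n"
                 "single_hairpin_mode = false\n")
    cfg = ScanConfig.from_file(p)
    assert cfg.mfe_max == -35.0
    assert cfg.window_step == 10
    assert cfg.motifs["BBOX"].max_mismatch == 0
    with pytest.raises(ValueError):
        ScanConfig().with_overrides(no_such_key=1)
    with pytest.raises(ValueError):
        ScanConfig(window_step=0)
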