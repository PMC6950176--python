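"""Synthetic LTR-like fixtures with planted Pol III miRNA cassettes.

Generates random-background "LTR" sequences carrying planted cassettes --
an upstream TATA box, a GC-rich perfect-complement double hairpin whose
designed span falls in the 111-128 nt envelope, optional gene-internal A/B
boxes embedded in the stems, and a downstream poly-T terminator -- together
with a ground-truth table, so the whole detection pipeline is testable
without any external data.

Every planted dumbbell is verified at generation time: folded in isolation
with the built-in model it must form exactly two hairpin loops, pair from
its first to its last base, and reach an MFE at or below -30 kcal/mol;
failing draws are resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fold import fold_mfe, parse_structure
from .motifs import IUPAC
from .seqio import SeqRecordT, revcomp, write_fasta

_TATA_REALIZATION = "TATAAAA"
_TERMINATOR = "TTTTT"
_ABOX_LEN = 12
_BBOX_LEN = 9

SPAN_MIN, SPAN_MAX = 111, 128


@dataclass(frozen=True)
class PlantSpec:
    """Geometry and context of one planted cassette.

    Defaults give a 114-126 nt dumbbell (two 22-25 bp GC-rich arms with 8 nt
    loops on a 4 bp basal helix), a TATA box 25 nt upstream, and a T5
    terminator 10 nt downstream -- the size class and Pol III context the
    detector is built for.
    """

    arm1_stem_bp: int = 25
    arm2_stem_bp: int = 25
    loop1: int = 8
    loop2: int = 8
    basal_bp: int = 4
    spacer: int = 2
    gc_stem_fraction: float = 0.7
    with_tata: bool = True
    with_abox: bool = False
    with_bbox: bool = False
    with_terminator: bool = True
    tata_offset: int = 25  # nt from TATA start to dumbbell 5' edge
    term_offset: int = 10  # nt from dumbbell 3' edge to terminator start
    rng_seed: int = 0

    @property
    def span(self) -> int:
        return (2 * self.basal_bp + 2 * self.arm1_stem_bp + self.loop1
                + self.spacer + 2 * self.arm2_stem_bp + self.loop2)


@dataclass
class TruthRecord:
    """Ground-truth coordinates of one planted cassette (0-based half-open)."""

    genome_id: str
    dumbbell_start: int
    dumbbell_end: int
    span: int
    arm1_start: int
    arm1_end: int
    arm2_start: int
    arm2_end: int
    tata_start: int  # -1 if absent
    abox_start: int
    bbox_start: int
    term_start: int
    has_boxes: bool
    designed_mfe: float


def random_background(length: int, gc_fraction: float = 0.4,
                      rng_seed: int | np.random.Generator = 0) -> str:
    """I.i.d. DNA at the given GC fraction; reproducible per seed."""
    if length < 0 or not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("invalid background parameters")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    at, gc = (1 - gc_fraction) / 2, gc_fraction / 2
    return "".join(rng.choice(list("ACGT"), size=length, p=[at, gc, gc, at]))


def _weighted_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    at = (1 - gc) / 2
    return "".join(rng.choice(list("ACGT"), size=length, p=[at, gc / 2, gc / 2, at]))


def _loop_seq(rng: np.random.Generator, length: int) -> str:
    # A/C-only loops cannot pair with each other, keeping loops open
    return "".join(rng.choice(list("AC"), size=length, p=[0.7, 0.3]))


def _realize(rng: np.random.Generator, consensus: str) -> str:
    """One concrete sequence matching an IUPAC consensus (GC-biased Ns)."""
    out = []
    for c in consensus:
        allowed = IUPAC[c]
        strong = [b for b in allowed if b in "GC"]
        pool = strong if strong and len(allowed) > 1 else allowed
        out.append(pool[rng.integers(len(pool))])
    return "".join(out)


def _build_dumbbell(rng: np.random.Generator, spec: PlantSpec) -> tuple[str, dict]:
    basal = _weighted_seq(rng, spec.basal_bp, spec.gc_stem_fraction)
    stem1 = _weighted_seq(rng, spec.arm1_stem_bp, spec.gc_stem_fraction)
    stem2 = _weighted_seq(rng, spec.arm2_stem_bp, spec.gc_stem_fraction)
    abox_off = bbox_off = -1
    if spec.with_abox:
        from .motifs import default_motif_specs
        box = _realize(rng, default_motif_specs()["ABOX"].consensus)
        stem1 = stem1[:2] + box + stem1[2 + _ABOX_LEN:]
        abox_off = 2
    if spec.with_bbox:
        from .motifs import default_motif_specs
        box = _realize(rng, default_motif_specs()["BBOX"].consensus)
        stem2 = stem2[:2] + box + stem2[2 + _BBOX_LEN:]
        bbox_off = 2
    arm1 = stem1 + _loop_seq(rng, spec.loop1) + revcomp(stem1)
    arm2 = stem2 + _loop_seq(rng, spec.loop2) + revcomp(stem2)
    spacer = _loop_seq(rng, spec.spacer)
    seq = basal + arm1 + spacer + arm2 + revcomp(basal)
    layout = {
        "arm1_start": spec.basal_bp,
        "arm1_end": spec.basal_bp + len(arm1),
        "arm2_start": spec.basal_bp + len(arm1) + spec.spacer,
        "arm2_end": spec.basal_bp + len(arm1) + spec.spacer + len(arm2),
        "abox_start": spec.basal_bp + abox_off if abox_off >= 0 else -1,
        "bbox_start": (spec.basal_bp + len(arm1) + spec.spacer + bbox_off
                       if bbox_off >= 0 else -1),
    }
    return seq, layout


def plant_cassette(background: str, position: int,
                   spec: PlantSpec) -> tuple[str, TruthRecord]:
    """Overwrite ``background`` with a cassette whose dumbbell starts at
    ``position``; returns the new sequence and the truth record.

    The dumbbell is redrawn (new stems/loops from the spec's RNG stream)
    until the built-in folder confirms the designed topology: exactly two
    hairpins, fully paired ends, MFE <= -30 kcal/mol.
    """
    if not SPAN_MIN <= spec.span <= SPAN_MAX:
        raise ValueError(
            f"designed dumbbell span {spec.span} outside [{SPAN_MIN}, {SPAN_MAX}]")
    rng = np.random.default_rng(spec.rng_seed)
    grow = spec
    for attempt in range(60):
        db_seq, layout = _build_dumbbell(rng, grow)
        result = fold_mfe(db_seq)
        tree = parse_structure(result.dot_bracket)
        if (tree.n_hairpins == 2 and result.mfe <= -30.0
                and tree.paired_span == (0, len(db_seq))):
            break
        if attempt == 30:  # stubborn draw: push stem GC up a notch
            grow = replace(grow, gc_stem_fraction=min(0.9, grow.gc_stem_fraction + 0.1))
    else:
        raise RuntimeError("could not realize a stable planted dumbbell")

    end = position + len(db_seq)
    tata_start = position - spec.tata_offset if spec.with_tata else -1
    term_start = end + spec.term_offset if spec.with_terminator else -1
    if position < 0 or end > len(background):
        raise IndexError("cassette does not fit at the requested position")
    if spec.with_tata and tata_start < 0:
        raise IndexError("no room for the upstream TATA box")
    if spec.with_terminator and term_start + len(_TERMINATOR) + 1 > len(background):
        raise IndexError("no room for the downstream terminator")

    chars = list(background)
    chars[position:end] = db_seq
    if spec.with_tata:
        chars[tata_start:tata_start + len(_TATA_REALIZATION)] = _TATA_REALIZATION
    if spec.with_terminator:
        chars[term_start:term_start + len(_TERMINATOR)] = _TERMINATOR
        # keep the planted run maximal exactly as recorded
        if term_start > 0 and chars[term_start - 1] == "T":
            chars[term_start - 1] = "C"
        after = term_start + len(_TERMINATOR)
        if after < len(chars) and chars[after] == "T":
            chars[after] = "C"
    truth = TruthRecord(
        genome_id="", dumbbell_start=position, dumbbell_end=end,
        span=len(db_seq),
        arm1_start=position + layout["arm1_start"],
        arm1_end=position + layout["arm1_end"],
        arm2_start=position + layout["arm2_start"],
        arm2_end=position + layout["arm2_end"],
        tata_start=tata_start,
        abox_start=position + layout["abox_start"] if layout["abox_start"] >= 0 else -1,
        bbox_start=position + layout["bbox_start"] if layout["bbox_start"] >= 0 else -1,
        term_start=term_start,
        has_boxes=layout["abox_start"] >= 0 or layout["bbox_start"] >= 0,
        designed_mfe=result.mfe,
    )
    return "".join(chars), truth


DEFAULT_SPEC_RANGES = {
    "arm_stem_bp": (22, 25),  # inclusive; keeps spans inside 111-128 nt
    "tata_offset": (18, 35),
    "term_offset": (3, 15),
    "box_probability": 0.4,
}


def make_records(n_genomes: int, plant_probability: float = 1.0,
                 spec_ranges: Optional[dict] = None, rng_seed: int = 17,
                 genome_length: int = 800, gc_background: float = 0.4,
                 ) -> tuple[list[SeqRecordT], pd.DataFrame]:
    """Generate synthetic genomes plus their truth table, in memory.

    Each genome carries Binomial(2, plant_probability) cassettes, one per
    genome half, with randomized arm sizes, element offsets, and optional
    internal boxes.  Fully reproducible per seed.
    """
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    ranges = {**DEFAULT_SPEC_RANGES, **(spec_ranges or {})}
    rng = np.random.default_rng(rng_seed)
    records: list[SeqRecordT] = []
    rows: list[TruthRecord] = []
    for g in range(n_genomes):
        name = f"syn{g:03d}"
        seq = random_background(genome_length, gc_background, rng)
        n_plant = int(rng.binomial(2, plant_probability))
        half = genome_length // 2
        slots = [(60, half - 240), (half + 60, genome_length - 240)]
        for slot in range(n_plant):
            lo, hi = slots[slot]
            a_lo, a_hi = ranges["arm_stem_bp"]
            spec = PlantSpec(
                arm1_stem_bp=int(rng.integers(a_lo, a_hi + 1)),
                arm2_stem_bp=int(rng.integers(a_lo, a_hi + 1)),
                with_abox=bool(rng.random() < ranges["box_probability"]),
                with_bbox=bool(rng.random() < ranges["box_probability"]),
                tata_offset=int(rng.integers(*ranges["tata_offset"])),
                term_offset=int(rng.integers(*ranges["term_offset"])),
                rng_seed=int(rng.integers(0, 2**31 - 1)),
            )
            position = int(rng.integers(lo, hi))
            seq, truth = plant_cassette(seq, position, spec)
            truth.genome_id = name
            rows.append(truth)
        records.append(SeqRecordT(id=name, seq=seq,
                                  description=f"synthetic LTR {g}"))
    columns = list(TruthRecord.__dataclass_fields__)
    truth_df = (pd.DataFrame([vars(r) for r in rows], columns=columns)
                if rows else pd.DataFrame(columns=columns))
    return records, truth_df


def make_dataset(n_genomes: int, plant_probability: float = 1.0,
                 spec_ranges: Optional[dict] = None, rng_seed: int = 17,
                 out_dir: str | Path = ".", **kwargs) -> tuple[Path, Path]:
    """Write a synthetic dataset to ``out_dir``; returns (FASTA, truth TSV)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, truth = make_records(n_genomes, plant_probability, spec_ranges,
                                  rng_seed, **kwargs)
    fasta_path = out_dir / "synthetic.fasta"
    truth_path = out_dir / "truth.tsv"
    write_fasta(records, fasta_path)
    truth.to_csv(truth_path, sep="\t", index=False)
    return fasta_path, truth_path


def write_genbank(record: SeqRecordT, path) -> None:
    """Write a record (with its LTR features) as a GenBank flat file."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    rec = SeqRecord(Seq(record.seq), id=record.id, name=record.id.split(".")[0],
                    description=record.description or record.id)
    rec.annotations["molecule_type"] = "DNA"
    for kind, region in record.features:
        rec.features.append(SeqFeature(
            FeatureLocation(region.start, region.end,
                            strand=-1 if region.strand == "-" else 1),
            type=kind))
    from Bio import SeqIO
    SeqIO.write([rec], str(path), "genbank")


def evaluate_against_truth(summaries: Sequence, truth: pd.DataFrame,
                           min_overlap: float = 0.5) -> dict:
    """Compare scan results to the planted truth table.

    A planted cassette counts as recovered when a reported cassette's
    trimmed dumbbell span overlaps at least ``min_overlap`` of the planted
    span; reported cassettes overlapping no planted span are false calls.
    """
    truth_by_genome: dict[str, list[tuple[int, int]]] = {}
    for _, row in truth.iterrows():
        truth_by_genome.setdefault(row["genome_id"], []).append(
            (int(row["dumbbell_start"]), int(row["dumbbell_end"])))
    n_planted = int(len(truth))
    recovered = 0
    false_calls = 0
    for summary in summaries:
        planted = truth_by_genome.get(summary.accession, [])
        matched = [False] * len(planted)
        for cas in summary.cassettes:
            ts, te = cas.dumbbell.trim_start, cas.dumbbell.trim_end
            hit = False
            for idx, (ds, de) in enumerate(planted):
                ov = min(te, de) - max(ts, ds)
                if ov >= min_overlap * (de - ds):
                    matched[idx] = True
                    hit = True
            if not hit:
                false_calls += 1
        recovered += sum(matched)
    n_genomes = len(summaries)
    return {
        "n_planted": n_planted,
        "n_recovered": recovered,
        "sensitivity": recovered / n_planted if n_planted else float("nan"),
        "n_false": false_calls,
        "false_per_genome": false_calls / n_genomes if n_genomes else float("nan"),
    }
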