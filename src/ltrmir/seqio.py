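"""Sequence and annotation I/O.

Reads FASTA and GenBank records (via Biopython), BED region lists, and
writes cassette annotations as GFF3 plus per-genome summary tables as TSV.

Coordinate conventions: all in-memory intervals are 0-based half-open on a
named sequence (``SeqRegion``); GFF3 output is 1-based inclusive; BED input
is 0-based half-open.  Sequences are normalized on read: uppercased, U -> T,
with N permitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Optional

from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from .scan import Cassette, GenomeSummary

_ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Malformed input file (bad FASTA characters, missing GenBank ORIGIN)."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeqRegion:
    """Strand-aware half-open interval [start, end) on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid region [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "SeqRegion") -> bool:
        return (self.seq_id == other.seq_id
                and self.start < other.end and other.start < self.end)

    def contains(self, other: "SeqRegion") -> bool:
        return (self.seq_id == other.seq_id
                and self.start <= other.start and other.end <= self.end)


@dataclass
class SeqRecordT:
    """A normalized DNA record with optional LTR/repeat annotations."""

    id: str
    seq: str
    description: str = ""
    features: list[tuple[str, SeqRegion]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.seq)


def normalize_seq(raw: str, record_id: str = "?") -> str:
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _ALPHABET
    if bad:
        raise FormatError(
            f"record {record_id!r}: invalid sequence character {sorted(bad)[0]!r}")
    return seq


def read_fasta(path) -> list[SeqRecordT]:
    """Read a FASTA file into normalized records, preserving order."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SeqRecordT(
            id=rec.id,
            seq=normalize_seq(str(rec.seq), rec.id),
            description=rec.description,
        ))
    return records


def read_genbank(path) -> SeqRecordT:
    """Read a GenBank flat file; id is ACCESSION.VERSION when available.

    Features keyed ``LTR`` or ``repeat_region`` are kept, converted from
    GenBank 1-based inclusive to 0-based half-open coordinates (Biopython
    already stores them half-open).
    """
    try:
        rec = next(SeqIO.parse(str(path), "genbank"))
    except StopIteration:
        raise FormatError(f"{path}: no GenBank record found") from None
    except ValueError as exc:
        raise FormatError(f"{path}: malformed GenBank record: {exc}") from None
    try:
        seq = str(rec.seq)
    except Exception:
        raise FormatError(f"{path}: GenBank record has no ORIGIN sequence") from None
    if not seq:
        raise FormatError(f"{path}: GenBank record has no ORIGIN sequence")
    features = []
    for feat in rec.features:
        if feat.type in ("LTR", "repeat_region"):
            strand = "-" if feat.location.strand == -1 else "+"
            features.append((feat.type, SeqRegion(
                rec.id, int(feat.location.start), int(feat.location.end), strand)))
    return SeqRecordT(id=rec.id, seq=normalize_seq(seq, rec.id),
                      description=rec.description, features=features)


def read_bed(path) -> list[SeqRegion]:
    """Read BED (>= 3 columns; strand from column 6 when present)."""
    regions = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{line_no}: BED line has < 3 columns")
            strand = parts[5] if len(parts) >= 6 and parts[5] in "+-" else "+"
            regions.append(SeqRegion(parts[0], int(parts[1]), int(parts[2]), strand))
    return regions


def extract_region(record: SeqRecordT, region: SeqRegion) -> str:
    """Substring [start, end), reverse-complemented for '-' strand."""
    if region.start < 0 or region.end > len(record.seq):
        raise IndexError(
            f"region [{region.start}, {region.end}) outside record "
            f"{record.id!r} of length {len(record.seq)}")
    sub = record.seq[region.start:region.end]
    return revcomp(sub) if region.strand == "-" else sub


def write_fasta(records: Iterable[SeqRecordT], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id \
                else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), 70):
                fh.write(rec.seq[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# outputs
# ---------------------------------------------------------------------------

_GFF_CHILD_TYPES = {"TATA": "TATA_box", "ABOX": "A_box", "BBOX": "B_box",
                    "TERM": "terminator"}


def _gff_line(seq_id: str, ftype: str, region: SeqRegion, score: str,
              attrs: str) -> str:
    return "\t".join([seq_id, "ltrmir", ftype, str(region.start + 1),
                      str(region.end), score, region.strand, ".", attrs])


def write_gff3(cassettes: "Iterable[Cassette]", path) -> None:
    """GFF3 with one ``pri_miRNA_cassette`` parent per cassette and child
    features for promoter elements, terminator, and the two stem-loops.
    Score column carries the dumbbell MFE in kcal/mol."""
    lines = ["##gff-version 3"]
    for idx, cas in enumerate(cassettes, 1):
        cid = f"cassette{idx:03d}"
        seq_id = cas.cassette_region.seq_id
        mfe = f"{cas.dumbbell.fold.mfe:.2f}"
        lines.append(_gff_line(seq_id, "pri_miRNA_cassette", cas.cassette_region,
                               mfe, f"ID={cid}"))
        for hit in cas.promoter_hits:
            ftype = _GFF_CHILD_TYPES[hit.spec_name]
            lines.append(_gff_line(seq_id, ftype, hit.region, ".",
                                   f"Parent={cid}"))
        if cas.terminator is not None:
            lines.append(_gff_line(seq_id, "terminator", cas.terminator.region,
                                   ".", f"Parent={cid}"))
        for arm in cas.dumbbell.arm_regions:
            lines.append(_gff_line(seq_id, "stem_loop", arm, ".",
                                   f"Parent={cid}"))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path) -> list[tuple[str, str, SeqRegion, Optional[float]]]:
    """Re-parse GFF3 written by :func:`write_gff3` back into 0-based regions.

    Returns (feature_type, attributes, region, score) tuples; used for
    round-trip verification and downstream tooling.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}: GFF3 line with {len(cols)} columns")
            region = SeqRegion(cols[0], int(cols[3]) - 1, int(cols[4]), cols[6])
            score = None if cols[5] == "." else float(cols[5])
            out.append((cols[2], cols[8], region, score))
    return out


def write_summary_tsv(summaries: "Iterable[GenomeSummary]", path) -> None:
    """TSV with the two reported per-genome columns: cassette count and
    box-bearing cassette count."""
    with open(path, "w") as fh:
        fh.write("accession\tn_cassettes\tn_box_cassettes\n")
        for s in summaries:
            fh.write(f"{s.accession}\t{s.n_cassettes}\t{s.n_box_cassettes}\n")


def write_outputs(cassettes: "Iterable[Cassette]",
                  summaries: "Iterable[GenomeSummary]",
                  gff_path, tsv_path) -> None:
    """Write the GFF3 annotation and the per-genome summary table."""
    write_gff3(cassettes, gff_path)
    write_summary_tsv(summaries, tsv_path)
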