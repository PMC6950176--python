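"""IUPAC consensus scanning for RNA Pol III promoter and terminator elements.

The cassette scanner needs four element classes: an upstream TATA box
(external type-3 promoter), gene-internal A- and B-boxes (type-2 promoter,
as in tRNA genes), and the Pol III terminator, a run of >= 4 T residues on
the coding strand.  Boxes are matched against IUPAC consensus strings with a
per-motif mismatch budget; terminators are maximal T-runs.

An ``N`` in the subject sequence never matches a non-N consensus symbol:
ambiguity in the data is counted as a mismatch, only ambiguity in the
consensus is permissive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .seqio import SeqRegion, revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGTN",
}

_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
    "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N",
}


class MotifConfigError(ValueError):
    """Invalid motif specification (bad consensus alphabet, bad run length)."""


@dataclass(frozen=True)
class MotifSpec:
    """A named consensus element with a mismatch budget.

    ``TERM`` specs carry ``min_run`` (minimum T-run length) instead of a
    consensus; all other specs match an IUPAC string.
    """

    name: str
    consensus: str = ""
    max_mismatch: int = 0
    min_run: int = 0

    def __post_init__(self):
        if self.name == "TERM":
            if self.min_run < 4:
                raise MotifConfigError(
                    f"terminator min_run must be >= 4 (Pol III termination), got {self.min_run}")
            return
        if not self.consensus:
            raise MotifConfigError(f"motif {self.name!r} has an empty consensus")
        bad = [c for c in self.consensus if c not in IUPAC]
        if bad:
            raise MotifConfigError(
                f"motif {self.name!r}: invalid IUPAC character {bad[0]!r}")
        if not 0 <= self.max_mismatch < len(self.consensus):
            raise MotifConfigError(
                f"motif {self.name!r}: max_mismatch {self.max_mismatch} out of range")


@dataclass(frozen=True)
class MotifHit:
    """A located element: spec name, genomic region, matched text, mismatches."""

    spec_name: str
    region: SeqRegion
    matched: str
    mismatches: int = 0


def revcomp_consensus(consensus: str) -> str:
    """Reverse complement of an IUPAC consensus (R<->Y, K<->M, etc.)."""
    return "".join(_IUPAC_COMPLEMENT[c] for c in reversed(consensus))


def default_motif_specs() -> dict[str, MotifSpec]:
    """Calibration defaults: canonical TATA (exact) plus degenerate tRNA-style
    A/B boxes with one mismatch allowed, and a >=4 T terminator."""
    return {
        "TATA": MotifSpec("TATA", "TATAWAW", max_mismatch=0),
        "ABOX": MotifSpec("ABOX", "TRGCNNARYNNG", max_mismatch=1),
        "BBOX": MotifSpec("BBOX", "GTTCRANNC", max_mismatch=1),
        "TERM": MotifSpec("TERM", min_run=4),
    }


def scan_consensus(seq: str, spec: MotifSpec, seq_id: str = "",
                   offset: int = 0, strand: str = "+") -> list[MotifHit]:
    """All windows of ``seq`` matching ``spec.consensus`` within the budget.

    ``offset`` shifts reported coordinates so region-local scans can emit
    genome coordinates.  N in the subject counts as a mismatch against any
    non-N consensus symbol.
    """
    if spec.name == "TERM":
        raise MotifConfigError("TERM specs are scanned with find_terminators")
    m = len(spec.consensus)
    allowed = [IUPAC[c] for c in spec.consensus]
    hits: list[MotifHit] = []
    for start in range(0, len(seq) - m + 1):
        window = seq[start:start + m]
        mismatches = sum(1 for c, ok in zip(window, allowed) if c not in ok)
        if mismatches <= spec.max_mismatch:
            region = SeqRegion(seq_id, offset + start, offset + start + m, strand)
            hits.append(MotifHit(spec.name, region, window, mismatches))
    return hits


def find_terminators(seq: str, min_run: int = 4, seq_id: str = "",
                     offset: int = 0, strand: str = "+") -> list[MotifHit]:
    """Maximal runs of >= ``min_run`` consecutive T, one hit per run."""
    if min_run < 4:
        raise MotifConfigError(
            f"terminator min_run must be >= 4, got {min_run}")
    hits: list[MotifHit] = []
    i, n = 0, len(seq)
    while i < n:
        if seq[i] == "T":
            j = i
            while j < n and seq[j] == "T":
                j += 1
            if j - i >= min_run:
                region = SeqRegion(seq_id, offset + i, offset + j, strand)
                hits.append(MotifHit("TERM", region, seq[i:j], 0))
            i = j
        else:
            i += 1
    return hits


def scan_all_motifs(seq: str, specs: Iterable[MotifSpec] | dict[str, MotifSpec],
                    seq_id: str = "", offset: int = 0,
                    strand: str = "+") -> list[MotifHit]:
    """Union of consensus hits and terminator runs, sorted by (start, name)."""
    if isinstance(specs, dict):
        specs = specs.values()
    hits: list[MotifHit] = []
    for spec in specs:
        if spec.name == "TERM":
            hits.extend(find_terminators(seq, spec.min_run, seq_id, offset, strand))
        else:
            hits.extend(scan_consensus(seq, spec, seq_id, offset, strand))
    hits.sort(key=lambda h: (h.region.start, h.spec_name))
    return hits
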