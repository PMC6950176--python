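"""Candidate mature miRNA arms and seed-identity matching.

Mature FV miRNAs derive from the two stem-loops of the dumbbell precursor,
with the high-abundance species on the 5' strand of each stem-loop.  Without
modeling Dicer cleavage, candidate arms are fixed-length slices anchored at
the ends of each stem-loop: the 5p arm is the first ``arm_length`` nt of the
arm region, the 3p arm the last.  The seed is the canonical miRNA seed,
nucleotides 2-8 (a 7-mer); two miRNAs "share seed identity" when those
7-mers are equal.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Sequence

from .dumbbell import DumbbellCall
from .fold import to_rna


@dataclass(frozen=True)
class ArmConfig:
    arm_length: int = 22
    seed_start: int = 1  # 0-based; canonical seed is positions 2-8
    seed_length: int = 7

    def __post_init__(self):
        if self.arm_length < self.seed_start + self.seed_length:
            raise ValueError("arm_length too short to carry a seed")


@dataclass(frozen=True)
class MatureArm:
    """A candidate mature arm: hairpin 1 or 2, 5p or 3p strand."""

    cassette_id: str
    hairpin_index: int  # 1 or 2
    arm: str  # 5p or 3p
    seq: str  # RNA
    seed: str  # RNA 7-mer (positions 2-8)
    short: bool = False  # arm region shorter than the requested length

    @property
    def name(self) -> str:
        return f"{self.cassette_id}-h{self.hairpin_index}-{self.arm}"


@dataclass(frozen=True)
class SeedMatch:
    arm: MatureArm
    host_mirna_name: str
    host_seed: str


def seed_of(seq: str, config: ArmConfig = ArmConfig()) -> str:
    """Seed 7-mer at canonical positions 2-8 (0-based [1, 8))."""
    seq = to_rna(seq)
    end = config.seed_start + config.seed_length
    if len(seq) < end:
        raise ValueError(f"sequence of {len(seq)} nt too short for a seed "
                         f"(need >= {end})")
    return seq[config.seed_start:end]


def extract_arms(seq: str, call: DumbbellCall, config: ArmConfig = ArmConfig(),
                 cassette_id: str = "cassette") -> list[MatureArm]:
    """5p and 3p candidate arms of each stem-loop of a dumbbell call.

    ``seq`` is the full sequence the call's coordinates refer to.  Arms are
    emitted in transcript order: h1-5p, h1-3p, h2-5p, h2-3p; DNA input is
    transcribed to RNA.  Arm regions shorter than ``arm_length`` yield
    clipped arms flagged ``short``.
    """
    if not call.passes_topology:
        raise RuntimeError("extract_arms requires a call that passes topology")
    arms: list[MatureArm] = []
    for index, region in enumerate(call.arm_regions, start=1):
        arm_seq = to_rna(seq[region.start:region.end])
        n = min(config.arm_length, len(arm_seq))
        short = n < config.arm_length
        for arm_name, piece in (("5p", arm_seq[:n]), ("3p", arm_seq[-n:])):
            arms.append(MatureArm(
                cassette_id=cassette_id, hairpin_index=index, arm=arm_name,
                seq=piece, seed=seed_of(piece, config), short=short,
            ))
    return arms


def match_seeds(arms: Sequence[MatureArm],
                host_catalog: Sequence[tuple[str, str]],
                config: ArmConfig = ArmConfig()) -> list[SeedMatch]:
    """Exact seed-identity matches between arms and a mature-miRNA catalog.

    ``host_catalog`` holds (name, mature RNA sequence) pairs, e.g. parsed
    from a miRBase-style FASTA.  All matching pairs are reported, sorted by
    arm name then catalog name.
    """
    by_seed: dict[str, list[tuple[str, str]]] = defaultdict(list)
    for name, mature in host_catalog:
        by_seed[seed_of(mature, config)].append((name, mature))
    matches: list[SeedMatch] = []
    for arm in arms:
        for name, _ in by_seed.get(arm.seed, ()):
            matches.append(SeedMatch(arm=arm, host_mirna_name=name,
                                     host_seed=arm.seed))
    matches.sort(key=lambda m: (m.arm.name, m.arm.arm, m.host_mirna_name))
    return matches


def read_mature_fasta(path) -> list[tuple[str, str]]:
    """Parse a miRBase-dialect mature FASTA into (name, RNA seq) pairs."""
    from Bio import SeqIO

    catalog = []
    for rec in SeqIO.parse(str(path), "fasta"):
        catalog.append((rec.id, to_rna(str(rec.seq))))
    return catalog
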