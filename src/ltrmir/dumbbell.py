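"""Dumbbell topology classification of folded windows.

A dumbbell-shaped pri-miRNA folds into exactly two stem-loops, optionally
carried on a short basal helix (two arms branching either from the exterior
loop or from a single two-branch multiloop).  Classification is performed on
the trimmed structure -- unpaired flanking bases of the window are ignored --
so calls are invariant to how much background a scan window happens to
include around the structured core.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .fold import FoldResult, Hairpin, Helix, Interior, Multiloop, parse_structure
from .seqio import SeqRegion


@dataclass(frozen=True)
class TopologyConfig:
    """Thresholds defining an acceptable dumbbell.

    mfe_max: energy cutoff in kcal/mol (a window passes if MFE <= mfe_max).
    min_arm_stem_bp: minimum total base pairs on the path from the branch
        point to each hairpin loop (helix interruptions are aggregated).
    min_basal_helix_bp: minimum pairs in the shared closing stem (0 = the
        basal helix is optional, the two arms may sit on the exterior loop).
    min_paired_fraction: minimum fraction of paired bases over the trimmed
        span; guards against two tiny hairpins in a mostly open window.
    single_hairpin_mode: accept exactly one stem-loop instead of two
        (the BLV-style cassette variant).
    """

    mfe_max: float = -30.0
    min_arm_stem_bp: int = 8
    min_basal_helix_bp: int = 0
    min_paired_fraction: float = 0.5
    single_hairpin_mode: bool = False

    def __post_init__(self):
        if self.mfe_max >= 0:
            raise ValueError("mfe_max must be negative")
        if self.min_arm_stem_bp < 1:
            raise ValueError("min_arm_stem_bp must be >= 1")


@dataclass
class DumbbellCall:
    """Result of classifying one folded window."""

    window: SeqRegion
    fold: FoldResult
    n_hairpins: int
    basal_helix_bp: int
    arm_regions: tuple[SeqRegion, ...]
    loop_sizes: tuple[int, ...]
    passes_energy: bool
    passes_topology: bool
    trim_start: int  # absolute coordinate of first paired base
    trim_end: int  # absolute, exclusive, last paired base + 1

    @property
    def mfe(self) -> float:
        return self.fold.mfe

    @property
    def span(self) -> Optional[SeqRegion]:
        if self.trim_end <= self.trim_start:
            return None
        return SeqRegion(self.window.seq_id, self.trim_start, self.trim_end,
                         self.window.strand)


def _chain_to_branch(helix: Helix) -> tuple[int, Helix]:
    """Follow a linear helix/interior chain; return (total bp, last helix)."""
    bp = helix.length
    while isinstance(helix.child, Interior):
        helix = helix.child.inner
        bp += helix.length
    return bp, helix


def _arm_stats(helix: Helix) -> Optional[tuple[int, int]]:
    """(total stem bp, hairpin loop size) for a linear arm, else None."""
    bp, last = _chain_to_branch(helix)
    if isinstance(last.child, Hairpin):
        return bp, last.child.size
    return None


def classify_dumbbell(fold: FoldResult, window: SeqRegion,
                      config: TopologyConfig) -> DumbbellCall:
    """Classify a folded window as dumbbell (or single hairpin) or not.

    Total on any valid :class:`FoldResult`; never raises.
    """
    tree = parse_structure(fold.dot_bracket)
    n_hairpins = tree.n_hairpins
    passes_energy = fold.mfe <= config.mfe_max

    span = tree.paired_span
    if span is None:
        return DumbbellCall(window, fold, 0, 0, (), (), passes_energy, False,
                            window.start, window.start)
    trim_start = window.start + span[0]
    trim_end = window.start + span[1]
    span_len = span[1] - span[0]
    paired_fraction = 2 * tree.n_pairs / span_len

    basal_bp = 0
    arms: list[Helix] = []
    want = 1 if config.single_hairpin_mode else 2

    if n_hairpins == want:
        top = tree.root.branches
        if config.single_hairpin_mode:
            if len(top) == 1:
                arms = top
        elif len(top) == 2:
            arms = top  # two stem-loops directly on the exterior loop
        elif len(top) == 1:
            # descend the shared basal stem to the two-branch multiloop
            helix = top[0]
            basal_bp = helix.length
            while isinstance(helix.child, Interior):
                helix = helix.child.inner
                basal_bp += helix.length
            if isinstance(helix.child, Multiloop) and len(helix.child.branches) == 2:
                arms = helix.child.branches

    arm_regions: list[SeqRegion] = []
    loop_sizes: list[int] = []
    arm_bps: list[int] = []
    for arm in arms:
        stats = _arm_stats(arm)
        if stats is None:  # nested branching inside an arm: not a clean arm
            arm_regions, loop_sizes, arm_bps = [], [], []
            break
        bp, loop = stats
        i, j = arm.outer
        arm_regions.append(SeqRegion(window.seq_id, window.start + i,
                                     window.start + j + 1, window.strand))
        loop_sizes.append(loop)
        arm_bps.append(bp)

    passes_topology = (
        len(arm_regions) == want
        and all(bp >= config.min_arm_stem_bp for bp in arm_bps)
        and basal_bp >= config.min_basal_helix_bp
        and paired_fraction >= config.min_paired_fraction
    )

    return DumbbellCall(
        window=window, fold=fold, n_hairpins=n_hairpins,
        basal_helix_bp=basal_bp, arm_regions=tuple(arm_regions),
        loop_sizes=tuple(loop_sizes), passes_energy=passes_energy,
        passes_topology=passes_topology, trim_start=trim_start,
        trim_end=trim_end,
    )


def dumbbell_span(call: DumbbellCall) -> int:
    """Pri-miRNA size: nt from first to last paired base of the structure."""
    if not call.passes_topology:
        raise RuntimeError("dumbbell_span requires a call that passes topology")
    return call.trim_end - call.trim_start
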