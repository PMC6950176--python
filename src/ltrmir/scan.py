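"""Sliding-window cassette scanning.

Realizes the detection rule for Pol III dumbbell pri-miRNA cassettes: slide
windows of 100-140 nt across each target region, fold each window, keep
windows whose MFE is at or below the energy cutoff (default -30 kcal/mol)
and whose structure is a clean double stem-loop, deduplicate overlapping
candidates by best energy, then require the Pol III context -- a T-run
terminator starting within a short distance downstream of the structure and
either an upstream TATA box or at least one gene-internal A/B box.  The
per-genome outcome is the cassette count and the count of box-bearing
cassettes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Optional, Sequence

from . import fold as _fold
from .dumbbell import DumbbellCall, TopologyConfig, classify_dumbbell
from .motifs import MotifHit, MotifSpec, default_motif_specs, scan_all_motifs
from .seqio import SeqRecordT, SeqRegion, extract_region, revcomp


@dataclass(frozen=True)
class ScanConfig:
    """Full parameterization of a cassette scan.

    Windows bracket the ~130 nt dumbbell size class; the TATA box is
    accepted 15-40 nt upstream of the trimmed structure's 5' edge, the
    terminator within 25 nt downstream of its 3' edge.  All values are
    overridable from the CLI or a key=value config file.
    """

    window_min: int = 100
    window_max: int = 140
    window_step: int = 5
    topology: TopologyConfig = field(default_factory=TopologyConfig)
    motifs: dict[str, MotifSpec] = field(default_factory=default_motif_specs)
    tata_upstream_min: int = 15
    tata_upstream_max: int = 40
    terminator_downstream: int = 25
    require_terminator: bool = True
    require_promoter: bool = True
    strand: str = "+"  # +, -, or both
    backend: str = "builtin"  # builtin or vienna
    dedup_identical: bool = True
    box_count_mode: str = "cassettes"  # cassettes (box-bearing) or boxes (raw)

    def __post_init__(self):
        if self.window_min > self.window_max or self.window_step < 1:
            raise ValueError("invalid window sweep parameters")
        if self.strand not in ("+", "-", "both"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.backend not in ("builtin", "vienna"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.box_count_mode not in ("cassettes", "boxes"):
            raise ValueError(f"unknown box_count_mode {self.box_count_mode!r}")

    @property
    def mfe_max(self) -> float:
        return self.topology.mfe_max

    def to_dict(self) -> dict:
        d = {}
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "topology":
                d.update({tf.name: getattr(v, tf.name) for tf in fields(v)})
            elif f.name == "motifs":
                for spec in v.values():
                    key = spec.name.lower()
                    if spec.name == "TERM":
                        d["term_min_run"] = spec.min_run
                    else:
                        d[f"{key}_consensus"] = spec.consensus
                        d[f"{key}_max_mismatch"] = spec.max_mismatch
            else:
                d[f.name] = v
        return d

    @classmethod
    def from_file(cls, path) -> "ScanConfig":
        """Load overrides from a flat ``key = value`` text file."""
        overrides: dict[str, str] = {}
        with open(path) as fh:
            for raw in fh:
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}: expected key=value, got {line!r}")
                key, val = (part.strip() for part in line.split("=", 1))
                overrides[key] = val
        return cls.default().with_overrides(**overrides)

    @classmethod
    def default(cls) -> "ScanConfig":
        return cls()

    def with_overrides(self, **overrides) -> "ScanConfig":
        """Apply string- or value-typed overrides by key (flat namespace)."""
        topo_keys = {tf.name for tf in fields(TopologyConfig)}
        scan_kwargs: dict = {}
        topo_kwargs: dict = {}
        motifs = dict(self.motifs)
        for key, val in overrides.items():
            if val is None:
                continue
            if key in topo_keys:
                topo_kwargs[key] = _coerce(val)
            elif key.endswith("_consensus"):
                name = key[:-len("_consensus")].upper()
                motifs[name] = replace(motifs[name], consensus=str(val))
            elif key.endswith("_max_mismatch"):
                name = key[:-len("_max_mismatch")].upper()
                motifs[name] = replace(motifs[name], max_mismatch=int(val))
            elif key == "term_min_run":
                motifs["TERM"] = replace(motifs["TERM"], min_run=int(val))
            elif key in {f.name for f in fields(ScanConfig)}:
                scan_kwargs[key] = _coerce(val)
            else:
                raise ValueError(f"unknown configuration key {key!r}")
        topology = replace(self.topology, **topo_kwargs) if topo_kwargs else self.topology
        return replace(self, topology=topology, motifs=motifs, **scan_kwargs)


def _coerce(val):
    if not isinstance(val, str):
        return val
    low = val.lower()
    if low in ("true", "false"):
        return low == "true"
    try:
        return int(val)
    except ValueError:
        pass
    try:
        return float(val)
    except ValueError:
        return val


@dataclass
class Cassette:
    """An accepted dumbbell with its Pol III context."""

    dumbbell: DumbbellCall
    promoter_hits: tuple[MotifHit, ...]
    terminator: Optional[MotifHit]
    cassette_region: SeqRegion
    has_internal_boxes: bool
    n_internal_boxes: int
    score: float  # dumbbell MFE; lower is better


@dataclass
class GenomeSummary:
    """Per-genome cassette count and box count (the reported columns)."""

    accession: str
    n_cassettes: int
    n_box_cassettes: int
    cassettes: list[Cassette] = field(default_factory=list)


# ---------------------------------------------------------------------------
# window sweep
# ---------------------------------------------------------------------------


def generate_windows(region: SeqRegion, config: ScanConfig) -> list[SeqRegion]:
    """All fully-contained sweep windows, ordered by start then width."""
    if len(region) < config.window_min:
        return []
    widths = range(config.window_min, config.window_max + 1, config.window_step)
    windows = []
    for start in range(region.start, region.end - config.window_min + 1,
                       config.window_step):
        for w in widths:
            if start + w <= region.end:
                windows.append(SeqRegion(region.seq_id, start, start + w,
                                         region.strand))
    return windows


def _scan_calls_local(oseq: str, seq_id: str, config: ScanConfig,
                      model: Optional[_fold.EnergyModel] = None) -> list[DumbbellCall]:
    """Dumbbell calls over an oriented sequence, in local coordinates."""
    L = len(oseq)
    if L < config.window_min:
        return []
    region = SeqRegion(seq_id, 0, L)
    mfe_max_int = round(config.mfe_max * 100)
    want = 1 if config.topology.single_hairpin_mode else 2
    calls: list[DumbbellCall] = []

    if config.backend == "vienna":
        cache: dict[tuple[int, int], _fold.FoldResult] = {}
        for win in generate_windows(region, config):
            fr = cache.get((win.start, win.end))
            if fr is None:
                fr = _fold.fold_vienna(oseq[win.start:win.end])
                cache[(win.start, win.end)] = fr
            if fr.mfe > config.mfe_max:
                continue
            call = classify_dumbbell(fr, win, config.topology)
            if call.passes_energy and call.passes_topology:
                calls.append(call)
    else:
        folder = _fold.ScanFolder(oseq, config.window_max, model=model)
        widths = list(range(config.window_min, config.window_max + 1,
                            config.window_step))
        for start in range(0, L - config.window_min + 1, config.window_step):
            e_max = min(start + config.window_max, L)
            W = folder.window_mfes(start, e_max)
            for w in widths:
                if start + w > L:
                    continue
                if W[w - 1] > mfe_max_int:
                    continue
                n_h, _, _, _ = folder.struct_stats(start, start + w)
                if n_h != want:
                    continue
                fr = folder.fold_window(start, start + w)
                win = SeqRegion(seq_id, start, start + w)
                call = classify_dumbbell(fr, win, config.topology)
                if call.passes_energy and call.passes_topology:
                    calls.append(call)
    calls.sort(key=lambda c: (c.mfe, c.trim_start, len(c.window)))
    return calls


def scan_region(seq: str, region: SeqRegion, config: ScanConfig,
                model: Optional[_fold.EnergyModel] = None) -> list[DumbbellCall]:
    """Fold every sweep window of ``region`` and keep dumbbell calls.

    Retains calls passing both the energy cutoff and the topology test,
    sorted by score (MFE ascending) then start.  For '-' strand regions the
    reverse complement is scanned and coordinates are mapped back.
    """
    oseq = extract_region(SeqRecordT(id=region.seq_id, seq=seq), region)
    calls = _scan_calls_local(oseq, region.seq_id, config, model=model)
    if region.strand == "-" or region.start != 0:
        calls = [_globalize_call(c, region) for c in calls]
    return calls


# ---------------------------------------------------------------------------
# coordinate mapping between oriented-local and genome frames
# ---------------------------------------------------------------------------


def _map_interval(a: int, b: int, frame: SeqRegion) -> tuple[int, int]:
    if frame.strand == "-":
        L = len(frame)
        return frame.start + L - b, frame.start + L - a
    return frame.start + a, frame.start + b


def _map_region(r: SeqRegion, frame: SeqRegion) -> SeqRegion:
    a, b = _map_interval(r.start, r.end, frame)
    return SeqRegion(frame.seq_id, a, b, frame.strand)


def _globalize_call(call: DumbbellCall, frame: SeqRegion) -> DumbbellCall:
    ts, te = _map_interval(call.trim_start, call.trim_end, frame)
    return DumbbellCall(
        window=_map_region(call.window, frame),
        fold=call.fold,
        n_hairpins=call.n_hairpins,
        basal_helix_bp=call.basal_helix_bp,
        arm_regions=tuple(_map_region(r, frame) for r in call.arm_regions),
        loop_sizes=call.loop_sizes,
        passes_energy=call.passes_energy,
        passes_topology=call.passes_topology,
        trim_start=ts, trim_end=te,
    )


def _globalize_hit(hit: MotifHit, frame: SeqRegion) -> MotifHit:
    return MotifHit(hit.spec_name, _map_region(hit.region, frame),
                    hit.matched, hit.mismatches)


def _globalize_cassette(cas: Cassette, frame: SeqRegion) -> Cassette:
    return Cassette(
        dumbbell=_globalize_call(cas.dumbbell, frame),
        promoter_hits=tuple(_globalize_hit(h, frame) for h in cas.promoter_hits),
        terminator=_globalize_hit(cas.terminator, frame) if cas.terminator else None,
        cassette_region=_map_region(cas.cassette_region, frame),
        has_internal_boxes=cas.has_internal_boxes,
        n_internal_boxes=cas.n_internal_boxes,
        score=cas.score,
    )


# ---------------------------------------------------------------------------
# deduplication and cassette assembly
# ---------------------------------------------------------------------------


def merge_overlapping(calls: Sequence[DumbbellCall]) -> list[DumbbellCall]:
    """Greedy best-MFE selection among overlapping candidates.

    Calls are taken by ascending MFE (ties: leftmost, then narrowest); any
    call whose trimmed span overlaps an already-selected call's trimmed span
    by at least one nt is discarded.  Output sorted by start.
    """
    ordered = sorted(calls, key=lambda c: (c.mfe, c.trim_start, len(c.window)))
    selected: list[DumbbellCall] = []
    for call in ordered:
        if any(call.window.seq_id == s.window.seq_id
               and call.trim_start < s.trim_end and s.trim_start < call.trim_end
               for s in selected):
            continue
        selected.append(call)
    selected.sort(key=lambda c: c.trim_start)
    return selected


def assemble_cassettes(seq: str, calls: Sequence[DumbbellCall],
                       motif_hits: Sequence[MotifHit],
                       config: ScanConfig) -> list[Cassette]:
    """Attach Pol III context to deduplicated dumbbell calls.

    A call becomes a cassette iff a terminator run starts within
    ``terminator_downstream`` nt after the trimmed 3' end, and either a TATA
    box starts 15-40 nt upstream of the trimmed 5' end or at least one A/B
    box lies inside the dumbbell span.  Coordinates of calls and hits must
    share one frame in which 5'->3' is increasing.
    """
    cassettes: list[Cassette] = []
    terms = [h for h in motif_hits if h.spec_name == "TERM"]
    tatas = [h for h in motif_hits if h.spec_name == "TATA"]
    boxes = [h for h in motif_hits if h.spec_name in ("ABOX", "BBOX")]
    for call in calls:
        db_start, db_end = call.trim_start, call.trim_end
        term_cands = [h for h in terms
                      if db_end <= h.region.start <= db_end + config.terminator_downstream]
        terminator = min(term_cands, key=lambda h: h.region.start) if term_cands else None
        if config.require_terminator and terminator is None:
            continue
        tata_hits = [h for h in tatas
                     if config.tata_upstream_min <= db_start - h.region.start
                     <= config.tata_upstream_max]
        internal = [h for h in boxes
                    if db_start <= h.region.start and h.region.end <= db_end]
        if config.require_promoter and not tata_hits and not internal:
            continue
        promoter_hits = tuple(sorted(tata_hits + internal,
                                     key=lambda h: (h.region.start, h.spec_name)))
        start = min([db_start] + [h.region.start for h in promoter_hits])
        end = terminator.region.end if terminator else db_end
        cassettes.append(Cassette(
            dumbbell=call,
            promoter_hits=promoter_hits,
            terminator=terminator,
            cassette_region=SeqRegion(call.window.seq_id, start, end,
                                      call.window.strand),
            has_internal_boxes=bool(internal),
            n_internal_boxes=len(internal),
            score=call.mfe,
        ))
    return cassettes


def merge_overlapping_cassettes(cassettes: Sequence[Cassette]) -> list[Cassette]:
    """Greedy best-MFE selection among assembled cassettes.

    Same rule as :func:`merge_overlapping`, applied after context assembly:
    alternative foldings of one locus whose chance flank pairs extend the
    structure over the terminator fail assembly and therefore never shadow
    the clean call, so deduplication happens among context-complete
    candidates only.
    """
    ordered = sorted(cassettes, key=lambda c: (c.score, c.dumbbell.trim_start,
                                               len(c.dumbbell.window)))
    selected: list[Cassette] = []
    for cas in ordered:
        d = cas.dumbbell
        if any(d.window.seq_id == s.dumbbell.window.seq_id
               and d.trim_start < s.dumbbell.trim_end
               and s.dumbbell.trim_start < d.trim_end
               for s in selected):
            continue
        selected.append(cas)
    selected.sort(key=lambda c: c.dumbbell.trim_start)
    return selected


def summarize_genome(accession: str, cassettes: Sequence[Cassette],
                     box_count_mode: str = "cassettes") -> GenomeSummary:
    """Collapse a genome's cassettes into the two reported counts."""
    if box_count_mode == "boxes":
        n_box = sum(c.n_internal_boxes for c in cassettes)
    else:
        n_box = sum(1 for c in cassettes if c.has_internal_boxes)
    return GenomeSummary(accession=accession, n_cassettes=len(cassettes),
                         n_box_cassettes=n_box, cassettes=list(cassettes))


# ---------------------------------------------------------------------------
# genome-level driver
# ---------------------------------------------------------------------------


def _target_regions(record: SeqRecordT,
                    regions: Optional[Sequence[SeqRegion]]) -> list[SeqRegion]:
    if regions:
        return [r for r in regions if r.seq_id == record.id]
    ltr = [reg for kind, reg in record.features if kind in ("LTR", "repeat_region")]
    if ltr:
        return [SeqRegion(record.id, r.start, r.end) for r in ltr]
    return [SeqRegion(record.id, 0, len(record.seq))]


def scan_record(record: SeqRecordT, config: ScanConfig,
                regions: Optional[Sequence[SeqRegion]] = None,
                model: Optional[_fold.EnergyModel] = None) -> GenomeSummary:
    """Scan one genome: windows -> folds -> dumbbells -> cassettes -> counts.

    Target regions come from the caller, from annotated LTR/repeat_region
    features, or default to the whole sequence.  Identical cassette
    sequences found at several loci (5' and 3' LTR copies) are reported once
    when ``config.dedup_identical`` is set.
    """
    strands = ["+", "-"] if config.strand == "both" else [config.strand]
    all_cassettes: list[Cassette] = []
    for region in _target_regions(record, regions):
        if len(region) < config.window_min:
            continue
        for strand in strands:
            frame = SeqRegion(record.id, region.start, region.end, strand)
            oseq = extract_region(record, frame)
            calls = _scan_calls_local(oseq, record.id, config, model=model)
            hits = scan_all_motifs(oseq, config.motifs, seq_id=record.id)
            cassettes = merge_overlapping_cassettes(
                assemble_cassettes(oseq, calls, hits, config))
            all_cassettes.extend(_globalize_cassette(c, frame) for c in cassettes)
    if config.dedup_identical:
        seen: set[str] = set()
        unique = []
        for cas in sorted(all_cassettes,
                          key=lambda c: (c.cassette_region.strand,
                                         c.cassette_region.start)):
            key = extract_region(record, cas.cassette_region)
            if key in seen:
                continue
            seen.add(key)
            unique.append(cas)
        all_cassettes = unique
    all_cassettes.sort(key=lambda c: (c.cassette_region.start,
                                      c.cassette_region.strand))
    return summarize_genome(record.id, all_cassettes, config.box_count_mode)


def scan_records(records: Sequence[SeqRecordT], config: ScanConfig,
                 regions: Optional[Sequence[SeqRegion]] = None,
                 model: Optional[_fold.EnergyModel] = None) -> list[GenomeSummary]:
    return [scan_record(rec, config, regions=regions, model=model)
            for rec in records]
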