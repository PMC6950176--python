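# Methods

## Detection model

A Pol III dumbbell miRNA cassette is modeled as three independent pieces of
evidence that must co-occur on the sense strand:

* a **thermodynamically stable double stem-loop**: a window whose minimum
  free energy at 37 °C is at most −30 kcal/mol and whose MFE structure,
  after trimming unpaired flanks, consists of exactly two hairpin loops —
  either as siblings on the exterior loop or as the two branches of a single
  multiloop beneath a shared basal helix;
* **promoter evidence**: an external TATA box upstream, or gene-internal
  A/B boxes (the type-2 Pol III arrangement of tRNA genes) inside the
  structure;
* a **terminator**: a run of ≥ 4 T on the coding strand shortly downstream,
  where Pol III terminates.

The −30 kcal/mol threshold and the ~130 nt size class define the screen; the
111–128 nt spans reported per cassette are an outcome (the trimmed paired
extent), not an input constraint.

## Energy model and folder

Energies are handled as integer centi-kcal/mol. The nearest-neighbor model
contains: stacking energies for all ordered pairs of {AU, UA, CG, GC, GU,
UG} (Watson–Crick stacks −3.4…−0.9 kcal/mol, wobble-containing stacks
weaker), hairpin-loop penalties tabulated for sizes 3–9, bulge penalties for
1–6 and interior-loop penalties for 2–6 unpaired nt, each extrapolated
log-linearly (Jacobson–Stockmayer form, 1.75·RT·ln(n/n₀)) for larger loops,
and an affine multiloop term of 3.4 + 0.4·(branches incl. the closing pair)
kcal/mol with free multiloop-interior unpaired bases. There are no dangling
ends, terminal-mismatch terms, coaxial stacks or special hairpins; interior
loops larger than 30 unpaired nt are prohibited, hairpin loops are ≥ 3 nt,
`N` never pairs, exterior unpaired bases are free. The parameter table can
be overridden from a plain-text file.

The values are implementation constants chosen to be of published nearest-
neighbor magnitude; they are validated by *minimality under the shared
model* (see below), never claimed to be Turner-exact. Exact-parameter
folding is delegated to the optional ViennaRNA backend, which the tests use
as an independent cross-check of dumbbell/non-dumbbell classification
(energies of the two backends are not comparable).

The folder is a banded Zuker dynamic program (tables `V`, `WM` plus an
exterior array), filled once per scanned sequence with pair spans bounded by
the largest window, so every sub-window's MFE is read off without
refolding. Among co-optimal structures the reported dot-bracket is the
lexicographically smallest (`(` < `)` < `.`), reconstructed by memoized
feasibility-checked traceback — this makes every output deterministic.
Standalone folds are capped at 500 nt: the program is cubic and meant for
windows, not genomes.

**Oracle.** `brute_force_fold` enumerates every nested structure of
sequences up to 24 nt and scores each by explicit loop decomposition under
the identical parameter table. Because both routes use integer energies,
agreement with the DP is exact, including the tie-break. This equivalence
(200 seeded random sequences per run) is the folding module's central test.

## Scan engineering

Two shortcuts keep the window sweep (per genome: ~130 starts × 9 widths)
fast without changing any reported value's definition:

* windows that pass the energy cutoff are first screened with a cheap
  deterministic traceback that only counts hairpin loops; only windows with
  the right count proceed to the exact lexicographic traceback. Windows
  containing, e.g., a single strong arm are rejected at kernel speed.
* tracebacks are cached by (trimmed paired span, energy): the many
  overlapping windows that share one structured core are traced once, and
  the dot-bracket is re-padded per window. In the degenerate case of a
  co-optimal alternative that pairs flank bases, the cached structure may
  differ from the full window's lexicographic minimum; classification is
  computed on the trimmed structure, so calls are unaffected.

## Candidate selection order

Overlapping candidate windows are deduplicated by greedy lowest-MFE
selection on trimmed spans (ties: leftmost, then narrowest). Deduplication
runs **after** promoter/terminator assembly, not before: chance pairing of
window flank bases can extend the MFE structure a few nucleotides past the
real 3′ end, over the terminator's first T — such a variant has the lowest
energy but no downstream terminator left, and if it were selected first it
would shadow the correct call at the same locus. Assembling context for all
passing windows and then deduplicating keeps exactly one context-complete
cassette per locus; on the 50-genome synthetic set this ordering raises
sensitivity from ~0.17 to 1.0 with no change in the false-call rate. The
pure call-level dedup (`merge_overlapping`) is retained and tested for use
on already-assembled or single-structure inputs.

TATA association measures from the TATA start to the trimmed 5′ edge
(accepted at 15–40 nt, spanning typical TATA–TSS spacing); the terminator
must *start* within 0–25 nt after the trimmed 3′ end, keeping the implied
Pol III transcript near the ~120 nt size class. Genomes whose two LTR
copies carry identical cassette sequences report them once by default
(`dedup_identical`), since the LTRs are copies of one U3 locus.

## Synthetic data

The generator emulates what the detector needs from real LTRs and no more:
i.i.d. background at GC 0.40 (LTR-like composition), planted cassettes with
perfect-complement GC-rich stems (fraction 0.70) of 22–25 bp per arm, 8 nt
A/C loops, a 4 bp basal helix and a 2 nt spacer — spans 114–126 nt, inside
the 111–128 nt envelope, which is asserted at generation time. Each planted
precursor is folded in isolation and redrawn until it shows exactly two
hairpins, pairs end-to-end, and reaches ≤ −30 kcal/mol. The Pol III context
is a `TATAAAA` box 18–35 nt upstream, a T₅ run 3–15 nt downstream (flanked
by non-T so the planted run is maximal as recorded), and, with probability
0.4 each, an A- or B-box realization embedded in a stem strand (the
complementary strand mirrors it, preserving the helix).

Default dataset: 50 genomes of 800 nt, two cassettes per genome (one per
half), fixed seed. These sizes make a full end-to-end evaluation run in
about a minute on one core while providing ≥ 100 planted truths.

What the fixtures do **not** emulate: phylogenetic sequence structure,
imperfect stems with large bulges, overlapping reading frames, LTR repeat
architecture, or miRNA expression. Passing the recovery test therefore
demonstrates the pipeline's correctness and its behavior at realistic GC
and stability contrasts — not its sensitivity on diverged natural stems,
which should be assessed on annotated genomes (see below).

Chance motif hits are real in random sequence: degenerate A/B-box consensi
with one mismatch occur inside ~120 nt structures often enough that some
cassettes planted without boxes are still reported as box-bearing. The truth
table records planted elements only; evaluation is by dumbbell-span overlap
(≥ 50 % of the planted span).

## Calibration against published genomes

Scanning the published foamy-virus genome set requires fetching the
versioned accessions (`ltrmir fetch`, network) and is therefore not part of
the test suite. The defaults shipped here (consensi `TATAWAW`/
`TRGCNNARYNNG`/`GTTCRANNC`, mismatch budgets 0/1/1, T≥4 terminator, window
100–140 nt, −30 kcal/mol) are the documented starting point for that
calibration; every one of them is a config key, and the scan manifest
records the resolved values of each run.

## Known limitations

* The simplified energy model understabilizes structures relative to full
  Turner parameters (no dangles/mismatches); absolute MFEs differ from
  ViennaRNA by several kcal/mol on ~130 nt windows, so threshold-sensitive
  calls near −30 kcal/mol can differ between backends.
* Single-hairpin mode (the BLV-style cassette class) is implemented and
  tested for its classification rule, but its thresholds are not calibrated
  against any annotated single-hairpin set.
* Arms are fixed-length slices anchored at stem-loop termini; no
  Drosha/Dicer processing model, so 3p-arm ends in particular are
  approximate.
* Both-strand scanning reports mirrored coordinates correctly but the
  biological default is the sense strand, where these cassettes reside.
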