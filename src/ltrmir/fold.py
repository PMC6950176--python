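"""RNA secondary-structure prediction by free-energy minimization.

This module provides the folding engine used to screen candidate pri-miRNA
windows: a simplified nearest-neighbor energy model (stacking energies plus
size-dependent loop penalties at 37 degC, no dangling ends, no coaxial
stacking), a Zuker-style dynamic program returning one minimum-free-energy
structure in dot-bracket notation, an exhaustive enumeration oracle for short
sequences, and a parser that turns dot-bracket strings into an explicit
loop/helix tree.

Energies are handled internally as integer centi-kcal/mol so that the dynamic
program and the enumeration oracle agree exactly; the public API reports
kcal/mol floats.
"""

from __future__ import annotations

import functools
import math
import shutil
import subprocess
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
from numba import njit

INF = 10**9

#: base encoding used by the kernels; N (=4) never pairs
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3, "N": 4}

# pair codes: 0 = no pair, 1..6 = AU, UA, CG, GC, GU, UG
_PAIR_TABLE = np.zeros((5, 5), dtype=np.int64)
_PAIR_TABLE[0, 3] = 1
_PAIR_TABLE[3, 0] = 2
_PAIR_TABLE[1, 2] = 3
_PAIR_TABLE[2, 1] = 4
_PAIR_TABLE[2, 3] = 5
_PAIR_TABLE[3, 2] = 6

#: minimum hairpin loop size (unpaired nt closed by a pair)
MIN_HAIRPIN = 3

#: largest interior/bulge loop considered (total unpaired nt); larger loops
#: are treated as prohibitively unstable, as in standard MFE folders
MAX_INTERIOR = 30

_MAX_LEN = 500
_BRUTE_MAX_LEN = 24


class FoldSizeError(ValueError):
    """Sequence outside the length range a folding routine accepts."""


def encode(seq: str) -> np.ndarray:
    """Encode a DNA/RNA string as int8 codes (A=0, C=1, G=2, U/T=3, N=4)."""
    try:
        return np.array([_BASE_CODE[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-nucleotide character {exc.args[0]!r} in sequence") from None


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def pair_code(a: int, b: int) -> int:
    return int(_PAIR_TABLE[a, b])


# ---------------------------------------------------------------------------
# energy model
# ---------------------------------------------------------------------------

# stacking free energies in kcal/mol, indexed [pair(i,j)][pair(i+1,j-1)]
# with pair codes AU,UA,CG,GC,GU,UG = 1..6.  Watson-Crick stacks span
# -3.4..-0.9; wobble-containing stacks are weaker.
_STACK_KCAL = {
    (1, 1): -0.9, (1, 2): -1.1, (1, 3): -2.2, (1, 4): -2.1, (1, 5): -0.6, (1, 6): -1.4,
    (2, 1): -1.3, (2, 2): -0.9, (2, 3): -2.4, (2, 4): -2.1, (2, 5): -1.0, (2, 6): -1.3,
    (3, 1): -2.1, (3, 2): -2.1, (3, 3): -3.3, (3, 4): -2.4, (3, 5): -1.4, (3, 6): -2.1,
    (4, 1): -2.4, (4, 2): -2.2, (4, 3): -3.4, (4, 4): -3.3, (4, 5): -1.5, (4, 6): -2.5,
    (5, 1): -1.3, (5, 2): -1.4, (5, 3): -2.5, (5, 4): -2.1, (5, 5): -0.5, (5, 6): -0.4,
    (6, 1): -1.0, (6, 2): -0.6, (6, 3): -1.4, (6, 4): -1.3, (6, 5): -0.3, (6, 6): -0.5,
}

_HAIRPIN_KCAL = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
_BULGE_KCAL = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
_INTERNAL_KCAL = {2: 1.5, 3: 1.6, 4: 1.7, 5: 2.0, 6: 2.1}

# Jacobson-Stockmayer extrapolation: 1.75 * R * T at 310.15 K, kcal/mol
_JS_COEF = 1.75 * 0.0019872 * 310.15


def _loop_array(table: dict[int, float], max_size: int) -> np.ndarray:
    """Integer centi-kcal loop-penalty array with log-linear extrapolation."""
    arr = np.full(max_size + 1, INF, dtype=np.int64)
    n0 = max(table)
    for size, kcal in table.items():
        arr[size] = round(kcal * 100)
    for size in range(n0 + 1, max_size + 1):
        arr[size] = round((table[n0] + _JS_COEF * math.log(size / n0)) * 100)
    return arr


@dataclass(frozen=True)
class EnergyModel:
    """Nearest-neighbor parameter set (integer centi-kcal/mol, 37 degC).

    ``stack[p][q]`` is the energy of stacking inner pair ``q`` on outer pair
    ``p`` (pair codes 1..6); loop arrays are indexed by unpaired size; the
    multiloop energy is affine: ``ml_init + ml_branch * (branches incl. the
    closing pair) + ml_unpaired * unpaired``.
    """

    stack: np.ndarray
    hairpin: np.ndarray
    bulge: np.ndarray
    internal: np.ndarray
    ml_init: int = 340
    ml_branch: int = 40
    ml_unpaired: int = 0
    max_interior: int = MAX_INTERIOR

    @classmethod
    def default(cls, max_loop: int = _MAX_LEN) -> "EnergyModel":
        stack = np.zeros((7, 7), dtype=np.int64)
        for (p, q), kcal in _STACK_KCAL.items():
            stack[p, q] = round(kcal * 100)
        return cls(
            stack=stack,
            hairpin=_loop_array(_HAIRPIN_KCAL, max_loop),
            bulge=_loop_array(_BULGE_KCAL, max_loop),
            internal=_loop_array(_INTERNAL_KCAL, max_loop),
        )

    @classmethod
    def from_file(cls, path) -> "EnergyModel":
        """Load parameter overrides from a ``key value`` plain-text table.

        Recognized keys: ``stack <p> <q> <kcal>`` (pair codes 1..6),
        ``hairpin|bulge|internal <size> <kcal>``, ``ml_init|ml_branch|
        ml_unpaired <kcal>``.  Unlisted entries keep their defaults.
        """
        base = cls.default()
        stack = base.stack.copy()
        loops = {"hairpin": base.hairpin.copy(), "bulge": base.bulge.copy(),
                 "internal": base.internal.copy()}
        ml = {"ml_init": base.ml_init, "ml_branch": base.ml_branch,
              "ml_unpaired": base.ml_unpaired}
        with open(path) as fh:
            for raw in fh:
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                parts = line.split()
                key = parts[0]
                if key == "stack":
                    stack[int(parts[1]), int(parts[2])] = round(float(parts[3]) * 100)
                elif key in loops:
                    loops[key][int(parts[1])] = round(float(parts[2]) * 100)
                elif key in ml:
                    ml[key] = round(float(parts[1]) * 100)
                else:
                    raise ValueError(f"unknown energy-model key {key!r}")
        return cls(stack=stack, hairpin=loops["hairpin"], bulge=loops["bulge"],
                   internal=loops["internal"], **ml)

    def loop_energy(self, n1: int, n2: int, outer_pair: int, inner_pair: int) -> int:
        """Energy (centi-kcal) of the two-branch loop between nested pairs."""
        if n1 == 0 and n2 == 0:
            return int(self.stack[outer_pair, inner_pair])
        total = n1 + n2
        if total > self.max_interior:
            return INF
        if n1 == 0 or n2 == 0:
            return int(self.bulge[total])
        return int(self.internal[total])


@functools.lru_cache(maxsize=1)
def default_model() -> EnergyModel:
    return EnergyModel.default()


# ---------------------------------------------------------------------------
# dynamic programming kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _fill_tables(enc, max_span, stack, hairpin, bulge, internal,
                 ml_init, ml_branch, ml_unpaired, max_interior):  # pragma: no cover
    """Banded Zuker fill: V[i,j] = MFE given i.j paired, WM = multiloop part."""
    n = enc.shape[0]
    V = np.full((n, n), INF, dtype=np.int64)
    WM = np.full((n, n), INF, dtype=np.int64)
    for span in range(1, min(n, max_span + 1)):
        for i in range(0, n - span):
            j = i + span
            p = _PAIR_TABLE[enc[i], enc[j]]
            if p != 0 and span >= MIN_HAIRPIN + 1:
                best = hairpin[span - 1]
                # interior loops / bulges / stacks, total unpaired <= cap
                n1_max = min(max_interior, j - i - 2 - (MIN_HAIRPIN + 1))
                for n1 in range(0, n1_max + 1):
                    k = i + 1 + n1
                    for n2 in range(0, max_interior - n1 + 1):
                        l = j - 1 - n2
                        if l - k < MIN_HAIRPIN + 1:
                            break
                        if V[k, l] >= INF:
                            continue
                        q = _PAIR_TABLE[enc[k], enc[l]]
                        if n1 == 0 and n2 == 0:
                            loop = stack[p, q]
                        elif n1 == 0 or n2 == 0:
                            loop = bulge[n1 + n2]
                        else:
                            loop = internal[n1 + n2]
                        e = loop + V[k, l]
                        if e < best:
                            best = e
                # multiloop closure: two non-empty WM parts inside
                for k in range(i + 2, j - 1):
                    if WM[i + 1, k - 1] < INF and WM[k, j - 1] < INF:
                        e = ml_init + ml_branch + WM[i + 1, k - 1] + WM[k, j - 1]
                        if e < best:
                            best = e
                V[i, j] = best
            # WM: >=1 branch within a multiloop
            best = INF
            if V[i, j] < INF:
                best = V[i, j] + ml_branch
            if WM[i + 1, j] < INF:
                e = WM[i + 1, j] + ml_unpaired
                if e < best:
                    best = e
            if WM[i, j - 1] < INF:
                e = WM[i, j - 1] + ml_unpaired
                if e < best:
                    best = e
            for k in range(i + 1, j + 1):
                if WM[i, k - 1] < INF and WM[k, j] < INF:
                    e = WM[i, k - 1] + WM[k, j]
                    if e < best:
                        best = e
            if best < WM[i, j]:
                WM[i, j] = best
    return V, WM


@njit(cache=True)
def _suffix_exterior(V, s, e):  # pragma: no cover
    """E[t] = MFE of exterior segment [s+t, e); unpaired exterior bases free."""
    w = e - s
    E = np.zeros(w + 1, dtype=np.int64)
    for t in range(w - 1, -1, -1):
        i = s + t
        best = E[t + 1]
        for j in range(i + MIN_HAIRPIN + 1, e):
            if V[i, j] < INF:
                c = V[i, j] + E[j - s + 1]
                if c < best:
                    best = c
        E[t] = best
    return E


@njit(cache=True)
def _prefix_window_mfe(V, s, e_max):  # pragma: no cover
    """W[t] = MFE of window [s, s+t+1); yields all window widths at start s."""
    w = e_max - s
    W = np.zeros(w, dtype=np.int64)
    for t in range(w):
        j = s + t
        best = W[t - 1] if t > 0 else 0
        for i in range(s, j - MIN_HAIRPIN):
            if V[i, j] < INF:
                left = W[i - s - 1] if i > s else 0
                c = left + V[i, j]
                if c < best:
                    best = c
        W[t] = best
    return W


@njit(cache=True)
def _fast_struct_stats(enc, V, WM, E, s, e, stack, hairpin, bulge, internal,
                       ml_init, ml_branch, ml_unpaired, max_interior):  # pragma: no cover
    """Cheap deterministic traceback of one MFE structure for window [s, e).

    Returns (n_hairpins, first_paired, last_paired_exclusive, n_pairs) for a
    first-feasible-choice co-optimal structure.  Used to prefilter scan
    windows before the exact lexicographic traceback.
    """
    n_hairpins = 0
    n_pairs = 0
    first = -1
    last = -1
    # task stack: kind 0 = V(i,j), 1 = WM(i,j)
    cap = 4 * (e - s) + 8
    kinds = np.empty(cap, dtype=np.int64)
    ais = np.empty(cap, dtype=np.int64)
    ajs = np.empty(cap, dtype=np.int64)
    top = 0
    # exterior walk
    i = s
    while i < e:
        paired = False
        for j in range(i + MIN_HAIRPIN + 1, e):
            if V[i, j] < INF and V[i, j] + E[j - s + 1] == E[i - s]:
                kinds[top] = 0
                ais[top] = i
                ajs[top] = j
                top += 1
                i = j + 1
                paired = True
                break
        if not paired:
            i += 1
    while top > 0:
        top -= 1
        kind = kinds[top]
        i = ais[top]
        j = ajs[top]
        if kind == 0:
            n_pairs += 1
            if first < 0 or i < first:
                first = i
            if j + 1 > last:
                last = j + 1
            target = V[i, j]
            if hairpin[j - i - 1] == target:
                n_hairpins += 1
                continue
            p = _PAIR_TABLE[enc[i], enc[j]]
            done = False
            n1_lim = min(max_interior, j - i - 2 - (MIN_HAIRPIN + 1))
            for n1 in range(0, n1_lim + 1):
                if done:
                    break
                k = i + 1 + n1
                for n2 in range(0, max_interior - n1 + 1):
                    l = j - 1 - n2
                    if l - k < MIN_HAIRPIN + 1:
                        break
                    if V[k, l] >= INF:
                        continue
                    q = _PAIR_TABLE[enc[k], enc[l]]
                    if n1 == 0 and n2 == 0:
                        loop = stack[p, q]
                    elif n1 == 0 or n2 == 0:
                        loop = bulge[n1 + n2]
                    else:
                        loop = internal[n1 + n2]
                    if loop + V[k, l] == target:
                        kinds[top] = 0
                        ais[top] = k
                        ajs[top] = l
                        top += 1
                        done = True
                        break
            if done:
                continue
            for k in range(i + 2, j - 1):
                if (WM[i + 1, k - 1] < INF and WM[k, j - 1] < INF
                        and ml_init + ml_branch + WM[i + 1, k - 1] + WM[k, j - 1] == target):
                    kinds[top] = 1
                    ais[top] = i + 1
                    ajs[top] = k - 1
                    top += 1
                    kinds[top] = 1
                    ais[top] = k
                    ajs[top] = j - 1
                    top += 1
                    break
        else:
            # WM segment: peel deterministically
            while True:
                target = WM[i, j]
                if V[i, j] < INF and V[i, j] + ml_branch == target:
                    kinds[top] = 0
                    ais[top] = i
                    ajs[top] = j
                    top += 1
                    break
                if i < j and WM[i + 1, j] < INF and WM[i + 1, j] + ml_unpaired == target:
                    i += 1
                    continue
                if i < j and WM[i, j - 1] < INF and WM[i, j - 1] + ml_unpaired == target:
                    j -= 1
                    continue
                found = False
                for k in range(i + 1, j + 1):
                    if (WM[i, k - 1] < INF and WM[k, j] < INF
                            and WM[i, k - 1] + WM[k, j] == target):
                        kinds[top] = 1
                        ais[top] = i
                        ajs[top] = k - 1
                        top += 1
                        i = k
                        found = True
                        break
                if not found:
                    break
    return n_hairpins, first, last, n_pairs


# ---------------------------------------------------------------------------
# traceback (lexicographically smallest co-optimal dot-bracket)
# ---------------------------------------------------------------------------


class _LexTracer:
    """Reconstructs the lexicographically smallest MFE dot-bracket.

    Works on the filled V/WM tables plus a suffix exterior array for one
    window [s, e).  '(' sorts before ')' and '.', so structures that open a
    pair as early as possible are preferred; ties among alternative pairings
    are resolved by full string comparison on memoized substrings.
    """

    def __init__(self, enc: np.ndarray, V: np.ndarray, WM: np.ndarray,
                 E: np.ndarray, model: EnergyModel, s: int, e: int):
        self.enc, self.V, self.WM, self.E, self.m = enc, V, WM, E, model
        self.s, self.e = s, e
        self._v_memo: dict[tuple[int, int], str] = {}
        self._wm_memo: dict[tuple[int, int], str] = {}
        self._ext_memo: dict[int, str] = {}

    def exterior(self, i: int) -> str:
        if i >= self.e:
            return ""
        if i in self._ext_memo:
            return self._ext_memo[i]
        E, V, s = self.E, self.V, self.s
        target = E[i - s]
        cands = []
        for j in range(i + MIN_HAIRPIN + 1, self.e):
            if V[i, j] < INF and V[i, j] + E[j - s + 1] == target:
                cands.append(self.vstr(i, j) + self.exterior(j + 1))
        if not cands and E[i - s + 1] == target:
            cands.append("." + self.exterior(i + 1))
        out = min(cands)
        self._ext_memo[i] = out
        return out

    def vstr(self, i: int, j: int) -> str:
        key = (i, j)
        if key in self._v_memo:
            return self._v_memo[key]
        enc, V, WM, m = self.enc, self.V, self.WM, self.m
        target = V[i, j]
        p = pair_code(enc[i], enc[j])
        cands = []
        if m.hairpin[j - i - 1] == target:
            cands.append("(" + "." * (j - i - 1) + ")")
        n1_max = min(m.max_interior, j - i - 2 - (MIN_HAIRPIN + 1))
        for n1 in range(0, n1_max + 1):
            k = i + 1 + n1
            for n2 in range(0, m.max_interior - n1 + 1):
                l = j - 1 - n2
                if l - k < MIN_HAIRPIN + 1:
                    break
                if V[k, l] >= INF:
                    continue
                q = pair_code(enc[k], enc[l])
                if m.loop_energy(n1, n2, p, q) + V[k, l] == target:
                    cands.append("(" + "." * n1 + self.vstr(k, l) + "." * n2 + ")")
        for k in range(i + 2, j - 1):
            if (WM[i + 1, k - 1] < INF and WM[k, j - 1] < INF
                    and m.ml_init + m.ml_branch + WM[i + 1, k - 1] + WM[k, j - 1] == target):
                cands.append("(" + self.wmstr(i + 1, k - 1) + self.wmstr(k, j - 1) + ")")
        out = min(cands)
        self._v_memo[key] = out
        return out

    def wmstr(self, i: int, j: int) -> str:
        key = (i, j)
        if key in self._wm_memo:
            return self._wm_memo[key]
        V, WM, m = self.V, self.WM, self.m
        target = WM[i, j]
        cands = []
        if V[i, j] < INF and V[i, j] + m.ml_branch == target:
            cands.append(self.vstr(i, j))
        if i < j:
            if WM[i + 1, j] < INF and WM[i + 1, j] + m.ml_unpaired == target:
                cands.append("." + self.wmstr(i + 1, j))
            if WM[i, j - 1] < INF and WM[i, j - 1] + m.ml_unpaired == target:
                cands.append(self.wmstr(i, j - 1) + ".")
            for k in range(i + 1, j + 1):
                if WM[i, k - 1] < INF and WM[k, j] < INF and WM[i, k - 1] + WM[k, j] == target:
                    cands.append(self.wmstr(i, k - 1) + self.wmstr(k, j))
        out = min(cands)
        self._wm_memo[key] = out
        return out


# ---------------------------------------------------------------------------
# public folding API
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FoldResult:
    """A folded sequence: RNA string, dot-bracket, and MFE in kcal/mol."""

    seq: str
    dot_bracket: str
    mfe: float

    def __post_init__(self):
        if len(self.seq) != len(self.dot_bracket):
            raise ValueError("sequence and structure lengths differ")

    @property
    def pairs(self) -> tuple[tuple[int, int], ...]:
        return tuple(_pairs_from_dotbracket(self.dot_bracket))


def fold_mfe(seq: str, model: Optional[EnergyModel] = None) -> FoldResult:
    """Minimum-free-energy structure of ``seq`` under the built-in model.

    DNA input is transcribed (T -> U).  Among co-optimal structures the
    lexicographically smallest dot-bracket is returned, which makes the
    result deterministic.  Sequences longer than 500 nt are rejected:
    scanner windows are far shorter and the cubic dynamic program is not
    meant for whole genomes.
    """
    n = len(seq)
    if n < 1 or n > _MAX_LEN:
        raise FoldSizeError(f"sequence length {n} outside [1, {_MAX_LEN}]")
    model = model or default_model()
    rna = to_rna(seq)
    enc = encode(rna)
    V, WM = _fill_tables(enc, n, model.stack, model.hairpin, model.bulge,
                         model.internal, model.ml_init, model.ml_branch,
                         model.ml_unpaired, model.max_interior)
    E = _suffix_exterior(V, 0, n)
    db = _LexTracer(enc, V, WM, E, model, 0, n).exterior(0)
    return FoldResult(seq=rna, dot_bracket=db, mfe=E[0] / 100.0)


class ScanFolder:
    """Shared folding state for sliding-window scans over one sequence.

    The Zuker tables are filled once for the whole sequence with pair spans
    banded at ``max_span``; every sub-window's MFE and structure can then be
    read off without refolding, since V[i, j] depends only on the
    subsequence i..j.
    """

    def __init__(self, seq: str, max_span: int,
                 model: Optional[EnergyModel] = None):
        self.model = model or default_model()
        self.rna = to_rna(seq)
        self.enc = encode(self.rna)
        m = self.model
        self.V, self.WM = _fill_tables(self.enc, max_span, m.stack, m.hairpin,
                                       m.bulge, m.internal, m.ml_init,
                                       m.ml_branch, m.ml_unpaired,
                                       m.max_interior)
        self._trim_cache: dict[tuple[int, int, int], str] = {}

    def window_mfes(self, start: int, end_max: int) -> np.ndarray:
        """Centi-kcal MFE of [start, start+t+1) for t = 0..end_max-start-1."""
        return _prefix_window_mfe(self.V, start, end_max)

    def struct_stats(self, s: int, e: int) -> tuple[int, int, int, int]:
        """(n_hairpins, first_paired, last_paired_excl, n_pairs) of one MFE
        structure of window [s, e) via the fast deterministic traceback."""
        m = self.model
        E = _suffix_exterior(self.V, s, e)
        return _fast_struct_stats(self.enc, self.V, self.WM, E, s, e, m.stack,
                                  m.hairpin, m.bulge, m.internal, m.ml_init,
                                  m.ml_branch, m.ml_unpaired, m.max_interior)

    def fold_window(self, s: int, e: int) -> FoldResult:
        """Exact fold of window [s, e) with the lexicographic tie-break.

        Tracebacks are cached by trimmed paired span and energy, so the many
        scan windows that share one structured core are traced once.
        """
        E = _suffix_exterior(self.V, s, e)
        mfe_int = int(E[0])
        _, first, last, _ = self.struct_stats(s, e)
        if first >= 0:
            key = (first, last, mfe_int)
            trimmed = self._trim_cache.get(key)
            if trimmed is None:
                Et = _suffix_exterior(self.V, first, last)
                if int(Et[0]) == mfe_int:
                    trimmed = _LexTracer(self.enc, self.V, self.WM, Et,
                                         self.model, first, last).exterior(first)
                    self._trim_cache[key] = trimmed
            if trimmed is not None:
                db = "." * (first - s) + trimmed + "." * (e - last)
                return FoldResult(seq=self.rna[s:e], dot_bracket=db,
                                  mfe=mfe_int / 100.0)
        db = _LexTracer(self.enc, self.V, self.WM, E, self.model, s, e).exterior(s)
        return FoldResult(seq=self.rna[s:e], dot_bracket=db, mfe=mfe_int / 100.0)


def _pairs_from_dotbracket(db: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for pos, c in enumerate(db):
        if c == "(":
            stack.append(pos)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {pos}")
            pairs.append((stack.pop(), pos))
        elif c != ".":
            raise ValueError(f"invalid character {c!r} at position {pos}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return sorted(pairs)


def energy_of_structure(seq: str, dot_bracket: str,
                        model: Optional[EnergyModel] = None) -> float:
    """Free energy (kcal/mol) of an explicit structure under the model."""
    model = model or default_model()
    enc = encode(to_rna(seq))
    pairs = _pairs_from_dotbracket(dot_bracket)
    return _structure_energy_int(enc, pairs, model) / 100.0


def _structure_energy_int(enc: np.ndarray, pairs: Sequence[tuple[int, int]],
                          model: EnergyModel) -> int:
    """Loop-decomposition energy in centi-kcal; INF if any loop is illegal."""
    total = 0
    children: dict[Optional[tuple[int, int]], list[tuple[int, int]]] = {None: []}
    open_stack: list[tuple[int, int]] = []
    for pair in pairs:  # sorted by opening position; nested by construction
        while open_stack and pair[0] > open_stack[-1][1]:
            open_stack.pop()
        parent = open_stack[-1] if open_stack else None
        children.setdefault(pair, [])
        children.setdefault(parent, []).append(pair)
        open_stack.append(pair)
    for (i, j) in pairs:
        p = pair_code(enc[i], enc[j])
        if p == 0:
            return INF
        kids = children[(i, j)]
        if not kids:
            size = j - i - 1
            if size < MIN_HAIRPIN:
                return INF
            total += int(model.hairpin[size])
        elif len(kids) == 1:
            (k, l) = kids[0]
            q = pair_code(enc[k], enc[l])
            e = model.loop_energy(k - i - 1, j - l - 1, p, q)
            if e >= INF:
                return INF
            total += e
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for (k, l) in kids)
            total += (model.ml_init + model.ml_branch * (len(kids) + 1)
                      + model.ml_unpaired * unpaired)
    return total


def _enumerate_structures(enc: np.ndarray, i: int, j: int) -> Iterator[tuple]:
    """All nested structures over [i, j) with pair span >= MIN_HAIRPIN + 1."""
    if j - i <= 0:
        yield ()
        return
    for rest in _enumerate_structures(enc, i + 1, j):
        yield rest
    for k in range(i + MIN_HAIRPIN + 1, j):
        if pair_code(enc[i], enc[k]) == 0:
            continue
        for inside in _enumerate_structures(enc, i + 1, k):
            for after in _enumerate_structures(enc, k + 1, j):
                yield ((i, k),) + inside + after


def brute_force_fold(seq: str, model: Optional[EnergyModel] = None) -> FoldResult:
    """Exhaustive-enumeration MFE fold for sequences up to 24 nt.

    Enumerates every nested structure, scores each one by explicit loop
    decomposition, and returns the global minimum (lexicographically smallest
    dot-bracket among co-optimal structures).  Serves as the independent
    oracle for :func:`fold_mfe`.
    """
    n = len(seq)
    if n < 1 or n > _BRUTE_MAX_LEN:
        raise FoldSizeError(f"brute force limited to 1..{_BRUTE_MAX_LEN} nt, got {n}")
    model = model or default_model()
    rna = to_rna(seq)
    enc = encode(rna)
    best_e = 0
    best_db = "." * n
    for pairs in _enumerate_structures(enc, 0, n):
        e = _structure_energy_int(enc, sorted(pairs), model)
        if e > best_e:
            continue
        db_chars = ["."] * n
        for (a, b) in pairs:
            db_chars[a] = "("
            db_chars[b] = ")"
        db = "".join(db_chars)
        if e < best_e or (e == best_e and db < best_db):
            best_e, best_db = e, db
    return FoldResult(seq=rna, dot_bracket=best_db, mfe=best_e / 100.0)


# ---------------------------------------------------------------------------
# structure tree
# ---------------------------------------------------------------------------


@dataclass
class Hairpin:
    size: int


@dataclass
class Interior:
    left: int
    right: int
    inner: "Helix"


@dataclass
class Multiloop:
    branches: list["Helix"]
    unpaired: int


@dataclass
class Helix:
    """A maximal run of stacked pairs; ``outer`` is its outermost pair."""

    outer: tuple[int, int]
    length: int
    child: "Hairpin | Interior | Multiloop" = field(default=None)  # type: ignore

    @property
    def inner(self) -> tuple[int, int]:
        i, j = self.outer
        return (i + self.length - 1, j - self.length + 1)


@dataclass
class Exterior:
    branches: list[Helix]
    unpaired: int


class StructureTree:
    """Loop/helix decomposition of a dot-bracket string."""

    def __init__(self, dot_bracket: str):
        self.dot_bracket = dot_bracket
        pairs = _pairs_from_dotbracket(dot_bracket)
        self._partner = {}
        for (a, b) in pairs:
            self._partner[a] = b
            self._partner[b] = a
        top = self._top_level_pairs(0, len(dot_bracket))
        unpaired = len(dot_bracket) - sum(b - a + 1 for (a, b) in top)
        self.root = Exterior(branches=[self._build_helix(a, b) for (a, b) in top],
                             unpaired=unpaired)

    def _top_level_pairs(self, i: int, j: int) -> list[tuple[int, int]]:
        out = []
        pos = i
        while pos < j:
            if pos in self._partner and self._partner[pos] > pos:
                out.append((pos, self._partner[pos]))
                pos = self._partner[pos] + 1
            else:
                pos += 1
        return out

    def _build_helix(self, i: int, j: int) -> Helix:
        length = 1
        while (i + length in self._partner
               and self._partner[i + length] == j - length):
            length += 1
        hi, hj = i + length - 1, j - length + 1
        kids = self._top_level_pairs(hi + 1, hj)
        child: Hairpin | Interior | Multiloop
        if not kids:
            child = Hairpin(size=hj - hi - 1)
        elif len(kids) == 1:
            (k, l) = kids[0]
            child = Interior(left=k - hi - 1, right=hj - l - 1,
                             inner=self._build_helix(k, l))
        else:
            unpaired = (hj - hi - 1) - sum(b - a + 1 for (a, b) in kids)
            child = Multiloop(branches=[self._build_helix(a, b) for (a, b) in kids],
                              unpaired=unpaired)
        return Helix(outer=(i, j), length=length, child=child)

    # -- queries ---------------------------------------------------------

    def serialize(self) -> str:
        """Rebuild the dot-bracket string from the tree."""
        chars = ["."] * len(self.dot_bracket)

        def emit(h: Helix) -> None:
            i, j = h.outer
            for t in range(h.length):
                chars[i + t] = "("
                chars[j - t] = ")"
            if isinstance(h.child, Interior):
                emit(h.child.inner)
            elif isinstance(h.child, Multiloop):
                for b in h.child.branches:
                    emit(b)

        for b in self.root.branches:
            emit(b)
        return "".join(chars)

    def _walk(self):
        stack = list(self.root.branches)
        while stack:
            h = stack.pop()
            yield h
            if isinstance(h.child, Interior):
                stack.append(h.child.inner)
            elif isinstance(h.child, Multiloop):
                stack.extend(h.child.branches)

    @property
    def n_hairpins(self) -> int:
        return sum(1 for h in self._walk() if isinstance(h.child, Hairpin))

    @property
    def n_multiloops(self) -> int:
        return sum(1 for h in self._walk() if isinstance(h.child, Multiloop))

    @property
    def helix_lengths(self) -> list[int]:
        return [h.length for h in self._walk()]

    @property
    def n_pairs(self) -> int:
        return len(self._partner) // 2

    @property
    def paired_span(self) -> Optional[tuple[int, int]]:
        """Half-open interval from first to last paired base, or None."""
        if not self._partner:
            return None
        return (min(self._partner), max(self._partner) + 1)


def parse_structure(dot_bracket: str) -> StructureTree:
    """Parse dot-bracket notation into a loop/helix tree.

    Raises ``ValueError`` naming the offending position for unbalanced input.
    """
    return StructureTree(dot_bracket)


# ---------------------------------------------------------------------------
# optional external backend
# ---------------------------------------------------------------------------


def vienna_available() -> bool:
    return shutil.which("RNAfold") is not None


def fold_vienna(seq: str) -> FoldResult:
    """Fold with the external ViennaRNA ``RNAfold`` program (full Turner
    parameters).  Used as an independent cross-check / alternative backend;
    energies are not comparable to the built-in model's constants."""
    rna = to_rna(seq)
    proc = subprocess.run(
        ["RNAfold", "--noPS"], input=rna + "\n", text=True,
        capture_output=True, check=True,
    )
    lines = proc.stdout.strip().splitlines()
    struct_line = lines[-1]
    db = struct_line.split(None, 1)[0]
    mfe = float(struct_line.rsplit("(", 1)[1].rstrip(")").strip())
    return FoldResult(seq=rna, dot_bracket=db, mfe=mfe)


def fold_with_backend(seq: str, backend: str = "builtin",
                      model: Optional[EnergyModel] = None) -> FoldResult:
    if backend == "builtin":
        return fold_mfe(seq, model=model)
    if backend == "vienna":
        return fold_vienna(seq)
    raise ValueError(f"unknown folding backend {backend!r}")
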