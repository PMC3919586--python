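"""Minimum-free-energy RNA secondary structure for short sequences.

A deliberately small nearest-neighbour model: only stacked base pairs
contribute favourable energy (per-step table shipped in ``data/``), loops
are charged size-dependent penalties, single unstacked pairs score 0.
This is not the Turner model and makes no claim of numeric agreement with
RNAfold; it exists to discriminate genuine hairpins from unstructured
sequence at a configurable dG threshold, and is exactly verifiable against
an exhaustive enumeration oracle (:func:`enumerate_mfe`).

All energies are handled internally as integer tenths of kcal/mol, so
dynamic programming and enumeration agree bit-for-bit.

Conventions: T is treated as U; N never pairs; allowed pairs are the six
canonical + wobble pairs (AU, UA, GC, CG, GU, UG); minimum hairpin loop is
3 nt; no pseudoknots.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from numba import njit

MIN_LOOP = 3
MAX_FOLD_LEN = 200
MAX_ENUM_LEN = 18

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3, "N": 4}
_PAIR_NAMES = {"AU": (0, 3), "UA": (3, 0), "GC": (2, 1), "CG": (1, 2),
               "GU": (2, 3), "UG": (3, 2)}

_INF = np.int64(1) << 50
_PACK = 1024  # cost = deci_energy * _PACK + n_pairs  (n_pairs < _PACK always)


@dataclass
class EnergyModel:
    """Simplified stacking/loop model, integer deci-kcal internally."""

    stack: np.ndarray          # (5,5,5,5) int32 deci-kcal, INF-like 0 for invalid
    pair_ok: np.ndarray        # (5,5) bool
    hairpin_pen: np.ndarray    # indexed by loop size, deci-kcal
    internal_pen: np.ndarray   # indexed by loop size, deci-kcal
    multiloop_pen: int         # deci-kcal

    @property
    def max_len(self) -> int:
        return len(self.hairpin_pen) - 1


def _extend(table: dict, lo: int, hi: int) -> np.ndarray:
    out = np.zeros(hi + 1, dtype=np.int32)
    last = 0
    for s in range(lo, hi + 1):
        last = table.get(s, last)
        out[s] = last
    return out


def load_energy_model(max_len: int = MAX_FOLD_LEN) -> EnergyModel:
    """Load the versioned energy tables shipped with the package."""
    pair_ok = np.zeros((5, 5), dtype=np.bool_)
    for a, b in _PAIR_NAMES.values():
        pair_ok[a, b] = True
    stack = np.zeros((5, 5, 5, 5), dtype=np.int32)
    data = resources.files("slicerscan.data")
    with (data / "stack_energies.tsv").open() as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("pair5"):
                continue
            p5, p3, kcal = line.split()
            a, b = _PAIR_NAMES[p5]
            c, d = _PAIR_NAMES[p3]
            stack[a, b, c, d] = round(float(kcal) * 10)
    hp: dict = {}
    internal: dict = {}
    ml = 30
    with (data / "loop_penalties.tsv").open() as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("kind"):
                continue
            kind, size, kcal = line.split()
            deci = round(float(kcal) * 10)
            if kind == "hairpin":
                hp[int(size)] = deci
            elif kind == "internal":
                internal[int(size)] = deci
            elif kind == "multiloop":
                ml = deci
    return EnergyModel(
        stack=stack,
        pair_ok=pair_ok,
        hairpin_pen=_extend(hp, MIN_LOOP, max_len),
        internal_pen=_extend(internal, 1, max_len),
        multiloop_pen=ml,
    )


_DEFAULT_MODEL: EnergyModel | None = None


def default_model() -> EnergyModel:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = load_energy_model()
    return _DEFAULT_MODEL


def encode(seq: str) -> np.ndarray:
    codes = np.empty(len(seq), dtype=np.int8)
    for i, ch in enumerate(seq.upper()):
        if ch not in _BASE_CODE:
            raise ValueError(f"illegal character {ch!r} at position {i}")
        codes[i] = _BASE_CODE[ch]
    return codes


# ---------------------------------------------------------------------------
# dynamic programming kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _fill(codes, pair_ok, stack, hp_pen, int_pen, ml_pen):  # pragma: no cover
    n = codes.shape[0]
    INF = np.int64(1) << 50
    PACK = np.int64(1024)
    V = np.full((n, n), INF, dtype=np.int64)
    B = np.full((n, n), INF, dtype=np.int64)
    M2 = np.full((n, n), INF, dtype=np.int64)
    Wl = np.zeros(n + 1, dtype=np.int64)  # Wl[j+1] = exterior best on 0..j
    for span in range(2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1
            ci = codes[i]
            cj = codes[j]
            # V: best structure on i..j closed by pair (i, j)
            if pair_ok[ci, cj] and j - i - 1 >= 3:
                best = np.int64(hp_pen[j - i - 1]) * PACK
                if j - 1 - (i + 1) - 1 >= 3 and V[i + 1, j - 1] < INF:
                    cand = (np.int64(stack[ci, cj, codes[i + 1], codes[j - 1]])
                            * PACK + V[i + 1, j - 1])
                    if cand < best:
                        best = cand
                for ip in range(i + 1, j - 4 + 1):
                    for jp in range(ip + 4, j):
                        if ip == i + 1 and jp == j - 1:
                            continue
                        if V[ip, jp] >= INF:
                            continue
                        size = (ip - i - 1) + (j - jp - 1)
                        cand = np.int64(int_pen[size]) * PACK + V[ip, jp]
                        if cand < best:
                            best = cand
                if j - 1 - (i + 1) >= 0 and M2[i + 1, j - 1] < INF:
                    cand = np.int64(ml_pen) * PACK + M2[i + 1, j - 1]
                    if cand < best:
                        best = cand
                V[i, j] = best + 1  # own pair
            # B: >=1 helix branch inside i..j (multiloop interior component)
            b = B[i, j - 1] if j - 1 >= i else INF
            for k in range(i, j - 4 + 1):
                if V[k, j] >= INF:
                    continue
                pre = np.int64(0)
                if k > i and B[i, k - 1] < 0:
                    pre = B[i, k - 1]
                cand = V[k, j] + pre
                if cand < b:
                    b = cand
            B[i, j] = b
            # M2: >=2 branches inside i..j
            m2 = M2[i, j - 1] if j - 1 >= i else INF
            for k in range(i + 5, j - 4 + 1):
                if V[k, j] >= INF or B[i, k - 1] >= INF:
                    continue
                cand = B[i, k - 1] + V[k, j]
                if cand < m2:
                    m2 = cand
            M2[i, j] = m2
    for j in range(n):
        w = Wl[j]
        for k in range(0, j - 4 + 1):
            if V[k, j] < INF:
                cand = Wl[k] + V[k, j]
                if cand < w:
                    w = cand
        Wl[j + 1] = w
    return V, B, M2, Wl


@njit(cache=True)
def _mfe_cost(codes, pair_ok, stack, hp_pen, int_pen, ml_pen):  # pragma: no cover
    _, _, _, Wl = _fill(codes, pair_ok, stack, hp_pen, int_pen, ml_pen)
    return Wl[codes.shape[0]]


@njit(cache=True)
def _mfe_all(n, pair_ok, stack, hp_pen, int_pen, ml_pen):  # pragma: no cover
    """MFE deci-energy for every 4^n sequence of length n (base-4 order)."""
    total = 1
    for _ in range(n):
        total *= 4
    out = np.empty(total, dtype=np.int64)
    codes = np.empty(n, dtype=np.int8)
    for s in range(total):
        x = s
        for p in range(n - 1, -1, -1):
            codes[p] = x % 4
            x //= 4
        cost = _mfe_cost(codes, pair_ok, stack, hp_pen, int_pen, ml_pen)
        pmod = cost % 1024
        if pmod < 0:
            pmod += 1024
        out[s] = (cost - pmod) // 1024
    return out


def _unpack_energy(cost: int) -> tuple[int, int]:
    npairs = int(cost % _PACK)
    if npairs < 0:
        npairs += _PACK
    deci = (int(cost) - npairs) // _PACK
    return deci, npairs


# ---------------------------------------------------------------------------
# public fold API
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    sequence: str
    structure: str
    dg: float
    pairs: list = field(default_factory=list)
    loop: tuple | None = None
    arm5: tuple | None = None
    arm3: tuple | None = None

    @property
    def paired_fraction(self) -> float:
        if not self.sequence:
            return 0.0
        return 2 * len(self.pairs) / len(self.sequence)


def _traceback(codes, model, V, B, M2, Wl) -> list:
    n = codes.shape[0]
    PACK = _PACK
    pairs: list = []
    stack_t = model.stack
    hp = model.hairpin_pen
    ipen = model.internal_pen
    ml = model.multiloop_pen

    def trace_pair(i: int, j: int) -> None:
        pairs.append((i, j))
        rest = V[i, j] - 1
        if rest == int(hp[j - i - 1]) * PACK:
            return
        if (j - 1 - (i + 1) - 1 >= 3 and V[i + 1, j - 1] < _INF
                and rest == int(stack_t[codes[i], codes[j], codes[i + 1],
                                        codes[j - 1]]) * PACK + V[i + 1, j - 1]):
            trace_pair(i + 1, j - 1)
            return
        for ip in range(i + 1, j - 3):
            for jp in range(ip + 4, j):
                if ip == i + 1 and jp == j - 1:
                    continue
                if V[ip, jp] >= _INF:
                    continue
                size = (ip - i - 1) + (j - jp - 1)
                if rest == int(ipen[size]) * PACK + V[ip, jp]:
                    trace_pair(ip, jp)
                    return
        if M2[i + 1, j - 1] < _INF and rest == ml * PACK + M2[i + 1, j - 1]:
            trace_m2(i + 1, j - 1)
            return
        raise AssertionError("traceback failed at V")

    def trace_m2(i: int, j: int) -> None:
        while j - 1 >= i and M2[i, j] == M2[i, j - 1]:
            j -= 1
        for k in range(i + 5, j - 3):
            if V[k, j] >= _INF or B[i, k - 1] >= _INF:
                continue
            if M2[i, j] == B[i, k - 1] + V[k, j]:
                trace_pair(k, j)
                trace_b(i, k - 1)
                return
        raise AssertionError("traceback failed at M2")

    def trace_b(i: int, j: int) -> None:
        while j - 1 >= i and B[i, j] == B[i, j - 1]:
            j -= 1
        for k in range(i, j - 3):
            if V[k, j] >= _INF:
                continue
            pre = 0
            if k > i and B[i, k - 1] < 0:
                pre = int(B[i, k - 1])
            if B[i, j] == V[k, j] + pre:
                trace_pair(k, j)
                if pre != 0:
                    trace_b(i, k - 1)
                return
        raise AssertionError("traceback failed at B")

    j = n - 1
    while j >= 0:
        if Wl[j + 1] == Wl[j]:
            j -= 1
            continue
        found = False
        for k in range(0, j - 3):
            if V[k, j] < _INF and Wl[j + 1] == Wl[k] + V[k, j]:
                trace_pair(k, j)
                j = k - 1
                found = True
                break
        if not found:
            raise AssertionError("traceback failed at exterior")
    return sorted(pairs)


def fold_mfe(seq: str, model: EnergyModel | None = None) -> FoldResult:
    """Minimum-free-energy fold of ``seq`` under the simplified model.

    Ties are broken toward fewer pairs (exact secondary DP objective) and
    then by a fixed deterministic traceback order, so output is byte-stable.
    The all-unpaired structure (dG = 0) is always admissible, hence dG <= 0.
    """
    model = model or default_model()
    if not 1 <= len(seq) <= model.max_len:
        raise ValueError(f"sequence length {len(seq)} outside [1, {model.max_len}]")
    codes = encode(seq)
    if len(seq) < 5:
        return FoldResult(seq, "." * len(seq), 0.0)
    V, B, M2, Wl = _fill(codes, model.pair_ok, model.stack,
                         model.hairpin_pen, model.internal_pen,
                         np.int64(model.multiloop_pen))
    deci, _ = _unpack_energy(int(Wl[len(seq)]))
    pairs = _traceback(codes, model, V, B, M2, Wl) if deci < 0 else []
    structure = ["."] * len(seq)
    for i, j in pairs:
        structure[i] = "("
        structure[j] = ")"
    return _attach_anatomy(FoldResult(seq, "".join(structure), deci / 10.0, pairs))


def fold_all_lengths(n: int, model: EnergyModel | None = None) -> np.ndarray:
    """dG (deci-kcal, int) of every length-n sequence, in base-4 lexicographic
    order over the alphabet ACGU.  Used for exhaustive validation."""
    model = model or default_model()
    return _mfe_all(n, model.pair_ok, model.stack, model.hairpin_pen,
                    model.internal_pen, np.int64(model.multiloop_pen))


# ---------------------------------------------------------------------------
# exhaustive enumeration oracle
# ---------------------------------------------------------------------------

def enumerate_structures(n: int) -> list[tuple[tuple[int, int], ...]]:
    """All non-crossing pair sets on n positions with minimum loop 3."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def gen(i: int, j: int) -> tuple:
        if j - i + 1 < 5:
            return ((),)
        out = list(gen(i + 1, j))  # i unpaired
        for k in range(i + 4, j + 1):
            for inner in gen(i + 1, k - 1):
                for outer in gen(k + 1, j):
                    out.append(((i, k),) + inner + outer)
        return tuple(out)

    result = gen(0, n - 1)
    gen.cache_clear()
    return [tuple(sorted(s)) for s in result]


def structure_energy(codes: np.ndarray, pairs, model: EnergyModel) -> int | None:
    """Deci-kcal energy of an explicit structure; None if a pair is illegal.

    Scores by direct loop classification (hairpin / stack / internal /
    multiloop), independent of the DP recurrences.
    """
    for i, j in pairs:
        if not model.pair_ok[codes[i], codes[j]]:
            return None
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    total = 0
    for i, j in pairs:
        children = []
        k = i + 1
        while k < j:
            if k in partner and partner[k] > k:
                children.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        if not children:
            total += int(model.hairpin_pen[j - i - 1])
        elif len(children) == 1:
            ip, jp = children[0]
            if ip == i + 1 and jp == j - 1:
                total += int(model.stack[codes[i], codes[j], codes[ip], codes[jp]])
            else:
                size = (ip - i - 1) + (j - jp - 1)
                total += int(model.internal_pen[size])
        else:
            total += model.multiloop_pen
    return total


def _classify_terms(pairs):
    """Split a structure's energy into (constant-loop terms, stack steps).

    Returns ``(loops, stacks)`` where ``loops`` is a list of
    ('hairpin'|'internal'|'multiloop', size) and ``stacks`` a list of
    (i, j, i+1, j-1) index quadruples.
    """
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i
    loops, stacks = [], []
    for i, j in pairs:
        children = []
        k = i + 1
        while k < j:
            if k in partner and partner[k] > k:
                children.append((k, partner[k]))
                k = partner[k] + 1
            else:
                k += 1
        if not children:
            loops.append(("hairpin", j - i - 1))
        elif len(children) == 1:
            ip, jp = children[0]
            if ip == i + 1 and jp == j - 1:
                stacks.append((i, j, ip, jp))
            else:
                loops.append(("internal", (ip - i - 1) + (j - jp - 1)))
        else:
            loops.append(("multiloop", 0))
    return loops, stacks


@njit(cache=True)
def _oracle_all(n, pen, p_i, p_j, p_off, s_idx, s_off, pair_ok, stack):  # pragma: no cover
    total = 1
    for _ in range(n):
        total *= 4
    nstruct = pen.shape[0]
    out = np.zeros(total, dtype=np.int64)
    codes = np.empty(n, dtype=np.int8)
    for s in range(total):
        x = s
        for p in range(n - 1, -1, -1):
            codes[p] = x % 4
            x //= 4
        best = np.int64(0)
        for t in range(nstruct):
            ok = True
            for q in range(p_off[t], p_off[t + 1]):
                if not pair_ok[codes[p_i[q]], codes[p_j[q]]]:
                    ok = False
                    break
            if not ok:
                continue
            e = np.int64(pen[t])
            for q in range(s_off[t], s_off[t + 1], 4):
                e += stack[codes[s_idx[q]], codes[s_idx[q + 1]],
                           codes[s_idx[q + 2]], codes[s_idx[q + 3]]]
            if e < best:
                best = e
        out[s] = best
    return out


def oracle_all_lengths(n: int, model: EnergyModel | None = None) -> np.ndarray:
    """Brute-force MFE (deci-kcal) for every length-n sequence, by scoring
    every enumerated structure against every sequence.  Search is exhaustive
    and independent of the dynamic program; order matches
    :func:`fold_all_lengths`."""
    model = model or default_model()
    structs = enumerate_structures(n)
    structs = [s for s in structs if s]  # empty structure scores 0 implicitly
    pen = np.zeros(len(structs), dtype=np.int64)
    p_i, p_j, p_off = [], [], [0]
    s_idx, s_off = [], [0]
    for t, pairs in enumerate(structs):
        loops, stacks = _classify_terms(pairs)
        c = 0
        for kind, size in loops:
            if kind == "hairpin":
                c += int(model.hairpin_pen[size])
            elif kind == "internal":
                c += int(model.internal_pen[size])
            else:
                c += model.multiloop_pen
        pen[t] = c
        for i, j in pairs:
            p_i.append(i)
            p_j.append(j)
        p_off.append(len(p_i))
        for quad in stacks:
            s_idx.extend(quad)
        s_off.append(len(s_idx))
    return _oracle_all(
        n, pen,
        np.array(p_i, dtype=np.int32), np.array(p_j, dtype=np.int32),
        np.array(p_off, dtype=np.int32),
        np.array(s_idx if s_idx else [0], dtype=np.int32),
        np.array(s_off, dtype=np.int32),
        model.pair_ok, model.stack,
    )


def enumerate_mfe(seq: str, model: EnergyModel | None = None) -> float:
    """Exact MFE by brute-force enumeration of every structure (test oracle).

    Refuses sequences longer than 18 nt (combinatorial blow-up).
    """
    model = model or default_model()
    if len(seq) > MAX_ENUM_LEN:
        raise ValueError(f"enumeration limited to {MAX_ENUM_LEN} nt")
    codes = encode(seq)
    best = 0
    for pairs in enumerate_structures(len(seq)):
        e = structure_energy(codes, pairs, model)
        if e is not None and e < best:
            best = e
    return best / 10.0


# ---------------------------------------------------------------------------
# structure anatomy + dot-bracket helpers
# ---------------------------------------------------------------------------

def parse_dotbracket(structure: str) -> list[tuple[int, int]]:
    stack = []
    pairs = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at {i}")
            pairs.append((stack.pop(), i))
        elif ch != ".":
            raise ValueError(f"bad structure character {ch!r}")
    if stack:
        raise ValueError("unbalanced '(' remain")
    return sorted(pairs)


def hairpin_anatomy(fold: FoldResult):
    """Split a single-hairpin fold into (arm5, loop, arm3) intervals.

    Returns None when the structure is unpaired or has more than one
    terminal loop (two stems, multiloop).  Intervals are half-open in
    sequence coordinates.
    """
    pairs = fold.pairs or parse_dotbracket(fold.structure)
    if not pairs:
        return None
    # terminal loop = pair enclosing no other pair
    enclosed = []
    for i, j in pairs:
        inner = [p for p in pairs if i < p[0] and p[1] < j]
        if not inner:
            enclosed.append((i, j))
    if len(enclosed) != 1:
        return None
    i_star, j_star = enclosed[0]
    first = min(p[0] for p in pairs)
    last = max(p[1] for p in pairs)
    arm5 = (first, i_star + 1)
    loop = (i_star + 1, j_star)
    arm3 = (j_star, last + 1)
    return arm5, loop, arm3


def dominant_hairpin(fold: FoldResult):
    """(arm5, loop, arm3) of the main stem, tolerant of side structure.

    Picks the terminal loop supported by the deepest helix (pairs that
    enclose that loop and no other), so a small incidental stem in flanking
    sequence does not abolish the loop call the way the strict
    :func:`hairpin_anatomy` does.
    """
    pairs = fold.pairs or parse_dotbracket(fold.structure)
    if not pairs:
        return None
    terminal = [(i, j) for i, j in pairs
                if not any(i < a and b < j for a, b in pairs)]
    best = None
    for ti, tj in terminal:
        chain = [(i, j) for i, j in pairs
                 if i <= ti and tj <= j
                 and not any(i <= a and b <= j for a, b in terminal
                             if (a, b) != (ti, tj))]
        depth = len(chain)
        if best is None or depth > best[0]:
            first = min(i for i, _ in chain)
            last = max(j for _, j in chain)
            best = (depth, (first, ti + 1), (ti + 1, tj), (tj, last + 1))
    return best[1:] if best else None


def _attach_anatomy(res: FoldResult) -> FoldResult:
    anatomy = hairpin_anatomy(res) or dominant_hairpin(res)
    if anatomy is not None:
        res.arm5, res.loop, res.arm3 = anatomy
    return res


# ---------------------------------------------------------------------------
# optional external folder plug-in
# ---------------------------------------------------------------------------

def rnafold_folder(seq: str) -> FoldResult:
    """Fold with the external RNAfold program (ViennaRNA), if installed.

    Used as an optional plug-in folder for the scan; threshold decisions in
    the scanner are folder-agnostic.
    """
    rna = seq.upper().replace("T", "U")
    try:
        proc = subprocess.run(
            ["RNAfold", "--noPS"], input=rna, text=True,
            capture_output=True, check=True,
        )
    except FileNotFoundError as exc:
        raise RuntimeError("RNAfold binary not found on PATH") from exc
    lines = proc.stdout.strip().splitlines()
    struct_line = lines[-1]
    structure = struct_line.split()[0]
    dg = float(struct_line[struct_line.rindex("(") + 1:struct_line.rindex(")")])
    pairs = parse_dotbracket(structure)
    return _attach_anatomy(FoldResult(rna, structure, min(dg, 0.0), pairs))
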