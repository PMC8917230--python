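"""Secondary structure prediction: MFE, partition function, probabilities.

The dynamic programs use the ensemble energy convention
(:data:`~m6afold.energy.ENSEMBLE_OPTIONS`): terminal-stack decorations on
every multibranch/exterior helix end computed from both neighbouring bases,
no coaxial stacking, lonely pairs allowed, hairpin loops >= 3, interior
loops capped at ``params.max_loop`` unpaired nucleotides.  Under this
convention the MFE search, the exhaustive enumerator, and
:func:`~m6afold.energy.structure_energy` agree loop by loop, which is what
the oracle tests assert.

The partition function is McCaskill-style inside/outside over the same
model.  Besides pair probabilities it exposes the probability P_i that a
nucleotide is *buried in a helix* -- paired, with both neighbouring pairs
formed:

    P_i = (1/Q) * sum_j V'(i-1, j+1) K_stack(i-1,j+1,i,j)
                          K_stack(i,j,i+1,j-1) V(i+1, j-1)

with V the interior and V' the exterior partial partition function and
K_stack the Boltzmann factor of a helix stack.  Q normalises the sum so
each term is the joint probability that the three pairs coexist.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import RT37
from .energy import (ENSEMBLE_OPTIONS, EnergyError, _Seq,
                     hairpin_energy, internal_bulge_energy, structure_energy)
from .params import NNParameterSet
from .structure import SecondaryStructure, StructureError

_ENUM_LIMIT = 22


@dataclass(frozen=True)
class FoldResult:
    structure: SecondaryStructure
    dg37: float


# ----------------------------------------------------------------------
# shared model terms (ensemble convention)

class _Model:
    """Precomputed per-sequence terms of the ensemble energy model."""

    def __init__(self, params: NNParameterSet, seq: str):
        self.p = params
        self.s = _Seq(params, seq)
        self.n = self.s.n
        alpha = params.alphabet
        s = self.s
        self.can = [[False] * (self.n + 2) for _ in range(self.n + 2)]
        for i in range(1, self.n + 1):
            for j in range(i + 4, self.n + 1):
                self.can[i][j] = alpha.can_pair(s[i], s[j])

    def hairpin(self, i, j):
        return hairpin_energy(self.p, self.s, i, j)

    def interior(self, i, j, k, l):
        return internal_bulge_energy(self.p, self.s, i, j, k, l)

    def ml_branch(self, p, q):
        """Branch term inside a multibranch loop (without V)."""
        s, prm = self.s, self.p
        pair = s.pair(p, q)
        return (prm.ml_branch + prm.terminal_pair_penalty(pair)
                + prm.tstackm[(pair, s[p - 1], s[q + 1])])

    def ml_closing(self, i, j):
        """Closing-pair term of a multibranch loop (a + c + inward stack)."""
        s, prm = self.s, self.p
        pair = s.pair(j, i)
        return (prm.ml_closing + prm.ml_branch
                + prm.terminal_pair_penalty(pair)
                + prm.tstackm[(pair, s[j - 1], s[i + 1])])

    def ext_branch(self, p, q):
        """Exterior-loop term of a helix (p, q) (without V)."""
        s, prm = self.s, self.p
        pair = s.pair(p, q)
        e = prm.terminal_pair_penalty(pair)
        if p > 1 and q < self.n:
            e += prm.tstack[(pair, s[p - 1], s[q + 1])]
        elif p > 1:
            e += prm.dangle5[(pair, s[p - 1])]
        elif q < self.n:
            e += prm.dangle3[(pair, s[q + 1])]
        return e


# ----------------------------------------------------------------------
# exhaustive enumeration (test oracle)

def enumerate_structures(params: NNParameterSet, seq: str,
                         options=ENSEMBLE_OPTIONS):
    """Yield every valid nested structure with its energy (small inputs).

    The energies come from :func:`structure_energy` under *options*; the
    default is the ensemble convention the dynamic programs use, so the
    minimum over this stream equals the MFE.
    """
    s = _Seq(params, seq)
    n = s.n
    if n > _ENUM_LIMIT:
        raise ValueError(f"enumeration limited to length {_ENUM_LIMIT}")
    alpha = params.alphabet
    can = [[1 <= i <= n and i + 3 < j <= n and alpha.can_pair(s[i], s[j])
            for j in range(n + 2)] for i in range(n + 2)]

    from functools import lru_cache

    @lru_cache(maxsize=None)
    def region(i, j):
        """All pair-tuples over region i..j."""
        if i >= j:
            return (frozenset(),)
        out = list(region(i + 1, j))
        for k in range(i + 4, j + 1):
            if can[i][k]:
                inner = region(i + 1, k - 1)
                outer = region(k + 1, j)
                for a in inner:
                    base = a | {(i, k)}
                    for b in outer:
                        out.append(base | b)
        return tuple(out)

    for pairs in region(1, n):
        st = SecondaryStructure(n, pairs)
        yield st, structure_energy(params, seq, st, options)


# ----------------------------------------------------------------------
# MFE folding

def mfe_fold(params: NNParameterSet, seq: str) -> FoldResult:
    """Minimum free energy structure under the ensemble convention.

    Ties are broken deterministically (first decomposition found scanning
    pairing partners and split points in ascending order).
    """
    m = _Model(params, seq)
    n = m.n
    INF = math.inf
    maxl = m.p.max_loop
    b = m.p.ml_unpaired

    V = [[INF] * (n + 1) for _ in range(n + 2)]
    WM = [[INF] * (n + 1) for _ in range(n + 2)]
    WM2 = [[INF] * (n + 1) for _ in range(n + 2)]

    for span in range(4, n):
        for i in range(1, n - span + 1):
            j = i + span
            if m.can[i][j]:
                best = m.hairpin(i, j)
                for k in range(i + 1, j):
                    if k - i - 1 > maxl:
                        break
                    for l in range(max(k + 4, j - (maxl - (k - i - 1)) - 1),
                                   j):
                        if m.can[k][l] and (k, l) != (i, j):
                            e = m.interior(i, j, k, l) + V[k][l]
                            if e < best:
                                best = e
                if j - i >= 10:  # room for two branches
                    e = m.ml_closing(i, j) + WM2[i + 1][j - 1]
                    if e < best:
                        best = e
                V[i][j] = best
            # multibranch chain arrays (valid for 2 <= i, j <= n-1)
            if 2 <= i and j <= n - 1:
                best1 = WM[i][j - 1] + b if WM[i][j - 1] < INF else INF
                best2 = WM2[i][j - 1] + b if WM2[i][j - 1] < INF else INF
                for p in range(i, j - 3):
                    if m.can[p][j] and V[p][j] < INF:
                        bq = V[p][j] + m.ml_branch(p, j)
                        first = min(WM[i][p - 1] if p > i else INF,
                                    b * (p - i))
                        if first + bq < best1:
                            best1 = first + bq
                        if p > i and WM[i][p - 1] + bq < best2:
                            best2 = WM[i][p - 1] + bq
                WM[i][j] = best1
                WM2[i][j] = best2

    W = [0.0] * (n + 1)
    for j in range(1, n + 1):
        best = W[j - 1]
        for p in range(1, j - 3):
            if m.can[p][j] and V[p][j] < INF:
                e = W[p - 1] + m.ext_branch(p, j) + V[p][j]
                if e < best:
                    best = e
        W[j] = best

    # ------------------------------------------------------- traceback
    pairs: list[tuple[int, int]] = []
    eps = 1e-9

    def trace_v(i, j):
        pairs.append((i, j))
        e = V[i][j]
        if abs(e - m.hairpin(i, j)) < eps:
            return
        for k in range(i + 1, j):
            if k - i - 1 > maxl:
                break
            for l in range(max(k + 4, j - (maxl - (k - i - 1)) - 1), j):
                if m.can[k][l]:
                    if abs(e - (m.interior(i, j, k, l) + V[k][l])) < eps:
                        trace_v(k, l)
                        return
        if abs(e - (m.ml_closing(i, j) + WM2[i + 1][j - 1])) < eps:
            trace_wm(i + 1, j - 1, two=True)
            return
        raise AssertionError("traceback failed in V")

    def trace_wm(i, j, two):
        arr = WM2 if two else WM
        e = arr[i][j]
        if arr[i][j - 1] < INF and abs(e - (arr[i][j - 1] + b)) < eps:
            trace_wm(i, j - 1, two)
            return
        for p in range(i, j - 3):
            if m.can[p][j] and V[p][j] < INF:
                bq = V[p][j] + m.ml_branch(p, j)
                if two:
                    if p > i and abs(e - (WM[i][p - 1] + bq)) < eps:
                        trace_wm(i, p - 1, two=False)
                        trace_v(p, j)
                        return
                else:
                    first = min(WM[i][p - 1] if p > i else INF, b * (p - i))
                    if abs(e - (first + bq)) < eps:
                        if p > i and abs(first - WM[i][p - 1]) < eps \
                                and WM[i][p - 1] <= b * (p - i):
                            trace_wm(i, p - 1, two=False)
                        trace_v(p, j)
                        return
        raise AssertionError("traceback failed in WM")

    def trace_w(j):
        while j > 0:
            if abs(W[j] - W[j - 1]) < eps:
                j -= 1
                continue
            for p in range(1, j - 3):
                if m.can[p][j] and V[p][j] < INF:
                    if abs(W[j] - (W[p - 1] + m.ext_branch(p, j)
                                   + V[p][j])) < eps:
                        trace_v(p, j)
                        j = p - 1
                        break
            else:
                raise AssertionError("traceback failed in W")

    trace_w(n)
    st = SecondaryStructure(n, pairs)
    return FoldResult(st, structure_energy(params, seq, st, ENSEMBLE_OPTIONS))


# ----------------------------------------------------------------------
# partition function

@dataclass
class PartitionResult:
    """Inside/outside partition arrays and derived probabilities."""

    N: int
    Q: float
    pairprob: np.ndarray      # (N+1, N+1), symmetric, 1-based
    buried: np.ndarray        # (N+1,), 1-based
    _qv: dict
    _out: dict

    def V(self, i: int, j: int) -> float:
        """Interior partial partition function given i-j paired."""
        return self._qv.get((i, j), 0.0)

    def Vext(self, i: int, j: int) -> float:
        """Exterior partial partition function given i-j paired
        (includes the pair's decorations in its enclosing loop)."""
        return self._out.get((i, j), 0.0)


def partition(params: NNParameterSet, seq: str) -> PartitionResult:
    """Boltzmann ensemble over all nested structures (ensemble convention).

    ``Q = sum over structures of exp(-dG37/RT)``; overflow is raised as an
    error for sequences whose ensemble leaves float range (use windows).
    """
    m = _Model(params, seq)
    n = m.n
    maxl = m.p.max_loop
    rt = RT37

    def w(e):
        return math.exp(-e / rt)

    eb = w(m.p.ml_unpaired)

    QV: dict = {}
    QM = [[0.0] * (n + 1) for _ in range(n + 2)]
    QM2 = [[0.0] * (n + 1) for _ in range(n + 2)]
    ebp = [eb ** k for k in range(n + 2)]

    for span in range(4, n):
        for i in range(1, n - span + 1):
            j = i + span
            if m.can[i][j]:
                q = w(m.hairpin(i, j))
                for k in range(i + 1, j):
                    if k - i - 1 > maxl:
                        break
                    for l in range(max(k + 4, j - (maxl - (k - i - 1)) - 1),
                                   j):
                        if m.can[k][l]:
                            qv = QV.get((k, l))
                            if qv:
                                q += w(m.interior(i, j, k, l)) * qv
                if j - i >= 10:
                    q += w(m.ml_closing(i, j)) * QM2[i + 1][j - 1]
                if q:
                    QV[(i, j)] = q
            if 2 <= i and j <= n - 1:
                acc1 = QM[i][j - 1] * eb
                acc2 = QM2[i][j - 1] * eb
                for p in range(i, j - 3):
                    qv = QV.get((p, j))
                    if qv:
                        bq = qv * w(m.ml_branch(p, j))
                        left = QM[i][p - 1] if p > i else 0.0
                        acc1 += (left + ebp[p - i]) * bq
                        acc2 += left * bq
                QM[i][j] = acc1
                QM2[i][j] = acc2

    QW = [1.0] * (n + 1)
    for j in range(1, n + 1):
        acc = QW[j - 1]
        for p in range(1, j - 3):
            qv = QV.get((p, j))
            if qv:
                acc += QW[p - 1] * w(m.ext_branch(p, j)) * qv
        QW[j] = acc
    Q = QW[n]
    if not math.isfinite(Q):
        raise OverflowError(
            "partition function overflow; fold a shorter window")

    QWbar = [1.0] * (n + 2)
    for j in range(n, 0, -1):
        acc = QWbar[j + 1]
        for q in range(j + 4, n + 1):
            qv = QV.get((j, q))
            if qv:
                acc += w(m.ext_branch(j, q)) * qv * QWbar[q + 1]
        QWbar[j] = acc

    # outside pass, decreasing span
    OUT: dict = {}
    B1 = [[0.0] * (n + 2) for _ in range(n + 2)]
    B2 = [[0.0] * (n + 2) for _ in range(n + 2)]

    def cf(k, l):
        return w(m.ml_closing(k, l))

    spans = sorted({j - i for (i, j) in QV}, reverse=True)
    by_span: dict = {}
    for (i, j) in QV:
        by_span.setdefault(j - i, []).append((i, j))

    for span in spans:
        newly = []
        for (i, j) in sorted(by_span[span]):
            o = QW[i - 1] * w(m.ext_branch(i, j)) * QWbar[j + 1]
            for k in range(max(1, i - maxl - 1), i):
                if (i - k - 1) > maxl:
                    continue
                for l in range(j + 1, min(n, j + 1 + (maxl - (i - k - 1)))
                               + 1):
                    ok = OUT.get((k, l))
                    if ok and m.can[k][l]:
                        o += w(m.interior(k, l, i, j)) * ok
            # multibranch contexts via the helper sums
            if 2 <= i and j <= n - 1:
                wml = w(m.ml_branch(i, j))
                acc = 0.0
                for k in range(1, i - 1 + 1):
                    if B1[k][j] and k + 1 <= i - 1 and QM[k + 1][i - 1]:
                        acc += QM[k + 1][i - 1] * B1[k][j]
                    if B2[k][j]:
                        acc += ebp[i - 1 - k] * B2[k][j]
                o += wml * acc
            if o:
                OUT[(i, j)] = o
                newly.append((i, j))
        for (k, l) in newly:
            a = OUT[(k, l)] * cf(k, l)
            if not a:
                continue
            for jj in range(k + 1, l):
                qmx = (QM[jj + 1][l - 1] if jj + 1 <= l - 1 else 0.0) \
                    + ebp[l - 1 - jj]
                B1[k][jj] += a * qmx
                qm = QM[jj + 1][l - 1] if jj + 1 <= l - 1 else 0.0
                if qm:
                    B2[k][jj] += a * qm

    pairprob = np.zeros((n + 1, n + 1))
    for (i, j), qv in QV.items():
        p = qv * OUT.get((i, j), 0.0) / Q
        pairprob[i, j] = pairprob[j, i] = p

    buried = np.zeros(n + 1)
    s = m.s
    for x in range(2, n):
        for y in range(x + 5, n):
            if not (m.can[x][y] and m.can[x - 1][y + 1]
                    and m.can[x + 1][y - 1]):
                continue
            outer = OUT.get((x - 1, y + 1))
            inner = QV.get((x + 1, y - 1))
            if not outer or not inner:
                continue
            k1 = w(m.p.stack[(s.pair(x - 1, y + 1), s.pair(y, x))])
            k2 = w(m.p.stack[(s.pair(x, y), s.pair(y - 1, x + 1))])
            p = outer * k1 * k2 * inner / Q
            buried[x] += p
            buried[y] += p

    return PartitionResult(N=n, Q=Q, pairprob=pairprob, buried=buried,
                           _qv=QV, _out=OUT)


def buried_probability(params: NNParameterSet, seq: str) -> np.ndarray:
    """P_i that each nucleotide is paired and stacked between two pairs.

    Returns a length-N vector (0-based index i-1 for nucleotide i).
    """
    return partition(params, seq).buried[1:]


# ----------------------------------------------------------------------
# accessibility and windows

def opening_cost(params: NNParameterSet, seq: str,
                 closed: SecondaryStructure, open_: SecondaryStructure,
                 options=None) -> float:
    """dG37 of converting *closed* into the sub-structure *open_* (both
    evaluated with full efn2 semantics by default)."""
    if not open_.is_substructure_of(closed):
        raise StructureError("open structure must be a sub-structure of "
                             "the closed structure")
    kw = {} if options is None else {"options": options}
    return (structure_energy(params, seq, open_, **kw)
            - structure_energy(params, seq, closed, **kw))


@dataclass(frozen=True)
class WindowProfile:
    start: int            # 1-based window start in the long sequence
    end: int              # inclusive
    site_offset: int      # 1-based position of the site within the window
    buried: np.ndarray    # per-window-nucleotide P_i


def window_bounds(length: int, site_index: int,
                  window: int = 800) -> tuple[int, int]:
    """1-based inclusive window bounds placing the site at position
    ``window//2 + 1`` (the 401st for the default 800), clamped at the
    sequence ends."""
    if length == 0:
        raise ValueError("empty sequence")
    if not 1 <= site_index <= length:
        raise ValueError(f"site {site_index} outside 1..{length}")
    anchor = window // 2 + 1
    start = max(1, site_index - (anchor - 1))
    end = start + window - 1
    if end > length:
        end = length
        start = max(1, end - window + 1)
    return start, end


def window_profile(params: NNParameterSet, long_seq: str, site_index: int,
                   window: int = 800) -> WindowProfile:
    """Buried-in-helix profile of a window centred on a site of interest.

    A window of at most *window* nucleotides is cut with the site at
    position ``window//2 + 1`` (the 401st for the default 800) whenever the
    flanks allow, clamping at the sequence ends otherwise.
    """
    seq = params.alphabet.canonicalize(long_seq)
    start, end = window_bounds(len(seq), site_index, window)
    sub = seq[start - 1:end]
    prof = buried_probability(params, sub)
    return WindowProfile(start=start, end=end,
                         site_offset=site_index - start + 1, buried=prof)
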