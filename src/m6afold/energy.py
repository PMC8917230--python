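"""Free-energy evaluation of duplexes and nested secondary structures.

Implements the loop-decomposition (efn2-style) evaluator over an
:class:`~m6afold.params.NNParameterSet`: helix stacks, hairpin loops with
special-sequence overrides, bulge and interior loops (small-loop lookup
tables, 1xn / 2x3 / generic decompositions with asymmetry), multibranch
loops with a linear model, and exterior loops.

Two decoration conventions for helix ends in multibranch/exterior loops are
supported through :class:`EnergyOptions`:

``dangle_min`` (default)
    every unpaired nucleotide adjacent to a helix end contributes the more
    favourable of its 5'/3' dangle options, counted once; coaxial stacking
    may be enabled on top (exhaustive per-loop enumeration).

``mismatch``
    every helix end contributes a terminal-stack term computed from both
    neighbouring bases regardless of their pairing status (the convention
    the folding dynamic programs use: it decomposes exactly, so the
    minimum-free-energy search, the partition function, and this evaluator
    agree structure by structure).

Coordinates are 1-based throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import NNParameterSet, ParameterError
from .structure import SecondaryStructure, StructureError


class EnergyError(ValueError):
    pass


@dataclass(frozen=True)
class EnergyOptions:
    terminal_stacking: str = "dangle_min"  # dangle_min | mismatch | none
    coaxial: bool = True


#: convention used by the MFE / partition dynamic programs
ENSEMBLE_OPTIONS = EnergyOptions(terminal_stacking="mismatch", coaxial=False)
DEFAULT_OPTIONS = EnergyOptions()


class _Seq:
    """1-based canonicalized sequence view."""

    __slots__ = ("s", "n")

    def __init__(self, params: NNParameterSet, seq: str):
        self.s = " " + params.alphabet.canonicalize(seq)
        self.n = len(self.s) - 1

    def __getitem__(self, i: int) -> str:
        return self.s[i]

    def pair(self, i: int, j: int) -> str:
        return self.s[i] + self.s[j]


# ----------------------------------------------------------------------
# elementary terms

def stack_energy(params: NNParameterSet, pair1: str, pair2: str) -> float:
    """Stack of *pair1* followed by *pair2*, both written (5' base, 3' base).

    ``stack_energy(p, "6U", "UA")`` is the helix stack 5'(6U)(UA)3'.
    """
    key = (pair1, pair2[::-1])
    try:
        return params.stack[key]
    except KeyError:
        raise EnergyError(f"disallowed stack context {pair1}/{pair2}") from None


def terminal_end_adjustment(params: NNParameterSet, pair: str) -> float:
    """Penalty for ending a helix on *pair*, applied once per helix end."""
    return params.terminal_pair_penalty(pair)


def _hairpin_extras(params, s: _Seq, i: int, j: int) -> float:
    """2004-rule hairpin extras not folded into the mismatch table:
    oligo-C loops and the G-U closure preceded by two G's."""
    extra = 0.0
    size = j - i - 1
    if all(s[x] == "C" for x in range(i + 1, j)):
        extra += 1.4 if size == 3 else 0.3 * size + 1.6
    if s.pair(i, j) == "GU" and i >= 3 and s[i - 1] == "G" and s[i - 2] == "G":
        extra += -2.2
    return extra


def _loop_init(table: dict, size: int, lxc: float) -> float:
    if size in table:
        return table[size]
    longest = max(table)
    if size > longest:
        return table[longest] + lxc * math.log(size / longest)
    raise EnergyError(f"no initiation for loop size {size}")


def hairpin_energy(params: NNParameterSet, seq, i: int, j: int) -> float:
    """Hairpin loop closed by (i, j); *seq* may be a str or _Seq."""
    s = seq if isinstance(seq, _Seq) else _Seq(params, seq)
    size = j - i - 1
    if size < 3:
        raise EnergyError(f"hairpin of pair ({i},{j}) shorter than 3")
    if not params.alphabet.can_pair(s[i], s[j]):
        raise EnergyError(f"pair {s[i]}-{s[j]} not allowed")
    full = "".join(s[x] for x in range(i, j + 1))
    if full in params.special_hairpins:
        return params.special_hairpins[full]
    init = _loop_init(params.hairpin_init, size, params.lxc)
    if size == 3:
        return init + params.terminal_pair_penalty(s.pair(i, j)) \
            + _hairpin_extras(params, s, i, j)
    mm = params.tstackh[(s.pair(i, j), s[i + 1], s[j - 1])]
    return init + mm + _hairpin_extras(params, s, i, j)


def internal_bulge_energy(params: NNParameterSet, seq, i: int, j: int,
                          k: int, l: int) -> float:
    """Bulge or interior loop between outer pair (i, j) and inner (k, l)."""
    s = seq if isinstance(seq, _Seq) else _Seq(params, seq)
    if not (i < k < l < j):
        raise EnergyError(f"malformed loop geometry ({i},{j})/({k},{l})")
    n1, n2 = k - i - 1, j - l - 1
    pij = s.pair(i, j)
    plk = s.pair(l, k)  # inner pair read from the j side
    for p in (pij, plk):
        if tuple(p) not in params.alphabet.pairs:
            raise EnergyError(f"pair {p} not allowed")
    if n1 == 0 and n2 == 0:
        return params.stack[(pij, plk)]
    if n1 == 0 or n2 == 0:
        n = n1 + n2
        if n == 1:
            # single-nucleotide bulge: cross stack kept, bulged base ignored
            return params.bulge_init[1] + params.stack[(pij, plk)]
        return (_loop_init(params.bulge_init, n, params.lxc)
                + params.terminal_pair_penalty(pij)
                + params.terminal_pair_penalty(plk))
    if n1 == 1 and n2 == 1:
        return params.int11[(pij, plk, s[i + 1], s[j - 1])]
    if n1 == 1 and n2 == 2:
        return params.int21[(pij, plk, s[i + 1], s[l + 1], s[j - 1])]
    if n1 == 2 and n2 == 1:
        return params.int21[(plk, pij, s[l + 1], s[i + 1], s[k - 1])]
    if n1 == 2 and n2 == 2:
        return params.int22[(pij, plk, s[i + 1], s[k - 1], s[l + 1], s[j - 1])]
    init = _loop_init(params.internal_init, n1 + n2, params.lxc)
    asym = min(params.ninio_max, abs(n1 - n2) * params.ninio)
    if min(n1, n2) == 1:
        mm1 = params.tstacki1n[(pij, s[i + 1], s[j - 1])]
        mm2 = params.tstacki1n[(plk, s[l + 1], s[k - 1])]
    elif (n1, n2) in ((2, 3), (3, 2)):
        mm1 = params.tstacki23[(pij, s[i + 1], s[j - 1])]
        mm2 = params.tstacki23[(plk, s[l + 1], s[k - 1])]
    else:
        mm1 = params.tstacki[(pij, s[i + 1], s[j - 1])]
        mm2 = params.tstacki[(plk, s[l + 1], s[k - 1])]
    return init + asym + mm1 + mm2


# ----------------------------------------------------------------------
# loop decorations (multibranch / exterior)

def _branch_term_mismatch(params, s, i, j, interior_facing=False):
    """d2-style end term for a helix (i, j) seen from the loop outside it
    (or inside it for a multibranch closing pair, with *interior_facing*)."""
    if interior_facing:
        pair = s.pair(j, i)
        x, y = s[j - 1], s[i + 1]
        return params.tstackm[(pair, x, y)] + params.terminal_pair_penalty(pair)
    pair = s.pair(i, j)
    pen = params.terminal_pair_penalty(pair)
    if i > 1 and j < s.n:
        return params.tstack[(pair, s[i - 1], s[j + 1])] + pen
    if i > 1:
        return params.dangle5[(pair, s[i - 1])] + pen
    if j < s.n:
        return params.dangle3[(pair, s[j + 1])] + pen
    return pen


def _ml_branch_term_mismatch(params, s, i, j):
    pair = s.pair(i, j)
    return params.tstackm[(pair, s[i - 1], s[j + 1])] \
        + params.terminal_pair_penalty(pair)


def _loop_dangles_min(params, s, partner, ends, unpaired):
    """Per-nucleotide best-dangle decoration.

    *ends* is a list of helix ends as tuples (pair_name, five_pos,
    three_pos): the positions 5' and 3' adjacent to that end, or None.
    *unpaired* is the set of unpaired positions in the loop.  Each unpaired
    position adjacent to at least one end contributes the most favourable
    available dangle, once.
    """
    options: dict[int, list[float]] = {}
    for pair, five, three in ends:
        if five is not None and five in unpaired:
            options.setdefault(five, []).append(params.dangle5[(pair, s[five])])
        if three is not None and three in unpaired:
            options.setdefault(three, []).append(params.dangle3[(pair, s[three])])
    return sum(min(v) for v in options.values())


def _coax_flush(params, s, q, p, r, t):
    """Flush coaxial stack: helix ending (p, q) abutting helix (r, t),
    r = q + 1; evaluated as the helix stack of the junction."""
    return params.stack[(s.pair(q, p), s.pair(t, r))]


def _enumerate_coax(params, s, branches, unpaired, cyclic):
    """Best decoration of a multibranch/exterior loop with coaxial stacking.

    *branches* are (i, j) pairs in loop order; for a multibranch loop the
    flipped closing pair is the first entry and the list is cyclic.
    Returns the minimum over configurations of non-overlapping coaxial
    stacks at junctions with 0 or 1 intervening unpaired nucleotides, with
    per-nucleotide best dangles for everything unclaimed.
    """
    k = len(branches)
    junctions = []
    for t in range(k if cyclic else k - 1):
        a = branches[t]
        b = branches[(t + 1) % k]
        gap_start, gap_end = a[1] + 1, b[0] - 1
        gap = gap_end - gap_start + 1
        if cyclic and gap < 0:
            continue
        if gap == 0:
            junctions.append((t, (t + 1) % k, _coax_flush(
                params, s, a[1], a[0], b[0], b[1]), ()))
        elif gap == 1:
            x = gap_start
            opts = []
            # the intervening base forms a discontinuous-backbone stack
            # with a neighbour of either helix, when that base is free
            w = a[0] - 1
            if w >= 1 and w in unpaired:
                opts.append((params.tstackm[(s.pair(a[1], a[0]), s[x], s[w])]
                             + params.coax_discontinuous, (x, w)))
            v = b[1] + 1
            if v <= s.n and v in unpaired:
                opts.append((params.tstackm[(s.pair(b[1], b[0]), s[v], s[x])]
                             + params.coax_discontinuous, (x, v)))
            for e, used in opts:
                junctions.append((t, (t + 1) % k, e, used))

    ends = []
    for (i, j) in branches:
        five = i - 1 if i > 1 else None
        three = j + 1 if j <= s.n - 1 else None
        ends.append((s.pair(i, j), five, three))

    best = math.inf
    m = len(junctions)
    for mask in range(1 << m):
        chosen = [junctions[t] for t in range(m) if mask >> t & 1]
        used_branches = [b for (a, b2, _, _) in chosen for b in (a, b2)]
        if len(set(used_branches)) != len(used_branches):
            continue
        used_nts = {x for (_, _, _, nts) in chosen for x in nts}
        coax_e = sum(e for (_, _, e, _) in chosen)
        free_ends = [ends[t] for t in range(k)
                     if t not in set(used_branches)]
        free_unpaired = unpaired - used_nts
        e = coax_e + _loop_dangles_min(params, s, None, free_ends,
                                       free_unpaired)
        best = min(best, e)
    return best


# ----------------------------------------------------------------------
# whole-structure evaluation

def _children(partner, i, j):
    out = []
    x = i + 1
    while x < j:
        if partner[x] > x:
            out.append((x, partner[x]))
            x = partner[x] + 1
        else:
            x += 1
    return out


def structure_energy(params: NNParameterSet, seq: str,
                     structure: SecondaryStructure,
                     options: EnergyOptions = DEFAULT_OPTIONS,
                     _breakdown: list | None = None) -> float:
    """Folding free energy change of *structure* (kcal/mol, efn2 semantics).

    Pass ``options=ENSEMBLE_OPTIONS`` for the convention used by the
    folding dynamic programs.
    """
    s = _Seq(params, seq)
    if structure.length != s.n:
        raise StructureError("structure length does not match sequence")
    for i, j in structure.pairs:
        if not params.alphabet.can_pair(s[i], s[j]):
            raise StructureError(f"pair {s[i]}{i}-{s[j]}{j} not allowed")
    partner = structure.partner()
    total = 0.0

    def note(kind, detail, e):
        if _breakdown is not None:
            _breakdown.append((kind, detail, e))

    # exterior loop
    top = _children(partner, 0, s.n + 1)
    e = _decorate_loop(params, s, top, partner, options, closing=None)
    note("exterior", tuple(top), e)
    total += e

    stack_run = []
    for (i, j) in sorted(structure.pairs):
        kids = _children(partner, i, j)
        if not kids:
            e = hairpin_energy(params, s, i, j)
            note("hairpin", (i, j), e)
        elif len(kids) == 1:
            (k, l) = kids[0]
            e = internal_bulge_energy(params, s, i, j, k, l)
            kind = "stack" if (k, l) == (i + 1, j - 1) else "internal"
            note(kind, (i, j, k, l), e)
        else:
            e = _decorate_loop(params, s, kids, partner, options,
                               closing=(i, j))
            note("multibranch", (i, j), e)
        total += e
    return total


def _decorate_loop(params, s, branches, partner, options, closing):
    """Energy of a multibranch (closing != None) or exterior loop."""
    if closing is not None:
        i, j = closing
        inside = set(range(i + 1, j))
        unpaired = {x for x in inside if partner[x] == 0}
        base = (params.ml_closing
                + params.ml_unpaired * len(unpaired)
                + params.ml_branch * (len(branches) + 1))
    else:
        unpaired = {x for x in range(1, s.n + 1) if partner[x] == 0}
        base = 0.0

    if options.terminal_stacking == "none":
        deco = sum(params.terminal_pair_penalty(s.pair(p, q))
                   for p, q in branches)
        if closing is not None:
            deco += params.terminal_pair_penalty(s.pair(j, i))
        return base + deco

    if options.terminal_stacking == "mismatch":
        deco = sum(
            _ml_branch_term_mismatch(params, s, p, q) if closing is not None
            else _branch_term_mismatch(params, s, p, q)
            for p, q in branches)
        if closing is not None:
            deco += _branch_term_mismatch(params, s, i, j,
                                          interior_facing=True)
        return base + deco

    # dangle_min (+ optional coaxial)
    pens = sum(params.terminal_pair_penalty(s.pair(p, q)) for p, q in branches)
    loop_branches = list(branches)
    if closing is not None:
        pens += params.terminal_pair_penalty(s.pair(j, i))
        # flipped closing pair participates in the loop like a branch
        loop_branches = [(j, i)] + loop_branches

    if options.coaxial and len(loop_branches) >= 2:
        if closing is not None:
            deco = _enumerate_coax_ml(params, s, closing, branches, unpaired)
        else:
            deco = _enumerate_coax(params, s, loop_branches, unpaired,
                                   cyclic=False)
        return base + pens + deco

    ends = []
    for (p, q) in branches:
        ends.append((s.pair(p, q),
                     p - 1 if p > 1 else None,
                     q + 1 if q < s.n else None))
    if closing is not None:
        # interior-facing decorations of the closing pair
        ends.append((s.pair(j, i), j - 1, i + 1))
    deco = _loop_dangles_min(params, s, partner, ends, unpaired)
    return base + pens + deco


def _enumerate_coax_ml(params, s, closing, branches, unpaired):
    """Coaxial enumeration inside a multibranch loop: the flipped closing
    pair joins the branch cycle."""
    i, j = closing

    class _View:
        """Index view that lets the closing pair act like a branch (j, i)."""
        pass

    # represent the cycle explicitly: closing pair flipped, then branches.
    # junction gaps are computed on the real coordinates.
    cyc = [(None, (j, i))] + [((p, q), (p, q)) for p, q in branches]
    k = len(cyc)
    junctions = []
    for t in range(k):
        (_, a) = cyc[t]
        (_, b) = cyc[(t + 1) % k]
        # 3' end of a within the loop / 5' end of b within the loop
        a_end = i if a == (j, i) else a[1]
        b_start = j if b == (j, i) else b[0]
        gap_positions = []
        x = a_end + 1
        while x != b_start and x <= j:
            gap_positions.append(x)
            x += 1
        gap = len(gap_positions)
        if gap == 0:
            if a == (j, i):
                e = params.stack[(s.pair(j, i), s.pair(b[1], b[0]))]
            elif b == (j, i):
                e = params.stack[(s.pair(a[1], a[0]), s.pair(i, j))]
            else:
                e = _coax_flush(params, s, a[1], a[0], b[0], b[1])
            junctions.append((t, (t + 1) % k, e, ()))
        elif gap == 1:
            x = gap_positions[0]
            opts = []
            a_pair = s.pair(a[1], a[0]) if a != (j, i) else s.pair(j, i)
            a_far = (a[0] - 1) if a != (j, i) else j - 1
            if a_far in unpaired:
                opts.append((params.tstackm[(a_pair, s[x], s[a_far])]
                             + params.coax_discontinuous, (x, a_far)))
            b_pair = s.pair(b[1], b[0]) if b != (j, i) else s.pair(j, i)
            b_far = (b[1] + 1) if b != (j, i) else i + 1
            if b_far in unpaired:
                opts.append((params.tstackm[(b_pair, s[b_far], s[x])]
                             + params.coax_discontinuous, (x, b_far)))
            for e, used in opts:
                junctions.append((t, (t + 1) % k, e, used))

    ends = []
    for (_, a) in cyc:
        if a == (j, i):
            ends.append((s.pair(j, i), j - 1, i + 1))
        else:
            ends.append((s.pair(a[0], a[1]), a[0] - 1, a[1] + 1))

    best = math.inf
    m = len(junctions)
    for mask in range(1 << m):
        chosen = [junctions[t] for t in range(m) if mask >> t & 1]
        used_branches = [b for (x, y, _, _) in chosen for b in (x, y)]
        if len(set(used_branches)) != len(used_branches):
            continue
        used_nts = {x for (_, _, _, nts) in chosen for x in nts}
        coax_e = sum(e for (_, _, e, _) in chosen)
        free_ends = [ends[t] for t in range(k) if t not in set(used_branches)]
        e = coax_e + _loop_dangles_min(params, s, None, free_ends,
                                       unpaired - used_nts)
        best = min(best, e)
    return best


# ----------------------------------------------------------------------
# duplexes

@dataclass(frozen=True)
class DuplexSpec:
    """Two strands written 5'->3'; *strand2* defaults to *strand1* for a
    self-complementary duplex.  *pairs* optionally lists (i on strand1,
    j on strand2) base pairs; by default every pairable position of the
    antiparallel register strand1[i] : strand2[n2+1-i] is paired."""

    strand1: str
    strand2: str | None = None
    self_complementary: bool | None = None
    pairs: tuple[tuple[int, int], ...] | None = None

    def resolved(self, params):
        s1 = params.alphabet.canonicalize(self.strand1)
        s2 = params.alphabet.canonicalize(self.strand2 or self.strand1)
        selfc = self.self_complementary
        if selfc is None:
            selfc = self.strand2 is None or s1 == s2
        return s1, s2, selfc


def duplex_energy(params: NNParameterSet, duplex: DuplexSpec | str,
                  structure=None) -> float:
    """Folding free energy change of a duplex (kcal/mol).

    dG37 = duplex initiation + stacks/loops + helix-end adjustments
    + terminal mismatch/dangle decorations of unpaired overhangs
    + symmetry correction for self-complementary duplexes.
    """
    if isinstance(duplex, str):
        duplex = DuplexSpec(duplex)
    s1, s2, selfc = duplex.resolved(params)
    n1, n2 = len(s1), len(s2)
    if duplex.pairs is not None:
        pairs12 = sorted(duplex.pairs)
    elif structure is not None:
        pairs12 = sorted(structure)
    else:
        if n1 != n2:
            raise EnergyError("register pairing needs equal strand lengths "
                              "(pass explicit pairs otherwise)")
        pairs12 = [(i, n2 + 1 - i) for i in range(1, n1 + 1)
                   if params.alphabet.can_pair(s1[i - 1], s2[n2 - i])]
    if not pairs12:
        raise EnergyError("unpairable register: no base pairs in duplex")
    for a in range(len(pairs12) - 1):
        if not (pairs12[a][0] < pairs12[a + 1][0]
                and pairs12[a][1] > pairs12[a + 1][1]):
            raise EnergyError("duplex pairs must be nested in the register")

    # concatenated view: strand1 then strand2; pair (i, j) -> (i, n1 + j)
    s = _Seq(params, s1 + s2)
    cp = [(i, n1 + j) for i, j in pairs12]

    total = params.duplex_init
    if selfc:
        total += params.symmetry_corr

    # interior loops / stacks between consecutive pairs
    for (i, j), (k, l) in zip(cp, cp[1:]):
        total += internal_bulge_energy(params, s, i, j, k, l)

    # outer (left) end of the duplex
    i, j = cp[0]
    pair = s.pair(i, j)
    total += params.terminal_pair_penalty(pair)
    has5 = i > 1
    has3 = j < s.n
    if has5 and has3:
        total += params.tstack[(pair, s[i - 1], s[j + 1])]
    elif has5:
        total += params.dangle5[(pair, s[i - 1])]
    elif has3:
        total += params.dangle3[(pair, s[j + 1])]

    # inner (right) end, read from the other strand
    i, j = cp[-1]
    pair = s.pair(j, i)
    total += params.terminal_pair_penalty(pair)
    has5 = j > n1 + 1   # unpaired 5' overhang on strand2 side
    has3 = i < n1       # unpaired 3' overhang on strand1 side
    if has5 and has3:
        total += params.tstack[(pair, s[j - 1], s[i + 1])]
    elif has5:
        total += params.dangle5[(pair, s[j - 1])]
    elif has3:
        total += params.dangle3[(pair, s[i + 1])]
    return total
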