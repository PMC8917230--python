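"""Nearest-neighbor parameter sets and their plain-text table dialect.

A :class:`NNParameterSet` holds every free-energy table of the 2004-style
nearest-neighbor model at 37 degC: helix stacks, dangling ends, terminal
mismatches (separate tables for exterior helix ends, hairpin closures,
interior-loop closures of the 1xn / 2x3 / generic kinds, and multibranch
ends), the 1x1 / 2x1 / 2x2 interior-loop lookup tables, length-dependent
loop initiations, tabulated special hairpin loops, multibranch-loop linear
coefficients, and the duplex initiation / symmetry / terminal-pair
constants.

Tables are stored on disk as whitespace-delimited numeric grids, one file
per table, with ``#`` comments carrying the index order and an optional
``scale:`` directive; disallowed contexts are ``NA``.  ``read_parameter_set``
/ ``write_parameter_set`` round-trip values exactly.

The m6A parameter set is not stored expanded on disk: it is constructed by
:func:`build_m6a_tables` from the rna set, the 15 fitted m6A-U helix stacks,
and any directly measured loop motifs, following the substitution rules of
the m6A nearest-neighbor model (see docs/methods.md).

Index conventions (mirroring the field's standard tables):

* a base pair is a two-character string ``XY`` meaning X at the 5' position
  i paired to Y at j;
* ``stack[(p1, p2)]`` is the stack of outer pair ``p1`` = (i, j) over the
  inner pair read from the j-side, ``p2`` = (j-1, i+1); strand reversal is
  the transposition ``(p2, p1)``;
* mismatch tables are keyed ``(closing pair, 5' nt, 3' nt)``;
* ``int11[(p1, p2, x, y)]``, ``int21[(p1, p2, x, y1, y2)]`` and
  ``int22[(p1, p2, a, b, c, d)]`` follow the standard inner-pair-reversed
  convention documented in each table file.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

from .alphabet import Alphabet, m6a_alphabet, rna_alphabet

_TABLE_FILES = (
    "stack", "dangle5", "dangle3", "tstack", "tstackh", "tstacki",
    "tstacki1n", "tstacki23", "tstackm", "int11", "int21", "int22",
    "loops", "special_hairpins", "misc",
)


class ParameterError(ValueError):
    """Missing table file, dimension mismatch, or malformed cell."""


@dataclass(frozen=True)
class MeasuredMotif:
    """A loop motif whose stability was measured directly.

    Measured values take precedence over every rule-based estimate when the
    m6A tables are assembled.

    ``motif_kind`` is one of ``dangle5``, ``dangle3``, ``terminal_mismatch``;
    ``context`` is ``(closing pair, nt)`` for dangles and
    ``(closing pair, nt5, nt3)`` for mismatches.
    """

    motif_kind: str
    context: tuple[str, ...]
    dg37: float
    sigma: float = 0.0

    def __post_init__(self):
        if self.motif_kind not in ("dangle5", "dangle3", "terminal_mismatch"):
            raise ValueError(f"unknown motif kind {self.motif_kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass
class NNParameterSet:
    alphabet: Alphabet
    stack: dict = field(default_factory=dict)
    dangle5: dict = field(default_factory=dict)
    dangle3: dict = field(default_factory=dict)
    tstack: dict = field(default_factory=dict)      # exterior terminal mismatch
    tstackh: dict = field(default_factory=dict)     # hairpin closure mismatch
    tstacki: dict = field(default_factory=dict)     # generic interior closure
    tstacki1n: dict = field(default_factory=dict)   # 1xn interior closure
    tstacki23: dict = field(default_factory=dict)   # 2x3 interior closure
    tstackm: dict = field(default_factory=dict)     # multibranch end stack
    int11: dict = field(default_factory=dict)
    int21: dict = field(default_factory=dict)
    int22: dict = field(default_factory=dict)
    hairpin_init: dict = field(default_factory=dict)
    bulge_init: dict = field(default_factory=dict)
    internal_init: dict = field(default_factory=dict)
    special_hairpins: dict = field(default_factory=dict)
    end_penalty: dict = field(default_factory=dict)  # per pair, at helix ends
    duplex_init: float = 4.09
    symmetry_corr: float = 0.43
    ninio: float = 0.6
    ninio_max: float = 3.0
    ml_closing: float = 9.3
    ml_unpaired: float = 0.0
    ml_branch: float = -0.9
    coax_discontinuous: float = -2.1
    lxc: float = 1.07856
    max_loop: int = 30

    # ------------------------------------------------------------------
    @property
    def pair_names(self) -> tuple[str, ...]:
        return self.alphabet.pair_names

    def terminal_pair_penalty(self, pair: str) -> float:
        """Free-energy cost of ending a helix on *pair* (kcal/mol)."""
        try:
            return self.end_penalty[pair]
        except KeyError:
            raise ParameterError(f"pair {pair!r} not allowed in alphabet "
                                 f"{self.alphabet.name!r}") from None

    def restricted_to_rna(self) -> "NNParameterSet":
        """The sub-tables over {A,C,G,U} only (drops every m6A context)."""
        alpha = rna_alphabet()
        ok = set("ACGU")

        def keep(key):
            return all(set(k) <= ok for k in (key if isinstance(key, tuple) else (key,)))

        def filt(d):
            return {k: v for k, v in d.items() if keep(k)}

        return replace(
            self,
            alphabet=alpha,
            stack=filt(self.stack), dangle5=filt(self.dangle5),
            dangle3=filt(self.dangle3), tstack=filt(self.tstack),
            tstackh=filt(self.tstackh), tstacki=filt(self.tstacki),
            tstacki1n=filt(self.tstacki1n), tstacki23=filt(self.tstacki23),
            tstackm=filt(self.tstackm), int11=filt(self.int11),
            int21=filt(self.int21), int22=filt(self.int22),
            special_hairpins=dict(self.special_hairpins),
            end_penalty=filt(self.end_penalty),
        )


# ----------------------------------------------------------------------
# dialect parsing

def _parse_tab(path: Path):
    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    if not path.exists():
        raise ParameterError(f"missing table file {path}")
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        stripped = raw.strip()
        if stripped.startswith("#"):
            m = re.match(r"#\s*([\w ]+?):\s*(.+)$", stripped)
            if m:
                meta[m.group(1).strip()] = m.group(2).strip()
            # a data line may carry a trailing "# label" comment
        body = raw.split("#", 1)[0].strip()
        if not body:
            continue
        rows.append(body.split())
    scale = float(meta.get("scale", "1"))
    return meta, rows, scale, path


def _cell(tok: str, scale: float, where) -> float | None:
    if tok == "NA":
        return None
    try:
        return round(float(tok) * scale, 6)
    except ValueError:
        raise ParameterError(f"non-numeric cell {tok!r} in {where}") from None


def _grid(path: Path, nrows: int, ncols: int):
    meta, rows, scale, _ = _parse_tab(path)
    flat = [t for r in rows for t in r]
    if len(flat) != nrows * ncols:
        raise ParameterError(
            f"{path.name}: expected {nrows}x{ncols}={nrows * ncols} cells, "
            f"got {len(flat)} (dimension mismatch with alphabet?)"
        )
    vals = [_cell(t, scale, path.name) for t in flat]
    return [vals[i * ncols:(i + 1) * ncols] for i in range(nrows)]


def read_parameter_set(directory, alphabet: Alphabet) -> NNParameterSet:
    """Read a parameter table directory written in the m6afold dialect."""
    d = Path(directory)
    ps = NNParameterSet(alphabet=alphabet)
    pairs = list(alphabet.pair_names)
    nts = list(alphabet.nucleotides)
    np_, nn = len(pairs), len(nts)

    g = _grid(d / "stack.tab", np_, np_)
    for i, p1 in enumerate(pairs):
        for j, p2 in enumerate(pairs):
            if g[i][j] is not None:
                ps.stack[(p1, p2)] = g[i][j]

    for name, table in (("dangle5", ps.dangle5), ("dangle3", ps.dangle3)):
        g = _grid(d / f"{name}.tab", np_, nn)
        for i, p in enumerate(pairs):
            for j, x in enumerate(nts):
                if g[i][j] is not None:
                    table[(p, x)] = g[i][j]

    for name in ("tstack", "tstackh", "tstacki", "tstacki1n", "tstacki23",
                 "tstackm"):
        table = getattr(ps, name)
        g = _grid(d / f"{name}.tab", np_ * nn, nn)
        for i, p in enumerate(pairs):
            for xi, x in enumerate(nts):
                for yi, y in enumerate(nts):
                    v = g[i * nn + xi][yi]
                    if v is not None:
                        table[(p, x, y)] = v

    g = _grid(d / "int11.tab", np_ * np_ * nn, nn)
    r = 0
    for p1 in pairs:
        for p2 in pairs:
            for x in nts:
                for yi, y in enumerate(nts):
                    v = g[r][yi]
                    if v is not None:
                        ps.int11[(p1, p2, x, y)] = v
                r += 1

    g = _grid(d / "int21.tab", np_ * np_ * nn * nn, nn)
    r = 0
    for p1 in pairs:
        for p2 in pairs:
            for x in nts:
                for y1 in nts:
                    for y2i, y2 in enumerate(nts):
                        v = g[r][y2i]
                        if v is not None:
                            ps.int21[(p1, p2, x, y1, y2)] = v
                    r += 1

    g = _grid(d / "int22.tab", np_ * np_ * nn * nn * nn, nn)
    r = 0
    for p1 in pairs:
        for p2 in pairs:
            for a in nts:
                for b in nts:
                    for c in nts:
                        for di, dd in enumerate(nts):
                            v = g[r][di]
                            if v is not None:
                                ps.int22[(p1, p2, a, b, c, dd)] = v
                        r += 1

    meta, rows, scale, _ = _parse_tab(d / "loops.tab")
    for row in rows:
        if len(row) != 4:
            raise ParameterError(f"loops.tab: expected 4 columns, got {row}")
        n = int(row[0])
        for tok, table in zip(row[1:], (ps.hairpin_init, ps.bulge_init,
                                        ps.internal_init)):
            v = _cell(tok, scale, "loops.tab")
            if v is not None:
                table[n] = v

    meta, rows, scale, _ = _parse_tab(d / "special_hairpins.tab")
    for row in rows:
        if len(row) != 2:
            raise ParameterError(f"special_hairpins.tab: bad row {row}")
        seq = alphabet.canonicalize(row[0])
        ps.special_hairpins[seq] = _cell(row[1], scale, "special_hairpins.tab")

    meta, rows, scale, _ = _parse_tab(d / "misc.tab")
    misc = {row[0]: float(row[1]) for row in rows}
    for key in ("duplex_init", "symmetry", "ninio", "ninio_max", "ml_closing",
                "ml_unpaired", "ml_branch", "coax_discontinuous", "lxc"):
        attr = "symmetry_corr" if key == "symmetry" else key
        if key in misc:
            setattr(ps, attr, misc[key])
    if "max_loop" in misc:
        ps.max_loop = int(misc["max_loop"])
    term_au = misc.get("terminal_au", 0.45)
    term_gu = misc.get("terminal_gu", 0.0)
    ps._terminal_gu_legacy = misc.get("terminal_gu_legacy", 0.45)
    for p in pairs:
        if p in ("AU", "UA"):
            ps.end_penalty[p] = term_au
        elif p in ("GU", "UG"):
            ps.end_penalty[p] = term_gu
        else:
            ps.end_penalty[p] = 0.0
    return ps


# ----------------------------------------------------------------------
# writing

def _fmt(v: float | None, scale: float = 1.0) -> str:
    if v is None:
        return "NA"
    if scale != 1.0:
        return str(int(round(v / scale)))
    s = f"{v:.4f}".rstrip("0").rstrip(".")
    return s if s not in ("-0", "") else "0"


def write_parameter_set(ps: NNParameterSet, directory) -> None:
    """Write *ps* as a table directory; read_parameter_set round-trips it."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pairs = list(ps.pair_names)
    nts = list(ps.alphabet.nucleotides)

    def head(name, extra=()):
        lines = [f"# m6afold table: {name}", "# units: kcal/mol at 37 C",
                 "# pairs: " + " ".join(pairs),
                 "# nucleotides: " + " ".join(nts)]
        lines += list(extra)
        return lines

    def dump(name, lines):
        (d / name).write_text("\n".join(lines) + "\n")

    lines = head("stack")
    for p1 in pairs:
        lines.append(" ".join(
            f"{_fmt(ps.stack.get((p1, p2))):>7}" for p2 in pairs) + f"  # {p1}")
    dump("stack.tab", lines)

    for name in ("dangle5", "dangle3"):
        t = getattr(ps, name)
        lines = head(name)
        for p in pairs:
            lines.append(" ".join(
                f"{_fmt(t.get((p, x))):>7}" for x in nts) + f"  # {p}")
        dump(f"{name}.tab", lines)

    for name in ("tstack", "tstackh", "tstacki", "tstacki1n", "tstacki23",
                 "tstackm"):
        t = getattr(ps, name)
        lines = head(name)
        for p in pairs:
            for x in nts:
                lines.append(" ".join(
                    f"{_fmt(t.get((p, x, y))):>7}" for y in nts)
                    + f"  # {p},{x}")
        dump(f"{name}.tab", lines)

    lines = head("int11")
    for p1 in pairs:
        for p2 in pairs:
            for x in nts:
                lines.append(" ".join(
                    f"{_fmt(ps.int11.get((p1, p2, x, y))):>7}" for y in nts))
    dump("int11.tab", lines)

    lines = head("int21", ["# scale: 0.01"])
    for p1 in pairs:
        for p2 in pairs:
            for x in nts:
                for y1 in nts:
                    lines.append(" ".join(
                        f"{_fmt(ps.int21.get((p1, p2, x, y1, y2)), 0.01):>5}"
                        for y2 in nts))
    dump("int21.tab", lines)

    lines = head("int22", ["# scale: 0.01"])
    for p1 in pairs:
        for p2 in pairs:
            for a in nts:
                for b in nts:
                    for c in nts:
                        lines.append(" ".join(
                            f"{_fmt(ps.int22.get((p1, p2, a, b, c, dd)), 0.01):>5}"
                            for dd in nts))
    dump("int22.tab", lines)

    lines = head("loops", ["# columns: n hairpin bulge internal"])
    for n in range(1, ps.max_loop + 1):
        lines.append(f"{n:>3} {_fmt(ps.hairpin_init.get(n)):>7} "
                     f"{_fmt(ps.bulge_init.get(n)):>7} "
                     f"{_fmt(ps.internal_init.get(n)):>7}")
    dump("loops.tab", lines)

    lines = head("special_hairpins")
    for seq, v in sorted(ps.special_hairpins.items()):
        lines.append(f"{seq:<10} {_fmt(v):>7}")
    dump("special_hairpins.tab", lines)

    lines = head("misc", ["# key value"])
    for k, v in [
        ("duplex_init", ps.duplex_init),
        ("terminal_au", ps.end_penalty.get("AU", 0.45)),
        ("terminal_gu", ps.end_penalty.get("GU", 0.0)),
        ("terminal_gu_legacy", getattr(ps, "_terminal_gu_legacy", 0.45)),
        ("symmetry", ps.symmetry_corr),
        ("ninio", ps.ninio), ("ninio_max", ps.ninio_max),
        ("ml_closing", ps.ml_closing), ("ml_unpaired", ps.ml_unpaired),
        ("ml_branch", ps.ml_branch),
        ("coax_discontinuous", ps.coax_discontinuous),
        ("lxc", ps.lxc), ("max_loop", ps.max_loop),
    ]:
        lines.append(f"{k:<20} {v}")
    dump("misc.tab", lines)


# ----------------------------------------------------------------------
# m6A table construction

def canonical_stack(p1: str, p2: str) -> tuple[str, str]:
    """Canonical key for a stack context: the lexicographically smaller of
    the two strand-reading directions (p1, p2) and (p2, p1)."""
    return min((p1, p2), (p2, p1))


def m6a_stack_contexts() -> list[tuple[str, str]]:
    """The 15 canonical stack contexts containing at least one m6A-U pair."""
    pairs = ("CG", "GC", "GU", "UG", "AU", "UA", "6U", "U6")
    seen = set()
    out = []
    for p1 in pairs:
        for p2 in pairs:
            if "6" not in p1 + p2:
                continue
            key = canonical_stack(p1, p2)
            if key not in seen:
                seen.add(key)
                out.append(key)
    return sorted(out)


def _analog(s: str) -> str:
    return s.replace("6", "A")


#: mean extra stability of a dangling m6A vs the analogous A (kcal/mol)
DANGLE_M6A_BONUS = -0.4
#: mean extra stability of an m6A-containing terminal mismatch (kcal/mol)
MISMATCH_M6A_BONUS = -0.3
#: interior-loop closure penalty carried by A-U closing pairs, removed
#: for m6A-U closures (kcal/mol)
INTERNAL_AU_CLOSURE = 0.7


def build_m6a_tables(
    rna: NNParameterSet,
    fitted_stacks: dict[tuple[str, str], float],
    measured: list[MeasuredMotif] = (),
) -> NNParameterSet:
    """Assemble the m6A parameter set from the rna set plus m6A data.

    Substitution rules, in order of precedence:

    1. a directly measured motif value overrides everything else;
    2. helix stacks containing an m6A-U pair come from *fitted_stacks*
       (keyed by canonical context);
    3. a dangling m6A takes the analogous-A value - 0.4 kcal/mol; dangles
       on an m6A-U closing pair take the A-U-closure values;
    4. a terminal mismatch containing m6A takes the analogous-A value
       - 0.3 kcal/mol (a single -0.3 even for an m6A-m6A mismatch); a
       mismatch on an m6A-U closing pair gains a further -0.3 (additive);
    5. loop initiations are unchanged;
    6. 1x1/2x1/2x2 interior-loop entries with unpaired m6A take the
       analogous-A entry; entries closed by m6A-U take the analogous
       A-U-closed entry with the +0.7 closure penalty removed;
    7. interior-loop terminal-stack tables take analogous-A values, with
       the +0.7 A-U closure penalty removed for m6A-U closures;
    8. special hairpin tables are unchanged; hairpin-closure mismatches
       take analogous-A values;
    9. multibranch constants are unchanged; multibranch end stacks follow
       the terminal-mismatch rule (4);
    10. terminal m6A-U pairs carry no helix-end penalty.
    """
    alphabet = m6a_alphabet()
    pairs = alphabet.pair_names
    nts = alphabet.nucleotides
    ps = NNParameterSet(
        alphabet=alphabet,
        hairpin_init=dict(rna.hairpin_init),
        bulge_init=dict(rna.bulge_init),
        internal_init=dict(rna.internal_init),
        special_hairpins=dict(rna.special_hairpins),
        duplex_init=rna.duplex_init, symmetry_corr=rna.symmetry_corr,
        ninio=rna.ninio, ninio_max=rna.ninio_max,
        ml_closing=rna.ml_closing, ml_unpaired=rna.ml_unpaired,
        ml_branch=rna.ml_branch,
        coax_discontinuous=rna.coax_discontinuous,
        lxc=rna.lxc, max_loop=rna.max_loop,
    )
    ps._terminal_gu_legacy = getattr(rna, "_terminal_gu_legacy", 0.45)

    def n6(*parts):
        return sum(p.count("6") for p in parts)

    # (2) + copy: helix stacks
    for p1 in pairs:
        for p2 in pairs:
            if "6" in p1 + p2:
                key = canonical_stack(p1, p2)
                if key not in fitted_stacks:
                    raise ParameterError(f"missing fitted stack for context {key}")
                ps.stack[(p1, p2)] = fitted_stacks[key]
            else:
                ps.stack[(p1, p2)] = rna.stack[(p1, p2)]

    # (3) dangling ends
    for table, rtable in ((ps.dangle5, rna.dangle5), (ps.dangle3, rna.dangle3)):
        for p in pairs:
            for x in nts:
                v = rtable[(_analog(p), _analog(x))]
                if x == "6":
                    v += DANGLE_M6A_BONUS
                table[(p, x)] = round(v, 6)

    # (4) exterior terminal mismatches; (9) multibranch end stacks
    for table, rtable in ((ps.tstack, rna.tstack), (ps.tstackm, rna.tstackm)):
        for p in pairs:
            for x in nts:
                for y in nts:
                    v = rtable[(_analog(p), _analog(x), _analog(y))]
                    if "6" in x + y:
                        v += MISMATCH_M6A_BONUS
                    if "6" in p:
                        v += MISMATCH_M6A_BONUS
                    table[(p, x, y)] = round(v, 6)

    # (8) hairpin closures: analogous-A values, no bonus
    for p in pairs:
        for x in nts:
            for y in nts:
                ps.tstackh[(p, x, y)] = rna.tstackh[(_analog(p), _analog(x),
                                                     _analog(y))]

    # (7) interior-loop terminal stacks
    for table, rtable in ((ps.tstacki, rna.tstacki),
                          (ps.tstacki1n, rna.tstacki1n),
                          (ps.tstacki23, rna.tstacki23)):
        for p in pairs:
            for x in nts:
                for y in nts:
                    v = rtable[(_analog(p), _analog(x), _analog(y))]
                    if "6" in p:
                        v -= INTERNAL_AU_CLOSURE
                    table[(p, x, y)] = round(v, 6)

    # (6) small interior-loop lookup tables
    for p1 in pairs:
        for p2 in pairs:
            closure = (INTERNAL_AU_CLOSURE * (("6" in p1) + ("6" in p2)))
            a1, a2 = _analog(p1), _analog(p2)
            for x in nts:
                for y in nts:
                    ps.int11[(p1, p2, x, y)] = round(
                        rna.int11[(a1, a2, _analog(x), _analog(y))]
                        - closure, 6)
                    for z in nts:
                        ps.int21[(p1, p2, x, y, z)] = round(
                            rna.int21[(a1, a2, _analog(x), _analog(y),
                                       _analog(z))] - closure, 6)
            for a in nts:
                for b in nts:
                    for c in nts:
                        for dd in nts:
                            ps.int22[(p1, p2, a, b, c, dd)] = round(
                                rna.int22[(a1, a2, _analog(a), _analog(b),
                                           _analog(c), _analog(dd))]
                                - closure, 6)

    # (10) helix-end penalties
    for p in pairs:
        ps.end_penalty[p] = 0.0 if "6" in p else rna.end_penalty[p]

    # (1) measured motifs override
    for m in measured:
        ctx = tuple(alphabet.canonicalize(c) for c in m.context)
        if m.motif_kind == "dangle5":
            if ctx not in ps.dangle5:
                raise ParameterError(f"measured dangle5 context {ctx} unknown")
            ps.dangle5[ctx] = m.dg37
        elif m.motif_kind == "dangle3":
            if ctx not in ps.dangle3:
                raise ParameterError(f"measured dangle3 context {ctx} unknown")
            ps.dangle3[ctx] = m.dg37
        else:
            if ctx not in ps.tstack:
                raise ParameterError(f"measured mismatch context {ctx} unknown")
            ps.tstack[ctx] = m.dg37
    return ps


# ----------------------------------------------------------------------
# package-data loaders

def _data_dir(name: str):
    return resources.files("m6afold").joinpath(f"data/{name}")


def load_rna_params(legacy_gu_end: bool = False) -> NNParameterSet:
    """The shipped Turner-2004-style rna parameter set.

    By default terminal G-U pairs carry no helix-end penalty (the revised
    convention the m6A set follows); ``legacy_gu_end=True`` restores the
    2004 behaviour of penalizing any terminal pair containing U.
    """
    with resources.as_file(_data_dir("rna")) as d:
        ps = read_parameter_set(d, rna_alphabet())
    if legacy_gu_end:
        for p in ("GU", "UG"):
            ps.end_penalty[p] = ps._terminal_gu_legacy
    return ps


def read_fitted_stacks(path) -> dict[tuple[str, str], float]:
    """Read a fitted-stack table: rows ``p1 p2 dG37`` with canonical keys."""
    out = {}
    _meta, rows, scale, _ = _parse_tab(Path(path))
    for row in rows:
        if len(row) != 3:
            raise ParameterError(f"fitted stack row {row!r} needs 'p1 p2 dG'")
        out[canonical_stack(row[0], row[1])] = float(row[2]) * scale
    return out


def read_measured_motifs(path) -> list[MeasuredMotif]:
    """Read measured motifs: rows ``kind closing-pair nts dG37 sigma``."""
    out = []
    _meta, rows, scale, _ = _parse_tab(Path(path))
    for row in rows:
        kind, pair, nts_, dg, sigma = row
        ctx = (pair, *nts_) if kind == "terminal_mismatch" else (pair, nts_)
        out.append(MeasuredMotif(kind, ctx, float(dg) * scale, float(sigma)))
    return out


def load_m6a_params(legacy_gu_end: bool = False) -> NNParameterSet:
    """The m6A parameter set built from the rna tables, the shipped fitted
    m6A-U stacks, and the shipped measured loop motifs."""
    rna = load_rna_params(legacy_gu_end=legacy_gu_end)
    with resources.as_file(_data_dir("m6a")) as d:
        fitted = read_fitted_stacks(Path(d) / "fitted_stacks_synthetic.tab")
        measured = read_measured_motifs(Path(d) / "measured_motifs_synthetic.tab")
    return build_m6a_tables(rna, fitted, measured)


def load_params(alphabet_name: str = "rna", params_dir=None,
                legacy_gu_end: bool = False) -> NNParameterSet:
    """Entry point used by the CLI: shipped sets by name, or a directory."""
    if params_dir is not None:
        alpha = m6a_alphabet() if alphabet_name.lower() in ("m6a", "m6A") \
            else rna_alphabet()
        return read_parameter_set(params_dir, alpha)
    name = alphabet_name.lower()
    if name == "rna":
        return load_rna_params(legacy_gu_end=legacy_gu_end)
    if name == "m6a":
        return load_m6a_params(legacy_gu_end=legacy_gu_end)
    raise ParameterError(f"unknown alphabet {alphabet_name!r}")
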