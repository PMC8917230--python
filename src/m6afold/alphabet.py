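"""Nucleotide alphabets with user-defined base pairing.

An :class:`Alphabet` is the set of single-character nucleotides a parameter
set knows about, together with the symmetric matrix of allowed base pairs
and any input aliases (``M`` is accepted everywhere for N6-methyladenosine
and normalised to the canonical ``6``; lowercase input is uppercased).

Alphabets are defined in small plain-text specification files::

    # name: m6A
    nucleotides A C G U 6
    alias M 6
    pair A U
    pair G C
    pair G U
    pair 6 U

Pair lines are symmetrised: listing ``pair A U`` allows both A-U and U-A.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources


class AlphabetError(ValueError):
    """Malformed alphabet specification or sequence character."""


@dataclass(frozen=True)
class Alphabet:
    name: str
    nucleotides: tuple[str, ...]
    pairs: frozenset[tuple[str, str]]  # symmetric: (x, y) and (y, x) both present
    aliases: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        seen = set()
        for n in self.nucleotides:
            if len(n) != 1:
                raise AlphabetError(f"nucleotide {n!r} is not a single character")
            if n in seen:
                raise AlphabetError(f"duplicate nucleotide {n!r}")
            seen.add(n)
        if not self.nucleotides:
            raise AlphabetError("empty alphabet")
        for x, y in self.pairs:
            if x not in seen or y not in seen:
                raise AlphabetError(f"pair {x}-{y} references unknown nucleotide")
            if (y, x) not in self.pairs:
                raise AlphabetError(f"pair matrix not symmetric for {x}-{y}")
        for src, dst in self.aliases.items():
            if dst not in seen:
                raise AlphabetError(f"alias target {dst!r} is not a nucleotide")

    # -- sequences ---------------------------------------------------------

    def canonicalize(self, seq: str) -> str:
        """Return *seq* with aliases substituted; reject unknown characters."""
        out = []
        for i, c in enumerate(seq):
            c = self.aliases.get(c, self.aliases.get(c.upper(), c.upper()))
            c = self.aliases.get(c, c)
            if c not in self.nucleotides:
                raise AlphabetError(
                    f"character {seq[i]!r} at position {i + 1} not in alphabet "
                    f"{self.name!r}"
                )
            out.append(c)
        return "".join(out)

    def can_pair(self, x: str, y: str) -> bool:
        return (x, y) in self.pairs

    def index(self, nt: str) -> int:
        return self.nucleotides.index(nt)

    @property
    def pair_names(self) -> tuple[str, ...]:
        """Allowed pairs as two-character strings, in a stable order.

        Watson-Crick/wobble pairs of the four-letter core come first in the
        conventional CG GC GU UG AU UA order; any additional pairs follow in
        alphabet order.
        """
        conventional = ("CG", "GC", "GU", "UG", "AU", "UA")
        names = [p for p in conventional if tuple(p) in self.pairs]
        extra = sorted(
            "".join(p) for p in self.pairs if "".join(p) not in conventional
        )
        return tuple(names + extra)


def parse_alphabet_spec(text: str, name: str = "custom") -> Alphabet:
    """Build an :class:`Alphabet` from specification text (see module doc)."""
    nucleotides: list[str] = []
    aliases: dict[str, str] = {}
    pairs: set[tuple[str, str]] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            m = raw.strip()
            if m.startswith("#") and "name:" in m:
                name = m.split("name:", 1)[1].strip() or name
            continue
        fields = line.split()
        kind, args = fields[0].lower(), fields[1:]
        if kind == "nucleotides":
            for n in args:
                if n in nucleotides:
                    raise AlphabetError(f"line {lineno}: duplicate nucleotide {n!r}")
                nucleotides.append(n)
        elif kind == "alias":
            if len(args) != 2:
                raise AlphabetError(f"line {lineno}: alias takes two characters")
            aliases[args[0]] = args[1]
        elif kind == "pair":
            if len(args) != 2:
                raise AlphabetError(f"line {lineno}: pair takes two characters")
            x, y = args
            if x not in nucleotides or y not in nucleotides:
                raise AlphabetError(
                    f"line {lineno}: pair {x}-{y} references unknown nucleotide"
                )
            pairs.add((x, y))
            pairs.add((y, x))
        else:
            raise AlphabetError(f"line {lineno}: unknown directive {kind!r}")
    if not nucleotides:
        raise AlphabetError("empty alphabet")
    return Alphabet(name, tuple(nucleotides), frozenset(pairs), aliases)


def load_alphabet(source) -> Alphabet:
    """Load an alphabet from a file path or from specification text."""
    text = str(source)
    if "\n" not in text:
        with open(text) as fh:
            text = fh.read()
    return parse_alphabet_spec(text)


def _builtin(name: str) -> Alphabet:
    ref = resources.files("m6afold").joinpath(f"data/alphabets/{name}.alpha")
    return parse_alphabet_spec(ref.read_text(), name=name)


def rna_alphabet() -> Alphabet:
    """A, C, G, U with A-U, G-C and G-U wobble pairs."""
    return _builtin("rna")


def m6a_alphabet() -> Alphabet:
    """RNA extended with N6-methyladenosine ('6', alias 'M'); 6 pairs U only."""
    return _builtin("m6a")
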