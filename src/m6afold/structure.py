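"""Nested RNA secondary structures (1-based coordinates).

A :class:`SecondaryStructure` is a set of base pairs (i, j), 1 <= i < j <= N,
with no shared nucleotides, no pseudoknots, and hairpin loops of at least
three unpaired nucleotides.  Whether each pair is chemically allowed is a
property of an alphabet and is checked when a structure meets a sequence.
"""

from __future__ import annotations

from dataclasses import dataclass


class StructureError(ValueError):
    pass


@dataclass(frozen=True)
class SecondaryStructure:
    length: int
    pairs: frozenset[tuple[int, int]]

    def __init__(self, length: int, pairs=()):
        norm = set()
        for i, j in pairs:
            if i > j:
                i, j = j, i
            if i == j:
                raise StructureError(f"nucleotide {i} paired with itself")
            if not (1 <= i < j <= length):
                raise StructureError(f"pair ({i},{j}) outside 1..{length}")
            if j - i - 1 < 3:
                raise StructureError(f"hairpin of pair ({i},{j}) shorter than 3")
            norm.add((i, j))
        seen = {}
        for i, j in norm:
            for x in (i, j):
                if x in seen:
                    raise StructureError(f"nucleotide {x} in two pairs")
                seen[x] = True
        plist = sorted(norm)
        for a in range(len(plist)):
            i, j = plist[a]
            for b in range(a + 1, len(plist)):
                k, l = plist[b]
                if k > j:
                    break
                if i < k < j < l:
                    raise StructureError(
                        f"pseudoknot between ({i},{j}) and ({k},{l})")
        object.__setattr__(self, "length", length)
        object.__setattr__(self, "pairs", frozenset(norm))

    # ------------------------------------------------------------------
    def partner(self) -> list[int]:
        """0 for unpaired; table[i] = j for pairs, 1-based (index 0 unused)."""
        table = [0] * (self.length + 1)
        for i, j in self.pairs:
            table[i] = j
            table[j] = i
        return table

    def is_substructure_of(self, other: "SecondaryStructure") -> bool:
        return self.length == other.length and self.pairs <= other.pairs

    def to_dotbracket(self) -> str:
        chars = ["."] * self.length
        for i, j in self.pairs:
            chars[i - 1] = "("
            chars[j - 1] = ")"
        return "".join(chars)

    @classmethod
    def from_dotbracket(cls, db: str) -> "SecondaryStructure":
        stack = []
        pairs = []
        for pos, c in enumerate(db, start=1):
            if c == "(":
                stack.append(pos)
            elif c == ")":
                if not stack:
                    raise StructureError(f"unmatched ')' at position {pos}")
                pairs.append((stack.pop(), pos))
            elif c != ".":
                raise StructureError(f"unexpected character {c!r} at {pos}")
        if stack:
            raise StructureError(f"unmatched '(' at position {stack[-1]}")
        return cls(len(db), pairs)

    def __len__(self):
        return self.length
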