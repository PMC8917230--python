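"""Readers and writers for FASTA, CT and dot-bracket files.

Sequences are normalised on input ('M' -> '6', 'T' -> 'U', uppercased).
CT files follow the 1-based six-column convention: a header line with the
nucleotide count and a title, then one row per nucleotide with

    index  base  index-1  index+1  pairing-partner(0 if none)  index
"""

from __future__ import annotations

from pathlib import Path

from .alphabet import Alphabet, m6a_alphabet
from .structure import SecondaryStructure, StructureError


class FormatError(ValueError):
    pass


def read_fasta(path, alphabet: Alphabet | None = None):
    """Parse FASTA records as (name, sequence) with alias normalisation."""
    from Bio import SeqIO

    alphabet = alphabet or m6a_alphabet()
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: empty record {rec.id!r}")
        records.append((rec.id, alphabet.canonicalize(str(rec.seq))))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(records, path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="")
         for name, seq in records),
        str(path), "fasta")


def write_ct(structure: SecondaryStructure, seq: str, path,
             title: str = "", energy: float | None = None) -> None:
    """Write a structure in CT format (energy in the title when given)."""
    if len(seq) != structure.length:
        raise FormatError("sequence length does not match structure")
    partner = structure.partner()
    head = f"{structure.length}"
    if energy is not None:
        head += f"  ENERGY = {energy:.2f}"
    head += f"  {title}".rstrip()
    lines = [head]
    for i in range(1, structure.length + 1):
        lines.append(f"{i:>5} {seq[i - 1]} {i - 1:>5} "
                     f"{(i + 1) if i < structure.length else 0:>5} "
                     f"{partner[i]:>5} {i:>5}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ct(path, alphabet: Alphabet | None = None):
    """Read the first structure of a CT file -> (seq, SecondaryStructure)."""
    alphabet = alphabet or m6a_alphabet()
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty CT file")
    try:
        n = int(lines[0].split()[0])
    except (IndexError, ValueError):
        raise FormatError(f"{path}:1: malformed CT header") from None
    if len(lines) < n + 1:
        raise FormatError(f"{path}: expected {n} rows, found {len(lines) - 1}")
    seq = []
    pairs = []
    for lineno, line in enumerate(lines[1:n + 1], start=2):
        fields = line.split()
        if len(fields) < 6:
            raise FormatError(f"{path}:{lineno}: expected 6 CT columns")
        try:
            i, base, partner = int(fields[0]), fields[1], int(fields[4])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: malformed CT row") from None
        if i != lineno - 1:
            raise FormatError(f"{path}:{lineno}: out-of-order index {i}")
        seq.append(alphabet.canonicalize(base))
        if partner > i:
            pairs.append((i, partner))
    try:
        return "".join(seq), SecondaryStructure(n, pairs)
    except StructureError as exc:
        raise FormatError(f"{path}: invalid structure: {exc}") from None


def read_dotbracket(path, alphabet: Alphabet | None = None):
    """Read a (sequence, dot-bracket) file: optional '>' header, sequence
    line, structure line."""
    alphabet = alphabet or m6a_alphabet()
    lines = [l.strip() for l in Path(path).read_text().splitlines()
             if l.strip()]
    if lines and lines[0].startswith(">"):
        lines = lines[1:]
    if len(lines) < 2:
        raise FormatError(f"{path}: need sequence and structure lines")
    seq = alphabet.canonicalize(lines[0])
    st = SecondaryStructure.from_dotbracket(lines[1])
    if st.length != len(seq):
        raise FormatError(f"{path}: structure length differs from sequence")
    return seq, st


def write_dotbracket(seq: str, structure: SecondaryStructure, path,
                     name: str = "structure") -> None:
    Path(path).write_text(
        f">{name}\n{seq}\n{structure.to_dotbracket()}\n")
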