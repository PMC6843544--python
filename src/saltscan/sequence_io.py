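"""Sequence I/O, ORF finding, translation and codon-coordinate mapping.

All coordinates are 1-based and inclusive throughout the package, matching
the convention used for coding-sequence positions in the rice HKT1;5
literature (e.g. residue 332 occupies nucleotides 994-996 of the CDS).

Reverse-strand ORFs are reported on the reverse complement's own 1-based
axis together with a strand flag, so :func:`codon_span` stays
strand-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

__all__ = [
    "SeqRecord",
    "OrfHit",
    "CodonSpan",
    "ParseError",
    "read_fasta",
    "write_fasta",
    "translate",
    "find_orfs",
    "longest_orf",
    "codon_span",
    "nt_to_aa",
]

Alphabet = Literal["nucleotide", "protein"]

# IUPAC nucleotide codes including ambiguity codes; protein = 20 standard
# amino acids plus X.  Gaps are not legal in unaligned records.
_NT_CODES = set("ACGTURYSWKMBDHVN")
_AA_CODES = set("ACDEFGHIKLMNPQRSTVWYX")

_STOPS = set(standard_dna_table.stop_codons)  # {"TAA", "TAG", "TGA"}


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class SeqRecord:
    """A named sequence with a declared alphabet.

    Residues are stored uppercase; nucleotide records may carry IUPAC
    ambiguity codes, protein records the 20 amino-acid codes plus X.
    """

    id: str
    residues: str
    alphabet: Alphabet = "protein"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        codes = _NT_CODES if self.alphabet == "nucleotide" else _AA_CODES
        bad = set(self.residues) - codes
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal {self.alphabet} characters "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class OrfHit:
    """An ATG→stop open reading frame on one strand.

    ``start``/``end`` are 1-based inclusive nucleotide positions on the
    given strand's own axis (for ``-`` the reverse complement's axis).
    The translated protein excludes the stop symbol.
    """

    start: int
    end: int
    strand: Literal["+", "-"]
    frame: int
    protein: str

    def __post_init__(self) -> None:
        span = self.end - self.start + 1
        if span % 3 != 0:
            raise ValueError("ORF span not a codon multiple")
        if len(self.protein) != span // 3 - 1:
            raise ValueError("protein length inconsistent with span")


@dataclass(frozen=True)
class CodonSpan:
    """The CDS nucleotide span encoding one residue (1-based, inclusive)."""

    aa_pos: int
    nt_start: int
    nt_end: int


def _validate(name: str, seq: str, alphabet: Alphabet, line: int) -> str:
    seq = seq.upper()
    codes = _NT_CODES if alphabet == "nucleotide" else _AA_CODES
    for ch in seq:
        if ch not in codes:
            raise ParseError(
                f"record {name!r} (near line {line}): character {ch!r} is not "
                f"a legal {alphabet} code"
            )
    return seq


def read_fasta(path: str | Path, alphabet: Alphabet) -> list[SeqRecord]:
    """Read a FASTA file into validated :class:`SeqRecord` objects.

    Order is preserved, sequences are uppercased and whitespace-stripped.
    Characters illegal for the declared alphabet raise :class:`ParseError`
    naming the offending record.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    # track line numbers for error messages
    header_lines: dict[str, int] = {}
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            if raw.startswith(">"):
                name = raw[1:].split(None, 1)[0] if raw[1:].strip() else ""
                if not name:
                    raise ParseError(f"{path.name}: malformed header at line {i}")
                header_lines.setdefault(name, i)
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = "".join(str(rec.seq).split())
        line = header_lines.get(rec.id, 0)
        records.append(
            SeqRecord(
                id=rec.id,
                residues=_validate(rec.id, seq, alphabet, line),
                alphabet=alphabet,
                description=rec.description,
            )
        )
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id else rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def translate(nt_seq: str) -> str:
    """Translate a CDS under the standard genetic code.

    Length must be a codon multiple.  Ambiguous codons yield ``X`` and
    internal stops are rendered ``*`` (no early termination).
    """
    nt_seq = nt_seq.upper().replace("U", "T")
    if len(nt_seq) % 3 != 0:
        raise ValueError(f"sequence length {len(nt_seq)} not divisible by 3")
    out = []
    table = standard_dna_table.forward_table
    for i in range(0, len(nt_seq), 3):
        codon = nt_seq[i : i + 3]
        if codon in _STOPS:
            out.append("*")
        elif codon in table:
            out.append(table[codon])
        else:
            out.append("X")
    return "".join(out)


def _orfs_one_strand(seq: str, strand: Literal["+", "-"], min_aa_len: int) -> list[OrfHit]:
    hits = []
    n = len(seq)
    for frame in range(3):
        i = frame
        while i + 3 <= n:
            if seq[i : i + 3] == "ATG":
                # scan forward for the first in-frame stop
                j = i + 3
                while j + 3 <= n and seq[j : j + 3] not in _STOPS:
                    j += 3
                if j + 3 <= n:  # stop found
                    protein = translate(seq[i : j + 3])[:-1]
                    if len(protein) >= min_aa_len:
                        hits.append(
                            OrfHit(start=i + 1, end=j + 3, strand=strand, frame=frame, protein=protein)
                        )
            i += 3
    return hits


def find_orfs(nt_seq: str | SeqRecord, min_aa_len: int = 0) -> list[OrfHit]:
    """All ATG→stop ORFs on both strands with translation ≥ ``min_aa_len``.

    Sorted by descending protein length, then ``+`` strand before ``-``,
    then ascending start.  Nested in-frame ATGs each start their own ORF.
    """
    seq = nt_seq.residues if isinstance(nt_seq, SeqRecord) else nt_seq.upper().replace("U", "T")
    rc = str(Seq(seq).reverse_complement())
    hits = _orfs_one_strand(seq, "+", min_aa_len) + _orfs_one_strand(rc, "-", min_aa_len)
    hits.sort(key=lambda h: (-len(h.protein), h.strand != "+", h.start))
    return hits


def longest_orf(nt_seq: str | SeqRecord, min_aa_len: int = 0) -> OrfHit | None:
    """The single longest ORF; ties broken 5'-most on the + strand."""
    hits = find_orfs(nt_seq, min_aa_len)
    return hits[0] if hits else None


def codon_span(aa_pos: int) -> CodonSpan:
    """Map a 1-based residue index to its CDS codon span.

    ``nt_start = 3*(aa_pos-1)+1``; e.g. residue 332 → nucleotides 994-996.
    """
    if aa_pos < 1:
        raise ValueError(f"aa_pos must be >= 1, got {aa_pos}")
    nt_start = 3 * (aa_pos - 1) + 1
    return CodonSpan(aa_pos=aa_pos, nt_start=nt_start, nt_end=nt_start + 2)


def nt_to_aa(nt_pos: int) -> int:
    """Inverse of :func:`codon_span`: CDS nucleotide → residue index."""
    if nt_pos < 1:
        raise ValueError(f"nt_pos must be >= 1, got {nt_pos}")
    return (nt_pos - 1) // 3 + 1
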