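"""Phenotype-segregating substitution scanning over labeled protein panels.

The central question this module answers: which alignment columns carry a
residue partition that exactly separates salt-tolerant from salt-sensitive
accessions?  A column is *strict segregating* when the tolerant and
sensitive residue sets are disjoint, each non-empty, and gap-free — the
pattern shown by the Asp332His and Val395Leu substitutions in rice HKT1;5,
and deliberately failed by the Ala/Pro mixture seen at position 140.

Multiple alignments are consumed, not computed (the study panels come from
CLUSTALW-style tools); an exact affine-gap pairwise global aligner (Gotoh)
is included so pairwise difference counts need no external tool.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import pandas as pd
from Bio import AlignIO

from .sequence_io import CodonSpan, SeqRecord, codon_span, translate

__all__ = [
    "LabeledSequencePanel",
    "AlignmentMatrix",
    "SiteReport",
    "PairwiseDiff",
    "align_pair",
    "pairwise_differences",
    "scan_segregating_sites",
    "map_column_to_ref",
    "nucleotide_site_table",
    "read_alignment",
    "read_labels",
]

Label = Literal["tolerant", "moderately_tolerant", "sensitive", "unknown"]
LABELS: tuple[str, ...] = ("tolerant", "moderately_tolerant", "sensitive", "unknown")

GAP = "-"


@dataclass(frozen=True)
class LabeledSequencePanel:
    """Protein records plus a tolerance-class label per record id."""

    records: tuple[SeqRecord, ...]
    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.id not in self.labels:
                raise ValueError(f"record {rec.id!r} has no label")
        bad = set(self.labels.values()) - set(LABELS)
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}; expected one of {LABELS}")

    def ids_with_label(self, label: str) -> list[str]:
        return [r.id for r in self.records if self.labels[r.id] == label]


class AlignmentMatrix:
    """Equal-length aligned rows with column ↔ ungapped-position maps.

    Columns are 1-based.  Ungapping any row reproduces the input sequence.
    """

    def __init__(self, ids: Sequence[str], rows: Sequence[str]):
        if len(ids) != len(rows):
            raise ValueError("ids and rows length mismatch")
        if not rows:
            raise ValueError("empty alignment")
        width = len(rows[0])
        if any(len(r) != width for r in rows):
            raise ValueError("aligned rows have unequal lengths")
        self.ids = list(ids)
        self.rows = {i: r.upper() for i, r in zip(ids, rows)}
        self.width = width
        # per-row map: column index (0-based) -> ungapped pos (1-based) or None
        self._col_to_pos: dict[str, list[int | None]] = {}
        for rid, row in self.rows.items():
            pos = 0
            cmap: list[int | None] = []
            for ch in row:
                if ch == GAP:
                    cmap.append(None)
                else:
                    pos += 1
                    cmap.append(pos)
            self._col_to_pos[rid] = cmap

    def __contains__(self, rid: str) -> bool:
        return rid in self.rows

    def ungapped(self, rid: str) -> str:
        return self.rows[rid].replace(GAP, "")

    def column(self, col: int) -> dict[str, str]:
        """Residues of 1-based column ``col`` keyed by row id."""
        if not 1 <= col <= self.width:
            raise IndexError(f"column {col} outside [1, {self.width}]")
        return {rid: row[col - 1] for rid, row in self.rows.items()}

    def position_of(self, rid: str, col: int) -> int | None:
        """Ungapped 1-based position of row ``rid`` at column ``col``."""
        if rid not in self.rows:
            raise KeyError(f"unknown row id {rid!r}")
        if not 1 <= col <= self.width:
            raise IndexError(f"column {col} outside [1, {self.width}]")
        return self._col_to_pos[rid][col - 1]


@dataclass(frozen=True)
class SiteReport:
    """One polymorphic alignment column and its segregation verdict."""

    column: int
    ref_id: str
    ref_pos: int | None  # None marks a gap in the reference row
    residues_by_class: Mapping[str, frozenset[str]]
    verdict: Literal["strict_segregating", "non_segregating", "candidate_with_exceptions"]
    codon: CodonSpan | None = None
    n_exceptions: int = 0


@dataclass(frozen=True)
class PairwiseDiff:
    """Substitution positions between two aligned rows.

    ``positions`` are 1-based ungapped coordinates on ``id_a``'s sequence;
    columns where exactly one row is gapped are listed separately as
    ``indel_columns`` (alignment columns), never counted as substitutions.
    """

    id_a: str
    id_b: str
    positions: tuple[int, ...]
    indel_columns: tuple[int, ...] = ()

    @property
    def count(self) -> int:
        return len(self.positions)


# ---------------------------------------------------------------------------
# Affine-gap global alignment (Gotoh), deterministic traceback.

_NEG_INF = float("-inf")


def align_pair(
    a: SeqRecord | str,
    b: SeqRecord | str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignmentMatrix:
    """Optimal end-to-end alignment of two protein sequences.

    Affine gap penalties: a gap of length L costs
    ``gap_open + (L - 1) * gap_extend``.  Traceback ties resolve
    diagonal > up (gap in b) > left (gap in a), so the output is
    deterministic.
    """
    id_a, sa = (a.id, a.residues) if isinstance(a, SeqRecord) else ("a", a.upper())
    id_b, sb = (b.id, b.residues) if isinstance(b, SeqRecord) else ("b", b.upper())
    if not sa or not sb:
        raise ValueError("cannot align an empty sequence")

    n, m = len(sa), len(sb)
    # M: last pair aligned; X: gap in b (consumes a, "up"); Y: gap in a ("left")
    M = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[_NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = max(M[i - 1][0] - gap_open, X[i - 1][0] - gap_extend)
    for j in range(1, m + 1):
        Y[0][j] = max(M[0][j - 1] - gap_open, Y[0][j - 1] - gap_extend)

    for i in range(1, n + 1):
        ca = sa[i - 1]
        Mi, Mi1 = M[i], M[i - 1]
        Xi, Xi1 = X[i], X[i - 1]
        Yi = Y[i]
        for j in range(1, m + 1):
            s = match if ca == sb[j - 1] else mismatch
            Mi[j] = s + max(Mi1[j - 1], Xi1[j - 1], Y[i - 1][j - 1])
            Xi[j] = max(Mi1[j] - gap_open, Xi1[j] - gap_extend)
            Yi[j] = max(Mi[j - 1] - gap_open, Yi[j - 1] - gap_extend)

    # traceback; state preference diagonal (M) > up (X) > left (Y)
    i, j = n, m
    best = max(M[i][j], X[i][j], Y[i][j])
    state = "M" if M[i][j] == best else ("X" if X[i][j] == best else "Y")
    out_a: list[str] = []
    out_b: list[str] = []
    while (i, j) != (0, 0):
        if state == "M":
            s = match if sa[i - 1] == sb[j - 1] else mismatch
            out_a.append(sa[i - 1])
            out_b.append(sb[j - 1])
            target = M[i][j]
            i, j = i - 1, j - 1
            if M[i][j] + s == target:
                state = "M"
            elif X[i][j] + s == target:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            out_a.append(sa[i - 1])
            out_b.append(GAP)
            target = X[i][j]
            i -= 1
            state = "M" if M[i][j] - gap_open == target else "X"
        else:
            out_a.append(GAP)
            out_b.append(sb[j - 1])
            target = Y[i][j]
            j -= 1
            state = "M" if M[i][j] - gap_open == target else "Y"
    aln = AlignmentMatrix([id_a, id_b], ["".join(reversed(out_a)), "".join(reversed(out_b))])
    aln.score = best  # type: ignore[attr-defined]
    return aln


def alignment_score(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> float:
    """Optimal global affine-gap score only (no traceback)."""
    aln = align_pair(a, b, match, mismatch, gap_open, gap_extend)
    return aln.score  # type: ignore[attr-defined]


def pairwise_differences(aln: AlignmentMatrix, id_a: str, id_b: str) -> PairwiseDiff:
    """Substitution columns between two rows of an alignment.

    A substitution column has both residues non-gap and unequal; its
    coordinate is the ungapped position in ``id_a``'s sequence.  Columns
    gapped in exactly one row are indels, reported separately.
    """
    for rid in (id_a, id_b):
        if rid not in aln:
            raise KeyError(f"unknown row id {rid!r}")
    ra, rb = aln.rows[id_a], aln.rows[id_b]
    positions: list[int] = []
    indels: list[int] = []
    for col in range(1, aln.width + 1):
        x, y = ra[col - 1], rb[col - 1]
        if x == GAP and y == GAP:
            continue
        if x == GAP or y == GAP:
            indels.append(col)
        elif x != y:
            positions.append(aln.position_of(id_a, col))  # type: ignore[arg-type]
    return PairwiseDiff(id_a=id_a, id_b=id_b, positions=tuple(positions), indel_columns=tuple(indels))


def map_column_to_ref(aln: AlignmentMatrix, ref_id: str, column: int) -> int | None:
    """1-based ungapped position of ``column`` in the reference row.

    Returns ``None`` (an explicit gap marker) when the reference row is
    gapped at that column — never a silently shifted coordinate.
    """
    return aln.position_of(ref_id, column)


def scan_segregating_sites(
    aln: AlignmentMatrix,
    panel: LabeledSequencePanel,
    ref_id: str | None = None,
    policy: Literal["exclude", "include_as_tolerant"] = "exclude",
    max_exceptions: int = 0,
) -> list[SiteReport]:
    """Scan every polymorphic column for class-segregating residues.

    ``policy`` controls moderately_tolerant/unknown ids: ``exclude`` drops
    them from the partition test (the default — intermediate genotypes are
    a separate category), ``include_as_tolerant`` folds moderately_tolerant
    into the tolerant class (unknown is always excluded).

    A column is ``strict_segregating`` iff the tolerant and sensitive
    residue sets are disjoint, both non-empty and gap-free.  If removing at
    most ``max_exceptions`` sequences would restore disjointness the
    verdict is ``candidate_with_exceptions``.  Gap-containing columns can
    never be strict.
    """
    ids = [r.id for r in panel.records if r.id in aln]
    if len(ids) < len(panel.records):
        missing = {r.id for r in panel.records} - set(ids)
        raise KeyError(f"panel ids missing from alignment: {sorted(missing)}")
    eff_label: dict[str, str] = {}
    for rid in ids:
        lab = panel.labels[rid]
        if lab == "moderately_tolerant" and policy == "include_as_tolerant":
            lab = "tolerant"
        eff_label[rid] = lab
    tol_ids = [i for i in ids if eff_label[i] == "tolerant"]
    sen_ids = [i for i in ids if eff_label[i] == "sensitive"]
    if not tol_ids or not sen_ids:
        raise ValueError(
            f"need at least one tolerant and one sensitive sequence after policy "
            f"filtering (got {len(tol_ids)} tolerant, {len(sen_ids)} sensitive)"
        )
    if ref_id is None:
        ref_id = ids[0]
    if ref_id not in aln:
        raise KeyError(f"unknown reference id {ref_id!r}")

    reports: list[SiteReport] = []
    for col in range(1, aln.width + 1):
        residues = aln.column(col)
        tested = {rid: residues[rid] for rid in tol_ids + sen_ids}
        if len(set(tested.values())) < 2:
            continue  # monomorphic among tested classes
        by_class: dict[str, frozenset[str]] = {}
        for lab in LABELS:
            members = [residues[rid] for rid in ids if eff_label[rid] == lab]
            if members:
                by_class[lab] = frozenset(members)
        tol_set = by_class["tolerant"]
        sen_set = by_class["sensitive"]
        has_gap = GAP in tol_set or GAP in sen_set
        shared = tol_set & sen_set
        if not shared and not has_gap:
            verdict, n_exc = "strict_segregating", 0
        else:
            # minimal removals to restore a gap-free disjoint partition
            n_exc = 0
            for r in shared:
                n_tol = sum(1 for rid in tol_ids if residues[rid] == r)
                n_sen = sum(1 for rid in sen_ids if residues[rid] == r)
                n_exc += min(n_tol, n_sen)
            n_exc += sum(1 for rid in tol_ids + sen_ids if residues[rid] == GAP)
            if 0 < n_exc <= max_exceptions:
                verdict = "candidate_with_exceptions"
            else:
                verdict = "non_segregating"
        ref_pos = aln.position_of(ref_id, col)
        reports.append(
            SiteReport(
                column=col,
                ref_id=ref_id,
                ref_pos=ref_pos,
                residues_by_class=by_class,
                verdict=verdict,
                codon=codon_span(ref_pos) if ref_pos is not None else None,
                n_exceptions=n_exc,
            )
        )
    return reports


def nucleotide_site_table(
    aln: AlignmentMatrix,
    panel: LabeledSequencePanel,
    sites: Sequence[SiteReport],
    cds_by_id: Mapping[str, str],
) -> pd.DataFrame:
    """Codon-level table for reported sites: per-class codons and the CDS
    nucleotide offsets that differ between tolerant and sensitive classes.

    Each supplied CDS must match its protein (length 3·L or 3·L + 3 with a
    terminal stop, and translation agreeing with the panel sequence).
    Offsets are 1-based within the codon, so a first-position SNP at
    residue 332 is offset 1 = CDS position 994.
    """
    seqs = {r.id: r.residues for r in panel.records}
    for rid, cds in cds_by_id.items():
        if rid not in seqs:
            raise KeyError(f"CDS supplied for unknown id {rid!r}")
        prot = seqs[rid]
        if len(cds) not in (3 * len(prot), 3 * len(prot) + 3):
            raise ValueError(
                f"CDS/protein length mismatch for {rid!r}: "
                f"CDS {len(cds)} nt vs protein {len(prot)} aa"
            )
        if translate(cds[: 3 * len(prot)]) != prot:
            raise ValueError(f"CDS for {rid!r} does not translate to its protein")

    rows = []
    for site in sites:
        codons_by_class: dict[str, set[str]] = {}
        for rid, cds in cds_by_id.items():
            pos = aln.position_of(rid, site.column)
            if pos is None:
                continue
            span = codon_span(pos)
            codon = cds[span.nt_start - 1 : span.nt_end]
            lab = panel.labels[rid]
            codons_by_class.setdefault(lab, set()).add(codon)
        tol = codons_by_class.get("tolerant", set())
        sen = codons_by_class.get("sensitive", set())
        if not tol or not sen:
            raise ValueError(
                f"site column {site.column}: need a CDS for at least one tolerant "
                f"and one sensitive sequence"
            )
        diff_offsets = []
        for k in range(3):
            tol_nt = {c[k] for c in tol}
            sen_nt = {c[k] for c in sen}
            if not (tol_nt & sen_nt):
                diff_offsets.append(k + 1)
        span = site.codon
        rows.append(
            {
                "column": site.column,
                "ref_pos": site.ref_pos,
                "nt_start": span.nt_start if span else None,
                "nt_end": span.nt_end if span else None,
                "verdict": site.verdict,
                "tolerant_codons": ",".join(sorted(tol)),
                "sensitive_codons": ",".join(sorted(sen)),
                "differing_offsets": ",".join(map(str, diff_offsets)),
                "differing_nt_positions": ",".join(
                    str(span.nt_start + k - 1) for k in diff_offsets
                )
                if span
                else "",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# File readers


def read_alignment(path: str | Path, fmt: str | None = None) -> AlignmentMatrix:
    """Read an aligned FASTA or Clustal (.aln/.clustal) file."""
    path = Path(path)
    if fmt is None:
        fmt = "clustal" if path.suffix.lower() in {".aln", ".clustal"} else "fasta"
    aln = AlignIO.read(str(path), fmt)
    return AlignmentMatrix([rec.id for rec in aln], [str(rec.seq) for rec in aln])


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a 2-column CSV (id,label); a header row is optional."""
    labels: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].startswith("#"):
                continue
            if row[0].strip().lower() == "id":
                continue
            if len(row) < 2:
                raise ValueError(f"label row needs 2 columns, got {row!r}")
            labels[row[0].strip()] = row[1].strip()
    return labels
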