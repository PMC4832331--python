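"""Pairwise and progressive multiple alignment of protein sequences.

Pairwise global alignment is Needleman–Wunsch with affine gaps
(BLOSUM62, gap open 10, gap extend 0.5 by default; a gap of length L
costs open + (L-1)*extend). Multiple alignment is a classic progressive
scheme: a UPGMA guide tree on k-mer distances, then profile–profile
alignment merged leaf-to-root. Alignment columns are 0-based
internally and 1-based in all reports; residue numbering is 1-based.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = AMINO_ACIDS + "X"
GAP = "-"


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceRecord:
    """A labelled, ungapped protein sequence."""

    id: str
    residues: str
    taxon: str = ""

    def __post_init__(self):
        if not self.residues:
            raise AlignmentError(f"empty sequence for {self.id!r}")
        bad = set(self.residues.upper()) - set(ALPHABET)
        if bad:
            raise AlignmentError(
                f"unknown residue symbol(s) {sorted(bad)} in {self.id!r}"
            )
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class PairwiseAlignment:
    a: SequenceRecord
    b: SequenceRecord
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise AlignmentError("aligned rows differ in length")
        if self.aligned_a.replace(GAP, "") != self.a.residues:
            raise AlignmentError("row A does not degap to input A")
        if self.aligned_b.replace(GAP, "") != self.b.residues:
            raise AlignmentError("row B does not degap to input B")

    @property
    def columns(self):
        return zip(self.aligned_a, self.aligned_b)


@dataclass
class MultipleAlignment:
    """Column-aligned sequences; degapping row i reproduces input i."""

    ids: list[str]
    rows: list[str]
    taxa: list[str] = field(default_factory=list)

    def __post_init__(self):
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise AlignmentError("alignment rows have unequal lengths")
        if len(self.ids) != len(self.rows):
            raise AlignmentError("ids/rows length mismatch")
        if not self.taxa:
            self.taxa = list(self.ids)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def column_count(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, rec_id: str) -> str:
        return self.rows[self.ids.index(rec_id)]

    def degapped(self, rec_id: str) -> str:
        return self.row(rec_id).replace(GAP, "")

    def to_records(self) -> list[SequenceRecord]:
        return [
            SequenceRecord(i, r.replace(GAP, ""), t)
            for i, r, t in zip(self.ids, self.rows, self.taxa)
        ]

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)


@dataclass(frozen=True)
class Scoring:
    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def matrix(self):
        return substitution_matrices.load(self.matrix_name)


DEFAULT_SCORING = Scoring()


@dataclass
class ReferenceMap:
    """Bijection between alignment columns and reference residue numbers.

    ``column_of[k]`` gives the 0-based alignment column carrying
    1-based reference residue k; ``residue_of`` is the inverse (gap
    columns of the reference are absent).
    """

    reference_id: str
    column_of: dict[int, int]
    residue_of: dict[int, int]


# ---------------------------------------------------------------------------
# pairwise


def _aligner(scoring: Scoring) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = scoring.matrix()
    # First gap residue costs `gap_open`, each further one `gap_extend`.
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def global_align(
    a: SequenceRecord, b: SequenceRecord, scoring: Scoring = DEFAULT_SCORING
) -> PairwiseAlignment:
    """Optimal global (Needleman–Wunsch, affine-gap) alignment of a and b."""
    aln = _aligner(scoring).align(a.residues, b.residues)
    best = aln[0]
    return PairwiseAlignment(a, b, str(best[0]), str(best[1]), float(best.score))


def percent_identity(aln: PairwiseAlignment) -> float:
    """Identical pairs / columns (both-gap columns excluded), in percent."""
    cols = [(x, y) for x, y in aln.columns if not (x == GAP and y == GAP)]
    if not cols:
        raise AlignmentError("alignment has no aligned columns")
    same = sum(1 for x, y in cols if x == y and x != GAP)
    return 100.0 * same / len(cols)


def percent_similarity(
    aln: PairwiseAlignment, scoring: Scoring = DEFAULT_SCORING
) -> float:
    """Identical-or-positively-scoring pairs / columns, in percent."""
    mat = scoring.matrix()
    cols = [(x, y) for x, y in aln.columns if not (x == GAP and y == GAP)]
    if not cols:
        raise AlignmentError("alignment has no aligned columns")
    sim = sum(
        1
        for x, y in cols
        if x != GAP and y != GAP and (x == y or mat[x, y] > 0)
    )
    return 100.0 * sim / len(cols)


def identity_similarity_matrix(
    records: list[SequenceRecord], scoring: Scoring = DEFAULT_SCORING
):
    """All-vs-all percent identity / similarity (pandas DataFrames)."""
    import pandas as pd

    ids = [r.id for r in records]
    n = len(records)
    ident = np.full((n, n), 100.0)
    simil = np.full((n, n), 100.0)
    for i, j in itertools.combinations(range(n), 2):
        aln = global_align(records[i], records[j], scoring)
        ident[i, j] = ident[j, i] = percent_identity(aln)
        simil[i, j] = simil[j, i] = percent_similarity(aln, scoring)
    return (
        pd.DataFrame(ident, index=ids, columns=ids),
        pd.DataFrame(simil, index=ids, columns=ids),
    )


# ---------------------------------------------------------------------------
# progressive MSA

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def _profile(rows: list[str]) -> np.ndarray:
    """L x 21 column frequency profile (20 residues + gap); X spread uniformly."""
    length = len(rows[0])
    prof = np.zeros((length, 21))
    for row in rows:
        for j, c in enumerate(row):
            if c == GAP:
                prof[j, 20] += 1.0
            elif c == "X":
                prof[j, :20] += 1.0 / 20.0
            else:
                prof[j, _AA_INDEX[c]] += 1.0
    return prof / len(rows)


def _score_matrix_20(scoring: Scoring) -> np.ndarray:
    mat = scoring.matrix()
    s = np.zeros((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            s[i, j] = mat[a, b]
    return s


def _profile_align(
    rows_a: list[str], rows_b: list[str], scoring: Scoring
) -> tuple[list[str], list[str]]:
    """Affine-gap global DP between two profiles, vectorised per row.

    The horizontal/vertical gap states use the closed form
    E[i][j] = max_{k<j}(best[i][k] + k*ext) - open - (j-1)*ext, which
    allows a prefix-max scan instead of a serial inner loop.
    """
    if scoring.gap_open < scoring.gap_extend:
        raise AlignmentError("gap_open must be >= gap_extend")
    pa, pb = _profile(rows_a), _profile(rows_b)
    s20 = _score_matrix_20(scoring)
    m, n = len(pa), len(pb)
    # expected column-pair score between profile columns (gap fractions
    # score 0 against residues; gap penalties live in the DP states)
    match = pa[:, :20] @ s20 @ pb[:, :20].T
    open_, ext = scoring.gap_open, scoring.gap_extend

    # A gap of length L costs open + (L-1)*ext, so a gap spanning
    # columns k+1..j sourced at cell k contributes
    # best[k] - open - (j-1-k)*ext = (best[k] + k*ext) - open - (j-1)*ext,
    # which turns the affine gap state into a running prefix maximum
    # (valid because open >= ext makes split gaps never optimal).
    best = np.empty((m + 1, n + 1))
    best[0, 0] = 0.0
    best[0, 1:] = -open_ - ext * np.arange(n)
    best[1:, 0] = -open_ - ext * np.arange(m)
    jj = np.arange(n + 1)
    colmax = best[0, :] + 0.0  # max over rows k<i of best[k, j] + k*ext
    for i in range(1, m + 1):
        diag = best[i - 1, :-1] + match[i - 1, :]
        vert = colmax - open_ - (i - 1) * ext
        row = np.empty(n + 1)
        row[0] = best[i, 0]
        row[1:] = np.maximum(diag, vert[1:])
        pref = np.maximum.accumulate((row + jj * ext)[:-1])
        horiz = pref - open_ - np.arange(n) * ext
        row[1:] = np.maximum(row[1:], horiz)
        best[i, :] = row
        colmax = np.maximum(colmax, row + i * ext)

    # traceback using the closed forms
    out_a: list[int | None] = []
    out_b: list[int | None] = []
    i, j = m, n
    tol = 1e-9
    while i > 0 or j > 0:
        v = best[i, j]
        if i > 0 and j > 0 and abs(best[i - 1, j - 1] + match[i - 1, j - 1] - v) < tol:
            out_a.append(i - 1)
            out_b.append(j - 1)
            i, j = i - 1, j - 1
            continue
        moved = False
        if j > 0:
            ks = np.arange(j)
            cand = best[i, ks] - open_ - (j - 1 - ks) * ext
            k = int(np.argmax(cand))
            if abs(cand[k] - v) < tol:
                for jj in range(j - 1, k - 1, -1):
                    out_a.append(None)
                    out_b.append(jj)
                j = k
                moved = True
        if not moved and i > 0:
            ks = np.arange(i)
            cand = best[ks, j] - open_ - (i - 1 - ks) * ext
            k = int(np.argmax(cand))
            if abs(cand[k] - v) < tol:
                for ii in range(i - 1, k - 1, -1):
                    out_a.append(ii)
                    out_b.append(None)
                i = k
                moved = True
        if not moved:  # pragma: no cover - numerical safety net
            raise AlignmentError("profile alignment traceback failed")
    out_a.reverse()
    out_b.reverse()

    new_a = [
        "".join(r[k] if k is not None else GAP for k in out_a) for r in rows_a
    ]
    new_b = [
        "".join(r[k] if k is not None else GAP for k in out_b) for r in rows_b
    ]
    return new_a, new_b


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    if len(a) < k or len(b) < k:
        return 1.0
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    shared = len(ka & kb)
    return 1.0 - shared / min(len(ka), len(kb))


def progressive_msa(
    records: list[SequenceRecord], scoring: Scoring = DEFAULT_SCORING
) -> MultipleAlignment:
    """Progressive multiple alignment (UPGMA guide tree on k-mer distances)."""
    if len(records) < 2:
        raise AlignmentError("progressive_msa needs at least 2 records")
    if len(records) == 2:
        pw = global_align(records[0], records[1], scoring)
        return MultipleAlignment(
            [records[0].id, records[1].id],
            [pw.aligned_a, pw.aligned_b],
            [records[0].taxon, records[1].taxon],
        )
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    n = len(records)
    dm = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        dm[i, j] = dm[j, i] = _kmer_distance(records[i].residues, records[j].residues)
    link = linkage(squareform(dm, checks=False), method="average")

    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [records[i].residues]) for i in range(n)
    }
    for step, (x, y, _, _) in enumerate(link):
        ia, rows_a = clusters.pop(int(x))
        ib, rows_b = clusters.pop(int(y))
        new_a, new_b = _profile_align(rows_a, rows_b, scoring)
        clusters[n + step] = (ia + ib, new_a + new_b)
    order, rows = clusters.popitem()[1]
    by_index = dict(zip(order, rows))
    return MultipleAlignment(
        [records[i].id for i in sorted(by_index)],
        [by_index[i] for i in sorted(by_index)],
        [records[i].taxon for i in sorted(by_index)],
    )


def map_to_reference(aln: MultipleAlignment, reference_id: str) -> ReferenceMap:
    """Map alignment columns to 1-based residue numbers of one row."""
    if reference_id not in aln.ids:
        raise KeyError(f"reference {reference_id!r} not in alignment")
    row = aln.row(reference_id)
    column_of: dict[int, int] = {}
    residue_of: dict[int, int] = {}
    res = 0
    for col, c in enumerate(row):
        if c != GAP:
            res += 1
            column_of[res] = col
            residue_of[col] = res
    return ReferenceMap(reference_id, column_of, residue_of)


# ---------------------------------------------------------------------------
# FASTA / Clustal IO


def read_fasta(path) -> list[SequenceRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxon = rec.description.split(maxsplit=1)[1] if " " in rec.description else ""
        records.append(SequenceRecord(rec.id, str(rec.seq), taxon))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.taxon)
        for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


def read_alignment_fasta(path) -> MultipleAlignment:
    ids, rows, taxa = [], [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq).upper())
        taxa.append(rec.description.split(maxsplit=1)[1] if " " in rec.description else "")
    return MultipleAlignment(ids, rows, taxa)


def write_alignment_fasta(aln: MultipleAlignment, path) -> None:
    bio = [
        _BioSeqRecord(Seq(row), id=i, description=t)
        for i, row, t in zip(aln.ids, aln.rows, aln.taxa)
    ]
    SeqIO.write(bio, str(path), "fasta")


def write_alignment_clustal(aln: MultipleAlignment, path) -> None:
    from Bio.Align import MultipleSeqAlignment

    msa = MultipleSeqAlignment(
        [_BioSeqRecord(Seq(row), id=i, description="") for i, row in zip(aln.ids, aln.rows)]
    )
    from Bio import AlignIO

    AlignIO.write(msa, str(path), "clustal")
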