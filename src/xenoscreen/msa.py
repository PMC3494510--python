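"""Progressive multiple alignment and automated column trimming.

The aligner is a ClustalX-style progressive scheme: a neighbor-joining guide
tree on k-mer distances, then profile-profile global alignment with affine
gap penalties, merging profiles leaf-to-root.  Column scores are
sum-of-pairs expectations under BLOSUM62 with gap characters contributing
zero, so gap placement is governed entirely by the affine penalties.

Manual curation of alignments is replaced by two deterministic column
filters (gap fraction, majority-residue fraction); rows are never removed
automatically, but a per-row mean-identity report is available for human
review.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from Bio.Align import substitution_matrices

from .errors import DataError
from .io_formats import SequenceRecord

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
_ALPHABET = str(_BLOSUM62.alphabet)  # ARNDCQEGHILKMFPSTWYVBZX*
_NSYM = len(_ALPHABET) + 1  # + gap
_GAP_IDX = _NSYM - 1

# extended score matrix: gap scores 0 against everything
_SCORES = np.zeros((_NSYM, _NSYM))
_SCORES[: len(_ALPHABET), : len(_ALPHABET)] = np.asarray(_BLOSUM62)

_CODE = {c: i for i, c in enumerate(_ALPHABET)}
_CODE["-"] = _GAP_IDX

NEG = -1e30


@dataclass
class Alignment:
    """Aligned SequenceRecords of equal length; '-' is the gap character.

    ``kept_columns`` indexes the retained columns of the alignment this one
    was trimmed from (identity mapping for untrimmed alignments).
    """

    records: List[SequenceRecord]
    kept_columns: List[int] = field(default_factory=list)

    def __post_init__(self):
        if not self.records:
            raise DataError("empty alignment")
        lengths = {len(r.seq) for r in self.records}
        if len(lengths) != 1:
            raise DataError("alignment rows have unequal lengths")
        if not self.kept_columns:
            self.kept_columns = list(range(self.width))
        if list(self.kept_columns) != sorted(set(self.kept_columns)):
            raise DataError("kept_columns must be strictly increasing")

    @property
    def width(self) -> int:
        return len(self.records[0].seq)

    def column(self, j: int) -> str:
        return "".join(r.seq[j] for r in self.records)


def kmer_distance(a: str, b: str, k: int = 3) -> float:
    """1 - (shared distinct k-mers / min(#kmers a, #kmers b))."""
    if len(a) < k or len(b) < k:
        raise DataError(f"sequences shorter than k={k}")
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE.get(c, _CODE["X"]) for c in seq], dtype=np.int64)


def _profile(rows: np.ndarray) -> np.ndarray:
    """(L, NSYM) column residue frequencies of an encoded alignment block.

    Frequencies (not counts) keep profile-profile column scores on the
    single-substitution-matrix scale regardless of profile depth, so the
    fixed affine gap penalties stay meaningful as profiles grow.
    """
    L = rows.shape[1]
    prof = np.zeros((L, _NSYM))
    for j in range(L):
        counts = np.bincount(rows[:, j], minlength=_NSYM)
        prof[j] = counts / rows.shape[0]
    return prof


def _align_profiles(
    rows_a: np.ndarray, rows_b: np.ndarray, gap_open: float, gap_extend: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Global affine-gap profile-profile alignment (Gotoh, vectorised rows).

    Returns the gapped row blocks.  Gap penalties: a gap of length g costs
    gap_open + g * gap_extend, applied once per alignment column regardless
    of profile depth.
    """
    pa, pb = _profile(rows_a), _profile(rows_b)
    La, Lb = pa.shape[0], pb.shape[0]
    # sum-of-pairs expected column scores: S[i, j] = pa[i] . SCORES . pb[j]
    S = pa @ _SCORES @ pb.T
    go, ge = gap_open + gap_extend, gap_extend  # first gap column costs go

    M = np.full(Lb + 1, NEG)
    Ix = np.full(Lb + 1, NEG)  # gap in B (consumes A rows)
    Iy = np.full(Lb + 1, NEG)  # gap in A (consumes B columns)
    M[0] = 0.0
    j_idx = np.arange(Lb + 1)
    Iy[1:] = -go - ge * (j_idx[1:] - 1)

    ptr_M = np.zeros((La + 1, Lb + 1), dtype=np.int8)  # 0=M,1=Ix,2=Iy
    ptr_Ix = np.zeros((La + 1, Lb + 1), dtype=np.int8)  # 0 from M, 1 extend
    org_Iy = np.zeros((La + 1, Lb + 1), dtype=np.int32)  # source column of gap run
    org_Iy[0, 1:] = 0

    for i in range(1, La + 1):
        best_prev = np.maximum(np.maximum(M, Ix), Iy)
        choice = np.select([M >= best_prev - 1e-12, Ix >= best_prev - 1e-12], [0, 1], default=2)
        newM = np.full(Lb + 1, NEG)
        newM[1:] = S[i - 1] + best_prev[:-1]
        ptr_M[i, 1:] = choice[:-1]
        newIx = np.maximum(M - go, Ix - ge)
        ptr_Ix[i] = np.where(M - go >= Ix - ge, 0, 1)
        # Iy within the new row: Iy[j] = max_{j0 < j} newM[j0] - go - ge*(j-1-j0)
        B = newM + ge * j_idx
        cm = np.maximum.accumulate(B)
        arg = np.where(B >= cm, j_idx, 0)
        arg = np.maximum.accumulate(arg)
        newIy = np.full(Lb + 1, NEG)
        newIy[1:] = cm[:-1] - go - ge * (j_idx[1:] - 1)
        org_Iy[i, 1:] = arg[:-1]
        M, Ix, Iy = newM, newIx, newIy

    # traceback; state 0 = M (match column), 1 = Ix (gap in B), 2 = Iy (gap in A)
    i, j = La, Lb
    finals = np.array([M[Lb], Ix[Lb], Iy[Lb]])
    state = int(np.argmax(finals))
    cols: List[Tuple[int, int]] = []  # column = (A row index or -1, B col index or -1)
    while i > 0 or j > 0:
        if state == 0:
            cols.append((i - 1, j - 1))
            state = int(ptr_M[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            cols.append((i - 1, -1))
            state = int(ptr_Ix[i, j])  # 0: opened from M, 1: extends Ix
            i -= 1
        else:
            j0 = int(org_Iy[i, j])  # gap run in A opened from M at (i, j0)
            while j > j0:
                cols.append((-1, j - 1))
                j -= 1
            state = 0
    cols.reverse()
    na, nb = rows_a.shape[0], rows_b.shape[0]
    out_a = np.full((na, len(cols)), _GAP_IDX, dtype=np.int64)
    out_b = np.full((nb, len(cols)), _GAP_IDX, dtype=np.int64)
    for c, (ia, ib) in enumerate(cols):
        if ia >= 0:
            out_a[:, c] = rows_a[:, ia]
        if ib >= 0:
            out_b[:, c] = rows_b[:, ib]
    return out_a, out_b


def _decode(row: np.ndarray) -> str:
    sym = _ALPHABET + "-"
    return "".join(sym[i] for i in row)


def progressive_align(
    records: Sequence[SequenceRecord],
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> Alignment:
    """Progressive multiple alignment over an NJ guide tree on k-mer distances.

    Output row order equals input order.  Guide-tree ties are resolved by
    input position (sequence ids sorted upstream give lexicographic
    tie-breaking).  Degapping any output row reproduces its input sequence.
    """
    records = list(records)
    if len(records) < 2:
        raise DataError("progressive alignment requires at least 2 sequences")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate sequence ids in alignment input")
    encoded = {r.id: _encode(r.seq)[None, :] for r in records}

    if len(records) == 2:
        merge_order = [(ids[0], ids[1])]
    else:
        from .tree_inference import DistanceMatrix, nj_tree  # local import: avoid cycle

        n = len(records)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = kmer_distance(records[i].seq, records[j].seq)
        guide = nj_tree(DistanceMatrix(ids, d))
        merge_order = _merge_order(guide)

    blocks: Dict[str, Tuple[List[str], np.ndarray]] = {
        r.id: ([r.id], encoded[r.id]) for r in records
    }
    key = None
    for left, right in merge_order:
        ids_l, rows_l = blocks.pop(left)
        ids_r, rows_r = blocks.pop(right)
        out_l, out_r = _align_profiles(rows_l, rows_r, gap_open, gap_extend)
        key = left
        blocks[key] = (ids_l + ids_r, np.vstack([out_l, out_r]))
    member_ids, rows = blocks[key]
    row_of = {sid: k for k, sid in enumerate(member_ids)}
    out_records = [
        SequenceRecord(r.id, _decode(rows[row_of[r.id]]), "protein") for r in records
    ]
    aln = Alignment(out_records)
    # content conservation check (cheap, guards the aligner)
    for rec, orig in zip(out_records, records):
        if rec.seq.replace("-", "") != orig.seq:
            raise DataError(f"aligner corrupted sequence {orig.id!r}")
    return aln


def _merge_order(guide) -> List[Tuple[str, str]]:
    """Leaf-to-root merge schedule from an (unrooted) guide tree.

    Each internal node merges its children's blocks pairwise; each block is
    keyed by the id of its first member.
    """
    order: List[Tuple[str, str]] = []

    def visit(node) -> str:
        if node.is_leaf():
            return node.taxon.label
        keys = [visit(c) for c in node.child_nodes()]
        acc = keys[0]
        for k in keys[1:]:
            order.append((acc, k))
        return acc

    visit(guide.tree.seed_node)
    return order


def trim_alignment(
    aln: Alignment, max_gap_frac: float = 0.5, min_majority_frac: float = 0.0
) -> Alignment:
    """Drop gappy and (optionally) low-majority columns.

    A column is removed when its gap fraction exceeds ``max_gap_frac`` or
    when the frequency of its most common residue (among non-gap characters)
    is below ``min_majority_frac``.  Rows are never removed.  Idempotent.
    """
    n = len(aln.records)
    keep: List[int] = []
    for j in range(aln.width):
        col = aln.column(j)
        gap_frac = col.count("-") / n
        if gap_frac > max_gap_frac:
            continue
        residues = [c for c in col if c != "-"]
        if min_majority_frac > 0 and residues:
            top = max(residues.count(c) for c in set(residues))
            if top / n < min_majority_frac:
                continue
        keep.append(j)
    if not keep:
        raise DataError(
            "all columns trimmed; relax max_gap_frac / min_majority_frac"
        )
    records = [
        SequenceRecord(r.id, "".join(r.seq[j] for j in keep), r.moltype)
        for r in aln.records
    ]
    kept = [aln.kept_columns[j] for j in keep]
    return Alignment(records, kept_columns=kept)


def row_identity_report(aln: Alignment) -> Dict[str, float]:
    """Mean pairwise percent identity of each row against all other rows.

    Emitted for human review in place of automated removal of misaligned
    sequences.
    """
    rows = [r.seq for r in aln.records]
    n = len(rows)
    out = {}
    for i in range(n):
        idents = []
        for j in range(n):
            if i == j:
                continue
            pairs = [
                (a, b) for a, b in zip(rows[i], rows[j]) if a != "-" and b != "-"
            ]
            if pairs:
                idents.append(100.0 * sum(a == b for a, b in pairs) / len(pairs))
        out[aln.records[i].id] = float(np.mean(idents)) if idents else float("nan")
    return out
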