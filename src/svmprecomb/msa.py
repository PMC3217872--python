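"""Pairwise and progressive multiple alignment, percent identity, column filtering.

The aligner is a global Needleman-Wunsch with affine gap costs (gotoh three-state
DP), vectorized row-by-row with numpy; horizontal gap states use a max-plus
prefix-scan so each DP row costs O(m) vector operations. Traceback tie-breaking
is deterministic: diagonal, then up (gap in the second sequence), then left.

Progressive alignment builds a neighbor-joining guide tree from pairwise
p-distances and merges profiles leaves-to-root ("once a gap, always a gap").
Percent identity excludes columns where either row is gapped from the
denominator and counts N as a mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
from Bio.Align import substitution_matrices

from .seqio import SequenceRecord

NT_CODE = {c: i for i, c in enumerate("ACGTN-")}
NT_GAP = NT_CODE["-"]
NT_N = NT_CODE["N"]

AA_ORDER = "ARNDCQEGHILKMFPSTWYVBZX*"
AA_CODE = {c: i for i, c in enumerate(AA_ORDER + "-")}
AA_GAP = AA_CODE["-"]

_NEG = np.float32(-1e9)


@dataclass(frozen=True)
class AlignParams:
    """Scoring parameters: nt match/mismatch plus affine gap costs.

    ``gap_open`` is the total cost of a length-1 gap; each additional gap
    column costs ``gap_extend``. Protein profiles are scored with the
    substitution table named by ``aa_matrix``.
    """

    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = -10.0
    gap_extend: float = -1.0
    aa_matrix: str = "BLOSUM62"

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("require gap_open <= gap_extend <= 0")


class PercentIdentity(NamedTuple):
    value: float
    counted: int


@dataclass
class IdentityProfile:
    """Sliding-window percent identity between two aligned rows."""

    pair: tuple[str, str]
    window: int
    step: int
    centers: list[int]
    values: list[float]
    counted: list[int]


class MultipleAlignment:
    """Gapped sequences over a shared column space, with coordinate mapping."""

    def __init__(self, ids: list[str], rows: list[str], moltype: str = "nt"):
        if len(ids) != len(rows):
            raise ValueError("ids and rows length mismatch")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ids in alignment")
        if not rows:
            raise ValueError("empty alignment")
        ncols = len(rows[0])
        if any(len(r) != ncols for r in rows):
            raise ValueError("rows have unequal lengths")
        self.ids = list(ids)
        self.rows = list(rows)
        self.moltype = moltype
        self._index = {i: k for k, i in enumerate(self.ids)}
        self._encoded: np.ndarray | None = None

    # -- basic accessors ---------------------------------------------------
    @property
    def ncols(self) -> int:
        return len(self.rows[0])

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, id_: str) -> int:
        if id_ not in self._index:
            raise KeyError(f"id {id_!r} not in alignment")
        return self._index[id_]

    def row(self, id_: str) -> str:
        return self.rows[self.index(id_)]

    def degapped(self, id_: str) -> str:
        return self.row(id_).replace("-", "")

    @property
    def encoded(self) -> np.ndarray:
        """(nrows, ncols) uint8 matrix of symbol codes (gap included)."""
        if self._encoded is None:
            code = NT_CODE if self.moltype == "nt" else AA_CODE
            self._encoded = np.array(
                [[code[c] for c in row] for row in self.rows], dtype=np.uint8
            )
        return self._encoded

    # -- coordinate mapping (all 1-based) ----------------------------------
    def pos_to_col(self, id_: str, pos: int) -> int:
        """Column housing residue ``pos`` of row ``id_`` (1-based both)."""
        row = self.row(id_)
        count = 0
        for col, char in enumerate(row, start=1):
            if char != "-":
                count += 1
                if count == pos:
                    return col
        raise ValueError(f"residue {pos} beyond row {id_!r} (length {count})")

    def col_to_pos(self, id_: str, col: int) -> int:
        """Residue index at column ``col`` of row ``id_``.

        If the column is a gap, returns the index of the last residue at or
        before it (0 when none) — the natural convention for mapping
        breakpoint columns onto ungapped sequence coordinates.
        """
        if not (1 <= col <= self.ncols):
            raise ValueError(f"column {col} outside [1, {self.ncols}]")
        row = self.row(id_)
        return sum(1 for c in row[:col] if c != "-")

    # -- construction / output ---------------------------------------------
    @classmethod
    def from_records(cls, records: list[SequenceRecord]) -> "MultipleAlignment":
        """Wrap pre-aligned (equal-length, possibly gapped) records."""
        moltype = records[0].moltype if records else "nt"
        return cls([r.id for r in records], [r.seq for r in records], moltype)

    def to_records(self) -> list[SequenceRecord]:
        return [
            SequenceRecord(i, r.replace("-", ""), self.moltype)
            for i, r in zip(self.ids, self.rows)
        ]

    def write_fasta(self, path: str, width: int = 70) -> None:
        with open(path, "w") as handle:
            for id_, row in zip(self.ids, self.rows):
                handle.write(f">{id_}\n")
                for i in range(0, len(row), width):
                    handle.write(row[i : i + width] + "\n")

    @classmethod
    def read_fasta(cls, path: str, moltype: str = "nt") -> "MultipleAlignment":
        ids: list[str] = []
        rows: list[str] = []
        current: list[str] | None = None
        with open(path) as handle:
            for line in handle:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    ids.append(line[1:].split()[0])
                    current = []
                    rows.append(current)  # type: ignore[arg-type]
                else:
                    current.append(line.upper())  # type: ignore[union-attr]
        return cls(ids, ["".join(r) for r in rows], moltype)

    def subalignment_columns(self, start: int, end: int) -> "MultipleAlignment":
        """Columns [start, end] (1-based inclusive), keeping all rows."""
        if not (1 <= start <= end <= self.ncols):
            raise ValueError(f"invalid column range ({start}, {end})")
        return MultipleAlignment(
            self.ids, [r[start - 1 : end] for r in self.rows], self.moltype
        )


# ---------------------------------------------------------------------------
# Affine-gap DP engine (shared by pairwise and profile alignment)
# ---------------------------------------------------------------------------


def _affine_dp(score: np.ndarray, gap_open: float, gap_extend: float) -> tuple[list[int | None], list[int | None]]:
    """Global affine-gap alignment over a precomputed (n, m) column-score matrix.

    Returns two equal-length index paths (0-based indices into each side, None
    for gap columns). Tie preference during traceback: diagonal (M), then up
    (X: consuming rows / gap in columns), then left (Y).
    """
    n, m = score.shape
    go = np.float32(gap_open)
    ge = np.float32(gap_extend)

    M = np.full((n + 1, m + 1), _NEG, dtype=np.float32)
    X = np.full((n + 1, m + 1), _NEG, dtype=np.float32)
    Y = np.full((n + 1, m + 1), _NEG, dtype=np.float32)
    M[0, 0] = 0.0
    if n:
        X[1:, 0] = go + ge * np.arange(n, dtype=np.float32)
    if m:
        Y[0, 1:] = go + ge * np.arange(m, dtype=np.float32)

    jj = np.arange(m, dtype=np.float32)
    for i in range(1, n + 1):
        mp, xp, yp = M[i - 1], X[i - 1], Y[i - 1]
        X[i, 1:] = np.maximum(mp[1:] + go, xp[1:] + ge)
        X[i, 0] = go + ge * (i - 1)
        best_prev = np.maximum(np.maximum(mp[:-1], xp[:-1]), yp[:-1])
        M[i, 1:] = best_prev + score[i - 1]
        # Y[i, j] = max(M[i, j-1] + go, Y[i, j-1] + ge): max-plus prefix scan.
        a = M[i, :-1] + go
        run = np.maximum.accumulate(a - ge * jj)
        Y[i, 1:] = run + ge * jj
    # Which matrix ends best (preference M > X > Y on ties).
    return _traceback(M, X, Y, score, go, ge, n, m)


def _traceback(M, X, Y, score, go, ge, n, m):
    end_scores = (M[n, m], X[n, m], Y[n, m])
    state = int(np.argmax([end_scores[0] + 1e-4, end_scores[1] + 1e-5, end_scores[2]]))
    # small epsilon bias implements M > X > Y preference under exact ties
    path_a: list[int | None] = []
    path_b: list[int | None] = []
    i, j = n, m
    states = "MXY"
    cur = states[state]
    while i > 0 or j > 0:
        if cur == "M":
            if i == 0 or j == 0:
                raise RuntimeError("traceback error")
            path_a.append(i - 1)
            path_b.append(j - 1)
            target = M[i, j] - score[i - 1, j - 1]
            i, j = i - 1, j - 1
            if abs(M[i, j] - target) < 1e-3:
                cur = "M"
            elif abs(X[i, j] - target) < 1e-3:
                cur = "X"
            else:
                cur = "Y"
        elif cur == "X":
            path_a.append(i - 1)
            path_b.append(None)
            val = X[i, j]
            i -= 1
            cur = "M" if abs(M[i, j] + go - val) < 1e-3 else "X"
        else:
            path_a.append(None)
            path_b.append(j - 1)
            val = Y[i, j]
            j -= 1
            cur = "M" if abs(M[i, j] + go - val) < 1e-3 else "Y"
    path_a.reverse()
    path_b.reverse()
    return path_a, path_b


def _nt_score_matrix(params: AlignParams) -> np.ndarray:
    """Symbol-level scores for A,C,G,T,N: N scores as mismatch against all."""
    s = np.full((5, 5), params.mismatch, dtype=np.float32)
    for i in range(4):
        s[i, i] = params.match
    return s


_AA_MATRIX_CACHE: dict[str, np.ndarray] = {}


def _aa_score_matrix(params: AlignParams) -> np.ndarray:
    if params.aa_matrix not in _AA_MATRIX_CACHE:
        table = substitution_matrices.load(params.aa_matrix)
        nsym = len(AA_ORDER)
        s = np.zeros((nsym, nsym), dtype=np.float32)
        for i, a in enumerate(AA_ORDER):
            for j, b in enumerate(AA_ORDER):
                try:
                    s[i, j] = table[a, b]
                except (KeyError, IndexError):
                    s[i, j] = 0.0
        _AA_MATRIX_CACHE[params.aa_matrix] = s
    return _AA_MATRIX_CACHE[params.aa_matrix]


def _symbol_scores(moltype: str, params: AlignParams) -> np.ndarray:
    return _nt_score_matrix(params) if moltype == "nt" else _aa_score_matrix(params)


def pairwise_align(
    a: SequenceRecord, b: SequenceRecord, params: AlignParams | None = None
) -> MultipleAlignment:
    """Global affine-gap alignment of two records (2-row alignment)."""
    params = params or AlignParams()
    if a.moltype != b.moltype:
        raise ValueError("cannot align records of different moltypes")
    if not a.seq or not b.seq:
        raise ValueError("cannot align empty sequence")
    code = NT_CODE if a.moltype == "nt" else AA_CODE
    ea = np.array([code[c] for c in a.seq], dtype=np.intp)
    eb = np.array([code[c] for c in b.seq], dtype=np.intp)
    sym = _symbol_scores(a.moltype, params)
    score = sym[np.ix_(ea, eb)]
    pa, pb = _affine_dp(score, params.gap_open, params.gap_extend)
    row_a = "".join("-" if i is None else a.seq[i] for i in pa)
    row_b = "".join("-" if j is None else b.seq[j] for j in pb)
    return MultipleAlignment([a.id, b.id], [row_a, row_b], a.moltype)


def alignment_score(aln: MultipleAlignment, params: AlignParams | None = None) -> float:
    """Affine score of a 2-row alignment (for oracle comparisons)."""
    params = params or AlignParams()
    if len(aln) != 2:
        raise ValueError("alignment_score is defined for pairwise alignments")
    sym = _symbol_scores(aln.moltype, params)
    gap = NT_GAP if aln.moltype == "nt" else AA_GAP
    e = aln.encoded
    total = 0.0
    in_gap = [False, False]
    for col in range(aln.ncols):
        x, y = int(e[0, col]), int(e[1, col])
        if x == gap and y == gap:
            raise ValueError("all-gap column in pairwise alignment")
        if x == gap or y == gap:
            which = 0 if x == gap else 1
            total += params.gap_extend if in_gap[which] else params.gap_open
            in_gap[which] = True
            in_gap[1 - which] = False
        else:
            total += sym[x, y]
            in_gap = [False, False]
    return total


# ---------------------------------------------------------------------------
# Progressive MSA
# ---------------------------------------------------------------------------


def _profile(aln_rows: np.ndarray, nsym: int, gap_code: int) -> np.ndarray:
    """(ncols, nsym) residue frequency profile (gaps excluded, weight 0)."""
    ncols = aln_rows.shape[1]
    prof = np.zeros((ncols, nsym), dtype=np.float32)
    nrows = aln_rows.shape[0]
    for s in range(nsym):
        prof[:, s] = (aln_rows == s).sum(axis=0)
    return prof / nrows


def _merge_alignments(
    left_ids: list[str],
    left_rows: np.ndarray,
    right_ids: list[str],
    right_rows: np.ndarray,
    sym: np.ndarray,
    gap_code: int,
    params: AlignParams,
) -> tuple[list[str], np.ndarray]:
    nsym = sym.shape[0]
    pl = _profile(left_rows, nsym, gap_code)
    pr = _profile(right_rows, nsym, gap_code)
    score = (pl @ sym) @ pr.T
    pa, pb = _affine_dp(score, params.gap_open, params.gap_extend)
    ncols = len(pa)
    out = np.full((left_rows.shape[0] + right_rows.shape[0], ncols), gap_code, dtype=np.uint8)
    for col, (i, j) in enumerate(zip(pa, pb)):
        if i is not None:
            out[: left_rows.shape[0], col] = left_rows[:, i]
        if j is not None:
            out[left_rows.shape[0] :, col] = right_rows[:, j]
    return left_ids + right_ids, out


def progressive_msa(
    records: list[SequenceRecord], params: AlignParams | None = None
) -> MultipleAlignment:
    """Progressive multiple alignment with an NJ guide tree.

    Guide distances are p-distances from all pairwise alignments; profiles are
    merged leaves-to-root with the same affine DP engine, so gaps introduced at
    one merge persist ("once a gap, always a gap").
    """
    params = params or AlignParams()
    if not records:
        raise ValueError("no records to align")
    moltypes = {r.moltype for r in records}
    if len(moltypes) != 1:
        raise ValueError("mixed moltypes in progressive_msa")
    moltype = records[0].moltype
    if len(records) == 1:
        return MultipleAlignment([records[0].id], [records[0].seq], moltype)
    if len(records) == 2:
        return pairwise_align(records[0], records[1], params)

    from .phylo import DistanceMatrix, nj_tree  # local import: phylo uses msa types

    ids = [r.id for r in records]
    n = len(records)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pair = pairwise_align(records[i], records[j], params)
            pid = percent_identity(pair, records[i].id, records[j].id)
            dist[i, j] = dist[j, i] = 1.0 - pid.value / 100.0
    guide = nj_tree(DistanceMatrix(ids, dist))

    code = NT_CODE if moltype == "nt" else AA_CODE
    gap_code = NT_GAP if moltype == "nt" else AA_GAP
    sym = _symbol_scores(moltype, params)
    by_id = {r.id: r for r in records}

    def build(node) -> tuple[list[str], np.ndarray]:
        if not node.children:
            rec = by_id[node.name]
            row = np.array([[code[c] for c in rec.seq]], dtype=np.uint8)
            return [rec.id], row
        parts = [build(child) for child in node.children]
        ids_acc, rows_acc = parts[0]
        for ids_next, rows_next in parts[1:]:
            ids_acc, rows_acc = _merge_alignments(
                ids_acc, rows_acc, ids_next, rows_next, sym, gap_code, params
            )
        return ids_acc, rows_acc

    out_ids, out_rows = build(guide.root)
    symbols = "ACGTN-" if moltype == "nt" else AA_ORDER + "-"
    rows = ["".join(symbols[c] for c in row) for row in out_rows]
    # restore input record order
    order = {id_: k for k, id_ in enumerate(out_ids)}
    ordered_ids = [r.id for r in records]
    return MultipleAlignment(ordered_ids, [rows[order[i]] for i in ordered_ids], moltype)


# ---------------------------------------------------------------------------
# Identity computations
# ---------------------------------------------------------------------------


def _pair_masks(
    aln: MultipleAlignment, i: str, j: str
) -> tuple[np.ndarray, np.ndarray]:
    """(counted, matched) boolean column masks for a row pair."""
    e = aln.encoded
    gap = NT_GAP if aln.moltype == "nt" else AA_GAP
    a = e[aln.index(i)]
    b = e[aln.index(j)]
    counted = (a != gap) & (b != gap)
    matched = counted & (a == b)
    if aln.moltype == "nt":
        matched &= a != NT_N  # N counts as mismatch even against N
    return counted, matched


def percent_identity(
    aln: MultipleAlignment,
    i: str,
    j: str,
    region: tuple[int, int] | str = "all",
) -> PercentIdentity:
    """Percent identity between two rows over a column region.

    Columns where either row is gapped are excluded from the denominator;
    N counts as a mismatch. Returns the identity and the counted-column count.
    """
    counted, matched = _pair_masks(aln, i, j)
    if region != "all":
        start, end = region
        if not (1 <= start <= end <= aln.ncols):
            raise ValueError(f"region ({start}, {end}) outside [1, {aln.ncols}]")
        sel = slice(start - 1, end)
        counted = counted[sel]
        matched = matched[sel]
    n_counted = int(counted.sum())
    if n_counted == 0:
        raise ValueError(f"empty comparison between {i!r} and {j!r}")
    return PercentIdentity(100.0 * matched.sum() / n_counted, n_counted)


def identity_profile(
    aln: MultipleAlignment, i: str, j: str, window: int = 30, step: int = 3
) -> IdentityProfile:
    """Sliding-window percent identity along alignment columns."""
    if window < 10:
        raise ValueError("window must be >= 10")
    if step < 1:
        raise ValueError("step must be >= 1")
    if window > aln.ncols:
        raise ValueError(f"window {window} exceeds alignment width {aln.ncols}")
    counted, matched = _pair_masks(aln, i, j)
    centers: list[int] = []
    values: list[float] = []
    counts: list[int] = []
    for start in range(0, aln.ncols - window + 1, step):
        c = int(counted[start : start + window].sum())
        if c == 0:
            continue
        m = int(matched[start : start + window].sum())
        centers.append(start + (window + 1) // 2)
        values.append(100.0 * m / c)
        counts.append(c)
    return IdentityProfile((i, j), window, step, centers, values, counts)


def write_identity_profile(profile: IdentityProfile, path: str) -> None:
    with open(path, "w") as handle:
        handle.write("center\tvalue\tcounted_columns\n")
        for c, v, n in zip(profile.centers, profile.values, profile.counted):
            handle.write(f"{c}\t{v:.4f}\t{n}\n")


def filter_columns(
    aln: MultipleAlignment, max_gap_fraction: float
) -> tuple[MultipleAlignment, list[int]]:
    """Drop columns whose gap fraction exceeds ``max_gap_fraction``.

    Returns the kept alignment and the original 1-based indices of removed
    columns. Row order is preserved.
    """
    if not (0 <= max_gap_fraction <= 1):
        raise ValueError("max_gap_fraction must be in [0, 1]")
    gap = NT_GAP if aln.moltype == "nt" else AA_GAP
    frac = (aln.encoded == gap).mean(axis=0)
    keep = frac <= max_gap_fraction
    removed = [int(c) + 1 for c in np.nonzero(~keep)[0]]
    if not keep.any():
        raise ValueError("all columns removed by gap filter")
    rows = ["".join(ch for ch, k in zip(row, keep) if k) for row in aln.rows]
    return MultipleAlignment(aln.ids, rows, aln.moltype), removed
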