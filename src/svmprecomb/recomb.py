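"""Recombination signal detection.

Two detectors operate on multi-domain toxin cDNAs:

* **Triplet shift-region segmentation** — for three aligned sequences (A, B, C),
  each gap-free column is classified by which pair agrees (AB, AC, BC), all
  equal (ALL_EQ) or all different (ALL_DIFF). A recombinant produces a
  characteristic inversion of identity: one pair dominates the 5' side, a
  different pair the 3' side, often separated by a run where all three are
  identical (the "shift region"). Segment boundaries between different
  dominant pair-states are reported as candidate recombination breakpoints,
  with an uncertainty interval from the last informative column of the left
  state to the first informative column of the right state.

* **Repeat / reverse-complement segment scan** — short (~12 bp) segments
  repeated in, or complementary to, other regions of the same or other
  sequences; such segments could mediate template switching or loop formation
  during recombination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .msa import NT_GAP, MultipleAlignment
from .seqio import SequenceRecord, reverse_complement

ALL_EQ = "ALL_EQ"
ALL_DIFF = "ALL_DIFF"
PAIR_STATES = ("AB", "AC", "BC")
INFORMATIVE = frozenset(PAIR_STATES)


@dataclass
class TripletStateVector:
    """Per-column identity states for a sequence triplet (gap columns skipped)."""

    ids: tuple[str, str, str]
    columns: list[int]  # 1-based alignment columns actually counted
    states: list[str]


@dataclass
class Segment:
    start_col: int
    end_col: int
    dominant_state: str
    pair_identities: dict[str, float] = field(default_factory=dict)


@dataclass
class Breakpoint:
    column: int  # midpoint of the uncertainty interval, alignment coords
    left_state: str
    right_state: str
    interval: tuple[int, int]  # last informative col of left, first of right
    shift_region: tuple[int, int] | None = None


@dataclass
class ShiftSegmentation:
    ids: tuple[str, str, str]
    segments: list[Segment]
    shift_regions: list[tuple[int, int]]
    breakpoints: list[Breakpoint]


@dataclass
class MotifHit:
    kind: str  # repeat | complement
    k: int
    source: tuple[str, int, int]  # id, start, end (1-based inclusive)
    target: tuple[str, int, int]
    mismatches: int
    orientation: str  # direct | reverse-complement


def triplet_states(
    aln: MultipleAlignment, a: str, b: str, c: str
) -> TripletStateVector:
    """Classify each gap-free column of a triplet by pairwise equality."""
    if len({a, b, c}) != 3:
        raise ValueError("triplet requires three distinct ids")
    e = aln.encoded
    ra, rb, rc = (e[aln.index(x)] for x in (a, b, c))
    ok = (ra != NT_GAP) & (rb != NT_GAP) & (rc != NT_GAP)
    cols: list[int] = []
    states: list[str] = []
    ab = ra == rb
    ac = ra == rc
    bc = rb == rc
    for col in np.nonzero(ok)[0]:
        if ab[col] and ac[col]:
            state = ALL_EQ
        elif ab[col]:
            state = "AB"
        elif ac[col]:
            state = "AC"
        elif bc[col]:
            state = "BC"
        else:
            state = ALL_DIFF
        cols.append(int(col) + 1)
        states.append(state)
    return TripletStateVector((a, b, c), cols, states)


# ---------------------------------------------------------------------------
# Shift-region segmentation
# ---------------------------------------------------------------------------


def _informative_columns(vec: TripletStateVector) -> list[tuple[int, str]]:
    """(column, state) for informative columns; neutral columns are skipped."""
    return [
        (col, state)
        for col, state in zip(vec.columns, vec.states)
        if state in INFORMATIVE
    ]


def _plurality_filter(
    cols: list[tuple[int, str]], halfwidth: int
) -> list[str]:
    """Smoothed label per informative column: plurality state among the
    ``halfwidth`` informative neighbors on each side (ties keep the column's
    own state when it participates, else resolve lexicographically)."""
    n = len(cols)
    labels: list[str] = []
    for i in range(n):
        lo, hi = max(0, i - halfwidth), min(n, i + halfwidth + 1)
        tally: dict[str, int] = {}
        for _, st in cols[lo:hi]:
            tally[st] = tally.get(st, 0) + 1
        best = max(tally.values())
        top = sorted(s for s, v in tally.items() if v == best)
        own = cols[i][1]
        labels.append(own if own in top else top[0])
    return labels


def _labeled_runs(
    cols: list[tuple[int, str]], labels: list[str]
) -> tuple[list[list[tuple[int, str]]], list[str]]:
    """Group informative columns into maximal runs of equal smoothed label.

    Runs keep each column's *original* state so that dominance and support
    statistics are judged on raw evidence, not on the smoothed labels.
    """
    runs: list[list[tuple[int, str]]] = []
    states: list[str] = []
    for (col, orig), label in zip(cols, labels):
        if runs and states[-1] == label:
            runs[-1].append((col, orig))
        else:
            runs.append([(col, orig)])
            states.append(label)
    return runs, states


def _collapse_equal(runs: list, states: list[str]) -> None:
    """Merge newly adjacent runs that share the same dominant state (in place)."""
    idx = 0
    while idx < len(runs) - 1:
        if states[idx] == states[idx + 1]:
            runs[idx : idx + 2] = [runs[idx] + runs[idx + 1]]
            states[idx : idx + 2] = [states[idx]]
        else:
            idx += 1


def _majority_state(cols: list[tuple[int, str]], prefer: str) -> str:
    tally: dict[str, int] = {}
    for _, st in cols:
        tally[st] = tally.get(st, 0) + 1
    best = max(tally.values())
    top = [s for s, v in tally.items() if v == best]
    return prefer if prefer in top else sorted(top)[0]


def segment_shift_regions(
    vec: TripletStateVector,
    min_segment: int = 20,
    smooth: int = 9,
    shift_min: int | None = None,
    dominance: float = 0.7,
    min_support: int = 8,
    anchor_support: int = 12,
    anchor_dominance: float = 0.85,
) -> ShiftSegmentation:
    """Segment a triplet state vector into dominant-pair-state regions.

    Informative columns are first smoothed by a plurality vote over their
    ``smooth`` informative neighbors on each side. A run then survives as a
    segment only if it spans at least ``min_segment`` columns, contains at
    least ``min_support`` informative columns of its dominant pair-state,
    and that state holds at least a ``dominance`` fraction against its
    runner-up; runs failing any criterion are merged into their larger
    neighbor (the merged run takes the majority state).

    A boundary between two surviving segments is accepted as a breakpoint
    only if at least one flank is an *anchor*: dominant-state count at least
    ``anchor_support`` and dominance fraction at least ``anchor_dominance``.
    A genuine recombination junction always has such a flank — on one side
    of the junction the recombinant is a recent copy of its partner, so that
    pair-state is near-pure — whereas boundaries arising from drift between
    roughly equidistant lineages are contaminated on both sides by the
    runner-up state. Boundaries without an anchor are dissolved by merging
    the weaker flank. Remaining breakpoints are emitted wherever adjacent
    segments have different dominant states; an intervening all-identical
    run of at least ``shift_min`` (default: ``min_segment``) counted columns
    is reported as a shift region.
    """
    if min_segment < 1:
        raise ValueError("min_segment must be >= 1")
    if not (0.5 <= dominance <= 1.0):
        raise ValueError("dominance must be in [0.5, 1.0]")
    shift_min = min_segment if shift_min is None else shift_min
    ids = vec.ids
    if not vec.columns:
        return ShiftSegmentation(ids, [], [], [])
    first_col, last_col = vec.columns[0], vec.columns[-1]

    info_cols = _informative_columns(vec)
    if not info_cols:
        seg = Segment(first_col, last_col, ALL_EQ, _segment_identities(vec, first_col, last_col))
        return ShiftSegmentation(ids, [seg], [], [])

    # 1. plurality smoothing over neighboring informative columns collapses
    # isolated disagreements so genuine identity-partner blocks cohere
    labels = _plurality_filter(info_cols, halfwidth=smooth)
    runs, states = _labeled_runs(info_cols, labels)

    # 2. merge runs that cannot stand as segments into their larger neighbor.
    # A surviving segment needs: span >= min_segment columns, at least
    # min_support informative columns of its dominant state, and that state
    # dominating its runner-up by at least the dominance fraction.

    def _span(idx: int) -> int:
        return runs[idx][-1][0] - runs[idx][0][0] + 1

    def _dom_count(idx: int) -> int:
        return sum(1 for _, st in runs[idx] if st == states[idx])

    def _ok(idx: int) -> bool:
        tally: dict[str, int] = {}
        for _, st in runs[idx]:
            tally[st] = tally.get(st, 0) + 1
        dom = tally.get(states[idx], 0)
        runner = max((v for s, v in tally.items() if s != states[idx]), default=0)
        # dominance is judged against the runner-up pair-state only: a third
        # sequence's private mutations create columns of the complementary
        # state that say nothing about which pair is the identity partner
        return (
            _span(idx) >= min_segment
            and dom >= min_support
            and dom / max(dom + runner, 1) >= dominance
        )

    def _merge(idx: int, neigh: int) -> None:
        lo, hi = sorted((idx, neigh))
        merged_cols = runs[lo] + runs[hi]
        merged_state = _majority_state(merged_cols, prefer=states[neigh])
        runs[lo : hi + 1] = [merged_cols]
        states[lo : hi + 1] = [merged_state]
        _collapse_equal(runs, states)

    while len(runs) > 1:
        bad = [idx for idx in range(len(runs)) if not _ok(idx)]
        if not bad:
            break
        idx = min(bad, key=lambda w: (_dom_count(w), _span(w), w))
        if idx == 0:
            neigh = 1
        elif idx == len(runs) - 1:
            neigh = len(runs) - 2
        else:
            neigh = idx - 1 if len(runs[idx - 1]) >= len(runs[idx + 1]) else idx + 1
        _merge(idx, neigh)

    # 3. boundary acceptance: a breakpoint needs one near-pure anchor flank

    def _frac(idx: int) -> float:
        tally: dict[str, int] = {}
        for _, st in runs[idx]:
            tally[st] = tally.get(st, 0) + 1
        dom = tally.get(states[idx], 0)
        runner = max((v for s, v in tally.items() if s != states[idx]), default=0)
        return dom / max(dom + runner, 1)

    def _is_anchor(idx: int) -> bool:
        return _dom_count(idx) >= anchor_support and _frac(idx) >= anchor_dominance

    changed = True
    while changed and len(runs) > 1:
        changed = False
        for ri in range(len(runs) - 1):
            if not (_is_anchor(ri) or _is_anchor(ri + 1)):
                weak = ri if _dom_count(ri) <= _dom_count(ri + 1) else ri + 1
                _merge(weak, ri + 1 if weak == ri else ri)
                changed = True
                break

    # 4. build tiling segments and breakpoints
    col_state = dict(zip(vec.columns, vec.states))
    segments: list[Segment] = []
    shift_regions: list[tuple[int, int]] = []
    breakpoints: list[Breakpoint] = []

    bounds: list[tuple[int, int]] = []  # (start, end) per final run, in alignment cols
    for ri, run in enumerate(runs):
        start = first_col if ri == 0 else None
        end = last_col if ri == len(runs) - 1 else None
        bounds.append((start, end))

    for ri in range(len(runs) - 1):
        left_run, right_run = runs[ri], runs[ri + 1]
        copy_state = states[ri] if _frac(ri) >= _frac(ri + 1) else states[ri + 1]
        left_last, right_first = _refine_boundary(
            vec, left_run, right_run, states[ri], states[ri + 1], copy_state
        )
        # counted neutral columns strictly between the two runs
        gap_cols = [
            c for c in vec.columns if left_last < c < right_first
        ]
        shift: tuple[int, int] | None = None
        # longest ALL_EQ run inside the gap
        best_run: tuple[int, int] | None = None
        cur_start = None
        prev = None
        for c in gap_cols + [None]:
            if c is not None and col_state[c] == ALL_EQ:
                if cur_start is None:
                    cur_start = c
                prev = c
            else:
                if cur_start is not None:
                    if best_run is None or (prev - cur_start) > (best_run[1] - best_run[0]):
                        best_run = (cur_start, prev)
                    cur_start = None
        if best_run is not None and (best_run[1] - best_run[0] + 1) >= shift_min:
            shift = best_run
            shift_regions.append(shift)
            left_end = shift[0] - 1
            right_start = shift[1] + 1
        else:
            midpoint = (left_last + right_first) // 2
            left_end = midpoint
            right_start = midpoint + 1
        bounds[ri] = (bounds[ri][0], left_end)
        bounds[ri + 1] = (right_start, bounds[ri + 1][1])
        breakpoints.append(
            Breakpoint(
                column=(left_last + right_first) // 2,
                left_state=states[ri],
                right_state=states[ri + 1],
                interval=(left_last, right_first),
                shift_region=shift,
            )
        )

    for ri, run in enumerate(runs):
        start, end = bounds[ri]
        segments.append(
            Segment(start, end, states[ri], _segment_identities(vec, start, end))
        )
        if ri < len(runs) - 1 and breakpoints[ri].shift_region is not None:
            s, e = breakpoints[ri].shift_region
            segments.append(Segment(s, e, ALL_EQ, _segment_identities(vec, s, e)))

    return ShiftSegmentation(ids, segments, shift_regions, breakpoints)


#: states contradicting a given copy-pair state: every informative or
#: all-different column where that pair disagrees
_CONTRARY = {
    "AB": ("AC", "BC", ALL_DIFF),
    "AC": ("AB", "BC", ALL_DIFF),
    "BC": ("AB", "AC", ALL_DIFF),
}


def _refine_boundary(
    vec: TripletStateVector,
    left_run: list[tuple[int, str]],
    right_run: list[tuple[int, str]],
    left_state: str,
    right_state: str,
    copy_state: str,
) -> tuple[int, int]:
    """Change-point refinement of the boundary between two dominant states.

    At a genuine junction one flank carries the copy pair (the recombinant
    and its sequence partner), which agrees at every column up to the
    junction. Any column where that pair *disagrees* — the other two pair
    states and ALL_DIFF alike — is therefore hard evidence that the junction
    lies on the copy side of it, so the change point is placed between
    copy-state columns and all contrary columns (not merely the opposite
    dominant state, whose columns are only a subset of the contrary
    evidence). ``copy_state`` names the purer flank's state. The split
    maximizes copy-state columns on the copy side plus contrary columns on
    the other (ties: middle of the optimal plateau). Returns the flanking
    evidence columns (last copy-pair agreement, first copy-pair
    disagreement, in left-to-right order).
    """
    lo, hi = left_run[0][0], right_run[-1][0]
    contrary = _CONTRARY[copy_state]
    cols = [
        (c, s)
        for c, s in zip(vec.columns, vec.states)
        if lo <= c <= hi and (s == copy_state or s in contrary)
    ]
    if not cols:
        return left_run[-1][0], right_run[0][0]
    flipped = copy_state == right_state
    if flipped:  # scan with the copy side first
        cols.reverse()
    # score(k) = #copy_state in cols[:k] + #contrary in cols[k:]
    total_contrary = sum(1 for _, s in cols if s != copy_state)
    scores = [total_contrary]
    acc = total_contrary
    for _, s in cols:
        acc += 1 if s == copy_state else -1
        scores.append(acc)
    best_score = max(scores)
    plateau = [k for k, sc in enumerate(scores) if sc == best_score]
    k = plateau[len(plateau) // 2]
    copy_cols = [c for c, s in cols[:k] if s == copy_state]
    contra_cols = [c for c, s in cols[k:] if s != copy_state]
    copy_col = copy_cols[-1] if copy_cols else cols[0][0]
    contra_col = contra_cols[0] if contra_cols else cols[-1][0]
    return (contra_col, copy_col) if flipped else (copy_col, contra_col)


def _segment_identities(
    vec: TripletStateVector, start_col: int, end_col: int
) -> dict[str, float]:
    """Per-pair percent identity over a segment, from the state vector itself."""
    agree = {"AB": 0, "AC": 0, "BC": 0}
    total = 0
    for col, state in zip(vec.columns, vec.states):
        if not (start_col <= col <= end_col):
            continue
        total += 1
        if state == ALL_EQ:
            for key in agree:
                agree[key] += 1
        elif state in agree:
            agree[state] += 1
    if total == 0:
        return {}
    return {pair: 100.0 * n / total for pair, n in agree.items()}


def scan_triplet(
    aln: MultipleAlignment,
    a: str,
    b: str,
    c: str,
    min_segment: int = 20,
    smooth: int = 9,
    dominance: float = 0.7,
    min_support: int = 8,
    anchor_support: int = 12,
    anchor_dominance: float = 0.85,
) -> tuple[ShiftSegmentation, list[dict[str, int]]]:
    """Segment a triplet and map each breakpoint into ungapped coordinates.

    Returns the segmentation plus, per breakpoint, a dict id -> 1-based
    position in that sequence's own (ungapped) coordinates.
    """
    vec = triplet_states(aln, a, b, c)
    seg = segment_shift_regions(
        vec, min_segment=min_segment, smooth=smooth, dominance=dominance,
        min_support=min_support, anchor_support=anchor_support,
        anchor_dominance=anchor_dominance,
    )
    positions = [
        {id_: aln.col_to_pos(id_, bp.column) for id_ in (a, b, c)}
        for bp in seg.breakpoints
    ]
    return seg, positions


# ---------------------------------------------------------------------------
# Repeat / reverse-complement segment scan
# ---------------------------------------------------------------------------


def _window_mismatches(ea: np.ndarray, eb: np.ndarray, k: int) -> np.ndarray:
    """(len(a)-k+1, len(b)-k+1) mismatch counts of all k-window pairs."""
    na, nb = len(ea) - k + 1, len(eb) - k + 1
    if na <= 0 or nb <= 0:
        return np.zeros((max(na, 0), max(nb, 0)), dtype=np.int16)
    eq = np.equal.outer(ea, eb)
    acc = np.zeros((na, nb), dtype=np.int16)
    for t in range(k):
        acc += eq[t : t + na, t : t + nb]
    return (k - acc).astype(np.int16)


def _encode(seq: str) -> np.ndarray:
    table = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
    return np.array([table[c] for c in seq], dtype=np.int8)


def find_repeats_and_complements(
    records: list[SequenceRecord],
    k: int = 12,
    max_mismatch: int = 1,
    min_separation: int = 24,
    merge: bool = True,
) -> list[MotifHit]:
    """Find k-length segments repeated or reverse-complementary elsewhere.

    All pairs of k-windows within one sequence or across sequences are
    compared directly (repeats) and against the reverse complement
    (complements), allowing up to ``max_mismatch`` mismatches. Within-sequence
    pairs must have start positions at least ``min_separation`` apart; the
    trivial self-hit is excluded. With ``merge`` true, diagonally overlapping
    hits are merged into maximal runs (mismatches recounted over the run).
    """
    if k < 6:
        raise ValueError("k must be >= 6")
    for rec in records:
        if rec.moltype != "nt":
            raise TypeError("repeat scan requires nucleotide records")
        if len(rec.seq) < k:
            raise ValueError(f"record {rec.id!r} shorter than k={k}")

    enc = {r.id: _encode(r.seq) for r in records}
    rc_enc = {r.id: _encode(reverse_complement(r.seq)) for r in records}
    hits: list[MotifHit] = []

    for x in range(len(records)):
        for y in range(x, len(records)):
            a, b = records[x], records[y]
            same = x == y
            la, lb = len(a.seq), len(b.seq)

            # direct repeats
            mm = _window_mismatches(enc[a.id], enc[b.id], k)
            for i, j in zip(*np.nonzero(mm <= max_mismatch)):
                i, j = int(i), int(j)
                if same:
                    if j <= i:  # canonical order, excludes self-hit
                        continue
                    if j - i < min_separation:
                        continue
                hits.append(
                    MotifHit(
                        "repeat", k,
                        (a.id, i + 1, i + k),
                        (b.id, j + 1, j + k),
                        int(mm[i, j]), "direct",
                    )
                )

            # reverse-complement matches: window j' in rc(b) covers b positions
            # [lb - j' - k + 1, lb - j'] (1-based)
            mm = _window_mismatches(enc[a.id], rc_enc[b.id], k)
            for i, jr in zip(*np.nonzero(mm <= max_mismatch)):
                i, jr = int(i), int(jr)
                j_start = lb - jr - k  # 0-based start in b
                if same:
                    if j_start < i:  # canonical: source start <= target start
                        continue
                    if abs(j_start - i) < min_separation:
                        continue
                hits.append(
                    MotifHit(
                        "complement", k,
                        (a.id, i + 1, i + k),
                        (b.id, j_start + 1, j_start + k),
                        int(mm[i, jr]), "reverse-complement",
                    )
                )

    if not merge:
        return hits
    return _merge_hits(hits, {r.id: r.seq for r in records})


def _merge_hits(hits: list[MotifHit], seqs: dict[str, str]) -> list[MotifHit]:
    """Merge diagonally overlapping hits into maximal runs."""
    groups: dict[tuple, list[MotifHit]] = {}
    for h in hits:
        sid, ss, _ = h.source
        tid, ts, te = h.target
        diag = (ss - ts) if h.kind == "repeat" else (ss + te)
        groups.setdefault((h.kind, sid, tid, diag), []).append(h)

    merged: list[MotifHit] = []
    for (kind, sid, tid, _), group in sorted(groups.items(), key=lambda kv: kv[0]):
        group.sort(key=lambda h: h.source[1])
        current = group[0]
        cs, ce = current.source[1], current.source[2]
        acc = [current]
        for nxt in group[1:]:
            if nxt.source[1] <= ce:  # overlapping on the source side
                ce = max(ce, nxt.source[2])
                acc.append(nxt)
            else:
                merged.append(_combine(kind, sid, tid, acc, cs, ce, seqs))
                cs, ce = nxt.source[1], nxt.source[2]
                acc = [nxt]
        merged.append(_combine(kind, sid, tid, acc, cs, ce, seqs))
    return merged


def _combine(kind, sid, tid, acc, cs, ce, seqs) -> MotifHit:
    t_lo = min(h.target[1] for h in acc)
    t_hi = max(h.target[2] for h in acc)
    length = ce - cs + 1
    src = seqs[sid][cs - 1 : ce]
    tgt = seqs[tid][t_lo - 1 : t_hi]
    if kind == "complement":
        tgt = reverse_complement(tgt)
    mism = sum(1 for p, q in zip(src, tgt) if p != q)
    return MotifHit(kind, length, (sid, cs, ce), (tid, t_lo, t_hi), mism, acc[0].orientation)


def write_motif_hits(hits: list[MotifHit], path: str) -> None:
    with open(path, "w") as handle:
        handle.write(
            "kind\tsource_id\tsource_start\tsource_end\t"
            "target_id\ttarget_start\ttarget_end\tmismatches\torientation\n"
        )
        for h in hits:
            handle.write(
                f"{h.kind}\t{h.source[0]}\t{h.source[1]}\t{h.source[2]}\t"
                f"{h.target[0]}\t{h.target[1]}\t{h.target[2]}\t"
                f"{h.mismatches}\t{h.orientation}\n"
            )


def write_segmentation_tsv(
    seg: ShiftSegmentation, aln: MultipleAlignment, path: str, append: bool = False
) -> None:
    """Segmentation report: alignment and ungapped-query coordinates per segment."""
    a, b, c = seg.ids
    mode = "a" if append else "w"
    with open(path, mode) as handle:
        if not append:
            handle.write(
                "triplet\tsegment_start_col\tsegment_end_col\t"
                "query_start\tquery_end\tdominant_state\t"
                "pid_AB\tpid_AC\tpid_BC\n"
            )
        name = f"{a}|{b}|{c}"
        for s in seg.segments:
            qs = aln.col_to_pos(a, s.start_col)
            qe = aln.col_to_pos(a, s.end_col)
            pid = s.pair_identities
            handle.write(
                f"{name}\t{s.start_col}\t{s.end_col}\t{qs}\t{qe}\t{s.dominant_state}\t"
                f"{pid.get('AB', float('nan')):.2f}\t{pid.get('AC', float('nan')):.2f}\t"
                f"{pid.get('BC', float('nan')):.2f}\n"
            )
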