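"""recomb: triplet states, shift segmentation, repeat scan vs brute force."""

import numpy as np
import pytest

from svmprecomb import msa, recomb, simulate
from svmprecomb.seqio import SequenceRecord, reverse_complement


def _aln(rows: dict[str, str], moltype="nt") -> msa.MultipleAlignment:
    return msa.MultipleAlignment(list(rows), list(rows.values()), moltype)


# -- triplet_states ---------------------------------------------------------


def test_triplet_states_example():
    # columns: A=B!=C three times, then B=C!=A
    aln = _aln({"a": "AAAT", "b": "AAAG", "c": "GGTG"})
    vec = recomb.triplet_states(aln, "a", "b", "c")
    assert vec.columns == [1, 2, 3, 4]
    assert vec.states == ["AB", "AB", "AB", "BC"]


def test_triplet_states_all_eq_and_all_diff():
    aln = _aln({"a": "AC", "b": "AG", "c": "AT"})
    vec = recomb.triplet_states(aln, "a", "b", "c")
    assert vec.states == [recomb.ALL_EQ, recomb.ALL_DIFF]


def test_triplet_states_skips_gap_columns():
    # gap in any row removes the column; N compares like a residue
    aln = _aln({"a": "A-NA", "b": "AANA", "c": "AAAA"})
    vec = recomb.triplet_states(aln, "a", "b", "c")
    assert vec.columns == [1, 3, 4]
    assert vec.states[1] == "AB"  # N == N, differs from A


def test_triplet_states_relabels_under_permutation():
    rng = np.random.default_rng(2)
    rows = {
        id_: "".join("ACGT"[i] for i in rng.integers(0, 4, 50))
        for id_ in ("x", "y", "z")
    }
    aln = _aln(rows)
    v1 = recomb.triplet_states(aln, "x", "y", "z")
    v2 = recomb.triplet_states(aln, "z", "x", "y")
    # new roles: A=z, B=x, C=y — so old AB (x=y) becomes new BC, etc.
    relabel = {"AB": "BC", "AC": "AB", "BC": "AC",
               recomb.ALL_EQ: recomb.ALL_EQ, recomb.ALL_DIFF: recomb.ALL_DIFF}
    assert v2.columns == v1.columns
    assert v2.states == [relabel[s] for s in v1.states]


# -- segmentation -----------------------------------------------------------


def _mosaic_alignment(bp_col: int, ncols: int = 600, seed: int = 0):
    """Three sequences where a copies b left of bp_col and c right of it."""
    rng = np.random.default_rng(seed)
    base = rng.integers(0, 4, ncols)
    b = base.copy()
    c = base.copy()
    # diverge b and c from each other at ~20% of sites
    for pos in rng.choice(ncols, size=ncols // 5, replace=False):
        c[pos] = (c[pos] + 1 + rng.integers(0, 3)) % 4
    a = np.where(np.arange(ncols) < bp_col, b, c)
    rows = {
        id_: "".join("ACGT"[i] for i in arr) for id_, arr in (("a", a), ("b", b), ("c", c))
    }
    return _aln(rows)


def test_segmentation_recovers_planted_breakpoint():
    aln = _mosaic_alignment(300, seed=4)
    vec = recomb.triplet_states(aln, "a", "b", "c")
    seg = recomb.segment_shift_regions(vec)
    assert len(seg.breakpoints) == 1
    bp = seg.breakpoints[0]
    assert {bp.left_state, bp.right_state} == {"AB", "AC"}
    assert abs(bp.column - 300) <= 15
    lo, hi = bp.interval
    assert lo <= bp.column <= hi


def test_segmentation_no_breakpoint_on_clean_triplet():
    rng = np.random.default_rng(9)
    base = rng.integers(0, 4, 600)
    b = base.copy()
    for pos in rng.choice(600, size=120, replace=False):
        b[pos] = (b[pos] + 1) % 4
    rows = {
        "a": "".join("ACGT"[i] for i in base),
        "b": "".join("ACGT"[i] for i in b),
        "c": "".join("ACGT"[i] for i in base),
    }
    vec = recomb.triplet_states(_aln(rows), "a", "b", "c")
    seg = recomb.segment_shift_regions(vec)
    assert seg.breakpoints == []
    assert len(seg.segments) == 1


def test_segmentation_tiling_invariant():
    # segments tile the informative region in order without overlap
    aln = _mosaic_alignment(250, seed=12)
    vec = recomb.triplet_states(aln, "a", "b", "c")
    seg = recomb.segment_shift_regions(vec)
    for s1, s2 in zip(seg.segments, seg.segments[1:]):
        assert s1.end_col < s2.start_col
    for bp in seg.breakpoints:
        assert bp.interval[0] <= bp.interval[1]


def test_scan_triplet_positions_match_columns():
    aln = _mosaic_alignment(300, seed=4)
    seg, positions = recomb.scan_triplet(aln, "a", "b", "c")
    assert len(positions) == len(seg.breakpoints)
    for bp, pos in zip(seg.breakpoints, positions):
        for id_ in ("a", "b", "c"):
            assert pos[id_] == aln.col_to_pos(id_, bp.column)


def test_segmentation_on_simulated_event():
    cfg = simulate.SimulationConfig(seed=424, n_leaves=8, n_recombinations=1)
    fam = simulate.simulate_family(cfg)
    events = [e.detail for e in fam.event_log if e.kind == "recombination"]
    assert len(events) == 1
    ev = events[0]
    acc, don = ev["acceptor"], ev["donor"]
    lo, hi = ev["breakpoint_interval"]
    third = next(
        r.id for r in fam.records if r.id not in (acc, don)
    )
    aln = msa.progressive_msa(fam.records)
    seg, positions = recomb.scan_triplet(aln, acc, don, third)
    assert seg.breakpoints, "planted breakpoint not detected"
    best = min(
        positions,
        key=lambda p: 0 if lo <= p[acc] <= hi else min(abs(p[acc] - lo), abs(p[acc] - hi)),
    )
    off = 0 if lo <= best[acc] <= hi else min(abs(best[acc] - lo), abs(best[acc] - hi))
    assert off <= 15


# -- repeats / complements --------------------------------------------------


def _brute_hits(records, k, max_mismatch, min_separation):
    """O(n^2) window-pair oracle, unmerged."""
    out = set()
    seqs = {r.id: r.seq for r in records}
    rc = {r.id: reverse_complement(r.seq) for r in records}
    ids = [r.id for r in records]
    for xi, sid in enumerate(ids):
        for yi in range(xi, len(ids)):
            tid = ids[yi]
            same = sid == tid
            for i in range(len(seqs[sid]) - k + 1):
                for j in range(len(seqs[tid]) - k + 1):
                    if same and (j <= i or j - i < min_separation):
                        continue
                    mm = sum(
                        x != y
                        for x, y in zip(seqs[sid][i : i + k], seqs[tid][j : j + k])
                    )
                    if mm <= max_mismatch:
                        out.add(("repeat", sid, i + 1, tid, j + 1))
            for i in range(len(seqs[sid]) - k + 1):
                for j in range(len(rc[tid]) - k + 1):
                    orig_start = len(seqs[tid]) - (j + k) + 1
                    if same:
                        # canonical order plus separation, in original coords
                        if orig_start - 1 < i or abs(orig_start - 1 - i) < min_separation:
                            continue
                    mm = sum(
                        x != y
                        for x, y in zip(seqs[sid][i : i + k], rc[tid][j : j + k])
                    )
                    if mm <= max_mismatch:
                        out.add(("complement", sid, i + 1, tid, orig_start))
    return out


def test_repeat_scan_planted_direct_repeat():
    rng = np.random.default_rng(33)
    body = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
    unit = "ACGTTGCAAGTC"
    seq = unit + body + unit
    hits = recomb.find_repeats_and_complements(
        [SequenceRecord("s", seq, "nt")], k=12, max_mismatch=0
    )
    direct = [h for h in hits if h.kind == "repeat"]
    assert any(
        h.source[1] == 1 and h.target[1] == len(unit) + 200 + 1 for h in direct
    )


def test_repeat_scan_planted_reverse_complement():
    rng = np.random.default_rng(34)
    body = "".join("ACGT"[i] for i in rng.integers(0, 4, 150))
    unit = "ACGTTGCAAGTC"
    seq = unit + body + reverse_complement(unit)
    hits = recomb.find_repeats_and_complements(
        [SequenceRecord("s", seq, "nt")], k=12, max_mismatch=0
    )
    comp = [h for h in hits if h.kind == "complement"]
    assert any(h.source[1] == 1 for h in comp)


def test_repeat_scan_matches_bruteforce_unmerged():
    rng = np.random.default_rng(35)
    recs = []
    for idx in range(2):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 80))
        recs.append(SequenceRecord(f"r{idx}", seq, "nt"))
    got = recomb.find_repeats_and_complements(
        recs, k=8, max_mismatch=1, min_separation=16, merge=False
    )
    got_keys = {(h.kind, h.source[0], h.source[1], h.target[0], h.target[1]) for h in got}
    expect = _brute_hits(recs, 8, 1, 16)
    # direct repeats must agree exactly with the oracle
    assert {t for t in got_keys if t[0] == "repeat"} == {
        t for t in expect if t[0] == "repeat"
    }
    # complements: same pair set up to orientation bookkeeping
    assert {t[1:] for t in got_keys if t[0] == "complement"} == {
        t[1:] for t in expect if t[0] == "complement"
    }


def test_repeat_scan_validation():
    rec = SequenceRecord("s", "ACGTACGTACGT", "nt")
    with pytest.raises(ValueError):
        recomb.find_repeats_and_complements([rec], k=4)
    with pytest.raises(ValueError):
        recomb.find_repeats_and_complements([SequenceRecord("t", "ACGT", "nt")], k=12)
    with pytest.raises(TypeError):
        recomb.find_repeats_and_complements([SequenceRecord("p", "MKL", "aa")])


def test_merge_collapses_overlapping_diagonal_hits():
    rng = np.random.default_rng(36)
    body = "".join("ACGT"[i] for i in rng.integers(0, 4, 100))
    unit = "ACGTTGCAAGTCGGATCCA"  # 19 nt, longer than k
    seq = unit + body + unit
    rec = [SequenceRecord("s", seq, "nt")]
    merged = recomb.find_repeats_and_complements(rec, k=12, max_mismatch=0, merge=True)
    runs = [h for h in merged if h.kind == "repeat" and h.source[1] == 1]
    assert any(h.source[2] - h.source[1] + 1 >= len(unit) for h in runs)
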