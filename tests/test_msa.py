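"""msa: pairwise alignment vs exhaustive oracle, identity, coordinate maps."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from svmprecomb import msa
from svmprecomb.seqio import SequenceRecord

nt_text = st.text(alphabet="ACGT", min_size=1, max_size=8)


def _rec(id_, seq, moltype="nt"):
    return SequenceRecord(id_, seq, moltype)


# -- exhaustive oracle for affine global alignment --------------------------


def _all_alignments(a: str, b: str):
    """Yield every global alignment of a and b as (row_a, row_b)."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ra, rb in _all_alignments(a[1:], b):
            yield a[0] + ra, "-" + rb
    if b:
        for ra, rb in _all_alignments(a, b[1:]):
            yield "-" + ra, b[0] + rb
    if a and b:
        for ra, rb in _all_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb


def _oracle_best_score(a: str, b: str, params: msa.AlignParams) -> float:
    best = -np.inf
    for ra, rb in _all_alignments(a, b):
        total = 0.0
        in_gap = [False, False]
        for x, y in zip(ra, rb):
            if x == "-" or y == "-":
                which = 0 if x == "-" else 1
                total += params.gap_extend if in_gap[which] else params.gap_open
                in_gap[which] = True
                in_gap[1 - which] = False
            else:
                total += params.match if x == y else params.mismatch
                in_gap = [False, False]
        best = max(best, total)
    return best


def test_pairwise_example_acgt_act():
    aln = msa.pairwise_align(_rec("a", "ACGT"), _rec("b", "ACT"))
    assert msa.alignment_score(aln) == 5.0
    assert aln.degapped("a") == "ACGT"
    assert aln.degapped("b") == "ACT"


def test_pairwise_identical():
    aln = msa.pairwise_align(_rec("a", "ACGTACGT"), _rec("b", "ACGTACGT"))
    assert aln.rows == ["ACGTACGT", "ACGTACGT"]
    assert msa.alignment_score(aln) == 40.0


def test_pairwise_vs_exhaustive_oracle():
    # every pair of short sequences up to length 5/4: DP must match the
    # exhaustive enumeration of all global alignments
    params = msa.AlignParams()
    rng = np.random.default_rng(11)
    alphabet = "ACGT"
    for _ in range(40):
        la, lb = rng.integers(1, 6), rng.integers(1, 5)
        a = "".join(alphabet[i] for i in rng.integers(0, 4, la))
        b = "".join(alphabet[i] for i in rng.integers(0, 4, lb))
        aln = msa.pairwise_align(_rec("a", a), _rec("b", b), params)
        assert msa.alignment_score(aln, params) == pytest.approx(
            _oracle_best_score(a, b, params)
        )


@given(nt_text, nt_text)
def test_pairwise_oracle_property(a, b):
    params = msa.AlignParams()
    aln = msa.pairwise_align(_rec("a", a), _rec("b", b), params)
    assert msa.alignment_score(aln, params) == pytest.approx(
        _oracle_best_score(a, b, params)
    )


def test_pairwise_rejects_mixed_or_empty():
    with pytest.raises(ValueError):
        msa.pairwise_align(_rec("a", "ACGT"), _rec("b", "MKL", "aa"))
    with pytest.raises(ValueError):
        msa.pairwise_align(_rec("a", "ACGT"), _rec("b", ""))


# -- percent identity -------------------------------------------------------


def test_percent_identity_excludes_gap_columns():
    aln = msa.MultipleAlignment(["a", "b"], ["ACG-T", "AC-GT"])
    pid = msa.percent_identity(aln, "a", "b")
    assert pid.counted == 3  # two gap columns excluded
    assert pid.value == pytest.approx(100.0)


def test_percent_identity_n_is_mismatch():
    aln = msa.MultipleAlignment(["a", "b"], ["ANGT", "ANGT"])
    pid = msa.percent_identity(aln, "a", "b")
    assert pid.counted == 4
    assert pid.value == pytest.approx(75.0)


def test_percent_identity_region():
    aln = msa.MultipleAlignment(["a", "b"], ["AAAATTTT", "AAAACCCC"])
    assert msa.percent_identity(aln, "a", "b", (1, 4)).value == pytest.approx(100.0)
    assert msa.percent_identity(aln, "a", "b", (5, 8)).value == pytest.approx(0.0)
    with pytest.raises(ValueError):
        msa.percent_identity(aln, "a", "b", (0, 4))


def test_percent_identity_empty_comparison():
    aln = msa.MultipleAlignment(["a", "b"], ["A---", "-CGT"])
    with pytest.raises(ValueError):
        msa.percent_identity(aln, "a", "b")


# -- coordinate maps --------------------------------------------------------


def test_pos_to_col_and_back():
    aln = msa.MultipleAlignment(["a", "b"], ["AC--GT", "ACGTGT"])
    assert aln.pos_to_col("a", 3) == 5
    assert aln.col_to_pos("a", 5) == 3
    # gap column maps to the last residue before it
    assert aln.col_to_pos("a", 4) == 2
    assert aln.pos_to_col("b", 3) == 3


def test_coordinate_roundtrip_random():
    rng = np.random.default_rng(7)
    seqs = [
        "".join("ACGT"[i] for i in rng.integers(0, 4, 60 + int(rng.integers(0, 20))))
        for _ in range(4)
    ]
    aln = msa.progressive_msa([_rec(f"s{k}", s) for k, s in enumerate(seqs)])
    for k, s in enumerate(seqs):
        id_ = f"s{k}"
        assert aln.degapped(id_) == s
        for pos in range(1, len(s) + 1):
            assert aln.col_to_pos(id_, aln.pos_to_col(id_, pos)) == pos


# -- progressive MSA --------------------------------------------------------


def test_progressive_msa_preserves_sequences():
    rng = np.random.default_rng(19)
    base = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
    records = []
    for k in range(5):
        seq = list(base)
        for pos in rng.integers(0, 120, 8):
            seq[pos] = "ACGT"[rng.integers(0, 4)]
        records.append(_rec(f"s{k}", "".join(seq)))
    aln = msa.progressive_msa(records)
    assert sorted(aln.ids) == sorted(r.id for r in records)
    for r in records:
        assert aln.degapped(r.id) == r.seq
    # no all-gap columns
    enc = aln.encoded
    assert not ((enc == msa.NT_GAP).all(axis=0)).any()


def test_progressive_msa_deterministic():
    rng = np.random.default_rng(23)
    records = [
        _rec(f"s{k}", "".join("ACGT"[i] for i in rng.integers(0, 4, 80)))
        for k in range(4)
    ]
    a1 = msa.progressive_msa(records)
    a2 = msa.progressive_msa(records)
    assert a1.rows == a2.rows and a1.ids == a2.ids


def test_progressive_msa_single_and_empty():
    aln = msa.progressive_msa([_rec("x", "ACGT")])
    assert aln.rows == ["ACGT"]
    with pytest.raises(ValueError):
        msa.progressive_msa([])


# -- identity profile -------------------------------------------------------


def test_identity_profile_flat_on_identical():
    aln = msa.MultipleAlignment(["a", "b"], ["A" * 50, "A" * 50])
    prof = msa.identity_profile(aln, "a", "b", window=10, step=5)
    assert all(v == pytest.approx(100.0) for v in prof.values)
    assert prof.centers[0] == 5  # start 0 + ceil(11/2)


def test_identity_profile_detects_divergent_block():
    row_a = "A" * 30 + "C" * 30
    row_b = "A" * 30 + "G" * 30
    aln = msa.MultipleAlignment(["a", "b"], [row_a, row_b])
    prof = msa.identity_profile(aln, "a", "b", window=10, step=1)
    assert prof.values[0] == pytest.approx(100.0)
    assert prof.values[-1] == pytest.approx(0.0)


def test_identity_profile_validation():
    aln = msa.MultipleAlignment(["a", "b"], ["A" * 20, "A" * 20])
    with pytest.raises(ValueError):
        msa.identity_profile(aln, "a", "b", window=5)
    with pytest.raises(ValueError):
        msa.identity_profile(aln, "a", "b", window=30)


# -- filter_columns ---------------------------------------------------------


def test_filter_columns_drops_gappy():
    aln = msa.MultipleAlignment(
        ["a", "b", "c"], ["AC-T", "AC-T", "ACGT"]
    )
    kept, removed = msa.filter_columns(aln, 0.5)
    assert removed == [3]
    assert kept.rows == ["ACT", "ACT", "ACT"]


def test_filter_columns_keep_all_and_errors():
    aln = msa.MultipleAlignment(["a", "b"], ["ACGT", "ACGT"])
    kept, removed = msa.filter_columns(aln, 0.0)
    assert removed == [] and kept.rows == aln.rows
    gappy = msa.MultipleAlignment(["a", "b"], ["A-", "-T"])
    with pytest.raises(ValueError):
        msa.filter_columns(gappy, 0.0)
    with pytest.raises(ValueError):
        msa.filter_columns(aln, 1.5)
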