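"""Hydropathy profiles, TM segmentation, receptor models, global identity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from Bio.SeqUtils.ProtParamData import kd as KD

from b3locus.receptors import (
    _make_aligner,
    build_receptor_model,
    global_identity,
    hydropathy_profile,
    identity_matrix,
    predict_tm_segments,
)
from b3locus.synthetic import generate_receptor_gene


def _oracle_profile(pep, window):
    """Independent truncated-window mean."""
    h = window // 2
    vals = [KD.get(a, 0.0) for a in pep]
    return [
        sum(vals[max(0, i - h): i + h + 1]) / len(vals[max(0, i - h): i + h + 1])
        for i in range(len(pep))
    ]


def test_poly_ile_and_poly_arg_profiles():
    prof_i = hydropathy_profile("I" * 30, 19)
    prof_r = hydropathy_profile("R" * 30, 19)
    assert np.allclose(prof_i[9:-9], 4.5)
    assert np.allclose(prof_r[9:-9], -4.5)


def test_alternating_profile_matches_arithmetic_oracle():
    pep = "IR" * 20
    got = hydropathy_profile(pep, 19)
    assert np.allclose(got, _oracle_profile(pep, 19))
    # interior windows hold 10 of one residue and 9 of the other
    assert np.allclose(np.abs(got[9:-9]), 4.5 / 19)


def test_profile_validation():
    with pytest.raises(ValueError, match="odd"):
        hydropathy_profile("I" * 30, 10)
    with pytest.raises(ValueError, match="exceeds"):
        hydropathy_profile("IRI", 19)
    with pytest.warns(UserWarning, match="unknown residue"):
        hydropathy_profile("I" * 20 + "U", 19)


def test_all_hydrophilic_peptide_has_no_segments():
    assert predict_tm_segments("R" * 200) == []


def test_close_stretches_merge():
    pep = "R" * 20 + "I" * 21 + "D" + "I" * 21 + "R" * 20
    segments = predict_tm_segments(pep, merge_gap=3)
    assert len(segments) == 1
    assert (segments[0].start, segments[0].end) == (21, 63)


def test_seven_tm_recovery_at_truth_positions():
    """Generator receptors give exactly 7 segments within 2 residues of truth."""
    for seed in range(100):
        rng = np.random.default_rng(seed)
        _dna, truth = generate_receptor_gene(rng, 420, 100)
        segments = predict_tm_segments(truth["peptide"])
        assert len(segments) == 7
        for seg, (ts, te) in zip(segments, truth["tm_segments"]):
            assert abs(seg.start - ts) <= 2 and abs(seg.end - te) <= 2


def test_receptor_model_tail_rule():
    rng = np.random.default_rng(1)
    _dna, truth = generate_receptor_gene(rng, 328, 30)
    model = build_receptor_model("r30", truth["peptide"], tail_threshold=50)
    assert model.receptor_like and model.c_tail_len == 30
    _dna, truth = generate_receptor_gene(rng, 700, 300)
    model = build_receptor_model("r300", truth["peptide"], tail_threshold=50)
    assert len(model.segments) == 7 and not model.receptor_like
    assert model.c_tail_len == 300


def test_receptor_topology_alternates_from_extracellular_n_terminus():
    rng = np.random.default_rng(3)
    _dna, truth = generate_receptor_gene(rng, 470, 120)
    model = build_receptor_model("r", truth["peptide"])
    assert model.topology == ("out->in", "in->out") * 3 + ("out->in",)
    assert model.n_tail_len == truth["n_tail_len"]


def test_non_seven_tm_protein_flagged_with_warning():
    pep = "R" * 30 + "I" * 21 + "R" * 30
    with pytest.warns(UserWarning, match="expected 7"):
        model = build_receptor_model("x", pep)
    assert not model.receptor_like and len(model.segments) == 1


def test_hydrophilic_flank_invariance():
    """Appending hydrophilic flanks shifts nothing; the C-tail grows exactly."""
    rng = np.random.default_rng(11)
    _dna, truth = generate_receptor_gene(rng, 420, 100)
    pep = truth["peptide"]
    base = predict_tm_segments(pep)
    extended = predict_tm_segments("N" * 25 + pep + "Q" * 40)
    assert [(s.start + 25, s.end + 25) for s in base] == [
        (s.start, s.end) for s in extended
    ]
    m0 = build_receptor_model("a", pep)
    m1 = build_receptor_model("b", pep + "Q" * 40)
    assert m1.c_tail_len == m0.c_tail_len + 40


# --- global identity -------------------------------------------------------

def test_identity_of_identical_sequences_is_100():
    r = global_identity("MKTAYIAKQR", "MKTAYIAKQR")
    assert r.identity_pct == 100.0 and r.matches == r.aligned_columns == 10


def test_identity_single_substitution_hand_dp():
    r = global_identity("ACDEFG", "ACDKFG")
    assert r.matches == 5 and r.aligned_columns == 6
    assert r.identity_pct == pytest.approx(100 * 5 / 6)


def test_identity_rejects_empty():
    with pytest.raises(ValueError, match="non-empty"):
        global_identity("", "ACD")


def test_truncated_mode_cuts_the_longer_sequence():
    a = "MKTAYIAKQRQISFVK"
    b = a + "WWWWWWWWWW"  # non-corresponding C-terminal extension
    full = global_identity(a, b).identity_pct
    trunc = global_identity(a, b, mode="truncated").identity_pct
    assert trunc == 100.0 and full < 100.0
    # explicit truncation length
    partial = global_identity(a, b, mode="truncated", truncate_len=len(a) + 2)
    assert partial.identity_pct < 100.0


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=3, max_size=25),
    st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=3, max_size=25),
)
def test_identity_is_symmetric(a, b):
    assert global_identity(a, b).identity_pct == pytest.approx(
        global_identity(b, a).identity_pct
    )


def _enumerate_alignment_score(a, b, sub, gap_open=-10.0, gap_extend=-0.5):
    """Exhaustive recursion over all global alignments (affine gaps)."""
    best = [-np.inf]

    def rec(i, j, score, state):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + sub[a[i], b[j]], "M")
        if i < len(a):
            pen = gap_extend if state == "D" else gap_open
            rec(i + 1, j, score + pen, "D")
        if j < len(b):
            pen = gap_extend if state == "I" else gap_open
            rec(i, j + 1, score + pen, "I")

    rec(0, 0, 0.0, "M")
    return best[0]


@pytest.mark.parametrize("seed", range(6))
def test_alignment_score_equals_exhaustive_enumeration(seed):
    """DP score equals brute force over all alignments for <=8-residue pairs."""
    from Bio.Align import substitution_matrices

    sub = substitution_matrices.load("BLOSUM62")
    rng = np.random.default_rng(seed)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    a = "".join(rng.choice(aa, size=rng.integers(2, 9)))
    b = "".join(rng.choice(aa, size=rng.integers(2, 9)))
    aligner = _make_aligner("BLOSUM62", 10, 0.5)
    assert aligner.score(a, b) == pytest.approx(_enumerate_alignment_score(a, b, sub))


def test_identity_matrix_is_symmetric_with_unit_diagonal():
    prots = [("p1", "MKTAYIAKQR"), ("p2", "MKTAYIHKQR"), ("p3", "MKAAYIAKQW")]
    mat = identity_matrix(prots)
    assert np.allclose(mat.values, mat.values.T)
    assert np.allclose(np.diag(mat.values), 100.0)
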