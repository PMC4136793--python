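"""CaaX detection, cleavage grammar, mature-peptide prediction."""

import numpy as np
import pytest

from b3locus.orfs import Orf
from b3locus.pheromones import (
    align_precursors,
    classify_pheromone,
    enumerate_cleavage_sites,
    find_caax,
    precursor_table,
    predict_mature,
    PheromonePrecursor,
)
from b3locus.synthetic import generate_precursor_gene

AA_NO_MRC = [a for a in "ACDEFGHIKLNPQSTVWY" if a not in "MRC"]


def _orf(pep: str) -> Orf:
    return Orf("t", 1, 3 * (len(pep) + 1), "+", 0, pep)


@pytest.mark.parametrize(
    "tail,found",
    [("CVIA", True), ("AVIC", False), ("CVCH", True), ("CVRG", True), ("CVVA", True)],
)
def test_find_caax_tests_only_the_cys_at_minus4(tail, found):
    pep = "MDAFGHKLST" + tail
    motif = find_caax(pep)
    assert (motif is not None) == found
    if found:
        assert motif.motif == tail and motif.cys_offset == 4


def test_find_caax_short_peptide_is_none():
    assert find_caax("MAC") is None


def test_cleavage_example_with_full_context():
    # M + 10xA + P A D E R + 12 residues ending CVIA
    pep = "M" + "A" * 10 + "PADER" + "GLHKSTQW" + "CVIA"
    sites = enumerate_cleavage_sites(pep)
    assert len(sites) == 1
    s = sites[0]
    assert s.doublet == "ER"
    assert s.has_pro_minus4 and s.has_dn_minus2
    assert s.score == 3
    assert s.doublet_end_offset == 13  # 12 residues follow the R


def test_no_doublet_anywhere_gives_empty_list():
    pep = "M" + "A" * 30 + "CVIA"
    assert enumerate_cleavage_sites(pep) == []


def test_equal_score_ties_break_toward_smaller_offset():
    """Two context-free doublets in the window: brute-force order check."""
    # offsets of R: place ER with R at offsets 18 and 14, no P/DN context
    body = list("G" * 40)
    n = len(body)
    for d in (18, 14):
        # R sits at peptide index L - d; the peptide is M + body + CVIA,
        # so the body index of the R is (n + 5) - d - 1
        body[n + 4 - d] = "R"
        body[n + 3 - d] = "E"
    pep = "M" + "".join(body) + "CVIA"
    # independent enumeration: all E/T-R pairs with R-offset in [13,19]
    L = len(pep)
    oracle = sorted(
        d for d in range(13, 20)
        if pep[L - d] == "R" and pep[L - d - 1] in "ET"
    )
    sites = enumerate_cleavage_sites(pep)
    assert [s.doublet_end_offset for s in sites] == oracle == [14, 18]
    assert all(s.score == 1 for s in sites)


@pytest.mark.parametrize("offset,mature_len", [(16, 12), (17, 13)])
def test_predict_mature_length_arithmetic(offset, mature_len):
    """Mature length is doublet_end_offset - 4, and the peptide ends in Cys."""
    body = "G" * (offset - 5)  # residues strictly between R and the Cys at -4
    pep = "M" + "A" * 20 + "ER" + body + "CVIA"
    orf = _orf(pep)
    precursor = PheromonePrecursor(orf, find_caax(pep), tuple(enumerate_cleavage_sites(pep)))
    done = predict_mature(precursor)
    assert done.chosen_site is not None
    assert done.chosen_site.doublet_end_offset == offset
    assert done.mature_length == mature_len
    assert done.mature_peptide.endswith("C")
    assert done.mature_peptide == body + "C"


def test_predict_mature_requires_sites():
    pep = "M" + "A" * 30 + "CVIA"
    with pytest.raises(ValueError):
        predict_mature(PheromonePrecursor(_orf(pep), find_caax(pep), ()))


def test_size_filter_rejects_long_orf():
    pep = "M" + "A" * 120 + "PADER" + "G" * 11 + "CVIA"
    assert classify_pheromone(_orf(pep)) is None


def test_truth_precursors_recovered_exactly():
    """Generator output is classified with its exact mature peptide (20 seeds)."""
    for seed in range(20):
        rng = np.random.default_rng(seed)
        _dna, truth = generate_precursor_gene(rng)
        p = classify_pheromone(_orf(truth["peptide"]))
        assert p is not None
        assert p.mature_peptide == truth["mature_peptide"]
        assert p.chosen_site.doublet == truth["doublet"]
        assert p.chosen_site.score == 3


def _random_peptides(n, rng):
    out = []
    for _ in range(n):
        length = int(rng.integers(10, 101))
        out.append("M" + "".join(rng.choice(list("ACDEFGHIKLNPQRSTVWY"), size=length - 1)))
    return out


def test_grammar_specificity_against_brute_force():
    """On random decoys the full grammar accepts strictly fewer than CaaX alone."""
    rng = np.random.default_rng(123)
    peps = _random_peptides(1000, rng)

    def brute_caax(p):
        return len(p) >= 4 and p[-4] == "C"

    def brute_full(p):
        if not brute_caax(p):
            return False
        L = len(p)
        for d in range(13, 20):
            i = L - d
            if i >= 4 and p[i] == "R" and p[i - 1] in "ET" \
                    and p[i - 4] == "P" and p[i - 2] in "DN":
                return True
        return False

    caax_only = sum(
        classify_pheromone(_orf(p), strict=False) is not None for p in peps
    )
    full = sum(classify_pheromone(_orf(p), strict=True) is not None for p in peps)
    assert caax_only == sum(map(brute_caax, peps))
    assert full == sum(map(brute_full, peps))
    assert full < caax_only


def test_context_constraints_are_monotone():
    """Raising min_site_score never accepts more precursors."""
    rng = np.random.default_rng(7)
    peps = _random_peptides(400, rng)
    counts = [
        sum(
            classify_pheromone(_orf(p), strict=True, min_site_score=s) is not None
            for p in peps
        )
        for s in (1, 2, 3)
    ]
    assert counts[0] >= counts[1] >= counts[2]


def test_shuffled_precursors_rarely_accepted():
    """Composition alone does not carry the grammar: shuffles accepted << always."""
    rng = np.random.default_rng(5)
    accepted = 0
    trials = 100
    for seed in range(trials):
        _dna, truth = generate_precursor_gene(np.random.default_rng(seed))
        pep = truth["peptide"]
        shuffled = "M" + "".join(rng.permutation(list(pep[1:])))
        if classify_pheromone(_orf(shuffled)) is not None:
            accepted += 1
    assert accepted / trials < 0.2


def test_align_precursors_requires_two():
    _dna, truth = generate_precursor_gene(np.random.default_rng(0))
    p = classify_pheromone(_orf(truth["peptide"]))
    with pytest.raises(ValueError, match="at least 2"):
        align_precursors([p])


def test_align_precursors_identical_rows_and_anchoring():
    precursors = []
    for seed in range(4):
        _dna, truth = generate_precursor_gene(np.random.default_rng(seed))
        precursors.append(classify_pheromone(_orf(truth["peptide"])))
    block = align_precursors(precursors)
    lines = block.splitlines()
    assert len(lines) == 5  # 4 rows + ruler
    width = len(lines[0].split("  ", 1)[1])
    # the CaaX Cys column coincides across rows (C-terminal anchoring)
    for line, p in zip(lines[:4], precursors):
        row = line[-width:]
        assert row[width - 4].upper() == "C"
    # two identical precursors produce identical rows
    twin = align_precursors([precursors[0], precursors[0]])
    r1, r2 = twin.splitlines()[:2]
    assert r1.split("  ", 1)[1] == r2.split("  ", 1)[1]


def test_precursor_table_reports_mature_columns():
    precursors = []
    for seed in range(3):
        _dna, truth = generate_precursor_gene(np.random.default_rng(seed))
        precursors.append(classify_pheromone(_orf(truth["peptide"])))
    df = precursor_table(precursors)
    assert (df.mature_length == df.mature_peptide.str.len()).all()
    assert df.mature_peptide.str.endswith("C").all()
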