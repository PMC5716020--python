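"""Kinship correction, frequencies, PhiST/AMOVA, MDS and PCA."""

import numpy as np
import pandas as pd
import pytest

from hvspop.core import EMPTY_MOTIF, Sample, SequenceBlock
from hvspop.popstats import (
    DistanceMatrix,
    amova,
    difference_matrix,
    haplogroup_frequencies,
    kinship_correct,
    mds,
    pairwise_phist,
    pca_frequencies,
    phist_from_distances,
)


def make_samples(spec):
    """spec: list of (sample_id, haplotype, grave, haplogroup)."""
    return [
        Sample(
            sample_id=sid,
            population="pop",
            motif=EMPTY_MOTIF,
            grave_id=grave,
            haplotype_id=hap,
            haplogroup=hg,
        )
        for sid, hap, grave, hg in spec
    ]


# ---------------------------------------------------------------------------
# kinship correction


def test_kinship_collapses_within_grave(table3):
    units = kinship_correct(table3.samples)
    assert len(units) == 46
    assert all(u.weight == 1 for u in units)


def test_kinship_all_unique():
    samples = make_samples(
        [(f"s{i}", f"h{i}", f"g{i}", "A") for i in range(5)]
    )
    units = kinship_correct(samples)
    assert len(units) == 5
    assert sum(u.weight for u in units) == 5


def test_kinship_two_graves_two_units():
    samples = make_samples(
        [("s1", "h1", "g1", "A"), ("s2", "h1", "g1", "A"), ("s3", "h1", "g2", "A")]
    )
    units = kinship_correct(samples)
    assert len(units) == 1
    assert units[0].weight == 2


def test_kinship_idempotent(table3):
    units = kinship_correct(table3.samples)
    # re-correcting one representative per (haplotype, grave) changes nothing
    reps = {}
    for s in table3.samples:
        reps.setdefault((s.haplotype_id, s.grave_id), s)
    again = kinship_correct(list(reps.values()))
    assert [(u.haplotype_id, u.weight) for u in again] == [
        (u.haplotype_id, u.weight) for u in units
    ]


def test_kinship_excludes_unassigned():
    samples = make_samples([("s1", "h1", "g1", "A")])
    samples.append(
        Sample(sample_id="s2", population="pop", motif=EMPTY_MOTIF)
    )
    assert len(kinship_correct(samples)) == 1


# ---------------------------------------------------------------------------
# frequencies


def test_fixture_macro_frequencies(table3):
    freq = haplogroup_frequencies(kinship_correct(table3.samples))
    assert freq.loc["D", "percent"] == 34.78
    assert freq.loc["C", "percent"] == 10.87
    assert freq.loc["F", "percent"] == 8.70
    assert freq.loc["A", "percent"] == 8.70
    assert freq["count"].sum() == 46
    assert np.isclose(freq["freq"].sum(), 1.0)


def test_single_haplogroup_is_100_percent():
    units = kinship_correct(make_samples([("s1", "h1", "g1", "Z")]))
    freq = haplogroup_frequencies(units)
    assert freq.loc["Z", "percent"] == 100.0


def test_empty_units_error():
    with pytest.raises(ValueError):
        haplogroup_frequencies([])


# ---------------------------------------------------------------------------
# PhiST


def block_from(seqs, window=None):
    window = window or (1, len(seqs[0]))
    return SequenceBlock(
        labels=[f"s{i}" for i in range(len(seqs))], sequences=list(seqs),
        window=window,
    )


def test_phist_identical_populations_zero():
    seqs = ["AAAA", "AAAT", "AAAA", "AAAT"]  # pop1 == pop2 as multisets
    block = block_from(seqs)
    dist, pvals, raw = pairwise_phist(
        block, ["p1", "p1", "p2", "p2"], permutations=99, seed=0
    )
    assert dist.values[0, 1] == 0.0
    assert raw.iloc[0, 1] <= 0.0
    assert pvals.iloc[0, 1] > 0.05


def test_phist_fully_differentiated_one():
    seqs = ["AAAA", "AAAA", "TTTT", "TTTT"]
    block = block_from(seqs)
    dist, pvals, _ = pairwise_phist(
        block, ["p1", "p1", "p2", "p2"], permutations=99, seed=0
    )
    assert dist.values[0, 1] == pytest.approx(1.0)


def test_phist_matches_hand_decomposition():
    """Two populations of four sequences against the explicit sum-of-squares
    arithmetic of the molecular-variance decomposition."""
    seqs = [
        "AAAAA", "AAAAT", "AATAT", "AAAAA",  # pop 1
        "TTAAA", "TTAAT", "TTTAT", "TTAAA",  # pop 2
    ]
    block = block_from(seqs)
    d = difference_matrix(block)
    # independent hand arithmetic
    n1 = n2 = 4
    n = n1 + n2
    ss_total = d[np.triu_indices(n, 1)].sum() / n
    ss_w1 = d[:4, :4][np.triu_indices(4, 1)].sum() / n1
    ss_w2 = d[4:, 4:][np.triu_indices(4, 1)].sum() / n2
    ss_within = ss_w1 + ss_w2
    sigma_w = ss_within / (n - 2)
    n_eff = (n - (n1**2 + n2**2) / n) / 1
    sigma_a = ((ss_total - ss_within) / 1 - sigma_w) / n_eff
    expected = sigma_a / (sigma_a + sigma_w)

    assert phist_from_distances(d, [4, 4]) == pytest.approx(expected)
    dist, _, raw = pairwise_phist(
        block, ["p1"] * 4 + ["p2"] * 4, permutations=49, seed=1
    )
    assert raw.iloc[0, 1] == pytest.approx(expected)


def test_phist_requires_two_sequences_per_population():
    block = block_from(["AAAA", "AAAT", "TTTT"])
    with pytest.raises(ValueError, match="p2"):
        pairwise_phist(block, ["p1", "p1", "p2"], permutations=9)


def test_phist_invariant_to_relabeling_within_populations(rng):
    seqs = ["AAAA", "ATAA", "AATA", "TTTT", "TTTA", "TATT"]
    labels = ["p1"] * 3 + ["p2"] * 3
    block = block_from(seqs)
    _, _, raw = pairwise_phist(block, labels, permutations=9, seed=0)
    perm = [2, 0, 1, 5, 3, 4]  # shuffle within populations
    block2 = block_from([seqs[i] for i in perm])
    _, _, raw2 = pairwise_phist(block2, labels, permutations=9, seed=0)
    assert raw.iloc[0, 1] == pytest.approx(raw2.iloc[0, 1])


# ---------------------------------------------------------------------------
# AMOVA


def test_amova_percentages_sum_to_100():
    seqs = [
        "AAAAA", "AAAAT", "AATAT", "AAAAA",
        "TTAAA", "TTAAT", "TTTAT", "TTAAA",
        "AATTT", "AATTA", "TATTA", "AATTT",
        "GGGAA", "GGGAT", "GGGTT", "GGGAA",
    ]
    block = block_from(seqs)
    assignment = ["p1"] * 4 + ["p2"] * 4 + ["p3"] * 4 + ["p4"] * 4
    grouping = {"north": ["p1", "p2"], "south": ["p3", "p4"]}
    result = amova(block, assignment, grouping, permutations=99, seed=0)
    assert sum(result.percentages.values()) == pytest.approx(100.0, abs=1e-9)
    assert set(result.p_values) == {"PhiCT", "PhiSC", "PhiST"}
    assert all(0 < p <= 1 for p in result.p_values.values())


def test_amova_two_pop_equals_pairwise_phist():
    seqs = [
        "AAAAA", "AAAAT", "AATAT", "AAAAA",
        "TTAAA", "TTAAT", "TTTAT", "TTAAA",
    ]
    block = block_from(seqs)
    assignment = ["p1"] * 4 + ["p2"] * 4
    _, _, raw = pairwise_phist(block, assignment, permutations=9, seed=0)
    result = amova(
        block, assignment, {"g1": ["p1"], "g2": ["p2"]}, permutations=9, seed=0
    )
    # with one population per group PhiCT plays the role of PhiST
    assert result.phi["PhiST"] == pytest.approx(raw.iloc[0, 1])


def test_amova_identical_groups_no_group_variance():
    seqs = ["AAAA", "AAAT", "AAAA", "AAAT", "AAAA", "AAAT", "AAAA", "AAAT"]
    block = block_from(seqs)
    assignment = ["p1"] * 2 + ["p2"] * 2 + ["p3"] * 2 + ["p4"] * 2
    grouping = {"g1": ["p1", "p2"], "g2": ["p3", "p4"]}
    result = amova(block, assignment, grouping, permutations=99, seed=0)
    assert abs(result.variance_components["among_groups"]) < 1e-9
    assert result.p_values["PhiCT"] > 0.05


def test_amova_single_group_reduces_with_notice():
    seqs = ["AAAA", "AAAT", "TTTT", "TTTA"]
    block = block_from(seqs)
    with pytest.warns(UserWarning, match="one-level"):
        result = amova(
            block,
            ["p1", "p1", "p2", "p2"],
            {"only": ["p1", "p2"]},
            permutations=19,
            seed=0,
        )
    assert "among_populations" in result.variance_components


def test_amova_three_level_hand_oracle():
    """Toy 2x2 design checked against an independently coded decomposition
    (explicit SSD terms and expected-mean-square coefficients)."""
    seqs = [
        "AAAAA", "AAAAT", "AAATT",      # p1 (3)
        "ATAAA", "ATAAT",               # p2 (2)
        "TTTTT", "TTTTA", "TTTAA",      # p3 (3)
        "TATTT", "TATTA",               # p4 (2)
    ]
    block = block_from(seqs)
    assignment = ["p1"] * 3 + ["p2"] * 2 + ["p3"] * 3 + ["p4"] * 2
    grouping = {"g1": ["p1", "p2"], "g2": ["p3", "p4"]}
    result = amova(block, assignment, grouping, permutations=9, seed=0)

    d = difference_matrix(block)
    idx = {
        "p1": [0, 1, 2], "p2": [3, 4], "p3": [5, 6, 7], "p4": [8, 9],
        "g1": [0, 1, 2, 3, 4], "g2": [5, 6, 7, 8, 9],
    }

    def ssd(rows):
        sub = d[np.ix_(rows, rows)]
        return sub.sum() / (2 * len(rows))

    n = 10
    ssd_t = ssd(list(range(n)))
    ssd_wp = sum(ssd(idx[p]) for p in ("p1", "p2", "p3", "p4"))
    ssd_wg = ssd(idx["g1"]) + ssd(idx["g2"])
    sigma_c = ssd_wp / (n - 4)
    # coefficients for the unbalanced design (two groups of 5, pops 3+2)
    n_coef = (n - ((9 + 4) / 5 + (9 + 4) / 5)) / 2
    n_prime = (((9 + 4) / 5 + (9 + 4) / 5) - (9 + 4 + 9 + 4) / n) / 1
    n_dprime = (n - (25 + 25) / n) / 1
    sigma_b = ((ssd_wg - ssd_wp) / 2 - sigma_c) / n_coef
    sigma_a = ((ssd_t - ssd_wg) / 1 - sigma_c - n_prime * sigma_b) / n_dprime

    assert result.variance_components["within_populations"] == pytest.approx(sigma_c)
    assert result.variance_components[
        "among_populations_within_groups"
    ] == pytest.approx(sigma_b)
    assert result.variance_components["among_groups"] == pytest.approx(sigma_a)


# ---------------------------------------------------------------------------
# ordination


def test_mds_recovers_planar_configuration():
    points = np.array([[0, 0], [3, 0], [0, 4], [3, 4], [1.5, 2.0]])
    d = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))
    dist = DistanceMatrix(labels=list("abcde"), values=d)
    coords, stress = mds(dist, dims=2, seed=0)
    assert stress < 1e-6
    recon = np.sqrt(
        ((coords.values[:, None] - coords.values[None]) ** 2).sum(-1)
    )
    assert np.allclose(recon, d, atol=1e-6)


def test_mds_triangle_matches_analytic_embedding():
    # triangle with sides 3, 4, 5: exact planar embedding exists
    d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
    dist = DistanceMatrix(labels=list("abc"), values=d)
    coords, stress = mds(dist, dims=2, seed=0)
    assert stress < 1e-6


def test_mds_constant_addition_increases_stress():
    d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
    dist = DistanceMatrix(labels=list("abc"), values=d)
    _, stress0 = mds(dist, dims=1, seed=0)
    d2 = d + 2.0
    np.fill_diagonal(d2, 0)
    _, stress1 = mds(DistanceMatrix(labels=list("abc"), values=d2), dims=1, seed=0)
    assert stress1 > stress0


def test_mds_dims_bounds():
    d = np.array([[0, 1], [1, 0]], dtype=float)
    dist = DistanceMatrix(labels=["a", "b"], values=d)
    with pytest.raises(ValueError):
        mds(dist, dims=2)


def test_pca_identical_populations_at_origin():
    freq = pd.DataFrame(
        [[0.5, 0.3, 0.2]] * 2, index=["p1", "p2"], columns=list("ABC")
    )
    with pytest.warns(UserWarning):
        scores, ratios = pca_frequencies(freq)
    assert scores.empty or np.allclose(scores.values, 0)


def test_pca_rank_one_structure():
    base = np.array([0.5, 0.3, 0.2])
    delta = np.array([0.1, -0.05, -0.05])
    rows = [base + t * delta for t in (-1, 0, 1, 2)]
    freq = pd.DataFrame(rows, index=list("wxyz"), columns=list("ABC"))
    scores, ratios = pca_frequencies(freq)
    assert ratios[0] == pytest.approx(1.0)


def test_pca_matches_eigendecomposition():
    rng = np.random.default_rng(3)
    x = rng.dirichlet([2, 2, 2], size=4)
    freq = pd.DataFrame(x, index=list("abcd"), columns=list("XYZ"))
    scores, ratios = pca_frequencies(freq)
    xc = x - x.mean(0)
    vals, vecs = np.linalg.eigh(xc.T @ xc)
    order = np.argsort(vals)[::-1]
    expected_scores = xc @ vecs[:, order]
    for c in range(scores.shape[1]):
        got = scores.values[:, c]
        exp = expected_scores[:, c]
        assert np.allclose(np.abs(got), np.abs(exp), atol=1e-8)
    assert np.all(np.diff(ratios) <= 1e-12)
    assert ratios.sum() <= 1 + 1e-9
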