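"""ABC engine: summaries, rejection, model choice, adjustment, HPD."""

import math

import numpy as np
import pytest

from hvspop.abc_engine import (
    ModelTable,
    ReferenceTable,
    SummaryStats,
    _weighted_hpd,
    adjust_parameters,
    lr_model_choice,
    reject,
    summarize_codes,
)


def gaussian_table(rng, m=40_000, n_obs=10, lo=-10.0, hi=10.0, label="gauss"):
    """1-parameter toy: theta ~ U(lo, hi), data = n_obs draws N(theta, 1),
    statistic = sample mean.  Flat-prior posterior: N(xbar, 1/n_obs)."""
    theta = rng.uniform(lo, hi, size=m)
    xbar = rng.normal(theta, 1.0 / math.sqrt(n_obs))
    return ReferenceTable(
        stat_names=["xbar"],
        models={
            label: ModelTable(
                label=label,
                param_names=["theta"],
                params=theta[:, None],
                stats=xbar[:, None],
            )
        },
    )


def observed_stat(value, names=("xbar",)):
    return SummaryStats(
        np.array([value], dtype=float), list(names), np.array([True])
    )


# ---------------------------------------------------------------------------
# summaries


def test_summary_monomorphic_dataset():
    pop = np.zeros((6, 30), dtype=np.uint8)
    stats = summarize_codes([pop, pop.copy()], ["x", "y"])
    by_name = dict(zip(stats.names, stats.values))
    assert by_name["x:n_haplotypes"] == 1
    assert by_name["x:segregating_sites"] == 0
    assert by_name["x:mean_pairwise_diff"] == 0
    assert by_name["x-y:phist"] == 0
    masked = dict(zip(stats.names, stats.mask))
    assert not masked["x:tajimas_d"]  # undefined with S=0, encoded 0


def test_summary_identical_populations_phist_zero(rng):
    pop = rng.integers(0, 4, size=(8, 40)).astype(np.uint8)
    stats = summarize_codes([pop, pop.copy()], ["x", "y"])
    by_name = dict(zip(stats.names, stats.values))
    assert by_name["x-y:phist"] == 0.0
    assert by_name["x-y:shared_haplotypes"] == by_name["x:n_haplotypes"]


def test_summary_hand_computed_toy():
    # two populations of 3 short sequences; statistics computed by hand
    p1 = np.array([[0, 0, 0, 0], [0, 0, 0, 1], [0, 0, 1, 1]], dtype=np.uint8)
    p2 = np.array([[2, 2, 0, 0], [2, 2, 0, 0], [2, 2, 0, 1]], dtype=np.uint8)
    stats = summarize_codes([p1, p2], ["a", "b"])
    by_name = dict(zip(stats.names, stats.values))
    assert by_name["a:n_haplotypes"] == 3
    assert by_name["b:n_haplotypes"] == 2
    # p1 pairwise: d(1,2)=1, d(1,3)=2, d(2,3)=1 -> pi = 4/3
    assert by_name["a:mean_pairwise_diff"] == pytest.approx(4 / 3)
    assert by_name["a:segregating_sites"] == 2
    assert by_name["b:segregating_sites"] == 1
    # haplotype diversity p2: (3/2) * (1 - (2/3)^2 - (1/3)^2) = 2/3
    assert by_name["b:haplotype_diversity"] == pytest.approx(2 / 3)
    assert by_name["a-b:shared_haplotypes"] == 0
    # dxy: mean over 9 cross pairs of difference counts
    cross = [
        (p1[i] != p2[j]).sum() for i in range(3) for j in range(3)
    ]
    assert by_name["a-b:dxy"] == pytest.approx(np.mean(cross))


# ---------------------------------------------------------------------------
# rejection


def test_reject_exact_match_first(rng):
    table = gaussian_table(rng, m=5000)
    target = float(table.models["gauss"].stats[1234, 0])
    result = reject(observed_stat(target), table, eps=0.002)
    assert result.accepted_rows[0] == 1234
    assert result.accepted_distances[0] == 0.0


def test_reject_eps_bounds(rng):
    table = gaussian_table(rng, m=1000)
    with pytest.raises(ValueError):
        reject(observed_stat(0.0), table, eps=0.0)
    with pytest.warns(UserWarning, match="accepted"):
        reject(observed_stat(0.0), table, eps=0.001)


def test_rejection_posterior_matches_conjugate(rng):
    """Rejection + local-linear adjustment recover the flat-prior Gaussian
    posterior N(xbar, 1/n): means and variances agree within 3 SE over
    independent repetitions."""
    n_obs, reps = 10, 30
    post_means, post_vars, xbars = [], [], []
    for _ in range(reps):
        table = gaussian_table(rng, m=20_000, n_obs=n_obs)
        xbar_obs = float(rng.normal(2.0, 1.0 / math.sqrt(n_obs)))
        obs = observed_stat(xbar_obs)
        # a window wide enough to identify the local-linear slope: the
        # adjustment then sharpens the kept draws to the true posterior
        result = reject(obs, table, eps=0.05)
        mt = table.models["gauss"]
        posts = adjust_parameters(
            mt.params[result.accepted_rows],
            mt.param_names,
            mt.stats[result.accepted_rows],
            obs,
            table.mad,
            result.accepted_distances,
            bounds={"theta": (-10.0, 10.0)},
            seed=0,
        )
        post = posts["theta"]
        w = post.weights / post.weights.sum()
        post_means.append(float(np.average(post.adjusted, weights=w)))
        post_vars.append(
            float(np.average((post.adjusted - post_means[-1]) ** 2, weights=w))
        )
        xbars.append(xbar_obs)
    errs = np.array(post_means) - np.array(xbars)
    se = errs.std(ddof=1) / math.sqrt(reps)
    assert abs(errs.mean()) < 3 * se + 1e-3
    var_err = np.array(post_vars) - 1.0 / n_obs
    se_v = var_err.std(ddof=1) / math.sqrt(reps)
    assert abs(var_err.mean()) < 3 * se_v + 2e-3


def test_adjustment_beats_plain_rejection(rng):
    """Squared error of posterior mean/variance against the analytic
    posterior is smaller with local-linear adjustment, on average."""
    n_obs, reps = 10, 40
    gain = []
    for _ in range(reps):
        table = gaussian_table(rng, m=8000, n_obs=n_obs)
        xbar_obs = float(rng.uniform(-5, 5))
        obs = observed_stat(xbar_obs)
        # wide window: plain rejection is visibly biased/overdispersed here
        result = reject(obs, table, eps=0.2)
        mt = table.models["gauss"]
        common = dict(
            param_names=mt.param_names,
            accepted_stats=mt.stats[result.accepted_rows],
            observed=obs,
            mad=table.mad,
            distances=result.accepted_distances,
            bounds={"theta": (-10.0, 10.0)},
            seed=0,
        )
        adj = adjust_parameters(mt.params[result.accepted_rows], **common)
        raw = adjust_parameters(
            mt.params[result.accepted_rows], method="none", **common
        )
        for posts, store in ((adj, 0), (raw, 1)):
            post = posts["theta"]
            w = post.weights / post.weights.sum()
            mean = float(np.average(post.adjusted, weights=w))
            var = float(np.average((post.adjusted - mean) ** 2, weights=w))
            err = (mean - xbar_obs) ** 2 + (var - 1.0 / n_obs) ** 2
            if store == 0:
                adj_err = err
            else:
                raw_err = err
        gain.append(raw_err - adj_err)
    assert np.mean(gain) > 0


def test_prior_recovered_as_eps_goes_to_one(rng):
    table = gaussian_table(rng, m=20_000)
    obs = observed_stat(0.0)
    result = reject(obs, table, eps=1.0)
    theta = table.models["gauss"].params[result.accepted_rows, 0]
    se = theta.std(ddof=1) / math.sqrt(len(theta))
    assert abs(theta.mean() - 0.0) < 3 * se  # prior mean of U(-10, 10)


def test_standardisation_affine_invariance(rng):
    table = gaussian_table(rng, m=5000)
    obs = observed_stat(1.5)
    base = reject(obs, table, eps=0.01)
    mt = table.models["gauss"]
    scaled = ReferenceTable(
        stat_names=["xbar"],
        models={
            "gauss": ModelTable(
                label="gauss",
                param_names=["theta"],
                params=mt.params,
                stats=mt.stats * 1000.0,
            )
        },
    )
    res2 = reject(observed_stat(1500.0), scaled, eps=0.01)
    assert np.array_equal(base.accepted_rows, res2.accepted_rows)


# ---------------------------------------------------------------------------
# model choice


def two_model_table(rng, m=8000, shift=0.0):
    out = {}
    for label, mu in (("m1", 0.0), ("m2", shift)):
        theta = rng.uniform(-10, 10, size=m)
        xbar = rng.normal(theta + mu, 0.5)
        out[label] = ModelTable(
            label=label, param_names=["theta"],
            params=theta[:, None], stats=xbar[:, None],
        )
    return ReferenceTable(stat_names=["xbar"], models=out)


def test_identical_models_equal_probabilities(rng):
    table = two_model_table(rng, m=10_000, shift=0.0)
    obs = observed_stat(0.0)
    result = reject(obs, table, eps=0.01)
    n_acc = len(result.accepted_labels)
    se = math.sqrt(0.25 / n_acc)
    assert abs(result.model_probs_ar["m1"] - 0.5) < 3 * se
    lr = lr_model_choice(obs, table, eps=0.01, rejection=result)
    assert abs(lr["m1"] - 0.5) < 0.15
    assert lr["m1"] + lr["m2"] == pytest.approx(1.0)


def test_separable_models_decisive(rng):
    # disjoint statistic supports: N(theta, .5) vs N(theta+100, .5)
    table = two_model_table(rng, m=4000, shift=100.0)
    lr = lr_model_choice(observed_stat(0.0), table, eps=0.05)
    assert lr["m1"] > 0.99


def test_label_permutation_equivariance(rng):
    rng1 = np.random.default_rng(5)
    table = two_model_table(rng1, m=4000, shift=1.0)
    obs = observed_stat(0.5)
    lr = lr_model_choice(obs, table, eps=0.02)
    swapped = ReferenceTable(
        stat_names=table.stat_names,
        models={
            "m2": ModelTable("m2", ["theta"],
                             table.models["m1"].params, table.models["m1"].stats),
            "m1": ModelTable("m1", ["theta"],
                             table.models["m2"].params, table.models["m2"].stats),
        },
        mad=table.mad,
    )
    lr_swapped = lr_model_choice(obs, swapped, eps=0.02)
    assert lr["m1"] == pytest.approx(lr_swapped["m2"], abs=1e-6)
    assert lr["m2"] == pytest.approx(lr_swapped["m1"], abs=1e-6)


def test_ar_probabilities_sum_to_one(rng):
    table = two_model_table(rng, m=3000, shift=2.0)
    result = reject(observed_stat(1.0), table, eps=0.01)
    assert sum(result.model_probs_ar.values()) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# adjustment and HPD


def test_adjustment_identity_at_symmetric_observed():
    # accepted stats symmetric around the observed vector with equal
    # distances -> uniform weights, zero net shift of the posterior mean
    # (large enough set that the regression adjustment is active)
    params = np.tile([[1.0], [2.0], [3.0], [4.0]], (10, 1))
    stats = np.tile([[-1.0], [1.0], [-1.0], [1.0]], (10, 1))
    obs = observed_stat(0.0)
    posts = adjust_parameters(
        params,
        ["p"],
        stats,
        obs,
        mad=np.array([1.0]),
        distances=np.ones(40),
        bounds={"p": (0.0, 5.0)},
        seed=0,
    )
    # the adjustment ran (draws moved) but the symmetric design leaves the
    # posterior mean in place
    assert not np.allclose(posts["p"].adjusted, posts["p"].samples)
    assert posts["p"].mean == pytest.approx(params.mean(), abs=1e-9)


def test_hpd_uniform_sample_length(rng):
    samples = rng.uniform(0, 1, size=20_000)
    lo, hi = _weighted_hpd(samples, np.ones_like(samples), mass=0.95)
    assert (hi - lo) == pytest.approx(0.95, abs=0.02)


def test_hpd_concentrates_on_density_peak(rng):
    samples = np.concatenate([rng.normal(0, 0.05, 9000), rng.uniform(-3, 3, 1000)])
    lo, hi = _weighted_hpd(samples, np.ones_like(samples), mass=0.5)
    assert -0.2 < lo < hi < 0.2


def test_hpd_coverage_calibrated_on_gaussian_toy(rng):
    """95% HPD of the adjusted posterior covers the generating parameter at
    the nominal rate (binomial 3-sigma band) over prior-drawn repetitions."""
    n_obs = 10
    table = gaussian_table(rng, m=30_000, n_obs=n_obs)
    mt = table.models["gauss"]
    reps, hits = 150, 0
    for _ in range(reps):
        theta_true = float(rng.uniform(-8, 8))
        xbar_obs = float(rng.normal(theta_true, 1.0 / math.sqrt(n_obs)))
        obs = observed_stat(xbar_obs)
        result = reject(obs, table, eps=0.005)
        posts = adjust_parameters(
            mt.params[result.accepted_rows],
            mt.param_names,
            mt.stats[result.accepted_rows],
            obs,
            table.mad,
            result.accepted_distances,
            bounds={"theta": (-10.0, 10.0)},
            seed=int(rng.integers(2**31 - 1)),
        )
        lo, hi = posts["theta"].hpd95
        hits += lo <= theta_true <= hi
    rate = hits / reps
    se = math.sqrt(0.95 * 0.05 / reps)
    assert abs(rate - 0.95) < 3 * se + 0.01
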