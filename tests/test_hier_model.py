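"""Gibbs sampler validation: closed forms, diagnostics, recovery, priors."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from turntaking import hier_model as hm


def make_data(rng, cell_means, dyads_per_group=4, n_per_dyad=30, sigma=200.0,
              tau=80.0, stage=False):
    rows = []
    # build dyads first so each dyad spans all its group's cells
    groups = sorted({k[0] for k in cell_means})
    for group in groups:
        offsets = rng.normal(0, tau, dyads_per_group)
        for d in range(dyads_per_group):
            dyad = f"{group}-d{d}"
            for key, mu in cell_means.items():
                if key[0] != group:
                    continue
                y = rng.normal(mu + offsets[d], sigma, n_per_dyad)
                for v in y:
                    row = {"fto_ms": v, "group": group, "dyad": dyad}
                    if len(key) > 1:
                        row["epoch2"] = key[1]
                    rows.append(row)
    return pd.DataFrame(rows)


def test_conjugate_closed_form_reduction():
    """Known variance, no random effect: the cell-mean posterior is the
    textbook normal-normal conjugate update."""
    rng = np.random.default_rng(0)
    y = rng.normal(300, 100, 10)
    df = pd.DataFrame({"fto_ms": y, "group": "ASD", "dyad": "d1"})
    spec = hm.ModelSpec(chains=2, iterations=4000, warmup=1000, seed=3,
                        include_random=False, fix_sigma=100.0)
    draws = hm.fit(df, spec)
    s0 = spec.priors.coef_scale_ms
    prec = len(y) / 100.0**2 + 1.0 / s0**2
    expected_mean = (y.sum() / 100.0**2) / prec
    expected_sd = prec**-0.5
    cell = draws.cell(("ASD",))
    mc_err = expected_sd / np.sqrt(len(cell) / 10)  # generous autocorr margin
    assert cell.mean() == pytest.approx(expected_mean, abs=4 * mc_err)
    assert cell.std() == pytest.approx(expected_sd, rel=0.1)


def test_recovers_known_group_difference():
    """Data simulated with a true CTR-ASD difference of -322 ms."""
    rng = np.random.default_rng(42)
    df = make_data(rng, {("ASD",): 500.0, ("CTR",): 178.0}, dyads_per_group=5,
                   n_per_dyad=120, sigma=550.0, tau=80.0)
    draws = hm.fit(df, hm.ModelSpec(chains=2, iterations=2000, warmup=1000, seed=1))
    delta, summ = hm.group_contrast_by_stage(draws)
    assert summ.mean_ms == pytest.approx(-322.0, abs=2 * delta.std())
    assert summ.ci_low_ms < summ.mean_ms < summ.ci_high_ms


def test_contrast_ci_equals_sorted_percentiles():
    rng = np.random.default_rng(5)
    df = make_data(rng, {("ASD",): 300.0, ("CTR",): 250.0}, dyads_per_group=3,
                   n_per_dyad=40)
    draws = hm.fit(df, hm.ModelSpec(chains=2, iterations=1200, warmup=600, seed=2))
    delta, summ = hm.contrast(draws, ("ASD",), ("CTR",))
    ranked = np.sort(delta)
    lo = ranked[int(np.floor(0.025 * len(ranked)))]
    hi = ranked[int(np.ceil(0.975 * len(ranked))) - 1]
    assert summ.ci_low_ms == pytest.approx(lo, abs=abs(lo) * 0.02 + 2.0)
    assert summ.ci_high_ms == pytest.approx(hi, abs=abs(hi) * 0.02 + 2.0)
    assert summ.p_gt_zero == (delta > 0).mean()


def test_symmetric_delta_has_p_half():
    """delta draws symmetric about zero give P(delta > 0) = 1/2 exactly."""
    rng = np.random.default_rng(8)
    half = rng.normal(40.0, 25.0, (2, 500))
    mu = np.zeros((2, 1000, 2))
    mu[:, :500, 1] = half
    mu[:, 500:, 1] = -half  # cell 2 - cell 1 is exactly sign-symmetric
    draws = hm.PosteriorDraws(
        cell_labels=[("ASD",), ("CTR",)], dyad_labels=["d1", "d2"],
        mu=mu, u=np.zeros((2, 1000, 2)), sigma=np.ones((2, 1000)),
        tau=np.ones((2, 1000)), cell_idx=np.zeros(1, int),
        dyad_idx=np.zeros(1, int), y=np.zeros(1),
        spec=hm.ModelSpec(chains=2, iterations=2, warmup=1),
    )
    _, summ = hm.contrast(draws, ("ASD",), ("CTR",))
    assert summ.p_gt_zero == pytest.approx(0.5, abs=1e-12)
    assert summ.mean_ms == pytest.approx(0.0, abs=1e-9)


def test_same_seed_reproduces_draws():
    rng = np.random.default_rng(1)
    df = make_data(rng, {("ASD",): 300.0, ("CTR",): 200.0}, dyads_per_group=3,
                   n_per_dyad=20)
    spec = hm.ModelSpec(chains=2, iterations=600, warmup=300, seed=9)
    a = hm.fit(df, spec)
    b = hm.fit(df, spec)
    np.testing.assert_array_equal(a.mu, b.mu)
    np.testing.assert_array_equal(a.sigma, b.sigma)


class TestDiagnostics:
    def _draws(self, mu):
        return hm.PosteriorDraws(
            cell_labels=[("ASD",)], dyad_labels=["d1", "d2"],
            mu=mu, u=np.zeros((mu.shape[0], mu.shape[1], 2)),
            sigma=np.abs(mu[:, :, 0]) + 1.0, tau=np.abs(mu[:, :, 0]) + 1.0,
            cell_idx=np.zeros(1, int), dyad_idx=np.zeros(1, int),
            y=np.zeros(1), spec=hm.ModelSpec(chains=2, iterations=2, warmup=1),
        )

    def test_identical_chains_rhat_near_one(self):
        rng = np.random.default_rng(0)
        chain = rng.normal(0, 1, (1, 1000, 1))
        diag = hm.diagnostics(self._draws(np.repeat(chain, 4, axis=0)))
        mu_row = diag[diag["parameter"] == "mu"].iloc[0]
        assert mu_row["rhat"] == pytest.approx(1.0, abs=0.01)

    def test_iid_draws_ess_near_sample_size(self):
        rng = np.random.default_rng(1)
        mu = rng.normal(0, 1, (4, 1000, 1))
        diag = hm.diagnostics(self._draws(mu))
        ess = diag[diag["parameter"] == "mu"].iloc[0]["ess"]
        assert ess == pytest.approx(4000, rel=0.2)

    def test_shifted_chain_detected(self):
        rng = np.random.default_rng(2)
        mu = rng.normal(0, 1, (4, 800, 1))
        mu[0] += 3.0
        diag = hm.diagnostics(self._draws(mu))
        assert diag[diag["parameter"] == "mu"].iloc[0]["rhat"] > 1.1

    def test_nonconvergence_warning_raised(self):
        # two tiny chains on conflicting initialisations rarely converge
        rng = np.random.default_rng(3)
        df = make_data(rng, {("ASD",): 300.0, ("CTR",): 200.0}, dyads_per_group=3,
                       n_per_dyad=10)
        with pytest.warns(RuntimeWarning, match="R-hat"):
            hm.fit(df, hm.ModelSpec(chains=2, iterations=22, warmup=2, seed=0))


class TestPriorRecovery:
    def test_zero_observations_sample_the_prior(self):
        spec = hm.ModelSpec(chains=2, iterations=6000, warmup=1000, seed=7)
        draws = hm.fit(
            pd.DataFrame(columns=["fto_ms", "group", "dyad"]),
            spec,
            cell_labels=[("ASD",)],
            dyad_labels=["d1"],
        )
        mu = draws.mu.reshape(-1)
        assert mu.mean() == pytest.approx(0.0, abs=40.0)
        assert mu.std() == pytest.approx(spec.priors.coef_scale_ms, rel=0.05)
        # sigma should follow its half-normal prior
        sigma = draws.sigma.reshape(-1)
        half_normal_median = spec.priors.sigma_scale_ms * stats.norm.ppf(0.75)
        assert np.median(sigma) == pytest.approx(half_normal_median, rel=0.10)


class TestPosteriorPredictive:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(11)
        df = make_data(rng, {("ASD",): 300.0, ("CTR",): 250.0}, dyads_per_group=4,
                       n_per_dyad=60, sigma=400.0, tau=60.0)
        draws = hm.fit(df, hm.ModelSpec(chains=2, iterations=1500, warmup=700, seed=5))
        return draws

    def test_zero_replicates_empty(self, fitted):
        assert hm.posterior_predictive(fitted, 0).empty

    def test_fixed_seed_reproducible(self, fitted):
        a = hm.posterior_predictive(fitted, 20, seed=3)
        b = hm.posterior_predictive(fitted, 20, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_observed_moments_inside_replicated_spread(self, fitted):
        """For a well-specified model the observed mean/SD fall inside the
        central 95% of the replicated statistics."""
        reps = hm.posterior_predictive(fitted, 200, seed=1)
        for stat in ("mean_ms", "sd_ms"):
            lo, hi = np.percentile(reps[stat], [2.5, 97.5])
            assert lo <= reps[f"obs_{stat}"].iloc[0] <= hi


def test_label_permutation_leaves_summaries_unchanged():
    """Renaming dyads must not change posterior summaries (same seed,
    identical likelihood; labels only reorder the intercept vector)."""
    rng = np.random.default_rng(21)
    df = make_data(rng, {("ASD",): 350.0, ("CTR",): 250.0}, dyads_per_group=3,
                   n_per_dyad=30)
    spec = hm.ModelSpec(chains=2, iterations=800, warmup=400, seed=13)
    base = hm.fit(df, spec)
    renamed = df.assign(dyad=df["dyad"].map(lambda d: "z" + d))
    perm = hm.fit(renamed, spec)
    _, a = hm.contrast(base, ("ASD",), ("CTR",))
    _, b = hm.contrast(perm, ("ASD",), ("CTR",))
    assert a.mean_ms == pytest.approx(b.mean_ms)
    assert a.ci_low_ms == pytest.approx(b.ci_low_ms)
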