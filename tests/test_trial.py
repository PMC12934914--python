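"""Trial emulation: randomization, deactivation, copula control arm."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from netrx.centrality import centrality
from netrx.ggm import GlassoConfig, estimate_network
from netrx.trial import (
    DeactivationConfig,
    deactivate,
    fit_copula,
    normalized_influence,
    run_trial,
    sample_controls,
    stratified_randomize,
)


class TestRandomization:
    def test_even_stratum_splits_exactly(self):
        arm = stratified_randomize(10, np.repeat("S", 10), seed=0)
        assert (arm == "intervention").sum() == 5

    def test_odd_stratum_gives_intervention_the_extra(self):
        arm = stratified_randomize(11, np.repeat("S", 11), seed=0)
        assert (arm == "intervention").sum() == 6

    def test_assignment_probability_near_half(self):
        labels = np.repeat(["A", "B"], [6, 6])
        counts = np.zeros(12)
        runs = 500
        for seed in range(runs):
            counts += stratified_randomize(12, labels, seed=seed) == "intervention"
        assert np.abs(counts / runs - 0.5).max() < 0.08

    def test_singleton_stratum_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            stratified_randomize(3, np.array(["A", "A", "B"]), seed=0)


@pytest.fixture(scope="module")
def ei_table(item_network):
    return centrality(item_network)


class TestDeactivation:
    def test_zero_dose_is_identity(self, catalog, cohort313, ei_table):
        cfg = DeactivationConfig(target_domain="DST", alpha=0.0)
        t1 = deactivate(cohort313.items, cfg, ei_table, catalog)
        assert np.array_equal(t1.to_numpy(), cohort313.items.to_numpy().astype(float))

    def test_full_dose_hits_scale_floor(self, catalog):
        """alpha = 1 with unit influence maps any severity to 1."""
        import netrx.centrality as centmod

        items = pd.DataFrame(
            {c: [5] * 4 for c in catalog.codes}, columns=list(catalog.codes)
        )
        table = pd.DataFrame(
            {
                "strength": 1.0,
                "expected_influence": 1.0,
                "closeness": 0.0,
                "betweenness": 0.0,
            },
            index=list(catalog.codes),
        )
        ei = centmod.CentralityTable(table=table)
        cfg = DeactivationConfig(target_domain="DST", alpha=1.0)
        t1 = deactivate(items, cfg, ei, catalog)
        assert (t1[catalog.members("DST")].to_numpy() == 1.0).all()
        assert (t1[catalog.members("POS")].to_numpy() == 5.0).all()

    def test_formula_arithmetic(self, catalog):
        import netrx.centrality as centmod

        items = pd.DataFrame(
            {c: [5] for c in catalog.codes}, columns=list(catalog.codes)
        )
        table = pd.DataFrame(
            {
                "strength": 1.0,
                "expected_influence": [
                    1.0 if c == "G2" else (0.5 if c == "G3" else 0.1)
                    for c in catalog.codes
                ],
                "closeness": 0.0,
                "betweenness": 0.0,
            },
            index=list(catalog.codes),
        )
        ei = centmod.CentralityTable(table=table)
        cfg = DeactivationConfig(target_domain="DST", alpha=0.5)
        t1 = deactivate(items, cfg, ei, catalog)
        # e(G3) = 0.5/1.0; x' = 5 - 0.5*0.5*(5-1) = 4
        assert t1["G3"].iloc[0] == pytest.approx(4.0)

    def test_mean_target_score_monotone_in_dose(self, catalog, cohort313, ei_table):
        means = []
        for alpha in (0.0, 0.25, 0.5, 1.0):
            cfg = DeactivationConfig(target_domain="DST", alpha=alpha)
            t1 = deactivate(cohort313.items, cfg, ei_table, catalog)
            means.append(t1[catalog.members("DST")].to_numpy().mean())
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_non_target_items_bit_identical(self, catalog, cohort313, ei_table):
        cfg = DeactivationConfig(target_domain="DST", alpha=0.7)
        t1 = deactivate(cohort313.items, cfg, ei_table, catalog)
        others = [c for c in catalog.codes if catalog.domain_of[c] != "DST"]
        assert np.array_equal(
            t1[others].to_numpy(), cohort313.items[others].to_numpy().astype(float)
        )

    def test_order_preserved_within_item(self, catalog, cohort313, ei_table):
        cfg = DeactivationConfig(target_domain="DST", alpha=0.6)
        t1 = deactivate(cohort313.items, cfg, ei_table, catalog)
        for c in catalog.members("DST"):
            x = cohort313.items[c].to_numpy()
            y = t1[c].to_numpy()
            order = np.argsort(x, kind="stable")
            assert (np.diff(y[order]) >= -1e-12).all()

    def test_nonpositive_influence_rejected(self, catalog, cohort313):
        import netrx.centrality as centmod

        table = pd.DataFrame(
            {
                "strength": 1.0,
                "expected_influence": -0.2,
                "closeness": 0.0,
                "betweenness": 0.0,
            },
            index=list(catalog.codes),
        )
        ei = centmod.CentralityTable(table=table)
        with pytest.raises(ValueError, match="no influence signal"):
            deactivate(
                cohort313.items, DeactivationConfig(target_domain="DST"), ei, catalog
            )

    def test_negative_influence_clipped_to_zero(self, catalog):
        import netrx.centrality as centmod

        table = pd.DataFrame(
            {
                "strength": 1.0,
                "expected_influence": [
                    -0.5 if c == "G3" else 1.0 for c in catalog.codes
                ],
                "closeness": 0.0,
                "betweenness": 0.0,
            },
            index=list(catalog.codes),
        )
        e = normalized_influence(
            centmod.CentralityTable(table=table), ["G2", "G3", "G4", "G6"]
        )
        assert e["G3"] == 0.0


class TestCopula:
    def test_two_point_marginal_cdf(self):
        rng = np.random.default_rng(0)
        col = np.where(rng.random(400) < 0.5, 1, 7)
        profiles = pd.DataFrame({"a": col, "b": rng.integers(1, 8, 400)})
        model = fit_copula(profiles)
        cdf = model.cdf[0]
        assert cdf[-1] == pytest.approx(1.0)
        assert 0.4 < cdf[0] < 0.6
        assert np.allclose(cdf[1:6], cdf[0])  # flat between the two support points

    def test_comonotone_pair_recovers_unit_latent_correlation(self):
        rng = np.random.default_rng(1)
        x = rng.integers(1, 8, 3000)
        model = fit_copula(pd.DataFrame({"a": x, "b": x}))
        assert model.latent_corr[0, 1] >= 0.98

    def test_independent_items_near_zero_latent_correlation(self):
        rng = np.random.default_rng(2)
        profiles = pd.DataFrame(
            rng.integers(1, 8, size=(5000, 4)), columns=list("abcd")
        )
        model = fit_copula(profiles)
        off = model.latent_corr[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_point_mass_item_resamples_constant(self):
        rng = np.random.default_rng(3)
        profiles = pd.DataFrame(
            {"a": np.full(200, 3), "b": rng.integers(1, 8, 200)}
        )
        with pytest.warns(UserWarning, match="point mass"):
            model = fit_copula(profiles)
        draws = sample_controls(model, 500, seed=0)
        assert (draws["a"] == 3).all()

    def test_small_fit_sample_refused(self):
        profiles = pd.DataFrame({"a": [1, 2] * 10, "b": [3, 4] * 10})
        with pytest.raises(ValueError, match="n >= 50"):
            fit_copula(profiles)

    def test_resamples_stay_on_scale_and_match_marginals(self, cohort2000):
        model = fit_copula(cohort2000.items)
        draws = sample_controls(model, 10_000, seed=4)
        vals = draws.to_numpy()
        assert vals.min() >= 1 and vals.max() <= 7
        for c in ("G6", "P1", "N4"):
            src = np.bincount(cohort2000.items[c], minlength=8)[1:] / len(cohort2000.items)
            out = np.bincount(draws[c], minlength=8)[1:] / len(draws)
            assert 0.5 * np.abs(src - out).sum() <= 0.05


class TestRunTrial:
    def test_full_reproducibility(self, catalog, cohort313, ei_table):
        stratum = np.where(cohort313.sa == 1, "SA+", "SA-")
        a = run_trial(cohort313.items, stratum, ei_table, catalog, seed=3)
        b = run_trial(cohort313.items, stratum, ei_table, catalog, seed=3)
        assert np.array_equal(a.arm, b.arm)
        pd.testing.assert_frame_equal(a.t1, b.t1)

    def test_arm_counts_balanced_within_strata(self, catalog, cohort313, ei_table):
        stratum = np.where(cohort313.sa == 1, "SA+", "SA-")
        state = run_trial(cohort313.items, stratum, ei_table, catalog, seed=5)
        for s in ("SA+", "SA-"):
            ni = ((state.arm == "intervention") & (state.stratum == s)).sum()
            nc = ((state.arm == "control") & (state.stratum == s)).sum()
            assert abs(ni - nc) <= 1

    def test_long_frame_shape(self, catalog, cohort313, ei_table):
        stratum = np.where(cohort313.sa == 1, "SA+", "SA-")
        state = run_trial(cohort313.items, stratum, ei_table, catalog, seed=5)
        long = state.long_frame()
        assert len(long) == 2 * len(cohort313.items)
        assert set(long.time) == {"T0", "T1"}
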