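"""Spearman profiles, permutation calibration, odds-ratio enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rumherit.abundance import AbundanceTable
from rumherit.association import (
    _spearman,
    animal_abundance,
    correlation_odds_ratio,
    mean_abs_corr_compare,
    mean_correlation_null,
    presence_abundance_correlation,
    spearman_profile,
)
from rumherit.errors import InputError


def long_profile(r_p_by_otu, index="ix"):
    """Build a spearman_profile-shaped frame from {otu: (r, p)}."""
    return pd.DataFrame(
        [dict(otu_id=o, index=index, r=r, p_value=p, n=50, reason="")
         for o, (r, p) in r_p_by_otu.items()]
    )


class TestAnimalAbundance:
    def test_mean_over_days(self):
        t = AbundanceTable.from_arrays(
            ["o1"], ["a1"], [1, 2, 3], np.array([[[0.1, 0.2, 0.3]]])
        )
        assert animal_abundance(t).loc["o1", "a1"] == pytest.approx(0.2)

    def test_available_case_mean_with_missing_day(self):
        data = pd.DataFrame(
            {"a1_d1": [0.1], "a1_d3": [0.3], "a2_d1": [0.2], "a2_d2": [0.2],
             "a2_d3": [0.2]},
            index=["o1"],
        )
        t = AbundanceTable(data, pd.Series([""], index=["o1"]))
        out = animal_abundance(t)
        assert out.loc["o1", "a1"] == pytest.approx(0.2)  # mean of available days

    def test_matches_loop_oracle(self, herd100):
        from rumherit.simulate import PlantedMicrobiome, simulate_abundances

        t = simulate_abundances(
            herd100.grm, PlantedMicrobiome(n_otus=10, n_heritable=2, seed=1)
        )
        out = animal_abundance(t)
        for oid in t.otu_ids[:3]:
            for animal in t.animals[:5]:
                days = [t.data.loc[oid, f"{animal}_d{d}"] for d in t.days]
                assert out.loc[oid, animal] == pytest.approx(np.mean(days))


class TestSpearman:
    def test_monotone_and_antitone(self):
        x = np.arange(20.0)
        assert _spearman(x, x**3)[0] == pytest.approx(1.0)
        assert _spearman(x, -x)[0] == pytest.approx(-1.0)

    def test_ties_match_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(0, 5, 30).astype(float)  # heavy ties
            y = rng.integers(0, 4, 30).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            r, p = _spearman(x, y)
            ref = stats.spearmanr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(1)
        x = rng.random(40) + 0.1
        y = rng.random(40)
        base = _spearman(x, y)[0]
        assert _spearman(np.log(x), y)[0] == pytest.approx(base, abs=1e-12)
        assert _spearman(stats.rankdata(x), y)[0] == pytest.approx(base, abs=1e-12)

    def test_constant_vector_recorded_as_missing(self):
        abund = pd.DataFrame([[0.5] * 12], index=["o1"],
                             columns=[f"a{i}" for i in range(12)])
        traits = pd.DataFrame({"ix": np.arange(12.0)},
                              index=[f"a{i}" for i in range(12)])
        out = spearman_profile(abund, traits)
        assert np.isnan(out.iloc[0]["r"]) and out.iloc[0]["reason"]


class TestMeanCorrelationNull:
    @pytest.fixture()
    def heritable_abund(self, herd100):
        from rumherit.simulate import PlantedMicrobiome, simulate_abundances

        t = simulate_abundances(
            herd100.grm, PlantedMicrobiome(n_otus=30, n_heritable=22, seed=2)
        )
        return animal_abundance(t).iloc[:22]

    def test_planted_index_detected(self, heritable_abund):
        driver = heritable_abund.iloc[0]
        traits = pd.DataFrame({"ix": 3.0 * driver}, index=heritable_abund.columns)
        res = mean_correlation_null(heritable_abund, traits, n_perm=1000, seed=3)
        assert res.summary.loc["ix", "p_mean_abs_r"] <= 0.002

    def test_independent_noise_index_not_detected(self, heritable_abund):
        rng = np.random.default_rng(4)
        ps = []
        for s in range(40):
            traits = pd.DataFrame({"ix": rng.standard_normal(100)},
                                  index=heritable_abund.columns)
            res = mean_correlation_null(heritable_abund, traits, n_perm=99, seed=s)
            ps.append(res.summary.loc["ix", "p_mean_abs_r"])
        # p-values under the null are roughly uniform, not concentrated low
        assert (np.asarray(ps) <= 0.05).mean() <= 0.15
        assert np.mean(ps) == pytest.approx(0.5, abs=0.2)

    def test_deterministic_under_seed(self, heritable_abund):
        traits = pd.DataFrame({"ix": np.arange(100.0)},
                              index=heritable_abund.columns)
        r1 = mean_correlation_null(heritable_abund, traits, n_perm=50, seed=9)
        r2 = mean_correlation_null(heritable_abund, traits, n_perm=50, seed=9)
        pd.testing.assert_frame_equal(r1.summary, r2.summary)


class TestMeanAbsCorrCompare:
    def test_shifted_group_detected(self):
        rng = np.random.default_rng(5)
        rp = {f"h{i}": (min(0.95, abs(rng.normal(0.5, 0.1))), 0.01) for i in range(22)}
        rp.update({f"n{i}": (rng.normal(0.0, 0.15), 0.5) for i in range(400)})
        out = mean_abs_corr_compare(long_profile(rp), [f"h{i}" for i in range(22)])
        assert out.iloc[0]["p_value"] < 0.05
        assert out.iloc[0]["mean_abs_r_heritable"] > out.iloc[0]["mean_abs_r_other"]

    def test_exchangeable_groups_rarely_flagged(self):
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(100):
            rp = {f"o{i}": (rng.normal(0, 0.2), 0.5) for i in range(80)}
            out = mean_abs_corr_compare(long_profile(rp), [f"o{i}" for i in range(20)])
            hits += out.iloc[0]["p_value"] < 0.05
        assert hits <= 12  # ~alpha * 100 with slack

    def test_single_member_group_skipped(self):
        rp = {"h1": (0.5, 0.01), "n1": (0.1, 0.5), "n2": (0.2, 0.4)}
        with pytest.warns(UserWarning, match="fewer than two"):
            out = mean_abs_corr_compare(long_profile(rp), ["h1"])
        assert out.empty


class TestCorrelationOddsRatio:
    def test_balanced_table_is_unity(self):
        rp = {"h1": (0.9, 0.01), "h2": (0.1, 0.9), "n1": (0.8, 0.01), "n2": (0.0, 0.9)}
        res = correlation_odds_ratio(long_profile(rp), ["h1", "h2"])[0]
        assert (res.hc, res.hn, res.nc, res.nn) == (1, 1, 1, 1)
        assert res.odds_ratio == pytest.approx(1.0)

    def test_methods_formula_example(self):
        rp = {}
        rp.update({f"h{i}": (0.5, 0.01) for i in range(10)})
        rp.update({f"h{i}": (0.1, 0.50) for i in range(10, 22)})
        rp.update({f"n{i}": (0.5, 0.01) for i in range(100)})
        rp.update({f"n{i}": (0.1, 0.50) for i in range(100, 1000)})
        res = correlation_odds_ratio(long_profile(rp), [f"h{i}" for i in range(22)])[0]
        assert (res.hc, res.hn, res.nc, res.nn) == (10, 12, 100, 900)
        assert res.odds_ratio == pytest.approx(7.5)

    def test_fisher_matches_enumeration(self):
        from test_phylo import fisher_two_sided_enumeration

        rp = {}
        rp.update({f"h{i}": (0.5, 0.01) for i in range(10)})
        rp.update({f"h{i}": (0.1, 0.50) for i in range(10, 22)})
        rp.update({f"n{i}": (0.5, 0.01) for i in range(100)})
        rp.update({f"n{i}": (0.1, 0.50) for i in range(100, 1000)})
        res = correlation_odds_ratio(long_profile(rp), [f"h{i}" for i in range(22)])[0]
        assert res.fisher_p == pytest.approx(
            fisher_two_sided_enumeration(10, 12, 100, 900), abs=1e-12
        )

    def test_missing_pvalue_counts_as_not_correlated(self):
        rp = {"h1": (np.nan, np.nan), "h2": (0.9, 0.001), "n1": (0.2, 0.3)}
        res = correlation_odds_ratio(long_profile(rp), ["h1", "h2"])[0]
        assert (res.hc, res.hn) == (1, 1)

    def test_infinite_and_undefined_odds(self):
        rp = {"h1": (0.9, 0.01), "h2": (0.8, 0.01), "n1": (0.1, 0.9)}
        res = correlation_odds_ratio(long_profile(rp), ["h1", "h2"])[0]
        assert np.isinf(res.odds_ratio)  # hn = 0 with hc*nn > 0

    def test_direction_agreement_with_one_sided_fisher(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            hc, hn, nc, nn = rng.integers(1, 40, 4)
            if hc * nn == hn * nc:
                continue
            p_g = stats.fisher_exact([[hc, hn], [nc, nn]], "greater")[1]
            p_g_t = stats.fisher_exact([[nc, nn], [hc, hn]], "greater")[1]
            orr = (hc / hn) / (nc / nn)
            if orr > 1:
                assert p_g < p_g_t
            elif orr < 1:
                assert p_g > p_g_t


class TestPresenceAbundance:
    def test_monotone_construction(self):
        abund = pd.DataFrame(
            [[0.1, 0.0, 0.0, 0.0],
             [0.2, 0.2, 0.0, 0.0],
             [0.3, 0.3, 0.3, 0.0],
             [0.4, 0.4, 0.4, 0.4]],
            index=[f"o{i}" for i in range(4)],
            columns=[f"a{i}" for i in range(4)],
        )
        r, p = presence_abundance_correlation(abund, abund.index)
        assert r == pytest.approx(1.0)

    def test_consistent_with_spearman_machinery(self):
        rng = np.random.default_rng(8)
        abund = pd.DataFrame(rng.random((8, 20)) * (rng.random((8, 20)) > 0.3),
                             index=[f"o{i}" for i in range(8)],
                             columns=[f"a{i}" for i in range(20)])
        r, _ = presence_abundance_correlation(abund, abund.index)
        pres = (abund > 0).sum(axis=1).to_numpy(dtype=float)
        sums = abund.sum(axis=1).to_numpy()
        assert r == pytest.approx(_spearman(pres, sums)[0], abs=1e-12)

    def test_constant_presence_flagged(self):
        abund = pd.DataFrame(np.full((3, 5), 0.1), index=list("abc"),
                             columns=[f"a{i}" for i in range(5)])
        with pytest.raises(InputError):
            presence_abundance_correlation(abund, list("abc"))
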