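"""Michaelis-Menten fitting, CLint arithmetic, Tukey comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from nat2kit.errors import InsufficientDataError, NonConvergentFitError
from nat2kit.kinetics import (
    MMFit,
    ReactionObservation,
    compare_alleles_tukey,
    compute_clint,
    fit_dataset,
    fit_michaelis_menten,
    mean_se,
    relative_clearance,
    summarize_kinetics,
)
from nat2kit.synthetic_data import KineticSimSpec, simulate_kinetic_dataset

CONCS = np.array([1.0, 3, 10, 30, 100, 300, 1000])


def _mm(s, km, vmax):
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s)


class TestFit:
    @pytest.mark.parametrize("method", ["lineweaver_burk", "nls"])
    def test_noiseless_data_recovered_exactly(self, method):
        fit = fit_michaelis_menten(CONCS, _mm(CONCS, 100.0, 50.0),
                                   method=method)
        assert fit.km == pytest.approx(100.0, rel=1e-6)
        assert fit.vmax == pytest.approx(50.0, rel=1e-6)
        assert fit.clint == pytest.approx(0.5, rel=1e-6)

    def test_accepts_observation_records(self):
        obs = [ReactionObservation("INH", "*4", 1, s, v)
               for s, v in zip(CONCS, _mm(CONCS, 128.1, 1496.5))]
        fit = fit_michaelis_menten(obs)
        assert fit.km == pytest.approx(128.1, rel=1e-6)

    def test_blank_and_too_few_points(self):
        # [S]=0 rows are blank checks, never regression points
        s = np.array([0.0, 1, 10, 100])
        fit = fit_michaelis_menten(s, _mm(s, 10, 5))
        assert fit.km == pytest.approx(10, rel=1e-6)
        with pytest.raises(InsufficientDataError):
            fit_michaelis_menten([100.0], [5.0])
        with pytest.raises(InsufficientDataError):
            fit_michaelis_menten([0.0, 10.0, 10.0], [0.0, 3.0, 3.1])

    def test_unphysical_reciprocal_line_reported(self):
        # velocity falling with concentration: negative reciprocal slope
        with pytest.raises(NonConvergentFitError, match="non-positive"):
            fit_michaelis_menten([1.0, 10, 100], [10.0, 5, 1])
        # superlinear growth: negative reciprocal intercept
        with pytest.raises(NonConvergentFitError, match="non-positive"):
            fit_michaelis_menten([1.0, 2, 4], [1.0, 2.2222, 5.0])

    def test_signal_floor_drops_low_velocities(self):
        s = np.array([0.3, 1, 3, 10, 30, 100])
        v = _mm(s, 10, 5)
        fit = fit_michaelis_menten(s, v, signal_floor=v[0])
        assert fit.n_points == len(s) - 1

    def test_recovery_at_published_truth(self):
        # 4 replicates at the AGT *4 truth with 5% CV noise: the mean of
        # the replicate nls estimates lands within 15% of Km = 76.24
        rng = np.random.default_rng(3)
        km, vmax = 76.24, 45.18
        s = np.array([0.3, 1, 3, 10, 30, 100, 300, 1000])
        sigma = np.sqrt(np.log1p(0.05 ** 2))
        kms = []
        for _ in range(4):
            noisy = _mm(s, km, vmax) * rng.lognormal(-sigma ** 2 / 2, sigma,
                                                     s.size)
            kms.append(fit_michaelis_menten(s, noisy, method="nls").km)
        assert abs(np.mean(kms) - km) / km < 0.15

    def test_nls_no_worse_than_lineweaver_burk_on_noisy_data(self):
        rng = np.random.default_rng(9)
        km, vmax = 76.24, 45.18
        s = np.array([0.3, 1, 3, 10, 30, 100, 300, 1000])
        sigma = np.sqrt(np.log1p(0.05 ** 2))
        err = {"lineweaver_burk": [], "nls": []}
        for _ in range(50):
            noisy = _mm(s, km, vmax) * rng.lognormal(-sigma ** 2 / 2, sigma,
                                                     s.size)
            for m in err:
                try:
                    err[m].append(abs(fit_michaelis_menten(s, noisy, m).km
                                      - km))
                except NonConvergentFitError:
                    # LB's reciprocal intercept can go negative under noise
                    err[m].append(np.inf)
        assert np.median(err["nls"]) <= np.median(err["lineweaver_burk"])
        assert np.isfinite(err["nls"]).all()


class TestClint:
    def test_published_reference_rows(self):
        assert round(compute_clint([MMFit(76.24, 45.18, "nls", 8)]).mean,
                     3) == 0.593
        assert round(compute_clint([(85.95, 0.34)]).mean, 3) == 0.004
        assert compute_clint([(5.0, 0.0)]).mean == 0.0
        with pytest.raises(ValueError):
            compute_clint([])

    def test_mean_of_ratios_with_se(self):
        ss = compute_clint([(10.0, 5.0), (20.0, 5.0)])  # ratios .5, .25
        assert ss.mean == pytest.approx(0.375)
        assert ss.se == pytest.approx(np.std([.5, .25], ddof=1) / np.sqrt(2))
        assert ss.n == 2

    def test_all_published_rows_consistent_within_5pct(self, kinetic_params):
        # ratio of printed means vs printed CLint: the residual reflects
        # per-replicate averaging with unprinted replicates
        for (drug, allele), row in kinetic_params.iterrows():
            ratio = row["vmax_mean"] / row["km_mean"]
            assert ratio == pytest.approx(row["clint_mean"], rel=0.05), \
                (drug, allele)
        agt4 = kinetic_params.loc[("AGT", "*4")]
        assert round(agt4["vmax_mean"] / agt4["km_mean"], 3) == 0.593


class TestRelativeClearance:
    def test_published_lower_bounds(self, kinetic_params):
        inh = kinetic_params.loc["INH"]["clint_mean"]
        assert round(relative_clearance(inh["*5"], inh["*4"]), 1) == 12.4
        assert round(relative_clearance(inh["*6"], inh["*4"]), 1) == 3.9

    def test_identity_and_errors(self):
        assert relative_clearance(0.3, 0.3) == pytest.approx(100.0)
        with pytest.raises(ValueError):
            relative_clearance(1.0, 0.0)

    @settings(max_examples=50, deadline=None)
    @given(clint=st.floats(1e-6, 1e6), ref=st.floats(1e-6, 1e6),
           c=st.floats(1e-6, 1e6))
    def test_scale_invariance(self, clint, ref, c):
        assert relative_clearance(clint * c, ref * c) == pytest.approx(
            relative_clearance(clint, ref), rel=1e-9)


class TestTukey:
    def test_equal_groups_give_p_one(self):
        res = compare_alleles_tukey({"*4": [1.0, 1.0], "*5": [1.0, 1.0]})
        assert res.degenerate
        assert res.p("*4", "*5") == 1.0
        assert res.letters["*5"] == ""

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compare_alleles_tukey({"*4": [1.0, 2.0]})

    def test_separated_groups_all_significant(self):
        rng = np.random.default_rng(8)
        means = {"*4": 100.0, "*5": 10.0, "*6": 1.0}
        groups = {a: m * rng.lognormal(0, 0.05, 4)
                  for a, m in means.items()}
        res = compare_alleles_tukey(groups)
        for pair, p in res.p_values.items():
            assert p < 0.05, pair
        assert res.letters == {"*4": "", "*5": "a", "*6": "a,b"}

    def test_matches_studentized_range_oracle(self):
        # adjusted p for one pair recomputed from the studentized-range
        # distribution: q = |mi - mj| / sqrt(MSE/n), df = N - k
        rng = np.random.default_rng(15)
        groups = {a: rng.normal(m, 1.0, 5)
                  for a, m in (("*4", 0.0), ("*5", 2.0), ("*6", 5.0))}
        res = compare_alleles_tukey(groups)
        arrays = [np.asarray(groups[a]) for a in ("*4", "*5", "*6")]
        n = 5
        mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / (3 * (n - 1))
        q = abs(arrays[0].mean() - arrays[1].mean()) / np.sqrt(mse / n)
        p_oracle = stats.studentized_range.sf(q, k=3, df=3 * (n - 1))
        assert res.p("*4", "*5") == pytest.approx(p_oracle, rel=1e-6)


class TestSummaries:
    def test_fit_dataset_and_summary_from_simulation(self):
        spec = KineticSimSpec(
            true_params={("AGT", "*4"): (76.24, 45.18),
                         ("AGT", "*6"): (187.75, 6.70)},
            concentration_design={"AGT": (0, 0.3, 1, 3, 10, 30, 100, 300,
                                          1000)},
            cv_noise=0.05, n_replicates=4, seed=2)
        fits = fit_dataset(simulate_kinetic_dataset(spec), method="nls")
        assert len(fits) == 8  # 2 alleles x 4 replicates
        summary = summarize_kinetics(fits)
        assert list(summary["allele"]) == ["*4", "*6"]
        row6 = summary[summary["allele"] == "*6"].iloc[0]
        assert row6["clint_letters"] == "a"  # clearly below *4
        assert summary[summary["allele"] == "*4"]["clint_letters"].iloc[0] == ""
        # CLint = mean of per-replicate ratios
        reps = fits[fits["allele"] == "*6"]["clint"]
        assert row6["clint_mean"] == pytest.approx(reps.mean())

    def test_mean_se_single_value(self):
        ss = mean_se([2.5])
        assert ss.mean == 2.5 and ss.se == 0.0 and ss.n == 1
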