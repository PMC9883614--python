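import numpy as np
import pytest

from vispathways import (
    DecodingResult,
    GeneratorConfig,
    NoiseSpec,
    RegionSignal,
    bootstrap_ci,
    bootstrap_onsets,
    channel_resample,
    decode_cohort,
    decode_timecourse,
    leave_category_out,
    precedence_binomial,
    residualize,
    simulate_participant,
)
from conftest import make_dataset


def _result(accuracy, chance=0.25, step=4.0, t0=-48.0):
    accuracy = np.asarray(accuracy, dtype=float)
    times = t0 + step * np.arange(accuracy.shape[1])
    return DecodingResult(accuracy=accuracy, chance=chance, times=times, region="dorsal")


class TestDecodeTimecourse:
    def test_noiseless_signal_decodes_perfectly_after_onset(self):
        cfg = GeneratorConfig(
            n_participants=1, n_reps=3, seed=11,
            epoch_window_ms=(-48.0, 152.0),
            region_sizes={"dorsal": 8, "ventral": 2},
            region_signals={"dorsal": RegionSignal(onset_ms=60.0, amplitude=1.0)},
            couplings=(), noise=NoiseSpec(white_sd=0.0),
            pattern_drift=0.0, exemplar_scale=0.1,
        )
        ds = simulate_participant(cfg, 0)
        acc = decode_timecourse(ds, "dorsal", n_folds=10, fold_seed=0)
        post = ds.times >= 60.0
        assert np.all(acc[post] == 1.0)
        # pre-onset features are exactly zero -> constant prediction = chance
        assert np.all(np.abs(acc[~post] - 0.25) < 1e-12)

    def test_permuted_labels_decode_at_chance(self, mini_cohort):
        ds = mini_cohort[0]
        rng = np.random.default_rng(0)
        perm = rng.permutation(ds.n_trials)
        shuffled = make_dataset(ds.data, list(ds.montage.regions),
                                ds.categories[perm], ds.exemplars[perm], t0_ms=ds.times[0])
        acc = decode_timecourse(shuffled, "dorsal", n_folds=20, fold_seed=1)
        assert abs(acc.mean() - 0.25) < 0.03

    def test_three_category_chance(self, mini_cohort):
        res = decode_cohort(mini_cohort, "dorsal", categories=[1, 2, 3], n_folds=4)
        assert res.chance == pytest.approx(1 / 3)

    def test_exemplar_unique_patterns_do_not_generalize(self):
        """Held-out exemplar decoding sits at chance when categories share no
        pattern.  A single 20-exemplar draw has idiosyncratic geometry, so the
        check averages over several independent pattern draws."""
        from vispathways.decode import _decode_array

        rng = np.random.default_rng(21)
        n_cat, n_ex, n_reps, n_ch = 4, 5, 4, 4
        cats = np.repeat(np.arange(n_cat), n_ex * n_reps)
        exs = np.tile(np.repeat(np.arange(n_ex), n_reps), n_cat)
        means = []
        for draw in range(100):
            pats = rng.standard_normal((n_cat, n_ex, n_ch))
            data = (pats[cats, exs] + 0.3 * rng.standard_normal((len(cats), n_ch)))[:, :, None]
            means.append(_decode_array(data, cats, exs, n_folds=10, fold_seed=draw)[0])
        assert abs(np.mean(means) - 0.25) < 0.03

    def test_too_few_exemplars_rejected(self):
        ds = make_dataset(np.zeros((8, 2, 5)), ["dorsal", "dorsal"],
                          categories=np.arange(8) % 4, exemplars=np.zeros(8, int) % 2)
        with pytest.raises(ValueError, match="3 exemplars"):
            decode_timecourse(ds, "dorsal", n_folds=2)


class TestBootstrapCI:
    def test_identical_participants_flagged_above_chance(self):
        acc = np.full((5, 10), 0.5)
        out = bootstrap_ci(_result(acc), n_boot=200, seed=0)
        assert out["above_chance"].all()

    def test_null_flag_rate_matches_one_sided_miscoverage(self):
        """Accuracy at chance: ~2.5% of timepoints flagged (95% percentile CI)."""
        rng = np.random.default_rng(1)
        acc = 0.25 + 0.05 * rng.standard_normal((20, 2000))
        out = bootstrap_ci(_result(acc), n_boot=1000, seed=2)
        assert out["above_chance"].mean() == pytest.approx(0.025, abs=0.015)

    def test_outlier_widens_interval(self):
        rng = np.random.default_rng(3)
        acc = 0.3 + 0.01 * rng.standard_normal((20, 5))
        with_outlier = acc.copy()
        with_outlier[0] = 0.9
        w0 = bootstrap_ci(_result(acc), n_boot=500, seed=4)
        w1 = bootstrap_ci(_result(with_outlier), n_boot=500, seed=4)
        width0 = w0["ci_high"] - w0["ci_low"]
        width1 = w1["ci_high"] - w1["ci_low"]
        assert np.all(width1 > width0)


class TestBootstrapOnsets:
    def test_step_function_onset_exact(self):
        times = -48.0 + 4.0 * np.arange(138)
        acc = np.where(times >= 66.0, 0.5, 0.25)[None, :].repeat(8, axis=0)
        dist = bootstrap_onsets(_result(acc, t0=-48.0), n_boot=300, seed=0)
        # zero-variance timepoints: significant iff mean > chance
        assert np.all(dist.onsets_ms == 68.0)  # first grid point >= 66 ms
        assert dist.median_onset_ms == 68.0

    def test_null_detection_rate_matches_monte_carlo_oracle(self):
        """Chance-level accuracy: the fraction of resamples with a detected
        onset matches an independent run-length Monte-Carlo (fresh t-tests and
        run detection coded here, not via the package)."""
        from scipy import stats as sstats

        rng = np.random.default_rng(5)
        n_p, n_tp, n_cohorts, n_boot = 12, 100, 25, 60

        def oracle_rate(acc, r):
            hits = 0
            for _ in range(n_boot):
                sub = acc[r.integers(0, n_p, n_p)]
                t = (sub.mean(0) - 0.25) / (sub.std(0, ddof=1) / np.sqrt(n_p))
                sig = sstats.t.sf(t, n_p - 1) < 0.05
                post = sig[12:]  # timepoints >= 0 ms
                if np.any(post[1:] & post[:-1]):
                    hits += 1
            return hits / n_boot

        pkg_rates, oracle_rates = [], []
        for c in range(n_cohorts):
            acc = 0.25 + 0.03 * np.random.default_rng(100 + c).standard_normal((n_p, n_tp))
            dist = bootstrap_onsets(_result(acc), n_boot=n_boot, seed=200 + c)
            pkg_rates.append(dist.detection_rate)
            oracle_rates.append(oracle_rate(acc, np.random.default_rng(300 + c)))
        assert np.mean(pkg_rates) == pytest.approx(np.mean(oracle_rates), abs=0.06)

    def test_consecutivity_requirement_is_monotone(self):
        rng = np.random.default_rng(7)
        acc = 0.25 + 0.03 * rng.standard_normal((12, 100))
        r1 = bootstrap_onsets(_result(acc), n_boot=300, consecutive=1, seed=8)
        r2 = bootstrap_onsets(_result(acc), n_boot=300, consecutive=2, seed=8)
        assert r1.detection_rate >= r2.detection_rate

    def test_requires_three_participants(self):
        with pytest.raises(ValueError, match="3 participants"):
            bootstrap_onsets(_result(np.full((2, 10), 0.3)), n_boot=10)


class TestPrecedenceBinomial:
    def test_always_first(self):
        out = precedence_binomial(np.full(50, 66.0), np.full(50, 94.0))
        assert out["proportion_a_first"] == 1.0
        assert out["p_value"] < 1e-6

    def test_exact_binomial_tail_for_8_of_10(self):
        # exact two-sided binomial: 2 * P(X >= 8 | n=10, p=.5) = 2*(45+10+1)/1024
        a = np.array([1.0] * 8 + [9.0] * 2)
        b = np.array([5.0] * 10)
        out = precedence_binomial(a, b)
        assert out["proportion_a_first"] == 0.8
        assert out["p_value"] == pytest.approx(0.109375, abs=1e-12)

    def test_single_missing_counts_as_other_preceding(self):
        a = np.array([np.nan, 10.0])
        b = np.array([20.0, np.nan])
        out = precedence_binomial(a, b)
        assert out["n_informative"] == 2
        assert out["proportion_a_first"] == 0.5

    def test_ties_and_double_missing_excluded(self):
        a = np.array([10.0, np.nan, 30.0])
        b = np.array([10.0, np.nan, 50.0])
        out = precedence_binomial(a, b)
        assert out["n_informative"] == 1
        assert out["proportion_a_first"] == 1.0

    def test_all_tied_raises(self):
        with pytest.raises(ValueError, match="no informative"):
            precedence_binomial(np.array([5.0, np.nan]), np.array([5.0, np.nan]))

    def test_swap_complements_proportion_exactly(self):
        rng = np.random.default_rng(9)
        a = rng.choice([60.0, 64.0, 68.0, np.nan], size=200)
        b = rng.choice([60.0, 64.0, 68.0, np.nan], size=200)
        informative = ~(np.isnan(a) & np.isnan(b))
        if not informative.any():  # pragma: no cover
            pytest.skip("degenerate draw")
        ab = precedence_binomial(a, b)
        ba = precedence_binomial(b, a)
        assert ab["proportion_a_first"] == pytest.approx(1.0 - ba["proportion_a_first"])
        assert ab["p_value"] == pytest.approx(ba["p_value"])


class TestControls:
    def test_leave_category_out_structure(self, mini_cohort):
        out = leave_category_out(mini_cohort, ("dorsal", "ventral"),
                                 n_resample=20, seed=0, n_folds=4)
        assert set(out["per_subset"]) == {0, 1, 2, 3}
        assert len(out["pooled_onsets"]["dorsal"]) == 80
        assert 0.0 <= out["pooled_precedence"]["proportion_a_first"] <= 1.0

    def test_channel_resample_deterministic(self, mini_cohort):
        a = channel_resample(mini_cohort, ("dorsal", "ventral"),
                             n_resample=3, seed=5, n_folds=3)
        b = channel_resample(mini_cohort, ("dorsal", "ventral"),
                             n_resample=3, seed=5, n_folds=3)
        np.testing.assert_array_equal(a["onsets"]["dorsal"], b["onsets"]["dorsal"])

    def test_residualize_removes_exact_linear_mixture(self):
        rng = np.random.default_rng(10)
        rest = rng.standard_normal((6, 3, 40))
        weights = rng.standard_normal(3)
        roi = np.einsum("c,tcs->ts", weights, rest)[:, None, :]
        data = np.concatenate([roi, rest], axis=1)
        ds = make_dataset(data, ["dorsal", "frontal", "frontal", "frontal"],
                          categories=np.arange(6) % 3, exemplars=np.arange(6) % 2)
        out = residualize([ds], roi_regions=("dorsal",), variance_retained=1.0)[0]
        roi_norm = np.linalg.norm(ds.data[:, 0, :])
        assert np.linalg.norm(out.data[:, 0, :]) < 1e-8 * roi_norm

    def test_residuals_orthogonal_to_retained_components(self):
        rng = np.random.default_rng(11)
        data = rng.standard_normal((5, 6, 30))
        ds = make_dataset(data, ["dorsal", "dorsal", "frontal", "frontal", "frontal", "frontal"],
                          categories=np.arange(5) % 3, exemplars=np.arange(5) % 2)
        out = residualize([ds], roi_regions=("dorsal",), variance_retained=0.95)[0]
        rest = data[:, 2:, :].transpose(0, 2, 1).reshape(-1, 4)
        rest = rest - rest.mean(axis=0)
        u, s, _ = np.linalg.svd(rest, full_matrices=False)
        k = int(np.searchsorted(np.cumsum(s**2) / (s**2).sum(), 0.95 - 1e-12) + 1)
        for ch in range(2):
            resid = out.data[:, ch, :].reshape(-1)
            assert np.abs(u[:, :k].T @ resid).max() < 1e-8
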