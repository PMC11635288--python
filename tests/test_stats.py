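"""Class summaries, rank-sum comparisons with letter displays, t-tests, report."""

import itertools
import json
from math import comb

import numpy as np
import pandas as pd
import pytest

from frapconn.stats import (
    assign_letters,
    ranksum_compare,
    summarize_classes,
    ttest_compare,
)


class TestSummarizeClasses:
    def test_single_class_is_100_percent(self):
        out = summarize_classes({"mock": ["fast"] * 10})
        assert out.loc["mock", "fast"] == pytest.approx(100.0)
        assert out.loc["mock", "n"] == 10

    def test_mixed_classes(self):
        out = summarize_classes({"g": ["fast", "no_recovery"]})
        row = out.loc["g"]
        assert row["fast"] == pytest.approx(50.0)
        assert row["medium"] == 0.0
        assert row["slow"] == 0.0
        assert row["no_recovery"] == pytest.approx(50.0)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(3)
        classes = list(rng.choice(["fast", "medium", "slow", "no_recovery"], 57))
        out = summarize_classes({"g": classes})
        assert out.loc["g", ["fast", "medium", "slow", "no_recovery"]].sum() == pytest.approx(
            100.0, abs=0.01
        )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_classes({"g": []})

    def test_simulated_connected_cohort_mostly_recovers(self):
        """A cohort of fast-exchanging connected vacuoles should land almost
        entirely in the recovering classes."""
        from frapconn.connectivity import classify_recovery
        from frapconn.recovery import build_curve, fit_single_exponential
        from frapconn.series_io import extract_intensity

        from conftest import simulate_experiment

        classes = []
        for seed in range(1, 11):
            # exchange slow enough that recovery is not missed inside the
            # bleach gap, deep bleach for a clear amplitude
            exp = simulate_experiment(
                "constricted",
                2,
                seed=seed,
                noise_model="poisson",
                geometry_params={"edge_half_time_s": 2.5},
                bleach_depth=0.8,
                n_postbleach=50,
            )
            trace = extract_intensity(exp.series, exp.rois["a"], "a")
            fit = fit_single_exponential(build_curve(trace, exp.series))
            classes.append(classify_recovery(fit).value)
        out = summarize_classes({"mock": classes})
        assert out.loc["mock", "no_recovery"] <= 10.0


def brute_force_mannwhitney_p(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all rank splits.

    Uses the symmetry of the null U distribution around n1*n2/2: the
    two-sided p is the null probability of a U at least as extreme (in
    either tail) as observed.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    stat_obs = min(u_obs, n1 * len(y) - u_obs)
    count = 0
    total = comb(len(pooled), n1)
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        u = sum(1 for xi in xs for yj in ys if xi > yj)
        if min(u, n1 * len(ys) - u) <= stat_obs:
            count += 1
    return count / total


class TestRanksum:
    def test_identical_groups_share_a_letter(self):
        res = ranksum_compare({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]})
        assert res.p_values.loc["a", "b"] == pytest.approx(1.0)
        assert set(res.letters["a"]) & set(res.letters["b"])

    def test_disjoint_small_samples_exact_p(self):
        # U = 0 is the most extreme of the 20 equally likely 3-vs-3 splits
        res = ranksum_compare({"lo": [1, 2, 3], "hi": [101, 102, 103]})
        assert res.p_values.loc["lo", "hi"] == pytest.approx(0.1)

    @pytest.mark.parametrize("n1,n2,seed", [(3, 3, 0), (4, 5, 1), (6, 6, 2), (5, 4, 3)])
    def test_exact_path_matches_brute_force_enumeration(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, n1)
        y = rng.normal(0.8, 1, n2)
        res = ranksum_compare({"x": list(x), "y": list(y)})
        expected = brute_force_mannwhitney_p(x, y)
        assert res.p_values.loc["x", "y"] == pytest.approx(expected, rel=1e-9)

    def test_shifted_cohorts_get_different_letters(self):
        rng = np.random.default_rng(7)
        fast = rng.normal(1.0, 0.2, 30).clip(0.1)
        slow = rng.normal(6.0, 1.0, 30).clip(0.1)
        res = ranksum_compare({"fast": list(fast), "slow": list(slow)})
        assert res.p_values.loc["fast", "slow"] < 0.05
        assert not (set(res.letters["fast"]) & set(res.letters["slow"]))

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="n < 3"):
            ranksum_compare({"a": [1, 2], "b": [1, 2, 3]})

    def test_all_identical_values_p_one(self):
        res = ranksum_compare({"a": [5, 5, 5], "b": [5, 5, 5]})
        assert res.p_values.loc["a", "b"] == 1.0


class TestLetterAssignment:
    @pytest.mark.parametrize("seed", range(8))
    def test_share_letter_iff_nonsignificant_three_groups(self, seed):
        """Over random 3-group p-matrices, two groups share a letter exactly
        when their pairwise p >= alpha."""
        rng = np.random.default_rng(seed)
        labels = ["g1", "g2", "g3"]
        p = pd.DataFrame(np.ones((3, 3)), index=labels, columns=labels)
        for i in range(3):
            for j in range(i + 1, 3):
                v = float(rng.uniform(0, 0.12))
                p.iloc[i, j] = p.iloc[j, i] = v
        letters = assign_letters(p, alpha=0.05)
        for i in range(3):
            for j in range(i + 1, 3):
                share = bool(set(letters[labels[i]]) & set(letters[labels[j]]))
                assert share == (p.iloc[i, j] >= 0.05), p.values


class TestTtest:
    def test_identical_groups(self):
        res = ttest_compare({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert res.p_values.loc["a", "b"] == pytest.approx(1.0)

    def test_three_sigma_shift_detected(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 50)
        y = rng.normal(3, 1, 50)
        res = ttest_compare({"x": list(x), "y": list(y)})
        assert res.p_values.loc["x", "y"] < 1e-3

    def test_zero_variance_paths(self):
        same = ttest_compare({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        assert same.p_values.loc["a", "b"] == 1.0
        diff = ttest_compare({"a": [2.0, 2.0], "b": [3.0, 3.0]})
        assert diff.p_values.loc["a", "b"] == 0.0

    def test_matched_simulated_zones_not_significant(self):
        """Cohorts with the same exchange physics but different geometry seeds
        should show no significant CI difference (the null expectation for
        connected vacuoles across root zones)."""
        from frapconn.connectivity import ci_from_series

        from conftest import simulate_experiment

        zones = {"MZ": [], "DZ": []}
        for seed in range(1, 7):
            for zone, offset in (("MZ", 0), ("DZ", 100)):
                exp = simulate_experiment(
                    "tubular", 4, seed=seed + offset, noise_model="poisson",
                    n_postbleach=10,
                )
                res = ci_from_series(exp.series, exp.rois)
                if res.qc_ok:
                    zones[zone].append(res.ci)
        res = ttest_compare(zones)
        assert res.p_values.loc["MZ", "DZ"] > 0.05


class TestReport:
    def _write_run(self, run_dir):
        rng = np.random.default_rng(0)
        rows = []
        for g, t_mu in (("mock", 1.0), ("treated", 3.0)):
            for i in range(12):
                t = float(rng.normal(t_mu, 0.2))
                rows.append(
                    {
                        "series_id": f"{g}_{i}",
                        "group": g,
                        "t_half_s": max(t, 0.05),
                        "mobile_fraction": 0.8,
                        "class": "fast" if t < 2 else "medium",
                    }
                )
        rows[0].update({"class": "no_recovery", "mobile_fraction": 0.1})
        pd.DataFrame(rows).to_csv(run_dir / "classes.csv", index=False)
        ci_rows = [
            {
                "series_id": f"z{z}_{i}",
                "group": z,
                "ci": float(np.clip(rng.normal(0.9, 0.05), 0, 1)),
                "qc_flag": "ok" if i else "drift_negative",
            }
            for z in ("MZ", "EZ", "DZ")
            for i in range(8)
        ]
        pd.DataFrame(ci_rows).to_csv(run_dir / "ci.csv", index=False)

    def test_report_bundle_and_determinism(self, tmp_path):
        from frapconn.report import report

        run = tmp_path / "run"
        run.mkdir()
        self._write_run(run)
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        stats1 = report(run, out1, make_plots=False)
        report(run, out2, make_plots=False)
        assert (out1 / "stats.json").read_bytes() == (out2 / "stats.json").read_bytes()
        assert (out1 / "class_percentages.csv").exists()
        # exclusion bookkeeping
        assert stats1["excluded"]["non_recovering_from_t_half"] == 1
        assert stats1["excluded"]["qc_flagged_ci"] == 3
        # percentages include non-recovering items
        assert stats1["class_percentages"]["mock"]["no_recovery"] > 0
        payload = json.loads((out1 / "stats.json").read_text())
        assert "t_half" in payload and "ci" in payload

    def test_missing_stage_named_in_error(self, tmp_path):
        from frapconn.report import report

        with pytest.raises(FileNotFoundError, match="classes.csv"):
            report(tmp_path, tmp_path / "out")

    def test_plots_written(self, tmp_path):
        from frapconn.report import report

        run = tmp_path / "run"
        run.mkdir()
        self._write_run(run)
        report(run, tmp_path / "out", make_plots=True)
        for name in ("class_distribution.png", "t_half_boxplot.png", "ci_strip.png"):
            assert (tmp_path / "out" / name).exists()
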