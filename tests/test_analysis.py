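"""Analysis pipeline: label statistics, DBSCAN extraction, convergence metrics."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from groupgame.analysis import (
    CategoryEntry,
    CategorySystem,
    adoption_frequency_correlation,
    choose_eps,
    classify_common_rare,
    convergence_report,
    critical_mass_rate,
    cumulative_successful_uses,
    dbscan,
    diversity,
    extract_category_system,
    jaccard_vocabulary,
    label_statistics,
    shared_label_fraction,
    zipf_fit,
)
from groupgame.logio import make_fixture
from groupgame.simulate import GameParams, TrialLog

from conftest import rec


# ---------------------------------------------------------------------------
# label statistics
# ---------------------------------------------------------------------------

class TestLabelStatistics:
    def test_exposure_trace_hand_example(self):
        # agent 0 introduces "fox", agent 1 adopts after hearing it, agent 2
        # introduces it independently: initial frequency 2, adopters 1
        stats = label_statistics(make_fixture("exposure_trace"))
        fox = stats.set_index("label").loc["fox"]
        assert fox["initial_frequency"] == 2
        assert fox["adopters"] == 1

    def test_single_successful_record(self):
        log = TrialLog(
            GameParams(n_agents=2, pairing_mode="fixed_partner"),
            [rec(1, 0, 1, (0, 500, 1000), 0, "orb", 0)],
        )
        stats = label_statistics(log)
        assert stats.iloc[0].to_dict() == {
            "label": "orb", "initial_frequency": 1, "adopters": 0, "successes": 1,
        }

    def test_empty_log(self):
        log = TrialLog(GameParams(n_agents=2, pairing_mode="fixed_partner"), [])
        assert len(label_statistics(log)) == 0

    def test_success_conservation(self, n8_log):
        stats = label_statistics(n8_log)
        assert stats["successes"].sum() == sum(r.success for r in n8_log.records)

    def test_confederate_speakers_excluded_on_request(self):
        log = make_fixture("confederate_mini")
        full = label_statistics(log).set_index("label")
        expt = label_statistics(log, exclude_confederate_speakers=True).set_index("label")
        assert full.loc["sumo", "successes"] > expt.loc["sumo", "successes"]


# ---------------------------------------------------------------------------
# eps selection and DBSCAN
# ---------------------------------------------------------------------------

def brute_force_dbscan(points, eps, min_pts):
    """Independent density-reachability oracle.

    Returns (core partition, noise set, border validity map): cores are
    grouped by connected components of the eps-graph restricted to cores;
    non-core points adjacent to a core are borders, the rest noise.
    """
    n = len(points)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    neigh = d <= eps
    core = neigh.sum(axis=1) >= min_pts  # self included
    # connected components among cores
    comp = [-1] * n
    c = 0
    for i in range(n):
        if not core[i] or comp[i] != -1:
            continue
        stack = [i]
        comp[i] = c
        while stack:
            u = stack.pop()
            for v in range(n):
                if core[v] and comp[v] == -1 and neigh[u][v]:
                    comp[v] = c
                    stack.append(v)
        c += 1
    border_options = {
        i: {comp[j] for j in range(n) if core[j] and neigh[i][j]}
        for i in range(n)
        if not core[i]
    }
    noise = {i for i, opts in border_options.items() if not opts}
    return core, comp, border_options, noise


class TestDBSCAN:
    def test_cluster_plus_noise_example(self):
        pts = np.array([[0.05, 0], [0, 0.05], [-0.05, 0], [0, -0.05], [0.02, 0.02],
                        [10.0, 10.0]])
        labels = dbscan(pts, eps=0.5, min_pts=3)
        assert (labels[:5] == labels[0]).all() and labels[0] != -1
        assert labels[5] == -1

    def test_empty_input(self):
        assert len(dbscan(np.empty((0, 2)), 0.5, 3)) == 0

    def test_identical_points_form_single_cluster(self):
        pts = np.zeros((5, 2))
        labels = dbscan(pts, eps=0.0, min_pts=3)
        assert set(labels) == {0}

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(7)
        for trial in range(25):
            n = int(rng.integers(5, 51))
            pts = rng.uniform(0, 1, size=(n, 2))
            eps = float(rng.uniform(0.05, 0.4))
            min_pts = int(rng.integers(1, 6))
            got = dbscan(pts, eps, min_pts)
            core, comp, border_options, noise = brute_force_dbscan(pts, eps, min_pts)
            # cores: same partition (cluster ids may be permuted)
            for i in range(n):
                for j in range(i + 1, n):
                    if core[i] and core[j]:
                        assert (comp[i] == comp[j]) == (got[i] == got[j])
                if core[i]:
                    assert got[i] != -1
            # borders must join a component of an adjacent core; noise is noise
            for i, opts in border_options.items():
                if i in noise:
                    assert got[i] == -1
                else:
                    core_comps = {
                        comp[j] for j in range(n) if core[j] and got[j] == got[i]
                    }
                    assert got[i] != -1 and core_comps and core_comps <= opts

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            dbscan(np.zeros((3, 2)), -1.0, 3)
        with pytest.raises(ValueError):
            dbscan(np.zeros((3, 2)), 0.5, 0)


class TestChooseEps:
    def test_knee_of_constructed_curve(self):
        # two dense clumps and sparse outliers give a k-distance curve with a
        # sharp elbow; the oracle recomputes the max-perpendicular-distance
        # point explicitly from the same sorted k-distances
        rng = np.random.default_rng(0)
        pts = np.vstack([
            rng.normal(0, 0.01, size=(20, 2)),
            rng.normal(5, 0.01, size=(20, 2)),
            rng.uniform(-20, 20, size=(6, 2)),
        ])
        k = 3
        got = choose_eps(pts, k)
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        kdist = np.sort(np.sort(d, axis=1)[:, k])
        x = np.arange(len(kdist), dtype=float)
        p0 = np.array([0.0, kdist[0]])
        p1 = np.array([x[-1], kdist[-1]])
        chord = p1 - p0
        perp = np.abs(
            (x - p0[0]) * chord[1] - (kdist - p0[1]) * chord[0]
        ) / np.hypot(*chord)
        assert got == pytest.approx(kdist[int(np.argmax(perp))])

    def test_degenerate_identical_points(self):
        with pytest.warns(UserWarning):
            assert choose_eps(np.zeros((6, 2)), 3) == 0.0

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            choose_eps(np.zeros((3, 2)), 3)

    def test_near_linear_curve_uses_quantile(self):
        # collinear points with slowly, linearly growing gaps produce an
        # (almost exactly) linear k-distance curve with no knee, so the
        # 90th-percentile fallback applies
        gaps = 1.0 + 0.001 * np.arange(19)
        pts = np.concatenate([[0.0], np.cumsum(gaps)])[:, None]
        got = choose_eps(pts, 1)
        d = np.abs(pts - pts.T)
        kdist = np.sort(np.sort(d, axis=1)[:, 1])
        assert got == pytest.approx(np.quantile(kdist, 0.9))


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

class TestExtraction:
    def test_dominant_labels_recovered(self):
        log = make_fixture("dominant4")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            system = extract_category_system(log)
        assert system.labels == {"alpha", "beta", "gamma", "delta"}

    def test_density_sums_to_success_count(self):
        log = make_fixture("dominant4")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            system = extract_category_system(log)
        stats = label_statistics(log).set_index("label")
        for lab, entry in system.entries.items():
            assert entry.density.sum() == stats.loc[lab, "successes"]

    def test_empty_log_rejected(self):
        log = TrialLog(GameParams(n_agents=2, pairing_mode="fixed_partner"), [])
        with pytest.raises(ValueError):
            extract_category_system(log)

    def test_region_tiebreak_goes_to_higher_success_label(self):
        d1 = np.zeros(50, dtype=int); d1[10] = 3
        d2 = np.zeros(50, dtype=int); d2[10] = 3; d2[11] = 1
        system = CategorySystem(
            trial_id="t",
            entries={
                "low": CategoryEntry("low", d1, ((10, 10),), 3),
                "high": CategoryEntry("high", d2, ((10, 11),), 4),
            },
            n_bins=50,
            n_slices=1500,
        )
        assert system.region_winners[10] == "high"
        assert system.region_winners[12] is None

    def test_fallback_on_few_labels(self, dyad_log):
        with warnings.catch_warnings(record=True):
            warnings.simplefilter("always")
            system = extract_category_system(dyad_log)
        assert 1 <= len(system.labels) <= 5


# ---------------------------------------------------------------------------
# convergence metrics
# ---------------------------------------------------------------------------

class TestJaccard:
    def test_identities(self):
        assert jaccard_vocabulary({"a", "b"}, {"a", "b"}) == 1.0
        assert jaccard_vocabulary({"a"}, {"b"}) == 0.0
        assert jaccard_vocabulary({"crab", "bunny", "sumo"}, {"crab", "fish"}) == 0.25

    def test_symmetry_and_bounds(self, rng):
        pool = list("abcdefghij")
        for _ in range(50):
            a = frozenset(rng.choice(pool, rng.integers(0, 8), replace=False))
            b = frozenset(rng.choice(pool, rng.integers(0, 8), replace=False))
            j1, j2 = jaccard_vocabulary(a, b), jaccard_vocabulary(b, a)
            if a or b:
                assert j1 == j2 and 0.0 <= j1 <= 1.0
                assert (j1 == 1.0) == (a == b)

    def test_both_empty_is_flagged_unity(self):
        with pytest.warns(UserWarning):
            assert jaccard_vocabulary(set(), set()) == 1.0


class TestConvergenceReport:
    def test_diversity_hand_example(self):
        log = TrialLog(GameParams(n_agents=4), [
            rec(1, 0, 1, (0, 500, 1000), 0, "a", 0),
            rec(1, 2, 3, (10, 510, 1010), 10, "c", 510),
            rec(2, 1, 0, (20, 520, 1020), 20, "b", 20),
            rec(2, 3, 2, (30, 530, 1030), 30, "c", 30),
        ])
        # agents 0,1 encounter {a,b}; agents 2,3 encounter {c}
        assert diversity(log) == pytest.approx(1.5)

    def test_matrix_shape_and_mean(self, small_ensemble):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = convergence_report(small_ensemble)
        n = len(small_ensemble)
        assert report.jaccard_matrix.shape == (n, n)
        off = [report.jaccard_matrix[i, j] for i in range(n) for j in range(i + 1, n)]
        assert report.mean_jaccard == pytest.approx(np.mean(off))
        assert len(off) == math.comb(n, 2)

    def test_identical_vocabularies_give_unity(self):
        log = make_fixture("dominant4")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = convergence_report([log, log])
        assert report.mean_jaccard == 1.0

    def test_requires_two_trials(self, small_ensemble):
        with pytest.raises(ValueError):
            convergence_report(small_ensemble[:1])


class TestSharedFraction:
    def test_hand_counts(self):
        assert shared_label_fraction([{"a", "b"}, {"b", "c"}, {"d"}]) == 0.25
        assert shared_label_fraction([{"a"}, {"a"}, {"a"}]) == 1.0
        assert shared_label_fraction([{"a"}, {"b"}]) == 0.0

    def test_requires_two_trials(self):
        with pytest.raises(ValueError):
            shared_label_fraction([{"a"}])


class TestCommonRare:
    def _frame(self, freqs):
        return pd.DataFrame({
            "label": [f"l{i}" for i in range(len(freqs))],
            "initial_frequency": freqs,
            "adopters": 0,
            "successes": 0,
        })

    def test_tukey_fence_hand_example(self):
        # sorted (1,1,1,1,2,50): Q3=1.75, IQR=0.75, fence=2.875 -> only 50
        classes = classify_common_rare([self._frame([50, 2, 1, 1, 1, 1])])
        assert classes["l0"] == "common"
        assert all(v == "rare" for k, v in classes.items() if k != "l0")

    def test_uniform_frequencies_all_rare(self):
        with pytest.warns(UserWarning):
            classes = classify_common_rare([self._frame([3, 3, 3, 3])])
        assert set(classes.values()) == {"rare"}

    def test_too_few_labels(self):
        with pytest.raises(ValueError):
            classify_common_rare([self._frame([1, 2, 3])])

    def test_pooling_across_trials(self):
        classes = classify_common_rare(
            [self._frame([10, 1, 1, 1]), self._frame([40, 1, 1, 1])]
        )
        assert classes["l0"] == "common"


class TestCriticalMassRate:
    def _log_with_introducers(self, label, k, n_agents=8):
        recs = [
            rec(i + 1, i, n_agents - 1 - i, (i * 10, i * 10 + 500, i * 10 + 1000),
                i * 10, label, i * 10)
            for i in range(k)
        ]
        return TrialLog(GameParams(n_agents=n_agents), recs)

    def test_hand_proportion(self):
        # threshold for N=8, theta=.25 is 2 introducers; 3 of 4 trials qualify
        ens = [self._log_with_introducers("orb", k) for k in (2, 3, 2, 1)]
        classes = {"orb": "common"}
        assert critical_mass_rate(ens, classes, "common") == 0.75

    def test_theta_zero_everything_qualifies(self):
        ens = [self._log_with_introducers("orb", 1)]
        assert critical_mass_rate(ens, {"orb": "rare"}, "rare", theta=0.0) == 1.0

    def test_empty_ensemble(self):
        with pytest.raises(ValueError):
            critical_mass_rate([], {}, "common")


class TestAdoptionCorrelation:
    def _linear_log(self, reverse=False):
        # labels a, b, c with initial frequencies 1, 2, 3 and adopter counts
        # 1, 2, 3 (or 3, 2, 1 when reversed): perfect (anti)correlation
        recs = []

        def add(sp, he, lab):
            t = 10 * len(recs)
            recs.append(rec(len(recs) + 1, sp, he, (t, t + 500, t + 998), t, lab, t))

        # introductions (all speakers unexposed to what they coin):
        add(0, 1, "a")  # a introduced by 0
        add(2, 0, "b")  # b introduced by 2
        add(1, 0, "b")  # b introduced by 1 (only ever heard a)
        add(3, 0, "c")  # c introduced by 3
        add(4, 0, "c")
        add(5, 0, "c")
        if not reverse:
            add(1, 2, "a")  # a adopted by 1
            add(0, 3, "b")  # b adopted by 0 and then 3
            add(3, 4, "b")
            add(0, 1, "c")  # c adopted by 0, 1, 2 along an exposure chain
            add(1, 2, "c")
            add(2, 5, "c")
        else:
            add(1, 2, "a")  # a adopted by 1, 2, 3
            add(2, 3, "a")
            add(3, 4, "a")
            add(0, 4, "b")  # b adopted by 0, 4
            add(4, 5, "b")
            add(0, 1, "c")  # c adopted by 0 only
        return TrialLog(GameParams(n_agents=6), recs)

    def test_perfect_positive(self):
        log = self._linear_log()
        assert adoption_frequency_correlation(log) == pytest.approx(1.0)

    def test_hand_ols_value(self):
        # independent arithmetic: r = cov(x, y) / (sd x * sd y) on the stats
        log = self._linear_log(reverse=True)
        stats = label_statistics(log)
        x = stats["initial_frequency"].to_numpy(float)
        y = stats["adopters"].to_numpy(float) / 6
        r_hand = (
            np.mean((x - x.mean()) * (y - y.mean()))
            / (x.std() * y.std())
        )
        assert adoption_frequency_correlation(log) == pytest.approx(r_hand)

    def test_zero_variance_rejected(self):
        recs = [
            rec(i + 1, i, 5 - i, (i * 10, i * 10 + 500, i * 10 + 1000),
                i * 10, lab, i * 10)
            for i, lab in enumerate(["a", "b", "c"])
        ]
        log = TrialLog(GameParams(n_agents=6), recs)
        with pytest.raises(ValueError):
            adoption_frequency_correlation(log)


class TestZipfFit:
    def test_hand_ols_on_three_points(self):
        # independent OLS arithmetic on log-log coordinates
        f = np.array([4.0, 2.0, 1.0])
        x = np.log(np.array([1.0, 2.0, 3.0]))
        y = np.log(f)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        b, _ = zipf_fit([4, 2, 1])
        assert b == pytest.approx(-slope)
        assert b == pytest.approx(1.2337, abs=1e-4)

    def test_exact_power_law(self):
        freqs = [1200.0 / r for r in range(1, 60)]
        b, intercept = zipf_fit(freqs)
        assert b == pytest.approx(1.0, abs=1e-12)
        assert intercept == pytest.approx(np.log(1200.0), abs=1e-10)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            zipf_fit([3, 1])
        with pytest.raises(ValueError):
            zipf_fit([3, 0, 1])
        with pytest.raises(ValueError):
            zipf_fit([2, 2, 2])


class TestCumulativeUses:
    def test_confederate_filtering(self):
        log = make_fixture("confederate_mini")
        sumo_all = cumulative_successful_uses(log, "sumo", experimental_only=False)
        sumo_expt = cumulative_successful_uses(log, "sumo")
        assert sumo_all[-1] > sumo_expt[-1]
        assert (np.diff(sumo_expt) >= 0).all()
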