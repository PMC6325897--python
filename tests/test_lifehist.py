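import math

import numpy as np
import pytest

from ma_mutkit.lifehist import (
    LifeHistoryRecord,
    LifeTable,
    broad_sense_h2,
    build_life_table,
    cv_m,
    delta_m,
    divergence_and_variance_tests,
    euler_lotka_residual,
    fecundity_for_r,
    group_by_line,
    solve_r,
    subline_r,
    treatment_interaction_test,
    variance_components,
    vm_ve,
)


def rec(line, sub, ages, sizes, longevity=30.0, survived=True, body=2.4,
        trt="Control", gens=100.0):
    return LifeHistoryRecord(line, sub, trt, gens, body, list(ages),
                             list(sizes), longevity, survived)


class TestLifeTable:
    def test_single_subline_single_clutch(self):
        t = build_life_table([rec("l", "s1", [8.0], [10.0])])
        assert t.ages.tolist() == [8.0]
        assert t.survivorship.tolist() == [1.0]
        assert t.fecundity.tolist() == [10.0]

    def test_death_before_age_halves_survivorship(self):
        t = build_life_table([rec("l", "s1", [8.0], [10.0]),
                              rec("l", "s2", [], [], longevity=5.0)])
        assert t.survivorship.tolist() == [0.5]

    def test_four_clutches_kept(self):
        t = build_life_table([rec("l", "s1", [5, 8, 11, 14],
                                  [6, 8, 9, 7])])
        assert len(t.ages) == 4
        assert t.fecundity.tolist() == [6, 8, 9, 7]

    def test_no_data_errors(self):
        with pytest.raises(ValueError):
            build_life_table([])
        with pytest.raises(ValueError):
            build_life_table([rec("l", "s1", [], [])])

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            LifeTable(np.array([1.0, 2.0]), np.array([0.5, 0.8]),
                      np.array([1.0, 1.0]))  # l_x increasing


class TestSolveR:
    def test_single_age_exact(self):
        t = LifeTable(np.array([1.0]), np.array([1.0]), np.array([math.e]))
        assert solve_r(t) == pytest.approx(1.0, abs=1e-10)

    def test_r_zero_when_R0_is_one(self):
        t = LifeTable(np.array([2.0, 3.0]), np.array([1.0, 0.5]),
                      np.array([0.6, 0.8]))  # sum l m = 1.0
        assert solve_r(t) == pytest.approx(0.0, abs=1e-10)

    def test_golden_ratio_schedule(self):
        t = LifeTable(np.array([1.0, 2.0]), np.array([1.0, 1.0]),
                      np.array([1.0, 1.0]))
        r = solve_r(t)
        assert r == pytest.approx(math.log((1 + math.sqrt(5)) / 2),
                                  abs=1e-10)

    def test_bisection_oracle_agreement(self):
        t = LifeTable(np.array([1.0, 2.0, 3.0, 4.0]),
                      np.array([1.0, 0.9, 0.8, 0.6]),
                      np.array([2.0, 5.0, 4.0, 3.0]))
        lo, hi = -5.0, 5.0
        for _ in range(200):  # plain bisection, independent of brentq
            mid = (lo + hi) / 2
            if euler_lotka_residual(mid, t) > 0:
                lo = mid
            else:
                hi = mid
        assert solve_r(t) == pytest.approx((lo + hi) / 2, abs=1e-10)
        assert abs(euler_lotka_residual(solve_r(t), t)) < 1e-10

    def test_no_growth_error(self):
        t = LifeTable(np.array([1.0]), np.array([1.0]), np.array([0.0]))
        with pytest.raises(ValueError):
            solve_r(t)

    def test_projection_agrees_with_euler_lotka(self):
        m = fecundity_for_r(1.3, [1.0, 2.0, 3.0, 4.0])
        t = LifeTable(np.array([1.0, 2.0, 3.0, 4.0]), np.ones(4),
                      np.full(4, m))
        r_el = solve_r(t)
        r_pr = solve_r(t, method="projection",
                       rng=np.random.default_rng(0), n_individuals=50_000)
        assert abs(r_pr - r_el) < 0.02

    def test_monotone_in_fecundity(self):
        base = LifeTable(np.array([1.0, 2.0]), np.array([1.0, 0.8]),
                         np.array([1.0, 1.0]))
        r0 = solve_r(base)
        for k in range(2):
            m = base.fecundity.copy()
            m[k] += 0.5
            bumped = LifeTable(base.ages, base.survivorship, m)
            assert solve_r(bumped) > r0


class TestDeltaM:
    def test_all_at_anchor_gives_zero(self):
        res = delta_m(np.array([2.0, 2.0, 2.0]), np.array([0.1, 0.1, 0.1]),
                      np.array([80, 100, 120.0]), 2.0, 0.05)
        assert res.slope == pytest.approx(0.0, abs=1e-15)
        assert res.delta_m_pct == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_two_lines(self):
        a = 2.0
        res = delta_m(np.array([a - 1, a - 2]), np.array([1.0, 1.0]),
                      np.array([100.0, 200.0]), a, 1.0)
        assert res.slope == pytest.approx(-0.01)
        assert res.delta_m_pct == pytest.approx(-1.0 / a * 100 * 0.01)
        assert res.delta_m_pct == pytest.approx(100 * -0.01 / a)

    def test_scale_invariance(self):
        vals = np.array([1.9, 1.7, 1.95])
        sds = np.array([0.1, 0.2, 0.15])
        g = np.array([80, 100, 120.0])
        r1 = delta_m(vals, sds, g, 2.0, 0.05)
        r2 = delta_m(2 * vals, 2 * sds, g, 4.0, 0.10)
        assert r2.delta_m_pct == pytest.approx(r1.delta_m_pct)

    def test_passes_exactly_through_anchor(self):
        res = delta_m(np.array([1.8, 1.6]), np.array([0.1, 0.3]),
                      np.array([90, 130.0]), 2.0, 0.05)
        predicted_at_zero = 2.0 + res.slope * 0.0
        assert predicted_at_zero == 2.0  # machine-exact

    def test_zero_sd_substituted(self):
        res = delta_m(np.array([1.8, 1.6, 1.7]),
                      np.array([0.1, 0.0, 0.2]),
                      np.array([90, 100, 130.0]), 2.0, 0.05)
        assert np.isfinite(res.delta_m_pct)


class TestVarianceComponents:
    def test_identical_values_cv_zero(self):
        by_line = {f"l{i}": np.full(5, 3.0) for i in range(4)}
        cv, dcv, _ = cv_m(by_line, 100.0)
        assert cv == 0.0 and dcv == 0.0

    def test_truncation_when_within_exceeds_among(self):
        rng = np.random.default_rng(5)
        # no true line effect: MS_among < MS_within happens often
        found = False
        for _ in range(50):
            by_line = {f"l{i}": rng.normal(0, 1, 4) for i in range(3)}
            vc = variance_components(by_line)
            if vc.ms_among < vc.ms_within:
                assert vc.v_line == 0.0
                found = True
                break
        assert found

    def test_known_components_recovered(self):
        rng = np.random.default_rng(6)
        v_l, v_e = 4.0, 1.0
        ests = []
        for _ in range(200):
            by_line = {}
            for i in range(10):
                b = rng.normal(0, math.sqrt(v_l))
                by_line[f"l{i}"] = 20.0 + b + rng.normal(0, math.sqrt(v_e), 5)
            cv, _, vc = cv_m(by_line, 100.0)
            ests.append(cv)
        mean = np.mean(ests)
        se = np.std(ests, ddof=1) / math.sqrt(len(ests))
        # CV_m = 100*sqrt(V_L)/mean = 100*2/20 = 10%
        assert abs(mean - 10.0) < 3 * se

    def test_vm_ve_algebra(self):
        # plant V_L = 2*t*V and MS_within = V -> ratio 1
        t_gen = 100.0
        by_line = {"a": np.array([0.0, 2.0]), "b": np.array([10.0, 12.0])}
        vc = variance_components(by_line)
        ratio, _ = vm_ve(by_line, vc.v_line / (2 * vc.ms_within),
                         divisor=2.0)
        assert ratio == pytest.approx(1.0)

    def test_vm_ve_zero_among(self):
        by_line = {"a": np.array([1.0, 2.0]), "b": np.array([1.0, 2.0])}
        ratio, vc = vm_ve(by_line, 100.0)
        assert vc.v_line == 0.0 and ratio == 0.0

    def test_single_line_errors(self):
        with pytest.raises(ValueError):
            variance_components({"a": np.array([1.0, 2.0])})


class TestHeritability:
    def test_no_within_variance_h2_one(self):
        by_line = {"a": np.array([1.0, 1.0]), "b": np.array([5.0, 5.0])}
        assert broad_sense_h2(by_line) == 1.0

    def test_no_among_variance_h2_zero(self):
        by_line = {"a": np.array([1.0, 3.0]), "b": np.array([1.0, 3.0])}
        assert broad_sense_h2(by_line) == 0.0

    def test_three_to_one_components(self):
        # the H2 ratio is biased downward in finite samples (Jensen), so
        # check the unbiased components at 2 SE and the ratio of component
        # means; also bound the per-replicate H2 mean loosely
        rng = np.random.default_rng(7)
        h2s, vls, vws = [], [], []
        for _ in range(200):
            by_line = {}
            for i in range(12):
                b = rng.normal(0, math.sqrt(3.0))
                by_line[f"l{i}"] = b + rng.normal(0, 1.0, 6)
            h2s.append(broad_sense_h2(by_line))
            vc = variance_components(by_line)
            vls.append(vc.v_line)
            vws.append(vc.ms_within)
        for est, truth in ((vls, 3.0), (vws, 1.0)):
            mean = np.mean(est)
            se = np.std(est, ddof=1) / math.sqrt(len(est))
            assert abs(mean - truth) < 2.5 * se
        assert np.mean(vls) / (np.mean(vls) + np.mean(vws)) == pytest.approx(
            0.75, abs=0.02)
        assert abs(np.mean(h2s) - 0.75) < 0.06


class TestTreatmentInteraction:
    def simulate(self, rng, slopes):
        vals, sds, gens, trts = [], [], [], []
        for trt, slope in slopes.items():
            for _ in range(8):
                g = rng.uniform(80, 130)
                vals.append(2.0 + slope * g + rng.normal(0, 0.05))
                sds.append(0.05)
                gens.append(g)
                trts.append(trt)
        return (np.array(vals), np.array(sds), np.array(gens),
                np.array(trts))

    def test_type_one_error_controlled(self):
        rng = np.random.default_rng(8)
        rejections = 0
        reps = 150
        for _ in range(reps):
            v, s, g, t = self.simulate(rng, {"A": -1e-4, "B": -1e-4})
            _, p = treatment_interaction_test(v, s, g, t, 2.0)
            rejections += p < 0.05
        assert rejections < reps * 0.05 + 2.5 * math.sqrt(
            reps * 0.05 * 0.95) + 1

    def test_power_for_divergent_slopes(self):
        rng = np.random.default_rng(9)
        hits = 0
        reps = 50
        for _ in range(reps):
            v, s, g, t = self.simulate(rng, {"A": -1e-3, "B": 1e-3})
            _, p = treatment_interaction_test(v, s, g, t, 2.0)
            hits += p < 0.05
        assert hits / reps > 0.8

    def test_single_treatment_errors(self):
        rng = np.random.default_rng(10)
        v, s, g, t = self.simulate(rng, {"A": 0.0})
        with pytest.raises(ValueError):
            treatment_interaction_test(v, s, g, t, 2.0)


class TestDivergenceTests:
    def test_all_equal_nonsignificant(self):
        rng = np.random.default_rng(11)
        by_line = {f"l{i}": rng.normal(0, 1, 5) for i in range(8)}
        trt = {lid: ("A" if i < 4 else "B")
               for i, lid in enumerate(by_line)}
        res = divergence_and_variance_tests(by_line, trt)
        assert all(p > 0.001 for p in res.anova_p.values())

    def test_shifted_line_flagged(self):
        rng = np.random.default_rng(12)
        by_line = {f"l{i}": rng.normal(0, 1, 6) for i in range(5)}
        by_line["l0"] = by_line["l0"] + 10.0
        trt = {lid: "A" for lid in by_line}
        res = divergence_and_variance_tests(by_line, trt)
        assert res.anova_p["A"] < 1e-6
        assert "l0" in res.tukey_flagged["A"]

    def test_bartlett_type_one_error(self):
        rng = np.random.default_rng(13)
        rejections = 0
        reps = 100
        for _ in range(reps):
            by_line = {f"l{i}": rng.normal(0, 1, 4) for i in range(12)}
            trt = {f"l{i}": "ABC"[i % 3] for i in range(12)}
            res = divergence_and_variance_tests(by_line, trt)
            rejections += res.bartlett_p < 0.05
        assert rejections < reps * 0.05 + 2.5 * math.sqrt(
            reps * 0.05 * 0.95) + 1


class TestRecordHelpers:
    def test_dead_sublines_excluded_from_r(self):
        recs = [rec("l", "s1", [1, 2], [3.0, 3.0]),
                rec("l", "s2", [], [], survived=False)]
        rs = subline_r(recs)
        assert list(rs) == ["s1"]

    def test_group_by_line_body_size(self):
        recs = [rec("l1", "a", [1], [2.0], body=2.3),
                rec("l1", "b", [1], [2.0], body=2.5),
                rec("l2", "c", [1], [2.0], body=2.1)]
        g = group_by_line(recs, "body_size")
        assert g["l1"].tolist() == [2.3, 2.5]
        assert g["l2"].tolist() == [2.1]
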