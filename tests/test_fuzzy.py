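import numpy as np
import pytest

from smartbed.fuzzy import (
    CONSEQUENT_NAMES,
    OUTPUT_UNIVERSE,
    FuzzyEngine,
    FuzzyRule,
    MembershipFunction,
    aggregate,
    build_rule_base,
    default_variables,
    defuzzify_cog,
    fire_rule,
    membership_degree,
)
from smartbed.preprocess import HoPBLevels, N_HOPB, level_to_phase


# --- independent brute-force oracle (own membership math, all-rule loop) ----

def tri(a, b, c, x):
    x = np.asarray(x, dtype=float)
    up = (x - a) / (b - a) if b > a else np.ones_like(x)
    down = (c - x) / (c - b) if c > b else np.ones_like(x)
    return np.clip(np.minimum(up, down), 0.0, 1.0)


TIME_TRI = {f"Time{k}": (k - 2, k, k + 2) for k in range(1, 9)}
PHASE_TRI = {f"Phase {k}": (c - 4, c, c + 4)
             for k, c in enumerate([2.5, 6.5, 10.5, 14.5, 18.5], start=1)}
OUT_TRI = {"Large Descent": (-2.0, -1.5, -1.0), "Slight Descent": (-1.2, -0.6, 0.0),
           "Not Moving": (-0.6, 0.0, 0.6), "Slight Rise": (0.0, 0.6, 1.2),
           "Large Rise": (1.0, 1.5, 2.0)}


def oracle_slat_setting(rules, hopb, posture, t, q, step=0.0005):
    """All-8000-rule dense-grid Mamdani evaluation, independent of the
    engine: min firing, min truncation, max aggregation, trapezoid COG."""
    y = np.arange(-2.0, 2.0 + step / 2, step)
    mu = np.zeros_like(y)
    for rule in rules:
        s_sel = 1.0 if (rule.hopb == hopb and rule.posture == posture) else 0.0
        s = min(s_sel,
                float(tri(*TIME_TRI[rule.time_set], np.clip(t, 1, 8))),
                float(tri(*PHASE_TRI[rule.phase_set], np.clip(q, 0, 20))))
        if s > 0:
            mu = np.maximum(mu, np.minimum(s, tri(*OUT_TRI[rule.consequent], y)))
    area = np.trapezoid(mu, y)
    return 0.0 if area <= 0 else float(np.trapezoid(y * mu, y) / area)


# --- membership functions ---------------------------------------------------

class TestMembership:
    def test_peak_foot_and_interpolation(self):
        mf = MembershipFunction("t", 0.0, 4.0, 8.0, (0.0, 8.0))
        assert membership_degree(mf, 4.0) == 1.0
        assert membership_degree(mf, 0.0) == 0.0
        assert membership_degree(mf, 2.0) == pytest.approx(0.5)

    def test_out_of_universe_clamps(self):
        mf = MembershipFunction("t", 1.0, 2.0, 3.0, (1.0, 8.0))
        assert membership_degree(mf, -5.0) == membership_degree(mf, 1.0)
        assert membership_degree(mf, 99.0) == membership_degree(mf, 8.0)

    def test_invalid_breakpoints_rejected(self):
        with pytest.raises(ValueError):
            MembershipFunction("bad", 3.0, 2.0, 1.0, (0.0, 8.0))

    def test_degrees_bounded(self, rng):
        variables = default_variables()
        for var in variables.values():
            xs = rng.uniform(var.universe[0] - 2, var.universe[1] + 2, 200)
            for mf in var.sets:
                mu = mf(xs)
                assert np.all((mu >= 0) & (mu <= 1))

    def test_input_sets_cover_their_universe(self):
        """Every crisp input value must belong to at least one set, so the
        full Cartesian rule base always fires."""
        variables = default_variables()
        for name in ("TimeLevel", "UlcerLevel"):
            var = variables[name]
            xs = np.linspace(*var.universe, 501)
            cover = np.max([mf(xs) for mf in var.sets], axis=0)
            assert np.all(cover > 0)


# --- rule firing and aggregation -------------------------------------------

class TestFireRule:
    def test_min_semantics(self, engine):
        rule = FuzzyRule(3, 0, "Time2", "Phase 2", "Not Moving")
        # time 3 -> Time2 degree 0.5; level 8.5 -> Phase 2 degree 0.5
        inputs = {"HoPB": 3, "Decubitus": 0, "TimeLevel": 3.0, "UlcerLevel": 8.5}
        assert fire_rule(rule, inputs, engine.variables) == pytest.approx(0.5)

    def test_zero_degree_annihilates(self, engine):
        rule = FuzzyRule(3, 0, "Time1", "Phase 1", "Not Moving")
        inputs = {"HoPB": 3, "Decubitus": 0, "TimeLevel": 8.0, "UlcerLevel": 2.5}
        assert fire_rule(rule, inputs, engine.variables) == 0.0

    def test_all_peaks_fire_fully(self, engine):
        rule = FuzzyRule(3, 0, "Time2", "Phase 2", "Not Moving")
        inputs = {"HoPB": 3, "Decubitus": 0, "TimeLevel": 2.0, "UlcerLevel": 6.5}
        assert fire_rule(rule, inputs, engine.variables) == 1.0

    def test_crisp_selector_mismatch(self, engine):
        rule = FuzzyRule(3, 0, "Time2", "Phase 2", "Not Moving")
        inputs = {"HoPB": 4, "Decubitus": 0, "TimeLevel": 2.0, "UlcerLevel": 6.5}
        assert fire_rule(rule, inputs, engine.variables) == 0.0

    def test_missing_input_rejected(self, engine):
        rule = FuzzyRule(3, 0, "Time2", "Phase 2", "Not Moving")
        with pytest.raises(KeyError):
            fire_rule(rule, {"HoPB": 3, "TimeLevel": 2.0}, engine.variables)


class TestAggregate:
    def test_single_full_strength_rule_is_its_consequent(self):
        nm = default_variables()["HoPBControl"]["Not Moving"]
        y = np.linspace(-2, 2, 401)
        np.testing.assert_allclose(aggregate([(1.0, nm)])(y), nm(y))

    def test_truncation_clips_at_strength(self):
        nm = default_variables()["HoPBControl"]["Not Moving"]
        y = np.linspace(-2, 2, 401)
        mu = aggregate([(0.4, nm)])(y)
        np.testing.assert_allclose(mu, np.minimum(0.4, nm(y)))

    def test_empty_aggregation_is_zero(self):
        y = np.linspace(-2, 2, 11)
        assert aggregate([])(y).sum() == 0.0

    def test_two_overlapping_sets_match_pointwise_max_oracle(self):
        out = default_variables()["HoPBControl"]
        fired = [(0.7, out["Slight Descent"]), (0.5, out["Not Moving"])]
        y = np.linspace(-2, 2, 2001)
        expected = np.maximum(np.minimum(0.7, tri(-1.2, -0.6, 0.0, y)),
                              np.minimum(0.5, tri(-0.6, 0.0, 0.6, y)))
        np.testing.assert_allclose(aggregate(fired)(y), expected, atol=1e-12)


class TestDefuzzify:
    def test_symmetric_set_centres_at_zero(self):
        nm = default_variables()["HoPBControl"]["Not Moving"]
        assert defuzzify_cog(aggregate([(0.8, nm)])) == pytest.approx(0.0, abs=1e-9)

    def test_untruncated_triangle_matches_analytic_centroid(self):
        mf = MembershipFunction("t", -1.0, 0.0, 1.8, OUTPUT_UNIVERSE)
        cog = defuzzify_cog(aggregate([(1.0, mf)]))
        assert cog == pytest.approx((-1.0 + 0.0 + 1.8) / 3, abs=2e-6)

    def test_frozen_mixed_case(self):
        """Slight Descent truncated at 0.5 plus full Not Moving: the centre
        of gravity is exactly -1/4 (closed-form piecewise integration)."""
        out = default_variables()["HoPBControl"]
        fired = [(0.5, out["Slight Descent"]), (1.0, out["Not Moving"])]
        assert defuzzify_cog(aggregate(fired)) == pytest.approx(-0.25, abs=1e-6)

    def test_matches_refined_grid(self, rng):
        out = default_variables()["HoPBControl"]
        for _ in range(40):
            k = rng.integers(1, 5)
            picks = rng.choice(5, size=k, replace=False)
            fired = [(float(rng.uniform(0.05, 1.0)), out.sets[int(s)])
                     for s in picks]
            mu = aggregate(fired)
            coarse = defuzzify_cog(mu)
            fine = defuzzify_cog(mu, resolution=0.00005)
            assert coarse == pytest.approx(fine, abs=1e-6)

    def test_zero_area_fails_safe_to_not_moving(self):
        assert defuzzify_cog(aggregate([])) == 0.0

    def test_nonfinite_membership_rejected(self):
        with pytest.raises(FloatingPointError):
            defuzzify_cog(lambda y: np.full_like(y, np.nan))


# --- rule base ---------------------------------------------------------------

class TestRuleBase:
    def test_full_cartesian_count(self, engine):
        assert len(engine.rules) == 8000

    def test_canonical_rule_examples(self, engine):
        """The canonical low-phase/high-phase pattern for slat 1 in supine at
        the first time level: phases 1-3 hold still, phases 4-5 descend."""
        by_key = {(r.hopb, r.posture, r.time_set, r.phase_set): r.consequent
                  for r in engine.rules}
        for q in (1, 2, 3):
            assert by_key[(1, 0, "Time1", f"Phase {q}")] == "Not Moving"
        for q in (4, 5):
            assert by_key[(1, 0, "Time1", f"Phase {q}")] == "Slight Descent"

    def test_duplicate_antecedents_rejected(self):
        rules = build_rule_base()
        with pytest.raises(ValueError, match="duplicate"):
            FuzzyEngine(rules + [FuzzyRule(1, 0, "Time1", "Phase 1",
                                           "Large Rise")])

    def test_rule_line_roundtrip(self, engine):
        for rule in engine.rules[::997]:
            assert FuzzyRule.from_line(rule.to_line()) == rule

    def test_completeness_every_input_fires(self, engine, rng):
        for _ in range(50):
            hopb = int(rng.integers(1, 21))
            posture = int(rng.integers(0, 10))
            t = float(rng.uniform(1, 8))
            q = float(rng.uniform(0, 20))
            inputs = {"HoPB": hopb, "Decubitus": posture,
                      "TimeLevel": t, "UlcerLevel": q}
            fired = sum(
                fire_rule(r, inputs, engine.variables) > 0
                for r in engine._index[(hopb, posture)])
            assert fired >= 1


# --- inference ---------------------------------------------------------------

def make_levels(level, time_level, slat=9):
    levels = np.zeros(N_HOPB, dtype=int)
    times = np.zeros(N_HOPB, dtype=int)
    heats = np.zeros(N_HOPB)
    levels[slat - 1] = level
    heats[slat - 1] = float(level)
    times[slat - 1] = time_level
    return HoPBLevels(heat=heats, level=levels,
                      phase=level_to_phase(levels), time_level=times)


class TestInfer:
    def test_no_contact_slats_hold_still(self, engine):
        levels = make_levels(0, 0)
        out = engine.infer(levels, 0)
        np.testing.assert_array_equal(out.settings, 0.0)

    def test_saturated_phase5_descends(self, engine):
        out = engine.infer(make_levels(20, 8), 0)
        assert out.settings[8] < 0

    def test_setting_monotone_nonincreasing_in_phase(self, engine):
        for t in (1, 4, 8):
            settings = [engine.infer_slat(9, 0, t, q)
                        for q in (2.5, 6.5, 10.5, 14.5, 18.5)]
            assert np.all(np.diff(settings) <= 1e-12)

    def test_output_within_support(self, engine, rng):
        for _ in range(20):
            s = engine.infer_slat(int(rng.integers(1, 21)), int(rng.integers(0, 10)),
                                  float(rng.uniform(1, 8)), float(rng.uniform(1, 20)))
            assert OUTPUT_UNIVERSE[0] <= s <= OUTPUT_UNIVERSE[1]

    def test_scaling_invariance_symmetric_single_rule(self, engine):
        """Truncation height cancels in the COG of one symmetric consequent."""
        out = engine.variables["HoPBControl"]
        for name in CONSEQUENT_NAMES:
            mf = out[name]
            refs = [defuzzify_cog(aggregate([(lam, mf)]))
                    for lam in (0.2, 0.5, 1.0)]
            assert max(refs) - min(refs) < 1e-9

    def test_matches_brute_force_oracle(self, engine, rng):
        for _ in range(20):
            hopb = int(rng.integers(1, 21))
            posture = int(rng.integers(0, 10))
            t = float(rng.uniform(1, 8))
            q = float(rng.uniform(0.5, 20))
            mine = engine.infer_slat(hopb, posture, t, q)
            ref = oracle_slat_setting(engine.rules, hopb, posture, t, q)
            assert mine == pytest.approx(ref, abs=1e-6)

    def test_invalid_posture_rejected(self, engine):
        with pytest.raises(ValueError):
            engine.infer(make_levels(5, 2), 12)


class TestPurge:
    def test_full_coverage_keeps_everything(self, engine):
        calibration = [(h, p, float(t), c)
                       for h in range(1, 21) for p in range(10)
                       for t in range(1, 9)
                       for c in (2.5, 6.5, 10.5, 14.5, 18.5)]
        kept = engine.purge_rules(calibration, epsilon=0.0)
        assert len(kept) == 8000

    def test_supine_only_calibration_drops_other_postures(self, engine):
        calibration = [(h, 0, float(t), 10.5)
                       for h in range(1, 21) for t in range(1, 9)]
        kept = engine.purge_rules(calibration, epsilon=0.0)
        assert all(r.posture == 0 for r in kept)
        assert len(kept) < 8000

    def test_purged_engine_reproduces_calibration_outputs(self, engine):
        calibration = [(9, 0, 4.0, 13.0), (10, 0, 7.0, 18.0), (5, 0, 2.0, 3.0)]
        kept = engine.purge_rules(calibration, epsilon=0.0)
        purged = FuzzyEngine(kept, engine.variables)
        for hopb, posture, t, q in calibration:
            assert purged.infer_slat(hopb, posture, t, q) == pytest.approx(
                engine.infer_slat(hopb, posture, t, q), abs=1e-9)

    def test_negative_epsilon_rejected(self, engine):
        with pytest.raises(ValueError):
            engine.purge_rules([], epsilon=-0.1)
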