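"""Membership thresholding, discard flag, metal assignment, shape labels."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from dynica import (
    ExperimentDesign,
    ThresholdConfig,
    assign_primary_metal,
    classify_shape,
    compute_threshold,
    dagostino_k2,
    flag_single_promoter,
    summarize_category_shift,
)


def brute_force_members(weights: pd.Series, cutoff: float = 800.0,
                        positive_only: bool = True):
    """Independent oracle: scan all prefix removals in descending |weight|
    order and take the shortest prefix whose remainder passes the cutoff,
    with scipy's omnibus normality statistic."""
    w = pd.Series(weights).astype(float)
    order = w.abs().sort_values(ascending=False, kind="stable").index
    values = w.loc[order].to_numpy()
    for i in range(len(values) - 19):
        stat, _ = scipy.stats.normaltest(values[i:])
        if stat < cutoff:
            removed = order[:i]
            if positive_only:
                return {p for p in removed if w.loc[p] > 0}
            return set(removed)
    raise AssertionError("oracle never dropped below cutoff")


class TestDagostinoK2:
    def test_matches_scipy_omnibus_statistic(self, rng):
        x = rng.normal(size=1000)
        stat, _ = scipy.stats.normaltest(x)
        assert dagostino_k2(x) == pytest.approx(stat, abs=1e-8)

    @pytest.mark.parametrize("dist", ["normal", "uniform", "lognormal",
                                      "student_t"])
    def test_matches_scipy_across_distributions(self, rng, dist):
        draw = {
            "normal": lambda: rng.normal(size=500),
            "uniform": lambda: rng.uniform(size=500),
            "lognormal": lambda: rng.lognormal(size=500),
            "student_t": lambda: rng.standard_t(5, size=500),
        }[dist]
        x = draw()
        stat, _ = scipy.stats.normaltest(x)
        assert dagostino_k2(x) == pytest.approx(stat, rel=1e-10)

    def test_planted_outliers_blow_past_cutoff(self, rng):
        x = np.concatenate([rng.normal(0, 0.01, size=1800), np.ones(5)])
        assert dagostino_k2(x) > 800

    def test_too_few_values(self):
        with pytest.raises(ValueError, match="20"):
            dagostino_k2(np.arange(10))

    def test_constant_input(self):
        with pytest.raises(ValueError, match="constant"):
            dagostino_k2(np.full(50, 2.0))


class TestComputeThreshold:
    def test_near_normal_column_has_empty_membership(self, rng):
        w = pd.Series(rng.normal(0, 0.01, size=1805),
                      index=[f"p{i}" for i in range(1805)])
        threshold, members = compute_threshold(w)
        assert threshold == math.inf
        assert members == set()

    def test_planted_positive_outliers_recovered_exactly(self, rng):
        w = np.concatenate([rng.normal(0, 0.01, size=1800), np.ones(5)])
        ids = [f"p{i}" for i in range(1805)]
        s = pd.Series(w, index=ids)
        threshold, members = compute_threshold(s)
        assert members == {f"p{i}" for i in range(1800, 1805)}
        assert members == brute_force_members(s)
        assert 0.01 < threshold <= 1.1

    def test_negative_outliers_removed_but_not_members(self, rng):
        w = np.concatenate([rng.normal(0, 0.01, size=1800), -np.ones(5)])
        s = pd.Series(w, index=[f"p{i}" for i in range(1805)])
        threshold, members = compute_threshold(s)
        assert members == set()
        assert math.isfinite(threshold)

    def test_membership_invariant_to_positive_rescaling(self, rng):
        w = np.concatenate([rng.normal(0, 0.01, size=500),
                            np.full(4, 0.5)])
        s = pd.Series(w, index=[f"p{i}" for i in range(504)])
        t1, m1 = compute_threshold(s)
        t2, m2 = compute_threshold(s * 37.0)
        assert m1 == m2
        if math.isfinite(t1):
            assert t2 == pytest.approx(37.0 * t1)

    @pytest.mark.parametrize("n_outliers", [0, 1, 3, 7, 10])
    def test_agrees_with_prefix_scan_oracle(self, rng, n_outliers):
        bulk = rng.normal(0, 0.02, size=1805 - n_outliers)
        out = rng.uniform(0.5, 1.5, size=n_outliers) * rng.choice(
            [-1, 1], size=n_outliers
        )
        s = pd.Series(np.concatenate([bulk, out]),
                      index=[f"p{i}" for i in range(1805)])
        _, members = compute_threshold(s)
        assert members == brute_force_members(s)

    def test_degenerate_component_raises(self, rng):
        # heavy-tailed everywhere: K^2 never drops before 20 values remain
        w = pd.Series(np.concatenate([rng.standard_cauchy(30) * 100,
                                      rng.normal(size=5)]))
        with pytest.raises(ValueError, match="degenerate"):
            compute_threshold(w, ThresholdConfig(k2_cutoff=1e-6))


class TestSinglePromoterFlag:
    def test_singleton_membership_flagged(self, rng):
        w = pd.Series(rng.normal(0, 0.01, size=100))
        assert flag_single_promoter(w, {"p1"}) is True

    def test_five_equal_members_not_flagged(self, rng):
        w = pd.Series(np.concatenate([rng.normal(0, 0.01, size=95),
                                      np.ones(5)]))
        members = {95, 96, 97, 98, 99}
        assert flag_single_promoter(w, members) is False

    def test_one_hot_vector_flagged(self):
        w = pd.Series(np.zeros(50))
        w.iloc[3] = 1.0
        assert flag_single_promoter(w, {3, 7}) is True


class TestPrimaryMetal:
    def test_activity_only_in_zinc_window(self, design6):
        a = np.zeros(36)
        a[0:6] = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        assert assign_primary_metal(a, design6) == "zinc"

    def test_highest_aggregate_wins(self, design6):
        a = np.zeros(36)
        a[0:6] = 3.0 / 6  # zinc sums to 3.0
        a[6:12] = 2.9 / 6  # copper sums to 2.9
        assert assign_primary_metal(a, design6) == "zinc"

    def test_tie_breaks_to_earlier_metal(self, design6):
        a = np.zeros(36)
        a[6:12] = 1.0  # copper
        a[12:18] = 1.0  # cadmium, exact tie
        assert assign_primary_metal(a, design6) == "copper"

    def test_length_mismatch_rejected(self, design6):
        with pytest.raises(ValueError):
            assign_primary_metal(np.zeros(35), design6)


class TestClassifyShape:
    @pytest.mark.parametrize(
        "window,cm,hp,label",
        [
            ((0.1, 0.2, 0.3, 0.4, 0.5, 0.6), 9.1 / 2.1, 6, "Steady"),
            ((1.0, 0.5, 0.2, 0.1, 0.0, 0.0), 3.0 / 1.8, 1, "Fast"),
            ((0.0, 0.2, 0.5, 1.0, 0.5, 0.2), 4.0, 4, "Intermediate"),
            ((0.0, 0.0, 0.0, 0.0, 0.0, 1.0), 6.0, 6, "Other"),
        ],
    )
    def test_hand_computed_examples(self, window, cm, hp, label):
        got_cm, got_hp, got_label = classify_shape(window)
        assert got_cm == pytest.approx(cm)
        assert got_hp == hp
        assert got_label == label

    def test_all_nonpositive_activity_is_other_with_missing_cm(self):
        cm, hp, label = classify_shape([-1.0, -0.5, 0.0, -0.2, -0.1, -0.3])
        assert cm is None
        assert label == "Other"

    def test_negative_values_do_not_shift_center_of_mass(self):
        base = [0.0, 0.0, 1.0, 0.0, 0.0, 0.0]
        with_repression = [-5.0, 0.0, 1.0, 0.0, 0.0, -5.0]
        assert classify_shape(base)[0] == classify_shape(with_repression)[0]

    @given(st.lists(st.floats(min_value=-1e6, max_value=1e6,
                              allow_nan=False, allow_infinity=False),
                    min_size=6, max_size=6))
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_every_finite_window_gets_exactly_one_label(self, window):
        cm, hp, label = classify_shape(window)
        assert label in {"Fast", "Intermediate", "Steady", "Other"}
        assert 1 <= hp <= 6
        if cm is not None:
            assert 1.0 <= cm <= 6.0
            # the precedence chain admits exactly one label
            rules = [
                ("Fast", cm <= 4 and hp <= 3),
                ("Intermediate", cm <= 4 and hp <= 4),
                ("Steady", cm <= 5 and hp >= 4),
            ]
            expected = next((name for name, hit in rules if hit), "Other")
            assert label == expected

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            classify_shape([1.0, 2.0, 3.0])


class TestShapeRecoveryThroughPipeline:
    def test_planted_shapes_get_matching_labels_across_seeds(self):
        """Fast/intermediate/steady planted modules keep their labels after
        the full raw -> preprocess -> robust ICA -> classify chain at a
        member-weight to activity-noise ratio of 5."""
        from dynica import (
            IcaConfig, SyntheticConfig, generate_raw_fluorescence,
            generate_truth, preprocess, robust_ica,
        )

        expected = {"fast": "Fast", "intermediate": "Intermediate",
                    "steady": "Steady"}
        hits = trials = 0
        for seed in range(10):
            cfg = SyntheticConfig(
                n_promoters=300, n_components=3, weight_sparsity=0.05,
                noise_sd=0.2, spike_prob=0.0, seed=seed,
                shape_assignment={0: ("zinc", "fast"),
                                  1: ("copper", "intermediate"),
                                  2: ("cadmium", "steady")},
            )
            design = ExperimentDesign(metals=cfg.metals)
            truth = generate_truth(cfg, design)
            series, control = generate_raw_fluorescence(truth, design, cfg)
            X = preprocess(series, control, design)
            dec = robust_ica(X, IcaConfig.fast(base_seed=seed))
            Mt = truth.M_true.loc[X.index].to_numpy()
            for j, comp in enumerate(truth.A_true.index):
                rs = [abs(np.corrcoef(dec.M.iloc[:, i], Mt[:, j])[0, 1])
                      for i in range(dec.k_robust)]
                if not rs or max(rs) < 0.8:
                    continue
                i = int(np.argmax(rs))
                metal = truth.metal_assignment[comp]
                profile = dec.A.iloc[i][
                    [f"{metal}:{t}" for t in range(1, 7)]
                ].to_numpy(dtype=float)
                _, _, label = classify_shape(profile)
                trials += 1
                hits += label == expected[truth.shape_labels[comp]]
        assert trials >= 25
        assert hits / trials >= 0.9


class TestCategoryShift:
    def test_all_stress_members(self):
        table = summarize_category_shift(
            {"a", "b"}, set(), {"a": "stress/damage", "b": "stress/damage"}
        )
        row = table[(table.phase == "induction")
                    & (table.category == "stress/damage")].iloc[0]
        assert row["count"] == 2
        assert row["fraction"] == pytest.approx(1.0)

    def test_nine_stress_of_twenty_is_45_percent(self):
        ann = {f"s{i}": "stress/damage" for i in range(9)}
        ann.update({f"o{i}": "other" for i in range(11)})
        members = set(ann)
        table = summarize_category_shift(members, set(), ann)
        row = table[(table.phase == "induction")
                    & (table.category == "stress/damage")].iloc[0]
        assert row["fraction"] == pytest.approx(0.45)

    def test_empty_member_sets_have_missing_fractions(self):
        table = summarize_category_shift(set(), set(), {})
        assert (table["count"] == 0).all()
        assert table["fraction"].isna().all()

    def test_unannotated_members_count_as_other(self):
        table = summarize_category_shift({"x"}, set(), {})
        row = table[(table.phase == "induction")
                    & (table.category == "other")].iloc[0]
        assert row["count"] == 1
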