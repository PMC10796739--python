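"""Sample masks, subject descriptors, elastic-net models, group statistics."""

import numpy as np
import pandas as pd
import pytest

from gdmwear.downstream import (
    classify_groups,
    gdm_sample_mask,
    group_statistics,
    pooled_cohens_d,
    regress_fma,
    subject_features,
)
from gdmwear.preprocess import KinematicsPair
from gdmwear.synthcohort import (
    SubjectSpec,
    TaskScript,
    TaskSegment,
    simulate_session,
)


class TestGdmSampleMask:
    def test_all_positive_windows_cover_everything(self):
        mask = gdm_sample_mask(100, np.array([0, 22, 44]), 50, np.ones(3, bool))
        assert mask[:94].all()
        assert not mask[94:].any()  # never covered

    def test_no_windows_all_false(self):
        mask = gdm_sample_mask(50, np.zeros(0, int), 10, np.zeros(0, bool))
        assert not mask.any()

    def test_majority_vote_matches_brute_force(self, rng):
        """Per-sample majority over covering windows equals a direct count."""
        n, win, hop = 300, 75, 22
        starts = np.arange(0, n - win + 1, hop)
        for _ in range(10):
            pred = rng.random(len(starts)) < 0.5
            mask = gdm_sample_mask(n, starts, win, pred)
            for i in range(0, n, 13):
                covering = [k for k, s in enumerate(starts) if s <= i < s + win]
                votes = sum(pred[k] for k in covering)
                expected = 2 * votes > len(covering)
                assert mask[i] == expected

    def test_any_rule_is_more_permissive(self, rng):
        n, win = 200, 75
        starts = np.arange(0, n - win + 1, 22)
        pred = rng.random(len(starts)) < 0.3
        majority = gdm_sample_mask(n, starts, win, pred, rule="majority")
        any_rule = gdm_sample_mask(n, starts, win, pred, rule="any")
        assert (any_rule | majority).sum() == any_rule.sum()

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            gdm_sample_mask(10, np.zeros(1, int), 5, np.ones(1, bool), rule="median")


def _kin(rng, n=400):
    return KinematicsPair(acc=rng.normal(size=(n, 3)), vel=rng.normal(size=(n, 3)))


class TestSubjectFeatures:
    def test_all_true_mask_equals_entire_recording(self, rng):
        kin = {"left": _kin(rng), "right": _kin(rng)}
        masks = {s: np.ones(400, dtype=bool) for s in kin}
        assert subject_features(kin, masks) == subject_features(kin, None)

    def test_missing_side_named_in_error(self, rng):
        with pytest.raises(ValueError, match="right"):
            subject_features({"left": _kin(rng)}, None)

    def test_too_few_masked_samples_rejected(self, rng):
        kin = {"left": _kin(rng), "right": _kin(rng)}
        masks = {s: np.zeros(400, dtype=bool) for s in kin}
        masks["left"][:4] = True
        with pytest.raises(ValueError, match="masked samples"):
            subject_features(kin, masks)

    def test_impaired_twin_has_more_acc_crossings(self):
        """Toggling impairment on an otherwise identical subject raises the
        zero-crossing count of the GDM periods."""
        from gdmwear.preprocess import preprocess
        from gdmwear.features import crossing_segments, crossing_stats

        script = TaskScript(tuple(
            TaskSegment("bimanual", 10.0, "both") for _ in range(4)
        ))
        counts = {}
        for label, subject in {
            "impaired": SubjectSpec("S", "stroke", 0.8, 30, "left"),
            "control": SubjectSpec("C", "control", 0.0, 66, "left"),
        }.items():
            total = 0
            for seed in range(5):
                session = simulate_session(subject, script, "left", seed=seed)
                kin = preprocess(session.acc, session.fs)
                n, _, _ = crossing_stats(crossing_segments(kin.acc))
                total += n
            counts[label] = total
        assert counts["impaired"] > counts["control"]


class TestClassifyGroups:
    def _features(self, rng, n_stroke=8, n_control=6, informative=True):
        idx = [f"S{i}" for i in range(n_stroke)] + [f"C{i}" for i in range(n_control)]
        groups = pd.Series(
            ["stroke"] * n_stroke + ["control"] * n_control, index=idx
        )
        x = pd.DataFrame(rng.normal(size=(len(idx), 5)), index=idx,
                         columns=[f"f{i}" for i in range(5)])
        if informative:
            x["f0"] = (groups == "stroke").astype(float)
        return x, groups

    def test_perfect_indicator_feature_classified_perfectly(self, rng):
        x, groups = self._features(rng)
        report = classify_groups(x, groups, seed=0)
        assert report.balanced_accuracy == 1.0

    def test_shuffled_labels_near_chance(self, rng):
        """Label permutation drives balanced accuracy toward 0.5."""
        x, groups = self._features(rng, informative=False)
        accs = []
        for _ in range(20):
            shuffled = pd.Series(
                rng.permutation(groups.to_numpy()), index=groups.index
            )
            if shuffled.value_counts().min() < 3:
                continue
            accs.append(classify_groups(x, shuffled, seed=0).balanced_accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.15

    def test_too_small_group_rejected(self, rng):
        x, groups = self._features(rng, n_stroke=2, n_control=6)
        with pytest.raises(ValueError):
            classify_groups(x, groups)

    def test_held_out_subject_not_in_fold_fit(self, rng):
        """Each subject's prediction reproduces an external refit that
        excludes that subject from scaling and model fitting."""
        from sklearn.linear_model import LogisticRegressionCV
        from sklearn.preprocessing import StandardScaler

        x, groups = self._features(rng)
        x["f0"] += rng.normal(0, 0.5, size=len(x))  # imperfect separator
        y = (groups == "stroke").to_numpy()
        report = classify_groups(x, groups, seed=0)
        for i in (0, len(x) - 1):
            tr = np.ones(len(y), dtype=bool)
            tr[i] = False
            scaler = StandardScaler().fit(x.to_numpy()[tr])
            clf = LogisticRegressionCV(
                Cs=10, cv=3, solver="saga", l1_ratios=[0.1, 0.5, 0.9],
                max_iter=5000, random_state=0,
                scoring="balanced_accuracy", n_jobs=1,
            ).fit(scaler.transform(x.to_numpy()[tr]), y[tr])
            external = clf.predict(scaler.transform(x.to_numpy()[[i]]))[0]
            assert report.predictions.iloc[i] == bool(external)


class TestRegressFma:
    def _features(self, rng, n=12):
        idx = [f"S{i}" for i in range(n)]
        x = pd.DataFrame(rng.normal(size=(n, 4)), index=idx,
                         columns=list("abcd"))
        return idx, x

    def test_linear_signal_recovered(self, rng):
        idx, x = self._features(rng)
        fma = pd.Series(40 + 10 * x["a"] + rng.normal(0, 0.1, len(x)), index=idx)
        report = regress_fma(x, fma, seed=0)
        assert report.explained_variance > 0.95

    def test_pure_noise_has_no_explained_variance(self, rng):
        idx, x = self._features(rng, n=16)
        fma = pd.Series(rng.normal(40, 8, len(x)), index=idx)
        report = regress_fma(x, fma, seed=0)
        assert report.explained_variance <= 0.2
        assert report.explained_variance >= -1.0  # reporting floor

    def test_constant_fma_rejected(self, rng):
        idx, x = self._features(rng)
        with pytest.raises(ValueError):
            regress_fma(x, pd.Series(37.0, index=idx))


def _sample_with_moments(rng, n, mean, sd):
    x = rng.normal(size=n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestGroupStatistics:
    @pytest.mark.parametrize("m1, s1, m2, s2, expected", [
        (0.21, 0.1, 0.5, 0.11, -2.81),
        (75.61, 43.6, 32.13, 5.1, 1.21),
    ])
    def test_cohens_d_worked_examples(self, rng, m1, s1, m2, s2, expected):
        """Pooled-SD d from constructed samples with exact (mean, SD)."""
        stroke = _sample_with_moments(rng, 20, m1, s1)
        control = _sample_with_moments(rng, 10, m2, s2)
        table = pd.DataFrame({"f": np.concatenate([stroke, control])})
        groups = pd.Series(["stroke"] * 20 + ["control"] * 10, index=table.index)
        out = group_statistics(table, groups)
        assert out.loc[0, "cohens_d"] == pytest.approx(expected, abs=0.005)

    def test_identical_groups_d_zero_p_one(self, rng):
        vals = rng.normal(size=10)
        table = pd.DataFrame({"f": np.concatenate([vals, vals])})
        groups = pd.Series(["stroke"] * 10 + ["control"] * 10, index=table.index)
        out = group_statistics(table, groups)
        assert out.loc[0, "cohens_d"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc[0, "p_value"] == pytest.approx(1.0)

    def test_antisymmetric_under_group_swap(self, rng):
        table = pd.DataFrame({"f": rng.normal(size=30)})
        groups = pd.Series(["stroke"] * 20 + ["control"] * 10, index=table.index)
        swapped = groups.map({"stroke": "control", "control": "stroke"})
        d1 = group_statistics(table, groups).loc[0, "cohens_d"]
        d2 = group_statistics(table, swapped).loc[0, "cohens_d"]
        assert d1 == pytest.approx(-d2)

    def test_invariant_under_affine_rescaling(self, rng):
        table = pd.DataFrame({"f": rng.normal(size=30)})
        groups = pd.Series(["stroke"] * 20 + ["control"] * 10, index=table.index)
        scaled = table * 13.7 + 5.0
        d1 = group_statistics(table, groups).loc[0, "cohens_d"]
        d2 = group_statistics(scaled, groups).loc[0, "cohens_d"]
        assert d1 == pytest.approx(d2)

    def test_single_subject_group_rejected(self, rng):
        table = pd.DataFrame({"f": rng.normal(size=3)})
        groups = pd.Series(["stroke", "stroke", "control"], index=table.index)
        with pytest.raises(ValueError):
            group_statistics(table, groups)

    def test_pooled_d_helper_matches_formula(self):
        assert pooled_cohens_d(0.21, 0.1, 20, 0.5, 0.11, 10) == \
            pytest.approx(-2.807, abs=0.001)
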