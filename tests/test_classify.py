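"""Threshold fitting, the decision tree, LOOCV, and the alpha sweep."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tcdmorph import classify, synth
from tcdmorph.classify import BELOW, TREE, VAI_ONLY, VCI_ONLY
from tcdmorph.errors import ValidationError
from tcdmorph.features import FeatureRow


def brute_force_threshold(values, pos_mask, alpha=0.5, direction=BELOW):
    """Independent O(n^2) J_alpha maximizer over midpoint candidates."""
    values = np.asarray(values, float)
    pos_mask = np.asarray(pos_mask, bool)
    uniq = sorted(set(values.tolist()))
    cands = [-np.inf] + [(a + b) / 2.0 for a, b in zip(uniq[:-1], uniq[1:])] + [np.inf]
    best = None
    for t in cands:
        pred = values < t if direction == BELOW else values > t
        tpr = pred[pos_mask].sum() / pos_mask.sum()
        fpr = pred[~pos_mask].sum() / (~pos_mask).sum()
        j = alpha * tpr - (1.0 - alpha) * fpr
        key = (j, -int(pred.sum()))
        if best is None or key > best[0]:
            best = (key, t)
    return best[1], best[0][0]


def _rows(vci, vai, labels):
    return [
        FeatureRow(f"s{i}", float(c), float(a), label=l)
        for i, (c, a, l) in enumerate(zip(vci, vai, labels))
    ]


def planted_rule_rows(n, rng, flip=0.0):
    """Cohort following VCI<2 => LVO; VCI>5 => IHC; else VAI<0.8 => LVO."""
    rows = []
    for i in range(n):
        u = rng.random()
        if u < 0.35:
            vci, vai = rng.uniform(0.2, 2.0), rng.uniform(0.3, 1.0)
        elif u < 0.65:
            vci, vai = rng.uniform(2.0, 5.0), rng.uniform(0.72, 1.0)
        else:
            vci, vai = rng.uniform(5.0, 8.0), rng.uniform(0.72, 1.0)
        label = "LVO" if (vci < 2.0 or (vci <= 5.0 and vai < 0.8)) else "IHC"
        if rng.random() < flip:
            label = "IHC" if label == "LVO" else "LVO"
        rows.append(FeatureRow(f"s{i}", vci=float(vci), vai=float(vai), label=label))
    return rows


class TestFitThreshold:
    def test_separated_groups_take_midpoint(self):
        m = classify.fit_threshold([1, 2, 5, 6], [True, True, False, False])
        assert m.threshold == 3.5

    def test_alpha_one_reaches_full_sensitivity(self):
        values = [1.0, 3.0, 2.0, 4.0]
        labels = [True, True, False, False]
        m = classify.fit_threshold(values, labels, alpha=1.0)
        assert m.predict(np.array(values))[:2].all()
        # tie-break: the least-positive cut achieving TPR=1
        assert m.threshold == 3.5

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            classify.fit_threshold([1, 2], [True, True])

    def test_string_labels_accepted(self):
        m = classify.fit_threshold([1, 2, 5, 6], ["LVO", "LVO", "IHC", "IHC"])
        assert m.threshold == 3.5

    @given(st.data())
    def test_matches_brute_force_including_ties(self, data):
        n = data.draw(st.integers(4, 20))
        values = data.draw(
            st.lists(st.integers(0, 6), min_size=n, max_size=n).map(
                lambda xs: [x / 2.0 for x in xs]
            )
        )
        labels = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda ls: any(ls) and not all(ls)
            )
        )
        alpha = data.draw(st.sampled_from([0.5, 0.6, 0.75, 0.9, 1.0]))
        m = classify.fit_threshold(values, labels, alpha=alpha)
        t_ref, _ = brute_force_threshold(values, labels, alpha)
        assert m.threshold == t_ref


class TestFitTree:
    def test_recovers_planted_rule_noiselessly(self):
        rows = planted_rule_rows(500, np.random.default_rng(42))
        m = classify.fit_tree(rows, alpha=0.5)
        vci = np.sort([r.vci for r in rows])
        spacing = np.diff(vci).max()
        assert abs(m.vci_min - 2.0) <= spacing
        assert abs(m.vci_max - 5.0) <= spacing
        assert abs(m.vai_crit - 0.8) <= 0.05

    def test_perfect_vci_separation_absorbed_by_stage_one(self):
        rows = _rows([1, 2, 3, 6, 7, 8], [0.5] * 6, ["LVO"] * 3 + ["IHC"] * 3)
        m = classify.fit_tree(rows)
        pred = classify.predict_tree(m, rows)
        assert (pred == [r.label for r in rows]).all()
        assert m.vci_min == 4.5

    def test_higher_alpha_never_lowers_training_sensitivity(self):
        rows = synth.generate_feature_cohort(synth.FeatureCohortSpec(seed=7))
        labels = [r.label for r in rows]
        sens = []
        for alpha in (0.5, 0.9):
            pred = classify.predict_tree(classify.fit_tree(rows, alpha), rows)
            sens.append(classify.confusion(labels, pred).sen)
        assert sens[1] >= sens[0]

    def test_thresholds_ordered_by_construction(self):
        for seed in range(5):
            rows = synth.generate_feature_cohort(
                synth.FeatureCohortSpec(n_lvo=15, n_ihc=15, seed=seed)
            )
            m = classify.fit_tree(rows, alpha=0.5)
            assert m.vci_min <= m.vci_max


class TestPredictTree:
    MODEL = classify.TreeModel(vci_min=2.0, vci_max=5.0, vai_crit=0.8, alpha=0.5)

    @pytest.mark.parametrize(
        "vci,vai,expected",
        [
            (1.0, 0.9, "LVO"),   # stage 1: low VCI
            (6.0, 0.3, "IHC"),   # stage 2 precedes the VAI rule
            (3.0, 0.69, "LVO"),  # uncertain VCI, asymmetric velocities
            (3.0, 0.9, "IHC"),
            (2.0, 0.9, "IHC"),   # equality falls through and stays IHC
            (3.0, 0.8, "IHC"),   # equality at the VAI cut predicts IHC
        ],
    )
    def test_cascade_rules(self, vci, vai, expected):
        rows = _rows([vci], [vai], [None])
        assert classify.predict_tree(self.MODEL, rows)[0] == expected

    def test_monotone_in_both_features(self, rng):
        for _ in range(200):
            vci, vai = rng.uniform(0, 8), rng.uniform(0, 1)
            base = classify.predict_tree(self.MODEL, _rows([vci], [vai], [None]))[0]
            if base == "LVO":
                lower = classify.predict_tree(
                    self.MODEL, _rows([vci * 0.7], [vai * 0.7], [None])
                )[0]
                assert lower == "LVO"


class TestLoocv:
    def test_four_subject_case_matches_hand_enumeration(self):
        rows = _rows([1, 2, 3, 4], [0.5] * 4, ["LVO", "IHC", "LVO", "IHC"])
        res = classify.loocv(rows, VCI_ONLY, alpha=0.5)
        assert (res.counts.tp, res.counts.fn, res.counts.fp, res.counts.tn) == (
            1, 1, 1, 1,
        )
        assert res.predictions == ("LVO", "LVO", "IHC", "IHC")

    @pytest.mark.parametrize("clf", [VAI_ONLY, VCI_ONLY, TREE])
    def test_perfect_separation_is_perfectly_cross_validated(self, clf):
        rows = _rows(
            [1, 1.5, 2, 6, 7, 8],
            [0.3, 0.35, 0.4, 0.9, 0.92, 0.95],
            ["LVO"] * 3 + ["IHC"] * 3,
        )
        res = classify.loocv(rows, clf, alpha=0.5)
        assert res.sen == res.spe == res.acc == 1.0

    def test_permuted_labels_score_at_chance(self):
        rows = synth.generate_feature_cohort(
            synth.FeatureCohortSpec(n_lvo=100, n_ihc=100, seed=3)
        )
        perm = np.random.default_rng(9).permutation([r.label for r in rows])
        prows = [
            FeatureRow(r.subject_id, r.vci, r.vai, label=l)
            for r, l in zip(rows, perm)
        ]
        res = classify.loocv(prows, TREE, alpha=0.5)
        assert 0.4 <= res.acc <= 0.6

    def test_requires_both_classes(self):
        rows = _rows([1, 2, 3], [0.5] * 3, ["LVO"] * 3)
        with pytest.raises(ValidationError):
            classify.loocv(rows, TREE)


@pytest.fixture(scope="module")
def rows66():
    return synth.generate_feature_cohort(synth.FeatureCohortSpec(seed=5))


class TestSensitivitySweep:

    def test_default_grid_has_51_rows(self, rows66):
        table = classify.sensitivity_sweep(rows66, VCI_ONLY)
        assert len(table) == 51
        assert table["alpha"].iloc[0] == 0.5
        assert table["alpha"].iloc[-1] == 1.0

    @pytest.mark.parametrize("clf", [VCI_ONLY, VAI_ONLY])
    def test_in_sample_sensitivity_monotone_and_maximal(self, rows66, clf):
        table = classify.sensitivity_sweep(rows66, clf)
        sen = table["sen_insample"].to_numpy()
        assert np.all(np.diff(sen) >= -1e-12)
        assert sen[-1] == 1.0

    def test_first_row_equals_plain_youden_loocv(self, rows66):
        table = classify.sensitivity_sweep(
            rows66, TREE, alpha_grid=[0.5, 0.6]
        )
        res = classify.loocv(rows66, TREE, alpha=0.5)
        assert table["acc"].iloc[0] == res.acc
        assert table["sen"].iloc[0] == res.sen
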