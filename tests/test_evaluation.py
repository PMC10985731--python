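import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spheroscore.errors import ValidationError
from spheroscore.evaluation import (ConfusionCounts, RaterSeries, accuracy,
                                    earth_movers_distance,
                                    f1_optimal_threshold, f1_score,
                                    id_ld_confusion, krippendorff_alpha,
                                    mask_iou, match_instances, pearson_matrix,
                                    pearson_r, quantize_expert,
                                    youden_optimal_threshold)


def alpha_coincidence_oracle(table) -> float:
    """Brute-force interval alpha from an explicit coincidence matrix.

    Enumerates every ordered pairable value pair within units into a
    coincidence matrix over the distinct values, then applies the
    observed/expected disagreement ratio.
    """
    arr = np.asarray(table, dtype=float)
    units = [row[~np.isnan(row)] for row in arr]
    units = [u for u in units if u.size >= 2]
    values = sorted({float(v) for u in units for v in u})
    idx = {v: i for i, v in enumerate(values)}
    k = len(values)
    coincidence = np.zeros((k, k))
    for u in units:
        m = len(u)
        for i in range(m):
            for j in range(m):
                if i != j:
                    coincidence[idx[float(u[i])], idx[float(u[j])]] += 1.0 / (m - 1)
    n_c = coincidence.sum(axis=1)
    n = n_c.sum()
    vals = np.array(values)
    delta2 = (vals[:, None] - vals[None, :]) ** 2
    d_obs = (coincidence * delta2).sum() / n
    d_exp = (np.outer(n_c, n_c) * delta2).sum() / (n * (n - 1))
    if d_exp == 0:
        return 1.0
    return 1.0 - d_obs / d_exp


def _square(r0, c0, size, shape=(30, 30)):
    m = np.zeros(shape, dtype=bool)
    m[r0:r0 + size, c0:c0 + size] = True
    return m


class TestMaskIoU:
    def test_identity_is_one(self):
        m = _square(2, 2, 10)
        assert mask_iou(m, m) == 1.0

    def test_disjoint_is_zero(self):
        assert mask_iou(_square(0, 0, 5), _square(20, 20, 5)) == 0.0

    def test_half_overlapping_squares(self):
        a = _square(0, 0, 10)
        b = _square(0, 5, 10)  # overlap strip 10x5
        assert mask_iou(a, b) == pytest.approx(1 / 3)

    def test_both_empty_defined_as_one(self):
        empty = np.zeros((8, 8), dtype=bool)
        assert mask_iou(empty, empty) == 1.0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            mask_iou(np.zeros((4, 4), bool), np.zeros((5, 5), bool))

    def test_symmetry_and_erosion_monotonicity(self):
        from scipy import ndimage as ndi
        rng = np.random.default_rng(0)
        a = ndi.binary_dilation(rng.random((40, 40)) < 0.05, iterations=3)
        b = ndi.binary_dilation(rng.random((40, 40)) < 0.05, iterations=3)
        assert mask_iou(a, b) == mask_iou(b, a)
        prev = mask_iou(a, b)
        eroded = a.copy()
        for _ in range(3):
            eroded = ndi.binary_erosion(eroded)
            if not eroded.any() or not (eroded & b).any():
                break
            cur = mask_iou(eroded, b)
            # eroding one argument inside the other can only shrink overlap
            assert cur <= prev + 1e-12 or (a & ~b).any()
            prev = cur


class TestMatchInstances:
    def test_perfect_matching(self):
        masks = [_square(i * 6, i * 6, 4) for i in range(5)]
        pairs, c = match_instances(masks, masks)
        assert (c.tp, c.fp, c.fn) == (5, 0, 0)
        assert all(iou == 1.0 for _, _, iou in pairs)

    def test_empty_prediction_all_missed(self):
        truths = [_square(i * 8, 0, 5) for i in range(3)]
        _, c = match_instances([], truths)
        assert (c.tp, c.fp, c.fn) == (0, 0, 3)

    def test_one_to_one_under_double_match(self):
        truth = [_square(0, 0, 10)]
        # two predictions, each IoU 0.6+ with the same truth
        preds = [_square(0, 0, 9), _square(1, 1, 9)]
        pairs, c = match_instances(preds, truth, iou_threshold=0.5)
        assert (c.tp, c.fp, c.fn) == (1, 1, 0)
        assert len(pairs) == 1


class TestF1Accuracy:
    @pytest.mark.parametrize("tp,fp,fn,expected", [
        (10, 0, 0, 1.0), (9, 1, 1, 0.9), (0, 5, 5, 0.0),
    ])
    def test_f1_closed_form(self, tp, fp, fn, expected):
        assert f1_score(ConfusionCounts(tp=tp, fp=fp, fn=fn)) == pytest.approx(expected)

    def test_f1_undefined_on_zero_counts(self):
        with pytest.raises(ValidationError):
            f1_score(ConfusionCounts())

    def test_accuracy(self):
        assert accuracy(ConfusionCounts(tp=8, fp=1, fn=1, tn=10)) == 0.9


class TestIdLdConfusion:
    def test_identity_gives_perfect_f1(self):
        vals = {f"i{k}": float(v) for k, v in enumerate(
            [50, 0, -1, 30, 80, -1, 0, 100] * 2)}
        conf = id_ld_confusion(vals, vals)
        assert f1_score(conf["ID"]) == 1.0
        assert f1_score(conf["LD"]) == 1.0

    def test_sentinel_truth_with_prediction_is_id_false_positive(self):
        conf = id_ld_confusion({"a": 30.0}, {"a": -1.0})
        assert conf["ID"].fp == 1
        assert conf["LD"].total == 0  # LD only where truth has spheroids

    def test_dead_call_on_live_truth_is_ld_false_negative(self):
        conf = id_ld_confusion({"a": 0.0}, {"a": 50.0})
        assert conf["LD"].fn == 1

    def test_all_dead_truth_vs_all_live_pred_zero_ld_f1(self):
        pred = {f"i{k}": 40.0 for k in range(5)}
        truth = {f"i{k}": 0.0 for k in range(5)}
        conf = id_ld_confusion(pred, truth)
        assert f1_score(conf["LD"]) == 0.0

    def test_unpaired_items_rejected(self):
        with pytest.raises(ValidationError):
            id_ld_confusion({"a": 1.0}, {"b": 1.0})


class TestEMD:
    def test_identical_distributions_zero(self):
        x = [10.0, 55.0, 90.0]
        assert earth_movers_distance(x, x) == 0.0

    def test_extreme_point_masses(self):
        assert earth_movers_distance([0.0] * 5, [100.0] * 5) == pytest.approx(1.0)

    def test_ten_point_translation(self):
        assert earth_movers_distance([50.0] * 4, [60.0] * 4) == pytest.approx(0.10)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            earth_movers_distance([], [50.0])

    @settings(derandomize=True, max_examples=50)
    @given(x=st.lists(st.floats(0, 90), min_size=1, max_size=20),
           delta=st.floats(0, 10))
    def test_translation_property(self, x, delta):
        shifted = [v + delta for v in x]
        emd = earth_movers_distance(x, shifted)
        assert emd == pytest.approx(delta / 100.0, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 100), min_size=1, max_size=12),
           st.lists(st.floats(0, 100), min_size=1, max_size=12),
           st.lists(st.floats(0, 100), min_size=1, max_size=12))
    def test_symmetry_and_triangle_inequality(self, x, y, z):
        dxy = earth_movers_distance(x, y)
        assert dxy == pytest.approx(earth_movers_distance(y, x), abs=1e-12)
        dxz = earth_movers_distance(x, z)
        dzy = earth_movers_distance(z, y)
        assert dxy <= dxz + dzy + 1e-9


class TestKrippendorffAlpha:
    def test_identical_raters_perfect(self):
        series = RaterSeries(item_ids=list(range(4)),
                             values_a=[10.0, 40.0, 70.0, 100.0],
                             values_b=[10.0, 40.0, 70.0, 100.0])
        assert krippendorff_alpha(series) == 1.0

    def test_all_values_identical_defined_as_one(self):
        series = RaterSeries(item_ids=[0, 1], values_a=[50.0, 50.0],
                             values_b=[50.0, 50.0])
        assert krippendorff_alpha(series) == 1.0

    def test_systematic_inversion_negative(self):
        b = [0.0, 20.0, 60.0, 100.0, 40.0]
        a = [100.0 - v for v in b]
        series = RaterSeries(item_ids=list(range(5)), values_a=a, values_b=b)
        alpha = krippendorff_alpha(series)
        table = np.column_stack([a, b])
        assert alpha == pytest.approx(alpha_coincidence_oracle(table), abs=1e-12)
        assert alpha < 0

    def test_matches_oracle_on_random_small_tables(self):
        rng = np.random.default_rng(123)
        checked = 0
        while checked < 100:
            n_items = rng.integers(2, 7)
            n_raters = rng.integers(2, 4)
            table = rng.integers(0, 11, (n_items, n_raters)).astype(float) * 10
            if rng.random() < 0.3:
                table[rng.integers(0, n_items), rng.integers(0, n_raters)] = np.nan
            units_ok = sum((~np.isnan(row)).sum() >= 2 for row in table) >= 2
            if not units_ok:
                continue
            expected = alpha_coincidence_oracle(table)
            assert krippendorff_alpha(table) == pytest.approx(expected, abs=1e-12)
            checked += 1

    def test_sentinels_dropped_from_pairs(self):
        series = RaterSeries(item_ids=[0, 1, 2, 3],
                             values_a=[10.0, -1.0, 70.0, 90.0],
                             values_b=[10.0, 50.0, 70.0, 90.0])
        assert krippendorff_alpha(series) == 1.0

    def test_too_few_units_rejected(self):
        series = RaterSeries(item_ids=[0], values_a=[10.0], values_b=[20.0])
        with pytest.raises(ValidationError):
            krippendorff_alpha(series)


class TestPearson:
    def test_exact_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_r(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)

    def test_exact_inverse(self):
        x = [1.0, 2.0, 3.0]
        assert pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_three_point_closed_form(self):
        assert pearson_r([1, 2, 3], [1, 2, 2]) == pytest.approx(np.sqrt(3) / 2,
                                                                abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            pearson_r([1, 2, 3], [5, 5, 5])

    def test_method_matrix_symmetric_unit_diagonal(self):
        methods = {"a": [1, 2, 3, 4], "b": [2, 4, 6, 9], "c": [4, 3, 2, 1]}
        mat = pearson_matrix(methods)
        assert np.allclose(np.diag(mat.values), 1.0)
        assert np.allclose(mat.values, mat.values.T)


class TestExpertQuantization:
    @pytest.mark.parametrize("value,expected", [(4.9, 0.0), (5.0, 0.0),
                                                (5.1, 10.0), (97.0, 100.0)])
    def test_rounds_to_ten_percent_steps(self, value, expected):
        assert quantize_expert(value) == expected


class TestThresholdScans:
    def test_f1_scan_separable_example(self):
        t, best = f1_optimal_threshold([0, 0, 80, 90],
                                       ["dead", "dead", "live", "live"])
        assert best == 1.0
        assert 0 <= t < 80

    def test_f1_scan_inverted_labels_imperfect(self):
        _, best = f1_optimal_threshold([0, 0, 80, 90],
                                       ["live", "live", "dead", "dead"])
        assert best < 1.0

    def test_f1_scan_separable_pair(self):
        t, best = f1_optimal_threshold([10, 50], ["dead", "live"])
        assert best == 1.0
        assert 10 < t < 50

    def test_youden_separable_quad(self):
        t, j = youden_optimal_threshold([1, 2, 3, 4], ["dead", "dead",
                                                       "live", "live"])
        assert j == pytest.approx(1.0)
        assert 2 < t < 3

    def test_youden_alternating_labels_near_zero(self):
        scores = list(range(200))
        labels = ["dead" if i % 2 == 0 else "live" for i in range(200)]
        _, j = youden_optimal_threshold(scores, labels)
        assert abs(j) <= 0.02

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            f1_optimal_threshold([1, 2, 3], ["live", "live", "live"])
        with pytest.raises(ValidationError):
            youden_optimal_threshold([1, 2, 3], ["dead", "dead", "dead"])

    def test_planted_boundary_recovery(self):
        rng = np.random.default_rng(7)
        dead = rng.uniform(0, 40, 60)
        live = rng.uniform(60, 100, 60)
        scores = np.concatenate([dead, live])
        labels = ["dead"] * 60 + ["live"] * 60
        t_f1, best_f1 = f1_optimal_threshold(scores, labels)
        t_j, best_j = youden_optimal_threshold(scores, labels)
        assert best_f1 == 1.0 and best_j == pytest.approx(1.0)
        assert 40 < t_f1 < 60
        assert 40 < t_j < 60
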