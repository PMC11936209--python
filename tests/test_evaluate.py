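"""Evaluation framework: the four scores, thresholding, and the
cross-model comparison report."""

import numpy as np
import pytest

from beatbench.core import Beat, BeatSet
from beatbench.distances import get_metric
from beatbench.evaluate import (
    EvalConfig,
    compare_models,
    compute_threshold,
    method1_score,
    method2_score,
    method3_best,
    method4_productivity,
    score_model,
)
from beatbench.templates import Template


def _tpl(vec, n=1):
    return Template(Beat(np.asarray(vec, float)), "explicit_index", n)


class TestMethod1:
    def test_single_generated_beat_full_portions(self):
        v = BeatSet(np.array([[0.0], [2.0]]))
        g = BeatSet(np.array([[1.0]]))
        assert method1_score(v, g, "euclidean") == pytest.approx(1.0)

    def test_two_by_two_full_cross_mean(self):
        v = BeatSet(np.array([[0.0], [2.0]]))
        g = BeatSet(np.array([[1.0], [3.0]]))
        assert method1_score(v, g, "euclidean") == pytest.approx(1.5)  # (1+3+1+1)/4

    def test_identical_sets_of_identical_beats(self):
        v = BeatSet(np.tile(np.arange(4.0), (3, 1)))
        assert method1_score(v, v, "dtw") == 0.0

    def test_full_portions_match_brute_force_double_sum(self, rng):
        v = BeatSet(rng.standard_normal((15, 6)))
        g = BeatSet(rng.standard_normal((20, 6)))
        for df in ("dtw", "frechet", "euclidean"):
            fn = get_metric(df)
            brute = np.mean([[fn(a, b) for b in g.data] for a in v.data])
            assert method1_score(v, g, df) == pytest.approx(brute, rel=1e-12)

    def test_portion_larger_than_set_rejected(self, rng):
        v = BeatSet(rng.standard_normal((5, 4)))
        cfg = EvalConfig(portion_real=10, portion_generated=5)
        with pytest.raises(ValueError):
            method1_score(v, v, "dtw", cfg)

    def test_subsampled_score_is_seed_deterministic(self, rng):
        v = BeatSet(rng.standard_normal((30, 6)))
        g = BeatSet(rng.standard_normal((30, 6)))
        cfg = EvalConfig(portion_real=10, portion_generated=10, seed=3)
        assert method1_score(v, g, "dtw", cfg) == method1_score(v, g, "dtw", cfg)


class TestMethods23:
    def test_mean_distance_to_template(self):
        g = BeatSet(np.array([[1.0], [3.0]]))
        assert method2_score(g, _tpl([0.0]), "euclidean") == pytest.approx(2.0)

    def test_template_member_gives_zero(self):
        t = np.arange(5.0)
        g = BeatSet(np.vstack([t, t + 2.0]))
        assert method2_score(BeatSet(t[None, :]), _tpl(t), "dtw") == 0.0
        idx, s3 = method3_best(g, _tpl(t), "euclidean")
        assert idx == 0 and s3 == 0.0

    def test_single_beat_mean_is_its_distance(self):
        g = BeatSet(np.array([[2.0, 2.0]]))
        expected = get_metric("euclidean")(g.data[0], np.zeros(2))
        assert method2_score(g, _tpl([0.0, 0.0]), "euclidean") == pytest.approx(expected)

    def test_best_beat_tie_breaks_to_lowest_index(self):
        t = np.zeros(3)
        rows = np.array([[5.0] * 3, [5.0] * 3, [1.0] * 3, [9.0] * 3, [9.0] * 3, [1.0] * 3])
        idx, s3 = method3_best(BeatSet(rows), _tpl(t), "euclidean")
        assert idx == 2  # ties between indices 2 and 5 resolve to 2
        assert s3 == pytest.approx(np.sqrt(3))

    def test_s3_never_exceeds_s2(self, rng):
        for _ in range(10):
            g = BeatSet(rng.standard_normal((8, 5)))
            t = _tpl(rng.standard_normal(5))
            for df in ("dtw", "frechet", "euclidean"):
                _, s3 = method3_best(g, t, df)
                assert s3 <= method2_score(g, t, df) + 1e-12


class TestThreshold:
    def test_printed_classic_gan_dtw_entries(self):
        assert compute_threshold(s2=4.13, s3=0.510) == pytest.approx(2.320)

    def test_degenerate_equal_scores(self):
        assert compute_threshold(s2=0.7, s3=0.7) == pytest.approx(0.7)

    def test_factor_mode(self):
        assert compute_threshold(s2=9.0, s3=0.5, mode="factor", a=2.0) == pytest.approx(1.0)

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            compute_threshold(s2=0.3, s3=0.5)


class TestProductivity:
    def test_inclusive_acceptance(self):
        g = BeatSet(np.array([[1.0], [3.0]]))
        accepted, s4 = method4_productivity(g, _tpl([0.0]), "euclidean", eta=2.0)
        assert list(accepted) == [0] and s4 == 50.0
        accepted, s4 = method4_productivity(g, _tpl([0.0]), "euclidean", eta=1.0)
        assert list(accepted) == [0] and s4 == 50.0  # boundary beat counts

    def test_zero_threshold_no_match(self, rng):
        g = BeatSet(rng.standard_normal((5, 4)) + 10.0)
        _, s4 = method4_productivity(g, _tpl(np.zeros(4)), "euclidean", eta=0.0)
        assert s4 == 0.0

    def test_huge_threshold_accepts_all(self, rng):
        g = BeatSet(rng.standard_normal((5, 4)))
        _, s4 = method4_productivity(g, _tpl(np.zeros(4)), "euclidean", eta=1e9)
        assert s4 == 100.0

    def test_monotone_in_threshold(self, rng):
        g = BeatSet(rng.standard_normal((20, 6)))
        t = _tpl(rng.standard_normal(6))
        rates = [method4_productivity(g, t, "dtw", eta)[1] for eta in np.linspace(0, 20, 15)]
        assert all(b >= a for a, b in zip(rates, rates[1:]))

    def test_best_beat_always_accepted_under_mean_threshold(self, rng):
        g = BeatSet(rng.standard_normal((12, 5)))
        t = _tpl(rng.standard_normal(5))
        s2 = method2_score(g, t, "dtw")
        _, s3 = method3_best(g, t, "dtw")
        eta = compute_threshold(s2, s3)
        _, s4 = method4_productivity(g, t, "dtw", eta)
        assert s4 >= 100.0 / g.count


class TestCompareModels:
    def test_generated_equals_template_scores_perfectly(self, rng):
        t_vec = rng.standard_normal(6)
        real = BeatSet(rng.standard_normal((5, 6)))
        runs = {"m": BeatSet(np.tile(t_vec, (4, 1)))}
        cfg = EvalConfig(portion_real=5, portion_generated=4)
        table = compare_models(runs, real, _tpl(t_vec), cfg)
        for df in ("dtw", "frechet", "euclidean"):
            assert table.loc["m", f"s2_{df}"] == 0.0
            assert table.loc["m", f"s3_{df}"] == 0.0
            assert table.loc["m", f"s4_{df}"] == 100.0

    def test_dominant_model_flagged_best(self, rng):
        # constant offsets make every distance proportional to the shift, so
        # the ranking is deterministic: "near" reproduces the template for 5
        # of 6 beats (one outlier inflates s2, hence its threshold accepts
        # the 5 exact copies -> s4 = 83%), while "far" spreads its beats so
        # its own threshold accepts only 2 of 6 (s4 = 33%)
        t_vec = rng.standard_normal(6)
        real = BeatSet(np.vstack([t_vec + 0.1 * k for k in range(6)]))
        near = BeatSet(np.vstack([t_vec] * 5 + [t_vec + 5.0]))
        far = BeatSet(np.vstack([t_vec + k for k in range(1, 7)]))
        cfg = EvalConfig(portion_real=6, portion_generated=6)
        table = compare_models({"near": near, "far": far}, real, _tpl(t_vec), cfg)
        for df in ("dtw", "frechet", "euclidean"):
            assert table.loc["near", f"best_s2_{df}"]
            assert table.loc["near", f"best_s3_{df}"]
            assert table.loc["near", f"best_s4_{df}"]

    def test_report_is_deterministic(self, rng):
        real = BeatSet(rng.standard_normal((10, 5)))
        gen = BeatSet(rng.standard_normal((10, 5)))
        cfg = EvalConfig(portion_real=6, portion_generated=6, seed=4)
        t = _tpl(np.zeros(5))
        a = compare_models({"m": gen}, real, t, cfg)
        b = compare_models({"m": gen}, real, t, cfg)
        assert a.equals(b)

    def test_length_mismatch_rejected(self, rng):
        real = BeatSet(rng.standard_normal((4, 5)))
        gen = BeatSet(rng.standard_normal((4, 6)))
        with pytest.raises(ValueError, match="length"):
            compare_models({"m": gen}, real, _tpl(np.zeros(5)),
                           EvalConfig(portion_real=4, portion_generated=4))

    def test_empty_runs_rejected(self, rng):
        real = BeatSet(rng.standard_normal((4, 5)))
        with pytest.raises(ValueError):
            compare_models({}, real, _tpl(np.zeros(5)), EvalConfig())


def test_score_model_records_threshold_and_counts(rng):
    real = BeatSet(rng.standard_normal((10, 6)))
    gen = BeatSet(rng.standard_normal((10, 6)))
    cfg = EvalConfig(portion_real=10, portion_generated=10)
    scores = score_model(real, gen, _tpl(np.zeros(6)), cfg, "unit")
    for df in ("dtw", "frechet", "euclidean"):
        sc = scores.per_distance[df]
        assert sc["eta"] == pytest.approx((sc["s2"] + sc["s3"]) / 2)
        assert 0 <= sc["s4"] <= 100
        assert sc["accepted_count"] <= 10


def test_gallery_export_writes_csv_per_model(tmp_path, rng):
    from beatbench.evaluate import export_gallery
    from beatbench.io import load_beats_csv

    runs = {"m1": BeatSet(rng.standard_normal((30, 8))),
            "m2": BeatSet(rng.standard_normal((10, 8)))}
    paths = export_gallery(runs, tmp_path, n_per_model=12, seed=3, plot=False)
    names = sorted(p.name for p in paths)
    assert names == ["gallery_m1.csv", "gallery_m2.csv"]
    assert load_beats_csv(tmp_path / "gallery_m1.csv").count == 12
    assert load_beats_csv(tmp_path / "gallery_m2.csv").count == 10
    again = export_gallery(runs, tmp_path, n_per_model=12, seed=3, plot=False)
    assert (tmp_path / "gallery_m1.csv").read_bytes() == again[0].read_bytes()
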