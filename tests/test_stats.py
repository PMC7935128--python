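"""Student's t-test, group/timepoint/curve comparisons, report rendering."""

import numpy as np
import pytest
from scipy import stats as sps

from mousegait.errors import (
    DegenerateVarianceError,
    InsufficientSampleError,
)
from mousegait.kinematics import GRID, NormalizedCurve
from mousegait.stats_report import (
    compare_curves,
    compare_groups,
    compare_timepoints,
    render_report,
    results_table,
    significance_tier,
    student_t_test,
)
from mousegait.study import run_study


def _pooled_t_oracle(a, b):
    """Textbook pooled-variance formula, coded independently."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * sps.t.sf(abs(t), na + nb - 2)
    return t, p


def test_t_test_matches_textbook_oracle_and_scipy():
    a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    res = student_t_test(a, b)
    t_ref, p_ref = _pooled_t_oracle(a, b)
    assert res.t_statistic == pytest.approx(t_ref, abs=1e-9)
    assert res.p_value == pytest.approx(p_ref, abs=1e-9)
    assert res.df == 4
    sp_t, sp_p = sps.ttest_ind(a, b, equal_var=True)
    assert res.t_statistic == pytest.approx(sp_t, abs=1e-9)
    assert res.p_value == pytest.approx(sp_p, abs=1e-9)


def test_t_test_random_samples_match_scipy(rng):
    for _ in range(100):
        a = rng.normal(0, 2, rng.integers(2, 12))
        b = rng.normal(1, 3, rng.integers(2, 12))
        res = student_t_test(a, b)
        sp_t, sp_p = sps.ttest_ind(a, b, equal_var=True)
        assert res.t_statistic == pytest.approx(sp_t, abs=1e-9)
        assert res.p_value == pytest.approx(sp_p, abs=1e-9)


def test_welch_variant_matches_scipy(rng):
    a, b = rng.normal(0, 1, 8), rng.normal(0.5, 3, 5)
    res = student_t_test(a, b, equal_var=False)
    sp_t, sp_p = sps.ttest_ind(a, b, equal_var=False)
    assert res.t_statistic == pytest.approx(sp_t, abs=1e-9)
    assert res.p_value == pytest.approx(sp_p, abs=1e-9)


def test_identical_samples_give_t_zero_p_one():
    res = student_t_test([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
    assert res.t_statistic == 0.0
    assert res.p_value == 1.0
    assert not res.significant


def test_degenerate_variance_with_unequal_means_raises():
    with pytest.raises(DegenerateVarianceError):
        student_t_test([1.0, 1.0], [2.0, 2.0])


def test_insufficient_sample_raises():
    with pytest.raises(InsufficientSampleError):
        student_t_test([1.0], [2.0, 3.0])


def test_group_swap_flips_t_keeps_p(rng):
    a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 7)
    r1, r2 = student_t_test(a, b), student_t_test(b, a)
    assert r1.t_statistic == pytest.approx(-r2.t_statistic, abs=1e-12)
    assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)


def test_p_invariant_under_affine_transform(rng):
    a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 7)
    base = student_t_test(a, b)
    moved = student_t_test(3.7 * a - 11.0, 3.7 * b - 11.0)
    assert moved.p_value == pytest.approx(base.p_value, abs=1e-12)
    flipped = student_t_test(-2.0 * a, -2.0 * b)
    assert flipped.p_value == pytest.approx(base.p_value, abs=1e-12)


def test_null_rejection_rate_calibrated():
    """2000 null draws (N(0,1), n=5 each): alpha=0.05 rejection in [.040,.061]."""
    rng = np.random.default_rng(1234)
    rejections = 0
    for _ in range(2000):
        res = student_t_test(rng.normal(0, 1, 5), rng.normal(0, 1, 5))
        rejections += res.significant
    assert 0.040 <= rejections / 2000 <= 0.061


def test_power_monotone_in_effect_size():
    rng = np.random.default_rng(99)
    powers = []
    for effect in (0.5, 1.5, 3.0):
        hits = sum(
            student_t_test(rng.normal(0, 1, 5), rng.normal(effect, 1, 5)).significant
            for _ in range(400)
        )
        powers.append(hits / 400)
    assert powers[0] < powers[1] < powers[2]


def test_significance_tiers_match_star_conventions():
    assert significance_tier(0.2) == ""
    assert significance_tier(0.04) == "*"
    assert significance_tier(0.004) == "**"
    assert significance_tier(0.0004) == "***"
    assert significance_tier(0.004, marker="#") == "##"


def _curves(truth, n, rng, sd=2.0, joint="ankle"):
    return [
        NormalizedCurve(joint=joint, percent=GRID.copy(),
                        angle=truth + rng.normal(0, sd, 101))
        for _ in range(n)
    ]


def test_identical_group_curves_give_empty_mask():
    rng = np.random.default_rng(0)
    truth = 100 + 20 * np.sin(2 * np.pi * GRID / 100)
    curves = _curves(truth, 4, rng)
    cc = compare_curves(curves, [NormalizedCurve("ankle", GRID.copy(), c.angle.copy())
                                 for c in curves])
    assert not cc.mask.any()


def test_curve_comparison_localizes_offset_region():
    """A 10 deg offset over 40-70% of the cycle is found there (Jaccard >= .5)."""
    true_region = (GRID >= 40) & (GRID <= 70)
    jaccards = []
    for seed in range(50):
        rng = np.random.default_rng(8800 + seed)
        base = 100 + 20 * np.sin(2 * np.pi * GRID / 100)
        shifted = base + 10 * true_region
        cc = compare_curves(_curves(base, 5, rng), _curves(shifted, 5, rng))
        inter = np.sum(cc.mask & true_region)
        union = np.sum(cc.mask | true_region)
        jaccards.append(inter / union if union else 0.0)
    assert np.mean(jaccards) >= 0.5


def test_curve_comparison_needs_two_subjects():
    rng = np.random.default_rng(1)
    truth = np.full(101, 90.0)
    with pytest.raises(InsufficientSampleError):
        compare_curves(_curves(truth, 1, rng), _curves(truth, 5, rng))


def test_compare_groups_flags_step_width_at_default_effects():
    df = run_study(seed=31, ages=(14,))
    res = compare_groups(df[df.group == "control"], df[df.group == "affected"])
    assert res["step_width"].significant
    assert res["step_width"].mean_b > res["step_width"].mean_a
    assert set(res) >= {"hip_rom", "knee_rom", "ankle_rom", "stride_length"}


def test_compare_groups_rejects_n_of_one():
    df = run_study(seed=32, ages=(14,), n_per_group=2)
    single = df[df.group == "control"].iloc[:1]
    with pytest.raises(InsufficientSampleError):
        compare_groups(single, df[df.group == "affected"])


def test_compare_timepoints_identical_tables_not_significant():
    df = run_study(seed=33, ages=(14,), n_per_group=3)
    ctrl = df[df.group == "control"]
    res = compare_timepoints(ctrl, ctrl.copy())
    assert all(not r.significant for r in res.values())
    assert all(r.marker == "#" for r in res.values())


def test_render_report_deterministic_and_complete(tmp_path):
    df = run_study(seed=34, ages=(6, 14), n_per_group=3)
    results = []
    for age in (6, 14):
        sub = df[df.age_weeks == age]
        res = compare_groups(sub[sub.group == "control"],
                             sub[sub.group == "affected"],
                             label_a="control", label_b="affected",
                             timepoint=str(age))
        results.extend(res.values())
    m1 = render_report(tmp_path / "r1", group_results=results)
    m2 = render_report(tmp_path / "r2", group_results=results)
    csv1 = (tmp_path / "r1" / "results.csv").read_bytes()
    csv2 = (tmp_path / "r2" / "results.csv").read_bytes()
    assert csv1 == csv2
    names = {p.name for p in m1}
    assert "results.csv" in names
    assert any(n.startswith("timecourse_step_width") for n in names)
    table = results_table(results)
    assert list(table.columns)[:4] == ["parameter", "timepoint", "group_a", "group_b"]


def test_render_report_empty_stub(tmp_path):
    manifest = render_report(tmp_path / "empty")
    assert (tmp_path / "empty" / "report.txt").read_text().startswith("no comparisons")
    assert (tmp_path / "empty" / "results.csv").exists()
    assert len(manifest) == 2
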