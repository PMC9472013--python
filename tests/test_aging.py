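"""Degradation alignment, group classification, statistics, headline flags."""

import itertools
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from ovomech import (
    OocyteTimeline,
    SynthConfig,
    align_to_degradation,
    classify_groups,
    compare_groups,
    gen_cohort,
    headline_summary,
    percentage,
    yield_table,
)


def _timeline(oid, hours, morph, e2=None, diss=None, cg=None, source="thawed"):
    n = len(hours)
    return OocyteTimeline(
        oocyte_id=oid, source=source,
        data=pd.DataFrame({
            "t_hours": hours,
            "E2_Pa": e2 if e2 is not None else [160.0] * n,
            "dissipation_fJ": diss if diss is not None else [0.3] * n,
            "cg_area": cg if cg is not None else [100.0] * n,
            "morphology": morph,
        }),
    )


# ---------------------------------------------------------------------------
# Alignment and classification
# ---------------------------------------------------------------------------


def test_alignment_rezeroes_on_degradation():
    tl = _timeline("a", [2, 3, 4, 5], ["healthy"] * 3 + ["degraded"])
    aligned = align_to_degradation(tl)
    np.testing.assert_allclose(aligned.data["t_rel"], [-3, -2, -1, 0])
    assert aligned.degraded


def test_never_degraded_keeps_absolute_time_with_flag():
    tl = _timeline("b", [0, 1, 2], ["healthy"] * 3)
    aligned = align_to_degradation(tl)
    np.testing.assert_allclose(aligned.data["t_rel"], [0, 1, 2])
    assert not aligned.degraded


def test_synthetic_cohort_aligned_series_end_at_zero():
    tls, _ = gen_cohort(SynthConfig(seed=50))
    for tl in tls:
        a = align_to_degradation(tl)
        if a.degraded:
            assert a.data["t_rel"].max() == 0.0


def test_degraded_label_is_absorbing():
    with pytest.raises(ValueError, match="absorbing"):
        _timeline("c", [0, 1, 2], ["healthy", "degraded", "healthy"])


def test_classification_boundary_and_empty_groups():
    healthy, degraded = classify_groups(
        [_timeline("a", [0, 6], ["healthy", "degraded"])], horizon=6.0
    )
    assert len(degraded) == 1 and len(healthy) == 0  # closed-interval rule
    healthy, degraded = classify_groups(
        [_timeline("b", [0, 6], ["healthy", "healthy"])], horizon=6.0
    )
    assert len(healthy) == 1 and len(degraded) == 0


def test_cohort_group_sizes_match_study_design():
    cfg = SynthConfig(seed=51)
    tls, _ = gen_cohort(cfg)
    healthy, degraded = classify_groups(tls, horizon=cfg.degradation_hi)
    assert (len(healthy), len(degraded)) == (15, 20)
    # order invariance of the partition
    h2, d2 = classify_groups(list(reversed(tls)), horizon=cfg.degradation_hi)
    assert {t.oocyte_id for t in h2} == {t.oocyte_id for t in healthy}
    assert {t.oocyte_id for t in d2} == {t.oocyte_id for t in degraded}


# ---------------------------------------------------------------------------
# Statistical tests
# ---------------------------------------------------------------------------


def test_identical_groups_give_central_u_and_p_near_one():
    g = np.arange(8.0)
    res = compare_groups([g, g], test="mann_whitney")
    assert res.statistic == pytest.approx(len(g) ** 2 / 2)
    assert res.p_value > 0.9


def test_mann_whitney_u_matches_rank_sum_oracle():
    rng = np.random.default_rng(52)
    for _ in range(10):
        x = rng.normal(0, 1, 6)
        y = rng.normal(0.8, 1, 7)
        res = compare_groups([x, y], test="mann_whitney")
        # independent formula: U = R1 - n1(n1+1)/2 from joint ranks
        ranks = sstats.rankdata(np.concatenate([x, y]))
        u_oracle = ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2
        assert res.statistic == pytest.approx(u_oracle)


def test_mann_whitney_p_close_to_exact_enumeration_at_small_n():
    rng = np.random.default_rng(53)
    for _ in range(4):
        x = rng.normal(0, 1, 5)
        y = rng.normal(1.0, 1, 5)
        res = compare_groups([x, y], test="mann_whitney")
        pooled = np.concatenate([x, y])
        n1 = len(x)
        mu = n1 * len(y) / 2
        obs = abs(res.statistic - mu)
        count = total = 0
        for idx in itertools.combinations(range(len(pooled)), n1):
            sel = np.zeros(len(pooled), bool)
            sel[list(idx)] = True
            u = float(np.sum(pooled[sel][:, None] > pooled[~sel][None, :]))
            count += abs(u - mu) >= obs - 1e-12
            total += 1
        p_exact = count / total
        assert abs(res.p_value - p_exact) < 0.06


def test_anova_and_kruskal_match_reference_implementation():
    rng = np.random.default_rng(54)
    groups = [rng.normal(m, 1, 9) for m in (0.0, 0.3, 1.0)]
    res_a = compare_groups(groups, test="anova")
    ref_a = sstats.f_oneway(*groups)
    assert res_a.statistic == pytest.approx(ref_a.statistic, rel=1e-10)
    assert res_a.p_value == pytest.approx(ref_a.pvalue, rel=1e-10)
    tied = [np.round(g) for g in groups]
    res_k = compare_groups(tied, test="kruskal_wallis")
    ref_k = sstats.kruskal(*tied)
    assert res_k.statistic == pytest.approx(ref_k.statistic, rel=1e-10)
    assert res_k.p_value == pytest.approx(ref_k.pvalue, rel=1e-10)


def test_anova_type_one_error_calibration():
    # equal-mean normal groups: rejection rate ~ alpha over 2000 simulations
    rng = np.random.default_rng(55)
    rejections = 0
    n_sim = 2000
    for _ in range(n_sim):
        groups = [rng.normal(0, 1, 10) for _ in range(3)]
        rejections += compare_groups(groups, test="anova").p_value < 0.05
    rate = rejections / n_sim
    se = np.sqrt(0.05 * 0.95 / n_sim)
    assert abs(rate - 0.05) < 3 * se


def test_insufficient_groups_or_sizes_error():
    with pytest.raises(ValueError):
        compare_groups([[1, 2, 3]], test="anova")
    with pytest.raises(ValueError):
        compare_groups([[1, 2], [3, 4, 5]], test="mann_whitney")
    with pytest.raises(ValueError):
        compare_groups([[1, 2, 3], [4, 5, 6], [7, 8, 9]], test="mann_whitney")


# ---------------------------------------------------------------------------
# Yield arithmetic
# ---------------------------------------------------------------------------


def test_percentage_printed_convention():
    assert percentage(4, 14) == 29  # aged-group 2-cell yield
    assert percentage(0, 14) == 0
    assert percentage(14, 14) == 100
    assert percentage(10, 14) == 71  # computed from counts (not the misprint)
    with pytest.raises(ValueError):
        percentage(1, 0)


def test_yield_table_from_stage_counts():
    table = yield_table({
        "1h": {"total": 14, "two_cell": 10, "early_blastocyst": 7},
        "6h": {"total": 14, "two_cell": 4, "early_blastocyst": 1},
    })
    six = table[table["group"] == "6h"].iloc[0]
    assert six["two_cell_pct"] == 29
    assert six["early_blastocyst_pct"] == 7
    with pytest.raises(ValueError):
        yield_table({"bad": {"total": 10, "stage": 12}})


# ---------------------------------------------------------------------------
# Headline summary
# ---------------------------------------------------------------------------


def test_headline_flags_stiffening_and_dissipation_drop_at_minus_one_hour():
    tls, _ = gen_cohort(SynthConfig(seed=56, n_healthy=0, n_degraded=20))
    aligned = [align_to_degradation(t) for t in tls]
    report = headline_summary(aligned)
    hour_e2, dir_e2 = report.flags["E2_Pa"]
    hour_d, dir_d = report.flags["dissipation_fJ"]
    assert hour_e2 == -1 and dir_e2 > 0  # stiffness doubles
    assert hour_d == -1 and dir_d < 0  # dissipation halves, opposite direction


def test_headline_no_flag_on_healthy_cohort():
    tls, _ = gen_cohort(SynthConfig(seed=57, n_healthy=15, n_degraded=0))
    aligned = [align_to_degradation(t) for t in tls]
    report = headline_summary(aligned)
    assert report.flags == {}


def test_cg_signal_rises_before_the_stiffness_flag():
    cfg = SynthConfig(seed=58, n_healthy=0, n_degraded=20)
    tls, _ = gen_cohort(cfg)
    aligned = [align_to_degradation(t) for t in tls]
    report = headline_summary(aligned, metrics=("cg_area", "E2_Pa"))
    assert report.flags["cg_area"][0] < report.flags["E2_Pa"][0]
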