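"""Unit and property tests for reference-panel expression scoring."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tumorboard.expression import (
    ExpressionPanel,
    SD_ZERO_SENTINEL,
    compute_cum_pct,
    compute_nrz,
    score_patient,
)


def panel(values: dict, role: str = "normal_reference") -> ExpressionPanel:
    return ExpressionPanel(pd.DataFrame(values).T, role)


def test_nrz_is_zero_at_normal_mean():
    normal = panel({"G1": [1.0, 2.0, 3.0]})
    tumor = pd.Series({"G1": 2.0})
    assert compute_nrz(tumor, normal)["G1"] == 0.0


def test_nrz_matches_hand_computed_value():
    # normal {1..5}: mean 3, sample sd sqrt(2.5); tumor 6 -> 3/sqrt(2.5)
    normal = panel({"G1": [1.0, 2.0, 3.0, 4.0, 5.0]})
    tumor = pd.Series({"G1": 6.0})
    assert compute_nrz(tumor, normal)["G1"] == pytest.approx(1.8973665961010275, abs=1e-12)


def test_nrz_brute_force_oracle():
    rng = np.random.default_rng(7)
    values = pd.DataFrame(rng.normal(5, 2, (30, 10)),
                          index=[f"G{i}" for i in range(30)])
    normal = ExpressionPanel(values, "normal_reference")
    tumor = pd.Series(rng.normal(5, 3, 30), index=values.index)
    nrz = compute_nrz(tumor, normal)
    for g in values.index:
        ref = values.loc[g].to_numpy()
        expected = (tumor[g] - ref.mean()) / ref.std(ddof=1)
        assert nrz[g] == pytest.approx(expected, abs=1e-12)


def test_nrz_sd_zero_gives_signed_sentinel_and_qc_flag():
    normal = panel({"G1": [2.0, 2.0, 2.0], "G2": [1.0, 2.0, 3.0]})
    cancer = panel({"G1": [1.0, 2.0], "G2": [1.0, 2.0]}, "cancer_reference")
    tumor = pd.Series({"G1": 5.0, "G2": 2.0})
    nrz = compute_nrz(tumor, normal)
    assert nrz["G1"] == SD_ZERO_SENTINEL
    scores = score_patient(tumor, normal, cancer)
    assert bool(scores.loc["G1", "qc_sd_zero"]) is True
    assert bool(scores.loc["G2", "qc_sd_zero"]) is False


def test_nrz_rejects_small_panel_and_disjoint_genes():
    with pytest.raises(ValueError, match=">=2 samples"):
        compute_nrz(pd.Series({"G1": 1.0}), panel({"G1": [1.0]}))
    with pytest.raises(ValueError, match="no genes"):
        compute_nrz(pd.Series({"G9": 1.0}), panel({"G1": [1.0, 2.0]}))


def test_panel_rejects_duplicates_and_nonfinite():
    values = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], index=["G1", "G1"])
    with pytest.raises(ValueError, match="duplicate"):
        ExpressionPanel(values, "tumor")
    values = pd.DataFrame({"s": [np.nan]}, index=["G1"])
    with pytest.raises(ValueError, match="non-finite"):
        ExpressionPanel(values, "tumor")


def test_cum_pct_counting_oracle():
    cohort = panel({"G1": list(range(1, 41))}, "cancer_reference")
    assert compute_cum_pct(pd.Series({"G1": 10.5}), cohort)["G1"] == pytest.approx(0.25)
    # strictly above all cohort values -> 1.0
    assert compute_cum_pct(pd.Series({"G1": 99.0}), cohort)["G1"] == 1.0
    # tie counts toward the numerator
    assert compute_cum_pct(pd.Series({"G1": 40.0}), cohort)["G1"] == 1.0
    assert compute_cum_pct(pd.Series({"G1": 1.0}), cohort)["G1"] == pytest.approx(1 / 40)


def test_cum_pct_rejects_empty_panel():
    empty = ExpressionPanel(pd.DataFrame(index=pd.Index(["G1"]), columns=[]),
                            "cancer_reference")
    with pytest.raises(ValueError, match="empty"):
        compute_cum_pct(pd.Series({"G1": 1.0}), empty)


@pytest.mark.parametrize(
    "nrz_val,cum,mode,expected",
    [
        (3.1, 0.9, "and", True),
        (3.1, 0.5, "and", False),
        (1.0, 0.9, "and", False),
        (3.1, 0.5, "or", True),
        (1.0, 0.9, "or", True),
        (1.0, 0.5, "or", False),
    ],
)
def test_over_flag_threshold_logic(nrz_val, cum, mode, expected):
    # build panels realizing the requested nrz and cum_pct for one gene
    normal = panel({"G1": [0.0, 1.0, -1.0, 0.5, -0.5]})
    sd = np.std([0.0, 1.0, -1.0, 0.5, -0.5], ddof=1)
    tumor = pd.Series({"G1": nrz_val * sd})
    n_cancer = 10
    k = int(round(cum * n_cancer))
    cancer_vals = [tumor["G1"] - 1] * k + [tumor["G1"] + 1] * (n_cancer - k)
    cancer = panel({"G1": cancer_vals}, "cancer_reference")
    scores = score_patient(tumor, normal, cancer, flag_mode=mode)
    assert bool(scores.loc["G1", "over_flag"]) is expected


def test_score_patient_matches_naive_double_loop(default_cohort):
    c = default_cohort
    tumor = c.profiles[0].expression
    scores = score_patient(tumor, c.normal_panel, c.cancer_panel)
    for g in list(scores.index)[::17]:  # sample a spread of genes
        ref = c.normal_panel.values.loc[g].to_numpy()
        z = (tumor[g] - ref.mean()) / ref.std(ddof=1)
        cohort_vals = c.cancer_panel.values.loc[g].to_numpy()
        pct = np.sum(cohort_vals <= tumor[g]) / cohort_vals.size
        assert scores.loc[g, "nrz"] == pytest.approx(z, abs=1e-12)
        assert scores.loc[g, "cum_pct"] == pytest.approx(pct, abs=1e-12)
        assert bool(scores.loc[g, "over_flag"]) == bool(z > 2 and pct > 0.75)


@settings(deadline=None, max_examples=50)
@given(
    shift=st.floats(-50, 50, allow_nan=False),
    scale=st.floats(0.01, 50, allow_nan=False),
)
def test_nrz_affine_invariance(shift, scale):
    base = np.array([1.0, 2.5, 3.0, 4.5, 7.0])
    tumor_val = 5.5
    normal_a = panel({"G1": list(base)})
    normal_b = panel({"G1": list(base * scale + shift)})
    z_a = compute_nrz(pd.Series({"G1": tumor_val}), normal_a)["G1"]
    z_b = compute_nrz(pd.Series({"G1": tumor_val * scale + shift}), normal_b)["G1"]
    assert z_b == pytest.approx(z_a, rel=1e-9, abs=1e-9)


@settings(deadline=None, max_examples=50)
@given(st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=10, unique=True))
def test_nrz_and_cum_pct_monotone_in_tumor_value(tumor_values):
    normal = panel({"G1": [0.0, 1.0, 2.0, 3.0]})
    cancer = panel({"G1": [0.5, 1.5, 2.5]}, "cancer_reference")
    ordered = sorted(tumor_values)
    zs = [compute_nrz(pd.Series({"G1": x}), normal)["G1"] for x in ordered]
    ps = [compute_cum_pct(pd.Series({"G1": x}), cancer)["G1"] for x in ordered]
    assert all(a <= b for a, b in zip(zs, zs[1:]))
    assert all(a <= b for a, b in zip(ps, ps[1:]))
    # ECDF bounds: whenever the tumor value reaches the panel minimum,
    # cum_pct lies in [1/N, 1]
    for x, p in zip(ordered, ps):
        if x >= 0.5:
            assert 1 / 3 <= p <= 1


def test_planted_overexpression_recovered(default_cohort):
    """Planted overexpressed genes score higher NRZ than background genes."""
    c = default_cohort
    for profile in c.profiles[:3]:
        scores = score_patient(profile.expression, c.normal_panel, c.cancer_panel)
        planted = set(c.truth.overexpressed[profile.patient_id])
        bg = [g for g in scores.index if g not in planted]
        assert scores.loc[sorted(planted), "nrz"].mean() > scores.loc[bg, "nrz"].mean() + 2
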