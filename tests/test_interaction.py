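"""Bliss arithmetic, the interaction LR test, Holm adjustment, family runs."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from blissassay.glm import DegenerateGroupError, DesignMatrix, fit_binomial_glm
from blissassay.interaction import (
    ANTAGONISM,
    INDEPENDENT,
    SYNERGISM,
    BlissRates,
    InteractionTestResult,
    InteractionTestSpec,
    abbott_corrected_survival,
    bliss_lr_test,
    classify_interaction,
    expected_bliss_survival,
    holm_adjust,
    run_interaction_family,
)
from blissassay.generate import default_design, default_dosage_labels, simulate_assay

from conftest import (
    BLISS_EXACT_COUNTS,
    TOY_COUNTS,
    counts_design,
    four_group_dataset,
    oracle_max_loglik,
)


# -- Bliss arithmetic ------------------------------------------------------

def test_abbott_correction_arithmetic():
    assert abbott_corrected_survival(0.63, 0.90) == pytest.approx(0.70)
    assert abbott_corrected_survival(0.74, 0.74) == 1.0
    with pytest.raises(ValueError):
        abbott_corrected_survival(0.80, 0.0)
    with pytest.warns(UserWarning, match="capped"):
        assert abbott_corrected_survival(0.9, 0.8) == 1.0


def test_expected_bliss_survival_is_the_product():
    assert expected_bliss_survival(1, 1, 1) == 1
    assert expected_bliss_survival(0.9, 0.8, 0.7) == pytest.approx(0.504)
    assert expected_bliss_survival(0.6, 1.0, 0.5) == pytest.approx(0.3)
    with pytest.raises(ValueError):
        expected_bliss_survival(1.2, 0.5, 0.5)


def test_bliss_rates_bundle():
    r = BlissRates(s0=0.90, raw_a=0.72, raw_b=0.63)
    assert r.sA == pytest.approx(0.8)
    assert r.sB == pytest.approx(0.7)
    assert r.expected_combined == pytest.approx(0.504)
    assert r.expected_combined <= min(r.s0, r.raw_a, r.raw_b)


# -- the LR interaction test ----------------------------------------------

def test_toy_interaction_matches_saturated_closed_form(toy_dataset):
    spec = InteractionTestSpec(
        control_group="control", group_a="agent_a", group_b="agent_b",
        group_ab="combo", scope="overall",
    )
    res = bliss_lr_test(toy_dataset, spec)
    assert res.beta_ab == pytest.approx(-0.23111, abs=1e-5)
    # LR equals twice the gap to the independently maximized reduced model
    design, y = counts_design(TOY_COUNTS, 100)
    red = DesignMatrix(design.matrix[:, :3], design.columns[:3])
    full_ll = fit_binomial_glm(design, y, "log").loglik
    red_ll_oracle, _ = oracle_max_loglik(red, y)
    assert res.lr == pytest.approx(2 * (full_ll - red_ll_oracle), abs=1e-4)
    assert res.df == 1 and 0 < res.p_raw < 1


def test_bliss_exact_data_yields_null_result():
    ds = four_group_dataset(BLISS_EXACT_COUNTS, 1000)
    spec = InteractionTestSpec(
        control_group="control", group_a="agent_a", group_b="agent_b",
        group_ab="combo",
    )
    res = bliss_lr_test(ds, spec)
    assert res.beta_ab == pytest.approx(0.0, abs=1e-5)
    assert res.lr == pytest.approx(0.0, abs=1e-6)
    assert res.p_raw == pytest.approx(1.0, abs=1e-3)


def test_interaction_test_requires_all_four_groups(toy_dataset):
    spec = InteractionTestSpec(
        control_group="control", group_a="agent_a", group_b="agent_b",
        group_ab="missing_combo",
    )
    with pytest.raises(ValueError, match="missing_combo"):
        bliss_lr_test(toy_dataset, spec)


def test_zero_survivor_group_raises_degenerate_error():
    ds = four_group_dataset((90, 72, 63, 0), 100)
    spec = InteractionTestSpec(
        control_group="control", group_a="agent_a", group_b="agent_b",
        group_ab="combo",
    )
    with pytest.raises(DegenerateGroupError, match="combo"):
        bliss_lr_test(ds, spec)


def test_spec_groups_must_be_distinct():
    with pytest.raises(ValueError):
        InteractionTestSpec(
            control_group="control", group_a="control", group_b="agent_b",
            group_ab="combo",
        )


def test_reduced_model_prediction_obeys_bliss_identity(toy_dataset):
    """Under the fitted null model, predicted combination survival is exactly
    control x corrected-A x corrected-B survival (log-link additivity)."""
    design, y = counts_design(TOY_COUNTS, 100)
    red = DesignMatrix(design.matrix[:, :3], design.columns[:3])
    fit = fit_binomial_glm(red, y, "log")
    p0 = math.exp(fit.coef("intercept"))
    pa = p0 * math.exp(fit.coef("x_A"))
    pb = p0 * math.exp(fit.coef("x_B"))
    p_combo = math.exp(fit.coef("intercept") + fit.coef("x_A") + fit.coef("x_B"))
    assert p_combo == pytest.approx(
        expected_bliss_survival(p0, pa / p0, pb / p0), abs=1e-12
    )


# -- direction calls -------------------------------------------------------

def _result(beta, p_holm):
    spec = InteractionTestSpec(
        control_group="c", group_a="a", group_b="b", group_ab="ab"
    )
    return InteractionTestResult(
        spec=spec, beta_ab=beta, lr=1.0, p_raw=min(p_holm, 1.0), p_holm=p_holm
    )


def test_direction_calls_follow_the_sign_rule():
    assert classify_interaction(_result(-0.5, 0.044), 0.05) == SYNERGISM
    assert classify_interaction(_result(-0.5, 0.50), 0.05) == INDEPENDENT
    assert classify_interaction(_result(+0.4, 0.01), 0.05) == ANTAGONISM


def test_classify_requires_adjusted_p():
    res = _result(-0.5, 0.01)
    res.p_holm = None
    with pytest.raises(ValueError):
        classify_interaction(res)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(
    beta=st.floats(min_value=0.0, max_value=5.0, allow_nan=False),
    p=st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
    alpha=st.floats(min_value=1e-6, max_value=0.999),
)
def test_never_synergism_for_nonnegative_interaction(beta, p, alpha):
    assert classify_interaction(_result(beta, p), alpha) != SYNERGISM


# -- Holm adjustment -------------------------------------------------------

def test_holm_hand_computed_examples():
    assert holm_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])
    assert holm_adjust([0.2]) == [0.2]
    assert holm_adjust([0.5, 0.9]) == [1.0, 1.0]


def test_holm_family_of_nine_reproduces_printed_adjustment():
    """The smallest of nine p-values with min 0.004858 adjusts to 9x, i.e.
    0.0437, which reports as 0.044."""
    raw = [0.004858, 0.07, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7]
    adj = holm_adjust(raw)
    assert min(adj) == pytest.approx(9 * 0.004858)
    assert round(min(adj), 3) == 0.044


def test_holm_rejects_invalid_inputs():
    with pytest.raises(ValueError):
        holm_adjust([])
    with pytest.raises(ValueError):
        holm_adjust([0.1, 1.5])
    with pytest.raises(ValueError):
        holm_adjust([-0.1])


@settings(derandomize=True, max_examples=100, deadline=None)
@given(
    p=st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
               min_size=1, max_size=12)
)
def test_holm_properties(p):
    adj = holm_adjust(p)
    m = len(p)
    # pointwise >= raw, <= Bonferroni, capped at 1
    for raw, a in zip(p, adj):
        assert a >= raw - 1e-15
        assert a <= min(1.0, m * raw) + 1e-12
    # permutation equivariance
    perm = list(reversed(range(m)))
    adj_perm = holm_adjust([p[i] for i in perm])
    assert adj_perm == pytest.approx([adj[i] for i in perm])
    # monotone: larger raw p never gets smaller adjusted p
    for i in range(m):
        for j in range(m):
            if p[i] <= p[j]:
                assert adj[i] <= adj[j] + 1e-12


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    p=st.lists(st.floats(min_value=1e-8, max_value=1.0, allow_nan=False),
               min_size=1, max_size=10)
)
def test_holm_matches_statsmodels(p):
    multipletests = pytest.importorskip("statsmodels.stats.multitest").multipletests
    ref = multipletests(p, method="holm")[1]
    assert holm_adjust(p) == pytest.approx(list(ref), abs=1e-12)


# -- family runner ---------------------------------------------------------

def test_single_test_family_adjusted_equals_raw(toy_dataset):
    fam = run_interaction_family(
        toy_dataset, {"only": 1440.0}, scopes=("overall",), alpha=0.05,
        control_group="control",
    )
    assert len(fam.results) == 1
    r = fam.results[0]
    assert r.p_holm == pytest.approx(r.p_raw)
    assert r.direction in (SYNERGISM, ANTAGONISM, INDEPENDENT)


def test_full_battery_structure_and_families():
    data = simulate_assay(default_design(seed=21))
    fam = run_interaction_family(data, default_dosage_labels())
    frame = fam.to_frame()
    assert len(frame) == 12
    assert len(fam.families["overall"]) == 3
    assert len(fam.families["stage-specific"]) == 9
    # Holm within family: adjusted >= raw, capped at 1
    ok = frame[frame["error"].isna()]
    assert (ok["p_holm"] >= ok["p_raw"] - 1e-12).all()
    assert (ok["p_holm"] <= 1.0).all()
    for col in ("label", "scope", "beta_AB", "LR", "p_raw", "p_holm", "call"):
        assert col in frame.columns


def test_failed_member_is_recorded_not_dropped():
    data = simulate_assay(default_design(seed=21))
    df = data.df.copy()
    # force zero survivors of the larval stage in one combination group
    mask = df["group_label"] == "combo_low"
    df.loc[mask, "fate"] = "died"
    df.loc[mask, "fate_day"] = 3
    df.loc[mask, "fate_stage"] = "larva"
    from blissassay.assay import AssayDataset

    broken = AssayDataset(df, data.schedule, control_group="control_pos")
    fam = run_interaction_family(broken, default_dosage_labels())
    frame = fam.to_frame()
    assert len(frame) == 12
    failed = frame[frame["error"].notna()]
    assert set(failed["label"]) == {
        "low:overall", "low:larva", "low:prepupa", "low:pupa"
    }
    # surviving members of each family still get adjusted p-values
    ok = frame[frame["error"].isna()]
    assert ok["p_holm"].notna().all()


def test_custom_family_definition():
    data = simulate_assay(default_design(seed=22))
    labels = [f"{d}:{s}" for d in ("low", "med", "high")
              for s in ("overall", "larva", "prepupa", "pupa")]
    fam = run_interaction_family(
        data, default_dosage_labels(), families={"all": labels}
    )
    assert len(fam.families["all"]) == 12
    raws = [r.p_raw for r in fam.results]
    adj = holm_adjust(raws)
    assert [r.p_holm for r in fam.results] == pytest.approx(adj)


def test_family_serialization_roundtrip(tmp_path, toy_dataset):
    import json

    fam = run_interaction_family(
        toy_dataset, {"only": 1440.0}, scopes=("overall",),
        control_group="control",
    )
    payload = json.loads(fam.to_json())
    assert payload["alpha"] == 0.05
    assert len(payload["tests"]) == 1
    out = tmp_path / "fam.tsv"
    fam.to_tsv(out)
    back = pd.read_csv(out, sep="\t")
    assert back.loc[0, "beta_AB"] == pytest.approx(fam.results[0].beta_ab)
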