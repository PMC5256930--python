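"""The four-test battery: regression machinery, classification, batteries."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from citscreen import (
    CIT,
    CollinearityError,
    SyntheticConfig,
    classify,
    cit_forward,
    cit_reverse,
    fit_model,
    generate,
    generate_replicates,
    run_battery,
)
from citscreen.cit import (
    CAUSAL,
    CAUSAL_MARGINAL,
    INDEPENDENT,
    LABELS,
    NOT_ASSESSED,
    REACTIVE,
    UNDETERMINED,
)
from conftest import dip_design, ols_partial_f

# ------------------------------------------------------------------ fit_model


@pytest.mark.parametrize("coding", ["categorical", "additive"])
@pytest.mark.parametrize("formula_id", [1, 2, 3, 4])
def test_model_pvalues_match_normal_equations_oracle(
    small_causal_frame, formula_id, coding
):
    f = small_causal_frame
    dips = f["diplotype"].to_numpy(object)
    r = f["expr"].to_numpy()
    t = f["trait"].to_numpy()
    fit = fit_model(formula_id, dips, r, t, coding=coding)
    D = dip_design(dips, coding)
    designs = {
        1: (t, D, []),
        2: (r, D, [t.reshape(-1, 1)]),
        3: (t, r.reshape(-1, 1), [D]),
        4: (t, D, [r.reshape(-1, 1)]),
    }
    y, tested, cond = designs[formula_id]
    f_oracle, p_oracle = ols_partial_f(y, tested, cond)
    assert abs(fit.f_stat - f_oracle) < 1e-10
    assert abs(fit.p_dependent - p_oracle) < 1e-10


def test_model1_constant_trait_gives_p_one_and_zero_effects():
    dips = np.repeat(["B/B", "B/C", "C/C"], 5)
    fit = fit_model(1, dips, np.arange(15.0), np.full(15, 7.0))
    assert fit.p_dependent == 1.0
    np.testing.assert_allclose(fit.params[1:], 0.0, atol=1e-10)
    assert fit.beta0 == pytest.approx(7.0)


def test_model4_absorbs_genotype_effect_under_strong_mediation(large_causal_frame):
    res = CIT.from_dataframe(large_causal_frame, "expr", "trait").fit()
    assert res.p1 < 1e-10 and res.p2 < 1e-10 and res.p3 < 1e-10
    assert res.p4 > 0.05
    assert res.label == CAUSAL


def test_expression_collinear_with_categorical_diplotype_raises():
    dips = np.repeat(["B/B", "B/C", "C/C"], 5)
    r = np.array([{"B/B": 0.0, "B/C": 1.0, "C/C": 2.0}[d] for d in dips])
    t = np.random.default_rng(0).normal(size=15)
    with pytest.raises(CollinearityError):
        fit_model(3, dips, r, t, coding="categorical")


def test_expression_identical_to_trait_raises_named_error():
    dips = np.repeat(["B/B", "B/C", "C/C"], 5)
    t = np.random.default_rng(1).normal(size=15)
    with pytest.raises(CollinearityError, match="identical to the response"):
        fit_model(3, dips, t, t)


# ------------------------------------------------------------------ batteries


def test_failed_test2_stops_battery_and_flags_not_assessed():
    f = generate(SyntheticConfig(architecture="null", seed=0)).frame
    res = CIT.from_dataframe(f, "expr", "trait").fit()
    assert res.p2 >= 0.05
    assert math.isnan(res.p3) and math.isnan(res.p4)
    assert not res.p3_assessed and not res.p4_assessed
    assert "NA" in res.summary()


def test_reverse_battery_is_forward_with_roles_swapped(small_causal_frame):
    f = small_causal_frame
    dips = f["diplotype"].to_numpy(object)
    r = f["expr"].to_numpy()
    t = f["trait"].to_numpy()
    fwd_swapped = cit_forward(dips, t, r, early_stop=False)
    rev = cit_reverse(dips, r, t, early_stop=False)
    for key in ("p1", "p2", "p3", "p4"):
        assert rev[key] == fwd_swapped[key]


def test_triplet_validation():
    with pytest.raises(ValueError):
        CIT([1.0] * 5, [1.0] * 5, ["B/B", "B/B", "B/C", "B/C", "C/C"])
    with pytest.raises(Exception):
        CIT([1.0] * 6, [2.0] * 6, ["B/B"] * 6)  # missing classes


# ------------------------------------------------------------------- classify


@pytest.mark.parametrize(
    "pvals, expected",
    [
        # reported triplet outcomes: mediated WAT traits, a parallel lipid
        # trait, and a marginal mediation call
        ((0.019, 0.00024, 0.025, 0.58), CAUSAL),
        ((0.019, 0.024, 0.29, 0.030), INDEPENDENT),
        ((0.019, 0.00054, 0.058, 0.78), CAUSAL_MARGINAL),
        ((0.5, 0.001, 0.001, 0.5), NOT_ASSESSED),  # trait fails Test 1
        ((0.019, 0.071, float("nan"), float("nan")), NOT_ASSESSED),
        ((0.019, 0.001, 0.5, 0.5), UNDETERMINED),
        ((0.019, 0.001, 0.001, 0.001), UNDETERMINED),  # no reverse info
    ],
)
def test_classify_rule_table(pvals, expected):
    assert classify(*pvals) == expected


def test_classify_reactive_requires_fully_passing_reverse_battery():
    forward = (0.002, 0.0027, 0.015, 0.0031)  # all conditional tests reject
    assert classify(*forward) == UNDETERMINED
    assert classify(*forward, 0.001, 0.001, 0.5) == REACTIVE
    assert classify(*forward, 0.001, 0.001, 0.01) == UNDETERMINED  # p4r rejects
    # early-stopped forward battery + passing reverse: trait-mediated chain
    assert classify(0.002, 0.29, float("nan"), float("nan"), 0.001, 0.001, 0.5) == REACTIVE


def test_classify_treats_prescreened_test1_as_passed():
    assert classify(None, 0.001, 0.001, 0.5) == CAUSAL


@settings(derandomize=True, max_examples=200)
@given(
    ps=st.lists(
        st.one_of(st.floats(0.0, 1.0), st.just(float("nan"))), min_size=7, max_size=7
    )
)
def test_classify_is_total_over_pvalue_patterns(ps):
    assert classify(*ps) in LABELS


# ---------------------------------------------------------------- run_battery


def test_planted_causal_gene_is_the_only_causal_call():
    f = generate(
        SyntheticConfig(architecture="causal", n_sets=20, n_extra_genes=2, seed=15)
    ).frame
    res = run_battery(f, genes=["expr", "indep_1", "indep_2"], traits=["trait"])
    labels = res.set_index("gene")["label"]
    assert labels["expr"] == CAUSAL
    assert (labels.drop("expr") != CAUSAL).all()


def test_null_data_rarely_produces_causal_calls():
    n_causal = 0
    for ds in generate_replicates(SyntheticConfig(architecture="null"), 100, seed=5):
        res = CIT.from_dataframe(ds.frame, "expr", "trait").fit()
        n_causal += res.label in (CAUSAL, CAUSAL_MARGINAL)
    assert n_causal / 100 <= 0.05


def test_run_battery_row_layout(small_causal_frame):
    res = run_battery(small_causal_frame, genes=["expr"], traits=["trait"])
    assert list(res.columns) == [
        "gene", "trait", "p1", "p2", "p3", "p4", "p2r", "p3r", "p4r", "label",
    ]
    assert len(res) == 1
    assert res["label"].iloc[0] in LABELS
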