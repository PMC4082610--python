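"""Conservation score, divergence, inverse classification, enrichment tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asconsv.comparative import (
    INDUCED_SENSE,
    NO_CATEGORY,
    REPRESSED_SENSE,
    classify_inverse,
    conservation_enrichment,
    conservation_score,
    correlation_matrix,
    distribution_shift_test,
    expression_variation,
    fisher_from_counts,
    inverse_summary,
    join_homologs,
    pair_inverse_flags,
    proportion_test,
)


# ---------------------------------------------------------------------------
# conservation score


def test_equal_overlap_fractions_score_one():
    rec = conservation_score(1000, 500, 800, 400)  # C = 0.5 in both
    assert rec["S"] == pytest.approx(1.0)


def test_disparate_fractions_score():
    # C_Sc = 0.2, C_Sp = 0.6 -> S = 0.2 / 0.4 = 0.5
    rec = conservation_score(1000, 200, 1000, 600)
    assert rec["S"] == pytest.approx(0.5)


def test_absent_overlap_scores_zero():
    assert conservation_score(1000, 500, 1000, 0)["S"] == 0.0
    assert conservation_score(1000, 0, 1000, 0)["S"] == 0.0


def test_overlap_longer_than_sense_is_fatal():
    with pytest.raises(ValueError):
        conservation_score(100, 200, 100, 50)


@given(
    st.integers(1, 5000), st.integers(1, 5000),
    st.floats(0, 1), st.floats(0, 1),
)
def test_score_symmetric_and_bounded(l_sc, l_sp, f_sc, f_sp):
    o_sc, o_sp = round(l_sc * f_sc), round(l_sp * f_sp)
    a = conservation_score(l_sc, o_sc, l_sp, o_sp)["S"]
    b = conservation_score(l_sp, o_sp, l_sc, o_sc)["S"]  # species swapped
    assert a == pytest.approx(b)
    assert 0.0 <= a <= 1.0 + 1e-12
    c_sc, c_sp = o_sc / l_sc, o_sp / l_sp
    if c_sc == c_sp and c_sc > 0:
        assert a == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# expression variation


def test_variation_zero_when_equal():
    assert expression_variation(3.7, 3.7) == 0.0


def test_variation_log2_magnitude():
    assert expression_variation(4.0, 1.0) == pytest.approx(2.0)


def test_variation_symmetric():
    assert expression_variation(5.0, 2.0) == expression_variation(2.0, 5.0)


def test_variation_rejects_nonpositive():
    with pytest.raises(ValueError):
        expression_variation(0.0, 1.0)


# ---------------------------------------------------------------------------
# correlation matrix


def test_correlation_matrix_duplicated_and_inverted_columns():
    rng = np.random.default_rng(0)
    x = rng.lognormal(1, 1, size=50)
    table = pd.DataFrame({"a": x, "b": x, "c": 1.0 / x})
    mat = correlation_matrix(table)
    assert mat.loc["a", "b"] == pytest.approx(1.0)
    assert mat.loc["a", "c"] == pytest.approx(-1.0)  # negation in log space
    assert np.allclose(mat.values, mat.values.T)
    assert np.allclose(np.diag(mat.values), 1.0)


def test_correlation_matrix_needs_three_rows():
    table = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0]})
    with pytest.raises(ValueError, match="at least 3"):
        correlation_matrix(table)


# ---------------------------------------------------------------------------
# homology join


def _pairs(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "orf_t_id", "antisense_id", "chrom", "overlap_start",
            "overlap_end", "overlap_len", "sense_len", "primary",
        ],
    )


def test_join_empty_map_is_empty():
    homologs = pd.DataFrame(columns=["sc_orf_id", "sp_orf_id"])
    out = join_homologs(_pairs([]), _pairs([]), homologs, {}, {})
    assert len(out) == 0


def test_join_pair_in_one_species_gives_zero_overlap_in_other():
    homologs = pd.DataFrame({"sc_orf_id": ["Y1"], "sp_orf_id": ["Z1"]})
    pairs_sc = _pairs([("u1", "a1", "chrI", 0, 100, 100, 1000, True)])
    out = join_homologs(
        pairs_sc, _pairs([]), homologs,
        {"u1": "Y1"}, {"v1": "Z1"},
    )
    assert len(out) == 1
    assert out.iloc[0]["O_Sp"] == 0
    assert out.iloc[0]["S"] == 0.0


def test_join_matched_pairs_one_row_each():
    homologs = pd.DataFrame({"sc_orf_id": ["Y1", "Y2"], "sp_orf_id": ["Z1", "Z2"]})
    pairs_sc = _pairs(
        [
            ("u1", "a1", "chrI", 0, 100, 500, 1000, True),
            ("u2", "a2", "chrI", 0, 100, 300, 600, True),
        ]
    )
    pairs_sp = _pairs(
        [
            ("v1", "b1", "chrI", 0, 100, 400, 800, True),
            ("v2", "b2", "chrI", 0, 100, 300, 600, True),
        ]
    )
    out = join_homologs(
        pairs_sc, pairs_sp, homologs,
        {"u1": "Y1", "u2": "Y2"}, {"v1": "Z1", "v2": "Z2"},
    )
    assert len(out) == 2
    s = out.set_index("sc_orf_id")["S"]
    assert s["Y1"] == pytest.approx(1.0)  # 0.5 vs 0.5
    assert s["Y2"] == pytest.approx(1.0)


def test_join_duplicated_map_is_fatal():
    homologs = pd.DataFrame({"sc_orf_id": ["Y1", "Y1"], "sp_orf_id": ["Z1", "Z2"]})
    with pytest.raises(ValueError, match="one-to-one"):
        join_homologs(_pairs([]), _pairs([]), homologs, {}, {})


# ---------------------------------------------------------------------------
# inverse-expression classification


def _pair_expr(rows):
    cols = [
        f"{kind}_{sp}_{cond}"
        for kind in ("sense", "anti")
        for sp in ("Sc", "Sp")
        for cond in ("ML", "ES", "HS")
    ]
    return pd.DataFrame(rows, columns=cols)


def _one_pair(sense_fc, anti_fc, cond="ES"):
    """One pair, Sc only carrying the given fold changes in `cond`."""
    row = {}
    for kind in ("sense", "anti"):
        for sp in ("Sc", "Sp"):
            for c in ("ML", "ES", "HS"):
                row[f"{kind}_{sp}_{c}"] = 10.0
    row[f"sense_Sc_{cond}"] = 10.0 * sense_fc
    row[f"anti_Sc_{cond}"] = 10.0 * anti_fc
    return pd.DataFrame([row])


def test_strict_rule_requires_both_members():
    rec = classify_inverse(_one_pair(0.5, 2.0), fold_threshold=1.5)
    hit = rec[(rec.species == "Sc") & (rec.condition == "ES")].iloc[0]
    assert hit["category"] == REPRESSED_SENSE
    assert hit["significant"]

    rec = classify_inverse(_one_pair(0.8, 2.0), fold_threshold=1.5)
    hit = rec[(rec.species == "Sc") & (rec.condition == "ES")].iloc[0]
    assert hit["category"] == REPRESSED_SENSE  # direction still inverse
    assert not hit["significant"]  # 0.8 > 1/1.5


def test_either_mode_relaxes_the_rule():
    rec = classify_inverse(_one_pair(0.8, 2.0), fold_threshold=1.5, mode="either")
    hit = rec[(rec.species == "Sc") & (rec.condition == "ES")].iloc[0]
    assert hit["significant"]


def test_no_change_is_no_category():
    rec = classify_inverse(_one_pair(1.0, 1.0))
    assert (rec["category"] == NO_CATEGORY).all()


def test_induced_sense_mirror_rule():
    rec = classify_inverse(_one_pair(2.0, 0.5), fold_threshold=1.5)
    hit = rec[(rec.species == "Sc") & (rec.condition == "ES")].iloc[0]
    assert hit["category"] == INDUCED_SENSE and hit["significant"]


def test_nonpositive_ml_is_fatal():
    df = _one_pair(0.5, 2.0)
    df.loc[0, "sense_Sc_ML"] = 0.0
    with pytest.raises(ValueError, match="ML"):
        classify_inverse(df)


def _brute_force(pair_expr, threshold, mode):
    """Literal per-cell re-derivation of categories and significance."""
    rows = []
    for idx, r in pair_expr.iterrows():
        for sp in ("Sc", "Sp"):
            for cond in ("ES", "HS"):
                fs = r[f"sense_{sp}_{cond}"] / r[f"sense_{sp}_ML"]
                fa = r[f"anti_{sp}_{cond}"] / r[f"anti_{sp}_ML"]
                if fs < 1 and fa > 1:
                    cat = REPRESSED_SENSE
                    checks = [fs <= 1 / threshold, fa >= threshold]
                elif fs > 1 and fa < 1:
                    cat = INDUCED_SENSE
                    checks = [fs >= threshold, fa <= 1 / threshold]
                else:
                    cat, checks = NO_CATEGORY, [False]
                sig = (
                    False
                    if cat == NO_CATEGORY
                    else (all(checks) if mode == "both" else any(checks))
                )
                rows.append((idx, sp, cond, cat, sig))
    return rows


@given(st.integers(0, 2**31 - 1), st.sampled_from(["both", "either"]))
@settings(max_examples=25)
def test_classification_matches_brute_force(seed, mode):
    rng = np.random.default_rng(seed)
    n = rng.integers(1, 100)
    vals = rng.lognormal(1.0, 1.0, size=(n, 12))
    pair_expr = _pair_expr(vals)
    rec = classify_inverse(pair_expr, fold_threshold=1.5, mode=mode)
    got = list(
        rec[["pair", "species", "condition", "category", "significant"]]
        .itertuples(index=False, name=None)
    )
    assert got == _brute_force(pair_expr, 1.5, mode)


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=15)
def test_significant_at_higher_threshold_is_subset(seed):
    rng = np.random.default_rng(seed)
    pair_expr = _pair_expr(rng.lognormal(1.0, 1.0, size=(40, 12)))
    strict = classify_inverse(pair_expr, fold_threshold=1.5)
    loose = classify_inverse(pair_expr, fold_threshold=1.0)
    key = ["pair", "species", "condition"]
    s = set(map(tuple, strict[strict.significant][key].values))
    l = set(map(tuple, loose[loose.significant][key].values))
    assert s <= l


def test_inverse_summary_accounting():
    # pair P1: repressed-sense inverse in both species in ES only;
    # pair P2: in Sc only, in HS only
    rows = []
    for i, row in enumerate(
        [_one_pair(0.5, 2.0, "ES"), _one_pair(0.5, 2.0, "HS")]
    ):
        row.index = [f"P{i + 1}"]
        rows.append(row)
    expr = pd.concat(rows)
    expr.loc["P1", "sense_Sp_ES"] = 5.0  # 10 * 0.5
    expr.loc["P1", "anti_Sp_ES"] = 20.0
    rec = classify_inverse(expr, fold_threshold=1.5)
    summ = inverse_summary(rec)
    assert summ.loc[REPRESSED_SENSE, ("both-species", "ES-only")] == 1
    assert summ.loc[REPRESSED_SENSE, ("Sc-only", "HS-only")] == 1
    assert summ.loc[REPRESSED_SENSE, ("both-species", "total")] == 1
    assert summ.loc[INDUCED_SENSE].sum() == 0


# ---------------------------------------------------------------------------
# Fisher / proportion / rank-sum tests


def test_fisher_balanced_table_p_one():
    assert fisher_from_counts([[10, 10], [10, 10]])["p_value"] == pytest.approx(1.0)


def test_fisher_fully_separated_table():
    # 5-0 / 0-5: two-sided exact p = 2 / C(10,5) = 2/252
    res = fisher_from_counts([[5, 0], [0, 5]])
    assert res["p_value"] == pytest.approx(2 / 252)


def test_fisher_empty_margin_is_informative():
    with pytest.raises(ValueError, match="margin"):
        fisher_from_counts([[0, 0], [3, 4]])


def test_enrichment_builds_expected_table():
    records = pd.DataFrame(
        {
            "sc_orf_id": ["a", "b", "c", "d"],
            "S": [0.9, 0.95, 0.2, 0.1],
        }
    )
    flags = pd.DataFrame(
        {
            "inverse_both_ES": [True, False, False, False],
            "inverse_any_ES": [True, True, True, True],
        },
        index=["a", "b", "c", "d"],
    )
    res = conservation_enrichment(records, flags, "ES")
    assert res["table"].tolist() == [[1, 1], [0, 2]]


def test_proportion_test_null_centered():
    assert proportion_test(10, 100, 10, 100) >= 0.5


def test_proportion_test_detects_difference():
    # exact oracle by binomial enumeration under the pooled null
    k1, n1, k2, n2 = 10, 10, 0, 10
    p_pool = (k1 + k2) / (n1 + n2)
    exact = 0.0
    for a in range(n1 + 1):
        for b in range(n2 + 1):
            if a / n1 - b / n2 >= k1 / n1 - k2 / n2:
                exact += (
                    math.comb(n1, a) * p_pool**a * (1 - p_pool) ** (n1 - a)
                    * math.comb(n2, b) * p_pool**b * (1 - p_pool) ** (n2 - b)
                )
    p = proportion_test(k1, n1, k2, n2)
    assert p < 0.01
    assert exact < 0.01  # the approximation agrees with the exact tail


def test_proportion_test_degenerate_is_fatal():
    with pytest.raises(ValueError):
        proportion_test(1, 0, 1, 10)


def test_rank_sum_identical_samples():
    assert distribution_shift_test([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]) >= 0.5


def test_rank_sum_fully_separated_exact():
    # {6..10} vs {1..5}: one-sided exact p = 1/252
    p = distribution_shift_test([6, 7, 8, 9, 10], [1, 2, 3, 4, 5])
    assert p == pytest.approx(1 / 252)


def test_rank_sum_invariant_under_monotone_transform():
    a = [2.0, 5.0, 9.0, 11.0]
    b = [1.0, 3.0, 4.0, 8.0]
    assert distribution_shift_test(a, b) == pytest.approx(
        distribution_shift_test(np.exp(a), np.exp(b))
    )


def test_rank_sum_degenerate_input_is_informative():
    with pytest.raises(ValueError, match="tied"):
        distribution_shift_test([2.0, 2.0], [2.0, 2.0])
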