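"""Normalization, the NB Wald stage, and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import adipomir as am
from adipomir.countmatrix import ValidationError


def _cm(counts: np.ndarray, sample_ids=None) -> am.CountMatrix:
    n_m, n_s = counts.shape
    sample_ids = sample_ids or [f"s{i}" for i in range(n_s)]
    meta = pd.DataFrame({"cell_type": ["preAC"] * n_s,
                         "condition": ["lean"] * n_s},
                        index=pd.Index(sample_ids, name="sample_id"))
    return am.CountMatrix(
        counts=pd.DataFrame(counts, index=[f"m{i}" for i in range(n_m)],
                            columns=sample_ids),
        sample_meta=meta)


# ------------------------------------------------------------- size factors

def test_size_factors_identical_samples_are_one():
    cm = _cm(np.array([[10, 10], [50, 50], [3, 3]]))
    sf = am.size_factors(cm)
    assert np.allclose(sf, 1.0)


def test_size_factors_doubled_sample_closed_form():
    """B = 2A for every miRNA -> factors (1/sqrt(2), sqrt(2)) against the
    geometric-mean reference."""
    a = np.array([10, 50, 3, 7, 120])
    cm = _cm(np.column_stack([a, 2 * a]))
    sf = am.size_factors(cm)
    assert sf.iloc[0] == pytest.approx(1 / np.sqrt(2))
    assert sf.iloc[1] == pytest.approx(np.sqrt(2))


def test_size_factors_toy_matrix_matches_brute_force():
    """5x3 toy matrix; expected factors from applying the median-of-ratios
    definition literally (log-geomean reference, per-sample median)."""
    counts = np.array([[10, 20, 5],
                       [100, 80, 120],
                       [50, 55, 60],
                       [5, 2, 9],
                       [200, 150, 300]])
    sf = am.size_factors(_cm(counts))
    assert np.allclose(sf, [1.0, 0.81096027, 1.2164404])


def test_size_factors_scale_equivariance():
    rng = np.random.default_rng(0)
    counts = rng.poisson(50, size=(40, 4)) + 1
    sf1 = am.size_factors(_cm(counts))
    scaled = counts.astype(float).copy()
    scaled[:, 2] *= 3.0
    sf2 = am.size_factors(_cm(scaled.astype(int)))
    # the reference shifts by 3^(1/4); sample 2's factor gains the rest
    assert sf2.iloc[2] / sf1.iloc[2] == pytest.approx(3 * sf2.iloc[0] / sf1.iloc[0])


def test_size_factors_no_common_mirna_raises():
    counts = np.array([[0, 5], [5, 0]])
    with pytest.raises(ValidationError, match="pseudo-reference"):
        am.size_factors(_cm(counts))


# ---------------------------------------------------------------------- BH

def test_bh_hand_example():
    assert np.allclose(am.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])


def test_bh_edge_cases():
    assert np.allclose(am.bh_adjust([1.0, 1.0, 1.0]), 1.0)
    assert am.bh_adjust([0.2])[0] == pytest.approx(0.2)
    out = am.bh_adjust([0.01, np.nan, 0.04])
    assert np.isnan(out[1])
    assert np.allclose(out[[0, 2]], [0.02, 0.04])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValidationError):
        am.bh_adjust([0.5, 1.5])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
def test_bh_matches_statsmodels_and_dominates_p(pvals):
    from statsmodels.stats.multitest import multipletests
    q = am.bh_adjust(pvals)
    assert (q >= np.asarray(pvals) - 1e-12).all()
    _, q_sm, _, _ = multipletests(pvals, method="fdr_bh")
    assert np.allclose(q, q_sm)


# ------------------------------------------------------------------ call_dems

def _cm_groups(rows, n_a, n_b):
    arr = np.asarray(rows)
    ids_a = [f"a{i}" for i in range(n_a)]
    ids_b = [f"b{i}" for i in range(n_b)]
    cm = _cm(arr, ids_a + ids_b)
    return cm, ids_a, ids_b


def test_call_dems_identical_groups_fc_zero():
    rows = np.array([[10, 10, 10, 10, 10, 10], [7, 7, 7, 7, 7, 7]])
    cm, a, b = _cm_groups(rows, 3, 3)
    ones = pd.Series(1.0, index=a + b)
    res = am.call_dems(cm, a, b, size_factors_override=ones)
    assert res.table.loc["m0", "log2fc"] == 0
    assert res.table.loc["m0", "direction"] == "none"


def test_call_dems_exact_fourfold_ratio():
    rows = np.array([[10, 10, 10, 40, 40, 40], [20, 20, 20, 20, 20, 20]])
    cm, a, b = _cm_groups(rows, 3, 3)
    ones = pd.Series(1.0, index=a + b)
    res = am.call_dems(cm, a, b, size_factors_override=ones)
    assert res.table.loc["m0", "log2fc"] == pytest.approx(2.0)


def test_call_dems_antisymmetry():
    spec = am.SimulationSpec(n_mirnas=200, seed=13)
    cm, _ = am.generate_counts(spec)
    pre = cm.samples("preAC")
    ac = cm.samples("AC")
    fwd = am.call_dems(cm, pre, ac)
    rev = am.call_dems(cm, ac, pre)
    f = fwd.table["log2fc"]
    r = rev.table["log2fc"]
    mask = f.notna()
    assert np.allclose(f[mask], -r[mask])


def test_call_dems_all_zero_mirna_undefined_p():
    rows = np.array([[10, 12, 9, 30, 33, 29], [0, 0, 0, 0, 0, 0]])
    cm, a, b = _cm_groups(rows, 3, 3)
    ones = pd.Series(1.0, index=a + b)
    res = am.call_dems(cm, a, b, size_factors_override=ones)
    assert np.isnan(res.table.loc["m1", "pvalue"])
    assert np.isnan(res.table.loc["m1", "qvalue"])
    assert res.table.loc["m1", "direction"] == "none"


def test_call_dems_validation_errors():
    rows = np.ones((3, 6), dtype=int) * 5
    cm, a, b = _cm_groups(rows, 3, 3)
    with pytest.raises(ValidationError, match="overlap"):
        am.call_dems(cm, a, a)
    with pytest.raises(ValidationError, match="at least 2"):
        am.call_dems(cm, a[:1], b)
    with pytest.raises(ValidationError, match="unknown"):
        am.call_dems(cm, a, b + ["nope"])


def test_qvalue_dominates_pvalue(default_contrasts):
    for res in default_contrasts.values():
        t = res.table.dropna(subset=["pvalue"])
        assert (t["qvalue"] >= t["pvalue"] - 1e-12).all()


def test_null_simulation_type_one_error_calibrated():
    """Null NB simulation at 6 vs 6, dispersion 0.1: the raw p<0.05
    fraction must sit near the nominal level."""
    spec = am.SimulationSpec(n_mirnas=2000, n_pre_lean=3, n_pre_obese=3,
                             n_ac_lean=3, n_ac_obese=3, class_fractions={},
                             dispersion=0.1, seed=11)
    cm, _ = am.generate_counts(spec)
    res = am.call_dems(cm, cm.samples("preAC"), cm.samples("AC"))
    p = res.table["pvalue"].dropna()
    assert 0.03 <= (p < 0.05).mean() <= 0.07


def test_planted_dem_recovery(default_sim, default_contrasts):
    """On the default synthetic design, planted common DEMs reach Q<0.01
    in both per-condition contrasts and nulls almost never do."""
    _, _, truth = default_sim
    lean, obese = default_contrasts["L_Ag"], default_contrasts["O_Ag"]
    common = truth.of_class("common_up", "common_down")
    both_sig = (lean.table.loc[common, "qvalue"] < 0.01) & \
               (obese.table.loc[common, "qvalue"] < 0.01)
    assert both_sig.mean() >= 0.90
    nulls = truth.of_class("null")
    either = (lean.table.loc[nulls, "qvalue"].fillna(1) < 0.01) | \
             (obese.table.loc[nulls, "qvalue"].fillna(1) < 0.01)
    assert either.mean() <= 0.02


def test_de_table_round_trip(tmp_path, default_contrasts):
    res = default_contrasts["L_Ag"]
    path = tmp_path / "de.tsv"
    res.write(path)
    back = am.read_contrast(path)
    assert back.contrast == "L_Ag"
    assert back.n_up == res.n_up and back.n_down == res.n_down
    pd.testing.assert_frame_equal(back.table, res.table, check_exact=False,
                                  rtol=1e-12)


def test_against_pydeseq2_on_small_fixture():
    """Independent cross-check: size factors agree exactly with DESeq2's
    median-of-ratios and log2FC estimates correlate strongly with
    pydeseq2's Wald fit on the same counts (the two engines differ in
    dispersion handling, so only close agreement is expected)."""
    pydeseq2 = pytest.importorskip("pydeseq2")
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    spec = am.SimulationSpec(n_mirnas=150, n_pre_lean=4, n_pre_obese=4,
                             n_ac_lean=4, n_ac_obese=4, seed=17,
                             class_fractions={"common": 0.3})
    cm, _ = am.generate_counts(spec)
    pre, ac = cm.samples("preAC"), cm.samples("AC")
    keep = (cm.counts > 0).all(axis=1)
    sub = cm.counts[keep]

    meta = pd.DataFrame({"group": ["pre"] * len(pre) + ["ac"] * len(ac)},
                        index=pre + ac)
    dds = DeseqDataSet(counts=sub[pre + ac].T, metadata=meta,
                       design="~group", quiet=True)
    dds.deseq2()
    stats = DeseqStats(dds, contrast=["group", "ac", "pre"], quiet=True)
    stats.summary()

    sf_ours = am.size_factors(sub[pre + ac])
    sf_theirs = pd.Series(dds.obs["size_factors"].to_numpy(), index=pre + ac)
    assert np.allclose(sf_ours, sf_theirs, rtol=1e-6)

    ours = am.call_dems(am.CountMatrix(sub, cm.sample_meta), pre, ac)
    merged = pd.DataFrame({"ours": ours.table["log2fc"],
                           "theirs": stats.results_df["log2FoldChange"]}).dropna()
    r = np.corrcoef(merged["ours"], merged["theirs"])[0, 1]
    assert r > 0.99
    assert np.abs(merged["ours"] - merged["theirs"]).median() < 0.1
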