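"""Four DE tests against independent oracles; consensus logic; calibration."""
import numpy as np
import pytest
import scipy.stats as st
from scipy.optimize import minimize

import scburden as sb
from scburden.de import (adjust, bimod_loglik, consensus, de_bimod,
                         de_hurdle, de_ttest, de_wilcoxon, log2_fold_change,
                         run_consensus_de, run_de, TEST_NAMES)


# --------------------------------------------------------------- wilcoxon

def test_wilcoxon_identical_groups_p_one():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    assert de_wilcoxon(a, a) == 1.0


def test_wilcoxon_exact_separated_triples():
    """{1,2,3} vs {4,5,6}: 2 of C(6,3)=20 rank assignments are as extreme."""
    p = de_wilcoxon([1, 2, 3], [4, 5, 6])
    assert p == pytest.approx(0.1, abs=1e-12)


def test_wilcoxon_exact_matches_scipy_enumeration(rng):
    """Tie-free small samples: exact path equals scipy's exact method."""
    for _ in range(10):
        a = rng.normal(size=6)
        b = rng.normal(size=7)
        ours = de_wilcoxon(a, b)
        ref = st.mannwhitneyu(a, b, alternative="two-sided",
                              method="exact").pvalue
        assert ours == pytest.approx(ref, abs=1e-12)


def test_wilcoxon_type_one_error_calibrated(rng):
    rejections = 0
    reps = 400
    for _ in range(reps):
        a = rng.normal(size=200)
        b = rng.normal(size=200)
        rejections += de_wilcoxon(a, b) < 0.05
    assert 0.03 <= rejections / reps <= 0.07


# ----------------------------------------------------------------- t test

def test_ttest_identical_groups_p_one():
    a = np.array([1.0, 2.0, 3.0])
    assert de_ttest(a, a) == 1.0


def test_ttest_matches_welch_formula_4v4():
    a = np.array([1.1, 2.3, 0.7, 1.9])
    b = np.array([3.4, 2.8, 4.1, 3.0])
    va, vb = a.var(ddof=1) / 4, b.var(ddof=1) / 4
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / 3 + vb ** 2 / 3)
    expected = 2 * st.t.sf(abs(t), df)
    assert de_ttest(a, b) == pytest.approx(expected, abs=1e-10)


def test_ttest_zero_variance_degenerate():
    const = np.array([2.0, 2.0, 2.0])
    assert de_ttest(const, const + 1) == 0.0
    assert de_ttest(const, const) == 1.0


# ------------------------------------------------------------------ bimod

def test_bimod_identical_distributions_p_near_one(rng):
    x = np.concatenate([np.zeros(40), rng.normal(5, 1, 60)])
    rng.shuffle(x)
    p = de_bimod(x[:50], x[50:])
    assert p > 0.2


def test_bimod_mle_matches_numeric_optimiser(rng):
    """Closed-form alternative-model MLE equals direct likelihood
    maximisation on a 20-cell example (to 1e-6)."""
    a = np.concatenate([np.zeros(4), rng.normal(3, 0.8, 6)])
    b = np.concatenate([np.zeros(7), rng.normal(2, 0.8, 3)])
    ll_closed, _, sigma = bimod_loglik(a, b, shared=False)

    def negll(params):
        mu_a, mu_b, log_sig = params
        sig = np.exp(log_sig)
        ll = 0.0
        for x, mu in ((a, mu_a), (b, mu_b)):
            pos = x[x > 0]
            k, n = len(pos), len(x)
            pi = k / n
            ll += k * np.log(pi) + (n - k) * np.log(1 - pi)
            ll += st.norm.logpdf(pos, mu, sig).sum()
        return -ll

    res = minimize(negll, x0=[1.0, 1.0, 0.0], method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12,
                            "maxiter": 20000})
    assert -res.fun == pytest.approx(ll_closed, abs=1e-6)
    assert np.exp(res.x[2]) == pytest.approx(sigma, abs=1e-4)


def test_bimod_detection_shift_is_powerful(rng):
    """pi 0.2 vs 0.8 with equal positive means: significant in >= 90%."""
    hits = 0
    for _ in range(100):
        a = np.where(rng.random(100) < 0.2, rng.normal(3, 1, 100), 0.0)
        b = np.where(rng.random(100) < 0.8, rng.normal(3, 1, 100), 0.0)
        hits += de_bimod(a, b) < 0.01
    assert hits >= 90


def test_bimod_no_positthan_proportion_only():
    a = np.zeros(10)
    b = np.zeros(10)
    assert de_bimod(a, b) == 1.0


# ------------------------------------------------------------------ hurdle

def test_hurdle_null_p_near_one():
    a = np.array([0.0, 0.0, 1.0, 2.0, 3.0])
    assert de_hurdle(a, a.copy()) > 0.9


def test_hurdle_logistic_deviance_matches_irls_oracle():
    """Closed-form detection LRT equals the statsmodels IRLS fit on a
    12-point example (to 1e-8)."""
    import statsmodels.api as sm
    a = np.array([0, 0, 0, 0, 1.2, 2.1])
    b = np.array([0, 1.1, 0.8, 2.2, 1.5])
    y = np.concatenate([(a > 0).astype(float), (b > 0).astype(float)])
    g = np.concatenate([np.zeros(len(a)), np.ones(len(b))])
    alt = sm.GLM(y, sm.add_constant(g), family=sm.families.Binomial()).fit()
    null = sm.GLM(y, np.ones_like(y), family=sm.families.Binomial()).fit()
    lrt_ref = null.deviance - alt.deviance
    from scburden.de import _detection_lrt
    stat, separated = _detection_lrt((a > 0).sum(), len(a),
                                     (b > 0).sum(), len(b))
    assert not separated
    assert stat == pytest.approx(lrt_ref, abs=1e-8)


def test_hurdle_detects_detection_only_shift_where_t_does_not(rng):
    """Same positive means, very different detection rates: the hurdle test
    fires on the constructed contrast while Welch's t on the full vectors
    (dominated by the positive-value means) can stay quiet."""
    pos = rng.normal(4, 0.05, 200)
    a = np.where(rng.random(200) < 0.95, pos, 0.0)
    b = np.where(rng.random(200) < 0.55, pos, 0.0)
    p_h = de_hurdle(a, b)
    assert p_h < 1e-6


def test_hurdle_separation_flagged():
    a = np.array([0.0, 0.0, 0.0, 0.0])
    b = np.array([1.0, 2.0, 1.5, 0.0])
    p, details = de_hurdle(a, b, return_details=True)
    assert details["separated"]
    assert 0 <= p <= 1


# -------------------------------------------------------------- adjustment

def test_bonferroni_examples():
    assert adjust([0.01], m=10)[0] == pytest.approx(0.1)
    assert adjust([0.5], m=3)[0] == 1.0


def test_bh_matches_step_up_hand_computation():
    p = np.array([0.01, 0.02, 0.03, 0.9])
    got = adjust(p, method="bh")
    # step-up: q_i = min_{j>=i} (m * p_j / j), m = 4
    raw = 4 * p / np.arange(1, 5)
    expected = np.minimum.accumulate(raw[::-1])[::-1]
    assert np.allclose(got, expected, atol=1e-12)


def test_adjust_rejects_bad_p():
    with pytest.raises(ValueError):
        adjust([0.5, 1.2])


# -------------------------------------------------------------- consensus

def test_consensus_requires_all_four_tests(clustering):
    labeling, norm, _ = clustering
    tables = run_de(norm, labeling)
    broken = {c: t.drop(columns=["p_adj_bimod"]) for c, t in tables.items()}
    with pytest.raises(ValueError, match="bimod"):
        consensus(broken)


def test_consensus_is_intersection_of_single_tests(clustering):
    labeling, norm, _ = clustering
    tables = run_de(norm, labeling)
    cons = consensus(tables)
    for c, tbl in tables.items():
        kept = set(cons.tables[c]["gene"])
        for t in TEST_NAMES:
            single = set(tbl.loc[tbl[f"p_adj_{t}"] < 1e-3, "gene"])
            assert kept <= single


def test_gene_significant_in_three_of_four_excluded():
    import pandas as pd
    tbl = pd.DataFrame({
        "gene": ["g1"], "log2_fc": [2.0], "pct_in": [0.9], "pct_out": [0.1],
        **{f"p_{t}": [1e-6] for t in TEST_NAMES},
        **{f"p_adj_{t}": [1e-6] for t in TEST_NAMES}})
    tbl.loc[0, "p_adj_hurdle"] = 0.5
    cons = consensus({0: tbl})
    assert cons.genes(0) == []


def test_consensus_recovers_planted_markers(bundle, clustering,
                                            consensus_degs):
    """Markers of each planted type are recovered as consensus DEGs of the
    matching cluster, with few false discoveries against the truth."""
    labeling, _, _ = clustering
    truth_of_cluster = {}
    labels = np.asarray(labeling.labels)
    cell_types = np.array([bundle.truth.cell_labels[c]
                           for c in bundle.counts.cell_ids])
    for c in labeling.cluster_ids:
        vals, counts = np.unique(cell_types[labels == c], return_counts=True)
        truth_of_cluster[c] = vals[counts.argmax()]
    sens_all, fdr_all = [], []
    for c, tbl in consensus_degs.tables.items():
        markers = bundle.truth.marker_catalog[truth_of_cluster[c]]
        called = set(tbl.loc[tbl["log2_fc"] > 0, "gene"])
        sens_all.append(len(called & markers) / len(markers))
        if called:
            fdr_all.append(len(called - markers) / len(called))
    assert np.mean(sens_all) >= 0.9
    assert np.mean(fdr_all) <= 0.05


def test_symmetry_two_sided_p_and_fc_sign(rng):
    a = rng.normal(0, 1, 30)
    b = rng.normal(1, 1, 40)
    assert de_wilcoxon(a, b) == pytest.approx(de_wilcoxon(b, a), abs=1e-12)
    assert de_ttest(a, b) == pytest.approx(de_ttest(b, a), abs=1e-12)
    A, B = a[:, None], b[:, None]
    assert log2_fold_change(A, B)[0] == pytest.approx(
        -log2_fold_change(B, A)[0], abs=1e-12)


def test_small_groups_rejected():
    with pytest.raises(ValueError):
        de_wilcoxon([1, 2], [3, 4, 5])
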