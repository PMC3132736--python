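"""Presence filter, rankings, nearest-centroid rule and the inner loop."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from strateval.compendium import CLASS_GP, CLASS_PP
from strateval.signatures import (
    InnerConfig,
    TrainedSignaturePredictor,
    choose_signature_size,
    estimate_variance_prior,
    inner_protocol,
    moderated_t_rank,
    nc_score,
    nc_score_samples,
    nc_train,
    prefix_nc_scores,
    presence_filter,
    snr_rank,
)
from strateval.synthetic import SyntheticConfig, simulate_compendium
from tests.conftest import tiny_compendium


# -- presence filter -------------------------------------------------------


def test_presence_filter_one_group_suffices():
    # gene 0: present in 7/10 PP, 0/10 GP -> kept; gene 1: 6/10 both -> dropped
    calls = np.zeros((3, 20), dtype=bool)
    calls[0, :7] = True            # PP side only
    calls[1, :6] = True
    calls[1, 10:16] = True
    calls[2, :] = True             # everywhere
    classes = [CLASS_PP] * 10 + [CLASS_GP] * 10
    C = tiny_compendium(np.zeros((3, 20)), classes, calls=calls)
    kept = presence_filter(C, C.sample_ids, threshold=0.70)
    assert kept == ["g0", "g2"]


def test_presence_filter_requires_calls():
    C = tiny_compendium(np.zeros((2, 4)), [CLASS_PP, CLASS_GP] * 2)
    with pytest.raises(ValueError, match="presence_threshold=None"):
        presence_filter(C, C.sample_ids)


# -- rankings --------------------------------------------------------------


def _learning_compendium(seed=0, n_genes=200, n_per_class=15):
    rng = np.random.default_rng(seed)
    classes = [CLASS_PP] * n_per_class + [CLASS_GP] * n_per_class
    values = rng.normal(size=(n_genes, 2 * n_per_class)) * rng.uniform(
        0.5, 2.0, size=(n_genes, 1)
    )
    values[:20, :n_per_class] += 1.0  # some true signal
    return tiny_compendium(values, classes)


def test_moderated_t_reduces_to_ordinary_t_without_prior():
    C = _learning_compendium()
    ranked = moderated_t_rank(C, C.sample_ids, C.genes, d0=0)
    assert ranked.method == "plain_t"
    pp = C.values.to_numpy()[:, :15]
    gp = C.values.to_numpy()[:, 15:]
    t_ref = sps.ttest_ind(pp, gp, axis=1, equal_var=True).statistic
    order_ref = [C.genes[i] for i in np.argsort(-np.abs(t_ref), kind="stable")]
    # same ordering up to exact ties (none with continuous data)
    assert list(ranked.genes) == order_ref
    stats_by_gene = dict(zip(ranked.genes, ranked.statistics))
    np.testing.assert_allclose(
        [stats_by_gene[g] for g in C.genes], t_ref, atol=1e-10
    )


def test_moderated_t_limits_to_mean_difference_with_infinite_prior():
    C = _learning_compendium(seed=1)
    ranked = moderated_t_rank(C, C.sample_ids, C.genes, d0=1e12, s0_sq=1.0)
    diff = C.values.to_numpy()[:, :15].mean(axis=1) - C.values.to_numpy()[:, 15:].mean(axis=1)
    order_ref = [C.genes[i] for i in np.argsort(-np.abs(diff), kind="stable")]
    assert list(ranked.genes) == order_ref


def test_moderated_t_matches_direct_formula_oracle():
    C = _learning_compendium(seed=2)
    d0, s0_sq = 4.0, 0.8
    ranked = moderated_t_rank(C, C.sample_ids, C.genes, d0=d0, s0_sq=s0_sq)
    # independent recomputation, gene by gene
    pp = C.values.to_numpy()[:, :15]
    gp = C.values.to_numpy()[:, 15:]
    n1 = n2 = 15
    df = n1 + n2 - 2
    stats_by_gene = dict(zip(ranked.genes, ranked.statistics))
    for i, g in enumerate(C.genes):
        s2 = ((n1 - 1) * pp[i].var(ddof=1) + (n2 - 1) * gp[i].var(ddof=1)) / df
        post = (d0 * s0_sq + df * s2) / (d0 + df)
        t = (pp[i].mean() - gp[i].mean()) / np.sqrt(post * (1 / n1 + 1 / n2))
        assert abs(stats_by_gene[g] - t) < 1e-10


def test_variance_prior_shrinks_toward_common_variance():
    rng = np.random.default_rng(3)
    df = 18
    s2 = rng.chisquare(df, size=2000) / df  # all genes share unit variance
    d0, s0_sq = estimate_variance_prior(s2, df)
    assert d0 > 50  # little excess spread -> strong shrinkage
    assert 0.8 < s0_sq < 1.2


def test_snr_statistic_arithmetic():
    values = np.array(
        [np.r_[np.full(5, 1.0), np.full(5, 0.0)], np.r_[np.full(5, 0.5), np.full(5, 0.5)]]
    )
    values[0] += np.array([-0.5, -0.25, 0, 0.25, 0.5] * 2)  # sd 0.395.. per class
    classes = [CLASS_PP] * 5 + [CLASS_GP] * 5
    rng = np.random.default_rng(4)
    values[1] += rng.normal(0, 0.3, 10)  # equal means, nonzero sd
    C = tiny_compendium(values, classes)
    ranked = snr_rank(C, C.sample_ids, C.genes)
    stats_by_gene = dict(zip(ranked.genes, ranked.statistics))
    pp, gp = values[0, :5], values[0, 5:]
    expected = (pp.mean() - gp.mean()) / (pp.std(ddof=1) + gp.std(ddof=1))
    assert abs(stats_by_gene["g0"] - expected) < 1e-12
    assert ranked.genes[0] == "g0"  # signal gene ranked first


def test_snr_zero_denominator_ranked_last():
    values = np.zeros((2, 8))
    values[0, :4] = 1.0  # signal with zero within-class sd -> 0/0 -> last
    values[1] = np.arange(8) * 0.1
    C = tiny_compendium(values, [CLASS_PP] * 4 + [CLASS_GP] * 4)
    ranked = snr_rank(C, C.sample_ids, C.genes)
    assert ranked.genes[-1] == "g0"
    assert np.isnan(ranked.statistics[-1])


# -- nearest centroid ------------------------------------------------------


def test_nc_train_centroids_are_class_means():
    rng = np.random.default_rng(5)
    values = rng.normal(size=(6, 10))
    classes = [CLASS_PP] * 4 + [CLASS_GP] * 6
    C = tiny_compendium(values, classes)
    P = nc_train(C, C.sample_ids, C.genes)
    np.testing.assert_allclose(P.centroid_pp, values[:, :4].mean(axis=1), atol=1e-12)
    np.testing.assert_allclose(P.centroid_gp, values[:, 4:].mean(axis=1), atol=1e-12)
    # one sample per class: centroids equal the samples
    P1 = nc_train(C, ["s0", "s4"], C.genes)
    np.testing.assert_allclose(P1.centroid_pp, values[:, 0])
    np.testing.assert_allclose(P1.centroid_gp, values[:, 4])
    # duplicating the learning set leaves centroids unchanged
    P2 = nc_train(C, C.sample_ids + C.sample_ids, C.genes)
    np.testing.assert_allclose(P2.centroid_pp, P.centroid_pp)


def test_nc_score_sign_and_hand_computed_cosine():
    P = TrainedSignaturePredictor(
        features=("g0", "g1"),
        centroid_gp=np.array([1.0, 1.0]) / np.sqrt(2),
        centroid_pp=np.array([0.0, 1.0]),
        n=2,
        ranking="moderated_t",
    )
    # x=(1,0): cos to GP = cos45, to PP = cos90 -> score = (1-cos45)-(1-0) < 0
    score = nc_score(P, np.array([1.0, 0.0]))
    assert abs(score - ((1 - np.cos(np.pi / 4)) - 1.0)) < 1e-12
    assert score < 0  # classified GP
    # a sample at the PP centroid scores positive
    assert nc_score(P, np.array([0.0, 1.0])) > 0


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    st.integers(min_value=0, max_value=1000),
    st.floats(min_value=0.01, max_value=100.0),
)
def test_nc_score_positive_scale_invariance(seed, alpha):
    rng = np.random.default_rng(seed)
    P = TrainedSignaturePredictor(
        features=tuple(f"g{i}" for i in range(5)),
        centroid_gp=rng.normal(size=5) + 0.1,
        centroid_pp=rng.normal(size=5) - 0.1,
        n=5,
        ranking="moderated_t",
    )
    x = rng.normal(size=5)
    if np.linalg.norm(x) == 0:
        return
    assert abs(nc_score(P, x) - nc_score(P, alpha * x)) < 1e-9


def test_nc_score_zero_norm_rejected():
    P = TrainedSignaturePredictor(
        features=("g0", "g1"),
        centroid_gp=np.array([1.0, 0.0]),
        centroid_pp=np.array([0.0, 1.0]),
        n=2,
        ranking="moderated_t",
    )
    with pytest.raises(ValueError, match="zero-norm"):
        nc_score(P, np.zeros(2))


def test_prefix_scores_match_per_size_nc_score():
    rng = np.random.default_rng(6)
    n_genes, n_samples = 12, 7
    X = rng.normal(size=(n_genes, n_samples))
    c_gp = rng.normal(size=n_genes)
    c_pp = rng.normal(size=n_genes)
    mat = prefix_nc_scores(X, c_gp, c_pp)
    for n in range(1, n_genes + 1):
        P = TrainedSignaturePredictor(
            features=tuple(f"g{i}" for i in range(n)),
            centroid_gp=c_gp[:n], centroid_pp=c_pp[:n], n=n, ranking="moderated_t",
        )
        for j in range(n_samples):
            assert abs(mat[n - 1, j] - nc_score(P, X[:n, j])) < 1e-10


def test_predictor_serialization_roundtrip():
    rng = np.random.default_rng(7)
    P = TrainedSignaturePredictor(
        features=("a", "b", "c"),
        centroid_gp=rng.normal(size=3), centroid_pp=rng.normal(size=3),
        n=3, ranking="snr",
    )
    Q = TrainedSignaturePredictor.from_dict(P.to_dict())
    assert Q.features == P.features and Q.ranking == P.ranking
    np.testing.assert_allclose(Q.centroid_gp, P.centroid_gp)


# -- signature-size selection ----------------------------------------------


def _scan_oracle(mean_curve, reps):
    i_star = int(np.argmax(mean_curve))
    sigma = np.std(reps[:, i_star], ddof=1) if len(reps) > 1 else 0.0
    best = None
    for n in range(1, len(mean_curve) + 1):
        if mean_curve[n - 1] >= mean_curve[i_star] - sigma:
            best = n
    return best


def test_flat_curve_picks_largest_size():
    curve = np.full(30, 70.0)
    reps = np.tile(curve, (5, 1))
    assert choose_signature_size(curve, reps) == 30


def test_increasing_curve_picks_largest_size():
    curve = np.linspace(50, 90, 40)
    reps = np.tile(curve, (3, 1))
    assert choose_signature_size(curve, reps) == 40


def test_stubbed_unimodal_curve_matches_scan_oracle():
    # peak at n=12, sd over repeats ~2, programmatic stub
    rng = np.random.default_rng(8)
    n = np.arange(1, 41)
    base = 80 - 0.15 * (n - 12.0) ** 2 / 4
    reps = base[None, :] + rng.normal(0, 2.0, size=(6, 40))
    mean_curve = reps.mean(axis=0)
    assert choose_signature_size(mean_curve, reps) == _scan_oracle(mean_curve, reps)
    # and on many random stubs
    for seed in range(20):
        r = np.random.default_rng(seed)
        reps = r.uniform(40, 90, size=(4, 25))
        mean_curve = reps.mean(axis=0)
        assert choose_signature_size(mean_curve, reps) == _scan_oracle(mean_curve, reps)


# -- inner protocol --------------------------------------------------------


def _training_compendium(seed=9):
    cfg = SyntheticConfig(
        counts={s: (12, 12) for s in ("lumA", "lumB", "Her2", "basal")},
        n_genes=200, delta_shared=1.0, delta_subtype=0.0, n_studies=1,
    )
    return simulate_compendium(cfg, seed=seed)[0]


def test_inner_protocol_deterministic_and_filtered():
    C = _training_compendium()
    config = InnerConfig(F=3, R=2, N_max=30)
    a = inner_protocol(C, C.sample_ids, config, seed=4)
    b = inner_protocol(C, C.sample_ids, config, seed=4)
    assert a.n_opt == b.n_opt
    assert a.predictor.features == b.predictor.features
    np.testing.assert_array_equal(a.curve.mean, b.curve.mean)
    # final signature only uses genes passing the full-set presence filter
    allowed = set(presence_filter(C, C.sample_ids, 0.70))
    assert set(a.predictor.features) <= allowed
    assert 1 <= a.n_opt <= 30
    # detectable shared signal: curve clearly above chance
    assert a.curve.mean.max() > 60


def test_inner_protocol_n_max_clipped():
    C = _training_compendium(seed=10)
    config = InnerConfig(F=3, R=1, N_max=10_000, presence_threshold=None)
    res = inner_protocol(C, C.sample_ids, config, seed=0)
    assert len(res.curve.mean) == C.n_genes
    assert res.n_opt <= C.n_genes


def test_inner_protocol_scores_validation_consistently():
    C = _training_compendium(seed=11)
    config = InnerConfig(F=3, R=1, N_max=20)
    res = inner_protocol(C, C.sample_ids[:60], config, seed=1)
    s = nc_score_samples(res.predictor, C, C.sample_ids[60:])
    assert np.isfinite(s.to_numpy()).all()
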