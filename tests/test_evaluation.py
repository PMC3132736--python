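"""Metrics, AUC, pooling contracts and the outer typed-vs-untyped loop."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strateval.evaluation import (
    ConfusionCounts,
    EvalConfig,
    auc,
    bar_weighted,
    evaluate_partition,
    metrics,
    outer_loop,
    paired_test,
    report_sweep,
)
from strateval.cohorts import stratified_folds
from strateval.partitions import (
    ElementarySubtypeSet,
    coarsest_partition,
    enumerate_partitions,
    finest_partition,
)
from strateval.signatures import InnerConfig
from strateval.synthetic import SyntheticConfig, simulate_compendium


# -- confusion metrics -----------------------------------------------------


def test_perfect_classifier_scores_100():
    m = metrics(ConfusionCounts(tp=5, fp=0, tn=7, fn=0))
    for key in ("sen", "spc", "acc", "ppv", "npv", "bar"):
        assert m[key] == 100.0


def test_majority_guessing_gives_bar_50():
    m = metrics(ConfusionCounts(tp=0, fp=0, tn=30, fn=10))
    assert m["sen"] == 0.0 and m["spc"] == 100.0 and m["bar"] == 50.0
    # all-positive guessing too
    m2 = metrics(ConfusionCounts(tp=10, fp=30, tn=0, fn=0))
    assert m2["bar"] == 50.0


def test_metric_arithmetic_example():
    m = metrics(ConfusionCounts(tp=3, fn=1, tn=2, fp=2))
    assert m["sen"] == 75.0
    assert m["spc"] == 50.0
    assert m["bar"] == 62.5
    assert m["acc"] == 62.5
    assert m["ppv"] == 60.0
    assert abs(m["npv"] - 200 / 3) < 1e-9


def test_empty_confusion_rejected():
    with pytest.raises(ValueError, match="empty"):
        metrics(ConfusionCounts(0, 0, 0, 0))
    with pytest.raises(ValueError, match="nonnegative"):
        ConfusionCounts(-1, 0, 0, 0)


def test_undefined_fields_are_nan_not_zero():
    m = metrics(ConfusionCounts(tp=0, fp=0, tn=3, fn=2))  # no positive predictions
    assert np.isnan(m["ppv"])
    assert not np.isnan(m["npv"])


# -- balanced accuracy as weighted accuracy --------------------------------


def test_bar_weighted_identity_on_random_tables():
    rng = np.random.default_rng(0)
    for _ in range(1000):
        tp, fp, tn, fn = rng.integers(0, 30, size=4)
        if tp + fn == 0 or tn + fp == 0:
            continue
        c = ConfusionCounts(int(tp), int(fp), int(tn), int(fn))
        correct = np.r_[np.ones(tp), np.zeros(fn), np.ones(tn), np.zeros(fp)].astype(bool)
        is_pos = np.r_[np.ones(tp + fn), np.zeros(tn + fp)].astype(bool)
        assert abs(bar_weighted(correct, is_pos) - metrics(c)["bar"]) < 1e-12


def test_bar_weighted_balanced_classes_equals_accuracy():
    correct = np.array([True, False, True, True, False, True])
    is_pos = np.array([True, True, True, False, False, False])
    assert abs(bar_weighted(correct, is_pos) - 100 * correct.mean()) < 1e-12


def test_bar_more_sensitive_to_minority_errors():
    # lumA-like imbalance: many GP, few PP
    base = ConfusionCounts(tp=10, fn=0, tn=100, fp=0)
    extra_pp_error = ConfusionCounts(tp=9, fn=1, tn=100, fp=0)
    extra_gp_error = ConfusionCounts(tp=10, fn=0, tn=99, fp=1)
    drop_pp = metrics(base)["bar"] - metrics(extra_pp_error)["bar"]
    drop_gp = metrics(base)["bar"] - metrics(extra_gp_error)["bar"]
    assert drop_pp > drop_gp


def test_bar_weighted_one_class_rejected():
    with pytest.raises(ValueError, match="both classes"):
        bar_weighted(np.array([True, False]), np.array([True, True]))


# -- AUC -------------------------------------------------------------------


def pair_counting_auc(scores, truth):
    pos = [s for s, t in zip(scores, truth) if t]
    neg = [s for s, t in zip(scores, truth) if not t]
    wins = sum(
        1.0 if p > n else (0.5 if p == n else 0.0) for p, n in itertools.product(pos, neg)
    )
    return 100.0 * wins / (len(pos) * len(neg))


def test_auc_reference_cases():
    assert auc([1, 2, 3, 10, 11], [False] * 3 + [True] * 2) == 100.0
    assert auc([5, 5, 5, 5], [True, False, True, False]) == 50.0
    assert auc([0.9, 0.4, 0.5, 0.1], [True, True, False, False]) == 75.0


def test_auc_matches_pair_counting_on_random_sets():
    rng = np.random.default_rng(1)
    for _ in range(50):
        n = rng.integers(4, 15)
        scores = np.round(rng.normal(size=n), 1)  # coarse -> ties happen
        truth = rng.random(n) > 0.5
        if truth.all() or not truth.any():
            continue
        assert abs(auc(scores, truth) - pair_counting_auc(scores, truth)) < 1e-10


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_auc_invariant_under_increasing_transform(seed):
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=12)
    truth = rng.random(12) > 0.4
    if truth.all() or not truth.any():
        return
    transformed = np.exp(3 * scores) + 1
    assert abs(auc(scores, truth) - auc(transformed, truth)) < 1e-9


def test_auc_one_class_rejected():
    with pytest.raises(ValueError, match="both classes"):
        auc([1, 2], [True, True])


# -- pooling contracts -----------------------------------------------------


def test_overall_metrics_from_summed_confusion():
    a = ConfusionCounts(tp=3, fp=2, tn=10, fn=1)
    b = ConfusionCounts(tp=8, fp=5, tn=3, fn=4)
    pooled = a + b
    m = metrics(pooled)
    assert m["acc"] == 100.0 * (pooled.tp + pooled.tn) / pooled.total
    # pooling is NOT averaging of part metrics
    assert m["bar"] != (metrics(a)["bar"] + metrics(b)["bar"]) / 2


def test_overall_bar_can_exceed_every_part_bar():
    # part 1: GP-heavy, classifier guesses mostly GP; part 2: PP-heavy, guesses mostly PP
    part1 = ConfusionCounts(tp=1, fn=19, tn=97, fp=3)
    part2 = ConfusionCounts(tp=18, fn=2, tn=1, fp=9)
    pooled = part1 + part2
    bar1 = metrics(part1)["bar"]
    bar2 = metrics(part2)["bar"]
    bar_all = metrics(pooled)["bar"]
    assert bar_all > bar1 and bar_all > bar2


# -- paired test -----------------------------------------------------------


def test_paired_test_degenerate_conventions():
    assert paired_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0
    assert paired_test([2.0, 3.0, 4.0], [1.0, 2.0, 3.0]) == 0.0
    with pytest.raises(ValueError):
        paired_test([1.0], [2.0])


def test_paired_test_textbook_formula():
    a = np.array([2.0, 4.0, 6.0, 8.0])
    b = np.array([1.0, 2.0, 3.0, 4.0])
    d = a - b
    t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    from scipy import stats as sps

    p_ref = 2 * sps.t.sf(abs(t), df=len(d) - 1)
    assert abs(paired_test(a, b) - p_ref) < 1e-10
    # symmetry: swapping arms keeps p
    assert abs(paired_test(b, a) - p_ref) < 1e-10


# -- outer loop on synthetic data ------------------------------------------


SUBTYPES4 = ("lumA", "lumB", "Her2", "basal")


def _eval_compendium(seed=0, delta_subtype=1.0, delta_shared=0.0, n=15):
    cfg = SyntheticConfig(
        counts={s: (n, n) for s in SUBTYPES4},
        n_genes=300,
        delta_subtype=delta_subtype,
        delta_shared=delta_shared,
    )
    return simulate_compendium(cfg, seed=seed)[0]


FAST_INNER = InnerConfig(F=2, R=1, N_max=15)


def test_coarsest_partition_typed_equals_untyped():
    C = _eval_compendium()
    S = ElementarySubtypeSet(list(SUBTYPES4))
    folds = stratified_folds(C, K=3, seed=2)
    config = EvalConfig(K_outer=3, R_outer=1, inner=FAST_INNER)
    top = coarsest_partition(S)
    rep_t = evaluate_partition(C, top, folds, "typed", config, seed=9, subtypes=S)
    rep_u = evaluate_partition(C, top, folds, "untyped", config, seed=9, subtypes=S)
    rep_b = evaluate_partition(C, top, folds, "baseline", config, seed=9, subtypes=S)
    for col in ("auc", "bar", "acc", "n"):
        assert rep_t.loc["overall", col] == rep_u.loc["overall", col]
        assert rep_t.loc["overall", col] == rep_b.loc["overall", col]


def test_partition_overall_pools_parts():
    C = _eval_compendium(seed=3)
    S = ElementarySubtypeSet(list(SUBTYPES4))
    folds = stratified_folds(C, K=3, seed=0)
    config = EvalConfig(K_outer=3, R_outer=1, inner=FAST_INNER)
    rep = evaluate_partition(C, finest_partition(S), folds, "typed", config, seed=1, subtypes=S)
    parts = [lab for lab in rep.index if lab != "overall"]
    summed = ConfusionCounts(
        tp=int(rep.loc[parts, "tp"].sum()),
        fp=int(rep.loc[parts, "fp"].sum()),
        tn=int(rep.loc[parts, "tn"].sum()),
        fn=int(rep.loc[parts, "fn"].sum()),
    )
    m = metrics(summed)
    for col in ("sen", "spc", "acc", "bar"):
        assert abs(rep.loc["overall", col] - m[col]) < 1e-9
    # typed and untyped arms share validation sets
    rep_u = evaluate_partition(C, finest_partition(S), folds, "untyped", config, seed=1, subtypes=S)
    assert (rep_u["n"] == rep["n"]).all()


def test_outer_loop_deterministic_and_reduces_to_single_repeat():
    C = _eval_compendium(seed=4)
    S = ElementarySubtypeSet(list(SUBTYPES4))
    config = EvalConfig(K_outer=3, R_outer=2, inner=FAST_INNER)
    fine = finest_partition(S)
    a = outer_loop(C, [fine], config, seed=5, subtypes=S)
    b = outer_loop(C, [fine], config, seed=5, subtypes=S)
    assert a.table.equals(b.table)
    r1 = outer_loop(C, [fine], EvalConfig(K_outer=3, R_outer=1, inner=FAST_INNER),
                    seed=5, subtypes=S)
    assert set(r1.table["repeat"]) == {0}
    assert len(r1.table) == len(a.table[a.table["repeat"] == 0])


def test_report_sweep_shapes_and_baseline_column():
    cfg = SyntheticConfig(
        counts={s: (8, 8) for s in ("A", "B", "C")},
        n_genes=120,
        module_sizes={"ER": 2, "HER2": 2, "AURKA": 2},
        n_shared=5, n_subtype_signal=3,
        delta_subtype=1.0,
    )
    C, _ = simulate_compendium(cfg, seed=6)
    S = ElementarySubtypeSet(["A", "B", "C"])
    partitions = enumerate_partitions(S)
    assert len(partitions) == 5
    config = EvalConfig(K_outer=2, R_outer=2, inner=FAST_INNER)
    result = outer_loop(C, partitions, config, seed=7, subtypes=S)
    wide, pvals = report_sweep(result)
    assert len(wide.columns) == 5 * 2  # partitions x arms
    assert list(wide.index) == ["auc", "bar", "sen", "spc", "acc", "ppv", "npv"]
    # the single-part partition is the typed==untyped baseline column
    base = "A.B.C"
    np.testing.assert_allclose(
        wide[(base, "typed")].to_numpy(dtype=float),
        wide[(base, "untyped")].to_numpy(dtype=float),
    )
    assert pvals.shape[1] == 5
    # round trip through TSV text
    import io
    import pandas as pd

    buf = io.StringIO()
    wide.to_csv(buf, sep="\t")
    buf.seek(0)
    back = pd.read_csv(buf, sep="\t", header=[0, 1], index_col=0)
    np.testing.assert_allclose(back.to_numpy(dtype=float), wide.to_numpy(dtype=float))
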