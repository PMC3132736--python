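"""Confusion metrics, ROC AUC, and the outer typed-vs-untyped evaluation loop.

All metrics are reported on the percent scale with the poor-prognosis (PP)
class as positive. Aggregation always pools assignments — per part over the
outer folds, and per partition over its parts — and recomputes metrics from
the pooled confusion, never by averaging part-level metrics. Pooling is what
lets an overall balanced accuracy exceed every per-part balanced accuracy
when class ratios differ between parts: the balanced accuracy is a weighted
accuracy whose per-sample weights depend on the class sizes of the set it
is computed on.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .compendium import CLASS_GP, CLASS_PP, ExpressionCompendium
from .cohorts import stratified_folds, typed_sets, untyped_sets, pool_untyped
from .partitions import (
    CompoundSubtype,
    ElementarySubtypeSet,
    Partition,
    abbreviations_for,
    part_label,
    partition_label,
)
from .signatures import InnerConfig, inner_protocol, nc_score_samples

logger = logging.getLogger(__name__)

METRICS = ("auc", "bar", "sen", "spc", "acc", "ppv", "npv")
ARMS = ("typed", "untyped", "baseline")


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with PP as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_assignments(cls, predicted_pp: np.ndarray, truth_pp: np.ndarray) -> "ConfusionCounts":
        predicted_pp = np.asarray(predicted_pp, dtype=bool)
        truth_pp = np.asarray(truth_pp, dtype=bool)
        return cls(
            tp=int((predicted_pp & truth_pp).sum()),
            fp=int((predicted_pp & ~truth_pp).sum()),
            tn=int((~predicted_pp & ~truth_pp).sum()),
            fn=int((~predicted_pp & truth_pp).sum()),
        )

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


def _ratio(num: int, den: int) -> float:
    return 100.0 * num / den if den else np.nan


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """sen/spc/acc/ppv/npv/bar in percent; undefined fields are NaN."""
    if c.total == 0:
        raise ValueError("empty confusion table")
    sen = _ratio(c.tp, c.tp + c.fn)
    spc = _ratio(c.tn, c.tn + c.fp)
    out = {
        "sen": sen,
        "spc": spc,
        "acc": _ratio(c.tp + c.tn, c.total),
        "ppv": _ratio(c.tp, c.tp + c.fp),
        "npv": _ratio(c.tn, c.tn + c.fn),
        "bar": (sen + spc) / 2.0 if np.isfinite(sen) and np.isfinite(spc) else np.nan,
    }
    return out


def bar_weighted(correct: np.ndarray, is_positive: np.ndarray) -> float:
    """Balanced accuracy as a per-sample weighted accuracy (percent).

    Positive samples weigh ``1/(2 N_pos)``, negative ones ``1/(2 N_neg)``,
    which reproduces (sen+spc)/2 exactly. Exposed separately because the
    weights change with the class sizes of the evaluated set: the same
    assignment errors are weighted differently per part and overall.
    """
    correct = np.asarray(correct, dtype=bool)
    is_positive = np.asarray(is_positive, dtype=bool)
    n_pos = int(is_positive.sum())
    n_neg = int((~is_positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    w = np.where(is_positive, 1.0 / (2 * n_pos), 1.0 / (2 * n_neg))
    return 100.0 * float((w * correct).sum())


def auc(scores: Iterable[float], truth_pp: Iterable[bool]) -> float:
    """ROC area as the Mann-Whitney pair statistic, in percent.

    Fraction of (PP, GP) pairs where the PP sample scores higher, ties
    counted half.
    """
    scores = np.asarray(list(scores), dtype=float)
    truth_pp = np.asarray(list(truth_pp), dtype=bool)
    return float(auc_rows(scores[None, :], truth_pp)[0])


def auc_rows(scores: np.ndarray, truth_pp: np.ndarray) -> np.ndarray:
    """Row-wise AUC (percent) for a rows x samples score matrix."""
    truth_pp = np.asarray(truth_pp, dtype=bool)
    n_pos = int(truth_pp.sum())
    n_neg = int((~truth_pp).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = stats.rankdata(scores, axis=1)
    pos_ranks = ranks[:, truth_pp].sum(axis=1)
    u = pos_ranks - n_pos * (n_pos + 1) / 2.0
    return 100.0 * u / (n_pos * n_neg)


def paired_test(a: Iterable[float], b: Iterable[float]) -> float:
    """Two-sided paired t-test p-value on per-repeat series.

    Degenerate conventions: all-zero differences give p = 1 (no evidence),
    zero-variance nonzero-mean differences give p = 0; both are logged.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired series must have equal length >= 2")
    d = a - b
    if np.std(d, ddof=1) == 0:
        if np.allclose(d, 0):
            logger.info("paired_test: identical series, p = 1 by convention")
            return 1.0
        logger.info("paired_test: zero-variance nonzero differences, p = 0 by convention")
        return 0.0
    return float(stats.ttest_rel(a, b).pvalue)


# -- outer loop ------------------------------------------------------------


@dataclass(frozen=True)
class EvalConfig:
    """Outer-loop settings; ``inner`` configures signature-size selection."""

    K_outer: int = 10
    R_outer: int = 1
    inner: InnerConfig = field(default_factory=InnerConfig)
    arms: tuple[str, ...] = ("typed", "untyped")
    alpha: float = 0.05

    def __post_init__(self):
        bad = set(self.arms) - set(ARMS)
        if bad:
            raise ValueError(f"unknown arm(s) {sorted(bad)}")
        if self.K_outer < 2 or self.R_outer < 1:
            raise ValueError("K_outer >= 2 and R_outer >= 1 required")


def _train_seed(master: int, repeat: int, fold: int, train_ids: tuple[str, ...]) -> int:
    # Arm-independent: identical training sets train identical predictors,
    # which makes the coarsest partition's typed and untyped arms coincide.
    h = zlib.crc32(",".join(train_ids).encode())
    return int(np.random.SeedSequence([master, repeat, fold, h]).generate_state(1)[0] % (2**31))


def _report(scores: np.ndarray, truth_pp: np.ndarray) -> pd.Series:
    conf = ConfusionCounts.from_assignments(scores > 0, truth_pp)
    vals = metrics(conf)
    try:
        vals["auc"] = float(auc_rows(scores[None, :], truth_pp)[0])
    except ValueError:
        vals["auc"] = np.nan
    vals.update(
        n=conf.total, n_pos=int(truth_pp.sum()), n_neg=int((~truth_pp).sum()),
        tp=conf.tp, fp=conf.fp, tn=conf.tn, fn=conf.fn,
    )
    return pd.Series(vals)


class _PartScorer:
    """Trains/caches one predictor per distinct training set within a repeat."""

    def __init__(self, compendium, folds, untyped_maps, config: EvalConfig,
                 master_seed: int, repeat: int):
        self.compendium = compendium
        self.folds = folds
        self.untyped_maps = untyped_maps
        self.config = config
        self.master_seed = master_seed
        self.repeat = repeat
        self._cache: dict[tuple[int, tuple[str, ...]], object] = {}
        self.full_parts = frozenset(compendium.samples.loc[folds.index, "subtype"].unique())

    def _predictor(self, fold: int, train_ids: tuple[str, ...]):
        key = (fold, train_ids)
        if key not in self._cache:
            seed = _train_seed(self.master_seed, self.repeat, fold, train_ids)
            self._cache[key] = inner_protocol(
                self.compendium, list(train_ids), self.config.inner, seed
            ).predictor
        return self._cache[key]

    def part_scores(self, part: CompoundSubtype, arm: str):
        """Pooled (scores, truth) over all folds for one part and arm."""
        K = int(self.folds.max())
        all_scores: list[float] = []
        all_truth: list[bool] = []
        for f in range(1, K + 1):
            typed_train, validation = typed_sets(self.compendium, self.folds, part, f)
            if not validation:
                continue
            if arm == "typed":
                train = tuple(sorted(typed_train))
            elif arm == "untyped":
                train = tuple(pool_untyped(part, self.untyped_maps[f]))
            elif arm == "baseline":
                train = tuple(sorted(self.folds.index[self.folds != f]))
            else:
                raise ValueError(f"unknown arm {arm!r}")
            cls = self.compendium.class_of(train)
            if (cls == CLASS_PP).sum() < 2 or (cls == CLASS_GP).sum() < 2:
                logger.warning("part %s fold %d arm %s lacks class samples; skipped",
                               sorted(part), f, arm)
                continue
            predictor = self._predictor(f, train)
            s = nc_score_samples(predictor, self.compendium, validation)
            all_scores.extend(s.to_numpy())
            all_truth.extend(self.compendium.class_of(validation) == CLASS_PP)
        return np.asarray(all_scores), np.asarray(all_truth, dtype=bool)


def evaluate_partition(
    compendium: ExpressionCompendium,
    partition: Partition,
    folds: pd.Series,
    arm: str,
    config: EvalConfig,
    seed: int,
    untyped_maps: dict[int, dict[str, list[str]]] | None = None,
    repeat: int = 0,
    subtypes: ElementarySubtypeSet | None = None,
) -> pd.DataFrame:
    """Per-part and overall metric reports for one partition and arm.

    Per part, validation assignments are pooled over folds; the overall row
    pools across parts before recomputing the metrics. Typed and untyped
    arms see identical validation samples.
    """
    if subtypes is None:
        subtypes = ElementarySubtypeSet(sorted(frozenset().union(*partition)))
    abbrev = abbreviations_for(subtypes)
    if untyped_maps is None:
        K = int(folds.max())
        child = np.random.SeedSequence([seed, repeat]).spawn(K)
        untyped_maps = {
            f: untyped_sets(compendium, folds, f, np.random.default_rng(child[f - 1]))
            for f in range(1, K + 1)
        }
    scorer = _PartScorer(compendium, folds, untyped_maps, config, seed, repeat)
    rows = {}
    pooled_scores: list[np.ndarray] = []
    pooled_truth: list[np.ndarray] = []
    for part in sorted(partition, key=lambda p: min(subtypes.index(m) for m in p)):
        scores, truth = scorer.part_scores(part, arm)
        lab = part_label(part, subtypes, abbrev)
        if scores.size == 0:
            logger.warning("part %s never appears in any validation fold", lab)
            continue
        rows[lab] = _report(scores, truth)
        pooled_scores.append(scores)
        pooled_truth.append(truth)
    if not pooled_scores:
        raise ValueError("no part produced any validation assignment")
    rows["overall"] = _report(np.concatenate(pooled_scores), np.concatenate(pooled_truth))
    frame = pd.DataFrame(rows).T
    frame.index.name = "part"
    return frame


@dataclass
class SweepResult:
    """Tidy per-repeat results of an outer-loop sweep.

    ``table`` columns: partition, part, arm, repeat, the seven metrics,
    n / n_pos / n_neg and the confusion counts.
    """

    table: pd.DataFrame
    subtypes: ElementarySubtypeSet
    config: EvalConfig
    seed: int

    def mean_report(self, partition_label_: str, arm: str, part: str = "overall") -> pd.Series:
        sel = self.table[
            (self.table["partition"] == partition_label_)
            & (self.table["arm"] == arm)
            & (self.table["part"] == part)
        ]
        return sel[list(METRICS)].mean()

    def repeat_series(
        self, partition_label_: str, arm: str, metric: str, part: str = "overall"
    ) -> np.ndarray:
        sel = self.table[
            (self.table["partition"] == partition_label_)
            & (self.table["arm"] == arm)
            & (self.table["part"] == part)
        ].sort_values("repeat")
        return sel[metric].to_numpy(dtype=float)


def outer_loop(
    compendium: ExpressionCompendium,
    partitions: list[Partition],
    config: EvalConfig,
    seed: int,
    subtypes: ElementarySubtypeSet | None = None,
) -> SweepResult:
    """Repeat the fold/bundle/train/evaluate cycle and collect tidy reports.

    Each repeat draws fresh stratified folds and fresh untyped shuffles from
    the master seed; predictors are cached per distinct training set within
    a repeat, so partitions sharing compound subtypes share their training
    work.
    """
    if subtypes is None:
        subtypes = ElementarySubtypeSet(sorted(frozenset().union(*partitions[0])))
    abbrev = abbreviations_for(subtypes)
    ss = np.random.SeedSequence(seed)
    repeat_seeds = ss.spawn(config.R_outer)
    records = []
    for r in range(config.R_outer):
        rep_ss = repeat_seeds[r]
        fold_seed, untyped_root = rep_ss.spawn(2)
        folds = stratified_folds(compendium, config.K_outer, np.random.default_rng(fold_seed))
        K = int(folds.max())
        fold_children = untyped_root.spawn(K)
        untyped_maps = {
            f: untyped_sets(compendium, folds, f, np.random.default_rng(fold_children[f - 1]))
            for f in range(1, K + 1)
        }
        scorer = _PartScorer(compendium, folds, untyped_maps, config, seed, r)
        # score each distinct (part, arm) once, then assemble partitions
        part_cache: dict[tuple[CompoundSubtype, str], tuple[np.ndarray, np.ndarray]] = {}
        distinct_parts = {part for partition in partitions for part in partition}
        for part in distinct_parts:
            for arm in config.arms:
                part_cache[(part, arm)] = scorer.part_scores(part, arm)
        for partition in partitions:
            plab = partition_label(partition, subtypes, abbrev)
            for arm in config.arms:
                pooled_s, pooled_t = [], []
                for part in sorted(
                    partition, key=lambda p: min(subtypes.index(m) for m in p)
                ):
                    scores, truth = part_cache[(part, arm)]
                    if scores.size == 0:
                        continue
                    rec = _report(scores, truth)
                    rec["partition"], rec["part"], rec["arm"], rec["repeat"] = (
                        plab, part_label(part, subtypes, abbrev), arm, r,
                    )
                    records.append(rec)
                    pooled_s.append(scores)
                    pooled_t.append(truth)
                rec = _report(np.concatenate(pooled_s), np.concatenate(pooled_t))
                rec["partition"], rec["part"], rec["arm"], rec["repeat"] = (
                    plab, "overall", arm, r,
                )
                records.append(rec)
    table = pd.DataFrame(records).reset_index(drop=True)
    return SweepResult(table=table, subtypes=subtypes, config=config, seed=seed)


def report_sweep(result: SweepResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Wide partition-sweep table plus paired typed-vs-untyped p-values.

    The wide table has the seven metrics as rows and a (partition, arm)
    column MultiIndex; partitions are ordered by part count then label, and
    the single-part partition is the baseline column (typed == untyped).
    The p-value table holds two-sided paired t-test p-values per partition
    and metric over the outer repeats (NaN with a single repeat).
    """
    tab = result.table
    overall = tab[tab["part"] == "overall"]
    part_counts = {
        p: len(p.split("|")) for p in overall["partition"].unique()
    }
    ordered = sorted(part_counts, key=lambda p: (part_counts[p], p))
    arms = [a for a in ("typed", "untyped", "baseline") if a in set(overall["arm"])]
    wide = {}
    for p in ordered:
        for arm in arms:
            sel = overall[(overall["partition"] == p) & (overall["arm"] == arm)]
            wide[(p, arm)] = sel[list(METRICS)].mean()
    wide_df = pd.DataFrame(wide)
    wide_df.columns.names = ["partition", "arm"]

    pvals = {}
    if {"typed", "untyped"} <= set(arms):
        for p in ordered:
            row = {}
            for m in METRICS:
                t = result.repeat_series(p, "typed", m)
                u = result.repeat_series(p, "untyped", m)
                good = np.isfinite(t) & np.isfinite(u)
                row[m] = paired_test(t[good], u[good]) if good.sum() >= 2 else np.nan
            pvals[p] = pd.Series(row)
    pval_df = pd.DataFrame(pvals) if pvals else pd.DataFrame(index=list(METRICS))
    return wide_df, pval_df
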