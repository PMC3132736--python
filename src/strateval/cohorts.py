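"""Stratified folds, typed/untyped training sets, balanced subsampling.

The comparison at the heart of the protocol pairs each *typed* training set
(samples of one compound subtype, outside the held-out fold) with an
*untyped* counterpart of identical size and class composition whose subtype
mix instead reflects the whole compendium. Untyped sets are built by a
class-preserving shuffle of subtype labels over the fold's training pool:
within the poor-prognosis pool and, separately, the good-prognosis pool the
subtype labels are permuted, and the untyped set of subtype ``s`` collects
the samples that received label ``s``. This makes three facts structural
rather than statistical: per-class sizes match the typed sets exactly, the
untyped sets of distinct subtypes are disjoint, and pooling them all
reproduces the full training pool (so the coarsest partition's typed and
untyped sets coincide — the baseline).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compendium import CLASS_GP, CLASS_PP, ExpressionCompendium, SubtypeCountTable
from .partitions import CompoundSubtype

logger = logging.getLogger(__name__)


def stratified_folds(
    compendium: ExpressionCompendium, K: int, seed: int | np.random.Generator
) -> pd.Series:
    """Assign included samples to folds 1..K, stratified by (subtype, class).

    Within each stratum the samples are shuffled (seeded) and dealt
    round-robin starting at fold 1, so fold sizes per stratum differ by at
    most one and any remainder lands in the lowest-indexed folds.
    """
    if K < 2:
        raise ValueError("K must be at least 2")
    rng = np.random.default_rng(seed)
    ids = compendium.included_ids()
    if K > len(ids):
        raise ValueError(f"K={K} exceeds the {len(ids)} included samples")
    ann = compendium.samples.loc[ids]
    assignment: dict[str, int] = {}
    for (subtype, cls), grp in ann.groupby(["subtype", "class_label"], sort=True):
        members = np.array(sorted(grp.index))
        if len(members) < K:
            logger.info(
                "stratum (%s, %s) has %d < K=%d samples; some folds will lack it",
                subtype, cls, len(members), K,
            )
        rng.shuffle(members)
        for j, sid in enumerate(members):
            assignment[sid] = j % K + 1
    fold = pd.Series({sid: assignment[sid] for sid in ids}, dtype=int)
    fold.index.name = "sample_id"
    return fold


def typed_sets(
    compendium: ExpressionCompendium,
    folds: pd.Series,
    part: CompoundSubtype,
    f: int,
) -> tuple[list[str], list[str]]:
    """Typed training/validation split for one compound subtype and fold.

    Training: the part's samples outside fold ``f`` (the per-subtype sets
    pooled). Validation: the part's samples inside fold ``f``.
    """
    ids = folds.index
    subtype = compendium.samples.loc[ids, "subtype"]
    in_part = subtype.isin(part)
    train = list(ids[in_part & (folds != f)])
    validation = list(ids[in_part & (folds == f)])
    if not validation:
        logger.warning("empty validation set for part %s in fold %d", sorted(part), f)
    return train, validation


def untyped_sets(
    compendium: ExpressionCompendium,
    folds: pd.Series,
    f: int,
    seed: int | np.random.Generator,
) -> dict[str, list[str]]:
    """Untyped counterpart sets for every elementary subtype in fold ``f``.

    Subtype labels are permuted within each class of the fold's training
    pool; the returned map sends each elementary subtype to the training
    samples carrying its shuffled label.
    """
    rng = np.random.default_rng(seed)
    train_ids = folds.index[folds != f]
    ann = compendium.samples.loc[train_ids]
    out: dict[str, list[str]] = {s: [] for s in sorted(ann["subtype"].unique())}
    for cls in (CLASS_GP, CLASS_PP):
        pool = ann.index[ann["class_label"] == cls]
        if len(pool) == 0:
            raise ValueError(f"fold {f}: no {cls} samples in the training pool")
        pool = np.array(sorted(pool))
        shuffled_labels = ann.loc[pool, "subtype"].to_numpy().copy()
        rng.shuffle(shuffled_labels)
        for sid, lab in zip(pool, shuffled_labels):
            out[lab].append(sid)
    return {s: sorted(v) for s, v in out.items()}


def pool_untyped(part: CompoundSubtype, untyped: dict[str, list[str]]) -> list[str]:
    """Union of the untyped sets of a compound subtype's members."""
    missing = [s for s in part if s not in untyped]
    if missing:
        raise KeyError(f"untyped map lacks subtype(s) {sorted(missing)}")
    out: list[str] = []
    for s in sorted(part):
        out.extend(untyped[s])
    return sorted(out)


@dataclass(frozen=True)
class TypedUntypedBundle:
    """Paired typed/untyped training sets sharing one validation set."""

    part: CompoundSubtype
    fold: int
    typed_train: tuple[str, ...]
    untyped_train: tuple[str, ...]
    validation: tuple[str, ...]


def build_bundles(
    compendium: ExpressionCompendium,
    folds: pd.Series,
    parts: list[CompoundSubtype],
    seed: int,
) -> list[TypedUntypedBundle]:
    """All (part, fold) bundles for the given compound subtypes.

    One subtype-label shuffle per fold is shared by every part, so the
    untyped sets of a partition's parts always tile the training pool.
    Bundles with an empty validation set are skipped with a warning.
    """
    K = int(folds.max())
    ss = np.random.SeedSequence(seed)
    fold_rngs = [np.random.default_rng(s) for s in ss.spawn(K)]
    bundles = []
    for f in range(1, K + 1):
        untyped = untyped_sets(compendium, folds, f, fold_rngs[f - 1])
        for part in parts:
            train, validation = typed_sets(compendium, folds, part, f)
            if not validation:
                continue
            bundles.append(
                TypedUntypedBundle(
                    part=part,
                    fold=f,
                    typed_train=tuple(sorted(train)),
                    untyped_train=tuple(pool_untyped(part, untyped)),
                    validation=tuple(sorted(validation)),
                )
            )
    return bundles


def max_balanced_sizes(table: SubtypeCountTable) -> tuple[int, int]:
    """Largest per-subtype (n_neg, n_pos) a fully balanced compendium can hold.

    A balanced compendium draws the same number of negatives and positives
    from every subtype, so the minima over subtypes bound both counts.
    """
    if (table.n_pos == 0).any() or (table.n_neg == 0).any():
        empty = [
            s for s in table.subtypes if table.n_pos[s] == 0 or table.n_neg[s] == 0
        ]
        raise ValueError(f"subtype(s) {empty} lack samples of one class; cannot balance")
    return int(table.n_neg.min()), int(table.n_pos.min())


@dataclass(frozen=True)
class BalancedCompendium:
    """A subsample with identical per-subtype class counts."""

    sample_ids: tuple[str, ...]
    n_neg_bal: int
    n_pos_bal: int
    seed: int


def draw_balanced_compendium(
    compendium: ExpressionCompendium, seed: int
) -> BalancedCompendium:
    """Undersample the compendium to identical per-subtype class counts.

    Per subtype, ``n_neg_bal`` good-prognosis and ``n_pos_bal``
    poor-prognosis samples are drawn without replacement (seeded).
    """
    table = SubtypeCountTable.from_compendium(compendium)
    n_neg_bal, n_pos_bal = max_balanced_sizes(table)
    rng = np.random.default_rng(seed)
    ann = compendium.samples.loc[compendium.included_ids()]
    chosen: list[str] = []
    for s in table.subtypes:
        for cls, n in ((CLASS_GP, n_neg_bal), (CLASS_PP, n_pos_bal)):
            pool = np.array(sorted(ann.index[(ann["subtype"] == s) & (ann["class_label"] == cls)]))
            chosen.extend(rng.choice(pool, size=n, replace=False))
    return BalancedCompendium(
        sample_ids=tuple(sorted(chosen)), n_neg_bal=n_neg_bal, n_pos_bal=n_pos_bal, seed=seed
    )


def bundles_frame(bundles: list[TypedUntypedBundle], subtypes) -> pd.DataFrame:
    """Tidy export of bundles: sample_id, fold, arm, part_label, role."""
    from .partitions import abbreviations_for, part_label

    abbrev = abbreviations_for(subtypes)
    rows = []
    for b in bundles:
        lab = part_label(b.part, subtypes, abbrev)
        for sid in b.typed_train:
            rows.append((sid, b.fold, "typed", lab, "train"))
        for sid in b.untyped_train:
            rows.append((sid, b.fold, "untyped", lab, "train"))
        for sid in b.validation:
            rows.append((sid, b.fold, "both", lab, "validation"))
    return pd.DataFrame(rows, columns=["sample_id", "fold", "arm", "part_label", "role"])
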