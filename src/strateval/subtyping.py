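"""Module-score computation and two-stage Gaussian-mixture subtyping.

Instead of clustering thousands of genes directly, each sample is first
summarised by a handful of *module scores* — signed, weighted averages of
gene sets tracking estrogen-receptor (ER) signalling, HER2 amplification
and proliferation (AURKA). A three-component Gaussian mixture on the
(ER, HER2) plane separates luminal, Her2 and basal tumours; a second
two-component mixture on the AURKA score splits the luminal group into
lumA (low proliferation) and lumB (high proliferation).

The mixture machinery is standard EM (scikit-learn); the module gene lists
are caller-supplied, so any module definition — including the synthetic
defaults shipped with :mod:`strateval.synthetic` — plugs in unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .compendium import ExpressionCompendium

logger = logging.getLogger(__name__)

LUMINAL = "luminal"
STAGE1_LABELS = (LUMINAL, "Her2", "basal")
STAGE2_LABELS = ("lumA", "lumB")
#: Canonical order used for deterministic tie-breaking.
SUBTYPE_ORDER = ("lumA", "lumB", "Her2", "basal")

ER, HER2, AURKA = "ER", "HER2", "AURKA"


@dataclass(frozen=True)
class ModuleDefinition:
    """A named gene set with per-gene signs and nonnegative weights.

    ``members`` is a list of ``(gene_id, sign, weight)``; weights are
    renormalized over the members actually present in a compendium.
    """

    name: str
    members: tuple[tuple[str, int, float], ...]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"module {self.name!r} has no members")
        for gene, sign, weight in self.members:
            if sign not in (-1, 1):
                raise ValueError(f"module {self.name!r}: sign for {gene!r} must be +1 or -1")
            if weight < 0:
                raise ValueError(f"module {self.name!r}: negative weight for {gene!r}")

    @classmethod
    def uniform(cls, name: str, genes, sign: int = 1) -> "ModuleDefinition":
        return cls(name, tuple((g, sign, 1.0) for g in genes))


def module_scores(
    compendium: ExpressionCompendium, modules: list[ModuleDefinition]
) -> pd.DataFrame:
    """Samples x modules score matrix: renormalized signed weighted averages.

    Module members absent from the compendium are dropped with a warning;
    a module with no present members is an error.
    """
    out = {}
    gene_index = compendium.values.index
    for mod in modules:
        present = [(g, s, w) for g, s, w in mod.members if g in gene_index]
        dropped = len(mod.members) - len(present)
        if not present:
            raise ValueError(f"module {mod.name!r}: no member genes present in the compendium")
        if dropped:
            logger.warning("module %s: dropped %d absent member gene(s)", mod.name, dropped)
        genes = [g for g, _, _ in present]
        w = np.array([s * w for _, s, w in present], dtype=float)
        norm = np.array([w2 for _, _, w2 in present], dtype=float).sum()
        expr = compendium.values.loc[genes].to_numpy(dtype=float)
        out[mod.name] = (w @ expr) / norm
    return pd.DataFrame(out, index=compendium.sample_ids)


@dataclass(frozen=True)
class SubtypeModel:
    """Fitted two-stage mixture with component -> subtype label maps."""

    stage1: GaussianMixture
    stage1_labels: tuple[str, ...]  # per component: luminal / Her2 / basal
    stage2: GaussianMixture
    stage2_labels: tuple[str, ...]  # per component: lumA / lumB
    score_columns: tuple[str, str, str] = (ER, HER2, AURKA)


def _check_nondegenerate(x: np.ndarray, what: str) -> None:
    if np.ptp(x, axis=0).max() < 1e-12:
        raise ValueError(f"degenerate {what}: all samples have identical scores (singular fit)")


def fit_subtype_model(
    scores: pd.DataFrame, seed: int = 0, n_restarts: int = 10
) -> SubtypeModel:
    """Fit the two-stage subtype mixture on ER/HER2/AURKA module scores.

    Stage 1: 3 full-covariance Gaussian components on the (ER, HER2) plane.
    The component with the highest HER2 mean is Her2; of the remaining two,
    the one with the higher ER mean is luminal and the other basal.
    Stage 2: 2 scalar-variance components on the AURKA score of the
    luminal-assigned samples; the higher AURKA mean is lumB.

    EM runs ``n_restarts`` seeded k-means++-style initializations and keeps
    the best log-likelihood.
    """
    for col in (ER, HER2, AURKA):
        if col not in scores.columns:
            raise ValueError(f"scores must contain a {col!r} column")
    xy = scores[[ER, HER2]].to_numpy(dtype=float)
    if len(xy) < 6:
        raise ValueError("need at least 6 samples to fit the stage-1 mixture")
    _check_nondegenerate(xy, "stage-1 scores")
    try:
        gm1 = GaussianMixture(
            n_components=3,
            covariance_type="full",
            n_init=n_restarts,
            random_state=seed,
            reg_covar=1e-9,
        ).fit(xy)
    except Exception as exc:  # pragma: no cover - sklearn-internal failures
        raise ValueError(f"stage-1 EM failed (seed={seed}, restarts={n_restarts}): {exc}") from exc
    means = gm1.means_
    her2_comp = int(np.argmax(means[:, 1]))
    rest = [i for i in range(3) if i != her2_comp]
    lum_comp = rest[int(np.argmax(means[rest, 0]))]
    basal_comp = next(i for i in rest if i != lum_comp)
    labels1 = [""] * 3
    labels1[her2_comp] = "Her2"
    labels1[lum_comp] = LUMINAL
    labels1[basal_comp] = "basal"

    stage1_assign = np.array([labels1[c] for c in gm1.predict(xy)])
    lum_mask = stage1_assign == LUMINAL
    aurka = scores.loc[lum_mask, AURKA].to_numpy(dtype=float).reshape(-1, 1)
    if len(aurka) < 4:
        raise ValueError(
            f"only {len(aurka)} luminal-assigned samples; need at least 4 for the stage-2 mixture"
        )
    _check_nondegenerate(aurka, "stage-2 scores")
    try:
        gm2 = GaussianMixture(
            n_components=2,
            covariance_type="spherical",
            n_init=n_restarts,
            random_state=seed,
            reg_covar=1e-9,
        ).fit(aurka)
    except Exception as exc:  # pragma: no cover
        raise ValueError(f"stage-2 EM failed (seed={seed}, restarts={n_restarts}): {exc}") from exc
    hi = int(np.argmax(gm2.means_[:, 0]))
    labels2 = ["lumA", "lumA"]
    labels2[hi] = "lumB"
    return SubtypeModel(
        stage1=gm1, stage1_labels=tuple(labels1), stage2=gm2, stage2_labels=tuple(labels2)
    )


def assign_subtypes(model: SubtypeModel, scores: pd.DataFrame) -> pd.DataFrame:
    """Maximum-posterior subtype per sample through the two-stage rule.

    Returns a DataFrame indexed like ``scores`` with columns ``subtype``,
    ``posterior`` (for luminal sub-labels: stage-1 luminal posterior times
    the stage-2 posterior) and ``tie`` (True when the winning posterior was
    not unique; broken toward the earliest label in canonical order).
    """
    for col in model.score_columns:
        if col not in scores.columns:
            raise ValueError(f"scores lack required column {col!r}")
    xy = scores[[ER, HER2]].to_numpy(dtype=float)
    post1 = model.stage1.predict_proba(xy)
    aurka = scores[[AURKA]].to_numpy(dtype=float)
    post2 = model.stage2.predict_proba(aurka)

    n = len(scores)
    labels = np.empty(n, dtype=object)
    posterior = np.zeros(n)
    tie = np.zeros(n, dtype=bool)
    order = {lab: i for i, lab in enumerate(SUBTYPE_ORDER)}
    for i in range(n):
        # stage 1 winner with deterministic tie-break
        p1 = post1[i]
        best = p1.max()
        cands = [c for c in range(3) if p1[c] == best]
        if len(cands) > 1:
            tie[i] = True
            cands.sort(key=lambda c: order.get(model.stage1_labels[c], 99))
        comp = cands[0]
        lab1 = model.stage1_labels[comp]
        if lab1 != LUMINAL:
            labels[i] = lab1
            posterior[i] = p1[comp]
            continue
        p2 = post2[i]
        best2 = p2.max()
        cands2 = [c for c in range(2) if p2[c] == best2]
        if len(cands2) > 1:
            tie[i] = True
            cands2.sort(key=lambda c: order[model.stage2_labels[c]])
        comp2 = cands2[0]
        labels[i] = model.stage2_labels[comp2]
        posterior[i] = p1[comp] * p2[comp2]
    return pd.DataFrame(
        {"subtype": labels, "posterior": posterior, "tie": tie}, index=scores.index
    )


def subtype_compendium(
    compendium: ExpressionCompendium,
    modules: list[ModuleDefinition],
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[ExpressionCompendium, SubtypeModel, pd.DataFrame]:
    """Convenience wrapper: scores -> fit -> assign -> annotated compendium."""
    scores = module_scores(compendium, modules)
    model = fit_subtype_model(scores, seed=seed, n_restarts=n_restarts)
    assignment = assign_subtypes(model, scores)
    samples = compendium.samples.copy()
    samples["subtype"] = assignment["subtype"]
    return compendium.with_samples(samples), model, assignment
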