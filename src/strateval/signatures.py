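"""Gene filtering, feature ranking and nearest-centroid signature training.

The prediction rule is deliberately simple: genes surviving a detection-call
filter are ranked by a moderated t-statistic (empirical-Bayes variance
shrinkage, limma-style) or a signal-to-noise ratio, and a nearest-centroid
classifier over the top-``n`` genes scores a sample by the difference of its
cosine-correlation distances to the good- and poor-prognosis centroids.
The signature size ``n`` is chosen by an inner cross-validation loop: the
largest size whose mean performance curve stays within one standard
deviation of the curve's maximum (larger signatures tend to be more robust,
so ties are broken upward).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma

from .compendium import CLASS_GP, CLASS_PP, ExpressionCompendium
from .cohorts import stratified_folds

logger = logging.getLogger(__name__)

#: Effectively-infinite prior degrees of freedom (variances fully pooled).
D0_CAP = 1e6


def presence_filter(
    compendium: ExpressionCompendium,
    learning_ids: list[str],
    threshold: float = 0.70,
) -> list[str]:
    """Genes detected in at least ``threshold`` of one class's learning samples.

    A gene is kept when its fraction of Present calls reaches the threshold
    within the poor-prognosis group *or* within the good-prognosis group, so
    genes expressed in only one class survive.
    """
    if compendium.calls is None:
        raise ValueError(
            "compendium has no detection calls; pass presence_threshold=None to disable the filter"
        )
    cls = compendium.class_of(learning_ids)
    keep = np.zeros(compendium.n_genes, dtype=bool)
    any_class = False
    for c in (CLASS_PP, CLASS_GP):
        ids = list(cls.index[cls == c])
        if not ids:
            continue
        any_class = True
        frac = compendium.calls[ids].to_numpy().mean(axis=1)
        keep |= frac >= threshold
    if not any_class:
        raise ValueError("learning set contains no GP/PP samples")
    return [g for g, k in zip(compendium.genes, keep) if k]


@dataclass(frozen=True)
class RankedFeatureList:
    """Genes sorted by |statistic| descending, with the statistic values."""

    genes: tuple[str, ...]
    statistics: tuple[float, ...]
    method: str  # moderated_t | snr | plain_t

    def top(self, n: int) -> list[str]:
        return list(self.genes[:n])

    def __len__(self) -> int:
        return len(self.genes)


def _class_split(compendium: ExpressionCompendium, learning_ids, genes):
    cls = compendium.class_of(learning_ids)
    pos = list(cls.index[cls == CLASS_PP])
    neg = list(cls.index[cls == CLASS_GP])
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError(
            f"need at least 2 samples per class, got {len(pos)} PP / {len(neg)} GP"
        )
    X = compendium.values.loc[list(genes)]
    return X[pos].to_numpy(dtype=float), X[neg].to_numpy(dtype=float)


def _trigamma_inverse(y: float) -> float:
    # Newton iteration for trigamma^{-1}; y > 0.
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled-F model on log sample variances -> (d0, s0^2).

    The spread of log sample variances in excess of what ``df`` residual
    degrees of freedom explain determines the prior degrees of freedom
    ``d0``; no excess spread means the variances are exchangeable and ``d0``
    is capped at a large finite value standing in for infinity.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise ValueError("all genes have zero variance; cannot estimate a variance prior")
    z = np.log(positive)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    if e.size < 2:
        return D0_CAP, float(np.exp(emean))
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if evar <= 0:
        return D0_CAP, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    if d0 > D0_CAP:
        return D0_CAP, float(np.exp(emean))
    s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def _order_by_abs(genes, stats) -> tuple[tuple[str, ...], tuple[float, ...]]:
    # NaN statistics (0/0 cases) sort last; ties broken by gene id for determinism.
    key = np.where(np.isnan(stats), -np.inf, np.abs(stats))
    order = sorted(range(len(genes)), key=lambda i: (-key[i], genes[i]))
    return tuple(genes[i] for i in order), tuple(float(stats[i]) for i in order)


def moderated_t_rank(
    compendium: ExpressionCompendium,
    learning_ids: list[str],
    genes: list[str],
    d0: float | None = None,
    s0_sq: float | None = None,
) -> RankedFeatureList:
    """Rank genes by |moderated t| (poor minus good prognosis).

    Per gene the pooled within-class variance ``s_g^2`` (``d_g = n1+n2-2``
    d.f.) is shrunk toward an empirical-Bayes prior ``(d0, s0^2)`` estimated
    from all genes, giving the posterior variance
    ``(d0*s0^2 + d_g*s_g^2)/(d0+d_g)``; the statistic is the mean difference
    over the posterior standard error. ``d0=0`` disables shrinkage (ordinary
    t); very large ``d0`` approaches a mean-difference ranking.
    """
    Xp, Xn = _class_split(compendium, learning_ids, genes)
    n1, n2 = Xp.shape[1], Xn.shape[1]
    df = n1 + n2 - 2
    diff = Xp.mean(axis=1) - Xn.mean(axis=1)
    s2 = ((n1 - 1) * Xp.var(axis=1, ddof=1) + (n2 - 1) * Xn.var(axis=1, ddof=1)) / df
    if not np.any(s2 > 0) and not (d0 and s0_sq):
        raise ValueError("all genes have zero within-class variance")
    if d0 is None:
        d0, s0_sq_est = estimate_variance_prior(s2, df)
        if s0_sq is None:
            s0_sq = s0_sq_est
    elif d0 > 0 and s0_sq is None:
        _, s0_sq = estimate_variance_prior(s2, df)
    if d0 == 0:
        post = s2
        method = "plain_t"
    else:
        post = (d0 * s0_sq + df * s2) / (d0 + df)
        method = "moderated_t"
    se = np.sqrt(post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    return RankedFeatureList(*_order_by_abs(list(genes), t), method=method)


def snr_rank(
    compendium: ExpressionCompendium, learning_ids: list[str], genes: list[str]
) -> RankedFeatureList:
    """Rank genes by |signal-to-noise ratio| = |mean diff| / (sd_PP + sd_GP)."""
    Xp, Xn = _class_split(compendium, learning_ids, genes)
    diff = Xp.mean(axis=1) - Xn.mean(axis=1)
    denom = Xp.std(axis=1, ddof=1) + Xn.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(denom > 0, diff / denom, np.nan)  # zero-denominator: last
    n_zero = int((denom == 0).sum())
    if n_zero:
        logger.info("snr_rank: %d gene(s) with zero denominator ranked last", n_zero)
    return RankedFeatureList(*_order_by_abs(list(genes), snr), method="snr")


RANKERS = {"moderated_t": moderated_t_rank, "snr": snr_rank}


@dataclass(frozen=True)
class TrainedSignaturePredictor:
    """Nearest-centroid rule over a fixed gene signature (cosine distance)."""

    features: tuple[str, ...]
    centroid_gp: np.ndarray
    centroid_pp: np.ndarray
    n: int
    ranking: str

    def __post_init__(self):
        if self.n < 1 or self.n != len(self.features):
            raise ValueError("signature size must match the feature list")
        if not (np.isfinite(self.centroid_gp).all() and np.isfinite(self.centroid_pp).all()):
            raise ValueError("non-finite centroid")

    def to_dict(self) -> dict:
        return {
            "features": list(self.features),
            "centroid_gp": [float(v) for v in self.centroid_gp],
            "centroid_pp": [float(v) for v in self.centroid_pp],
            "n": self.n,
            "ranking": self.ranking,
            "distance": "cosine",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedSignaturePredictor":
        return cls(
            features=tuple(d["features"]),
            centroid_gp=np.asarray(d["centroid_gp"], dtype=float),
            centroid_pp=np.asarray(d["centroid_pp"], dtype=float),
            n=int(d["n"]),
            ranking=d["ranking"],
        )


def nc_train(
    compendium: ExpressionCompendium,
    learning_ids: list[str],
    genes: list[str],
    ranking: str = "moderated_t",
) -> TrainedSignaturePredictor:
    """Per-class mean centroids over the given signature genes."""
    cls = compendium.class_of(learning_ids)
    pos = list(cls.index[cls == CLASS_PP])
    neg = list(cls.index[cls == CLASS_GP])
    if not pos or not neg:
        raise ValueError("both classes must be present in the learning set")
    X = compendium.values.loc[list(genes)]
    return TrainedSignaturePredictor(
        features=tuple(genes),
        centroid_gp=X[neg].to_numpy(dtype=float).mean(axis=1),
        centroid_pp=X[pos].to_numpy(dtype=float).mean(axis=1),
        n=len(genes),
        ranking=ranking,
    )


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-norm vector over the signature; cosine distance undefined")
    return float(a @ b) / (na * nb)


def nc_score(predictor: TrainedSignaturePredictor, x: np.ndarray | pd.Series) -> float:
    """Distance difference d(x, GP centroid) - d(x, PP centroid).

    Positive scores favor poor prognosis; the hard classification is PP iff
    the score is strictly positive (ties go to the majority GP class). The
    score is invariant under positive rescaling of ``x``.
    """
    if isinstance(x, pd.Series):
        x = x.loc[list(predictor.features)].to_numpy(dtype=float)
    x = np.asarray(x, dtype=float)
    if x.shape != (predictor.n,):
        raise ValueError(f"sample vector must cover the {predictor.n} signature genes")
    d_gp = 1.0 - _cosine(x, predictor.centroid_gp)
    d_pp = 1.0 - _cosine(x, predictor.centroid_pp)
    return d_gp - d_pp


def nc_score_samples(
    predictor: TrainedSignaturePredictor,
    compendium: ExpressionCompendium,
    ids: list[str],
) -> pd.Series:
    """Vectorized :func:`nc_score` over a set of compendium samples."""
    X = compendium.values.loc[list(predictor.features), list(ids)].to_numpy(dtype=float)
    xn = np.linalg.norm(X, axis=0)
    gn = np.linalg.norm(predictor.centroid_gp)
    pn = np.linalg.norm(predictor.centroid_pp)
    if gn == 0 or pn == 0 or (xn == 0).any():
        raise ValueError("zero-norm vector over the signature; cosine distance undefined")
    cos_gp = (predictor.centroid_gp @ X) / (xn * gn)
    cos_pp = (predictor.centroid_pp @ X) / (xn * pn)
    return pd.Series(cos_pp - cos_gp, index=list(ids))


def prefix_nc_scores(
    X: np.ndarray, centroid_gp: np.ndarray, centroid_pp: np.ndarray
) -> np.ndarray:
    """Nearest-centroid scores for every signature prefix size at once.

    ``X`` is ranked-genes x samples; row ``n-1`` of the result holds the
    score of each sample under the top-``n`` signature. Cosine terms over a
    prefix are cumulative sums, so the whole curve costs one pass. Zero-norm
    prefixes (a sample or centroid all-zero over the top-``n`` genes) take
    cosine 0, i.e. the orthogonal convention.
    """
    xg = np.cumsum(X * centroid_gp[:, None], axis=0)
    xp = np.cumsum(X * centroid_pp[:, None], axis=0)
    x2 = np.cumsum(X * X, axis=0)
    g2 = np.cumsum(centroid_gp**2)[:, None]
    p2 = np.cumsum(centroid_pp**2)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        cos_gp = np.where(x2 * g2 > 0, xg / np.sqrt(x2 * g2), 0.0)
        cos_pp = np.where(x2 * p2 > 0, xp / np.sqrt(x2 * p2), 0.0)
    return cos_pp - cos_gp


@dataclass(frozen=True)
class InnerConfig:
    """Inner-loop settings for signature-size selection."""

    F: int = 10                 # inner folds
    R: int = 5                  # inner repeats
    N_max: int = 80             # largest signature size on the curve
    metric: str = "auc"         # auc | bar
    ranking: str = "moderated_t"
    presence_threshold: float | None = 0.70  # None disables the call filter

    def __post_init__(self):
        if self.F < 2:
            raise ValueError("inner fold count F must be at least 2")
        if self.metric not in ("auc", "bar"):
            raise ValueError(f"unknown inner metric {self.metric!r}")
        if self.ranking not in RANKERS:
            raise ValueError(f"unknown ranking {self.ranking!r}")


@dataclass(frozen=True)
class PerformanceCurve:
    """Mean and sd (over repeats) of a metric per signature size 1..N_max."""

    metric: str
    mean: np.ndarray
    sd: np.ndarray
    repeats: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n": np.arange(1, len(self.mean) + 1), "mean": self.mean, "sd": self.sd}
        )


def choose_signature_size(mean_curve: np.ndarray, repeat_curves: np.ndarray) -> int:
    """Largest size whose mean performance is within one sd of the maximum.

    ``repeat_curves`` is repeats x sizes; the sd is taken at the maximizing
    size. A flat curve with zero sd therefore returns the largest size.
    """
    mean_curve = np.asarray(mean_curve, dtype=float)
    i_star = int(np.nanargmax(mean_curve))
    s_star = mean_curve[i_star]
    reps = np.asarray(repeat_curves, dtype=float)
    sigma = float(np.std(reps[:, i_star], ddof=1)) if reps.shape[0] > 1 else 0.0
    ok = np.where(mean_curve >= s_star - sigma)[0]
    return int(ok[-1]) + 1


def _metric_from_scores(scores: np.ndarray, truth_pp: np.ndarray, metric: str) -> np.ndarray:
    """Row-wise metric (percent) for a sizes x samples score matrix."""
    from .evaluation import auc_rows

    if metric == "auc":
        return auc_rows(scores, truth_pp)
    # bar: classify PP iff score > 0
    pred = scores > 0
    pos, neg = truth_pp, ~truth_pp
    sen = (pred & pos).sum(axis=1) / max(pos.sum(), 1)
    spc = (~pred & neg).sum(axis=1) / max(neg.sum(), 1)
    return 100.0 * (sen + spc) / 2.0


def _filter_and_rank(
    compendium: ExpressionCompendium, ids: list[str], config: InnerConfig
) -> RankedFeatureList:
    if config.presence_threshold is not None:
        genes = presence_filter(compendium, ids, config.presence_threshold)
    else:
        genes = compendium.genes
    if not genes:
        raise ValueError("presence filter removed every gene")
    return RANKERS[config.ranking](compendium, ids, genes)


@dataclass(frozen=True)
class InnerResult:
    n_opt: int
    curve: PerformanceCurve
    predictor: TrainedSignaturePredictor
    config: InnerConfig = field(repr=False, default=InnerConfig())


def inner_protocol(
    compendium: ExpressionCompendium,
    train_ids: list[str],
    config: InnerConfig,
    seed: int,
) -> InnerResult:
    """Signature-size selection by repeated inner cross-validation.

    For each of ``R`` repeats the training set is split into ``F`` folds
    stratified by (class, subtype); per fold the learning part is filtered
    and ranked, nearest-centroid predictors for sizes 1..N_max score the
    held-out part, and the pooled assignments give one curve point per size.
    The repeat-averaged curve picks ``n_opt`` (largest size within one sd of
    the maximum); the final predictor re-ranks on the full training set.
    """
    train_ids = sorted(train_ids)
    sub = compendium.subset(train_ids)
    ss = np.random.SeedSequence(seed)
    repeat_seeds = ss.spawn(config.R)
    n_max = min(config.N_max, compendium.n_genes)
    repeat_curves = []
    for r in range(config.R):
        rng = np.random.default_rng(repeat_seeds[r])
        F = min(config.F, len(train_ids))
        folds = stratified_folds(sub, F, rng)
        pooled_scores: list[np.ndarray] = []
        pooled_truth: list[np.ndarray] = []
        for f in range(1, F + 1):
            learn = sorted(folds.index[folds != f])
            evaluate = sorted(folds.index[folds == f])
            if not evaluate:
                continue
            cls_learn = sub.class_of(learn)
            if (cls_learn == CLASS_PP).sum() < 2 or (cls_learn == CLASS_GP).sum() < 2:
                logger.info("inner fold %d lacks a class; skipped", f)
                continue
            ranked = _filter_and_rank(sub, learn, config)
            n_here = min(n_max, len(ranked))
            top = ranked.top(n_here)
            centroids = nc_train(sub, learn, top, ranking=config.ranking)
            X = sub.values.loc[top, evaluate].to_numpy(dtype=float)
            score_mat = prefix_nc_scores(X, centroids.centroid_gp, centroids.centroid_pp)
            if n_here < n_max:  # pad so all folds share one size axis
                pad = np.repeat(score_mat[-1:], n_max - n_here, axis=0)
                score_mat = np.vstack([score_mat, pad])
            pooled_scores.append(score_mat)
            pooled_truth.append((sub.class_of(evaluate) == CLASS_PP).to_numpy())
        if not pooled_scores:
            logger.warning("inner repeat %d produced no usable folds; skipped", r)
            continue
        scores = np.hstack(pooled_scores)
        truth = np.concatenate(pooled_truth)
        repeat_curves.append(_metric_from_scores(scores, truth, config.metric))
    if repeat_curves:
        reps = np.vstack(repeat_curves)
        mean_curve = reps.mean(axis=0)
        sd_curve = reps.std(axis=0, ddof=1) if reps.shape[0] > 1 else np.zeros_like(mean_curve)
        n_opt = choose_signature_size(mean_curve, reps)
    else:
        # training set too small for any inner split: fall back to the
        # largest signature (the selection rule's answer for a flat curve)
        logger.warning("no usable inner folds at all; using n_opt = N_max = %d", n_max)
        mean_curve = np.full(n_max, np.nan)
        sd_curve = np.full(n_max, np.nan)
        n_opt = n_max
    ranked_full = _filter_and_rank(sub, train_ids, config)
    n_final = min(n_opt, len(ranked_full))
    if n_final < n_opt:
        logger.warning("full-set filter leaves %d genes; clipping n_opt=%d", n_final, n_opt)
    predictor = nc_train(sub, train_ids, ranked_full.top(n_final), ranking=config.ranking)
    curve = PerformanceCurve(
        metric=config.metric, mean=mean_curve, sd=sd_curve, repeats=len(repeat_curves)
    )
    return InnerResult(n_opt=n_final, curve=curve, predictor=predictor, config=config)
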