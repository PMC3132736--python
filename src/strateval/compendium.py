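"""Expression-compendium data model, I/O, labeling and standardization.

A compendium pools several expression studies measured on one platform:
a genes x samples value matrix, optional Present/Absent detection calls,
and per-sample annotation (study of origin, distant-metastasis-free
survival, binary prognosis class, molecular subtype).

Class labels follow the five-year distant-metastasis rule: a sample is
poor prognosis (PP) when it had a distant metastasis within five years,
good prognosis (GP) when it remained event-free with at least five years
of follow-up; late events and short event-free follow-up are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLASS_GP = "GP"
CLASS_PP = "PP"
CLASS_EXCLUDED = "excluded"
CLASS_UNKNOWN = "unknown"
CLASS_TOKENS = (CLASS_GP, CLASS_PP, CLASS_EXCLUDED, CLASS_UNKNOWN)

SUBTYPE_UNKNOWN = "unknown"

ANNOTATION_COLUMNS = ["sample_id", "study_id", "t_dmfs", "e_dmfs", "class_label", "subtype"]


@dataclass(frozen=True)
class ExpressionCompendium:
    """Genes x samples expression values with annotations and optional calls.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    samples
        DataFrame indexed by sample id with columns ``study_id``, ``t_dmfs``
        (years, NaN if unknown), ``e_dmfs`` (0/1, NaN if unknown),
        ``class_label`` (GP/PP/excluded/unknown) and ``subtype``.
    calls
        Optional boolean DataFrame, same shape/axes as ``values``; True means
        the gene was called Present in that hybridization.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    calls: pd.DataFrame | None = None

    def __post_init__(self):
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids in expression matrix")
        if self.samples.index.duplicated().any():
            raise ValueError("duplicate sample ids in annotation")
        if list(self.samples.index) != list(self.values.columns):
            missing = set(self.values.columns) ^ set(self.samples.index)
            raise ValueError(
                f"annotation and expression matrix disagree on samples: {sorted(missing)[:5]}"
            )
        bad = set(self.samples["class_label"]) - set(CLASS_TOKENS)
        if bad:
            raise ValueError(f"unknown class tokens {sorted(bad)}; expected one of {CLASS_TOKENS}")
        if self.calls is not None:
            if not self.calls.index.equals(self.values.index) or not self.calls.columns.equals(
                self.values.columns
            ):
                raise ValueError("calls matrix axes do not match the expression matrix")

    # -- convenience views ------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def has_calls(self) -> bool:
        return self.calls is not None

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def included_ids(self) -> list[str]:
        """Samples carrying a proper class label (GP or PP) and a known subtype."""
        m = self.samples["class_label"].isin([CLASS_GP, CLASS_PP]) & (
            self.samples["subtype"] != SUBTYPE_UNKNOWN
        )
        return list(self.samples.index[m])

    def class_of(self, ids) -> pd.Series:
        return self.samples.loc[list(ids), "class_label"]

    def subtype_of(self, ids) -> pd.Series:
        return self.samples.loc[list(ids), "subtype"]

    def subset(self, ids) -> "ExpressionCompendium":
        """New compendium restricted to ``ids`` (order preserved as given)."""
        ids = list(ids)
        return ExpressionCompendium(
            values=self.values[ids],
            samples=self.samples.loc[ids],
            calls=None if self.calls is None else self.calls[ids],
        )

    def with_samples(self, samples: pd.DataFrame) -> "ExpressionCompendium":
        return replace(self, samples=samples)


def _normalize_annotation(samples: pd.DataFrame) -> pd.DataFrame:
    out = samples.copy()
    for col, default in (
        ("t_dmfs", np.nan),
        ("e_dmfs", np.nan),
        ("class_label", CLASS_UNKNOWN),
        ("subtype", SUBTYPE_UNKNOWN),
    ):
        if col not in out.columns:
            out[col] = default
    out["class_label"] = out["class_label"].fillna(CLASS_UNKNOWN)
    out["subtype"] = out["subtype"].fillna(SUBTYPE_UNKNOWN)
    return out


def derive_class_labels(
    samples: pd.DataFrame, horizon: float = 5.0, overwrite: bool = True
) -> pd.DataFrame:
    """Set GP/PP/excluded/unknown from distant-metastasis-free survival.

    PP: event within the horizon (``e_dmfs == 1`` and ``t_dmfs <= horizon``).
    GP: event-free with follow-up of at least the horizon.
    excluded: late event, or event-free follow-up shorter than the horizon.
    unknown: survival data missing. Boundary times exactly at the horizon are
    inclusive on both sides (event at t == horizon is PP; censoring at
    t == horizon is GP).
    """
    t = pd.to_numeric(samples["t_dmfs"], errors="raise")
    e = pd.to_numeric(samples["e_dmfs"], errors="raise")
    if (t.dropna() < 0).any():
        bad = samples.index[t < 0][:5]
        raise ValueError(f"negative dmfs time for samples {list(bad)}")
    known = t.notna() & e.notna()
    if not set(e[known].unique()) <= {0, 1}:
        raise ValueError("e_dmfs must be 0 or 1")
    label = pd.Series(CLASS_UNKNOWN, index=samples.index, dtype=object)
    label[known & (e == 1) & (t <= horizon)] = CLASS_PP
    label[known & (e == 0) & (t >= horizon)] = CLASS_GP
    label[known & (e == 1) & (t > horizon)] = CLASS_EXCLUDED
    label[known & (e == 0) & (t < horizon)] = CLASS_EXCLUDED
    out = samples.copy()
    if overwrite:
        out["class_label"] = label
    else:
        keep = out["class_label"].isin([CLASS_GP, CLASS_PP, CLASS_EXCLUDED])
        out.loc[~keep, "class_label"] = label[~keep]
    return out


def standardize_per_study(compendium: ExpressionCompendium) -> ExpressionCompendium:
    """Z-score each gene within each study (population-sd convention).

    Pooling studies on different intensity scales requires putting every
    (gene, study) block on a common scale first. Constant blocks map to 0.
    Idempotent up to float tolerance; detection calls are untouched.
    """
    study = compendium.samples["study_id"]
    if study.isna().any():
        raise ValueError("every sample needs a study_id for per-study standardization")
    sizes = study.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise ValueError(f"studies with fewer than 2 samples: {list(small.index)}")
    values = compendium.values.copy()
    for sid, cols in compendium.samples.groupby(study, sort=False).groups.items():
        block = values[list(cols)].to_numpy(dtype=float)
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=0, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (block - mu) / sd
        z[np.broadcast_to(sd == 0, z.shape)] = 0.0
        values[list(cols)] = z
    return replace(compendium, values=values)


@dataclass(frozen=True)
class SubtypeCountTable:
    """Per-subtype GP/PP counts with totals and negative:positive ratios."""

    counts: pd.DataFrame  # index: subtype (ordered); columns: n_neg, n_pos
    order: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if (self.counts[["n_neg", "n_pos"]] < 0).any().any():
            raise ValueError("negative counts")

    @classmethod
    def from_counts(cls, counts: dict[str, tuple[int, int]]) -> "SubtypeCountTable":
        """Build directly from ``{subtype: (n_neg, n_pos)}`` (insertion order kept)."""
        frame = pd.DataFrame(
            [(s, int(n), int(p)) for s, (n, p) in counts.items()],
            columns=["subtype", "n_neg", "n_pos"],
        ).set_index("subtype")
        return cls(counts=frame, order=tuple(counts))

    @classmethod
    def from_compendium(
        cls, compendium: ExpressionCompendium, order: list[str] | None = None
    ) -> "SubtypeCountTable":
        ids = compendium.included_ids()
        ann = compendium.samples.loc[ids]
        subtypes = order if order is not None else sorted(ann["subtype"].unique())
        rows = {}
        for s in subtypes:
            sub = ann[ann["subtype"] == s]
            rows[s] = (
                int((sub["class_label"] == CLASS_GP).sum()),
                int((sub["class_label"] == CLASS_PP).sum()),
            )
        return cls.from_counts(rows)

    @property
    def subtypes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_neg(self) -> pd.Series:
        return self.counts["n_neg"]

    @property
    def n_pos(self) -> pd.Series:
        return self.counts["n_pos"]

    @property
    def totals(self) -> pd.Series:
        return self.n_neg + self.n_pos

    @property
    def ratios(self) -> pd.Series:
        """n_neg / n_pos per subtype; NaN (undefined) where n_pos is zero."""
        with np.errstate(divide="ignore", invalid="ignore"):
            r = self.n_neg / self.n_pos.replace(0, np.nan)
        return r

    @property
    def overall(self) -> pd.Series:
        n_neg, n_pos = int(self.n_neg.sum()), int(self.n_pos.sum())
        total = n_neg + n_pos
        ratio = n_neg / n_pos if n_pos else np.nan
        return pd.Series({"n_neg": n_neg, "n_pos": n_pos, "total": total, "ratio": ratio})

    def shares(self) -> pd.Series:
        """Per-subtype total as a percentage of the grand total."""
        return 100.0 * self.totals / self.overall["total"]

    def to_frame(self, decimals: int = 1) -> pd.DataFrame:
        """Display table: rows n_neg/n_pos/total/ratio, columns subtypes + overall."""
        cols = {}
        for s in self.subtypes:
            cols[s] = [
                self.n_neg[s],
                self.n_pos[s],
                int(self.totals[s]),
                round(float(self.ratios[s]), decimals) if np.isfinite(self.ratios[s]) else np.nan,
            ]
        ov = self.overall
        cols["overall"] = [ov["n_neg"], ov["n_pos"], ov["total"], round(float(ov["ratio"]), decimals)]
        return pd.DataFrame(cols, index=["n_neg", "n_pos", "total", "ratio"])


def count_table(
    compendium: ExpressionCompendium, order: list[str] | None = None
) -> SubtypeCountTable:
    """Subtype x class tally over properly labeled samples."""
    return SubtypeCountTable.from_compendium(compendium, order=order)


# -- TSV I/O ---------------------------------------------------------------


def write_compendium(
    compendium: ExpressionCompendium,
    expr_path: str | Path,
    annot_path: str | Path,
    calls_path: str | Path | None = None,
) -> None:
    """Write expression, annotation and (optionally) calls as TSV files."""
    values = compendium.values.copy()
    values.index.name = "gene_id"
    values.to_csv(expr_path, sep="\t")
    ann = compendium.samples.copy()
    ann.index.name = "sample_id"
    ann.reset_index()[ANNOTATION_COLUMNS].to_csv(annot_path, sep="\t", index=False)
    if calls_path is not None:
        if compendium.calls is None:
            raise ValueError("compendium has no detection calls to write")
        calls = compendium.calls.map(lambda present: "P" if present else "A")
        calls.index.name = "gene_id"
        calls.to_csv(calls_path, sep="\t")


def read_compendium(
    expr_path: str | Path,
    annot_path: str | Path,
    calls_path: str | Path | None = None,
) -> ExpressionCompendium:
    """Read a compendium written by :func:`write_compendium`.

    The expression TSV has gene ids in the first column and one column per
    sample; the annotation TSV has columns sample_id, study_id, t_dmfs,
    e_dmfs and optionally class_label and subtype. A calls TSV uses P/A
    tokens on the same axes as the expression matrix.
    """
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.columns = values.columns.astype(str)
    ann = pd.read_csv(annot_path, sep="\t", dtype={"sample_id": str, "study_id": str})
    if "sample_id" not in ann.columns:
        raise ValueError("annotation file lacks a sample_id column")
    if ann["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in annotation file")
    ann = ann.set_index("sample_id")
    extra = set(ann.index) - set(values.columns)
    if extra:
        raise ValueError(f"annotation references samples absent from the matrix: {sorted(extra)[:5]}")
    missing = set(values.columns) - set(ann.index)
    if missing:
        raise ValueError(f"samples missing from annotation: {sorted(missing)[:5]}")
    ann = _normalize_annotation(ann.loc[list(values.columns)])
    calls = None
    if calls_path is not None:
        raw = pd.read_csv(calls_path, sep="\t", index_col=0)
        raw.index = raw.index.astype(str)
        raw.columns = raw.columns.astype(str)
        if not raw.index.equals(values.index) or not raw.columns.equals(values.columns):
            raise ValueError("calls file axes do not match the expression matrix")
        tokens = set(np.unique(raw.to_numpy(dtype=str)))
        if not tokens <= {"P", "A"}:
            raise ValueError(f"calls file contains tokens other than P/A: {sorted(tokens - {'P', 'A'})}")
        calls = raw == "P"
    else:
        logger.info("no calls file given; the presence filter will be unavailable")
    return ExpressionCompendium(values=values, samples=ann, calls=calls)
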