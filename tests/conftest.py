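import numpy as np
import pandas as pd
import pytest

from strateval import (
    ElementarySubtypeSet,
    ExpressionCompendium,
    SubtypeCountTable,
    fixture_toy,
)
from strateval.synthetic import TABLE1_COUNTS, SyntheticConfig, simulate_compendium


@pytest.fixture(scope="session")
def toy() -> ExpressionCompendium:
    """Deterministic 18-sample, 3-subtype toy compendium (3 GP + 3 PP each)."""
    return fixture_toy()


@pytest.fixture(scope="session")
def table1() -> SubtypeCountTable:
    """The published compendium's subtype x class counts."""
    return SubtypeCountTable.from_counts(TABLE1_COUNTS)


@pytest.fixture(scope="session")
def four_subtypes() -> ElementarySubtypeSet:
    return ElementarySubtypeSet(["lumA", "lumB", "Her2", "basal"])


@pytest.fixture(scope="session")
def table1_compendium() -> ExpressionCompendium:
    """Small-gene-panel compendium whose class/subtype tallies equal the published table."""
    cfg = SyntheticConfig(counts=dict(TABLE1_COUNTS), n_genes=250)
    compendium, _ = simulate_compendium(cfg, seed=11)
    return compendium


@pytest.fixture(scope="session")
def signal_compendium():
    """Balanced 4-subtype compendium with subtype-specific prognostic signal only."""
    cfg = SyntheticConfig(
        counts={s: (15, 15) for s in ("lumA", "lumB", "Her2", "basal")},
        n_genes=300,
        delta_shared=0.0,
        delta_subtype=1.0,
    )
    return simulate_compendium(cfg, seed=5)


def tiny_compendium(values: np.ndarray, classes, subtypes=None, calls=None, studies=None):
    """Hand-rolled compendium for arithmetic-level tests."""
    n_genes, n_samples = values.shape
    genes = [f"g{i}" for i in range(n_genes)]
    ids = [f"s{i}" for i in range(n_samples)]
    samples = pd.DataFrame(
        {
            "study_id": studies if studies is not None else ["st1"] * n_samples,
            "t_dmfs": np.nan,
            "e_dmfs": np.nan,
            "class_label": list(classes),
            "subtype": list(subtypes) if subtypes is not None else ["A"] * n_samples,
        },
        index=pd.Index(ids, name="sample_id"),
    )
    calls_df = None
    if calls is not None:
        calls_df = pd.DataFrame(np.asarray(calls, dtype=bool), index=genes, columns=ids)
    return ExpressionCompendium(
        values=pd.DataFrame(values, index=genes, columns=ids),
        samples=samples,
        calls=calls_df,
    )
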