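"""Synthetic expression compendia with known subtype and prognosis structure.

The generator emulates the structure of a pooled breast-cancer compendium:
four molecular subtypes of unequal size and unequal good:poor prognosis
ratios (the default counts mirror a published 892-sample compendium), study
batches, module-gene structure (ER-, HER2- and proliferation-like gene
blocks that drive subtyping), survival times bracketing the five-year
labeling horizon, and Present/Absent detection calls. Prognostic signal is
split into a *shared* component (the same genes separate the classes in
every subtype) and *subtype-specific* components (each subtype has its own
signal genes), so the value of subtype-stratified training can be dialed
from zero to dominant.

Truth (subtype, class, study, signal gene sets) is returned alongside the
compendium, making every pipeline stage testable without any download.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compendium import CLASS_GP, CLASS_PP, ExpressionCompendium
from .subtyping import ModuleDefinition

#: Good/poor prognosis counts per subtype emulating the published compendium.
TABLE1_COUNTS: dict[str, tuple[int, int]] = {
    "lumA": (273, 42),
    "lumB": (216, 94),
    "basal": (100, 57),
    "Her2": (74, 36),
}

LUMINAL_SUBTYPES = ("lumA", "lumB")


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults emulate the published compendium shape.

    counts
        ``{subtype: (n_neg, n_pos)}``. In fixed-count mode (default) these
        are realized exactly; in sampled mode they only set the subtype
        proportions and per-subtype poor-prognosis prevalences.
    n_genes
        Total gene count; module and signal gene sets are disjoint blocks
        carved from it, the remainder is pure noise.
    module_sizes / delta_module
        Sizes of the ER/HER2/AURKA-like blocks and the cluster separation
        (in noise-sd units) they induce: ER genes are shifted +delta in
        luminal samples, HER2 genes in Her2 samples, AURKA genes in lumB.
    n_shared, delta_shared / n_subtype_signal, delta_subtype
        Shared prognostic genes shift +delta_shared in every poor-prognosis
        sample; each subtype additionally owns ``n_subtype_signal`` genes
        shifting +delta_subtype only in its own poor-prognosis samples.
    sigma
        Gaussian noise standard deviation (the unit for all deltas).
    n_studies / batch_sd
        Samples are spread over studies; each (gene, study) pair gets a
        Gaussian offset with sd ``batch_sd`` (removed by per-study
        standardization).
    call_slope / call_center
        Present-call probability is ``sigmoid(slope * (expr - center))``;
        the defaults make roughly 90% of calls Present.
    hard_boundary
        When True, the first good- and poor-prognosis sample of each subtype
        gets a survival time of exactly 5 years (boundary-rule tests).
    """

    counts: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(TABLE1_COUNTS)
    )
    n_genes: int = 2000
    module_sizes: dict[str, int] = field(
        default_factory=lambda: {"ER": 40, "HER2": 15, "AURKA": 25}
    )
    delta_module: float = 3.0
    n_shared: int = 30
    delta_shared: float = 0.5
    n_subtype_signal: int = 20
    delta_subtype: float = 0.5
    sigma: float = 1.0
    n_studies: int = 3
    batch_sd: float = 0.5
    call_slope: float = 1.5
    call_center: float = -2.0
    fixed_counts: bool = True
    hard_boundary: bool = False
    horizon: float = 5.0

    def __post_init__(self):
        if not self.counts:
            raise ValueError("counts must name at least one subtype")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        needed = (
            sum(self.module_sizes.values())
            + self.n_shared
            + self.n_subtype_signal * len(self.counts)
        )
        if needed > self.n_genes:
            raise ValueError(
                f"gene-set allocation needs {needed} genes but n_genes={self.n_genes}"
            )
        if self.n_studies < 1:
            raise ValueError("need at least one study")

    @property
    def subtypes(self) -> tuple[str, ...]:
        return tuple(self.counts)

    @property
    def n_samples(self) -> int:
        return sum(n + p for n, p in self.counts.values())


def _allocate_genes(cfg: SyntheticConfig) -> dict:
    gene_ids = [f"g{i:05d}" for i in range(cfg.n_genes)]
    cursor = 0

    def take(n):
        nonlocal cursor
        block = gene_ids[cursor : cursor + n]
        cursor += n
        return block

    sets = {
        "modules": {name: take(n) for name, n in cfg.module_sizes.items()},
        "shared": take(cfg.n_shared),
        "subtype": {s: take(cfg.n_subtype_signal) for s in cfg.subtypes},
    }
    return gene_ids, sets


def simulate_compendium(
    cfg: SyntheticConfig, seed: int
) -> tuple[ExpressionCompendium, dict]:
    """Draw one synthetic compendium and its ground truth.

    Returns ``(compendium, truth)`` where ``truth`` carries the per-sample
    frame (sample_id, subtype, class, study) and the gene-set allocation
    (module blocks, shared and per-subtype prognostic genes).
    """
    rng = np.random.default_rng(seed)
    gene_ids, sets = _allocate_genes(cfg)

    # -- sample roster ----------------------------------------------------
    subtype: list[str] = []
    label: list[str] = []
    if cfg.fixed_counts:
        for s, (n_neg, n_pos) in cfg.counts.items():
            subtype += [s] * (n_neg + n_pos)
            label += [CLASS_GP] * n_neg + [CLASS_PP] * n_pos
    else:
        total = cfg.n_samples
        names = list(cfg.counts)
        pi = np.array([sum(cfg.counts[s]) for s in names], dtype=float)
        pi /= pi.sum()
        prevalence = {
            s: cfg.counts[s][1] / max(sum(cfg.counts[s]), 1) for s in names
        }
        z = rng.choice(names, size=total, p=pi)
        for s in z:
            subtype.append(s)
            label.append(CLASS_PP if rng.random() < prevalence[s] else CLASS_GP)
    n = len(subtype)
    sample_ids = [f"s{i:04d}" for i in range(n)]
    subtype_arr = np.array(subtype)
    is_pp = np.array(label) == CLASS_PP

    # studies: deal round-robin within (subtype, class) after a shuffle, so
    # every study sees every stratum
    study = np.empty(n, dtype=object)
    for s in cfg.subtypes:
        for pp in (False, True):
            idx = np.where((subtype_arr == s) & (is_pp == pp))[0]
            rng.shuffle(idx)
            for j, i in enumerate(idx):
                study[i] = f"study{j % cfg.n_studies + 1}"

    # -- expression matrix ------------------------------------------------
    gi = {g: i for i, g in enumerate(gene_ids)}
    X = rng.normal(0.0, cfg.sigma, size=(cfg.n_genes, n))

    study_names = sorted(set(study))
    batch = rng.normal(0.0, cfg.batch_sd, size=(cfg.n_genes, len(study_names)))
    for j, sn in enumerate(study_names):
        X[:, study == sn] += batch[:, [j]]

    d = cfg.delta_module * cfg.sigma
    lum = np.isin(subtype_arr, LUMINAL_SUBTYPES)
    for g in sets["modules"].get("ER", []):
        X[gi[g], lum] += d
    for g in sets["modules"].get("HER2", []):
        X[gi[g], subtype_arr == "Her2"] += d
    for g in sets["modules"].get("AURKA", []):
        X[gi[g], subtype_arr == "lumB"] += d

    for g in sets["shared"]:
        X[gi[g], is_pp] += cfg.delta_shared * cfg.sigma
    for s, genes in sets["subtype"].items():
        mask = is_pp & (subtype_arr == s)
        for g in genes:
            X[gi[g], mask] += cfg.delta_subtype * cfg.sigma

    # -- survival bracketing the horizon ----------------------------------
    t = np.where(
        is_pp,
        rng.uniform(0.5, 4.5, size=n),
        rng.uniform(5.5, 10.0, size=n),
    )
    e = is_pp.astype(int)
    if cfg.hard_boundary:
        for s in cfg.subtypes:
            for pp in (False, True):
                idx = np.where((subtype_arr == s) & (is_pp == pp))[0]
                if idx.size:
                    t[idx[0]] = cfg.horizon

    # -- detection calls ---------------------------------------------------
    p_present = 1.0 / (1.0 + np.exp(-cfg.call_slope * (X - cfg.call_center)))
    calls = rng.random(size=X.shape) < p_present

    values = pd.DataFrame(X, index=gene_ids, columns=sample_ids)
    calls_df = pd.DataFrame(calls, index=gene_ids, columns=sample_ids)
    samples = pd.DataFrame(
        {
            "study_id": study,
            "t_dmfs": t,
            "e_dmfs": e,
            "class_label": label,
            "subtype": subtype,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    compendium = ExpressionCompendium(values=values, samples=samples, calls=calls_df)
    truth = {
        "samples": samples[["subtype", "class_label", "study_id"]].copy(),
        "gene_sets": sets,
        "config": cfg,
        "seed": seed,
    }
    return compendium, truth


def default_module_definitions(truth: dict) -> list[ModuleDefinition]:
    """Uniform-weight module definitions matching a simulation's gene blocks."""
    return [
        ModuleDefinition.uniform(name, genes)
        for name, genes in truth["gene_sets"]["modules"].items()
    ]


def fixture_toy(seed: int = 20110708) -> ExpressionCompendium:
    """Deterministic 18-sample toy compendium: 3 subtypes x (3 GP + 3 PP).

    A minimal panel (20 genes, one study, no batch effects, calls all
    informative) mirroring the classic stratification walkthrough; intended
    for unit tests of fold construction and the typed/untyped set algebra.
    """
    cfg = SyntheticConfig(
        counts={"luminal": (3, 3), "Her2": (3, 3), "basal": (3, 3)},
        n_genes=20,
        module_sizes={"ER": 2, "HER2": 2, "AURKA": 2},
        delta_module=2.0,
        n_shared=3,
        delta_shared=1.0,
        n_subtype_signal=2,
        delta_subtype=1.0,
        n_studies=1,
        batch_sd=0.0,
    )
    compendium, _ = simulate_compendium(cfg, seed=seed)
    return compendium


def table1_config(n_genes: int = 2000, **overrides) -> SyntheticConfig:
    """Config whose fixed counts reproduce the published subtype table exactly."""
    return SyntheticConfig(counts=dict(TABLE1_COUNTS), n_genes=n_genes, **overrides)


def write_truth(truth: dict, path) -> None:
    """Write the per-sample truth table as TSV (sample_id, subtype, class, study)."""
    frame = truth["samples"].copy()
    frame.index.name = "sample_id"
    frame.to_csv(path, sep="\t")
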