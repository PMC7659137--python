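"""Synthetic expression datasets and Cq panels with planted ground truth.

Two generative models, both seeded end-to-end:

* Expression (screening inputs): per-gene log-normal abundances.  A target
  CV maps analytically to the log-scale SD via CV^2 = exp(sigma_ln^2) - 1,
  and the location is chosen so the distribution mean equals the requested
  base abundance.  Condition- and disease-responsive archetypes add
  multiplicative per-condition effects on top.
* Cq panels (stability / normalization inputs): additive cycles,
  Cq = base + sample shift + group effect + noise, with the sample shift
  (RNA loading / RT yield) shared across genes, so every proper stability
  measure should be blind to it.

Ground truth (which genes were planted stable, the per-gene true stability
score, expected screen counts) is derived from the specification alone,
never from the realized noise.  The random stream is split per dataset by a
stable hash of the dataset id, so adding a dataset never perturbs others.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .screening import ExpressionDataset
from .stability import CqPanel

__all__ = [
    "GeneSpec",
    "ExpressionDatasetSpec",
    "CqPanelSpec",
    "GroundTruth",
    "simulate_expression_dataset",
    "simulate_cq_panel",
    "study_manifest_spec",
    "validation_panel_spec",
]

ARCHETYPES = ("stable", "condition_responsive", "disease_responsive", "noisy")


def _stable_seed(seed: int, dataset_id: str) -> np.random.Generator:
    """Deterministic per-dataset stream: global seed + stable id hash."""
    h = int.from_bytes(hashlib.sha256(dataset_id.encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence([int(seed), h]))


@dataclass(frozen=True)
class GeneSpec:
    """One gene archetype.

    For expression datasets: ``base`` is the mean abundance (expression
    units) and ``cv`` the target coefficient of variation; ``effects`` maps
    condition labels to log2 fold changes.  For Cq panels: ``base`` is the
    base Cq (cycles), ``noise_sd`` the gene-specific noise SD (cycles) and
    ``effects`` maps group labels to Cq shifts in cycles.
    """

    gene_id: str
    archetype: str = "stable"
    base: float = 1000.0
    cv: float = 0.1
    noise_sd: float = 0.2
    effects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"bad spec: unknown archetype {self.archetype!r}")
        if self.base <= 0 or self.cv < 0 or self.noise_sd < 0:
            raise ValueError("bad spec: base must be > 0 and cv/noise_sd >= 0")


@dataclass
class ExpressionDatasetSpec:
    dataset_id: str
    tissue: str
    platform: str
    genes: list[GeneSpec]
    # per sample: (condition, health); condition keys into GeneSpec.effects
    samples: list[tuple[str, str]]
    seed: int = 0


@dataclass
class CqPanelSpec:
    panel_id: str
    genes: list[GeneSpec]
    # group label -> number of samples
    group_sizes: dict[str, int]
    sample_shift_sd: float = 1.0
    seed: int = 0


@dataclass
class GroundTruth:
    """Planted truth, derivable from the spec alone."""

    stable_genes: frozenset[str]
    true_stability: pd.Series | None = None    # Cq panels: cycles
    expected_screen_count: int | None = None


def _expression_truth(spec: ExpressionDatasetSpec, min_mean=500.0, max_cv=0.2) -> GroundTruth:
    stable = frozenset(
        g.gene_id.upper()
        for g in spec.genes
        if g.archetype == "stable" and g.base > min_mean and g.cv < max_cv
    )
    return GroundTruth(stable_genes=stable, expected_screen_count=len(stable))


def simulate_expression_dataset(spec: ExpressionDatasetSpec) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw a genes x samples abundance matrix from log-normal archetypes."""
    rng = _stable_seed(spec.seed, spec.dataset_id)
    n = len(spec.samples)
    sample_ids = [f"{spec.dataset_id}_s{i+1:03d}" for i in range(n)]
    conditions = [c for c, _ in spec.samples]
    health = [h for _, h in spec.samples]
    rows = []
    for g in spec.genes:
        sigma_ln = float(np.sqrt(np.log1p(g.cv**2)))
        mu = np.log(g.base) - sigma_ln**2 / 2.0
        vals = np.exp(rng.normal(mu, sigma_ln, size=n)) if sigma_ln > 0 else np.full(n, g.base)
        log2fc = np.array([g.effects.get(c, 0.0) for c in conditions])
        rows.append(vals * 2.0**log2fc)
    abundances = pd.DataFrame(rows, index=[g.gene_id for g in spec.genes], columns=sample_ids)
    labels = pd.DataFrame({"condition": conditions, "health": health}, index=sample_ids)
    ds = ExpressionDataset(
        dataset_id=spec.dataset_id,
        tissue=spec.tissue,
        platform=spec.platform,
        abundances=abundances,
        sample_labels=labels,
    )
    return ds, _expression_truth(spec)


def simulate_cq_panel(spec: CqPanelSpec) -> tuple[CqPanel, GroundTruth]:
    """Draw a Cq panel: base + shared sample shift + group effect + noise.

    True stability per gene is sqrt(Var_groups(effect) + noise_sd^2) in
    cycles, where Var_groups is the population variance of the gene's group
    effects across the panel's groups (zero effect where unspecified).
    """
    rng = _stable_seed(spec.seed, spec.panel_id)
    if spec.sample_shift_sd < 0:
        raise ValueError("bad spec: sample_shift_sd must be >= 0")
    groups_order = list(spec.group_sizes)
    sample_ids, group_labels = [], []
    for g in groups_order:
        for i in range(spec.group_sizes[g]):
            sample_ids.append(f"{g}_s{i+1:03d}")
            group_labels.append(g)
    n = len(sample_ids)
    shift = rng.normal(0.0, spec.sample_shift_sd, size=n) if spec.sample_shift_sd > 0 else np.zeros(n)
    rows, truth = [], {}
    for g in spec.genes:
        eff = np.array([g.effects.get(lbl, 0.0) for lbl in group_labels])
        noise = rng.normal(0.0, g.noise_sd, size=n) if g.noise_sd > 0 else np.zeros(n)
        rows.append(g.base + shift + eff + noise)
        eff_per_group = np.array([g.effects.get(lbl, 0.0) for lbl in groups_order])
        truth[g.gene_id] = float(np.sqrt(np.var(eff_per_group) + g.noise_sd**2))
    cq = pd.DataFrame(rows, index=[g.gene_id for g in spec.genes], columns=sample_ids)
    panel = CqPanel(cq=cq, groups=pd.Series(group_labels, index=sample_ids, name="group"))
    gt = GroundTruth(
        stable_genes=frozenset(g.gene_id for g in spec.genes if g.archetype == "stable"),
        true_stability=pd.Series(truth, name="true_stability"),
    )
    return panel, gt


def study_manifest_spec(
    seed: int,
    n_stable: int = 30,
    n_other: int = 120,
    diseased_destabilize: bool = True,
) -> list[ExpressionDatasetSpec]:
    """A multistudy manifest shaped like the source study's design.

    Seven datasets across three tissues: two placental, two luteal (one
    with a drug-treatment condition), three uterine of which two mix healthy
    and diseased samples.  ``n_stable`` genes are planted stable (high base
    mean, low CV) in every dataset; the remaining genes are either
    low-abundance or high-CV.  When ``diseased_destabilize`` is set, the
    planted stable genes carry strong disease effects in diseased uterine
    samples, so the cross-tissue intersection is empty unless diseased
    samples are excluded.
    """
    stable_ids = [f"STB{i:03d}" for i in range(n_stable)]
    other_ids = [f"VAR{i:03d}" for i in range(n_other)]

    def genes_for(diseased_dataset: bool) -> list[GeneSpec]:
        genes = []
        for gid in stable_ids:
            effects = {}
            if diseased_dataset and diseased_destabilize:
                effects = {"diseased": 3.0}     # 8x shift wrecks the CV
            genes.append(GeneSpec(gid, "stable", base=2000.0, cv=0.05, effects=effects))
        for j, gid in enumerate(other_ids):
            if j % 2 == 0:
                genes.append(GeneSpec(gid, "noisy", base=2000.0, cv=0.6))
            else:
                genes.append(GeneSpec(gid, "noisy", base=50.0, cv=0.1))
        return genes

    healthy = lambda cond, k: [(cond, "healthy")] * k  # noqa: E731
    diseased = lambda cond, k: [(cond, "diseased")] * k  # noqa: E731
    specs = [
        ExpressionDatasetSpec("sim_placenta_1", "placenta", "rnaseq", genes_for(False),
                              healthy("midgestation", 5) + healthy("luteolysis", 4), seed),
        ExpressionDatasetSpec("sim_placenta_2", "placenta", "microarray", genes_for(False),
                              healthy("midgestation", 6), seed),
        ExpressionDatasetSpec("sim_cl_1", "CL", "rnaseq", genes_for(False),
                              healthy("pregnant", 8) + healthy("luteolysis", 7), seed),
        ExpressionDatasetSpec("sim_cl_2", "CL", "rnaseq", genes_for(False),
                              healthy("control", 12) + healthy("treated", 12), seed),
        ExpressionDatasetSpec("sim_uterus_1", "uterus", "microarray", genes_for(True),
                              healthy("diestrus", 10) + diseased("diseased", 12), seed),
        ExpressionDatasetSpec("sim_uterus_2", "uterus", "microarray", genes_for(True),
                              healthy("control", 4) + diseased("diseased", 4), seed),
        ExpressionDatasetSpec("sim_uterus_3", "uterus", "microarray", genes_for(False),
                              healthy("nonpregnant", 7) + healthy("pregnant", 7), seed),
    ]
    return specs


def validation_panel_spec(seed: int) -> CqPanelSpec:
    """A 55-sample validation panel: 23 CL, 19 uterus, 13 placenta samples.

    Seven candidate genes: four planted stable (low noise, no group
    effects) and three legacy references carrying tissue-dependent shifts
    plus higher noise, mirroring a panel where newly screened candidates
    outperform traditional ones.
    """
    genes = [
        GeneSpec("KD1", "stable", base=24.0, noise_sd=0.15),
        GeneSpec("KD2", "stable", base=26.0, noise_sd=0.20),
        GeneSpec("KD3", "stable", base=25.0, noise_sd=0.25),
        GeneSpec("KD4", "stable", base=27.0, noise_sd=0.30),
        GeneSpec("LG1", "noisy", base=20.0, noise_sd=0.6,
                 effects={"1-CL": -0.8, "2-placenta": 0.9}),
        GeneSpec("LG2", "noisy", base=19.0, noise_sd=0.7,
                 effects={"2-placenta": -1.2, "3-uterus": 0.8}),
        GeneSpec("LG3", "noisy", base=21.0, noise_sd=0.8,
                 effects={"1-CL": 1.0}),
    ]
    return CqPanelSpec(
        panel_id="sim_validation_55",
        genes=genes,
        group_sizes={"1-CL": 23, "3-uterus": 19, "2-placenta": 13},
        sample_shift_sd=0.8,
        seed=seed,
    )
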