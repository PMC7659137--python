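"""Multistudy screening for stably expressed genes.

Each expression dataset (one study: genes x samples, normalized counts or
intensities) is screened gene-by-gene with two filters: a base-mean floor
that removes under-represented genes, and a coefficient-of-variation (CV)
ceiling that removes variable genes.  Per-dataset candidate lists are then
intersected within each tissue and across tissues to find universal
reference-gene candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionDataset",
    "GeneScreenStats",
    "ScreenCriteria",
    "CandidateSet",
    "compute_gene_stats",
    "apply_screen",
    "intersect_sets",
    "run_multistudy_screen",
]

TISSUES = ("CL", "uterus", "placenta")
PLATFORMS = ("rnaseq", "microarray")


@dataclass
class ExpressionDataset:
    """One study's genes x samples abundance matrix with sample labels.

    Parameters
    ----------
    dataset_id : str
        Unique study identifier (e.g. a GEO accession).
    tissue : str
        One of ``CL``, ``uterus``, ``placenta``.
    platform : str
        ``rnaseq`` or ``microarray``.
    abundances : pandas.DataFrame
        Nonnegative expression values, index = gene ids, columns = sample ids.
    sample_labels : pandas.DataFrame
        One row per sample (index = sample ids) with at least a ``health``
        column (``healthy`` / ``diseased``); ``condition`` and ``treatment``
        columns are carried through when present.
    """

    dataset_id: str
    tissue: str
    platform: str
    abundances: pd.DataFrame
    sample_labels: pd.DataFrame

    def __post_init__(self) -> None:
        if self.tissue not in TISSUES:
            raise ValueError(f"unknown tissue {self.tissue!r}; expected one of {TISSUES}")
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}; expected one of {PLATFORMS}")
        if self.abundances.size == 0:
            raise ValueError("empty dataset")
        if self.abundances.shape[1] < 2:
            raise ValueError("insufficient samples: a dataset needs >= 2 samples")
        if self.abundances.index.duplicated().any():
            dups = self.abundances.index[self.abundances.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if (self.abundances.to_numpy() < 0).any():
            raise ValueError("negative abundance values are not allowed")
        missing = set(self.abundances.columns) - set(self.sample_labels.index)
        if missing:
            raise ValueError(f"samples without labels: {sorted(missing)}")
        if "health" not in self.sample_labels.columns:
            raise ValueError("every sample needs a health label")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.abundances.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundances.columns)


@dataclass(frozen=True)
class GeneScreenStats:
    """Per-gene screening statistics: base mean, sample SD (n-1) and CV."""

    gene_id: str
    mean: float
    sd: float
    cv: float  # NaN when mean == 0 (undefined)

    @property
    def cv_defined(self) -> bool:
        return not np.isnan(self.cv)


@dataclass(frozen=True)
class ScreenCriteria:
    """Screen thresholds: retain genes with mean > min_mean and CV < max_cv.

    Defaults follow the published screen (base mean > 500, CV < 0.2);
    ``strict=False`` relaxes the comparisons to >= / <=.
    """

    min_mean: float = 500.0
    max_cv: float = 0.2
    strict: bool = True

    def __post_init__(self) -> None:
        if self.min_mean < 0:
            raise ValueError("min_mean must be >= 0")
        if self.max_cv <= 0:
            raise ValueError("max_cv must be > 0")


@dataclass
class CandidateSet:
    """An unordered set of candidate gene ids for one scope.

    ``scope`` names what the set covers (a dataset id, a tissue, or
    ``cross-tissue``); ``provenance`` lists the contributing dataset ids.
    """

    scope: str
    gene_ids: frozenset[str]
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.gene_ids)


def compute_gene_stats(dataset: ExpressionDataset, sample_filter=None) -> list[GeneScreenStats]:
    """Compute mean, SD (n-1) and CV per gene over the retained samples.

    ``sample_filter`` is an optional predicate on a sample's label row
    (a pandas Series); samples for which it returns False are dropped
    before any statistic is computed.
    """
    mat = dataset.abundances
    if sample_filter is not None:
        keep = [s for s in mat.columns if sample_filter(dataset.sample_labels.loc[s])]
        mat = mat[keep]
    if mat.shape[1] < 2:
        raise ValueError("insufficient samples: fewer than 2 samples retained")
    means = mat.mean(axis=1).to_numpy()
    sds = mat.std(axis=1, ddof=1).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        cvs = np.where(means > 0, sds / means, np.nan)
    return [
        GeneScreenStats(gene_id=str(g), mean=float(m), sd=float(s), cv=float(c))
        for g, m, s, c in zip(mat.index, means, sds, cvs)
    ]


def apply_screen(
    stats: list[GeneScreenStats],
    criteria: ScreenCriteria = ScreenCriteria(),
    scope: str = "screen",
    provenance: tuple[str, ...] = (),
) -> CandidateSet:
    """Retain genes passing both filters; undefined-CV genes never pass."""
    if not stats:
        raise ValueError("stats must be nonempty")
    retained = []
    for st in stats:
        if not st.cv_defined:
            continue
        if criteria.strict:
            ok = st.mean > criteria.min_mean and st.cv < criteria.max_cv
        else:
            ok = st.mean >= criteria.min_mean and st.cv <= criteria.max_cv
        if ok:
            retained.append(st.gene_id)
    return CandidateSet(scope=scope, gene_ids=frozenset(retained), provenance=provenance)


def intersect_sets(sets: list[CandidateSet], scope: str) -> CandidateSet:
    """Genes present in every input set; provenance is the contributor union."""
    if not sets:
        raise ValueError("no sets to intersect")
    genes = frozenset.intersection(*(s.gene_ids for s in sets))
    prov: list[str] = []
    for s in sets:
        for p in s.provenance or (s.scope,):
            if p not in prov:
                prov.append(p)
    return CandidateSet(scope=scope, gene_ids=genes, provenance=tuple(prov))


def _case_normalized(ds: ExpressionDataset) -> ExpressionDataset:
    """Uppercase gene symbols; multiple rows per symbol collapse to max mean."""
    mat = ds.abundances.copy()
    upper = mat.index.astype(str).str.upper()
    if upper.duplicated().any():
        n_dup = int(upper.duplicated().sum())
        logger.warning(
            "%s: %d duplicate gene symbols after case-normalization; keeping max-mean row",
            ds.dataset_id, n_dup,
        )
        mat.index = upper
        mat = mat.assign(_mean=mat.mean(axis=1))
        mat = (
            mat.sort_values("_mean", ascending=False)
            .groupby(level=0, sort=False)
            .head(1)
            .drop(columns="_mean")
            .sort_index()
        )
    else:
        mat.index = upper
    return ExpressionDataset(
        dataset_id=ds.dataset_id,
        tissue=ds.tissue,
        platform=ds.platform,
        abundances=mat,
        sample_labels=ds.sample_labels,
    )


def run_multistudy_screen(
    manifest: list[ExpressionDataset],
    criteria: ScreenCriteria = ScreenCriteria(),
    exclude_diseased: bool = False,
) -> dict[str, CandidateSet]:
    """Screen every dataset and intersect within tissues and across tissues.

    Returns a mapping with one :class:`CandidateSet` per dataset id, one per
    tissue (intersection of the tissue's datasets) and one ``cross-tissue``
    set (intersection of the tissue sets).  With ``exclude_diseased`` samples
    labeled ``diseased`` are dropped before statistics; datasets left with
    fewer than 2 samples are dropped from the screen with a warning.
    """
    if not manifest:
        raise ValueError("manifest covers no datasets")
    out: dict[str, CandidateSet] = {}
    by_tissue: dict[str, list[CandidateSet]] = {}
    covered_tissues = {ds.tissue for ds in manifest}
    for ds in manifest:
        ds = _case_normalized(ds)
        sample_filter = None
        if exclude_diseased:
            sample_filter = lambda labels: labels["health"] != "diseased"  # noqa: E731
        try:
            stats = compute_gene_stats(ds, sample_filter=sample_filter)
        except ValueError:
            logger.warning("%s: fewer than 2 samples after exclusion; dataset dropped", ds.dataset_id)
            continue
        cand = apply_screen(stats, criteria, scope=ds.dataset_id, provenance=(ds.dataset_id,))
        out[ds.dataset_id] = cand
        by_tissue.setdefault(ds.tissue, []).append(cand)
    tissue_sets = []
    for tissue in sorted(covered_tissues):
        if tissue not in by_tissue:
            raise ValueError(f"tissue uncovered: no dataset for {tissue!r} survived")
        tset = intersect_sets(by_tissue[tissue], scope=tissue)
        out[tissue] = tset
        tissue_sets.append(tset)
    out["cross-tissue"] = intersect_sets(tissue_sets, scope="cross-tissue")
    return out
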