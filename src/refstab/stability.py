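"""Stability ranking of candidate reference genes from qPCR Cq data.

Four established stability measures are computed on one Cq panel:

* geNorm: a gene's M-value is the mean standard deviation of its pairwise
  log2 expression ratios with every other candidate; stepwise exclusion of
  the least stable gene yields a ranking, and the pairwise variation curve
  V(n/n+1) between successive normalization factors recommends how many
  reference genes to use (0.15 cutoff).
* NormFinder: a model-based decomposition of each gene's variation into
  intragroup variance and (shrunken) intergroup deviation; lower stability
  value = more stable.  Also reports the best single gene and best pair.
* BestKeeper: per-gene Cq dispersion (SD of cycles), CV% of Cq, and Pearson
  correlation with the BestKeeper index (per-sample geometric mean Cq).
* Comparative delta-Ct: mean over partner genes of the SD of the pairwise
  Cq difference.

The four per-method rankings are aggregated into a comprehensive ranking by
the geometric mean of ranks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CqPanel",
    "RelativeQuantities",
    "GenormResult",
    "NormFinderResult",
    "BestKeeperResult",
    "DeltaCtResult",
    "ComprehensiveRanking",
    "to_relative_quantities",
    "genorm_rank",
    "genorm_v_curve",
    "normfinder_stability",
    "bestkeeper_stats",
    "delta_ct_stability",
    "comprehensive_rank",
]


@dataclass
class CqPanel:
    """Candidate-gene Cq matrix with per-sample groups and efficiencies.

    Parameters
    ----------
    cq : pandas.DataFrame
        Quantification cycles, index = gene ids, columns = sample ids.
        Values must lie in (0, 50) and the matrix must be complete.
    groups : pandas.Series
        Per-sample group label (e.g. tissue), indexed by sample id.
    efficiency : pandas.Series or float
        Per-gene amplification factor in (1, 2]; 2.0 means perfect doubling
        per cycle ("100% efficiency").
    """

    cq: pd.DataFrame
    groups: pd.Series
    efficiency: pd.Series | float = 2.0

    def __post_init__(self) -> None:
        if isinstance(self.efficiency, (int, float)):
            self.efficiency = pd.Series(float(self.efficiency), index=self.cq.index)
        self.efficiency = self.efficiency.reindex(self.cq.index)
        if self.cq.index.duplicated().any() or self.cq.columns.duplicated().any():
            raise ValueError("gene and sample ids must be unique")
        # single-gene panels are legal containers (normalization targets);
        # each stability method enforces its own gene minimum
        if self.cq.shape[0] < 1:
            raise ValueError("a Cq panel needs >= 1 gene")
        if self.cq.shape[1] < 3:
            raise ValueError("a Cq panel needs >= 3 samples")
        vals = self.cq.to_numpy(dtype=float)
        if np.isnan(vals).any():
            missing = [
                (g, s)
                for g, s in zip(*np.nonzero(np.isnan(vals)))
            ]
            raise ValueError(f"missing Cq for {len(missing)} gene x sample cells")
        if (vals <= 0).any() or (vals >= 50).any():
            raise ValueError("implausible Cq: values must lie in (0, 50)")
        missing_groups = set(self.cq.columns) - set(self.groups.index)
        if missing_groups:
            raise ValueError(f"samples without group labels: {sorted(missing_groups)}")
        self.groups = self.groups.reindex(self.cq.columns)
        eff = self.efficiency.to_numpy(dtype=float)
        if np.isnan(eff).any() or (eff <= 1).any() or (eff > 2).any():
            raise ValueError("bad efficiency: amplification factors must lie in (1, 2]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.cq.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.cq.columns)

    def subset(self, gene_ids) -> "CqPanel":
        return CqPanel(self.cq.loc[list(gene_ids)], self.groups, self.efficiency.loc[list(gene_ids)])


@dataclass
class RelativeQuantities:
    """Per-gene relative quantities q = E^(minCq - Cq); max per gene is 1."""

    q: pd.DataFrame
    groups: pd.Series


@dataclass
class GenormResult:
    m_value: pd.Series            # final M per gene (at its last evaluation)
    exclusion_order: list[str]    # first entry = least stable (first removed)
    ranking: list[str]            # most to least stable; first two tied
    v_curve: list[float] = field(default_factory=list)
    recommended_n: int | None = None
    cutoff_satisfied: bool = True


@dataclass
class NormFinderResult:
    stability: pd.Series                  # per gene; lower = more stable
    intragroup_var: pd.DataFrame | None   # gene x group
    intergroup_dev: pd.DataFrame | None   # gene x group
    shrunken_dev: pd.DataFrame | None     # gene x group
    gamma2: float
    best_gene: str
    best_pair: tuple[str, str] | None
    best_pair_stability: float | None
    grouped: bool


@dataclass
class BestKeeperResult:
    sd_cq: pd.Series
    cv_pct: pd.Series
    r_index: pd.Series    # NaN where the gene's Cq has zero variance
    index: pd.Series      # per-sample geometric mean Cq


@dataclass
class DeltaCtResult:
    mean_pair_sd: pd.Series


@dataclass
class ComprehensiveRanking:
    method_ranks: pd.DataFrame    # genes x {genorm, normfinder, bestkeeper, delta_ct}
    geomean_rank: pd.Series
    final_order: list[str]


def to_relative_quantities(panel: CqPanel) -> RelativeQuantities:
    """Transform Cq to relative quantities q = E^(minCq - Cq), per gene."""
    cq = panel.cq.to_numpy(dtype=float)
    eff = panel.efficiency.to_numpy(dtype=float)[:, None]
    q = eff ** (cq.min(axis=1, keepdims=True) - cq)
    return RelativeQuantities(
        q=pd.DataFrame(q, index=panel.cq.index, columns=panel.cq.columns),
        groups=panel.groups,
    )


def _genorm_m(logq: np.ndarray) -> np.ndarray:
    """M per gene: mean over partners of SD(log2 ratio) across samples."""
    m_genes = logq.shape[0]
    v = np.zeros((m_genes, m_genes))
    for j in range(m_genes):
        for k in range(m_genes):
            if j != k:
                v[j, k] = np.std(logq[j] - logq[k], ddof=1)
    return v.sum(axis=1) / (m_genes - 1)


def genorm_rank(q: RelativeQuantities) -> GenormResult:
    """geNorm M-values with stepwise exclusion down to a tied final pair."""
    qmat = q.q.to_numpy(dtype=float)
    if (qmat <= 0).any():
        raise ValueError("invalid quantity: all relative quantities must be positive")
    genes = list(q.q.index)
    if len(genes) < 3:
        raise ValueError("genorm needs >= 3 genes")
    if qmat.shape[1] < 2:
        raise ValueError("genorm needs >= 2 samples")
    logq = np.log2(qmat)
    active = list(range(len(genes)))
    final_m = {}
    exclusion: list[str] = []
    while len(active) > 2:
        m = _genorm_m(logq[active])
        for idx, mi in zip(active, m):
            final_m[genes[idx]] = float(mi)
        worst = float(np.max(m))
        # ties: remove the lexicographically first gene among the maxima
        tied = [active[i] for i in range(len(active)) if m[i] == worst]
        drop = min(tied, key=lambda i: genes[i])
        exclusion.append(genes[drop])
        active.remove(drop)
    m = _genorm_m(logq[active])
    for idx, mi in zip(active, m):
        final_m[genes[idx]] = float(mi)
    last_two = sorted((genes[i] for i in active))
    ranking = last_two + list(reversed(exclusion))
    m_series = pd.Series({g: final_m[g] for g in genes}, name="m_value").loc[genes]
    return GenormResult(m_value=m_series, exclusion_order=exclusion, ranking=ranking)


def genorm_v_curve(
    q: RelativeQuantities, ranking: list[str], cutoff: float = 0.15
) -> tuple[list[float], int, bool]:
    """Pairwise variation V(n/n+1) along a stability ranking.

    NF_n per sample is the geometric mean of the n most stable genes'
    quantities; V(n/n+1) is the SD over samples of log2(NF_n / NF_{n+1}).
    Returns (v_curve, recommended_n, cutoff_satisfied); ``recommended_n`` is
    the smallest n with V < cutoff, or the number of genes when no n
    satisfies the cutoff (flagged False).
    """
    if len(ranking) < 3:
        raise ValueError("curve undefined: the ranking must cover >= 3 genes")
    logq = np.log2(q.q.loc[list(ranking)].to_numpy(dtype=float))
    m = len(ranking)
    v_curve = []
    for n in range(2, m):
        nf_n = logq[:n].mean(axis=0)       # log2 geometric mean
        nf_n1 = logq[: n + 1].mean(axis=0)
        v_curve.append(float(np.std(nf_n - nf_n1, ddof=1)))
    for n, v in zip(range(2, m), v_curve):
        if v < cutoff:
            return v_curve, n, True
    return v_curve, m, False


def normfinder_stability(panel: CqPanel, log_base: float = 2.0) -> NormFinderResult:
    """Model-based stability values (intra/intergroup variance decomposition).

    Expression is analysed as y = log relative quantity.  Each sample is
    centered across genes (removing sample loading), within-group variances
    are bias-corrected for the centering step (factor k/(k-2), k = gene
    count), intergroup deviations are shrunken toward zero by an
    empirical-Bayes factor built from the moment estimate of the variance of
    group differences, and the stability value combines the absolute
    shrunken deviation with the posterior SD.  Requires >= 3 genes; grouped
    mode requires >= 2 groups each with >= 2 samples, otherwise the
    ungrouped variant (stability = sqrt of corrected variance) is used.
    """
    genes = panel.gene_ids
    k = len(genes)
    if k < 3:
        raise ValueError("too few genes: NormFinder needs >= 3 genes")
    q = to_relative_quantities(panel)
    y = np.log(q.q.to_numpy(dtype=float)) / np.log(log_base)
    # center each sample across genes
    z = y - y.mean(axis=0, keepdims=True)
    group_labels = panel.groups.to_numpy()
    group_ids = list(pd.unique(group_labels))
    grouped = len(group_ids) >= 2
    if grouped:
        for g in group_ids:
            if (group_labels == g).sum() < 2:
                raise ValueError(f"degenerate group: group {g!r} has < 2 samples")
    else:
        group_ids = [group_ids[0]]

    n_g = {g: int((group_labels == g).sum()) for g in group_ids}
    G = len(group_ids)

    # within-group sample variances, then bias-correct for the centering
    s2 = np.zeros((k, G))
    zbar = np.zeros((k, G))
    for j, g in enumerate(group_ids):
        cols = group_labels == g
        s2[:, j] = z[:, cols].var(axis=1, ddof=1)
        zbar[:, j] = z[:, cols].mean(axis=1)
    sigma2 = np.maximum(0.0, (s2 - s2.sum(axis=0, keepdims=True) / (k * (k - 1))) * k / (k - 2))

    if not grouped:
        stability = pd.Series(np.sqrt(sigma2[:, 0]), index=genes, name="stability")
        best = stability.idxmin()
        return NormFinderResult(
            stability=stability,
            intragroup_var=pd.DataFrame(sigma2, index=genes, columns=group_ids),
            intergroup_dev=None,
            shrunken_dev=None,
            gamma2=0.0,
            best_gene=str(best),
            best_pair=None,
            best_pair_stability=None,
            grouped=False,
        )

    d = zbar - zbar.mean(axis=1, keepdims=True)
    ng_vec = np.array([n_g[g] for g in group_ids], dtype=float)
    var_term = sigma2 / ng_vec[None, :]
    gamma2 = max(
        0.0,
        float((d**2).sum() / (k * (G - 1)) - var_term.sum() / (k * G)),
    )
    denom = gamma2 + var_term
    with np.errstate(invalid="ignore", divide="ignore"):
        shrink = np.where(denom > 0, gamma2 / denom, 0.0)
        post_var = np.where(denom > 0, gamma2 * var_term / denom, 0.0)
    d_tilde = d * shrink
    stability_vals = (np.abs(d_tilde) + np.sqrt(post_var)).mean(axis=1)
    stability = pd.Series(stability_vals, index=genes, name="stability")

    best = str(stability.idxmin())
    best_pair = None
    best_pair_val = np.inf
    for a, b in itertools.combinations(range(k), 2):
        pair_val = float(
            np.mean(
                np.abs((d_tilde[a] + d_tilde[b]) / 2.0)
                + np.sqrt((post_var[a] + post_var[b]) / 4.0)
            )
        )
        if pair_val < best_pair_val:
            best_pair_val = pair_val
            best_pair = (genes[a], genes[b])

    return NormFinderResult(
        stability=stability,
        intragroup_var=pd.DataFrame(sigma2, index=genes, columns=group_ids),
        intergroup_dev=pd.DataFrame(d, index=genes, columns=group_ids),
        shrunken_dev=pd.DataFrame(d_tilde, index=genes, columns=group_ids),
        gamma2=gamma2,
        best_gene=best,
        best_pair=best_pair,
        best_pair_stability=best_pair_val,
        grouped=True,
    )


def bestkeeper_stats(panel: CqPanel, dispersion: str = "sd") -> BestKeeperResult:
    """BestKeeper descriptive stats on raw Cq.

    ``dispersion`` selects the per-gene spread measure: ``"sd"`` (sample SD,
    n-1; the default) or ``"mad"`` (mean absolute deviation around the mean,
    the historical tool's convention).
    """
    if dispersion not in ("sd", "mad"):
        raise ValueError("dispersion must be 'sd' or 'mad'")
    cq = panel.cq.to_numpy(dtype=float)
    genes = panel.gene_ids
    if len(genes) < 2:
        raise ValueError("BestKeeper needs >= 2 genes")
    means = cq.mean(axis=1)
    if dispersion == "sd":
        disp = cq.std(axis=1, ddof=1)
    else:
        disp = np.abs(cq - means[:, None]).mean(axis=1)
    cv_pct = 100.0 * disp / means
    index = np.exp(np.log(cq).mean(axis=0))
    r = np.full(len(genes), np.nan)
    if np.std(index) > 0:
        for i in range(len(genes)):
            if np.std(cq[i]) > 0:
                r[i] = sps.pearsonr(cq[i], index)[0]
    return BestKeeperResult(
        sd_cq=pd.Series(disp, index=genes, name="sd_cq"),
        cv_pct=pd.Series(cv_pct, index=genes, name="cv_pct"),
        r_index=pd.Series(r, index=genes, name="r_index"),
        index=pd.Series(index, index=panel.cq.columns, name="bestkeeper_index"),
    )


def delta_ct_stability(panel: CqPanel) -> DeltaCtResult:
    """Comparative delta-Ct: mean over partners of SD(Cq_j - Cq_k)."""
    cq = panel.cq.to_numpy(dtype=float)
    m = cq.shape[0]
    if m < 3:
        raise ValueError("delta-Ct needs >= 3 genes")
    pair_sd = np.zeros((m, m))
    for j in range(m):
        for kk in range(m):
            if j != kk:
                pair_sd[j, kk] = np.std(cq[j] - cq[kk], ddof=1)
    mean_sd = pair_sd.sum(axis=1) / (m - 1)
    return DeltaCtResult(mean_pair_sd=pd.Series(mean_sd, index=panel.gene_ids, name="mean_pair_sd"))


def _rank_with_ties(values: pd.Series) -> pd.Series:
    """Ascending 1..m ranks; ties get the mean of the tied positions."""
    return pd.Series(sps.rankdata(values.to_numpy(), method="average"), index=values.index)


def comprehensive_rank(
    genorm: GenormResult,
    normfinder: NormFinderResult,
    bestkeeper: BestKeeperResult,
    deltact: DeltaCtResult,
) -> ComprehensiveRanking:
    """Aggregate the four method rankings by the geometric mean of ranks.

    Each method contributes ranks 1..m (ties = mean of tied positions; the
    geNorm final pair is tied at 1.5).  Genes are ordered by ascending
    geometric mean rank, residual ties broken lexicographically by gene id.
    """
    genes = sorted(normfinder.stability.index)
    sets = [
        set(genorm.ranking),
        set(normfinder.stability.index),
        set(bestkeeper.sd_cq.index),
        set(deltact.mean_pair_sd.index),
    ]
    if any(s != set(genes) for s in sets):
        raise ValueError("inconsistent inputs: the four results cover different gene sets")

    # geNorm ranks from its exclusion ordering: final pair tied at 1.5
    genorm_ranks = pd.Series(index=genes, dtype=float)
    for pos, g in enumerate(genorm.ranking, start=1):
        genorm_ranks[g] = float(pos)
    genorm_ranks[genorm.ranking[0]] = 1.5
    genorm_ranks[genorm.ranking[1]] = 1.5

    ranks = pd.DataFrame(
        {
            "genorm": genorm_ranks,
            "normfinder": _rank_with_ties(normfinder.stability),
            "bestkeeper": _rank_with_ties(bestkeeper.sd_cq),
            "delta_ct": _rank_with_ties(deltact.mean_pair_sd),
        }
    ).loc[genes]
    geomean = np.exp(np.log(ranks.to_numpy()).mean(axis=1))
    geomean_rank = pd.Series(geomean, index=genes, name="geomean_rank")
    final_order = sorted(genes, key=lambda g: (geomean_rank[g], g))
    return ComprehensiveRanking(
        method_ranks=ranks, geomean_rank=geomean_rank, final_order=final_order
    )


def rank_panel(panel: CqPanel, cutoff: float = 0.15) -> dict:
    """Run all four methods plus aggregation on one panel.

    Convenience wrapper returning a dict with keys ``genorm``,
    ``normfinder``, ``bestkeeper``, ``delta_ct``, ``comprehensive``; the
    geNorm result carries the V-curve and recommended gene count.
    """
    q = to_relative_quantities(panel)
    gn = genorm_rank(q)
    v_curve, rec_n, ok = genorm_v_curve(q, gn.ranking, cutoff=cutoff)
    gn.v_curve, gn.recommended_n, gn.cutoff_satisfied = v_curve, rec_n, ok
    nf = normfinder_stability(panel)
    bk = bestkeeper_stats(panel)
    dc = delta_ct_stability(panel)
    comp = comprehensive_rank(gn, nf, bk, dc)
    return {
        "genorm": gn,
        "normfinder": nf,
        "bestkeeper": bk,
        "delta_ct": dc,
        "comprehensive": comp,
    }
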