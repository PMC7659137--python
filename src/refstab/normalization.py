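"""Multi-reference ddCq normalization and group comparisons.

Target-gene Cq values are normalized against the geometric mean quantity of
a reference-gene set (equivalently, against the arithmetic mean reference Cq
when all assays amplify with efficiency 2), calibrated so that a chosen
calibrator group has geometric mean relative expression 1.  Groups are
summarized as geometric mean x/ geometric SD, and compared with an unpaired
two-tailed t-test (two groups) or one-way ANOVA with a Tukey-Kramer
post-test (three or more), both on log2 values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .stability import CqPanel

__all__ = [
    "NormalizedExpression",
    "GroupSummary",
    "GroupComparison",
    "normalize_ddcq",
    "summarize_group_geometric",
    "compare_groups",
]


@dataclass
class NormalizedExpression:
    """Per-sample relative expression of one target gene (positive, unitless).

    Values are calibrated so the calibrator group's geometric mean is 1.
    """

    target: str
    values: pd.Series          # indexed by sample id
    groups: pd.Series
    reference_genes: tuple[str, ...]
    calibrator_group: str


@dataclass(frozen=True)
class GroupSummary:
    group: str
    n: int
    xg: float     # geometric mean
    gsd: float    # geometric SD, multiplicative factor >= 1
    single_sample: bool = False


@dataclass
class GroupComparison:
    test: str                        # "t_test_two_tailed_unpaired" | "anova_tukey"
    statistic: float
    p_value: float
    pairwise: pd.DataFrame | None    # Tukey table (group1, group2, p_adj, reject)
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)


def normalize_ddcq(
    targets: CqPanel,
    references: CqPanel,
    calibrator_group: str,
) -> dict[str, NormalizedExpression]:
    """ddCq relative expression of each target gene against a reference set.

    Per sample the target quantity is divided by the geometric mean of the
    reference quantities; the ratio is then calibrated so the calibrator
    group's geometric mean equals 1.  With all efficiencies equal to 2 this
    reduces to dCq = Cq_target - mean(reference Cq) and relative expression
    2^-(dCq - mean dCq over calibrator samples); gene-specific efficiencies
    route through explicit quantities, and both paths agree.
    """
    if references.cq.shape[0] == 0:
        raise ValueError("no references")
    if list(targets.cq.columns) != list(references.cq.columns):
        raise ValueError("sample mismatch: targets and references must share samples")
    groups = targets.groups
    cal_mask = (groups == calibrator_group).to_numpy()
    if not cal_mask.any():
        raise ValueError(f"calibrator group {calibrator_group!r} has no samples")

    # log2 quantities per gene; per-gene min-Cq anchoring cancels in calibration
    ref_logq = (
        np.log2(references.efficiency.to_numpy(dtype=float))[:, None]
        * (-references.cq.to_numpy(dtype=float))
    )
    ref_norm = ref_logq.mean(axis=0)     # log2 geometric-mean normalization factor
    out: dict[str, NormalizedExpression] = {}
    for gene in targets.gene_ids:
        eff = float(targets.efficiency.loc[gene])
        t_logq = np.log2(eff) * (-targets.cq.loc[gene].to_numpy(dtype=float))
        log_ratio = t_logq - ref_norm
        log_rel = log_ratio - log_ratio[cal_mask].mean()
        out[gene] = NormalizedExpression(
            target=gene,
            values=pd.Series(2.0 ** log_rel, index=targets.cq.columns, name=gene),
            groups=groups,
            reference_genes=tuple(references.gene_ids),
            calibrator_group=calibrator_group,
        )
    return out


def summarize_group_geometric(values: pd.Series, groups: pd.Series) -> list[GroupSummary]:
    """Geometric mean and geometric SD per group (log2 scale, n-1 SD)."""
    vals = values.to_numpy(dtype=float)
    if (vals <= 0).any():
        raise ValueError("geometric summary undefined for nonpositive values")
    out = []
    for g in pd.unique(groups.reindex(values.index)):
        gv = np.log2(vals[(groups.reindex(values.index) == g).to_numpy()])
        n = gv.size
        xg = float(2.0 ** gv.mean())
        if n == 1:
            out.append(GroupSummary(group=str(g), n=1, xg=xg, gsd=1.0, single_sample=True))
        else:
            out.append(
                GroupSummary(group=str(g), n=int(n), xg=xg, gsd=float(2.0 ** gv.std(ddof=1)))
            )
    return out


def compare_groups(
    values: pd.Series,
    groups: pd.Series,
    design: str | None = None,
    alpha: float = 0.05,
    log_scale: bool = True,
) -> GroupComparison:
    """Compare relative expression between groups.

    Two groups: unpaired two-tailed Student's t-test (pooled variance).
    Three or more: one-way ANOVA followed by a Tukey-Kramer post-test
    (handles unequal group sizes).  Tests run on log2 values by default,
    consistent with geometric-mean reporting; ``log_scale=False`` tests the
    linear fold changes instead.
    """
    groups = groups.reindex(values.index)
    labels = pd.unique(groups)
    per_group = [values[(groups == g).to_numpy()].to_numpy(dtype=float) for g in labels]
    if log_scale:
        per_group = [np.log2(v) for v in per_group]
    if design is None:
        design = "two_group" if len(labels) == 2 else "multi_group"
    if any(len(v) < 2 for v in per_group):
        raise ValueError("insufficient replication: every group needs n >= 2")
    if design == "two_group":
        if len(labels) != 2:
            raise ValueError("two_group design requires exactly 2 groups")
        t, p = sps.ttest_ind(per_group[0], per_group[1], equal_var=True)
        return GroupComparison(
            test="t_test_two_tailed_unpaired", statistic=float(t), p_value=float(p),
            pairwise=None, alpha=alpha,
        )
    if len(labels) < 3:
        raise ValueError("multi_group design requires >= 3 groups")
    f, p = sps.f_oneway(*per_group)
    flat = np.concatenate(per_group)
    glab = np.concatenate([[str(g)] * len(v) for g, v in zip(labels, per_group)])
    tk = pairwise_tukeyhsd(flat, glab, alpha=alpha)
    table = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    return GroupComparison(
        test="anova_tukey", statistic=float(f), p_value=float(p), pairwise=table, alpha=alpha
    )
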