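"""Readers and writers for expression matrices, Cq tables and reports.

Canonical formats:

* Expression matrix: TSV/CSV, first column gene id, header row of sample
  ids, UTF-8, "." decimal.
* Manifest: YAML/JSON listing per dataset: path, tissue, platform and
  per-sample labels (condition, health, treatment).
* Cq table: long-format TSV with columns sample, group, gene, cq and an
  optional efficiency column; duplicate (sample, gene) rows are technical
  replicates and are averaged with a logged count.
* Reports: TSV / JSON with stable ordering and floats at 6 significant
  digits, so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .screening import CandidateSet, ExpressionDataset, GeneScreenStats
from .stability import CqPanel

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1.0"

__all__ = [
    "read_expression_matrix",
    "read_manifest",
    "read_cq_table",
    "write_expression_matrix",
    "write_cq_table",
    "write_screen_report",
    "write_stability_report",
    "fmt6",
]


def fmt6(x: float) -> str:
    """Format a float to 6 significant digits (deterministic report output)."""
    if isinstance(x, float) and np.isnan(x):
        return "NA"
    return f"{x:.6g}"


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def read_expression_matrix(path: str | Path, manifest_entry: dict) -> ExpressionDataset:
    """Read one expression matrix and attach its manifest labels.

    ``manifest_entry`` must provide ``dataset_id``, ``tissue``, ``platform``
    and a ``samples`` mapping of sample id -> {condition, health, treatment}.
    Non-numeric cells are a hard parse error naming the cell; samples in the
    matrix that the manifest does not label are a label mismatch.
    """
    raw = _read_table(path)
    mat = raw.apply(pd.to_numeric, errors="coerce")
    if mat.isna().to_numpy().any():
        r, c = np.argwhere(mat.isna().to_numpy())[0]
        raise ValueError(
            f"parse error in {path}: non-numeric value at gene {mat.index[r]!r}, "
            f"sample {mat.columns[c]!r}"
        )
    samples = manifest_entry.get("samples", {})
    unlabeled = set(mat.columns) - set(samples)
    if unlabeled:
        raise ValueError(f"label mismatch: samples {sorted(unlabeled)} absent from manifest")
    labels = pd.DataFrame.from_dict(samples, orient="index").reindex(mat.columns)
    if mat.index.duplicated().any():
        n = int(mat.index.duplicated().sum())
        logger.warning("%s: %d duplicate gene ids collapsed to max-mean row", path, n)
        mat = (
            mat.assign(_mean=mat.mean(axis=1))
            .sort_values("_mean", ascending=False)
            .groupby(level=0, sort=False)
            .head(1)
            .drop(columns="_mean")
            .sort_index()
        )
    return ExpressionDataset(
        dataset_id=manifest_entry["dataset_id"],
        tissue=manifest_entry["tissue"],
        platform=manifest_entry["platform"],
        abundances=mat,
        sample_labels=labels,
    )


def read_manifest(path: str | Path) -> list[ExpressionDataset]:
    """Read a YAML/JSON manifest and all expression matrices it lists."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
    datasets = []
    for entry in doc["datasets"]:
        mpath = Path(entry["path"])
        if not mpath.is_absolute():
            mpath = path.parent / mpath
        datasets.append(read_expression_matrix(mpath, entry))
    return datasets


def read_cq_table(path: str | Path, missing_policy: str = "strict") -> CqPanel:
    """Read a long-format Cq TSV (sample, group, gene, cq[, efficiency]).

    Duplicate (sample, gene) rows are technical replicates, averaged with a
    logged count.  An incomplete gene x sample grid is an error under
    ``strict``; ``drop-sample`` removes incomplete samples instead.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "group", "gene", "cq"}
    if not required <= set(df.columns):
        raise ValueError(f"Cq table must have columns {sorted(required)}")
    df["gene"] = df["gene"].astype(str).str.upper()
    n_dup = int(df.duplicated(subset=["sample", "gene"]).sum())
    if n_dup:
        logger.info("%s: %d technical replicate rows averaged", path, n_dup)
    cq = df.pivot_table(index="gene", columns="sample", values="cq", aggfunc="mean")
    groups = df.drop_duplicates("sample").set_index("sample")["group"]
    cq = cq[groups.index.intersection(cq.columns)]
    if cq.isna().to_numpy().any():
        if missing_policy == "drop-sample":
            keep = cq.columns[~cq.isna().any(axis=0)]
            logger.warning("%s: dropped %d incomplete samples", path, cq.shape[1] - len(keep))
            cq = cq[keep]
        else:
            cells = [
                f"({cq.index[r]}, {cq.columns[c]})"
                for r, c in np.argwhere(cq.isna().to_numpy())
            ]
            raise ValueError(f"missing Cq for cells: {', '.join(cells)}")
    if "efficiency" in df.columns:
        eff = df.groupby("gene")["efficiency"].mean().reindex(cq.index).fillna(2.0)
    else:
        eff = pd.Series(2.0, index=cq.index)
    return CqPanel(cq=cq, groups=groups.reindex(cq.columns), efficiency=eff)


def write_expression_matrix(ds: ExpressionDataset, path: str | Path) -> None:
    out = ds.abundances.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


def write_cq_table(panel: CqPanel, path: str | Path) -> None:
    rows = []
    for gene in panel.gene_ids:
        for sample in panel.sample_ids:
            rows.append(
                {
                    "sample": sample,
                    "group": panel.groups[sample],
                    "gene": gene,
                    "cq": fmt6(float(panel.cq.loc[gene, sample])),
                    "efficiency": fmt6(float(panel.efficiency.loc[gene])),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_screen_report(
    results: dict[str, CandidateSet],
    stats_by_dataset: dict[str, list[GeneScreenStats]],
    out_dir: str | Path,
) -> None:
    """Per-scope candidate TSVs plus a JSON summary of set sizes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = {"schema_version": SCHEMA_VERSION, "set_sizes": {}}
    for scope in sorted(results):
        cand = results[scope]
        summary["set_sizes"][scope] = len(cand)
        rows = []
        for gene in sorted(cand.gene_ids):
            row = {"gene_id": gene}
            for ds_id in cand.provenance:
                for st in stats_by_dataset.get(ds_id, []):
                    if st.gene_id.upper() == gene:
                        row[f"{ds_id}_mean"] = fmt6(st.mean)
                        row[f"{ds_id}_sd"] = fmt6(st.sd)
                        row[f"{ds_id}_cv"] = fmt6(st.cv)
            rows.append(row)
        pd.DataFrame(rows).to_csv(out_dir / f"candidates_{scope.replace('/', '_')}.tsv",
                                  sep="\t", index=False)
    with open(out_dir / "screen_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_stability_report(results: dict, out_dir: str | Path) -> None:
    """Stability TSV (gene x method value/rank) + JSON (V-curve, best pair)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gn, nf, bk, dc = results["genorm"], results["normfinder"], results["bestkeeper"], results["delta_ct"]
    comp = results["comprehensive"]
    rows = []
    for gene in comp.final_order:
        rows.append(
            {
                "gene_id": gene,
                "genorm_m": fmt6(float(gn.m_value[gene])),
                "genorm_rank": fmt6(float(comp.method_ranks.loc[gene, "genorm"])),
                "normfinder_stability": fmt6(float(nf.stability[gene])),
                "normfinder_rank": fmt6(float(comp.method_ranks.loc[gene, "normfinder"])),
                "bestkeeper_sd": fmt6(float(bk.sd_cq[gene])),
                "bestkeeper_cv_pct": fmt6(float(bk.cv_pct[gene])),
                "bestkeeper_r": fmt6(float(bk.r_index[gene])),
                "bestkeeper_rank": fmt6(float(comp.method_ranks.loc[gene, "bestkeeper"])),
                "delta_ct_mean_sd": fmt6(float(dc.mean_pair_sd[gene])),
                "delta_ct_rank": fmt6(float(comp.method_ranks.loc[gene, "delta_ct"])),
                "geomean_rank": fmt6(float(comp.geomean_rank[gene])),
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "stability_report.tsv", sep="\t", index=False)
    doc = {
        "schema_version": SCHEMA_VERSION,
        "final_order": comp.final_order,
        "v_curve": [float(fmt6(v)) for v in gn.v_curve],
        "recommended_n": gn.recommended_n,
        "cutoff_satisfied": gn.cutoff_satisfied,
        "normfinder_best_gene": nf.best_gene,
        "normfinder_best_pair": list(nf.best_pair) if nf.best_pair else None,
    }
    with open(out_dir / "stability_report.json", "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_stability_report(out_dir: str | Path) -> dict:
    """Round-trip reader for the JSON stability report."""
    with open(Path(out_dir) / "stability_report.json", encoding="utf-8") as fh:
        return json.load(fh)
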