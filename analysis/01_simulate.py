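#!/usr/bin/env python
"""Generate the simulated multistudy inputs for the downstream analyses.

Writes, under scratch/sim/:
  * seven expression matrices (two placental, two luteal, three uterine
    studies; two uterine studies mix healthy and diseased samples) plus a
    manifest.yaml, shaped like a multistudy screen across three
    reproductive tissues;
  * a 55-sample validation Cq panel (23 CL, 19 uterus, 13 placenta) of
    seven candidate genes — four planted stable, three "legacy" references
    with tissue-dependent shifts and higher noise.

The planted ground truth (which genes are stable, the true per-gene
stability in cycles) goes to results/simulation_ground_truth.json.
"""

import argparse
import json
from pathlib import Path

from refstab import io as rio
from refstab.simulate import (
    simulate_cq_panel,
    simulate_expression_dataset,
    study_manifest_spec,
    validation_panel_spec,
)
import yaml

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int) -> None:
    sim_dir = ROOT / "scratch" / "sim"
    res_dir = ROOT / "results"
    sim_dir.mkdir(parents=True, exist_ok=True)
    res_dir.mkdir(exist_ok=True)

    entries, truth = [], {}
    for spec in study_manifest_spec(seed):
        ds, gt = simulate_expression_dataset(spec)
        rio.write_expression_matrix(ds, sim_dir / f"{ds.dataset_id}.tsv")
        entries.append({
            "dataset_id": ds.dataset_id,
            "path": f"{ds.dataset_id}.tsv",
            "tissue": ds.tissue,
            "platform": ds.platform,
            "samples": {
                s: {"condition": str(ds.sample_labels.loc[s, "condition"]),
                    "health": str(ds.sample_labels.loc[s, "health"])}
                for s in ds.sample_ids
            },
        })
        truth[ds.dataset_id] = {
            "n_samples": len(ds.sample_ids),
            "n_diseased": int((ds.sample_labels["health"] == "diseased").sum()),
            "planted_stable": sorted(gt.stable_genes),
        }
        print(f"wrote {ds.dataset_id}: {ds.abundances.shape[0]} genes x "
              f"{ds.abundances.shape[1]} samples ({ds.tissue}, {ds.platform})")
    with open(sim_dir / "manifest.yaml", "w") as fh:
        yaml.safe_dump({"datasets": entries}, fh, sort_keys=False)

    panel, gt = simulate_cq_panel(validation_panel_spec(seed))
    rio.write_cq_table(panel, sim_dir / "cq_validation.tsv")
    truth["cq_validation"] = {
        "true_stability_cycles": {g: round(float(v), 6)
                                  for g, v in gt.true_stability.items()},
        "planted_stable": sorted(gt.stable_genes),
    }
    print(f"wrote cq_validation: {panel.cq.shape[0]} genes x {panel.cq.shape[1]} samples")

    with open(res_dir / "simulation_ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    print(f"ground truth -> {res_dir / 'simulation_ground_truth.json'}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
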