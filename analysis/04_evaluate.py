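#!/usr/bin/env python
"""Evaluate all models against the simulated responses.

Produces the package's summary table: per pair, between-participant
congruity, preserved-order percentage, and for each model the mean distance
to the median response with paired t, p and JZS BF10 against the
human-to-median distances.  Written to results/evaluation.csv and .json.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from shapecorr import congruity, median_responses, ordering_preservation
from shapecorr import io as scio
from shapecorr.metrics import compare_model


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--sim-dir", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--pred-dir", type=Path, default=Path("results/predictions"))
    ap.add_argument("--out", type=Path, default=Path("results/evaluation"))
    args = ap.parse_args()

    rows = []
    results = {}
    for resp_path in sorted(args.sim_dir.glob("*_responses.csv")):
        pair_id = resp_path.name.replace("_responses.csv", "")
        table = scio.load_responses_csv(resp_path, pair_id)
        cong = congruity(table)
        med = median_responses(table)
        preserved, reversals = ordering_preservation(med)
        pair_res = {"congruity": cong.congruity, "preserved_percent": preserved}
        pred_df = pd.read_csv(args.pred_dir / f"{pair_id}_predictions.csv")
        for model_id, sub in pred_df.groupby("model"):
            sub = sub.sort_values("probe_index")
            pred = np.where(sub["valid"].astype(bool), sub["predicted_s"], np.nan)
            cmp_res = compare_model(table, pred)
            pair_res[model_id] = float(np.mean(cmp_res.model_distance))
            rows.append({
                "pair_id": pair_id, "model": model_id,
                "human_distance": float(np.mean(cmp_res.human_distance)),
                "model_distance": float(np.mean(cmp_res.model_distance)),
                "t": cmp_res.t, "df": cmp_res.df, "p": cmp_res.p,
                "BF10": cmp_res.bf10,
            })
        results[pair_id] = pair_res

    df = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out.with_suffix(".csv"), index=False, float_format="%.4g")
    args.out.with_suffix(".json").write_text(json.dumps(results, indent=1) + "\n")

    wide = df.pivot(index="pair_id", columns="model", values="model_distance")
    wide["human"] = df.groupby("pair_id")["human_distance"].first()
    print(wide.round(2).to_string())
    sem_best = (wide["semantic"] < wide[["uniform", "curvature"]].min(axis=1))
    print(f"\nsemantic model best on {sem_best.sum()}/{len(wide)} pairs "
          f"(distances in % of perimeter)")


if __name__ == "__main__":
    main()
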