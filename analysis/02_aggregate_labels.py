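#!/usr/bin/env python
"""Aggregate simulated labeler votes into part segmentations.

Reads the vote tables written by 01_simulate.py, takes per-point modal
labels, merges them into maximal labeled arcs, and compares the recovered
segmentation with the generating ground truth (they should agree everywhere
except within the boundary-jitter band).
"""

import argparse
from pathlib import Path

import numpy as np

from shapecorr import arc_distance, majority_labels, segment_parts
from shapecorr import io as scio


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--in-dir", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/labels"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    for votes_path in sorted(args.in_dir.glob("*_votes.csv")):
        pair_id = votes_path.name.replace("_votes.csv", "")
        votes = scio.load_votes_csv(votes_path)
        labels = majority_labels(votes)
        seg = segment_parts(labels, votes.positions)
        scio.save_segmentation_json(seg, args.out_dir / f"{pair_id}_recovered_seg.json")

        truth = scio.load_segmentation_json(args.in_dir / f"{pair_id}_base_seg.json")
        agree = np.mean([
            seg.label_at(s) == truth.label_at(s) for s in votes.positions
        ])
        bounds = np.array([a for _, a, _ in truth.segments])
        off_boundary = [
            s for s in votes.positions if arc_distance(bounds, s).min() > 0.01
        ]
        agree_off = np.mean([seg.label_at(s) == truth.label_at(s) for s in off_boundary])
        print(f"{pair_id}: {len(seg.segments)} segments recovered, "
              f"label agreement {agree:.1%} (off-boundary {agree_off:.1%})")


if __name__ == "__main__":
    main()
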