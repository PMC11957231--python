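#!/usr/bin/env python
"""Download helpers for the public 2D/3D registration benchmarks.

These datasets are multi-gigabyte and are NOT required for building or
testing this package — the synthetic phantom module covers everything the
test suite and acceptance script need.  This script only records where the
public benchmarks live and fetches them for users who want to rerun the
full-scale SMSR/AUC evaluations on real data with the `fluoropose` CLI
(train a model per subject, `register` each X-ray, `evaluate` the result
directory).

Sources (public project pages of the respective authors):
  DeepFluoro   https://github.com/rg2/DeepFluoroLabeling-IPCAI2020
  Ljubljana    https://lit.fe.uni-lj.si/en/research/resources/3D-2D-GS-CA
  CTPelvic1K   https://github.com/MIRACLE-Center/CTPelvic1K
  NITRC MRA    https://www.nitrc.org/projects/icbmmra
  TotalSegmentator  https://github.com/wasserth/TotalSegmentator

Usage:
  python scripts/fetch_benchmarks.py --dataset deepfluoro --out data/
"""

from __future__ import annotations

import argparse
import subprocess
import sys
from pathlib import Path

DATASETS = {
    "deepfluoro": {
        "kind": "git",
        "url": "https://github.com/rg2/DeepFluoroLabeling-IPCAI2020",
        "note": "Follow the repository README to pull the HDF5 image data "
                "(hosted via the project's release links).",
    },
    "ctpelvic1k": {
        "kind": "git",
        "url": "https://github.com/MIRACLE-Center/CTPelvic1K",
        "note": "CT volumes are linked from the repository README "
                "(external hosting; registration may be required).",
    },
    "totalsegmentator": {
        "kind": "git",
        "url": "https://github.com/wasserth/TotalSegmentator",
        "note": "The public CT dataset is linked from the repository README.",
    },
    "ljubljana": {
        "kind": "manual",
        "url": "https://lit.fe.uni-lj.si/en/research/resources/3D-2D-GS-CA",
        "note": "Distributed by the University of Ljubljana on request; "
                "visit the page and follow the access instructions.",
    },
    "nitrc-mra": {
        "kind": "manual",
        "url": "https://www.nitrc.org/projects/icbmmra",
        "note": "Requires a (free) NITRC account; download from the project "
                "page.",
    },
}


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__,
                                 formatter_class=argparse.RawDescriptionHelpFormatter)
    ap.add_argument("--dataset", choices=sorted(DATASETS) + ["all"], default="all")
    ap.add_argument("--out", type=Path, default=Path("data"))
    args = ap.parse_args()

    names = sorted(DATASETS) if args.dataset == "all" else [args.dataset]
    args.out.mkdir(parents=True, exist_ok=True)
    rc = 0
    for name in names:
        info = DATASETS[name]
        dest = args.out / name
        print(f"== {name}: {info['url']}")
        if info["kind"] == "git":
            if dest.exists():
                print(f"   {dest} already exists, skipping clone")
            else:
                try:
                    subprocess.run(
                        ["git", "clone", "--depth", "1", info["url"], str(dest)],
                        check=True,
                    )
                except subprocess.CalledProcessError as exc:
                    print(f"   clone failed ({exc}); fetch manually from the URL")
                    rc = 1
        else:
            print("   manual download required")
        print(f"   note: {info['note']}")
    return rc


if __name__ == "__main__":
    sys.exit(main())
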