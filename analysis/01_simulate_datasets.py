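"""Generate the canonical synthetic datasets for the downstream analyses.

Writes one of each dataset kind (extracellular CA3 trace with known burst
times, spine stack series, fEPSP session, labeling table, seizure cohort
with the published incidence counts) under scratch/datasets/, and a small
text inventory under results/. All downstream drivers regenerate what they
need in memory, so this step exists to leave an inspectable dataset on
disk, not to feed the other scripts.
"""

import argparse
import json
from pathlib import Path

from spineburst.pipeline import make_fixtures

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    out = ROOT / "scratch" / "datasets"
    checksums = make_fixtures(out, seed=args.seed)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    (results / "dataset_inventory.json").write_text(json.dumps(checksums, indent=1))
    print(f"wrote {len(checksums)} files to {out}")
    print("inventory with SHA-256 checksums -> results/dataset_inventory.json")


if __name__ == "__main__":
    main()
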