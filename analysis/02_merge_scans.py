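#!/usr/bin/env python
"""Merge each array's 10%- and 100%-power scans into one extended-range table.

Fits a robust (LAD) line of high-scan on low-scan background-subtracted
intensity per channel over the unsaturated support, keeps high-scan values
where valid and substitutes calibrated low-scan values where the high scan
clipped.  Writes results/run/merged_scans.tsv plus per-array calibrations.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from chronoclass import io
from chronoclass.scan_merge import fit_and_merge


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--run", type=Path, default=Path("results/run"))
    args = ap.parse_args()
    run = args.run

    samples = io.read_sample_table(run / "samples.tsv")
    merged_all, calibs_all = [], {}
    n_sub = 0
    for sid in samples["sample_id"]:
        low = io.read_scan_table(run / "scans" / f"{sid}_low.tsv")
        high = io.read_scan_table(run / "scans" / f"{sid}_high.tsv")
        merged, calibs = fit_and_merge(low, high)
        n_sub += int((merged["source_scan"] == "low").sum())
        merged_all.append(merged.assign(array_id=sid))
        calibs_all[sid] = {
            ch: {"slope": c.slope, "intercept": c.intercept,
                 "n_support": c.n_support}
            for ch, c in calibs.items()
        }
    table = pd.concat(merged_all, ignore_index=True)
    table.to_csv(run / "merged_scans.tsv", sep="\t", index=False)
    (run / "scan_calibrations.json").write_text(
        json.dumps(calibs_all, indent=2, sort_keys=True) + "\n"
    )

    slopes = [c["green"]["slope"] for c in calibs_all.values()]
    print(f"merged {len(calibs_all)} arrays; green-channel gain "
          f"{min(slopes):.2f}-{max(slopes):.2f} (median "
          f"{sorted(slopes)[len(slopes) // 2]:.2f})")
    print(f"{n_sub} feature-channel rows were saturated at full power and "
          f"took calibrated low-scan values")


if __name__ == "__main__":
    main()
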