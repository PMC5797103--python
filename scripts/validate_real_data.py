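#!/usr/bin/env python
"""Validation against user-supplied real yield data (not part of CI).

Given a CSV of observed annual fresh-fruit-bunch yields per region
(columns: region, year, yield), recompute the loess variation rate, the
±0.7-SD classification threshold and the resulting low/high year lists,
and print them for comparison with published values (for the Malaysian
series 1987–2014 the reference thresholds are ±3.02% for Malaysia,
±3.35% for Peninsular Malaysia and ±3.29% for Sabah/Sarawak).

Usage::

    python scripts/validate_real_data.py --yields-csv mpob_yields.csv \
        [--region Malaysia] [--span 0.32] [--k 0.7]
"""

from __future__ import annotations

import argparse

import pandas as pd

from palmclim.io import read_yields
from palmclim.variability import build_record


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--yields-csv", required=True)
    parser.add_argument("--region", default=None,
                        help="Region to select; default: every region in the file.")
    parser.add_argument("--span", type=float, default=0.32)
    parser.add_argument("--k", type=float, default=0.7)
    args = parser.parse_args()

    frame = pd.read_csv(args.yields_csv)
    regions = [args.region] if args.region else sorted(frame["region"].unique())
    for region in regions:
        yields = read_yields(args.yields_csv, region=region)
        record = build_record(region, yields, span=args.span, k=args.k)
        print(f"== {region} ({yields.index.min()}-{yields.index.max()}) ==")
        print(f"  threshold: ±{record.threshold:.2f}%")
        print(f"  low years:  {', '.join(map(str, record.low_years))}")
        print(f"  high years: {', '.join(map(str, record.high_years))}")


if __name__ == "__main__":
    main()
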