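"""Clean the raw fixes: drop LC Z, apply the 8 m/s swim-speed filter, and
truncate tracks at the first gap over 4 days.

Writes results/fixes_clean.csv and results/filter_report.json, and prints the
share of data each stage removed.
"""

import argparse
import pathlib

from coreud import io
from coreud.preprocess import clean_fixes


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=pathlib.Path, default=pathlib.Path("results"))
    ap.add_argument("--vmax-ms", type=float, default=8.0)
    ap.add_argument("--max-gap-days", type=float, default=4.0)
    args = ap.parse_args()

    fixes = io.read_fixes_csv(args.results / "fixes_raw.csv")
    clean, report = clean_fixes(fixes, vmax_ms=args.vmax_ms,
                                max_gap_h=args.max_gap_days * 24.0)
    io.write_fixes_csv(clean, args.results / "fixes_clean.csv")
    io.write_report_json(report, args.results / "filter_report.json")

    n = report.n_input
    print(f"input fixes:        {n}")
    for label, k in (("LC Z removed", report.n_lcz_removed),
                     ("speed filtered", report.n_speed_removed),
                     ("gap truncated", report.n_gap_truncated)):
        print(f"{label:<18s}  {k}  ({100 * k / n:.1f}%)")
    print(f"kept {report.n_output} fixes across {report.segments_kept} animals")


if __name__ == "__main__":
    main()
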