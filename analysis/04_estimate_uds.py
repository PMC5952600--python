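"""Estimate utilization distributions: per-animal bi-monthly kernel densities
for eligible samples (> 50 pseudolocations, pseudo-to-raw ratio < 3) and the
effort-corrected pooled UD, all on a 1-km grid with likelihood
cross-validation bandwidths.

Writes results/ud/<animal>_<season>.asc(+json) and results/ud/pooled.asc.
"""

import argparse
import pathlib

import numpy as np
import pandas as pd

from coreud import io, ud
from coreud.ctcrw import PseudoTrack
from coreud.range_core import assign_bimonth, eligibility


def load_pseudotracks(path):
    df = pd.read_csv(path, parse_dates=["time"])
    for aid, sub in df.groupby("animal_id"):
        sub = sub.reset_index(drop=True)
        yield PseudoTrack(str(aid), sub, 2.0,
                          int(sub.n_imputations.iloc[0]), int(sub.n_raw.iloc[0]))


def extent_for(pts, landscape, margin):
    return (min(landscape.xmin, pts[:, 0].min()) - margin,
            max(landscape.xmax, pts[:, 0].max()) + margin,
            min(landscape.ymin, pts[:, 1].min()) - margin,
            max(landscape.ymax, pts[:, 1].max()) + margin)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=pathlib.Path, default=pathlib.Path("results"))
    ap.add_argument("--cell-km", type=float, default=1.0)
    args = ap.parse_args()
    out = args.results / "ud"
    out.mkdir(parents=True, exist_ok=True)

    haulouts = io.read_haulouts_geojson(args.results / "haulouts.geojson")
    landscape = io.read_landmask_ascii(args.results / "landmask.asc", haulouts)
    tracks = list(load_pseudotracks(args.results / "pseudotracks.csv"))

    n_eligible = 0
    for pt in tracks:
        for season, sub in assign_bimonth(pt).items():
            ok = eligibility(len(sub.df), sub.n_raw)
            status = "eligible" if ok else "ineligible"
            print(f"{pt.animal_id} {season}: {len(sub.df)} pseudolocations, "
                  f"ratio {len(sub.df) / sub.n_raw:.2f} -> {status}")
            if not ok:
                continue
            pts = sub.df[["x_km", "y_km"]].to_numpy()
            bw = ud.lcv_bandwidth(pts, cell_size=args.cell_km)
            grid = ud.kde_grid(pts, bw.h,
                               extent_for(pts, landscape, 3 * bw.h + 1),
                               args.cell_km)
            io.write_density_grid(grid, out / f"{pt.animal_id}_{season}")
            n_eligible += 1

    per_animal = {pt.animal_id: pt.df[["x_km", "y_km"]].to_numpy()
                  for pt in tracks}
    pooled_pts = np.vstack(list(per_animal.values()))
    bw = ud.lcv_bandwidth(pooled_pts, cell_size=args.cell_km)
    pooled, counts = ud.pooled_effort_corrected_ud(
        per_animal, bw.h, extent_for(pooled_pts, landscape, 3 * bw.h + 1),
        args.cell_km)
    io.write_density_grid(pooled, out / "pooled")
    print(f"wrote {n_eligible} bi-monthly UDs and the pooled effort-corrected "
          f"UD (bandwidth {bw.h:.2f} km, {pooled.n_points} pseudolocations)")


if __name__ == "__main__":
    main()
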