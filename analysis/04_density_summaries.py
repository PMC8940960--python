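#!/usr/bin/env python
"""Kernel-density summaries of the HRV features by gender and state.

For every feature and every (gender, state) cell a Gaussian KDE is
evaluated on a common-format grid and written in long form to
results/densities.csv, plus a Poincare scatter export for one example
subject pair. Prints, per feature, how far apart the male and female
fatigue-state density peaks sit as a quick dimorphism summary.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from hrvfatigue.ecg import artifact_filter
from hrvfatigue.io import read_manifest, read_rr_text
from hrvfatigue.nonlinear import poincare_descriptors
from hrvfatigue.stats import estimate_pdf


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--features", type=Path, default=Path("results/features.csv"))
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    features = pd.read_csv(args.features)
    feature_cols = [c for c in features.columns
                    if c not in ("subject_id", "gender", "state")]

    rows = []
    peaks: dict[tuple[str, str, str], float] = {}
    for (gender, state), sub in features.groupby(["gender", "state"]):
        for feat in feature_cols:
            vals = sub[feat].dropna().to_numpy()
            if vals.size < 5 or np.ptp(vals) == 0:
                continue
            de = estimate_pdf(vals, label=f"{gender}/{state}")
            peaks[(feat, gender, state)] = float(de.grid[np.argmax(de.density)])
            rows.extend({"feature": feat, "gender": gender, "state": state,
                         "x": x, "density": d}
                        for x, d in zip(de.grid, de.density))
    density_path = args.out / "densities.csv"
    pd.DataFrame(rows).to_csv(density_path, index=False)

    print("fatigue-state density peak locations (male vs female):")
    for feat in ("SDSD", "LF/HF", "HF norm", "SampleEn_RR"):
        m = peaks.get((feat, "male", "fatigue"))
        f = peaks.get((feat, "female", "fatigue"))
        if m is not None and f is not None:
            print(f"  {feat}: male {m:.3g}, female {f:.3g}")

    # Poincare scatter for the first subject, both states
    manifest = read_manifest(args.cohort / "manifest.csv")
    first = manifest["subject_id"].iloc[0]
    for state in ("nonfatigue", "fatigue"):
        entry = manifest[(manifest["subject_id"] == first)
                         & (manifest["state"] == state)].iloc[0]
        clean, _ = artifact_filter(read_rr_text(entry["rr_path"]))
        pc = poincare_descriptors(clean)
        out = args.out / f"poincare_{first}_{state}.csv"
        pd.DataFrame(pc.points, columns=["RR_i", "RR_i+1"]).to_csv(out, index=False)
        print(f"{state} Poincare ellipse for {first}: "
              f"SD1 {pc.sd1:.1f} ms, SD2 {pc.sd2:.1f} ms -> {out}")
    print(f"density grids in {density_path}")


if __name__ == "__main__":
    main()
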