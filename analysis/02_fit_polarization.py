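#!/usr/bin/env python
"""Segment stripes and fit the polarization sinusoid per ROI.

Re-renders the step-01 scene (same seed), splits each body-region ROI
into black/white stripes by per-image Otsu thresholding, fits
L = a·sin(2(θ+φ)) + b to each class's mean luminance across the 7
filter angles, and reports the degree of polarization d = a/b, the
phase, the fit correlation and the significance gate (r > 0.71,
df = 6) — then checks the recovered values against the generator's
ground truth. Writes the per-ROI study table under results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from polstripe import RegionOfInterest, SceneConfig, render_series, segment_roi
from polstripe.fitting import roi_polarimetry

ROIS = [
    RegionOfInterest("shoulder", (24, 24, 40, 40)),
    RegionOfInterest("flank", (48, 48, 48, 48)),
    RegionOfInterest("rump", (70, 24, 36, 36)),
]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--noise-sd", type=float, default=3.2)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    cfg = SceneConfig(noise_sd=args.noise_sd, texture_sd=0.05, seed=args.seed)
    series, truth = render_series(cfg)

    rows = []
    for roi in ROIS:
        seg = segment_roi(series, roi)
        if seg.excluded:
            print(f"{roi.label}: EXCLUDED ({seg.reason})")
            continue
        pol = roi_polarimetry(series, seg)
        for klass, fit, d_true in (
            ("black", pol.black, cfg.black_spec.degree),
            ("white", pol.white, cfg.white_spec.degree),
        ):
            rows.append(
                {
                    "zebra_id": "demo",
                    "roi_label": roi.label,
                    "class": klass,
                    "d": fit.degree_d,
                    "d_true": d_true,
                    "phase_deg": fit.phase_deg,
                    "phase_true": -45.0,
                    "fit_r": fit.fit_r,
                    "significant": bool(fit.significant),
                    "contrast": pol.michelson_contrast,
                }
            )
        print(
            f"{roi.label}: d_black={pol.black.degree_d:.3f} (true {cfg.black_spec.degree}), "
            f"d_white={pol.white.degree_d:.3f} (true {cfg.white_spec.degree}), "
            f"phase=({pol.black.phase_deg:.1f}, {pol.white.phase_deg:.1f}) deg, "
            f"contrast={pol.michelson_contrast:.3f}, gated={pol.phase_pairable}"
        )

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    table = pd.DataFrame(rows)
    path = out / "demo_study_table.csv"
    table.to_csv(path, index=False)
    err = (table["d"] - table["d_true"]).abs().max()
    print(f"max |d - d_true| across ROIs/classes: {err:.4f}")
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
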