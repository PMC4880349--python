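"""Cohort-level summary statistics over pipeline outputs.

Operates on a *study table*: one row per (zebra, ROI, stripe class)
holding the fitted polarization degree, phase, fit quality and stripe
contrast, plus capture covariates. Provides the paired black-vs-white
degree comparison, the phase correlation on gated ROIs, box-plot-style
group summaries, and the zebra-vs-background polarization comparison.
Mixed-model ANOVA/ANCOVA is deliberately out of scope: the table is
exported as CSV so any such model can be run externally.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fitting import wrap_phase_difference

REQUIRED_COLUMNS = ("zebra_id", "roi_label", "class", "d", "phase_deg", "fit_r", "significant", "contrast")


def validate_study_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the study-table schema and pairing invariants."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"study table missing columns: {missing}")
    bad = set(table["class"].unique()) - {"black", "white"}
    if bad:
        raise ValueError(f"unknown stripe classes: {sorted(bad)}")
    if ((table["d"] < 0) | (table["d"] > 1)).any():
        raise ValueError("d values must lie in [0, 1]")
    counts = table.groupby(["zebra_id", "roi_label"])["class"].nunique()
    if (counts != 2).any():
        bad_idx = counts[counts != 2].index.tolist()
        raise ValueError(f"each (zebra, ROI) needs exactly one black and one white row; bad: {bad_idx[:5]}")
    return table


def _paired(table: pd.DataFrame) -> pd.DataFrame:
    """Wide (one row per ROI) table with black/white columns."""
    validate_study_table(table)
    wide = table.pivot_table(
        index=["zebra_id", "roi_label"],
        columns="class",
        values=["d", "phase_deg", "fit_r", "significant"],
        aggfunc="first",
    )
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    return wide.reset_index()


def stripe_d_comparison(table: pd.DataFrame) -> dict:
    """Paired comparison of black- vs white-stripe polarization degree.

    Reports the per-ROI relative difference (d_black − d_white)
    normalized by the white-stripe degree (and, because the choice of
    denominator is a convention, also by the black-stripe degree), the
    medians of both, the Wilcoxon signed-rank test on the raw pair
    differences and the Pearson correlation between paired degrees.
    """
    wide = _paired(table)
    if len(wide) < 2:
        raise ValueError("need at least 2 paired ROIs")
    db, dw = wide["d_black"].to_numpy(), wide["d_white"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_vs_white = (db - dw) / dw
        rel_vs_black = (db - dw) / db
    if np.all(db == dw):
        wstat, wp = float("nan"), 1.0
    else:
        res = sps.wilcoxon(db, dw)
        wstat, wp = float(res.statistic), float(res.pvalue)
    if np.ptp(db) == 0 or np.ptp(dw) == 0:  # degenerate: correlation undefined
        pear_r, pear_p = float("nan"), float("nan")
    else:
        pear = sps.pearsonr(db, dw)
        pear_r, pear_p = float(pear.statistic), float(pear.pvalue)
    return {
        "n_pairs": int(len(wide)),
        "median_rel_diff_vs_white": float(np.nanmedian(rel_vs_white)),
        "median_rel_diff_vs_black": float(np.nanmedian(rel_vs_black)),
        "median_d_black": float(np.median(db)),
        "median_d_white": float(np.median(dw)),
        "wilcoxon_statistic": wstat,
        "wilcoxon_p": wp,
        "pearson_r": pear_r,
        "pearson_p": pear_p,
    }


def phase_correlation(table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Black-vs-white phase agreement on significance-gated ROIs.

    Uses only ROIs where both class fits passed the gate. Reports the
    gated count, the Pearson correlation between black and white
    phases, the mean absolute circular phase difference, and a paired
    t-test on the signed differences (H0: no systematic phase offset).
    """
    wide = _paired(table)
    gated = wide[(wide["significant_black"] == True) & (wide["significant_white"] == True)]  # noqa: E712
    if len(gated) < 3:
        raise ValueError(f"need ≥ 3 gated ROI pairs for phase analysis, got {len(gated)}")
    pb = gated["phase_deg_black"].to_numpy()
    pw = gated["phase_deg_white"].to_numpy()
    diffs = np.array([wrap_phase_difference(b, w) for b, w in zip(pb, pw)])
    pear = sps.pearsonr(pb, pw)
    if np.allclose(diffs, diffs[0]):
        tstat, tp = 0.0, 1.0
    else:
        t_res = sps.ttest_1samp(diffs, 0.0)
        tstat, tp = float(t_res.statistic), float(t_res.pvalue)
    return {
        "n_gated": int(len(gated)),
        "n_total": int(len(wide)),
        "pearson_r": float(pear.statistic),
        "pearson_p": float(pear.pvalue),
        "mean_abs_phase_diff_deg": float(np.mean(np.abs(diffs))),
        "paired_t": tstat,
        "paired_t_p": tp,
    }


def cohort_summary(table: pd.DataFrame, group_cols: Sequence[str] = ("roi_label", "class", "illumination")) -> pd.DataFrame:
    """Box-plot statistics of d per group: quartiles, mean, 95% CI, outliers.

    Outliers follow the 1.5×IQR rule relative to the quartiles. Groups
    default to (body region, stripe class, illumination).
    """
    group_cols = [c for c in group_cols if c in table.columns]
    if not group_cols:
        group_cols = ["class"]
    rows = []
    for keys, grp in table.groupby(list(group_cols)):
        if not isinstance(keys, tuple):
            keys = (keys,)
        v = grp["d"].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        outliers = v[(v < lo) | (v > hi)]
        n = len(v)
        mean = float(v.mean())
        if n > 1:
            half = float(sps.t.ppf(0.975, n - 1) * v.std(ddof=1) / np.sqrt(n))
        else:
            half = float("nan")
        rows.append(
            dict(zip(group_cols, keys))
            | {
                "n": n,
                "mean": mean,
                "median": float(med),
                "q1": float(q1),
                "q3": float(q3),
                "ci95_low": mean - half,
                "ci95_high": mean + half,
                "n_outliers": int(outliers.size),
                "outliers": tuple(float(x) for x in outliers),
            }
        )
    return pd.DataFrame(rows)


def background_comparison(pairs: Sequence[tuple[float, float]] | pd.DataFrame) -> dict:
    """Compare coat polarization against adjacent background vegetation.

    Each pair is (zebra_d, background_d): the coat degree (mean of the
    black- and white-class degrees of an ROI) and the degree of an
    adjacent, identically illuminated background patch (mask-free
    fit). Reports per-pair ratios, the median ratio, and a paired
    t-test on the degree difference. Pairs with a missing member are
    excluded with a warning.
    """
    if isinstance(pairs, pd.DataFrame):
        pairs = list(zip(pairs["zebra_d"], pairs["background_d"]))
    clean = [(z, b) for z, b in pairs if np.isfinite(z) and np.isfinite(b)]
    if len(clean) < len(pairs):
        warnings.warn(f"excluded {len(pairs) - len(clean)} incomplete pair(s)", stacklevel=2)
    if len(clean) < 2:
        raise ValueError("need at least 2 complete (zebra, background) pairs")
    z = np.array([p[0] for p in clean])
    b = np.array([p[1] for p in clean])
    if np.any(b <= 0):
        raise ValueError("background degrees must be positive to form ratios")
    ratios = z / b
    if np.allclose(z, b):
        tstat, tp = 0.0, 1.0
    else:
        res = sps.ttest_rel(z, b)
        tstat, tp = float(res.statistic), float(res.pvalue)
    return {
        "n_pairs": int(len(clean)),
        "ratios": ratios.tolist(),
        "median_ratio": float(np.median(ratios)),
        "mean_zebra_d": float(z.mean()),
        "mean_background_d": float(b.mean()),
        "paired_t": tstat,
        "paired_t_p": tp,
    }
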