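"""Bundled six-system multicenter validation summary.

Summary data from a six-scanner (two each from three vendors) multicenter
agar-sphere phantom study of retrospective gradient-nonlinearity bias
correction: per-system generic-model channel scale factors and acquisition
parameters, and the pre-/post-correction ADC ROI histogram statistics at a
superior offset (position 2), a composite superior-anterior offset
(position 3), and the isocenter reference scan.  ADC medians and FWHM are
in 1e-3 mm^2/s (tabulated CI +/- 0.02); ROI centers in mm (AP, RL, SI);
volumes in cm^3.

These tables drive the cross-system statistics (`summarize_systems`) and
supply realistic scale factors for the synthetic validation suite.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .roi import cross_system_summary, pearson, rank_sum_exact

SYSTEMS = ("PH1", "PH2", "GE1", "GE2", "SM1", "SM2")

#: per-system (F_AP, F_RL, F_SI) generic-model value-scale factors
SCALE_FACTORS = {
    "PH1": (1.0, 1.0, 0.7),
    "PH2": (1.25, 1.15, 0.7),
    "GE1": (1.2, 1.2, 0.2),
    "GE2": (4.0, 2.2, 0.45),
    "SM1": (1.1, 1.2, 0.9),
    "SM2": (2.0, 1.9, 0.9),
}

#: echo times (ms) of the validation acquisitions
ECHO_TIME_MS = {"PH1": 95, "PH2": 88, "GE1": 108, "GE2": 90, "SM1": 117, "SM2": 120}

_ROI_STATS = {
    # system: ((pos2 median/FWHM pre, post), (pos3 pre, post), ref (median, fwhm))
    "PH1": ((1.65, 0.32, 1.96, 0.11), (1.87, 0.13, 2.08, 0.18), (1.93, 0.05)),
    "PH2": ((1.67, 0.35, 1.95, 0.08), (2.04, 0.16, 1.96, 0.08), (1.95, 0.06)),
    "GE1": ((1.72, 0.24, 1.89, 0.11), (1.84, 0.11, 1.92, 0.10), (1.83, 0.06)),
    "GE2": ((1.55, 0.45, 1.89, 0.08), (1.83, 0.14, 1.91, 0.11), (1.86, 0.05)),
    "SM1": ((1.88, 0.21, 2.06, 0.15), (2.08, 0.20, 2.16, 0.15), (2.11, 0.10)),
    "SM2": ((1.80, 0.31, 1.96, 0.14), (2.12, 0.27, 2.08, 0.16), (1.95, 0.08)),
}

_ROI_GEOMETRY = {
    # system: (pos2 center, pos2 vol, pos3 center, pos3 vol, ref center, ref vol)
    "PH1": ((6, 2, 123), 41, (-92, 16, 123), 41, (0, 0, 0), 32),
    "PH2": ((7, 26, 113), 53, (-96, 99, 99), 54, (0, 0, 0), 33),
    "GE1": ((5, 12, 94), 41, (-92, 16, 104), 34, (-1, -8, 0), 27),
    "GE2": ((7, 1, 86), 46, (-93, 4, 95), 42, (0, -1, 0), 27),
    "SM1": ((7, -28, 90), 55, (-91, -45, 45), 37, (2, -2, 0), 32),
    "SM2": ((3, -18, 84), 43, (-86, 13, 79), 49, (3, 0, 0), 34),
}


def validation_summary() -> pd.DataFrame:
    """Long-format table of the bundled per-system ROI histogram metrics."""
    rows = []
    for sysid in SYSTEMS:
        (p2, p3, ref) = _ROI_STATS[sysid]
        geo = _ROI_GEOMETRY[sysid]
        rows += [
            dict(system=sysid, position=2, phase="pre", median=p2[0], fwhm=p2[1],
                 center=geo[0], volume_cm3=geo[1]),
            dict(system=sysid, position=2, phase="post", median=p2[2], fwhm=p2[3],
                 center=geo[0], volume_cm3=geo[1]),
            dict(system=sysid, position=3, phase="pre", median=p3[0], fwhm=p3[1],
                 center=geo[2], volume_cm3=geo[3]),
            dict(system=sysid, position=3, phase="post", median=p3[2], fwhm=p3[3],
                 center=geo[2], volume_cm3=geo[3]),
            dict(system=sysid, position=1, phase="reference", median=ref[0],
                 fwhm=ref[1], center=geo[4], volume_cm3=geo[5]),
        ]
    df = pd.DataFrame(rows)
    df["nonuniformity"] = df["fwhm"] / df["median"]
    ref = df[df.phase == "reference"].set_index("system")["median"]
    df["percent_bias"] = 100.0 * (
        df["median"] - df["system"].map(ref)
    ) / df["system"].map(ref)
    return df


def _select(df: pd.DataFrame, position: int, phase: str, col: str) -> np.ndarray:
    sub = df[(df.position == position) & (df.phase == phase)]
    return sub.set_index("system").loc[list(SYSTEMS), col].to_numpy(float)


def summarize_systems(df: pd.DataFrame | None = None) -> dict[str, float]:
    """Cross-system statistics of the bundled validation table.

    Recomputes, from the per-system table alone, the study-level figures of
    merit: cross-system median/range of ADC medians per position and phase,
    nonuniformity medians, median absolute percent bias, exact Wilcoxon
    rank-sum p-values for pre/post FWHM changes and ROI-volume contrasts,
    and Pearson correlations of position medians with the reference.
    """
    if df is None:
        df = validation_summary()
    ref_med = _select(df, 1, "reference", "median")
    out: dict[str, float] = {}

    for pos in (2, 3):
        for phase in ("pre", "post"):
            med = _select(df, pos, phase, "median")
            cs = cross_system_summary(med)
            out[f"pos{pos}_{phase}_median"] = cs["median"]
            out[f"pos{pos}_{phase}_range"] = cs["range"]
            out[f"pos{pos}_{phase}_range_to_median"] = cs["range_to_median"]
            nu = _select(df, pos, phase, "nonuniformity")
            out[f"pos{pos}_{phase}_nonuniformity_median_pct"] = 100 * float(
                np.median(nu)
            )
            out[f"pos{pos}_{phase}_nonuniformity_min_pct"] = 100 * float(nu.min())
            out[f"pos{pos}_{phase}_nonuniformity_max_pct"] = 100 * float(nu.max())
            pb = np.abs(_select(df, pos, phase, "percent_bias"))
            out[f"pos{pos}_{phase}_abs_percent_bias_median"] = float(np.median(pb))
            out[f"pos{pos}_{phase}_abs_percent_bias_min"] = float(pb.min())
            out[f"pos{pos}_{phase}_abs_percent_bias_max"] = float(pb.max())
        out[f"pos{pos}_fwhm_p"] = rank_sum_exact(
            _select(df, pos, "pre", "fwhm"), _select(df, pos, "post", "fwhm")
        )
        out[f"pos{pos}_nonuniformity_p"] = rank_sum_exact(
            _select(df, pos, "pre", "nonuniformity"),
            _select(df, pos, "post", "nonuniformity"),
        )
        for phase in ("pre", "post"):
            r, p = pearson(_select(df, pos, phase, "median"), ref_med)
            out[f"pos{pos}_{phase}_ref_R"] = r
            out[f"pos{pos}_{phase}_ref_p"] = p

    cs = cross_system_summary(ref_med)
    out["reference_median"] = cs["median"]
    out["reference_range"] = cs["range"]
    out["reference_range_to_median"] = cs["range_to_median"]
    nu_ref = _select(df, 1, "reference", "nonuniformity")
    out["reference_nonuniformity_median_pct"] = 100 * float(np.median(nu_ref))
    out["reference_nonuniformity_min_pct"] = 100 * float(nu_ref.min())
    out["reference_nonuniformity_max_pct"] = 100 * float(nu_ref.max())
    out["reference_fwhm_median"] = float(np.median(_select(df, 1, "reference", "fwhm")))

    vol2 = _select(df, 2, "pre", "volume_cm3")
    vol3 = _select(df, 3, "pre", "volume_cm3")
    volr = _select(df, 1, "reference", "volume_cm3")
    out["volume_p_pos2_vs_pos3"] = rank_sum_exact(vol2, vol3)
    out["volume_p_ref_vs_pos2"] = rank_sum_exact(volr, vol2)
    out["volume_p_ref_vs_pos3"] = rank_sum_exact(volr, vol3)
    out["reference_volume_min_cm3"] = float(volr.min())

    te = np.array([ECHO_TIME_MS[s] for s in SYSTEMS], float)
    r, p = pearson(_select(df, 1, "reference", "fwhm"), te)
    out["reference_fwhm_te_R"] = r
    out["reference_fwhm_te_p"] = p

    out["abs_percent_bias_fold_reduction_pos2"] = (
        out["pos2_pre_abs_percent_bias_median"]
        / out["pos2_post_abs_percent_bias_median"]
    )
    out["variability_fold_reduction_pos2"] = (
        out["pos2_pre_range_to_median"] / out["pos2_post_range_to_median"]
    )
    return out
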