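"""First-order features — 50 values.

Three sub-blocks: intensity statistics on the raw in-mask values (18),
intensity-histogram features on the discretized levels (23), and
intensity–volume-histogram features (9). Statistics undefined on degenerate
(constant) ROIs — skewness, kurtosis, coefficients of variation and the
intensity-fraction quantities — emit NaN, the documented degenerate rule.
"""

from __future__ import annotations

import numpy as np

from ..grids import ROIMask, VolumeGrid
from .quantize import QuantizedROI

__all__ = ["intensity_features", "STAT_FEATURES", "IH_FEATURES", "IVH_FEATURES"]

STAT_FEATURES = [
    "stat_mean", "stat_var", "stat_skew", "stat_kurt", "stat_median",
    "stat_min", "stat_p10", "stat_p90", "stat_max", "stat_iqr", "stat_range",
    "stat_mad", "stat_rmad", "stat_medad", "stat_cov", "stat_qcod",
    "stat_energy", "stat_rms",
]
IH_FEATURES = [
    "ih_mean", "ih_var", "ih_skew", "ih_kurt", "ih_median", "ih_min",
    "ih_p10", "ih_p90", "ih_max", "ih_mode", "ih_iqr", "ih_range", "ih_mad",
    "ih_rmad", "ih_medad", "ih_cov", "ih_qcod", "ih_entropy",
    "ih_uniformity", "ih_max_grad", "ih_max_grad_level", "ih_min_grad",
    "ih_min_grad_level",
]
IVH_FEATURES = [
    "ivh_v10", "ivh_v25", "ivh_v50", "ivh_v75", "ivh_v90",
    "ivh_i10", "ivh_i90", "ivh_v10_minus_v90", "ivh_i10_minus_i90",
]


def _moments(x: np.ndarray) -> dict[str, float]:
    """Shared statistical skeleton for raw and histogram intensities."""
    n = x.size
    mu = float(x.mean())
    var = float(x.var())  # population variance, per the reference definitions
    sd = np.sqrt(var)
    out = {
        "mean": mu,
        "var": var,
        "skew": float(((x - mu) ** 3).mean() / sd**3) if sd > 0 else float("nan"),
        "kurt": float(((x - mu) ** 4).mean() / sd**4 - 3) if sd > 0 else float("nan"),
        "median": float(np.median(x)),
        "min": float(x.min()),
        "p10": float(np.percentile(x, 10)),
        "p90": float(np.percentile(x, 90)),
        "max": float(x.max()),
    }
    out["iqr"] = float(np.percentile(x, 75) - np.percentile(x, 25))
    out["range"] = out["max"] - out["min"]
    out["mad"] = float(np.abs(x - mu).mean())
    sel = (x >= out["p10"]) & (x <= out["p90"])
    out["rmad"] = float(np.abs(x[sel] - x[sel].mean()).mean()) if sel.any() else float("nan")
    out["medad"] = float(np.abs(x - out["median"]).mean())
    out["cov"] = sd / mu if mu != 0 else float("nan")
    q75, q25 = np.percentile(x, 75), np.percentile(x, 25)
    out["qcod"] = float((q75 - q25) / (q75 + q25)) if (q75 + q25) != 0 else float("nan")
    return out


def intensity_features(
    volume: VolumeGrid, mask: ROIMask, quantized: QuantizedROI
) -> dict[str, float]:
    """Compute the 50-feature first-order block."""
    if mask.n_voxels == 0:
        raise ValueError("mask is empty")
    x = volume.data[mask.data].astype(float)
    out: dict[str, float] = {}

    m = _moments(x)
    for key in ("mean", "var", "skew", "kurt", "median", "min", "p10", "p90",
                "max", "iqr", "range", "mad", "rmad", "medad", "cov", "qcod"):
        out[f"stat_{key}"] = m[key]
    out["stat_energy"] = float((x**2).sum())
    out["stat_rms"] = float(np.sqrt((x**2).mean()))

    g = quantized.levels[quantized.mask].astype(float)
    ng = quantized.n_levels
    mh = _moments(g)
    for key in ("mean", "var", "skew", "kurt", "median", "min", "p10", "p90",
                "max", "iqr", "range", "mad", "rmad", "medad", "cov", "qcod"):
        out[f"ih_{key}"] = mh[key]
    counts = np.bincount(g.astype(int), minlength=ng + 1)[1:]
    p = counts / counts.sum()
    nz = p[p > 0]
    out["ih_mode"] = float(np.argmax(counts) + 1)
    out["ih_entropy"] = float(-(nz * np.log2(nz)).sum())
    out["ih_uniformity"] = float((p**2).sum())
    grad = np.gradient(counts.astype(float))
    out["ih_max_grad"] = float(grad.max())
    out["ih_max_grad_level"] = float(np.argmax(grad) + 1)
    out["ih_min_grad"] = float(grad.min())
    out["ih_min_grad_level"] = float(np.argmin(grad) + 1)

    # intensity-volume histogram: volume fraction above an intensity fraction,
    # and intensity fraction above a volume fraction
    rng_x = x.max() - x.min()
    if rng_x > 0:
        gamma = (x - x.min()) / rng_x  # intensity fractions in [0, 1]
        for nu in (10, 25, 50, 75, 90):
            out[f"ivh_v{nu}"] = float((gamma >= nu / 100.0).mean())
        # intensity fraction at which nu% of the volume remains above
        sorted_desc = np.sort(gamma)[::-1]
        for nu in (10, 90):
            k = max(int(np.ceil(nu / 100.0 * len(sorted_desc))) - 1, 0)
            out[f"ivh_i{nu}"] = float(sorted_desc[k])
        out["ivh_v10_minus_v90"] = out["ivh_v10"] - out["ivh_v90"]
        out["ivh_i10_minus_i90"] = out["ivh_i10"] - out["ivh_i90"]
    else:
        for name in IVH_FEATURES:
            out[name] = float("nan")
    return out
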