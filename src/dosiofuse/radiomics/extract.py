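"""Full feature-extraction pipeline: 215 features per (volume, mask).

Order of operations: resample to 1 mm isotropic -> discretize to 64 gray
levels (fixed bin number) -> compute morphology (29), first-order (50) and
texture (136) blocks, concatenated in the fixed manifest order.
"""

from __future__ import annotations

import pandas as pd

from ..grids import ROIMask, VolumeGrid
from .intensity import IH_FEATURES, IVH_FEATURES, STAT_FEATURES, intensity_features
from .morphology import MORPH_FEATURES, morphology_features
from .quantize import discretize_fbn, resample_isotropic
from .texture import (
    GLCM_FEATURES, GLDZM_FEATURES, GLRLM_FEATURES, GLSZM_FEATURES,
    NGLDM_FEATURES, NGTDM_FEATURES,
    glcm_features, gldzm_features, glrlm_features, glszm_features,
    ngldm_features, ngtdm_features,
)

__all__ = ["FEATURE_MANIFEST", "extract_features", "extract_feature_table"]


def _build_manifest() -> list[str]:
    names: list[str] = []
    names += MORPH_FEATURES                                            # 29
    names += STAT_FEATURES + IH_FEATURES + IVH_FEATURES                # 50
    for agg in ("avg", "mrg"):
        names += [f"glcm_{g}_{agg}" for g in GLCM_FEATURES]            # 50
    for agg in ("avg", "mrg"):
        names += [f"{n}_{agg}" for n in GLRLM_FEATURES]                # 32
    names += GLSZM_FEATURES                                            # 16
    names += GLDZM_FEATURES                                            # 16
    names += NGTDM_FEATURES                                            # 5
    names += NGLDM_FEATURES                                            # 17
    return names


FEATURE_MANIFEST: list[str] = _build_manifest()
assert len(FEATURE_MANIFEST) == 215, len(FEATURE_MANIFEST)
assert len(set(FEATURE_MANIFEST)) == 215


def extract_features(
    volume: VolumeGrid,
    mask: ROIMask,
    n_levels: int = 64,
    isotropic_spacing: float | None = 1.0,
) -> dict[str, float]:
    """Extract the full 215-feature vector from one volume + ROI mask.

    Parameters
    ----------
    volume, mask : co-registered intensity volume and ROI on one lattice.
    n_levels : gray levels for the fixed-bin-number discretization.
    isotropic_spacing : target spacing in mm, or None to skip resampling.
    """
    if mask.n_voxels == 0:
        raise ValueError("mask is empty")
    if not volume.same_lattice(mask):
        raise ValueError("volume and mask must share one lattice")
    if isotropic_spacing is not None:
        volume, mask = resample_isotropic(volume, mask, spacing=isotropic_spacing)
    q = discretize_fbn(volume, mask, n_levels=n_levels)

    out: dict[str, float] = {}
    stages = [
        ("morph", lambda: morphology_features(mask, volume)),
        ("firstorder", lambda: intensity_features(volume, mask, q)),
        ("glcm", lambda: glcm_features(q)),
        ("glrlm", lambda: glrlm_features(q)),
        ("glszm", lambda: glszm_features(q)),
        ("gldzm", lambda: gldzm_features(q)),
        ("ngtdm", lambda: ngtdm_features(q)),
        ("ngldm", lambda: ngldm_features(q)),
    ]
    for family, fn in stages:
        try:
            out.update(fn())
        except Exception as exc:
            raise RuntimeError(f"feature family {family!r} failed: {exc}") from exc
    ordered = {name: float(out[name]) for name in FEATURE_MANIFEST}
    assert len(ordered) == 215
    return ordered


def extract_feature_table(
    items: dict[str, tuple[VolumeGrid, ROIMask]], **kwargs
) -> pd.DataFrame:
    """Extract features for many patients; rows indexed by patient id."""
    rows = {pid: extract_features(vol, msk, **kwargs) for pid, (vol, msk) in items.items()}
    return pd.DataFrame.from_dict(rows, orient="index", columns=FEATURE_MANIFEST)
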