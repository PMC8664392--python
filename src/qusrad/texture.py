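"""GLCM texture and texture-derivative features of parametric maps.

Second-order (QUS-Tex1) features are gray-level co-occurrence statistics of
the QUS parametric maps; third-order (QUS-Tex1-Tex2) features repeat the
GLCM analysis on *texture maps* — maps whose cells hold the local GLCM
feature value computed in a small neighborhood — capturing the spatial
organization of heterogeneity itself.

The co-occurrence matrix here is symmetric (each pixel pair counted in both
directions), normalized to unit sum, evaluated at the four principal angles
0/45/90/135 degrees, and skips any pair touching an invalid (masked) cell;
features are averaged over the four angles.  Feature definitions:

    CON = sum (i-j)^2 p(i,j)                      contrast
    COR = sum (i-mu_i)(j-mu_j) p(i,j)/(s_i s_j)   correlation (0 if s=0)
    ENE = sum p(i,j)^2                            energy
    HOM = sum p(i,j) / (1 + |i-j|)                homogeneity
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .spectral import ParametricMap

__all__ = [
    "GLCMSpec",
    "QuantizedMap",
    "TextureFeatures",
    "TextureMap",
    "GLCMError",
    "quantize_map",
    "compute_glcm",
    "glcm_features",
    "texture_of_map",
    "texture_map_of",
    "texture_derivative",
    "TEXTURE_FEATURE_NAMES",
    "DERIVATIVE_PARAMS",
]

TEXTURE_FEATURE_NAMES = ("CON", "COR", "ENE", "HOM")
#: parameters whose texture maps feed the second texture pass (SS and SAS
#: texture maps are excluded from the derivative tier)
DERIVATIVE_PARAMS = ("MBF", "SI", "ASD", "AAC")

_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


class GLCMError(ValueError):
    """No valid pixel pairs for the requested displacement/angle."""


@dataclass(frozen=True)
class GLCMSpec:
    """Gray-level count, displacement and angle set for co-occurrence analysis."""

    n_levels: int = 16
    displacement: int = 1
    angles: tuple[int, ...] = (0, 45, 90, 135)

    def __post_init__(self) -> None:
        if self.displacement < 1:
            raise ValueError("displacement must be >= 1")
        if self.n_levels < 2:
            raise ValueError("need >= 2 gray levels")
        bad = set(self.angles) - set(_ANGLE_OFFSETS)
        if bad:
            raise ValueError(f"unsupported angles {sorted(bad)}")


@dataclass
class QuantizedMap:
    """Integer gray-level map in [1, n_levels]; 0 marks invalid cells."""

    levels: np.ndarray
    n_levels: int
    source_range: tuple[float, float]

    @property
    def valid(self) -> np.ndarray:
        return self.levels > 0


@dataclass(frozen=True)
class TextureFeatures:
    con: float
    cor: float
    ene: float
    hom: float

    def as_dict(self) -> dict[str, float]:
        return {"CON": self.con, "COR": self.cor, "ENE": self.ene, "HOM": self.hom}


@dataclass
class TextureMap:
    """Local texture-feature values regenerated on the sub-ROI lattice."""

    base_parameter: str
    texture_feature: str
    values: np.ndarray
    valid_mask: np.ndarray

    def as_parametric(self) -> ParametricMap:
        return ParametricMap(
            f"{self.base_parameter}-{self.texture_feature}",
            np.nan_to_num(self.values),
            self.valid_mask,
        )


def quantize_map(pmap: ParametricMap, n_levels: int = 16) -> QuantizedMap:
    """Uniform min-max binning of valid cells into ``n_levels`` gray levels.

    A constant map collapses to level 1 everywhere.  Invalid cells get
    level 0 and are excluded from all pair counts downstream.
    """
    if not pmap.valid_mask.any():
        raise ValueError(f"cannot quantize all-invalid map {pmap.parameter_name}")
    v = pmap.values
    vmin = float(v[pmap.valid_mask].min())
    vmax = float(v[pmap.valid_mask].max())
    levels = np.zeros(v.shape, dtype=np.int32)
    if vmax == vmin:
        levels[pmap.valid_mask] = 1
    else:
        scaled = (v - vmin) / (vmax - vmin) * n_levels
        lv = np.clip(np.floor(scaled).astype(np.int32) + 1, 1, n_levels)
        levels[pmap.valid_mask] = lv[pmap.valid_mask]
    return QuantizedMap(levels=levels, n_levels=n_levels, source_range=(vmin, vmax))


def compute_glcm(q: QuantizedMap, spec: GLCMSpec, angle: int) -> np.ndarray:
    """Symmetric, sum-normalized co-occurrence matrix at one angle.

    Pairs are taken at ``spec.displacement`` pixels along ``angle``
    (0 deg = lateral, 90 deg = axial-up, following image-row convention);
    any pair with an invalid endpoint is skipped.
    """
    dr, dc = _ANGLE_OFFSETS[angle]
    d = spec.displacement
    dr, dc = dr * d, dc * d
    lv = q.levels
    H, W = lv.shape
    r0, r1 = max(0, -dr), min(H, H - dr)
    c0, c1 = max(0, -dc), min(W, W - dc)
    if r1 <= r0 or c1 <= c0:
        raise GLCMError(f"map too small for displacement {d} at angle {angle}")
    a = lv[r0:r1, c0:c1]
    b = lv[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    ok = (a > 0) & (b > 0)
    if not ok.any():
        raise GLCMError(f"no valid pixel pairs at angle {angle}")
    n = spec.n_levels
    codes = (a[ok] - 1) * n + (b[ok] - 1)
    counts = np.bincount(codes, minlength=n * n).reshape(n, n).astype(float)
    counts = counts + counts.T  # symmetric: count both directions
    return counts / counts.sum()


def glcm_features(glcm: np.ndarray) -> TextureFeatures:
    """Contrast, correlation, energy and homogeneity of a normalized GLCM."""
    p = np.asarray(glcm, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("GLCM must be square")
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("GLCM must be normalized to sum 1")
    n = p.shape[0]
    i = np.arange(n, dtype=float)[:, None]
    j = np.arange(n, dtype=float)[None, :]
    con = float(((i - j) ** 2 * p).sum())
    ene = float((p**2).sum())
    hom = float((p / (1.0 + np.abs(i - j))).sum())
    pi = p.sum(axis=1)
    mu = float((np.arange(n) * pi).sum())
    var = float(((np.arange(n) - mu) ** 2 * pi).sum())
    if var <= 0:
        cor = 0.0
    else:
        cor = float(((i - mu) * (j - mu) * p).sum() / var)
    return TextureFeatures(con=con, cor=cor, ene=ene, hom=hom)


def _angle_averaged_features(q: QuantizedMap, spec: GLCMSpec) -> TextureFeatures:
    feats = []
    for ang in spec.angles:
        try:
            feats.append(glcm_features(compute_glcm(q, spec, ang)))
        except GLCMError as e:
            warnings.warn(f"skipping angle {ang}: {e}", stacklevel=3)
    if not feats:
        raise GLCMError("no angle produced a valid GLCM")
    return TextureFeatures(
        con=float(np.mean([f.con for f in feats])),
        cor=float(np.mean([f.cor for f in feats])),
        ene=float(np.mean([f.ene for f in feats])),
        hom=float(np.mean([f.hom for f in feats])),
    )


def texture_of_map(pmap: ParametricMap, spec: GLCMSpec | None = None) -> TextureFeatures:
    """Whole-map, angle-averaged GLCM features (the QUS-Tex1 scalars)."""
    spec = spec or GLCMSpec()
    return _angle_averaged_features(quantize_map(pmap, spec.n_levels), spec)


def texture_map_of(
    pmap: ParametricMap,
    spec: GLCMSpec | None = None,
    neighborhood: int = 5,
) -> dict[str, TextureMap]:
    """Regenerate local texture maps: per-cell GLCM features in a sliding
    neighborhood.

    Quantization uses the map-global bin edges (local windows are too small
    to define stable level sets of their own); neighborhoods are clipped at
    the lattice border.  Cells whose neighborhood has no valid pair at any
    angle are invalid in all four output maps.
    """
    spec = spec or GLCMSpec()
    if neighborhood < 3 or neighborhood % 2 == 0:
        raise ValueError("neighborhood must be odd and >= 3")
    H, W = pmap.values.shape
    if neighborhood > max(H, W):
        raise ValueError(
            f"neighborhood {neighborhood} exceeds map shape {(H, W)}"
        )
    q = quantize_map(pmap, spec.n_levels)
    half = neighborhood // 2
    out = {f: np.full((H, W), np.nan) for f in TEXTURE_FEATURE_NAMES}
    ok = np.zeros((H, W), dtype=bool)
    for r in range(H):
        r0, r1 = max(0, r - half), min(H, r + half + 1)
        for c in range(W):
            c0, c1 = max(0, c - half), min(W, c + half + 1)
            sub = QuantizedMap(
                q.levels[r0:r1, c0:c1], q.n_levels, q.source_range
            )
            if not sub.valid.any():
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    tf = _angle_averaged_features(sub, spec)
                except GLCMError:
                    continue
            for f, v in tf.as_dict().items():
                out[f][r, c] = v
            ok[r, c] = True
    return {
        f: TextureMap(pmap.parameter_name, f, out[f], ok)
        for f in TEXTURE_FEATURE_NAMES
    }


def texture_derivative(
    texture_maps: dict[tuple[str, str], TextureMap],
    spec: GLCMSpec | None = None,
) -> dict[str, float]:
    """Second texture pass: GLCM features *of the texture maps*.

    Expects the 16 eligible texture maps — parameters {MBF, SI, ASD, AAC}
    crossed with features {CON, COR, ENE, HOM} — and returns the 64 named
    third-order scalars ``PARAM-TEX1-TEX2`` (e.g. ``SI-COR-CON``).  Each
    texture map is re-quantized on its own min-max range before the second
    GLCM pass.
    """
    spec = spec or GLCMSpec()
    out: dict[str, float] = {}
    for param in DERIVATIVE_PARAMS:
        for t1 in TEXTURE_FEATURE_NAMES:
            key = (param, t1)
            if key not in texture_maps:
                raise KeyError(
                    f"missing texture map {param}-{t1} required for the "
                    "texture-derivative tier"
                )
            tf = texture_of_map(texture_maps[key].as_parametric(), spec)
            for t2, v in tf.as_dict().items():
                out[f"{param}-{t1}-{t2}"] = v
    return out
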