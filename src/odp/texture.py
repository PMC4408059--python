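"""Gray-level co-occurrence texture statistics of CWT heat-maps.

Each of the four transform planes is treated as a texture image: valid
pixels are quantised into ``N`` gray levels (uniform min-max bins over the
plane's valid region), ordered level pairs at a fixed horizontal offset of
``L`` pixels within each scale row are counted into an ``N x N``
co-occurrence matrix, and the four classical Haralick statistics
(homogeneity, energy, contrast, correlation) are computed from the
normalised matrix.  With the defaults ``N = 8`` and ``L = 25`` (0.0625 s
at 400 Hz) this yields the 16-feature vector used by the detectors.

Pairs with either pixel in the blanked (cone-of-influence) region are
excluded; normalisation is by the number of valid pairs.  Counting is
ordered and single-direction (+L along the time axis): no symmetrisation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .wavelet import CWTResult, HeatMap, PLANES, heatmaps

__all__ = [
    "STATISTICS",
    "FEATURE_NAMES",
    "LevelImage",
    "quantize",
    "CooccurrenceMatrix",
    "cooccurrence",
    "TextureStats",
    "texture_statistics",
    "FeatureVector",
    "extract_features",
]

STATISTICS = ("homogeneity", "correlation", "energy", "contrast")

#: Canonical, ordered names of the 16 features: plane-major, statistic-minor.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{plane}_{stat}" for plane in PLANES for stat in STATISTICS
)


@dataclass(frozen=True)
class LevelImage:
    """Integer gray-level image with levels in {1..n_levels} on valid pixels."""

    levels: np.ndarray
    valid_mask: np.ndarray
    n_levels: int


def quantize(heat_map: HeatMap, n_levels: int = 8) -> LevelImage:
    """Quantise a plane into ``n_levels`` uniform bins over its valid range.

    Value ``v`` maps to level ``min(N, 1 + floor(N*(v - lo)/(hi - lo)))``
    where ``lo``/``hi`` are the min/max over valid pixels; a degenerate
    plane (``hi == lo``) maps every valid pixel to level 1.  The mapping is
    invariant to positive affine transforms of the plane.  Masked pixels
    are left at level 0 (unassigned).
    """
    mask = heat_map.valid_mask
    if not mask.any():
        raise ValueError("cannot quantize a plane with an empty valid region")
    vals = heat_map.values
    lo = vals[mask].min()
    hi = vals[mask].max()
    levels = np.zeros(vals.shape, dtype=np.int64)
    if hi == lo:
        levels[mask] = 1
    else:
        scaled = np.floor(n_levels * (vals[mask] - lo) / (hi - lo)).astype(np.int64)
        levels[mask] = np.minimum(n_levels, 1 + scaled)
    return LevelImage(levels=levels, valid_mask=mask, n_levels=n_levels)


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Normalised ordered-pair frequencies at horizontal offset ``offset``."""

    probabilities: np.ndarray
    offset: int
    pair_count: int


def cooccurrence(img: LevelImage, offset: int = 25) -> CooccurrenceMatrix:
    """Count ordered pairs (column c, column c+offset) within each row.

    Only pairs with both pixels valid contribute; counts are normalised by
    the total number of valid pairs.
    """
    if offset < 1:
        raise ValueError(f"offset must be >= 1, got {offset}")
    n_levels = img.n_levels
    if offset >= img.levels.shape[1]:
        raise ValueError("no valid pixel pair at the requested offset")
    left = img.levels[:, :-offset]
    right = img.levels[:, offset:]
    pair_ok = img.valid_mask[:, :-offset] & img.valid_mask[:, offset:]
    i = left[pair_ok] - 1
    j = right[pair_ok] - 1
    if i.size == 0:
        raise ValueError("no valid pixel pair at the requested offset")
    counts = np.bincount(i * n_levels + j, minlength=n_levels * n_levels)
    counts = counts.reshape(n_levels, n_levels).astype(float)
    return CooccurrenceMatrix(
        probabilities=counts / i.size, offset=offset, pair_count=int(i.size)
    )


@dataclass(frozen=True)
class TextureStats:
    """The four Haralick statistics of one co-occurrence matrix.

    ``correlation`` is ``None`` when a marginal standard deviation is zero
    (e.g. all mass on a single level), in which case correlation is
    undefined rather than an error.
    """

    homogeneity: float
    energy: float
    contrast: float
    correlation: float | None


def texture_statistics(P: CooccurrenceMatrix) -> TextureStats:
    """Homogeneity, energy, contrast and correlation of a normalised GLCM.

    With ``p_ij`` the pair probability of levels ``(i, j)``:

    - homogeneity = sum p_ij / (1 + |i - j|)
    - energy      = sum p_ij^2
    - contrast    = sum p_ij (i - j)^2
    - correlation = sum p_ij (i - mu_i)(j - mu_j) / (sigma_i sigma_j)

    where ``mu``/``sigma`` are means and standard deviations of the row and
    column marginals.
    """
    p = P.probabilities
    n = p.shape[0]
    lev = np.arange(1, n + 1, dtype=float)
    ii, jj = np.meshgrid(lev, lev, indexing="ij")
    diff = ii - jj
    homogeneity = float(np.sum(p / (1.0 + np.abs(diff))))
    energy = float(np.sum(p * p))
    contrast = float(np.sum(p * diff**2))

    p_i = p.sum(axis=1)
    p_j = p.sum(axis=0)
    mu_i = float(np.dot(lev, p_i))
    mu_j = float(np.dot(lev, p_j))
    var_i = float(np.dot((lev - mu_i) ** 2, p_i))
    var_j = float(np.dot((lev - mu_j) ** 2, p_j))
    if var_i <= 0.0 or var_j <= 0.0:
        correlation = None
    else:
        cov = float(np.sum(p * (ii - mu_i) * (jj - mu_j)))
        correlation = cov / math.sqrt(var_i * var_j)
    return TextureStats(
        homogeneity=homogeneity, energy=energy, contrast=contrast,
        correlation=correlation,
    )


@dataclass(frozen=True)
class FeatureVector:
    """The 16 named texture features of one signal's transform.

    Undefined correlations are encoded as 0.0 so that classifiers receive a
    complete numeric vector; their names are retained in ``undefined``.
    """

    values: np.ndarray
    undefined: tuple[str, ...] = ()
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise ValueError(
                f"expected {len(self.names)} features, got {len(self.values)}"
            )
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def as_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in zip(self.names, self.values)}


def extract_features(
    result: CWTResult, n_levels: int = 8, offset: int = 25
) -> FeatureVector:
    """Quantise each plane, form its GLCM, and assemble the 16 features.

    At 400 Hz the default offset of 25 pixels corresponds to 0.0625 s of
    delay; offsetting beyond direct neighbours counteracts the smoothness
    of the transform, which would otherwise pile probability mass onto the
    GLCM diagonal.
    """
    maps = heatmaps(result)
    values: list[float] = []
    undefined: list[str] = []
    for plane in PLANES:
        img = quantize(maps[plane], n_levels)
        stats = texture_statistics(cooccurrence(img, offset))
        for stat in STATISTICS:
            v = getattr(stats, stat)
            if v is None:
                undefined.append(f"{plane}_{stat}")
                v = 0.0
            values.append(float(v))
    return FeatureVector(values=np.array(values), undefined=tuple(undefined))
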