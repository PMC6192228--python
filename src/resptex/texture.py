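"""Gray-level co-occurrence texture features of the dB spectrogram image.

The dB image is reduced to G = 16 gray levels by linear min-max scaling
(shape-preserving, not histogram equalization). For each orientation
psi in {0, 45, 90, 135} degrees at pixel distance d (default 1) a
symmetric, normalized co-occurrence matrix P(i, j | d, psi) is counted,
and four scalar texture measures are computed from each:

    energy      = sum_ij P^2
    inertia     = sum_ij (i - j)^2 P^2          (contrast-like; the
                  squared-P form is this pipeline's definition, the
                  classical Haralick contrast uses P — flag below)
    correlation = (sum_ij i*j*P - u1*u2) / (d1*d2)
    entropy     = -sum_ij P log10 P             (0 log 0 := 0)

u1, u2 are the marginal means and d1, d2 the marginal standard
deviations of P; with symmetric counting the two marginals coincide.
Sputum secretions superimpose short broadband crackle transients on the
breath noise, which appear as vertical striations in the spectrogram;
pairs taken along the time axis (psi = 0) cross those striation edges,
so the 0-degree inertia in particular carries the sputum signal.

4 measures x 4 orientations give the 16-attribute vector per cycle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .spectrogram import Spectrogram

DEFAULT_GRAY_LEVELS = 16
DEFAULT_DISTANCE = 1

ORIENTATIONS = (0, 45, 90, 135)
MEASURES = ("energy", "inertia", "correlation", "entropy")
#: fixed attribute order: measure-major, orientation-minor
FEATURE_NAMES = tuple(f"{m}_{psi}" for m in MEASURES for psi in ORIENTATIONS)

# (d_row, d_col) per orientation on an image whose rows are frequency and
# columns are time: 0 deg pairs along time, 90 deg along frequency,
# 45/135 the diagonals (same convention as scikit-image's graycomatrix).
_OFFSETS = {
    0: lambda d: (0, d),
    45: lambda d: (-d, d),
    90: lambda d: (-d, 0),
    135: lambda d: (-d, -d),
}


@dataclass
class QuantizedImage:
    levels: np.ndarray  # integer matrix, entries in 0..n_levels-1
    n_levels: int
    min_value: float
    max_value: float


@dataclass
class GLCMatrix:
    P: np.ndarray       # n_levels x n_levels, non-negative, sums to 1
    distance: int
    psi: int            # orientation in degrees
    offset: tuple[int, int]

    @property
    def n_levels(self) -> int:
        return self.P.shape[0]


@dataclass
class TextureFeatures:
    """16-attribute texture vector of one respiratory cycle."""

    values: np.ndarray  # ordered per FEATURE_NAMES
    names: tuple[str, ...] = FEATURE_NAMES

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def quantize(db_image: np.ndarray,
             n_levels: int = DEFAULT_GRAY_LEVELS) -> QuantizedImage:
    """Reduce a gray image to ``n_levels`` levels by linear min-max scaling.

    level = floor(G * (v - min) / (max - min)), clipped to G - 1; a
    constant image maps to all zeros.
    """
    img = np.asarray(db_image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("cannot quantize an empty image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        levels = np.zeros(img.shape, dtype=np.intp)
    else:
        levels = np.floor(n_levels * (img - lo) / (hi - lo)).astype(np.intp)
        np.clip(levels, 0, n_levels - 1, out=levels)
    return QuantizedImage(levels, n_levels, lo, hi)


def glcm(img: QuantizedImage, distance: int = DEFAULT_DISTANCE,
         psi: int = 0) -> GLCMatrix:
    """Symmetric normalized co-occurrence matrix at offset (d, psi).

    Each ordered pixel pair separated by the offset is counted in both
    directions, and the counts are divided by their total, so P sums to 1
    and P(i, j) = P(j, i).
    """
    if distance < 1:
        raise ValueError("pixel distance must be >= 1")
    if psi not in _OFFSETS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}, got {psi}")
    dr, dc = _OFFSETS[psi](distance)
    lv = img.levels
    rows, cols = lv.shape
    r0, r1 = max(0, -dr), min(rows, rows - dr)
    c0, c1 = max(0, -dc), min(cols, cols - dc)
    if r0 >= r1 or c0 >= c1:
        raise ValueError(
            f"image of shape {lv.shape} too small for offset ({dr}, {dc})")
    a = lv[r0:r1, c0:c1].ravel()
    b = lv[r0 + dr:r1 + dr, c0 + dc:c1 + dc].ravel()
    G = img.n_levels
    counts = np.bincount(a * G + b, minlength=G * G).reshape(G, G)
    counts = counts + counts.T  # symmetric counting
    P = counts / counts.sum()
    return GLCMatrix(P, distance, psi, (dr, dc))


def haralick_features(glc: GLCMatrix, classic_inertia: bool = False,
                      classic_marginal_sd: bool = False
                      ) -> tuple[float, float, float, float]:
    """(energy, inertia, correlation, entropy) of one co-occurrence matrix.

    ``classic_inertia`` switches the inertia sum from (i-j)^2 P^2 to the
    classical Haralick contrast (i-j)^2 P. ``classic_marginal_sd`` computes
    d2 about the column-marginal mean u2 instead of u1; with symmetric
    counting the marginals coincide, so the flag only matters for an
    asymmetric P supplied directly. Correlation of a single-level image
    (d1*d2 = 0) is defined as 0 with a warning.
    """
    P = glc.P
    G = P.shape[0]
    i = np.arange(G, dtype=np.float64)
    pi = P.sum(axis=1)  # row marginal
    pj = P.sum(axis=0)  # column marginal
    u1 = float(i @ pi)
    u2 = float(i @ pj)
    d1 = float(np.sqrt(((i - u1) ** 2) @ pi))
    center2 = u2 if classic_marginal_sd else u1
    d2 = float(np.sqrt(((i - center2) ** 2) @ pj))

    energy = float((P ** 2).sum())
    diff2 = (i[:, None] - i[None, :]) ** 2
    inertia = float((diff2 * (P if classic_inertia else P ** 2)).sum())
    if d1 * d2 > 0:
        correlation = float((i[:, None] * i[None, :] * P).sum() - u1 * u2) / (d1 * d2)
    else:
        warnings.warn("degenerate (single-level) image: correlation set to 0",
                      stacklevel=2)
        correlation = 0.0
    nz = P[P > 0]
    entropy = float(-(nz * np.log10(nz)).sum())
    return energy, inertia, correlation, entropy


def feature_vector(spec: Spectrogram, distance: int = DEFAULT_DISTANCE,
                   n_levels: int = DEFAULT_GRAY_LEVELS,
                   classic_inertia: bool = False) -> TextureFeatures:
    """16-attribute texture vector of one cycle's spectrogram.

    Quantizes the dB image, builds the four orientation GLCMs at the shared
    distance, and lays the measures out per :data:`FEATURE_NAMES`.
    """
    q = quantize(spec.db_image, n_levels)
    per_psi = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate-image correlation
        for psi in ORIENTATIONS:
            per_psi[psi] = haralick_features(
                glcm(q, distance, psi), classic_inertia=classic_inertia)
    values = np.array([per_psi[psi][mi]
                       for mi, _ in enumerate(MEASURES)
                       for psi in ORIENTATIONS])
    return TextureFeatures(values)
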