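"""Textural features 22-130: entropy, GLCM, Fourier, wavelet and Gabor.

All texture statistics are computed on the contrast-enhanced grayscale
image restricted to the tissue bounding box (co-occurrence statistics on a
binary mask are degenerate, so the gray image is the meaningful substrate).
The 109-entry block is laid out as::

    [entropy(1) | GLCM(12) | Fourier(6) | wavelet(60) | Gabor(30)]

* GLCM: symmetric, averaged over the four standard offsets (0, 45, 90,
  135 degrees), 32 gray levels, distances {2, 4, 8}; contrast, correlation,
  energy and homogeneity per distance (distance-major).
* Fourier: statistics of the 2-D DFT magnitude spectrum with the DC term
  excluded (otherwise the spectral mean is just a brightness proxy).
* Wavelet: 3-level Daubechies-4 decomposition in the orthogonal
  (periodization) form — the unique depth that yields ten sub-images with
  one retained approximation, and the form in which sub-band energies sum
  to the image energy.  Detail bands level-major, approximation last.
* Gabor: five scales on a geometric frequency ladder f0 / 2^k, four
  orientations averaged per scale (the feature list indexes scale only),
  statistics of the complex response magnitude.

Each coefficient collection is summarized by the same six statistics
("StatSextet"): energy, entropy, mean, standard deviation, and the
standardized third and fourth moments (skewness and Pearson kurtosis; both
0 for zero-variance collections).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from skimage.feature import graycomatrix
from skimage.filters import gabor_kernel

from .preprocess import ProcessedImage

__all__ = [
    "StatSextet",
    "TextureConfig",
    "TEXTURE_FEATURE_NAMES",
    "image_entropy",
    "glcm_features",
    "fourier_features",
    "wavelet_features",
    "gabor_features",
    "texture_feature_vector",
    "combine_features",
    "stat_sextet",
]

GLCM_DISTANCES = (2, 4, 8)
GLCM_ANGLES = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)


@dataclass(frozen=True)
class TextureConfig:
    n_bins: int = 256  # histogram bins for image entropy
    glcm_levels: int = 32
    glcm_distances: tuple[int, ...] = GLCM_DISTANCES
    wavelet: str = "db4"
    wavelet_levels: int = 3
    gabor_scales: int = 5
    gabor_f0: float = 0.25  # cycles/px, highest-frequency scale
    gabor_orientations: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    include_fourier_dc: bool = False


@dataclass(frozen=True)
class StatSextet:
    energy: float
    entropy: float
    mean: float
    std: float
    third_moment: float
    fourth_moment: float

    def as_array(self) -> np.ndarray:
        return np.array([self.energy, self.entropy, self.mean, self.std,
                         self.third_moment, self.fourth_moment])


def stat_sextet(values: np.ndarray, energy: str = "mean") -> StatSextet:
    """Six summary statistics of a coefficient collection.

    ``energy`` is the mean (default) or sum of squared values — sub-band
    decompositions use ``sum`` so that band energies are additive.  Entropy
    is the Shannon entropy (bits) of the L1-normalized magnitude
    distribution.  Third/fourth moments are standardized (skewness and
    Pearson kurtosis), 0 by convention when the variance is 0.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        return StatSextet(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    sq = v * v
    e = float(np.sum(sq)) if energy == "sum" else float(np.mean(sq))
    mag = np.abs(v)
    tot = mag.sum()
    if tot > 0:
        p = mag[mag > 0] / tot
        ent = float(-np.sum(p * np.log2(p)))
    else:
        ent = 0.0
    mu = float(np.mean(v))
    sd = float(np.std(v))
    if sd <= 1e-12 * max(1.0, abs(mu)):  # zero variance up to round-off
        sd = 0.0
    if sd > 0:
        z = (v - mu) / sd
        m3 = float(np.mean(z**3))
        m4 = float(np.mean(z**4))
    else:
        m3 = m4 = 0.0
    return StatSextet(e, ent, mu, sd, m3, m4)


# ---------------------------------------------------------------------------


def _tissue_crop(proc_or_img) -> np.ndarray:
    """Enhanced grayscale restricted to the tissue bounding box."""
    if isinstance(proc_or_img, ProcessedImage):
        img = proc_or_img.enhanced
        tis = proc_or_img.tissue_mask
        if tis.any():
            rows = np.nonzero(tis.any(axis=1))[0]
            cols = np.nonzero(tis.any(axis=0))[0]
            return img[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
        return img
    return np.asarray(proc_or_img, dtype=float)


def image_entropy(img: np.ndarray, n_bins: int = 256) -> float:
    """Shannon entropy (bits) of the gray-level histogram."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    x = np.asarray(img, dtype=float).ravel()
    if x.size == 0:
        warnings.warn("empty region: entropy 0")
        return 0.0
    hist, _ = np.histogram(x, bins=n_bins)
    p = hist[hist > 0] / x.size
    return float(-np.sum(p * np.log2(p)))


def _quantize(img: np.ndarray, levels: int) -> np.ndarray:
    x = np.asarray(img, dtype=float)
    lo, hi = x.min(), x.max()
    if hi <= lo:
        return np.zeros(x.shape, dtype=np.uint8)
    q = np.floor((x - lo) / (hi - lo) * levels).astype(int)
    return np.clip(q, 0, levels - 1).astype(np.uint8)


def _haralick(p: np.ndarray) -> tuple[float, float, float, float]:
    """Contrast, correlation, energy, homogeneity of one normalized GLCM.

    Correlation is 0 by convention when either marginal variance is 0
    (e.g. a constant image).
    """
    n = p.shape[0]
    i, j = np.mgrid[0:n, 0:n]
    contrast = float(np.sum(p * (i - j) ** 2))
    energy = float(np.sum(p * p))
    homogeneity = float(np.sum(p / (1.0 + np.abs(i - j))))
    pi = p.sum(axis=1)
    mu_i = float(np.sum(np.arange(n) * pi))
    var_i = float(np.sum((np.arange(n) - mu_i) ** 2 * pi))
    pj = p.sum(axis=0)
    mu_j = float(np.sum(np.arange(n) * pj))
    var_j = float(np.sum((np.arange(n) - mu_j) ** 2 * pj))
    if var_i > 0 and var_j > 0:
        corr = float(np.sum((i - mu_i) * (j - mu_j) * p)
                     / np.sqrt(var_i * var_j))
    else:
        corr = 0.0
    return contrast, corr, energy, homogeneity


def glcm_features(img: np.ndarray,
                  distances: tuple[int, ...] = GLCM_DISTANCES,
                  n_levels: int = 32) -> np.ndarray:
    """Haralick contrast/correlation/energy/homogeneity at each distance.

    The co-occurrence matrix is symmetric, averaged over the four standard
    orientations and normalized to sum 1; output is distance-major:
    ``[contrast, correlation, energy, homogeneity]`` per distance.
    """
    x = np.asarray(img, dtype=float)
    if min(x.shape) <= max(distances):
        raise ValueError(
            f"image of shape {x.shape} is too small for GLCM distance "
            f"{max(distances)}")
    q = _quantize(x, n_levels)
    glcm = graycomatrix(q, distances=list(distances), angles=list(GLCM_ANGLES),
                        levels=n_levels, symmetric=True, normed=False)
    out = []
    for di in range(len(distances)):
        # average counts over orientations, then normalize
        p = glcm[:, :, di, :].astype(float).mean(axis=2)
        s = p.sum()
        if s > 0:
            p = p / s
        out.extend(_haralick(p))
    return np.array(out)


def fourier_features(img: np.ndarray,
                     include_dc: bool = False) -> StatSextet:
    """StatSextet of the 2-D DFT magnitude spectrum.

    The DC term is excluded by default.  Energy is defined as
    ``sum(|F_k|^2) / N^2`` over the retained bins; by Parseval this equals
    the image's pixel variance when DC is excluded.
    """
    x = np.asarray(img, dtype=float)
    f = np.fft.fft2(x)
    mag = np.abs(f).ravel()
    if not include_dc:
        mag = np.delete(mag, 0)  # fft2 stores DC at the flat index 0
    n_pix = x.size
    s = stat_sextet(mag, energy="sum")
    return StatSextet(s.energy / (n_pix * n_pix), s.entropy, s.mean, s.std,
                      s.third_moment, s.fourth_moment)


def wavelet_features(img: np.ndarray, wavelet_name: str = "db4",
                     levels: int = 3) -> np.ndarray:
    """StatSextets of the 10 sub-images of a 3-level 2-D DWT (60 values).

    Ordering is level-major over the detail bands (LH, HL, HH at level 1,
    then level 2, then level 3) with the retained approximation (LL) last.
    The orthogonal (periodization) form is used so that sub-band energies
    sum to the total image energy.
    """
    x = np.asarray(img, dtype=float)
    min_len = 2**levels
    if min(x.shape) < min_len:
        raise ValueError(
            f"image of shape {x.shape} too small for a {levels}-level "
            f"decomposition (needs >= {min_len} px per side)")
    coeffs = pywt.wavedec2(x, wavelet_name, mode="periodization",
                           level=levels)
    # floor numerical noise so constant regions give exactly-zero bands
    # (otherwise the standardized moments of ~1e-13 round-off explode)
    tol = 1e-9 * max(1.0, float(np.abs(x).max()))
    coeffs = [np.where(np.abs(c) < tol, 0.0, c) if isinstance(c, np.ndarray)
              else tuple(np.where(np.abs(b) < tol, 0.0, b) for b in c)
              for c in coeffs]
    ll = coeffs[0]
    details = coeffs[1:]  # coarsest first: [(LH_L, HL_L, HH_L), ..., level 1]
    out = []
    for lvl in range(1, levels + 1):  # finest (level 1) first
        lh, hl, hh = details[levels - lvl]
        for band in (lh, hl, hh):
            out.extend(stat_sextet(band, energy="sum").as_array())
    out.extend(stat_sextet(ll, energy="sum").as_array())
    return np.array(out)


def _gabor_bank(n_scales: int, f0: float,
                orientations_deg: tuple[float, ...]):
    bank = []
    for k in range(n_scales):
        freq = f0 / 2**k
        kernels = [gabor_kernel(frequency=freq,
                                theta=np.deg2rad(th), bandwidth=1.0)
                   for th in orientations_deg]
        bank.append((freq, kernels))
    return bank


def _convolve_periodic(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Circular convolution with the kernel centered at the origin.

    Periodic boundaries keep a constant image's response exactly constant
    and make the features invariant to circular shifts; low-frequency
    Gabor kernels can be larger than the image, in which case the kernel
    is wrapped (aliased) onto the image grid.
    """
    h, w = x.shape
    kh, kw = kernel.shape
    K = np.zeros((h, w), dtype=kernel.dtype)
    rows = (np.arange(kh) - kh // 2) % h
    cols = (np.arange(kw) - kw // 2) % w
    np.add.at(K, (rows[:, None], cols[None, :]), kernel)
    return np.fft.ifft2(np.fft.fft2(x) * np.fft.fft2(K))


def gabor_features(img: np.ndarray, n_scales: int = 5, f0: float = 0.25,
                   orientations: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0),
                   ) -> np.ndarray:
    """StatSextets of the Gabor magnitude response at each scale (30
    values, scale-major, finest scale first).

    The filter bank is a geometric frequency ladder ``f0 / 2^k`` with a
    1-octave bandwidth; complex responses are computed per orientation
    (periodic boundaries), their magnitudes averaged across orientations
    (the feature list indexes scale only), then summarized.
    """
    if n_scales < 1:
        raise ValueError("n_scales must be >= 1")
    x = np.asarray(img, dtype=float)
    out = []
    for freq, kernels in _gabor_bank(n_scales, f0, orientations):
        mags = [np.abs(_convolve_periodic(x, k)) for k in kernels]
        mag = np.mean(mags, axis=0)
        out.extend(stat_sextet(mag, energy="mean").as_array())
    return np.array(out)


# ---------------------------------------------------------------------------


def _sextet_names(prefix: str) -> list[str]:
    return [f"{prefix}_{s}" for s in
            ("energy", "entropy", "mean", "std", "moment3", "moment4")]


def _texture_names() -> list[str]:
    names = ["entropy"]
    for d in GLCM_DISTANCES:
        names += [f"glcm_d{d}_{s}" for s in
                  ("contrast", "correlation", "energy", "homogeneity")]
    names += _sextet_names("fourier")
    for lvl in (1, 2, 3):
        for band in ("lh", "hl", "hh"):
            names += _sextet_names(f"wavelet_l{lvl}_{band}")
    names += _sextet_names("wavelet_ll3")
    for k in range(5):
        names += _sextet_names(f"gabor_s{k + 1}")
    return names


TEXTURE_FEATURE_NAMES = _texture_names()
assert len(TEXTURE_FEATURE_NAMES) == 109


def texture_feature_vector(proc_or_img,
                           cfg: TextureConfig | None = None) -> np.ndarray:
    """All 109 textural features in fixed order (TEXTURE_FEATURE_NAMES).

    Accepts a :class:`ProcessedImage` (statistics are computed on the
    enhanced grayscale cropped to the tissue bounding box) or a bare 2-D
    array.
    """
    cfg = cfg or TextureConfig()
    x = _tissue_crop(proc_or_img)
    parts = [
        np.array([image_entropy(x, cfg.n_bins)]),
        glcm_features(x, cfg.glcm_distances, cfg.glcm_levels),
        fourier_features(x, cfg.include_fourier_dc).as_array(),
        wavelet_features(x, cfg.wavelet, cfg.wavelet_levels),
        gabor_features(x, cfg.gabor_scales, cfg.gabor_f0,
                       cfg.gabor_orientations),
    ]
    out = np.concatenate(parts)
    if out.shape != (109,):
        raise RuntimeError(f"texture vector has {out.shape} entries")
    return out


def combine_features(morph: np.ndarray, texture: np.ndarray) -> np.ndarray:
    """Concatenate the 21 morphological and 109 textural features (130)."""
    morph = np.asarray(morph, dtype=float)
    texture = np.asarray(texture, dtype=float)
    if morph.shape != (21,):
        raise ValueError(f"expected 21 morphological features, "
                         f"got {morph.shape}")
    if texture.shape != (109,):
        raise ValueError(f"expected 109 textural features, "
                         f"got {texture.shape}")
    return np.concatenate([morph, texture])
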