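"""Per-pixel image feature bank shared by the segmentation and counting models.

Six Gaussian-derivative feature families are computed at a fixed set of
scales (sigma = 1.0, 1.6, 3.5 and 5.0 px by default): Gaussian smoothing,
Laplacian of Gaussian, Gaussian gradient magnitude, difference of Gaussians,
structure-tensor eigenvalues and Hessian eigenvalues.  With all families
enabled this yields 8 channels per scale (the two tensor families contribute
two eigenvalue channels each), i.e. 32 channels at the default four scales.

All filters use reflect boundary handling, so the stack is translation
equivariant away from the image border.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage as ndi

#: Canonical family order; channel layout follows this order within each scale.
FEATURE_FAMILIES: Tuple[str, ...] = (
    "gaussian_smoothing",
    "laplacian_of_gaussian",
    "gaussian_gradient_magnitude",
    "difference_of_gaussians",
    "structure_tensor_eigenvalues",
    "hessian_eigenvalues",
)

_EIGEN_FAMILIES = {"structure_tensor_eigenvalues", "hessian_eigenvalues"}


@dataclass(frozen=True)
class FeatureBankConfig:
    """Configuration of the Gaussian-derivative feature bank.

    Parameters
    ----------
    sigmas:
        Strictly increasing positive scales in pixels.
    families:
        Subset of :data:`FEATURE_FAMILIES`, kept in canonical order.
    dog_ratio:
        The difference of Gaussians at scale ``s`` uses the pair
        ``(s, dog_ratio * s)``.
    """

    sigmas: Tuple[float, ...] = (1.0, 1.6, 3.5, 5.0)
    families: Tuple[str, ...] = FEATURE_FAMILIES
    dog_ratio: float = 1.6

    def __post_init__(self) -> None:
        sigmas = tuple(float(s) for s in self.sigmas)
        if len(sigmas) == 0:
            raise ValueError("at least one sigma is required")
        if any(s <= 0 for s in sigmas):
            raise ValueError("sigmas must be positive")
        if any(b <= a for a, b in zip(sigmas, sigmas[1:])):
            raise ValueError("sigmas must be strictly increasing")
        unknown = set(self.families) - set(FEATURE_FAMILIES)
        if unknown:
            raise ValueError(f"unknown feature families: {sorted(unknown)}")
        object.__setattr__(self, "sigmas", sigmas)
        # keep canonical order regardless of user order
        object.__setattr__(
            self,
            "families",
            tuple(f for f in FEATURE_FAMILIES if f in set(self.families)),
        )

    @property
    def n_channels(self) -> int:
        per_scale = sum(2 if f in _EIGEN_FAMILIES else 1 for f in self.families)
        return per_scale * len(self.sigmas)

    def channel_names(self) -> Tuple[str, ...]:
        names = []
        for s in self.sigmas:
            for fam in self.families:
                if fam in _EIGEN_FAMILIES:
                    names.append(f"{fam}_ev0_s{s:g}")
                    names.append(f"{fam}_ev1_s{s:g}")
                else:
                    names.append(f"{fam}_s{s:g}")
        return tuple(names)


def _sym2x2_eigenvalues(a: np.ndarray, b: np.ndarray, c: np.ndarray):
    """Eigenvalues of the symmetric matrix [[a, b], [b, c]], sorted descending."""
    half_trace = 0.5 * (a + c)
    disc = np.sqrt(np.square(0.5 * (a - c)) + np.square(b))
    return half_trace + disc, half_trace - disc


def compute_features(image: np.ndarray, config: FeatureBankConfig | None = None) -> np.ndarray:
    """Compute the per-pixel feature stack.

    Parameters
    ----------
    image:
        2-D array with finite values.
    config:
        Feature bank configuration (defaults used when omitted).

    Returns
    -------
    ndarray of shape ``(H, W, n_channels)``, float32, channels grouped by
    scale then by family in canonical order.
    """
    if config is None:
        config = FeatureBankConfig()
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")

    mode = "reflect"
    chans = []
    for s in config.sigmas:
        smooth = ndi.gaussian_filter(img, s, mode=mode)
        for fam in config.families:
            if fam == "gaussian_smoothing":
                chans.append(smooth)
            elif fam == "laplacian_of_gaussian":
                chans.append(ndi.gaussian_laplace(img, s, mode=mode))
            elif fam == "gaussian_gradient_magnitude":
                chans.append(ndi.gaussian_gradient_magnitude(img, s, mode=mode))
            elif fam == "difference_of_gaussians":
                chans.append(smooth - ndi.gaussian_filter(img, config.dog_ratio * s, mode=mode))
            elif fam == "structure_tensor_eigenvalues":
                # inner (derivative) scale s/2, outer (integration) scale s
                gy = ndi.gaussian_filter(img, s / 2.0, order=(1, 0), mode=mode)
                gx = ndi.gaussian_filter(img, s / 2.0, order=(0, 1), mode=mode)
                axx = ndi.gaussian_filter(gx * gx, s, mode=mode)
                axy = ndi.gaussian_filter(gx * gy, s, mode=mode)
                ayy = ndi.gaussian_filter(gy * gy, s, mode=mode)
                hi, lo = _sym2x2_eigenvalues(axx, axy, ayy)
                chans.extend([hi, lo])
            elif fam == "hessian_eigenvalues":
                hyy = ndi.gaussian_filter(img, s, order=(2, 0), mode=mode)
                hxy = ndi.gaussian_filter(img, s, order=(1, 1), mode=mode)
                hxx = ndi.gaussian_filter(img, s, order=(0, 2), mode=mode)
                hi, lo = _sym2x2_eigenvalues(hxx, hxy, hyy)
                chans.extend([hi, lo])
    return np.stack(chans, axis=-1).astype(np.float32)
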