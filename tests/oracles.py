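"""Independent reference computations used to check the pipeline.

These deliberately avoid the package's rasterization, projection,
interpolation and crossing code: the sphere projection is analytic,
the width measurement is a direct dense-grid crossing search, and the
Student-t CDF for four degrees of freedom is the closed form

    F4(t) = 1/2 + (t^3 + 6 t) / (2 (t^2 + 4)^(3/2)).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.ndimage import gaussian_filter


def t_cdf_df4(t: float) -> float:
    """Closed-form CDF of Student's t with 4 degrees of freedom."""
    return 0.5 + (t**3 + 6.0 * t) / (2.0 * (t**2 + 4.0) ** 1.5)


def two_sided_p_df4(t: float) -> float:
    return 2.0 * (1.0 - t_cdf_df4(abs(t)))


def student_t_unpaired(a, b) -> tuple[float, float]:
    """Equal-variance two-sample t statistic and its df, from first principles."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    return t, na + nb - 2


def projected_sphere_image(radius_px: float, sigma_px: float, oversample: int = 10,
                           half_size_px: float | None = None) -> tuple[np.ndarray, float]:
    """Sum-projection of a uniform sphere on a fine 2D grid, optionally blurred.

    Returns (image, grid spacing in px).  The projection of a uniform
    unit-density sphere is the chord length 2*sqrt(r^2 - rho^2); blur
    along z commutes with the z-sum, so only the lateral PSF matters.
    """
    half = half_size_px if half_size_px is not None else radius_px * 2.5 + 4 * sigma_px + 2
    step = 1.0 / oversample
    coords = np.arange(-half, half + step / 2, step)
    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    rho2 = yy**2 + xx**2
    img = 2.0 * np.sqrt(np.maximum(radius_px**2 - rho2, 0.0))
    if sigma_px > 0:
        img = gaussian_filter(img, sigma_px * oversample, mode="constant")
    return img, step


def width_at_half_max_dense(values: np.ndarray, spacing: float) -> float:
    """Outermost half-maximum width of a dense 1D profile (baseline 0)."""
    level = 0.5 * values.max()
    above = values >= level
    idx = np.flatnonzero(above)
    j, k = idx[0], idx[-1]
    if j == 0 or k == values.size - 1:
        raise ValueError("level not crossed inside the profile")
    left = (j - 1) + (level - values[j - 1]) / (values[j] - values[j - 1])
    right = k + (level - values[k]) / (values[k + 1] - values[k])
    return (right - left) * spacing


def sphere_fwhm_oracle(radius_px: float, sigma_px: float, oversample: int = 10) -> float:
    """FWHM (px) of a blurred projected sphere, from the analytic projection."""
    img, step = projected_sphere_image(radius_px, sigma_px, oversample)
    centre_row = img[img.shape[0] // 2]
    return width_at_half_max_dense(centre_row, step)
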