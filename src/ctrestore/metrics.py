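"""Image-quality and contour-agreement metrics.

MAE, MSE, PSNR and SSIM quantify agreement between a test image and a
reference (the normal-dose scan in the study design); DSC and the 95th
percentile Hausdorff distance quantify agreement between binary contour
volumes; `effective_dose` is the scanner dose-length-product arithmetic;
`paired_t_report` is the classic equal-variance two-sample t test used in
the reporting tables.

Conventions (recorded in every report):

* PSNR = 10·log10(MAX²/MSE).  MAX is the reference-image maximum by
  default (``reference_max``) or the declared 2800 HU window
  (``fixed_range``).  A historical variant 20·log10(MAX/MSE) is exposed as
  ``as_printed`` for auditability only.
* SSIM is windowed by default (11×11 Gaussian weights, σ=1.5); ``global``
  mode evaluates the SSIM formula once from whole-image moments.  C1, C2
  default to (0.01·L)² and (0.03·L)² with L the dynamic range.
* HD95 pools directed surface distances both ways (symmetric); surfaces
  are face-connectivity boundary voxels, distances in mm via spacing.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .io import ContourMask

__all__ = ["mae", "mse", "psnr", "ssim", "dsc", "hd95", "relative_change",
           "effective_dose", "paired_t_report", "evaluate_volumes"]

FIXED_RANGE_HU = 2800.0


def _check_shapes(X, Y):
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Y.shape}")
    return X, Y


def mae(X, Y) -> float:
    """Mean absolute error (1/m)·Σ|Xᵢ−Yᵢ|."""
    X, Y = _check_shapes(X, Y)
    return float(np.abs(X - Y).mean())


def mse(X, Y) -> float:
    """Mean squared error (1/m)·Σ|Xᵢ−Yᵢ|²."""
    X, Y = _check_shapes(X, Y)
    return float(((X - Y) ** 2).mean())


def psnr(X, Y, max_convention: str = "reference_max",
         as_printed: bool = False) -> float:
    """Peak signal-to-noise ratio in dB; Y is the reference image.

    Returns +inf when the images are identical (MSE = 0).
    """
    X, Y = _check_shapes(X, Y)
    if max_convention == "reference_max":
        peak = float(np.max(Y))
    elif max_convention == "fixed_range":
        peak = FIXED_RANGE_HU
    else:
        raise ValueError(f"unknown MAX convention {max_convention!r}")
    err = mse(X, Y)
    if err == 0.0:
        return math.inf
    if as_printed:
        return 20.0 * math.log10(peak / err)
    return 10.0 * math.log10(peak ** 2 / err)


def _ssim_global(X, Y, C1, C2) -> float:
    mx, my = X.mean(), Y.mean()
    vx, vy = X.var(), Y.var()
    cov = ((X - mx) * (Y - my)).mean()
    return float(((2 * mx * my + C1) * (2 * cov + C2))
                 / ((mx ** 2 + my ** 2 + C1) * (vx + vy + C2)))


def ssim(X, Y, mode: str = "windowed", C1: float | None = None,
         C2: float | None = None, dynamic_range: float | None = None,
         sigma: float = 1.5, truncate: float = 3.5) -> float:
    """Structural similarity between X and the reference Y.

    ``windowed`` evaluates the SSIM formula per 11×11 Gaussian-weighted
    window (σ=1.5) and averages over the interior; ``global`` evaluates it
    once from whole-image moments.
    """
    X, Y = _check_shapes(X, Y)
    if dynamic_range is None:
        dynamic_range = float(Y.max() - Y.min())
        if dynamic_range == 0.0:
            dynamic_range = 1.0
    L = dynamic_range
    if C1 is None:
        C1 = (0.01 * L) ** 2
    if C2 is None:
        C2 = (0.03 * L) ** 2
    if mode == "global":
        return _ssim_global(X, Y, C1, C2)
    if mode != "windowed":
        raise ValueError(f"unknown SSIM mode {mode!r}")

    def filt(a):
        return ndimage.gaussian_filter(a, sigma, truncate=truncate)

    ux, uy = filt(X), filt(Y)
    vx = filt(X * X) - ux * ux
    vy = filt(Y * Y) - uy * uy
    cov = filt(X * Y) - ux * uy
    S = ((2 * ux * uy + C1) * (2 * cov + C2)) \
        / ((ux ** 2 + uy ** 2 + C1) * (vx + vy + C2))
    r = int(truncate * sigma + 0.5)   # window radius: 5 -> 11x11 support
    interior = S[tuple(slice(r, s - r) for s in S.shape)]
    return float(interior.mean()) if interior.size else float(S.mean())


# ------------------------------------------------------------------ contours
def _mask_voxels(m) -> np.ndarray:
    return m.voxels.astype(bool) if isinstance(m, ContourMask) \
        else np.asarray(m).astype(bool)


def dsc(A, B) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|); both empty → 1.0."""
    a, b = _mask_voxels(A), _mask_voxels(B)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def _surface_points(mask: np.ndarray, spacing) -> np.ndarray:
    """Physical coordinates (mm) of face-connectivity boundary voxels."""
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    eroded = ndimage.binary_erosion(mask, structure=structure,
                                    border_value=0)
    surface = mask & ~eroded
    idx = np.argwhere(surface)
    return idx * np.asarray(spacing, dtype=np.float64)


def hd95(A, B, spacing=None) -> float:
    """95th percentile of pooled directed surface-to-surface distances (mm)."""
    a, b = _mask_voxels(A), _mask_voxels(B)
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        which = "first" if not a.any() else "second"
        raise ValueError(f"hd95 undefined: {which} mask is empty")
    if spacing is None:
        sp_a = A.spacing if isinstance(A, ContourMask) else (1.0,) * a.ndim
        sp_b = B.spacing if isinstance(B, ContourMask) else sp_a
        if not np.allclose(sp_a, sp_b):
            raise ValueError(f"mask spacings differ: {sp_a} vs {sp_b}")
        spacing = sp_a
    pa = _surface_points(a, spacing)
    pb = _surface_points(b, spacing)
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))


# ---------------------------------------------------------------- summaries
def relative_change(before: float, after: float,
                    direction: str = "decrease") -> float:
    """Percent change relative to `before`; sign follows `direction`."""
    if before == 0:
        raise ValueError("relative change undefined for before == 0")
    if direction == "decrease":
        return (before - after) / before * 100.0
    if direction == "increase":
        return (after - before) / before * 100.0
    raise ValueError(f"unknown direction {direction!r}")


def effective_dose(dlp: float, weight_factor: float = 0.015) -> float:
    """Effective dose in mSv from a dose-length product in mGy·cm.

    The default 0.015 mSv/(mGy·cm) is the adult abdominal/pelvic tissue
    weighting factor (AAPM Report 96).
    """
    return dlp * weight_factor


def paired_t_report(values_a, values_b) -> dict:
    """Equal-variance two-sample t test (two-sided), with summary stats."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("need at least two values per sample")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    t = 0.0 if denom == 0.0 else float((a.mean() - b.mean()) / denom)
    df = na + nb - 2
    p = float(2.0 * stats.t.sf(abs(t), df))
    return {"t": t, "p": p, "df": df,
            "mean_a": float(a.mean()), "sd_a": float(a.std(ddof=1)),
            "mean_b": float(b.mean()), "sd_b": float(b.std(ddof=1))}


def evaluate_volumes(reference, test, label: str = "",
                     max_convention: str = "reference_max",
                     ssim_mode: str = "windowed") -> dict:
    """Per-slice and volume-mean MAE/MSE/PSNR/SSIM of `test` vs `reference`."""
    ref = np.asarray(reference.voxels if hasattr(reference, "voxels")
                     else reference, dtype=np.float64)
    tst = np.asarray(test.voxels if hasattr(test, "voxels") else test,
                     dtype=np.float64)
    if ref.shape != tst.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {tst.shape}")
    per_slice = []
    for k in range(ref.shape[0]):
        X, Y = tst[k], ref[k]
        per_slice.append({
            "slice": k,
            "mae": mae(X, Y), "mse": mse(X, Y),
            "psnr": psnr(X, Y, max_convention),
            "ssim": ssim(X, Y, mode=ssim_mode),
        })
    summary = {m: float(np.mean([s[m] for s in per_slice]))
               for m in ("mae", "mse", "psnr", "ssim")}
    return {"label": label, "parameters": {"max_convention": max_convention,
                                           "ssim_mode": ssim_mode},
            "per_slice": per_slice, "mean": summary}
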