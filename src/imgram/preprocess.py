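"""Optional image conditioning: grayscale conversion, Perona-Malik
anisotropic-diffusion denoising, white-border fill, and rotation placing
a region's longest (maximum Feret) diameter horizontal.

All steps are optional and coarse by design: the n-gram features are
robust to preprocessing quality, so only denoising-level conditioning is
offered (no histogram equalization or brightness correction).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

from .encode import validate_gray_image

# ITU-R BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Reduce a single- or 3-channel image to an integer gray image.

    3-channel inputs are combined with standard luminance weights and
    rounded; single-channel integer inputs pass through unchanged.
    """
    arr = np.asarray(image)
    if arr.ndim == 2:
        return validate_gray_image(arr)
    if arr.ndim == 3 and arr.shape[2] == 3:
        gray = np.rint(arr.astype(np.float64) @ _LUMA)
        return validate_gray_image(np.clip(gray, 0, 255).astype(np.uint8))
    raise ValueError(
        f"expected a 2-D or H x W x 3 image, got shape {arr.shape}"
    )


def anisotropic_diffusion(
    img: np.ndarray,
    iterations: int = 10,
    kappa: float = 30.0,
    dt: float = 0.2,
) -> np.ndarray:
    """Perona-Malik diffusion with exponential conductance.

    Smooths speckle while preserving edges: the conductance
    exp(-(grad/kappa)^2) shuts diffusion down across strong gradients.
    Borders are reflecting (Neumann), which conserves total intensity up
    to final rounding.  dt must lie in (0, 0.25] for stability of the
    4-neighbour explicit scheme; the output is re-clamped and rounded to
    [0, 255].
    """
    arr = validate_gray_image(img)
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if not 0 < dt <= 0.25:
        raise ValueError(f"dt must be in (0, 0.25], got {dt}")
    if kappa <= 0:
        raise ValueError(f"kappa must be > 0, got {kappa}")
    if iterations == 0:
        return arr.copy()

    u = arr.astype(np.float64)
    for _ in range(iterations):
        # neighbour minus centre with reflected (zero-flux) borders
        dn = np.vstack([u[:1], u[:-1]]) - u
        ds = np.vstack([u[1:], u[-1:]]) - u
        dw = np.hstack([u[:, :1], u[:, :-1]]) - u
        de = np.hstack([u[:, 1:], u[:, -1:]]) - u
        flux = sum(np.exp(-((d / kappa) ** 2)) * d for d in (dn, ds, dw, de))
        u += dt * flux
    return np.clip(np.rint(u), 0, 255).astype(arr.dtype)


def fill_white_border(img: np.ndarray, white_threshold: int = 250) -> np.ndarray:
    """Blacken bright regions connected to the image boundary.

    Every pixel >= ``white_threshold`` that reaches the boundary through
    a 4-connected path of equally bright pixels is set to 0; bright blobs
    strictly in the interior are left untouched.  This removes the
    irregular white frames left by scan-region cropping.
    """
    arr = validate_gray_image(img)
    if not 1 <= white_threshold <= 255:
        raise ValueError(f"white_threshold must be in [1, 255], got {white_threshold}")
    bright = arr >= white_threshold
    labels, _ = ndimage.label(bright)  # default structure = 4-connectivity
    edge_labels = np.unique(
        np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
    )
    edge_labels = edge_labels[edge_labels > 0]
    out = arr.copy()
    out[np.isin(labels, edge_labels)] = 0
    return out


def _feret_angle_deg(mask: np.ndarray) -> float:
    """Orientation (degrees, in array coordinates) of the farthest pair
    of region points — the maximum Feret diameter."""
    pts = np.argwhere(mask)  # (row, col)
    if len(pts) == 0:
        raise ValueError("mask is empty")
    if len(pts) == 1:
        return 0.0
    cand = pts.astype(float)
    if len(cand) > 3:
        try:
            cand = cand[ConvexHull(cand).vertices]
        except Exception:  # degenerate (collinear) masks
            pass
    d = pdist(cand)
    ii, jj = np.triu_indices(len(cand), k=1)
    k = int(np.argmax(d))
    i, j = int(ii[k]), int(jj[k])
    dr = cand[j, 0] - cand[i, 0]
    dc = cand[j, 1] - cand[i, 1]
    ang = np.degrees(np.arctan2(dr, dc))
    # fold into (-90, 90]: a diameter has no direction
    if ang > 90:
        ang -= 180
    elif ang <= -90:
        ang += 180
    return float(ang)


def rotate_longest_diameter_horizontal(
    img: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rotate image and mask so the mask's longest diameter is horizontal.

    The orientation of the maximum Feret diameter (farthest pair of mask
    points) is measured and both arrays are rotated by its negative,
    with zero fill outside and padding as needed; the image is
    interpolated bilinearly, the mask nearest-neighbour.  A mask that is
    already horizontal is returned unchanged.
    """
    arr = validate_gray_image(img)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != arr.shape:
        raise ValueError("mask shape must equal image shape")
    if not mask.any():
        raise ValueError("mask is empty")
    angle = _feret_angle_deg(mask)
    if abs(angle) < 1e-9:
        return arr.copy(), mask.copy()
    # ndimage.rotate(angle) turns array content by +angle degrees in the
    # (row, col) plane, bringing a diameter at `angle` (rows increasing
    # downward) to horizontal.  Pixel discretization of thin masks biases
    # both the measured orientation and the resampled result by a couple
    # of degrees, so the angle is refined by a small grid search that
    # minimizes the measured residual of the rotated mask, always
    # rotating from the original.
    offsets = np.concatenate([[0.0], np.repeat(np.arange(0.5, 4.01, 0.5), 2) * np.tile([1, -1], 8)])
    best_angle, best_resid = angle, np.inf
    for off in offsets:
        cand = angle + off
        mask_rot = ndimage.rotate(mask, cand, reshape=True, order=0, cval=False)
        resid = abs(_feret_angle_deg(mask_rot))
        if resid < best_resid:
            best_angle, best_resid = cand, resid
        if resid <= 0.5:
            break
    angle = best_angle
    img_rot = ndimage.rotate(arr.astype(np.float64), angle, reshape=True, order=1, cval=0.0)
    mask_rot = ndimage.rotate(mask, angle, reshape=True, order=0, cval=False)
    img_out = np.clip(np.rint(img_rot), 0, 255).astype(arr.dtype)
    return img_out, mask_rot.astype(bool)
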