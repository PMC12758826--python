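"""Quantification of reporter-positive cells and TUNEL apoptosis from
multi-channel fluorescence stacks.

The imaging convention is a channels x z x y x x stack with declared
channel roles (nuclear counterstain, GFP reporter, an empty red channel
capturing nonspecific staining, a far-red marker, TUNEL). Processing
follows the quantification pipeline used for reporter-cell counting:
maximum-intensity projection, subtraction of the background red channel
from the green channel (clamped at zero), thresholding and connected-
component cell counting.

For the death profile, nuclei are scored TUNEL-positive when they carry
at least ``puncta_threshold`` (default 3) puncta, and the positive
fraction is accumulated in 100-µm distance bins from the edge of the
GFP-positive cluster across a 900 x 300 µm field. A bounded
least-squares fit of an exponential distance-decay
``p(d) = p_far + (p_near - p_far) * exp(-d / l)`` summarizes the
profile.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage, optimize
from skimage import filters, measure

__all__ = [
    "save_stack",
    "load_stack",
    "CHANNEL_ROLES",
    "ImageStack",
    "CellDetection",
    "TunelBinProfile",
    "DecayFitResult",
    "max_projection",
    "subtract_background",
    "segment_cells",
    "count_puncta",
    "classify_tunel",
    "distance_profile",
    "fit_decay",
    "decay_curve",
    "nucleus_label_image",
]

#: Recognized channel roles.
CHANNEL_ROLES = ("nuclei_405", "gfp_488", "background_red", "farred_647", "tunel")


@dataclass
class ImageStack:
    """Multi-channel 3-D stack: ``voxels[channel, z, y, x]``."""

    voxels: np.ndarray
    channel_roles: dict[str, int]
    pixel_size_um: float
    z_step_um: float = 1.0

    def __post_init__(self) -> None:
        if self.voxels.ndim != 4:
            raise ValueError(f"voxels must be (channels, z, y, x), got ndim={self.voxels.ndim}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        n_chan = self.voxels.shape[0]
        for role, idx in self.channel_roles.items():
            if not 0 <= idx < n_chan:
                raise ValueError(f"channel role {role!r} maps to index {idx} outside 0..{n_chan-1}")

    def channel(self, role: str) -> np.ndarray:
        if role not in self.channel_roles:
            raise KeyError(f"stack has no channel with role {role!r}; has {sorted(self.channel_roles)}")
        return self.voxels[self.channel_roles[role]]


def save_stack(stack: ImageStack, path) -> None:
    """Write a multi-channel stack as TIFF; channel roles and voxel
    sizes go into the image description as JSON."""
    meta = {
        "channel_roles": stack.channel_roles,
        "pixel_size_um": stack.pixel_size_um,
        "z_step_um": stack.z_step_um,
        "axes": "CZYX",
    }
    tifffile.imwrite(
        path,
        stack.voxels.astype(np.float32),
        photometric="minisblack",
        planarconfig="contig",
        description=json.dumps(meta),
    )


def load_stack(path) -> ImageStack:
    """Read a stack written by :func:`save_stack`."""
    with tifffile.TiffFile(path) as tif:
        voxels = tif.asarray()
        desc = tif.pages[0].description
    try:
        meta = json.loads(desc)
    except (TypeError, json.JSONDecodeError) as exc:
        raise ValueError(f"{path}: missing or malformed stack metadata") from exc
    voxels = voxels.reshape((-1,) + voxels.shape[-3:])
    return ImageStack(
        voxels=voxels,
        channel_roles={k: int(v) for k, v in meta["channel_roles"].items()},
        pixel_size_um=float(meta["pixel_size_um"]),
        z_step_um=float(meta.get("z_step_um", 1.0)),
    )


def max_projection(stack: ImageStack, role: str) -> np.ndarray:
    """Maximum-intensity projection over z for the given channel role."""
    return stack.channel(role).max(axis=0)


def subtract_background(green: np.ndarray, red: np.ndarray) -> np.ndarray:
    """Pixelwise ``green - red`` clamped at zero.

    The red channel is imaged empty and captures nonspecific staining;
    subtracting it removes autofluorescence from the reporter channel.
    """
    green = np.asarray(green)
    red = np.asarray(red)
    if green.shape != red.shape:
        raise ValueError(f"shape mismatch: green {green.shape} vs red {red.shape}")
    out = green.astype(float) - red.astype(float)
    np.maximum(out, 0, out=out)
    return out.astype(green.dtype) if np.issubdtype(green.dtype, np.floating) else out


@dataclass(frozen=True)
class CellDetection:
    centroid_xy_um: tuple[float, float]
    area_um2: float
    mean_intensity: float
    channel_role: str = "gfp_488"


def _threshold_value(img: np.ndarray, method: str) -> float:
    if method == "otsu":
        if img.max() == img.min():
            return float(img.max())  # flat image: nothing above threshold
        return float(filters.threshold_otsu(img))
    if method.startswith("fixed:"):
        return float(method.split(":", 1)[1])
    if method.startswith("percentile:"):
        return float(np.percentile(img, float(method.split(":", 1)[1])))
    raise ValueError(f"unknown threshold method {method!r}")


def segment_cells(
    img: np.ndarray,
    pixel_size_um: float,
    method: str = "otsu",
    min_area_um2: float = 10.0,
    max_area_um2: float = 500.0,
    channel_role: str = "gfp_488",
) -> list[CellDetection]:
    """Threshold + 8-connected components + area filter -> detections.

    ``method`` is ``"otsu"``, ``"fixed:<value>"`` or ``"percentile:<q>"``.
    Centroids are reported in µm as (x, y).
    """
    if min_area_um2 >= max_area_um2:
        raise ValueError("min_area_um2 must be < max_area_um2")
    img = np.asarray(img, dtype=float)
    if img.min() < 0:
        raise ValueError("image must be nonnegative")
    thr = _threshold_value(img, method)
    mask = img > thr
    labels = measure.label(mask, connectivity=2)
    px_area = pixel_size_um**2
    detections = []
    for region in measure.regionprops(labels, intensity_image=img):
        area = region.area * px_area
        if not (min_area_um2 <= area <= max_area_um2):
            continue
        cy, cx = region.centroid
        detections.append(
            CellDetection(
                centroid_xy_um=(cx * pixel_size_um, cy * pixel_size_um),
                area_um2=float(area),
                mean_intensity=float(region.intensity_mean),
                channel_role=channel_role,
            )
        )
    return detections


def nucleus_label_image(
    centers_xy_um: Sequence[tuple[float, float]],
    shape_yx: tuple[int, int],
    radius_um: float,
    pixel_size_um: float,
) -> np.ndarray:
    """Disk label image from nucleus centers (label i+1 for nucleus i).

    Convenience for building disjoint nucleus masks from known or
    segmented centroids; centers must be separated by more than
    2*radius for the masks to be disjoint.
    """
    labels = np.zeros(shape_yx, dtype=np.int32)
    r_px = radius_um / pixel_size_um
    half = int(np.ceil(r_px))
    for i, (x_um, y_um) in enumerate(centers_xy_um):
        cx, cy = x_um / pixel_size_um, y_um / pixel_size_um
        y0, y1 = max(int(cy) - half, 0), min(int(cy) + half + 1, shape_yx[0])
        x0, x1 = max(int(cx) - half, 0), min(int(cx) + half + 1, shape_yx[1])
        yy, xx = np.mgrid[y0:y1, x0:x1]
        sel = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
        window = labels[y0:y1, x0:x1]
        if (window[sel] != 0).any():
            raise ValueError(f"nucleus {i} mask overlaps a previous nucleus")
        window[sel] = i + 1
    return labels


def _disk_footprint(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (yy**2 + xx**2) <= radius**2


def _ball_footprint(radius: int, z_radius: int = 1) -> np.ndarray:
    zz, yy, xx = np.mgrid[-z_radius : z_radius + 1, -radius : radius + 1, -radius : radius + 1]
    return (yy**2 + xx**2) <= radius**2


def count_puncta(
    tunel_img: np.ndarray,
    nucleus_labels: np.ndarray,
    intensity_threshold: float | None = None,
    merge_radius_px: int = 3,
) -> dict[int, int]:
    """Per-nucleus TUNEL puncta counts.

    Puncta are strict local maxima of the TUNEL image above an intensity
    threshold (Otsu by default) within each labelled nucleus; maxima
    closer than ``merge_radius_px`` (Euclidean) are merged into one.
    Accepts a 2-D projection with 2-D labels, or a raw 3-D stack with
    2-D labels (applied to every plane) or 3-D labels.
    """
    img = np.asarray(tunel_img, dtype=float)
    labels = np.asarray(nucleus_labels)
    if img.ndim == 3 and labels.ndim == 2:
        labels = np.broadcast_to(labels, img.shape).copy()
    if img.shape != labels.shape:
        raise ValueError(f"image shape {img.shape} does not match labels {labels.shape}")
    ids = [int(i) for i in np.unique(labels) if i != 0]
    if not ids:
        return {}
    if intensity_threshold is None:
        if img.max() == img.min():
            return {i: 0 for i in ids}
        intensity_threshold = float(filters.threshold_otsu(img))
    footprint = _disk_footprint(merge_radius_px) if img.ndim == 2 else _ball_footprint(merge_radius_px)
    pad = merge_radius_px
    counts = {}
    slices = ndimage.find_objects(labels)
    for nid in ids:
        sl = slices[nid - 1]
        if sl is None:
            counts[nid] = 0
            continue
        # expand the bounding box so the merge footprint sees the full mask
        sl = tuple(
            slice(max(s.start - pad, 0), min(s.stop + pad, dim))
            for s, dim in zip(sl, img.shape)
        )
        masked = np.where(labels[sl] == nid, img[sl], -np.inf)
        local_max = masked == ndimage.maximum_filter(
            masked, footprint=footprint, mode="constant", cval=-np.inf
        )
        peaks = local_max & (masked > intensity_threshold)
        # a plateau of equal maxima within one punctum counts once
        _, n_peaks = ndimage.label(peaks, structure=np.ones((3,) * img.ndim, dtype=bool))
        counts[nid] = int(n_peaks)
    return counts


def classify_tunel(counts: Mapping[int, int] | Sequence[int], threshold: int = 3):
    """TUNEL-positive iff puncta count >= threshold (default 3)."""
    if isinstance(counts, Mapping):
        return {k: v >= threshold for k, v in counts.items()}
    return [c >= threshold for c in counts]


@dataclass
class TunelBinProfile:
    """Distance-binned death profile from the GFP cluster edge.

    ``fraction`` is n_positive/n_nuclei per half-open bin
    [k*width, (k+1)*width); NaN where a bin holds no nuclei (also
    listed in ``empty_bins``). Nuclei at negative distance (inside the
    cluster) are assigned to bin 0 and counted in ``n_inside_cluster``.
    """

    bin_edges_um: np.ndarray
    n_nuclei: np.ndarray
    n_positive: np.ndarray
    fraction: np.ndarray
    n_inside_cluster: int = 0
    empty_bins: list[int] = field(default_factory=list)
    mean_distance_um: np.ndarray | None = None

    @property
    def bin_centers_um(self) -> np.ndarray:
        return (self.bin_edges_um[:-1] + self.bin_edges_um[1:]) / 2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start_um": self.bin_edges_um[:-1],
                "bin_end_um": self.bin_edges_um[1:],
                "n_nuclei": self.n_nuclei,
                "n_tunel_positive": self.n_positive,
                "fraction": self.fraction,
            }
        )


def distance_profile(
    nuclei: pd.DataFrame,
    cluster_edge_x_um: float,
    bin_width_um: float = 100.0,
    extent_um: float = 900.0,
    mode: str = "axial",
    cluster_center_xy_um: tuple[float, float] | None = None,
) -> TunelBinProfile:
    """Bin nuclei by distance from the cluster edge and compute the
    TUNEL-positive fraction per bin.

    ``nuclei`` needs columns ``x_um``, ``y_um`` (only x is used in the
    default axial mode) and ``tunel_positive``. Axial distance is
    ``x - cluster_edge_x_um`` along the long axis of the field;
    ``mode="euclidean"`` instead measures from ``cluster_center_xy_um``
    minus the edge radius. Nuclei at or beyond ``extent_um`` are
    excluded; negative distances map to bin 0.
    """
    required = {"x_um", "tunel_positive"}
    if not required <= set(nuclei.columns):
        raise ValueError(f"nuclei table needs columns {sorted(required)}")
    if mode == "axial":
        d = nuclei["x_um"].to_numpy(dtype=float) - cluster_edge_x_um
    elif mode == "euclidean":
        if cluster_center_xy_um is None:
            raise ValueError("euclidean mode needs cluster_center_xy_um")
        cx, cy = cluster_center_xy_um
        radial = np.hypot(nuclei["x_um"] - cx, nuclei["y_um"] - cy)
        d = radial.to_numpy(dtype=float) - cluster_edge_x_um
    else:
        raise ValueError(f"unknown mode {mode!r}")
    positive = nuclei["tunel_positive"].to_numpy(dtype=bool)
    n_bins = int(round(extent_um / bin_width_um))
    edges = np.arange(n_bins + 1, dtype=float) * bin_width_um
    in_field = d < extent_um
    d_in = d[in_field]
    pos_in = positive[in_field]
    n_inside = int((d_in < 0).sum())
    bin_idx = np.clip(np.floor(d_in / bin_width_um).astype(int), 0, n_bins - 1)
    n_nuclei = np.bincount(bin_idx, minlength=n_bins)
    n_positive = np.bincount(bin_idx, weights=pos_in.astype(float), minlength=n_bins).astype(int)
    with np.errstate(invalid="ignore", divide="ignore"):
        fraction = np.where(n_nuclei > 0, n_positive / np.maximum(n_nuclei, 1), np.nan)
        # mean clamped distance per bin: nuclei inside the cluster sit at
        # the edge (d = 0), which matters for bin 0
        d_sum = np.bincount(bin_idx, weights=np.maximum(d_in, 0.0), minlength=n_bins)
        mean_d = np.where(n_nuclei > 0, d_sum / np.maximum(n_nuclei, 1), np.nan)
    empty = [int(i) for i in np.flatnonzero(n_nuclei == 0)]
    return TunelBinProfile(edges, n_nuclei, n_positive, fraction, n_inside, empty, mean_d)


def decay_curve(d, p_near: float, p_far: float, decay_length_um: float):
    """Exponential distance-decay ``p(d) = p_far + (p_near - p_far) * exp(-d/l)``."""
    d = np.asarray(d, dtype=float)
    return p_far + (p_near - p_far) * np.exp(-d / decay_length_um)


@dataclass(frozen=True)
class DecayFitResult:
    p_near: float
    p_far: float
    decay_length_um: float
    rss: float
    n_bins: int
    success: bool
    fitted_drop: float = float("nan")

    @property
    def amplitude(self) -> float:
        """Asymptotic drop ``p_near - p_far``.

        For profiles with no real distance dependence the decay length
        is unidentifiable and this parameter difference can wander
        along a likelihood ridge; ``fitted_drop`` (the drop of the
        fitted curve across the observed distance range) is the
        identifiable amplitude measure.
        """
        return self.p_near - self.p_far


def fit_decay(profile: TunelBinProfile, method: str = "mle") -> DecayFitResult:
    """Fit the exponential decay to the per-bin TUNEL fractions.

    ``method="mle"`` (default) maximizes the binomial likelihood of the
    per-bin positive counts — the efficient estimator for binned
    Bernoulli outcomes; ``method="wls"`` minimizes squared residuals of
    the bin fractions weighted by n_nuclei. In both cases the model is
    evaluated at each bin's mean clamped distance (falling back to bin
    centers), which keeps bin 0 unbiased when it holds inside-cluster
    nuclei at distance zero. Probabilities are bounded to [0, 1] and
    the decay length to be positive. Needs >= 4 nonempty bins.
    """
    if method not in ("mle", "wls"):
        raise ValueError("method must be 'mle' or 'wls'")
    mask = profile.n_nuclei > 0
    if int(mask.sum()) < 4:
        raise ValueError(f"need >= 4 nonempty bins to fit a decay, got {int(mask.sum())}")
    if profile.mean_distance_um is not None and not np.any(np.isnan(profile.mean_distance_um[mask])):
        d = profile.mean_distance_um[mask]
    else:
        d = profile.bin_centers_um[mask]
    frac = profile.fraction[mask]
    n = profile.n_nuclei[mask].astype(float)
    k = profile.n_positive[mask].astype(float)

    p_near0 = float(np.clip(frac[0], 1e-3, 1 - 1e-3))
    p_far0 = float(np.clip(frac[-1], 1e-3, 1 - 1e-3))
    l0 = max(float(d[-1] - d[0]) / 3.0, 1.0)
    inits = [(p_near0, p_far0, li) for li in (l0, l0 / 4, l0 * 4)]

    if method == "wls":
        w = np.sqrt(n)

        def residuals(theta):
            return w * (decay_curve(d, *theta) - frac)

        best = None
        for x0 in inits:
            sol = optimize.least_squares(
                residuals,
                x0=x0,
                bounds=([0.0, 0.0, 1e-6], [1.0, 1.0, np.inf]),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
            if best is None or sol.cost < best.cost:
                best = sol
        p_near, p_far, length = (float(v) for v in best.x)
        success = bool(best.success)
    else:
        eps = 1e-9

        def nll(theta):
            p = np.clip(decay_curve(d, *theta), eps, 1 - eps)
            return -(k * np.log(p) + (n - k) * np.log(1 - p)).sum()

        best = None
        for x0 in inits:
            sol = optimize.minimize(
                nll,
                x0=x0,
                method="L-BFGS-B",
                bounds=[(eps, 1 - eps), (eps, 1 - eps), (1e-3, 1e7)],
                options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 1000},
            )
            if best is None or sol.fun < best.fun:
                best = sol
        p_near, p_far, length = (float(v) for v in best.x)
        success = bool(best.success)

    fitted = decay_curve(d, p_near, p_far, length)
    rss = float((n * (fitted - frac) ** 2).sum())
    drop = float(fitted[0] - fitted[-1])
    return DecayFitResult(p_near, p_far, length, rss, int(mask.sum()), success, drop)
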