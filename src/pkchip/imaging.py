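"""Spheroid image quantification and the synthetic image generator.

The measurement chain mirrors a standard ImageJ-style spheroid workflow:
segment the projected spheroid in brightfield, take min/max Feret (caliper)
diameters of the mask, convert their mean to an average radius and a sphere
volume, then detect nuclei in the Hoechst channel and score per-marker
positive cells.  DNA-damage (γH2AX) and apoptosis (CC3) positives are
normalized by spheroid projection area (per 10⁴ µm²); the proliferation
marker Ki67 is reported as a fraction of nuclei and needs no area
normalization.

The generator draws a roughly circular spheroid (250–370 µm diameters are
typical at treatment start) with Poisson-disc-packed nuclei rendered as
Gaussian spots, lights a seeded subset of nuclei in each marker channel, and
records full ground truth, so every operator in the chain can be scored
against known answers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile
from scipy import ndimage
from scipy.spatial import ConvexHull
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label
from skimage.morphology import disk

__all__ = [
    "CHANNELS",
    "MARKERS",
    "SpheroidImage",
    "SpheroidMeasurement",
    "BiomarkerCounts",
    "generate_synthetic_spheroid",
    "segment_spheroid",
    "feret_diameters",
    "spheroid_volume",
    "measure_spheroid",
    "detect_nuclei",
    "count_positive",
    "quantify_spheroid",
]

CHANNELS = ("brightfield", "nuclei", "gammaH2AX", "CC3", "Ki67")
MARKERS = ("gammaH2AX", "CC3", "Ki67")
#: markers reported as positives per 10⁴ µm² of spheroid area
AREA_NORMALIZED_MARKERS = ("gammaH2AX", "CC3")
DENSITY_UNIT_UM2 = 1e4


@dataclass
class SpheroidImage:
    """Multichannel 2-D raster of one spheroid (+ optional ground truth)."""

    channels: dict[str, np.ndarray]
    pixel_size: float  # µm/pixel
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("all channels must share one shape")
        for name, ch in self.channels.items():
            if np.any(ch < 0):
                raise ValueError(f"channel {name!r} has negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def save(self, path: str | Path) -> None:
        """Write a multichannel TIFF plus a JSON sidecar with metadata."""
        path = Path(path)
        names = list(self.channels)
        stack = np.stack([self.channels[n].astype(np.float32) for n in names])
        tifffile.imwrite(path, stack)
        meta = {"channels": names, "pixel_size": self.pixel_size}
        if self.ground_truth is not None:
            gt = dict(self.ground_truth)
            gt["centroids"] = np.asarray(gt["centroids"]).tolist()
            gt["positives"] = {m: np.asarray(v).astype(int).tolist() for m, v in gt["positives"].items()}
            gt.pop("mask", None)  # recomputable; keep the sidecar textual and small
            meta["ground_truth"] = gt
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SpheroidImage":
        path = Path(path)
        stack = tifffile.imread(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        channels = {n: stack[i] for i, n in enumerate(meta["channels"])}
        gt = meta.get("ground_truth")
        if gt is not None:
            gt["centroids"] = np.asarray(gt["centroids"], dtype=float)
            gt["positives"] = {
                m: np.asarray(v, dtype=bool) for m, v in gt["positives"].items()
            }
        return cls(channels=channels, pixel_size=meta["pixel_size"], ground_truth=gt)


@dataclass
class SpheroidMeasurement:
    """Size summary of one spheroid projection.

    ``average_radius = (feret_min + feret_max) / 4`` (mean of the two caliper
    diameters, halved) and ``volume = 4/3·π·average_radius³`` by
    construction.
    """

    area: float  # µm²
    feret_min: float  # µm
    feret_max: float  # µm

    def __post_init__(self) -> None:
        if not 0 < self.feret_min <= self.feret_max:
            raise ValueError("need 0 < feret_min <= feret_max")
        if self.area <= 0:
            raise ValueError("area must be > 0")

    @property
    def average_radius(self) -> float:
        return (self.feret_min + self.feret_max) / 4.0

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.average_radius**3


@dataclass
class BiomarkerCounts:
    """Nuclei and marker-positive counts for one spheroid."""

    n_nuclei: int
    positives: dict[str, int]
    spheroid_area: float  # µm²

    def __post_init__(self) -> None:
        for m, p in self.positives.items():
            if not 0 <= p <= max(self.n_nuclei, 0):
                raise ValueError(f"{m}: positives must lie in [0, n_nuclei]")

    def density(self, marker: str) -> float:
        """Positive cells per 10⁴ µm² of spheroid projection area."""
        return self.positives[marker] / self.spheroid_area * DENSITY_UNIT_UM2

    @property
    def ki67_fraction(self) -> float:
        if self.n_nuclei == 0:
            return 0.0
        return self.positives.get("Ki67", 0) / self.n_nuclei


def _poisson_disc(
    rng: np.random.Generator,
    mask: np.ndarray,
    n_points: int,
    min_spacing_px: float,
    max_attempts_per_point: int = 400,
) -> np.ndarray:
    """Seeded dart-throwing Poisson-disc sample of ``n_points`` inside mask."""
    area_px = int(mask.sum())
    # a dart-throwing packing saturates well below the hexagonal bound
    capacity = 0.55 * area_px / (math.pi * (min_spacing_px / 2.0) ** 2)
    if n_points > capacity:
        raise ValueError(
            f"{n_points} nuclei infeasible for this area at spacing "
            f"{min_spacing_px:.1f} px (capacity ~{int(capacity)})"
        )
    rows, cols = np.nonzero(mask)
    accepted = np.empty((n_points, 2))
    count = 0
    attempts = 0
    budget = max_attempts_per_point * n_points
    min_sq = min_spacing_px**2
    while count < n_points:
        if attempts >= budget:
            raise ValueError("Poisson-disc sampling failed to place all nuclei")
        attempts += 1
        j = rng.integers(rows.size)
        p = np.array([rows[j], cols[j]]) + rng.random(2) - 0.5
        if count and np.min(np.sum((accepted[:count] - p) ** 2, axis=1)) < min_sq:
            continue
        accepted[count] = p
        count += 1
    return accepted


def _render_spots(
    shape: tuple[int, int],
    centers: np.ndarray,
    sigma_px: float,
    amplitude: float,
) -> np.ndarray:
    out = np.zeros(shape, dtype=float)
    half = max(int(math.ceil(3 * sigma_px)), 1)
    win = np.arange(-half, half + 1)
    gy = np.exp(-(win**2) / (2 * sigma_px**2))
    stamp = amplitude * np.outer(gy, gy)
    for r, c in centers:
        ri, ci = int(round(r)), int(round(c))
        r0, r1 = max(ri - half, 0), min(ri + half + 1, shape[0])
        c0, c1 = max(ci - half, 0), min(ci + half + 1, shape[1])
        out[r0:r1, c0:c1] += stamp[
            r0 - (ri - half) : stamp.shape[0] - ((ri + half + 1) - r1),
            c0 - (ci - half) : stamp.shape[1] - ((ci + half + 1) - c1),
        ]
    return out


def generate_synthetic_spheroid(
    radius_um: float = 150.0,
    pixel_size: float = 1.0,
    n_cells: int = 300,
    positive_fractions: Mapping[str, float] | None = None,
    noise_sd: float = 2.0,
    seed: int = 0,
    aspect_ratio: float = 1.0,
    rotation_deg: float = 0.0,
    margin_um: float = 40.0,
    nucleus_radius_um: float = 4.0,
) -> SpheroidImage:
    """Generate a synthetic spheroid image with full ground truth.

    The spheroid is a disc (or rotated ellipse when ``aspect_ratio`` > 1,
    semi-axes ``radius_um`` and ``radius_um / aspect_ratio``) of packed
    nuclei.  ``positive_fractions`` maps marker name to the fraction of
    nuclei lit in that channel (exactly ``round(fraction * n_cells)`` nuclei,
    chosen by the seeded generator).  Ground truth records the mask, nuclei
    centroids (row, col pixels), per-marker positive labels and the true
    radius.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be > 0")
    if positive_fractions is None:
        positive_fractions = {}
    for m, f in positive_fractions.items():
        if m not in MARKERS:
            raise ValueError(f"unknown marker {m!r}; valid: {MARKERS}")
        if not 0 <= f <= 1:
            raise ValueError(f"{m}: positive fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    half_px = int(math.ceil((radius_um + margin_um) / pixel_size))
    n_px = 2 * half_px + 1
    yy, xx = np.mgrid[:n_px, :n_px].astype(float)
    yc = xc = half_px
    theta = math.radians(rotation_deg)
    u = (yy - yc) * math.sin(theta) + (xx - xc) * math.cos(theta)
    v = (yy - yc) * math.cos(theta) - (xx - xc) * math.sin(theta)
    a = radius_um / pixel_size
    b = a / aspect_ratio
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0

    r_nuc_px = nucleus_radius_um / pixel_size
    spacing_px = 2.5 * r_nuc_px
    # keep nucleus centres away from the rim so spots stay inside the mask
    inner = ndimage.binary_erosion(mask, disk(max(int(round(r_nuc_px)), 1)))
    centroids = _poisson_disc(rng, inner, n_cells, spacing_px)

    sigma_spot = r_nuc_px / 3.0
    amp = 150.0
    channels: dict[str, np.ndarray] = {}
    channels["nuclei"] = _render_spots(mask.shape, centroids, sigma_spot, amp)
    soft = gaussian(mask.astype(float), sigma=2.0)
    channels["brightfield"] = 200.0 - 120.0 * soft

    positives: dict[str, np.ndarray] = {}
    for marker in MARKERS:
        frac = float(positive_fractions.get(marker, 0.0))
        k = int(round(frac * n_cells))
        chosen = np.zeros(n_cells, dtype=bool)
        if k:
            chosen[rng.permutation(n_cells)[:k]] = True
        positives[marker] = chosen
        channels[marker] = _render_spots(
            mask.shape, centroids[chosen], sigma_spot, amp
        )

    for name in channels:
        noisy = channels[name] + rng.normal(0.0, noise_sd, size=mask.shape)
        channels[name] = np.clip(noisy, 0.0, None)

    gt = {
        "mask": mask,
        "centroids": centroids,
        "positives": positives,
        "radius_um": radius_um,
        "nucleus_radius_um": nucleus_radius_um,
    }
    return SpheroidImage(channels=channels, pixel_size=pixel_size, ground_truth=gt)


def segment_spheroid(channel: np.ndarray, smooth_sigma: float = 2.0) -> np.ndarray:
    """Segment the spheroid projection in a brightfield image.

    Otsu threshold on the smoothed channel, polarity resolved from the image
    border (the object is the side of the threshold the border does not
    belong to), then the largest 8-connected component with holes filled.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.size == 0:
        raise ValueError("empty channel")
    smoothed = gaussian(channel, sigma=smooth_sigma)
    if np.ptp(smoothed) < 1e-9:
        raise ValueError("no spheroid detected")
    thr = threshold_otsu(smoothed)
    border = np.concatenate(
        (smoothed[0], smoothed[-1], smoothed[:, 0], smoothed[:, -1])
    )
    fg = smoothed < thr if np.median(border) >= thr else smoothed > thr
    if not fg.any() or fg.all():
        raise ValueError("no spheroid detected")
    labels = label(fg, connectivity=2)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = ndimage.binary_fill_holes(labels == largest)
    return mask


def feret_diameters(
    mask: np.ndarray,
    pixel_size: float = 1.0,
    angular_step_deg: float = 1.0,
) -> tuple[float, float]:
    """Min and max caliper (Feret) diameters of a binary mask, in µm.

    Rotating-calipers extents of the convex hull of boundary pixels sampled
    at ``angular_step_deg`` resolution; extents include the one-pixel
    footprint of boundary pixels.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("mask too small for Feret diameters")
    boundary = mask & ~ndimage.binary_erosion(mask)
    pts = np.argwhere(boundary).astype(float)
    if pts.shape[0] >= 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except Exception:  # collinear masks: fall back to raw boundary pixels
            pass
    angles = np.deg2rad(np.arange(0.0, 180.0, angular_step_deg))
    dirs = np.stack((np.cos(angles), np.sin(angles)))
    proj = pts @ dirs
    extents = proj.max(axis=0) - proj.min(axis=0) + 1.0  # + pixel footprint
    return (
        float(extents.min() * pixel_size),
        float(extents.max() * pixel_size),
    )


def spheroid_volume(feret_min: float, feret_max: float) -> float:
    """Sphere volume (µm³) from the caliper diameters.

    ``average_radius = (feret_min + feret_max) / 4``;
    ``volume = 4/3·π·average_radius³``.
    """
    if not 0 < feret_min <= feret_max:
        raise ValueError("need 0 < feret_min <= feret_max")
    r = (feret_min + feret_max) / 4.0
    return 4.0 / 3.0 * math.pi * r**3


def measure_spheroid(mask: np.ndarray, pixel_size: float) -> SpheroidMeasurement:
    """Area, Feret diameters (and hence radius/volume) of a spheroid mask."""
    fmin, fmax = feret_diameters(mask, pixel_size)
    area = float(np.count_nonzero(mask)) * pixel_size**2
    return SpheroidMeasurement(area=area, feret_min=fmin, feret_max=fmax)


def detect_nuclei(
    channel: np.ndarray,
    mask: np.ndarray,
    pixel_size: float = 1.0,
    nucleus_radius_um: float = 4.0,
) -> np.ndarray:
    """Detect nuclei centroids in the Hoechst channel, restricted to the mask.

    Large-scale background is subtracted, the result smoothed at half the
    nucleus radius, and local maxima extracted with a minimum separation of
    twice the nucleus radius.  The intensity floor is set from the noise
    statistics outside the spheroid.  Returns an (N, 2) array of (row, col)
    pixel coordinates.
    """
    channel = np.asarray(channel, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    r_px = nucleus_radius_um / pixel_size
    background = gaussian(channel, sigma=6.0 * r_px)
    smoothed = gaussian(channel - background, sigma=r_px / 2.0)
    outside = ~ndimage.binary_dilation(mask, disk(max(int(round(2 * r_px)), 1)))
    if outside.any():
        floor = float(smoothed[outside].mean() + 6.0 * smoothed[outside].std())
    else:
        floor = 0.0
    inmask_max = float(smoothed[mask].max()) if mask.any() else 0.0
    threshold = max(floor, 0.15 * inmask_max)
    if inmask_max <= threshold or not mask.any():
        return np.empty((0, 2))
    peaks = peak_local_max(
        smoothed,
        min_distance=max(int(round(2.0 * r_px)) - 1, 1),
        threshold_abs=threshold,
        labels=mask.astype(int),
    )
    return peaks.astype(float)


def count_positive(
    centroids: np.ndarray,
    marker_channels: Mapping[str, np.ndarray],
    mask: np.ndarray,
    pixel_size: float = 1.0,
    nucleus_radius_um: float = 4.0,
    rule: str = "background_3sd",
) -> BiomarkerCounts:
    """Score marker-positive nuclei and area-normalized counts.

    A nucleus is positive for a marker when the mean marker intensity inside
    a nucleus-radius disc around its centroid exceeds the background mean
    plus three standard deviations (``background_3sd``, the default rule;
    background is sampled outside the dilated spheroid mask).  γH2AX and CC3
    are reported per 10⁴ µm² of spheroid area via
    :meth:`BiomarkerCounts.density`; Ki67 as a fraction of nuclei.
    """
    if rule != "background_3sd":
        raise ValueError(f"unknown positivity rule {rule!r}")
    mask = np.asarray(mask, dtype=bool)
    centroids = np.asarray(centroids, dtype=float).reshape(-1, 2)
    area_um2 = float(np.count_nonzero(mask)) * pixel_size**2
    if area_um2 <= 0:
        raise ValueError("empty spheroid mask")
    r_px = max(nucleus_radius_um / pixel_size, 1.0)
    outside = ~ndimage.binary_dilation(mask, disk(max(int(round(2 * r_px)), 1)))

    n = centroids.shape[0]
    positives: dict[str, int] = {}
    footprint = disk(int(round(r_px))).astype(bool)
    half = footprint.shape[0] // 2
    for marker, channel in marker_channels.items():
        channel = np.asarray(channel, dtype=float)
        if outside.any():
            bg = channel[outside]
            threshold = float(bg.mean() + 3.0 * bg.std())
        else:
            threshold = float(channel.mean() + 3.0 * channel.std())
        count = 0
        for r, c in centroids:
            ri, ci = int(round(r)), int(round(c))
            r0, r1 = max(ri - half, 0), min(ri + half + 1, channel.shape[0])
            c0, c1 = max(ci - half, 0), min(ci + half + 1, channel.shape[1])
            patch = channel[r0:r1, c0:c1]
            fp = footprint[
                r0 - (ri - half) : footprint.shape[0] - ((ri + half + 1) - r1),
                c0 - (ci - half) : footprint.shape[1] - ((ci + half + 1) - c1),
            ]
            if patch[fp].mean() > threshold:
                count += 1
        positives[marker] = count
    return BiomarkerCounts(n_nuclei=n, positives=positives, spheroid_area=area_um2)


def quantify_spheroid(
    image: SpheroidImage,
    nucleus_radius_um: float | None = None,
) -> tuple[SpheroidMeasurement, BiomarkerCounts]:
    """Full pipeline: segmentation → Feret/volume → nuclei → marker counts."""
    if nucleus_radius_um is None:
        gt = image.ground_truth or {}
        nucleus_radius_um = float(gt.get("nucleus_radius_um", 4.0))
    mask = segment_spheroid(image.channels["brightfield"])
    measurement = measure_spheroid(mask, image.pixel_size)
    centroids = detect_nuclei(
        image.channels["nuclei"], mask, image.pixel_size, nucleus_radius_um
    )
    markers = {m: image.channels[m] for m in MARKERS if m in image.channels}
    counts = count_positive(
        centroids, markers, mask, image.pixel_size, nucleus_radius_um
    )
    return measurement, counts
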