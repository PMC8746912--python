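"""Synthetic fundus images with ground-truth vessel masks.

The simulator draws a recursive bifurcating vascular tree over a circular
field of view (FOV), renders it as a fundus-photograph-like RGB raster
(vessels darker than background in the green channel, bright optic disc,
smooth background gradient, pixel noise), and can corrupt the result with
controlled degradations (blur, occlusion, over-exposure).  Every operation
is a pure function of its arguments including the seed, so downstream
training and quantification stages are exactly reproducible.

The tree model is deliberately geometric rather than biophysical: binary
bifurcation with Gaussian jitter on angles and lengths, child calibers set
by a Murray-type split ``w_child = w_parent * 2**(-1/gamma)``, and a smooth
sinusoidal tortuosity applied along each segment.  Its one essential
property is that the fractal dimension and vascular density of the
rasterized mask respond smoothly and monotonically to branching depth.

Coordinates are pixel-centered ``(row, col)`` with the origin at the
top-left corner, row-major.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, gaussian_filter
from skimage.draw import disk as draw_disk

__all__ = [
    "TreeParams",
    "Segment",
    "VascularTree",
    "FundusImage",
    "Appearance",
    "DegradeSpec",
    "generate_tree",
    "rasterize_tree",
    "render_fundus",
    "degrade_image",
    "make_fov",
    "simulate_image_dataset",
    "write_image_dataset",
]

MAX_GENERATIONS = 12
DEFAULT_CANVAS = (256, 256)
FOV_RADIUS_FRACTION = 0.48
# optic-disc point, in unit-FOV coordinates relative to the FOV center
DISC_OFFSET = (0.0, 0.54)


@dataclass(frozen=True)
class TreeParams:
    """Parameters of the bifurcating vascular tree.

    generations: number of bifurcation rounds (0 = trunks only), capped at 12
    branch_angle_deg: mean half-angle between sibling branches, degrees
    length_ratio: child/parent segment length, in (0, 1)
    width_root_px: trunk caliber in pixels (>= 1)
    murray_exponent: caliber-split exponent; child width = parent * 2**(-1/exp)
    tortuosity_amp: amplitude (px) of the sinusoidal path perturbation
    n_roots: number of trunks emanating from the optic-disc point
    seed: RNG seed; same params + seed => identical tree
    """

    generations: int = 5
    branch_angle_deg: float = 35.0
    length_ratio: float = 0.78
    width_root_px: float = 4.0
    murray_exponent: float = 3.0
    tortuosity_amp: float = 1.5
    n_roots: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.generations <= MAX_GENERATIONS):
            raise ValueError(f"generations must be in [0, {MAX_GENERATIONS}], got {self.generations}")
        if not (0.0 < self.length_ratio < 1.0):
            raise ValueError("length_ratio must be in (0, 1)")
        if self.width_root_px < 1.0:
            raise ValueError("width_root_px must be >= 1 pixel")
        if self.n_roots < 1:
            raise ValueError("n_roots must be >= 1")
        if self.murray_exponent <= 0:
            raise ValueError("murray_exponent must be positive")


@dataclass(frozen=True)
class Segment:
    """One straight vessel segment in unit-FOV coordinates (width in px)."""

    start: tuple[float, float]
    end: tuple[float, float]
    width_px: float
    generation: int


@dataclass(frozen=True)
class VascularTree:
    segments: tuple[Segment, ...]
    params: TreeParams

    def __len__(self) -> int:
        return len(self.segments)


@dataclass
class FundusImage:
    """RGB fundus-like raster with its FOV disc mask and minimal metadata."""

    pixels: np.ndarray  # (H, W, 3) float in [0, 1]
    fov: np.ndarray  # (H, W) bool
    eye: str = "right"
    participant_id: str = ""

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be (H, W, 3)")
        if self.pixels.shape[:2] != self.fov.shape:
            raise ValueError("pixels and fov shapes disagree")
        if min(self.fov.shape) < 64:
            raise ValueError("canvas must be at least 64x64")
        if self.eye not in ("right", "left"):
            raise ValueError("eye must be 'right' or 'left'")


@dataclass(frozen=True)
class Appearance:
    """Rendering parameters (intensities in [0, 1])."""

    background_green: float = 0.58
    background_gradient: float = 0.10  # extra brightness at FOV center
    vessel_contrast: float = 0.32  # green-channel dip under vessels
    disc_brightness: float = 0.22
    noise_sd: float = 0.015
    outside_fov_level: float = 0.02


@dataclass(frozen=True)
class DegradeSpec:
    """A single degradation: blur, occlusion, or exposure, graded by severity."""

    mode: str
    severity: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("blur", "occlusion", "exposure"):
            raise ValueError(f"unknown degradation mode: {self.mode!r}")
        if not (0.0 <= self.severity <= 1.0):
            raise ValueError("severity must be in [0, 1]")


def _unit_disc_point() -> np.ndarray:
    return np.array([0.5 + DISC_OFFSET[0] * 0.5, 0.5 + DISC_OFFSET[1] * 0.5])


def generate_tree(params: TreeParams) -> VascularTree:
    """Grow a bifurcating tree in unit-FOV coordinates.

    Each trunk starts at the optic-disc point and fans into the FOV; every
    generation splits each terminal segment into two children rotated by
    roughly +/- ``branch_angle_deg`` with Gaussian jitter, shortened by
    ``length_ratio`` and thinned by the Murray rule.  Deterministic given
    ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    origin = _unit_disc_point()
    to_center = np.arctan2(0.5 - origin[0], 0.5 - origin[1])  # angle (row, col) frame

    base_len = 0.26
    segments: list[Segment] = []
    frontier: list[tuple[np.ndarray, float, float, float]] = []  # (end, angle, length, width)

    if params.n_roots == 1:
        root_angles = [to_center]
    else:
        fan = np.deg2rad(140.0)
        root_angles = list(to_center + np.linspace(-fan / 2, fan / 2, params.n_roots))
    for ang in root_angles:
        a = ang + rng.normal(0.0, np.deg2rad(4.0))
        length = base_len * (1.0 + rng.normal(0.0, 0.06))
        end = origin + length * np.array([np.sin(a), np.cos(a)])
        seg = Segment(tuple(origin), tuple(end), params.width_root_px, 0)
        segments.append(seg)
        frontier.append((end, a, length, params.width_root_px))

    width_factor = 2.0 ** (-1.0 / params.murray_exponent)
    half = np.deg2rad(params.branch_angle_deg)
    for gen in range(1, params.generations + 1):
        new_frontier = []
        for end, ang, length, width in frontier:
            child_len = length * params.length_ratio * (1.0 + rng.normal(0.0, 0.08))
            child_w = max(1.0, width * width_factor)
            for sign in (+1.0, -1.0):
                a = ang + sign * half * (1.0 + rng.normal(0.0, 0.18))
                c_end = end + child_len * np.array([np.sin(a), np.cos(a)])
                segments.append(Segment(tuple(end), tuple(c_end), child_w, gen))
                new_frontier.append((c_end, a, child_len, child_w))
        frontier = new_frontier
    return VascularTree(tuple(segments), params)


def make_fov(canvas: tuple[int, int], fov_radius: float | None = None) -> np.ndarray:
    """Filled FOV disc centered on the canvas."""
    h, w = canvas
    if fov_radius is None:
        fov_radius = FOV_RADIUS_FRACTION * min(h, w)
    fov = np.zeros((h, w), dtype=bool)
    rr, cc = draw_disk(((h - 1) / 2.0, (w - 1) / 2.0), fov_radius, shape=(h, w))
    fov[rr, cc] = True
    return fov


def rasterize_tree(
    tree: VascularTree,
    canvas: tuple[int, int] = DEFAULT_CANVAS,
    fov_radius: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize a tree to a hard binary vessel mask clipped to the FOV disc.

    Unit-FOV coordinates map so that the unit circle of radius 0.5 lands on
    the FOV disc.  Segments are drawn by stamping discs of radius
    ``width/2`` along the (tortuosity-perturbed) path — no anti-aliasing;
    the mask is hard binary.  Returns ``(mask, fov)``.
    """
    h, w = canvas
    if min(h, w) < 64:
        raise ValueError("canvas must be at least 64x64")
    if fov_radius is None:
        fov_radius = FOV_RADIUS_FRACTION * min(h, w)
    fov = make_fov(canvas, fov_radius)
    mask = np.zeros((h, w), dtype=bool)
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    scale = 2.0 * fov_radius  # unit length -> px

    rng = np.random.default_rng(tree.params.seed + 1)
    amp = tree.params.tortuosity_amp
    # bucket path points by stamp radius, then dilate each bucket once
    buckets: dict[float, list[np.ndarray]] = {}
    for seg in tree.segments:
        p0 = center + (np.asarray(seg.start) - 0.5) * scale
        p1 = center + (np.asarray(seg.end) - 0.5) * scale
        pts = _segment_points(p0, p1, amp, rng)
        if pts is None:
            continue
        r = max(0.5, seg.width_px / 2.0)
        buckets.setdefault(round(r * 2) / 2.0, []).append(pts)
    for r, pts_list in buckets.items():
        pts = np.rint(np.concatenate(pts_list)).astype(int)
        keep = (pts[:, 0] >= 0) & (pts[:, 0] < h) & (pts[:, 1] >= 0) & (pts[:, 1] < w)
        pts = pts[keep]
        if pts.size == 0:
            continue
        layer = np.zeros((h, w), dtype=bool)
        layer[pts[:, 0], pts[:, 1]] = True
        mask |= binary_dilation(layer, _disc_footprint(r)) if r > 0.5 else layer
    if tree.segments and not mask.any():
        warnings.warn("tree lies wholly outside the canvas: empty mask", stacklevel=2)
    mask &= fov
    return mask, fov


def _disc_footprint(r: float) -> np.ndarray:
    n = int(np.floor(r))
    yy, xx = np.mgrid[-n : n + 1, -n : n + 1]
    return (yy**2 + xx**2) <= r**2


def _segment_points(p0, p1, tort_amp, rng) -> np.ndarray | None:
    """Dense sub-pixel sample points along a tortuous segment path.

    The wiggle is a smooth sinusoid that vanishes at both endpoints, so
    child segments stay attached to their parent.
    """
    d = p1 - p0
    length = float(np.hypot(*d))
    phase_cycles = rng.uniform(0.8, 1.6)
    amp_scale = rng.uniform(0.5, 1.0) * np.sign(rng.uniform(-1, 1))
    if length < 1e-9:
        return None
    u = d / length
    perp = np.array([-u[1], u[0]])
    n_steps = max(2, int(np.ceil(length / 0.4)) + 1)
    t = np.linspace(0.0, 1.0, n_steps)
    offset = tort_amp * amp_scale * np.sin(np.pi * phase_cycles * t) * np.sin(np.pi * t)
    return p0[None, :] + t[:, None] * d[None, :] + offset[:, None] * perp[None, :]


def render_fundus(
    mask: np.ndarray,
    fov: np.ndarray,
    appearance: Appearance | None = None,
    seed: int = 0,
    eye: str = "right",
    participant_id: str = "",
) -> FundusImage:
    """Render a binary vessel mask as a fundus-photograph-like RGB image.

    Vessels appear darker than the retinal background in the green channel;
    the background carries a smooth radial gradient, a bright optic-disc
    region, and Gaussian pixel noise.  Deterministic given ``seed``.
    """
    if mask.shape != fov.shape:
        raise ValueError("mask and fov shapes disagree")
    app = appearance or Appearance()
    h, w = mask.shape
    rng = np.random.default_rng(seed)

    yy, xx = np.mgrid[0:h, 0:w]
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    radius = FOV_RADIUS_FRACTION * min(h, w)
    rdist = np.hypot(yy - center[0], xx - center[1]) / radius

    green = app.background_green + app.background_gradient * np.clip(1.0 - rdist, 0.0, 1.0)
    # optic-disc bright blob at the trunk origin
    disc = _unit_disc_point()
    disc_px = (center[0] + (disc[0] - 0.5) * 2 * radius, center[1] + (disc[1] - 0.5) * 2 * radius)
    dsig = 0.07 * min(h, w)
    green = green + app.disc_brightness * np.exp(
        -((yy - disc_px[0]) ** 2 + (xx - disc_px[1]) ** 2) / (2 * dsig**2)
    )

    vessel = gaussian_filter(mask.astype(float), 0.6)
    vessel /= max(vessel.max(), 1e-9)
    green = green - app.vessel_contrast * vessel

    red = np.clip(green + 0.22, 0.0, 1.0)
    blue = np.clip(green - 0.30, 0.0, 1.0)
    img = np.stack([red, green, blue], axis=-1)
    img += rng.normal(0.0, app.noise_sd, size=img.shape)
    img[~fov] = app.outside_fov_level
    np.clip(img, 0.0, 1.0, out=img)
    return FundusImage(img, fov.copy(), eye=eye, participant_id=participant_id)


def degrade_image(image: FundusImage, spec: DegradeSpec) -> FundusImage:
    """Apply one graded corruption; severity 0 is the identity, FOV preserved."""
    img = image.pixels.copy()
    fov = image.fov
    s = float(spec.severity)
    if s == 0.0:
        return FundusImage(img, fov.copy(), image.eye, image.participant_id)

    if spec.mode == "blur":
        sigma = 6.0 * s
        for c in range(3):
            img[:, :, c] = gaussian_filter(img[:, :, c], sigma)
        img[~fov] = image.pixels[~fov]
    elif spec.mode == "occlusion":
        rng = np.random.default_rng(spec.seed)
        h, w = fov.shape
        radius = FOV_RADIUS_FRACTION * min(h, w)
        center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        # radius chosen so severity 1 swallows the whole FOV
        r = radius * (0.15 + 1.05 * s)
        jitter = (1.0 - s) * 0.4 * radius
        c = center + rng.uniform(-jitter, jitter, size=2)
        patch_val = rng.uniform(0.15, 0.85)
        rr, cc = draw_disk(tuple(c), r, shape=(h, w))
        occ = np.zeros((h, w), dtype=bool)
        occ[rr, cc] = True
        img[occ & fov] = patch_val
    elif spec.mode == "exposure":
        # push the FOV toward saturation (washed-out over-exposure)
        img[fov] = np.clip(img[fov] * (1.0 + 1.8 * s) + 0.25 * s, 0.0, 1.0)
    np.clip(img, 0.0, 1.0, out=img)
    return FundusImage(img, fov.copy(), image.eye, image.participant_id)


# ---------------------------------------------------------------------------
# dataset helpers

POOR_SEVERITY_THRESHOLD = 0.4  # degradations at/above this are labelled "poor"


@dataclass
class SimulatedImage:
    image: FundusImage
    mask: np.ndarray
    fov: np.ndarray
    label: str  # "good" | "poor"
    degradation: DegradeSpec | None
    tree_params: TreeParams


def simulate_image_dataset(
    n_images: int,
    frac_degraded: float = 0.5,
    seed: int = 0,
    canvas: tuple[int, int] = DEFAULT_CANVAS,
    generations_range: tuple[int, int] = (4, 8),
    degrade_severity_range: tuple[float, float] = (0.4, 1.0),
) -> list[SimulatedImage]:
    """Generate a labelled set of clean and degraded fundus images.

    Each image gets its own tree (branching depth uniform over
    ``generations_range``), alternating right/left eyes, two images per
    simulated participant.  A ``frac_degraded`` share receives one random
    degradation with severity in ``degrade_severity_range``; severities at
    or above 0.4 are labelled "poor", mirroring a quality-control ground
    truth that is unambiguous by construction.
    """
    rng = np.random.default_rng(seed)
    out: list[SimulatedImage] = []
    modes = ("blur", "occlusion", "exposure")
    for i in range(n_images):
        g = int(rng.integers(generations_range[0], generations_range[1] + 1))
        tp = TreeParams(
            generations=g,
            branch_angle_deg=float(rng.uniform(28, 42)),
            length_ratio=float(rng.uniform(0.72, 0.84)),
            width_root_px=float(rng.uniform(3.0, 5.0)),
            tortuosity_amp=float(rng.uniform(0.8, 2.2)),
            n_roots=int(rng.integers(3, 6)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        tree = generate_tree(tp)
        mask, fov = rasterize_tree(tree, canvas=canvas)
        eye = "right" if i % 2 == 0 else "left"
        pid = f"P{i // 2:05d}"
        img = render_fundus(mask, fov, seed=int(rng.integers(0, 2**31 - 1)), eye=eye, participant_id=pid)
        degr = None
        label = "good"
        if rng.uniform() < frac_degraded:
            sev = float(rng.uniform(*degrade_severity_range))
            degr = DegradeSpec(mode=modes[int(rng.integers(0, 3))], severity=sev,
                               seed=int(rng.integers(0, 2**31 - 1)))
            img = degrade_image(img, degr)
            label = "poor" if sev >= POOR_SEVERITY_THRESHOLD else "good"
        out.append(SimulatedImage(img, mask, fov, label, degr, tp))
    return out


def write_image_dataset(records: list[SimulatedImage], out_dir: str | Path) -> Path:
    """Write images/masks as 8-bit PNGs plus a TSV manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, rec in enumerate(records):
        img_name = f"img_{i:05d}.png"
        mask_name = f"mask_{i:05d}.png"
        fov_name = f"fov_{i:05d}.png"
        iio.imwrite(out_dir / img_name, (rec.image.pixels * 255).round().astype(np.uint8))
        iio.imwrite(out_dir / mask_name, rec.mask.astype(np.uint8) * 255)
        iio.imwrite(out_dir / fov_name, rec.fov.astype(np.uint8) * 255)
        rows.append(
            {
                "image": img_name,
                "mask": mask_name,
                "fov": fov_name,
                "participant_id": rec.image.participant_id,
                "eye": rec.image.eye,
                "label": rec.label,
                "degrade_mode": rec.degradation.mode if rec.degradation else "",
                "severity": rec.degradation.severity if rec.degradation else 0.0,
                "generations": rec.tree_params.generations,
                "tree_seed": rec.tree_params.seed,
            }
        )
    manifest = out_dir / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest
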