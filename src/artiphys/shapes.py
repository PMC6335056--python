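"""Closed-shape stimulus banks: generation, rotation, descriptors, rasterization.

Stimuli are simple closed 2-D shapes described by their boundary: each
boundary element carries a normalized curvature in [-1, +1] (-1 sharp
concavity, +1 sharp convexity) and an angular position in degrees about
the shape center.  Shapes are generated as radial harmonic profiles
r(theta) = 1 + sum_m a_m cos(m(theta - phi_m)), so curvature descriptors
are exact by construction (analytic curvature of a polar curve), and the
rotational symmetry of a shape follows from the harmonics it contains.

Conventions
-----------
* Pixel coordinates are 0-based (row, col); angular position 0 deg points
  rightward (increasing column) and angles increase counterclockwise.
* Rasterization is binary white-on-black: background exactly 0, foreground
  exactly ``amplitude``; no anti-aliasing.
* ``size_px`` is the diameter of the reference big circle; all shapes in a
  bank share one global pixel scale so relative sizes are preserved.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from skimage.draw import polygon as _sk_polygon

__all__ = [
    "BoundaryElement",
    "BoundaryShape",
    "StimulusImage",
    "generate_shape_bank",
    "rotate_shape",
    "render_shape",
    "render_bank",
    "bank_scale",
    "max_stimulus_width",
    "save_bank",
    "load_bank",
]

#: Default image field width/height in pixels.
FIELD_PX = 227
#: Default diameter, in pixels, of the reference big circle.
SIZE_PX = 32
#: Default foreground luminance.
AMPLITUDE = 255
#: Default number of uniformly spaced boundary samples per shape.
N_BOUNDARY_SAMPLES = 50
#: Fine angular sampling (points) used for curvature extrema and rendering.
_FINE_N = 720


@dataclass(frozen=True)
class BoundaryElement:
    """One boundary descriptor: (normalized curvature, angular position)."""

    curvature: float
    angular_position: float

    def __post_init__(self):
        if not -1.0 <= self.curvature <= 1.0:
            raise ValueError(f"curvature {self.curvature} outside [-1, 1]")
        object.__setattr__(self, "angular_position", float(self.angular_position) % 360.0)


@dataclass
class BoundaryShape:
    """A closed shape as an ordered list of boundary elements.

    ``radial_profile`` maps angle in degrees to radius in shape units
    (the big reference circle has radius 1) and is required only for
    rasterization; descriptor-level analyses use ``elements`` alone.
    """

    shape_id: str
    elements: tuple
    rotation_deg: float = 0.0
    symmetry_order: int = 1
    radial_profile: Callable[[np.ndarray], np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self):
        if len(self.elements) == 0:
            raise ValueError("shape must have at least one boundary element")
        if not 1 <= int(self.symmetry_order) <= 8:
            raise ValueError(f"symmetry_order {self.symmetry_order} not in 1..8")
        self.elements = tuple(self.elements)

    @property
    def curvatures(self) -> np.ndarray:
        return np.array([e.curvature for e in self.elements])

    @property
    def angular_positions(self) -> np.ndarray:
        return np.array([e.angular_position for e in self.elements])


@dataclass
class StimulusImage:
    """Binary raster of one stimulus plus placement metadata."""

    pixels: np.ndarray
    amplitude: float
    center_xy: tuple
    size_px: int

    @property
    def foreground_mask(self) -> np.ndarray:
        return self.pixels == self.amplitude


# ---------------------------------------------------------------------------
# Radial-profile machinery
# ---------------------------------------------------------------------------

def _harmonic_profile(amps: np.ndarray, phases: np.ndarray, orders: np.ndarray,
                      base: float = 1.0) -> Callable[[np.ndarray], np.ndarray]:
    """r(theta_deg) = base + sum_m amps*cos(orders*(theta - phases))."""

    def profile(theta_deg):
        th = np.deg2rad(np.asarray(theta_deg, dtype=float))
        ph = np.deg2rad(phases)
        r = np.full_like(th, float(base))
        for a, m, p in zip(amps, orders, ph):
            r = r + a * np.cos(m * (th - p))
        return r

    return profile


def _polar_curvature(r: np.ndarray, theta_rad: np.ndarray) -> np.ndarray:
    """Signed curvature of a polar curve r(theta) sampled on a uniform grid.

    kappa = (r^2 + 2 r'^2 - r r'') / (r^2 + r'^2)^{3/2}; positive for a
    counterclockwise convex boundary.
    """
    dt = theta_rad[1] - theta_rad[0]
    rp = np.gradient(r, dt, edge_order=2)
    rpp = np.gradient(rp, dt, edge_order=2)
    num = r ** 2 + 2 * rp ** 2 - r * rpp
    den = (r ** 2 + rp ** 2) ** 1.5
    return num / den


def normalize_curvature(kappa: np.ndarray) -> np.ndarray:
    """Map raw contour curvature to [-1, 1] via kappa/(1+|kappa|).

    Raw curvature is in units of 1/radius with the reference circle at
    radius 1 (so the unit circle maps to +0.5); sharp convexities approach
    +1 and sharp concavities approach -1.
    """
    kappa = np.asarray(kappa, dtype=float)
    return kappa / (1.0 + np.abs(kappa))


def _descriptors_from_profile(profile, sampling: str = "both",
                              n_samples: int = N_BOUNDARY_SAMPLES) -> tuple:
    """Sample boundary elements from a radial profile.

    ``sampling`` is one of "uniform" (n_samples evenly spaced boundary
    points), "extrema" (local curvature extrema only) or "both".
    """
    fine_deg = np.linspace(0.0, 360.0, _FINE_N, endpoint=False)
    r = profile(fine_deg)
    c = normalize_curvature(_polar_curvature(r, np.deg2rad(fine_deg)))

    idx: list[int] = []
    if sampling in ("uniform", "both"):
        idx.extend(np.round(np.linspace(0, _FINE_N, n_samples, endpoint=False)).astype(int))
    if sampling in ("extrema", "both"):
        prev = np.roll(c, 1)
        nxt = np.roll(c, -1)
        ext = np.where(((c >= prev) & (c > nxt)) | ((c <= prev) & (c < nxt)))[0]
        idx.extend(ext.tolist())
    if sampling not in ("uniform", "extrema", "both"):
        raise ValueError(f"unknown sampling mode {sampling!r}")
    idx = sorted(set(int(i) % _FINE_N for i in idx))
    return tuple(BoundaryElement(float(np.clip(c[i], -1, 1)), float(fine_deg[i])) for i in idx)


# ---------------------------------------------------------------------------
# Bank generation
# ---------------------------------------------------------------------------

def default_symmetry_orders(n_base: int) -> list:
    """Per-base-shape rotation counts.

    The first two shapes are circles (full rotational symmetry, one
    rotation each); the rest are generic 8-rotation shapes except the
    last eight, which have 2-fold profile symmetry and hence 4 distinct
    45-degree rotations.  For the default 51-shape bank this expands to
    2 + 41*8 + 8*4 = 362 stimuli, the standard bank size.
    """
    if n_base < 1:
        raise ValueError("n_base must be >= 1")
    orders = [1, 1][: min(2, n_base)]
    n_rest = n_base - len(orders)
    orders += [8] * n_rest
    if n_rest >= 8:
        orders[-8:] = [4] * 8
    return orders


def _base_shape(shape_idx: int, order: int, rng: np.random.Generator) -> BoundaryShape:
    """One unrotated base shape whose profile symmetry matches ``order``."""
    if order == 1:  # circles: small then big (the size-defining shape)
        radius = 0.55 if shape_idx == 0 else 1.0
        prof = _harmonic_profile(np.array([]), np.array([]), np.array([]), base=radius)
        elements = _descriptors_from_profile(prof, sampling="uniform")
        return BoundaryShape(f"s{shape_idx:03d}", elements, 0.0, 1, prof)
    # Distinct 45-degree rotations = 8 / gcd(g, 8), where g is the gcd of
    # the radial harmonic orders; pick harmonics to hit the requested count.
    if order == 8:
        required = [int(rng.choice([3, 5, 7]))]          # odd harmonic -> g odd
        extras = [2, 3, 4, 5, 6, 7]
    elif order == 4:
        required = [int(rng.choice([2, 6]))]             # gcd(g, 8) = 2
        extras = [2, 4, 6]
    elif order == 2:
        required = [4]                                   # gcd(g, 8) = 4
        extras = [4]
    else:
        raise ValueError(f"unsupported symmetry_order {order}")
    extras = [m for m in extras if m != required[0]]
    n_extra = int(rng.integers(0, 3))
    chosen_extra = (rng.choice(extras, size=min(n_extra, len(extras)), replace=False)
                    if extras and n_extra else np.array([], dtype=int))
    chosen = np.array(required + sorted(int(m) for m in chosen_extra))
    amps = rng.uniform(0.05, 0.22, size=len(chosen))
    phases = rng.uniform(0, 360, size=len(chosen))
    base = rng.uniform(0.55, 0.80)
    # keep the profile positive and every shape strictly smaller than the
    # big reference circle (r = 1), which defines the bank's pixel scale
    cap = min(0.45 * base, 0.98 - base)
    if amps.sum() > cap:
        amps *= cap / amps.sum()
    prof = _harmonic_profile(amps, phases, chosen.astype(float), base=base)
    elements = _descriptors_from_profile(prof)
    return BoundaryShape(f"s{shape_idx:03d}", elements, 0.0, int(order), prof)


def generate_shape_bank(n_base_shapes: int = 51, seed: int = 0,
                        rotations_policy: str = "symmetry",
                        symmetry_orders: Sequence[int] | None = None) -> list:
    """Generate a bank of base shapes expanded across their rotations.

    Each base shape is rotated in 45-degree steps, with the number of
    distinct rotations dictated by its rotational symmetry (the
    "symmetry" policy) or forced to one ("none").  Deterministic for a
    fixed seed.  The default configuration yields 362 stimuli.
    """
    if n_base_shapes < 1:
        raise ValueError("n_base_shapes must be >= 1")
    if symmetry_orders is None:
        symmetry_orders = default_symmetry_orders(n_base_shapes)
    if len(symmetry_orders) != n_base_shapes:
        raise ValueError("symmetry_orders length must equal n_base_shapes")
    for o in symmetry_orders:
        if not 1 <= int(o) <= 8:
            raise ValueError(f"symmetry_order {o} not in 1..8")

    rng = np.random.default_rng(seed)
    bank: list[BoundaryShape] = []
    for i, order in enumerate(symmetry_orders):
        base = _base_shape(i, int(order), rng)
        n_rot = 1 if rotations_policy == "none" else base.symmetry_order
        for k in range(n_rot):
            bank.append(rotate_shape(base, 45.0 * k))
    return bank


def rotate_shape(shape: BoundaryShape, theta: float) -> BoundaryShape:
    """Rotate a shape counterclockwise by ``theta`` degrees.

    Curvatures are preserved element-wise; angular positions shift by
    theta modulo 360; the radial profile rotates consistently.
    """
    theta = float(theta)
    elements = tuple(
        BoundaryElement(e.curvature, (e.angular_position + theta) % 360.0)
        for e in shape.elements
    )
    prof = shape.radial_profile
    if prof is not None and theta % 360.0 != 0.0:
        base_prof = prof

        def rotated(theta_deg, _p=base_prof, _t=theta):
            return _p(np.asarray(theta_deg, dtype=float) - _t)

        prof = rotated
    return BoundaryShape(shape.shape_id, elements,
                         (shape.rotation_deg + theta) % 360.0,
                         shape.symmetry_order, prof)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _shape_diameter_units(shape: BoundaryShape) -> float:
    """Maximal caliper width of the radial profile, in shape units."""
    th = np.linspace(0.0, 180.0, _FINE_N // 2, endpoint=False)
    r1 = shape.radial_profile(th)
    r2 = shape.radial_profile(th + 180.0)
    return float(np.max(r1 + r2))


def bank_scale(bank: Sequence[BoundaryShape], size_px: int = SIZE_PX) -> float:
    """Pixels per shape unit such that the largest shape's diameter is size_px."""
    if len(bank) == 0:
        raise ValueError("empty bank")
    dmax = max(_shape_diameter_units(s) for s in bank if s.radial_profile is not None)
    return size_px / dmax


def render_shape(shape: BoundaryShape, size_px: int = SIZE_PX,
                 amplitude: float = AMPLITUDE,
                 center_xy: tuple = (FIELD_PX // 2, FIELD_PX // 2),
                 field: int = FIELD_PX,
                 px_per_unit: float | None = None) -> StimulusImage:
    """Rasterize a shape as a binary (0/amplitude) image.

    ``center_xy`` is (row, col) of the shape centroid.  ``px_per_unit``
    is the global bank scale; if omitted the shape itself is taken as the
    size-defining one (its diameter becomes ``size_px``).
    """
    if shape.radial_profile is None:
        raise ValueError("shape has no radial_profile; cannot rasterize")
    if px_per_unit is None:
        px_per_unit = size_px / _shape_diameter_units(shape)

    th_deg = np.linspace(0.0, 360.0, _FINE_N, endpoint=False)
    r = shape.radial_profile(th_deg) * px_per_unit
    th = np.deg2rad(th_deg)
    x = r * np.cos(th)
    y = r * np.sin(th)

    # area centroid of the polygon (shoelace), so placement is by centroid
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y2 - x2 * y
    area = cross.sum() / 2.0
    cx = ((x + x2) * cross).sum() / (6.0 * area)
    cy = ((y + y2) * cross).sum() / (6.0 * area)

    row0, col0 = center_xy
    rows = row0 - (y - cy)  # image rows grow downward
    cols = col0 + (x - cx)
    if rows.min() < -0.5 or cols.min() < -0.5 or rows.max() > field - 0.5 or cols.max() > field - 0.5:
        raise ValueError(
            f"shape {shape.shape_id} exceeds the {field}x{field} field at center {center_xy}"
        )
    img = np.zeros((field, field), dtype=float)
    rr, cc = _sk_polygon(rows, cols, shape=(field, field))
    img[rr, cc] = amplitude
    return StimulusImage(img, amplitude, (int(round(row0)), int(round(col0))), size_px)


def render_bank(bank: Sequence[BoundaryShape], size_px: int = SIZE_PX,
                amplitude: float = AMPLITUDE,
                center_xy: tuple = (FIELD_PX // 2, FIELD_PX // 2),
                field: int = FIELD_PX) -> list:
    """Render every shape in a bank with one shared global scale."""
    scale = bank_scale(bank, size_px)
    return [render_shape(s, size_px, amplitude, center_xy, field, px_per_unit=scale)
            for s in bank]


def max_stimulus_width(bank: Sequence[BoundaryShape], size_px: int = SIZE_PX,
                       axis: str = "horizontal") -> int:
    """Maximal pixel extent over all rendered stimuli along one axis."""
    if len(bank) == 0:
        raise ValueError("empty bank")
    images = render_bank(bank, size_px=size_px)
    widths = []
    for im in images:
        mask = im.foreground_mask
        proj = mask.any(axis=0) if axis == "horizontal" else mask.any(axis=1)
        nz = np.where(proj)[0]
        widths.append(0 if len(nz) == 0 else int(nz[-1] - nz[0] + 1))
    return max(widths)


# ---------------------------------------------------------------------------
# Serialization (descriptor level)
# ---------------------------------------------------------------------------

def bank_to_frame(bank: Sequence[BoundaryShape]) -> pd.DataFrame:
    rows = []
    for i, s in enumerate(bank):
        for e in s.elements:
            rows.append(dict(stimulus_index=i, shape_id=s.shape_id,
                             rotation_deg=s.rotation_deg,
                             symmetry_order=s.symmetry_order,
                             curvature=e.curvature,
                             angular_position=e.angular_position))
    return pd.DataFrame(rows)


def save_bank(bank: Sequence[BoundaryShape], path) -> None:
    bank_to_frame(bank).to_csv(path, index=False)


def load_bank(path) -> list:
    """Load a descriptor-level bank (no radial profiles, fitting only)."""
    df = pd.read_csv(path)
    bank = []
    for idx, grp in df.groupby("stimulus_index", sort=True):
        elements = tuple(BoundaryElement(c, a)
                         for c, a in zip(grp["curvature"], grp["angular_position"]))
        bank.append(BoundaryShape(str(grp["shape_id"].iloc[0]), elements,
                                  float(grp["rotation_deg"].iloc[0]),
                                  int(grp["symmetry_order"].iloc[0])))
    return bank
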