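"""Synthetic microscopy generators with exact ground truth.

Two instruments are emulated at the geometry of the real acquisitions:

* spinning-disk confocal mosaics (SDM): two-channel 16-bit fields,
  84 nm/pixel, 43.008 x 43.008 um field of view, PSD95/SAP102-like
  fluorescent puncta rendered as anisotropic Gaussian spots over a noisy
  background;
* FIB-SEM stacks: labeled voxel volumes at 5 x 5 x 20 nm, containing
  synapses built as paired curved plates (presynaptic density + PSD
  separated by a narrow cleft), with log-normal synaptic apposition
  surface (SAS) areas and an asymmetric/symmetric (AS/SS) mixture.

Every rendered object has exactly one ground-truth record, so detection,
segmentation, counting and calibration can all be scored against known
truth.  All randomness flows through a single integer seed; identical
specs and seeds give bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

# 10%-of-peak isocontour of a 2D Gaussian encloses area 2*pi*sx*sy*ln(10)
_LN10 = float(np.log(10.0))


class PlacementError(RuntimeError):
    """Raised when hard-core placement cannot satisfy the requested density."""


# --------------------------------------------------------------------------
# SDM-like two-channel puncta fields
# --------------------------------------------------------------------------

@dataclass
class PunctaFieldSpec:
    """Parameters of a synthetic two-channel SDM field.

    Densities are puncta per 100 um^2 per channel; ``coloc_fraction`` is the
    fraction of distinct entities that carry both labels (the colocalization
    index c).  Punctum ground-truth areas (the 10%-of-peak isocontour, nm^2)
    are log-normal with parameters ``punctum_area_mu``/``punctum_area_sigma``
    on the log-nm^2 scale; defaults match the measured PSD95 punctum size
    distribution (mu 11.21, sigma 0.46).  Default densities and c mirror the
    stratum lacunosum-moleculare condition.
    """

    field_width: float = 43.008        # um
    field_height: float = 43.008       # um
    pixel_size: float = 84.0           # nm
    density_ch1: float = 91.3103       # puncta / 100 um^2
    density_ch2: float = 77.1788
    coloc_fraction: float = 0.5840
    punctum_area_mu: float = 11.21     # log nm^2
    punctum_area_sigma: float = 0.46
    background_level: float = 500.0
    noise_sd: float = 30.0
    amplitude_range: tuple[float, float] = (500.0, 3000.0)
    aspect_range: tuple[float, float] = (1.0, 1.8)
    min_separation_nm: float = 250.0   # hard core between distinct entities
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.field_width <= 0 or self.field_height <= 0:
            raise ValueError("field dimensions must be positive")
        if self.density_ch1 < 0 or self.density_ch2 < 0:
            raise ValueError("densities must be non-negative")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        ny = int(round(self.field_height * 1000.0 / self.pixel_size))
        nx = int(round(self.field_width * 1000.0 / self.pixel_size))
        return ny, nx

    @property
    def area_um2(self) -> float:
        return self.field_width * self.field_height


def _hardcore_positions(rng, n, width_nm, height_nm, min_sep_nm,
                        max_tries_per_point=400):
    """Rejection-sample ``n`` points with pairwise distance >= min_sep_nm."""
    if n == 0:
        return np.empty((0, 2))
    pts: list[np.ndarray] = []
    tries = 0
    budget = max_tries_per_point * n
    tree = None
    rebuild_at = 1
    while len(pts) < n:
        if tries >= budget:
            raise PlacementError(
                f"could not place {n} entities with a {min_sep_nm:.0f} nm hard "
                f"core after {budget} attempts; requested density too high")
        p = rng.uniform([0.0, 0.0], [width_nm, height_nm])
        tries += 1
        if pts:
            if tree is None or len(pts) >= rebuild_at:
                tree = cKDTree(np.asarray(pts))
                rebuild_at = max(rebuild_at * 2, len(pts) + 32)
            # check tree plus the tail not yet in the tree
            if tree.query_ball_point(p, min_sep_nm, return_length=True):
                continue
            tail = np.asarray(pts[tree.n:]) if tree.n < len(pts) else None
            if tail is not None and len(tail) and (
                    np.min(np.hypot(*(tail - p).T)) < min_sep_nm):
                continue
        pts.append(p)
    return np.asarray(pts)


def _render_spot(image, cx, cy, amp, sx, sy, theta):
    """Add one rotated anisotropic Gaussian spot (pixel units) in place."""
    extent = int(np.ceil(4.0 * max(sx, sy))) + 1
    x0, x1 = int(np.floor(cx)) - extent, int(np.floor(cx)) + extent + 1
    y0, y1 = int(np.floor(cy)) - extent, int(np.floor(cy)) + extent + 1
    x0c, x1c = max(x0, 0), min(x1, image.shape[1])
    y0c, y1c = max(y0, 0), min(y1, image.shape[0])
    if x0c >= x1c or y0c >= y1c:
        return
    xs = np.arange(x0c, x1c) - cx
    ys = np.arange(y0c, y1c) - cy
    X, Y = np.meshgrid(xs, ys)
    ct, st = np.cos(theta), np.sin(theta)
    u = ct * X + st * Y
    v = -st * X + ct * Y
    image[y0c:y1c, x0c:x1c] += amp * np.exp(
        -0.5 * ((u / sx) ** 2 + (v / sy) ** 2))


def make_puncta_field(spec: PunctaFieldSpec):
    """Render a two-channel SDM-like field.

    Returns ``(image, truth)`` where ``image`` has shape ``(2, ny, nx)``
    (float32, 16-bit range) and ``truth`` is a DataFrame with one row per
    (entity, channel) membership: columns ``entity_id, channel, x_px, y_px,
    area_nm2, amplitude, sigma_x_px, sigma_y_px, theta, colocalized``.

    Entity counts per channel are Poisson with mean density x area; a
    fraction ``coloc_fraction`` of entities appear in both channels at the
    same location (independent sub-pixel jitter <= 0.5 px per channel).  The
    ground-truth ``area_nm2`` of each record equals the analytic area of the
    spot's 10%-of-peak isocontour.
    """
    rng = np.random.default_rng(spec.seed)
    ny, nx = spec.shape
    a100 = spec.area_um2 / 100.0   # field area in units of 100 um^2
    c = spec.coloc_fraction
    d_total = (spec.density_ch1 + spec.density_ch2) / (1.0 + c)
    lam_both = c * d_total
    lam_only1 = spec.density_ch1 - lam_both
    lam_only2 = spec.density_ch2 - lam_both
    eps = 1e-9 * max(spec.density_ch1 + spec.density_ch2, 1.0)
    if lam_only1 < -eps or lam_only2 < -eps:
        raise ValueError(
            "coloc_fraction incompatible with the per-channel densities: "
            "the implied single-channel rate is negative")
    n_both = rng.poisson(lam_both * a100)
    n_only1 = rng.poisson(max(lam_only1, 0.0) * a100)
    n_only2 = rng.poisson(max(lam_only2, 0.0) * a100)
    n_total = n_both + n_only1 + n_only2

    width_nm = spec.field_width * 1000.0
    height_nm = spec.field_height * 1000.0
    pos_nm = _hardcore_positions(rng, n_total, width_nm, height_nm,
                                 spec.min_separation_nm)

    membership = (["both"] * n_both + ["ch1"] * n_only1 + ["ch2"] * n_only2)
    image = np.zeros((2, ny, nx), dtype=np.float64)
    rows = []
    px = spec.pixel_size
    for eid, (kind, p) in enumerate(zip(membership, pos_nm)):
        channels = (1, 2) if kind == "both" else ((1,) if kind == "ch1" else (2,))
        for ch in channels:
            jitter = rng.uniform(-0.5, 0.5, size=2)  # px, per channel
            cx = p[0] / px + jitter[0]
            cy = p[1] / px + jitter[1]
            area_nm2 = float(np.exp(rng.normal(spec.punctum_area_mu,
                                               spec.punctum_area_sigma)))
            # 10%-of-peak contour area = 2*pi*sx*sy*ln(10)  (pixel units)
            s2 = area_nm2 / (2.0 * np.pi * _LN10 * px * px)
            rho = rng.uniform(*spec.aspect_range)
            sx = float(np.sqrt(s2 * rho))
            sy = float(np.sqrt(s2 / rho))
            theta = float(rng.uniform(0.0, np.pi))
            amp = float(rng.uniform(*spec.amplitude_range))
            _render_spot(image[ch - 1], cx, cy, amp, sx, sy, theta)
            rows.append((eid, ch, cx, cy, area_nm2, amp, sx, sy, theta,
                         kind == "both"))

    image += spec.background_level
    image += rng.normal(0.0, spec.noise_sd, size=image.shape)
    np.clip(image, 0.0, 65535.0, out=image)

    truth = pd.DataFrame(
        rows, columns=["entity_id", "channel", "x_px", "y_px", "area_nm2",
                       "amplitude", "sigma_x_px", "sigma_y_px", "theta",
                       "colocalized"])
    return image.astype(np.float32), truth


# --------------------------------------------------------------------------
# FIB-SEM-like labeled volumes
# --------------------------------------------------------------------------

@dataclass
class EmVolumeSpec:
    """Parameters of a synthetic FIB-SEM-like labeled volume.

    Voxels are anisotropic (default 5 x 5 x 20 nm, the acquisition geometry);
    the default extent is a desk-scale 5.12 x 3.84 x 1.6 um block.  Synapse
    SAS areas are log-normal per type on the log-nm^2 scale (defaults from
    the measured AS/SS distributions); AS and SS differ by PSD plate
    thickness (40 vs 20 nm against a 15 nm presynaptic plate).
    """

    dims: tuple[float, float, float] = (5.12, 3.84, 1.6)  # um (x, y, z)
    voxel_size: tuple[float, float, float] = (5.0, 5.0, 20.0)  # nm (dx,dy,dz)
    as_density: float = 2.1307        # synapses / um^3
    ss_density: float = 0.098         # ~4.4% of the total mixture
    sas_mu_as: float = 10.54          # log nm^2
    sas_sigma_as: float = 0.64
    sas_mu_ss: float = 10.70
    sas_sigma_ss: float = 0.69
    psd_thickness_as: float = 40.0    # nm
    psd_thickness_ss: float = 20.0
    presynaptic_thickness: float = 15.0
    cleft_nm: float = 20.0
    curvature_factor: float = 2.5     # sphere radius = factor * disc radius
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.dims):
            raise ValueError("volume dimensions must be positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel dimensions must be positive")
        if self.as_density < 0 or self.ss_density < 0:
            raise ValueError("densities must be non-negative")

    @classmethod
    def acquisition_field(cls, depth_um: float = 1.6, **kw) -> "EmVolumeSpec":
        """Spec with the full 10.24 x 7.68 um acquisition field of view."""
        return cls(dims=(10.24, 7.68, depth_um), **kw)

    @property
    def shape(self) -> tuple[int, int, int]:
        """Volume shape (nz, ny, nx)."""
        dx, dy, dz = self.voxel_size
        return (int(round(self.dims[2] * 1000.0 / dz)),
                int(round(self.dims[1] * 1000.0 / dy)),
                int(round(self.dims[0] * 1000.0 / dx)))

    @property
    def volume_um3(self) -> float:
        return self.dims[0] * self.dims[1] * self.dims[2]


def _random_unit_vector(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def sample_synapse_params(rng, spec: EmVolumeSpec, syn_type: str) -> dict:
    """Draw geometry for one synapse: a spherical-cap plate pair.

    The SAS midsurface is a spherical cap of area exactly ``area_nm2``
    (2*pi*R*h with cap height h = area/(2*pi*R)); the PSD plate sits on the
    convex side, the presynaptic plate on the concave side, separated by the
    cleft.
    """
    if syn_type == "AS":
        mu, sigma, t_post = spec.sas_mu_as, spec.sas_sigma_as, spec.psd_thickness_as
    else:
        mu, sigma, t_post = spec.sas_mu_ss, spec.sas_sigma_ss, spec.psd_thickness_ss
    area = float(np.exp(rng.normal(mu, sigma)))
    disc_r = float(np.sqrt(area / np.pi))
    R = spec.curvature_factor * disc_r
    h = area / (2.0 * np.pi * R)
    h = min(h, R)                      # guard extreme draws
    rim_r = float(np.sqrt(max(2.0 * R * h - h * h, 0.0)))
    return dict(type=syn_type, area_nm2=area, sphere_r=R, cap_h=h,
                rim_r=rim_r, normal=_random_unit_vector(rng),
                t_post=t_post, t_pre=spec.presynaptic_thickness,
                cleft=spec.cleft_nm)


def synapse_extent_nm(params: dict) -> float:
    """Conservative bounding radius around the synapse center."""
    return params["rim_r"] + params["t_post"] + params["t_pre"] + \
        params["cleft"] + 2.0 * params["cap_h"] + 40.0


def rasterize_synapse(params: dict, center_nm, voxel_size, shape,
                      origin_nm=(0.0, 0.0, 0.0)):
    """Voxelize one synapse into boolean (pre, post) masks.

    ``shape`` is (nz, ny, nx); coordinates are physical nm with the voxel
    center of index (k, j, i) at origin + ((i+.5)dx, (j+.5)dy, (k+.5)dz).
    Returns ``(slices, pre, post)`` where ``slices`` index the enclosing
    subvolume and the masks are defined on that subvolume.  Plates are
    radial shells around the cap's sphere center; each voxel is included if
    the radial interval it spans intersects the shell, which keeps plates
    thinner than a voxel watertight.
    """
    dx, dy, dz = voxel_size
    ext = synapse_extent_nm(params)
    cx, cy, cz = center_nm
    i0 = max(int((cx - origin_nm[0] - ext) / dx), 0)
    i1 = min(int((cx - origin_nm[0] + ext) / dx) + 2, shape[2])
    j0 = max(int((cy - origin_nm[1] - ext) / dy), 0)
    j1 = min(int((cy - origin_nm[1] + ext) / dy) + 2, shape[1])
    k0 = max(int((cz - origin_nm[2] - ext) / dz), 0)
    k1 = min(int((cz - origin_nm[2] + ext) / dz) + 2, shape[0])
    if i0 >= i1 or j0 >= j1 or k0 >= k1:
        empty = np.zeros((0, 0, 0), dtype=bool)
        return (slice(0, 0), slice(0, 0), slice(0, 0)), empty, empty

    xs = origin_nm[0] + (np.arange(i0, i1) + 0.5) * dx - cx
    ys = origin_nm[1] + (np.arange(j0, j1) + 0.5) * dy - cy
    zs = origin_nm[2] + (np.arange(k0, k1) + 0.5) * dz - cz
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")

    u = params["normal"]
    R, h = params["sphere_r"], params["cap_h"]
    # sphere center placed so the cap rim plane passes near the synapse center
    C = -u * (R - h)
    PX, PY, PZ = X - C[0], Y - C[1], Z - C[2]
    d = np.sqrt(PX * PX + PY * PY + PZ * PZ)
    axial = PX * u[0] + PY * u[1] + PZ * u[2]
    lateral2 = np.maximum(d * d - axial * axial, 0.0)
    # both plates share one lateral footprint (a cylinder of the rim
    # radius): the pre- and postsynaptic densities have matched extents,
    # and equal footprints keep plate volume proportional to thickness on
    # either side of the curved cleft
    in_cap = (axial > 0) & (lateral2 <= params["rim_r"] ** 2)
    # radial half-span of a voxel along the local radial direction
    rx, ry, rz = (np.abs(PX) / np.maximum(d, 1e-9),
                  np.abs(PY) / np.maximum(d, 1e-9),
                  np.abs(PZ) / np.maximum(d, 1e-9))
    half = 0.5 * (rx * dx + ry * dy + rz * dz)
    g2 = 0.5 * params["cleft"]
    post_lo, post_hi = R + g2, R + g2 + params["t_post"]
    pre_lo, pre_hi = R - g2 - params["t_pre"], R - g2
    post = in_cap & (d + half >= post_lo) & (d - half <= post_hi)
    pre = in_cap & (d + half >= pre_lo) & (d - half <= pre_hi)
    return (slice(k0, k1), slice(j0, j1), slice(i0, i1)), pre, post


def make_em_volume(spec: EmVolumeSpec):
    """Build a labeled FIB-SEM-like volume.

    Returns ``(labels, truth)``: ``labels`` is a uint32 array of shape
    (nz, ny, nx) where synapse ``id`` (1-based) stores its postsynaptic
    density as ``2*id`` and its presynaptic plate as ``2*id + 1``; ``truth``
    has one row per synapse (id, type, center x/y/z in um, true SAS area in
    nm^2, plate thicknesses).  Counts per type are Poisson with mean
    density x volume; centers are hard-core so objects never overlap.
    Centers may fall near the boundary, in which case the object is clipped
    (as in a real acquisition).
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    vol = spec.volume_um3
    n_as = rng.poisson(spec.as_density * vol)
    n_ss = rng.poisson(spec.ss_density * vol)
    types = ["AS"] * n_as + ["SS"] * n_ss
    params = [sample_synapse_params(rng, spec, t) for t in types]
    radii = np.array([p["rim_r"] + p["t_post"] + p["t_pre"] for p in params])

    dims_nm = np.array(spec.dims) * 1000.0
    centers = np.zeros((len(params), 3))
    placed: list[np.ndarray] = []
    budget = 400 * max(len(params), 1)
    tries = 0
    order = np.argsort(-radii)         # place big ones first
    for idx in order:
        while True:
            if tries >= budget:
                raise PlacementError(
                    "could not place all synapses without overlap; "
                    "requested density too high for this volume")
            c = rng.uniform([0, 0, 0], dims_nm)
            tries += 1
            ok = True
            for j, q in enumerate(placed):
                lim = radii[idx] + radii[order[j]] + 10.0
                if np.sum((c - q) ** 2) < lim * lim:
                    ok = False
                    break
            if ok:
                centers[idx] = c
                placed.append(c)
                break

    labels = np.zeros(shape, dtype=np.uint32)
    rows = []
    for sid, (p, c) in enumerate(zip(params, centers), start=1):
        sl, pre, post = rasterize_synapse(p, c, spec.voxel_size, shape)
        region = labels[sl]
        region[post & (region == 0)] = 2 * sid
        region[pre & (region == 0)] = 2 * sid + 1
        rows.append((sid, p["type"], c[0] / 1000.0, c[1] / 1000.0,
                     c[2] / 1000.0, p["area_nm2"], p["t_post"], p["t_pre"]))
    truth = pd.DataFrame(rows, columns=["id", "type", "x_um", "y_um", "z_um",
                                        "sas_area_nm2", "t_post_nm",
                                        "t_pre_nm"])
    return labels, truth


def label_map(truth: pd.DataFrame) -> dict:
    """JSON-serializable map synapse id -> component labels and type."""
    return {int(r.id): {"post": int(2 * r.id), "pre": int(2 * r.id + 1),
                        "type": str(r.type)}
            for r in truth.itertuples()}


# --------------------------------------------------------------------------
# Region density tables
# --------------------------------------------------------------------------

#: Fixture rows kept in every generated table: a low-density thalamic-like
#: and a high-density thalamic-like region (totals 19.78 and 110.15 per
#: 100 um^2) pin the extrapolation arithmetic in regression tests.
FIXTURE_REGIONS = (
    ("ventral-medial-like", 19.78),
    ("posterior-complex-like", 110.15),
)


def make_region_table(n_regions: int, density_range=(10.0, 160.0),
                      coloc_range=(0.3, 0.8), seed: int = 0) -> pd.DataFrame:
    """Synthesize a per-region puncta density table.

    Returns columns ``region, dPSD95, dSAP102, c``; two fixed fixture rows
    with total densities 19.78 and 110.15 puncta/100 um^2 are always
    appended after ``n_regions`` random rows.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_regions):
        c = float(rng.uniform(*coloc_range))
        d_total = float(rng.uniform(*density_range))
        split = float(rng.uniform(0.35, 0.65))
        s = d_total * (1.0 + c)
        rows.append((f"region-{i:03d}", split * s, (1.0 - split) * s, c))
    for name, d_total in FIXTURE_REGIONS:
        c = 0.5
        s = d_total * (1.0 + c)
        rows.append((name, 0.5 * s, 0.5 * s, c))
    return pd.DataFrame(rows, columns=["region", "dPSD95", "dSAP102", "c"])


# --------------------------------------------------------------------------
# I/O helpers
# --------------------------------------------------------------------------

def write_field(path, image, truth, spec: PunctaFieldSpec) -> None:
    """Write a field as 16-bit TIFF + ground-truth CSV + JSON sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, np.round(image).astype(np.uint16))
    truth.to_csv(path.with_suffix(".truth.csv"), index=False)
    path.with_suffix(".spec.json").write_text(
        json.dumps(asdict(spec), indent=2, default=list))


def write_volume(path, labels, truth, spec: EmVolumeSpec) -> None:
    """Write a labeled volume as multipage TIFF + CSV + JSON label map."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, labels)
    truth.to_csv(path.with_suffix(".truth.csv"), index=False)
    sidecar = {"spec": asdict(spec), "labels": label_map(truth)}
    path.with_suffix(".labels.json").write_text(
        json.dumps(sidecar, indent=2, default=list))
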