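"""Sector <-> rectangle scan conversion via thin-plate splines.

B-mode frames are displayed as a sector (apex at the top, beam pointing
down) while propagation is computed on a rectangular grid of scanlines
(row = depth sample, column = scanline).  The two grids are linked by paired
landmarks — rectangle node ``(i, j)`` versus the sector point at radius
``r_s + i * depth_step`` and angle ``-fov/2 + j * fov/(n-1)`` from the apex —
and a thin-plate spline fitted to those landmarks.  The TPS minimizes the
classical bending-energy functional; its solution splits into a global
affine part ``A`` and a kernel warp ``W`` (kernel ``U(r) = r^2 log r``),
separated here with the standard QR trick so that the warp carries no
affine content.  With regularization ``lambda = 0`` the landmarks are
matched exactly.

Slice extraction samples the CT volume on the plane spanned by the beam
direction and the in-plane lateral axis of the probe pose, trilinearly, on a
regular mm grid that covers the sector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .volume_io import CTVolume

__all__ = [
    "SectorGeometry",
    "TPSTransform",
    "ScanlineSet",
    "ProbePose",
    "SliceImage",
    "build_correspondences",
    "tps_fit",
    "tps_apply",
    "tps_bending_energy",
    "fit_sector_transforms",
    "extract_sector_slice",
    "resample_to_rectangle",
    "map_to_sector",
]


@dataclass
class SectorGeometry:
    """Field of view, radii and sampling of one sector.

    Angles in degrees; radii and apex in slice mm.  ``axis_angle = 0`` means
    the beam center points straight down (+y in slice coordinates); positive
    angles rotate counter-clockwise.  ``m`` radial and ``n`` tangential
    samples fix the resolution of the simulated frame.
    """

    fov: float = 75.0
    r_short: float = 10.0
    r_long: float = 130.0
    m: int = 101
    n: int = 100
    apex: tuple = (0.0, 0.0)
    axis_angle: float = 0.0

    def __post_init__(self):
        if not 0 < self.fov < 180:
            raise ValueError(f"fov must be in (0, 180) degrees, got {self.fov}")
        if not 0 <= self.r_short < self.r_long:
            raise ValueError(
                f"need 0 <= r_short < r_long, got {self.r_short}, {self.r_long}"
            )
        if self.m < 2 or self.n < 2:
            raise ValueError("m and n must both be >= 2")
        self.apex = tuple(float(a) for a in self.apex)

    @property
    def depth_step(self) -> float:
        """mm between consecutive radial samples."""
        return (self.r_long - self.r_short) / (self.m - 1)

    def ray_direction(self, angle_offset_deg: np.ndarray) -> np.ndarray:
        """Unit direction(s) for angles measured from the central axis."""
        a = np.deg2rad(self.axis_angle + np.asarray(angle_offset_deg, float))
        return np.stack([np.sin(a), np.cos(a)], axis=-1)

    def polar(self, points: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """(radius mm, angle deg from central axis) of slice-coordinate points."""
        p = np.asarray(points, float) - np.asarray(self.apex)
        r = np.hypot(p[..., 0], p[..., 1])
        ang = np.rad2deg(np.arctan2(p[..., 0], p[..., 1])) - self.axis_angle
        return r, ang

    def bounding_box(self, margin: float = 0.0) -> Tuple[float, float, float, float]:
        """(x0, y0, x1, y1) slice-mm box containing the whole sector."""
        offsets = np.linspace(-self.fov / 2, self.fov / 2, 181)
        dirs = self.ray_direction(offsets)
        pts = np.concatenate(
            [np.asarray(self.apex) + self.r_short * dirs,
             np.asarray(self.apex) + self.r_long * dirs]
        )
        x0, y0 = pts.min(axis=0) - margin
        x1, y1 = pts.max(axis=0) + margin
        return float(x0), float(y0), float(x1), float(y1)


@dataclass
class TPSTransform:
    """Fitted thin-plate spline: global affine + non-affine kernel warp.

    ``affine`` is homogeneous 3x3 acting on row vectors ``[x, y, 1]``;
    ``warp`` is (n_ctrl, 2) with zero net affine content (columns orthogonal
    to ``[1 | q]`` by the QR construction).
    """

    affine: np.ndarray
    warp: np.ndarray
    control_points: np.ndarray
    kernel: str = "r2logr"
    lambda_reg: float = 0.0

    def __post_init__(self):
        if self.warp.shape[0] != self.control_points.shape[0]:
            raise ValueError("warp rows must equal number of control points")


@dataclass
class ScanlineSet:
    """m x n rectangular sample grid (row = depth, column = scanline)."""

    rect: np.ndarray
    geometry: SectorGeometry
    depth_step: float

    def __post_init__(self):
        expected = self.geometry.depth_step
        if abs(self.depth_step - expected) > 1e-9 * max(1.0, expected):
            raise ValueError("depth_step inconsistent with geometry")


@dataclass
class ProbePose:
    """Apex position (mm, world), beam direction, and in-plane lateral axis."""

    apex: tuple = (0.0, 0.0, 0.0)
    beam_dir: tuple = (0.0, 1.0, 0.0)
    in_plane: tuple = (1.0, 0.0, 0.0)

    def frame(self) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Orthonormal (apex, lateral_hat, beam_hat); errors if degenerate."""
        apex = np.asarray(self.apex, float)
        b = np.asarray(self.beam_dir, float)
        l = np.asarray(self.in_plane, float)
        nb = np.linalg.norm(b)
        if nb == 0:
            raise ValueError("beam direction must be nonzero")
        b = b / nb
        l = l - (l @ b) * b
        nl = np.linalg.norm(l)
        if nl < 1e-9:
            raise ValueError("in-plane direction is parallel to the beam")
        return apex, l / nl, b


@dataclass
class SliceImage:
    """2D mm-gridded slice: data[row, col] at (origin + (col, row) * pitch)."""

    data: np.ndarray
    origin: tuple
    pitch: float
    geometry: Optional[SectorGeometry] = None

    def sample(self, points: np.ndarray, cval: float = 0.0) -> np.ndarray:
        """Bilinear sample at slice-mm points (N, 2)."""
        p = np.asarray(points, float)
        cols = (p[..., 0] - self.origin[0]) / self.pitch
        rows = (p[..., 1] - self.origin[1]) / self.pitch
        return ndimage.map_coordinates(
            np.asarray(self.data, float),
            [rows.ravel(), cols.ravel()],
            order=1, mode="constant", cval=cval,
        ).reshape(p.shape[:-1])


# ---------------------------------------------------------------------------
# correspondences
# ---------------------------------------------------------------------------


def build_correspondences(
    geometry: SectorGeometry, control: Optional[int] = None
) -> Tuple[np.ndarray, np.ndarray]:
    """Paired landmarks (sector points p, rectangle points q).

    Rectangle point ``(col=j, row=i)`` pairs with the sector point at radius
    ``r_short + i * depth_step`` and angle ``-fov/2 + j * fov/(n-1)`` from
    the apex, so arc length is uniform along each row.  With ``control=k``
    the full m x n lattice is subsampled to at most k x k nodes (the TPS
    normal equations are cubic in landmark count).
    """
    g = geometry
    rows = np.arange(g.m)
    cols = np.arange(g.n)
    if control is not None and control >= 2:
        rows = np.unique(np.round(np.linspace(0, g.m - 1, min(control, g.m))).astype(int))
        cols = np.unique(np.round(np.linspace(0, g.n - 1, min(control, g.n))).astype(int))
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    radii = g.r_short + rr * g.depth_step
    angles = -g.fov / 2 + cc * (g.fov / (g.n - 1))
    dirs = g.ray_direction(angles)
    p = np.asarray(g.apex) + radii[..., None] * dirs
    q = np.stack([cc, rr], axis=-1).astype(float)  # (x=col, y=row)
    return p.reshape(-1, 2), q.reshape(-1, 2)


# ---------------------------------------------------------------------------
# thin-plate spline
# ---------------------------------------------------------------------------


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log r, evaluated from squared distances; U(0) = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 0.5 * r2 * np.log(np.where(r2 > 0, r2, 1.0))
    return np.where(r2 > 0, out, 0.0)


def _kernel_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
    return _tps_kernel(d2)


def tps_fit(p: np.ndarray, q: np.ndarray, lambda_reg: float = 0.0) -> TPSTransform:
    """Fit the TPS mapping source landmarks ``q`` onto targets ``p``.

    Minimizes ``sum ||p_i - f(q_i)||^2 + lambda * bending`` over maps of the
    form ``f(x) = [x, 1] A + U(||x - q||) W``.  QR separation: with
    ``P = [1 | q] = [Q1 Q2][R1; 0]``,

    ``W = Q2 (Q2' K Q2 + lambda I)^-1 Q2' p``,
    ``A = R1^-1 Q1' (p - K W)``,

    which enforces ``P' W = 0`` (no affine content in the warp) and, at
    ``lambda = 0``, exact landmark interpolation.
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 2:
        raise ValueError("p and q must both be (n, 2) with equal n")
    n = p.shape[0]
    if n < 3:
        raise ValueError("at least 3 landmarks are required")
    if lambda_reg < 0:
        raise ValueError("lambda_reg must be >= 0")
    P = np.column_stack([np.ones(n), q])
    if np.linalg.matrix_rank(P) < 3:
        raise np.linalg.LinAlgError("landmarks are collinear; TPS fit is rank-deficient")
    K = _kernel_matrix(q, q)
    Q, R = np.linalg.qr(P, mode="complete")
    Q1, Q2 = Q[:, :3], Q[:, 3:]
    R1 = R[:3, :]
    core = Q2.T @ K @ Q2 + lambda_reg * np.eye(n - 3)
    W = Q2 @ np.linalg.solve(core, Q2.T @ p)
    A_mat = np.linalg.solve(R1, Q1.T @ (p - K @ W))  # rows: [const, x, y]
    affine = np.eye(3)
    affine[0, :2] = A_mat[1]
    affine[1, :2] = A_mat[2]
    affine[2, :2] = A_mat[0]
    return TPSTransform(
        affine=affine, warp=W, control_points=q.copy(),
        kernel="r2logr", lambda_reg=float(lambda_reg),
    )


def tps_apply(transform: TPSTransform, points: np.ndarray) -> np.ndarray:
    """Evaluate the fitted map at arbitrary 2D points (shape (..., 2))."""
    pts = np.asarray(points, float)
    flat = pts.reshape(-1, 2)
    hom = np.column_stack([flat, np.ones(len(flat))])
    out = hom @ transform.affine[:, :2]
    out += _kernel_matrix(flat, transform.control_points) @ transform.warp
    return out.reshape(pts.shape)


def tps_bending_energy(transform: TPSTransform) -> float:
    """trace(W' K W): the thin-plate bending energy of the fitted warp."""
    K = _kernel_matrix(transform.control_points, transform.control_points)
    return float(np.trace(transform.warp.T @ K @ transform.warp))


def fit_sector_transforms(
    geometry: SectorGeometry, control: int = 10, lambda_reg: float = 0.0
) -> Tuple[TPSTransform, TPSTransform]:
    """(forward rect->sector, inverse sector->rect) TPS pair for a sector."""
    p, q = build_correspondences(geometry, control=control)
    return tps_fit(p, q, lambda_reg), tps_fit(q, p, lambda_reg)


# ---------------------------------------------------------------------------
# slice extraction and resampling
# ---------------------------------------------------------------------------


def extract_sector_slice(
    volume: CTVolume,
    pose: ProbePose,
    geometry: SectorGeometry,
    pitch: float = 1.0,
    background: float = -1000.0,
    margin: float = 4.0,
) -> SliceImage:
    """Trilinearly sample the probe plane onto a regular mm grid.

    The slice frame puts the apex at (0, 0) with the beam along +y; the grid
    covers the sector's bounding box plus ``margin`` mm.  Samples outside
    the volume read ``background`` (air by default).
    """
    if pitch <= 0:
        raise ValueError("pitch must be > 0")
    apex3, l_hat, b_hat = pose.frame()
    in_slice = SectorGeometry(
        fov=geometry.fov, r_short=geometry.r_short, r_long=geometry.r_long,
        m=geometry.m, n=geometry.n, apex=(0.0, 0.0), axis_angle=geometry.axis_angle,
    )
    x0, y0, x1, y1 = in_slice.bounding_box(margin)
    xs = x0 + pitch * np.arange(int(np.ceil((x1 - x0) / pitch)) + 1)
    ys = y0 + pitch * np.arange(int(np.ceil((y1 - y0) / pitch)) + 1)
    XX, YY = np.meshgrid(xs, ys)  # rows follow y
    world = apex3[None, None, :] + XX[..., None] * l_hat + YY[..., None] * b_hat
    spacing = np.asarray(volume.spacing)
    origin = np.asarray(volume.origin)
    idx = (world - origin) / spacing  # voxel-centered continuous indices
    data = ndimage.map_coordinates(
        np.asarray(volume.data, float),
        [idx[..., 0].ravel(), idx[..., 1].ravel(), idx[..., 2].ravel()],
        order=1, mode="constant", cval=float(background),
    ).reshape(XX.shape)
    return SliceImage(data=data, origin=(float(x0), float(y0)), pitch=float(pitch),
                      geometry=in_slice)


def resample_to_rectangle(
    slice_img: SliceImage,
    geometry: SectorGeometry,
    transform: TPSTransform,
    cval: float = -1000.0,
) -> ScanlineSet:
    """Sample the slice at the TPS image of every rectangle grid node."""
    cols, rows = np.meshgrid(np.arange(geometry.n), np.arange(geometry.m))
    q = np.stack([cols, rows], axis=-1).astype(float)
    sector_pts = tps_apply(transform, q.reshape(-1, 2)).reshape(q.shape)
    rect = slice_img.sample(sector_pts, cval=cval)
    return ScanlineSet(rect=rect, geometry=geometry, depth_step=geometry.depth_step)


def sector_mask(
    geometry: SectorGeometry, origin: tuple, pitch: float, shape: tuple
) -> np.ndarray:
    """Boolean raster of pixels whose centers lie inside the sector."""
    ys = origin[1] + pitch * np.arange(shape[0])
    xs = origin[0] + pitch * np.arange(shape[1])
    XX, YY = np.meshgrid(xs, ys)
    r, ang = geometry.polar(np.stack([XX, YY], axis=-1))
    return (
        (r >= geometry.r_short) & (r <= geometry.r_long)
        & (np.abs(ang) <= geometry.fov / 2)
    )


def map_to_sector(
    rect_image: np.ndarray,
    geometry: SectorGeometry,
    inverse_transform: TPSTransform,
    pitch: float = 0.5,
) -> Tuple[np.ndarray, np.ndarray, tuple, float]:
    """Render an m x n rectangle image into the sector raster.

    Every pixel inside the sector mask is filled by mapping its slice-mm
    center through the inverse TPS to rectangle coordinates and bilinearly
    sampling ``rect_image``; pixels outside the mask are 0.  Returns
    ``(image, mask, origin, pitch)``.
    """
    rect_image = np.asarray(rect_image, float)
    if rect_image.shape != (geometry.m, geometry.n):
        raise ValueError(
            f"rect image shape {rect_image.shape} != (m, n)=({geometry.m}, {geometry.n})"
        )
    x0, y0, x1, y1 = geometry.bounding_box(0.0)
    nx = int(np.ceil((x1 - x0) / pitch)) + 1
    ny = int(np.ceil((y1 - y0) / pitch)) + 1
    mask = sector_mask(geometry, (x0, y0), pitch, (ny, nx))
    out = np.zeros((ny, nx), float)
    if mask.any():
        ys = y0 + pitch * np.arange(ny)
        xs = x0 + pitch * np.arange(nx)
        XX, YY = np.meshgrid(xs, ys)
        pts = np.stack([XX[mask], YY[mask]], axis=-1)
        rect_xy = tps_apply(inverse_transform, pts)  # (x=col, y=row)
        vals = ndimage.map_coordinates(
            rect_image, [rect_xy[:, 1], rect_xy[:, 0]],
            order=1, mode="nearest",
        )
        out[mask] = vals
    return out, mask, (float(x0), float(y0)), float(pitch)
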