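"""Vascular hysteresis loop (vessel vortex curve) geometry.

Plotting the spin-echo relaxation change dR2(t) on the x-axis against
the gradient-echo change dR2*(t) on the y-axis for every time point
traces a closed time-parametrized loop whose shape encodes the voxel's
vascular architecture.  Six scalars are extracted:

- orientation: +1 if the loop is traversed clockwise, -1 counter-
  clockwise, 0 degenerate.  A spin-echo curve peaking before the
  gradient-echo curve (capillary/venule-dominated tissue) produces a
  counterclockwise loop.
- VTI (vessel type indicator): orientation-signed enclosed area, 1/s^2.
- I (distance map): orientation-signed maximum separation between the
  ascending and descending branches, 1/s.
- CGI (caliber gradient indicator): slope of the loop's long axis.
- BVF: length of the long axis (tracks blood volume fraction), 1/s.
- CBI (capillary bed identifier): length of the short axis, 1/s.
- VIPS: time-to-peak difference ttp_SE - ttp_GE of the fitted curves,
  seconds; negative values indicate slow-flowing venule predominance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .relaxometry import GammaVariateFit

__all__ = [
    "VortexLoop",
    "VHLParameters",
    "build_vortex_loop",
    "loop_orientation",
    "compute_vti",
    "compute_i",
    "principal_axes",
    "compute_vips",
    "compute_vhl_parameters",
    "DEGENERATE_AREA_TOL",
]

#: enclosed areas below this (1/s)^2 are treated as degenerate (orientation 0)
DEGENERATE_AREA_TOL = 1e-12


def _shoelace(points: np.ndarray) -> float:
    """Signed polygon area; positive for counterclockwise traversal."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class VortexLoop:
    """A closed, time-ordered loop in the (dR2, dR2*) plane.

    ``points[:, 0]`` is the spin-echo axis, ``points[:, 1]`` the
    gradient-echo axis.  ``peak_split_index`` marks the point most
    distant from the origin and separates the ascending branch (bolus
    wash-in) from the descending branch (wash-out).
    """

    points: np.ndarray = field(repr=False)
    orientation: int = 0
    peak_split_index: int = 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")

    @classmethod
    def from_points(cls, points: np.ndarray) -> "VortexLoop":
        points = np.asarray(points, dtype=float)
        orient = loop_orientation(points)
        split = int(np.argmax(np.hypot(points[:, 0], points[:, 1])))
        return cls(points=points, orientation=orient, peak_split_index=split)


def loop_orientation(points: np.ndarray, tol: float = DEGENERATE_AREA_TOL) -> int:
    """Traversal direction: +1 clockwise, -1 counterclockwise, 0 degenerate.

    The shoelace signed area is positive for a counterclockwise polygon
    in standard axes, so the returned sign is the negated sign of the
    shoelace area.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        raise ValueError("need at least 3 points to orient a loop")
    area = _shoelace(points)
    if abs(area) < tol:
        return 0
    return -1 if area > 0 else 1


def build_vortex_loop(
    fit_se: GammaVariateFit,
    fit_ge: GammaVariateFit,
    grid: np.ndarray | None = None,
    n_points: int = 240,
) -> VortexLoop | None:
    """Sample both fitted curves on a dense common grid and close the loop.

    Returns ``None`` when either fit is invalid (the voxel then carries
    no loop parameters).  The loop is closed by appending the origin:
    both gamma-variate curves are exactly zero before bolus arrival and
    decay toward zero afterwards.
    """
    if not (fit_se.valid and fit_ge.valid):
        return None
    if grid is None:
        start = min(fit_se.t0, fit_ge.t0)
        end = float(fit_se.times[-1])
        grid = np.linspace(start, end, max(n_points, 200))
    grid = np.asarray(grid, dtype=float)
    pts = np.column_stack([fit_se(grid), fit_ge(grid)])
    if not np.allclose(pts[-1], 0.0):
        pts = np.vstack([pts, [0.0, 0.0]])
    return VortexLoop.from_points(pts)


def compute_vti(loop: VortexLoop) -> float:
    """Orientation-signed enclosed loop area in (1/s)^2."""
    if loop.orientation == 0:
        return 0.0
    return loop.orientation * abs(_shoelace(loop.points))


def _branch_profile(branch: np.ndarray, xgrid: np.ndarray) -> np.ndarray:
    """Interpolate a branch's y as a function of x on ``xgrid``."""
    order = np.argsort(branch[:, 0], kind="stable")
    x, y = branch[order, 0], branch[order, 1]
    return np.interp(xgrid, x, y)


def compute_i(loop: VortexLoop, n_resample: int = 256) -> float:
    """Orientation-signed maximum ascending/descending branch separation.

    Both branches are resampled at common spin-echo (x) values over
    their overlapping x-range; the separation is the vertical (dR2*)
    difference.  Returns NaN when the branches share no x-range.
    """
    if loop.orientation == 0:
        return 0.0
    split = loop.peak_split_index
    asc = loop.points[: split + 1]
    desc = loop.points[split:]
    if len(asc) < 2 or len(desc) < 2:
        return float("nan")
    lo = max(asc[:, 0].min(), desc[:, 0].min())
    hi = min(asc[:, 0].max(), desc[:, 0].max())
    if not hi > lo:
        return float("nan")
    xgrid = np.linspace(lo, hi, n_resample)
    gap = np.abs(_branch_profile(desc, xgrid) - _branch_profile(asc, xgrid))
    return loop.orientation * float(np.max(gap))


def principal_axes(loop: VortexLoop) -> tuple[float, float, float]:
    """Long/short axis geometry of the loop point cloud.

    Returns ``(bvf, cgi, cbi)``: the long-axis length (range of the
    projections onto the first principal direction), the long-axis
    slope dR2*/dR2, and the short-axis length.  Collinear point clouds
    are allowed and give ``cbi = 0``.
    """
    pts = loop.points
    if len(pts) < 3:
        raise ValueError("need at least 3 points for principal axes")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)  # ascending eigenvalues
    long_dir = evecs[:, 1]
    short_dir = evecs[:, 0]
    proj_long = centered @ long_dir
    proj_short = centered @ short_dir
    bvf = float(proj_long.max() - proj_long.min())
    cbi = float(proj_short.max() - proj_short.min())
    if long_dir[0] == 0.0:
        cgi = float("inf") if long_dir[1] != 0 else float("nan")
    else:
        cgi = float(long_dir[1] / long_dir[0])
    return bvf, cgi, cbi


def compute_vips(fit_se: GammaVariateFit, fit_ge: GammaVariateFit) -> float:
    """Peak-time shift ``ttp_SE - ttp_GE`` in seconds (fitted, sub-sample)."""
    if not (fit_se.valid and fit_ge.valid):
        return float("nan")
    return float(fit_se.ttp - fit_ge.ttp)


@dataclass
class VHLParameters:
    """The six loop-derived scalars for one voxel (NaN when missing)."""

    i: float
    vti: float
    cgi: float
    bvf: float
    cbi: float
    vips: float


def compute_vhl_parameters(
    fit_se: GammaVariateFit, fit_ge: GammaVariateFit
) -> VHLParameters:
    """All six loop parameters from one fitted curve pair."""
    loop = build_vortex_loop(fit_se, fit_ge)
    if loop is None:
        nan = float("nan")
        return VHLParameters(nan, nan, nan, nan, nan, nan)
    vti = compute_vti(loop)
    i_val = compute_i(loop)
    bvf, cgi, cbi = principal_axes(loop)
    vips = compute_vips(fit_se, fit_ge)
    return VHLParameters(i=i_val, vti=vti, cgi=cgi, bvf=bvf, cbi=cbi, vips=vips)
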