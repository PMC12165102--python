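"""Right-angled mixture-triangle (RMT) response surfaces.

The RMT projects the 3-component macronutrient simplex onto a 2D
right triangle: protein % on the x-axis, fat % on the y-axis, and
carbohydrate implicit on the hypotenuse (carb % = 100 - x - y). A fitted
Scheffé model is evaluated on a grid over the triangle, masked to the
sampled design window, contoured into isolines, and rendered as a
filled surface (red = high response, blue = low) with the design diets
overplotted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import contourpy
import numpy as np

from .diet_design import DESIGN_BOUNDS, DietComposition
from .mixture_models import MixtureModelFit, build_design_matrix

__all__ = [
    "RMTGrid",
    "RMTSurface",
    "EmptyRegionError",
    "project_rmt",
    "unproject_rmt",
    "evaluate_surface",
    "contour_isolines",
    "render_rmt",
]

log = logging.getLogger(__name__)

#: Default design-window bounds in percent: (protein, carb, fat) ranges.
DEFAULT_BOUNDS = tuple(
    (100 * lo, 100 * hi) for lo, hi in (DESIGN_BOUNDS[k] for k in ("protein", "carb", "fat"))
)


class EmptyRegionError(ValueError):
    """No grid point falls inside the requested design region."""


def project_rmt(diet: DietComposition) -> tuple[float, float]:
    """Project a composition to RMT coordinates (protein %, fat %).

    Carbohydrate is recoverable as ``100 - x - y``; the map is an
    invertible affine bijection on the simplex.
    """
    return 100.0 * diet.protein_frac, 100.0 * diet.fat_frac


def unproject_rmt(x: float, y: float, label: str = "pt") -> DietComposition:
    """Inverse of :func:`project_rmt`: (protein %, fat %) back to a composition."""
    p = x / 100.0
    f = y / 100.0
    return DietComposition(label, p, 1.0 - p - f, f)


@dataclass(frozen=True)
class RMTGrid:
    """Regular grid over the RMT with an inside-design-region mask.

    ``xs`` and ``ys`` are the protein % and fat % axes; ``mask[i, j]``
    is True where the point (xs[j], ys[i]) lies inside the design
    window (and hence inside the triangle x >= 0, y >= 0, x + y <= 100).
    """

    xs: np.ndarray
    ys: np.ndarray
    mask: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        if self.mask.shape != (len(self.ys), len(self.xs)):
            raise ValueError("mask shape must be (len(ys), len(xs))")

    @property
    def mesh(self) -> tuple[np.ndarray, np.ndarray]:
        return np.meshgrid(self.xs, self.ys)


@dataclass(frozen=True)
class RMTSurface:
    """Predicted response on an RMT grid; NaN outside the mask."""

    grid: RMTGrid
    values: np.ndarray
    fit: MixtureModelFit | None = None

    def __post_init__(self) -> None:
        if self.values.shape != self.grid.mask.shape:
            raise ValueError("values shape must match grid mask shape")

    @property
    def value_range(self) -> tuple[float, float]:
        inside = self.values[self.grid.mask]
        return float(np.min(inside)), float(np.max(inside))


def _make_grid(bounds, resolution: float, hull_points: np.ndarray | None = None) -> RMTGrid:
    (p_lo, p_hi), (c_lo, c_hi), (f_lo, f_hi) = bounds
    if not (0 < resolution < 100):
        raise ValueError(f"resolution must be in (0, 100), got {resolution}")
    xs = np.arange(0.0, 100.0 + resolution / 2, resolution)
    ys = xs.copy()
    X, Y = np.meshgrid(xs, ys)
    C = 100.0 - X - Y
    mask = (
        (X >= p_lo) & (X <= p_hi)
        & (Y >= f_lo) & (Y <= f_hi)
        & (C >= c_lo) & (C <= c_hi)
    )
    if hull_points is not None:
        from scipy.spatial import Delaunay

        tri = Delaunay(hull_points)
        pts = np.column_stack([X.ravel(), Y.ravel()])
        mask &= (tri.find_simplex(pts) >= 0).reshape(mask.shape)
    return RMTGrid(xs=xs, ys=ys, mask=mask, resolution=resolution)


def evaluate_surface(
    fit: MixtureModelFit,
    bounds=DEFAULT_BOUNDS,
    resolution: float = 1.0,
    design=None,
    hull_mask: bool = False,
) -> RMTSurface:
    """Evaluate a fitted mixture model over the masked RMT grid.

    Parameters
    ----------
    fit
        A fitted Scheffé model.
    bounds
        ((p_lo, p_hi), (c_lo, c_hi), (f_lo, f_hi)) in percent; the grid
        is masked to this window — no extrapolation outside it. Defaults
        to the sampled 5-60 / 20-75 / 20-75 window.
    resolution
        Grid step in percent (default 1).
    design
        Optional design whose diets are stored for overplotting; with
        ``hull_mask=True`` the mask is additionally restricted to the
        convex hull of the design diets.
    """
    hull = None
    if hull_mask:
        if design is None:
            raise ValueError("hull_mask=True requires a design")
        hull = np.array([project_rmt(d) for d in design])
    grid = _make_grid(bounds, resolution, hull)
    if not grid.mask.any():
        raise EmptyRegionError(f"no grid point inside bounds {bounds} at resolution {resolution}")
    X, Y = grid.mesh
    values = np.full(grid.mask.shape, np.nan)
    ii, jj = np.nonzero(grid.mask)
    comps = [
        DietComposition("g", X[i, j] / 100.0, (100.0 - X[i, j] - Y[i, j]) / 100.0, Y[i, j] / 100.0)
        for i, j in zip(ii, jj)
    ]
    dm = build_design_matrix(comps, fit.model_id)
    values[ii, jj] = dm @ fit.coefficients
    return RMTSurface(grid=grid, values=values, fit=fit)


def contour_isolines(surface: RMTSurface, levels) -> list[dict]:
    """Marching-squares isolines of the surface at the given levels.

    Levels outside the observed value range are skipped with a logged
    warning. Returns one dict per polyline: ``{"level", "x", "y",
    "segment_id"}``; polylines are clipped to the mask (NaN cells break
    contours).
    """
    lo, hi = surface.value_range
    z = np.ma.masked_invalid(surface.values)
    X, Y = surface.grid.mesh
    gen = contourpy.contour_generator(X, Y, z)
    out: list[dict] = []
    seg_id = 0
    for level in sorted(levels):
        if not (lo <= level <= hi):
            log.warning("isoline level %s outside surface range [%g, %g]; skipped", level, lo, hi)
            continue
        for line in gen.lines(level):
            arr = np.asarray(line)
            if len(arr) < 2:
                continue
            out.append(
                {"level": float(level), "x": arr[:, 0], "y": arr[:, 1], "segment_id": seg_id}
            )
            seg_id += 1
    return out


def render_rmt(
    surface: RMTSurface,
    path,
    levels=None,
    design=None,
    palette: str = "RdBu_r",
    title: str | None = None,
):
    """Render the surface to a figure file (PNG or SVG).

    Filled response surface (red high, blue low by default; pass
    ``palette="RdYlGn"`` for the red-to-green variant), labelled
    isolines, and design diets overplotted as circles. Output is
    deterministic for a fixed surface: fixed style, no timestamps.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not surface.grid.mask.any():
        raise EmptyRegionError("cannot render a surface with an empty mask")
    lo, hi = surface.value_range
    if levels is None:
        levels = np.linspace(lo, hi, 9)[1:-1]

    X, Y = surface.grid.mesh
    z = np.ma.masked_invalid(surface.values)
    fig, ax = plt.subplots(figsize=(5, 5))
    filled = ax.contourf(X, Y, z, levels=64, cmap=palette)
    if hi > lo:
        cs = ax.contour(X, Y, z, levels=levels, colors="k", linewidths=0.6)
        ax.clabel(cs, fmt="%.3g", fontsize=7)
    if design is not None:
        pts = np.array([project_rmt(d) for d in design])
        ax.scatter(pts[:, 0], pts[:, 1], facecolor="none", edgecolor="k", s=45, zorder=5)
    ax.plot([0, 100], [100, 0], color="0.4", lw=0.8)  # hypotenuse: carb = 0
    ax.set_xlim(0, 100)
    ax.set_ylim(0, 100)
    ax.set_xlabel("Protein (% energy)")
    ax.set_ylabel("Fat (% energy)")
    ax.set_aspect("equal")
    if title:
        ax.set_title(title)
    fig.colorbar(filled, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=150, metadata=_no_timestamp_metadata(str(path)))
    plt.close(fig)
    return path


def _no_timestamp_metadata(path: str) -> dict | None:
    if path.endswith(".svg"):
        return {"Date": None}
    if path.endswith(".png"):
        return {"Software": "nutrigeom"}
    return None


def isolines_to_frame(isolines: list[dict]):
    """Flatten isoline polylines to a table ``level,x,y,segment_id``."""
    import pandas as pd

    rows = []
    for seg in isolines:
        for x, y in zip(seg["x"], seg["y"]):
            rows.append({"level": seg["level"], "x": x, "y": y, "segment_id": seg["segment_id"]})
    return pd.DataFrame(rows, columns=["level", "x", "y", "segment_id"])
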