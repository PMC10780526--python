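"""Randomized dielectric phantom synthesis.

Phantoms are built by superimposing 6–24 randomly posed ellipses and convex
polygons inside a circular imaging region, each carrying a random relative
permittivity in [10, 80] and conductivity in [0.2, 2.5] S/m — the span of
most human tissues (fat ~10–15, bone ~11–21, skin ~38–45, brain ~45–53,
CSF ~66–70 in permittivity). Where shapes overlap, their property values
add; the per-case object-support values are then affinely rescaled back
into the design intervals. Everything outside the imaging circle is the
matching medium (εr 40, σ 0.1 S/m) that couples the antennas to the
tissue-like interior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Literal, Sequence

import numpy as np
from matplotlib.path import Path as MplPath

from .config import ConfigError, DomainConfig


class GeometryError(ValueError):
    """Raised for degenerate geometric inputs."""


@dataclass(frozen=True)
class ShapeSpec:
    """One random ellipse or convex polygon with pose and dielectric values.

    ``major_axis``/``minor_axis`` are *full* axis lengths in mm. Polygons are
    inscribed in the (rotated) ellipse defined by the same axes.
    """

    kind: Literal["ellipse", "polygon"]
    center: tuple[float, float]         # mm, domain coordinates
    major_axis: float                   # mm
    minor_axis: float                   # mm
    rotation: float                     # degrees in [0, 360)
    eps_value: float                    # relative permittivity
    sigma_value: float                  # S/m
    n_edges: int | None = None          # polygon only
    vertex_angles: tuple[float, ...] | None = None  # polygon only, degrees

    def vertices(self) -> np.ndarray:
        """Polygon vertices (n_edges, 2) in mm, domain coordinates."""
        if self.kind != "polygon":
            raise GeometryError("vertices() is only defined for polygons")
        ang = np.deg2rad(np.asarray(self.vertex_angles, dtype=float))
        a = self.major_axis / 2.0
        b = self.minor_axis / 2.0
        local = np.column_stack([a * np.cos(ang), b * np.sin(ang)])
        th = np.deg2rad(self.rotation)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        return local @ rot.T + np.asarray(self.center)


@dataclass
class PhantomCase:
    """A rasterized phantom: solver-grid property maps plus the label image."""

    case_id: str
    shapes: list[ShapeSpec]
    eps_map: np.ndarray       # (n_cells, n_cells), relative permittivity
    sigma_map: np.ndarray     # (n_cells, n_cells), S/m
    label_eps: np.ndarray     # (label_size, label_size), relative permittivity
    group_index: int          # number of superimposed shapes


def sample_shape(rng: np.random.Generator, cfg: DomainConfig) -> ShapeSpec:
    """Draw one random shape intersecting the imaging circle.

    Kind is uniform over {ellipse, polygon}; full axis lengths are uniform in
    ``cfg.axis_range`` (major = larger draw); rotation uniform in [0, 360);
    centers uniform over the imaging disc; dielectric values independent
    uniforms over ``cfg.eps_range`` × ``cfg.sigma_range``.
    """
    kind = "ellipse" if rng.random() < 0.5 else "polygon"
    # uniform over the disc: r = R*sqrt(u)
    r = cfg.imaging_radius * np.sqrt(rng.random())
    theta = rng.random() * 2 * np.pi
    center = (r * np.cos(theta), r * np.sin(theta))
    ax1, ax2 = rng.uniform(*cfg.axis_range, size=2)
    rotation = rng.random() * 360.0
    eps_value = rng.uniform(*cfg.eps_range)
    sigma_value = rng.uniform(*cfg.sigma_range)
    n_edges = None
    vertex_angles = None
    if kind == "polygon":
        lo, hi = cfg.polygon_edges_range
        n_edges = int(rng.integers(lo, hi + 1))
        vertex_angles = tuple(np.sort(rng.random(n_edges) * 360.0))
    return ShapeSpec(
        kind=kind,
        center=center,
        major_axis=max(ax1, ax2),
        minor_axis=min(ax1, ax2),
        rotation=rotation % 360.0,
        eps_value=eps_value,
        sigma_value=sigma_value,
        n_edges=n_edges,
        vertex_angles=vertex_angles,
    )


def rasterize_shape(
    shape: ShapeSpec, cfg: DomainConfig, resolution: int | None = None
) -> np.ndarray:
    """Boolean mask of cells whose centers lie inside the shape AND the
    imaging circle.

    Ellipse membership uses the rotated quadratic form; polygon membership a
    point-in-polygon test. ``resolution`` defaults to the solver grid.
    """
    n = cfg.n_cells if resolution is None else int(resolution)
    if n < 2:
        raise ConfigError("resolution must be >= 2")
    coords = cfg.cell_centers(n)
    xx, yy = np.meshgrid(coords, coords, indexing="xy")  # xx varies with column
    inside_circle = xx**2 + yy**2 <= cfg.imaging_radius**2

    if shape.kind == "ellipse":
        th = np.deg2rad(shape.rotation)
        dx = xx - shape.center[0]
        dy = yy - shape.center[1]
        u = dx * np.cos(th) + dy * np.sin(th)
        v = -dx * np.sin(th) + dy * np.cos(th)
        a = shape.major_axis / 2.0
        b = shape.minor_axis / 2.0
        member = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    else:
        verts = shape.vertices()
        if len(verts) < 3:
            raise GeometryError("polygon needs at least 3 vertices")
        # area by the shoelace formula; collinear vertices give ~0
        x, y = verts[:, 0], verts[:, 1]
        area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        if area < 1e-9:
            raise GeometryError("degenerate polygon: collinear vertices")
        path = MplPath(verts, closed=False)
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        member = path.contains_points(pts).reshape(xx.shape)
    return member & inside_circle


def _raw_sum_maps(
    shapes: Sequence[ShapeSpec], cfg: DomainConfig, resolution: int | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Additive property maps over shape masks; returns (eps, sigma, support)."""
    n = cfg.n_cells if resolution is None else int(resolution)
    eps = np.zeros((n, n))
    sigma = np.zeros((n, n))
    support = np.zeros((n, n), dtype=bool)
    for s in shapes:
        mask = rasterize_shape(s, cfg, n)
        eps[mask] += s.eps_value
        sigma[mask] += s.sigma_value
        support |= mask
    return eps, sigma, support


def _affine_params(
    raw: np.ndarray, support: np.ndarray, target: tuple[float, float]
) -> tuple[float, float]:
    """Per-case affine map sending [support min, support max] onto target.

    Returns (scale, offset) for ``scaled = scale * raw + offset``. A constant
    support keeps its value, clipped into the target interval downstream.
    """
    lo, hi = target
    vmin = float(raw[support].min())
    vmax = float(raw[support].max())
    if vmax - vmin < 1e-12:
        return 1.0, 0.0
    scale = (hi - lo) / (vmax - vmin)
    return scale, lo - scale * vmin


def compose_phantom(
    shapes: Sequence[ShapeSpec],
    cfg: DomainConfig,
    case_id: str = "case",
    group_index: int | None = None,
) -> PhantomCase:
    """Superimpose shapes into a phantom on the matching-medium background.

    Overlapping shapes add their property values; the object-support cells of
    each property are then affinely rescaled so the support minimum and
    maximum land exactly on the configured design interval. The 256×256 label
    image is rendered from the same analytic shape set (nearest-neighbour,
    not resampled from the solver grid) using the affine parameters fitted on
    the solver grid, so label and phantom agree in value.
    """
    if len(shapes) == 0:
        raise ConfigError("compose_phantom needs at least one shape")
    raw_eps, raw_sig, support = _raw_sum_maps(shapes, cfg, None)
    if not support.any():
        raise GeometryError("all shapes clipped away: empty object support")

    se, oe = _affine_params(raw_eps, support, cfg.eps_range)
    ss, os_ = _affine_params(raw_sig, support, cfg.sigma_range)

    def _apply(raw, support, scale, offset, target, background):
        out = np.full(raw.shape, background, dtype=float)
        vals = scale * raw[support] + offset
        out[support] = np.clip(vals, *target)
        return out

    eps_map = _apply(raw_eps, support, se, oe, cfg.eps_range, cfg.matching_eps)
    sigma_map = _apply(raw_sig, support, ss, os_, cfg.sigma_range, cfg.matching_sigma)

    raw_eps_l, _, support_l = _raw_sum_maps(shapes, cfg, cfg.label_size)
    label_eps = _apply(
        raw_eps_l, support_l, se, oe, cfg.eps_range, cfg.matching_eps
    )
    return PhantomCase(
        case_id=case_id,
        shapes=list(shapes),
        eps_map=eps_map,
        sigma_map=sigma_map,
        label_eps=label_eps,
        group_index=group_index if group_index is not None else len(shapes),
    )


N_GROUPS = 10


def group_shape_count(group: int, cfg: DomainConfig) -> int:
    """Shape count for database group ``group`` (0-based): 6, 8, …, 24."""
    lo, hi = cfg.n_shapes_range
    if N_GROUPS == 1:
        return lo
    stepped = lo + round(group * (hi - lo) / (N_GROUPS - 1))
    return int(stepped)


def generate_case(
    rng: np.random.Generator, cfg: DomainConfig, n_shapes: int, case_id: str
) -> PhantomCase:
    """One phantom with ``n_shapes`` superimposed random shapes.

    Retries the (rare) draw in which every shape is clipped away.
    """
    for _ in range(100):
        shapes = [sample_shape(rng, cfg) for _ in range(n_shapes)]
        try:
            return compose_phantom(shapes, cfg, case_id, group_index=n_shapes)
        except GeometryError:
            continue
    raise GeometryError("could not draw a non-empty phantom in 100 attempts")


def generate_database(
    n_cases: int,
    cfg: DomainConfig,
    seed: int,
    grouped: bool = True,
    n_shapes: int | None = None,
) -> Iterator[PhantomCase]:
    """Stream of reproducible random phantoms.

    With ``grouped=True`` (the database layout), ``n_cases`` is split into 10
    equal groups whose shape counts step from 6 up to 24. ``grouped=False``
    with ``n_shapes`` draws every case with a fixed count or, with
    ``n_shapes=None``, uniformly from ``cfg.n_shapes_range`` — the simple
    Data-B-style mode uses e.g. ``n_shapes_range=(1, 2)`` through the same
    code path.
    """
    if n_cases < 0:
        raise ConfigError("n_cases must be >= 0")
    if grouped and n_cases % N_GROUPS != 0:
        raise ConfigError(
            f"n_cases={n_cases} must be divisible by {N_GROUPS} groups"
        )
    seeds = np.random.SeedSequence(seed).spawn(n_cases)
    per_group = n_cases // N_GROUPS if grouped else 0
    for i in range(n_cases):
        rng = np.random.default_rng(seeds[i])
        if grouped:
            count = group_shape_count(i // per_group, cfg)
        elif n_shapes is not None:
            count = n_shapes
        else:
            lo, hi = cfg.n_shapes_range
            count = int(rng.integers(lo, hi + 1))
        yield generate_case(rng, cfg, count, case_id=f"case_{i:05d}")
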