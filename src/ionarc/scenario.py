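"""Cylindrical phantom scenarios: voxel grids, ROI masks, pO2 maps.

The study geometry is a water cylinder (H = 200 mm, r = 100 mm) with a
cylindrical target at isocenter (H = 60 mm, r = 30 mm) and, for the
clinical-like case B, a cylindrical OAR at a 5 mm radial gap on the +x side.
Coordinates: isocenter at the origin, cylinder axes along z, gantry angle
measured clockwise from +y in the axial plane. Voxel centers sit at
(i + 0.5) * h - 100 mm. Generation is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PHANTOM_RADIUS = 100.0
PHANTOM_HEIGHT = 200.0
TARGET_RADIUS = 30.0
TARGET_HEIGHT = 60.0
CORE_RADIUS = 5.0
PO2_NORMOXIC = 21.0
PO2_OUTER = 5.0
PO2_CORE = 0.25
N_PO2_LEVELS = 9


@dataclass
class Scenario:
    """Voxelized study phantom with ROI masks (all arrays shaped (nx, ny, nz))."""

    case_id: str
    voxel_size: float
    shape: tuple
    phantom: np.ndarray
    target: np.ndarray
    core: np.ndarray
    oar: np.ndarray | None
    normal: np.ndarray
    oar_radius: float = 10.0
    oar_gap: float = 5.0
    pO2: np.ndarray | None = None
    po2_levels: np.ndarray | None = None

    def axes(self) -> tuple:
        """Voxel-center coordinates (x, y, z) in mm."""
        h = self.voxel_size
        n = self.shape[0]
        c = (np.arange(n) + 0.5) * h - PHANTOM_RADIUS
        return c, c.copy(), c.copy()

    def grid(self) -> tuple:
        x, y, z = self.axes()
        return np.meshgrid(x, y, z, indexing="ij")


def build_scenario(case_id: str = "A", voxel_size: float = 2.0,
                   oar_radius: float = 10.0, oar_gap: float = 5.0) -> Scenario:
    """Generate the case A (target only) or case B (target + OAR) phantom.

    Case B places the OAR cylinder (default r = 10 mm, H = 60 mm, axis
    parallel to the target axis) at a radial surface gap of ``oar_gap`` mm on
    the +x side of the target.
    """
    case_id = case_id.upper()
    if case_id not in ("A", "B"):
        raise ValueError("case_id must be 'A' or 'B'")
    if voxel_size not in (1.0, 2.0, 4.0):
        raise ValueError("voxel_size must be 1, 2 or 4 mm")
    if voxel_size > oar_gap:
        raise ValueError("voxel size cannot resolve the target-OAR gap")

    n = int(round(2 * PHANTOM_RADIUS / voxel_size))
    c = (np.arange(n) + 0.5) * voxel_size - PHANTOM_RADIUS
    x, y, z = np.meshgrid(c, c, c, indexing="ij")
    r2 = x**2 + y**2

    phantom = (r2 <= PHANTOM_RADIUS**2) & (np.abs(z) <= PHANTOM_HEIGHT / 2)
    in_height = np.abs(z) <= TARGET_HEIGHT / 2
    target = (r2 <= TARGET_RADIUS**2) & in_height
    core = (r2 <= CORE_RADIUS**2) & in_height

    oar = None
    if case_id == "B":
        cx = TARGET_RADIUS + oar_gap + oar_radius
        oar = ((x - cx) ** 2 + y**2 <= oar_radius**2) & in_height
        oar &= phantom

    normal = phantom & ~target
    if oar is not None:
        normal &= ~oar

    return Scenario(
        case_id=case_id,
        voxel_size=voxel_size,
        shape=(n, n, n),
        phantom=phantom,
        target=target,
        core=core,
        oar=oar,
        normal=normal,
        oar_radius=oar_radius,
        oar_gap=oar_gap,
    )


@dataclass
class PO2Map:
    """Per-voxel oxygen tension (% O2) with its in-target level ladder."""

    values: np.ndarray
    levels: np.ndarray
    ring_edges: np.ndarray  # outer radii of the 9 shells, mm


def po2_levels() -> np.ndarray:
    """The nine log-spaced pO2 levels, 5% (outer ring) down to 0.25% (core)."""
    k = np.arange(N_PO2_LEVELS)
    return PO2_OUTER * (PO2_CORE / PO2_OUTER) ** (k / (N_PO2_LEVELS - 1))


def build_po2_map(scenario: Scenario) -> PO2Map:
    """Assign the radial pO2 gradient: 9 equal-width shells between r = 30 mm
    and r = 5 mm carry the log-spaced levels; the r <= 5 mm core continues the
    innermost level (0.25%); everything outside the target is normoxic (21%).
    """
    if scenario.target is None or not scenario.target.any():
        raise ValueError("scenario has no target mask")
    x, y, _ = scenario.grid()
    r = np.sqrt(x**2 + y**2)
    levels = po2_levels()
    width = (TARGET_RADIUS - CORE_RADIUS) / N_PO2_LEVELS
    edges = TARGET_RADIUS - width * np.arange(1, N_PO2_LEVELS + 1)

    values = np.full(scenario.shape, PO2_NORMOXIC)
    shell_idx = np.clip(np.floor((TARGET_RADIUS - r) / width), 0, N_PO2_LEVELS - 1).astype(int)
    values[scenario.target] = levels[shell_idx[scenario.target]]
    scenario.pO2 = values
    scenario.po2_levels = levels
    return PO2Map(values=values, levels=levels, ring_edges=edges)


def beam_unit_vectors(gantry_angle_deg: float) -> tuple:
    """(beam direction, lateral BEV axis) in the axial plane.

    The gantry angle is measured clockwise from +y: at 0 deg the source sits
    on +y and the beam travels toward -y; at 90 deg the source is on +x.
    The lateral axis completes a right-handed (u, v=z, beam) triad.
    """
    th = np.deg2rad(gantry_angle_deg)
    src = np.array([np.sin(th), np.cos(th), 0.0])
    d = -src
    u_lat = np.array([np.cos(th), -np.sin(th), 0.0])
    return d, u_lat


def radiological_depth(scenario: Scenario, point, gantry_angle_deg: float) -> float:
    """Water-equivalent depth of ``point`` (mm, (x, y, z)) along the beam.

    For the homogeneous water cylinder this is the geometric distance from
    the beam's entry on the lateral surface to the point.
    """
    p = np.asarray(point, dtype=float)
    if p[0] ** 2 + p[1] ** 2 > PHANTOM_RADIUS**2 or abs(p[2]) > PHANTOM_HEIGHT / 2:
        raise ValueError("point outside phantom")
    d, u_lat = beam_unit_vectors(gantry_angle_deg)
    s = p[0] * d[0] + p[1] * d[1]
    l_perp = p[0] * u_lat[0] + p[1] * u_lat[1]
    return float(s + np.sqrt(PHANTOM_RADIUS**2 - l_perp**2))


def depth_grid(scenario_or_points, gantry_angle_deg: float,
               points: np.ndarray | None = None) -> np.ndarray:
    """Vectorized radiological depth for an (N, >=2) array of points."""
    pts = np.asarray(points if points is not None else scenario_or_points, dtype=float)
    d, u_lat = beam_unit_vectors(gantry_angle_deg)
    s = pts[:, 0] * d[0] + pts[:, 1] * d[1]
    l_perp = pts[:, 0] * u_lat[0] + pts[:, 1] * u_lat[1]
    return s + np.sqrt(np.maximum(PHANTOM_RADIUS**2 - l_perp**2, 0.0))
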