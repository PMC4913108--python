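"""Scalp geometry helper for the NIRS probe layout.

The probe runs along the great-circle arc joining the F3 and Cz scalp
locations: the source sits 15 mm toward Cz from FC1, with a short-separation
detector 8 mm and a long-separation detector 30 mm toward F3 from the
source.  Short separations sample extra-cerebral tissue, long separations
cortex.  The scalp is approximated by a least-squares sphere fitted to an
electrode coordinate set; placements and separations are computed on that
sphere (both along-arc and straight-line chord metrics are reported — the
two differ, and no adjudication between them is attempted).

The packaged electrode table is a synthetic, idealized spherical 10-10
layout (generated from the standard angular construction, head radius
87 mm), not digitized human coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OptodeLayout",
    "point_distance",
    "fit_sphere",
    "arc_place",
    "arc_distance",
    "idealized_1020_positions",
    "build_probe_layout",
]


def point_distance(p, q) -> float:
    """Euclidean (chord) distance in millimeters."""
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise ValueError("coordinates must be finite")
    return float(np.linalg.norm(p - q))


def fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares sphere through ``points`` (algebraic fit).

    Solves ||p - c||^2 = r^2 linearized as 2 p.c + (r^2 - |c|^2) = |p|^2.
    Returns (center, radius).
    """
    p = np.asarray(points, dtype=np.float64)
    if p.ndim != 2 or p.shape[1] != 3 or p.shape[0] < 4:
        raise ValueError("need >= 4 non-coplanar 3-D points")
    a = np.column_stack([2 * p, np.ones(p.shape[0])])
    b = (p ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(sol[3] + center @ center))
    return center, radius


def _project(point, center, radius) -> np.ndarray:
    v = np.asarray(point, dtype=np.float64) - center
    nv = np.linalg.norm(v)
    if nv == 0:
        raise ValueError("point coincides with the sphere center")
    return center + v * (radius / nv)


def arc_distance(p, q, center, radius) -> float:
    """Great-circle distance between two points projected onto the sphere."""
    u = (_project(p, center, radius) - center) / radius
    v = (_project(q, center, radius) - center) / radius
    return float(radius * np.arccos(np.clip(u @ v, -1.0, 1.0)))


def arc_place(center: np.ndarray, radius: float, a, b,
              arc_offsets) -> np.ndarray:
    """Points on the great-circle arc from ``a`` toward ``b``.

    ``arc_offsets`` are along-arc lengths (mm) from ``a``; each returned
    point lies on the sphere.  Antipodal endpoints leave the arc undefined.
    """
    center = np.asarray(center, dtype=np.float64)
    pa = _project(a, center, radius)
    pb = _project(b, center, radius)
    u = (pa - center) / radius
    v = (pb - center) / radius
    cosang = float(np.clip(u @ v, -1.0, 1.0))
    if cosang <= -1.0 + 1e-12:
        raise ValueError("antipodal anchor points: great-circle arc undefined")
    # orthonormal in-plane direction from u toward v
    w = v - cosang * u
    nw = np.linalg.norm(w)
    if nw < 1e-12:
        w = np.zeros(3)
    else:
        w = w / nw
    total = radius * np.arccos(cosang)
    offsets = np.atleast_1d(np.asarray(arc_offsets, dtype=np.float64))
    if np.any(offsets < 0) or (total > 0 and np.any(offsets > total + 1e-9)):
        raise ValueError("arc offsets must lie within the a->b arc length")
    theta = offsets / radius
    pts = center + radius * (np.outer(np.cos(theta), u) + np.outer(np.sin(theta), w))
    return pts


def idealized_1020_positions(radius: float = 87.0) -> dict[str, np.ndarray]:
    """Synthetic idealized 10-10 electrode positions on a sphere.

    Standard angular construction: vertex Cz on top, midline positions at
    multiples of 18 degrees of polar angle, lateral rings by azimuth;
    intermediate electrodes (F1/F3/F5, FC1/FC3/FC5, ...) equally spaced
    along the great-circle arc between their midline and outer-ring
    anchors.  x right, y anterior, z up; millimeters.  A stand-in for
    digitized MNI scalp coordinates, adequate for arc-geometry checks.
    """

    def sph(polar_deg: float, azim_deg: float) -> np.ndarray:
        # polar from vertex; azimuth from +y (anterior) toward -x (left)
        th = np.radians(polar_deg)
        az = np.radians(azim_deg)
        return radius * np.array([-np.sin(th) * np.sin(az),
                                  np.sin(th) * np.cos(az),
                                  np.cos(th)])

    pos: dict[str, np.ndarray] = {
        "Cz": sph(0, 0),
        "Fz": sph(36, 0), "Pz": sph(36, 180),
        "Fpz": sph(72, 0), "Oz": sph(72, 180),
        "FCz": sph(18, 0), "CPz": sph(18, 180),
        "T7": sph(72, 90), "T8": sph(72, -90),
        "C3": sph(36, 90), "C4": sph(36, -90),
        "Fp1": sph(72, 18), "Fp2": sph(72, -18),
        "F7": sph(72, 54), "F8": sph(72, -54),
        "P7": sph(72, 126), "P8": sph(72, -126),
        "O1": sph(72, 162), "O2": sph(72, -162),
    }
    center = np.zeros(3)

    def between(a: str, b: str, names: list[str]) -> None:
        n = len(names) + 1
        total = arc_distance(pos[a], pos[b], center, radius)
        pts = arc_place(center, radius, pos[a], pos[b],
                        [total * k / n for k in range(1, n)])
        for name, p in zip(names, pts):
            pos[name] = p

    between("Fz", "F7", ["F1", "F3", "F5"])
    between("Fz", "F8", ["F2", "F4", "F6"])
    between("FCz", "T7", ["FC1", "FC3", "FC5"])
    between("FCz", "T8", ["FC2", "FC4", "FC6"])
    between("Cz", "T7", ["C1", "C3x", "C5"])  # C3x: arc-constructed C3
    between("Cz", "T8", ["C2", "C4x", "C6"])
    # prefer the ring definitions of C3/C4 from the primary table
    del pos["C3x"], pos["C4x"]
    return pos


@dataclass
class OptodeLayout:
    """NIRS probe optodes with chord and along-arc separations (mm)."""

    points: dict[str, np.ndarray]     # source, short_detector, long_detector, anchors
    sphere_center: np.ndarray
    sphere_radius: float
    chord_separations: dict[str, float]
    arc_separations: dict[str, float]

    def max_sphere_deviation(self) -> float:
        devs = [abs(np.linalg.norm(p - self.sphere_center) - self.sphere_radius)
                for p in self.points.values()]
        return float(max(devs))


def build_probe_layout(positions: dict[str, np.ndarray] | None = None,
                       source_offset: float = 15.0,
                       short_separation: float = 8.0,
                       long_separation: float = 30.0) -> OptodeLayout:
    """Place the probe on the F3-Cz arc of a sphere fitted to the electrodes.

    The probe anchor is FC1 projected onto the F3-Cz great circle; the
    source sits ``source_offset`` mm toward Cz from that anchor and the two
    detectors ``short_separation`` and ``long_separation`` mm toward F3
    from the source (all along-arc).
    """
    if not short_separation < long_separation:
        raise ValueError("short separation must be smaller than long")
    pos = positions if positions is not None else idealized_1020_positions()
    pts = np.array([pos[k] for k in sorted(pos)])
    center, radius = fit_sphere(pts)

    f3 = _project(pos["F3"], center, radius)
    cz = _project(pos["Cz"], center, radius)
    fc1 = _project(pos["FC1"], center, radius)
    # anchor: point of the F3->Cz arc nearest FC1
    total = arc_distance(f3, cz, center, radius)
    grid = np.linspace(0.0, total, 2001)
    cand = arc_place(center, radius, f3, cz, grid)
    anchor = cand[np.argmin(np.linalg.norm(cand - fc1, axis=1))]

    source = arc_place(center, radius, anchor, cz, [source_offset])[0]
    short_d, long_d = arc_place(center, radius, source, f3,
                                [short_separation, long_separation])

    points = {"source": source, "short_detector": short_d,
              "long_detector": long_d, "anchor_FC1": anchor,
              "F3": f3, "Cz": cz}
    chord = {
        "short": point_distance(source, short_d),
        "long": point_distance(source, long_d),
    }
    arc = {
        "short": arc_distance(source, short_d, center, radius),
        "long": arc_distance(source, long_d, center, radius),
    }
    return OptodeLayout(points=points, sphere_center=center,
                        sphere_radius=radius, chord_separations=chord,
                        arc_separations=arc)
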