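"""Parametric stenosed-vessel geometry.

Builds analytic, smoothly varying tube geometries that stand in for segmented
renal arteries: a 3-D centerline (optionally bent and/or mildly tortuous, since
renal arteries are tortuous and typically stenosed near the ostium) together
with a radius profile that superimposes one or more smooth cosine-bell
constrictions on a healthy reference lumen.

All geometric quantities are in millimetres.  Severity is expressed as percent
*diameter* reduction relative to the healthy reference diameter, the convention
used clinically for grading renal artery stenosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import trimesh


class GeometryError(ValueError):
    """Raised for invalid vessel specifications."""


@dataclass(frozen=True)
class StenosisSpec:
    """One axisymmetric constriction of the lumen.

    Parameters
    ----------
    center : float
        Arc-length position of the throat along the centerline (mm).
    length : float
        Axial extent (support) of the constriction (mm).
    severity : float
        Percent diameter reduction at the throat relative to the healthy
        reference diameter, in [0, 100).
    """

    center: float
    length: float
    severity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.severity < 100.0:
            raise GeometryError(
                f"severity must be in [0, 100), got {self.severity}"
            )
        if self.length <= 0.0:
            raise GeometryError(f"stenosis length must be > 0, got {self.length}")

    @property
    def start(self) -> float:
        return self.center - 0.5 * self.length

    @property
    def end(self) -> float:
        return self.center + 0.5 * self.length


def cosine_bell(xi: np.ndarray) -> np.ndarray:
    """Smooth C1 bump: 1 at xi=0, 0 for |xi| >= 1, with zero slope at both."""
    xi = np.asarray(xi, dtype=float)
    out = np.zeros_like(xi)
    inside = np.abs(xi) < 1.0
    out[inside] = 0.5 * (1.0 + np.cos(np.pi * xi[inside]))
    return out


@dataclass
class VesselGeometry:
    """Analytic stenosed tube: centerline + radius profile.

    The centerline is parameterized by arc length ``s`` in [0, total_length]
    (mm).  By default it is a planar circular arc turning through
    ``bend_angle_deg`` over the whole length (0 gives a straight vessel);
    a seeded low-frequency tortuosity perturbation may be superimposed.

    ``radius_fn``, when given, overrides the built-in cosine-bell profile
    (used for piecewise/hand-specified lumens); it maps arc length (mm) to
    local radius (mm).
    """

    reference_diameter: float
    total_length: float
    stenoses: list[StenosisSpec] = field(default_factory=list)
    bend_angle_deg: float = 0.0
    tortuosity_amplitude: float = 0.0
    seed: int | None = None
    radius_fn: Callable[[np.ndarray], np.ndarray] | None = None

    # tortuosity mode coefficients, fixed at construction for determinism
    _tort_coeffs: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.reference_diameter <= 0.0:
            raise GeometryError("reference_diameter must be > 0")
        if self.total_length <= 0.0:
            raise GeometryError("total_length must be > 0")
        for st in self.stenoses:
            if st.start < 0.0 or st.end > self.total_length:
                raise GeometryError(
                    f"stenosis support [{st.start}, {st.end}] mm lies outside "
                    f"the vessel extent [0, {self.total_length}] mm"
                )
        ordered = sorted(self.stenoses, key=lambda s: s.center)
        for a, b in zip(ordered, ordered[1:]):
            if a.end > b.start:
                raise GeometryError(
                    f"overlapping stenoses at {a.center} mm and {b.center} mm"
                )
        n_modes = 3
        if self.tortuosity_amplitude > 0.0:
            rng = np.random.default_rng(self.seed)
            # signed amplitudes decaying with mode number; endpoints stay pinned
            amps = self.tortuosity_amplitude * rng.uniform(-1.0, 1.0, (2, n_modes))
            amps /= np.arange(1, n_modes + 1)
        else:
            amps = np.zeros((2, n_modes))
        object.__setattr__(self, "_tort_coeffs", amps)

    # ------------------------------------------------------------------ lumen
    @property
    def reference_radius(self) -> float:
        return 0.5 * self.reference_diameter

    def radius(self, s: np.ndarray | float) -> np.ndarray:
        """Local lumen radius (mm) at arc length ``s`` (mm)."""
        s = np.asarray(s, dtype=float)
        if self.radius_fn is not None:
            return np.asarray(self.radius_fn(s), dtype=float)
        reduction = np.zeros_like(s)
        for st in self.stenoses:
            xi = (s - st.center) / (0.5 * st.length)
            reduction += (st.severity / 100.0) * cosine_bell(xi)
        return self.reference_radius * (1.0 - reduction)

    def diameter(self, s: np.ndarray | float) -> np.ndarray:
        return 2.0 * self.radius(s)

    def min_diameter(self, n_samples: int = 8192) -> float:
        """Minimum lumen diameter (mm), sampled densely plus at all throats."""
        s = np.linspace(0.0, self.total_length, n_samples)
        if self.radius_fn is None and self.stenoses:
            s = np.concatenate([s, [st.center for st in self.stenoses]])
        return float(2.0 * self.radius(s).min())

    # ------------------------------------------------------------- centerline
    def _tortuosity(self, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Lateral perturbation (2, n) and its derivative (2, n), mm."""
        amps = self._tort_coeffs
        n_modes = amps.shape[1]
        k = np.arange(1, n_modes + 1)[:, None]  # (modes, 1)
        arg = np.pi * k * s[None, :] / self.total_length  # (modes, n)
        # sin(pi k s / L): vanishes at both ends, keeping endpoints in place
        disp = amps @ np.sin(arg)
        dd = (amps * (np.pi * k.T / self.total_length)) @ np.cos(arg)
        return disp, dd

    def centerline(self, s: np.ndarray | float) -> np.ndarray:
        """Centerline points (n, 3) in mm at arc lengths ``s``."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        theta_tot = np.deg2rad(self.bend_angle_deg)
        if abs(theta_tot) > 1e-12:
            rad = self.total_length / theta_tot  # bend radius
            ang = s / rad
            x = rad * (1.0 - np.cos(ang))
            z = rad * np.sin(ang)
        else:
            x = np.zeros_like(s)
            z = s.copy()
        y = np.zeros_like(s)
        pts = np.stack([x, y, z], axis=1)
        if self.tortuosity_amplitude > 0.0:
            disp, _ = self._tortuosity(s)
            pts[:, 0] += disp[0]
            pts[:, 1] += disp[1]
        return pts

    def tangent(self, s: np.ndarray | float) -> np.ndarray:
        """Unit tangent vectors (n, 3) of the centerline."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        theta_tot = np.deg2rad(self.bend_angle_deg)
        if abs(theta_tot) > 1e-12:
            rad = self.total_length / theta_tot
            ang = s / rad
            t = np.stack([np.sin(ang), np.zeros_like(s), np.cos(ang)], axis=1)
        else:
            t = np.tile([0.0, 0.0, 1.0], (s.size, 1))
        if self.tortuosity_amplitude > 0.0:
            _, dd = self._tortuosity(s)
            t[:, 0] += dd[0]
            t[:, 1] += dd[1]
            t /= np.linalg.norm(t, axis=1, keepdims=True)
        return t

    def frames(self, s: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Parallel-transported orthonormal frames (T, N, B) along ``s``.

        Twist-minimizing: the normal is propagated by projecting the previous
        normal onto the plane orthogonal to the next tangent, which avoids
        the frame flips a Frenet frame suffers at inflection points.
        """
        s = np.asarray(s, dtype=float)
        T = self.tangent(s)
        N = np.empty_like(T)
        ref = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(ref, T[0])) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        n0 = ref - np.dot(ref, T[0]) * T[0]
        N[0] = n0 / np.linalg.norm(n0)
        for k in range(1, len(s)):
            n = N[k - 1] - np.dot(N[k - 1], T[k]) * T[k]
            nrm = np.linalg.norm(n)
            if nrm < 1e-12:  # pathological kink; restart from reference
                n = ref - np.dot(ref, T[k]) * T[k]
                nrm = np.linalg.norm(n)
            N[k] = n / nrm
        B = np.cross(T, N)
        return T, N, B

    # ---------------------------------------------------------------- volume
    def lumen_volume(self, n_samples: int = 4096) -> float:
        """Analytic lumen volume (mm^3): integral of pi r(s)^2 ds."""
        s = np.linspace(0.0, self.total_length, n_samples)
        return float(np.trapezoid(np.pi * self.radius(s) ** 2, s))

    # ------------------------------------------------------------------- I/O
    def to_dict(self) -> dict:
        return {
            "reference_diameter_mm": self.reference_diameter,
            "length_mm": self.total_length,
            "bend_angle_deg": self.bend_angle_deg,
            "tortuosity_amplitude_mm": self.tortuosity_amplitude,
            "seed": self.seed,
            "stenoses": [
                {
                    "center_mm": st.center,
                    "length_mm": st.length,
                    "severity_pct": st.severity,
                }
                for st in self.stenoses
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VesselGeometry":
        return build_stenosed_vessel(
            reference_diameter=d["reference_diameter_mm"],
            length=d["length_mm"],
            stenoses=[
                StenosisSpec(
                    center=s["center_mm"],
                    length=s["length_mm"],
                    severity=s["severity_pct"],
                )
                for s in d.get("stenoses", [])
            ],
            bend_angle_deg=d.get("bend_angle_deg", 0.0),
            tortuosity_amplitude=d.get("tortuosity_amplitude_mm", 0.0),
            seed=d.get("seed"),
        )


def build_stenosed_vessel(
    reference_diameter: float,
    length: float,
    stenoses: Sequence[StenosisSpec] = (),
    bend_angle_deg: float = 0.0,
    tortuosity_amplitude: float = 0.0,
    seed: int | None = None,
) -> VesselGeometry:
    """Construct a stenosed-vessel geometry.

    Parameters
    ----------
    reference_diameter : float
        Healthy lumen diameter (mm).
    length : float
        Vessel length along the centerline (mm).
    stenoses : sequence of StenosisSpec
        Non-overlapping constrictions; the minimum diameter of the result
        equals ``reference_diameter * (1 - max severity / 100)``.
    bend_angle_deg : float
        Total turning angle of the planar centerline bend (0 = straight).
    tortuosity_amplitude : float
        RMS-scale lateral perturbation (mm) of the centerline; 0 disables.
    seed : int, optional
        Seed for the tortuosity perturbation; the geometry is deterministic
        for a fixed (spec, seed) pair.
    """
    return VesselGeometry(
        reference_diameter=reference_diameter,
        total_length=length,
        stenoses=list(stenoses),
        bend_angle_deg=bend_angle_deg,
        tortuosity_amplitude=tortuosity_amplitude,
        seed=seed,
    )


def renal_template(
    severity: float | None = 72.0,
    reference_diameter: float = 5.0,
    length: float = 40.0,
    stenosis_center: float = 5.0,
    stenosis_length: float = 8.0,
    bend_angle_deg: float = 30.0,
) -> VesselGeometry:
    """Default synthetic renal-artery-like vessel.

    A 5 mm, 40 mm-long artery with a single gentle 30 degree planar bend and
    an ostial stenosis centred 5 mm from the inlet — the configuration most
    commonly seen in atherosclerotic renal artery stenosis, where lesions sit
    close to the ostium.  ``severity=None`` or 0 gives the unobstructed vessel.
    """
    stenoses = []
    if severity:
        stenoses = [
            StenosisSpec(
                center=stenosis_center, length=stenosis_length, severity=severity
            )
        ]
    return build_stenosed_vessel(
        reference_diameter=reference_diameter,
        length=length,
        stenoses=stenoses,
        bend_angle_deg=bend_angle_deg,
    )


def percent_diameter_stenosis(geometry: VesselGeometry) -> float:
    """Percent diameter reduction: 100 * (1 - min diameter / reference)."""
    return 100.0 * (1.0 - geometry.min_diameter() / geometry.reference_diameter)


def surface_mesh(
    geometry: VesselGeometry,
    circumferential_n: int = 32,
    axial_spacing: float = 0.5,
) -> trimesh.Trimesh:
    """Closed, outward-oriented triangulated surface of the lumen.

    Cross-sections are circles of the local radius, placed in
    parallel-transported frames along the centerline; flat caps close the
    inlet and outlet.
    """
    if circumferential_n < 8:
        raise GeometryError("circumferential_n must be >= 8")
    if axial_spacing <= 0.0 or axial_spacing > geometry.total_length:
        raise GeometryError("axial_spacing must be in (0, total_length]")
    n_axial = max(2, int(round(geometry.total_length / axial_spacing)) + 1)
    s = np.linspace(0.0, geometry.total_length, n_axial)
    centers = geometry.centerline(s)
    _, N, B = geometry.frames(s)
    r = geometry.radius(s)
    phi = np.linspace(0.0, 2.0 * np.pi, circumferential_n, endpoint=False)
    # ring vertices: (n_axial, n_circ, 3)
    rings = (
        centers[:, None, :]
        + r[:, None, None] * np.cos(phi)[None, :, None] * N[:, None, :]
        + r[:, None, None] * np.sin(phi)[None, :, None] * B[:, None, :]
    )
    verts = rings.reshape(-1, 3)
    nc = circumferential_n
    idx = np.arange(n_axial * nc).reshape(n_axial, nc)
    faces = []
    for k in range(n_axial - 1):
        a = idx[k]
        b = idx[k + 1]
        a1 = np.roll(a, -1)
        b1 = np.roll(b, -1)
        # two outward-wound triangles per side quad
        faces.append(np.stack([a, b1, b], axis=1))
        faces.append(np.stack([a, a1, b1], axis=1))
    faces = np.concatenate(faces, axis=0)
    # caps: fan to the centerline points
    c0 = len(verts)
    c1 = c0 + 1
    verts = np.vstack([verts, centers[0], centers[-1]])
    ring0 = idx[0]
    ring1 = idx[-1]
    cap0 = np.stack(
        [np.full(nc, c0), np.roll(ring0, -1), ring0], axis=1
    )  # inlet cap, normal -T
    cap1 = np.stack([np.full(nc, c1), ring1, np.roll(ring1, -1)], axis=1)
    faces = np.vstack([faces, cap0, cap1])
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def export_surface(mesh: trimesh.Trimesh, path: str, ascii_stl: bool = False) -> None:
    """Write a surface to STL (binary or ASCII) or legacy-VTK PolyData."""
    path = str(path)
    if path.endswith(".vtk"):
        from .vtkio import write_polydata

        write_polydata(path, mesh.vertices, mesh.faces)
    else:
        file_type = "stl_ascii" if ascii_stl else "stl"
        mesh.export(path, file_type=file_type)
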