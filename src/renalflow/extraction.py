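"""Virtual translesional pressure-ratio (vPd/Pa) extraction.

Mirrors the catheter protocol: the distal pressure Pd is the arithmetic mean
of area-averaged pressures on three cross-sections placed 10, 15 and 20 mm
past the distal end of the stenosis (the range a pressure wire samples), and
the proximal pressure Pa comes from one upstream cross-section placed far
enough from both the throat and the inlet to avoid the Bernoulli pressure
extremes next to a near-ostial lesion.  vPd/Pa = Pd_mean / Pa.

Classification of physiological significance uses the clinical resting
threshold Pd/Pa <= 0.9, with values rounded to two decimals before the
comparison (the precision at which such ratios are read clinically).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import VesselGeometry
from .solver import FlowSolution, probe_plane

#: Downstream plane offsets past the stenosis end (mm).
DOWNSTREAM_OFFSETS_MM = (10.0, 15.0, 20.0)

#: Resting Pd/Pa at or below this is physiologically significant.
SIGNIFICANCE_THRESHOLD = 0.9


class ExtractionError(ValueError):
    pass


@dataclass
class PressureRatioResult:
    """vPd/Pa with its plane-to-plane variability.

    ``Pd_sd`` is the standard deviation of the three downstream plane
    pressures — a measure of how sensitive the virtual measurement is to the
    exact probing location, which grows with anatomical complexity.
    """

    Pa_value: float  # Pa
    Pd_mean: float  # Pa
    Pd_sd: float  # Pa
    vPdPa: float
    plane_locations: list[float]  # [upstream, d1, d2, d3] arc lengths (mm)
    downstream_pressures: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "Pa_Pa": self.Pa_value,
            "Pd_mean_Pa": self.Pd_mean,
            "Pd_sd_Pa": self.Pd_sd,
            "vPdPa": self.vPdPa,
            "plane_locations_mm": list(self.plane_locations),
            "downstream_pressures_Pa": list(self.downstream_pressures),
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2)


def plane_positions(geometry: VesselGeometry) -> tuple[float, list[float]]:
    """Arc-length positions of the upstream and three downstream planes.

    Downstream planes sit 10/15/20 mm past the distal stenosis end; when
    less than 20 mm of vessel remains they are compressed proportionally
    (with a warning).  The upstream plane sits 2 reference diameters proximal
    of the first throat but at least 1 diameter from the inlet; for ostial
    lesions where both are impossible it is clamped proximal of the lesion
    start, as far from inlet and lesion as the geometry allows.
    """
    if not geometry.stenoses:
        raise ExtractionError("geometry has no stenosis to probe across")
    ordered = sorted(geometry.stenoses, key=lambda s: s.center)
    distal_end = ordered[-1].end
    margin = 1.0  # keep planes off the outlet face (mm)
    available = geometry.total_length - distal_end - margin
    if available <= 0.0:
        raise ExtractionError(
            "no vessel downstream of the stenosis to place distal planes"
        )
    offsets = np.asarray(DOWNSTREAM_OFFSETS_MM)
    if available < offsets[-1]:
        warnings.warn(
            f"only {available:.1f} mm downstream of the stenosis; "
            "compressing the 10-20 mm probing range proportionally",
            stacklevel=2,
        )
        offsets = offsets * (available / offsets[-1])
    downstream = [float(distal_end + o) for o in offsets]

    d_ref = geometry.reference_diameter
    first = ordered[0]
    s_up = max(first.center - 2.0 * d_ref, d_ref)
    if s_up > first.start - 1.0:
        s_up = max(first.start - 1.0, 0.5 * first.start)
        warnings.warn(
            "ostial lesion: upstream plane clamped to "
            f"{s_up:.2f} mm from the inlet",
            stacklevel=2,
        )
    if s_up <= 0.0:
        raise ExtractionError("no room for an upstream plane before the lesion")
    return float(s_up), downstream


def extract_pd_pa(
    solution: FlowSolution, geometry: VesselGeometry
) -> PressureRatioResult:
    """Compute vPd/Pa from a converged flow solution.

    Planes are cross-sections normal to the centerline at the positions from
    :func:`plane_positions`; each pressure is the area-weighted average over
    the plane-lumen intersection.
    """
    if not solution.converged:
        raise ExtractionError("flow solution is not converged")
    s_up, downstream = plane_positions(geometry)

    def plane_pressure(s: float) -> float:
        pt = geometry.centerline(np.array([s]))[0]
        nrm = geometry.tangent(np.array([s]))[0]
        return probe_plane(solution, pt, nrm)["pressure"]

    pa = plane_pressure(s_up)
    pds = np.array([plane_pressure(s) for s in downstream])
    pd_mean = float(pds.mean())
    pd_sd = float(pds.std(ddof=1))  # sample SD over the three planes
    return PressureRatioResult(
        Pa_value=pa,
        Pd_mean=pd_mean,
        Pd_sd=pd_sd,
        vPdPa=pd_mean / pa,
        plane_locations=[s_up, *downstream],
        downstream_pressures=[float(p) for p in pds],
    )


def classify_physiological_significance(
    vPdPa: float, threshold: float = SIGNIFICANCE_THRESHOLD
) -> bool:
    """True when the ratio, rounded to 2 decimals, is at or below threshold.

    Rounding first means 0.903 reads as 0.90 and counts as significant —
    matching how resting pressure ratios are reported and acted on at the
    bedside.
    """
    if vPdPa <= 0.0:
        raise ExtractionError(f"vPdPa must be > 0, got {vPdPa}")
    return bool(np.round(vPdPa, 2) <= threshold + 1e-12)
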