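"""Vascular histomorphometry: compartment volumes from serial sections.

Lumen/intima/media/adventitia areas measured every 200 um over 2000 um of
carotid length are integrated to compartment volumes (trapezoidal rule,
exact for the piecewise-linear reading of serial sections), reduced to an
intima/media ratio, and converted to nested equivalent-circle radii for a
stacked-disc 3D surface rendering.

A missing (unmeasurable) intima — the non-ligated-artery case — is a NaN
sentinel and propagates as missing, never as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

COMPARTMENTS = ("lumen", "intima", "media", "adventitia")

#: Rendering color code per compartment.
COMPARTMENT_COLORS = {
    "lumen": "black",
    "intima": "yellow",
    "media": "red",
    "adventitia": "green",
}


@dataclass
class SectionAreas:
    """Compartment areas (um^2) at evenly spaced axial stations (um)."""

    stations_um: np.ndarray
    areas_um2: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.stations_um = np.asarray(self.stations_um, dtype=float)
        if self.stations_um.size < 2:
            raise ValueError("need at least 2 stations")
        d = np.diff(self.stations_um)
        if np.any(d <= 0):
            raise ValueError("stations must be strictly increasing")
        self.areas_um2 = {k: np.asarray(v, dtype=float) for k, v in self.areas_um2.items()}
        for name, a in self.areas_um2.items():
            if a.shape != self.stations_um.shape:
                raise ValueError(f"{name}: area profile length mismatch")
            if np.any(a[np.isfinite(a)] < 0):
                raise ValueError(f"{name}: negative area")

    def spacing(self, rtol: float = 1e-6) -> float:
        d = np.diff(self.stations_um)
        if np.any(np.abs(d - d[0]) > rtol * d[0]):
            raise ValueError("station spacing is uneven beyond tolerance")
        return float(d[0])


@dataclass
class CompartmentVolumes:
    """Per-compartment volumes (um^3) over the covered length (um).
    Missing compartments are NaN."""

    volumes_um3: dict[str, float]
    length_um: float


def compartment_volumes(areas: SectionAreas) -> CompartmentVolumes:
    """Trapezoidal integration of each area profile over the station span.

    An all-missing profile (sham intima) yields a missing (NaN) volume.
    """
    areas.spacing()  # validates even spacing
    length = float(areas.stations_um[-1] - areas.stations_um[0])
    vols: dict[str, float] = {}
    for name, profile in areas.areas_um2.items():
        if np.any(~np.isfinite(profile)):
            vols[name] = float("nan")
        else:
            vols[name] = float(np.trapezoid(profile, areas.stations_um))
    return CompartmentVolumes(volumes_um3=vols, length_um=length)


def intima_media_ratio(v: CompartmentVolumes) -> float:
    """Intima volume / media volume; NaN when the intima is missing."""
    media = v.volumes_um3.get("media", float("nan"))
    if not media > 0:
        raise ValueError(f"media volume must be > 0, got {media}")
    intima = v.volumes_um3.get("intima", float("nan"))
    return intima / media


def stacked_surface_model(areas: SectionAreas) -> np.ndarray:
    """Per-station nested equivalent-circle radii (um) for rendering.

    Column k is the outer radius of compartment ``COMPARTMENTS[k]``:
    r_k = sqrt(sum of areas lumen..k / pi).  A missing intima contributes
    zero thickness (its radius coincides with the lumen radius).  Radii
    are non-decreasing outward at every station.
    """
    n = areas.stations_um.size
    radii = np.zeros((n, len(COMPARTMENTS)))
    cum = np.zeros(n)
    for k, name in enumerate(COMPARTMENTS):
        a = areas.areas_um2.get(name)
        if a is None:
            a = np.zeros(n)
        cum = cum + np.where(np.isfinite(a), a, 0.0)
        radii[:, k] = np.sqrt(cum / np.pi)
    return radii
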