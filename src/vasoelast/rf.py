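"""Synthetic radio-frequency ultrasound frames.

A frame is the superposition, over point scatterers, of a separable
point-spread function: a 40 MHz Gaussian-modulated pulse along the axial
(depth) axis and a Gaussian beam profile along the lateral axis,
evaluated on the RF sample grid.  This is the standard convolution model
for linear imaging of weak scatterers, and is the test bed for the block
matcher — not a beamforming simulator.

Axial distances are expressed in mm of depth; the RF carrier appears at
spatial period ``c / (2 f0)`` (two-way travel), ~19.25 um at 40 MHz.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
import warnings

import numpy as np

from vasoelast.phantom import ScattererSet
from vasoelast.units import SOUND_SPEED_MM_PER_S


@dataclass
class FrameGeometry:
    """RF sample grid: axial samples x beam lines, coordinates in um."""

    axial_start_um: float
    lateral_start_um: float
    n_axial: int
    n_lateral: int
    sampling_hz: float = 250e6     # axial RF sampling rate
    beam_pitch_um: float = 2.54    # lateral line spacing
    center_freq_hz: float = 40e6

    def __post_init__(self) -> None:
        if self.sampling_hz < 4 * self.center_freq_hz:
            raise ValueError("axial sampling must be >= 4x the center frequency")

    @property
    def axial_step_um(self) -> float:
        # depth per RF sample: c / (2 fs), two-way travel
        return SOUND_SPEED_MM_PER_S * 1e3 / (2.0 * self.sampling_hz)

    @property
    def carrier_period_um(self) -> float:
        return SOUND_SPEED_MM_PER_S * 1e3 / (2.0 * self.center_freq_hz)

    @cached_property
    def axial_positions_um(self) -> np.ndarray:
        return self.axial_start_um + np.arange(self.n_axial) * self.axial_step_um

    @cached_property
    def lateral_positions_um(self) -> np.ndarray:
        return self.lateral_start_um + np.arange(self.n_lateral) * self.beam_pitch_um

    @classmethod
    def covering(
        cls,
        axial_span_um: tuple[float, float],
        lateral_span_um: tuple[float, float],
        **kw,
    ) -> "FrameGeometry":
        tmp = cls(0.0, 0.0, 2, 2, **kw)
        na = int(np.ceil((axial_span_um[1] - axial_span_um[0]) / tmp.axial_step_um)) + 1
        nl = int(np.ceil((lateral_span_um[1] - lateral_span_um[0]) / tmp.beam_pitch_um)) + 1
        return cls(axial_span_um[0], lateral_span_um[0], na, nl, **kw)


@dataclass
class RFFrame:
    """2D RF echo samples (axial sample x beam line) with geometry."""

    samples: np.ndarray
    geometry: FrameGeometry

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (self.geometry.n_axial, self.geometry.n_lateral):
            raise ValueError("sample array does not match frame geometry")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("RF samples must be finite")


def simulate_rf(
    scatterers: ScattererSet,
    geometry: FrameGeometry,
    sigma_axial_um: float = 15.0,
    sigma_lateral_um: float = 30.0,
    seed: int | None = None,
) -> RFFrame:
    """Render an RF frame from a scatterer set (deterministic given inputs).

    Each scatterer adds ``amplitude * exp(-dz^2/2s_a^2) cos(2 pi dz / T)
    * exp(-dx^2/2s_l^2)`` where ``dz, dx`` are axial/lateral offsets from
    the scatterer and ``T`` the two-way carrier period.  Scatterer
    positions are in mm (phantom frame) and are converted to um here.
    ``seed`` is accepted for interface symmetry; the render is
    deterministic and does not consume randomness.
    """
    del seed
    out = np.zeros((geometry.n_axial, geometry.n_lateral))
    if scatterers.positions.shape[0] == 0:
        warnings.warn("empty scatterer set: returning an all-zero frame")
        return RFFrame(out, geometry)

    z_axis = geometry.axial_positions_um
    x_axis = geometry.lateral_positions_um
    dz_step = geometry.axial_step_um
    dx_step = geometry.beam_pitch_um
    period = geometry.carrier_period_um
    half_a = int(np.ceil(4.0 * sigma_axial_um / dz_step))
    half_l = int(np.ceil(4.0 * sigma_lateral_um / dx_step))

    pos_um = scatterers.positions * 1e3
    for (z, x), amp in zip(pos_um, scatterers.amplitudes):
        iz = int(round((z - geometry.axial_start_um) / dz_step))
        ix = int(round((x - geometry.lateral_start_um) / dx_step))
        a0, a1 = max(0, iz - half_a), min(geometry.n_axial, iz + half_a + 1)
        l0, l1 = max(0, ix - half_l), min(geometry.n_lateral, ix + half_l + 1)
        if a0 >= a1 or l0 >= l1:
            continue
        dz = z_axis[a0:a1] - z
        dx = x_axis[l0:l1] - x
        pulse = np.exp(-0.5 * (dz / sigma_axial_um) ** 2) * np.cos(2 * np.pi * dz / period)
        beam = np.exp(-0.5 * (dx / sigma_lateral_um) ** 2)
        out[a0:a1, l0:l1] += amp * np.outer(pulse, beam)
    return RFFrame(out, geometry)
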