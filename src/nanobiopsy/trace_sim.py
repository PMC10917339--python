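"""Synthetic double-barrel nanopipette ion-current traces.

Generates aqueous-barrel injection traces (approach, hop retract, bias
switch, stepped descent with membrane touch, vibrational noise near the
substrate, zero-current substrate contact, retract-and-hold) and
organic-barrel extraction traces (hold, electrowetting transient, hold),
together with ground-truth phase boundaries so that detectors can be
validated sample-by-sample.

The trace morphology follows the platform's acquisition protocol: 10 kHz
sampling, 99.5% set-point approach, 2-um hop, 100-nm descent steps at
10 nm/ms, ~2% current drop at membrane touch, band-limited vibrational
noise close to the coverslip, zero current at contact, and a -500 mV
10-s electrowetting pulse whose transient is carried by the velocity of
the liquid-liquid interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .sicm_model import (
    DEFAULT_KAPPA_CYT,
    DEFAULT_KAPPA_ORG,
    DEFAULT_LENGTH_M,
    DEFAULT_R_TIP_M,
    BarrelElectrics,
    CalibrationError,
    InvalidParameterError,
    PipetteGeometry,
    PlugState,
    access_coefficient,
    calibrate_taper,
    invert_ingress,
    plug_resistance,
)

__all__ = [
    "TraceChannel",
    "InjectionProtocol",
    "ExtractionProtocol",
    "NoiseModel",
    "GroundTruth",
    "CellPreset",
    "OrganicPipette",
    "GeometryError",
    "default_aqueous_electrics",
    "simulate_injection_trace",
    "simulate_extraction_trace",
    "calibrate_extraction_example",
    "band_limited_noise",
]

DEFAULT_SAMPLE_RATE = 10_000.0  # Hz

# Median maximum indentation before membrane rupture, per cell type.
GLIAL_MEMBRANE_Z_M = 5.06e-6
EPITHELIAL_MEMBRANE_Z_M = 3.32e-6


class GeometryError(ValueError):
    """The simulated geometry cannot produce an ordered phase sequence."""


@dataclass
class TraceChannel:
    """One recorded channel: current, applied bias and (optionally) the
    vertical tip position, all sampled on a common clock."""

    sample_rate: float
    current: np.ndarray
    bias: np.ndarray
    position: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not (self.sample_rate > 0):
            raise InvalidParameterError("sample_rate must be > 0")
        n = len(self.current)
        if len(self.bias) != n or (self.position is not None and len(self.position) != n):
            raise InvalidParameterError("all trace channels must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.current)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate


@dataclass(frozen=True)
class InjectionProtocol:
    """Nanoinjection motion/bias protocol (SI units)."""

    hop_height: float = 2e-6
    step: float = 100e-9
    descent_speed: float = 1e-5  # 10 nm/ms
    hold_duration: float = 60.0
    membrane_drop_fraction: float = 0.02
    inject_bias: float = -0.5
    approach_start: float = 2e-6  # initial tip-membrane distance
    baseline_window: float = 0.05  # feedback's baseline-measurement window
    feedback_latency: float = 0.003  # overshoot time before the halt
    dwell: float = 0.04  # pause between descent steps
    settle: float = 0.05  # pause after the bias switch
    contact_dwell: float = 0.02  # pause at the substrate before retracting

    def __post_init__(self) -> None:
        for name in ("hop_height", "step", "descent_speed", "hold_duration",
                     "approach_start", "dwell", "settle", "contact_dwell"):
            if not (getattr(self, name) > 0):
                raise InvalidParameterError(f"{name} must be > 0")
        if not (0 < self.membrane_drop_fraction < 0.5):
            raise InvalidParameterError("membrane_drop_fraction must be in (0, 0.5)")


@dataclass(frozen=True)
class ExtractionProtocol:
    """Electrowetting extraction protocol (SI units).

    ``interface_coeff`` (A*s/m, >= 0) converts the liquid-liquid interface
    velocity into an extra current contribution with the sign of the
    extraction bias, producing the fast-then-slow transient.
    """

    hold_bias: float = 0.3
    extract_bias: float = -0.5
    extract_duration: float = 10.0
    ingress_max: float = 0.0
    ingress_tau: float = 1.5
    interface_coeff: float = 0.0
    pre_hold_duration: float = 2.0
    post_hold_duration: float = 2.0

    def __post_init__(self) -> None:
        if not (self.extract_duration > 0):
            raise InvalidParameterError("extract_duration must be > 0")
        if self.ingress_max < 0 or self.ingress_tau <= 0:
            raise InvalidParameterError("ingress parameters must be non-negative / positive")
        if self.interface_coeff < 0:
            raise InvalidParameterError("interface_coeff must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Additive noise: white Gaussian everywhere plus band-limited
    'vibrational' noise switched on near the substrate."""

    white_sd: float = 10e-12
    vibration_band: tuple = (50.0, 500.0)
    vibration_amp: float = 50e-12  # RMS amplitude of the in-band component
    vibration_onset_distance: float = 300e-9

    def __post_init__(self) -> None:
        f_lo, f_hi = self.vibration_band
        if not (0 < f_lo < f_hi):
            raise InvalidParameterError("vibration band must satisfy 0 < f_lo < f_hi")
        if self.white_sd < 0 or self.vibration_amp < 0:
            raise InvalidParameterError("noise amplitudes must be >= 0")


@dataclass
class GroundTruth:
    """Sample indices of the simulated phase transitions (None if absent)."""

    hop_stop: Optional[int] = None
    membrane_touch: Optional[int] = None
    vibration_onset: Optional[int] = None
    substrate_contact: Optional[int] = None
    retraction: Optional[int] = None
    extraction_switch_on: Optional[int] = None
    extraction_switch_off: Optional[int] = None

    _ORDER = (
        "hop_stop",
        "membrane_touch",
        "vibration_onset",
        "substrate_contact",
        "retraction",
        "extraction_switch_on",
        "extraction_switch_off",
    )

    def present(self) -> dict:
        return {k: getattr(self, k) for k in self._ORDER if getattr(self, k) is not None}

    def validate(self, n_samples: int) -> None:
        vals = list(self.present().values())
        if any(not (0 <= v < n_samples) for v in vals):
            raise InvalidParameterError("ground-truth index outside trace")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise InvalidParameterError("ground-truth indices not strictly increasing")


@dataclass(frozen=True)
class CellPreset:
    """Cell placed on the substrate: membrane height and the fractional
    current drop registered when the tip touches it (None uses the
    protocol default)."""

    membrane_z: float = GLIAL_MEMBRANE_Z_M
    membrane_drop: Optional[float] = None


@dataclass(frozen=True)
class OrganicPipette:
    """Organic-barrel parameters used by the extraction simulator."""

    geometry: PipetteGeometry
    kappa_cyt: float = DEFAULT_KAPPA_CYT
    kappa_org: float = DEFAULT_KAPPA_ORG

    def resistance(self, ell: float) -> float:
        return plug_resistance(PlugState(ell, self.kappa_cyt), self.geometry, self.kappa_org)


def default_aqueous_electrics(
    bias: float = 0.2,
    bulk_resistance: float = 45.7e6,
    conductivity: float = 1.30,
    z_setpoint: float = 100e-9,
    setpoint_fraction: float = 0.995,
) -> BarrelElectrics:
    """Aqueous barrel at the platform's median calibration: +200 mV across
    45.7 Mohm, with access resistance fixed so the current magnitude falls
    to the 99.5% set point at ``z_setpoint``."""
    return BarrelElectrics(
        conductivity=conductivity,
        bias=bias,
        bulk_resistance=bulk_resistance,
        access_coeff=access_coefficient(bulk_resistance, z_setpoint, setpoint_fraction),
    )


def band_limited_noise(n: int, sample_rate: float, band: tuple, rms: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with all spectral energy inside ``band``, scaled to
    the requested RMS amplitude (brick-wall FFT filter)."""
    if rms == 0 or n < 4:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
    out = np.fft.irfft(spec, n)
    scale = out.std()
    if scale == 0:
        return np.zeros(n)
    return out * (rms / scale)


def simulate_injection_trace(
    protocol: InjectionProtocol,
    electrics: BarrelElectrics,
    noise: NoiseModel,
    cell: CellPreset = CellPreset(),
    seed: int = 0,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    z_setpoint: float = 100e-9,
) -> tuple:
    """Simulate one aqueous-barrel nanoinjection trace.

    The tip coordinate ``zeta`` is the height above the substrate; the
    membrane sits at ``cell.membrane_z``.  Above the membrane the current
    follows the access-resistance approach curve; the tip-membrane distance
    is floored at ``z_setpoint`` once the soft membrane is indented, the
    membrane touch registers as an instantaneous fractional drop, and the
    current is zero while the tip rests on the substrate.

    Returns ``(TraceChannel, GroundTruth)``.  Identical arguments and seed
    give bit-identical output.
    """
    if cell.membrane_z <= 0:
        raise GeometryError("membrane_z must be > 0")
    if protocol.approach_start <= z_setpoint:
        raise GeometryError("approach must start above the set-point distance")
    if noise.vibration_onset_distance >= cell.membrane_z:
        raise GeometryError(
            "vibration onset distance must be below the membrane height "
            "for the phase sequence to be ordered"
        )
    drop = protocol.membrane_drop_fraction if cell.membrane_drop is None else cell.membrane_drop
    dt = 1.0 / sample_rate
    dz = protocol.descent_speed * dt  # vertical travel per sample while moving
    zeta_mem = cell.membrane_z

    pos_parts: list = []
    truth = GroundTruth()

    def ramp(z0: float, z1: float) -> np.ndarray:
        n = max(int(round(abs(z1 - z0) / dz)), 1)
        return z0 + (z1 - z0) * np.arange(1, n + 1) / n

    def dwell(z: float, duration: float) -> np.ndarray:
        return np.full(max(int(round(duration * sample_rate)), 1), z)

    # (i) approach: continuous descent until the current magnitude falls
    # to setpoint_fraction x the feedback's own measured baseline (the
    # median over its initial window, as on the instrument), then retract
    # by the hop height
    setpoint_fraction = 1.0 / (1.0 + electrics.access_coeff / (electrics.bulk_resistance * z_setpoint))
    z_full = ramp(protocol.approach_start, dz)
    norm_full = 1.0 / (1.0 + electrics.access_coeff / (electrics.bulk_resistance * z_full))
    n_base = max(min(int(round(protocol.baseline_window * sample_rate)), len(z_full) // 2), 1)
    measured_baseline = float(np.median(norm_full[:n_base]))
    crossed = np.nonzero(norm_full <= setpoint_fraction * measured_baseline)[0]
    if len(crossed) == 0:
        raise GeometryError("approach never reaches the set point; start farther out")
    stop = int(crossed[0])
    # feedback latency: the probe keeps moving briefly after the set-point
    # event before halting, as on the instrument
    overshoot = int(round(protocol.feedback_latency * sample_rate))
    halt = min(stop + overshoot, len(z_full) - 1)
    approach = zeta_mem + z_full[: halt + 1]
    pos_parts.append(approach)
    truth.hop_stop = stop
    z_halt = float(z_full[halt])
    zeta_hop = zeta_mem + z_halt + protocol.hop_height
    pos_parts.append(ramp(zeta_mem + z_halt, zeta_hop))
    n_aq = sum(len(p) for p in pos_parts)

    # (ii) bias switch + settle, (iii) stepped descent to the substrate
    pos_parts.append(dwell(zeta_hop, protocol.settle))
    z_cur = zeta_hop
    while z_cur > 0:
        z_next = max(z_cur - protocol.step, 0.0)
        pos_parts.append(ramp(z_cur, z_next))
        z_cur = z_next
        if z_cur > 0:
            pos_parts.append(dwell(z_cur, protocol.dwell))
    # (v) contact, (vi) retract one step and hold
    pos_parts.append(dwell(0.0, protocol.contact_dwell))
    pos_parts.append(ramp(0.0, protocol.step))
    pos_parts.append(dwell(protocol.step, protocol.hold_duration))

    zeta = np.concatenate(pos_parts)
    n = len(zeta)

    bias = np.empty(n)
    bias[:n_aq] = electrics.bias
    bias[n_aq:] = protocol.inject_bias

    # deterministic current: access curve w.r.t. the true membrane
    # distance during the aqueous approach/retract; during the stepped
    # descent the soft membrane deflects ahead of genuine contact and does
    # not seal after it, so the access distance is floored at the
    # set-point distance; x drop factor after touch; zero on the substrate
    z_mem_dist = zeta - zeta_mem
    in_descent = np.arange(n) >= n_aq
    z_mem_dist = np.where(in_descent, np.maximum(z_mem_dist, z_setpoint), z_mem_dist)
    denom = electrics.bulk_resistance + electrics.access_coeff / z_mem_dist
    current = bias / denom

    touched = np.zeros(n, dtype=bool)
    idx_touch = np.nonzero((zeta <= zeta_mem) & (np.arange(n) >= n_aq))[0]
    if len(idx_touch):
        truth.membrane_touch = int(idx_touch[0])
        touched[idx_touch[0]:] = True
        current[touched] *= 1.0 - drop

    in_vib = (zeta <= noise.vibration_onset_distance) & (zeta > 0) & (np.arange(n) >= n_aq)
    idx_vib = np.nonzero(in_vib)[0]
    if len(idx_vib):
        truth.vibration_onset = int(idx_vib[0])

    on_substrate = zeta <= 0
    idx_contact = np.nonzero(on_substrate)[0]
    if len(idx_contact):
        truth.substrate_contact = int(idx_contact[0])
        current[on_substrate] = 0.0
        idx_retract = np.nonzero(~on_substrate & (np.arange(n) > idx_contact[0]))[0]
        if len(idx_retract):
            truth.retraction = int(idx_retract[0])

    rng = np.random.default_rng(seed)
    if noise.white_sd > 0:
        current = current + rng.normal(0.0, noise.white_sd, n)
    if noise.vibration_amp > 0 and in_vib.any():
        vib = band_limited_noise(n, sample_rate, noise.vibration_band, noise.vibration_amp, rng)
        current = current + vib * in_vib

    trace = TraceChannel(sample_rate=sample_rate, current=current, bias=bias, position=zeta)
    truth.validate(n)
    return trace, truth


def simulate_extraction_trace(
    protocol: ExtractionProtocol,
    pipette: OrganicPipette,
    noise: NoiseModel = NoiseModel(vibration_amp=0.0),
    seed: int = 0,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
) -> tuple:
    """Simulate one organic-barrel extraction trace.

    Hold at ``hold_bias`` with an empty barrel, switch to ``extract_bias``
    for ``extract_duration`` during which the cytoplasm column grows as
    ``ell(t) = ingress_max (1 - exp(-t/tau))`` and the interface velocity
    contributes ``sign(extract_bias) * beta * dell/dt``; then hold again at
    ``hold_bias`` with the column pinned at ``ingress_max``.
    """
    if protocol.ingress_max > pipette.geometry.length:
        raise InvalidParameterError("ingress_max exceeds the barrel length")
    dt = 1.0 / sample_rate
    n_pre = int(round(protocol.pre_hold_duration * sample_rate))
    n_ext = int(round(protocol.extract_duration * sample_rate))
    n_post = int(round(protocol.post_hold_duration * sample_rate))
    n = n_pre + n_ext + n_post

    bias = np.concatenate([
        np.full(n_pre, protocol.hold_bias),
        np.full(n_ext, protocol.extract_bias),
        np.full(n_post, protocol.hold_bias),
    ])

    current = np.empty(n)
    current[:n_pre] = protocol.hold_bias / pipette.resistance(0.0)

    t = np.arange(n_ext) * dt
    ell = protocol.ingress_max * (1.0 - np.exp(-t / protocol.ingress_tau))
    dell_dt = (protocol.ingress_max / protocol.ingress_tau) * np.exp(-t / protocol.ingress_tau)
    resistances = np.array([pipette.resistance(float(l)) for l in ell])
    current[n_pre:n_pre + n_ext] = (
        protocol.extract_bias / resistances
        + math.copysign(1.0, protocol.extract_bias) * protocol.interface_coeff * dell_dt
    )
    current[n_pre + n_ext:] = protocol.hold_bias / pipette.resistance(protocol.ingress_max)

    rng = np.random.default_rng(seed)
    if noise.white_sd > 0:
        current = current + rng.normal(0.0, noise.white_sd, n)

    truth = GroundTruth(extraction_switch_on=n_pre, extraction_switch_off=n_pre + n_ext)
    trace = TraceChannel(sample_rate=sample_rate, current=current, bias=bias)
    truth.validate(n)
    return trace, truth


def calibrate_extraction_example(
    targets: dict,
    r_tip: float = DEFAULT_R_TIP_M,
    length: float = DEFAULT_LENGTH_M,
    kappa_cyt: float = DEFAULT_KAPPA_CYT,
    kappa_org: float = DEFAULT_KAPPA_ORG,
    hold_bias: float = 0.3,
    extract_bias: float = -0.5,
    extract_duration: float = 10.0,
    ingress_tau: float = 1.5,
) -> tuple:
    """Pipette + protocol reproducing a printed extraction trace.

    ``targets`` holds ``pre_hold_nA``, ``peak_nA`` and ``post_hold_nA`` as
    current magnitudes.  The barrel taper is calibrated so the empty-barrel
    resistance matches the pre-extraction hold current at ``hold_bias``;
    the ingress length is inverted from the post-extraction hold current;
    and the interface coefficient is set so the instantaneous current at
    the bias switch matches the printed peak.

    Returns ``(ExtractionProtocol, OrganicPipette)``.
    """
    pre = abs(targets["pre_hold_nA"]) * 1e-9
    peak = abs(targets["peak_nA"]) * 1e-9
    post = abs(targets["post_hold_nA"]) * 1e-9
    if pre <= 0 or post < pre:
        raise CalibrationError(
            "targets must satisfy |post_hold| >= |pre_hold| > 0 "
            f"(got pre={targets['pre_hold_nA']}, post={targets['post_hold_nA']} nA)"
        )
    r_empty = abs(hold_bias) / pre
    taper = calibrate_taper(r_empty, r_tip, kappa_org, length)
    geometry = PipetteGeometry(r_tip=r_tip, taper=taper, length=length)
    pipette = OrganicPipette(geometry=geometry, kappa_cyt=kappa_cyt, kappa_org=kappa_org)

    if post == pre:
        ingress_max, beta = 0.0, 0.0
    else:
        r_after = abs(hold_bias) / post
        ingress_max = invert_ingress(r_after, geometry, kappa_cyt, kappa_org)
        ohmic_peak = abs(extract_bias) / r_empty
        if peak < ohmic_peak:
            raise CalibrationError(
                f"peak magnitude {targets['peak_nA']} nA below the ohmic jump "
                f"{ohmic_peak * 1e9:.3g} nA implied by the pre-hold resistance"
            )
        beta = (peak - ohmic_peak) * ingress_tau / ingress_max

    protocol = ExtractionProtocol(
        hold_bias=hold_bias,
        extract_bias=extract_bias,
        extract_duration=extract_duration,
        ingress_max=ingress_max,
        ingress_tau=ingress_tau,
        interface_coeff=beta,
    )
    return protocol, pipette
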