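"""Synthetic data emulating the study's voltage-clamp and trajectory inputs.

No raw oocyte recordings or MD trajectories exist for download, so every
analysis stage is exercised on generated inputs whose ground truth is known
and recorded alongside: inactivating K+ current families from the
three-state scheme, gating-current sweeps whose noise-free ON integral
equals a prescribed Boltzmann charge, Q(V) datasets mixing one or two
Boltzmann components, and fourfold-symmetric selectivity-filter
trajectories with programmable widening, collapse, ion-exit and pull-site
drift events written as multi-model PDB.

All generators are pure functions of (parameters, seed): the same call
yields bit-identical output.  Geometry magnitudes of the toy filter
(0.25 nm carbonyl rings stacked 0.3 nm apart, ions on the pore axis) are
chosen for plausibility; they are synthetic, not structural truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .charge import QVCurve, boltzmann
from .geometry import Frame, write_trajectory
from .kinetics import KineticRates, simulate_three_state, voltage_dependent_activation
from .traces import CurrentTrace, GatingTrace

__all__ = [
    "ProtocolSpec",
    "NoiseSpec",
    "INACTIVATION_PROTOCOL",
    "ACTIVATION_PROTOCOL",
    "GATING_PROTOCOL",
    "gen_inactivation_family",
    "gen_gating_current",
    "gen_qv_dataset",
    "gen_filter_trajectory",
]


@dataclass(frozen=True)
class ProtocolSpec:
    """A voltage-step family: holding voltage, test steps, timing (seconds)."""

    holding_voltage: float  # mV
    step_voltages: tuple[float, ...]  # mV
    step_duration: float  # s
    sample_interval: float  # s

    def __post_init__(self) -> None:
        if self.step_duration <= 0 or self.sample_interval <= 0:
            raise ValueError("durations must be positive")
        if len(self.step_voltages) < 1:
            raise ValueError("need at least one step voltage")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise scaled to the trace peak, with explicit seed."""

    sigma_fraction_of_peak: float = 0.0
    seed: int = 0
    kind: str = "gaussian_additive"

    def __post_init__(self) -> None:
        if self.sigma_fraction_of_peak < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.kind != "gaussian_additive":
            raise ValueError(f"unknown noise kind {self.kind!r}")


# The study's three stimulus protocols: 10-s inactivation steps, 100-ms
# activation families, and 60-ms gating-current pulses.
INACTIVATION_PROTOCOL = ProtocolSpec(
    holding_voltage=-80.0,
    step_voltages=tuple(np.arange(-40.0, 80.0 + 1, 20.0)),
    step_duration=10.0,
    sample_interval=0.01,
)
ACTIVATION_PROTOCOL = ProtocolSpec(
    holding_voltage=-80.0,
    step_voltages=tuple(np.arange(-80.0, 100.0 + 1, 10.0)),
    step_duration=0.1,
    sample_interval=1e-4,
)
GATING_PROTOCOL = ProtocolSpec(
    holding_voltage=-80.0,
    step_voltages=tuple(np.arange(-150.0, 100.0 + 1, 10.0)),
    step_duration=0.06,
    sample_interval=5e-5,
)

# Inactivation rates reproducing the wild-type decay (tau 4.8 s, 30% steady
# state): kappa = (1-SS)/tau, lambda = SS/tau.
WT_RATES = KineticRates(
    alpha=voltage_dependent_activation()[0],
    beta=voltage_dependent_activation()[1],
    kappa=0.7 / 4.8,
    lambda_=0.3 / 4.8,
)


def _add_noise(current: np.ndarray, noise: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    if noise.sigma_fraction_of_peak == 0:
        return current
    sigma = noise.sigma_fraction_of_peak * np.max(np.abs(current))
    return current + rng.normal(0.0, sigma, size=current.shape)


@dataclass(frozen=True)
class InactivationFamily:
    traces: tuple[CurrentTrace, ...]
    truth: dict = field(default_factory=dict)  # label -> {kappa, lambda, ...}


def gen_inactivation_family(
    rates_by_condition: dict[str, KineticRates],
    protocol: ProtocolSpec = INACTIVATION_PROTOCOL,
    noise: NoiseSpec = NoiseSpec(),
    g_max: float = 0.025,
    v_rev: float = -80.0,
) -> InactivationFamily:
    """Simulate an inactivating current family for each condition.

    One trace per (condition, step voltage) via the exact three-state
    propagator, plus seeded Gaussian noise; the true rate constants per
    condition are recorded in the ``truth`` sidecar for recovery tests.
    """
    rng = np.random.default_rng(noise.seed)
    traces: list[CurrentTrace] = []
    truth: dict[str, dict] = {}
    for label, rates in rates_by_condition.items():
        truth[label] = {
            "kappa_per_s": rates.kappa,
            "lambda_per_s": rates.lambda_,
            "tau_s": 1.0 / (rates.kappa + rates.lambda_)
            if rates.kappa + rates.lambda_ > 0
            else float("inf"),
            "ss_frac": rates.lambda_ / (rates.kappa + rates.lambda_)
            if rates.kappa + rates.lambda_ > 0
            else 1.0,
        }
        for v in protocol.step_voltages:
            clean = simulate_three_state(
                rates,
                step_voltage=v,
                holding_voltage=protocol.holding_voltage,
                duration=protocol.step_duration,
                dt=protocol.sample_interval,
                g_max=g_max,
                v_rev=v_rev,
                label=label,
            )
            noisy = CurrentTrace(
                time=clean.time,
                current=_add_noise(clean.current, noise, rng),
                step_voltage=v,
                holding_voltage=protocol.holding_voltage,
                label=label,
            )
            traces.append(noisy)
    return InactivationFamily(traces=tuple(traces), truth=truth)


def _gating_shape(t_ms: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Unit-integral ON gating-current shape with a slow rising phase."""
    s = (1.0 - np.exp(-t_ms / tau_rise)) * np.exp(-t_ms / tau_decay)
    # closed-form integral of the shape on [0, inf)
    integral = tau_decay**2 / (tau_rise + tau_decay)
    return s / integral


@dataclass(frozen=True)
class GatingFamily:
    traces: tuple[GatingTrace, ...]
    truth: dict = field(default_factory=dict)


def gen_gating_current(
    q_total: float,
    v_half: float,
    slope: float,
    tau_on: float = 1.7,
    tau_off: float = 5.2,
    protocol: ProtocolSpec = GATING_PROTOCOL,
    tau_rise: float = 0.3,
    spike_amplitude: float = 0.0,
    spike_tau: float = 0.2,
    leak_g: float = 0.0,
    noise: NoiseSpec = NoiseSpec(),
    baseline_ms: float = 5.0,
    off_ms: float = 60.0,
) -> GatingFamily:
    """Generate gating-current sweeps whose ON integral follows a Boltzmann.

    The charge moved at step voltage V is ``Q(V) = q_total * B(V; v_half,
    slope)`` (nC); the noise-free, spike-free, leak-free ON current
    integrates to exactly that charge, and the OFF current returns the same
    charge with the slower time constant ``tau_off``, so ON and OFF charges
    balance by construction.  Optional ingredients: a fast capacitive spike
    at both edges (sub-``1.5 ms`` decay), an ohmic leak ``leak_g`` (µS), and
    seeded additive noise.

    Times in ms; the sweep spans ``-baseline_ms`` to pulse end + ``off_ms``.
    """
    if tau_on <= 0 or tau_off <= 0 or tau_rise <= 0:
        raise ValueError("time constants must be positive")
    rng = np.random.default_rng(noise.seed)
    dt = protocol.sample_interval * 1e3  # ms
    dur = protocol.step_duration * 1e3  # ms
    time = np.arange(-baseline_ms, dur + off_ms + dt / 2, dt)
    traces: list[GatingTrace] = []
    truth = {
        "q_total_nC": q_total,
        "v_half_mV": v_half,
        "slope_mV": slope,
        "tau_on_ms": tau_on,
        "tau_off_ms": tau_off,
        "charge_nC_by_voltage": {},
    }
    for v in protocol.step_voltages:
        q_v = q_total * float(boltzmann(np.array([v]), 1.0, v_half, slope)[0])
        current = np.zeros_like(time)
        on = (time >= 0) & (time <= dur)
        off = time > dur
        current[on] = q_v * _gating_shape(time[on], tau_rise, tau_on)
        current[off] = -q_v * _gating_shape(time[off] - dur, tau_rise, tau_off)
        if spike_amplitude:
            current[on] += spike_amplitude * np.exp(-time[on] / spike_tau)
            current[off] -= spike_amplitude * np.exp(-(time[off] - dur) / spike_tau)
        if leak_g:
            volts = np.full_like(time, protocol.holding_voltage)
            volts[on] = v
            current += leak_g * volts * 1e-3  # µS * mV = nA -> µA
        current = _add_noise(current, noise, rng)
        traces.append(
            GatingTrace(
                time=time,
                current=current,
                step_voltage=v,
                holding_voltage=protocol.holding_voltage,
                pulse_duration=dur,
            )
        )
        truth["charge_nC_by_voltage"][float(v)] = q_v
    return GatingFamily(traces=tuple(traces), truth=truth)


@dataclass(frozen=True)
class QVDataset:
    curve: QVCurve
    truth: dict = field(default_factory=dict)


def gen_qv_dataset(
    components: list[tuple[float, float]],
    slope: float = 10.0,
    voltages: np.ndarray | None = None,
    holding_voltage: float = -80.0,
    noise: NoiseSpec = NoiseSpec(),
) -> QVDataset:
    """Generate a normalized Q(V) dataset from 1-2 Boltzmann components.

    ``components`` is a list of (fraction, v_half); fractions must sum to 1
    and all components share ``slope``.  Noise (fraction of the maximum) is
    added before the final percent normalization.
    """
    fracs = np.array([c[0] for c in components], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError(f"component fractions must sum to 1, got {fracs.sum()}")
    if voltages is None:
        voltages = np.arange(-150.0, 100.0 + 1, 10.0)
    voltages = np.asarray(voltages, dtype=float)
    q = np.zeros_like(voltages)
    for frac, vh in components:
        q += frac * boltzmann(voltages, 1.0, vh, slope)
    rng = np.random.default_rng(noise.seed)
    q = _add_noise(q, noise, rng)
    pct = 100.0 * q / q.max()
    curve = QVCurve(voltages=voltages, charge_pct=pct, holding_voltage=holding_voltage)
    truth = {
        "components": [{"fraction": f, "v_half_mV": vh} for f, vh in components],
        "slope_mV": slope,
    }
    return QVDataset(curve=curve, truth=truth)


# ---------------------------------------------------------------------------
# toy selectivity-filter trajectory

_CHAIN_ANGLES = {"A": 0.0, "B": 90.0, "C": 180.0, "D": 270.0}
_BACKBONE_RADII = {"N": 0.40, "CA": 0.45, "C": 0.35, "O": 0.25}
_BACKBONE_ANGLE_OFFSETS = {"N": -8.0, "CA": 0.0, "C": 8.0, "O": 3.0}
_RING_SPACING = 0.3  # nm between stacked residue rings
_F416_RADIUS = 1.2  # nm from the pore axis
_F416_Z = 0.45


def _base_frame_atoms(
    f416_radius: float,
    diameter_offsets: dict[int, float],
    ion_positions: list[tuple[str, np.ndarray]],
) -> tuple[list, np.ndarray]:
    """Atom records and coordinates of the idealized fourfold channel."""
    records = []  # (chain, res_id, res_name, atom_name, element)
    coords = []
    for chain, angle0 in _CHAIN_ANGLES.items():
        for res in range(441, 447):
            z = (res - 441) * _RING_SPACING
            extra = diameter_offsets.get(res, 0.0) / 2.0  # diameter -> radius
            for atom, radius in _BACKBONE_RADII.items():
                theta = np.deg2rad(angle0 + _BACKBONE_ANGLE_OFFSETS[atom])
                r = radius + extra
                records.append((chain, res, "GLY", atom, atom[0]))
                coords.append([r * np.cos(theta), r * np.sin(theta), z])
        # F416 side-chain site: two carbons straddling the COM radially
        theta = np.deg2rad(angle0 + 45.0)
        for atom, dr in (("CB", -0.05), ("CG", 0.05)):
            r = f416_radius + dr
            records.append((chain, 416, "PHE", atom, "C"))
            coords.append([r * np.cos(theta), r * np.sin(theta), _F416_Z])
    for i, (ion_name, pos) in enumerate(ion_positions):
        records.append(("I", 901 + i, ion_name, ion_name, ion_name))
        coords.append(list(pos))
    return records, np.array(coords)


@dataclass(frozen=True)
class FilterTrajectory:
    frames: tuple[Frame, ...]
    truth: dict = field(default_factory=dict)

    def write(self, pdb_path: str | Path) -> None:
        write_trajectory(list(self.frames), pdb_path)
        sidecar = Path(str(pdb_path) + ".json")
        sidecar.write_text(json.dumps(self.truth, indent=1))


def gen_filter_trajectory(
    n_frames: int = 50,
    frame_dt: float = 1.0,
    widening_schedule: dict[int, float] | None = None,
    collapse_frame: int | None = None,
    collapse_positions: tuple[int, ...] = (444, 445),
    collapse_step: float = 0.1,
    ion_exit_frame: int | None = None,
    f416_drift: float = 0.0,
    jitter_sigma: float = 0.0,
    seed: int = 0,
) -> FilterTrajectory:
    """Generate a toy selectivity-filter trajectory with programmed events.

    Parameters
    ----------
    n_frames, frame_dt : int, float
        Number of frames and time per frame (ns).
    widening_schedule : dict, optional
        Residue position -> diameter growth per frame (nm/frame), applied
        cumulatively from frame 0.
    collapse_frame : int, optional
        Frame index at which ``collapse_step`` nm is added abruptly to the
        diameter of ``collapse_positions``.
    ion_exit_frame : int, optional
        Frame index at which the uppermost K+ ion leaves the filter.
    f416_drift : float
        Outward (centrifugal) speed of each residue-416 site in nm/ns; the
        opposing-pair COM distance therefore grows at twice this rate.
    jitter_sigma : float
        Gaussian positional noise per coordinate (nm), seeded.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    widening_schedule = widening_schedule or {}
    if collapse_frame is not None and not (0 <= collapse_frame < n_frames):
        raise ValueError("collapse_frame outside trajectory")
    if ion_exit_frame is not None and not (0 <= ion_exit_frame < n_frames):
        raise ValueError("ion_exit_frame outside trajectory")

    rng = np.random.default_rng(seed)
    ions_home = [
        ("K", np.array([0.0, 0.0, 0.75])),  # on-axis, between the 443/446 rings
        ("K", np.array([0.0, 0.0, 1.2])),
        ("NA", np.array([2.0, 0.0, 1.5])),  # bulk sodium, outside the filter
    ]
    frames: list[Frame] = []
    for k in range(n_frames):
        t = k * frame_dt
        offsets = {pos: rate * k for pos, rate in widening_schedule.items()}
        if collapse_frame is not None and k >= collapse_frame:
            for pos in collapse_positions:
                offsets[pos] = offsets.get(pos, 0.0) + collapse_step
        ions = [(name, pos.copy()) for name, pos in ions_home]
        if ion_exit_frame is not None and k >= ion_exit_frame:
            ions[1] = ("K", np.array([2.5, 2.5, 1.8]))  # top K+ leaves
        records, coords = _base_frame_atoms(
            f416_radius=_F416_RADIUS + f416_drift * t,
            diameter_offsets=offsets,
            ion_positions=ions,
        )
        if jitter_sigma > 0:
            coords = coords + rng.normal(0.0, jitter_sigma, size=coords.shape)
        frames.append(
            Frame(
                chain_id=np.array([r[0] for r in records]),
                res_id=np.array([r[1] for r in records]),
                res_name=np.array([r[2] for r in records]),
                atom_name=np.array([r[3] for r in records]),
                element=np.array([r[4] for r in records]),
                coords=coords,
                frame_time=t,
            )
        )
    truth = {
        "n_frames": n_frames,
        "frame_dt_ns": frame_dt,
        "widening_schedule_nm_per_frame": {str(k): v for k, v in widening_schedule.items()},
        "collapse_frame": collapse_frame,
        "collapse_positions": list(collapse_positions),
        "collapse_step_nm": collapse_step,
        "ion_exit_frame": ion_exit_frame,
        "f416_drift_nm_per_ns": f416_drift,
        "f416_pair_distance_rate_nm_per_ns": 2 * f416_drift,
        "jitter_sigma_nm": jitter_sigma,
        "seed": seed,
    }
    return FilterTrajectory(frames=tuple(frames), truth=truth)
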