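"""Seeded synthetic driving-behavior generator.

Produces six-channel telemetry for normal and alcohol-impaired drivers on
three route archetypes (accident-prone urban, urban, highway). The plant is
a kinematic single-track model; the driver is a delayed proportional-
derivative lane-keeping controller with curvature feedforward plus a
proportional speed tracker. Impairment lengthens the reaction delay, scales
the control noise, and adds a sinusoidal lane weave — the qualitative
signatures of drunk driving (larger, faster steering corrections and poorer
lane keeping) without attempting vehicle-dynamics fidelity.

Everything is deterministic in the seed: the same spec and seed reproduce a
record bit-for-bit, and the null impairment reproduces the normal branch
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .records import DrivingRecord, write_record

#: Sober baseline reaction delay (s); impairment delay is added on top.
BASE_REACTION_S = 0.2

# vehicle and driver constants (kinematic single-track)
WHEELBASE_M = 2.7
MAX_WHEEL_ANGLE_RAD = 0.5
ACCEL_MAX = 3.0           # m/s^2 at full throttle
BRAKE_MAX = 5.0           # m/s^2 at full brake
DRAG_COEF = 0.002         # quadratic drag, 1/m
ROLL_RESIST = 0.05        # m/s^2
LAT_KP = 1.0              # lateral accel per m of lane error, 1/s^2
LAT_KD = 1.6              # lateral accel per m/s of error rate, 1/s
SPEED_KP = 0.4            # accel per m/s of speed error, 1/s
STEER_NOISE_STD = 0.4     # AR(1) steering noise, in lateral-accel units m/s^2
STEER_NOISE_RHO = 0.9
SPEED_NOISE_STD = 0.25    # AR(1) innovation on commanded accel, m/s^2
SPEED_NOISE_RHO = 0.95


@dataclass
class ScenarioSpec:
    """Route geometry and speed plan for one journey."""

    route: str
    duration_s: float
    frame_rate: float = 10.0
    #: list of (start_s, target_speed_kmh); piecewise-constant
    target_speed_profile: list[tuple[float, float]] = field(default_factory=list)
    #: list of (start_s, duration_s, peak_curvature_per_m)
    curvature_events: list[tuple[float, float, float]] = field(default_factory=list)
    #: list of (start_s, duration_s); target speed forced to 0
    stop_events: list[tuple[float, float]] = field(default_factory=list)

    def validate(self) -> None:
        if self.duration_s <= 0 or self.frame_rate <= 0:
            raise ValueError("duration_s and frame_rate must be positive")
        if not self.target_speed_profile:
            raise ValueError("target_speed_profile must not be empty")
        for start, dur, _ in self.curvature_events:
            if not (0 <= start and start + dur <= self.duration_s):
                raise ValueError("curvature event outside [0, duration_s]")
        for start, dur in self.stop_events:
            if not (0 <= start and start + dur <= self.duration_s):
                raise ValueError("stop event outside [0, duration_s]")


@dataclass
class ImpairmentSpec:
    """Behavioral modifiers applied to the driver controller.

    The null spec (0, 1, 1, 0, inf, 1) leaves the normal controller
    untouched.
    """

    reaction_delay_s: float = 0.4
    gain_multiplier: float = 1.0
    steering_noise_multiplier: float = 2.0
    weave_amplitude: float = 0.3       # m
    weave_period_s: float = 6.0
    speed_noise_multiplier: float = 2.0

    def validate(self) -> None:
        if self.reaction_delay_s < 0 or self.gain_multiplier <= 0:
            raise ValueError("invalid impairment spec")
        if (self.steering_noise_multiplier < 1 or self.weave_amplitude < 0
                or self.weave_period_s <= 0 or self.speed_noise_multiplier < 1):
            raise ValueError("invalid impairment spec")


NULL_IMPAIRMENT = ImpairmentSpec(0.0, 1.0, 1.0, 0.0, math.inf, 1.0)


def default_scenario(route: str, duration_s: float | None = None) -> ScenarioSpec:
    """Shipped per-route scenario defaults.

    Highway runs longer, faster and with gentler curvature than the urban
    routes; the accident route has the densest curvature and stop events.
    """
    if route == "urban":
        spec = ScenarioSpec(
            route="urban", duration_s=120.0,
            target_speed_profile=[(0, 40), (30, 50), (60, 30), (90, 45)],
            curvature_events=[(20, 8, 0.010), (55, 6, -0.012), (100, 8, 0.008)],
            stop_events=[(70, 6)])
    elif route == "accident":
        spec = ScenarioSpec(
            route="accident", duration_s=120.0,
            target_speed_profile=[(0, 35), (25, 45), (50, 25), (80, 40)],
            curvature_events=[(15, 5, 0.015), (40, 6, -0.018),
                              (62, 5, 0.012), (95, 6, -0.015)],
            stop_events=[(32, 5), (85, 6)])
    elif route == "highway":
        spec = ScenarioSpec(
            route="highway", duration_s=180.0,
            target_speed_profile=[(0, 80), (60, 100), (120, 90)],
            curvature_events=[(30, 20, 0.003), (90, 25, -0.004),
                              (140, 20, 0.003)],
            stop_events=[])
    else:
        raise ValueError(f"unknown route {route!r}")
    if duration_s is not None:
        scale = duration_s / spec.duration_s
        spec = replace(
            spec, duration_s=duration_s,
            target_speed_profile=[(s * scale, v)
                                  for s, v in spec.target_speed_profile],
            curvature_events=[(s * scale, d * scale, k)
                              for s, d, k in spec.curvature_events],
            stop_events=[(s * scale, d * scale) for s, d in spec.stop_events])
    return spec


@dataclass
class SimConfig:
    """Dataset-level generator configuration; identical configs yield
    byte-identical datasets."""

    seed: int = 0
    records_per_cell: int = 5
    n_participants: int = 6
    duration_override_s: float | None = None
    impairment: ImpairmentSpec = field(default_factory=ImpairmentSpec)


def _piecewise_target(spec: ScenarioSpec, t: np.ndarray) -> np.ndarray:
    v = np.zeros_like(t)
    for start, kmh in sorted(spec.target_speed_profile):
        v[t >= start] = kmh / 3.6
    for start, dur in spec.stop_events:
        v[(t >= start) & (t < start + dur)] = 0.0
    return v


def _curvature(spec: ScenarioSpec, t: np.ndarray) -> np.ndarray:
    k = np.zeros_like(t)
    for start, dur, peak in spec.curvature_events:
        mask = (t >= start) & (t < start + dur)
        k[mask] += peak * np.sin(np.pi * (t[mask] - start) / dur) ** 2
    return k


def simulate_record(scenario: ScenarioSpec,
                    impairment: ImpairmentSpec | None,
                    seed: int | np.random.SeedSequence,
                    record_id: str = "sim-000",
                    participant_id: str = "p00") -> DrivingRecord:
    """Generate one journey by closed-loop simulation.

    ``impairment=None`` selects the null impairment (normal driving). The
    same inputs reproduce the record exactly.
    """
    scenario.validate()
    imp = NULL_IMPAIRMENT if impairment is None else impairment
    imp.validate()
    status = "normal" if impairment is None else "drunk"
    rng = np.random.default_rng(seed)

    dt = 1.0 / scenario.frame_rate
    T = int(round(scenario.duration_s * scenario.frame_rate))
    t = np.arange(T) * dt
    v_target = _piecewise_target(scenario, t)
    kappa = _curvature(scenario, t)

    delay_frames = int(round((BASE_REACTION_S + imp.reaction_delay_s)
                             / dt))
    # measurement buffers for the delayed driver
    e_hist = np.zeros(delay_frames + 1)
    ed_hist = np.zeros(delay_frames + 1)
    v_hist = np.zeros(delay_frames + 1)

    steer_sigma = STEER_NOISE_STD * imp.steering_noise_multiplier
    accel_sigma = SPEED_NOISE_STD * imp.speed_noise_multiplier
    weave_omega = (0.0 if not math.isfinite(imp.weave_period_s)
                   else 2.0 * math.pi / imp.weave_period_s)

    v = v_target[0]
    e = 0.0           # lane-center deviation, m
    psi = 0.0         # heading error relative to road, rad
    n_steer = 0.0
    n_accel = 0.0
    out = np.zeros((T, 6))
    v_hist[:] = v

    for i in range(T):
        e_hist = np.roll(e_hist, 1)
        ed_hist = np.roll(ed_hist, 1)
        v_hist = np.roll(v_hist, 1)
        e_hist[0] = e
        ed_hist[0] = v * math.sin(psi)
        v_hist[0] = v

        e_meas = e_hist[delay_frames]
        ed_meas = ed_hist[delay_frames]
        v_meas = v_hist[delay_frames]

        # driver lateral control: PD on (delayed) lane error toward the
        # weave reference, curvature feedforward, AR(1) command noise
        e_ref = imp.weave_amplitude * math.sin(weave_omega * t[i])
        n_steer = (STEER_NOISE_RHO * n_steer
                   + math.sqrt(1 - STEER_NOISE_RHO ** 2)
                   * rng.normal(0.0, steer_sigma))
        a_lat = (-(LAT_KP * (e_meas - e_ref) + LAT_KD * ed_meas)
                 * imp.gain_multiplier + n_steer)
        v_eff = max(v, 3.0)  # low-speed steering authority floor
        u = (WHEELBASE_M * (a_lat + v_eff ** 2 * kappa[i])
             / (v_eff ** 2 * MAX_WHEEL_ANGLE_RAD))
        u = min(1.0, max(-1.0, u))

        # driver longitudinal control: proportional tracking + noise
        n_accel = (SPEED_NOISE_RHO * n_accel
                   + math.sqrt(1 - SPEED_NOISE_RHO ** 2)
                   * rng.normal(0.0, accel_sigma))
        a_cmd = SPEED_KP * (v_target[i] - v_meas) + n_accel
        feedforward = (DRAG_COEF * v * v + ROLL_RESIST) / ACCEL_MAX
        throttle = min(1.0, max(0.0, a_cmd / ACCEL_MAX + feedforward))
        brake = min(1.0, max(0.0, -a_cmd / BRAKE_MAX))

        # plant update (kinematic single-track)
        wheel = u * MAX_WHEEL_ANGLE_RAD
        r = v / WHEELBASE_M * math.tan(wheel)
        out[i] = (v * 3.6, u, throttle, brake, e, r)

        psi += (r - v * kappa[i]) * dt
        e += v * math.sin(psi) * dt
        v += (throttle * ACCEL_MAX - brake * BRAKE_MAX
              - DRAG_COEF * v * v - ROLL_RESIST) * dt
        v = max(v, 0.0)

    return DrivingRecord(
        record_id=record_id, participant_id=participant_id,
        route=scenario.route, status=status,
        frame_rate=scenario.frame_rate, frames=out)


def simulate_dataset(config: SimConfig) -> list[DrivingRecord]:
    """records_per_cell journeys per (route x status) cell.

    Child seeds derive deterministically from ``config.seed``; participant
    ids are assigned round-robin.
    """
    if config.records_per_cell < 1:
        raise ValueError("records_per_cell must be >= 1")
    records: list[DrivingRecord] = []
    idx = 0
    for route in ("accident", "urban", "highway"):
        scenario = default_scenario(route, config.duration_override_s)
        for status in ("normal", "drunk"):
            imp = None if status == "normal" else config.impairment
            for i in range(config.records_per_cell):
                child = np.random.SeedSequence(
                    entropy=config.seed, spawn_key=(idx,))
                pid = f"p{idx % config.n_participants:02d}"
                rid = f"{route}-{status}-{i:03d}"
                records.append(simulate_record(
                    scenario, imp, child, record_id=rid, participant_id=pid))
                idx += 1
    return records


def write_fixtures(records: list[DrivingRecord], directory: str | Path,
                   overwrite: bool = False) -> pd.DataFrame:
    """Write one CSV per record plus a manifest; refuses to clobber an
    existing manifest unless ``overwrite`` is set."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_path = directory / "manifest.csv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(
            f"{manifest_path} exists; pass overwrite=True to replace")
    rows = []
    for rec in records:
        fname = f"{rec.record_id}.csv"
        write_record(rec, directory / fname)
        rows.append({"record_id": rec.record_id,
                     "participant_id": rec.participant_id,
                     "route": rec.route, "status": rec.status,
                     "frame_rate": rec.frame_rate,
                     "n_frames": rec.n_frames, "file": fname})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(manifest_path, index=False)
    return manifest
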