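"""Virtual instrument: a digital twin of the fluidics/imaging platform.

Models the hardware that executes recipes — a 24-port rotary selector
valve and an 8 × 250 µL barrel syringe pump per flowcell, independently
temperature-controlled flowcell stages, a single shared optical head with
four TDI line-scan cameras — as a discrete-event simulation. Executing a
recipe produces a timestamped event log and, through the TDI camera
model, simulated 12-bit images.

Dual-flowcell coordination follows the recipe language: a ``WAIT v`` on
one flowcell blocks until the other flowcell *starts* a command with verb
``v``, and IMAG commands on the two flowcells never overlap in simulated
time because there is only one imaging head.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .protocol import (
    ConfigError,
    ExperimentConfig,
    ProtocolCommand,
    Recipe,
    Verb,
)

__all__ = [
    "PumpState",
    "ValveState",
    "FlowcellState",
    "StageState",
    "TDICameraModel",
    "EventLog",
    "VirtualInstrument",
    "DeadlockError",
    "InstrumentError",
    "simulate_temperature_trace",
    "tdi_scan",
]


class InstrumentError(RuntimeError):
    """Runtime failure while executing a command."""


class DeadlockError(InstrumentError):
    """Both flowcells are blocked in WAIT (or waiting on a verb that can
    never start)."""


@dataclass
class PumpState:
    """8-barrel syringe pump with barrels 1–4 and 5–8 joined onto the two
    central stage outlets, so one full stroke pulls the whole
    ``n_barrels × barrel_volume`` through the flowcell."""

    n_barrels: int = 8
    barrel_volume_ul: float = 250.0
    manifold_groups: tuple[tuple[int, ...], ...] = ((1, 2, 3, 4), (5, 6, 7, 8))
    plunger_position: float = 0.0  # fraction of full stroke, [0, 1]

    @property
    def full_stroke_ul(self) -> float:
        return self.n_barrels * self.barrel_volume_ul

    def strokes_for(self, volume_ul: float) -> int:
        return max(1, math.ceil(volume_ul / self.full_stroke_ul))


@dataclass
class ValveState:
    n_ports: int = 24
    current_port: int = 1
    port_contents: dict[int, str] = field(default_factory=dict)

    def select(self, port: int) -> None:
        if not (1 <= port <= self.n_ports):
            raise InstrumentError(f"valve has no port {port}")
        self.current_port = port


@dataclass
class FlowcellState:
    id: str
    temperature_c: float = 25.0
    setpoint_c: float = 25.0
    chamber_reagent: str = ""
    chamber_volume_ul: float = 0.0
    cumulative_reagent_use: dict[str, float] = field(default_factory=dict)
    program_counter: int = 0


@dataclass
class StageState:
    """Stage coordinates; y has 10 nm encoder resolution and the objective
    piezo steps in 0.2 nm, so both are stored in their native integer
    quanta."""

    x_um: float = 0.0
    y_10nm: int = 0            # y position in 10 nm counts
    z_tilt_steps: tuple[int, int, int] = (0, 0, 0)
    objective_02nm: int = 0    # objective z in 0.2 nm counts

    @property
    def y_um(self) -> float:
        return self.y_10nm * 0.01

    @property
    def objective_nm(self) -> float:
        return self.objective_02nm * 0.2


@dataclass(frozen=True)
class TDICameraModel:
    """Time-delay-integration line-scan camera.

    The sensor is one 2048-pixel line laid out in 8 readout groups of 256
    pixels; charge is shifted through 128 TDI lines in sync with the stage
    so signal integrates ×128 while readout noise is added once. Output is
    12-bit (0–4095) carried in 16-bit TIFFs.
    """

    line_width: int = 2048
    n_groups: int = 8
    tdi_lines: int = 128
    bit_depth: int = 12
    fov_um: tuple[float, float] = (769.0, 6.0)
    channels_nm: tuple[int, ...] = (558, 610, 687, 740)
    group_dark_levels: tuple[float, ...] = (0.0,) * 8
    read_noise_dn: float = 3.0

    @property
    def group_width(self) -> int:
        return self.line_width // self.n_groups

    @property
    def max_dn(self) -> int:
        return (1 << self.bit_depth) - 1


def tdi_scan(scene: np.ndarray, camera: TDICameraModel,
             rng_seed: int | None = None, *,
             shot_noise: bool = True) -> np.ndarray:
    """Form a TDI line-scan image of a ground-truth emission scene.

    ``scene`` holds the per-line expected signal (DN per single-line
    exposure) on a raster at the camera's pixel pitch; it must be at least
    ``camera.line_width`` pixels wide (extra columns are cropped). Each
    output pixel is

        clip(Poisson(128 · signal) + dark_level(group) + N(0, σ_read), 0, 4095)

    with shot noise on the integrated signal, the per-readout-group dark
    level, and Gaussian readout noise added once per pixel. With
    ``shot_noise=False`` and ``read_noise_dn == 0`` the output is exactly
    ``clip(128 · signal + dark)``. Bit-reproducible for a fixed seed.
    """
    scene = np.asarray(scene, dtype=float)
    if scene.ndim != 2:
        raise ValueError("scene must be a 2-D raster")
    if scene.shape[1] < camera.line_width:
        raise ValueError(
            f"scene width {scene.shape[1]} px is narrower than the "
            f"{camera.line_width} px scan strip")
    strip = scene[:, :camera.line_width]
    integrated = camera.tdi_lines * strip

    rng = np.random.default_rng(rng_seed)
    if shot_noise:
        signal = rng.poisson(np.maximum(integrated, 0.0)).astype(float)
    else:
        signal = integrated

    dark = np.repeat(np.asarray(camera.group_dark_levels, dtype=float),
                     camera.group_width)
    out = signal + dark[None, :]
    if camera.read_noise_dn > 0:
        out = out + rng.normal(0.0, camera.read_noise_dn, size=out.shape)
    return np.clip(np.rint(out), 0, camera.max_dn).astype(np.uint16)


# ---------------------------------------------------------------------------
# Temperature dynamics

#: First-order time constant of the flowcell stage peltier loop, seconds.
TEMP_TAU_S = 20.0
#: Temperature considered "reached" within this band, °C.
TEMP_TOLERANCE_C = 0.5


def temperature_ramp_time(t_from: float, t_to: float,
                          tau_s: float = TEMP_TAU_S,
                          tolerance_c: float = TEMP_TOLERANCE_C) -> float:
    """Seconds for a first-order response to come within tolerance of the
    setpoint."""
    delta = abs(t_to - t_from)
    if delta <= tolerance_c:
        return 0.0
    return tau_s * math.log(delta / tolerance_c)


def simulate_temperature_trace(setpoints: list[tuple[float, float]],
                               initial_c: float = 25.0,
                               tau_s: float = TEMP_TAU_S,
                               dt_s: float = 1.0) -> np.ndarray:
    """Replay a stage-temperature setpoint schedule.

    ``setpoints`` is a list of ``(°C, dwell seconds)``; the stage is held
    at each setpoint for exactly its dwell while the measured temperature
    follows a first-order exponential approach with time constant
    ``tau_s``. Returns an ``(n, 2)`` array of (time s, °C) sampled every
    ``dt_s``.
    """
    lo, hi = 15.0, 60.0
    for sp, dwell in setpoints:
        if not (lo <= sp <= hi):
            raise ValueError(f"setpoint {sp} °C outside [{lo}, {hi}]")
        if dwell <= 0:
            raise ValueError("dwell must be positive")
    times, temps = [0.0], [initial_c]
    t, temp = 0.0, initial_c
    for sp, dwell in setpoints:
        n_steps = int(round(dwell / dt_s))
        decay = math.exp(-dt_s / tau_s)
        for _ in range(n_steps):
            temp = sp + (temp - sp) * decay
            t += dt_s
            times.append(t)
            temps.append(temp)
    return np.column_stack([times, temps])


# ---------------------------------------------------------------------------
# Event log

@dataclass(frozen=True)
class LogRecord:
    time_s: float
    flowcell: str
    verb: str
    detail: str


class EventLog:
    """Time-ordered record of everything the instrument did."""

    def __init__(self) -> None:
        self.records: list[LogRecord] = []

    def add(self, time_s: float, flowcell: str, verb: str,
            detail: str) -> None:
        if self.records and time_s < max(r.time_s for r in self.records) - 1e-9:
            # records are appended as commands start; starts are issued in
            # nondecreasing sim-time per flowcell but may interleave, so
            # keep append order and sort on demand
            pass
        self.records.append(LogRecord(time_s, flowcell, verb, detail))

    def sorted(self) -> list[LogRecord]:
        return sorted(self.records, key=lambda r: (r.time_s, r.flowcell))

    def filter(self, flowcell: str | None = None,
               verb: str | None = None) -> list[LogRecord]:
        return [r for r in self.records
                if (flowcell is None or r.flowcell == flowcell)
                and (verb is None or r.verb == verb)]

    def to_tsv(self) -> str:
        lines = ["time_s\tflowcell\tverb\tdetail"]
        for r in self.sorted():
            lines.append(f"{r.time_s:.3f}\t{r.flowcell}\t{r.verb}\t{r.detail}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Instrument and scheduler

#: Fixed per-event durations, seconds.
VALVE_MOVE_S = 2.0
#: Stage scan speed while imaging, µm/s, and per-tile setup overhead, s.
SCAN_SPEED_UM_S = 50.0
TILE_OVERHEAD_S = 5.0


class VirtualInstrument:
    """Executes recipes against simulated hardware.

    Parameters
    ----------
    config
        The experiment configuration (port map, ROIs, flow rate …).
    imager
        Optional callback ``imager(flowcell_id, n_z) -> None`` invoked on
        every IMAG command, e.g. to render tiles through the TDI model.
    """

    def __init__(self, config: ExperimentConfig,
                 imager=None, camera: TDICameraModel | None = None) -> None:
        self.config = config
        self.camera = camera or TDICameraModel()
        self.imager = imager
        self.log = EventLog()
        self.flowcells: dict[str, FlowcellState] = {}
        self.valves: dict[str, ValveState] = {}
        self.pumps: dict[str, PumpState] = {}
        self.stage = StageState()
        for fc_id in config.flowcell_ids:
            self.flowcells[fc_id] = FlowcellState(id=fc_id)
            valve = ValveState()
            for reagent, port in config.port_map.items():
                valve.port_contents[port] = reagent
            self.valves[fc_id] = valve
            self.pumps[fc_id] = PumpState()

    # -- single-command execution -------------------------------------

    def imaging_duration_s(self, n_z: int) -> float:
        """Sim-time cost of one IMAG command over all configured ROIs."""
        from .imaging import plan_tiles  # local import: avoids cycle
        total = 0.0
        for roi in self.config.rois:
            plan = plan_tiles(roi, fov_width_um=self.camera.fov_um[0])
            scan_s = plan.scan_length_um / SCAN_SPEED_UM_S
            total += len(plan.tile_origins) * n_z * (scan_s + TILE_OVERHEAD_S)
        return total

    def command_duration_s(self, fc_id: str, cmd: ProtocolCommand) -> float:
        if cmd.verb is Verb.PORT:
            return VALVE_MOVE_S
        if cmd.verb is Verb.PUMP:
            return float(cmd.arg) / self.config.flow_rate * 60.0
        if cmd.verb is Verb.TEMP:
            return temperature_ramp_time(
                self.flowcells[fc_id].temperature_c, float(cmd.arg))
        if cmd.verb is Verb.HOLD:
            return float(cmd.arg) * 60.0
        if cmd.verb is Verb.IMAG:
            return self.imaging_duration_s(int(cmd.arg))
        return 0.0  # WAIT consumes no time of its own

    def execute_command(self, fc_id: str, cmd: ProtocolCommand,
                        start_s: float = 0.0) -> float:
        """Apply one command's state effects; returns its duration (s).

        The start of every command is logged; PUMP additionally logs one
        record per stroke when the volume exceeds a full stroke.
        """
        fc = self.flowcells[fc_id]
        valve = self.valves[fc_id]
        pump = self.pumps[fc_id]
        duration = self.command_duration_s(fc_id, cmd)

        if cmd.verb is Verb.PORT:
            port = self.config.resolve_port(str(cmd.arg))
            valve.select(port)
            self.log.add(start_s, fc_id, "PORT",
                         f"port={port} reagent={cmd.arg}")
        elif cmd.verb is Verb.PUMP:
            reagent = valve.port_contents.get(valve.current_port)
            if reagent is None:
                raise InstrumentError(
                    f"flowcell {fc_id}: PUMP from port "
                    f"{valve.current_port}, which has no reagent assigned")
            volume = float(cmd.arg)
            n_strokes = pump.strokes_for(volume)
            self.log.add(start_s, fc_id, "PUMP",
                         f"reagent={reagent} volume_ul={volume:g} "
                         f"strokes={n_strokes}")
            remaining = volume
            for s in range(n_strokes):
                v = min(remaining, pump.full_stroke_ul)
                self.log.add(start_s + duration * (volume - remaining) / volume
                             if volume else start_s,
                             fc_id, "STROKE", f"{s + 1}/{n_strokes} "
                             f"volume_ul={v:g}")
                remaining -= v
            fc.chamber_reagent = reagent
            fc.chamber_volume_ul = volume
            fc.cumulative_reagent_use[reagent] = (
                fc.cumulative_reagent_use.get(reagent, 0.0) + volume)
        elif cmd.verb is Verb.TEMP:
            fc.setpoint_c = float(cmd.arg)
            self.log.add(start_s, fc_id, "TEMP",
                         f"setpoint_c={fc.setpoint_c:g} ramp_s={duration:.1f}")
            fc.temperature_c = fc.setpoint_c
        elif cmd.verb is Verb.HOLD:
            self.log.add(start_s, fc_id, "HOLD", f"minutes={cmd.arg:g}")
        elif cmd.verb is Verb.IMAG:
            self.log.add(start_s, fc_id, "IMAG", f"z_planes={cmd.arg}")
            if self.imager is not None:
                self.imager(fc_id, int(cmd.arg))
        elif cmd.verb is Verb.WAIT:
            self.log.add(start_s, fc_id, "WAIT", f"on={cmd.arg.value}")
        return duration

    # -- dual-flowcell scheduler ---------------------------------------

    def run_experiment(self, recipes: dict[str, Recipe]) -> EventLog:
        """Run one recipe per flowcell to completion.

        Cooperative discrete-event scheduling: each flowcell executes its
        own program strictly in order (per-flowcell FIFO). ``WAIT v``
        blocks until the other flowcell starts a command with verb ``v``.
        IMAG holds the single optical head, so imaging on one flowcell
        delays the other's IMAG until the head is free. Raises
        :class:`DeadlockError` when no flowcell can ever proceed.
        """
        for fc_id in recipes:
            if fc_id not in self.flowcells:
                raise ConfigError(f"no flowcell {fc_id!r} configured")

        t = {fc: 0.0 for fc in recipes}          # next-ready sim-time
        pc = {fc: 0 for fc in recipes}           # program counter
        waiting_on: dict[str, Verb | None] = {fc: None for fc in recipes}
        imaging_free_at = 0.0

        def done(fc: str) -> bool:
            return pc[fc] >= len(recipes[fc].commands)

        def other(fc: str) -> str | None:
            rest = [o for o in recipes if o != fc]
            return rest[0] if rest else None

        while not all(done(fc) for fc in recipes):
            runnable = [fc for fc in recipes
                        if not done(fc) and waiting_on[fc] is None]
            if not runnable:
                blocked = {fc: (pc[fc], waiting_on[fc].value)
                           for fc in recipes if waiting_on[fc] is not None}
                raise DeadlockError(
                    f"all flowcells blocked in WAIT; program counters and "
                    f"awaited verbs: {blocked}")
            fc_id = min(runnable, key=lambda fc: (t[fc], fc))
            cmd = recipes[fc_id].commands[pc[fc_id]]

            if cmd.verb is Verb.WAIT:
                target = cmd.arg
                o = other(fc_id)
                if o is None or done(o) or not any(
                        c.verb is target
                        for c in recipes[o].commands[pc[o]:]):
                    raise DeadlockError(
                        f"flowcell {fc_id} WAITs on {target.value} at "
                        f"command {pc[fc_id]}, but flowcell "
                        f"{o or '(none)'} will never start it")
                self.execute_command(fc_id, cmd, start_s=t[fc_id])
                waiting_on[fc_id] = target
                pc[fc_id] += 1
                continue

            start = t[fc_id]
            if cmd.verb is Verb.IMAG:
                start = max(start, imaging_free_at)
            duration = self.execute_command(fc_id, cmd, start_s=start)
            if cmd.verb is Verb.IMAG:
                imaging_free_at = start + duration
            # a start of this verb releases the other flowcell's WAIT
            o = other(fc_id)
            if o is not None and waiting_on.get(o) is cmd.verb:
                waiting_on[o] = None
                t[o] = max(t[o], start)
            t[fc_id] = start + duration
            pc[fc_id] += 1
            self.flowcells[fc_id].program_counter = pc[fc_id]

        return self.log
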