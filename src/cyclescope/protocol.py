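"""Protocol (recipe) and experiment-configuration language.

An automated experiment is driven by two plain-text files:

* a **recipe** — an ordered program of six possible commands, one per line
  in ``VERB: argument`` form (``#`` starts a comment, verbs are
  case-insensitive):

  ========  =======================================================
  PORT      move the 24-port selector valve to the named reagent
  PUMP      draw the given volume (µL) through the flowcell
  TEMP      ramp the flowcell stage to the given temperature (°C)
  IMAG      image all configured ROIs at the given number of z planes
  HOLD      pause this flowcell for the given number of minutes
  WAIT      block until the *other* flowcell starts the named verb
  ========  =======================================================

* a **configuration** — INI-style sections ``[experiment]``,
  ``[reagents]``, ``[rois]`` and ``[imaging]`` giving the cycle count,
  reagent→valve-port map, ROI bounding boxes (slide-frame millimetres)
  and imaging settings.

This module parses, validates, serializes and generates both.
"""

from __future__ import annotations

import configparser
import enum
import io
import math
from dataclasses import dataclass, field, replace

__all__ = [
    "Verb",
    "ProtocolCommand",
    "Recipe",
    "ROI",
    "ExperimentConfig",
    "RecipeError",
    "ConfigError",
    "parse_recipe",
    "serialize_recipe",
    "parse_config",
    "serialize_config",
    "validate_recipe",
    "generate_4i_recipe",
    "default_4i_config",
]

# Instrument limits (stock hardware).
VALVE_PORTS = 24
MAX_CHILLED_REAGENTS = 18
TEMP_RANGE_C = (15.0, 60.0)
# Usable capture area of a flowcell on a 25 x 75 mm slide, slide-frame mm.
# x spans the short slide axis, y the long (scan) axis; origin at the slide
# corner nearest the fluidic inlet.
CAPTURE_AREA_MM = (0.0, 0.0, 22.0, 60.0)  # x_min, y_min, x_max, y_max


class RecipeError(ValueError):
    """Malformed or invalid recipe text."""


class ConfigError(ValueError):
    """Malformed or invalid experiment configuration."""


class Verb(str, enum.Enum):
    PORT = "PORT"
    PUMP = "PUMP"
    TEMP = "TEMP"
    IMAG = "IMAG"
    HOLD = "HOLD"
    WAIT = "WAIT"


@dataclass(frozen=True)
class ProtocolCommand:
    """One step of a recipe.

    ``arg`` is verb-dependent: PORT → reagent name (str), PUMP → volume in
    µL (float > 0), TEMP → °C (float within instrument range), IMAG →
    z-plane count (int ≥ 1), HOLD → minutes (float ≥ 0), WAIT → verb name
    to synchronize on.
    """

    verb: Verb
    arg: object

    def __post_init__(self) -> None:
        v, a = self.verb, self.arg
        if v is Verb.PUMP:
            if not (isinstance(a, (int, float)) and a > 0):
                raise RecipeError(f"PUMP volume must be > 0 µL, got {a!r}")
        elif v is Verb.TEMP:
            lo, hi = TEMP_RANGE_C
            if not (isinstance(a, (int, float)) and lo <= a <= hi):
                raise RecipeError(
                    f"TEMP must lie in [{lo}, {hi}] °C, got {a!r}")
        elif v is Verb.IMAG:
            if not (isinstance(a, int) and a >= 1):
                raise RecipeError(f"IMAG z-plane count must be ≥ 1, got {a!r}")
        elif v is Verb.HOLD:
            if not (isinstance(a, (int, float)) and a >= 0):
                raise RecipeError(f"HOLD minutes must be ≥ 0, got {a!r}")
        elif v is Verb.WAIT:
            if not (isinstance(a, Verb)):
                raise RecipeError(
                    f"WAIT must name one of the six verbs, got {a!r}")
        elif v is Verb.PORT:
            if not (isinstance(a, str) and a.strip()):
                raise RecipeError(f"PORT needs a reagent name, got {a!r}")

    def serialize(self) -> str:
        a = self.arg.value if isinstance(self.arg, Verb) else self.arg
        if isinstance(a, float) and a == int(a):
            a = int(a)
        return f"{self.verb.value}: {a}"


@dataclass(frozen=True)
class Recipe:
    """An ordered, named program for one flowcell."""

    commands: tuple[ProtocolCommand, ...]
    name: str = "recipe"

    def __post_init__(self) -> None:
        if not self.commands:
            raise RecipeError("recipe is empty")

    def __len__(self) -> int:
        return len(self.commands)

    def count(self, verb: Verb) -> int:
        return sum(1 for c in self.commands if c.verb is verb)


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest in slide-frame millimetres.

    Boxes are half-open, ``[min, max)`` on both axes.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    z_planes: int = 1
    label: str = "roi"

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ConfigError(
                f"ROI {self.label!r} must have x_max > x_min and "
                f"y_max > y_min (area > 0)")
        if self.z_planes < 1:
            raise ConfigError(f"ROI {self.label!r} z_planes must be ≥ 1")

    @property
    def width_mm(self) -> float:
        return self.x_max - self.x_min

    @property
    def height_mm(self) -> float:
        return self.y_max - self.y_min


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything an automated run needs besides the recipe itself."""

    n_cycles: int
    port_map: dict[str, int]            # reagent name -> valve port (1..24)
    rois: tuple[ROI, ...]
    flow_rate: float = 500.0            # µL/min
    z_planes: int = 1
    laser_powers: dict[int, float] = field(
        default_factory=lambda: {532: 100.0, 660: 100.0})  # mW per line
    autofocus_mode: str = "full"
    flowcell_ids: tuple[str, ...] = ("A",)
    chilled_reagents: tuple[str, ...] = ()  # subset of port_map on the chiller

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ConfigError("n_cycles must be ≥ 1")
        if self.autofocus_mode not in (
                "full", "partial", "full_once", "partial_once", "manual"):
            raise ConfigError(
                f"unknown autofocus mode {self.autofocus_mode!r}")
        for fc in self.flowcell_ids:
            if fc not in ("A", "B"):
                raise ConfigError(f"flowcell id must be A or B, got {fc!r}")
        for name, port in self.port_map.items():
            if not (1 <= port <= VALVE_PORTS):
                raise ConfigError(
                    f"reagent {name!r} assigned to port {port}; valid ports "
                    f"are 1..{VALVE_PORTS}")
        if len(self.chilled_reagents) > MAX_CHILLED_REAGENTS:
            raise ConfigError(
                f"{len(self.chilled_reagents)} reagents assigned to the "
                f"onboard chiller; at most {MAX_CHILLED_REAGENTS} fit per "
                f"flowcell")
        unknown = set(self.chilled_reagents) - set(self.port_map)
        if unknown:
            raise ConfigError(
                f"chilled reagents not in port map: {sorted(unknown)}")
        cx0, cy0, cx1, cy1 = CAPTURE_AREA_MM
        for roi in self.rois:
            if not (cx0 <= roi.x_min and roi.x_max <= cx1
                    and cy0 <= roi.y_min and roi.y_max <= cy1):
                raise ConfigError(
                    f"ROI {roi.label!r} [{roi.x_min},{roi.y_min})–"
                    f"[{roi.x_max},{roi.y_max}) lies outside the flowcell "
                    f"capture area {CAPTURE_AREA_MM} mm")

    def resolve_port(self, reagent: str) -> int:
        """Look up the valve port for a reagent name.

        Cycle-suffixed names (``primary_2``) fall back to the un-suffixed
        entry when not mapped explicitly, supporting per-cycle remapping.
        """
        if reagent in self.port_map:
            return self.port_map[reagent]
        base, _, suffix = reagent.rpartition("_")
        if base and suffix.isdigit() and base in self.port_map:
            return self.port_map[base]
        raise ConfigError(f"reagent {reagent!r} not in port map")


# ---------------------------------------------------------------------------
# Recipe parsing / serialization

def _parse_arg(verb: Verb, raw: str, lineno: int):
    try:
        if verb is Verb.PORT:
            return raw
        if verb is Verb.PUMP or verb is Verb.HOLD or verb is Verb.TEMP:
            return float(raw)
        if verb is Verb.IMAG:
            return int(raw)
        if verb is Verb.WAIT:
            return Verb(raw.strip().upper())
    except (ValueError, KeyError) as exc:
        raise RecipeError(
            f"line {lineno}: malformed {verb.value} argument {raw!r}") from exc
    raise AssertionError(verb)


def parse_recipe(text: str, name: str = "recipe") -> Recipe:
    """Parse recipe text into a :class:`Recipe`.

    One command per non-comment line, ``VERB: argument``; verbs are
    case-insensitive and ``#`` starts a comment. Raises
    :class:`RecipeError` with the offending line number on unknown verbs
    or malformed arguments, and on empty input.
    """
    commands: list[ProtocolCommand] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        verb_s, sep, arg_s = line.partition(":")
        if not sep:
            raise RecipeError(f"line {lineno}: expected 'VERB: argument', "
                              f"got {line!r}")
        verb_s = verb_s.strip().upper()
        try:
            verb = Verb(verb_s)
        except ValueError:
            raise RecipeError(
                f"line {lineno}: unknown verb {verb_s!r}; expected one of "
                f"{', '.join(v.value for v in Verb)}") from None
        try:
            cmd = ProtocolCommand(verb, _parse_arg(verb, arg_s.strip(), lineno))
        except RecipeError as exc:
            raise RecipeError(f"line {lineno}: {exc}") from None
        commands.append(cmd)
    if not commands:
        raise RecipeError("recipe contains no commands")
    return Recipe(tuple(commands), name=name)


def serialize_recipe(recipe: Recipe) -> str:
    """Inverse of :func:`parse_recipe` (up to comments/whitespace)."""
    return "\n".join(c.serialize() for c in recipe.commands) + "\n"


def validate_recipe(recipe: Recipe, config: ExperimentConfig) -> list[str]:
    """Cross-check a recipe against a config; returns diagnostics.

    An empty list means the recipe is executable: every PORT reagent
    resolves against the port map.
    """
    diagnostics = []
    for i, cmd in enumerate(recipe.commands):
        if cmd.verb is Verb.PORT:
            try:
                config.resolve_port(str(cmd.arg))
            except ConfigError as exc:
                diagnostics.append(f"command {i + 1}: {exc}")
    return diagnostics


# ---------------------------------------------------------------------------
# Config parsing / serialization (INI dialect)

def parse_config(text: str) -> ExperimentConfig:
    """Parse INI-style configuration text into an :class:`ExperimentConfig`.

    Sections: ``[experiment]`` (cycles, flowcells, autofocus), ``[reagents]``
    (``name = port`` or ``name = port, chilled``), ``[rois]``
    (``label = x_min, y_min, x_max, y_max[, z_planes]``) and ``[imaging]``
    (flow_rate, z_planes, laser powers).
    """
    cp = configparser.ConfigParser(inline_comment_prefixes=("#",))
    try:
        cp.read_string(text)
    except configparser.Error as exc:
        raise ConfigError(f"malformed config: {exc}") from exc
    if not cp.has_section("experiment"):
        raise ConfigError("missing [experiment] section")

    exp = cp["experiment"]
    n_cycles = exp.getint("cycles", fallback=1)
    flowcells = tuple(
        s.strip().upper() for s in exp.get("flowcells", "A").split(","))
    autofocus = exp.get("autofocus", "full").strip()

    port_map: dict[str, int] = {}
    chilled: list[str] = []
    if cp.has_section("reagents"):
        for name, value in cp["reagents"].items():
            parts = [p.strip() for p in value.split(",")]
            try:
                port_map[name] = int(parts[0])
            except ValueError:
                raise ConfigError(
                    f"reagent {name!r}: port must be an integer, "
                    f"got {parts[0]!r}") from None
            if any(p.lower() == "chilled" for p in parts[1:]):
                chilled.append(name)

    rois: list[ROI] = []
    if cp.has_section("rois"):
        for label, value in cp["rois"].items():
            parts = [p.strip() for p in value.split(",")]
            if len(parts) not in (4, 5):
                raise ConfigError(
                    f"ROI {label!r}: expected 'x_min, y_min, x_max, y_max"
                    f"[, z_planes]', got {value!r}")
            x0, y0, x1, y1 = (float(p) for p in parts[:4])
            z = int(parts[4]) if len(parts) == 5 else 1
            rois.append(ROI(x0, y0, x1, y1, z_planes=z, label=label))

    img = cp["imaging"] if cp.has_section("imaging") else {}
    flow_rate = float(img.get("flow_rate", 500.0))
    z_planes = int(img.get("z_planes", 1))
    laser_powers = {}
    for line_nm in (532, 660):
        key = f"laser_{line_nm}"
        laser_powers[line_nm] = float(img.get(key, 100.0))

    return ExperimentConfig(
        n_cycles=n_cycles,
        port_map=port_map,
        rois=tuple(rois),
        flow_rate=flow_rate,
        z_planes=z_planes,
        laser_powers=laser_powers,
        autofocus_mode=autofocus,
        flowcell_ids=flowcells,
        chilled_reagents=tuple(chilled),
    )


def serialize_config(config: ExperimentConfig) -> str:
    """Inverse of :func:`parse_config`."""
    cp = configparser.ConfigParser()
    cp["experiment"] = {
        "cycles": str(config.n_cycles),
        "flowcells": ", ".join(config.flowcell_ids),
        "autofocus": config.autofocus_mode,
    }
    cp["reagents"] = {
        name: (f"{port}, chilled" if name in config.chilled_reagents
               else str(port))
        for name, port in config.port_map.items()
    }
    cp["rois"] = {
        roi.label: f"{roi.x_min}, {roi.y_min}, {roi.x_max}, {roi.y_max}, "
                   f"{roi.z_planes}"
        for roi in config.rois
    }
    cp["imaging"] = {
        "flow_rate": str(config.flow_rate),
        "z_planes": str(config.z_planes),
        **{f"laser_{nm}": str(p) for nm, p in config.laser_powers.items()},
    }
    buf = io.StringIO()
    cp.write(buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# 4i recipe generation

#: Elution incubations per cycle by tissue type: complete antibody removal
#: needs 4 ten-minute elution-buffer incubations on mouse spinal cord and
#: 5 on postmortem human spinal cord.
ELUTIONS_BY_TISSUE = {"mouse": 4, "human": 5}

#: Default reagent-exchange volume, µL. One full pump stroke with joined
#: barrels; enough to fully replace the flowcell chamber contents.
EXCHANGE_VOLUME_UL = 500.0


def generate_4i_recipe(tissue: str, n_cycles: int,
                       volume_ul: float = EXCHANGE_VOLUME_UL) -> Recipe:
    """Generate the standard iterative-immunofluorescence (4i) recipe.

    Each cycle: 1 h blocking, 2 h primary antibody, 2 h secondary
    antibody, exchange into imaging buffer and image, then ``k`` ten-minute
    elution incubations (k = 4 for mouse tissue, 5 for human). Antibody
    reagents are cycle-suffixed (``primary_1`` …) so each cycle can draw
    from a different port.
    """
    try:
        k_elutions = ELUTIONS_BY_TISSUE[tissue]
    except KeyError:
        raise ValueError(
            f"tissue must be one of {sorted(ELUTIONS_BY_TISSUE)}, "
            f"got {tissue!r}") from None
    if n_cycles < 1:
        raise ValueError(f"n_cycles must be ≥ 1, got {n_cycles}")

    def exchange(reagent: str) -> list[ProtocolCommand]:
        return [ProtocolCommand(Verb.PORT, reagent),
                ProtocolCommand(Verb.PUMP, volume_ul)]

    commands: list[ProtocolCommand] = []
    for cycle in range(1, n_cycles + 1):
        commands += exchange("blocking")
        commands.append(ProtocolCommand(Verb.HOLD, 60.0))
        commands += exchange(f"primary_{cycle}")
        commands.append(ProtocolCommand(Verb.HOLD, 120.0))
        commands += exchange(f"secondary_{cycle}")
        commands.append(ProtocolCommand(Verb.HOLD, 120.0))
        commands += exchange("imaging")
        commands.append(ProtocolCommand(Verb.IMAG, 1))
        for _ in range(k_elutions):
            commands += exchange("elution")
            commands.append(ProtocolCommand(Verb.HOLD, 10.0))
    return Recipe(tuple(commands), name=f"4i_{tissue}_{n_cycles}cycles")


def load_fixture(name: str) -> str:
    """Read one of the shipped recipe/config fixtures by filename
    (e.g. ``4i_mouse.recipe``, ``example_human.cfg``)."""
    from importlib import resources

    return (resources.files("cyclescope") / "fixtures" / name).read_text()


def default_4i_config(tissue: str, n_cycles: int) -> ExperimentConfig:
    """A minimal config whose port map resolves the generated 4i recipe."""
    port_map = {"blocking": 1, "imaging": 2, "elution": 3,
                "primary": 4, "secondary": 5}
    # per-cycle antibody ports, cycling over the remaining valve positions
    for cycle in range(1, n_cycles + 1):
        port_map[f"primary_{cycle}"] = 4 + (2 * (cycle - 1)) % 18
        port_map[f"secondary_{cycle}"] = 5 + (2 * (cycle - 1)) % 18
    chilled = tuple(n for n in port_map if n.startswith(("primary", "secondary")))[
        :MAX_CHILLED_REAGENTS]
    return ExperimentConfig(
        n_cycles=n_cycles,
        port_map=port_map,
        rois=(ROI(2.0, 5.0, 5.0, 10.0, z_planes=1, label="section_1"),),
        autofocus_mode="full_once" if tissue == "mouse" else "partial_once",
        chilled_reagents=chilled,
    )
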