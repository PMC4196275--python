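"""Run configuration, the plain-text config dialect, and named fixtures.

Configs are flat ``key = value`` text files with dotted namespaces
(``params.hes7.dmC = 0.067``); ``#`` starts a comment.  Files ending in
``.yaml``/``.yml`` are read through YAML with the same key set.  Parsing
is strict: unknown keys, type errors and out-of-range values are all
collected and reported together.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .grn_model import DEFAULT_PARAMETERS, GrnModel, ParameterSet
from .tissue import GradientSpec, GrowthOptions, PsmTissue, Tissue, build_tissue

__all__ = [
    "RunConfig", "PsmConfig", "ConfigError",
    "read_config", "write_config", "generate_fixture", "FIXTURE_NAMES",
    "export_sbml",
]


class ConfigError(ValueError):
    """Raised with the full list of configuration problems."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid configuration:\n  " + "\n  ".join(self.problems))


@dataclass
class PsmConfig:
    """Growing-PSM options (conveyor slab with posterior growth zone)."""

    enabled: bool = False
    initial_length: int = 10
    cross_section: tuple[int, ...] = (7, 3)
    growth_zone_depth: int = 3
    cell_cycle_min: float = 30.0
    mitosis_shutdown_min: float = 0.0
    division_noise_percent: float = 0.0
    jitter_min: float = 5.0
    max_length: int = 60
    gradient_amplitude: float = 0.5
    gradient_length_scale: float = 5.0


@dataclass
class RunConfig:
    """Full, reproducible description of one simulation run."""

    shape: tuple[int, ...] = (2,)
    neighborhood: str = "extended"
    lfng_enabled: bool = False
    nicd_transport: str = "swapped"
    dll1_recycling: bool = False
    dt: float = 0.1
    steps: int = 50000
    noise_percent: float = 0.0
    seed: int = 0
    initial: str = "canonical"          # canonical | zero | asymmetric
    record_species: tuple[str, ...] = ("hes7.mC",)
    record_stride: int = 10
    param_overrides: dict[str, dict[str, float]] = field(default_factory=dict)
    psm: PsmConfig = field(default_factory=PsmConfig)

    # -- factories ---------------------------------------------------------
    def parameter_set(self) -> ParameterSet:
        return ParameterSet(self.param_overrides)

    def build_model(self) -> GrnModel:
        return GrnModel(self.parameter_set(),
                        lfng_enabled=self.lfng_enabled,
                        nicd_transport=self.nicd_transport,
                        dll1_recycling=self.dll1_recycling)

    def build_tissue(self) -> Tissue | PsmTissue:
        if self.psm.enabled:
            return PsmTissue(
                self.psm.initial_length,
                cross_section=self.psm.cross_section,
                neighborhood_mode=self.neighborhood,
                growth=GrowthOptions(
                    cell_cycle_min=self.psm.cell_cycle_min,
                    growth_zone_depth=self.psm.growth_zone_depth,
                    mitosis_shutdown_min=self.psm.mitosis_shutdown_min,
                    division_noise_percent=self.psm.division_noise_percent,
                    jitter_min=self.psm.jitter_min,
                    max_length=self.psm.max_length,
                ),
                gradient=GradientSpec(
                    amplitude=self.psm.gradient_amplitude,
                    length_scale=self.psm.gradient_length_scale,
                ),
            )
        return build_tissue(self.shape, self.neighborhood)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        problems: list[str] = []
        if not (1 <= len(self.shape) <= 3) or any(s < 1 for s in self.shape):
            problems.append(f"lattice.shape: invalid {self.shape}")
        if self.neighborhood not in ("von_neumann", "extended"):
            problems.append(f"lattice.neighborhood: unknown {self.neighborhood!r}")
        if self.nicd_transport not in ("literal", "swapped"):
            problems.append(f"model.nicd_transport: unknown {self.nicd_transport!r}")
        if self.dt <= 0:
            problems.append(f"run.dt: must be > 0 (got {self.dt})")
        if self.steps < 1:
            problems.append(f"run.steps: must be >= 1 (got {self.steps})")
        if self.noise_percent < 0:
            problems.append(f"noise.percent: must be >= 0 (got {self.noise_percent})")
        if self.record_stride < 1:
            problems.append(f"record.stride: must be >= 1 (got {self.record_stride})")
        if self.initial not in ("canonical", "zero", "asymmetric"):
            problems.append(f"init.mode: unknown {self.initial!r}")
        from .grn_model import species_names
        known = set(species_names(lfng_enabled=True))
        for s in self.record_species:
            if s not in known:
                problems.append(f"record.species: unknown species {s!r}")
        try:
            self.parameter_set()
        except (KeyError, ValueError) as exc:
            problems.append(f"params: {exc}")
        p = self.psm
        if p.enabled:
            if p.initial_length < 2:
                problems.append("psm.initial_length: must be >= 2")
            if p.cell_cycle_min <= 0:
                problems.append("psm.cell_cycle_min: must be > 0")
            if p.mitosis_shutdown_min < 0 or p.division_noise_percent < 0:
                problems.append("psm: shutdown/noise must be >= 0")
            if p.gradient_amplitude < 0 or p.gradient_length_scale <= 0:
                problems.append("psm: gradient amplitude >= 0 and length scale > 0 required")
        if problems:
            raise ConfigError(problems)


# ---------------------------------------------------------------------------
# flat key-value (de)serialization

def _flatten(cfg: RunConfig) -> dict[str, str]:
    out: dict[str, str] = {
        "lattice.shape": "x".join(str(s) for s in cfg.shape),
        "lattice.neighborhood": cfg.neighborhood,
        "model.lfng_enabled": str(cfg.lfng_enabled).lower(),
        "model.nicd_transport": cfg.nicd_transport,
        "model.dll1_recycling": str(cfg.dll1_recycling).lower(),
        "run.dt": repr(cfg.dt),
        "run.steps": str(cfg.steps),
        "run.seed": str(cfg.seed),
        "noise.percent": repr(cfg.noise_percent),
        "init.mode": cfg.initial,
        "record.species": ",".join(cfg.record_species),
        "record.stride": str(cfg.record_stride),
    }
    for gene, block in sorted(cfg.param_overrides.items()):
        for key, val in sorted(block.items()):
            out[f"params.{gene}.{key}"] = repr(float(val))
    p = cfg.psm
    out["psm.enabled"] = str(p.enabled).lower()
    if p.enabled:
        out.update({
            "psm.initial_length": str(p.initial_length),
            "psm.cross_section": "x".join(str(c) for c in p.cross_section),
            "psm.growth_zone_depth": str(p.growth_zone_depth),
            "psm.cell_cycle_min": repr(p.cell_cycle_min),
            "psm.mitosis_shutdown_min": repr(p.mitosis_shutdown_min),
            "psm.division_noise_percent": repr(p.division_noise_percent),
            "psm.jitter_min": repr(p.jitter_min),
            "psm.max_length": str(p.max_length),
            "psm.gradient_amplitude": repr(p.gradient_amplitude),
            "psm.gradient_length_scale": repr(p.gradient_length_scale),
        })
    return out


def _parse_shape(text: str) -> tuple[int, ...]:
    return tuple(int(tok) for tok in str(text).lower().split("x"))


def _parse_bool(text: str) -> bool:
    t = str(text).strip().lower()
    if t in ("true", "1", "yes", "on"):
        return True
    if t in ("false", "0", "no", "off"):
        return False
    raise ValueError(f"not a boolean: {text!r}")


def _unflatten(pairs: dict[str, Any]) -> RunConfig:
    problems: list[str] = []
    cfg = RunConfig()
    overrides: dict[str, dict[str, float]] = {}
    psm_kwargs: dict[str, Any] = {}

    scalar_keys = {
        "lattice.shape": ("shape", _parse_shape),
        "lattice.neighborhood": ("neighborhood", str),
        "model.lfng_enabled": ("lfng_enabled", _parse_bool),
        "model.nicd_transport": ("nicd_transport", str),
        "model.dll1_recycling": ("dll1_recycling", _parse_bool),
        "run.dt": ("dt", float),
        "run.steps": ("steps", int),
        "run.seed": ("seed", int),
        "noise.percent": ("noise_percent", float),
        "init.mode": ("initial", str),
        "record.stride": ("record_stride", int),
    }
    psm_keys = {
        "psm.enabled": ("enabled", _parse_bool),
        "psm.initial_length": ("initial_length", int),
        "psm.cross_section": ("cross_section", _parse_shape),
        "psm.growth_zone_depth": ("growth_zone_depth", int),
        "psm.cell_cycle_min": ("cell_cycle_min", float),
        "psm.mitosis_shutdown_min": ("mitosis_shutdown_min", float),
        "psm.division_noise_percent": ("division_noise_percent", float),
        "psm.jitter_min": ("jitter_min", float),
        "psm.max_length": ("max_length", int),
        "psm.gradient_amplitude": ("gradient_amplitude", float),
        "psm.gradient_length_scale": ("gradient_length_scale", float),
    }

    for key, raw in pairs.items():
        try:
            if key in scalar_keys:
                attr, conv = scalar_keys[key]
                setattr(cfg, attr, conv(raw))
            elif key in psm_keys:
                attr, conv = psm_keys[key]
                psm_kwargs[attr] = conv(raw)
            elif key == "record.species":
                toks = [t.strip() for t in str(raw).split(",") if t.strip()]
                cfg.record_species = tuple(toks)
            elif key.startswith("params."):
                parts = key.split(".")
                if len(parts) != 3:
                    raise ValueError("expected params.<gene>.<name>")
                gene, name = parts[1], parts[2]
                if gene not in DEFAULT_PARAMETERS or name not in DEFAULT_PARAMETERS[gene]:
                    raise ValueError(f"unknown parameter {gene}.{name}")
                overrides.setdefault(gene, {})[name] = float(raw)
            else:
                raise ValueError("unknown key")
        except (ValueError, TypeError) as exc:
            problems.append(f"{key}: {exc}")

    if problems:
        raise ConfigError(problems)
    cfg.param_overrides = overrides
    cfg.psm = PsmConfig(**psm_kwargs)
    cfg.validate()
    return cfg


def write_config(cfg: RunConfig, path: str | Path) -> None:
    """Serialize a config to the flat key-value dialect."""
    cfg.validate()
    lines = [f"{k} = {v}" for k, v in _flatten(cfg).items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path) -> RunConfig:
    """Read and strictly validate a config file (flat dialect or YAML)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        data = yaml.safe_load(text) or {}
        pairs = {str(k): v for k, v in _flatten_yaml(data).items()}
    else:
        pairs = {}
        problems = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            stripped = line.split("#", 1)[0].strip()
            if not stripped:
                continue
            if "=" not in stripped:
                problems.append(f"line {lineno}: expected 'key = value'")
                continue
            key, val = (tok.strip() for tok in stripped.split("=", 1))
            if key in pairs:
                problems.append(f"line {lineno}: duplicate key {key!r}")
            pairs[key] = val
        if problems:
            raise ConfigError(problems)
    return _unflatten(pairs)


def _flatten_yaml(data: dict, prefix: str = "") -> dict[str, Any]:
    out: dict[str, Any] = {}
    for key, val in data.items():
        dotted = f"{prefix}{key}"
        if isinstance(val, dict):
            out.update(_flatten_yaml(val, prefix=f"{dotted}."))
        else:
            out[dotted] = val
    return out


def config_to_dict(cfg: RunConfig) -> dict[str, str]:
    """Flat, serializable snapshot of a config (embedded in traces)."""
    return _flatten(cfg)


# ---------------------------------------------------------------------------
# fixtures emulating the reference simulation setups

FIXTURE_NAMES = (
    "cube7_cis", "cube7_nocis", "chain1d", "sheet2d", "twocell",
    "psm_slab", "psm_slab_mitosis", "lfng_cube",
)


def generate_fixture(name: str, seed: int = 0) -> RunConfig:
    """Fully specified config for one of the named study scenarios.

    * ``cube7_cis``/``cube7_nocis`` -- 7x7x7 cube, 100% initial noise,
      5000 min, with (rDNcis = 0.01) and without cis-inhibition.
    * ``chain1d``/``sheet2d`` -- dimensionality comparison at matched cell
      count (343-cell chain, 18x19 sheet), 100% noise.
    * ``twocell`` -- deterministic asymmetric two-cell system.
    * ``psm_slab`` -- growing 7x3 slab, 100% noise at each division.
    * ``psm_slab_mitosis`` -- growing slab with 20-min transcription
      shutdown in dividing cells, diagonal signaling enabled.
    * ``lfng_cube`` -- cube with the Lfng-extended network, 150% noise.
    """
    if name not in FIXTURE_NAMES:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    if name == "cube7_cis":
        cfg = RunConfig(shape=(7, 7, 7), noise_percent=100.0, steps=50000)
    elif name == "cube7_nocis":
        cfg = RunConfig(shape=(7, 7, 7), noise_percent=100.0, steps=50000,
                        param_overrides={"coupling": {"rDNcis": 0.0}})
    elif name == "chain1d":
        cfg = RunConfig(shape=(343,), noise_percent=100.0, steps=50000)
    elif name == "sheet2d":
        cfg = RunConfig(shape=(18, 19), noise_percent=100.0, steps=50000)
    elif name == "twocell":
        cfg = RunConfig(shape=(2,), noise_percent=0.0, steps=50000,
                        initial="asymmetric")
    elif name == "psm_slab":
        cfg = RunConfig(steps=12000, noise_percent=0.0,
                        psm=PsmConfig(enabled=True, division_noise_percent=100.0))
    elif name == "psm_slab_mitosis":
        cfg = RunConfig(steps=12000, noise_percent=0.0, neighborhood="extended",
                        psm=PsmConfig(enabled=True, mitosis_shutdown_min=20.0))
    else:  # lfng_cube
        cfg = RunConfig(shape=(7, 7, 7), noise_percent=150.0, steps=7200,
                        lfng_enabled=True)
    cfg.seed = seed
    cfg.validate()
    return cfg


def export_sbml(cfg: RunConfig, path: str | Path) -> None:
    """Export a two-cell, non-growing config as an SBML L3V2 document."""
    from .sbml import export_sbml as _export
    _export(cfg, path)
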