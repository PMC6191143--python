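"""Structured-text run configuration.

One YAML (or JSON) document describes a run: domain and boundary, grid,
ion table, porous-medium parameters, scheme and tolerances, sources,
probes and outputs, plus a single seed that feeds every source of
randomness. Keys carrying physical quantities name their unit in the
suffix (spacing_um, dt_ms, current_nA, ...); parsing converts everything
to SI once, so the numerical core never sees mixed units.

Unknown keys are rejected with the offending key path, which catches
typos that would otherwise silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .electrolyte import IonSet, PorousMedium, default_ion_set, load_ion_table
from .schemes import BoundarySpec, NewtonOptions, SchemeConfig

__all__ = ["ConfigError", "RunConfig", "parse_config"]


class ConfigError(ValueError):
    """A configuration document violates the schema."""


@dataclass
class RunConfig:
    """Fully resolved run description, SI units throughout."""

    seed: int
    extents: list[tuple[float, float]]
    spacing: list[float]
    boundary: BoundarySpec
    ions: IonSet
    scheme: SchemeConfig
    sources_file: str | None = None
    synthetic: dict | None = None
    initial: dict = field(default_factory=lambda: {"kind": "baseline"})
    probes: list[tuple[str, tuple[float, ...], str]] = field(default_factory=list)
    out_dir: Path = Path("electrodiff_out")
    snapshot_times: list[float] = field(default_factory=list)
    raw: dict = field(default_factory=dict)

    @property
    def dim(self) -> int:
        return len(self.extents)


def _expect(section: Mapping, allowed: set[str], required: set[str], path: str) -> None:
    unknown = sorted(set(section) - allowed)
    if unknown:
        raise ConfigError(f"{path}: unknown keys {unknown}")
    for key in sorted(required - set(section)):
        raise ConfigError(f"{path}: missing required key {key!r}")


def _positive(value, path: str) -> float:
    try:
        value = float(value)
    except (TypeError, ValueError):
        raise ConfigError(f"{path}: expected a number, got {value!r}") from None
    if value <= 0:
        raise ConfigError(f"{path}: must be strictly positive, got {value}")
    return value


def parse_config(path: str | Path) -> RunConfig:
    """Read, validate and resolve a run configuration document."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: document must be a mapping")
    return resolve_config(doc)


def resolve_config(doc: Mapping[str, Any]) -> RunConfig:
    _expect(doc, {"seed", "domain", "grid", "ions", "porous", "scheme",
                  "sources", "probes", "outputs"},
            {"domain", "grid", "scheme"}, "config")

    seed = int(doc.get("seed", 0))

    domain = doc["domain"]
    _expect(domain, {"extents_um", "boundary", "potential_bc",
                     "clamp_concentrations_mM"}, {"extents_um"}, "domain")
    extents_um = domain["extents_um"]
    if not isinstance(extents_um, list) or not extents_um:
        raise ConfigError("domain.extents_um: expected a list of [min, max] pairs")
    if not isinstance(extents_um[0], list):
        extents_um = [extents_um]
    extents = []
    for i, pair in enumerate(extents_um):
        if len(pair) != 2 or not pair[1] > pair[0]:
            raise ConfigError(f"domain.extents_um[{i}]: expected [min, max] with max > min")
        extents.append((float(pair[0]) * 1e-6, float(pair[1]) * 1e-6))
    if len(extents) not in (1, 3):
        raise ConfigError("domain.extents_um: must describe a 1-D or 3-D box")
    clamp = domain.get("clamp_concentrations_mM")
    try:
        boundary = BoundarySpec(
            kind=domain.get("boundary", "sealed"),
            clamp_concentrations=tuple(clamp) if clamp is not None else None,
            potential_bc=domain.get("potential_bc", "neumann"),
        )
    except ValueError as exc:
        raise ConfigError(f"domain: {exc}") from None

    grid_sec = doc["grid"]
    _expect(grid_sec, {"spacing_um"}, {"spacing_um"}, "grid")
    spacing_um = grid_sec["spacing_um"]
    if not isinstance(spacing_um, list):
        spacing_um = [spacing_um] * len(extents)
    if len(spacing_um) != len(extents):
        raise ConfigError("grid.spacing_um: one value, or one per axis")
    spacing = [_positive(h, f"grid.spacing_um[{i}]") * 1e-6
               for i, h in enumerate(spacing_um)]

    porous_sec = doc.get("porous", {})
    _expect(porous_sec, {"lambda_tort", "alpha"}, set(), "porous")
    try:
        porous = PorousMedium(
            lambda_tort=float(porous_sec.get("lambda_tort", 1.6)),
            alpha=float(porous_sec.get("alpha", 0.2)),
        )
    except ValueError as exc:
        raise ConfigError(f"porous: {exc}") from None

    ions_sec = doc.get("ions", {})
    _expect(ions_sec, {"table"}, set(), "ions")
    table = ions_sec.get("table")
    if table is None:
        ions = default_ion_set(porous=porous)
    elif table == "binary":
        from .applications import binary_ion_set

        ions = binary_ion_set(porous=porous)
    else:
        if not Path(table).exists():
            raise ConfigError(f"ions.table: file {table} does not exist")
        ions = load_ion_table(table, porous=porous)

    scheme_sec = doc["scheme"]
    _expect(scheme_sec, {"name", "dt_ms", "t_end_s", "newton", "linear_tol",
                         "zero_mean", "vc_constant_sigma"},
            {"name", "dt_ms", "t_end_s"}, "scheme")
    newton_sec = scheme_sec.get("newton", {})
    _expect(newton_sec, {"abs_tol", "rel_tol", "step_tol", "max_iter"}, set(),
            "scheme.newton")
    try:
        newton = NewtonOptions(
            abs_tol=float(newton_sec.get("abs_tol", 1e-10)),
            rel_tol=float(newton_sec.get("rel_tol", 1e-8)),
            step_tol=float(newton_sec.get("step_tol", 1e-12)),
            max_iter=int(newton_sec.get("max_iter", 20)),
        )
        scheme = SchemeConfig(
            scheme=str(scheme_sec["name"]),
            dt=_positive(scheme_sec["dt_ms"], "scheme.dt_ms") * 1e-3,
            t_end=_positive(scheme_sec["t_end_s"], "scheme.t_end_s"),
            newton=newton,
            linear_tol=float(scheme_sec.get("linear_tol", 1e-8)),
            zero_mean=bool(scheme_sec.get("zero_mean", True)),
            vc_constant_sigma=bool(scheme_sec.get("vc_constant_sigma", False)),
        )
    except ConfigError:
        raise
    except ValueError as exc:
        raise ConfigError(f"scheme: {exc}") from None

    sources_sec = doc.get("sources", {}) or {}
    _expect(sources_sec, {"file", "synthetic"}, set(), "sources")
    synthetic = sources_sec.get("synthetic")
    if synthetic is not None:
        _expect(synthetic, {"firing_rate_hz", "duration_s", "n_compartments",
                            "dt_source_ms", "ap_amplitude_nA",
                            "background_exchange_nA", "soma_position_um",
                            "dendrite_length_um"},
                set(), "sources.synthetic")
        synthetic = dict(synthetic)

    probes_sec = doc.get("probes", []) or []
    probes = []
    for i, p in enumerate(probes_sec):
        _expect(p, {"label", "point_um", "quantity"},
                {"label", "point_um", "quantity"}, f"probes[{i}]")
        point = tuple(float(x) * 1e-6 for x in p["point_um"])
        if len(point) != len(extents):
            raise ConfigError(f"probes[{i}].point_um: {len(point)} coordinates "
                              f"for a {len(extents)}-D domain")
        probes.append((str(p["label"]), point, str(p["quantity"])))

    outputs_sec = doc.get("outputs", {}) or {}
    _expect(outputs_sec, {"dir", "snapshot_times_s"}, set(), "outputs")
    out_dir = Path(outputs_sec.get("dir", "electrodiff_out"))
    snapshot_times = [float(t) for t in outputs_sec.get("snapshot_times_s", [])]

    return RunConfig(
        seed=seed,
        extents=extents,
        spacing=spacing,
        boundary=boundary,
        ions=ions,
        scheme=scheme,
        sources_file=sources_sec.get("file"),
        synthetic=synthetic,
        probes=probes,
        out_dir=out_dir,
        snapshot_times=snapshot_times,
        raw=dict(doc),
    )
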