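"""Reference simulation setups and result diagnostics.

Three packaged setups exercise the schemes:

1. A 1-D NaX salt bath with a step concentration profile and sealed
   boundaries, on a nanometre/nanosecond grid (where PNP is affordable)
   and on a 100 um / seconds grid.
2. A 3-D box of standard ECS solution with a K+ point source and sink,
   probed 5 um from each electrode.
3. A surrogate spiking neuron (synthetic compartment sources) in a large
   clamped box, probed near the soma and near the apical dendrites.

The module also carries the closed-form oracles used to check them:
free-space step diffusion (erf profile), the point-source volume-conductor
potential I/(4 pi alpha sigma r), and the implied-Poisson-voltage
diagnostic that converts a charge-density profile into the potential
Poisson's equation would demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import erf

from .electrolyte import (
    IonSet,
    IonSpecies,
    PhysicalConstants,
    PorousMedium,
    default_ion_set,
)
from .grid import StructuredGrid, assemble_div_a_grad, build_grid, probe
from .schemes import (
    BoundarySpec,
    SchemeConfig,
    SimulationState,
    StepReport,
    _SchemeBase,
    _solve_pinned,
    initial_state,
    make_scheme,
)
from .sources import CompartmentSource, SourceSet, synthetic_neuron_sources

__all__ = [
    "ProbeSeries",
    "AppResult",
    "analytic_step_diffusion",
    "lowpass_average",
    "vc_point_source_potential",
    "implied_poisson_voltage",
    "binary_ion_set",
    "run_simulation",
    "run_app1",
    "run_app2",
    "run_app3_surrogate",
]


@dataclass
class ProbeSeries:
    """Time series of one field quantity sampled at one point."""

    label: str
    point: tuple[float, ...]
    times: np.ndarray
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("probe times must be strictly increasing")


@dataclass
class AppResult:
    """Everything a packaged run produces."""

    final_state: SimulationState
    probes: dict[str, ProbeSeries]
    snapshots: dict[float, dict[str, np.ndarray]] = field(default_factory=dict)
    reports: list[StepReport] = field(default_factory=list)

    def probe_frame(self):
        """Probe series as a pandas DataFrame (column per label)."""
        import pandas as pd

        cols = {}
        for label, series in self.probes.items():
            cols.setdefault("t_s", series.times)
            cols[label] = series.values
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Closed-form oracles and diagnostics

def analytic_step_diffusion(x, t: float, D: float, c_lo: float, c_hi: float):
    """Free-space diffusion of an initial step c_lo (x<=0) / c_hi (x>0).

    c(x, t) = (c_lo+c_hi)/2 + (c_hi-c_lo)/2 * erf(x / (2 sqrt(D t))).
    """
    if t <= 0:
        raise ValueError("t must be positive")
    x = np.asarray(x, dtype=float)
    mid = 0.5 * (c_lo + c_hi)
    amp = 0.5 * (c_hi - c_lo)
    out = mid + amp * erf(x / (2.0 * np.sqrt(D * t)))
    return float(out[()]) if out.ndim == 0 else out


def lowpass_average(series: ProbeSeries, window: float = 0.1) -> ProbeSeries:
    """Non-overlapping block means over a fixed window (default 100 ms).

    Block timestamps sit at the block centers; a trailing partial block
    is dropped. This is the standard way to isolate the slow (diffusive)
    component of an extracellular potential.
    """
    if series.times.size < 2:
        raise ValueError("series too short to average")
    dt = float(np.median(np.diff(series.times)))
    if window < dt - 1e-12 * dt:
        raise ValueError(f"window {window} s shorter than sampling interval {dt} s")
    m = max(int(round(window / dt)), 1)
    n_blocks = series.times.size // m
    if n_blocks == 0:
        raise ValueError("window longer than the whole series")
    t = series.times[: n_blocks * m].reshape(n_blocks, m).mean(axis=1)
    v = series.values[: n_blocks * m].reshape(n_blocks, m).mean(axis=1)
    return ProbeSeries(series.label + "_lowpass", series.point, t, v, series.units)


def vc_point_source_potential(points, sources: Sequence[tuple[Sequence[float], float]],
                              sigma: float, alpha: float):
    """Free-space volume-conductor potential sum_s I_s / (4 pi alpha sigma r_s).

    `sources` is a list of (position, current) pairs in SI units; the
    ECS volume fraction alpha scales the current density the same way the
    simulated point sources are scaled.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    phi = np.zeros(len(pts))
    for pos, current in sources:
        r = np.linalg.norm(pts - np.asarray(pos, dtype=float), axis=1)
        if np.any(r == 0):
            raise ValueError("evaluation point coincides with a source")
        phi += current / (4.0 * np.pi * alpha * sigma * r)
    return float(phi[0]) if np.ndim(points) == 1 else phi


def implied_poisson_voltage(c: np.ndarray, ions: IonSet, grid: StructuredGrid,
                            constants: PhysicalConstants | None = None) -> float:
    """Potential range Poisson's equation implies for a 1-D charge profile.

    Forms rho = F sum_k z_k c_k from the given concentration fields,
    solves d^2 phi / dx^2 = -rho/eps with zero-field (Neumann) ends and a
    zero-mean constraint, and returns max(phi) - min(phi) in volts.

    An electroneutral field returns 0; profiles produced by independent
    diffusion of unequal-mobility ions imply physically absurd voltages,
    which is the classic argument for electroneutral bulk schemes.
    """
    if grid.dim != 1:
        raise ValueError("implied_poisson_voltage is a 1-D diagnostic")
    constants = constants or ions.constants
    rho = np.tensordot(constants.F * ions.z, np.atleast_2d(c), axes=(0, 0))
    L1 = assemble_div_a_grad(grid, np.ones(grid.n_nodes))
    phi = _solve_pinned(L1, -rho / constants.eps, grid,
                        BoundarySpec(potential_bc="neumann"), zero_mean=True)
    return float(np.max(phi) - np.min(phi))


# ---------------------------------------------------------------------------
# Generic run loop

_QUANTITIES = ("phi", "phi_vc", "phi_diff")


def _sample(state: SimulationState, point, quantity: str) -> float:
    if quantity in _QUANTITIES:
        return probe(getattr(state, quantity), point, state.grid)
    if quantity.startswith("c:"):
        k = state.ions.index(quantity[2:])
        return probe(state.c[k], point, state.grid)
    raise ValueError(f"unknown probe quantity {quantity!r}")


def run_simulation(
    scheme: _SchemeBase,
    state: SimulationState,
    sources: SourceSet | None,
    dt: float,
    t_end: float,
    probe_defs: Sequence[tuple[str, Sequence[float], str]] = (),
    snapshot_times: Sequence[float] = (),
    snapshot_fields: Sequence[str] = ("phi",),
) -> AppResult:
    """Advance a scheme to t_end, recording probes each step.

    Deterministic: probe CSVs from two runs of the same configuration are
    bit-identical.
    """
    n_steps = int(round((t_end - state.t) / dt))
    times = np.empty(n_steps)
    records = {label: np.empty(n_steps) for label, _, _ in probe_defs}
    snapshots: dict[float, dict[str, np.ndarray]] = {}
    reports: list[StepReport] = []
    want = sorted(snapshot_times)
    for i in range(n_steps):
        state, report = scheme.step(state, sources, dt)
        reports.append(report)
        times[i] = state.t
        for label, point, quantity in probe_defs:
            records[label][i] = _sample(state, point, quantity)
        while want and state.t >= want[0] - 0.5 * dt:
            t_snap = want.pop(0)
            snap = {}
            for name in snapshot_fields:
                if name.startswith("c:"):
                    snap[name] = state.c[state.ions.index(name[2:])].copy()
                else:
                    snap[name] = getattr(state, name).copy()
            snapshots[t_snap] = snap
    probes = {
        label: ProbeSeries(label, tuple(point), times, records[label])
        for label, point, _ in probe_defs
    }
    return AppResult(state, probes, snapshots, reports)


# ---------------------------------------------------------------------------
# Application 1: 1-D NaX step

def binary_ion_set(porous: PorousMedium | None = None,
                   constants: PhysicalConstants | None = None) -> IonSet:
    """Na+ / X- binary salt with the packaged mobilities, baseline 145 mM."""
    return IonSet(
        [IonSpecies("Na", 1, 1.33e-9, 145.0), IonSpecies("X", -1, 2.03e-9, 145.0)],
        porous=porous, constants=constants,
    )


_APP1 = {
    "short": dict(extent=0.1e-6, spacing=0.02e-9, dt=0.1e-9, t_end=0.1e-6),
    "long": dict(extent=50e-6, spacing=0.01e-6, dt=1e-3, t_end=10.0),
}


def run_app1(scheme: str = "KNP", variant: str = "short",
             overrides: Mapping | None = None) -> AppResult:
    """1-D NaX step-concentration run (sealed box, no sources).

    Initial condition: both species at 140 mM for x <= 0 and 150 mM for
    x > 0. The probe records dphi = phi(x_right) - phi(x_left) at the
    domain ends. PNP is refused on the 'long' variant unless explicitly
    overridden (allow_pnp=True): a 10 nm Debye process cannot be resolved
    on a 10 nm-per-cell-millionth grid with millisecond steps.
    """
    if variant not in _APP1:
        raise ValueError(f"variant must be one of {sorted(_APP1)}")
    p = dict(_APP1[variant])
    ov = dict(overrides or {})
    if scheme == "PNP" and variant == "long" and not ov.pop("allow_pnp", False):
        raise ValueError("PNP on the long variant needs allow_pnp=True "
                         "(grid far too coarse for charge relaxation)")
    for key in ("spacing", "dt", "t_end", "extent"):
        if key in ov:
            p[key] = ov.pop(key)
    c_lo, c_hi = ov.pop("c_lo", 140.0), ov.pop("c_hi", 150.0)
    snapshot_times = ov.pop("snapshot_times", ())
    cfg = ov.pop("cfg", None) or SchemeConfig(scheme=scheme, dt=p["dt"], t_end=p["t_end"])
    if ov:
        raise ValueError(f"unknown overrides {sorted(ov)}")
    ions = binary_ion_set()
    grid = build_grid(1, [(-p["extent"], p["extent"])], p["spacing"])
    x = grid.axes[0]
    c0 = np.where(x <= 0, c_lo, c_hi)
    state = initial_state(grid, ions, np.stack([c0, c0]))
    boundary = BoundarySpec(kind="sealed")
    sch = make_scheme(scheme, grid, ions, boundary, cfg)
    x_left, x_right = (-p["extent"],), (p["extent"],)
    probe_defs = [
        ("phi_left", x_left, "phi"),
        ("phi_right", x_right, "phi"),
    ]
    result = run_simulation(sch, state, None, p["dt"], p["t_end"], probe_defs,
                            snapshot_times, ("phi", "c:Na", "c:X"))
    dphi = result.probes["phi_right"].values - result.probes["phi_left"].values
    result.probes["dphi"] = ProbeSeries(
        "dphi", x_right, result.probes["phi_right"].times, dphi, "V")
    return result


# ---------------------------------------------------------------------------
# Application 2: K+ point source and sink in a 3-D box

def app2_sources(I: float = 0.1e-9, stim_off: float = 1.0, t_end: float = 2.0,
                 x_source=(120e-6, 200e-6, 20e-6),
                 x_sink=(280e-6, 200e-6, 20e-6)) -> SourceSet:
    """Constant-current K+ source/sink pair, on for t in [0, stim_off)."""
    n = max(int(np.ceil(t_end / stim_off - 1e-12)), 1)
    series = np.zeros(n)
    series[0] = I
    comps = [
        CompartmentSource(0, np.asarray(x_source), {"K": series}),
        CompartmentSource(1, np.asarray(x_sink), {"K": -series}),
    ]
    return SourceSet(comps, t0=0.0, dt_source=stim_off)


def run_app2(scheme: str = "KNP", overrides: Mapping | None = None) -> AppResult:
    """K+ source/sink pair in a 400 x 400 x 40 um box of ECS solution.

    Clamp boundaries at the baseline composition; source at (120,200,20)
    um and sink at (280,200,20) um, +/- 0.1 nA, on for one second, run to
    two seconds with 2 ms steps. Probes sit 5 um from each electrode;
    dphi = phi(left probe) - phi(right probe), likewise for phi_VC.
    """
    ov = dict(overrides or {})
    spacing = ov.pop("spacing", 5e-6)
    dt = ov.pop("dt", 2e-3)
    t_end = ov.pop("t_end", 2.0)
    stim_off = ov.pop("stim_off", 1.0)
    I = ov.pop("I", 0.1e-9)
    extents = ov.pop("extents", [(0.0, 400e-6), (0.0, 400e-6), (0.0, 40e-6)])
    x_source = ov.pop("x_source", (120e-6, 200e-6, 20e-6))
    x_sink = ov.pop("x_sink", (280e-6, 200e-6, 20e-6))
    probe_left = ov.pop("probe_left", (120e-6, 205e-6, 20e-6))
    probe_right = ov.pop("probe_right", (280e-6, 205e-6, 20e-6))
    snapshot_times = ov.pop("snapshot_times", ())
    cfg = ov.pop("cfg", None) or SchemeConfig(scheme=scheme, dt=dt, t_end=t_end)
    if ov:
        raise ValueError(f"unknown overrides {sorted(ov)}")
    ions = default_ion_set()
    grid = build_grid(3, extents, spacing)
    for pt, name in ((probe_left, "left"), (probe_right, "right")):
        if grid.nearest_node(pt) in (grid.nearest_node(x_source), grid.nearest_node(x_sink)):
            raise ValueError(f"{name} probe coincides with a source node; refine the grid")
    sources = app2_sources(I, stim_off, t_end, x_source, x_sink)
    state = initial_state(grid, ions)
    boundary = BoundarySpec(kind="clamp")
    sch = make_scheme(scheme, grid, ions, boundary, cfg)
    probe_defs = []
    for side, pt in (("left", probe_left), ("right", probe_right)):
        probe_defs += [
            (f"phi_{side}", pt, "phi"),
            (f"phi_vc_{side}", pt, "phi_vc"),
            (f"phi_diff_{side}", pt, "phi_diff"),
            (f"cK_{side}", pt, "c:K"),
        ]
    result = run_simulation(sch, state, sources, dt, t_end, probe_defs,
                            snapshot_times, ("phi", "phi_vc", "phi_diff", "c:K"))
    times = result.probes["phi_left"].times
    for name in ("phi", "phi_vc", "phi_diff"):
        delta = result.probes[f"{name}_left"].values - result.probes[f"{name}_right"].values
        result.probes[f"d{name}"] = ProbeSeries(f"d{name}", tuple(probe_left),
                                                times, delta, "V")
    return result


# ---------------------------------------------------------------------------
# Application 3 (surrogate): spiking neuron sources in a large box

def run_app3_surrogate(sources: SourceSet | None = None,
                       overrides: Mapping | None = None,
                       seed: int = 0) -> AppResult:
    """Surrogate neuron in a clamped box approximating a tissue cylinder.

    The domain is the bounding box [-500, 500] x [-400, 1100] x
    [-500, 500] um of a 500 um-radius, 1500 um-tall cylinder with the
    soma at the origin. Probes: near the soma at (20, 20, 20) um and near
    the apical dendrites at (-100, 1100, 0) um. Sources default to the
    seeded synthetic generator at 5 AP/s.
    """
    ov = dict(overrides or {})
    spacing = ov.pop("spacing", 50e-6)
    dt = ov.pop("dt", 0.1)
    t_end = ov.pop("t_end", 80.0)
    scheme = ov.pop("scheme", "KNP")
    firing_rate = ov.pop("firing_rate", 5.0)
    extents = ov.pop("extents", [(-500e-6, 500e-6), (-400e-6, 1100e-6), (-500e-6, 500e-6)])
    probe_green = ov.pop("probe_green", (20e-6, 20e-6, 20e-6))
    probe_purple = ov.pop("probe_purple", (-100e-6, 1100e-6, 0.0))
    snapshot_times = ov.pop("snapshot_times", ())
    gen_kwargs = ov.pop("generator", {})
    cfg = ov.pop("cfg", None) or SchemeConfig(scheme=scheme, dt=dt, t_end=t_end)
    if ov:
        raise ValueError(f"unknown overrides {sorted(ov)}")
    ions = default_ion_set()
    grid = build_grid(3, extents, spacing)
    if sources is None:
        sources = synthetic_neuron_sources(firing_rate=firing_rate, duration=t_end,
                                           seed=seed, **gen_kwargs)
    for comp in sources.compartments:
        grid._check_inside(comp.position[: grid.dim])
    state = initial_state(grid, ions)
    boundary = BoundarySpec(kind="clamp")
    sch = make_scheme(scheme, grid, ions, boundary, cfg)
    probe_defs = []
    for label, pt in (("green", probe_green), ("purple", probe_purple)):
        for name in ions.names:
            probe_defs.append((f"c{name}_{label}", pt, f"c:{name}"))
        for q in ("phi", "phi_vc", "phi_diff"):
            probe_defs.append((f"{q}_{label}", pt, q))
    result = run_simulation(sch, state, sources, dt, t_end, probe_defs,
                            snapshot_times, ("phi", "phi_vc", "phi_diff"))
    # concentration changes relative to baseline
    for label in ("green", "purple"):
        for k, name in enumerate(ions.names):
            series = result.probes[f"c{name}_{label}"]
            result.probes[f"dc{name}_{label}"] = ProbeSeries(
                f"dc{name}_{label}", series.point, series.times,
                series.values - ions.c_baseline[k], "mol/m^3")
    return result
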