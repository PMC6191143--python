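"""Point current sources representing neuronal membrane exchange.

A neuron is reduced to a set of compartments, each a point in the ECS that
exchanges ions with the medium. Every compartment carries per-species
current series I_k(t) and a capacitive series I_cap(t), sampled on one
uniform time base and treated as piecewise constant. Positive current
means positive charge flowing out of the cell into the ECS.

The module also provides a seeded synthetic generator that stands in for
an external compartmental neuron simulation. It is a surrogate: the
waveform shape is stylised, and only the firing rate, the Na/K sign
convention during action potentials, and exact whole-cell current balance
(sum_j I^j(t) = 0) are anchored to how real membrane sources behave.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .electrolyte import IonSet
from .grid import StructuredGrid

__all__ = [
    "CompartmentSource",
    "SourceSet",
    "load_sources",
    "save_sources",
    "integrate_step",
    "deposit",
    "synthetic_neuron_sources",
    "validate_charge_balance",
]

CAP = "cap"  # reserved species label for the capacitive current
_KNOWN_SPECIES = ("Na", "K", "Ca", "X", CAP)


@dataclass
class CompartmentSource:
    """One membrane compartment: a position plus its current series (A)."""

    comp_id: int
    position: np.ndarray  # (3,), m
    currents: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.currents = {k: np.asarray(v, dtype=float) for k, v in self.currents.items()}

    def total_series(self) -> np.ndarray:
        """Sum of ionic plus capacitive current, per sample."""
        return np.sum(list(self.currents.values()), axis=0)


class SourceSet:
    """Ordered compartments sharing one uniform source time base.

    Sample s holds on [t0 + s*dt_source, t0 + (s+1)*dt_source). A closed
    cell has sum_j I^j(t) = 0 at every sample (membrane currents merely
    redistribute charge); loading warns when that balance is violated.
    """

    def __init__(self, compartments: Sequence[CompartmentSource], t0: float,
                 dt_source: float, balance_tol: float = 1e-15) -> None:
        self.compartments = list(compartments)
        if not self.compartments:
            raise ValueError("no sources")
        if dt_source <= 0:
            raise ValueError("dt_source must be positive")
        self.t0 = float(t0)
        self.dt_source = float(dt_source)
        lengths = {len(v) for c in self.compartments for v in c.currents.values()}
        if len(lengths) != 1:
            raise ValueError("all current series must share one time base")
        self.n_samples = lengths.pop()
        imbalance = validate_charge_balance(self)
        scale = max(
            (float(np.max(np.abs(v))) for c in self.compartments for v in c.currents.values()),
            default=0.0,
        )
        if imbalance > balance_tol + 1e-9 * scale:
            warnings.warn(
                f"total membrane current does not balance: max |sum_j I^j| = {imbalance:g} A",
                stacklevel=2,
            )

    @property
    def times(self) -> np.ndarray:
        """Sample start times, s."""
        return self.t0 + self.dt_source * np.arange(self.n_samples)

    @property
    def t_end(self) -> float:
        return self.t0 + self.dt_source * self.n_samples

    def species_names(self) -> list[str]:
        seen: list[str] = []
        for c in self.compartments:
            for k in c.currents:
                if k not in seen:
                    seen.append(k)
        return seen

    def total_current(self) -> np.ndarray:
        """sum_j I^j per sample (ionic + capacitive), A."""
        return np.sum([c.total_series() for c in self.compartments], axis=0)

    def __len__(self) -> int:
        return len(self.compartments)


def validate_charge_balance(sources: SourceSet, tol: float | None = None) -> float:
    """Worst-case total-current imbalance max_t |sum_j I^j(t)|, A."""
    return float(np.max(np.abs(sources.total_current())))


# ---------------------------------------------------------------------------
# Time integration of the piecewise-constant series

def _cumulative(series: np.ndarray, t0: float, dt: float):
    edges = t0 + dt * np.arange(len(series) + 1)
    cum = np.concatenate([[0.0], np.cumsum(series) * dt])
    return edges, cum


def integrate_step(sources: SourceSet, t: float, dt: float) -> dict[str, np.ndarray]:
    """Exact charge transferred per compartment over [t, t+dt], C.

    Integrates the piecewise-constant series rather than sampling, so
    arbitrary window/sample alignment is handled exactly. Returns a dict
    keyed by species label ('cap' included), each an (n_compartments,)
    array.
    """
    eps = 1e-9 * sources.dt_source
    if t < sources.t0 - eps or t + dt > sources.t_end + eps:
        raise ValueError(
            f"window [{t}, {t + dt}] outside source time base "
            f"[{sources.t0}, {sources.t_end}]")
    out: dict[str, np.ndarray] = {
        name: np.zeros(len(sources.compartments)) for name in sources.species_names()
    }
    for j, comp in enumerate(sources.compartments):
        for name, series in comp.currents.items():
            edges, cum = _cumulative(series, sources.t0, sources.dt_source)
            out[name][j] = np.interp(t + dt, edges, cum) - np.interp(t, edges, cum)
    return out


# ---------------------------------------------------------------------------
# Deposition onto the grid

def deposit(sources: SourceSet, grid: StructuredGrid, t: float, dt: float,
            ions: IonSet) -> tuple[np.ndarray, np.ndarray]:
    """Turn compartment currents over [t, t+dt] into nodal source fields.

    Each Dirac point source is deposited on the single nearest grid node
    (ties toward the smaller flat index) and divided by that node's
    control volume. Returns (f_hat, i_cap): f_hat has shape
    (n_species, N) in mol/(m^3 s) referred to ECS volume, i_cap has shape
    (N,) in A/m^3 (charge per ECS volume per time). The grid integrals of
    the deposited fields reproduce the compartment currents exactly.
    """
    F = ions.constants.F
    alpha = ions.porous.alpha
    charges = integrate_step(sources, t, dt)
    vol = grid.node_volumes()
    f_hat = np.zeros((len(ions), grid.n_nodes))
    i_cap = np.zeros(grid.n_nodes)
    node_of = [grid.nearest_node(c.position[: grid.dim]) for c in sources.compartments]
    for name, q in charges.items():
        mean_I = q / dt
        if name == CAP:
            for j, node in enumerate(node_of):
                i_cap[node] += mean_I[j] / (alpha * vol[node])
            continue
        try:
            k = ions.index(name)
        except ValueError:
            raise ValueError(f"source species {name!r} not present in the ion set") from None
        z = ions.z[k]
        for j, node in enumerate(node_of):
            f_hat[k, node] += mean_I[j] / (F * z * alpha * vol[node])
    return f_hat, i_cap


# ---------------------------------------------------------------------------
# CSV dialect

_CSV_COLUMNS = ["t_ms", "comp_id", "x_um", "y_um", "z_um", "species", "current_nA"]


def load_sources(path: str | Path) -> SourceSet:
    """Read a source CSV (t_ms,comp_id,x_um,y_um,z_um,species,current_nA).

    One row per (sample, compartment, species); species in
    {Na, K, Ca, X, cap}; the t grid must be uniform and shared.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"source file {path} is missing columns {missing}")
    if df.empty:
        raise ValueError("no sources")
    bad = set(df["species"]) - set(_KNOWN_SPECIES)
    if bad:
        raise ValueError(f"unknown species names {sorted(bad)}; expected {_KNOWN_SPECIES}")
    times_ms_exact = np.sort(df["t_ms"].unique())
    times = times_ms_exact * 1e-3
    if len(times) > 1:
        dts = np.diff(times)
        dt_source = float(np.median(dts))
        if np.any(np.abs(dts - dt_source) > 1e-6 * dt_source):
            raise ValueError("source time base is not uniform")
    else:
        dt_source = float(times[0]) if times[0] > 0 else 1e-3
    n_samples = len(times)
    compartments = []
    for comp_id, g in df.groupby("comp_id", sort=True):
        pos = g[["x_um", "y_um", "z_um"]].iloc[0].to_numpy() * 1e-6
        currents: dict[str, np.ndarray] = {}
        for name, gg in g.groupby("species", sort=False):
            if len(gg) != n_samples:
                raise ValueError(
                    f"compartment {comp_id} species {name}: {len(gg)} rows, "
                    f"expected {n_samples} (one per sample)")
            gg = gg.sort_values("t_ms")
            currents[name] = gg["current_nA"].to_numpy() * 1e-9
        comp = CompartmentSource(int(comp_id), pos, currents)
        # keep the file's exact nA values so re-saving round-trips bitwise
        comp._currents_nA = {name: gg.sort_values("t_ms")["current_nA"].to_numpy()
                             for name, gg in g.groupby("species", sort=False)}
        compartments.append(comp)
    out = SourceSet(compartments, t0=float(times[0]), dt_source=dt_source)
    out._times_ms = times_ms_exact  # keep the file's exact grid for round-trips
    return out


def save_sources(sources: SourceSet, path: str | Path) -> None:
    """Write a SourceSet in the CSV dialect (canonical row order)."""
    order = [s for s in _KNOWN_SPECIES]
    rows: dict[str, list] = {c: [] for c in _CSV_COLUMNS}
    times_ms = getattr(sources, "_times_ms", sources.times * 1e3)
    for t_ms, s in zip(times_ms, range(sources.n_samples)):
        for comp in sources.compartments:
            nA = getattr(comp, "_currents_nA", None)
            for name in sorted(comp.currents, key=order.index):
                rows["t_ms"].append(t_ms)
                rows["comp_id"].append(comp.comp_id)
                rows["x_um"].append(comp.position[0] * 1e6)
                rows["y_um"].append(comp.position[1] * 1e6)
                rows["z_um"].append(comp.position[2] * 1e6)
                rows["species"].append(name)
                rows["current_nA"].append(
                    nA[name][s] if nA is not None else comp.currents[name][s] * 1e9)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Synthetic surrogate generator

def synthetic_neuron_sources(
    n_compartments: int = 20,
    dendrite_length: float = 1000e-6,
    firing_rate: float = 5.0,
    duration: float = 80.0,
    seed: int | None = 0,
    dt_source: float = 0.25e-3,
    ap_amplitude: float = 0.5e-9,
    background_exchange: float = 0.0,
    soma_position: Sequence[float] = (0.0, 0.0, 0.0),
) -> SourceSet:
    """Seeded surrogate for the membrane currents of a spiking neuron.

    Layout: a soma compartment at soma_position plus n_compartments-1
    dendritic compartments in a line along +y up to dendrite_length.
    Each Poisson-timed action potential emits a stereotyped ~2 ms biphasic
    event concentrated near the soma: 1 ms of Na+ influx (negative ECS
    source) followed by 1 ms of K+ efflux, both triangular in time, with
    total amplitude ap_amplitude. The capacitive return current is spread
    uniformly over all compartments and constructed so that
    sum_j I^j(t) = 0 holds exactly at every sample. A constant background
    K+/Na+ exchange of background_exchange amperes per dendritic
    compartment emulates slow synaptic activity (balanced per
    compartment, so it does not disturb the whole-cell balance).

    Deterministic given the seed; firing_rate in AP/s, duration in s.
    """
    if firing_rate < 0:
        raise ValueError("firing_rate must be >= 0")
    rng = np.random.default_rng(seed)
    n_samples = max(int(round(duration / dt_source)), 1)
    soma = np.asarray(soma_position, dtype=float)
    positions = [soma]
    for i in range(1, n_compartments):
        frac = i / max(n_compartments - 1, 1)
        positions.append(soma + np.array([0.0, frac * dendrite_length, 0.0]))

    zeros = lambda: np.zeros(n_samples)
    I_na = [zeros() for _ in range(n_compartments)]
    I_k = [zeros() for _ in range(n_compartments)]

    # action potentials: Poisson count, uniform times
    n_events = rng.poisson(firing_rate * duration)
    event_times = np.sort(rng.uniform(0.0, duration, size=n_events))
    half = max(int(round(1e-3 / dt_source)), 1)  # samples per 1 ms phase
    tri = 1.0 - np.abs(np.linspace(-1, 1, half + 2)[1:-1])  # triangular, >0
    tri = tri / (tri.sum() * dt_source)  # unit charge per phase
    # spatial split of the AP currents: mostly somatic
    n_near = min(4, n_compartments - 1)
    weights = np.zeros(n_compartments)
    weights[0] = 0.6
    if n_near:
        weights[1 : 1 + n_near] = 0.4 / n_near
    else:
        weights[0] = 1.0
    q_phase = ap_amplitude * 1e-3  # charge moved per phase, C
    for t_e in event_times:
        s0 = int(round((t_e) / dt_source))
        for phase, (series_list, sign, offset) in enumerate(
            [(I_na, -1.0, 0), (I_k, +1.0, half)]
        ):
            lo = s0 + offset
            hi = min(lo + half, n_samples)
            if hi <= lo:
                continue
            pulse = sign * q_phase * tri[: hi - lo]
            for j in range(n_compartments):
                if weights[j]:
                    series_list[j][lo:hi] += weights[j] * pulse

    # slow background synaptic exchange on the dendrites (balanced per comp)
    for j in range(1, n_compartments):
        I_k[j] += background_exchange
        I_na[j] -= background_exchange

    # capacitive return current: cancels the total ionic current exactly
    total_ionic = np.sum(I_na, axis=0) + np.sum(I_k, axis=0)
    cap_w = np.full(n_compartments, 1.0 / n_compartments)

    compartments = []
    for j in range(n_compartments):
        compartments.append(
            CompartmentSource(
                j,
                positions[j],
                {"Na": I_na[j], "K": I_k[j], CAP: -cap_w[j] * total_ionic},
            )
        )
    return SourceSet(compartments, t0=0.0, dt_source=dt_source)
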