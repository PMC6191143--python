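"""Electrolyte constitutive relations shared by every scheme.

Physical constants, ion species data, the porous-medium (tortuosity /
volume-fraction) corrections, and the nodewise quantities that the field
equations are built from: the conductivity sigma, the diffusive-current
coefficient b, the charge density rho and the Nernst-Planck flux.

Internal units are strict SI throughout: m, s, V, mol/m^3 (numerically
equal to mM), S/m, C/m^3, A. Configuration files may use um, ms, mM, nA;
conversion happens at load time, never here.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "PhysicalConstants",
    "PorousMedium",
    "IonSpecies",
    "IonSet",
    "thermal_voltage",
    "effective_diffusion",
    "scale_source",
    "conductivity",
    "diffusive_potential_coefficient_b",
    "charge_density",
    "nernst_planck_flux",
    "binary_salt_diffusion",
    "junction_potential_binary",
    "load_ion_table",
    "default_ion_set",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Thermodynamic and electrostatic constants of the bath.

    Defaults describe extracellular saline at 300 K with the relative
    permittivity of water (80).
    """

    R: float = 8.314        # gas constant, J/(K mol)
    T: float = 300.0        # temperature, K
    F: float = 9.648e4      # Faraday constant, C/mol
    eps0: float = 8.854e-12  # vacuum permittivity, F/m
    eps_r: float = 80.0     # relative permittivity of the medium

    def __post_init__(self) -> None:
        for name in ("R", "T", "F", "eps0", "eps_r"):
            if not getattr(self, name) > 0:
                raise ValueError(f"PhysicalConstants.{name} must be strictly positive")

    @property
    def psi(self) -> float:
        """Thermal voltage RT/F, V (~25.9 mV at 300 K)."""
        return self.R * self.T / self.F

    @property
    def eps(self) -> float:
        """Absolute permittivity eps_r * eps0, F/m."""
        return self.eps_r * self.eps0


@dataclass(frozen=True)
class PorousMedium:
    """Porous-medium description of brain tissue.

    lambda_tort: tortuosity; obstacles slow diffusion so that the
        effective coefficient is D/lambda^2.
    alpha: extracellular volume fraction; sources referred to tissue
        volume are scaled by 1/alpha when expressed per ECS volume.
    """

    lambda_tort: float = 1.6
    alpha: float = 0.2

    def __post_init__(self) -> None:
        if self.lambda_tort < 1:
            raise ValueError("tortuosity must be >= 1")
        if not (0 < self.alpha <= 1):
            raise ValueError("ECS volume fraction alpha must lie in (0, 1]")


def thermal_voltage(constants: PhysicalConstants) -> float:
    """Return the thermal voltage psi = R*T/F in volts."""
    return constants.psi


def effective_diffusion(D_free: float, porous: PorousMedium) -> float:
    """Tortuosity-corrected diffusion coefficient D/lambda^2 (same units as D)."""
    if D_free <= 0:
        raise ValueError("free diffusion coefficient must be positive")
    return D_free / porous.lambda_tort**2


def scale_source(f, porous: PorousMedium):
    """Scale a source density by 1/alpha to refer it to ECS volume."""
    return np.asarray(f) / porous.alpha if np.ndim(f) else f / porous.alpha


@dataclass(frozen=True)
class IonSpecies:
    """One ionic species: valence, mobility and baseline ECS concentration.

    D_free is the free-solution diffusion coefficient in m^2/s; the
    tortuosity-corrected value lives on IonSet (D_eff), which is what the
    simulations use.
    """

    name: str
    z: int
    D_free: float          # m^2/s
    c_baseline: float      # mol/m^3 (== mM)

    def __post_init__(self) -> None:
        if self.z == 0:
            raise ValueError(f"ion {self.name!r}: valence must be nonzero")
        if self.D_free <= 0:
            raise ValueError(f"ion {self.name!r}: D_free must be positive")
        if self.c_baseline < 0:
            raise ValueError(f"ion {self.name!r}: baseline concentration must be >= 0")


class IonSet:
    """Ordered collection of ion species plus the porous medium they live in.

    Effective (tilde) diffusion coefficients are computed once at
    construction and used everywhere downstream.
    """

    def __init__(
        self,
        species: Iterable[IonSpecies],
        porous: PorousMedium | None = None,
        constants: PhysicalConstants | None = None,
    ) -> None:
        self.species: tuple[IonSpecies, ...] = tuple(species)
        if not self.species:
            raise ValueError("IonSet needs at least one species")
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate species names in {names}")
        self.porous = porous if porous is not None else PorousMedium()
        self.constants = constants if constants is not None else PhysicalConstants()
        self.names: tuple[str, ...] = tuple(names)
        self.z = np.array([s.z for s in self.species], dtype=float)
        self.D_free = np.array([s.D_free for s in self.species])
        self.D_eff = self.D_free / self.porous.lambda_tort**2
        self.c_baseline = np.array([s.c_baseline for s in self.species])
        net = float(np.dot(self.z, self.c_baseline))
        scale = float(np.dot(np.abs(self.z), self.c_baseline)) or 1.0
        if abs(net) > 1e-9 * scale:
            warnings.warn(
                f"baseline composition is not electroneutral: sum z_k c_k = {net:g} mol/m^3",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.species)

    def __iter__(self):
        return iter(self.species)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def __repr__(self) -> str:  # pragma: no cover
        return f"IonSet({', '.join(self.names)}; lambda={self.porous.lambda_tort}, alpha={self.porous.alpha})"


def _stack(concentrations, n_species: int) -> np.ndarray:
    """Coerce per-species concentrations to shape (n_species, ...)."""
    arrs = [np.atleast_1d(np.asarray(c, dtype=float)) for c in concentrations]
    if len(arrs) != n_species:
        raise ValueError(f"expected {n_species} concentration arrays, got {len(arrs)}")
    return np.stack(np.broadcast_arrays(*arrs))


def _check_nonnegative(c: np.ndarray, ions: IonSet) -> None:
    for k, name in enumerate(ions.names):
        if np.any(c[k] < 0):
            raise ValueError(f"negative concentration for species {name!r}")


def conductivity(concentrations: Sequence, ions: IonSet, psi: float | None = None):
    """Electrical conductivity sigma = F * sum_k D_k z_k^2 c_k / psi, S/m.

    Applied nodewise when given concentration fields. Strictly positive
    whenever any concentration is positive.
    """
    psi = ions.constants.psi if psi is None else psi
    c = _stack(concentrations, len(ions))
    _check_nonnegative(c, ions)
    w = ions.constants.F * ions.D_eff * ions.z**2 / psi
    out = np.tensordot(w, c, axes=(0, 0))
    return out.item() if out.size == 1 else out


def diffusive_potential_coefficient_b(concentrations: Sequence, ions: IonSet):
    """Coefficient b = F * sum_k D_k z_k c_k, A/m (signed: z not squared).

    The gradient of b is the diffusive current density; unequal mobilities
    of anions and cations make b vary along concentration gradients, which
    is the origin of liquid-junction (diffusion) potentials.
    """
    c = _stack(concentrations, len(ions))
    _check_nonnegative(c, ions)
    w = ions.constants.F * ions.D_eff * ions.z
    out = np.tensordot(w, c, axes=(0, 0))
    return out.item() if out.size == 1 else out


def charge_density(concentrations: Sequence, ions: IonSet):
    """Charge density rho = F * sum_k z_k c_k, C/m^3."""
    c = _stack(concentrations, len(ions))
    w = ions.constants.F * ions.z
    out = np.tensordot(w, c, axes=(0, 0))
    return out.item() if out.size == 1 else out


def nernst_planck_flux(c_k, grad_c, grad_phi, species: IonSpecies,
                       psi: float, porous: PorousMedium | None = None):
    """Nernst-Planck flux -D (grad c + z c grad(phi) / psi), mol/(m^2 s).

    Diffusive (Fickian) plus electric-drift component; D is the effective
    (tortuosity-corrected) coefficient when a porous medium is given.
    """
    D = species.D_free if porous is None else effective_diffusion(species.D_free, porous)
    c_k = np.asarray(c_k, dtype=float)
    if np.any(c_k < 0):
        raise ValueError(f"negative concentration for species {species.name!r}")
    return -D * (np.asarray(grad_c) + species.z * c_k * np.asarray(grad_phi) / psi)


def binary_salt_diffusion(D_a: float, D_b: float) -> float:
    """Effective diffusion coefficient 2*Da*Db/(Da+Db) of a binary 1:1 salt.

    A dissolved binary salt moves as a single species with this
    harmonic-mean coefficient: the faster ion is held back, the slower one
    dragged along, by the ambipolar electric field.
    """
    if D_a <= 0 or D_b <= 0:
        raise ValueError("diffusion coefficients must be positive")
    return 2.0 * D_a * D_b / (D_a + D_b)


def junction_potential_binary(c_lo: float, c_hi: float, D_cat: float,
                              D_an: float, psi: float) -> float:
    """Quasi-steady liquid-junction potential of a 1:1 binary salt, V.

    Integrating the zero-current condition sigma * dphi/dx + db/dx = 0
    across a concentration profile running from c_lo to c_hi gives

        phi(hi) - phi(lo) = psi * (D_an - D_cat)/(D_an + D_cat) * ln(c_hi/c_lo)

    (the Henderson formula specialised to one 1:1 salt). Returns the
    potential of the high-concentration side relative to the low side.
    """
    if c_lo <= 0 or c_hi <= 0:
        raise ValueError("concentrations must be positive")
    return psi * (D_an - D_cat) / (D_an + D_cat) * float(np.log(c_hi / c_lo))


# ---------------------------------------------------------------------------
# Ion table I/O

_ION_TABLE_COLUMNS = ["name", "z", "D_um2_per_ms", "c_baseline_mM"]


def load_ion_table(path: str | Path, porous: PorousMedium | None = None,
                   constants: PhysicalConstants | None = None) -> IonSet:
    """Read an ion table CSV (columns name,z,D_um2_per_ms,c_baseline_mM).

    D is given in um^2/ms (= 1e-9 m^2/s) and concentrations in mM
    (= mol/m^3), the units tables in this field are printed in.
    """
    df = pd.read_csv(path)
    missing = [c for c in _ION_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ion table {path} is missing columns {missing}")
    species = [
        IonSpecies(
            name=str(row["name"]),
            z=int(row["z"]),
            D_free=float(row["D_um2_per_ms"]) * 1e-9,
            c_baseline=float(row["c_baseline_mM"]),
        )
        for _, row in df.iterrows()
    ]
    return IonSet(species, porous=porous, constants=constants)


def default_ion_set(porous: PorousMedium | None = None,
                    constants: PhysicalConstants | None = None) -> IonSet:
    """The packaged four-species ECS composition (Na+, K+, X-, Ca2+).

    X- is a lumped anion carrying the properties of Cl-. The composition
    is electroneutral: 150 + 3 - 155.8 + 2*1.4 = 0 mM of charge.
    """
    ref = importlib.resources.files("electrodiff.data") / "ion_table.csv"
    with importlib.resources.as_file(ref) as p:
        return load_ion_table(p, porous=porous, constants=constants)
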