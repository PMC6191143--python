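"""Uniform structured grids and conservative discrete operators.

Vertex-centered finite volumes on uniform 1-D or 3-D grids. Each node owns
a control volume (halved at boundaries); two-point fluxes with arithmetic
face averaging discretise div(a grad u) for a nodal coefficient field a.
With homogeneous Neumann boundaries the boundary face flux is simply
dropped, which makes the discrete operator conservative by construction.

Node ordering is fixed: x fastest, then y, then z (flat index
ix + nx*(iy + ny*iz)); fields are stored as flat (N,) arrays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "StructuredGrid",
    "ScalarField",
    "build_grid",
    "assemble_div_a_grad",
    "assemble_div_grad_wrt_coeff",
    "apply_div_a_grad",
    "probe",
    "total_content",
    "export_field_csv",
    "export_fields_vtk",
]


class StructuredGrid:
    """Uniform tensor-product grid on a box, 1-D or 3-D.

    extents: per-axis (min, max) in metres. For dim=1 the transverse
    cross-section is taken as 1 m^2, so 1-D "volumes" are lengths.
    """

    def __init__(self, extents: Sequence[Sequence[float]], spacing: Sequence[float]) -> None:
        extents = [tuple(map(float, e)) for e in extents]
        spacing = [float(h) for h in spacing]
        if len(extents) not in (1, 3) or len(spacing) != len(extents):
            raise ValueError("grid must be 1-D or 3-D with one spacing per axis")
        self.dim = len(extents)
        self.extents = tuple(extents)
        counts, adj_spacing, axes = [], [], []
        for (lo, hi), h in zip(extents, spacing):
            if not hi > lo:
                raise ValueError(f"extent ({lo}, {hi}) is not well ordered")
            if not h > 0:
                raise ValueError("spacing must be positive")
            length = hi - lo
            n_cells = length / h
            n_round = round(n_cells)
            if n_round >= 1 and abs(n_cells - n_round) <= 1e-9 * max(n_cells, 1.0):
                n_cells = n_round
            else:
                n_cells = int(np.ceil(n_cells - 1e-12))
                logger.info("spacing %g does not divide extent %g; adjusted to %g",
                            h, length, length / n_cells)
            if n_cells < 2:
                raise ValueError("need at least 3 nodes (2 cells) per axis")
            counts.append(n_cells + 1)
            adj_spacing.append(length / n_cells)
            axes.append(np.linspace(lo, hi, n_cells + 1))
        self.node_counts = tuple(counts)
        self.spacing = tuple(adj_spacing)
        self.axes = tuple(axes)
        self.n_nodes = int(np.prod(counts))
        self.cell_volume = float(np.prod(adj_spacing))
        # numpy view shape: z slowest ... x fastest
        self.shape = tuple(counts[::-1])
        self._node_volumes: np.ndarray | None = None

    # -- geometry -----------------------------------------------------------

    def reshape(self, values: np.ndarray) -> np.ndarray:
        return np.asarray(values).reshape(self.shape)

    def _axis_widths(self, d: int) -> np.ndarray:
        """Per-node control width along axis d (h, halved at the two ends)."""
        n, h = self.node_counts[d], self.spacing[d]
        w = np.full(n, h)
        w[0] = w[-1] = h / 2
        return w

    def node_volumes(self) -> np.ndarray:
        """Control volume of every node, flat (N,), m^3 (m for dim=1)."""
        if self._node_volumes is None:
            vol = np.ones(self.shape)
            for d in range(self.dim):
                w = self._axis_widths(d)
                shape = [1] * self.dim
                shape[self.dim - 1 - d] = len(w)
                vol = vol * w.reshape(shape)
            self._node_volumes = vol.ravel()
        return self._node_volumes

    def node_coordinates(self) -> np.ndarray:
        """(N, dim) array of node coordinates in grid ordering."""
        mesh = np.meshgrid(*self.axes[::-1], indexing="ij")
        return np.stack([m.ravel() for m in mesh[::-1]], axis=1)

    def boundary_mask(self) -> np.ndarray:
        mask = np.zeros(self.shape, dtype=bool)
        for ax in range(len(self.shape)):
            sl = [slice(None)] * len(self.shape)
            sl[ax] = 0
            mask[tuple(sl)] = True
            sl[ax] = -1
            mask[tuple(sl)] = True
        return mask.ravel()

    def nearest_node(self, point: Sequence[float]) -> int:
        """Flat index of the node nearest to a point (ties -> smaller index)."""
        self._check_inside(point)
        flat = 0
        for d in reversed(range(self.dim)):
            lo, _ = self.extents[d]
            u = (point[d] - lo) / self.spacing[d]
            i = int(np.ceil(u - 0.5))  # .5 ties break toward the smaller index
            i = min(max(i, 0), self.node_counts[d] - 1)
            flat = flat * self.node_counts[d] + i
        return flat

    def _check_inside(self, point: Sequence[float]) -> None:
        if len(point) != self.dim:
            raise ValueError(f"point has {len(point)} coordinates, grid is {self.dim}-D")
        for d, x in enumerate(point):
            lo, hi = self.extents[d]
            tol = 1e-12 * (hi - lo)
            if not (lo - tol <= x <= hi + tol):
                raise ValueError(f"point coordinate {x} outside extent ({lo}, {hi}) on axis {d}")

    def __repr__(self) -> str:  # pragma: no cover
        return f"StructuredGrid(dim={self.dim}, nodes={self.node_counts}, spacing={self.spacing})"


@dataclass
class ScalarField:
    """One value per grid node with declared units (plumbing for c_k, phi, ...)."""

    grid: StructuredGrid
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.shape != (self.grid.n_nodes,):
            raise ValueError(
                f"field has {self.values.size} values, grid has {self.grid.n_nodes} nodes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite values")


def build_grid(dim: int, extents, spacing) -> StructuredGrid:
    """Construct a uniform grid; scalar spacing is broadcast to every axis."""
    if dim == 1 and np.ndim(extents[0]) == 0:
        extents = [extents]
    if np.ndim(spacing) == 0:
        spacing = [spacing] * dim
    if len(extents) != dim:
        raise ValueError(f"expected {dim} extents, got {len(extents)}")
    return StructuredGrid(extents, spacing)


def _as_values(field) -> np.ndarray:
    return field.values if isinstance(field, ScalarField) else np.asarray(field, dtype=float).ravel()


# ---------------------------------------------------------------------------
# Face machinery

def _faces(grid: StructuredGrid, d: int) -> tuple[np.ndarray, np.ndarray]:
    """Flat node index pairs (I, J) for all faces along axis d."""
    idx = np.arange(grid.n_nodes).reshape(grid.shape)
    ax = grid.dim - 1 - d
    n = grid.node_counts[d]
    I = np.take(idx, range(0, n - 1), axis=ax).ravel()
    J = np.take(idx, range(1, n), axis=ax).ravel()
    return I, J


def _face_row_weights(grid: StructuredGrid, d: int) -> tuple[np.ndarray, np.ndarray]:
    """1/(h_d * w_d) factors for the two rows touched by each face along d."""
    n, h = grid.node_counts[d], grid.spacing[d]
    wI = np.full(n - 1, h)
    wI[0] = h / 2
    wJ = np.full(n - 1, h)
    wJ[-1] = h / 2
    shape = [1] * grid.dim
    shape[grid.dim - 1 - d] = n - 1
    ones = np.ones(grid.shape[:grid.dim - 1 - d] + (1,) + grid.shape[grid.dim - d:])
    cI = (ones * wI.reshape(shape)).ravel()
    cJ = (ones * wJ.reshape(shape)).ravel()
    return 1.0 / (h * cI), 1.0 / (h * cJ)


def assemble_div_a_grad(grid: StructuredGrid, a, dirichlet_mask: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse operator L with (L u)_i ~ (div(a grad u))_i pointwise.

    Two-point flux with arithmetic face averaging of the nodal coefficient;
    boundary faces are dropped (homogeneous Neumann). Rows flagged in
    dirichlet_mask are replaced by identity rows, for clamped values.
    """
    a = _as_values(a)
    if a.shape != (grid.n_nodes,):
        a = np.full(grid.n_nodes, float(a)) if a.size == 1 else a
    if np.any(a <= 0):
        raise ValueError("coefficient field must be strictly positive")
    rows, cols, vals = [], [], []
    for d in range(grid.dim):
        I, J = _faces(grid, d)
        t = 0.5 * (a[I] + a[J])
        fI, fJ = _face_row_weights(grid, d)
        rows += [I, I, J, J]
        cols += [J, I, I, J]
        vals += [t * fI, -t * fI, t * fJ, -t * fJ]
    L = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(grid.n_nodes, grid.n_nodes),
    )
    if dirichlet_mask is not None:
        L = _set_identity_rows(L, dirichlet_mask)
    return L


def assemble_div_grad_wrt_coeff(grid: StructuredGrid, u) -> sp.csr_matrix:
    """Sparse map M with M a ~ div(a grad u) pointwise (linear in a).

    div(a grad u) is linear in the nodal coefficient a for a fixed u; this
    is the exact Jacobian block of the flux divergence with respect to a.
    """
    u = _as_values(u)
    rows, cols, vals = [], [], []
    for d in range(grid.dim):
        I, J = _faces(grid, d)
        g = 0.5 * (u[J] - u[I])
        fI, fJ = _face_row_weights(grid, d)
        rows += [I, I, J, J]
        cols += [I, J, I, J]
        vals += [g * fI, g * fI, -g * fJ, -g * fJ]
    return sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(grid.n_nodes, grid.n_nodes),
    )


def apply_div_a_grad(grid: StructuredGrid, a, u) -> np.ndarray:
    """Matrix-free evaluation of div(a grad u), flat (N,).

    Same stencil as assemble_div_a_grad; used in residual evaluations
    where assembling a sparse matrix per call would dominate the cost.
    """
    A = grid.reshape(_as_values(a))
    U = grid.reshape(_as_values(u))
    out = np.zeros(grid.shape)
    for d in range(grid.dim):
        ax = grid.dim - 1 - d
        h = grid.spacing[d]
        flux = 0.5 * (np.take(A, range(1, grid.node_counts[d]), axis=ax)
                      + np.take(A, range(0, grid.node_counts[d] - 1), axis=ax))
        flux = flux * np.diff(U, axis=ax) / h
        pad = [(0, 0)] * grid.dim
        pad[ax] = (1, 1)
        flux = np.pad(flux, pad)
        w = grid._axis_widths(d)
        shape = [1] * grid.dim
        shape[ax] = len(w)
        out += np.diff(flux, axis=ax) / w.reshape(shape)
    return out.ravel()


def _set_identity_rows(L: sp.csr_matrix, mask: np.ndarray) -> sp.csr_matrix:
    """Replace the rows flagged by mask with identity rows."""
    mask = np.asarray(mask, dtype=bool)
    d = np.ones(L.shape[0])
    d[mask] = 0.0
    L = sp.diags(d) @ L + sp.diags(mask.astype(float))
    return sp.csr_matrix(L)


# ---------------------------------------------------------------------------
# Sampling and integrals

def probe(field, point: Sequence[float], grid: StructuredGrid | None = None) -> float:
    """Multilinear interpolation of a nodal field at a point inside the domain."""
    if isinstance(field, ScalarField):
        grid, values = field.grid, field.values
    else:
        if grid is None:
            raise ValueError("probe of a bare array needs the grid")
        values = np.asarray(field, dtype=float).ravel()
    grid._check_inside(point)
    V = grid.reshape(values)
    idx_lo, frac = [], []
    for d in range(grid.dim):
        lo, hi = grid.extents[d]
        u = (point[d] - lo) / grid.spacing[d]
        i = int(np.floor(u))
        i = min(max(i, 0), grid.node_counts[d] - 2)
        idx_lo.append(i)
        frac.append(u - i)
    result = 0.0
    for corner in range(2 ** grid.dim):
        w, sl = 1.0, []
        for d in range(grid.dim):
            bit = (corner >> d) & 1
            w *= frac[d] if bit else (1 - frac[d])
            sl.append(idx_lo[d] + bit)
        result += w * V[tuple(sl[::-1])]
    return float(result)


def total_content(field, grid: StructuredGrid | None = None) -> float:
    """Control-volume-weighted integral of a density field over the domain.

    Equals the trapezoidal rule on a uniform grid. Units: field units
    times m^3 (mol for mol/m^3, C for C/m^3; per 1 m^2 cross-section in 1-D).
    """
    if isinstance(field, ScalarField):
        grid, values = field.grid, field.values
    else:
        if grid is None:
            raise ValueError("total_content of a bare array needs the grid")
        values = np.asarray(field, dtype=float).ravel()
    return float(np.dot(values, grid.node_volumes()))


# ---------------------------------------------------------------------------
# Export

def export_field_csv(path: str | Path, grid: StructuredGrid, values,
                     name: str = "value") -> None:
    """Write a 1-D field as x,value CSV."""
    if grid.dim != 1:
        raise ValueError("CSV export is for 1-D fields; use VTK in 3-D")
    import pandas as pd

    pd.DataFrame({"x_m": grid.axes[0], name: _as_values(values)}).to_csv(path, index=False)


def export_fields_vtk(path: str | Path, grid: StructuredGrid,
                      fields: Mapping[str, np.ndarray]) -> None:
    """Write 3-D nodal fields as legacy ASCII VTK structured points."""
    if grid.dim != 3:
        raise ValueError("VTK image-data export is for 3-D grids")
    nx, ny, nz = grid.node_counts
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nelectrodiff fields\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {grid.extents[0][0]:.9g} {grid.extents[1][0]:.9g} {grid.extents[2][0]:.9g}\n")
        fh.write(f"SPACING {grid.spacing[0]:.9g} {grid.spacing[1]:.9g} {grid.spacing[2]:.9g}\n")
        fh.write(f"POINT_DATA {grid.n_nodes}\n")
        for name, values in fields.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, _as_values(values), fmt="%.9g")
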