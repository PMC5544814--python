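"""Frequency-domain 2D scattering solves and S-parameter extraction.

The solver works with the out-of-plane magnetic field H_z (TM polarization),
governed by

    div( (1/eps_r) grad H ) + k0^2 H = 0,

with eps_r the complex relative permittivity (eps' - j eps'', e^{+j omega t}
convention).  In this polarization a perfect electric conductor is the
*natural* (Neumann) boundary condition, so the parallel-plate waveguide ports
carry a cutoff-free TEM fundamental mode with propagation constant
beta = k0 sqrt(eps_port) -- the 2D section of a broadband parallel-plate
antenna.  Each port plane carries a first-order modal (Robin) condition

    dH/dn + j beta H = 2 j beta H_inc,

which absorbs the outgoing TEM mode and injects a unit incident wave on the
excited port; the outer truncation circle carries a first-order absorbing
condition with curvature correction.  One sparse LU factorization per
frequency is reused for all port excitations.  S_ij is the TEM modal overlap
(mean of H over the port plane) minus the incident wave; because all ports
are identical the power-wave normalizations cancel and the discrete
formulation is exactly reciprocal (S = S^T up to factorization round-off).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .dielectrics import C0, MaterialSet
from .geometry import REGION_MATERIAL, HeadModelConfig, ScenarioGeometry, ScenarioParams
from .mesh import Mesh, generate_mesh

__all__ = [
    "PortSpec",
    "SParameterSet",
    "solve_frequency",
    "sweep_scenario",
    "mirror_sparams",
    "default_frequency_grid",
    "paper_frequency_grid",
]


class SolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class PortSpec:
    """One parallel-plate waveguide port (TEM fundamental mode)."""

    name: str
    eps_fill: float = 20.0
    width: float = 0.025

    def beta(self, frequency: float) -> float:
        """TEM propagation constant at ``frequency`` (rad/m); no cutoff."""
        return 2.0 * math.pi * frequency / C0 * math.sqrt(self.eps_fill)


def default_frequency_grid(n: int = 16, f_min: float = 0.5e9, f_max: float = 2.5e9) -> np.ndarray:
    """Default simulation grid: 16 points over 0.5-2.5 GHz."""
    return np.linspace(f_min, f_max, n)


def paper_frequency_grid() -> np.ndarray:
    """Measurement-style grid: 0.1-3.0 GHz at 7.25 MHz steps (401 points)."""
    return np.linspace(0.1e9, 3.0e9, 401)


@dataclass
class SParameterSet:
    """N-port complex scattering matrices on a frequency grid for one scenario."""

    frequencies: np.ndarray  # (F,) Hz
    s: np.ndarray  # (F, N, N) complex
    params: ScenarioParams | None = None

    def __post_init__(self) -> None:
        self.frequencies = np.atleast_1d(np.asarray(self.frequencies, dtype=float))
        self.s = np.asarray(self.s, dtype=complex)
        if self.s.ndim != 3 or self.s.shape[0] != len(self.frequencies):
            raise ValueError("s must be (F, N, N) matching frequencies")
        if self.s.shape[1] != self.s.shape[2]:
            raise ValueError("S matrices must be square")

    @property
    def n_ports(self) -> int:
        return self.s.shape[1]

    def reciprocity_error(self) -> float:
        """max |S - S^T| / max |S| over the grid."""
        denom = np.abs(self.s).max()
        if denom == 0:
            return 0.0
        return float(np.abs(self.s - self.s.transpose(0, 2, 1)).max() / denom)

    def passivity_excess(self) -> float:
        """max over frequencies/columns of (sum_i |S_ij|^2) - 1."""
        col_power = (np.abs(self.s) ** 2).sum(axis=1)
        return float(col_power.max() - 1.0)

    def symmetrized(self) -> "SParameterSet":
        return SParameterSet(
            self.frequencies, 0.5 * (self.s + self.s.transpose(0, 2, 1)), self.params
        )

    # Touchstone I/O lives in subwave.touchstone; thin convenience wrappers:
    def write_touchstone(self, path) -> None:
        from .touchstone import write_touchstone

        write_touchstone(path, self.frequencies, self.s)

    @classmethod
    def read_touchstone(cls, path) -> "SParameterSet":
        from .touchstone import read_touchstone

        f, s = read_touchstone(path)
        return cls(f, s)


# --------------------------------------------------------------------------
# assembly
# --------------------------------------------------------------------------

class _FemWorkspace:
    """Per-mesh precomputation reused across frequencies."""

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        p = mesh.nodes[mesh.triangles]
        x, y = p[..., 0], p[..., 1]
        b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
        c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
        area = 0.5 * (b[:, 0] * c[:, 1] - b[:, 1] * c[:, 0])
        self.area = area
        # element stiffness (M, 3, 3): (b_i b_j + c_i c_j) / (4 A)
        self.ke = (
            b[:, :, None] * b[:, None, :] + c[:, :, None] * c[:, None, :]
        ) / (4.0 * area[:, None, None])
        # element mass: A/12 * (1 + delta_ij)
        m0 = (np.ones((3, 3)) + np.eye(3)) / 12.0
        self.me = area[:, None, None] * m0
        tri = mesh.triangles
        self.rows = np.repeat(tri, 3, axis=1).ravel()
        self.cols = np.tile(tri, (1, 3)).ravel()
        self.n = mesh.n_nodes

        # boundary edge precomputation
        self.edge_sets = {}
        for tag, edges in mesh.boundary_edges.items():
            pe = mesh.nodes[edges]
            lengths = np.hypot(
                pe[:, 1, 0] - pe[:, 0, 0], pe[:, 1, 1] - pe[:, 0, 1]
            )
            self.edge_sets[tag] = (edges, lengths)

    def port_tags(self) -> list[str]:
        return sorted(
            (t for t in self.edge_sets if t.startswith("port:")),
            key=lambda t: int(t.split(":")[1]),
        )


def _edge_matrix_coo(edges: np.ndarray, lengths: np.ndarray):
    """COO data for sum_e coeff * L/6 [[2,1],[1,2]] (coeff applied later)."""
    e2 = (np.ones((2, 2)) + np.eye(2)) / 6.0
    data = lengths[:, None, None] * e2
    rows = np.repeat(edges, 2, axis=1).ravel()
    cols = np.tile(edges, (1, 2)).ravel()
    return rows, cols, data.ravel()


def solve_frequency(
    mesh: Mesh,
    materials: MaterialSet,
    ports: list[PortSpec],
    frequency: float,
    _ws: _FemWorkspace | None = None,
    return_fields: bool = False,
):
    """Solve one frequency and return the N x N complex S matrix.

    ``ports[k]`` corresponds to boundary tag ``port:k``.  The system matrix is
    factorized once and reused for the N port excitations.  With
    ``return_fields=True`` also returns the nodal H_z solution, one column per
    excited port.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    ws = _ws if _ws is not None else _FemWorkspace(mesh)
    k0 = 2.0 * math.pi * frequency / C0

    # per-element complex permittivity
    eps_by_region = np.array(
        [
            materials.eps(REGION_MATERIAL[name], frequency)
            for name in mesh.region_names
        ],
        dtype=complex,
    )
    eps_e = eps_by_region[mesh.labels]
    data = (ws.ke * (1.0 / eps_e)[:, None, None] - k0**2 * ws.me).ravel()
    rows_list = [ws.rows]
    cols_list = [ws.cols]
    data_list = [data]

    port_tags = ws.port_tags()
    if len(port_tags) != len(ports):
        raise SolverError(
            f"mesh has {len(port_tags)} port boundaries, {len(ports)} PortSpec given"
        )

    for tag, spec in zip(port_tags, ports):
        edges, lengths = ws.edge_sets[tag]
        beta = spec.beta(frequency)
        r, c, d = _edge_matrix_coo(edges, lengths)
        rows_list.append(r)
        cols_list.append(c)
        data_list.append(1j * beta / spec.eps_fill * d)

    if "absorbing" in ws.edge_sets:
        edges, lengths = ws.edge_sets["absorbing"]
        rb = np.abs(np.hypot(*mesh.nodes[edges[0, 0]])) if len(edges) else 1.0
        gamma = 1j * k0 + 0.5 / rb  # first-order ABC with curvature correction
        r, c, d = _edge_matrix_coo(edges, lengths)
        rows_list.append(r)
        cols_list.append(c)
        data_list.append(gamma * d)

    K = sp.coo_matrix(
        (np.concatenate(data_list), (np.concatenate(rows_list), np.concatenate(cols_list))),
        shape=(ws.n, ws.n),
    ).tocsc()

    try:
        lu = spla.splu(K)
    except RuntimeError as exc:
        raise SolverError(f"singular system at {frequency/1e9:.3f} GHz: {exc}") from exc

    nport = len(ports)
    rhs = np.zeros((ws.n, nport), dtype=complex)
    overlap_vecs = []
    widths = []
    for j, (tag, spec) in enumerate(zip(port_tags, ports)):
        edges, lengths = ws.edge_sets[tag]
        m = np.zeros(ws.n)
        np.add.at(m, edges[:, 0], 0.5 * lengths)
        np.add.at(m, edges[:, 1], 0.5 * lengths)
        overlap_vecs.append(m)
        widths.append(lengths.sum())
        beta = spec.beta(frequency)
        rhs[:, j] = 2j * beta / spec.eps_fill * m

    H = lu.solve(rhs)
    if not np.all(np.isfinite(H)):
        raise SolverError(f"non-finite solution at {frequency/1e9:.3f} GHz")

    S = np.empty((nport, nport), dtype=complex)
    for i in range(nport):
        S[i, :] = overlap_vecs[i] @ H / widths[i]
    S[np.diag_indices(nport)] -= 1.0  # subtract the unit incident wave
    if return_fields:
        return S, H
    return S


#: regions counted as "the head" for power-absorption diagnostics
HEAD_REGIONS = ("skull", "csf", "csf_interior", "brain", "bleeding")


def absorbed_power_fraction(
    mesh: Mesh,
    materials: MaterialSet,
    ports: list[PortSpec],
    frequency: float,
    fields: np.ndarray,
    excite_port: int = 0,
    regions: tuple[str, ...] = HEAD_REGIONS,
) -> float:
    """Fraction of the incident port power dissipated inside ``regions``.

    For the TM (H_z) formulation the dissipation density is
    (Im 1/eps) |grad H|^2 / (2 omega eps0)  (positive: eps = eps' - j eps''),
    and the incident TEM power on a
    unit-amplitude port of width w is w beta / (2 omega eps0 eps_port); the
    common prefactor cancels in the ratio.
    """
    ws = _FemWorkspace(mesh)
    eps_by_region = np.array(
        [materials.eps(REGION_MATERIAL[name], frequency) for name in mesh.region_names],
        dtype=complex,
    )
    eps_e = eps_by_region[mesh.labels]
    sel = np.isin(np.asarray(mesh.region_names, dtype=object)[mesh.labels], regions)
    h = fields[:, excite_port]
    he = h[mesh.triangles[sel]]
    # sum_e (-Im 1/eps_e) * h^H K_e h   (grad-squared integral per element)
    grad2 = np.einsum("eij,ei,ej->e", ws.ke[sel], he.conj(), he).real
    p_diss = float(np.sum(np.imag(1.0 / eps_e[sel]) * grad2))
    spec = ports[excite_port]
    p_inc = spec.width * spec.beta(frequency) / spec.eps_fill
    return p_diss / p_inc


def save_sweeps_hdf5(path, sweeps: list[SParameterSet]) -> None:
    """Bulk store: (scenarios x frequencies x N x N) complex, with scenario
    parameters as JSON attributes.  All sweeps must share the grid."""
    import json

    import h5py

    if not sweeps:
        raise ValueError("no sweeps to store")
    f0 = sweeps[0].frequencies
    for sp in sweeps[1:]:
        if not np.array_equal(sp.frequencies, f0):
            raise ValueError("all sweeps must share the frequency grid")
    with h5py.File(path, "w") as f:
        f.create_dataset("frequencies", data=f0)
        f.create_dataset("s", data=np.stack([sp.s for sp in sweeps]))
        f.attrs["scenario_params"] = json.dumps(
            [sp.params.__dict__ if sp.params is not None else None for sp in sweeps]
        )


def load_sweeps_hdf5(path) -> list[SParameterSet]:
    import json

    import h5py

    from .geometry import ScenarioParams

    with h5py.File(path, "r") as f:
        freqs = f["frequencies"][:]
        s = f["s"][:]
        plist = json.loads(f.attrs["scenario_params"])
    return [
        SParameterSet(freqs, si, params=ScenarioParams(**p) if p else None)
        for si, p in zip(s, plist)
    ]


def ports_from_config(config: HeadModelConfig) -> list[PortSpec]:
    return [
        PortSpec(name=f"port{k+1}", eps_fill=config.port_eps, width=config.aperture_width)
        for k in range(config.n_ports)
    ]


def sweep_scenario(
    geometry: ScenarioGeometry,
    frequencies: np.ndarray,
    materials: MaterialSet | None = None,
    elements_per_wavelength: int = 8,
    mesh: Mesh | None = None,
    reciprocity_tol: float = 1e-6,
    passivity_tol: float = 0.02,
    enforce_reciprocity: bool = True,
) -> SParameterSet:
    """Mesh a scenario once and solve the full frequency grid.

    Reciprocity is verified against ``reciprocity_tol`` and the matrices are
    then symmetrized; passivity is verified against ``passivity_tol``.
    """
    freqs = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if freqs.size == 0:
        raise ValueError("empty frequency grid")
    ms = materials if materials is not None else MaterialSet()
    if mesh is None:
        mesh = generate_mesh(
            geometry, float(freqs.max()), elements_per_wavelength, materials=ms
        )
    ws = _FemWorkspace(mesh)
    ports = ports_from_config(geometry.config)
    out = np.empty((len(freqs), len(ports), len(ports)), dtype=complex)
    for idx, f in enumerate(freqs):
        try:
            out[idx] = solve_frequency(mesh, ms, ports, float(f), _ws=ws)
        except SolverError as exc:
            raise SolverError(f"frequency index {idx}: {exc}") from exc
    sps = SParameterSet(freqs, out, params=geometry.params)
    rec = sps.reciprocity_error()
    if rec > reciprocity_tol:
        raise SolverError(f"reciprocity violated: {rec:.3e} > {reciprocity_tol:.1e}")
    if enforce_reciprocity:
        sps = sps.symmetrized()
    exc_p = sps.passivity_excess()
    if exc_p > passivity_tol:
        raise SolverError(f"passivity violated: column power 1 + {exc_p:.3e}")
    return sps


def mirror_sparams(
    sps: SParameterSet, port_reflection_permutation: np.ndarray | None = None
) -> SParameterSet:
    """S-parameters of the mirrored scenario: S' = P S P^T per frequency.

    ``port_reflection_permutation`` must be an involution consistent with the
    port layout symmetry (default: the 8-port ring mirrored about the y-axis).
    The scenario reference, if present, flips side and negates the rotation.
    """
    if port_reflection_permutation is None:
        port_reflection_permutation = HeadModelConfig().mirror_permutation()
    perm = np.asarray(port_reflection_permutation, dtype=int)
    if perm.shape != (sps.n_ports,) or not np.array_equal(
        perm[perm], np.arange(sps.n_ports)
    ):
        raise ValueError("permutation must be an involution on the port set")
    s_new = sps.s[:, perm][:, :, perm]
    params = sps.params
    if params is not None:
        params = dc_replace(
            params,
            side="left" if params.side == "right" else "right",
            rotation_deg=-params.rotation_deg,
        )
    return SParameterSet(sps.frequencies, s_new, params=params)
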