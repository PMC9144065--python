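"""Small-strain isotropic linear-elastic FE solver on voxel meshes.

One 8-node hexahedron per in-body voxel, trilinear shape functions,
2x2x2 Gauss quadrature for the stiffness, centroid (mean-quadrature)
strain/stress recovery.  Units are consistent N / mm / MPa.

All voxels share the same geometry, so the element stiffness factors as
``K_e = E_e * K0(nu_e)`` and assembly reduces to scaling a precomputed
per-element block by the Young's modulus — which is what makes the
progressive element-kill loop cheap: killing elements only rescales data
in an otherwise frozen sparsity pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import cg, splu

from .calibration import MaterialField
from .regions import OUTSIDE, SCREW
from .volume import HUVolume

#: Local node offsets of a voxel hexahedron (standard VTK ordering).
HEX_OFFSETS = np.array(
    [
        [0, 0, 0],
        [1, 0, 0],
        [1, 1, 0],
        [0, 1, 0],
        [0, 0, 1],
        [1, 0, 1],
        [1, 1, 1],
        [0, 1, 1],
    ],
    dtype=np.int64,
)

#: Relative solver residual above which a solve is flagged non-converged.
RESIDUAL_TOL = 1e-8


class NonConvergenceError(RuntimeError):
    """Structured signal: the linear solve did not produce a valid state."""


def isotropic_D(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic elasticity matrix, Voigt order (xx,yy,zz,yz,xz,xy),
    engineering shear strains."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] = lam + 2 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu
    return D


def _shape_gradients(xi: np.ndarray, spacing) -> np.ndarray:
    """Physical shape-function gradients (8, 3) at natural point xi."""
    signs = 2.0 * HEX_OFFSETS - 1.0  # (8,3) of +-1
    grads = np.empty((8, 3))
    for i in range(8):
        s = signs[i]
        grads[i, 0] = s[0] * (1 + s[1] * xi[1]) * (1 + s[2] * xi[2]) / 8.0
        grads[i, 1] = s[1] * (1 + s[0] * xi[0]) * (1 + s[2] * xi[2]) / 8.0
        grads[i, 2] = s[2] * (1 + s[0] * xi[0]) * (1 + s[1] * xi[1]) / 8.0
    return grads * (2.0 / np.asarray(spacing))


def _b_matrix(grads: np.ndarray) -> np.ndarray:
    """Strain-displacement matrix (6, 24) from shape gradients."""
    B = np.zeros((6, 24))
    for i in range(8):
        gx, gy, gz = grads[i]
        c = 3 * i
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c + 1] = gz
        B[3, c + 2] = gy
        B[4, c] = gz
        B[4, c + 2] = gx
        B[5, c] = gy
        B[5, c + 1] = gx
    return B


def hex8_stiffness(D: np.ndarray, spacing) -> np.ndarray:
    """24x24 element stiffness for a voxel of the given spacing (mm)."""
    hx, hy, hz = spacing
    detJ = hx * hy * hz / 8.0
    g = 1.0 / np.sqrt(3.0)
    K = np.zeros((24, 24))
    for sx in (-g, g):
        for sy in (-g, g):
            for sz in (-g, g):
                B = _b_matrix(_shape_gradients(np.array([sx, sy, sz]), spacing))
                K += B.T @ D @ B * detJ
    return K


def hex8_centroid_B(spacing) -> np.ndarray:
    return _b_matrix(_shape_gradients(np.zeros(3), spacing))


@dataclass
class LoadCase:
    """A compressive resultant with an optional superimposed moment.

    The total compressive force is split ``body_fraction`` to the vertebra
    (of which ``facet_fraction_of_body`` goes to the facet-analogue set and
    the rest to the superior end plate) and the remainder to the screws.
    When the mesh carries no screw set, the whole load goes to the body.
    The moment (N*mm, about ``moment_axis`` through the end-plate centroid)
    is realised as a statically equivalent linearly varying nodal traction
    over the superior end plate and is held constant while the compressive
    force ramps.
    """

    name: str = "EXT"
    direction: tuple[float, float, float] = (0.0, 0.0, -1.0)
    moment_nmm: float = 4700.0
    moment_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    body_fraction: float = 0.8
    facet_fraction_of_body: float = 0.3

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        self.direction = tuple(d / np.linalg.norm(d))
        if not 0.0 < self.body_fraction <= 1.0:
            raise ValueError("body_fraction must be in (0, 1]")
        if not 0.0 <= self.facet_fraction_of_body < 1.0:
            raise ValueError("facet_fraction_of_body must be in [0, 1)")

    def nodal_forces(
        self, model: "FEModel", force_magnitude: float, include_moment: bool = True
    ) -> np.ndarray:
        """Global force vector (3*nn,) for the given compressive magnitude."""
        nn = len(model.nodes)
        f = np.zeros(3 * nn)
        d = np.asarray(self.direction)

        screws = model.node_sets.get("screw_head", np.array([], dtype=int))
        body_share = self.body_fraction if len(screws) else 1.0
        facet = model.node_sets.get("facet", np.array([], dtype=int))
        facet_share = body_share * (
            self.facet_fraction_of_body if len(facet) else 0.0
        )
        plate_share = body_share - facet_share

        def spread(nodes, weights, magnitude):
            if magnitude == 0.0 or len(nodes) == 0:
                return
            w = weights / weights.sum()
            f.reshape(-1, 3)[nodes] += magnitude * w[:, None] * d

        top = model.node_sets["top"]
        spread(top, model.set_weights["top"], plate_share * force_magnitude)
        if len(facet):
            spread(
                facet, model.set_weights["facet"], facet_share * force_magnitude
            )
        if len(screws):
            spread(
                screws,
                np.ones(len(screws)),
                (1.0 - body_share) * force_magnitude,
            )

        if include_moment and self.moment_nmm != 0.0:
            m_hat = np.asarray(self.moment_axis, dtype=float)
            m_hat = m_hat / np.linalg.norm(m_hat)
            w = model.set_weights["top"]
            r = model.nodes[top]
            centroid = (w[:, None] * r).sum(axis=0) / w.sum()
            rho = r - centroid
            # lever of a force along `d` about axis m_hat: (rho x d) . m_hat
            lever = np.cross(rho, d) @ m_hat
            denom = float(np.sum(w * lever**2))
            if denom <= 0:
                raise ValueError(
                    "end-plate set cannot carry a moment about this axis"
                )
            c = self.moment_nmm / denom
            f.reshape(-1, 3)[top] += (c * w * lever)[:, None] * d
        return f


#: Standard load cases: extension bends about the mediolateral (x) axis,
#: left lateral bending about the anteroposterior (y) axis.
def extension_load(moment_nmm: float = 4700.0, **kw) -> LoadCase:
    return LoadCase(name="EXT", moment_axis=(1.0, 0.0, 0.0), moment_nmm=moment_nmm, **kw)


def lateral_bending_load(moment_nmm: float = 4700.0, **kw) -> LoadCase:
    return LoadCase(name="LLB", moment_axis=(0.0, 1.0, 0.0), moment_nmm=moment_nmm, **kw)


@dataclass
class FEModel:
    """Voxel mesh with materials, constraint set and named load sets."""

    nodes: np.ndarray  # (nn, 3) mm
    conn: np.ndarray  # (ne, 8) node ids
    material: MaterialField
    spacing: tuple[float, float, float]
    dirichlet_dofs: np.ndarray  # global dof ids with prescribed zero value
    node_sets: dict
    set_weights: dict  # tributary face areas aligned with node_sets
    load_case: LoadCase | None = None
    voxel_ijk: np.ndarray | None = None
    _cache: dict = dc_field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if len(self.dirichlet_dofs) == 0:
            raise ValueError("dirichlet set must be non-empty")
        if self.material.n_elements != len(self.conn):
            raise ValueError("material field not aligned with elements")

    @property
    def n_dofs(self) -> int:
        return 3 * len(self.nodes)

    def _ensure_cache(self) -> None:
        if "dofs" in self._cache:
            return
        conn = self.conn
        dofs = (3 * conn[:, :, None] + np.arange(3)).reshape(len(conn), 24)
        self._cache["dofs"] = dofs
        self._cache["rows"] = np.repeat(dofs, 24, axis=1).ravel()
        self._cache["cols"] = np.tile(dofs, (1, 24)).ravel()
        # unit-modulus element stiffness per element (depends on nu only)
        nus = self.material.nu
        base = np.empty((len(conn), 24, 24))
        for nu in np.unique(nus):
            K0 = hex8_stiffness(isotropic_D(1.0, float(nu)), self.spacing)
            base[nus == nu] = K0
        self._cache["base"] = base
        self._cache["B0"] = hex8_centroid_B(self.spacing)
        free = np.ones(self.n_dofs, dtype=bool)
        free[self.dirichlet_dofs] = False
        self._cache["free"] = free

    def assemble(self) -> sp.csr_matrix:
        """Global stiffness (full, unconstrained) for the current E field."""
        self._ensure_cache()
        data = self._cache["base"] * self.material.E[:, None, None]
        K = sp.coo_matrix(
            (data.ravel(), (self._cache["rows"], self._cache["cols"])),
            shape=(self.n_dofs, self.n_dofs),
        )
        return K.tocsr()


@dataclass
class SolutionFields:
    """Displacements plus centroid strain/stress recovery."""

    displacement: np.ndarray  # (nn, 3) mm
    strain: np.ndarray  # (ne, 6) Voigt, engineering shear
    stress: np.ndarray  # (ne, 6) MPa
    principal_strains: np.ndarray  # (ne, 3) descending
    principal_stresses: np.ndarray  # (ne, 3) MPa descending
    internal_force: np.ndarray  # (nn, 3) N, K @ u
    residual: float
    load_magnitude: float


def _voigt_principal(voigt: np.ndarray, shear_factor: float) -> np.ndarray:
    """Principal values (descending) of symmetric tensors in Voigt form."""
    n = len(voigt)
    T = np.empty((n, 3, 3))
    T[:, 0, 0] = voigt[:, 0]
    T[:, 1, 1] = voigt[:, 1]
    T[:, 2, 2] = voigt[:, 2]
    T[:, 1, 2] = T[:, 2, 1] = shear_factor * voigt[:, 3]
    T[:, 0, 2] = T[:, 2, 0] = shear_factor * voigt[:, 4]
    T[:, 0, 1] = T[:, 1, 0] = shear_factor * voigt[:, 5]
    return np.linalg.eigvalsh(T)[:, ::-1]


def _solve_spd(
    K_ff: sp.csc_matrix,
    f_f: np.ndarray,
    solver: str,
    x0: np.ndarray | None,
) -> tuple[np.ndarray, float]:
    """Solve the reduced SPD system; returns (u, relative residual).

    ``solver="auto"`` tries Jacobi-preconditioned CG first (voxel systems
    are SPD and diagonally scalable even with killed elements) and falls
    back to a direct sparse LU factorisation when CG does not reach the
    residual tolerance.
    """
    f_norm = np.linalg.norm(f_f)
    if f_norm == 0.0:
        return np.zeros_like(f_f), 0.0

    def rel_res(u):
        return float(np.linalg.norm(K_ff @ u - f_f) / f_norm)

    if solver in ("auto", "cg"):
        M = sp.diags(1.0 / K_ff.diagonal())
        u, _ = cg(K_ff, f_f, rtol=1e-13, atol=0.0, maxiter=20_000, M=M, x0=x0)
        if np.all(np.isfinite(u)):
            res = rel_res(u)
            if res <= RESIDUAL_TOL:
                return u, res
        if solver == "cg":
            raise NonConvergenceError("CG did not reach the residual tolerance")
    try:
        u = splu(K_ff, permc_spec="COLAMD").solve(f_f)
    except Exception as exc:  # singular factorisation
        raise NonConvergenceError(f"sparse factorisation failed: {exc}") from exc
    if not np.all(np.isfinite(u)):
        raise NonConvergenceError("non-finite displacement (singular system)")
    return u, rel_res(u)


def solve_elastic(
    model: FEModel,
    load_magnitude: float = 0.0,
    external_force: np.ndarray | None = None,
    solver: str = "auto",
    x0: np.ndarray | None = None,
) -> SolutionFields:
    """Solve K u = f on the Dirichlet-reduced system and recover fields.

    ``x0`` (full dof vector) seeds the iterative solver — the damage loop
    warm-starts each re-solve from the previous displacement state.
    Raises :class:`NonConvergenceError` when the solve fails or the
    relative residual exceeds 1e-8 — the signal the progressive-damage
    loop interprets as loss of load-carrying capacity.
    """
    model._ensure_cache()
    if external_force is None:
        if model.load_case is None:
            raise ValueError("model has no load case and no external force")
        f = model.load_case.nodal_forces(model, load_magnitude)
    else:
        f = np.asarray(external_force, dtype=float).ravel()
    K = model.assemble()
    free = model._cache["free"]
    K_ff = K[free][:, free].tocsc()
    f_f = f[free]
    u_f, res = _solve_spd(
        K_ff, f_f, solver, None if x0 is None else np.asarray(x0).ravel()[free]
    )
    if np.linalg.norm(f_f) > 0 and res > RESIDUAL_TOL:
        raise NonConvergenceError(f"relative residual {res:.2e} > {RESIDUAL_TOL}")

    u = np.zeros(model.n_dofs)
    u[free] = u_f
    dofs = model._cache["dofs"]
    B0 = model._cache["B0"]
    strain = u[dofs] @ B0.T  # (ne, 6)

    E, nu = model.material.E, model.material.nu
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    tr = strain[:, :3].sum(axis=1)
    stress = np.empty_like(strain)
    stress[:, :3] = lam[:, None] * tr[:, None] + 2 * mu[:, None] * strain[:, :3]
    stress[:, 3:] = mu[:, None] * strain[:, 3:]

    return SolutionFields(
        displacement=u.reshape(-1, 3),
        strain=strain,
        stress=stress,
        principal_strains=_voigt_principal(strain, 0.5),
        principal_stresses=_voigt_principal(stress, 1.0),
        internal_force=(K @ u).reshape(-1, 3),
        residual=float(res),
        load_magnitude=float(load_magnitude),
    )


def reaction_and_displacement(
    model: FEModel, solution: SolutionFields
) -> tuple[float, float]:
    """Reaction resultant (N) and mean displacement (mm) at the top plate.

    The reaction is the internal nodal forces summed over the superior
    end-plate set along the loading direction; the displacement is the
    magnitude of the mean top-plate displacement component along that
    direction.
    """
    top = model.node_sets.get("top")
    if top is None or len(top) == 0:
        raise ValueError("model has no superior end-plate node set")
    d = (
        np.asarray(model.load_case.direction)
        if model.load_case is not None
        else np.array([0.0, 0.0, -1.0])
    )
    f_r = float(np.sum(solution.internal_force[top] @ d))
    u_top = float(abs(np.mean(solution.displacement[top] @ d)))
    return f_r, u_top


def mesh_from_volume(
    volume: HUVolume,
    material: MaterialField,
    load_case: LoadCase | None = None,
    facet_band_fraction: float = 0.25,
) -> FEModel:
    """Build a hex8 voxel mesh over in-body voxels.

    Node/face sets are derived from labels and geometry: ``top`` /
    ``bottom`` are the nodes of exposed superior/inferior faces (with
    tributary-area weights), ``facet`` is the posterior
    ``facet_band_fraction`` band of the top set (articular-facet
    analogue), ``screw`` the nodes of screw elements and ``screw_head``
    their posterior end.  The inferior end plate is fully constrained.
    """
    labels = volume.labels
    mask = labels != OUTSIDE
    if not np.any(mask):
        raise ValueError("volume has no in-body voxels")
    nx, ny, nz = labels.shape
    order = volume.element_order()
    if material.n_elements != len(order):
        raise ValueError("material field not aligned with volume elements")
    ijk = np.stack(np.unravel_index(order, labels.shape), axis=1)  # (ne, 3)

    node_grid_ids = (
        (ijk[:, None, 0] + HEX_OFFSETS[None, :, 0]) * (ny + 1)
        + (ijk[:, None, 1] + HEX_OFFSETS[None, :, 1])
    ) * (nz + 1) + (ijk[:, None, 2] + HEX_OFFSETS[None, :, 2])
    used, conn = np.unique(node_grid_ids, return_inverse=True)
    conn = conn.reshape(node_grid_ids.shape).astype(np.int64)

    gi, rem = np.divmod(used, (ny + 1) * (nz + 1))
    gj, gk = np.divmod(rem, nz + 1)
    spacing = np.asarray(volume.spacing)
    nodes = np.asarray(volume.origin) + np.stack([gi, gj, gk], axis=1) * spacing

    # exposed top/bottom faces: no in-body voxel above/below
    def exposed(dz: int) -> np.ndarray:
        k_nb = ijk[:, 2] + dz
        inside = (k_nb >= 0) & (k_nb < nz)
        nb = np.zeros(len(ijk), dtype=bool)
        nb[inside] = mask[ijk[inside, 0], ijk[inside, 1], k_nb[inside]]
        return ~nb

    face_local = {+1: [4, 5, 6, 7], -1: [0, 1, 2, 3]}
    area = spacing[0] * spacing[1]
    sets: dict = {}
    weights: dict = {}
    for dz, name in ((+1, "top"), (-1, "bottom")):
        els = np.flatnonzero(exposed(dz))
        face_nodes = conn[np.ix_(els, face_local[dz])].ravel()
        uniq, inv = np.unique(face_nodes, return_inverse=True)
        w = np.bincount(inv, minlength=len(uniq)) * area / 4.0
        sets[name] = uniq
        weights[name] = w

    regions = material.region
    screw_els = np.flatnonzero(regions == SCREW)
    screw_nodes = np.unique(conn[screw_els]) if len(screw_els) else np.array([], dtype=int)
    sets["screw"] = screw_nodes
    if len(screw_nodes):
        y = nodes[screw_nodes, 1]
        head = screw_nodes[y <= y.min() + spacing[1]]
        sets["screw_head"] = head
        weights["screw_head"] = np.ones(len(head))
    else:
        sets["screw_head"] = np.array([], dtype=int)

    top = sets["top"]
    y_top = nodes[top, 1]
    band = y_top <= y_top.min() + facet_band_fraction * np.ptp(y_top)
    # the facet analogue only makes sense when it is a strict sub-region
    if 0 < band.sum() < len(top):
        sets["facet"] = top[band]
        weights["facet"] = weights["top"][band]
    else:
        sets["facet"] = np.array([], dtype=int)

    dirichlet = (3 * sets["bottom"][:, None] + np.arange(3)).ravel()

    return FEModel(
        nodes=nodes,
        conn=conn,
        material=material,
        spacing=tuple(float(s) for s in volume.spacing),
        dirichlet_dofs=dirichlet,
        node_sets=sets,
        set_weights=weights,
        load_case=load_case,
        voxel_ijk=ijk,
    )
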