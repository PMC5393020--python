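"""Quasistatic equilibrium of rigid bodies connected by elastic elements.

The mechanical system is a set of rigid bodies, each carrying six generalized
coordinates (three translations in mm, three rotations), connected by

* *cables* -- straight-line springs between two attachment points.  By default
  they are tension-only (zero force at or below the rest length), the standard
  idealization of spinal ligaments; a ``bilateral`` flag turns them into
  ordinary two-sided springs (used for screw-rod connectors).
* *six-dimensional springs* -- a diagonal stiffness acting on the relative
  translation and relative rotation of two attachment frames.  Intervertebral
  discs, facet capsules and rod beam segments are all expressed this way.

Equilibrium is found by incremental load stepping with a modified
Newton-Raphson iteration: the residual (generalized force imbalance) is
evaluated exactly from the nonlinear element laws, while the tangent is
assembled from analytic per-element stiffness blocks (material + geometric
for cables, frame-projected diagonal blocks for 6-D springs).  Rotations are
parametrized per body as rotation vectors re-linearized at every iteration,
which is robust for the sub-90-degree rotations occurring in spine mechanics.

Units: mm, N, N·mm; rotations are radians internally and degrees at the API
surface.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "System",
    "State",
    "Configuration",
    "StepRecord",
    "SolverOptions",
    "ConvergenceError",
    "residual",
    "assemble_tangent",
    "elastic_energy",
    "solve_equilibrium",
]

#: default convergence tolerances (spec'd as config constants)
FORCE_TOL_N = 0.5
TORQUE_TOL_NMM = 50.0

_EPS_LEN = 1e-12

#: width (mm) of the C1 blend zone of the tension-only cable law just above
#: the rest length.  The force is exactly 0 at and below the rest length and
#: exactly linear beyond the zone; the deviation from the ideal kinked law
#: is at most k*delta/2 < the force tolerance, and the smoothing removes the
#: semismooth stall of Newton iterations when many cables sit at the kink.
CABLE_SMOOTHING_MM = 0.1


def _cable_law(ext, k, bilateral):
    """Smoothed tension-only force and its derivative.

    f = 0 for ext <= 0; quadratic blend on (0, delta); k*(ext - delta/2)
    beyond.  Bilateral cables (screw-rod connectors) stay exactly linear.
    """
    d = CABLE_SMOOTHING_MM
    f_lin = k * ext
    f_blend = k * ext**2 / (2.0 * d)
    f_upper = k * (ext - 0.5 * d)
    f = np.where(ext <= 0.0, 0.0,
                 np.where(ext < d, f_blend, f_upper))
    fp = np.where(ext <= 0.0, 0.0,
                  np.where(ext < d, k * ext / d, k))
    f = np.where(bilateral, f_lin, f)
    fp = np.where(bilateral, k, fp)
    return f, fp


def _cable_energy_density(ext, k, bilateral):
    d = CABLE_SMOOTHING_MM
    e_blend = k * ext**3 / (6.0 * d)
    e_upper = 0.5 * k * (ext - 0.5 * d)**2 + k * d**2 / 24.0
    e = np.where(ext <= 0.0, 0.0,
                 np.where(ext < d, e_blend, e_upper))
    return np.where(bilateral, 0.5 * k * ext**2, e)


class ConvergenceError(RuntimeError):
    """Raised when Newton iteration fails after the maximum step halvings."""

    def __init__(self, msg, last_residual=None, state=None):
        super().__init__(msg)
        self.last_residual = last_residual
        self.state = state


def _skew(v):
    """Batched skew-symmetric matrices, v: (..., 3) -> (..., 3, 3)."""
    out = np.zeros(v.shape[:-1] + (3, 3))
    out[..., 0, 1] = -v[..., 2]
    out[..., 0, 2] = v[..., 1]
    out[..., 1, 0] = v[..., 2]
    out[..., 1, 2] = -v[..., 0]
    out[..., 2, 0] = -v[..., 1]
    out[..., 2, 1] = v[..., 0]
    return out


@dataclass
class System:
    """Arrays describing bodies and elements; built once, cheap to evaluate.

    Attachment offsets are stored in the *initial world frame* of each body
    (bodies are assembled with identity orientation, so local = world at
    assembly); the current world attachment point of body ``i`` with offset
    ``a`` is ``x0[i] + u[i] + R[i] @ a``.
    """

    x0: np.ndarray                      # (n, 3) initial reference positions
    fixed: np.ndarray                   # (n, 6) bool, fixed DOFs
    # cables
    cab_bodies: np.ndarray = None       # (m, 2) int
    cab_off: np.ndarray = None          # (m, 2, 3)
    cab_k: np.ndarray = None            # (m,) N/mm
    cab_L0: np.ndarray = None           # (m,) mm
    cab_bilateral: np.ndarray = None    # (m,) bool
    # 6-D springs
    spr_bodies: np.ndarray = None       # (s, 2) int
    spr_off: np.ndarray = None          # (s, 2, 3)
    spr_E0: np.ndarray = None           # (s, 3, 3) element frame at assembly
    spr_Kt: np.ndarray = None           # (s, 3) N/mm, element-frame diagonal
    spr_Kr: np.ndarray = None           # (s, 3) N·mm/rad diagonal
    spr_dt0: np.ndarray = None          # (s, 3) rest relative translation
    spr_dr0: np.ndarray = None          # (s, 3) rest relative rotation (rad)

    def __post_init__(self):
        n = self.x0.shape[0]
        if self.cab_bodies is None:
            self.cab_bodies = np.zeros((0, 2), dtype=int)
            self.cab_off = np.zeros((0, 2, 3))
            self.cab_k = np.zeros(0)
            self.cab_L0 = np.zeros(0)
        if self.cab_bilateral is None:
            self.cab_bilateral = np.zeros(len(self.cab_k), dtype=bool)
        if self.spr_bodies is None:
            self.spr_bodies = np.zeros((0, 2), dtype=int)
            self.spr_off = np.zeros((0, 2, 3))
            self.spr_E0 = np.zeros((0, 3, 3))
            self.spr_Kt = np.zeros((0, 3))
            self.spr_Kr = np.zeros((0, 3))
            self.spr_dt0 = np.zeros((0, 3))
        if self.spr_dr0 is None:
            self.spr_dr0 = np.zeros((len(self.spr_Kt), 3))
        assert self.fixed.shape == (n, 6)

    @property
    def n_bodies(self):
        return self.x0.shape[0]

    @property
    def free_mask(self):
        return ~self.fixed.reshape(-1)


@dataclass
class State:
    """Current configuration: translations and rotation matrices per body."""

    u: np.ndarray        # (n, 3) mm
    R: np.ndarray        # (n, 3, 3)

    @classmethod
    def rest(cls, system: System) -> "State":
        n = system.n_bodies
        return cls(np.zeros((n, 3)), np.tile(np.eye(3), (n, 1, 1)))

    def copy(self):
        return State(self.u.copy(), self.R.copy())

    def body_positions(self, system: System):
        return system.x0 + self.u


@dataclass
class StepRecord:
    step: int
    load_factor: float
    iterations: int
    max_force_residual: float
    max_torque_residual: float
    converged: bool


@dataclass
class Configuration:
    """Solved generalized coordinates relative to the initial geometry."""

    u: np.ndarray                 # (n, 3) mm
    rotvec_deg: np.ndarray        # (n, 3) rotation-vector parameters, deg
    records: list = field(default_factory=list)
    converged: bool = True

    @property
    def n_bodies(self):
        return self.u.shape[0]

    def to_state(self) -> State:
        return State(self.u.copy(),
                     Rotation.from_rotvec(self.rotvec_deg, degrees=True).as_matrix())

    @classmethod
    def from_state(cls, state: State, records=None, converged=True):
        rv = Rotation.from_matrix(state.R).as_rotvec(degrees=True)
        return cls(state.u.copy(), rv, records or [], converged)


@dataclass
class SolverOptions:
    force_tol: float = FORCE_TOL_N
    torque_tol: float = TORQUE_TOL_NMM
    max_iter: int = 40
    max_halvings: int = 8
    regularization: float = 1e-8


# ---------------------------------------------------------------------------
# element kinematics / forces


def _cable_geometry(system: System, state: State):
    bi = system.cab_bodies
    xa = system.x0[bi[:, 0]] + state.u[bi[:, 0]]
    xb = system.x0[bi[:, 1]] + state.u[bi[:, 1]]
    pa = xa + np.einsum("mij,mj->mi", state.R[bi[:, 0]], system.cab_off[:, 0])
    pb = xb + np.einsum("mij,mj->mi", state.R[bi[:, 1]], system.cab_off[:, 1])
    d = pb - pa
    L = np.linalg.norm(d, axis=1)
    n = d / np.maximum(L, _EPS_LEN)[:, None]
    return xa, xb, pa, pb, L, n


def cable_tensions(system: System, state: State):
    """Scalar cable forces (N); tension positive, slack cables exactly 0."""
    if len(system.cab_k) == 0:
        return np.zeros(0)
    *_, L, _ = _cable_geometry(system, state)
    f, _ = _cable_law(L - system.cab_L0, system.cab_k, system.cab_bilateral)
    return f


def _spring_geometry(system: System, state: State):
    bi = system.spr_bodies
    Ra = state.R[bi[:, 0]]
    Rb = state.R[bi[:, 1]]
    xa = system.x0[bi[:, 0]] + state.u[bi[:, 0]]
    xb = system.x0[bi[:, 1]] + state.u[bi[:, 1]]
    pa = xa + np.einsum("mij,mj->mi", Ra, system.spr_off[:, 0])
    pb = xb + np.einsum("mij,mj->mi", Rb, system.spr_off[:, 1])
    EA = np.einsum("mij,mjk->mik", Ra, system.spr_E0)
    EB = np.einsum("mij,mjk->mik", Rb, system.spr_E0)
    return xa, xb, pa, pb, EA, EB


def spring_deflections(system: System, state: State):
    """Relative translation (element frame, mm) and rotation (rad) per spring."""
    s = len(system.spr_Kt)
    if s == 0:
        return np.zeros((0, 3)), np.zeros((0, 3))
    xa, xb, pa, pb, EA, EB = _spring_geometry(system, state)
    dt = np.einsum("mji,mj->mi", EA, pb - pa) - system.spr_dt0
    Rrel = np.einsum("mji,mjk->mik", EA, EB)
    dr = Rotation.from_matrix(Rrel).as_rotvec() - system.spr_dr0
    return dt, dr


def _jr_inv_T(dr):
    """Transposed inverse right Jacobian of the rotation vector, batched.

    Maps K_r*dr to the conjugate moment of a rotation-vector spring; valid
    for |dr| < pi (this application stays well under 90 deg)."""
    th = np.linalg.norm(dr, axis=1)
    S = _skew(dr)
    S2 = np.einsum("mij,mjk->mik", S, S)
    small = th < 1e-8
    ths = np.where(small, 1.0, th)
    c = np.where(small, 1.0 / 12.0,
                 1.0 / ths**2 - (1.0 + np.cos(ths))
                 / (2.0 * ths * np.sin(ths)))
    J = np.eye(3)[None] + 0.5 * S + c[:, None, None] * S2
    return np.transpose(J, (0, 2, 1))


def residual(system: System, state, loads=None, load_factor=1.0):
    """Generalized force residual per body DOF, (n, 6).

    Sum of element generalized forces plus external loads; zero at
    equilibrium.  Torques are taken about each body's current reference
    point.  ``state`` may be a :class:`State` or a :class:`Configuration`.
    """
    if isinstance(state, Configuration):
        state = state.to_state()
    n = system.n_bodies
    res = np.zeros((n, 6))

    if len(system.cab_k):
        xa, xb, pa, pb, L, nv = _cable_geometry(system, state)
        f, _ = _cable_law(L - system.cab_L0, system.cab_k,
                          system.cab_bilateral)
        F = f[:, None] * nv                        # force on A, toward B
        ia, ib = system.cab_bodies[:, 0], system.cab_bodies[:, 1]
        np.add.at(res, ia, np.concatenate([F, np.cross(pa - xa, F)], axis=1))
        np.add.at(res, ib, np.concatenate([-F, np.cross(pb - xb, -F)], axis=1))

    if len(system.spr_Kt):
        xa, xb, pa, pb, EA, EB = _spring_geometry(system, state)
        dt = np.einsum("mji,mj->mi", EA, pb - pa) - system.spr_dt0
        Rrel = np.einsum("mji,mjk->mik", EA, EB)
        dr = Rotation.from_matrix(Rrel).as_rotvec()
        # variationally exact (conservative) generalized forces: the force
        # pair +/-F acts at B's attachment point and the rotational couple
        # carries the inverse-right-Jacobian of the rotation vector; the
        # residual is exactly -grad of the elastic energy, and the element
        # transmits no net wrench (exact action/reaction)
        F = np.einsum("mij,mj->mi", EA, system.spr_Kt * dt)
        Mb = -np.einsum("mij,mjk,mk->mi", EB, _jr_inv_T(dr),
                        system.spr_Kr * (dr - system.spr_dr0))
        ia, ib = system.spr_bodies[:, 0], system.spr_bodies[:, 1]
        np.add.at(res, ia, np.concatenate(
            [F, np.cross(pb - xa, F) - Mb], axis=1))
        np.add.at(res, ib, np.concatenate(
            [-F, np.cross(pb - xb, -F) + Mb], axis=1))

    if loads is not None:
        res = res + load_factor * loads
    return res


def elastic_energy(system: System, state: State) -> float:
    """Total elastic strain energy (N·mm) of all elements."""
    e = 0.0
    if len(system.cab_k):
        *_, L, _ = _cable_geometry(system, state)
        e += float(np.sum(_cable_energy_density(
            L - system.cab_L0, system.cab_k, system.cab_bilateral)))
    if len(system.spr_Kt):
        dt, dr = spring_deflections(system, state)
        e += 0.5 * np.sum(system.spr_Kt * dt**2)
        e += 0.5 * np.sum(system.spr_Kr * dr**2)
    return float(e)


def assemble_tangent(system: System, state: State):
    """Approximate (symmetric) tangent stiffness, dense (6n, 6n)."""
    n = system.n_bodies
    K = np.zeros((6 * n, 6 * n))

    if len(system.cab_k):
        xa, xb, pa, pb, L, nv = _cable_geometry(system, state)
        f, km = _cable_law(L - system.cab_L0, system.cab_k,
                           system.cab_bilateral)
        Ls = np.maximum(L, 1e-6)
        nnT = np.einsum("mi,mj->mij", nv, nv)
        Kpp = km[:, None, None] * nnT + (f / Ls)[:, None, None] * (np.eye(3) - nnT)
        _scatter_point_stiffness(K, system.cab_bodies, pa - xa, pb - xb, Kpp)
        _scatter_lever_geometric(K, system.cab_bodies, pa - xa, pb - xb,
                                 f[:, None] * nv)

    if len(system.spr_Kt):
        xa, xb, pa, pb, EA, EB = _spring_geometry(system, state)
        dt = np.einsum("mji,mj->mi", EA, pb - pa) - system.spr_dt0
        F = np.einsum("mij,mj->mi", EA, system.spr_Kt * dt)
        Kt_w = np.einsum("mij,mj,mkj->mik", EA, system.spr_Kt, EA)
        _scatter_point_stiffness(K, system.spr_bodies, pb - xa, pb - xb, Kt_w)
        _scatter_lever_geometric(K, system.spr_bodies, pb - xa, pb - xb, F)
        Kr_w = np.einsum("mij,mj,mkj->mik", EA, system.spr_Kr, EA)
        _scatter_rotational_stiffness(K, system.spr_bodies, Kr_w)

    return K


def _dof_indices(bodies):
    """(m, 12) global DOF indices for body pairs."""
    base = bodies * 6
    offs = np.arange(6)
    return np.concatenate(
        [base[:, 0:1] + offs[None, :], base[:, 1:2] + offs[None, :]], axis=1
    )


def _scatter_point_stiffness(K, bodies, ra, rb, Kpp):
    """Point-coupling stiffness Kpp between levers ra (on A) and rb (on B)."""
    m = len(Kpp)
    G = np.zeros((m, 3, 12))
    I3 = np.eye(3)
    G[:, :, 0:3] = I3
    G[:, :, 3:6] = -_skew(ra)
    G[:, :, 6:9] = -I3
    G[:, :, 9:12] = _skew(rb)
    K12 = np.einsum("mia,mij,mjb->mab", G, Kpp, G)
    idx = _dof_indices(bodies)
    np.add.at(K, (idx[:, :, None], idx[:, None, :]), K12)


def _scatter_lever_geometric(K, bodies, ra, rb, F):
    """Rotational geometric stiffness of a force pair at material levers:
    the symmetrized -skew(F) skew(r) term (F on A at lever ra, -F on B at
    rb).  Stabilizes Newton when element forces become comparable to the
    elastic stiffness scale."""
    SF = _skew(F)
    Ta = -np.einsum("mij,mjk->mik", SF, _skew(ra))
    Tb = np.einsum("mij,mjk->mik", SF, _skew(rb))
    Ta = 0.5 * (Ta + np.transpose(Ta, (0, 2, 1)))
    Tb = 0.5 * (Tb + np.transpose(Tb, (0, 2, 1)))
    rot = np.arange(3, 6)
    ia = bodies[:, 0] * 6
    ib = bodies[:, 1] * 6
    idx_a = ia[:, None] + rot[None, :]
    idx_b = ib[:, None] + rot[None, :]
    np.add.at(K, (idx_a[:, :, None], idx_a[:, None, :]), Ta)
    np.add.at(K, (idx_b[:, :, None], idx_b[:, None, :]), Tb)


def _scatter_rotational_stiffness(K, bodies, Kr_w):
    m = len(Kr_w)
    H = np.zeros((m, 3, 12))
    I3 = np.eye(3)
    H[:, :, 3:6] = I3
    H[:, :, 9:12] = -I3
    K12 = np.einsum("mia,mij,mjb->mab", H, Kr_w, H)
    idx = _dof_indices(bodies)
    np.add.at(K, (idx[:, :, None], idx[:, None, :]), K12)


# ---------------------------------------------------------------------------
# Newton iteration


def _residual_norms(res, free):
    r = res.reshape(-1)[free].reshape(-1)
    rf = res[:, :3].reshape(-1)
    rt = res[:, 3:].reshape(-1)
    fmask = np.zeros_like(res, dtype=bool)
    fmask[:, :3] = True
    fmask = fmask.reshape(-1)
    free_f = free & fmask
    free_t = free & ~fmask
    full = res.reshape(-1)
    mf = np.max(np.abs(full[free_f])) if free_f.any() else 0.0
    mt = np.max(np.abs(full[free_t])) if free_t.any() else 0.0
    return mf, mt, float(np.linalg.norm(r))


def _apply_update(state: State, dq):
    """dq: (n, 6); translations then incremental rotation vectors (rad)."""
    new = state.copy()
    new.u += dq[:, :3]
    w = dq[:, 3:]
    nz = np.linalg.norm(w, axis=1) > 0
    if nz.any():
        dR = Rotation.from_rotvec(w[nz]).as_matrix()
        new.R[nz] = np.einsum("mij,mjk->mik", dR, new.R[nz])
    return new


def _fd_tangent(system, state, loads, lam, free):
    """Finite-difference Jacobian of the residual on the free DOFs (exact
    up to O(h); used as a fallback when the analytic tangent stalls)."""
    r0 = residual(system, state, loads, lam).reshape(-1)[free]
    n = system.n_bodies
    idx = np.flatnonzero(free)
    J = np.zeros((len(idx), len(idx)))
    for col, j in enumerate(idx):
        h = 1e-4 if (j % 6) < 3 else 1e-6
        dq = np.zeros(6 * n)
        dq[j] = h
        trial = _apply_update(state, dq.reshape(-1, 6))
        r1 = residual(system, trial, loads, lam).reshape(-1)[free]
        J[:, col] = -(r1 - r0) / h
    return J


def _newton_solve(system, state, loads, lam, opts):
    """Damped (Levenberg-style) Newton at fixed load factor.

    The analytic tangent truncates some frame terms of the 6-D springs, so
    a pure Newton step can increase the residual; adaptive diagonal damping
    makes each accepted step strictly decrease the residual norm.  If the
    analytic direction stalls above tolerance, the iteration switches to a
    finite-difference Jacobian, which removes the approximation error
    floor.
    """
    free = system.free_mask
    damp = 0.0
    use_fd = False
    for it in range(opts.max_iter):
        res = residual(system, state, loads, lam)
        mf, mt, nrm = _residual_norms(res, free)
        if mf <= opts.force_tol and mt <= opts.torque_tol:
            return state, it, mf, mt, True
        if use_fd:
            Kff = _fd_tangent(system, state, loads, lam, free)
        else:
            K = assemble_tangent(system, state)
            Kff = K[np.ix_(free, free)]
        scale = max(np.abs(np.diag(Kff)).max(), 1.0)
        r = res.reshape(-1)[free]
        accepted = None
        for _ in range(10):
            M = Kff.copy()
            M[np.diag_indices_from(M)] += (opts.regularization + damp) * scale
            try:
                dq_f = np.linalg.solve(M, r)
            except np.linalg.LinAlgError:
                damp = max(10.0 * damp, 1e-6)
                continue
            dq = np.zeros(6 * system.n_bodies)
            dq[free] = dq_f
            dq = dq.reshape(-1, 6)
            for alpha in (1.0, 0.5, 0.25, 0.1):
                trial = _apply_update(state, alpha * dq)
                t_nrm = _residual_norms(
                    residual(system, trial, loads, lam), free)[2]
                if t_nrm < nrm * (1.0 - 1e-6) or t_nrm < 1e-12:
                    accepted = (trial, t_nrm)
                    break
            if accepted is not None:
                damp *= 0.25
                if damp < 1e-10:
                    damp = 0.0
                break
            damp = max(10.0 * damp, 1e-6)
        if accepted is None:
            if not use_fd:
                use_fd = True          # analytic direction exhausted
                damp = 0.0
                continue
            break                      # stuck even with the exact Jacobian
        # detect slow creep (approximation error floor) and switch to FD
        if not use_fd and accepted[1] > 0.98 * nrm:
            use_fd = True
            damp = 0.0
        state = accepted[0]
    res = residual(system, state, loads, lam)
    mf, mt, _ = _residual_norms(res, free)
    return state, opts.max_iter, mf, mt, (mf <= opts.force_tol and mt <= opts.torque_tol)


def solve_equilibrium(system: System, loads=None, n_steps=1, state=None,
                      options: SolverOptions | None = None,
                      start_factor=0.0) -> Configuration:
    """Equilibrate the system under ``loads`` ramped over ``n_steps`` increments.

    ``loads`` is an (n, 6) array of generalized external forces (N, N·mm).
    A warm-start ``state`` may be supplied (e.g. from the previous maneuver
    step).  Deterministic.  Raises :class:`ConvergenceError` if a step fails
    after the maximum number of halvings.
    """
    opts = options or SolverOptions()
    if state is None:
        state = State.rest(system)
    else:
        state = state.copy()
    records = []
    if loads is None:
        loads = np.zeros((system.n_bodies, 6))

    targets = start_factor + (1.0 - start_factor) * (
        np.arange(1, n_steps + 1) / n_steps)
    # minimum load increment before giving up: halving the increment is the
    # continuation safety net for strongly nonlinear paths (soft pendulum
    # modes coupled to stiff axial chains need many small increments)
    min_step = max((1.0 - start_factor), 1e-12) / (2 ** opts.max_halvings) \
        / max(n_steps, 1)
    lam_done = start_factor
    step_no = 0
    for lam_target in targets:
        pending = [lam_target]
        while pending:
            lam = pending[-1]
            saved = state.copy()
            state, iters, mf, mt, ok = _newton_solve(system, state, loads, lam, opts)
            step_no += 1
            records.append(StepRecord(step_no, lam, iters, mf, mt, ok))
            if ok:
                pending.pop()
                lam_done = lam
            else:
                state = saved
                if (lam - lam_done) < min_step:
                    raise ConvergenceError(
                        f"no convergence at load factor {lam:.6f} with "
                        f"increments below {min_step:.2e} "
                        f"(last residuals {mf:.3g} N, {mt:.3g} N·mm)",
                        last_residual=(mf, mt),
                        state=Configuration.from_state(state, records, False),
                    )
                pending[-1:] = [lam, 0.5 * (lam_done + lam)]   # retry smaller first
    return Configuration.from_state(state, records, True)
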