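"""First-order implicit (Backward Euler) time stepping.

Each step solves the linearized implicit system

    (M + dt D + dt^2 K) dv = dt (f0 - dt K v0 - ...)

with forces f0 and operators assembled at the start-of-step state by
:class:`JawSystem`.  For linear force fields this reproduces the
classic Backward Euler update exactly (constant force:
v1 = v0 + dt f/M; linear spring:
v1 = (v0 - dt (k/m) x0) / (1 + dt^2 k/m)).

Unilateral cartilage contact enters as secant-regularized springs from
the substrate surface whose stiffness is iterated to the predicted
end-of-step depth (fixed-point sweeps with an active-set update), so
the converged constraint force equals the foundation law evaluated at
the end-of-step penetration.  Non-converged sweeps, large per-step
depth changes of loaded contacts, and element inversions trigger time
substepping; a damped-Newton fallback with fresh FEM tangents engages
on large predicted nodal increments.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fem import ElementInversionError
from .system import JawSystem

__all__ = ["SimConfig", "StepReport", "RunResult", "backward_euler_update", "step", "run",
           "incisal_gap"]


@dataclass
class SimConfig:
    dt: float = 1e-3
    duration: float = 1.0
    newton_iters: int = 1
    max_active_set_sweeps: int = 5
    solver_tol: float = 1e-10
    fem_tangent_lag: int = 8  # reassemble FEM tangents every this many steps
    contact_damping_s: float = 5e-3  # normal contact damping = this * k_secant
    tangential_damping_s: float = 2e-4  # viscous shear (synovial) damping * k_secant
    output_every: int = 25  # steps between logged/written frames
    gravity_on: bool = True
    seed: int = 0
    frames_dir: str | None = None  # write VTK frames here if set

    def __post_init__(self):
        if self.dt <= 0 or self.duration < 0:
            raise ValueError("dt must be positive and duration non-negative")
        if self.solver_tol <= 0:
            raise ValueError("solver tolerance must be positive")


@dataclass
class StepReport:
    sweeps: int = 1
    active_set_converged: bool = True
    residual_norm: float = 0.0


@dataclass
class RunResult:
    """Per-frame logs plus peak stress/pressure tracking."""

    times: list = field(default_factory=list)
    log: dict[str, list] = field(default_factory=dict)
    peak_von_mises: float = 0.0
    peak_max_principal: float = 0.0
    peak_pressure: float = 0.0
    warnings: int = 0
    stable: bool = True
    failure: str | None = None

    def append(self, t, row: dict):
        self.times.append(t)
        for k, v in row.items():
            self.log.setdefault(k, []).append(v)

    def column(self, key):
        return np.asarray(self.log[key])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({"time_s": self.times, **self.log})


def backward_euler_update(M, D, K, f, v0, dt):
    """One linear Backward Euler velocity update: (M+dtD+dt^2K) v1 = M v0 + dt f.

    ``f`` is evaluated at the start-of-step configuration.  Dense or
    sparse operators; used directly by the toy-system checks and mirrors
    the first Newton iteration of :func:`step`.
    """
    M = np.atleast_2d(np.asarray(M, float)) if not sp.issparse(M) else M
    A = M + dt * D + dt * dt * K
    rhs = M @ np.atleast_1d(v0) + dt * np.atleast_1d(f)
    if sp.issparse(A):
        return spla.spsolve(A.tocsc(), rhs)
    return np.linalg.solve(A, rhs)


def _solve(J, rhs, cache, system, snap, level: str = "lu"):
    """Solve J x = rhs: CG preconditioned with a recycled LU factorization.

    The system matrix changes slowly between steps (mass and FEM terms
    dominate), so an LU of a recent matrix makes an excellent
    preconditioner; it is refreshed whenever CG stalls.  ``level`` keys
    the cached factorization (substeps use different dt, hence
    different matrices).
    """
    lu = cache.get(level)
    if lu is not None:
        P = spla.LinearOperator(J.shape, lu.solve)
        iters = 0

        def _count(_):
            nonlocal iters
            iters += 1

        x, info = spla.cg(J, rhs, M=P, rtol=1e-10, atol=0.0, maxiter=45, callback=_count)
        if info == 0 and iters <= 35:
            return x
    try:
        lu = spla.splu(J)
    except RuntimeError as e:
        system.restore(snap)
        raise RuntimeError(f"implicit solve failed (factorization): {e}") from e
    cache[level] = lu
    return lu.solve(rhs)


def step(system: JawSystem, cfg: SimConfig, activations: dict[str, float],
         _cache: dict | None = None, _dt: float | None = None, _depth: int = 0) -> StepReport:
    """Advance the coupled system by one Backward Euler step (in place).

    If the active-set sweeps fail to reach a consistent contact set (or
    an element inverts during a violent transient), the step is retried
    as two half steps, recursively up to 4 levels.
    """
    dt = cfg.dt if _dt is None else _dt
    cache = _cache if _cache is not None else {}
    lag = max(cfg.fem_tangent_lag, 1)
    if _depth == 0:
        if cache.get("age", lag) >= lag:
            cache["fem_tangent"] = {}
            cache["age"] = 0
        cache["age"] = cache.get("age", 0) + 1
    fem_tangent = cache.setdefault("fem_tangent", {})

    snap = system.snapshot()
    err = None
    try:
        report = _step_once(system, cfg, activations, dt, snap, cache, fem_tangent)
    except (ElementInversionError, RuntimeError, ValueError) as e:
        report, err = None, e
    if report is None or not report.active_set_converged:
        if _depth < 2:
            system.restore(snap)
            r1 = step(system, cfg, activations, _cache=cache, _dt=dt / 2, _depth=_depth + 1)
            r2 = step(system, cfg, activations, _cache=cache, _dt=dt / 2, _depth=_depth + 1)
            return StepReport(
                sweeps=r1.sweeps + r2.sweeps,
                active_set_converged=r1.active_set_converged and r2.active_set_converged,
                residual_norm=r2.residual_norm,
            )
        if err is not None:  # inversion persisted at the smallest substep
            system.restore(snap)
            raise err
    return report


def _step_once(system, cfg, activations, dt, snap, cache, fem_tangent):
    """One linearized Backward Euler solve with active-set contact sweeps.

    All forces and the contact constraints are anchored at the
    start-of-step state x0: non-contact forces f0 with tangent K, and
    per contact the force lam0 = p(d0) A with compliance slope
    k = A dp/dd (lam0 = k d0 <= 0 for anticipated contacts still
    separated at x0).  Within the step each contact force is the linear
    model lam(v1) = lam0 - k dt g.v1 (g = separation-rate row), so the
    strongly nonlinear foundation law is never evaluated at extrapolated
    states.  The active set is updated from the linear model (drop
    lam1 < 0, add predicted penetrations) until it is self-consistent.
    """
    system.restore(snap)
    v0 = system.get_velocities()
    M = system.mass_matrix()
    f0, D, K, _ = system.evaluate(activations, fem_tangent=fem_tangent,
                                  include_contacts=False)
    constraints = system.contact_constraints()
    active = {id(c) for c in constraints if c.depth >= 0.0}
    # secant regularization: each contact is a linear spring from the
    # substrate surface, lam = k_sec(dhat) * d1, with the secant
    # stiffness k_sec = p(dhat) A / dhat iterated on the predicted
    # end-of-step depth dhat.  At the fixed point lam = p(d1) A exactly
    # (a fully implicit evaluation of the foundation law), the force is
    # unilateral by construction, and a Backward Euler solve against a
    # surface-anchored spring cannot eject a contact past the surface.
    n = system.n_dof
    m_c = len(constraints)
    report = StepReport()
    v1 = v0.copy()
    base_rhs = dt * f0 - dt * dt * (K @ v0)
    base_A = (M + dt * D + dt * dt * K).tocsc()
    if m_c:
        # stack every candidate constraint row into one sparse operator
        rows = np.repeat(np.arange(m_c), [len(c.cols) for c in constraints])
        cols = np.concatenate([c.cols for c in constraints])
        vals = np.concatenate([c.vals for c in constraints])
        G_all = sp.coo_matrix((vals, (rows, cols)), shape=(m_c, n)).tocsr()
        # tangential rows (two per contact) for viscous shear damping
        tr = [row for c in constraints for row in c.t_rows]
        t_rows = np.repeat(np.arange(2 * m_c), [len(r[0]) for r in tr])
        t_cols = np.concatenate([r[0] for r in tr])
        t_vals = np.concatenate([r[1] for r in tr])
        Gt_all = sp.coo_matrix((t_vals, (t_rows, t_cols)), shape=(2 * m_c, n)).tocsr()
        depth = np.array([c.depth for c in constraints])
        thick = np.array([c.thickness for c in constraints])
        area = np.array([c.area for c in constraints])
        Klaw = np.array([c.K_law for c in constraints])
        damp_s = np.array([c.damping_s if c.damping_s is not None
                           else cfg.contact_damping_s for c in constraints])

        def secant_k(d):
            dhat = np.clip(d, 1e-3 * thick, 0.99 * thick)
            p = Klaw * np.log1p(-dhat / thick)  # >= 0 (Klaw < 0)
            return area * p / dhat

        k_sec = secant_k(depth)
        active = depth >= 0.0
    else:
        G_all = None
        active = np.zeros(0, bool)
        k_sec = np.zeros(0)
        depth = np.zeros(0)
        thick = np.zeros(0)
    lam_scale = 1e-3
    for sweep in range(max(cfg.max_active_set_sweeps, 2)):
        report.sweeps = sweep + 1
        if m_c and np.any(active):
            idx = np.nonzero(active)[0]
            G = G_all[idx]
            ks = k_sec[idx]
            Kc = (G.T @ sp.diags(ks) @ G).tocsc()
            # spring from the surface: lam(v1) = k (d0 - dt g v1), plus
            # implicit normal damping (synovial-like) tied to the stiffness
            fc = G.T @ (ks * depth[idx])
            Dc = (G.T @ sp.diags(damp_s[idx] * ks) @ G).tocsc()
            if cfg.tangential_damping_s > 0.0 and Gt_all is not None:
                t_idx = np.concatenate([2 * idx, 2 * idx + 1])
                Gt = Gt_all[t_idx]
                kt = cfg.tangential_damping_s * np.concatenate([ks, ks])
                Dc = Dc + (Gt.T @ sp.diags(kt) @ Gt).tocsc()
            A = (base_A + dt * dt * Kc + dt * Dc).tocsc()
            rhs = base_rhs + dt * fc - dt * dt * (Kc @ v0) - dt * (Dc @ v0)
        else:
            A = base_A
            rhs = base_rhs
        dv = _solve(A, rhs, cache, system, snap, level=f"lu_{dt:.2e}")
        v1 = v0 + dv
        if not m_c:
            report.active_set_converged = True
            break
        # update secant stiffnesses at predicted end depths; adjust the
        # active set, ignoring flicker of contacts whose force is
        # negligible next to the current load level
        s_rate = G_all @ v1
        d1 = depth - dt * s_rate
        now = d1 > 0.0
        # convergence is judged on force consistency: the solve applied
        # lam = k_sec d1 on the active set; compare against the exact
        # foundation law at the predicted end depths
        lam_applied = np.where(active & now, k_sec * np.maximum(d1, 0.0), 0.0)
        dcl = np.clip(d1, 0.0, 0.99 * thick)
        lam_law = np.where(now, area * (Klaw * np.log1p(-dcl / thick)), 0.0)
        lam_scale = max(1e-3, float(lam_law.max(initial=0.0)))
        f_err = float(np.abs(lam_applied - lam_law).sum())
        f_tot = float(lam_law.sum())
        k_sec = np.where(now, 0.5 * (secant_k(d1) + k_sec), k_sec)  # under-relaxed
        active = now
        if f_err <= 0.05 * max(f_tot, 1e-2):
            report.active_set_converged = True
            break
    else:
        report.active_set_converged = False
    if m_c:
        # impact guard: a significantly loaded contact whose depth changes
        # by a large layer fraction in one step invalidates the
        # linearization; substep in time.  Lightly loaded rattling
        # vertices are exempt.
        s_rate = G_all @ v1
        d1 = depth - dt * s_rate
        lam_b = k_sec * np.maximum(np.maximum(d1, depth), 0.0)
        bad = (np.abs(dt * s_rate) > 0.35 * thick) & ((depth > 0) | (d1 > 0)) & (
            lam_b > 0.05 * lam_scale)
        if np.any(bad):
            report.active_set_converged = False

    # Escalate to full Newton (fresh FEM tangents per iterate) when the
    # linearized solve predicts nodal displacement increments the stale
    # tangent cannot be trusted for, or when asked for via newton_iters.
    act = [c for i, c in enumerate(constraints) if active[i]]
    needs_newton = cfg.newton_iters > 1 or _fem_increment_too_large(system, dt, v1)
    if needs_newton:
        # hand the Newton fallback the secant spring model
        for i, c in enumerate(constraints):
            if active[i]:
                c.k = float(k_sec[i])
                c.lam0 = c.k * c.depth
        v1 = _newton_solve(system, cfg, activations, dt, snap, v0, v1, M, D, act, report)

    system.restore(snap)
    system.advance_positions(dt, v1)
    if not np.all(np.isfinite(v1)):
        raise RuntimeError("non-finite velocities after implicit solve")
    # a committed state with inverted elements is rejected (the outer
    # step retries with substeps) unless the body is configured to
    # continue with regularized elements
    for fb in system.fem_bodies.values():
        if fb.allow_inversion:
            continue
        detF = np.linalg.det(fb.deformation_gradients())
        if np.any(detF <= 0):
            raise ElementInversionError(np.nonzero(detF <= 0)[0])
    return report


def _fem_increment_too_large(system, dt, v1) -> bool:
    for name, fb in system.fem_bodies.items():
        sl = system.dof_slice(name)
        dx = dt * np.abs(v1[sl]).max()
        if dx > 0.25 * fb.min_edge:
            return True
    return False


def _newton_solve(system, cfg, activations, dt, snap, v0, v_init, M, D, act, report):
    """Damped Newton on the Backward Euler residual.

    FEM internal forces and tangents are re-evaluated at every iterate
    (the nearly incompressible disk stiffens steeply under compression,
    so a start-of-step linearization can overshoot into element
    inversion); contact keeps the anchored linear unilateral model with
    the multiplier clamped at zero.
    """
    v = v_init.copy()
    n = system.n_dof
    best_v, best_r = v.copy(), np.inf
    if act:
        rows = np.repeat(np.arange(len(act)), [len(c.cols) for c in act])
        cols = np.concatenate([c.cols for c in act])
        vals = np.concatenate([c.vals for c in act])
        G = sp.coo_matrix((vals, (rows, cols)), shape=(len(act), n)).tocsr()
        kdiag = sp.diags([c.k for c in act])
        Kc = (G.T @ kdiag @ G).tocsc()
        lam0 = np.array([c.lam0 for c in act])
        kvec = np.array([c.k for c in act])
    else:
        G, Kc, lam0, kvec = None, None, None, None

    newton_ft: dict = {}

    def residual(vv, inversion_ok, fresh_tangent=True):
        if fresh_tangent:
            newton_ft.clear()
        system.restore(snap)
        system.advance_positions(dt, vv)
        try:
            f, _, K, _ = system.evaluate(activations, fem_tangent=newton_ft,
                                         include_contacts=False)
        except ElementInversionError:
            if inversion_ok:
                return None, None
            raise
        r = M @ (vv - v0) - dt * f
        if G is not None:
            lam = np.maximum(lam0 - kvec * dt * (G @ vv), 0.0)
            r -= dt * (G.T @ lam)
        return r, K

    r, K = residual(v, inversion_ok=False)
    scale = 1.0 + float(np.linalg.norm(M @ v0))
    for _ in range(max(cfg.newton_iters, 6)):
        rn = float(np.linalg.norm(r))
        if rn < best_r:
            best_r, best_v = rn, v.copy()
        if rn < 1e3 * cfg.solver_tol * scale:
            break
        J = (M + dt * D + dt * dt * K)
        if Kc is not None:
            J = J + dt * dt * Kc
        try:
            dv = spla.splu(J.tocsc()).solve(-r)
        except RuntimeError:
            break  # singular trial Jacobian: keep the best iterate so far
        alpha = 1.0
        for ls in range(6):  # backtracking line search, inversion-aware
            r_new, _ = residual(v + alpha * dv, inversion_ok=True, fresh_tangent=False)
            if r_new is not None and np.linalg.norm(r_new) < rn:
                break
            alpha *= 0.5
        else:
            break
        v = v + alpha * dv
        r, K = residual(v, inversion_ok=True)
        if r is None:  # should not happen (line search verified), be safe
            v = best_v
            r, K = residual(v, inversion_ok=False)
            break
    report.residual_norm = min(best_r, float(np.linalg.norm(r)))
    return best_v if best_r < float(np.linalg.norm(r)) else v


def incisal_gap(system: JawSystem) -> dict[str, float]:
    """Inter-incisal separation in mm: total plus x/y/z components.

    Components follow the anatomical axes of the model frame:
    x anterior-posterior, y lateral, z vertical.
    """
    up = system.landmarks["incisor_upper"]
    lo = system.landmarks["incisor_lower"]
    p_up = system.bodies[up.body].world_point(up.point)
    p_lo = system.bodies[lo.body].world_point(lo.point)
    d = (p_up - p_lo) / 1e-3
    return {
        "gap_mm": float(np.linalg.norm(d)),
        "gap_x_mm": float(d[0]),
        "gap_y_mm": float(d[1]),
        "gap_z_mm": float(d[2]),
    }


def run(system: JawSystem, cfg: SimConfig, schedule, progress: bool = False) -> RunResult:
    """Run a task schedule for ``cfg.duration`` seconds.

    Logs incisal gap, speeds, energies, contact statistics at the output
    cadence and tracks peak disk von Mises / max-principal stress and
    peak contact pressure.  Individual step failures (element inversion,
    solver breakdown) mark the result unstable instead of raising.
    """
    import warnings as _warnings

    if not cfg.gravity_on:
        saved_g = system.gravity.copy()
        system.gravity = np.zeros(3)
    n_steps = int(round(cfg.duration / cfg.dt))
    result = RunResult()
    cache: dict = {}
    frames = Path(cfg.frames_dir) if cfg.frames_dir else None
    if frames:
        frames.mkdir(parents=True, exist_ok=True)
    t0 = _time.time()
    try:
        for i in range(n_steps + 1):
            t = i * cfg.dt
            acts = schedule.activations(t, system.muscles) if schedule is not None else {}
            if i % cfg.output_every == 0 or i == n_steps:
                _log_frame(system, cfg, acts, result, t, i, frames)
            if i == n_steps:
                break
            with _warnings.catch_warnings(record=True) as wlist:
                _warnings.simplefilter("always")
                step(system, cfg, acts, _cache=cache)
            result.warnings += len(wlist)
            if progress and i % 100 == 0:
                print(f"  t={t:.3f}s  ({_time.time() - t0:.1f}s wall)")
    except RuntimeError as e:
        result.stable = False
        result.failure = str(e)
    finally:
        if not cfg.gravity_on:
            system.gravity = saved_g
    return result


def _log_frame(system, cfg, acts, result, t, i, frames):
    from .mesh_io import write_vtk_frame

    _, _, _, contact_sets = system.evaluate(acts, with_stiffness=False)
    en = system.energies(contact_sets)
    n_contacts = sum(len(cs.depths) for cs in contact_sets.values())
    max_pen = 0.0
    max_p = 0.0
    for cs in contact_sets.values():
        if len(cs.depths):
            layer = system.ef_layers[cs.layer]
            max_pen = max(max_pen, float(cs.depths.max() / layer.thickness))
            max_p = max(max_p, float(cs.pressures.max()))
    result.peak_pressure = max(result.peak_pressure, max_p)
    row = {}
    if "incisor_upper" in system.landmarks:
        row.update(incisal_gap(system))
    mand = next((b for b in system.bodies.values() if b.dynamic), None)
    if mand is not None:
        row["mandible_speed_m_s"] = float(np.linalg.norm(mand.velocity))
        row["mandible_omega_rad_s"] = float(np.linalg.norm(mand.omega))
    row.update({f"energy_{k}_J": v for k, v in en.items()})
    row["n_contacts"] = n_contacts
    row["max_penetration_frac"] = max_pen
    row["max_pressure_Pa"] = max_p
    for name, fb in system.fem_bodies.items():
        sf = fb.stress_recovery()
        vm = float(sf.nodal_von_mises.max(initial=0.0))
        mp = float(sf.nodal_max_principal.max(initial=0.0))
        row[f"{name}_max_von_mises_Pa"] = vm
        row[f"{name}_max_principal_Pa"] = mp
        result.peak_von_mises = max(result.peak_von_mises, vm)
        result.peak_max_principal = max(result.peak_max_principal, mp)
        if frames:
            write_vtk_frame(
                frames / f"{name}_{i:06d}.vtk",
                type(fb.mesh)(fb.positions, fb.mesh.tets),
                point_fields={
                    "von_mises": sf.nodal_von_mises,
                    "max_principal": sf.nodal_max_principal,
                },
            )
    result.append(t, row)
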