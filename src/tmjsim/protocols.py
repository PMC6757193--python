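"""Desk-scale study protocols on the synthetic anatomy.

These are the standard end-to-end exercises of the model: the three
forward-simulation tasks (postural rest, active opening, clenching) and
the 15-cell Mooney-Rivlin sensitivity grid, at problem sizes that run
on a single desktop core (disk lattice edge 1.2 mm, dt = 1 ms, task
windows of a few hundred milliseconds).  Both the validation tests and
the reproduction script drive the model through these functions so they
exercise identical conditions.
"""

from __future__ import annotations

from .experiments import SweepSpec, material_sweep
from .integrator import RunResult, SimConfig, incisal_gap, run
from .synthetic import AnatomyParams, generate_anatomy

__all__ = ["TASK_DURATIONS", "end_state_metrics", "run_task", "run_study_tasks",
           "run_material_grid"]

TASK_DURATIONS = {"rest": 1.0, "open": 0.35, "clench": 0.35}


def end_state_metrics(bundle, task: str, t_end: float) -> dict:
    """Stress/pressure map maxima at the task end state.

    These are the analogues of end-of-task stress and pressure maps:
    maximal nodal von Mises and maximum-principal stress over both
    disks, the maximal cartilage contact pressure, and the per-side
    contact counts.  (Transient running maxima can be polluted by
    isolated capped vertices during fast phases; end-state fields are
    the comparable quantity.)
    """
    system = bundle.system
    acts = bundle.tasks[task].activations(t_end, system.muscles)
    _, _, _, contact_sets = system.evaluate(acts, with_stiffness=False)
    p_max = max((float(cs.pressures.max()) for cs in contact_sets.values()
                 if len(cs.pressures)), default=0.0)
    vm = s1 = 0.0
    for fb in system.fem_bodies.values():
        sf = fb.stress_recovery()
        vm = max(vm, float(sf.nodal_von_mises.max()))
        s1 = max(s1, float(sf.nodal_max_principal.max()))
    contacts = {side: sum(len(cs.depths) for key, cs in contact_sets.items()
                          if key[0] == f"disk_{side}")
                for side in ("right", "left")}
    return {"von_mises_pa": vm, "max_principal_pa": s1, "pressure_pa": p_max,
            "contacts": contacts}


def run_task(name: str, seed: int = 0, duration: float | None = None,
             dt: float = 1e-3, edge_length: float = 1.2):
    """Run one named task on a freshly generated anatomy.

    Returns ``(bundle, RunResult, final incisal gap dict, end-state
    metrics dict)``.
    """
    dur = duration or TASK_DURATIONS.get(name, 0.35)
    bundle = generate_anatomy(AnatomyParams(seed=seed, edge_length=edge_length))
    cfg = SimConfig(dt=dt, duration=dur, output_every=20, seed=seed)
    result = run(bundle.system, cfg, bundle.tasks[name])
    gap = incisal_gap(bundle.system) if result.stable else {}
    metrics = end_state_metrics(bundle, name, dur) if result.stable else {}
    return bundle, result, gap, metrics


def run_study_tasks(seed: int = 0) -> dict[str, tuple]:
    """Rest, opening and clench runs at the standard desk-scale windows."""
    return {name: run_task(name, seed=seed) for name in ("rest", "open", "clench")}


def run_material_grid(seed: int = 0, duration: float = 0.04):
    """The 15-simulation Mooney-Rivlin grid on a short opening window.

    C1 is scaled one order of magnitude either way and C2 two orders,
    all cells with the identical seed and task.  The short window keeps
    the full grid tractable; it captures the early opening trajectory
    whose end position is the compared output.
    """
    spec = SweepSpec(base_params=AnatomyParams(seed=seed), task="open",
                     duration=duration, dt=1e-3)
    return material_sweep(spec)
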