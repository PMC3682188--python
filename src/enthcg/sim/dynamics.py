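"""NVT dynamics: velocity Verlet with a Nose-Hoover thermostat.

Lipid orientations evolve by torque integration of the director as a
constrained unit vector (linear-rotor scheme: tangent-projected director
velocity, renormalization each step).  With the thermostat disabled the
integrator is plain velocity Verlet and conserves energy (NVE), which is
the integrator's correctness check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..constants import KB, KCAL_TO_KJ
from .kernels import build_neighbor_pairs, compute_forces
from .params import LIPID_INERTIA
from .system import CGSystem


class SimulationError(RuntimeError):
    """Raised on energy divergence; carries a diagnostic frame."""

    def __init__(self, message: str, frame: dict | None = None):
        super().__init__(message)
        self.frame = frame or {}


@dataclass
class SimResult:
    """Trajectory snapshots plus the thermodynamic log."""

    log: pd.DataFrame
    snapshots: list = field(default_factory=list)   # dicts of arrays
    final_temperature: float = np.nan

    def snapshot_protein_coords(self, idx: int) -> list:
        return self.snapshots[idx]["proteins"]


def _energy_terms(system: CGSystem, allpos, dirs, types, pid, pairs,
                  springs):
    gbp = system.gb.as_tuple()
    mode, eps, sig, cut = system.interactions.build_tables()
    f, g, e_ll, e_sp, e_pl, e_pp = compute_forces(
        allpos, dirs, types, pid, system.n_lipids, pairs,
        system.config.box, system.config.periodic, *gbp,
        mode, eps, sig, cut, *springs)
    return f, g, {"lipid_lipid": e_ll, "springs": e_sp,
                  "protein_lipid": e_pl, "protein_protein": e_pp}


def total_energy(system: CGSystem) -> dict:
    """Potential energy decomposition; 'total' is the exact sum of terms."""
    allpos, types, pid = system.packed()
    dirs = np.ascontiguousarray(system.lipid_dir)
    rmax = max(system.gb.cutoff,
               system.interactions.lj_cutoff_factor
               * system.interactions.sigma_protein_lipid)
    pairs = build_neighbor_pairs(allpos, system.config.box,
                                 system.config.periodic, rmax)
    springs = system.spring_arrays()
    _, _, terms = _energy_terms(system, allpos, dirs, types, pid, pairs,
                                springs)
    terms["total"] = sum(terms.values())
    return terms


def _init_velocities(n, n_lipids, masses, dirs, temperature, seed):
    rng = np.random.default_rng(seed)
    kt_kj = KB * temperature * KCAL_TO_KJ
    v = rng.standard_normal((n, 3)) * np.sqrt(kt_kj / masses)[:, None]
    v -= (masses[:, None] * v).sum(axis=0) / masses.sum()
    w = rng.standard_normal((n_lipids, 3)) * np.sqrt(kt_kj / LIPID_INERTIA)
    w -= np.sum(w * dirs, axis=1)[:, None] * dirs   # tangent to directors
    return v, w


def kinetic_temperature(v, w, masses) -> float:
    """Instantaneous kinetic temperature (translation + rotation), K."""
    k_kj = 0.5 * float((masses[:, None] * v * v).sum()) \
        + 0.5 * LIPID_INERTIA * float((w * w).sum())
    nf = 3 * len(v) - 3 + 2 * len(w)
    return 2.0 * k_kj / (nf * KB * KCAL_TO_KJ)


def run_nvt(system: CGSystem, n_steps: int, thermostat: bool = True,
            seed: int | None = None, log_stride: int | None = None,
            snapshot_stride: int | None = None) -> SimResult:
    """Advance the system ``n_steps`` with velocity Verlet at constant NVT.

    Updates the system in place and returns the log plus snapshots.  With
    ``thermostat=False`` the run is NVE (no velocity rescaling at all).
    """
    cfg = system.config
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    seed = cfg.seed if seed is None else seed
    log_stride = log_stride or cfg.log_stride
    snapshot_stride = snapshot_stride or cfg.snapshot_stride

    allpos, types, pid = system.packed()
    dirs = np.ascontiguousarray(system.lipid_dir.copy())
    n, nl = len(allpos), system.n_lipids
    masses = system.masses()
    springs = system.spring_arrays()
    dt = cfg.dt
    t0 = cfg.temperature
    tau = cfg.thermostat_tau
    rmax = max(system.gb.cutoff,
               system.interactions.lj_cutoff_factor
               * system.interactions.sigma_protein_lipid)
    rlist = rmax + cfg.neighbor_skin

    v, w = _init_velocities(n, nl, masses, dirs, t0, seed)
    xi = 0.0

    pairs = build_neighbor_pairs(allpos, cfg.box, cfg.periodic, rlist)
    pos_ref = allpos.copy()
    f, g, terms = _energy_terms(system, allpos, dirs, types, pid, pairs,
                                springs)

    inv_m = (KCAL_TO_KJ / masses)[:, None]
    inv_i = KCAL_TO_KJ / LIPID_INERTIA
    log_rows = []
    snapshots = []
    e_prev = None

    def log_state(step):
        nonlocal e_prev
        tk = kinetic_temperature(v, w, masses)
        e_pot = sum(terms.values())
        e_kin = (0.5 * float((masses[:, None] * v * v).sum())
                 + 0.5 * LIPID_INERTIA * float((w * w).sum())) / KCAL_TO_KJ
        e_tot = e_pot + e_kin
        if not np.isfinite(e_tot) or (
                e_prev is not None
                and abs(e_tot - e_prev) > 1e3 * max(log_stride, 1)):
            raise SimulationError(
                f"energy divergence at step {step}: total {e_tot:.3g} "
                f"(previous {e_prev})",
                frame={"step": step, "positions": allpos.copy(),
                       "directors": dirs.copy(), "velocities": v.copy()})
        e_prev = e_tot
        log_rows.append({"step": step, "temperature": tk,
                         "e_potential": e_pot, "e_kinetic": e_kin,
                         "e_total": e_tot, **terms})

    def snapshot(step):
        system.lipid_pos = allpos[:nl].copy()
        system.lipid_dir = dirs.copy()
        system.unpack_proteins(allpos)
        snapshots.append({
            "step": step,
            "lipid_pos": allpos[:nl].copy(),
            "lipid_dir": dirs.copy(),
            "proteins": [c.copy() for c in system.protein_coords]})

    log_state(0)
    snapshot(0)

    half = 0.5 * dt
    for step in range(1, n_steps + 1):
        if thermostat:
            tk = kinetic_temperature(v, w, masses)
            xi += half * (tk / t0 - 1.0) / (tau * tau)
            s = np.exp(-xi * half)
            v *= s
            w *= s
        v += half * f * inv_m
        fu = -(g - np.sum(g * dirs, axis=1)[:, None] * dirs)
        w += half * fu * inv_i

        allpos += dt * v
        # SHAKE for the unit-director constraint: u_new = u + dt*w + lam*u
        # with lam solving |u_new| = 1 exactly
        u_raw = dirs + dt * w
        b = np.einsum("ij,ij->i", u_raw, dirs)
        c = np.einsum("ij,ij->i", u_raw, u_raw) - 1.0
        lam = -b + np.sqrt(np.maximum(b * b - c, 0.0))
        u_new = u_raw + lam[:, None] * dirs
        w = w + (lam / dt)[:, None] * dirs
        dirs = u_new

        disp = allpos - pos_ref
        if float(np.max(np.einsum("ij,ij->i", disp, disp))) \
                > (0.5 * cfg.neighbor_skin) ** 2:
            pairs = build_neighbor_pairs(allpos, cfg.box, cfg.periodic,
                                         rlist)
            pos_ref = allpos.copy()
        f, g, terms = _energy_terms(system, allpos, dirs, types, pid,
                                    pairs, springs)

        v += half * f * inv_m
        fu = -(g - np.sum(g * dirs, axis=1)[:, None] * dirs)
        w += half * fu * inv_i
        w -= np.sum(w * dirs, axis=1)[:, None] * dirs
        if thermostat:
            tk = kinetic_temperature(v, w, masses)
            s = np.exp(-xi * half)
            v *= s
            w *= s
            tk = kinetic_temperature(v, w, masses)
            xi += half * (tk / t0 - 1.0) / (tau * tau)

        if step % log_stride == 0 or step == n_steps:
            log_state(step)
        if step % snapshot_stride == 0 or step == n_steps:
            snapshot(step)

    system.lipid_pos = allpos[:nl].copy()
    system.lipid_dir = dirs.copy()
    system.unpack_proteins(allpos)
    log = pd.DataFrame(log_rows)
    return SimResult(log=log, snapshots=snapshots,
                     final_temperature=float(log["temperature"].iloc[-1]))
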