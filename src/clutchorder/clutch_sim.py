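"""Brownian-dynamics molecular-clutch simulation of nascent adhesion assembly.

A 1 um^2 membrane patch carries diffusing integrins 20 nm above an elastic,
ligand-coated substrate.  A free integrin that comes within the binding
radius of a free ligand may activate and bind (Bernoulli gate with
probability P_a); the engaged clutch is then convected with the actin
retrograde flow, stretching the substrate spring (k_sub = Y*A/L) and building
tension that (i) throttles the flow through the linear motor force-velocity
relation and (ii) sets the unbinding rates of the integrin-ligand bond and
of the force-recruited vinculin-actin bonds.  A clutch dissolves only when
the integrin bond and every vinculin bond are broken, at which point the
ligand is freed and the integrin resumes diffusion.

Both P_a and the probability P_v,+ that a vinculin follows the directional
(pointed-end) unbinding pathway ramp linearly with ligand density: 0.5 at
100 ligands/um^2 up to a configurable maximum at 200 ligands/um^2.

Two execution engines share these semantics: a compiled numba kernel
(default, used for full 300-s runs) and a pure-numpy reference loop built
from the step functions below (convenient for unit testing and inspection).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import warnings
from dataclasses import dataclass, field, asdict, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import kinetics
from .kinetics import (
    CatchSlipBond,
    VinculinRecruitmentRule,
    INTEGRIN_FIBRONECTIN,
    VINCULIN_DIRECTIONAL,
    VINCULIN_NONDIRECTIONAL,
    unbinding_probability,
    unbinding_rate,
    vinculin_count,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "ClutchEvent",
    "SimState",
    "substrate_stiffness",
    "probability_ramp",
    "flow_velocity",
    "initialize_state",
    "diffuse_free_integrins",
    "attempt_binding",
    "load_engaged_clutches",
    "attempt_unbinding",
    "run_simulation",
    "summarize",
    "sweep",
    "single_clutch_rupture_force",
    "single_clutch_rupture_forces",
]


# ---------------------------------------------------------------------------
# configuration and results
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Full parameterization of one clutch simulation.

    Units: young_modulus kPa; ligand_density ligands/um^2; domain_side um;
    gap and binding_radius nm; cross_section nm^2; diffusion um^2/s;
    kBT pN*nm; dt, duration, sample_interval, short_lived_cutoff s;
    unloaded_velocity um/s; stall_force pN.
    """

    young_modulus: float = 6.0
    ligand_density: float = 100.0
    n_integrins: int = 100
    p_a_max: float = 0.5          # activation-ramp value at n = 200
    p_vplus_max: float = 0.5      # directional-pathway-ramp value at n = 200
    domain_side: float = 1.0
    gap: float = 20.0
    cross_section: float = 80.0
    diffusion: float = 0.29
    kBT: float = 4.11
    dt: float = 1e-4
    duration: float = 300.0
    sample_interval: float = 1.0
    unloaded_velocity: float = 0.11
    n_motors: int = 135
    stall_force: float = 2.0
    binding_radius: float = 21.0
    short_lived_cutoff: float = 0.9
    force_model: str = "convective"  # or "literal_langevin"
    full_load_vinculin: bool = False  # share tension equally unless set
    burn_in: float = 0.0              # seconds discarded from summaries
    seed: int = 0
    integrin_bond: CatchSlipBond = INTEGRIN_FIBRONECTIN
    directional_bond: CatchSlipBond = VINCULIN_DIRECTIONAL
    nondirectional_bond: CatchSlipBond = VINCULIN_NONDIRECTIONAL
    recruitment: VinculinRecruitmentRule = field(default_factory=VinculinRecruitmentRule)

    def __post_init__(self) -> None:
        positive = (
            "young_modulus", "ligand_density", "domain_side", "gap",
            "cross_section", "diffusion", "dt", "duration", "sample_interval",
            "unloaded_velocity", "stall_force", "binding_radius",
            "short_lived_cutoff",
        )
        for name in positive:
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be strictly positive")
        if self.kBT < 0:
            raise ValueError("kBT must be non-negative")
        if self.n_integrins < 1 or self.n_motors < 1:
            raise ValueError("n_integrins and n_motors must be >= 1")
        if self.force_model not in ("convective", "literal_langevin"):
            raise ValueError(f"unknown force_model {self.force_model!r}")
        if self.burn_in < 0 or self.burn_in >= self.duration:
            raise ValueError("burn_in must lie in [0, duration)")

    @property
    def n_ligands_total(self) -> int:
        return int(round(self.ligand_density * self.domain_side**2))

    @property
    def friction(self) -> float:
        """Friction coefficient zeta = kBT/D in pN*s/um (kBT converted from pN*nm)."""
        return self.kBT * 1e-3 / self.diffusion

    @property
    def k_sub(self) -> float:
        return substrate_stiffness(self.young_modulus, self.cross_section, self.gap)

    @property
    def p_a(self) -> float:
        return probability_ramp(self.ligand_density, self.p_a_max)

    @property
    def p_vplus(self) -> float:
        return probability_ramp(self.ligand_density, self.p_vplus_max)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("integrin_bond", "directional_bond", "nondirectional_bond"):
            d[key] = asdict(getattr(self, key))
        d["recruitment"] = {
            "force_thresholds": list(self.recruitment.force_thresholds),
            "counts": list(self.recruitment.counts),
        }
        return d

    def config_hash(self) -> str:
        return hashlib.sha1(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:10]


@dataclass(frozen=True)
class ClutchEvent:
    """One completed engagement: bind/unbind times, lifetime, peak tension."""

    bind_time: float
    unbind_time: float
    peak_force: float

    @property
    def lifetime(self) -> float:
        return self.unbind_time - self.bind_time


@dataclass
class SimulationResult:
    """Time series, clutch-event log and summaries of one simulation."""

    config: SimulationConfig
    sampled_times: np.ndarray
    fraction_ligated: np.ndarray
    flow_velocity: np.ndarray
    event_bind_times: np.ndarray
    event_unbind_times: np.ndarray
    event_peak_forces: np.ndarray
    seed: int
    events_lost: int = 0

    @property
    def event_lifetimes(self) -> np.ndarray:
        return self.event_unbind_times - self.event_bind_times

    @property
    def events(self) -> list[ClutchEvent]:
        return [
            ClutchEvent(b, u, p)
            for b, u, p in zip(
                self.event_bind_times, self.event_unbind_times, self.event_peak_forces
            )
        ]

    @property
    def mean_fraction(self) -> float:
        keep = self.sampled_times > self.config.burn_in
        return float(np.mean(self.fraction_ligated[keep]))

    @property
    def short_lived_percent(self) -> float:
        """% of events shorter than the cutoff; NaN when no events completed."""
        lt = self.event_lifetimes
        if lt.size == 0:
            return float("nan")
        return 100.0 * float(np.mean(lt < self.config.short_lived_cutoff))


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def substrate_stiffness(young_modulus: float, cross_section: float = 80.0,
                        gap: float = 20.0) -> float:
    """Substrate spring constant k_sub = Y*A/L in pN/nm.

    ``young_modulus`` in kPa (1 kPa = 1e-3 pN/nm^2), ``cross_section`` in
    nm^2, ``gap`` in nm.
    """
    if young_modulus <= 0 or cross_section <= 0 or gap <= 0:
        raise ValueError("substrate_stiffness inputs must be strictly positive")
    return young_modulus * 1e-3 * cross_section / gap


def probability_ramp(ligand_density: float, p_max: float) -> float:
    """Ligand-density ramp: 0.5 at n = 100 rising linearly to p_max at n = 200.

    Densities outside [100, 200] are clamped with a warning; the result is
    clamped to [0.5, p_max].
    """
    if not (0.5 <= p_max <= 1.0):
        raise ValueError("p_max must lie in [0.5, 1]")
    n = ligand_density
    if n < 100.0 or n > 200.0:
        warnings.warn(
            f"ligand density {n} outside the ramp domain [100, 200]; clamping",
            stacklevel=2,
        )
        n = min(max(n, 100.0), 200.0)
    p = 0.5 + (p_max - 0.5) * (n - 100.0) / 100.0
    return min(max(p, 0.5), p_max)


def flow_velocity(total_clutch_force: float, v_u: float = 0.11,
                  n_motors: int = 135, stall_force: float = 2.0) -> float:
    """Motor-limited retrograde flow v_u*(1 - F_tot/(n_m*F_m)), clamped to [0, v_u]."""
    if total_clutch_force < 0:
        raise ValueError("total clutch force must be non-negative")
    v = v_u * (1.0 - total_clutch_force / (n_motors * stall_force))
    return min(max(v, 0.0), v_u)


# ---------------------------------------------------------------------------
# reference (numpy) state and step functions
# ---------------------------------------------------------------------------

@dataclass
class SimState:
    """Array-of-agents state shared by the reference step functions.

    ``lig[i] >= 0`` means integrin i is clutched to that ligand index;
    ``integrin_bound`` tracks the integrin-ligand bond within an engaged
    clutch (a clutch can persist on vinculins alone).
    """

    x: np.ndarray
    y: np.ndarray
    lig: np.ndarray
    anchor_x: np.ndarray
    stretch: np.ndarray          # nm
    integrin_bound: np.ndarray   # bool
    n_created: np.ndarray
    n_dir: np.ndarray
    n_nondir: np.ndarray
    bind_time: np.ndarray
    peak_force: np.ndarray
    lig_x: np.ndarray
    lig_y: np.ndarray
    occupied: np.ndarray         # bool per ligand
    time: float = 0.0

    @property
    def engaged(self) -> np.ndarray:
        return self.lig >= 0

    @property
    def n_clutched(self) -> int:
        return int(np.count_nonzero(self.engaged))

    def total_clutch_force(self, k_sub: float) -> float:
        return float(k_sub * self.stretch[self.engaged].sum())


def initialize_state(config: SimulationConfig, rng: np.random.Generator) -> SimState:
    """Uniform random ligand and integrin positions on the periodic patch."""
    n_lig = config.n_ligands_total
    n = config.n_integrins
    side = config.domain_side
    lig_xy = rng.random((n_lig, 2)) * side
    xy = rng.random((n, 2)) * side
    return SimState(
        x=xy[:, 0], y=xy[:, 1],
        lig=np.full(n, -1, dtype=np.int64),
        anchor_x=np.zeros(n),
        stretch=np.zeros(n),
        integrin_bound=np.zeros(n, dtype=bool),
        n_created=np.zeros(n, dtype=np.int64),
        n_dir=np.zeros(n, dtype=np.int64),
        n_nondir=np.zeros(n, dtype=np.int64),
        bind_time=np.zeros(n),
        peak_force=np.zeros(n),
        lig_x=lig_xy[:, 0], lig_y=lig_xy[:, 1],
        occupied=np.zeros(n_lig, dtype=bool),
    )


def diffuse_free_integrins(state: SimState, config: SimulationConfig,
                           rng: np.random.Generator) -> None:
    """Explicit-Euler thermal step for free integrins with periodic wrap.

    The displacement per axis is (F_T/zeta)*dt with Gaussian F_T of variance
    2*kBT*zeta/dt, i.e. std sqrt(2*D*dt); kBT = 0 switches thermal motion
    off.  Clutched agents are not thermally displaced in convective mode.
    """
    free = ~state.engaged
    n_free = int(np.count_nonzero(free))
    if n_free == 0 or config.kBT == 0:
        return
    sigma = math.sqrt(2.0 * config.diffusion * config.dt)
    side = config.domain_side
    state.x[free] = np.mod(state.x[free] + sigma * rng.standard_normal(n_free), side)
    state.y[free] = np.mod(state.y[free] + sigma * rng.standard_normal(n_free), side)


def _nearest_free_ligand(state: SimState, i: int, radius_um: float,
                         side: float) -> int:
    """Index of the nearest unoccupied ligand within radius, or -1.

    Ties in distance break toward the lowest ligand index.
    """
    dx = state.x[i] - state.lig_x
    dy = state.y[i] - state.lig_y
    dx -= side * np.round(dx / side)
    dy -= side * np.round(dy / side)
    d2 = dx * dx + dy * dy
    d2[state.occupied] = np.inf
    j = int(np.argmin(d2))  # argmin returns the first (lowest) index on ties
    if d2[j] <= radius_um * radius_um:
        return j
    return -1


def attempt_binding(state: SimState, config: SimulationConfig,
                    rng: np.random.Generator) -> None:
    """Activation + binding for free integrins near free ligands.

    Each free agent with at least one unoccupied ligand within the binding
    radius draws Bernoulli(P_a); on success it binds the nearest free ligand,
    the clutch starts at zero stretch and receives the zero-force vinculin
    set with pathways drawn Bernoulli(P_v,+).
    """
    p_a = config.p_a
    p_v = config.p_vplus
    radius_um = config.binding_radius * 1e-3
    side = config.domain_side
    base = vinculin_count(config.recruitment, 0.0)
    for i in np.flatnonzero(~state.engaged):
        j = _nearest_free_ligand(state, i, radius_um, side)
        if j < 0:
            continue
        if rng.random() >= p_a:
            continue
        state.lig[i] = j
        state.occupied[j] = True
        state.anchor_x[i] = state.x[i]
        state.stretch[i] = 0.0
        state.integrin_bound[i] = True
        state.bind_time[i] = state.time
        state.peak_force[i] = 0.0
        state.n_created[i] = base
        n_dir = int(np.count_nonzero(rng.random(base) < p_v))
        state.n_dir[i] = n_dir
        state.n_nondir[i] = base - n_dir


def load_engaged_clutches(state: SimState, config: SimulationConfig, v: float,
                          rng: np.random.Generator | None = None) -> None:
    """Build clutch tension from the actin flow.

    Convective mode: every engaged clutch is convected with the flow, so the
    stretch grows by v*dt.  Literal-Langevin mode: the engaged integrin moves
    under thermal force + flow drag - spring restoring force and the stretch
    is the (absolute) excursion from the binding anchor.
    """
    eng = state.engaged
    if not eng.any():
        return
    if config.force_model == "convective":
        state.stretch[eng] += v * config.dt * 1e3  # um/s -> nm
    else:
        zeta = config.friction
        k_sub = config.k_sub
        sigma = 0.0 if config.kBT == 0 else math.sqrt(2.0 * config.diffusion * config.dt)
        n_eng = int(np.count_nonzero(eng))
        thermal = sigma * (rng.standard_normal(n_eng) if rng is not None else 0.0)
        spring = k_sub * state.stretch[eng] * np.sign(
            state.x[eng] - state.anchor_x[eng])
        det = (zeta * v - spring) / zeta * config.dt
        side = config.domain_side
        state.x[eng] = np.mod(state.x[eng] + det + thermal, side)
        s = state.x[eng] - state.anchor_x[eng]
        s -= side * np.round(s / side)
        state.stretch[eng] = np.abs(s) * 1e3
    force = config.k_sub * state.stretch
    np.maximum(state.peak_force, np.where(eng, force, 0.0), out=state.peak_force)


def attempt_unbinding(state: SimState, config: SimulationConfig,
                      rng: np.random.Generator) -> list[ClutchEvent]:
    """Recruit vinculins, draw bond ruptures, dissolve fully broken clutches.

    Per engaged clutch: (1) top the vinculin list up to the force-band target
    (new recruits draw their pathway); (2) the integrin bond and each intact
    vinculin independently break with exact exponential per-step
    probabilities, vinculins sharing the tension equally unless
    ``full_load_vinculin``; (3) the clutch dissolves -- ligand freed, event
    logged -- only when the integrin bond and all vinculins are broken.
    Forces beyond the 200 pN cap rupture every bond deterministically.
    """
    events: list[ClutchEvent] = []
    dt = config.dt
    rule = config.recruitment
    p_v = config.p_vplus
    for i in np.flatnonzero(state.engaged):
        force = config.k_sub * state.stretch[i]
        if force > kinetics.FORCE_CAP_PN:
            state.integrin_bound[i] = False
            state.n_dir[i] = 0
            state.n_nondir[i] = 0
        else:
            target = vinculin_count(rule, force)
            if target > state.n_created[i]:
                extra = int(target - state.n_created[i])
                n_dir = int(np.count_nonzero(rng.random(extra) < p_v))
                state.n_dir[i] += n_dir
                state.n_nondir[i] += extra - n_dir
                state.n_created[i] = target
            if state.integrin_bound[i]:
                p = unbinding_probability(unbinding_rate(config.integrin_bond, force), dt)
                if rng.random() < p:
                    state.integrin_bound[i] = False
            n_intact = int(state.n_dir[i] + state.n_nondir[i])
            if n_intact > 0:
                share = force if config.full_load_vinculin else force / n_intact
                if state.n_dir[i] > 0:
                    p = unbinding_probability(
                        unbinding_rate(config.directional_bond, share), dt)
                    state.n_dir[i] -= rng.binomial(int(state.n_dir[i]), p)
                if state.n_nondir[i] > 0:
                    p = unbinding_probability(
                        unbinding_rate(config.nondirectional_bond, share), dt)
                    state.n_nondir[i] -= rng.binomial(int(state.n_nondir[i]), p)
        if not state.integrin_bound[i] and state.n_dir[i] + state.n_nondir[i] == 0:
            events.append(ClutchEvent(state.bind_time[i], state.time, state.peak_force[i]))
            state.occupied[state.lig[i]] = False
            state.lig[i] = -1
            state.stretch[i] = 0.0
    return events


# ---------------------------------------------------------------------------
# drivers
# ---------------------------------------------------------------------------

def _run_reference(config: SimulationConfig) -> SimulationResult:
    rng = np.random.default_rng(config.seed)
    state = initialize_state(config, rng)
    n_steps = int(round(config.duration / config.dt))
    samp_every = max(int(round(config.sample_interval / config.dt)), 1)
    times, fractions, vflows = [], [], []
    all_events: list[ClutchEvent] = []
    v = config.unloaded_velocity
    for step in range(n_steps):
        state.time = (step + 1) * config.dt
        v = flow_velocity(state.total_clutch_force(config.k_sub),
                          config.unloaded_velocity, config.n_motors,
                          config.stall_force)
        diffuse_free_integrins(state, config, rng)
        attempt_binding(state, config, rng)
        load_engaged_clutches(state, config, v, rng)
        all_events.extend(attempt_unbinding(state, config, rng))
        if (step + 1) % samp_every == 0:
            times.append(state.time)
            fractions.append(state.n_clutched / config.n_integrins)
            vflows.append(v)
    return SimulationResult(
        config=config,
        sampled_times=np.asarray(times),
        fraction_ligated=np.asarray(fractions),
        flow_velocity=np.asarray(vflows),
        event_bind_times=np.asarray([e.bind_time for e in all_events]),
        event_unbind_times=np.asarray([e.unbind_time for e in all_events]),
        event_peak_forces=np.asarray([e.peak_force for e in all_events]),
        seed=config.seed,
    )


def _run_fast(config: SimulationConfig) -> SimulationResult:
    from ._engine import _run_kernel

    rng = np.random.default_rng(config.seed)
    state = initialize_state(config, rng)
    n_steps = int(round(config.duration / config.dt))
    samp_every = max(int(round(config.sample_interval / config.dt)), 1)
    sigma = 0.0 if config.kBT == 0 else math.sqrt(2.0 * config.diffusion * config.dt)
    ev_cap = max(int(config.n_integrins * config.duration * 30), 10_000)
    ib, db, nb = (config.integrin_bond, config.directional_bond,
                  config.nondirectional_bond)
    th = config.recruitment.force_thresholds
    ct = config.recruitment.counts
    if len(th) != 3:
        # the compiled kernel is specialized to the 4-band recruitment rule
        return _run_reference(config)
    samp_t, frac, vflow, ev_b, ev_u, ev_p, lost = _run_kernel(
        config.seed & 0x7FFFFFFF,
        n_steps,
        config.dt,
        state.lig_x, state.lig_y,
        state.x, state.y,
        config.k_sub,
        config.p_a,
        config.p_vplus,
        config.binding_radius * 1e-3,
        config.unloaded_velocity,
        float(config.n_motors * config.stall_force),
        sigma,
        samp_every,
        config.domain_side,
        config.force_model == "convective",
        config.friction,
        ib.a1, ib.b1, ib.a2, ib.b2,
        db.a1, db.b1, db.a2, db.b2,
        nb.a1, nb.b1, nb.a2, nb.b2,
        th[0], th[1], th[2],
        ct[0], ct[1], ct[2], ct[3],
        config.full_load_vinculin,
        ev_cap,
    )
    if lost:
        warnings.warn(f"event log capacity exceeded; {lost} events uncounted")
    return SimulationResult(
        config=config,
        sampled_times=samp_t,
        fraction_ligated=frac,
        flow_velocity=vflow,
        event_bind_times=ev_b,
        event_unbind_times=ev_u,
        event_peak_forces=ev_p,
        seed=config.seed,
        events_lost=int(lost),
    )


def run_simulation(config: SimulationConfig, engine: str = "fast") -> SimulationResult:
    """Run one clutch simulation; fixed seed => bit-identical result.

    ``engine="fast"`` uses the compiled kernel, ``engine="reference"`` the
    pure-numpy step functions (identical semantics, different random
    streams, ~100x slower -- intended for short runs and testing).
    """
    if engine not in ("fast", "reference"):
        raise ValueError(f"unknown engine {engine!r}")
    n_steps = int(round(config.duration / config.dt))
    logger.info(
        "clutch run: config=%s seed=%d steps=%d engine=%s",
        config.config_hash(), config.seed, n_steps, engine,
    )
    if engine == "reference":
        return _run_reference(config)
    return _run_fast(config)


def summarize(result: SimulationResult) -> dict:
    """One flat summary row for a result (see sweep for the table layout)."""
    if result.sampled_times.size == 0:
        raise ValueError("result has no samples")
    keep = result.sampled_times > result.config.burn_in
    frac = result.fraction_ligated[keep]
    return {
        "Y_kPa": result.config.young_modulus,
        "n_per_um2": result.config.ligand_density,
        "Pa_max": result.config.p_a_max,
        "Pvplus_max": result.config.p_vplus_max,
        "seed": result.seed,
        "mean_fraction": float(np.mean(frac)),
        "sd_fraction": float(np.std(frac, ddof=1)) if frac.size > 1 else 0.0,
        "short_lived_pct": result.short_lived_percent,
        "mean_vflow": float(np.mean(result.flow_velocity[keep])),
        "n_events": int(result.event_bind_times.size),
    }


def sweep(configs: Iterable[SimulationConfig], n_replicates: int = 1,
          engine: str = "fast") -> pd.DataFrame:
    """Run a batch of configurations (seed, seed+1, ... per replicate).

    Returns one row per (config, replicate); a failed run yields a row with
    NaN summaries and the error message, and the sweep continues.
    """
    rows = []
    for cfg in configs:
        for rep in range(n_replicates):
            run_cfg = replace(cfg, seed=cfg.seed + rep)
            try:
                rows.append({**summarize(run_simulation(run_cfg, engine=engine)),
                             "error": ""})
            except Exception as exc:  # noqa: BLE001 - sweep must continue
                logger.warning("sweep run failed: %s", exc)
                rows.append({
                    "Y_kPa": run_cfg.young_modulus,
                    "n_per_um2": run_cfg.ligand_density,
                    "Pa_max": run_cfg.p_a_max,
                    "Pvplus_max": run_cfg.p_vplus_max,
                    "seed": run_cfg.seed,
                    "mean_fraction": float("nan"),
                    "sd_fraction": float("nan"),
                    "short_lived_pct": float("nan"),
                    "mean_vflow": float("nan"),
                    "n_events": 0,
                    "error": str(exc),
                })
    return pd.DataFrame(rows)


def single_clutch_rupture_force(bond: CatchSlipBond, loading_rate: float,
                                dt: float, rng: np.random.Generator,
                                f_max: float = 500.0) -> float:
    """Rupture force of one bond loaded at a constant rate (pN/s).

    Uses the simulator's per-step Bernoulli discretization: F = rate*t and
    the bond breaks with probability 1 - exp(-k_off(F)*dt) each step.  This
    is the single-clutch reduction of the engine used to cross-check the
    discretization against a Gillespie oracle.
    """
    f = 0.0
    while f < f_max:
        f += loading_rate * dt
        k = bond.a1 * math.exp(-bond.b1 * f) + bond.a2 * math.exp(bond.b2 * f)
        if rng.random() < -math.expm1(-k * dt):
            return f
    return f_max


def single_clutch_rupture_forces(bond: CatchSlipBond, loading_rate: float,
                                 dt: float, n_repeats: int, seed: int = 0,
                                 f_max: float = 500.0) -> np.ndarray:
    """Batch version of :func:`single_clutch_rupture_force` (compiled kernel)."""
    from ._engine import _rupture_forces

    return _rupture_forces(seed & 0x7FFFFFFF, n_repeats, loading_rate, dt,
                           bond.a1, bond.b1, bond.a2, bond.b2, f_max)
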