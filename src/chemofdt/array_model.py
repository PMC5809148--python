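"""Stochastic simulation of a clustered chemoreceptor array.

The model coarse-grains the receptor lattice into independent *signaling
teams* of N allosteric units (trimers of receptor dimers).  Each team is a
two-state (ON/OFF) variable switching as a telegraph process whose stationary
occupancy is the Boltzmann equilibrium of the team free energy and whose
relaxation time is the effective cluster response time ``tau_eff``.  With the
methylation enzymes switched off the process satisfies detailed balance, which
is what the fluctuation-dissipation validation of the analysis pipeline
requires.  CheR/CheB molecules from shared per-cell pools bind single teams
(CheR only inactive teams, CheB only active ones), (de)methylate them at rate
``k_cat`` while bound, and unbind at the first step the team changes state.
Cell activity is the mean ON fraction over teams, reported on a 1 s grid to
match the FRET acquisition rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ArrayModelParams",
    "TeamState",
    "ActivityTrace",
    "team_equilibrium_activity",
    "team_free_energy",
    "step_team",
    "simulate_cell",
    "simulate_ensemble",
]

# Per-step event probabilities above this are refused as under-resolved.
_MAX_EVENT_PROB = 0.2


@dataclass
class ArrayModelParams:
    """Parameters of the signaling-team array model (energies in k_B·T)."""

    N: int = 14                # allosteric units (trimers) per team
    N_T: int = 10_000          # receptor dimers per cell
    epsilon_m: float = 0.5     # free-energy decrement per methyl group per trimer
    m_max: int = 8             # max methylation level per trimer
    tau_eff: float = 10.0      # team response timescale, s
    sigma_F: float = 0.0       # OU free-energy noise amplitude, k_B·T per trimer
    tau_F: float = 10.0        # OU free-energy noise correlation time, s
    n_R: int = 140             # CheR molecules per cell
    n_B: int = 140             # CheB molecules per cell
    k_bind: float = 0.01       # binding rate per free enzyme per eligible team, 1/s
    k_cat: float = 0.3         # (de)methylation rate while bound, 1/s
    f0: float = 0.0            # baseline free energy per trimer, k_B·T
    dt: float = 0.05           # integration step, s

    @property
    def n_teams(self) -> int:
        return int(self.N_T // (3 * self.N))

    def validate(self) -> None:
        if self.N < 1 or self.N_T < 1:
            raise ValueError("N and N_T must be positive integers")
        if self.n_teams < 1:
            raise ValueError("N_T too small for one team of 3*N dimers")
        if 3 * self.N * self.n_teams > self.N_T:
            raise AssertionError("team partition exceeds receptor count")
        for name in ("tau_eff", "tau_F", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("k_bind", "k_cat"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_R < 0 or self.n_B < 0:
            raise ValueError("enzyme counts must be non-negative")
        if self.m_max < 0:
            raise ValueError("m_max must be >= 0")
        if self.dt > self.tau_eff / 10:
            raise ValueError("dt must be <= tau_eff/10")
        if self.dt / self.tau_eff > _MAX_EVENT_PROB:
            raise ValueError("switching probability per step > 0.2; reduce dt")
        if self.k_cat * self.dt > _MAX_EVENT_PROB:
            raise ValueError("catalysis probability per step > 0.2; reduce dt")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_teams"] = self.n_teams
        return d


@dataclass
class TeamState:
    """State of a single signaling team (scalar form, used by step_team)."""

    active: int = 0
    m: int = 0
    bound_enzyme: str = "none"  # one of none / R / B
    F: float = 0.0              # current team free energy, k_B·T
    eta: float = 0.0            # OU free-energy noise per trimer


@dataclass
class ActivityTrace:
    """Per-cell activity time series on a uniform 1 s grid."""

    time: np.ndarray
    A: np.ndarray
    n_bound_R: np.ndarray
    n_bound_B: np.ndarray
    seed: int | None = None
    params: ArrayModelParams | None = None

    def __post_init__(self):
        if len(self.A) != len(self.time):
            raise ValueError("A and time must have equal length")


def team_equilibrium_activity(F):
    """Equilibrium ON probability of a team with free energy ``F`` (k_B·T).

    A_eq = 1 / (1 + exp(F)); strictly decreasing in F.
    """
    F = np.asarray(F, dtype=float)
    if not np.all(np.isfinite(F)):
        raise ValueError("free energy must be finite")
    out = 1.0 / (1.0 + np.exp(np.clip(F, -700.0, 700.0)))
    return float(out) if out.ndim == 0 else out


def team_free_energy(m, epsilon_m, f0, L_term, eta, N, m_max=8):
    """Team free energy N·(f0 − m·epsilon_m + L_term + eta) in k_B·T.

    ``m`` is the methylation level per trimer; the factor N implements the
    allosteric amplification of per-trimer free-energy changes at team level.
    """
    m = np.asarray(m)
    if np.any(m < 0) or np.any(m > m_max):
        raise ValueError("methylation level out of [0, m_max]")
    out = N * (f0 - m * epsilon_m + L_term + eta)
    return float(out) if np.ndim(out) == 0 else out


def _ou_update(eta, dt, tau, sigma, rng):
    """Exact one-step update of a stationary OU process."""
    phi = math.exp(-dt / tau)
    return eta * phi + sigma * math.sqrt(1.0 - phi * phi) * rng.standard_normal(
        np.shape(eta)
    )


def step_team(state: TeamState, params: ArrayModelParams, L_term: float,
              dt: float, rng: np.random.Generator,
              free_R: int = 0, free_B: int = 0) -> tuple[TeamState, int, int]:
    """Advance a single team by one step; returns (state, free_R, free_B).

    Scalar reference implementation of the update used (vectorized) by
    :func:`simulate_cell`.  Event order: OU noise -> free energy -> switching
    -> enzyme unbinding -> catalysis -> enzyme binding.
    """
    if dt > params.tau_eff / 10:
        raise ValueError("dt must be <= tau_eff/10")
    s = TeamState(state.active, state.m, state.bound_enzyme, state.F, state.eta)
    if params.sigma_F > 0:
        s.eta = float(_ou_update(s.eta, dt, params.tau_F, params.sigma_F, rng))
    s.F = team_free_energy(s.m, params.epsilon_m, params.f0, L_term, s.eta,
                           params.N, params.m_max)
    a_eq = team_equilibrium_activity(s.F)
    p_on = a_eq * dt / params.tau_eff
    p_off = (1.0 - a_eq) * dt / params.tau_eff
    p_bind_R = 1.0 - (1.0 - params.k_bind * dt) ** max(free_R, 0)
    p_bind_B = 1.0 - (1.0 - params.k_bind * dt) ** max(free_B, 0)
    if max(p_on, p_off, params.k_cat * dt, p_bind_R, p_bind_B) > _MAX_EVENT_PROB:
        raise ValueError("event probability per step > 0.2; dt too coarse")
    u = rng.random()
    if s.active == 0 and u < p_on:
        s.active = 1
    elif s.active == 1 and u < p_off:
        s.active = 0
    # unbind at the first step the team state no longer matches the enzyme
    if s.bound_enzyme == "R" and s.active == 1:
        s.bound_enzyme = "none"
        free_R += 1
    elif s.bound_enzyme == "B" and s.active == 0:
        s.bound_enzyme = "none"
        free_B += 1
    if s.bound_enzyme == "R" and rng.random() < params.k_cat * dt:
        s.m = min(s.m + 1, params.m_max)
    elif s.bound_enzyme == "B" and rng.random() < params.k_cat * dt:
        s.m = max(s.m - 1, 0)
    if s.bound_enzyme == "none":
        if s.active == 0 and free_R > 0 and rng.random() < p_bind_R:
            s.bound_enzyme = "R"
            free_R -= 1
        elif s.active == 1 and free_B > 0 and rng.random() < p_bind_B:
            s.bound_enzyme = "B"
            free_B -= 1
    return s, free_R, free_B


def _resolve_protocol(protocol, duration: float) -> Callable[[float], float]:
    """Return L_term(t) in k_B·T per trimer from a protocol description.

    Accepts None (L=0), a callable t -> L, or an object with ``events`` as an
    ordered list of (time_s, L_term) pairs (levels held until the next event).
    """
    if protocol is None:
        return lambda t: 0.0
    if callable(protocol):
        return protocol
    events = list(getattr(protocol, "events", protocol))
    times = np.array([e[0] for e in events], dtype=float)
    levels = np.array([float(e[1]) for e in events], dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("protocol event times must be strictly increasing")
    if np.any(times < 0) or np.any(times > duration):
        raise ValueError("protocol times outside [0, duration]")

    def L_of_t(t: float) -> float:
        idx = np.searchsorted(times, t, side="right") - 1
        return 0.0 if idx < 0 else float(levels[idx])

    return L_of_t


def simulate_cell(params: ArrayModelParams, protocol=None, duration: float = 400.0,
                  rng=None, m0: int | None = None, burn_in: float = 0.0) -> ActivityTrace:
    """Simulate one cell; thin wrapper over :func:`simulate_ensemble`."""
    return simulate_ensemble(params, protocol, duration, rng, n_cells=1,
                             m0=m0, burn_in=burn_in)[0]


def simulate_ensemble(params: ArrayModelParams, protocol=None,
                      duration: float = 400.0, rng=None, n_cells: int = 1,
                      f0_cells: Sequence[float] | None = None,
                      m0: int | None = None,
                      burn_in: float = 0.0) -> list[ActivityTrace]:
    """Simulate ``n_cells`` cells sharing parameters (vectorized over teams).

    All teams of a cell share the CheR/CheB pools; ``f0_cells`` optionally
    gives per-cell baseline free energies (cell-to-cell variability).
    ``burn_in`` seconds are simulated and discarded before recording.
    """
    params.validate()
    if duration < 10 * params.tau_eff:
        raise ValueError("duration must be >= 10*tau_eff")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(rng)
    seed = None
    L_of_t = _resolve_protocol(protocol, duration)

    nt = params.n_teams
    dt = params.dt
    n_out = int(round(duration))
    sub = max(int(round(1.0 / dt)), 1)
    n_steps = int(round((burn_in + duration) / dt))
    record_from = int(round(burn_in / dt))

    f0 = np.full(n_cells, params.f0, dtype=float)
    if f0_cells is not None:
        f0 = np.asarray(f0_cells, dtype=float)
        if f0.shape != (n_cells,):
            raise ValueError("f0_cells must have length n_cells")
    f0 = f0[:, None]

    if m0 is None:
        m0 = params.m_max // 2 if (params.n_R or params.n_B) else 0
    m = np.full((n_cells, nt), int(m0), dtype=np.int16)
    eta = np.zeros((n_cells, nt))
    if params.sigma_F > 0:
        eta = params.sigma_F * rng.standard_normal((n_cells, nt))
    L0 = L_of_t(0.0)
    F = params.N * (f0 - m * params.epsilon_m + L0 + eta)
    active = rng.random((n_cells, nt)) < team_equilibrium_activity(F)
    bound = np.zeros((n_cells, nt), dtype=np.int8)  # 0 none, 1 R, 2 B
    free_R = np.full(n_cells, params.n_R, dtype=np.int64)
    free_B = np.full(n_cells, params.n_B, dtype=np.int64)

    A_out = np.empty((n_cells, n_out))
    nR_out = np.empty((n_cells, n_out), dtype=np.int64)
    nB_out = np.empty((n_cells, n_out), dtype=np.int64)

    phi = math.exp(-dt / params.tau_F)
    ou_amp = params.sigma_F * math.sqrt(1.0 - phi * phi)
    p_cat = params.k_cat * dt
    enzymes = (params.n_R > 0 or params.n_B > 0) and params.k_bind > 0
    i_out = 0
    for step in range(n_steps):
        t = (step - record_from) * dt  # protocol clock starts after burn-in
        if params.sigma_F > 0:
            eta = eta * phi + ou_amp * rng.standard_normal((n_cells, nt))
        L = L_of_t(max(t, 0.0))
        F = params.N * (f0 - m * params.epsilon_m + L + eta)
        a_eq = team_equilibrium_activity(F)
        u = rng.random((n_cells, nt))
        p_on = a_eq * (dt / params.tau_eff)
        p_off = (1.0 - a_eq) * (dt / params.tau_eff)
        flip = np.where(active, u < p_off, u < p_on)
        active = active ^ flip

        if enzymes:
            # unbind enzymes whose team no longer matches their substrate state
            rel_R = (bound == 1) & active
            rel_B = (bound == 2) & ~active
            free_R += rel_R.sum(axis=1)
            free_B += rel_B.sum(axis=1)
            bound[rel_R | rel_B] = 0
            # catalysis while bound
            cat = rng.random((n_cells, nt)) < p_cat
            np.minimum(m + ((bound == 1) & cat), params.m_max, out=m,
                       casting="unsafe")
            np.maximum(m - ((bound == 2) & cat), 0, out=m, casting="unsafe")
            # binding from the shared free pools
            for which, free, substrate_inactive in ((1, free_R, True),
                                                    (2, free_B, False)):
                eligible = (bound == 0) & (active != substrate_inactive)
                p_bind = 1.0 - np.power(1.0 - params.k_bind * dt,
                                        free.astype(float))[:, None]
                if np.any(p_bind > _MAX_EVENT_PROB):
                    raise ValueError(
                        "binding probability per step > 0.2; dt too coarse")
                hit = eligible & (rng.random((n_cells, nt)) < p_bind)
                n_hit = hit.sum(axis=1)
                over = n_hit > free
                if np.any(over):
                    for c in np.nonzero(over)[0]:
                        idx = np.nonzero(hit[c])[0]
                        keep = rng.choice(idx, size=int(free[c]), replace=False)
                        hit[c] = False
                        hit[c, keep] = True
                    n_hit = hit.sum(axis=1)
                bound[hit] = which
                free -= n_hit

        if step >= record_from and (step - record_from) % sub == sub - 1:
            A_out[:, i_out] = active.mean(axis=1)
            nR_out[:, i_out] = (bound == 1).sum(axis=1)
            nB_out[:, i_out] = (bound == 2).sum(axis=1)
            i_out += 1
    assert i_out == n_out

    time = np.arange(1, n_out + 1, dtype=float)
    return [
        ActivityTrace(time=time.copy(), A=A_out[c].copy(),
                      n_bound_R=nR_out[c].copy(), n_bound_B=nB_out[c].copy(),
                      seed=seed, params=params)
        for c in range(n_cells)
    ]
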