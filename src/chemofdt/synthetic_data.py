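"""Synthetic single-cell FRET ensembles emulating the strains and conditions
of the chemosensory noise study.

Two backends generate traces:

* a *phenomenological* generator producing the FRET ratio directly as
  R_t = (μ + λ·a(t) + λ·scale(t)·x_t)·(1 − bleach·t) + w_t, with x_t a
  stationary OU process (correlation time τ, variance V_A), w_t white
  measurement shot noise, and a(t) the deterministic activity level set by a
  stimulation protocol.  Fluctuations are scaled by √(4a(1−a)) so they vanish
  at zero and full activity and have variance V_A at a = 1/2, emulating the
  two-state origin of the noise.  The ratio is an unbounded Gaussian: the
  measured activity variance at intermediate activity (0.46) exceeds what any
  [0,1]-bounded variable can produce, so amplitude-calibrated fixtures must
  generate at the ratio level.
* the mechanistic :mod:`~chemofdt.array_model`, rendered to FRET via R = λA+μ.

``make_fixture`` exposes named, seeded ensembles (wild-type in buffer,
adaptation-deficient variants, cluster-disruption CheW-X2, receptorless and
bead controls, and mechanistic counterparts).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .array_model import ArrayModelParams, ActivityTrace, simulate_ensemble
from .processes import adaptation_filter, adaptation_gain_sq, ou_series

__all__ = [
    "StimulusProtocol",
    "FRETTrace",
    "Ensemble",
    "GeneratorParams",
    "generate_phenomenological_trace",
    "render_fret_from_activity",
    "make_fixture",
    "make_step_response_pair",
    "meas_p_free_energy",
    "FIXTURES",
    "SHOT_SIGMA",
    "EPSILON_N2",
]

# Shot-noise calibration: a flat per-bin PSD level of eps_n^2 = 0.9e-3 on a
# unit-mean ratio sampled at 1 Hz corresponds to white noise of std
# sqrt(0.9e-3) per frame (two-sided discrete PSD of white noise = sigma^2).
EPSILON_N2 = 0.9e-3
SHOT_SIGMA = math.sqrt(EPSILON_N2)

# MeAsp -> free energy per trimer, standard two-dissociation-constant
# log-ratio form; K values are conventions of this package (config-only).
MEASP_KI_UM = 18.0
MEASP_KA_UM = 2900.0


@dataclass
class StimulusProtocol:
    """Ordered stimulus events: (time_s, level) with level either a free
    energy in k_B·T per trimer (float) or a labeled token such as
    'MeAsp 30 uM' or 'buffer' resolved through a fixture mapping."""

    events: list
    flow_delay_s: float = 0.0

    def __post_init__(self):
        times = [e[0] for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")

    def validate_duration(self, duration: float) -> None:
        if any(not (0 <= e[0] <= duration) for e in self.events):
            raise ValueError("protocol times outside [0, duration]")

    def windows(self, duration: float):
        """Yield (label, t_start, t_end) for each constant-stimulus window."""
        ev = list(self.events)
        for i, (t0, level) in enumerate(ev):
            t1 = ev[i + 1][0] if i + 1 < len(ev) else duration
            yield level, float(t0), float(t1)


@dataclass
class FRETTrace:
    """One cell's FRET time series on a 1 Hz grid."""

    time: np.ndarray
    ratio: np.ndarray
    cfp: np.ndarray | None = None
    yfp: np.ndarray | None = None
    cell_id: str = ""
    fixture_name: str = ""
    seed: int | None = None

    def __post_init__(self):
        if np.any(np.asarray(self.ratio) <= 0):
            raise ValueError("FRET ratio must be positive; parameters unphysical")
        if self.cfp is not None and self.yfp is not None:
            if not np.allclose(self.ratio, np.asarray(self.yfp) / np.asarray(self.cfp),
                               rtol=0, atol=1e-12):
                raise ValueError("ratio must equal yfp/cfp")


@dataclass
class Ensemble:
    """A named collection of traces plus the metadata analyses need."""

    traces: list
    fixture_name: str = ""
    seed: int | None = None
    protocol: StimulusProtocol | None = None
    activity_map: dict | None = None
    duration: float = 0.0
    params: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.traces)

    def __len__(self):
        return len(self.traces)


@dataclass
class GeneratorParams:
    """Phenomenological FRET-ratio generator parameters."""

    lam: float = 0.10        # FRET-ratio change per unit activity
    mu: float = 1.0          # zero-activity baseline ratio
    A_bar: float = 0.5       # mean activity
    V_A: float = 0.46        # stationary activity-fluctuation variance (at A=1/2)
    tau: float = 9.5         # fluctuation correlation time, s
    shot_sigma: float = SHOT_SIGMA  # white measurement noise std of the ratio
    bleach_rate: float = 0.0        # fractional ratio drift per s

    def __post_init__(self):
        if self.lam <= 0 or self.V_A < 0 or self.tau <= 0 or self.shot_sigma < 0:
            raise ValueError("invalid generator parameters")


def meas_p_free_energy(conc_um: float, ki_um: float = MEASP_KI_UM,
                       ka_um: float = MEASP_KA_UM) -> float:
    """MeAsp concentration -> ligand free energy per trimer (k_B·T),
    two-K log-ratio form ln((1+c/K_I)/(1+c/K_A))."""
    if conc_um < 0:
        raise ValueError("concentration must be >= 0")
    return math.log((1.0 + conc_um / ki_um) / (1.0 + conc_um / ka_um))


def _token_concentration(token) -> float:
    """Parse 'MeAsp 30 uM'-style tokens; 'buffer' -> 0."""
    if isinstance(token, (int, float)):
        raise TypeError("numeric levels are free energies, not tokens")
    if token == "buffer":
        return 0.0
    m = re.match(r"MeAsp\s+([0-9.]+)\s*[uµ]M", str(token))
    if not m:
        raise ValueError(f"unknown stimulus token: {token!r}")
    return float(m.group(1))


def resolve_level_activity(level, activity_map, default):
    if isinstance(level, (int, float)):
        return float(level)
    if activity_map is None or level not in activity_map:
        raise ValueError(f"no activity mapping for stimulus token {level!r}")
    return float(activity_map[level])


def _activity_profile(protocol, duration, A_bar, activity_map):
    """Deterministic activity level a(t) on the 1 Hz grid."""
    n = int(round(duration))
    a = np.full(n, A_bar, dtype=float)
    if protocol is None:
        return a
    protocol.validate_duration(duration)
    t = np.arange(n, dtype=float)
    for level, t0, t1 in protocol.windows(duration):
        a[(t >= t0) & (t < t1)] = resolve_level_activity(level, activity_map, A_bar)
    if protocol.flow_delay_s > 0:
        # exponential smoothing of solution exchange in the flow chamber
        phi = math.exp(-1.0 / protocol.flow_delay_s)
        for i in range(1, n):
            a[i] = phi * a[i - 1] + (1 - phi) * a[i]
    return a


def generate_phenomenological_trace(params: GeneratorParams,
                                    protocol: StimulusProtocol | None = None,
                                    duration: float = 1800.0,
                                    rng=None,
                                    activity_map: dict | None = None,
                                    cell_id: str = "",
                                    fixture_name: str = "") -> FRETTrace:
    """Generate one synthetic FRET-ratio trace (see module docstring)."""
    if duration < 10 * params.tau:
        raise ValueError("duration must be >= 10*tau")
    rng = np.random.default_rng(rng)
    n = int(round(duration))
    t = np.arange(n, dtype=float)
    a = _activity_profile(protocol, duration, params.A_bar, activity_map)
    scale = np.sqrt(np.clip(4.0 * a * (1.0 - a), 0.0, None))
    x = ou_series(n, 1.0, params.tau, params.V_A, rng) if params.V_A > 0 else np.zeros(n)
    r = (params.mu + params.lam * (a + scale * x)) * (1.0 - params.bleach_rate * t)
    if params.shot_sigma > 0:
        r = r + params.shot_sigma * rng.standard_normal(n)
    return FRETTrace(time=t, ratio=r, cell_id=cell_id, fixture_name=fixture_name)


def render_fret_from_activity(activity: ActivityTrace, params: GeneratorParams,
                              rng=None, channels: bool = False,
                              c0: float = 100.0, beta: float = 0.0,
                              channel_noise: float = 0.0,
                              cell_id: str = "", fixture_name: str = "") -> FRETTrace:
    """Render a mechanistic activity trace to a FRET ratio, R = λA + μ + w."""
    rng = np.random.default_rng(rng)
    a = np.asarray(activity.A, dtype=float)
    n = len(a)
    r = params.lam * a + params.mu
    if params.bleach_rate:
        r = r * (1.0 - params.bleach_rate * np.asarray(activity.time))
    if params.shot_sigma > 0:
        r = r + params.shot_sigma * rng.standard_normal(n)
    cfp = yfp = None
    if channels:
        cfp = c0 * np.exp(-beta * np.asarray(activity.time))
        if channel_noise > 0:
            cfp = cfp * (1.0 + channel_noise * rng.standard_normal(n))
        yfp = r * cfp
    return FRETTrace(time=np.asarray(activity.time, float), ratio=r,
                     cfp=cfp, yfp=yfp, cell_id=cell_id, fixture_name=fixture_name)


# ---------------------------------------------------------------------------
# fixture registry

# Two-step sorting/λ-estimation protocol: buffer (full activity) -> 30 µM
# (intermediate) -> buffer -> 100 µM (saturating, zero activity) -> buffer.
QEQE_PROTOCOL = StimulusProtocol(events=[
    (0.0, "buffer"),
    (300.0, "MeAsp 30 uM"),
    (740.0, "buffer"),
    (1040.0, "MeAsp 100 uM"),
    (1340.0, "buffer"),
])
QEQE_ACTIVITY = {"buffer": 1.0, "MeAsp 30 uM": 0.5, "MeAsp 100 uM": 0.0}

# Imposed adaptation parameters of the wild-type-like paired fixtures; the
# adaptation rate is the printed angular rate (rad/s), i.e. ω_RB/2π ≈ 0.0095 Hz.
WT_OMEGA_RB = 0.06
WT_ALPHA = 0.1
_PAIR_TAU = 34.0    # passive (thermal) correlation time shared by the pair, s
_PAIR_V_TH = 0.25   # thermal activity variance of the passive member
_WT_VAR_TOTAL = 0.46  # total activity variance of the adapted member


def _filtered_thermal_variance(tau: float, v: float, omega_rb: float,
                               alpha: float) -> float:
    """Variance of OU(τ, V) after the adaptation filter (analytic integral)."""
    def integrand(w):
        s_th = 2.0 * v * tau / (1.0 + (w * tau) ** 2)
        return adaptation_gain_sq(w, omega_rb, alpha) * s_th / (2.0 * math.pi)
    val, _ = quad(integrand, 0, np.inf, limit=200)
    return 2.0 * val  # integrand is even


def _phenom_builder(gp: GeneratorParams, protocol=None, activity_map=None,
                    duration=1800.0):
    def build(n_cells, rng, dur=None):
        dur = duration if dur is None else dur
        seeds = rng.spawn(n_cells)
        traces = [
            generate_phenomenological_trace(
                gp, protocol, dur, seeds[i], activity_map,
                cell_id=f"cell{i:04d}")
            for i in range(n_cells)
        ]
        return traces, protocol, activity_map, dur, {"generator": vars(gp).copy()}
    return build


def _adaptation_on_builder(duration=1800.0):
    """Adapted (enzymes-on) phenomenological ensemble: thermal OU through the
    adaptation filter plus a methylation component whose spectrum
    ∝ ω²/(ω²+ω_RB²)² peaks at ω = ω_RB."""
    var_t = _filtered_thermal_variance(_PAIR_TAU, _PAIR_V_TH, WT_OMEGA_RB, WT_ALPHA)
    v_raw = 2.0 * max(_WT_VAR_TOTAL - var_t, 0.0)  # high-pass halves OU variance

    def build(n_cells, rng, dur=None):
        dur = duration if dur is None else dur
        n = int(round(dur))
        t = np.arange(n, dtype=float)
        traces = []
        for i, child in enumerate(rng.spawn(n_cells)):
            r = np.random.default_rng(child)
            x_th = ou_series(n, 1.0, _PAIR_TAU, _PAIR_V_TH, r)
            y_th = adaptation_filter(x_th, 1.0, WT_OMEGA_RB, WT_ALPHA)
            m_raw = ou_series(n, 1.0, 1.0 / WT_OMEGA_RB, v_raw, r)
            y_m = adaptation_filter(m_raw, 1.0, WT_OMEGA_RB, 0.0)
            ratio = 1.0 + 0.10 * (0.5 + y_th + y_m) \
                + SHOT_SIGMA * r.standard_normal(n)
            traces.append(FRETTrace(time=t.copy(), ratio=ratio,
                                    cell_id=f"cell{i:04d}"))
        meta = {"omega_rb": WT_OMEGA_RB, "alpha": WT_ALPHA, "tau": _PAIR_TAU,
                "V_thermal": _PAIR_V_TH, "V_total": _WT_VAR_TOTAL}
        return traces, None, None, dur, meta
    return build


def _mech_builder(mp: ArrayModelParams, protocol=None, duration=1800.0,
                  gp: GeneratorParams | None = None, burn_in=0.0,
                  f0_spread=0.0):
    gp = gp or GeneratorParams(V_A=0.0)

    def build(n_cells, rng, dur=None):
        dur = duration if dur is None else dur
        sim_rng, render_rng = rng.spawn(2)
        f0_cells = None
        if f0_spread > 0:
            f0_cells = mp.f0 + f0_spread * (
                np.random.default_rng(sim_rng).random(n_cells) - 0.5) * 2
            sim_rng, = sim_rng.spawn(1)
        acts = simulate_ensemble(mp, protocol, dur,
                                 np.random.default_rng(sim_rng),
                                 n_cells=n_cells, f0_cells=f0_cells,
                                 burn_in=burn_in)
        seeds = render_rng.spawn(n_cells)
        traces = [
            render_fret_from_activity(a, gp, seeds[i], cell_id=f"cell{i:04d}")
            for i, a in enumerate(acts)
        ]
        meta = {"array_model": mp.to_dict(), "generator": vars(gp).copy()}
        return traces, protocol, None, dur, meta, acts
    return build


def _receptorless_builder(shot=SHOT_SIGMA, duration=1800.0):
    gp = GeneratorParams(A_bar=0.0, V_A=0.0, tau=1.0, shot_sigma=shot)

    def build(n_cells, rng, dur=None):
        dur = duration if dur is None else dur
        traces = [
            generate_phenomenological_trace(gp, None, dur, s,
                                            cell_id=f"cell{i:04d}")
            for i, s in enumerate(rng.spawn(n_cells))
        ]
        return traces, None, None, dur, {"generator": vars(gp).copy()}
    return build


def _beads_builder(shot=0.01, duration=1800.0):
    def build(n_cells, rng, dur=None):
        dur = duration if dur is None else dur
        n = int(round(dur))
        t = np.arange(n, dtype=float)
        traces = []
        for i, child in enumerate(rng.spawn(n_cells)):
            r = np.random.default_rng(child)
            ratio = 1.0 + shot * r.standard_normal(n)
            cfp = np.full(n, 200.0)
            traces.append(FRETTrace(time=t.copy(), ratio=ratio, cfp=cfp,
                                    yfp=ratio * cfp, cell_id=f"cell{i:04d}"))
        return traces, None, None, dur, {"shot_sigma": shot}
    return build


FIXTURES = {
    # phenomenological strains/conditions
    "wt_buffer": _phenom_builder(
        GeneratorParams(A_bar=0.5, V_A=0.46, tau=9.5)),
    "wt_buffer_bleach": _phenom_builder(
        GeneratorParams(A_bar=0.5, V_A=0.46, tau=9.5, bleach_rate=2e-5)),
    "rb_minus_intermediate": _phenom_builder(
        GeneratorParams(A_bar=0.5, V_A=0.25, tau=34.0)),
    "rb_minus_qeqe_protocol": _phenom_builder(
        GeneratorParams(A_bar=1.0, V_A=0.25, tau=34.0),
        protocol=QEQE_PROTOCOL, activity_map=QEQE_ACTIVITY, duration=1640.0),
    "chewx2": _phenom_builder(
        GeneratorParams(A_bar=0.5, V_A=0.0, tau=9.5),
        protocol=None),
    "receptorless": _receptorless_builder(),
    "beads": _beads_builder(),
    "adaptation_off_paired": _phenom_builder(
        GeneratorParams(A_bar=0.5, V_A=_PAIR_V_TH, tau=_PAIR_TAU)),
    "adaptation_on_paired": _adaptation_on_builder(),
    # mechanistic variants (rendered with λ=0.10, μ=1.0 and calibrated shot)
    "mech_equilibrium": _mech_builder(
        ArrayModelParams(n_R=0, n_B=0, tau_eff=10.0, f0=0.0),
        gp=GeneratorParams(V_A=0.0)),
    "mech_rb_minus": _mech_builder(
        ArrayModelParams(n_R=0, n_B=0, tau_eff=34.0, f0=0.0),
        gp=GeneratorParams(V_A=0.0)),
    "mech_wt": _mech_builder(
        ArrayModelParams(tau_eff=10.0, f0=0.0),
        gp=GeneratorParams(V_A=0.0), burn_in=200.0),
    "mech_chewx2": _mech_builder(
        ArrayModelParams(N=2, tau_eff=1.0, n_R=0, n_B=0, f0=0.0),
        gp=GeneratorParams(V_A=0.0)),
}


def make_fixture(name: str, n_cells: int, rng=None,
                 duration: float | None = None,
                 return_activity: bool = False) -> Ensemble:
    """Build a named, seeded fixture ensemble.

    Identical (name, n_cells, seed) give bit-identical traces.  ``duration``
    overrides the fixture default (protocol fixtures keep their own).
    """
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture: {name!r}; known: {sorted(FIXTURES)}")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    seed = int(rng) if isinstance(rng, (int, np.integer)) else None
    ss = rng if isinstance(rng, np.random.SeedSequence) else np.random.SeedSequence(seed)
    out = FIXTURES[name](n_cells, ss, duration)
    traces, protocol, amap, dur, meta = out[:5]
    for tr in traces:
        tr.fixture_name = name
    ens = Ensemble(traces=traces, fixture_name=name, seed=seed,
                   protocol=protocol, activity_map=amap, duration=dur,
                   params=meta)
    if return_activity:
        return ens, (out[5] if len(out) > 5 else None)
    return ens


def make_step_response_pair(n_cells: int, rng=None, tau: float = _PAIR_TAU,
                            omega_rb: float = WT_OMEGA_RB, alpha: float = WT_ALPHA,
                            epsilon0: float = 0.04, N: int = 14,
                            A_mean: float = 0.5, lam: float = 0.10,
                            mu: float = 1.0, shot: float = SHOT_SIGMA,
                            t_stim: float = 150.0, duration: float = 650.0):
    """Synthetic step-response ensembles: a passive (enzymes-off) exponential
    response and its adaptation-filtered (enzymes-on) counterpart.

    Passive: ΔA(t) = −N·A(1−A)·ε0·(1 − e^{−(t−t0)/τ}) for t ≥ t0; the adapted
    trace is the same drive passed through H(ω) = (iω+α·ω_RB)/(iω+ω_RB).
    """
    seed = int(rng) if isinstance(rng, (int, np.integer)) else None
    ss = np.random.SeedSequence(seed)
    n = int(round(duration))
    t = np.arange(n, dtype=float)
    x_a = N * A_mean * (1.0 - A_mean)
    da = np.where(t >= t_stim,
                  -x_a * epsilon0 * (1.0 - np.exp(-(t - t_stim) / tau)), 0.0)
    da_plus = adaptation_filter(da, 1.0, omega_rb, alpha)
    minus, plus = [], []
    for i, child in enumerate(ss.spawn(n_cells)):
        r = np.random.default_rng(child)
        for da_k, bucket in ((da, minus), (da_plus, plus)):
            ratio = mu + lam * (A_mean + da_k) + shot * r.standard_normal(n)
            bucket.append(FRETTrace(time=t.copy(), ratio=ratio,
                                    cell_id=f"cell{i:04d}"))
    meta = dict(tau=tau, omega_rb=omega_rb, alpha=alpha, epsilon0=epsilon0,
                N=N, A_mean=A_mean, lam=lam, t_stim=t_stim)
    return (Ensemble(minus, "step_minus", seed, None, None, duration, meta),
            Ensemble(plus, "step_plus", seed, None, None, duration, meta))
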