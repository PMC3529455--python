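"""Stimulus construction and fixed-step integration of the coupled network.

All neurons are advanced simultaneously with a fixed time step (forward Euler
by default, dt = 0.02 ms; classical RK4 is available as an accuracy oracle).
Gap-junction currents are evaluated from the same-step voltages.  The hot
loop is compiled with numba; a plain-numpy backend that calls the reference
right-hand side in :mod:`gapcpg.model_core` is kept for cross-checking.

The stimulus is a per-neuron square current pulse with independently jittered
onset/offset (normal draws, negative onsets clamped to zero — the jitter
stands in for axonal delay spread) and optional white noise redrawn at every
time step, uniform on [-noise_halfwidth, +noise_halfwidth].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace

import numpy as np
from numba import njit

from .model_core import ModelParams, NeuronState, membrane_rhs, steady_state
from .network import GapNetwork, gap_currents

__all__ = [
    "StimulusProtocol",
    "SimulationResult",
    "build_stimulus",
    "run_simulation",
    "detect_spikes",
    "single_neuron_fI",
    "reduced_protocol",
]

SPIKE_THRESHOLD = 0.0   # mV, upward crossing
SPIKE_LOCKOUT = 2.0     # ms


@dataclass(frozen=True)
class StimulusProtocol:
    """Square-wave current protocol with per-neuron onset/offset jitter.

    ``onset_jitter``/``offset_jitter`` are standard deviations of normal
    draws around the means; negative onsets are clamped to 0 ms.  Gap
    junctions conduct only inside [gap_open_time, gap_close_time] (the
    defaults keep them open for the whole run).

    ``amplitude`` and ``noise_halfwidth`` are given on the scale the
    stimulus values are quoted on (0.08-0.1 nA for the reduced model);
    ``amplitude_scale`` converts them to the nA of the voltage equation.
    The default of 100 reconciles the quoted stimulus scale with the uS/nF
    membrane: the quoted values sit two orders of magnitude below the
    ~6.4 nA rheobase those conductances imply, and a gain of 100 places
    them exactly in the narrow suprathreshold window (7.5-11 nA) where the
    neuron fires tonically — 0.08 and 0.1 land just above rheobase, which
    is where a near-threshold pattern generator must operate.
    """

    amplitude: float
    noise_halfwidth: float = 0.0
    amplitude_scale: float = 100.0
    onset_mean: float = 100.0
    onset_jitter: float = 200.0
    offset_mean: float = 1400.0
    offset_jitter: float = 0.0
    gap_open_time: float = -math.inf
    gap_close_time: float = math.inf
    seed: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def reduced_protocol(amplitude: float = 0.1, seed: int | None = None,
                     **overrides) -> StimulusProtocol:
    """Published reduced-model drive: constant square pulse over 100+-200 ms
    to 1400 ms, no step noise, gap junctions open throughout."""
    return StimulusProtocol(amplitude=amplitude, seed=seed, **overrides)


@dataclass
class SimulationResult:
    """Traces and spike raster of one network run.

    ``V_traces`` is (n_neurons, n_samples) float32 at the integration step;
    ``spikes`` is a (K, 2) array of (neuron index, spike time ms) rows sorted
    by time.  ``aux_traces`` optionally holds the AHP gate and calcium
    traces.  ``config`` is a JSON-compatible snapshot sufficient to re-run.
    """

    time: np.ndarray
    V_traces: np.ndarray
    spikes: np.ndarray
    config: dict
    aux_traces: dict | None = None

    @property
    def n_neurons(self) -> int:
        return self.V_traces.shape[0]

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def spike_times(self, neuron: int) -> np.ndarray:
        sel = self.spikes[:, 0] == neuron
        return self.spikes[sel, 1]

    def save_raster(self, path) -> None:
        np.savetxt(path, self.spikes, fmt=["%d", "%.4f"],
                   header="neuron_id spike_time_ms")


def build_stimulus(protocol: StimulusProtocol, n_neurons: int,
                   time_grid: np.ndarray, seed: int | None = None,
                   ) -> np.ndarray:
    """Per-neuron input current on a uniform time grid, shape (T, N) in nA.

    Onset/offset are drawn once per neuron; the white-noise term is redrawn
    independently for every neuron at every step while the pulse is on.
    """
    time_grid = np.asarray(time_grid, dtype=float)
    if time_grid.size > 1:
        steps = np.diff(time_grid)
        if not np.allclose(steps, steps[0]):
            raise ValueError("time grid must be uniform")
    rng = np.random.default_rng(protocol.seed if seed is None else seed)
    onsets = rng.normal(protocol.onset_mean, protocol.onset_jitter, n_neurons)
    onsets = np.maximum(onsets, 0.0)
    offsets = rng.normal(protocol.offset_mean, protocol.offset_jitter,
                         n_neurons)
    eps = float(steps[0]) if time_grid.size > 1 else 1e-9
    offsets = np.maximum(offsets, onsets + eps)  # offset strictly after onset
    on = (time_grid[:, None] >= onsets[None, :]) \
        & (time_grid[:, None] < offsets[None, :])
    I = np.where(on, protocol.amplitude, 0.0)
    if protocol.noise_halfwidth > 0:
        noise = rng.uniform(-protocol.noise_halfwidth,
                            protocol.noise_halfwidth,
                            size=(time_grid.size, n_neurons))
        I = I + np.where(on, noise, 0.0)
    return I * protocol.amplitude_scale


# ----------------------------------------------------------------- numba core

@njit(cache=True)
def _rhs_nb(V, n, p, z, Ca, Irow, gahp, gapon, indptr, indices, g_gap,
            gl, gna, gk, gca, el, ena, ek, eca, cm,
            cais, cadr, zhalf, zhill, taun, tauz, mslope,
            dV, dn, dp, dz, dCa):
    N = V.shape[0]
    for i in range(N):
        vi = V[i]
        igap = 0.0
        if gapon:
            s = 0.0
            for k in range(indptr[i], indptr[i + 1]):
                s += vi - V[indices[k]]
            igap = g_gap * s
        minf = 1.0 / (1.0 + math.exp((-26.5 - vi) / mslope))
        ica = gca * p[i] * (vi - eca)
        dV[i] = (Irow[i] - gl * (vi - el) - gna * minf * (vi - ena)
                 - gk * n[i] * (vi - ek) - ica
                 - gahp * z[i] * (vi - ek) - igap) / cm
        ninf = 1.0 / (1.0 + math.exp((-20.0 - vi) / 5.0))
        pinf = 1.0 / (1.0 + math.exp((-40.0 - vi) / 5.0))
        taup = 6.0 / (1.0 + math.exp((55.0 + vi) / 2.0)) + 0.5
        ca = Ca[i]
        zinf = 1.0 / (1.0 + (zhalf / ca) ** zhill) if ca > 0.0 else 0.0
        dn[i] = (ninf - n[i]) / taun
        dp[i] = (pinf - p[i]) / taup
        dz[i] = (zinf - z[i]) / tauz
        dCa[i] = -cais * ica - cadr * ca


@njit(cache=True)
def _clamp_nb(n, p, z, Ca):
    for i in range(n.shape[0]):
        n[i] = min(max(n[i], 0.0), 1.0)
        p[i] = min(max(p[i], 0.0), 1.0)
        z[i] = min(max(z[i], 0.0), 1.0)
        Ca[i] = max(Ca[i], 0.0)


@njit(cache=True)
def _integrate_nb(V, n, p, z, Ca, I_stim, gahp_t, gap_on, indptr, indices,
                  g_gap, dt, gl, gna, gk, gca, el, ena, ek, eca, cm,
                  cais, cadr, zhalf, zhill, taun, tauz, mslope,
                  use_rk4, record_aux):
    T, N = I_stim.shape
    Vtr = np.empty((T + 1, N), dtype=np.float32)
    n_aux = T + 1 if record_aux else 0
    Ztr = np.empty((n_aux, N), dtype=np.float32)
    Catr = np.empty((n_aux, N), dtype=np.float32)
    Vtr[0] = V.astype(np.float32)
    if record_aux:
        Ztr[0] = z.astype(np.float32)
        Catr[0] = Ca.astype(np.float32)

    dV = np.empty(N); dn = np.empty(N); dp = np.empty(N)
    dz = np.empty(N); dCa = np.empty(N)
    # RK4 scratch
    aV = np.empty(N); an = np.empty(N); ap = np.empty(N)
    az = np.empty(N); aCa = np.empty(N)
    kV = np.empty(N); kn = np.empty(N); kp = np.empty(N)
    kz = np.empty(N); kCa = np.empty(N)

    bad_i = -1
    bad_t = -1
    for t in range(T):
        Irow = I_stim[t]
        gahp = gahp_t[t]
        gapon = gap_on[t]
        if not use_rk4:
            _rhs_nb(V, n, p, z, Ca, Irow, gahp, gapon, indptr, indices,
                    g_gap, gl, gna, gk, gca, el, ena, ek, eca, cm,
                    cais, cadr, zhalf, zhill, taun, tauz, mslope,
                    dV, dn, dp, dz, dCa)
            for i in range(N):
                V[i] += dt * dV[i]
                n[i] += dt * dn[i]
                p[i] += dt * dp[i]
                z[i] += dt * dz[i]
                Ca[i] += dt * dCa[i]
        else:
            # k1
            _rhs_nb(V, n, p, z, Ca, Irow, gahp, gapon, indptr, indices,
                    g_gap, gl, gna, gk, gca, el, ena, ek, eca, cm,
                    cais, cadr, zhalf, zhill, taun, tauz, mslope,
                    dV, dn, dp, dz, dCa)
            for i in range(N):
                kV[i] = dV[i]; kn[i] = dn[i]; kp[i] = dp[i]
                kz[i] = dz[i]; kCa[i] = dCa[i]
                aV[i] = V[i] + 0.5 * dt * dV[i]
                an[i] = n[i] + 0.5 * dt * dn[i]
                ap[i] = p[i] + 0.5 * dt * dp[i]
                az[i] = z[i] + 0.5 * dt * dz[i]
                aCa[i] = Ca[i] + 0.5 * dt * dCa[i]
            # k2
            _rhs_nb(aV, an, ap, az, aCa, Irow, gahp, gapon, indptr, indices,
                    g_gap, gl, gna, gk, gca, el, ena, ek, eca, cm,
                    cais, cadr, zhalf, zhill, taun, tauz, mslope,
                    dV, dn, dp, dz, dCa)
            for i in range(N):
                kV[i] += 2.0 * dV[i]; kn[i] += 2.0 * dn[i]
                kp[i] += 2.0 * dp[i]; kz[i] += 2.0 * dz[i]
                kCa[i] += 2.0 * dCa[i]
                aV[i] = V[i] + 0.5 * dt * dV[i]
                an[i] = n[i] + 0.5 * dt * dn[i]
                ap[i] = p[i] + 0.5 * dt * dp[i]
                az[i] = z[i] + 0.5 * dt * dz[i]
                aCa[i] = Ca[i] + 0.5 * dt * dCa[i]
            # k3
            _rhs_nb(aV, an, ap, az, aCa, Irow, gahp, gapon, indptr, indices,
                    g_gap, gl, gna, gk, gca, el, ena, ek, eca, cm,
                    cais, cadr, zhalf, zhill, taun, tauz, mslope,
                    dV, dn, dp, dz, dCa)
            for i in range(N):
                kV[i] += 2.0 * dV[i]; kn[i] += 2.0 * dn[i]
                kp[i] += 2.0 * dp[i]; kz[i] += 2.0 * dz[i]
                kCa[i] += 2.0 * dCa[i]
                aV[i] = V[i] + dt * dV[i]
                an[i] = n[i] + dt * dn[i]
                ap[i] = p[i] + dt * dp[i]
                az[i] = z[i] + dt * dz[i]
                aCa[i] = Ca[i] + dt * dCa[i]
            # k4
            _rhs_nb(aV, an, ap, az, aCa, Irow, gahp, gapon, indptr, indices,
                    g_gap, gl, gna, gk, gca, el, ena, ek, eca, cm,
                    cais, cadr, zhalf, zhill, taun, tauz, mslope,
                    dV, dn, dp, dz, dCa)
            for i in range(N):
                V[i] += dt / 6.0 * (kV[i] + dV[i])
                n[i] += dt / 6.0 * (kn[i] + dn[i])
                p[i] += dt / 6.0 * (kp[i] + dp[i])
                z[i] += dt / 6.0 * (kz[i] + dz[i])
                Ca[i] += dt / 6.0 * (kCa[i] + dCa[i])
        _clamp_nb(n, p, z, Ca)
        Vtr[t + 1] = V.astype(np.float32)
        if record_aux:
            Ztr[t + 1] = z.astype(np.float32)
            Catr[t + 1] = Ca.astype(np.float32)
        if t % 250 == 0:
            for i in range(N):
                if not np.isfinite(V[i]):
                    bad_i = i
                    bad_t = t
                    break
            if bad_i >= 0:
                break
    return bad_i, bad_t, Vtr, Ztr, Catr


# ---------------------------------------------------------------- numpy core

def _integrate_np(state: NeuronState, params: ModelParams,
                  I_stim: np.ndarray, gahp_t: np.ndarray,
                  gap_on: np.ndarray, network: GapNetwork, dt: float,
                  use_rk4: bool) -> np.ndarray:
    """Reference integrator driving :func:`model_core.membrane_rhs` directly;
    slow, used to validate the compiled kernel."""
    T, N = I_stim.shape
    Vtr = np.empty((T + 1, N), dtype=np.float32)
    s = state.as_arrays()
    V, n, p, z, Ca = (np.array(np.broadcast_to(x, N)) for x in
                      (s.V, s.n, s.p, s.z, s.Ca))
    Vtr[0] = V

    def rhs(V, n, p, z, Ca, t):
        pars = params if gahp_t[t] == params.g_AHP \
            else params.replace(g_AHP=float(gahp_t[t]))
        I_gap = gap_currents(V, network) if gap_on[t] else np.zeros(N)
        d = membrane_rhs(NeuronState(V, n, p, z, Ca), pars,
                         I_input=I_stim[t], I_gap=I_gap)
        return d.V, d.n, d.p, d.z, d.Ca

    for t in range(T):
        k1 = rhs(V, n, p, z, Ca, t)
        if use_rk4:
            y = (V, n, p, z, Ca)
            k2 = rhs(*(a + 0.5 * dt * b for a, b in zip(y, k1)), t)
            k3 = rhs(*(a + 0.5 * dt * b for a, b in zip(y, k2)), t)
            k4 = rhs(*(a + dt * b for a, b in zip(y, k3)), t)
            incr = [dt / 6.0 * (a + 2 * b + 2 * c + d)
                    for a, b, c, d in zip(k1, k2, k3, k4)]
        else:
            incr = [dt * a for a in k1]
        V = V + incr[0]
        n = np.clip(n + incr[1], 0.0, 1.0)
        p = np.clip(p + incr[2], 0.0, 1.0)
        z = np.clip(z + incr[3], 0.0, 1.0)
        Ca = np.maximum(Ca + incr[4], 0.0)
        Vtr[t + 1] = V
    return Vtr


def detect_spikes(V_traces: np.ndarray, time: np.ndarray,
                  threshold: float = SPIKE_THRESHOLD,
                  lockout: float = SPIKE_LOCKOUT) -> np.ndarray:
    """Spike raster from voltage traces: upward threshold crossings with a
    refractory lockout.  Returns (K, 2) rows (neuron, time ms) sorted by time.
    """
    V = np.asarray(V_traces)
    rows = []
    for i in range(V.shape[0]):
        up = np.flatnonzero((V[i, :-1] < threshold)
                            & (V[i, 1:] >= threshold)) + 1
        if up.size:
            t = time[up]
            keep = [0]
            for k in range(1, t.size):
                if t[k] - t[keep[-1]] >= lockout:
                    keep.append(k)
            for k in keep:
                rows.append((i, t[k]))
    if not rows:
        return np.empty((0, 2))
    out = np.array(rows, dtype=float)
    return out[np.argsort(out[:, 1], kind="stable")]


def _ahp_series(params: ModelParams, time_grid: np.ndarray,
                ahp_schedule) -> np.ndarray:
    g0 = params.g_AHP
    if ahp_schedule is None:
        return np.full(time_grid.size, g0)
    if callable(ahp_schedule):
        return np.array([float(ahp_schedule(t)) for t in time_grid])
    t0, t1 = ahp_schedule  # linear ramp g_AHP -> 0 over [t0, t1], 0 after
    frac = np.clip((time_grid - t0) / max(t1 - t0, 1e-9), 0.0, 1.0)
    return g0 * (1.0 - frac)


def run_simulation(params: ModelParams, network: GapNetwork,
                   protocol: StimulusProtocol, dt: float = 0.02,
                   t_end: float = 1500.0, method: str = "euler",
                   seed: int | None = None, record_aux: bool = False,
                   ahp_schedule=None, initial_state: NeuronState | None = None,
                   backend: str = "numba") -> SimulationResult:
    """Integrate the coupled network and return traces plus spike raster.

    Reproducible from (seed, config): the stimulus RNG is seeded with
    ``protocol.seed`` when set, else with ``seed``.  ``ahp_schedule`` may be
    ``(ramp_start, ramp_end)`` for a linear g_AHP ramp to zero, or a callable
    t -> g_AHP.  Aborts with a diagnostic naming the first neuron whose
    voltage went non-finite.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if method not in ("euler", "rk4"):
        raise ValueError("method must be 'euler' or 'rk4'")
    n_steps = int(round(t_end / dt))
    step_times = np.arange(n_steps) * dt
    stim_seed = protocol.seed if protocol.seed is not None else seed
    I_stim = build_stimulus(protocol, network.n_neurons, step_times,
                            seed=stim_seed)
    gahp_t = _ahp_series(params, step_times, ahp_schedule)
    gap_on = ((step_times >= protocol.gap_open_time)
              & (step_times <= protocol.gap_close_time)).astype(np.uint8)
    state = (initial_state or steady_state(params.E_leak, params=params)) \
        .as_arrays()
    N = network.n_neurons
    V0, n0, p0, z0, Ca0 = (np.array(np.broadcast_to(x, N), dtype=float)
                           for x in (state.V, state.n, state.p,
                                     state.z, state.Ca))
    time = np.arange(n_steps + 1) * dt

    if backend == "numpy":
        Vtr = _integrate_np(NeuronState(V0, n0, p0, z0, Ca0), params, I_stim,
                            gahp_t, gap_on, network, dt, method == "rk4")
        aux = None
    elif backend == "numba":
        indptr, indices = network.neighbor_csr()
        bad_i, bad_t, Vtr, Ztr, Catr = _integrate_nb(
            V0, n0, p0, z0, Ca0, I_stim, gahp_t, gap_on,
            indptr, indices, float(network.g_gap), float(dt),
            params.g_leak, params.g_Na, params.g_K, params.g_Ca,
            params.E_leak, params.E_Na, params.E_K, params.E_Ca,
            params.C_m, params.ca_influx_scale, params.ca_decay_rate,
            params.z_half_ca, params.z_hill, params.tau_n, params.tau_z,
            params.m_slope, method == "rk4", record_aux)
        if bad_i >= 0:
            raise FloatingPointError(
                f"voltage of neuron {bad_i} became non-finite near "
                f"t = {bad_t * dt:.2f} ms")
        aux = {"z": Ztr.T, "Ca": Catr.T} if record_aux else None
    else:
        raise ValueError("backend must be 'numba' or 'numpy'")

    V_traces = Vtr.T
    if not np.all(np.isfinite(V_traces)):
        bad = np.argwhere(~np.isfinite(Vtr))
        raise FloatingPointError(
            f"voltage of neuron {bad[0, 1]} became non-finite near "
            f"t = {bad[0, 0] * dt:.2f} ms")
    spikes = detect_spikes(V_traces, time)
    config = {
        "params": params.to_dict(),
        "protocol": protocol.to_dict(),
        "network": {"n_neurons": network.n_neurons,
                    "n_edges": network.n_edges,
                    "g_gap": network.g_gap, "seed": network.seed,
                    "radius": network.radius},
        "dt": dt, "t_end": t_end, "method": method, "seed": seed,
        "stimulus_seed": stim_seed, "backend": backend,
        "ahp_ramp": list(ahp_schedule)
        if isinstance(ahp_schedule, (tuple, list)) else None,
    }
    return SimulationResult(time=time, V_traces=V_traces, spikes=spikes,
                            config=config, aux_traces=aux)


def single_neuron_fI(params: ModelParams, I_values, dt: float = 0.02,
                     t_end: float = 2000.0) -> np.ndarray:
    """Steady-state firing rate (Hz) of one uncoupled neuron per current.

    The rate is counted over the last half of a ``t_end`` run with a constant
    un-jittered current step from t = 0; 0 Hz when no spikes occur there.
    """
    I_values = np.atleast_1d(np.asarray(I_values, dtype=float))
    net = GapNetwork(1, np.empty((0, 2), dtype=np.int64), g_gap=0.0)
    rates = np.empty(I_values.size)
    for k, I in enumerate(I_values):
        proto = StimulusProtocol(amplitude=float(I), onset_mean=0.0,
                                 onset_jitter=0.0, offset_mean=t_end + 1.0,
                                 offset_jitter=0.0, seed=0)
        res = run_simulation(params, net, proto, dt=dt, t_end=t_end)
        t = res.spikes[:, 1] if res.spikes.size else np.empty(0)
        n = int(np.sum(t >= t_end / 2.0))
        rates[k] = n / (t_end / 2.0) * 1000.0
    return rates
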