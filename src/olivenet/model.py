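"""Conductance-based 3x3 inferior-olive network model.

Each model neuron has a soma (Na, delayed-rectifier K, low-threshold Ca,
h-current), a dendrite (high-threshold Ca, Ca-gated K) and four glomerular
spine compartments.  Spines carry the gap junctions (conductance ``g_c``,
drawn per junction within +-20% of the configured mean) and a GABAergic
conductance ``g_i`` that shunts junctional current and thereby sets the
effective coupling between neighbours.  The kinetics follow the classic
olivary soma/dendrite formulation with the sodium conductance raised to
110 mS/cm^2, which places the coupled network in a chaotic firing regime.

Synaptic noise: soma, dendrite and spines receive 10, 80 and 10 excitatory
and inhibitory synapses each, driven by independent Poisson generators.
Inhibitory input rates of 10/20/50/70 Hz define the four candidate models
used by the Bayesian model-averaging inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from . import _kernel
from .dataset import SpikeDataset

__all__ = [
    "NeuronParams",
    "NetworkConfig",
    "NetworkModel",
    "SimulationResult",
    "CCProtocolSpec",
    "build_network",
    "simulate",
    "coupling_coefficient_protocol",
    "run_parameter_grid",
    "grid_values",
]


@dataclass
class NeuronParams:
    """Per-neuron biophysical parameters (conductances in mS/cm^2).

    ``g_Na``, ``g_s`` and the varied ``g_i``/``g_c`` follow the study design;
    the remaining channel densities are the canonical olivary values.  The
    GABAergic conductance splits into a tonic shunt (``tonic_fraction * g_i``,
    present also without synaptic noise, as probed by the coupling-coefficient
    protocol) and a phasic part gating the spine inhibitory synapses.
    """

    g_Na: float = 110.0          # somatic Na, raised to the chaotic regime
    g_Kdr: float = 18.0          # somatic delayed rectifier
    g_Ca_l: float = 1.6          # somatic low-threshold Ca
    g_h: float = 0.25            # somatic h-current
    g_Ca_h: float = 4.5          # dendritic high-threshold Ca
    g_K_Ca: float = 35.0         # dendritic Ca-gated K
    g_leak: float = 0.015
    g_int: float = 0.25          # soma-dendrite axial, ref units
    g_s: float = 0.1             # spine axial conductance, fixed
    g_i: float = 1.15            # GABAergic spine conductance (varied)
    tonic_fraction: float = 0.1   # tonic share of g_i (calibration, see docs)
    spine_inh_gain: float = 0.45  # phasic spine IPSP amplitude per event / g_i
    C_m: float = 1.0             # uF/cm^2
    E_Na: float = 55.0
    E_K: float = -75.0
    E_Ca: float = 120.0
    E_h: float = -43.0
    E_leak: float = 10.0         # combined-leak reversal of the olivary model
    E_gaba: float = -63.0        # glomerular GABA-A reversal
    p_soma: float = 0.2          # compartment area fractions
    p_dend: float = 0.7
    p_spine: float = 0.1         # all four spines together
    spine_scale: float = 1.1     # glomerular coupling scale (calibration)

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name.startswith(("g_", "C_", "p_")) or f.name in (
                    "tonic_fraction", "spine_inh_gain"):
                v = getattr(self, f.name)
                if v < 0:
                    raise ValueError(f"{f.name} must be >= 0, got {v}")
        if not np.isclose(self.p_soma + self.p_dend + self.p_spine, 1.0):
            raise ValueError("compartment area fractions must sum to 1")


@dataclass
class NetworkConfig:
    """Network topology, heterogeneity and synaptic-noise settings."""

    shape: tuple[int, int] = (3, 3)
    mean_g_c: float = 1.19       # mS/cm^2, per-junction mean
    heterogeneity: float = 0.2   # uniform +-20% of the mean, per junction
    boundary: str = "open"       # 'open' | 'periodic'
    n_syn: tuple[int, int, int] = (10, 80, 10)  # soma/dendrite/spines
    excit_rate: float = 20.0     # Hz per synapse
    inhib_rate: float = 20.0     # Hz per synapse; models use {10,20,50,70}
    syn_amp_exc: float = 0.007   # local mS/cm^2 per event (calibrated)
    syn_amp_inh: float = 0.001
    cal_heterogeneity: float = 0.3   # per-neuron spread of g_Ca_l (natural
                                     # oscillation frequencies are detuned)
    tau_exc: float = 1.0         # ms
    tau_inh: float = 5.0         # ms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_g_c < 0:
            raise ValueError(f"mean_g_c must be >= 0, got {self.mean_g_c}")
        if not 0 <= self.heterogeneity <= 1:
            raise ValueError("heterogeneity must be in [0, 1]")
        if self.boundary not in ("open", "periodic"):
            raise ValueError(f"unknown boundary mode {self.boundary!r}")


def _grid_edges(shape: tuple[int, int], boundary: str) -> np.ndarray:
    """Edge list of the rectangular grid (4-neighbour connectivity)."""
    nr, nc = shape
    idx = lambda r, c: r * nc + c
    edges = []
    for r in range(nr):
        for c in range(nc):
            if c + 1 < nc:
                edges.append((idx(r, c), idx(r, c + 1)))
            elif boundary == "periodic" and nc > 2:
                edges.append((idx(r, c), idx(r, 0)))
            if r + 1 < nr:
                edges.append((idx(r, c), idx(r + 1, c)))
            elif boundary == "periodic" and nr > 2:
                edges.append((idx(r, c), idx(0, c)))
    return np.array(sorted(set(map(tuple, map(sorted, edges)))), dtype=np.int32)


@dataclass
class NetworkModel:
    """A built network: parameters plus realized per-junction conductances."""

    params: NeuronParams
    config: NetworkConfig
    edges: np.ndarray            # (E, 2) cell indices
    edge_g_c: np.ndarray         # (E,) realized junction conductances
    g_ca_l: np.ndarray = None    # (n,) realized per-neuron Ca_l conductances

    @property
    def n_cells(self) -> int:
        return self.config.shape[0] * self.config.shape[1]

    @property
    def degree(self) -> np.ndarray:
        d = np.zeros(self.n_cells, dtype=np.int32)
        for a, b in self.edges:
            d[a] += 1
            d[b] += 1
        return d

    @property
    def center_cell(self) -> int:
        nr, nc = self.config.shape
        return (nr // 2) * nc + nc // 2


@dataclass
class SimulationResult:
    dataset: SpikeDataset
    voltages: np.ndarray | None  # (n_cells, T) somatic voltage, mV
    voltage_dt: float | None     # s between recorded samples
    edge_g_c: np.ndarray = field(default_factory=lambda: np.empty(0))
    seed: int = 0


def build_network(neuron_params: NeuronParams, net_config: NetworkConfig) -> NetworkModel:
    """Draw per-junction gap conductances and assemble the network.

    Junction values are uniform in ``mean * (1 +- heterogeneity)``;
    deterministic given ``net_config.seed``.
    """
    edges = _grid_edges(net_config.shape, net_config.boundary)
    rng = np.random.default_rng(net_config.seed)
    lo = net_config.mean_g_c * (1.0 - net_config.heterogeneity)
    hi = net_config.mean_g_c * (1.0 + net_config.heterogeneity)
    edge_g_c = rng.uniform(lo, hi, size=len(edges))
    n = net_config.shape[0] * net_config.shape[1]
    het = net_config.cal_heterogeneity
    g_ca_l = neuron_params.g_Ca_l * rng.uniform(1.0 - het, 1.0 + het, size=n)
    return NetworkModel(neuron_params, net_config, edges, edge_g_c, g_ca_l)


def _pack_params(m: NetworkModel) -> np.ndarray:
    p, c = m.params, m.config
    P = np.zeros(_kernel.NPAR)
    P[_kernel.P_C] = p.C_m
    P[_kernel.P_GNA] = p.g_Na
    P[_kernel.P_GKDR] = p.g_Kdr
    P[_kernel.P_GCAL] = p.g_Ca_l
    P[_kernel.P_GH] = p.g_h
    P[_kernel.P_GCAH] = p.g_Ca_h
    P[_kernel.P_GKCA] = p.g_K_Ca
    P[_kernel.P_GL] = p.g_leak
    P[_kernel.P_EL] = p.E_leak
    P[_kernel.P_ENA] = p.E_Na
    P[_kernel.P_EK] = p.E_K
    P[_kernel.P_ECA] = p.E_Ca
    P[_kernel.P_EH] = p.E_h
    P[_kernel.P_EGABA] = p.E_gaba
    P[_kernel.P_GINT] = p.g_int
    P[_kernel.P_PS] = p.p_soma
    P[_kernel.P_PD] = p.p_dend
    P[_kernel.P_PSP] = p.spine_scale
    P[_kernel.P_GS] = p.g_s
    P[_kernel.P_GI_TONIC] = p.tonic_fraction * p.g_i
    P[_kernel.P_GI] = p.g_i
    P[_kernel.P_TAUE] = c.tau_exc
    P[_kernel.P_TAUI] = c.tau_inh
    P[_kernel.P_AMPE] = c.syn_amp_exc
    P[_kernel.P_AMPI] = c.syn_amp_inh
    P[_kernel.P_RATEE] = c.excit_rate
    P[_kernel.P_RATEI] = c.inhib_rate
    P[_kernel.P_NSYN_S] = c.n_syn[0]
    P[_kernel.P_NSYN_D] = c.n_syn[1]
    P[_kernel.P_NSYN_SP] = c.n_syn[2]
    P[_kernel.P_SP_INH_GAIN] = p.spine_inh_gain
    P[_kernel.P_EE] = 0.0
    P[_kernel.P_EI] = -75.0
    return P


_DT_STABILITY_BOUND = 0.2  # ms; forward-Euler voltage update limit


def simulate(
    model: NetworkModel,
    duration: float,
    dt: float = 0.05,
    seed: int = 0,
    noise: bool = True,
    record_voltage: bool = False,
    voltage_stride: int = 20,
    i_base: np.ndarray | None = None,
    i_step: np.ndarray | None = None,
    step_window: tuple[float, float] = (0.0, 0.0),
    spike_threshold: float = -20.0,
    refractory: float = 10.0,
) -> SimulationResult:
    """Integrate the network for ``duration`` seconds.

    ``dt`` is the integration step in milliseconds (exponential Euler on the
    gating variables, forward Euler on the voltages).  Somatic spikes are
    upward crossings of ``spike_threshold`` (mV) with a ``refractory`` (ms)
    lockout.  Holding/step currents (uA/cm^2, somatic) enable the
    coupling-coefficient protocol.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if dt > _DT_STABILITY_BOUND:
        raise ValueError(
            f"dt={dt} ms exceeds the stability bound {_DT_STABILITY_BOUND} ms")
    n = model.n_cells
    rng = np.random.default_rng(seed)
    v_init = -60.0 + rng.uniform(-3.0, 3.0, size=n)
    zeros = np.zeros(n)
    res = _kernel.run_network(
        n, model.edges, model.edge_g_c, model.degree, _pack_params(model),
        model.g_ca_l,
        duration * 1e3, dt, int(seed) % (2 ** 31), noise, v_init,
        i_base if i_base is not None else zeros,
        i_step if i_step is not None else zeros,
        step_window[0] * 1e3, step_window[1] * 1e3,
        voltage_stride if record_voltage else 0,
        spike_threshold, refractory,
    )
    sp_t, sp_id, v_rec, fail_t = res
    if fail_t >= 0:
        raise FloatingPointError(
            f"numerical divergence at t = {fail_t * 1e-3:.3f} s")
    trains = {i: sp_t[sp_id == i] * 1e-3 for i in range(n)}
    ds = SpikeDataset(trains, duration, meta={
        "g_i": model.params.g_i, "mean_g_c": model.config.mean_g_c,
        "inhib_rate": model.config.inhib_rate, "seed": seed, "dt_ms": dt,
    })
    return SimulationResult(
        dataset=ds,
        voltages=v_rec if record_voltage else None,
        voltage_dt=dt * voltage_stride * 1e-3 if record_voltage else None,
        edge_g_c=model.edge_g_c, seed=seed,
    )


@dataclass
class CCProtocolSpec:
    """Current-injection protocol for the coupling coefficient.

    All somata are held with ``i_hyp`` throughout; after ``settle`` seconds a
    step ``i_cmd`` is added to the centre soma for ``step_duration`` seconds.
    Steady state is the mean over the last 20% of each window; the protocol
    errors out if the pre-step baseline still drifts faster than
    ``drift_tolerance`` (mV/s).
    """

    i_hyp: float = -1.0          # uA/cm^2, all somata
    i_cmd: float = -1.0          # uA/cm^2, centre soma
    settle: float = 8.0          # s
    step_duration: float = 2.0   # s
    drift_tolerance: float = 0.01  # mV/s

    def __post_init__(self) -> None:
        if self.settle <= 0 or self.step_duration <= 0:
            raise ValueError("settle and step_duration must be positive")


def coupling_coefficient_protocol(
    model: NetworkModel, spec: CCProtocolSpec | None = None,
    dt: float = 0.05, return_details: bool = False,
):
    """Noise-free coupling coefficient of the centre cell and its neighbours.

    CC is the mean over the four neighbours of the ratio of their steady-state
    somatic voltage deflection to the master's deflection in response to the
    step current.
    """
    spec = spec or CCProtocolSpec()
    n = model.n_cells
    center = model.center_cell
    neighbors = [int(a) if b == center else int(b)
                 for a, b in model.edges if center in (a, b)]
    i_base = np.full(n, spec.i_hyp)
    i_step = np.zeros(n)
    i_step[center] = spec.i_cmd
    duration = spec.settle + spec.step_duration
    stride = max(int(1.0 / dt), 1)  # 1-ms sampling
    res = simulate(
        model, duration, dt=dt, seed=0, noise=False, record_voltage=True,
        voltage_stride=stride,
        i_base=i_base, i_step=i_step,
        step_window=(spec.settle, duration),
    )
    v = res.voltages
    t = np.arange(v.shape[1]) * res.voltage_dt
    pre = (t > 0.8 * spec.settle) & (t < spec.settle)
    post = t > spec.settle + 0.8 * spec.step_duration
    # baseline drift check on the master cell
    tp = t[pre]
    vp = v[center][pre]
    drift = abs(np.polyfit(tp, vp, 1)[0])
    if drift > spec.drift_tolerance:
        raise RuntimeError(
            f"no steady state: baseline drift {drift:.4f} mV/s exceeds "
            f"tolerance {spec.drift_tolerance} mV/s")
    dv_master = v[center][post].mean() - v[center][pre].mean()
    ratios = [(v[j][post].mean() - v[j][pre].mean()) / dv_master
              for j in neighbors]
    cc = float(np.mean(ratios))
    if return_details:
        return cc, {"neighbors": neighbors, "ratios": ratios,
                    "dv_master": dv_master, "v_hold": v[center][pre].mean()}
    return cc


def grid_values(start: float = 0.0, stop: float = 2.0, step: float = 0.05) -> np.ndarray:
    """Inclusive conductance grid axis (default 0-2 mS/cm^2 in 0.05 steps)."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


def run_parameter_grid(
    g_i_range: np.ndarray,
    g_c_range: np.ndarray,
    noise_rate: float = 20.0,
    duration: float = 100.0,
    seed: int = 0,
    dt: float = 0.05,
    feature_spec=None,
    neuron_params: NeuronParams | None = None,
    progress: bool = False,
):
    """Simulate every (g_i, g_c) grid point and return a FeatureLibrary.

    One network realization per grid point; the stored feature vector is the
    mean across the nine simulated neurons.
    """
    from .features import FeatureLibrary, FeatureSpec, extract_feature_matrix

    g_i_range = np.asarray(g_i_range, dtype=float)
    g_c_range = np.asarray(g_c_range, dtype=float)
    if g_i_range.size == 0 or g_c_range.size == 0:
        raise ValueError("empty parameter range")
    spec = feature_spec or FeatureSpec()
    base = neuron_params or NeuronParams()
    coords = []
    vectors = []
    total = g_i_range.size * g_c_range.size
    done = 0
    for gi in g_i_range:
        for gc in g_c_range:
            params = NeuronParams(**{**_asdict(base), "g_i": float(gi)})
            cfg = NetworkConfig(mean_g_c=float(gc), inhib_rate=noise_rate,
                                seed=seed)
            net = build_network(params, cfg)
            res = simulate(net, duration, dt=dt, seed=seed, noise=True)
            fm = extract_feature_matrix(res.dataset, spec)
            coords.append((float(gi), float(gc), float(noise_rate)))
            vectors.append(np.nanmean(fm, axis=0))
            done += 1
            if progress:
                print(f"  grid {done}/{total}: g_i={gi:.2f} g_c={gc:.2f}")
    return FeatureLibrary(
        coords=np.array(coords), vectors=np.vstack(vectors), spec=spec,
        g_i_axis=g_i_range, g_c_axis=g_c_range, noise_rate=noise_rate,
    )


def _asdict(p: NeuronParams) -> dict:
    return {f.name: getattr(p, f.name) for f in fields(p)}
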