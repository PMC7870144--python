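"""Ground-truthed synthetic inputs for every analysis stage.

Each generator emulates the statistical structure of one class of study
input and records the quantities the corresponding analysis module is
supposed to recover:

* branching neurite trees that elongate over differentiation days, with
  multiplicative species and batch scale effects;
* single-compartment RC membrane responses (access resistance Rs in series
  with Rcell parallel Ccell) to voltage-step, voltage-ramp and
  current-step protocols, integrated analytically piece by piece;
* Poisson trains of biexponential synaptic events in Gaussian noise;
* negative-binomial gene-by-cell count matrices with planted differentially
  expressed genes, planted gene-set enrichment and per-cell mitochondrial
  fractions.

All generators are deterministic given a :class:`numpy.random.Generator`
(or an integer seed): the same seed yields byte-identical serializations.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

from .ephys import RampProtocol, StepProtocol, Trace, _command_voltage
from .morphology import Neurite, NeuronMorphology

__all__ = [
    "MorphGenParams",
    "MembraneSimParams",
    "EpscTrainParams",
    "CountsGenParams",
    "generate_morphology",
    "sholl_oracle_dense",
    "simulate_voltage_clamp",
    "simulate_ramp",
    "simulate_current_clamp",
    "simulate_epsc_trace",
    "simulate_counts",
    "make_gene_sets",
    "rng_from",
]


def rng_from(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Morphology
# ---------------------------------------------------------------------------

@dataclass
class MorphGenParams:
    """Branching-tree growth model.

    A cell sprouts ``n_primary`` neurites (drawn over the inclusive range
    with ``n_primary_weights``, defaulting to the observed polarity mix of
    induced-neuron cultures: a few percent unipolar, roughly a third
    bipolar, the rest multipolar); each grows by segments of
    ~``segment_length`` µm with direction persistence, branching with
    probability ``branch_prob`` per node. Total arbor size scales as
    ``elongation_per_day ** (day - 7)`` times the species and batch factors,
    reproducing the observed growth from a few hundred µm at day 7 to over
    a thousand µm by day 35.
    """

    n_primary: tuple[int, int] = (1, 5)   # inclusive range
    n_primary_weights: tuple[float, ...] | None = (
        0.06, 0.31, 0.26, 0.21, 0.16)
    branch_prob: float = 0.12
    segment_length: tuple[float, float] = (10.0, 3.0)   # mean, sd µm
    base_segments: int = 12               # per primary neurite at day 7
    elongation_per_day: float = 1.06
    species_scale: float = 1.0
    batch_scale: float = 1.0
    max_nodes: int = 400

    def __post_init__(self) -> None:
        if not 0.0 <= self.branch_prob <= 1.0:
            raise ValueError("branch_prob must be in [0, 1]")
        for name in ("elongation_per_day", "species_scale", "batch_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _grow_neurite(p: MorphGenParams, day: int,
                  rng: np.random.Generator) -> Neurite:
    growth = (p.elongation_per_day ** (day - 7)
              * p.species_scale * p.batch_scale)
    n_target = max(2, int(round(p.base_segments * growth)))
    n_target = min(n_target, p.max_nodes)

    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    nodes = [np.zeros(3)]
    parents = [-1]
    # frontier of (node index, direction) growth cones
    tips = [(0, direction)]
    while tips and len(nodes) - 1 < n_target:
        new_tips = []
        for idx, d in tips:
            if len(nodes) - 1 >= n_target:
                break
            seg = max(0.5, rng.normal(*p.segment_length))
            d_new = d + 0.35 * rng.normal(size=3)
            d_new /= np.linalg.norm(d_new)
            nodes.append(nodes[idx] + seg * d_new)
            parents.append(idx)
            child = len(nodes) - 1
            new_tips.append((child, d_new))
            if rng.random() < p.branch_prob:
                d_b = d_new + 0.9 * rng.normal(size=3)
                d_b /= np.linalg.norm(d_b)
                new_tips.append((child, d_b))
        tips = new_tips
    return Neurite(np.array(nodes), np.array(parents))


def generate_morphology(p: MorphGenParams, day: int,
                        rng: int | np.random.Generator,
                        cell_id: str = "synthetic",
                        metadata: Mapping | None = None
                        ) -> tuple[NeuronMorphology, dict]:
    """Grow one cell; the truth record carries the generator's bookkeeping
    (per-neurite lengths, node/branch counts) for round-trip tests."""
    rng = rng_from(rng)
    choices = np.arange(p.n_primary[0], p.n_primary[1] + 1)
    if p.n_primary_weights is not None:
        w = np.asarray(p.n_primary_weights, dtype=float)
        if w.size != choices.size:
            raise ValueError("n_primary_weights must cover the n_primary "
                             "range")
        n_primary = int(rng.choice(choices, p=w / w.sum()))
    else:
        n_primary = int(rng.choice(choices))
    # soma placed away from the origin so translation invariance is exercised
    centroid = rng.normal(scale=20.0, size=3)
    neurites = []
    for _ in range(n_primary):
        nr = _grow_neurite(p, day, rng)
        nr = Neurite(nr.nodes + centroid, nr.parents, nr.radii)
        neurites.append(nr)
    meta = dict(metadata or {})
    meta.setdefault("day", day)
    m = NeuronMorphology(cell_id=cell_id, soma_centroid=centroid,
                         neurites=neurites, metadata=meta)
    per_lengths = [nr.total_length for nr in neurites]
    truth = {
        "n_primary": n_primary,
        "n_neurites": len(neurites),
        "n_nodes": int(sum(nr.n_nodes for nr in neurites)),
        "n_branch_points": int(sum(nr.n_branch_points for nr in neurites)),
        "per_neurite_lengths": per_lengths,
        "total_length": float(sum(per_lengths)),
        "axon_index": int(np.argmax(per_lengths)),
        "axon_length": float(max(per_lengths)),
    }
    return m, truth


def sholl_oracle_dense(m: NeuronMorphology, radii: Sequence[float],
                       ds: float = 0.01) -> np.ndarray:
    """Independent Sholl count: resample every segment at ``ds`` µm and
    count sign changes of (distance to soma - r) along each segment."""
    c = m.soma_centroid
    counts = np.zeros(len(radii), dtype=int)
    radii = np.asarray(radii, dtype=float)
    for nr in m.neurites:
        for a, b in zip(nr.segment_starts, nr.segment_ends):
            seg_len = float(np.linalg.norm(b - a))
            if seg_len == 0:
                continue
            n_pts = max(2, int(math.ceil(seg_len / ds)) + 1)
            t = np.linspace(0.0, 1.0, n_pts)
            pts = a[None, :] + t[:, None] * (b - a)[None, :]
            d = np.linalg.norm(pts - c, axis=1)
            for i, r in enumerate(radii):
                sign = d >= r
                counts[i] += int(np.count_nonzero(sign[1:] != sign[:-1]))
    return counts


# ---------------------------------------------------------------------------
# Membrane simulation
# ---------------------------------------------------------------------------

@dataclass
class MembraneSimParams:
    """Single-compartment passive cell with optional subthreshold sodium
    conductance and stylized spikes (units: MΩ, pF, mV, pA, nS)."""

    rcell_mohm: float = 500.0
    ccell_pf: float = 30.0
    rs_mohm: float = 15.0
    vrmp_mv: float = -75.0
    noise_sd_pa: float = 5.0
    # subthreshold conductance: (reversal mV, gmax nS, activation midpoint mV)
    na_reversal_mv: float = 60.0
    na_gmax_ns: float = 0.0
    na_midpoint_mv: float = -55.0
    na_slope_mv: float = 4.0
    spike_threshold_mv: float = -40.0
    spike_peak_mv: float = 20.0
    spike_width_ms: float = 2.0

    def __post_init__(self) -> None:
        for name in ("rcell_mohm", "ccell_pf", "rs_mohm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd_pa < 0:
            raise ValueError("noise_sd_pa must be >= 0")

    @property
    def tau_clamp_ms(self) -> float:
        """Voltage-clamp time constant (Rs || Rcell)·Ccell, in ms."""
        rpar = self.rs_mohm * self.rcell_mohm / (self.rs_mohm
                                                 + self.rcell_mohm)
        return rpar * self.ccell_pf / 1000.0

    @property
    def tau_membrane_ms(self) -> float:
        return self.rcell_mohm * self.ccell_pf / 1000.0


def simulate_voltage_clamp(p: MembraneSimParams, protocol: StepProtocol,
                           rng: int | np.random.Generator,
                           sampling_rate: float = 20000.0
                           ) -> tuple[list[Trace], dict]:
    """Analytic current responses to the four-step family.

    For each step the clamp current is
    I(t) = I_ss + (I_0 - I_ss)·exp(-t/tau) with
    tau = (Rs||Rcell)·Ccell, I_ss = dV/(Rs+Rcell) relative to rest and the
    instantaneous jump I_0 carried entirely by Rs.
    """
    rng = rng_from(rng)
    fs = sampling_rate
    rs, rc, e = p.rs_mohm, p.rcell_mohm, p.vrmp_mv
    tau_ms = p.tau_clamp_ms
    n = int(round((protocol.step_onset + protocol.step_duration)
                  / 1000.0 * fs))
    onset_idx = int(round(protocol.step_onset / 1000.0 * fs))
    t_ms = np.arange(n) / fs * 1000.0
    traces = []
    vm_hold = e + (protocol.holding - e) * rc / (rs + rc)
    i_hold = 1000.0 * (protocol.holding - e) / (rs + rc)
    for target in protocol.step_targets:
        i_ss = 1000.0 * (target - e) / (rs + rc)
        i_0 = 1000.0 * (target - vm_hold) / rs
        i = np.full(n, i_hold)
        tt = t_ms[onset_idx:] - t_ms[onset_idx]
        i[onset_idx:] = i_ss + (i_0 - i_ss) * np.exp(-tt / tau_ms)
        if p.noise_sd_pa > 0:
            i = i + rng.normal(scale=p.noise_sd_pa, size=n)
        traces.append(Trace(sampling_rate=fs, samples=i))
    truth = {"rcell_mohm": rc, "ccell_pf": p.ccell_pf, "rs_mohm": rs,
             "vrmp_mv": e, "tau_clamp_ms": tau_ms,
             "plateau_slope_mohm": rs + rc}
    return traces, truth


def _msub(v: np.ndarray, p: MembraneSimParams) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(v - p.na_midpoint_mv) / p.na_slope_mv))


def simulate_ramp(p: MembraneSimParams, protocol: RampProtocol,
                  rng: int | np.random.Generator,
                  sampling_rate: float = 20000.0) -> tuple[Trace, dict]:
    """Clamp current during the voltage ramp.

    The passive case is integrated exactly per linear piece of the command:
    for dVm/dt = (u(t) - Vm)/tau with linear drive u, the solution is the
    particular linear response u - tau·u' plus an exponentially decaying
    deviation. With a subthreshold conductance the ODE is integrated
    numerically (sub-stepped forward Euler).
    """
    rng = rng_from(rng)
    fs = sampling_rate
    n = int(round((protocol.pre_duration + protocol.ramp_duration)
                  / 1000.0 * fs)) + 1
    vcmd = _command_voltage(protocol, n, fs)
    rs, rc, e, cc = p.rs_mohm, p.rcell_mohm, p.vrmp_mv, p.ccell_pf
    rpar = rs * rc / (rs + rc)
    tau_ms = rpar * cc / 1000.0
    dt_ms = 1000.0 / fs

    if p.na_gmax_ns == 0.0:
        vm = np.empty(n)
        # drive u(t) = (Vc/Rs + E/Rcell) * (Rs||Rcell)
        u = (vcmd / rs + e / rc) * rpar
        t_ms = np.arange(n) * dt_ms
        pre_n = int(round(protocol.pre_duration / 1000.0 * fs))
        vm[:pre_n] = u[:pre_n]  # steady at holding
        # ramp piece: linear drive with slope k·rpar/rs
        k_u = protocol.slope_mv_per_ms * rpar / rs
        tt = t_ms[pre_n:] - t_ms[pre_n]
        v0 = u[pre_n] if pre_n else u[0]
        vm[pre_n:] = (u[pre_n:] - tau_ms * k_u
                      + (v0 - u[pre_n] + tau_ms * k_u) * np.exp(-tt / tau_ms))
    else:
        vm = np.empty(n)
        v = e
        sub = 4
        for i in range(n):
            vm[i] = v
            for _ in range(sub):
                i_ax = 1000.0 * (vcmd[i] - v) / rs
                i_leak = 1000.0 * (v - e) / rc
                i_na = p.na_gmax_ns * _msub(np.array(v), p) * (
                    v - p.na_reversal_mv)
                v = v + (dt_ms / sub) * (i_ax - i_leak - i_na) / cc
    i_pa = 1000.0 * (vcmd - vm) / rs
    if p.noise_sd_pa > 0:
        i_pa = i_pa + rng.normal(scale=p.noise_sd_pa, size=n)
    truth = {"rcell_mohm": rc, "vrmp_mv": e, "ccell_pf": cc,
             "rs_mohm": rs}
    return Trace(sampling_rate=fs, samples=i_pa), truth


def simulate_current_clamp(p: MembraneSimParams,
                           step_currents_pa: Sequence[float],
                           n_spikes: Sequence[int],
                           rng: int | np.random.Generator,
                           sampling_rate: float = 10000.0,
                           step_duration_ms: float = 500.0,
                           onset_ms: float = 50.0,
                           noise_sd_mv: float = 0.3
                           ) -> tuple[list[Trace], dict]:
    """Current-clamp step family with stylized action potentials.

    The subthreshold voltage is the passive charging curve; the requested
    number of spikes per step is inserted as 2-ms triangular waveforms
    peaking at ``spike_peak_mv``, evenly spaced within the step. Spike
    realism is irrelevant downstream — only threshold crossings are
    counted — so the truth is exact by construction.
    """
    rng = rng_from(rng)
    if len(step_currents_pa) != len(n_spikes):
        raise ValueError("one spike count per step required")
    fs = sampling_rate
    n = int(round((onset_ms + step_duration_ms + 50.0) / 1000.0 * fs))
    t_ms = np.arange(n) / fs * 1000.0
    tau_m = p.tau_membrane_ms
    traces = []
    half_w = p.spike_width_ms / 2.0
    for i_pa, k in zip(step_currents_pa, n_spikes):
        v = np.full(n, p.vrmp_mv)
        on = t_ms >= onset_ms
        dt_on = t_ms[on] - onset_ms
        dv_ss = i_pa * p.rcell_mohm / 1000.0   # pA·MΩ = µV·1000 -> mV
        v[on] = p.vrmp_mv + dv_ss * (1.0 - np.exp(-dt_on / tau_m))
        off = t_ms >= onset_ms + step_duration_ms
        v[off] = p.vrmp_mv + (v[np.argmax(off)] - p.vrmp_mv) * np.exp(
            -(t_ms[off] - (onset_ms + step_duration_ms)) / tau_m)
        # the subthreshold voltage saturates at spike threshold (a real
        # cell fires instead of charging past it)
        v = np.minimum(v, p.spike_threshold_mv)
        if k > 0:
            centers = onset_ms + (np.arange(k) + 0.5) * step_duration_ms / k
            for c_ms in centers:
                mask = np.abs(t_ms - c_ms) <= half_w
                shape = 1.0 - np.abs(t_ms[mask] - c_ms) / half_w
                v[mask] = np.maximum(
                    v[mask],
                    v[mask] + (p.spike_peak_mv - v[mask]) * shape)
        if noise_sd_mv > 0:
            v = v + rng.normal(scale=noise_sd_mv, size=n)
        traces.append(Trace(sampling_rate=fs, samples=v))
    truth = {"n_spikes": list(int(x) for x in n_spikes),
             "max_count": int(max(n_spikes) if len(n_spikes) else 0)}
    return traces, truth


# ---------------------------------------------------------------------------
# EPSC trains
# ---------------------------------------------------------------------------

@dataclass
class EpscTrainParams:
    """Homogeneous Poisson train of biexponential inward events.

    Defaults reproduce the study's recording condition: 60 s at -80 mV,
    ~14 pA baseline noise, event amplitudes log-normal with the bulk of the
    mass between 30 and 100 pA, kinetics inside the template's 1.5 ms rise /
    6 ms fall acceptance window.
    """

    rate_hz: float = 0.5
    amp_median_pa: float = 55.0
    amp_sigma_ln: float = 0.3
    rise_ms: float = 0.5
    decay_ms: float = 4.0
    noise_sd_pa: float = 14.0
    duration_s: float = 60.0

    def __post_init__(self) -> None:
        if self.rate_hz < 0:
            raise ValueError("rate_hz must be >= 0")
        if self.rise_ms >= self.decay_ms:
            raise ValueError("rise must be faster than decay")


def _biexp_kernel(rise_ms: float, decay_ms: float,
                  fs: float) -> np.ndarray:
    t_ms = np.arange(0.0, 8.0 * decay_ms, 1000.0 / fs)
    k = np.exp(-t_ms / decay_ms) - np.exp(-t_ms / rise_ms)
    return k / k.max()


def simulate_epsc_trace(p: EpscTrainParams,
                        rng: int | np.random.Generator,
                        sampling_rate: float = 10000.0
                        ) -> tuple[Trace, dict]:
    """Simulate the 60-s voltage-clamp trace; truth lists the planted event
    times (kernel peak times) and amplitudes."""
    rng = rng_from(rng)
    fs = sampling_rate
    n = int(round(p.duration_s * fs))
    x = np.zeros(n)
    n_events = rng.poisson(p.rate_hz * p.duration_s)
    onsets = np.sort(rng.uniform(0.0, p.duration_s, size=n_events))
    amps = rng.lognormal(mean=math.log(p.amp_median_pa),
                         sigma=p.amp_sigma_ln, size=n_events)
    kernel = _biexp_kernel(p.rise_ms, p.decay_ms, fs)
    peak_offset = int(np.argmax(kernel))
    times = []
    for t0, a in zip(onsets, amps):
        i0 = int(round(t0 * fs))
        i1 = min(n, i0 + kernel.size)
        if i1 <= i0:
            continue
        x[i0:i1] -= a * kernel[:i1 - i0]   # inward = negative
        times.append((i0 + peak_offset) / fs)
    if p.noise_sd_pa > 0:
        x = x + rng.normal(scale=p.noise_sd_pa, size=n)
    truth = {"event_times_s": times,
             "event_amplitudes_pa": list(map(float, amps)),
             "n_events": len(times)}
    return Trace(sampling_rate=fs, samples=x), truth


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

@dataclass
class CountsGenParams:
    """Negative-binomial gene-by-cell counts with planted structure.

    Group A plays the neuronal cells, group B the progenitors; the planted
    genes are elevated ``fold_change``-fold in group A. ``n_mito`` genes
    are named ``MT-*`` and tuned so most cells carry ~``mito_baseline``
    mitochondrial fraction; ``n_high_mito``/``n_low_depth`` cells are
    planted QC violations.
    """

    n_genes: int = 2000
    n_cells_a: int = 200
    n_cells_b: int = 200
    mean_log_mu: float = 0.0
    mean_log_sd: float = 1.0
    dispersion: float = 2.0
    n_planted: int = 100
    fold_change: float = 4.0
    n_mito: int = 10
    mito_baseline: float = 0.03
    n_high_mito: int = 0
    high_mito_fraction: float = 0.10
    n_low_depth: int = 0
    low_depth_factor: float = 0.05
    libsize_sigma_ln: float = 0.25
    n_batches: int = 2

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_cells_a, self.n_cells_b) <= 0:
            raise ValueError("dimensions must be positive")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")


def simulate_counts(p: CountsGenParams,
                    rng: int | np.random.Generator
                    ) -> tuple[ad.AnnData, dict]:
    """Sample the count matrix as an AnnData (cells x genes).

    obs carries group/batch/cluster annotations; var carries the
    mitochondrial flag. The truth record lists planted DEG genes, planted
    QC-violating cells and the realized per-cell QC statistics.
    """
    rng = rng_from(rng)
    n_cells = p.n_cells_a + p.n_cells_b
    gene_names = [f"G{i:04d}" for i in range(p.n_genes - p.n_mito)]
    gene_names += [f"MT-{i}" for i in range(p.n_mito)]
    is_mito = np.array([g.startswith("MT-") for g in gene_names])

    mu = rng.lognormal(p.mean_log_mu, p.mean_log_sd, size=p.n_genes)
    # mitochondrial genes share the baseline fraction of the expected library
    nonmito_total = mu[~is_mito].sum()
    mu[is_mito] = (p.mito_baseline / (1 - p.mito_baseline)
                   * nonmito_total / max(p.n_mito, 1))

    candidates = np.flatnonzero(~is_mito)
    planted = rng.choice(candidates, size=p.n_planted, replace=False)
    planted = np.sort(planted)

    fold = np.ones((n_cells, p.n_genes))
    fold[:p.n_cells_a, planted] = p.fold_change

    libsize = rng.lognormal(0.0, p.libsize_sigma_ln, size=n_cells)
    low_cells = rng.choice(n_cells, size=p.n_low_depth, replace=False) \
        if p.n_low_depth else np.array([], dtype=int)
    libsize[low_cells] *= p.low_depth_factor

    high_mito = np.array([], dtype=int)
    remaining = np.setdiff1d(np.arange(n_cells), low_cells)
    if p.n_high_mito:
        high_mito = rng.choice(remaining, size=p.n_high_mito, replace=False)

    mean_matrix = libsize[:, None] * fold * mu[None, :]
    if p.n_high_mito:
        # scale mitochondrial means so those cells exceed the 5 % threshold
        for c in high_mito:
            target = p.high_mito_fraction
            nonmito_c = mean_matrix[c, ~is_mito].sum()
            mean_matrix[c, is_mito] = (target / (1 - target)
                                       * nonmito_c / max(p.n_mito, 1))

    theta = p.dispersion
    counts = rng.negative_binomial(
        theta, theta / (theta + mean_matrix)).astype(np.int32)

    obs = pd.DataFrame({
        "group": ["A"] * p.n_cells_a + ["B"] * p.n_cells_b,
        "cluster": ["neuron"] * p.n_cells_a + ["progenitor"] * p.n_cells_b,
        "batch": [f"b{i % p.n_batches}" for i in range(n_cells)],
    }, index=[f"cell{i:04d}" for i in range(n_cells)])
    var = pd.DataFrame({"mito": is_mito},
                       index=pd.Index(gene_names, name="gene"))
    adata = ad.AnnData(X=counts, obs=obs, var=var)

    genes_detected = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1)
    mito_frac = np.divide(counts[:, is_mito].sum(axis=1), totals,
                          out=np.zeros(n_cells), where=totals > 0)
    keep = ((genes_detected >= 500) & (genes_detected <= 6000)
            & (mito_frac <= 0.05))
    truth = {
        "planted_genes": [gene_names[i] for i in planted],
        "low_depth_cells": [obs.index[i] for i in low_cells],
        "high_mito_cells": [obs.index[i] for i in high_mito],
        "genes_detected": genes_detected.tolist(),
        "mito_fraction": mito_frac.tolist(),
        "qc_keep_cells": [obs.index[i] for i in np.flatnonzero(keep)],
    }
    return adata, truth


def make_gene_sets(background: Sequence[str], deg_genes: Sequence[str],
                   rng: int | np.random.Generator,
                   n_null_terms: int = 50, term_size: int = 40,
                   n_planted_terms: int = 3,
                   planted_deg_fraction: float = 0.8
                   ) -> tuple[dict, dict]:
    """Gene-set collection with planted enrichment.

    Null terms draw members uniformly from the background; planted terms
    draw ``planted_deg_fraction`` of their members from the DEG list, so a
    one-sided enrichment test should flag exactly the planted terms.
    Returns (collection mapping term_id -> (name, members), truth).
    """
    rng = rng_from(rng)
    background = list(background)
    deg_genes = [g for g in deg_genes if g in set(background)]
    non_deg = list(set(background) - set(deg_genes))
    sets: dict[str, tuple[str, list[str]]] = {}
    for i in range(n_null_terms):
        members = rng.choice(background, size=min(term_size, len(background)),
                             replace=False)
        sets[f"NULL:{i:03d}"] = (f"null term {i}", sorted(members))
    planted_ids = []
    for i in range(n_planted_terms):
        k = int(round(term_size * planted_deg_fraction))
        k = min(k, len(deg_genes))
        members = list(rng.choice(deg_genes, size=k, replace=False))
        members += list(rng.choice(non_deg, size=term_size - k,
                                   replace=False))
        tid = f"PLANT:{i:03d}"
        sets[tid] = (f"planted term {i}", sorted(members))
        planted_ids.append(tid)
    truth = {"planted_terms": planted_ids}
    return sets, truth
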