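"""Synthetic cohort generator with known ground truth.

Every downstream stage of the pipeline has a parameter-recovery test built
on this module. The generator emits (cohort, truth) pairs; the truth object
is never consumed by analysis code.

Generating laws (documented assumptions):

* Sweep-to-sweep incidence is independent Bernoulli(p_fire).
* Persistent spike trains: a guaranteed onset spike at t0 = stim_offset +
  latency (so intended incidence is always realized; disable with
  ``onset_spike=False`` for pure-Poisson rate studies), followed by an
  inhomogeneous Poisson process with rate lambda(t) = Ymax*(1 - exp(-(t -
  t0)/tau)) thinned to a 4 ms refractory period.
* Action potentials are a piecewise analytic template (quadratic foot ->
  raised-cosine rise/fall -> exponential tail) whose detector-facing
  features (threshold, ~82 mV amplitude, ~1.8 ms half-width) sit in the
  physiological range.
* ADP/plateau: instantaneous rise to the per-cell ADP peak at stimulus
  offset, exponential decay with pp_decay_tau toward holding.
* Postburst AHP: alpha-function medium component (negative peak = per-cell
  mAHP draw at +80 ms) plus a slow exponential whose value at +1 s equals
  the per-cell sAHP draw.
* EMG trials: rectified white noise; a conditioned response is a half-sine
  burst (default 6x noise SD, 50 ms) centered inside the scoring window;
  non-CR trials may carry an early alpha deflection outside the window.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .abf_io import reconstruct_command
from .model import (
    Animal,
    CellQC,
    CellRecord,
    Cohort,
    EMGTrial,
    Session,
    StimulusProtocol,
    Sweep,
    standard_protocols,
)

REFRACTORY_S = 0.004

# AP template geometry (ms, relative to peak at 0)
_QUAD_C = 100.0          # mV/ms^2 curvature of the onset foot
_QUAD_MS = 0.3           # quadratic segment length
_RISE_MS = 0.6           # raised-cosine rise to peak
_FALL_MS = 3.0           # raised-cosine fall back to threshold
_TAIL_TAU_MS = 2.0       # exponential tail toward the local envelope
_TAIL_MS = 8.0
_FOOT_VS = 5.0           # sub-detection foot slope, V/s


@dataclass
class GroupSpec:
    """Ground-truth parameters for one experimental group."""

    group: str
    n_cells: int = 0
    p_fire: float = 1.0
    rate_ymax: float = 6.0           # spikes/s
    rate_tau: float = 2.0            # s
    latency_mean: float = 1.5        # s
    latency_sd: float = 0.3
    adp_peak_mean: float = 2.5       # mV
    adp_peak_sd: float = 0.5
    pp_decay_tau: float = 3.0        # s
    mahp_mean: float = -5.6          # mV (negative)
    mahp_sd: float = 0.5
    sahp_mean: float = -3.6
    sahp_sd: float = 0.4
    cr_prob_by_session: tuple = (0.2, 0.35, 0.5, 0.6, 0.7)
    n_animals: int = 0
    paradigm: str = "conditioned"

    def __post_init__(self):
        if not 0.0 <= self.p_fire <= 1.0:
            raise ValueError("p_fire must be in [0, 1]")
        if any(not 0.0 <= p <= 1.0 for p in self.cr_prob_by_session):
            raise ValueError("cr_prob_by_session values must be in [0, 1]")
        if self.rate_tau <= 0 or self.pp_decay_tau <= 0:
            raise ValueError("time constants must be positive")
        for sd in (self.latency_sd, self.adp_peak_sd, self.mahp_sd, self.sahp_sd):
            if sd < 0:
                raise ValueError("sd parameters must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "GroupSpec":
        d = dict(d)
        if "cr_prob_by_session" in d:
            d["cr_prob_by_session"] = tuple(d["cr_prob_by_session"])
        return cls(**d)


@dataclass
class SimulatedTruth:
    """Ground truth emitted alongside a cohort; never read by analysis code."""

    cells: dict = field(default_factory=dict)
    animals: dict = field(default_factory=dict)


# ------------------------------------------------------------------ waveforms
def ap_template_times() -> dict:
    """Key offsets of the AP template relative to the peak, in ms."""
    return {"quad_start": -(_RISE_MS + _QUAD_MS), "rise_start": -_RISE_MS,
            "fall_end": _FALL_MS, "tail_end": _FALL_MS + _TAIL_MS}


def ap_waveform(t_ms: np.ndarray, v_start: float, v_threshold: float,
                v_peak: float) -> np.ndarray:
    """Evaluate the AP template at times ``t_ms`` relative to the peak.

    Piecewise: linear foot at 5 V/s up to 1 mV below threshold, quadratic
    onset through the detector's 20 V/s crossing exactly at ``v_threshold``,
    raised-cosine rise/fall, exponential tail back to ``v_start``.
    """
    amp = v_peak - v_threshold
    # quadratic onset v(t) = v_q0 + C*(t - t_q0)^2; its slope passes the
    # detector's 20 V/s exactly at v == v_threshold (0.1 ms into the segment)
    t_q0 = -(_RISE_MS + _QUAD_MS)
    v_q0 = v_threshold - _QUAD_C * (0.1) ** 2  # slope 20 V/s at 0.1 ms into the quad
    v_rise0 = v_q0 + _QUAD_C * _QUAD_MS ** 2   # value entering the cosine rise
    foot_len_ms = max((v_q0 - v_start), 0.0) / _FOOT_VS
    t_foot0 = t_q0 - foot_len_ms

    v = np.full_like(t_ms, v_start, dtype=float)
    m = (t_ms >= t_foot0) & (t_ms < t_q0)
    v[m] = v_start + _FOOT_VS * (t_ms[m] - t_foot0)
    m = (t_ms >= t_q0) & (t_ms < -_RISE_MS)
    v[m] = v_q0 + _QUAD_C * (t_ms[m] - t_q0) ** 2
    m = (t_ms >= -_RISE_MS) & (t_ms < 0)
    v[m] = v_rise0 + (v_peak - v_rise0) * (1 - np.cos(
        np.pi * (t_ms[m] + _RISE_MS) / _RISE_MS)) / 2
    m = (t_ms >= 0) & (t_ms < _FALL_MS)
    v[m] = v_threshold + amp * (1 + np.cos(np.pi * t_ms[m] / _FALL_MS)) / 2
    m = t_ms >= _FALL_MS
    v[m] = v_start + (v_threshold - v_start) * np.exp(
        -(t_ms[m] - _FALL_MS) / _TAIL_TAU_MS)
    return v


def insert_spikes(voltage: np.ndarray, sample_rate_hz: float,
                  spike_times_s, v_threshold: float, v_peak: float):
    """Overlay AP templates (peak aligned to each spike time) onto a trace.

    Templates are merged with the existing trace by pointwise maximum, so
    the subthreshold envelope is preserved between spikes.
    """
    n = len(voltage)
    dt_ms = 1e3 / sample_rate_hz
    # template support, generous on the left for deep holding potentials
    left_ms = _RISE_MS + _QUAD_MS + 80.0 / _FOOT_VS
    k_left = int(np.ceil(left_ms / dt_ms))
    k_right = int(np.ceil((_FALL_MS + _TAIL_MS) / dt_ms))
    rel_ms = np.arange(-k_left, k_right + 1) * dt_ms
    for ts in np.atleast_1d(spike_times_s):
        ipk = int(round(ts * sample_rate_hz))
        i0, i1 = max(ipk - k_left, 0), min(ipk + k_right + 1, n)
        if i0 >= i1:
            continue
        seg = slice(i0, i1)
        v_start = float(voltage[ipk]) if 0 <= ipk < n else float(voltage[i0])
        tpl = ap_waveform(rel_ms[(i0 - (ipk - k_left)):(i1 - (ipk - k_left))],
                          v_start, v_threshold, v_peak)
        np.maximum(voltage[seg], tpl, out=voltage[seg])


def sample_rise_poisson(rng: np.random.Generator, t0: float, t_end: float,
                        ymax: float, tau: float,
                        refractory_s: float = REFRACTORY_S) -> np.ndarray:
    """Inhomogeneous Poisson spike times on [t0, t_end] via thinning.

    Rate law lambda(t) = ymax * (1 - exp(-(t - t0)/tau)); a refractory
    period is enforced by dropping spikes closer than ``refractory_s`` to
    the previously accepted spike.
    """
    if ymax <= 0 or t_end <= t0:
        return np.array([])
    n_hom = rng.poisson(ymax * (t_end - t0))
    cand = np.sort(rng.uniform(t0, t_end, n_hom))
    keep = rng.uniform(size=n_hom) < (1 - np.exp(-(cand - t0) / tau))
    cand = cand[keep]
    out = []
    last = -np.inf
    for t in cand:
        if t - last >= refractory_s:
            out.append(t)
            last = t
    return np.array(out)


# --------------------------------------------------------------- ephys cohort
AHP_PEAK_AT_S = 0.08


def _ahp_envelope(t_post: np.ndarray, mahp: float, sahp: float) -> np.ndarray:
    """Postburst deflection relative to holding at times after burst offset.

    Biexponential-style shape with an exact construction: half-cosine dip to
    ``mahp`` (the minimum, at +80 ms), then exponential decay toward holding
    whose time constant is solved so the value at +1 s equals ``sahp``.
    Requires mahp < sahp < 0 (the generator clips its draws accordingly).
    """
    t_m = AHP_PEAK_AT_S
    tau_d = (1.0 - t_m) / np.log(mahp / sahp)
    dip = mahp * (1.0 - np.cos(np.pi * np.minimum(t_post, t_m) / t_m)) / 2.0
    decay = mahp * np.exp(-(np.maximum(t_post, t_m) - t_m) / tau_d)
    return np.where(t_post >= 0, np.where(t_post <= t_m, dip, decay), 0.0)


def generate_ephys_cohort(specs, seed: int,
                          protocols=("train20hz_250ms_2mv",),
                          sample_rate_hz: float = 10_000.0,
                          noise_sd_mV: float = 0.2,
                          sweep_duration_s: float = 20.0,
                          n_sweeps: int = 3,
                          include_ahp: bool = True,
                          include_adp: bool = True,
                          onset_spike: bool = True):
    """Generate cells for each :class:`GroupSpec`. Returns (cohort, truth)."""
    rng = np.random.default_rng(seed)
    registry = standard_protocols()
    cohort = Cohort()
    truth = SimulatedTruth()
    for spec in specs:
        for ci in range(spec.n_cells):
            cell_id = f"{spec.group}_c{ci:03d}"
            cell, cell_truth = _generate_cell(
                rng, spec, cell_id, registry, protocols, sample_rate_hz,
                noise_sd_mV, sweep_duration_s, n_sweeps, include_ahp,
                include_adp, onset_spike)
            cohort.cells.append(cell)
            truth.cells[cell_id] = cell_truth
    return cohort, truth


def _generate_cell(rng, spec: GroupSpec, cell_id, registry, protocols,
                   fs, noise_sd, dur, n_sweeps, include_ahp, include_adp,
                   onset_spike):
    thr = rng.normal(-41.0, 1.0)
    rest = thr - abs(rng.normal(31.0, 2.0))
    rin = rng.normal(55.0, 5.0)
    adp_peak = max(rng.normal(spec.adp_peak_mean, spec.adp_peak_sd), 0.05)
    mahp = min(rng.normal(spec.mahp_mean, spec.mahp_sd), -0.5)
    # envelope construction needs mahp < sahp < 0
    sahp = float(np.clip(rng.normal(spec.sahp_mean, spec.sahp_sd),
                         0.95 * mahp, -0.1))
    v_peak = thr + 82.0

    cell = CellRecord(
        cell_id=cell_id, group=spec.group, spontaneous_threshold_mV=thr,
        resting_potential_mV=rest, condition="carbachol",
        qc=CellQC(resting_potential_mV=rest, input_resistance_MOhm=rin,
                  max_ap_height_above_holding_mV=v_peak - (thr - 2.0)))
    cell_truth = {
        "params": {"threshold_mV": thr, "adp_peak_mV": adp_peak,
                   "mahp_mV": mahp, "sahp_mV": sahp},
        "protocols": {}, "ahp": [], "adp": [],
    }

    for pname in protocols:
        proto = registry[pname]
        holding = cell.holding_for(proto)
        sweeps, sweep_truths = [], []
        for k in range(n_sweeps):
            fires = bool(rng.uniform() < spec.p_fire)
            latency = np.nan
            persist = np.array([])
            if fires:
                latency = float(np.clip(
                    rng.normal(spec.latency_mean, spec.latency_sd), 0.05, 9.5))
                t0 = proto.stim_offset_s + latency
                persist = sample_rise_poisson(rng, t0, dur, spec.rate_ymax,
                                              spec.rate_tau)
                if onset_spike:
                    persist = np.concatenate([[t0], persist[persist >= t0 + REFRACTORY_S]])
            sw = _build_persistence_sweep(
                rng, proto, fs, dur, k, holding, thr, v_peak, adp_peak,
                spec.pp_decay_tau, persist, noise_sd)
            sweeps.append(sw)
            sweep_truths.append({"fires": fires, "latency_s": latency,
                                 "spike_times_s": persist.tolist()})
        cell.sweeps[pname] = sweeps
        cell_truth["protocols"][pname] = sweep_truths

    if include_adp:
        proto = registry["adp_10mv"]
        holding = cell.holding_for(proto)
        sweeps = []
        for k in range(proto.n_repeats):
            sw = _build_persistence_sweep(
                rng, proto, fs, 5.0, k, holding, thr, v_peak, adp_peak,
                spec.pp_decay_tau, np.array([]), noise_sd)
            sweeps.append(sw)
            cell_truth["adp"].append({"adp_peak_mV": adp_peak})
        cell.sweeps["adp_10mv"] = sweeps

    if include_ahp:
        proto = registry["ahp_burst"]
        holding = proto.absolute_holding_mV
        sweeps = []
        for k in range(proto.n_repeats):
            sw = _build_ahp_sweep(rng, proto, fs, 3.0, k, holding, thr,
                                  v_peak, mahp, sahp, noise_sd)
            sweeps.append(sw)
            cell_truth["ahp"].append({"mahp_mV": mahp, "sahp_mV": sahp})
        cell.sweeps["ahp_burst"] = sweeps

    return cell, cell_truth


def _build_persistence_sweep(rng, proto, fs, dur, index, holding, thr, v_peak,
                             adp_peak, pp_tau, persist_times, noise_sd):
    n = int(round(fs * dur))
    t = np.arange(n) / fs
    v = np.full(n, holding)
    off = proto.stim_offset_s
    post = t > off
    v[post] += adp_peak * np.exp(-(t[post] - off) / pp_tau)
    # evoked spikes: one per pulse (trains) or 20 Hz during the step
    if proto.kind == "step":
        n_evoked = int(round(proto.step_duration_s * 20.0))
        evoked = proto.stim_onset_s + 0.002 + np.arange(n_evoked) / 20.0
    else:
        evoked = proto.pulse_onsets_s() + 0.0015
    insert_spikes(v, fs, evoked, thr, v_peak)
    if len(persist_times):
        insert_spikes(v, fs, persist_times, thr, v_peak)
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, n)
    cmd = reconstruct_command(proto, fs, dur)
    return Sweep(sample_rate_hz=fs, voltage_mV=v, command_current_pA=cmd,
                 protocol=proto, sweep_index=index, duration_s=dur,
                 holding_mV=holding)


def _build_ahp_sweep(rng, proto, fs, dur, index, holding, thr, v_peak,
                     mahp, sahp, noise_sd):
    n = int(round(fs * dur))
    t = np.arange(n) / fs
    v = np.full(n, holding)
    off = proto.stim_offset_s
    post = t > off
    v[post] += _ahp_envelope(t[post] - off, mahp, sahp)
    insert_spikes(v, fs, proto.pulse_onsets_s() + 0.0015, thr, v_peak)
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, n)
    cmd = reconstruct_command(proto, fs, dur)
    return Sweep(sample_rate_hz=fs, voltage_mV=v, command_current_pA=cmd,
                 protocol=proto, sweep_index=index, duration_s=dur,
                 holding_mV=holding)


# ------------------------------------------------------------ behavior cohort
TRIAL_DURATION_S = 1.8
CS_ONSET_S = 0.5
BURST_WIDTH_S = 0.050


def make_emg_trial(rng, sample_rate_hz: float, noise_sd: float,
                   is_cr: bool, trial_type: str = "paired",
                   burst_sd_units: float = 6.0,
                   alpha: bool = False) -> EMGTrial:
    """One rectified-EMG trial; CR bursts sit inside the scoring window."""
    n = int(round(TRIAL_DURATION_S * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    emg = np.abs(rng.normal(0.0, noise_sd, n))
    us_onset = CS_ONSET_S + 0.250 + 0.500
    if is_cr and trial_type != "us_alone":
        _add_half_sine(emg, t, center=us_onset - 0.1,
                       amp=burst_sd_units * noise_sd)
    if alpha and not is_cr:
        # startle deflection to the CS, entirely before the scoring window
        _add_half_sine(emg, t, center=CS_ONSET_S + 0.05,
                       amp=burst_sd_units * noise_sd)
    if trial_type == "us_alone":
        _add_half_sine(emg, t, center=us_onset + 0.05, amp=10.0 * noise_sd)
    return EMGTrial(sample_rate_hz=sample_rate_hz, emg=emg,
                    cs_onset_s=CS_ONSET_S, trial_type=trial_type)


def _add_half_sine(emg, t, center, amp):
    m = np.abs(t - center) <= BURST_WIDTH_S / 2
    emg[m] += amp * np.cos(np.pi * (t[m] - center) / BURST_WIDTH_S)


def generate_behavior_cohort(specs, seed: int,
                             sample_rate_hz: float = 1000.0,
                             noise_sd: float = 1.0,
                             burst_sd_units: float = 6.0,
                             alpha_prob: float = 0.2,
                             n_trials: int = 30,
                             exact_counts: bool = False):
    """Generate 5-session behavioral animals per group. Returns (cohort, truth).

    With ``exact_counts=True`` each session contains exactly
    ``round(p * n_trials)`` CR trials (placed first), giving exact %CR.
    """
    rng = np.random.default_rng(seed)
    cohort = Cohort()
    truth = SimulatedTruth()
    for spec in specs:
        for ai in range(spec.n_animals):
            animal_id = f"{spec.group}_a{ai:03d}"
            animal = Animal(animal_id=animal_id, group=spec.group,
                            paradigm=spec.paradigm)
            truth.animals[animal_id] = {"sessions": {}}
            for si, p in enumerate(spec.cr_prob_by_session, start=1):
                if exact_counts:
                    k = int(round(p * n_trials))
                    cr_flags = np.array([True] * k + [False] * (n_trials - k))
                else:
                    cr_flags = rng.uniform(size=n_trials) < p
                trials = []
                if spec.paradigm == "conditioned":
                    for cr in cr_flags:
                        trials.append(make_emg_trial(
                            rng, sample_rate_hz, noise_sd, bool(cr), "paired",
                            burst_sd_units,
                            alpha=bool(rng.uniform() < alpha_prob)))
                else:
                    kinds = np.array(["cs_alone"] * n_trials + ["us_alone"] * n_trials)
                    kinds = kinds[rng.permutation(2 * n_trials)]
                    cr_iter = iter(cr_flags)
                    flags_in_order = []
                    for kind in kinds:
                        if kind == "cs_alone":
                            cr = bool(next(cr_iter))
                            flags_in_order.append(cr)
                            trials.append(make_emg_trial(
                                rng, sample_rate_hz, noise_sd, cr, "cs_alone",
                                burst_sd_units,
                                alpha=bool(rng.uniform() < alpha_prob)))
                        else:
                            trials.append(make_emg_trial(
                                rng, sample_rate_hz, noise_sd, False,
                                "us_alone", burst_sd_units))
                    cr_flags = np.array(flags_in_order)
                animal.sessions.append(Session(session_index=si, trials=trials,
                                               paradigm=spec.paradigm))
                truth.animals[animal_id]["sessions"][si] = cr_flags.tolist()
            cohort.animals.append(animal)
    return cohort, truth
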