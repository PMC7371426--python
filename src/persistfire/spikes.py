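"""Action-potential detection, per-AP waveform features, passive properties.

Detector: an AP is registered where dV/dt crosses ``dvdt_threshold`` upward
and the voltage subsequently peaks at least 20 mV above the crossing point
within 5 ms. Spike time is the peak time. Threshold voltage/time are
refined by linear sub-sample interpolation of the dV/dt crossing.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SampleRateTooLowError, SingularFitError
from .model import Sweep

DVDT_THRESHOLD_VS = 20.0     # V/s
MIN_SAMPLE_RATE_HZ = 2000.0
CONFIRM_WINDOW_S = 0.005
CONFIRM_AMP_MV = 20.0
REFRACTORY_FLOOR_S = 0.002


@dataclass
class APFeatures:
    threshold_mV: float
    amplitude_mV: float
    half_width_ms: float
    dvdt_max_Vs: float
    peak_time_s: float
    threshold_time_s: float


@dataclass
class SpikeTrain:
    spike_times_s: np.ndarray
    features: list = field(default_factory=list)

    def __post_init__(self):
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)

    def __len__(self):
        return len(self.spike_times_s)

    def in_window(self, start_s: float, end_s: float,
                  inclusive_end: bool = True) -> np.ndarray:
        t = self.spike_times_s
        m = (t > start_s) & ((t <= end_s) if inclusive_end else (t < end_s))
        return t[m]


@dataclass
class InputResistanceFit:
    slope_MOhm: float
    intercept_mV: float
    r_squared: float


def _dvdt_Vs(v_mV: np.ndarray, fs: float, smooth_samples: int = 0) -> np.ndarray:
    """Central-difference dV/dt in V/s (== mV/ms); optional boxcar smoothing."""
    v = v_mV
    if smooth_samples and smooth_samples > 1:
        kern = np.ones(smooth_samples) / smooth_samples
        v = np.convolve(v, kern, mode="same")
    d = np.empty_like(v)
    d[1:-1] = (v[2:] - v[:-2]) * fs / 2.0
    d[0] = (v[1] - v[0]) * fs
    d[-1] = (v[-1] - v[-2]) * fs
    return d / 1000.0  # mV/s -> V/s


def detect_spikes(sweep: Sweep, dvdt_threshold: float = DVDT_THRESHOLD_VS,
                  smooth_samples: int = 0) -> SpikeTrain:
    """Detect APs in one sweep and compute per-AP features."""
    fs = sweep.sample_rate_hz
    if fs < MIN_SAMPLE_RATE_HZ:
        raise SampleRateTooLowError(
            f"sample rate {fs} Hz < {MIN_SAMPLE_RATE_HZ} Hz: cannot estimate dV/dt")
    v = sweep.voltage_mV
    if not np.all(np.isfinite(v)):
        raise ValueError("voltage series contains non-finite values")
    d = _dvdt_Vs(v, fs, smooth_samples)

    above = d >= dvdt_threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    confirm = max(int(round(CONFIRM_WINDOW_S * fs)), 2)

    times, feats = [], []
    last_peak_idx = -np.inf
    for c in crossings:
        if c - last_peak_idx < REFRACTORY_FLOOR_S * fs:
            continue
        seg = v[c:min(c + confirm, len(v))]
        if not len(seg):
            continue
        rel_peak = int(np.argmax(seg))
        pk = c + rel_peak
        # local maximum required (not a rising edge cut by the window end)
        if pk + 1 < len(v) and v[pk + 1] > v[pk]:
            continue
        if v[pk] - v[c] < CONFIRM_AMP_MV:
            continue
        # sub-sample refinement of the crossing
        f = (dvdt_threshold - d[c - 1]) / (d[c] - d[c - 1]) if d[c] != d[c - 1] else 0.0
        f = float(np.clip(f, 0.0, 1.0))
        thr_v = v[c - 1] + f * (v[c] - v[c - 1])
        thr_t = (c - 1 + f) / fs
        amp = v[pk] - thr_v
        hw = _half_width_ms(v, fs, c, pk, thr_v + amp / 2.0)
        dvdt_max = float(np.max(d[c:pk + 1])) if pk >= c else float(d[c])
        times.append(pk / fs)
        feats.append(APFeatures(threshold_mV=float(thr_v), amplitude_mV=float(amp),
                                half_width_ms=hw, dvdt_max_Vs=dvdt_max,
                                peak_time_s=pk / fs, threshold_time_s=thr_t))
        last_peak_idx = pk
    return SpikeTrain(spike_times_s=np.array(times), features=feats)


def _half_width_ms(v, fs, c, pk, half_level) -> float:
    """Width at half height (threshold + amplitude/2), linear interpolation."""
    # upward crossing between c and pk
    i_up = None
    for i in range(max(c - 1, 0), pk):
        if v[i] < half_level <= v[i + 1]:
            i_up = i + (half_level - v[i]) / (v[i + 1] - v[i])
            break
    # downward crossing after the peak
    i_dn = None
    stop = min(pk + int(0.02 * fs), len(v) - 1)
    for i in range(pk, stop):
        if v[i] >= half_level > v[i + 1]:
            i_dn = i + (v[i] - half_level) / (v[i] - v[i + 1])
            break
    if i_up is None or i_dn is None:
        return float("nan")
    return (i_dn - i_up) / fs * 1e3


def split_evoked_persistent(train: SpikeTrain, sweep: Sweep):
    """Tag spikes with peaks inside the stimulus window as evoked.

    Only post-offset spikes count toward persistence metrics.
    """
    proto = sweep.protocol
    t = train.spike_times_s
    evoked = (t >= proto.stim_onset_s) & (t <= proto.stim_offset_s)
    post = t > proto.stim_offset_s
    return t[evoked], t[post]


def ap_features_first_last(sweeps, trains=None, dvdt_threshold=DVDT_THRESHOLD_VS):
    """Features of the first persistent-firing AP and the last AP per sweep.

    Returns a dict with per-sweep (first, last) feature pairs and cross-sweep
    means; sweeps with no post-offset spikes contribute nothing. If no sweep
    has post-offset spikes the result is explicitly empty (``n=0``), not an
    exception.
    """
    if trains is None:
        trains = [detect_spikes(sw, dvdt_threshold) for sw in sweeps]
    per_sweep = []
    for sw, tr in zip(sweeps, trains):
        off = sw.protocol.stim_offset_s
        post_idx = np.flatnonzero(tr.spike_times_s > off)
        if not len(post_idx):
            continue
        per_sweep.append((tr.features[post_idx[0]], tr.features[post_idx[-1]]))
    result = {"n": len(per_sweep), "per_sweep": per_sweep}
    if per_sweep:
        for label, sel in (("first", 0), ("last", 1)):
            for attr in ("threshold_mV", "amplitude_mV", "half_width_ms",
                         "dvdt_max_Vs"):
                vals = [getattr(p[sel], attr) for p in per_sweep]
                result[f"mean_{label}_{attr}"] = float(np.nanmean(vals))
    return result


def steady_state_voltage(sweep: Sweep, window=(0.7, 0.9)) -> float:
    """Mean voltage over 700-900 ms of a 1 s current step (from step onset)."""
    on = sweep.protocol.stim_onset_s
    t = sweep.time_s()
    m = (t >= on + window[0]) & (t < on + window[1])
    return float(np.mean(sweep.voltage_mV[m]))


def input_resistance(steps) -> InputResistanceFit:
    """OLS slope of steady-state voltage (mV) vs injected current (pA), in MOhm.

    ``steps`` is a sequence of (current_pA, steady_state_voltage_mV) pairs.
    mV per nA equals MOhm, so the slope is scaled by 1000 from mV/pA.
    """
    steps = np.asarray(list(steps), dtype=float)
    if steps.ndim != 2 or len(steps) < 2:
        raise SingularFitError("need at least 2 (current, voltage) points")
    i_pA, v_mV = steps[:, 0], steps[:, 1]
    if np.ptp(i_pA) == 0:
        raise SingularFitError("identical current levels: singular fit")
    slope_mV_per_pA, intercept = np.polyfit(i_pA, v_mV, 1)
    pred = slope_mV_per_pA * i_pA + intercept
    ss_res = float(np.sum((v_mV - pred) ** 2))
    ss_tot = float(np.sum((v_mV - np.mean(v_mV)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return InputResistanceFit(slope_MOhm=float(slope_mV_per_pA * 1e3),
                              intercept_mV=float(intercept), r_squared=r2)
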