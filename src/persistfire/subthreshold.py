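"""Postburst AHP and ADP/plateau-potential quantification.

Sign convention: both AHP components are (trace value - holding), so
hyperpolarizations are negative. ADP peak and area are likewise relative to
holding (area may be negative if the trace dips below holding).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

from .errors import SpikeContaminationError, WindowOutOfRangeError
from .model import Sweep
from .spikes import detect_spikes

MAHP_SEARCH_S = 0.5        # negative-peak search window after burst offset
SAHP_AT_S = 1.0            # sAHP sampled exactly 1 s after burst offset
ADP_PEAK_SEARCH_S = 2.0    # ADP peak search window after stimulus offset
BASELINE_S = 0.1           # pre-stimulus window for holding estimation


def estimate_holding(sweep: Sweep, baseline_s: float = BASELINE_S) -> float:
    """Mean voltage over the 100 ms immediately preceding stimulus onset."""
    fs = sweep.sample_rate_hz
    i1 = int(round(sweep.protocol.stim_onset_s * fs))
    i0 = max(i1 - int(round(baseline_s * fs)), 0)
    return float(np.mean(sweep.voltage_mV[i0:i1]))


@dataclass
class AHPResult:
    mAHP_mV: float
    sAHP_mV: float
    holding_mV: float


@dataclass
class ADPResult:
    adp_peak_mV: float
    auc_mV_ms: float
    integration_window_s: tuple
    holding_mV: float


def measure_ahp(sweep: Sweep, burst_offset_s: Optional[float] = None,
                holding_mV: Optional[float] = None,
                mahp_search_s: float = MAHP_SEARCH_S) -> AHPResult:
    """mAHP (post-burst negative peak) and sAHP (value at +1 s), one sweep."""
    if burst_offset_s is None:
        burst_offset_s = sweep.protocol.stim_offset_s
    if holding_mV is None:
        holding_mV = sweep.holding_mV if sweep.holding_mV is not None \
            else estimate_holding(sweep)
    fs = sweep.sample_rate_hz
    if burst_offset_s + SAHP_AT_S > sweep.duration_s:
        raise WindowOutOfRangeError(
            "burst offset + 1 s extends past the end of the sweep")
    i0 = int(np.floor(burst_offset_s * fs)) + 1          # strictly after offset
    i1 = int(np.floor((burst_offset_s + mahp_search_s) * fs)) + 1
    mahp = float(np.min(sweep.voltage_mV[i0:i1])) - holding_mV
    i_s = int(round((burst_offset_s + SAHP_AT_S) * fs))
    sahp = float(sweep.voltage_mV[min(i_s, sweep.n_samples - 1)]) - holding_mV
    return AHPResult(mAHP_mV=mahp, sAHP_mV=sahp, holding_mV=holding_mV)


def measure_adp(sweep: Sweep, stim_offset_s: Optional[float] = None,
                holding_mV: Optional[float] = None,
                window_end_s: Optional[float] = None,
                peak_search_s: float = ADP_PEAK_SEARCH_S,
                check_spikes: bool = True) -> ADPResult:
    """ADP peak and trapezoidal area under (voltage - holding), one sweep.

    The integration window defaults to stimulus offset -> sweep end. The
    protocol is designed to preclude firing; detected post-offset spikes
    raise :class:`SpikeContaminationError`.
    """
    if stim_offset_s is None:
        stim_offset_s = sweep.protocol.stim_offset_s
    if holding_mV is None:
        holding_mV = sweep.holding_mV if sweep.holding_mV is not None \
            else estimate_holding(sweep)
    if window_end_s is None:
        window_end_s = sweep.duration_s
    if window_end_s > sweep.duration_s:
        raise WindowOutOfRangeError("integration window extends past sweep end")

    if check_spikes:
        train = detect_spikes(sweep)
        if np.any(train.spike_times_s > stim_offset_s):
            raise SpikeContaminationError(
                "post-offset action potentials detected in ADP sweep")

    fs = sweep.sample_rate_hz
    t = sweep.time_s()
    rel = sweep.voltage_mV - holding_mV

    m_pk = (t > stim_offset_s) & (t <= stim_offset_s + peak_search_s)
    adp_peak = float(np.max(rel[m_pk]))

    m_int = (t > stim_offset_s) & (t <= window_end_s)
    auc = float(np.trapezoid(rel[m_int], t[m_int])) * 1e3  # mV*s -> mV*ms
    return ADPResult(adp_peak_mV=adp_peak, auc_mV_ms=auc,
                     integration_window_s=(stim_offset_s, window_end_s),
                     holding_mV=holding_mV)


def cell_ahp(sweeps, **kwargs) -> dict:
    """Per-sweep AHP measurements and their means (target 5 sweeps)."""
    per_sweep = [measure_ahp(sw, **kwargs) for sw in sweeps]
    return {
        "per_sweep": per_sweep,
        "n_sweeps": len(per_sweep),
        "mAHP_mV": float(np.mean([r.mAHP_mV for r in per_sweep])),
        "sAHP_mV": float(np.mean([r.sAHP_mV for r in per_sweep])),
    }


def cell_adp(sweeps, **kwargs) -> dict:
    """Per-sweep ADP measurements and their means (target 3 sweeps)."""
    per_sweep = [measure_adp(sw, **kwargs) for sw in sweeps]
    return {
        "per_sweep": per_sweep,
        "n_sweeps": len(per_sweep),
        "adp_peak_mV": float(np.mean([r.adp_peak_mV for r in per_sweep])),
        "auc_mV_ms": float(np.mean([r.auc_mV_ms for r in per_sweep])),
    }


def adp_firing_relationships(adp_peaks, mean_rates=None, onset_latencies=None,
                             fired_flags=None) -> dict:
    """Pearson correlations of ADP peak with rate/latency + a threshold scan.

    The threshold scan reports the ADP value best separating firing from
    non-firing cells (fewest misclassifications; midpoint of the optimal
    split) for the 5-mV-below condition.
    """
    adp = np.asarray(adp_peaks, dtype=float)
    if len(adp) < 3:
        raise ValueError("need at least 3 paired cells")
    out = {}
    if mean_rates is not None:
        r, p = sps.pearsonr(adp, np.asarray(mean_rates, dtype=float))
        out["rate"] = {"r": float(r), "p": float(p)}
    if onset_latencies is not None:
        r, p = sps.pearsonr(adp, np.asarray(onset_latencies, dtype=float))
        out["latency"] = {"r": float(r), "p": float(p)}
    if fired_flags is not None:
        out["firing_boundary_mV"] = _best_separating_threshold(
            adp, np.asarray(fired_flags, dtype=bool))
    return out


def _best_separating_threshold(x: np.ndarray, y: np.ndarray) -> float:
    """Cut c minimizing misclassifications of rule (x >= c) -> fires."""
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    cuts = np.concatenate([[xs[0] - 1.0], (xs[1:] + xs[:-1]) / 2.0,
                           [xs[-1] + 1.0]])
    best_c, best_err = cuts[0], np.inf
    for c in cuts:
        err = np.sum((xs >= c) != ys)
        if err < best_err:
            best_c, best_err = c, err
    return float(best_c)


def paired_condition_compare(pre, post) -> dict:
    """Paired pre/post comparison: differences + Wilcoxon signed-rank.

    Reports the signed-rank sum W = sum(sign(d) * rank|d|) over nonzero
    differences, with an exact two-sided p for n <= 20 (normal approximation
    above). Identical pre/post (all-zero differences) is reported as
    degenerate rather than raising.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length")
    diff = post - pre
    nz = diff[diff != 0.0]
    out = {
        "n": int(len(diff)),
        "mean_pre": float(np.mean(pre)),
        "mean_post": float(np.mean(post)),
        "mean_diff": float(np.mean(diff)),
        "differences": diff.tolist(),
    }
    if len(nz) == 0:
        out.update({"W": 0.0, "p_value": None, "degenerate": True})
        return out
    ranks = sps.rankdata(np.abs(nz))
    w_signed = float(np.sum(np.sign(nz) * ranks))
    method = "exact" if len(nz) <= 20 else "approx"
    res = sps.wilcoxon(nz, alternative="two-sided", method=method)
    out.update({"W": w_signed, "p_value": float(res.pvalue),
                "degenerate": False, "method": method})
    return out
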