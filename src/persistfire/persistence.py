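"""Persistent-firing metrics: incidence, probability, binned rate, latency,
and the one-phase exponential rise fit.

Conventions (fixed here, configurable where noted):

* Incidence window: strictly after stimulus offset, inclusive at +10 s.
* Rate bins: half-open [k, k+1) s anchored at stimulus offset; bin value is
  the spike count (spikes/s, since bins are 1 s wide). Empty bins are 0 and
  non-firing sweeps of a partially firing cell contribute all-zero vectors.
* Mean rate: per-sweep mean over all post-offset bins, then the cross-sweep
  mean (zero-filled sweeps included). Cells with 0% probability are excluded.
* Onset latency: first post-offset spike time minus offset, averaged over
  firing sweeps only.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .errors import ExcludedCellError
from .model import Sweep
from .spikes import SpikeTrain, detect_spikes

INCIDENCE_WINDOW_S = 10.0
FIT_WINDOW_S = 9.0


def classify_incidence(spikes: SpikeTrain, stim_offset_s: float,
                       window_s: float = INCIDENCE_WINDOW_S) -> bool:
    """True iff at least one spike lies in (offset, offset + window]."""
    t = spikes.spike_times_s
    return bool(np.any((t > stim_offset_s) & (t <= stim_offset_s + window_s)))


def cell_probability(incidences) -> float:
    """Proportion of recorded sweeps with positive incidence."""
    incidences = list(incidences)
    if not incidences:
        raise ValueError("no recorded sweeps")
    return float(sum(bool(i) for i in incidences) / len(incidences))


def binned_rate(spikes: SpikeTrain, stim_offset_s: float,
                sweep_end_s: float) -> np.ndarray:
    """Spike counts in 1 s bins [offset+k, offset+k+1), zero-filled.

    The final bin is allowed to be partial (when sweep_end - offset is not a
    whole number of seconds) so that the bin sum conserves the number of
    post-offset spikes.
    """
    n_bins = int(np.ceil(sweep_end_s - stim_offset_s))
    t = spikes.spike_times_s
    t = t[t > stim_offset_s]
    counts, _ = np.histogram(t - stim_offset_s, bins=n_bins, range=(0, n_bins))
    return counts.astype(float)


def onset_latency(spike_trains, stim_offset_s: float,
                  window_s: float = INCIDENCE_WINDOW_S) -> float:
    """Mean first-spike latency over firing sweeps only."""
    lat = per_sweep_latencies(spike_trains, stim_offset_s, window_s)
    lat = [x for x in lat if np.isfinite(x)]
    if not lat:
        raise ExcludedCellError("no firing sweeps: latency undefined")
    return float(np.mean(lat))


def per_sweep_latencies(spike_trains, stim_offset_s: float,
                        window_s: float = INCIDENCE_WINDOW_S):
    out = []
    for tr in spike_trains:
        post = tr.in_window(stim_offset_s, stim_offset_s + window_s)
        out.append(float(post[0] - stim_offset_s) if len(post) else np.nan)
    return out


def mean_rate(binned_vectors) -> float:
    """Cross-sweep mean of per-sweep whole-window mean rates."""
    binned_vectors = [np.asarray(b, dtype=float) for b in binned_vectors]
    if not binned_vectors:
        raise ExcludedCellError("cell excluded: no rate vectors (0% probability)")
    return float(np.mean([b.mean() for b in binned_vectors]))


@dataclass
class PersistenceResult:
    """Per-cell persistence summary across the protocol's sweeps."""

    cell_id: str
    group: str
    protocol: str
    incidence: list
    probability: float
    onset_latency_s: Optional[float]
    binned_rate_per_sweep: list           # one vector per sweep, zero-filled
    mean_rate: Optional[float]
    peak_rate: Optional[float]
    peak_bin: Optional[int]
    excluded_from_rate: bool

    @property
    def mean_binned_rate(self) -> Optional[np.ndarray]:
        if self.excluded_from_rate:
            return None
        return np.mean(np.vstack(self.binned_rate_per_sweep), axis=0)


def analyze_cell(cell, protocol_name: str, dvdt_threshold: float = 20.0,
                 incidence_window_s: float = INCIDENCE_WINDOW_S,
                 trains=None) -> PersistenceResult:
    """Run detection + all persistence metrics for one cell and protocol."""
    sweeps = cell.sweeps[protocol_name]
    if trains is None:
        trains = [detect_spikes(sw, dvdt_threshold) for sw in sweeps]
    off = sweeps[0].protocol.stim_offset_s
    end = sweeps[0].duration_s
    incid = [classify_incidence(tr, off, incidence_window_s) for tr in trains]
    prob = cell_probability(incid)
    excluded = prob == 0.0

    binned = [binned_rate(tr, off, end) for tr in trains]
    # zero-fill rule: sweeps without incidence contribute all-zero vectors
    binned = [b if inc else np.zeros_like(b) for b, inc in zip(binned, incid)]

    if excluded:
        return PersistenceResult(
            cell_id=cell.cell_id, group=cell.group, protocol=protocol_name,
            incidence=incid, probability=prob, onset_latency_s=None,
            binned_rate_per_sweep=binned, mean_rate=None, peak_rate=None,
            peak_bin=None, excluded_from_rate=True)

    lat = onset_latency(trains, off, incidence_window_s)
    mr = mean_rate(binned)
    mean_curve = np.mean(np.vstack(binned), axis=0)
    peak_bin = int(np.argmax(mean_curve))
    return PersistenceResult(
        cell_id=cell.cell_id, group=cell.group, protocol=protocol_name,
        incidence=incid, probability=prob, onset_latency_s=lat,
        binned_rate_per_sweep=binned, mean_rate=mr,
        peak_rate=float(mean_curve[peak_bin]), peak_bin=peak_bin,
        excluded_from_rate=False)


def group_probability(results) -> dict:
    """Group probability as mean% +/- SEM plus quartiles of cell proportions."""
    probs = np.asarray([r.probability for r in results], dtype=float)
    if not len(probs):
        raise ValueError("no cells")
    n = len(probs)
    sem = float(np.std(probs, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    q1, med, q3 = np.percentile(probs, [25, 50, 75])  # linear interpolation
    return {"n": n, "mean_pct": float(probs.mean() * 100.0),
            "sem_pct": sem * 100.0, "q1": float(q1), "median": float(med),
            "q3": float(q3)}


def group_mean_curve(results) -> np.ndarray:
    """Cross-cell mean of per-cell mean binned-rate curves (rate cells only)."""
    curves = [r.mean_binned_rate for r in results if not r.excluded_from_rate]
    if not curves:
        raise ExcludedCellError("no rate-eligible cells in group")
    n = min(len(c) for c in curves)
    return np.mean(np.vstack([c[:n] for c in curves]), axis=0)


@dataclass
class RateFit:
    ymax: float
    tau: float
    rss: float
    converged: bool
    fit_window_s: tuple = (0.0, FIT_WINDOW_S)
    message: str = ""


def rise_model(t, ymax, tau):
    """Y(t) = Ymax * (1 - exp(-t / tau)): saturating one-phase rise."""
    return ymax * (1.0 - np.exp(-t / tau))


def fit_rise(rate_curve, window_s: float = FIT_WINDOW_S,
             n_restarts: int = 5, seed: int = 0) -> RateFit:
    """Least-squares fit of the one-phase rise to a binned rate curve.

    Bin k is evaluated at its center t = k + 0.5 s; only bins whose centers
    fall inside [0, window_s] are fitted. Non-convergence after bounded
    jittered restarts returns ``converged=False`` (no exception).
    """
    y = np.asarray(rate_curve, dtype=float)
    t = np.arange(len(y)) + 0.5
    m = t <= window_s
    t, y = t[m], y[m]
    if len(t) < 3:
        raise ValueError("need at least 3 bins inside the fit window")

    ymax0 = max(float(np.max(y)), 1e-6)
    bounds = ([1e-9, 0.05], [10.0 * ymax0, 50.0])
    rng = np.random.default_rng(seed)
    best = None
    for k in range(n_restarts):
        p0 = (ymax0, 2.0) if k == 0 else (
            float(ymax0 * rng.uniform(0.3, 2.0)),
            float(np.exp(rng.uniform(np.log(0.1), np.log(20.0)))))
        try:
            popt, _ = curve_fit(rise_model, t, y, p0=p0, bounds=bounds,
                                maxfev=10000)
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((y - rise_model(t, *popt)) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        return RateFit(ymax=float("nan"), tau=float("nan"), rss=float("inf"),
                       converged=False, fit_window_s=(0.0, window_s),
                       message="no restart converged")
    (ymax, tau), rss = best
    msg = ""
    # near-degenerate: a flat curve pushes tau to its lower bound
    if tau <= 0.0501 or ymax >= 10.0 * ymax0 * 0.999:
        msg = "near-degenerate fit (parameter at bound)"
    return RateFit(ymax=float(ymax), tau=float(tau), rss=rss, converged=True,
                   fit_window_s=(0.0, window_s), message=msg)


def fit_group_rise(results, window_s: float = FIT_WINDOW_S) -> RateFit:
    """Fit to the cross-cell mean curve (the table-matching quantity)."""
    return fit_rise(group_mean_curve(results), window_s=window_s)


def fit_per_cell_rise(results, window_s: float = FIT_WINDOW_S) -> dict:
    """Per-cell fits, offered alongside the group fit."""
    out = {}
    for r in results:
        if not r.excluded_from_rate:
            out[r.cell_id] = fit_rise(r.mean_binned_rate, window_s=window_s)
    return out
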