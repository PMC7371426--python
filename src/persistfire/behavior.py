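"""EMG conditioned-response scoring, session %CR, learning curves, and the
impaired/unimpaired split of aged animals.

Scoring rule: a trial is a conditioned response (CR) when the smoothed
rectified EMG exceeds baseline mean + 4 SD anywhere inside the 200 ms window
immediately preceding US onset ("late" CRs: startle/alpha deflections to the
CS fall outside this window and never count). The rule is scale-free.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientBaselineError, UnscoreableTrialError
from .model import EMGTrial, Session

SD_THRESHOLD = 4.0
BASELINE_S = 0.250        # pre-CS baseline window
SCORING_WINDOW_S = 0.200  # window ending at US onset
SMOOTH_S = 0.010          # moving-average width
CRITERION_PCT = 60.0      # unimpaired/impaired split on the final session


@dataclass
class TrialScore:
    is_cr: bool
    baseline_mean: float
    baseline_sd: float
    max_in_window: float
    window_s: tuple


def _smooth_rectified(emg: np.ndarray, fs: float,
                      smooth_s: float = SMOOTH_S) -> np.ndarray:
    x = np.abs(emg)
    k = max(int(round(smooth_s * fs)), 1)
    if k == 1:
        return x
    return np.convolve(x, np.ones(k) / k, mode="same")


def score_trial(trial: EMGTrial, sd_threshold: float = SD_THRESHOLD,
                baseline_s: float = BASELINE_S,
                window_s: float = SCORING_WINDOW_S,
                smooth_s: float = SMOOTH_S) -> TrialScore:
    """Score one paired or cs_alone trial; us_alone trials are never scored."""
    if trial.trial_type == "us_alone":
        raise UnscoreableTrialError("us_alone trials are never scored")
    fs = trial.sample_rate_hz
    rect = np.abs(trial.emg)
    x = _smooth_rectified(trial.emg, fs, smooth_s)
    t = np.arange(len(x)) / fs

    b_mask = (t >= trial.cs_onset_s - baseline_s) & (t < trial.cs_onset_s)
    if b_mask.sum() < 2 or trial.cs_onset_s - baseline_s < 0:
        raise InsufficientBaselineError(
            f"need {baseline_s * 1e3:.0f} ms of pre-CS baseline")
    # baseline statistics from the rectified (unsmoothed) signal: the
    # smoothed envelope has too few independent baseline samples for a
    # stable SD estimate; the comparison stays scale-free either way
    base = rect[b_mask]
    mu, sd = float(np.mean(base)), float(np.std(base, ddof=1))

    w0 = trial.us_onset_s - window_s
    w_mask = (t >= w0) & (t < trial.us_onset_s)
    mx = float(np.max(x[w_mask]))
    return TrialScore(is_cr=bool(mx > mu + sd_threshold * sd),
                      baseline_mean=mu, baseline_sd=sd, max_in_window=mx,
                      window_s=(w0, trial.us_onset_s))


def session_pct_cr(session: Session, **score_kwargs) -> float:
    """100 x CR trials / scoreable trials (paired or cs_alone)."""
    scoreable = [tr for tr in session.trials if tr.trial_type != "us_alone"]
    if not scoreable:
        raise ValueError("session has no scoreable trials")
    n_cr = sum(score_trial(tr, **score_kwargs).is_cr for tr in scoreable)
    return 100.0 * n_cr / len(scoreable)


def classify_aged(final_session_pct: float) -> str:
    """AU iff the animal reached the 60% criterion (inclusive), else AI."""
    if not 0.0 <= final_session_pct <= 100.0:
        raise ValueError("percentage must be in [0, 100]")
    return "AU" if final_session_pct >= CRITERION_PCT else "AI"


@dataclass
class LearningCurve:
    animal_id: str
    group: str
    pct_cr_by_session: list   # sessions 1..5

    @property
    def final_session_pct(self) -> float:
        return self.pct_cr_by_session[-1]


def animal_learning_curve(animal, **score_kwargs) -> LearningCurve:
    """%CR per training session; the habituation session (0) is never scored."""
    sessions = sorted((s for s in animal.sessions if s.session_index > 0),
                      key=lambda s: s.session_index)
    pcts = [session_pct_cr(s, **score_kwargs) for s in sessions]
    return LearningCurve(animal_id=animal.animal_id, group=animal.group,
                         pct_cr_by_session=pcts)


def learning_curves(animals, **score_kwargs) -> dict:
    """Per-animal curves plus per-group per-session mean +/- SEM."""
    curves = [animal_learning_curve(a, **score_kwargs) for a in animals]
    groups = {}
    for c in curves:
        groups.setdefault(c.group, []).append(c)
    summary = {}
    for g in sorted(groups):
        mat = np.array([c.pct_cr_by_session for c in groups[g]], dtype=float)
        n = mat.shape[0]
        sem = mat.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(mat.shape[1])
        summary[g] = {"n": n, "mean": mat.mean(axis=0).tolist(),
                      "sem": sem.tolist()}
    return {"curves": curves, "group_summary": summary}


def split_aged(curves) -> dict:
    """Assign each animal AU/AI by its final-session %CR."""
    return {c.animal_id: classify_aged(c.final_session_pct) for c in curves}
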