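"""Shared helpers/fixtures: hand-built sweeps and small synthetic cohorts."""
import numpy as np
import pytest

from persistfire.abf_io import reconstruct_command
from persistfire.model import EMGTrial, Sweep, standard_protocols
from persistfire.simulate import GroupSpec, insert_spikes

PROTOCOLS = standard_protocols()


def make_sweep(spike_times=(), protocol="train20hz_250ms_2mv", fs=10_000.0,
               duration_s=20.0, holding=-43.0, threshold=-41.0, peak=41.0,
               noise_sd=0.0, seed=0, voltage=None):
    """A sweep at constant holding with AP templates at the given times."""
    proto = PROTOCOLS[protocol]
    n = int(round(fs * duration_s))
    if voltage is None:
        v = np.full(n, float(holding))
        insert_spikes(v, fs, np.asarray(spike_times, dtype=float),
                      threshold, peak)
        if noise_sd > 0:
            v = v + np.random.default_rng(seed).normal(0, noise_sd, n)
    else:
        v = np.asarray(voltage, dtype=float)
    return Sweep(sample_rate_hz=fs, voltage_mV=v,
                 command_current_pA=reconstruct_command(proto, fs, duration_s),
                 protocol=proto, sweep_index=0, duration_s=duration_s,
                 holding_mV=float(holding))


def make_emg_trial(emg, fs=1000.0, cs_onset=0.5, trial_type="paired"):
    return EMGTrial(sample_rate_hz=fs, emg=np.asarray(emg, dtype=float),
                    cs_onset_s=cs_onset, trial_type=trial_type)


@pytest.fixture(scope="session")
def tiny_cohort():
    """2 cells + 1 animal, low sample rate: cheap but fully populated."""
    from persistfire.simulate import generate_behavior_cohort, generate_ephys_cohort

    spec = GroupSpec(group="YN", n_cells=2, p_fire=1.0, n_animals=1,
                     cr_prob_by_session=(0.4,) * 5)
    cohort, truth = generate_ephys_cohort([spec], seed=11,
                                          sample_rate_hz=2000.0,
                                          noise_sd_mV=0.1)
    bc, bt = generate_behavior_cohort([spec], seed=12)
    cohort.animals = bc.animals
    truth.animals = bt.animals
    return cohort, truth
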