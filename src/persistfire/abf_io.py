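"""Optional read-only adapter for Axon Binary Format (ABF) episodic files.

The adapter requires ``pyabf`` (install extra ``persistfire[abf]``). The core
pipeline never imports this module implicitly, so it functions with zero ABF
files and without pyabf present.
"""
from __future__ import annotations

import numpy as np

from .errors import ABFSupportError, MissingChannelError
from .model import StimulusProtocol, Sweep


def _load_pyabf():
    try:
        import pyabf  # type: ignore
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ABFSupportError(
            "pyabf is not installed; install 'persistfire[abf]' to read ABF files"
        ) from exc
    return pyabf


def reconstruct_command(protocol: StimulusProtocol, sample_rate_hz: float,
                        duration_s: float) -> np.ndarray:
    """Idealized command-current waveform (pA) from protocol metadata.

    Used when an ABF file lacks a recorded command channel.
    """
    n = int(round(sample_rate_hz * duration_s))
    cmd = np.zeros(n)
    if protocol.kind == "step":
        i0 = int(round(protocol.stim_onset_s * sample_rate_hz))
        i1 = int(round(protocol.stim_offset_s * sample_rate_hz))
        cmd[i0:i1] = protocol.step_amplitude_pA
    else:
        amp_pA = protocol.pulse_amplitude_nA * 1000.0
        w = int(round(protocol.pulse_width_ms / 1e3 * sample_rate_hz))
        for t0 in protocol.pulse_onsets_s():
            i0 = int(round(t0 * sample_rate_hz))
            cmd[i0:i0 + w] = amp_pA
    return cmd


def read_abf_sweeps(path, channel_map: dict,
                    protocol: StimulusProtocol = None) -> list:
    """Read every episode of an episodic ABF file as a list of :class:`Sweep`.

    ``channel_map`` maps roles to ADC channel names, e.g.
    ``{"voltage": "Vm", "current": "Im"}``. If ``"current"`` is omitted or
    absent from the file, the command is reconstructed from ``protocol``
    (required in that case). Units are converted to mV/pA based on the
    file's declared channel units.
    """
    pyabf = _load_pyabf()
    try:
        abf = pyabf.ABF(str(path))
    except Exception as exc:
        raise ABFSupportError(f"cannot open ABF file {path}: {exc}") from exc
    if abf.sweepCount < 1 or getattr(abf, "nOperationMode", 5) not in (5,):
        # mode 5 = episodic stimulation; gap-free and others unsupported
        raise ABFSupportError(f"{path}: not an episodic (sweep-based) recording")

    names = list(abf.adcNames)
    if "voltage" not in channel_map:
        raise MissingChannelError("channel_map must name a 'voltage' channel")
    if channel_map["voltage"] not in names:
        raise MissingChannelError(
            f"voltage channel {channel_map['voltage']!r} not in {names}")
    v_ch = names.index(channel_map["voltage"])
    i_ch = None
    if "current" in channel_map and channel_map["current"] in names:
        i_ch = names.index(channel_map["current"])
    if i_ch is None and protocol is None:
        raise MissingChannelError(
            "no current channel available and no protocol supplied for reconstruction")

    sweeps = []
    fs = float(abf.sampleRate)
    for k in range(abf.sweepCount):
        abf.setSweep(k, channel=v_ch)
        v = np.asarray(abf.sweepY, dtype=float)
        v = _to_unit(v, abf.adcUnits[v_ch], {"mV": 1.0, "V": 1000.0}, "voltage")
        dur = len(v) / fs
        if i_ch is not None:
            abf.setSweep(k, channel=i_ch)
            i = np.asarray(abf.sweepY, dtype=float)
            i = _to_unit(i, abf.adcUnits[i_ch], {"pA": 1.0, "nA": 1000.0}, "current")
        else:
            i = reconstruct_command(protocol, fs, dur)
        sweeps.append(Sweep(sample_rate_hz=fs, voltage_mV=v, command_current_pA=i,
                            protocol=protocol, sweep_index=k, duration_s=dur))
    return sweeps


def _to_unit(x: np.ndarray, unit: str, scales: dict, role: str) -> np.ndarray:
    if unit not in scales:
        raise ABFSupportError(f"unsupported {role} unit {unit!r} in ABF file")
    return x * scales[unit]
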