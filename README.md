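# persistfire

Analysis pipeline for carbachol-evoked **persistent firing** in current-clamp
recordings and for EMG-scored **trace eyeblink conditioning**, plus a
synthetic-cohort generator with known ground truth so that every stage is
verifiable end to end.

What it computes:

* **Spike detection & AP features** — dV/dt-crossing detector (20 V/s,
  configurable) with amplitude confirmation; threshold, amplitude,
  half-width, dV/dt max; input resistance from steady-state V/I steps.
* **Persistence metrics** — incidence (any spike within 10 s after stimulus
  offset), per-cell probability (proportion of 3 sweeps), 1 s binned firing
  rate with zero-fill of silent sweeps, mean/peak rate (0%-probability cells
  excluded), onset latency, and the one-phase exponential rise fit
  `Y(t) = Ymax (1 - exp(-t/tau))` over the 0–9 s bins.
* **Subthreshold metrics** — postburst mAHP (negative-going peak after the
  15-pulse 50 Hz burst) and sAHP (value at +1 s) relative to holding; ADP
  peak and ADP/PP area under the curve (mV·ms); ADP–firing correlations and
  paired pre/post condition comparisons (Wilcoxon signed-rank).
* **Behavior** — conditioned-response scoring (smoothed rectified EMG
  exceeding baseline mean + 4 SD inside the 200 ms window before US onset),
  session %CR, learning curves, and the 60%-criterion aged
  unimpaired/impaired split.
* **Statistics & report** — mean ± SEM / quartile summaries, Mann-Whitney
  (exact for small n), Kruskal-Wallis + Dunn, ANOVA + Tukey/Sidak,
  Greenhouse-Geisser-corrected repeated-measures ANOVA, Pearson; CSV tables
  and a machine-readable `metrics.json`, deterministically ordered.

## CLI

```bash
# generate a synthetic cohort (native format + ground-truth JSON)
persistfire simulate --spec groups.yaml --seed 1 --out cohort/ \
    --noise-sd 0.2 --sample-rate 10000

# per-cell persistence metrics + group summary for one protocol
persistfire analyze-ephys --cohort cohort/ --protocol train20hz_250ms_2mv \
    --out tables/

# EMG scoring and learning curves
persistfire analyze-behavior --cohort cohort/ --out tables/ --sd-threshold 4

# everything, including subthreshold metrics and metrics.json
persistfire report --cohort cohort/ --out report/
```

`groups.yaml` holds a list of group specifications (see
`persistfire.simulate.GroupSpec`), e.g.

```yaml
groups:
  - {group: YN, n_cells: 22, p_fire: 1.0, rate_ymax: 6.0, rate_tau: 2.0}
  - {group: AN, n_cells: 10, p_fire: 0.67, rate_ymax: 4.2, rate_tau: 4.7}
```

## Native cohort format

All plain text, versioned with `format_version`:

```
cohort/
  cohort.json                       # index of cell + animal ids
  cells/<id>/cell.json              # group, thresholds, QC, protocol defs,
                                    # sweep manifest
  cells/<id>/sweeps/<proto>_s<k>.csv  # time_s, voltage_mV, current_pA
  animals/<id>/animal.json          # paradigm, session manifest
  animals/<id>/sessions/session<k>_trial<j>.csv  # time_s, emg
```

Units: seconds / mV / pA (nA pulses stored as pA). Metadata round-trips
bit-exactly; series round-trip to the written precision (1e-4 mV).

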