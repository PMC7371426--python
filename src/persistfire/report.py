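"""Report assembly: per-cell/per-animal tables, group summaries with the
paper-style layout (n, mean +/- SEM, median/quartiles, pairwise p), and a
machine-readable JSON bundle. All outputs are deterministically ordered.
"""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import persistence as pst
from . import stats as st
from . import subthreshold as sub

PER_CELL_COLUMNS = [
    "cell_id", "group", "protocol", "n_sweeps", "probability",
    "onset_latency_s", "mean_rate", "peak_rate", "peak_bin",
    "excluded_from_rate",
]
SUBTHRESHOLD_COLUMNS = [
    "cell_id", "group", "mAHP_mV", "sAHP_mV", "adp_peak_mV", "auc_mV_ms",
]
BEHAVIOR_COLUMNS = ["animal_id", "group"] + [f"session{k}_pct_cr"
                                             for k in range(1, 6)]


def analyze_ephys(cohort, protocol: str, dvdt_threshold: float = 20.0) -> dict:
    """Persistence metrics for every cell carrying ``protocol`` sweeps."""
    results = [pst.analyze_cell(c, protocol, dvdt_threshold)
               for c in cohort.cells if protocol in c.sweeps]
    results.sort(key=lambda r: r.cell_id)
    by_group: dict = {}
    for r in results:
        by_group.setdefault(r.group, []).append(r)

    rows = [{
        "cell_id": r.cell_id, "group": r.group, "protocol": r.protocol,
        "n_sweeps": len(r.incidence), "probability": r.probability,
        "onset_latency_s": r.onset_latency_s, "mean_rate": r.mean_rate,
        "peak_rate": r.peak_rate, "peak_bin": r.peak_bin,
        "excluded_from_rate": r.excluded_from_rate,
    } for r in results]
    per_cell = pd.DataFrame(rows, columns=PER_CELL_COLUMNS)

    summary_rows, fits = [], {}
    for g in sorted(by_group):
        rs = by_group[g]
        prob = pst.group_probability(rs)
        rate_cells = [r for r in rs if not r.excluded_from_rate]
        row = {"group": g, "n": prob["n"],
               "probability_pct": prob["mean_pct"],
               "probability_sem": prob["sem_pct"],
               "probability_q1": prob["q1"], "probability_median": prob["median"],
               "probability_q3": prob["q3"], "n_rate_cells": len(rate_cells)}
        if rate_cells:
            for key, vals in (
                    ("mean_rate", [r.mean_rate for r in rate_cells]),
                    ("peak_rate", [r.peak_rate for r in rate_cells]),
                    ("latency_s", [r.onset_latency_s for r in rate_cells])):
                s = st.summarize(vals)
                row[key] = s.mean
                row[f"{key}_sem"] = s.sem
            fit = pst.fit_group_rise(rate_cells)
            fits[g] = fit
            row["fit_ymax"], row["fit_tau"] = fit.ymax, fit.tau
        summary_rows.append(row)
    group_summary = pd.DataFrame(summary_rows)

    tests = {}
    if len(by_group) >= 2:
        probs = {g: [r.probability for r in rs] for g, rs in by_group.items()}
        if len(by_group) == 2:
            g1, g2 = sorted(by_group)
            tests["probability"] = [st.compare_two_unpaired(
                probs[g1], probs[g2], "mann_whitney", f"{g1} vs {g2}")]
        else:
            res = st.compare_many(probs, "kruskal_dunn")
            tests["probability"] = [res["omnibus"]] + res["pairwise"]
    return {"results_by_group": by_group, "per_cell": per_cell,
            "group_summary": group_summary, "fits": fits, "tests": tests}


def analyze_subthreshold(cohort, ahp_protocol: str = "ahp_burst",
                         adp_protocol: str = "adp_10mv") -> dict:
    """Per-cell AHP/ADP means plus per-group summaries."""
    rows = []
    for cell in sorted(cohort.cells, key=lambda c: c.cell_id):
        row = {"cell_id": cell.cell_id, "group": cell.group,
               "mAHP_mV": np.nan, "sAHP_mV": np.nan,
               "adp_peak_mV": np.nan, "auc_mV_ms": np.nan}
        if ahp_protocol in cell.sweeps:
            ahp = sub.cell_ahp(cell.sweeps[ahp_protocol])
            row["mAHP_mV"], row["sAHP_mV"] = ahp["mAHP_mV"], ahp["sAHP_mV"]
        if adp_protocol in cell.sweeps:
            adp = sub.cell_adp(cell.sweeps[adp_protocol])
            row["adp_peak_mV"], row["auc_mV_ms"] = (adp["adp_peak_mV"],
                                                    adp["auc_mV_ms"])
        if ahp_protocol in cell.sweeps or adp_protocol in cell.sweeps:
            rows.append(row)
    per_cell = pd.DataFrame(rows, columns=SUBTHRESHOLD_COLUMNS)

    summary_rows = []
    if len(per_cell):
        for g, grp in per_cell.groupby("group", sort=True):
            row = {"group": g}
            for col in ("mAHP_mV", "sAHP_mV", "adp_peak_mV", "auc_mV_ms"):
                vals = grp[col].dropna()
                if len(vals):
                    s = st.summarize(vals)
                    row[f"{col}_n"] = s.n
                    row[f"{col}_mean"] = s.mean
                    row[f"{col}_sem"] = s.sem
            summary_rows.append(row)
    return {"per_cell": per_cell, "group_summary": pd.DataFrame(summary_rows)}


def analyze_behavior(cohort, **score_kwargs) -> dict:
    """Learning curves, group means and the AU/AI split for aged animals."""
    animals = sorted(cohort.animals, key=lambda a: a.animal_id)
    lc = bhv.learning_curves(animals, **score_kwargs) if animals \
        else {"curves": [], "group_summary": {}}
    rows = []
    for c in lc["curves"]:
        row = {"animal_id": c.animal_id, "group": c.group}
        for k, pct in enumerate(c.pct_cr_by_session, start=1):
            row[f"session{k}_pct_cr"] = pct
        rows.append(row)
    per_animal = pd.DataFrame(rows, columns=BEHAVIOR_COLUMNS)
    split = bhv.split_aged([c for c in lc["curves"]
                            if c.group in ("AU", "AI", "other")])
    summary_rows = []
    for g, s in sorted(lc["group_summary"].items()):
        for sess, (m, sem) in enumerate(zip(s["mean"], s["sem"]), start=1):
            summary_rows.append({"group": g, "n": s["n"], "session": sess,
                                 "pct_cr_mean": m, "pct_cr_sem": sem})
    return {"curves": lc["curves"], "per_animal": per_animal,
            "group_summary": pd.DataFrame(
                summary_rows, columns=["group", "n", "session",
                                       "pct_cr_mean", "pct_cr_sem"]),
            "aged_split": split}


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (st.TestResult, st.GroupSummary, pst.RateFit)):
        return _jsonable(asdict(obj))
    if isinstance(obj, (np.floating, float)):
        return None if not np.isfinite(obj) else float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def build_report(cohort, out_dir, protocols=("train20hz_250ms_2mv",),
                 include_subthreshold: bool = True,
                 include_behavior: bool = True) -> dict:
    """Run the full analysis and write CSV tables + metrics.json.

    Rerunning on identical inputs produces byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    metrics: dict = {"protocols": {}}

    for proto in protocols:
        has = [c for c in cohort.cells if proto in c.sweeps]
        if has:
            eph = analyze_ephys(cohort, proto)
        else:
            eph = {"per_cell": pd.DataFrame(columns=PER_CELL_COLUMNS),
                   "group_summary": pd.DataFrame(), "fits": {}, "tests": {}}
        eph["per_cell"].to_csv(out / f"per_cell_{proto}.csv", index=False)
        eph["group_summary"].to_csv(out / f"group_summary_{proto}.csv",
                                    index=False)
        metrics["protocols"][proto] = {
            "fits": {g: eph["fits"][g] for g in sorted(eph["fits"])},
            "tests": eph["tests"],
        }

    if include_subthreshold:
        sth = analyze_subthreshold(cohort)
        sth["per_cell"].to_csv(out / "subthreshold_per_cell.csv", index=False)
        sth["group_summary"].to_csv(out / "subthreshold_group_summary.csv",
                                    index=False)

    if include_behavior:
        beh = analyze_behavior(cohort)
        beh["per_animal"].to_csv(out / "behavior_per_animal.csv", index=False)
        beh["group_summary"].to_csv(out / "behavior_group_summary.csv",
                                    index=False)
        metrics["aged_split"] = beh["aged_split"]

    (out / "metrics.json").write_text(
        json.dumps(_jsonable(metrics), indent=1, sort_keys=True) + "\n")
    return metrics
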