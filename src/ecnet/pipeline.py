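"""End-to-end cohort analysis: preprocessing -> connectivity -> graphs -> stats.

``run_pipeline`` is a pure function of (dataset, config): repeated runs with
the same inputs and seed produce identical output files.  Per subject,
condition and band it writes the thresholded adjacency, a nodal metric
table and a one-row global metric table; per cohort it writes the
subjective/behavioral statistics, hemisphere-flow tables and the
metric-outcome correlation tables, plus a run log with the seed and a
config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .connectivity import psi_all_bands
from .graphs import global_metrics, local_efficiency, nodal_metrics
from .io import write_adjacency, write_table
from .montage import default_montage
from .preprocess import preprocess
from .simulate import CohortDataset, GROUPS
from .stats import (DEFAULT_CORR_SELECTION, correlate_metrics, group_manova,
                    hemisphere_flow, paired_t, tukey_hsd)

log = logging.getLogger("ecnet")


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def analyze_recording(rec, config: PipelineConfig, montage=None):
    """Preprocess one recording and return per-band adjacencies."""
    mont = montage or default_montage()
    nper = int(round(rec.fs / config.df))
    clean, mask, _ = preprocess(
        rec, mont, lo=config.filter_lo, hi=config.filter_hi,
        reject_uv=config.reject_uv, apply_csd=config.apply_csd,
        reject_window=nper)
    return psi_all_bands(clean, config, mask=mask)


def run_pipeline(config: PipelineConfig, dataset: CohortDataset,
                 out_dir: str | Path) -> dict:
    """Run the full analysis over a cohort and write the report bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mont = default_montage()
    metric_rows = []
    hemi_rows = []
    for subj in dataset.subjects:
        for cond_name, rec in (("EO", subj.eo), ("L", subj.learning)):
            if rec is None:
                raise ValueError(f"subject {subj.id} lacks a {cond_name} recording")
            try:
                adjs = analyze_recording(rec, config, mont)
            except Exception as err:
                raise RuntimeError(
                    f"stage connectivity failed for subject {subj.id}, "
                    f"condition {cond_name}: {err}") from err
            for band, adj in adjs.items():
                stem = f"{subj.id}_{cond_name}_{band}"
                write_adjacency(adj.matrix, adj.labels,
                                out / f"{stem}_adjacency.tsv",
                                comment=f"band={band}; threshold={adj.threshold}")
                nodal = nodal_metrics(adj, quantile=config.hub_quantile)
                write_table(nodal, out / f"{stem}_nodal.tsv")
                write_table(global_metrics(adj, quantile=config.hub_quantile),
                            out / f"{stem}_global.tsv")
                hemi = hemisphere_flow(adj.psi, mont)
                hemi.insert(0, "condition", cond_name)
                hemi.insert(0, "subject", subj.id)
                hemi_rows.append(hemi)
                for _, row in nodal.iterrows():
                    for metric in ("C", "BC", "TD", "PL"):
                        metric_rows.append({
                            "subject": subj.id, "group": subj.group,
                            "condition": cond_name, "band": band,
                            "metric": {"C": "CC"}.get(metric, metric),
                            "electrode": row["node"],
                            "value": row[metric]})
                le_i, _ = local_efficiency(adj)
                for node, v in zip(adj.labels, le_i):
                    metric_rows.append({
                        "subject": subj.id, "group": subj.group,
                        "condition": cond_name, "band": band,
                        "metric": "LE", "electrode": node, "value": v})
    metrics = pd.DataFrame(metric_rows)
    write_table(metrics, out / "nodal_metrics_long.tsv")
    hemi_all = pd.concat(hemi_rows, ignore_index=True)
    write_table(hemi_all, out / "hemisphere_flow.tsv")

    stats_df, corr_full, corr_sig = cohort_statistics(dataset, metrics)
    write_table(stats_df, out / "group_stats.tsv")
    write_table(corr_full, out / "correlations_full.tsv")
    write_table(corr_sig, out / "correlations_significant.tsv")

    run_log = {"seed": config.seed, "config_hash": _config_hash(config),
               "n_subjects": len(dataset.subjects),
               "bands": sorted(config.bands)}
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2,
                                                 sort_keys=True))
    return {"metrics": metrics, "hemisphere_flow": hemi_all,
            "group_stats": stats_df, "correlations": corr_full,
            "run_log": run_log}


def sam_outcome_table(dataset: CohortDataset) -> pd.DataFrame:
    """Long outcome table (subject, group, outcome, value) with SAM changes
    (post minus pre) and behavioral measures."""
    rows = []
    for s in dataset.subjects:
        dv, da, dd = s.sam_change()
        for name, val in (("dV", dv), ("dA", da), ("dD", dd),
                          ("RT1", s.rt1), ("ACC1", s.acc1),
                          ("RT2", s.rt2), ("ACC2", s.acc2)):
            rows.append({"subject": s.id, "group": s.group,
                         "outcome": name, "value": float(val)})
    return pd.DataFrame(rows)


def cohort_statistics(dataset: CohortDataset, metrics: pd.DataFrame | None = None,
                      ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Subjective/behavioral statistics and metric-outcome correlations.

    Returns (group statistics table, full correlation table, significant
    correlation view).  Correlations are computed within groups on the
    learning-condition nodal metrics, restricted to the default
    band/metric/outcome selection.
    """
    outcomes = sam_outcome_table(dataset)
    rows = []
    for g in GROUPS:
        subs = dataset.group(g)
        if not subs:
            continue
        for dim, idx in (("V", 0), ("A", 1), ("D", 2)):
            pre = np.array([s.pre_sam[idx] for s in subs], dtype=float)
            post = np.array([s.post_sam[idx] for s in subs], dtype=float)
            try:
                res = paired_t(pre, post)
                rows.append({"test": "paired_t", "group": g, "variable": dim,
                             "statistic": res.statistic, "df": res.df[0],
                             "p": res.p, "wilks_lambda": None,
                             "partial_eta_sq": None, "comparison": None})
            except ValueError as err:
                log.warning("paired t skipped for %s/%s: %s", g, dim, err)
    groups_arr = np.array([s.group for s in dataset.subjects])
    sam_delta = np.array([s.sam_change() for s in dataset.subjects], dtype=float)
    beh = np.array([[s.rt1, s.acc1, s.rt2, s.acc2]
                    for s in dataset.subjects], dtype=float)
    for name, Y in (("SAM_change", sam_delta), ("behavior", beh)):
        try:
            res = group_manova(Y, groups_arr)
            rows.append({"test": "manova", "group": "all", "variable": name,
                         "statistic": res.statistic, "df": str(res.df),
                         "p": res.p, "wilks_lambda": res.wilks_lambda,
                         "partial_eta_sq": res.partial_eta_sq,
                         "comparison": None})
        except ValueError as err:
            log.warning("MANOVA skipped for %s: %s", name, err)
    for outcome, od in outcomes.groupby("outcome"):
        try:
            res = tukey_hsd(od["value"].to_numpy(),
                            od["group"].to_numpy())
        except ValueError as err:
            log.warning("Tukey skipped for %s: %s", outcome, err)
            continue
        for (a, b), p in res.pairwise_p.items():
            rows.append({"test": "tukey_hsd", "group": "all",
                         "variable": outcome, "statistic": None,
                         "df": str(res.df), "p": p, "wilks_lambda": None,
                         "partial_eta_sq": None, "comparison": f"{a} vs {b}"})
    stats_df = pd.DataFrame(rows)

    corr_full = pd.DataFrame(columns=["band", "metric", "electrode",
                                      "outcome", "n", "r", "p", "p_bh"])
    corr_sig = corr_full.copy()
    if metrics is not None and len(metrics):
        m = metrics[metrics["condition"] == "L"] \
            if "condition" in metrics.columns else metrics
        fulls, sigs = [], []
        for g in GROUPS:
            mg = m[m["group"] == g] if "group" in m.columns else m
            og = outcomes[outcomes["group"] == g]
            if not len(mg):
                continue
            f, s = correlate_metrics(mg, og, selection=DEFAULT_CORR_SELECTION)
            f.insert(0, "group", g)
            s.insert(0, "group", g)
            fulls.append(f)
            sigs.append(s)
        if fulls:
            corr_full = pd.concat(fulls, ignore_index=True)
            corr_sig = pd.concat(sigs, ignore_index=True)
    return stats_df, corr_full, corr_sig
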