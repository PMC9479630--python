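"""End-to-end orchestration: cohort -> scans -> staircases -> suppression -> stats."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import mrs, stats
from .cohort import (CohortSpec, GroundTruth, generate_cohort, records_to_frame,
                     simulate_sessions, synthesize_scan, EYES, CONFIGS,
                     ORIENTATIONS)
from .staircase import StaircaseConfig, outcomes_from_trials, cell_thresholds
from .suppression import analyze_suppression

REGIONS = ("visual", "sensorimotor")

MRS_COLUMNS = ["subject_id", "region", "gaba_cr", "n_blocks_used",
               "exclusion_fraction"]


def quantify_cohort_mrs(records, truth: GroundTruth, spec: CohortSpec,
                        n_scans: int = 4, regions=REGIONS,
                        max_deviant: int = 300) -> pd.DataFrame:
    """Synthesize and quantify MEGA-PRESS scans for every unflagged subject.

    Per subject and region, ``n_scans`` scans are synthesized from the true
    GABA:Cr at the cohort's spectral SNR and pushed through the full
    quantification chain; the per-subject value is the mean over scans.
    """
    rng = np.random.default_rng(spec.seed + 1)
    rows = []
    for rec in records:
        if rec.mrs_quality_flag:
            continue
        for region in regions:
            true_val = (truth.gaba_visual if region == "visual"
                        else truth.gaba_motor)[rec.subject_id]
            estimates = []
            frac = []
            for s in range(n_scans):
                scan = synthesize_scan(true_val, snr=spec.snr_spectra,
                                       seed=int(rng.integers(2 ** 31)),
                                       scan_id=f"{rec.subject_id}_{region}_{s}")
                try:
                    est = mrs.gaba_cr_ratio(scan, max_deviant=max_deviant)
                except (mrs.QcError, mrs.QuantificationError):
                    continue
                estimates.append(est)
                frac.append(est.qc.exclusion_fraction)
            if not estimates:
                continue
            rows.append({"subject_id": rec.subject_id, "region": region,
                         "gaba_cr": float(np.mean([e.gaba_cr for e in estimates])),
                         "n_blocks_used": int(np.sum([e.n_blocks_used for e in estimates])),
                         "exclusion_fraction": float(np.mean(frac))})
    return pd.DataFrame(rows, columns=MRS_COLUMNS)


def run_behavior(records, truth: GroundTruth, spec: CohortSpec,
                 subjects=None, config: StaircaseConfig | None = None) -> dict:
    """Simulate sessions, replay the staircases, aggregate cell thresholds."""
    trials = simulate_sessions(records, truth, spec, config=config,
                               subjects=subjects)
    outcomes = outcomes_from_trials(trials, config or StaircaseConfig())
    cells = cell_thresholds(outcomes)
    return {"trials": trials, "outcomes": outcomes, "cells": cells}


def run_stats(analysis: dict, clinical: pd.DataFrame,
              mrs_table: pd.DataFrame | None = None,
              n_perm: int = 10_000, seed: int = 0) -> dict:
    """The inference battery on a suppression-pipeline analysis."""
    report = {}
    summary = analysis["summary"]
    ratios = analysis["suppression_ratios"].merge(
        clinical[["subject_id", "group"]], on="subject_id")
    osss = analysis["osss_ratios"].merge(
        clinical[["subject_id", "group"]], on="subject_id")

    tests = {}
    for (group, cfg, ori), sub in ratios.groupby(["group", "ocular_config",
                                                  "orientation"]):
        if len(sub) >= 2:
            t, df, p = stats.one_sample_t(sub["ratio"], 1.0)
            tests[f"ratio_vs_1[{group},{cfg},{ori}]"] = {
                "mean": float(sub["ratio"].mean()), "t": t, "df": df, "p": p,
                "n": len(sub)}
    report["suppression_ratio_tests"] = tests

    osss_tests = {}
    for (group, eye, cfg), sub in osss.groupby(["group", "eye", "ocular_config"]):
        if len(sub) >= 2:
            t, df, p = stats.one_sample_t(sub["ratio"], 1.0)
            osss_tests[f"osss_vs_1[{group},{eye},{cfg}]"] = {
                "mean": float(sub["ratio"].mean()), "t": t, "df": df, "p": p,
                "n": len(sub)}
    report["osss_tests"] = osss_tests

    if mrs_table is not None and not mrs_table.empty:
        gaba_by_group = {}
        vis = mrs_table[mrs_table["region"] == "visual"].merge(
            clinical[["subject_id", "group"]], on="subject_id")
        for group, sub in vis.groupby("group"):
            gaba_by_group[group] = sub["gaba_cr"].to_numpy()
        if set(gaba_by_group) == {"PWA", "NSP"}:
            t, df, p = stats.two_sample_t(gaba_by_group["PWA"], gaba_by_group["NSP"])
            report["gaba_group_comparison"] = {
                "t": t, "df": df, "p": p,
                "d": stats.cohens_d(gaba_by_group["PWA"], gaba_by_group["NSP"]).d}

        pwa = clinical[clinical["group"] == "PWA"].copy()
        pwa["depth"] = pwa["acuity_nde_logmar"] - pwa["acuity_de_logmar"]
        depth_rho = {}
        for region in mrs_table["region"].unique():
            sub = mrs_table[mrs_table["region"] == region].merge(
                pwa[["subject_id", "depth"]], on="subject_id").dropna()
            if len(sub) >= 4:
                res = stats.perm_test_rho(sub["gaba_cr"], sub["depth"],
                                          n_perm=n_perm, seed=seed)
                depth_rho[region] = {"rho": res.rho, "n": res.n,
                                     "p_perm": res.p_perm}
        report["gaba_depth_correlation"] = depth_rho
        if {"visual", "sensorimotor"} <= set(depth_rho):
            v, m = depth_rho["visual"], depth_rho["sensorimotor"]
            fz = stats.fisher_z_compare(v["rho"], v["n"], m["rho"], m["n"])
            report["voxel_specificity_fisher"] = {
                "z": fz.z, "p": fz.p_two_tailed}

    eye_tests = {}
    if "gaba_cr_visual" in summary.columns:
        pwa_sum = summary[summary["group"] == "PWA"]
        for (cfg, ori), sub in pwa_sum.groupby(["ocular_config", "orientation"]):
            wide = sub.pivot_table(index="subject_id", columns="eye",
                                   values="t_rel")
            gaba = sub.drop_duplicates("subject_id").set_index("subject_id")[
                "gaba_cr_visual"]
            wide = wide.join(gaba).dropna()
            if len(wide) >= 4 and {"DE", "NDE"} <= set(wide.columns):
                delta, p = stats.perm_test_delta_rho_eyes(
                    wide["gaba_cr_visual"], wide["DE"], wide["NDE"],
                    n_perm=n_perm, seed=seed)
                eye_tests[f"delta_rho[{cfg},{ori}]"] = {"delta_rho": delta,
                                                        "p": p, "n": len(wide)}
    report["eye_difference_tests"] = eye_tests

    long = summary.dropna(subset=["t_rel"])
    if (long.groupby(["orientation", "ocular_config", "eye", "group"])
            .ngroups >= 8):
        aov = stats.omnibus_anova(long)
        report["omnibus_anova"] = aov.table.to_dict(orient="records")
    return report


def run_cohort_pipeline(spec: CohortSpec, n_scans: int = 4,
                        psychophysics_subjects=None,
                        n_perm: int = 10_000, cstar="auto") -> dict:
    """The whole study on one synthetic cohort, ground truth attached."""
    records, truth = generate_cohort(spec)
    clinical = records_to_frame(records)
    mrs_table = quantify_cohort_mrs(records, truth, spec, n_scans=n_scans)
    behavior = run_behavior(records, truth, spec,
                            subjects=psychophysics_subjects)
    analysis = analyze_suppression(behavior["cells"], clinical,
                                   mrs_table=mrs_table, cstar=cstar)
    report = run_stats(analysis, clinical, mrs_table,
                       n_perm=n_perm, seed=spec.seed)
    return {"records": records, "truth": truth, "clinical": clinical,
            "mrs": mrs_table, **behavior, "analysis": analysis,
            "stats": report}
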