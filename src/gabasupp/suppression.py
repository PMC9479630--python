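"""From per-cell thresholds to normalized suppression measures.

Thresholds measured with a surround are expressed relative to the baseline
(no-surround) contrast discrimination threshold T0 of the eye that viewed the
annulus: relative threshold T-hat = T / T0 and relative surround contrast
C-hat = C_surround / T0, with the same T0.  This removes interocular and
inter-subject differences in intrinsic contrast discrimination, so the
NDE:DE suppression ratio R = T-hat_NDE / T-hat_DE and the orientation
selectivity ratio Q = T-hat_iso / T-hat_cross isolate the surround's effect.

A single reference relative surround contrast C* is chosen data-driven across
the pooled cohort: it must reliably evoke suppression (mean T-hat > 1 at the
nearest points) while keeping the C-hat values actually used balanced between
the two eyes; each subject-condition then contributes the point nearest C*
in log C-hat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import EYES, CONFIGS, ORIENTATIONS, SubjectRecord

#: The eight surround conditions: 2 (annulus eye) x 2 (configuration) x
#: 2 (relative surround orientation).
CONDITION_KEYS = [(eye, cfg, ori) for eye in EYES for cfg in CONFIGS
                  for ori in ORIENTATIONS]

DEFAULT_CSTAR_GRID = np.geomspace(1.0, 20.0, 40)
ROBUSTNESS_RANGE = (2.0, 10.0)


class SelectionError(RuntimeError):
    """No candidate reference contrast reliably evokes suppression."""


@dataclass
class CstarSelection:
    cstar: float
    score_table: pd.DataFrame       # candidate, frac_suppressing, eye_bias

    def to_json_dict(self):
        return {"cstar": self.cstar,
                "score_table": self.score_table.to_dict(orient="records")}


def depth_of_amblyopia(record: SubjectRecord) -> float:
    """D = logMAR acuity of the amblyopic (NDE) minus fellow (DE) eye."""
    return record.acuity_nde - record.acuity_de


def assign_eye_dominance(record: SubjectRecord,
                         baseline_thresholds: dict | None = None) -> dict:
    """Map physical eyes (OS/OD) to DE/NDE labels.

    PWA: the amblyopic eye is the NDE (clinical designation).  NSP: the NDE is
    the eye with the higher baseline contrast discrimination threshold; an
    exact tie breaks deterministically to the right eye (OD) with a warning.
    """
    if record.group == "PWA":
        if record.amb_eye not in ("OS", "OD"):
            raise ValueError(f"{record.subject_id}: PWA record lacks amb_eye")
        nde = record.amb_eye
    else:
        if not baseline_thresholds or not {"OS", "OD"} <= set(baseline_thresholds):
            raise ValueError(
                f"{record.subject_id}: NSP dominance needs both baseline thresholds")
        t_os, t_od = baseline_thresholds["OS"], baseline_thresholds["OD"]
        if t_os == t_od:
            warnings.warn(f"{record.subject_id}: baseline tie; OD labeled NDE")
            nde = "OD"
        else:
            nde = "OS" if t_os > t_od else "OD"
    de = "OD" if nde == "OS" else "OS"
    return {de: "DE", nde: "NDE"}


def normalize_points(cells: pd.DataFrame, baselines: dict) -> pd.DataFrame:
    """Attach relative threshold and relative surround contrast columns.

    ``cells`` holds per-cell thresholds (columns subject_id, eye,
    ocular_config, orientation, surround_contrast, threshold); ``baselines``
    maps (subject_id, eye) to the no-surround threshold T0 of the
    annulus-viewing eye.  Subject-eyes without a baseline are dropped with a
    warning.  Baseline rows normalize to exactly 1.
    """
    rows = []
    dropped = set()
    for _, row in cells.iterrows():
        key = (row["subject_id"], row["eye"])
        t0 = baselines.get(key)
        if t0 is None or not np.isfinite(t0) or t0 <= 0:
            dropped.add(key)
            continue
        if row.get("threshold") is None or not np.isfinite(row["threshold"]):
            continue
        out = dict(row)
        out["t_rel"] = row["threshold"] / t0
        out["c_rel"] = (row["surround_contrast"] / t0
                        if np.isfinite(row.get("surround_contrast", np.nan))
                        else np.nan)
        rows.append(out)
    if dropped:
        warnings.warn(f"missing baseline, excluded subject-eyes: {sorted(dropped)}")
    return pd.DataFrame(rows)


def _nearest_points(points: pd.DataFrame, cstar: float) -> pd.DataFrame:
    """Per (subject, eye, config, orientation): the point nearest C* in log C-hat.

    Ties in log distance break to the lower C-hat.
    """
    surround = points[points["ocular_config"].isin(CONFIGS)].copy()
    surround = surround[np.isfinite(surround["c_rel"]) & (surround["c_rel"] > 0)]
    if surround.empty:
        return surround
    surround["logdist"] = np.abs(np.log(surround["c_rel"]) - np.log(cstar))
    surround = surround.sort_values(["logdist", "c_rel"], kind="stable")
    keys = ["subject_id", "eye", "ocular_config", "orientation"]
    return surround.groupby(keys, as_index=False, sort=False).first()


def select_reference_contrast(points: pd.DataFrame,
                              grid=DEFAULT_CSTAR_GRID) -> CstarSelection:
    """Data-driven choice of the reference relative surround contrast C*.

    Over the candidate grid, the primary score is the fraction of conditions
    (eye x configuration x orientation) whose nearest-point mean relative
    threshold exceeds 1 (reliable suppression); among candidates tied on that
    score, the one minimizing the between-eye bias
    |mean log C-hat used (DE) - mean log C-hat used (NDE)| wins.  The full
    score table is returned for audit.
    """
    grid = np.asarray(list(grid), dtype=float)
    if grid.size == 0:
        raise SelectionError("empty candidate grid")
    rows = []
    for cstar in grid:
        sel = _nearest_points(points, cstar)
        if sel.empty:
            rows.append({"cstar": cstar, "frac_suppressing": 0.0,
                         "eye_bias": np.inf, "center_dist": np.inf,
                         "mean_t_rel": np.nan})
            continue
        cond_means = sel.groupby(["eye", "ocular_config", "orientation"])["t_rel"].mean()
        frac = float((cond_means > 1.0).mean())
        by_eye = sel.groupby("eye")["c_rel"].apply(lambda c: np.log(c).mean())
        bias = (abs(by_eye.get("DE", np.nan) - by_eye.get("NDE", np.nan))
                if {"DE", "NDE"} <= set(by_eye.index) else 0.0)
        rows.append({"cstar": float(cstar), "frac_suppressing": frac,
                     "eye_bias": float(bias),
                     "center_dist": float(abs(np.log(cstar)
                                              - np.log(sel["c_rel"]).mean())),
                     "mean_t_rel": float(sel["t_rel"].mean())})
    table = pd.DataFrame(rows)
    viable = table[table["frac_suppressing"] > 0]
    if viable.empty or (viable["mean_t_rel"] <= 1.0).all():
        raise SelectionError(
            "no candidate reference contrast evokes suppression (all mean "
            "relative thresholds <= 1)")
    best_frac = table["frac_suppressing"].max()
    tied = table[table["frac_suppressing"] == best_frac]
    # ties on the suppression score break by between-eye balance, then by
    # closeness to the C-hat values the candidate actually selects
    best = tied.sort_values(["eye_bias", "center_dist", "cstar"],
                            kind="stable").iloc[0]
    return CstarSelection(cstar=float(best["cstar"]), score_table=table)


def extract_condition_value(points: pd.DataFrame, cstar: float) -> pd.DataFrame:
    """Selected relative threshold per subject x eye x configuration x
    orientation: the point whose C-hat is nearest C* in the log domain."""
    sel = _nearest_points(points, cstar)
    keys = ["subject_id", "eye", "ocular_config", "orientation"]
    return sel[keys + ["t_rel", "c_rel", "threshold", "surround_contrast"]]


def suppression_ratio(selected: pd.DataFrame) -> pd.DataFrame:
    """NDE:DE suppression ratio R per subject x configuration x orientation."""
    wide = selected.pivot_table(index=["subject_id", "ocular_config", "orientation"],
                                columns="eye", values="t_rel")
    wide = wide.dropna(subset=[e for e in EYES if e in wide.columns])
    if not {"DE", "NDE"} <= set(wide.columns):
        return pd.DataFrame(columns=["subject_id", "ocular_config", "orientation", "ratio"])
    out = wide.reset_index()
    out["ratio"] = out["NDE"] / out["DE"]
    return out[["subject_id", "ocular_config", "orientation", "ratio"]]


def osss_ratio(selected: pd.DataFrame) -> pd.DataFrame:
    """Orientation-selective surround suppression: Q = T-hat iso / T-hat cross
    per subject x eye x configuration."""
    wide = selected.pivot_table(index=["subject_id", "eye", "ocular_config"],
                                columns="orientation", values="t_rel")
    if not {"iso", "cross"} <= set(wide.columns):
        return pd.DataFrame(columns=["subject_id", "eye", "ocular_config", "ratio"])
    wide = wide.dropna(subset=["iso", "cross"])
    out = wide.reset_index()
    out["ratio"] = out["iso"] / out["cross"]
    return out[["subject_id", "eye", "ocular_config", "ratio"]]


def analyze_suppression(cells: pd.DataFrame, clinical: pd.DataFrame,
                        mrs_table: pd.DataFrame | None = None,
                        cstar="auto") -> dict:
    """Full behavioral pipeline for a cohort.

    ``cells``: per-cell thresholds (from the staircase module), including
    baseline rows (ocular_config == "baseline").  ``clinical``: the clinical
    table.  ``mrs_table``: optional per-subject GABA:Cr rows
    (subject_id, region, gaba_cr).  Returns a dict with the normalized
    points, the C* selection audit, selected values, R and Q ratio tables,
    and a per-subject summary (depth of amblyopia, GABA:Cr merged in).
    """
    baselines = {}
    base_rows = cells[cells["ocular_config"] == "baseline"]
    for _, row in base_rows.iterrows():
        if row["threshold"] is not None and np.isfinite(row["threshold"]):
            baselines[(row["subject_id"], row["eye"])] = float(row["threshold"])
    points = normalize_points(cells, baselines)
    if cstar == "auto":
        selection = select_reference_contrast(points)
    else:
        selection = CstarSelection(cstar=float(cstar), score_table=pd.DataFrame())
    selected = extract_condition_value(points, selection.cstar)
    ratios = suppression_ratio(selected)
    osss = osss_ratio(selected)

    summary = selected.merge(
        clinical[["subject_id", "group", "acuity_de_logmar", "acuity_nde_logmar"]],
        on="subject_id", how="left")
    summary["depth"] = np.where(
        summary["group"] == "PWA",
        summary["acuity_nde_logmar"] - summary["acuity_de_logmar"], np.nan)
    if mrs_table is not None and not mrs_table.empty:
        for region in mrs_table["region"].unique():
            sub = mrs_table[mrs_table["region"] == region][["subject_id", "gaba_cr"]]
            summary = summary.merge(
                sub.rename(columns={"gaba_cr": f"gaba_cr_{region}"}),
                on="subject_id", how="left")
    return {"points": points, "selection": selection, "selected": selected,
            "suppression_ratios": ratios, "osss_ratios": osss,
            "summary": summary, "baselines": baselines}
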