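"""Cohort-level analysis: filtering, statistics, pipeline driver, reports.

Consumes the tabular cohort (per-airway areas and peribronchial expansions
at conditions B/P/T, per-segment expansions and volumes, per-subject
spirometry and whole-lung expansions) and derives, per subject:

* vertical expansion-gradient fits and the conversion factor ``k_bar``;
* per-airway mechanics (RD, iso-volume areas, critical expansions);
* closure and gas-trapping predictions;

then summarises across the cohort: group means, paired/unpaired t-tests,
and the association set linking whole-lung behaviour to individual-airway
mechanics (lung-volume rise vs mean luminal narrowing, vs the least stable
airway's iso-volume lumen, vs the predicted closure volume; FVC drop vs
predicted trapped gas, with per-group regression lines).

Statistical conventions: two-sided tests, significance at P < 0.05,
Pearson correlation for all reported R values, no multiple-testing
correction (flagged in the report footer).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .airway_mechanics import compute_airway_mechanics, subject_min_lumen
from .closure_prediction import (
    critical_volume_change,
    expansion_at_rv,
    residual_volume_post,
    trapped_volume,
)
from .expansion_gradients import conversion_factor, fit_de_mean_vs_elung, fit_vertical_gradient
from .synthetic_cohort import Cohort

__all__ = [
    "CohortResult",
    "filter_airways",
    "fractional_lumen_change",
    "paired_t",
    "unpaired_t",
    "pearson_r",
    "analyze_cohort",
    "summarize_cohort",
    "run_pipeline",
]

CONDITIONS = ("B", "P", "T")
SIGNIFICANCE = 0.05
SCHEMA_VERSION = "1"


@dataclass
class CohortResult:
    """Per-airway, per-subject and per-fit outputs of the analysis."""

    airway_mechanics: pd.DataFrame
    gradients: pd.DataFrame
    subjects: pd.DataFrame
    exclusions: pd.DataFrame


def filter_airways(
    airways: pd.DataFrame,
    min_lumen_mm2: float = 3.1,
    require_all_conditions: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic airway filter with a per-exclusion log.

    Drops airways whose lumen falls below ``min_lumen_mm2`` in any
    condition (the validated measurement bound) and, by default, airways
    not characterised in all three scans.  An optional ``exclude_reason``
    column (analyst's visual call, e.g. oblique centreline) is honoured.
    """
    if airways.empty:
        raise ValueError("empty airway table")
    logs = []
    keep_keys = []
    for (sid, aid), grp in airways.groupby(["subject_id", "airway_id"], sort=False):
        conds = set(grp["condition"])
        reason = None
        if "exclude_reason" in grp.columns:
            manual = grp["exclude_reason"].dropna()
            manual = manual[manual.astype(str).str.len() > 0]
            if len(manual):
                reason = f"manual:{manual.iloc[0]}"
        if reason is None and require_all_conditions and not set(CONDITIONS) <= conds:
            missing = sorted(set(CONDITIONS) - conds)
            reason = f"missing_condition:{','.join(missing)}"
        if reason is None and (grp["a_i_mm2"] < min_lumen_mm2).any():
            reason = f"lumen_below_{min_lumen_mm2}mm2"
        if reason is None:
            keep_keys.append((sid, aid))
        else:
            logs.append(dict(subject_id=sid, airway_id=aid, reason=reason))
    if not keep_keys:
        raise ValueError("all airways excluded by the filter")
    idx = pd.MultiIndex.from_tuples(keep_keys, names=["subject_id", "airway_id"])
    filtered = airways.set_index(["subject_id", "airway_id"]).loc[idx].reset_index()
    return filtered, pd.DataFrame(logs, columns=["subject_id", "airway_id", "reason"])


def fractional_lumen_change(a_i_b, a_i_p):
    """Degree of luminal narrowing (A_i,B - A_i,P)/A_i,B; negative = dilation."""
    a_i_b = np.asarray(a_i_b, dtype=float)
    if np.any(a_i_b <= 0):
        raise ValueError("baseline lumen must be positive")
    return (a_i_b - np.asarray(a_i_p, dtype=float)) / a_i_b


def paired_t(x, y) -> tuple[float, float]:
    """Two-sided paired t-test; returns (t, p)."""
    res = stats.ttest_rel(np.asarray(x, float), np.asarray(y, float))
    return float(res.statistic), float(res.pvalue)


def unpaired_t(x, y) -> tuple[float, float]:
    """Two-sided unpaired t-test (equal variances); returns (t, p)."""
    res = stats.ttest_ind(np.asarray(x, float), np.asarray(y, float))
    return float(res.statistic), float(res.pvalue)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation; returns (r, p).  Errors on zero variance."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def _analyze_subject(sid, group, aw, seg, subj_row, mode):
    """Derive gradients, mechanics and predictions for one subject."""
    piv = aw.pivot(index="airway_id", columns="condition",
                   values=["a_i_mm2", "a_o_mm2", "e_pb", "cp_z_mm"])
    segp = seg.pivot(index="segment_id", columns="condition",
                     values=["e_sl", "center_z_mm", "volume_ml"])
    ids = piv.index.to_numpy()
    h = float(subj_row["lung_height_mm"])
    dh = (segp.loc[ids, ("center_z_mm", "B")].to_numpy()
          - piv[("cp_z_mm", "B")].to_numpy()) / h

    gradients = []
    de_mean = {}
    for c in CONDITIONS:
        de = segp.loc[ids, ("e_sl", c)].to_numpy() - piv[("e_pb", c)].to_numpy()
        fit = fit_vertical_gradient(dh, de)
        de_mean[c] = fit.intercept
        gradients.append(dict(subject_id=sid, condition=c, slope=fit.slope,
                              intercept=fit.intercept, de_mean=fit.de_mean,
                              r2=fit.r_squared, n=fit.n))
    cf = conversion_factor(de_mean["P"], float(subj_row["e_lung_p"]),
                           de_mean["T"], float(subj_row["e_lung_t"]))
    for g in gradients:
        g["k_bar"] = cf.k_bar

    mech_rows = []
    for aid in ids:
        a_o_p, a_o_t = piv.loc[aid, ("a_o_mm2", "P")], piv.loc[aid, ("a_o_mm2", "T")]
        a_w_p = a_o_p - piv.loc[aid, ("a_i_mm2", "P")]
        a_w_t = a_o_t - piv.loc[aid, ("a_i_mm2", "T")]
        e_pb = {c: piv.loc[aid, ("e_pb", c)] for c in CONDITIONS}
        m = compute_airway_mechanics(
            a_o_p=a_o_p, a_o_t=a_o_t, a_w_p=a_w_p, a_w_t=a_w_t,
            e_pb_b=e_pb["B"], e_pb_p=e_pb["P"], e_pb_t=e_pb["T"],
        )
        mech_rows.append(dict(
            subject_id=sid, group=group, airway_id=aid,
            rd=m.rd, a_star_o=m.a_star_o, a_star_i=m.a_star_i,
            e_crit_mlv=np.nan if m.e_crit_mlv is None else m.e_crit_mlv,
            e_crit_fvc=np.nan if m.e_crit_fvc is None else m.e_crit_fvc,
            flag_mlv=m.flag_mlv, flag_fvc=m.flag_fvc,
            validity_flag=m.validity_flag,
            closed_at_baseline=m.closure_flag_baseline,
            e_pb_b_over_t=e_pb["B"] / e_pb["T"],
            frac_lumen_change=float(fractional_lumen_change(
                piv.loc[aid, ("a_i_mm2", "B")], piv.loc[aid, ("a_i_mm2", "P")])),
        ))
    mech = pd.DataFrame(mech_rows)

    # closure predictions use airways with positive RD only
    pos = mech[mech["rd"] > 0]
    tlc = float(subj_row["tlc_l"])
    rv_p = residual_volume_post(tlc, float(subj_row["fvc_p_l"]))
    e_pb_rv = expansion_at_rv(rv_p, tlc, cf.k_bar)
    if len(pos) >= 2:
        min_asi, mean_m2sd = subject_min_lumen(pos["a_star_i"])
        ls = pos.loc[pos["a_star_i"].idxmin()]
        e_crit_ls = 0.0 if np.isnan(ls["e_crit_mlv"]) else float(ls["e_crit_mlv"])
        delta_vc = critical_volume_change(e_crit_ls, float(ls["e_pb_b_over_t"]), cf.k_bar)
        ls_flag = ls["flag_mlv"]
        ls_id = int(ls["airway_id"])
    else:
        min_asi = mean_m2sd = delta_vc = np.nan
        ls_flag, ls_id = "indeterminate", -1

    frac_t = (segp.loc[ids, ("volume_ml", "T")].to_numpy() / 1000.0) / tlc
    ecf = mech["e_crit_fvc"].where(mech["rd"] > 0, np.nan).to_numpy()
    fvc_b = float(subj_row["fvc_b_l"])
    v_tr_w, closing = trapped_volume(ecf, frac_t, k_bar=cf.k_bar, rv_p=rv_p,
                                     tlc=tlc, fvc_b=fvc_b, mode="weighted")
    v_tr_l, _ = trapped_volume(ecf, frac_t, k_bar=cf.k_bar, rv_p=rv_p,
                               tlc=tlc, fvc_b=fvc_b, mode="literal")

    subject = dict(
        subject_id=sid, group=group,
        k_bar=cf.k_bar,
        de_mean_b=de_mean["B"], de_mean_p=de_mean["P"], de_mean_t=de_mean["T"],
        rd_mean=float(mech["rd"].mean()),
        min_a_star_i=min_asi, min_a_star_i_mean_2sd=mean_m2sd,
        least_stable_airway=ls_id, least_stable_flag=ls_flag,
        delta_vc_over_tlc=delta_vc,
        dvl_over_tlc=(float(subj_row["mlv_p_l"]) - float(subj_row["mlv_b_l"])) / tlc,
        e_pb_rv=e_pb_rv, rv_p_l=rv_p,
        n_closing=int(closing.sum()),
        v_tr_weighted=v_tr_w, v_tr_literal=v_tr_l,
        v_tr_over_fvc_b=v_tr_w if mode == "weighted" else v_tr_l,
        dfvc_over_fvcb=(fvc_b - float(subj_row["fvc_p_l"])) / fvc_b,
        mean_frac_lumen_change=float(mech["frac_lumen_change"].mean()),
        n_airways=len(mech),
        n_rd_nonpositive=int((mech["rd"] <= 0).sum()),
        mode=mode,
    )
    return mech, gradients, subject


def analyze_cohort(
    cohort: Cohort,
    *,
    mode: str = "weighted",
    min_lumen_mm2: float = 3.1,
    require_all_conditions: bool = True,
) -> CohortResult:
    """Run gradients -> mechanics -> closure on a tabular cohort."""
    airways, exclusions = filter_airways(
        cohort.airways, min_lumen_mm2=min_lumen_mm2,
        require_all_conditions=require_all_conditions,
    )
    mech_frames, gradient_rows, subject_rows = [], [], []
    subjects = cohort.subjects.set_index("subject_id")
    for sid, aw in airways.groupby("subject_id", sort=False):
        seg = cohort.segments[cohort.segments["subject_id"] == sid]
        subj_row = subjects.loc[sid]
        group = str(aw["group"].iloc[0])
        mech, grads, subj = _analyze_subject(sid, group, aw, seg, subj_row, mode)
        mech_frames.append(mech)
        gradient_rows += grads
        subject_rows.append(subj)
    return CohortResult(
        airway_mechanics=pd.concat(mech_frames, ignore_index=True),
        gradients=pd.DataFrame(gradient_rows),
        subjects=pd.DataFrame(subject_rows),
        exclusions=exclusions,
    )


def _mean_sd(x) -> str:
    x = np.asarray(x, float)
    return f"{x.mean():.2f}+/-{x.std(ddof=1):.2f}"


def summarize_cohort(result: CohortResult, cohort: Cohort) -> dict[str, pd.DataFrame]:
    """Cohort summary tables: expansion-gradient block, associations, tests."""
    subj = result.subjects.merge(cohort.subjects, on=["subject_id", "group"])
    grads = result.gradients.merge(
        subj[["subject_id", "group", "tlc_l", "mlv_b_l", "mlv_p_l",
              "e_lung_b", "e_lung_p", "e_lung_t"]],
        on="subject_id",
    )
    rows = []
    for (group, c), g in grads.groupby(["group", "condition"]):
        vl = {"B": g["mlv_b_l"] / g["tlc_l"], "P": g["mlv_p_l"] / g["tlc_l"],
              "T": pd.Series(np.ones(len(g)))}[c] * 100.0
        e_lung = g[{"B": "e_lung_b", "P": "e_lung_p", "T": "e_lung_t"}[c]]
        rows.append(dict(
            group=group, condition=c, n=len(g),
            vl_pct_tlc=_mean_sd(vl),
            slope=_mean_sd(g["slope"]), intercept=_mean_sd(g["intercept"]),
            r2=_mean_sd(g["r2"]), de_mean=_mean_sd(g["de_mean"]),
            e_lung=_mean_sd(e_lung), k_bar=_mean_sd(g["k_bar"]),
        ))
    gradient_table = pd.DataFrame(rows)

    # dE_mean vs E_Lung regression per group over subject-condition points
    fit_rows = []
    for group, g in grads.groupby("group"):
        pts_x, pts_y = [], []
        for c in CONDITIONS:
            gc = g[g["condition"] == c]
            pts_x += list(gc[{"B": "e_lung_b", "P": "e_lung_p", "T": "e_lung_t"}[c]])
            pts_y += list(gc["de_mean"])
        fit = fit_de_mean_vs_elung(pts_x, pts_y)
        fit_rows.append(dict(group=group, slope=fit.slope, intercept=fit.intercept,
                             r2=fit.r_squared, n=fit.n))
    de_vs_elung = pd.DataFrame(fit_rows)

    # association set (pooled Pearson R; per-group lines for the FVC plot)
    assoc_rows = []
    pairs = [
        ("dvl_vs_narrowing", "mean_frac_lumen_change", "dvl_over_tlc"),
        ("dvl_vs_min_a_star_i", "min_a_star_i", "dvl_over_tlc"),
        ("dvl_vs_delta_vc", "delta_vc_over_tlc", "dvl_over_tlc"),
        # the FVC association mirrors the printed (unweighted) trapping sum
        ("dfvc_vs_v_tr", "v_tr_literal", "dfvc_over_fvcb"),
    ]
    s = subj.dropna(subset=["min_a_star_i", "delta_vc_over_tlc"])
    for name, xcol, ycol in pairs:
        r, p = pearson_r(s[xcol], s[ycol])
        assoc_rows.append(dict(association=name, r=r, p=p, n=len(s),
                               significant=p < SIGNIFICANCE))
    associations = pd.DataFrame(assoc_rows)

    fvc_rows = []
    for group, g in s.groupby("group"):
        A = np.c_[np.ones(len(g)), g["v_tr_literal"].to_numpy()]
        coef, *_ = np.linalg.lstsq(A, g["dfvc_over_fvcb"].to_numpy(), rcond=None)
        fvc_rows.append(dict(group=group, intercept=float(coef[0]),
                             slope=float(coef[1]), n=len(g)))
    fvc_lines = pd.DataFrame(fvc_rows)

    # condition and group comparisons
    test_rows = []
    for group, g in subj.groupby("group"):
        t, p = paired_t(g["mlv_b_l"] / g["tlc_l"], g["mlv_p_l"] / g["tlc_l"])
        test_rows.append(dict(test=f"vl_fraction_B_vs_P[{group}]", t=t, p=p,
                              significant=p < SIGNIFICANCE))
    gas = subj[subj["group"] == "AS"]
    gna = subj[subj["group"] == "NA"]
    if len(gas) > 1 and len(gna) > 1:
        for col in ("dvl_over_tlc", "rd_mean", "dfvc_over_fvcb"):
            t, p = unpaired_t(gas[col], gna[col])
            test_rows.append(dict(test=f"AS_vs_NA[{col}]", t=t, p=p,
                                  significant=p < SIGNIFICANCE))
    tests = pd.DataFrame(test_rows)
    tests.attrs["footnote"] = (
        "Two-sided tests, significance at P < 0.05; no multiple-testing correction."
    )
    return dict(
        gradient_table=gradient_table,
        de_mean_vs_e_lung=de_vs_elung,
        associations=associations,
        fvc_regression=fvc_lines,
        tests=tests,
    )


def run_pipeline(
    *,
    config=None,
    input_dir=None,
    out_dir=None,
    mode: str = "weighted",
    min_lumen_mm2: float = 3.1,
):
    """End-to-end driver: generate or load a cohort, analyse, summarise.

    Exactly one of ``config`` (synthetic generation) or ``input_dir``
    (CSV cohort) must be given.  Idempotent: rerunning with the same
    inputs produces identical outputs.
    """
    from .synthetic_cohort import generate_tabular_cohort, read_cohort, write_cohort

    if (config is None) == (input_dir is None):
        raise ValueError("provide exactly one of config or input_dir")
    truth = None
    if config is not None:
        cohort, truth = generate_tabular_cohort(config)
    else:
        cohort = read_cohort(input_dir)
    result = analyze_cohort(cohort, mode=mode, min_lumen_mm2=min_lumen_mm2)
    summary = summarize_cohort(result, cohort)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if config is not None:
            write_cohort(cohort, truth, out / "cohort")
        result.airway_mechanics.to_csv(out / "airway_mechanics.csv", index=False)
        result.gradients.to_csv(out / "gradients.csv", index=False)
        result.subjects.to_csv(out / "subject_predictions.csv", index=False)
        result.exclusions.to_csv(out / "exclusions.csv", index=False)
        for name, df in summary.items():
            df.to_csv(out / f"summary_{name}.csv", index=False)
    return cohort, truth, result, summary
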