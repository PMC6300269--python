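"""Synthetic two-group cohorts with known ground truth.

Emulates the study conditions of a supine CT broncho-provocation protocol:
two groups (7 asthmatic "AS", 9 control "NA" subjects), ~19 segmental
airways each, imaged at three conditions — baseline mean lung volume (B),
post-challenge mean lung volume (P) and total lung capacity (T).

Forward model
-------------
Per subject, whole-lung expansion ``E_Lung,c`` is drawn at B and T and
linearly interpolated in lung-volume fraction at P.  The height-adjusted
segment-minus-peribronchial expansion difference follows
``dE_mean,c = beta * E_Lung,c + alpha`` (per-subject slope/intercept), so
the peribronchial expansion level ``L_c = E_Lung,c - dE_mean,c`` is shared
by every airway of the subject and the conversion factor identity
``k_bar * E_Lung,P/E_Lung,T = E_pb,P/E_pb,T`` holds exactly.  Per airway,
``dE`` lies exactly on the vertical-gradient line
``dE = dE_mean,c + slope_c * dh`` and the segment expansion is
``E_SL = E_Lung,c + slope_c * dh``.

Airway areas at P and T lie on a line of slope RD (drawn per airway from a
clipped normal) through (1, 1) in the ``(e^(2/3), A_o/A_o,T)`` plane; the
baseline outer area sits off that line, on a relaxed-airway expansion
curve of comparable local slope (so between-subject expansion levels
cancel out of the B->P narrowing, leaving the volume rise as its driver).
Wall area is constant from B to P and 10% larger at T.  Airways are
accepted only if the lumen is measurable (>= 4.2 mm^2) in all three
conditions, mirroring the measurable set of a segmental-airway CT study.

Volume defense: when enabled, the post-challenge breathing volume is the
resting rise plus an active-control coupling to the predicted closure
volume of the subject's least stable airway, floored at 1.15x that closure
volume — the generative form of the observation that subjects keep their
breathing volume at least 15% above first-closure.  The post-challenge FVC
is set so its fractional drop follows a per-group linear response to the
predicted trapped-gas volume (solved to a fixed point, since trapped gas
itself depends on the post-challenge residual volume).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .airway_mechanics import TWO_THIRDS, critical_expansion_fvc, critical_expansion_mlv
from .closure_prediction import trapped_volume

__all__ = [
    "GeneratorConfig",
    "Cohort",
    "SyntheticTruth",
    "CohortGenerationError",
    "generate_tabular_cohort",
    "write_cohort",
    "read_cohort",
    "AIRWAY_LABELS",
]

# 19 segmental bronchi (LB7 commonly absent/shared in humans)
AIRWAY_LABELS = tuple(f"RB{i}" for i in range(1, 11)) + tuple(
    f"LB{i}" for i in (1, 2, 3, 4, 5, 6, 8, 9, 10)
)


class CohortGenerationError(RuntimeError):
    """Raised when a configuration admits no physically valid cohort."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the tabular cohort generator.

    Defaults are the conditions of the emulated study: group sizes 7/9,
    19 segmental airways, RD ~ N(0.75, 0.5) clipped to [-1, 3], wall
    fractions A_w,P/A_o,T in [0.3, 0.6], lung-volume fractions
    MLV_B/TLC ~ 0.54 +/- 0.08 and MLV_P/TLC ~ 0.67 +/- 0.11, vertical
    expansion gradient 3.0 dE per unit dh.
    """

    n_subjects_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"AS": 7, "NA": 9}
    )
    n_airways: int = 19
    rd_mean: float = 0.75
    rd_sd: float = 0.5
    rd_range: tuple[float, float] = (-1.0, 3.0)
    wall_fraction_range: tuple[float, float] = (0.3, 0.6)
    baseline_vl_fraction: tuple[float, float] = (0.54, 0.08)
    post_vl_fraction: tuple[float, float] = (0.67, 0.11)
    vertical_slope: float = 3.0
    vertical_slope_sd: float = 0.6
    hu_noise_sd: float = 0.0
    seed: int = 0
    volume_defense: bool = True
    # secondary study conditions
    wall_tlc_ratio: float = 1.1  # A_w,T / A_w,P
    lumen_floor_mm2: float = 4.2  # measurable-lumen floor, all conditions
    elung_b: tuple[float, float] = (3.88, 0.70)
    elung_t: tuple[float, float] = (8.66, 1.05)
    de_mean_slope: tuple[float, float] = (0.30, 0.05)  # beta vs E_Lung
    de_mean_intercept: tuple[float, float] = (-0.95, 0.15)  # alpha
    tlc_l: tuple[float, float] = (5.4, 0.9)
    fvc_b_over_tlc: tuple[float, float] = (0.70, 0.06)
    dh: tuple[float, float] = (0.02, 0.05)
    lung_height_mm: float = 200.0
    outer_area_range_mm2: tuple[float, float] = (15.0, 80.0)
    defense_base: tuple[float, float] = (0.12, 0.05)  # resting MLV rise
    defense_coupling: float = 0.6  # active-control gain on dV_C
    defense_margin: float = 0.005
    dv_floor: float = 0.02
    fig8_response: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"AS": (1.74, 0.15), "NA": (0.97, 0.07)}
    )
    fvc_response_noise_sd: float = 0.01
    # per-airway local expansion heterogeneity: each airway's normalised
    # peribronchial expansion is the subject's raised to a log-normal
    # exponent q (q<1: locally better expanded, q>1: locally under-expanded)
    expansion_heterogeneity_sd: float = 0.35
    airway_corr: float = 0.0  # shared smooth-muscle component of RD across a subject
    trapped_mode: str = "weighted"

    def __post_init__(self) -> None:
        for name in ("baseline_vl_fraction", "post_vl_fraction", "fvc_b_over_tlc"):
            mean, _sd = getattr(self, name)
            if not (0.0 < mean < 1.0):
                raise ValueError(f"{name} mean must be in (0, 1)")
        lo, hi = self.rd_range
        if not (lo <= self.rd_mean <= hi):
            raise ValueError("rd_range must contain rd_mean")
        wlo, whi = self.wall_fraction_range
        if not (0.0 < wlo <= whi < 1.0):
            raise ValueError("wall_fraction_range must lie in (0, 1)")
        if not (0.0 <= self.airway_corr <= 1.0):
            raise ValueError("airway_corr must be in [0, 1]")
        if self.n_airways < 3:
            raise ValueError("need at least 3 airways per subject")


@dataclass
class Cohort:
    """Tabular cohort: per-airway, per-segment and per-subject tables."""

    airways: pd.DataFrame
    segments: pd.DataFrame
    subjects: pd.DataFrame


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a cohort; self-consistent with it."""

    airways: pd.DataFrame
    subjects: pd.DataFrame
    config: GeneratorConfig


def _tnorm(rng, mean, sd, lo, hi):
    """Normal draw clipped to [lo, hi]."""
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def _draw_airway(rng, cfg: GeneratorConfig, e_b: float, e_p0: float, z_subj: float):
    """Rejection-sample one airway; None if the draw is not measurable.

    ``e_p0`` is the subject's normalised peribronchial expansion at the
    lowest post-challenge lung volume this subject can end up breathing at
    (the defense rule only ever raises it), so a lumen measurable at
    ``e_p0`` stays measurable in the emitted cohort.
    """
    floor = cfg.lumen_floor_mm2
    a_lo, a_hi = cfg.outer_area_range_mm2
    a_o_t = float(np.exp(rng.uniform(np.log(a_lo), np.log(a_hi))))
    w = float(rng.uniform(*cfg.wall_fraction_range))
    rho = cfg.airway_corr
    z = rho * z_subj + np.sqrt(1.0 - rho**2) * rng.standard_normal()
    rd = float(np.clip(cfg.rd_mean + cfg.rd_sd * z, *cfg.rd_range))
    dh = _tnorm(rng, cfg.dh[0], cfg.dh[1], -0.14, 0.18)
    q = float(np.exp(np.clip(rng.normal(0.0, cfg.expansion_heterogeneity_sd), -0.59, 0.59)))
    floor_frac = floor / a_o_t
    w_t = cfg.wall_tlc_ratio * w
    if 1.0 - w_t < floor_frac:  # lumen at TLC
        return None
    if rd > 0:
        a_p_floor = 1.0 - rd * (1.0 - (e_p0**q) ** TWO_THIRDS)
        if a_p_floor - w < floor_frac:  # lumen at the lowest admissible MLV_P
            return None
    b_lo = w + floor_frac + 0.02
    if b_lo >= 0.98:
        return None
    # relaxed baseline state: off the constricted P-T line, but on its own
    # expansion curve — a relaxed airway in a better-expanded baseline lung
    # is bigger, with a local slope comparable to the constricted one
    rd_relax = _tnorm(rng, 0.75, 0.25, 0.1, 1.5)
    e_b_a = e_b**q
    a_b = _tnorm(
        rng, 0.82 + rd_relax * (e_b_a**TWO_THIRDS - 0.68), 0.04, b_lo, 0.98
    )
    return dict(a_o_t=a_o_t, w=w, w_t=w_t, rd=rd, dh=dh, a_b=a_b,
                q=q, e_b=e_b_a)


def _least_stable(airways: list[dict]):
    """Index, iso-volume lumen and closure expansion of the least stable airway."""
    best = None
    for i, a in enumerate(airways):
        if a["rd"] <= 0:
            continue
        a_star_o = 1.0 - a["rd"] * (1.0 - a["e_b"] ** TWO_THIRDS)
        a_star_i = a_star_o - a["w"]
        if best is None or a_star_i < best[1]:
            best = (i, a_star_i)
    if best is None:
        raise CohortGenerationError("no airway with positive RD; closure undefined")
    i, a_star_i = best
    e_crit, flag = critical_expansion_mlv(airways[i]["e_b"], a_star_i, airways[i]["rd"])
    if e_crit is None:  # never closes before full deflation: most stable possible
        e_crit = 0.0
    return i, a_star_i, e_crit, flag


def _generate_subject(rng, cfg: GeneratorConfig, group: str, sid: str):
    # --- subject-level physiology -------------------------------------
    tlc = _tnorm(rng, *cfg.tlc_l, 3.5, 8.0)
    v_b = _tnorm(rng, *cfg.baseline_vl_fraction, 0.35, 0.72)
    e_lung_b = _tnorm(rng, *cfg.elung_b, 2.2, 6.0)
    e_lung_t = _tnorm(rng, *cfg.elung_t, e_lung_b + 2.0, 14.0)
    beta = _tnorm(rng, *cfg.de_mean_slope, 0.05, 0.60)
    alpha = _tnorm(rng, *cfg.de_mean_intercept, -1.5, -0.4)
    slopes = {c: float(rng.normal(cfg.vertical_slope, cfg.vertical_slope_sd)) for c in "BPT"}
    fvc_b = _tnorm(rng, *cfg.fvc_b_over_tlc, 0.50, 0.85) * tlc

    def e_lung_p_at(v_p):
        return e_lung_b + (e_lung_t - e_lung_b) * (v_p - v_b) / (1.0 - v_b)

    def level(e_lung):  # peribronchial expansion level L_c = E_Lung - dE_mean
        return (1.0 - beta) * e_lung - alpha

    l_b, l_t = level(e_lung_b), level(e_lung_t)
    if l_b <= 0 or l_t <= l_b:
        raise CohortGenerationError("drawn expansions give a non-physical peribronchial level")
    e_b = l_b / l_t

    def k_bar_at(v_p):
        e_lung_p = e_lung_p_at(v_p)
        return (level(e_lung_p) / e_lung_p) / (l_t / e_lung_t)

    # --- post-challenge lung-volume floor, then airways ----------------
    # The measurable-lumen check must hold at the volume the subject will
    # actually breathe at; the defense rule only ever raises the volume
    # above this floor, so checking at the floor is exact, not conservative.
    dv_sampled = max(cfg.dv_floor, float(rng.normal(*cfg.defense_base)))
    v_p_direct = _tnorm(rng, *cfg.post_vl_fraction, v_b + cfg.dv_floor, 0.97)
    if cfg.volume_defense:
        # guaranteed lower bound: the bounded coupling can subtract at most
        # 0.08 * coupling from the resting rise
        v_p0 = v_b + max(dv_sampled - 0.08 * cfg.defense_coupling, cfg.dv_floor)
    else:
        v_p0 = v_p_direct
    e_p0 = level(e_lung_p_at(v_p0)) / l_t

    z_subj = rng.standard_normal()
    airways: list[dict] = []
    for _ in range(cfg.n_airways):
        for _attempt in range(500):
            a = _draw_airway(rng, cfg, e_b, e_p0, z_subj)
            if a is not None:
                airways.append(a)
                break
        else:
            raise CohortGenerationError(
                "no measurable airway can be generated: wall fraction meets or "
                "exceeds the attainable outer-area ratio for every draw"
            )

    ls_idx, min_a_star_i_pos, e_crit_ls, ls_flag = _least_stable(airways)
    e_b_ls = airways[ls_idx]["e_b"]

    # --- post-challenge lung volume (volume defense) -------------------
    if cfg.volume_defense:
        v_p = v_p0
        for _ in range(200):
            d = (e_crit_ls - e_b_ls) * k_bar_at(v_p)
            # the irritation-driven resting rise is not fully cancelled in
            # very stable lungs: the coupling term is bounded below
            dv = max(dv_sampled + cfg.defense_coupling * max(d, -0.08),
                     1.15 * d + cfg.defense_margin,
                     cfg.dv_floor)
            v_p_new = v_b + dv
            if v_p_new > 0.97:
                raise CohortGenerationError(
                    f"subject {sid}: volume defense would require MLV_P/TLC > 0.97"
                )
            if abs(v_p_new - v_p) < 1e-13:
                v_p = v_p_new
                break
            v_p = v_p_new
    else:
        v_p = v_p_direct
    delta_vc = (e_crit_ls - e_b_ls) * k_bar_at(v_p)

    e_lung_p = e_lung_p_at(v_p)
    l_p = level(e_lung_p)
    e_p = l_p / l_t
    k_bar = k_bar_at(v_p)
    de_mean = {"B": beta * e_lung_b + alpha,
               "P": beta * e_lung_p + alpha,
               "T": beta * e_lung_t + alpha}
    e_lung = {"B": e_lung_b, "P": e_lung_p, "T": e_lung_t}
    levels = {"B": l_b, "P": l_p, "T": l_t}

    # --- per-airway critical expansions for forced exhalation ----------
    e_crit_fvc = []
    for a in airways:
        val, _flag = critical_expansion_fvc(a["w_t"], 1.0, a["rd"])
        e_crit_fvc.append(np.nan if val is None else val)
    e_crit_fvc = np.asarray(e_crit_fvc)

    # segment fractional lung volumes (5% of the lung is unsegmented)
    f = rng.uniform(0.7, 1.3, size=cfg.n_airways)
    f = 0.95 * f / f.sum()

    # --- FVC response: fixed point of the trapped-gas feedback ---------
    # the per-group FVC response (slope, intercept) is expressed against the
    # literal (unweighted) trapping sum, the scale the response was defined on
    slope_g, icpt_g = cfg.fig8_response[group]
    noise = float(rng.normal(0.0, cfg.fvc_response_noise_sd))

    def _fvc_residual(dfvc_try: float) -> float:
        # trapped gas falls as the FVC drop (hence RV_P) grows, so this
        # residual is strictly decreasing: the fixed point is unique, but
        # plain iteration can oscillate when slope_g * n_closing > 1 —
        # solve by bisection instead
        rv = tlc - fvc_b * (1.0 - dfvc_try)
        v_tr, _ = trapped_volume(
            e_crit_fvc, f, k_bar=k_bar, rv_p=rv, tlc=tlc, fvc_b=fvc_b, mode="literal"
        )
        return float(np.clip(icpt_g + slope_g * v_tr + noise, 0.02, 0.55)) - dfvc_try

    lo, hi = 0.02, 0.55
    if _fvc_residual(lo) <= 0:
        dfvc = lo
    elif _fvc_residual(hi) >= 0:
        dfvc = hi
    else:
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if _fvc_residual(mid) > 0:
                lo = mid
            else:
                hi = mid
        dfvc = 0.5 * (lo + hi)
    fvc_p = fvc_b * (1.0 - dfvc)
    rv_p = tlc - fvc_p
    v_tr_w, closing = trapped_volume(
        e_crit_fvc, f, k_bar=k_bar, rv_p=rv_p, tlc=tlc, fvc_b=fvc_b, mode="weighted"
    )
    v_tr_l, _ = trapped_volume(
        e_crit_fvc, f, k_bar=k_bar, rv_p=rv_p, tlc=tlc, fvc_b=fvc_b, mode="literal"
    )

    # --- geometry and emitted rows -------------------------------------
    h = cfg.lung_height_mm
    airway_rows, segment_rows, truth_rows = [], [], []
    for i, a in enumerate(airways):
        label = AIRWAY_LABELS[i % len(AIRWAY_LABELS)]
        z_a = float(rng.uniform(0.15, 0.85)) * h
        x_a, y_a = float(rng.uniform(20, 180)), float(rng.uniform(20, 180))
        z_s = z_a + a["dh"] * h
        x_s, y_s = x_a + float(rng.normal(0, 8)), y_a + float(rng.normal(0, 8))
        e_b_a, e_p_a = a["e_b"], e_p ** a["q"]
        e_pb_of = {"B": l_t * e_b_a, "P": l_t * e_p_a, "T": l_t}
        a_of = {"B": a["a_b"], "T": 1.0,
                "P": 1.0 - a["rd"] * (1.0 - e_p_a**TWO_THIRDS)}
        w_of = {"B": a["w"], "P": a["w"], "T": a["w_t"]}
        for c in "BPT":
            e_pb_c = e_pb_of[c]
            e_sl_c = e_pb_c + de_mean[c] + slopes[c] * a["dh"]
            vol_l = {"B": v_b * tlc, "P": v_p * tlc, "T": tlc}[c]
            airway_rows.append(dict(
                subject_id=sid, group=group, airway_id=i, label=label, condition=c,
                a_i_mm2=(a_of[c] - w_of[c]) * a["a_o_t"],
                a_o_mm2=a_of[c] * a["a_o_t"],
                cp_x_mm=x_a, cp_y_mm=y_a, cp_z_mm=z_a,
                e_pb=e_pb_c,
            ))
            segment_rows.append(dict(
                subject_id=sid, segment_id=i, label=label, condition=c,
                e_sl=e_sl_c,
                center_x_mm=x_s, center_y_mm=y_s, center_z_mm=z_s,
                volume_ml=f[i] * vol_l * 1000.0,
            ))
        a_star_o = a_of["P"] - a["rd"] * (e_p_a**TWO_THIRDS - e_b_a**TWO_THIRDS)
        a_star_i = a_star_o - a["w"]
        ec_mlv, flag_mlv = critical_expansion_mlv(e_b_a, a_star_i, a["rd"])
        truth_rows.append(dict(
            subject_id=sid, airway_id=i, label=label,
            rd=a["rd"], wall_fraction_p=a["w"], wall_fraction_t=a["w_t"],
            a_o_t_mm2=a["a_o_t"], dh=a["dh"], q=a["q"],
            e_b_airway=e_b_a, e_p_airway=e_p_a,
            a_star_o=a_star_o, a_star_i=a_star_i,
            e_crit_mlv=np.nan if ec_mlv is None else ec_mlv,
            e_crit_fvc=e_crit_fvc[i],
            flag_mlv=flag_mlv,
            closes_in_fvc=bool(closing[i]),
            segment_fraction=f[i],
        ))

    subject_row = dict(
        subject_id=sid, group=group,
        tlc_l=tlc, fvc_b_l=fvc_b, fvc_p_l=fvc_p,
        mlv_b_l=v_b * tlc, mlv_p_l=v_p * tlc,
        fev1_b_l=0.82 * fvc_b * float(rng.normal(1.0, 0.05)),
        fev1_p_l=0.70 * fvc_p * float(rng.normal(1.0, 0.07)),
        e_lung_b=e_lung_b, e_lung_p=e_lung_p, e_lung_t=e_lung_t,
        lung_height_mm=h,
    )
    subject_truth = dict(
        subject_id=sid, group=group,
        e_b=e_b, e_p=e_p, k_bar=k_bar,
        de_mean_b=de_mean["B"], de_mean_p=de_mean["P"], de_mean_t=de_mean["T"],
        slope_b=slopes["B"], slope_p=slopes["P"], slope_t=slopes["T"],
        beta=beta, alpha=alpha,
        least_stable_airway=ls_idx, min_a_star_i=min_a_star_i_pos,
        e_crit_least_stable=e_crit_ls, least_stable_flag=ls_flag,
        e_b_least_stable=e_b_ls,
        delta_vc_over_tlc=delta_vc,
        dvl_over_tlc=v_p - v_b,
        rv_p_l=rv_p, e_pb_rv=(rv_p / tlc) / k_bar,
        v_tr_weighted=v_tr_w, v_tr_literal=v_tr_l,
        dfvc_over_fvcb=dfvc,
        n_closing=int(closing.sum()),
    )
    return airway_rows, segment_rows, subject_row, subject_truth, truth_rows


def generate_tabular_cohort(config: GeneratorConfig) -> tuple[Cohort, SyntheticTruth]:
    """Generate a tabular cohort and its ground truth.

    Fully determined by ``config.seed``: the same configuration yields a
    byte-identical cohort.
    """
    rng = np.random.default_rng(config.seed)
    airway_rows, segment_rows, subject_rows = [], [], []
    truth_subject_rows, truth_airway_rows = [], []
    for group, n in config.n_subjects_per_group.items():
        for j in range(n):
            sid = f"{group}{j + 1}"
            # a rare draw can be physiologically unsatisfiable (e.g. the
            # defense rule would push MLV_P above TLC): redraw the subject;
            # a config that fails every retry is genuinely unsolvable
            last_err = None
            for _retry in range(50):
                try:
                    a, s, subj, t_subj, t_air = _generate_subject(rng, config, group, sid)
                    break
                except CohortGenerationError as err:
                    last_err = err
            else:
                raise CohortGenerationError(
                    f"could not generate subject {sid} in 50 attempts: {last_err}"
                )
            airway_rows += a
            segment_rows += s
            subject_rows.append(subj)
            truth_subject_rows.append(t_subj)
            truth_airway_rows += t_air
    cohort = Cohort(
        airways=pd.DataFrame(airway_rows),
        segments=pd.DataFrame(segment_rows),
        subjects=pd.DataFrame(subject_rows),
    )
    truth = SyntheticTruth(
        airways=pd.DataFrame(truth_airway_rows),
        subjects=pd.DataFrame(truth_subject_rows),
        config=config,
    )
    return cohort, truth


def write_cohort(cohort: Cohort, truth: SyntheticTruth | None, outdir) -> None:
    """Write a cohort as CSV files plus a JSON truth sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.airways.to_csv(outdir / "airways.csv", index=False)
    cohort.segments.to_csv(outdir / "segments.csv", index=False)
    cohort.subjects.to_csv(outdir / "subjects.csv", index=False)
    if truth is not None:
        sidecar = {
            "config": {k: (dict(v) if isinstance(v, Mapping) else v)
                       for k, v in asdict(truth.config).items()},
            "subjects": truth.subjects.to_dict(orient="records"),
            "airways": truth.airways.to_dict(orient="records"),
        }
        (outdir / "truth.json").write_text(json.dumps(sidecar, indent=1, default=float))


def read_cohort(indir) -> Cohort:
    """Read a cohort previously written by :func:`write_cohort`."""
    indir = Path(indir)
    return Cohort(
        airways=pd.read_csv(indir / "airways.csv"),
        segments=pd.read_csv(indir / "segments.csv"),
        subjects=pd.read_csv(indir / "subjects.csv"),
    )


# voxel tier re-export: the phantom generator lives in its own file but is
# part of the synthetic-cohort surface
from .phantom import VoxelGridSpec, generate_voxel_phantom, write_phantom  # noqa: E402

__all__ += ["VoxelGridSpec", "generate_voxel_phantom", "write_phantom"]
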