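"""Pipeline presets binding the stages into the two processing chains.

``roi_glm_branch``: trim/resample -> TDDR -> Beer-Lambert -> ROI aggregation
-> FIR GLM with the engagement modulator -> group models.

``image_branch``: motion detection -> spline -> wavelet -> band-pass ->
Beer-Lambert -> epoching/block averages -> Tikhonov image reconstruction of
window means.

Everything is deterministic given (config, seed); every output carries the
resolved-config hash.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import forward_recon, gaze as gaze_mod, glm, group as group_mod, io as io_mod, preprocess, synth
from .containers import CONDITIONS, EXPECTED, UNEXPECTED, default_probe

PRESETS = ("roi_glm_branch", "image_branch")


@dataclass
class PipelineConfig:
    """Every numeric stage parameter, under its conventional name."""

    preset: str = "roi_glm_branch"
    seed: int = 0
    # synthesis
    n_subjects: int = 25
    n_trials: int | None = None
    p_expected: float = 0.8
    attention_coupling: float = 0.5
    condition_gaze_effect: float = -0.10
    b1: float | None = None
    gaze_loss_rate: float = 0.05
    n_tile_cols: int = 4
    n_tile_rows: int = 3
    # preprocessing (names as conventionally printed)
    tMotion: float = 1.0
    tMask: float = 1.0
    STDEV: float = 15.0
    AMPthresh: float = 0.4
    p: float = 0.99
    IQR: float = 0.8
    DPF: float = 5.1
    bandpass_lo_hz: float = 0.01
    bandpass_hi_hz: float = 0.5
    max_sep_mm: float = 60.0
    cv_max_percent: float = 8.0
    resample_hz: float = 4.0
    # reconstruction / ROI
    tikhonov_lambda: float = 0.01
    sep_range_mm: tuple[float, float] = (12.0, 45.0)
    node_spacing_mm: float = 8.0
    # GLM
    basis: str = "fir"
    n_bins: int = 28
    avg_bin_lo: int = 12
    avg_bin_hi: int = 24
    fdr_q: float = 0.05
    dtr_scale: tuple[float, float] = (0.1, 1.0)
    min_trials_per_type: int = 3
    max_ar_order: int | None = 4

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {PRESETS}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("sep_range_mm", "dtr_scale"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def hash(self) -> str:
        return io_mod.config_hash(self.to_dict())


@dataclass
class PipelineResult:
    """Bundle of tables, fits and provenance from one pipeline run."""

    dtr_table: pd.DataFrame
    beta_table: pd.DataFrame
    contrast_table: pd.DataFrame
    group_fits: dict
    subject_log: pd.DataFrame
    provenance: dict
    images: dict = field(default_factory=dict)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.dtr_table.to_csv(out / "dtr_table.tsv", sep="\t", index=False)
        self.beta_table.to_csv(out / "beta_table.tsv", sep="\t", index=False)
        self.contrast_table.to_csv(out / "contrast_table.tsv", sep="\t", index=False)
        self.subject_log.to_csv(out / "subject_log.tsv", sep="\t", index=False)
        io_mod.write_json(self.provenance, out / "provenance.json")
        fits = {}
        for name, fit in self.group_fits.items():
            if isinstance(fit, group_mod.MixedFitResult):
                fits[name] = {
                    "params": fit.params.to_dict(),
                    "se": fit.se.to_dict(),
                    "p": fit.pvalues.to_dict(),
                    "sigma2_subject": fit.sigma2_subject,
                    "sigma2_resid": fit.sigma2_resid,
                    "r2_marginal": fit.r2_marginal,
                    "r2_conditional": fit.r2_conditional,
                }
            elif isinstance(fit, group_mod.LogisticFitResult):
                fits[name] = asdict(fit)
        io_mod.write_json(fits, out / "group_fits.json")


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the configured preset end to end on a synthetic cohort."""
    rng = np.random.default_rng(config.seed)
    cohort = synth.generate_cohort(
        n_subjects=config.n_subjects,
        b1=config.b1,
        seed=int(rng.integers(0, 2**31 - 1)),
        n_trials=config.n_trials,
        p_expected=config.p_expected,
        attention_coupling=config.attention_coupling,
        condition_gaze_effect=config.condition_gaze_effect,
    )
    probe = default_probe(n_tile_cols=config.n_tile_cols, n_tile_rows=config.n_tile_rows)
    sens = forward_recon.compute_sensitivity(
        probe, nodes=forward_recon.default_node_grid(probe, spacing_mm=config.node_spacing_mm)
    )
    roi_masks = forward_recon.default_rois(sens)
    rois = [
        forward_recon.roi_weights(sens, mask, sep_range_mm=config.sep_range_mm, name=name)
        for name, mask in roi_masks.items()
    ]

    dtr_rows, beta_rows, log_rows = [], [], []
    image_acc: dict[str, list] = {}
    for rec in cohort.subjects:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        gz = synth.generate_gaze(
            rec.schedule, rec.truth, loss_rate=config.gaze_loss_rate, seed=sub_seed
        )
        dtr = gaze_mod.compute_dtr(gz, rec.schedule)
        include, counts = gaze_mod.subject_inclusion(dtr, rec.schedule, config.min_trials_per_type)
        df = dtr.to_frame()
        df.insert(0, "subject", rec.subject)
        df["condition"] = df["type"]
        dtr_rows.append(df)
        log_rows.append(
            {
                "subject": rec.subject,
                "included": include,
                "usable_expected": counts[EXPECTED],
                "usable_unexpected": counts[UNEXPECTED],
                "n_trials": rec.schedule.n_trials,
            }
        )
        if not include:
            continue
        ts, _ = synth.generate_channel_data(rec.schedule, rec.truth, probe, seed=sub_seed + 1)
        if config.preset == "roi_glm_branch":
            beta_rows.extend(_roi_glm_subject(config, rec, ts, dtr, rois))
        else:
            _image_subject(config, rec, ts, sens, image_acc)

    dtr_table = pd.concat(dtr_rows, ignore_index=True)
    subject_log = pd.DataFrame(log_rows)
    beta_table = pd.DataFrame(beta_rows)
    if not beta_table.empty:
        truths = {s.subject: s.truth for s in cohort.subjects}
        beta_table["trait_anxiety"] = beta_table["subject"].map(lambda s: truths[s].trait_anxiety)
        beta_table["state_anxiety"] = beta_table["subject"].map(lambda s: truths[s].state_anxiety)
        beta_table["clinical"] = beta_table["trait_anxiety"] > cohort.anxiety_cfg.clinical_cutoff

    contrast_table = group_contrasts(beta_table, q=config.fdr_q) if not beta_table.empty else pd.DataFrame()

    group_fits: dict = {}
    usable_dtr = dtr_table.dropna(subset=["dtr"])
    group_fits["dtr_condition"] = group_mod.fit_random_intercept(usable_dtr, "dtr", "condition")
    group_fits["dtr_habituation"] = group_mod.fit_random_intercept(usable_dtr, "dtr", "trial * condition")
    if not beta_table.empty:
        hbo = beta_table[beta_table["chromophore"] == "HbO"]
        r_mpfc = hbo[hbo["roi"] == "R_mPFC"]
        if r_mpfc["subject"].nunique() >= 2:
            group_fits["anxiety_interaction"] = group_mod.fit_anxiety_interaction(r_mpfc)
            try:
                group_fits["logistic_clinical"] = group_mod.fit_logistic_clinical(r_mpfc)
            except ValueError:
                group_fits["logistic_clinical"] = None

    images = {k: np.mean(v, axis=0) for k, v in image_acc.items()}
    provenance = {
        "config": config.to_dict(),
        "config_hash": config.hash,
        "preset_order": _preset_order(config.preset),
        "tikhonov_scaling": "lambda * max diag(J J^T)",
        "n_subjects_included": int(subject_log["included"].sum()),
    }
    return PipelineResult(
        dtr_table=dtr_table,
        beta_table=beta_table,
        contrast_table=contrast_table,
        group_fits=group_fits,
        subject_log=subject_log,
        provenance=provenance,
        images=images,
    )


def _preset_order(preset: str) -> list[str]:
    if preset == "roi_glm_branch":
        return ["trim_resample", "tddr", "mbll", "roi_timeseries", "fir_glm", "group"]
    return ["detect_motion", "spline", "wavelet", "bandpass", "mbll", "block_average", "reconstruct"]


def _roi_glm_subject(config, rec, ts, dtr, rois) -> list[dict]:
    """ROI/GLM branch for one subject: returns beta-table rows."""
    ts = preprocess.resample_trim(ts, target_hz=config.resample_hz, schedule=rec.schedule)
    ts = preprocess.correct_tddr(ts)
    hb = preprocess.mbll(ts, dpf=config.DPF)
    roi_df = forward_recon.roi_timeseries(hb, rois)
    scaled = gaze_mod.scale_dtr(dtr, *config.dtr_scale)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        design = glm.build_design(
            rec.schedule,
            scaled,
            basis=config.basis,
            rate_hz=ts.rate_hz,
            n_times=ts.n_times,
            t0_s=ts.t0_s,
            n_bins=config.n_bins,
        )
        for r in roi_df.itertuples(index=False):
            if np.isnan(r.series).any():
                continue
            fit = glm.ar_irls_fit(r.series, design, max_ar_order=config.max_ar_order)
            if config.basis == "fir":
                summ = glm.average_bins(fit, config.avg_bin_lo, config.avg_bin_hi)
                for cond in summ.conditions:
                    i = summ.conditions.index(cond)
                    rows.append(
                        {
                            "subject": rec.subject,
                            "roi": r.roi,
                            "chromophore": r.chromophore,
                            "condition": cond,
                            "beta": summ.estimates[cond],
                            "se": float(np.sqrt(summ.cov[i, i])),
                        }
                    )
            else:
                for cond in CONDITIONS:
                    rows.append(
                        {
                            "subject": rec.subject,
                            "roi": r.roi,
                            "chromophore": r.chromophore,
                            "condition": cond,
                            "beta": fit[cond],
                            "se": fit.se(cond),
                        }
                    )
    return rows


def _image_subject(config, rec, ts, sens, image_acc) -> None:
    """Image branch for one subject: accumulate window-mean Hb images."""
    mask = preprocess.detect_motion(
        ts, t_motion_s=config.tMotion, t_mask_s=config.tMask, std_thresh=config.STDEV, amp_thresh=config.AMPthresh
    )
    ts = preprocess.correct_spline(ts, mask, p=config.p)
    ts = preprocess.correct_wavelet(ts, iqr_mult=config.IQR)
    ts = preprocess.bandpass(ts, config.bandpass_lo_hz, config.bandpass_hi_hz)
    # window means of OD per channel per condition, reconstructed to Hb images
    rate = ts.rate_hz
    tbl = ts.channels.reset_index(drop=True)
    pairs = sens.pair_table
    for cond in CONDITIONS:
        onsets = rec.schedule.stim_onsets[rec.schedule.types == cond]
        if len(onsets) == 0:
            continue
        od_by_wl = {}
        for wl in sorted(tbl["wavelength_nm"].unique()):
            sel_rows = tbl.index[tbl["wavelength_nm"] == wl]
            aligned = _align_pairs(tbl.loc[sel_rows], pairs)
            vals = np.zeros(len(pairs))
            for onset in onsets:
                i0 = int(round((onset + 3.0 - ts.t0_s) * rate))
                i1 = int(round((onset + 6.0 - ts.t0_s) * rate))
                b0 = int(round((onset - 2.0 - ts.t0_s) * rate))
                b1 = int(round((onset - ts.t0_s) * rate))
                if b0 < 0 or i1 > ts.n_times:
                    continue
                win = ts.data[sel_rows, i0:i1].mean(axis=1) - ts.data[sel_rows, b0:b1].mean(axis=1)
                vals += win[aligned]
            od_by_wl[float(wl)] = vals / len(onsets)
        img = forward_recon.reconstruct_hb(sens, od_by_wl, lam=config.tikhonov_lambda)
        image_acc.setdefault(f"{cond}_hbo", []).append(img.hbo)
        image_acc.setdefault(f"{cond}_hbr", []).append(img.hbr)


def _align_pairs(sub_table: pd.DataFrame, pairs: pd.DataFrame) -> np.ndarray:
    """Index array mapping the sensitivity pair order into sub_table rows."""
    key = {(int(s), int(d)): i for i, (s, d) in enumerate(zip(sub_table["source"], sub_table["detector"]))}
    return np.array([key[(int(s), int(d))] for s, d in zip(pairs["source"], pairs["detector"])])


def group_contrasts(beta_table: pd.DataFrame, q: float = 0.05) -> pd.DataFrame:
    """Group contrast table: per ROI and chromophore, U vs baseline and U-E.

    The main-analysis family pools 6 ROIs x 2 contrasts = 12 comparisons per
    chromophore for Benjamini-Hochberg correction.
    """
    rows = []
    for chrom, sub in beta_table.groupby("chromophore"):
        fam = []
        for roi, rsub in sub.groupby("roi"):
            piv = rsub.pivot_table(index="subject", columns="condition", values="beta")
            if UNEXPECTED not in piv or EXPECTED not in piv:
                continue
            u = piv[UNEXPECTED].dropna()
            d = (piv[UNEXPECTED] - piv[EXPECTED]).dropna()
            for label, series in (("U_vs_baseline", u), ("U_minus_E", d)):
                n = len(series)
                est = float(series.mean())
                se = float(series.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
                t = est / se if se and se > 0 else np.nan
                p = float(2 * stats.t.sf(abs(t), n - 1)) if np.isfinite(t) else np.nan
                fam.append({"roi": roi, "chromophore": chrom, "contrast": label, "estimate": est, "se": se, "t": t, "dof": n - 1, "p": p})
        if fam:
            pvals = [r["p"] for r in fam]
            p_adj, reject = glm.fdr_bh(pvals, q=q)
            for r, pa, rj in zip(fam, p_adj, reject):
                r["p_adj"] = float(pa)
                r["significant"] = bool(rj)
            rows.extend(fam)
    return pd.DataFrame(rows)
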