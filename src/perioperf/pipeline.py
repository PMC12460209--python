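"""End-to-end orchestration: simulate a cohort, map T1, fit kinetics,
segment compartments, stratify lesions and run the statistical battery.

Every stage consumes only its predecessors' outputs and the seeded
configuration, so a rerun with the same seed reproduces all numeric
outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import AcquisitionConfig, AIFParams, Compartment
from .io import save_nifti
from .kinetics import (compute_auc, fit_tofts, rigid_motion_correct,
                       sample_aif, signal_to_concentration)
from .phantom import CohortDesign, build_subject, render_acquisition, \
    solve_matched_control_t1
from .relaxometry import fit_vfa_t1
from .segmentation import (compose_labelmap, control_stats, perilesional_shell,
                           segment_lesion)
from .stats import ComparisonResult, compare_dichotomy, compare_regions, \
    icc_agreement
from .stratify import classify_mismatch, extract_region_means, place_site_voi

__all__ = ["PipelineConfig", "CohortReport", "PipelineError", "run_pipeline"]

REGIONS = ["T1C+", "T2W+", "PL", "C"]
PERFUSION_MAPS = ["ktrans", "ve", "auc"]
STRUCTURAL_MAPS = ["t1c", "t2w", "cbct"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and a QC snapshot."""

    def __init__(self, stage: str, qc: dict, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.qc = qc


@dataclass(frozen=True)
class PipelineConfig:
    """Full study configuration: acquisition, cohort design, segmentation
    and statistics settings, seed, optional output directory."""

    acq: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    design: CohortDesign = field(default_factory=CohortDesign)
    k_threshold: float = 2.0
    rater2_k: float = 2.5          # second-reader threshold for the ICC check
    mismatch_mode: str = "reference_range"
    stats_mode: str = "auto"
    dunn_family: str = "control"
    motion_correct: str = "auto"   # auto | always | never
    motion_amplitude_vox: float = 0.0
    voi_voxels: int = 40
    seed: int = 0
    out_dir: str | None = None
    write_volumes: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        acq = AcquisitionConfig(**{k: tuple(v) if isinstance(v, list) else v
                                   for k, v in raw.pop("acq", {}).items()})
        design = CohortDesign(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in raw.pop("design", {}).items()})
        return cls(acq=acq, design=design, **raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class CohortReport:
    """All cohort-level outputs: subjects × regions tables per map, omnibus
    and dichotomy comparison results, the per-site lesion table,
    inter-reader ICCs, QC counters and provenance."""

    region_tables: dict[str, pd.DataFrame]
    region_results: dict[str, ComparisonResult]
    dichotomy_results: dict[str, ComparisonResult]
    lesion_table: pd.DataFrame
    icc: dict[str, tuple[float, tuple[float, float]]]
    qc: dict
    config_hash: str
    seed: int


def _subject_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def process_subject(
    dataset: dict,
    truth,
    cfg: PipelineConfig,
    control_mask: np.ndarray,
) -> dict:
    """Analyze one subject's rendered dataset.

    ``control_mask`` stands in for the reader-placed control VOI of distant
    normal bone.  Returns region means per map, segmentation masks, site-VOI
    records and QC counters.
    """
    acq, design = cfg.acq, cfg.design
    stage = "motion"
    try:
        dynamic = dataset["dynamic"]
        moved = cfg.motion_correct == "always" or (
            cfg.motion_correct == "auto" and cfg.motion_amplitude_vox > 0)
        if moved:
            dynamic, shifts = rigid_motion_correct(dynamic, design.spacing)
        else:
            shifts = None

        stage = "t1map"
        t1m0 = fit_vfa_t1(dataset["vfa"], acq.flip_vfa, acq.tr_dynamic)

        stage = "segment"
        st1c = control_stats(dataset["t1c"], control_mask)
        st2w = control_stats(dataset["t2w"], control_mask)
        lesions = segment_lesion(dataset["t1c"], dataset["t2w"], st1c, st2w,
                                 k=cfg.k_threshold)
        # the reader-designated control VOI is normal bone by definition
        for name in lesions:
            lesions[name] &= ~control_mask
        pl = perilesional_shell(lesions, design.spacing, design.shell_radius_mm,
                                dataset["t1c"], dataset["t2w"], st1c, st2w,
                                k=cfg.k_threshold)
        labelmap = compose_labelmap({**lesions, "PL": pl}, control_mask,
                                    meta={"k": cfg.k_threshold,
                                          "radius_mm": design.shell_radius_mm,
                                          "thr_t1c": st1c.threshold(cfg.k_threshold),
                                          "thr_t2w": st2w.threshold(cfg.k_threshold)})

        # second reader: same workflow at a stricter threshold
        lesions2 = segment_lesion(dataset["t1c"], dataset["t2w"], st1c, st2w,
                                  k=cfg.rater2_k)
        for name in lesions2:
            lesions2[name] &= ~control_mask

        stage = "kinetics"
        conc = signal_to_concentration(dynamic, t1m0, acq)
        aifs = dataset["aif_samples"] or sample_aif(
            AIFParams(onset_delay=acq.bolus_onset), acq.frame_times)
        fit_mask = (labelmap.labels > 0) | lesions2["T1C+"] | lesions2["T2W+"]
        pmaps = fit_tofts(conc, aifs, mask=fit_mask & conc.mask)
        enh = dynamic / np.maximum(
            dynamic[..., :acq.baseline_frames].mean(axis=-1, keepdims=True), 1e-9) - 1.0
        auc = compute_auc(enh, aifs.cp, acq.auc_window, t_s=acq.frame_times,
                          aif_t_s=aifs.t_min * 60.0)
        pmaps.auc = auc

        stage = "stratify"
        maps = {"ktrans": pmaps.ktrans, "ve": pmaps.ve, "auc": auc,
                "t1c": dataset["t1c"], "t2w": dataset["t2w"],
                "cbct": dataset["cbct"]}
        region_means = extract_region_means(maps, labelmap.labels)

        # rater means for the agreement analysis
        rater = {}
        for rk, les in (("r1", lesions), ("r2", lesions2)):
            for name in ("T1C+", "T2W+"):
                m = les[name]
                rater[f"{rk}_{name}"] = (float(np.nanmean(pmaps.ktrans[m]))
                                         if m.any() else np.nan)

        # 40-voxel site VOIs within the segmented T1C+ lesion
        site_rows = []
        lesion_mask = labelmap.labels == Compartment.T1C
        for _, a in truth.site_anchors.iterrows():
            rec = dict(tooth=int(a["tooth"]), site=a["site"])
            clin = truth.clinical.query("tooth == @a.tooth and site == @a.site")
            rec["bop"] = int(clin["bop"].iloc[0])
            rec["bone_loss"] = int(clin["bone_loss"].iloc[0])
            if lesion_mask.any():
                voi, short = place_site_voi(
                    lesion_mask, (a["i"], a["j"], a["k"]),
                    n_voxels=cfg.voi_voxels, spacing=design.spacing)
                for m_name in PERFUSION_MAPS:
                    vals = maps[m_name][voi]
                    rec[f"mean_{m_name}"] = float(np.nanmean(vals))
                rec["voi_voxels"] = int(voi.sum())
                rec["shortfall"] = bool(short)
            else:
                for m_name in PERFUSION_MAPS:
                    rec[f"mean_{m_name}"] = np.nan
                rec["voi_voxels"] = 0
                rec["shortfall"] = True
            site_rows.append(rec)

        qc = dict(conc.qc)
        qc["fit_voxels"] = int(np.sum(fit_mask))
        qc["motion_corrected"] = bool(moved)
        return {
            "region_means": region_means,
            "labelmap": labelmap,
            "rater_means": rater,
            "site_records": site_rows,
            "lesion_volumes": {
                "T1C+": int(lesions["T1C+"].sum()),
                "T2W+": int(lesions["T2W+"].sum()),
            },
            "maps": maps,
            "qc": qc,
            "shifts": shifts,
        }
    except PipelineError:
        raise
    except Exception as exc:  # halt with stage name and QC snapshot
        raise PipelineError(stage, {"subject_qc": "unavailable"}, exc) from exc


def run_pipeline(cfg: PipelineConfig) -> CohortReport:
    """Run the full synthetic-cohort study defined by ``cfg``.

    Simulates ``cfg.design.n_subjects`` subjects, analyzes each one, then
    assembles the regional tables, dichotomized comparisons, ICC agreement
    and QC report.  Writes CSV/JSON (and optionally NIfTI) outputs when
    ``cfg.out_dir`` is set.
    """
    acq, design = cfg.acq, cfg.design
    aif = AIFParams(onset_delay=acq.bolus_onset)
    control_t1 = solve_matched_control_t1(
        design.pl_ktrans, design.pl_ve, design.pl_t1,
        design.c_ktrans, design.c_ve, acq, aif,
        jitter_sd=np.hypot(design.subject_sd, design.compartment_sd))

    seeds = _subject_seeds(cfg.seed, design.n_subjects)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).generate_state(1)[0])

    per_subject = []
    region_rows = {m: [] for m in PERFUSION_MAPS + STRUCTURAL_MAPS}
    site_rows = []
    rater_rows = []
    lesion_vols = {"T1C+": [], "T2W+": []}
    qc_total: dict = {"subjects": design.n_subjects}

    for s, sseed in enumerate(seeds):
        truth = build_subject(design, acq, seed=sseed, control_t1=control_t1, aif=aif)
        motion = None
        if cfg.motion_amplitude_vox > 0:
            motion = rng.normal(0.0, cfg.motion_amplitude_vox,
                                (acq.n_cycles, 3))
            motion[:acq.baseline_frames] = 0.0
        dataset = render_acquisition(truth, acq, aif, noise_sd=design.noise_sd,
                                     motion=motion, seed=sseed + 1)
        result = process_subject(dataset, truth, cfg,
                                 control_mask=truth.compartment_mask(Compartment.CONTROL))
        per_subject.append(result)

        rm = result["region_means"].set_index("region")
        for m in region_rows:
            region_rows[m].append(
                {"subject": s, **{r: rm.loc[r, m] if r in rm.index else np.nan
                                  for r in REGIONS}})
        for rec in result["site_records"]:
            site_rows.append({"subject": s, **rec})
        rater_rows.append({"subject": s, **result["rater_means"]})
        for name in lesion_vols:
            lesion_vols[name].append(result["lesion_volumes"][name])
        for k, v in result["qc"].items():
            if isinstance(v, (int, np.integer)):
                qc_total[k] = qc_total.get(k, 0) + int(v)

    region_tables = {m: pd.DataFrame(rows).set_index("subject")
                     for m, rows in region_rows.items()}

    region_results = {}
    for m, tab in region_tables.items():
        complete = tab.dropna()
        if len(complete) >= 3:
            region_results[m] = compare_regions(
                complete, mode=cfg.stats_mode, control="C",
                dunn_family=cfg.dunn_family)

    lesion_table = pd.DataFrame(site_rows)
    mismatch = classify_mismatch(np.asarray(lesion_vols["T1C+"], float),
                                 np.asarray(lesion_vols["T2W+"], float),
                                 mode=cfg.mismatch_mode)
    lesion_table["mismatch"] = mismatch[lesion_table["subject"].to_numpy()].astype(int)

    dichotomy_results = _dichotomies(lesion_table, region_tables, mismatch)

    rater_df = pd.DataFrame(rater_rows)
    icc = {}
    for name in ("T1C+", "T2W+"):
        mat = rater_df[[f"r1_{name}", f"r2_{name}"]].dropna().to_numpy()
        if mat.shape[0] >= 5 and np.ptp(mat) > 0:
            icc[name] = icc_agreement(mat, form="icc2")

    report = CohortReport(
        region_tables=region_tables,
        region_results=region_results,
        dichotomy_results=dichotomy_results,
        lesion_table=lesion_table,
        icc=icc,
        qc=qc_total,
        config_hash=cfg.config_hash,
        seed=cfg.seed,
    )
    if cfg.out_dir:
        _write_report(report, cfg, per_subject)
    return report


def _dichotomies(lesion_table, region_tables, mismatch) -> dict[str, ComparisonResult]:
    """BOP (paired within subject), mismatch and bone-loss (between lesions)
    comparisons of the perfusion indices."""
    out = {}
    for m in PERFUSION_MAPS:
        col = f"mean_{m}"
        # BOP: within-subject means of positive vs negative sites, paired
        g = lesion_table.groupby(["subject", "bop"])[col].mean().unstack("bop")
        if g.shape[1] == 2:
            both = g.dropna()
            if len(both) >= 2:
                out[f"bop_{m}"] = compare_dichotomy(
                    both[1].to_numpy(), both[0].to_numpy(), paired=True)
        # mismatch / bone loss: between lesions (one per subject)
        t1c = region_tables[m]["T1C+"]
        for flag_name, flags in (
                ("mismatch", mismatch),
                ("bone_loss", lesion_table.groupby("subject")["bone_loss"]
                 .first().to_numpy().astype(bool))):
            pos, neg = t1c[flags], t1c[~flags]
            if pos.notna().sum() >= 2 and neg.notna().sum() >= 2:
                out[f"{flag_name}_{m}"] = compare_dichotomy(
                    pos.dropna(), neg.dropna(), paired=False, parametric=True)
    return out


def _result_to_dict(res: ComparisonResult) -> dict:
    return {"test": res.test, "statistic": res.statistic, "p_value": res.p_value,
            "posthoc": res.posthoc, "raw_posthoc": res.raw_posthoc,
            "direction": res.direction, "normality": res.normality}


def _write_report(report: CohortReport, cfg: PipelineConfig, per_subject) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {"config_hash": report.config_hash, "seed": report.seed}
    for m, tab in report.region_tables.items():
        tab.assign(**prov).to_csv(out / f"region_means_{m}.csv")
    report.lesion_table.assign(**prov).to_csv(out / "lesion_table.csv", index=False)
    results = {
        "regions": {m: _result_to_dict(r) for m, r in report.region_results.items()},
        "dichotomies": {k: _result_to_dict(r)
                        for k, r in report.dichotomy_results.items()},
        "icc": {k: {"icc": v[0], "ci95": list(v[1])} for k, v in report.icc.items()},
        "qc": report.qc, **prov,
    }
    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=2, default=float)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh)
    if cfg.write_volumes:
        for s, res in enumerate(per_subject):
            sdir = out / "subjects" / f"sub{s:02d}"
            save_nifti(res["labelmap"].labels, sdir / "labels.nii.gz",
                       cfg.design.spacing)
            for name, vol in res["maps"].items():
                save_nifti(np.nan_to_num(vol), sdir / f"{name}.nii.gz",
                           cfg.design.spacing)
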