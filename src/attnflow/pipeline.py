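"""End-to-end synthetic study: simulate -> ROI stats -> GLM -> DCM/BMS -> GCM.

:func:`run_study` executes the full chain on a ground-truth group with a
single :class:`StudyConfig`, writing every stage artifact (TSV/JSON)
under the output directory and returning the assembled report.  The run
is deterministic for a fixed config: every stochastic stage derives its
seed from the config seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import io as aio
from .bms import family_inference, rfx_bms
from .dcm import DCMPriors, HemoParams, fit_dcm, integrate_dcm, posterior_edge_test
from .gcm import granger_analysis
from .glm import build_design_matrix, fit_glm, group_rfx_contrast, two_gamma_hrf
from .model_space import build_direction_families, enumerate_feedback_models
from .preprocess import extract_block_amplitude, grand_mean_scale, mean_condition_amplitudes
from .stats import attention_index, one_sample_t, paired_t, pearson_r
from .synthetic import (
    GroupTruth,
    NoiseSpec,
    default_neural_truth,
    noise_sd_for_snr,
    simulate_group,
    standard_design,
)

log = logging.getLogger(__name__)

__all__ = ["StudyConfig", "run_study"]


@dataclass
class StudyConfig:
    """Configuration of the synthetic study.

    The defaults reproduce the standard conditions at a desk scale:
    the 8x16 s / 8x12 s block design at TR 2 s, a 5-node frontoparietal
    + visual network whose generating model modulates the IFJ feedback
    to the ignored-side visual node with 0.5 Hz, SNR 1 observation
    noise, and analysis with the single-source models of the feedback
    space.
    """

    # simulation
    n_blocks: int = 8
    block_dur: float = 16.0
    blank_dur: float = 12.0
    tr: float = 2.0
    microtime_bins: int = 8
    n_subjects: int = 8
    snr: float = 1.0
    generating_model: str = "3"
    b_value: float = 0.5
    seed: int = 0
    # analysis
    fit_models: tuple[str, ...] = ("1", "2", "3", "4")
    run_family_inference: bool = False
    bms_draws: int = 100_000
    gcm_n_boot: int = 1000
    gcm_order: int | None = 1
    fdr_q: float = 0.05
    jobs: int = 1

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fit_models"] = list(self.fit_models)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "fit_models" in d:
            d["fit_models"] = tuple(str(m) for m in d["fit_models"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path


def _stage(report: dict, name: str, started: float) -> None:
    report.setdefault("stages", {})[name] = {"wall_s": round(time.time() - started, 3)}
    log.info("stage %-12s done in %.2fs", name, time.time() - started)


def _fit_subject_models(args):
    data, specs, design, priors = args
    return [fit_dcm(data, spc, design, priors=priors) for spc in specs]


def run_study(config: StudyConfig, out_dir: str | Path | None = None) -> dict:
    """Execute every stage and return (and optionally write) the report."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_dict(), "seed": config.seed}

    # ----------------------------------------------------------- simulate
    t0 = time.time()
    design = standard_design(
        config.n_blocks, config.block_dur, config.blank_dur,
        tr=config.tr, microtime_bins=config.microtime_bins,
    )
    space = enumerate_feedback_models()
    gen_spec = space.spec(config.generating_model)
    truth_params = default_neural_truth(gen_spec, b_value=config.b_value)
    hemo = HemoParams()
    clean = integrate_dcm(gen_spec, truth_params, hemo, design)
    noise = NoiseSpec(sd=noise_sd_for_snr(clean, config.snr))
    truth = GroupTruth(truth_params, hemo, n_subjects=config.n_subjects)
    group = simulate_group(truth, gen_spec, design, noise, seed=config.seed)
    if out is not None:
        aio.write_design_json(design, out / "design.json")
        for s, ts in enumerate(group):
            aio.write_timeseries_tsv(ts, out / f"subject_{s:02d}.tsv")
    report["simulate"] = {
        "n_subjects": config.n_subjects,
        "noise_sd": noise.sd,
        "regions": list(gen_spec.regions),
        "generating_model": config.generating_model,
    }
    _stage(report, "simulate", t0)

    visual = gen_spec.regions[-1]
    frontal = [r for r in gen_spec.regions if r != visual]

    # ---------------------------------------------------------- ROI stats
    t0 = time.time()
    amp_frames = []
    for s, ts in enumerate(group):
        scaled = grand_mean_scale(ts)
        amp_frames.append(extract_block_amplitude(scaled, design, subject=s))
    import pandas as pd

    amplitudes = pd.concat(amp_frames, ignore_index=True)
    means = mean_condition_amplitudes(amplitudes)
    ia = means.assign(
        I_A=[attention_index(r.Same, r.Different) for r in means.itertuples()]
    )
    roi = {}
    for region in gen_spec.regions:
        sub = ia[ia.region == region].sort_values("subject")
        t_ia = one_sample_t(sub.I_A.to_numpy())
        t_amp = paired_t(
            means[means.region == region].sort_values("subject").Same.to_numpy(),
            means[means.region == region].sort_values("subject").Different.to_numpy(),
        )
        roi[region] = {
            "mean_I_A": float(sub.I_A.mean()),
            "t_I_A": t_ia.statistic, "df": t_ia.df, "p_I_A": t_ia.p,
            "t_paired_amp": t_amp.statistic, "p_paired_amp": t_amp.p,
        }
    ia_vis = ia[ia.region == visual].sort_values("subject").I_A.to_numpy()
    correlations = {}
    for region in frontal:
        ia_r = ia[ia.region == region].sort_values("subject").I_A.to_numpy()
        res = pearson_r(ia_vis, ia_r)
        correlations[region] = {"r": res.statistic, "p": res.p}
    report["roi_stats"] = {"per_region": roi, "correlation_with_visual": correlations}
    if out is not None:
        ia.to_csv(out / "attention_index.tsv", sep="\t", index=False)
    _stage(report, "roi_stats", t0)

    # ---------------------------------------------------------------- GLM
    t0 = time.time()
    hrf = two_gamma_hrf(design.tr, design.microtime_bins)
    X = build_design_matrix(design, hrf)
    contrast = X.contrast_vector({"Same": 1.0, "Different": -1.0})
    subj_con = np.array(
        [fit_glm(ts, X).contrast_value(contrast) for ts in group]
    )  # subjects x regions
    grp = group_rfx_contrast(subj_con, q=config.fdr_q, region_labels=gen_spec.regions)
    report["glm"] = {
        "contrast": "Same > Different",
        "n_columns": len(X.columns),
        "group_t": grp["t"].tolist(),
        "group_p_fdr": grp["p_fdr"].tolist(),
        "significant_regions": [
            r for r, sig in zip(gen_spec.regions, grp["significant"]) if sig
        ],
    }
    _stage(report, "glm", t0)

    # ------------------------------------------------------------ DCM/BMS
    t0 = time.time()
    priors = DCMPriors()
    specs = [space.spec(m) for m in config.fit_models]
    datasets = [ts.copy_with(ts.data - 100.0) for ts in group]
    if config.jobs > 1:
        from joblib import Parallel, delayed

        all_fits = Parallel(n_jobs=config.jobs)(
            delayed(_fit_subject_models)((d, specs, design, priors)) for d in datasets
        )
    else:
        all_fits = [_fit_subject_models((d, specs, design, priors)) for d in datasets]
    F = np.array([[f.free_energy for f in fits] for fits in all_fits])
    bms_res = rfx_bms(F, model_ids=config.fit_models,
                      n_draws=config.bms_draws, seed=config.seed)
    # modulatory edge test on the winning model
    win = bms_res.best()
    wi = list(config.fit_models).index(win)
    win_spec = space.spec(win)
    mod_edges = [
        (win_spec.regions[j], win_spec.regions[i])
        for i, j in zip(*np.where(win_spec.b_masks["Same"]))
    ]
    edge_tests = {}
    for edge in mod_edges:
        res = posterior_edge_test([fits[wi] for fits in all_fits], edge, "Same")
        edge_tests[f"{edge[0]}->{edge[1]}"] = {
            "t": res.statistic, "df": res.df, "p": res.p,
            "mean_b": float(np.mean(
                [fits[wi].modulatory_mean("Same", edge) for fits in all_fits]
            )),
        }
    report["dcm"] = {
        "fit_models": list(config.fit_models),
        "free_energy": F.tolist(),
        "exceedance": dict(zip(bms_res.model_ids, bms_res.exceedance.tolist())),
        "best_model": win,
        "edge_tests": edge_tests,
    }
    if out is not None:
        aio.write_report_json(bms_res.to_dict(), out / "bms.json")
    _stage(report, "dcm_bms", t0)

    if config.run_family_inference:
        t0 = time.time()
        (fam1, fam2, fam3), partition = build_direction_families()
        fam_models = list(fam1.models) + list(fam2.models) + list(fam3.models)
        Ff = np.array([
            [fit_dcm(d, spc, design, priors=priors).free_energy for _, spc in fam_models]
            for d in datasets
        ])
        fam_res = family_inference(
            Ff, partition, model_ids=[m for m, _ in fam_models],
            n_draws=config.bms_draws, seed=config.seed,
        )
        report["family_inference"] = {
            "exceedance": dict(zip(fam_res.model_ids, fam_res.exceedance.tolist())),
            "best_family": fam_res.best(),
        }
        _stage(report, "family_inference", t0)

    # ---------------------------------------------------------------- GCM
    t0 = time.time()
    nets = []
    for s, ts in enumerate(group):
        scaled = grand_mean_scale(ts)
        nets.append(
            granger_analysis(
                scaled, p=config.gcm_order, n_boot=config.gcm_n_boot,
                q=config.fdr_q, seed=config.seed * 1000 + s,
            )
        )
    mean_gc = np.mean([net.gc for net in nets], axis=0)
    majority = np.mean([net.sig_mask for net in nets], axis=0) >= 0.5
    from .gcm import degree_metrics

    group_net = degree_metrics(mean_gc, majority, gen_spec.regions)
    report["gcm"] = {
        "order": nets[0].meta.get("order"),
        "n_boot": config.gcm_n_boot,
        "group_source": group_net.source,
        "group_sink": group_net.sink,
        "subject_sources": [net.source for net in nets],
        "group_outflow": group_net.outflow.tolist(),
        "group_netflow": group_net.netflow.tolist(),
        "group_inflow": group_net.inflow.tolist(),
    }
    if out is not None:
        aio.write_report_json(group_net.to_dict(), out / "granger_group.json")
    _stage(report, "gcm", t0)

    report["versions"] = {"attnflow": __import__("attnflow").__version__}
    if out is not None:
        aio.write_report_json(report, out / "report.json")
    return report
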