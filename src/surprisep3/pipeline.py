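"""End-to-end orchestration: simulate -> surprise -> mapping -> ERP panel
-> stopping -> component refits, with a serializable configuration and a
machine-readable summary.

All randomness flows from a single root seed through per-stage derived
seeds, so a run re-executed from its emitted configuration is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import components as comp_mod
from . import erp as erp_mod
from . import io as io_mod
from . import mapping as map_mod
from . import stopping as stop_mod
from . import surprise as sur_mod
from . import synthetic as syn_mod
from .montage import FRONTOCENTRAL, channel_index

log = logging.getLogger(__name__)

STAGES = ("simulate", "surprise", "map", "erp", "stopping", "ic")

TARGET_PAIRS = [("stop_p3", "cmo_aud_p3"), ("stop_p3", "cmo_vis_p3")]
N1_PAIR = [("sst_go_n1", "cmo_target_n1")]
CONTROL_PAIRS = [
    ("stop_p3", "sst_go_n1"),
    ("stop_p3", "cmo_target_n1"),
    ("stop_p3", "cmo_std_p3"),
]


@dataclass
class RunConfig:
    """Fully serializable run configuration (YAML round-trip)."""

    seed: int = 0
    n_subjects: int = 55
    generative_model: str = "separate"
    shared_gain_rho: float = 0.5
    b1_p3_per_surprise: float = 8.0
    n_blocks: int = 4
    trials_per_block: int = 60
    proportions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    sst_n_trials: int = 300
    p_stop: float = 1 / 3
    family_alpha_map: float = 0.01
    family_alpha_behavior: float = 0.05
    bootstrap_n_iter: int = 5000
    selection_window_ms: tuple[float, float] = (200.0, 300.0)
    include_standards_variant: bool = True
    truth_overrides: dict = field(default_factory=dict)
    out_dir: str | None = None

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("proportions", "selection_window_ms"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sig_cells(statmap, channels=FRONTOCENTRAL, centers=(300.0, 350.0), sign=1):
    """Significant channel x window cells of a map restricted to a scalp
    region and window set, with the required beta sign."""
    ci = channel_index(statmap.channel_labels, channels)
    wi = [statmap.centers_ms.index(c) for c in centers]
    cells = []
    for i, ch in zip(ci, channels):
        for j, c in zip(wi, centers):
            if statmap.sig_mask[i, j] and np.sign(statmap.mean_beta[i, j]) == sign:
                cells.append([ch, c])
    return cells


def _statmap_summary(statmap) -> dict:
    return {
        "contrast": statmap.contrast,
        "adjusted_alpha": statmap.adjusted_alpha,
        "n_significant": int(np.nansum(statmap.sig_mask)),
        "frontocentral_300_350_positive": _sig_cells(statmap),
        "mean_beta_fcz_300": float(
            statmap.mean_beta[
                channel_index(statmap.channel_labels, ["FCz"])[0],
                statmap.centers_ms.index(300.0),
            ]
        ),
    }


def run_pipeline(config: RunConfig, stages=STAGES, write_outputs: bool = True) -> dict:
    """Execute the pipeline stages in order and return the report bundle.

    The bundle's ``summary`` entry is a JSON-serializable dict of every
    cohort-level statistic; per-module artifacts are written under
    ``config.out_dir`` when `write_outputs` and an output directory is
    configured.
    """
    stages = tuple(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    t0 = time.time()
    out_dir = Path(config.out_dir) if (config.out_dir and write_outputs) else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out_dir / "config.yaml")

    summary: dict = {"config": dataclasses.asdict(config), "stage_seconds": {}}
    bundle: dict = {"summary": summary}

    # ---- simulate -------------------------------------------------------
    truth = syn_mod.make_ground_truth(
        config.n_subjects,
        generative_model=config.generative_model,
        seed=config.seed,
        shared_gain_rho=config.shared_gain_rho,
        b1_p3_per_surprise=config.b1_p3_per_surprise,
        **config.truth_overrides,
    )
    cmo_seqs, sst_seqs = syn_mod.cohort_sequences(
        truth,
        n_blocks=config.n_blocks,
        trials_per_block=config.trials_per_block,
        sst_n_trials=config.sst_n_trials,
    )
    bundle["truth"] = truth
    bundle["cmo_sequences"] = cmo_seqs
    bundle["sst_sequences"] = sst_seqs
    summary["simulate"] = {
        "n_subjects": config.n_subjects,
        "cue_counts": pd.Series(
            [t.cue_type for t in cmo_seqs[0]]
        ).value_counts().to_dict(),
        "mean_stop_success": float(
            np.mean([syn_mod.stop_success_rate(s) for s in sst_seqs])
        ),
    }
    if out_dir:
        io_mod.write_json(truth.to_json_dict(), out_dir / "ground_truth.json")
        for s in range(config.n_subjects):
            io_mod.write_trials_tsv(cmo_seqs[s], out_dir / f"sub-{s+1:02d}_cmo.tsv")
            io_mod.write_trials_tsv(sst_seqs[s], out_dir / f"sub-{s+1:02d}_sst.tsv")
    summary["stage_seconds"]["simulate"] = round(time.time() - t0, 2)
    if set(stages) <= {"simulate"}:
        return bundle

    # ---- surprise -------------------------------------------------------
    t1 = time.time()
    series = {
        model: [
            sur_mod.compute_surprise(seq, model=model, subject_id=f"sub-{s+1:02d}")
            for s, seq in enumerate(cmo_seqs)
        ]
        for model in ("separate", "common")
    }
    bundle["series"] = series
    summary["surprise"] = {
        "mean_surprise": {
            m: float(np.mean([ser["surprise"].mean() for ser in series[m]]))
            for m in series
        }
    }
    if out_dir:
        pd.concat(series["separate"]).to_csv(
            out_dir / "surprise_separate.tsv", sep="\t", index=False
        )
        pd.concat(series["common"]).to_csv(
            out_dir / "surprise_common.tsv", sep="\t", index=False
        )
    summary["stage_seconds"]["surprise"] = round(time.time() - t1, 2)

    need_epochs = {"map", "erp", "stopping", "ic"} & set(stages)
    if not need_epochs:
        return bundle

    # ---- per-subject epoch pass (streamed to keep memory flat) ---------
    t2 = time.time()
    spec = map_mod.WindowSpec()
    betas = {m: [] for m in ("separate", "common")}
    betas_std = {m: [] for m in ("separate", "common")}
    rt_betas = {m: {"all": [], "first_half": []} for m in ("separate", "common")}
    panel_rows = []
    onsets: list[dict] = []
    variant_betas: dict[str, list] = {}
    selection_reports = []
    stop_summaries = []
    decomp = None

    for s in range(config.n_subjects):
        eps = syn_mod.gen_subject_epochs(truth, s, cmo_seqs[s], sst_seqs[s])
        cmo = eps["cmo"]
        unexpected = np.asarray(cmo.events["cue_type"] != "standard")
        cmo_unexp = cmo.select_trials(unexpected)
        sid = cmo.subject_id

        if "map" in stages:
            w_unexp = map_mod.window_average(cmo_unexp, spec)
            for model in ("separate", "common"):
                ser = series[model][s]
                betas[model].append(
                    map_mod.fit_surprise_map(
                        w_unexp, ser, sid, cmo.channel_labels, spec.centers_ms
                    )
                )
                rts = np.array(
                    [
                        t.rt_ms if t.rt_ms is not None else np.nan
                        for t in cmo_seqs[s]
                        if t.cue_type != "standard"
                    ]
                )
                blocks = np.array(
                    [t.block for t in cmo_seqs[s] if t.cue_type != "standard"]
                )
                for subset in ("all", "first_half"):
                    rt_betas[model][subset].append(
                        map_mod.fit_rt_surprise(ser, rts, blocks, subset)
                    )
                if config.include_standards_variant:
                    ser_std = sur_mod.compute_surprise(
                        cmo_seqs[s], model=model, include_standards=True
                    )
                    w_all = map_mod.window_average(cmo, spec)
                    betas_std[model].append(
                        map_mod.fit_surprise_map(
                            w_all, ser_std, sid, cmo.channel_labels, spec.centers_ms
                        )
                    )

        if "erp" in stages or "stopping" in stages or "ic" in stages:
            stop_summaries.append(
                stop_mod.summarize_stop_behavior(sst_seqs[s], subject_id=sid)
            )

        if "erp" in stages:
            t_ms = cmo.times_ms
            labels = cmo.channel_labels

            def peak(ep, mask, comp):
                return erp_mod.peak_amplitude(
                    erp_mod.condition_erp(ep, mask), t_ms, labels, comp
                ).amplitude_uv

            ev = cmo.events
            succ = np.asarray(eps["sst_stop"].events["outcome"] == "stop_success")
            panel_rows.append(
                {
                    "subject_id": sid,
                    "stop_p3": peak(eps["sst_stop"], succ, "P3"),
                    "cmo_aud_p3": peak(
                        cmo, np.asarray(ev["cue_type"] == "unexpected_auditory"), "P3"
                    ),
                    "cmo_vis_p3": peak(
                        cmo, np.asarray(ev["cue_type"] == "unexpected_visual"), "P3"
                    ),
                    "cmo_std_p3": peak(
                        cmo, np.asarray(ev["cue_type"] == "standard"), "P3"
                    ),
                    "sst_go_n1": peak(eps["sst_go"], None, "N1"),
                    "cmo_target_n1": peak(eps["cmo_target"], None, "N1"),
                    "ssrt_ms": stop_summaries[-1].ssrt_ms,
                }
            )

        if "ic" in stages:
            decomp = comp_mod.decomposition_from_truth(truth, s)
            try:
                report = comp_mod.select_stop_p3_ic(
                    decomp,
                    eps["sst_stop"],
                    eps["sst_go"],
                    window_ms=config.selection_window_ms,
                )
            except comp_mod.SelectionFailure:
                log.warning("%s: stop-P3 component selection failed", sid)
                selection_reports.append({"selected": None})
                if "stopping" in stages:
                    onsets.append({"stop_success": None, "stop_fail": None})
                continue
            selection_reports.append(report)
            selected = report["selected"]
            variants = comp_mod.reconstruct_variants(
                decomp, cmo_unexp, selected, seed=np.random.SeedSequence(
                    [config.seed, s, 7]
                ).generate_state(1)[0]
            )
            for name, ep in variants.items():
                w = map_mod.window_average(ep, spec)
                variant_betas.setdefault(name, []).append(
                    map_mod.fit_surprise_map(
                        w,
                        series["separate"][s],
                        sid,
                        cmo.channel_labels,
                        spec.centers_ms,
                    )
                )
            if "stopping" in stages:
                sel_stop = comp_mod.backproject(decomp, eps["sst_stop"], [selected])
                sel_go = comp_mod.backproject(decomp, eps["sst_go"], [selected])
                succ = np.asarray(sel_stop.events["outcome"] == "stop_success")
                onsets.append(
                    {
                        cond: stop_mod.p3_onset(
                            sel_stop, sel_go, sid, cond, stop_mask=(succ if cond == "stop_success" else ~succ)
                        ).onset_ms
                        for cond in ("stop_success", "stop_fail")
                    }
                )
        elif "stopping" in stages:
            eps_stop = eps["sst_stop"]
            succ = np.asarray(eps_stop.events["outcome"] == "stop_success")
            onsets.append(
                {
                    cond: stop_mod.p3_onset(
                        eps_stop, eps["sst_go"], sid, cond,
                        stop_mask=(succ if cond == "stop_success" else ~succ),
                    ).onset_ms
                    for cond in ("stop_success", "stop_fail")
                }
            )
    summary["stage_seconds"]["per_subject_pass"] = round(time.time() - t2, 2)

    # ---- group-level reductions ----------------------------------------
    if "map" in stages:
        t3 = time.time()
        maps = map_mod.group_and_compare(
            betas["separate"], betas["common"], config.family_alpha_map
        )
        bundle["group_maps"] = maps
        summary["map"] = {name: _statmap_summary(m) for name, m in maps.items()}
        summary["map"]["n_tests_per_set"] = int(maps["model1_vs_model2"].p.size)
        summary["rt_regression"] = {
            m: {
                subset: map_mod.group_rt_test(np.array(v))
                for subset, v in rt_betas[m].items()
            }
            for m in rt_betas
        }
        if config.include_standards_variant:
            fcz = channel_index(betas["separate"][0].channel_labels, FRONTOCENTRAL)
            w300 = [spec.centers_ms.index(c) for c in (300.0, 350.0)]

            def fc_mean(maps_list):
                b = np.stack([m.beta for m in maps_list])
                return float(np.nanmean(b[:, fcz][:, :, w300]))

            summary["include_standards"] = {
                m: {
                    "fc_mean_beta_default": fc_mean(betas[m]),
                    "fc_mean_beta_with_standards": fc_mean(betas_std[m]),
                }
                for m in ("separate", "common")
            }
        if out_dir:
            for name, m in maps.items():
                io_mod.write_statmap_csv(
                    m, out_dir / f"group_{name.replace(':', '_')}.csv"
                )
        summary["stage_seconds"]["map_group"] = round(time.time() - t3, 2)

    if "erp" in stages:
        t4 = time.time()
        panel = pd.DataFrame(panel_rows)
        bundle["panel"] = panel
        try:
            corr = erp_mod.corr_panel(
                panel,
                TARGET_PAIRS + N1_PAIR,
                CONTROL_PAIRS,
                n_iter=config.bootstrap_n_iter,
                seed=int(np.random.SeedSequence([config.seed, 5]).generate_state(1)[0]),
            )
            partials = {
                f"{crit}": erp_mod.partial_regression(
                    panel, crit, "stop_p3",
                    ["sst_go_n1", "cmo_target_n1", "cmo_std_p3"],
                )
                for crit in ("cmo_aud_p3", "cmo_vis_p3")
            }
            summary["erp"] = {"correlations": corr, "partial_regressions": partials}
        except ValueError as exc:
            log.warning("correlation stage skipped: %s", exc)
            summary["erp"] = {"warning": str(exc)}
        if out_dir:
            panel.to_csv(out_dir / "subject_panel.csv", index=False)
        summary["stage_seconds"]["erp_group"] = round(time.time() - t4, 2)

    if "stopping" in stages:
        summary["stopping"] = {
            "mean_go_rt_ms": float(np.mean([b.go_rt_ms for b in stop_summaries])),
            "mean_failed_stop_rt_ms": float(
                np.mean([b.failed_stop_rt_ms for b in stop_summaries])
            ),
            "mean_ssrt_ms": float(np.mean([b.ssrt_ms for b in stop_summaries])),
            "mean_p_respond_given_stop": float(
                np.mean([b.p_respond_given_stop for b in stop_summaries])
            ),
        }
        if onsets:
            try:
                summary["stopping"]["onset_validation"] = stop_mod.validate_stop_component(
                    onsets, np.array([b.ssrt_ms for b in stop_summaries])
                )
            except ValueError as exc:
                log.warning("onset validation skipped: %s", exc)
                summary["stopping"]["onset_validation"] = {"warning": str(exc)}
        if out_dir:
            pd.DataFrame([vars(b) for b in stop_summaries]).to_csv(
                out_dir / "stop_behavior.csv", index=False
            )

    if "ic" in stages and variant_betas:
        t5 = time.time()
        refits = comp_mod.group_variant_betas(variant_betas, config.family_alpha_map)
        bundle["refits"] = refits
        summary["ic"] = {
            "n_selected": sum(r.get("selected") is not None for r in selection_reports),
            "selected_ids": [r.get("selected") for r in selection_reports],
            "refits": {name: _statmap_summary(m) for name, m in refits.items()},
        }
        if out_dir:
            for name, m in refits.items():
                io_mod.write_statmap_csv(m, out_dir / f"refit_{name}.csv")
        summary["stage_seconds"]["ic_group"] = round(time.time() - t5, 2)

    summary["stage_seconds"]["total"] = round(time.time() - t0, 2)
    if out_dir:
        io_mod.write_json(summary, out_dir / "summary.json")
    return bundle
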