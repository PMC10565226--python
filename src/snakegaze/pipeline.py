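"""End-to-end orchestration: simulate -> process -> curate -> fit.

Each stage reads only the previous stage's CSV files, so a run can be resumed
from any intermediate product.  All randomness flows from the single seed in
the configuration; a repeated run writes byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import curation, events, lmm
from .design import ScreenGeometry, make_aoi_set
from .simulate import AttentionParams, StudyConfig, simulate_study

log = logging.getLogger("snakegaze")

__all__ = ["RunConfig", "run_simulate", "run_process", "run_curate",
           "run_fit", "run_all"]


@dataclass
class RunConfig:
    data_dir: Path = Path("data")
    out_dir: Path = Path("out")
    seed: int = 0
    screen: ScreenGeometry = field(default_factory=ScreenGeometry)
    radius_px: float = 23.0
    min_run: int = 2
    sample_rate_hz: float = 30.0
    qc_threshold_ms: float = 2000.0
    alpha: float = 0.05
    responses: tuple[str, ...] = ("diff_fix", "diff_dwell_ms")
    simulate_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw: dict = {}
        paths = raw.get("paths", {})
        if "data_dir" in paths:
            kw["data_dir"] = Path(paths["data_dir"])
        if "out_dir" in paths:
            kw["out_dir"] = Path(paths["out_dir"])
        screen = raw.get("screen", {})
        if screen:
            kw["screen"] = ScreenGeometry(
                width_px=int(screen.get("width_px", 1366)),
                height_px=int(screen.get("height_px", 768)),
                viewing_distance_cm=float(screen.get("distance_cm", 60.0)),
                dispersion_radius_px=float(
                    screen.get("dispersion_radius_px", 23.0)
                ),
            )
        proc = raw.get("process", {})
        for k_yaml, k_cfg in (("radius_px", "radius_px"), ("min_run", "min_run"),
                              ("sample_rate_hz", "sample_rate_hz")):
            if k_yaml in proc:
                kw[k_cfg] = proc[k_yaml]
        cur = raw.get("curate", {})
        if "qc_threshold_ms" in cur:
            kw["qc_threshold_ms"] = float(cur["qc_threshold_ms"])
        model = raw.get("model", {})
        if "alpha" in model:
            kw["alpha"] = float(model["alpha"])
        if "responses" in model:
            kw["responses"] = tuple(model["responses"])
        sim = dict(raw.get("simulate", {}))
        if "seed" in sim:
            kw["seed"] = int(sim.pop("seed"))
        kw["simulate_overrides"] = sim
        return cls(**kw)

    def study_config(self) -> StudyConfig:
        ov = dict(self.simulate_overrides)
        kw: dict = {"screen": self.screen, "sample_rate_hz": self.sample_rate_hz}
        if "n_by_group" in ov:
            kw["n_by_group"] = {
                nat: {g: int(n) for g, n in gr.items()}
                for nat, gr in ov.pop("n_by_group").items()
            }
        if "catalogue" in ov:
            kw["catalogue"] = tuple(map(tuple, ov.pop("catalogue")))
            kw["allow_nonstandard_counts"] = True
        param_overrides = {
            k: ov.pop(k)
            for k in list(ov)
            if k in {f.name for f in dataclasses.fields(AttentionParams)}
        }
        cfg = StudyConfig(**kw)
        if param_overrides:
            cfg = dataclasses.replace(
                cfg,
                params_by_nationality={
                    nat: dataclasses.replace(p, **param_overrides)
                    for nat, p in cfg.params_by_nationality.items()
                },
            )
        if ov:
            raise ValueError(f"unknown simulate config keys: {sorted(ov)}")
        return cfg


def run_simulate(cfg: RunConfig) -> None:
    study = cfg.study_config()
    cfg.data_dir.mkdir(parents=True, exist_ok=True)
    participants, trials, samples = simulate_study(
        study, seed=cfg.seed, out_dir=cfg.data_dir
    )
    log.info(
        "simulate: seed=%d participants=%d trials=%d samples=%d -> %s",
        cfg.seed, len(participants), len(trials), len(samples), cfg.data_dir,
    )


def run_process(cfg: RunConfig) -> None:
    samples = pd.read_csv(cfg.data_dir / "samples.csv")
    aois = make_aoi_set(cfg.screen)
    fixations, metrics = events.process_trials(
        samples, aois, radius_px=cfg.radius_px, min_run=cfg.min_run,
        sample_rate_hz=cfg.sample_rate_hz,
    )
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    fixations.to_csv(cfg.out_dir / "fixations.csv", index=False)
    metrics.to_csv(cfg.out_dir / "trial_metrics.csv", index=False)
    log.info(
        "process: trials=%d fixations=%d radius=%g min_run=%d",
        len(metrics), len(fixations), cfg.radius_px, cfg.min_run,
    )


def run_curate(cfg: RunConfig) -> curation.CurationSummary:
    metrics = pd.read_csv(cfg.out_dir / "trial_metrics.csv")
    trials = pd.read_csv(cfg.data_dir / "trials.csv")
    participants = pd.read_csv(cfg.data_dir / "participants.csv")
    stimuli = pd.read_csv(cfg.data_dir / "stimuli.csv")
    observations, excluded, summary = curation.curate(
        metrics, trials, participants, stimuli,
        min_combined_dwell_ms=cfg.qc_threshold_ms,
    )
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    observations.to_csv(cfg.out_dir / "observations.csv", index=False)
    excluded[["trial_id", "combined_lr_dwell_ms", "reason"]].to_csv(
        cfg.out_dir / "exclusions.csv", index=False
    )
    (cfg.out_dir / "curation_summary.json").write_text(
        json.dumps(dataclasses.asdict(summary), indent=2) + "\n"
    )
    log.info(
        "curate: total=%d excluded=%d (%.2f%%) retained=%d observations=%d",
        summary.n_trials_total, summary.n_excluded, summary.excluded_percent,
        summary.n_retained, summary.n_observations,
    )
    return summary


_REPORT_COLS = ["level", "estimate", "ci_lo", "ci_hi", "df", "t", "p"]


def _emm_report(emm: pd.DataFrame, level_cols: list[str]) -> pd.DataFrame:
    out = emm.copy()
    out["level"] = out[level_cols].agg(" / ".join, axis=1)
    return out[_REPORT_COLS]


def run_fit(cfg: RunConfig) -> dict[str, lmm.ReductionResult]:
    observations = pd.read_csv(cfg.out_dir / "observations.csv")
    results: dict[str, lmm.ReductionResult] = {}
    for response in cfg.responses:
        red = lmm.backward_reduce(
            observations, response=response, alpha=cfg.alpha
        )
        results[response] = red
        tag = response
        red.trace.to_csv(cfg.out_dir / f"elimination_{tag}.csv", index=False)
        fit = red.final
        from scipy import stats as _st

        bse = fit.bse
        coef_rows = []
        for term, idx in fit.model.design.term_slices.items():
            dfd = fit.denominator_df(term)
            for i in idx:
                est = float(fit.params.iloc[i])
                se = float(bse.iloc[i])
                tval = est / se if se > 0 else float("inf")
                coef_rows.append(
                    {
                        "term": fit.model.design.columns[i],
                        "estimate": est,
                        "se": se,
                        "df": dfd,
                        "t": tval,
                        "p": float(2 * _st.t.sf(abs(tval), dfd)),
                    }
                )
        pd.DataFrame(coef_rows).to_csv(
            cfg.out_dir / f"fit_summary_{tag}.csv", index=False
        )
        (cfg.out_dir / f"model_summary_{tag}.txt").write_text(
            fit.summary() + "\n"
        )

        terms = fit.terms
        if "morphotype:nationality" in terms:
            by = ["morphotype", "nationality"]
        elif "morphotype" in terms:
            by = ["morphotype"]
        else:
            by = []
        if by:
            emm = fit.emmeans(by)
            _emm_report(emm, by).to_csv(
                cfg.out_dir / f"emmeans_{tag}.csv", index=False
            )
        if "nationality" in terms:
            con = fit.contrasts(
                "nationality", by=["morphotype"] if "morphotype" in terms else []
            )
            con.to_csv(cfg.out_dir / f"contrasts_{tag}.csv", index=False)
        log.info(
            "fit[%s]: final terms=%s  LRT full-vs-final stat=%.3f df=%d p=%.3f "
            "AIC full=%.2f final=%.2f",
            response, list(terms), red.lrt_stat, red.lrt_df, red.lrt_p,
            red.aic_full, red.aic_final,
        )
    return results


def run_all(cfg: RunConfig) -> dict[str, lmm.ReductionResult]:
    run_simulate(cfg)
    run_process(cfg)
    run_curate(cfg)
    return run_fit(cfg)
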