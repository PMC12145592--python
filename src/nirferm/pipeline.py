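"""End-to-end pipeline: config loading, stage orchestration, artifact output.

A run executes: simulate (or load CSVs) -> contamination filter -> preprocess
(optionally selecting the SG window by cross-validated performance) -> split
-> PLS fit with LOO component tuning -> metrics.  Every artifact embeds the
seed and a hash of the resolved configuration, and a second invocation with
the same config and seed reproduces all numeric outputs byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

from . import synthetic
from .errors import ConfigError, NirfermError, StageError
from .evaluation import (
    MetricsReport,
    TimeCoursePrediction,
    evaluate_model,
    predict_timecourse,
    spectral_noise_analysis,
)
from .pls import PLSModel, fit_pls_with_cv, load_model, save_model
from .preprocess import (
    PreprocessConfig,
    default_preprocess_config,
    run_preprocess,
    select_sg_window,
)
from .spectra import (
    CONSTITUENTS,
    ConcentrationTable,
    SpectraSet,
    join_dataset,
    read_concentration_table,
    read_spectra_table,
    write_concentration_table,
    write_spectra_table,
)
from .splits import SplitResult, SplitSpec, filter_contaminated, make_splits

log = logging.getLogger("nirferm")

_ODD_WINDOWS = tuple(range(3, 22, 2))


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PreprocessSettings(_Strict):
    pre_truncation: Optional[tuple[float, float]] = None   # None -> profile default
    removed_regions: Optional[list[tuple[float, float]]] = None
    snv: bool = True
    sg_window: int | Literal["auto"] = 11
    sg_candidates: list[int] = list(_ODD_WINDOWS)
    sg_polyorder: int = 2
    sg_deriv: int = 1
    post_truncation: Optional[tuple[float, float]] = None

    @field_validator("sg_window")
    @classmethod
    def _odd_window(cls, v):
        if v != "auto" and (v % 2 == 0 or not 3 <= v <= 21):
            raise ValueError(f"sg_window must be odd and in [3, 21], got {v}")
        return v

    @field_validator("sg_candidates")
    @classmethod
    def _odd_candidates(cls, v):
        bad = [w for w in v if w % 2 == 0 or not 3 <= w <= 21]
        if bad:
            raise ValueError(f"sg_candidates must be odd integers in [3, 21]; bad: {bad}")
        return v


class SplitSettings(_Strict):
    unique_experiment_id: str = "auto"
    validation_fraction: Optional[float] = None   # None -> 0.40 lab at-line, 0.25 otherwise
    pca_variance_threshold: float = 0.95

    @field_validator("validation_fraction")
    @classmethod
    def _frac(cls, v):
        if v is not None and not 0 < v < 1:
            raise ValueError("validation_fraction must be in (0, 1)")
        return v


class PLSSettings(_Strict):
    max_components: int = 20
    pls2: bool = True

    @field_validator("max_components")
    @classmethod
    def _pos(cls, v):
        if v < 1:
            raise ValueError("max_components must be >= 1")
        return v


class EvaluationSettings(_Strict):
    noise_lo: float = 4300.0
    noise_hi: float = 4480.0
    noise_channels: int = 10
    contamination_threshold: float = 2.5


class CampaignSettings(_Strict):
    n_experiments: int = 10
    samples_per_experiment: int = 8
    contamination_prob: float = 0.1
    contaminant_magnitude: float = 5.0
    reference_base_sd: float = 0.5


class FeasibilitySettings(_Strict):
    n: int = 40
    c_max: float = 60.0
    max_abs_corr: float = 0.3
    reference_base_sd: float = 0.5


class PipelineConfig(_Strict):
    """Fully validated pipeline configuration with study-protocol defaults."""

    mode: Literal["campaign", "feasibility"] = "campaign"
    profile: str = "lab_at_line"
    seed: int = 0
    output_dir: str = "outputs"
    spectra_csv: Optional[str] = None
    concentrations_csv: Optional[str] = None
    preprocess: PreprocessSettings = PreprocessSettings()
    split: SplitSettings = SplitSettings()
    pls: PLSSettings = PLSSettings()
    evaluation: EvaluationSettings = EvaluationSettings()
    campaign: CampaignSettings = CampaignSettings()
    feasibility: FeasibilitySettings = FeasibilitySettings()

    def effective_validation_fraction(self) -> float:
        if self.split.validation_fraction is not None:
            return self.split.validation_fraction
        return 0.40 if self.profile == "lab_at_line" else 0.25

    def resolve_preprocess(self, sg_window: int | None = None) -> PreprocessConfig:
        """Merge user settings with per-profile defaults into a PreprocessConfig."""
        base = default_preprocess_config(self.profile)
        pp = self.preprocess
        window = sg_window if sg_window is not None else (
            pp.sg_window if pp.sg_window != "auto" else 11)
        return PreprocessConfig(
            pre_truncation=pp.pre_truncation if pp.pre_truncation is not None else base.pre_truncation,
            removed_regions=tuple(tuple(r) for r in pp.removed_regions)
            if pp.removed_regions is not None else base.removed_regions,
            snv=pp.snv,
            sg_window=window,
            sg_polyorder=pp.sg_polyorder,
            sg_deriv=pp.sg_deriv,
            post_truncation=pp.post_truncation,
        )

    def config_hash(self) -> str:
        """Hash of the result-determining settings (where outputs land is not one)."""
        data = self.model_dump(mode="json")
        data.pop("output_dir", None)
        blob = json.dumps(data, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML/JSON config; unknown keys are rejected and all
    validation failures are reported together."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    try:
        return PipelineConfig(**raw)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


@dataclass
class PipelineResult:
    config: PipelineConfig
    model: PLSModel
    metrics: MetricsReport
    split: SplitResult | None
    artifacts: dict[str, Path]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except NirfermError as exc:
                if isinstance(exc, StageError):
                    raise
                raise StageError(name, str(exc)) from exc
            except FileNotFoundError as exc:
                raise StageError(name, str(exc)) from exc
        return wrapped
    return deco


@_stage("load")
def _acquire_data(cfg: PipelineConfig) -> tuple[SpectraSet, ConcentrationTable, ConcentrationTable | None]:
    """Return (spectra, measured concentrations, true concentrations or None)."""
    if cfg.spectra_csv is not None:
        if cfg.concentrations_csv is None:
            raise ConfigError("spectra_csv given without concentrations_csv")
        log.info("loading spectra from %s", cfg.spectra_csv)
        spectra = read_spectra_table(cfg.spectra_csv)
        conc = read_concentration_table(cfg.concentrations_csv)
        return spectra, conc, None
    master = np.random.SeedSequence(cfg.seed)
    if cfg.mode == "feasibility":
        log.info("simulating feasibility design (n=%d)", cfg.feasibility.n)
        s_design, s_render, s_ref = master.spawn(3)
        true = synthetic.simulate_feasibility_design(
            n=cfg.feasibility.n, c_max=cfg.feasibility.c_max,
            seed=np.random.default_rng(s_design),
            max_abs_corr=cfg.feasibility.max_abs_corr,
        )
        prof = synthetic.get_profile(cfg.profile)
        spectra = synthetic.render_spectra(
            true, synthetic.build_default_library(), prof,
            seed=np.random.default_rng(s_render))
        measured = synthetic.simulate_reference_measurement(
            true, cfg.feasibility.reference_base_sd, seed=np.random.default_rng(s_ref))
        return spectra, measured, true
    log.info("simulating campaign (%d experiments x %d samples)",
             cfg.campaign.n_experiments, cfg.campaign.samples_per_experiment)
    camp = synthetic.simulate_campaign(synthetic.CampaignConfig(
        n_experiments=cfg.campaign.n_experiments,
        samples_per_experiment=cfg.campaign.samples_per_experiment,
        profile=cfg.profile,
        seed=cfg.seed,
        contamination_prob=cfg.campaign.contamination_prob,
        contaminant_magnitude=cfg.campaign.contaminant_magnitude,
        reference_base_sd=cfg.campaign.reference_base_sd,
    ))
    return camp.spectra, camp.measured_conc, camp.true_conc


def run_pipeline(cfg: PipelineConfig, output_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full workflow and write the artifact bundle.

    Campaign mode produces the three-way split and all four RMSE families;
    feasibility mode (the n=40 uncorrelated-mixtures design) trains on all
    samples and reports cross-validated performance only, matching how the
    feasibility experiment was analyzed.
    """
    out = Path(output_dir if output_dir is not None else cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": cfg.seed, "config_hash": cfg.config_hash()}
    artifacts: dict[str, Path] = {}

    def write_json(name: str, payload: dict):
        path = out / name
        path.write_text(json.dumps({**stamp, **payload}, sort_keys=True, indent=1))
        artifacts[name] = path

    spectra, measured, true = _acquire_data(cfg)
    write_spectra_table(spectra, out / "spectra.csv")
    write_concentration_table(measured, out / "concentrations_measured.csv")
    artifacts["spectra.csv"] = out / "spectra.csv"
    artifacts["concentrations_measured.csv"] = out / "concentrations_measured.csv"
    if true is not None:
        write_concentration_table(true, out / "concentrations_true.csv")
        artifacts["concentrations_true.csv"] = out / "concentrations_true.csv"

    # --- filter ---
    @_stage("filter")
    def do_filter():
        joined = join_dataset(spectra, measured)
        fres = filter_contaminated(joined.conc, cfg.evaluation.contamination_threshold)
        keep = [i for i, sid in enumerate(joined.spectra.sample_ids)
                if sid in set(fres.kept_ids)]
        log.info("contamination filter: kept %d, excluded %d", len(fres.kept_ids),
                 len(fres.excluded_ids))
        return joined.spectra.select_rows(np.asarray(keep)), joined.conc.subset(
            [joined.spectra.sample_ids[i] for i in keep]), fres
    f_spectra, f_conc, fres = do_filter()
    write_json("filter.json", {"kept": fres.kept_ids, "excluded": fres.excluded_ids,
                               "reasons": fres.reasons})

    # --- preprocess (with optional SG window selection) ---
    @_stage("preprocess")
    def do_preprocess():
        if cfg.preprocess.sg_window == "auto":
            base = cfg.resolve_preprocess(sg_window=cfg.preprocess.sg_candidates[0])
            chosen = select_sg_window(f_spectra, f_conc, base,
                                      cfg.preprocess.sg_candidates,
                                      a_max=min(10, cfg.pls.max_components))
            log.info("selected SG window %d by cross-validated performance", chosen)
        else:
            chosen = cfg.preprocess.sg_window
        pcfg = cfg.resolve_preprocess(sg_window=chosen)
        return run_preprocess(f_spectra, pcfg), pcfg
    pm, pcfg = do_preprocess()
    write_json("preprocess.json", {"config": pcfg.to_dict(), "provenance": pm.provenance,
                                   "n_channels": int(pm.matrix.shape[1])})

    y_all = f_conc.matrix(CONSTITUENTS)
    ids = pm.sample_ids
    id_index = {sid: i for i, sid in enumerate(ids)}

    # --- split ---
    split_result: SplitResult | None = None
    if cfg.mode == "campaign":
        @_stage("split")
        def do_split():
            return make_splits(pm, SplitSpec(
                unique_experiment_id=cfg.split.unique_experiment_id,
                validation_fraction=cfg.effective_validation_fraction(),
                pca_variance_threshold=cfg.split.pca_variance_threshold,
                seed=cfg.seed,
            ))
        split_result = do_split()
        write_json("splits.json", split_result.to_dict())
        cal_idx = [id_index[s] for s in split_result.calibration_ids]
        val_idx = [id_index[s] for s in split_result.validation_ids]
        unq_idx = [id_index[s] for s in split_result.unique_ids]
    else:
        cal_idx, val_idx, unq_idx = list(range(len(ids))), [], []

    # --- train ---
    @_stage("train")
    def do_train():
        a_max = min(cfg.pls.max_components, len(cal_idx) - 2, pm.matrix.shape[1])
        return fit_pls_with_cv(
            pm.matrix[cal_idx], y_all[cal_idx], a_max=a_max,
            response_names=list(CONSTITUENTS), pls2=cfg.pls.pls2,
            provenance={**stamp, "preprocess": pcfg.to_dict(),
                        "split": "calibration" if split_result else "all",
                        "n_calibration": len(cal_idx)},
        )
    model, cv = do_train()
    save_model(model, out / "model.json")
    artifacts["model.json"] = out / "model.json"
    cv_df = pd.DataFrame(cv.rmsecv, index=CONSTITUENTS, columns=cv.a_values)
    cv_df.index.name = "constituent"
    cv_df.to_csv(out / "cv.csv", float_format="%.10g")
    artifacts["cv.csv"] = out / "cv.csv"

    # --- evaluate ---
    @_stage("evaluate")
    def do_evaluate():
        return evaluate_model(
            model,
            calibration=(pm.matrix[cal_idx], y_all[cal_idx]),
            validation=(pm.matrix[val_idx], y_all[val_idx]) if val_idx else None,
            unique=(pm.matrix[unq_idx], y_all[unq_idx]) if unq_idx else None,
            cv=cv,
        )
    metrics = do_evaluate()
    metrics.table.to_csv(out / "metrics.csv", float_format="%.10g")
    artifacts["metrics.csv"] = out / "metrics.csv"
    write_json("metrics.json", metrics.to_json_dict())
    for name, df in metrics.plot_data.items():
        path = out / f"plot_{name}.csv"
        df.to_csv(path, index=False, float_format="%.10g")
        artifacts[path.name] = path
    return PipelineResult(config=cfg, model=model, metrics=metrics,
                          split=split_result, artifacts=artifacts)


def run_monitor(
    cfg: PipelineConfig,
    model_path: str | Path,
    stream_path: str | Path,
    measured_path: str | Path | None = None,
    output_dir: str | Path | None = None,
) -> TimeCoursePrediction:
    """Apply a trained model to an on-line spectra stream and write predictions."""
    out = Path(output_dir if output_dir is not None else cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    @_stage("monitor")
    def go():
        model = load_model(model_path)
        pcfg = PreprocessConfig.from_dict(model.provenance["preprocess"])
        stream = read_spectra_table(stream_path)
        measured = read_concentration_table(measured_path) if measured_path else None
        return predict_timecourse(model, pcfg, stream, measured)
    tc = go()
    tc.predictions.to_csv(out / "timecourse.csv", index=False, float_format="%.10g")
    if tc.residuals is not None:
        tc.residuals.to_csv(out / "timecourse_residuals.csv", index=False,
                            float_format="%.10g")
    return tc
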