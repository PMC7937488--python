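"""End-to-end orchestration: simulate/load -> denoise -> window -> features
-> PCA -> classify -> evaluate.

``run_pipeline`` executes every stage in order, optionally writing all
intermediate artifacts (recording CSV + sidecar, feature CSV, PCA JSON,
evaluation reports) to an output directory.  A run is fully reproducible
from (config, seed): every random stage derives its seed from the root
seed in the config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from . import classifiers as clf
from .abc_opt import ABCConfig, optimize_svm
from .config import ConfigError, PipelineConfig, derive_seed
from .dimred import fit_pca, select_components, transform
from .evaluation import EvaluationReport, improvement, per_phase_rates, split
from .features import FeatureMatrix, FuEnParams, extract_features
from .preprocessing import denoise_recording, sliding_windows
from .synthetic import (GaitCycleSpec, Recording, default_muscle_profiles,
                        generate_recording, well_separated_profiles)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    reports: dict[str, EvaluationReport]
    features: FeatureMatrix
    reduced_features: FeatureMatrix | None
    n_components: int | None
    best_C: float | None = None
    best_g: float | None = None
    abc_history: list[float] = field(default_factory=list)

    @property
    def improvement(self) -> float | None:
        if {"svm", "abc_svm"} <= self.reports.keys():
            return improvement(self.reports["abc_svm"].overall,
                               self.reports["svm"].overall)
        return None


def _stage(name: str):
    """Decorator-free stage wrapper: annotate failures with the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, ConfigError):
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def _build_recording(cfg: PipelineConfig) -> Recording:
    if cfg.input_csv:
        return Recording.from_csv(cfg.input_csv)
    sim = cfg.simulate
    spec = GaitCycleSpec(sim.cycle_duration, tuple(sim.phase_fractions),
                         sim.n_cycles)
    if sim.profiles == "well_separated":
        profiles = well_separated_profiles(gain=sim.separation_gain)
    elif sim.profiles == "default":
        profiles = default_muscle_profiles()
    else:
        raise ConfigError(f"unknown profile set: {sim.profiles!r}")
    return generate_recording(profiles, spec, fs=sim.fs, noise_sd=sim.noise_sd,
                              seed=derive_seed(cfg.seed, "simulate"))


def run_pipeline(config: PipelineConfig | None = None,
                 outdir: str | Path | None = None) -> PipelineResult:
    """Run the full recognition pipeline described by ``config``.

    Returns per-classifier evaluation reports on the held-out test split.
    When ``outdir`` is given, all intermediate artifacts are written
    there.
    """
    cfg = config or PipelineConfig()
    out = Path(outdir) if outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    with _stage("acquire"):
        recording = _build_recording(cfg)
    if out:
        recording.to_csv(out / "recording.csv",
                         params={"seed": cfg.seed, **vars(cfg.simulate)})

    with _stage("denoise"):
        den = cfg.denoise
        recording = denoise_recording(recording, den.method, den.wavelet,
                                      den.levels, den.persistence_min)

    with _stage("window"):
        windows = sliding_windows(recording, cfg.window.length_samples,
                                  cfg.window.step_samples)

    with _stage("features"):
        feat_cfg = cfg.features
        fuen = FuEnParams(n=feat_cfg.fuen_n, r=feat_cfg.fuen_r, p=feat_cfg.fuen_p)
        features = extract_features(
            windows, families=tuple(feat_cfg.families), zc_eps=feat_cfg.zc_eps,
            psd_method=feat_cfg.psd_method, wavelet=feat_cfg.wavelet,
            wavelet_levels=feat_cfg.wavelet_levels, fuen_params=fuen,
            var_subtract_mean=feat_cfg.var_subtract_mean,
        )
    if out:
        features.to_csv(out / "features.csv")

    with _stage("split"):
        train, test = split(features, cfg.split.train_fraction,
                            seed=derive_seed(cfg.seed, "split"))

    reduced = None
    n_components = None
    if cfg.pca.enabled:
        with _stage("pca"):
            model = fit_pca(train)
            n_components = select_components(model.contribution_rates,
                                             cfg.pca.threshold)
            train_r = transform(model, train, n_components)
            test_r = transform(model, test, n_components)
            reduced = transform(model, features, n_components)
        if out:
            model.to_json(out / "pca.json")
    else:
        train_r, test_r = train, test

    x_tr, y_tr = train_r.to_numpy(), train_r.labels
    x_te, y_te = test_r.to_numpy(), test_r.labels

    reports: dict[str, EvaluationReport] = {}
    result = PipelineResult(reports, features, reduced, n_components)
    meta = {"seed": cfg.seed, "families": list(cfg.features.families),
            "n_components": n_components}

    for name in cfg.classifiers:
        with _stage(f"classify:{name}"):
            if name == "svm":
                model = clf.train_svm(x_tr, y_tr, C=cfg.svm.C, g=cfg.svm.g)
                pred = clf.predict_svm(model, x_te)
            elif name == "abc_svm":
                abc_cfg = ABCConfig(
                    colony_size=cfg.abc.colony_size, max_cycle=cfg.abc.max_cycle,
                    limit=cfg.abc.limit,
                    bounds=((cfg.abc.lower_bound, cfg.abc.upper_bound),) * 2,
                    seed=derive_seed(cfg.seed, "abc"), mode="max",
                )
                c_best, g_best, model, history = optimize_svm(
                    x_tr, y_tr, abc_cfg, cv_folds=cfg.abc.cv_folds)
                result.best_C, result.best_g = c_best, g_best
                result.abc_history = history
                pred = clf.predict_svm(model, x_te)
            elif name == "lda":
                model = clf.train_lda(x_tr, y_tr)
                pred = clf.predict_lda(model, x_te)
            elif name == "elm":
                model = clf.train_elm(x_tr, y_tr, hidden_size=cfg.elm.hidden,
                                      seed=derive_seed(cfg.seed, "elm"))
                pred = clf.predict_elm(model, x_te)
            else:
                raise ConfigError(f"unknown classifier: {name!r}")
            reports[name] = per_phase_rates(
                y_te, pred, metadata={**meta, "classifier": name})
        if out:
            reports[name].to_json(out / f"report_{name}.json")
            clf.save_model(model, out / f"model_{name}.json")

    if out:
        summary = {name: rep.to_dict() for name, rep in reports.items()}
        if result.improvement is not None:
            summary["improvement_points"] = round(result.improvement, 4)
        if result.best_C is not None:
            summary["abc_best"] = {"C": result.best_C, "g": result.best_g}
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        frames = [rep.to_frame() for rep in reports.values()]
        if frames:
            import pandas as pd

            pd.concat(frames).to_csv(out / "report_table.csv",
                                     index_label="classifier")
    return result
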