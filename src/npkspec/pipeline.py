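"""End-to-end orchestration: simulate/load -> preprocess -> features +
wavelet + selection -> fit -> evaluate -> compare.

Every stage persists its output as delimited text in the run directory
so each step can be inspected or re-run in isolation; a stage failure
raises :class:`PipelineError` naming the stage, and a ``FAILED`` marker
is left next to whatever partial outputs exist.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as npk_io
from .evaluation import AHP_WEIGHTS, EvaluationReport, evaluate_model, relative_improvement
from .features import feature_table
from .models import FAMILIES, fit_nn, fit_pls, fit_univariate
from .preprocess import ReferenceSet, radiometric_correct, remove_outliers, split_modeling_validation
from .selection import correlation_table, select_sensitivity_coefficients
from .synthetic import NUTRIENTS, SimConfig, generate_dataset
from .wavelet import BASES, detail_bank

__all__ = ["RunConfig", "PipelineError", "PipelineResult", "run_pipeline", "compare_models"]

log = logging.getLogger("npkspec")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    # input: either simulate (default) or load from files
    sim: SimConfig = field(default_factory=SimConfig)
    spectra_path: str | None = None
    samples_path: str | None = None
    correction_mode: str | None = None  # applied only when WHITE/DARK rows exist
    # preprocessing
    outlier_method: str = "mahalanobis-pca"
    outlier_threshold: float = 0.999
    split_fraction: float = 2.0 / 3.0
    split_seed: int = 0
    stratify_split: bool = False
    # features / wavelet / selection
    extrema_mode: str = "reflectance"
    area_mode: str = "reflectance"
    bases: tuple[str, ...] = BASES
    levels: int = 5
    selection_k: int = 3
    selection_scope: str = "modeling"  # or "all"
    # models
    families: tuple[str, ...] = FAMILIES
    skip_infeasible: bool = True
    top_features: int = 3
    pls_components: int = 2
    nn_hidden: int = 10
    nn_seed: int = 0
    # output
    out_dir: str = "runs/npkspec-run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = dataclasses.asdict(self.sim)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("sim", {})
        cfg = cls(sim=SimConfig(**sim), **d)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class PipelineResult:
    run_dir: Path
    samples: pd.DataFrame
    features: pd.DataFrame
    reports: dict[str, list[EvaluationReport]]
    comparison: pd.DataFrame
    improvements: pd.DataFrame
    selected: dict[str, list]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                log.info("stage %s", name)
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(name, exc) from exc
        return wrapper
    return deco


@_stage("simulate/load")
def _load_inputs(config: RunConfig):
    if config.spectra_path is not None:
        spectra, refs = npk_io.read_spectra(config.spectra_path)
        samples = (
            npk_io.read_samples(config.samples_path)
            if config.samples_path else None
        )
        if config.correction_mode and refs:
            refset = ReferenceSet(white=refs["WHITE"], dark=refs["DARK"])
            spectra = pd.DataFrame(
                [radiometric_correct(spectra.loc[i], refset, config.correction_mode)
                 for i in spectra.index]
            )
        return spectra, samples
    ds = generate_dataset(config.sim)
    return ds.spectra, ds.samples


def run_pipeline(config: RunConfig | None = None) -> PipelineResult:
    """Execute the full diagnostic pipeline and persist all artifacts."""
    config = config if config is not None else RunConfig()
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(run_dir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, run_dir)
    except Exception:
        (run_dir / "FAILED").write_text("pipeline run failed; see pipeline.log\n")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, run_dir: Path) -> PipelineResult:
    config.to_yaml(run_dir / "config.yaml")

    spectra, samples = _load_inputs(config)
    if samples is None:
        raise PipelineError("simulate/load", ValueError("no sample table available"))
    npk_io.write_spectra(spectra, run_dir / "spectra.csv")
    npk_io.write_samples(samples, run_dir / "samples.csv")
    log.info("loaded %d samples x %d bands", *spectra.shape)

    @_stage("outliers")
    def _outliers():
        return remove_outliers(
            spectra, samples, method=config.outlier_method,
            threshold=config.outlier_threshold,
        )

    spectra_kept, samples_kept, outlier_report = _outliers()
    npk_io.write_table(outlier_report, run_dir / "outliers.csv")
    log.info("outlier screening removed %d of %d samples",
             int(outlier_report["removed"].sum()), len(outlier_report))

    @_stage("split")
    def _split():
        return split_modeling_validation(
            spectra_kept.index, fraction=config.split_fraction,
            seed=config.split_seed,
            treatments=samples_kept["treatment"] if config.stratify_split else None,
        )

    split = _split()
    (run_dir / "split.json").write_text(json.dumps({
        "modeling": list(split.modeling_ids),
        "validation": list(split.validation_ids),
        "seed": split.seed,
    }, indent=2))
    log.info("split: %d modeling / %d validation",
             len(split.modeling_ids), len(split.validation_ids))

    @_stage("features")
    def _features():
        return feature_table(spectra_kept, config.extrema_mode, config.area_mode)

    feats = _features()
    npk_io.write_table(feats, run_dir / "features.csv")

    @_stage("wavelet")
    def _wavelet():
        return detail_bank(spectra_kept, bases=config.bases, levels=config.levels)

    bank = _wavelet()
    log.info("wavelet bank: %d (basis, level) series x %d bands",
             len(bank), spectra_kept.shape[1])

    model_ids = list(split.modeling_ids)
    valid_ids = list(split.validation_ids)
    scope_ids = (
        model_ids if config.selection_scope == "modeling"
        else list(spectra_kept.index)
    )
    scope_pos = [spectra_kept.index.get_loc(i) for i in scope_ids]

    reports: dict[str, list[EvaluationReport]] = {}
    selected: dict[str, list] = {}
    corr_frames = []
    equations: list[str] = []

    for nutrient in NUTRIENTS:
        y_all = samples_kept[nutrient]
        y_model = y_all.loc[model_ids].to_numpy(dtype=float)
        y_valid = y_all.loc[valid_ids].to_numpy(dtype=float)

        @_stage("correlation")
        def _corr(nutrient=nutrient, y_all=y_all):
            tab = correlation_table(feats.loc[scope_ids], y_all.loc[scope_ids])
            tab.insert(0, "nutrient", nutrient)
            return tab

        corr = _corr()
        corr_frames.append(corr)
        ranked = corr["r"].abs().sort_values(ascending=False)
        top_feats = list(ranked.index[:config.top_features])
        log.info("%s: top features %s", nutrient, top_feats)

        nutrient_reports: list[EvaluationReport] = []

        @_stage("fit-univariate")
        def _fit_univariate(nutrient=nutrient, top_feats=top_feats,
                            y_model=y_model, y_valid=y_valid):
            out = []
            for feat in top_feats:
                x_model = feats.loc[model_ids, feat].to_numpy(dtype=float)
                x_valid = feats.loc[valid_ids, feat].to_numpy(dtype=float)
                for family in config.families:
                    try:
                        res = fit_univariate(
                            x_model, y_model, family=family,
                            predictor_name=feat, response_name=nutrient,
                        )
                        report = evaluate_model(
                            res, x_model, y_model, x_valid, y_valid,
                            model_id=f"{nutrient}:{feat}:{family}",
                        )
                    except ValueError as exc:
                        if not config.skip_infeasible:
                            raise
                        log.info("skipped %s %s on %s: %s",
                                 family, nutrient, feat, exc)
                        continue
                    equations.append(f"{report.model_id}: {res.equation()}")
                    out.append(report)
            return out

        nutrient_reports += _fit_univariate()

        @_stage("select")
        def _select(y_all=y_all):
            sub_bank = {
                key: mat[scope_pos] for key, mat in bank.items()
            }
            return select_sensitivity_coefficients(
                sub_bank, y_all.loc[scope_ids].to_numpy(dtype=float),
                k=config.selection_k,
            )

        coeffs = _select()
        selected[nutrient] = coeffs
        log.info("%s: sensitivity coefficients %s",
                 nutrient, [(c.basis, c.level, c.band_index, round(c.r, 3)) for c in coeffs])

        model_pos = [spectra_kept.index.get_loc(i) for i in model_ids]
        valid_pos = [spectra_kept.index.get_loc(i) for i in valid_ids]
        X_model = np.column_stack([
            bank[(c.basis, c.level)][model_pos, c.band_index] for c in coeffs
        ])
        X_valid = np.column_stack([
            bank[(c.basis, c.level)][valid_pos, c.band_index] for c in coeffs
        ])
        names = [c.name for c in coeffs]

        @_stage("fit-pls")
        def _fit_pls(nutrient=nutrient, X_model=X_model, y_model=y_model,
                     X_valid=X_valid, y_valid=y_valid, names=names):
            res = fit_pls(X_model, y_model, n_components=config.pls_components,
                          predictor_names=names, response_name=nutrient)
            report = evaluate_model(res, X_model, y_model, X_valid, y_valid,
                                    model_id=f"{nutrient}:PLS")
            equations.append(f"{report.model_id}: {res.equation()}")
            return report

        nutrient_reports.append(_fit_pls())

        @_stage("fit-nn")
        def _fit_nn(nutrient=nutrient, X_model=X_model, y_model=y_model,
                    X_valid=X_valid, y_valid=y_valid, names=names):
            res = fit_nn(X_model, y_model, hidden_units=config.nn_hidden,
                         seed=config.nn_seed, predictor_names=names,
                         response_name=nutrient)
            return evaluate_model(res, X_model, y_model, X_valid, y_valid,
                                  model_id=f"{nutrient}:NN")

        nutrient_reports.append(_fit_nn())
        reports[nutrient] = nutrient_reports

    npk_io.write_table(pd.concat(corr_frames), run_dir / "correlations.csv")
    (run_dir / "model_equations.txt").write_text("\n".join(equations) + "\n")
    pd.DataFrame(
        [
            {"nutrient": nut, "rank": i + 1, "basis": c.basis, "level": c.level,
             "band_index": c.band_index,
             "wavelength_nm": float(spectra_kept.columns[c.band_index]),
             "r": c.r}
            for nut, cs in selected.items() for i, c in enumerate(cs)
        ]
    ).to_csv(run_dir / "selected_coefficients.csv", index=False)

    evaluation = pd.DataFrame(
        [{"nutrient": nut, **rep.to_dict()}
         for nut, reps in reports.items() for rep in reps]
    )
    evaluation.to_csv(run_dir / "evaluation.csv", index=False)

    comparison, improvements = compare_models(reports)
    comparison.to_csv(run_dir / "comparison.csv", index=False)
    improvements.to_csv(run_dir / "improvements.csv", index=False)

    return PipelineResult(
        run_dir=run_dir, samples=samples_kept, features=feats,
        reports=reports, comparison=comparison, improvements=improvements,
        selected=selected,
    )


def compare_models(
    reports: dict[str, list[EvaluationReport]]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-nutrient comparison of best univariate vs PLS vs NN.

    Returns (comparison, improvements): the comparison lists each
    finalist's metrics with the minimum-T winner flagged (ties broken by
    model name); improvements gives the signed percent change of every
    metric for each finalist pair (R^2 larger-is-better, the rest
    smaller-is-better).
    """
    comp_rows, impr_rows = [], []
    for nutrient, reps in reports.items():
        if len(reps) < 2:
            raise ValueError(f"need >= 2 reports per nutrient, got {len(reps)}")
        uni = [r for r in reps if r.model_id.count(":") == 2]
        finalists = []
        if uni:
            finalists.append(min(uni, key=lambda r: (r.t, r.model_id)))
        finalists += [r for r in reps if r.model_id.endswith(":PLS")]
        finalists += [r for r in reps if r.model_id.endswith(":NN")]
        if len(finalists) < 2:
            finalists = sorted(reps, key=lambda r: (r.t, r.model_id))
        winner = min(finalists, key=lambda r: (r.t, r.model_id))
        for rep in finalists:
            row = {"nutrient": nutrient, **rep.to_dict()}
            row["best"] = rep is winner
            comp_rows.append(row)
        for ref in finalists:
            for cand in finalists:
                if ref is cand:
                    continue
                impr_rows.append({
                    "nutrient": nutrient,
                    "reference": ref.model_id,
                    "candidate": cand.model_id,
                    "R2_improvement_percent": relative_improvement(
                        ref.r2_modeling, cand.r2_modeling),
                    "MRE_improvement_percent": relative_improvement(
                        ref.mre_percent, cand.mre_percent, smaller_is_better=True),
                    "NRMSE_improvement_percent": relative_improvement(
                        ref.nrmse_value, cand.nrmse_value, smaller_is_better=True),
                    "T_improvement_percent": relative_improvement(
                        ref.t, cand.t, smaller_is_better=True),
                })
    return pd.DataFrame(comp_rows), pd.DataFrame(impr_rows)
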