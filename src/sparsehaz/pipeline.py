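"""End-to-end study orchestration.

Reproduces the shape of a high-dimensional additive-hazards survival study:

1. load (or simulate) an expression matrix with survival outcomes and four
   clinical covariates;
2. split 80/20 into training and test, stratified by event status;
3. for each penalty (lasso, SCAD, SICA): 10-fold CV on the training split,
   fit at the selected tuning, score the test split with the linear predictor
   and compute its time-dependent AUC curve and median AUC;
4. bootstrap .632+ prediction-error curves for a clinical-only model and for
   each clinical-plus-selected-genes model, with the entire selection
   pipeline re-run inside every bootstrap training draw (no selection
   leakage);
5. selection-stability tables over repeated 80% subsample refits.

Standardization statistics are always computed on the training portion of
whatever split or resample is in play, never on held-out samples. All
randomness derives from a single root seed. Outputs are plain TSV tables plus
a key/value run report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data_model import (
    SurvivalDataset,
    apply_standardization,
    assemble_dataset,
    read_expression,
    read_outcomes,
    standardize_columns,
)
from .evaluation import (
    EvalCurve,
    StabilityTable,
    auc_t,
    baseline_cumhaz,
    error632plus,
    median_auc,
    predict_survival,
    stability_replicates,
)
from .model_selection import cross_validate
from .penalties import PenaltySpec
from .solver import default_lambda_grid, fit
from .suffstats import compute_suffstats, unpenalized_fit
from .synthetic import SyntheticConfig, generate

__all__ = ["StudyConfig", "StudyResult", "run_study", "top_features_by_auc"]


@dataclass
class StudyConfig:
    """Configuration of a full study run (see module docstring for the stages)."""

    penalties: tuple[str, ...] = ("lasso", "scad", "sica")
    seed: int = 0
    test_fraction: float = 0.2
    cv_folds: int = 10
    n_lambdas: int = 25
    b_boot: int = 25  # .632+ bootstrap replicates
    r_replicates: int = 25  # stability replicates
    n_eval_times: int = 30  # cap on the evaluation time grid
    refit_in_bootstrap: bool = True
    plots: bool = False  # also render AUC / error curves as PNG
    synthetic: SyntheticConfig | None = None
    expression_path: str | None = None
    outcomes_path: str | None = None
    features_as_rows: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        syn = d.pop("synthetic", None)
        cfg = cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})
        if syn is not None:
            cfg.synthetic = SyntheticConfig(**syn)
        if isinstance(cfg.penalties, list):
            cfg.penalties = tuple(cfg.penalties)
        return cfg


@dataclass
class StudyResult:
    config: StudyConfig
    auc_curves: dict[str, EvalCurve]
    median_aucs: dict[str, float]
    error_curves: dict[str, EvalCurve]
    mean_errors: dict[str, float]
    stability: dict[str, StabilityTable]
    coefficients: dict[str, pd.DataFrame]
    selected: dict[str, dict]
    out_dir: Path | None = None


def _derived_seed(seed: int, *tags: int) -> int:
    return int(
        np.random.SeedSequence([int(seed), *map(int, tags)]).generate_state(1)[0]
        % (2**31)
    )


def _stratified_split(status: np.ndarray, test_fraction: float, seed: int):
    """Seeded event-stratified train/test index split."""
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for grp in (0.0, 1.0):
        idx = np.where(status == grp)[0]
        idx = rng.permutation(idx)
        n_test = int(round(test_fraction * idx.size))
        test_idx.append(idx[:n_test])
        train_idx.append(idx[n_test:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx))


def _design(data: SurvivalDataset):
    """Raw design matrix: gene block plus (if present) clinical block."""
    if data.clinical is None:
        return data.covariates, list(data.feature_ids)
    return (
        np.hstack([data.covariates, data.clinical]),
        list(data.feature_ids) + list(data.clinical_ids),
    )


def _penalized_procedure(kind: str, cfg: StudyConfig, seed: int):
    """Training closure: standardize, CV-select, fit, estimate the baseline.

    Returns a ``fit_procedure`` suitable for :func:`error632plus`: it maps a
    raw-scale training dataset to a predictor over raw-scale covariates.
    """

    def procedure(train: SurvivalDataset):
        Zs, center, scale = standardize_columns(train.covariates)
        std_train = train.with_covariates(Zs, train.feature_ids)
        ss = compute_suffstats(std_train)
        cv = cross_validate(
            std_train,
            kind,
            K=cfg.cv_folds,
            seed=seed,
            n_lambdas=cfg.n_lambdas,
        )
        lams = cv.lambdas[cv.lambdas >= cv.selected_lambda]
        beta = np.zeros(ss.p)
        for lam in lams:
            beta = fit(
                ss, PenaltySpec(kind, float(lam), cv.selected_a), beta_init=beta
            ).beta
        cumhaz = baseline_cumhaz(std_train, beta)

        def predictor(covariates_raw: np.ndarray, times: np.ndarray) -> np.ndarray:
            Znew = apply_standardization(covariates_raw, center, scale)
            return predict_survival(beta, cumhaz, Znew, times)

        predictor.beta = beta
        predictor.cv = cv
        predictor.center = center
        predictor.scale = scale
        return predictor

    return procedure


def _clinical_procedure():
    """Training closure for the clinical-only model: unpenalized fit on q <= n
    covariates."""

    def procedure(train: SurvivalDataset):
        Zs, center, scale = standardize_columns(train.covariates)
        std_train = train.with_covariates(Zs, train.feature_ids)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            beta = unpenalized_fit(compute_suffstats(std_train))
        cumhaz = baseline_cumhaz(std_train, beta)

        def predictor(covariates_raw, times):
            Znew = apply_standardization(covariates_raw, center, scale)
            return predict_survival(beta, cumhaz, Znew, times)

        predictor.beta = beta
        return predictor

    return procedure


def _eval_times(data: SurvivalDataset, cap: int) -> np.ndarray:
    """Distinct event times within (0, tau], thinned to at most ``cap``."""
    ts = np.unique(data.time[(data.status == 1.0) & (data.time <= data.tau)])
    if ts.size > cap:
        ts = ts[np.unique(np.linspace(0, ts.size - 1, cap).astype(int))]
    return ts


def load_study_data(cfg: StudyConfig) -> SurvivalDataset:
    """Materialize the study dataset from files or the synthetic generator.

    Covariates are returned on the raw scale; standardization happens inside
    each training stage.
    """
    if cfg.synthetic is not None:
        data, _ = generate(cfg.synthetic)
        return data
    if cfg.expression_path is None or cfg.outcomes_path is None:
        raise ValueError("config needs either a synthetic block or input paths")
    features = read_expression(cfg.expression_path, cfg.features_as_rows)
    outcomes = read_outcomes(cfg.outcomes_path)
    return assemble_dataset(features, outcomes, standardize=False)


def run_study(
    config: StudyConfig | dict | str | Path,
    out_dir: str | Path | None = None,
    data: SurvivalDataset | None = None,
) -> StudyResult:
    """Run the full study; optionally write every table to ``out_dir``.

    Reruns with an identical config produce byte-identical tables.
    """
    if isinstance(config, (str, Path)):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh)
    if isinstance(config, dict):
        config = StudyConfig.from_dict(config)
    cfg = config

    if data is None:
        data = load_study_data(cfg)

    full_X, full_ids = _design(data)
    full = data.with_covariates(full_X, full_ids)

    tr_idx, te_idx = _stratified_split(
        full.status, cfg.test_fraction, _derived_seed(cfg.seed, 0)
    )
    train, test = full.subset(tr_idx), full.subset(te_idx)

    eval_times_test = _eval_times(test, cfg.n_eval_times)
    eval_times_full = _eval_times(full, cfg.n_eval_times)

    auc_curves: dict[str, EvalCurve] = {}
    median_aucs: dict[str, float] = {}
    error_curves: dict[str, EvalCurve] = {}
    mean_errors: dict[str, float] = {}
    stability: dict[str, StabilityTable] = {}
    coefficients: dict[str, pd.DataFrame] = {}
    selected: dict[str, dict] = {}

    # ------------------------------------------------ penalized models
    for ki, kind in enumerate(cfg.penalties):
        proc = _penalized_procedure(kind, cfg, _derived_seed(cfg.seed, 1, ki))
        predictor = proc(train)
        beta = predictor.beta
        marker = apply_standardization(
            test.covariates, predictor.center, predictor.scale
        ) @ beta
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curve = auc_t(marker, test, eval_times_test)
        auc_curves[kind] = curve
        median_aucs[kind] = median_auc(curve)
        nz = beta != 0.0
        coefficients[kind] = pd.DataFrame(
            {
                "coef_standardized": beta[nz],
                "coef_raw": beta[nz] / predictor.scale[nz],
            },
            index=pd.Index(np.asarray(full_ids)[nz], name="feature_id"),
        )
        selected[kind] = {
            "lambda": predictor.cv.selected_lambda,
            "a": predictor.cv.selected_a,
            "n_nonzero": int(nz.sum()),
        }

        if not cfg.refit_in_bootstrap:
            warnings.warn(
                "refit_in_bootstrap=False: gene selection is frozen across "
                "bootstrap replicates, which biases the .632+ error downward",
                stacklevel=2,
            )
            frozen = proc(full)

            def frozen_proc(_train, _frozen=frozen):
                return _frozen

            boot_proc = frozen_proc
        else:
            boot_proc = _penalized_procedure(kind, cfg, _derived_seed(cfg.seed, 2, ki))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            err = error632plus(
                full,
                boot_proc,
                eval_times_full,
                B=cfg.b_boot,
                seed=_derived_seed(cfg.seed, 3, ki),
            )
        error_curves[kind] = err
        mean_errors[kind] = float(err.values.mean())

        def selector(train_rep, rep_seed, _kind=kind):
            p = _penalized_procedure(_kind, cfg, rep_seed)(train_rep)
            return p.beta

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stability[kind] = stability_replicates(
                full,
                selector,
                R=cfg.r_replicates,
                seed=_derived_seed(cfg.seed, 4, ki),
            )

    # ------------------------------------------------ clinical-only baseline
    if data.clinical is not None:
        clin = data.with_covariates(data.clinical, data.clinical_ids)
        cproc = _clinical_procedure()
        cpred = cproc(clin.subset(tr_idx))
        cmarker = apply_standardization(
            clin.subset(te_idx).covariates, *_center_scale(clin.subset(tr_idx))
        ) @ cpred.beta
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ccurve = auc_t(cmarker, clin.subset(te_idx), eval_times_test)
        auc_curves["clinical"] = ccurve
        median_aucs["clinical"] = median_auc(ccurve)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cerr = error632plus(
                clin,
                cproc,
                eval_times_full,
                B=cfg.b_boot,
                seed=_derived_seed(cfg.seed, 5),
            )
        error_curves["clinical"] = cerr
        mean_errors["clinical"] = float(cerr.values.mean())

    result = StudyResult(
        config=cfg,
        auc_curves=auc_curves,
        median_aucs=median_aucs,
        error_curves=error_curves,
        mean_errors=mean_errors,
        stability=stability,
        coefficients=coefficients,
        selected=selected,
    )
    if out_dir is not None:
        result.out_dir = Path(out_dir)
        _write_report(result)
    return result


def _center_scale(train: SurvivalDataset):
    _, center, scale = standardize_columns(train.covariates)
    return center, scale


def _write_report(res: StudyResult) -> None:
    out = res.out_dir
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%.10g"
    for name, curve in res.auc_curves.items():
        df = curve.to_frame()
        df.to_csv(out / f"auc_{name}.tsv", sep="\t", index=False, float_format=fmt)
    for name, curve in res.error_curves.items():
        curve.to_frame().to_csv(
            out / f"error632plus_{name}.tsv", sep="\t", index=False, float_format=fmt
        )
    for name, tab in res.stability.items():
        tab.table.to_csv(
            out / f"stability_{name}.tsv", sep="\t", index=True, float_format=fmt
        )
    for name, coefs in res.coefficients.items():
        coefs.to_csv(
            out / f"coefficients_{name}.tsv", sep="\t", index=True, float_format=fmt
        )
    if res.config.plots:
        from .evaluation import plot_curves

        plot_curves(res.auc_curves, "AUC(t)", out / "auc_curves.png")
        plot_curves(res.error_curves, ".632+ prediction error", out / "error_curves.png")
    lines = [f"sparsehaz_version\t{__version__}"]
    cfg = res.config
    for key in (
        "penalties",
        "seed",
        "test_fraction",
        "cv_folds",
        "n_lambdas",
        "b_boot",
        "r_replicates",
        "refit_in_bootstrap",
    ):
        lines.append(f"config.{key}\t{getattr(cfg, key)}")
    if cfg.synthetic is not None:
        for key in ("n", "p", "n_signal", "rho", "lambda0", "target_events", "seed"):
            lines.append(f"config.synthetic.{key}\t{getattr(cfg.synthetic, key)}")
    for name, v in sorted(res.median_aucs.items()):
        lines.append(f"median_auc.{name}\t{v:.10g}")
    for name, v in sorted(res.mean_errors.items()):
        lines.append(f"mean_error632plus.{name}\t{v:.10g}")
    for name, sel in sorted(res.selected.items()):
        for k, v in sel.items():
            lines.append(f"selected.{name}.{k}\t{v}")
    (out / "report.tsv").write_text("\n".join(lines) + "\n")


def top_features_by_auc(
    data: SurvivalDataset, times, k: int = 5
) -> pd.DataFrame:
    """Rank single features by the median time-dependent AUC of the feature
    itself used as a risk marker.

    Returns the top ``k`` as a DataFrame with the per-feature median AUC and
    the sign of association taken from the univariate (single-covariate)
    unpenalized additive-hazards coefficient.
    """
    if k > data.p:
        raise ValueError(f"k={k} exceeds the number of features {data.p}")
    times = np.atleast_1d(np.asarray(times, dtype=float))
    meds = np.empty(data.p)
    signs = np.empty(data.p)
    for j in range(data.p):
        single = data.with_covariates(data.covariates[:, [j]], [data.feature_ids[j]])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curve = auc_t(data.covariates[:, j], data, times)
            meds[j] = median_auc(curve) if curve.values.size else np.nan
            ss = compute_suffstats(single)
            coef = ss.b[0] / ss.V_diag()[0] if ss.V_diag()[0] > 0 else 0.0
        signs[j] = np.sign(coef)
    order = np.argsort(-meds, kind="stable")[:k]
    return pd.DataFrame(
        {
            "median_auc": meds[order],
            "sign": signs[order],
        },
        index=pd.Index(np.asarray(data.feature_ids)[order], name="feature_id"),
    )
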