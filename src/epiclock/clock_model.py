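"""Elastic-net methylation clock: training, shrinking, prediction, acceleration.

The clock regresses calibrated chronological age (see :mod:`.calibration`)
on CpG beta values with an elastic-net penalty (mixing parameter ``alpha``,
default 0.5; penalty strength ``lam`` chosen by k-fold cross-validation
minimizing mean squared error on the transformed scale).  The fitted model
is a sparse weighted average of clock CpGs: the linear score
``intercept + sum_i w_i * beta_i`` is pushed through the inverse calibration
to give DNAm age in years.  Age acceleration is either the plain difference
``dnam_age - age`` or the residual from regressing DNAm age on age.

Predictors are standardized internally for fitting; reported coefficients
are on the raw beta scale, so a saved coefficient table is directly usable
for prediction without knowledge of the training data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet, ElasticNetCV

from .calibration import CalibrationSpec, inverse_transform_age, transform_age
from .io_formats import BetaMatrix, CoefficientTable, SampleTable

__all__ = [
    "ClockModel",
    "PredictionResult",
    "fit_clock",
    "shrink_clock",
    "predict_dnam_age",
    "compute_age_acceleration",
    "model_to_coefficient_table",
    "model_from_coefficient_table",
]

DEFAULT_ALPHA = 0.5
DEFAULT_FOLDS = 10
DEFAULT_MAX_MISSING = 10
MIN_TRAIN_SAMPLES = 20
# coordinate descent is deterministic for fixed data, folds and tolerance;
# 1e-4 on standardized predictors changes selected CpGs negligibly vs 1e-6
# while keeping the full CV path fast on a single core
_SOLVER_TOL = 1e-4
_MAX_ITER = 20_000


class DataError(ValueError):
    """Input data cannot support the requested fit."""


class ConfigurationError(ValueError):
    """Invalid fitting configuration (folds, sample counts...)."""


@dataclass
class ClockModel:
    """A fitted (or loaded) methylation clock.

    ``coefficients`` holds only nonzero weights on the raw beta scale.
    ``gold_standard_means`` are training-set probe means used to impute
    missing betas at prediction time.
    """

    coefficients: dict[str, float]
    intercept: float
    calibration: CalibrationSpec = field(default_factory=CalibrationSpec)
    gold_standard_means: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    alpha: float = DEFAULT_ALPHA
    lam: float = float("nan")
    cv_folds: int = DEFAULT_FOLDS
    seed: int = 0
    n_train_samples: int = 0
    n_train_probes: int = 0
    shrunken: bool = False
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not math.isfinite(self.intercept):
            raise ValueError("intercept must be finite")
        clean = {}
        for p, w in self.coefficients.items():
            if not math.isfinite(w):
                raise ValueError(f"non-finite coefficient for {p!r}")
            if w != 0.0:
                clean[p] = float(w)
        self.coefficients = clean

    @property
    def clock_size(self) -> int:
        return len(self.coefficients)


@dataclass
class PredictionResult:
    """Per-sample DNAm age predictions.

    ``table`` is indexed by sample_id with columns ``linear_score``,
    ``dnam_age``, ``n_imputed_probes``, ``warn_majority_imputed`` and, once
    acceleration has been attached, ``age``, ``acceleration_diff``,
    ``acceleration_resid``.  ``errors`` maps sample_id -> message for
    samples with no usable probes (their dnam_age is missing).
    """

    table: pd.DataFrame
    errors: dict[str, str] = field(default_factory=dict)

    @property
    def dnam_age(self) -> pd.Series:
        return self.table["dnam_age"]


# ---------------------------------------------------------------------------
# training

def _cv_fold_ids(samples: pd.DataFrame, n_folds: int, seed: int) -> np.ndarray:
    """Fold assignment, stratified by dataset_id when available.

    Within each dataset (or globally if no dataset_id column) sample order is
    shuffled with the given seed and folds are dealt round-robin, so every
    fold sees every dataset where possible.
    """
    rng = np.random.default_rng(seed)
    fold = np.empty(len(samples), dtype=int)
    if "dataset_id" in samples.columns and samples["dataset_id"].notna().any():
        groups = samples.groupby(samples["dataset_id"].astype(str), sort=True).indices
    else:
        groups = {"_all": np.arange(len(samples))}
    offset = 0
    for key in sorted(groups):
        idx = np.asarray(groups[key])
        perm = rng.permutation(len(idx))
        fold[idx[perm]] = (offset + np.arange(len(idx))) % n_folds
        offset += len(idx)
    return fold


def _prepare_training(betas: BetaMatrix, samples: SampleTable, max_missing: int):
    """Select usable samples/probes and mean-impute residual missingness."""
    shared = [s for s in betas.sample_ids if s in samples.data.index]
    meta = samples.data.loc[shared]
    meta = meta[meta["age"].notna()]
    if len(meta) < MIN_TRAIN_SAMPLES:
        raise DataError(
            f"need >= {MIN_TRAIN_SAMPLES} samples with known age, got {len(meta)}"
        )
    mat = betas.values[list(meta.index)]
    keep = mat.isna().sum(axis=1) < max_missing
    mat = mat.loc[keep]
    if mat.shape[0] == 0:
        raise DataError("no probe passed the missing-value filter")
    means = mat.mean(axis=1, skipna=True)
    mat = mat.T.fillna(means).T
    return mat, meta, means


def fit_clock(
    betas: BetaMatrix,
    samples: SampleTable,
    alpha: float = DEFAULT_ALPHA,
    cv_folds: int = DEFAULT_FOLDS,
    seed: int = 0,
    max_missing: int = DEFAULT_MAX_MISSING,
    calibration: CalibrationSpec | None = None,
    n_lambdas: int = 100,
) -> ClockModel:
    """Train the elastic-net clock on a beta matrix plus sample ages.

    Probes with ``max_missing`` or more missing values are excluded before
    fitting; remaining gaps are filled with the training probe mean.  The
    penalty strength is chosen on a log-spaced path of ``n_lambdas`` values
    by ``cv_folds``-fold cross-validation (folds stratified by dataset id
    when present, shuffled with ``seed``), minimizing CV mean squared error
    with no one-standard-error rule.  Identical inputs and seed give
    bit-identical coefficients.
    """
    if not 0.0 < alpha <= 1.0:
        raise ConfigurationError(f"alpha must be in (0, 1], got {alpha}")
    if cv_folds < 3:
        raise ConfigurationError(f"cv_folds must be >= 3, got {cv_folds}")
    calibration = calibration or CalibrationSpec()
    mat, meta, means = _prepare_training(betas, samples, max_missing)
    if len(meta) < cv_folds:
        raise ConfigurationError(
            f"{len(meta)} usable samples < {cv_folds} CV folds"
        )
    y = transform_age(meta["age"].to_numpy(float), calibration)

    X = mat.to_numpy(float).T  # samples x probes
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    informative = sd > 0
    probe_ids = np.asarray(mat.index)[informative]
    warnings: list[str] = []
    if not informative.any():
        model = ClockModel(
            coefficients={},
            intercept=float(np.mean(y)),
            calibration=calibration,
            gold_standard_means=means,
            alpha=alpha,
            lam=float("inf"),
            cv_folds=cv_folds,
            seed=seed,
            n_train_samples=len(meta),
            n_train_probes=int(mat.shape[0]),
            warnings=["all probes constant; intercept-only model"],
        )
        return model
    Z = (X[:, informative] - mu[informative]) / sd[informative]

    fold = _cv_fold_ids(meta, cv_folds, seed)
    splits = [
        (np.where(fold != k)[0], np.where(fold == k)[0]) for k in range(cv_folds)
    ]
    enet = ElasticNetCV(
        l1_ratio=alpha,
        alphas=n_lambdas,  # int: length of the automatic log-spaced path
        cv=splits,
        fit_intercept=True,
        max_iter=_MAX_ITER,
        tol=_SOLVER_TOL,
        selection="cyclic",
        n_jobs=1,
    )
    enet.fit(Z, y)
    if enet.n_iter_ >= _MAX_ITER:
        warnings.append("solver hit the iteration cap; coefficients may be inexact")

    w_std = enet.coef_
    w_raw = w_std / sd[informative]
    intercept = float(enet.intercept_ - np.sum(w_raw * mu[informative]))
    coefficients = {
        str(p): float(w) for p, w in zip(probe_ids, w_raw) if w != 0.0
    }
    return ClockModel(
        coefficients=coefficients,
        intercept=intercept,
        calibration=calibration,
        gold_standard_means=means,
        alpha=alpha,
        lam=float(enet.alpha_),
        cv_folds=cv_folds,
        seed=seed,
        n_train_samples=len(meta),
        n_train_probes=int(mat.shape[0]),
        warnings=warnings,
    )


def _fit_at_lambda(Z, y, alpha, lam):
    enet = ElasticNet(
        alpha=lam, l1_ratio=alpha, fit_intercept=True,
        max_iter=_MAX_ITER, tol=_SOLVER_TOL, selection="cyclic",
    )
    enet.fit(Z, y)
    return enet


def shrink_clock(
    model: ClockModel,
    betas: BetaMatrix,
    samples: SampleTable,
    target_size: int,
    max_missing: int = DEFAULT_MAX_MISSING,
) -> ClockModel:
    """Refit the clock restricted to its own CpGs under a stronger penalty.

    The penalty is increased (binary search over ``lam``) until at most
    ``target_size`` CpGs keep nonzero coefficients, mirroring how a compact
    sub-clock can be culled from the full clock with little loss of
    accuracy.  If no penalty on the path gives exactly the requested size
    (sparsity changes in jumps), the closest achievable size not exceeding
    the target is returned and a warning is recorded.
    """
    if target_size < 0:
        raise ConfigurationError("target_size must be >= 0")
    if target_size > model.clock_size:
        raise ConfigurationError(
            f"target_size {target_size} exceeds current clock size {model.clock_size}"
        )
    if target_size == 0:
        mat, meta, _ = _prepare_training(betas, samples, max_missing)
        y = transform_age(meta["age"].to_numpy(float), model.calibration)
        return replace(
            model, coefficients={}, intercept=float(np.mean(y)),
            lam=float("inf"), shrunken=True, warnings=[],
        )

    mat, meta, means = _prepare_training(betas, samples, max_missing)
    clock_probes = [p for p in model.coefficients if p in mat.index]
    if not clock_probes:
        raise DataError("none of the model's CpGs are present in the data")
    sub = mat.loc[clock_probes]
    y = transform_age(meta["age"].to_numpy(float), model.calibration)
    X = sub.to_numpy(float).T
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    def nnz_at(lam):
        fit = _fit_at_lambda(Z, y, model.alpha, lam)
        return int(np.count_nonzero(fit.coef_)), fit

    lo = model.lam if math.isfinite(model.lam) else 1e-4
    n_lo, fit_lo = nnz_at(lo)
    if n_lo <= target_size:
        best_n, best_fit, best_lam = n_lo, fit_lo, lo
    else:
        hi = lo
        while True:
            hi *= 2.0
            n_hi, fit_hi = nnz_at(hi)
            if n_hi <= target_size:
                break
        best_n, best_fit, best_lam = n_hi, fit_hi, hi
        # shrink the bracket: find the weakest penalty still <= target
        for _ in range(60):
            mid = math.sqrt(lo * hi)
            n_mid, fit_mid = nnz_at(mid)
            if n_mid <= target_size:
                hi = mid
                if n_mid >= best_n:
                    best_n, best_fit, best_lam = n_mid, fit_mid, mid
            else:
                lo = mid
            if hi / lo < 1.0 + 1e-6:
                break

    w_raw = best_fit.coef_ / sd
    intercept = float(best_fit.intercept_ - np.sum(w_raw * mu))
    coefficients = {
        str(p): float(w) for p, w in zip(clock_probes, w_raw) if w != 0.0
    }
    warnings = []
    if best_n != target_size:
        warnings.append(
            f"requested clock size {target_size} not on the penalty path; "
            f"closest achievable is {best_n}"
        )
    return replace(
        model,
        coefficients=coefficients,
        intercept=intercept,
        gold_standard_means=means,
        lam=float(best_lam),
        shrunken=True,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# prediction

def predict_dnam_age(model: ClockModel, betas: BetaMatrix) -> PredictionResult:
    """Predict DNAm age for every sample in a beta matrix.

    Model CpGs missing from the matrix (absent rows or NaN cells) are imputed
    from the model's gold-standard means.  A sample missing more than half of
    the model's CpGs is flagged; a sample with no observed model CpG at all
    gets an error record and a missing prediction.  Deterministic.
    """
    if model.clock_size == 0:
        score = np.full(betas.n_samples, model.intercept)
        table = pd.DataFrame(
            {
                "linear_score": score,
                "dnam_age": inverse_transform_age(score, model.calibration),
                "n_imputed_probes": 0,
                "warn_majority_imputed": False,
            },
            index=pd.Index(betas.sample_ids, name="sample_id"),
        )
        return PredictionResult(table=table)

    probes = list(model.coefficients)
    w = np.array([model.coefficients[p] for p in probes])
    sub = betas.values.reindex(probes)
    fill = model.gold_standard_means.reindex(probes)
    if fill.isna().any():
        missing = fill.index[fill.isna()][0]
        raise ValueError(f"model lacks a gold-standard mean for {missing!r}")

    arr = sub.to_numpy(float)
    observed = ~np.isnan(arr)
    n_imputed = (~observed).sum(axis=0)
    filled = np.where(observed, arr, fill.to_numpy(float)[:, None])
    score = model.intercept + w @ filled

    n_obs = observed.sum(axis=0)
    warn = n_imputed > len(probes) / 2
    errors: dict[str, str] = {}
    dnam = inverse_transform_age(score, model.calibration)
    dnam = np.asarray(dnam, dtype=float)
    for j, sid in enumerate(betas.sample_ids):
        if n_obs[j] == 0:
            errors[str(sid)] = "no model CpG observed for this sample"
            dnam[j] = np.nan
            score[j] = np.nan
    table = pd.DataFrame(
        {
            "linear_score": score,
            "dnam_age": dnam,
            "n_imputed_probes": n_imputed.astype(int),
            "warn_majority_imputed": warn,
        },
        index=pd.Index(betas.sample_ids, name="sample_id"),
    )
    return PredictionResult(table=table, errors=errors)


def compute_age_acceleration(
    pred: PredictionResult,
    samples: SampleTable,
    method: str = "difference",
) -> pd.Series:
    """Age acceleration per sample, in years.

    ``difference``: dnam_age - chronological age.  ``residual``: residual
    from the ordinary least-squares regression of dnam_age on age over the
    provided samples (mean zero, uncorrelated with age by construction);
    needs at least 3 samples with non-constant age.
    """
    if method not in ("difference", "residual"):
        raise ValueError(f"unknown method {method!r}")
    shared = pred.table.index.intersection(samples.data.index)
    age = samples.data.loc[shared, "age"]
    dnam = pred.table.loc[shared, "dnam_age"]
    ok = age.notna() & dnam.notna()
    out = pd.Series(np.nan, index=pred.table.index)
    if method == "difference":
        out.loc[shared[ok]] = dnam[ok] - age[ok]
        return out.rename("acceleration_diff")
    a = age[ok].to_numpy(float)
    d = dnam[ok].to_numpy(float)
    if len(a) < 3:
        raise DataError("residual acceleration needs >= 3 samples with age")
    if np.ptp(a) == 0:
        raise DataError("residual acceleration undefined for constant age")
    slope, icpt = np.polyfit(a, d, 1)
    out.loc[shared[ok]] = d - (icpt + slope * a)
    return out.rename("acceleration_resid")


# ---------------------------------------------------------------------------
# serialization bridge

GOLD_STD_COL = "goldStandardMean"


def model_to_coefficient_table(model: ClockModel) -> CoefficientTable:
    """Express the model in the coefficient-file dialect (for saving)."""
    extras = pd.DataFrame(
        {GOLD_STD_COL: model.gold_standard_means.reindex(model.coefficients)},
        index=pd.Index(list(model.coefficients), name="CpGmarker"),
    )
    return CoefficientTable(
        coefficients=dict(model.coefficients),
        intercept=model.intercept,
        extras=extras,
    )


def model_from_coefficient_table(
    table: CoefficientTable,
    calibration: CalibrationSpec | None = None,
) -> ClockModel:
    """Build a predict-ready model from a loaded coefficient table.

    If the table carries a gold-standard-mean column it is used for
    imputation; otherwise a neutral 0.5 is assumed for every CpG (and a
    warning recorded), since prediction must still be possible from a bare
    published coefficient list.
    """
    warnings = []
    if GOLD_STD_COL in table.extras.columns and table.extras[GOLD_STD_COL].notna().all():
        means = table.extras[GOLD_STD_COL].astype(float)
    else:
        means = pd.Series(0.5, index=pd.Index(list(table.coefficients)))
        warnings.append("no gold-standard means in file; imputing with 0.5")
    return ClockModel(
        coefficients=dict(table.coefficients),
        intercept=table.intercept,
        calibration=calibration or CalibrationSpec(),
        gold_standard_means=means,
        warnings=warnings,
    )
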