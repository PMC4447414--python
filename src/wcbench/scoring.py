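"""Submission scoring and analytics.

Three statistics rank submissions:

* parameter error  ``e_param  = (1/N) sum_i (log10(v_est_i / v_true_i))^2``
  over the N unknown parameters;
* prediction error ``e_predict = (1/M) sum_i ((v_true_i - v_est_i) / sigma_i)^2``
  over the M measurements with true variance above a small floor;
* overall score    ``s = -ln(p_param * p_predict)``

where the p-values are empirical: the observed error is ranked against the
errors of "meta" vectors built by resampling each coordinate independently
and uniformly from the pool of submitted vectors.  Add-one smoothing keeps
p-values strictly positive so the combined score is always finite.

Also provided: the per-parameter error decomposition averaged over the
top-scoring submissions, per-measurement coefficients of variation across a
cell population, and rank correlations between each unknown parameter's
submitted value and the submission prediction error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .toycell import ContractError, DataSetBundle, ParameterSet

DEFAULT_VARIANCE_FLOOR = 1e-12
DEFAULT_N_META = 10_000


class DomainError(ValueError):
    """A value outside the statistic's domain (non-positive value or p)."""


@dataclass
class Submission:
    """A team's estimate: absolute values for every unknown parameter."""

    values: dict                      # name -> estimated value
    team: str = "anonymous"
    timestamp: str | None = None
    predicted_means: np.ndarray | None = None
    prediction_error: float | None = None

    def __post_init__(self):
        for name, v in self.values.items():
            if not (v > 0 and math.isfinite(v)):
                raise DomainError(f"submission value for {name} must be positive")

    def vector(self, names) -> np.ndarray:
        missing = [n for n in names if n not in self.values]
        if missing:
            raise ContractError(f"submission missing parameters: {missing}")
        return np.array([self.values[n] for n in names], dtype=float)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"name": list(self.values), "value": list(self.values.values())}
        )

    def to_tsv(self, path):
        self.as_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, team: str = "anonymous") -> "Submission":
        df = pd.read_csv(path, sep="\t")
        return cls(values=dict(zip(df["name"], df["value"])), team=team)


@dataclass
class ScoreReport:
    """Full scoring record for one submission."""

    team: str
    e_param: float
    e_predict: float | None
    p_param: float | None
    p_predict: float | None
    s: float | None
    per_name_error: dict = field(default_factory=dict)
    per_class_error: dict = field(default_factory=dict)
    n_excluded_measurements: int = 0
    n_meta: int | None = None
    seed: int | None = None

    def to_json(self) -> dict:
        return {
            "team": self.team,
            "e_param": self.e_param,
            "e_predict": self.e_predict,
            "p_param": self.p_param,
            "p_predict": self.p_predict,
            "s": self.s,
            "per_name_error": self.per_name_error,
            "per_class_error": self.per_class_error,
            "n_excluded_measurements": self.n_excluded_measurements,
            "n_meta": self.n_meta,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# error statistics


def squared_log_ratios(est: np.ndarray, true: np.ndarray) -> np.ndarray:
    est = np.asarray(est, dtype=float)
    true = np.asarray(true, dtype=float)
    if np.any(est <= 0) or np.any(true <= 0):
        raise DomainError("log-ratio error requires strictly positive values")
    return np.log10(est / true) ** 2


def param_error(est, truth) -> float:
    """Mean squared log10 ratio between estimated and true parameter values.

    Accepts (Submission, ParameterSet) or two aligned positive vectors.
    """
    if isinstance(est, Submission) and isinstance(truth, ParameterSet):
        names = tuple(est.values)
        if set(names) != set(truth.names) and not set(names) <= set(truth.names):
            raise ContractError("submission names do not match the truth")
        est_v = est.vector(names)
        true_v = np.array([truth.value(n) for n in names])
    else:
        est_v = np.asarray(est, dtype=float)
        true_v = np.asarray(truth, dtype=float)
        if est_v.shape != true_v.shape:
            raise ContractError("estimate/truth shape mismatch")
    return float(np.mean(squared_log_ratios(est_v, true_v)))


def prediction_error(
    est_means,
    true_means,
    true_vars,
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
    return_detail: bool = False,
):
    """Variance-normalized least-squares prediction error.

    Measurements whose true variance is at or below ``variance_floor`` are
    excluded and counted; M is the number of included measurements.
    """
    est_means = np.asarray(est_means, dtype=float)
    true_means = np.asarray(true_means, dtype=float)
    true_vars = np.asarray(true_vars, dtype=float)
    if not (est_means.shape == true_means.shape == true_vars.shape):
        raise ContractError("measurement vectors must have equal length")
    if np.any(true_vars < 0):
        raise ContractError("variances must be non-negative")
    included = true_vars > variance_floor
    n_excluded = int(np.sum(~included))
    if not np.any(included):
        raise EstimationUndefinedError("all measurements excluded by the variance floor")
    z2 = (true_means[included] - est_means[included]) ** 2 / true_vars[included]
    err = float(np.mean(z2))
    if return_detail:
        detail = np.full(est_means.shape, np.nan)
        detail[included] = z2
        return err, detail, n_excluded
    return err


class EstimationUndefinedError(RuntimeError):
    """The statistic is undefined for the given inputs."""


def prediction_error_by_class(
    bundle_true: DataSetBundle,
    est_means: np.ndarray,
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
) -> dict:
    """Per-data-class decomposition of the prediction error."""
    _, detail, _ = prediction_error(
        est_means,
        bundle_true.means,
        bundle_true.variances,
        variance_floor=variance_floor,
        return_detail=True,
    )
    out = {}
    for cls in bundle_true.registry["data_class"].unique():
        mask = bundle_true.class_mask(cls)
        vals = detail[mask]
        vals = vals[np.isfinite(vals)]
        out[cls] = float(np.mean(vals)) if vals.size else math.nan
    return out


# ---------------------------------------------------------------------------
# empirical p-values and the combined score


def empirical_pvalue(
    observed_error: float,
    pool: np.ndarray,
    error_fn,
    n_meta: int = DEFAULT_N_META,
    seed=0,
) -> float:
    """Empirical p-value of an observed error against coordinate-resampled
    meta vectors.

    ``pool`` is an (n_submissions, n_coordinates) array of submitted vectors.
    Each of the ``n_meta`` meta vectors draws every coordinate independently
    and uniformly from the pool's values at that coordinate; ``error_fn``
    maps a vector to its error.  Returns
    ``(1 + #{meta error <= observed}) / (n_meta + 1)`` -- add-one smoothing
    keeps the p-value strictly positive.
    """
    pool = np.asarray(pool, dtype=float)
    if pool.ndim != 2 or pool.shape[0] < 2:
        raise ContractError("pool must contain at least two submissions")
    if n_meta < 1:
        raise ContractError("n_meta must be >= 1")
    if np.all(pool == pool[0]):
        return 1.0  # degenerate pool: every meta vector is identical
    rng = np.random.default_rng(seed)
    n_sub, n_coord = pool.shape
    rows = rng.integers(0, n_sub, size=(n_meta, n_coord))
    meta = pool[rows, np.arange(n_coord)]
    meta_errors = np.array([error_fn(meta[i]) for i in range(n_meta)])
    return float((1 + np.sum(meta_errors <= observed_error)) / (n_meta + 1))


def overall_score(p_param: float, p_predict: float) -> float:
    """Combined challenge score ``s = -ln(p_param * p_predict)``."""
    if not (0 < p_param <= 1) or not (0 < p_predict <= 1):
        raise DomainError("p-values must lie in (0, 1]")
    return float(-math.log(p_param * p_predict))


# ---------------------------------------------------------------------------
# batch scoring


def score_submissions(
    submissions,
    truth: ParameterSet,
    unknown_names,
    bundle_true: DataSetBundle | None = None,
    n_meta: int = DEFAULT_N_META,
    seed=0,
    variance_floor: float = DEFAULT_VARIANCE_FLOOR,
) -> list:
    """Score a pool of submissions against each other (the p-values are
    relative to the pool, as in a leaderboard).

    Submissions carrying ``predicted_means`` get a prediction error and a
    prediction p-value; the combined score needs both p-values.
    """
    unknown_names = tuple(unknown_names)
    truth_v = np.array([truth.value(n) for n in unknown_names])
    param_pool = np.stack([s.vector(unknown_names) for s in submissions])
    rng = np.random.default_rng(seed)
    seed_param, seed_pred = rng.integers(0, 2**31, size=2)

    have_pred = all(
        s.predicted_means is not None or s.prediction_error is not None
        for s in submissions
    ) and bundle_true is not None
    pred_pool = None
    if have_pred and all(s.predicted_means is not None for s in submissions):
        pred_pool = np.stack([s.predicted_means for s in submissions])

    reports = []
    for sub in submissions:
        est_v = sub.vector(unknown_names)
        per_name = squared_log_ratios(est_v, truth_v)
        e_param = float(np.mean(per_name))
        if len(submissions) >= 2:
            p_param = empirical_pvalue(
                e_param,
                param_pool,
                lambda v: param_error(v, truth_v),
                n_meta=n_meta,
                seed=seed_param,
            )
        else:
            p_param = None  # an empirical null needs a pool of submissions
        e_pred = p_pred = s_score = None
        per_class = {}
        n_excl = 0
        if have_pred:
            if sub.predicted_means is not None:
                e_pred, detail, n_excl = prediction_error(
                    sub.predicted_means,
                    bundle_true.means,
                    bundle_true.variances,
                    variance_floor=variance_floor,
                    return_detail=True,
                )
                per_class = prediction_error_by_class(
                    bundle_true, sub.predicted_means, variance_floor
                )
            else:
                e_pred = sub.prediction_error
            if pred_pool is not None and len(submissions) >= 2:
                p_pred = empirical_pvalue(
                    e_pred,
                    pred_pool,
                    lambda v: prediction_error(
                        v,
                        bundle_true.means,
                        bundle_true.variances,
                        variance_floor=variance_floor,
                    ),
                    n_meta=n_meta,
                    seed=seed_pred,
                )
            if p_param is not None and p_pred is not None:
                s_score = overall_score(p_param, p_pred)
        reports.append(
            ScoreReport(
                team=sub.team,
                e_param=e_param,
                e_predict=e_pred,
                p_param=p_param,
                p_predict=p_pred,
                s=s_score,
                per_name_error=dict(zip(unknown_names, per_name)),
                per_class_error=per_class,
                n_excluded_measurements=n_excl,
                n_meta=n_meta,
                seed=int(seed) if isinstance(seed, (int, np.integer)) else None,
            )
        )
    return reports


def leaderboard(reports) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "team": [r.team for r in reports],
            "e_param": [r.e_param for r in reports],
            "e_predict": [r.e_predict for r in reports],
            "p_param": [r.p_param for r in reports],
            "p_predict": [r.p_predict for r in reports],
            "s": [r.s for r in reports],
        }
    )
    by = "s" if df["s"].notna().all() else "e_param"
    ascending = by == "e_param"
    return df.sort_values(by, ascending=ascending).reset_index(drop=True)


# ---------------------------------------------------------------------------
# submission analytics


def per_parameter_errors(
    submissions,
    truth: ParameterSet,
    unknown_names,
    top_k: int = 50,
    scores=None,
) -> pd.DataFrame:
    """Per-name squared log10 ratios averaged over the ``top_k`` submissions
    (ranked by ``scores`` descending when given, else by parameter error
    ascending).  Returns a frame with a ``truncated`` attribute flag when
    fewer than ``top_k`` submissions exist."""
    unknown_names = tuple(unknown_names)
    truth_v = np.array([truth.value(n) for n in unknown_names])
    errs = np.stack(
        [squared_log_ratios(s.vector(unknown_names), truth_v) for s in submissions]
    )
    if scores is not None:
        order = np.argsort(-np.asarray(scores))
    else:
        order = np.argsort(errs.mean(axis=1))
    truncated = len(submissions) < top_k
    take = order[: min(top_k, len(submissions))]
    out = pd.DataFrame(
        {"name": unknown_names, "mean_sq_log10_error": errs[take].mean(axis=0)}
    )
    out.attrs["truncated"] = truncated
    return out


def coefficient_of_variation(cells: np.ndarray, zero_tol: float = 1e-12) -> pd.DataFrame:
    """Per-measurement sd/|mean| across cells (unbiased sd).

    Zero-mean measurements are flagged rather than divided.  ``cells`` is an
    (n_cells, M) table, e.g. ``DataSetBundle.cell_values``.
    """
    cells = np.asarray(cells, dtype=float)
    if cells.ndim != 2 or cells.shape[0] < 2:
        raise ContractError("need a table of at least two cells")
    mean = cells.mean(axis=0)
    sd = cells.std(axis=0, ddof=1)
    zero_mean = np.abs(mean) <= zero_tol
    cv = np.full(mean.shape, np.nan)
    cv[~zero_mean] = sd[~zero_mean] / np.abs(mean[~zero_mean])
    return pd.DataFrame({"mean": mean, "sd": sd, "cv": cv, "zero_mean": zero_mean})


def bundle_cv_by_class(bundle: DataSetBundle) -> pd.DataFrame:
    """Median coefficient of variation per data class across the bundle's
    stored per-cell table (cell-to-cell variability ranking)."""
    if bundle.cell_values is None:
        raise ContractError("bundle does not carry per-cell values")
    cv = coefficient_of_variation(bundle.cell_values)
    cv["data_class"] = bundle.registry["data_class"].to_numpy()
    return (
        cv.dropna(subset=["cv"])
        .groupby("data_class")["cv"]
        .median()
        .sort_values(ascending=False)
        .to_frame("median_cv")
    )


def parameter_error_correlation(submissions, unknown_names) -> pd.DataFrame:
    """Rank correlation between each unknown parameter's submitted value and
    the submission prediction error.

    Requires at least three submissions with prediction errors; constant
    columns are flagged undefined rather than reported as zero.
    """
    subs = [s for s in submissions if s.prediction_error is not None]
    if len(subs) < 3:
        frame = pd.DataFrame(
            {"name": tuple(unknown_names), "rho": np.nan, "defined": False}
        )
        frame.attrs["undefined"] = True
        return frame
    unknown_names = tuple(unknown_names)
    values = np.stack([s.vector(unknown_names) for s in subs])
    errors = np.array([s.prediction_error for s in subs])
    rows = []
    for j, name in enumerate(unknown_names):
        col = values[:, j]
        if np.all(col == col[0]) or np.all(errors == errors[0]):
            rows.append((name, np.nan, False))
        else:
            rho = spearmanr(col, errors).statistic
            rows.append((name, float(rho), True))
    frame = pd.DataFrame(rows, columns=["name", "rho", "defined"])
    frame.attrs["undefined"] = False
    return frame
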