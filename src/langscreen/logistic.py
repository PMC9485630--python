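"""Logistic risk modelling for the two screening stages.

Fitting is maximum likelihood (Newton/IRLS via statsmodels) with
standard errors from the observed information.  On top of the fits this
module provides the likelihood-ratio backward elimination used to build
the stage-1 model, Wald odds-ratio intervals, Nagelkerke's pseudo-R2,
and x-standardized coefficients.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

__all__ = [
    "EffectSummary",
    "LogisticFit",
    "SeparationError",
    "backward_eliminate_lr",
    "build_design",
    "fit_logistic",
    "lr_test",
    "nagelkerke_r2",
    "predict_frame",
    "predict_probability",
    "standardized_coefficients",
    "wald_or_ci",
]

EDUCATION_LEVELS = ("compulsory", "vocational", "university_entrance", "university")

#: Maximum |coefficient| beyond which a fit is treated as (quasi-)separated.
_SEPARATION_COEF = 20.0


class SeparationError(ValueError):
    """Complete or quasi-complete separation; plain ML estimates diverge.

    Penalized (Firth) regression would be the standard remedy; this
    package deliberately does not fit one and reports the offending
    predictor instead.
    """

    def __init__(self, message: str, column: str | None = None):
        super().__init__(message)
        self.column = column


@dataclass
class LogisticFit:
    """A fitted logistic risk model.

    ``predictor_names`` starts with ``"intercept"``; ``coefficients``
    and ``standard_errors`` align with it.  ``terms`` groups design
    columns into model terms (a categorical factor is one term with
    several dummy columns) for likelihood-ratio bookkeeping.
    """

    predictor_names: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    log_likelihood: float
    null_log_likelihood: float
    n: int
    converged: bool
    terms: dict[str, list[str]] = field(default_factory=dict)
    elimination_log: list[dict] = field(default_factory=list)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.standard_errors = np.asarray(self.standard_errors, dtype=float)
        if not (
            len(self.predictor_names)
            == len(self.coefficients)
            == len(self.standard_errors)
        ):
            raise ValueError("names, coefficients and standard errors must align")

    @property
    def coef(self) -> dict[str, float]:
        return dict(zip(self.predictor_names, self.coefficients))

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize the fit (enough to score new data without refitting)."""
        payload = {
            "predictor_names": self.predictor_names,
            "coefficients": self.coefficients.tolist(),
            "standard_errors": self.standard_errors.tolist(),
            "log_likelihood": self.log_likelihood,
            "null_log_likelihood": self.null_log_likelihood,
            "n": self.n,
            "converged": self.converged,
            "terms": self.terms,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "LogisticFit":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(
            predictor_names=payload["predictor_names"],
            coefficients=np.asarray(payload["coefficients"], dtype=float),
            standard_errors=np.asarray(payload["standard_errors"], dtype=float),
            log_likelihood=payload["log_likelihood"],
            null_log_likelihood=payload["null_log_likelihood"],
            n=payload["n"],
            converged=payload["converged"],
            terms={k: list(v) for k, v in payload.get("terms", {}).items()},
        )


@dataclass
class EffectSummary:
    """Odds ratio with Wald CI; optionally a standardized coefficient."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    standardized_b: float | None = None
    nagelkerke_r2: float | None = None


def build_design(
    df: pd.DataFrame, candidates: list[str]
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Expand cohort columns into a numeric design matrix (no intercept).

    ``parental_education`` becomes three dummies against the
    ``university`` reference; ``sex`` becomes an indicator for male;
    everything else is cast to float.  Returns the matrix and the
    term -> column mapping used by the LR elimination.
    """
    cols: dict[str, np.ndarray] = {}
    terms: dict[str, list[str]] = {}
    for cand in candidates:
        if cand == "parental_education":
            names = []
            for level in EDUCATION_LEVELS[:-1]:
                name = f"education_{level}"
                cols[name] = (df[cand] == level).to_numpy(dtype=float)
                names.append(name)
            terms[cand] = names
        elif cand == "sex":
            cols["sex_male"] = (df[cand] == "male").to_numpy(dtype=float)
            terms[cand] = ["sex_male"]
        else:
            cols[cand] = df[cand].to_numpy(dtype=float)
            terms[cand] = [cand]
    return pd.DataFrame(cols, index=df.index), terms


def _find_separating_column(X: pd.DataFrame, y: np.ndarray) -> str | None:
    """Cheap screen for a single column that completely separates y.

    Quasi-complete separation without a single separating column is
    caught after the fit by the diverging-coefficient check.
    """
    for name in X.columns:
        x = X[name].to_numpy(dtype=float)
        x1, x0 = x[y == 1], x[y == 0]
        if len(x1) == 0 or len(x0) == 0:
            continue
        if x1.min() > x0.max() or x1.max() < x0.min():
            return name
    return None


def fit_logistic(
    design: pd.DataFrame,
    outcome,
    terms: dict[str, list[str]] | None = None,
    tol: float = 1e-8,
    maxiter: int = 100,
) -> LogisticFit:
    """ML logistic fit of ``outcome`` on ``design`` plus an intercept.

    Raises
    ------
    SeparationError
        On complete/quasi-complete separation (diverging estimates),
        naming the offending predictor.
    ValueError
        On zero-variance predictors or a singular design.
    """
    y = np.asarray(outcome, dtype=float)
    if design.shape[0] != len(y):
        raise ValueError("design and outcome lengths differ")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    n, p = design.shape
    if n <= p + 1:
        raise ValueError(f"n={n} too small for {p} predictors plus intercept")
    variances = design.var(axis=0, ddof=0)
    dead = [c for c in design.columns if variances[c] == 0.0]
    if dead:
        raise ValueError(f"zero-variance predictor(s): {dead}")

    X = sm.add_constant(design.to_numpy(dtype=float), prepend=True)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix (collinear predictors)")

    sep = _find_separating_column(design, y)
    if sep is not None:
        raise SeparationError(
            f"complete separation by predictor '{sep}'; maximum-likelihood "
            "estimates do not exist (consider penalized/Firth regression)",
            column=sep,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, X)
        try:
            res = model.fit(method="newton", maxiter=maxiter, tol=tol, disp=False)
        except np.linalg.LinAlgError:
            # Newton's Hessian goes singular under near-separation; a
            # quasi-Newton pass still yields parameters so the
            # diverging column can be identified below.
            try:
                res = model.fit(method="bfgs", maxiter=5 * maxiter, disp=False)
            except Exception as exc:
                raise SeparationError(f"logistic fit failed: {exc}") from exc
        except Exception as exc:  # statsmodels raises on hard separation
            raise SeparationError(f"logistic fit failed: {exc}") from exc

    params = np.asarray(res.params, dtype=float)
    bse = np.asarray(res.bse, dtype=float)
    if len(params) > 1 and not np.all(np.isfinite(bse)):
        worst = design.columns[int(np.argmax(np.abs(params[1:])))]
        raise SeparationError(
            f"information matrix singular at the optimum (suspect '{worst}')",
            column=str(worst),
        )
    if len(params) > 1 and np.max(np.abs(params[1:])) > _SEPARATION_COEF:
        worst = design.columns[int(np.argmax(np.abs(params[1:])))]
        raise SeparationError(
            f"quasi-complete separation suspected (|b| > {_SEPARATION_COEF} "
            f"for predictor '{worst}')",
            column=str(worst),
        )

    q = y.mean()
    ll0 = n * (q * np.log(q) + (1 - q) * np.log(1 - q)) if 0 < q < 1 else 0.0
    names = ["intercept"] + list(design.columns)
    return LogisticFit(
        predictor_names=names,
        coefficients=params,
        standard_errors=bse,
        log_likelihood=float(res.llf),
        null_log_likelihood=float(ll0),
        n=n,
        converged=bool(res.mle_retvals.get("converged", False)),
        terms=terms or {c: [c] for c in design.columns},
    )


def lr_test(full: LogisticFit, reduced: LogisticFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fits: (chi2, df, p)."""
    stat = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    df = len(full.predictor_names) - len(reduced.predictor_names)
    if df <= 0:
        raise ValueError("models are not properly nested")
    return max(stat, 0.0), df, float(stats.chi2.sf(max(stat, 0.0), df))


def backward_eliminate_lr(
    design: pd.DataFrame,
    outcome,
    removal_alpha: float = 0.10,
    terms: dict[str, list[str]] | None = None,
) -> LogisticFit:
    """Stepwise backward elimination by likelihood-ratio tests.

    At each step the term with the largest single-term LR p-value above
    ``removal_alpha`` is removed (a multi-column categorical factor is
    removed as a whole) and the model refitted.  The returned fit
    carries an ``elimination_log`` of (term, LR chi2, df, p at removal).

    A term whose maximum-likelihood estimate diverges (separation, e.g.
    a rare category with no outcome events) cannot be kept in any
    model; it is removed immediately with a logged reason.
    """
    if terms is None:
        terms = {c: [c] for c in design.columns}
    active = dict(terms)
    log: list[dict] = []

    def fit_terms(term_map):
        cols = [c for t in term_map.values() for c in t]
        return fit_logistic(design[cols], outcome, terms=dict(term_map))

    def fit_active_dropping_separated():
        while True:
            try:
                return fit_terms(active)
            except SeparationError as exc:
                offender = next(
                    (t for t, cols in active.items() if exc.column in cols), None
                )
                if offender is None or len(active) <= 1:
                    raise
                log.append(
                    {"term": offender, "lr_chi2": np.nan, "df": len(active[offender]),
                     "p": np.nan, "reason": str(exc)}
                )
                del active[offender]

    current = fit_active_dropping_separated()
    while len(active) > 1:
        worst_name, worst_p, worst_stat, worst_df = None, -1.0, 0.0, 0
        separated_term = None
        for name in active:
            reduced_map = {k: v for k, v in active.items() if k != name}
            try:
                reduced = fit_terms(reduced_map)
            except SeparationError as exc:
                separated_term = next(
                    (t for t, cols in active.items() if exc.column in cols), None
                )
                if separated_term is None:
                    raise
                break
            stat, df, p = lr_test(current, reduced)
            if p > worst_p:
                worst_name, worst_p, worst_stat, worst_df = name, p, stat, df
        if separated_term is not None:
            log.append(
                {"term": separated_term, "lr_chi2": np.nan,
                 "df": len(active[separated_term]), "p": np.nan,
                 "reason": "estimate diverges (separation)"}
            )
            del active[separated_term]
            current = fit_active_dropping_separated()
            continue
        if worst_p <= removal_alpha:
            break
        log.append(
            {"term": worst_name, "lr_chi2": worst_stat, "df": worst_df, "p": worst_p}
        )
        del active[worst_name]
        current = fit_active_dropping_separated()
    current.elimination_log = log
    return current


def predict_probability(fit: LogisticFit, record_values) -> float:
    """Inverse-logit score for one predictor vector (intercept excluded)."""
    values = np.asarray(record_values, dtype=float)
    if values.shape != (len(fit.predictor_names) - 1,):
        raise ValueError(
            f"expected {len(fit.predictor_names) - 1} values for "
            f"{fit.predictor_names[1:]}, got shape {values.shape}"
        )
    eta = fit.coefficients[0] + values @ fit.coefficients[1:]
    return float(expit(eta))


def predict_frame(fit: LogisticFit, design: pd.DataFrame) -> np.ndarray:
    """Vectorized scores for a design matrix carrying the fit's columns."""
    missing = [c for c in fit.predictor_names[1:] if c not in design.columns]
    if missing:
        raise ValueError(f"design lacks predictor column(s): {missing}")
    X = design[fit.predictor_names[1:]].to_numpy(dtype=float)
    return expit(fit.coefficients[0] + X @ fit.coefficients[1:])


def wald_or_ci(b: float, se: float, level: float = 0.95) -> EffectSummary:
    """Odds ratio exp(b) with Wald interval exp(b +- z * se)."""
    if se <= 0:
        raise ValueError(f"standard error must be positive, got {se}")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return EffectSummary(
        odds_ratio=float(np.exp(b)),
        ci_low=float(np.exp(b - z * se)),
        ci_high=float(np.exp(b + z * se)),
    )


def nagelkerke_r2(fit: LogisticFit) -> float:
    """Nagelkerke's normalized Cox-Snell pseudo-R2."""
    if fit.n == 0:
        raise ValueError("fit has n=0")
    cox_snell = 1.0 - np.exp(
        (2.0 / fit.n) * (fit.null_log_likelihood - fit.log_likelihood)
    )
    max_cs = 1.0 - np.exp((2.0 / fit.n) * fit.null_log_likelihood)
    if max_cs == 0.0:
        return 0.0
    return float(cox_snell / max_cs)


def standardized_coefficients(
    fit: LogisticFit, design: pd.DataFrame, method: str = "x"
) -> dict[str, float]:
    """Standardized slopes ``b_j * SD(x_j)`` (sample SD, ddof=1).

    ``method="latent"`` additionally divides by the SD of the latent
    response implied by the fit, ``sqrt(var(X b) + pi^2 / 3)``.  The
    plain x-standardization is the default and is what the effect
    summaries report.
    """
    sds = design[fit.predictor_names[1:]].std(axis=0, ddof=1)
    if (sds == 0).any():
        raise ValueError(f"zero-variance predictor(s): {list(sds[sds == 0].index)}")
    std_b = {
        name: float(fit.coefficients[i + 1] * sds[name])
        for i, name in enumerate(fit.predictor_names[1:])
    }
    if method == "latent":
        eta = fit.coefficients[0] + design[fit.predictor_names[1:]].to_numpy(
            dtype=float
        ) @ np.asarray(fit.coefficients[1:])
        denom = np.sqrt(np.var(eta, ddof=1) + np.pi**2 / 3.0)
        std_b = {k: v / denom for k, v in std_b.items()}
    elif method != "x":
        raise ValueError(f"unknown standardization method {method!r}")
    return std_b
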