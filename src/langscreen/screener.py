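"""A scikit-learn style estimator for the two-stage risk screen.

``TwoStageScreener.fit`` reproduces the construction of the screen on a
training cohort: likelihood-ratio backward elimination over the stage-1
candidate predictors, a stage-1 probability cutoff targeting high
sensitivity, a stage-2 model (retained stage-1 predictors plus the
direct word-comprehension score) fitted to stage-1 failures only, the
composite two-stage score, and the two constrained risk-tier cutoffs
(high risk by a PPV floor, moderate risk by a sensitivity target).

The estimator composes with sklearn tooling: ``predict_proba`` returns
the composite SLD probability, ``predict`` the screen-positive
indicator at the combined moderate-or-high cutoff, and
``predict_tier`` the three-level risk grade.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .accuracy import compose_two_stage, cutoff_for_ppv, cutoff_for_sensitivity, stratify_risk
from .logistic import backward_eliminate_lr, build_design, fit_logistic, predict_frame

__all__ = ["TwoStageScreener", "StatisticalAbort", "DEFAULT_STAGE1_CANDIDATES"]

DEFAULT_STAGE1_CANDIDATES = (
    "parental_education",
    "sex",
    "age_months",
    "parental_concerns",
    "no_two_word",
    "vocab_count",
)

#: Minimum outcome events among stage-1 failures required to fit stage 2.
MIN_STAGE2_EVENTS = 10


class StatisticalAbort(RuntimeError):
    """The staged construction cannot proceed on this cohort."""


class TwoStageScreener(BaseEstimator, ClassifierMixin):
    """Two-stage predictive screen with risk grading.

    Parameters
    ----------
    stage1_candidates : sequence of str
        Cohort columns offered to the stage-1 backward elimination.
    stage2_extra : str
        Direct-assessment column added in stage 2 (only read for
        stage-1 failures).
    stage1_target_se : float
        Sensitivity target for the stage-1 referral cutoff (default
        0.90, so stage 2 sees ~90% of true cases).
    removal_alpha : float
        LR-test p-value above which a term is eliminated.
    high_risk_target_ppv : float
        PPV floor defining the high-risk cutoff (default 0.80).
    moderate_target_se : float
        Sensitivity target for the moderate-risk cutoff (default 0.75).
    fit_stage2_on : {"failures", "all"}
        Fit stage 2 on stage-1 failures only (the screening protocol)
        or on the full cohort (sensitivity analysis).
    """

    def __init__(
        self,
        stage1_candidates=DEFAULT_STAGE1_CANDIDATES,
        stage2_extra: str = "word_comprehension",
        stage1_target_se: float = 0.90,
        removal_alpha: float = 0.10,
        high_risk_target_ppv: float = 0.80,
        moderate_target_se: float = 0.75,
        ci_level: float = 0.95,
        fit_stage2_on: str = "failures",
        freeze_stage1_cutoff: float | None = None,
    ):
        self.stage1_candidates = stage1_candidates
        self.stage2_extra = stage2_extra
        self.stage1_target_se = stage1_target_se
        self.removal_alpha = removal_alpha
        self.high_risk_target_ppv = high_risk_target_ppv
        self.moderate_target_se = moderate_target_se
        self.ci_level = ci_level
        self.fit_stage2_on = fit_stage2_on
        self.freeze_stage1_cutoff = freeze_stage1_cutoff

    # ------------------------------------------------------------------
    def _validate_X(self, X: pd.DataFrame, need_stage2: bool = False) -> None:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a cohort DataFrame")
        needed = set(self.stage1_candidates)
        if need_stage2:
            needed.add(self.stage2_extra)
        missing = sorted(needed - set(X.columns))
        if missing:
            raise ValueError(f"cohort lacks column(s): {missing}")

    def fit(self, X: pd.DataFrame, y) -> "TwoStageScreener":
        """Construct the screen on a cohort with known age-3 outcomes."""
        self._validate_X(X, need_stage2=True)
        y = np.asarray(y).astype(int)
        for target, name in (
            (self.stage1_target_se, "stage1_target_se"),
            (self.high_risk_target_ppv, "high_risk_target_ppv"),
            (self.moderate_target_se, "moderate_target_se"),
        ):
            if not 0.0 < target < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {target}")
        if self.fit_stage2_on not in ("failures", "all"):
            raise ValueError("fit_stage2_on must be 'failures' or 'all'")

        design, terms = build_design(X, list(self.stage1_candidates))
        self.stage1_fit_ = backward_eliminate_lr(
            design, y, removal_alpha=self.removal_alpha, terms=terms
        )
        stage1_prob = predict_frame(self.stage1_fit_, design)

        if self.freeze_stage1_cutoff is not None:
            self.stage1_cutoff_ = float(self.freeze_stage1_cutoff)
            self.stage1_cutoff_result_ = None
        else:
            self.stage1_cutoff_result_ = cutoff_for_sensitivity(
                stage1_prob, y, self.stage1_target_se, self.ci_level
            )
            self.stage1_cutoff_ = self.stage1_cutoff_result_.cutoff

        fail = stage1_prob >= self.stage1_cutoff_
        subset = np.ones(len(y), dtype=bool) if self.fit_stage2_on == "all" else fail
        if y[subset].sum() < MIN_STAGE2_EVENTS:
            raise StatisticalAbort(
                f"only {int(y[subset].sum())} outcome events among stage-1 "
                f"failures; need >= {MIN_STAGE2_EVENTS} to fit stage 2"
            )
        stage2_cols = list(self.stage1_fit_.predictor_names[1:]) + [self.stage2_extra]
        stage2_design = design.copy()
        stage2_design[self.stage2_extra] = X[self.stage2_extra].to_numpy(dtype=float)
        if np.isnan(stage2_design.loc[subset, self.stage2_extra]).any():
            raise ValueError(
                "missing word-comprehension score for a stage-1 failure"
            )
        self.stage2_fit_ = fit_logistic(
            stage2_design.loc[subset, stage2_cols], y[subset]
        )

        stage2_prob = np.full(len(y), np.nan)
        stage2_prob[fail] = predict_frame(
            self.stage2_fit_, stage2_design.loc[fail, stage2_cols]
        )
        composed = compose_two_stage(stage1_prob, self.stage1_cutoff_, stage2_prob)
        total = composed["total_score"].to_numpy()

        self.high_cutoff_result_ = cutoff_for_ppv(
            total, y, self.high_risk_target_ppv, self.ci_level
        )
        self.moderate_cutoff_result_ = cutoff_for_sensitivity(
            total, y, self.moderate_target_se, self.ci_level
        )
        self.cut_high_ = self.high_cutoff_result_.cutoff
        self.cut_moderate_ = min(
            self.moderate_cutoff_result_.cutoff, self.cut_high_
        )
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = design.shape[1]
        self.training_scores_ = composed
        return self

    # ------------------------------------------------------------------
    def score_frame(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-child scores and risk tiers for a (new) cohort.

        Word comprehension is read only for stage-1 failures, so a
        cohort with the score masked for passes scores identically to
        the unmasked cohort.
        """
        self._check_fitted()
        self._validate_X(X, need_stage2=False)
        if len(X) == 0:
            return pd.DataFrame(
                columns=[
                    "stage1_prob",
                    "stage1_fail",
                    "stage2_prob",
                    "total_score",
                    "risk_tier",
                ]
            )
        design, _ = build_design(X, list(self.stage1_candidates))
        stage1_prob = predict_frame(self.stage1_fit_, design)
        fail = stage1_prob >= self.stage1_cutoff_
        stage2_prob = np.full(len(X), np.nan)
        if fail.any():
            if self.stage2_extra not in X.columns:
                raise ValueError(f"cohort lacks column(s): ['{self.stage2_extra}']")
            stage2_design = design.copy()
            stage2_design[self.stage2_extra] = X[self.stage2_extra].to_numpy(
                dtype=float
            )
            cols = self.stage2_fit_.predictor_names[1:]
            if np.isnan(stage2_design.loc[fail, self.stage2_extra]).any():
                raise ValueError(
                    "missing word-comprehension score for a stage-1 failure"
                )
            stage2_prob[fail] = predict_frame(
                self.stage2_fit_, stage2_design.loc[fail, cols]
            )
        composed = compose_two_stage(stage1_prob, self.stage1_cutoff_, stage2_prob)
        tiers, _ = stratify_risk(
            composed["total_score"], self.cut_high_, self.cut_moderate_
        )
        composed["risk_tier"] = tiers
        composed.index = X.index
        return composed

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        return self.score_frame(X)["total_score"].to_numpy()

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        total = self.decision_function(X)
        return np.column_stack([1.0 - total, total])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Screen-positive (moderate or high risk) indicator."""
        return (self.decision_function(X) >= self.cut_moderate_).astype(int)

    def predict_tier(self, X: pd.DataFrame) -> np.ndarray:
        return self.score_frame(X)["risk_tier"].to_numpy()

    def _check_fitted(self) -> None:
        if not hasattr(self, "stage1_fit_"):
            raise RuntimeError("TwoStageScreener is not fitted yet")
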