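"""End-to-end construction and validation of the two-stage screen.

``run_pipeline`` takes a cohort (simulated or loaded from CSV), fits
the staged models, estimates all constrained cutoffs, compares the
composite against the stage-1-only screen with paired ROC inference,
grades risk tiers, and validates the grading against the continuous
reference scales.  The output is a structured, JSON-serializable
report with stage-model tables, a tier accuracy table, flow counts and
the statistical comparisons; a seeded run is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .accuracy import (
    CutpointResult,
    compose_two_stage,
    confusion_at,
    cutoff_for_ppv,
    cutoff_for_sensitivity,
    diagnostic_stats,
    stratify_risk,
)
from .cohort import GeneratorConfig, generate_cohort, read_cohort_csv
from .logistic import (
    LogisticFit,
    build_design,
    nagelkerke_r2,
    predict_frame,
    standardized_coefficients,
    wald_or_ci,
)
from .roc import bootstrap_paired_test, delong_paired_test, mcnemar_paired, welch_anova
from .screener import DEFAULT_STAGE1_CANDIDATES, StatisticalAbort, TwoStageScreener

__all__ = [
    "PipelineConfig",
    "ValidationReport",
    "run_pipeline",
    "sample_comparison",
    "score_with_published_model",
]


@dataclass
class PipelineConfig:
    """Configuration of a full validation run.

    Exactly one of ``generator`` / ``cohort_csv`` supplies the cohort.
    """

    generator: GeneratorConfig | None = None
    cohort_csv: str | None = None
    stage1_candidates: tuple = DEFAULT_STAGE1_CANDIDATES
    stage1_target_se: float = 0.90
    high_risk_target_ppv: float = 0.80
    moderate_target_se: float = 0.75
    removal_alpha: float = 0.10
    ci_level: float = 0.95
    n_boot: int = 2000
    seed: int = 0
    freeze_stage1_cutoff: float | None = None
    fit_stage2_on: str = "failures"
    output_dir: str | None = None

    def __post_init__(self):
        if (self.generator is None) == (self.cohort_csv is None):
            raise ValueError("provide exactly one of generator / cohort_csv")
        for t in (self.stage1_target_se, self.high_risk_target_ppv, self.moderate_target_se):
            if not 0.0 < t < 1.0:
                raise ValueError(f"targets must lie in (0, 1), got {t}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = raw.pop("generator", None)
        cfg = cls(
            generator=GeneratorConfig(**gen) if gen is not None else None,
            **raw,
        )
        return cfg


@dataclass
class ValidationReport:
    """All artifacts of one validation run (JSON-serializable)."""

    n: int
    n_dropped: int
    prevalence: float
    sample_table: dict
    stage1_table: dict
    stage2_table: dict
    stage1_cutoff: float
    stage1_stats: dict
    tier_table: list
    flow: dict
    roc_comparison: dict
    paired_tests: dict
    group_comparison: dict
    decisions_log: list
    config: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, allow_nan=True)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(self.to_json() + "\n")
        pd.DataFrame(self.tier_table).to_csv(outdir / "tier_table.csv", index=False)
        for name in ("stage1_table", "stage2_table"):
            pd.DataFrame(getattr(self, name)["rows"]).to_csv(
                outdir / f"{name}.csv", index=False
            )


def _estimate_dict(est) -> dict:
    return {"value": est.value, "ci_low": est.ci_low, "ci_high": est.ci_high}


def _stats_dict(ds) -> dict:
    return {
        "sensitivity": _estimate_dict(ds.sensitivity),
        "specificity": _estimate_dict(ds.specificity),
        "ppv": _estimate_dict(ds.ppv),
        "npv": _estimate_dict(ds.npv),
        "dlr_pos": _estimate_dict(ds.dlr_pos),
        "dlr_neg": _estimate_dict(ds.dlr_neg),
        "fail_rate": ds.fail_rate,
    }


def _model_table(fit: LogisticFit, design: pd.DataFrame, ci_level: float) -> dict:
    std_b = standardized_coefficients(fit, design)
    rows = []
    for i, name in enumerate(fit.predictor_names):
        b = float(fit.coefficients[i])
        se = float(fit.standard_errors[i])
        row = {"term": name, "b": b, "se": se}
        if name != "intercept":
            eff = wald_or_ci(b, se, ci_level)
            z = b / se if se > 0 else np.nan
            row.update(
                odds_ratio=eff.odds_ratio,
                or_ci_low=eff.ci_low,
                or_ci_high=eff.ci_high,
                standardized_b=std_b[name],
                wald_p=float(2 * stats.norm.sf(abs(z))),
            )
        rows.append(row)
    return {
        "rows": rows,
        "nagelkerke_r2": nagelkerke_r2(fit),
        "log_likelihood": fit.log_likelihood,
        "n": fit.n,
        "eliminated": [e["term"] for e in fit.elimination_log],
    }


def _tier_entry(label: str, result: CutpointResult, n: int) -> dict:
    return {
        "screen": label.split("/")[0],
        "risk_level": label.split("/")[1],
        "cutoff": result.cutoff,
        "target_met": result.target_met,
        **{
            k: (v["value"] if isinstance(v, dict) else v)
            for k, v in _stats_dict(result.stats).items()
        },
        "stats": _stats_dict(result.stats),
    }


def run_pipeline(config: PipelineConfig) -> ValidationReport:
    """Execute the full construction-and-validation analysis."""
    decisions: list[str] = []
    if config.generator is not None:
        cohort = generate_cohort(config.generator)
        source = f"generator(seed={config.generator.seed}, n={config.generator.n})"
    else:
        cohort = read_cohort_csv(config.cohort_csv)
        source = str(config.cohort_csv)

    # Listwise deletion: stage-1 predictors and outcome must be complete.
    needed = [c for c in config.stage1_candidates] + ["sld_age3"]
    complete = cohort[needed].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        decisions.append(f"dropped {n_dropped} records with incomplete stage-1 data")
    df = cohort[complete].reset_index(drop=True)
    y = df["sld_age3"].to_numpy().astype(int)

    screener = TwoStageScreener(
        stage1_candidates=config.stage1_candidates,
        stage1_target_se=config.stage1_target_se,
        removal_alpha=config.removal_alpha,
        high_risk_target_ppv=config.high_risk_target_ppv,
        moderate_target_se=config.moderate_target_se,
        ci_level=config.ci_level,
        fit_stage2_on=config.fit_stage2_on,
        freeze_stage1_cutoff=config.freeze_stage1_cutoff,
    )

    # Failures with a missing stage-2 assessment cannot be scored; they
    # are dropped with a logged count before the final fit.
    wc_missing = df["word_comprehension"].isna().to_numpy()
    if wc_missing.any():
        d1, t1 = build_design(df, list(config.stage1_candidates))
        from .logistic import backward_eliminate_lr

        pre_fit = backward_eliminate_lr(d1, y, config.removal_alpha, t1)
        pre_prob = predict_frame(pre_fit, d1)
        if config.freeze_stage1_cutoff is not None:
            pre_cut = config.freeze_stage1_cutoff
        else:
            pre_cut = cutoff_for_sensitivity(
                pre_prob, y, config.stage1_target_se, config.ci_level
            ).cutoff
        drop2 = wc_missing & (pre_prob >= pre_cut)
        if drop2.any():
            decisions.append(
                f"dropped {int(drop2.sum())} stage-1 failures lacking the "
                "word-comprehension assessment"
            )
            n_dropped += int(drop2.sum())
            df = df[~drop2].reset_index(drop=True)
            y = df["sld_age3"].to_numpy().astype(int)

    try:
        screener.fit(df, y)
    except StatisticalAbort:
        raise

    for entry in screener.stage1_fit_.elimination_log:
        decisions.append(
            f"stage 1: eliminated '{entry['term']}' "
            f"(LR chi2={entry['lr_chi2']:.3f}, p={entry['p']:.4f})"
        )
    decisions.append(f"stage-1 cutoff {screener.stage1_cutoff_:.6f}")
    if not screener.high_cutoff_result_.target_met:
        decisions.append(
            "warning: no cutoff reached the PPV target; reporting max-PPV cutoff"
        )

    scores = screener.training_scores_
    stage1_prob = scores["stage1_prob"].to_numpy()
    total = scores["total_score"].to_numpy()

    design_now, _ = build_design(df, list(config.stage1_candidates))
    stage2_design = design_now.copy()
    stage2_design["word_comprehension"] = df["word_comprehension"].to_numpy(dtype=float)
    stage1_table = _model_table(
        screener.stage1_fit_, design_now, config.ci_level
    )
    stage2_subset = (
        scores["stage1_fail"].to_numpy()
        if config.fit_stage2_on == "failures"
        else np.ones(len(df), dtype=bool)
    )
    stage2_table = _model_table(
        screener.stage2_fit_,
        stage2_design.loc[stage2_subset],
        config.ci_level,
    )

    stage1_stats = diagnostic_stats(
        confusion_at(stage1_prob, y, screener.stage1_cutoff_), config.ci_level
    )

    # Tier accuracy table for both screens at all three cutoff targets.
    tier_table = []
    for label, s in (("one_stage", stage1_prob), ("two_stage", total)):
        tier_table.append(
            _tier_entry(f"{label}/high", cutoff_for_ppv(s, y, config.high_risk_target_ppv, config.ci_level), len(y))
        )
        tier_table.append(
            _tier_entry(
                f"{label}/moderate_plus_high",
                cutoff_for_sensitivity(s, y, config.moderate_target_se, config.ci_level),
                len(y),
            )
        )

    tiers, tier_summary = stratify_risk(
        total, screener.cut_high_, screener.cut_moderate_, y, config.ci_level
    )
    flow = {
        "n": len(y),
        "sld_total": int(y.sum()),
        "no_sld_total": int(len(y) - y.sum()),
        "stage1_failures": int(scores["stage1_fail"].sum()),
        "screen_negative": int(np.sum(tiers == "low")),
        "tiers": tier_summary.to_dict(orient="records"),
    }

    delong = delong_paired_test(total, stage1_prob, y, config.ci_level)
    boot = bootstrap_paired_test(
        total, stage1_prob, y, n_boot=config.n_boot, seed=config.seed
    )

    # Paired McNemar comparisons at the matched tier cutoffs.
    one_high = cutoff_for_ppv(stage1_prob, y, config.high_risk_target_ppv).cutoff
    two_high = screener.cut_high_
    one_mod = cutoff_for_sensitivity(stage1_prob, y, config.moderate_target_se).cutoff
    two_mod = screener.cut_moderate_
    diseased = y == 1
    healthy = ~diseased
    paired_tests = {}
    try:
        mc_se = mcnemar_paired(
            (total >= two_high)[diseased], (stage1_prob >= one_high)[diseased]
        )
        paired_tests["sensitivity_high_risk"] = dataclasses.asdict(mc_se)
    except ValueError as exc:
        paired_tests["sensitivity_high_risk"] = {"undefined": str(exc)}
    try:
        mc_sp = mcnemar_paired(
            (total < two_mod)[healthy], (stage1_prob < one_mod)[healthy]
        )
        paired_tests["specificity_moderate"] = dataclasses.asdict(mc_sp)
    except ValueError as exc:
        paired_tests["specificity_moderate"] = {"undefined": str(exc)}

    group_comparison = {}
    for scale in ("ref_vocab_z", "ref_grammar_z"):
        groups = {
            tier: df.loc[tiers == tier, scale].to_numpy()
            for tier in ("low", "moderate", "high")
            if np.sum(tiers == tier) >= 2
        }
        try:
            gc = welch_anova(groups)
            group_comparison[scale] = dataclasses.asdict(gc)
        except ValueError as exc:
            group_comparison[scale] = {"undefined": str(exc)}

    report = ValidationReport(
        n=len(y),
        n_dropped=n_dropped,
        prevalence=float(y.mean()),
        sample_table=_describe_sample(df),
        stage1_table=stage1_table,
        stage2_table=stage2_table,
        stage1_cutoff=float(screener.stage1_cutoff_),
        stage1_stats=_stats_dict(stage1_stats),
        tier_table=tier_table,
        flow=flow,
        roc_comparison={
            "delong": dataclasses.asdict(delong),
            "bootstrap": dataclasses.asdict(boot),
        },
        paired_tests=paired_tests,
        group_comparison=group_comparison,
        decisions_log=decisions,
        config={
            "source": source,
            "stage1_candidates": list(config.stage1_candidates),
            "stage1_target_se": config.stage1_target_se,
            "high_risk_target_ppv": config.high_risk_target_ppv,
            "moderate_target_se": config.moderate_target_se,
            "removal_alpha": config.removal_alpha,
            "ci_level": config.ci_level,
            "n_boot": config.n_boot,
            "seed": config.seed,
        },
    )
    if config.output_dir is not None:
        report.write(config.output_dir)
    return report


def _describe_sample(df: pd.DataFrame) -> dict:
    return {
        "n": len(df),
        "age_mean": float(df["age_months"].mean()),
        "age_sd": float(df["age_months"].std(ddof=1)),
        "male_pct": float((df["sex"] == "male").mean() * 100),
        "education_pct": {
            k: float(v * 100)
            for k, v in df["parental_education"].value_counts(normalize=True).items()
        },
        "vocab_mean": float(df["vocab_count"].mean()),
        "vocab_sd": float(df["vocab_count"].std(ddof=1)),
        "no_two_word_pct": float(df["no_two_word"].mean() * 100),
        "concerns_pct": float(df["parental_concerns"].mean() * 100),
        "comprehension_mean": float(df["word_comprehension"].mean()),
        "comprehension_sd": float(df["word_comprehension"].std(ddof=1)),
        "sld_pct": float(df["sld_age3"].mean() * 100),
    }


def sample_comparison(sample_a: pd.DataFrame, sample_b: pd.DataFrame) -> pd.DataFrame:
    """Representativeness check between two cohorts.

    Categorical fields: chi-square test with phi (2 levels) or Cramer's
    V; continuous fields: two-sample t-test with pooled-SD Cohen's d.
    """
    if len(sample_a) == 0 or len(sample_b) == 0:
        raise ValueError("empty cohort")
    categorical = ["sex", "parental_education", "no_two_word", "parental_concerns", "sld_age3"]
    continuous = ["age_months", "vocab_count", "word_comprehension"]
    rows = []
    for col in categorical:
        a = sample_a[col]
        b = sample_b[col]
        levels = sorted(set(a.unique()) | set(b.unique()), key=str)
        table = np.array(
            [[np.sum(a == lv) for lv in levels], [np.sum(b == lv) for lv in levels]]
        )
        table = table[:, table.sum(axis=0) > 0]
        if table.shape[1] < 2:
            chi2, p, effect, name = 0.0, 1.0, 0.0, "phi"
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            n = table.sum()
            if table.shape[1] == 2:
                effect, name = float(np.sqrt(chi2 / n)), "phi"
            else:
                k = min(table.shape) - 1
                effect, name = float(np.sqrt(chi2 / (n * k))), "cramers_v"
        rows.append(
            {"field": col, "test": "chi2", "statistic": float(chi2), "p": float(p),
             "effect_size": effect, "effect_name": name}
        )
    for col in continuous:
        a = sample_a[col].dropna().to_numpy(dtype=float)
        b = sample_b[col].dropna().to_numpy(dtype=float)
        t, p = stats.ttest_ind(a, b, equal_var=True)
        na, nb = len(a), len(b)
        pooled = np.sqrt(
            ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        )
        d = float((a.mean() - b.mean()) / pooled) if pooled > 0 else 0.0
        rows.append(
            {"field": col, "test": "t", "statistic": float(t), "p": float(p),
             "effect_size": d, "effect_name": "cohens_d"}
        )
    return pd.DataFrame(rows)


def score_with_published_model(
    cohort: pd.DataFrame,
    stage1_fit: LogisticFit | str | Path,
    stage2_fit: LogisticFit | str | Path,
    stage1_cutoff: float,
    cut_high: float,
    cut_moderate: float,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Score a cohort with frozen (published) coefficients; no refitting.

    Returns the per-child score frame and, when the cohort carries the
    outcome, a tier summary.
    """
    if not isinstance(stage1_fit, LogisticFit):
        stage1_fit = LogisticFit.from_json(stage1_fit)
    if not isinstance(stage2_fit, LogisticFit):
        stage2_fit = LogisticFit.from_json(stage2_fit)
    if len(cohort) == 0:
        empty = pd.DataFrame(
            columns=["stage1_prob", "stage1_fail", "stage2_prob", "total_score", "risk_tier"]
        )
        return empty, None

    candidates = []
    for name in stage1_fit.predictor_names[1:] + stage2_fit.predictor_names[1:]:
        cand = (
            "parental_education"
            if name.startswith("education_")
            else ("sex" if name == "sex_male" else name)
        )
        if cand not in candidates:
            candidates.append(cand)
    missing = [c for c in candidates if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort lacks predictor column(s): {missing}")
    design, _ = build_design(cohort, candidates)

    stage1_prob = predict_frame(stage1_fit, design)
    fail = stage1_prob >= stage1_cutoff
    stage2_prob = np.full(len(cohort), np.nan)
    if fail.any():
        if np.isnan(design.loc[fail, stage2_fit.predictor_names[1:]].to_numpy()).any():
            raise ValueError("missing stage-2 predictor value for a stage-1 failure")
        stage2_prob[fail] = predict_frame(stage2_fit, design.loc[fail])
    composed = compose_two_stage(stage1_prob, stage1_cutoff, stage2_prob)
    labels = (
        cohort["sld_age3"].to_numpy().astype(int) if "sld_age3" in cohort.columns else None
    )
    tiers, summary = stratify_risk(
        composed["total_score"], cut_high, cut_moderate, labels
    )
    composed["risk_tier"] = tiers
    composed.index = cohort.index
    return composed, summary
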