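"""Synthetic screening cohorts with a one-factor latent-ability structure.

The simulator emulates a community sample of two-year-olds screened for
risk of a significant language deficit (SLD) one year later.  A single
latent language ability at age 2 (``L2``, standard normal) drives every
language-related observable; ability at age 3 is an AR(1)-style mixture
``L3 = rho * L2 + sqrt(1 - rho^2) * noise`` whose lower tail (calibrated
to the target prevalence) defines the SLD outcome.  Bounded count scores
(expressive-vocabulary word list, word-comprehension subtest) are
binomial with a logistic-normal success probability; binary flags
(no two-word combinations, parental concerns) are Bernoulli with a
logit linear in ``L2``.  Sociodemographics are independent of ability by
default, which makes them planted null predictors for variable-selection
experiments.

Marginal calibration (rates, means, SDs) is done by Gauss-Hermite
quadrature over the latent distribution, so large simulated cohorts hit
the configured targets in expectation, not merely approximately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

__all__ = [
    "COHORT_COLUMNS",
    "EDUCATION_LEVELS",
    "ChildRecord",
    "CohortValidationError",
    "GeneratorConfig",
    "ItemMatrix",
    "generate_cohort",
    "generate_item_matrix",
    "read_cohort_csv",
    "write_cohort_csv",
]

EDUCATION_LEVELS = ("compulsory", "vocational", "university_entrance", "university")

COHORT_COLUMNS = (
    "child_id",
    "age_months",
    "sex",
    "parental_education",
    "vocab_count",
    "no_two_word",
    "parental_concerns",
    "word_comprehension",
    "sld_age3",
    "ref_vocab_z",
    "ref_grammar_z",
)

VOCAB_ITEMS = 37
COMPREHENSION_ITEMS = 9

# Age distribution on {23, 24, 25} months matching the reported sample
# mean 23.92 and SD 0.972 exactly (the SD forces mass to the endpoints).
_AGE_PROBS = (0.5155, 0.049, 0.4355)
_SEX_MALE_RATE = 0.518
_EDUCATION_PROBS = (0.014, 0.470, 0.258, 0.258)

# 61-node Gauss-Hermite rule for expectations over a standard normal.
_GH_X, _GH_W = np.polynomial.hermite_e.hermegauss(61)
_GH_W = _GH_W / np.sqrt(2.0 * np.pi)


class CohortValidationError(ValueError):
    """Raised when a cohort table violates the schema, with row-level detail."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        preview = "; ".join(self.problems[:10])
        more = "" if len(self.problems) <= 10 else f" (+{len(self.problems) - 10} more)"
        super().__init__(f"cohort validation failed: {preview}{more}")


@dataclass(frozen=True)
class ChildRecord:
    """One screened child.

    ``word_comprehension`` may be missing (``None``) for children who
    passed stage 1 in data collected under the real two-stage protocol;
    the simulator always generates it and lets the pipeline mask it.
    """

    child_id: str
    age_months: int
    sex: str
    parental_education: str
    vocab_count: int
    no_two_word: bool
    parental_concerns: bool
    word_comprehension: int | None
    sld_age3: bool
    ref_vocab_z: float
    ref_grammar_z: float


@dataclass
class GeneratorConfig:
    """Parameters of the generative cohort model.

    Parameters
    ----------
    n : int
        Cohort size.
    seed : int
        Seed for the numpy Generator; identical config+seed reproduces
        the cohort field-for-field.
    latent_stability_rho : float in [0, 1]
        Correlation between age-2 and age-3 latent ability.  The default
        0.6 reflects the well-documented instability of early language
        trajectories (roughly half of late talkers catch up by age 3).
    target_prevalence : float in (0, 1)
        SLD rate at age 3; the latent age-3 score below its
        ``target_prevalence`` quantile defines the outcome.
    loadings : dict
        Log-odds change per 1 SD of age-2 ability for the binary flags
        (negative: low ability raises the flag rate), correlations of
        the reference scales with age-3 ability, and
        ``comprehension_direct``: the weight with which the directly
        assessed word-comprehension score mixes in the age-3 innovation
        (receptive language taps persistence of the deficit, which the
        parent-reported expressive measures do not see; 0 restores a
        strict one-factor structure).
    marginal_targets : dict
        Population rates / moments the calibration reproduces.
    overdispersion : float >= 0
        SD of extra per-child logit noise added to the two bounded count
        scores; 0 (default) keeps the calibrated marginals exact.
    """

    n: int
    seed: int = 0
    latent_stability_rho: float = 0.6
    target_prevalence: float = 0.113
    loadings: dict = field(
        default_factory=lambda: {
            "no_two_word": -2.5,
            "parental_concerns": -2.0,
            "comprehension_direct": 0.5,
            "ref_vocab": 0.9,
            "ref_grammar": 0.9,
        }
    )
    marginal_targets: dict = field(
        default_factory=lambda: {
            "no_two_word_rate": 0.056,
            "concerns_rate": 0.124,
            "comprehension_mean": 6.86,
            "comprehension_sd": 1.80,
            "vocab_mean": 20.0,
            "vocab_sd": 9.0,
        }
    )
    overdispersion: float = 0.0

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if not 0.0 <= self.latent_stability_rho <= 1.0:
            raise ValueError(
                f"latent_stability_rho must be in [0, 1], got {self.latent_stability_rho}"
            )
        if not 0.0 < self.target_prevalence < 1.0:
            raise ValueError(
                f"target_prevalence must be in (0, 1), got {self.target_prevalence}"
            )
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")


@dataclass
class ItemMatrix:
    """Binary word-production responses, one row per child.

    ``responses`` has one 0/1 column per item (``item_000``, ...);
    ``child_id`` and ``age_months`` align row-wise with the cohort
    generated from the same config (both draw the latent ability as the
    first variate from the seeded generator).
    """

    child_id: pd.Series
    age_months: pd.Series
    responses: pd.DataFrame

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]


def _latent_mean(f) -> float:
    """E[f(L)] for L ~ N(0,1) by Gauss-Hermite quadrature."""
    return float(np.sum(_GH_W * f(_GH_X)))


def _calibrate_bernoulli(rate: float, loading: float) -> float:
    """Intercept a with E[expit(a + loading * L)] == rate."""

    def gap(a):
        return _latent_mean(lambda x: expit(a + loading * x)) - rate

    return float(optimize.brentq(gap, -40.0, 40.0, xtol=1e-12))


def _binomial_moments(k: int, a: float, b: float) -> tuple[float, float]:
    """Mean and variance of Binomial(k, expit(a + b L)), L ~ N(0,1)."""
    p = expit(a + b * _GH_X)
    ep = float(np.sum(_GH_W * p))
    ep2 = float(np.sum(_GH_W * p * p))
    mean = k * ep
    var = k * (ep - ep2) + k * k * (ep2 - ep * ep)
    return mean, var


def _calibrate_binomial(k: int, mean: float, sd: float) -> tuple[float, float]:
    """Solve (a, b) so the logistic-normal binomial hits (mean, sd)."""

    def residual(theta):
        m, v = _binomial_moments(k, theta[0], theta[1])
        return [m - mean, np.sqrt(v) - sd]

    x0 = np.array([logit(np.clip(mean / k, 1e-6, 1 - 1e-6)), 1.0])
    sol = optimize.least_squares(residual, x0, bounds=([-20.0, 0.0], [20.0, 20.0]))
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-6:
        raise ValueError(
            f"cannot calibrate Binomial({k}) to mean={mean}, sd={sd}: "
            f"residual {sol.fun}"
        )
    return float(sol.x[0]), float(sol.x[1])


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Simulate a screening cohort.

    Returns a DataFrame with exactly :data:`COHORT_COLUMNS`.  The
    word-comprehension score is generated for every child; masking it
    for stage-1 passes (the real two-stage protocol) is the pipeline's
    job, not the generator's.
    """
    config.validate()
    tg = config.marginal_targets
    rng = np.random.default_rng(config.seed)
    n = config.n
    rho = config.latent_stability_rho

    l2 = rng.standard_normal(n)
    innovation = rng.standard_normal(n)
    l3 = rho * l2 + np.sqrt(1.0 - rho * rho) * innovation
    sld = l3 < stats.norm.ppf(config.target_prevalence)

    a_v, b_v = _calibrate_binomial(VOCAB_ITEMS, tg["vocab_mean"], tg["vocab_sd"])
    a_c, b_c = _calibrate_binomial(
        COMPREHENSION_ITEMS, tg["comprehension_mean"], tg["comprehension_sd"]
    )
    # The direct comprehension assessment taps, with weight w, the part
    # of age-3 ability the parent-reported measures cannot see.
    w = config.loadings.get("comprehension_direct", 0.0)
    l_comp = (l2 + w * innovation) / np.sqrt(1.0 + w * w)
    od = config.overdispersion
    extra_v = od * rng.standard_normal(n) if od > 0 else 0.0
    extra_c = od * rng.standard_normal(n) if od > 0 else 0.0
    vocab = rng.binomial(VOCAB_ITEMS, expit(a_v + b_v * l2 + extra_v))
    comprehension = rng.binomial(
        COMPREHENSION_ITEMS, expit(a_c + b_c * l_comp + extra_c)
    )

    a_ntw = _calibrate_bernoulli(tg["no_two_word_rate"], config.loadings["no_two_word"])
    a_pc = _calibrate_bernoulli(tg["concerns_rate"], config.loadings["parental_concerns"])
    no_two_word = rng.random(n) < expit(a_ntw + config.loadings["no_two_word"] * l2)
    concerns = rng.random(n) < expit(a_pc + config.loadings["parental_concerns"] * l2)

    age = rng.choice([23, 24, 25], size=n, p=_AGE_PROBS)
    sex = np.where(rng.random(n) < _SEX_MALE_RATE, "male", "female")
    education = rng.choice(EDUCATION_LEVELS, size=n, p=_EDUCATION_PROBS)

    lam_v = config.loadings["ref_vocab"]
    lam_g = config.loadings["ref_grammar"]
    ref_vocab = lam_v * l3 + np.sqrt(1.0 - lam_v * lam_v) * rng.standard_normal(n)
    ref_grammar = lam_g * l3 + np.sqrt(1.0 - lam_g * lam_g) * rng.standard_normal(n)

    return pd.DataFrame(
        {
            "child_id": [f"C{i:06d}" for i in range(n)],
            "age_months": age.astype(int),
            "sex": sex,
            "parental_education": education,
            "vocab_count": vocab.astype(int),
            "no_two_word": no_two_word,
            "parental_concerns": concerns,
            "word_comprehension": comprehension.astype(float),
            "sld_age3": sld,
            "ref_vocab_z": ref_vocab,
            "ref_grammar_z": ref_grammar,
        }
    )


def item_difficulties(n_items: int, scale: float = 1.5) -> np.ndarray:
    """Default per-item difficulties: normal quantiles spread by `scale`.

    A wide spread guarantees that some items fall under any reasonable
    usage threshold while others are near-universal.
    """
    q = (np.arange(n_items) + 0.5) / n_items
    return scale * stats.norm.ppf(q)


def expected_endorsement(difficulty: float, slope: float = 1.3) -> float:
    """Closed-form endorsement rate E[expit(slope * (L - difficulty))]."""
    if np.isposinf(difficulty):
        return 0.0
    if np.isneginf(difficulty):
        return 1.0
    return _latent_mean(lambda x: expit(slope * (x - difficulty)))


def generate_item_matrix(
    config: GeneratorConfig,
    n_items: int = 260,
    difficulties: np.ndarray | None = None,
    slope: float = 1.3,
) -> ItemMatrix:
    """Simulate the full word-production checklist.

    Endorsement of item ``j`` by child ``i`` is Bernoulli with
    ``P = expit(slope * (L2_i - d_j))``.  The latent ability is drawn as
    the first variate from the seeded generator, so the rows align with
    :func:`generate_cohort` run on the same config.
    """
    config.validate()
    if n_items < 1:
        raise ValueError(f"n_items must be >= 1, got {n_items}")
    if difficulties is None:
        difficulties = item_difficulties(n_items)
    difficulties = np.asarray(difficulties, dtype=float)
    if difficulties.shape != (n_items,):
        raise ValueError("difficulties must have length n_items")

    rng = np.random.default_rng(config.seed)
    n = config.n
    l2 = rng.standard_normal(n)
    with np.errstate(invalid="ignore"):
        probs = expit(slope * (l2[:, None] - difficulties[None, :]))
    probs = np.nan_to_num(probs, nan=0.0)  # inf - inf guard for degenerate items
    responses = (rng.random((n, n_items)) < probs).astype(int)
    age = rng.choice([23, 24, 25], size=n, p=_AGE_PROBS)

    cols = [f"item_{j:03d}" for j in range(n_items)]
    return ItemMatrix(
        child_id=pd.Series([f"C{i:06d}" for i in range(n)], name="child_id"),
        age_months=pd.Series(age.astype(int), name="age_months"),
        responses=pd.DataFrame(responses, columns=cols),
    )


def _validate_cohort_frame(df: pd.DataFrame) -> list[str]:
    problems: list[str] = []
    unknown = [c for c in df.columns if c not in COHORT_COLUMNS]
    if unknown:
        problems.append(f"unknown columns: {unknown}")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        problems.append(f"missing columns: {missing}")
    if problems:
        return problems
    if len(df) == 0:
        return ["no records"]

    def flag(mask, message):
        for row in df.index[np.asarray(mask)][:50]:
            problems.append(f"row {row}: {message}")

    flag(~df["age_months"].isin([23, 24, 25]), "age_months outside [23, 25]")
    flag(~df["sex"].isin(["male", "female"]), "sex not in {male, female}")
    flag(
        ~df["parental_education"].isin(EDUCATION_LEVELS),
        "parental_education not a recognized level",
    )
    flag(
        (df["vocab_count"] < 0) | (df["vocab_count"] > VOCAB_ITEMS),
        f"vocab_count outside [0, {VOCAB_ITEMS}]",
    )
    wc = df["word_comprehension"]
    flag(
        wc.notna() & ((wc < 0) | (wc > COMPREHENSION_ITEMS)),
        f"word_comprehension outside [0, {COMPREHENSION_ITEMS}]",
    )
    for col in ("no_two_word", "parental_concerns", "sld_age3"):
        flag(~df[col].isin([0, 1]), f"{col} not binary 0/1")
    return problems


def write_cohort_csv(records: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table; booleans as 0/1, missing comprehension empty."""
    df = records.copy()
    for col in ("no_two_word", "parental_concerns", "sld_age3"):
        df[col] = df[col].astype(int)
    df = df[list(COHORT_COLUMNS)]
    df.to_csv(
        path, index=False, float_format="%.10g", na_rep="", lineterminator="\n"
    )


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort table written by :func:`write_cohort_csv`.

    Raises :class:`CohortValidationError` with row-level diagnostics on
    schema violations; an empty table is rejected ("no records").
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise CohortValidationError(["no records"]) from None
    problems = _validate_cohort_frame(df)
    if problems:
        raise CohortValidationError(problems)
    out = df.copy()
    out["child_id"] = out["child_id"].astype(str)
    out["age_months"] = out["age_months"].astype(int)
    out["vocab_count"] = out["vocab_count"].astype(int)
    for col in ("no_two_word", "parental_concerns", "sld_age3"):
        out[col] = out[col].astype(bool)
    out["word_comprehension"] = out["word_comprehension"].astype(float)
    return out


def records_from_frame(df: pd.DataFrame) -> list[ChildRecord]:
    """View a cohort table as typed records."""
    out = []
    for row in df.itertuples(index=False):
        wc = row.word_comprehension
        out.append(
            ChildRecord(
                child_id=str(row.child_id),
                age_months=int(row.age_months),
                sex=row.sex,
                parental_education=row.parental_education,
                vocab_count=int(row.vocab_count),
                no_two_word=bool(row.no_two_word),
                parental_concerns=bool(row.parental_concerns),
                word_comprehension=None if pd.isna(wc) else int(wc),
                sld_age3=bool(row.sld_age3),
                ref_vocab_z=float(row.ref_vocab_z),
                ref_grammar_z=float(row.ref_grammar_z),
            )
        )
    return out
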