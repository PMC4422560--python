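"""Screen-level statistics: in-well-control normalization, phenotype scores,
and a two-Gaussian replicate-error model.

Every well carries two cell populations: the perturbed (experimental)
population and an in-well control. Since both share the well's conditions,
the control value predicts the experimental value up to the perturbation
effect. A robust linear trendline (iteratively reweighted least squares,
Tukey bisquare) is fit across all wells of a batch, experimental ~ control;
the expected value from the trendline normalizes each well:

    normalized = experimental / (slope · control + intercept)
    phenotype score = normalized − 1

so 0 means "behaves like the control". When experimental and control values
are not positively correlated (Spearman < 0.1 or negative slope — typical
for angular bias, where well-to-well variation is below the statistical
noise), the plate median of the experimental values is used as the expected
value instead.

The chemokinesis score captures the stimulus-induced speed boost over and
above a general motility change: it is the signed residual of the
stimulated-speed score from a robust trendline against the basal-speed
score.

Measurement error of a phenotype score is modeled as a zero-mean mixture of
two Gaussians (a tight core plus a wide outlier component). If the error X
has density w₁N(0,σ₁²) + w₂N(0,σ₂²), the difference of two replicates is
the self-convolution, a three-component mixture with weights
(w₁², 2w₁w₂, w₂²) and variances (2σ₁², σ₁²+σ₂², 2σ₂²); the parameters are
estimated by maximum likelihood on observed within-condition replicate
differences. The mean of n replicates of a null condition is again a
Gaussian mixture (binomial weights over component assignments), whose
closed-form CDF yields symmetric confidence intervals and two-sided
P-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.special import expit, logit

BISQUARE_TUNING = 4.685
SPEARMAN_FALLBACK = 0.1
DEFAULT_COVERAGE = 0.98


@dataclass(frozen=True)
class TrendlineFit:
    """Robust trendline experimental ~ control across the wells of a batch.

    ``fallback`` is set when the control does not usefully predict the
    experimental values (Spearman < 0.1, negative slope, or undefined
    correlation); normalization then divides by the plate median instead.
    """

    slope: float
    intercept: float
    spearman: float
    fallback: bool
    weight_function: str = "bisquare"


def fit_trendline(experimental: np.ndarray, control: np.ndarray) -> TrendlineFit:
    """Fit the robust normalization trendline (IRLS with bisquare weights,
    tuning constant 4.685, tolerance 1e-8, at most 50 iterations)."""
    experimental = np.asarray(experimental, dtype=float)
    control = np.asarray(control, dtype=float)
    ok = np.isfinite(experimental) & np.isfinite(control)
    if ok.sum() < 8:
        raise ValueError("need at least 8 paired wells to fit a trendline")
    y, x = experimental[ok], control[ok]
    if np.ptp(x) == 0:
        return TrendlineFit(math.nan, math.nan, math.nan, fallback=True)
    rho = stats.spearmanr(y, x).statistic
    model = sm.RLM(y, sm.add_constant(x), M=sm.robust.norms.TukeyBiweight(BISQUARE_TUNING))
    fit = model.fit(maxiter=50, tol=1e-8)
    intercept, slope = fit.params
    fallback = (not np.isfinite(rho)) or rho < SPEARMAN_FALLBACK or slope < 0
    return TrendlineFit(float(slope), float(intercept), float(rho), bool(fallback))


def normalize(
    experimental: np.ndarray,
    control: np.ndarray | None = None,
    fit: TrendlineFit | None = None,
) -> pd.DataFrame:
    """Normalize experimental values and derive phenotype scores.

    With a usable trendline the expected value per well is
    ``slope · control + intercept``; under fallback (or when no fit/control
    is given) it is the plate median of the experimental values. Wells with
    a non-positive expected value are flagged and get NaN scores.

    Returns a DataFrame with columns ``expected, normalized, score,
    excluded``.
    """
    experimental = np.asarray(experimental, dtype=float)
    use_fallback = fit is None or fit.fallback or control is None
    if use_fallback:
        expected = np.full_like(experimental, np.nanmedian(experimental))
    else:
        control = np.asarray(control, dtype=float)
        expected = fit.slope * control + fit.intercept
    excluded = ~(expected > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = np.where(excluded, np.nan, experimental / expected)
    return pd.DataFrame(
        {
            "expected": expected,
            "normalized": normalized,
            "score": normalized - 1.0,
            "excluded": excluded,
        }
    )


def chemokinesis_scores(
    basal_scores: np.ndarray, stimulated_scores: np.ndarray
) -> np.ndarray:
    """Signed residual of the stimulated-speed score from a robust trendline
    against the basal-speed score.

    Perturbations that change motility in general move along the trendline;
    the residual isolates the stimulus-specific speed change. Constant basal
    scores degenerate to residuals around a robust location (slope 0).
    """
    basal = np.asarray(basal_scores, dtype=float)
    stim = np.asarray(stimulated_scores, dtype=float)
    ok = np.isfinite(basal) & np.isfinite(stim)
    out = np.full(len(stim), np.nan)
    if np.ptp(basal[ok]) == 0:
        loc = sm.RLM(
            stim[ok], np.ones((ok.sum(), 1)), M=sm.robust.norms.TukeyBiweight(BISQUARE_TUNING)
        ).fit().params[0]
        out[ok] = stim[ok] - loc
        return out
    fit = sm.RLM(
        stim[ok], sm.add_constant(basal[ok]),
        M=sm.robust.norms.TukeyBiweight(BISQUARE_TUNING),
    ).fit(maxiter=50, tol=1e-8)
    intercept, slope = fit.params
    out[ok] = stim[ok] - (intercept + slope * basal[ok])
    return out


@dataclass(frozen=True)
class ErrorModel:
    """Zero-mean two-component Gaussian mixture for per-well score error,
    with σ₁ ≤ σ₂ (tight core + wide outlier component)."""

    w1: float
    sigma1: float
    sigma2: float

    @property
    def w2(self) -> float:
        return 1.0 - self.w1

    @property
    def variance(self) -> float:
        return self.w1 * self.sigma1**2 + self.w2 * self.sigma2**2

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)

    def mean_components(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Mixture components of the mean of n iid draws: for k of the n
        draws coming from component 1, weight C(n,k)·w₁ᵏ·w₂ⁿ⁻ᵏ and variance
        (kσ₁² + (n−k)σ₂²)/n²."""
        k = np.arange(n + 1)
        weights = stats.binom.pmf(k, n, self.w1)
        variances = (k * self.sigma1**2 + (n - k) * self.sigma2**2) / n**2
        return weights, np.sqrt(variances)

    def cdf_mean(self, x, n: int = 1):
        """Closed-form CDF of the null mean of n replicates."""
        w, s = self.mean_components(n)
        x = np.asarray(x, dtype=float)
        return np.sum(w * stats.norm.cdf(x[..., None] / s), axis=-1)

    def rvs(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """Draw single-measurement errors."""
        comp = rng.random(size) >= self.w1
        sd = np.where(comp, self.sigma2, self.sigma1)
        return rng.normal(0.0, 1.0, size) * sd


def replicate_differences(scores: pd.Series | np.ndarray, conditions) -> np.ndarray:
    """Differences between all unordered within-condition replicate pairs
    (a condition with 3 replicates contributes 3 differences)."""
    df = pd.DataFrame({"score": np.asarray(scores, dtype=float), "cond": np.asarray(conditions)})
    diffs = []
    for _, d in df.dropna().groupby("cond"):
        v = d["score"].to_numpy()
        for i in range(len(v)):
            for j in range(i + 1, len(v)):
                diffs.append(v[i] - v[j])
    return np.asarray(diffs)


def _diff_mixture(w1: float, s1: float, s2: float) -> tuple[np.ndarray, np.ndarray]:
    w2 = 1.0 - w1
    weights = np.array([w1**2, 2 * w1 * w2, w2**2])
    sds = np.sqrt(np.array([2 * s1**2, s1**2 + s2**2, 2 * s2**2]))
    return weights, sds


def fit_error_model(
    diffs: np.ndarray, n_starts: int = 10, seed: int = 0
) -> ErrorModel:
    """Maximum-likelihood fit of the error model to replicate differences.

    The difference density is the self-convolution of the error mixture.
    Optimization runs over (logit w₁, log σ₁, log σ₂) with Nelder–Mead from
    one moment-based start plus ``n_starts − 1`` randomized starts (seeded);
    the best converged solution wins, with σ₁ ≤ σ₂ enforced by relabeling.
    """
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[np.isfinite(diffs)]
    if len(diffs) < 10:
        raise ValueError("too few replicate differences to fit an error model")
    sd1 = max(float(np.std(diffs)) / math.sqrt(2.0), 1e-12)

    def nll(params: np.ndarray) -> float:
        w1 = expit(params[0])
        s1, s2 = np.exp(params[1]), np.exp(params[2])
        w, s = _diff_mixture(w1, s1, s2)
        dens = np.sum(w * stats.norm.pdf(diffs[:, None] / s) / s, axis=1)
        if np.any(dens <= 0) or not np.all(np.isfinite(dens)):
            return np.inf
        return -float(np.sum(np.log(dens)))

    rng = np.random.default_rng(seed)
    starts = [np.array([logit(0.7), math.log(0.6 * sd1), math.log(1.8 * sd1)])]
    for _ in range(n_starts - 1):
        starts.append(
            np.array(
                [
                    rng.normal(0.0, 1.5),
                    math.log(sd1) + rng.normal(0.0, 1.0),
                    math.log(sd1) + rng.normal(0.0, 1.0),
                ]
            )
        )
    best = None
    for x0 in starts:
        res = optimize.minimize(
            nll, x0, method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10},
        )
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(
            f"error-model MLE failed to converge from {n_starts} starts "
            f"(n={len(diffs)}, sd={sd1:.3g})"
        )
    w1 = float(expit(best.x[0]))
    s1, s2 = float(np.exp(best.x[1])), float(np.exp(best.x[2]))
    if s1 > s2:
        s1, s2, w1 = s2, s1, 1.0 - w1
    return ErrorModel(w1, s1, s2)


@dataclass(frozen=True)
class NullInterval:
    """Symmetric interval containing the mean of n replicate measurements
    for a given fraction of zero-effect perturbations."""

    lower: float
    upper: float
    n: int
    coverage: float


def null_interval(
    model: ErrorModel, n: int = 3, coverage: float = DEFAULT_COVERAGE
) -> NullInterval:
    """Symmetric null interval for the mean of n replicates, by bisection on
    the closed-form mixture CDF (bracketing tolerance 1e-6 of coverage)."""
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must be in (0, 1)")
    target = (1.0 + coverage) / 2.0

    def f(b: float) -> float:
        return float(model.cdf_mean(np.array(b), n)) - target

    hi = 20.0 * model.sigma2
    while f(hi) < 0:
        hi *= 2.0
    bound = optimize.brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-12)
    return NullInterval(-bound, bound, n, coverage)


def p_value(mean_score, model: ErrorModel, n: int = 3):
    """Two-sided P-value for a condition's mean score under the null error
    model: p = 2·(1 − F(|m|)) with F the CDF of the null mean of n."""
    m = np.abs(np.asarray(mean_score, dtype=float))
    p = 2.0 * (1.0 - model.cdf_mean(m, n))
    return np.clip(p, 0.0, 1.0)


SPEED_SCORES = ("basal_speed", "stimulated_speed", "directed_speed", "angular_bias")


def analyze_screen(
    plate: pd.DataFrame,
    coverage: float = DEFAULT_COVERAGE,
    n_interval: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Full screen analysis from per-well motility summaries.

    ``plate`` holds one row per well per population (columns ``well,
    condition, replicate, population`` plus the four motility statistics;
    populations ``experimental`` and ``control``). For each statistic a
    trendline is fit across wells, wells are normalized into phenotype
    scores, the chemokinesis score is derived from the basal/stimulated
    scores, and a per-score-type error model is fit on within-condition
    replicate differences.

    Returns ``(condition_scores, well_scores, models)`` where
    ``condition_scores`` has one row per condition per score type with the
    mean score, replicate count, two-sided P-value (at the condition's own
    n) and whether the mean falls outside the coverage interval for
    ``n_interval`` replicates.
    """
    wide = plate.pivot_table(
        index=["well", "condition", "replicate"],
        columns="population",
        values=list(SPEED_SCORES),
    )
    well_scores = pd.DataFrame(index=wide.index)
    fits = {}
    for stat in SPEED_SCORES:
        exp_vals = wide[(stat, "experimental")].to_numpy()
        ctrl_vals = wide[(stat, "control")].to_numpy()
        fit = fit_trendline(exp_vals, ctrl_vals)
        fits[stat] = fit
        well_scores[stat] = normalize(exp_vals, ctrl_vals, fit)["score"].to_numpy()
    well_scores["chemokinesis"] = chemokinesis_scores(
        well_scores["basal_speed"].to_numpy(),
        well_scores["stimulated_speed"].to_numpy(),
    )
    well_scores = well_scores.reset_index()

    score_types = list(SPEED_SCORES) + ["chemokinesis"]
    models = {}
    rows = []
    for stat in score_types:
        diffs = replicate_differences(well_scores[stat], well_scores["condition"])
        model = fit_error_model(diffs, seed=seed)
        interval = null_interval(model, n=n_interval, coverage=coverage)
        models[stat] = {"error_model": model, "interval": interval, "trendline": fits.get(stat)}
        for cond, d in well_scores.groupby("condition"):
            vals = d[stat].dropna().to_numpy()
            if len(vals) == 0:
                continue
            m = float(np.mean(vals))
            rows.append(
                {
                    "condition": cond,
                    "score_type": stat,
                    "mean_score": m,
                    "n_reps": len(vals),
                    "p_value": float(p_value(m, model, n=len(vals))),
                    "outside_ci": abs(m) > interval.upper,
                }
            )
    condition_scores = pd.DataFrame(rows).sort_values(
        ["score_type", "condition"], ignore_index=True
    )
    return condition_scores, well_scores, models
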