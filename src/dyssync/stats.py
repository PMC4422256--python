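"""Response classification and the CRT prediction statistics.

Covers the statistical pipeline that evaluates a dyssynchrony measure as
a predictor of response to cardiac resynchronization therapy: reverse
remodelling (>=15% reduction in LV end-systolic volume) and 2-of-3
clinical response classification, ROC analysis with a Youden-optimal
cut-off, prevalence ratios (PR) from log-link Poisson regression with a
robust sandwich variance, Fisher's exact tests on 2x2 tables, and
Bland-Altman reproducibility summaries.

Prevalence ratios rather than odds ratios are the natural effect
measure when the outcome (response) is common; the Poisson working
model with robust standard errors is the standard way to estimate them
for binary outcomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from sklearn.metrics import roc_curve as _sk_roc_curve

from dyssync.errors import InvalidInputError, UndefinedROCError

__all__ = [
    "ROCResult",
    "PRResult",
    "BlandAltmanResult",
    "classify_rr",
    "classify_clinical",
    "roc_analysis",
    "prevalence_ratio",
    "fisher_exact",
    "bland_altman",
    "phase2_model",
    "forest_plot",
]

#: Published covariate cut-offs for the response model: QRS duration in
#: ms, scar burden and volume-change SDI in % (exposure = value above
#: the cut-off; QRS uses >=, the others strict >).
QRS_CUTOFF_MS = 150.0
SCAR_CUTOFF_PCT = 14.7
SDI_CUTOFF_PCT = 9.75


# --------------------------------------------------------------------------
# response classification


def classify_rr(esv_pre, esv_post):
    """Reverse remodelling: >=15% reduction in end-systolic volume.

    The boundary is inclusive (exactly 15% counts as remodelled).
    Accepts scalars or arrays; volumes must be positive ml.
    """
    pre = np.asarray(esv_pre, dtype=float)
    post = np.asarray(esv_post, dtype=float)
    if np.any(pre <= 0) or np.any(post <= 0):
        raise InvalidInputError("end-systolic volumes must be positive")
    out = (pre - post) / pre >= 0.15
    return bool(out) if out.ndim == 0 else out


def classify_clinical(walk_delta_pct, nyha_delta, qol_delta_pct):
    """Clinical response: at least 2 of 3 criteria met (all boundaries inclusive).

    Criteria: six-minute walk improved by >=10% (``walk_delta_pct >= 10``),
    NYHA class reduced by >=1 (``nyha_delta <= -1``), quality-of-life
    score reduced by >=20% (``qol_delta_pct <= -20``).
    """
    walk = np.asarray(walk_delta_pct, dtype=float)
    nyha = np.asarray(nyha_delta, dtype=float)
    qol = np.asarray(qol_delta_pct, dtype=float)
    count = (walk >= 10.0).astype(int) + (nyha <= -1.0).astype(int) + (qol <= -20.0).astype(int)
    out = count >= 2
    return bool(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# ROC


@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC curve with the Youden-optimal operating point."""

    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    optimal_cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float


def roc_analysis(scores, labels) -> ROCResult:
    """Empirical ROC over all distinct thresholds, trapezoidal AUC.

    The optimal cut-off maximizes the Youden index J = sensitivity +
    specificity - 1; ties are broken toward higher specificity.  The
    cut-off is reported as the midpoint between the adjacent observed
    scores straddling the decision boundary, so that "score > cut-off"
    reproduces the selected operating point.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise UndefinedROCError("ROC needs both outcome classes present")

    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    sens, spec = tpr, 1.0 - fpr
    auc = float(np.trapezoid(tpr, fpr))

    j = sens + spec - 1.0
    best = np.flatnonzero(j == j.max())
    i = best[np.argmax(spec[best])]
    # thr[i] is the smallest score classified positive (>= convention);
    # report the midpoint to the next-lower observed score so a strict
    # "greater than" comparison lands on the same partition.
    uniq = np.unique(scores)
    t = thr[i]
    lower = uniq[uniq < t]
    cutoff = float((t + lower[-1]) / 2.0) if len(lower) else float(t) - 1e-9

    pred = scores > cutoff
    sens_at = float(np.mean(pred[labels]))
    spec_at = float(np.mean(~pred[~labels]))
    return ROCResult(
        thresholds=thr,
        sensitivities=sens,
        specificities=spec,
        auc=auc,
        optimal_cutoff=cutoff,
        sens_at_cutoff=sens_at,
        spec_at_cutoff=spec_at,
    )


# --------------------------------------------------------------------------
# prevalence ratios


@dataclass(frozen=True)
class PRResult:
    """Prevalence ratio with robust 95% CI and Wald p-value."""

    pr: float
    ci_low: float
    ci_high: float
    p: float
    covariates: tuple[str, ...]
    n: int
    term: str = "exposure"


def prevalence_ratio(
    outcome,
    exposure,
    covariates: pd.DataFrame | None = None,
    cov_type: str = "HC0",
    ci_level: float = 0.95,
) -> PRResult:
    """PR of a binary outcome for a binary exposure, robust Poisson GLM.

    Fits a log-link Poisson working model to the binary outcome by
    iteratively reweighted least squares and reads the PR off the
    exposure coefficient; the variance is the heteroscedasticity-robust
    sandwich estimator (``HC0`` by default, ``HC1`` available).  With a
    single binary exposure and no covariates the estimate equals the
    crude risk ratio exactly.
    """
    y = np.asarray(outcome).astype(float)
    x = np.asarray(exposure).astype(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise InvalidInputError("outcome must be binary")
    data = {"exposure": x}
    names = []
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        for c in cov.columns:
            data[str(c)] = np.asarray(cov[c], dtype=float)
            names.append(str(c))
    X = sm.add_constant(pd.DataFrame(data), has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise InvalidInputError("design matrix is rank deficient")
    model = sm.GLM(y, X, family=sm.families.Poisson())
    try:
        fit = model.fit(cov_type=cov_type)
    except Exception as exc:  # pragma: no cover - diagnostic path
        raise InvalidInputError(f"Poisson GLM failed to converge: {exc}") from exc
    if not fit.converged:
        raise InvalidInputError(
            f"Poisson GLM did not converge in {fit.fit_history['iteration']} iterations; "
            f"deviance trace {fit.fit_history.get('deviance')}"
        )
    beta = fit.params["exposure"]
    se = fit.bse["exposure"]
    z = scipy.stats.norm.ppf(0.5 + ci_level / 2.0)
    p = 2.0 * scipy.stats.norm.sf(abs(beta / se)) if se > 0 else (0.0 if beta != 0 else 1.0)
    return PRResult(
        pr=float(np.exp(beta)),
        ci_low=float(np.exp(beta - z * se)),
        ci_high=float(np.exp(beta + z * se)),
        p=float(p),
        covariates=tuple(names),
        n=len(y),
    )


# --------------------------------------------------------------------------
# exact test and reproducibility


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table.

    Uses the point-probability convention: the p-value sums the
    hypergeometric probabilities of all tables (with the same margins)
    no more probable than the observed one.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise InvalidInputError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer) and not np.allclose(t, np.round(t)):
        raise InvalidInputError("counts must be non-negative integers")
    t = np.round(t).astype(int)
    if np.any(t < 0):
        raise InvalidInputError("counts must be non-negative integers")
    return float(scipy.stats.fisher_exact(t, alternative="two-sided")[1])


@dataclass(frozen=True)
class BlandAltmanResult:
    """Agreement between two paired measurement series."""

    mean_difference: float
    sd_differences: float
    loa_low: float
    loa_high: float
    cov_mean_pct: float
    cov_sd_pct: float
    n_pairs: int


def bland_altman(a, b) -> BlandAltmanResult:
    """Bland-Altman agreement and per-pair coefficient of variation.

    The limits of agreement are mean difference +/- 1.96 SD.  Each
    pair's COV is the sample SD of the two values over their mean, in
    percent, summarized as mean +/- SD across pairs.  Pairs with zero
    mean are excluded with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise InvalidInputError("need two equal-length series with at least 2 pairs")
    diff = a - b
    mean_pair = (a + b) / 2.0
    ok = mean_pair != 0
    if not np.all(ok):
        warnings.warn("pairs with zero mean excluded from the COV", stacklevel=2)
    sd_pair = np.abs(diff[ok]) / np.sqrt(2.0)  # sample SD of two values
    cov = sd_pair / np.abs(mean_pair[ok]) * 100.0
    md = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanResult(
        mean_difference=md,
        sd_differences=sd,
        loa_low=md - 1.96 * sd,
        loa_high=md + 1.96 * sd,
        cov_mean_pct=float(cov.mean()),
        cov_sd_pct=float(cov.std(ddof=1)) if len(cov) > 1 else 0.0,
        n_pairs=int(len(a)),
    )


# --------------------------------------------------------------------------
# the dichotomized response model


def _exposures(cohort: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        "sdi_gt_9.75": (cohort["sdi"].to_numpy(dtype=float) > SDI_CUTOFF_PCT).astype(float),
        "qrs_ge_150": (cohort["qrs_ms"].to_numpy(dtype=float) >= QRS_CUTOFF_MS).astype(float),
        "lbbb": (cohort["qrs_morphology"].astype(str) == "LBBB").to_numpy().astype(float),
        "scar_gt_14.7": (cohort["scar_burden"].to_numpy(dtype=float) > SCAR_CUTOFF_PCT).astype(float),
    }


def phase2_model(cohort: pd.DataFrame, outcome: str = "rr") -> dict[str, dict[str, PRResult]]:
    """Uni- and multivariate PRs of response for the dichotomized predictors.

    Exposures follow the published dichotomizations: volume-change SDI
    > 9.75%, QRS duration >= 150 ms, LBBB morphology (vs RBBB/IVCD),
    scar burden > 14.7% of myocardium.  Returns
    ``{"univariate": {name: PRResult}, "multivariate": {name: PRResult}}``.
    """
    y = cohort[outcome].to_numpy().astype(float)
    expo = _exposures(cohort)
    uni = {name: prevalence_ratio(y, x) for name, x in expo.items()}
    multi: dict[str, PRResult] = {}
    names = list(expo)
    for name in names:
        others = pd.DataFrame({o: expo[o] for o in names if o != name})
        res = prevalence_ratio(y, expo[name], covariates=others)
        multi[name] = PRResult(
            pr=res.pr,
            ci_low=res.ci_low,
            ci_high=res.ci_high,
            p=res.p,
            covariates=res.covariates,
            n=res.n,
            term=name,
        )
    return {"univariate": uni, "multivariate": multi}


def forest_plot(results: dict[str, PRResult], path=None, title: str = "Prevalence ratio of response"):
    """Render PR estimates with CIs as a forest plot (SVG if ``path`` given)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(results)
    fig, ax = plt.subplots(figsize=(6, 0.6 * len(names) + 1.5))
    for i, name in enumerate(names):
        r = results[name]
        ax.errorbar(
            r.pr, i, xerr=[[r.pr - r.ci_low], [r.ci_high - r.pr]], fmt="s", color="k", capsize=3
        )
    ax.axvline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_yticks(range(len(names)), names)
    ax.set_xscale("log")
    ax.set_xlabel("prevalence ratio (95% CI)")
    ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
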