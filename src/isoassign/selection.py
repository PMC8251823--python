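"""Habitat-selection hypothesis tests via bootstrap logistic regression.

Four hypotheses make distinct predictions about how the probability of
long-distance immigration relates to plot covariates:

* random immigration — positive effect of habitat amount only;
* ideal free — positive effects of patch quality and conspecific density;
* ideal dominance — positive quality effect, negative density effect;
* social cues — positive quality effect and a hump-shaped density effect
  (positive linear, negative quadratic term).

Immigrant status per individual (from each bootstrap replicate of the
assignment model) is regressed on its plot's covariate with a
single-predictor logistic model; the mean, 2.5/97.5% percentile interval
and the proportion of replicate slopes above/below zero (a one-tailed
sign probability) summarise each effect across replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

COVARIATE_COLUMNS = ("R", "habitat_ha", "density")

#: One-tailed test direction per predictor under the social-cues hypothesis:
#: +1 tests Pr(coef > 0), -1 tests Pr(coef < 0).
PREDICTED_SIGNS = {
    "R": +1,
    "habitat_ha": +1,
    "density": +1,          # linear term
    "density_quad": -1,     # quadratic term
}


def validate_covariates(table: pd.DataFrame) -> pd.DataFrame:
    """Check a plot-covariates table (plot_id, R, habitat_ha, density, n)."""
    required = {"plot_id", "R", "habitat_ha", "density", "n"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"covariates table missing columns: {sorted(missing)}")
    if (table["habitat_ha"] <= 0).any():
        raise ValueError("habitat_ha must be positive")
    if (table["density"] < 0).any():
        raise ValueError("density must be non-negative")
    if (table["n"] < 1).any():
        raise ValueError("plot sample size n must be >= 1")
    return table


class SeparationError(RuntimeError):
    """Complete separation: the MLE does not exist for this replicate."""


def fit_logistic_single(z, x, quadratic: bool = False) -> np.ndarray:
    """Single-predictor logistic regression by maximum likelihood.

    Parameters
    ----------
    z : (n,) binary response (per-individual immigrant status)
    x : (n,) covariate value (individuals inherit their plot's covariate)
    quadratic : include a quadratic term (used for conspecific density)

    Returns
    -------
    coefficient array ``(intercept, beta1)`` or ``(intercept, beta1, beta2)``.
    The optimiser works on an internally rescaled column (raw-unit habitat
    amounts in the thousands of hectares are badly conditioned); reported
    coefficients are back-transformed to raw units.
    """
    z = np.asarray(z, dtype=float)
    x = np.asarray(x, dtype=float)
    if z.shape != x.shape or z.ndim != 1:
        raise ValueError("z and x must be aligned 1-d arrays")
    if not np.all(np.isfinite(x)):
        raise ValueError("covariate contains non-finite values")
    uniq = np.unique(z)
    if not np.all(np.isin(uniq, [0.0, 1.0])):
        raise ValueError("response must be binary 0/1")
    if uniq.size < 2:
        raise SeparationError("response contains a single class")

    scale = np.max(np.abs(x))
    scale = scale if scale > 0 else 1.0
    xs = x / scale
    cols = [np.ones_like(xs), xs] + ([xs ** 2] if quadratic else [])
    X = np.column_stack(cols)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(z, X).fit(disp=0, maxiter=200, method="newton")
    except (PerfectSeparationError, np.linalg.LinAlgError) as err:
        raise SeparationError(str(err)) from err
    if not res.mle_retvals.get("converged", False):
        raise SeparationError("logistic MLE failed to converge")
    beta = np.asarray(res.params, dtype=float)
    # large |coef| on the scaled column signals quasi-separation
    if np.max(np.abs(beta)) > 50.0:
        raise SeparationError("quasi-complete separation (diverging coefficients)")
    beta[1] /= scale
    if quadratic:
        beta[2] /= scale ** 2
    return beta


@dataclass
class EffectSummary:
    """Bootstrap summary of one predictor's effect on immigration."""

    predictor: str
    quadratic: bool
    coefficients: pd.DataFrame = field(repr=False)  # one row per converged replicate
    n_replicates: int = 0
    n_converged: int = 0

    @property
    def warning(self) -> bool:
        """True when more than half the replicates failed to converge."""
        return self.n_converged < 0.5 * self.n_replicates

    def table(self) -> pd.DataFrame:
        """Per-coefficient mean, percentile interval, and tail proportions."""
        rows = []
        for col in self.coefficients.columns:
            v = self.coefficients[col].to_numpy()
            rows.append({
                "predictor": self.predictor,
                "coefficient": col,
                "mean": float(np.mean(v)),
                "q2.5": float(np.percentile(v, 2.5)),
                "q97.5": float(np.percentile(v, 97.5)),
                "pr_positive": float(np.mean(v > 0)),
                "pr_negative": float(np.mean(v < 0)),
                "n_converged": self.n_converged,
                "n_failed": self.n_replicates - self.n_converged,
            })
        return pd.DataFrame(rows)

    def sign_probability(self, coefficient: str, direction: int) -> float:
        """One-tailed sign probability Pr(coef > 0) (direction=+1) or
        Pr(coef < 0) (direction=-1) across converged replicates."""
        v = self.coefficients[coefficient].to_numpy()
        return float(np.mean(v > 0) if direction > 0 else np.mean(v < 0))


def bootstrap_effects(flags: np.ndarray, plot_ids, covariates: pd.DataFrame,
                      predictor: str, quadratic: bool = False,
                      standardize: bool = False) -> EffectSummary:
    """Fit the single-predictor logistic model to every bootstrap replicate.

    Parameters
    ----------
    flags : (B, n_individuals) replicate immigrant indicators
    plot_ids : per-individual plot membership, aligned with ``flags`` columns
    covariates : plot-covariates table (plot_id + Table-1 columns)
    predictor : one of ``R``, ``habitat_ha``, ``density``
    quadratic : add a quadratic term (the social-cues density model)
    standardize : z-score the covariate before fitting (robustness check;
        off by default so coefficients stay in raw Table-1 units)
    """
    validate_covariates(covariates)
    if predictor not in COVARIATE_COLUMNS:
        raise ValueError(f"unknown predictor {predictor!r}; "
                         f"choose from {COVARIATE_COLUMNS}")
    flags = np.atleast_2d(np.asarray(flags))
    lookup = dict(zip(covariates["plot_id"], covariates[predictor]))
    try:
        x = np.array([lookup[p] for p in np.asarray(plot_ids)], dtype=float)
    except KeyError as err:
        raise ValueError(f"individual references unknown plot_id {err}") from err
    if standardize:
        sd = x.std()
        if sd == 0:
            raise ValueError("cannot standardize a zero-variance covariate")
        x = (x - x.mean()) / sd

    names = ["intercept", predictor] + ([f"{predictor}_quad"] if quadratic else [])
    fitted = []
    for b in range(flags.shape[0]):
        try:
            fitted.append(fit_logistic_single(flags[b], x, quadratic=quadratic))
        except SeparationError:
            continue
    summary = EffectSummary(
        predictor=predictor,
        quadratic=quadratic,
        coefficients=pd.DataFrame(fitted, columns=names),
        n_replicates=flags.shape[0],
        n_converged=len(fitted),
    )
    if summary.warning:
        warnings.warn(
            f"{predictor}: only {summary.n_converged}/{summary.n_replicates} "
            "replicates converged; summaries are unreliable", RuntimeWarning,
            stacklevel=2,
        )
    return summary


def covariate_correlations(covariates: pd.DataFrame,
                           columns=COVARIATE_COLUMNS) -> pd.DataFrame:
    """Pairwise Pearson correlations among plot covariates.

    Zero-variance columns yield NaN entries (undefined correlation), as
    pandas reports them.
    """
    if len(covariates) < 3:
        raise ValueError("need at least 3 plots for meaningful correlations")
    return covariates[list(columns)].corr(method="pearson")
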