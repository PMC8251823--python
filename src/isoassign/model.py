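"""Model/Results interface tying the pipeline together.

:class:`DispersalModel` holds the data (individuals, basemap, plots) and
model inputs (kernel prior, marker covariance); ``fit()`` runs the
bootstrap and returns a :class:`DispersalResults` carrying replicate
kernel fits, immigrant classifications, plot immigration rates and the
habitat-selection regressions, with a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dispersal, selection
from .assignment import (GAMMA1, SIGMA_DEFAULT, KernelPrior, posterior_matrix,
                         read_individuals, validate_sigma)
from .basemaps import Basemap, StudyPlots, distance_matrix


class DispersalModel:
    """Bayesian multi-marker assignment model for natal dispersal.

    Parameters
    ----------
    individuals : DataFrame
        Columns individual_id, plot_id, d2hf_permil, wing_mm.
    basemap : Basemap
        Candidate-origin cells with expected markers and abundance prior.
    plots : StudyPlots
        Breeding plots (optionally with covariate columns R, habitat_ha,
        density, n for the habitat-selection regressions).
    prior : KernelPrior
        Weibull dispersal-kernel prior (default the most restrictive
        standard prior, shape 0.75 / scale 9.26 km).
    sigma : (2, 2) array
        Fixed marker covariance.
    d_floor_km : float, optional
        Distance floor for kernel evaluation and refitting; defaults to
        half the basemap cell size.
    """

    def __init__(self, individuals: pd.DataFrame, basemap: Basemap,
                 plots: StudyPlots, prior: KernelPrior = GAMMA1,
                 sigma=SIGMA_DEFAULT, d_floor_km: float | None = None):
        self.individuals = individuals.reset_index(drop=True)
        self.basemap = basemap
        self.plots = plots
        self.prior = prior
        self.sigma = validate_sigma(sigma)
        self.d_floor_km = (basemap.cell_size_km / 2.0
                           if d_floor_km is None else float(d_floor_km))
        self._distances = None
        self._posteriors = None

    @classmethod
    def from_csv(cls, individuals_path, basemap_path, plots_path,
                 cell_size_km: float = 30.0, **kwargs) -> "DispersalModel":
        return cls(read_individuals(individuals_path),
                   Basemap.from_csv(basemap_path, cell_size_km=cell_size_km),
                   StudyPlots.from_csv(plots_path), **kwargs)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def plot_distances(self) -> np.ndarray:
        """(n_plots, n_cells) great-circle distances."""
        if self._distances is None:
            self._distances = distance_matrix(self.plots, self.basemap)
        return self._distances

    @property
    def individual_distances(self) -> np.ndarray:
        """(n_individuals, n_cells): each individual's plot distance row."""
        rows = [self.plots.row_index(p) for p in self.individuals["plot_id"]]
        return self.plot_distances[rows]

    @property
    def posteriors(self) -> np.ndarray:
        """(n_individuals, n_cells) posterior origin probabilities."""
        if self._posteriors is None:
            self._posteriors = posterior_matrix(
                self.individuals, self.basemap, self.plots, self.prior,
                sigma=self.sigma, d_floor_km=self.d_floor_km,
                distances=self.plot_distances)
        return self._posteriors

    def fit(self, n_boot: int = dispersal.DEFAULT_N_BOOT, seed: int = 0,
            thresholds=(dispersal.DEFAULT_THRESHOLD_KM,)) -> "DispersalResults":
        """Run the bootstrap: draw B origin samples per individual, derive
        distances, refit the kernel per replicate."""
        draws = dispersal.bootstrap_origins(
            self.posteriors, self.individual_distances,
            self.individuals["plot_id"].to_numpy(), n_boot=n_boot, seed=seed)
        fits = draws.fit_kernels(self.d_floor_km)
        return DispersalResults(model=self, draws=draws, kernel_fits=fits,
                                thresholds=tuple(float(t) for t in thresholds))


@dataclass
class DispersalResults:
    """Fitted bootstrap results of a :class:`DispersalModel`."""

    model: DispersalModel
    draws: dispersal.BootstrapDraws
    kernel_fits: pd.DataFrame = field(repr=False)
    thresholds: tuple = (dispersal.DEFAULT_THRESHOLD_KM,)

    # ---- dispersal kernel ------------------------------------------------
    @property
    def kernel_summary(self) -> pd.DataFrame:
        return dispersal.kernel_summary(self.kernel_fits)

    @property
    def shape_hat(self) -> float:
        return float(self.kernel_summary.set_index("parameter").loc["shape", "mean"])

    @property
    def scale_hat(self) -> float:
        return float(self.kernel_summary.set_index("parameter").loc["scale", "mean"])

    @property
    def median_km(self) -> float:
        return dispersal.weibull_median(self.shape_hat, self.scale_hat)

    def conf_int(self, parameter: str = "shape") -> tuple[float, float]:
        """Bootstrap 95% percentile interval for 'shape', 'scale' or
        'median_km'."""
        row = self.kernel_summary.set_index("parameter").loc[parameter]
        return float(row["q2.5"]), float(row["q97.5"])

    # ---- immigrants ------------------------------------------------------
    def immigrant_flags(self, threshold_km=None) -> np.ndarray:
        t = self.thresholds[0] if threshold_km is None else threshold_km
        return self.draws.immigrant_flags(t)

    def immigrant_counts(self, threshold_km=None) -> pd.DataFrame:
        t = self.thresholds[0] if threshold_km is None else threshold_km
        return self.draws.immigrant_counts(t)

    def immigration_rates(self, threshold_km=None) -> pd.Series:
        tab = self.immigrant_counts(threshold_km)
        return tab.set_index("plot_id")["immigration_rate"]

    # ---- habitat-selection regressions ----------------------------------
    def covariates(self) -> pd.DataFrame:
        cov = self.model.plots.table
        return selection.validate_covariates(cov)

    def regress(self, predictor: str, quadratic: bool = False,
                threshold_km=None, covariates: pd.DataFrame | None = None,
                standardize: bool = False) -> selection.EffectSummary:
        """Bootstrap logistic regression of immigrant status on one plot
        covariate (quadratic=True adds the squared term, the social-cues
        density model)."""
        cov = self.covariates() if covariates is None else covariates
        return selection.bootstrap_effects(
            self.immigrant_flags(threshold_km), self.draws.plot_ids, cov,
            predictor, quadratic=quadratic, standardize=standardize)

    def selection_tests(self, threshold_km=None,
                        covariates: pd.DataFrame | None = None) -> pd.DataFrame:
        """The standard battery: patch quality (R), habitat amount, and
        linear+quadratic conspecific density; one row per coefficient."""
        parts = [
            self.regress("R", threshold_km=threshold_km, covariates=covariates),
            self.regress("habitat_ha", threshold_km=threshold_km,
                         covariates=covariates),
            self.regress("density", quadratic=True, threshold_km=threshold_km,
                         covariates=covariates),
        ]
        return pd.concat([p.table() for p in parts], ignore_index=True)

    # ---- reporting -------------------------------------------------------
    def summary(self) -> str:
        m = self.model
        lines = [
            "Natal dispersal assignment: bootstrap results",
            "=" * 56,
            f"individuals: {m.n_individuals}   cells: {m.basemap.n_cells}   "
            f"plots: {len(m.plots)}",
            f"prior kernel: {m.prior.label or 'custom'} "
            f"(shape {m.prior.shape}, scale {m.prior.scale} km, "
            f"median {m.prior.median_km:.1f} km)",
            f"bootstrap replicates: {self.draws.n_boot} (seed {self.draws.seed})",
            "",
            "Fitted dispersal kernel (mean [95% bootstrap interval]):",
        ]
        ks = self.kernel_summary.set_index("parameter")
        for name, label in [("shape", "shape"), ("scale", "scale (km)"),
                            ("median_km", "median (km)")]:
            r = ks.loc[name]
            lines.append(f"  {label:<12} {r['mean']:8.2f}  "
                         f"[{r['q2.5']:.2f}, {r['q97.5']:.2f}]")
        nfail = int(ks["n_failed"].iloc[0])
        if nfail:
            lines.append(f"  ({nfail} replicate fit(s) failed to converge)")
        for t in self.thresholds:
            tab = self.immigrant_counts(t)
            lines += ["", f"Long-distance immigrants (threshold {t:g} km):",
                      "  plot    n   median [95% CI]   rate"]
            for r in tab.to_dict("records"):
                lines.append(
                    f"  {r['plot_id']!s:<5} {int(r['n']):4d}   "
                    f"{r['median_immigrants']:5.1f} "
                    f"[{r['q2.5']:.1f}, {r['q97.5']:.1f}]   "
                    f"{r['immigration_rate']:.3f}")
        return "\n".join(lines)
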