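"""Bootstrap dispersal-distance estimation from posterior origin surfaces.

Each bootstrap replicate draws one origin cell per individual from its
posterior (a categorical draw over cells), converts the draws into
dispersal distances, classifies long-distance immigrants against a
distance threshold, and refits the Weibull kernel by maximum likelihood.
Percentile summaries over the B replicates propagate assignment
uncertainty into every downstream quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_THRESHOLD_KM = 100.0
DEFAULT_N_BOOT = 1000


def weibull_median(shape: float, scale: float) -> float:
    """Closed-form Weibull median: scale * (ln 2)**(1/shape) (km)."""
    if shape <= 0 or scale <= 0:
        raise ValueError("Weibull shape and scale must be positive")
    return scale * np.log(2.0) ** (1.0 / shape)


def draw_origin(posterior, rng) -> int:
    """Draw a single origin cell index from a posterior probability vector."""
    p = np.asarray(posterior, dtype=float)
    if not np.all(np.isfinite(p)) or abs(p.sum() - 1.0) > 1e-6 or np.any(p < 0):
        raise ValueError("degenerate posterior: must be finite, >= 0 and sum to 1")
    return int(rng.choice(p.size, p=p))


def draw_origin_matrix(posteriors: np.ndarray, n_boot: int, rng) -> np.ndarray:
    """Draw origins for all individuals in all replicates.

    Parameters
    ----------
    posteriors : (n_individuals, n_cells) row-stochastic array
    n_boot : number of bootstrap replicates B
    rng : numpy Generator

    Returns
    -------
    (n_boot, n_individuals) integer array of cell indices.  Uses the
    inverse-CDF trick on per-individual cumulative posteriors so all draws
    come from a single uniform block (fast and reproducible).
    """
    p = np.asarray(posteriors, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("posteriors contain non-finite values")
    cdf = np.cumsum(p, axis=1)
    if np.any(np.abs(cdf[:, -1] - 1.0) > 1e-6):
        raise ValueError("posterior rows must each sum to 1")
    cdf[:, -1] = 1.0
    u = rng.random((n_boot, p.shape[0]))
    out = np.empty((n_boot, p.shape[0]), dtype=np.intp)
    for i in range(p.shape[0]):
        out[:, i] = np.searchsorted(cdf[i], u[:, i], side="right")
    return out


def classify_immigrant(distance_km, threshold_km: float = DEFAULT_THRESHOLD_KM):
    """Long-distance-immigrant indicator: 1 iff distance >= threshold.

    The boundary is inclusive: an individual exactly at the threshold counts
    as an immigrant.
    """
    d = np.asarray(distance_km, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    return (d >= threshold_km).astype(np.int8)


def immigration_rate(flags) -> float:
    """Plot immigration rate: mean immigrant indicator, sum(z)/n."""
    z = np.asarray(flags)
    if z.size == 0:
        raise ValueError("immigration_rate of an empty plot is undefined")
    return float(np.mean(z))


def fit_weibull_mle(distances_km, d_floor_km: float = 0.0):
    """Maximum-likelihood Weibull (shape, scale) fit to dispersal distances.

    Distances of exactly zero (an individual assigned to its own plot's
    cell) are shifted to ``d_floor_km`` first, since the Weibull support is
    positive.  Returns ``(shape_hat, scale_hat)``; raises if the optimiser
    fails or the sample is too small.
    """
    d = np.asarray(distances_km, dtype=float)
    if d.size < 10:
        raise ValueError(f"need at least 10 distances to fit a kernel, got {d.size}")
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    d = np.maximum(d, d_floor_km)
    if np.any(d <= 0):
        raise ValueError("zero distances present; supply a positive d_floor_km")
    shape_hat, loc, scale_hat = stats.weibull_min.fit(d, floc=0)
    if not (np.isfinite(shape_hat) and np.isfinite(scale_hat)
            and shape_hat > 0 and scale_hat > 0):
        raise FloatingPointError("Weibull MLE did not converge")
    return float(shape_hat), float(scale_hat)


@dataclass
class BootstrapDraws:
    """Per-replicate origin draws and derived distances.

    ``origins``/``distances``: (B, n_individuals) arrays of cell indices and
    km; ``plot_ids``: per-individual plot membership; ``seed``: root seed the
    replicate substreams were spawned from.
    """

    origins: np.ndarray
    distances: np.ndarray
    plot_ids: np.ndarray
    seed: int

    @property
    def n_boot(self) -> int:
        return self.origins.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.origins.shape[1]

    def immigrant_flags(self, threshold_km: float = DEFAULT_THRESHOLD_KM) -> np.ndarray:
        """(B, n_individuals) 0/1 indicator of long-distance immigration."""
        return classify_immigrant(self.distances, threshold_km)

    def immigrant_counts(self, threshold_km: float = DEFAULT_THRESHOLD_KM) -> pd.DataFrame:
        """Per-plot median and 95% percentile interval of the immigrant count
        across replicates, plus the plot immigration rate."""
        z = self.immigrant_flags(threshold_km)
        rows = []
        for pid in pd.unique(self.plot_ids):
            mask = self.plot_ids == pid
            counts = z[:, mask].sum(axis=1)
            n = int(mask.sum())
            rows.append({
                "plot_id": pid,
                "n": n,
                "median_immigrants": float(np.median(counts)),
                "q2.5": float(np.percentile(counts, 2.5)),
                "q97.5": float(np.percentile(counts, 97.5)),
                "immigration_rate": float(counts.mean()) / n,
            })
        return pd.DataFrame(rows)

    def fit_kernels(self, d_floor_km: float) -> pd.DataFrame:
        """Weibull MLE per replicate.

        Returns a frame with one row per replicate (replicate, shape_hat,
        scale_hat, median_km, converged); non-converged replicates carry NaN
        estimates and are excluded from quantile summaries.
        """
        rows = []
        for b in range(self.n_boot):
            try:
                shape_hat, scale_hat = fit_weibull_mle(self.distances[b], d_floor_km)
                rows.append((b, shape_hat, scale_hat,
                             weibull_median(shape_hat, scale_hat), True))
            except (ValueError, FloatingPointError, RuntimeError):
                rows.append((b, np.nan, np.nan, np.nan, False))
        return pd.DataFrame(rows, columns=["replicate", "shape_hat", "scale_hat",
                                           "median_km", "converged"])


def bootstrap_origins(posteriors: np.ndarray, distances_km: np.ndarray,
                      plot_ids, n_boot: int = DEFAULT_N_BOOT,
                      seed: int = 0) -> BootstrapDraws:
    """Draw B bootstrap origin samples for every individual and convert them
    to dispersal distances.

    Parameters
    ----------
    posteriors : (n_individuals, n_cells) posterior matrix
    distances_km : (n_individuals, n_cells) plot-to-cell distances, each row
        the distance row of that individual's breeding plot
    plot_ids : per-individual plot membership
    n_boot : replicate count B
    seed : root seed; a dedicated substream is spawned for the draws so the
        bootstrap is reproducible in isolation
    """
    posteriors = np.asarray(posteriors, dtype=float)
    distances_km = np.asarray(distances_km, dtype=float)
    if posteriors.shape != distances_km.shape:
        raise ValueError("posteriors and distance rows are misaligned")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    origins = draw_origin_matrix(posteriors, n_boot, rng)
    dist_draws = np.take_along_axis(distances_km, origins.T, axis=1).T
    return BootstrapDraws(origins=origins, distances=dist_draws,
                          plot_ids=np.asarray(plot_ids), seed=seed)


def kernel_summary(fits: pd.DataFrame) -> pd.DataFrame:
    """Mean and 2.5/97.5% percentile summary of replicate kernel fits."""
    ok = fits[fits["converged"]]
    if ok.empty:
        raise ValueError("no converged replicate kernel fits to summarise")
    rows = []
    for col, name in [("shape_hat", "shape"), ("scale_hat", "scale"),
                      ("median_km", "median_km")]:
        v = ok[col].to_numpy()
        rows.append({
            "parameter": name,
            "mean": float(np.mean(v)),
            "q2.5": float(np.percentile(v, 2.5)),
            "q97.5": float(np.percentile(v, 97.5)),
            "n_converged": int(len(ok)),
            "n_failed": int(len(fits) - len(ok)),
        })
    return pd.DataFrame(rows)
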