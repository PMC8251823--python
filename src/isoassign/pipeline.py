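"""Pipeline orchestration: assign -> bootstrap -> classify -> regress.

Runs the full analysis for one or more kernel priors and thresholds,
writes deterministic CSV outputs plus a machine-readable run manifest
(config hash, seed, library versions, output checksums).  Identical
config + seed produces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assignment import SIGMA_DEFAULT, STANDARD_PRIORS, KernelPrior
from .model import DispersalModel

log = logging.getLogger("isoassign")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run (paths + model settings)."""

    basemap: str
    individuals: str
    plots: str
    outdir: str = "results"
    covariates: str | None = None          # defaults to plots table columns
    cell_size_km: float = 30.0
    sigma: list = field(default_factory=lambda: SIGMA_DEFAULT.tolist())
    priors: list = field(default_factory=lambda: ["gamma1", "gamma2", "gamma3"])
    thresholds_km: list = field(default_factory=lambda: [100.0])
    n_boot: int = 1000
    seed: int = 0
    d_floor_km: float | None = None
    write_posteriors: bool = False
    run_regressions: bool = True

    def __post_init__(self):
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if any(t <= 0 for t in self.thresholds_km):
            raise ValueError("thresholds must be positive")

    def resolve_priors(self) -> list[KernelPrior]:
        out = []
        for p in self.priors:
            if isinstance(p, KernelPrior):
                out.append(p)
            elif str(p).lower() in STANDARD_PRIORS:
                out.append(STANDARD_PRIORS[str(p).lower()])
            else:
                raise ValueError(f"unknown prior {p!r}; use "
                                 f"{sorted(STANDARD_PRIORS)} or a KernelPrior")
        return out

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _file_sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write outputs under ``config.outdir``.

    Returns the manifest dict (also written as ``manifest.json``).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    try:
        priors = config.resolve_priors()
    except ValueError as err:
        raise StageError("config", err) from err

    results = {}
    for prior in priors:
        label = prior.label.lower() or f"w{prior.shape}_{prior.scale}"
        try:
            model = DispersalModel.from_csv(
                config.individuals, config.basemap, config.plots,
                cell_size_km=config.cell_size_km, prior=prior,
                sigma=np.asarray(config.sigma, dtype=float),
                d_floor_km=config.d_floor_km)
            log.info("[%s] read %d individuals, %d cells in range, %d plots",
                     label, model.n_individuals, model.basemap.n_cells,
                     len(model.plots))
        except Exception as err:
            raise StageError("read", err) from err

        try:
            if config.write_posteriors:
                post = pd.DataFrame(
                    model.posteriors,
                    columns=[f"cell{c}" for c in model.basemap.cells["cell_id"]])
                post.insert(0, "individual_id", model.individuals["individual_id"])
                p = outdir / f"posteriors_{label}.csv"
                post.to_csv(p, index=False, float_format="%.10g")
                written.append(p)
        except Exception as err:
            raise StageError("assign", err) from err

        try:
            res = model.fit(n_boot=config.n_boot, seed=config.seed,
                            thresholds=tuple(config.thresholds_km))
            n_conv = int(res.kernel_fits["converged"].sum())
            log.info("[%s] bootstrap B=%d, %d kernel fits converged",
                     label, config.n_boot, n_conv)
            p = outdir / f"kernel_fits_{label}.csv"
            res.kernel_fits.to_csv(p, index=False, float_format="%.10g")
            written.append(p)
            p = outdir / f"kernel_summary_{label}.csv"
            res.kernel_summary.to_csv(p, index=False, float_format="%.10g")
            written.append(p)
        except StageError:
            raise
        except Exception as err:
            raise StageError("bootstrap", err) from err

        try:
            for t in config.thresholds_km:
                tab = res.immigrant_counts(t)
                tab.insert(1, "prior", prior.label)
                tab.insert(2, "threshold_km", t)
                p = outdir / f"immigrants_{label}_t{t:g}.csv"
                tab.to_csv(p, index=False, float_format="%.10g")
                written.append(p)
        except Exception as err:
            raise StageError("classify", err) from err

        if config.run_regressions:
            try:
                cov = (pd.read_csv(config.covariates) if config.covariates
                       else None)
                frames = []
                for t in config.thresholds_km:
                    tab = res.selection_tests(threshold_km=t, covariates=cov)
                    tab.insert(1, "prior", prior.label)
                    tab.insert(2, "threshold_km", t)
                    frames.append(tab)
                p = outdir / f"selection_{label}.csv"
                pd.concat(frames, ignore_index=True).to_csv(
                    p, index=False, float_format="%.10g")
                written.append(p)
            except Exception as err:
                raise StageError("regress", err) from err
        results[prior.label] = res

    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": _versions(),
        "outputs": {p.name: _file_sha256(p) for p in written},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True, default=str))
    manifest["results"] = results
    return manifest


def _versions() -> dict:
    import scipy
    import statsmodels

    from . import __version__
    return {"isoassign": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__}
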