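"""End-to-end analysis pipeline and result persistence.

A run takes a validated cohort through the full sequence — history-complete
filtering, univariate pre-selection, the joint MCMC fit, and the evaluation
battery — and writes every artefact under one output directory together with
a manifest recording the resolved configuration, the seeds, and SHA-256
digests of the written files, so a run can be audited and re-derived exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort, Covariate, ExclusionReport, filter_history_complete
from .evaluate import (
    BrierReport,
    ConditionalAbnormality,
    CorrelationSummary,
    PredictiveBands,
    posterior_predictive_bands,
    prob_abnormal_given_others_normal,
    random_intercept_correlations,
    scaled_brier,
)
from .mcmc import McmcConfig, PosteriorDraws, fit
from .model import ModelConfig, PreselectionResult, preselect_covariates
from .outcomes import OUTCOME_NAMES

__all__ = ["PipelineResult", "RunManifest", "run_pipeline",
           "save_draws", "load_draws", "write_roster", "read_roster"]


# ---------------------------------------------------------------------------
# Draw persistence
# ---------------------------------------------------------------------------

_ARRAY_FIELDS = ("beta0", "beta_time", "beta", "alpha", "gamma", "Sigma",
                 "tau_slope", "sigma_resid", "theta_miss", "b", "s", "x_miss")


def save_draws(draws: PosteriorDraws, path: str | Path) -> None:
    """Persist posterior draws to a ``.npz`` archive (metadata as JSON)."""
    meta = {
        "covariate_names": draws.covariate_names,
        "miss_cells": [list(c) for c in draws.miss_cells],
        "mcmc": asdict(draws.mcmc),
        "converged": draws.converged,
    }
    arrays = {n: getattr(draws, n) for n in _ARRAY_FIELDS}
    np.savez_compressed(path, _meta=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_draws(path: str | Path) -> PosteriorDraws:
    with np.load(path) as z:
        meta = json.loads(bytes(z["_meta"]).decode())
        arrays = {n: z[n] for n in _ARRAY_FIELDS}
    draws = PosteriorDraws(
        **arrays,
        miss_cells=[tuple(c) for c in meta["miss_cells"]],
        covariate_names=meta["covariate_names"],
        mcmc=McmcConfig(**meta["mcmc"]),
    )
    draws.converged = meta["converged"]
    return draws


# ---------------------------------------------------------------------------
# Roster files
# ---------------------------------------------------------------------------

def write_roster(roster: list[Covariate], path: str | Path) -> None:
    """Write the covariate roster as YAML (list of name/role mappings)."""
    import yaml

    Path(path).write_text(yaml.safe_dump(
        [{"name": c.name, "role": c.role} for c in roster], sort_keys=False))


def read_roster(path: str | Path) -> list[Covariate]:
    import yaml

    items = yaml.safe_load(Path(path).read_text())
    return [Covariate(d["name"], d["role"]) for d in items]


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Audit record of one pipeline run (deterministic for a fixed input)."""

    seed: int
    mcmc: dict
    config_description: str
    config_sha256: str
    n_patients: int
    n_visits: int
    covariates_used: list[str]
    excluded_visits: int
    excluded_patients: list[str]
    converged: bool | None
    file_digests: dict[str, str] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1) + "\n")


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    cohort: Cohort                       # history-complete analysis cohort
    exclusions: ExclusionReport
    preselection: PreselectionResult | None
    config: ModelConfig                  # after roster restriction
    draws: PosteriorDraws
    bands: PredictiveBands
    briers: dict[str, BrierReport]
    correlations: list[CorrelationSummary]
    conditional: dict[str, ConditionalAbnormality]
    manifest: RunManifest


def run_pipeline(
    cohort: Cohort,
    config: ModelConfig,
    mcmc: McmcConfig,
    out_dir: str | Path | None = None,
    preselect: bool = True,
    band_level: float = 0.95,
    eval_seed: int = 0,
    progress: bool = False,
) -> PipelineResult:
    """Run filtering, pre-selection, fitting and evaluation in sequence.

    When ``out_dir`` is given, writes: ``draws.npz``, ``posterior_summary.csv``
    (per-parameter mean/sd/CI), ``inclusion_probabilities.csv``,
    ``convergence.csv``, ``predictive_bands.csv``, ``brier.csv``,
    ``correlations.csv``, ``conditional_abnormality.csv`` and
    ``manifest.json``.  Identical inputs reproduce identical files.
    """
    cohort, excl = filter_history_complete(cohort)
    presel = None
    if preselect:
        presel = preselect_covariates(cohort, config)
        config = presel.restrict(config)
        cohort = presel.restrict_cohort(cohort)

    draws = fit(cohort, config, mcmc, progress=progress)
    bands = posterior_predictive_bands(draws, cohort, config,
                                       level=band_level, seed=eval_seed)
    briers = scaled_brier(draws, cohort, config)
    corrs = random_intercept_correlations(draws)
    conditional = {n: prob_abnormal_given_others_normal(draws, cohort, config, n)
                   for n in OUTCOME_NAMES}

    desc = config.describe()
    manifest = RunManifest(
        seed=mcmc.seed,
        mcmc=asdict(mcmc),
        config_description=desc,
        config_sha256=hashlib.sha256(desc.encode()).hexdigest(),
        n_patients=cohort.n_patients,
        n_visits=len(cohort.df),
        covariates_used=config.covariate_names,
        excluded_visits=len(excl.dropped_visits),
        excluded_patients=list(excl.dropped_patients),
        converged=draws.converged,
    )
    result = PipelineResult(
        cohort=cohort, exclusions=excl, preselection=presel, config=config,
        draws=draws, bands=bands, briers=briers, correlations=corrs,
        conditional=conditional, manifest=manifest,
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def posterior_summary(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior mean, sd and central 95% interval per scalar parameter."""
    df = draws.to_dataframe().drop(columns=["chain", "draw"])
    rows = []
    for col in df.columns:
        v = df[col].to_numpy()
        lo, hi = np.percentile(v, [2.5, 97.5])
        rows.append({"parameter": col, "mean": v.mean(), "sd": v.std(ddof=1),
                     "q2.5": lo, "q97.5": hi})
    return pd.DataFrame(rows)


def _write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    files["draws.npz"] = out / "draws.npz"
    save_draws(result.draws, files["draws.npz"])

    files["posterior_summary.csv"] = out / "posterior_summary.csv"
    posterior_summary(result.draws).to_csv(files["posterior_summary.csv"],
                                           index=False)

    files["inclusion_probabilities.csv"] = out / "inclusion_probabilities.csv"
    pd.DataFrame(
        sorted(result.draws.inclusion_probabilities().items()),
        columns=["covariate", "pip"],
    ).to_csv(files["inclusion_probabilities.csv"], index=False)

    files["convergence.csv"] = out / "convergence.csv"
    result.draws.diagnostics.to_csv(files["convergence.csv"], index=False)

    files["predictive_bands.csv"] = out / "predictive_bands.csv"
    result.bands.table.to_csv(files["predictive_bands.csv"], index=False)

    files["brier.csv"] = out / "brier.csv"
    pd.DataFrame([asdict(b) for b in result.briers.values()]).to_csv(
        files["brier.csv"], index=False)

    files["correlations.csv"] = out / "correlations.csv"
    pd.DataFrame([
        {"outcome_a": c.pair[0], "outcome_b": c.pair[1], "rho": c.rho_hat,
         "ci_lo": c.ci95[0], "ci_hi": c.ci95[1]}
        for c in result.correlations
    ]).to_csv(files["correlations.csv"], index=False)

    files["conditional_abnormality.csv"] = out / "conditional_abnormality.csv"
    pd.DataFrame([
        {"outcome": c.outcome, "median": c.median, "q1": c.q1, "q3": c.q3,
         "n_visits": c.n_visits}
        for c in result.conditional.values()
    ]).to_csv(files["conditional_abnormality.csv"], index=False)

    if result.preselection is not None:
        files["preselection.csv"] = out / "preselection.csv"
        pd.DataFrame([
            {"covariate": n, "max_abs_wald": w,
             "selected": n in result.preselection.selected}
            for n, w in result.preselection.ranking.items()
        ]).to_csv(files["preselection.csv"], index=False)

    result.manifest.file_digests = {n: _sha256(p) for n, p in files.items()}
    result.manifest.write(out / "manifest.json")
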