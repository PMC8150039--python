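"""End-to-end pipeline: simulate/ingest -> clean -> score -> psychometrics
-> specification curve -> summaries -> decomposed variance -> figures.

Every run is driven by a :class:`RunConfig` and leaves a manifest (JSON)
with per-stage counts, the config hash and the seed, so that identical
configurations reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from . import cleaning as cl
from . import scales as scl
from . import simulate as sim
from .cfa import OneFactorCFA
from .curve import (SpecificationCurve, build_default_space,
                    correlation_matrix)
from .decompose import CurveVarianceDecomposition, rerun_without_predictor

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""
    data: str | None = None          # CSV path; None -> simulate
    out: str = "speccurve_out"
    seed: int = 0
    n_respondents: int = 743
    sensitivity_mode: bool = False
    item_level: bool = False
    figures: bool = True
    psychometrics: bool = True
    bootstrap_samples: int = 1000
    covariate_detail: bool = True
    drop_anomalous: str | None = "odba"  # rerun decomposition without it

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _psychometric_table(cleaned: pd.DataFrame, battery, B, seed) -> pd.DataFrame:
    rows = []
    for name in scl.predictor_scale_names():
        scale = battery[name]
        X = cleaned[list(scale.items)].to_numpy(dtype=float)
        # reverse-coded items aligned before factoring
        for j, col in enumerate(scale.items):
            if col in scale.reverse:
                X[:, j] = 6.0 - X[:, j]
        res = OneFactorCFA(X).fit()
        fi = res.fit_indices()
        lo, hi = res.omega_ci(B=B, seed=seed)
        rows.append({
            "scale": name, "n_items": scale.n_items, "chi2": fi.chi2,
            "df": fi.df, "pvalue": fi.pvalue, "cfi": fi.cfi,
            "rmsea": fi.rmsea, "rmsea_lo": fi.rmsea_ci[0],
            "rmsea_hi": fi.rmsea_ci[1], "srmr": fi.srmr,
            "omega": res.omega, "omega_lo": lo, "omega_hi": hi,
            "converged": res.converged,
        })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dict.

    On stage failure all files written so far are removed and the error is
    re-raised with a stage tag.
    """
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
    }

    def emit(name, writer):
        path = out / name
        writer(path)
        written.append(path)
        return path

    stage = "setup"
    try:
        battery = scl.default_scales()

        stage = "simulate/ingest"
        if config.data is None:
            gcfg = sim.GeneratorConfig(n_respondents=config.n_respondents,
                                       seed=config.seed)
            raw, truth = sim.generate_dataset(gcfg)
            emit("simulated_data.csv", lambda p: sim.write_dataset(raw, p))
            emit("ground_truth.json", truth.to_json)
        else:
            raw = sim.read_dataset(config.data)
        manifest["stages"]["ingest"] = {"n_rows": int(len(raw))}

        stage = "clean"
        cleaned, report = cl.clean_dataset(
            raw, sensitivity_mode=config.sensitivity_mode)
        emit("cleaning_report.json", report.to_json)
        manifest["stages"]["clean"] = {
            "n_initial": report.n_initial,
            "n_incomplete_removed": report.n_incomplete_removed,
            "n_careless_removed": report.n_careless_removed,
            "n_retained": report.n_retained,
            "sensitivity_mode": report.sensitivity_mode,
        }

        stage = "score"
        on_missing = "nan" if config.sensitivity_mode else "raise"
        scored = cl.score_dataset(cleaned, battery, on_missing=on_missing)
        if config.sensitivity_mode:
            scored = scored.dropna(
                subset=scl.predictor_scale_names() + scl.outcome_names())
        emit("scored_data.csv",
             lambda p: scored.to_csv(p, index=False))
        manifest["stages"]["score"] = {
            "n_scored": int(len(scored)),
            "n_playtime_outliers": int(scored["playtime_outlier"].sum()),
        }

        corr = correlation_matrix(scored)
        emit("correlation_matrix.csv", lambda p: corr.to_csv(p))

        stage = "psychometrics"
        if config.psychometrics:
            complete = scored.dropna()
            psy_source = cleaned.loc[cleaned.index.intersection(
                complete.index)]
            psy = _psychometric_table(psy_source, battery,
                                      config.bootstrap_samples, config.seed)
            emit("psychometrics.csv", lambda p: psy.to_csv(p, index=False))
            manifest["stages"]["psychometrics"] = {
                "n_scales": int(len(psy)),
                "all_converged": bool(psy["converged"].all()),
            }

        stage = "curve"
        space = build_default_space(scored, item_level=config.item_level)
        results = SpecificationCurve(
            scored, space, covariate_detail=config.covariate_detail).fit()
        emit("curve_results.csv",
             lambda p: results.results.to_csv(p, index=False))
        if config.covariate_detail:
            emit("covariate_results.csv",
                 lambda p: results.covariate_results.to_csv(p, index=False))
        manifest["stages"]["curve"] = {
            "n_specifications": len(space),
            "n_fitted": len(results),
            "n_skipped": len(results.skipped),
            "median_beta": results.median_beta,
            "frac_significant": results.frac_significant,
        }

        stage = "summaries"
        tables = [results.summary_table("predictor"),
                  results.summary_table("outcome"),
                  results.summary_table("outliers")]
        if config.covariate_detail:
            tables.append(results.summary_table("covariate"))
        summary = pd.concat(tables, ignore_index=True)
        emit("curve_summaries.csv",
             lambda p: summary.to_csv(p, index=False))

        stage = "decompose"
        decomp = CurveVarianceDecomposition(results).fit()
        frames = [decomp.to_frame().assign(curve="full")]
        reduced = None
        if (config.drop_anomalous and not config.item_level
                and config.drop_anomalous in set(results.results["predictor"])):
            reduced = rerun_without_predictor(results, config.drop_anomalous)
            frames.append(reduced.to_frame().assign(
                curve=f"without_{config.drop_anomalous}"))
        emit("variance_decomposition.csv",
             lambda p: pd.concat(frames, ignore_index=True)
             .to_csv(p, index=False))
        manifest["stages"]["decompose"] = {
            "shares": decomp.shares,
            "shares_reduced": reduced.shares if reduced else None,
            "method": decomp.method,
        }

        stage = "figures"
        if config.figures:
            import matplotlib.pyplot as plt
            fig = results.plot(path_stem=out / "specification_curve")
            plt.close(fig)
            fig = results.plot_boxplots(path_stem=out / "choice_boxplots")
            plt.close(fig)
            fig = decomp.plot(path_stem=out / "variance_shares",
                              comparison=reduced)
            plt.close(fig)
            from .plots import plot_correlation_matrix
            fig = plot_correlation_matrix(
                corr, path_stem=out / "correlation_matrix")
            plt.close(fig)
            for stem in ("specification_curve", "choice_boxplots",
                         "variance_shares", "correlation_matrix"):
                written.extend([out / f"{stem}.png", out / f"{stem}.svg"])

        manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        return manifest

    except Exception as err:
        for path in written:
            try:
                path.unlink(missing_ok=True)
            except OSError:
                pass
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
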