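"""End-to-end driver: simulate -> validate -> summarise -> fit both models
-> diagnostics -> comparison table, with a run manifest for reproducibility.

A single global seed fans out to per-stage sub-seeds through
``numpy.random.SeedSequence.spawn``, so each stage is independently
reproducible and a rerun with the same config and seed gives identical
numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import cohort as ledger
from . import cox as coxmod
from . import illness_death as idm
from . import simulate as sim

__all__ = ["run_pipeline", "PipelineError"]

log = logging.getLogger("semicompete")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def run_pipeline(config, outdir, seed: int | None = None,
                 clock: str | None = None) -> dict:
    """Run the full analysis on a synthetic cohort and write all artifacts.

    Parameters
    ----------
    config : GeneratorConfig | str | Path
        Generator configuration or path to its YAML form.
    outdir : str | Path
        Output directory (created if absent).
    seed : int, optional
        Overrides ``config.seed``.
    clock : str, optional
        Transition-3 clock for the joint fit; defaults to the generator's.

    Returns the run manifest (also written to ``manifest.json``).
    """
    if not isinstance(config, sim.GeneratorConfig):
        config = sim.GeneratorConfig.from_yaml(config)
    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    clock = clock or config.true_params.clock

    manifest: dict = {
        "seed": config.seed,
        "n_requested": config.n,
        "clock": clock,
        "stages": {},
    }
    manifest_path = outdir / "manifest.json"

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                info = fn()
            except Exception as exc:  # persist what completed, then abort
                manifest["failed_stage"] = name
                manifest_path.write_text(
                    json.dumps(manifest, indent=2, default=_jsonable)
                )
                raise PipelineError(name, exc) from exc
            info["seconds"] = round(time.perf_counter() - t0, 4)
            manifest["stages"][name] = info
            log.info("stage %s: done in %.2fs", name, info["seconds"])
            return info

        return deco

    state: dict = {}

    @stage("simulate")
    def _simulate():
        cohort, truth = sim.generate_cohort(config)
        cpath, tpath = outdir / "cohort.csv", outdir / "truth.csv"
        ledger.write_cohort(cohort, cpath)
        truth.to_csv(tpath, index=False)
        state["cohort_path"] = cpath
        return {"out": [str(cpath), str(tpath)], "rows": len(cohort)}

    @stage("validate")
    def _validate():
        cohort = ledger.read_cohort(state["cohort_path"])
        state["cohort"] = cohort
        return {"rows": len(cohort), "excluded": cohort.n_excluded_invalid}

    @stage("flow_counts")
    def _flow():
        fc = ledger.flow_counts(state["cohort"])
        state["flow"] = fc
        path = outdir / "flow_counts.json"
        path.write_text(json.dumps(dataclasses.asdict(fc), indent=2))
        return {"out": [str(path)], "rows": fc.n_total,
                "n_nonterminal": fc.n_nonterminal}

    @stage("baseline_table")
    def _baseline():
        summ = ledger.baseline_table(state["cohort"])
        path = outdir / "baseline_table.csv"
        summ.formatted().to_csv(path, index=False)
        assert summ.n_group0 == state["flow"].n_no_nonterminal
        assert summ.n_group1 == state["flow"].n_nonterminal
        return {"out": [str(path)], "rows": len(summ.table)}

    @stage("fit_cox")
    def _fit_cox():
        cohort = state["cohort"]
        t, e = coxmod.censor_at_death(cohort)
        fit = coxmod.cox_fit(t, e, cohort.X, covariate_names=cohort.covariate_names)
        state["cox"] = fit
        path = outdir / "cox_fit.json"
        path.write_text(json.dumps(fit.to_dict(), indent=2, default=_jsonable))
        return {"out": [str(path)], "rows": len(cohort),
                "converged": bool(fit.converged), "loglik": fit.loglik}

    @stage("fit_idm")
    def _fit_idm():
        fit = idm.fit_mle(state["cohort"], clock=clock)
        state["idm"] = fit
        path = outdir / "idm_fit.json"
        path.write_text(json.dumps(fit.to_dict(), indent=2, default=_jsonable))
        return {"out": [str(path)], "rows": fit.n_used,
                "converged": bool(fit.converged), "loglik": fit.loglik,
                "theta_hat": fit.estimates.theta}

    @stage("diagnostics")
    def _diag():
        cohort = state["cohort"]
        t, e = coxmod.censor_at_death(cohort)
        ph = coxmod.schoenfeld_ph_test(state["cox"], t, e, cohort.X)
        r, pv = coxmod.event_correlation(cohort)
        path = outdir / "diagnostics.json"
        doc = {
            "ph_global_statistic": ph.global_statistic,
            "ph_global_p": ph.global_p,
            "ph_transform": ph.transform,
            "ph_n_satisfying": ph.n_satisfying,
            "ph_n_covariates": len(ph.table),
            "ph_per_covariate": ph.table.to_dict(orient="records"),
            "event_correlation": r,
            "event_correlation_p": pv,
        }
        path.write_text(json.dumps(doc, indent=2, default=_jsonable))
        return {"out": [str(path)], "rows": len(ph.table)}

    @stage("comparison")
    def _compare():
        table = coxmod.hr_comparison_table(state["cox"], state["idm"])
        path = outdir / "hr_comparison.csv"
        table.to_csv(path, index=False)
        return {"out": [str(path)], "rows": len(table),
                "n_discordant": int(table["discordant"].sum())}

    manifest_path.write_text(json.dumps(manifest, indent=2, default=_jsonable))
    return manifest
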