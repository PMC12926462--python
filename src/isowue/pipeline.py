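"""End-to-end pipeline: simulate → compute iWUE → fit trends → attribute.

Each stage writes its artifact under the configured output directory and a
manifest records every input, seed, constant and artifact hash, so a rerun
with the same configuration reproduces identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .attribution import DEFAULT_FEATURES, fit_attribution, rank_report, vif_screen
from .constants import Formulation
from .io import PipelineConfig, validate_table, write_json
from .lmm import fit_pathway_trends
from .physio import compute_iwue_table
from .synthetic import TransectConfig, generate_transect

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; message carries the stage tag."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all enabled stages; returns the artifact directory.

    Stage toggles allow resuming: a disabled stage's artifact must already
    exist in ``out_dir`` for downstream stages to consume it.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    constants = config.fractionation_constants()
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "formulation": config.formulation,
        "ca_ppm": config.ca,
        "delta13c_air_permil": config.delta13c_air,
        "constants": constants.to_dict(),
        "stages": dict(config.stages),
        "artifacts": {},
        "timings_s": {},
    }

    def _record(name: str, path: Path) -> None:
        manifest["artifacts"][name] = {"path": str(path), "sha256": _sha256(path)}

    def _run_stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 — re-tagged with the stage name
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        manifest["timings_s"][name] = round(time.perf_counter() - t0, 3)
        logger.info("stage %s finished in %.2fs", name, manifest["timings_s"][name])
        return result

    transect_csv = out_dir / "transect.csv"
    if config.stages.get("simulate", True) and config.input_csv is None:
        def _simulate():
            gen_cfg = TransectConfig(**{"seed": config.seed, **config.generator})
            table, truth = generate_transect(gen_cfg, constants)
            table.to_csv(transect_csv, index=False)
            truth.to_json(out_dir / "ground_truth.json")
            write_json(dataclasses.asdict(gen_cfg), out_dir / "generator_config.json")
            return table

        table = _run_stage("simulate", _simulate)
        _record("transect", transect_csv)
        _record("ground_truth", out_dir / "ground_truth.json")
    else:
        src = Path(config.input_csv) if config.input_csv else transect_csv
        if not src.exists():
            raise StageError(f"stage 'simulate' disabled but input {src} is missing")
        table, _ = validate_table(src)
        _record("transect", src)

    iwue_csv = out_dir / "iwue.csv"
    if config.stages.get("compute_iwue", True):
        def _compute():
            table_checked, report = validate_table(table)
            if report.warnings:
                logger.info("validation warnings: %d", len(report.warnings))
            return compute_iwue_table(
                table_checked,
                constants=constants,
                formulation=Formulation(config.formulation),
                ca=config.ca,
                delta13c_air=config.delta13c_air,
                drop_out_of_range=config.drop_out_of_range,
            )

        iwue_table = _run_stage("compute_iwue", _compute)
        iwue_table.to_csv(iwue_csv, index=False)
        _record("iwue", iwue_csv)
    else:
        if not iwue_csv.exists():
            raise StageError("stage 'compute_iwue' disabled but iwue.csv is missing")
        iwue_table = pd.read_csv(iwue_csv)

    if config.stages.get("fit", True):
        def _fit():
            fits = fit_pathway_trends(iwue_table)
            payload = {
                p: None if f is None else {
                    "coef": f.coef, "se": f.se, "pvalues": f.pvalues,
                    "conf_int": f.conf_int,
                    "r2_marginal": f.r2_marginal, "r2_conditional": f.r2_conditional,
                    "var_fixed": f.var_fixed, "var_group": f.var_group,
                    "var_resid": f.var_resid,
                    "n_obs": f.n_obs, "n_groups": f.n_groups,
                    "singular": f.singular, "metadata": f.metadata,
                }
                for p, f in fits.items()
            }
            write_json(payload, out_dir / "lmm_fits.json")
            return fits

        _run_stage("fit", _fit)
        _record("lmm_fits", out_dir / "lmm_fits.json")

    if config.stages.get("attribute", True):
        def _attribute():
            results = {}
            for pathway in ("C3", "C4"):
                sub = iwue_table.loc[iwue_table["pathway"].astype(str) == pathway]
                feats = [c for c in DEFAULT_FEATURES if c in sub.columns]
                if len(sub) < 2 * len(feats):
                    logger.warning("pathway %s: too few rows for attribution", pathway)
                    continue
                fs = vif_screen(sub, feats)
                res = fit_attribution(sub, fs.retained, "iWUE", seed=config.seed)
                pdir = out_dir / f"attribution_{pathway.lower()}"
                rank_report(res, pdir, plot=True)
                write_json(
                    {"retained": fs.retained, "dropped": fs.dropped,
                     "final_vif": fs.final_vif,
                     "hyperparameters": res.hyperparameters,
                     "best_iteration": res.best_iteration},
                    pdir / "metadata.json",
                )
                results[pathway] = res
            return results

        _run_stage("attribute", _attribute)
        for pathway in ("C3", "C4"):
            p = out_dir / f"attribution_{pathway.lower()}" / "importance.csv"
            if p.exists():
                _record(f"attribution_{pathway}", p)

    write_json(manifest, out_dir / "manifest.json")
    return out_dir
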