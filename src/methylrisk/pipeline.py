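"""End-to-end orchestration: simulate -> diffmeth -> derive -> score ->
validate -> survival -> enrich, from one stage-keyed configuration.

Each stage writes its standard plain-text outputs into the run
directory and the run finishes with a machine-readable manifest
(inputs, outputs, seed, package versions, per-stage wall-clock).
Rerunning an identical configuration reproduces byte-identical
scientific outputs; a failing stage aborts the run with the stage named
and renames that stage's partial outputs with a ``.partial`` suffix.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .diffmeth import binomial_skew_test, cpg_logistic_scan, select_candidates
from .ensemble_signature import EnsembleConfig, signature_summary, stack_ensemble
from .enrichment import hypergeom_enrichment
from .methio import (BetaMatrix, SampleSheet, read_annotation, read_beta_matrix,
                     read_gene_sets, read_sample_sheet, read_signature,
                     write_annotation, write_beta_matrix, write_gene_sets,
                     write_sample_sheet, write_signature)
from .risk_validation import (cox_binary_hr, dichotomize_scores, score_samples,
                              somers_auc)
from .synthetic_data import (SimConfig, make_annotation, simulate_discovery,
                             simulate_prospective)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline",
           "load_pipeline_config"]

log = logging.getLogger("methylrisk")

STAGES = ("simulate", "diffmeth", "derive", "score", "validate",
          "survival", "enrich")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Stage-keyed pipeline settings.

    ``stages`` toggles each step; with ``simulate`` disabled the
    ``paths`` mapping must point at existing beta/sheet/annotation/GMT
    files.  ``sim``/``diffmeth``/``derive`` carry per-stage keyword
    overrides.
    """

    outdir: str = "methylrisk_run"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    sim: dict = field(default_factory=dict)
    diffmeth: dict = field(default_factory=dict)
    derive: dict = field(default_factory=dict)
    annotation: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, True)

    def validate_inputs(self) -> None:
        """Fail before any stage runs if required inputs are absent."""
        if not self.stages.get("simulate", True):
            needed = ["discovery_beta", "discovery_sheet"]
            if self.stages.get("score") or self.stages.get("validate"):
                needed += ["prospective_beta", "prospective_sheet"]
            if self.stages.get("enrich"):
                needed += ["annotation", "gene_sets"]
            for key in needed:
                p = self.paths.get(key)
                if p is None or not Path(p).exists():
                    raise PipelineError(
                        f"config error: simulation disabled and required "
                        f"input {key!r} missing ({p!r})")


def load_pipeline_config(path) -> PipelineConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    allowed = {f.name for f in dc_fields(PipelineConfig)}
    unknown = set(raw) - allowed
    if unknown:
        raise PipelineError(f"config error: unknown keys {sorted(unknown)}")
    return PipelineConfig(**raw)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def _write_json(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                               default=_json_default) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    config.validate_inputs()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [],
                      "versions": _versions()}
    t_run = time.perf_counter()
    state: dict = {}
    for stage in STAGES:
        if not config.stages.get(stage, True):
            continue
        t0 = time.perf_counter()
        runner = _RUNNERS[stage]
        written: list[Path] = []
        try:
            outputs = runner(config, outdir, state, written)
        except Exception as e:
            for p in written:
                if p.exists():
                    p.rename(p.with_suffix(p.suffix + ".partial"))
            raise PipelineError(f"stage {stage!r} failed: {e}") from e
        elapsed = time.perf_counter() - t0
        log.info("stage %s finished in %.2fs", stage, elapsed)
        manifest["stages"].append({
            "name": stage, "outputs": [str(p) for p in outputs],
            "seconds": round(elapsed, 3)})
    manifest["wallclock_seconds"] = round(time.perf_counter() - t_run, 3)
    _write_json(manifest, outdir / "manifest.json")
    return manifest


def _versions() -> dict:
    import pandas
    import scipy
    import sklearn
    return {"methylrisk": __version__, "numpy": np.__version__,
            "pandas": pandas.__version__, "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__}


# ---------------------------------------------------------------------------
# stage runners: (config, outdir, shared state, written-paths) -> outputs


def _track(written: list[Path], path: Path) -> Path:
    written.append(path)
    return path


def _stage_simulate(cfg: PipelineConfig, outdir: Path, state: dict,
                    written: list[Path]):
    sim = SimConfig(seed=cfg.seed, **cfg.sim)
    ann_cfg = {"n_genes": max(2, sim.n_cpgs // 3), "target_set_fraction": 0.1,
               **cfg.annotation}
    ann, sets = make_annotation(sim.n_cpgs, ann_cfg["n_genes"],
                                ann_cfg["target_set_fraction"], seed=cfg.seed)
    disc_beta, disc_sheet, truth = simulate_discovery(sim, ann, sets)
    prosp_beta, prosp_sheet = simulate_prospective(sim, truth)
    outs = []
    pairs = [
        (disc_beta, "discovery_beta.tsv", write_beta_matrix),
        (disc_sheet, "discovery_sheet.csv", write_sample_sheet),
        (prosp_beta, "prospective_beta.tsv", write_beta_matrix),
        (prosp_sheet, "prospective_sheet.csv", write_sample_sheet),
        (ann, "annotation.csv", write_annotation),
        (sets, "gene_sets.gmt", write_gene_sets),
    ]
    for obj, name, writer in pairs:
        p = _track(written, outdir / name)
        writer(obj, p)
        outs.append(p)
    truth_path = _track(written, outdir / "truth.csv")
    truth.as_series().rename("signed_effect").to_csv(truth_path)
    outs.append(truth_path)
    state.update(discovery=(disc_beta, disc_sheet), prospective=(prosp_beta,
                 prosp_sheet), truth=truth, annotation=ann, gene_sets=sets)
    return outs


def _load_discovery(cfg: PipelineConfig, state: dict):
    if "discovery" not in state:
        state["discovery"] = (read_beta_matrix(cfg.paths["discovery_beta"]),
                              read_sample_sheet(cfg.paths["discovery_sheet"]))
    return state["discovery"]


def _load_prospective(cfg: PipelineConfig, state: dict):
    if "prospective" not in state:
        state["prospective"] = (read_beta_matrix(cfg.paths["prospective_beta"]),
                                read_sample_sheet(cfg.paths["prospective_sheet"]))
    return state["prospective"]


def _stage_diffmeth(cfg: PipelineConfig, outdir: Path, state: dict,
                    written: list[Path]):
    matrix, sheet = _load_discovery(cfg, state)
    opts = dict(cfg.diffmeth)
    fdr = opts.pop("fdr", 0.3)
    covariates = opts.pop("covariates", ["age", "batch", "cancer_status"])
    table = cpg_logistic_scan(matrix, sheet, covariates)
    cand = select_candidates(table, fdr)
    skew_p = (binomial_skew_test(cand.n_hyper, len(cand))
              if len(cand) else float("nan"))
    p = _track(written, outdir / "diffmeth.csv")
    table.data.to_csv(p, index_label="cpg_id", float_format="%.12g")
    summary = _track(written, outdir / "diffmeth_summary.json")
    _write_json({"n_scanned": len(table), "fdr_threshold": fdr,
                 "n_candidates": len(cand), "n_hyper": cand.n_hyper,
                 "n_hypo": cand.n_hypo, "binomial_skew_p": skew_p,
                 "n_flagged": table.n_flagged}, summary)
    state.update(diffmeth=table, candidates=cand)
    return [p, summary]


def _stage_derive(cfg: PipelineConfig, outdir: Path, state: dict,
                  written: list[Path]):
    matrix, sheet = _load_discovery(cfg, state)
    if "candidates" not in state:
        raise ValueError("derive requires the diffmeth stage")
    ens = EnsembleConfig(seed=cfg.seed, **cfg.derive)
    sig = stack_ensemble(matrix, sheet.group, ens, state["candidates"])
    p = _track(written, outdir / "signature.csv")
    write_signature(sig, p)
    state["signature"] = sig
    return [p]


def _get_signature(cfg: PipelineConfig, state: dict):
    if "signature" not in state:
        state["signature"] = read_signature(cfg.paths["signature"])
    return state["signature"]


def _stage_score(cfg: PipelineConfig, outdir: Path, state: dict,
                 written: list[Path]):
    matrix, _sheet = _load_prospective(cfg, state)
    sig = _get_signature(cfg, state)
    table = score_samples(matrix, sig)
    p = _track(written, outdir / "scores.csv")
    table.scores.to_csv(p, float_format="%.12g")
    state["scores"] = table
    return [p]


def _stage_validate(cfg: PipelineConfig, outdir: Path, state: dict,
                    written: list[Path]):
    _matrix, sheet = _load_prospective(cfg, state)
    table = state["scores"]
    rep = somers_auc(table.scores.loc[sheet.sample_ids], sheet.group)
    p = _track(written, outdir / "validation.json")
    _write_json({"auc": rep.auc, "dxy": rep.dxy, "ci_low": rep.ci_low,
                 "ci_high": rep.ci_high, "p_value": rep.p_value,
                 "n_cpgs_used": table.n_cpgs_used,
                 "n_cpgs_missing": table.n_cpgs_missing}, p)
    return [p]


def _stage_survival(cfg: PipelineConfig, outdir: Path, state: dict,
                    written: list[Path]):
    _matrix, sheet = _load_prospective(cfg, state)
    scores = state["scores"].scores.loc[sheet.sample_ids]
    high = dichotomize_scores(scores.to_numpy())
    rep = cox_binary_hr(sheet.data["followup_time"].to_numpy(),
                        sheet.data["event"].to_numpy(dtype=int), high)
    p = _track(written, outdir / "survival.json")
    _write_json({"hr": rep.hr, "hr_ci": list(rep.hr_ci),
                 "logrank_p": rep.logrank_p, "monotone": rep.monotone,
                 "threshold_rule": "mean_split",
                 "n_high": int(high.sum()), "n_low": int((1 - high).sum())}, p)
    return [p]


def _stage_enrich(cfg: PipelineConfig, outdir: Path, state: dict,
                  written: list[Path]):
    sig = _get_signature(cfg, state)
    ann = state.get("annotation") or read_annotation(cfg.paths["annotation"])
    sets = state.get("gene_sets") or read_gene_sets(cfg.paths["gene_sets"])
    universe = (state["diffmeth"].data.index if "diffmeth" in state
                else ann.data.index)
    _total, _nh, _nl = signature_summary(sig)
    outs = []
    for direction, mask in (("hyper", sig.coefficients > 0),
                            ("hypo", sig.coefficients < 0)):
        query = sig.cpg_ids[mask]
        p = _track(written, outdir / f"enrichment_{direction}.csv")
        if len(query):
            tab = hypergeom_enrichment(query, ann, sets, universe)
            tab.data.to_csv(p, float_format="%.12g")
        else:
            p.write_text("set_name,n_query_in_set,n_set_in_universe,"
                         "expected_overlap,p_value,adjusted_p\n")
        outs.append(p)
    return outs


_RUNNERS = {
    "simulate": _stage_simulate,
    "diffmeth": _stage_diffmeth,
    "derive": _stage_derive,
    "score": _stage_score,
    "validate": _stage_validate,
    "survival": _stage_survival,
    "enrich": _stage_enrich,
}
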