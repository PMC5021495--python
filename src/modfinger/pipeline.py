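"""End-to-end pipeline runner driven by a single YAML config.

Stages run in dependency order (simulate/load -> dge -> fingerprint ->
signature -> cluster -> enrich); every referenced input path is checked
before any stage runs, the effective config (defaults resolved) is
written next to the outputs, and a manifest records a sha256 per
artifact plus seed, versions and per-stage wall time.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

import modfinger
from modfinger import clustering, dge, enrichment, fingerprint, signature, synthetic_data
from modfinger import io_formats as iof

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("modfinger.pipeline")


class PipelineError(RuntimeError):
    pass


_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "out_dir": "modfinger_out",
    "alpha": 0.05,
    "collapse": "max-mean",
    "fingerprint": {"denominator": "measured"},
    "signature": {"enabled": True, "folds": 5, "priors": "frequency", "n_deltas": 30},
    "cluster": {
        "enabled": True,
        "k_cut": 2,
        "distance": "correlation",
        "linkage": "average",
        "heatmap": True,
    },
    "enrich": {"enabled": True},
}


class RunConfig:
    """Validated pipeline configuration (YAML mapping with defaults resolved)."""

    def __init__(self, raw: dict[str, Any], base_dir: Path | None = None):
        if not isinstance(raw, dict):
            raise PipelineError("config must be a mapping")
        self.base_dir = Path(base_dir) if base_dir else Path.cwd()
        cfg = _merge(_DEFAULTS, raw)
        self.cfg = cfg
        self.seed = int(cfg["seed"])
        self.alpha = float(cfg["alpha"])
        self.out_dir = self._resolve(cfg["out_dir"])
        if "simulate" not in cfg and "inputs" not in cfg:
            raise PipelineError("config needs a 'simulate' or an 'inputs' section")
        contrasts = cfg.get("contrasts")
        if not contrasts:
            raise PipelineError("config needs a non-empty 'contrasts' list")
        self.contrasts: list[tuple[str, str, str]] = []
        for c in contrasts:
            try:
                cid, (ga, gb) = c["id"], c["groups"]
            except (KeyError, TypeError, ValueError):
                raise PipelineError(
                    f"malformed contrast entry {c!r}; need id and two groups"
                ) from None
            self.contrasts.append((str(cid), str(ga), str(gb)))
        if len({c[0] for c in self.contrasts}) != len(self.contrasts):
            raise PipelineError("duplicate contrast ids")
        self.validate_paths()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise PipelineError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(raw, base_dir=path.parent)

    def _resolve(self, p: str | Path) -> Path:
        p = Path(p)
        return p if p.is_absolute() else self.base_dir / p

    def validate_paths(self) -> None:
        """Fail fast: every referenced input must exist before any stage runs."""
        inputs = self.cfg.get("inputs")
        if inputs:
            for key in ("expr", "meta", "modules"):
                if key not in inputs:
                    raise PipelineError(f"'inputs' section is missing {key!r}")
                p = self._resolve(inputs[key])
                if not p.exists():
                    raise PipelineError(f"input file for {key!r} not found: {p}")

    def effective_yaml(self) -> str:
        return yaml.safe_dump(self.cfg, sort_keys=True)


def _merge(defaults: dict, override: dict) -> dict:
    out: dict[str, Any] = {}
    for k, v in defaults.items():
        if k in override and isinstance(v, dict) and isinstance(override[k], dict):
            out[k] = _merge(v, override[k])
        elif k in override:
            out[k] = override[k]
        else:
            out[k] = json.loads(json.dumps(v)) if isinstance(v, dict) else v
    for k, v in override.items():
        if k not in out:
            out[k] = v
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig | dict | str | Path) -> dict[str, Any]:
    """Run every enabled stage; returns (and writes) the artifact manifest.

    On stage failure the manifest marks the failure point, partial
    outputs are retained and :class:`PipelineError` is raised.
    """
    if isinstance(config, (str, Path)):
        config = RunConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = RunConfig(config)
    cfg = config.cfg
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict[str, Any] = {
        "package": "modfinger",
        "version": modfinger.__version__,
        "seed": config.seed,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "stages": [],
        "artifacts": {},
        "status": "running",
    }
    manifest_path = out / "manifest.json"

    def record(path: Path) -> None:
        manifest["artifacts"][str(path.relative_to(out))] = _sha256(path)

    def finish_stage(name: str, t0: float) -> None:
        manifest["stages"].append({"stage": name, "seconds": round(time.time() - t0, 3)})
        log.info("stage %s done in %.2fs", name, time.time() - t0)

    (out / "config.effective.yaml").write_text(config.effective_yaml())
    record(out / "config.effective.yaml")

    try:
        # ---- stage: simulate or load -------------------------------------
        t0 = time.time()
        if "simulate" in cfg:
            sim = cfg["simulate"] or {}
            if sim.get("paper_like", True):
                sconf = synthetic_data.make_paper_like_design(
                    seed=config.seed, n_genes=int(sim.get("n_genes", 1500))
                )
            else:
                raise PipelineError(
                    "only 'paper_like: true' simulate configs are supported; "
                    "build a SimulationConfig in code for custom designs"
                )
            expr, meta, modules, truth = synthetic_data.simulate_cohorts(sconf)
            iof.write_expression(expr, out / "expr.tsv")
            iof.write_metadata(meta, out / "meta.tsv")
            iof.write_gmt(modules, out / "modules.gmt")
            synthetic_data.write_truth(truth, out / "truth.tsv")
            for name in ("expr.tsv", "meta.tsv", "modules.gmt", "truth.tsv"):
                record(out / name)
            finish_stage("simulate", t0)
        else:
            inputs = cfg["inputs"]
            expr = iof.read_expression(
                config._resolve(inputs["expr"]),
                format=inputs.get("format", "tsv"),
                collapse=cfg["collapse"],
            )
            meta = iof.read_metadata(config._resolve(inputs["meta"]))
            modules = iof.read_gmt(config._resolve(inputs["modules"]))
            finish_stage("load", t0)

        # ---- stage: dge ---------------------------------------------------
        t0 = time.time()
        dge_tables: list[tuple[str, pd.DataFrame]] = []
        for cid, ga, gb in config.contrasts:
            table = dge.moderated_t(expr, meta, (ga, gb))
            iof.write_dge(table, out / f"dge_{cid}.tsv")
            record(out / f"dge_{cid}.tsv")
            dge_tables.append((cid, table))
        finish_stage("dge", t0)

        # ---- stage: fingerprint -------------------------------------------
        t0 = time.time()
        denom = cfg["fingerprint"]["denominator"]
        grid = fingerprint.fingerprint_grid(
            dge_tables, modules, alpha=config.alpha, denominator=denom
        )
        for cid in grid.contrast_ids:
            fp = grid.fingerprints[cid]
            iof.write_fingerprint(fp, out / f"fingerprint_{cid}.tsv")
            iof.write_fingerprint_json(fp, out / f"fingerprint_{cid}.json")
            record(out / f"fingerprint_{cid}.tsv")
            record(out / f"fingerprint_{cid}.json")
        fingerprint.render_grid(grid, out / "fingerprint_grid.tsv")
        record(out / "fingerprint_grid.tsv")
        finish_stage("fingerprint", t0)

        first_cid, first_a, first_b = config.contrasts[0]
        pair_samples = [
            s for s in meta.sample_ids
            if meta.group_of()[s] in (first_a, first_b) and s in set(expr.sample_ids)
        ]
        pair_expr = expr.subset_samples(pair_samples)
        pair_meta = meta.subset(pair_samples)
        pair_meta = iof.SampleMetadata(
            pair_meta.sample_ids, pair_meta.groups, allowed_groups=(first_a, first_b)
        )

        # ---- stage: signature ----------------------------------------------
        sig_cfg = cfg["signature"]
        if sig_cfg.get("enabled", True):
            t0 = time.time()
            cv = signature.nsc_cv(
                pair_expr,
                pair_meta,
                n_folds=int(sig_cfg.get("folds", 5)),
                seed=config.seed,
                priors=sig_cfg.get("priors", "frequency"),
                n_deltas=int(sig_cfg.get("n_deltas", 30)),
            )
            cv.model.to_json(out / "signature_model.json")
            pd.DataFrame(
                {
                    "delta": cv.deltas,
                    "cv_errors": cv.total_errors,
                    "genes_surviving": cv.genes_surviving,
                }
            ).to_csv(out / "signature_cv.tsv", sep="\t", index=False)
            record(out / "signature_model.json")
            record(out / "signature_cv.tsv")
            finish_stage("signature", t0)

        # ---- stage: cluster --------------------------------------------------
        clu_cfg = cfg["cluster"]
        if clu_cfg.get("enabled", True):
            t0 = time.time()
            up, down = dge.significant_genes(dge_tables[0][1], config.alpha)
            de_genes = up | down
            if not de_genes:
                raise PipelineError(
                    f"no significant genes at alpha={config.alpha} for contrast "
                    f"{first_cid!r}; cannot cluster"
                )
            tree = clustering.cluster_samples(
                pair_expr,
                genes=de_genes,
                distance=clu_cfg.get("distance", "correlation"),
                method=clu_cfg.get("linkage", "average"),
            )
            target = clu_cfg.get("target", first_a)
            sep = clustering.separation_score(
                tree, pair_meta, target_group=target, k_cut=int(clu_cfg.get("k_cut", 2))
            )
            with open(out / "cluster_separation.tsv", "w") as fh:
                fh.write("target_group\tk_cut\tseparated_count\ttarget_group_size\n")
                fh.write(
                    f"{sep.target_group}\t{sep.k_cut}\t{sep.separated_count}\t"
                    f"{sep.target_group_size}\n"
                )
            record(out / "cluster_separation.tsv")
            if clu_cfg.get("heatmap", True):
                clustering.render_heatmap(
                    pair_expr,
                    de_genes,
                    pair_meta,
                    out / "heatmap.png",
                    distance=clu_cfg.get("distance", "correlation"),
                    method=clu_cfg.get("linkage", "average"),
                )
                record(out / "heatmap.png")
            finish_stage("cluster", t0)

        # ---- stage: enrich ----------------------------------------------------
        if cfg["enrich"].get("enabled", True):
            t0 = time.time()
            up, down = dge.significant_genes(dge_tables[0][1], config.alpha)
            query = up | down
            if query:
                table = enrichment.hypergeometric_enrichment(
                    query, modules, universe=set(expr.gene_ids)
                )
                table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
                record(out / "enrichment.tsv")
            finish_stage("enrich", t0)

    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = str(exc)
        manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(str(exc)) from exc

    manifest["status"] = "ok"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
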