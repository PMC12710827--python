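"""End-to-end pipeline: model + signatures + collections → ranked genes + ORA.

Writes, under the output directory, one mapping TSV per signature, one
enrichment TSV per signature x collection, and a JSON run-manifest recording
parameters, package version and SHA-256 digests of every input so runs are
reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .enrichment import read_gmt, run_ora
from .mapping import canonical_rule, read_signature, signature_to_genes
from .model import load_gem
from .specificity import WeightParams

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat configuration for a full pipeline run.

    CLI flags override config-file values; defaults are the module defaults.
    """

    model: str = ""
    model_format: str = "toy-json"
    rule: str = "non-directional"
    collapse_compartments: bool = True
    weight_a: float = 2.0
    weight_b: float | None = None  # default: half-point at s = 0.05
    half_point_s: float | None = None
    universe: str = "collapsed"
    alpha: float = 0.05
    background: str | None = None  # path to custom background list, or None
    use_weights: bool = True
    outdir: str = "gemsig-out"
    seed: int = 0
    log_level: str = "INFO"

    def weight_params(self) -> WeightParams:
        if self.half_point_s is not None:
            return WeightParams.from_half_point(self.half_point_s, a=self.weight_a)
        if self.weight_b is not None:
            return WeightParams(a=self.weight_a, b=self.weight_b)
        return WeightParams(a=self.weight_a)

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        canonical_rule(self.rule)
        if self.model and not Path(self.model).exists():
            raise FileNotFoundError(self.model)
        if self.background and not Path(self.background).exists():
            raise FileNotFoundError(self.background)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_tsv(df, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.4g")


def run_pipeline(
    config: RunConfig,
    signature_files: list[str],
    gmt_files: list[str],
) -> dict:
    """Run map → score → enrich and write all artifacts; returns the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    model = load_gem(config.model, config.model_format)
    collections = [read_gmt(p) for p in gmt_files]
    background = None
    if config.background:
        background = {
            ln.strip()
            for ln in Path(config.background).read_text().splitlines()
            if ln.strip()
        }
    else:
        background = set(model.genes)

    signatures = []
    for p in signature_files:
        signatures.extend(read_signature(p))

    params = config.weight_params()
    results = signature_to_genes(
        signatures,
        model,
        rule=config.rule,
        weight_params=params,
        collapse_compartments=config.collapse_compartments,
        universe=config.universe,
    )

    artifacts: list[str] = []
    full_precision: dict[str, dict] = {}
    for sig, res in zip(signatures, results):
        stem = sig.label.replace(" ", "_")
        map_path = outdir / f"{stem}.mapping.tsv"
        _write_tsv(res.to_frame(), map_path)
        artifacts.append(str(map_path))
        full_precision[stem] = {
            g.gene_id: {"s_i": g.s_i, "w_i": g.w_i} for g in res.mapped_genes
        }
        if not res.mapped_genes:
            log.warning("signature %s mapped no genes; enrichment skipped", sig.label)
            continue
        for report in run_ora(
            res,
            collections,
            background=background,
            use_weights=config.use_weights,
            alpha=config.alpha,
        ):
            enr_path = outdir / f"{stem}.{report.collection}.enrichment.tsv"
            _write_tsv(report.to_frame(), enr_path)
            artifacts.append(str(enr_path))

    sidecar = outdir / "scores.json"
    sidecar.write_text(json.dumps(full_precision, indent=1) + "\n")
    manifest = {
        "gemsig_version": __version__,
        "config": {k: getattr(config, k) for k in config.__dataclass_fields__},
        "inputs": {
            "model": {"path": str(config.model), "sha256": _sha256(config.model)},
            "signatures": [
                {"path": str(p), "sha256": _sha256(p)} for p in signature_files
            ],
            "gene_sets": [{"path": str(p), "sha256": _sha256(p)} for p in gmt_files],
        },
        "artifacts": artifacts + [str(sidecar)],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
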