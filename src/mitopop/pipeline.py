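"""Pipeline orchestration: run curation, diversity, structure, drift
simulation, and rho dating from a single YAML config with a manifest.

Config layout (all stages optional; defaults mirror the standard study
parameters)::

    seed: 1
    out_dir: results/
    inputs:
      fasta: data/aln.fasta
      metadata: data/meta.tsv
    mask:
      ranges: [[303, 315], [16183, 16194]]
      drop_indel_columns: true
    stages:
      curate: true
      diversity: true
      structure:
        n_perm: 1000
        groupings: {linguistic: config/groups.tsv}
      driftsim:
        presets: [a, b, c, d]
        n_outer: 10000
        n_inner: 100
      rho:
        founder_fasta: data/founder.fasta
        clock: 3533
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .dating import rho_estimate
from .diversity import diversity_table, sharing_summary
from .driftsim import SPLIT_YEARS_DEFAULT, preset_scenario, run_grid
from .errors import ConfigError
from .seqdata import (
    MaskSpec,
    apply_mask,
    collapse_haplotypes,
    impute_missing,
    pairwise_diff_matrix,
    read_alignment,
    read_metadata,
)
from .structure import amova, geo_distance_matrix, mantel, phi_st_pairwise

log = logging.getLogger("mitopop.pipeline")


@dataclass
class RunConfig:
    seed: int
    out_dir: Path
    fasta: Path | None = None
    metadata: Path | None = None
    mask: MaskSpec = field(default_factory=MaskSpec)
    stages: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config must be a YAML mapping")
        unknown = set(raw) - {"seed", "out_dir", "inputs", "mask", "stages"}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "out_dir" not in raw:
            raise ConfigError("config requires out_dir")
        inputs = raw.get("inputs", {}) or {}
        mask_raw = raw.get("mask", {}) or {}
        mask = MaskSpec(
            ranges=[tuple(r) for r in mask_raw.get("ranges", [])],
            drop_indel_columns=bool(mask_raw.get("drop_indel_columns", False)),
        )
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            out_dir=Path(raw["out_dir"]),
            fasta=Path(inputs["fasta"]) if "fasta" in inputs else None,
            metadata=Path(inputs["metadata"]) if "metadata" in inputs else None,
            mask=mask,
            stages=raw.get("stages", {}) or {},
        )
        for key, p in (("fasta", cfg.fasta), ("metadata", cfg.metadata)):
            if p is not None and not p.exists():
                raise ConfigError(f"input {key} does not exist: {p}")
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_enabled(stages: dict, name: str) -> bool:
    return bool(stages.get(name, False))


def _stage_opts(stages: dict, name: str) -> dict:
    v = stages.get(name)
    return v if isinstance(v, dict) else {}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in dependency order and write a manifest.

    Returns the manifest dict.  Any stage failure raises with the stage
    name; already-produced outputs stay on disk.
    """
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "stages": {},
        "files": {},
    }

    aln = meta = None
    need_data = any(
        _stage_enabled(cfg.stages, s) for s in ("curate", "diversity", "structure", "rho")
    )
    if need_data:
        if cfg.fasta is None or cfg.metadata is None:
            raise ConfigError("curate/diversity/structure/rho stages require "
                              "inputs.fasta and inputs.metadata")
        aln = read_alignment(cfg.fasta)
        meta = read_metadata(cfg.metadata)
        known = {r.sample_id for r in meta}
        orphans = [s for s in aln.sample_ids if s not in known]
        if orphans:
            raise ConfigError(f"aligned samples without metadata: {orphans}")

    def emit(name: str, path: Path) -> None:
        manifest["files"][str(path.relative_to(out))] = _sha256(path)

    try:
        if _stage_enabled(cfg.stages, "curate"):
            log.info("stage=curate masking and imputing")
            aln = apply_mask(aln, cfg.mask)
            aln, report = impute_missing(aln)
            aln.write_fasta(out / "curated.fasta")
            report.write_tsv(out / "imputation_report.tsv")
            ht = collapse_haplotypes(aln, meta)
            ht.write_tsv(out / "haplotypes.tsv")
            emit("curate", out / "curated.fasta")
            emit("curate", out / "imputation_report.tsv")
            emit("curate", out / "haplotypes.tsv")
            manifest["stages"]["curate"] = "ok"

        if _stage_enabled(cfg.stages, "diversity"):
            log.info("stage=diversity per-population statistics")
            table = diversity_table(aln, meta)
            table.to_csv(out / "diversity.tsv", sep="\t", index=False)
            emit("diversity", out / "diversity.tsv")
            opts = _stage_opts(cfg.stages, "diversity")
            if "sharing_groups" in opts:
                grouping = _read_grouping(opts["sharing_groups"])
                ht = collapse_haplotypes(aln, meta)
                summary = sharing_summary(ht, grouping)
                with open(out / "sharing.json", "w") as fh:
                    json.dump(summary.to_json_dict(), fh, indent=2)
                emit("diversity", out / "sharing.json")
            manifest["stages"]["diversity"] = "ok"

        if _stage_enabled(cfg.stages, "structure"):
            opts = _stage_opts(cfg.stages, "structure")
            n_perm = int(opts.get("n_perm", 1000))
            log.info("stage=structure phi_st/amova/mantel n_perm=%d", n_perm)
            pops = {r.sample_id: r.population for r in meta}
            d = pairwise_diff_matrix(aln)
            phi, pmat = phi_st_pairwise(d, pops, n_perm=n_perm, seed=cfg.seed)
            phi.write_tsv(out / "phi_st.tsv")
            pmat.write_tsv(out / "phi_st_pvalues.tsv")
            emit("structure", out / "phi_st.tsv")
            emit("structure", out / "phi_st_pvalues.tsv")
            amova_results = {}
            amova_results["one_level"] = amova(
                d, pops, n_perm=n_perm, seed=cfg.seed
            ).to_json_dict()
            for name, path in (opts.get("groupings") or {}).items():
                grouping = _read_grouping(path)
                amova_results[name] = amova(
                    d, pops, groups=grouping, n_perm=n_perm, seed=cfg.seed
                ).to_json_dict()
            with open(out / "amova.json", "w") as fh:
                json.dump(amova_results, fh, indent=2)
            emit("structure", out / "amova.json")
            shared = []
            if opts.get("mantel", True) and any(r.lat is not None for r in meta):
                geo = geo_distance_matrix(meta)
                shared = [p for p in phi.labels if p in geo.labels]
            if len(shared) >= 3:
                res = mantel(
                    phi.subset(shared), geo.subset(shared),
                    n_perm=n_perm, seed=cfg.seed,
                )
                with open(out / "mantel.json", "w") as fh:
                    json.dump(res.__dict__, fh, indent=2)
                emit("structure", out / "mantel.json")
            manifest["stages"]["structure"] = "ok"

        if _stage_enabled(cfg.stages, "driftsim"):
            opts = _stage_opts(cfg.stages, "driftsim")
            presets = opts.get("presets", ["a", "b", "c", "d"])
            splits = [int(s) for s in opts.get("splits", SPLIT_YEARS_DEFAULT)]
            log.info("stage=driftsim presets=%s", presets)
            for name in presets:
                sc, freqs = preset_scenario(
                    name,
                    n_outer=int(opts.get("n_outer", 10000)),
                    n_inner=int(opts.get("n_inner", 100)),
                    seed=cfg.seed,
                )
                grid = run_grid(opts.get("freqs", freqs), splits, sc)
                grid.write_tsv(out / f"driftsim_{name}.tsv")
                grid.write_json(out / f"driftsim_{name}.json")
                emit("driftsim", out / f"driftsim_{name}.tsv")
                emit("driftsim", out / f"driftsim_{name}.json")
            manifest["stages"]["driftsim"] = "ok"

        if _stage_enabled(cfg.stages, "rho"):
            opts = _stage_opts(cfg.stages, "rho")
            founder_path = opts.get("founder_fasta")
            if founder_path is None:
                raise ConfigError("rho stage requires founder_fasta")
            founder_aln = read_alignment(founder_path)
            res = rho_estimate(
                aln, founder_aln.sequences()[0],
                clock=float(opts.get("clock", 3533.0)),
            )
            res.write_json(out / "rho.json")
            emit("rho", out / "rho.json")
            manifest["stages"]["rho"] = "ok"
    except Exception as exc:
        stage = next(
            (s for s in ("curate", "diversity", "structure", "driftsim", "rho")
             if s not in manifest["stages"] and _stage_enabled(cfg.stages, s)),
            "unknown",
        )
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _read_grouping(path) -> dict[str, str]:
    """Two-column TSV (population, group) -> mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["population", "group"],
                     dtype=str, comment="#")
    return dict(zip(df["population"], df["group"]))
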