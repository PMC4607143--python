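"""End-to-end orchestration: filter -> diversity/haplotypes -> parentage.

A run is driven by a YAML config; every output TSV starts with a header
comment carrying the tool version, config hash and seed, and a machine-
readable manifest records input checksums so a run can be reproduced
exactly. Logs report counts (loci removed, amplicons flagged, offspring per
confidence class), never genotypes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from . import __version__
from .diversity import diversity_report, individual_heterozygosity, locus_stats
from .filtering import FilterConfig, amplicon_qc, apply_maf_filter
from .io import (read_genotypes, read_panel_csv, read_registry_csv,
                 read_samples_csv, write_genotypes)
from .parentage import ParentageConfig, assign_parentage

log = logging.getLogger("ampliped")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    panel: str
    genotypes: str
    genotype_format: str = "wide_csv"
    registry: str | None = None
    samples: str | None = None
    out_dir: str = "ampliped_out"
    seed: int = 0
    log_level: str = "INFO"
    filter: FilterConfig = field(default_factory=FilterConfig)
    parentage: ParentageConfig = field(default_factory=ParentageConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "filter" in doc and isinstance(doc["filter"], dict):
            doc["filter"] = FilterConfig(**doc["filter"])
        if "parentage" in doc and isinstance(doc["parentage"], dict):
            doc["parentage"] = ParentageConfig(**doc["parentage"])
        return cls(**doc)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header(cfg: RunConfig) -> str:
    return f"# ampliped {__version__} config={cfg.config_hash()} seed={cfg.seed}\n"


def _write_tsv(df: pd.DataFrame, path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(cfg))
        df.to_csv(fh, sep="\t", index=False)


def _checksum(path) -> str:
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()[:16]


def version_manifest(cfg: RunConfig, extra: dict | None = None) -> dict:
    """Machine-readable run record: version, config hash, seed, input checksums."""
    inputs = {}
    for name in ("panel", "genotypes", "registry", "samples"):
        path = getattr(cfg, name)
        if path and os.path.exists(path):
            inputs[name] = _checksum(path)
    manifest = {
        "tool": "ampliped",
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "inputs": inputs,
    }
    if extra:
        manifest.update(extra)
    return manifest


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute filter -> stats/haplotypes -> parentage; returns output paths
    and stage counts. Any stage error aborts with the stage named."""
    os.makedirs(cfg.out_dir, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(os.path.join(cfg.out_dir, "run.log"))
    fh.setLevel(logging.INFO)
    log.addHandler(fh)
    out: dict = {"outputs": {}, "counts": {}}

    try:
        panel = read_panel_csv(cfg.panel)
        matrix = read_genotypes(cfg.genotypes, cfg.genotype_format, panel)
    except Exception as exc:
        raise PipelineError("load", exc) from exc

    try:
        filtered, removed = apply_maf_filter(matrix, cfg.filter)
        out["counts"]["loci_input"] = matrix.n_loci
        out["counts"]["loci_removed_maf"] = len(removed)
        out["counts"]["loci_retained"] = filtered.n_loci
        log.info("MAF filter: %d of %d loci removed (threshold %.3f)",
                 len(removed), matrix.n_loci, cfg.filter.maf_threshold)
        removed_path = os.path.join(cfg.out_dir, "removed_loci.tsv")
        _write_tsv(pd.DataFrame({"locus_id": removed,
                                 "reason": ["maf_below_threshold"] * len(removed)}),
                   removed_path, cfg)
        geno_path = os.path.join(cfg.out_dir, "genotypes_filtered.csv")
        write_genotypes(filtered, geno_path, "wide_csv")
        qc = amplicon_qc(filtered, panel)
        out["counts"]["amplicons_flagged"] = int((qc["qc_flags"] != "").sum())
        qc_path = os.path.join(cfg.out_dir, "amplicon_qc.tsv")
        _write_tsv(qc, qc_path, cfg)
        out["outputs"].update(removed_loci=removed_path, genotypes=geno_path,
                              amplicon_qc=qc_path)
    except Exception as exc:
        raise PipelineError("filter", exc) from exc

    try:
        stats = locus_stats(filtered, panel)
        stats_df = pd.DataFrame([asdict(s) for s in stats])
        stats_path = os.path.join(cfg.out_dir, "locus_stats.tsv")
        _write_tsv(stats_df, stats_path, cfg)
        het, (edges, counts) = individual_heterozygosity(filtered)
        het_path = os.path.join(cfg.out_dir, "individual_het.tsv")
        _write_tsv(pd.DataFrame([asdict(h) for h in het]), het_path, cfg)
        hist_path = os.path.join(cfg.out_dir, "het_histogram.tsv")
        _write_tsv(pd.DataFrame({"bin_low": edges[:-1], "bin_high": edges[1:],
                                 "n_individuals": counts}), hist_path, cfg)
        report = diversity_report(filtered, panel)
        report_path = os.path.join(cfg.out_dir, "diversity_report.tsv")
        _write_tsv(report, report_path, cfg)
        out["counts"]["loci_not_in_hwe"] = int(sum(not s.in_hwe for s in stats))
        out["outputs"].update(locus_stats=stats_path, individual_het=het_path,
                              het_histogram=hist_path, diversity_report=report_path)
    except Exception as exc:
        raise PipelineError("stats", exc) from exc

    if cfg.registry:
        try:
            registry = read_registry_csv(cfg.registry)
            samples = read_samples_csv(cfg.samples) if cfg.samples else None
            pcfg = dataclasses.replace(cfg.parentage, rng_seed=cfg.seed)
            results = assign_parentage(registry, filtered, panel, pcfg, samples)
            rows = []
            for r in results:
                top = r.candidates[0] if r.candidates else None
                rows.append({
                    "offspring_id": r.offspring_id,
                    "mode": r.mode,
                    "assignment": r.assignment or "",
                    "confidence": r.confidence,
                    "delta": r.delta,
                    "critical_delta_strict": r.critical_delta.get("strict", ""),
                    "critical_delta_relaxed": r.critical_delta.get("relaxed", ""),
                    "top_candidate": top.candidate_id if top else "",
                    "top_lod": top.lod if top else "",
                    "top_shared_loci": top.shared_loci if top else 0,
                    "top_exclusions": top.exclusions if top else 0,
                    "ranking": ";".join(
                        f"{s.candidate_id}:{s.lod:.3f}:{s.shared_loci}:{s.exclusions}"
                        for s in r.candidates),
                    "notes": r.notes,
                })
            par_path = os.path.join(cfg.out_dir, "parentage.tsv")
            _write_tsv(pd.DataFrame(rows), par_path, cfg)
            by_conf: dict[str, int] = {}
            for r in results:
                by_conf[r.confidence] = by_conf.get(r.confidence, 0) + 1
            out["counts"]["offspring_by_confidence"] = by_conf
            log.info("parentage confidence classes: %s", by_conf)
            out["outputs"]["parentage"] = par_path
        except Exception as exc:
            raise PipelineError("parentage", exc) from exc

    manifest = version_manifest(cfg, extra={"counts": out["counts"]})
    manifest_path = os.path.join(cfg.out_dir, "manifest.json")
    with open(manifest_path, "w") as fhj:
        json.dump(manifest, fhj, indent=1, sort_keys=True)
    out["outputs"]["manifest"] = manifest_path
    log.removeHandler(fh)
    fh.close()
    return out
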