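"""End-to-end pipeline runners with config files, manifests, and logging.

Two entry points wire the modules together: the anti-CRISPR discovery
pipeline (catalog -> filter cascade -> structural screen -> fusion scan)
and the defense-island pipeline (system annotations -> inter-system
regions -> intervening proteins -> defense-candidate screen -> marker
prevalence). Each run takes one YAML config naming every input path and
any threshold overrides, and writes its reports plus a JSON manifest
(config snapshot, input checksums, version, seed, funnel counts, wall
clock per stage) so a run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import yaml

from . import __version__, islands, screens
from .io_formats import (ProteinRecord, read_ca_trace, read_defense_table,
                         read_domain_table, read_fasta, write_report)
from .structalign import AlignConfig

logger = logging.getLogger(__name__)


class PipelineConfigError(Exception):
    """A config or input-validation problem (CLI exit code 2)."""


def _load_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise PipelineConfigError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise PipelineConfigError(f"config {path} is not a mapping")
    return cfg


def _require(cfg: dict, key: str, base: Path) -> Path:
    if key not in cfg:
        raise PipelineConfigError(f"config missing required key {key!r}")
    p = Path(cfg[key])
    if not p.is_absolute():
        p = base / p
    if not p.exists():
        raise PipelineConfigError(f"input path for {key!r} not found: {p}")
    return p


def _screen_config(cfg: dict) -> screens.ScreenConfig:
    overrides = cfg.get("screen", {}) or {}
    valid = {f.name for f in dataclasses.fields(screens.ScreenConfig)}
    bad = set(overrides) - valid
    if bad:
        raise PipelineConfigError(f"unknown screen option(s): {sorted(bad)}")
    return screens.ScreenConfig(**overrides)


def _align_config(cfg: dict) -> AlignConfig:
    overrides = cfg.get("align", {}) or {}
    valid = {f.name for f in dataclasses.fields(AlignConfig)}
    bad = set(overrides) - valid
    if bad:
        raise PipelineConfigError(f"unknown align option(s): {sorted(bad)}")
    return AlignConfig(**overrides)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_pdb_dir(pdb_dir: Path) -> dict:
    models = {}
    for p in sorted(pdb_dir.glob("*.pdb")):
        models[p.stem] = read_ca_trace(p)
    return models


def _manifest(out_dir: Path, cfg: dict, inputs: list[Path], seed: int,
              funnel: screens.FunnelLog | None, timings: dict[str, float]) -> None:
    manifest = {
        "tool": "phagescan",
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "input_checksums": {str(p): _sha256(p) for p in sorted(set(inputs))},
        "funnel": [
            {"stage": s, "n_in": a, "n_retained": b, "n_excluded": c}
            for s, a, b, c in (funnel.stages if funnel else [])
        ],
        "wall_clock_s": {k: round(v, 3) for k, v in timings.items()},
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def run_acr_pipeline(config_path: str | Path) -> Path:
    """Run the full anti-CRISPR screen plus fusion scan from a YAML config.

    Required config keys: catalog_fasta, pdb_dir, refs_fasta, refs_pdb_dir,
    domains_tsv, out_dir. Optional: seed, screen:{...}, align:{...}.
    Writes report.tsv, funnel.tsv, fusions.tsv, manifest.json.
    """
    cfg = _load_config(config_path)
    base = Path(config_path).parent
    catalog_p = _require(cfg, "catalog_fasta", base)
    pdb_dir = _require(cfg, "pdb_dir", base)
    refs_p = _require(cfg, "refs_fasta", base)
    refs_pdb = _require(cfg, "refs_pdb_dir", base)
    domains_p = _require(cfg, "domains_tsv", base)
    if "out_dir" not in cfg:
        raise PipelineConfigError("config missing required key 'out_dir'")
    out_dir = Path(cfg["out_dir"])
    if not out_dir.is_absolute():
        out_dir = base / out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))

    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    catalog = read_fasta(catalog_p)
    structures = _read_pdb_dir(pdb_dir)
    refs = read_fasta(refs_p)
    ref_structures = _read_pdb_dir(refs_pdb)
    domains = read_domain_table(domains_p)
    missing = [r.protein_id for r in refs if r.protein_id not in ref_structures]
    if missing:
        raise PipelineConfigError(
            f"reference(s) without structure in {refs_pdb}: {missing}")
    timings["load"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    reports, funnel = screens.acr_screen(
        catalog, structures, refs, ref_structures, domains,
        _screen_config(cfg), _align_config(cfg))
    timings["acr_screen"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    fusions = screens.fusion_scan(reports, _screen_config(cfg))
    timings["fusion_scan"] = time.perf_counter() - t0

    write_report(reports, out_dir / "report.tsv")
    funnel.write_tsv(out_dir / "funnel.tsv")
    with open(out_dir / "fusions.tsv", "w") as fh:
        fh.write("candidate_id\tref_a\tref_b\tspan_a\tspan_b\tjaccard\t"
                 "putative_fusion\n")
        for f in fusions:
            fh.write(f"{f.candidate_id}\t{f.reference_ids[0]}\t"
                     f"{f.reference_ids[1]}\t"
                     f"{f.intervals[0][0]}-{f.intervals[0][1]}\t"
                     f"{f.intervals[1][0]}-{f.intervals[1][1]}\t"
                     f"{f.jaccard:.4f}\t{int(f.putative_fusion)}\n")
    _manifest(out_dir, cfg, [catalog_p, refs_p, domains_p], seed, funnel,
              timings)
    return out_dir


def read_gene_table(path: str | Path, sequences: dict[str, str]) -> list[ProteinRecord]:
    """Join a gene-coordinate TSV (protein_id, genome_id, contig_id, start,
    end, strand) with sequences from FASTA into coordinate-bearing records."""
    import csv

    out: list[ProteinRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for col in ("protein_id", "genome_id", "contig_id", "start", "end",
                    "strand"):
            if col not in (reader.fieldnames or []):
                raise PipelineConfigError(f"gene table {path}: missing column {col!r}")
        for row in reader:
            seq = sequences.get(row["protein_id"])
            if seq is None:
                logger.warning("gene %s has no sequence; skipped",
                               row["protein_id"])
                continue
            out.append(ProteinRecord(
                protein_id=row["protein_id"], sequence=seq,
                genome_id=row["genome_id"], contig_id=row["contig_id"],
                start=int(row["start"]), end=int(row["end"]),
                strand=row["strand"]))
    return out


def run_defense_pipeline(config_path: str | Path) -> Path:
    """Run island mining, the defense-candidate screen, and marker
    prevalence from a YAML config.

    Required keys: systems_tsv, genes_tsv, genes_fasta, pdb_dir, refs_fasta,
    refs_pdb_dir, domains_tsv, out_dir. Optional: marker_hits_tsv,
    system_name (default BREX_type_3), seed, screen/align overrides.
    Writes regions.tsv, report.tsv, funnel.tsv, prevalence.tsv,
    manifest.json.
    """
    cfg = _load_config(config_path)
    base = Path(config_path).parent
    systems_p = _require(cfg, "systems_tsv", base)
    genes_tsv = _require(cfg, "genes_tsv", base)
    genes_fa = _require(cfg, "genes_fasta", base)
    pdb_dir = _require(cfg, "pdb_dir", base)
    refs_p = _require(cfg, "refs_fasta", base)
    refs_pdb = _require(cfg, "refs_pdb_dir", base)
    domains_p = _require(cfg, "domains_tsv", base)
    if "out_dir" not in cfg:
        raise PipelineConfigError("config missing required key 'out_dir'")
    out_dir = Path(cfg["out_dir"])
    if not out_dir.is_absolute():
        out_dir = base / out_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    sconfig = _screen_config(cfg)

    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    systems = read_defense_table(systems_p)
    seqs = {r.protein_id: r.sequence for r in read_fasta(genes_fa)}
    genes = read_gene_table(genes_tsv, seqs)
    structures = _read_pdb_dir(pdb_dir)
    refs = read_fasta(refs_p)
    ref_structures = _read_pdb_dir(refs_pdb)
    domains = read_domain_table(domains_p)
    timings["load"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    regions = islands.find_intersystem_regions(
        systems, genes, sconfig.island_min_gap, sconfig.island_max_gap)
    catalog = {g.protein_id: g for g in genes}
    intervening = islands.extract_intervening_proteins(regions, catalog)
    timings["islands"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    reports, funnel = screens.defense_candidate_screen(
        intervening, structures, refs, ref_structures, domains, sconfig,
        _align_config(cfg))
    timings["defense_screen"] = time.perf_counter() - t0

    with open(out_dir / "regions.tsv", "w") as fh:
        fh.write("genome_id\tcontig_id\tleft_system\tright_system\tgap_bp\t"
                 "intervening_ids\n")
        for r in regions:
            fh.write(f"{r.genome_id}\t{r.contig_id}\t"
                     f"{r.left_system.system_name}\t"
                     f"{r.right_system.system_name}\t{r.gap_bp}\t"
                     f"{','.join(r.intervening_protein_ids) or '.'}\n")
    write_report(reports, out_dir / "report.tsv")
    funnel.write_tsv(out_dir / "funnel.tsv")

    inputs = [systems_p, genes_tsv, genes_fa, refs_p, domains_p]
    if "marker_hits_tsv" in cfg:
        marker_p = _require(cfg, "marker_hits_tsv", base)
        inputs.append(marker_p)
        with open(marker_p) as fh:
            header = fh.readline()
            hits = {line.strip() for line in fh if line.strip()}
        system_name = cfg.get("system_name", "BREX_type_3")
        try:
            prev = islands.prevalence(systems, hits, system_name)
            row = (f"{prev.system_name}\t{prev.marker_id}\t{prev.carriers}\t"
                   f"{prev.total}\t{prev.percent}\n")
        except ValueError as exc:
            raise PipelineConfigError(str(exc)) from exc
        with open(out_dir / "prevalence.tsv", "w") as fh:
            fh.write("system_name\tmarker_id\tcarriers\ttotal\tpercent\n")
            fh.write(row)
        logger.info("prevalence: %s", row.strip())
    _manifest(out_dir, cfg, inputs, seed, funnel, timings)
    return out_dir
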