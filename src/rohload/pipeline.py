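"""End-to-end orchestration: simulate -> filter -> polarize -> roh ->
demography -> load -> rxy, with per-stage JSON manifests and deterministic
seed fan-out.

A single global seed fans out to per-stage seeds through a fixed counter
scheme (``stage_seed = (global_seed * 64 + stage_index) % 2**31``); every
manifest records both, so any stage can be rerun in isolation and reproduced
bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .demography import LengthClassSpec, froh_by_class, ne_trajectory
from .load_stats import compute_loads, fixed_attribution, group_contrast, nucleotide_diversity, rxy
from .polarize import AncestralFasta, polarize
from .roh import ROHConfig, call_roh, compute_froh
from .synthetic import SimConfig, perturb_ancestral, simulate_population, write_truth_bed
from .variant_io import (FilterConfig, apply_site_filters,
                         attach_annotations, read_annotations, read_sample_table,
                         read_roh_bed, read_vcf, write_annotations, write_roh_bed,
                         write_sample_table, write_vcf)

log = logging.getLogger("rohload")

STAGES = ("simulate", "filter", "polarize", "roh", "demography", "load", "rxy")

DEFAULT_GENOME_LENGTH_BP = 2_440_000_000


def stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) * 64 + STAGES.index(stage)) % 2**31


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(path, stage: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"[{stage}] missing input file: {p}")
    return p


def write_manifest(out_dir, stage: str, inputs, config: dict, seed, global_seed) -> None:
    manifest = {
        "stage": stage,
        "version": __version__,
        "global_seed": global_seed,
        "stage_seed": seed,
        "inputs": {str(p): _sha256(p) for p in inputs if Path(p).exists()},
        "config": config,
    }
    path = Path(out_dir) / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")


class PipelineConfig:
    """Flat YAML-backed configuration for the whole pipeline.

    Recognized keys: ``out_dir``, ``seed``, ``genome_length_bp``, plus
    optional per-stage blocks ``sim``, ``filter``, ``roh``, ``demography``
    (``n_boot``), ``rxy`` (``classes``, ``n_boot``), ``ancestral_defects``
    (``frac_missing``, ``frac_mismatch``).
    """

    def __init__(self, data: dict):
        self.data = dict(data)
        self.out_dir = Path(self.data.get("out_dir", "rohload_out"))
        self.seed = int(self.data.get("seed", 0))
        self.genome_length_bp = float(self.data.get("genome_length_bp", DEFAULT_GENOME_LENGTH_BP))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def block(self, name: str) -> dict:
        return dict(self.data.get(name, {}) or {})


def _sim_config(cfg: PipelineConfig) -> SimConfig:
    block = cfg.block("sim")
    block.setdefault("seed", stage_seed(cfg.seed, "simulate"))
    if "chromosome_lengths" in block:
        block["chromosome_lengths"] = tuple(block["chromosome_lengths"])
    if "ne_trajectory" in block:
        block["ne_trajectory"] = tuple(tuple(x) for x in block["ne_trajectory"])
    if "population_trajectories" in block:
        block["population_trajectories"] = {
            k: tuple(tuple(x) for x in v) for k, v in block["population_trajectories"].items()
        }
    return SimConfig(**block)


def run_all(cfg: PipelineConfig) -> dict:
    """Execute every stage on synthetic inputs; returns a result summary.

    Each stage writes its outputs plus a JSON manifest (input checksums,
    config echo, seeds, version) under ``cfg.out_dir``. Any stage failure
    propagates with the stage name in the message.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"out_dir": str(out), "seed": cfg.seed}

    # --- simulate -----------------------------------------------------------
    sim_cfg = _sim_config(cfg)
    dataset, anc, truth = simulate_population(sim_cfg)
    defects = cfg.block("ancestral_defects")
    ledger = {"missing": set(), "mismatch": set()}
    if defects:
        anc, ledger = perturb_ancestral(
            anc, dataset, float(defects.get("frac_missing", 0.0)),
            float(defects.get("frac_mismatch", 0.0)),
            seed=stage_seed(cfg.seed, "simulate") + 1,
        )
    vcf_path = out / "simulated.vcf"
    write_vcf(dataset, vcf_path)
    write_sample_table(dataset.samples, out / "samples.tsv")
    write_annotations(dataset, out / "annotations.tsv")
    write_truth_bed(truth, out / "truth_roh.bed")
    anc.to_fasta(out / "ancestral.fasta")
    write_manifest(out, "simulate", [], dataclasses.asdict(sim_cfg), sim_cfg.seed, cfg.seed)
    log.info("[simulate] %d samples x %d sites", dataset.n_samples, dataset.n_sites)

    # --- filter ---------------------------------------------------------------
    ds, report = run_filter(
        vcf_path, out / "samples.tsv", out / "filtered.vcf",
        FilterConfig(**cfg.block("filter")), annotations_path=out / "annotations.tsv",
    )
    summary["filter"] = report.as_dict()
    write_manifest(out, "filter", [vcf_path, out / "samples.tsv"],
                   summary["filter"], None, cfg.seed)

    # --- polarize ---------------------------------------------------------------
    ds_pol, pol_report = polarize(ds, anc)
    write_vcf(ds_pol, out / "polarized.vcf")
    summary["polarize"] = pol_report.as_dict()
    write_manifest(out, "polarize", [out / "filtered.vcf", out / "ancestral.fasta"],
                   summary["polarize"], None, cfg.seed)

    # --- roh ----------------------------------------------------------------------
    roh_cfg = ROHConfig(**cfg.block("roh"))
    segments = call_roh(ds_pol, roh_cfg)
    write_roh_bed(segments, out / "roh_segments.bed")
    froh = compute_froh(segments, cfg.genome_length_bp, sample_ids=ds_pol.sample_ids)
    froh.to_csv(out / "froh.tsv", sep="\t", index=False)
    froh_contrast = group_contrast(
        froh.set_index("sample_id").loc[ds_pol.sample_ids, "froh"],
        ds_pol.samples["management"], response="froh",
    )
    summary["roh"] = {"n_segments": len(segments),
                      "froh_mean": float(froh["froh"].mean()),
                      "froh_beta_management": froh_contrast.beta,
                      "froh_beta_ci": [froh_contrast.ci_low, froh_contrast.ci_high],
                      "froh_beta_p": froh_contrast.p_value}
    write_manifest(out, "roh", [out / "polarized.vcf"], dataclasses.asdict(roh_cfg),
                   None, cfg.seed)

    # --- demography ------------------------------------------------------------------
    demo_block = cfg.block("demography")
    spec = LengthClassSpec()
    class_froh, class_report = froh_by_class(segments, spec, cfg.genome_length_bp,
                                             sample_ids=ds_pol.sample_ids)
    seed_demo = stage_seed(cfg.seed, "demography")
    ne_tab = ne_trajectory(class_froh, ds_pol.samples, spec,
                           n_boot=int(demo_block.get("n_boot", 100)), seed=seed_demo)
    ne_tab.to_csv(out / "ne.tsv", sep="\t", index=False)
    summary["demography"] = {"n_unassigned": class_report["n_unassigned"]}
    write_manifest(out, "demography", [out / "roh_segments.bed"], demo_block,
                   seed_demo, cfg.seed)

    # --- load ----------------------------------------------------------------------
    loads = compute_loads(ds_pol)
    loads.to_csv(out / "load.tsv", sep="\t", index=False)
    fixed = fixed_attribution(ds_pol)
    fixed.to_csv(out / "fixed_attribution.tsv", sep="\t", index=False)
    pi_by_pop = {}
    for pop, grp in ds_pol.samples.groupby("population_id"):
        pi_by_pop[pop] = nucleotide_diversity(ds_pol, list(grp["sample_id"]))["pi"]
    summary["load"] = {"pi_by_population_polymorphic_only": pi_by_pop}
    write_manifest(out, "load", [out / "polarized.vcf", out / "annotations.tsv"],
                   {}, None, cfg.seed)

    # --- rxy -----------------------------------------------------------------------
    rxy_block = cfg.block("rxy")
    managed = list(ds_pol.samples.loc[ds_pol.samples["management"] == "MANAGED", "sample_id"])
    unmanaged = list(ds_pol.samples.loc[ds_pol.samples["management"] == "UNMANAGED", "sample_id"])
    seed_rxy = stage_seed(cfg.seed, "rxy")
    rxy_out = {}
    if managed and unmanaged:
        for impact in rxy_block.get("classes", ["LOF", "MISSENSE"]):
            res = rxy(ds_pol, unmanaged, managed, impact,
                      n_boot=int(rxy_block.get("n_boot", 100)), seed=seed_rxy)
            rxy_out[impact] = dataclasses.asdict(res)
    (out / "rxy.json").write_text(json.dumps(rxy_out, indent=2) + "\n")
    summary["rxy"] = rxy_out
    write_manifest(out, "rxy", [out / "polarized.vcf"], rxy_block, seed_rxy, cfg.seed)

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float) + "\n")
    return summary


# ---------------------------------------------------------------------------
# standalone stage runners (file-path interfaces used by the CLI)
# ---------------------------------------------------------------------------

def run_filter(vcf_path, sample_table, out_vcf, filter_cfg: FilterConfig,
               annotations_path=None):
    ds = read_vcf(_require(vcf_path, "filter"), _require(sample_table, "filter"))
    if annotations_path is not None:
        ds = attach_annotations(ds, read_annotations(_require(annotations_path, "filter")))
    ds, report = apply_site_filters(ds, filter_cfg)
    write_vcf(ds, out_vcf)
    log.info("[filter] retained %d / %d sites (%s)", report.n_retained,
             report.n_input, report.removed)
    return ds, report


def run_polarize(vcf_path, sample_table, fasta_path, out_vcf, annotations_path=None):
    ds = read_vcf(_require(vcf_path, "polarize"), _require(sample_table, "polarize"))
    if annotations_path is not None:
        ds = attach_annotations(ds, read_annotations(_require(annotations_path, "polarize")))
    anc = AncestralFasta.from_fasta(_require(fasta_path, "polarize"))
    ds_pol, report = polarize(ds, anc)
    write_vcf(ds_pol, out_vcf)
    log.info("[polarize] %s", report.as_dict())
    return ds_pol, report


def run_roh(vcf_path, sample_table, out_bed, roh_cfg: ROHConfig,
            genome_length_bp: float = DEFAULT_GENOME_LENGTH_BP, froh_out=None):
    ds = read_vcf(_require(vcf_path, "roh"), _require(sample_table, "roh"))
    segments = call_roh(ds, roh_cfg)
    write_roh_bed(segments, out_bed)
    froh = compute_froh(segments, genome_length_bp, sample_ids=ds.sample_ids)
    if froh_out:
        froh.to_csv(froh_out, sep="\t", index=False)
    return segments, froh


def run_demography(segments_bed, sample_table, out_tsv,
                   genome_length_bp: float = DEFAULT_GENOME_LENGTH_BP,
                   n_boot: int = 100, seed: int = 0):
    segments = read_roh_bed(_require(segments_bed, "demography"))
    samples = read_sample_table(_require(sample_table, "demography"))
    spec = LengthClassSpec()
    class_froh, _ = froh_by_class(segments, spec, genome_length_bp,
                                  sample_ids=list(samples["sample_id"]))
    tab = ne_trajectory(class_froh, samples, spec, n_boot=n_boot, seed=seed)
    tab.to_csv(out_tsv, sep="\t", index=False)
    return tab
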