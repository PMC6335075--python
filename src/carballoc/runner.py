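"""Configuration-driven orchestration of the full pipeline.

Stages run in dependency order (simulate -> introgress -> express -> modules
-> enrich -> signature -> metabolome); every output file is recorded in a
manifest with its sha256 so seeded reruns can be compared hash-for-hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time

import numpy as np
import pandas as pd
import yaml

from . import exprkit, metkit, netkit, setkit, sigkit, simdata, varkit

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "introgress",
    "express",
    "modules",
    "enrich",
    "signature",
    "metabolome",
)


class PipelineError(RuntimeError):
    pass


@dataclasses.dataclass
class PipelineConfig:
    outdir: str = "pipeline_out"
    seed: int = 0
    stages: dict = dataclasses.field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    sim: dict = dataclasses.field(default_factory=dict)
    bin_width: int = 100_000
    min_snps: int = 5
    majority: float = 0.9
    min_depth: int = 0
    power: float = 6.0
    min_module_size: int = 30
    cut_height: float | None = None
    r_min: float = 0.7
    p_max: float = 0.05
    q_max: float = 0.2
    de_q_max: float = 0.05
    de_lfc_min: float = 1.0
    network_genotype: str = "CL"

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.stages = {s: cfg.stages.get(s, False) for s in STAGES}
        return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(manifest: dict, stage: str, key: str) -> str:
    for st in manifest["stages"].values():
        if key in st["outputs"]:
            return st["outputs"][key]["path"]
    raise PipelineError(f"stage {stage!r} needs missing input {key!r}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute enabled stages; returns (and writes) the manifest."""
    os.makedirs(config.outdir, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}

    def record(stage: str, outputs: dict[str, str], t0: float, **info) -> None:
        manifest["stages"][stage] = {
            "outputs": {
                name: {"path": path, "sha256": _sha256(path)}
                for name, path in outputs.items()
            },
            "wall_time_s": round(time.time() - t0, 3),
            **info,
        }
        logger.info("stage %s done (%d outputs)", stage, len(outputs))

    if config.stages.get("simulate"):
        t0 = time.time()
        sim_cfg = simdata.SimConfig(seed=config.seed, **config.sim)
        bundle = simdata.simulate_all(sim_cfg)
        fixdir = os.path.join(config.outdir, "fixtures")
        paths = simdata.write_fixtures(fixdir, bundle)
        record("simulate", paths, t0, n_genes=sim_cfg.n_genes)

    if config.stages.get("introgress"):
        t0 = time.time()
        conv = varkit.filter_homozygous(
            varkit.read_vcf(_require(manifest, "introgress", "vcf_CL")),
            config.min_depth,
        )
        p1 = varkit.filter_homozygous(
            varkit.read_vcf(_require(manifest, "introgress", "vcf_P1")),
            config.min_depth,
        )
        p2 = varkit.filter_homozygous(
            varkit.read_vcf(_require(manifest, "introgress", "vcf_P2")),
            config.min_depth,
        )
        genes = varkit.read_gff_genes(_require(manifest, "introgress", "gff3"))
        classified = varkit.classify_trio(conv, p1, p2)
        bins = varkit.bin_genome(
            classified, config.bin_width, config.min_snps, config.majority
        )
        segments = varkit.call_segments(bins, genes)
        outputs = {}
        p = os.path.join(config.outdir, "bins.bed")
        varkit.write_bed(p, bins, ["n_group1", "n_group2", "call"])
        outputs["bins"] = p
        p = os.path.join(config.outdir, "segments.bed")
        seg_bed = segments.copy()
        seg_bed["n_genes"] = seg_bed["genes"].map(len)
        varkit.write_bed(p, seg_bed, ["n_bins", "n_genes"])
        outputs["segments_bed"] = p
        p = os.path.join(config.outdir, "segments.json")
        with open(p, "w") as fh:
            json.dump(
                [
                    {
                        "chrom": r.chrom, "start": int(r.start),
                        "end": int(r.end), "n_bins": int(r.n_bins),
                        "genes": list(r.genes),
                    }
                    for r in segments.itertuples(index=False)
                ],
                fh,
            )
        outputs["segments"] = p
        record("introgress", outputs, t0, n_segments=len(segments))

    counts = samples = log_expr = None
    if config.stages.get("express"):
        t0 = time.time()
        counts = simdata.read_counts(_require(manifest, "express", "counts"))
        samples = simdata.read_samples(_require(manifest, "express", "samples"))
        genes = varkit.read_gff_genes(_require(manifest, "express", "gff3"))
        lengths = pd.Series(
            (genes["end"] - genes["start"]).to_numpy(), index=genes["gene_id"]
        )
        expr = exprkit.rpkm(counts, lengths)
        log_expr = exprkit.log_rpkm(expr)
        outputs = {}
        p = os.path.join(config.outdir, "log_rpkm.tsv")
        log_expr.round(4).to_csv(p, sep="\t")
        outputs["log_rpkm"] = p
        de_frames = []
        tps = sorted(samples["timepoint"].unique())
        for geno in sorted(samples["genotype"].unique()):
            for ta, tb in zip(tps, tps[1:]):
                res = exprkit.de_test(
                    counts, samples, geno, (ta, tb),
                    q_max=config.de_q_max, lfc_min=config.de_lfc_min,
                )
                res.insert(0, "genotype", geno)
                de_frames.append(res)
        de_all = pd.concat(de_frames, ignore_index=True)
        p = os.path.join(config.outdir, "de_results.tsv")
        de_all.to_csv(p, sep="\t", index=False)
        outputs["de"] = p
        record("express", outputs, t0, n_tests=len(de_all))

    if config.stages.get("modules"):
        t0 = time.time()
        if log_expr is None or samples is None:
            raise PipelineError("stage 'modules' needs outputs of 'express'")
        geno = config.network_genotype
        cols = samples.loc[samples["genotype"] == geno, "sample"]
        mods = netkit.detect_modules(
            log_expr[list(cols)],
            power=config.power,
            min_module_size=config.min_module_size,
            cut_height=config.cut_height,
            genotype=geno,
        )
        egs = netkit.module_eigengene(log_expr[list(cols)], mods.labels)
        kme = netkit.module_membership(log_expr[list(cols)], egs)
        outputs = {}
        p = os.path.join(config.outdir, "modules.tsv")
        mods.labels.rename("module").to_csv(p, sep="\t")
        outputs["modules"] = p
        p = os.path.join(config.outdir, "eigengenes.tsv")
        pd.DataFrame({e.module: e.values for e in egs}).round(6).to_csv(p, sep="\t")
        outputs["eigengenes"] = p
        p = os.path.join(config.outdir, "kme.tsv")
        kme.round(4).to_csv(p, sep="\t")
        outputs["kme"] = p
        record("modules", outputs, t0, n_modules=len(egs))

    if config.stages.get("enrich"):
        t0 = time.time()
        mod_path = _require(manifest, "enrich", "modules")
        labels = pd.read_csv(mod_path, sep="\t", index_col=0)["module"]
        sets = setkit.read_gene_sets(_require(manifest, "enrich", "gene_sets"))
        universe = set(labels.index.astype(str))
        mat = setkit.directional_matrix(
            labels, sets, universe, config.p_max, config.q_max
        )
        p = os.path.join(config.outdir, "directional_matrix.tsv")
        mat.to_csv(p, sep="\t")
        record("enrich", {"directional_matrix": p}, t0)

    if config.stages.get("signature"):
        t0 = time.time()
        if log_expr is None or samples is None:
            raise PipelineError("stage 'signature' needs outputs of 'express'")
        metab = simdata.read_metabolites(
            _require(manifest, "signature", "metabolites")
        )
        genes = varkit.read_gff_genes(_require(manifest, "signature", "gff3"))
        with open(_require(manifest, "signature", "segments")) as fh:
            segs = pd.DataFrame(json.load(fh))
        if segs.empty:
            segs = pd.DataFrame(columns=["chrom", "start", "end"])
        de_all = pd.read_csv(_require(manifest, "signature", "de"), sep="\t")
        de_cl = set(
            de_all.loc[
                (de_all["genotype"] == "CL") & (de_all["direction"] != "ns"),
                "gene",
            ]
        )
        means = exprkit.group_means(log_expr, samples)
        signal = sigkit.metabolite_means(metab, simdata.T6P_ID)
        r = sigkit.correlate_with_signal(means, signal)
        candidates = sigkit.candidate_filter(
            genes, segs, de_cl, r, r_min=config.r_min
        )
        p = os.path.join(config.outdir, "candidates.tsv")
        candidates.to_csv(p, sep="\t", index=False)
        record("signature", {"candidates": p}, t0, n_candidates=len(candidates))

    if config.stages.get("metabolome"):
        t0 = time.time()
        metab = simdata.read_metabolites(
            _require(manifest, "metabolome", "metabolites")
        )
        summary = metkit.diff_metabolite_summary(metab)
        p = os.path.join(config.outdir, "metabolite_summary.tsv")
        summary.to_csv(p, sep="\t")
        record("metabolome", {"summary": p}, t0)

    mpath = os.path.join(config.outdir, "manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
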