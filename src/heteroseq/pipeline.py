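"""End-to-end orchestration: simulate (or load) inputs, then quantify,
call differential expression, classify allele-specific expression,
test overrepresentation, and emit a reproducibility manifest.

Stages run in dependency order; every output table declares the
thresholds that produced it in a header comment, and the manifest
records row counts and SHA-256 checksums so a re-run with the same
configuration can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .allelic import ase_table, call_parental_snps, gene_allelic_counts, summarize_ase
from .enrichment import enrich
from .expression import de_table, venn_partition
from .heterosis import (
    cluster_profiles,
    dominance_table,
    heterosis_table,
    hormone_matrix,
)
from .io import (
    read_annotation,
    read_count_matrix,
    read_hormones,
    read_phenotypes,
    read_pileup,
    write_annotation,
    write_count_matrix,
    write_hormones,
    write_phenotypes,
    write_pileup,
    write_snps_vcf,
)
from .simulate import SimConfig, simulate_all
from .util import ConfigError, DataError, logger

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

_ALL_STAGES = ("simulate", "phenotype", "hormones", "quantify", "de", "ase",
               "enrich")


@dataclass
class PipelineConfig:
    """One reproducible run: seed, thresholds, stage toggles, paths.

    With ``simulate`` enabled the synthetic generators write every
    input table into ``outdir`` and later stages read them back
    through the same parsers used for external data.  Thresholds
    default to the published analysis settings: minimum SNP coverage
    8, ASE fold 5, alphas 0.05 / 0.01 / 0.001, DE fold log2 >= 1.
    """

    outdir: Path = Path("heteroseq_run")
    seed: int = 0
    stages: dict = field(
        default_factory=lambda: {s: True for s in _ALL_STAGES}
    )
    sim: SimConfig | None = None
    # input paths, used when the simulate stage is disabled
    counts_path: Path | None = None
    pileup_path: Path | None = None
    phenotypes_path: Path | None = None
    hormones_path: Path | None = None
    annotation_path: Path | None = None
    # thresholds
    alpha: float = 0.05
    de_min_log2_fold: float = 1.0
    min_coverage: int = 8
    purity: float = 0.95
    ase_fold: float = 5.0
    alpha_bias: float = 0.05
    alpha_mono: float = 0.001
    alpha_ael_rel: float = 0.01

    def __post_init__(self) -> None:
        for name in ("alpha", "de_min_log2_fold", "min_coverage", "purity",
                     "ase_fold", "alpha_bias", "alpha_mono",
                     "alpha_ael_rel"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"threshold {name} must be positive")
        if self.sim is None:
            self.sim = SimConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "sim"})
        if sim:
            cfg.sim = SimConfig(seed=cfg.seed, **sim)
        cfg.outdir = Path(cfg.outdir)
        return cfg


@dataclass
class RunManifest:
    """What a run produced: config snapshot, versions, checksums."""

    config: dict
    version: str
    started: str
    finished: str
    stages: dict

    def to_json(self) -> str:
        return json.dumps(
            _jsonable(dataclasses.asdict(self)), indent=2, default=str
        )


def _jsonable(obj):
    """Stringify non-string mapping keys so the manifest serialises."""
    if isinstance(obj, dict):
        return {
            (k if isinstance(k, str) else repr(k)): _jsonable(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _record(stage_rec: dict, path: Path, rows: int | None = None) -> None:
    stage_rec[path.name] = {"rows": rows, "sha256": _sha256(path)}


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every enabled stage in dependency order.

    Returns the manifest (also written to ``outdir/manifest.json``).
    A stage whose upstream inputs are missing aborts with the stage
    name in the error.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    stages: dict[str, dict] = {}
    thr = (
        f"alpha={config.alpha} de_min_log2_fold={config.de_min_log2_fold} "
        f"min_coverage={config.min_coverage} purity={config.purity} "
        f"ase_fold={config.ase_fold} alpha_bias={config.alpha_bias} "
        f"alpha_mono={config.alpha_mono} alpha_ael_rel={config.alpha_ael_rel}"
    )

    paths = {
        "counts": config.counts_path,
        "pileup": config.pileup_path,
        "phenotypes": config.phenotypes_path,
        "hormones": config.hormones_path,
        "annotation": config.annotation_path,
    }
    truth = None
    if config.stages.get("simulate", False):
        sim = simulate_all(config.sim)
        rec: dict = {}
        paths = {
            "counts": out / "counts.tsv",
            "pileup": out / "pileup.tsv",
            "phenotypes": out / "phenotypes.csv",
            "hormones": out / "hormones.csv",
            "annotation": out / "annotation.tsv",
        }
        write_count_matrix(sim.counts, paths["counts"])
        write_pileup(sim.pileup, paths["pileup"])
        write_phenotypes(sim.phenotypes, paths["phenotypes"])
        write_hormones(sim.hormones, paths["hormones"])
        write_annotation(sim.annotation, paths["annotation"])
        sim.truth.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
        sim.term_truth.to_csv(out / "truth_terms.tsv", sep="\t", index=False)
        truth = sim.truth
        for p in list(paths.values()) + [out / "truth_genes.tsv",
                                         out / "truth_terms.tsv"]:
            _record(rec, p)
        stages["simulate"] = rec
    else:
        stages["simulate"] = {"skipped": True}

    def need(key: str, stage: str) -> Path:
        p = paths.get(key)
        if p is None or not Path(p).exists():
            raise DataError(
                f"stage {stage!r}: missing upstream input {key!r}"
            )
        return Path(p)

    if config.stages.get("phenotype", False):
        rec = {}
        pheno = read_phenotypes(need("phenotypes", "phenotype"))
        het = heterosis_table(pheno, alpha=config.alpha)
        path = out / "heterosis.tsv"
        with open(path, "w") as fh:
            fh.write(f"# thresholds: {thr}\n")
            het.to_csv(fh, sep="\t", index=False)
        _record(rec, path, len(het))
        stages["phenotype"] = rec
    else:
        stages["phenotype"] = {"skipped": True}

    if config.stages.get("hormones", False):
        rec = {}
        horm = read_hormones(need("hormones", "hormones"))
        dom = dominance_table(horm, alpha=config.alpha)
        path = out / "hormone_dominance.tsv"
        with open(path, "w") as fh:
            fh.write(f"# thresholds: {thr}\n")
            dom.to_csv(fh, sep="\t", index=False)
        _record(rec, path, len(dom))
        mat = hormone_matrix(horm)
        if len(mat) >= 2:
            dend, display = cluster_profiles(mat)
            (out / "hormone_dendrogram.nwk").write_text(dend.to_newick() + "\n")
            display.to_csv(out / "hormone_display_matrix.tsv", sep="\t")
            _record(rec, out / "hormone_dendrogram.nwk")
            _record(rec, out / "hormone_display_matrix.tsv", len(display))
        stages["hormones"] = rec
    else:
        stages["hormones"] = {"skipped": True}

    cm = None
    if config.stages.get("quantify", False) or config.stages.get("de", False):
        cm = read_count_matrix(need("counts", "quantify"))
        if {"P1", "P2"} <= set(cm.samples):
            cm = cm.with_merged(["P1", "P2"], "MPV")

    if config.stages.get("quantify", False):
        rec = {}
        fpkm_path = out / "fpkm.tsv"
        with open(fpkm_path, "w") as fh:
            fh.write(f"# thresholds: {thr}\n")
            cm.fpkm_frame().to_csv(fh, sep="\t")
        _record(rec, fpkm_path, len(cm.gene_ids))
        stages["quantify"] = rec
    else:
        stages["quantify"] = {"skipped": True}

    de_results: dict[str, pd.DataFrame] = {}
    if config.stages.get("de", False):
        rec = {}
        comparisons = [
            ("P1", "P2"), ("F1", "P1"), ("F1", "P2"), ("F1", "MPV"),
        ]
        for a, b in comparisons:
            if a not in cm.samples or b not in cm.samples:
                continue
            tab = de_table(
                cm, a, b,
                min_log2_fold=config.de_min_log2_fold,
                alpha=config.alpha,
            )
            de_results[f"{a}_vs_{b}"] = tab
            path = out / f"de_{a}_vs_{b}.tsv"
            with open(path, "w") as fh:
                fh.write(f"# thresholds: {thr}\n")
                tab.to_csv(fh, sep="\t", index=False)
            _record(rec, path, len(tab))
        if len(de_results) >= 2:
            sets = {
                name: set(tab.loc[tab["de_flag"], "gene_id"])
                for name, tab in de_results.items()
            }
            venn = venn_partition(sets)
            venn_path = out / "venn.json"
            venn_path.write_text(
                json.dumps(
                    {
                        "intersections": venn.intersections,
                        "exclusive": venn.exclusive,
                    },
                    indent=2,
                )
            )
            _record(rec, venn_path)
        stages["de"] = rec
    else:
        stages["de"] = {"skipped": True}

    if config.stages.get("ase", False):
        rec = {}
        pileups = read_pileup(need("pileup", "ase"))
        for s in ("P1", "P2", "F1"):
            if s not in pileups:
                raise DataError(f"stage 'ase': pileup lacks sample {s!r}")
        snps = call_parental_snps(
            pileups["P1"], pileups["P2"],
            min_coverage=config.min_coverage, purity=config.purity,
        )
        write_snps_vcf(snps, out / "parental_snps.vcf")
        _record(rec, out / "parental_snps.vcf", len(snps))
        snp_tsv = out / "parental_snps.tsv"
        with open(snp_tsv, "w") as fh:
            fh.write(f"# thresholds: {thr}\n")
            snps.to_csv(fh, sep="\t", index=False)
        _record(rec, snp_tsv, len(snps))
        allelic = gene_allelic_counts(pileups["F1"], snps)
        ase = ase_table(
            allelic, snps,
            fold=config.ase_fold, alpha_bias=config.alpha_bias,
            alpha_mono=config.alpha_mono,
            alpha_ael_rel=config.alpha_ael_rel,
        )
        ase_path = out / "ase.tsv"
        with open(ase_path, "w") as fh:
            fh.write(f"# thresholds: {thr}\n")
            ase.to_csv(fh, sep="\t", index=False)
        _record(rec, ase_path, len(ase))
        summary = summarize_ase(ase)
        sum_path = out / "ase_summary.json"
        sum_path.write_text(json.dumps(summary, indent=2, default=float))
        _record(rec, sum_path)
        stages["ase"] = rec
    else:
        stages["ase"] = {"skipped": True}

    if config.stages.get("enrich", False):
        rec = {}
        if not de_results:
            raise DataError("stage 'enrich': needs DE results upstream")
        annotation = read_annotation(need("annotation", "enrich"))
        for name, tab in de_results.items():
            universe = set(tab["gene_id"])  # expressed genes
            gene_list = set(tab.loc[tab["de_flag"], "gene_id"])
            if not gene_list:
                continue
            res = enrich(gene_list, annotation, universe)
            path = out / f"enrichment_{name}.tsv"
            with open(path, "w") as fh:
                fh.write(f"# thresholds: {thr}\n")
                res.to_csv(fh, sep="\t", index=False)
            _record(rec, path, len(res))
        stages["enrich"] = rec
    else:
        stages["enrich"] = {"skipped": True}

    cfg_dict = dataclasses.asdict(config)
    cfg_dict["sim"] = dataclasses.asdict(config.sim)
    manifest = RunManifest(
        config=cfg_dict,
        version=__version__,
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
        stages=stages,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    logger.info("pipeline finished; manifest at %s", out / "manifest.json")
    return manifest
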