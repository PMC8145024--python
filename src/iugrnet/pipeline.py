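"""Configuration-driven end-to-end orchestration of the analysis stages.

Stage order: phenotyping -> preprocessing -> differential expression ->
target hybridization -> integration/network -> enrichment -> (optional)
qPCR concordance.  Every numeric threshold quoted by the protocol lives in
:class:`PipelineConfig`, which is loadable from a YAML file; a manifest
JSON records the config hash, seed, package version and per-stage row
counts, and reruns with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import io as pio
from .diffexpr import run_de
from .enrichment import read_gmt, run_ora, write_gmt
from .hybridization import load_energy_model, predict_targets
from .integration import (
    build_pairs,
    classify_novel,
    collapse_probes_to_genes,
    correlate,
    count_targets_per_mirna,
    export_network,
)
from .phenotype import (
    IUGR,
    classify_iugr,
    select_discordant_pairs,
    summarize_groups,
)
from .preprocessing import (
    filter_by_presence,
    filter_mirna_by_length,
    validate_annotation,
)
from .qpcr import concordance, relative_expression

log = logging.getLogger("iugrnet")

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "run_demo"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """All inputs, outputs and thresholds of one pipeline run."""

    seed: int = 0
    outdir: str = "iugrnet_run"
    # input paths
    phenotype_tsv: str = ""
    mirna_values_tsv: str = ""
    mirna_mask_tsv: str = ""
    mrna_values_tsv: str = ""
    mrna_mask_tsv: str = ""
    annotation_tsv: str = ""
    regions_fasta: str = ""
    mirna_fasta: str = ""
    gene_sets_gmt: str = ""
    known_iugr_txt: str = ""
    known_muscle_txt: str = ""
    ct_tsv: str = ""  # optional
    assay_map_tsv: str = ""  # optional
    energy_model_yaml: str = ""  # empty -> packaged table
    # thresholds (protocol defaults)
    sd_multiplier: float = 2.0
    n_per_group: int = 12
    presence_min_fraction: float = 0.80
    mirna_max_len: int = 30
    mirna_alpha: float = 0.05
    mrna_fdr: float = 0.05
    fragment_len: int = 2000
    overlap: int = 50
    mfe_threshold: float = -25.0
    r_threshold: float = -0.3
    ora_fdr: float = 0.05
    helix: tuple = (2, 7)

    def validate(self) -> "PipelineConfig":
        if not (0 <= self.presence_min_fraction <= 1):
            raise ValueError("presence_min_fraction must be in [0, 1]")
        if self.overlap >= self.fragment_len or self.overlap < 0:
            raise ValueError("need fragment_len > overlap >= 0")
        for name in ("mirna_alpha", "mrna_fdr", "ora_fdr"):
            if not (0 < getattr(self, name) < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.mfe_threshold >= 0:
            raise ValueError("mfe_threshold must be negative (kcal/mol)")
        if not (-1 <= self.r_threshold <= 0):
            raise ValueError("r_threshold must be in [-1, 0]")
        required = [
            "phenotype_tsv",
            "mirna_values_tsv",
            "mirna_mask_tsv",
            "mrna_values_tsv",
            "mrna_mask_tsv",
            "annotation_tsv",
            "regions_fasta",
            "mirna_fasta",
            "gene_sets_gmt",
            "known_iugr_txt",
            "known_muscle_txt",
        ]
        for name in required:
            path = getattr(self, name)
            if not path or not Path(path).exists():
                raise ValueError(f"input {name} missing or not found: {path!r}")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        if isinstance(cfg.helix, list):
            cfg.helix = tuple(cfg.helix)
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["helix"] = list(self.helix)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def content_hash(self) -> str:
        data = asdict(self)
        data["helix"] = list(self.helix)
        data.pop("outdir")  # where results land is not analytic content
        return hashlib.sha256(
            json.dumps(data, sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        wrapped.__name__ = fn.__name__
        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest dict (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    def emit(df: pd.DataFrame, name: str):
        pio.write_table(df, outdir / name)
        counts[name] = len(df)

    # --- phenotyping -----------------------------------------------------
    @_stage("phenotyping")
    def phenotyping():
        fetuses = pio.read_phenotypes(config.phenotype_tsv)
        labeled = classify_iugr(fetuses, sd_multiplier=config.sd_multiplier)
        cohort, pairs = select_discordant_pairs(labeled, n_per_group=config.n_per_group)
        summary, welch_p = summarize_groups(cohort)
        log.info(
            "phenotyping: %d fetuses -> %d discordant pairs (Welch p=%.3g)",
            len(fetuses), len(pairs), welch_p,
        )
        pio.write_phenotypes(cohort, outdir / "selected_cohort.tsv")
        counts["selected_cohort.tsv"] = len(cohort)
        emit(summary, "group_summary.tsv")
        return cohort

    cohort = phenotyping()
    sample_ids = [f.fetus_id for f in cohort]
    pheno = pd.DataFrame(
        {
            "fetus_id": sample_ids,
            "dam": [f.dam for f in cohort],
            "sex": [f.sex for f in cohort],
            "group": [f.group for f in cohort],
        }
    )

    # --- preprocessing ---------------------------------------------------
    @_stage("preprocessing")
    def preprocessing():
        annotation = validate_annotation(pd.read_csv(config.annotation_tsv, sep="\t", keep_default_na=False))
        out = {}
        for track, vals, mask in (
            ("miRNA", config.mirna_values_tsv, config.mirna_mask_tsv),
            ("mRNA", config.mrna_values_tsv, config.mrna_mask_tsv),
        ):
            em = pio.read_expression(vals, mask)
            missing = [s for s in sample_ids if s not in set(em.sample_ids)]
            if missing:
                raise ValueError(f"{track} matrix lacks cohort samples: {missing}")
            em = type(em)(em.values[sample_ids], em.present[sample_ids])
            before = em.shape[0]
            em, presence_report = filter_by_presence(em, config.presence_min_fraction)
            if track == "miRNA":
                em, length_report = filter_mirna_by_length(
                    em, annotation, config.mirna_max_len
                )
                emit(length_report, "filter_mirna_length_report.tsv")
            emit(presence_report, f"filter_presence_{track}.tsv")
            log.info("preprocessing %s: %d -> %d probes", track, before, em.shape[0])
            out[track] = em
        return out["miRNA"], out["mRNA"], annotation

    mirna_em, mrna_em, annotation = preprocessing()

    # --- differential expression ----------------------------------------
    @_stage("diffexpr")
    def diffexpr():
        de_mir = run_de(mirna_em, pheno, "miRNA", alpha=config.mirna_alpha)
        de_mrna = run_de(mrna_em, pheno, "mRNA", alpha=config.mrna_fdr)
        emit(de_mir, "de_mirna.tsv")
        emit(de_mrna, "de_mrna.tsv")
        log.info(
            "diffexpr: %d/%d significant miRNA probes, %d/%d significant mRNA probes",
            int(de_mir["significant"].sum()), len(de_mir),
            int(de_mrna["significant"].sum()), len(de_mrna),
        )
        return de_mir, de_mrna

    de_mir, de_mrna = diffexpr()

    # --- target hybridization -------------------------------------------
    @_stage("hybridization")
    def hybridization():
        model = load_energy_model(config.energy_model_yaml or None)
        mirna_seqs = pio.read_mirna_fasta(config.mirna_fasta)
        regions = pio.read_region_fasta(config.regions_fasta)
        genes = collapse_probes_to_genes(de_mrna, annotation)
        sig_genes = genes.loc[genes["significant"]]
        sig_mir = de_mir.loc[de_mir["significant"]]
        mirnas = [
            (r.probe_id, mirna_seqs[r.probe_id], r.direction)
            for r in sig_mir.itertuples(index=False)
        ]
        gene_dirs = dict(zip(sig_genes["gene_id"], sig_genes["direction"]))
        hits = predict_targets(
            mirnas,
            regions,
            gene_dirs,
            model,
            mfe_threshold=config.mfe_threshold,
            fragment_len=config.fragment_len,
            overlap=config.overlap,
            helix=config.helix,
        )
        pio.write_hits(hits, outdir / "hits.tsv")
        counts["hits.tsv"] = len(hits)
        log.info("hybridization: %d hits below %.1f kcal/mol", len(hits), config.mfe_threshold)
        return hits, genes

    hits, gene_de = hybridization()

    # --- integration -----------------------------------------------------
    @_stage("integration")
    def integration():
        sig_mir = de_mir.loc[de_mir["significant"]]
        sig_genes = gene_de.loc[gene_de["significant"]]
        corr = correlate(
            mirna_em.values.loc[sig_mir["probe_id"]],
            mrna_em.values.loc[sig_genes["probe_id"]],
        )
        pairs = build_pairs(de_mir, sig_genes, hits, corr, r_threshold=config.r_threshold)
        emit(pairs, "pairs.tsv")
        emit(count_targets_per_mirna(pairs), "targets_per_mirna.tsv")
        up_mirnas = sig_mir.loc[sig_mir["direction"] == "up", "probe_id"]
        novel = classify_novel(
            up_mirnas,
            pio.read_id_list(config.known_iugr_txt),
            pio.read_id_list(config.known_muscle_txt),
        )
        emit(novel, "novel_mirna_classification.tsv")
        export_network(pairs, outdir)
        counts["network_edges.tsv"] = len(pairs)
        log.info("integration: %d pairs pass all three gates", len(pairs))
        return pairs

    pairs = integration()

    # --- enrichment ------------------------------------------------------
    @_stage("enrichment")
    def enrichment():
        gene_sets = read_gmt(config.gene_sets_gmt)
        universe = sorted(
            set(
                annotation.loc[
                    annotation["probe_id"].isin(mrna_em.probe_ids), "gene_symbol"
                ]
            )
            - {""}
        )
        for gdir, fname in (("down", "ora_down_targets.tsv"), ("up", "ora_up_targets.tsv")):
            genes = sorted(set(pairs.loc[pairs["gene_direction"] == gdir, "gene_id"]))
            table = run_ora(genes, gene_sets, universe, fdr_threshold=config.ora_fdr)
            emit(table, fname)
            log.info(
                "enrichment (%s-regulated targets, n=%d): %d significant sets",
                gdir, len(genes), int(table["significant"].sum()),
            )

    enrichment()

    # --- qPCR (optional) -------------------------------------------------
    if config.ct_tsv:
        @_stage("qpcr")
        def qpcr():
            ct = pd.read_csv(config.ct_tsv, sep="\t")
            assay_map = pd.read_csv(config.assay_map_tsv, sep="\t")
            rel = relative_expression(ct)
            report = concordance(
                rel, pheno, assay_map, {"miRNA": de_mir, "mRNA": de_mrna}
            )
            emit(rel, "qpcr_relative_expression.tsv")
            emit(report, "qpcr_concordance.tsv")
            log.info(
                "qpcr: fraction concordant = %.2f",
                report.attrs["fraction_concordant"],
            )

        qpcr()

    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "iugrnet_version": __version__,
        "row_counts": counts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def write_synthetic_inputs(bundle, indir) -> PipelineConfig:
    """Write a SimBundle as pipeline input files; returns a ready config."""
    from .synthetic import annotation_from_truth  # noqa: F401  (bundle carries it)

    indir = Path(indir)
    indir.mkdir(parents=True, exist_ok=True)
    pio.write_phenotypes(bundle.fetuses, indir / "phenotypes.tsv")
    pio.write_expression(bundle.mirna, indir / "mirna_values.tsv", indir / "mirna_mask.tsv")
    pio.write_expression(bundle.mrna, indir / "mrna_values.tsv", indir / "mrna_mask.tsv")
    pio.write_table(bundle.annotation, indir / "annotation.tsv")
    pio.write_region_fasta(bundle.gene_regions, indir / "regions.fasta")
    pio.write_mirna_fasta(
        {m: s for m, s in bundle.truth.mirna_sequences.items()}, indir / "mirna.fasta"
    )
    write_gmt(bundle.gene_sets, indir / "gene_sets.gmt")
    pio.write_id_list(bundle.known_iugr, indir / "known_iugr.txt")
    pio.write_id_list(bundle.known_muscle, indir / "known_muscle.txt")
    pio.write_table(bundle.ct_table, indir / "qpcr_ct.tsv")
    pio.write_table(bundle.assay_map, indir / "qpcr_assays.tsv")
    (indir / "truth.json").write_text(bundle.truth.to_json())
    return PipelineConfig(
        seed=bundle.config.seed,
        phenotype_tsv=str(indir / "phenotypes.tsv"),
        mirna_values_tsv=str(indir / "mirna_values.tsv"),
        mirna_mask_tsv=str(indir / "mirna_mask.tsv"),
        mrna_values_tsv=str(indir / "mrna_values.tsv"),
        mrna_mask_tsv=str(indir / "mrna_mask.tsv"),
        annotation_tsv=str(indir / "annotation.tsv"),
        regions_fasta=str(indir / "regions.fasta"),
        mirna_fasta=str(indir / "mirna.fasta"),
        gene_sets_gmt=str(indir / "gene_sets.gmt"),
        known_iugr_txt=str(indir / "known_iugr.txt"),
        known_muscle_txt=str(indir / "known_muscle.txt"),
        ct_tsv=str(indir / "qpcr_ct.tsv"),
        assay_map_tsv=str(indir / "qpcr_assays.tsv"),
        n_per_group=bundle.config.n_per_group,
    )


def run_demo(seed: int = 0, outdir: str = "iugrnet_demo", sim_config=None) -> dict:
    """One-command synthetic demonstration: simulate, write inputs, run."""
    from .synthetic import SimConfig, simulate_all

    cfg = sim_config if sim_config is not None else SimConfig(seed=seed)
    bundle = simulate_all(cfg)
    outdir = Path(outdir)
    pipe_cfg = write_synthetic_inputs(bundle, outdir / "inputs")
    pipe_cfg.outdir = str(outdir / "results")
    pipe_cfg.to_yaml(outdir / "pipeline_config.yaml")
    return run_pipeline(pipe_cfg)
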