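"""End-to-end orchestration: simulate -> process -> normalise -> global
methylation -> three planned DMR contrasts -> regulatory integration ->
stabilisation, with a seeded, checksummed manifest.

The third contrast (n-3-SAL vs n-6-SAL) is a negative control; its
significant-site count is reported prominently in the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import core, dmr, io, processing, regulatory, simulate, stabilise

logger = logging.getLogger(__name__)

_SECTION_KEYS = {
    "processing": {"adapter", "quality_cutoff", "max_mismatches", "min_overlap",
                   "trim_max_mismatches", "min_keep", "index_k"},
    "dmr": {"min_depth", "q_cut", "region_gap", "promoter_window", "shore_width",
            "delta_cut_pathway"},
    "regulatory": {"window", "dhs_cutoff", "mecp2_cutoff"},
    "stabilisation": {"p_threshold", "magnitude_ratio", "p_column"},
}
_SIM_KEYS = {f.name for f in dataclasses.fields(simulate.SimulationConfig)} - {"seed"}


@dataclass
class PipelineConfig:
    seed: int
    simulation: dict = field(default_factory=dict)
    processing: dict = field(default_factory=dict)
    dmr: dict = field(default_factory=dict)
    regulatory: dict = field(default_factory=dict)
    stabilisation: dict = field(default_factory=dict)
    contrasts: list | None = None  # None = the three planned comparisons
    log_level: str = "INFO"

    def __post_init__(self):
        unknown = set(self.simulation) - _SIM_KEYS
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
        for section, allowed in _SECTION_KEYS.items():
            unknown = set(getattr(self, section)) - allowed
            if unknown:
                raise ValueError(f"unknown {section} keys: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValueError("config must set a seed")
        return cls(**raw)

    def echo(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage on a fresh synthetic study; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": _pkg_version("methylrescue"),
        "seed": config.seed,
        "parameters": config.echo(),
        "stages": {},
    }

    # --- simulate ------------------------------------------------------
    sim_cfg = simulate.SimulationConfig(seed=config.seed, **config.simulation)
    reference = simulate.generate_reference(sim_cfg)
    units = simulate.make_design(np.random.default_rng(
        np.random.SeedSequence([config.seed, 10])))
    truth = simulate.assign_methylation(reference, units, sim_cfg)
    fragments = simulate.size_select(
        simulate.digest_mspi(reference.contigs), sim_cfg.size_range
    )
    io.write_fasta(reference.contigs, outdir / "reference.fa")
    io.write_genes_bed12(reference.genes, outdir / "genes.bed")
    io.write_islands_bed(reference.islands, outdir / "islands.bed")
    io.write_design(units, outdir / "design.tsv")
    truth.probs.to_csv(outdir / "truth_probs.tsv", sep="\t")
    pd.DataFrame(
        sorted(truth.dmr_site_ids), columns=["contig", "pos"]
    ).assign(rescued=lambda d: [
        (c, p) in truth.rescued_site_ids for c, p in zip(d.contig, d.pos)
    ]).to_csv(outdir / "truth_dmr_sites.tsv", sep="\t", index=False)

    contig_lengths = {c: len(s) for c, s in reference.contigs.items()}
    rng_tags = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    dmr_list = sorted(truth.dmr_site_ids)
    n_dhs = int(round(sim_cfg.dhs_dmr_fraction * len(dmr_list)))
    n_mecp2 = int(round(sim_cfg.mecp2_dmr_fraction * len(dmr_list)))
    perm = rng_tags.permutation(len(dmr_list))
    dhs_enriched = [dmr_list[i] for i in perm[:n_dhs]]
    mecp2_enriched = [dmr_list[i] for i in perm[::-1][:n_mecp2]]
    for name, enriched in (("dhs", dhs_enriched), ("mecp2", mecp2_enriched)):
        tags = simulate.simulate_tag_track(
            contig_lengths, enriched, sim_cfg.tag_background_rate,
            sim_cfg.tag_enrichment_fold, rng_tags, sim_cfg.tag_window,
        )
        io.write_tags_bed(tags, outdir / f"{name}_tags.bed")
    manifest["stages"]["simulate"] = {
        "n_units": len(units),
        "n_fragments_kept": len(fragments),
        "n_cpg_sites": int(len(truth.probs)),
        "n_dmr_sites": len(truth.dmr_site_ids),
        "n_rescued_sites": len(truth.rescued_site_ids),
    }

    # --- process + global estimator -----------------------------------
    index = processing.build_index(reference, k=config.processing.get("index_k", 12))
    proc_kw = {k: v for k, v in config.processing.items() if k != "index_k"}
    unit_counts: dict[str, pd.DataFrame] = {}
    summaries = []
    estimates = []
    for i, unit in enumerate(units):
        rng_u = np.random.default_rng(np.random.SeedSequence([config.seed, 12, i]))
        reads = simulate.simulate_reads(fragments, truth, unit, sim_cfg, reference, rng_u)
        fq = outdir / f"reads_{unit.unit_id}.fastq"
        io.write_fastq(reads, fq)
        estimates.append(core.global_ccgg_methylation(reads, unit.unit_id))
        counts, summary = processing.process_unit(reads, index, unit.unit_id, **proc_kw)
        unit_counts[unit.unit_id] = counts
        summaries.append(summary)
        io.write_coverage(counts, outdir / f"coverage_{unit.unit_id}.tsv")
    summaries = pd.DataFrame(summaries).set_index("unit_id")
    summaries.to_csv(outdir / "alignment_summary.tsv", sep="\t")
    manifest["stages"]["process"] = {
        "reads_in": int(summaries["reads_in"].sum()),
        "kept_aligned": int(summaries["kept_aligned"].sum()),
        "unmapped": int(summaries["unmapped"].sum()),
        "ambiguous": int(summaries["ambiguous"].sum()),
        "trim_discarded": int(summaries["trim_discarded"].sum()),
        "quality_dropped": int(summaries["quality_dropped"].sum()),
    }

    # --- global methylation GLM ----------------------------------------
    design = simulate.design_frame(units)
    global_df = pd.DataFrame(
        [
            {"unit_id": e.unit_id, "n_cgg": e.n_cgg, "n_tgg": e.n_tgg,
             "n_other": e.n_other, "percent": e.percent}
            for e in estimates
        ]
    ).set_index("unit_id").join(design)
    global_df.to_csv(outdir / "global_methylation.tsv", sep="\t")
    glm = core.glm_global_methylation(global_df.reset_index())
    glm.anova.to_csv(outdir / "global_glm_anova.tsv", sep="\t")
    glm.t_tests.to_csv(outdir / "global_t_tests.tsv", sep="\t", index=False)
    mia_row = glm.t_tests.query("name == 'n-6-SAL vs n-6-POL' and stratum == 'all'").iloc[0]
    manifest["stages"]["global"] = {
        "r_squared": glm.r_squared,
        "group_delta_pct": float(mia_row["delta"]),
        "group_t_p": float(mia_row["p"]),
    }

    # --- normalise + contrasts -----------------------------------------
    matrix = core.MethylationMatrix.from_unit_counts(unit_counts)
    matrix = core.quantile_normalize_depth(matrix)
    contrasts = (
        dmr.planned_contrasts(units)
        if config.contrasts is None
        else [
            dmr.contrast_from_cells(c["name"], units, c["a"], c["b"])
            for c in config.contrasts
        ]
    )
    dmr_kw = dict(config.dmr)
    delta_cut = dmr_kw.pop("delta_cut_pathway", 3.0)
    if "promoter_window" in dmr_kw:
        dmr_kw["promoter_window"] = tuple(dmr_kw["promoter_window"])
    results: dict[str, dmr.ContrastResult] = {}
    for contrast in contrasts:
        res = dmr.run_contrast(
            matrix, contrast, reference.genes, reference.islands, **dmr_kw
        )
        results[contrast.name] = res
        tag = contrast.name.replace(" ", "_")
        res.table.to_csv(outdir / f"dmr_{tag}.tsv", sep="\t")
        ranked, pathway_genes = dmr.rank_and_filter(res.table, res.q_cut, delta_cut)
        ranked.to_csv(outdir / f"dmr_ranked_{tag}.tsv", sep="\t")
        classes, class_counts = dmr.classify_gene_direction(res.significant)
        classes.rename("direction_class").to_csv(outdir / f"gene_classes_{tag}.tsv", sep="\t")
        circular = res.significant.reset_index()[["contig", "pos", "q_value", "delta_pct", "direction"]]
        circular["neg_log10_q"] = -np.log10(np.clip(circular.pop("q_value"), 1e-300, None))
        circular.to_csv(outdir / f"circular_{tag}.tsv", sep="\t", index=False)
        manifest["stages"][f"contrast:{contrast.name}"] = {
            "eligible_sites": int(len(res.table)),
            "significant_sites": int(len(res.significant)),
            "genes": class_counts,
            "pathway_genes": len(pathway_genes),
        }
    neg = results.get("n-3-SAL vs n-6-SAL")
    if neg is not None:
        manifest["negative_control_significant_sites"] = int(len(neg.significant))

    # --- regulatory integration ---------------------------------------
    mia_res = results.get("n-6-SAL vs n-6-POL")
    if mia_res is not None:
        dhs_track = regulatory.TagTrack(io.read_tags_bed(outdir / "dhs_tags.bed"), "DHS")
        mecp2_track = regulatory.TagTrack(io.read_tags_bed(outdir / "mecp2_tags.bed"), "MECP2")
        reg_kw = dict(config.regulatory)
        # scenario defaults: narrow windows and background-anchored cutoffs,
        # so planted peaks stay sparse on the miniature genome
        reg_kw.setdefault("window", 100)
        reg_kw.setdefault("dhs_cutoff", "auto")
        reg_kw.setdefault("mecp2_cutoff", "auto")
        reg = regulatory.integrate(
            mia_res.table.index, mia_res.significant.index,
            dhs_track, mecp2_track, **reg_kw,
        )
        reg["dhs_density"].to_csv(outdir / "dhs_density.tsv", sep="\t")
        reg["mecp2_density"].to_csv(outdir / "mecp2_density.tsv", sep="\t")
        pd.Series(reg["venn"]).to_csv(outdir / "venn_counts.tsv", sep="\t", header=False)
        manifest["stages"]["regulatory"] = {
            "venn": reg["venn"],
            "dhs_p": reg["tests"]["DHS"]["p_value"],
            "mecp2_p": reg["tests"]["MECP2"]["p_value"],
        }

    # --- stabilisation --------------------------------------------------
    diet_res = results.get("n-3-POL vs n-6-POL")
    if mia_res is not None and diet_res is not None:
        pairs = stabilise.pair_contrasts(mia_res.significant, diet_res.table)
        diet_only = set(diet_res.significant["nearest_gene"].dropna()) - set(
            mia_res.significant["nearest_gene"].dropna()
        )
        report = stabilise.classify_stabilisation(
            pairs, diet_only_genes=diet_only, **config.stabilisation
        )
        report.site_table.to_csv(outdir / "stabilisation_sites.tsv", sep="\t")
        report.gene_table.to_csv(outdir / "stabilisation_genes.tsv", sep="\t")
        manifest["stages"]["stabilisation"] = {
            "n_mia_genes": report.n_mia_genes,
            "n_stabilised": report.n_stabilised,
            "n_diet_only": report.n_diet_only,
            "rescue_fraction_pct": report.rescue_fraction,
            "ks_D": report.ks_D, "ks_p": report.ks_p,
            "wilcoxon_V": report.wilcoxon_V, "wilcoxon_p": report.wilcoxon_p,
        }
    else:
        logger.info("stabilisation skipped: MIA or diet contrast not configured")
        manifest["stages"]["stabilisation"] = {"skipped": "contrast missing"}

    # --- manifest -------------------------------------------------------
    checksums = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.is_file() and p.name not in ("manifest.json", "report.txt")
    }
    manifest["checksums"] = checksums
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    _write_text_report(manifest, outdir / "report.txt")
    return manifest


def _write_text_report(manifest: dict, path: Path) -> None:
    lines = [f"methylrescue pipeline report (seed {manifest['seed']})", ""]
    for stage, info in manifest["stages"].items():
        lines.append(f"[{stage}]")
        for k, v in info.items():
            lines.append(f"  {k}: {v}")
        lines.append("")
    if "negative_control_significant_sites" in manifest:
        lines.append(
            "negative control (n-3-SAL vs n-6-SAL) significant sites: "
            f"{manifest['negative_control_significant_sites']}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
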