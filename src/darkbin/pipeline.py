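"""End-to-end orchestration from a single JSON configuration.

The pipeline chains the analysis stages in their natural order —
simulate (or load) inputs, align contigs to references, assign taxonomy
with the 90/90 rule, bin the residual dark matter on GC/coverage, call
novelty by ANI, place bins on a core-genome tree, type strains by MLST,
and run the diversity/paired-site protocol — writing per-stage outputs
plus one machine-readable report.  The report is a deterministic
function of (config, seed): keys are sorted and no timestamps or host
details enter it, so identical runs are byte-identical.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import ani as ani_mod
from . import binning, coregenome, diversity, mlst, simulate, taxonomy
from .align import SubjectIndex, align_to_index
from .seqio import read_contigs, read_fasta, write_contigs, write_fasta, write_hit_table

__all__ = ["ConfigError", "PipelineConfig", "validate_config", "run_pipeline", "DEFAULT_THRESHOLDS"]

DEFAULT_THRESHOLDS: dict[str, float] = {
    "breadth": taxonomy.BREADTH_THRESHOLD,
    "identity": taxonomy.IDENTITY_THRESHOLD,
    "min_contig_len": taxonomy.MIN_BINNED_CONTIG_LEN,
    "gc_tol": binning.GC_TOL,
    "cov_tol": binning.COV_TOL,
    "sep_threshold": binning.SEP_THRESHOLD,
    "silhouette_floor": binning.SILHOUETTE_FLOOR,
    "k_max": 8,
    "ani_threshold": ani_mod.ANI_SPECIES_THRESHOLD,
    "frag_len": ani_mod.FRAG_LEN,
    "min_frag_identity": ani_mod.MIN_FRAG_IDENTITY,
    "min_frag_cov": ani_mod.MIN_FRAG_COV,
    "min_ortholog_len": coregenome.MIN_ORTHOLOG_LEN,
    "min_ortholog_identity": coregenome.MIN_ORTHOLOG_IDENTITY,
    "min_core_prevalence": coregenome.MIN_CORE_PREVALENCE,
    "max_gap_fraction": coregenome.MAX_GAP_FRACTION,
    "rarefaction_depth": diversity.RAREFACTION_DEPTH,
}

# (lower, upper, lower_open, upper_open) domains for validation
_THRESHOLD_DOMAINS: dict[str, tuple[float, float, bool, bool]] = {
    "breadth": (0.0, 1.0, False, False),
    "identity": (0.0, 1.0, False, False),
    "min_contig_len": (0, 1e9, False, False),
    "gc_tol": (0.0, 1.0, True, True),
    "cov_tol": (0.0, 10.0, True, False),
    "sep_threshold": (0.0, 1e6, False, False),
    "silhouette_floor": (-1.0, 1.0, False, False),
    "k_max": (2, 64, False, False),
    "ani_threshold": (0.0, 100.0, False, False),
    "frag_len": (100, 1e7, False, False),
    "min_frag_identity": (0.0, 1.0, False, False),
    "min_frag_cov": (0.0, 1.0, False, False),
    "min_ortholog_len": (0, 1e9, False, False),
    "min_ortholog_identity": (0.0, 1.0, False, False),
    "min_core_prevalence": (0.0, 1.0, False, True),
    "max_gap_fraction": (0.0, 1.0, False, False),
    "rarefaction_depth": (1, 1e12, False, False),
}

_KNOWN_KEYS = {"seed", "outdir", "thresholds", "simulation", "paths"}


class ConfigError(ValueError):
    """Invalid pipeline configuration (message names the offending field)."""


@dataclass
class PipelineConfig:
    seed: int
    outdir: Path
    thresholds: dict[str, float]
    simulation: dict[str, Any] | None = None
    paths: dict[str, str] = field(default_factory=dict)


def validate_config(raw: dict[str, Any]) -> PipelineConfig:
    """Validate, fill defaults and normalise a raw config mapping."""
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    if "seed" not in raw:
        raise ConfigError("seed: mandatory (stochastic stages are enabled)")
    try:
        seed = int(raw["seed"])
    except (TypeError, ValueError):
        raise ConfigError("seed: must be an integer")
    if "outdir" not in raw:
        raise ConfigError("outdir: mandatory")
    thresholds = dict(DEFAULT_THRESHOLDS)
    for key, value in (raw.get("thresholds") or {}).items():
        if key not in DEFAULT_THRESHOLDS:
            raise ConfigError(f"thresholds.{key}: unknown threshold")
        lo, hi, lo_open, hi_open = _THRESHOLD_DOMAINS[key]
        v = float(value)
        ok_lo = v > lo if lo_open else v >= lo
        ok_hi = v < hi if hi_open else v <= hi
        if not (ok_lo and ok_hi):
            lb, rb = ("(" if lo_open else "["), (")" if hi_open else "]")
            raise ConfigError(f"thresholds.{key}: {v} outside domain {lb}{lo}, {hi}{rb}")
        thresholds[key] = v
    simulation = raw.get("simulation")
    paths = raw.get("paths") or {}
    if simulation is not None and paths.get("contigs"):
        raise ConfigError("simulation and paths.contigs are mutually exclusive")
    if simulation is None:
        for required in ("contigs", "references", "reference_metadata"):
            p = paths.get(required)
            if not p:
                raise ConfigError(f"paths.{required}: required when no simulation spec is given")
            if not Path(p).exists():
                raise ConfigError(f"paths.{required}: {p} does not exist")
    return PipelineConfig(
        seed=seed,
        outdir=Path(raw["outdir"]),
        thresholds=thresholds,
        simulation=simulation,
        paths={k: str(v) for k, v in paths.items()},
    )


def _log(msg: str) -> None:
    print(f"[darkbin] {msg}", file=sys.stderr)


def _simulate_inputs(cfg: PipelineConfig, outdir: Path) -> dict[str, Any]:
    """Generate the full synthetic input bundle described by the config.

    The simulation spec lists reference species, known-strain and novel
    genomes as divergences from shared ancestors; contigs, a cohort count
    table and MLST reads are derived from them.
    """
    sim = cfg.simulation or {}
    seed = cfg.seed
    genome_specs = sim.get("genomes", {})
    ancestor = simulate.GenomeSpec(**genome_specs.get("ancestor", {"id": "anc", "length": 60000}))
    children = [simulate.GenomeSpec(**g) for g in genome_specs.get("children", [])]
    genomes, truth = simulate.evolve_genome_set(ancestor, children, seed=seed)
    references = {g: genomes[g] for g in sim.get("references", [])}
    species_map = dict(sim.get("reference_species", {}))
    contig_specs = sim.get("contigs", [])
    contigs = []
    for spec in contig_specs:
        contigs.extend(
            simulate.fragment_to_contigs(
                genomes[spec["genome"]],
                n_contigs=spec.get("n_contigs", 20),
                coverage_mean=spec.get("coverage_mean", 30.0),
                coverage_cv=spec.get("coverage_cv", 0.1),
                min_len=spec.get("min_len", 1500),
                seed=seed + spec.get("seed_offset", 0),
                source=spec["genome"],
            )
        )
    write_fasta(references, outdir / "references.fasta")
    write_contigs(contigs, outdir / "contigs.fasta")
    truth.to_csv(outdir / "divergence_truth.tsv", sep="\t")
    pd.DataFrame(
        [{"genome_id": g, "species": s} for g, s in species_map.items()]
    ).to_csv(outdir / "reference_species.tsv", sep="\t", index=False)

    cohort_cfg = sim.get("cohort", {})
    cohort_spec = simulate.CohortSpec(seed=seed + 1, **cohort_cfg)
    counts, metadata, cohort_truth = simulate.simulate_cohort(cohort_spec)
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    metadata.to_csv(outdir / "metadata.tsv", sep="\t")
    cohort_truth.to_csv(outdir / "cohort_truth.tsv", sep="\t")

    mlst_cfg = sim.get("mlst", {})
    scheme = mlst.make_scheme(seed=seed + 2, **mlst_cfg.get("scheme", {}))
    scheme.to_directory(outdir / "scheme")
    sample_reads = {}
    for sample in mlst_cfg.get("samples", [{"id": "S1", "st": 1}, {"id": "S2", "st": 1}]):
        st = sample.get("st", 1)
        alleles = {
            locus: scheme.alleles[locus][int(scheme.profiles.loc[st, locus])]
            for locus in scheme.loci
        }
        reads, _ = simulate.simulate_mlst_reads(
            alleles,
            read_len=mlst_cfg.get("read_len", 100),
            coverage=mlst_cfg.get("coverage", 20.0),
            error_rate=mlst_cfg.get("error_rate", 0.01),
            seed=seed + 3 + sample.get("seed_offset", 0),
        )
        sample_reads[sample["id"]] = reads
    gene_cfg = sim.get("genes", {"n_genes": 25, "gene_len": 800})
    genes = simulate.gene_windows(genomes[ancestor.id], **gene_cfg)
    write_fasta(genes, outdir / "reference_genes.fasta")
    return {
        "genomes": genomes,
        "references": references,
        "species_map": species_map,
        "contigs": contigs,
        "counts": counts,
        "metadata": metadata,
        "scheme": scheme,
        "sample_reads": sample_reads,
        "genes": genes,
    }


def _load_inputs(cfg: PipelineConfig, outdir: Path) -> dict[str, Any]:
    references = read_fasta(cfg.paths["references"])
    meta = pd.read_csv(cfg.paths["reference_metadata"], sep="\t")
    species_map = dict(zip(meta["genome_id"], meta["species"]))
    contigs = read_contigs(cfg.paths["contigs"])
    data: dict[str, Any] = {
        "references": references,
        "species_map": species_map,
        "contigs": contigs,
        "genomes": dict(references),
    }
    if cfg.paths.get("counts") and cfg.paths.get("metadata"):
        data["counts"] = pd.read_csv(cfg.paths["counts"], sep="\t", index_col=0)
        data["metadata"] = pd.read_csv(cfg.paths["metadata"], sep="\t", index_col=0)
    if cfg.paths.get("scheme"):
        data["scheme"] = mlst.Scheme.from_directory(cfg.paths["scheme"])
    if cfg.paths.get("reference_genes"):
        data["genes"] = read_fasta(cfg.paths["reference_genes"])
    data["sample_reads"] = {}
    return data


def run_pipeline(raw_config: dict[str, Any]) -> dict[str, Any]:
    """Run every stage and return (and write) the JSON report."""
    cfg = validate_config(raw_config)
    outdir = cfg.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    thr = cfg.thresholds
    report: dict[str, Any] = {"seed": cfg.seed, "thresholds": thr, "stages": {}}

    stage = "simulate" if cfg.simulation is not None else "load"
    try:
        _log(f"stage {stage}: preparing inputs")
        data = (
            _simulate_inputs(cfg, outdir)
            if cfg.simulation is not None
            else _load_inputs(cfg, outdir)
        )
        report["stages"][stage] = {
            "n_references": len(data["references"]),
            "n_contigs": len(data["contigs"]),
        }

        stage = "align"
        _log("stage align: mapping contigs to references")
        hits = []
        for ref_id, ref_seq in data["references"].items():
            index = SubjectIndex(ref_id, ref_seq)
            for contig in data["contigs"]:
                hits.extend(align_to_index(contig.id, contig.seq, index))
        hits.sort(key=lambda h: (h.query_id, h.query_start, h.subject_id))
        write_hit_table(hits, outdir / "hits.tsv")
        report["stages"]["align"] = {"n_hits": len(hits)}

        stage = "assign"
        _log("stage assign: 90/90 conservative taxonomy")
        assignments = taxonomy.assign_contigs(data["contigs"], hits, data["species_map"])
        taxonomy.write_assignments(assignments, outdir / "assignments.tsv")
        species_bins, residual = taxonomy.bin_by_label(
            assignments, data["contigs"], min_contig_len=int(thr["min_contig_len"])
        )
        report["stages"]["assign"] = {
            "n_assigned": sum(1 for a in assignments if a.label != taxonomy.UNASSIGNED),
            "n_unassigned": sum(1 for a in assignments if a.label == taxonomy.UNASSIGNED),
            "species_bins": {k: b.n_contigs for k, b in sorted(species_bins.items())},
            "n_residual": len(residual),
        }

        stage = "bin"
        _log("stage bin: GC/coverage K-means + curation")
        bins, labels, feats = binning.cluster_unassigned(
            residual, k_max=int(thr["k_max"]), seed=cfg.seed,
            silhouette_floor=thr["silhouette_floor"],
        )
        curated, rejected, records = binning.curate_bins(
            bins, feats, labels,
            gc_tol=thr["gc_tol"], cov_tol=thr["cov_tol"], sep_threshold=thr["sep_threshold"],
        )
        binning.write_curation(records, outdir / "bin_curation.tsv")
        binning.write_scatter(
            residual, labels, {r.bin_id: r.status for r in records}, outdir / "bin_scatter.tsv"
        )
        for bid, tb in sorted(curated.items()):
            write_contigs(tb.contigs, outdir / f"{bid}.fasta")
        report["stages"]["bin"] = {
            "n_preliminary": len(bins),
            "curated": sorted(curated),
            "rejected": {r.bin_id: r.reject_reason for r in records if r.status == "rejected"},
        }

        stage = "ani"
        _log("stage ani: novelty calls for curated bins")
        ani_reports = []
        bin_calls = {}
        ref_indexes = {
            rid: SubjectIndex(rid, rseq) for rid, rseq in data["references"].items()
        }
        for bid, tb in sorted(curated.items()):
            seqs = [c.seq for c in tb.contigs]
            reports = [
                ani_mod.fragment_ani(
                    seqs, ref_indexes[rid], query_id=bid,
                    frag_len=int(thr["frag_len"]),
                    min_frag_identity=thr["min_frag_identity"],
                    min_frag_cov=thr["min_frag_cov"],
                )
                for rid in sorted(data["references"])
            ]
            call, best = ani_mod.classify_bin(reports, threshold=thr["ani_threshold"])
            ani_reports.extend(reports)
            bin_calls[bid] = {
                "call": call,
                "best_reference": best.reference_id if best else None,
                "ani_mean": round(best.ani_mean, 4) if best else None,
            }
        ani_mod.write_ani_reports(ani_reports, outdir / "ani.tsv")
        report["stages"]["ani"] = bin_calls
        novel_bins = sorted(b for b, c in bin_calls.items() if c["call"] == ani_mod.CALL_NOVEL)
        report["novel_bins"] = novel_bins

        if "genes" in data and len(data["references"]) + len(curated) >= 3:
            stage = "coregenome"
            _log("stage coregenome: concatenated core + NJ tree")
            genome_set = {g: s for g, s in data["references"].items()}
            for bid, tb in sorted(curated.items()):
                genome_set[bid] = "".join(c.seq for c in tb.contigs)
            table = coregenome.find_orthologs(
                data["genes"], genome_set,
                min_len=int(thr["min_ortholog_len"]),
                min_identity=thr["min_ortholog_identity"],
            )
            core = coregenome.select_core(table, min_prevalence=thr["min_core_prevalence"])
            aln = coregenome.build_concat_alignment(core, table, data["genes"])
            aln = coregenome.trim_alignment(aln, max_gap_fraction=thr["max_gap_fraction"])
            tree = coregenome.nj_tree(aln)
            coregenome.write_core_genes(core, table, outdir / "core_genes.tsv")
            coregenome.write_alignment_fasta(aln, outdir / "core_alignment.fasta")
            (outdir / "core_tree.nwk").write_text(tree + "\n")
            report["stages"]["coregenome"] = {
                "n_core_genes": len(core),
                "alignment_columns": aln.n_columns,
                "n_leaves": len(aln.genome_ids),
            }

        if "scheme" in data and data["sample_reads"]:
            stage = "mlst"
            _log("stage mlst: consensus typing + strain identity")
            profiles = []
            for sample_id, reads in sorted(data["sample_reads"].items()):
                pileups = mlst.pileup_reads(reads, data["scheme"])
                consensus = {
                    locus: mlst.consensus_allele(p) for locus, p in pileups.items()
                }
                profiles.append(mlst.assign_st(consensus, data["scheme"], sample_id=sample_id))
            mlst.write_profiles(profiles, outdir / "mlst_profiles.tsv")
            identity = {}
            for i in range(len(profiles)):
                for j in range(i + 1, len(profiles)):
                    same, _snps = mlst.strains_identical(profiles[i], profiles[j])
                    identity[f"{profiles[i].sample_id}|{profiles[j].sample_id}"] = bool(same)
            report["stages"]["mlst"] = {
                "sts": {p.sample_id: p.st for p in profiles},
                "strain_identity": identity,
            }

        if "counts" in data:
            stage = "diversity"
            _log("stage diversity: rarefaction, alpha/beta, paired test")
            depth = int(thr["rarefaction_depth"])
            rng = np.random.default_rng(cfg.seed + 7)
            records_div = []
            for sid in data["counts"].index:
                try:
                    sub = diversity.rarefy_counts(data["counts"].loc[sid], depth, rng)
                except diversity.SampleTooShallow:
                    continue
                records_div.append(diversity.alpha_diversity(sub, sample_id=sid))
            diversity.write_diversity(records_div, outdir / "diversity.tsv")
            intra, inter, beta_summary = diversity.intra_inter_beta(
                data["counts"], data["metadata"]
            )
            paired = diversity.paired_site_test(
                data["counts"], data["metadata"], seed=cfg.seed + 8
            )
            diversity.write_paired_results(paired, outdir / "paired_test.tsv")
            report["stages"]["diversity"] = {
                "n_samples_rarefied": len(records_div),
                "intra_mean_bray_curtis": round(beta_summary["intra_mean"], 6),
                "inter_mean_bray_curtis": round(beta_summary["inter_mean"], 6),
                "significant_taxa": sorted(
                    r.taxon for r in paired if r.p_adjusted < 0.05
                ),
            }
    except Exception as exc:
        _log(f"stage {stage} failed: {exc}")
        raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") from exc

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    _log(f"report written to {report_path}")
    return report
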