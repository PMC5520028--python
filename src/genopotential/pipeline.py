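"""End-to-end orchestration: config, stage ordering, report bundle, demo.

``run_pipeline`` executes the stages in dependency order (parse → bin QC →
dereplication → heme/hydrogenase/pathway annotation → abundance → profile
matrix) and writes per-stage TSVs plus one JSON summary holding the
headline accounting: bins and high-quality bins, distinct genomes after
dereplication, hydrogenases by class, predicted iron reducers, genome-level
co-occurrence fractions, and the rpS3 community accounting.  Everything is
deterministic under a fixed seed and every threshold used is echoed into
the summary so any number is auditable.
"""

from __future__ import annotations

import json
import logging
import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from . import community as comm
from . import heme_scan, hydrogenase_typing, pathway_profile
from .core_model import (DEFAULT_BIT_SCORE_CUTOFF, GenomeBin, Thresholds,
                         map_genes_to_bins, parse_bin_membership,
                         parse_coverage_table, parse_gene_calls,
                         parse_nucleotide_fasta, parse_profile_hits,
                         parse_protein_fasta)
from .synthetic_data import SyntheticTruth, generate_community

logger = logging.getLogger("genopotential")

SCHEMA_VERSION = 1
ALL_STAGES = ("binqc", "derep", "heme", "hyd", "pathway", "abundance",
              "matrix")

#: replicate layout of the bundled demo community: four faithful replicates
#: (0.5 % point mutation) and four decoys (10 %)
DEMO_REPLICATE_SPEC = ((0, 0.005), (1, 0.005), (2, 0.005), (3, 0.005),
                       (4, 0.10), (5, 0.10), (6, 0.10), (7, 0.10))
DEMO_N_BINS = 12


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage and offending input."""


@dataclass
class RunConfig:
    paths: dict                 # proteins/scaffolds/genes/hits/coverage/bins/markers
    outdir: str
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    stages: tuple = ALL_STAGES
    rules_path: Optional[str] = None
    top_k: int = 50

    REQUIRED = ("proteins", "scaffolds", "genes", "hits", "coverage", "bins",
                "markers")

    def validate(self) -> None:
        missing = [k for k in self.REQUIRED if k not in self.paths]
        if missing:
            raise PipelineError(f"config lacks input paths: {missing}")
        for key in self.REQUIRED:
            if not os.path.exists(self.paths[key]):
                raise PipelineError(
                    f"input file for {key!r} not found: {self.paths[key]}")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise PipelineError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        base = os.path.dirname(os.path.abspath(path))
        with open(path) as fh:
            data = json.load(fh)

        def resolve(p):
            return p if os.path.isabs(p) else os.path.join(base, p)

        thresholds = Thresholds(**data.get("thresholds", {}))
        return cls(
            paths={k: resolve(v) for k, v in data["paths"].items()},
            outdir=resolve(data["outdir"]),
            seed=int(data.get("seed", 0)),
            thresholds=thresholds,
            stages=tuple(data.get("stages", ALL_STAGES)),
            rules_path=(resolve(data["rules"]) if "rules" in data else None),
            top_k=int(data.get("top_k", 50)),
        )


def write_summary(summary: dict, path) -> str:
    """Canonical JSON serialization (sorted keys, trailing newline)."""
    text = json.dumps(summary, indent=2, sort_keys=True) + "\n"
    with open(path, "w") as fh:
        fh.write(text)
    return text


def _write_tsv(df: pd.DataFrame, path: str, seed: int, index=True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=index)


def parse_marker_table(path) -> comm.MarkerSet:
    df = pd.read_csv(path, sep="\t")
    return comm.MarkerSet(domain="bacteria",
                          markers=tuple(df["marker"].astype(str)))


def run_pipeline(config: RunConfig) -> dict:
    """Run every enabled stage; returns the summary dict (also written).

    Any stage error aborts the run as a ``PipelineError`` naming the stage.
    """
    config.validate()
    thr = config.thresholds
    os.makedirs(config.outdir, exist_ok=True)
    log_path = os.path.join(config.outdir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.info("thresholds: %s", thr.to_dict())
    summary: dict = {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "thresholds": thr.to_dict(),
    }
    try:
        stage = "parse"
        proteins = parse_protein_fasta(config.paths["proteins"])
        scaffold_seqs = parse_nucleotide_fasta(config.paths["scaffolds"])
        gene_calls = parse_gene_calls(config.paths["genes"])
        hits = parse_profile_hits(config.paths["hits"],
                                  default_cutoff=DEFAULT_BIT_SCORE_CUTOFF)
        coverage = parse_coverage_table(config.paths["coverage"])
        membership = parse_bin_membership(config.paths["bins"])
        marker_set = parse_marker_table(config.paths["markers"])
        rules = pathway_profile.load_rulebook(config.rules_path)

        bins = [GenomeBin(bin_id=b, scaffold_ids=set(s))
                for b, s in sorted(membership.items())]
        gene_bins = map_genes_to_bins(gene_calls, membership)
        summary["bins"] = {"n_bins": len(bins)}

        if "binqc" in config.stages:
            stage = "binqc"
            comm.qc_bins(bins, hits, gene_bins, marker_set, thr)
            qc = pd.DataFrame(
                [{"bin_id": b.bin_id, "completeness": b.completeness,
                  "contamination": b.contamination,
                  "is_high_quality": b.is_high_quality} for b in bins]
            ).set_index("bin_id")
            _write_tsv(qc, os.path.join(config.outdir, "bin_qc.tsv"),
                       config.seed)
            summary["bins"]["n_high_quality"] = int(
                sum(1 for b in bins if b.is_high_quality))

        if "derep" in config.stages:
            stage = "derep"
            derep = comm.dereplicate_from_scaffolds(bins, scaffold_seqs, thr)
            rows = [{"bin_id": b, "representative": derep.representative[c]}
                    for c in derep.clusters for b in sorted(c)]
            _write_tsv(pd.DataFrame(rows).set_index("bin_id"),
                       os.path.join(config.outdir, "dereplication.tsv"),
                       config.seed)
            summary["dereplication"] = {"n_clusters": len(derep.clusters)}

        if "heme" in config.stages:
            stage = "heme"
            mhcs = heme_scan.call_mhcs(proteins, thr)
            preds = heme_scan.predict_iron_reducers(bins, mhcs, gene_bins,
                                                    thr)
            mhc_df = pd.DataFrame(
                [{"gene_id": m.gene_id, "bin_id": gene_bins.get(m.gene_id, ""),
                  "motif_count": m.motif_count, "is_mhc": m.is_mhc}
                 for m in mhcs]).set_index("gene_id")
            _write_tsv(mhc_df, os.path.join(config.outdir, "mhc_scan.tsv"),
                       config.seed)
            iron_df = pd.DataFrame(
                [{"bin_id": p.bin_id, "n_mhcs": p.n_mhcs,
                  "max_motifs_single_protein": p.max_motifs_single_protein,
                  "predicted_iron_reducer": p.predicted_iron_reducer}
                 for p in preds]).set_index("bin_id")
            _write_tsv(iron_df, os.path.join(config.outdir,
                                             "iron_prediction.tsv"),
                       config.seed)
            summary["iron"] = {
                "n_mhc_proteins": int(sum(p.n_mhcs for p in preds)),
                "n_iron_reducer_bins": int(
                    sum(1 for p in preds if p.predicted_iron_reducer)),
                "max_motifs_single_protein": int(
                    max((p.max_motifs_single_protein for p in preds),
                        default=0)),
            }

        hyd_summary = None
        if "hyd" in config.stages:
            stage = "hyd"
            calls = hydrogenase_typing.classify_hydrogenases(
                gene_calls, hits, thr)
            hyd_summary = hydrogenase_typing.summarize_hydrogenases(
                bins, calls, hits, gene_bins)
            call_df = pd.DataFrame(
                [{"gene_id": c.gene_id,
                  "bin_id": gene_bins.get(c.gene_id, ""),
                  "cofactor": c.cofactor, "group": c.group,
                  "subgroup": c.subgroup, "label": c.label,
                  "evidence": ";".join(f"{g}:{r}" for g, r in c.evidence)}
                 for c in calls]).set_index("gene_id")
            _write_tsv(call_df,
                       os.path.join(config.outdir, "hydrogenase_calls.tsv"),
                       config.seed)
            by_label = Counter(c.label for c in calls
                               if c.gene_id in gene_bins)
            a1a3, a3rnf, ba3 = hydrogenase_typing.cooccurrence_stats(
                hyd_summary)
            summary["hydrogenases"] = {
                "total": int(sum(by_label.values())),
                "by_label": {k: int(v) for k, v in sorted(by_label.items())},
            }
            summary["cooccurrence"] = {
                "frac_a1_with_a3": a1a3,
                "frac_bifurcating_with_rnf": a3rnf,
                "frac_b_with_a3": ba3,
            }

        pathway_calls = []
        labels_by_bin = {b.bin_id: set() for b in bins}
        for h in hits:
            bin_id = gene_bins.get(h.gene_id)
            if bin_id in labels_by_bin:
                labels_by_bin[bin_id].add(h.profile)
        if "pathway" in config.stages:
            stage = "pathway"
            pathway_calls = pathway_profile.call_pathways(labels_by_bin,
                                                          rules)
            pw_df = pd.DataFrame(
                [{"bin_id": c.bin_id, "pathway": c.pathway,
                  "status": c.status,
                  "satisfied_clauses": c.satisfied_clauses,
                  "genes_found": ";".join(c.genes_found)}
                 for c in pathway_calls]).set_index("bin_id")
            _write_tsv(pw_df, os.path.join(config.outdir,
                                           "pathway_calls.tsv"), config.seed)
            counts: dict = {}
            for c in pathway_calls:
                counts.setdefault(c.pathway, Counter())[c.status] += 1
            summary["pathways"] = {
                p: {"complete": int(ctr["complete"]),
                    "partial": int(ctr["partial"]),
                    "absent": int(ctr["absent"])}
                for p, ctr in sorted(counts.items())}

        abundance = None
        if "abundance" in config.stages:
            stage = "abundance"
            lengths = {s: len(seq) for s, seq in scaffold_seqs.items()}
            abundance = comm.relative_abundance(bins, lengths, coverage)
            _write_tsv(abundance, os.path.join(config.outdir,
                                               "abundance.tsv"), config.seed)
            rps3_genes = {h.gene_id for h in hits if h.profile == "rpS3"}
            scaffold_of = {c.gene_id: c.scaffold_id for c in gene_calls}
            rps3_seqs = {g: proteins[g] for g in sorted(rps3_genes)
                         if g in proteins}
            clusters = comm.cluster_rps3(rps3_seqs, thr)
            rank_table, rank_summary = comm.rank_abundance(
                clusters, scaffold_of, coverage, membership, thr,
                top_k=config.top_k)
            _write_tsv(rank_table, os.path.join(config.outdir,
                                                "rank_abundance.tsv"),
                       config.seed)
            summary["community"] = rank_summary

        if "matrix" in config.stages:
            stage = "matrix"
            if abundance is None:
                lengths = {s: len(seq) for s, seq in scaffold_seqs.items()}
                abundance = comm.relative_abundance(bins, lengths, coverage)
            matrix = pathway_profile.build_profile_matrix(
                bins, pathway_calls, hyd_summary, abundance,
                bin_genes_by_bin=labels_by_bin, rules=rules, thresholds=thr)
            _write_tsv(matrix, os.path.join(config.outdir,
                                            "profile_matrix.tsv"),
                       config.seed)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    write_summary(summary, os.path.join(config.outdir, "summary.json"))
    return summary


# ---------------------------------------------------------------------------
# truth-side expected summary and the demo bundle
# ---------------------------------------------------------------------------

def summary_from_truth(truth: SyntheticTruth, seed: int,
                       thresholds: Optional[Thresholds] = None,
                       n_markers: int = 51, top_k: int = 50) -> dict:
    """The summary a pipeline run must reproduce, derived from planted truth.

    Every count is recomputed from the truth records (marker complements,
    planted motif counts, planted operon labels, replicate substitution
    counts), not from pipeline outputs.
    """
    thr = thresholds or Thresholds()
    bins = sorted(truth.marker_complement)
    n_hq = 0
    for b in bins:
        comp = 100.0 * len(truth.marker_complement[b]["present"]) / n_markers
        cont = 100.0 * len(truth.marker_complement[b]["duplicated"]) / n_markers
        if comp > thr.hq_min_completeness and cont < thr.hq_max_contamination:
            n_hq += 1

    mhc_per_bin = {b: sum(1 for n in truth.planted_motifs.get(b, {}).values()
                          if n >= thr.mhc_min_motifs) for b in bins}
    all_motifs = [n for b in bins
                  for n in truth.planted_motifs.get(b, {}).values()]

    by_label = Counter(label for b in bins
                       for label in truth.hydrogenase_labels.get(b, {}).values())
    a1_bins = {b for b in bins
               if "A1" in truth.hydrogenase_labels.get(b, {}).values()}
    a3_bins = {b for b in bins
               if "A3" in truth.hydrogenase_labels.get(b, {}).values()}
    b_bins = {b for b in bins
              if "B" in truth.hydrogenase_labels.get(b, {}).values()}
    rnf_bins = set(truth.rnf_bins)

    def frac(first, second):
        if not first:
            return None
        return len(first & second) / len(first)

    pathway_counts: dict = {}
    for b in bins:
        for pathway, status in truth.pathway_status.get(b, {}).items():
            pathway_counts.setdefault(pathway, Counter())[status] += 1

    # community accounting from planted abundances and planted clusters
    samples = sorted(truth.abundance)
    gene_to_org = {v["gene"]: org for org, v in truth.rps3_genes.items()}
    reps = [c["representative"] for c in truth.rps3_clusters]
    mean_rel = {}
    for rep in reps:
        org = gene_to_org[rep]
        vals = []
        for s in samples:
            total = sum(truth.abundance[s][gene_to_org[r]] for r in reps)
            vals.append(truth.abundance[s][org] / total)
        mean_rel[rep] = sum(vals) / len(vals)
    ranked = sorted(truth.rps3_clusters,
                    key=lambda c: (-mean_rel[c["representative"]],
                                   c["representative"]))
    k = min(top_k, len(ranked))
    unbinned = [c for c in ranked if not c["binned"]]
    community = {
        "n_organisms": len(ranked),
        "top_k": k,
        "top_k_binned": int(sum(1 for c in ranked[:k] if c["binned"])),
        "n_unbinned": len(unbinned),
        "frac_unbinned_below_rare": (
            sum(1 for c in unbinned
                if mean_rel[c["representative"]] < thr.rare_abundance_frac)
            / len(unbinned) if unbinned else None),
    }

    return {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "thresholds": thr.to_dict(),
        "bins": {"n_bins": len(bins), "n_high_quality": n_hq},
        "dereplication": {"n_clusters": len(truth.derep_clusters)},
        "iron": {
            "n_mhc_proteins": int(sum(mhc_per_bin.values())),
            "n_iron_reducer_bins": int(
                sum(1 for v in mhc_per_bin.values()
                    if v >= thr.iron_min_mhcs)),
            "max_motifs_single_protein": int(max(all_motifs, default=0)),
        },
        "hydrogenases": {
            "total": int(sum(by_label.values())),
            "by_label": {k: int(v) for k, v in sorted(by_label.items())},
        },
        "cooccurrence": {
            "frac_a1_with_a3": frac(a1_bins, a3_bins),
            "frac_bifurcating_with_rnf": frac(a3_bins, rnf_bins),
            "frac_b_with_a3": frac(b_bins, a3_bins),
        },
        "pathways": {
            p: {"complete": int(ctr["complete"]),
                "partial": int(ctr["partial"]),
                "absent": int(ctr["absent"])}
            for p, ctr in sorted(pathway_counts.items())},
        "community": community,
    }


def make_demo(seed: int, outdir: str,
              thresholds: Optional[Thresholds] = None) -> dict:
    """Write a ~20-bin demo community plus its expected summary and config.

    Returns the path map, including ``config`` (ready for ``run_pipeline``)
    and ``expected_summary`` (what the run must reproduce byte-for-byte).
    """
    thr = thresholds or Thresholds()
    bundle = generate_community(n_bins=DEMO_N_BINS,
                                replicate_spec=DEMO_REPLICATE_SPEC,
                                seed=seed, thresholds=thr)
    paths = bundle.write(outdir)
    expected = summary_from_truth(bundle.truth, seed=seed, thresholds=thr,
                                  n_markers=len(bundle.marker_set.markers))
    paths["expected_summary"] = os.path.join(outdir, "expected_summary.json")
    write_summary(expected, paths["expected_summary"])
    config = {
        "paths": {k: os.path.basename(paths[k])
                  for k in RunConfig.REQUIRED},
        "outdir": "results",
        "seed": seed,
    }
    paths["config"] = os.path.join(outdir, "config.json")
    with open(paths["config"], "w") as fh:
        json.dump(config, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
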