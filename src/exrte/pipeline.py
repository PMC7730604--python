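"""End-to-end orchestration: catalog -> expression -> age -> ORF/motif ->
proximity -> mobilome -> statistics.

Each stage writes one table; a machine-readable summary records the counts
at every filter step (the survey funnel) together with the configuration
hash and seed.  Re-running on identical inputs and configuration produces
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from exrte import catalog as cat
from exrte import expression as expr
from exrte import mobilome as mob
from exrte import orfs as orfmod
from exrte import proximity as prox
from exrte import stats as st
from exrte.config import PipelineConfig
from exrte.insertion_age import K2PDomainError, date_ltr_pair
from exrte.simulate import DOMAIN_TAGS

logger = logging.getLogger(__name__)


@dataclass
class InputPaths:
    """Locations of the pipeline inputs."""

    genome: Path
    rte_gff: Path
    gene_gff: Path
    counts: Path
    library_sizes: Path
    depth_bedgraphs: dict[str, Path]
    cultivar_depth: Path
    domain_hits: Path | None = None  # optional external ORF->domain table

    @classmethod
    def from_dataset_dir(cls, dataset: str | Path) -> "InputPaths":
        """Input layout written by :func:`exrte.simulate.generate_dataset`."""
        d = Path(dataset)
        depths = {
            p.stem.removeprefix("depth_"): p for p in sorted(d.glob("depth_*.bedgraph"))
        }
        return cls(
            genome=d / "genome.fa",
            rte_gff=d / "rtes.gff3",
            gene_gff=d / "genes.gff3",
            counts=d / "counts.tsv",
            library_sizes=d / "library_sizes.tsv",
            depth_bedgraphs=depths,
            cultivar_depth=d / "cultivar_depth.tsv",
        )


def _fmt(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def run_pipeline(
    config: PipelineConfig, inputs: InputPaths, outdir: str | Path
) -> dict:
    """Run every stage; write tables plus ``summary.json``; return the summary."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": config.hash(), "seed": config.seed, "funnel": {}}

    # ---- catalog -------------------------------------------------------
    logger.info("stage catalog: parsing %s", inputs.rte_gff)
    rtes = cat.parse_ltr_gff(inputs.rte_gff)
    summary["funnel"]["annotated"] = len(rtes)
    candidates = cat.filter_candidates(
        rtes, min_len=config.min_rte_length, required_domains=set(config.required_domains)
    )
    summary["funnel"]["candidates"] = len(candidates)
    seqs = cat.extract_sequences(inputs.genome, candidates)
    _fmt(
        pd.DataFrame(
            {
                "rte_id": [r.id for r in candidates],
                "chrom": [r.chrom for r in candidates],
                "start": [r.start for r in candidates],
                "end": [r.end for r in candidates],
                "length": [r.length for r in candidates],
                "strand": [r.strand for r in candidates],
                "domains": [",".join(sorted(r.domains())) for r in candidates],
                "max_domain_aa": [r.max_domain_aa for r in candidates],
                "superfamily": [r.superfamily for r in candidates],
                "clade": [r.clade for r in candidates],
            }
        ),
        outdir / "catalog.tsv",
    )

    # ---- expression ----------------------------------------------------
    logger.info("stage expression: %d samples", len(inputs.depth_bedgraphs))
    libs_df = pd.read_csv(inputs.library_sizes, sep="\t")
    library_sizes = dict(zip(libs_df["sample"], libs_df["library_size"].astype(float)))
    sample_labels = dict(zip(libs_df["sample"], libs_df["condition"]))
    chrom_lengths = {
        rec.id: len(rec.seq) for rec in SeqIO.parse(str(inputs.genome), "fasta")
    }
    depth_by_sample = {
        s: expr.read_bedgraph(p, chrom_lengths) for s, p in inputs.depth_bedgraphs.items()
    }
    counts = pd.read_csv(inputs.counts, sep="\t")
    profiles = expr.build_profiles(
        candidates, counts, library_sizes, depth_by_sample,
        pooled_coverage=config.pooled_coverage,
    )
    # funnel sub-steps (cumulative, for the summary only)
    n_rpkm = sum(
        1 for p in profiles.values() if any(ev.rpkm >= config.rpkm_min for ev in p.samples.values())
    )
    n_cov = sum(
        1
        for p in profiles.values()
        if any(ev.rpkm >= config.rpkm_min for ev in p.samples.values())
        and any(ev.covered_fraction >= config.cov_min for ev in p.samples.values())
    )
    ex_ids, nex_ids = expr.call_expressed(
        profiles,
        candidates,
        seqs=seqs,
        rpkm_min=config.rpkm_min,
        cov_min=config.cov_min,
        min_domain_aa=config.min_domain_aa,
        dedup_identity=config.dedup_identity,
        strict_same_sample=config.strict_same_sample,
    )
    summary["funnel"]["rpkm_pass"] = n_rpkm
    summary["funnel"]["coverage_pass"] = n_cov
    summary["funnel"]["exrte"] = len(ex_ids)
    summary["n_exrte"] = len(ex_ids)
    summary["n_nexrte"] = len(nex_ids)
    _fmt(expr.profiles_to_frame(profiles), outdir / "expression.tsv")
    venn = expr.condition_partition(
        profiles, ex_ids, sample_labels, rpkm_min=config.rpkm_min, cov_min=config.cov_min
    )
    summary["condition_partition"] = venn
    ex_set = set(ex_ids)

    # ---- insertion age -------------------------------------------------
    logger.info("stage age: dating %d elements", len(candidates))
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(inputs.genome), "fasta")}
    age_rows = []
    for r in candidates:
        ltr5 = genome[r.chrom][r.ltr5[0] : r.ltr5[1]]
        ltr3 = genome[r.chrom][r.ltr3[0] : r.ltr3[1]]
        try:
            est = date_ltr_pair(
                r.id, ltr5, ltr3, r=config.mutation_rate,
                recent_boundary=config.recent_boundary_years,
            )
            age_rows.append(
                {
                    "rte_id": r.id,
                    "set": "exRTE" if r.id in ex_set else "n-exRTE",
                    "aligned_columns": est.aligned_columns,
                    "p": est.p,
                    "q": est.q,
                    "k": est.k,
                    "t_mya": est.t_years / 1e6,
                    "recency": est.recency,
                }
            )
        except K2PDomainError as exc:
            logger.warning("element %s undatable: %s", r.id, exc)
            age_rows.append(
                {
                    "rte_id": r.id,
                    "set": "exRTE" if r.id in ex_set else "n-exRTE",
                    "aligned_columns": 0,
                    "p": math.nan,
                    "q": math.nan,
                    "k": math.nan,
                    "t_mya": math.nan,
                    "recency": "undatable",
                }
            )
    age_columns = ["rte_id", "set", "aligned_columns", "p", "q", "k", "t_mya", "recency"]
    age_df = pd.DataFrame(age_rows, columns=age_columns)
    _fmt(age_df, outdir / "age.tsv")
    summary["recency_counts"] = {
        group: {
            k: int(v)
            for k, v in age_df[age_df["set"] == group]["recency"].value_counts().items()
        }
        for group in ("exRTE", "n-exRTE")
    }

    # ---- ORFs, domains, RBM screen -------------------------------------
    logger.info("stage orfs")
    all_orfs: list[orfmod.OrfRecord] = []
    for r in candidates:
        all_orfs.extend(orfmod.find_orfs(seqs[r.id], config.min_orf_nt, rte_id=r.id))
    if inputs.domain_hits is not None:
        hits_df = pd.read_csv(inputs.domain_hits, sep="\t")
        orfmod.label_orfs_with_table(
            all_orfs, dict(zip(hits_df["orf_id"], hits_df["domain"]))
        )
    else:
        orfmod.label_orfs_by_tags(all_orfs, config.domain_tags or DOMAIN_TAGS)
    _fmt(
        pd.DataFrame(
            [
                {
                    "orf_id": o.orf_id,
                    "rte_id": o.rte_id,
                    "start": o.start,
                    "end": o.end,
                    "strand": o.strand,
                    "frame": o.frame,
                    "nt_length": o.nt_length,
                    "domain": o.domain,
                    "rbm_count": o.rbm_count,
                }
                for o in all_orfs
            ]
        ),
        outdir / "orfs.tsv",
    )
    rbm = orfmod.compute_rbm_fdr(all_orfs)
    summary["rbm"] = {
        "n_gag_orfs": rbm.n_gag_orfs,
        "n_gag_with_rbm": rbm.n_gag_with_rbm,
        "n_nongag_orfs": rbm.n_nongag_orfs,
        "n_nongag_with_rbm": rbm.n_nongag_with_rbm,
        "fdr": rbm.fdr,
        "fdr_percent": st.percent(rbm.n_nongag_with_rbm, rbm.n_nongag_orfs)[0]
        if rbm.n_nongag_orfs
        else None,
        "by_set": orfmod.gag_rbm_by_set(all_orfs, ex_set),
    }
    domsum = orfmod.summarize_domains(candidates, all_orfs, ex_set)
    _fmt(domsum.per_rte, outdir / "domain_summary.tsv")
    _fmt(domsum.combinations, outdir / "domain_combinations.tsv")

    # ---- gene proximity ------------------------------------------------
    logger.info("stage proximity")
    genes = prox.parse_gene_gff(inputs.gene_gff)
    prox_df = prox.classify_all(candidates, genes, ex_set)
    _fmt(prox_df, outdir / "proximity.tsv")
    summary["proximity_counts"] = {
        group: {
            k: int(v)
            for k, v in prox_df[prox_df["set"] == group]["category"].value_counts().items()
        }
        for group in ("exRTE", "n-exRTE")
    }

    # ---- mobilome ------------------------------------------------------
    logger.info("stage mobilome")
    depth = pd.read_csv(inputs.cultivar_depth, sep="\t")
    ref_ids = depth[depth["feature_type"] == "ref_gene"]["feature_id"].tolist()
    depth_mat = depth.set_index("feature_id").drop(columns=["feature_type"])
    acm_ids = [rid for rid in ex_ids if rid in depth_mat.index]
    profiles_acm, cutoff, absent = mob.compute_acm_profiles(
        depth_mat,
        acm_ids,
        ref_ids,
        cutoff=config.acm_cutoff,
        group1_min=config.group1_min_cultivars,
    )
    acm_rows = [
        {
            "rte_id": rid,
            "group": p.group,
            "n_above_cutoff": p.n_above_cutoff,
            **{f"acm_{c}": v for c, v in p.acm.items()},
        }
        for rid, p in profiles_acm.items()
    ]
    _fmt(pd.DataFrame(acm_rows), outdir / "acm.tsv")
    if profiles_acm:
        mob.acm_log2_matrix(profiles_acm).to_csv(
            outdir / "acm_log2_matrix.tsv", sep="\t", float_format="%.8g"
        )
    groups = [p.group for p in profiles_acm.values()]
    summary["acm"] = {
        "cutoff": cutoff,
        "group1": groups.count("group1"),
        "group2": groups.count("group2"),
        "absent": absent,
    }

    # ---- enrichment statistics -----------------------------------------
    logger.info("stage stats")
    features = domsum.per_rte.merge(
        age_df[["rte_id", "recency"]], on="rte_id", how="left"
    ).merge(prox_df[["rte_id", "distance"]], on="rte_id", how="left")
    features["superfamily"] = [
        {r.id: r.superfamily for r in candidates}.get(rid) for rid in features["rte_id"]
    ]
    features["clade"] = [
        {r.id: r.clade for r in candidates}.get(rid) for rid in features["rte_id"]
    ]
    features["has_gag"] = ["GAG" in d.split(",") for d in features["domains"].fillna("")]
    gag_rbm_rtes = {o.rte_id for o in all_orfs if o.domain == "GAG" and o.rbm_count > 0}
    features["has_rbm_gag"] = [rid in gag_rbm_rtes for rid in features["rte_id"]]
    categorical = {
        "superfamily": "Ty1/Copia",
        "recency": "recent",
        "has_gag": "True",
        "full_length": "True",
        "has_rbm_gag": "True",
    }
    report = st.enrichment_report(
        features,
        categorical=categorical,
        continuous=["max_orf_nt", "n_orfs", "distance"],
    )
    _fmt(report, outdir / "enrichment.tsv")
    _fmt(features, outdir / "features.tsv")

    config.dump_yaml(outdir / "effective_config.yaml")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, default=str)
    logger.info("pipeline finished: %d exRTEs / %d n-exRTEs", len(ex_ids), len(nex_ids))
    return summary
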