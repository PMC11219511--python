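"""One-command synthetic reproduction of the whole analysis chain.

``run_synthetic`` drives genome -> digestion -> annotation -> methylome ->
reads -> counting -> filtering -> RPM -> summaries -> PCA/distances ->
differential methylation from a single config and seed, and returns a
truth-comparison report: exact motif-count recovery, exact read/count
round-trip, RPM conservation, and recovery of the planted differential
sites.
"""

from __future__ import annotations

import json
import os
from typing import Mapping

import numpy as np
import pandas as pd

from methylrad import annotation as annot_mod
from methylrad import io as io_mod
from methylrad import simulate as sim
from methylrad.diffmeth import DifferentialMethylation
from methylrad.digestion import extract_fragments, scan_motifs
from methylrad.multivariate import compare_distance_groups, detect_outliers, \
    epi_distances, mantel, pca
from methylrad.quantification import count_tags, filter_sites, \
    methylation_summary, rpm_normalize

__all__ = ["DEFAULT_CONFIG", "run_synthetic"]

DEFAULT_CONFIG: dict = {
    "genome_length": 130_000,
    "motif_counts": dict(sim.DEFAULT_MOTIF_COUNTS),
    "n_genes": 139,
    "genic_fraction": 0.6,
    "flank": 14,
    "baseline_occupancy": dict(sim.DEFAULT_OCCUPANCY),
    "n_diff_sites": 20,
    "log2fc": 2.0,
    "dispersion": 0.1,
    "mean_depth": 50.0,
    "library_size_sd": 0.3,
    "noise_rate": 0.02,
    "error_rate": 0.0,
    "diff_factor": "origin",
    "diff_level": "Spitsbergen",
    "mantel_noise_sd": 0.5,
    "mantel_permutations": 999,
}


def run_synthetic(
    config: Mapping | None = None,
    seed: int = 1,
    outdir: str | None = None,
) -> dict:
    """Run the full synthetic pipeline; return the truth-comparison report."""
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config or {})
    report: dict = {"seed": seed, "config": cfg}

    # --- genome and digestion -------------------------------------------
    genome, genome_truth = sim.simulate_genome(
        length=cfg["genome_length"],
        motif_counts=cfg["motif_counts"],
        seed=seed,
    )
    sites = scan_motifs(genome)
    found = {}
    for s in sites:
        found[s.motif.pattern] = found.get(s.motif.pattern, 0) + 1
    planted = {m: len(p) for m, p in genome_truth.planted_positions.items()}
    report["digestion"] = {
        "n_sites": len(sites),
        "per_motif": found,
        "n_cg": sum(1 for s in sites if s.context == "CG"),
        "n_chg": sum(1 for s in sites if s.context == "CHG"),
        "motif_recovery_exact": found == {m: n for m, n in planted.items() if n},
    }

    # --- annotation ------------------------------------------------------
    gene_annot = sim.simulate_annotation(
        genome, n_genes=cfg["n_genes"], seed=seed + 1,
        genic_fraction=cfg["genic_fraction"],
    )
    annotated = annot_mod.annotate_sites(sites, gene_annot)
    region_counts = pd.Series([a.region for a in annotated]).value_counts()
    report["annotation"] = {
        "n_genes": len(gene_annot),
        "regions": region_counts.to_dict(),
    }

    # --- methylome, reads, counting (round trip) ------------------------
    fragments = extract_fragments(genome, sites, flank=cfg["flank"],
                                  circular=True)
    design = sim.default_design()
    counts, meth_truth = sim.simulate_methylome(
        sites,
        design=design,
        baseline_occupancy=cfg["baseline_occupancy"],
        n_diff_sites=cfg["n_diff_sites"],
        log2fc=cfg["log2fc"],
        dispersion=cfg["dispersion"],
        mean_depth=cfg["mean_depth"],
        seed=seed + 2,
        diff_factor=cfg["diff_factor"],
        diff_level=cfg["diff_level"],
        library_size_sd=cfg["library_size_sd"],
        noise_rate=cfg["noise_rate"],
    )
    reads = sim.simulate_reads(fragments, counts,
                               error_rate=cfg["error_rate"], seed=seed + 3)
    recovered = count_tags(reads, fragments, metadata=design)
    round_trip_exact = recovered.counts.loc[counts.site_ids,
                                            counts.sample_ids].equals(counts.counts)
    report["counting"] = {
        "n_reads": int(sum(len(r) for r in reads.values())),
        "round_trip_exact": bool(round_trip_exact),
        "unmatched": int(recovered.discards["unmatched"].sum()),
        "ambiguous": int(recovered.discards["ambiguous"].sum()),
    }

    # --- filter, normalize, summarize ------------------------------------
    filtered = filter_sites(recovered)
    rpm = rpm_normalize(filtered)
    col_sums = rpm.values.sum(axis=0)
    n_potential = {"CG": report["digestion"]["n_cg"],
                   "CHG": report["digestion"]["n_chg"]}
    context_map = {s.site_id: s.context for s in sites}
    summary = methylation_summary(filtered, context_map, n_potential)
    report["quantification"] = {
        "n_sites_kept": len(filtered.site_ids),
        "rpm_column_sums_equal_1e6": bool(
            np.allclose(col_sums.to_numpy(), 1e6, rtol=1e-9)
        ),
        "methylation_levels": summary.group_mean_sd().to_dict("records"),
    }

    # --- multivariate -----------------------------------------------------
    ord_res = pca(rpm)
    outliers = detect_outliers(ord_res)
    dist_cult = epi_distances(ord_res, design.factor("cultivation"))
    dist_origin = epi_distances(ord_res, design.factor("origin"))
    report["multivariate"] = {
        "variance_explained_pc1_pc2": [
            round(float(v), 2) for v in ord_res.variance_explained[:2]
        ],
        "outliers": list(outliers.index),
        "cultivation_comparison": compare_distance_groups(dist_cult)
        .to_dict("records")[0],
        "origin_comparison": compare_distance_groups(dist_origin)
        .to_dict("records")[0],
    }

    # Mantel against an emulated second (nuclear) methylome distance matrix:
    # the chloroplast distances plus lognormal perturbation
    rng = np.random.default_rng(seed + 4)
    d1 = dist_origin.matrix
    noise = np.exp(rng.normal(0.0, cfg["mantel_noise_sd"], size=d1.shape))
    noise = (noise + noise.T) / 2
    d2 = d1 * noise
    np.fill_diagonal(d2.values, 0.0)
    mres = mantel(d1, d2, n_perm=cfg["mantel_permutations"], seed=seed + 5)
    report["mantel"] = {"r": round(mres.r, 4), "p": mres.p,
                        "n_perm": mres.n_perm}

    # --- differential methylation ----------------------------------------
    levels = list(pd.unique(design.factor(cfg["diff_factor"]).astype(str)))
    level2 = cfg["diff_level"]
    level1 = next(l for l in levels if l != level2)
    model = DifferentialMethylation(filtered, cfg["diff_factor"],
                                    level1, level2)
    results = model.fit()
    planted_sites = [s for s in meth_truth.diff_sites
                     if s in results.table.index]
    recovered_diff = [
        s for s in planted_sites if bool(results.table.loc[s, "significant"])
    ]
    power = len(recovered_diff) / len(planted_sites) if planted_sites else None
    false_pos = [
        s for s in results.significant_sites if s not in meth_truth.diff_sites
    ]
    report["diffmeth"] = {
        "contrast": f"{cfg['diff_factor']}: {level2} vs {level1}",
        "n_significant": results.n_significant,
        "n_planted": len(meth_truth.diff_sites),
        "n_planted_recovered": len(recovered_diff),
        "planted_recovery_rate": power,
        "n_other_significant": len(false_pos),
    }

    # --- outputs ----------------------------------------------------------
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        io_mod.write_fasta(genome, os.path.join(outdir, "genome.fasta"))
        io_mod.write_gff3(gene_annot, os.path.join(outdir, "genes.gff3"))
        io_mod.write_sites(annotated, os.path.join(outdir, "sites.tsv"),
                           fmt="tsv")
        io_mod.write_sites(sites, os.path.join(outdir, "sites.gff3"),
                           fmt="gff3", genome_id=genome.id)
        io_mod.write_count_table(recovered.counts,
                                 os.path.join(outdir, "counts.tsv"))
        io_mod.write_count_table(rpm.values,
                                 os.path.join(outdir, "rpm.tsv"))
        io_mod.write_metadata(design, os.path.join(outdir, "metadata.tsv"))
        results.to_tsv(os.path.join(outdir, "diffmeth.tsv"))
        meth_truth.to_json(os.path.join(outdir, "truth.json"))
        with open(os.path.join(outdir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=1, default=str)
    return report
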