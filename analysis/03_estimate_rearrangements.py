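"""Turn the simulated type counts into rearrangement-rate estimates,
cluster the type-3 clones into breakpoints, and score both against truth.

Also prints the worked arithmetic the estimators encode: double-hit
expectation at a 17% hit rate, breakpoint spacing at 1/3 discordance and
at a 5% intra ratio, the per-chromosome breakpoint/inversion counts, and
the expected paralog loss per chromosome.
"""
import json

from besmap.classify import read_classifications, tabulate_types
from besmap.rearrange import (
    breakpoint_spacing,
    breakpoints_per_chromosome,
    cluster_breakpoints,
    estimate_rearrangements,
    expected_double_hit_rate,
    expected_paralog_loss,
    genome_breakpoints,
    intra_ratio,
    match_clusters_to_truth,
    write_clusters_tsv,
    write_estimates_tsv,
)
from besmap.sim import simulate

from common import RESULTS, SCRATCH, ensure_dirs, survey_config


def main() -> None:
    ensure_dirs()
    cls_path = SCRATCH / "classifications.tsv"
    if not cls_path.exists():
        raise SystemExit("run 02_classify_clones.py first")
    classifications = read_classifications(cls_path)
    config = survey_config()
    truth = simulate(config).truth

    counts = tabulate_types(classifications, library="simulated", target="target")
    est = estimate_rearrangements(
        counts, insert=config.insert_mean,
        chrom_length=config.chrom_length,
        genome_size=config.n_chromosomes * config.chrom_length,
    )
    clusters = cluster_breakpoints(classifications, window=config.insert_mean,
                                   min_support=2)
    report = match_clusters_to_truth(clusters, truth, min_support=2)
    intra_edges = {i for i, b in enumerate(truth.breakpoints)
                   if b.kind == "inversion-edge"}
    true_spacing = (config.n_chromosomes * config.chrom_length
                    / max(1, len(truth.breakpoints)))

    write_estimates_tsv({("simulated", "target"): est}, RESULTS / "03_estimates.tsv")
    write_clusters_tsv(clusters, RESULTS / "03_breakpoint_clusters.tsv")
    recovery = {
        "true_breakpoints": len(truth.breakpoints),
        "true_inversion_edges": len(intra_edges),
        "clusters_min_support_2": len(clusters.clusters),
        "mean_cluster_support": clusters.mean_support,
        "edges_recovered": len(report.recovered & intra_edges),
        "spurious_clusters": len(report.spurious),
        "estimated_intra_spacing_bp": est.spacing_intra,
        "true_mean_spacing_bp": true_spacing,
    }
    (RESULTS / "03_recovery.json").write_text(json.dumps(recovery, indent=2) + "\n")

    r = intra_ratio(counts)
    print(f"intra ratio {r:.3f} -> spacing {est.spacing_intra / 1e6:.2f} Mb "
          f"(true mean spacing {true_spacing / 1e6:.2f} Mb)")
    print(f"-> {est.breakpoints_per_chrom:.1f} breakpoints "
          f"({est.inversions_per_chrom:.1f} inversions) per 48 Mb chromosome; "
          f"simulated truth: 16 edges (8 inversions) per chromosome")
    print(f"clusters (support >= 2): {len(clusters.clusters)}, "
          f"mean support {clusters.mean_support:.2f}; "
          f"recovered {recovery['edges_recovered']}/{len(intra_edges)} "
          f"inversion edges, {len(report.spurious)} spurious")
    print("worked arithmetic:")
    print(f"  0.17^2 double-hit expectation      = "
          f"{100 * expected_double_hit_rate(0.17):.2f}%")
    print(f"  spacing at discordance 1/3         = "
          f"{breakpoint_spacing(1 / 3, 150_000) / 1e3:.0f} kb")
    print(f"  spacing at intra ratio 0.05        = "
          f"{breakpoint_spacing(0.05, 150_000) / 1e6:.0f} Mb")
    print(f"  48 Mb chromosome at 3 Mb spacing   = "
          f"{breakpoints_per_chromosome(48e6, 3e6):.0f} breakpoints")
    print(f"  1 Gb genome at 450 kb spacing      = "
          f"{genome_breakpoints(1e9, 450e3):.0f} breakpoints")
    print(f"  1,250 genes/chromosome at 5% loss  = "
          f"{expected_paralog_loss(1250, 0.05):.1f} genes lost")


if __name__ == "__main__":
    main()
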