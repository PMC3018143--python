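"""Simulate the BAC-end survey: rearranged target genome, clone library,
alignment hits and ground truth.

Writes the true breakpoint table and a library summary under
results/analysis/, and the bulky hit table under scratch/analysis/ for the
downstream scripts.
"""
import json
from collections import Counter

from besmap.hits import write_tabular_hits
from besmap.rearrange import expected_double_hit_rate
from besmap.sim import simulate, write_chrom_sizes

from common import RESULTS, SCRATCH, ensure_dirs, survey_config


def main() -> None:
    ensure_dirs()
    config = survey_config()
    result = simulate(config)

    n_ends = 2 * config.n_clones
    n_hits = len(result.hits)
    types = Counter(result.truth.clone_truth.values())
    both = sum(v for t, v in types.items() if t >= 2)
    expected_both = expected_double_hit_rate(config.detect_prob)

    summary = {
        "n_clones": config.n_clones,
        "n_end_reads": n_ends,
        "n_hits": n_hits,
        "per_end_hit_rate": round(n_hits / n_ends, 4),
        "configured_detect_prob": config.detect_prob,
        "clones_with_both_ends_hit": both,
        "both_end_fraction": round(both / config.n_clones, 4),
        "expected_both_end_fraction": round(expected_both, 4),
        "true_breakpoints": len(result.breakpoints),
        "true_type_counts": {str(k): types[k] for k in sorted(types)},
    }

    result.truth.write_breakpoints(RESULTS / "01_truth_breakpoints.tsv")
    write_chrom_sizes(result.coord_map.target_lengths, RESULTS / "01_chrom_sizes.tsv")
    (RESULTS / "01_library_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    write_tabular_hits(result.hits, SCRATCH / "hits.tsv")

    print(f"simulated {config.n_clones} clones on a "
          f"{config.n_chromosomes} x {config.chrom_length / 1e6:.0f} Mb genome "
          f"with {len(result.breakpoints)} true breakpoints")
    print(f"per-end hit rate {summary['per_end_hit_rate']:.3f} "
          f"(configured {config.detect_prob})")
    print(f"both-end clones {both} ({100 * both / config.n_clones:.2f}%; "
          f"independent-detection expectation {100 * expected_both:.2f}%)")
    print(f"true type counts: {dict(sorted(types.items()))}")
    print(f"hit table -> {SCRATCH / 'hits.tsv'}")


if __name__ == "__main__":
    main()
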