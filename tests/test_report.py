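"""Summary tables, browser tracks, Circos links, score histograms, CLI."""
import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from besmap.classify import classify_clones, tabulate_types
from besmap.cli import main as cli_main
from besmap.errors import ValidationError
from besmap.hits import best_hit_per_end, filter_hits, pair_ends
from besmap.report import (
    read_chrom_sizes,
    score_distribution,
    summary_frame,
    write_circos_links,
    write_summary,
    write_tracks,
)
from besmap.sim import SimConfig, simulate, write_chrom_sizes

from _oracles import random_clone_records


@pytest.fixture(scope="module")
def pipeline(small_config_module=None):
    cfg = SimConfig(
        n_chromosomes=3, chrom_length=2_000_000,
        n_inversions=2, n_translocations=1,
        genes_per_chrom=100, gene_length=4_000,
        dup_fraction=0.5, loss_prob=0.3,
        n_clones=600, insert_mean=150_000, insert_sd=15_000,
        end_length=500, detect_prob=0.8, seed=13,
    )
    result = simulate(cfg)
    records, tally = pair_ends(best_hit_per_end(filter_hits(result.hits)))
    classifications = classify_clones(records)
    return result, classifications, tally


class TestSummary:
    def test_empty_counts_header_only(self, tmp_path):
        path = tmp_path / "summary.tsv"
        write_summary([], path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("library\ttarget")

    def test_combined_row_sums_and_self_consistency(self, pipeline, tmp_path):
        result, classifications, tally = pipeline
        half = len(classifications) // 2
        a = tabulate_types(classifications[:half], library="A", target="T")
        b = tabulate_types(classifications[half:], library="B", target="T")
        path = tmp_path / "summary.tsv"
        write_summary([a, b], path)
        frame = pd.read_csv(path, sep="\t")
        combined = frame[frame.library == "Combined"].iloc[0]
        for col in ("type1", "type2", "type3", "type4"):
            assert combined[col] == frame[frame.library != "Combined"][col].sum()
        # ratio columns re-derivable from the count columns of the same file
        for _, row in frame.iterrows():
            n2, n3, n4 = row.type2, row.type3, row.type4
            assert row.ratio_3_23 == pytest.approx(n3 / (n2 + n3), abs=5e-4)
            assert row.ratio_34_234 == pytest.approx(
                (n3 + n4) / (n2 + n3 + n4), abs=5e-4
            )

    def test_ratio_formatting_three_decimals(self):
        from besmap.classify import TypeCounts

        counts = TypeCounts(library="L", target="T", n1=0, n2=1355, n3=94, n4=850)
        frame = summary_frame([counts], add_combined=False)
        assert frame.ratio_3_23.iloc[0] == "0.065"


class TestTracks:
    def test_every_placement_written_once(self, pipeline, tmp_path):
        result, classifications, _ = pipeline
        paths = write_tracks(classifications, result.coord_map.target_lengths,
                             tmp_path / "tracks")
        total_lines = sum(
            len(p.read_text().splitlines()) for p in paths.values()
        )
        total_placements = sum(len(c.placements) for c in classifications)
        assert total_lines == total_placements

    def test_type2_clone_yields_two_bed_lines(self, tmp_path):
        cls = classify_clones(
            [r for r in random_clone_records(np.random.default_rng(1), 50)]
        )
        two = [c for c in cls if c.synteny_type == 2][:1]
        assert two
        paths = write_tracks(two, {"chr1": 10**7, "chr2": 10**7, "chr3": 10**7},
                             tmp_path)
        assert len(paths[2].read_text().splitlines()) == 2

    def test_record_at_chromosome_end_clipped(self, tmp_path):
        cls = classify_clones(random_clone_records(np.random.default_rng(2), 30))
        one = [c for c in cls if c.synteny_type == 1][:1]
        assert one
        placement = one[0].placement_a
        sizes = {c: placement.end - 100 for c in ("chr1", "chr2", "chr3")}
        if placement.start >= sizes[placement.target_chrom]:
            pytest.skip("random record starts beyond truncated chromosome")
        paths = write_tracks(one, sizes, tmp_path)
        line = paths[one[0].synteny_type].read_text().splitlines()[0]
        assert int(line.split("\t")[2]) == sizes[placement.target_chrom]

    def test_placement_beyond_chromosome_raises(self, tmp_path):
        cls = classify_clones(random_clone_records(np.random.default_rng(3), 5))
        with pytest.raises(ValidationError, match=cls[0].clone_id):
            write_tracks(cls[:1], {c: 10 for c in ("chr1", "chr2", "chr3")},
                         tmp_path)


class TestCircos:
    def test_one_link_per_requested_clone(self, pipeline, tmp_path):
        _, classifications, _ = pipeline
        path = tmp_path / "links.txt"
        n = write_circos_links(classifications, path, types=(3,))
        n3 = sum(1 for c in classifications if c.synteny_type == 3)
        assert n == n3
        assert len(path.read_text().splitlines()) == n3

    def test_link_endpoints_match_classifications(self, pipeline, tmp_path):
        _, classifications, _ = pipeline
        path = tmp_path / "links.txt"
        write_circos_links(classifications, path, types=(4,))
        wanted = {
            c.clone_id: c for c in classifications if c.synteny_type == 4
        }
        for line in path.read_text().splitlines():
            fields = line.split()
            cid = fields[6].removeprefix("id=")
            c = wanted[cid]
            assert fields[0] == c.placement_a.target_chrom
            assert int(fields[1]) == c.placement_a.start
            assert fields[3] == c.placement_b.target_chrom

    def test_empty_input_empty_file(self, tmp_path):
        path = tmp_path / "links.txt"
        assert write_circos_links([], path) == 0
        assert path.read_text() == ""


class TestScoreDistribution:
    def test_single_value_single_bin(self):
        cls = classify_clones(random_clone_records(np.random.default_rng(4), 1))
        hist = score_distribution(cls)
        assert hist.to_numpy().sum() == len(cls[0].placements)

    def test_bins_conserve_placements(self, pipeline):
        _, classifications, _ = pipeline
        hist = score_distribution(classifications)
        assert hist.to_numpy().sum() == sum(
            len(c.placements) for c in classifications
        )

    def test_paralog_driven_type4_scores_worse_than_type2(self, pipeline):
        _, classifications, _ = pipeline
        hist = score_distribution(classifications)
        exponents = hist.index.to_numpy()

        def mean_exponent(col):
            w = hist[col].to_numpy()
            return (exponents * w).sum() / w.sum()

        # higher (less negative) e-value exponent == weaker hit
        assert mean_exponent("type4") > mean_exponent("type2")


class TestCli:
    def test_full_pipeline_runs_and_is_seeded(self, tmp_path):
        runner = CliRunner()
        simdir = tmp_path / "sim"
        args = [
            "simulate", "--seed", "3", "--n-chromosomes", "3",
            "--chrom-length", "2000000", "--n-inversions", "2",
            "--n-translocations", "0", "--genes-per-chrom", "50",
            "--gene-length", "2000", "--dup-fraction", "0.3",
            "--loss-prob", "0.1", "--n-clones", "300",
            "--detect-prob", "0.6", "--write-fasta",
            "--out-dir", str(simdir),
        ]
        assert runner.invoke(cli_main, args).exit_code == 0
        assert (simdir / "hits.tsv").exists()

        clsdir = tmp_path / "cls"
        res = runner.invoke(cli_main, [
            "classify", "--hits", str(simdir / "hits.tsv"),
            "--end-ids", str(simdir / "ends.fasta"),
            "--out-dir", str(clsdir),
        ])
        assert res.exit_code == 0, res.output

        estdir = tmp_path / "est"
        res = runner.invoke(cli_main, [
            "estimate", "--classifications", str(clsdir / "classifications.tsv"),
            "--out-dir", str(estdir),
        ])
        assert res.exit_code == 0, res.output
        assert (estdir / "estimates.json").exists()

        repdir = tmp_path / "rep"
        res = runner.invoke(cli_main, [
            "report", "--classifications", str(clsdir / "classifications.tsv"),
            "--chrom-sizes", str(simdir / "chrom_sizes.tsv"),
            "--out-dir", str(repdir),
        ])
        assert res.exit_code == 0, res.output
        assert (repdir / "circos_links.txt").exists()

        anndir = tmp_path / "ann"
        res = runner.invoke(cli_main, [
            "annotate", "--fasta", str(simdir / "ends.fasta"),
            "--out-dir", str(anndir),
        ])
        assert res.exit_code == 0, res.output
        assert (anndir / "microsatellites.gff3").exists()

    def test_missing_input_is_usage_error(self):
        runner = CliRunner()
        res = runner.invoke(cli_main, ["classify", "--hits", "/nonexistent.tsv",
                                       "--out-dir", "/tmp/x"])
        assert res.exit_code == 2


def test_chrom_sizes_roundtrip(tmp_path):
    sizes = {"chr1": 123, "chr2": 456}
    path = tmp_path / "sizes.tsv"
    write_chrom_sizes(sizes, path)
    assert read_chrom_sizes(path) == sizes
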