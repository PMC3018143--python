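"""Simulator: genome construction, rearrangement maps, paralogs, library
sampling, hit emission and the reproducibility contract."""
import numpy as np
import pytest

from besmap.errors import ConfigurationError
from besmap.sim import (
    CoordinateMap,
    SimConfig,
    apply_paralog_model,
    apply_rearrangements,
    build_genome,
    clone_ends,
    emit_truth_hits,
    sample_bac_library,
    simulate,
    write_end_fasta,
)


class TestBuildGenome:
    def test_empty_gene_case(self):
        cfg = SimConfig(n_chromosomes=1, genes_per_chrom=0, dup_fraction=0.0)
        genome = build_genome(cfg)
        assert genome.names == ["chr1"]
        assert len(genome.genes["chr1"]) == 0

    def test_total_genome_size(self):
        cfg = SimConfig(n_chromosomes=20, chrom_length=48_000_000, genes_per_chrom=0)
        assert build_genome(cfg).total_length == 960_000_000

    def test_gene_intervals_do_not_overlap(self):
        cfg = SimConfig(n_chromosomes=2, genes_per_chrom=1250, seed=3)
        genome = build_genome(cfg)
        n = 0
        for arr in genome.genes.values():
            n += len(arr)
            # sorted starts with at least one gene length between them
            assert (np.diff(arr[:, 0]) >= cfg.gene_length).all()
            assert arr[0, 0] >= 0 and arr[-1, 1] <= cfg.chrom_length
        assert n == 2500

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(genes_per_chrom=100, gene_length=1_000_000),  # genes don't fit
            dict(insert_mean=1_000, end_length=600),           # insert too short
            dict(chrom_length=100_000, insert_mean=150_000, genes_per_chrom=0),
            dict(detect_prob=1.5),
            dict(n_chromosomes=1, dup_fraction=0.5),           # no "other" chromosome
        ],
    )
    def test_invalid_configurations_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimConfig(**kwargs).validate()


class TestRearrangements:
    def test_no_rearrangements_is_identity(self, rng):
        genome = build_genome(SimConfig(n_chromosomes=2, genes_per_chrom=0))
        cmap, bps = apply_rearrangements(genome, 0, 0, rng)
        assert bps == []
        for pos in (0, 1, 47_999_999, 1_234_567):
            assert cmap.map_position("chr2", pos) == ("chr2", pos, 1)

    def test_single_inversion_flips_interior(self, rng):
        genome = build_genome(
            SimConfig(n_chromosomes=1, chrom_length=5_000_000, genes_per_chrom=0,
                      dup_fraction=0.0)
        )
        cmap, bps = apply_rearrangements(genome, 1, 0, rng, min_separation=150_000)
        assert len(bps) == 2 and all(b.kind == "inversion-edge" for b in bps)
        a, b = sorted(bp.pos for bp in bps)
        inside = (a + b) // 2
        assert cmap.map_position("chr1", inside)[2] == -1
        assert cmap.map_position("chr1", a - 1) == ("chr1", a - 1, 1)
        assert cmap.map_position("chr1", b + 1) == ("chr1", b + 1, 1)
        # interior positions are mirrored around the inverted block
        assert cmap.map_position("chr1", a)[1] == b - 1

    def test_breakpoint_count_and_separation(self, small_config, rng):
        genome = build_genome(small_config)
        cmap, bps = apply_rearrangements(
            genome, 3, 2, rng, min_separation=small_config.insert_mean
        )
        assert len(bps) == 2 * 3 + 2 * 2
        by_chrom = {}
        for bp in bps:
            by_chrom.setdefault(bp.chrom, []).append(bp.pos)
        for positions in by_chrom.values():
            positions.sort()
            assert all(
                q - p >= small_config.insert_mean
                for p, q in zip(positions, positions[1:])
            )

    def test_roundtrip_map_inverse(self, small_config, rng):
        genome = build_genome(small_config)
        cmap, _ = apply_rearrangements(genome, 2, 1, rng, min_separation=150_000)
        pos_rng = np.random.default_rng(0)
        for _ in range(1000):
            chrom = genome.names[int(pos_rng.integers(len(genome.names)))]
            pos = int(pos_rng.integers(genome.lengths[chrom]))
            t_chrom, t_pos, _ = cmap.map_position(chrom, pos)
            assert cmap.inverse_position(t_chrom, t_pos)[:2] == (chrom, pos)

    def test_translocation_conserves_total_length(self, rng):
        genome = build_genome(
            SimConfig(n_chromosomes=3, chrom_length=2_000_000, genes_per_chrom=0,
                      dup_fraction=0.0)
        )
        cmap, bps = apply_rearrangements(genome, 0, 2, rng, min_separation=100_000)
        assert sum(b.kind == "translocation-edge" for b in bps) == 4
        assert sum(cmap.target_lengths.values()) == genome.total_length

    def test_impossible_separation_raises(self, rng):
        genome = build_genome(
            SimConfig(n_chromosomes=1, chrom_length=400_000, genes_per_chrom=0,
                      dup_fraction=0.0, insert_mean=160_000)
        )
        with pytest.raises(ConfigurationError):
            apply_rearrangements(genome, 5, 0, rng, min_separation=160_000)


class TestParalogModel:
    def test_zero_duplication_gives_empty_map(self, rng):
        genome = build_genome(SimConfig(n_chromosomes=2, genes_per_chrom=100))
        assert apply_paralog_model(genome, 0.0, 0.5, rng) == {}

    def test_loss_count_within_binomial_bound(self, rng):
        # 10,000 duplicated genes at d = 0.05: 3 SD of Binomial(10000, 0.05)
        cfg = SimConfig(n_chromosomes=4, chrom_length=48_000_000,
                        genes_per_chrom=2500, seed=2)
        genome = build_genome(cfg)
        pmap = apply_paralog_model(genome, 1.0, 0.05, rng)
        assert len(pmap) == 10_000
        lost = sum(r.syntenic_lost for r in pmap.values())
        sd = np.sqrt(10_000 * 0.05 * 0.95)
        assert abs(lost - 500) <= 3 * sd

    def test_paralog_lands_on_other_chromosome(self, rng):
        genome = build_genome(
            SimConfig(n_chromosomes=3, chrom_length=2_000_000, genes_per_chrom=30,
                      gene_length=2_000)
        )
        pmap = apply_paralog_model(genome, 1.0, 0.1, rng)
        assert all(r.par_chrom != r.syn_chrom for r in pmap.values())


class TestLibrary:
    def test_insert_sd_zero_gives_exact_spans(self, rng):
        cfg = SimConfig(n_chromosomes=2, chrom_length=2_000_000, genes_per_chrom=0,
                        dup_fraction=0.0, n_clones=50, insert_sd=0)
        clones = sample_bac_library(build_genome(cfg), cfg, rng)
        assert all(c.insert == cfg.insert_mean for c in clones)

    def test_end_reads_inside_clone_span(self, small_config, rng):
        genome = build_genome(small_config)
        clones = sample_bac_library(genome, small_config, rng)
        for c in clones:
            assert 0 <= c.start < c.end <= genome.lengths[c.chrom]
            for _label, s, e, _o in clone_ends(c, small_config.end_length):
                assert c.start <= s < e <= c.end

    def test_library_scale_matches_survey(self, rng):
        # 73,728 clones x 150 kb inserts -> ~11.06 Gbp of cloned DNA
        cfg = SimConfig(genes_per_chrom=0, dup_fraction=0.0, seed=9)
        clones = sample_bac_library(build_genome(cfg), cfg, rng)
        total = sum(c.insert for c in clones)
        assert total == pytest.approx(73_728 * 150_000, rel=0.005)


class TestHitEmission:
    def test_p_zero_emits_nothing(self, null_config, rng):
        genome = build_genome(null_config)
        clones = sample_bac_library(genome, null_config, rng)
        cmap = CoordinateMap.identity(genome.lengths)
        hits, truth = emit_truth_hits(clones, cmap, {}, 0.0, rng, end_length=500)
        assert hits == [] and truth.clone_truth == {}

    def test_null_model_all_type2(self, null_config):
        result = simulate(null_config)
        assert len(result.hits) == 2 * null_config.n_clones
        assert set(result.truth.clone_truth.values()) == {2}

    def test_truth_covers_exactly_detected_clones(self, small_config):
        result = simulate(small_config)
        detected = {h.query_id.rsplit(".", 1)[0] for h in result.hits}
        assert set(result.truth.clone_truth) == detected
        library_ids = {c.clone_id for c in result.clones}
        assert set(result.truth.clone_truth) <= library_ids

    def test_same_seed_byte_identical_outputs(self, small_config, tmp_path):
        r1 = simulate(small_config)
        r2 = simulate(small_config)
        assert r1.hits == r2.hits
        assert r1.truth.clone_truth == r2.truth.clone_truth
        for name in ("a.fasta", "b.fasta"):
            write_end_fasta(
                r1.clones[:20], small_config.end_length, tmp_path / name,
                np.random.default_rng(99),
            )
        assert (tmp_path / "a.fasta").read_bytes() == (tmp_path / "b.fasta").read_bytes()

    def test_redirected_ends_score_lower(self):
        """Paralog-redirected hits carry systematically lower bit scores, the
        signature separating paralog pickup from orthologous placement."""
        cfg = SimConfig(
            n_chromosomes=3, chrom_length=2_000_000,
            n_inversions=0, n_translocations=0,
            genes_per_chrom=200, gene_length=5_000,
            dup_fraction=1.0, loss_prob=0.5,
            n_clones=300, insert_mean=150_000, insert_sd=10_000,
            end_length=500, detect_prob=1.0, seed=8,
        )
        result = simulate(cfg)
        type4 = {cid for cid, t in result.truth.clone_truth.items() if t == 4}
        type2 = {cid for cid, t in result.truth.clone_truth.items() if t == 2}
        assert type4 and type2
        bits4 = [h.bit_score for h in result.hits
                 if h.query_id.rsplit(".", 1)[0] in type4]
        bits2 = [h.bit_score for h in result.hits
                 if h.query_id.rsplit(".", 1)[0] in type2]
        assert np.mean(bits4) < np.mean(bits2)
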