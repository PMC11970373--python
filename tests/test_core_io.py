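import numpy as np
import pytest

from k9diff import (
    BinnedTrack,
    GenomeModel,
    PromoterConfig,
    Region,
    extract_promoters,
    read_bed,
    read_bedgraph,
    read_chrom_sizes,
    read_repeat_bed,
    write_bed,
    write_bedgraph,
    write_repeat_bed,
)


class TestChromSizes:
    def test_parses_in_file_order(self, tmp_path):
        p = tmp_path / "g.sizes"
        p.write_text("chrA\t10000\nchrB\t5000\n")
        g = read_chrom_sizes(p)
        assert g.names == ["chrA", "chrB"]
        assert g.length("chrA") == 10000 and g.length("chrB") == 5000

    @pytest.mark.parametrize("content,err", [
        ("chrA\t10000\nchrA\t9000\n", "duplicate"),
        ("chrA\t0\n", "positive"),
        ("chrA\t-5\n", "positive"),
        ("chrA\tten\n", "non-integer"),
        ("", "empty"),
    ])
    def test_rejects_malformed(self, tmp_path, content, err):
        p = tmp_path / "bad.sizes"
        p.write_text(content)
        with pytest.raises(ValueError, match=err):
            read_chrom_sizes(p)


class TestBedGraph:
    def test_multi_bin_line_expands_and_zero_fills(self, tmp_path):
        g = GenomeModel([("chrA", 600)])
        p = tmp_path / "t.bedgraph"
        p.write_text("chrA\t0\t400\t3.0\n")
        track = read_bedgraph(p, g, 200)
        assert list(track.values["chrA"]) == [3.0, 3.0, 0.0]

    def test_off_grid_interval_rejected(self, tmp_path, genome):
        p = tmp_path / "t.bedgraph"
        p.write_text("chrA\t100\t300\t1.0\n")
        with pytest.raises(ValueError, match="off the 200-bp"):
            read_bedgraph(p, genome, 200)

    def test_beyond_chromosome_end_rejected(self, tmp_path, genome):
        p = tmp_path / "t.bedgraph"
        p.write_text("chrB\t4800\t5200\t1.0\n")
        with pytest.raises(ValueError, match="beyond"):
            read_bedgraph(p, genome, 200)

    def test_unknown_chromosome_rejected(self, tmp_path, genome):
        p = tmp_path / "t.bedgraph"
        p.write_text("chrZ\t0\t200\t1.0\n")
        with pytest.raises(ValueError, match="unknown"):
            read_bedgraph(p, genome, 200)

    def test_empty_file_gives_all_zero_track(self, tmp_path, genome):
        p = tmp_path / "t.bedgraph"
        p.write_text("")
        track = read_bedgraph(p, genome, 200)
        assert not track.flatten().any()

    def test_truncated_last_bin_is_on_grid(self, tmp_path):
        g = GenomeModel([("chrA", 500)])
        p = tmp_path / "t.bedgraph"
        p.write_text("chrA\t400\t500\t2\n")
        track = read_bedgraph(p, g, 200)
        assert list(track.values["chrA"]) == [0.0, 0.0, 2.0]

    def test_merge_equal_run_length_encodes(self, tmp_path):
        g = GenomeModel([("chrA", 600)])
        track = BinnedTrack(g, 200, {"chrA": np.array([3.0, 3.0, 0.0])})
        p = tmp_path / "out.bedgraph"
        write_bedgraph(track, p, merge_equal=True)
        assert p.read_text() == "chrA\t0\t400\t3\nchrA\t400\t600\t0\n"

    def test_unmerged_writes_one_line_per_bin(self, tmp_path):
        g = GenomeModel([("chrA", 400)])
        track = BinnedTrack(g, 200, {"chrA": np.array([1.0, 2.0])})
        p = tmp_path / "out.bedgraph"
        write_bedgraph(track, p, merge_equal=False)
        assert p.read_text() == "chrA\t0\t200\t1\nchrA\t200\t400\t2\n"

    @pytest.mark.parametrize("merge", [True, False])
    def test_round_trip_random_track(self, tmp_path, genome, rng, merge):
        values = {c: np.round(rng.normal(size=genome.length(c) // 200 +
                                         (genome.length(c) % 200 > 0)), 6)
                  for c in genome.names}
        track = BinnedTrack(genome, 200, values)
        p = tmp_path / "rt.bedgraph"
        write_bedgraph(track, p, merge_equal=merge)
        assert read_bedgraph(p, genome, 200) == track


class TestBed:
    def test_read_basic(self, tmp_path, genome):
        p = tmp_path / "r.bed"
        p.write_text("chrA\t0\t200\tp1\n")
        (r,) = read_bed(p, genome)
        assert r == Region("chrA", 0, 200, name="p1")

    def test_empty_interval_rejected(self, tmp_path, genome):
        p = tmp_path / "r.bed"
        p.write_text("chrA\t200\t200\n")
        with pytest.raises(ValueError):
            read_bed(p, genome)

    def test_unknown_chrom_rejected(self, tmp_path, genome):
        p = tmp_path / "r.bed"
        p.write_text("chrQ\t0\t200\n")
        with pytest.raises(ValueError, match="unknown"):
            read_bed(p, genome)

    def test_round_trip_preserves_optional_columns(self, tmp_path, genome, rng):
        regions = []
        for i in range(50):
            start = int(rng.integers(0, 9000))
            end = start + int(rng.integers(1, 1000))
            regions.append(Region("chrA", start, min(end, 10000),
                                  name=f"r{i}", score=float(i),
                                  strand=["+", "-", None][i % 3]))
        p = tmp_path / "rt.bed"
        write_bed(regions, p)
        assert read_bed(p, genome) == regions


class TestRepeatBed:
    def test_slash_dialect_splits_class_and_subfamily(self, tmp_path, genome):
        p = tmp_path / "rm.bed"
        p.write_text("chrA\t0\t300\tAluY\t.\t+\tSINE/Alu\n"
                     "chrA\t400\t600\tSAR\t.\t-\tSatellite\n")
        a, b = read_repeat_bed(p, genome, dialect="slash")
        assert (a.repeat_class, a.repeat_subfamily) == ("SINE", "Alu")
        # a bare class string means subfamily defaults to the class
        assert (b.repeat_class, b.repeat_subfamily) == ("Satellite", "Satellite")

    def test_columns_dialect(self, tmp_path, genome):
        p = tmp_path / "rm.bed"
        p.write_text("chrA\t0\t300\tAluY\t.\t+\tSINE\tAlu\n")
        (e,) = read_repeat_bed(p, genome, dialect="columns")
        assert (e.repeat_name, e.repeat_class, e.repeat_subfamily) == ("AluY", "SINE", "Alu")

    def test_uncertain_class_kept_verbatim(self, tmp_path, genome):
        p = tmp_path / "rm.bed"
        p.write_text("chrA\t0\t300\tX1\t.\t+\tDNA?/hAT?\n")
        (e,) = read_repeat_bed(p, genome, dialect="slash")
        assert e.repeat_class == "DNA?" and e.repeat_subfamily == "hAT?"

    def test_missing_class_column_rejected(self, tmp_path, genome):
        p = tmp_path / "rm.bed"
        p.write_text("chrA\t0\t300\tAluY\n")
        with pytest.raises(ValueError, match="class"):
            read_repeat_bed(p, genome, dialect="slash")

    def test_round_trip_columns_dialect(self, tmp_path, genome):
        p = tmp_path / "rm.bed"
        p.write_text("chrA\t0\t300\tAluY\t.\t+\tSINE\tAlu\n"
                     "chrB\t100\t900\tMLT1A\t.\t-\tLTR\tERVL-MalR\n")
        elements = read_repeat_bed(p, genome, dialect="columns")
        q = tmp_path / "rt.bed"
        write_repeat_bed(elements, q)
        assert read_repeat_bed(q, genome, dialect="columns") == elements


class TestPromoters:
    CFG = PromoterConfig(flank=1000)

    def test_plus_strand_tss_is_start(self, genome):
        gene = Region("chrA", 5000, 8000, strand="+")
        (p,) = extract_promoters([gene], self.CFG, genome)
        assert (p.start, p.end) == (4000, 6000)

    def test_minus_strand_tss_is_end(self, genome):
        gene = Region("chrA", 5000, 8000, strand="-")
        (p,) = extract_promoters([gene], self.CFG, genome)
        assert (p.start, p.end) == (7000, 9000)

    def test_exact_duplicates_removed(self, genome):
        genes = [Region("chrA", 5000, 8000, name="g1", strand="+"),
                 Region("chrA", 5000, 7000, name="g2", strand="+")]
        assert len(extract_promoters(genes, self.CFG, genome)) == 1

    def test_clipping_at_chromosome_bounds(self, genome):
        start_gene = Region("chrA", 300, 2000, strand="+")
        end_gene = Region("chrB", 1000, 4800, strand="-")
        ps = extract_promoters([start_gene, end_gene], self.CFG, genome)
        assert (ps[0].start, ps[0].end) == (0, 1300)
        assert (ps[1].start, ps[1].end) == (3800, 5000)

    def test_unstranded_gene_rejected(self, genome):
        with pytest.raises(ValueError, match="strand"):
            extract_promoters([Region("chrA", 0, 100)], self.CFG, genome)

    def test_output_sorted_by_genome_order(self, genome):
        genes = [Region("chrB", 2000, 3000, strand="+"),
                 Region("chrA", 9000, 9500, strand="+"),
                 Region("chrA", 2000, 3000, strand="+")]
        ps = extract_promoters(genes, self.CFG, genome)
        assert [(p.chrom, p.start) for p in ps] == [
            ("chrA", 1000), ("chrA", 8000), ("chrB", 1000)]
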