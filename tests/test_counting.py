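import numpy as np
import pandas as pd
import pytest

from trasplice import DataError, GeneModel, count_reads, derive_introns, rpkm
from trasplice.counting import read_bed, read_gtf, write_bed, write_gtf


def bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


class TestGeneModel:
    @pytest.mark.parametrize(
        "exons, introns",
        [
            ([(100, 200), (300, 400)], [(200, 300)]),
            ([(0, 50)], []),
            ([(0, 10), (10, 20)], []),  # abutting exons merge, zero-length gap
            ([(0, 10), (20, 30), (40, 50)], [(10, 20), (30, 40)]),
        ],
    )
    def test_derive_introns(self, exons, introns):
        m = GeneModel.from_exons("g", "chr1", exons)
        assert derive_introns(m) == introns

    def test_lengths(self):
        m = GeneModel.from_exons("g", "chr1", [(100, 200), (300, 400)])
        assert m.exonic_length == 200
        assert m.intronic_length == 100
        single = GeneModel.from_exons("s", "chr1", [(0, 500)])
        assert single.intronic_length == 0

    def test_overlapping_exons_merged(self):
        m = GeneModel.from_exons("g", "chr1", [(0, 30), (20, 50)])
        assert m.exons == ((0, 50),)

    def test_malformed_interval(self):
        with pytest.raises(DataError):
            GeneModel.from_exons("g", "chr1", [(100, 100)])


class TestCountReads:
    @pytest.fixture
    def gene(self):
        return GeneModel.from_exons("gA", "chr1", [(100, 200), (300, 400)])

    def test_assignment_rules(self, gene):
        reads = bed(
            [
                ("chr1", 150, 180),  # inside exon
                ("chr1", 250, 270),  # inside intron
                ("chr1", 190, 210),  # spans exon/intron boundary -> intron
                ("chr1", 500, 550),  # intergenic
                ("chr1", 90, 120),  # hangs off the gene start, touches no intron
            ]
        )
        counts = count_reads({"s1": reads}, [gene])
        assert counts.exon.at["gA", "s1"] == 1
        assert counts.intron.at["gA", "s1"] == 2
        summary = counts.assignment_summary.loc["s1"]
        assert summary["intergenic"] == 1
        assert summary["unassigned_edge"] == 1
        assert summary["ambiguous"] == 0

    def test_ambiguous_read_discarded(self, gene):
        other = GeneModel.from_exons("gB", "chr1", [(380, 450)])  # overlaps gA's last exon
        reads = bed([("chr1", 390, 410)])
        counts = count_reads({"s1": reads}, [gene, other])
        assert counts.total()["s1"].sum() == 0
        assert counts.assignment_summary.loc["s1", "ambiguous"] == 1

    def test_invalid_bed_rejected(self, gene):
        with pytest.raises(DataError, match="line 1"):
            count_reads({"s1": bed([("chr1", 200, 150)])}, [gene])


def brute_force_count(reads_by_sample, models):
    """Per-read, per-base overlap oracle implementing the same convention."""
    exon_bases = {}
    intron_bases = {}
    span = {}
    for m in models:
        exon_bases[m.gene_id] = set(b for s, e in m.exons for b in range(s, e))
        intron_bases[m.gene_id] = set(b for s, e in m.introns for b in range(s, e))
        span[m.gene_id] = (m.chrom, m.start, m.end)
    out = {}
    for sample, reads in reads_by_sample.items():
        exon = {m.gene_id: 0 for m in models}
        intron = {m.gene_id: 0 for m in models}
        tallies = {"ambiguous": 0, "intergenic": 0, "unassigned_edge": 0}
        for _, r in reads.iterrows():
            bases = set(range(r["start"], r["end"]))
            hits = [
                g for g, (chrom, s, e) in span.items()
                if chrom == r["chrom"] and bases & set(range(s, e))
            ]
            if not hits:
                tallies["intergenic"] += 1
            elif len(hits) > 1:
                tallies["ambiguous"] += 1
            elif bases & intron_bases[hits[0]]:
                intron[hits[0]] += 1
            elif bases <= exon_bases[hits[0]]:
                exon[hits[0]] += 1
            else:
                tallies["unassigned_edge"] += 1
        out[sample] = (exon, intron, tallies)
    return out


def random_instance(rng):
    models = []
    cursor = 0
    for i in range(rng.integers(3, 50)):
        cursor += rng.integers(0, 60)  # small gaps; genes may nearly touch
        exons = []
        for _ in range(rng.integers(1, 4)):
            length = int(rng.integers(5, 40))
            exons.append((cursor, cursor + length))
            cursor += length + int(rng.integers(5, 40))
        models.append(GeneModel.from_exons(f"g{i}", "chr1", exons))
    hi = cursor + 50
    n_reads = int(rng.integers(50, 2000))
    starts = rng.integers(0, hi, size=n_reads)
    lengths = rng.integers(1, 30, size=n_reads)
    reads = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + lengths})
    return models, {"s1": reads}


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_count_reads_matches_per_base_oracle(seed):
    rng = np.random.default_rng(seed)
    models, reads = random_instance(rng)
    counts = count_reads(reads, models)
    oracle = brute_force_count(reads, models)
    exon, intron, tallies = oracle["s1"]
    for m in models:
        assert counts.exon.at[m.gene_id, "s1"] == exon[m.gene_id]
        assert counts.intron.at[m.gene_id, "s1"] == intron[m.gene_id]
    summary = counts.assignment_summary.loc["s1"]
    for k, v in tallies.items():
        assert summary[k] == v
    # conservation: every input read lands in exactly one class
    assert (
        summary["exon"] + summary["intron"] + summary["ambiguous"]
        + summary["intergenic"] + summary["unassigned_edge"]
    ) == len(reads["s1"])


class TestRpkm:
    def make_counts(self, exon, intron, exonic_length):
        genes = [f"g{i}" for i in range(len(exonic_length))]
        from trasplice import FeatureCountMatrix

        return FeatureCountMatrix(
            exon=pd.DataFrame(exon, index=genes),
            intron=pd.DataFrame(intron, index=genes),
            exonic_length=pd.Series(exonic_length, index=genes),
            intronic_length=pd.Series([0] * len(genes), index=genes),
        )

    def test_closed_forms(self):
        # library sizes are summed over exon+intron of all genes
        counts = self.make_counts(
            exon={"s1": [10, 1_000_000 - 10]},
            intron={"s1": [0, 0]},
            exonic_length=[1000, 10],
        )
        expr = rpkm(counts)
        assert expr.library_size["s1"] == 1e6
        assert expr.rpkm.at["g0", "s1"] == pytest.approx(10.0)

        counts = self.make_counts(
            exon={"s1": [25, 2_000_000 - 25]},
            intron={"s1": [0, 0]},
            exonic_length=[500, 10],
        )
        assert rpkm(counts).rpkm.at["g0", "s1"] == pytest.approx(25.0)

    def test_zero_count_zero_rpkm(self):
        counts = self.make_counts(exon={"s1": [0, 5]}, intron={"s1": [0, 5]}, exonic_length=[100, 100])
        expr = rpkm(counts)
        assert expr.rpkm.at["g0", "s1"] == 0.0
        assert (expr.rpkm.to_numpy() == 0).sum() == 1  # rpkm == 0 iff exon count == 0

    def test_relabeling_invariance(self, simulated):
        *_, counts = simulated
        expr = rpkm(counts)
        from trasplice import FeatureCountMatrix

        perm = np.random.default_rng(3).permutation(len(counts.gene_ids))
        shuffled = FeatureCountMatrix(
            exon=counts.exon.iloc[perm],
            intron=counts.intron.iloc[perm],
            exonic_length=counts.exonic_length.iloc[perm],
            intronic_length=counts.intronic_length.iloc[perm],
        )
        expr2 = rpkm(shuffled)
        pd.testing.assert_frame_equal(expr2.rpkm.sort_index(), expr.rpkm.sort_index())

    def test_errors(self):
        counts = self.make_counts(exon={"s1": [0]}, intron={"s1": [0]}, exonic_length=[100])
        with pytest.raises(DataError, match="library"):
            rpkm(counts)
        counts = self.make_counts(exon={"s1": [1]}, intron={"s1": [0]}, exonic_length=[0])
        with pytest.raises(DataError, match="exonic length"):
            rpkm(counts)


def test_gtf_round_trip(tmp_path):
    models = [
        GeneModel.from_exons("gA", "chr1", [(100, 200), (300, 400)], strand="+"),
        GeneModel.from_exons("gB", "chr1", [(1000, 1100)], strand="-"),
    ]
    path = tmp_path / "models.gtf"
    write_gtf(models, path)
    back = read_gtf(path)
    assert back == models


def test_bed_round_trip(tmp_path):
    reads = pd.DataFrame(
        {"chrom": ["chr1", "chr1"], "start": [10, 50], "end": [40, 90],
         "name": ["r0", "r1"], "score": [0, 0], "strand": ["+", "+"]}
    )
    path = tmp_path / "reads.bed"
    write_bed(reads, path)
    back = read_bed(path)
    pd.testing.assert_frame_equal(back, reads)
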