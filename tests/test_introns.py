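"""Intron extraction, boundary classification and genome-level statistics."""
import numpy as np
import pytest
from Bio.Seq import Seq

from orgatlas import (
    GeneModel,
    Intron,
    InvariantError,
    SimConfig,
    classify_intron_boundaries,
    extract_introns,
    generate_synthetic_gene_models,
    summarize_intron_stats,
)


def make_genome(intron_left, intron_right, total=320):
    """Contig with exons 1-100 and 201-300; the intron's first and last two
    bases are set explicitly."""
    rng = np.random.default_rng(0)
    seq = list("ACGT"[i] for i in rng.integers(0, 4, size=total))
    seq[100:102] = list(intron_left)   # genomic 101-102
    seq[198:200] = list(intron_right)  # genomic 199-200
    return {"c1": "".join(seq)}


def model(strand):
    return GeneModel("g1", "m1", "c1", strand, ((1, 100), (201, 300)))


class TestExtractIntrons:
    def test_plus_strand_definition(self):
        genome = make_genome("GT", "AG")
        (intron,) = extract_introns([model("+")], genome)
        assert (intron.start, intron.end) == (101, 200)
        assert (intron.donor, intron.acceptor) == ("GT", "AG")
        assert intron.boundary_class == "GT-AG"

    def test_minus_strand_boundaries_read_in_transcription_orientation(self):
        # genomic CT at 101-102 and AC at 199-200; on the minus strand the
        # donor is the revcomp of the genomic right end
        genome = make_genome("CT", "AC")
        (intron,) = extract_introns([model("-")], genome)
        assert (intron.donor, intron.acceptor) == ("GT", "AG")
        # independent oracle: reverse-complement the spliced-out sequence
        spliced = str(Seq(genome["c1"][100:200]).reverse_complement())
        assert intron.donor == spliced[:2]
        assert intron.acceptor == spliced[-2:]

    def test_single_exon_mrna_yields_no_introns(self):
        gm = GeneModel("g1", "m1", "c1", "+", ((1, 100),))
        assert extract_introns([gm], {"c1": "A" * 100}) == []

    def test_too_short_intron_flagged_not_dropped(self):
        gm = GeneModel("g1", "m1", "c1", "+", ((1, 10), (13, 30)))
        (intron,) = extract_introns([gm], {"c1": "A" * 30})
        assert intron.too_short
        assert intron.boundary_class == "other"

    def test_exon_beyond_contig_end_hard_error(self):
        gm = GeneModel("g1", "m1", "c1", "+", ((1, 100), (201, 300)))
        with pytest.raises(InvariantError, match="beyond contig"):
            extract_introns([gm], {"c1": "A" * 150})

    def test_missing_contig_hard_error(self):
        with pytest.raises(InvariantError, match="not in genome"):
            extract_introns([model("+")], {"other": "A" * 400})


@pytest.mark.parametrize(
    "donor, acceptor, expected",
    [
        ("GT", "AG", "GT-AG"),
        ("GC", "AG", "GC-AG"),
        ("GT", "GG", "other"),  # the unusual boundary pattern
        ("NT", "AG", "other"),
        ("AT", "AC", "other"),
    ],
)
def test_classify_intron_boundaries(donor, acceptor, expected):
    intron = Intron("c", 10, 60, "+", donor, acceptor, expected)
    assert classify_intron_boundaries(intron) == expected


class TestSummarize:
    @staticmethod
    def introns_for(gene_id, mrna_id, n, cls="GT-AG"):
        return [
            Intron("c", 100 * i + 1, 100 * i + 50, "+", "GT", "AG", cls,
                   gene_id, mrna_id)
            for i in range(n)
        ]

    @staticmethod
    def gm(gene_id, mrna_id, n_exons=2):
        exons = tuple((100 * i + 1, 100 * i + 50) for i in range(n_exons))
        return GeneModel(gene_id, mrna_id, "c", "+", exons)

    def test_density_and_fractions(self):
        introns = self.introns_for("g1", "m1", 3) + self.introns_for("g2", "m2", 4)
        models = [self.gm("g1", "m1", 4), self.gm("g2", "m2", 5)]
        s = summarize_intron_stats(introns, models, "all_mrnas")
        assert s.density == pytest.approx(3.5)
        assert s.class_fractions == {"GT-AG": 1.0}
        assert s.total_introns == 7

    def test_zero_introns_degenerate(self):
        s = summarize_intron_stats([], [self.gm(f"g{i}", f"m{i}") for i in range(5)],
                                   "all_mrnas")
        assert s.density == 0
        assert s.class_fractions == {}

    def test_zero_genes_error(self):
        with pytest.raises(InvariantError):
            summarize_intron_stats([], [], "all_mrnas")

    def test_unknown_policy_rejected(self):
        with pytest.raises(InvariantError):
            summarize_intron_stats([], [self.gm("g", "m")], "every_exon_twice")

    def test_isoform_policies_disagree_when_isoforms_share_introns(self):
        # two isoforms of one gene share the same 3 introns
        introns = self.introns_for("g1", "m1", 3) + self.introns_for("g1", "m2", 3)
        models = [self.gm("g1", "m1", 4), self.gm("g1", "m2", 4)]
        assert summarize_intron_stats(introns, models, "all_mrnas").density == 3.0
        assert summarize_intron_stats(introns, models, "longest_isoform").density == 3.0
        unique = summarize_intron_stats(introns, models, "unique_introns_per_gene")
        assert unique.density == 3.0
        assert unique.total_introns == 3
        assert unique.genes_considered == 1


class TestSpliceRoundTrip:
    def test_exons_plus_introns_reconstruct_gene_span(self):
        """Concatenating exon and intron sequences in genomic order must
        reproduce the genomic span exactly on both strands."""
        config = SimConfig(seed=23, n_genes=40, mean_introns_per_gene=3.0)
        genome, models, _ = generate_synthetic_gene_models(config)
        introns = extract_introns(models, genome)
        by_mrna = {}
        for i in introns:
            by_mrna.setdefault(i.mrna_id, []).append(i)
        strands = set()
        for gm in models:
            contig = genome[gm.seq_id]
            pieces = []
            for idx, (s, e) in enumerate(gm.exons):
                pieces.append(contig[s - 1 : e])
                if idx < len(gm.exons) - 1:
                    intron = sorted(by_mrna[gm.mrna_id], key=lambda i: i.start)[idx]
                    pieces.append(contig[intron.start - 1 : intron.end])
            span_start, span_end = gm.span
            assert "".join(pieces) == contig[span_start - 1 : span_end]
            strands.add(gm.strand)
        assert strands == {"+", "-"}  # both strands exercised
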