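"""Strand-aware intron extraction and splice-boundary statistics.

Introns are the gaps between consecutive exons of a gene model. Donor and
acceptor dinucleotides are always reported in transcription orientation:
for a minus-strand gene the donor is the reverse complement of the last two
genomic bases of the intron interval. Boundary classes follow spliceosomal
convention: GT-AG (canonical), GC-AG (minor canonical), everything else —
including any N — is "other".

Coordinates are 1-based inclusive at the interface (as in GFF3); interval
arithmetic inside this module is half-open and converted back on output.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .errors import InvariantError
from .io import GeneModel

BOUNDARY_GT_AG = "GT-AG"
BOUNDARY_GC_AG = "GC-AG"
BOUNDARY_OTHER = "other"

ISOFORM_POLICIES = ("all_mrnas", "longest_isoform", "unique_introns_per_gene")

#: minimum intron length for donor and acceptor dinucleotides not to overlap
MIN_INTRON_LENGTH = 4


@dataclass(frozen=True)
class Intron:
    """One intron with its splice boundaries in transcription orientation."""

    seq_id: str
    start: int  # 1-based inclusive, genomic
    end: int
    strand: str
    donor: str
    acceptor: str
    boundary_class: str
    gene_id: str = ""
    mrna_id: str = ""
    too_short: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class IntronSummary:
    """Genome-level intron statistics under a stated isoform policy."""

    total_introns: int
    genes_considered: int
    density: float
    class_fractions: dict[str, float]
    isoform_policy: str


def classify_intron_boundaries(intron: Intron) -> str:
    """GT+AG -> GT-AG; GC+AG -> GC-AG; anything else (incl. N) -> other."""
    return _classify(intron.donor, intron.acceptor)


def _classify(donor: str, acceptor: str) -> str:
    if donor == "GT" and acceptor == "AG":
        return BOUNDARY_GT_AG
    if donor == "GC" and acceptor == "AG":
        return BOUNDARY_GC_AG
    return BOUNDARY_OTHER


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_introns(
    gene_models: Sequence[GeneModel],
    genome_sequences: Mapping[str, str],
) -> list[Intron]:
    """Derive the introns of every gene model from its sorted exons.

    An mRNA with n exons yields n-1 introns. Introns shorter than
    :data:`MIN_INTRON_LENGTH` are kept, flagged ``too_short`` and classed
    "other" (their boundary dinucleotides would overlap). An exon running
    past its contig end is a hard error.
    """
    introns: list[Intron] = []
    for gm in gene_models:
        if gm.seq_id not in genome_sequences:
            raise InvariantError(f"{gm.mrna_id}: contig {gm.seq_id!r} not in genome")
        contig = genome_sequences[gm.seq_id]
        if gm.exons[-1][1] > len(contig):
            raise InvariantError(
                f"{gm.mrna_id}: exon end {gm.exons[-1][1]} beyond contig "
                f"{gm.seq_id} length {len(contig)}"
            )
        for (_, prev_end), (next_start, _) in zip(gm.exons, gm.exons[1:]):
            start, end = prev_end + 1, next_start - 1  # 1-based inclusive
            length = end - start + 1
            seq = contig[start - 1 : end]  # half-open slice of the intron
            if length < MIN_INTRON_LENGTH:
                donor = seq[:2] if gm.strand == "+" else _revcomp(seq[-2:])
                acceptor = seq[-2:] if gm.strand == "+" else _revcomp(seq[:2])
                introns.append(
                    Intron(
                        gm.seq_id, start, end, gm.strand, donor, acceptor,
                        BOUNDARY_OTHER, gm.gene_id, gm.mrna_id, too_short=True,
                    )
                )
                continue
            if gm.strand == "+":
                donor, acceptor = seq[:2], seq[-2:]
            else:
                donor, acceptor = _revcomp(seq[-2:]), _revcomp(seq[:2])
            introns.append(
                Intron(
                    gm.seq_id, start, end, gm.strand, donor, acceptor,
                    _classify(donor, acceptor), gm.gene_id, gm.mrna_id,
                )
            )
    return introns


def _select_longest_isoforms(gene_models: Sequence[GeneModel]) -> set[str]:
    best: dict[str, GeneModel] = {}
    for gm in gene_models:
        cur = best.get(gm.gene_id)
        # longer exonic span wins; ties break to the lexicographically
        # smaller mrna_id for determinism
        if cur is None or gm.exonic_length > cur.exonic_length or (
            gm.exonic_length == cur.exonic_length and gm.mrna_id < cur.mrna_id
        ):
            best[gm.gene_id] = gm
    return {gm.mrna_id for gm in best.values()}


def summarize_intron_stats(
    introns: Sequence[Intron],
    gene_models: Sequence[GeneModel],
    isoform_policy: str = "unique_introns_per_gene",
) -> IntronSummary:
    """Compute intron density and boundary-class fractions.

    Policies:

    ``all_mrnas``
        every mRNA's introns are counted; denominator = number of mRNAs.
    ``longest_isoform``
        per gene only the mRNA with the longest exonic span is counted;
        denominator = number of genes.
    ``unique_introns_per_gene``
        distinct intron coordinates per gene are counted once; denominator
        = number of genes. This is the default because isoforms otherwise
        double-count shared introns.

    With zero introns the density is 0 and the fraction map is empty.
    Zero gene models is an error.
    """
    if isoform_policy not in ISOFORM_POLICIES:
        raise InvariantError(f"unknown isoform policy {isoform_policy!r}")
    if not gene_models:
        raise InvariantError("no gene models: intron density undefined")

    if isoform_policy == "all_mrnas":
        counted = list(introns)
        genes_considered = len({gm.mrna_id for gm in gene_models})
    elif isoform_policy == "longest_isoform":
        keep = _select_longest_isoforms(gene_models)
        counted = [i for i in introns if i.mrna_id in keep]
        genes_considered = len({gm.gene_id for gm in gene_models})
    else:  # unique_introns_per_gene
        seen: set[tuple[str, str, int, int, str]] = set()
        counted = []
        for intron in introns:
            key = (intron.gene_id, intron.seq_id, intron.start, intron.end, intron.strand)
            if key not in seen:
                seen.add(key)
                counted.append(intron)
        genes_considered = len({gm.gene_id for gm in gene_models})

    total = len(counted)
    fractions: dict[str, float] = {}
    if total:
        for intron in counted:
            fractions[intron.boundary_class] = fractions.get(intron.boundary_class, 0) + 1
        fractions = {k: v / total for k, v in sorted(fractions.items())}
    return IntronSummary(
        total_introns=total,
        genes_considered=genes_considered,
        density=total / genes_considered,
        class_fractions=fractions,
        isoform_policy=isoform_policy,
    )


def write_intron_table(introns: Iterable[Intron], path) -> None:
    """BED-like TSV: seq_id, start-1 (half-open), end, strand, class."""
    with open(path, "w") as fh:
        fh.write("seq_id\tstart\tend\tstrand\tboundary_class\tdonor\tacceptor\t"
                 "gene_id\tmrna_id\ttoo_short\n")
        for i in introns:
            fh.write(
                f"{i.seq_id}\t{i.start - 1}\t{i.end}\t{i.strand}\t{i.boundary_class}\t"
                f"{i.donor}\t{i.acceptor}\t{i.gene_id}\t{i.mrna_id}\t"
                f"{int(i.too_short)}\n"
            )


def write_intron_summary(summary: IntronSummary, path) -> None:
    with open(path, "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"total_introns\t{summary.total_introns}\n")
        fh.write(f"genes_considered\t{summary.genes_considered}\n")
        fh.write(f"density\t{summary.density:.6g}\n")
        fh.write(f"isoform_policy\t{summary.isoform_policy}\n")
        for cls, frac in summary.class_fractions.items():
            fh.write(f"fraction_{cls}\t{frac:.6g}\n")
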