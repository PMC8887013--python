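"""Readers and writers for every external format the pipeline touches.

Sequence data come in as protein/nucleotide FASTA (via Biopython) and GFF3
gene models (via gffutils). Evidence produced by external localization
predictors is consumed as tab-separated tables in small documented dialects,
one per tool; the tools themselves (TargetP, PSORT II, MultiLoc2, NommPred,
TMHMM, the PTS1 predictor) are never re-implemented here. BLAST hits are
consumed in tabular ``-outfmt 6``.

Dialect column maps
-------------------
``targetp2``
    Comment lines start with ``#``. Columns: identifier, predicted class
    (``mTP``/``SP``/``noTP``/``OTHER``), then per-class probabilities
    ``noTP  SP  mTP`` (plant column absent in non-plant runs).
``psortii``
    Columns: identifier, compartment token (``mit``, ``cyt``, ``nuc``,
    ``ER``, ``pero``, ``PM``, ``extr``, ``vesi``...), optional score.
``multiloc2``
    Columns: identifier, setting (``animal``/``fungal``/``plant``),
    compartment token, optional probability.
``nommpred``
    Columns: identifier, setting (``MRO``/``Dictyostelium``), predicted
    label (``MRO`` or ``mitochondrial`` count as positive), optional score.
``tmhmm``
    TMHMM "short" one-line format: identifier followed by ``key=value``
    tokens; ``PredHel=N`` is extracted as the helix count.
``pts1predictor``
    Columns: identifier, classification (``Targeted`` / ``Twilight zone`` /
    ``Not targeted``), optional score (GENERAL function, twelve C-terminal
    residues evaluated by the external server).
``generic``
    Columns: protein_id, tool, setting, label, score — already in the
    pipeline's own vocabulary.

Unknown compartment tokens are preserved under label ``other`` with the raw
token kept on the row and logged, so predictor-version drift surfaces in
logs rather than silently changing calls.
"""
from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO

from .calls import SYMBOL_TO_TIER, CandidateCall
from .errors import DuplicateIdError, FormatError, InvariantError

logger = logging.getLogger("orgatlas")

# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" "XBZU")


@dataclass(frozen=True)
class ProteinRecord:
    """One proteome entry: identifier, description, amino-acid sequence.

    Sequences are upper case, contain no whitespace, and carry no trailing
    stop symbol; an internal ``*`` is rejected as a broken gene model.
    """

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise InvariantError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise InvariantError(f"protein {self.id}: empty sequence")
        bad = set(self.sequence) - _AA_ALPHABET
        if bad:
            raise InvariantError(
                f"protein {self.id}: invalid residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A single mRNA's exon structure on a genomic sequence.

    Exons are 1-based inclusive ``(start, end)`` intervals, stored sorted by
    start regardless of strand or of the order features appeared in the file.
    """

    gene_id: str
    mrna_id: str
    seq_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InvariantError(f"{self.mrna_id}: invalid strand {self.strand!r}")
        if not self.exons:
            raise InvariantError(f"{self.mrna_id}: no exons")
        prev_end = 0
        for start, end in self.exons:
            if start > end:
                raise InvariantError(
                    f"{self.mrna_id}: exon start {start} > end {end}"
                )
            if start <= prev_end:
                raise InvariantError(
                    f"{self.mrna_id}: overlapping or unsorted exons"
                )
            prev_end = end

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(end - start + 1 for start, end in self.exons)


EVIDENCE_TOOLS = frozenset(
    {
        "targetp2",
        "psortii",
        "multiloc2",
        "nommpred",
        "tmhmm",
        "pts1predictor",
        "blast",
        "experimental",
    }
)

#: the pipeline's controlled compartment vocabulary for evidence labels
EVIDENCE_LABELS = frozenset(
    {
        "mitochondrial",
        "cytosolic",
        "nuclear",
        "secretory",
        "peroxisomal",
        "membrane",
        "vesicular",
        "other",
    }
)


@dataclass(frozen=True)
class EvidenceRow:
    """One predictor call for one protein, in the pipeline vocabulary."""

    protein_id: str
    tool: str
    setting: str = "default"
    label: str = "other"
    score: float | None = None
    raw_label: str | None = None

    def __post_init__(self) -> None:
        if self.tool not in EVIDENCE_TOOLS:
            raise InvariantError(f"unknown tool {self.tool!r}")
        if self.label not in EVIDENCE_LABELS:
            raise InvariantError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class BlastHit:
    """One BLAST tabular (outfmt 6) hit against a reference organelle set."""

    query_id: str
    subject_id: str
    reference_set: str
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise InvariantError("evalue must be >= 0")


#: reference organelle proteomes the homology screen is run against
DEFAULT_REFERENCE_SETS = frozenset(
    {"Mb_hydrogenosome", "Eh_mitosome", "Ac_mitochondrion", "Mb_peroxisome"}
)


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def read_protein_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA into validated, normalized records.

    Sequences are upcased and a single terminal ``*`` is stripped; internal
    stops, duplicate identifiers and empty sequences are hard errors.
    Input order is preserved.
    """
    path = Path(path)
    _check_fasta_header(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"{path}: duplicate protein id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if seq.endswith("*"):
            seq = seq[:-1]
        if "*" in seq:
            raise FormatError(
                f"{path}: protein {rec.id!r} has an internal stop codon"
            )
        if not seq:
            raise FormatError(f"{path}: protein {rec.id!r} has an empty sequence")
        records.append(ProteinRecord(rec.id, rec.description, seq))
    return records


def _check_fasta_header(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FormatError(
                    f"{path}: line {lineno}: not FASTA (expected '>' header)"
                )
            return
    raise FormatError(f"{path}: empty file, not FASTA")


def write_protein_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.description if rec.description else rec.id
            if not header.startswith(rec.id):
                header = f"{rec.id} {header}"
            fh.write(f">{header}\n{rec.sequence}\n")


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    """Read a nucleotide FASTA into a dict of upper-case sequences."""
    path = Path(path)
    _check_fasta_header(path)
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise DuplicateIdError(f"{path}: duplicate sequence id {rec.id!r}")
        genome[rec.id] = str(rec.seq).upper()
    return genome


def write_genome_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for seq_id, seq in sequences.items():
            fh.write(f">{seq_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# --------------------------------------------------------------------------
# GFF3
# --------------------------------------------------------------------------

def read_gff3_gene_models(path: str | Path) -> list[GeneModel]:
    """Read GFF3 gene models: one :class:`GeneModel` per mRNA/transcript.

    Exon features are the carriers of splicing; mRNAs that lack exon rows
    fall back to their CDS rows. Exon/CDS features whose Parent cannot be
    resolved are counted, logged as a warning, and skipped. Overlapping
    exons within one mRNA are a hard error. Coordinates stay 1-based
    inclusive as in GFF3.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
    )
    known_types = set(db.featuretypes())
    mrna_types = [t for t in ("mRNA", "transcript") if t in known_types]

    orphans = 0
    for feat_type in ("exon", "CDS"):
        if feat_type not in known_types:
            continue
        for feat in db.features_of_type(feat_type):
            if "Parent" in feat.attributes and not any(
                True for _ in db.parents(feat, level=1)
            ):
                orphans += 1
    if orphans:
        logger.warning(
            "%s: skipped %d exon/CDS feature(s) without a resolvable Parent",
            path,
            orphans,
        )

    models: list[GeneModel] = []
    for feat_type in mrna_types:
        for mrna in db.features_of_type(feat_type, order_by=("seqid", "start")):
            exons = [
                (f.start, f.end) for f in db.children(mrna, featuretype="exon")
            ]
            if not exons:
                exons = [
                    (f.start, f.end) for f in db.children(mrna, featuretype="CDS")
                ]
            if not exons:
                logger.warning("%s: mRNA %s has no exon/CDS children", path, mrna.id)
                continue
            exons.sort()
            gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
            try:
                models.append(
                    GeneModel(
                        gene_id=gene_id,
                        mrna_id=mrna.id,
                        seq_id=mrna.seqid,
                        strand=mrna.strand,
                        exons=tuple(exons),
                    )
                )
            except InvariantError as exc:
                raise FormatError(f"{path}: {exc}") from exc
    return models


def write_gff3_gene_models(models: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/exon features linked by ID/Parent attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        by_gene: dict[str, list[GeneModel]] = {}
        for gm in models:
            by_gene.setdefault(gm.gene_id, []).append(gm)
        for gene_id, group in by_gene.items():
            start = min(gm.span[0] for gm in group)
            end = max(gm.span[1] for gm in group)
            seq_id, strand = group[0].seq_id, group[0].strand
            fh.write(
                f"{seq_id}\torgatlas\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
                f"ID={gene_id}\n"
            )
            for gm in group:
                s, e = gm.span
                fh.write(
                    f"{gm.seq_id}\torgatlas\tmRNA\t{s}\t{e}\t.\t{gm.strand}\t.\t"
                    f"ID={gm.mrna_id};Parent={gene_id}\n"
                )
                for i, (es, ee) in enumerate(gm.exons, start=1):
                    fh.write(
                        f"{gm.seq_id}\torgatlas\texon\t{es}\t{ee}\t.\t{gm.strand}\t.\t"
                        f"ID={gm.mrna_id}.exon{i};Parent={gm.mrna_id}\n"
                    )


# --------------------------------------------------------------------------
# evidence tables
# --------------------------------------------------------------------------

_TARGETP2_LABELS = {"mTP": "mitochondrial", "SP": "secretory", "noTP": "other",
                    "OTHER": "other"}

_PSORTII_LABELS = {
    "mit": "mitochondrial",
    "mitochondrial": "mitochondrial",
    "cyt": "cytosolic",
    "cytoplasmic": "cytosolic",
    "cytosolic": "cytosolic",
    "nuc": "nuclear",
    "nuclear": "nuclear",
    "pero": "peroxisomal",
    "peroxisomal": "peroxisomal",
    "er": "secretory",
    "extr": "secretory",
    "extracellular": "secretory",
    "pm": "membrane",
    "plasma membrane": "membrane",
    "vesi": "vesicular",
    "vesicular": "vesicular",
}

_MULTILOC2_LABELS = {
    "mitochondrial": "mitochondrial",
    "mitochondrion": "mitochondrial",
    "cytoplasmic": "cytosolic",
    "nuclear": "nuclear",
    "secretory": "secretory",
    "er": "secretory",
    "extracellular": "secretory",
    "peroxisomal": "peroxisomal",
    "plasma membrane": "membrane",
    "golgi": "secretory",
    "lysosomal": "other",
    "vacuolar": "other",
}

_NOMMPRED_LABELS = {
    "mro": "mitochondrial",
    "mitochondrial": "mitochondrial",
    "mitochondrion": "mitochondrial",
    "not-mro": "other",
    "non-mitochondrial": "other",
    "other": "other",
}

_PTS1PRED_LABELS = {
    "targeted": "peroxisomal",
    "twilight zone": "other",
    "not targeted": "other",
}


def _iter_rows(path: Path, comment: str | None = None):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if comment and line.startswith(comment):
                continue
            yield lineno, line.split("\t")


def _map_label(raw: str, mapping: dict[str, str], tool: str, path: Path,
               lineno: int) -> tuple[str, str | None]:
    label = mapping.get(raw) or mapping.get(raw.lower())
    if label is None:
        logger.warning(
            "%s: line %d: unknown %s label %r kept as 'other'", path, lineno, tool, raw
        )
        return "other", raw
    return label, raw


def _parse_targetp2(path: Path) -> list[EvidenceRow]:
    rows = []
    for lineno, fields in _iter_rows(path, comment="#"):
        if len(fields) < 2:
            raise FormatError(f"{path}: line {lineno}: expected >= 2 columns")
        pid, pred = fields[0], fields[1]
        label, raw = _map_label(pred, _TARGETP2_LABELS, "targetp2", path, lineno)
        score = None
        score_col = {"noTP": 2, "SP": 3, "mTP": 4}.get(pred)
        if score_col is not None and len(fields) > score_col:
            try:
                score = float(fields[score_col])
            except ValueError:
                score = None
        rows.append(EvidenceRow(pid, "targetp2", "non-plant", label, score, raw))
    return rows


def _parse_psortii(path: Path) -> list[EvidenceRow]:
    rows = []
    for lineno, fields in _iter_rows(path, comment="#"):
        if len(fields) < 2:
            raise FormatError(f"{path}: line {lineno}: expected >= 2 columns")
        pid, pred = fields[0], fields[1]
        label, raw = _map_label(pred, _PSORTII_LABELS, "psortii", path, lineno)
        score = float(fields[2]) if len(fields) > 2 and fields[2] else None
        rows.append(EvidenceRow(pid, "psortii", "default", label, score, raw))
    return rows


def _parse_multiloc2(path: Path) -> list[EvidenceRow]:
    rows = []
    for lineno, fields in _iter_rows(path, comment="#"):
        if len(fields) < 3:
            raise FormatError(f"{path}: line {lineno}: expected >= 3 columns")
        pid, setting, pred = fields[0], fields[1], fields[2]
        label, raw = _map_label(pred, _MULTILOC2_LABELS, "multiloc2", path, lineno)
        score = float(fields[3]) if len(fields) > 3 and fields[3] else None
        rows.append(EvidenceRow(pid, "multiloc2", setting, label, score, raw))
    return rows


def _parse_nommpred(path: Path) -> list[EvidenceRow]:
    rows = []
    for lineno, fields in _iter_rows(path, comment="#"):
        if len(fields) < 3:
            raise FormatError(f"{path}: line {lineno}: expected >= 3 columns")
        pid, setting, pred = fields[0], fields[1], fields[2]
        label, raw = _map_label(pred, _NOMMPRED_LABELS, "nommpred", path, lineno)
        score = float(fields[3]) if len(fields) > 3 and fields[3] else None
        rows.append(EvidenceRow(pid, "nommpred", setting, label, score, raw))
    return rows


def _parse_tmhmm(path: Path) -> list[EvidenceRow]:
    rows = []
    for lineno, line_fields in _iter_rows(path, comment="#"):
        fields = [tok for f in line_fields for tok in f.split()]
        if not fields:
            continue
        pid = fields[0]
        helices = None
        for tok in fields[1:]:
            if tok.startswith("PredHel="):
                try:
                    helices = int(tok.split("=", 1)[1])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: line {lineno}: bad PredHel value"
                    ) from exc
        if helices is None:
            raise FormatError(f"{path}: line {lineno}: no PredHel= token")
        label = "membrane" if helices > 0 else "other"
        rows.append(EvidenceRow(pid, "tmhmm", "default", label, float(helices)))
    return rows


def _parse_pts1predictor(path: Path) -> list[EvidenceRow]:
    rows = []
    for lineno, fields in _iter_rows(path, comment="#"):
        if len(fields) < 2:
            raise FormatError(f"{path}: line {lineno}: expected >= 2 columns")
        pid, pred = fields[0], fields[1]
        label, raw = _map_label(pred, _PTS1PRED_LABELS, "pts1predictor", path, lineno)
        score = float(fields[2]) if len(fields) > 2 and fields[2] else None
        rows.append(EvidenceRow(pid, "pts1predictor", "GENERAL", label, score, raw))
    return rows


def _parse_generic(path: Path) -> list[EvidenceRow]:
    rows = []
    header: list[str] | None = None
    for lineno, fields in _iter_rows(path, comment="#"):
        if header is None and fields[0] == "protein_id":
            header = fields
            continue
        if len(fields) < 4:
            raise FormatError(f"{path}: line {lineno}: expected >= 4 columns")
        pid, tool, setting, label = fields[:4]
        score = float(fields[4]) if len(fields) > 4 and fields[4] else None
        if label not in EVIDENCE_LABELS:
            logger.warning(
                "%s: line %d: unknown label %r kept as 'other'", path, lineno, label
            )
            rows.append(EvidenceRow(pid, tool, setting, "other", score, label))
        else:
            rows.append(EvidenceRow(pid, tool, setting, label, score))
    return rows


EVIDENCE_DIALECTS = {
    "targetp2": _parse_targetp2,
    "psortii": _parse_psortii,
    "multiloc2": _parse_multiloc2,
    "nommpred": _parse_nommpred,
    "tmhmm": _parse_tmhmm,
    "pts1predictor": _parse_pts1predictor,
    "generic": _parse_generic,
}


def read_evidence_table(
    path: str | Path,
    dialect: str,
    known_proteins: set[str] | None = None,
) -> list[EvidenceRow]:
    """Read one predictor's output table in the named dialect.

    Rows referencing proteins absent from ``known_proteins`` (when given)
    are retained with a warning — they are joined to the proteome later.
    ``(protein_id, tool, setting)`` must be unique within the table.
    """
    path = Path(path)
    try:
        parser = EVIDENCE_DIALECTS[dialect]
    except KeyError:
        raise FormatError(
            f"unknown evidence dialect {dialect!r}; "
            f"known: {sorted(EVIDENCE_DIALECTS)}"
        ) from None
    rows = parser(path)
    seen: set[tuple[str, str, str]] = set()
    for row in rows:
        key = (row.protein_id, row.tool, row.setting)
        if key in seen:
            raise DuplicateIdError(f"{path}: duplicate evidence row for {key}")
        seen.add(key)
        if known_proteins is not None and row.protein_id not in known_proteins:
            logger.warning(
                "%s: evidence for unknown protein %r retained", path, row.protein_id
            )
    return rows


def write_evidence_table(rows: Iterable[EvidenceRow], path: str | Path) -> None:
    """Write evidence rows in the ``generic`` dialect."""
    with open(path, "w") as fh:
        fh.write("protein_id\ttool\tsetting\tlabel\tscore\n")
        for row in rows:
            score = "" if row.score is None else repr(row.score)
            fh.write(f"{row.protein_id}\t{row.tool}\t{row.setting}\t{row.label}\t{score}\n")


def write_tmhmm_table(rows: Iterable[EvidenceRow], path: str | Path) -> None:
    """Write TMHMM evidence back out in the "short" one-line dialect."""
    with open(path, "w") as fh:
        for row in rows:
            if row.tool != "tmhmm":
                continue
            helices = int(row.score or 0)
            fh.write(f"{row.protein_id}\tPredHel={helices}\tTopology=o\n")


def write_pts1predictor_table(rows: Iterable[EvidenceRow], path: str | Path) -> None:
    """Write PTS1-predictor evidence in its two/three-column dialect."""
    with open(path, "w") as fh:
        for row in rows:
            if row.tool != "pts1predictor":
                continue
            verdict = "Targeted" if row.label == "peroxisomal" else "Not targeted"
            score = "" if row.score is None else f"\t{row.score!r}"
            fh.write(f"{row.protein_id}\t{verdict}{score}\n")


# --------------------------------------------------------------------------
# BLAST outfmt 6
# --------------------------------------------------------------------------

def read_blast_outfmt6(
    path: str | Path,
    reference_set: str,
    registry: frozenset[str] | set[str] = DEFAULT_REFERENCE_SETS,
) -> list[BlastHit]:
    """Read BLAST tabular (outfmt 6: qseqid sseqid pident length mismatch
    gapopen qstart qend sstart send evalue bitscore) hits against one
    reference organelle proteome."""
    if reference_set not in registry:
        raise FormatError(
            f"reference set {reference_set!r} not in registry {sorted(registry)}"
        )
    path = Path(path)
    hits: list[BlastHit] = []
    for lineno, fields in _iter_rows(path, comment="#"):
        if len(fields) < 12:
            raise FormatError(
                f"{path}: line {lineno}: expected 12 outfmt-6 columns, got {len(fields)}"
            )
        try:
            evalue = float(fields[10])
            bitscore = float(fields[11])
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: malformed numeric field") from exc
        hits.append(BlastHit(fields[0], fields[1], reference_set, evalue, bitscore))
    return hits


# --------------------------------------------------------------------------
# candidate tables (Table S2/S3-shaped TSV)
# --------------------------------------------------------------------------

def write_candidate_table(calls: Sequence[CandidateCall], path: str | Path) -> None:
    """Write calls as a TSV: id, compartment, tier symbol, one column per
    evidence channel; rows ordered by (protein_id, compartment)."""
    channels = sorted({ch for call in calls for ch in call.evidence})
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["protein_id", "compartment", "tier"] + channels)
        for call in sorted(calls, key=lambda c: (c.protein_id, c.compartment)):
            writer.writerow(
                [call.protein_id, call.compartment, call.tier_symbol]
                + [call.evidence.get(ch, "") for ch in channels]
            )


def read_candidate_table(path: str | Path) -> list[CandidateCall]:
    """Inverse of :func:`write_candidate_table` (empty cells drop out)."""
    path = Path(path)
    calls: list[CandidateCall] = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty candidate table") from None
        if header[:3] != ["protein_id", "compartment", "tier"]:
            raise FormatError(f"{path}: not a candidate table (bad header)")
        channels = header[3:]
        for fields in reader:
            if not fields:
                continue
            pid, compartment, symbol = fields[0], fields[1], fields[2]
            if symbol not in SYMBOL_TO_TIER:
                raise FormatError(f"{path}: unknown tier symbol {symbol!r}")
            evidence = {
                ch: val for ch, val in zip(channels, fields[3:]) if val != ""
            }
            calls.append(
                CandidateCall(pid, compartment, SYMBOL_TO_TIER[symbol], evidence)
            )
    return calls


# --------------------------------------------------------------------------
# small curated tables
# --------------------------------------------------------------------------

def read_experimental_table(path: str | Path):
    """Read the curated heterologous-localization table
    (protein_id, observed, note)."""
    from .mro import ExperimentalEvidence  # local import: avoid cycle

    path = Path(path)
    out = []
    for lineno, fields in _iter_rows(path, comment="#"):
        if fields[0] == "protein_id":
            continue
        if len(fields) < 2:
            raise FormatError(f"{path}: line {lineno}: expected >= 2 columns")
        note = fields[2] if len(fields) > 2 else ""
        out.append(ExperimentalEvidence(fields[0], fields[1], note))
    return out


def read_ortholog_map(path: str | Path) -> list[tuple[str, str]]:
    """Read a curated two-column ortholog map (id_a, id_b)."""
    path = Path(path)
    pairs = []
    for lineno, fields in _iter_rows(path, comment="#"):
        if fields[0] in ("id_a", "protein_id_a"):
            continue
        if len(fields) < 2:
            raise FormatError(f"{path}: line {lineno}: expected 2 columns")
        pairs.append((fields[0], fields[1]))
    return pairs
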