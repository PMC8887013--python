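"""Synthetic proteomes, evidence tables and annotated genomes with ground truth.

Every pipeline stage is testable offline against data whose truth is known
by construction:

* proteomes with planted PTS1 tripeptides, PTS2 nonapeptides,
  excluded-tripeptide decoys, transmembrane decoys (hydrophobic segment
  plus a valid PTS1 ending, so the TM filter is load-bearing) and
  mitochondrial-truth proteins;
* per-tool localization evidence drawn with configurable sensitivity and
  specificity against the planted truth;
* gene models whose intron counts are Poisson-distributed (default mean
  7.43 introns/gene) with configurable splice-boundary class frequencies
  (default 98.41% GT-AG, 1.59% GC-AG).

Accidental motifs are scrubbed from classes that should not carry them, so
on perfect evidence the calling stages recover the planted truth exactly.
All outputs are deterministic under the mandatory seed; a single seeded
generator is consumed in documented field order (class assignment, lengths,
residues, per-class fixes; then per-gene structure left to right).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConfigError
from .introns import BOUNDARY_GC_AG, BOUNDARY_GT_AG, Intron, _classify, _revcomp
from .io import EvidenceRow, GeneModel, ProteinRecord
from .pts import PtsMotifConfig, enumerate_pts1_set, scan_pts2

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_NT = np.array(list("ACGT"))
_HYDROPHOBIC = np.array(list("AILVFMW"))

SIGNAL_CLASSES = ("pts1", "pts2", "excluded_decoy", "tm", "mitochondrial")

#: tool -> settings drawn for in the evidence simulator
DEFAULT_TOOL_SETTINGS: dict[str, tuple[str, ...]] = {
    "targetp2": ("non-plant",),
    "psortii": ("default",),
    "multiloc2": ("animal", "fungal"),
    "nommpred": ("MRO", "Dictyostelium"),
    "tmhmm": ("default",),
    "pts1predictor": ("GENERAL",),
}


@dataclass(frozen=True)
class ToolRates:
    """Sensitivity/specificity of one simulated predictor."""

    sensitivity: float = 1.0
    specificity: float = 1.0

    def __post_init__(self) -> None:
        for value in (self.sensitivity, self.specificity):
            if not 0.0 <= value <= 1.0:
                raise ConfigError("rates must lie in [0, 1]")


@dataclass(frozen=True)
class ProteinTruth:
    """Planted ground truth for one synthetic protein."""

    protein_id: str
    planted_signal: str  # none | pts1 | pts2 | excluded_decoy | tm | mitochondrial
    motif: str | None = None
    position: int | None = None  # 1-based


@dataclass
class SyntheticTruth:
    """Ground truth for a synthetic bundle: per-protein and per-intron."""

    proteins: dict[str, ProteinTruth] = field(default_factory=dict)
    introns: list[Intron] = field(default_factory=list)

    def ids_with_signal(self, *signals: str) -> set[str]:
        return {
            pid for pid, t in self.proteins.items() if t.planted_signal in signals
        }

    @property
    def peroxisomal_ids(self) -> set[str]:
        """Proteins that genuinely belong to the peroxisomal matrix."""
        return self.ids_with_signal("pts1", "pts2")

    @property
    def mitochondrial_ids(self) -> set[str]:
        return self.ids_with_signal("mitochondrial")


@dataclass(frozen=True)
class SimConfig:
    """Stated world of the simulators; the seed is mandatory.

    Proteome defaults put modest fractions of each signal class on a
    background of uniformly drawn standard residues; genome defaults are
    the observed intron density (7.43/gene) and boundary-class frequencies
    (98.41% GT-AG, 1.59% GC-AG) of the single-cell genome assembly this
    pipeline models, with uniform intron lengths on [40, 500] nt.
    """

    seed: int
    n_proteins: int = 200
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "pts1": 0.15,
            "pts2": 0.05,
            "excluded_decoy": 0.05,
            "tm": 0.10,
            "mitochondrial": 0.15,
        }
    )
    protein_length_range: tuple[int, int] = (120, 600)
    n_genes: int = 1000
    mean_introns_per_gene: float = 7.43
    boundary_class_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            BOUNDARY_GT_AG: 0.9841,
            BOUNDARY_GC_AG: 0.0159,
            "other": 0.0,
        }
    )
    exon_length_range: tuple[int, int] = (100, 300)
    intron_length_range: tuple[int, int] = (40, 500)
    flank: int = 50
    other_boundary: tuple[str, str] = ("GT", "GG")

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError("seed is mandatory and must be an integer")
        unknown = set(self.class_fractions) - set(SIGNAL_CLASSES)
        if unknown:
            raise ConfigError(f"unknown signal classes: {sorted(unknown)}")
        total = sum(self.class_fractions.values())
        if total > 1.0 + 1e-9 or any(f < 0 for f in self.class_fractions.values()):
            raise ConfigError("class fractions must be >= 0 and sum to <= 1")
        if abs(sum(self.boundary_class_probs.values()) - 1.0) > 1e-9:
            raise ConfigError("boundary class probabilities must sum to 1")
        if self.mean_introns_per_gene <= 0:
            raise ConfigError("mean introns per gene must be > 0")
        if self.intron_length_range[0] < 4:
            raise ConfigError("introns shorter than 4 nt cannot carry boundaries")
        if _classify(*self.other_boundary) != "other":
            raise ConfigError("other_boundary must not be a canonical pair")


# --------------------------------------------------------------------------
# proteome
# --------------------------------------------------------------------------

def _random_residues(rng: np.random.Generator, n: int) -> np.ndarray:
    return _AA[rng.integers(0, len(_AA), size=n)]


def _record(pid: str, residues: np.ndarray) -> ProteinRecord:
    return ProteinRecord(pid, pid, "".join(residues))


def _scrub_pts2(
    residues: np.ndarray,
    rng: np.random.Generator,
    motif_config: PtsMotifConfig,
    keep_position: int | None = None,
) -> None:
    """Mutate the leading R of accidental PTS2 matches until none remain
    (the planted match at ``keep_position``, 1-based, is preserved)."""
    non_r = _AA[_AA != "R"]
    while True:
        matches = scan_pts2(_record("tmp", residues), motif_config)
        extra = [m for m in matches if m.position != keep_position]
        if not extra:
            return
        for m in extra:
            residues[m.position - 1] = rng.choice(non_r)


def generate_synthetic_proteome(
    config: SimConfig,
    motif_config: PtsMotifConfig = PtsMotifConfig(),
) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Generate a proteome with planted targeting signals and decoys.

    Class counts are ``round(fraction * n)`` (the remainder is unlabeled
    background); the class of each protein is a seeded permutation so
    identifiers carry no information. Same seed, same config: byte-identical
    records.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    labels: list[str] = []
    for cls in SIGNAL_CLASSES:
        labels.extend([cls] * int(round(config.class_fractions.get(cls, 0.0) * n)))
    if len(labels) > n:
        raise ConfigError("class fractions produce more proteins than n_proteins")
    labels.extend(["none"] * (n - len(labels)))
    labels = [labels[i] for i in rng.permutation(n)]

    pts1_set = sorted(enumerate_pts1_set(motif_config))
    excluded = sorted(motif_config.pts1_excluded)
    lo, hi = config.protein_length_range

    records: list[ProteinRecord] = []
    truth = SyntheticTruth()
    for i, cls in enumerate(labels):
        pid = f"sp{i:05d}"
        length = int(rng.integers(lo, hi + 1))
        residues = _random_residues(rng, length)
        motif: str | None = None
        position: int | None = None

        if cls == "tm":
            # hydrophobic 19-mer makes it a TMHMM-truth membrane protein
            start = int(rng.integers(5, length - 30))
            residues[start : start + 19] = _HYDROPHOBIC[
                rng.integers(0, len(_HYDROPHOBIC), size=19)
            ]

        if cls == "pts2":
            window_end = min(length, motif_config.pts2_window)
            pos = int(rng.integers(0, window_end - 9 + 1))  # 0-based
            span = np.concatenate(
                [
                    np.array(["R", rng.choice(sorted(motif_config.pts2_position2_class))]),
                    _random_residues(rng, 5),
                    np.array(["H", "L"]),
                ]
            )
            residues[pos : pos + 9] = span
            motif, position = "".join(span), pos + 1
            _scrub_pts2(residues, rng, motif_config, keep_position=position)
        else:
            _scrub_pts2(residues, rng, motif_config)

        if cls in ("pts1", "tm"):
            tri = pts1_set[int(rng.integers(0, len(pts1_set)))]
            residues[-3:] = np.array(list(tri))
            motif = motif or tri
            position = position or (length - 2)
        elif cls == "excluded_decoy":
            tri = excluded[int(rng.integers(0, len(excluded)))]
            residues[-3:] = np.array(list(tri))
            motif, position = tri, length - 2
        else:
            while "".join(residues[-3:]) in pts1_set:
                residues[-3:] = _random_residues(rng, 3)

        records.append(_record(pid, residues))
        truth.proteins[pid] = ProteinTruth(pid, cls, motif, position)
    return records, truth


# --------------------------------------------------------------------------
# evidence
# --------------------------------------------------------------------------

def generate_synthetic_evidence(
    truth: SyntheticTruth,
    per_tool_rates: Mapping[str, ToolRates] | None = None,
    seed: int = 0,
) -> list[EvidenceRow]:
    """Simulate per-tool localization evidence against the planted truth.

    Each (tool, setting) labels each positive-truth protein positive with
    probability ``sensitivity`` and each other protein positive with
    probability ``1 - specificity``, independently. Truth classes per tool:
    NTS tools score ``mitochondrial`` proteins, the PTS1 predictor scores
    ``pts1`` proteins, TMHMM scores ``tm`` proteins (2 predicted helices
    when positive, 0 otherwise).
    """
    rates = dict(per_tool_rates or {})
    unknown = set(rates) - set(DEFAULT_TOOL_SETTINGS)
    if unknown:
        raise ConfigError(f"unknown tools in rates: {sorted(unknown)}")
    for tool in DEFAULT_TOOL_SETTINGS:
        rates.setdefault(tool, ToolRates())

    rng = np.random.default_rng(seed)
    rows: list[EvidenceRow] = []
    ids = sorted(truth.proteins)
    for tool in sorted(DEFAULT_TOOL_SETTINGS):
        tool_rates = rates[tool]
        for setting in DEFAULT_TOOL_SETTINGS[tool]:
            for pid in ids:
                signal = truth.proteins[pid].planted_signal
                if tool == "pts1predictor":
                    is_true = signal == "pts1"
                elif tool == "tmhmm":
                    is_true = signal == "tm"
                else:
                    is_true = signal == "mitochondrial"
                p_positive = (
                    tool_rates.sensitivity if is_true else 1.0 - tool_rates.specificity
                )
                positive = rng.random() < p_positive
                if tool == "pts1predictor":
                    label = "peroxisomal" if positive else "other"
                    rows.append(EvidenceRow(pid, tool, setting, label))
                elif tool == "tmhmm":
                    label = "membrane" if positive else "other"
                    rows.append(
                        EvidenceRow(pid, tool, setting, label, 2.0 if positive else 0.0)
                    )
                else:
                    label = "mitochondrial" if positive else "other"
                    rows.append(EvidenceRow(pid, tool, setting, label))
    return rows


# --------------------------------------------------------------------------
# genome + gene models
# --------------------------------------------------------------------------

def generate_synthetic_gene_models(
    config: SimConfig,
) -> tuple[dict[str, str], list[GeneModel], SyntheticTruth]:
    """Generate one contig per gene with Poisson intron counts and planted
    splice-boundary classes.

    Each gene's intron count is Poisson(``mean_introns_per_gene``); each
    intron draws a boundary class from ``boundary_class_probs`` and its
    boundary dinucleotides are written into the contig accordingly (in
    transcription orientation — reverse-complemented on the minus strand).
    The FASTA and GFF3 views are mutually consistent and the truth records
    the exact intron coordinates and classes.
    """
    rng = np.random.default_rng(config.seed)
    class_names = list(config.boundary_class_probs)
    class_probs = np.array([config.boundary_class_probs[c] for c in class_names])
    pairs = {
        BOUNDARY_GT_AG: ("GT", "AG"),
        BOUNDARY_GC_AG: ("GC", "AG"),
        "other": config.other_boundary,
    }
    exon_lo, exon_hi = config.exon_length_range
    intron_lo, intron_hi = config.intron_length_range

    sequences: dict[str, str] = {}
    models: list[GeneModel] = []
    truth = SyntheticTruth()
    for g in range(config.n_genes):
        seq_id = f"ctg{g:05d}"
        gene_id = f"g{g:05d}"
        mrna_id = f"{gene_id}.t1"
        strand = "+" if rng.random() < 0.5 else "-"
        n_introns = int(rng.poisson(config.mean_introns_per_gene))
        exon_lens = rng.integers(exon_lo, exon_hi + 1, size=n_introns + 1)
        intron_lens = rng.integers(intron_lo, intron_hi + 1, size=n_introns)
        classes = [
            class_names[k]
            for k in rng.choice(len(class_names), size=n_introns, p=class_probs)
        ]
        total = 2 * config.flank + int(exon_lens.sum()) + int(intron_lens.sum())
        contig = _NT[rng.integers(0, 4, size=total)]

        exons: list[tuple[int, int]] = []
        pos = config.flank + 1  # 1-based start of the first exon
        for j in range(n_introns + 1):
            exon_end = pos + int(exon_lens[j]) - 1
            exons.append((pos, exon_end))
            if j < n_introns:
                i_start = exon_end + 1
                i_end = i_start + int(intron_lens[j]) - 1
                donor, acceptor = pairs[classes[j]]
                if strand == "+":
                    contig[i_start - 1 : i_start + 1] = list(donor)
                    contig[i_end - 2 : i_end] = list(acceptor)
                else:
                    contig[i_start - 1 : i_start + 1] = list(_revcomp(acceptor))
                    contig[i_end - 2 : i_end] = list(_revcomp(donor))
                truth.introns.append(
                    Intron(
                        seq_id, i_start, i_end, strand, donor, acceptor,
                        _classify(donor, acceptor), gene_id, mrna_id,
                    )
                )
                pos = i_end + 1
        sequences[seq_id] = "".join(contig)
        models.append(GeneModel(gene_id, mrna_id, seq_id, strand, tuple(exons)))
    return sequences, models, truth
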