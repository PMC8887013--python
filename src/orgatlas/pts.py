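"""Peroxisomal targeting-signal (PTS) grammar and the candidate cascade.

Peroxisomal matrix proteins are imported by Pex5 recognizing a C-terminal
tripeptide (PTS1) or by Pex7 recognizing an N-terminal nonapeptide (PTS2).
The PTS1 grammar used here is the tripeptide set ``[SAP][KR][LM]`` minus the
experimentally excluded tripeptides AKM, PKM and PRM, plus the literal SRI
(proline at -3 and methionine at -1 are admitted on the strength of
experimental verification in a related archamoeba). The PTS2 grammar is the
nonapeptide ``R[LI]x(5)HL`` searched within an N-terminal window; a wider
second-position class ``{L,I,V}`` is selectable.

A protein becomes a peroxisomal candidate when it carries a PTS motif and/or
an external PTS1-predictor positive, and carries no predicted transmembrane
helix (TMHMM evidence): membrane proteins are filtered out because the
grammar targets soluble matrix proteins.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .calls import TIER_EXCLUDED, TIER_STRONG, TIER_WEAK, CandidateCall
from .errors import ConfigError
from .io import EvidenceRow, ProteinRecord

logger = logging.getLogger("orgatlas")

_STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PtsMotifConfig:
    """Tunable PTS grammar.

    Defaults encode the published grammar: PTS1 = SRI plus ``[SAP][KR][LM]``
    minus {AKM, PKM, PRM}; PTS2 = ``R[LI]x(5)HL`` within the first
    ``pts2_window`` residues (40 by default — generous for known PTS2
    placements, and configurable). Ambiguous residues (X/B/Z/U) never
    satisfy a position class.
    """

    pts1_extra: frozenset[str] = frozenset({"SRI"})
    pts1_position1: frozenset[str] = frozenset("SAP")
    pts1_position2: frozenset[str] = frozenset("KR")
    pts1_position3: frozenset[str] = frozenset("LM")
    pts1_excluded: frozenset[str] = frozenset({"AKM", "PKM", "PRM"})
    pts2_position2_class: frozenset[str] = frozenset("LI")
    pts2_window: int = 40

    def __post_init__(self) -> None:
        if self.pts2_window < 9:
            raise ConfigError("pts2_window must be >= 9 (nonapeptide length)")
        classes = (
            self.pts1_position1
            | self.pts1_position2
            | self.pts1_position3
            | self.pts2_position2_class
        )
        bad = classes - _STANDARD_AA
        if bad:
            raise ConfigError(f"non-standard residues in motif classes: {sorted(bad)}")
        pattern = {
            a + b + c
            for a in self.pts1_position1
            for b in self.pts1_position2
            for c in self.pts1_position3
        }
        if not self.pts1_excluded <= pattern:
            raise ConfigError(
                "pts1_excluded must be a subset of the pattern-generated tripeptides"
            )

    def with_pts2_variant(self, variant: str) -> "PtsMotifConfig":
        """Return a copy with the second PTS2 position class set to the named
        variant: ``"LI"`` (default) or ``"LIV"``."""
        if variant not in ("LI", "LIV"):
            raise ConfigError(f"unknown PTS2 variant {variant!r}")
        return PtsMotifConfig(
            pts1_extra=self.pts1_extra,
            pts1_position1=self.pts1_position1,
            pts1_position2=self.pts1_position2,
            pts1_position3=self.pts1_position3,
            pts1_excluded=self.pts1_excluded,
            pts2_position2_class=frozenset(variant),
            pts2_window=self.pts2_window,
        )


@dataclass(frozen=True)
class PtsMatch:
    """A located targeting-signal occurrence (1-based start position)."""

    protein_id: str
    signal_type: str  # "PTS1" | "PTS2"
    motif: str
    position: int


def enumerate_pts1_set(config: PtsMotifConfig = PtsMotifConfig()) -> frozenset[str]:
    """Expand the PTS1 grammar into the concrete tripeptide set.

    Pure function of the config: pattern expansion minus exclusions, union
    the literal extras. The default grammar yields 10 tripeptides.
    """
    pattern = {
        "".join(tri)
        for tri in itertools.product(
            sorted(config.pts1_position1),
            sorted(config.pts1_position2),
            sorted(config.pts1_position3),
        )
    }
    return frozenset((pattern - config.pts1_excluded) | config.pts1_extra)


def scan_pts1(
    protein: ProteinRecord, config: PtsMotifConfig = PtsMotifConfig()
) -> PtsMatch | None:
    """Match the C-terminal tripeptide against the PTS1 set.

    The signal is strictly C-terminal: only the final three residues are
    examined, and the match position is ``len - 2`` (1-based). Proteins
    shorter than 3 residues cannot carry the signal and yield ``None``.
    """
    if len(protein) < 3:
        logger.info("protein %s shorter than 3 residues; no PTS1 scan", protein.id)
        return None
    tripeptide = protein.sequence[-3:]
    if tripeptide in enumerate_pts1_set(config):
        return PtsMatch(protein.id, "PTS1", tripeptide, len(protein) - 2)
    return None


def scan_pts2(
    protein: ProteinRecord, config: PtsMotifConfig = PtsMotifConfig()
) -> list[PtsMatch]:
    """Find all PTS2 nonapeptides ``R[LI]x(5)HL`` in the N-terminal window.

    A match is reported only when the whole 9-residue span lies within the
    first ``pts2_window`` residues. Overlapping occurrences are all
    reported; ambiguous residues never satisfy the R/H/L/class positions.
    """
    seq = protein.sequence
    matches: list[PtsMatch] = []
    last_start = min(len(seq), config.pts2_window) - 9
    for i in range(last_start + 1):
        span = seq[i : i + 9]
        if (
            span[0] == "R"
            and span[1] in config.pts2_position2_class
            and span[7] == "H"
            and span[8] == "L"
        ):
            matches.append(PtsMatch(protein.id, "PTS2", span, i + 1))
    return matches


def _predictor_positive(rows: Iterable[EvidenceRow]) -> dict[str, bool]:
    out: dict[str, bool] = {}
    for row in rows:
        if row.tool != "pts1predictor":
            continue
        out[row.protein_id] = out.get(row.protein_id, False) or (
            row.label == "peroxisomal"
        )
    return out


def _tm_helix_counts(rows: Iterable[EvidenceRow]) -> dict[str, int]:
    out: dict[str, int] = {}
    for row in rows:
        if row.tool != "tmhmm":
            continue
        out[row.protein_id] = int(row.score or 0)
    return out


def call_peroxisomal_candidates(
    proteins: Sequence[ProteinRecord],
    tm_evidence: Iterable[EvidenceRow] = (),
    pts1_predictor_evidence: Iterable[EvidenceRow] = (),
    config: PtsMotifConfig = PtsMotifConfig(),
) -> list[CandidateCall]:
    """Run the peroxisomal cascade: motif scan, predictor union, TM filter.

    A protein is a candidate iff (PTS1 motif OR PTS2 motif OR external PTS1
    predictor positive) AND its TMHMM helix count is 0. Tier is ``strong``
    when a motif and the predictor agree, ``weak`` when exactly one channel
    fires. Proteins whose only flaw is predicted TM helices appear in the
    output at tier ``excluded`` so the filtering is auditable; proteins with
    no firing channel are omitted. Proteins absent from the TM table count
    as soluble (0 helices).
    """
    known = {p.id for p in proteins}
    tm_counts = _tm_helix_counts(tm_evidence)
    for pid in tm_counts:
        if pid not in known:
            logger.warning("TM evidence for unknown protein %r ignored", pid)
    predictor = _predictor_positive(pts1_predictor_evidence)

    calls: list[CandidateCall] = []
    for protein in proteins:
        m1 = scan_pts1(protein, config)
        m2 = scan_pts2(protein, config)
        pred = predictor.get(protein.id, False)
        motif = (m1 is not None) or bool(m2)
        if not (motif or pred):
            continue
        helices = tm_counts.get(protein.id, 0)
        evidence = {
            "pts1": m1.motif if m1 else "-",
            "pts2": m2[0].motif if m2 else "-",
            "pts1_predictor": "positive" if pred else "negative",
            "tmhmm": str(helices),
        }
        if helices > 0:
            tier = TIER_EXCLUDED
        elif motif and pred:
            tier = TIER_STRONG
        else:
            tier = TIER_WEAK
        calls.append(CandidateCall(protein.id, "peroxisome", tier, evidence))
    return calls
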