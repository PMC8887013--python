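"""Homology evidence from BLAST hits and cross-species organelle overlap.

Alignment itself happens upstream (BLAST tabular output is consumed, never
computed); this module reduces hit tables to one best hit per (query,
reference set) under an e-value cutoff, and counts the overlap between two
organelle candidate sets through a curated ortholog map.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import ConfigError
from .io import BlastHit

logger = logging.getLogger("orgatlas")


@dataclass(frozen=True)
class HomologyEvidence:
    """Best hit of one query protein against one reference organelle set."""

    protein_id: str
    reference_set: str
    best_subject_id: str
    best_evalue: float
    best_bitscore: float


@dataclass(frozen=True)
class OverlapResult:
    """Overlap between two organelle candidate sets via an ortholog map."""

    set_a_name: str
    set_b_name: str
    shared: tuple[tuple[str, str], ...]
    count_a: int
    count_b: int
    count_shared: int


def collect_homology_evidence(
    blast_hits: Iterable[BlastHit],
    evalue_threshold: float = 1e-10,
) -> list[HomologyEvidence]:
    """Filter hits at the e-value cutoff and keep the best per
    (query, reference set).

    "Best" is highest bitscore; ties break to the lower e-value, then the
    lexicographically smaller subject id. The default cutoff 1e-10 is a
    common organellar-homology choice (no cutoff is prescribed by the
    source screens) and is config-exposed. Filtering keeps hits with
    ``evalue <= threshold``, so raising the threshold never shrinks the
    evidence set.
    """
    if evalue_threshold <= 0:
        raise ConfigError("evalue_threshold must be > 0")
    best: dict[tuple[str, str], BlastHit] = {}
    for hit in blast_hits:
        if hit.evalue > evalue_threshold:
            continue
        key = (hit.query_id, hit.reference_set)
        cur = best.get(key)
        if cur is None or (-hit.bitscore, hit.evalue, hit.subject_id) < (
            -cur.bitscore, cur.evalue, cur.subject_id
        ):
            best[key] = hit
    return [
        HomologyEvidence(q, r, h.subject_id, h.evalue, h.bitscore)
        for (q, r), h in sorted(best.items())
    ]


def shared_organelle_candidates(
    candidates_a: Iterable[str],
    candidates_b: Iterable[str],
    ortholog_map: Sequence[tuple[str, str]],
    set_a_name: str = "A",
    set_b_name: str = "B",
) -> OverlapResult:
    """Count candidates shared between two species' organelle proteomes.

    ``ortholog_map`` lists accepted (id_a, id_b) pairs — e.g. curated
    reciprocal best hits. A pair is shared when id_a is in set A and id_b
    in set B. Map rows touching neither set are logged as a warning.
    """
    set_a = set(candidates_a)
    set_b = set(candidates_b)
    shared: list[tuple[str, str]] = []
    for a, b in ortholog_map:
        if a in set_a and b in set_b:
            shared.append((a, b))
        elif a not in set_a and b not in set_b:
            logger.warning("ortholog pair (%s, %s) matches neither set", a, b)
    shared = sorted(set(shared))
    return OverlapResult(
        set_a_name=set_a_name,
        set_b_name=set_b_name,
        shared=tuple(shared),
        count_a=len(set_a),
        count_b=len(set_b),
        count_shared=len(shared),
    )


def write_overlap_report(result: OverlapResult, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {result.set_a_name} (n={result.count_a}) vs "
                 f"{result.set_b_name} (n={result.count_b}): "
                 f"{result.count_shared} shared\n")
        fh.write("id_a\tid_b\n")
        for a, b in result.shared:
            fh.write(f"{a}\t{b}\n")
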