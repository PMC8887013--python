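"""MRO candidate calling: NTS consensus plus three-line evidence fusion.

The mitochondrion-related organelle (MRO) proteome is inferred from three
independent lines of evidence:

1. homology to reference organelle proteomes (hydrogenosome, mitosome,
   aerobic mitochondrion) collected from BLAST hits,
2. N-terminal targeting-sequence (NTS) predictions from external tools,
   fused by a consensus rule — a protein counts as NTS-positive when at
   least one setting of a *deciding* tool (MultiLoc2 or NommPred by
   default) labels it mitochondrial; TargetP and PSORT II calls are
   recorded as supporting but do not flip the verdict, and plant-model
   settings are dropped because the organism carries no plastid,
3. curated heterologous-localization results (tagged expression in yeast).

The fusion assigns tiers by counting positive channels (>=2 strong ``+``,
exactly 1 weak ``+?``, 0 excluded ``-``) with three documented overrides:

* a curated non-mitochondrial localization excludes a protein whose only
  other support is a single-tool NTS call (the ATP-citrate-lyase pattern);
* hallmark homologs (Tom40, Sam50, mtHSP70, cpn60, cpn10 by default) stay
  at strong tier even when yeast localization fails, because NTS import
  into yeast mitochondria is known to fail for some genuine MRO proteins
  (the cpn10 pattern);
* a protein excluded from the MRO that carries a PTS motif is flagged for
  reassignment to the peroxisomal candidate list (the P5CR pattern).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .calls import TIER_EXCLUDED, TIER_STRONG, TIER_WEAK, CandidateCall
from .errors import ConfigError, InvariantError
from .io import EVIDENCE_TOOLS, EvidenceRow

DEFAULT_HALLMARKS = frozenset({"Tom40", "Sam50", "mtHSP70", "cpn60", "cpn10"})

EXPERIMENTAL_COMPARTMENTS = frozenset(
    {"mitochondrial", "cytosolic", "peroxisomal", "vesicular", "other"}
)


@dataclass(frozen=True)
class ConsensusRuleConfig:
    """Which tools decide, which merely support, and plant-setting policy."""

    deciding_tools: frozenset[str] = frozenset({"multiloc2", "nommpred"})
    supporting_tools: frozenset[str] = frozenset({"targetp2", "psortii"})
    omit_plant_settings: bool = True

    def __post_init__(self) -> None:
        if self.deciding_tools & self.supporting_tools:
            raise ConfigError("deciding and supporting tool sets must be disjoint")
        unknown = (self.deciding_tools | self.supporting_tools) - EVIDENCE_TOOLS
        if unknown:
            raise ConfigError(f"unknown tools in rule config: {sorted(unknown)}")


@dataclass(frozen=True)
class ExperimentalEvidence:
    """One curated heterologous-localization observation."""

    protein_id: str
    observed: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.observed not in EXPERIMENTAL_COMPARTMENTS:
            raise InvariantError(
                f"{self.protein_id}: unknown observed compartment {self.observed!r}"
            )


@dataclass(frozen=True)
class NtsVerdict:
    """Per-protein NTS consensus with its audit trail."""

    protein_id: str
    positive: bool
    contributing: tuple[tuple[str, str], ...] = ()  # deciding (tool, setting)
    supporting: tuple[tuple[str, str], ...] = ()  # supporting-tool positives
    unscored: bool = False


def nts_consensus(
    evidence_rows: Iterable[EvidenceRow],
    rule_config: ConsensusRuleConfig = ConsensusRuleConfig(),
    protein_ids: Iterable[str] | None = None,
) -> dict[str, NtsVerdict]:
    """Fuse per-tool NTS calls into one verdict per protein.

    Positive iff at least one (deciding tool, setting) pair labels the
    protein mitochondrial. Supporting-tool mitochondrial calls are recorded
    but never flip the verdict. When ``protein_ids`` is given, proteins
    with no evidence rows are emitted as negative with ``unscored=True``.
    """
    contributing: dict[str, set[tuple[str, str]]] = {}
    supporting: dict[str, set[tuple[str, str]]] = {}
    scored: set[str] = set()
    observed: set[str] = set()
    for row in evidence_rows:
        observed.add(row.protein_id)
        if rule_config.omit_plant_settings and row.setting.lower() == "plant":
            continue
        if row.tool in rule_config.deciding_tools | rule_config.supporting_tools:
            scored.add(row.protein_id)
        if row.label != "mitochondrial":
            continue
        if row.tool in rule_config.deciding_tools:
            contributing.setdefault(row.protein_id, set()).add((row.tool, row.setting))
        elif row.tool in rule_config.supporting_tools:
            supporting.setdefault(row.protein_id, set()).add((row.tool, row.setting))

    ids = observed | scored | set(contributing) | set(supporting)
    if protein_ids is not None:
        ids |= set(protein_ids)
    verdicts: dict[str, NtsVerdict] = {}
    for pid in sorted(ids):
        verdicts[pid] = NtsVerdict(
            protein_id=pid,
            positive=pid in contributing,
            contributing=tuple(sorted(contributing.get(pid, ()))),
            supporting=tuple(sorted(supporting.get(pid, ()))),
            unscored=pid not in scored,
        )
    return verdicts


def _experimental_by_protein(
    experimental_evidence: Iterable[ExperimentalEvidence],
) -> dict[str, ExperimentalEvidence]:
    by_id: dict[str, ExperimentalEvidence] = {}
    for ev in experimental_evidence:
        prev = by_id.get(ev.protein_id)
        if prev is not None and prev.observed != ev.observed:
            raise InvariantError(
                f"conflicting experimental rows for {ev.protein_id!r}: "
                f"{prev.observed} vs {ev.observed} (curation required)"
            )
        by_id[ev.protein_id] = ev
    return by_id


def integrate_mro_evidence(
    nts_verdicts: Mapping[str, NtsVerdict],
    homology_evidence: Iterable,
    experimental_evidence: Iterable[ExperimentalEvidence] = (),
    hallmark_set: frozenset[str] | set[str] = DEFAULT_HALLMARKS,
    pts_positive: set[str] | frozenset[str] = frozenset(),
) -> list[CandidateCall]:
    """Fuse the three evidence lines into tiered MRO calls.

    ``homology_evidence`` is an iterable of
    :class:`~orgatlas.homology.HomologyEvidence`. A protein counts as a
    hallmark when its own id or any best-hit subject id is in
    ``hallmark_set``. ``pts_positive`` names proteins carrying a PTS motif;
    an excluded protein in that set is flagged ``reassignment=peroxisome``.

    Output is deterministic: sorted by protein id, independent of input
    order. Conflicting duplicate experimental rows are a hard error.
    """
    homology: dict[str, list] = {}
    for ev in homology_evidence:
        homology.setdefault(ev.protein_id, []).append(ev)
    experimental = _experimental_by_protein(experimental_evidence)

    ids = sorted(set(nts_verdicts) | set(homology) | set(experimental))
    calls: list[CandidateCall] = []
    for pid in ids:
        verdict = nts_verdicts.get(pid)
        nts_pos = bool(verdict and verdict.positive)
        n_deciding = len(verdict.contributing) if verdict else 0
        hits = sorted(
            homology.get(pid, []), key=lambda h: (h.reference_set, h.best_subject_id)
        )
        has_homology = bool(hits)
        hallmark = pid in hallmark_set or any(
            h.best_subject_id in hallmark_set for h in hits
        )
        exp = experimental.get(pid)
        exp_positive = exp is not None and exp.observed == "mitochondrial"
        exp_negative = exp is not None and exp.observed != "mitochondrial"

        if hallmark:
            # hallmark homology retains the protein even when heterologous
            # localization fails (NTS import into yeast is unreliable here)
            tier = TIER_STRONG
        elif exp_negative and nts_pos and n_deciding == 1 and not has_homology:
            # curated non-mitochondrial localization overrides a lone
            # single-tool NTS call
            tier = TIER_EXCLUDED
        else:
            n_positive = int(has_homology) + int(nts_pos) + int(exp_positive)
            if n_positive >= 2:
                tier = TIER_STRONG
            elif n_positive == 1:
                tier = TIER_WEAK
            else:
                tier = TIER_EXCLUDED

        if verdict is None:
            nts_summary = "unscored"
        elif nts_pos:
            nts_summary = "positive(" + ",".join(
                f"{t}:{s}" for t, s in verdict.contributing
            ) + ")"
        elif verdict.unscored:
            nts_summary = "unscored"
        else:
            nts_summary = "negative"
        evidence = {
            "nts": nts_summary,
            "homology": ";".join(
                f"{h.reference_set}:{h.best_subject_id}" for h in hits
            ) or "-",
            "experimental": exp.observed if exp else "-",
            "hallmark": "yes" if hallmark else "-",
        }
        if tier == TIER_EXCLUDED and pid in pts_positive:
            evidence["reassignment"] = "peroxisome"
        calls.append(CandidateCall(pid, "MRO", tier, evidence))
    return calls
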