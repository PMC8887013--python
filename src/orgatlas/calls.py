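"""Candidate localization calls and the confidence-tier vocabulary.

A :class:`CandidateCall` is the unit of output of both organelle pipelines:
a protein, the compartment it is inferred to occupy (MRO or peroxisome), a
confidence tier, and a per-channel evidence summary from which the verdict
can be audited.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .errors import InvariantError

#: Confidence tiers and the symbols used in tabular output:
#: ``+`` confidently localized, ``+?`` localized with low confidence,
#: ``-`` excluded from the organelle proteome.
TIER_STRONG = "strong"
TIER_WEAK = "weak"
TIER_EXCLUDED = "excluded"

TIERS = (TIER_STRONG, TIER_WEAK, TIER_EXCLUDED)

TIER_TO_SYMBOL = {TIER_STRONG: "+", TIER_WEAK: "+?", TIER_EXCLUDED: "-"}
SYMBOL_TO_TIER = {v: k for k, v in TIER_TO_SYMBOL.items()}

COMPARTMENTS = ("MRO", "peroxisome")


@dataclass(frozen=True)
class CandidateCall:
    """A protein's inferred compartment with confidence tier and evidence.

    Parameters
    ----------
    protein_id:
        Identifier of the protein in the query proteome.
    compartment:
        ``"MRO"`` or ``"peroxisome"``.
    tier:
        ``"strong"`` (+), ``"weak"`` (+?) or ``"excluded"`` (-).
    evidence:
        Mapping of evidence channel name to a short human-readable verdict
        (e.g. ``{"pts1": "SKL", "tmhmm": "0"}``). Every verdict traces back
        to an evidence row or a motif match.
    """

    protein_id: str
    compartment: str
    tier: str
    evidence: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise InvariantError(f"unknown compartment {self.compartment!r}")
        if self.tier not in TIERS:
            raise InvariantError(f"unknown tier {self.tier!r}")

    @property
    def tier_symbol(self) -> str:
        return TIER_TO_SYMBOL[self.tier]
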