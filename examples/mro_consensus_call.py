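"""Fuse three evidence lines into tiered MRO candidate calls.

Reconstructs three instructive arbitration patterns: a hallmark chaperonin
whose yeast localization failed, a weakly predicted protein contradicted by
yeast vesicles, and a protein reassigned to the peroxisome list because it
carries a PTS motif.
"""
from orgatlas import (
    EvidenceRow,
    ExperimentalEvidence,
    HomologyEvidence,
    integrate_mro_evidence,
    nts_consensus,
)

nts_rows = [
    EvidenceRow("cpn10", "multiloc2", "animal", "mitochondrial"),
    EvidenceRow("acl", "nommpred", "MRO", "mitochondrial"),
    EvidenceRow("p5cr", "multiloc2", "fungal", "mitochondrial"),
    EvidenceRow("hydA", "multiloc2", "animal", "mitochondrial"),
    EvidenceRow("hydA", "nommpred", "MRO", "mitochondrial"),
]
homology = [
    HomologyEvidence("cpn10", "Mb_hydrogenosome", "cpn10", 1e-60, 310.0),
    HomologyEvidence("hydA", "Mb_hydrogenosome", "Mb_HydA", 1e-80, 420.0),
]
experimental = [
    ExperimentalEvidence("cpn10", "cytosolic", "failed to enter yeast mitochondria"),
    ExperimentalEvidence("acl", "vesicular", "non-mitochondrial vesicles in yeast"),
    ExperimentalEvidence("p5cr", "cytosolic", "cytosolic in yeast; C-tag masks PTS1"),
    ExperimentalEvidence("hydA", "mitochondrial", "colocalized with MitoTracker"),
]

verdicts = nts_consensus(nts_rows)
calls = integrate_mro_evidence(verdicts, homology, experimental,
                               pts_positive={"p5cr"})
for call in calls:
    print(f"{call.protein_id:<6} {call.tier_symbol:<3} {call.evidence}")
print()
print("hydA is '+' (homology + NTS + yeast mitochondria all agree); cpn10 is")
print("retained at '+' because hallmark homology outweighs failed yeast import;")
print("acl is '-' (lone single-tool NTS call contradicted by yeast); p5cr is")
print("'-' for the MRO but flagged for reassignment to the peroxisome list.")
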