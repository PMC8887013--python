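"""Scan a small proteome for peroxisomal targeting signals.

Builds four proteins in memory, runs the PTS1/PTS2 grammar plus the
transmembrane filter, and prints the resulting candidate table.
"""
from orgatlas import EvidenceRow, ProteinRecord, call_peroxisomal_candidates

proteins = [
    # glutamate-dehydrogenase-like: terminal SKL, soluble
    ProteinRecord("gdh", "glutamate dehydrogenase", "MSTAYKEQNVLRAGTPYVSKL"),
    # decoy ending in an excluded tripeptide: never called
    ProteinRecord("decoy", "excluded-tripeptide decoy", "MSTAYKEQNVLRAGTPYVPRM"),
    # PTS2 nonapeptide near the N-terminus
    ProteinRecord("thiolase", "PTS2 carrier", "MARLQSTVSHLEKAGNNDDWQPTV"),
    # membrane protein with a motif: filtered out by the TM evidence
    ProteinRecord("carrier", "membrane protein", "MSTAYKEQNVLRAGTPYVSKL"),
]
tm_evidence = [EvidenceRow("carrier", "tmhmm", "default", "membrane", 3.0)]

calls = call_peroxisomal_candidates(proteins, tm_evidence)
print(f"{'protein':<10} {'tier':<4} evidence")
for call in calls:
    print(f"{call.protein_id:<10} {call.tier_symbol:<4} {call.evidence}")
print()
print("'+?' marks a candidate supported by one channel (motif or external")
print("predictor); '-' marks a motif-bearing protein rejected because TMHMM")
print("predicts membrane helices — the grammar targets soluble matrix proteins.")
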