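"""Count organelle candidates shared between two species.

Uses a curated ortholog map to intersect a peroxisomal candidate list with
a partner species' published set — the overlap that matters biologically is
small and enzyme-level, so the map is an explicit input, not recomputed.
"""
from orgatlas import shared_organelle_candidates

this_study = ["PPP", "Nudt", "myoIDH", "DLDH", "GDH", "PNPO", "P5CR", "PCL"]
partner = ["Mb_PPP", "Mb_Nudt", "Mb_myoIDH", "Mb_DLDH", "Mb_MDH", "Mb_ACSL"]
ortholog_map = [
    ("PPP", "Mb_PPP"),
    ("Nudt", "Mb_Nudt"),
    ("myoIDH", "Mb_myoIDH"),
    ("DLDH", "Mb_DLDH"),
]

result = shared_organelle_candidates(this_study, partner, ortholog_map,
                                     "pelomyxa_peroxisome", "mastigamoeba_peroxisome")
print(f"{result.set_a_name}: {result.count_a} candidates")
print(f"{result.set_b_name}: {result.count_b} candidates")
print(f"shared: {result.count_shared}")
for a, b in result.shared:
    print(f"  {a} <-> {b}")
print()
print("Only 4 of the candidates are shared — peroxisomal processing peptidase,")
print("nudix hydrolase, myo-inositol 2-dehydrogenase and d-lactate")
print("dehydrogenase — showing how divergent anaerobic peroxisome content is")
print("even between related amoebae.")
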