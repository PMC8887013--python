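# Methods

This note documents the models and procedures `orgatlas` implements, the
defaults that matter, what the synthetic generators do and do not emulate,
and the design choices made where the method left room.

## Peroxisomal targeting-signal grammar

PTS1 is modelled as a closed set of C-terminal tripeptides: the positional
pattern `[SAP][KR][LM]` (12 expansions) minus the excluded tripeptides
{AKM, PKM, PRM}, plus the literal SRI — 10 tripeptides under the defaults.
Proline at position −3 and methionine at position −1 are unusual for PTS1
grammars but experimentally supported in a related archamoeba, which is why
they are in the default classes rather than options. Matching is strictly
terminal: only the last three residues are read, and the reported position
is `len − 2` (1-based). Proteins shorter than three residues are logged and
skipped, not errors.

PTS2 is the nonapeptide `R[LI]x(5)HL`. The second-position class is
configurable to `{L,I,V}` because both variants circulate in the
literature for this organism group; `{L,I}` is the default and the switch
(`PtsMotifConfig.with_pts2_variant("LIV")`) is explicit so the discrepancy
stays visible. The whole 9-residue span must lie within the first
`pts2_window` residues; the default of 40 generously covers known PTS2
placements (the signal is defined only as "N-terminal") and is pinned by
tests so a silent change would be caught. All overlapping occurrences are
reported. Ambiguous residues (X, B, Z, U) never satisfy a class position —
conservative calling.

The candidate cascade unions the motif channel with an external
PTS1-predictor positive, then removes every protein with ≥ 1 TMHMM-predicted
helix. Proteins absent from the TMHMM table count as soluble, since the
screen filters on positive TMHMM calls only. Tiering: motif and predictor
agree → `+` (strong); exactly one channel → `+?` (weak); TM-filtered
motif/predictor carriers are emitted at `-` so the filtering is auditable;
proteins with no firing channel are omitted from the table. Order of motif
union and TM filter is observationally irrelevant to the final set; it is
fixed (union first) for reproducible intermediate logs.

## NTS consensus and MRO evidence fusion

Per-tool predictions are reduced to one verdict per protein: positive iff
at least one *(deciding tool, setting)* pair labels the protein
mitochondrial. Deciding tools default to {MultiLoc2, NommPred} (any
setting); TargetP 2 and PSORT II are recorded as supporting but never flip
the verdict; plant-model settings are dropped by default because the
organism carries no plastid. Proteins whose rows are all filtered, or that
appear only in the supplied protein list, come out negative with an
`unscored` flag.

Fusion counts three channels — homology (any retained best hit), NTS
consensus, curated experimental mitochondrial localization — and assigns
`+` at ≥ 2, `+?` at 1, `-` at 0. Three overrides, in the order they are
evaluated:

1. **Hallmark homology** (default set {Tom40, Sam50, mtHSP70, cpn60,
   cpn10}) forces `+` even when yeast localization failed: NTS presequences
   of reduced organelles are known to import poorly into yeast
   mitochondria, so a failed heterologous localization cannot overturn an
   unambiguous marker. A protein counts as hallmark when its own id or any
   best-hit subject id is in the hallmark set (the set names families, the
   evidence rows carry subject ids — matching on both covers curated and
   automatic naming).
2. **Experimental contradiction of a lone call**: a curated
   non-mitochondrial localization excludes a protein whose only other
   support is a single *(tool, setting)* NTS positive with no homology.
   This cannot collide with override 1 because its precondition excludes
   homology-supported proteins.
3. **Peroxisomal reassignment**: an excluded protein that carries a PTS
   motif is flagged `reassignment=peroxisome`. The fusion function takes
   the PTS-positive id set as an optional keyword (`pts_positive`) because
   the motif scan is a separate stage; the orchestrator wires it through.

The ≥2/1/0 thresholds formalize a confidence scheme the source material
describes only graphically; the output vocabulary (`-`/`+`/`+?`) is fixed,
the combination rule is config-visible and pinned by an exhaustive
truth-table test (27 channel combinations × the override fixtures).
Conflicting duplicate experimental rows are a hard error — they encode
wet-lab results and need curation, not arbitration.

## Intron extraction and statistics

Gene models store exons as 1-based inclusive intervals sorted by start,
strand-agnostically; interval arithmetic is half-open internally and
converted back at the boundary, which removes the classic off-by-one in
intron derivation. An mRNA with n exons yields n−1 introns. Donor and
acceptor dinucleotides are reported in transcription orientation: on the
minus strand the donor is the reverse complement of the intron's last two
genomic bases. Classes: GT-AG, GC-AG, everything else — including any N,
no imputation — is `other`. Introns shorter than 4 nt (the floor at which
donor and acceptor are disjoint) are kept, flagged `too_short`, and
classed `other`.

Density = introns / genes under an explicit isoform policy:
`all_mrnas` (denominator mRNAs), `longest_isoform` (one isoform per gene,
ties to the lexicographically smaller mRNA id), or the default
`unique_introns_per_gene` (distinct coordinates per gene; denominator
genes). The default avoids double-counting introns shared between
isoforms; the policy is recorded in the summary because published
intron-density figures rarely state their denominator, and the three
policies legitimately disagree on isoform-rich annotations. Zero genes is
an error; zero introns gives density 0 and an empty fraction map.

## Homology and overlap

BLAST tabular hits are filtered at `evalue ≤ threshold` (default 1e-10, a
common organellar-homology cutoff made explicit because none is prescribed)
and reduced to the best hit per (query, reference set): highest bitscore,
ties to lower e-value, then lexicographic subject id — total and
deterministic. Cross-species overlap is counted through a *curated*
ortholog map rather than a reciprocal-best-hit engine: alignment stays out
of scope and the overlap stays reproducible from supplied tables, covering
both gene-name and sequence-level orthology conventions.

## Synthetic generators: what a green test establishes

The proteome generator plants, on a uniform background over the 20
standard residues (composition is configurable but does not affect
rule-based calls), five signal classes: PTS1 tripeptides drawn uniformly
from the allowed set; PTS2 nonapeptides at a uniform position inside the
window; excluded-tripeptide decoys; transmembrane decoys (a hydrophobic
19-mer *plus* a valid PTS1 ending, so the TM filter is load-bearing in
recovery tests, not decorative); and mitochondrial-truth proteins for the
evidence simulator. Accidental motifs are scrubbed from classes that must
not carry them (the terminal tripeptide is redrawn; spurious PTS2 matches
have their leading R mutated), so perfect-evidence precision/recall = 1.0
is a property of the stated world. Class counts are `round(fraction × n)`;
class-to-id assignment is a seeded permutation.

The evidence simulator draws each *(tool, setting, protein)* call
independently: positive with probability `sensitivity` on truth-positives
and `1 − specificity` otherwise. It emulates calibrated, independent
predictors; real predictors are correlated (they share training data and
the same N-terminus), so recovery under simulated sensitivity 0.8 bounds
sampling behaviour, not real-tool behaviour.

The genome generator emits one contig per gene: Poisson intron counts
(default mean 7.43), exon lengths uniform on [100, 300] nt, intron lengths
uniform on [40, 500] nt (any positive-length model suffices for rule
testing), strands random, boundary dinucleotides written into the sequence
per the drawn class (`other` defaults to GT-GG, a boundary observed
exactly once in the genomes this models). It does not emulate alternative
splicing, overlapping genes, intron-length distributions of real genomes,
or sequencing error. A single seeded NumPy generator is consumed in
documented field order per invocation; same seed, same bytes.

## Numerical and interface choices

* Tables are plain TSV; the run manifest is sorted-key JSON with SHA-256
  checksums of every input and report. Identical config + inputs give
  byte-identical outputs (the output directory itself is excluded from the
  config echo for that reason).
* Evidence dialects are declared column maps (documented in `orgatlas.io`),
  never sniffed — predictor output formats drift between versions, and
  unknown labels degrade to `other` with the raw token logged rather than
  failing or silently remapping. Which export format two of the predictors
  archived is not documented anywhere authoritative, so those dialects are
  best-effort and user-overridable via the `generic` dialect.
* FASTA normalization: upcase, strip a single terminal `*`; an internal
  stop is a hard error (broken gene model), as are duplicate ids and empty
  sequences.
* Class fractions in summaries are exact ratios of integer counts; no
  smoothing anywhere.

## Known limitations

* The exact boolean combination behind published MRO/peroxisome candidate
  counts for any particular organism is typically not printed; the decision
  table here is a documented reconstruction, config-exposed, and validated
  against its own specification — not against an archived predictor-output
  bundle, which would require the external predictors to be re-run.
* The external predictors themselves (TargetP 2, PSORT II, MultiLoc2,
  NommPred, TMHMM, the PTS1 predictor) are consumed, never re-implemented;
  there is deliberately no in-house hydrophobicity fallback for missing TM
  evidence.
* `read_gff3_gene_models` requires an ID/Parent-linked gene→mRNA→exon (or
  CDS) hierarchy; GTF and attribute-free dialects are out of scope.
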