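"""End-to-end orchestration of the organelle-annotation stages.

:func:`run_pipeline` wires the library stages together from a validated
:class:`PipelineConfig`: peroxisomal motif scan, MRO consensus call, intron
statistics and cross-species overlap, each optional depending on which
inputs are configured. Outputs are plain TSV reports plus a JSON run
manifest carrying input/output checksums and a config echo; identical
config and inputs produce byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

from . import io
from .errors import ConfigError, OrgAtlasError, PipelineError
from .homology import collect_homology_evidence, shared_organelle_candidates, write_overlap_report
from .introns import extract_introns, summarize_intron_stats, write_intron_summary, write_intron_table
from .mro import ConsensusRuleConfig, DEFAULT_HALLMARKS, integrate_mro_evidence, nts_consensus
from .pts import PtsMotifConfig, call_peroxisomal_candidates, scan_pts1, scan_pts2


@dataclass(frozen=True)
class PipelineConfig:
    """Paths and parameters of one pipeline run.

    Stages activate based on what is configured: the motif scan needs
    ``proteome_path``; the MRO call needs ``nts_tables``; intron statistics
    need ``genome_path`` and ``gff_path``; the overlap stage needs
    ``ortholog_map_path`` plus ``overlap_reference_ids``.
    """

    outdir: str | Path
    proteome_path: str | Path | None = None
    tm_table: str | Path | None = None
    pts1_predictor_table: str | Path | None = None
    #: (path, dialect) pairs of NTS predictor outputs
    nts_tables: tuple[tuple[str, str], ...] = ()
    experimental_table: str | Path | None = None
    #: (path, reference_set) pairs of BLAST outfmt-6 tables
    blast_tables: tuple[tuple[str, str], ...] = ()
    genome_path: str | Path | None = None
    gff_path: str | Path | None = None
    ortholog_map_path: str | Path | None = None
    #: the partner species' organelle candidate id set for the overlap stage
    overlap_reference_ids: tuple[str, ...] = ()
    overlap_names: tuple[str, str] = ("this_study", "reference_species")
    motif_config: PtsMotifConfig = PtsMotifConfig()
    rule_config: ConsensusRuleConfig = ConsensusRuleConfig()
    hallmarks: frozenset[str] = DEFAULT_HALLMARKS
    evalue_threshold: float = 1e-10
    isoform_policy: str = "unique_introns_per_gene"

    def validate(self) -> None:
        """Check every referenced input path exists before any stage runs."""
        paths = [self.proteome_path, self.tm_table, self.pts1_predictor_table,
                 self.experimental_table, self.genome_path, self.gff_path,
                 self.ortholog_map_path]
        paths += [p for p, _ in self.nts_tables] + [p for p, _ in self.blast_tables]
        for p in paths:
            if p is not None and not Path(p).exists():
                raise ConfigError(f"configured input does not exist: {p}")
        if (self.genome_path is None) != (self.gff_path is None):
            raise ConfigError("genome_path and gff_path must be configured together")


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _config_echo(config: PipelineConfig) -> dict:
    def clean(value):
        if isinstance(value, (frozenset, set)):
            return sorted(value)
        if isinstance(value, Path):
            return str(value)
        if dataclasses.is_dataclass(value) and not isinstance(value, type):
            return {k: clean(v) for k, v in dataclasses.asdict(value).items()}
        if isinstance(value, (list, tuple)):
            return [clean(v) for v in value]
        if isinstance(value, dict):
            return {k: clean(v) for k, v in value.items()}
        return value

    # outdir is where the manifest itself lives; leaving it out keeps reruns
    # into different directories byte-identical
    return {
        f.name: clean(getattr(config, f.name))
        for f in dataclasses.fields(config)
        if f.name != "outdir"
    }


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run every configured stage and return the report paths.

    Any stage failure raises :class:`PipelineError` naming the stage; the
    manifest is only written when all configured stages succeeded, so a
    missing manifest marks a partial output directory as incomplete.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    proteins = None
    if config.proteome_path is not None:
        proteins = io.read_protein_fasta(config.proteome_path)

    pts_ids: set[str] = set()
    perox_calls = None
    if proteins is not None:
        try:
            tm_rows = (
                io.read_evidence_table(config.tm_table, "tmhmm")
                if config.tm_table else []
            )
            pred_rows = (
                io.read_evidence_table(config.pts1_predictor_table, "pts1predictor")
                if config.pts1_predictor_table else []
            )
            perox_calls = call_peroxisomal_candidates(
                proteins, tm_rows, pred_rows, config.motif_config
            )
            pts_ids = {
                p.id for p in proteins
                if scan_pts1(p, config.motif_config) or scan_pts2(p, config.motif_config)
            }
            path = outdir / "peroxisome_candidates.tsv"
            io.write_candidate_table(perox_calls, path)
            outputs["peroxisome_candidates"] = path
        except OrgAtlasError as exc:
            raise PipelineError("scan-pts", str(exc)) from exc

    if config.nts_tables:
        try:
            known = {p.id for p in proteins} if proteins else None
            rows = []
            for table_path, dialect in config.nts_tables:
                rows.extend(io.read_evidence_table(table_path, dialect, known))
            verdicts = nts_consensus(rows, config.rule_config, protein_ids=known)
            homology = []
            for table_path, reference_set in config.blast_tables:
                homology.extend(
                    collect_homology_evidence(
                        io.read_blast_outfmt6(table_path, reference_set),
                        config.evalue_threshold,
                    )
                )
            experimental = (
                io.read_experimental_table(config.experimental_table)
                if config.experimental_table else []
            )
            mro_calls = integrate_mro_evidence(
                verdicts, homology, experimental, config.hallmarks, pts_ids
            )
            path = outdir / "mro_candidates.tsv"
            io.write_candidate_table(mro_calls, path)
            outputs["mro_candidates"] = path
        except OrgAtlasError as exc:
            raise PipelineError("mro-call", str(exc)) from exc

    if config.genome_path is not None:
        try:
            genome = io.read_genome_fasta(config.genome_path)
            models = io.read_gff3_gene_models(config.gff_path)
            introns = extract_introns(models, genome)
            summary = summarize_intron_stats(introns, models, config.isoform_policy)
            table_path = outdir / "introns.tsv"
            summary_path = outdir / "intron_summary.tsv"
            write_intron_table(introns, table_path)
            write_intron_summary(summary, summary_path)
            outputs["introns"] = table_path
            outputs["intron_summary"] = summary_path
        except OrgAtlasError as exc:
            raise PipelineError("intron-stats", str(exc)) from exc

    if config.ortholog_map_path is not None:
        try:
            if perox_calls is None:
                raise ConfigError("overlap stage needs the motif-scan stage")
            mapping = io.read_ortholog_map(config.ortholog_map_path)
            ours = [
                c.protein_id for c in perox_calls if c.tier != "excluded"
            ]
            result = shared_organelle_candidates(
                ours, config.overlap_reference_ids, mapping, *config.overlap_names
            )
            path = outdir / "overlap.tsv"
            write_overlap_report(result, path)
            outputs["overlap"] = path
        except OrgAtlasError as exc:
            raise PipelineError("overlap", str(exc)) from exc

    try:
        pkg_version = version("orgatlas")
    except PackageNotFoundError:  # running from a source tree
        pkg_version = "unknown"
    manifest = {
        "package": {"name": "orgatlas", "version": pkg_version},
        "config": _config_echo(config),
        "inputs": {
            str(p): _sha256(Path(p))
            for p in sorted(
                str(x) for x in (
                    [config.proteome_path, config.tm_table,
                     config.pts1_predictor_table, config.experimental_table,
                     config.genome_path, config.gff_path,
                     config.ortholog_map_path]
                    + [p for p, _ in config.nts_tables]
                    + [p for p, _ in config.blast_tables]
                ) if x is not None
            )
        },
        "outputs": {name: _sha256(path) for name, path in sorted(outputs.items())},
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    outputs["manifest"] = manifest_path
    return outputs
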