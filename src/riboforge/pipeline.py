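"""End-to-end orchestration: ingest -> QC -> transcript calling -> TIS calling
-> variant integration -> proteoform assembly.

Each stage writes a re-loadable flat-file artifact under the output directory
and a JSON manifest records the exact parameter set, so stages are
individually re-runnable and identical configuration + inputs yield identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import annotation as ann_mod
from . import assembly as asm_mod
from . import ingest as ingest_mod
from . import qc as qc_mod
from . import tis as tis_mod
from . import transcripts as tr_mod
from . import variants as var_mod

logger = logging.getLogger("riboforge")


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    gtf: str
    fasta: str
    chx_bam: str
    out_dir: str
    ltm_bam: str | None = None
    sample_vcf: str | None = None
    dbsnp_vcf: str | None = None
    id_map: str | None = None
    canonical_fasta: str | None = None
    combine_canonical: bool = False
    seed: int = 1
    min_protein_len: int = asm_mod.MIN_PROTEIN_LENGTH
    make_plots: bool = False
    tis_params: dict[str, tuple[int, float]] = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        for name in ("gtf", "fasta", "chx_bam"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        for name in ("ltm_bam", "sample_vcf", "dbsnp_vcf", "id_map", "canonical_fasta"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")
        if self.combine_canonical and self.canonical_fasta is None:
            raise ValueError("combine_canonical requires canonical_fasta")
        if self.min_protein_len < 1:
            raise ValueError("min_protein_len must be >= 1")
        for cat, pair in self.tis_params.items():
            if cat not in tis_mod.DEFAULT_PARAMS:
                raise ValueError(f"unknown TIS category {cat!r}")
            mc, dr = pair
            if int(mc) < 0:
                raise ValueError("min_count must be >= 0")

    def resolved_tis_params(self) -> dict[str, tis_mod.CategoryThresholds]:
        params = tis_mod.default_params()
        for cat, (mc, dr) in self.tis_params.items():
            params[cat] = tis_mod.CategoryThresholds(int(mc), float(dr))
        return params


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Run all stages in order; returns a manifest of output paths."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    paths: dict[str, str] = {}

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("annotation")
        annotation = ann_mod.load_annotation(config.gtf, config.fasta)
    except Exception as exc:
        raise StageError("annotation", exc) from exc

    try:
        stage("ingest")
        chx_qc = ingest_mod.build_profile(
            config.chx_bam, ingest_mod.UNIQUE_ONLY, ingest_mod.ELONGATING
        )
        chx_db = ingest_mod.build_profile(
            config.chx_bam, ingest_mod.MULTIMAP_LEQ_15, ingest_mod.ELONGATING
        )
        ltm_db = None
        if config.ltm_bam is not None:
            ltm_db = ingest_mod.build_profile(
                config.ltm_bam, ingest_mod.MULTIMAP_LEQ_15, ingest_mod.INITIATING
            )
        else:
            logger.warning(
                "no initiating sample: TIS stage restricted to aTIS NO_DATA semantics"
            )
        tracks = out / "tracks"
        tracks.mkdir(exist_ok=True)
        for name, prof in [("chx", chx_db)] + ([("ltm", ltm_db)] if ltm_db else []):
            for strand, tag in (("+", "fw"), ("-", "rev")):
                p = tracks / f"{name}_{tag}.bedgraph"
                ingest_mod.write_bedgraph(prof, p, strand)
                paths[f"track_{name}_{tag}"] = str(p)
        chx_qc.write_tsv(out / "psites_chx_unique.tsv")
        chx_db.write_tsv(out / "psites_chx_multimap.tsv")
        paths["psites_chx_unique"] = str(out / "psites_chx_unique.tsv")
        paths["psites_chx_multimap"] = str(out / "psites_chx_multimap.tsv")
        if ltm_db is not None:
            ltm_db.write_tsv(out / "psites_ltm_multimap.tsv")
            paths["psites_ltm_multimap"] = str(out / "psites_ltm_multimap.tsv")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("ingest", exc) from exc

    try:
        stage("qc")
        qc_dir = out / "qc"
        qc_dir.mkdir(exist_ok=True)
        meta = qc_mod.metagenic_classification(chx_qc, annotation)
        meta.to_frame().to_csv(qc_dir / "metagenic.tsv", sep="\t", index=False)
        meta.biotypes_to_frame().to_csv(qc_dir / "biotypes.tsv", sep="\t", index=False)
        dist = qc_mod.gene_distribution(chx_qc, annotation)
        dist.to_csv(qc_dir / "gene_distribution.tsv", sep="\t", index=False)
        paths["qc_metagenic"] = str(qc_dir / "metagenic.tsv")
        paths["qc_biotypes"] = str(qc_dir / "biotypes.tsv")
        paths["qc_gene_distribution"] = str(qc_dir / "gene_distribution.tsv")
        if config.make_plots:
            qc_mod.plot_gene_distribution(dist, qc_dir)
    except Exception as exc:
        raise StageError("qc", exc) from exc

    try:
        stage("transcripts")
        calls = tr_mod.call_all(annotation, chx_db)
        tr_mod.write_calls_tsv(calls, out / "transcript_calls.tsv")
        paths["transcript_calls"] = str(out / "transcript_calls.tsv")
        translated_ids = {tid for tid, c in calls.items() if c.is_translated}
    except Exception as exc:
        raise StageError("transcripts", exc) from exc

    try:
        stage("tis")
        params = config.resolved_tis_params()
        if ltm_db is not None:
            tis_calls = tis_mod.call_tis(
                annotation, ltm_db, chx_db, params=params, translated_ids=translated_ids
            )
        else:
            # without initiating data every translated transcript's annotated
            # start is emitted as NO_DATA
            empty = ingest_mod.PsiteProfile(
                condition=ingest_mod.INITIATING,
                multimap_policy=ingest_mod.MULTIMAP_LEQ_15,
            )
            tis_calls = tis_mod.call_tis(
                annotation, empty, chx_db, params=params, translated_ids=translated_ids
            )
        tis_mod.write_calls_tsv(tis_calls, out / "tis_calls.tsv")
        paths["tis_calls"] = str(out / "tis_calls.tsv")
    except Exception as exc:
        raise StageError("tis", exc) from exc

    try:
        stage("variants")
        final_variants = var_mod.integrate_variants(
            annotation,
            config.chx_bam if config.dbsnp_vcf else None,
            config.sample_vcf,
            config.dbsnp_vcf,
        )
        var_mod.write_variants_tsv(final_variants, out / "variants.tsv")
        paths["variants"] = str(out / "variants.tsv")
    except Exception as exc:
        raise StageError("variants", exc) from exc

    try:
        stage("assemble")
        id_map = asm_mod.read_id_map(config.id_map) if config.id_map else None
        canonical = (
            asm_mod.read_canonical_fasta(config.canonical_fasta)
            if config.canonical_fasta
            else None
        )
        records = asm_mod.assemble(
            annotation.transcripts,
            annotation.genome,
            tis_calls,
            variants=final_variants,
            seed=config.seed,
            min_protein_length=config.min_protein_len,
            id_map=id_map,
            canonical_seqs=canonical,
        )
        fasta_out = out / "proteoforms.fasta"
        asm_mod.write_fasta(
            records,
            fasta_out,
            canonical_seqs=canonical,
            include_canonical_db=config.combine_canonical,
        )
        paths["proteoforms_fasta"] = str(fasta_out)
    except Exception as exc:
        raise StageError("assemble", exc) from exc

    manifest = {
        "config": dataclasses.asdict(config),
        "outputs": paths,
        "n_transcripts": len(annotation.transcripts),
        "n_translated": len(translated_ids),
        "n_tis_calls": len(tis_calls),
        "n_variants": len(final_variants),
        "n_proteoforms": len(records),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    paths["manifest"] = str(out / "manifest.json")
    return paths
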