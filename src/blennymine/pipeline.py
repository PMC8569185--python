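"""End-to-end mining pipeline: contigs -> motif candidates -> hits -> profile.

``run_pipeline`` reads a contig FASTA, a 3-column metadata TSV and a query
precursor FASTA, runs motif selection, homology search, unique-hit
deduplication, taxonomic profiling and sequence-logo computation, and writes
a result bundle (hits, unique hits, taxon profile, logo matrices, run
summary). The run summary records the config hash, input checksums and
per-stage counts (contigs in -> motif-selected -> hits -> unique hits). A
failure in any stage aborts with a stage-named message and removes partial
outputs. Inputs are never mutated.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

from blennymine import homology, io, mining
from blennymine.config import PipelineConfig
from blennymine.exceptions import BlennymineError, InputError

logger = logging.getLogger(__name__)

OUTPUT_FILES = (
    "hits.tsv",
    "unique_hits.tsv",
    "taxon_profile.tsv",
    "run_summary.json",
)


@dataclass
class PipelineResult:
    n_contigs: int
    n_selected: int
    n_hits: int
    n_unique_hits: int
    hits: list[homology.AlignmentHit]
    unique_hits: list[homology.UniqueHit]
    profile: homology.TaxonProfile | None
    outdir: Path


def load_contigs(contigs_path: str | Path, metadata_path: str | Path) -> list[mining.Contig]:
    """Join a contig FASTA with its species/taxon metadata table."""
    records = io.read_fasta(contigs_path)
    metadata = io.read_metadata_tsv(metadata_path)
    meta = metadata.set_index("contig_id")
    contigs = []
    for rec in records:
        if rec.id not in meta.index:
            raise InputError(f"contig {rec.id!r} missing from metadata table")
        row = meta.loc[rec.id]
        contigs.append(
            mining.Contig(
                id=rec.id,
                sequence=rec.sequence,
                species=str(row["species"]),
                taxon=str(row["taxon"]),
            )
        )
    return contigs


def load_query(query_path: str | Path, dynA_interval: tuple[int, int]) -> homology.QueryPrecursor:
    records = io.read_fasta(query_path)
    if len(records) != 1:
        raise InputError(f"query FASTA must contain exactly one record, found {len(records)}")
    return homology.QueryPrecursor(
        id=records[0].id, sequence=records[0].sequence, dynA_interval=dynA_interval
    )


def run_pipeline(
    config: PipelineConfig,
    contigs_path: str | Path,
    metadata_path: str | Path,
    query_path: str | Path,
    outdir: str | Path,
) -> PipelineResult:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "load"
    try:
        contigs = load_contigs(contigs_path, metadata_path)
        metadata = io.read_metadata_tsv(metadata_path)
        query = load_query(query_path, config.dynA_interval)

        stage = "select"
        candidates = mining.select_candidates(contigs, motif=config.motif)

        stage = "search"
        hits = homology.search(
            query,
            candidates,
            threshold=config.evalue_threshold,
            min_overlap=config.min_dynA_overlap,
            matrix=config.matrix,
            gap_open=config.gap_open,
            gap_extend=config.gap_extend,
            lam=config.karlin_lambda,
            K=config.karlin_k,
        )

        stage = "dedup"
        unique_hits = homology.dedup_hits(hits)

        stage = "profile"
        taxonomy = dict(zip(metadata["species"], metadata["taxon"]))
        # One transcriptome dataset per species in the fixture layout.
        transcriptomes = (
            metadata.drop_duplicates("species").groupby("taxon")["species"].count().to_dict()
        )
        profile = homology.taxonomic_profile(unique_hits, taxonomy, transcriptomes)

        stage = "logo"
        logos: dict[str, homology.LogoMatrix] = {}
        matures = [h.mature_sequence for h in hits]
        if matures:
            logos["all"] = homology.logo_matrix(
                matures, small_sample_correction=config.small_sample_correction
            )
            by_taxon: dict[str, list[str]] = {}
            for h in hits:
                by_taxon.setdefault(h.taxon, []).append(h.mature_sequence)
            for taxon, seqs in sorted(by_taxon.items()):
                logos[taxon] = homology.logo_matrix(
                    seqs, small_sample_correction=config.small_sample_correction
                )

        stage = "write"
        hits_df = homology.hits_to_frame(hits)
        io.write_tsv(hits_df, outdir / "hits.tsv")
        written.append(outdir / "hits.tsv")
        uh_df = homology.unique_hits_to_frame(unique_hits)
        io.write_tsv(uh_df, outdir / "unique_hits.tsv")
        written.append(outdir / "unique_hits.tsv")
        io.write_tsv(profile.table.reset_index(), outdir / "taxon_profile.tsv")
        written.append(outdir / "taxon_profile.tsv")
        logo_dir = outdir / "logos"
        logo_dir.mkdir(exist_ok=True)
        for name, logo in logos.items():
            path = logo_dir / f"logo_{name}.tsv"
            io.write_tsv(homology.logo_to_frame(logo), path)
            written.append(path)

        summary = {
            "config_hash": config.config_hash,
            "inputs": {
                "contigs": io.checksum_file(contigs_path),
                "metadata": io.checksum_file(metadata_path),
                "query": io.checksum_file(query_path),
            },
            "counts": {
                "contigs_in": len(contigs),
                "motif_selected": candidates.n_contigs,
                "hits": len(hits),
                "unique_hits": sum(u.n_pairs for u in unique_hits),
            },
            "db_len": candidates.db_len,
            "species_with_hits_fraction": profile.species_with_hits_fraction,
            "taxa_with_hits_fraction": profile.taxa_with_hits_fraction,
        }
        with open(outdir / "run_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        written.append(outdir / "run_summary.json")
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        if isinstance(exc, BlennymineError):
            raise type(exc)(f"pipeline stage {stage!r}: {exc}") from exc
        raise BlennymineError(f"pipeline stage {stage!r} failed: {exc}") from exc

    logger.info(
        "pipeline: %d contigs -> %d motif-selected -> %d hits -> %d unique hits",
        len(contigs),
        candidates.n_contigs,
        len(hits),
        sum(u.n_pairs for u in unique_hits),
    )
    return PipelineResult(
        n_contigs=len(contigs),
        n_selected=candidates.n_contigs,
        n_hits=len(hits),
        n_unique_hits=sum(u.n_pairs for u in unique_hits),
        hits=hits,
        unique_hits=unique_hits,
        profile=profile,
        outdir=outdir,
    )
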