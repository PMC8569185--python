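"""Six-frame conceptual translation and motif-based candidate selection.

Transcriptome contigs are translated in all six reading frames without any ORF
calling: translation runs straight through stop codons (rendered ``*``) and
codons containing ``N`` translate to ``X``. A contig becomes a *candidate* for
the homology stage when at least one of its six frame translations contains the
opioid-peptide motif (``YGGF`` by default) as an exact substring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from Bio.Seq import Seq

from blennymine.exceptions import InputError, ParameterError

logger = logging.getLogger(__name__)

VALID_NUCLEOTIDES = frozenset("ACGTN")
CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
DEFAULT_MOTIF = "YGGF"


@dataclass(frozen=True)
class Contig:
    """A nucleotide record with species and taxonomic-group metadata."""

    id: str
    sequence: str
    species: str
    taxon: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InputError(f"contig {self.id!r}: empty sequence")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - VALID_NUCLEOTIDES
        if bad:
            raise InputError(
                f"contig {self.id!r}: invalid nucleotide characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class FrameTranslation:
    """One of the six conceptual translations of a contig.

    ``strand`` is '+' or '-'; ``frame_offset`` (0, 1, 2) is counted on the
    strand being read. The protein may contain '*' (stop, read through) and
    'X' (ambiguous codon).
    """

    contig_id: str
    strand: str
    frame_offset: int
    protein: str


@dataclass(frozen=True)
class MotifOccurrence:
    contig_id: str
    strand: str
    frame_offset: int
    protein_position: int  # 0-based index of motif start in the frame protein
    motif: str


@dataclass
class CandidateSet:
    """Motif-bearing frame translations, grouped by contig.

    ``db_len`` — the total residue count over all selected frame translations —
    is the database length used for E-value computation downstream.
    """

    contigs: dict[str, Contig] = field(default_factory=dict)
    frames: list[FrameTranslation] = field(default_factory=list)
    occurrences: list[MotifOccurrence] = field(default_factory=list)

    @property
    def n_contigs(self) -> int:
        return len(self.contigs)

    @property
    def db_len(self) -> int:
        return sum(len(f.protein) for f in self.frames)


def translate_six_frames(contig: Contig, genetic_code: int = 1) -> list[FrameTranslation]:
    """Conceptually translate a contig in all six reading frames.

    Forward frames translate ``sequence[offset:]``; reverse frames translate
    ``reverse_complement(sequence)[offset:]``. Trailing 1-2 nucleotides that do
    not fill a codon are dropped. No ORF splitting is performed.
    """
    if len(contig.sequence) < 3:
        raise ParameterError(
            f"contig {contig.id!r}: sequence shorter than one codon"
        )
    forward = Seq(contig.sequence)
    reverse = forward.reverse_complement()
    frames: list[FrameTranslation] = []
    for strand, seq in (("+", forward), ("-", reverse)):
        for offset in range(3):
            sub = seq[offset:]
            sub = sub[: len(sub) - len(sub) % 3]
            protein = str(sub.translate(table=genetic_code))
            frames.append(
                FrameTranslation(
                    contig_id=contig.id,
                    strand=strand,
                    frame_offset=offset,
                    protein=protein,
                )
            )
    return frames


def scan_motif(
    translation: FrameTranslation, motif: str = DEFAULT_MOTIF
) -> list[MotifOccurrence]:
    """All (possibly overlapping) exact motif occurrences, left to right."""
    if not motif:
        raise ParameterError("motif must be non-empty")
    bad = set(motif) - set(CANONICAL_RESIDUES)
    if bad:
        raise ParameterError(f"motif contains non-canonical residues: {sorted(bad)}")
    occurrences: list[MotifOccurrence] = []
    start = translation.protein.find(motif)
    while start != -1:
        occurrences.append(
            MotifOccurrence(
                contig_id=translation.contig_id,
                strand=translation.strand,
                frame_offset=translation.frame_offset,
                protein_position=start,
                motif=motif,
            )
        )
        start = translation.protein.find(motif, start + 1)
    return occurrences


def select_candidates(
    contigs: list[Contig],
    motif: str = DEFAULT_MOTIF,
    genetic_code: int = 1,
) -> CandidateSet:
    """Select contigs with >=1 motif occurrence in >=1 of their 6 frames.

    Only the motif-bearing frame translations enter the candidate set (and
    hence the search database); motif-free frames of selected contigs are
    discarded.
    """
    result = CandidateSet()
    if not contigs:
        logger.warning("select_candidates: empty contig dataset")
        return result
    for contig in contigs:
        for frame in translate_six_frames(contig, genetic_code=genetic_code):
            occ = scan_motif(frame, motif=motif)
            if occ:
                result.contigs[contig.id] = contig
                result.frames.append(frame)
                result.occurrences.extend(occ)
    logger.info(
        "select_candidates: %d of %d contigs carry the %s motif",
        result.n_contigs,
        len(contigs),
        motif,
    )
    return result
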