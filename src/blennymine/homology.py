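"""Local protein alignment, significance filtering and downstream sequence analysis.

The search stage is a full affine-gap Smith-Waterman (no heuristic seeding)
scored with BLOSUM62, gap open 11 / gap extend 1 — classic protein-BLAST
defaults. Significance uses the Karlin-Altschul expectation

    E = K * m * n * exp(-lambda * S)

with the published gapped-BLOSUM62 parameters lambda = 0.267, K = 0.041 and
no composition or edge-effect corrections, so E-values are deliberately
simpler than (and will differ somewhat from) NCBI-BLAST's. ``m`` is the query
length and ``n`` the total residue count of the motif-bearing candidate frame
translations being searched.

Retained hits must overlap the query's annotated mature dynorphin A 1-17
segment; the aligned subject residues over that segment are extracted as a
17-column mature peptide (gap '-' where no subject residue aligns), which
feeds deduplication ("a novel sequence, or a known sequence in a new species,
is a unique hit"), taxonomic profiling and sequence-logo matrices.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from blennymine.exceptions import ConfigError, InputError, ParameterError
from blennymine.mining import CANONICAL_RESIDUES, CandidateSet, FrameTranslation

logger = logging.getLogger(__name__)

# Published Karlin-Altschul parameters for gapped BLOSUM62 (open 11, extend 1).
GAPPED_BLOSUM62_LAMBDA = 0.267
GAPPED_BLOSUM62_K = 0.041

DEFAULT_GAP_OPEN = 11
DEFAULT_GAP_EXTEND = 1
NONCANONICAL_SCORE = -4  # 'X' and '*' against anything

GAP_CHAR = "-"
DYNA_LENGTH = 17

_MATRIX_CACHE: dict[str, dict[tuple[str, str], int]] = {}


def load_matrix(name: str = "BLOSUM62") -> dict[tuple[str, str], int]:
    """Load a substitution matrix as a pair->score dict.

    Pairs involving residues outside the 20 canonical amino acids (notably
    'X' and '*') score :data:`NONCANONICAL_SCORE`.
    """
    if name in _MATRIX_CACHE:
        return _MATRIX_CACHE[name]
    try:
        raw = substitution_matrices.load(name)
    except FileNotFoundError as exc:
        raise ConfigError(f"unknown substitution matrix: {name!r}") from exc
    table: dict[tuple[str, str], int] = {}
    for a in CANONICAL_RESIDUES:
        for b in CANONICAL_RESIDUES:
            table[(a, b)] = int(raw[a, b])
    _MATRIX_CACHE[name] = table
    return table


def _score(table: dict[tuple[str, str], int], a: str, b: str) -> int:
    return table.get((a, b), NONCANONICAL_SCORE)


@dataclass(frozen=True)
class QueryPrecursor:
    """The query precursor with its annotated mature dyn A 1-17 segment.

    ``dynA_interval`` is 1-based inclusive and must span 17 residues starting
    with the YGGF motif.
    """

    id: str
    sequence: str
    dynA_interval: tuple[int, int]

    def __post_init__(self) -> None:
        start, end = self.dynA_interval
        if end - start + 1 != DYNA_LENGTH:
            raise InputError(
                f"dynA_interval must span {DYNA_LENGTH} residues, got {self.dynA_interval}"
            )
        if not (1 <= start and end <= len(self.sequence)):
            raise InputError("dynA_interval outside the precursor sequence")
        if not self.sequence[start - 1 : start + 3] == "YGGF":
            raise InputError("dynA_interval does not begin with the YGGF motif")


@dataclass(frozen=True)
class LocalAlignment:
    """Optimal local alignment core: score, 1-based inclusive spans, gapped strings."""

    score: int
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]
    aligned_query: str
    aligned_subject: str

    @property
    def is_empty(self) -> bool:
        return self.score == 0 and not self.aligned_query


@dataclass(frozen=True)
class AlignmentHit:
    """A significant local alignment of a candidate frame against the query."""

    contig_id: str
    species: str
    taxon: str
    strand: str
    frame_offset: int
    score: int
    bitscore: float
    evalue: float
    query_interval: tuple[int, int]
    subject_interval: tuple[int, int]
    aligned_query: str
    aligned_subject: str
    mature_sequence: str


@dataclass
class UniqueHit:
    """A deduplicated mature peptide; species and taxa where it was observed."""

    mature_sequence: str
    species_set: set[str] = field(default_factory=set)
    taxon_counts: dict[str, int] = field(default_factory=dict)
    first_seen: str = ""

    @property
    def n_pairs(self) -> int:
        return len(self.species_set)


@dataclass
class TaxonProfile:
    """Per-taxon unique-hit accounting with overall coverage fractions."""

    table: pd.DataFrame  # index taxon; columns n_unique_hits, n_transcriptomes, n_species_with_hits
    total_unique_hits: int
    total_species_with_hits: int
    species_with_hits_fraction: float
    taxa_with_hits_fraction: float


@dataclass
class LogoMatrix:
    """Per-column residue frequencies and information content (bits)."""

    frequencies: pd.DataFrame  # index 1..n_columns, columns = residues
    information: np.ndarray  # bits per column
    counts: np.ndarray  # non-gap residue count per column
    n_sequences: int

    @property
    def n_columns(self) -> int:
        return len(self.frequencies)


def align_local(
    query: str,
    subject: str,
    matrix: str = "BLOSUM62",
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
) -> LocalAlignment:
    """Optimal affine-gap Smith-Waterman local alignment.

    A gap of length L costs ``gap_open + gap_extend * L``. The empty alignment
    (score 0) is allowed. Ties among equal-scoring optima are broken by
    preferring the alignment ending at the smallest subject coordinate, then
    the smallest query coordinate, with traceback preferring diagonal moves
    over gaps in the subject over gaps in the query.
    """
    if not query or not subject:
        raise ParameterError("align_local requires non-empty sequences")
    table = load_matrix(matrix)
    m, n = len(query), len(subject)
    neg = -(10**9)
    open_cost = gap_open + gap_extend

    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), neg, dtype=np.int64)  # gap in query (left move)
    F = np.full((m + 1, n + 1), neg, dtype=np.int64)  # gap in subject (up move)

    # Precompute substitution score rows as python lists for speed.
    sub_rows = []
    for i in range(m):
        qc = query[i]
        sub_rows.append([_score(table, qc, sc) for sc in subject])

    best_score = 0
    best_i = 0
    best_j = 0
    for i in range(1, m + 1):
        row = sub_rows[i - 1]
        Hi, Hp = H[i], H[i - 1]
        Ei = E[i]
        Fi, Fp = F[i], F[i - 1]
        for j in range(1, n + 1):
            e = max(Hi[j - 1] - open_cost, Ei[j - 1] - gap_extend)
            f = max(Hp[j] - open_cost, Fp[j] - gap_extend)
            h = Hp[j - 1] + row[j - 1]
            v = h if h > 0 else 0
            if f > v:
                v = f
            if e > v:
                v = e
            Ei[j] = e
            Fi[j] = f
            Hi[j] = v
            if v > best_score or (
                v == best_score and v > 0 and (j < best_j or (j == best_j and i < best_i))
            ):
                best_score = int(v)
                best_i, best_j = i, j

    if best_score == 0:
        return LocalAlignment(0, (0, 0), (0, 0), "", "")

    # Traceback from (best_i, best_j) in state H until H == 0.
    aq: list[str] = []
    asub: list[str] = []
    i, j = best_i, best_j
    state = "H"
    while True:
        if state == "H":
            if H[i][j] == 0:
                break
            diag = H[i - 1][j - 1] + sub_rows[i - 1][j - 1]
            if H[i][j] == diag:
                aq.append(query[i - 1])
                asub.append(subject[j - 1])
                i -= 1
                j -= 1
            elif H[i][j] == F[i][j]:
                state = "F"
            elif H[i][j] == E[i][j]:
                state = "E"
            else:  # pragma: no cover - DP consistency guard
                raise AssertionError("inconsistent traceback")
        elif state == "F":  # gap in subject, consume query residue
            aq.append(query[i - 1])
            asub.append(GAP_CHAR)
            closes = F[i][j] == H[i - 1][j] - open_cost
            i -= 1
            if closes:
                state = "H"
        else:  # state == "E": gap in query, consume subject residue
            aq.append(GAP_CHAR)
            asub.append(subject[j - 1])
            closes = E[i][j] == H[i][j - 1] - open_cost
            j -= 1
            if closes:
                state = "H"

    return LocalAlignment(
        score=best_score,
        query_interval=(i + 1, best_i),
        subject_interval=(j + 1, best_j),
        aligned_query="".join(reversed(aq)),
        aligned_subject="".join(reversed(asub)),
    )


def evalue(
    score: float,
    query_len: int,
    db_len: int,
    lam: float = GAPPED_BLOSUM62_LAMBDA,
    K: float = GAPPED_BLOSUM62_K,
) -> tuple[float, float]:
    """Karlin-Altschul expectation and bit score for a raw alignment score.

    Returns ``(E, bitscore)`` where ``E = K*m*n*exp(-lambda*S)`` and the bit
    score is ``S' = (lambda*S - ln K) / ln 2`` (so that ``E = m*n*2**(-S')``).
    """
    if query_len < 1 or db_len < 1:
        raise ParameterError("sequence and database lengths must be >= 1")
    if lam <= 0 or K <= 0:
        raise ParameterError("lambda and K must be positive")
    e = K * query_len * db_len * math.exp(-lam * score)
    bitscore = (lam * score - math.log(K)) / math.log(2)
    return e, bitscore


def _interval_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Length of the intersection of two 1-based inclusive intervals."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def extract_mature(
    alignment: LocalAlignment | AlignmentHit, query: QueryPrecursor
) -> str:
    """Extract the 17-column mature peptide aligned to the query's dyn A segment.

    Columns where the subject has no aligned residue (outside the alignment, or
    a subject gap) are '-'; subject insertions relative to the query inside the
    segment are dropped.
    """
    start, end = query.dynA_interval
    if _interval_overlap(alignment.query_interval, query.dynA_interval) == 0:
        raise ParameterError("alignment does not overlap the dyn A interval")
    columns = [GAP_CHAR] * DYNA_LENGTH
    qpos = alignment.query_interval[0]  # 1-based query coordinate of next column
    for qc, sc in zip(alignment.aligned_query, alignment.aligned_subject):
        if qc == GAP_CHAR:
            continue  # subject insertion relative to the query: dropped
        if start <= qpos <= end and sc != GAP_CHAR:
            columns[qpos - start] = sc
        qpos += 1
    return "".join(columns)


def search(
    query: QueryPrecursor,
    candidates: CandidateSet,
    threshold: float = 1e-6,
    min_overlap: int = 8,
    matrix: str = "BLOSUM62",
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
    lam: float = GAPPED_BLOSUM62_LAMBDA,
    K: float = GAPPED_BLOSUM62_K,
) -> list[AlignmentHit]:
    """Align the query against every candidate frame; keep significant hits.

    One best local alignment is evaluated per candidate frame translation
    (no sub-optimal HSPs). A hit is retained iff its E-value is <= ``threshold``
    and its aligned query span overlaps the dyn A 1-17 interval by at least
    ``min_overlap`` residues. Hits are returned sorted by ascending E-value
    (ties: contig id, strand, frame).
    """
    if candidates.n_contigs == 0:
        logger.warning("search: empty candidate set")
        return []
    db_len = candidates.db_len
    hits: list[AlignmentHit] = []
    for frame in candidates.frames:
        aln = align_local(
            query.sequence,
            frame.protein,
            matrix=matrix,
            gap_open=gap_open,
            gap_extend=gap_extend,
        )
        if aln.is_empty:
            continue
        e, bits = evalue(aln.score, len(query.sequence), db_len, lam=lam, K=K)
        if e > threshold:
            continue
        if _interval_overlap(aln.query_interval, query.dynA_interval) < min_overlap:
            continue
        contig = candidates.contigs[frame.contig_id]
        hits.append(
            AlignmentHit(
                contig_id=frame.contig_id,
                species=contig.species,
                taxon=contig.taxon,
                strand=frame.strand,
                frame_offset=frame.frame_offset,
                score=aln.score,
                bitscore=bits,
                evalue=e,
                query_interval=aln.query_interval,
                subject_interval=aln.subject_interval,
                aligned_query=aln.aligned_query,
                aligned_subject=aln.aligned_subject,
                mature_sequence=extract_mature(aln, query),
            )
        )
    hits.sort(key=lambda h: (h.evalue, h.contig_id, h.strand, h.frame_offset))
    logger.info(
        "search: %d significant hits (E <= %g) from %d candidate frames",
        len(hits),
        threshold,
        len(candidates.frames),
    )
    return hits


def dedup_hits(hits: list[AlignmentHit]) -> list[UniqueHit]:
    """Deduplicate hits: distinct (mature_sequence, species) pairs are unique.

    Hits sharing a mature sequence are aggregated under one :class:`UniqueHit`
    carrying the species set and per-taxon pair counts. Output order is
    deterministic (by sequence, then the aggregation is order-free).
    """
    groups: dict[str, UniqueHit] = {}
    seen_pairs: set[tuple[str, str]] = set()
    for hit in hits:
        if not hit.species:
            raise InputError(f"hit on contig {hit.contig_id!r} lacks species metadata")
        key = (hit.mature_sequence, hit.species)
        if key in seen_pairs:
            continue
        seen_pairs.add(key)
        uh = groups.get(hit.mature_sequence)
        if uh is None:
            uh = UniqueHit(mature_sequence=hit.mature_sequence, first_seen=hit.contig_id)
            groups[hit.mature_sequence] = uh
        uh.species_set.add(hit.species)
        uh.taxon_counts[hit.taxon] = uh.taxon_counts.get(hit.taxon, 0) + 1
    return [groups[seq] for seq in sorted(groups)]


def taxonomic_profile(
    unique_hits: list[UniqueHit],
    taxonomy: dict[str, str],
    transcriptome_counts: dict[str, int],
) -> TaxonProfile:
    """Cluster unique hits into a taxonomic profile.

    ``taxonomy`` maps every species to exactly one taxon;
    ``transcriptome_counts`` gives the number of transcriptome datasets
    available per taxon. Reports per-taxon unique-hit and species-with-hit
    counts plus the fraction of species with >= 1 hit and the fraction of taxa
    (among those with transcriptomes) with >= 1 hit.
    """
    taxa = sorted(set(taxonomy.values()) | set(transcriptome_counts))
    n_hits = {t: 0 for t in taxa}
    species_with_hits: dict[str, set[str]] = {t: set() for t in taxa}
    for uh in unique_hits:
        for species in uh.species_set:
            if species not in taxonomy:
                raise InputError(f"species {species!r} has no taxon mapping")
            taxon = taxonomy[species]
            n_hits[taxon] += 1
            species_with_hits[taxon].add(species)
    table = pd.DataFrame(
        {
            "n_unique_hits": [n_hits[t] for t in taxa],
            "n_transcriptomes": [int(transcriptome_counts.get(t, 0)) for t in taxa],
            "n_species_with_hits": [len(species_with_hits[t]) for t in taxa],
        },
        index=pd.Index(taxa, name="taxon"),
    )
    total_hits = int(table["n_unique_hits"].sum())
    total_species_hit = int(table["n_species_with_hits"].sum())
    n_species = len(taxonomy)
    taxa_with_data = [t for t in taxa if transcriptome_counts.get(t, 0) > 0]
    taxa_hit = sum(1 for t in taxa_with_data if n_hits[t] > 0)
    return TaxonProfile(
        table=table,
        total_unique_hits=total_hits,
        total_species_with_hits=total_species_hit,
        species_with_hits_fraction=total_species_hit / n_species if n_species else 0.0,
        taxa_with_hits_fraction=taxa_hit / len(taxa_with_data) if taxa_with_data else 0.0,
    )


def logo_matrix(
    mature_peptides: list[str], small_sample_correction: bool = False
) -> LogoMatrix:
    """Position frequency matrix and per-column information content in bits.

    Frequencies are computed over non-gap residues per column. Information is
    R_i = log2(20) - (H_i + e_n) with Shannon entropy H_i in bits and, when
    ``small_sample_correction`` is set, e_n = 19 / (2 ln2 n_i) where n_i is
    the non-gap count in column i; R_i is clamped at 0.
    """
    if not mature_peptides:
        raise InputError("logo_matrix requires at least one sequence")
    width = len(mature_peptides[0])
    for seq in mature_peptides:
        if len(seq) != width:
            raise InputError("logo_matrix: ragged input lengths")
    residues = list(CANONICAL_RESIDUES)
    counts = np.zeros((width, len(residues)), dtype=np.int64)
    index = {r: k for k, r in enumerate(residues)}
    for seq in mature_peptides:
        for i, ch in enumerate(seq):
            if ch in index:
                counts[i, index[ch]] += 1
    n_i = counts.sum(axis=1)
    freqs = np.zeros_like(counts, dtype=float)
    nonzero = n_i > 0
    freqs[nonzero] = counts[nonzero] / n_i[nonzero, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    entropy = -plogp.sum(axis=1)
    info = np.log2(20.0) - entropy
    if small_sample_correction:
        with np.errstate(divide="ignore"):
            e_n = np.where(n_i > 0, 19.0 / (2.0 * np.log(2.0) * np.maximum(n_i, 1)), 0.0)
        info = info - e_n
    info = np.where(n_i > 0, np.clip(info, 0.0, None), 0.0)
    freq_df = pd.DataFrame(
        freqs, index=pd.RangeIndex(1, width + 1, name="column"), columns=residues
    )
    return LogoMatrix(
        frequencies=freq_df,
        information=info,
        counts=n_i,
        n_sequences=len(mature_peptides),
    )


def logo_to_frame(logo: LogoMatrix) -> pd.DataFrame:
    """Flatten a LogoMatrix to a writable table (one row per column)."""
    df = logo.frequencies.copy()
    df["information_bits"] = logo.information
    df["n_residues"] = logo.counts
    return df.reset_index()


def hits_to_frame(hits: list[AlignmentHit]) -> pd.DataFrame:
    """Hits as a BLAST outfmt-6-like table with extensions (1-based coords)."""
    rows = [
        {
            "contig_id": h.contig_id,
            "species": h.species,
            "taxon": h.taxon,
            "strand": h.strand,
            "frame": h.frame_offset,
            "score": h.score,
            "bitscore": round(h.bitscore, 2),
            "evalue": h.evalue,
            "query_start": h.query_interval[0],
            "query_end": h.query_interval[1],
            "subject_start": h.subject_interval[0],
            "subject_end": h.subject_interval[1],
            "mature_sequence": h.mature_sequence,
        }
        for h in hits
    ]
    columns = [
        "contig_id", "species", "taxon", "strand", "frame", "score", "bitscore",
        "evalue", "query_start", "query_end", "subject_start", "subject_end",
        "mature_sequence",
    ]
    return pd.DataFrame(rows, columns=columns)


def unique_hits_to_frame(unique_hits: list[UniqueHit]) -> pd.DataFrame:
    rows = [
        {
            "mature_sequence": uh.mature_sequence,
            "n_unique_hits": uh.n_pairs,
            "species": ";".join(sorted(uh.species_set)),
            "taxa": ";".join(f"{t}:{c}" for t, c in sorted(uh.taxon_counts.items())),
            "first_seen": uh.first_seen,
        }
        for uh in unique_hits
    ]
    columns = ["mature_sequence", "n_unique_hits", "species", "taxa", "first_seen"]
    return pd.DataFrame(rows, columns=columns)
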