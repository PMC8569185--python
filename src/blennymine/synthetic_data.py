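"""Synthetic fixtures for every input the pipeline consumes.

Transcriptome fixtures plant back-translated dynorphin-like precursors at
random offsets, strands and frames inside random-nucleotide contigs, among
decoy contigs guaranteed to carry no in-frame YGGF, and record every planting
in a ground-truth manifest so that mining recall and false-positive rates are
exactly testable. Assay simulators generate competition-binding (Poisson
counting noise on cpm), cAMP concentration-response (additive Gaussian noise,
3% of the dynamic range by default) and BRET kinetic traces (mono-exponential
ligand-induced ratio rise, Gaussian ratio noise) from stated ground-truth
parameters. All generators are deterministic given their integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from blennymine.assays import BindingDataset, BRETTrace, DoseResponseDataset
from blennymine.exceptions import ParameterError
from blennymine.mining import CANONICAL_RESIDUES, Contig, translate_six_frames
from blennymine.homology import QueryPrecursor

# Mature human dynorphin A 1-17.
HUMAN_DYNA_117 = "YGGFLRRIRPKLKWDNQ"
MOTIF = "YGGF"

# Reference agonist (dyn A 1-13) parameters at the mouse KOR used by the
# simulators for normalization presets: Ki 0.0310 nM, EC50 2.80 nM, Emax 100%.
REFERENCE_EC50_NM = 2.80
REFERENCE_EMAX = 100.0
REFERENCE_CONC_NM = 10_000.0  # 10 uM saturating reference concentration

# Printed scintillation-counter calibration, stored as a conversion constant.
# Not used by any default because its direction/units cannot be reconciled
# with the membrane amounts used per assay; exposed for completeness only.
CPM_PER_FMOL = 38.4

DEFAULT_BINDING_GRID = np.logspace(np.log10(0.1), np.log10(30_000.0), 12)
DEFAULT_CAMP_GRID = np.logspace(np.log10(0.03), np.log10(30_000.0), 12)
DEFAULT_BRET_TIMEPOINTS = np.arange(-300.0, 2460.0 + 1.0, 60.0)

_NUCLEOTIDES = np.array(list("ACGT"))


def _codon_choices() -> dict[str, list[str]]:
    """Synonymous codons per residue from the standard genetic code (table 1)."""
    table = CodonTable.unambiguous_dna_by_id[1]
    choices: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        choices.setdefault(aa, []).append(codon)
    return {aa: sorted(codons) for aa, codons in choices.items()}


_CODONS = _codon_choices()


@dataclass(frozen=True)
class PrecursorTemplate:
    """A synthetic dynorphin-like precursor with its planted 17-residue core."""

    species_name: str
    taxon: str
    protein_sequence: str
    core_interval: tuple[int, int]  # 1-based inclusive

    def __post_init__(self) -> None:
        start, end = self.core_interval
        core = self.protein_sequence[start - 1 : end]
        if end - start + 1 != 17 or not core.startswith(MOTIF):
            raise ParameterError("core must be a 17-residue segment starting with YGGF")
        if set(self.protein_sequence) - set(CANONICAL_RESIDUES):
            raise ParameterError("precursor must use canonical residues only")

    @property
    def core(self) -> str:
        start, end = self.core_interval
        return self.protein_sequence[start - 1 : end]


@dataclass(frozen=True)
class PlantedEntry:
    contig_id: str
    species_name: str
    taxon: str
    strand: str
    frame: int
    nucleotide_interval: tuple[int, int]  # 1-based inclusive, forward coords
    planted_core_sequence: str


@dataclass
class GroundTruthManifest:
    """Record of every planted precursor; the oracle for recall testing."""

    entries: list[PlantedEntry] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "contig_id": e.contig_id,
                "species": e.species_name,
                "taxon": e.taxon,
                "strand": e.strand,
                "frame": e.frame,
                "nt_start": e.nucleotide_interval[0],
                "nt_end": e.nucleotide_interval[1],
                "planted_core_sequence": e.planted_core_sequence,
            }
            for e in self.entries
        ]
        columns = [
            "contig_id", "species", "taxon", "strand", "frame",
            "nt_start", "nt_end", "planted_core_sequence",
        ]
        return pd.DataFrame(rows, columns=columns)


@dataclass
class AssaySimConfig:
    """Ground-truth parameters and noise settings for the assay simulators.

    Concentrations are in nM; ``radioligand_conc`` defaults to the 1 nM
    [3H]-diprenorphine used experimentally and ``radioligand_kd`` to its
    previously determined Kd of 0.87 nM. ``b0`` is the total-binding cpm scale
    and ``ns`` the nonspecific level (default 10% of b0, the operational
    10 uM naloxone condition). ``noise_frac`` scales the additive Gaussian
    noise of the cAMP and BRET simulators as a fraction of each assay's
    dynamic range; cpm noise is Poisson (disable via ``counting_noise``).
    """

    true_ki: float | None = None  # nM
    radioligand_conc: float = 1.0  # [L], nM
    radioligand_kd: float = 0.87  # nM
    b0: float = 4000.0  # total-binding cpm scale
    ns: float | None = None  # nonspecific cpm; default 0.1 * b0
    true_ec50: float | None = None  # nM
    true_emax: float | None = None  # percent of reference
    bret_efficacy_ratio: float = 0.70
    bret_tau: float = 300.0  # s
    n_replicates: int = 3
    seed: int = 0
    noise_frac: float = 0.03
    counting_noise: bool = True
    camp_reference_effect: float = 2000.0  # raw HTRF-scale effect of the reference
    bret_amplitude_ref: float = 0.10  # ratio units, reference ligand plateau
    bret_baseline_ratio: float = 0.80
    bret_donor_counts: float = 10_000.0

    def __post_init__(self) -> None:
        for name in ("true_ki", "radioligand_conc", "radioligand_kd", "true_ec50"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ParameterError(f"{name} must be positive, got {value}")
        if self.ns is None:
            self.ns = 0.1 * self.b0
        if self.b0 <= 0 or self.ns < 0:
            raise ParameterError("b0 must be positive and ns non-negative")
        if not 0.0 <= self.bret_efficacy_ratio <= 1.5:
            raise ParameterError("bret_efficacy_ratio must lie in [0, 1.5]")
        if self.bret_tau <= 0:
            raise ParameterError("bret_tau must be positive")
        if self.n_replicates < 1:
            raise ParameterError("n_replicates must be >= 1")
        if self.noise_frac < 0:
            raise ParameterError("noise_frac must be >= 0")


def _random_protein(rng: np.random.Generator, length: int) -> str:
    residues = np.array(list(CANONICAL_RESIDUES))
    return "".join(rng.choice(residues, size=length))


def make_precursor_set(
    seed: int,
    n_species: int,
    mutation_rate: float,
    flank_length: int = 30,
    n_taxa: int = 8,
) -> list[PrecursorTemplate]:
    """Generate one dynorphin-like precursor template per synthetic species.

    Each core is human dyn A 1-17 with positions 5-17 independently replaced
    by a different residue with probability ``mutation_rate``; the YGGF motif
    (positions 1-4) is never mutated. Flanking precursor sequence is random.
    """
    if not 0.0 <= mutation_rate < 1.0:
        raise ParameterError(f"mutation_rate must be in [0, 1), got {mutation_rate}")
    if n_species < 1:
        raise ParameterError("n_species must be >= 1")
    rng = np.random.default_rng(seed)
    residues = list(CANONICAL_RESIDUES)
    templates = []
    for i in range(n_species):
        core = list(HUMAN_DYNA_117)
        for pos in range(4, 17):  # 0-based positions 4..16 = residues 5..17
            if rng.random() < mutation_rate:
                alternatives = [r for r in residues if r != core[pos]]
                core[pos] = alternatives[rng.integers(len(alternatives))]
        flank_n = _random_protein(rng, flank_length)
        flank_c = _random_protein(rng, flank_length)
        protein = flank_n + "".join(core) + flank_c
        templates.append(
            PrecursorTemplate(
                species_name=f"species_{i:04d}",
                taxon=f"taxon_{i % n_taxa:02d}",
                protein_sequence=protein,
                core_interval=(flank_length + 1, flank_length + 17),
            )
        )
    return templates


def make_query_precursor(
    seed: int = 101,
    length: int = 254,
    dynA_interval: tuple[int, int] = (207, 223),
) -> QueryPrecursor:
    """Synthetic stand-in for the human preprodynorphin query precursor.

    The mature dyn A 1-17 segment is the true human sequence placed at
    ``dynA_interval``; all flanking residues are random. This is a synthetic
    surrogate for the real UniProt P01213 entry, sized to match it (254 aa).
    """
    start, end = dynA_interval
    if not (1 <= start and end <= length and end - start + 1 == 17):
        raise ParameterError("dynA_interval must span 17 residues inside the precursor")
    rng = np.random.default_rng(seed)
    sequence = list(_random_protein(rng, length))
    sequence[start - 1 : end] = list(HUMAN_DYNA_117)
    return QueryPrecursor(
        id="synthetic_preprodynorphin",
        sequence="".join(sequence),
        dynA_interval=dynA_interval,
    )


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """Back-translate with uniformly random synonymous codons (standard code)."""
    codons = []
    for aa in protein:
        options = _CODONS[aa]
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_NUCLEOTIDES, size=length))


def _has_motif_in_frame(sequence: str) -> bool:
    probe = Contig(id="probe", sequence=sequence, species="", taxon="")
    return any(MOTIF in f.protein for f in translate_six_frames(probe))


def embed_in_contigs(
    templates: list[PrecursorTemplate],
    seed: int,
    n_decoys: int,
    contig_length: tuple[int, int] = (300, 600),
) -> tuple[list[Contig], pd.DataFrame, GroundTruthManifest]:
    """Embed back-translated precursors into random contigs among decoys.

    Each template is placed at a uniformly random offset, strand and frame of
    a random-nucleotide contig. Decoy contigs are rejection-sampled so that no
    frame translation contains the YGGF motif. Returns the contigs, a 3-column
    metadata table and the ground-truth manifest.
    """
    lo, hi = contig_length
    if lo > hi or lo < 3:
        raise ParameterError(f"invalid contig_length range {contig_length}")
    max_protein = max((len(t.protein_sequence) for t in templates), default=0)
    if templates and lo < 3 * max_protein + 6:
        raise ParameterError(
            f"contig_length lower bound {lo} too short for a {max_protein}-residue "
            f"precursor (needs >= {3 * max_protein + 6})"
        )
    rng = np.random.default_rng(seed)
    contigs: list[Contig] = []
    manifest = GroundTruthManifest()
    counter = 0

    for template in templates:
        coding = back_translate(template.protein_sequence, rng)
        clen = int(rng.integers(lo, hi + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        offset = int(rng.integers(0, clen - len(coding) + 1))
        insert = coding
        if strand == "-":
            comp = str.maketrans("ACGT", "TGCA")
            insert = coding.translate(comp)[::-1]
        sequence = (
            _random_nt(rng, offset)
            + insert
            + _random_nt(rng, clen - offset - len(coding))
        )
        if strand == "+":
            frame = offset % 3
        else:
            frame = (clen - (offset + len(coding))) % 3
        contig_id = f"contig_{counter:05d}"
        counter += 1
        contigs.append(
            Contig(
                id=contig_id,
                sequence=sequence,
                species=template.species_name,
                taxon=template.taxon,
            )
        )
        manifest.entries.append(
            PlantedEntry(
                contig_id=contig_id,
                species_name=template.species_name,
                taxon=template.taxon,
                strand=strand,
                frame=frame,
                nucleotide_interval=(offset + 1, offset + len(coding)),
                planted_core_sequence=template.core,
            )
        )

    species_pool = [(t.species_name, t.taxon) for t in templates] or [
        ("species_decoy", "taxon_00")
    ]
    for _ in range(n_decoys):
        clen = int(rng.integers(lo, hi + 1))
        while True:
            sequence = _random_nt(rng, clen)
            if not _has_motif_in_frame(sequence):
                break
        species, taxon = species_pool[rng.integers(len(species_pool))]
        contigs.append(
            Contig(
                id=f"contig_{counter:05d}",
                sequence=sequence,
                species=species,
                taxon=taxon,
            )
        )
        counter += 1

    metadata = pd.DataFrame(
        [
            {"contig_id": c.id, "species": c.species, "taxon": c.taxon}
            for c in contigs
        ],
        columns=["contig_id", "species", "taxon"],
    )
    return contigs, metadata, manifest


def expected_displacement(cfg: AssaySimConfig, concentrations: np.ndarray) -> np.ndarray:
    """Noise-free expected total-binding cpm at each inhibitor concentration."""
    if cfg.true_ki is None:
        raise ParameterError("true_ki must be set to simulate displacement")
    ic50 = cfg.true_ki * (1.0 + cfg.radioligand_conc / cfg.radioligand_kd)
    return cfg.ns + (cfg.b0 - cfg.ns) / (1.0 + concentrations / ic50)


def simulate_displacement(
    cfg: AssaySimConfig, concentrations: np.ndarray | None = None
) -> BindingDataset:
    """Simulate a competition displacement experiment with Poisson cpm noise."""
    conc = np.asarray(
        DEFAULT_BINDING_GRID if concentrations is None else concentrations, dtype=float
    )
    if np.any(conc <= 0):
        raise ParameterError("concentrations must be positive")
    rng = np.random.default_rng(cfg.seed)
    mu = expected_displacement(cfg, conc)
    replicates: list[tuple[float, float]] = []
    for _ in range(cfg.n_replicates):
        if cfg.counting_noise:
            observed = rng.poisson(mu).astype(float)
        else:
            observed = mu.copy()
        replicates.extend(zip(conc.tolist(), observed.tolist()))
    return BindingDataset(
        ligand_id=f"sim_ki_{cfg.true_ki:g}nM",
        replicates=replicates,
        radioligand_conc=cfg.radioligand_conc,
        radioligand_kd=cfg.radioligand_kd,
        nonspecific_cpm=float(cfg.ns),
    )


def expected_camp_percent(cfg: AssaySimConfig, concentrations: np.ndarray) -> np.ndarray:
    """Noise-free expected cAMP inhibition in percent of the reference effect."""
    if cfg.true_ec50 is None or cfg.true_emax is None:
        raise ParameterError("true_ec50 and true_emax must be set to simulate cAMP data")
    return cfg.true_emax / (1.0 + cfg.true_ec50 / concentrations)


def simulate_camp(
    cfg: AssaySimConfig, concentrations: np.ndarray | None = None
) -> DoseResponseDataset:
    """Simulate a cAMP inhibition concentration-response experiment.

    Responses are on a raw HTRF-effect scale; the reference ligand's response
    at 10 uM (mean of ``n_replicates`` simulated wells) is included for
    normalization. Gaussian noise SD = ``noise_frac`` x reference effect.
    """
    conc = np.asarray(
        DEFAULT_CAMP_GRID if concentrations is None else concentrations, dtype=float
    )
    if np.any(conc <= 0):
        raise ParameterError("concentrations must be positive")
    rng = np.random.default_rng(cfg.seed)
    sd = cfg.noise_frac * cfg.camp_reference_effect
    percent = expected_camp_percent(cfg, conc)
    raw = percent / 100.0 * cfg.camp_reference_effect
    replicates: list[tuple[float, float]] = []
    for _ in range(cfg.n_replicates):
        observed = raw + (rng.normal(0.0, sd, size=raw.shape) if sd > 0 else 0.0)
        replicates.extend(zip(conc.tolist(), observed.tolist()))
    # The percent scale is operationally defined by the reference ligand's
    # inhibition at 10 uM, so that raw effect IS the reference scale.
    ref_raw = cfg.camp_reference_effect
    ref_wells = ref_raw + (
        rng.normal(0.0, sd, size=cfg.n_replicates) if sd > 0 else np.zeros(cfg.n_replicates)
    )
    return DoseResponseDataset(
        ligand_id=f"sim_ec50_{cfg.true_ec50:g}nM",
        replicates=replicates,
        reference_response_at_10uM=float(np.mean(ref_wells)),
        scale="raw",
    )


def bret_delta(
    times: np.ndarray, amplitude: float, tau: float
) -> np.ndarray:
    """Mono-exponential ligand-induced BRET ratio change, zero before addition."""
    return np.where(times > 0.0, amplitude * (1.0 - np.exp(-np.maximum(times, 0.0) / tau)), 0.0)


def simulate_bret(
    cfg: AssaySimConfig, timepoints: np.ndarray | None = None
) -> tuple[BRETTrace, BRETTrace, BRETTrace]:
    """Simulate (ligand, vehicle, reference) BRET kinetic traces.

    Ligand addition occurs at t = 0 after a 300 s baseline. The acceptor/donor
    ratio of the ligand trace rises as A * (1 - exp(-t/tau)) with
    A = bret_efficacy_ratio x A_reference; the vehicle trace has A = 0.
    Gaussian ratio noise SD = ``noise_frac`` x A_reference.
    """
    times = np.asarray(
        DEFAULT_BRET_TIMEPOINTS if timepoints is None else timepoints, dtype=float
    )
    if int(np.sum(times < 0)) < 2:
        raise ParameterError("timepoints must include >=2 baseline samples before t=0")
    if times.max() < 2411.0 or times.min() > 0.0:
        raise ParameterError("timepoints must span at least 0-2411 s")
    rng = np.random.default_rng(cfg.seed)
    sd = cfg.noise_frac * cfg.bret_amplitude_ref
    traces = []
    amplitudes = {
        "ligand": cfg.bret_efficacy_ratio * cfg.bret_amplitude_ref,
        "vehicle": 0.0,
        "reference": cfg.bret_amplitude_ref,
    }
    for name, amplitude in amplitudes.items():
        ratio = cfg.bret_baseline_ratio + bret_delta(times, amplitude, cfg.bret_tau)
        if sd > 0:
            ratio = ratio + rng.normal(0.0, sd, size=times.shape)
        em460 = np.full_like(times, cfg.bret_donor_counts)
        em510 = ratio * em460
        traces.append(
            BRETTrace(
                ligand_id=name,
                times=times,
                em460=em460,
                em510=em510,
                addition_time=0.0,
            )
        )
    return traces[0], traces[1], traces[2]


def with_seed(cfg: AssaySimConfig, seed: int) -> AssaySimConfig:
    """A copy of the config with a different seed (replicate experiments)."""
    return replace(cfg, seed=seed)
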