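# Methods

`blennymine` re-implements, as a tested and reusable pipeline, a genome-mining
procedure for dynorphin-like neuropeptide precursors in bony-fish
transcriptomes, together with the pharmacological quantification used to
characterise the discovered peptides (the blenniorphins) at the κ-opioid
receptor (KOR). This note documents the models, the defaults and why they
were chosen, the numerical choices, what the synthetic fixtures do and do not
emulate, and the known limitations.

## Mining model

Transcriptome contigs (nucleotide sequences over `{A,C,G,T,N}`) are
conceptually translated in all six reading frames. No ORF calling is
performed: translation runs straight through stop codons (rendered `*`) and
any codon containing `N` translates to `X`. The rationale is that the
pre-alignment filter operates on conceptual translations, and candidate
regions need not respect start/stop structure; trailing 1–2 nucleotides that
do not fill a codon are dropped. A contig becomes a *candidate* when at least
one frame translation contains the invariant opioid tetrapeptide motif
`YGGF` as an exact substring (overlapping occurrences allowed; `X` never
matches). Only the motif-bearing frames of candidate contigs are carried
forward — they constitute the search database.

### Alignment and significance

Candidate frames are aligned against a preprodynorphin query precursor by
full affine-gap Smith–Waterman (no heuristic seeding; exact dynamic
programming is affordable at fixture scale), scored with BLOSUM62, gap open
11 and gap extend 1 — the classic protein-BLAST defaults; a gap of length L
costs `open + extend·L`. `X` and `*` score −4 against everything, penalising
ambiguous and stop positions without rejecting the frame. One optimal local
alignment is evaluated per candidate frame (no sub-optimal HSPs); ties among
equal-scoring optima are resolved deterministically (smallest subject end
coordinate, then smallest query end, traceback preferring
diagonal > subject-gap > query-gap).

Significance uses the Karlin–Altschul expectation

    E = K · m · n · exp(−λ·S),     S′ = (λS − ln K)/ln 2,

with the published gapped-BLOSUM62 parameters λ = 0.267, K = 0.041
(configurable), `m` the query length and `n` the total residue count of the
candidate frames. No composition-based statistics and no length/edge-effect
corrections are applied, so E-values differ somewhat from NCBI-BLAST's; the
payoff is simplicity and exact determinism. The significance threshold is
E ≤ 10⁻⁶.

A retained hit must additionally overlap the query's annotated mature
dynorphin A 1–17 segment by at least 8 aligned query residues (configurable;
requiring the full 17 would discard genuinely homologous fragments, and no
canonical overlap rule exists for this filter). The subject residues aligned
to the 17 dyn A columns are extracted as the *mature peptide* (gap `-` where
no subject residue aligns; subject insertions inside the segment dropped).

### Deduplication, profiling, logos

A *unique hit* is a distinct (mature sequence, species) pair: a novel
sequence, or a known sequence observed in a new species, counts once. Unique
hits are clustered by taxon into a profile reporting per-taxon unique-hit and
species-with-hit counts, the fraction of species with ≥ 1 hit, and the
fraction of taxa (among those with transcriptome data) with ≥ 1 hit. In the
fixture layout each species carries one transcriptome, so per-taxon
transcriptome counts are the distinct-species counts.

Sequence-logo matrices are per-column residue frequencies over non-gap
residues with information content

    R_i = log2(20) − (H_i + e_n),

`H_i` the Shannon entropy in bits and, optionally, the small-sample
correction `e_n = 19/(2·ln2·n_i)` with `n_i` the non-gap count in column `i`;
`R_i` is clamped at 0. Rendering is out of scope — matrices are written as
TSV and can be fed to any logo plotter.

## Pharmacology models

**Competition binding.** Displacement of 1 nM [³H]-diprenorphine (Kd
0.87 nM, both configurable) is fit on the raw total-binding cpm scale with a
three-parameter logistic Hill equation, slope fixed at 1:

    y = bottom + (top − bottom) / (1 + 10^(log10 c − log10 IC50)).

The bottom plateau is left free rather than pinned to the experimentally
defined nonspecific level (10 µM naloxone condition), which is reported
alongside for comparison; fitting raw cpm (not specific binding) was chosen
because both plateaus are then estimated from the data. IC50 converts to the
inhibition constant by the Cheng–Prusoff approximation
`Ki = IC50 / (1 + [L]/Kd)`.

**cAMP inhibition.** Raw responses are normalized so that 100% equals the
inhibition elicited by the reference agonist dyn A 1–13 at its saturating
10 µM concentration — an operational definition: that single raw effect *is*
the scale. Normalized data are fit with the monophasic inhibition equation

    y = Emax / (1 + EC50/c)

(bottom fixed at 0 by the normalization, slope 1). Emax is the fitted
plateau, not the response at the top concentration; a fitted Emax above 120%
triggers a warning only.

**BRET β-arrestin-2 recruitment.** Ligand-induced BRET is the pointwise
difference of acceptor/donor emission ratios,
`Δ(t) = (em510/em460)_ligand − (em510/em460)_vehicle`, computed on the ligand
time grid (unequal grids are linearly interpolated). Relative recruitment is
`100 × mean(Δ_ligand)/mean(Δ_reference)` over the 311–2411 s window
(endpoints inclusive). The quantity is invariant to any common positive
rescaling of both emission channels.

**Fitting numerics.** Nonlinear least squares uses `scipy.optimize.curve_fit`
with tight tolerances (1e-12 on x/f/g), three deterministic starts
(data-driven midpoint and ±1 log-unit shifts, extremes seeded from the
concentration ordering) and the best-SSE solution reported. Fits require ≥ 4
distinct concentrations; flat data return a flagged degenerate result rather
than silent values; non-convergence is flagged, never masked. Summaries
report mean ± sample SD (n−1) across independent experiments, with SD marked
NaN for a single experiment.

## Synthetic fixtures: what they emulate

The generators produce every input the pipeline consumes, each deterministic
given its integer seed (same seed ⇒ byte-identical output).

**Transcriptome fixtures.** A precursor template per synthetic species
carries the human dyn A 1–17 core (`YGGFLRRIRPKLKWDNQ`) with positions 5–17
independently substituted (to a *different* residue) with a configurable
mutation rate — positions 1–4 (`YGGF`) are never mutated, mirroring the
motif's invariance — flanked by 30 random residues on each side (a compact
precursor; real preprodynorphins are longer and contain additional opioid
cores, which the fixture does not emulate). Templates are back-translated
with uniformly random synonymous codons (standard genetic code; any codon
usage suffices for fixture realism) and embedded at a uniformly random
offset, strand and frame in random-nucleotide contigs of 300–600 nt. Decoy
contigs are rejection-sampled until no frame translation contains `YGGF`
(a ~600 nt random contig carries an in-frame `YGGF` with probability ~10⁻³,
so unfiltered decoys would occasionally be motif-positive). Every planting is
recorded in a ground-truth manifest, the oracle for recall and
false-positive testing. The query precursor used by fixtures is a *synthetic*
stand-in for human preprodynorphin: 254 residues with the true dyn A 1–17
core at positions 207–223 and random flanks.

At mutation rate 0 the planted core aligns gap-free to the query core with
raw score 97 (BLOSUM62 diagonal sum), giving E ≈ 5×10⁻⁷ at the default
database size — comfortably under the 10⁻⁶ threshold — so pipeline recall is
100% with zero decoy false positives, and the tests assert exactly that.
Because flanking sequence is random, fixtures do not probe sensitivity to
distant homology, sequencing error, assembly artifacts or alternative codon
usage; a green suite shows the machinery is correct, not that the thresholds
are optimal for real transcriptomes.

**Assay simulators.** Displacement: expected
`cpm(c) = NS + (B0 − NS)/(1 + c/IC50)` with `IC50 = Ki·(1 + L/Kd)`, observed
counts Poisson (the natural model for scintillation counting). B0 defaults
to 4000 cpm and NS to 10% of B0 — the printed calibration constant
1 cpm ≙ 38.4 fmol is stored in config but unused because it cannot be
reconciled dimensionally with the stated Bmax and membrane amounts without
extra assumptions. Default grid: 12 log-spaced concentrations, 0.1 nM–30 µM,
in triplicate. cAMP: expected percent `Emax/(1 + EC50/c)` mapped to a raw
HTRF-effect scale, additive Gaussian noise with SD = 3% of the reference
effect (a standard detector model; no value is stated for the real assay);
grid 0.03 nM–30 µM; the reference-at-10 µM raw effect is the mean of
simulated replicate wells. BRET: ligand addition at t = 0 after a 300 s
baseline, readings every 60 s to 2460 s; the ratio rises mono-exponentially,
`Δ(t) = A(1 − e^(−t/τ))`, with `A = efficacy_ratio × A_reference`,
`A_reference = 0.10` ratio units and Gaussian ratio noise (SD = 3% of
A_reference). The blenniorphin preset uses efficacy ratio 0.70 — the
recruitment deficit observed experimentally — and τ = 300 s for both ligand
and reference (kinetics were comparable; no time constant is reported, so a
minutes-scale arrestin-recruitment value is used). With matched kinetics the
exponential cancels in the window-mean ratio, so the noise-free relative
value is exactly the efficacy ratio.

## Design choices where the design was open

- Motif filtering is per-frame, not per-ORF (ORF rules are unstated and the
  filter is a pre-screen, not a gene caller).
- The E-value database length counts only motif-bearing candidate frames —
  they are the database actually searched.
- The dyn A overlap requirement is ≥ 8 residues, configurable, since no
  threshold is published for "aligning to dyn A 1–17".
- Only the stated unique-hit rule is applied in deduplication; no manual
  curation step is modelled.
- Hill slopes are fixed at 1 throughout (three-parameter logistic form).

## Problem sizes

The default mining fixture is 50 planted precursors among 500 decoys
(~250 kb of contig sequence; exact-DP search of the ~50 candidate frames
takes a few seconds). Parameter-recovery checks use 3 simulated experiments
per binding/cAMP ligand and 4 per BRET preset, matching the replicate
structure of the real experiments; the recovery-distribution property uses
100 seeded repetitions. These sizes make the full suite run in well under a
minute while keeping every statistical check meaningful.

## Known limitations

- One optimal alignment per frame: a frame containing two homologous regions
  yields a single hit.
- E-values are uncorrected Karlin–Altschul; absolute values differ from
  NCBI-BLAST (typically within an order of magnitude at these scores).
- The logo information content uses the non-gap count per column; columns
  with no aligned residues carry zero information by convention.
- The mass module covers linear peptides with free termini only — no
  modifications, average masses or fragment ions.
- Reported peptide [M+H]⁺ values from MALDI are observed masses; theory is
  compared with a ±0.15 Da tolerance (observed values sit ~+0.1 Da above
  theoretical monoisotopic masses).
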