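# blennymine

Genome mining for dynorphin-like neuropeptides in fish transcriptomes, with
the κ-opioid receptor (KOR) pharmacology used to characterise them.

Opioid peptides share an invariant N-terminal Tyr-Gly-Gly-Phe (`YGGF`) motif.
Blenny-fish transcriptomes harbour preprodynorphin-like precursors whose
mature peptides — the *blenniorphins* — bind and activate the mammalian KOR
with nanomolar affinity. `blennymine` packages the complete in-silico
workflow that finds such peptides and the quantification of the wet-lab
assays that validate them, for computational biologists who want to mine
their own sequence sets or fit their own plate-reader data:

1. **Mining** — six-frame conceptual translation of contigs, `YGGF` motif
   filtering, affine-gap Smith–Waterman search against a preprodynorphin
   query with Karlin–Altschul significance (`E = K·m·n·e^{−λS}`, threshold
   `E ≤ 10⁻⁶`), extraction of the subject residues aligned to mature
   dyn A 1–17, unique-hit deduplication (distinct (sequence, species)
   pairs), taxonomic profiling and sequence-logo matrices
   (`R_i = log₂20 − H_i`).
2. **Pharmacology** — competition radioligand binding fit with a
   three-parameter logistic (slope 1) and Cheng–Prusoff conversion
   `K_i = IC₅₀/(1+[L]/K_d)`; monophasic cAMP inhibition
   `y = E_max/(1+EC₅₀/c)` after normalization to the reference agonist's
   10 µM effect; BRET β-arrestin-2 recruitment via the ligand-minus-vehicle
   acceptor/donor ratio difference, quantified as the 311–2411 s windowed
   mean relative to the reference ligand.
3. **Synthetic fixtures** — generators for transcriptome contigs with
   ground-truth manifests and for all three assay types with stated noise
   models, so the whole pipeline is testable without downloads.
4. **Peptide masses** — monoisotopic and [M+H]⁺ masses for linear peptides.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Generate a synthetic transcriptome fixture (50 planted precursors among 500
motif-free decoys) and run the full mining pipeline:

```bash
$ blennymine simulate transcriptome --seed 1 --n-species 50 --n-decoys 500 --outdir demo
wrote 550 contigs (50 planted) to demo
$ blennymine run --contigs demo/contigs.fasta --metadata demo/metadata.tsv \
      --query demo/query.fasta --outdir demo/out
550 contigs -> 50 motif-selected -> 50 hits -> 50 unique hits
```

All 550 contigs are translated in six frames; exactly the 50 planted contigs
carry `YGGF` in a frame, every one of them yields a significant alignment
(recall 100%), and no decoy does (0 false positives). The hit table is
BLAST-outfmt-6-like with 1-based coordinates:

```
contig_id     species      taxon    strand frame score bitscore evalue    ... mature_sequence
contig_00049  species_0049 taxon_01 -      2     123   51.99    4.29e-10  ... YGGFLRRIRPKLKWDNQ
```

The 50 hits collapse to one unique mature sequence observed in 50 species
(50 unique (sequence, species) pairs). Simulate and fit a displacement
experiment at a known affinity:

```bash
$ blennymine simulate binding --seed 1 --ki 3.3 --out demo/binding.csv
wrote 36 cpm observations to demo/binding.csv
$ blennymine pharm fit-binding --data demo/binding.csv
ligand=sim_ki_3.3nM IC50=7.116 nM Ki=3.311 nM top=4022.4 bottom=397.7 converged=True
```

The fitted IC₅₀ of 7.12 nM converts via Cheng–Prusoff ([L] = 1 nM,
K_d = 0.87 nM) to K_i = 3.31 nM, recovering the simulated ground truth of
3.30 nM to within Poisson counting noise. Peptide masses:

```bash
$ blennymine mass YGGFMRRV
id       monoisotopic  mh_plus
peptide  984.4963      985.5036
```

The same operations are available as library functions
(`blennymine.mining`, `blennymine.homology`, `blennymine.pharmacology`,
`blennymine.synthetic_data`, `blennymine.peptide_chem`).

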