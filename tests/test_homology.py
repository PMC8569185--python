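import math

import numpy as np
import pytest
from Bio import Align

from blennymine.exceptions import InputError, ParameterError
from blennymine.homology import (
    AlignmentHit,
    LocalAlignment,
    QueryPrecursor,
    align_local,
    dedup_hits,
    evalue,
    extract_mature,
    load_matrix,
    logo_matrix,
    search,
    taxonomic_profile,
)
from blennymine.mining import CandidateSet, Contig, FrameTranslation
from blennymine.synthetic_data import HUMAN_DYNA_117, make_query_precursor

from oracles import brute_force_local_score

RESIDUES = list("ACDEFGHIKLMNPQRSTVWY")


def _query():
    return make_query_precursor(seed=101)


class TestAlignLocal:
    def test_identity_motif_score(self):
        aln = align_local("YGGF", "YGGF")
        assert aln.score == 25  # BLOSUM62 diagonal: Y/Y=7, G/G=6 x2, F/F=6
        assert aln.aligned_query == "YGGF" and aln.aligned_subject == "YGGF"
        assert aln.query_interval == (1, 4) and aln.subject_interval == (1, 4)

    def test_no_positive_pair_gives_empty_alignment(self):
        aln = align_local("YGGF", "AAAA")
        assert aln.score == 0 and aln.is_empty

    def test_empty_sequence_rejected(self):
        with pytest.raises(ParameterError):
            align_local("", "YGGF")

    def test_matches_brute_force_oracle_on_short_pairs(self):
        table = load_matrix("BLOSUM62")
        rng = np.random.default_rng(17)
        for _ in range(40):
            a = "".join(rng.choice(RESIDUES, size=int(rng.integers(1, 9))))
            b = "".join(rng.choice(RESIDUES, size=int(rng.integers(1, 9))))
            assert align_local(a, b).score == brute_force_local_score(a, b, table)

    def test_matches_biopython_aligner_on_longer_pairs(self):
        aligner = Align.PairwiseAligner()
        aligner.substitution_matrix = Align.substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -12
        aligner.extend_gap_score = -1
        aligner.mode = "local"
        rng = np.random.default_rng(23)
        for _ in range(30):
            a = "".join(rng.choice(RESIDUES, size=int(rng.integers(10, 60))))
            b = "".join(rng.choice(RESIDUES, size=int(rng.integers(10, 60))))
            expected = max(0, int(aligner.score(a, b)))
            assert align_local(a, b).score == expected

    def test_alignment_is_recomputable(self):
        # Ungapping reproduces interval substrings; the score equals the sum of
        # substitution scores minus affine gap costs over the alignment.
        table = load_matrix("BLOSUM62")
        rng = np.random.default_rng(31)
        for _ in range(20):
            a = "".join(rng.choice(RESIDUES, size=40))
            b = "".join(rng.choice(RESIDUES, size=40))
            aln = align_local(a, b)
            if aln.is_empty:
                continue
            qs, qe = aln.query_interval
            ss, se = aln.subject_interval
            assert aln.aligned_query.replace("-", "") == a[qs - 1 : qe]
            assert aln.aligned_subject.replace("-", "") == b[ss - 1 : se]
            score = 0
            gap_run = 0
            for qc, sc in zip(aln.aligned_query, aln.aligned_subject):
                if qc == "-" or sc == "-":
                    score -= 1 if gap_run else 12
                    gap_run += 1
                else:
                    score += table[(qc, sc)]
                    gap_run = 0
            assert score == aln.score


class TestEvalue:
    def test_linear_in_database_length(self):
        e1, _ = evalue(100, 254, 10_000)
        e2, _ = evalue(100, 254, 20_000)
        assert e2 == pytest.approx(2 * e1)

    def test_unit_expectation_closed_form(self):
        lam, K, m, n = 0.267, 0.041, 254, 10_000
        s = math.log(K * m * n) / lam
        e, _ = evalue(s, m, n, lam=lam, K=K)
        assert e == pytest.approx(1.0)

    def test_gapped_blosum62_defaults_direct_formula(self):
        e, bits = evalue(100, 254, 10_000)
        assert e == pytest.approx(0.041 * 254 * 10_000 * math.exp(-26.7))
        assert bits == pytest.approx((0.267 * 100 - math.log(0.041)) / math.log(2))
        # E = m * n * 2**(-S') is the equivalent bit-score form.
        assert 254 * 10_000 * 2.0 ** (-bits) == pytest.approx(e)

    def test_monotone_in_score_and_lengths(self):
        assert evalue(101, 254, 10_000)[0] < evalue(100, 254, 10_000)[0]
        assert evalue(100, 255, 10_000)[0] > evalue(100, 254, 10_000)[0]

    def test_invalid_lengths(self):
        with pytest.raises(ParameterError):
            evalue(100, 0, 10_000)


class TestExtractMature:
    def test_identity_alignment_recovers_core(self):
        query = _query()
        aln = align_local(query.sequence, query.sequence)
        assert extract_mature(aln, query) == query.sequence[206:223]
        assert extract_mature(aln, query) == HUMAN_DYNA_117

    def test_partial_alignment_pads_with_gaps(self):
        query = _query()
        start = query.dynA_interval[0]
        aln = LocalAlignment(
            score=50,
            query_interval=(start, start + 7),
            subject_interval=(1, 8),
            aligned_query=query.sequence[start - 1 : start + 7],
            aligned_subject="YGGFMRRV",
        )
        assert extract_mature(aln, query) == "YGGFMRRV---------"

    def test_subject_insertions_are_dropped(self):
        query = _query()
        start = query.dynA_interval[0]
        aligned_query = query.sequence[start - 1 : start + 3] + "-" + query.sequence[
            start + 3 : start + 7
        ]
        aln = LocalAlignment(
            score=40,
            query_interval=(start, start + 7),
            subject_interval=(1, 9),
            aligned_query=aligned_query,
            aligned_subject="YGGFAMRRV",
        )
        assert extract_mature(aln, query) == "YGGFMRRV---------"

    def test_zero_overlap_rejected(self):
        query = _query()
        aln = LocalAlignment(20, (1, 8), (1, 8), "A" * 8, "A" * 8)
        with pytest.raises(ParameterError):
            extract_mature(aln, query)


class TestSearch:
    def test_default_fixture_recall_and_no_decoys(
        self, default_fixture, default_search
    ):
        planted = {e.contig_id for e in default_fixture.manifest.entries}
        hit_ids = [h.contig_id for h in default_search.hits]
        assert set(hit_ids) == planted and len(hit_ids) == len(planted)
        for hit in default_search.hits:
            assert hit.mature_sequence == HUMAN_DYNA_117
            assert hit.evalue <= 1e-6

    def test_hits_sorted_by_evalue(self, default_search):
        evalues = [h.evalue for h in default_search.hits]
        assert evalues == sorted(evalues)

    def test_zero_threshold_yields_nothing(self, default_fixture, default_search):
        assert (
            search(default_fixture.query, default_search.candidates, threshold=0.0)
            == []
        )

    def test_alignment_outside_dynA_is_excluded(self):
        # A subject identical to a query region far from the mature segment
        # aligns with a tiny E-value but fails the overlap requirement.
        query = _query()
        decoy_protein = query.sequence[:60]
        candidates = CandidateSet(
            contigs={
                "c0": Contig(id="c0", sequence="ATG", species="sp", taxon="tx")
            },
            frames=[FrameTranslation("c0", "+", 0, decoy_protein)],
        )
        assert search(query, candidates) == []

    def test_empty_candidates_warn(self, caplog):
        with caplog.at_level("WARNING"):
            assert search(_query(), CandidateSet()) == []
        assert "empty" in caplog.text


def _hit(mature, species, taxon="tx", contig="c1"):
    return AlignmentHit(
        contig_id=contig, species=species, taxon=taxon, strand="+", frame_offset=0,
        score=97, bitscore=31.0, evalue=1e-9, query_interval=(207, 223),
        subject_interval=(1, 17), aligned_query=mature, aligned_subject=mature,
        mature_sequence=mature,
    )


class TestDedupHits:
    def test_same_sequence_in_three_species(self):
        hits = [_hit("YGGFMRRV" + "-" * 9, s) for s in ("sp1", "sp2", "sp3")]
        unique = dedup_hits(hits)
        assert len(unique) == 1
        assert unique[0].n_pairs == 3 and unique[0].species_set == {"sp1", "sp2", "sp3"}

    def test_same_sequence_same_species_counted_once(self):
        hits = [_hit("A" * 17, "sp1", contig=c) for c in ("c1", "c2")]
        assert sum(u.n_pairs for u in dedup_hits(hits)) == 1

    def test_distinct_sequences_one_species(self):
        # Pair-counting oracle: count distinct (sequence, species) pairs directly.
        rng = np.random.default_rng(2)
        hits = [
            _hit("".join(rng.choice(RESIDUES, size=17)), "sp1") for _ in range(5)
        ]
        expected = len({(h.mature_sequence, h.species) for h in hits})
        assert sum(u.n_pairs for u in dedup_hits(hits)) == expected

    def test_idempotent_and_bounded(self, default_search):
        unique = dedup_hits(default_search.hits)
        total = sum(u.n_pairs for u in unique)
        assert total <= len(default_search.hits)
        # Re-deduplicating a flattened copy changes nothing.
        flattened = [
            _hit(u.mature_sequence, species, taxon=t)
            for u in unique
            for species in sorted(u.species_set)
            for t in [next(iter(u.taxon_counts))]
        ]
        again = dedup_hits(flattened)
        assert [(u.mature_sequence, sorted(u.species_set)) for u in again] == [
            (u.mature_sequence, sorted(u.species_set)) for u in unique
        ]

    def test_missing_species_is_an_error(self):
        with pytest.raises(InputError, match="c1"):
            dedup_hits([_hit("A" * 17, "")])


class TestTaxonomicProfile:
    def test_species_fraction_matches_counts(self):
        # 146 of 200 species with hits -> fraction 0.73.
        taxonomy = {f"sp{i}": f"tax{i % 10}" for i in range(200)}
        transcriptomes = {f"tax{j}": 20 for j in range(10)}
        from blennymine.homology import UniqueHit

        hits = [
            UniqueHit(
                mature_sequence=f"{'YGGF'}{i:013d}"[:17],
                species_set={f"sp{i}"},
                taxon_counts={taxonomy[f"sp{i}"]: 1},
            )
            for i in range(146)
        ]
        profile = taxonomic_profile(hits, taxonomy, transcriptomes)
        assert profile.total_species_with_hits == 146
        assert profile.species_with_hits_fraction == pytest.approx(0.73)

    def test_empty_hits(self):
        profile = taxonomic_profile([], {"sp": "tax"}, {"tax": 1})
        assert profile.total_unique_hits == 0
        assert (profile.table["n_unique_hits"] == 0).all()

    def test_single_taxon_totals(self, default_search):
        unique = dedup_hits(default_search.hits)
        taxonomy = {s: "only" for u in unique for s in u.species_set}
        profile = taxonomic_profile(unique, taxonomy, {"only": len(taxonomy)})
        assert profile.total_unique_hits == profile.table.loc["only", "n_unique_hits"]

    def test_unmapped_species_is_an_error(self):
        from blennymine.homology import UniqueHit

        hits = [UniqueHit("A" * 17, species_set={"mystery"}, taxon_counts={"t": 1})]
        with pytest.raises(InputError, match="mystery"):
            taxonomic_profile(hits, {"other": "t"}, {"t": 1})


class TestLogoMatrix:
    def test_single_residue_column_max_information(self):
        logo = logo_matrix(["Y"])
        assert logo.information[0] == pytest.approx(math.log2(20))

    def test_uniform_column_zero_information(self):
        logo = logo_matrix(list("ACDEFGHIKLMNPQRSTVWY"))
        assert logo.information[0] == pytest.approx(0.0, abs=1e-12)

    def test_half_half_column_one_bit_entropy(self):
        logo = logo_matrix(["Y"] * 10 + ["F"] * 10)
        assert logo.information[0] == pytest.approx(math.log2(20) - 1.0)

    def test_small_sample_correction(self):
        n = 4
        logo = logo_matrix(["Y"] * n, small_sample_correction=True)
        expected = math.log2(20) - 19.0 / (2.0 * math.log(2) * n)
        assert logo.information[0] == pytest.approx(expected)

    def test_frequencies_sum_to_one_and_bounds(self, default_search):
        matures = [h.mature_sequence for h in default_search.hits]
        logo = logo_matrix(matures)
        sums = logo.frequencies.sum(axis=1).to_numpy()
        assert np.allclose(sums[logo.counts > 0], 1.0, atol=1e-9)
        assert np.all(logo.information >= 0)
        assert np.all(logo.information <= math.log2(20) + 1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(9)
        seqs = ["".join(rng.choice(RESIDUES, size=17)) for _ in range(12)]
        forward = logo_matrix(seqs)
        shuffled = logo_matrix(seqs[::-1])
        assert np.allclose(forward.information, shuffled.information)
        assert forward.frequencies.equals(shuffled.frequencies)

    def test_gap_columns_excluded_from_frequencies(self):
        logo = logo_matrix(["Y---", "YY--", "YY-Y"])
        assert logo.counts.tolist() == [3, 2, 0, 1]
        assert logo.information[2] == 0.0

    def test_ragged_input_rejected(self):
        with pytest.raises(InputError):
            logo_matrix(["YGGF", "YGG"])
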