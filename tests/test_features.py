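"""Transcript decomposition and the feature registry."""

from functools import lru_cache

import numpy as np
import pandas as pd
import pytest

from polysome.features import (
    FEATURE_COLUMNS,
    AuxTables,
    au_element_fraction,
    codon_window_stats,
    decompose,
    mirna_site_stats,
    nussinov_max_pairs,
    reverse_complement,
    scan_uorfs,
    structure_scores,
    tabulate,
    uorf_density,
)


def _toy_sequences():
    leader = "GGCCTTGGCCTTGGCCTTGGCCTTGGCCTT"  # 30 nt, no uORF starts
    cds = "ATG" + "GCC" * 8 + "TAA"  # 30 nt
    utr3 = "CCGGTTCCGGTTCCGGTTCCGGTTCCGGTT"  # 30 nt
    return leader, cds, utr3


class TestDecompose:
    def test_single_exon_plus_strand_hand_coordinates(self):
        leader, cds, utr3 = _toy_sequences()
        chrom = leader + cds + utr3
        model = decompose("t1", "g1", "c1", "+", [(0, 90)], (30, 60), chrom)
        assert (len(model.leader), len(model.cds), len(model.utr3)) == (30, 30, 30)
        assert model.leader == leader and model.cds == cds and model.utr3 == utr3

    def test_minus_strand_leader_from_3prime_genomic_side(self):
        leader, cds, utr3 = _toy_sequences()
        transcript = leader + cds + utr3
        chrom = reverse_complement(transcript)
        model = decompose("t1", "g1", "c1", "-", [(0, 90)], (30, 60), chrom)
        assert model.leader == leader and model.cds == cds and model.utr3 == utr3

    def test_noncoding_transcript_flagged(self):
        model = decompose("t1", "g1", "c1", "+", [(0, 30)], None, "GC" * 15)
        assert not model.coding
        assert model.leader == "" and model.utr3 == ""

    def test_cds_outside_exons_rejected(self):
        with pytest.raises(ValueError):
            decompose("t1", "g1", "c1", "+", [(0, 30)], (40, 70), "A" * 100)

    def test_spliced_cds_across_intron(self):
        leader, cds, utr3 = _toy_sequences()
        # insert a 20-nt intron in the middle of the CDS
        chrom = leader + cds[:15] + "G" * 20 + cds[15:] + utr3
        exons = [(0, 45), (65, 110)]
        model = decompose("t1", "g1", "c1", "+", exons, (30, 80), chrom)
        assert model.cds == cds
        assert model.exon_count == 2

    def test_region_additivity_and_validity_on_generated_models(self, small_annotation):
        _, _, ann = small_annotation
        for model in ann.models:
            assert len(model.leader) + len(model.cds) + len(model.utr3) == model.length
            model.validate()  # ATG start, stop end, length % 3 == 0

    def test_strand_round_trip(self):
        leader, cds, utr3 = _toy_sequences()
        transcript = leader + cds + utr3
        plus = decompose("t", "g", "c", "+", [(0, 90)], (30, 60), transcript)
        minus = decompose(
            "t", "g", "c", "-", [(0, 90)], (30, 60), reverse_complement(transcript)
        )
        assert (plus.leader, plus.cds, plus.utr3) == (
            minus.leader, minus.cds, minus.utr3,
        )


class TestAuElementFraction:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("GCGCGCGCGC", 0.0),
            ("AAAAAA", 1.0),
            ("GGAAAAAAGG", 0.6),
            ("AAAAA", 0.0),  # run of 5 is not >5
            ("AUAUAU", 1.0),  # U accepted as T
        ],
    )
    def test_hand_cases(self, seq, expected):
        assert au_element_fraction(seq) == pytest.approx(expected)

    def test_empty_sequence_flagged(self):
        with pytest.raises(ValueError):
            au_element_fraction("")

    def test_bounded_and_monotone_when_extending_run(self):
        rng = np.random.default_rng(0)
        base = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 60)]) + "ATATAT"
        prev = au_element_fraction(base)
        assert 0.0 <= prev <= 1.0
        covered_prev = prev * len(base)
        for extra in range(1, 6):
            seq = base + "A" * extra
            covered = au_element_fraction(seq) * len(seq)
            assert covered >= covered_prev - 1e-9
            covered_prev = covered


class TestCodonWindowStats:
    def test_uniform_table_min_equals_value(self):
        usage = {c: 10.0 for c in ["ATG", "GCC", "TAA"]}
        mean, min_w, _ = codon_window_stats("ATGGCCGCCTAA", usage)
        assert mean == min_w == 10.0

    def test_single_window_mean(self):
        usage = {"AAA": 10.0, "CCC": 1.0}
        cds = "AAA" + "AAA" + "CCC" + "AAA" + "AAA"
        _, min_w, _ = codon_window_stats(cds, usage)
        assert min_w == pytest.approx(8.2)

    def test_cds_shorter_than_window_uses_full_cds(self):
        usage = {"AAA": 4.0, "CCC": 2.0}
        mean, min_w, _ = codon_window_stats("AAACCC", usage)
        assert min_w == pytest.approx(3.0) == mean

    def test_rare_stretch_counting(self):
        # rarity threshold = bottom decile of table values
        usage = {f"{a}{b}{c}": 50.0 for a in "ACGT" for b in "ACGT" for c in "ACGT"}
        usage["AAA"] = 0.1  # rare codon
        cds = "AAA" * 3 + "GGG" * 2 + "AAA" * 4
        _, _, stretches = codon_window_stats(cds, usage)
        assert stretches == 2
        _, _, none = codon_window_stats("AAA" * 2 + "GGG", usage)
        assert none == 0  # run of 2 below min stretch length

    def test_frame_and_vocabulary_errors(self):
        with pytest.raises(ValueError):
            codon_window_stats("ATGA", {"ATG": 1.0})
        with pytest.raises(KeyError):
            codon_window_stats("ATGNNN", {"ATG": 1.0})


class TestScanUorfs:
    def test_single_cognate_uorf(self):
        calls = scan_uorfs("CCCATGAAATAACCC")
        cognate = [c for c in calls if c.cognate]
        assert len(cognate) == 1
        assert (cognate[0].start, cognate[0].end) == (3, 12)

    def test_no_starts_no_calls(self):
        assert scan_uorfs("GGGGGG") == []

    def test_near_cognate_start_is_noncognate(self):
        calls = scan_uorfs("CCCTGAAATGACC")  # CTG ... TGA
        assert any(c.start_codon == "CTG" and not c.cognate for c in calls)

    def test_start_without_stop_not_called(self):
        assert all(not c.cognate for c in scan_uorfs("CCATGAAAAAA"))

    def test_table_mode_counts_leader_records(self):
        table = pd.DataFrame(
            {
                "transcript_id": ["t1", "t1", "t2"],
                "start": [2, 500, 1],
                "end": [11, 509, 10],
                "start_codon": ["ATG", "ATG", "CTG"],
            }
        )
        calls = scan_uorfs("A" * 40, mode="table", table=table, transcript_id="t1")
        assert len(calls) == 1  # the record at 500 is beyond the leader

    def test_planted_uorfs_detected_in_generated_leaders(self, small_annotation):
        _, truth, ann = small_annotation
        with_uorf = truth.index[truth["uorf_config"] == "cognate"]
        models = {m.transcript_id: m for m in ann.models}
        assert len(with_uorf) > 0
        for tx in with_uorf:
            calls = scan_uorfs(models[tx].leader)
            assert any(c.cognate for c in calls)


class TestUorfDensity:
    def test_per_hundred_isoforms(self):
        from polysome.features import UorfCall

        calls = {f"i{k}": [UorfCall(0, 9, "ATG", True)] for k in range(10)}
        cognate, noncognate = uorf_density([f"i{k}" for k in range(50)], calls)
        assert cognate == 20.0 and noncognate == 0.0

    def test_no_uorfs(self):
        assert uorf_density(["a", "b"], {}) == (0.0, 0.0)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            uorf_density([], {})


class TestStructureScores:
    def test_unpairable_sequence_scores_zero(self):
        assert structure_scores("A" * 75) == (0.0, 0.0)

    def test_perfect_hairpin_counts_stem_pairs(self):
        stem = "GCATGCCATG"
        hairpin = stem + "AAAA" + reverse_complement(stem)
        assert nussinov_max_pairs(hairpin) == 10
        cap, min_w = structure_scores(hairpin)
        assert min_w == -10.0

    def test_window_longer_than_leader_single_window(self):
        cap, min_w = structure_scores("GCGCAAAAGCGC", window=75)
        assert cap == min_w

    def test_min_window_at_most_cap(self):
        rng = np.random.default_rng(1)
        leader = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 100)])
        cap, min_w = structure_scores(leader)
        assert min_w <= cap

    def test_nonnucleotide_rejected(self):
        with pytest.raises(ValueError):
            nussinov_max_pairs("ACGX")

    def test_matches_exhaustive_pairing_oracle(self):
        pairs = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}

        def oracle(s, min_loop=3):
            @lru_cache(None)
            def best(i, j):  # max pairs in s[i:j]
                if j - i < min_loop + 2:
                    return 0
                b = best(i, j - 1)
                for k in range(i, j - min_loop - 1):
                    if (s[k], s[j - 1]) in pairs:
                        b = max(b, best(i, k) + 1 + best(k + 1, j - 1))
                return b

            return best(0, len(s))

        rng = np.random.default_rng(2)
        for _ in range(150):
            seq = "".join(
                np.array(list("ACGT"))[rng.integers(0, 4, rng.integers(1, 17))]
            )
            assert nussinov_max_pairs(seq) == oracle(seq), seq

    def test_pluggable_backend(self):
        cap, min_w = structure_scores("ACGT" * 30, window=75, backend=len)
        assert cap == 75.0 and min_w == 75.0


class TestMirnaSiteStats:
    def _table(self):
        return pd.DataFrame(
            {
                "transcript_id": ["t"] * 3,
                "site_start": [100, 150, 10],
                "site_end": [108, 158, 18],
                "miRNA_id": ["miR-1", "miR-2", "miR-1"],
                "context_score": [-0.3, -0.2, -0.5],
            }
        )

    def test_empty_table_zeros(self):
        empty = self._table().iloc[:0]
        assert mirna_site_stats((90, 200), empty, {"miR-1"}) == (0, 0.0, 0, 0.0)

    def test_expressed_filtering(self):
        count_a, score_a, count_e, score_e = mirna_site_stats(
            (90, 200), self._table(), {"miR-1"}
        )
        assert (count_a, count_e) == (2, 1)
        assert score_a == pytest.approx(-0.5)
        assert score_e == pytest.approx(-0.3)

    def test_site_outside_utr_not_counted(self):
        count_a, *_ = mirna_site_stats((90, 200), self._table(), None)
        assert count_a == 2  # the site at 10-18 is upstream of the UTR

    def test_malformed_table_rejected(self):
        with pytest.raises(ValueError):
            mirna_site_stats((0, 10), pd.DataFrame({"oops": [1]}), None)


class TestTabulate:
    def test_full_synthetic_run_covers_registry(self, small_annotation):
        counts, truth, ann = small_annotation
        avg = counts.T.groupby(
            counts.columns.map(lambda c: c.rsplit("_", 1)[0])
        ).mean().T
        models = ann.models[:25]
        table = tabulate(models, matrix=avg, aux=ann.aux)
        assert list(table.columns) == list(FEATURE_COLUMNS)
        assert len(table) == len(models)
        assert not table.isna().all().any(), "no feature column may be entirely missing"

    def test_missing_half_life_is_missing_not_zero(self, small_annotation):
        _, _, ann = small_annotation
        aux = AuxTables(
            codon_usage=ann.aux.codon_usage,
            half_life={},  # no records at all
        )
        table = tabulate(ann.models[:3], aux=aux)
        assert table["half_life"].isna().all()

    def test_median_polysome_expression_is_hand_median(self, small_annotation):
        counts, _, ann = small_annotation
        from polysome.quantify import RIBO_FRACTIONS

        avg = counts.T.groupby(
            counts.columns.map(lambda c: c.rsplit("_", 1)[0])
        ).mean().T
        model = ann.models[0]
        table = tabulate([model], matrix=avg, aux=ann.aux)
        expected = np.median(avg.loc[model.transcript_id, list(RIBO_FRACTIONS)])
        assert table.at[model.transcript_id, "median_polysome_expression"] == expected

    def test_planted_utr_length_contrast(self, small_annotation):
        _, truth, ann = small_annotation
        lengths = pd.Series(
            {m.transcript_id: len(m.utr3) for m in ann.models}
        )
        long_mean = lengths[truth["utr3_class"] == "long"].mean()
        short_mean = lengths[truth["utr3_class"] == "short"].mean()
        assert long_mean > short_mean
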