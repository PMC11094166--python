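import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from utrkit import atlas
from utrkit.models import CleavageSite, TranscriptModel


def brute_force_local_modes(pos_counts: dict, radius: int):
    """Independent oracle: literal restatement of the iterative merge rule."""
    remaining = dict(pos_counts)
    peaks = {}
    while remaining:
        top = max(remaining.items(), key=lambda kv: (kv[1], -kv[0]))[0]
        absorbed = [p for p in remaining if abs(p - top) <= radius]
        peaks[top] = sum(remaining[p] for p in absorbed)
        for p in absorbed:
            del remaining[p]
    return peaks


def _cov(pos_counts, chrom="c", strand="+", group="x"):
    return pd.DataFrame({
        "chrom": chrom, "position": list(pos_counts), "strand": strand,
        "count": list(pos_counts.values()), "cell_type": group,
    })


class TestCallPeaks:
    def test_merge_example(self):
        pk = atlas.call_peaks(_cov({100: 10, 115: 4, 180: 7}), radius=30,
                              rpm_threshold=5, library_size=10**6)
        assert {(p.position, p.support) for p in pk} == {(100, 14), (180, 7)}

    def test_rpm_strictly_greater_retains(self):
        pk = atlas.call_peaks(_cov({500: 6}), library_size=10**6)
        assert [(p.position, p.support) for p in pk] == [(500, 6)]

    def test_rpm_at_threshold_is_dropped(self):
        assert atlas.call_peaks(_cov({500: 5}), library_size=10**6) == []

    def test_empty_coverage_and_bad_library_size(self):
        assert atlas.call_peaks(_cov({})) == []
        with pytest.raises(ValueError):
            atlas.call_peaks(_cov({10: 1}), library_size=0)

    @settings(max_examples=300, derandomize=True)
    @given(st.dictionaries(st.integers(0, 200), st.integers(1, 50),
                           min_size=1, max_size=12))
    def test_greedy_matches_exhaustive_oracle(self, pos_counts):
        modes, supports, _ = atlas.merge_local_modes(
            list(pos_counts), list(pos_counts.values()), radius=30)
        assert dict(zip(modes.tolist(), supports.tolist())) == \
            brute_force_local_modes(pos_counts, 30)

    @settings(max_examples=200, derandomize=True)
    @given(st.dictionaries(st.integers(0, 500), st.integers(1, 50),
                           min_size=1, max_size=12))
    def test_peaks_pairwise_beyond_radius(self, pos_counts):
        modes, _, _ = atlas.merge_local_modes(
            list(pos_counts), list(pos_counts.values()), radius=30)
        modes = np.sort(modes)
        assert (np.diff(modes) > 30).all()


class TestHarmonize:
    def test_cross_celltype_merge(self):
        a = atlas.call_peaks(_cov({100: 14}), library_size=10**6)
        b = atlas.call_peaks(_cov({110: 9}), library_size=10**6)
        merged = atlas.harmonize_peaks({"A": a, "B": b}, radius=30)
        assert len(merged) == 1
        site = merged[0]
        assert (site.position, site.support, site.n_celltypes_used) == (100, 23, 2)

    def test_idempotent_on_isolated_peaks(self):
        a = atlas.call_peaks(_cov({100: 14, 300: 9}), library_size=10**6)
        merged = atlas.harmonize_peaks({"A": a}, radius=30)
        assert [(s.position, s.support) for s in merged] == [(100, 14), (300, 9)]

    def test_beyond_radius_kept_separate(self):
        a = atlas.call_peaks(_cov({100: 10}), library_size=10**6)
        b = atlas.call_peaks(_cov({161: 10}), library_size=10**6)
        merged = atlas.harmonize_peaks({"A": a, "B": b}, radius=30)
        assert [s.position for s in merged] == [100, 161]


class TestPrimingFilter:
    @pytest.mark.parametrize("seq,expected", [
        ("ACGTACGTACGTACGTACGT", True),    # 25% A
        ("AAAAAAAACGTACGTACGTA", False),   # 8-A run
        ("AAGAAGAAAGAAAGAAGAAA", False),   # 13/20 = 0.65 A fraction
    ])
    def test_downstream_composition(self, seq, expected):
        genome = {"c": "G" * 100 + "C" + seq + "G" * 100}
        site = CleavageSite(chrom="c", strand="+", position=100)
        assert atlas.internal_priming_filter(site, genome) is expected

    def test_minus_strand_uses_transcript_orientation(self):
        # upstream genomic T-stretch reads as downstream A on the minus strand
        genome = {"c": "G" * 80 + "T" * 20 + "C" + "G" * 100}
        site = CleavageSite(chrom="c", strand="-", position=100)
        assert atlas.internal_priming_filter(site, genome) is False

    def test_window_truncated_at_contig_end(self):
        genome = {"c": "G" * 10 + "AC"}
        site = CleavageSite(chrom="c", strand="+", position=9)
        assert atlas.internal_priming_filter(site, genome) is True


class TestClassify:
    def _genome(self):
        return {"c": "ACGT" * 5000}

    def _site(self, pos):
        return CleavageSite(chrom="c", strand="+", position=pos, support=10)

    def test_validated_within_window(self):
        ends = pd.DataFrame({"chrom": ["c"], "position": [1000], "strand": ["+"]})
        clusters = pd.DataFrame(columns=["chrom", "position", "strand", "tpm"])
        out = atlas.classify_sites([self._site(1015)], ends, clusters, self._genome())
        assert out[0].class_label == "validated"

    def test_supported_by_external_cluster(self):
        ends = pd.DataFrame({"chrom": ["c"], "position": [1000], "strand": ["+"]})
        clusters = pd.DataFrame({"chrom": ["c"], "position": [1026], "strand": ["+"],
                                 "tpm": [10.0]})
        out = atlas.classify_sites([self._site(1021)], ends, clusters, self._genome())
        assert out[0].class_label == "supported"

    def test_weak_cluster_ignored_and_priming_discards(self):
        ends = pd.DataFrame(columns=["chrom", "position", "strand"])
        clusters = pd.DataFrame({"chrom": ["c"], "position": [1021], "strand": ["+"],
                                 "tpm": [2.0]})
        genome = {"c": "G" * 2000 + "A" * 100}
        out = atlas.classify_sites([CleavageSite("c", "+", 1999)], ends, clusters, genome)
        assert out[0].class_label == "discarded"

    def test_labels_partition_and_retained_atlas(self):
        ends = pd.DataFrame({"chrom": ["c"], "position": [1000], "strand": ["+"]})
        clusters = pd.DataFrame({"chrom": ["c"], "position": [2000], "strand": ["+"],
                                 "tpm": [5.0]})
        genome = {"c": "ACGT" * 1000 + "A" * 50 + "ACGT" * 1000}
        sites = [CleavageSite("c", "+", p) for p in (1010, 2005, 3000, 3999)]
        out = atlas.classify_sites(sites, ends, clusters, genome)
        labels = [s.class_label for s in out]
        assert set(labels) <= {"validated", "supported", "likely", "discarded"}
        retained = atlas.retained_atlas(out)
        assert all(s.class_label in ("supported", "likely") for s in retained)
        assert not any(s.class_label == "discarded" for s in retained)


class TestAnnotateRegion:
    def _transcripts(self):
        utr_tx = TranscriptModel("t1", "g1", "c", "+", [(100, 2000)],
                                 cds_start=200, cds_end=1500)
        intronic = TranscriptModel("t2", "g2", "c", "+", [(1500, 1600), (1900, 2200)])
        return [utr_tx, intronic]

    def test_three_prime_utr_takes_precedence_over_intron(self):
        site = CleavageSite("c", "+", 1700)
        out = atlas.annotate_region(site, self._transcripts())
        assert out.region_label == "three_prime_UTR"
        assert out.gene_id == "g1"

    def test_extended_three_prime_utr(self):
        site = atlas.annotate_region(CleavageSite("c", "+", 2500), self._transcripts())
        assert site.region_label == "extended_three_prime_UTR"

    def test_intergenic_beyond_extensions(self):
        site = atlas.annotate_region(CleavageSite("c", "+", 9000), self._transcripts())
        assert site.region_label == "intergenic"

    def test_five_prime_side_labels(self):
        txs = self._transcripts()
        assert atlas.annotate_region(CleavageSite("c", "+", 150), txs).region_label \
            == "five_prime_UTR"
        assert atlas.annotate_region(CleavageSite("c", "+", 50), txs).region_label \
            == "extended_five_prime_UTR"

    def test_opposite_strand_never_matches(self):
        site = atlas.annotate_region(CleavageSite("c", "-", 1700), self._transcripts())
        assert site.region_label == "intergenic"


class TestUsageScore:
    def test_minor_fraction(self):
        score, klass = atlas.usage_score({f"ct{i}" for i in range(5)},
                                         {f"ct{i}" for i in range(50)})
        assert score == pytest.approx(0.1) and klass == "minor"

    def test_full_usage_is_major_with_enough_celltypes(self):
        cts = {f"ct{i}" for i in range(12)}
        score, klass = atlas.usage_score(cts, cts)
        assert score == 1.0 and klass == "major"

    def test_nine_of_nine_is_minor_under_count_rule(self):
        cts = {f"ct{i}" for i in range(9)}
        score, klass = atlas.usage_score(cts, cts)
        assert score == 1.0 and klass == "minor"
        # documented switch: the fraction rule calls the same site major
        _, klass_frac = atlas.usage_score(cts, cts, minor_rule="fraction")
        assert klass_frac == "major"

    def test_undefined_when_gene_not_expressed(self):
        with pytest.raises(ValueError):
            atlas.usage_score(set(), set())

    def test_score_monotone_in_usage(self):
        expressing = {f"ct{i}" for i in range(20)}
        scores = [atlas.usage_score({f"ct{i}" for i in range(k)}, expressing)[0]
                  for k in range(1, 21)]
        assert all(b >= a for a, b in zip(scores, scores[1:]))
        assert all(0.0 <= s <= 1.0 for s in scores)


class TestMotifDensity:
    def test_planted_pas_spike(self):
        rng = np.random.default_rng(1)
        base = "".join(rng.choice(list("CG"), size=5000))
        # plant AATAAA ending 21 nt upstream of each CS (occupies -26..-21)
        sites = []
        seq = list(base)
        for pos in (1000, 2000, 3000):
            seq[pos - 26: pos - 20] = list("AATAAA")
            sites.append(CleavageSite("c", "+", pos))
        genome = {"c": "".join(seq)}
        dens = atlas.motif_positional_density(
            sites, genome, {"PAS": ("AWTAAA", (-50, 0))})["PAS"]
        assert dens.idxmax() == -24
        assert dens.max() == 1.0
        assert dens.drop(index=-24).max() == 0.0

    def test_absent_motif_all_zero(self):
        genome = {"c": "C" * 200}
        dens = atlas.motif_positional_density(
            [CleavageSite("c", "+", 100)], genome, {"PAS": ("AWTAAA", (-50, 0))})["PAS"]
        assert (dens == 0).all()

    def test_iupac_expansion_counts_both_variants(self):
        seq = "C" * 40 + "AATAAA" + "C" * 10 + "ATTAAA" + "C" * 40
        genome = {"c": seq}
        site = CleavageSite("c", "+", 90)
        dens = atlas.motif_positional_density(
            [site], genome, {"PAS": ("AWTAAA", (-60, 0))})["PAS"]
        assert (dens > 0).sum() == 2

    def test_invalid_iupac_symbol_errors(self):
        with pytest.raises(ValueError, match="IUPAC"):
            atlas.iupac_to_regex("AXTAAA")
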