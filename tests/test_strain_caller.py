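"""Caller contracts: quality filter, alignment rule, thresholding, rescue."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mastkit import (
    CallerParams,
    QualityRead,
    Strain,
    align_read,
    call_strains,
    filter_reads,
    make_marker_reference,
    reads_at_threshold,
    rescue_cryptic,
    snp_distance,
)

REF = make_marker_reference(40, seed=0, name="m")


def _sub(seq, i):
    """Substitute position i with a base guaranteed to differ."""
    new = "A" if seq[i] != "A" else "C"
    return seq[:i] + new + seq[i + 1 :]


def _read(bases, qual):
    quals = np.full(len(bases), qual) if np.isscalar(qual) else np.asarray(qual)
    return QualityRead("r", bases, quals)


class TestFilterReads:
    @pytest.mark.parametrize(
        "qual,kept",
        [(40, True), (30, True), (29, False), (0, False)],
        ids=["q40", "q30-boundary", "q29", "q0"],
    )
    def test_mean_quality_boundary(self, qual, kept):
        reads = [_read("ACGT" * 10, qual)]
        retained, discarded = filter_reads(reads)
        assert (len(retained), discarded) == ((1, 0) if kept else (0, 1))

    def test_mixed_qualities_average_exactly_thirty_retained(self):
        bases = "A" * 20
        quals = [20] * 10 + [40] * 10
        retained, _ = filter_reads([_read(bases, quals)])
        assert len(retained) == 1

    def test_n_bases_discarded_by_default(self):
        reads = [_read("ACGN" + "A" * 10, 40)]
        assert filter_reads(reads)[1] == 1
        assert filter_reads(reads, CallerParams(allow_n=True))[1] == 0

    def test_quality_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            QualityRead("r", "ACGT", np.array([40, 40]))


class TestAlignRead:
    def test_identical_to_reference(self):
        assert align_read(REF.sequence, REF) == REF.sequence

    def test_substitutions_kept_no_mismatch_limit(self):
        hap = "T" * len(REF)
        assert align_read(hap, REF) == hap

    def test_length_mismatch_rejected(self):
        assert align_read(REF.sequence[:-1], REF) is None
        assert align_read(REF.sequence + "A", REF) is None


class TestCallStrains:
    def test_threshold_is_strict(self):
        """At 46,000 reads, exactly 1% (460 reads) is not called; 461 is."""
        assert reads_at_threshold(46_000, 0.01) == 460
        variant = "A" * len(REF) if REF.sequence[0] != "A" else "C" * len(REF)
        for support, called in [(460, False), (461, True)]:
            pool = [REF.sequence] * (46_000 - support) + [variant] * support
            table = call_strains({("s1", "m"): pool}, {"m": REF})
            assert (variant in {s.sequence for s in table.registry.values()}) is called

    def test_single_sample_uniform_pool(self):
        table = call_strains({("s1", "m"): [REF.sequence] * 100}, {"m": REF})
        assert len(table.registry) == 1
        assert table.frequencies().iloc[0, 0] == 1.0

    def test_registry_strain_reported_where_subthreshold(self):
        """Called somewhere -> counted everywhere, but present only above 1%."""
        hap = _sub(REF.sequence, 0)
        pool_a = [REF.sequence] * 95 + [hap] * 5          # 5%
        pool_b = [REF.sequence] * 998 + [hap] * 2         # 0.2%
        table = call_strains({("a", "m"): pool_a, ("b", "m"): pool_b}, {"m": REF})
        seqs = {sid: s.sequence for sid, s in table.registry.items()}
        sid = next(k for k, v in seqs.items() if v == hap)
        assert table.counts.loc[("m", sid), "b"] == 2
        pres = table.presence("m")
        assert bool(pres.loc[sid, "a"]) and not bool(pres.loc[sid, "b"])

    def test_count_conservation_and_read_order_invariance(self, small_truth, clean_sim, clean_table):
        from mastkit import pools_from_reads

        pools, _ = pools_from_reads(clean_sim.quality_reads(), small_truth.references)
        for (sample, marker), haps in pools.items():
            total = clean_table.totals.loc[marker, sample]
            assert total == len(haps)
        rng = np.random.default_rng(0)
        shuffled = {k: [v[i] for i in rng.permutation(len(v))] for k, v in pools.items()}
        table2 = call_strains(shuffled, small_truth.references)
        assert table2.counts.equals(clean_table.counts)
        assert {s.sequence for s in table2.registry.values()} == {
            s.sequence for s in clean_table.registry.values()
        }

    def test_raising_threshold_never_grows_registry(self):
        rng = np.random.default_rng(4)
        haps = [REF.sequence, _sub(REF.sequence, 0), _sub(REF.sequence, 1)]
        pools = {
            (f"s{i}", "m"): [haps[j] for j in rng.choice(3, 200, p=[0.9, 0.07, 0.03])]
            for i in range(4)
        }
        sizes = [
            len(call_strains(pools, {"m": REF}, CallerParams(freq_threshold=t)).registry)
            for t in (0.005, 0.02, 0.05, 0.2)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_oracle_equivalence_on_error_free_reads(self, small_truth, clean_table):
        """Called presence exactly matches planted composition above 1%."""
        pres = clean_table.presence()
        seq_of = {sid: s.sequence for sid, s in clean_table.registry.items()}
        for marker in small_truth.markers:
            for bee in small_truth.bees:
                expected = small_truth.expected_strains(bee, marker)
                called = {
                    seq_of[sid]
                    for sid in clean_table.presence(marker).index
                    if clean_table.presence(marker).loc[sid, bee]
                }
                assert called == expected

    def test_missing_samples_flagged(self):
        table = call_strains(
            {("a", "m"): [REF.sequence] * 10}, {"m": REF}, samples=["a", "b"]
        )
        assert np.isnan(table.totals.loc["m", "b"])
        assert table.marker_samples("m") == ["a"]


class TestSnpDistance:
    def test_identity_and_direct_count(self):
        s = REF.sequence
        assert snp_distance(s, s) == 0
        assert snp_distance(s, _sub(_sub(s, 0), 5)) == 2

    def test_marker_mismatch_rejected(self):
        a = Strain("m1", "a", REF.sequence, frozenset())
        b = Strain("m2", "b", REF.sequence, frozenset())
        with pytest.raises(ValueError):
            snp_distance(a, b)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.sampled_from("ACGT"), min_size=12, max_size=12).map("".join),
           st.lists(st.sampled_from("ACGT"), min_size=12, max_size=12).map("".join),
           st.lists(st.sampled_from("ACGT"), min_size=12, max_size=12).map("".join))
    def test_metric_properties(self, a, b, c):
        assert snp_distance(a, b) == snp_distance(b, a)
        assert (snp_distance(a, b) == 0) == (a == b)
        assert snp_distance(a, c) <= snp_distance(a, b) + snp_distance(b, c)


class TestRescueCryptic:
    def test_fold_change_construction(self):
        """A strain above threshold in one sample and single-read in another
        doubles its prevalence under the relaxed search."""
        hap = _sub(REF.sequence, 0)
        pools = {
            ("a", "m"): [REF.sequence] * 90 + [hap] * 10,   # 10% -> called
            ("b", "m"): [REF.sequence] * 999 + [hap] * 1,   # 0.1% -> cryptic
            ("c", "m"): [REF.sequence] * 100,
        }
        table = call_strains(pools, {"m": REF})
        rescue = rescue_cryptic(table, pools)
        seqs = {sid: s.sequence for sid, s in table.registry.items()}
        row = rescue.loc[next(k for k, v in seqs.items() if v == hap)]
        assert row["strict_prevalence"] == pytest.approx(1 / 3)
        assert row["relaxed_prevalence"] == pytest.approx(2 / 3)
        assert row["fold_change"] == pytest.approx(2.0)
        ref_row = rescue.loc[next(k for k, v in seqs.items() if v == REF.sequence)]
        assert ref_row["fold_change"] == pytest.approx(1.0)

    def test_relaxed_never_below_strict(self, small_truth, clean_sim, clean_table):
        rescue = rescue_cryptic(clean_table, clean_sim.pools())
        assert (rescue["relaxed_prevalence"] >= rescue["strict_prevalence"] - 1e-12).all()
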