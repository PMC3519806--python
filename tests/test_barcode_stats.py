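"""K2P distances, group summaries, site classification and the barcode gap."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from allobarcode.barcode_stats import (
    EmptyOverlapError,
    PairwiseSiteCounts,
    barcode_gap,
    classify_sites,
    count_site_differences,
    k2p,
    k2p_matrix,
    p_distance,
    summarize_groups,
)
from conftest import make_matrix

# reference K80 distances for the fixed 6-sequence oracle alignment,
# computed independently with ape::dist.dna(model="K80",
# pairwise.deletion=TRUE)
ORACLE_SEQS = {
    "s1": "ATGCGTAGAAGAGTGTGTGCCTATTGCAGCCAAGTATGCGATGCATATGGGACCCAGAGG",
    "s2": "ATGCCTAGGAGTGGGTTATCGCATTGCTGCCAAGTATACCATGCATCTGGTACCCAGAGG",
    "s3": "ATCCCTCCAAGTGGGTGATCGCACTATTCCAAAGTATTCGGTGCATCTGTTACCCAGAGG",
    "s4": "ATGCCTAGAAGTGTGGGATCGCAGTGCTGCCAAGTATTCGATGCATCTGTTCCCCAGAAG",
    "s5": "ATGCCTACAA---TGTGATCGCATCGCTGCAACGTATGCGATGCATCTGTTACCCAGAGG",
    "s6": "AGGCCAAGAA---TGTGATCGCATTGCTGCCAAGTATTCGACTCGTCTGTTACCCACAGG",
}
ORACLE_K80 = [
    ("s1", "s2", 0.280761823888),
    ("s1", "s3", 0.474527031815),
    ("s1", "s4", 0.308568232666),
    ("s1", "s5", 0.274616626362),
    ("s1", "s6", 0.354998569891),
    ("s2", "s3", 0.279554983744),
    ("s2", "s4", 0.189110507733),
    ("s2", "s5", 0.199893604993),
    ("s2", "s6", 0.247563230202),
    ("s3", "s4", 0.255740959249),
    ("s3", "s5", 0.223836795081),
    ("s3", "s6", 0.351884941970),
    ("s4", "s5", 0.177667723708),
    ("s4", "s6", 0.199893604993),
    ("s5", "s6", 0.223295376353),
]

random_dna = st.text(alphabet="ACGT", min_size=1, max_size=80)


class TestSiteCounts:
    def test_identical_sequences(self):
        counts = count_site_differences("A" * 50, "A" * 50)
        assert (counts.compared_sites, counts.transitions,
                counts.transversions) == (50, 0, 0)

    def test_single_transition(self):
        counts = count_site_differences("ACGT", "GCGT")
        assert counts.transitions == 1 and counts.transversions == 0

    @pytest.mark.parametrize("a,b,ts,tv", [
        ("AC", "AT", 1, 0),     # C<->T: both pyrimidines, a transition
        ("AA", "AG", 1, 0),     # A<->G: both purines, a transition
        ("AA", "AC", 0, 1),     # purine vs pyrimidine: a transversion
        ("AA", "AT", 0, 1),
    ])
    def test_transition_definition(self, a, b, ts, tv):
        counts = count_site_differences(a, b)
        assert (counts.transitions, counts.transversions) == (ts, tv)

    def test_proportions_from_planted_differences(self):
        base = list("ACGT" * 25)
        other = base.copy()
        for col in (0, 8, 16, 24):          # A -> G transitions
            other[col] = "G"
        for col in (33, 41):                # C -> A transversions
            other[col] = "A"
        counts = count_site_differences("".join(base), "".join(other))
        assert counts.compared_sites == 100
        assert counts.P == pytest.approx(0.04)
        assert counts.Q == pytest.approx(0.02)

    def test_gaps_and_ambiguity_excluded(self):
        counts = count_site_differences("AC-GN", "ACAGT")
        assert counts.compared_sites == 3

    def test_empty_overlap(self):
        with pytest.raises(EmptyOverlapError):
            count_site_differences("--AA", "TT--")


class TestK2P:
    def test_zero_distance(self):
        assert k2p(PairwiseSiteCounts(100, 0, 0)) == 0.0

    def test_closed_form(self):
        counts = PairwiseSiteCounts(100, 4, 2)
        expected = -0.5 * math.log(1 - 2 * 0.04 - 0.02) \
            - 0.25 * math.log(1 - 2 * 0.02)
        assert k2p(counts) == pytest.approx(expected, abs=1e-12)
        assert k2p(counts) == pytest.approx(0.06289, abs=5e-6)

    def test_saturation_flag(self):
        assert math.isnan(k2p(PairwiseSiteCounts(100, 50, 0)))

    def test_matches_independent_reference_distances(self):
        dm = k2p_matrix(make_matrix(ORACLE_SEQS))
        for id1, id2, expected in ORACLE_K80:
            assert dm.get(id1, id2) == pytest.approx(expected, abs=1e-9)

    @given(st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_k2p_dominates_p_distance(self, data):
        seq1 = data.draw(random_dna)
        seq2 = data.draw(st.text(alphabet="ACGT", min_size=len(seq1),
                                 max_size=len(seq1)))
        counts = count_site_differences(seq1, seq2)
        d = k2p(counts)
        if not math.isnan(d):
            assert d >= p_distance(counts) - 1e-12

    def test_jukes_cantor_consistency(self):
        # with transitions:transversions at 1:2 the K2P correction must
        # numerically match the JC69 closed form at small distances
        for p in (0.01, 0.03, 0.06):
            n = 30000
            ts = int(round(p * n / 3))
            counts = PairwiseSiteCounts(n, ts, 2 * ts)
            p_obs = 3 * ts / n
            jc = -0.75 * math.log(1 - 4 * p_obs / 3)
            assert k2p(counts) == pytest.approx(jc, abs=1e-3)


class TestK2PMatrix:
    def test_identical_sequences_zero_matrix(self):
        dm = k2p_matrix(make_matrix({"a": "ACGT", "b": "ACGT", "c": "ACGT"}))
        assert np.allclose(dm.values, 0.0)

    def test_equals_pairwise_brute_force(self, small_dataset):
        matrix = small_dataset.matrices["trnLF"].subset(
            small_dataset.matrices["trnLF"].ids()[:8]
        )
        dm = k2p_matrix(matrix)
        for i, j in itertools.combinations(range(len(matrix)), 2):
            expected = k2p(count_site_differences(
                matrix.records[i].residues, matrix.records[j].residues))
            assert dm.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_permutation_consistency(self):
        seqs = dict(ORACLE_SEQS)
        dm = k2p_matrix(make_matrix(seqs))
        reversed_ids = list(seqs)[::-1]
        dm_rev = k2p_matrix(make_matrix({k: seqs[k] for k in reversed_ids}))
        for id1, id2, _ in ORACLE_K80:
            assert dm.get(id1, id2) == pytest.approx(dm_rev.get(id1, id2))

    def test_complete_set_deletion_drops_gap_columns(self):
        m = make_matrix({"a": "ACGTAC", "b": "AC-TAC", "c": "ACGTAT"})
        dm = k2p_matrix(m, "complete-set")
        pairwise = k2p_matrix(m, "pairwise")
        # a/c differ at the last column which survives both policies
        assert dm.get("a", "c") == pytest.approx(
            k2p(count_site_differences("ACTAC", "ACTAT")))
        assert pairwise.get("a", "c") > 0


class TestGroupSummary:
    def test_singleton_groups(self):
        m = make_matrix({"a": "A" * 100, "b": "A" * 95 + "G" * 5})
        dm = k2p_matrix(m)
        summary = summarize_groups(dm, {"a": "A", "b": "B"})
        assert summary.intra["A"].mean is None
        assert summary.inter_between("A", "B").mean == pytest.approx(
            dm.get("a", "b"))

    def test_equals_brute_force_enumeration(self):
        labels = {"s1": "A", "s2": "A", "s3": "A", "s4": "B", "s5": "B",
                  "s6": "B"}
        dm = k2p_matrix(make_matrix(ORACLE_SEQS))
        summary = summarize_groups(dm, labels)
        for group in ("A", "B"):
            members = [sid for sid, g in labels.items() if g == group]
            values = [dm.get(a, b)
                      for a, b in itertools.combinations(members, 2)]
            stats = summary.intra[group]
            assert stats.mean == pytest.approx(np.mean(values))
            assert stats.minimum == pytest.approx(min(values))
            assert stats.maximum == pytest.approx(max(values))
            assert stats.sd == pytest.approx(np.std(values, ddof=1))
        cross = [dm.get(a, b)
                 for a in ("s1", "s2", "s3") for b in ("s4", "s5", "s6")]
        assert summary.inter_between("A", "B").mean == pytest.approx(
            np.mean(cross))


class TestClassifySites:
    def test_single_fixed_difference(self):
        m = make_matrix({"a1": "ACGT", "a2": "ACGT", "b1": "TCGT",
                         "b2": "TCGT"})
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        sites = classify_sites(m, labels)
        assert sites.variable_sites == [0]
        assert sites.diagnostic_sites == [(0, "A", "T")]

    def test_polymorphic_column_not_diagnostic(self):
        m = make_matrix({"a1": "ACGT", "a2": "ACGT", "b1": "ACGT",
                         "b2": "GCGT"})
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        sites = classify_sites(m, labels)
        assert sites.variable_sites == [0]
        assert sites.diagnostic_sites == []

    def test_planted_differences_recovered(self):
        rng = np.random.default_rng(5)
        length = 120
        backbone = "".join(rng.choice(list("ACGT"), length))
        other = list(backbone)
        planted = sorted(rng.choice(length, 10, replace=False))
        for col in planted:
            other[col] = {"A": "G", "G": "A", "C": "T", "T": "C"}[other[col]]
        m = make_matrix({"a1": backbone, "a2": backbone,
                         "b1": "".join(other), "b2": "".join(other)})
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        sites = classify_sites(m, labels)
        assert [c for c, _, _ in sites.diagnostic_sites] == planted

    def test_diagnostic_indel_runs(self):
        m = make_matrix({"a1": "ACGTACGT", "a2": "ACGTACGT",
                         "b1": "AC--ACGT", "b2": "AC--ACGT"})
        labels = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        sites = classify_sites(m, labels)
        assert len(sites.diagnostic_indels) == 1
        run = sites.diagnostic_indels[0]
        assert (run.start, run.stop, run.gapped_group) == (2, 4, "B")
        # gap columns are not nucleotide-diagnostic sites
        assert all(c not in (2, 3) for c, _, _ in sites.diagnostic_sites)


class TestBarcodeGap:
    def test_gap_present_with_margin(self):
        m = make_matrix({
            "a1": "A" * 200, "a2": "A" * 198 + "GG",
            "b1": "C" * 20 + "A" * 180, "b2": "C" * 20 + "A" * 178 + "GG",
        })
        summary = summarize_groups(
            k2p_matrix(m), {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        report = barcode_gap(summary)
        assert report.gap_present and report.margin > 0

    def test_gap_absent_when_intra_exceeds_inter(self):
        m = make_matrix({
            "a1": "A" * 200, "a2": "C" * 30 + "A" * 170,
            "b1": "G" + "A" * 199, "b2": "G" + "C" * 30 + "A" * 169,
        })
        summary = summarize_groups(
            k2p_matrix(m), {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert not barcode_gap(summary).gap_present

    def test_undefined_intra_warns(self):
        m = make_matrix({"a": "A" * 100, "b": "C" * 10 + "A" * 90})
        summary = summarize_groups(k2p_matrix(m), {"a": "A", "b": "B"})
        with pytest.warns(UserWarning):
            report = barcode_gap(summary)
        assert not report.gap_present
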