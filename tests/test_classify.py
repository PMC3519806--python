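"""Type calling, recombinant detection, verdicts and clone-screening math."""

import itertools

import numpy as np
import pytest

from allobarcode.seqio import PARENTAL_A, PARENTAL_B, RECOMBINANT
from allobarcode.triangle_classify import (
    LocusProfile,
    NUCLEAR_MULTICOPY,
    NUCLEAR_SINGLE_COPY,
    PLASTID,
    TypeCall,
    UNASSIGNED,
    call_species,
    call_type,
    clones_needed,
    detect_recombinant,
    detection_probability,
)

ROLES = {"trnLF": PLASTID, "ITS": NUCLEAR_MULTICOPY, "GI": NUCLEAR_SINGLE_COPY}


def make_profile(n_sites=30, length=None):
    """A profile with A fixed to 'A' and B fixed to 'G' at every other column."""
    length = length or 2 * n_sites
    positions = tuple(range(0, 2 * n_sites, 2))
    return LocusProfile("GI", positions, "A" * n_sites, "G" * n_sites)


def seq_from_states(profile, states, length=None, filler="C"):
    length = length or (max(profile.positions) + 1)
    seq = [filler] * length
    for pos, state in zip(profile.positions, states):
        seq[pos] = state
    return "".join(seq)


class TestCallType:
    def test_pure_parental(self):
        profile = make_profile()
        call = call_type(seq_from_states(profile, "A" * 30), profile)
        assert call.call == PARENTAL_A
        assert call.matches_a == 30 and call.matches_b == 0

    def test_all_sites_gapped_unassigned(self):
        profile = make_profile()
        call = call_type(seq_from_states(profile, "-" * 30), profile)
        assert call.call == UNASSIGNED and call.scored_sites == 0

    def test_single_homoplasy_tolerated(self):
        profile = make_profile()
        states = "A" + "G" * 29      # B-derived with one homoplastic A state
        call = call_type(seq_from_states(profile, states), profile)
        assert call.call == PARENTAL_B
        assert call.matches_a == 1 and call.matches_b == 29

    def test_third_state_casts_no_vote(self):
        profile = make_profile()
        states = "T" * 5 + "A" * 25  # non-parental states are silent
        call = call_type(seq_from_states(profile, states), profile)
        assert call.call == PARENTAL_A and call.scored_sites == 25

    def test_never_misassigns_pure_synthetic_sequences(self, small_dataset):
        from allobarcode.barcode_stats import classify_sites
        from allobarcode.triangle_classify import DiagnosticProfile

        matrix = small_dataset.matrices["GI"]
        labels = {r.sequence_id: {"parentA": "A", "parentB": "B"}.get(
            r.species_label) for r in matrix.records}
        labels = {k: v for k, v in labels.items() if v}
        profile = DiagnosticProfile.from_site_classifications(
            {"GI": classify_sites(matrix, labels)})
        for rec in matrix.records:
            if rec.species_label not in ("parentA", "parentB"):
                continue
            call = call_type(rec.residues, profile, "GI")
            expected = PARENTAL_A if rec.species_label == "parentA" \
                else PARENTAL_B
            assert call.call == expected


class TestDetectRecombinant:
    def test_clean_splice_detected(self):
        profile = make_profile()
        states = "A" * 15 + "G" * 15
        seq = seq_from_states(profile, states)
        hit = detect_recombinant(seq, profile)
        assert hit is not None
        breakpoint, orientation = hit
        assert orientation == "A->B"
        assert breakpoint == profile.positions[15]
        call = call_type(seq, profile)
        assert call.call == RECOMBINANT and call.breakpoint == breakpoint

    def test_pure_sequence_not_recombinant(self):
        profile = make_profile()
        assert detect_recombinant(
            seq_from_states(profile, "A" * 30), profile) is None

    def test_alternating_states_rejected(self):
        profile = make_profile()
        states = "AG" * 15          # no split satisfies segment purity
        assert detect_recombinant(
            seq_from_states(profile, states), profile) is None

    def test_short_segment_rejected(self):
        profile = make_profile()
        states = "G" * 2 + "A" * 28   # left segment below min_segment
        seq = seq_from_states(profile, states)
        assert detect_recombinant(seq, profile) is None

    def test_agrees_with_exhaustive_scan(self):
        profile = make_profile(n_sites=12)
        rng = np.random.default_rng(0)
        for _ in range(40):
            states = "".join(rng.choice(list("AG"), 12))
            seq = seq_from_states(profile, states)
            got = detect_recombinant(seq, profile)
            # exhaustive oracle over splits and orientations
            votes = list(states)
            n = len(votes)
            best = None
            single = max(votes.count("A"), votes.count("G"))
            for split in range(3, n - 2):
                for left, right in (("A", "G"), ("G", "A")):
                    lh = votes[:split].count(left)
                    rh = votes[split:].count(right)
                    if lh / split < 0.9 or rh / (n - split) < 0.9:
                        continue
                    if best is None or lh + rh > best[0]:
                        best = (lh + rh, split)
            expect_hit = best is not None and best[0] - single >= 2
            assert (got is not None) == expect_hit


class TestCallSpecies:
    def make_call(self, locus, ptype, i=0):
        return TypeCall(f"s:{locus}:{i}", locus, ptype,
                        breakpoint=-1 if ptype == RECOMBINANT else None)

    def test_both_gi_types_give_hybrid(self):
        result = call_species("s", {
            "GI": [self.make_call("GI", PARENTAL_A),
                   self.make_call("GI", PARENTAL_B, 1)]}, ROLES)
        assert result.verdict == "hybrid"
        assert result.rule.startswith("both-parental-types")

    def test_plastid_nuclear_discordance_gives_hybrid(self):
        result = call_species("s", {
            "trnLF": [self.make_call("trnLF", PARENTAL_B)],
            "ITS": [self.make_call("ITS", PARENTAL_A)]}, ROLES)
        assert result.verdict == "hybrid"
        assert result.rule == "plastid-nuclear-discordance"

    def test_full_concordance_gives_parent(self):
        result = call_species("s", {
            "trnLF": [self.make_call("trnLF", PARENTAL_A)],
            "ITS": [self.make_call("ITS", PARENTAL_A)],
            "GI": [self.make_call("GI", PARENTAL_A)]}, ROLES)
        assert result.verdict == "parentA"
        assert result.rule == "concordant-all-loci"

    def test_single_locus_parental_is_unconfirmed(self):
        result = call_species("s", {
            "ITS": [self.make_call("ITS", PARENTAL_B)]}, ROLES)
        assert result.verdict == "parentB"
        assert result.rule == "single-locus-unconfirmed"

    def test_recombinant_plus_parental_gives_hybrid(self):
        result = call_species("s", {
            "GI": [self.make_call("GI", RECOMBINANT),
                   self.make_call("GI", PARENTAL_B, 1)]}, ROLES)
        assert result.verdict == "hybrid"

    def test_no_informative_calls_raises(self):
        with pytest.raises(ValueError):
            call_species("s", {"ITS": [self.make_call("ITS", UNASSIGNED)]},
                         ROLES)

    def test_adding_a_locus_never_flips_hybrid_to_parental(self):
        # monotonicity: every hybrid-calling locus subset stays hybrid when
        # more loci are added
        options = {
            "trnLF": [[self.make_call("trnLF", PARENTAL_A)],
                      [self.make_call("trnLF", PARENTAL_B)]],
            "ITS": [[self.make_call("ITS", PARENTAL_A)],
                    [self.make_call("ITS", PARENTAL_A),
                     self.make_call("ITS", PARENTAL_B, 1)]],
            "GI": [[self.make_call("GI", PARENTAL_B)],
                   [self.make_call("GI", PARENTAL_A),
                    self.make_call("GI", PARENTAL_B, 1)]],
        }
        loci = list(options)
        for choice in itertools.product(*(range(2) for _ in loci)):
            calls = {locus: options[locus][c]
                     for locus, c in zip(loci, choice)}
            for subset_size in (1, 2):
                for subset in itertools.combinations(loci, subset_size):
                    sub = {l: calls[l] for l in subset}
                    if call_species("s", sub, ROLES).verdict != "hybrid":
                        continue
                    for bigger in itertools.combinations(loci,
                                                         subset_size + 1):
                        if not set(subset) <= set(bigger):
                            continue
                        big = {l: calls[l] for l in bigger}
                        assert call_species("s", big, ROLES).verdict == \
                            "hybrid"


class TestCloneMath:
    def test_closed_form_examples(self):
        assert detection_probability(5, 0.5) == pytest.approx(0.9375)
        assert detection_probability(1, 0.3) == 0.0
        assert detection_probability(4, 0.0) == 0.0

    @pytest.mark.parametrize("n", [1, 2, 3, 5, 8, 12])
    @pytest.mark.parametrize("q", [0.1, 0.3, 0.5])
    def test_matches_exhaustive_enumeration(self, n, q):
        # enumerate all 2^n clone outcomes and add up those showing both
        total = 0.0
        for outcome in itertools.product((0, 1), repeat=n):
            if 0 < sum(outcome) < n:
                k = sum(outcome)
                total += q ** k * (1 - q) ** (n - k)
        assert detection_probability(n, q) == pytest.approx(total, abs=1e-12)

    def test_clones_needed_examples(self):
        assert clones_needed(0.5, 0.95) == 6
        assert clones_needed(0.1, 0.95) == 29
        assert clones_needed(0.5, 1e-9) == 2

    def test_clones_needed_degenerate_q(self):
        with pytest.raises(ValueError):
            clones_needed(0.0, 0.95)
        with pytest.raises(ValueError):
            clones_needed(1.0, 0.95)

    def test_realised_detection_rate_within_binomial_bounds(self):
        """GI clone sampling in the generator hits the closed-form rate."""
        from scipy.stats import binom

        from allobarcode.synthdata import SynthParams, generate

        n_hyb = 200
        params = SynthParams(seed=17, n_parent_a=6, n_parent_b=6,
                             n_hybrids=n_hyb, single_copy_retain_both=1.0)
        ds = generate(params)
        gi = ds.copy_origins[ds.copy_origins.locus == "GI"]
        hybrids = gi[gi.sample_id.str.startswith("H")]
        detected = sum(
            1 for _, grp in hybrids.groupby("sample_id")
            if set(grp.origin) == {"A", "B"}
        )
        p = detection_probability(params.n_clones,
                                  params.minority_clone_fraction)
        lo, hi = binom.ppf([0.025, 0.975], n_hyb, p)
        assert lo <= detected <= hi
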