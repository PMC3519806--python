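"""Species verdicts for a diploid-diploid-allotetraploid triangle.

Per-sequence parental-type calls are made against a diagnostic-site profile
(columns fixed for different states in the two diploid parents).  A
sequence votes at every scoreable diagnostic site; near-unanimous votes give
a parental call, a two-segment vote pattern gives a recombinant call with a
breakpoint, anything else is unassigned.

Per-individual verdicts combine loci:

1. a nuclear locus showing both parental types (or a recombinant plus a
   parental type) is direct evidence of the allopolyploid;
2. disagreement between the plastid type and a unanimous nuclear type
   betrays a hybrid whose nuclear copies converged to the non-maternal
   parent;
3. full concordance across the plastid and all nuclear loci gives the
   corresponding parent;
4. a single concordant locus cannot exclude a fully converged hybrid and
   yields an unconfirmed parental call;
5. anything else is ambiguous.

A hybrid that inherited its plastid from one parent AND converged its
multicopy nuclear locus toward that same parent is indistinguishable from
that parent with the plastid+multicopy pair alone -- the decision engine
reproduces this failure mode rather than papering over it; cloning a
single-copy nuclear locus resolves it, and the clone-screening helpers
quantify how many clones are needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .barcode_stats import SiteClassification
from .seqio import (
    GAP_CODE,
    GroundTruth,
    PARENTAL_A,
    PARENTAL_B,
    RECOMBINANT,
    ROLE_HYBRID,
    ROLE_PARENT_A,
    ROLE_PARENT_B,
    TypeCallTable,
    encode_residues,
)

UNASSIGNED = "unassigned"

DEFAULT_PURITY = 0.9
DEFAULT_MIN_MARGIN = 2
DEFAULT_MIN_SEGMENT = 3

PLASTID = "plastid"
NUCLEAR_MULTICOPY = "nuclear-multicopy"
NUCLEAR_SINGLE_COPY = "nuclear-single-copy"

VERDICT_AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class LocusProfile:
    """Diagnostic columns of one locus with their fixed parental states."""

    locus_id: str
    positions: tuple[int, ...]
    states_a: str
    states_b: str

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError(f"no diagnostic sites for locus {self.locus_id!r}")


@dataclass
class DiagnosticProfile:
    """Per-locus diagnostic-site profiles used for type calling."""

    loci: dict[str, LocusProfile]

    @classmethod
    def from_site_classifications(
        cls, classifications: Mapping[str, SiteClassification]
    ) -> "DiagnosticProfile":
        loci = {}
        for locus_id, sites in classifications.items():
            if not sites.diagnostic_sites:
                continue
            positions, states_a, states_b = zip(*sites.diagnostic_sites)
            loci[locus_id] = LocusProfile(
                locus_id, tuple(positions), "".join(states_a), "".join(states_b)
            )
        return cls(loci)


@dataclass
class TypeCall:
    """Parental-type call for one sequence at one locus."""

    sequence_id: str
    locus_id: str
    call: str                       # A-type / B-type / recombinant / unassigned
    matches_a: int = 0
    matches_b: int = 0
    scored_sites: int = 0
    breakpoint: Optional[int] = None    # alignment column; half-open split
    orientation: Optional[str] = None   # "A->B" or "B->A"

    def __post_init__(self) -> None:
        if self.call == RECOMBINANT and self.breakpoint is None:
            raise ValueError("recombinant call requires a breakpoint")


def _site_votes(seq: str, profile: LocusProfile) -> list[tuple[int, Optional[str]]]:
    """(column, vote) per diagnostic site; vote None where gap/ambiguity."""
    enc = encode_residues(seq)
    enc_a = encode_residues(profile.states_a)
    enc_b = encode_residues(profile.states_b)
    votes: list[tuple[int, Optional[str]]] = []
    for k, col in enumerate(profile.positions):
        state = enc[col]
        if state >= GAP_CODE:
            votes.append((col, None))
        elif state == enc_a[k]:
            votes.append((col, "A"))
        elif state == enc_b[k]:
            votes.append((col, "B"))
        else:
            votes.append((col, None))   # third state: no vote
    return votes


def call_type(
    seq: str,
    profile: DiagnosticProfile | LocusProfile,
    locus_id: Optional[str] = None,
    purity: float = DEFAULT_PURITY,
    min_margin: int = DEFAULT_MIN_MARGIN,
    min_segment: int = DEFAULT_MIN_SEGMENT,
    sequence_id: str = "?",
) -> TypeCall:
    """Call a sequence A-type, B-type, recombinant or unassigned.

    A parental call requires the matching votes to reach ``purity`` of all
    parental votes; failing that, a breakpoint scan looks for a recombinant
    signature; with no scoreable diagnostic site the call is unassigned.
    """
    locus = profile.loci[locus_id] if isinstance(profile, DiagnosticProfile) \
        else profile
    votes = _site_votes(seq, locus)
    matches_a = sum(1 for _, v in votes if v == "A")
    matches_b = sum(1 for _, v in votes if v == "B")
    scored = matches_a + matches_b
    base = dict(
        sequence_id=sequence_id,
        locus_id=locus.locus_id,
        matches_a=matches_a,
        matches_b=matches_b,
        scored_sites=scored,
    )
    if scored == 0:
        return TypeCall(call=UNASSIGNED, **base)
    if matches_a / scored >= purity:
        return TypeCall(call=PARENTAL_A, **base)
    if matches_b / scored >= purity:
        return TypeCall(call=PARENTAL_B, **base)
    hit = detect_recombinant(seq, locus, purity=purity,
                             min_margin=min_margin, min_segment=min_segment)
    if hit is not None:
        breakpoint, orientation = hit
        return TypeCall(call=RECOMBINANT, breakpoint=breakpoint,
                        orientation=orientation, **base)
    return TypeCall(call=UNASSIGNED, **base)


def detect_recombinant(
    seq: str,
    profile: DiagnosticProfile | LocusProfile,
    locus_id: Optional[str] = None,
    purity: float = DEFAULT_PURITY,
    min_margin: int = DEFAULT_MIN_MARGIN,
    min_segment: int = DEFAULT_MIN_SEGMENT,
) -> Optional[tuple[int, str]]:
    """Scan for a single inter-parental breakpoint along the diagnostic sites.

    Every split between consecutive scoreable sites is tried in both
    orientations; a split qualifies when each segment has at least
    ``min_segment`` scoreable sites and vote purity >= ``purity`` for its
    own parent, with the two parents differing.  The best qualifying split
    is declared only if its total matched votes beat the best single-parent
    assignment by at least ``min_margin``.  Returns ``(breakpoint_column,
    orientation)`` where the breakpoint is the alignment column of the first
    right-segment site (half-open convention), or ``None``.
    """
    locus = profile.loci[locus_id] if isinstance(profile, DiagnosticProfile) \
        else profile
    votes = [(col, v) for col, v in _site_votes(seq, locus) if v is not None]
    if len(votes) < 2 * min_segment:
        return None
    n = len(votes)
    best_single = max(
        sum(1 for _, v in votes if v == "A"),
        sum(1 for _, v in votes if v == "B"),
    )
    best: Optional[tuple[int, int, str]] = None   # (total, breakpoint, orient)
    prefix_a = [0]
    for _, v in votes:
        prefix_a.append(prefix_a[-1] + (v == "A"))
    total_a = prefix_a[-1]
    for split in range(min_segment, n - min_segment + 1):
        left_a = prefix_a[split]
        left_b = split - left_a
        right_a = total_a - left_a
        right_b = (n - split) - right_a
        for orient, left_hits, right_hits in (
            ("A->B", left_a, right_b),
            ("B->A", left_b, right_a),
        ):
            if left_hits / split < purity:
                continue
            if right_hits / (n - split) < purity:
                continue
            total = left_hits + right_hits
            if best is None or total > best[0]:
                best = (total, votes[split][0], orient)
    if best is None or best[0] - best_single < min_margin:
        return None
    return best[1], best[2]


@dataclass
class IndividualCall:
    """Per-sample verdict with its audit trail."""

    sample_id: str
    locus_calls: dict[str, list[TypeCall]]
    verdict: str                    # parentA / parentB / hybrid / ambiguous
    rule: str

    def calls_at(self, locus_id: str) -> list[TypeCall]:
        return self.locus_calls.get(locus_id, [])


def _locus_types(calls: Sequence[TypeCall]) -> set[str]:
    return {c.call for c in calls if c.call != UNASSIGNED}


def call_species(
    sample_id: str,
    locus_calls: Mapping[str, Sequence[TypeCall]],
    locus_roles: Mapping[str, str],
) -> IndividualCall:
    """Combine per-locus type calls into a triangle species verdict.

    ``locus_roles`` maps each locus to ``plastid``, ``nuclear-multicopy`` or
    ``nuclear-single-copy``.  Loci with no assigned calls are ignored; with
    no informative locus at all a ``ValueError`` is raised.
    """
    informative = {
        locus: list(calls)
        for locus, calls in locus_calls.items()
        if _locus_types(calls)
    }
    if not informative:
        raise ValueError(f"sample {sample_id!r} has no informative calls")

    def verdict(v: str, rule: str) -> IndividualCall:
        return IndividualCall(sample_id, dict(informative), v, rule)

    # rule 1: intra-locus evidence of both parental genomes at a nuclear locus
    for locus, calls in informative.items():
        if locus_roles.get(locus, "").startswith("nuclear"):
            types = _locus_types(calls)
            if PARENTAL_A in types and PARENTAL_B in types:
                return verdict(ROLE_HYBRID, f"both-parental-types:{locus}")
            if RECOMBINANT in types and types & {PARENTAL_A, PARENTAL_B}:
                return verdict(ROLE_HYBRID, f"recombinant-plus-parental:{locus}")

    plastid_types: set[str] = set()
    nuclear_types: set[str] = set()
    per_locus_nuclear: list[set[str]] = []
    for locus, calls in informative.items():
        types = _locus_types(calls) - {RECOMBINANT}
        if locus_roles.get(locus) == PLASTID:
            plastid_types |= types
        else:
            nuclear_types |= types
            if types:
                per_locus_nuclear.append(types)

    # rule 2: plastid vs unanimous nuclear discordance
    if len(plastid_types) == 1 and len(nuclear_types) == 1 \
            and plastid_types != nuclear_types:
        return verdict(ROLE_HYBRID, "plastid-nuclear-discordance")
    # rule 2b: two nuclear loci unanimously fixed for different parents is
    # itself evidence of the combined genome
    if len(per_locus_nuclear) > 1 \
            and all(len(t) == 1 for t in per_locus_nuclear) \
            and len(set.union(*per_locus_nuclear)) > 1:
        return verdict(ROLE_HYBRID, "nuclear-nuclear-discordance")

    parental = plastid_types | nuclear_types
    if len(parental) == 1:
        parent = ROLE_PARENT_A if parental == {PARENTAL_A} else ROLE_PARENT_B
        if len(informative) == 1:
            # rule 4: one locus cannot exclude a fully converged hybrid
            return verdict(parent, "single-locus-unconfirmed")
        if plastid_types:
            return verdict(parent, "concordant-all-loci")   # rule 3
        return verdict(parent, "concordant-nuclear-only")
    return verdict(VERDICT_AMBIGUOUS, "conflicting-calls")  # rule 5


def calls_from_type_table(
    table: TypeCallTable, loci: Optional[Sequence[str]] = None
) -> dict[str, dict[str, list[TypeCall]]]:
    """Expand a survey type-call table into per-sample TypeCall lists.

    Each haplotype listed for a sample becomes one call carrying its tagged
    parental type (haplotypes listed under both parental columns arrive
    tagged recombinant; they get a sentinel breakpoint of -1 since the
    table records no coordinates).
    """
    loci = list(loci) if loci is not None else table.loci
    out: dict[str, dict[str, list[TypeCall]]] = {}
    for row in table.rows:
        per_locus: dict[str, list[TypeCall]] = {}
        for locus in loci:
            calls = []
            locus_calls = row.loci.get(locus)
            if locus_calls is None or locus_calls.missing:
                continue
            for hap_id, ptype in sorted(locus_calls.haplotypes.items()):
                calls.append(
                    TypeCall(
                        sequence_id=f"{row.sample_id}:{locus}:{hap_id}",
                        locus_id=locus,
                        call=ptype,
                        breakpoint=-1 if ptype == RECOMBINANT else None,
                    )
                )
            if calls:
                per_locus[locus] = calls
        out[row.sample_id] = per_locus
    return out


# ---------------------------------------------------------------------------
# clone-screening math
# ---------------------------------------------------------------------------

def detection_probability(n: int, q: float) -> float:
    """Probability that both parental copies appear among ``n`` clones when
    each clone independently draws the minority copy with probability ``q``:
    ``1 - q**n - (1-q)**n``."""
    if n < 1:
        raise ValueError("need at least one clone")
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must be a probability")
    return 1.0 - q ** n - (1.0 - q) ** n


def clones_needed(q: float, p_target: float, max_n: int = 10_000) -> int:
    """Smallest clone count whose detection probability reaches ``p_target``."""
    if not 0.0 < q < 1.0:
        raise ValueError("both copies must be drawable: need 0 < q < 1")
    if not 0.0 < p_target < 1.0:
        raise ValueError("p_target must be in (0, 1)")
    for n in range(2, max_n + 1):
        if detection_probability(n, q) >= p_target:
            return n
    raise ValueError(f"target {p_target} unattainable within {max_n} clones")


# ---------------------------------------------------------------------------
# identification-success scoring
# ---------------------------------------------------------------------------

@dataclass
class SuccessReport:
    """Per-species identification success for a given locus combination."""

    locus_set: tuple[str, ...]
    per_species: dict[str, tuple[Optional[float], int, int]]
    # species -> (percentage or None, n_correct, n_scored)
    denominator_policy: str = (
        "samples with at least one informative call at every requested locus"
    )

    def percentage(self, species: str) -> Optional[float]:
        return self.per_species[species][0]


def identification_success(
    sample_calls: Mapping[str, Mapping[str, Sequence[TypeCall]]],
    truth: GroundTruth,
    locus_set: Sequence[str],
    locus_roles: Mapping[str, str],
    restrict_to: Optional[set[str]] = None,
) -> SuccessReport:
    """Score verdicts from a locus combination against ground truth.

    A sample enters a species' denominator when the truth labels it as that
    species, it carries an informative call at *every* locus in
    ``locus_set`` (missing loci exclude the sample, as documented in the
    report), and, if ``restrict_to`` is given, its id is in that set.
    Success means the recomputed verdict equals the true species.
    """
    locus_set = tuple(locus_set)
    tally: dict[str, list[int]] = {}
    for sample_id, per_locus in sample_calls.items():
        entry = truth.get(sample_id)
        if entry is None:
            continue
        if restrict_to is not None and sample_id not in restrict_to:
            continue
        used = {
            locus: per_locus[locus]
            for locus in locus_set
            if locus in per_locus and _locus_types(per_locus[locus])
        }
        if len(used) < len(locus_set):
            continue
        result = call_species(sample_id, used, locus_roles)
        counts = tally.setdefault(entry.species_label, [0, 0])
        counts[1] += 1
        if result.verdict == entry.species_label:
            counts[0] += 1
    per_species = {}
    for species, (correct, scored) in sorted(tally.items()):
        pct = 100.0 * correct / scored if scored else None
        per_species[species] = (pct, correct, scored)
    return SuccessReport(locus_set, per_species)
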