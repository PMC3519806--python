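"""Kimura two-parameter distances, group summaries and barcode-gap detection.

The distance layer distinguishes transitions (A<->G, C<->T) from
transversions and applies the K2P correction

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

where P and Q are the transition and transversion proportions over the
columns compared for a pair.  Columns carrying a gap or an IUPAC ambiguity
code in either sequence are excluded pairwise by default (MEGA-style
pairwise deletion); complete-set deletion, which drops any column that is
not unambiguous across the whole matrix, is available by flag.  Pairs whose
substitution load saturates the correction (a non-positive log argument)
carry no finite distance and are flagged instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .seqio import AlignedLocusMatrix, GAP_CODE, encode_residues

DeletionPolicy = Literal["pairwise", "complete-set"]

INTRA_PREFIX = "intra"
INTER_PREFIX = "inter"


class EmptyOverlapError(ValueError):
    """A sequence pair shares no unambiguous, ungapped columns."""


@dataclass(frozen=True)
class PairwiseSiteCounts:
    """Transition/transversion counts over the compared columns of one pair."""

    compared_sites: int
    transitions: int
    transversions: int

    def __post_init__(self) -> None:
        if self.transitions + self.transversions > self.compared_sites:
            raise ValueError("more differences than compared sites")

    @property
    def P(self) -> float:
        return self.transitions / self.compared_sites

    @property
    def Q(self) -> float:
        return self.transversions / self.compared_sites


def count_site_differences(
    seq1: str,
    seq2: str,
    deletion_policy: DeletionPolicy = "pairwise",
    column_mask: Optional[np.ndarray] = None,
) -> PairwiseSiteCounts:
    """Count compared sites, transitions and transversions for one pair.

    ``column_mask`` restricts the comparison to pre-selected columns; it is
    how :func:`k2p_matrix` implements complete-set deletion.  For a single
    pair the two policies coincide, since only the pair itself is available.
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences differ in length")
    a = encode_residues(seq1)
    b = encode_residues(seq2)
    comparable = (a < GAP_CODE) & (b < GAP_CODE)
    if column_mask is not None:
        comparable &= column_mask
    compared = int(comparable.sum())
    if compared == 0:
        raise EmptyOverlapError("no comparable sites between the two sequences")
    diff = comparable & (a != b)
    transitions = int((diff & ((a & 1) == (b & 1))).sum())
    transversions = int(diff.sum()) - transitions
    return PairwiseSiteCounts(compared, transitions, transversions)


def k2p(counts: PairwiseSiteCounts) -> float:
    """K2P distance for one pair; ``nan`` when the correction saturates."""
    P, Q = counts.P, counts.Q
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1) - 0.25 * math.log(w2) + 0.0   # avoid -0.0


def p_distance(counts: PairwiseSiteCounts) -> float:
    return (counts.transitions + counts.transversions) / counts.compared_sites


@dataclass
class K2PDistanceMatrix:
    """Symmetric pairwise K2P distances with per-pair saturation flags."""

    sequence_ids: list[str]
    values: np.ndarray          # (n, n) float, nan where saturated
    saturated: np.ndarray       # (n, n) bool

    def __post_init__(self) -> None:
        n = len(self.sequence_ids)
        assert self.values.shape == (n, n) and self.saturated.shape == (n, n)

    def __len__(self) -> int:
        return len(self.sequence_ids)

    def index(self, sequence_id: str) -> int:
        return self.sequence_ids.index(sequence_id)

    def get(self, id1: str, id2: str) -> float:
        return float(self.values[self.index(id1), self.index(id2)])

    def any_saturated(self) -> bool:
        return bool(self.saturated.any())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sequence_ids, columns=self.sequence_ids
        )

    def subset(self, sequence_ids: Sequence[str]) -> "K2PDistanceMatrix":
        idx = np.array([self.index(sid) for sid in sequence_ids])
        return K2PDistanceMatrix(
            list(sequence_ids),
            self.values[np.ix_(idx, idx)],
            self.saturated[np.ix_(idx, idx)],
        )


def k2p_matrix(
    matrix: AlignedLocusMatrix, deletion_policy: DeletionPolicy = "pairwise"
) -> K2PDistanceMatrix:
    """All-pairs K2P distances for an aligned matrix.

    Vectorised row-against-block comparison; equivalent to looping
    :func:`count_site_differences` and :func:`k2p` over all unordered pairs.
    """
    n = len(matrix)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    enc = matrix.encoded()
    valid = enc < GAP_CODE
    if deletion_policy == "complete-set":
        keep = valid.all(axis=0)
        enc = enc[:, keep]
        valid = valid[:, keep]
    elif deletion_policy != "pairwise":
        raise ValueError(f"unknown deletion policy {deletion_policy!r}")

    values = np.zeros((n, n))
    saturated = np.zeros((n, n), dtype=bool)
    parity = enc & 1
    for i in range(n - 1):
        comp = valid[i] & valid[i + 1:]
        compared = comp.sum(axis=1).astype(float)
        diff = comp & (enc[i + 1:] != enc[i])
        ts = (diff & (parity[i + 1:] == parity[i])).sum(axis=1)
        tv = diff.sum(axis=1) - ts
        with np.errstate(divide="ignore", invalid="ignore"):
            P = ts / compared
            Q = tv / compared
            w1 = 1.0 - 2.0 * P - Q
            w2 = 1.0 - 2.0 * Q
            d = np.where(
                (w1 > 0) & (w2 > 0),
                -0.5 * np.log(np.where(w1 > 0, w1, 1.0))
                - 0.25 * np.log(np.where(w2 > 0, w2, 1.0)),
                np.nan,
            )
        d = np.where(compared == 0, np.nan, d) + 0.0    # avoid -0.0
        values[i, i + 1:] = d
        values[i + 1:, i] = d
        bad = np.isnan(d)
        saturated[i, i + 1:] = bad
        saturated[i + 1:, i] = bad
    return K2PDistanceMatrix(matrix.ids(), values, saturated)


@dataclass(frozen=True)
class GroupStats:
    """Summary of pairwise distances within or between groups."""

    label: str
    n_pairs: int
    n_saturated: int
    mean: Optional[float]
    minimum: Optional[float]
    maximum: Optional[float]
    sd: Optional[float]

    @property
    def defined(self) -> bool:
        return self.mean is not None


@dataclass
class GroupDistanceSummary:
    """Intra- and inter-group distance statistics for one locus."""

    intra: dict[str, GroupStats]
    inter: dict[tuple[str, str], GroupStats]
    sd_mode: str = "sample"

    def inter_between(self, g1: str, g2: str) -> GroupStats:
        key = tuple(sorted((g1, g2)))
        return self.inter[key]    # type: ignore[index]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for stats in list(self.intra.values()) + list(self.inter.values()):
            rows.append(
                {
                    "group": stats.label,
                    "n_pairs": stats.n_pairs,
                    "n_saturated": stats.n_saturated,
                    "mean": stats.mean,
                    "min": stats.minimum,
                    "max": stats.maximum,
                    "sd": stats.sd,
                }
            )
        return pd.DataFrame(rows)


def _stats_from(label: str, d: np.ndarray, sd_mode: str) -> GroupStats:
    finite = d[~np.isnan(d)]
    n_sat = int(np.isnan(d).sum())
    if finite.size == 0:
        return GroupStats(label, int(d.size), n_sat, None, None, None, None)
    ddof = 1 if sd_mode == "sample" else 0
    sd = float(np.std(finite, ddof=ddof)) if finite.size > ddof else None
    return GroupStats(
        label,
        int(d.size),
        n_sat,
        float(np.mean(finite)),
        float(np.min(finite)),
        float(np.max(finite)),
        sd,
    )


def summarize_groups(
    dm: K2PDistanceMatrix,
    labels: Mapping[str, str],
    sd_mode: str = "sample",
) -> GroupDistanceSummary:
    """Intra/inter statistics over unordered pairs, per group and group pair.

    Sequences absent from ``labels`` are ignored.  Saturated pairs are
    excluded from the statistics and counted in ``n_saturated``.  Groups
    with fewer than two members get an undefined (not zero) intra entry.
    """
    groups: dict[str, np.ndarray] = {}
    for group in sorted(set(labels.values())):
        idx = [i for i, sid in enumerate(dm.sequence_ids)
               if labels.get(sid) == group]
        groups[group] = np.array(idx, dtype=int)

    intra = {}
    for group, idx in groups.items():
        if len(idx) < 2:
            intra[group] = GroupStats(f"{INTRA_PREFIX}-{group}", 0, 0,
                                      None, None, None, None)
            continue
        iu = np.triu_indices(len(idx), k=1)
        d = dm.values[np.ix_(idx, idx)][iu]
        intra[group] = _stats_from(f"{INTRA_PREFIX}-{group}", d, sd_mode)

    inter = {}
    names = sorted(groups)
    for i, g1 in enumerate(names):
        for g2 in names[i + 1:]:
            d = dm.values[np.ix_(groups[g1], groups[g2])].ravel()
            label = f"{INTER_PREFIX}-{g1}-{g2}"
            inter[(g1, g2)] = _stats_from(label, d, sd_mode)
    return GroupDistanceSummary(intra, inter, sd_mode)


@dataclass(frozen=True)
class IndelRun:
    """A run of gap columns fixed in one group, as a half-open interval."""

    start: int
    stop: int
    gapped_group: str


@dataclass
class SiteClassification:
    """Variable and diagnostic columns of an alignment.

    Diagnostic sites are fixed for one unambiguous state in every group-A
    sequence and a different one in every group-B sequence; diagnostic
    indels are maximal runs of columns gapped in exactly one group.
    Percentages are relative to the alignment length.
    """

    length: int
    variable_sites: list[int]
    diagnostic_sites: list[tuple[int, str, str]]    # (column, state_A, state_B)
    diagnostic_indels: list[IndelRun]

    @property
    def n_variable(self) -> int:
        return len(self.variable_sites)

    @property
    def n_diagnostic(self) -> int:
        return len(self.diagnostic_sites)

    @property
    def pct_variable(self) -> float:
        return 100.0 * self.n_variable / self.length

    @property
    def pct_diagnostic(self) -> float:
        return 100.0 * self.n_diagnostic / self.length


_DECODE = {0: "A", 1: "C", 2: "G", 3: "T", 4: "-"}


def classify_sites(
    matrix: AlignedLocusMatrix,
    group_labels: Mapping[str, str],
    group_a: str = "A",
    group_b: str = "B",
) -> SiteClassification:
    """Classify alignment columns as variable and/or diagnostic.

    Variability is assessed over every sequence in the matrix; diagnosis is
    restricted to the two parental groups named by ``group_a``/``group_b``
    (hybrid sequences, which carry both states, should not be labelled).
    """
    enc = matrix.encoded()
    ids = matrix.ids()
    idx_a = [i for i, sid in enumerate(ids) if group_labels.get(sid) == group_a]
    idx_b = [i for i, sid in enumerate(ids) if group_labels.get(sid) == group_b]
    if not idx_a or not idx_b:
        raise ValueError("both parental groups must be non-empty")

    unambig = enc < GAP_CODE
    # variable: >=2 distinct unambiguous states anywhere in the matrix
    variable = []
    for col in range(matrix.length):
        states = set(enc[unambig[:, col], col].tolist())
        if len(states) >= 2:
            variable.append(col)

    sub_a = enc[idx_a]
    sub_b = enc[idx_b]
    fixed_a = (sub_a == sub_a[0]).all(axis=0)
    fixed_b = (sub_b == sub_b[0]).all(axis=0)
    state_a = sub_a[0]
    state_b = sub_b[0]
    diag_mask = (
        fixed_a & fixed_b & (state_a != state_b)
        & (state_a < GAP_CODE) & (state_b < GAP_CODE)
    )
    diagnostic = [
        (int(c), _DECODE[int(state_a[c])], _DECODE[int(state_b[c])])
        for c in np.nonzero(diag_mask)[0]
    ]

    # indel runs: columns gapped in every member of exactly one group and
    # unambiguous non-gap in every member of the other
    gap_a = fixed_a & (state_a == GAP_CODE) & fixed_b & (state_b < GAP_CODE)
    gap_b = fixed_b & (state_b == GAP_CODE) & fixed_a & (state_a < GAP_CODE)
    indels: list[IndelRun] = []
    for mask, group in ((gap_a, group_a), (gap_b, group_b)):
        cols = np.nonzero(mask)[0]
        if cols.size == 0:
            continue
        start = prev = int(cols[0])
        for col in cols[1:]:
            if int(col) != prev + 1:
                indels.append(IndelRun(start, prev + 1, group))
                start = int(col)
            prev = int(col)
        indels.append(IndelRun(start, prev + 1, group))
    indels.sort(key=lambda run: run.start)
    return SiteClassification(matrix.length, variable, diagnostic, indels)


@dataclass
class BarcodeGapReport:
    """Barcode-gap verdict: smallest inter-group vs largest intra-group d."""

    max_intra: dict[str, Optional[float]]
    min_inter: Optional[float]
    gap_present: bool
    margin: Optional[float]


def barcode_gap(
    summary: GroupDistanceSummary,
    group_a: str = "A",
    group_b: str = "B",
) -> BarcodeGapReport:
    """Test for a barcode gap between two groups of a distance summary."""
    max_intra = {}
    for group in (group_a, group_b):
        stats = summary.intra.get(group)
        if stats is None or not stats.defined:
            warnings.warn(f"intra-group distances undefined for {group!r}; "
                          "gap evaluated against available groups")
            max_intra[group] = None
        else:
            max_intra[group] = stats.maximum
    inter = summary.inter_between(group_a, group_b)
    if not inter.defined:
        return BarcodeGapReport(max_intra, None, False, None)
    observed = [v for v in max_intra.values() if v is not None]
    if not observed:
        return BarcodeGapReport(max_intra, inter.minimum, False, None)
    margin = inter.minimum - max(observed)
    return BarcodeGapReport(max_intra, inter.minimum, margin > 0, margin)
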