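"""Truth-labelled synthetic datasets for the species-triangle analysis.

The generator emulates the statistical structure the barcode analysis
assumes: two deeply diverged, internally near-homogeneous parental
haplogroups per locus, and allotetraploid hybrids that carry one copy from
each parent, with

* biased maternal plastid inheritance (the plastid locus follows the seed
  parent, drawn from parent B with probability ``maternal_from_b``);
* all-or-nothing concerted evolution at the multicopy nuclear locus (the
  two copies either converge to one parent's ribotype or both survive);
* near-universal homeolog retention at the single-copy nuclear locus,
  observed only through a finite clone sample; and
* rare single-breakpoint inter-parental recombinant copies.

Parental divergence is planted as a fixed set of diagnostic differences
whose count is obtained by inverting the K2P expectation at the configured
transition:transversion ratio and subtracting the intraspecific
contribution, so the expected inter-parental distance matches the target
``d_ab``.  Within-group diversity is haplotype-structured, as in real
selfing populations where many individuals share a common variant: each
pool carries a few haplotype classes with geometrically skewed frequencies,
each class separated from the pool backbone by its own small set of
mutations, calibrated so the expected pairwise intra-pool difference equals
``theta``.  Substitution is per-column independent with transition bias and
no rate heterogeneity; there is no indel process by default, but planted
fixed gap runs are available for exercising diagnostic-indel reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .seqio import (
    AlignedLocusMatrix,
    GroundTruth,
    ROLE_HYBRID,
    ROLE_PARENT_A,
    ROLE_PARENT_B,
    SeqEntry,
    TruthEntry,
    write_aligned_fasta,
)
from .triangle_classify import NUCLEAR_MULTICOPY, NUCLEAR_SINGLE_COPY, PLASTID

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

ITS_FATE_CONVERT_A = "convert-to-A"
ITS_FATE_CONVERT_B = "convert-to-B"
ITS_FATE_RETAIN_BOTH = "retain-both"


@dataclass(frozen=True)
class LocusSpec:
    """Length, target inter-parental divergence and role of one locus."""

    locus_id: str
    length: int
    d_ab: float
    role: str
    kappa: float = 2.0          # transition:transversion count ratio
    indel_runs: tuple[tuple[int, int], ...] = ()
    # optional planted indel events: (start column, run length) fixed as
    # gaps in parent B


def default_loci() -> tuple[LocusSpec, ...]:
    """The three surveyed loci: plastid spacer, multicopy ribosomal spacer
    and a single-copy nuclear gene fragment."""
    return (
        LocusSpec("trnLF", 782, 0.024, PLASTID),
        LocusSpec("ITS", 612, 0.055, NUCLEAR_MULTICOPY),
        LocusSpec("GI", 665, 0.038, NUCLEAR_SINGLE_COPY),
    )


@dataclass
class SynthParams:
    """Generator parameters; defaults reproduce the surveyed study design."""

    loci: tuple[LocusSpec, ...] = field(default_factory=default_loci)
    n_parent_a: int = 56
    n_parent_b: int = 43
    n_hybrids: int = 111
    theta: float = 0.005                    # expected pairwise intra diversity
    maternal_from_b: float = 0.962          # plastid drawn from parent B
    its_fates: tuple[float, float, float] = (0.83, 0.064, 0.106)
    # (convert-to-A, convert-to-B, retain-both); must sum to 1
    single_copy_retain_both: float = 0.967
    minority_clone_fraction: float = 0.5    # q: clone draws the minority copy
    n_clones: int = 5
    recombination_prob: float = 0.02        # per hybrid per nuclear locus
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.maternal_from_b, self.single_copy_retain_both,
                  self.minority_clone_fraction, self.recombination_prob,
                  *self.its_fates):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.its_fates) - 1.0) > 1e-9:
            raise ValueError("ITS fate probabilities must sum to 1")


def divergence_fraction(d_ab: float, kappa: float) -> float:
    """Invert the K2P expectation: the per-column difference fraction x such
    that differences split pt = kappa/(kappa+1) transitions give distance
    ``d_ab``."""
    pt = kappa / (kappa + 1.0)

    def gap(x: float) -> float:
        P, Q = pt * x, (1.0 - pt) * x
        return (-0.5 * math.log(1.0 - 2.0 * P - Q)
                - 0.25 * math.log(1.0 - 2.0 * Q)) - d_ab

    upper = 0.999 / (2.0 * pt + (1.0 - pt))    # keep log arguments positive
    return float(brentq(gap, 1e-12, upper * 0.999999))


@dataclass
class ParentalPools:
    """Per-locus parental sequences plus the planted diagnostic truth."""

    locus: LocusSpec
    backbone_a: str
    backbone_b: str
    pool_a: list[str]
    pool_b: list[str]
    diagnostic_map: dict[int, tuple[str, str]]   # column -> (state A, state B)


#: haplotype classes per parental pool; frequencies fall off geometrically
POOL_HAPLOTYPE_CLASSES = 5


def _substitute(base: str, pt: float, rng: np.random.Generator) -> str:
    """One substitution with transition probability ``pt``."""
    if rng.random() < pt:
        return _TRANSITION[base]
    partners = _TRANSVERSIONS[base]
    return partners[rng.integers(2)]


def _randomized_round(value: float, rng: np.random.Generator) -> int:
    """Integer with expectation exactly ``value``."""
    floor = math.floor(value)
    return floor + (1 if rng.random() < value - floor else 0)


def make_parental_pools(
    params: SynthParams, locus: LocusSpec, rng: np.random.Generator
) -> ParentalPools:
    """Simulate the two parental pools for one locus.

    A random ancestor acquires a fixed set of planted differences on the
    parent-B backbone (transition-biased; the count inverts the K2P
    expectation for ``d_ab`` minus the intraspecific contribution).  Each
    pool then holds ``POOL_HAPLOTYPE_CLASSES`` haplotype classes with
    geometrically skewed frequencies; a class differs from its backbone by
    a small calibrated set of mutations so the expected pairwise intra-pool
    difference is ``theta``.  Randomized rounding keeps all expectations
    exact.
    """
    length = locus.length
    pt = locus.kappa / (locus.kappa + 1.0)

    # haplotype-class frequencies and per-class mutation load
    n_classes = POOL_HAPLOTYPE_CLASSES
    weights = 0.5 ** np.arange(n_classes)
    freqs = weights / weights.sum()
    p_distinct = 1.0 - float((freqs ** 2).sum())
    lam = params.theta * length / (2.0 * p_distinct)

    # planted inter-parental differences: a class mutation landing on a
    # planted column adds no new difference and recreates the other
    # parent's state with probability p_eq, so the expected cross-pool
    # difference is k + 2*lam - 2*lam*(k/L)*(1 + p_eq) columns; invert
    # that against the K2P inversion of d_ab
    x = divergence_fraction(locus.d_ab, locus.kappa)
    p_eq = pt ** 2 + (1.0 - pt) ** 2 / 2.0
    k_target = (x * length - 2.0 * lam) / (
        1.0 - (2.0 * lam / length) * (1.0 + p_eq)
    )
    k = _randomized_round(k_target, rng)
    if k < 1 or k >= length:
        raise ValueError(
            f"divergence {locus.d_ab} infeasible for length {length} "
            f"at theta {params.theta}"
        )

    ancestor = rng.choice(list(_BASES), size=length)
    backbone_a = ancestor.copy()
    backbone_b = ancestor.copy()
    k_ts = int(round(pt * k))
    forbidden = set()
    for start, run in locus.indel_runs:
        forbidden.update(range(start, start + run))
    candidates = np.array([c for c in range(length) if c not in forbidden])
    sites = rng.choice(candidates, size=k, replace=False)
    for rank, col in enumerate(sites):
        base = str(backbone_a[col])
        if rank < k_ts:
            backbone_b[col] = _TRANSITION[base]
        else:
            backbone_b[col] = _substitute(base, 0.0, rng)
    for start, run in locus.indel_runs:
        backbone_b[start:start + run] = "-"

    diagnostic_map = {
        int(col): (str(backbone_a[col]), str(backbone_b[col]))
        for col in sorted(sites)
    }

    def haplotype_classes(backbone: np.ndarray) -> list[str]:
        variants = []
        for _ in range(n_classes):
            seq = list(backbone)
            n_mut = _randomized_round(lam, rng)
            for col in rng.choice(length, size=n_mut, replace=False):
                if seq[col] != "-":
                    seq[col] = _substitute(seq[col], pt, rng)
            variants.append("".join(seq))
        return variants

    def individuals(backbone: np.ndarray, n: int) -> list[str]:
        variants = haplotype_classes(backbone)
        assignment = rng.choice(n_classes, size=n, p=freqs)
        return [variants[i] for i in assignment]

    return ParentalPools(
        locus,
        "".join(backbone_a),
        "".join(backbone_b),
        individuals(backbone_a, params.n_parent_a),
        individuals(backbone_b, params.n_parent_b),
        diagnostic_map,
    )


@dataclass
class HybridRecord:
    """Truth for one simulated hybrid."""

    sample_id: str
    maternal_parent: str                       # parentA / parentB
    its_fate: str
    gi_retained_both: bool
    recombinant_loci: dict[str, tuple[int, str]]   # locus -> (breakpoint, orient)


@dataclass
class SynthDataset:
    """Matrices, per-sequence truth and generator parameters."""

    params: SynthParams
    matrices: dict[str, AlignedLocusMatrix]
    pools: dict[str, ParentalPools]
    hybrids: list[HybridRecord]
    copy_origins: pd.DataFrame     # sequence_id, sample_id, locus, origin

    def ground_truth(self) -> GroundTruth:
        entries = {}
        for matrix in self.matrices.values():
            for rec in matrix.records:
                if rec.sample_id in entries:
                    continue
                role = rec.species_label
                n2 = {ROLE_PARENT_A: 10, ROLE_PARENT_B: 20,
                      ROLE_HYBRID: 30}.get(role)
                entries[rec.sample_id] = TruthEntry(role, n2, "count")
        return GroundTruth(entries)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for locus_id, matrix in self.matrices.items():
            write_aligned_fasta(matrix, out / f"{locus_id}.fasta")
        self.copy_origins.to_csv(out / "copy_origins.tsv", sep="\t",
                                 index=False)
        truth = pd.DataFrame(
            [
                {
                    "sample_id": h.sample_id,
                    "maternal_parent": h.maternal_parent,
                    "its_fate": h.its_fate,
                    "gi_retained_both": h.gi_retained_both,
                    "recombinant_loci": ";".join(
                        f"{locus}:{bp}:{orient}"
                        for locus, (bp, orient)
                        in sorted(h.recombinant_loci.items())
                    ),
                }
                for h in self.hybrids
            ]
        )
        truth.to_csv(out / "hybrid_truth.tsv", sep="\t", index=False)
        diag = pd.DataFrame(
            [
                {"locus": locus_id, "column": col, "state_A": a, "state_B": b}
                for locus_id, pool in self.pools.items()
                for col, (a, b) in pool.diagnostic_map.items()
            ]
        )
        diag.to_csv(out / "planted_diagnostics.tsv", sep="\t", index=False)


def _splice(seq_a: str, seq_b: str, breakpoint: int, orient: str) -> str:
    if orient == "A->B":
        return seq_a[:breakpoint] + seq_b[breakpoint:]
    return seq_b[:breakpoint] + seq_a[breakpoint:]


def make_hybrids(
    params: SynthParams,
    pools: dict[str, ParentalPools],
    rng: np.random.Generator,
) -> tuple[dict[str, list[SeqEntry]], list[HybridRecord], list[dict]]:
    """Simulate hybrid individuals from the parental pools.

    Each hybrid draws one parent-A and one parent-B gamete per locus (a
    random pool member).  The plastid locus emits the maternal gamete as a
    direct sequence; the multicopy nuclear locus follows its sampled fate;
    the single-copy locus keeps both homeologs with the configured
    probability and is observed through ``n_clones`` clones, each drawing
    the designated minority copy with probability q.  With probability
    ``recombination_prob`` (per nuclear locus) one copy is replaced by a
    single-breakpoint inter-parental splice.
    """
    width = len(str(max(params.n_hybrids, 1)))
    entries: dict[str, list[SeqEntry]] = {locus_id: [] for locus_id in pools}
    records: list[HybridRecord] = []
    origins: list[dict] = []
    fate_names = (ITS_FATE_CONVERT_A, ITS_FATE_CONVERT_B, ITS_FATE_RETAIN_BOTH)
    q = params.minority_clone_fraction

    for h in range(params.n_hybrids):
        sample = f"H{h + 1:0{width}d}"
        maternal = ROLE_PARENT_B if rng.random() < params.maternal_from_b \
            else ROLE_PARENT_A
        its_fate = fate_names[
            rng.choice(3, p=np.asarray(params.its_fates))
        ]
        gi_both = rng.random() < params.single_copy_retain_both
        rec_loci: dict[str, tuple[int, str]] = {}

        for locus_id, pool in pools.items():
            locus = pool.locus
            copy_a = pool.pool_a[rng.integers(len(pool.pool_a))]
            copy_b = pool.pool_b[rng.integers(len(pool.pool_b))]

            if locus.role == PLASTID:
                chosen = copy_b if maternal == ROLE_PARENT_B else copy_a
                origin = "B" if maternal == ROLE_PARENT_B else "A"
                sid = f"{sample}|{ROLE_HYBRID}"
                entries[locus_id].append(
                    SeqEntry(sid, sample, chosen, None, ROLE_HYBRID)
                )
                origins.append({"sequence_id": sid, "sample_id": sample,
                                "locus": locus_id, "origin": origin})
                continue

            # nuclear: possibly recombine one copy
            if rng.random() < params.recombination_prob:
                breakpoint = int(rng.integers(1, locus.length))
                orient = "A->B" if rng.random() < 0.5 else "B->A"
                spliced = _splice(copy_a, copy_b, breakpoint, orient)
                if orient == "A->B":
                    copy_a = spliced     # replaces the A-side copy
                else:
                    copy_b = spliced
                rec_loci[locus_id] = (breakpoint, orient)

            def emit(residues: str, origin: str, clone: Optional[str]) -> None:
                sid = f"{sample}|{ROLE_HYBRID}" + (f"|{clone}" if clone else "")
                entries[locus_id].append(
                    SeqEntry(sid, sample, residues, clone, ROLE_HYBRID)
                )
                origins.append({"sequence_id": sid, "sample_id": sample,
                                "locus": locus_id, "origin": origin})

            if locus.role == NUCLEAR_MULTICOPY:
                if its_fate == ITS_FATE_CONVERT_A:
                    emit(copy_a, "A", None)
                elif its_fate == ITS_FATE_CONVERT_B:
                    emit(copy_b, "B", None)
                else:
                    for c in range(params.n_clones):
                        minority_is_b = True   # designate B the minority copy
                        take_minority = rng.random() < q
                        pick_b = take_minority == minority_is_b
                        emit(copy_b if pick_b else copy_a,
                             "B" if pick_b else "A", f"c{c + 1}")
            else:   # single-copy nuclear
                if gi_both:
                    minority_is_b = rng.random() < 0.5
                    for c in range(params.n_clones):
                        take_minority = rng.random() < q
                        pick_b = take_minority == minority_is_b
                        emit(copy_b if pick_b else copy_a,
                             "B" if pick_b else "A", f"c{c + 1}")
                else:
                    keep_b = rng.random() < 0.5
                    for c in range(params.n_clones):
                        emit(copy_b if keep_b else copy_a,
                             "B" if keep_b else "A", f"c{c + 1}")

        records.append(HybridRecord(sample, maternal, its_fate,
                                    gi_both, rec_loci))
    return entries, records, origins


def generate(params: SynthParams, out_dir=None) -> SynthDataset:
    """Generate a full dataset; bit-identical for a given seed."""
    root = np.random.SeedSequence(params.seed)
    pool_seeds, hybrid_seed = root.spawn(2)
    pools: dict[str, ParentalPools] = {}
    for locus, child in zip(params.loci, pool_seeds.spawn(len(params.loci))):
        pools[locus.locus_id] = make_parental_pools(
            params, locus, np.random.default_rng(child)
        )

    width_a = len(str(max(params.n_parent_a, 1)))
    width_b = len(str(max(params.n_parent_b, 1)))
    matrices: dict[str, AlignedLocusMatrix] = {}
    hybrid_entries, hybrid_records, origins = make_hybrids(
        params, pools, np.random.default_rng(hybrid_seed)
    )
    origin_rows = list(origins)
    for locus_id, pool in pools.items():
        records = []
        for i, residues in enumerate(pool.pool_a):
            sample = f"A{i + 1:0{width_a}d}"
            records.append(SeqEntry(f"{sample}|{ROLE_PARENT_A}", sample,
                                    residues, None, ROLE_PARENT_A))
            origin_rows.append({"sequence_id": f"{sample}|{ROLE_PARENT_A}",
                                "sample_id": sample, "locus": locus_id,
                                "origin": "A"})
        for i, residues in enumerate(pool.pool_b):
            sample = f"B{i + 1:0{width_b}d}"
            records.append(SeqEntry(f"{sample}|{ROLE_PARENT_B}", sample,
                                    residues, None, ROLE_PARENT_B))
            origin_rows.append({"sequence_id": f"{sample}|{ROLE_PARENT_B}",
                                "sample_id": sample, "locus": locus_id,
                                "origin": "B"})
        records.extend(hybrid_entries[locus_id])
        matrices[locus_id] = AlignedLocusMatrix(locus_id, records)

    dataset = SynthDataset(
        params, matrices, pools, hybrid_records,
        pd.DataFrame(origin_rows,
                     columns=["sequence_id", "sample_id", "locus", "origin"]),
    )
    if out_dir is not None:
        dataset.write(out_dir)
    return dataset
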