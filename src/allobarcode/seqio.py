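"""Aligned-matrix and tabular I/O.

Sequence data enter the pipeline as pre-aligned multi-FASTA files, one per
locus.  Headers follow the convention ``sampleID|species|cloneID`` where the
species and clone fields are optional; a header without a clone field denotes
a direct-PCR consensus sequence.  The legacy ``sampleID_cN`` clone suffix is
also recognised.

The per-sample haplotype type-call table (the survey transcription shipped
with the package) and ground-truth species labels are tab-separated files.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

# Canonical residue alphabet.  Case-insensitive on input; U is treated as T.
IUPAC_AMBIGUITY = set("RYSWKMBDHVN")
ALPHABET = set("ACGT-") | IUPAC_AMBIGUITY

# Numeric encoding used throughout the numeric layer: A,C,G,T -> 0..3,
# gap -> 4, any ambiguity code -> 5.  Codes 0/2 are purines and 1/3
# pyrimidines, so two unequal codes < 4 with equal parity are a transition.
GAP_CODE = 4
AMBIG_CODE = 5
_ENCODE = np.full(256, 255, dtype=np.uint8)
for i, base in enumerate("ACGT"):
    _ENCODE[ord(base)] = i
_ENCODE[ord("-")] = GAP_CODE
for code in IUPAC_AMBIGUITY:
    _ENCODE[ord(code)] = AMBIG_CODE

ROLE_PARENT_A = "parentA"
ROLE_PARENT_B = "parentB"
ROLE_HYBRID = "hybrid"

#: default species-name -> triangle-role map for the packaged survey table
DEFAULT_TAXON_ROLES = {
    "B. distachyon": ROLE_PARENT_A,
    "B. stacei": ROLE_PARENT_B,
    "B. hybridum": ROLE_HYBRID,
    ROLE_PARENT_A: ROLE_PARENT_A,
    ROLE_PARENT_B: ROLE_PARENT_B,
    ROLE_HYBRID: ROLE_HYBRID,
}

#: chromosome number expected for each triangle role (2n)
ROLE_CHROMOSOMES = {10: ROLE_PARENT_A, 20: ROLE_PARENT_B, 30: ROLE_HYBRID}


class AlignmentError(ValueError):
    """Ragged alignment: a record's length differs from the matrix length."""


class ResidueError(ValueError):
    """A residue outside the accepted alphabet, reported with its position."""


def normalize_residues(residues: str, sequence_id: str = "?") -> str:
    """Uppercase, map U->T and validate against the alphabet."""
    out = residues.upper().replace("U", "T")
    for pos, char in enumerate(out):
        if char not in ALPHABET:
            raise ResidueError(
                f"illegal residue {char!r} at column {pos} in record {sequence_id!r}"
            )
    return out


def encode_residues(residues: str) -> np.ndarray:
    """Encode a canonical residue string as a uint8 vector (see module docs)."""
    return _ENCODE[np.frombuffer(residues.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class SeqEntry:
    """One aligned sequence with its sample/clone/species annotation."""

    sequence_id: str
    sample_id: str
    residues: str
    clone_id: Optional[str] = None
    species_label: Optional[str] = None


@dataclass
class AlignedLocusMatrix:
    """Equal-length residue strings for one locus.

    Invariants (checked on construction): all residue strings share
    ``length`` columns, sequence ids are unique, and residues are drawn from
    the canonical alphabet (input is case-normalised).
    """

    locus_id: str
    records: list[SeqEntry]

    def __post_init__(self) -> None:
        normalized = []
        seen: set[str] = set()
        length = None
        for rec in self.records:
            residues = normalize_residues(rec.residues, rec.sequence_id)
            if length is None:
                length = len(residues)
            elif len(residues) != length:
                raise AlignmentError(
                    f"record {rec.sequence_id!r} has length {len(residues)}, "
                    f"expected {length} (locus {self.locus_id!r})"
                )
            if rec.sequence_id in seen:
                raise ValueError(f"duplicate sequence id {rec.sequence_id!r}")
            seen.add(rec.sequence_id)
            normalized.append(
                SeqEntry(rec.sequence_id, rec.sample_id, residues,
                         rec.clone_id, rec.species_label)
            )
        self.records = normalized

    @property
    def length(self) -> int:
        """Number of alignment columns (0 for an empty matrix)."""
        return len(self.records[0].residues) if self.records else 0

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return [rec.sequence_id for rec in self.records]

    def encoded(self) -> np.ndarray:
        """(n_sequences, length) uint8 matrix of encoded residues."""
        if not self.records:
            return np.zeros((0, 0), dtype=np.uint8)
        return np.vstack([encode_residues(r.residues) for r in self.records])

    def subset(self, sequence_ids: Iterable[str]) -> "AlignedLocusMatrix":
        wanted = set(sequence_ids)
        return AlignedLocusMatrix(
            self.locus_id, [r for r in self.records if r.sequence_id in wanted]
        )

    def species_labels(self) -> dict[str, Optional[str]]:
        return {r.sequence_id: r.species_label for r in self.records}


def _default_id_parser(header: str) -> tuple[str, Optional[str], Optional[str]]:
    """Parse ``sample|species|clone`` (preferred) or ``sample_cN`` headers."""
    if "|" in header:
        parts = header.split("|")
        sample = parts[0].strip()
        species = parts[1].strip() or None if len(parts) > 1 else None
        clone = parts[2].strip() or None if len(parts) > 2 else None
        return sample, species, clone
    match = re.match(r"^(.*)_c(\d+)$", header)
    if match:
        return match.group(1), None, f"c{match.group(2)}"
    return header.strip(), None, None


def read_aligned_fasta(path, locus_id: str, id_parser=None) -> AlignedLocusMatrix:
    """Read an aligned FASTA file into an :class:`AlignedLocusMatrix`.

    ``id_parser`` maps a full header line to ``(sample, species, clone)``;
    the default understands the package's ``sample|species|clone`` convention.
    """
    id_parser = id_parser or _default_id_parser
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description.strip()
        sample, species, clone = id_parser(header)
        records.append(
            SeqEntry(header, sample, str(rec.seq), clone, species)
        )
    return AlignedLocusMatrix(locus_id, records)


def write_aligned_fasta(matrix: AlignedLocusMatrix, path, width: int = 70) -> None:
    """Write a matrix as standard FASTA, regenerating the header convention.

    Headers are emitted as ``sample|species|clone`` with trailing empty
    fields dropped, so that ``read_aligned_fasta(write(...))`` is the
    identity on matrices built through this module.
    """
    if not matrix.records:
        warnings.warn(f"writing empty matrix for locus {matrix.locus_id!r}")
    with open(path, "w") as handle:
        for rec in matrix.records:
            fields = [rec.sample_id, rec.species_label or "", rec.clone_id or ""]
            while fields and not fields[-1]:
                fields.pop()
            handle.write(">" + "|".join(fields) + "\n")
            for start in range(0, len(rec.residues), width):
                handle.write(rec.residues[start:start + width] + "\n")


# ---------------------------------------------------------------------------
# Type-call table (survey transcription) and ground truth
# ---------------------------------------------------------------------------

PARENTAL_A = "A-type"
PARENTAL_B = "B-type"
RECOMBINANT = "recombinant"

MISSING_TOKENS = {"", "n.a", "n.a.", "na", "NA"}


@dataclass(frozen=True)
class LocusCalls:
    """Per-sample, per-locus haplotype calls.

    ``haplotypes`` maps haplotype id -> parental type.  A haplotype listed
    under both parental columns of the source table is tagged recombinant.
    """

    haplotypes: Mapping[str, str]
    cloned: bool
    missing: bool

    def types(self) -> set[str]:
        return set(self.haplotypes.values())

    def has_data(self) -> bool:
        return bool(self.haplotypes)


@dataclass
class TypeCallRow:
    sample_id: str
    taxon_label: str            # parentA / parentB / hybrid
    species_name: Optional[str]
    chromosomes_2n: Optional[int]
    count_evidence: str         # count / literature / none
    loci: dict[str, LocusCalls] = field(default_factory=dict)


@dataclass
class TypeCallTable:
    rows: list[TypeCallRow]
    loci: list[str]

    def __len__(self) -> int:
        return len(self.rows)

    def by_taxon(self, taxon_label: str) -> list[TypeCallRow]:
        return [r for r in self.rows if r.taxon_label == taxon_label]

    def get(self, sample_id: str) -> TypeCallRow:
        for row in self.rows:
            if row.sample_id == sample_id:
                return row
        raise KeyError(sample_id)


def _parse_call_cell(cell: str) -> tuple[list[str], bool, bool]:
    """Return (haplotype ids, cloned flag, explicit-missing flag)."""
    text = str(cell).strip()
    if text in MISSING_TOKENS:
        return [], False, text not in {""}
    cloned = False
    if re.search(r"\bc\s*$", text):
        text = re.sub(r",?\s*c\s*$", "", text)
        cloned = True
    haps = [tok.strip() for tok in re.split(r"[;,]", text) if tok.strip()]
    return haps, cloned, False


def read_type_call_table(
    path, taxon_roles: Optional[Mapping[str, str]] = None
) -> TypeCallTable:
    """Read the tab-separated per-sample haplotype type-call table.

    Expected columns: ``sample_id``, ``taxon`` plus ``<locus>_A``/``<locus>_B``
    pairs; optional ``chromosomes_2n`` and ``count_evidence``.  Haplotype sets
    are semicolon-separated, a trailing ``c`` marks cloned sequences and
    ``n.a`` marks a locus that did not amplify.
    """
    taxon_roles = dict(DEFAULT_TAXON_ROLES, **(taxon_roles or {}))
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if len(frame) == 0 and "sample_id" not in frame.columns:
        return TypeCallTable([], [])
    loci = []
    for col in frame.columns:
        if col.endswith("_A") and f"{col[:-2]}_B" in frame.columns:
            loci.append(col[:-2])
    rows: list[TypeCallRow] = []
    seen: set[str] = set()
    for _, rec in frame.iterrows():
        sample = rec["sample_id"].strip()
        if sample in seen:
            raise ValueError(f"duplicate sample_id {sample!r}")
        seen.add(sample)
        taxon_name = rec["taxon"].strip()
        if taxon_name not in taxon_roles:
            raise ValueError(f"unknown taxon label {taxon_name!r}")
        chrom_text = str(rec.get("chromosomes_2n", "")).strip()
        chrom = int(chrom_text) if chrom_text else None
        evidence = str(rec.get("count_evidence", "")).strip() or (
            "none" if chrom is None else "literature"
        )
        row = TypeCallRow(
            sample_id=sample,
            taxon_label=taxon_roles[taxon_name],
            species_name=taxon_name if taxon_name not in (
                ROLE_PARENT_A, ROLE_PARENT_B, ROLE_HYBRID) else None,
            chromosomes_2n=chrom,
            count_evidence=evidence,
        )
        for locus in loci:
            haps_a, cloned_a, miss_a = _parse_call_cell(rec[f"{locus}_A"])
            haps_b, cloned_b, miss_b = _parse_call_cell(rec[f"{locus}_B"])
            shared = set(haps_a) & set(haps_b)
            mapping: dict[str, str] = {}
            for hap in haps_a:
                mapping[hap] = RECOMBINANT if hap in shared else PARENTAL_A
            for hap in haps_b:
                mapping.setdefault(hap, PARENTAL_B)
            row.loci[locus] = LocusCalls(
                haplotypes=mapping,
                cloned=cloned_a or cloned_b,
                missing=not mapping,
            )
        rows.append(row)
    return TypeCallTable(rows, loci)


@dataclass(frozen=True)
class TruthEntry:
    species_label: str
    chromosomes_2n: Optional[int]
    evidence: str   # count / literature / none


class GroundTruth(dict):
    """sample_id -> :class:`TruthEntry`, with the 2n/species consistency check."""

    def __init__(self, entries: Mapping[str, TruthEntry]):
        super().__init__(entries)
        for sample, entry in self.items():
            if entry.chromosomes_2n is not None:
                expected = ROLE_CHROMOSOMES.get(entry.chromosomes_2n)
                if expected is not None and expected != entry.species_label:
                    raise ValueError(
                        f"sample {sample!r}: 2n={entry.chromosomes_2n} "
                        f"inconsistent with species {entry.species_label!r}"
                    )


def ground_truth_from_table(table: TypeCallTable) -> GroundTruth:
    """Derive ground truth labels from a type-call table's taxon column."""
    return GroundTruth({
        row.sample_id: TruthEntry(
            row.taxon_label, row.chromosomes_2n, row.count_evidence
        )
        for row in table.rows
    })


def read_ground_truth(path) -> GroundTruth:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    entries = {}
    for _, rec in frame.iterrows():
        chrom_text = str(rec.get("chromosomes_2n", "")).strip()
        entries[rec["sample_id"].strip()] = TruthEntry(
            rec["species_label"].strip(),
            int(chrom_text) if chrom_text else None,
            str(rec.get("evidence", "none")).strip() or "none",
        )
    return GroundTruth(entries)


def write_ground_truth(truth: GroundTruth, path) -> None:
    frame = pd.DataFrame(
        [
            {
                "sample_id": sample,
                "species_label": entry.species_label,
                "chromosomes_2n": "" if entry.chromosomes_2n is None
                else entry.chromosomes_2n,
                "evidence": entry.evidence,
            }
            for sample, entry in truth.items()
        ]
    )
    frame.to_csv(path, sep="\t", index=False)


SURVEY_TABLE_RESOURCE = "brachypodium_calls.tsv"


def load_survey_table() -> TypeCallTable:
    """Load the packaged 210-sample Brachypodium survey type-call table."""
    source = resources.files("allobarcode") / "data" / SURVEY_TABLE_RESOURCE
    with resources.as_file(source) as path:
        return read_type_call_table(path)
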