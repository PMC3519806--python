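"""End-to-end orchestration: stats -> networks -> trees -> classification.

The pipeline consumes one aligned FASTA per locus (or a freshly generated
synthetic dataset), runs each analysis stage and assembles a JSON-canonical
report.  Numbers in the report are exactly the numbers the stage functions
return; the pipeline adds no transformations of its own.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .barcode_stats import (
    barcode_gap,
    classify_sites,
    k2p_matrix,
    summarize_groups,
)
from .hapnet import (
    build_network,
    collapse_haplotypes,
    intercluster_steps,
    tag_haplotypes,
    DEFAULT_CONNECTION_LIMIT,
)
from .njtree import (
    DEFAULT_DISCRIMINATION_THRESHOLD,
    SaturatedPairError,
    monophyly_fraction,
    nj,
)
from .seqio import (
    AlignedLocusMatrix,
    GroundTruth,
    ROLE_HYBRID,
    ROLE_PARENT_A,
    ROLE_PARENT_B,
    read_aligned_fasta,
    read_ground_truth,
)
from .triangle_classify import (
    DEFAULT_MIN_MARGIN,
    DEFAULT_MIN_SEGMENT,
    DEFAULT_PURITY,
    DiagnosticProfile,
    PARENTAL_A,
    PARENTAL_B,
    PLASTID,
    call_species,
    call_type,
    identification_success,
)

logger = logging.getLogger(__name__)

VALID_ROLES = {PLASTID, "nuclear-multicopy", "nuclear-single-copy"}


@dataclass
class LocusConfig:
    locus_id: str
    role: str
    path: Optional[str] = None


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Exactly one plastid locus and at least one nuclear locus are required;
    thresholds must lie in their documented ranges.
    """

    loci: list[LocusConfig]
    ground_truth_path: Optional[str] = None
    purity: float = DEFAULT_PURITY
    min_margin: int = DEFAULT_MIN_MARGIN
    min_segment: int = DEFAULT_MIN_SEGMENT
    connection_limit: int = DEFAULT_CONNECTION_LIMIT
    discrimination_threshold: float = DEFAULT_DISCRIMINATION_THRESHOLD
    deletion_policy: str = "pairwise"
    output_dir: Optional[str] = None
    seed: int = 0
    verbosity: int = 1

    def validate(self) -> list[str]:
        problems = []
        plastid = [l for l in self.loci if l.role == PLASTID]
        nuclear = [l for l in self.loci if l.role != PLASTID]
        if len(plastid) != 1:
            problems.append(f"need exactly one plastid locus, got {len(plastid)}")
        if not nuclear:
            problems.append("need at least one nuclear locus")
        for locus in self.loci:
            if locus.role not in VALID_ROLES:
                problems.append(f"unknown role {locus.role!r} for {locus.locus_id}")
        if not 0.5 <= self.purity <= 1.0:
            problems.append("purity must lie in [0.5, 1]")
        if not 0.0 < self.discrimination_threshold < 1.0:
            problems.append("discrimination threshold must lie in (0, 1)")
        if self.connection_limit < 1:
            problems.append("connection limit must be >= 1")
        if self.deletion_policy not in ("pairwise", "complete-set"):
            problems.append(f"unknown deletion policy {self.deletion_policy!r}")
        return problems

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        loci = [LocusConfig(**entry) for entry in raw.pop("loci", [])]
        return cls(loci=loci, **raw)

    def digest(self) -> str:
        payload = json.dumps(
            {
                "loci": [(l.locus_id, l.role, l.path) for l in self.loci],
                "purity": self.purity,
                "min_margin": self.min_margin,
                "min_segment": self.min_segment,
                "connection_limit": self.connection_limit,
                "discrimination_threshold": self.discrimination_threshold,
                "deletion_policy": self.deletion_policy,
                "seed": self.seed,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class ConfigError(ValueError):
    pass


_GROUP_OF_ROLE = {ROLE_PARENT_A: "A", ROLE_PARENT_B: "B"}


def _diploid_labels(matrix: AlignedLocusMatrix) -> dict[str, str]:
    return {
        rec.sequence_id: _GROUP_OF_ROLE[rec.species_label]
        for rec in matrix.records
        if rec.species_label in _GROUP_OF_ROLE
    }


def analyse_locus(
    matrix: AlignedLocusMatrix,
    config: PipelineConfig,
) -> dict:
    """Run the distance/site/network/tree stages for one locus."""
    diploid = _diploid_labels(matrix)
    sites = classify_sites(matrix, diploid)
    profile = DiagnosticProfile.from_site_classifications(
        {matrix.locus_id: sites}
    )

    # type every hybrid sequence so summaries can split A-like/B-like copies
    labels = dict(diploid)
    type_calls = {}
    for rec in matrix.records:
        if rec.species_label == ROLE_HYBRID:
            call = call_type(
                rec.residues, profile, matrix.locus_id,
                purity=config.purity, min_margin=config.min_margin,
                min_segment=config.min_segment, sequence_id=rec.sequence_id,
            )
            type_calls[rec.sequence_id] = call
            if call.call == PARENTAL_A:
                labels[rec.sequence_id] = "hybrid-A-like"
            elif call.call == PARENTAL_B:
                labels[rec.sequence_id] = "hybrid-B-like"

    dm = k2p_matrix(matrix, config.deletion_policy)
    summary = summarize_groups(dm, labels)
    gap = barcode_gap(summary)

    haps = collapse_haplotypes(matrix)
    tag_haplotypes(
        haps,
        {sid: {"A": "A-type", "B": "B-type",
               "hybrid-A-like": "A-type",
               "hybrid-B-like": "B-type"}.get(g)
         for sid, g in labels.items() if g is not None},
    )
    network = build_network(haps, config.connection_limit)
    a_ids = [sid for sid, g in diploid.items() if g == "A"]
    b_ids = [sid for sid, g in diploid.items() if g == "B"]
    try:
        steps = intercluster_steps(haps, a_ids, b_ids)
    except ValueError:
        steps = None

    tree_block: dict = {}
    diploid_matrix = matrix.subset(diploid)
    try:
        tree = nj(k2p_matrix(diploid_matrix, config.deletion_policy))
        for group_name, ids in (("parentA", a_ids), ("parentB", b_ids)):
            frac = monophyly_fraction(tree, ids)
            tree_block[group_name] = {
                "monophyly_fraction": frac,
                "discriminated": frac > config.discrimination_threshold,
            }
        tree_block["clamped_branches"] = tree.clamped
    except (ValueError, SaturatedPairError) as exc:
        tree_block["error"] = str(exc)

    return {
        "locus_id": matrix.locus_id,
        "n_sequences": len(matrix),
        "alignment_length": matrix.length,
        "sites": {
            "n_variable": sites.n_variable,
            "pct_variable": sites.pct_variable,
            "n_diagnostic": sites.n_diagnostic,
            "pct_diagnostic": sites.pct_diagnostic,
            "diagnostic_indels": [
                [run.start, run.stop, run.gapped_group]
                for run in sites.diagnostic_indels
            ],
        },
        "distances": {
            stats.label: {
                "mean": stats.mean, "min": stats.minimum,
                "max": stats.maximum, "sd": stats.sd,
                "n_pairs": stats.n_pairs, "n_saturated": stats.n_saturated,
            }
            for stats in list(summary.intra.values())
            + list(summary.inter.values())
        },
        "barcode_gap": {
            "gap_present": gap.gap_present,
            "min_inter": gap.min_inter,
            "max_intra": gap.max_intra,
            "margin": gap.margin,
        },
        "network": {
            "n_haplotypes": len(haps),
            "n_inferred": network.n_inferred,
            "n_components": len(network.components),
            "intercluster_steps": steps,
        },
        "tree": tree_block,
        "_profile": profile,
        "_type_calls": type_calls,
    }


def classify_samples(
    matrices: dict[str, AlignedLocusMatrix],
    locus_results: dict[str, dict],
    config: PipelineConfig,
    truth: Optional[GroundTruth] = None,
) -> dict:
    """Per-sample verdicts from the per-sequence type calls of every locus."""
    roles = {l.locus_id: l.role for l in config.loci}
    per_sample: dict[str, dict[str, list]] = {}
    for locus_id, matrix in matrices.items():
        result = locus_results[locus_id]
        profile = result["_profile"]
        for rec in matrix.records:
            if rec.species_label in (ROLE_PARENT_A, ROLE_PARENT_B):
                call = call_type(
                    rec.residues, profile, locus_id,
                    purity=config.purity, min_margin=config.min_margin,
                    min_segment=config.min_segment,
                    sequence_id=rec.sequence_id,
                )
            else:
                call = result["_type_calls"].get(rec.sequence_id)
                if call is None:
                    continue
            per_sample.setdefault(rec.sample_id, {}).setdefault(
                locus_id, []
            ).append(call)

    verdicts = {}
    for sample_id, locus_calls in sorted(per_sample.items()):
        try:
            result = call_species(sample_id, locus_calls, roles)
            verdicts[sample_id] = {
                "verdict": result.verdict,
                "rule": result.rule,
            }
        except ValueError:
            verdicts[sample_id] = {"verdict": "no-data", "rule": "no-calls"}

    block: dict = {"verdicts": verdicts}
    if truth is not None:
        report = identification_success(
            per_sample, truth, list(matrices), roles
        )
        block["success"] = {
            species: {"percentage": pct, "n_correct": correct, "n": scored}
            for species, (pct, correct, scored) in report.per_species.items()
        }
    return block


def run(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return the canonical report dict.

    A locus that fails a stage is dropped from the combined classification
    with a logged reason rather than aborting the run.
    """
    problems = config.validate()
    if problems:
        raise ConfigError("; ".join(problems))

    matrices: dict[str, AlignedLocusMatrix] = {}
    for locus in config.loci:
        if locus.path is None:
            raise ConfigError(f"locus {locus.locus_id!r} has no input path")
        matrices[locus.locus_id] = read_aligned_fasta(
            locus.path, locus.locus_id
        )
        logger.info("read %s: %d sequences x %d columns", locus.locus_id,
                    len(matrices[locus.locus_id]),
                    matrices[locus.locus_id].length)

    truth = (
        read_ground_truth(config.ground_truth_path)
        if config.ground_truth_path else None
    )

    locus_results: dict[str, dict] = {}
    failed: dict[str, str] = {}
    for locus_id, matrix in matrices.items():
        try:
            locus_results[locus_id] = analyse_locus(matrix, config)
        except Exception as exc:   # dropped from combined classification
            logger.warning("locus %s failed: %s", locus_id, exc)
            failed[locus_id] = str(exc)

    usable = {lid: m for lid, m in matrices.items() if lid in locus_results}
    classification = classify_samples(usable, locus_results, config, truth)

    report = {
        "provenance": {
            "tool": "allobarcode",
            "version": __version__,
            "config_digest": config.digest(),
            "seed": config.seed,
        },
        "loci": {
            lid: {k: v for k, v in res.items() if not k.startswith("_")}
            for lid, res in locus_results.items()
        },
        "failed_loci": failed,
        "classification": classification,
    }
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
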