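"""Presence–absence matrix, core/accessory/unique classification, consensus
gene order and core/maximum cluster reconstruction.

The classification follows standard pangenome practice adapted to gene
clusters: because a BGC holds far fewer genes than a genome, an OG is core
only when present in every member (threshold 1.0 by default, adjustable).
OGs found in a single member are unique; everything in between is
accessory. Prevalence uses presence (>= 1 copy), never copy number, and the
threshold comparison is done in exact rational arithmetic so boundary cases
such as 3 of 4 members at a 0.75 cutoff behave predictably.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import NamedTuple, Optional

import numpy as np
from scipy import stats

from .exceptions import IncompleteAssignmentError
from .model import GCF

CORE = "core"
ACCESSORY = "accessory"
UNIQUE = "unique"


@dataclass
class PresenceAbsenceMatrix:
    """BGC x OG copy-number table; the substrate of classification and of
    every openness metric."""

    bgc_ids: list[str]
    og_ids: list[str]
    counts: np.ndarray  # shape (n_bgcs, n_ogs), integer copy numbers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.bgc_ids), len(self.og_ids)):
            raise ValueError("counts shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("negative copy numbers")
        if len(self.bgc_ids) and (self.counts.sum(axis=1) == 0).any():
            raise ValueError("every BGC row must contain at least one gene")
        if len(self.og_ids) and (self.counts.sum(axis=0) == 0).any():
            raise ValueError("every OG column must occur in at least one BGC")

    @property
    def n_bgcs(self) -> int:
        return len(self.bgc_ids)

    @property
    def n_ogs(self) -> int:
        return len(self.og_ids)

    def presence(self) -> np.ndarray:
        """Boolean presence (>= 1 copy) view of the counts."""
        return self.counts > 0

    def presence_sets(self) -> list[frozenset[str]]:
        """Per-BGC set of OGs present, copy numbers ignored."""
        present = self.presence()
        return [
            frozenset(self.og_ids[j] for j in np.flatnonzero(present[i]))
            for i in range(self.n_bgcs)
        ]


@dataclass
class ClassificationConfig:
    """``core_threshold`` is the minimum prevalence fraction for core
    status; 1.0 reproduces the strict every-member definition."""

    core_threshold: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.core_threshold <= 1.0):
            raise ValueError("core_threshold must be in (0, 1]")

    def threshold_fraction(self) -> Fraction:
        # limit_denominator keeps float cutoffs like 0.95 exactly 19/20
        return Fraction(self.core_threshold).limit_denominator(10**6)


def build_presence_absence(gcf: GCF) -> PresenceAbsenceMatrix:
    """Count copies of every OG in every member BGC.

    Rows follow member order; columns follow og id order of first
    appearance. Requires a total ortholog assignment.
    """
    missing = gcf.unassigned_genes()
    if missing:
        raise IncompleteAssignmentError(missing)
    og_ids = gcf.og_ids()
    col = {og: j for j, og in enumerate(og_ids)}
    counts = np.zeros((gcf.n_bgcs, len(og_ids)), dtype=int)
    for i, member in enumerate(gcf.members):
        for gene in member.genes:
            counts[i, col[gene.og_id]] += 1
    return PresenceAbsenceMatrix(
        bgc_ids=[m.bgc_id for m in gcf.members], og_ids=og_ids, counts=counts
    )


def classify_ogs(
    matrix: PresenceAbsenceMatrix, config: Optional[ClassificationConfig] = None
) -> dict[str, str]:
    """Assign each OG one of ``core`` / ``accessory`` / ``unique``.

    Core is tested first: prevalence >= threshold (exact rational
    comparison). A non-core OG in exactly one member is unique; the rest
    are accessory. In a single-member family every OG is therefore core.
    """
    config = config or ClassificationConfig()
    cutoff = config.threshold_fraction()
    n = matrix.n_bgcs
    present_counts = matrix.presence().sum(axis=0)
    categories: dict[str, str] = {}
    for og_id, k in zip(matrix.og_ids, present_counts):
        if Fraction(int(k), n) >= cutoff:
            categories[og_id] = CORE
        elif k == 1:
            categories[og_id] = UNIQUE
        else:
            categories[og_id] = ACCESSORY
    return categories


def _orientation_sign(reference_order: list[str], member_order: list[str]) -> int:
    """Spearman correlation sign between a member's OG order and the
    reference member's, over shared OGs. Negative means the member is
    recorded on the opposite strand and should be reversed; zero keeps it."""
    ref_pos = {og: i for i, og in enumerate(_first_occurrences(reference_order))}
    mem_first = _first_occurrences(member_order)
    shared = [og for og in mem_first if og in ref_pos]
    if len(shared) < 2:
        return 1
    x = [ref_pos[og] for og in shared]
    y = [mem_first.index(og) for og in shared]
    rho = stats.spearmanr(x, y).statistic
    if np.isnan(rho) or rho == 0:
        return 1
    return 1 if rho > 0 else -1


def _first_occurrences(seq: list[str]) -> list[str]:
    seen: dict[str, None] = {}
    for s in seq:
        if s not in seen:
            seen[s] = None
    return list(seen)


def consensus_order(gcf: GCF, matrix: PresenceAbsenceMatrix) -> list[str]:
    """Derive a single OG ordering summarizing member gene orders.

    Each member is first orientation-normalized against the first member
    (clusters are recorded on arbitrary strands). Genes then receive
    normalized ranks position/len(member); an OG's score is the mean
    normalized rank of its copies across the members containing it. Output
    ascends by score with ties broken by higher prevalence then
    lexicographic og id.
    """
    missing = gcf.unassigned_genes()
    if missing:
        raise IncompleteAssignmentError(missing)
    ref_order = [g.og_id for g in gcf.members[0].genes]
    scores: dict[str, list[float]] = {og: [] for og in matrix.og_ids}
    for member in gcf.members:
        order = [g.og_id for g in member.genes]
        if _orientation_sign(ref_order, order) < 0:
            order = order[::-1]
        m = len(order)
        for pos, og in enumerate(order):
            scores[og].append(pos / m)
    prevalence = dict(zip(matrix.og_ids, matrix.presence().sum(axis=0)))
    return sorted(
        matrix.og_ids,
        key=lambda og: (
            float(np.mean(scores[og])),
            -int(prevalence[og]),
            og,
        ),
    )


class ReconstructedOG(NamedTuple):
    """One slot of a reconstructed (core or maximum) cluster."""

    og_id: str
    category: str
    mean_length: Optional[float]


def og_mean_lengths(gcf: GCF) -> dict[str, Optional[float]]:
    """Mean protein length (residues) per OG; None when no copy carries a
    protein sequence."""
    lengths: dict[str, list[int]] = {}
    for gene in gcf.genes():
        if gene.og_id is None:
            continue
        if gene.protein:
            lengths.setdefault(gene.og_id, []).append(len(gene.protein))
        else:
            lengths.setdefault(gene.og_id, [])
    return {
        og: (float(np.mean(v)) if v else None) for og, v in lengths.items()
    }


def reconstruct_bgc(
    gcf: GCF,
    mode: str,
    config: Optional[ClassificationConfig] = None,
    matrix: Optional[PresenceAbsenceMatrix] = None,
) -> list[ReconstructedOG]:
    """Reconstruct the core BGC or the theoretical maximum BGC.

    ``mode='max'`` merges every OG observed anywhere in the family;
    ``mode='core'`` keeps only OGs meeting the core threshold. Both are
    laid out in consensus gene order and carry the mean protein length per
    slot. An empty core list (no OG meets the cutoff) is valid and flagged
    upstream in the summary.
    """
    if mode not in ("core", "max"):
        raise ValueError("mode must be 'core' or 'max'")
    matrix = matrix if matrix is not None else build_presence_absence(gcf)
    categories = classify_ogs(matrix, config)
    order = consensus_order(gcf, matrix)
    lengths = og_mean_lengths(gcf)
    selected = (
        order if mode == "max" else [og for og in order if categories[og] == CORE]
    )
    return [
        ReconstructedOG(og, categories[og], lengths.get(og)) for og in selected
    ]
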