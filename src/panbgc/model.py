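"""Core data model: genes, BGC records, and gene cluster families.

A biosynthetic gene cluster (BGC) is a physically co-located run of genes
encoding the biosynthesis, export and regulation of a specialized
metabolite. A gene cluster family (GCF) is a set of architecturally
similar BGCs, treated here as a population: the unit on which pangenome
concepts (core / accessory / unique genes, openness) are applied.

Coordinates are 0-based half-open throughout; GenBank I/O converts at the
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

FORWARD = 1
REVERSE = -1


@dataclass
class Gene:
    """One protein-coding gene inside a BGC.

    ``og_id`` stays ``None`` until ortholog grouping (or an external
    assignment table) has run.
    """

    gene_id: str
    bgc_id: str
    start: int
    end: int
    strand: int = FORWARD
    protein: Optional[str] = None
    product: Optional[str] = None
    og_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in (FORWARD, REVERSE):
            raise ValueError(f"gene {self.gene_id}: strand must be +1 or -1")
        if self.protein is not None:
            if not self.protein:
                raise ValueError(f"gene {self.gene_id}: protein present but empty")
            bad = set(self.protein.upper()) - AA_ALPHABET
            if bad:
                raise ValueError(
                    f"gene {self.gene_id}: protein contains non-amino-acid symbols {sorted(bad)}"
                )

    @property
    def length_nt(self) -> int:
        return self.end - self.start


@dataclass
class BGCRecord:
    """One BGC: an ordered, non-empty list of genes plus metadata.

    ``contig_edge`` marks clusters that touch a contig boundary and may be
    truncated; such records are parsed normally but flagged so downstream
    interpretation can discount them.
    """

    bgc_id: str
    genes: list[Gene]
    source: str = "user"  # one of antismash, mibig, user, synthetic
    bgc_class: list[str] = field(default_factory=list)
    contig_edge: bool = False

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"BGC {self.bgc_id}: must contain at least one gene")
        starts = [g.start for g in self.genes]
        if starts != sorted(starts):
            raise ValueError(f"BGC {self.bgc_id}: genes must be sorted by start")
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            raise ValueError(f"BGC {self.bgc_id}: duplicate gene ids")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)


@dataclass
class GCF:
    """A gene cluster family: member BGCs plus (once grouping has run) a
    total assignment of every gene to exactly one ortholog group."""

    gcf_id: str
    members: list[BGCRecord]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"GCF {self.gcf_id}: needs at least one member BGC")
        ids = [m.bgc_id for m in self.members]
        if len(ids) != len(set(ids)):
            raise ValueError(f"GCF {self.gcf_id}: duplicate BGC ids")

    @property
    def n_bgcs(self) -> int:
        return len(self.members)

    def genes(self) -> Iterator[Gene]:
        """All genes of all members, in member order then gene order."""
        for member in self.members:
            yield from member.genes

    @property
    def og_assignment(self) -> dict[tuple[str, str], str]:
        """Map (bgc_id, gene_id) -> og_id for every assigned gene."""
        return {
            (g.bgc_id, g.gene_id): g.og_id
            for g in self.genes()
            if g.og_id is not None
        }

    def assignment_is_total(self) -> bool:
        return all(g.og_id is not None for g in self.genes())

    def unassigned_genes(self) -> list[str]:
        return [g.gene_id for g in self.genes() if g.og_id is None]

    def og_ids(self) -> list[str]:
        """Distinct og ids in order of first appearance."""
        seen: dict[str, None] = {}
        for g in self.genes():
            if g.og_id is not None and g.og_id not in seen:
                seen[g.og_id] = None
        return list(seen)


@dataclass
class OrthologGroup:
    """Summary of one ortholog group within a family.

    ``prevalence`` is the fraction of member BGCs carrying at least one
    copy; ``copy_total`` counts every copy. ``category`` is set by
    classification, ``consensus_index`` by the consensus-order step.
    """

    og_id: str
    members: list[tuple[str, str]]  # (bgc_id, gene_id)
    prevalence: float
    copy_total: int
    mean_length: Optional[float] = None
    consensus_index: Optional[int] = None
    category: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"OG {self.og_id}: empty member list")
        if not (0.0 < self.prevalence <= 1.0):
            raise ValueError(f"OG {self.og_id}: prevalence must be in (0, 1]")
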