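"""Greedy single-linkage ortholog grouping.

A deterministic, self-contained grouper: proteins are compared all against
all by global (Needleman–Wunsch) alignment, an edge connects pairs whose
identity over the shorter sequence reaches the identity threshold and whose
length ratio reaches the coverage threshold, and single-linkage connected
components become ortholog groups. Permissive transitive closure suits the
modular, repetitive genes of biosynthetic clusters better than
reciprocal-best-hit schemes. OG ids are assigned in order of first-member
appearance (BGC order, then gene order), so output is deterministic for a
given input order and thresholds.
"""

from __future__ import annotations

import edlib

from .exceptions import UngroupableGeneError
from .model import GCF, Gene

DEFAULT_IDENTITY = 0.5
DEFAULT_COVERAGE = 0.7


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of identical aligned positions over the shorter sequence,
    under a unit-cost global alignment."""
    if not a or not b:
        return 0.0
    result = edlib.align(a, b, mode="NW", task="path")
    cigar = result["cigar"]
    matches = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch == "=":
                matches += int(num)
            num = ""
    return matches / min(len(a), len(b))


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            # smaller root wins: keeps component representatives stable
            if ri < rj:
                self.parent[rj] = ri
            else:
                self.parent[ri] = rj


def _usable_sequence(gene: Gene) -> str:
    if gene.protein:
        return gene.protein
    raise UngroupableGeneError(
        f"gene {gene.gene_id} of BGC {gene.bgc_id} has no protein or recoverable sequence"
    )


def assign_orthologs_greedy(
    gcf: GCF,
    identity_threshold: float = DEFAULT_IDENTITY,
    coverage_threshold: float = DEFAULT_COVERAGE,
) -> GCF:
    """Partition every gene of the family into ortholog groups in place.

    Parameters
    ----------
    gcf:
        Family whose genes all carry a protein sequence (the GenBank reader
        falls back to conceptual translation where it can).
    identity_threshold:
        Minimum fraction of identical aligned positions over the shorter
        protein, in (0, 1].
    coverage_threshold:
        Minimum length ratio shorter/longer, in (0, 1]. Pairs below it are
        never linked, whatever their identity.

    Returns
    -------
    GCF
        The same object with ``og_id`` set on every gene. Multi-copy genes
        within one BGC share an OG when similar; copy numbers surface later
        in the presence–absence matrix.
    """
    if not (0.0 < identity_threshold <= 1.0):
        raise ValueError("identity_threshold must be in (0, 1]")
    if not (0.0 < coverage_threshold <= 1.0):
        raise ValueError("coverage_threshold must be in (0, 1]")

    genes = list(gcf.genes())
    seqs = [_usable_sequence(g) for g in genes]
    uf = _UnionFind(len(genes))
    for i in range(len(genes)):
        li = len(seqs[i])
        for j in range(i + 1, len(genes)):
            lj = len(seqs[j])
            if min(li, lj) / max(li, lj) < coverage_threshold:
                continue
            if pairwise_identity(seqs[i], seqs[j]) >= identity_threshold:
                uf.union(i, j)

    # og ids in order of first-member appearance
    root_to_og: dict[int, str] = {}
    counter = 0
    for i, gene in enumerate(genes):
        root = uf.find(i)
        if root not in root_to_og:
            root_to_og[root] = f"OG{counter:04d}"
            counter += 1
        gene.og_id = root_to_og[root]
    return gcf
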