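"""Synthetic gene cluster families with known ground truth.

The generator emulates the structure the framework assumes real families
have: a conserved core present in every member, an accessory pool each
member samples with fixed probability, fresh never-reused unique genes,
optional tandem duplication, gene-order shuffling (with strand
randomization) and terminal truncation with a contig-edge flag. Proteins
are built as per-OG random templates with small per-copy point mutation,
so the greedy grouper can re-discover the true partition end to end.

Everything is driven by one integer seed through
``numpy.random.default_rng``; identical specs yield identical families.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import EmptyFamilyError
from .model import FORWARD, REVERSE, GCF, BGCRecord, Gene

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

#: fixed reverse-translation codon per amino acid, so emitted GenBank
#: nucleotide spans conceptually translate back to the protein
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

SPACER_NT = 50


@dataclass
class SyntheticGCFSpec:
    """Parameters of one synthetic family.

    ``unique_rate`` is the Poisson mean of fresh, never-reused OGs per
    member; ``accessory_prob`` the per-OG per-member inclusion
    probability; ``mutation_rate`` the per-residue substitution
    probability applied to each copy of an OG template.
    """

    n_bgcs: int = 10
    core_size: int = 5
    accessory_pool_size: int = 5
    accessory_prob: float = 0.5
    unique_rate: float = 0.5
    duplication_prob: float = 0.0
    shuffle: bool = False
    truncate_prob: float = 0.0
    mean_protein_length: int = 150
    mutation_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("accessory_prob", "duplication_prob", "truncate_prob", "mutation_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_bgcs < 1:
            raise ValueError("n_bgcs must be >= 1")
        if self.unique_rate < 0:
            raise ValueError("unique_rate must be >= 0")
        if self.mean_protein_length < 10:
            raise ValueError("mean_protein_length must be >= 10")
        if self.core_size == 0 and self.accessory_pool_size == 0 and self.unique_rate == 0:
            raise EmptyFamilyError("spec can generate no genes at all")


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length))


def _mutate(rng: np.random.Generator, template: str, rate: float) -> str:
    if rate == 0.0:
        return template
    chars = np.array(list(template))
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        choices = _AA[_AA != chars[i]]
        chars[i] = rng.choice(choices)
    return "".join(chars)


def reverse_translate(protein: str) -> str:
    """Deterministic nucleotide encoding of a protein plus a TAA stop."""
    return "".join(_CODON[aa] for aa in protein) + "TAA"


def generate_gcf(spec: SyntheticGCFSpec, gcf_id: str = "synthetic_gcf") -> GCF:
    """Generate one family with ground-truth OG labels on every gene.

    Core OGs appear in every member; accessory OGs are Bernoulli-included
    per member; unique OGs are drawn fresh per member and never reused, so
    they are unique by construction. A member that would otherwise be
    empty receives one fresh unique gene to keep records non-empty.
    """
    rng = np.random.default_rng(spec.seed)
    sd = max(1.0, 0.1 * spec.mean_protein_length)

    def template_length() -> int:
        return max(30, int(round(rng.normal(spec.mean_protein_length, sd))))

    core_ids = [f"OGC{i:03d}" for i in range(spec.core_size)]
    acc_ids = [f"OGA{i:03d}" for i in range(spec.accessory_pool_size)]
    templates = {og: _random_protein(rng, template_length()) for og in core_ids + acc_ids}
    unique_counter = 0

    members = []
    for b in range(spec.n_bgcs):
        bgc_id = f"{gcf_id}_bgc{b:03d}"
        ogs = list(core_ids)
        ogs += [og for og in acc_ids if rng.random() < spec.accessory_prob]
        n_unique = int(rng.poisson(spec.unique_rate))
        for _ in range(n_unique):
            og = f"OGU{unique_counter:05d}"
            unique_counter += 1
            templates[og] = _random_protein(rng, template_length())
            ogs.append(og)
        if not ogs:
            og = f"OGU{unique_counter:05d}"
            unique_counter += 1
            templates[og] = _random_protein(rng, template_length())
            ogs.append(og)

        # tandem duplication: a duplicate copy right after its parent
        with_dups: list[str] = []
        for og in ogs:
            with_dups.append(og)
            if rng.random() < spec.duplication_prob:
                with_dups.append(og)

        if spec.shuffle:
            order = rng.permutation(len(with_dups))
            with_dups = [with_dups[i] for i in order]
            strands = [FORWARD if rng.random() < 0.5 else REVERSE for _ in with_dups]
        else:
            strands = [FORWARD] * len(with_dups)

        contig_edge = False
        if spec.truncate_prob > 0 and rng.random() < spec.truncate_prob and len(with_dups) > 1:
            if rng.random() < 0.5:
                with_dups, strands = with_dups[1:], strands[1:]
            else:
                with_dups, strands = with_dups[:-1], strands[:-1]
            contig_edge = True

        genes = []
        cursor = 0
        for ordinal, (og, strand) in enumerate(zip(with_dups, strands), 1):
            protein = _mutate(rng, templates[og], spec.mutation_rate)
            span = 3 * len(protein) + 3  # coding region plus stop codon
            genes.append(
                Gene(
                    gene_id=f"{bgc_id}_g{ordinal}",
                    bgc_id=bgc_id,
                    start=cursor,
                    end=cursor + span,
                    strand=strand,
                    protein=protein,
                    og_id=og,
                )
            )
            cursor += span + SPACER_NT
        members.append(
            BGCRecord(
                bgc_id=bgc_id,
                genes=genes,
                source="synthetic",
                bgc_class=["synthetic"],
                contig_edge=contig_edge,
            )
        )
    return GCF(gcf_id=gcf_id, members=members)


def true_core_ids(spec: SyntheticGCFSpec) -> list[str]:
    """OG ids the generator guarantees to be present in every member."""
    return [f"OGC{i:03d}" for i in range(spec.core_size)]


def emit_genbank(gcf: GCF, out_dir, with_truth_table: bool = True) -> None:
    """Write each member as a GenBank file (plus the ground-truth ortholog
    table) so parser and grouper can be exercised on disk fixtures.

    Nucleotide sequences are deterministic reverse translations joined by
    A-run spacers; reverse-strand genes are emitted as the reverse
    complement of their coding sequence.
    """
    from pathlib import Path

    from Bio.Seq import Seq

    from . import io as gcf_io

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for member in gcf.members:
        length = max(g.end for g in member.genes)
        seq = ["A"] * length
        for gene in member.genes:
            coding = reverse_translate(gene.protein)[: gene.end - gene.start]
            if gene.strand == REVERSE:
                coding = str(Seq(coding).reverse_complement())
            seq[gene.start : gene.start + len(coding)] = list(coding)
        gcf_io.write_region_genbank(member, out_dir / f"{member.bgc_id}.gbk", "".join(seq))
    if with_truth_table:
        gcf_io.write_ortholog_table(gcf, out_dir / "ortholog_table.tsv")


def generate_powerlaw_curve(
    k: float, gamma: float, n: int, noise_sd: float = 0.0, seed: int = 0
) -> np.ndarray:
    """y_i = k * x_i^gamma * exp(eps_i), eps ~ Normal(0, noise_sd), at
    x = 1..n. The multiplicative noise keeps values positive, as real
    accumulation curves are."""
    if n < 3:
        raise ValueError("n must be >= 3")
    if k <= 0:
        raise ValueError("k must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    x = np.arange(1, n + 1, dtype=float)
    y = k * x**gamma
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y * np.exp(rng.normal(0.0, noise_sd, size=n))
    return y
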