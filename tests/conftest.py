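"""Shared fixtures: tiny hand-built families and GenBank fixture text."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from panbgc.model import GCF, BGCRecord, Gene
from panbgc.pangenome import PresenceAbsenceMatrix

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_gene(gene_id, bgc_id, index, og_id=None, protein=None, strand=1):
    start = index * 400
    return Gene(
        gene_id=gene_id,
        bgc_id=bgc_id,
        start=start,
        end=start + 300,
        strand=strand,
        protein=protein,
        og_id=og_id,
    )


def make_bgc(bgc_id, og_ids, proteins=None):
    """A BGC whose genes are already assigned to the given OGs, in order."""
    genes = [
        make_gene(
            f"{bgc_id}_g{i + 1}",
            bgc_id,
            i,
            og_id=og,
            protein=proteins[i] if proteins else None,
        )
        for i, og in enumerate(og_ids)
    ]
    return BGCRecord(bgc_id=bgc_id, genes=genes, source="user")


def make_family(gcf_id, member_og_lists):
    members = [
        make_bgc(f"{gcf_id}_b{i}", ogs) for i, ogs in enumerate(member_og_lists)
    ]
    return GCF(gcf_id=gcf_id, members=members)


def matrix_from_rows(bgc_ids, og_ids, rows):
    return PresenceAbsenceMatrix(
        bgc_ids=list(bgc_ids), og_ids=list(og_ids), counts=np.asarray(rows, dtype=int)
    )


@pytest.fixture
def worked_family():
    """The 3-member family {A,B}, {A,C}, {A,B,C} used as a hand oracle."""
    return make_family("toy3", [["A", "B"], ["A", "C"], ["A", "B", "C"]])


@pytest.fixture
def worked_matrix():
    return matrix_from_rows(
        ["b0", "b1", "b2"],
        ["A", "B", "C"],
        [[1, 1, 0], [1, 0, 1], [1, 1, 1]],
    )


#: Minimal valid GenBank text with three CDS features:
#: 1..300 (+), 401..700 (complement), 801..1100 (+); 1-based inclusive.
FIXTURE_GBK = """\
LOCUS       FIXBGC001               1200 bp    DNA     linear   BCT 01-JAN-2024
DEFINITION  fixture cluster.
ACCESSION   FIXBGC001
VERSION     FIXBGC001.1
KEYWORDS    .
SOURCE      synthetic construct
  ORGANISM  synthetic construct
            .
FEATURES             Location/Qualifiers
     region          1..1200
                     /product="NRPS"
                     /contig_edge="False"
     CDS             1..300
                     /locus_tag="geneA"
                     /product="alpha"
     CDS             complement(401..700)
                     /locus_tag="geneB"
                     /product="beta"
     CDS             801..1100
                     /locus_tag="geneC"
ORIGIN
""" + "\n".join(
    f"{i * 60 + 1:>9} " + " ".join(["acgtacgtac"] * 6) for i in range(20)
) + "\n//\n"


#: GenBank record whose feature table has no CDS at all.
NO_CDS_GBK = """\
LOCUS       EMPTY001                 600 bp    DNA     linear   BCT 01-JAN-2024
DEFINITION  featureless record.
ACCESSION   EMPTY001
FEATURES             Location/Qualifiers
     region          1..600
                     /product="terpene"
ORIGIN
""" + "\n".join(
    f"{i * 60 + 1:>9} " + " ".join(["acgtacgtac"] * 6) for i in range(10)
) + "\n//\n"


@pytest.fixture
def fixture_gbk(tmp_path):
    path = tmp_path / "fixture.gbk"
    path.write_text(FIXTURE_GBK)
    return path


@pytest.fixture
def no_cds_gbk(tmp_path):
    path = tmp_path / "no_cds.gbk"
    path.write_text(NO_CDS_GBK)
    return path
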