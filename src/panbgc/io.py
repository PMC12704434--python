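"""Reading and writing the formats the framework touches.

GenBank records (antiSMASH "region" dialect or MIBiG dialect) are parsed
into :class:`~panbgc.model.BGCRecord` objects via Biopython. Coordinates are
converted at this boundary from GenBank 1-based inclusive to the internal
0-based half-open convention. Ortholog assignments travel as a three-column
TSV (``og_id  bgc_id  gene_id``); analysis results as a structured JSON
document; the presence–absence matrix as CSV; reconstructed clusters as
protein FASTA.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .exceptions import (
    ConflictError,
    EmptyRecordError,
    FormatError,
    IncompleteAssignmentError,
    UnknownGeneError,
)
from .model import GCF, BGCRecord, Gene

# Feature keys whose ``product`` qualifiers carry BGC class labels.
# "region"/"cand_cluster"/"protocluster" are the antiSMASH dialect;
# "cluster" is the legacy/MIBiG dialect.
_CLASS_FEATURES = ("region", "cand_cluster", "protocluster", "cluster")


def _record_sequence(record: SeqRecord) -> Optional[str]:
    """Return the nucleotide sequence as a string, or None if undefined."""
    try:
        seq = str(record.seq)
    except Exception:
        return None
    if not seq or set(seq.upper()) <= {"N"}:
        return None
    return seq


def _conceptual_translation(seq: str, start: int, end: int, strand: int) -> Optional[str]:
    """Translate a nucleotide span; used when a CDS lacks a translation
    qualifier. Trailing stop is stripped; internal stops disqualify."""
    sub = Seq(seq[start:end])
    if strand == -1:
        sub = sub.reverse_complement()
    if len(sub) < 3:
        return None
    sub = sub[: len(sub) - len(sub) % 3]
    aa = str(sub.translate(table=1))
    if aa.endswith("*"):
        aa = aa[:-1]
    if not aa or "*" in aa:
        return None
    return aa


def read_region_genbank(path: str | Path, dialect: str = "auto") -> BGCRecord:
    """Parse one BGC from a GenBank file.

    Parameters
    ----------
    path:
        GenBank flat file with at least one record; if the file holds
        several records only the first is read.
    dialect:
        ``auto``, ``antismash`` or ``mibig``. Affects only the ``source``
        tag on the returned record; class labels and contig-edge flags are
        harvested from whichever qualifiers are present.

    Returns
    -------
    BGCRecord
        CDS features become genes with 0-based half-open coordinates;
        compound (join) locations are collapsed to their min/max envelope.
    """
    if dialect not in ("auto", "antismash", "mibig"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises ValueError with line info
        raise FormatError(f"{path}: not parseable as GenBank: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no GenBank records found")
    record = records[0]

    bgc_id = record.name or record.id or path.stem
    if not bgc_id or bgc_id == "<unknown name>":
        bgc_id = path.stem

    classes: list[str] = []
    contig_edge = False
    saw_region = False
    for feature in record.features:
        if feature.type in _CLASS_FEATURES:
            if feature.type == "region":
                saw_region = True
            for label in feature.qualifiers.get("product", []):
                if label and label not in classes:
                    classes.append(label)
            edge = feature.qualifiers.get("contig_edge", ["False"])[0]
            if str(edge).lower() == "true":
                contig_edge = True

    if dialect == "auto":
        source = "antismash" if saw_region else "mibig"
    else:
        source = dialect

    nt_seq = _record_sequence(record)

    cds = [f for f in record.features if f.type == "CDS"]
    if not cds:
        raise EmptyRecordError(f"{path}: record {bgc_id} has no CDS features")

    raw = []
    for feature in cds:
        start = int(feature.location.start)  # Biopython is already 0-based half-open
        end = int(feature.location.end)
        strand = -1 if feature.location.strand == -1 else 1
        locus = feature.qualifiers.get("locus_tag", [None])[0]
        protein = feature.qualifiers.get("translation", [None])[0]
        if protein is None and nt_seq is not None:
            protein = _conceptual_translation(nt_seq, start, end, strand)
        product = feature.qualifiers.get("product", [None])[0]
        raw.append((start, end, locus, strand, protein, product))

    raw.sort(key=lambda r: (r[0], r[1], r[2] or ""))
    genes = []
    for ordinal, (start, end, locus, strand, protein, product) in enumerate(raw, 1):
        gene_id = locus if locus else f"{bgc_id}_g{ordinal}"
        genes.append(
            Gene(
                gene_id=gene_id,
                bgc_id=bgc_id,
                start=start,
                end=end,
                strand=strand,
                protein=protein,
                product=product,
            )
        )
    return BGCRecord(
        bgc_id=bgc_id,
        genes=genes,
        source=source,
        bgc_class=classes,
        contig_edge=contig_edge,
    )


def write_region_genbank(
    bgc: BGCRecord, path: str | Path, sequence: Optional[str] = None
) -> None:
    """Write a BGC back to a GenBank flat file.

    Coordinates are converted from internal 0-based half-open back to
    GenBank convention by Biopython. When ``sequence`` is omitted an
    N-filled placeholder of the right length is emitted.
    """
    length = max(g.end for g in bgc.genes)
    if sequence is None:
        sequence = "N" * length
    if len(sequence) < length:
        raise ValueError("sequence shorter than last gene end")
    record = SeqRecord(
        Seq(sequence),
        id=bgc.bgc_id,
        name=bgc.bgc_id[:37],
        description=f"panbgc export of {bgc.bgc_id}",
    )
    record.annotations["molecule_type"] = "DNA"
    region_qualifiers = {
        "product": list(bgc.bgc_class),
        "contig_edge": [str(bgc.contig_edge)],
    }
    record.features.append(
        SeqFeature(
            SimpleLocation(0, len(sequence), strand=1),
            type="region",
            qualifiers=region_qualifiers,
        )
    )
    for gene in bgc.genes:
        qualifiers: dict[str, list[str]] = {"locus_tag": [gene.gene_id]}
        if gene.protein is not None:
            qualifiers["translation"] = [gene.protein]
        if gene.product is not None:
            qualifiers["product"] = [gene.product]
        record.features.append(
            SeqFeature(
                SimpleLocation(gene.start, gene.end, strand=gene.strand),
                type="CDS",
                qualifiers=qualifiers,
            )
        )
    SeqIO.write([record], str(path), "genbank")


def read_gcf_directory(directory: str | Path, gcf_id: Optional[str] = None) -> GCF:
    """Read every GenBank file (``*.gbk``/``*.gb``/``*.gbff``) in a
    directory into one GCF, sorted by filename for determinism."""
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in (".gbk", ".gb", ".gbff")
    )
    if not paths:
        raise FormatError(f"{directory}: no GenBank files found")
    members = [read_region_genbank(p) for p in paths]
    return GCF(gcf_id=gcf_id or directory.name, members=members)


# ---------------------------------------------------------------------------
# Ortholog table TSV


def read_ortholog_table(path: str | Path, gcf: GCF) -> GCF:
    """Apply an external ortholog assignment (ZOL-style TSV) to a family.

    The file is tab-separated with header columns ``og_id``, ``bgc_id``,
    ``gene_id``; lines starting with ``#`` are ignored. The assignment must
    be total (cover every gene) and single-valued.
    """
    path = Path(path)
    known = {(g.bgc_id, g.gene_id): g for g in gcf.genes()}
    seen: dict[tuple[str, str], str] = {}
    with open(path) as handle:
        header = None
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                required = {"og_id", "bgc_id", "gene_id"}
                if not required <= set(header):
                    raise FormatError(
                        f"{path}:{lineno}: header must contain og_id, bgc_id, gene_id"
                    )
                idx = {name: header.index(name) for name in required}
                continue
            try:
                og_id = fields[idx["og_id"]]
                bgc_id = fields[idx["bgc_id"]]
                gene_id = fields[idx["gene_id"]]
            except IndexError:
                raise FormatError(f"{path}:{lineno}: expected 3 tab-separated fields")
            key = (bgc_id, gene_id)
            if key not in known:
                raise UnknownGeneError(
                    f"{path}:{lineno}: gene {gene_id} of BGC {bgc_id} not in GCF {gcf.gcf_id}"
                )
            if key in seen and seen[key] != og_id:
                raise ConflictError(
                    f"{path}:{lineno}: gene {gene_id} of BGC {bgc_id} assigned to both "
                    f"{seen[key]} and {og_id}"
                )
            seen[key] = og_id
    missing = [f"{b}/{g}" for (b, g) in known if (b, g) not in seen]
    if missing:
        raise IncompleteAssignmentError(missing)
    for key, gene in known.items():
        gene.og_id = seen[key]
    return gcf


def write_ortholog_table(gcf: GCF, path: str | Path) -> None:
    """Write the family's assignment in the TSV dialect read back by
    :func:`read_ortholog_table`."""
    missing = gcf.unassigned_genes()
    if missing:
        raise IncompleteAssignmentError(missing)
    with open(path, "w") as handle:
        handle.write("og_id\tbgc_id\tgene_id\n")
        for gene in gcf.genes():
            handle.write(f"{gene.og_id}\t{gene.bgc_id}\t{gene.gene_id}\n")


# ---------------------------------------------------------------------------
# Presence–absence CSV


def write_presence_absence_csv(matrix, path: str | Path) -> None:
    """First column ``bgc_id``, remaining columns og ids, integer cells."""
    frame = pd.DataFrame(matrix.counts, index=matrix.bgc_ids, columns=matrix.og_ids)
    frame.index.name = "bgc_id"
    frame.to_csv(path)


def read_presence_absence_csv(path: str | Path):
    from .pangenome import PresenceAbsenceMatrix

    frame = pd.read_csv(path, index_col="bgc_id")
    return PresenceAbsenceMatrix(
        bgc_ids=[str(i) for i in frame.index],
        og_ids=[str(c) for c in frame.columns],
        counts=frame.to_numpy(dtype=int),
    )


# ---------------------------------------------------------------------------
# Summary JSON


def write_gcf_json(summary: dict, path: str | Path) -> None:
    """Serialize an analysis bundle (see :func:`panbgc.analysis.summarize_gcf`)
    to JSON. Re-reading reproduces every field bit-exactly."""
    try:
        text = json.dumps(summary, indent=2, ensure_ascii=False, allow_nan=False)
    except (TypeError, ValueError) as exc:
        raise PanbgcInternalError(f"summary bundle not serializable: {exc}") from exc
    Path(path).write_text(text + "\n")


class PanbgcInternalError(RuntimeError):
    """Bug surface: an analysis bundle that cannot be serialized."""


def read_gcf_json(path: str | Path) -> dict:
    with open(path) as handle:
        return json.load(handle)


# ---------------------------------------------------------------------------
# Protein FASTA export of reconstructed BGCs


def write_reconstruction_fasta(gcf: GCF, reconstruction, path: str | Path) -> None:
    """Write one representative protein per OG of a reconstructed cluster.

    The representative is the first assigned copy in member order; headers
    are ``>og_id category mean_length=<residues>``.
    """
    representative: dict[str, str] = {}
    for gene in gcf.genes():
        if gene.og_id is not None and gene.protein and gene.og_id not in representative:
            representative[gene.og_id] = gene.protein
    records = []
    for entry in reconstruction:
        og_id, category, mean_length = entry.og_id, entry.category, entry.mean_length
        protein = representative.get(og_id)
        if protein is None:
            continue
        desc = f"{category} mean_length={mean_length:.1f}" if mean_length else category
        records.append(SeqRecord(Seq(protein), id=og_id, description=desc))
    SeqIO.write(records, str(path), "fasta")
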