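"""Readers and writers for FASTA, GFF3 and TSV plus CDS translation.

All coordinates held in memory are 0-based half-open.  The GFF3 boundary is
the single place where the 1-based inclusive convention of the format is
converted; nothing else in the package ever adds or subtracts one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from ._iupac import NUCLEOTIDE_LETTERS, reverse_complement

_PROTEIN_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWYXBZJUO*")


@dataclass
class SeqRecord:
    """A named ungapped sequence.

    ``alphabet`` is either ``"nucleotide"`` or ``"protein"``.  Gap characters
    are rejected: gaps only exist inside alignments, never in records.
    """

    id: str
    residues: str
    description: str = ""
    alphabet: str = "nucleotide"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        if any(ch.isspace() for ch in self.id) or not self.id:
            raise ValueError(f"record id {self.id!r} is empty or contains whitespace")
        if self.alphabet not in ("nucleotide", "protein"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        letters = NUCLEOTIDE_LETTERS if self.alphabet == "nucleotide" else _PROTEIN_LETTERS
        bad = set(self.residues) - letters
        if bad:
            raise ValueError(
                f"record {self.id!r} contains characters invalid for "
                f"{self.alphabet} sequence: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "SeqRecord":
        if self.alphabet != "nucleotide":
            raise ValueError("reverse_complement requires a nucleotide record")
        return SeqRecord(self.id, reverse_complement(self.residues),
                         self.description, self.alphabet)


@dataclass
class GeneModel:
    """A gene (or CDS) on a parent sequence; 0-based half-open coordinates."""

    gene_id: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"gene {self.gene_id!r}: invalid interval "
                             f"[{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: unknown strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ClusterAnnotation:
    """Ordered gene models on one sequence."""

    seq_id: str
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))
        ids = [g.gene_id for g in self.genes]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene ids in annotation {self.seq_id!r}: {dup}")


def read_fasta(path: str | Path, alphabet: str = "nucleotide") -> list[SeqRecord]:
    """Read a FASTA file into a list of :class:`SeqRecord`.

    Residues are uppercased and line breaks removed; record order is
    preserved.  An empty file raises ``ValueError("no records")``.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"record {rec.id!r} has an empty sequence")
        records.append(SeqRecord(rec.id, seq, rec.description, alphabet))
    if not records:
        raise ValueError(f"no records in {path}")
    return records


def write_fasta(records: list[SeqRecord], path: str | Path, wrap: int = 70) -> None:
    """Write records to FASTA with lines wrapped at ``wrap`` characters."""
    if wrap < 1:
        raise ValueError("wrap must be >= 1")
    if not records:
        raise ValueError("refusing to write an empty FASTA file")
    ids = [r.id for r in records]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate record ids")
    with open(path, "w") as fh:
        writer = FastaWriter(fh, wrap=wrap)
        for r in records:
            desc = r.description if r.description != r.id else ""
            writer.write_record(_BioSeqRecord(Seq(r.residues), id=r.id, description=desc))


def read_gff3(path: str | Path,
              feature_types: tuple[str, ...] = ("gene", "CDS")) -> list[ClusterAnnotation]:
    """Parse gene/CDS features (or any requested types) from a GFF3 file.

    Coordinates are converted from the 1-based inclusive convention of the
    format to 0-based half-open.  Features are grouped by seqid and sorted by
    start.  When both a ``gene`` and ``CDS`` row carry the same identifier,
    the CDS extent wins (translation must use coding coordinates); multiple
    CDS rows with one identifier are unioned into a single extent.
    """
    genes: dict[str, dict[str, GeneModel]] = {}
    cds_seen: dict[tuple[str, str], bool] = {}
    auto = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
            if ftype not in feature_types:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end1 < start1:
                raise ValueError(f"{path}:{lineno}: end ({end1}) < start ({start1})")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            gid = attr.get("ID") or attr.get("Parent")
            if gid is None:
                auto += 1
                gid = f"feature{auto}"
            start, end = start1 - 1, end1
            bucket = genes.setdefault(seqid, {})
            key = (seqid, gid)
            is_cds = ftype == "CDS"
            if gid in bucket:
                prev = bucket[gid]
                if is_cds and cds_seen.get(key):
                    bucket[gid] = GeneModel(gid, min(prev.start, start),
                                            max(prev.end, end), strand, prev.product)
                elif is_cds:
                    bucket[gid] = GeneModel(gid, start, end, strand,
                                            attr.get("product", prev.product))
                # gene row after CDS row: CDS extent already wins, keep it
            else:
                bucket[gid] = GeneModel(gid, start, end, strand, attr.get("product", ""))
            if is_cds:
                cds_seen[key] = True
    return [ClusterAnnotation(seqid, list(models.values()))
            for seqid, models in genes.items()]


def write_gff3(annotation: ClusterAnnotation, path: str | Path,
               feature_type: str = "gene", source: str = "clusterscope") -> None:
    """Emit an annotation as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation.genes:
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write("\t".join([
                annotation.seq_id, source, feature_type,
                str(g.start + 1), str(g.end), ".", g.strand, ".", attrs,
            ]) + "\n")


def translate_cds(record: SeqRecord, gene: GeneModel) -> SeqRecord:
    """Translate a gene's coding sequence with the standard genetic code.

    Minus-strand genes are reverse-complemented first.  A trailing stop codon
    is dropped; an internal stop raises a warning and truncates the protein.
    """
    if record.alphabet != "nucleotide":
        raise ValueError("translate_cds requires a nucleotide record")
    if gene.end > len(record.residues):
        raise ValueError(f"gene {gene.gene_id!r} extends past the end of {record.id!r}")
    cds = record.residues[gene.start:gene.end]
    if gene.strand == "-":
        cds = reverse_complement(cds)
    if len(cds) % 3 != 0:
        raise ValueError(f"gene {gene.gene_id!r}: CDS length {len(cds)} "
                         "is not divisible by 3")
    protein = str(Seq(cds).translate(table=1))
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        warnings.warn(f"gene {gene.gene_id!r}: internal stop codon; "
                      "translation truncated", stacklevel=2)
        protein = protein.split("*", 1)[0]
    if not protein:
        raise ValueError(f"gene {gene.gene_id!r}: empty translation")
    return SeqRecord(gene.gene_id, protein, gene.product, "protein")
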