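"""Ortholog mapping, collinearity checks and identity matrices for clusters.

Orthology is reciprocal best hit by global protein identity — clusters carry
on the order of a dozen genes, so all-vs-all global alignment is cheap and
fully deterministic, with no external search dependency.  Protein percent
identity uses the ``exclude_gap_columns`` policy, the convention for
published per-protein identity tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .align_core import global_align_aa, percent_identity
from .formats_io import ClusterAnnotation, SeqRecord, translate_cds

PROTEIN_IDENTITY_POLICY = "exclude_gap_columns"


@dataclass
class AnnotatedCluster:
    """A cluster's proteins plus (optionally) the gene layout they came from."""

    id: str
    proteins: list[SeqRecord]
    annotation: ClusterAnnotation | None = None

    @classmethod
    def from_sequence(cls, record: SeqRecord, annotation: ClusterAnnotation,
                      cluster_id: str | None = None) -> "AnnotatedCluster":
        """Translate every annotated gene; untranslatable genes are dropped
        with a warning rather than aborting the whole comparison."""
        proteins = []
        for gene in annotation.genes:
            try:
                proteins.append(translate_cds(record, gene))
            except ValueError as exc:
                warnings.warn(f"skipping gene {gene.gene_id!r}: {exc}", stacklevel=2)
        return cls(cluster_id or record.id, proteins, annotation)

    def protein(self, gene_id: str) -> SeqRecord:
        for p in self.proteins:
            if p.id == gene_id:
                return p
        raise KeyError(gene_id)


@dataclass
class OrthologPair:
    gene_a: str
    gene_b: str
    identity: float
    matches: int = 0
    aligned_columns: int = 0


@dataclass
class OrthologTable:
    cluster_a: str
    cluster_b: str
    pairs: list[OrthologPair]
    unpaired_a: list[str] = field(default_factory=list)
    unpaired_b: list[str] = field(default_factory=list)

    def pair_for_a(self, gene_a: str) -> OrthologPair | None:
        for p in self.pairs:
            if p.gene_a == gene_a:
                return p
        return None

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_a\tgene_b\tidentity\n")
            for p in self.pairs:
                fh.write(f"{p.gene_a}\t{p.gene_b}\t{p.identity:.4f}\n")
            for g in self.unpaired_a:
                fh.write(f"{g}\t.\t.\n")
            for g in self.unpaired_b:
                fh.write(f".\t{g}\t.\n")


@dataclass
class CollinearityReport:
    collinear: bool
    order_b_given_a: list[int]
    breakpoints: int
    orientation: str = "forward"

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("collinear\tbreakpoints\torientation\torder_b_given_a\n")
            order = ",".join(map(str, self.order_b_given_a))
            fh.write(f"{self.collinear}\t{self.breakpoints}\t{self.orientation}\t{order}\n")


def _identity_counts(aln) -> tuple[int, int]:
    """(matching columns, gap-free columns) of a protein alignment."""
    av = np.frombuffer(aln.a_gapped.encode(), dtype=np.uint8)
    bv = np.frombuffer(aln.b_gapped.encode(), dtype=np.uint8)
    aligned = (av != ord("-")) & (bv != ord("-"))
    return int((aligned & (av == bv)).sum()), int(aligned.sum())


def map_orthologs(a: AnnotatedCluster, b: AnnotatedCluster,
                  min_identity: float = 0.30) -> OrthologTable:
    """Pair genes between two clusters by reciprocal best protein identity."""
    if not a.proteins or not b.proteins:
        raise ValueError("both clusters need at least one translatable gene")
    na, nb = len(a.proteins), len(b.proteins)
    ident = np.zeros((na, nb))
    counts = {}
    for i, pa in enumerate(a.proteins):
        for j, pb in enumerate(b.proteins):
            aln = global_align_aa(pa, pb)
            m, cols = _identity_counts(aln)
            ident[i, j] = m / cols if cols else 0.0
            counts[i, j] = (m, cols)
    best_b = ident.argmax(axis=1)
    best_a = ident.argmax(axis=0)
    pairs = []
    paired_a, paired_b = set(), set()
    for i in range(na):
        j = int(best_b[i])
        if int(best_a[j]) == i and ident[i, j] >= min_identity:
            m, cols = counts[i, j]
            pairs.append(OrthologPair(a.proteins[i].id, b.proteins[j].id,
                                      ident[i, j], m, cols))
            paired_a.add(i)
            paired_b.add(j)
    return OrthologTable(
        a.id, b.id, pairs,
        unpaired_a=[a.proteins[i].id for i in range(na) if i not in paired_a],
        unpaired_b=[b.proteins[j].id for j in range(nb) if j not in paired_b],
    )


def check_collinearity(table: OrthologTable, a: ClusterAnnotation,
                       b: ClusterAnnotation) -> CollinearityReport:
    """Is the gene order of the ortholog pairs conserved?

    Pairs are ordered by gene start in A; the sequence of B-ranks is
    orientation-normalized (whole-cluster strand flips are not breakpoints)
    and the number of adjacent rank descents is reported.
    """
    if len(table.pairs) < 2:
        raise ValueError("insufficient pairs for a collinearity check")
    a_start = {g.gene_id: g.start for g in a.genes}
    b_start = {g.gene_id: g.start for g in b.genes}
    ordered = sorted(table.pairs, key=lambda p: a_start[p.gene_a])
    b_sorted = sorted(ordered, key=lambda p: b_start[p.gene_b])
    rank_of = {p.gene_b: r + 1 for r, p in enumerate(b_sorted)}
    ranks = [rank_of[p.gene_b] for p in ordered]
    fwd = sum(1 for x, y in zip(ranks, ranks[1:]) if y < x)
    rev = sum(1 for x, y in zip(ranks, ranks[1:]) if y > x)
    if rev < fwd:
        breakpoints, orientation = rev, "reversed"
    else:
        breakpoints, orientation = fwd, "forward"
    return CollinearityReport(breakpoints == 0, ranks, breakpoints, orientation)


def identity_matrix(clusters: list[AnnotatedCluster], reference_cluster: str,
                    min_identity: float = 0.30) -> pd.DataFrame:
    """Reference-protein x cluster matrix of ortholog identities (fractions).

    Cells are NaN (rendered as ``absent``) when the reference protein has no
    reciprocal best hit in that cluster.
    """
    ref = next((c for c in clusters if c.id == reference_cluster), None)
    if ref is None:
        raise ValueError(f"reference cluster {reference_cluster!r} not in input")
    rows = [p.id for p in ref.proteins]
    out = pd.DataFrame(index=rows, columns=[c.id for c in clusters], dtype=float)
    for c in clusters:
        if c.id == ref.id:
            out[c.id] = 1.0
            continue
        table = map_orthologs(ref, c, min_identity)
        lookup = {p.gene_a: p.identity for p in table.pairs}
        out[c.id] = [lookup.get(r, np.nan) for r in rows]
    return out


def overall_identity(clusters: list[AnnotatedCluster],
                     min_identity: float = 0.30) -> pd.DataFrame:
    """Cluster x cluster identity over concatenated per-ortholog alignments.

    Only proteins with an ortholog in *every* cluster enter the concatenation
    (per-pair common proteins are deliberately not used).  Identity is the
    pooled ``matches / gap-free columns`` over the concatenated alignment,
    which equals the column-count-weighted mean of per-protein identities.
    The matrix is symmetric with a unit diagonal.
    """
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    anchor = clusters[0]
    others = clusters[1:]
    tables = {c.id: map_orthologs(anchor, c, min_identity) for c in others}
    common = [p.id for p in anchor.proteins
              if all(tables[c.id].pair_for_a(p.id) for c in others)]
    if not common:
        raise ValueError("no protein occurs in all clusters")

    partner = {anchor.id: {g: g for g in common}}
    for c in others:
        partner[c.id] = {g: tables[c.id].pair_for_a(g).gene_b for g in common}

    ids = [c.id for c in clusters]
    by_id = {c.id: c for c in clusters}
    out = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
    for i, ci in enumerate(ids):
        for cj in ids[i + 1:]:
            matches = cols = 0
            for g in common:
                pa = by_id[ci].protein(partner[ci][g])
                pb = by_id[cj].protein(partner[cj][g])
                m, n = _identity_counts(global_align_aa(pa, pb))
                matches += m
                cols += n
            value = matches / cols
            out.loc[ci, cj] = value
            out.loc[cj, ci] = value
    return out


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write an identity matrix as TSV with percent values to one decimal;
    missing orthologs are written as ``absent``."""
    formatted = matrix.map(
        lambda v: "absent" if pd.isna(v) else f"{100.0 * v:.1f}")
    formatted.to_csv(path, sep="\t", index_label="protein")
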