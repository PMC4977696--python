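"""Ground-truth generators: cluster genomes, diverged strains, split contigs,
marker panels and planted-site fixtures.

Every generator takes an explicit seed (no global randomness) and returns a
:class:`SimulationTruth` describing exactly what was planted, so downstream
stages can be checked against known answers.  Substitutions are uniform over
the three alternative bases; flanks are independent uniform-random sequence,
which aligns at roughly the 30 % windowed identity expected for unrelated
DNA.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ._iupac import AMBIGUITY_FOR_BASE, reverse_complement
from .align_core import PairwiseAlignment
from .formats_io import (ClusterAnnotation, GeneModel, SeqRecord, write_fasta,
                         write_gff3)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                 if a + b + c not in _STOPS]


@dataclass
class SimulationTruth:
    """What a generator planted, in parent-sequence coordinates."""

    seed: int
    core_interval: tuple[int, int] | None = None
    planted_core_identity: float | None = None
    realized_core_identity: float | None = None
    overlap_len: int | None = None
    overlap_identity: float | None = None
    realized_overlap_identity: float | None = None
    junction: int | None = None
    substitution_positions: list[int] = field(default_factory=list)
    ambiguity_positions: list[int] = field(default_factory=list)
    gap_columns: list[int] = field(default_factory=list)
    indel_events: list[tuple[int, int, str]] = field(default_factory=list)
    diagnostic_columns: list[int] = field(default_factory=list)
    ortholog_map: list[tuple[str, str]] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return _jsonable(asdict(self))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _random_orf(rng: np.random.Generator, length: int) -> str:
    """An ORF of ``length`` bases: start codon, sense codons, one stop."""
    if length % 3 or length < 9:
        raise ValueError("ORF length must be a multiple of 3 and >= 9")
    n_codons = length // 3 - 2
    idx = rng.integers(0, len(_SENSE_CODONS), n_codons)
    return "ATG" + "".join(_SENSE_CODONS[i] for i in idx) + "TAA"


def generate_cluster_genome(n_genes: int = 12,
                            gene_len_range: tuple[int, int] = (900, 3000),
                            nrps_len_range: tuple[int, int] = (20400, 21600),
                            intergenic_len_range: tuple[int, int] = (200, 1500),
                            flank_len: int = 5000, seed: int = 0,
                            name: str = "cluster"):
    """A synthetic gene cluster: ORFs on random strands inside a gene-bearing
    core, flanked by unrelated random sequence.

    One gene is NRPS-like (~21 kb) so that the extreme gene-length
    heterogeneity of real clusters is represented.  Defaults put the core in
    the 45-60 kb range.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    lo, hi = gene_len_range
    if not (9 <= lo <= hi):
        raise ValueError("impossible gene length constraints")
    rng = np.random.default_rng(seed)
    nrps_idx = int(rng.integers(0, n_genes))
    lengths = []
    for i in range(n_genes):
        rlo, rhi = nrps_len_range if i == nrps_idx else gene_len_range
        lengths.append(int(rng.integers(rlo, rhi + 1)) // 3 * 3)
    strands = [("+", "-")[rng.integers(0, 2)] for _ in range(n_genes)]

    pieces = [random_dna(rng, flank_len)]
    pos = flank_len
    genes = []
    for i, (length, strand) in enumerate(zip(lengths, strands)):
        orf = _random_orf(rng, length)
        if strand == "-":
            orf = reverse_complement(orf)
        product = "nrps-like" if i == nrps_idx else f"protein {i + 1}"
        genes.append(GeneModel(f"gene{i + 1:02d}", pos, pos + length, strand, product))
        pieces.append(orf)
        pos += length
        if i < n_genes - 1:
            gap = int(rng.integers(*intergenic_len_range))
            pieces.append(random_dna(rng, gap))
            pos += gap
    core_end = pos
    pieces.append(random_dna(rng, flank_len))
    record = SeqRecord(name, "".join(pieces))
    annotation = ClusterAnnotation(name, genes)
    truth = SimulationTruth(seed=seed, core_interval=(flank_len, core_end),
                            extras={"n_genes": n_genes, "nrps_gene": f"gene{nrps_idx + 1:02d}",
                                    "core_length": core_end - flank_len})
    return record, annotation, truth


def _cds_arrays(annotation: ClusterAnnotation | None, n: int, pad: int = 3):
    """Boolean CDS membership (padded) and per-position gene index (-1 outside)."""
    in_cds = np.zeros(n, dtype=bool)
    gene_at = np.full(n, -1, dtype=np.int64)
    if annotation is not None:
        for gi, g in enumerate(annotation.genes):
            lo, hi = max(0, g.start - pad), min(n, g.end + pad)
            in_cds[lo:hi] = True
            gene_at[max(0, g.start):min(n, g.end)] = gi
    return in_cds, gene_at


def _creates_stop(seq: bytearray, pos: int, new_base: str, gene: GeneModel) -> bool:
    """Would substituting ``new_base`` at ``pos`` put a stop codon in frame?"""
    if gene.strand == "+":
        codon_start = gene.start + (pos - gene.start) // 3 * 3
        codon = bytearray(seq[codon_start:codon_start + 3])
        codon[pos - codon_start] = ord(new_base)
        return codon.decode() in _STOPS
    offset = (gene.end - 1 - pos) // 3
    codon_start = gene.end - 3 * (offset + 1)
    codon = bytearray(seq[codon_start:codon_start + 3])
    codon[pos - codon_start] = ord(new_base)
    return reverse_complement(codon.decode()) in _STOPS


def evolve_sequence(record: SeqRecord, sub_rate: float = 0.0,
                    indel_rate: float = 0.0, indel_len_geometric_p: float = 0.5,
                    ambiguity_rate: float = 0.0, protect_orfs: bool = False,
                    annotation: ClusterAnnotation | None = None, seed: int = 0,
                    name: str | None = None):
    """Mutate a sequence with per-site substitutions, indels and ambiguities.

    Substitutions are Bernoulli per site, uniform over the three alternative
    bases; indels are seeded per site with geometric lengths (insertion or
    deletion with equal probability); ambiguity injection replaces a base by
    a compatible two-base IUPAC code.  With ``protect_orfs`` (requires
    ``annotation``) indels and ambiguities are kept out of CDS regions and
    substitutions never create an in-frame stop or touch a start/stop codon,
    so every annotated ORF stays translatable.

    Returns ``(child record, SimulationTruth)``; all event positions are in
    parent coordinates.
    """
    for r in (sub_rate, indel_rate, ambiguity_rate):
        if not 0.0 <= r < 1.0:
            raise ValueError("rates must be in [0, 1)")
    if sub_rate + indel_rate + ambiguity_rate >= 0.5:
        raise ValueError("total mutation rate must be < 0.5")
    if protect_orfs and annotation is None:
        raise ValueError("protect_orfs requires an annotation")
    rng = np.random.default_rng(seed)
    n = len(record.residues)
    seq = bytearray(record.residues.encode())
    in_cds, gene_at = _cds_arrays(annotation if protect_orfs else None, n)

    u = rng.random(n)
    sub_sites = np.flatnonzero(u < sub_rate)
    amb_sites = np.flatnonzero((u >= sub_rate) & (u < sub_rate + ambiguity_rate))
    indel_sites = np.flatnonzero((u >= sub_rate + ambiguity_rate)
                                 & (u < sub_rate + ambiguity_rate + indel_rate))

    applied_subs = []
    for pos in sub_sites:
        pos = int(pos)
        old = chr(seq[pos])
        if old not in "ACGT":
            continue
        new = "ACGT".replace(old, "")[rng.integers(0, 3)]
        gi = gene_at[pos]
        if protect_orfs and gi >= 0:
            g = annotation.genes[gi]
            if pos < g.start + 3 or pos >= g.end - 3:
                continue
            if _creates_stop(seq, pos, new, g):
                continue
        seq[pos] = ord(new)
        applied_subs.append(pos)

    applied_ambig = []
    for pos in amb_sites:
        pos = int(pos)
        old = chr(seq[pos])
        if old not in "ACGT" or (protect_orfs and in_cds[pos]):
            continue
        codes = AMBIGUITY_FOR_BASE[old]
        seq[pos] = ord(codes[rng.integers(0, len(codes))])
        applied_ambig.append(pos)

    events = []  # (parent_pos, length, kind)
    for pos in indel_sites:
        pos = int(pos)
        length = int(rng.geometric(indel_len_geometric_p))
        insertion = bool(rng.integers(0, 2))
        if insertion:
            if protect_orfs and in_cds[pos]:
                continue
            events.append((pos, length, "ins"))
        else:
            if protect_orfs and in_cds[pos:min(n, pos + length)].any():
                continue
            events.append((pos, min(length, n - pos), "del"))

    events.sort()
    out = []
    cursor = 0
    for pos, length, kind in events:
        if pos < cursor:
            continue  # swallowed by a previous deletion
        out.append(bytes(seq[cursor:pos]).decode())
        if kind == "ins":
            out.append(random_dna(rng, length))
            cursor = pos
        else:
            cursor = pos + length
    out.append(bytes(seq[cursor:]).decode())
    child_residues = "".join(out)

    child = SeqRecord(name or f"{record.id}_evolved", child_residues)
    truth = SimulationTruth(
        seed=seed,
        substitution_positions=applied_subs,
        ambiguity_positions=applied_ambig,
        indel_events=events,
        realized_core_identity=1.0 - len(applied_subs) / n,
        extras={"parent_length": n, "child_length": len(child_residues)},
    )
    return child, truth


def lift_positions(truth: SimulationTruth, positions) -> np.ndarray:
    """Map parent coordinates through the indel events of an evolution run."""
    positions = np.asarray(positions, dtype=np.int64)
    shift = np.zeros_like(positions)
    for pos, length, kind in truth.indel_events:
        if kind == "ins":
            shift = shift + np.where(positions >= pos, length, 0)
        else:
            inside = (positions >= pos) & (positions < pos + length)
            after = positions >= pos + length
            shift = shift - np.where(after, length, 0) - np.where(
                inside, positions - pos, 0)
    return positions + shift


def lift_annotation(annotation: ClusterAnnotation, truth: SimulationTruth,
                    seq_id: str, offset: int = 0) -> ClusterAnnotation:
    """Annotation coordinates after an evolution run, plus a constant offset."""
    starts = lift_positions(truth, [g.start for g in annotation.genes]) + offset
    ends = lift_positions(truth, [g.end for g in annotation.genes]) + offset
    genes = [GeneModel(g.gene_id, int(s), int(e), g.strand, g.product)
             for g, s, e in zip(annotation.genes, starts, ends)]
    return ClusterAnnotation(seq_id, genes)


def split_with_overlap(record: SeqRecord, junction: int, overlap_len: int = 400,
                       overlap_divergence: float = 0.04, seed: int = 0):
    """Split a sequence into two contigs sharing a terminal overlap.

    ``left`` ends with the overlap region; ``right`` begins with an
    independently substituted copy of it (divergence = substitution rate),
    emulating the same locus sequenced twice in two contigs.
    """
    n = len(record.residues)
    if not overlap_len < junction < n - overlap_len:
        raise ValueError("junction must leave overlap_len clearance on both sides")
    rng = np.random.default_rng(seed)
    left = SeqRecord(f"{record.id}_left", record.residues[:junction + overlap_len])
    shared = bytearray(record.residues[junction:junction + overlap_len].encode())
    n_subs = 0
    for pos in np.flatnonzero(rng.random(overlap_len) < overlap_divergence):
        old = chr(shared[pos])
        if old not in "ACGT":
            continue
        shared[pos] = ord("ACGT".replace(old, "")[rng.integers(0, 3)])
        n_subs += 1
    right = SeqRecord(f"{record.id}_right",
                      shared.decode() + record.residues[junction + overlap_len:])
    truth = SimulationTruth(
        seed=seed, junction=junction, overlap_len=overlap_len,
        overlap_identity=1.0 - overlap_divergence,
        realized_overlap_identity=1.0 - n_subs / overlap_len,
        extras={"overlap_in_left": (junction, junction + overlap_len),
                "overlap_in_right": (0, overlap_len)},
    )
    return left, right, truth


def _spaced_positions(rng: np.random.Generator, lo: int, hi: int, n: int,
                      min_separation: int) -> list[int]:
    """n positions in [lo, hi) pairwise separated by >= min_separation."""
    span = (hi - lo) // n
    if span <= min_separation:
        raise ValueError("region too small for the requested separation")
    positions = []
    for k in range(n):
        slot_lo = lo + k * span + min_separation // 2
        slot_hi = lo + (k + 1) * span - min_separation // 2
        positions.append(int(rng.integers(slot_lo, slot_hi)))
    return positions


def plant_events(record: SeqRecord, n_subs: int = 3,
                 deletion_lengths: tuple[int, ...] = (10, 10),
                 insertion_lengths: tuple[int, ...] = (10, 10),
                 n_ambig: int = 12, min_separation: int = 1500,
                 region: tuple[int, int] | None = None, seed: int = 0,
                 name: str | None = None):
    """Plant a known set of substitutions, indels and ambiguities.

    Events are placed far apart (``min_separation``) so that re-alignment of
    the mutated sequence against the parent recovers each one without
    alignment-shift confounding.  Event positions are parent coordinates.
    """
    rng = np.random.default_rng(seed)
    n = len(record.residues)
    lo, hi = region if region else (min_separation, n - min_separation)
    n_events = n_subs + n_ambig + len(deletion_lengths) + len(insertion_lengths)
    positions = _spaced_positions(rng, lo, hi, n_events, min_separation)
    order = rng.permutation(n_events)
    sub_pos = sorted(positions[i] for i in order[:n_subs])
    amb_pos = sorted(positions[i] for i in order[n_subs:n_subs + n_ambig])
    indel_pos = [positions[i] for i in order[n_subs + n_ambig:]]

    seq = bytearray(record.residues.encode())
    applied_subs = []
    for pos in sub_pos:
        old = chr(seq[pos])
        if old not in "ACGT":
            continue
        seq[pos] = ord("ACGT".replace(old, "")[rng.integers(0, 3)])
        applied_subs.append(pos)
    applied_ambig = []
    for pos in amb_pos:
        old = chr(seq[pos])
        if old not in "ACGT":
            continue
        codes = AMBIGUITY_FOR_BASE[old]
        seq[pos] = ord(codes[rng.integers(0, len(codes))])
        applied_ambig.append(pos)

    events = []
    kinds = ["del"] * len(deletion_lengths) + ["ins"] * len(insertion_lengths)
    lengths = list(deletion_lengths) + list(insertion_lengths)
    for pos, kind, length in zip(sorted(indel_pos), kinds, lengths):
        events.append((pos, length, kind))
    out = []
    cursor = 0
    for pos, length, kind in sorted(events):
        out.append(bytes(seq[cursor:pos]).decode())
        if kind == "ins":
            out.append(random_dna(rng, length))
            cursor = pos
        else:
            cursor = pos + length
    out.append(bytes(seq[cursor:]).decode())

    child = SeqRecord(name or f"{record.id}_derived", "".join(out))
    truth = SimulationTruth(
        seed=seed, substitution_positions=applied_subs,
        ambiguity_positions=applied_ambig, indel_events=sorted(events),
        extras={"expected_gap_columns": sum(lengths)},
    )
    return child, truth


def plant_alignment(length: int = 5000, n_subs: int = 3, n_gap_cols: int = 40,
                    n_ambig: int = 12, seed: int = 0) -> tuple[PairwiseAlignment, SimulationTruth]:
    """Build a nucleotide alignment directly, with known column classes.

    Gap columns are split between one-sided gaps in either row; ambiguity
    columns replace one residue by a compatible code.  Truth lists the exact
    column index of every planted site.
    """
    rng = np.random.default_rng(seed)
    base = random_dna(rng, length)
    n_events = n_subs + n_gap_cols + n_ambig
    sites = _spaced_positions(rng, 20, length - 20, n_events, 10)
    order = rng.permutation(n_events)
    subs = sorted(sites[i] for i in order[:n_subs])
    gaps = sorted(sites[i] for i in order[n_subs:n_subs + n_gap_cols])
    ambigs = sorted(sites[i] for i in order[n_subs + n_gap_cols:])
    kind = {}
    for p in subs:
        kind[p] = "sub"
    for i, p in enumerate(gaps):
        kind[p] = "gap_a" if i % 2 else "gap_b"
    for p in ambigs:
        kind[p] = "amb"

    row_a, row_b = [], []
    truth_cols = {"sub": [], "gap": [], "amb": []}
    col = 0
    for i, ch in enumerate(base):
        k = kind.get(i)
        if k == "gap_a":            # insertion in b relative to a
            row_a.append(ch)
            row_b.append(ch)
            row_a.append("-")
            row_b.append(random_dna(rng, 1))
            truth_cols["gap"].append(col + 1)
            col += 2
            continue
        if k == "sub":
            row_a.append(ch)
            row_b.append("ACGT".replace(ch, "")[rng.integers(0, 3)])
            truth_cols["sub"].append(col)
        elif k == "gap_b":
            row_a.append(ch)
            row_b.append("-")
            truth_cols["gap"].append(col)
        elif k == "amb":
            row_a.append(ch)
            codes = AMBIGUITY_FOR_BASE[ch]
            row_b.append(codes[rng.integers(0, len(codes))])
            truth_cols["amb"].append(col)
        else:
            row_a.append(ch)
            row_b.append(ch)
        col += 1

    a_str, b_str = "".join(row_a), "".join(row_b)
    aln = PairwiseAlignment("truthA", "truthB", a_str, b_str,
                            score=0.0, a_start=0, a_end=length,
                            b_start=0, b_end=len(b_str) - b_str.count("-"),
                            alphabet="nucleotide")
    truth = SimulationTruth(seed=seed,
                            substitution_positions=truth_cols["sub"],
                            gap_columns=truth_cols["gap"],
                            ambiguity_positions=truth_cols["amb"])
    return aln, truth


SCENARIOS = ("ani_vs_ae", "ecd_hty_reassembly", "marker_panel", "two_clade_msa")


@dataclass
class FixtureBundle:
    """Everything one scenario produced, plus the truth to check it against."""

    scenario: str
    seed: int
    records: dict[str, SeqRecord] = field(default_factory=dict)
    annotations: dict[str, ClusterAnnotation] = field(default_factory=dict)
    contigs: list[SeqRecord] = field(default_factory=list)
    rows: dict[str, str] = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for key, rec in self.records.items():
            p = outdir / f"{key}.fasta"
            write_fasta([rec], p)
            paths[key] = p
        for key, ann in self.annotations.items():
            p = outdir / f"{key}.gff3"
            write_gff3(ann, p)
            paths[f"{key}_gff3"] = p
        if self.contigs:
            (outdir / "contigs").mkdir(exist_ok=True)
            for rec, stem in zip(self.contigs, ("left", "right")):
                p = outdir / "contigs" / f"{stem}.fasta"
                write_fasta([rec], p)
                paths[stem] = p
        if self.rows:
            p = outdir / "aligned_rows.fasta"
            with open(p, "w") as fh:
                for rid, row in self.rows.items():
                    fh.write(f">{rid}\n{row}\n")
            paths["aligned_rows"] = p
        p = outdir / "truth.json"
        with open(p, "w") as fh:
            json.dump(_jsonable(self.truth), fh, indent=1, sort_keys=True)
        paths["truth"] = p
        return paths


def _fixture_ani_vs_ae(seed: int) -> FixtureBundle:
    record, annotation, truth = generate_cluster_genome(seed=seed, name="genomeA")
    cs, ce = truth.core_interval
    core = SeqRecord("coreA", record.residues[cs:ce])
    core_ann = ClusterAnnotation("coreA", [
        GeneModel(g.gene_id, g.start - cs, g.end - cs, g.strand, g.product)
        for g in annotation.genes])
    evolved, etruth = evolve_sequence(core, sub_rate=0.11, indel_rate=2e-4,
                                      indel_len_geometric_p=0.5,
                                      ambiguity_rate=5e-5, protect_orfs=True,
                                      annotation=core_ann, seed=seed + 1)
    flank_rng = np.random.default_rng(seed + 2)
    flank_len = 5000
    residues_b = (random_dna(flank_rng, flank_len) + evolved.residues
                  + random_dna(flank_rng, flank_len))
    genome_b = SeqRecord("genomeB", residues_b)
    ann_b = lift_annotation(core_ann, etruth, "genomeB", offset=flank_len)
    bundle = FixtureBundle("ani_vs_ae", seed)
    bundle.records = {"genomeA": record, "genomeB": genome_b}
    bundle.annotations = {"annotA": annotation, "annotB": ann_b}
    bundle.truth = {
        "core_interval_a": [cs, ce],
        "core_interval_b": [flank_len, flank_len + len(evolved.residues)],
        "planted_core_identity": 0.89,
        "realized_core_identity": etruth.realized_core_identity,
        "ortholog_map": [[g.gene_id, g.gene_id] for g in annotation.genes],
    }
    return bundle


def _fixture_ecd_hty(seed: int) -> FixtureBundle:
    record, annotation, truth = generate_cluster_genome(seed=seed, flank_len=3000,
                                                        name="reference")
    cs, ce = truth.core_interval
    derived, ptruth = plant_events(record, n_subs=3, deletion_lengths=(10, 10),
                                   insertion_lengths=(10, 10), n_ambig=12,
                                   min_separation=1500, region=(cs + 500, ce - 500),
                                   seed=seed + 1, name="derived")
    junction = len(derived.residues) // 2
    left, right, struth = split_with_overlap(derived, junction, overlap_len=400,
                                             overlap_divergence=0.04, seed=seed + 2)
    bundle = FixtureBundle("ecd_hty_reassembly", seed)
    bundle.records = {"reference": record, "original": derived}
    bundle.annotations = {"annot_reference": annotation}
    bundle.contigs = [left, right]
    bundle.truth = {
        "substitution_positions": ptruth.substitution_positions,
        "ambiguity_positions": ptruth.ambiguity_positions,
        "indel_events": ptruth.indel_events,
        "expected_gap_columns": ptruth.extras["expected_gap_columns"],
        "junction": struth.junction,
        "overlap_len": struth.overlap_len,
        "overlap_identity": struth.overlap_identity,
        "realized_overlap_identity": struth.realized_overlap_identity,
        "reference_length": len(record.residues),
    }
    return bundle


def _fixture_marker_panel(seed: int) -> FixtureBundle:
    rng = np.random.default_rng(seed)
    its_a = SeqRecord("its_a", random_dna(rng, 600))
    its_b_child, its_truth = plant_events(its_a, n_subs=1, deletion_lengths=(),
                                          insertion_lengths=(), n_ambig=0,
                                          min_separation=40, seed=seed + 1,
                                          name="its_b")
    cal_a = SeqRecord("cal_a", random_dna(rng, 700))
    cal_b_child, cal_truth = plant_events(cal_a, n_subs=2, deletion_lengths=(3,),
                                          insertion_lengths=(), n_ambig=0,
                                          min_separation=60, seed=seed + 2,
                                          name="cal_b")
    bundle = FixtureBundle("marker_panel", seed)
    bundle.records = {"its_a": its_a, "its_b": its_b_child,
                      "cal_a": cal_a, "cal_b": cal_b_child}
    bundle.truth = {
        "its_differences": len(its_truth.substitution_positions),
        "cal_differences": len(cal_truth.substitution_positions),
        "cal_gap_columns": 3,
        "its_substitutions": its_truth.substitution_positions,
        "cal_substitutions": cal_truth.substitution_positions,
    }
    return bundle


def _fixture_two_clade(seed: int, n_diagnostic: int = 30, length: int = 720,
                       per_clade: int = 3) -> FixtureBundle:
    rng = np.random.default_rng(seed)
    base = random_dna(rng, length)
    cols = _spaced_positions(rng, 10, length - 10, n_diagnostic + 20, 4)
    order = rng.permutation(len(cols))
    diag_cols = sorted(cols[i] for i in order[:n_diagnostic])
    noise_cols = [cols[i] for i in order[n_diagnostic:]]

    clade_b_base = bytearray(base.encode())
    for c in diag_cols:
        old = chr(clade_b_base[c])
        clade_b_base[c] = ord("ACGT".replace(old, "")[rng.integers(0, 3)])
    rows = {}
    for k in range(per_clade):
        rows[f"a{k + 1}"] = bytearray(base.encode())
        rows[f"b{k + 1}"] = bytearray(clade_b_base)
    # private noise: polymorphisms, gaps and ambiguities in single rows, at
    # columns where the clades agree -- never creates a diagnostic column
    ids = sorted(rows)
    for i, c in enumerate(noise_cols):
        rid = ids[int(rng.integers(0, len(ids)))]
        mode = i % 3
        old = chr(rows[rid][c])
        if mode == 0:
            rows[rid][c] = ord("ACGT".replace(old, "")[rng.integers(0, 3)])
        elif mode == 1:
            rows[rid][c] = ord("-")
        else:
            codes = AMBIGUITY_FOR_BASE[old]
            rows[rid][c] = ord(codes[rng.integers(0, len(codes))])
    str_rows = {rid: row.decode() for rid, row in rows.items()}

    bundle = FixtureBundle("two_clade_msa", seed)
    bundle.rows = str_rows
    bundle.truth = {
        "diagnostic_columns": diag_cols,
        "group_a": [f"a{k + 1}" for k in range(per_clade)],
        "group_b": [f"b{k + 1}" for k in range(per_clade)],
    }
    return bundle


def make_comparison_fixture(scenario: str, seed: int = 0,
                            outdir: str | Path | None = None) -> FixtureBundle:
    """Build one of the named comparison scenarios, optionally writing a
    self-contained fixture directory (FASTA/GFF3 + ``truth.json``)."""
    builders = {
        "ani_vs_ae": _fixture_ani_vs_ae,
        "ecd_hty_reassembly": _fixture_ecd_hty,
        "marker_panel": _fixture_marker_panel,
        "two_clade_msa": _fixture_two_clade,
    }
    if scenario not in builders:
        raise ValueError(f"unknown scenario {scenario!r}; valid: {', '.join(SCENARIOS)}")
    bundle = builders[scenario](seed)
    if outdir is not None:
        bundle.write(outdir)
    return bundle
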