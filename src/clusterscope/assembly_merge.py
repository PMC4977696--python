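"""Suffix-prefix overlap detection between contigs and provenance-tracked merging.

All ordered contig pairs are searched in both orientations, because deposited
subcluster sequences may be recorded on either strand.  The headline overlap
length is the alignment column count; per-contig overlap lengths can differ
when the overlap alignment contains indels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from ._iupac import AMBIG_TABLE
from .align_core import (DEFAULT_NT_SCORING, NtScoring, PairwiseAlignment,
                         global_align_nt, overlap_align, percent_identity)
from .cluster_profile import (WindowIdentityProfile, count_genuine_inconsistencies,
                              window_identity_profile)
from .formats_io import SeqRecord

FORWARD = "forward"
REVCOMP = "revcomp"


@dataclass
class OverlapHit:
    """A detected suffix-prefix overlap between two (oriented) contigs."""

    left_id: str
    right_id: str
    left_orientation: str
    right_orientation: str
    overlap_len_left: int
    overlap_len_right: int
    identity: float
    alignment: PairwiseAlignment

    @property
    def columns(self) -> int:
        return len(self.alignment)


@dataclass
class MergedSequence:
    """Merged contig with a per-position source label.

    ``junction`` is the half-open range of the overlap consensus in merged
    coordinates (the left contig's frame); provenance labels are ``left``,
    ``consensus`` and ``right`` and partition the sequence.
    """

    id: str
    residues: str
    junction: tuple[int, int]
    provenance: list[str]
    conflicts: int = 0

    def __len__(self) -> int:
        return len(self.residues)

    def to_record(self) -> SeqRecord:
        return SeqRecord(self.id, self.residues)

    def write_provenance_bed(self, path: str | Path) -> None:
        """BED intervals of the three provenance segments over the merge."""
        with open(path, "w") as fh:
            start = 0
            for label in ("left", "consensus", "right"):
                end = start
                while end < len(self.provenance) and self.provenance[end] == label:
                    end += 1
                if end > start:
                    fh.write(f"{self.id}\t{start}\t{end}\t{label}\n")
                start = end


def _oriented(record: SeqRecord, orientation: str) -> SeqRecord:
    return record if orientation == FORWARD else record.reverse_complement()


def find_best_overlap(contigs: list[SeqRecord], min_len: int = 100,
                      min_identity: float = 0.90,
                      scoring: NtScoring = DEFAULT_NT_SCORING,
                      max_overlap: int = 3000) -> OverlapHit | None:
    """Best suffix-prefix overlap over all ordered pairs and orientations.

    Candidates must span at least ``min_len`` alignment columns at
    ``min_identity`` (all-columns policy); among those the hit maximizing
    ``identity * min(overlap_len_left, overlap_len_right)`` wins.  Returns
    ``None`` when nothing passes — the defaults are chosen so that random
    unrelated contigs never do.
    """
    if len(contigs) < 2:
        raise ValueError("overlap search needs at least 2 contigs")
    best: OverlapHit | None = None
    best_key = (-1.0, -1)
    for i, left in enumerate(contigs):
        for j, right in enumerate(contigs):
            if i == j:
                continue
            for ol in (FORWARD, REVCOMP):
                for orr in (FORWARD, REVCOMP):
                    a = _oriented(left, ol)
                    b = _oriented(right, orr)
                    aln = overlap_align(a, b, scoring, max_overlap=max_overlap)
                    if len(aln) < min_len:
                        continue
                    ident = percent_identity(aln, "all_columns")
                    if ident < min_identity:
                        continue
                    len_l = aln.a_end - aln.a_start
                    len_r = aln.b_end - aln.b_start
                    # ties (e.g. the revcomp-swapped duplicate of a hit)
                    # resolve toward forward orientations for determinism
                    key = (ident * min(len_l, len_r),
                           (ol == FORWARD) + (orr == FORWARD))
                    if key > best_key:
                        best_key = key
                        best = OverlapHit(left.id, right.id, ol, orr,
                                          len_l, len_r, ident, aln)
    return best


def merge_contigs(hit: OverlapHit, left: SeqRecord, right: SeqRecord,
                  conflict_policy: str = "prefer_unambiguous") -> MergedSequence:
    """Merge two contigs through a detected overlap.

    The merged sequence is the left-unique prefix, the overlap consensus and
    the right-unique suffix.  Within the overlap, matching columns emit the
    shared base; one-sided gap columns emit the present base; conflicting
    columns are resolved by ``conflict_policy``:

    ``prefer_left`` / ``prefer_right``
        always take that contig's residue;
    ``prefer_unambiguous`` (default)
        take the concrete residue when exactly one side is an IUPAC ambiguity
        code, otherwise fall back to the left residue.
    """
    if conflict_policy not in ("prefer_left", "prefer_right", "prefer_unambiguous"):
        raise ValueError(f"unknown conflict policy {conflict_policy!r}")
    if {hit.left_id, hit.right_id} != {left.id, right.id} or left.id == right.id:
        raise ValueError("hit does not refer to the given contigs")
    if left.id != hit.left_id:
        left, right = right, left
    left = _oriented(left, hit.left_orientation)
    right = _oriented(right, hit.right_orientation)
    aln = hit.alignment

    consensus = []
    conflicts = 0
    for x, y in zip(aln.a_gapped, aln.b_gapped):
        if x == "-":
            consensus.append(y)
        elif y == "-" or x == y:
            consensus.append(x)
        else:
            conflicts += 1
            if conflict_policy == "prefer_right":
                consensus.append(y)
            elif conflict_policy == "prefer_unambiguous":
                x_amb, y_amb = AMBIG_TABLE[ord(x)], AMBIG_TABLE[ord(y)]
                consensus.append(y if (x_amb and not y_amb) else x)
            else:
                consensus.append(x)
    consensus = "".join(consensus)

    prefix = left.residues[:aln.a_start]
    suffix = right.residues[aln.b_end:]
    residues = prefix + consensus + suffix
    provenance = (["left"] * len(prefix) + ["consensus"] * len(consensus)
                  + ["right"] * len(suffix))
    merged_id = f"{left.id}+{right.id}"
    return MergedSequence(merged_id, residues,
                          (len(prefix), len(prefix) + len(consensus)),
                          provenance, conflicts)


def reference_verify(merged: MergedSequence | SeqRecord, reference: SeqRecord,
                     window_size: int = 50,
                     scoring: NtScoring = DEFAULT_NT_SCORING) -> dict:
    """Globally align a merged sequence to a reference cluster and report
    full-length identity, the windowed profile and the genuine-inconsistency
    count — the numbers that back "99.9 % / three base pairs" style claims."""
    record = merged.to_record() if isinstance(merged, MergedSequence) else merged
    aln = global_align_nt(record, reference, scoring)
    profile = window_identity_profile(aln, window_size)
    inconsistencies = count_genuine_inconsistencies(aln)
    return {
        "identity": percent_identity(aln, "all_columns"),
        "identity_genuine": percent_identity(aln, "exclude_gap_and_ambiguity"),
        "profile": profile,
        "inconsistencies": inconsistencies["count"],
        "inconsistency_columns": inconsistencies["positions"],
        "alignment": aln,
    }
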