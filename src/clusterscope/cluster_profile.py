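"""Windowed identity profiles, core-boundary delimitation and site triage.

Windows live in alignment-column space, not reference-base space, which makes
profiles symmetric in the two sequences.  Window classes follow fixed
thresholds: ``full`` means every column matches, ``low`` means identity below
0.30, everything else is ``partial``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._iupac import AMBIG_TABLE, MASK_TABLE
from .align_core import (GAP, GENUINE_SUBSTITUTION, MATCH, DEFAULT_NT_SCORING,
                         NtScoring, PairwiseAlignment, SiteClassCounts,
                         classify_column_codes, classify_columns,
                         global_align_nt)
from .formats_io import SeqRecord

FULL_THRESHOLD = 1.0
LOW_THRESHOLD = 0.30


@dataclass(frozen=True)
class Window:
    col_start: int
    col_end: int
    identity: float
    cls: str


@dataclass
class WindowIdentityProfile:
    """Non-overlapping identity windows tiling an alignment.

    ``column_matches`` keeps the per-column match indicator so that boundary
    refinement can work at column resolution without re-running the
    classification.
    """

    window_size: int
    windows: list[Window]
    column_matches: np.ndarray = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def n_columns(self) -> int:
        return self.windows[-1].col_end if self.windows else 0

    def identities(self) -> np.ndarray:
        return np.array([w.identity for w in self.windows])

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("col_start\tcol_end\tidentity\tclass\n")
            for w in self.windows:
                fh.write(f"{w.col_start}\t{w.col_end}\t{w.identity:.4f}\t{w.cls}\n")


@dataclass
class CoreInterval:
    """Alignment-column span of the conserved core plus summary identities."""

    col_start: int
    col_end: int
    mean_core_identity: float
    mean_flank_identity: float
    window_start: int = 0
    window_end: int = 0


def _window_class(identity: float) -> str:
    if identity >= FULL_THRESHOLD:
        return "full"
    if identity < LOW_THRESHOLD:
        return "low"
    return "partial"


def window_identity_profile(aln: PairwiseAlignment,
                            window_size: int = 50) -> WindowIdentityProfile:
    """Tile the alignment with ``window_size``-column windows.

    A final partial window shorter than ``window_size / 2`` is merged into the
    previous window; otherwise it stands on its own.  Per-window identity uses
    the ``all_columns`` policy.  Alignments shorter than one window yield a
    single window.
    """
    if window_size < 10:
        raise ValueError("window_size must be >= 10")
    codes = classify_column_codes(aln)
    matches = (codes == MATCH).astype(np.float64)
    n = len(matches)
    if n == 0:
        raise ValueError("empty alignment")
    edges = list(range(0, n, window_size))
    if len(edges) > 1 and n - edges[-1] < window_size / 2:
        edges.pop()
    bounds = edges + [n]
    windows = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        ident = float(matches[lo:hi].mean())
        windows.append(Window(lo, hi, ident, _window_class(ident)))
    return WindowIdentityProfile(window_size, windows, matches)


def detect_core_boundaries(profile: WindowIdentityProfile, t_high: float = 0.60,
                           t_low: float = 0.40, max_low_run: int = 2) -> CoreInterval:
    """Delimit the conserved core as the maximal high-identity window run.

    A run consists of windows with identity >= ``t_high``; interior dips are
    tolerated for at most ``max_low_run`` consecutive windows provided they
    stay >= ``t_low``.  Boundaries are refined to column resolution inside the
    terminal windows by a 50-column running mean crossing ``(t_high+t_low)/2``.
    """
    if not profile.windows:
        raise ValueError("empty profile")
    ident = profile.identities()
    n = len(ident)
    high = ident >= t_high
    dead = ident < t_low
    if not high.any():
        raise ValueError("no core detected: no window reaches t_high")

    best: tuple[int, int] | None = None
    best_cols = -1
    i = 0
    while i < n:
        if not high[i]:
            i += 1
            continue
        last_high = i
        j = i + 1
        low_run = 0
        while j < n:
            if high[j]:
                last_high = j
                low_run = 0
            elif dead[j]:
                break
            else:
                low_run += 1
                if low_run > max_low_run:
                    break
            j += 1
        cols = profile.windows[last_high].col_end - profile.windows[i].col_start
        if cols > best_cols:
            best_cols = cols
            best = (i, last_high)
        i = last_high + 1
    ws, we = best

    col_start = profile.windows[ws].col_start
    col_end = profile.windows[we].col_end
    m = profile.column_matches
    if m is not None:
        mid = (t_high + t_low) / 2.0
        w = 50
        win = profile.windows[ws]
        for c in range(win.col_start, min(win.col_end, len(m) - w + 1)):
            if m[c:c + w].mean() >= mid:
                col_start = c
                break
        win = profile.windows[we]
        for c in range(win.col_end - 1, max(win.col_start - 1, w - 2), -1):
            if m[c - w + 1:c + 1].mean() >= mid:
                col_end = c + 1
                break

    core_mean = float(m[col_start:col_end].mean())
    outside = np.concatenate([m[:col_start], m[col_end:]])
    flank_mean = float(outside.mean()) if outside.size else 0.0
    return CoreInterval(col_start, col_end, core_mean, flank_mean, ws, we)


def count_genuine_inconsistencies(aln: PairwiseAlignment) -> dict:
    """Columns where both rows carry unambiguous, different bases."""
    codes = classify_column_codes(aln)
    positions = np.flatnonzero(codes == GENUINE_SUBSTITUTION)
    return {"count": int(positions.size), "positions": positions.tolist()}


def marker_diff(a: SeqRecord, b: SeqRecord,
                scoring: NtScoring = DEFAULT_NT_SCORING) -> SiteClassCounts:
    """Align two marker sequences and tally column classes.

    The headline "basepair difference" of a marker comparison is the
    ``genuine_substitution`` count.
    """
    return classify_columns(global_align_nt(a, b, scoring))


def conserved_group_differences(aligned_rows: dict[str, str] | list[tuple[str, str]],
                                group_a: set[str], group_b: set[str]) -> dict:
    """Count columns that cleanly separate two groups of aligned rows.

    A column counts when every group-A row carries one identical concrete
    (non-gap, non-ambiguous) base, every group-B row likewise, and the two
    bases differ.  Polymorphic, gapped or ambiguous columns never count.
    """
    rows = dict(aligned_rows)
    group_a, group_b = set(group_a), set(group_b)
    if group_a & group_b:
        raise ValueError("groups must be disjoint")
    missing = (group_a | group_b) - rows.keys()
    if missing:
        raise ValueError(f"rows missing for ids: {sorted(missing)}")
    lengths = {len(s) for s in rows.values()}
    if len(lengths) != 1:
        raise ValueError("aligned rows differ in length")

    def stack(ids):
        return np.vstack([np.frombuffer(rows[i].encode(), dtype=np.uint8)
                          for i in sorted(ids)])

    def clean_consensus(mat):
        concrete = (MASK_TABLE[mat] > 0) & ~AMBIG_TABLE[mat]
        uniform = (mat == mat[0]).all(axis=0) & concrete.all(axis=0)
        return uniform, mat[0]

    ok_a, res_a = clean_consensus(stack(group_a))
    ok_b, res_b = clean_consensus(stack(group_b))
    diagnostic = ok_a & ok_b & (res_a != res_b)
    cols = np.flatnonzero(diagnostic)
    return {"count": int(cols.size), "columns": cols.tolist()}


def star_align(records: list[SeqRecord],
               scoring: NtScoring = DEFAULT_NT_SCORING) -> dict[str, str]:
    """Multi-row alignment by star alignment around the longest record.

    Each record is globally aligned to the longest one; insertions relative to
    the reference are merged by padding, the classic star-alignment
    construction.  Deliberately simple — this package has no progressive MSA.
    """
    if len(records) < 2:
        raise ValueError("star_align needs at least 2 records")
    ref = max(records, key=len)
    others = [r for r in records if r is not ref]
    # ins[i] = columns inserted before reference position i (i == len -> at end)
    n = len(ref)
    ins = np.zeros(n + 1, dtype=int)
    alns = []
    for rec in others:
        aln = global_align_nt(ref, rec, scoring)
        alns.append(aln)
        run = 0
        pos = 0
        for ch in aln.a_gapped:
            if ch == "-":
                run += 1
            else:
                if run:
                    ins[pos] = max(ins[pos], run)
                run = 0
                pos += 1
        if run:
            ins[n] = max(ins[n], run)

    def project(aln: PairwiseAlignment) -> str:
        out = []
        pos = 0
        pending = ""
        for x, y in zip(aln.a_gapped, aln.b_gapped):
            if x == "-":
                pending += y
            else:
                out.append(pending + "-" * (ins[pos] - len(pending)))
                out.append(y)
                pending = ""
                pos += 1
        out.append(pending + "-" * (ins[n] - len(pending)))
        return "".join(out)

    result = {ref.id: "".join("-" * ins[i] + ref.residues[i] for i in range(n))
              + "-" * ins[n]}
    for aln, rec in zip(alns, others):
        result[rec.id] = project(aln)
    return result


def write_inconsistency_tsv(aln: PairwiseAlignment, path: str | Path) -> None:
    """TSV report of every non-match column with its class."""
    codes = classify_column_codes(aln)
    names = {MATCH: "match", GENUINE_SUBSTITUTION: "genuine_substitution",
             GAP: "gap", 3: "ambiguity"}
    with open(path, "w") as fh:
        fh.write("column\ta_residue\tb_residue\tclass\n")
        for col in np.flatnonzero(codes != MATCH):
            col = int(col)
            fh.write(f"{col}\t{aln.a_gapped[col]}\t{aln.b_gapped[col]}\t"
                     f"{names[int(codes[col])]}\n")
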