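"""Paired reads -> clonotype table with full CDR3 V(D)J architecture.

Stages: quality-weighted pair joining, V/J classification against the
germline registry, clustering into clonotypes keyed by (V, J, CDR3), merging
of 1-bp PCR-error neighbours into >= 20-fold more abundant clonotypes, the
0.001% clonotype-frequency cutoff, and junction decomposition into
V-truncation | N1 | D (>= 5 nt) | N2 | J-truncation with in-frame/stop-free
functionality calling.

The CDR3 spans from the first base of the conserved V cysteine codon through
the last base of the conserved J phenylalanine codon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_core import GermlineSegment, Read, RunConfig, registry_by_kind, revcomp
from .synthetic_data import is_functional

logger = logging.getLogger("repscan")

__all__ = [
    "join_read_pair",
    "assign_v_j",
    "cluster_clonotypes",
    "merge_neighbor_clonotypes",
    "apply_frequency_cutoff",
    "decompose_architecture",
    "profile_reads",
    "VDJArchitecture",
]


# ---------------------------------------------------------------------------
# Read joining
# ---------------------------------------------------------------------------

def join_read_pair(
    r1: Read,
    r2: Read,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.25,
) -> Optional[str]:
    """Quality-weighted consensus of a read pair, or None on rejection.

    R2 is reverse-complemented and slid ungapped against R1; among overlaps of
    length >= ``min_overlap`` with mismatch fraction <= ``max_mismatch_frac``
    the one with the lowest mismatch fraction (ties: longest overlap) wins.
    At each overlap mismatch the base with the higher quality is kept, with
    R1 winning ties.
    """
    s1, q1 = r1.sequence, r1.qualities
    s2 = revcomp(r2.sequence)
    q2 = r2.qualities[::-1]
    n1, n2 = len(s1), len(s2)
    if n1 == 0 or n2 == 0:
        return None
    a1 = np.frombuffer(s1.encode(), dtype=np.uint8)
    a2 = np.frombuffer(s2.encode(), dtype=np.uint8)
    best: tuple[float, int, int] | None = None  # (mismatch_frac, -ov_len, shift)
    # shift = offset of s2's start relative to s1's start
    for shift in range(-(n2 - min_overlap), n1 - min_overlap + 1):
        lo1, hi1 = max(0, shift), min(n1, shift + n2)
        ov = hi1 - lo1
        if ov < min_overlap:
            continue
        mism = int((a1[lo1:hi1] != a2[lo1 - shift : hi1 - shift]).sum())
        frac = mism / ov
        if frac > max_mismatch_frac:
            continue
        cand = (frac, -ov, shift)
        if best is None or cand[:2] < best[:2]:
            best = cand
    if best is None:
        return None
    shift = best[2]
    lo1, hi1 = max(0, shift), min(n1, shift + n2)
    mid = []
    for i in range(lo1, hi1):
        j = i - shift
        if s1[i] == s2[j] or q1[i] >= q2[j]:
            mid.append(s1[i])
        else:
            mid.append(s2[j])
    left = s1[:lo1] if shift >= 0 else s2[: -shift]
    right = s2[hi1 - shift :] if shift + n2 > n1 else s1[hi1:]
    return left + "".join(mid) + right


# ---------------------------------------------------------------------------
# V / J classification
# ---------------------------------------------------------------------------

def _anchor_window(seg: GermlineSegment, max_len: int = 30) -> tuple[str, int]:
    """Conserved window used for classification and its anchor position.

    For V: window ends at the last base of the cysteine codon (always intact
    in a read, since 3' truncation happens downstream of the anchor); for J:
    window starts at the first base of the phenylalanine codon.
    """
    if seg.kind == "V":
        end = seg.anchor_offset + 3
        start = max(0, end - max_len)
        return seg.sequence[start:end], end - start - 3
    start = seg.anchor_offset
    end = min(len(seg.sequence), start + max_len)
    return seg.sequence[start:end], 0


def _best_match(joined: np.ndarray, window: str) -> tuple[int, int]:
    """(best offset, matches) of an ungapped slide of window over joined."""
    w = np.frombuffer(window.encode(), dtype=np.uint8)
    n = joined.size - w.size + 1
    if n <= 0:
        return -1, -1
    views = np.lib.stride_tricks.sliding_window_view(joined, w.size)
    matches = (views == w).sum(axis=1)
    off = int(matches.argmax())
    return off, int(matches[off])


def assign_v_j(
    joined: str,
    registry: Sequence[GermlineSegment],
    min_ident: float = 0.9,
    min_len: int = 15,
) -> Optional[tuple[str, str, int, int]]:
    """Classify a joined read; returns (v_name, j_name, v_anchor, j_anchor).

    Anchors are positions in the joined read of the first base of the V
    cysteine / J phenylalanine codons.  Ties are broken by longer match, then
    lexicographically smallest segment name.  Returns None on rejection.
    """
    arr = np.frombuffer(joined.encode(), dtype=np.uint8)
    best: dict[str, tuple[float, int, str, int]] = {}
    for seg in registry:
        if seg.kind == "D":
            continue
        window, anchor_in_window = _anchor_window(seg)
        if len(window) < min_len:
            continue
        off, matches = _best_match(arr, window)
        if off < 0:
            continue
        ident = matches / len(window)
        if ident < min_ident:
            continue
        anchor_pos = off + anchor_in_window if seg.kind == "V" else off
        cand = (ident, len(window), seg.name, anchor_pos)
        cur = best.get(seg.kind)
        # maximize identity, then window length; minimize name
        if cur is None or (cand[0], cand[1], _neg_name(cand[2])) > (
            cur[0], cur[1], _neg_name(cur[2])
        ):
            best[seg.kind] = cand
    if "V" not in best or "J" not in best:
        return None
    v, j = best["V"], best["J"]
    if v[3] + 3 > j[3]:  # anchors out of order: no CDR3 interval
        return None
    return v[2], j[2], v[3], j[3]


class _neg_name(str):
    """Orders strings descending so that max() picks the smallest name."""

    def __lt__(self, other) -> bool:  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other) -> bool:  # type: ignore[override]
        return str.__lt__(self, other)


# ---------------------------------------------------------------------------
# Clustering, merging, cutoff
# ---------------------------------------------------------------------------

def cluster_clonotypes(assigned: pd.DataFrame) -> pd.DataFrame:
    """One row per unique (v_name, j_name, cdr3_nt) with read counts.

    ``frequency`` is read_count over total assigned reads.
    """
    if len(assigned) == 0:
        return pd.DataFrame(
            columns=["v_name", "j_name", "cdr3_nt", "read_count", "frequency"]
        )
    table = (
        assigned.groupby(["v_name", "j_name", "cdr3_nt"], as_index=False)
        .size()
        .rename(columns={"size": "read_count"})
    )
    table["frequency"] = table["read_count"] / table["read_count"].sum()
    return table.sort_values(
        ["read_count", "v_name", "j_name", "cdr3_nt"],
        ascending=[False, True, True, True],
    ).reset_index(drop=True)


def _hamming1(a: str, b: str) -> bool:
    if len(a) != len(b):
        return False
    seen = False
    for x, y in zip(a, b):
        if x != y:
            if seen:
                return False
            seen = True
    return seen


def merge_neighbor_clonotypes(table: pd.DataFrame, fold_threshold: float = 20.0) -> pd.DataFrame:
    """Absorb 1-substitution neighbours into >= fold-threshold more abundant ones.

    A clonotype merges into the most abundant clonotype with the same V, J and
    CDR3 length at Hamming distance 1 whose count is at least
    ``fold_threshold`` times its own.  Rows are processed in ascending
    abundance and eligibility is recomputed after every merge; the total read
    count is conserved exactly.
    """
    if len(table) == 0:
        return table.copy()
    rows = table.to_dict("records")
    counts = {i: int(r["read_count"]) for i, r in enumerate(rows)}
    alive = set(counts)
    buckets: dict[tuple[str, str, int], list[int]] = {}
    for i, r in enumerate(rows):
        buckets.setdefault((r["v_name"], r["j_name"], len(r["cdr3_nt"])), []).append(i)
    # ascending abundance, deterministic tie-break on the clonotype key
    order = sorted(alive, key=lambda i: (counts[i], rows[i]["cdr3_nt"]))
    for i in order:
        if i not in alive:
            continue
        key = (rows[i]["v_name"], rows[i]["j_name"], len(rows[i]["cdr3_nt"]))
        candidates = [
            k for k in buckets[key]
            if k != i and k in alive
            and counts[k] >= fold_threshold * counts[i]
            and _hamming1(rows[i]["cdr3_nt"], rows[k]["cdr3_nt"])
        ]
        if not candidates:
            continue
        recipient = max(candidates, key=lambda k: (counts[k], rows[k]["cdr3_nt"]))
        counts[recipient] += counts[i]
        alive.discard(i)
    total = sum(int(r["read_count"]) for r in rows)
    out = pd.DataFrame([dict(rows[i], read_count=counts[i]) for i in sorted(alive)])
    out["frequency"] = out["read_count"] / total
    merged = len(rows) - len(out)
    logger.info("merge_neighbor_clonotypes: merged %d of %d clonotypes", merged, len(rows))
    return out.sort_values(
        ["read_count", "v_name", "j_name", "cdr3_nt"],
        ascending=[False, True, True, True],
    ).reset_index(drop=True)


def apply_frequency_cutoff(table: pd.DataFrame, cutoff: float = 1e-5) -> pd.DataFrame:
    """Drop rows with frequency strictly below the cutoff (no renormalization)."""
    if len(table) == 0:
        return table.copy()
    kept = table[table["frequency"] >= cutoff].reset_index(drop=True)
    logger.info("apply_frequency_cutoff: %d -> %d clonotypes at %.6g",
                len(table), len(kept), cutoff)
    return kept


# ---------------------------------------------------------------------------
# Architecture decomposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VDJArchitecture:
    """Junctional decomposition of one clonotype's CDR3."""

    d_name: str                 # "" when no D of >= min_d_match nt is found
    v_trunc: int
    j_trunc: int
    d5_trunc: Optional[int]
    d3_trunc: Optional[int]
    n1_seq: str
    n2_seq: str
    cdr3_len: int
    functional: bool
    d_ambiguous: bool = False


def _longest_d_match(junction: str, d_segments: Sequence[GermlineSegment],
                     min_d_match: int) -> tuple[Optional[GermlineSegment], int, int, int, bool]:
    """Longest contiguous exact D substring in the junction.

    Returns (segment, junction offset, offset in D, match length, ambiguous).
    Ties prefer the longer match, then D1 over D2 (genomic order), then the
    leftmost junction placement, then the leftmost placement within D.
    """
    segs = sorted(d_segments, key=lambda s: s.name)  # genomic order: D1 before D2
    candidates: list[tuple[int, int, int, int]] = []  # (length, rank, jpos, dpos)
    for rank, seg in enumerate(segs):
        d = seg.sequence
        for length in range(min(len(d), len(junction)), min_d_match - 1, -1):
            found = False
            for jpos in range(len(junction) - length + 1):
                sub = junction[jpos : jpos + length]
                dpos = d.find(sub)
                while dpos >= 0:
                    candidates.append((length, rank, jpos, dpos))
                    found = True
                    dpos = d.find(sub, dpos + 1)
            if found:
                break  # only the longest match per segment can win
    if not candidates:
        return None, -1, -1, 0, False
    max_len = max(c[0] for c in candidates)
    at_best = sorted(c for c in candidates if c[0] == max_len)
    length, rank, jpos, dpos = at_best[0][0], at_best[0][1], at_best[0][2], at_best[0][3]
    return segs[rank], jpos, dpos, length, len(at_best) > 1


def decompose_architecture(
    cdr3_nt: str,
    v: GermlineSegment,
    j: GermlineSegment,
    d_segments: Sequence[GermlineSegment],
    min_d_match: int = 5,
) -> VDJArchitecture:
    """Split a CDR3 into kept-V | N1 | kept-D | N2 | kept-J.

    The kept V part is the longest CDR3 prefix matching the germline V from
    its cysteine anchor; the kept J part is the longest suffix matching the
    germline J up to and including its phenylalanine codon.  The D segment is
    the longest contiguous exact germline-D substring of the remaining
    junction, requiring at least ``min_d_match`` nt; below that the whole
    junction is reported as N1.  Functionality = in-frame and stop-free in
    the anchor reading frame.
    """
    v_tail = v.sequence[v.anchor_offset :]
    j_head = j.sequence[: j.anchor_offset + 3]
    v_kept = 0
    while (v_kept < min(len(v_tail), len(cdr3_nt))
           and cdr3_nt[v_kept] == v_tail[v_kept]):
        v_kept += 1
    j_kept = 0
    while (j_kept < min(len(j_head), len(cdr3_nt) - v_kept)
           and cdr3_nt[len(cdr3_nt) - 1 - j_kept] == j_head[len(j_head) - 1 - j_kept]):
        j_kept += 1
    v_trunc = len(v_tail) - v_kept
    j_trunc = len(j_head) - j_kept
    junction = cdr3_nt[v_kept : len(cdr3_nt) - j_kept]
    seg, jpos, dpos, length, ambiguous = _longest_d_match(
        junction, d_segments, min_d_match
    )
    functional = is_functional(cdr3_nt)
    if seg is None:
        return VDJArchitecture("", v_trunc, j_trunc, None, None, junction, "",
                               len(cdr3_nt), functional)
    return VDJArchitecture(
        seg.name, v_trunc, j_trunc,
        dpos, len(seg.sequence) - dpos - length,
        junction[:jpos], junction[jpos + length :],
        len(cdr3_nt), functional, ambiguous,
    )


# ---------------------------------------------------------------------------
# End-to-end profiling
# ---------------------------------------------------------------------------

def profile_reads(
    pairs,
    registry: Sequence[GermlineSegment],
    config: RunConfig | None = None,
    sample: str = "sample",
) -> pd.DataFrame:
    """Full pipeline: join, assign, cluster, merge, cutoff, decompose.

    ``pairs`` is an iterable of (Read, Read).  Returns the clonotype table
    with architecture columns; deterministic for identical inputs.
    """
    cfg = config or RunConfig()
    by_kind = registry_by_kind(list(registry))
    n_pairs = n_joined = 0
    assigned_rows = []
    for r1, r2 in pairs:
        n_pairs += 1
        joined = join_read_pair(r1, r2, cfg.join_min_overlap, cfg.join_max_mismatch_frac)
        if joined is None:
            continue
        n_joined += 1
        hit = assign_v_j(joined, registry, cfg.assign_min_ident, cfg.assign_min_len)
        if hit is None:
            continue
        v_name, j_name, v_anchor, j_anchor = hit
        assigned_rows.append(
            dict(v_name=v_name, j_name=j_name, cdr3_nt=joined[v_anchor : j_anchor + 3])
        )
    logger.info("profile_reads[%s]: %d pairs, %d joined, %d assigned",
                sample, n_pairs, n_joined, len(assigned_rows))
    table = cluster_clonotypes(pd.DataFrame(assigned_rows))
    if cfg.cutoff_before_merge:
        table = apply_frequency_cutoff(table, cfg.clonotype_frequency_cutoff)
        table = merge_neighbor_clonotypes(table, cfg.merge_fold_threshold)
    else:
        table = merge_neighbor_clonotypes(table, cfg.merge_fold_threshold)
        table = apply_frequency_cutoff(table, cfg.clonotype_frequency_cutoff)
    seg_by_name = {s.name: s for s in registry}
    archs = []
    for _, row in table.iterrows():
        arch = decompose_architecture(
            row["cdr3_nt"], seg_by_name[row["v_name"]], seg_by_name[row["j_name"]],
            by_kind["D"], cfg.min_d_match,
        )
        archs.append(arch)
    table = table.copy()
    table["sample"] = sample
    table["d_name"] = [a.d_name for a in archs]
    table["cdr3_len"] = [a.cdr3_len for a in archs]
    table["v_trunc"] = [a.v_trunc for a in archs]
    table["j_trunc"] = [a.j_trunc for a in archs]
    table["d5_trunc"] = [float("nan") if a.d5_trunc is None else float(a.d5_trunc)
                         for a in archs]
    table["d3_trunc"] = [float("nan") if a.d3_trunc is None else float(a.d3_trunc)
                         for a in archs]
    table["n1_seq"] = [a.n1_seq for a in archs]
    table["n2_seq"] = [a.n2_seq for a in archs]
    table["n1_len"] = [len(a.n1_seq) for a in archs]
    table["n2_len"] = [len(a.n2_seq) for a in archs]
    table["functional"] = [a.functional for a in archs]
    table["d_ambiguous"] = [a.d_ambiguous for a in archs]
    cols = ["sample", "v_name", "d_name", "j_name", "cdr3_nt", "cdr3_len",
            "read_count", "frequency", "v_trunc", "d5_trunc", "d3_trunc",
            "j_trunc", "n1_seq", "n2_seq", "n1_len", "n2_len", "functional",
            "d_ambiguous"]
    return table[cols]
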