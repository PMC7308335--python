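"""Position weight matrices, normalized similarity scoring, stranded scanning,
and composite RSS (heptamer-spacer-nonamer) models.

The similarity score is the information-weighted normalized match score

    sim(w) = sum_i ci * f_i(w_i) / sum_i ci * max_b f_i(b),   ci = 2 + sum_b f_i(b) log2 f_i(b)

which is 1.0 exactly for the per-column-argmax consensus and lives in [0, 1].
A matrix match is a window whose similarity reaches the matrix threshold
(0.8 throughout the default configuration).  An RSS module is a heptamer match
and a nonamer match on the same strand separated by a spacer of 12+/-1 or
23+/-1 bp; eight module models arise from two heptamer matrices x two nonamer
matrices x two spacer classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io_core import Region, revcomp

__all__ = [
    "PWM",
    "MotifHit",
    "RSSModel",
    "RSSModuleHit",
    "build_pwm",
    "pwm_from_frequencies",
    "similarity",
    "scan",
    "scan_rss_modules",
    "consensus",
    "default_heptamer_pwms",
    "default_nonamer_pwms",
    "default_runx1_pwm",
    "default_rss_models",
    "write_pwm",
    "read_pwm",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _b, _i in _BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i

# Canonical RSS element seed sets (CACAGTG / ACAAAAACC orientation): the
# 3' RSS of the D segments and the 5' RSS of the J segments of the loci that
# carry D elements (TCRb, TCRd, IGH).  These ship as defaults and are
# user-replaceable through the matrix file format.
HEPTAMER_SEEDS_D3 = ("CACAGTG", "CACAATG", "CACGGTG", "CACAGCG")
HEPTAMER_SEEDS_J5 = ("CACTGTG", "CACAGTG", "CACAGTA", "CACTGTC")
NONAMER_SEEDS_D3 = ("ACAAAAACC", "GCAAAAACC", "ACATAAACC", "ACAAAAACA")
NONAMER_SEEDS_J5 = ("ACAAAAACC", "ACAAGAACC", "ACAAAAATC", "ACAAAAACT")


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class PWM:
    """Per-position base-frequency matrix with information weights (bits)."""

    name: str
    freqs: np.ndarray          # (width, 4), rows sum to 1
    weights: np.ndarray = field(init=False)
    max_col_freq: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        if freqs.ndim != 2 or freqs.shape[1] != 4 or freqs.shape[0] < 4:
            raise ValueError(f"{self.name}: frequency matrix must be (width>=4, 4)")
        if not np.allclose(freqs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"{self.name}: columns must each sum to 1")
        object.__setattr__(self, "freqs", freqs)
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
        weights = 2.0 + plogp.sum(axis=1)
        object.__setattr__(self, "weights", np.clip(weights, 0.0, 2.0))
        object.__setattr__(self, "max_col_freq", freqs.max(axis=1))

    @property
    def width(self) -> int:
        return self.freqs.shape[0]

    def reverse_complement(self) -> "PWM":
        return PWM(self.name, self.freqs[::-1, ::-1].copy())


@dataclass(frozen=True)
class MotifHit:
    """A scored matrix match within a region (region-local half-open coords).

    Minus-strand hits are scored on the reverse complement but reported in
    plus-strand coordinates.
    """

    start: int
    end: int
    strand: str
    score: float
    matrix_name: str
    region_ref: Optional[Region] = None

    def overlap(self, other: "MotifHit") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class RSSModel:
    """Composite heptamer-spacer-nonamer model."""

    name: str
    heptamer_matrix: PWM
    nonamer_matrix: PWM
    spacer_min: int
    spacer_max: int

    def __post_init__(self) -> None:
        if self.spacer_max - self.spacer_min != 2:
            raise ValueError("spacer class must span center +/- 1")


@dataclass(frozen=True)
class RSSModuleHit:
    heptamer_hit: MotifHit
    nonamer_hit: MotifHit
    spacer_len: int
    model_name: str
    strand: str


def build_pwm(seeds: Sequence[str], pseudocount: float = 0.01, name: str = "pwm") -> PWM:
    """Build a PWM from equal-length seed sequences.

    f[i][b] = (count + pseudocount) / (n + 4 * pseudocount) over the unique
    seeds; at least two unique seeds are required.
    """
    uniq = sorted(set(s.upper() for s in seeds))
    if len(uniq) < 2:
        raise ValueError("need >= 2 unique seed sequences")
    width = len(uniq[0])
    if any(len(s) != width for s in uniq):
        raise ValueError("seed sequences must all have the same length")
    if any(set(s) - set(_BASES) for s in uniq):
        raise ValueError("seed sequences must be ACGT only")
    counts = np.zeros((width, 4))
    for s in uniq:
        for i, b in enumerate(s):
            counts[i, _BASE_INDEX[b]] += 1
    freqs = (counts + pseudocount) / (len(uniq) + 4 * pseudocount)
    return PWM(name, freqs)


def pwm_from_frequencies(name: str, freqs: Sequence[Sequence[float]]) -> PWM:
    return PWM(name, np.asarray(freqs, dtype=float))


def consensus(pwm: PWM) -> str:
    """Per-column argmax sequence (ties broken toward A<C<G<T order)."""
    return "".join(_BASES[i] for i in pwm.freqs.argmax(axis=1))


def similarity(pwm: PWM, window: str) -> float:
    """Normalized information-weighted similarity of one window, in [0, 1].

    Windows containing non-ACGT characters, and any window against a matrix
    whose columns are all uninformative (zero total weight), score 0.
    """
    if len(window) != pwm.width:
        raise ValueError(f"window length {len(window)} != matrix width {pwm.width}")
    enc = _encode(window.upper())
    if (enc == 4).any():
        return 0.0
    norm = float(pwm.weights @ pwm.max_col_freq)
    if norm <= 0.0:
        return 0.0
    num = float((pwm.weights * pwm.freqs[np.arange(pwm.width), enc]).sum())
    return num / norm


def _score_all(arr: np.ndarray, pwm: PWM) -> np.ndarray:
    """Similarity of every window of ``arr`` (encoded sequence) against ``pwm``."""
    w = pwm.width
    n = arr.size - w + 1
    if n <= 0:
        return np.empty(0)
    norm = float(pwm.weights @ pwm.max_col_freq)
    smat = np.hstack([pwm.weights[:, None] * pwm.freqs, np.full((w, 1), -np.inf)])
    windows = np.lib.stride_tricks.sliding_window_view(arr, w)
    scores = smat[np.arange(w)[None, :], windows].sum(axis=1)
    if norm <= 0.0:
        return np.zeros(n)
    out = scores / norm
    return np.where(np.isfinite(out), out, 0.0)


def scan(region: Region, pwm: PWM, threshold: float, strands: str = "both") -> list[MotifHit]:
    """All matrix matches in a region at or above ``threshold``, both strands.

    Minus-strand windows are scored on their reverse complement and reported
    at plus-strand coordinates.  Output is sorted by (start, strand).
    """
    arr = _encode(region.sequence.upper())
    eps = 1e-9
    hits: list[MotifHit] = []
    todo = []
    if strands in ("both", "+"):
        todo.append(("+", pwm))
    if strands in ("both", "-"):
        todo.append(("-", pwm.reverse_complement()))
    for strand, mat in todo:
        scores = _score_all(arr, mat)
        for off in np.flatnonzero(scores >= threshold - eps):
            hits.append(
                MotifHit(int(off), int(off) + pwm.width, strand,
                         float(scores[off]), pwm.name, region)
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def scan_rss_modules(
    region: Region,
    models: Sequence[RSSModel],
    heptamer_threshold: float = 0.8,
    nonamer_threshold: float = 0.8,
) -> list[RSSModuleHit]:
    """RSS module hits: heptamer + same-strand nonamer at class spacer distance.

    The nonamer lies distal to the heptamer's 3' side in module orientation:
    downstream of the heptamer for plus-strand modules, upstream for minus.
    At most one hit is kept per (heptamer start, strand, model) - the one with
    the smallest spacer.
    """
    out: dict[tuple[int, str, str], RSSModuleHit] = {}
    pwm_hits: dict[str, list[MotifHit]] = {}

    def hits_for(pwm: PWM, threshold: float) -> list[MotifHit]:
        if pwm.name not in pwm_hits:
            pwm_hits[pwm.name] = scan(region, pwm, threshold)
        return pwm_hits[pwm.name]

    for model in models:
        hepts = hits_for(model.heptamer_matrix, heptamer_threshold)
        nonas = hits_for(model.nonamer_matrix, nonamer_threshold)
        for h in hepts:
            for n in nonas:
                if n.strand != h.strand:
                    continue
                spacer = n.start - h.end if h.strand == "+" else h.start - n.end
                if not model.spacer_min <= spacer <= model.spacer_max:
                    continue
                key = (h.start, h.strand, model.name)
                prev = out.get(key)
                if prev is None or spacer < prev.spacer_len:
                    out[key] = RSSModuleHit(h, n, spacer, model.name, h.strand)
    return sorted(out.values(), key=lambda m: (m.heptamer_hit.start, m.strand, m.model_name))


# ---------------------------------------------------------------------------
# Default matrices and models
# ---------------------------------------------------------------------------

def default_heptamer_pwms() -> tuple[PWM, PWM]:
    return (
        build_pwm(HEPTAMER_SEEDS_D3, name="heptamer_D3"),
        build_pwm(HEPTAMER_SEEDS_J5, name="heptamer_J5"),
    )


def default_nonamer_pwms() -> tuple[PWM, PWM]:
    return (
        build_pwm(NONAMER_SEEDS_D3, name="nonamer_D3"),
        build_pwm(NONAMER_SEEDS_J5, name="nonamer_J5"),
    )


def default_runx1_pwm() -> PWM:
    """11-column RUNX1 binding-site matrix: TGTGG core with a preferred T at
    the following position and weakly informative flanks (consensus
    AATGTGGTTTT).  Any user matrix in the same file format may replace it."""
    lo_a = [0.4, 0.2, 0.2, 0.2]
    lo_t = [0.2, 0.2, 0.2, 0.4]
    hi = {b: [0.95 if _BASES[i] == b else 0.05 / 3 for i in range(4)] for b in _BASES}
    mid_t = [0.1, 0.1, 0.1, 0.7]
    cols = [lo_a, lo_a, hi["T"], hi["G"], hi["T"], hi["G"], hi["G"], mid_t,
            lo_t, lo_t, lo_t]
    return pwm_from_frequencies("RUNX1_core11", cols)


def default_rss_models() -> list[RSSModel]:
    """The eight RSS models: 2 heptamer x 2 nonamer matrices x 2 spacer classes."""
    models = []
    for hept in default_heptamer_pwms():
        for nona in default_nonamer_pwms():
            for lo, hi in ((11, 13), (22, 24)):
                center = (lo + hi) // 2
                name = f"{hept.name}|{nona.name}|{center}"
                models.append(RSSModel(name, hept, nona, lo, hi))
    return models


# ---------------------------------------------------------------------------
# Matrix file format: header line '>name', then one tab-separated row per
# base (A, C, G, T) of per-position frequencies.
# ---------------------------------------------------------------------------

def write_pwm(pwm: PWM, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pwm.name}\n")
        for bi, base in enumerate(_BASES):
            vals = "\t".join(f"{v:.6f}" for v in pwm.freqs[:, bi])
            fh.write(f"{base}\t{vals}\n")


def read_pwm(path: str | Path) -> PWM:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith(">"):
            raise ValueError(f"{path}: matrix file must start with '>name'")
        name = header[1:].strip()
        rows = {}
        for line in fh:
            if not line.strip():
                continue
            base, *vals = line.split()
            rows[base] = [float(v) for v in vals]
    if set(rows) != set(_BASES):
        raise ValueError(f"{path}: need exactly one row per base A/C/G/T")
    freqs = np.array([[rows[b][i] for b in _BASES] for i in range(len(rows["A"]))])
    freqs = freqs / freqs.sum(axis=1, keepdims=True)  # tolerate count matrices
    return PWM(name, freqs)
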