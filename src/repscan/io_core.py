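"""Core I/O: germline registry, FASTQ pairs, BED-like regions, run configuration.

All genomic intervals in this package are 0-based half-open (BED convention);
conversion to 1-based display, where needed, happens only in report rendering.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import yaml
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger("repscan")

_VALID_BASES = frozenset("ACGT")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string."""
    return seq.translate(COMPLEMENT)[::-1]


class ParseError(ValueError):
    """Raised for malformed input files; message names the offending record."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RSSAnnotation:
    """Recombination signal sequence flanking a germline segment."""

    heptamer: str
    spacer: int
    nonamer: str
    side: str  # "5p" or "3p"

    def __post_init__(self) -> None:
        if self.side not in ("5p", "3p"):
            raise ValueError(f"RSS side must be '5p' or '3p', got {self.side!r}")
        if len(self.heptamer) != 7 or len(self.nonamer) != 9:
            raise ValueError("heptamer must be 7 nt and nonamer 9 nt")


@dataclass(frozen=True)
class GermlineSegment:
    """A germline V, D or J reference sequence.

    For V segments ``anchor_offset`` is the 0-based offset of the first base of
    the conserved cysteine codon; for J segments, of the conserved phenylalanine
    codon.  D segments carry no anchor.  ``cluster`` labels the J cluster
    (``J1``/``J2``) and is empty for V and D.
    """

    name: str
    kind: str  # "V", "D" or "J"
    sequence: str
    anchor_offset: Optional[int] = None
    rss: Optional[RSSAnnotation] = None
    cluster: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("V", "D", "J"):
            raise ValueError(f"kind must be V, D or J, got {self.kind!r}")
        if not self.sequence or set(self.sequence) - _VALID_BASES:
            raise ValueError(f"{self.name}: sequence must be non-empty uppercase ACGT")
        if self.kind in ("V", "J"):
            if self.anchor_offset is None:
                raise ValueError(f"{self.name}: {self.kind} segment requires an anchor")
            if not 0 <= self.anchor_offset or self.anchor_offset + 3 > len(self.sequence):
                raise ValueError(f"{self.name}: anchor codon out of bounds")
        else:
            if self.anchor_offset is not None:
                raise ValueError(f"{self.name}: D segments carry no anchor")
            if len(self.sequence) < 5:
                raise ValueError(f"{self.name}: D segment must be >= 5 nt")


@dataclass
class Region:
    """A half-open genomic interval with its sequence attached."""

    chrom: str
    start: int
    end: int
    sequence: str
    role: str = "other"
    border_position: Optional[int] = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.chrom}:{self.start}-{self.end}: start must be < end")
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"{self.chrom}:{self.start}-{self.end}: sequence length "
                f"{len(self.sequence)} != interval length {self.end - self.start}"
            )
        if self.border_position is not None and not (
            self.start <= self.border_position <= self.end
        ):
            raise ValueError("border_position outside the region")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class RunConfig:
    """Every tunable constant of the two analysis arms, in one flat document.

    Defaults are the operating points of the published procedure: a 0.001%
    clonotype-frequency cutoff, a 20-fold threshold for merging 1-bp neighbour
    clonotypes, a 5-nt minimum D-segment match, 0.8 matrix-similarity
    thresholds, 7-nt heptamer windows, a 4-nt minimum RUNX1/heptamer overlap,
    12+/-1 and 23+/-1 bp RSS spacer classes and 60-bp deletion-end spans.
    """

    clonotype_frequency_cutoff: float = 1e-5
    merge_fold_threshold: float = 20.0
    min_d_match: int = 5
    similarity_threshold_runx1: float = 0.8
    similarity_threshold_heptamer: float = 0.8
    similarity_threshold_nonamer: float = 0.8
    window_flank: int = 7
    min_runx1_heptamer_overlap: int = 4
    spacer_class_12: tuple[int, int] = (11, 13)
    spacer_class_23: tuple[int, int] = (22, 24)
    partial_spacer_classes: tuple[tuple[int, int], ...] = ((12, 12), (19, 25))
    region_inner_span: int = 60
    join_min_overlap: int = 10
    join_max_mismatch_frac: float = 0.25
    assign_min_ident: float = 0.9
    assign_min_len: int = 15
    cutoff_before_merge: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for f in (
            "clonotype_frequency_cutoff",
            "similarity_threshold_runx1",
            "similarity_threshold_heptamer",
            "similarity_threshold_nonamer",
        ):
            v = getattr(self, f)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{f} must be in (0, 1], got {v}")
        for f in ("min_d_match", "window_flank", "min_runx1_heptamer_overlap",
                  "region_inner_span", "join_min_overlap", "assign_min_len"):
            v = getattr(self, f)
            if int(v) != v or v <= 0:
                raise ValueError(f"{f} must be a positive integer, got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ParseError(f"unknown config keys: {sorted(unknown)}")
        for key in ("spacer_class_12", "spacer_class_23"):
            if key in doc:
                doc[key] = tuple(doc[key])
        if "partial_spacer_classes" in doc:
            doc["partial_spacer_classes"] = tuple(
                tuple(x) for x in doc["partial_spacer_classes"]
            )
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["spacer_class_12"] = list(self.spacer_class_12)
        doc["spacer_class_23"] = list(self.spacer_class_23)
        doc["partial_spacer_classes"] = [list(x) for x in self.partial_spacer_classes]
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Read:
    name: str
    sequence: str
    qualities: tuple[int, ...]


def _iter_fastq(path: str | Path) -> Iterator[Read]:
    count = 0
    try:
        with open(path) as fh:
            for title, seq, qual in FastqGeneralIterator(fh):
                count += 1
                if len(seq) != len(qual):
                    raise ParseError(
                        f"{path}: record {count}: sequence and quality lengths differ"
                    )
                yield Read(title.split()[0], seq.upper(),
                           tuple(ord(c) - 33 for c in qual))
    except ValueError as exc:
        if isinstance(exc, ParseError):
            raise
        raise ParseError(f"{path}: record {count + 1}: {exc}") from exc


def read_fastq_pairs(path_r1: str | Path, path_r2: str | Path) -> Iterator[tuple[Read, Read]]:
    """Stream matched read pairs from two Phred+33 FASTQ files.

    Raises :class:`ParseError` naming the record index on truncated records or
    when the two files hold different numbers of records.
    """
    it1, it2 = _iter_fastq(path_r1), _iter_fastq(path_r2)
    idx = 0
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        idx += 1
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            short = path_r1 if r1 is None else path_r2
            raise ParseError(f"{short}: record {idx}: mate file exhausted early")
        yield r1, r2


# ---------------------------------------------------------------------------
# Genome FASTA and BED-like regions
# ---------------------------------------------------------------------------

def read_genome(path: str | Path) -> dict[str, str]:
    """Load a (small) genome FASTA into an upper-case in-memory dict."""
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    logger.info("read_genome: %d sequences from %s", len(genome), path)
    return genome


def write_genome(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_regions(path: str | Path, genome: dict[str, str], role: str = "other") -> list[Region]:
    """Read a BED-like file (chrom, start, end[, name]) and attach sequences."""
    regions: list[Region] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(f"{path}: line {lineno}: expected >= 3 columns")
            chrom, s, e = parts[0], parts[1], parts[2]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if start >= end:
                raise ParseError(f"{path}: line {lineno}: start {start} >= end {end}")
            if chrom not in genome:
                raise ParseError(f"{path}: line {lineno}: chrom {chrom!r} not in genome")
            if end > len(genome[chrom]):
                raise ParseError(
                    f"{path}: line {lineno}: end {end} beyond {chrom} "
                    f"length {len(genome[chrom])}"
                )
            name = parts[3] if len(parts) > 3 else ""
            regions.append(
                Region(chrom, start, end, genome[chrom][start:end], role=role, name=name)
            )
    logger.info("read_regions: %d regions from %s", len(regions), path)
    return regions


def write_regions(regions: Sequence[Region], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name or r.role}\n")


# ---------------------------------------------------------------------------
# Germline registry
# ---------------------------------------------------------------------------

_REGISTRY_COLUMNS = (
    "name", "kind", "sequence", "anchor_offset", "cluster",
    "rss_heptamer", "rss_spacer", "rss_nonamer", "rss_side",
)

# Fixed primer-landing sequences used by the amplicon design of the read
# simulator; they flank the V...J insert on either side.
PRIMER_5 = "GATCCTACGGCAGTCA"
PRIMER_3 = "TGCACGTTAGCCGATA"

# Toy TCRb-like locus used throughout the test-suite: 4 V, the two mouse D
# segments, and 6 J in two clusters.  V bodies are arbitrary fixed sequences;
# each V ends in a conserved-cysteine tail and each J carries a conserved
# phenylalanine codon at offset 12.  Real (IMGT-derived) references are
# supplied by the user in the same tabular format.
_BUILTIN_ROWS: tuple[tuple, ...] = (
    ("TRBV1", "V", "TGGTGTTAACCTTACTATACTCCCGCTCCGGGG" "TGTGCCAGCAGT", 33,
     "", "CACAGTG", 23, "ACAAAAACC", "3p"),
    ("TRBV2", "V", "TTTGGCTCATATGAACAAGTCTTTGCGCCCATA" "TGCACCAGCAGC", 33,
     "", "CACAGTG", 23, "ACAAAAACC", "3p"),
    ("TRBV3", "V", "AATGTAGCCAGTGAGCTTAGTTGGAGCAAGGGG" "TGTGCCTCCAGC", 33,
     "", "CACAGTG", 23, "ACAAAAACC", "3p"),
    ("TRBV4", "V", "TGCGGAAGCGCAACTCCGTCGCGCGGGTAGCCA" "TGCAGTGCTGAA", 33,
     "", "CACAGTG", 23, "ACAAAAACC", "3p"),
    ("TRBD1", "D", "GGGACAGGGGGC", None, "", "CACAGTG", 23, "ACAAAAACC", "3p"),
    ("TRBD2", "D", "GGGACTGGGGGGGC", None, "", "CACAATG", 23, "ACAAAAACC", "3p"),
    ("TRBJ1-1", "J", "ACTACTTAAGAC" "TTCGGTGGAACCACTGAG", 12, "J1",
     "CACTGTG", 12, "GGTTTTTGT", "5p"),
    ("TRBJ1-2", "J", "CTAGGATTCTGT" "TTTGGCGGAACGTCCTAG", 12, "J1",
     "CACTGTG", 12, "GGTTTTTGT", "5p"),
    ("TRBJ1-3", "J", "TGCAGATTAGAA" "TTCGGCGGTACAGGATCC", 12, "J1",
     "CACTGTG", 12, "GGTTTTTGT", "5p"),
    ("TRBJ2-1", "J", "CTTGGGACTCAA" "TTCGGTGGTTCCCAGTAC", 12, "J2",
     "CACTGTG", 12, "GGTTTTTGT", "5p"),
    ("TRBJ2-2", "J", "GATTGCTGCCCT" "TTTGGAGGAACGTTCAGA", 12, "J2",
     "CACTGTG", 12, "GGTTTTTGT", "5p"),
    ("TRBJ2-3", "J", "AAGCTATACTAG" "TTCGGGGGAACAACCTGA", 12, "J2",
     "CACTGTG", 12, "GGTTTTTGT", "5p"),
)


def _segment_from_row(row: Sequence) -> GermlineSegment:
    name, kind, seq, anchor, cluster, hept, spacer, nona, side = row
    rss = None
    if hept:
        rss = RSSAnnotation(hept, int(spacer), nona, side)
    anchor = None if anchor in (None, "", "NA") else int(anchor)
    return GermlineSegment(name, kind, seq, anchor, rss, cluster or "")


def load_germline_registry(path: str | Path | None = "builtin") -> list[GermlineSegment]:
    """Load germline segments from a registry TSV, or the packaged toy locus.

    The tabular format has the columns ``name kind sequence anchor_offset
    cluster rss_heptamer rss_spacer rss_nonamer rss_side`` with ``NA`` for
    absent values; it is deliberately version-agnostic so that any IMGT
    release can be exported into it.
    """
    if path in (None, "builtin"):
        return [_segment_from_row(r) for r in _BUILTIN_ROWS]
    segments: list[GermlineSegment] = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if tuple(header) != _REGISTRY_COLUMNS:
            raise ParseError(f"{path}: bad registry header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(_REGISTRY_COLUMNS):
                raise ParseError(f"{path}: line {lineno}: wrong column count")
            name, kind, seq, anchor, cluster, hept, spacer, nona, side = parts
            row = (name, kind, seq,
                   None if anchor == "NA" else int(anchor),
                   "" if cluster == "NA" else cluster,
                   "" if hept == "NA" else hept,
                   0 if spacer == "NA" else int(spacer),
                   "" if nona == "NA" else nona,
                   "" if side == "NA" else side)
            try:
                segments.append(_segment_from_row(row))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    logger.info("load_germline_registry: %d segments from %s", len(segments), path)
    return segments


def write_germline_registry(segments: Sequence[GermlineSegment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_REGISTRY_COLUMNS) + "\n")
        for s in segments:
            rss = s.rss
            fh.write("\t".join([
                s.name, s.kind, s.sequence,
                "NA" if s.anchor_offset is None else str(s.anchor_offset),
                s.cluster or "NA",
                rss.heptamer if rss else "NA",
                str(rss.spacer) if rss else "NA",
                rss.nonamer if rss else "NA",
                rss.side if rss else "NA",
            ]) + "\n")


def registry_by_kind(segments: Sequence[GermlineSegment]) -> dict[str, list[GermlineSegment]]:
    out: dict[str, list[GermlineSegment]] = {"V": [], "D": [], "J": []}
    for s in segments:
        out[s.kind].append(s)
    return out
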