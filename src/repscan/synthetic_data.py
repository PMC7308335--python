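"""Synthetic repertoires, reads, genomes and deletion cohorts.

The repertoire generator draws V(D)J rearrangements with known junctional
architecture: segment choice (including the D1-vs-D2 probability), geometric
exonucleolytic truncation of segment ends, Poisson-length non-templated N
regions with i.i.d. uniform bases, and Zipf-distributed clone sizes.  The
genome generator plants heptamer / nonamer / RUNX1 motif instances (matrix
consensus sequences) at controlled, recorded positions in i.i.d. background
sequence.  Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .io_core import (
    PRIMER_3,
    PRIMER_5,
    GermlineSegment,
    registry_by_kind,
    revcomp,
)
from . import motif_engine as me

logger = logging.getLogger("repscan")

_BASES = np.array(list("ACGT"))

STOP_CODONS = {"TAA", "TAG", "TGA"}

# Plus-strand template in which a minus-strand RUNX1 site (window [0, 11),
# consensus AATGTGGTTTT up to one low-weight flank base) overlaps the
# heptamer CACAGTG at [5, 12) by 6 nt.
RUNX1_HEPTAMER_TEMPLATE = "AAAACCACAGTG"
RUNX1_TEMPLATE_RUNX1_OFFSET = 0
RUNX1_TEMPLATE_HEPT_OFFSET = 5


@dataclass(frozen=True)
class RepertoireSimParams:
    """Knobs of the repertoire generator.

    Truncation means are in nucleotides (geometric laws supported on 0, 1,
    ...); ``n_len_mean`` is the Poisson mean applied independently to N1 and
    N2; ``clone_size_shape`` is the Zipf exponent of the clone-abundance law;
    ``functional_fraction``, when set, rebalances the repertoire to the given
    fraction of functional (in-frame, stop-free) clonotypes, emulating
    thymic selection pressure.
    """

    n_clonotypes: int = 2000
    p_d2: float = 0.3
    v_trunc_mean: float = 2.0
    j_trunc_mean: float = 2.0
    d5_trunc_mean: float = 2.0
    d3_trunc_mean: float = 1.0
    n_len_mean: float = 2.5
    clone_size_shape: float = 1.3
    read_depth: int = 50_000
    error_rate: float = 0.001
    functional_fraction: Optional[float] = None
    min_d_match: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_d2 <= 1.0:
            raise ValueError(f"p_d2 must be in [0, 1], got {self.p_d2}")
        if not 0.0 <= self.error_rate <= 0.1:
            raise ValueError(f"error_rate must be in [0, 0.1], got {self.error_rate}")
        for f in ("v_trunc_mean", "j_trunc_mean", "d5_trunc_mean",
                  "d3_trunc_mean", "n_len_mean"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        if self.n_clonotypes < 1:
            raise ValueError("n_clonotypes must be >= 1")


@dataclass(frozen=True)
class GenomeSimParams:
    """Synthetic background genome with planted motif instances."""

    length: int = 100_000
    gc: float = 0.41
    n_planted_rss: int = 0
    n_planted_runx1_overlap: int = 0
    n_planted_lone_heptamer: int = 0
    seed: int = 0
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        if self.length < 1000:
            raise ValueError("genome length must be >= 1000")
        if min(self.n_planted_rss, self.n_planted_runx1_overlap,
               self.n_planted_lone_heptamer) < 0:
            raise ValueError("planted counts must be >= 0")


def _geometric0(rng: np.random.Generator, mean: float, size: int) -> np.ndarray:
    """Geometric on {0, 1, ...} with the given mean."""
    if mean <= 0:
        return np.zeros(size, dtype=int)
    return rng.geometric(1.0 / (1.0 + mean), size) - 1


def _random_bases(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return "".join(_BASES[rng.integers(0, 4, n)])


def is_functional(cdr3: str) -> bool:
    """In-frame (length divisible by 3) and stop-free in the anchor frame."""
    if len(cdr3) % 3 != 0:
        return False
    return not any(cdr3[i : i + 3] in STOP_CODONS for i in range(0, len(cdr3), 3))


def _check_trunc_caps(params: RepertoireSimParams,
                      by_kind: dict[str, list[GermlineSegment]]) -> None:
    v_cap = min(len(v.sequence) - v.anchor_offset - 3 for v in by_kind["V"])
    j_cap = min(j.anchor_offset for j in by_kind["J"])
    d_cap = min(len(d.sequence) for d in by_kind["D"])
    if params.v_trunc_mean > v_cap:
        raise ValueError(f"v_trunc_mean {params.v_trunc_mean} exceeds V cap {v_cap}")
    if params.j_trunc_mean > j_cap:
        raise ValueError(f"j_trunc_mean {params.j_trunc_mean} exceeds J cap {j_cap}")
    if params.d5_trunc_mean > d_cap or params.d3_trunc_mean > d_cap:
        raise ValueError("D truncation mean exceeds D segment length")


def _draw_clonotypes(rng: np.random.Generator, m: int, params: RepertoireSimParams,
                     by_kind: dict[str, list[GermlineSegment]]) -> list[dict]:
    vs, ds, js = by_kind["V"], by_kind["D"], by_kind["J"]
    d1 = next(d for d in ds if "D1" in d.name)
    d2 = next(d for d in ds if "D2" in d.name)
    vi = rng.integers(0, len(vs), m)
    ji = rng.integers(0, len(js), m)
    use_d2 = rng.random(m) < params.p_d2
    vt = _geometric0(rng, params.v_trunc_mean, m)
    jt = _geometric0(rng, params.j_trunc_mean, m)
    d5 = _geometric0(rng, params.d5_trunc_mean, m)
    d3 = _geometric0(rng, params.d3_trunc_mean, m)
    n1l = rng.poisson(params.n_len_mean, m)
    n2l = rng.poisson(params.n_len_mean, m)
    rows = []
    for k in range(m):
        v, j = vs[vi[k]], js[ji[k]]
        d = d2 if use_d2[k] else d1
        v_trunc = int(min(vt[k], len(v.sequence) - v.anchor_offset - 3))
        j_trunc = int(min(jt[k], j.anchor_offset))
        d5_trunc = int(min(d5[k], len(d.sequence)))
        d3_trunc = int(min(d3[k], len(d.sequence) - d5_trunc))
        kept_d = d.sequence[d5_trunc : len(d.sequence) - d3_trunc]
        n1 = _random_bases(rng, int(n1l[k]))
        n2 = _random_bases(rng, int(n2l[k]))
        v_part = v.sequence[v.anchor_offset : len(v.sequence) - v_trunc]
        j_part = j.sequence[j_trunc : j.anchor_offset + 3]
        cdr3 = v_part + n1 + kept_d + n2 + j_part
        if len(kept_d) >= params.min_d_match:
            row = dict(v_name=v.name, d_name=d.name, j_name=j.name,
                       v_trunc=v_trunc, j_trunc=j_trunc,
                       d5_trunc=float(d5_trunc), d3_trunc=float(d3_trunc),
                       n1_seq=n1, n2_seq=n2)
        else:
            # The D remnant is too short to call: the whole junction reads as
            # a single non-templated stretch, exactly as the profiler sees it.
            row = dict(v_name=v.name, d_name="", j_name=j.name,
                       v_trunc=v_trunc, j_trunc=j_trunc,
                       d5_trunc=float("nan"), d3_trunc=float("nan"),
                       n1_seq=n1 + kept_d + n2, n2_seq="")
        row.update(cdr3_nt=cdr3, cdr3_len=len(cdr3), functional=is_functional(cdr3))
        rows.append(row)
    return rows


def simulate_repertoire(params: RepertoireSimParams,
                        registry: Sequence[GermlineSegment]) -> pd.DataFrame:
    """Generate a truth table of unique clonotypes with full architecture.

    Returns one row per clonotype with the same architecture columns the
    profiling pipeline emits, plus the generating truth (``n1_seq``,
    ``n2_seq``) and a ``frequency`` column from the Zipf clone-size law.
    """
    by_kind = registry_by_kind(list(registry))
    _check_trunc_caps(params, by_kind)
    rng = np.random.default_rng(params.seed)
    want_func = params.functional_fraction
    n = params.n_clonotypes
    if want_func is not None:
        n_func_target = int(round(want_func * n))
        pools: dict[bool, list[dict]] = {True: [], False: []}
    seen: set[tuple[str, str, str]] = set()
    accepted: list[dict] = []
    for _ in range(200):
        if want_func is None and len(accepted) >= n:
            break
        if want_func is not None and (
            len(pools[True]) >= n_func_target
            and len(pools[False]) >= n - n_func_target
        ):
            break
        batch = _draw_clonotypes(rng, max(2 * n, 200), params, by_kind)
        for row in batch:
            key = (row["v_name"], row["j_name"], row["cdr3_nt"])
            if key in seen:
                continue
            seen.add(key)
            if want_func is None:
                accepted.append(row)
            else:
                pools[row["functional"]].append(row)
    else:
        raise RuntimeError("could not generate the requested repertoire size")
    if want_func is not None:
        accepted = pools[True][:n_func_target] + pools[False][: n - n_func_target]
    accepted = accepted[:n]
    order = rng.permutation(len(accepted))
    rows = [accepted[i] for i in order]
    weights = np.arange(1, len(rows) + 1, dtype=float) ** (-params.clone_size_shape)
    weights /= weights.sum()
    df = pd.DataFrame(rows)
    df["frequency"] = weights
    df["n1_len"] = df["n1_seq"].str.len()
    df["n2_len"] = df["n2_seq"].str.len()
    df["d_ambiguous"] = False
    logger.info("simulate_repertoire: %d clonotypes (seed %d)", len(df), params.seed)
    return df


def amplicon_sequence(row: pd.Series | dict,
                      by_kind: dict[str, list[GermlineSegment]]) -> str:
    """Primer-flanked amplicon: 5' landing + V body + CDR3 + J tail + 3' landing."""
    v = next(s for s in by_kind["V"] if s.name == row["v_name"])
    j = next(s for s in by_kind["J"] if s.name == row["j_name"])
    return (PRIMER_5 + v.sequence[: v.anchor_offset] + row["cdr3_nt"]
            + j.sequence[j.anchor_offset + 3 :] + PRIMER_3)


def reads_from_repertoire(
    truth: pd.DataFrame,
    params: RepertoireSimParams,
    registry: Sequence[GermlineSegment],
    path_r1: str | Path,
    path_r2: str | Path,
    read_length: int = 150,
    min_overlap: int = 10,
    base_quality: int = 35,
) -> None:
    """Write paired FASTQ files for a truth repertoire.

    Read counts per clonotype are multinomial over the truth frequencies;
    substitution errors are i.i.d. per base at ``error_rate``; R2 is the
    reverse-complement strand.  Byte-identical output for identical seeds.
    """
    by_kind = registry_by_kind(list(registry))
    rng = np.random.default_rng(params.seed + 1)
    qual = chr(base_quality + 33)
    amplicons = [amplicon_sequence(row, by_kind) for _, row in truth.iterrows()]
    limit = 2 * read_length - min_overlap
    for amp in amplicons:
        if len(amp) > limit:
            raise ValueError(
                f"amplicon length {len(amp)} exceeds 2x{read_length} - "
                f"{min_overlap} overlap design"
            )
    if params.read_depth > 0:
        counts = rng.multinomial(params.read_depth, truth["frequency"].to_numpy())
    else:
        counts = np.zeros(len(truth), dtype=int)

    def mutate(seq: str) -> str:
        if params.error_rate <= 0:
            return seq
        n_err = rng.binomial(len(seq), params.error_rate)
        if n_err == 0:
            return seq
        pos = rng.choice(len(seq), size=n_err, replace=False)
        chars = list(seq)
        for p in pos:
            alt = "ACGT".replace(chars[p], "")
            chars[p] = alt[rng.integers(0, 3)]
        return "".join(chars)

    with open(path_r1, "w") as f1, open(path_r2, "w") as f2:
        for ci, (amp, cnt) in enumerate(zip(amplicons, counts)):
            fwd = amp[:read_length]
            rev = revcomp(amp)[:read_length]
            for rep in range(int(cnt)):
                name = f"clon{ci}_{rep}"
                r1, r2 = mutate(fwd), mutate(rev)
                f1.write(f"@{name}/1\n{r1}\n+\n{qual * len(r1)}\n")
                f2.write(f"@{name}/2\n{r2}\n+\n{qual * len(r2)}\n")
    logger.info("reads_from_repertoire: %d pairs -> %s / %s",
                int(counts.sum()), path_r1, path_r2)


# ---------------------------------------------------------------------------
# Knockout-style cohorts
# ---------------------------------------------------------------------------

# Genotype presets emulating the thymic repertoire shifts of a RUNX1-null
# hematopoietic knockout relative to wildtype (heterozygous == wildtype):
# ~4-fold lower richness, functional:non-functional ratio dropping from ~2.9
# to ~1 (i.e. ~50% non-functional), 1.2-fold longer N regions, 1.2-fold more
# *measured* 5' D truncation (the knockout d5 mean is calibrated upward to
# 2.8 because truncation is only measurable on clonotypes whose D remnant
# stays callable, which trims the upper tail), and a 2.5-fold higher
# *measured* D1/D2 usage ratio (knockout p_d2 = 0.2, i.e. input odds 4.0
# rather than 2.5 x 1.5 = 3.75, compensating the differential dropout of the
# shorter D1 under heavier truncation).
GENOTYPE_PRESETS: dict[str, dict] = {
    "wildtype": dict(n_clonotypes=2000, p_d2=0.4, v_trunc_mean=2.0,
                     j_trunc_mean=2.0, d5_trunc_mean=2.0, d3_trunc_mean=1.0,
                     n_len_mean=2.5, functional_fraction=0.745),
    "heterozygous": dict(n_clonotypes=2000, p_d2=0.4, v_trunc_mean=2.0,
                         j_trunc_mean=2.0, d5_trunc_mean=2.0, d3_trunc_mean=1.0,
                         n_len_mean=2.5, functional_fraction=0.745),
    "knockout": dict(n_clonotypes=500, p_d2=0.2, v_trunc_mean=2.4,
                     j_trunc_mean=2.2, d5_trunc_mean=2.8, d3_trunc_mean=1.0,
                     n_len_mean=3.0, functional_fraction=0.5),
}


def simulate_cohort(
    genotype: str,
    n_samples: int,
    registry: Sequence[GermlineSegment],
    seed: int = 0,
    richness_cv: float = 0.15,
    overrides: Optional[dict] = None,
) -> list[pd.DataFrame]:
    """Simulate a cohort of per-sample truth repertoires for one genotype.

    Per-sample clonotype counts vary log-normally around the preset with
    coefficient of variation ``richness_cv``; all other parameters are the
    genotype preset values (optionally overridden).
    """
    preset = dict(GENOTYPE_PRESETS[genotype])
    preset.update(overrides or {})
    base_n = preset.pop("n_clonotypes")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log(1.0 + richness_cv**2))
    mu = math.log(base_n) - sigma**2 / 2.0
    tables = []
    for i in range(n_samples):
        n_i = max(50, int(round(rng.lognormal(mu, sigma))))
        params = RepertoireSimParams(
            n_clonotypes=n_i, seed=int(rng.integers(0, 2**31 - 1)), **preset)
        tables.append(simulate_repertoire(params, registry))
    return tables


# ---------------------------------------------------------------------------
# Genomes with planted motifs
# ---------------------------------------------------------------------------

def _planted_templates(rng: np.random.Generator) -> dict[str, tuple[str, int, int]]:
    """class -> (template sequence, heptamer offset, runx1 offset or -1)."""
    hept = me.consensus(me.default_heptamer_pwms()[0])
    nona = me.consensus(me.default_nonamer_pwms()[0])
    spacer = _random_bases(rng, 12)
    spacer2 = _random_bases(rng, 12)
    return {
        "rss": (hept + spacer + nona, 0, -1),
        "rss_runx1": (RUNX1_HEPTAMER_TEMPLATE + spacer2 + nona,
                      RUNX1_TEMPLATE_HEPT_OFFSET, RUNX1_TEMPLATE_RUNX1_OFFSET),
        "lone_heptamer": (hept, 0, -1),
    }


def _place_nonoverlapping(rng: np.random.Generator, length: int,
                          sizes: list[int], margin: int = 25) -> list[int]:
    """Random non-overlapping placements; raises if the genome is too crowded."""
    taken: list[tuple[int, int]] = []
    out = []
    for size in sizes:
        for _ in range(2000):
            pos = int(rng.integers(margin, length - size - margin))
            if all(pos + size + margin <= s or pos >= e + margin for s, e in taken):
                taken.append((pos, pos + size))
                out.append(pos)
                break
        else:
            raise ValueError("cannot place planted sites without overlap")
    return out


def simulate_genome(params: GenomeSimParams) -> tuple[dict[str, str], pd.DataFrame]:
    """Background genome with planted motif instances.

    Returns the genome dict and a truth table with one row per planted site:
    chrom, start, end (template span), class, strand, hept_start, runx1_start
    (absolute positions; -1 when the class has no RUNX1 site).
    """
    rng = np.random.default_rng(params.seed)
    p = np.array([(1 - params.gc) / 2, params.gc / 2, params.gc / 2, (1 - params.gc) / 2])
    seq = rng.choice(_BASES, size=params.length, p=p)
    templates = _planted_templates(rng)
    plan = (["rss"] * params.n_planted_rss
            + ["rss_runx1"] * params.n_planted_runx1_overlap
            + ["lone_heptamer"] * params.n_planted_lone_heptamer)
    sizes = [len(templates[c][0]) for c in plan]
    positions = _place_nonoverlapping(rng, params.length, sizes)
    records = []
    for cls, pos in zip(plan, positions):
        template, h_off, r_off = templates[cls]
        strand = "+" if rng.random() < 0.5 else "-"
        planted = template if strand == "+" else revcomp(template)
        seq[pos : pos + len(template)] = list(planted)
        if strand == "+":
            h_abs = pos + h_off
            r_abs = pos + r_off if r_off >= 0 else -1
        else:
            h_abs = pos + len(template) - h_off - 7
            r_abs = pos + len(template) - r_off - 11 if r_off >= 0 else -1
        records.append(dict(chrom=params.chrom, start=pos, end=pos + len(template),
                            cls=cls, strand=strand, hept_start=h_abs,
                            runx1_start=r_abs))
    truth = pd.DataFrame(
        records, columns=["chrom", "start", "end", "cls", "strand",
                          "hept_start", "runx1_start"])
    genome = {params.chrom: "".join(seq)}
    logger.info("simulate_genome: %d bp, %d planted sites (seed %d)",
                params.length, len(truth), params.seed)
    return genome, truth


DistanceLaw = tuple | Callable[[np.random.Generator], int]


def _draw_distance(law: DistanceLaw, rng: np.random.Generator) -> int:
    if callable(law):
        return int(law(rng))
    kind = law[0]
    if kind == "constant":
        return int(law[1])
    if kind == "uniform":
        return int(rng.integers(law[1], law[2] + 1))
    raise ValueError(f"unknown distance law {law!r}")


def simulate_deletion_cohort(
    genome: dict[str, str],
    n_deletions: int,
    enriched_fraction: float,
    distance_law: DistanceLaw = ("constant", 6),
    seed: int = 0,
    deletion_length: int = 400,
    inner_span: int = 60,
    flank: int = 7,
    plant_kind: str = "heptamer",
) -> tuple[dict[str, str], list[tuple[str, int, int]], pd.DataFrame]:
    """Plant RUNX1-overlapping heptamers at deletion borders.

    For the enriched fraction of deletions one randomly chosen end carries a
    planted RUNX1-overlapping heptamer (``plant_kind="rss"`` adds a
    12-spacer and nonamer, making it a full RSS module) at a border distance
    drawn from ``distance_law``; the remaining ends are untouched background.
    Returns the modified genome, the deletion intervals, and a truth table of
    planted sites.
    """
    rng = np.random.default_rng(seed)
    chrom = max(genome, key=lambda c: len(genome[c]))
    seq = list(genome[chrom])
    length = len(seq)
    gap = 2 * (inner_span + flank) + 20
    need = n_deletions * (deletion_length + gap)
    if need > length - 2 * gap:
        raise ValueError("genome too short for the requested deletion cohort")
    starts = _place_nonoverlapping(rng, length, [deletion_length] * n_deletions,
                                   margin=gap)
    starts.sort()
    deletions = [(chrom, s, s + deletion_length) for s in starts]
    n_enriched = int(round(enriched_fraction * n_deletions))
    enriched = set(rng.choice(n_deletions, size=n_enriched, replace=False).tolist())
    nona = me.consensus(me.default_nonamer_pwms()[0])
    records = []
    for i, (_, dstart, dend) in enumerate(deletions):
        if i not in enriched:
            continue
        template = RUNX1_HEPTAMER_TEMPLATE
        if plant_kind == "rss":
            template = template + _random_bases(rng, 12) + nona
        dist = _draw_distance(distance_law, rng)
        side = "5p" if rng.random() < 0.5 else "3p"
        border = dstart if side == "5p" else dend
        if side == "5p":
            # Template reads into the deleted interval; RUNX1 window at its 5' end.
            plant_start = border + dist
            planted = template
            runx1_abs = plant_start
        else:
            # Mirrored at the 3' border: RUNX1 window at the template's far end.
            plant_start = border - dist - len(template) + 11
            planted = revcomp(template)
            runx1_abs = plant_start + len(template) - 11
        lo = border - flank if side == "5p" else border - inner_span
        hi = lo + inner_span + flank
        if plant_start < lo or plant_start + len(template) > hi:
            raise ValueError(
                f"distance {dist} places the {len(template)}-nt template outside "
                f"the {inner_span + flank}-bp end region"
            )
        seq[plant_start : plant_start + len(template)] = list(planted)
        records.append(dict(deletion=i, side=side, border=border,
                            runx1_start=runx1_abs,
                            distance=abs(runx1_abs - border), cls=plant_kind))
    truth = pd.DataFrame(records, columns=["deletion", "side", "border",
                                           "runx1_start", "distance", "cls"])
    out_genome = dict(genome)
    out_genome[chrom] = "".join(seq)
    logger.info("simulate_deletion_cohort: %d deletions, %d planted (seed %d)",
                n_deletions, len(truth), seed)
    return out_genome, deletions, truth
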