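"""Deletion-border and ChIP-peak RUNX1/RSS enrichment analyses.

Builds 67-bp deletion-end regions (60 bp of deletion end + 7 bp flank),
extracts +/-7-nt windows around heptamer matches (merged when overlapping by
at least 1 nt), counts windows whose heptamer overlaps a RUNX1 match by at
least 4 nt, and compares foreground counts against a whole-genome background
with fold, continuity-corrected Z-score and exact binomial tail (or a seeded
resampling alternative).  Also classifies each RUNX1 hit by its spatial
relation to heptamers/RSS modules and its distance to the deletion border.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_core import Region, RunConfig
from .motif_engine import (
    MotifHit,
    PWM,
    RSSModel,
    RSSModuleHit,
    default_rss_models,
    default_runx1_pwm,
    scan,
    scan_rss_modules,
)
from .stats_core import binomial_lower_tail, binomial_upper_tail, z_score

logger = logging.getLogger("repscan")

__all__ = [
    "RegionHits",
    "HeptamerWindow",
    "EnrichmentResult",
    "BackgroundStats",
    "compute_region_hits",
    "build_deletion_end_regions",
    "extract_heptamer_windows",
    "count_runx1_overlaps",
    "background_window_stats",
    "enrichment",
    "deletion_border_enrichment",
    "spatial_classify",
    "chip_peak_rss_enrichment",
]

SPATIAL_CATEGORIES = ("RUNX1_RSS", "RUNX1_heptamer",
                      "RUNX1_partial_heptamer_nonamer", "RUNX1_only")


@dataclass
class RegionHits:
    """All matrix and module hits of one region."""

    region: Region
    heptamer_hits: list[MotifHit]
    nonamer_hits: list[MotifHit]
    module_hits: list[RSSModuleHit]
    runx1_hits: list[MotifHit]

    @property
    def module_heptamer_keys(self) -> set[tuple[int, str]]:
        return {(m.heptamer_hit.start, m.strand) for m in self.module_hits}


@dataclass
class HeptamerWindow:
    """A merged +/-flank window around one or more heptamer hits."""

    region: Region
    start: int
    end: int
    contributing_hits: list[MotifHit]
    in_rss_module: bool


@dataclass(frozen=True)
class EnrichmentResult:
    """Observed vs expected counts for a foreground-background comparison."""

    observed: int
    n_foreground: int
    background_rate: float
    expected: float
    fold: float
    z: float
    p_binomial: float
    method: str
    n_resamples: int = 0
    seed: int = 0

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "observed", "n_foreground", "background_rate", "expected",
            "fold", "z", "p_binomial", "method", "n_resamples", "seed")}


@dataclass(frozen=True)
class BackgroundStats:
    """Whole-genome window and module statistics used as background."""

    n_windows: int
    n_windows_runx1: int
    n_module_windows: int
    n_module_windows_runx1: int

    @property
    def window_rate(self) -> float:
        return self.n_windows_runx1 / self.n_windows if self.n_windows else 0.0

    @property
    def module_rate(self) -> float:
        return (self.n_module_windows_runx1 / self.n_module_windows
                if self.n_module_windows else 0.0)


def _dedup_hits(hits: Sequence[MotifHit]) -> list[MotifHit]:
    best: dict[tuple[int, int, str], MotifHit] = {}
    for h in hits:
        key = (h.start, h.end, h.strand)
        if key not in best or h.score > best[key].score:
            best[key] = h
    return sorted(best.values(), key=lambda h: (h.start, h.strand))


def compute_region_hits(
    region: Region,
    models: Sequence[RSSModel] | None = None,
    runx1_pwm: PWM | None = None,
    config: RunConfig | None = None,
) -> RegionHits:
    """Scan one region with all heptamer/nonamer matrices, the eight RSS
    models and the RUNX1 matrix.  Heptamer/nonamer hits from the two
    matrices of each element are pooled and deduplicated by position."""
    cfg = config or RunConfig()
    models = list(models) if models is not None else default_rss_models()
    runx1_pwm = runx1_pwm or default_runx1_pwm()
    hept_pwms = {m.heptamer_matrix.name: m.heptamer_matrix for m in models}
    nona_pwms = {m.nonamer_matrix.name: m.nonamer_matrix for m in models}
    hept_hits = _dedup_hits([
        h for pwm in hept_pwms.values()
        for h in scan(region, pwm, cfg.similarity_threshold_heptamer)
    ])
    nona_hits = _dedup_hits([
        h for pwm in nona_pwms.values()
        for h in scan(region, pwm, cfg.similarity_threshold_nonamer)
    ])
    module_hits = scan_rss_modules(
        region, models, cfg.similarity_threshold_heptamer,
        cfg.similarity_threshold_nonamer)
    runx1_hits = scan(region, runx1_pwm, cfg.similarity_threshold_runx1)
    return RegionHits(region, hept_hits, nona_hits, module_hits, runx1_hits)


def build_deletion_end_regions(
    deletions: Sequence[tuple[str, int, int]],
    genome: dict[str, str],
    inner_span: int = 60,
    flank: int = 7,
) -> list[Region]:
    """Two end regions per deletion: 5' end [start-flank, start+inner_span)
    and 3' end [end-inner_span, end+flank), each carrying the border position.

    Regions running off a chromosome end are clipped and flagged in the name.
    """
    regions: list[Region] = []
    for idx, (chrom, start, end) in enumerate(deletions):
        if chrom not in genome:
            raise ValueError(f"deletion {idx}: chrom {chrom!r} not in genome")
        if end - start < inner_span:
            raise ValueError(
                f"deletion {idx}: length {end - start} shorter than the "
                f"{inner_span}-bp analysis span"
            )
        chrom_len = len(genome[chrom])
        for role, lo, hi, border in (
            ("deletion_5prime_end", start - flank, start + inner_span, start),
            ("deletion_3prime_end", end - inner_span, end + flank, end),
        ):
            clipped = lo < 0 or hi > chrom_len
            lo_c, hi_c = max(0, lo), min(chrom_len, hi)
            name = f"del{idx}_{role}" + ("_clipped" if clipped else "")
            regions.append(Region(chrom, lo_c, hi_c, genome[chrom][lo_c:hi_c],
                                  role=role, border_position=border, name=name))
    logger.info("build_deletion_end_regions: %d deletions -> %d regions",
                len(deletions), len(regions))
    return regions


def extract_heptamer_windows(hits: RegionHits, flank: int = 7) -> list[HeptamerWindow]:
    """Expand heptamer hits by +/-flank (clipped), merging overlapping windows.

    Windows overlapping by at least one nucleotide are merged; a merged
    window is in an RSS module iff any contributing heptamer hit is the
    heptamer of a module hit.  Merging is idempotent by construction.
    """
    region_len = len(hits.region)
    module_keys = hits.module_heptamer_keys
    expanded = sorted(
        ((max(0, h.start - flank), min(region_len, h.end + flank), h)
         for h in hits.heptamer_hits),
        key=lambda t: (t[0], t[1], t[2].strand),
    )
    windows: list[HeptamerWindow] = []
    for s, e, h in expanded:
        if windows and s < windows[-1].end:
            last = windows[-1]
            last.end = max(last.end, e)
            last.contributing_hits.append(h)
            last.in_rss_module |= (h.start, h.strand) in module_keys
        else:
            windows.append(HeptamerWindow(hits.region, s, e, [h],
                                          (h.start, h.strand) in module_keys))
    return windows


def count_runx1_overlaps(
    windows: Sequence[HeptamerWindow],
    runx1_hits: Sequence[MotifHit],
    min_overlap: int = 4,
) -> tuple[int, int, list[dict]]:
    """Count windows whose heptamer overlaps a RUNX1 match by >= min_overlap.

    The overlap is demanded between the RUNX1 hit and a contributing heptamer
    hit itself, not merely the flanked window.
    """
    detail = []
    n_pos = 0
    for w in windows:
        overlaps = [
            (r, h, r.overlap(h))
            for r in runx1_hits
            for h in w.contributing_hits
            if r.overlap(h) >= min_overlap
        ]
        positive = bool(overlaps)
        n_pos += positive
        detail.append(dict(start=w.start, end=w.end, in_rss_module=w.in_rss_module,
                           runx1_positive=positive,
                           best_overlap=max((o for *_, o in overlaps), default=0)))
    return len(windows), n_pos, detail


def background_window_stats(
    genome: dict[str, str],
    models: Sequence[RSSModel] | None = None,
    runx1_pwm: PWM | None = None,
    config: RunConfig | None = None,
) -> BackgroundStats:
    """Scan a whole genome with identical thresholds and window rules."""
    cfg = config or RunConfig()
    n_w = n_wr = n_m = n_mr = 0
    for chrom, seq in genome.items():
        region = Region(chrom, 0, len(seq), seq, role="background_window")
        hits = compute_region_hits(region, models, runx1_pwm, cfg)
        windows = extract_heptamer_windows(hits, cfg.window_flank)
        _, _, detail = count_runx1_overlaps(windows, hits.runx1_hits,
                                            cfg.min_runx1_heptamer_overlap)
        n_w += len(detail)
        n_wr += sum(d["runx1_positive"] for d in detail)
        n_m += sum(d["in_rss_module"] for d in detail)
        n_mr += sum(d["in_rss_module"] and d["runx1_positive"] for d in detail)
    logger.info("background_window_stats: %d windows (%d RUNX1+), "
                "%d module windows (%d RUNX1+)", n_w, n_wr, n_m, n_mr)
    return BackgroundStats(n_w, n_wr, n_m, n_mr)


def enrichment(
    observed: int,
    n_foreground: int,
    background_positive: int,
    background_total: int,
    method: str = "analytic",
    n_resamples: int = 10_000,
    seed: int = 0,
) -> EnrichmentResult:
    """Foreground-vs-background enrichment of positive units.

    analytic: expected = n*p with p the background positive rate; Z is
    continuity-corrected with binomial SD sqrt(n p (1-p)); the tail
    probability is the exact binomial upper tail P(X >= observed) (lower
    tail when observed < expected).  resampling: ``n_resamples`` seeded
    draws of n_foreground units from the background (without replacement),
    Z from the empirical mean/SD and the tail from empirical frequency.
    """
    if background_total <= 0 or n_foreground <= 0:
        raise ValueError("background_total and n_foreground must be > 0")
    p = background_positive / background_total
    expected = n_foreground * p
    fold = observed / expected if expected > 0 else float("nan")
    if method == "analytic":
        var = n_foreground * p * (1.0 - p)
        z = z_score(observed, expected, math.sqrt(var)) if var > 0 else float("nan")
        if p == 0.0:
            p_tail = 0.0 if observed > 0 else 1.0
        elif observed >= expected:
            p_tail = binomial_upper_tail(observed, n_foreground, p)
        else:
            p_tail = binomial_lower_tail(observed, n_foreground, p)
        return EnrichmentResult(observed, n_foreground, p, expected, fold, z,
                                p_tail, "analytic")
    if method == "resampling":
        rng = np.random.default_rng(seed)
        draws = rng.hypergeometric(background_positive,
                                   background_total - background_positive,
                                   n_foreground, size=n_resamples)
        sd = float(draws.std(ddof=1))
        z = z_score(observed, float(draws.mean()), sd) if sd > 0 else float("nan")
        if observed >= expected:
            p_tail = (1 + int((draws >= observed).sum())) / (n_resamples + 1)
        else:
            p_tail = (1 + int((draws <= observed).sum())) / (n_resamples + 1)
        return EnrichmentResult(observed, n_foreground, p, expected, fold, z,
                                p_tail, "resampling", n_resamples, seed)
    raise ValueError(f"unknown method {method!r}")


def deletion_border_enrichment(
    regions: Sequence[Region],
    background: BackgroundStats,
    models: Sequence[RSSModel] | None = None,
    runx1_pwm: PWM | None = None,
    config: RunConfig | None = None,
    method: str = "analytic",
    seed: int = 0,
) -> dict:
    """RUNX1 overrepresentation at deletion-end regions.

    Returns foreground counts plus two EnrichmentResults: over all merged
    heptamer windows, and over the subset of windows within RSS modules.
    """
    cfg = config or RunConfig()
    n_w = n_wr = n_m = n_mr = 0
    per_region: list[RegionHits] = []
    for region in regions:
        hits = compute_region_hits(region, models, runx1_pwm, cfg)
        per_region.append(hits)
        windows = extract_heptamer_windows(hits, cfg.window_flank)
        _, _, detail = count_runx1_overlaps(windows, hits.runx1_hits,
                                            cfg.min_runx1_heptamer_overlap)
        n_w += len(detail)
        n_wr += sum(d["runx1_positive"] for d in detail)
        n_m += sum(d["in_rss_module"] for d in detail)
        n_mr += sum(d["in_rss_module"] and d["runx1_positive"] for d in detail)
    out = {
        "n_windows": n_w, "n_windows_runx1": n_wr,
        "n_module_windows": n_m, "n_module_windows_runx1": n_mr,
        "region_hits": per_region,
    }
    if n_w > 0 and background.n_windows > 0:
        out["all_heptamer"] = enrichment(
            n_wr, n_w, background.n_windows_runx1, background.n_windows,
            method=method, seed=seed)
    if n_m > 0 and background.n_module_windows > 0:
        out["rss_module"] = enrichment(
            n_mr, n_m, background.n_module_windows_runx1,
            background.n_module_windows, method=method, seed=seed)
    return out


def _partial_heptamer_nonamer(
    hits: RegionHits,
    runx1: MotifHit,
    spacer_classes: Sequence[tuple[int, int]],
) -> bool:
    """A GTG/CAC trinucleotide immediately flanking the RUNX1 hit plus a
    same-strand nonamer at a spacer of 12 or 19-25 nt from that trinucleotide."""
    seq = hits.region.sequence
    sides = []
    left = seq[runx1.start - 3 : runx1.start] if runx1.start >= 3 else ""
    right = seq[runx1.end : runx1.end + 3]
    if left in ("GTG", "CAC"):
        sides.append(("left", runx1.start - 3))
    if right in ("GTG", "CAC"):
        sides.append(("right", runx1.end))
    for side, tri_start in sides:
        for n in hits.nonamer_hits:
            if n.strand != runx1.strand:
                continue
            if side == "right":
                spacer = n.start - (tri_start + 3)
            else:
                spacer = tri_start - n.end
            if any(lo <= spacer <= hi for lo, hi in spacer_classes):
                return True
    return False


def spatial_classify(
    regions_hits: Sequence[RegionHits],
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Classify every RUNX1 hit by its relation to heptamers and RSS modules.

    Categories, in priority order: overlapping (>= 4 nt) a heptamer within an
    RSS module; overlapping a lone heptamer; a partial heptamer (GTG/CAC)
    flanking the hit with a spacer-distant nonamer; no heptamer relation.
    ``distance_bp`` is the unsigned distance of the hit's first position to
    the region's deletion border (a signed variant is also emitted).  Regions
    without a border are skipped with a warning.
    """
    cfg = config or RunConfig()
    rows = []
    for hits in regions_hits:
        region = hits.region
        if region.border_position is None:
            logger.warning("spatial_classify: region %s has no border; skipped",
                           region.name or region.chrom)
            continue
        module_keys = hits.module_heptamer_keys
        for r in hits.runx1_hits:
            module_olap = any(
                r.overlap(h) >= cfg.min_runx1_heptamer_overlap
                for h in hits.heptamer_hits if (h.start, h.strand) in module_keys
            )
            hept_olap = any(
                r.overlap(h) >= cfg.min_runx1_heptamer_overlap
                for h in hits.heptamer_hits
            )
            if module_olap:
                cat = "RUNX1_RSS"
            elif hept_olap:
                cat = "RUNX1_heptamer"
            elif _partial_heptamer_nonamer(hits, r, cfg.partial_spacer_classes):
                cat = "RUNX1_partial_heptamer_nonamer"
            else:
                cat = "RUNX1_only"
            abs_start = region.start + r.start
            signed = abs_start - region.border_position
            rows.append(dict(region=region.name, category=cat,
                             runx1_start=abs_start, strand=r.strand,
                             distance_bp=abs(signed), signed_distance=signed,
                             score=r.score))
    records = pd.DataFrame(rows, columns=["region", "category", "runx1_start",
                                          "strand", "distance_bp",
                                          "signed_distance", "score"])
    medians = {
        cat: float(records.loc[records["category"] == cat, "distance_bp"].median())
        for cat in SPATIAL_CATEGORIES
        if (records["category"] == cat).any()
    }
    return records, medians


def chip_peak_rss_enrichment(
    peaks: Sequence[Region],
    background: BackgroundStats,
    models: Sequence[RSSModel] | None = None,
    runx1_pwm: PWM | None = None,
    config: RunConfig | None = None,
    method: str = "analytic",
    seed: int = 0,
) -> tuple[int, int, Optional[EnrichmentResult]]:
    """RUNX1-overlap enrichment among peaks containing RSS modules.

    Counts peaks with at least one RSS module hit and, of those, peaks where
    a module heptamer overlaps a RUNX1 hit by >= 4 nt; compares against the
    genome background rate of RUNX1 overlap among RSS-module windows.
    """
    cfg = config or RunConfig()
    n_with_rss = n_with_runx1 = 0
    for peak in peaks:
        hits = compute_region_hits(peak, models, runx1_pwm, cfg)
        if not hits.module_hits:
            continue
        n_with_rss += 1
        module_hepts = [h for h in hits.heptamer_hits
                        if (h.start, h.strand) in hits.module_heptamer_keys]
        if any(r.overlap(h) >= cfg.min_runx1_heptamer_overlap
               for r in hits.runx1_hits for h in module_hepts):
            n_with_runx1 += 1
    if n_with_rss == 0 or background.n_module_windows == 0:
        return n_with_rss, n_with_runx1, None
    result = enrichment(n_with_runx1, n_with_rss,
                        background.n_module_windows_runx1,
                        background.n_module_windows, method=method, seed=seed)
    return n_with_rss, n_with_runx1, result
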