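"""SNP-index and delta-SNP-index tracks with sliding-window region calling.

The SNP-index of a bulk at a variant site is the fraction of that bulk's
reads carrying a chosen allele; the delta-SNP-index is the green-bulk
index minus the yellow-bulk index.  At sites unlinked to the causal locus
both bulks hover around 0.5 and delta around 0; at tightly linked sites
the green (recessive-phenotype) bulk is near 1 under the
yellow-parent-as-reference orientation while the yellow bulk sits near
1/3, so delta approaches 2/3.  Windowed means of these tracks are
thresholded (index > 0.875 and delta > 0.5 by default, strict) to call
candidate regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .variantio import DEFAULT_SAMPLES, SampleNames


def snp_index(alt_depth: int, total_depth: int) -> float:
    """Fraction of reads carrying the counted allele; NaN when depth is 0."""
    if alt_depth < 0 or total_depth < 0:
        raise ValueError("depths must be non-negative")
    if alt_depth > total_depth:
        raise ValueError(f"alt depth {alt_depth} exceeds total depth {total_depth}")
    if total_depth == 0:
        return math.nan
    return alt_depth / total_depth


def delta_snp_index(index_g: float, index_y: float) -> float:
    """Green-bulk index minus yellow-bulk index; NaN if either is undefined."""
    if math.isnan(index_g) or math.isnan(index_y):
        return math.nan
    return index_g - index_y


@dataclass
class SNPIndexRecord:
    """Per-site SNP-index of each bulk and their difference."""

    chrom: str
    pos: int
    index_g: float
    index_y: float
    delta: float


def compute_records(sites, samples: SampleNames = DEFAULT_SAMPLES, allele: str = "alt") -> list[SNPIndexRecord]:
    """Per-site index records for both bulks.

    ``allele`` selects which allele is counted: "alt" (the VCF ALT allele)
    or "green_parent" (the allele the green parent is homozygous for,
    flipping sites where the green parent is homozygous REF).  Sites where
    either bulk has zero depth are dropped.
    """
    if allele not in ("alt", "green_parent"):
        raise ValueError("allele must be 'alt' or 'green_parent'")
    out = []
    for site in sites:
        flip = False
        if allele == "green_parent":
            g_gt = site.gt.get(samples.parent_g)
            if g_gt is None:
                continue
            flip = set(g_gt) == {0}
        rg, ag = site.ad[samples.green_bulk]
        ry, ay = site.ad[samples.yellow_bulk]
        if flip:
            rg, ag, ry, ay = ag, rg, ay, ry
        ig = snp_index(ag, rg + ag)
        iy = snp_index(ay, ry + ay)
        d = delta_snp_index(ig, iy)
        if math.isnan(d):
            continue
        out.append(SNPIndexRecord(site.chrom, site.pos, ig, iy, d))
    return out


@dataclass(frozen=True)
class WindowConfig:
    """Sliding-window geometry: window 1 Mb, step 100 kb, >= 10 sites."""

    window_size_bp: int = 1_000_000
    step_bp: int = 100_000
    min_sites: int = 10

    def __post_init__(self):
        if self.window_size_bp <= 0 or self.step_bp <= 0 or self.min_sites <= 0:
            raise ValueError("window size, step and min_sites must all be > 0")
        if self.step_bp > self.window_size_bp:
            raise ValueError("step must not exceed window size")


@dataclass
class WindowStat:
    """Windowed means of the index tracks; membership is [start, start+window)."""

    chrom: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive (start + window - 1)
    n_sites: int
    mean_g: float
    mean_y: float
    mean_delta: float
    eligible: bool  # n_sites >= min_sites; ineligible windows are never called


def _check_sorted(records) -> dict[str, slice]:
    blocks: dict[str, slice] = {}
    start = 0
    for i in range(1, len(records) + 1):
        if i == len(records) or records[i].chrom != records[start].chrom:
            chrom = records[start].chrom
            if chrom in blocks:
                raise ValueError(f"records not grouped by chromosome ({chrom} appears twice)")
            blocks[chrom] = slice(start, i)
            start = i
    for chrom, sl in blocks.items():
        pos = [r.pos for r in records[sl]]
        if any(b < a for a, b in zip(pos, pos[1:])):
            raise ValueError(f"records not sorted by position on {chrom}")
    return blocks


def sliding_window_means(records, cfg: WindowConfig = WindowConfig(), chrom_lengths: dict | None = None) -> list[WindowStat]:
    """Mean index_g / index_y / delta per sliding window.

    Records must be sorted by chromosome then position.  Windows start at
    1 and advance by ``step_bp`` while they still start at or before the
    chromosome's last site (or ``chrom_lengths[chrom]`` when provided).
    """
    blocks = _check_sorted(records)
    windows: list[WindowStat] = []
    for chrom, sl in blocks.items():
        sub = records[sl]
        pos = np.array([r.pos for r in sub])
        ig = np.array([r.index_g for r in sub])
        iy = np.array([r.index_y for r in sub])
        dd = np.array([r.delta for r in sub])
        last = chrom_lengths.get(chrom, int(pos[-1])) if chrom_lengths else int(pos[-1])
        for start in range(1, last + 1, cfg.step_bp):
            lo = int(np.searchsorted(pos, start, side="left"))
            hi = int(np.searchsorted(pos, start + cfg.window_size_bp, side="left"))
            n = hi - lo
            if n:
                mg, my, md = float(ig[lo:hi].mean()), float(iy[lo:hi].mean()), float(dd[lo:hi].mean())
            else:
                mg = my = md = math.nan
            end = min(start + cfg.window_size_bp - 1, last)
            windows.append(WindowStat(chrom, start, end, n, mg, my, md, n >= cfg.min_sites))
    return windows


@dataclass(frozen=True)
class RegionCallConfig:
    """Thresholds for calling candidate regions (strict inequalities)."""

    snp_index_threshold: float = 0.875
    delta_threshold: float = 0.5
    min_consecutive_windows: int = 3

    def __post_init__(self):
        if not (0 < self.snp_index_threshold <= 1 and 0 < self.delta_threshold <= 1):
            raise ValueError("thresholds must be in (0, 1]")
        if self.min_consecutive_windows < 1:
            raise ValueError("min_consecutive_windows must be >= 1")


@dataclass
class CandidateRegion:
    """A maximal run of qualifying windows (union of their spans)."""

    chrom: str
    start: int
    end: int
    n_windows: int
    mean_index_g: float
    mean_delta: float
    criteria: tuple[str, ...] = ("snp_index", "delta")


def call_candidate_regions(windows, cfg: RegionCallConfig = RegionCallConfig()) -> list[CandidateRegion]:
    """Maximal runs of >= min_consecutive_windows qualifying windows.

    A window qualifies when it is eligible (enough sites) and BOTH its
    mean green-bulk index exceeds snp_index_threshold AND its mean delta
    exceeds delta_threshold (strict).  Any non-qualifying window breaks a
    run; runs are never merged across a failing window.
    """
    regions: list[CandidateRegion] = []
    run: list[WindowStat] = []

    def flush():
        if len(run) >= cfg.min_consecutive_windows:
            regions.append(
                CandidateRegion(
                    run[0].chrom,
                    run[0].start,
                    run[-1].end,
                    len(run),
                    float(np.mean([w.mean_g for w in run])),
                    float(np.mean([w.mean_delta for w in run])),
                )
            )
        run.clear()

    prev_chrom = None
    for w in windows:
        if w.chrom != prev_chrom:
            flush()
            prev_chrom = w.chrom
        ok = (
            w.eligible
            and not math.isnan(w.mean_g)
            and w.mean_g > cfg.snp_index_threshold
            and w.mean_delta > cfg.delta_threshold
        )
        if ok:
            run.append(w)
        else:
            flush()
    flush()
    return regions


def window_containing(windows, chrom: str, pos: int) -> WindowStat:
    """The window containing ``pos`` whose centre is nearest to it.

    With overlapping sliding windows several contain a position; the most
    central one is the natural readout for "the value at the locus".
    """
    best, best_d = None, None
    for w in windows:
        if w.chrom == chrom and w.start <= pos <= w.end:
            d = abs((w.start + w.end) / 2 - pos)
            if best is None or d < best_d:
                best, best_d = w, d
    if best is None:
        raise ValueError(f"no window contains {chrom}:{pos}")
    return best
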