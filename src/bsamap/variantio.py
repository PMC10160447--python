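"""VCF ingestion: biallelic sites with per-sample allele depths.

This layer consumes the output of an upstream variant caller (one VCF with
the two parental lines and the two bulks as samples, each carrying an AD
allele-depth field) and selects parent-informative sites: sites where the
two inbred parents are called homozygous for opposite alleles.  Upstream
read alignment and variant calling are out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pysam

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SampleNames:
    """VCF sample names for the two parents and the two bulks."""

    parent_g: str = "G"
    parent_y: str = "Y"
    green_bulk: str = "G_pool"
    yellow_bulk: str = "Y_pool"

    def as_tuple(self):
        return (self.parent_g, self.parent_y, self.green_bulk, self.yellow_bulk)


DEFAULT_SAMPLES = SampleNames()


@dataclass
class VariantSite:
    """One biallelic site: genotype calls and (ref, alt) read depths per sample."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gt: dict[str, tuple | None]
    ad: dict[str, tuple[int, int]]

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    def depth(self, sample: str) -> int:
        r, a = self.ad[sample]
        return r + a


@dataclass(frozen=True)
class FilterConfig:
    """Site-retention rules for the index computation.

    min_bulk_depth applies to each bulk's total (ref+alt) depth; parents
    must be called homozygous for opposite alleles (heterozygous or
    missing parent calls disqualify the site); snps_only optionally
    restricts the track to SNPs.
    """

    min_bulk_depth: int = 8
    require_opposite_homozygotes: bool = True
    snps_only: bool = False

    def __post_init__(self):
        if self.min_bulk_depth < 1:
            raise ValueError("min_bulk_depth must be >= 1")


def read_variants(path: str, samples: SampleNames = DEFAULT_SAMPLES) -> list[VariantSite]:
    """Parse a VCF into VariantSite records.

    One record per biallelic row; multiallelic rows are skipped with a
    logged count.  Raises ValueError if a required sample or its AD field
    is absent.
    """
    needed = samples.as_tuple()
    sites: list[VariantSite] = []
    n_multi = 0
    with pysam.VariantFile(path) as vf:
        present = set(vf.header.samples)
        for s in needed:
            if s not in present:
                raise ValueError(f"sample {s!r} not found in VCF (has: {sorted(present)})")
        if "AD" not in vf.header.formats:
            raise ValueError("VCF FORMAT field 'AD' (allele depth) is missing")
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                n_multi += 1
                continue
            gt, ad = {}, {}
            for s in needed:
                call = rec.samples[s]
                raw_gt = call.get("GT")
                gt[s] = None if raw_gt is None or any(a is None for a in raw_gt) else tuple(raw_gt)
                raw_ad = call.get("AD")
                if raw_ad is None or all(v is None for v in raw_ad):
                    ad[s] = (0, 0)
                else:
                    ad[s] = (int(raw_ad[0] or 0), int(raw_ad[1] or 0))
            sites.append(VariantSite(rec.chrom, rec.pos, rec.ref, rec.alts[0], gt, ad))
    if n_multi:
        log.info("skipped %d non-biallelic rows", n_multi)
    return sites


def _parents_opposite_homozygous(site: VariantSite, samples: SampleNames) -> bool:
    g, y = site.gt.get(samples.parent_g), site.gt.get(samples.parent_y)
    if g is None or y is None:
        return False
    if len(set(g)) != 1 or len(set(y)) != 1:
        return False  # heterozygous parent disqualifies (inbred lines expected)
    return {g[0], y[0]} == {0, 1}


def filter_informative(
    sites, cfg: FilterConfig = FilterConfig(), samples: SampleNames = DEFAULT_SAMPLES
) -> list[VariantSite]:
    """Retain parent-informative sites with adequate bulk depth (order kept)."""
    kept = []
    for site in sites:
        if cfg.snps_only and site.is_indel:
            continue
        if cfg.require_opposite_homozygotes and not _parents_opposite_homozygous(site, samples):
            continue
        if site.depth(samples.green_bulk) < cfg.min_bulk_depth:
            continue
        if site.depth(samples.yellow_bulk) < cfg.min_bulk_depth:
            continue
        kept.append(site)
    log.info("informative-site filter: %d of %d sites retained", len(kept), len(sites))
    return kept
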