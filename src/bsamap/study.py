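"""Headline quantities of the synthetic mapping study at its design point.

The design point mirrors the mapping experiment the package emulates: an
F2 of 623 plants segregating 3:1 for a fully penetrant dominant locus,
33-plant phenotype-pure bulks, ~30x pooled depth with 0.5% base error,
one informative SNP every 10 kb on a 5 Mb causal chromosome (locus at
2.5 Mb) plus a 5 Mb unlinked control chromosome, and 1 Mb / 100 kb
sliding windows.  These functions run the full method on fresh
simulations and return the measured statistics; they are what the
acceptance checks and the reproduction script execute.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import numpy as np

from . import bsaindex, finemap, simcross, variantio
from .bsaindex import RegionCallConfig, WindowConfig
from .simcross import BulkSpec, CausalLocus, GeneticMap, SeqSimParams

DESIGN_CHROM = "LG10"
UNLINKED_CHROM = "LG03"
CAUSAL_POS = 2_500_000
N_F2 = 623
N_BC1 = 71


def design_map(with_unlinked: bool = True, spacing: int = 10_000) -> GeneticMap:
    chroms = [(DESIGN_CHROM, 5_000_000, 25.0)]
    if with_unlinked:
        chroms.append((UNLINKED_CHROM, 5_000_000, 25.0))
    return GeneticMap.uniform(chroms, spacing)


def _variant_sites(sim_sites) -> list[variantio.VariantSite]:
    """Adapt in-memory simulated sites to the ingestion record type."""
    return [
        variantio.VariantSite(s.chrom, s.pos, s.ref, s.alt, dict(s.gt), dict(s.ad))
        for s in sim_sites
    ]


def segregation_ratio(design: str, n: int, seed) -> tuple[float, int]:
    """Yellow:green ratio (as a float) in a simulated population of size n."""
    gmap = design_map(with_unlinked=False, spacing=1_000_000)
    pop = simcross.simulate_population(design, n, gmap, CausalLocus(DESIGN_CHROM, CAUSAL_POS), 0.0, seed)
    ny, ng = simcross.phenotype_counts(pop)
    return ny / ng, n


def bsa_design_point(seed, via_vcf: bool = True) -> dict:
    """Run one full BSA at the design point and read off the key statistics.

    Returns the windowed green-bulk SNP-index and delta at the window
    containing the causal locus, the per-site mean index on the unlinked
    chromosome averaged over both bulks, the unlinked mean delta, and the
    called candidate regions.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_pop, s_pool = ss.spawn(2)
    gmap = design_map()
    locus = CausalLocus(DESIGN_CHROM, CAUSAL_POS)
    pop = simcross.simulate_population("F2", N_F2, gmap, locus, 0.0, np.random.default_rng(s_pop))
    if via_vcf:
        with tempfile.TemporaryDirectory() as tmp:
            path = Path(tmp) / "bulks.vcf"
            simcross.simulate_vcf(pop, gmap, str(path), BulkSpec(33), SeqSimParams(30.0, 0.005), s_pool)
            sites = variantio.read_variants(str(path))
    else:
        g_bulk, y_bulk = simcross.build_bulks(pop, gmap, BulkSpec(33), np.random.default_rng(s_pool.spawn(2)[0]))
        sim = simcross.simulate_read_counts(
            g_bulk, y_bulk, gmap, SeqSimParams(30.0, 0.005), np.random.default_rng(s_pool.spawn(2)[1])
        )
        sites = _variant_sites(sim)
    informative = variantio.filter_informative(sites, variantio.FilterConfig(min_bulk_depth=8))
    records = bsaindex.compute_records(informative)
    chrom_lengths = {c.name: c.length_bp for c in gmap.chromosomes}
    windows = bsaindex.sliding_window_means(records, WindowConfig(), chrom_lengths)
    regions = bsaindex.call_candidate_regions(windows, RegionCallConfig())
    causal_win = bsaindex.window_containing(windows, DESIGN_CHROM, CAUSAL_POS)
    unlinked = [r for r in records if r.chrom == UNLINKED_CHROM]
    mean_g = float(np.mean([r.index_g for r in unlinked]))
    mean_y = float(np.mean([r.index_y for r in unlinked]))
    return {
        "index_g_causal_window": causal_win.mean_g,
        "delta_causal_window": causal_win.mean_delta,
        "unlinked_mean_index": (mean_g + mean_y) / 2,
        "unlinked_mean_delta": float(np.mean([r.delta for r in unlinked])),
        "n_unlinked_sites": len(unlinked),
        "regions": regions,
        "n_sites": len(records),
    }


def region_recovery_rate(n_runs: int = 100, seed: int = 0) -> tuple[int, int]:
    """How often the called candidate region contains the causal position.

    Each seed-indexed replicate simulates the design point on the causal
    chromosome only (in memory) and checks containment.
    """
    gmap = design_map(with_unlinked=False)
    locus = CausalLocus(DESIGN_CHROM, CAUSAL_POS)
    chrom_lengths = {c.name: c.length_bp for c in gmap.chromosomes}
    hits = 0
    for k in range(n_runs):
        ss = np.random.SeedSequence((seed, k))
        s_pop, s_bulk, s_reads = ss.spawn(3)
        pop = simcross.simulate_population("F2", N_F2, gmap, locus, 0.0, np.random.default_rng(s_pop))
        g_bulk, y_bulk = simcross.build_bulks(pop, gmap, BulkSpec(33), np.random.default_rng(s_bulk))
        sim = simcross.simulate_read_counts(g_bulk, y_bulk, gmap, SeqSimParams(30.0, 0.005), np.random.default_rng(s_reads))
        records = bsaindex.compute_records(
            variantio.filter_informative(_variant_sites(sim), variantio.FilterConfig())
        )
        windows = bsaindex.sliding_window_means(records, WindowConfig(), chrom_lengths)
        regions = bsaindex.call_candidate_regions(windows, RegionCallConfig())
        if any(r.chrom == DESIGN_CHROM and r.start <= CAUSAL_POS <= r.end for r in regions):
            hits += 1
    return hits, n_runs


def finemap_containment(
    n_runs: int = 100, seed: int = 0, n_plants: int = 200, n_markers: int = 12
) -> tuple[int, int]:
    """How often the narrowed interval contains the causal position.

    Each replicate simulates ``n_plants`` error-free F2 plants, genotypes
    them at ``n_markers`` evenly spaced co-dominant markers spanning the
    5 Mb chromosome, keeps the recombinants and intersects their
    phenotype-compatible regions.
    """
    gmap = design_map(with_unlinked=False, spacing=1_000_000)
    locus = CausalLocus(DESIGN_CHROM, CAUSAL_POS)
    chrom_len = gmap.chromosome(DESIGN_CHROM).length_bp
    marker_pos = np.linspace(1, chrom_len, n_markers).round().astype(np.int64)
    markers = [finemap.Marker(f"M{i+1:02d}", int(p)) for i, p in enumerate(marker_pos)]
    hits = 0
    for k in range(n_runs):
        pop = simcross.simulate_population(
            "F2", n_plants, gmap, locus, 0.0, np.random.default_rng(np.random.SeedSequence((seed, k)))
        )
        rows = []
        for j, ind in enumerate(pop):
            h0, h1 = ind.haplotypes[DESIGN_CHROM]
            n_green = (h0.origin_at(marker_pos) == simcross.ORIGIN_G).astype(int) + (
                h1.origin_at(marker_pos) == simcross.ORIGIN_G
            ).astype(int)
            calls = [("B", "H", "A")[g] for g in n_green]
            rows.append(finemap.IndividualCalls(f"P{j}", calls, ind.phenotype))
        table = finemap.RecombinantTable(markers, rows)
        interval = finemap.narrow_interval(table, "F2", drop_most_conflicting=True, max_drops=3)
        if interval.start <= CAUSAL_POS <= interval.end:
            hits += 1
    return hits, n_runs


def genome_wide_null(seed, n_unlinked: int = 19) -> dict:
    """Null behaviour of the index tracks over a whole unlinked genome.

    Simulates the design-point F2/BSA on a 20-chromosome genome (the
    species karyotype, 2n = 40): one causal chromosome plus
    ``n_unlinked`` 5 Mb chromosomes carrying no causal locus, and returns
    the mean per-site SNP-index (averaged over both bulks) and mean delta
    across all unlinked markers.
    """
    names = [f"LG{k:02d}" for k in range(1, n_unlinked + 3) if f"LG{k:02d}" != DESIGN_CHROM]
    chroms = [(DESIGN_CHROM, 5_000_000, 25.0)] + [(n, 5_000_000, 25.0) for n in names[:n_unlinked]]
    gmap = GeneticMap.uniform(chroms, 10_000)
    locus = CausalLocus(DESIGN_CHROM, CAUSAL_POS)
    ss = np.random.SeedSequence(seed)
    s_pop, s_bulk, s_reads = ss.spawn(3)
    pop = simcross.simulate_population("F2", N_F2, gmap, locus, 0.0, np.random.default_rng(s_pop))
    g_bulk, y_bulk = simcross.build_bulks(pop, gmap, BulkSpec(33), np.random.default_rng(s_bulk))
    sim = simcross.simulate_read_counts(
        g_bulk, y_bulk, gmap, SeqSimParams(30.0, 0.005), np.random.default_rng(s_reads)
    )
    records = bsaindex.compute_records(
        variantio.filter_informative(_variant_sites(sim), variantio.FilterConfig())
    )
    unlinked = [r for r in records if r.chrom != DESIGN_CHROM]
    mean_g = float(np.mean([r.index_g for r in unlinked]))
    mean_y = float(np.mean([r.index_y for r in unlinked]))
    return {
        "mean_index": (mean_g + mean_y) / 2,
        "mean_delta": float(np.mean([r.delta for r in unlinked])),
        "n_sites": len(unlinked),
        "n_chromosomes": len(gmap.chromosomes),
    }


def unlinked_mean_index(seed, n_reps: int = 100) -> tuple[float, int]:
    """Mean per-site SNP-index on the unlinked chromosome, averaged over
    both bulks and over ``n_reps`` replicate design-point simulations.

    Replicates average out bulk-composition noise (a 33-plant bulk's
    chromosome-wide allele frequency has sd ~ 0.04 on a single unlinked
    chromosome because parental mosaics are correlated along it), giving
    a precise estimate of the null mean.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    vals, n_sites = [], 0
    for child in ss.spawn(n_reps):
        m = bsa_design_point(child, via_vcf=False)
        vals.append(m["unlinked_mean_index"])
        n_sites += m["n_unlinked_sites"]
    return float(np.mean(vals)), n_sites
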