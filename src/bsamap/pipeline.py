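"""End-to-end reproducible workflow: simulate -> ingest -> index -> call -> fine-map.

A single integer seed drives every stage through independent substreams,
so a fixed (seed, config) pair yields byte-identical outputs.  The run
persists the simulated VCF, per-site and windowed index tracks (TSV), the
called candidate regions (BED, 0-based half-open), the recombinant marker
table (TSV) and a JSON report mirroring the study's headline artefacts:
the segregation table, the candidate region(s) and the fine-mapped
interval.  Internal coordinates are 1-based inclusive throughout; only
the BED export converts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import bsaindex, finemap, segregation, simcross, variantio
from .bsaindex import RegionCallConfig, WindowConfig
from .simcross import BulkSpec, CausalLocus, Chromosome, GeneticMap, SeqSimParams

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full parameterisation of one synthetic mapping study.

    Defaults reproduce the study design: an F2 of 623 plants and a BC1 of
    71 segregating for one dominant locus, 33-plant bulks sequenced at
    30x, a 5 Mb causal chromosome plus a 5 Mb unlinked control
    chromosome at 5 cM/Mb with one informative SNP every 10 kb.
    """

    seed: int = 0
    chromosomes: list = field(
        default_factory=lambda: [["LG10", 5_000_000, 25.0], ["LG03", 5_000_000, 25.0]]
    )
    marker_spacing_bp: int = 10_000
    causal_chrom: str = "LG10"
    causal_pos: int = 2_500_000
    n_f2: int = 623
    n_bc1: int = 71
    bulk_size: int = 33
    mean_depth: float = 30.0
    base_error_rate: float = 0.005
    misphenotyping_rate: float = 0.0
    window: dict = field(
        default_factory=lambda: {"window_size_bp": 1_000_000, "step_bp": 100_000, "min_sites": 10}
    )
    region: dict = field(
        default_factory=lambda: {
            "snp_index_threshold": 0.875,
            "delta_threshold": 0.5,
            "min_consecutive_windows": 3,
        }
    )
    min_bulk_depth: int = 8
    n_finemap_markers: int = 12

    def genetic_map(self) -> GeneticMap:
        return GeneticMap.uniform(
            [Chromosome(n, int(bp), float(cm)) for n, bp, cm in self.chromosomes],
            self.marker_spacing_bp,
        )

    def locus(self) -> CausalLocus:
        return CausalLocus(self.causal_chrom, self.causal_pos)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def fingerprint(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""


def _run_stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:
        raise StageError(f"stage {name!r} failed: {exc}") from exc


def export_tracks(records, windows, regions, destination) -> dict[str, Path]:
    """Write the per-site TSV, window TSV and region BED under ``destination``."""
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    paths = {
        "sites": dest / "snp_index_sites.tsv",
        "windows": dest / "snp_index_windows.tsv",
        "regions": dest / "candidate_regions.bed",
    }
    with open(paths["sites"], "w") as fh:
        fh.write("# per-site SNP-index track; positions 1-based\n")
        fh.write("chrom\tpos\tindex_G\tindex_Y\tdelta\n")
        for r in records:
            fh.write(f"{r.chrom}\t{r.pos}\t{r.index_g:.17g}\t{r.index_y:.17g}\t{r.delta:.17g}\n")
    with open(paths["windows"], "w") as fh:
        fh.write("# sliding-window means; start/end 1-based inclusive; membership [start, start+window)\n")
        fh.write("chrom\tstart\tend\tn_sites\tmean_G\tmean_Y\tmean_delta\teligible\n")
        for w in windows:
            fh.write(
                f"{w.chrom}\t{w.start}\t{w.end}\t{w.n_sites}\t{w.mean_g:.17g}\t"
                f"{w.mean_y:.17g}\t{w.mean_delta:.17g}\t{int(w.eligible)}\n"
            )
    with open(paths["regions"], "w") as fh:
        fh.write('track name=candidate_regions description="BSA candidate regions (BED 0-based half-open)"\n')
        for reg in regions:
            fh.write(f"{reg.chrom}\t{reg.start - 1}\t{reg.end}\tdelta={reg.mean_delta:.4f}\n")
    return paths


def read_window_tsv(path) -> list[bsaindex.WindowStat]:
    """Re-import a window track written by export_tracks (exact round-trip)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("chrom\t"):
                continue
            c, s, e, n, mg, my, md, el = line.rstrip("\n").split("\t")
            out.append(
                bsaindex.WindowStat(c, int(s), int(e), int(n), float(mg), float(my), float(md), bool(int(el)))
            )
    return out


def _genotype_table(individuals, chrom, marker_positions) -> finemap.RecombinantTable:
    """Co-dominant marker calls for each individual from its true haplotypes."""
    markers = [finemap.Marker(f"M{i+1:02d}", int(p)) for i, p in enumerate(marker_positions)]
    rows = []
    for k, ind in enumerate(individuals):
        h0, h1 = ind.haplotypes[chrom]
        n_green = (h0.origin_at(marker_positions) == simcross.ORIGIN_G).astype(int) + (
            h1.origin_at(marker_positions) == simcross.ORIGIN_G
        ).astype(int)
        calls = [{2: finemap.CALL_A, 1: finemap.CALL_H, 0: finemap.CALL_B}[int(g)] for g in n_green]
        rows.append(finemap.IndividualCalls(f"F2-{k+1:04d}", calls, ind.phenotype))
    return finemap.RecombinantTable(markers, rows)


def run_full(config: RunConfig, outdir) -> dict:
    """Execute the whole workflow and return the run report (also persisted).

    Stages: simulate F2/BC1 populations, segregation chi-squared tests,
    bulk + pooled sequencing into a VCF, VCF ingestion and informative-site
    filtering, SNP-index tracks, window means, candidate-region calling,
    and recombinant fine mapping inside the best called region.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gmap = _run_stage("config", config.genetic_map)
    locus = config.locus()
    params = _run_stage("config", SeqSimParams, config.mean_depth, config.base_error_rate)
    ss = np.random.SeedSequence(config.seed)
    s_f2, s_bc1, s_pool = ss.spawn(3)

    f2 = _run_stage(
        "simulate", simcross.simulate_population,
        "F2", config.n_f2, gmap, locus, config.misphenotyping_rate, np.random.default_rng(s_f2),
    )
    bc1 = _run_stage(
        "simulate", simcross.simulate_population,
        "BC1", config.n_bc1, gmap, locus, config.misphenotyping_rate, np.random.default_rng(s_bc1),
    )
    seg_rows = []
    for name, pop, ratio in (("F2", f2, (3, 1)), ("BC1", bc1, (1, 1))):
        ny, ng = simcross.phenotype_counts(pop)
        res = _run_stage("segtest", segregation.chi_square_gof, segregation.SegregationCount(ny, ng), ratio)
        seg_rows.append(
            {
                "population": name, "total": ny + ng, "n_yellow": ny, "n_green": ng,
                "ratio": f"{ratio[0]}:{ratio[1]}", "chi2": round(res.chi2, 4),
                "p": round(res.p, 4), "fits": res.fits,
            }
        )
        log.info("segregation %s: %d yellow / %d green, chi2=%.4f p=%.4f", name, ny, ng, res.chi2, res.p)

    vcf_path = outdir / "bulks.vcf"
    _, _, sim_sites = _run_stage(
        "sequence", simcross.simulate_vcf, f2, gmap, str(vcf_path),
        BulkSpec(config.bulk_size), params, s_pool,
    )

    sites = _run_stage("ingest", variantio.read_variants, str(vcf_path))
    informative = _run_stage(
        "filter", variantio.filter_informative, sites, variantio.FilterConfig(config.min_bulk_depth)
    )
    n_dropped = len(sites) - len(informative)
    assert len(sites) == len(informative) + n_dropped  # stage-count conservation
    log.info("sites: simulated=%d read=%d informative=%d dropped=%d",
             len(sim_sites), len(sites), len(informative), n_dropped)

    records = _run_stage("index", bsaindex.compute_records, informative)
    if not records:
        raise StageError("stage 'index' failed: no sites with defined SNP-index in both bulks")
    chrom_lengths = {c.name: c.length_bp for c in gmap.chromosomes}
    windows = _run_stage(
        "window", bsaindex.sliding_window_means, records, WindowConfig(**config.window), chrom_lengths
    )
    regions = _run_stage("call", bsaindex.call_candidate_regions, windows, RegionCallConfig(**config.region))
    track_paths = export_tracks(records, windows, regions, outdir)

    # fine mapping inside the strongest called region (fallback: the
    # chromosome holding the highest windowed delta)
    if regions:
        target = max(regions, key=lambda r: r.mean_delta)
        fm_chrom, fm_start, fm_end = target.chrom, target.start, target.end
    else:
        eligible = [w for w in windows if w.eligible]
        best = max(eligible, key=lambda w: w.mean_delta)
        fm_chrom, fm_start, fm_end = best.chrom, 1, chrom_lengths[best.chrom]
    fm_end = min(fm_end, chrom_lengths[fm_chrom])
    marker_pos = np.unique(np.linspace(fm_start, fm_end, config.n_finemap_markers).round().astype(np.int64))
    table = _run_stage("finemap", _genotype_table, f2, fm_chrom, marker_pos)
    recombinants = finemap.RecombinantTable(
        table.markers, [i for i in table.individuals if len(set(i.calls)) > 1]
    )
    recombinants.to_tsv(outdir / "recombinants.tsv")
    # tight double recombinants (no-interference meiosis) can mimic
    # misphenotyped plants; drop up to a few conflicting individuals
    interval = _run_stage(
        "finemap", finemap.narrow_interval,
        recombinants if recombinants.individuals else table, "F2",
        True, 3,
    )

    report = {
        "config_fingerprint": config.fingerprint(),
        "seed": config.seed,
        "segregation": seg_rows,
        "counts": {
            "sites_simulated": len(sim_sites),
            "sites_read": len(sites),
            "sites_informative": len(informative),
            "sites_filtered_out": n_dropped,
            "sites_indexed": len(records),
            "windows": len(windows),
            "n_recombinants": len(recombinants.individuals),
        },
        "candidate_regions": [
            {
                "chrom": r.chrom, "start": r.start, "end": r.end, "n_windows": r.n_windows,
                "mean_index_G": round(r.mean_index_g, 6), "mean_delta": round(r.mean_delta, 6),
            }
            for r in regions
        ],
        "mapped_interval": {
            "chrom": fm_chrom,
            "start": interval.start,
            "end": interval.end,
            "length_kb": round(finemap.interval_length_kb(interval), 3),
            "left_marker": interval.left_marker,
            "right_marker": interval.right_marker,
        },
        "simulated_truth": {"causal_chrom": config.causal_chrom, "causal_pos": config.causal_pos},
        "outputs": {k: v.name for k, v in track_paths.items()},
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    config.to_yaml(outdir / "config.yaml")
    return report
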