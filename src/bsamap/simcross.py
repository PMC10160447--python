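"""Simulation of biparental crosses, phenotype-selected bulks, and pooled
short-read allele counts for bulked segregant analysis (BSA).

The model is the classical single-locus dominant-trait setting: two fully
inbred parents (``G``, green peel; ``Y``, yellow peel) are fixed for
opposite alleles at every informative marker and at one causal locus.
Peel colour is fully penetrant dominant -- one Y-origin allele at the
causal locus makes a plant yellow.  Meiosis follows Haldane's
no-interference model: the crossover count on a chromosome is Poisson
distributed with mean ``length_cM / 100`` and crossover positions are
uniform in genetic distance, mapped to physical coordinates by linear
interpolation.

Pooled sequencing of a bulk is modelled per site as a Poisson total depth
and a binomial draw of reads carrying the green-parent allele at the
bulk's true allele frequency, perturbed by a symmetric base-error rate
``e`` (a read reports the wrong allele with probability ``e``).

Orientation convention: the simulated reference genome carries the
yellow-parent allele (REF) at every informative site and the ALT allele is
the green-parent allele.  The green bulk's SNP-index (ALT fraction) is
therefore high in the region linked to the causal locus, and
delta = index(G_pool) - index(Y_pool) is large and positive there.  All
coordinates are 1-based inclusive (VCF convention).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pysam

GREEN = "green"
YELLOW = "yellow"

#: Integer codes for parental origin of a chromosome segment.
ORIGIN_G = 0
ORIGIN_Y = 1

#: Default VCF sample names: the two parents and the two F2 bulks.
DEFAULT_SAMPLES = ("G", "Y", "G_pool", "Y_pool")

_BASES = np.array(["A", "C", "G", "T"])


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class Chromosome:
    """One chromosome of the genetic map (physical and genetic length)."""

    name: str
    length_bp: int
    length_cm: float

    def __post_init__(self):
        if self.length_bp < 1:
            raise ValueError(f"{self.name}: length_bp must be >= 1")
        if self.length_cm < 0:
            raise ValueError(f"{self.name}: length_cM must be >= 0")


@dataclass
class GeneticMap:
    """Chromosomes plus sorted informative-marker positions (bp, 1-based).

    Genetic position of a physical coordinate is obtained by linear
    interpolation between the chromosome ends (uniform recombination
    rate along each chromosome).
    """

    chromosomes: list[Chromosome]
    markers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if not self.chromosomes:
            raise ValueError("genetic map has no chromosomes")
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, pos in list(self.markers.items()):
            chrom = self.chromosome(name)
            pos = np.asarray(pos, dtype=np.int64)
            if pos.size and not np.all(np.diff(pos) > 0):
                raise ValueError(f"{name}: marker positions must be strictly increasing")
            if pos.size and (pos[0] < 1 or pos[-1] > chrom.length_bp):
                raise ValueError(f"{name}: marker positions outside [1, {chrom.length_bp}]")
            self.markers[name] = pos

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(f"unknown chromosome {name!r}")

    def cm_to_bp(self, name: str, cm: float) -> int:
        c = self.chromosome(name)
        bp = int(round(cm / c.length_cm * c.length_bp)) if c.length_cm > 0 else 1
        return min(max(bp, 1), c.length_bp)

    def bp_to_cm(self, name: str, bp: int) -> float:
        c = self.chromosome(name)
        return bp / c.length_bp * c.length_cm

    @classmethod
    def uniform(cls, chromosomes, marker_spacing_bp: int = 10_000) -> "GeneticMap":
        """Build a map with one marker every ``marker_spacing_bp``."""
        chroms = [Chromosome(*c) if not isinstance(c, Chromosome) else c for c in chromosomes]
        markers = {
            c.name: np.arange(marker_spacing_bp, c.length_bp + 1, marker_spacing_bp, dtype=np.int64)
            for c in chroms
        }
        return cls(chroms, markers)


@dataclass
class Haplotype:
    """A mosaic of parental origins along one chromosome.

    ``breaks[i]`` is the last bp (1-based, inclusive) of segment *i*;
    ``origins[i]`` is its parental origin (ORIGIN_G / ORIGIN_Y).
    The final break equals the chromosome length.
    """

    breaks: np.ndarray
    origins: np.ndarray

    def origin_at(self, positions) -> np.ndarray:
        """Parental origin at each 1-based position (vectorised)."""
        idx = np.searchsorted(self.breaks, np.asarray(positions), side="left")
        return self.origins[idx]

    def is_uniform(self) -> bool:
        return len(self.origins) == 1


def uniform_haplotype(length_bp: int, origin: int) -> Haplotype:
    return Haplotype(np.array([length_bp], dtype=np.int64), np.array([origin], dtype=np.int8))


@dataclass
class Individual:
    """Two haplotypes per chromosome plus an observed phenotype."""

    haplotypes: dict[str, tuple[Haplotype, Haplotype]]
    phenotype: str | None = None

    def alleles_at(self, chrom: str, pos: int) -> tuple[int, int]:
        h0, h1 = self.haplotypes[chrom]
        return int(h0.origin_at(pos)), int(h1.origin_at(pos))

    def n_dominant(self, locus: "CausalLocus") -> int:
        a = self.alleles_at(locus.chromosome, locus.position_bp)
        return sum(x == locus.dominant_allele_origin for x in a)


@dataclass(frozen=True)
class CausalLocus:
    """The single dominant locus controlling the trait (yellow peel)."""

    chromosome: str
    position_bp: int
    dominant_allele_origin: int = ORIGIN_Y


@dataclass(frozen=True)
class BulkSpec:
    """How many plants of each phenotype enter each bulk (pool)."""

    size_per_bulk: int = 33

    def __post_init__(self):
        if self.size_per_bulk < 1:
            raise ValueError("bulk size must be >= 1")


@dataclass(frozen=True)
class SeqSimParams:
    """Pooled-sequencing parameters.

    mean_depth
        Mean of the Poisson per-site total read depth for each bulk.
    base_error_rate
        Probability a read reports the wrong allele (symmetric).
    """

    mean_depth: float = 30.0
    base_error_rate: float = 0.005

    def __post_init__(self):
        if not self.mean_depth > 0:
            raise ValueError("mean_depth must be > 0")
        if not 0 <= self.base_error_rate < 0.5:
            raise ValueError("base_error_rate must be in [0, 0.5)")


def simulate_gamete(parent: Individual, gmap: GeneticMap, rng) -> dict[str, Haplotype]:
    """One recombinant gamete: a Haplotype per chromosome (Haldane model)."""
    rng = _as_rng(rng)
    gamete = {}
    for chrom in gmap.chromosomes:
        h0, h1 = parent.haplotypes[chrom.name]
        start = int(rng.integers(2))
        n_xo = int(rng.poisson(chrom.length_cm / 100.0)) if chrom.length_cm > 0 else 0
        # homozygous fast path: crossovers are invisible
        if h0.is_uniform() and h1.is_uniform() and h0.origins[0] == h1.origins[0]:
            gamete[chrom.name] = Haplotype(h0.breaks.copy(), h0.origins.copy())
            continue
        if n_xo == 0:
            src = (h0, h1)[start]
            gamete[chrom.name] = Haplotype(src.breaks.copy(), src.origins.copy())
            continue
        xo_cm = np.sort(rng.uniform(0.0, chrom.length_cm, size=n_xo))
        xo_bp = np.unique([gmap.cm_to_bp(chrom.name, x) for x in xo_cm])
        xo_bp = xo_bp[(xo_bp >= 1) & (xo_bp < chrom.length_bp)]
        gamete[chrom.name] = _recombine(h0, h1, xo_bp, start, chrom.length_bp)
    return gamete


def _recombine(h0: Haplotype, h1: Haplotype, xo_bp: np.ndarray, start: int, length: int) -> Haplotype:
    """Splice two haplotypes at crossover points (bp of last base before switch)."""
    haps = (h0, h1)
    breaks: list[int] = []
    origins: list[int] = []
    cur, prev = start, 0
    for cut in list(xo_bp) + [length]:
        h = haps[cur]
        i = int(np.searchsorted(h.breaks, prev + 1, side="left"))
        while h.breaks[i] < cut:
            breaks.append(int(h.breaks[i]))
            origins.append(int(h.origins[i]))
            i += 1
        breaks.append(int(cut))
        origins.append(int(h.origins[i]))
        prev, cur = cut, 1 - cur
    # merge adjacent segments of equal origin
    mb, mo = [breaks[0]], [origins[0]]
    for b, o in zip(breaks[1:], origins[1:]):
        if o == mo[-1]:
            mb[-1] = b
        else:
            mb.append(b)
            mo.append(o)
    return Haplotype(np.array(mb, dtype=np.int64), np.array(mo, dtype=np.int8))


def founder(gmap: GeneticMap, origin: int, phenotype: str) -> Individual:
    """A fully inbred parental line: both haplotypes uniform in one origin."""
    haps = {
        c.name: (uniform_haplotype(c.length_bp, origin), uniform_haplotype(c.length_bp, origin))
        for c in gmap.chromosomes
    }
    return Individual(haps, phenotype)


def simulate_population(
    design: str,
    n: int,
    gmap: GeneticMap,
    locus: CausalLocus,
    misphenotyping_rate: float = 0.0,
    seed=None,
) -> list[Individual]:
    """Simulate an F1, F2 or BC1 population segregating at ``locus``.

    F1 plants are uniform parental heterozygotes; each F2 plant is the
    union of two independent F1 gametes; each BC1 plant combines one F1
    gamete with one green-parent gamete.  Phenotype is yellow iff the
    plant carries at least one dominant allele at the causal locus, then
    flipped with probability ``misphenotyping_rate``.
    """
    if design not in ("F1", "F2", "BC1"):
        raise ValueError(f"unknown design {design!r}; expected F1, F2 or BC1")
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= misphenotyping_rate <= 1:
        raise ValueError("misphenotyping_rate must be in [0, 1]")
    chrom = gmap.chromosome(locus.chromosome)
    if not 1 <= locus.position_bp <= chrom.length_bp:
        raise ValueError("causal locus outside chromosome bounds")
    rng = _as_rng(seed)

    green = founder(gmap, ORIGIN_G, GREEN)
    f1_haps = {
        c.name: (uniform_haplotype(c.length_bp, ORIGIN_G), uniform_haplotype(c.length_bp, ORIGIN_Y))
        for c in gmap.chromosomes
    }
    f1 = Individual(f1_haps, YELLOW)

    pop: list[Individual] = []
    for _ in range(n):
        if design == "F1":
            ind = Individual({k: (h0, h1) for k, (h0, h1) in f1_haps.items()})
        elif design == "F2":
            g1 = simulate_gamete(f1, gmap, rng)
            g2 = simulate_gamete(f1, gmap, rng)
            ind = Individual({c: (g1[c], g2[c]) for c in g1})
        else:  # BC1
            g1 = simulate_gamete(f1, gmap, rng)
            g2 = simulate_gamete(green, gmap, rng)
            ind = Individual({c: (g1[c], g2[c]) for c in g1})
        ind.phenotype = YELLOW if ind.n_dominant(locus) >= 1 else GREEN
        if misphenotyping_rate > 0 and rng.random() < misphenotyping_rate:
            ind.phenotype = GREEN if ind.phenotype == YELLOW else YELLOW
        pop.append(ind)
    return pop


def phenotype_counts(population) -> tuple[int, int]:
    """(n_yellow, n_green) observed in a population."""
    ny = sum(1 for p in population if p.phenotype == YELLOW)
    return ny, len(population) - ny


@dataclass
class Bulk:
    """A phenotypically pure pool of plants with its true allele frequencies.

    ``green_allele_freq[chrom][j]`` is the frequency of the green-parent
    allele at marker *j*, i.e. the mean over the 2 x size member haplotypes.
    """

    phenotype: str
    members: list[Individual]
    green_allele_freq: dict[str, np.ndarray]


def _bulk_frequencies(members, gmap: GeneticMap) -> dict[str, np.ndarray]:
    freq = {}
    for chrom, pos in gmap.markers.items():
        if pos.size == 0:
            freq[chrom] = np.zeros(0)
            continue
        acc = np.zeros(pos.size)
        for ind in members:
            for h in ind.haplotypes[chrom]:
                acc += h.origin_at(pos) == ORIGIN_G
        freq[chrom] = acc / (2 * len(members))
    return freq


def build_bulks(population, gmap: GeneticMap, spec: BulkSpec = BulkSpec(), seed=None) -> tuple[Bulk, Bulk]:
    """Random disjoint yellow and green bulks with true allele frequencies.

    Returns ``(green_bulk, yellow_bulk)``.  Raises if the population does
    not contain enough plants of a phenotype.
    """
    rng = _as_rng(seed)
    yellows = [p for p in population if p.phenotype == YELLOW]
    greens = [p for p in population if p.phenotype == GREEN]
    for phen, avail in ((YELLOW, yellows), (GREEN, greens)):
        if len(avail) < spec.size_per_bulk:
            raise ValueError(
                f"need {spec.size_per_bulk} {phen} plants for the bulk, "
                f"only {len(avail)} available (deficit {spec.size_per_bulk - len(avail)})"
            )
    y_members = [yellows[i] for i in rng.choice(len(yellows), spec.size_per_bulk, replace=False)]
    g_members = [greens[i] for i in rng.choice(len(greens), spec.size_per_bulk, replace=False)]
    g_bulk = Bulk(GREEN, g_members, _bulk_frequencies(g_members, gmap))
    y_bulk = Bulk(YELLOW, y_members, _bulk_frequencies(y_members, gmap))
    return g_bulk, y_bulk


@dataclass
class SimulatedSite:
    """One simulated variant site with per-sample read depths.

    REF is the yellow-parent allele, ALT the green-parent allele; ``ad``
    maps sample name to (ref_depth, alt_depth) and ``gt`` to the
    genotype allele-index pair (bulks are unphased pools, GT is ./.).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    ad: dict[str, tuple[int, int]]
    gt: dict[str, tuple | None]


def simulate_read_counts(
    green_bulk: Bulk,
    yellow_bulk: Bulk,
    gmap: GeneticMap,
    params: SeqSimParams = SeqSimParams(),
    seed=None,
    samples=DEFAULT_SAMPLES,
) -> list[SimulatedSite]:
    """Draw pooled read counts at every map marker for parents and bulks.

    Per site and sample, total depth ~ Poisson(mean_depth) and the count
    of reads showing the green-parent (ALT) allele ~ Binomial(depth,
    f*(1-e) + (1-f)*e) where ``f`` is the sample's true green-allele
    frequency (1 for parent G, 0 for parent Y).
    """
    rng = _as_rng(seed)
    name_g, name_y, name_gp, name_yp = samples
    sites: list[SimulatedSite] = []
    for chrom in gmap.chromosomes:
        pos = gmap.markers.get(chrom.name, np.zeros(0, dtype=np.int64))
        if pos.size == 0:
            continue
        freqs = {
            name_g: np.ones(pos.size),
            name_y: np.zeros(pos.size),
            name_gp: green_bulk.green_allele_freq[chrom.name],
            name_yp: yellow_bulk.green_allele_freq[chrom.name],
        }
        depth = {s: rng.poisson(params.mean_depth, size=pos.size) for s in samples}
        e = params.base_error_rate
        alt_reads = {
            s: rng.binomial(depth[s], freqs[s] * (1 - e) + (1 - freqs[s]) * e) for s in samples
        }
        ref_idx = rng.integers(4, size=pos.size)
        alt_idx = (ref_idx + rng.integers(1, 4, size=pos.size)) % 4
        for j in range(pos.size):
            ad = {s: (int(depth[s][j] - alt_reads[s][j]), int(alt_reads[s][j])) for s in samples}
            gt = {name_g: (1, 1), name_y: (0, 0), name_gp: None, name_yp: None}
            sites.append(
                SimulatedSite(chrom.name, int(pos[j]), _BASES[ref_idx[j]], _BASES[alt_idx[j]], ad, gt)
            )
    return sites


def write_vcf(sites, gmap: GeneticMap, path: str, samples=DEFAULT_SAMPLES) -> None:
    """Write simulated sites as an uncompressed VCF with GT and AD fields."""
    header = pysam.VariantHeader()
    for c in gmap.chromosomes:
        header.add_line(f"##contig=<ID={c.name},length={c.length_bp}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line(
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">'
    )
    for s in samples:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as vf:
        for site in sites:
            rec = vf.new_record(
                contig=site.chrom, start=site.pos - 1, stop=site.pos - 1 + len(site.ref),
                alleles=(site.ref, site.alt),
            )
            for s in samples:
                if site.gt.get(s) is not None:
                    rec.samples[s]["GT"] = site.gt[s]
                rec.samples[s]["AD"] = site.ad[s]
            vf.write(rec)


def simulate_vcf(
    population,
    gmap: GeneticMap,
    path: str,
    spec: BulkSpec = BulkSpec(),
    params: SeqSimParams = SeqSimParams(),
    seed=None,
    samples=DEFAULT_SAMPLES,
):
    """Bulk the population, draw read counts and write a VCF.

    Returns ``(green_bulk, yellow_bulk, sites)``.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    s_bulk, s_reads = ss.spawn(2)
    g_bulk, y_bulk = build_bulks(population, gmap, spec, np.random.default_rng(s_bulk))
    sites = simulate_read_counts(g_bulk, y_bulk, gmap, params, np.random.default_rng(s_reads), samples)
    write_vcf(sites, gmap, path, samples)
    return g_bulk, y_bulk, sites
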