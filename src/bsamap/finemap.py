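"""Interval narrowing from recombinant genotypes at ordered co-dominant markers.

Each recombinant individual is genotyped at an ordered set of co-dominant
markers (A = homozygous green-parent, B = homozygous yellow-parent,
H = heterozygous, '-' = missing).  Under the single dominant locus model a
green plant must be A at the causal position, a yellow F2 plant H or B,
and a yellow BC1 plant (backcross to the green parent) H.  An
individual's genotype is known at its scored markers and constant across
runs of concordant markers; between two discordant adjacent markers the
crossover position is unobserved, so every position there is treated as
*possibly* compatible whenever either flanking call is allowed.  The
mapped interval is the intersection of possibly-compatible positions
across individuals, reported with its innermost flanking markers (the
convention in which such intervals are printed: the flanking marker
coordinates bound the locus, which lies strictly between them).

The module also selects gel-resolvable co-dominant InDel markers inside a
region and scores marker-phenotype concordance in a germplasm panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .simcross import GREEN, YELLOW

log = logging.getLogger(__name__)

CALL_A = "A"  # homozygous green-parent allele
CALL_B = "B"  # homozygous yellow-parent allele
CALL_H = "H"  # heterozygous
MISSING = "-"
_MISSING_TOKENS = {MISSING, "", ".", "NA", "nan", None}

_CONSTRAINTS = {
    (GREEN, "F2"): frozenset({CALL_A}),
    (GREEN, "BC1"): frozenset({CALL_A}),
    (YELLOW, "F2"): frozenset({CALL_H, CALL_B}),
    (YELLOW, "BC1"): frozenset({CALL_H}),
}


def normalize_call(call) -> str:
    if call in (CALL_A, CALL_B, CALL_H):
        return call
    if call in _MISSING_TOKENS or (isinstance(call, float) and call != call):
        return MISSING
    raise ValueError(f"unknown marker call {call!r}")


def genotype_constraint(phenotype: str, design: str = "F2") -> frozenset:
    """Genotype classes a phenotype allows at the causal locus."""
    if design not in ("F2", "BC1"):
        raise ValueError(f"unknown design {design!r}")
    try:
        return _CONSTRAINTS[(phenotype, design)]
    except KeyError:
        raise ValueError(f"unknown phenotype {phenotype!r}") from None


@dataclass(frozen=True)
class Marker:
    name: str
    position_bp: int


@dataclass
class IndividualCalls:
    name: str
    calls: list[str]
    phenotype: str


@dataclass
class RecombinantTable:
    """Ordered markers x individuals with phenotypes (one chromosome)."""

    markers: list[Marker]
    individuals: list[IndividualCalls]

    def __post_init__(self):
        pos = [m.position_bp for m in self.markers]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError("marker positions must be strictly increasing")
        for ind in self.individuals:
            if len(ind.calls) != len(self.markers):
                raise ValueError(f"{ind.name}: {len(ind.calls)} calls for {len(self.markers)} markers")
            ind.calls = [normalize_call(c) for c in ind.calls]

    def to_tsv(self, path: str) -> None:
        cols = ["individual", "phenotype"] + [m.name for m in self.markers]
        rows = [["position", "-"] + [m.position_bp for m in self.markers]]
        rows += [[i.name, i.phenotype] + list(i.calls) for i in self.individuals]
        pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str) -> "RecombinantTable":
        """Read the wide layout written by to_tsv (first data row = positions)."""
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if df.iloc[0]["individual"] != "position":
            raise ValueError("first data row must carry marker positions (individual='position')")
        marker_names = [c for c in df.columns if c not in ("individual", "phenotype")]
        markers = [Marker(m, int(df.iloc[0][m])) for m in marker_names]
        individuals = [
            IndividualCalls(r["individual"], [r[m] for m in marker_names], r["phenotype"])
            for _, r in df.iloc[1:].iterrows()
        ]
        return cls(markers, individuals)


@dataclass
class MappedInterval:
    """Causal interval with its innermost flanking markers (1-based, bp)."""

    start: int
    end: int
    left_marker: str
    right_marker: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("interval start must be < end")

    @property
    def length_bp(self) -> int:
        return self.end - self.start


def interval_length_kb(interval) -> float:
    """Interval length in kb: (end - start) / 1000."""
    if isinstance(interval, MappedInterval):
        return interval.length_bp / 1000.0
    start, end = interval
    return (end - start) / 1000.0


class MappingInconsistencyError(ValueError):
    """No position is compatible with every individual's phenotype."""

    def __init__(self, individuals):
        self.individuals = list(individuals)
        super().__init__(
            "phenotype/genotype inconsistency: no position satisfies all "
            f"individuals (offending: {', '.join(self.individuals)})"
        )


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1] + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def _compatible_segments(ind: IndividualCalls, markers, design, domain) -> list[tuple[int, int]]:
    """Union of [start, end] ranges possibly compatible with the phenotype.

    Genotype is the scored call at each marker; between two discordant
    adjacent markers the crossover point is unobserved, so those open
    intervals are compatible if either flanking call is allowed.  Regions
    outside the individual's scored markers (and missing calls) carry no
    information and are compatible.
    """
    allowed = genotype_constraint(ind.phenotype, design)
    known = [(m.position_bp, c) for m, c in zip(markers, ind.calls) if c != MISSING]
    if not known:
        return [domain]
    segs: list[tuple[int, int]] = []
    if domain[0] < known[0][0]:
        segs.append((domain[0], known[0][0] - 1))
    if known[-1][0] < domain[1]:
        segs.append((known[-1][0] + 1, domain[1]))
    for (p1, c1), (p2, c2) in zip(known, known[1:]):
        if c1 == c2:
            if c1 in allowed:
                segs.append((p1, p2))
        elif (c1 in allowed or c2 in allowed) and p2 - p1 > 1:
            segs.append((p1 + 1, p2 - 1))
    for p, c in known:
        if c in allowed:
            segs.append((p, p))
    return _merge(segs)


def _intersect(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out = []
    for s1, e1 in a:
        for s2, e2 in b:
            s, e = max(s1, s2), min(e1, e2)
            if s <= e:
                out.append((s, e))
    return sorted(out)


def narrow_interval(
    table: RecombinantTable,
    design: str = "F2",
    drop_most_conflicting: bool = False,
    max_drops: int = 1,
) -> MappedInterval:
    """Intersect per-individual compatible regions into the mapped interval.

    Returns the interval bounded by the innermost flanking markers: the
    locus lies strictly between ``left_marker`` and ``right_marker``
    (inclusive coordinates of those markers are reported, the convention
    in which marker-flanked intervals are printed).  With no recombinant
    individuals the interval is the full spanned region.

    Missing calls are uninformative.  On an empty intersection (some
    individual's phenotype contradicts the rest, e.g. a misphenotyped
    plant or a tight double recombinant) a MappingInconsistencyError is
    raised; with ``drop_most_conflicting`` the individual whose removal
    yields the largest non-empty intersection is dropped with a logged
    warning instead, repeating up to ``max_drops`` times.
    """
    if len(table.markers) < 2:
        raise ValueError("at least two markers required")
    if not table.individuals:
        raise ValueError("at least one individual required")
    domain = (table.markers[0].position_bp, table.markers[-1].position_bp)
    per_ind = [
        (ind.name, _compatible_segments(ind, table.markers, design, domain))
        for ind in table.individuals
    ]
    empties = [name for name, segs in per_ind if not segs]

    def _intersect_all(skip: set[str]):
        acc = [domain]
        for name, segs in per_ind:
            if name in skip:
                continue
            acc = _intersect(acc, segs)
            if not acc:
                return None, name
        return acc, None

    skipped: set[str] = set()
    while True:
        current, culprit = _intersect_all(skipped)
        if current is not None:
            break
        if not drop_most_conflicting or len(skipped) >= max_drops:
            raise MappingInconsistencyError(empties or [culprit])
        best = None
        for cand, _ in per_ind:
            if cand in skipped:
                continue
            acc, _ = _intersect_all(skipped | {cand})
            if acc is not None:
                widest = max(e - s for s, e in acc)
                if best is None or widest > best[1]:
                    best = (cand, widest)
        drop = best[0] if best is not None else culprit
        skipped.add(drop)
        log.warning("dropped most conflicting individual %s", drop)
    # an isolated excluded marker point (double-recombinant point evidence)
    # must not split the reported bound: bridge single-position holes
    bridged: list[list[int]] = []
    for s, e in current:
        if bridged and s - bridged[-1][1] <= 2:
            bridged[-1][1] = e
        else:
            bridged.append([s, e])
    start, end = max(bridged, key=lambda se: se[1] - se[0])
    left = table.markers[0]
    for m in table.markers:
        if m.position_bp <= start:
            left = m
    right = table.markers[-1]
    for m in reversed(table.markers):
        if m.position_bp >= end:
            right = m
    return MappedInterval(left.position_bp, right.position_bp, left.name, right.name)


def select_codominant_indels(sites, chrom: str, start: int, end: int, min_size_diff: int = 3):
    """InDel sites inside [start, end] whose allele-length difference is
    at least ``min_size_diff`` bp (resolvable on a PAGE gel), by position."""
    picked = [
        s
        for s in sites
        if s.chrom == chrom
        and start <= s.pos <= end
        and abs(len(s.ref) - len(s.alt)) >= min_size_diff
    ]
    return sorted(picked, key=lambda s: s.pos)


@dataclass
class ConcordanceResult:
    concordant: int
    scored: int
    missing: int

    @property
    def fraction(self) -> float:
        return self.concordant / self.scored


def marker_concordance(calls, phenotypes) -> ConcordanceResult:
    """Fraction of individuals whose phenotype matches the marker prediction.

    Under dominance the marker predicts yellow iff the call is H or B.
    Missing calls are excluded from the denominator and reported.
    """
    if len(calls) != len(phenotypes):
        raise ValueError("calls and phenotypes must have equal length")
    concordant = scored = missing = 0
    for call, phen in zip(calls, phenotypes):
        call = normalize_call(call)
        if call == MISSING:
            missing += 1
            continue
        scored += 1
        predicted = YELLOW if call in (CALL_H, CALL_B) else GREEN
        concordant += predicted == phen
    if scored == 0:
        raise ValueError("all marker calls are missing")
    return ConcordanceResult(concordant, scored, missing)
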