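"""Recombinant-based interval narrowing, marker selection, concordance."""

import numpy as np
import pytest

from bsamap import finemap as fm
from bsamap import simcross as sc
from bsamap import variantio as vio


def oracle_interval(table, design):
    """Independent position-by-position compatibility scan (1 bp grid).

    At a scored marker the genotype is the call; strictly between two
    scored markers the crossover point is unknown, so either flanking
    call is possible; outside the scored range anything is possible.
    """
    positions = [m.position_bp for m in table.markers]
    lo, hi = positions[0], positions[-1]

    def possible(ind, p):
        known = [(mp, c) for mp, c in zip(positions, ind.calls) if c != fm.MISSING]
        if not known or p < known[0][0] or p > known[-1][0]:
            return {fm.CALL_A, fm.CALL_B, fm.CALL_H}
        for mp, c in known:
            if p == mp:
                return {c}
        for (p1, c1), (p2, c2) in zip(known, known[1:]):
            if p1 < p < p2:
                return {c1, c2}
        raise AssertionError("unreachable")

    ok = np.ones(hi - lo + 1, dtype=bool)
    for ind in table.individuals:
        allowed = fm.genotype_constraint(ind.phenotype, design)
        for i, p in enumerate(range(lo, hi + 1)):
            if ok[i] and not (possible(ind, p) & allowed):
                ok[i] = False
    if not ok.any():
        return None
    # largest run, bridging single-position holes as the implementation does
    runs, start = [], None
    for i, v in enumerate(ok):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start + lo, i - 1 + lo))
            start = None
    if start is not None:
        runs.append((start + lo, hi))
    bridged = []
    for s, e in runs:
        if bridged and s - bridged[-1][1] <= 2:
            bridged[-1][1] = e
        else:
            bridged.append([s, e])
    a, b = max(bridged, key=lambda se: se[1] - se[0])
    left = max((p for p in positions if p <= a), default=lo)
    right = min((p for p in positions if p >= b), default=hi)
    return left, right


def table(marker_pos, rows):
    markers = [fm.Marker(f"M{i+1}", p) for i, p in enumerate(marker_pos)]
    inds = [fm.IndividualCalls(f"I{j}", list(calls), phen) for j, (calls, phen) in enumerate(rows)]
    return fm.RecombinantTable(markers, inds)


class TestGenotypeConstraint:
    @pytest.mark.parametrize(
        "phen,design,expected",
        [
            (sc.GREEN, "F2", {"A"}),
            (sc.GREEN, "BC1", {"A"}),
            (sc.YELLOW, "F2", {"H", "B"}),
            (sc.YELLOW, "BC1", {"H"}),
        ],
    )
    def test_allowed_sets(self, phen, design, expected):
        assert fm.genotype_constraint(phen, design) == frozenset(expected)

    def test_unknown_inputs_rejected(self):
        with pytest.raises(ValueError):
            fm.genotype_constraint("striped", "F2")
        with pytest.raises(ValueError):
            fm.genotype_constraint(sc.GREEN, "RIL")


class TestNarrowInterval:
    def test_single_green_recombinant_bounds_locus_right_of_switch(self):
        t = table([10, 30, 50, 70, 90], [("HHHAA", sc.GREEN)])
        iv = fm.narrow_interval(t, "F2")
        assert (iv.start, iv.end) == (50, 90)
        assert (iv.left_marker, iv.right_marker) == ("M3", "M5")
        assert oracle_interval(t, "F2") == (50, 90)

    def test_no_recombinants_gives_full_span(self):
        t = table([10, 50, 90], [("AAA", sc.GREEN), ("HHH", sc.YELLOW), ("BBB", sc.YELLOW)])
        iv = fm.narrow_interval(t, "F2")
        assert (iv.start, iv.end) == (10, 90)
        assert oracle_interval(t, "F2") == (10, 90)

    def test_opposing_recombinants_bracket_middle_marker(self):
        rows = [("HHAAA", sc.GREEN), ("AAAHH", sc.GREEN), ("HHHHH", sc.YELLOW)]
        t = table([10, 30, 50, 70, 90], rows)
        iv = fm.narrow_interval(t, "F2")
        assert (iv.start, iv.end) == (30, 70)
        assert iv.start < 50 < iv.end  # brackets the middle marker
        assert oracle_interval(t, "F2") == (30, 70)

    def test_yellow_f2_individuals_add_constraints(self):
        # a yellow plant that is A at distal markers excludes that side
        rows = [("HHHHH", sc.YELLOW), ("HHHAA", sc.YELLOW)]
        t = table([10, 30, 50, 70, 90], rows)
        iv = fm.narrow_interval(t, "F2")
        assert (iv.start, iv.end) == (10, 70)
        assert oracle_interval(t, "F2") == (10, 70)

    def test_bc1_yellow_cannot_be_homozygous(self):
        rows = [("HHBB", sc.YELLOW)]
        t = table([10, 30, 50, 70], rows)
        iv = fm.narrow_interval(t, "BC1")
        assert (iv.start, iv.end) == (10, 50)
        assert oracle_interval(t, "BC1") == (10, 50)

    def test_missing_calls_are_uninformative(self):
        t1 = table([10, 30, 50, 70, 90], [("HH-AA", sc.GREEN)])
        iv = fm.narrow_interval(t1, "F2")
        # with M3 missing, the switch is only known to lie in (M2, M4)
        assert (iv.start, iv.end) == (30, 90)
        assert oracle_interval(t1, "F2") == (30, 90)

    def test_inconsistency_raises_and_names_individual(self):
        # an all-H "green" plant is impossible under full penetrance
        t = table([10, 50, 90], [("AAA", sc.GREEN), ("HHH", sc.GREEN)])
        with pytest.raises(fm.MappingInconsistencyError, match="I1"):
            fm.narrow_interval(t, "F2")
        assert oracle_interval(t, "F2") is None

    def test_drop_most_conflicting_recovers(self):
        rows = [("HHAAA", sc.GREEN), ("AAAHH", sc.GREEN), ("HHH HH".replace(" ", ""), sc.GREEN)]
        t = table([10, 30, 50, 70, 90], rows)
        iv = fm.narrow_interval(t, "F2", drop_most_conflicting=True)
        assert (iv.start, iv.end) == (30, 70)

    def test_adding_individuals_never_widens(self, rng):
        gmap = sc.GeneticMap.uniform([sc.Chromosome("c", 10_000, 60.0)], 1_000)
        locus = sc.CausalLocus("c", 5_500)
        marker_pos = gmap.markers["c"]
        markers = [fm.Marker(f"M{i}", int(p)) for i, p in enumerate(marker_pos)]
        pop = sc.simulate_population("F2", 60, gmap, locus, seed=41)
        rows = []
        for j, ind in enumerate(pop):
            h0, h1 = ind.haplotypes["c"]
            ng = (h0.origin_at(marker_pos) == 0).astype(int) + (h1.origin_at(marker_pos) == 0).astype(int)
            rows.append(fm.IndividualCalls(f"P{j}", [("B", "H", "A")[g] for g in ng], ind.phenotype))
        widths = []
        for n in (5, 15, 30, 60):
            t = fm.RecombinantTable(markers, rows[:n])
            iv = fm.narrow_interval(t, "F2", drop_most_conflicting=True, max_drops=3)
            widths.append(iv.length_bp)
        assert all(b <= a for a, b in zip(widths, widths[1:]))

    def test_matches_oracle_on_simulated_tables(self):
        gmap = sc.GeneticMap.uniform([sc.Chromosome("c", 10_000, 60.0)], 1_000)
        locus = sc.CausalLocus("c", 5_500)
        marker_pos = gmap.markers["c"]
        markers = [fm.Marker(f"M{i}", int(p)) for i, p in enumerate(marker_pos)]
        for seed in range(5):
            pop = sc.simulate_population("F2", 40, gmap, locus, seed=100 + seed)
            rows = []
            for j, ind in enumerate(pop):
                h0, h1 = ind.haplotypes["c"]
                ng = (h0.origin_at(marker_pos) == 0).astype(int) + (
                    h1.origin_at(marker_pos) == 0
                ).astype(int)
                rows.append(fm.IndividualCalls(f"P{j}", [("B", "H", "A")[g] for g in ng], ind.phenotype))
            t = fm.RecombinantTable(markers, rows)
            expected = oracle_interval(t, "F2")
            if expected is None:
                with pytest.raises(fm.MappingInconsistencyError):
                    fm.narrow_interval(t, "F2")
            else:
                iv = fm.narrow_interval(t, "F2")
                assert (iv.start, iv.end) == expected
                assert iv.start <= locus.position_bp <= iv.end

    def test_tsv_round_trip(self, tmp_path):
        t = table([10, 30, 50], [("HHA", sc.GREEN), ("AA-", sc.YELLOW)])
        path = tmp_path / "rec.tsv"
        t.to_tsv(path)
        back = fm.RecombinantTable.from_tsv(path)
        assert [m.position_bp for m in back.markers] == [10, 30, 50]
        assert [i.calls for i in back.individuals] == [list("HHA"), list("AA-")]
        assert [i.phenotype for i in back.individuals] == [sc.GREEN, sc.YELLOW]


class TestIntervalLength:
    def test_published_style_coordinates(self):
        assert fm.interval_length_kb((8_812_267, 8_983_006)) == pytest.approx(170.739)

    @pytest.mark.parametrize("start,end,kb", [(5, 1_005, 1.0), (1, 1_000_001, 1000.0)])
    def test_simple_lengths(self, start, end, kb):
        assert fm.interval_length_kb((start, end)) == kb

    def test_accepts_mapped_interval(self):
        iv = fm.MappedInterval(1_000, 171_739, "L", "R")
        assert fm.interval_length_kb(iv) == pytest.approx(170.739)


class TestMarkerSelection:
    def _indel(self, pos, ref, alt):
        return vio.VariantSite(
            "LG10", pos, ref, alt,
            {"G": (1, 1), "Y": (0, 0), "G_pool": None, "Y_pool": None},
            {"G": (0, 30), "Y": (30, 0), "G_pool": (15, 15), "Y_pool": (15, 15)},
        )

    def test_selection_rules(self):
        inside_big = self._indel(2_000, "A", "A" + "T" * 55)  # 55 bp insertion
        inside_small = self._indel(3_000, "AT", "A")  # 1 bp, below gel resolution
        outside = self._indel(9_000, "A", "ATTTTT")
        snp = self._indel(2_500, "A", "T")
        picked = fm.select_codominant_indels([outside, inside_small, inside_big, snp], "LG10", 1_000, 5_000)
        assert picked == [inside_big]

    def test_empty_region(self):
        assert fm.select_codominant_indels([], "LG10", 1, 100) == []


class TestConcordance:
    def test_perfectly_linked_marker(self):
        calls = list("AHBHA")
        phens = [sc.GREEN, sc.YELLOW, sc.YELLOW, sc.YELLOW, sc.GREEN]
        assert fm.marker_concordance(calls, phens).fraction == 1.0

    def test_one_discordant_of_thirty_seven(self):
        calls = ["H"] * 20 + ["A"] * 17
        phens = [sc.YELLOW] * 20 + [sc.GREEN] * 16 + [sc.YELLOW]
        res = fm.marker_concordance(calls, phens)
        assert res.fraction == pytest.approx(36 / 37)
        assert res.scored == 37

    def test_missing_calls_excluded_and_counted(self):
        res = fm.marker_concordance(["H", "-", "A"], [sc.YELLOW, sc.YELLOW, sc.GREEN])
        assert res.scored == 2 and res.missing == 1 and res.fraction == 1.0

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            fm.marker_concordance(["-", "-"], [sc.GREEN, sc.YELLOW])
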