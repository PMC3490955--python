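"""Quadrat rasterisation, range areas and degree of sympatry."""
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st_h

from sympatree.geo import (
    GridSpec,
    LocalityTable,
    OverlapMatrix,
    RangeMap,
    degree_of_sympatry,
    haversine_km,
    overlap_matrix,
    range_area_km2,
    rasterize_ranges,
)


def make_rangemap(**quadrats):
    return RangeMap(
        quadrats={k: frozenset(v) for k, v in quadrats.items()},
        grid=GridSpec(),
    )


class TestLocalityTable:
    def test_valid_records(self):
        t = LocalityTable.from_records(
            [("a", -21.5, 165.5), ("a", -21.6, 165.4), ("b", -22.0, 166.0)]
        )
        assert t.counts() == {"a": 2, "b": 1}
        assert t.species == ["a", "b"]

    @pytest.mark.parametrize(
        "lat,lon", [(120.0, 165.5), (-91.0, 165.5), (-21.5, 181.0)]
    )
    def test_out_of_bounds_names_record(self, lat, lon):
        with pytest.raises(ValueError, match="record 1"):
            LocalityTable.from_records([("a", -21.5, 165.5), ("a", lat, lon)])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            LocalityTable.from_records([])


class TestRasterize:
    def test_distant_species_disjoint(self):
        # 100 km >> 2 * 4 km radius
        t = LocalityTable.from_records(
            [("a", -21.5, 165.5), ("b", -21.5, 166.47)]
        )
        rm = rasterize_ranges(t)
        assert not (rm["a"] & rm["b"])

    def test_close_localities_union_no_double_count(self):
        close = LocalityTable.from_records(
            [("a", -21.5, 165.5), ("a", -21.509, 165.5)]
        )
        rm = rasterize_ranges(close)
        single1 = rasterize_ranges(
            LocalityTable.from_records([("a", -21.5, 165.5)])
        )
        single2 = rasterize_ranges(
            LocalityTable.from_records([("a", -21.509, 165.5)])
        )
        assert rm["a"] == single1["a"] | single2["a"]
        assert len(rm["a"]) < len(single1["a"]) + len(single2["a"])

    def test_matches_brute_force_window_scan(self):
        grid = GridSpec()
        lat, lon = -21.5, 165.5
        rm = rasterize_ranges(
            LocalityTable.from_records([("a", lat, lon)]), grid
        )
        # independent scan of a 1-degree window, law-of-cosines distance
        expect = set()
        i0, j0 = grid.quadrat_of(lat, lon)
        for i in range(i0 - 20, i0 + 21):
            for j in range(j0 - 20, j0 + 21):
                clat, clon = grid.center(i, j)
                d = 6371.0 * math.acos(
                    min(
                        1.0,
                        math.sin(math.radians(lat)) * math.sin(math.radians(clat))
                        + math.cos(math.radians(lat))
                        * math.cos(math.radians(clat))
                        * math.cos(math.radians(clon - lon)),
                    )
                )
                if d <= grid.radius_km:
                    expect.add((i, j))
        expect.add((i0, j0))
        assert rm["a"] == expect

    def test_containing_quadrat_guard(self):
        # radius smaller than half a cell: the point's quadrat is still there
        grid = GridSpec(radius_km=0.1)
        rm = rasterize_ranges(
            LocalityTable.from_records([("a", -21.5001, 165.5001)]), grid
        )
        assert rm["a"] == {grid.quadrat_of(-21.5001, 165.5001)}


class TestArea:
    def test_hand_evaluated_cell_area(self):
        i = math.floor(-21.5 / 0.025)
        rm = make_rangemap(a=[(i, j) for j in range(8)])
        phi = (i + 0.5) * 0.025
        side = 0.025 * 111.32
        expected = 8 * side * side * math.cos(math.radians(phi))
        assert range_area_km2(rm, "a") == pytest.approx(expected, rel=1e-12)
        assert range_area_km2(rm, "a") == pytest.approx(57.66, abs=0.05)

    def test_doubling_quadrats_doubles_area(self):
        i = math.floor(-21.5 / 0.025)
        rm1 = make_rangemap(a=[(i, j) for j in range(8)])
        rm2 = make_rangemap(a=[(i, j) for j in range(16)])
        assert range_area_km2(rm2, "a") == pytest.approx(
            2 * range_area_km2(rm1, "a")
        )

    def test_empty_range_impossible(self):
        with pytest.raises(ValueError):
            make_rangemap(a=[])

    def test_unknown_species(self):
        rm = make_rangemap(a=[(0, 0)])
        with pytest.raises(KeyError):
            range_area_km2(rm, "zzz")


class TestDegreeOfSympatry:
    @pytest.mark.parametrize(
        "qa,qb,expected",
        [
            ([(0, 0), (0, 1)], [(0, 0), (0, 1)], 1.0),  # identical
            ([(0, 0)], [(5, 5)], 0.0),  # disjoint
            ([(0, 0), (0, 1)], [(0, 0), (0, 1), (0, 2), (1, 0)], 1.0),  # nested
            (
                [(0, 0), (0, 1), (0, 2), (0, 3)],
                [(0, 2), (0, 3)] + [(9, j) for j in range(8)],
                0.5,
            ),  # |A|=4, |B|=10, |A&B|=2
        ],
    )
    def test_examples(self, qa, qb, expected):
        rm = make_rangemap(a=qa, b=qb)
        assert degree_of_sympatry(rm, "a", "b") == pytest.approx(expected)
        assert degree_of_sympatry(rm, "b", "a") == pytest.approx(expected)

    def test_unknown_species(self):
        rm = make_rangemap(a=[(0, 0)], b=[(0, 1)])
        with pytest.raises(KeyError):
            degree_of_sympatry(rm, "a", "nope")


class TestOverlapMatrix:
    def test_identical_ranges_all_ones(self):
        rm = make_rangemap(a=[(0, 0)], b=[(0, 0)], c=[(0, 0)])
        om = overlap_matrix(rm)
        assert np.allclose(om.values, 1.0)

    def test_disjoint_off_diagonal_zero(self):
        om = overlap_matrix(make_rangemap(a=[(0, 0)], b=[(9, 9)]))
        assert om.value("a", "b") == 0.0
        assert om.value("a", "a") == 1.0

    def test_consistent_with_pairwise_calls(self):
        t = LocalityTable.from_records(
            [
                ("a", -21.5, 165.5),
                ("a", -21.52, 165.52),
                ("b", -21.51, 165.51),
                ("c", -21.8, 165.9),
            ]
        )
        rm = rasterize_ranges(t)
        om = overlap_matrix(rm)
        for x in rm.species:
            for y in rm.species:
                if x != y:
                    assert om.value(x, y) == pytest.approx(
                        degree_of_sympatry(rm, x, y)
                    )

    def test_single_species_rejected(self):
        with pytest.raises(ValueError):
            overlap_matrix(make_rangemap(a=[(0, 0)]))

    def test_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            OverlapMatrix(["a", "b"], np.array([[1.0, 0.2], [0.3, 1.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            OverlapMatrix(["a", "b"], np.array([[0.9, 0.2], [0.2, 1.0]]))


quadset = st_h.sets(
    st_h.tuples(
        st_h.integers(min_value=-5, max_value=5),
        st_h.integers(min_value=-5, max_value=5),
    ),
    min_size=1,
    max_size=12,
)


class TestProperties:
    @given(qa=quadset, qb=quadset)
    def test_overlap_bounds_and_symmetry(self, qa, qb):
        rm = make_rangemap(a=qa, b=qb)
        o = degree_of_sympatry(rm, "a", "b")
        assert 0.0 <= o <= 1.0
        assert o == degree_of_sympatry(rm, "b", "a")

    @given(qa=quadset, qb=quadset, qc=quadset)
    def test_relabeling_equivariance(self, qa, qb, qc):
        om1 = overlap_matrix(make_rangemap(a=qa, b=qb, c=qc))
        om2 = overlap_matrix(make_rangemap(c=qc, a=qa, b=qb))
        for x in "abc":
            for y in "abc":
                assert om1.value(x, y) == om2.value(x, y)

    @pytest.mark.parametrize("shift_cells", [1, 4, -40])
    def test_longitude_translation_invariance(self, shift_cells):
        base = [("a", -21.5, 165.5), ("a", -21.53, 165.52), ("b", -21.51, 165.6)]
        moved = [
            (sp, lat, lon + shift_cells * 0.025) for sp, lat, lon in base
        ]
        rm1 = rasterize_ranges(LocalityTable.from_records(base))
        rm2 = rasterize_ranges(LocalityTable.from_records(moved))
        for sp in ("a", "b"):
            assert len(rm1[sp]) == len(rm2[sp])
            assert rm2[sp] == {(i, j + shift_cells) for i, j in rm1[sp]}

    def test_adding_locality_grows_range_and_intersection(self):
        a1 = LocalityTable.from_records([("a", -21.5, 165.5)])
        a2 = LocalityTable.from_records(
            [("a", -21.5, 165.5), ("a", -21.7, 165.7)]
        )
        q1 = rasterize_ranges(a1)["a"]
        q2 = rasterize_ranges(a2)["a"]
        assert q1 <= q2
        other = rasterize_ranges(
            LocalityTable.from_records([("b", -21.55, 165.55)])
        )["b"]
        assert len(q1 & other) <= len(q2 & other)

    def test_haversine_sanity(self):
        # one degree of longitude at the equator ~ 111.2 km on R=6371
        assert haversine_km(0, 0, 0, 1) == pytest.approx(111.19, abs=0.05)

    def test_rangemap_json_roundtrip(self):
        rm = make_rangemap(a=[(0, 0), (1, 2)], b=[(3, 3)])
        back = RangeMap.from_json(rm.to_json())
        assert back.quadrats == dict(rm.quadrats)
        assert back.grid == rm.grid
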