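"""Gridding, presence matrices, branch incidence, redundancy, regridding."""

import numpy as np
import pytest

from spatialphylo.grid import (
    GridSpec,
    assign_cell,
    build_branch_incidence,
    build_presence_matrix,
    read_occurrences,
    regrid,
    sampling_redundancy,
)
from tests.conftest import C1, C2, C3, FIXTURE_RECORDS, random_instance


class TestAssignCell:
    @pytest.mark.parametrize(
        "lon,lat,res,expected_ll",
        [
            (-73.05, 4.12, 0.1, (-73.1, 4.1)),
            (-73.10, 4.10, 0.1, (-73.1, 4.1)),  # lower edge belongs to the cell
            (0.0, 0.0, 0.5, (0.0, 0.0)),
        ],
    )
    def test_floor_arithmetic(self, lon, lat, res, expected_ll):
        grid = GridSpec(resolution=res)
        cell = assign_cell(lon, lat, grid)
        ll = grid.lower_left(cell)
        assert ll[0] == pytest.approx(expected_ll[0])
        assert ll[1] == pytest.approx(expected_ll[1])

    def test_deterministic_and_half_open(self):
        grid = GridSpec(resolution=0.1)
        inside = assign_cell(0.0999999, 0.05, grid)
        edge = assign_cell(0.1, 0.05, grid)
        assert inside == (0, 0)
        assert edge == (1, 0)

    def test_invalid_resolution(self):
        with pytest.raises(ValueError):
            GridSpec(resolution=0)


class TestReadOccurrences:
    def _write(self, tmp_path, rows, header="species,decimalLongitude,decimalLatitude"):
        p = tmp_path / "occ.csv"
        p.write_text(header + "\n" + "\n".join(rows) + ("\n" if rows else ""))
        return p

    def test_valid_rows(self, tmp_path):
        p = self._write(tmp_path, ["A,1.0,2.0", "B,3.0,4.0", "C,5.0,6.0"])
        records, report = read_occurrences(p)
        assert len(records) == 3
        assert report.n_rejected == 0

    def test_out_of_bounds_dropped(self, tmp_path):
        p = self._write(tmp_path, ["A,1.0,95.0", "B,3.0,4.0"])
        records, report = read_occurrences(p)
        assert len(records) == 1
        assert report.n_rejected == 1

    def test_non_numeric_dropped(self, tmp_path):
        p = self._write(tmp_path, ["A,x,2.0", "B,3.0,4.0"])
        records, _ = read_occurrences(p)
        assert [r[0] for r in records] == ["B"]

    def test_missing_column_error(self, tmp_path):
        p = self._write(tmp_path, ["A,1.0"], header="species,decimalLongitude")
        with pytest.raises(ValueError, match="decimalLatitude"):
            read_occurrences(p)

    def test_empty_file_error(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(ValueError, match="no records"):
            read_occurrences(p)

    def test_configurable_columns(self, tmp_path):
        p = self._write(tmp_path, ["A,1.0,2.0"], header="sp,x,y")
        records, _ = read_occurrences(p, species_col="sp", lon_col="x", lat_col="y")
        assert records == [("A", 1.0, 2.0)]


class TestPresenceMatrix:
    def test_duplicates_collapse(self, fixture_grid):
        pm = build_presence_matrix(
            [("A", 0.01, 0.01), ("A", 0.02, 0.02)], fixture_grid
        )
        assert pm.incidence.sum() == 1
        assert pm.record_count[0] == 2

    def test_fixture_margins(self, fixture_pm):
        assert fixture_pm.cells == [C1, C2, C3]
        assert list(fixture_pm.richness) == [2, 2, 1]
        by_sp = dict(zip(fixture_pm.species, fixture_pm.range_size))
        assert by_sp == {"A": 2, "B": 1, "C": 1, "D": 1}

    def test_extent_filter_can_empty(self, fixture_grid):
        with pytest.raises(ValueError, match="no cells retained"):
            build_presence_matrix(
                [("A", 50.0, 50.0)], fixture_grid, extent=(0, 0, 1, 1)
            )

    def test_presence_counting_identity(self):
        # Σ_species range = number of presences = Σ_cells SR
        rng = np.random.default_rng(3)
        for _ in range(10):
            _, pm = random_instance(rng)
            assert pm.range_size.sum() == pm.incidence.sum() == pm.richness.sum()


class TestBranchIncidence:
    def test_internal_branches_are_unions(self, fixture_bi):
        by_id = dict(zip(fixture_bi.branch_ids, fixture_bi.branch_range))
        assert by_id["E"] == 2  # A in c1,c2 ∪ B in c1
        assert by_id["F"] == 2  # C in c2 ∪ D in c3
        i_f = fixture_bi.branch_ids.index("F")
        assert list(fixture_bi.incidence[:, i_f]) == [False, True, True]

    def test_tip_columns_equal_species_columns(self, fixture_pm, fixture_bi):
        for sp in fixture_pm.species:
            tip_col = fixture_bi.incidence[:, fixture_bi.branch_ids.index(sp)]
            pm_col = fixture_pm.incidence[:, fixture_pm.species.index(sp)]
            assert (tip_col == pm_col).all()

    def test_internal_dominates_descendants(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            tree, pm = random_instance(rng)
            bi = build_branch_incidence(pm, tree)
            # every branch's incidence dominates each descendant tip's
            for j, sp in enumerate(bi.species):
                anc_branches = np.flatnonzero(bi.ancestry[j])
                tip_col = pm.incidence[:, pm.species.index(sp)]
                for b in anc_branches:
                    assert (bi.incidence[:, b] >= tip_col).all()

    def test_no_overlap_error(self, fixture_pm):
        from spatialphylo.phylo import parse_newick

        other = parse_newick("(X:1,Y:1);")
        with pytest.raises(ValueError, match="no species shared"):
            build_branch_incidence(fixture_pm, other)

    def test_unshared_species_dropped_with_warning(self, fixture_grid, fixture_tree):
        pm = build_presence_matrix(
            FIXTURE_RECORDS + [("Zed", 0.31, 0.01)], fixture_grid
        )
        with pytest.warns(UserWarning, match="not on the tree"):
            bi = build_branch_incidence(pm, fixture_tree)
        assert "Zed" not in bi.species
        assert len(bi.cells) == 3  # Zed's private cell dropped


class TestRedundancy:
    @pytest.mark.parametrize(
        "records,richness,expected",
        [(5, 5, 0.0), (10, 4, 0.6), (1, 1, 0.0)],
    )
    def test_formula(self, records, richness, expected, fixture_grid):
        from spatialphylo.grid import PresenceMatrix

        inc = np.ones((1, richness), dtype=bool)
        pm = PresenceMatrix(
            [(0, 0)], [f"s{i}" for i in range(richness)], inc,
            np.array([records]), fixture_grid,
        )
        assert sampling_redundancy(pm)[0] == pytest.approx(expected)


class TestRegrid:
    def test_identity_factor(self, fixture_pm):
        assert regrid(fixture_pm, 1) is fixture_pm

    def test_union_within_block(self, fixture_grid):
        # one species in 2 adjacent fine cells inside one coarse cell
        pm = build_presence_matrix(
            [("A", 0.01, 0.01), ("A", 0.11, 0.01)], fixture_grid
        )
        coarse = regrid(pm, 5)
        assert coarse.n_cells == 1
        assert coarse.range_size[0] == 1
        assert coarse.record_count[0] == 2

    def test_non_integer_factor_error(self, fixture_pm):
        with pytest.raises(ValueError):
            regrid(fixture_pm, 2.5)

    def test_coarse_richness_dominates_fine(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            _, pm = random_instance(rng)
            coarse = regrid(pm, 5)
            fine_max = {}
            for i, (ix, iy) in enumerate(pm.cells):
                key = (ix // 5, iy // 5)
                fine_max[key] = max(fine_max.get(key, 0), pm.richness[i])
            for k, cell in enumerate(coarse.cells):
                assert coarse.richness[k] >= fine_max[cell]
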