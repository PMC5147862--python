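import numpy as np
import pytest

from raseff.contact_engine import CATEGORIES
from raseff.errors import EmptyInputError, SpecConflictError
from raseff.interaction_matrix import (
    build_matrix,
    detect_regions,
    hotspot_report,
    matrix_bundle,
)
from raseff.synthetic_data import make_hotspot_fixture, make_planted_matrix


@pytest.fixture(scope="module")
def hotspot():
    return make_hotspot_fixture(n_structures=3)


class TestBuildMatrix:
    def test_per_structure_counts_structures_not_pairs(self, hotspot):
        contacts, ras_maps, eff_maps, _ = hotspot
        m = build_matrix(contacts, ras_maps, eff_maps, mode="per-structure")
        # structures toy1 and toy2 both plant a contact at (37, 66)
        assert m.cell(37, 66) == 2
        assert m.counts.max() == 2

    def test_atom_pairs_mode_sums_pairs(self, hotspot):
        contacts, ras_maps, eff_maps, _ = hotspot
        per = build_matrix(contacts, ras_maps, eff_maps, mode="per-structure")
        ap = build_matrix(contacts, ras_maps, eff_maps, mode="atom-pairs")
        # each planted contact is one atom pair, so modes agree here
        assert np.array_equal(per.counts, ap.counts)

    def test_conservation_in_atom_pairs_mode(self, hotspot):
        contacts, ras_maps, eff_maps, _ = hotspot
        m = build_matrix(contacts, ras_maps, eff_maps, mode="atom-pairs")
        total_input = sum(
            rec.atom_pairs_total for recs in contacts.values() for rec in recs
        )
        assert m.counts.sum() == total_input - len(m.skip_report)

    def test_category_closure(self, hotspot):
        contacts, ras_maps, eff_maps, _ = hotspot
        m = build_matrix(contacts, ras_maps, eff_maps, mode="atom-pairs")
        stacked = sum(m.category_counts[c] for c in CATEGORIES)
        assert np.array_equal(stacked, m.counts)

    def test_structure_order_permutation_invariant(self, hotspot):
        contacts, ras_maps, eff_maps, _ = hotspot
        m1 = build_matrix(contacts, ras_maps, eff_maps)
        reordered = dict(reversed(list(contacts.items())))
        m2 = build_matrix(reordered, ras_maps, eff_maps)
        r1 = detect_regions(m1)
        r2 = detect_regions(m2)
        assert matrix_bundle(m1, r1) == matrix_bundle(m2, r2)

    def test_zero_structures_raise(self):
        with pytest.raises(EmptyInputError):
            build_matrix({}, {}, {})

    def test_unmappable_residue_goes_to_skip_report(self, hotspot):
        contacts, ras_maps, eff_maps, _ = hotspot
        # truncate one RAS map so its planted residues fall off the frame
        sid = sorted(contacts)[0]
        crippled = dict(ras_maps)
        crippled[sid] = type(ras_maps[sid])(
            protein_name="HRAS",
            residue_to_column={},
            column_to_reference=ras_maps[sid].column_to_reference,
        )
        m = build_matrix(contacts, crippled, eff_maps)
        assert len(m.skip_report) == len(contacts[sid])
        assert all(d["structure_id"] == sid for d in m.skip_report)


class TestDetectRegions:
    def test_all_zero_matrix_has_no_regions(self):
        assert detect_regions(np.zeros((10, 10), dtype=int)) == []

    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
    def test_planted_blocks_recovered_exactly(self, k):
        blocks = [((5 * i, 5 * i + 1), (6 * i, 6 * i + 2), 2 + i) for i in range(k)]
        matrix, truth = make_planted_matrix(blocks, (40, 40))
        regions = detect_regions(matrix)
        assert len(regions) == k
        assert {frozenset(t) for t in truth} == {r.cells for r in regions}

    def test_single_block_conserves_total(self):
        matrix, truth = make_planted_matrix([((2, 3), (4, 5), 3)], (10, 10))
        (region,) = detect_regions(matrix)
        assert region.total_count == 12
        assert region.label == "R1"

    def test_ranked_by_total_count(self):
        matrix, _ = make_planted_matrix(
            [((0, 1), (0, 1), 2), ((10, 11), (10, 11), 9)], (20, 20)
        )
        regions = detect_regions(matrix)
        assert [r.label for r in regions] == ["R1", "R2"]
        assert regions[0].row_span == (10, 11)

    def test_bridge_connects_across_sparse_rows(self):
        m = np.zeros((9, 9), dtype=int)
        m[2, 2] = m[4, 2] = m[2, 4] = m[4, 4] = 5  # holes of width 1
        assert len(detect_regions(m, min_count=2, min_cells=3, bridge=1)) == 1
        assert len(detect_regions(m, min_count=2, min_cells=4, bridge=0)) == 0

    def test_small_components_discarded(self):
        m = np.zeros((10, 10), dtype=int)
        m[0, 0] = m[0, 1] = 5
        assert detect_regions(m, min_count=2, min_cells=3) == []


class TestPlantedMatrixGenerator:
    def test_overlapping_blocks_rejected(self):
        with pytest.raises(SpecConflictError):
            make_planted_matrix([((0, 3), (0, 3), 2), ((2, 5), (2, 5), 2)], (10, 10))

    def test_too_close_blocks_rejected(self):
        with pytest.raises(SpecConflictError):
            make_planted_matrix([((0, 1), (0, 1), 2), ((0, 1), (3, 4), 2)], (10, 10))

    def test_no_blocks_gives_empty_matrix(self):
        matrix, truth = make_planted_matrix([], (5, 5))
        assert matrix.sum() == 0 and truth == []


class TestHotspotReport:
    def test_recognition_block_rows_are_backbone_dominated(self, hotspot):
        contacts, ras_maps, eff_maps, expected = hotspot
        m = build_matrix(contacts, ras_maps, eff_maps)
        regions = detect_regions(m)
        assert len(regions) >= 1
        report = hotspot_report(m, regions, top_k=5)
        top = report["regions"][0]
        lo, hi = expected["rows"]
        assert lo <= top["row_span"][0] and top["row_span"][1] <= hi
        for row in expected["mm_dominated_rows"]:
            assert top["row_dominant_category"][row] == "mm"

    def test_maxima_inside_planted_block(self, hotspot):
        contacts, ras_maps, eff_maps, expected = hotspot
        m = build_matrix(contacts, ras_maps, eff_maps)
        peak = np.unravel_index(np.argmax(m.counts), m.counts.shape)
        row, col = m.row_labels[peak[0]], m.col_labels[peak[1]]
        assert expected["rows"][0] <= row <= expected["rows"][1]
        assert expected["cols"][0] <= col <= expected["cols"][1]

    def test_marginals_conserve_cell_total(self, hotspot):
        contacts, ras_maps, eff_maps, _ = hotspot
        m = build_matrix(contacts, ras_maps, eff_maps)
        report = hotspot_report(m, detect_regions(m))
        assert sum(report["marginals"]["row_totals"].values()) == m.counts.sum()
        assert sum(report["marginals"]["col_totals"].values()) == m.counts.sum()

    def test_empty_region_list_gives_header_only_report(self, hotspot):
        contacts, ras_maps, eff_maps, _ = hotspot
        m = build_matrix(contacts, ras_maps, eff_maps)
        report = hotspot_report(m, [])
        assert report["regions"] == []
        assert "marginals" in report
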