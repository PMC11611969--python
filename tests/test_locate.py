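"""McDonald localization, atlas condensation, batch/single equivalence."""

import numpy as np
import pandas as pd
import pytest

from mslesion.change import label_components
from mslesion.io_volumes import LabelMap, VolumeGrid
from mslesion.locate import (
    AtlasCondensation,
    LocationParams,
    MappingCoverageError,
    RegionSet,
    assign_mcdonald_region,
    condense_atlas,
    default_condensation,
    locate_component_atlas,
    locate_components,
)
from mslesion.phantom import synthetic_full_atlas
from tests.conftest import make_mask


SHAPE = (20, 20, 20)


@pytest.fixture
def regions():
    vent = np.zeros(SHAPE, dtype=np.uint8)
    vent[8:12, 8:12, 8:12] = 1
    ribbon = np.zeros(SHAPE, dtype=np.uint8)
    ribbon[1:3, :, :] = 1  # a slab standing in for the cortical shell
    infra = np.zeros(SHAPE, dtype=np.uint8)
    infra[:, :, 0:3] = 1
    return RegionSet(
        ventricles=make_mask(vent),
        cortical_ribbon=make_mask(ribbon),
        infratentorial=make_mask(infra),
    )


def blob(*ranges):
    m = np.zeros(SHAPE, dtype=np.uint8)
    m[tuple(slice(a, b) for a, b in ranges)] = 1
    return make_mask(m)


def test_overlapping_masks_rejected():
    both = np.zeros(SHAPE, dtype=np.uint8)
    both[5, 5, 5] = 1
    with pytest.raises(ValueError, match="overlap"):
        RegionSet(ventricles=make_mask(both), cortical_ribbon=make_mask(both), infratentorial=make_mask(np.zeros(SHAPE, np.uint8)))


class TestMcDonald:
    def test_each_region_recovered(self, regions):
        assert assign_mcdonald_region(blob((10, 12), (10, 12), (0, 2)), regions) == "infratentorial"
        # shares voxels with the ventricle mask
        assert assign_mcdonald_region(blob((11, 14), (9, 11), (9, 11)), regions) == "periventricular"
        # majority inside the ribbon slab
        assert assign_mcdonald_region(blob((1, 3), (5, 8), (10, 13)), regions) == "cortical"
        # adjacent to (1 voxel from) the ribbon but mostly outside it
        assert assign_mcdonald_region(blob((3, 6), (5, 8), (10, 13)), regions) == "juxtacortical"
        assert assign_mcdonald_region(blob((14, 16), (14, 16), (10, 12)), regions) == "other"

    def test_near_but_not_touching_ventricle_is_other(self, regions):
        # 3 voxels clear of the ventricle cube, far from every other mask
        comp = blob((15, 17), (9, 11), (9, 11))
        assert assign_mcdonald_region(comp, regions, LocationParams(periventricular_distance_mm=0.0)) == "other"
        assert (
            assign_mcdonald_region(comp, regions, LocationParams(periventricular_distance_mm=4.0))
            == "periventricular"
        )

    def test_precedence_resolves_multi_region(self, regions):
        # overlaps both the infratentorial slab and the ventricles
        comp = blob((9, 11), (9, 11), (1, 10))
        assert assign_mcdonald_region(comp, regions) == "infratentorial"
        flipped = LocationParams(
            precedence=("periventricular", "infratentorial", "cortical", "juxtacortical", "other")
        )
        assert assign_mcdonald_region(comp, regions, flipped) == "periventricular"

    def test_empty_component_rejected(self, regions):
        with pytest.raises(ValueError, match="empty"):
            assign_mcdonald_region(make_mask(np.zeros(SHAPE, np.uint8)), regions)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            LocationParams(periventricular_distance_mm=-1)
        with pytest.raises(ValueError):
            LocationParams(precedence=("infratentorial", "other"))


class TestCondensation:
    def test_identity_mapping(self):
        atlas = synthetic_full_atlas((8, 8, 8), n_labels=5)
        ident = AtlasCondensation({i: i for i in range(1, 6)}, [f"a{i}" for i in range(1, 6)])
        np.testing.assert_array_equal(condense_atlas(atlas, ident).data, atlas.data)

    def test_shipped_table_condenses_95_to_23(self):
        table = default_condensation()
        assert table.n_key_areas == 23
        assert set(table.mapping) == set(range(1, 96))
        for name in ("temporal lobe", "cingulum", "basal ganglia"):
            assert name in table.key_area_names
        atlas = synthetic_full_atlas(n_labels=95)
        out = condense_atlas(atlas, table)
        assert out.labels().size == 23

    def test_unmapped_label_raises_named_error(self):
        atlas = synthetic_full_atlas(n_labels=96)
        with pytest.raises(MappingCoverageError, match="96"):
            condense_atlas(atlas, default_condensation())

    def test_foreground_support_preserved(self):
        atlas = synthetic_full_atlas(n_labels=95)
        out = condense_atlas(atlas, default_condensation())
        np.testing.assert_array_equal(out.data > 0, atlas.data > 0)


class TestAtlasOverlap:
    def grid_labels(self, data):
        return LabelMap(VolumeGrid(np.asarray(data, dtype=np.int32)))

    def test_full_containment(self):
        lab = np.full(SHAPE, 4, dtype=np.int32)
        comp = blob((2, 5), (2, 5), (2, 5))
        area, frac = locate_component_atlas(comp, self.grid_labels(lab))
        assert (area, frac) == (4, 1.0)

    def test_majority_and_tie_break(self):
        lab = np.zeros(SHAPE, dtype=np.int32)
        lab[:10], lab[10:] = 4, 9
        comp = blob((7, 12), (0, 2), (0, 2))  # 60% in 4, 40% in 9
        area, frac = locate_component_atlas(comp, self.grid_labels(lab))
        assert area == 4 and frac == pytest.approx(0.6)
        comp = blob((8, 12), (0, 2), (0, 2))  # 50/50 -> smaller label id
        area, frac = locate_component_atlas(comp, self.grid_labels(lab))
        assert area == 4 and frac == pytest.approx(0.5)

    def test_outside_all_labels(self):
        lab = np.zeros(SHAPE, dtype=np.int32)
        assert locate_component_atlas(blob((0, 2), (0, 2), (0, 2)), self.grid_labels(lab)) == (0, 0.0)


def test_locate_components_equals_single_calls(regions):
    mask = np.zeros(SHAPE, dtype=np.uint8)
    mask[10:12, 10:12, 1:3] = 1  # infratentorial
    mask[11:13, 9:11, 9:11] = 1  # periventricular
    mask[16:18, 16:18, 16:18] = 1  # other
    labels = label_components(make_mask(mask))
    df = locate_components(labels, regions)
    assert len(df) == 3
    for _, row in df.iterrows():
        single = make_mask((labels.data == row.component_id).astype(np.uint8))
        assert assign_mcdonald_region(single, regions) == row.region
        assert row.voxel_count == single.data.sum()
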