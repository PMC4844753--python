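import numpy as np
import pytest

from alveoquant import (
    CellRecord,
    ImageVolume,
    LabelVolume,
    NucleationClass,
    NucleusRecord,
    SceneSpec,
    VoxelSpacing,
    assign_nuclei,
    classify_nucleation,
    detect_fusion_candidates,
    edu_distribution,
    generate_scene,
    score_markers,
    segment_nuclei,
)
from conftest import digitize_sphere

ANISO = VoxelSpacing(1.0, 0.5, 0.5)


def render_spheres(centers, radius, shape, spacing, amplitude=1.0):
    data = np.zeros(shape)
    for c in centers:
        data[digitize_sphere(c, radius, shape, spacing)] = amplitude
    return ImageVolume(data, spacing, "nuclear")


class TestSegmentNuclei:
    def test_empty_channel_zero_labels(self):
        img = ImageVolume(np.zeros((10, 20, 20)), ANISO, "nuclear")
        assert segment_nuclei(img).label_ids().size == 0

    def test_two_separated_nuclei(self):
        centers = [(8.0, 8.0, 8.0), (8.0, 8.0, 24.0)]
        img = render_spheres(centers, 4.0, (16, 32, 64), ANISO)
        labels = segment_nuclei(img)
        ids = labels.label_ids()
        assert ids.size == 2
        from scipy import ndimage

        sp = np.array(ANISO.tuple)
        got = sorted(
            tuple(np.array(c) * sp)
            for c in ndimage.center_of_mass(labels.labels > 0, labels.labels, ids)
        )
        for (gz, gy, gx), (cz, cy, cx) in zip(got, sorted(centers)):
            assert abs(gz - cz) <= ANISO.dz and abs(gy - cy) <= ANISO.dy \
                and abs(gx - cx) <= ANISO.dx

    def test_touching_nuclei_split_by_watershed(self):
        radius = 4.0
        centers = [(8.0, 10.0, 10.0), (8.0, 10.0, 16.0)]  # distance 1.5 r
        img = render_spheres(centers, radius, (16, 40, 52), ANISO)
        labels = segment_nuclei(img)
        assert labels.label_ids().size == 2


class TestAssignNuclei:
    def _volumes(self):
        cells = np.zeros((6, 10, 10), dtype=np.int64)
        cells[:, :5] = 3
        cells[:, 5:] = 5
        nuclei = np.zeros_like(cells)
        return cells, nuclei

    def test_nucleus_inside_cell_unflagged(self):
        cells, nuclei = self._volumes()
        nuclei[2:4, 1:4, 1:4] = 1
        recs = assign_nuclei(LabelVolume(nuclei, ANISO), LabelVolume(cells, ANISO))
        assert recs[0].cell_label == 3
        assert not recs[0].ambiguous_flag
        assert recs[0].volume == pytest.approx(2 * 3 * 3 * 0.25)

    def test_sixty_forty_split_majority_unflagged(self):
        cells, nuclei = self._volumes()
        nuclei[0, 2:8, 0] = 1  # 6 voxels: y 2..7 -> 3 in cell 3, 3 in cell 5
        nuclei[1, 2:5, 0] = 1  # 3 more voxels in cell 3 -> 6/9 vs 3/9
        recs = assign_nuclei(LabelVolume(nuclei, ANISO), LabelVolume(cells, ANISO))
        assert recs[0].cell_label == 3
        assert not recs[0].ambiguous_flag  # 67% >= 50%

    def test_plurality_below_half_is_flagged(self):
        cells, nuclei = self._volumes()
        cells[:, :, :] = 0
        cells[:, 0:3] = 3
        cells[:, 3:6] = 5
        cells[:, 6:10] = 0
        nuclei[0, 1:8, 0] = 1  # 2 voxels cell3, 3 voxels cell5, 2 background
        recs = assign_nuclei(LabelVolume(nuclei, ANISO), LabelVolume(cells, ANISO))
        assert recs[0].cell_label == 5
        assert recs[0].ambiguous_flag

    def test_background_plurality_unassigned(self):
        cells, nuclei = self._volumes()
        cells[:, :, :] = 0
        cells[0, 0, 0] = 3
        nuclei[2:5, 7:9, 7:9] = 1
        recs = assign_nuclei(LabelVolume(nuclei, ANISO), LabelVolume(cells, ANISO))
        assert recs[0].cell_label == 0

    def test_fixture_scene_assignment_matches_truth(self, small_scene):
        channels, truth = small_scene
        labels = segment_nuclei(channels[1])
        recs = assign_nuclei(labels, truth.cell_labels)
        from alveoquant import match_labels

        nucleus_map = match_labels(truth.nucleus_labels, labels).mapping(0.5)
        got = {rec.nucleus_label: rec.cell_label for rec in recs}
        for true_nuc, pred_nuc in nucleus_map.items():
            assert got[pred_nuc] == truth.nucleus_to_cell[true_nuc]


class TestClassifyNucleation:
    def test_counts_map_to_classes(self):
        cells = np.zeros((2, 4, 8), dtype=np.int64)
        cells[:, :, :2] = 1
        cells[:, :, 2:4] = 2
        cells[:, :, 4:6] = 3
        cells[:, :, 6:] = 4
        assignments = (
            [NucleusRecord(nucleus_label=1, cell_label=2)]
            + [NucleusRecord(nucleus_label=i, cell_label=3) for i in (2, 3)]
            + [NucleusRecord(nucleus_label=i, cell_label=4) for i in (4, 5, 6)]
        )
        recs = classify_nucleation(LabelVolume(cells, ANISO), assignments)
        classes = {r.cell_label: r.nucleation_class for r in recs}
        assert classes[1] is NucleationClass.ANUCLEATE
        assert classes[2] is NucleationClass.MONONUCLEATED
        assert classes[3] is NucleationClass.BINUCLEATED
        assert classes[4] is NucleationClass.MULTINUCLEATED

    def test_nucleus_count_conservation(self):
        cells = np.ones((2, 4, 4), dtype=np.int64)
        assignments = [
            NucleusRecord(nucleus_label=i, cell_label=1) for i in range(1, 4)
        ]
        recs = classify_nucleation(LabelVolume(cells, ANISO), assignments)
        assert sum(r.nucleus_count for r in recs) == len(assignments)

    def test_permutation_invariance(self):
        cells = np.zeros((2, 4, 4), dtype=np.int64)
        cells[:, :2] = 1
        cells[:, 2:] = 2
        assignments = [
            NucleusRecord(nucleus_label=1, cell_label=1),
            NucleusRecord(nucleus_label=2, cell_label=2),
            NucleusRecord(nucleus_label=3, cell_label=2),
        ]
        a = classify_nucleation(LabelVolume(cells, ANISO), assignments)
        b = classify_nucleation(LabelVolume(cells, ANISO), assignments[::-1])
        assert [r.to_row() for r in a] == [r.to_row() for r in b]

    def test_unknown_cell_rejected(self):
        cells = np.ones((2, 2, 2), dtype=np.int64)
        with pytest.raises(ValueError, match="unknown cell"):
            classify_nucleation(
                LabelVolume(cells, ANISO),
                [NucleusRecord(nucleus_label=1, cell_label=9)],
            )

    def test_forced_trinucleated_cell_is_flagged_multinucleated(self, small_spec):
        channels, truth = generate_scene(
            small_spec, nucleus_count_override={3: 3}
        )
        labels = segment_nuclei(channels[1])
        recs = assign_nuclei(labels, truth.cell_labels)
        cells = classify_nucleation(truth.cell_labels, recs)
        classes = {c.cell_label: c.nucleation_class for c in cells}
        assert classes[3] is NucleationClass.MULTINUCLEATED


class TestMarkers:
    def _scene_with_marker(self):
        spec = SceneSpec(
            alveolus_radius=22.0, lumen_radius=13.0, n_cells=12,
            nucleus_radius=3.0, p_binucleated=0.5,
            marker_probs={"EdU": (0.3, 0.7)}, seed=21,
        )
        return generate_scene(spec)

    def test_zero_channel_all_negative(self):
        nuclei = LabelVolume(np.ones((4, 4, 4), dtype=np.int64), ANISO)
        recs = [NucleusRecord(nucleus_label=1)]
        chan = ImageVolume(np.zeros((4, 4, 4)), ANISO, "marker:EdU")
        score_markers(nuclei, [chan], recs)
        assert not recs[0].markers["marker:EdU"].positive

    def test_fixed_threshold_above_max_all_negative(self):
        nuclei = LabelVolume(np.ones((4, 4, 4), dtype=np.int64), ANISO)
        recs = [NucleusRecord(nucleus_label=1)]
        chan = ImageVolume(np.full((4, 4, 4), 5.0), ANISO, "marker:EdU")
        score_markers(nuclei, [chan], recs, threshold_rule={"marker:EdU": 10.0})
        assert not recs[0].markers["marker:EdU"].positive

    def test_otsu_recovers_truth_positivity(self):
        channels, truth = self._scene_with_marker()
        marker = [c for c in channels if c.channel_name == "marker:EdU"]
        recs = assign_nuclei(truth.nucleus_labels, truth.cell_labels)
        score_markers(truth.nucleus_labels, marker, recs)
        truth_by_cell = {c.cell_label: c.markers["EdU"].positive for c in truth.cells}
        for rec in recs:
            assert rec.markers["marker:EdU"].positive == truth_by_cell[rec.cell_label]

    def test_distribution_all_positive_fraction_one(self):
        cells = [CellRecord(cell_label=1, nucleus_count=1, nucleus_labels=[1]),
                 CellRecord(cell_label=2, nucleus_count=2, nucleus_labels=[2, 3])]
        from alveoquant.records import MarkerCall

        nuclei = [
            NucleusRecord(nucleus_label=i, cell_label=c,
                          markers={"m": MarkerCall(1.0, True)})
            for i, c in [(1, 1), (2, 2), (3, 2)]
        ]
        table = edu_distribution(cells, nuclei, "m")
        by_class = table.set_index("nucleation_class")
        assert by_class.loc["mononucleated", "fraction_positive"] == 1.0
        assert by_class.loc["binucleated", "fraction_positive"] == 1.0
        # empty classes are undefined, not zero
        assert np.isnan(by_class.loc["multinucleated", "fraction_positive"])
        assert by_class.loc["multinucleated", "n"] == 0


class TestFusionDetection:
    def _confetti_scene(self):
        spec = SceneSpec(
            alveolus_radius=22.0, lumen_radius=13.0, n_cells=12,
            nucleus_radius=3.0, reporter_colors=4, seed=13,
        )
        return generate_scene(spec)

    def test_single_coloured_scene_has_no_candidates(self):
        channels, truth = self._confetti_scene()
        reporters = [c for c in channels if c.channel_name.startswith("reporter:")]
        cells = [
            CellRecord(cell_label=c.cell_label, nucleus_count=c.nucleus_count,
                       nucleus_labels=list(c.nucleus_labels))
            for c in truth.cells
        ]
        assert detect_fusion_candidates(cells, reporters, truth.cell_labels) == []

    def test_painted_cell_is_the_only_candidate(self):
        channels, truth = self._confetti_scene()
        reporters = [c for c in channels if c.channel_name.startswith("reporter:")]
        target = truth.cells[0]
        own = target.reporter_colors_expressed[0]
        other = 1 + (own % 4)  # a colour the cell does not express
        painted = reporters[other - 1]
        data = np.asarray(painted.data).copy()
        data[truth.cell_labels.labels == target.cell_label] = 1.0
        reporters[other - 1] = ImageVolume(data, painted.spacing, painted.channel_name)
        cells = [
            CellRecord(cell_label=c.cell_label, nucleus_count=c.nucleus_count,
                       nucleus_labels=list(c.nucleus_labels))
            for c in truth.cells
        ]
        got = detect_fusion_candidates(cells, reporters, truth.cell_labels)
        assert got == [target.cell_label]

    def test_all_zero_channels_no_candidates(self):
        cells = [CellRecord(cell_label=1)]
        labels = LabelVolume(np.ones((4, 4, 4), dtype=np.int64), ANISO)
        chans = [
            ImageVolume(np.zeros((4, 4, 4)), ANISO, f"reporter:{i}") for i in (1, 2)
        ]
        assert detect_fusion_candidates(cells, chans, labels) == []

    def test_needs_two_channels(self):
        labels = LabelVolume(np.ones((4, 4, 4), dtype=np.int64), ANISO)
        with pytest.raises(ValueError, match="2 reporter"):
            detect_fusion_candidates(
                [], [ImageVolume(np.zeros((4, 4, 4)), ANISO, "reporter:1")], labels
            )


class TestFullChainOnFixture:
    def test_noiseless_chain_reproduces_truth_classes(self, small_spec):
        from dataclasses import replace

        spec = replace(small_spec, photons=0.0, read_noise_sd=0.0)
        channels, truth = generate_scene(spec)
        labels = segment_nuclei(channels[1])
        recs = assign_nuclei(labels, truth.cell_labels)
        cells = classify_nucleation(truth.cell_labels, recs)
        want = {c.cell_label: c.nucleus_count for c in truth.cells}
        got = {c.cell_label: c.nucleus_count for c in cells}
        assert got == want

    def test_nuclear_volumes_comparable_between_classes(self, default_scene):
        channels, truth = default_scene
        labels = segment_nuclei(channels[1])
        recs = assign_nuclei(labels, truth.cell_labels)
        count = {c.cell_label: c.nucleus_count for c in truth.cells}
        mono = [r.volume for r in recs if count.get(r.cell_label) == 1]
        bi = [r.volume for r in recs if count.get(r.cell_label) == 2]
        assert mono and bi
        assert abs(np.mean(mono) - np.mean(bi)) / np.mean(mono) < 0.05
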