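"""The Experiment facade: mapping, querying, and lazy pixel loading."""

from itertools import product

import numpy as np
import pytest
import yaml

from voltime.annotation import Label, Segment, Timeline
from voltime.core import frames_of_volumes
from voltime.database import UnknownGroupError
from voltime.experiment import Experiment
from voltime.fixtures import toy_annotations


class TestCreate:
    def test_toy_directory_summary(self, toy_experiment):
        d = toy_experiment.describe()
        assert d["n_files"] == 3
        assert d["n_frames"] == 42
        assert d["n_full_volumes"] == 4
        assert d["n_tail_frames"] == 2
        assert d["n_head_frames"] == 0

    def test_single_exact_file(self, tmp_path):
        import tifffile

        path = tmp_path / "one.tif"
        tifffile.imwrite(path, np.zeros((10, 4, 4), dtype=np.uint8), photometric="minisblack")
        exp = Experiment.create(files=[path], frames_per_volume=10)
        assert exp.volume_map.n_full_volumes == 1
        assert exp.tracks == {}

    def test_bad_annotation_names_group(self, toy_dir):
        bad = Timeline(
            group="light",
            segments=(
                Segment(label=Label(group="light", name="off"), duration=41),
            ),
        )
        with pytest.raises(ValueError, match="light"):
            Experiment.create(files=toy_dir, frames_per_volume=10,
                              annotations=[bad])

    def test_directory_order_is_lexicographic(self, toy_experiment):
        names = [f.path.name for f in toy_experiment.file_map.files]
        assert names == sorted(names) == ["toy_000.tif", "toy_001.tif", "toy_002.tif"]


class TestChooseFrames:
    def test_shape_square_frames(self, toy_experiment):
        expected = sorted(
            set(range(9, 17)) | set(range(25, 33)) | {41, 42}
        )
        assert toy_experiment.choose_frames([("shape", "square")], "or") == expected

    def test_empty_condition_list_is_an_error(self, toy_experiment):
        with pytest.raises(ValueError, match="condition"):
            toy_experiment.choose_frames([])

    def test_exhaustive_union(self, toy_experiment):
        result = toy_experiment.choose_frames(
            [("light", "on"), ("light", "off")], "or"
        )
        assert result == list(range(1, 43))

    def test_unknown_group(self, toy_experiment):
        with pytest.raises(UnknownGroupError, match="available"):
            toy_experiment.choose_frames([("sound", "loud")])


class TestChooseVolumes:
    def test_caption_and_query(self, toy_experiment):
        assert toy_experiment.choose_volumes(
            [("label", "c3"), ("light", "on")], "and"
        ) == [3]

    def test_caption_or_query(self, toy_experiment):
        assert toy_experiment.choose_volumes(
            [("label", "c3"), ("light", "on")], "or"
        ) == [2, 3]

    def test_shape_never_fills_a_volume(self, toy_experiment):
        # the shape switches mid-volume, so no full volume is all square
        assert toy_experiment.choose_volumes([("shape", "square")], "and") == []

    def test_memory_and_sql_paths_agree_exhaustively(self, toy_db_experiment):
        """Every condition pair x logic gives identical results on both paths."""
        exp_db = toy_db_experiment
        exp_mem = Experiment(
            file_map=exp_db.file_map,
            volume_map=exp_db.volume_map,
            tracks=exp_db.tracks,
            db=None,
        )
        labels = [
            (group, name)
            for group, track in exp_db.tracks.items()
            for name in track.label_names
        ]
        assert len(labels) == 7
        for (c1, c2), logic in product(product(labels, labels), ["and", "or"]):
            conds = [c1, c2]
            assert exp_db.choose_frames(conds, logic) == exp_mem.choose_frames(
                conds, logic
            )
            assert exp_db.choose_volumes(conds, logic) == exp_mem.choose_volumes(
                conds, logic
            )

    def test_and_result_within_every_single_condition(self, toy_experiment):
        conds = [("label", "c3"), ("light", "on")]
        both = set(toy_experiment.choose_volumes(conds, "and"))
        for cond in conds:
            assert both <= set(toy_experiment.choose_volumes([cond]))


class TestLoading:
    def test_volume_pixel_content(self, toy_experiment):
        stack = toy_experiment.load_volumes([3])
        assert stack.shape == (1, 10, 16, 16)
        assert stack[0, :, 0, 0].tolist() == list(range(31, 41))

    def test_two_volumes_caller_order(self, toy_experiment):
        stack = toy_experiment.load_volumes([3, 2])
        assert stack.shape == (2, 10, 16, 16)
        assert stack[0, 0, 0, 0] == 31 and stack[1, 0, 0, 0] == 21

    def test_empty_volume_request(self, toy_experiment):
        stack = toy_experiment.load_volumes([])
        assert stack.shape[0] == 0

    def test_partial_volume_requires_flag(self, toy_experiment):
        with pytest.raises(ValueError, match="partial"):
            toy_experiment.load_volumes([3, -2])
        stacks = toy_experiment.load_volumes([3, -2], allow_partial=True)
        assert stacks[0].shape == (10, 16, 16)
        assert stacks[1].shape == (2, 16, 16)
        assert stacks[1][:, 0, 0].tolist() == [41, 42]

    def test_frames_across_file_boundary(self, toy_experiment):
        stack = toy_experiment.load_frames([13, 14])
        assert stack.shape == (2, 16, 16)
        assert stack[:, 0, 0].tolist() == [13, 14]

    def test_duplicate_frames_preserved(self, toy_experiment):
        stack = toy_experiment.load_frames([5, 5, 1])
        assert stack[:, 0, 0].tolist() == [5, 5, 1]

    def test_choose_then_load_on_frames(self, toy_experiment):
        frames = toy_experiment.choose_frames([("light", "on")])
        stack = toy_experiment.load_frames(frames)
        assert stack.shape == (17, 16, 16)
        assert stack[:, 0, 0].tolist() == list(range(26, 43))

    def test_every_volume_matches_frame_loading(self, toy_experiment):
        """4D volume loading equals stacking the per-frame 3D loads."""
        for v in toy_experiment.volume_map.full_volume_codes:
            via_volume = toy_experiment.load_volumes([v])[0]
            frames = frames_of_volumes(toy_experiment.volume_map, [v])
            via_frames = toy_experiment.load_frames(frames)
            assert np.array_equal(via_volume, via_frames)

    def test_every_frame_content_matches_encoding(self, toy_experiment):
        stack = toy_experiment.load_frames(list(range(1, 43)))
        for f in range(1, 43):
            assert np.all(stack[f - 1] == f)


class TestDescribe:
    def test_group_label_counts(self, toy_experiment):
        d = toy_experiment.describe()
        assert d["n_groups"] == 3
        assert d["groups"]["light"]["label_counts"] == {"off": 25, "on": 17}
        assert d["groups"]["label"]["cycle_length"] == 40
        assert d["groups"]["shape"]["cycle_length"] == 16

    def test_counts_sum_to_total_per_group(self, toy_experiment):
        d = toy_experiment.describe()
        for group in d["groups"].values():
            assert sum(group["label_counts"].values()) == 42

    def test_empty_experiment_has_zero_groups(self, tmp_path):
        import tifffile

        path = tmp_path / "one.tif"
        tifffile.imwrite(path, np.zeros((10, 4, 4), dtype=np.uint8), photometric="minisblack")
        exp = Experiment.create(files=[path], frames_per_volume=5)
        assert exp.describe()["n_groups"] == 0


class TestFrameReport:
    def test_frame_30_full_bookkeeping(self, toy_experiment):
        report = toy_experiment.frame_report(30)
        assert report["file_order"] == 2 and report["page_index"] == 3
        assert report["volume_code"] == 2 and report["slice_index"] == 9
        assert report["labels"] == {"light": "on", "label": "c3", "shape": "square"}
        assert report["iterations"] == {"shape": 1, "label": 0}


class TestYamlConfig:
    def test_full_roundtrip(self, toy_dir, tmp_path):
        config = {
            "data_dir": str(toy_dir),
            "frames_per_volume": 10,
            "annotations": {
                "light": {
                    "kind": "timeline",
                    "segments": [{"off": 25}, {"on": 17}],
                },
                "label": {
                    "kind": "cycle",
                    "segments": [{"c1": 10}, {"c2": 10}, {"c3": 20}],
                },
                "shape": {
                    "kind": "cycle",
                    "segments": [{"circle": 8}, {"square": 8}],
                },
            },
        }
        path = tmp_path / "exp.yaml"
        path.write_text(yaml.safe_dump(config))
        exp = Experiment.from_config(path)
        assert exp.choose_volumes([("label", "c3"), ("light", "on")], "and") == [3]
        canonical = toy_annotations()
        assert set(exp.tracks) == {a.group for a in canonical}

    def test_explicit_file_list_overrides_order(self, toy_dir):
        files = [toy_dir / "toy_002.tif", toy_dir / "toy_000.tif",
                 toy_dir / "toy_001.tif"]
        exp = Experiment.from_config(
            {"files": [str(f) for f in files], "frames_per_volume": 10}
        )
        assert [f.path.name for f in exp.file_map.files] == [
            "toy_002.tif", "toy_000.tif", "toy_001.tif"
        ]
        assert exp.file_map.cumulative_offsets == (0, 16, 29)

    def test_bad_kind_rejected(self, toy_dir):
        with pytest.raises(ValueError, match="kind"):
            Experiment.from_config(
                {
                    "data_dir": str(toy_dir),
                    "frames_per_volume": 10,
                    "annotations": {"light": {"kind": "loop", "segments": []}},
                }
            )


class TestPersistenceRoundtrip:
    def test_restored_experiment_queries_without_tiffs(self, toy_dir, tmp_path):
        exp = Experiment.create(
            files=toy_dir, frames_per_volume=10, annotations=toy_annotations()
        )
        db_path = tmp_path / "exp.db"
        exp.save(db_path)
        restored = Experiment.load(db_path)
        assert restored.choose_volumes(
            [("label", "c3"), ("light", "on")], "and"
        ) == [3]
        assert restored.choose_frames([("shape", "circle")]) == \
            exp.choose_frames([("shape", "circle")])
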