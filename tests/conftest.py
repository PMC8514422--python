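import pytest
import trimesh

from autobend import (BendingConfig, JointFrame, LandmarkSet,
                      SegmentParams, build_segment, make_block_segment)


@pytest.fixture(scope="session")
def block():
    """Default synthetic block segment plus its ground truth."""
    return make_block_segment(SegmentParams())


@pytest.fixture
def unit_cube():
    return trimesh.creation.box((1.0, 1.0, 1.0))


@pytest.fixture
def cube_pair_segment():
    """Two unit cubes, gap 2 along x, axis-aligned landmark pairs.

    A minimal hand-built segment (no zyg tabs in the meshes; the zyg
    landmark pair is defined with reference length 2 for arithmetic tests).
    """
    a = trimesh.creation.box((1, 1, 1))
    a.apply_translation([-1.5, 0, 0])
    b = trimesh.creation.box((1, 1, 1))
    b.apply_translation([1.5, 0, 0])
    lm = LandmarkSet({
        "ant_dorsal": (-1, 0.5, 0), "ant_ventral": (-1, -0.5, 0),
        "ant_left": (-1, 0, 0.5), "ant_right": (-1, 0, -0.5),
        "post_dorsal": (1, 0.5, 0), "post_ventral": (1, -0.5, 0),
        "post_left": (1, 0, 0.5), "post_right": (1, 0, -0.5),
        "zyg_post_caudal": (1, 0.5, 0.5), "zyg_pre_cranial": (-1, 0.5, 0.5),
    })
    return build_segment(a, b, JointFrame.standard(), lm)


@pytest.fixture
def intersection_only():
    return BendingConfig(intersection_threshold=0.0, enabled=("intersection",))
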