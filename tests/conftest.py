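import numpy as np
import pytest

from micropop import synthetic as syn


@pytest.fixture(scope="session")
def space_hier():
    """Miniature symmetric layered reference space shared across tests."""
    return syn.make_reference_space(dims=(132, 80, 114), n_areas=4, seed=1)


@pytest.fixture(scope="session")
def space(space_hier):
    return space_hier[0]


@pytest.fixture(scope="session")
def hier(space_hier):
    return space_hier[1]


@pytest.fixture(scope="session")
def identity_study(space_hier):
    """10-section experiment with identity warp and known ground truth."""
    space, hier = space_hier
    return syn.make_experiment(space, hier, n_sections=10, warp_magnitude_px=0.0, seed=7)


@pytest.fixture(scope="session")
def flatmap(space_hier):
    space, hier = space_hier
    return syn.make_flatmap_lookup(space, hier)


def recover_experiment(study):
    """Run a synthetic study through clean → warp → voxelize → assemble.

    Returns (record, removed_px, clamped, out_of_space)."""
    from micropop.anchoring import build_warp
    from micropop.segmentation import clean_small_objects, recode_labels
    from micropop.voxelization import assemble_experiment, voxelize_section

    incs = []
    removed = clamped = oos = 0
    for s in study.sections:
        seg = recode_labels(s.raw_labels, stem=s.stem)
        cleaned, rep = clean_small_objects(seg)
        removed += sum(rep["pixels_removed"].values())
        warp = build_warp(s.markers, (s.anchor.width_px, s.anchor.height_px))
        src, tgt, vrep = voxelize_section(cleaned, s.anchor, warp, study.space)
        clamped += vrep["clamped"]
        oos += vrep["out_of_space"]
        incs.append((src, tgt))
    record = assemble_experiment(incs, study.experiment_id)
    return record, removed, clamped, oos
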