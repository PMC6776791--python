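import numpy as np
import pytest

import crevalid as cv


@pytest.fixture(scope="session")
def small_scene():
    """One modest FISH field with default co-expression, reused widely."""
    image, truth = cv.simulate_fish_image(
        n_cells=40, image_shape=(640, 640), seed=101
    )
    return image, truth


@pytest.fixture(scope="session")
def truth_label_map(small_scene):
    """A NucleusLabelMap built directly from the planted geometry."""
    _, truth = small_scene
    return label_map_from_truth(truth, (640, 640))


def label_map_from_truth(truth, shape):
    """Rasterize planted ellipses into core + disc-dilated label maps."""
    from crevalid.nucleus_segmentation import NucleusLabelMap, dilate_labels
    from crevalid.synthetic_data import _elliptical_radius_sq

    core = np.zeros(shape, dtype=np.int32)
    for i, ((r0, c0), (a, b), ang) in enumerate(
        zip(truth.nucleus_centers, truth.nucleus_axes, truth.nucleus_angles),
        start=1,
    ):
        rmax = int(np.ceil(max(a, b))) + 1
        rlo, rhi = max(0, int(r0) - rmax), min(shape[0], int(r0) + rmax + 1)
        clo, chi = max(0, int(c0) - rmax), min(shape[1], int(c0) + rmax + 1)
        rr, cc = np.mgrid[rlo:rhi, clo:chi]
        inside = _elliptical_radius_sq(rr, cc, (r0, c0), (a, b), ang) <= 1.0
        core[rlo:rhi, clo:chi][inside] = i
    labels = dilate_labels(core, truth.dilation_radius)
    counts = np.bincount(labels.ravel())
    areas = {i: int(counts[i]) for i in range(1, len(counts)) if counts[i]}
    return NucleusLabelMap(labels=labels, core_labels=core, areas=areas)


def puncta_set_from_truth(truth, probe):
    """A PunctaSet holding the planted puncta coordinates of one probe."""
    from crevalid.puncta_detection import PunctaSet

    table = truth.puncta[probe]
    return PunctaSet(
        channel=probe,
        centroids=table[["row", "col"]].to_numpy(dtype=float).reshape(-1, 2),
        object_sizes=np.full(len(table), 5, dtype=int),
    )
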