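import numpy as np
import pytest

import fundusvasc as fv
from fundusvasc.synthetic import VesselTreeTruth


def straight_truth(width: float = 5.0, rows: int = 200, cols: int = 200,
                   length: int = 160) -> VesselTreeTruth:
    """One horizontal straight vessel of the given width.

    The optic disc sits in the top-left corner region, well away from the
    vessel, so the bright disc never interferes with extraction along it.
    """
    c0 = (cols - length) // 2
    c = np.stack([np.full(length, rows / 2.0), np.arange(c0, c0 + length, 1.0)],
                 axis=1)
    return VesselTreeTruth([c], [np.full(length, width)], [0.0], [-1],
                           (15.0, 15.0), 6.0, (rows, cols))


def straight_disc(truth, scale: float = 1.0):
    """The OpticDisc matching a straight_truth fixture (optionally rescaled)."""
    import fundusvasc as fv

    return fv.OpticDisc((truth.disc_center[0] * scale,
                         truth.disc_center[1] * scale),
                        truth.disc_radius * scale)


@pytest.fixture(scope="session")
def tree_render():
    """A rendered synthetic tree with everything downstream stages need."""
    truth = fv.grow_vessel_tree(1, n_roots=6, bend_amplitude=20.0,
                                width_root=5.0, image_size=(256, 256))
    img, vmask = fv.render_fundus(truth, 5.0, rng=np.random.default_rng(2))
    roi = fv.make_general_cover(256, 256)
    disc = fv.detect_optic_disc(img)
    return truth, img, vmask, roi, disc


@pytest.fixture(scope="session")
def segment_graph(tree_render):
    _, img, _, roi, disc = tree_render
    vmap = fv.extract_vessels(img, roi, disc=disc)
    graph = fv.partition_segments(vmap, 30, disc=disc)
    fv.qualify_segments(graph)
    return graph
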