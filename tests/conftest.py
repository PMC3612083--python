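"""Shared fixtures: small synthetic scenes and the five-object filter field."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk, ellipse as draw_ellipse

from ibrp import GrayImage, LabelMap, SceneSpec, render_scene


@pytest.fixture
def flat_image():
    return GrayImage(np.full((64, 64), 100.0), bit_depth=16, exposure_ms=50.0)


@pytest.fixture
def small_scene():
    """A quick noiseless field of 12 beads on a 400x400 canvas."""
    spec = SceneSpec(
        shape=(400, 400),
        n_beads=12,
        noise_sd=0.0,
        background_level=100.0,
        base_intensity=200.0,
        seed=11,
    )
    return render_scene(spec)


def make_five_object_field(value: float = 1000.0):
    """The canonical filter fixture: five objects, two of which are
    clean beads; the others fail exactly one rule each.

    Returns (image, expected_keep_centroids).
    """
    img = np.zeros((300, 400), float)
    shape = img.shape
    rr, cc = draw_disk((80, 80), 30, shape=shape)          # clean disk
    img[rr, cc] = value
    rr, cc = draw_disk((80, 200), 5, shape=shape)          # area 69-79 < 200
    img[rr, cc] = value
    b = np.sqrt(2000 / (np.pi * 3))                        # 3:1 ellipse, area ~2000
    rr, cc = draw_ellipse(200, 120, b, 3 * b, shape=shape)
    img[rr, cc] = value
    rr, cc = draw_disk((0, 330), 30, shape=shape)          # cut by the border
    img[rr, cc] = value
    rr, cc = draw_disk((220, 300), 30, shape=shape)        # second clean disk
    img[rr, cc] = value
    return img, [(80.0, 80.0), (220.0, 300.0)]


@pytest.fixture
def five_object_field():
    return make_five_object_field()


def label_binary(binary: np.ndarray) -> LabelMap:
    from scipy import ndimage as ndi

    lab, _ = ndi.label(binary, structure=np.ones((3, 3), bool))
    return LabelMap(lab.astype(np.int32))


def match_centroids(true_xy, found_xy, tol=2.0):
    """Greedy nearest matching; returns (n_recovered, max_matched_err, n_false)."""
    from scipy.spatial import cKDTree

    true_xy = np.asarray(true_xy, float)
    found_xy = np.asarray(found_xy, float)
    if len(found_xy) == 0:
        return 0, np.inf, 0
    d, _ = cKDTree(found_xy).query(true_xy)
    matched = d <= tol
    d2, _ = cKDTree(true_xy).query(found_xy)
    n_false = int((d2 > 5.0).sum())
    max_err = float(d[matched].max()) if matched.any() else float("nan")
    return int(matched.sum()), max_err, n_false
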