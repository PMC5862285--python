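"""Watershed series, label-map composition and scripted curation."""

import numpy as np
import pytest

from embryotk import phantom_gen
from embryotk.errors import LabelNotFoundError, UnresolvedAnnotationError
from embryotk.types import Volume3D
from embryotk.watershed_seg import (
    Annotation,
    LabelMap,
    compose_label_map,
    edit_labels,
    gradient_magnitude,
    watershed_series,
)

from helpers import dice


# ---------------------------------------------------------------------------
# gradient magnitude
# ---------------------------------------------------------------------------

def test_gradient_of_constant_is_zero():
    vol = Volume3D(np.full((5, 5, 5), 40, np.uint8), (2.0, 2.0, 2.0))
    assert (gradient_magnitude(vol).data == 0).all()


def test_gradient_of_ramp_closed_form():
    """Ramp of g grey per voxel along x at spacing s -> |grad| = g / s."""
    g, s = 6.0, 3.0
    ramp = np.broadcast_to(np.arange(20) * g, (5, 5, 20)).astype(np.float32)
    mag = gradient_magnitude(Volume3D(ramp, (s, s, s)), 0.0).data
    np.testing.assert_allclose(mag[:, :, 1:-1], g / s, rtol=1e-6)


def test_gradient_maxima_on_sphere_shell():
    dims, radius = (40, 40, 40), 12.0
    mask = phantom_gen.ellipsoid_mask(dims, (19.5, 19.5, 19.5), (radius,) * 3)
    vol = Volume3D((mask * 200).astype(np.uint8))
    mag = gradient_magnitude(vol, smoothing_sigma=1.0).data
    k, j, i = np.unravel_index(np.argmax(mag), mag.shape)
    dist = np.sqrt((k - 19.5) ** 2 + (j - 19.5) ** 2 + (i - 19.5) ** 2)
    assert abs(dist - radius) <= 2.0


# ---------------------------------------------------------------------------
# candidate series
# ---------------------------------------------------------------------------

def _two_blob_volume():
    data = np.full((24, 24, 24), 5, dtype=np.uint8)
    data[phantom_gen.ellipsoid_mask((24,) * 3, (7, 12, 7), (4, 4, 4))] = 180
    data[phantom_gen.ellipsoid_mask((24,) * 3, (17, 12, 17), (4, 4, 4))] = 220
    return Volume3D(data)


def test_two_separated_blobs_give_two_regions():
    series = watershed_series(_two_blob_volume(), [0.1])
    cand = series[0]
    assert cand.region_count >= 2
    # each blob core sits in exactly one region, and different ones
    a = cand.regions.data[7, 12, 7]
    b = cand.regions.data[17, 12, 17]
    assert a > 0 and b > 0 and a != b


def test_region_count_non_increasing(noisy_five_organ_phantom):
    series = watershed_series(noisy_five_organ_phantom.volume,
                              [0.02, 0.1, 0.3, 0.6, 1.0], sigma=14.0)
    counts = [c.region_count for c in series]
    assert counts == sorted(counts, reverse=True)


def test_level_one_merges_connected_foreground(five_organ_phantom):
    series = watershed_series(five_organ_phantom.volume, [1.0], sigma=14.0)
    assert series[0].region_count == 1


def test_partition_property(noisy_five_organ_phantom):
    """Foreground regions are disjoint and collectively cover the mask."""
    from embryotk.watershed_seg import foreground_mask
    vol = noisy_five_organ_phantom.volume
    series = watershed_series(vol, [0.05, 0.4], sigma=14.0)
    mask = foreground_mask(vol)
    for cand in series:
        labels = cand.regions.data
        assert ((labels > 0) == mask).all()  # exact cover, 0 elsewhere
        assert set(np.unique(labels)) == set(range(cand.region_count + 1))


def test_hierarchy_nesting(noisy_five_organ_phantom):
    """Each fine region maps into exactly one coarse region."""
    series = watershed_series(noisy_five_organ_phantom.volume,
                              [0.05, 0.2, 0.6], sigma=14.0)
    for fine, coarse in zip(series, series[1:]):
        f, c = fine.regions.data, coarse.regions.data
        for rid in range(1, fine.region_count + 1):
            owners = np.unique(c[f == rid])
            assert len(owners) == 1


def test_five_organ_dice(noisy_five_organ_phantom):
    """Best single-annotation-per-organ composition reaches Dice >= 0.90."""
    ph = noisy_five_organ_phantom
    series = watershed_series(ph.volume, [0.02, 0.05, 0.1, 0.2, 0.4], sigma=14.0)
    annotations = []
    for organ in ph.spec.organs:
        gt = ph.truth.data == organ.label_id
        best, best_ann = 0.0, None
        for cand in series:
            for rid in np.unique(cand.regions.data[gt]):
                if rid == 0:
                    continue
                d = dice(cand.regions.data == rid, gt)
                if d > best:
                    best = d
                    best_ann = Annotation(cand.level, int(rid),
                                          organ.label_id, organ.name)
        assert best >= 0.90, f"{organ.name}: best Dice {best:.3f}"
        annotations.append(best_ann)
    lm = compose_label_map(series, annotations)
    assert set(lm.names.values()) == {o.name for o in ph.spec.organs}


def test_invalid_levels_rejected(five_organ_phantom):
    with pytest.raises(ValueError):
        watershed_series(five_organ_phantom.volume, [])
    with pytest.raises(ValueError):
        watershed_series(five_organ_phantom.volume, [0.5, 0.2])
    with pytest.raises(ValueError):
        watershed_series(five_organ_phantom.volume, [0.0, 0.5])


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def _toy_series():
    # coarse candidate: one region covering columns 0..5; fine: splits it
    coarse = np.zeros((2, 3, 6), dtype=np.uint16)
    coarse[:, :, :] = 1
    fine = np.ones((2, 3, 6), dtype=np.uint16)
    fine[:, :, 3:] = 2
    from embryotk.watershed_seg import CandidateSegmentation
    mk = lambda lv, arr, n: CandidateSegmentation(  # noqa: E731
        lv, LabelMap(Volume3D(arr), {i: f"region_{i}" for i in range(1, n + 1)}), n)
    return [mk(0.2, fine, 2), mk(0.8, coarse, 1)]


def test_single_annotation_support():
    series = _toy_series()
    lm = compose_label_map(series, [Annotation(0.2, 2, 5, "liver")])
    assert ((lm.data == 5) == (series[0].regions.data == 2)).all()
    assert lm.names == {5: "liver"}


def test_last_annotation_wins_in_overlap():
    series = _toy_series()
    lm = compose_label_map(series, [
        Annotation(0.8, 1, 1, "body"),       # coarse covers everything
        Annotation(0.2, 2, 2, "liver"),      # fine refines the right half
    ])
    assert (lm.data[:, :, :3] == 1).all()
    assert (lm.data[:, :, 3:] == 2).all()
    assert lm.names == {1: "body", 2: "liver"}


def test_dangling_annotation_named_in_error():
    series = _toy_series()
    with pytest.raises(UnresolvedAnnotationError):
        compose_label_map(series, [Annotation(0.5, 1, 1, "x")])
    with pytest.raises(UnresolvedAnnotationError):
        compose_label_map(series, [Annotation(0.2, 99, 1, "x")])


def test_atlas_composition_names_ten_structures():
    """A mid-gestation phantom atlas composes to the expected organ names."""
    ph = phantom_gen.make_embryo_phantom(
        phantom_gen.e14_5_spec(dims=(64, 64, 64), noise_sd=1.0, seed=2))
    series = watershed_series(ph.volume, [0.02, 0.05, 0.1, 0.2], sigma=7.0)
    annotations = []
    for organ in ph.spec.organs:
        gt = ph.truth.data == organ.label_id
        best, best_ann = 0.0, None
        for cand in series:
            ids, cnts = np.unique(cand.regions.data[gt], return_counts=True)
            for rid, cnt in zip(ids, cnts):
                if rid == 0:
                    continue
                d = dice(cand.regions.data == rid, gt)
                if d > best:
                    best, best_ann = d, Annotation(cand.level, int(rid),
                                                   organ.label_id, organ.name)
        assert best_ann is not None, organ.name
        annotations.append(best_ann)
    lm = compose_label_map(series, annotations)
    expected = {"liver", "lungs", "kidney", "adrenal gland", "stomach lumen",
                "lateral brain ventricle", "mesencephalic vesicle",
                "dorsal root ganglia", "trigeminal ganglion",
                "humerus primordium"}
    assert set(lm.names.values()) == expected


# ---------------------------------------------------------------------------
# scripted curation
# ---------------------------------------------------------------------------

def _small_map():
    data = np.zeros((3, 3, 3), dtype=np.uint16)
    data[0] = 3
    data[1] = 4
    return LabelMap(Volume3D(data), {3: "liver", 4: "lungs"})


def test_delete_only_label():
    lm = LabelMap(Volume3D(np.full((2, 2, 2), 7, np.uint16)), {7: "x"})
    out = edit_labels(lm, [("delete", 7)])
    assert (out.data == 0).all() and out.names == {}


def test_relabel_transfers_counts_exactly():
    lm = _small_map()
    before = int((lm.data == 3).sum())
    out = edit_labels(lm, [("relabel", 3, 5)])
    assert int((out.data == 5).sum()) == before
    assert (out.data == 3).sum() == 0
    assert out.names == {5: "liver", 4: "lungs"}


def test_rename_leaves_data_unchanged():
    lm = _small_map()
    out = edit_labels(lm, [("rename", 4, "left lung")])
    np.testing.assert_array_equal(out.data, lm.data)
    assert out.names[4] == "left lung"


def test_unknown_label_rejected():
    with pytest.raises(LabelNotFoundError):
        edit_labels(_small_map(), [("delete", 99)])
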