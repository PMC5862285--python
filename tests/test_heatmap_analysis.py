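"""Heatmap region extraction, tables, vector filtering and overlays."""

import numpy as np
import pytest
from scipy import ndimage

from embryotk import phantom_gen
from embryotk.atlas_tools import DisplacementField
from embryotk.errors import AlignmentError
from embryotk.heatmap_analysis import (
    connected_regions,
    filter_by_t,
    filter_vectors,
    overlay_montage,
    read_region_table,
    region_table,
    write_region_table,
)
from embryotk.phantom_gen import BlobSpec
from embryotk.types import Volume3D

from helpers import flood_fill_regions


# ---------------------------------------------------------------------------
# t filtering
# ---------------------------------------------------------------------------

def test_filter_identity_and_annihilation(rng):
    hm = Volume3D(rng.normal(0, 3, (6, 6, 6)).astype(np.float32))
    np.testing.assert_array_equal(filter_by_t(hm, 0.0).data, hm.data)
    top = float(np.abs(hm.data).max())
    assert (filter_by_t(hm, top + 1).data == 0).all()


def test_filter_mask_oracle(rng):
    hm = Volume3D(rng.normal(0, 3, (8, 8, 8)).astype(np.float32))
    out = filter_by_t(hm, 3.0)
    keep = np.abs(hm.data) >= 3.0  # explicit scan
    np.testing.assert_array_equal(out.data[keep], hm.data[keep])
    assert (out.data[~keep] == 0).all()


def test_filter_idempotent_and_monotone(rng):
    hm = Volume3D(rng.normal(0, 3, (10, 10, 10)).astype(np.float32))
    once = filter_by_t(hm, 2.0)
    np.testing.assert_array_equal(filter_by_t(once, 2.0).data, once.data)
    stricter = filter_by_t(hm, 3.0)
    assert (stricter.data != 0).sum() <= (once.data != 0).sum()


# ---------------------------------------------------------------------------
# connected regions
# ---------------------------------------------------------------------------

def test_two_constant_blobs():
    t = np.zeros((20, 20, 20), dtype=np.float32)
    t[2:4, 2:4, 2:4] = 5.0           # 8 voxels
    t[10:13, 10:13, 10:13] = 5.0     # 27 voxels
    recs = connected_regions(Volume3D(t), min_voxels=1)
    assert [r.voxel_volume for r in recs] == [27, 8]
    assert all(r.mean_t == pytest.approx(5.0) for r in recs)
    assert all(r.sign == "positive" for r in recs)
    assert recs[0].region_id == 1


def test_sign_split_where_naive_cc_merges():
    """Touching +/- blobs must remain two regions even though plain
    connected components over the non-zero mask sees one."""
    hm, _ = phantom_gen.make_heatmap_phantom(
        (16, 16, 16),
        [BlobSpec((8, 8, 5), 3.0, 6.0), BlobSpec((8, 8, 11), 3.0, -6.0)])
    naive, n_naive = ndimage.label(hm.data != 0, np.ones((3, 3, 3)))
    assert n_naive == 1  # the fixture really is face-touching
    recs = connected_regions(hm, min_voxels=1)
    assert len(recs) == 2
    assert {r.sign for r in recs} == {"positive", "negative"}


def test_matches_flood_fill_oracle():
    for seed in range(10):
        hm = phantom_gen.random_sparse_heatmap(seed)
        recs = connected_regions(hm, min_voxels=1)
        oracle = flood_fill_regions(hm.data)
        assert len(recs) == len(oracle)
        ours = sorted((r.voxel_volume, round(r.mean_t, 6)) for r in recs)
        theirs = sorted((o["voxel_count"], round(o["mean_t"], 6)) for o in oracle)
        for (va, ma), (vb, mb) in zip(ours, theirs):
            assert va == vb
            assert abs(ma - mb) < 1e-6


def test_region_conservation(rng):
    hm = phantom_gen.random_sparse_heatmap(99)
    recs = connected_regions(hm, min_voxels=1)
    assert sum(r.voxel_volume for r in recs) == int((hm.data != 0).sum())


def test_min_voxels_drops_small_components():
    t = np.zeros((10, 10, 10), dtype=np.float32)
    t[1, 1, 1] = 4.0                 # singleton
    t[5:7, 5:7, 5:7] = 4.0           # 8 voxels
    recs = connected_regions(Volume3D(t), min_voxels=5)
    assert len(recs) == 1 and recs[0].voxel_volume == 8


def test_midpoint_is_bbox_midpoint():
    t = np.zeros((10, 10, 10), dtype=np.float32)
    t[2:7, 3:6, 4:9] = 1.0
    [rec] = connected_regions(Volume3D(t), min_voxels=1)
    assert rec.midpoint == (4, 4, 6)  # (lo + hi - 1) // 2
    b = rec.bbox
    assert (b.z0, b.z1, b.y0, b.y1, b.x0, b.x1) == (2, 7, 3, 6, 4, 9)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def test_empty_table_header_only(tmp_path):
    table = region_table([], (1.0, 1.0, 1.0))
    path = write_region_table(table, tmp_path / "r.tsv")
    lines = path.read_text().splitlines()
    assert len(lines) == 1 and lines[0].startswith("region_id")


def test_volume_mm3_arithmetic():
    t = np.zeros((12, 12, 12), dtype=np.float32)
    t[1:11, 1:11, 1:11] = 2.0  # 1000 voxels
    recs = connected_regions(Volume3D(t), min_voxels=1)
    table = region_table(recs, (10.0, 10.0, 10.0))
    assert table.loc[0, "volume_mm3"] == pytest.approx(0.001)


def test_table_round_trip(tmp_path):
    hm = phantom_gen.random_sparse_heatmap(5)
    recs = connected_regions(hm, min_voxels=1)
    table = region_table(recs, hm.spacing)
    path = write_region_table(table, tmp_path / "regions.tsv")
    back = read_region_table(path)
    assert list(back["region_id"]) == list(table["region_id"])
    np.testing.assert_allclose(back["mean_t"], table["mean_t"], rtol=1e-12)
    assert list(back["bbox"]) == list(table["bbox"])


# ---------------------------------------------------------------------------
# vector filtering
# ---------------------------------------------------------------------------

def test_filter_vectors_identity(rng):
    fld = DisplacementField(rng.normal(0, 2, (5, 5, 5, 3)).astype(np.float32))
    out = filter_vectors(fld, 0.0, 1)
    np.testing.assert_array_equal(out.vectors, fld.vectors)


def test_uniform_field_below_threshold_zeroed():
    vec = np.full((4, 4, 4, 3), 5 / np.sqrt(3), dtype=np.float32)  # |v| = 5
    out = filter_vectors(DisplacementField(vec), mag_min=6.0)
    assert (out.vectors == 0).all()


def test_filter_vectors_matches_loop_oracle(rng):
    vec = rng.normal(0, 2, (7, 8, 9, 3)).astype(np.float32)
    fld = DisplacementField(vec, (2.0, 2.0, 2.0))
    out = filter_vectors(fld, mag_min=2.0, stride=3)
    for k in range(0, 7, 3):
        for j in range(0, 8, 3):
            for i in range(0, 9, 3):
                v = vec[k, j, i]
                expected = v if float(np.sqrt((v ** 2).sum())) >= 2.0 else 0 * v
                np.testing.assert_array_equal(out.vectors[k // 3, j // 3, i // 3],
                                              expected)
    assert out.spacing == (6.0, 6.0, 6.0)


# ---------------------------------------------------------------------------
# overlays
# ---------------------------------------------------------------------------

def _avg_and_blob(sign=1.0):
    avg = Volume3D(np.full((12, 12, 12), 100, dtype=np.uint8))
    t = np.zeros((12, 12, 12), dtype=np.float32)
    t[5:8, 5:8, 5:8] = 6.0 * sign
    return avg, Volume3D(t)


def test_zero_heatmap_pure_greyscale(tmp_path):
    import imageio.v3 as iio
    avg, _ = _avg_and_blob()
    hm = Volume3D(np.zeros((12, 12, 12), dtype=np.float32))
    path = overlay_montage(avg, hm, tmp_path / "grey.png", indices=[6])
    img = iio.imread(path)
    assert (img[..., 0] == img[..., 1]).all() and (img[..., 1] == img[..., 2]).all()


def test_positive_blob_renders_red_only_at_blob(tmp_path):
    import imageio.v3 as iio
    avg, hm = _avg_and_blob(+1.0)
    path = overlay_montage(avg, hm, tmp_path / "pos.png", indices=[6])
    img = iio.imread(path).astype(int)
    reddish = (img[..., 0] > img[..., 2] + 10)
    expected = np.zeros((12, 12), dtype=bool)
    expected[5:8, 5:8] = True
    np.testing.assert_array_equal(reddish, expected)


def test_sign_flip_swaps_red_and_blue(tmp_path):
    import imageio.v3 as iio
    avg, hm_pos = _avg_and_blob(+1.0)
    _, hm_neg = _avg_and_blob(-1.0)
    img_p = iio.imread(overlay_montage(avg, hm_pos, tmp_path / "p.png",
                                       indices=[6])).astype(int)
    img_n = iio.imread(overlay_montage(avg, hm_neg, tmp_path / "n.png",
                                       indices=[6])).astype(int)
    red_p = img_p[..., 0] > img_p[..., 2] + 10
    blue_n = img_n[..., 2] > img_n[..., 0] + 10
    np.testing.assert_array_equal(red_p, blue_n)


def test_misaligned_overlay_rejected(tmp_path):
    avg, _ = _avg_and_blob()
    hm = Volume3D(np.zeros((5, 5, 5), dtype=np.float32))
    with pytest.raises(AlignmentError):
        overlay_montage(avg, hm, tmp_path / "x.png")
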