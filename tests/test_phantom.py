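"""Phantom generator: determinism, label contracts, IO, preprocessing, folds."""

import numpy as np
import pytest

from laamseg.metrics import mask_iou
from laamseg.phantom import (PhantomParams, external_shift, generate_phantom,
                             preprocess, read_label_file,
                             recover_mask_by_threshold, split_kfold,
                             transform_label, write_dataset)


@pytest.fixture(scope="module")
def small_params():
    return PhantomParams(image_size=160, n_images=8, seed=11)


def test_same_seed_and_index_render_identical_phantoms(small_params):
    a_img, a_lab = generate_phantom(small_params, 3)
    b_img, b_lab = generate_phantom(small_params, 3)
    assert np.array_equal(a_img, b_img)
    assert np.array_equal(a_lab[0].polygon, b_lab[0].polygon)
    assert a_lab[0].class_id == b_lab[0].class_id


def test_index_out_of_range_is_an_error(small_params):
    with pytest.raises(IndexError):
        generate_phantom(small_params, 8)


def test_param_validation():
    with pytest.raises(ValueError):
        PhantomParams(noise_sigma=-1)
    with pytest.raises(ValueError):
        PhantomParams(size_range=(0.5, 1.2))


def test_centers_and_sizes_stay_in_configured_ranges():
    p = PhantomParams(image_size=64, n_images=150, seed=5)
    for i in range(p.n_images):
        _, labs = generate_phantom(p, i)
        cx, cy, w, h = labs[0].bbox
        assert 0.2 <= cx <= 0.8 and 0.2 <= cy <= 0.6
        assert 0.2 <= w <= 0.6 and 0.2 <= h <= 0.6


def test_mask_is_exact_polygon_rasterization(small_params):
    _, labs = generate_phantom(small_params, 0)
    l = labs[0]
    assert mask_iou(l.rasterize((160, 160)), l.mask) == 1.0
    assert l.mask.any()


def test_noise_free_tumor_recoverable_by_thresholding():
    p = PhantomParams(image_size=320, n_images=10, noise_sigma=0, contrast=1.0, seed=3)
    for i in range(p.n_images):
        img, labs = generate_phantom(p, i)
        rec = recover_mask_by_threshold(img, labs[0])
        assert mask_iou(rec, labs[0].mask) > 0.99


def test_glioma_surrogate_has_lower_rim_contrast_than_meningioma():
    p = PhantomParams(image_size=160, n_images=40, noise_sigma=0, seed=2)
    peak = {0: [], 1: []}
    for i in range(p.n_images):
        img, labs = generate_phantom(p, i)
        peak[labs[0].class_id].append(img[labs[0].mask].max())
    assert np.mean(peak[0]) < np.mean(peak[1])


def test_external_shift_changes_noise_and_contrast(small_params):
    shifted = external_shift(small_params)
    assert shifted.noise_sigma > small_params.noise_sigma
    assert shifted.contrast < small_params.contrast
    assert shifted.seed != small_params.seed


# ---------------------------------------------------------------- preprocessing
def test_preprocess_square_input_is_pure_rescale(small_params):
    img, _ = generate_phantom(small_params, 1)
    chw, meta = preprocess(img, size=160)
    assert chw.shape == (3, 160, 160)
    assert chw.min() >= 0.0 and chw.max() <= 1.0
    assert np.allclose(chw[0], img.astype(np.float32) / 255.0, atol=1e-6)


def test_preprocess_letterboxes_and_maps_center():
    img = np.full((160, 320), 200, dtype=np.uint8)
    chw, meta = preprocess(img, size=320)
    assert meta["pad"] == (0, 80)
    from laamseg.metrics import InstanceLabel
    centered = InstanceLabel(0, np.array([[0.4, 0.4], [0.6, 0.4], [0.6, 0.6], [0.4, 0.6]]))
    mapped = transform_label(centered, meta)
    assert np.allclose(mapped.bbox[:2], [0.5, 0.5], atol=1e-3)
    # gray padding occupies the top/bottom bands equally
    assert np.allclose(chw[:, :80], 114 / 255, atol=1e-6)
    assert np.allclose(chw[:, -80:], 114 / 255, atol=1e-6)


def test_preprocess_rejects_zero_area_image():
    with pytest.raises(ValueError):
        preprocess(np.zeros((0, 10)))


# ------------------------------------------------------------------ dataset IO
def test_write_read_round_trip_to_six_decimals(tmp_path, small_params):
    imgs, labs = [], []
    for i in range(2):
        im, la = generate_phantom(small_params, i)
        imgs.append(im)
        labs.append(la)
    manifest = write_dataset(imgs, labs, tmp_path)
    assert manifest.exists()
    back = read_label_file(tmp_path / "labels" / "train" / "000000.txt")
    assert back[0].class_id == labs[0][0].class_id
    assert np.allclose(back[0].polygon, labs[0][0].polygon, atol=5e-7)
    line = (tmp_path / "labels" / "train" / "000000.txt").read_text().splitlines()[0]
    assert line.split()[0] == str(labs[0][0].class_id)


def test_instance_free_image_gets_empty_label_file(tmp_path, small_params):
    img, _ = generate_phantom(small_params, 0)
    write_dataset([img], [[]], tmp_path)
    assert (tmp_path / "labels" / "train" / "000000.txt").read_text() == ""
    assert read_label_file(tmp_path / "labels" / "train" / "000000.txt") == []


# ----------------------------------------------------------------------- folds
def test_kfold_partitions_are_disjoint_and_exhaustive():
    folds = split_kfold(50, 5, seed=1)
    all_val = sorted(i for _, val in folds for i in val)
    assert all_val == list(range(50))
    for train, val in folds:
        assert set(train).isdisjoint(val)
        assert sorted(train + val) == list(range(50))


def test_kfold_3000_by_5_gives_600_item_validation_folds():
    folds = split_kfold(3000, 5, seed=0)
    assert all(len(val) == 600 and len(train) == 2400 for train, val in folds)


def test_kfold_is_seeded_and_validates_k():
    assert split_kfold(10, 5, seed=3) == split_kfold(10, 5, seed=3)
    with pytest.raises(ValueError):
        split_kfold(4, 5)
    with pytest.raises(ValueError):
        split_kfold(10, 1)
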