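"""Segmentation, puncta detection, distance maps and region partitions."""

import dataclasses

import numpy as np
import pytest
import scipy.stats
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from myomol import (
    DetectionParams,
    PhantomSpec,
    PlacementModel,
    RenderSpec,
    SegmentationLabels,
    VoxelGrid,
    assign_regions,
    combine_segmentation,
    compute_distance_map,
    detect_puncta,
    generate_cell_phantom,
    partition_regions,
    place_puncta,
    render_volume,
    segment_cell,
    segment_nuclei,
    signal_density,
)
from myomol.localization import nuclear_perimeter, positions_to_indices

from conftest import SMALL_SPEC


def _quiet_render(labels, table, seed=0):
    return render_volume(labels, table, RenderSpec(seed=seed))


class TestSegmentNuclei:
    def test_recovers_phantom_nuclei(self, small_labels, small_dmap):
        t = place_puncta(small_labels,
                         PlacementModel(kind="uniform", n_puncta=0, seed=0),
                         small_dmap)
        vol = _quiet_render(small_labels, t, seed=3)
        nuclei = segment_nuclei(vol, "nuclei")
        assert nuclei.n_nuclei == SMALL_SPEC.n_nuclei
        az, ay, ax = SMALL_SPEC.nucleus_semiaxes
        expected = 4.0 / 3.0 * np.pi * az * ay * ax
        true_centroids = []
        for lb in small_labels.nucleus_labels:
            c = np.argwhere(small_labels.labels == lb).mean(axis=0)
            true_centroids.append((c + 0.5) * np.asarray(SMALL_SPEC.voxel_size))
        for lb in nuclei.nucleus_labels:
            vol_um3 = (nuclei.labels == lb).sum() * nuclei.voxel_volume
            assert vol_um3 == pytest.approx(expected, rel=0.10)
            c = (np.argwhere(nuclei.labels == lb).mean(axis=0) + 0.5) \
                * np.asarray(SMALL_SPEC.voxel_size)
            best = min(np.linalg.norm(c - tc) for tc in true_centroids)
            assert best < 0.5

    def test_flat_image_yields_zero_nuclei(self):
        grid = VoxelGrid({"nuclei": np.zeros((8, 8, 20))}, (0.5, 0.5, 0.5))
        with pytest.warns(UserWarning, match="flat"):
            nuclei = segment_nuclei(grid)
        assert nuclei.n_nuclei == 0


class TestSegmentCell:
    def test_jaccard_against_phantom(self, small_labels, rng):
        img = rng.poisson(small_labels.cell_mask * 20.0 + 2).astype(float)
        grid = VoxelGrid({"c": img}, small_labels.voxel_size)
        cell = segment_cell(grid, "c")
        inter = (cell.cell_mask & small_labels.cell_mask).sum()
        union = (cell.cell_mask | small_labels.cell_mask).sum()
        assert inter / union >= 0.95

    def test_explicit_mask_passthrough(self, small_labels):
        cell = segment_cell(mask=small_labels.cell_mask,
                            voxel_size=small_labels.voxel_size)
        assert np.array_equal(cell.cell_mask, small_labels.cell_mask)

    def test_two_blobs_keeps_larger_with_warning(self):
        img = np.zeros((10, 20, 20))
        img[2:8, 2:10, 2:16] = 50.0   # large blob
        img[2:4, 14:17, 17:19] = 50.0  # small distractor
        grid = VoxelGrid({"c": img}, (0.5, 0.5, 0.5))
        with pytest.warns(UserWarning, match="largest"):
            cell = segment_cell(grid, "c")
        assert cell.cell_mask[5, 5, 8]
        assert not cell.cell_mask[2, 15, 18]

    def test_no_foreground_raises(self):
        grid = VoxelGrid({"c": np.zeros((8, 8, 20))}, (0.5, 0.5, 0.5))
        with pytest.raises(ValueError, match="foreground"):
            segment_cell(grid, "c")


class TestDistanceMap:
    def test_single_voxel_nucleus_corner_distance(self):
        labels = np.ones((5, 5, 5), dtype=np.int32)
        labels[2, 2, 2] = 2
        seg = SegmentationLabels(labels, (1.0, 1.0, 1.0))
        dmap = compute_distance_map(seg)
        assert dmap.values[0, 0, 0] == pytest.approx(np.sqrt(12.0))
        assert dmap.values[2, 2, 2] == 0.0

    def test_zero_on_perimeter(self, small_labels, small_dmap):
        perim = nuclear_perimeter(small_labels)
        assert np.all(small_dmap.values[perim] == 0.0)

    def test_no_nuclei_raises(self):
        seg = SegmentationLabels(np.ones((5, 5, 5), dtype=np.int32), (1, 1, 1))
        with pytest.raises(ValueError, match="nuclei"):
            compute_distance_map(seg)

    @pytest.mark.parametrize("seed,shape,voxel", [
        (0, (12, 12, 12), (1.0, 1.0, 1.0)),
        (1, (20, 15, 25), (0.5, 0.3, 0.2)),
        (2, (25, 25, 25), (0.7, 0.25, 0.25)),
    ])
    def test_matches_bruteforce_nearest_perimeter(self, seed, shape, voxel):
        rng = np.random.default_rng(seed)
        labels = np.ones(shape, dtype=np.int32)
        # random blobby nucleus
        blob = rng.random(shape) > 0.9
        blob[tuple(s // 2 for s in shape)] = True
        labels[blob] = 2
        seg = SegmentationLabels(labels, voxel)
        dmap = compute_distance_map(seg)
        perim = nuclear_perimeter(seg)
        pcoords = (np.argwhere(perim) + 0.5) * np.asarray(voxel)
        all_coords = (np.argwhere(np.ones(shape, bool)) + 0.5) * np.asarray(voxel)
        brute = cdist(all_coords, pcoords).min(axis=1).reshape(shape)
        assert np.allclose(dmap.values, brute, atol=1e-9)

    def test_one_lipschitz_in_physical_distance(self, small_dmap):
        vals = small_dmap.values
        for axis, dv in enumerate(small_dmap.voxel_size):
            diff = np.abs(np.diff(vals, axis=axis))
            assert diff.max() <= dv + 1e-9


class TestDetectPuncta:
    def test_single_bright_punctum(self, small_labels, small_dmap):
        t = place_puncta(small_labels,
                         PlacementModel(kind="uniform", n_puncta=1, seed=17),
                         small_dmap)
        vol = render_volume(small_labels, t,
                            RenderSpec(background_rate=0.0, read_noise_sd=0.5,
                                       poisson_noise=False, seed=0))
        det = detect_puncta(vol, "puncta", small_labels)
        assert len(det.table) == 1
        err = np.abs(det.table[["z_um", "y_um", "x_um"]].to_numpy()[0]
                     - t[["z_um", "y_um", "x_um"]].to_numpy()[0])
        assert np.all(err / np.asarray(small_labels.voxel_size) < 0.5)

    def test_noise_only_false_positive_rate(self):
        labels = SegmentationLabels(np.ones((24, 24, 24), dtype=np.int32),
                                    (0.5, 0.25, 0.25))
        n_clean = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            img = rng.poisson(5.0, size=(24, 24, 24)).astype(float)
            img += rng.normal(0, 2.0, size=img.shape)
            grid = VoxelGrid({"puncta": img}, labels.voxel_size)
            det = detect_puncta(grid, "puncta", labels)
            n_clean += len(det.table) == 0
        assert n_clean >= 99

    def test_recall_precision_on_default_phantom(self, default_labels, default_dmap):
        # 200 well-separated puncta: greedy thinning to >= 2 um spacing
        cand = place_puncta(default_labels,
                            PlacementModel(kind="uniform", n_puncta=600, seed=5),
                            default_dmap)
        pos = cand[["z_um", "y_um", "x_um"]].to_numpy()
        keep: list[int] = []
        for i in range(len(pos)):
            if len(keep) == 200:
                break
            if not keep or cdist(pos[i:i + 1], pos[keep]).min() >= 2.0:
                keep.append(i)
        assert len(keep) == 200
        t = cand.iloc[keep].reset_index(drop=True)
        vol = _quiet_render(default_labels, t, seed=9)
        det = detect_puncta(vol, "puncta", default_labels)
        truth = t[["z_um", "y_um", "x_um"]].to_numpy()
        found = det.table[["z_um", "y_um", "x_um"]].to_numpy()
        # Hungarian matching with a 1 um gate
        dmat = cdist(truth, found)
        cost = np.where(dmat <= 1.0, dmat, 1e6)
        ri, ci = linear_sum_assignment(cost)
        matched = (dmat[ri, ci] <= 1.0).sum()
        assert matched / len(truth) >= 0.95      # recall
        assert matched / len(found) >= 0.95      # precision

    def test_translation_equivariance(self, small_labels, small_dmap):
        t = place_puncta(small_labels,
                         PlacementModel(kind="uniform", n_puncta=5, seed=31),
                         small_dmap)
        spec = RenderSpec(background_rate=0.0, read_noise_sd=0.0,
                          poisson_noise=False, seed=0)
        vol = render_volume(small_labels, t, spec)
        shift = (0, 2, 3)
        shifted = VoxelGrid(
            {"puncta": np.roll(vol.channel("puncta"), shift, axis=(0, 1, 2))},
            vol.voxel_size)
        full = SegmentationLabels(np.ones_like(small_labels.labels),
                                  small_labels.voxel_size)
        a = detect_puncta(VoxelGrid({"puncta": vol.channel("puncta")},
                                    vol.voxel_size), "puncta", full)
        b = detect_puncta(shifted, "puncta", full)
        assert len(a.table) == len(b.table)
        offset = np.asarray(shift) * np.asarray(small_labels.voxel_size)
        pa = np.sort(a.table[["z_um", "y_um", "x_um"]].to_numpy() + offset, axis=0)
        pb = np.sort(b.table[["z_um", "y_um", "x_um"]].to_numpy(), axis=0)
        # equivariant up to filter boundary handling (reflect padding),
        # which perturbs centroids far below the detector's 0.5 voxel spec
        assert np.allclose(pa, pb, atol=0.05)

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError, match="k"):
            DetectionParams(k=0.0)


class TestRegions:
    def test_partition_covers_cell(self, small_labels, small_partition):
        assert np.array_equal(small_partition.cell, small_labels.cell_mask)
        assert not np.any(small_partition.nucleus & small_partition.cytosol)
        assert np.all(small_partition.internuclear <= small_partition.cytosol)

    def test_single_nucleus_has_empty_internuclear(self):
        spec = dataclasses.replace(SMALL_SPEC, n_nuclei=1, nucleus_positions=None)
        labels = generate_cell_phantom(spec)
        part = partition_regions(labels)
        assert not np.any(part.internuclear)

    def test_cap_extent_matches_fraction(self, default_labels):
        part = partition_regions(default_labels, cap_fraction=0.05)
        xs = np.argwhere(part.id_caps)[:, 2] * default_labels.voxel_size[2]
        left = xs[xs < 50.0]
        # each intercalated-disk cap spans 5% of the 100 um long axis
        assert left.max() - left.min() == pytest.approx(5.0, abs=0.5)

    def test_invalid_cap_fraction(self, small_labels):
        with pytest.raises(ValueError, match="cap_fraction"):
            partition_regions(small_labels, cap_fraction=0.7)

    def test_nuclear_punctum_distance_zero(self, small_labels, small_dmap, small_partition):
        import pandas as pd
        nz = np.argwhere(small_labels.nucleus_mask)[0]
        pos = (nz + 0.5) * np.asarray(small_labels.voxel_size)
        capz = np.argwhere(small_partition.id_caps & small_labels.cytosol_mask)[0]
        cap_pos = (capz + 0.5) * np.asarray(small_labels.voxel_size)
        table = pd.DataFrame({
            "punctum_id": [0, 1],
            "z_um": [pos[0], cap_pos[0]],
            "y_um": [pos[1], cap_pos[1]],
            "x_um": [pos[2], cap_pos[2]],
        })
        out = assign_regions(table, small_partition, small_dmap)
        assert out.loc[0, "region"] == "nucleus"
        assert out.loc[0, "distance_um"] == 0.0
        assert out.loc[1, "region"] == "ID"

    def test_uniform_puncta_region_counts_multinomial(
            self, small_labels, small_dmap, small_partition, uniform_puncta):
        out = assign_regions(uniform_puncta, small_partition, small_dmap)
        # expected proportions: apply the same precedence to cytosol voxels
        p = small_partition
        prec = np.full(small_labels.labels.shape, "cytosol", dtype=object)
        prec[p.periphery] = "periphery"
        prec[p.internuclear] = "internuclear"
        prec[p.id_caps] = "ID"
        prec[p.nucleus] = "nucleus"
        cyto = small_labels.cytosol_mask
        regions = ["cytosol", "periphery", "internuclear", "ID"]
        expected = np.array([(prec[cyto] == r).sum() for r in regions], float)
        observed = np.array([(out["region"] == r).sum() for r in regions], float)
        expected *= observed.sum() / expected.sum()
        res = scipy.stats.chisquare(observed, expected)
        assert res.pvalue > 0.01


class TestSignalDensity:
    def test_arithmetic(self):
        region = np.ones((10, 10, 10), bool)  # 1000 voxels
        signal = np.zeros_like(region)
        signal[0, :5, :10] = True  # 50 voxels
        assert signal_density(signal, region) == pytest.approx(5.0)
        assert signal_density(np.zeros_like(region), region) == 0.0
        assert signal_density(region, region) == 100.0

    def test_empty_region_raises(self):
        with pytest.raises(ValueError, match="region"):
            signal_density(np.ones((2, 2, 2), bool), np.zeros((2, 2, 2), bool))
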