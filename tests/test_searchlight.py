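"""Searchlight mapping, smoothing, TFCE and permutation FWE correction."""

import numpy as np
import pytest

import crossdecode as cd
from crossdecode import searchlight as sl
from crossdecode import synth


class TestSmoothing:
    def test_fwhm_zero_identity(self, geom3mm):
        rng = np.random.default_rng(0)
        m = rng.normal(size=geom3mm.shape)
        assert np.array_equal(cd.smooth_map(m, 0.0, geom3mm), m)

    def test_constant_map_preserved(self, geom3mm):
        m = np.full(geom3mm.shape, 3.7)
        out = cd.smooth_map(m, 6.0, geom3mm)
        assert np.allclose(out, 3.7, atol=1e-6)

    def test_delta_response_width(self):
        """Measured FWHM of the impulse response matches the request
        within one voxel (linear interpolation across the half-maximum)."""
        geom = cd.VolumeGeometry((41, 41, 41), (3.0, 3.0, 3.0))
        delta = np.zeros(geom.shape)
        delta[20, 20, 20] = 1.0
        out = cd.smooth_map(delta, 9.0, geom)
        prof = out[:, 20, 20]
        half = prof.max() / 2
        above = np.flatnonzero(prof >= half)
        lo, hi = above[0], above[-1]
        # interpolate the crossings on both sides
        fl = lo - (prof[lo] - half) / (prof[lo] - prof[lo - 1])
        fr = hi + (prof[hi] - half) / (prof[hi] - prof[hi + 1])
        measured_mm = (fr - fl) * 3.0
        assert abs(measured_mm - 9.0) <= 3.0


def brute_force_tfce_1d(values, E, H, dh):
    """Independent 1-D TFCE: explicit component enumeration per step."""
    n = values.size
    out = np.zeros(n)
    h = dh
    vmax = values.max()
    while h <= vmax + 1e-12:
        supra = values >= h
        # enumerate maximal runs of consecutive suprathreshold voxels
        i = 0
        while i < n:
            if supra[i]:
                j = i
                while j + 1 < n and supra[j + 1]:
                    j += 1
                size = j - i + 1
                for v in range(i, j + 1):
                    out[v] += size ** E * h ** H * dh
                i = j + 1
            else:
                i += 1
        h += dh
    return out


class TestTfce:
    def test_zero_map(self):
        assert np.allclose(cd.tfce(np.zeros((4, 4, 4))), 0.0)

    def test_single_voxel_closed_form(self):
        """Isolated voxel of height h, E=0.5, H=2: TFCE -> h^3/3 as
        dh -> 0 (e = 1 at every threshold)."""
        h_max = 2.0
        m = np.zeros((5, 5, 5))
        m[2, 2, 2] = h_max
        out = cd.tfce(m, cd.TfceParams(E=0.5, H=2.0, dh=h_max / 1000))
        assert out[2, 2, 2] == pytest.approx(h_max ** 3 / 3, rel=0.01)

    def test_matches_brute_force_1d(self):
        rng = np.random.default_rng(4)
        vals = np.abs(rng.normal(size=30))
        dh = vals.max() / 50
        ref = brute_force_tfce_1d(vals, 0.5, 2.0, dh)
        out = cd.tfce(vals.reshape(30, 1, 1),
                      cd.TfceParams(E=0.5, H=2.0, dh=dh))
        assert np.allclose(out.ravel(), ref, rtol=1e-6, atol=1e-12)

    def test_monotonicity(self):
        rng = np.random.default_rng(5)
        a = np.abs(rng.normal(size=(6, 6, 6)))
        b = a + np.abs(rng.normal(size=(6, 6, 6))) * 0.5
        dh = b.max() / 100
        pa = cd.tfce(a, cd.TfceParams(dh=dh))
        pb = cd.tfce(b, cd.TfceParams(dh=dh))
        assert np.all(pb >= pa - 1e-12)

    def test_scaling_exponent(self):
        """Scaling the map by c scales TFCE by c^(H+1) in the fine-dh
        limit."""
        rng = np.random.default_rng(6)
        a = np.abs(rng.normal(size=(5, 5, 5)))
        c = 1.7
        H, E = 2.0, 0.5
        p1 = cd.tfce(a, cd.TfceParams(E=E, H=H, dh=a.max() / 2000))
        p2 = cd.tfce(c * a, cd.TfceParams(E=E, H=H, dh=c * a.max() / 2000))
        inside = p1 > 1e-3 * p1.max()
        ratio = p2[inside] / p1[inside]
        assert np.allclose(ratio, c ** (H + 1), rtol=0.01)

    def test_two_sided_antisymmetry(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(6, 6, 6))
        p = cd.tfce(a, two_sided=True)
        q = cd.tfce(-a, two_sided=True)
        assert np.allclose(p, -q)


class TestSearchlight:
    def _single_subject(self, amplitude, seed):
        sim = cd.SimConfig(n_subjects=1, search_runs=3, trials_per_run=8,
                           oneback_runs=2, grid_shape=(8, 8, 6),
                           rois=(cd.RoiSpec("blob", (2, 2, 1), (3, 3, 3)),),
                           information={"blob": ("cue_face",)},
                           amplitude=amplitude, oneback_iti=2.0, seed=seed)
        d = synth.simulate_subject(sim, subject_seed=seed)
        sbm = [cd.fit_glm(b, de) for b, de, _ in d["search"]]
        obm = [cd.fit_glm(b, de) for b, de, _ in d["oneback"]]
        brain = cd.RoiMask(np.ones(sim.grid_shape, bool), "brain",
                           sim.geometry)
        tr = cd.extract_patterns(sbm, brain, "cue", "face")
        te = cd.extract_patterns(obm, brain, "stim", "face")
        return sim, d["truth"], tr, te

    def test_center_equals_roi_pipeline(self):
        """A sphere covering exactly an ROI's voxels reproduces the ROI
        decode bit-for-bit."""
        sim, truth, tr, te = self._single_subject(2.0, seed=31)
        lm = cd.LabelMap(truth.association)
        blob = truth.masks["blob"]
        center = (3, 3, 2)      # blob spans 2:5 x 2:5 x 1:4
        flat = cd.sphere_indices(center, 4.4, sim.geometry, blob.data)
        assert set(flat) <= set(blob.flat_indices)
        cols = np.searchsorted(tr.voxel_indices, flat)
        acc_sl = cd.decode(tr.subset_voxels(cols), te.subset_voxels(cols),
                           "cue_face", label_map=lm).accuracy
        roi_tr = tr.subset_voxels(np.searchsorted(tr.voxel_indices, flat))
        roi_te = te.subset_voxels(np.searchsorted(te.voxel_indices, flat))
        acc_roi = cd.decode(roi_tr, roi_te, "cue_face", label_map=lm).accuracy
        assert acc_sl == acc_roi

    def test_null_map_near_chance(self):
        sim, truth, tr, te = self._single_subject(0.0, seed=37)
        lm = cd.LabelMap(truth.association)
        mask = np.zeros(sim.grid_shape, bool)
        mask[2:6, 2:6, 2:4] = True
        m = cd.run_searchlight(tr, te, "cue_face", sim.geometry, mask,
                               radius_mm=6.0, label_map=lm)
        vals = m.data[mask]
        assert np.isfinite(vals).all()
        assert abs(np.nanmean(vals) - 0.5) < 0.08
        assert np.isnan(m.data[~mask]).all()

    def test_informative_blob_is_local_peak(self):
        sim, truth, tr, te = self._single_subject(3.0, seed=41)
        lm = cd.LabelMap(truth.association)
        mask = np.ones(sim.grid_shape, bool)
        m = cd.run_searchlight(tr, te, "cue_face", sim.geometry, mask,
                               radius_mm=5.0, label_map=lm)
        peak = np.unravel_index(np.nanargmax(m.data), m.data.shape)
        assert np.linalg.norm(np.array(peak) - np.array([3, 3, 2])) <= 2.5


class TestCorrectedPmap:
    def _null_maps(self, n_subj, shape, seed):
        rng = np.random.default_rng(seed)
        return [rng.normal(size=shape) for _ in range(n_subj)]

    def test_sign_flip_symmetry(self):
        """Negating every subject map turns the negative clusters into the
        positive ones: the enhanced map of the flipped data equals the
        enhancement of the negated group t-map (at matched dh)."""
        maps = self._null_maps(6, (5, 5, 4), seed=3)
        params = cd.TfceParams(dh=0.05)
        tmap = sl._group_tmap(np.asarray(maps).reshape(6, -1)).reshape(5, 5, 4)
        _, t_pos, _ = cd.tfce_corrected_pmap(maps, params, n_perm=10, seed=9)
        _, t_neg, _ = cd.tfce_corrected_pmap([-m for m in maps], params,
                                             n_perm=10, seed=9)
        assert np.allclose(t_pos, cd.tfce(tmap, params))
        assert np.allclose(t_neg, cd.tfce(-tmap, params))

    def test_null_maps_rarely_significant(self):
        hits = 0
        for rep in range(20):
            maps = self._null_maps(8, (6, 6, 4), seed=100 + rep)
            p, _, _ = cd.tfce_corrected_pmap(maps, n_perm=100, seed=rep)
            hits += (np.nanmin(p) < 0.05)
        assert hits <= 4        # FWE-controlled

    def test_cluster_min_size_filter(self):
        p = np.ones((10, 10, 10))
        stat = np.zeros((10, 10, 10))
        p[1:3, 1:3, 1:3] = 0.001      # 8-voxel cluster
        stat[1:3, 1:3, 1:3] = 5.0
        tbl = cd.cluster_table(p, stat, p_threshold=0.005, min_size=50)
        assert len(tbl) == 0
        tbl2 = cd.cluster_table(p, stat, p_threshold=0.005, min_size=5)
        assert len(tbl2) == 1
        assert tbl2.loc[0, "n_voxels"] == 8
        assert tbl2.loc[0, "peak_stat"] == 5.0

    def test_signal_detected_in_group(self):
        rng = np.random.default_rng(55)
        shape = (6, 6, 4)
        signal = np.zeros(shape)
        signal[2:4, 2:4, 1:3] = 1.5
        maps = [signal + rng.normal(size=shape) * 0.5 for _ in range(10)]
        p, tfce_obs, _ = cd.tfce_corrected_pmap(maps, n_perm=200, seed=1)
        assert p[3, 3, 2] < 0.05
        assert p[0, 0, 0] > 0.2
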