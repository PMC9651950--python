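"""Assignment and contact colocalization rules and the four workflows."""

import dataclasses

import numpy as np
import pytest

import synconn as sc
from synconn.errors import ConfigError

from oracles import overlap_fraction_loop, pair_overlaps_loop


def _labels_from(site_voxels: dict[int, list[tuple[int, int, int]]], shape):
    data = np.zeros(shape, dtype=np.int32)
    for lab, voxels in site_voxels.items():
        for v in voxels:
            data[v] = lab
    return sc.LabelVolume(data=data)


class TestAssignment:
    def test_half_overlap_is_assigned_inclusive(self):
        shape = (4, 4, 12)
        sites = _labels_from({1: [(0, 0, x) for x in range(10)]}, shape)
        mask = np.zeros(shape, dtype=bool)
        mask[0, 0, :5] = True  # exactly 5 of 10 voxels
        assigned, fr = sc.assign_sites_to_mask(sites, sc.BinaryMask(data=mask), 0.5)
        assert assigned == [1] and fr[1] == 0.5

    def test_under_half_not_assigned(self):
        shape = (4, 4, 12)
        sites = _labels_from({1: [(0, 0, x) for x in range(10)]}, shape)
        mask = np.zeros(shape, dtype=bool)
        mask[0, 0, :4] = True
        assigned, fr = sc.assign_sites_to_mask(sites, sc.BinaryMask(data=mask), 0.5)
        assert assigned == [] and fr[1] == pytest.approx(0.4)

    def test_fractions_match_voxel_loop_oracle(self, rng):
        labels = sc.LabelVolume(data=rng.integers(0, 5, (16, 16, 16)).astype(np.int32))
        mask = sc.BinaryMask(data=rng.random((16, 16, 16)) < 0.5)
        _, fr = sc.assign_sites_to_mask(labels, mask, 0.5)
        assert fr == pytest.approx(overlap_fraction_loop(labels.data, mask.data))

    def test_assigned_set_shrinks_with_fraction(self, rng):
        labels = sc.LabelVolume(data=rng.integers(0, 8, (16, 16, 16)).astype(np.int32))
        mask = sc.BinaryMask(data=rng.random((16, 16, 16)) < 0.5)
        prev = None
        for f in (0.2, 0.5, 0.8):
            a, _ = sc.assign_sites_to_mask(labels, mask, f)
            if prev is not None:
                assert set(a) <= set(prev)
            prev = a

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            sc.assign_sites_to_mask(
                sc.LabelVolume(data=np.zeros((2, 2, 2), dtype=np.int32)),
                sc.BinaryMask(data=np.zeros((2, 2, 3), dtype=bool)), 0.5)


class TestSiteSiteContacts:
    def test_single_voxel_overlap_at_exact_threshold(self):
        shape = (10, 10, 30)
        post_vox = [(z, y, x) for z in range(10) for y in range(10) for x in range(10)]
        post = _labels_from({1: post_vox}, shape)  # exactly 1000 voxels
        pre = _labels_from({1: [(0, 0, 0), (0, 0, 29)]}, shape)  # one shared voxel
        conns = sc.find_site_site_contacts(pre, post)
        assert len(conns) == 1
        assert conns[0].overlap_fraction == pytest.approx(0.001)

    def test_zero_overlap_no_connection(self):
        shape = (6, 6, 6)
        pre = _labels_from({1: [(0, 0, 0)]}, shape)
        post = _labels_from({1: [(5, 5, 5)]}, shape)
        assert sc.find_site_site_contacts(pre, post) == []

    def test_polyadic_post_touching_two_pres(self):
        shape = (4, 8, 20)
        post = _labels_from({1: [(0, 0, x) for x in range(3, 17)]}, shape)
        pre = _labels_from({1: [(0, 0, 3)], 2: [(0, 0, 16)]}, shape)
        conns = sc.find_site_site_contacts(pre, post)
        assert len(conns) == 2
        assert {c.pre_site_id for c in conns} == {1, 2}
        assert {c.post_object_id for c in conns} == {1}

    def test_overlaps_match_exhaustive_oracle(self, rng):
        pre = sc.LabelVolume(data=rng.integers(0, 4, (12, 12, 12)).astype(np.int32))
        post = sc.LabelVolume(data=rng.integers(0, 4, (12, 12, 12)).astype(np.int32))
        conns = sc.find_site_site_contacts(pre, post)
        oracle = pair_overlaps_loop(pre.data, post.data)
        post_sizes = {q: int((post.data == q).sum()) for q in (1, 2, 3)}
        expected = {(p, q): ov for (p, q), ov in oracle.items()
                    if ov / post_sizes[q] >= 0.001}
        assert {(c.pre_site_id, c.post_object_id): c.overlap_voxels
                for c in conns} == expected

    def test_dilation_enables_apposed_contact(self):
        shape = (6, 6, 12)
        pre = _labels_from({1: [(2, 2, 2)]}, shape)
        post = _labels_from({1: [(2, 2, 4)]}, shape)  # 2 voxels away: no overlap
        cfg0 = sc.PipelineConfig()
        assert sc.find_site_site_contacts(pre, post, cfg0) == []
        cfg1 = dataclasses.replace(cfg0, contact_dilation_voxels=1)
        conns = sc.find_site_site_contacts(pre, post, cfg1)
        assert len(conns) == 0  # still 2 apart; radius-1 box reaches 1 voxel
        cfg2 = dataclasses.replace(cfg0, contact_dilation_voxels=2)
        assert len(sc.find_site_site_contacts(pre, post, cfg2)) == 1

    def test_emitted_fractions_bounded(self, rng):
        pre = sc.LabelVolume(data=rng.integers(0, 3, (10, 10, 10)).astype(np.int32))
        post = sc.LabelVolume(data=rng.integers(0, 3, (10, 10, 10)).astype(np.int32))
        for c in sc.find_site_site_contacts(pre, post):
            assert 0.001 <= c.overlap_fraction <= 1.0


class TestSiteMaskContacts:
    def test_fully_inside_mask(self):
        shape = (6, 6, 6)
        pre = _labels_from({1: [(2, 2, 2), (2, 2, 3)]}, shape)
        mask = sc.BinaryMask(data=np.ones(shape, dtype=bool))
        conns = sc.find_site_mask_contacts(pre, mask)
        assert len(conns) == 1
        assert conns[0].overlap_fraction == 1.0
        assert conns[0].post_object_type == "mask"

    def test_single_voxel_overlap_fraction(self):
        shape = (8, 10, 10)
        vox = [(z, y, x) for z in range(5) for y in range(10) for x in range(10)]
        pre = _labels_from({1: vox}, shape)  # 500 voxels
        mask = np.zeros(shape, dtype=bool)
        mask[0, 0, 0] = True
        conns = sc.find_site_mask_contacts(pre, sc.BinaryMask(data=mask))
        assert len(conns) == 1
        assert conns[0].overlap_fraction == pytest.approx(0.002)

    def test_disjoint_none(self):
        shape = (6, 6, 6)
        pre = _labels_from({1: [(0, 0, 0)]}, shape)
        mask = np.zeros(shape, dtype=bool)
        mask[5, 5, 5] = True
        assert sc.find_site_mask_contacts(pre, sc.BinaryMask(data=mask)) == []


class TestWorkflows:
    def test_w2_recovers_phantom_wiring(self, w2_report, default_phantom):
        spec = default_phantom.spec
        assert w2_report.summary == {
            "presyn_total": spec.n_presyn_per_neuron * spec.n_neurons,
            "presyn_on_neuron1": spec.n_presyn_per_neuron,
            "connections": spec.n_postsyn_apposed,
            "presyn_sites_connected": spec.n_postsyn_apposed,
        }

    def test_w2_polyadic_counts(self, small_phantom, default_cfg):
        spec = dataclasses.replace(small_phantom.spec, n_polyadic_extra=2)
        ds = sc.generate_phantom(spec)
        mask = sc.postprocess_neuron_mask(ds.neuron_channels[0], default_cfg)
        rep = sc.run_workflow(2, {"presyn": ds.presyn_channel,
                                  "postsyn": ds.postsyn_channel,
                                  "neuron1_mask": mask}, default_cfg)
        n = spec.n_postsyn_apposed
        assert rep.summary["connections"] == n + 2
        assert rep.summary["presyn_sites_connected"] == n  # polyadic pre counted once

    def test_w4_detect_only(self, small_phantom, default_cfg):
        rep = sc.run_workflow(4, {"marker": small_phantom.presyn_channel}, default_cfg)
        assert rep.summary == {"sites_total": len(small_phantom.assignment)}
        assert all(s.assigned_mask_id is None for s in rep.sites["sites"])

    def test_w1_assignment_counts(self, small_phantom, default_cfg):
        mask = sc.postprocess_neuron_mask(small_phantom.neuron_channels[0], default_cfg)
        rep = sc.run_workflow(1, {"marker": small_phantom.presyn_channel,
                                  "neuron1_mask": mask}, default_cfg)
        spec = small_phantom.spec
        assert rep.summary["sites_total"] == spec.n_presyn_per_neuron * spec.n_neurons
        assert rep.summary["sites_on_neuron1"] == spec.n_presyn_per_neuron

    def test_w3_sites_contacting_membrane(self, small_phantom, default_cfg):
        mask1 = sc.postprocess_neuron_mask(small_phantom.neuron_channels[0], default_cfg)
        mask2 = sc.postprocess_neuron_mask(small_phantom.neuron_channels[1], default_cfg)
        rep = sc.run_workflow(3, {"presyn": small_phantom.presyn_channel,
                                  "neuron1_mask": mask1,
                                  "neuron2_mask": mask2}, default_cfg)
        # phantom neurons live in disjoint slabs: no cross-neuron contacts
        assert rep.summary["connections"] == 0
        # whereas contacting neuron 1's own membrane finds every assigned site
        rep_self = sc.run_workflow(3, {"presyn": small_phantom.presyn_channel,
                                       "neuron1_mask": mask1,
                                       "neuron2_mask": mask1}, default_cfg)
        assert rep_self.summary["connections"] == rep_self.summary["presyn_on_neuron1"]

    def test_missing_channel_names_requirements(self, default_cfg):
        with pytest.raises(ConfigError, match="postsyn"):
            sc.run_workflow(2, {"presyn": sc.Volume(data=np.zeros((4, 4, 4), np.uint8)),
                                "neuron1_mask": sc.BinaryMask(data=np.zeros((4, 4, 4), bool))},
                            default_cfg)

    def test_label_permutation_invariance(self, small_phantom, default_cfg, rng):
        mask = sc.postprocess_neuron_mask(small_phantom.neuron_channels[0], default_cfg)
        pre = small_phantom.presyn_labels
        post = small_phantom.postsyn_labels
        conns = sc.find_site_site_contacts(pre, post, default_cfg)
        perm = rng.permutation(pre.max_label) + 1
        lut = np.concatenate([[0], perm]).astype(pre.data.dtype)
        pre_perm = sc.LabelVolume(data=lut[pre.data])
        conns_perm = sc.find_site_site_contacts(pre_perm, post, default_cfg)
        assert ({(int(lut[c.pre_site_id]), c.post_object_id, c.overlap_voxels) for c in conns}
                == {(c.pre_site_id, c.post_object_id, c.overlap_voxels) for c in conns_perm})

    def test_w2_whole_volume_mask_reduces_to_detect_everything(self, small_phantom,
                                                               default_cfg):
        whole = sc.BinaryMask(data=np.ones(small_phantom.presyn_channel.data.shape, bool))
        rep = sc.run_workflow(2, {"presyn": small_phantom.presyn_channel,
                                  "postsyn": small_phantom.postsyn_channel,
                                  "neuron1_mask": whole}, default_cfg)
        assert rep.summary["presyn_on_neuron1"] == rep.summary["presyn_total"]
        # every ground-truth apposition is then a connection
        assert rep.summary["connections"] == len(small_phantom.connections)
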