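import json

import numpy as np
import pytest

from plddtkit import (
    LDDTConfig, SyntheticSpec, compute_lddt, compute_rmsf, lddt_category,
    make_backbone, make_dataset, make_decoy, make_ensemble,
    make_feature_bundle, make_protein, training_pairs,
)


class TestBackbone:
    def test_consecutive_ca_distances(self):
        """Helix geometry: chord ~2*2.3*sin(50 deg) with 1.5 A rise -> ~3.83 A."""
        bb = make_backbone(10, seed=0)
        d = np.linalg.norm(np.diff(bb.ca_coords(), axis=0), axis=1)
        expected = np.sqrt((2 * 2.3 * np.sin(np.deg2rad(50))) ** 2 + 1.5 ** 2)
        assert (d >= 3.6).all() and (d <= 4.0).all()
        np.testing.assert_allclose(d, expected, atol=1e-6)

    def test_deterministic(self):
        a = make_backbone(50, seed=9)
        b = make_backbone(50, seed=9)
        np.testing.assert_array_equal(a.ca_coords(), b.ca_coords())
        assert a.sequence == b.sequence

    def test_minimal_and_invalid_length(self):
        assert len(make_backbone(2, seed=0)) == 2
        with pytest.raises(ValueError):
            make_backbone(1, seed=0)

    def test_has_side_chain_stubs(self):
        bb = make_backbone(30, seed=1)
        for r in bb.residues:
            names = {a.name for a in r.atoms}
            assert names == ({"CA"} if r.residue_name == "GLY" else {"CA", "CB"})


class TestDecoy:
    def test_zero_sigma_identity(self):
        ref = make_backbone(30, seed=2)
        decoy, prof = make_decoy(ref, SyntheticSpec(length=30, seed=3))
        np.testing.assert_array_equal(decoy.ca_coords(), ref.ca_coords())
        assert all(v == 100.0 for v in prof.per_residue.values())

    def test_tiny_sigma_keeps_high_lddt(self):
        ref = make_backbone(30, seed=2)
        for seed in range(5):
            spec = SyntheticSpec(length=30, seed=seed,
                                 error_segments=((1, 30, 0.01),))
            _, prof = make_decoy(ref, spec)
            assert min(prof.per_residue.values()) >= 99.0

    def test_noisy_segment_scores_lower(self):
        """Residues inside a sigma-10 segment average below clean residues."""
        ref = make_backbone(60, seed=4)
        seg_means, clean_means = [], []
        for seed in range(20):
            spec = SyntheticSpec(length=60, seed=seed,
                                 error_segments=((20, 30, 10.0),))
            _, prof = make_decoy(ref, spec)
            seg_means.append(np.mean([prof.per_residue[i] for i in range(20, 31)]))
            clean_means.append(np.mean([prof.per_residue[i] for i in range(1, 11)]))
        assert np.mean(seg_means) < np.mean(clean_means)

    def test_invalid_segments(self):
        with pytest.raises(ValueError):
            SyntheticSpec(length=10, error_segments=((5, 20, 1.0),))


class TestEnsemble:
    def test_zero_jitter_degenerate(self):
        ref = make_backbone(20, seed=5)
        prof = {i: 100.0 for i in ref.residue_indices}
        ens = make_ensemble(ref, prof, SyntheticSpec(length=20, ensemble_jitter_scale=0.0))
        rmsf = compute_rmsf(ens)
        assert max(rmsf.per_residue.values()) == pytest.approx(0.0, abs=1e-12)

    def test_member_count(self):
        ref = make_backbone(20, seed=5)
        prof = {i: 80.0 for i in ref.residue_indices}
        ens = make_ensemble(ref, prof, SyntheticSpec(length=20, ensemble_size=5))
        assert len(ens.members) == 5

    def test_low_lddt_residues_fluctuate_more(self):
        ref = make_backbone(20, seed=6)
        prof = {i: (40.0 if i == 10 else 100.0) for i in ref.residue_indices}
        lo, hi = [], []
        for seed in range(20):
            ens = make_ensemble(ref, prof, SyntheticSpec(length=20, seed=seed))
            rmsf = compute_rmsf(ens).per_residue
            lo.append(rmsf[10])
            hi.append(np.mean([v for i, v in rmsf.items() if i != 10]))
        assert np.mean(lo) > np.mean(hi)


class TestFeatureBundle:
    def test_high_snr_correlation(self):
        rng = np.random.default_rng(7)
        true = rng.uniform(20, 100, size=200)
        spec = SyntheticSpec(length=200, feature_snr=10.0, seed=1)
        b = make_feature_bundle(true, 200, spec)
        r = np.corrcoef(b.single[:, 0], true)[0, 1]
        assert r > 0.9

    def test_zero_snr_no_signal(self):
        rng = np.random.default_rng(8)
        true = rng.uniform(20, 100, size=200)
        spec = SyntheticSpec(length=200, feature_snr=0.0, seed=2)
        b = make_feature_bundle(true, 200, spec)
        assert abs(np.corrcoef(b.single[:, 0], true)[0, 1]) < 0.2
        assert abs(np.corrcoef(b.rmsf[:, 0], true)[0, 1]) < 0.2

    def test_deterministic_per_seed(self):
        true = np.linspace(30, 100, 50)
        spec = SyntheticSpec(length=50, seed=3)
        b1 = make_feature_bundle(true, 50, spec)
        b2 = make_feature_bundle(true, 50, spec)
        np.testing.assert_array_equal(b1.single, b2.single)
        np.testing.assert_array_equal(b1.pair, b2.pair)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            make_feature_bundle(np.zeros(5), 6, SyntheticSpec(length=6))


class TestDataset:
    def test_deterministic_manifest(self, tmp_path):
        make_dataset(3, (40, 50), seed=5, out_dir=tmp_path / "a")
        make_dataset(3, (40, 50), seed=5, out_dir=tmp_path / "b")
        ma = json.loads((tmp_path / "a" / "manifest.json").read_text())
        mb = json.loads((tmp_path / "b" / "manifest.json").read_text())
        assert ma == mb

    def test_lengths_in_range(self):
        recs = make_dataset(6, (40, 80), seed=6)
        assert all(40 <= rec.spec.length <= 80 for rec in recs)

    def test_all_four_categories_populated(self):
        recs = make_dataset(8, (40, 80), seed=7)
        cats = {lddt_category(v) for rec in recs
                for v in rec.true_lddt.per_residue.values()}
        assert len(cats) == 4

    def test_single_fixture_trains(self):
        from plddtkit.egnn import HeadConfig, train_head
        recs = make_dataset(1, (25, 30), seed=8)
        params, trace = train_head(training_pairs(recs), HeadConfig(epochs=1))
        assert len(trace) == 1 and np.isfinite(trace[0])

    def test_graph_uses_reference_geometry(self):
        rec = make_dataset(1, (30, 30), seed=9)[0]
        np.testing.assert_array_equal(rec.graph().coords, rec.reference.ca_coords())
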