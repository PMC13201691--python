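"""Manifest I/O, preprocessing, splits and the synthetic generator."""

import numpy as np
import pytest
from PIL import Image

import squeezevit as sv
from squeezevit.errors import ConfigurationError, ManifestError


def _write_csv(path, rows):
    lines = ["Image Index,Finding Labels"] + rows
    path.write_text("\n".join(lines) + "\n")


class TestReadManifest:
    def test_pipe_delimited_findings(self, tmp_path):
        _write_csv(tmp_path / "m.csv", ['img1.png,"Effusion|Cardiomegaly"'])
        m = sv.read_manifest(tmp_path / "m.csv")
        assert m.labels[0] == {"Effusion", "Cardiomegaly"}
        mat = m.label_matrix()
        assert mat.sum() == 2

    def test_no_finding_is_empty_positive_set(self, tmp_path):
        _write_csv(tmp_path / "m.csv", ["img2.png,No Finding"])
        m = sv.read_manifest(tmp_path / "m.csv")
        assert m.labels[0] == frozenset()
        assert sv.binarize_labels(m).label_matrix()[0, 0] == 0

    def test_sentinel_exclusivity_violation(self, tmp_path):
        _write_csv(tmp_path / "m.csv", ["ok.png,Edema",
                                        '"bad.png","No Finding|Edema"'])
        with pytest.raises(ManifestError, match="row 1"):
            sv.read_manifest(tmp_path / "m.csv")

    def test_unknown_class_reports_row(self, tmp_path):
        _write_csv(tmp_path / "m.csv", ["a.png,Edema", "b.png,Dragonpox"])
        with pytest.raises(ManifestError, match="row 1.*Dragonpox"):
            sv.read_manifest(tmp_path / "m.csv")

    def test_empty_findings_field(self, tmp_path):
        _write_csv(tmp_path / "m.csv", ['a.png,""'])
        with pytest.raises(ManifestError, match="row 0"):
            sv.read_manifest(tmp_path / "m.csv")

    def test_missing_image_file_reported(self, tmp_path):
        _write_csv(tmp_path / "m.csv", ["ghost.png,Edema"])
        with pytest.raises(ManifestError, match="ghost.png"):
            sv.read_manifest(tmp_path / "m.csv", tmp_path)

    def test_chexpert_dialect_maps_uncertain_to_negative(self, tmp_path):
        cols = ",".join(sv.NIH_CLASSES)
        vals = ["0"] * 14
        vals[1] = "1"   # Cardiomegaly positive
        vals[3] = "-1"  # Edema uncertain → negative
        (tmp_path / "c.csv").write_text(
            f"Path,{cols}\nimg.png,{','.join(vals)}\n")
        m = sv.read_manifest(tmp_path / "c.csv", dialect="chexpert")
        assert m.labels[0] == {"Cardiomegaly"}

    def test_round_trip_preserves_label_matrix(self, tmp_path, small_synth):
        out = tmp_path / "m.csv"
        sv.write_manifest(small_synth.manifest, out)
        back = sv.read_manifest(out, classes=small_synth.manifest.classes)
        np.testing.assert_array_equal(back.label_matrix(),
                                      small_synth.manifest.label_matrix())


class TestPreprocess:
    def test_constant_image_constant_output(self, tmp_path):
        Image.fromarray(np.full((50, 50), 100, np.uint8), "L").save(
            tmp_path / "c.png")
        out = sv.preprocess(tmp_path / "c.png")
        assert out.shape == (1, 224, 224)
        np.testing.assert_allclose(out, 100 / 255.0, atol=1e-6)

    def test_resize_contract_448_to_224(self, rng, tmp_path):
        arr = (rng.random((448, 448)) * 255).astype(np.uint8)
        Image.fromarray(arr, "L").save(tmp_path / "big.png")
        assert sv.preprocess(tmp_path / "big.png").shape == (1, 224, 224)

    def test_8bit_white_maps_to_one(self, tmp_path):
        Image.fromarray(np.full((224, 224), 255, np.uint8), "L").save(
            tmp_path / "w.png")
        assert sv.preprocess(tmp_path / "w.png").max() == pytest.approx(1.0)

    def test_rgb_collapsed_by_luminance(self, tmp_path):
        rgb = np.zeros((224, 224, 3), np.uint8)
        rgb[..., 1] = 255  # pure green
        Image.fromarray(rgb, "RGB").save(tmp_path / "g.png")
        out = sv.preprocess(tmp_path / "g.png")
        assert 0.5 < out.mean() < 0.75  # ITU luminance of green ≈ 0.59

    def test_undecodable_file_names_the_file(self, tmp_path):
        bad = tmp_path / "broken.png"
        bad.write_bytes(b"not an image")
        with pytest.raises(IOError, match="broken.png"):
            sv.preprocess(bad)


class TestSplit:
    def test_80_20_disjoint_exhaustive(self, small_synth):
        tr, te = sv.split_dataset(small_synth.manifest, 0.8, seed=4)
        assert len(tr) == 32 and len(te) == 8
        assert set(tr.image_ids).isdisjoint(te.image_ids)
        assert set(tr.image_ids) | set(te.image_ids) == \
            set(small_synth.manifest.image_ids)

    def test_same_seed_same_partition(self, small_synth):
        a = sv.split_dataset(small_synth.manifest, 0.8, seed=9)
        b = sv.split_dataset(small_synth.manifest, 0.8, seed=9)
        assert a[0].image_ids == b[0].image_ids

    def test_single_record_cannot_split(self, small_synth):
        one = small_synth.manifest.subset(np.array([0]))
        with pytest.raises(ConfigurationError):
            sv.split_dataset(one, 0.8, seed=0)

    def test_fraction_out_of_range(self, small_synth):
        with pytest.raises(ConfigurationError):
            sv.split_dataset(small_synth.manifest, 1.2, seed=0)

    def test_patient_level_split_keeps_patients_together(self, tmp_path):
        rows = [f'{p:08d}_{k:03d}.png,Edema' for p in range(10)
                for k in range(3)]
        _write_csv(tmp_path / "m.csv", rows)
        m = sv.read_manifest(tmp_path / "m.csv")
        tr, te = sv.split_dataset(m, 0.8, seed=1, unit="patient")
        from squeezevit.data import nih_patient_id
        tr_p = {nih_patient_id(i) for i in tr.image_ids}
        te_p = {nih_patient_id(i) for i in te.image_ids}
        assert tr_p.isdisjoint(te_p)
        assert len(tr) + len(te) == 30


class TestBinarize:
    def test_examples(self, tmp_path):
        _write_csv(tmp_path / "m.csv", [
            "a.png,No Finding",
            '"b.png","Cardiomegaly|Effusion"',
            "c.png,Edema",
        ])
        m = sv.binarize_labels(sv.read_manifest(tmp_path / "m.csv"))
        np.testing.assert_array_equal(m.label_matrix().ravel(), [0, 1, 1])
        assert m.classes == ("Abnormal",)


class TestSynthetic:
    def test_zero_prevalence_class_has_no_positives(self):
        prev = [0.4] * 5 + [0.0]
        ds = sv.generate_synthetic(sv.SyntheticSpec(
            n_images=50, image_side=32, n_classes=6, prevalence=tuple(prev),
            seed=2))
        assert ds.label_matrix[:, 5].sum() == 0

    def test_seed_determinism_byte_identical_manifest(self, tmp_path):
        spec = sv.SyntheticSpec(n_images=10, image_side=32, n_classes=4, seed=5)
        sv.generate_synthetic(spec, tmp_path / "a")
        sv.generate_synthetic(spec, tmp_path / "b")
        assert (tmp_path / "a" / "manifest.csv").read_bytes() == \
            (tmp_path / "b" / "manifest.csv").read_bytes()
        img = "synthetic_00003.png"
        assert (tmp_path / "a" / img).read_bytes() == \
            (tmp_path / "b" / img).read_bytes()

    def test_disk_and_memory_images_agree(self, tmp_path):
        spec = sv.SyntheticSpec(n_images=4, image_side=64, n_classes=3, seed=8)
        ds = sv.generate_synthetic(spec, tmp_path)
        arr = sv.preprocess(tmp_path / "synthetic_00000.png", side=64)
        np.testing.assert_allclose(arr, ds.images[0], atol=1e-6)

    def test_prevalence_within_3_binomial_se(self):
        spec = sv.SyntheticSpec(n_images=600, image_side=16, n_classes=8,
                                prevalence=0.3, seed=13)
        ds = sv.generate_synthetic(spec)
        emp = ds.label_matrix.mean(axis=0)
        se = np.sqrt(0.3 * 0.7 / 600)
        assert (np.abs(emp - 0.3) <= 3 * se).all()

    def test_co_occurrence_raises_pairwise_correlation(self):
        base = dict(n_images=800, image_side=16, n_classes=4, seed=21)
        indep = sv.generate_synthetic(sv.SyntheticSpec(**base)).label_matrix
        dep = sv.generate_synthetic(
            sv.SyntheticSpec(**base, co_occurrence=0.7)).label_matrix
        def mean_corr(m):
            c = np.corrcoef(m.T)
            return c[np.triu_indices_from(c, 1)].mean()
        assert mean_corr(dep) > mean_corr(indep) + 0.2

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(ConfigurationError):
            sv.SyntheticSpec(prevalence=1.4)

    def test_matched_filter_separates_small_noise(self, small_synth):
        scores = sv.matched_filter_scores(small_synth.images,
                                          small_synth.templates)
        rep = sv.classwise_auroc(scores, small_synth.label_matrix)
        assert rep.average_auroc > 0.95

    def test_oracle_auroc_decreases_with_noise(self):
        """The separability knob: more pixel noise, worse ideal observer."""
        aurocs = []
        for sigma in (0.1, 1.0, 3.0):
            ds = sv.generate_synthetic(sv.SyntheticSpec(
                n_images=150, image_side=64, n_classes=6,
                noise_sigma=sigma, seed=17))
            scores = sv.matched_filter_scores(ds.images, ds.templates)
            rep = sv.classwise_auroc(scores, ds.label_matrix)
            aurocs.append(rep.average_auroc)
        assert aurocs[0] > aurocs[1] > aurocs[2]
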