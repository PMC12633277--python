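import numpy as np
import pytest
from skimage.measure import label as cc_label

from cytocluster.errors import GenerationError, InputError, ParameterError
from cytocluster.fluor_extract import extract_stain_mask, green_channel, yellow_channel
from cytocluster.imageio_core import ClusterClass, PhenotypeLabel
from cytocluster.synth_fixtures import (
    SceneSpec,
    StainSpec,
    apply_staining,
    generate_dataset,
    generate_labeled_record,
    generate_scene,
)


class TestSceneSpec:
    def test_kind_constraints(self):
        with pytest.raises(ParameterError):
            SceneSpec(kind="blank", n_cells=2)
        with pytest.raises(ParameterError):
            SceneSpec(kind="cluster", n_cells=1)
        with pytest.raises(ParameterError):
            SceneSpec(kind="nonsense")


class TestGenerateScene:
    def test_blank(self):
        rec = generate_scene(SceneSpec(kind="blank", n_cells=0, seed=1))
        assert rec.truth_mask.area == 0
        assert rec.truth_class is ClusterClass.NON_CLUSTER

    def test_cluster_is_connected(self):
        rec = generate_scene(SceneSpec(kind="cluster", n_cells=3, seed=2))
        assert rec.truth_class is ClusterClass.CLUSTER
        assert cc_label(rec.truth_mask.grid, connectivity=2).max() == 1

    def test_separated_cells_are_disjoint_components(self):
        rec = generate_scene(SceneSpec(kind="separated_cells", n_cells=3, seed=3))
        assert cc_label(rec.truth_mask.grid, connectivity=2).max() == 3

    def test_deterministic(self):
        spec = SceneSpec(kind="cluster", n_cells=3, seed=9)
        a, b = generate_scene(spec), generate_scene(spec)
        assert np.array_equal(a.brightfield.pixels, b.brightfield.pixels)
        assert np.array_equal(a.truth_mask.grid, b.truth_mask.grid)

    def test_fluorescence_channels_dark(self):
        rec = generate_scene(SceneSpec(kind="cluster", n_cells=2, seed=4))
        assert rec.cd61.pixels.max() < 20
        assert rec.cd45.pixels.max() < 20

    def test_infeasible_packing(self):
        with pytest.raises(GenerationError):
            generate_scene(
                SceneSpec(
                    kind="separated_cells",
                    n_cells=4,
                    cell_radius=(30.0, 31.0),
                    height=64,
                    width=64,
                    seed=0,
                )
            )


class TestApplyStaining:
    @pytest.fixture
    def cluster_record(self):
        return generate_scene(SceneSpec(kind="cluster", n_cells=3, noise_sigma=0.0, seed=5))

    def test_rbc_paints_nothing(self, cluster_record):
        rec = apply_staining(
            cluster_record,
            StainSpec(target_phenotype=PhenotypeLabel.RBC_CLUSTER, artifact_area_px=0),
        )
        assert extract_stain_mask(rec.cd61, green_channel()).area == 0
        assert extract_stain_mask(rec.cd45, yellow_channel()).area == 0
        assert rec.truth_phenotype is PhenotypeLabel.RBC_CLUSTER

    def test_full_coverage_green(self, cluster_record):
        rec = apply_staining(
            cluster_record,
            StainSpec(
                target_phenotype=PhenotypeLabel.PLATELET_CLUSTER, coverage_frac=1.0
            ),
        )
        stain = extract_stain_mask(rec.cd61, green_channel(), apply_morphology=False)
        assert (stain.grid & rec.truth_mask.grid).sum() == rec.truth_mask.area

    def test_half_coverage_both_channels(self, cluster_record):
        """Painted-in-mask pixel counts give overlap 50 +- 2 pp per channel."""
        rec = apply_staining(
            cluster_record,
            StainSpec(
                target_phenotype=PhenotypeLabel.WBC_PLATELET_CLUSTER,
                coverage_frac=0.5,
            ),
        )
        area = rec.truth_mask.area
        for img, channel in ((rec.cd61, green_channel()), (rec.cd45, yellow_channel())):
            stain = extract_stain_mask(img, channel, apply_morphology=False)
            pct = 100.0 * (stain.grid & rec.truth_mask.grid).sum() / area
            assert pct == pytest.approx(50.0, abs=2.0)

    def test_artifact_strictly_outside(self, cluster_record):
        rec = apply_staining(
            cluster_record,
            StainSpec(
                target_phenotype=PhenotypeLabel.PLATELET_CLUSTER,
                coverage_frac=0.0,
                artifact_area_px=80,
            ),
        )
        stain = extract_stain_mask(rec.cd61, green_channel(), apply_morphology=False)
        assert stain.area == 80
        assert not (stain.grid & rec.truth_mask.grid).any()
        assert rec.truth_phenotype is PhenotypeLabel.EXCLUDED_ARTIFACT

    def test_noise_free_reextraction_exact(self, cluster_record):
        """Painted stain re-extracted at v_lo <= intensity - 10 is identical."""
        rec = apply_staining(
            cluster_record,
            StainSpec(
                target_phenotype=PhenotypeLabel.PLATELET_CLUSTER,
                coverage_frac=0.7,
                intensity=180,
            ),
        )
        stain = extract_stain_mask(
            rec.cd61, green_channel(v_lo=170), apply_morphology=False
        )
        n_painted = int(np.ceil(0.7 * rec.truth_mask.area))
        assert stain.area == n_painted
        assert (stain.grid & rec.truth_mask.grid).sum() == n_painted

    def test_requires_truth_mask(self):
        blank = generate_scene(SceneSpec(kind="blank", n_cells=0, seed=6))
        with pytest.raises(InputError):
            apply_staining(
                blank,
                StainSpec(
                    target_phenotype=PhenotypeLabel.PLATELET_CLUSTER, coverage_frac=0.5
                ),
            )

    def test_set_truth_false_keeps_label(self, cluster_record):
        rec = apply_staining(
            cluster_record,
            StainSpec(target_phenotype=PhenotypeLabel.WBC_CLUSTER, coverage_frac=0.5),
        )
        rec2 = apply_staining(
            rec,
            StainSpec(target_phenotype=PhenotypeLabel.PLATELET_CLUSTER, coverage_frac=0.05),
            set_truth=False,
        )
        assert rec2.truth_phenotype is PhenotypeLabel.WBC_CLUSTER


class TestGenerateDataset:
    def test_manifest_and_classes(self, tmp_path):
        manifest = generate_dataset(tmp_path, 30, seed=0)
        assert len(manifest) == 30
        assert set(manifest["class"]) == {"cluster", "non_cluster"}
        assert (tmp_path / "manifest.csv").is_file()

    def test_deterministic_manifests(self, tmp_path):
        generate_dataset(tmp_path / "a", 12, seed=5)
        generate_dataset(tmp_path / "b", 12, seed=5)
        assert (tmp_path / "a" / "manifest.csv").read_bytes() == (
            tmp_path / "b" / "manifest.csv"
        ).read_bytes()

    def test_artifact_rate_one(self, tmp_path):
        from cytocluster.imageio_core import read_image, read_mask

        manifest = generate_dataset(
            tmp_path,
            12,
            class_mix={"cluster": 1.0, "non_cluster": 0.0},
            phenotype_mix={PhenotypeLabel.PLATELET_CLUSTER: 1.0},
            artifact_rate=1.0,
            seed=3,
        )
        assert (manifest["phenotype"] == "excluded_artifact").all()
        for _, row in manifest.iterrows():
            cd61 = read_image(tmp_path / row["cd61"])
            truth = read_mask(tmp_path / row["mask"])
            stain = extract_stain_mask(cd61, green_channel(), apply_morphology=False)
            assert stain.area > 0
            assert not (stain.grid & truth.grid).any()

    def test_bad_mix(self, tmp_path):
        with pytest.raises(ParameterError):
            generate_dataset(tmp_path, 5, class_mix={"cluster": 0.7}, seed=0)


class TestGenerateLabeledRecord:
    @pytest.mark.parametrize(
        "pheno",
        [
            PhenotypeLabel.RBC_CLUSTER,
            PhenotypeLabel.PLATELET_CLUSTER,
            PhenotypeLabel.WBC_CLUSTER,
            PhenotypeLabel.WBC_PLATELET_CLUSTER,
        ],
    )
    def test_truth_label_set(self, pheno):
        rec = generate_labeled_record("x", True, pheno, seed=17)
        assert rec.truth_phenotype is pheno
        assert rec.truth_class is ClusterClass.CLUSTER

    def test_non_cluster(self):
        rec = generate_labeled_record("y", False, None, seed=17)
        assert rec.truth_class is ClusterClass.NON_CLUSTER
        assert rec.truth_phenotype is None
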