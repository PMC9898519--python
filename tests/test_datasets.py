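import numpy as np
import pytest

from contcls import datasets as ds
from contcls.datasets import (
    DatasetError,
    accumulate,
    balance_stage,
    build_fixed_testset,
    build_task_datasets,
    select_mass_per_side,
)
from contcls.records import (
    CaseRecord,
    ImageRecord,
    ManifestError,
    MassRecord,
    cases_to_frame,
    frame_to_cases,
    read_manifest,
    write_manifest,
)
from contcls.taxonomy import BENIGN, MALIGNANT


def _mass(mass_id, disease, case_id="c1", side="left", diameter=None, n_images=1):
    images = [
        ImageRecord(f"{mass_id}-i{j}", mass_id, pixels=np.zeros((16, 16)))
        for j in range(n_images)
    ]
    return MassRecord(mass_id, case_id, side, disease, diameter, images)


def _case(case_id, *mass_specs):
    masses = [
        _mass(f"{case_id}-{i}", disease, case_id=case_id, side=side,
              diameter=diam, n_images=n)
        for i, (disease, side, diam, n) in enumerate(mass_specs)
    ]
    return CaseRecord(case_id, age=40, masses=masses)


IDC = "Invasive ductal carcinoma of the breast"
DCIS = "Ductal carcinoma in situ of the breast"
CYST = "Breast cyst"
FIBRO = "Fibroadenoma of breast"


# ---------------------------------------------------------------------------
# per-side selection


class TestSelectMassPerSide:
    def test_malignant_beats_benign(self, taxonomy):
        cyst = _mass("m1", CYST, diameter=30)
        idc = _mass("m2", IDC)
        assert select_mass_per_side([cyst, idc], taxonomy) is idc

    def test_single_candidate(self, taxonomy):
        m = _mass("m1", CYST)
        assert select_mass_per_side([m], taxonomy) is m

    def test_largest_benign_wins(self, taxonomy):
        small = _mass("m1", CYST, diameter=12)
        large = _mass("m2", FIBRO, diameter=20)
        assert select_mass_per_side([small, large], taxonomy) is large

    def test_highest_grade_malignant_wins(self, taxonomy):
        # default taxonomy: IDC grade 9 > DCIS grade 3
        dcis = _mass("m1", DCIS)
        idc = _mass("m2", IDC)
        assert select_mass_per_side([dcis, idc], taxonomy) is idc

    def test_mixed_sides_rejected(self, taxonomy):
        left = _mass("m1", CYST, side="left")
        right = _mass("m2", CYST, side="right")
        with pytest.raises(DatasetError, match="case-sides"):
            select_mass_per_side([left, right], taxonomy)

    def test_benign_tie_missing_diameter_falls_back(self, taxonomy):
        a = _mass("a", CYST, n_images=1)
        b = _mass("b", FIBRO, n_images=3)
        assert select_mass_per_side([a, b], taxonomy) is b  # more images


# ---------------------------------------------------------------------------
# balancing


class TestBalanceStage:
    def _stage_cases(self, n_mal=22, n_ben=61, seed=0):
        rng = np.random.default_rng(seed)
        cases = []
        for i in range(n_mal):
            cases.append(_case(f"mal{i:03d}", (IDC, "left", None, int(rng.integers(2, 8)))))
        for i in range(n_ben):
            cases.append(_case(f"ben{i:03d}", (FIBRO, "left", 10.0, int(rng.integers(2, 8)))))
        return cases

    def test_parity_on_imbalanced_stage(self, taxonomy):
        """22 malignant cases with a benign surplus yields ~44 trained cases."""
        plan = balance_stage(self._stage_cases(), taxonomy, seed=3)
        n_mal = plan.case_counts[MALIGNANT]
        n_ben = plan.case_counts[BENIGN]
        assert n_mal == 22
        assert n_mal <= n_ben <= n_mal + 2
        assert 44 <= len(plan.balanced_cases) <= 46
        assert len(plan.excluded_benign) == 61 - n_ben

    def test_all_benign_kept_when_scarce(self, taxonomy):
        plan = balance_stage(self._stage_cases(n_mal=10, n_ben=4), taxonomy, seed=0)
        assert plan.case_counts[BENIGN] == 4
        assert plan.excluded_benign == []

    def test_seed_determinism(self, taxonomy):
        cases = self._stage_cases()
        p1 = balance_stage(cases, taxonomy, seed=11)
        p2 = balance_stage(cases, taxonomy, seed=11)
        assert [c.case_id for c in p1.excluded_benign] == [c.case_id for c in p2.excluded_benign]
        assert [c.case_id for c in p1.balanced_cases] == [c.case_id for c in p2.balanced_cases]


# ---------------------------------------------------------------------------
# accumulation


class TestAccumulate:
    def test_monotone_superset(self, taxonomy):
        s1 = [_case("c1", (IDC, "left", None, 2)), _case("c2", (CYST, "left", 5.0, 2))]
        plan1 = balance_stage(accumulate(None, s1), taxonomy, seed=0, stage=1)
        s2 = [_case("c3", (FIBRO, "right", 8.0, 2))]
        pool2 = accumulate(plan1, s2)
        ids1 = {c.case_id for c in plan1.accumulated_cases}
        ids2 = {c.case_id for c in pool2}
        assert ids1 <= ids2 and "c3" in ids2

    def test_empty_new_cases(self, taxonomy):
        s1 = [_case("c1", (IDC, "left", None, 2))]
        plan = balance_stage(accumulate(None, s1), taxonomy, seed=0, stage=1)
        assert [c.case_id for c in accumulate(plan, [])] == ["c1"]

    def test_duplicate_case_rejected(self, taxonomy):
        s1 = [_case("c1", (IDC, "left", None, 2))]
        plan = balance_stage(accumulate(None, s1), taxonomy, seed=0, stage=1)
        with pytest.raises(DatasetError, match="duplicate"):
            accumulate(plan, [_case("c1", (IDC, "left", None, 2))])


# ---------------------------------------------------------------------------
# task datasets


class TestBuildTaskDatasets:
    def _pool(self, n_idc=6, n_fibro=6, n_cyst_images=9, images_per=2):
        cases = [
            _case(f"i{k}", (IDC, "left", None, images_per)) for k in range(n_idc)
        ] + [
            _case(f"f{k}", (FIBRO, "left", 9.0, images_per)) for k in range(n_fibro)
        ]
        if n_cyst_images:
            cases.append(_case("cy", (CYST, "left", 5.0, n_cyst_images)))
        return cases

    def test_class_below_threshold_excluded_from_pd(self, taxonomy):
        # cyst contributes 9 images: below the inclusion threshold of 10
        sets = build_task_datasets(self._pool(), taxonomy, seed=0)
        assert CYST not in sets["PD"].classes
        assert "cystic lesion" not in sets["PT"].classes
        # but its images still count for the malignancy task
        n_bm_benign = len(sets["BM"].classes[BENIGN])
        assert n_bm_benign == 6 * 2 + 9

    def test_bm_has_exactly_two_classes(self, taxonomy):
        sets = build_task_datasets(self._pool(), taxonomy, seed=0)
        assert sets["BM"].class_names == (BENIGN, MALIGNANT)

    @pytest.mark.parametrize("n,expected_val", [(10, 2), (11, 2), (14, 3), (5, 1)])
    def test_split_rounding(self, taxonomy, n, expected_val):
        """8:2 split with val = max(1, round(0.2 n)), half rounded up."""
        cases = [_case(f"i{k}", (IDC, "left", None, 2)) for k in range(6)]
        cases.append(_case("fx", (FIBRO, "left", 9.0, n)))
        cases.append(_case("fy", (CYST, "left", 9.0, 12)))
        sets = build_task_datasets(cases, taxonomy, min_images=5, seed=0)
        val_count = sum(1 for it in sets["PD"].val if it.label == FIBRO)
        assert val_count == expected_val

    def test_no_leakage_between_train_and_val(self, taxonomy):
        for seed in range(5):
            sets = build_task_datasets(self._pool(images_per=4), taxonomy, seed=seed)
            for t in sets.values():
                train_ids = {it.image.image_id for it in t.train}
                val_ids = {it.image.image_id for it in t.val}
                assert not train_ids & val_ids
                assert len(train_ids) + len(val_ids) == sum(len(v) for v in t.classes.values())

    def test_bm_below_threshold_is_error(self, taxonomy):
        cases = [_case("i0", (IDC, "left", None, 3)), _case("f0", (FIBRO, "left", 9.0, 12))]
        with pytest.raises(DatasetError, match="too early"):
            build_task_datasets(cases, taxonomy, seed=0)


# ---------------------------------------------------------------------------
# frozen test sets


class TestFixedTestSet:
    def test_sizes_and_determinism(self, small_cohort, taxonomy):
        ts1 = build_fixed_testset(small_cohort, taxonomy, "BM", MALIGNANT, 40, 40, seed=5)
        ts2 = build_fixed_testset(small_cohort, taxonomy, "BM", MALIGNANT, 40, 40, seed=5)
        assert len(ts1.items) == 80
        assert sum(1 for it in ts1.items if it.label == "positive") == 40
        assert ts1.manifest() == ts2.manifest()

    def test_insufficient_images(self, small_cohort, taxonomy):
        with pytest.raises(DatasetError, match="insufficient"):
            build_fixed_testset(small_cohort, taxonomy, "BM", MALIGNANT, 10_000, 10, seed=0)


# ---------------------------------------------------------------------------
# manifests


class TestManifests:
    def test_round_trip(self, tmp_path, taxonomy):
        from contcls.synth import SynthConfig, generate_cohort

        cases = generate_cohort(
            SynthConfig(n_cases=10, image_size=16, seed=1), taxonomy, out_dir=tmp_path
        )
        path = tmp_path / "roundtrip.csv"
        write_manifest(cases, path)
        back = read_manifest(path, taxonomy)
        assert cases_to_frame(back).equals(cases_to_frame(cases))

    def test_unknown_disease_names_row(self, taxonomy):
        df = cases_to_frame([_case("c1", (IDC, "left", None, 1))])
        df.loc[0, "disease"] = "Not a disease"
        with pytest.raises(ManifestError, match="row 1"):
            frame_to_cases(df, taxonomy)
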