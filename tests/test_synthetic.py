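"""Generator contracts: round-trip exactness, calibration, determinism."""

import numpy as np
import pytest

from craniosym.errors import GenerationError
from craniosym.io import ANATOMICAL_LABELS
from craniosym.synthetic import (
    CohortConfig,
    generate_cohort,
    generate_subject,
    reliability_study,
    simulate_raters,
)


def zero_sd_config():
    cfg = CohortConfig()
    for by_sex in cfg.params.values():
        for cell in by_sex.values():
            for p in cell:
                cell[p] = (cell[p][0], 0.0)
    for norms in cfg.head_norms.values():
        for p in norms:
            norms[p] = (norms[p][0], 0.0)
    return cfg


class TestGenerateSubject:
    def test_zero_sd_reproduces_published_means_exactly(self):
        """With all SDs zero, the class-I male subject measures exactly the
        published class-I male means (e.g. Sn to N-Pg 6.49 mm)."""
        cfg = zero_sd_config()
        subj = generate_subject("I", "M", cfg, np.random.default_rng(0))
        rec = subj.measurements()
        cell = CohortConfig().params["I"]["M"]
        for param, (mean, _) in cell.items():
            assert getattr(rec, param) == pytest.approx(mean, abs=1e-6), param
        assert rec.Sn_to_NPg == pytest.approx(6.49, abs=1e-6)

    @pytest.mark.parametrize("cls", ["I", "II", "III"])
    @pytest.mark.parametrize("sex", ["M", "F"])
    def test_roundtrip_every_cell(self, cls, sex, default_config):
        """measure_subject reproduces every drawn target to 1e-6 in every
        class x sex cell."""
        rng = np.random.default_rng(hash((cls, sex)) % 2**31)
        for _ in range(10):
            subj = generate_subject(cls, sex, default_config, rng)
            rec = subj.measurements()
            for param, target in subj.targets.items():
                assert getattr(rec, param) == pytest.approx(target, abs=1e-6)

    def test_roundtrip_holds_in_mesh_mode(self, default_config):
        rng = np.random.default_rng(13)
        subj = generate_subject("II", "F", default_config, rng, with_mesh=True)
        rec = subj.measurements()
        for param, target in subj.targets.items():
            assert getattr(rec, param) == pytest.approx(target, abs=1e-6)

    def test_all_landmarks_present(self, class1_male_subject):
        assert class1_male_subject.landmarks.missing_anatomical() == []

    def test_bilateral_symmetry_of_landmarks(self, class1_male_subject):
        lms = class1_male_subject.landmarks
        for lb in ANATOMICAL_LABELS:
            if lb.endswith("-r"):
                r, l = lms[lb], lms[lb[:-2] + "-l"]
                np.testing.assert_allclose(r * [-1, 1, 1], l, atol=1e-12)

    def test_sampling_consistency(self, default_config):
        """1000 class-I female draws: N-Sn sample mean and SD within 3 SEM
        of the configured 43.53 / 2.43."""
        rng = np.random.default_rng(7)
        vals = np.array(
            [
                generate_subject("I", "F", default_config, rng).targets["N_Sn"]
                for _ in range(1000)
            ]
        )
        sem = 2.43 / np.sqrt(1000)
        assert abs(vals.mean() - 43.53) < 3 * sem
        sd_sem = 2.43 / np.sqrt(2 * 999)
        assert abs(vals.std(ddof=1) - 2.43) < 4 * sd_sem

    def test_derived_chain_parameters_match_config_moments(self, default_config):
        """The derived N-Sto inherits the configured mean and SD through
        the moment-matched joint draw."""
        rng = np.random.default_rng(8)
        vals = np.array(
            [
                generate_subject("I", "M", default_config, rng).targets["N_Sto"]
                for _ in range(1000)
            ]
        )
        assert abs(vals.mean() - 63.53) < 3 * 2.93 / np.sqrt(1000)
        assert abs(vals.std(ddof=1) - 2.93) < 4 * 2.93 / np.sqrt(2 * 999)

    def test_invalid_config_rejected(self):
        cfg = CohortConfig()
        cfg.params["I"]["M"]["N_Sn"] = (43.22, -1.0)
        with pytest.raises(GenerationError):
            cfg.validate()

    def test_infeasible_means_rejected(self):
        cfg = CohortConfig()
        # N-Sto mean far above N-Sn + Sn-Sto violates the triangle bound.
        cfg.params["I"]["M"]["N_Sto"] = (80.0, 1.0)
        with pytest.raises(GenerationError, match="consistent"):
            cfg.validate()


class TestGenerateCohort:
    def test_default_roster(self, tmp_path):
        cfg = CohortConfig(seed=21)
        df = generate_cohort(cfg, out_dir=tmp_path / "c")
        assert len(df) == 139
        counts = df.groupby("cls").size()
        assert counts["I"] == 74 and counts["II"] == 50 and counts["III"] == 15
        assert (tmp_path / "c" / "roster.csv").exists()
        assert len(list((tmp_path / "c" / "landmarks").glob("*.csv"))) == 139

    def test_seed_reproducibility_byte_identical(self, tmp_path):
        cfg = CohortConfig(seed=5)
        small = {("I", "M"): 3, ("I", "F"): 2, ("II", "M"): 2,
                 ("II", "F"): 2, ("III", "M"): 2, ("III", "F"): 2}
        cfg.group_sizes = small
        generate_cohort(cfg, out_dir=tmp_path / "a")
        generate_cohort(cfg, out_dir=tmp_path / "b")
        for name in ("roster.csv", "cohort.csv", "landmarks/S001.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_different_seeds_same_structure(self):
        small = {("I", "M"): 3, ("I", "F"): 3, ("II", "M"): 2,
                 ("II", "F"): 2, ("III", "M"): 2, ("III", "F"): 2}
        df1 = generate_cohort(CohortConfig(seed=1, group_sizes=small))
        df2 = generate_cohort(CohortConfig(seed=2, group_sizes=small))
        assert list(df1.columns) == list(df2.columns)
        assert (df1["cls"] == df2["cls"]).all() and (df1["sex"] == df2["sex"]).all()
        assert not np.allclose(df1["N_Gn"], df2["N_Gn"])

    def test_mean_age_near_configured(self):
        df = generate_cohort(CohortConfig(seed=3))
        assert df["age"].mean() == pytest.approx(9.13, abs=0.12)


class TestRaters:
    def test_zero_noise_perfect_icc(self, default_config):
        rng = np.random.default_rng(14)
        iccs = reliability_study(
            default_config, noise_ratio=0.0, rng=rng, mode="parameter"
        )
        for param, icc in iccs.items():
            assert icc == pytest.approx(1.0, abs=1e-9), param

    def test_zero_landmark_noise_identity(self, class1_male_subject):
        sets, recs = simulate_raters(
            class1_male_subject.landmarks, 2, 0.0, np.random.default_rng(15)
        )
        base = class1_male_subject.measurements()
        for rec in recs:
            np.testing.assert_allclose(rec.values14(), base.values14(), atol=1e-12)

    def test_quarter_sd_noise_iccs_in_published_band(self, default_config):
        """31 subjects x 2 raters at 25%-of-SD noise: parameter ICCs fall in
        the published 0.75-0.97 reliability band."""
        rng = np.random.default_rng(16)
        iccs = reliability_study(default_config, noise_ratio=0.25, rng=rng)
        for param, icc in iccs.items():
            assert 0.75 <= icc <= 0.97, (param, icc)

    def test_icc_decreases_with_noise(self, default_config):
        """Mean parameter ICC is monotone non-increasing in landmark noise
        (averaged over seeds)."""
        levels = (0.1, 0.5, 1.5)
        means = []
        for noise in levels:
            vals = []
            for seed in range(5):
                rng = np.random.default_rng(100 + seed)
                iccs = reliability_study(
                    default_config, n_subjects=12, noise_ratio=noise,
                    rng=rng, mode="landmark",
                )
                vals.append(np.mean(list(iccs.values())))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]

    def test_negative_noise_rejected(self, class1_male_subject):
        with pytest.raises(GenerationError):
            simulate_raters(class1_male_subject.landmarks, 2, -1.0)
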