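"""Synthetic cohort generator: calibration, determinism, round-trip."""

import dataclasses
import io

import numpy as np
import pandas as pd
import pytest

from dectrod import (
    CohortConfig,
    PhantomSpec,
    default_cohort_config,
    generate_cohort,
    generate_phantom,
    read_cohort,
    write_cohort,
)
from dectrod.cohort import COHORT_COLUMNS, ConfigError, CohortSchemaError, Marginal
from dectrod.stats import spearman


class TestGenerateCohort:
    def test_fixed_seed_is_bit_identical(self):
        cfg = default_cohort_config(300, seed=42)
        pd.testing.assert_frame_equal(generate_cohort(cfg), generate_cohort(cfg))

    def test_different_seeds_differ(self):
        a = generate_cohort(default_cohort_config(300, seed=1))
        b = generate_cohort(default_cohort_config(300, seed=2))
        assert not a.drop(columns="patient_id").equals(b.drop(columns="patient_id"))

    def test_metastasis_fraction(self, cohort_10k):
        # published prevalence 39/137 = 0.285
        assert abs(cohort_10k["group"].mean() - 39 / 137) < 0.02

    def test_group_marginals_converge(self, cohort_10k):
        cfg = default_cohort_config(10_000)
        for g, spec in ((1, cfg.metastasis), (0, cfg.non_metastasis)):
            sub = cohort_10k[cohort_10k["group"] == g]
            n = len(sub)
            for site in ("lesion", "node"):
                marg = getattr(spec, site)
                for p in ("att40_hu", "att70_hu", "ic_mgcm3", "wc_mgcm3", "effz"):
                    m = getattr(marg, p)
                    col = sub[f"{site}_{p}"]
                    assert abs(col.mean() - m.mean) < 3 * m.sd / np.sqrt(n), (g, site, p)
                    assert abs(col.std(ddof=1) - m.sd) < 3 * m.sd / np.sqrt(2 * n), (g, site, p)

    def test_rank_correlation_bands(self, cohort_10k):
        # published Spearman: 0.609-0.692 (metastasis), 0.115-0.165 (not)
        for g, lo, hi in ((1, 0.55, 0.75), (0, 0.0, 0.25)):
            sub = cohort_10k[cohort_10k["group"] == g]
            rho, _ = spearman(sub["lesion_att40_hu"], sub["node_att40_hu"])
            assert lo <= rho <= hi, (g, rho)

    def test_morphology_and_pathology_rates(self, cohort_10k):
        met = cohort_10k[cohort_10k["group"] == 1]
        non = cohort_10k[cohort_10k["group"] == 0]
        # positivity rejection truncates the diameter marginals slightly
        # upward (about +0.2 mm for the metastasis group), so the bands
        # allow for the truncated-Gaussian mean shift
        assert abs(met["node_short_mm"].mean() - 7.6) < 0.4
        assert abs(non["node_short_mm"].mean() - 3.4) < 0.15
        assert abs((1 - met["hilum_present"]).mean() - 24 / 39) < 0.03
        assert abs((1 - non["hilum_present"]).mean() - 10 / 98) < 0.02
        assert abs(met["er_positive"].mean() - 23 / 39) < 0.03
        # Ki67 stays inside (0, 100)%
        assert cohort_10k["ki67_pct"].between(0, 100, inclusive="neither").all()

    def test_physical_constraints(self, cohort_10k):
        df = cohort_10k
        for col in (
            "lesion_ic_mgcm3", "lesion_wc_mgcm3", "lesion_effz",
            "node_ic_mgcm3", "node_wc_mgcm3", "node_effz",
            "aorta_ic_mgcm3", "aorta_wc_mgcm3", "aorta_effz",
            "node_short_mm", "node_long_mm", "lesion_size_mm",
        ):
            assert (df[col] > 0).all(), col
        assert (df["lesion_att40_hu"] > df["lesion_att70_hu"]).all()
        assert (df["node_att40_hu"] > df["node_att70_hu"]).all()

    @pytest.mark.parametrize(
        "patch",
        [
            {"n_patients": 0},
            {"n_patients": -5},
            {"metastasis_fraction": 0.0},
            {"metastasis_fraction": 1.2},
        ],
    )
    def test_invalid_config_rejected(self, patch):
        cfg = dataclasses.replace(default_cohort_config(100), **patch)
        with pytest.raises(ConfigError):
            generate_cohort(cfg)

    def test_bad_scale_and_correlation_rejected(self):
        cfg = default_cohort_config(100)
        bad_marg = dataclasses.replace(
            cfg.metastasis,
            lesion=dataclasses.replace(
                cfg.metastasis.lesion, att40_hu=Marginal(250, -1.0)
            ),
        )
        with pytest.raises(ConfigError):
            generate_cohort(dataclasses.replace(cfg, metastasis=bad_marg))
        bad_rho = dataclasses.replace(cfg.metastasis, rank_correlation=1.0)
        with pytest.raises(ConfigError):
            generate_cohort(dataclasses.replace(cfg, metastasis=bad_rho))

    def test_config_json_round_trip(self, tmp_path):
        cfg = default_cohort_config(137, seed=9)
        path = tmp_path / "cfg.json"
        cfg.to_json(path)
        assert CohortConfig.from_json(path) == cfg


class TestCohortCSV:
    def test_round_trip_preserves_everything(self, tmp_path, small_cohort):
        cohort = small_cohort[list(COHORT_COLUMNS)]
        path = tmp_path / "cohort.csv"
        write_cohort(cohort, path)
        back = read_cohort(path)
        pd.testing.assert_frame_equal(back, cohort.reset_index(drop=True))

    def test_empty_cohort_writes_header_only(self, tmp_path):
        empty = pd.DataFrame(columns=list(COHORT_COLUMNS))
        path = tmp_path / "empty.csv"
        write_cohort(empty, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].split(",") == list(COHORT_COLUMNS)

    def test_missing_ki67_flagged_not_dropped(self, tmp_path, small_cohort):
        cohort = small_cohort[list(COHORT_COLUMNS)].head(10).copy()
        cohort.loc[cohort.index[3], "ki67_pct"] = np.nan
        path = tmp_path / "missing.csv"
        write_cohort(cohort, path)
        assert ",," in path.read_text()  # empty token on disk
        back = read_cohort(path)
        assert len(back) == 10
        assert back["ki67_pct"].isna().sum() == 1

    def test_non_numeric_cell_names_row_and_column(self, tmp_path, small_cohort):
        path = tmp_path / "bad.csv"
        write_cohort(small_cohort[list(COHORT_COLUMNS)].head(5), path)
        text = path.read_text().splitlines()
        row = text[3].split(",")
        row[COHORT_COLUMNS.index("node_ic_mgcm3")] = "oops"
        text[3] = ",".join(row)
        path.write_text("\n".join(text))
        with pytest.raises(CohortSchemaError, match="node_ic_mgcm3"):
            read_cohort(path)

    def test_schema_mismatch_rejected(self, tmp_path):
        path = tmp_path / "wrong.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(CohortSchemaError):
            read_cohort(path)


class TestPhantom:
    def test_noise_free_disk_is_uniform(self):
        spec = PhantomSpec((64, 64), background_value=10, lesion_center=(32, 32),
                           lesion_radius=12, lesion_value=240)
        img, excluded = generate_phantom(spec)
        rows, cols = np.mgrid[0:64, 0:64]
        disk = (rows - 32) ** 2 + (cols - 32) ** 2 <= 12**2
        assert (img[disk] == 240).all()
        assert (img[~disk] == 10).all()
        assert not excluded.any()

    def test_zero_core_radius_excludes_nothing(self):
        spec = PhantomSpec((32, 32), 0, (16, 16), 8, 100, excluded_core_radius=0)
        _, excluded = generate_phantom(spec)
        assert excluded.sum() == 0

    def test_noisy_disk_mean_within_standard_error(self):
        # SE of the disk mean is noise_sd / sqrt(pi r^2)
        spec = PhantomSpec((128, 128), 0, (64, 64), 20, 240, noise_sd=5, seed=3)
        img, _ = generate_phantom(spec)
        rows, cols = np.mgrid[0:128, 0:128]
        disk = (rows - 64) ** 2 + (cols - 64) ** 2 <= 400
        se = 5 / np.sqrt(np.pi * 400)
        assert abs(img[disk].mean() - 240) < 3 * se

    def test_deterministic_given_seed(self):
        spec = PhantomSpec((64, 64), 0, (32, 32), 10, 100, noise_sd=2, seed=5)
        a, _ = generate_phantom(spec)
        b, _ = generate_phantom(spec)
        np.testing.assert_array_equal(a, b)

    def test_disk_outside_grid_rejected(self):
        with pytest.raises(ConfigError):
            generate_phantom(PhantomSpec((32, 32), 0, (2, 2), 10, 100))
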