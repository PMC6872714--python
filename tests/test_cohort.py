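import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from airwaycp import (
    DegenerateDataError,
    GeometryParams,
    ParameterError,
    REFERENCE_AHI,
    classify_ahi,
    generate_cohort,
    load_cohort,
    run_cohort,
    save_cohort,
    severity_for_ahi,
)
from airwaycp.cohort import VirtualPatient

REFERENCE_CLASSIFICATIONS = (
    "none",
    "mild",
    "moderate",
    "moderate",
    "severe",
    "severe",
    "severe",
)


class TestClassifyAhi:
    @pytest.mark.parametrize(
        "ahi,expected",
        [
            (0, "none"),
            (4.9, "none"),
            (5, "mild"),
            (14.9, "mild"),
            (15, "moderate"),
            (29.9, "moderate"),
            (30, "severe"),
            (120, "severe"),
        ],
    )
    def test_cutoffs(self, ahi, expected):
        assert classify_ahi(ahi) == expected

    def test_reference_cohort_bands(self):
        """The seven-patient reference AHI row maps onto its published
        none/mild/moderate/moderate/severe/severe/severe banding."""
        assert tuple(classify_ahi(a) for a in REFERENCE_AHI) == (
            REFERENCE_CLASSIFICATIONS
        )

    def test_negative_rejected(self):
        with pytest.raises(ParameterError):
            classify_ahi(-1)


class TestGenerateCohort:
    def test_deterministic_under_seed(self):
        a = generate_cohort(10, seed=42)
        b = generate_cohort(10, seed=42)
        assert a == b

    def test_different_seeds_differ(self):
        a = generate_cohort(10, seed=1)
        b = generate_cohort(10, seed=2)
        assert a != b

    def test_noise_free_ahi_monotone_in_severity(self):
        patients = generate_cohort(15, seed=3, sigma_geom=0.0, sigma_ahi=0.0)
        ordered = sorted(patients, key=lambda p: p.severity)
        ahis = [p.ahi for p in ordered]
        assert all(b >= a for a, b in zip(ahis, ahis[1:]))

    def test_noise_free_spearman_is_one(self):
        """Noise-free severities and AHI are perfectly rank-correlated.
        Integer rounding with the zero clip can tie the lowest AHI values,
        so this uses a seeded draw whose 20 AHI values are distinct."""
        patients = generate_cohort(20, seed=14, sigma_geom=0.0, sigma_ahi=0.0)
        ahis = [p.ahi for p in patients]
        assert len(set(ahis)) == len(ahis)
        rho = sps.spearmanr([p.severity for p in patients], ahis).statistic
        assert rho == 1.0

    def test_severity_bounds_and_classification_consistency(self):
        for p in generate_cohort(50, seed=7, sigma_geom=0.3, sigma_ahi=0.5):
            assert 0.0 <= p.severity <= 1.0
            assert 0.0 <= p.geometry_params.severity <= 1.0
            assert 0 <= p.ahi <= 120
            assert p.classification == classify_ahi(p.ahi)

    def test_seven_patients_span_multiple_bands(self):
        """With sigma_ahi = 0.2, a 7-patient draw covers at least two
        clinical bands on >= 95% of 1000 seeds."""
        hits = 0
        for seed in range(1000):
            bands = {p.classification for p in generate_cohort(7, seed=seed)}
            hits += len(bands) >= 2
        assert hits / 1000 >= 0.95

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ParameterError):
            generate_cohort(1, seed=0)

    def test_inconsistent_classification_rejected(self):
        with pytest.raises(ParameterError):
            VirtualPatient("X", 0.5, GeometryParams(), ahi=50, classification="mild")


class TestSeverityForAhi:
    @pytest.mark.parametrize("ahi", REFERENCE_AHI)
    def test_inverts_noise_free_law(self, ahi):
        s = severity_for_ahi(ahi)
        patients = generate_cohort(
            2, seed=0, sigma_geom=0.0, sigma_ahi=0.0, severities=np.array([s, s])
        )
        assert patients[0].ahi == ahi


class TestRunCohort:
    def test_healthy_patient_has_minimal_cp_star(self, default_waveform):
        """Against any constricted airway (severity grid 0.25..1) the
        healthy s = 0 patient carries the smallest Cp*."""
        patients = generate_cohort(
            5, seed=0, sigma_geom=0.0, sigma_ahi=0.0,
            severities=np.array([0.0, 0.25, 0.5, 0.75, 1.0]),
        )
        table = run_cohort(patients, default_waveform)
        assert table.loc[0, "cp_star"] == table["cp_star"].min()

    def test_duplicate_patients_get_identical_rows(self, default_waveform):
        p = generate_cohort(
            2, seed=0, sigma_geom=0.0, sigma_ahi=0.0, severities=np.array([0.4, 0.4])
        )
        table = run_cohort(p, default_waveform)
        cols = ["cp_star", "pressure_drop_Pa", "v_v_mps", "wss_peak_Pa"]
        assert table.loc[0, cols].tolist() == table.loc[1, cols].tolist()

    def test_failure_is_isolated_per_row(self, default_waveform):
        patients = generate_cohort(
            3, seed=0, sigma_geom=0.0, sigma_ahi=0.0,
            severities=np.array([0.2, 0.5, 0.8]),
        )
        broken = VirtualPatient(
            patient_id="BAD",
            severity=patients[1].severity,
            geometry_params=patients[1].geometry_params.model_copy(
                update={"baseline_diameter_m": 1e-4}  # lumen below solver floor
            ),
            ahi=patients[1].ahi,
            classification=patients[1].classification,
        )
        table = run_cohort([patients[0], broken, patients[2]], default_waveform)
        assert table.loc[1, "error"] != ""
        assert np.isnan(table.loc[1, "cp_star"])
        assert table.loc[[0, 2], "error"].eq("").all()
        assert table.loc[[0, 2], "cp_star"].notna().all()

    def test_empty_cohort_rejected(self, default_waveform):
        with pytest.raises(ParameterError):
            run_cohort([], default_waveform)


class TestCohortIO:
    def test_round_trip(self, tmp_path, noise_free_cohort20):
        _, table = noise_free_cohort20
        path = tmp_path / "cohort.csv"
        save_cohort(table, path)
        loaded = load_cohort(path)
        assert list(loaded["patient_id"]) == list(table["patient_id"])
        np.testing.assert_allclose(loaded["cp_star"], table["cp_star"])

    def test_two_column_clinical_layout(self, tmp_path):
        path = tmp_path / "minimal.csv"
        pd.DataFrame(
            {"patient_id": [f"P{i}" for i in range(1, 8)], "ahi": REFERENCE_AHI}
        ).to_csv(path, index=False)
        df = load_cohort(path)
        assert tuple(df["classification"]) == REFERENCE_CLASSIFICATIONS

    def test_three_column_layout_with_extras(self, tmp_path):
        path = tmp_path / "supp.csv"
        pd.DataFrame(
            {
                "patient_id": ["a", "b", "c"],
                "ahi": [1, 20, 90],
                "cp_star": [0.2, 0.5, 0.9],
                "scanner": ["x", "y", "z"],
            }
        ).to_csv(path, index=False)
        df = load_cohort(path)
        assert "cp_star" in df.columns and "scanner" in df.columns

    def test_duplicate_ids_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        pd.DataFrame({"patient_id": ["a", "a"], "ahi": [1, 2]}).to_csv(path, index=False)
        with pytest.raises(DegenerateDataError):
            load_cohort(path)

    def test_missing_ahi_rejected(self, tmp_path):
        path = tmp_path / "na.csv"
        pd.DataFrame({"patient_id": ["a", "b"], "ahi": [1, None]}).to_csv(
            path, index=False
        )
        with pytest.raises(DegenerateDataError):
            load_cohort(path)
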