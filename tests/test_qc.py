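import numpy as np
import pandas as pd
import pytest

from metaboruta import (
    MetabolitePanel,
    QCThresholds,
    SimConfig,
    apply_filters,
    compute_cv,
    flag_outlier_samples,
    generate_panel,
)
from metaboruta.qc import QCConfigError, UndefinedCVError


def make_panel(conc: pd.DataFrame, lod=None, qc_rows=0):
    n = len(conc)
    ids = pd.Index([f"s{i}" for i in range(n - qc_rows)] + [f"q{i}" for i in range(qc_rows)],
                   name="sample_id")
    conc = conc.set_axis(ids, axis=0)
    smeta = pd.DataFrame(
        {
            "group": ["A"] * ((n - qc_rows) // 2) + ["B"] * (n - qc_rows - (n - qc_rows) // 2)
            + ["QC"] * qc_rows,
            "sex": ["M", "F"] * (n // 2) + ["M"] * (n % 2),
            "carcass_weight": [120.0] * (n - qc_rows) + [np.nan] * qc_rows,
            "is_qc": [False] * (n - qc_rows) + [True] * qc_rows,
        },
        index=ids,
    )
    lod = lod if lod is not None else {m: 0.0 for m in conc.columns}
    mmeta = pd.DataFrame(
        {"analyte_class": "AA", "lod": [lod[m] for m in conc.columns]},
        index=pd.Index(conc.columns, name="name"),
    )
    return MetabolitePanel(conc, smeta, mmeta)


class TestComputeCV:
    def test_identical_replicates_zero(self):
        assert compute_cv([5.0, 5.0]) == 0.0

    def test_worked_value(self):
        # sd([10,12]) = 1.41421, mean = 11 -> 12.856%
        assert compute_cv([10.0, 12.0]) == pytest.approx(12.8565, abs=1e-3)

    @pytest.mark.parametrize("values", [[5.0], [0.0, 0.0], [np.nan, 4.0]])
    def test_undefined_cases_raise(self, values):
        with pytest.raises(UndefinedCVError):
            compute_cv(values)


class TestApplyFilters:
    def test_high_cv_excluded_with_reason(self):
        conc = pd.DataFrame({
            "stable": [1.0] * 10 + [1.0, 1.01],
            "noisy": [1.0] * 10 + [1.0, 2.0],  # CV ~47%
        })
        panel = make_panel(conc, qc_rows=2)
        clean, report = apply_filters(panel, QCThresholds())
        assert report.metabolites.loc["noisy", "reason"] == "CV"
        assert "noisy" not in clean.metabolites
        assert "stable" in clean.metabolites

    def test_lod_samples_rule_at_40_percent(self):
        vals = [0.05] * 4 + [1.0] * 6  # 4/10 below lod=0.1 -> 40% > 30%
        conc = pd.DataFrame({"m": vals + [1.0, 1.0], "ok": [1.0] * 12})
        panel = make_panel(conc, lod={"m": 0.1, "ok": 0.0}, qc_rows=2)
        _, report = apply_filters(panel, QCThresholds())
        assert report.metabolites.loc["m", "reason"] == "LOD_SAMPLES"

    def test_lod_qc_rule_all_replicates_below(self):
        conc = pd.DataFrame({"m": [1.0] * 10 + [0.01, 0.02], "ok": [1.0] * 12})
        panel = make_panel(conc, lod={"m": 0.5, "ok": 0.0}, qc_rows=2)
        _, report = apply_filters(panel, QCThresholds(cv_max=None))
        assert report.metabolites.loc["m", "reason"] == "LOD_QC"

    def test_rule_precedence_cv_before_lod(self):
        # fails both CV and LOD_QC; CV is reported
        conc = pd.DataFrame({"m": [1.0] * 10 + [0.01, 0.05]})
        panel = make_panel(conc, lod={"m": 0.5}, qc_rows=2)
        _, report = apply_filters(panel, QCThresholds())
        assert report.metabolites.loc["m", "reason"] == "CV"

    def test_non_binding_thresholds_identity(self, strong_signal):
        panel, _ = strong_signal
        thr = QCThresholds(cv_max=None, lod_qc_rule=None,
                           lod_sample_frac=None, na_zero_frac=None)
        clean, report = apply_filters(panel, thr)
        assert list(clean.metabolites) == list(panel.metabolites)
        assert report.n_excluded == 0

    def test_report_covers_every_metabolite_once(self, strong_signal):
        panel, _ = strong_signal
        _, report = apply_filters(panel, QCThresholds())
        assert len(report.metabolites) == len(panel.metabolites)
        assert report.n_retained + report.n_excluded == len(panel.metabolites)

    def test_column_order_invariance(self):
        conc = pd.DataFrame({
            "a": [1.0] * 10 + [1.0, 1.01],
            "b": [0.01] * 10 + [1.0, 1.01],
        })
        panel = make_panel(conc, lod={"a": 0.0, "b": 0.1}, qc_rows=2)
        rev = MetabolitePanel(
            panel.concentrations[["b", "a"]],
            panel.sample_meta,
            panel.metabolite_meta.loc[["b", "a"]],
        )
        _, r1 = apply_filters(panel)
        _, r2 = apply_filters(rev)
        assert r1.metabolites.loc["b", "reason"] == r2.metabolites.loc["b", "reason"]
        assert r1.n_retained == r2.n_retained

    def test_relaxing_threshold_never_removes_more(self):
        cfg = SimConfig(n_metabolites=30, n_per_group=6, lod_quantile=0.25,
                        n_fail_cv=1, n_fail_lod_qc=2, n_fail_lod_samples=2, seed=4)
        panel, _ = generate_panel(cfg)
        strict = apply_filters(panel, QCThresholds(cv_max=10, lod_sample_frac=0.1))[1]
        loose = apply_filters(panel, QCThresholds(cv_max=40, lod_sample_frac=0.6))[1]
        assert loose.n_retained >= strict.n_retained

    def test_missing_qc_rows_is_config_error(self):
        conc = pd.DataFrame({"m": [1.0] * 6})
        panel = make_panel(conc, qc_rows=0)
        with pytest.raises(QCConfigError):
            apply_filters(panel, QCThresholds())

    def test_study_like_panel_retains_181_of_186(self):
        """Default generator plants 1 CV + 3 LOD-QC + 1 LOD-sample failures."""
        panel, truth = generate_panel(SimConfig(seed=0))
        clean, report = apply_filters(panel)
        assert len(panel.metabolites) == 186
        assert report.n_retained == 181
        reasons = report.reason_counts()
        assert reasons == {"CV": 1, "LOD_QC": 3, "LOD_SAMPLES": 1}
        excluded = set(report.metabolites.index[report.metabolites["excluded"]])
        planted = {m for v in truth.planted_qc_failures.values() for m in v}
        assert excluded == planted


class TestOutlierFlagging:
    def test_identical_samples_no_flags(self):
        conc = pd.DataFrame({"m1": [1.0] * 8, "m2": [2.0] * 8})
        panel = make_panel(conc)
        assert flag_outlier_samples(panel) == []

    def test_shifted_sample_flagged(self):
        rng = np.random.default_rng(0)
        x = rng.normal(10, 1, size=(12, 8))
        x[-1] += 10.0  # 10 sd away on every metabolite
        panel = make_panel(pd.DataFrame(x, columns=[f"m{i}" for i in range(8)]))
        flags = flag_outlier_samples(panel)
        assert [f["sample_id"] for f in flags] == ["s11"]

    def test_all_na_sample_flagged_unconditionally(self):
        x = np.ones((6, 3))
        frame = pd.DataFrame(x, columns=["m1", "m2", "m3"])
        frame.iloc[2] = np.nan
        panel = make_panel(frame)
        flags = flag_outlier_samples(panel)
        assert any(f["sample_id"] == "s2" and f["reason"] == "all values missing"
                   for f in flags)

    def test_advisory_only_default_pipeline_keeps_all_samples(self):
        panel, _ = generate_panel(SimConfig(seed=0))
        clean, report = apply_filters(panel)
        # flagging never removes samples: cleaned panel keeps every row
        assert list(clean.sample_ids) == list(panel.sample_ids)
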