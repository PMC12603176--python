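import numpy as np
import pytest

from metaboruta import (
    ComparisonSpec,
    QCThresholds,
    SimConfig,
    apply_filters,
    fit_and_residualize,
    generate_panel,
)
from metaboruta.simulate import fixture_configs

# QC disabled where a test wants the generated panel untouched
NO_QC = QCThresholds(cv_max=None, lod_qc_rule=None, lod_sample_frac=None,
                     na_zero_frac=None)


@pytest.fixture(scope="session")
def strong_signal():
    """Strong-signal fixture panel (fold 3-4 planted effects) + truth."""
    cfg = fixture_configs(0)["strong_signal"]
    return generate_panel(cfg)


@pytest.fixture(scope="session")
def strong_signal_residuals(strong_signal):
    panel, truth = strong_signal
    clean, _ = apply_filters(panel, NO_QC)
    return fit_and_residualize(clean)


@pytest.fixture(scope="session")
def null_panel():
    cfg = fixture_configs(0)["null"]
    return generate_panel(cfg)


@pytest.fixture(scope="session")
def confounded():
    cfg = fixture_configs(0)["confounded"]
    return generate_panel(cfg)


@pytest.fixture()
def tiny_panel():
    """4 biological samples x 3 metabolites + 2 QC rows, handy for I/O."""
    import pandas as pd

    from metaboruta import MetabolitePanel

    ids = pd.Index(["s1", "s2", "s3", "s4", "q1", "q2"], name="sample_id")
    conc = pd.DataFrame(
        {
            "m1": [1.0, 2.0, 3.0, 4.0, 2.5, 2.6],
            "m2": [10.0, 12.0, 9.0, 11.0, 10.5, 10.4],
            "m3": [0.5, np.nan, 0.7, 0.9, 0.6, 0.65],
        },
        index=ids,
    )
    smeta = pd.DataFrame(
        {
            "group": ["A", "A", "B", "B", "QC", "QC"],
            "sex": ["M", "F", "M", "F", "NA", "NA"],
            "carcass_weight": [120.0, 125.0, 130.0, 122.0, np.nan, np.nan],
            "is_qc": [False, False, False, False, True, True],
        },
        index=ids,
    )
    mmeta = pd.DataFrame(
        {"analyte_class": ["AA", "AC", "SM"], "lod": [0.01, 0.1, 0.05]},
        index=pd.Index(["m1", "m2", "m3"], name="name"),
    )
    return MetabolitePanel(conc, smeta, mmeta)
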