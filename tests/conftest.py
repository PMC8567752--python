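import numpy as np
import pandas as pd
import pytest

from dcebrix.brix import BrixParams
from dcebrix.synthetic_data import SimulationConfig, generate_cohort

# printed group-median kinetic parameters used throughout the tests
RETU_MEDIANS = dict(A=2.126, kep=0.048, kel=4.48e-4)
PCR_MEDIANS = dict(A=1.967, kep=0.046, kel=-1.52e-4)


@pytest.fixture(scope="session")
def retu_params() -> BrixParams:
    return BrixParams(**RETU_MEDIANS)


@pytest.fixture(scope="session")
def pcr_params() -> BrixParams:
    return BrixParams(**PCR_MEDIANS)


@pytest.fixture(scope="session")
def cohort():
    """One default 22-patient cohort (15 pCR / 7 ReTu), seed 1."""
    return generate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def noiseless_cohort():
    return generate_cohort(SimulationConfig(seed=2, noise_sd_fraction=0.0))


@pytest.fixture(scope="session")
def feature_table(cohort):
    """Features + labels for the default cohort, via the full pipeline path."""
    from dcebrix.brix import fit_brix
    from dcebrix.features import compute_features
    from dcebrix.preprocess import preprocess_curve

    records, curves = cohort
    labels = {r.patient_id: r.label for r in records}
    conv = {r.patient_id: r.conventional for r in records}
    rows = []
    for curve in curves:
        nc = preprocess_curve(curve)
        p = fit_brix(nc.times, nc.enhancement)
        cf = compute_features(p, window_end=float(nc.times[-1]))
        row = {"patient_id": curve.patient_id, "A": p.A, "kep": p.kep,
               "kel": p.kel, "TTP": cf.TTP, "PE": cf.PE, "AUC": cf.AUC,
               "wash_in": cf.wash_in, "wash_out": cf.wash_out,
               "label": labels[curve.patient_id]}
        row.update(conv[curve.patient_id])
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
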