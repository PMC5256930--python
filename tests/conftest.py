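import numpy as np
import pytest
from scipy import stats

from citscreen import SyntheticConfig, generate


def ols_partial_f(y, tested, conditioning):
    """Brute-force partial F-test via explicit normal equations.

    Independent oracle for the regression battery: solves X'X b = X'y
    directly for the full and reduced designs and compares residual sums of
    squares on the F distribution.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    ones = np.ones((n, 1))
    X_full = np.hstack([ones, tested] + conditioning)
    X_red = np.hstack([ones] + conditioning)

    def ssr(X):
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        return float(resid @ resid)

    q = tested.shape[1]
    df_den = n - X_full.shape[1]
    f = ((ssr(X_red) - ssr(X_full)) / q) / (ssr(X_full) / df_den)
    return f, float(stats.f.sf(f, q, df_den))


def dip_design(dips, coding):
    dips = np.asarray(dips, dtype=object)
    if coding == "categorical":
        return np.column_stack(
            [(dips == "B/C").astype(float), (dips == "C/C").astype(float)]
        )
    return np.array([{"B/B": 0.0, "B/C": 1.0, "C/C": 2.0}[d] for d in dips]).reshape(-1, 1)


@pytest.fixture(scope="session")
def small_causal_frame():
    """A fixed 15-individual causal dataset (the study's design size)."""
    return generate(SyntheticConfig(architecture="causal", seed=42)).frame


@pytest.fixture(scope="session")
def large_causal_frame():
    return generate(SyntheticConfig(architecture="causal", n_sets=100, seed=7)).frame
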