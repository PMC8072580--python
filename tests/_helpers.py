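"""Shared test utilities: synthetic tables and independent OLS oracles."""

import numpy as np

from chromqsar.dataset import CompoundRecord, CompoundTable


def pinv_ols_oracle(X, y):
    """Independent normal-equations solve: beta and SEs via explicit pseudo-inverse."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    XtX_inv = np.linalg.pinv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    n, p1 = X.shape
    s2 = resid @ resid / (n - p1)
    se = np.sqrt(np.diag(XtX_inv) * s2)
    return beta, se


def synthetic_table(X, y, names, response="log_Kp"):
    """Wrap a raw design matrix and response vector as a CompoundTable."""
    X = np.atleast_2d(np.asarray(X, float))
    recs, derived = [], {n: {} for n in names if n not in ("mw", "tpsa", "alpha")}
    for i in range(len(y)):
        vals = dict(zip(names, X[i]))
        recs.append(CompoundRecord(f"s{i}", mw=vals.get("mw", 300.0),
                                   tpsa=vals.get("tpsa", 60.0),
                                   alpha=vals.get("alpha", 30.0),
                                   responses={response: float(y[i])}))
        for n in derived:
            derived[n][f"s{i}"] = float(vals[n])
    return CompoundTable(records=recs, derived_descriptors=derived)
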