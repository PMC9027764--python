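"""Thin linear epsilon-SVR wrapper.

The permutation loops refit thousands of tiny SVR models, so per-fit
estimator overhead dominates.  When available we call the libsvm binding
shipped with scikit-learn directly (same solver the public
``sklearn.svm.SVR`` wraps); the public estimator remains the fallback and
the reference the fast path is tested against.
"""

from __future__ import annotations

import numpy as np
from sklearn.svm import SVR

try:  # pragma: no cover - exercised indirectly
    from sklearn.svm import _libsvm

    _libsvm.set_verbosity_wrap(0)  # silence per-fit solver chatter
    _HAVE_LIBSVM = True
except (ImportError, AttributeError):  # pragma: no cover
    _HAVE_LIBSVM = False

__all__ = ["fit_linear_svr", "SVR_TOL"]

# fixed solver tolerance so leave-one-out results reproduce across runs
SVR_TOL = 1e-3


def _fit_public(X: np.ndarray, y: np.ndarray, C: float, epsilon: float):
    model = SVR(kernel="linear", C=C, epsilon=epsilon, tol=SVR_TOL)
    model.fit(X, y)
    w = model.coef_.ravel().copy()
    b = float(model.intercept_[0])
    return w, b


def fit_linear_svr(
    X: np.ndarray, y: np.ndarray, C: float = 1.0, epsilon: float = 0.1
) -> tuple[np.ndarray, float]:
    """Fit a linear epsilon-SVR; returns (weights, intercept).

    Predictions are ``X @ weights + intercept``, identical to
    ``sklearn.svm.SVR(kernel="linear").fit(X, y).predict(X)``.
    """
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64)
    if not _HAVE_LIBSVM:
        return _fit_public(X, y, C, epsilon)
    try:
        out = _libsvm.fit(
            X, y, svm_type=3, kernel="linear", C=C, epsilon=epsilon, tol=SVR_TOL
        )
    except TypeError:  # signature drift in a future sklearn
        return _fit_public(X, y, C, epsilon)
    support_vectors, dual_coef, intercept = out[1], out[3], out[4]
    w = dual_coef.ravel() @ support_vectors
    return np.asarray(w, dtype=float), float(intercept[0])
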