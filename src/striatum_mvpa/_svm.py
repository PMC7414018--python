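"""Low-level soft-margin linear SVM fits on precomputed Gram matrices.

The decoding analyses run tens of thousands of small binary SVM fits (one
per class pair, per leave-one-sample-out fold, per label permutation). At
these problem sizes the estimator-level ``sklearn.svm.SVC`` API spends most
of its wall time in input validation, so this module calls scikit-learn's
libsvm binding directly. The test suite asserts exact agreement with the
public ``SVC`` on decision values, weights and predictions.

Conventions
-----------
* Training rows for a class pair (i, j), i < j, are always ordered with all
  class-i rows first. libsvm treats the first label it encounters as the
  positive class, so decision values here are positive for class i.
* ``fit_gram`` consumes an (n, n) Gram matrix of the training rows;
  ``decision_gram`` consumes an (m, n) matrix of test-against-training inner
  products.
"""
from __future__ import annotations

import numpy as np
from sklearn.svm import _libsvm as _backend

_backend.set_verbosity_wrap(0)


# SMO iteration cap. Ordinary fits finish in O(10^3) iterations; the cap
# only bites on adversarial inputs (e.g. near-duplicate samples relabelled
# by a permutation), where libsvm would otherwise oscillate unboundedly.
MAX_ITER = 500_000


def fit_gram(gram: np.ndarray, labels: np.ndarray, cost: float):
    """Fit a binary C-SVC on a precomputed Gram matrix.

    ``labels`` must be float64; the first element's label is the positive
    class of the returned model's decision function.
    """
    gram = np.ascontiguousarray(gram, dtype=np.float64)
    labels = np.ascontiguousarray(labels, dtype=np.float64)
    out = _backend.fit(gram, labels, svm_type=0, kernel="precomputed",
                       C=float(cost), max_iter=MAX_ITER)
    # (support, SV, n_class_SV, sv_coef, intercept, probA, probB)
    return out[:7]


def decision_gram(gram_test: np.ndarray, model) -> np.ndarray:
    """Decision values (positive -> first training label) for test rows."""
    gram_test = np.ascontiguousarray(gram_test, dtype=np.float64)
    return _backend.decision_function(
        gram_test, *model, svm_type=0, kernel="precomputed"
    ).ravel()


def primal_weights(model, X_train: np.ndarray) -> tuple[np.ndarray, float]:
    """Recover (w, b) of the linear decision function w.x + b.

    ``X_train`` are the rows the Gram matrix was built from, in the same
    order. Positive decision means the first training label.
    """
    support, _, _, sv_coef, intercept = model[0], model[1], model[2], model[3], model[4]
    w = sv_coef[0] @ X_train[support]
    return w, float(intercept[0])
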