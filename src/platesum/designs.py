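"""Design-matrix helpers for one-way layouts."""

from __future__ import annotations

import numpy as np

__all__ = ["one_way_design"]


def one_way_design(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Intercept + treatment-coded indicator design for a one-way layout.

    Returns the ``n x G`` design matrix (intercept, then one indicator per
    non-reference group in first-appearance order) and the ordered group
    labels. The coefficient for column ``k >= 1`` is the log-scale
    difference of group ``k`` relative to the first group.
    """
    groups = np.asarray(groups)
    labels, first = np.unique(groups, return_index=True)
    labels = labels[np.argsort(first)]
    X = np.ones((groups.size, labels.size))
    for k, lab in enumerate(labels[1:], start=1):
        X[:, k] = (groups == lab).astype(float)
    return X, labels
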