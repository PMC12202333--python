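"""Correlation-based feature pruning.

Highly collinear entropy features carry no extra information for the
classifier; before each training fold, any feature whose absolute Pearson
correlation with an earlier-kept feature exceeds the threshold (default
0.98) is dropped.  The scan is greedy in column order, which makes the
kept set deterministic.  The caller must pass only *training* rows so the
kept-feature list never sees test data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .data import FeatureTable


@dataclass
class PruneReport:
    kept: list[str]
    dropped: list[tuple[str, str, float]] = field(default_factory=list)
    threshold: float = 0.98

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"threshold": self.threshold, "kept": self.kept,
                       "dropped": [list(d) for d in self.dropped]}, fh,
                      indent=2)


def correlation_matrix(table: FeatureTable) -> tuple[np.ndarray, list[str]]:
    """Pearson matrix over features: symmetric, unit diagonal, in [-1, 1].

    Constant (zero-variance) columns get zero off-diagonal entries rather
    than NaN.
    """
    X = table.X
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows for a correlation matrix")
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.atleast_2d(corr)
    constant = sd == 0
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    return corr, list(table.feature_names)


def correlation_prune(table: FeatureTable, threshold: float = 0.98,
                      ) -> tuple[FeatureTable, PruneReport]:
    """Drop features with |r| > threshold against an earlier kept feature.

    Constant columns are dropped with partner "constant".  Returns the
    pruned table and a :class:`PruneReport`.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    corr, names = correlation_matrix(table)
    sd = table.X.std(axis=0)

    kept_idx: list[int] = []
    report = PruneReport(kept=[], threshold=threshold)
    for j, name in enumerate(names):
        if sd[j] == 0:
            report.dropped.append((name, "constant", 0.0))
            continue
        partner = None
        for i in kept_idx:
            if abs(corr[i, j]) > threshold:
                partner = i
                break
        if partner is None:
            kept_idx.append(j)
        else:
            report.dropped.append((name, names[partner],
                                   float(corr[partner, j])))
    report.kept = [names[j] for j in kept_idx]
    return table.select_features(report.kept), report
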