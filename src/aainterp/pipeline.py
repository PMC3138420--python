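"""Dataset-level driver: sequences -> fixed-width feature matrix.

Each sequence is descriptor-encoded and then length-normalized to a common
target dimension, producing one matrix row per sequence — the standard
preprocessing loop that turns a variable-length sequence set into input for
a fixed-dimension classifier or regressor.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np

from .descriptors import (
    DEFAULT_DESCRIPTOR_INDEX,
    DescriptorDatabase,
    NormalizationMode,
)
from .encode import SequenceRecord, encode
from .interpolate import InterpolationMethod, resample

logger = logging.getLogger(__name__)

#: Warn when any sequence is stretched or squeezed by more than this factor;
#: normalizing to less than half the original length loses information, and
#: stretching short sequences is preferable to squeezing long ones.
STRETCH_WARN_RATIO = 2.0


@dataclass
class FeatureMatrix:
    """n_sequences x dims real matrix with per-row sequence identifiers."""

    row_ids: list[str]
    data: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D matrix")
        if len(self.row_ids) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.row_ids)} row ids for {self.data.shape[0]} rows"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("matrix entries must be finite")

    @property
    def dims(self) -> int:
        return self.data.shape[1]

    def __len__(self) -> int:
        return self.data.shape[0]


def default_dims(lengths: Sequence[int]) -> int:
    """Default target dimension: the rounded median input length."""
    return int(round(statistics.median(lengths)))


def build_matrix(
    records: Sequence[SequenceRecord],
    db: DescriptorDatabase,
    descriptor_index: int = DEFAULT_DESCRIPTOR_INDEX,
    dims: int | None = None,
    method: str | InterpolationMethod = InterpolationMethod.LINEAR,
    mode: NormalizationMode | int = NormalizationMode.NONE,
    residue_policy: str = "strict",
    *,
    clamp: bool = False,
    skip_errors: bool = False,
    coerce_periodic: bool = False,
) -> FeatureMatrix:
    """Encode every record and normalize it to ``dims`` values.

    Row i is ``resample(encode(records[i]), dims, method)``; row order
    follows input order and the result is deterministic.

    ``dims=None`` uses the rounded median input length (logged).  A warning
    is emitted if any sequence is stretched or squeezed by more than a
    factor of two.  ``clamp`` restricts rows to the normalization-mode
    interval, since cubic interpolation may overshoot the input range; the
    default leaves the interpolant untouched.  With ``skip_errors`` a
    per-sequence failure removes that row and is collected into
    ``metadata["skipped"]`` instead of aborting.
    """
    if not records:
        raise ValueError("no input sequences")
    method = InterpolationMethod.parse(method)
    mode = NormalizationMode.from_code(mode)
    lengths = [len(r) for r in records]
    if dims is None:
        dims = default_dims(lengths)
        logger.info("dims not given; using rounded median input length %d", dims)
    ratio = max(max(lengths) / dims, dims / min(lengths))
    if ratio > STRETCH_WARN_RATIO:
        logger.warning(
            "stretch/squeeze ratio %.2f exceeds %.1fx; normalization this "
            "strong loses positional information",
            ratio,
            STRETCH_WARN_RATIO,
        )

    rows: list[np.ndarray] = []
    ids: list[str] = []
    skipped: list[tuple[str, str]] = []
    for rec in records:
        try:
            enc = encode(rec, db, descriptor_index, mode, residue_policy)
            row = resample(
                enc.values, dims, method, coerce_periodic=coerce_periodic
            )
        except (ValueError, IndexError) as exc:
            if skip_errors:
                skipped.append((rec.id, str(exc)))
                logger.warning("skipping %r: %s", rec.id, exc)
                continue
            raise type(exc)(f"record {rec.id!r}: {exc}") from exc
        rows.append(row)
        ids.append(rec.id)
    if not rows:
        raise ValueError("all sequences failed; nothing to assemble")
    data = np.vstack(rows)
    if clamp and mode.interval is not None:
        lo, hi = mode.interval
        np.clip(data, lo, hi, out=data)
    logger.info(
        "built %dx%d matrix (descriptor %d, method %s, mode %s, %d skipped)",
        data.shape[0],
        data.shape[1],
        descriptor_index,
        method.value,
        mode.name.lower(),
        len(skipped),
    )
    meta: dict[str, Any] = {
        "descriptor_index": descriptor_index,
        "method": method.value,
        "mode": mode.value,
        "dims": dims,
    }
    if skipped:
        meta["skipped"] = skipped
    return FeatureMatrix(row_ids=ids, data=data, metadata=meta)


def _default_classifier():
    from sklearn.linear_model import LogisticRegression

    return LogisticRegression(max_iter=1000)


def demo_classification(
    matrix: FeatureMatrix,
    labels: Sequence[int],
    classifier: Callable[[], Any] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> dict[str, Any]:
    """Cross-validated binary classification on a feature matrix.

    ``classifier`` is a zero-argument factory returning a fresh scikit-learn
    style estimator (fit / predict_proba or decision_function); the default
    is logistic regression.  Scores are pooled out-of-fold predictions from
    a stratified ``folds``-fold split, and the AUC is the area under the ROC
    curve of those pooled scores (trapezoidal rule).  Honest cross-validation
    is used because resubstitution-style estimates overestimate performance.

    Returns a dict with ``auc``, ``roc`` (fpr, tpr arrays), ``scores`` and
    ``labels`` in input order.
    """
    from sklearn.metrics import auc as _trapezoid_auc
    from sklearn.metrics import roc_curve
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray(labels, dtype=int)
    if len(y) != len(matrix):
        raise ValueError(f"{len(y)} labels for {len(matrix)} rows")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    factory = classifier or _default_classifier
    X = matrix.data
    scores = np.empty(len(y), dtype=float)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train, test in cv.split(X, y):
        clf = factory()
        clf.fit(X[train], y[train])
        if hasattr(clf, "predict_proba"):
            s = clf.predict_proba(X[test])[:, 1]
        else:
            s = clf.decision_function(X[test])
        scores[test] = s
    fpr, tpr, _ = roc_curve(y, scores)
    return {
        "auc": float(_trapezoid_auc(fpr, tpr)),
        "roc": (fpr, tpr),
        "scores": scores,
        "labels": y,
        "folds": folds,
    }
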