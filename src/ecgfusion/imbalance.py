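"""Class rebalancing: SMOTE over-sampling, ENN cleaning, and their hybrid.

SMOTE brings every class up to the majority count by interpolating new
points on the segment between a minority sample and one of its k nearest
same-class neighbors (Euclidean, k = 5).  ENN then prunes any point whose
own label disagrees with the majority label among its k nearest neighbors
(k = 3, self excluded).  Applied to flattened feature-image vectors within
each training fold, never to held-out data.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ResampleSpec:
    smote_k: int = 5
    enn_k: int = 3
    seed: int = 0
    apply_within_fold: bool = True

    def __post_init__(self) -> None:
        if self.smote_k < 1 or self.enn_k < 1:
            raise ValueError("neighbor counts must be >= 1")


def smote(X: np.ndarray, y: np.ndarray, spec: ResampleSpec = ResampleSpec()):
    """Over-sample every minority class up to the majority count.

    Each synthetic point is ``x_i + u * (x_nn - x_i)`` with u ~ U[0, 1] and
    ``x_nn`` one of the ``smote_k`` nearest same-class neighbors of x_i.
    Original points are never altered.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    counts = Counter(y.tolist())
    n_major = max(counts.values())
    rng = np.random.default_rng(spec.seed)
    new_X, new_y = [X], [y]
    for cls in sorted(counts, key=str):
        n_c = counts[cls]
        deficit = n_major - n_c
        if deficit == 0:
            continue
        if n_c == 1:
            raise ValueError(
                f"class {cls!r} has a single member; lower k or merge classes"
            )
        k = spec.smote_k
        if n_c <= k:
            k = n_c - 1
            logger.warning("smote: class %r has %d members; reducing k to %d", cls, n_c, k)
        Xc = X[y == cls]
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        _, nbr = nn.kneighbors(Xc)  # column 0 is the point itself
        parents = rng.integers(0, n_c, size=deficit)
        picks = rng.integers(1, k + 1, size=deficit)
        u = rng.random(deficit)
        xi = Xc[parents]
        xn = Xc[nbr[parents, picks]]
        synth = xi + u[:, None] * (xn - xi)
        new_X.append(synth.astype(X.dtype))
        new_y.append(np.full(deficit, cls, dtype=y.dtype))
    return np.concatenate(new_X), np.concatenate(new_y)


def enn(X: np.ndarray, y: np.ndarray, spec: ResampleSpec = ResampleSpec()):
    """Single-pass edited-nearest-neighbors cleaning.

    A point is removed when the majority label among its ``enn_k`` nearest
    neighbors (self excluded) disagrees with its own; vote ties keep the
    point.  Never creates points.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if len(X) <= spec.enn_k:
        return X, y
    nn = NearestNeighbors(n_neighbors=spec.enn_k + 1).fit(X)
    _, nbr = nn.kneighbors(X)
    keep = np.ones(len(X), dtype=bool)
    for i in range(len(X)):
        votes = Counter(y[nbr[i, 1:]].tolist())
        (top, n_top), *rest = votes.most_common()
        if top != y[i] and (not rest or n_top > rest[0][1]):
            keep[i] = False
    return X[keep], y[keep]


def smote_enn(X: np.ndarray, y: np.ndarray, spec: ResampleSpec = ResampleSpec()):
    """SMOTE first, then ENN over the union of real and synthetic points.

    Guarantees that no input class is annihilated and that the imbalance
    ratio (max/min class count) does not increase; both violations raise.
    """
    classes_in = set(np.asarray(y).tolist())
    c0 = Counter(np.asarray(y).tolist())
    ratio_in = max(c0.values()) / min(c0.values())
    Xs, ys = smote(X, y, spec)
    Xc, yc = enn(Xs, ys, spec)
    c1 = Counter(yc.tolist())
    missing = classes_in - set(c1)
    if missing:
        raise RuntimeError(f"resampling annihilated class(es) {sorted(map(str, missing))}")
    ratio_out = max(c1.values()) / min(c1.values())
    if ratio_out > max(ratio_in, 1.0) + 1e-9:
        raise RuntimeError(
            f"imbalance ratio increased from {ratio_in:.3f} to {ratio_out:.3f}"
        )
    logger.info("smote_enn: counts before %s, after %s", dict(c0), dict(c1))
    return Xc, yc


def class_report(y_before: np.ndarray, y_after: np.ndarray) -> dict[str, tuple[int, int]]:
    """Per-class (before, after) counts, for balancing reports."""
    b = Counter(np.asarray(y_before).tolist())
    a = Counter(np.asarray(y_after).tolist())
    return {str(k): (b.get(k, 0), a.get(k, 0)) for k in sorted(set(b) | set(a), key=str)}
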