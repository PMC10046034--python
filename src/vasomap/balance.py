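"""Class balancing by synthetic minority over-sampling (SMOTE).

Two variants are provided:

* ``standard`` (default) — the classic interpolation rule: a synthetic
  sample is x + λ(x_nn − x) with λ ~ U[0, 1] and x_nn one of the k nearest
  minority neighbors of a randomly chosen minority point.
* ``weighted_accumulation`` — a convex-combination rule: a point and its k
  nearest minority neighbors are blended with random weights normalized to
  sum to one, so the synthetic sample lies in their convex hull.

Balancing a labeled feature table oversamples each class up to a common
target; synthetic rows are flagged ``source = "synthetic"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

VARIANTS = ("standard", "weighted_accumulation")


@dataclass(frozen=True)
class SmoteParams:
    k_neighbors: int = 5
    n_synthetic: Union[int, str] = "auto"  # "auto" = majority − minority
    variant: str = "standard"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if isinstance(self.n_synthetic, int) and self.n_synthetic < 0:
            raise ValueError("n_synthetic must be >= 0")


def n_to_generate(minority: int, majority: int) -> int:
    """Number of synthetic samples needed to balance minority to majority."""
    if minority > majority:
        raise ValueError("minority class is larger than majority class")
    return majority - minority


def smote(
    minority: np.ndarray,
    params: SmoteParams,
    n_synthetic: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Generate synthetic minority samples in feature space.

    ``n_synthetic`` overrides ``params.n_synthetic`` (which must then be an
    integer — "auto" is resolved by the caller who knows the majority
    size).  The minority set must be strictly larger than ``k_neighbors``.
    """
    X = np.asarray(minority, dtype=float)
    if X.ndim != 2:
        raise ValueError("minority must be a 2-D (n, p) array")
    if n_synthetic is None:
        if params.n_synthetic == "auto":
            raise ValueError("resolve n_synthetic='auto' before calling smote")
        n_synthetic = int(params.n_synthetic)
    if n_synthetic == 0:
        return np.empty((0, X.shape[1]))
    if X.shape[0] <= params.k_neighbors:
        raise ValueError(
            f"minority size {X.shape[0]} must exceed k_neighbors {params.k_neighbors}"
        )
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    k = params.k_neighbors
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)  # column 0 is the point itself
    neighbors = idx[:, 1:]

    base = rng.integers(0, X.shape[0], size=n_synthetic)
    out = np.empty((n_synthetic, X.shape[1]))
    if params.variant == "standard":
        pick = rng.integers(0, k, size=n_synthetic)
        lam = rng.uniform(0.0, 1.0, size=n_synthetic)
        nn_pts = X[neighbors[base, pick]]
        out[:] = X[base] + lam[:, None] * (nn_pts - X[base])
    else:  # weighted_accumulation
        for i, b in enumerate(base):
            group = np.concatenate([[b], neighbors[b]])
            w = rng.uniform(0.0, 1.0, size=k + 1)
            w /= w.sum()
            out[i] = w @ X[group]
    return out


def balance_classes(
    X: np.ndarray,
    y: np.ndarray,
    params: SmoteParams,
    rng: Optional[np.random.Generator] = None,
):
    """Oversample the minority class of a binary problem up to the majority
    size.  Returns (X_balanced, y_balanced, source) with synthetic rows
    flagged."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("balance_classes expects exactly two classes")
    minority_cls = classes[np.argmin(counts)]
    n_new = n_to_generate(counts.min(), counts.max())
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    synth = smote(X[y == minority_cls], params, n_synthetic=n_new, rng=rng)
    Xb = np.vstack([X, synth])
    yb = np.concatenate([y, np.full(len(synth), minority_cls, dtype=y.dtype)])
    source = np.array(["original"] * len(X) + ["synthetic"] * len(synth))
    return Xb, yb, source


def balance_to(
    n_per_class: int,
    features: pd.DataFrame,
    params: SmoteParams,
    label_col: str = "label",
    feature_cols: Optional[list] = None,
) -> pd.DataFrame:
    """Oversample every class of a labeled feature table to ``n_per_class``
    rows, so class counts are exactly equal afterwards."""
    if feature_cols is None:
        feature_cols = [c for c in features.columns if c not in (label_col, "source", "subject_id")]
    rng = np.random.default_rng(params.rng_seed)
    pieces = [features.assign(**{"source": features.get("source", "original")})]
    for cls, group in features.groupby(label_col, sort=True):
        if len(group) > n_per_class:
            raise ValueError(
                f"class {cls!r} already has {len(group)} > target {n_per_class} rows"
            )
        n_new = n_per_class - len(group)
        if n_new == 0:
            continue
        synth = smote(group[feature_cols].to_numpy(float), params, n_synthetic=n_new, rng=rng)
        piece = pd.DataFrame(synth, columns=feature_cols)
        piece[label_col] = cls
        piece["source"] = "synthetic"
        pieces.append(piece)
    out = pd.concat(pieces, ignore_index=True)
    return out
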