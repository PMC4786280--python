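"""Supervised self-organizing maps.

A SOM is a grid of codebook vectors trained by competitive learning: each
presented sample moves its best-matching unit (BMU) and that unit's grid
neighborhood toward itself, with learning rate and neighborhood radius
decaying over training.  Supervision enters only afterwards: units are
labeled by the majority group of the training samples they capture, and a
query is classified by its BMU's label.

Three codebook initializations are supported, mirroring the three ANN
screening variants:

* ``random``  — small random values (the toolbox default),
* ``minmax``  — units seeded from the two groups' per-feature minimum and
  maximum vectors, interleaved across the grid,
* ``mean``    — units seeded from the two group mean vectors with small
  jitter.

Inputs are z-scored with training statistics inside the model, so the grid
geometry is scale-free.  Training is fully deterministic under a fixed seed.
The per-sample update loop is compiled with numba when available; the pure
NumPy fallback performs the identical arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SOMModel", "som_train", "som_classify"]

INIT_SCHEMES = ("random", "minmax", "mean")

try:  # optional compiled inner loop
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _train_loop_py(codebook, X, order, lrs, sigma2s, grid_d2):
    n_units = codebook.shape[0]
    for step in range(len(order)):
        x = X[order[step]]
        d2 = ((codebook - x) ** 2).sum(axis=1)
        bmu = int(np.argmin(d2))
        h = np.exp(-grid_d2[bmu] / (2.0 * sigma2s[step]))
        codebook += lrs[step] * h[:, None] * (x - codebook)
    return codebook


if _HAVE_NUMBA:

    @njit(cache=False)
    def _train_loop_nb(codebook, X, order, lrs, sigma2s, grid_d2):  # pragma: no cover
        n_units, dim = codebook.shape
        for step in range(len(order)):
            xi = order[step]
            bmu = 0
            best = 1e300
            for u in range(n_units):
                d2 = 0.0
                for k in range(dim):
                    diff = codebook[u, k] - X[xi, k]
                    d2 += diff * diff
                if d2 < best:
                    best = d2
                    bmu = u
            lr = lrs[step]
            s2 = 2.0 * sigma2s[step]
            for u in range(n_units):
                h = lr * np.exp(-grid_d2[bmu, u] / s2)
                for k in range(dim):
                    codebook[u, k] += h * (X[xi, k] - codebook[u, k])
        return codebook


@dataclass
class SOMModel:
    """A trained supervised SOM: codebook, grid, unit labels, scaling."""

    codebook: np.ndarray  # (n_units, dim), standardized space
    grid_shape: tuple[int, int]
    unit_labels: np.ndarray  # (n_units,) of group strings
    init_scheme: str
    seed: int
    feature_mean: np.ndarray
    feature_std: np.ndarray

    @property
    def n_units(self) -> int:
        return self.codebook.shape[0]

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(X) - self.feature_mean) / self.feature_std


def _grid_positions(rows: int, cols: int) -> np.ndarray:
    jj, ii = np.meshgrid(np.arange(cols), np.arange(rows))
    return np.column_stack([ii.ravel(), jj.ravel()]).astype(np.float64)


def _init_codebook(
    scheme: str,
    n_units: int,
    Xs: np.ndarray,
    labels: np.ndarray,
    groups: tuple[str, str],
    rng: np.random.Generator,
) -> np.ndarray:
    dim = Xs.shape[1]
    if scheme == "random":
        return rng.normal(0.0, 0.1, size=(n_units, dim))
    g0, g1 = groups
    X0, X1 = Xs[labels == g0], Xs[labels == g1]
    if scheme == "minmax":
        anchors = np.vstack([
            X0.min(axis=0), X0.max(axis=0), X1.min(axis=0), X1.max(axis=0),
        ])
    elif scheme == "mean":
        anchors = np.vstack([X0.mean(axis=0), X1.mean(axis=0)])
    else:
        raise ValueError(f"init_scheme must be one of {INIT_SCHEMES}, got {scheme!r}")
    tiled = np.vstack([anchors] * (n_units // len(anchors) + 1))[:n_units]
    return tiled + rng.normal(0.0, 0.02, size=(n_units, dim))


def som_train(
    X: np.ndarray,
    labels: np.ndarray | list[str],
    grid: tuple[int, int] = (8, 8),
    init_scheme: str = "random",
    epochs: int = 200,
    seed: int = 0,
    lr_range: tuple[float, float] = (0.5, 0.01),
    groups: tuple[str, str] = ("control", "case"),
) -> SOMModel:
    """Train a supervised SOM on labeled two-group data.

    Learning rate and Gaussian neighborhood radius decay exponentially from
    their initial values (0.5 and half the larger grid side) to their floors
    (0.01 and 1) over ``epochs``; sample presentation order is reshuffled
    every epoch.  After training, each unit takes the majority label of the
    samples it captures; unitless labels are inherited from the nearest
    labeled unit on the grid (ties to the lower unit index).
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    present = set(labels.tolist())
    if not set(groups) <= present:
        missing = set(groups) - present
        raise ValueError(f"supervised SOM needs both groups in training data; missing {missing}")
    if init_scheme not in INIT_SCHEMES:
        raise ValueError(f"init_scheme must be one of {INIT_SCHEMES}, got {init_scheme!r}")
    rows, cols = grid
    n_units = rows * cols
    n, dim = X.shape
    if n < n_units / 4:
        import warnings

        warnings.warn(
            f"only {n} training samples for a {rows}x{cols} grid; "
            "codebook will be sparsely supported",
            stacklevel=2,
        )
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Xs = (X - mean) / std

    rng = np.random.default_rng(seed)
    codebook = _init_codebook(init_scheme, n_units, Xs, labels, groups, rng)

    pos = _grid_positions(rows, cols)
    grid_d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)

    total = epochs * n
    step = np.arange(total)
    frac = step / max(1, total - 1)
    lr0, lr1 = lr_range
    lrs = lr0 * (lr1 / lr0) ** frac
    sigma0 = max(rows, cols) / 2.0
    sigmas = sigma0 * (1.0 / sigma0) ** frac if sigma0 > 1 else np.ones(total)
    order = np.concatenate([rng.permutation(n) for _ in range(epochs)]).astype(np.int64)

    loop = _train_loop_nb if _HAVE_NUMBA else _train_loop_py
    codebook = loop(
        np.ascontiguousarray(codebook),
        np.ascontiguousarray(Xs),
        order,
        lrs,
        np.square(sigmas),
        grid_d2,
    )

    # majority-vote unit labeling
    d = ((Xs[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2)
    bmus = d.argmin(axis=1)
    unit_labels = np.array([""] * n_units, dtype=object)
    for u in range(n_units):
        got = labels[bmus == u]
        if got.size:
            c0 = int(np.count_nonzero(got == groups[0]))
            c1 = int(np.count_nonzero(got == groups[1]))
            # ties go to the case group: screening errs toward sensitivity
            unit_labels[u] = groups[0] if c0 > c1 else groups[1]
    labeled = np.flatnonzero(unit_labels != "")
    if labeled.size == 0:
        raise RuntimeError("no unit captured any training sample")
    for u in np.flatnonzero(unit_labels == ""):
        dg = ((pos[labeled] - pos[u]) ** 2).sum(axis=1)
        unit_labels[u] = unit_labels[labeled[int(np.argmin(dg))]]

    return SOMModel(
        codebook=codebook,
        grid_shape=grid,
        unit_labels=unit_labels.astype(str),
        init_scheme=init_scheme,
        seed=seed,
        feature_mean=mean,
        feature_std=std,
    )


def som_classify(x: np.ndarray, model: SOMModel) -> str:
    """Label of the best-matching unit (ties to the lowest unit index)."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.shape[0] != model.codebook.shape[1]:
        raise ValueError(
            f"query has shape {x.shape}, model expects ({model.codebook.shape[1]},)"
        )
    xs = model.standardize(x)[0]
    d2 = ((model.codebook - xs) ** 2).sum(axis=1)
    return str(model.unit_labels[int(np.argmin(d2))])
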