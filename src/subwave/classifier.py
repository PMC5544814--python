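"""Nearest-subspace (SVD) classification of complex feature vectors.

Each class c is modeled as

    x_{c,i} = U_c alpha_c(i) + e_c,

i.e. the class's observations lie near a low-dimensional complex linear
subspace spanned by the orthonormal columns of U_c (the leading left
singular vectors of the class data matrix with observations as columns);
e_c is additive white noise.  A new observation x is assigned to the class
with the smallest orthogonal-projection residual

    d_c = || x - U_c U_c^H x ||_2 ,

ties broken towards the lowest class index.  By default the subspace
dimension m_c is one less than the class training count, i.e. U_c spans
(numerically) the whole class training set and d_c measures the distance to
that span.  This is the right regime for helmet data, where the dominant
within-class variability (head size, helmet rotation, CSF thickness) is
orders of magnitude stronger than the between-class lesion signature: a
truncated basis absorbs only the shared variability and leaves every class
with the same residual, while the full span keeps the class-specific fine
structure that separates bleeding sizes.  An energy-threshold rule
(smallest m_c capturing a given fraction of the class training energy) and
fixed dimensions are available as options.

The module follows the Model/Results convention: build a
:class:`NearestSubspaceModel` from data, call :meth:`fit` to obtain a
:class:`NearestSubspaceResults` carrying the bases, retained singular values
and a ``summary()`` table, and use the results object to compute distances
and predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import h5py
import numpy as np

__all__ = [
    "NearestSubspaceModel",
    "NearestSubspaceResults",
    "ClassificationResult",
    "fit_subspace",
    "subspace_distance",
    "classify",
]


def fit_subspace(class_data: np.ndarray, m_c: int) -> np.ndarray:
    """Orthonormal basis (D, m_c) of the leading left singular vectors.

    ``class_data`` holds observations as rows (n, D); the basis spans the
    dominant directions of the observation space (columns of the transposed
    data matrix).  Deterministic up to a per-column unit phase, which leaves
    projections (and hence distances) invariant.
    """
    A = np.asarray(class_data, dtype=complex)
    if A.ndim != 2 or len(A) == 0:
        raise ValueError("class_data must be a non-empty (n, D) array")
    n, dim = A.shape
    if not (1 <= m_c <= min(n, dim)):
        raise ValueError(f"m_c={m_c} out of range for {n} x {dim} class data")
    if not np.any(A):
        raise np.linalg.LinAlgError("degenerate (all-zero) class data")
    # economy SVD of the row matrix A = W S Vh.  The class data matrix with
    # observations as columns is the plain transpose A^T = conj(V) S W^T, so
    # its left singular vectors are the columns of conj(V) = vh^T (no extra
    # conjugation -- conj(V) spans the rows of A, V itself spans their
    # conjugates).
    _, s, vh = np.linalg.svd(A, full_matrices=False)
    if s[m_c - 1] <= 0:
        raise np.linalg.LinAlgError("requested dimension exceeds numerical rank")
    return vh[:m_c].T


def subspace_distance(x: np.ndarray, basis: np.ndarray) -> float:
    """Euclidean residual of the orthogonal projection of ``x`` onto the basis."""
    x = np.asarray(x, dtype=complex).ravel()
    U = np.asarray(basis, dtype=complex)
    if U.shape[0] != x.shape[0]:
        raise ValueError(f"dimension mismatch: x has {x.shape[0]}, basis {U.shape[0]}")
    coeff = U.conj().T @ x
    return float(np.linalg.norm(x - U @ coeff))


@dataclass
class ClassificationResult:
    """Predicted class and the full distance vector d_1..d_C."""

    predicted: int
    distances: np.ndarray

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if self.predicted != int(np.argmin(self.distances)):
            raise ValueError("predicted class must be the argmin distance")


class NearestSubspaceModel:
    """Multi-class subspace model of complex feature vectors.

    Parameters
    ----------
    X : (N, D) complex array, observations as rows.
    y : (N,) int class labels, 0..C-1.
    class_names : optional class label strings.
    """

    def __init__(self, X, y, class_names=None):
        self.X = np.asarray(X, dtype=complex)
        self.y = np.asarray(y, dtype=int)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X must be (N, D) with matching y")
        self.classes_ = np.unique(self.y)
        if class_names is None:
            class_names = [f"class{c}" for c in self.classes_]
        self.class_names = list(class_names)

    @classmethod
    def from_dataset(cls, dataset) -> "NearestSubspaceModel":
        """Build from a :class:`subwave.dataset.LabeledDataset`."""
        return cls(dataset.X, dataset.y, class_names=dataset.class_names)

    def fit(
        self,
        m: int | dict | None = None,
        energy: float | None = None,
        center: bool = False,
        normalize: bool = False,
    ) -> "NearestSubspaceResults":
        """Fit per-class orthonormal bases.

        ``m`` fixes the subspace dimension (int, or dict class->int);
        ``energy`` selects the smallest dimension capturing that fraction of
        the class training energy instead.  With neither given, m_c defaults
        to the class training count minus one (the full class span).  All
        rules cap m_c at count - 1 and at the feature dimension.  ``center``
        and ``normalize`` are off by default (no preprocessing of the raw
        vectors).
        """
        if m is not None and energy is not None:
            raise ValueError("give at most one of m and energy")
        X = self.X
        mean = np.zeros(X.shape[1], dtype=complex)
        if center:
            mean = X.mean(axis=0)
            X = X - mean
        if normalize:
            norms = np.linalg.norm(X, axis=1, keepdims=True)
            X = X / np.where(norms > 0, norms, 1.0)

        bases: dict[int, np.ndarray] = {}
        sing: dict[int, np.ndarray] = {}
        dims: dict[int, int] = {}
        for c in self.classes_:
            A = X[self.y == c]
            n = len(A)
            _, s, vh = np.linalg.svd(A, full_matrices=False)
            if m is not None:
                mc = m[c] if isinstance(m, dict) else int(m)
                if not (1 <= mc <= min(A.shape)):
                    raise ValueError(f"m={mc} out of range for class {c}")
            elif energy is not None:
                e = np.cumsum(s**2) / np.sum(s**2)
                mc = int(np.searchsorted(e, energy - 1e-12) + 1)
                mc = max(1, min(mc, n - 1 if n > 1 else 1, A.shape[1]))
            else:
                # span rule: all of the class training span
                mc = max(1, min(n - 1 if n > 1 else 1, A.shape[1]))
            bases[int(c)] = vh[:mc].T
            sing[int(c)] = s
            dims[int(c)] = mc
        return NearestSubspaceResults(
            model=self, bases=bases, singular_values=sing, dims=dims,
            energy=energy, fixed_m=m, mean=mean,
            center=center, normalize=normalize,
        )


class NearestSubspaceResults:
    """Fitted per-class bases with distance/prediction machinery."""

    def __init__(
        self, model, bases, singular_values, dims, energy, fixed_m, mean,
        center=False, normalize=False,
    ):
        self.model = model
        self.bases = bases
        self.singular_values = singular_values
        self.dims = dims
        self.energy = energy
        self.fixed_m = fixed_m
        self.mean = mean
        self.center = center
        self.normalize = normalize
        self.classes_ = sorted(bases)
        self.class_names = model.class_names if model is not None else [
            f"class{c}" for c in self.classes_
        ]

    # -- inference ----------------------------------------------------------

    def _prep(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=complex))
        if self.center:
            X = X - self.mean
        if self.normalize:
            norms = np.linalg.norm(X, axis=1, keepdims=True)
            X = X / np.where(norms > 0, norms, 1.0)
        return X

    def distances(self, X) -> np.ndarray:
        """(N, C) projection residuals d_c = ||x - U_c U_c^H x||."""
        X = self._prep(X)
        out = np.empty((len(X), len(self.classes_)))
        for k, c in enumerate(self.classes_):
            U = self.bases[c]
            coeff = X @ U.conj()  # rows are (U^H x)^T
            resid = X - coeff @ U.T
            out[:, k] = np.linalg.norm(resid, axis=1)
        return out

    def predict(self, X) -> np.ndarray:
        """Class of minimal distance per row; ties -> lowest class index."""
        d = self.distances(X)
        return np.asarray(self.classes_)[np.argmin(d, axis=1)]

    def classify_one(self, x) -> ClassificationResult:
        d = self.distances(np.atleast_2d(x))[0]
        return ClassificationResult(predicted=int(np.asarray(self.classes_)[np.argmin(d)]), distances=d)

    # -- reporting ------------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Nearest-subspace classification model",
            "=" * 64,
            f"{'class':<16}{'n_train':>8}{'m_c':>6}{'energy@m_c':>12}{'sigma_1':>12}",
            "-" * 64,
        ]
        for k, c in enumerate(self.classes_):
            s = self.singular_values[c]
            e = float(np.sum(s[: self.dims[c]] ** 2) / np.sum(s**2))
            n = len(s)
            name = self.class_names[k] if k < len(self.class_names) else str(c)
            lines.append(
                f"{name:<16}{n:>8}{self.dims[c]:>6}{e:>12.4f}{s[0]:>12.4g}"
            )
        lines.append("-" * 64)
        if self.fixed_m is not None:
            rule = f"fixed m = {self.fixed_m}"
        elif self.energy is not None:
            rule = f"smallest m with >= {self.energy:.0%} energy, capped at n-1"
        else:
            rule = "full class span (m = n - 1)"
        lines.append(f"dimension rule: {rule}")
        lines.append(f"preprocessing: center={self.center}, normalize={self.normalize}")
        return "\n".join(lines)

    # -- persistence ------------------------------------------------------------

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["energy"] = self.energy if self.energy is not None else -1.0
            f.attrs["center"] = self.center
            f.attrs["normalize"] = self.normalize
            f.attrs["class_names"] = json.dumps(self.class_names)
            f.create_dataset("mean", data=self.mean)
            for c in self.classes_:
                g = f.create_group(f"class_{c}")
                g.create_dataset("basis", data=self.bases[c])
                g.create_dataset("singular_values", data=self.singular_values[c])
                g.attrs["m_c"] = self.dims[c]

    @classmethod
    def load(cls, path) -> "NearestSubspaceResults":
        with h5py.File(path, "r") as f:
            bases, sing, dims = {}, {}, {}
            for key in f:
                if not key.startswith("class_"):
                    continue
                c = int(key.split("_")[1])
                bases[c] = f[key]["basis"][:]
                sing[c] = f[key]["singular_values"][:]
                dims[c] = int(f[key].attrs["m_c"])
            energy = float(f.attrs["energy"])
            res = cls(
                model=None, bases=bases, singular_values=sing, dims=dims,
                energy=energy if energy >= 0 else None, fixed_m=None,
                mean=f["mean"][:],
                center=bool(f.attrs["center"]), normalize=bool(f.attrs["normalize"]),
            )
            res.class_names = json.loads(f.attrs["class_names"])
        return res


def classify(x: np.ndarray, results: NearestSubspaceResults) -> ClassificationResult:
    """Functional form of single-observation classification."""
    return results.classify_one(x)
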