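"""Discriminant spatial-pattern feature extraction.

Two backends fit the projection from class-labeled vectorized trials:

``classic``
    Solves the generalized eigenproblem ``S_B w = lambda (S_W + r I) w``
    via symmetric whitening of the regularized within-class scatter, so
    the spectrum is real by construction. Serves as the reference oracle.

``improved``
    Closed-form per-class directions ``w_j = (S_W + r I)^{-1} n_j (M_j - M)``
    (one column per class). For two classes each column is proportional
    to the Fisher discriminant direction. No eigendecomposition is
    needed, and the solve can be done matrix-free from the centered data
    (Woodbury identity), which is essential when ``D = N * T'`` is in the
    tens of thousands.

The ridge ``r = gamma * mean(diag(S_W))`` keeps both backends well posed
when ``n < D`` (always the case for high-density ERP features).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.linalg

from .data_model import EpochSet

__all__ = [
    "VectorizedTrials",
    "ScatterSet",
    "DspModel",
    "vectorize",
    "devectorize",
    "scatter_matrices",
    "fisher_criterion",
    "ridge_solve_lowrank",
    "dsp_classic",
    "dsp_improved",
    "transform",
    "save_model",
    "load_model",
]

#: materialize DxD scatter matrices only below this dimensionality
DENSE_D_LIMIT = 2000


@dataclass
class VectorizedTrials:
    """Trials flattened to vectors (row-major, channel-major).

    ``vectors`` is ``n x D`` with ``D = N * T'``; row ``i`` is trial ``i``'s
    channel time-courses concatenated in channel order.
    """

    vectors: np.ndarray
    labels: list
    dims: tuple  # (N, T')
    band_tag: str = "raw"

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be 2-D (trials x D)")
        N, Tp = self.dims
        if self.vectors.shape[1] != N * Tp:
            raise ValueError(
                f"D = {self.vectors.shape[1]} does not equal "
                f"N*T' = {N}*{Tp} = {N * Tp}"
            )
        if len(self.labels) != self.vectors.shape[0]:
            raise ValueError("labels and vectors must align")

    @property
    def n_trials(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_features(self) -> int:
        return self.vectors.shape[1]

    @property
    def class_order(self) -> list:
        seen: dict = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return list(seen)

    @property
    def class_sizes(self) -> dict:
        sizes: dict = {}
        for lab in self.labels:
            sizes[lab] = sizes.get(lab, 0) + 1
        return sizes


def vectorize(epochs: EpochSet) -> VectorizedTrials:
    """Flatten every trial matrix into a vector (inverse: :func:`devectorize`)."""
    if epochs.n_trials == 0:
        raise ValueError("cannot vectorize an empty EpochSet")
    N, Tp = epochs.trials[0].shape
    vectors = np.stack([t.reshape(-1) for t in epochs.trials])
    return VectorizedTrials(
        vectors=vectors, labels=list(epochs.labels), dims=(N, Tp),
        band_tag=epochs.band_tag,
    )


def devectorize(vector: np.ndarray, dims) -> np.ndarray:
    """Reshape a flat trial vector back into its channels x samples matrix."""
    N, Tp = dims
    return np.asarray(vector).reshape(N, Tp)


@dataclass
class ScatterSet:
    """Class means, grand mean and (possibly implicit) scatter matrices.

    ``s_w``/``s_b`` are dense ``D x D`` arrays when materialized, else
    ``None``; the within-class-centered data matrix ``centered`` (n x D)
    is always kept so large-D solves can use the low-rank route.
    """

    class_order: list
    class_sizes: np.ndarray          # n_j aligned with class_order
    class_means: np.ndarray          # K x D
    grand_mean: np.ndarray           # D
    centered: np.ndarray             # n x D, X_i - M_{class(i)}
    reg_gamma: float
    dims: tuple
    s_w: np.ndarray | None = None
    s_b: np.ndarray | None = None

    @property
    def n_classes(self) -> int:
        return len(self.class_order)

    @property
    def n_trials(self) -> int:
        return int(self.class_sizes.sum())

    @property
    def n_features(self) -> int:
        return self.grand_mean.shape[0]

    @property
    def mean_diag_sw(self) -> float:
        """mean(diag(S_W)) = ||centered||_F^2 / D, no D x D needed."""
        return float(np.sum(self.centered ** 2)) / self.n_features

    @property
    def ridge(self) -> float:
        return self.reg_gamma * self.mean_diag_sw

    def class_offsets(self) -> np.ndarray:
        """n_j * (M_j - M) per class, stacked K x D."""
        return self.class_sizes[:, None] * (self.class_means - self.grand_mean)


def scatter_matrices(v: VectorizedTrials, reg_gamma: float = 1e-3,
                     materialize: bool | None = None) -> ScatterSet:
    """Compute within/between-class scatter statistics.

    ``S_W = sum_j sum_i (x - M_j)(x - M_j)^T`` and
    ``S_B = sum_j n_j (M_j - M)(M_j - M)^T``. The ridge coefficient is
    stored but not applied here. With ``materialize=False`` (automatic
    for ``D > 2000``) the dense matrices are never formed.
    """
    labels = np.asarray(v.labels, dtype=object)
    class_order = v.class_order
    if len(class_order) < 2:
        raise ValueError(
            "need at least 2 classes for discriminant scatter; got "
            f"{class_order}"
        )
    X = v.vectors
    n, D = X.shape
    if materialize is None:
        materialize = D <= DENSE_D_LIMIT

    sizes = np.array([int(np.sum(labels == c)) for c in class_order])
    means = np.stack([X[labels == c].mean(axis=0) for c in class_order])
    grand = X.mean(axis=0)

    centered = X.copy()
    for j, c in enumerate(class_order):
        centered[labels == c] -= means[j]

    s_w = s_b = None
    if materialize:
        s_w = centered.T @ centered
        diffs = means - grand
        s_b = (sizes[:, None] * diffs).T @ diffs

    return ScatterSet(
        class_order=class_order, class_sizes=sizes, class_means=means,
        grand_mean=grand, centered=centered, reg_gamma=float(reg_gamma),
        dims=v.dims, s_w=s_w, s_b=s_b,
    )


def fisher_criterion(W: np.ndarray, s: ScatterSet) -> float:
    """Determinant-ratio discriminability of a projection ``W`` (D x m).

    ``J(W) = det(W^T S_B W) / det(W^T (S_W + r I) W)`` with the stored
    ridge ``r``.
    """
    W = np.atleast_2d(np.asarray(W, dtype=np.float64))
    if W.shape[0] != s.n_features:
        W = W.T
    if s.s_w is None or s.s_b is None:
        raise ValueError("fisher_criterion needs materialized scatter matrices")
    r = s.ridge
    num = np.linalg.det(W.T @ s.s_b @ W)
    den = np.linalg.det(W.T @ (s.s_w + r * np.eye(s.n_features)) @ W)
    if not np.isfinite(den) or abs(den) < 1e-300:
        raise np.linalg.LinAlgError(
            "projected within-class scatter is singular; increase reg_gamma"
        )
    return float(num / den)


def ridge_solve_lowrank(centered: np.ndarray, ridge: float,
                        B: np.ndarray) -> np.ndarray:
    """Solve ``(centered^T centered + ridge I) X = B`` without forming D x D.

    Uses the Woodbury identity with the ``n x n`` Gram matrix of the
    centered data; cost is ``O(n^2 D + n^3)``.
    """
    if ridge <= 0:
        raise ValueError("ridge must be positive for the low-rank solve")
    B = np.atleast_2d(np.asarray(B, dtype=np.float64))
    transposed = False
    if B.shape[0] != centered.shape[1]:
        B = B.T
        transposed = True
    n = centered.shape[0]
    gram = centered @ centered.T
    gram[np.diag_indices(n)] += ridge
    cho = scipy.linalg.cho_factor(gram, lower=True)
    CB = centered @ B                       # n x k
    Y = scipy.linalg.cho_solve(cho, CB)     # n x k
    X = (B - centered.T @ Y) / ridge
    return X.T if transposed else X


def _finalize_columns(W: np.ndarray) -> np.ndarray:
    """Unit-normalize columns and fix sign: largest-|.| entry positive."""
    W = np.array(W, dtype=np.float64)
    for j in range(W.shape[1]):
        nrm = np.linalg.norm(W[:, j])
        if nrm == 0:
            raise np.linalg.LinAlgError(f"direction {j} collapsed to zero")
        W[:, j] /= nrm
        i = int(np.argmax(np.abs(W[:, j])))
        if W[i, j] < 0:
            W[:, j] = -W[:, j]
    return W


@dataclass
class DspModel:
    """Fitted projection: ``z = W1^T x + delta`` with ``delta = -W1^T M``."""

    W1: np.ndarray               # D x m
    delta: np.ndarray            # m
    grand_mean: np.ndarray       # D
    dims: tuple                  # (N, T')
    backend: str                 # "improved" | "classic"
    reg_gamma: float
    class_order: list = field(default_factory=list)
    eigenvalues: np.ndarray | None = None
    band_tag: str = "raw"

    @property
    def n_components(self) -> int:
        return self.W1.shape[1]


def dsp_classic(s: ScatterSet, m: int = 1) -> DspModel:
    """Top-``m`` generalized eigenvectors of ``(S_B, S_W + r I)``.

    Computed by symmetric whitening (eigendecompose the regularized
    ``S_W``, whiten ``S_B``, eigendecompose the whitened matrix), which
    guarantees a real spectrum.
    """
    if s.s_w is None or s.s_b is None:
        raise ValueError(
            "classic backend needs materialized scatter matrices "
            "(refit with materialize=True or reduce D)"
        )
    D = s.n_features
    if not 1 <= m <= D:
        raise ValueError(f"m must be in [1, {D}], got {m}")
    r = s.ridge
    if r <= 0:
        w_vals = np.linalg.eigvalsh(s.s_w)
        if w_vals[0] <= 1e-12 * max(w_vals[-1], 1.0):
            raise np.linalg.LinAlgError(
                "S_W is singular and reg_gamma is 0; set reg_gamma > 0"
            )
    vals, U = np.linalg.eigh(s.s_w + r * np.eye(D))
    whiten = U * (1.0 / np.sqrt(vals))           # D x D, S_W^{-1/2}
    A = whiten.T @ s.s_b @ whiten
    A = 0.5 * (A + A.T)
    evals, V = np.linalg.eigh(A)
    order = np.argsort(evals)[::-1][:m]
    W1 = _finalize_columns(whiten @ V[:, order])
    return DspModel(
        W1=W1, delta=-W1.T @ s.grand_mean, grand_mean=s.grand_mean.copy(),
        dims=s.dims, backend="classic", reg_gamma=s.reg_gamma,
        class_order=list(s.class_order), eigenvalues=evals[order],
        band_tag="raw",
    )


def dsp_improved(s: ScatterSet, method: str = "auto") -> DspModel:
    """Closed-form discriminant directions, one column per class.

    ``w_j = (S_W + r I)^{-1} n_j (M_j - M)``, unit-normalized, columns in
    class order. ``method`` selects the solve route: ``"dense"`` forms
    the regularized scatter explicitly, ``"lowrank"`` uses the Woodbury
    identity on the centered data, ``"auto"`` picks low-rank when the
    dense matrices were not materialized.
    """
    if method not in ("auto", "dense", "lowrank"):
        raise ValueError(f"unknown method {method!r}")
    if method == "auto":
        method = "dense" if s.s_w is not None else "lowrank"
    r = s.ridge
    if r <= 0:
        raise ValueError("dsp_improved requires reg_gamma > 0")
    B = s.class_offsets().T                      # D x K
    if method == "dense":
        if s.s_w is None:
            raise ValueError("dense solve requested but S_W not materialized")
        try:
            W = scipy.linalg.solve(
                s.s_w + r * np.eye(s.n_features), B, assume_a="pos",
            )
        except scipy.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"regularized within-class solve failed ({exc}); "
                "increase reg_gamma"
            ) from exc
    else:
        W = ridge_solve_lowrank(s.centered, r, B)
    W1 = _finalize_columns(W)
    return DspModel(
        W1=W1, delta=-W1.T @ s.grand_mean, grand_mean=s.grand_mean.copy(),
        dims=s.dims, backend="improved", reg_gamma=s.reg_gamma,
        class_order=list(s.class_order), eigenvalues=None,
        band_tag="raw",
    )


def transform(model: DspModel, v: VectorizedTrials):
    """Project trials into feature space: ``z_i = W1^T x_i + delta``.

    ``delta`` was frozen from the fitting data's grand mean, so applying
    the model to held-out trials does not leak test statistics.
    """
    from .selection import FeatureTable

    if v.n_features != model.W1.shape[0]:
        raise ValueError(
            f"trial dimension {v.n_features} does not match model "
            f"dimension {model.W1.shape[0]}"
        )
    Z = v.vectors @ model.W1 + model.delta
    provenance = [(v.band_tag, j) for j in range(model.n_components)]
    return FeatureTable(
        matrix=Z, labels=list(v.labels), feature_provenance=provenance,
    )


def save_model(model: DspModel, path) -> Path:
    """Serialize a fitted model to a flat JSON bundle."""
    path = Path(path)
    payload = {
        "schema": "dspline-model-1",
        "backend": model.backend,
        "dims": list(model.dims),
        "reg_gamma": model.reg_gamma,
        "class_order": list(model.class_order),
        "band_tag": model.band_tag,
        "W1": model.W1.tolist(),
        "delta": model.delta.tolist(),
        "grand_mean": model.grand_mean.tolist(),
        "eigenvalues": (
            model.eigenvalues.tolist() if model.eigenvalues is not None else None
        ),
    }
    path.write_text(json.dumps(payload))
    return path


def load_model(path) -> DspModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema") != "dspline-model-1":
        raise ValueError(f"unrecognized model file: {path}")
    eig = payload["eigenvalues"]
    return DspModel(
        W1=np.asarray(payload["W1"], dtype=np.float64),
        delta=np.asarray(payload["delta"], dtype=np.float64),
        grand_mean=np.asarray(payload["grand_mean"], dtype=np.float64),
        dims=tuple(payload["dims"]),
        backend=payload["backend"],
        reg_gamma=float(payload["reg_gamma"]),
        class_order=list(payload["class_order"]),
        eigenvalues=None if eig is None else np.asarray(eig, dtype=np.float64),
        band_tag=payload.get("band_tag", "raw"),
    )
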