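"""Signal normalization and online dictionary learning with L1 sparse coding.

Factorizes a t x n signal matrix X into an over-complete temporal basis
D (atom norms bounded by 1) and a sparse coefficient matrix alpha by
minimizing ``0.5 * ||X - D @ alpha||_F^2 + lam * sum(|alpha|)`` with an
online mini-batch learner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import sparse_encode

__all__ = [
    "SignalMatrix",
    "Dictionary",
    "SparseCodes",
    "normalize_signals",
    "sparse_code",
    "sparse_code_matrix",
    "learn_dictionary",
    "objective",
    "reconstruct",
]

ATOM_NORM_TOL = 1e-9


@dataclass
class SignalMatrix:
    """Column-normalized signals: each column has mean 0 and population sd 1."""

    X: np.ndarray  # (t, n)
    vertex_ids: np.ndarray  # (n,) identifiers of retained columns
    excluded_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.intp))

    @property
    def t(self) -> int:
        return self.X.shape[0]

    @property
    def n(self) -> int:
        return self.X.shape[1]


@dataclass
class Dictionary:
    D: np.ndarray  # (t, m)
    learn_params: dict = field(default_factory=dict)

    @property
    def m(self) -> int:
        return self.D.shape[1]

    def validate(self) -> None:
        norms = np.linalg.norm(self.D, axis=0)
        if np.any(norms > 1.0 + ATOM_NORM_TOL):
            raise ValueError("atom norm exceeds the unit-ball constraint")


@dataclass
class SparseCodes:
    alpha: np.ndarray  # (m, n)
    lam: float

    @property
    def m(self) -> int:
        return self.alpha.shape[0]

    @property
    def n(self) -> int:
        return self.alpha.shape[1]


def normalize_signals(X: np.ndarray, vertex_ids: np.ndarray | None = None) -> SignalMatrix:
    """Center each column and scale by its population (1/t) standard deviation.

    Zero-variance columns cannot be normalized; they are dropped from the
    returned matrix and their ids recorded in ``excluded_ids``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2D matrix with at least 2 timepoints")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite entries in signal matrix")
    if vertex_ids is None:
        vertex_ids = np.arange(X.shape[1], dtype=np.intp)
    vertex_ids = np.asarray(vertex_ids)

    sd = X.std(axis=0)  # population sd
    keep = sd > 0
    if not keep.any():
        raise ValueError("all columns have zero variance")
    Xn = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    return SignalMatrix(X=Xn, vertex_ids=vertex_ids[keep], excluded_ids=vertex_ids[~keep])


def _check_dims(x: np.ndarray, D: np.ndarray) -> None:
    if x.shape[0] != D.shape[0]:
        raise ValueError(f"signal length {x.shape[0]} != atom length {D.shape[0]}")


def sparse_code_matrix(X: np.ndarray, D: np.ndarray, lam: float,
                       max_iter: int = 2000) -> np.ndarray:
    """Lasso-code every column of X against D; returns alpha of shape (m, n).

    Solves ``argmin_a 0.5 * ||x - D a||_2^2 + lam * ||a||_1`` per column by
    coordinate descent (least squares when ``lam == 0``).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    D = np.asarray(D, dtype=float)
    _check_dims(X, D)
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite signal")
    if lam == 0:
        return np.linalg.lstsq(D, X, rcond=None)[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        alpha = sparse_encode(
            X.T, D.T, algorithm="lasso_cd", alpha=lam,
            max_iter=max_iter, positive=False,
        )
    return alpha.T


def sparse_code(x: np.ndarray, D: Dictionary | np.ndarray, lam: float) -> np.ndarray:
    """L1-regularized code of a single signal: length-m coefficient vector."""
    Dmat = D.D if isinstance(D, Dictionary) else np.asarray(D, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be a 1D signal")
    return sparse_code_matrix(x[:, None], Dmat, lam)[:, 0]


def objective(X: np.ndarray, D: np.ndarray, alpha: np.ndarray, lam: float) -> float:
    """``0.5 * ||X - D @ alpha||_F^2 + lam * sum(|alpha|)``."""
    X = np.asarray(X, dtype=float)
    D = np.asarray(D, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if D.shape[1] != alpha.shape[0] or X.shape != (D.shape[0], alpha.shape[1]):
        raise ValueError("inconsistent shapes")
    resid = X - D @ alpha
    return 0.5 * float(np.sum(resid ** 2)) + lam * float(np.abs(alpha).sum())


def reconstruct(D: np.ndarray | Dictionary, alpha: np.ndarray | SparseCodes) -> np.ndarray:
    """Matrix product ``D @ alpha``: reconstructed signals, one per column."""
    Dmat = D.D if isinstance(D, Dictionary) else np.asarray(D, dtype=float)
    amat = alpha.alpha if isinstance(alpha, SparseCodes) else np.asarray(alpha, dtype=float)
    if Dmat.shape[1] != amat.shape[0]:
        raise ValueError("inconsistent shapes")
    return Dmat @ amat


def _project_atom(u: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(u)
    return u / max(1.0, nrm)


def _init_dictionary(X: np.ndarray, m: int, rng: np.random.Generator) -> np.ndarray:
    """m distinct randomly chosen data columns, scaled to unit norm."""
    n = X.shape[1]
    idx = rng.choice(n, size=min(m, n), replace=False)
    D = X[:, idx].copy()
    if m > n:  # pad with random atoms when over-complete beyond data size
        extra = rng.normal(size=(X.shape[0], m - n))
        D = np.hstack([D, extra])
    norms = np.linalg.norm(D, axis=0)
    norms[norms == 0] = 1.0
    return D / norms


def learn_dictionary(X: SignalMatrix | np.ndarray, m: int, lam: float,
                     n_iter: int = 10, batch_size: int = 256,
                     seed: int = 0) -> tuple[Dictionary, SparseCodes]:
    """Online dictionary learning (mini-batch block coordinate descent).

    Atoms are initialized from randomly selected normalized data columns.
    Per mini-batch the batch is lasso-coded against the current atoms,
    sufficient statistics ``A += alpha alpha^T`` and ``B += X alpha^T``
    are accumulated, and each atom is updated in turn and projected onto
    the unit ball.  Atoms unused for a whole epoch are re-seeded from the
    currently worst-reconstructed signal.  The final codes are computed
    against the finished dictionary.  Deterministic given ``seed``.

    ``n_iter`` counts epochs (full passes over the columns).
    """
    Xmat = X.X if isinstance(X, SignalMatrix) else np.asarray(X, dtype=float)
    if not np.all(np.isfinite(Xmat)):
        raise ValueError("non-finite entries in signal matrix")
    if m < 2:
        raise ValueError("need at least 2 atoms")
    t, n = Xmat.shape
    if m > n:
        warnings.warn("more atoms than signals; proceeding", RuntimeWarning)

    rng = np.random.default_rng(seed)
    D = _init_dictionary(Xmat, m, rng)

    for epoch in range(n_iter):
        # statistics restart each epoch so stale codes from earlier
        # dictionaries cannot anchor the atoms
        A = np.zeros((m, m))
        B = np.zeros((t, m))
        used = np.zeros(m, dtype=bool)
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            batch = order[start:start + batch_size]
            Xb = Xmat[:, batch]
            ab = sparse_code_matrix(Xb, D, lam)
            used |= np.any(ab != 0, axis=1)
            A += ab @ ab.T
            B += Xb @ ab.T
            for _sweep in range(2):
                for j in range(m):
                    ajj = A[j, j]
                    if ajj < 1e-12:
                        continue
                    u = (B[:, j] - D @ A[:, j]) / ajj + D[:, j]
                    D[:, j] = _project_atom(u)
        # re-seed atoms that went unused, plus near-duplicates (keep the
        # more-used twin), from the worst-reconstructed signals
        bad = set(np.flatnonzero(~used))
        norms = np.maximum(np.linalg.norm(D, axis=0), 1e-12)
        gram = np.abs((D / norms).T @ (D / norms))
        np.fill_diagonal(gram, 0.0)
        for i, j in zip(*np.nonzero(gram > 0.95)):
            if i < j:
                bad.add(int(j) if A[j, j] <= A[i, i] else int(i))
        if bad and epoch < n_iter - 1:
            err = np.sum((Xmat - D @ sparse_code_matrix(Xmat, D, lam)) ** 2, axis=0)
            worst = np.argsort(err)[::-1]
            for rank, j in enumerate(sorted(bad)):
                col = Xmat[:, worst[rank % n]]
                nrm = np.linalg.norm(col)
                D[:, j] = col / nrm if nrm > 0 else rng.normal(size=t)

    alpha = sparse_code_matrix(Xmat, D, lam)
    dic = Dictionary(D=D, learn_params={
        "m": m, "lam": lam, "n_iter": n_iter, "batch_size": batch_size, "seed": seed,
    })
    dic.validate()
    return dic, SparseCodes(alpha=alpha, lam=lam)
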