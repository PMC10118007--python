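"""Discriminative projection learning via a generalized eigenproblem.

Given the HIP/LIP decomposition of the sample dictionary, we seek a
projection P (rows = directions) that preserves the between-class
energy of the high-information part while suppressing within-class
energy of both parts, by maximizing the trace ratio

    tr(P S_B^h P^T) / tr(P [beta S_W^h + (1-beta) S_W^l] P^T).

The maximizing directions are the top generalized eigenvectors of
(S_a, S_b) with S_a = S_B^h and S_b the beta-blended within-class
scatter. With k features and only n samples the scatters are rank
deficient, so S_b carries a small ridge eps_reg * I to make the
symmetric-definite eigenproblem well posed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "ScatterSet",
    "ProjectionModel",
    "scatter_between_hip",
    "scatter_within",
    "build_scatters",
    "default_eps_reg",
    "learn_projection",
    "apply_projection",
]


@dataclass(frozen=True)
class ScatterSet:
    """Between-class scatter of Dh and within-class scatters of Dh, Dl (all k x k PSD)."""

    S_Bh: np.ndarray
    S_Wh: np.ndarray
    S_Wl: np.ndarray


@dataclass(frozen=True)
class ProjectionModel:
    """Learned projection: rows of ``P`` (m x k) are generalized eigenvectors.

    Each row q satisfies S_a q = lambda S_b q with q^T S_b q = 1, rows
    ordered by descending eigenvalue, and the sign fixed so each row's
    largest-magnitude entry is positive.
    """

    P: np.ndarray
    eigvals: np.ndarray
    beta: float
    eps_reg: float

    @property
    def m(self) -> int:
        return self.P.shape[0]

    @property
    def k(self) -> int:
        return self.P.shape[1]

    @classmethod
    def identity(cls, k: int) -> "ProjectionModel":
        """Identity projection (bypass): reduces the pipeline to plain LASSO."""
        return cls(P=np.eye(k), eigvals=np.ones(k), beta=float("nan"), eps_reg=0.0)


def _class_columns(D: np.ndarray, labels: np.ndarray):
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    for cls in classes:
        yield D[:, labels == cls]


def scatter_between_hip(Dh: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Between-class scatter: sum_c (mean_c - grand_mean)(mean_c - grand_mean)^T.

    Means are over columns of Dh; with C classes the rank is at most C-1.
    """
    Dh = np.asarray(Dh, dtype=float)
    grand = Dh.mean(axis=1)
    S = np.zeros((Dh.shape[0], Dh.shape[0]))
    for Dc in _class_columns(Dh, labels):
        d = Dc.mean(axis=1) - grand
        S += np.outer(d, d)
    return S


def scatter_within(Dpart: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Within-class scatter: sum_c sum_{i in c} (d_i - mean_c)(d_i - mean_c)^T."""
    Dpart = np.asarray(Dpart, dtype=float)
    S = np.zeros((Dpart.shape[0], Dpart.shape[0]))
    for Dc in _class_columns(Dpart, labels):
        centered = Dc - Dc.mean(axis=1, keepdims=True)
        S += centered @ centered.T
    return S


def build_scatters(Dh: np.ndarray, Dl: np.ndarray, labels: np.ndarray) -> ScatterSet:
    """Assemble all three scatter matrices from a dictionary decomposition."""
    return ScatterSet(
        S_Bh=scatter_between_hip(Dh, labels),
        S_Wh=scatter_within(Dh, labels),
        S_Wl=scatter_within(Dl, labels),
    )


def default_eps_reg(scatters: ScatterSet, beta: float) -> float:
    """Ridge scale 1e-6 * trace(S_b)/k, falling back to 1e-6 for a zero blend."""
    S_b = beta * scatters.S_Wh + (1.0 - beta) * scatters.S_Wl
    k = S_b.shape[0]
    tr = float(np.trace(S_b))
    return 1e-6 * tr / k if tr > 0 else 1e-6


def learn_projection(
    scatters: ScatterSet,
    beta: float = 0.5,
    eps_reg: float | None = None,
    m: int | None = None,
) -> ProjectionModel:
    """Solve S_a q = lambda S_b q and keep the top-m eigenpairs.

    ``beta`` in [0, 1] balances the HIP and LIP within-class energies in
    S_b; ``eps_reg`` (> 0, default trace-scaled) is the ridge added to
    S_b; ``m`` directions are kept (default: all k). Rows are
    S_b-normalized and sign-fixed for reproducibility.
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must be in [0, 1]")
    S_a = np.asarray(scatters.S_Bh, dtype=float)
    k = S_a.shape[0]
    if eps_reg is None:
        eps_reg = default_eps_reg(scatters, beta)
    if eps_reg <= 0:
        raise ValueError("eps_reg must be > 0")
    if m is None:
        m = k
    if not 1 <= m <= k:
        raise ValueError(f"m must be in [1, {k}]")

    S_b = beta * scatters.S_Wh + (1.0 - beta) * scatters.S_Wl + eps_reg * np.eye(k)
    # symmetrize against accumulation noise before the definite solve
    S_a = 0.5 * (S_a + S_a.T)
    S_b = 0.5 * (S_b + S_b.T)
    try:
        eigvals, eigvecs = scipy.linalg.eigh(S_a, S_b)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError(
            "blended within-class scatter is numerically singular; increase eps_reg"
        ) from exc

    order = np.argsort(eigvals, kind="stable")[::-1][:m]
    lam = eigvals[order]
    P = eigvecs[:, order].T  # rows q_i, already q^T S_b q = 1 from eigh
    # deterministic sign: largest-magnitude entry of each row positive
    for i in range(P.shape[0]):
        j = int(np.argmax(np.abs(P[i])))
        if P[i, j] < 0:
            P[i] = -P[i]
    return ProjectionModel(P=P, eigvals=lam, beta=float(beta), eps_reg=float(eps_reg))


def apply_projection(model: ProjectionModel, D: np.ndarray) -> np.ndarray:
    """Project a k x n dictionary: returns P @ D (m x n)."""
    D = np.asarray(D, dtype=float)
    if D.shape[0] != model.k:
        raise ValueError(f"projection expects {model.k} rows, got {D.shape[0]}")
    return model.P @ D
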