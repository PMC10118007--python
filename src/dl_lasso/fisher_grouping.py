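"""Sample-dictionary sparse coding and Fisher-ratio atom grouping.

The training cohort itself serves as the dictionary: column i of
``D0 in R^{k x n}`` is sample i's (normalized) radiomic feature vector,
an *atom*. Each sample is then sparse-coded over the remaining atoms
(its own atom excluded, otherwise the trivial identity code wins), and
each atom's signed contribution across samples is scored by a Fisher
ratio — between-class spread of its coding contributions over
within-class spread. Atoms with high scores form the high-information
part (HIP) of the dictionary; the rest, plus the unexplained coding
residual, form the low-information part (LIP). The two parts sum back
to D0 exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .lasso_core import DEFAULT_MAX_ITER, DEFAULT_TOL, solve_lasso_gram

__all__ = [
    "SampleDictionary",
    "CodeMatrix",
    "AtomPartition",
    "DictionaryDecomposition",
    "code_samples",
    "atom_contributions",
    "fisher_ratio",
    "partition_atoms",
    "decompose_dictionary",
]

#: guard added to the within-class denominator of the Fisher ratio
EPS_FISHER = 1e-12


@dataclass(frozen=True)
class SampleDictionary:
    """Dictionary whose atoms are the training samples' feature vectors.

    ``D0`` is k x n (columns = samples); ``labels`` holds each atom's
    binary grade.
    """

    D0: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        D0 = np.asarray(self.D0, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "D0", D0)
        object.__setattr__(self, "labels", labels)
        if D0.ndim != 2:
            raise ValueError("D0 must be a k x n matrix")
        if not np.all(np.isfinite(D0)):
            raise ValueError("dictionary atoms must be finite")
        if labels.shape != (D0.shape[1],):
            raise ValueError("labels must have one entry per atom")
        if len(np.unique(labels)) < 2:
            raise ValueError("both classes must be present among atoms")

    @property
    def k(self) -> int:
        return self.D0.shape[0]

    @property
    def n(self) -> int:
        return self.D0.shape[1]

    @property
    def class_count(self) -> int:
        return len(np.unique(self.labels))

    @classmethod
    def from_table(cls, table) -> "SampleDictionary":
        """Build from a FeatureTable: D0 = X^T."""
        return cls(D0=table.values.T, labels=table.labels)


@dataclass(frozen=True)
class CodeMatrix:
    """Per-sample sparse codes: A[j, t] weights atom j in sample t's code.

    The diagonal is identically zero (self-exclusion).
    """

    A: np.ndarray
    mu_code: float

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        object.__setattr__(self, "A", A)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("A must be square (n x n)")
        if not np.all(np.isfinite(A)):
            raise ValueError("codes must be finite")
        if np.any(np.diag(A) != 0.0):
            raise ValueError("self-coefficients must be exactly zero")


@dataclass(frozen=True)
class AtomPartition:
    """Fisher scores and the HIP/LIP split of atom indices."""

    fisher: np.ndarray
    hip_idx: np.ndarray
    lip_idx: np.ndarray
    rho: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "fisher", np.asarray(self.fisher, dtype=float))
        object.__setattr__(self, "hip_idx", np.asarray(self.hip_idx, dtype=int))
        object.__setattr__(self, "lip_idx", np.asarray(self.lip_idx, dtype=int))
        n = self.fisher.shape[0]
        combined = np.sort(np.concatenate([self.hip_idx, self.lip_idx]))
        if not np.array_equal(combined, np.arange(n)):
            raise ValueError("hip_idx and lip_idx must partition {0..n-1}")


@dataclass(frozen=True)
class DictionaryDecomposition:
    """D0 = Dh + Dl, columnwise high- and low-information reconstructions."""

    Dh: np.ndarray
    Dl: np.ndarray


def code_samples(
    dictionary: SampleDictionary,
    mu_code: float,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> CodeMatrix:
    """Sparse-code every sample over the other atoms.

    Column t of the returned matrix solves the l1-penalized regression of
    atom d_t on the dictionary with atom t removed (its own coefficient
    pinned at 0). All n solves share the single n x n Gram matrix of D0,
    so the per-sample subproblem is assembled by dropping one row/column.
    """
    if dictionary.n < 3:
        raise ValueError("need at least 3 atoms to code samples")
    n = dictionary.n
    G0 = dictionary.D0.T @ dictionary.D0
    A = np.zeros((n, n))
    for t in range(n):
        keep = np.concatenate([np.arange(t), np.arange(t + 1, n)])
        G = G0[np.ix_(keep, keep)]
        b = G0[keep, t]
        fit = solve_lasso_gram(G, b, float(G0[t, t]), mu_code, tol=tol, max_iter=max_iter)
        A[keep, t] = fit.alpha
    return CodeMatrix(A=A, mu_code=float(mu_code))


def atom_contributions(dictionary: SampleDictionary, codes: CodeMatrix) -> np.ndarray:
    """Materialize the contribution tensor z[j, t] = A[j, t] * d_j in R^k.

    Returns an (n, n, k) array; intended for inspection and small
    problems — the pipeline works from the scalarized contributions
    inside :func:`fisher_ratio` instead.
    """
    if codes.A.shape[0] != dictionary.n:
        raise ValueError("code matrix does not match dictionary size")
    # z[j, t, :] = A[j, t] * D0[:, j]
    return np.einsum("jt,kj->jtk", codes.A, dictionary.D0)


def _contribution_scores(dictionary: SampleDictionary, codes: CodeMatrix, scalarization: str) -> np.ndarray:
    norms = np.linalg.norm(dictionary.D0, axis=0)
    if scalarization == "signed_norm":
        return codes.A * norms[:, None]
    if scalarization == "l2":
        return np.abs(codes.A) * norms[:, None]
    raise ValueError(f"unknown scalarization {scalarization!r}")


def fisher_ratio(
    dictionary: SampleDictionary,
    codes: CodeMatrix,
    scalarization: str = "signed_norm",
    eps: float = EPS_FISHER,
) -> np.ndarray:
    """Score each atom's class-discriminative power.

    Atom j's contribution to sample t is scalarized as
    ``s_j(t) = A[j, t] * ||d_j||_2`` (signed; ``scalarization='l2'``
    uses the contribution norm instead, discarding sign). Grouping the
    samples t by *their* grade label, the score is

        f_j = sum_c (sbar_j - sbar_{j,c})^2
              / ( sum_c (1/n_c) sum_{t in c} (s_j(t) - sbar_{j,c})^2 + eps )

    i.e. between-class scatter of the contributions over their mean
    within-class variance. f_j >= 0; a large value means atom j loads
    very differently on the two grades.
    """
    labels = dictionary.labels
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples for the Fisher ratio")
    S = _contribution_scores(dictionary, codes, scalarization)  # (n atoms, n samples)
    if not np.any(S):
        warnings.warn("all atom contributions are zero; Fisher scores set to 0", RuntimeWarning)
        return np.zeros(dictionary.n)

    grand = S.mean(axis=1)
    between = np.zeros(dictionary.n)
    within = np.zeros(dictionary.n)
    for cls, n_c in zip(classes, counts):
        Sc = S[:, labels == cls]
        mean_c = Sc.mean(axis=1)
        between += (grand - mean_c) ** 2
        within += ((Sc - mean_c[:, None]) ** 2).sum(axis=1) / n_c
    return between / (within + eps)


def partition_atoms(f: np.ndarray, rho: float) -> AtomPartition:
    """Split atoms into HIP/LIP at the top ``ceil(rho * n)`` Fisher scores.

    Ties are broken toward the lower atom index (stable descending sort),
    so the split is deterministic.
    """
    f = np.asarray(f, dtype=float)
    if not np.all(np.isfinite(f)) or np.any(f < 0):
        raise ValueError("Fisher scores must be finite and non-negative")
    if not 0.0 < rho < 1.0:
        raise ValueError("rho must be in (0, 1)")
    n = f.shape[0]
    n_hip = math.ceil(rho * n)
    order = np.argsort(-f, kind="stable")
    hip = np.sort(order[:n_hip])
    lip = np.sort(order[n_hip:])
    return AtomPartition(fisher=f, hip_idx=hip, lip_idx=lip, rho=float(rho))


def decompose_dictionary(
    dictionary: SampleDictionary,
    codes: CodeMatrix,
    partition: AtomPartition,
) -> DictionaryDecomposition:
    """Reconstruct each sample's high/low-information parts.

    The HIP column is the sample's code restricted to HIP atoms,
    d_t^h = sum_{j in HIP} A[j,t] d_j; everything else — the LIP-atom
    contributions plus the coding residual d_t - D0 A[:,t], which is
    unexplained and hence uninformative by construction — goes to the
    LIP column. Dh + Dl = D0 holds to rounding.
    """
    if codes.A.shape[0] != dictionary.n:
        raise ValueError("code matrix does not match dictionary size")
    hip = partition.hip_idx
    Dh = dictionary.D0[:, hip] @ codes.A[hip, :]
    Dl = dictionary.D0 - Dh
    return DictionaryDecomposition(Dh=Dh, Dl=Dl)
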