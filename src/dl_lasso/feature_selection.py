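"""End-to-end dl-LASSO feature selection.

Pipeline: normalize -> sparse-code the sample dictionary -> Fisher-ratio
atom partition -> HIP/LIP decomposition -> scatter matrices ->
discriminative projection -> LASSO of the grade labels on the projected
dictionary -> back-project coefficients to per-feature weights -> rank
and keep the top tau original radiomic features.

The learned design is ``X_tilde = (P D0)^T``; because
``X_tilde a = X (P^T a)``, the back-projected weight vector
``w = P^T alpha_proj`` is the unique linear model on the original
features that reproduces the projected model's predictions, and |w|
is the feature-importance used for selection.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .core_io import FeatureTable, zscore_apply, zscore_fit
from .dictionary_projection import (
    ProjectionModel,
    apply_projection,
    build_scatters,
    learn_projection,
)
from .fisher_grouping import (
    SampleDictionary,
    code_samples,
    decompose_dictionary,
    fisher_ratio,
    partition_atoms,
)
from .lasso_core import default_mu_grid, select_mu_cv, solve_lasso

__all__ = [
    "PipelineConfig",
    "SelectionResult",
    "dl_lasso_select",
    "plain_lasso_select",
    "effective_weights",
    "rank_and_select",
]


@dataclass
class PipelineConfig:
    """All tunables of the selection pipeline, with defaults.

    tau: number of features to keep. rho: HIP fraction of atoms.
    beta: HIP/LIP within-class energy balance in [0, 1]. mu / mu_code:
    LASSO penalties for the final fit and the per-sample coding (None =
    pick by cross-validation on, respectively, the projected design and
    the label regression). eps_reg: ridge for the generalized
    eigenproblem (None = trace-scaled default). m: projection directions
    kept (None = min(k, n-1)). identity_projection bypasses dictionary
    learning entirely, reducing the method to plain LASSO selection.
    """

    tau: int = 20
    rho: float = 0.5
    beta: float = 0.5
    mu: float | None = None
    mu_code: float | None = None
    eps_reg: float | None = None
    m: int | None = None
    mu_grid_size: int = 8
    mu_grid_decades: float = 3.0
    cv_folds: int = 5
    seed: int = 0
    normalize: bool = True
    identity_projection: bool = False
    scalarization: str = "signed_norm"
    tol: float = 1e-8
    cv_tol: float = 1e-5
    max_iter: int = 100_000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of a selection run.

    ``weights`` is the k-vector of effective per-feature importances
    (back-projected LASSO coefficients); ``selected_idx`` the indices of
    the tau largest |weights| (zero weights never selected), with the
    upstream hyperparameters echoed for the run record.
    """

    alpha_proj: np.ndarray
    weights: np.ndarray
    selected_idx: np.ndarray
    selected_names: tuple[str, ...]
    tau: int
    mu: float
    mu_code: float
    beta: float
    rho: float
    eps_reg: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.selected_idx) + 1),
                "feature_index": self.selected_idx,
                "feature_name": list(self.selected_names),
                "weight": self.weights[self.selected_idx],
            }
        )


def effective_weights(model: ProjectionModel, alpha_proj: np.ndarray) -> np.ndarray:
    """Back-project coefficients to the original feature axes: w = P^T alpha."""
    alpha_proj = np.asarray(alpha_proj, dtype=float).ravel()
    if alpha_proj.shape[0] != model.m:
        raise ValueError(f"expected {model.m} projected coefficients, got {alpha_proj.shape[0]}")
    return model.P.T @ alpha_proj


def rank_and_select(weights: np.ndarray, tau: int) -> np.ndarray:
    """Indices of the tau largest |weights|, descending; ties to lower index.

    Zero-weight features are never selected, so the result may be
    shorter than tau.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(-np.abs(weights), kind="stable")
    order = order[np.abs(weights[order]) > 0]
    return order[:tau]


def dl_lasso_select(train: FeatureTable, config: PipelineConfig | None = None) -> SelectionResult:
    """Run the full dictionary-learning LASSO selection on a training table."""
    cfg = config or PipelineConfig()
    if cfg.normalize:
        train = zscore_apply(train, zscore_fit(train))
    X = train.values
    y = train.labels.astype(float)
    n, k = X.shape

    if cfg.identity_projection:
        model = ProjectionModel.identity(k)
        mu_code = 0.0
    else:
        dictionary = SampleDictionary.from_table(train)
        mu_code = cfg.mu_code
        if mu_code is None:
            try:
                mu_code = select_mu_cv(
                    X, y, default_mu_grid(X, y, cfg.mu_grid_size, cfg.mu_grid_decades),
                    folds=cfg.cv_folds, seed=cfg.seed, tol=cfg.cv_tol, max_iter=cfg.max_iter,
                )
            except ValueError as exc:
                raise RuntimeError(f"dl-lasso [coding-penalty CV] failed: {exc}") from exc
        try:
            codes = code_samples(dictionary, mu_code, tol=cfg.tol, max_iter=cfg.max_iter)
            f = fisher_ratio(dictionary, codes, scalarization=cfg.scalarization)
            partition = partition_atoms(f, cfg.rho)
            decomp = decompose_dictionary(dictionary, codes, partition)
        except ValueError as exc:
            raise RuntimeError(f"dl-lasso [coding/grouping] failed: {exc}") from exc
        try:
            scatters = build_scatters(decomp.Dh, decomp.Dl, train.labels)
            m = cfg.m if cfg.m is not None else min(k, n - 1)
            model = learn_projection(scatters, beta=cfg.beta, eps_reg=cfg.eps_reg, m=m)
        except ValueError as exc:
            raise RuntimeError(f"dl-lasso [projection] failed: {exc}") from exc

    X_tilde = apply_projection(model, X.T).T  # n x m learned design

    mu = cfg.mu
    if mu is None:
        mu = select_mu_cv(
            X_tilde, y, default_mu_grid(X_tilde, y, cfg.mu_grid_size, cfg.mu_grid_decades),
            folds=cfg.cv_folds, seed=cfg.seed, tol=cfg.cv_tol, max_iter=cfg.max_iter,
        )
    fit = solve_lasso(X_tilde, y, mu, tol=cfg.tol, max_iter=cfg.max_iter)
    w = effective_weights(model, fit.alpha)
    selected = rank_and_select(w, cfg.tau)
    return SelectionResult(
        alpha_proj=fit.alpha,
        weights=w,
        selected_idx=selected,
        selected_names=tuple(train.feature_names[i] for i in selected),
        tau=cfg.tau,
        mu=float(mu),
        mu_code=float(mu_code),
        beta=cfg.beta,
        rho=cfg.rho,
        eps_reg=float(model.eps_reg),
    )


def plain_lasso_select(train: FeatureTable, config: PipelineConfig | None = None) -> SelectionResult:
    """Baseline: LASSO selection directly on the original features (no dictionary learning)."""
    cfg = config or PipelineConfig()
    cfg = PipelineConfig(**{**cfg.to_dict(), "identity_projection": True})
    return dl_lasso_select(train, cfg)
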