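"""Elastic-net stability selection of stage-specific genes.

For each pathology stage t the binary one-vs-rest label vector Y_t is
regressed on the standardized multi-omics feature matrix X under the
elastic-net objective

    (1/m) ||Y_t - X b||^2  +  lam * ( a * ||b||_1 + (1 - a) * ||b||_2^2 )

where ``a`` (``alpha_mix``) balances the lasso and ridge penalties
(a = 0.5 weights them equally) and the overall strength ``lam`` is swept
along a log-spaced path of ``n_models`` points from lambda_max — the
smallest penalty at which every coefficient is exactly zero — down to
``lambda_min_ratio * lambda_max``. The path floor (default 0.05) keeps
every model in the sparse regime: selection frequency only carries
information while models stay sparse, and with more features than samples
a nearly-unpenalized tail model activates almost everything, which would
credit noise features with high counts. A gene counts as selected by a model if
any of its feature columns (expression or methylation) has |beta| above
``coef_threshold`` at that path point; genes selected by at least
``cutoff`` of the models form the stage's signature-gene seed set.

The coordinate-descent solve at each path point is delegated to
scikit-learn's ElasticNet with the penalty reparameterized so the objective
above is minimized exactly; the path logic, counting rule and cutoff are
implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet

from .ingest import FeatureMatrix, StageLabelVector

__all__ = [
    "ElasticNetConfig",
    "CoefficientPath",
    "SelectionProfile",
    "objective",
    "fit_path",
    "count_selections",
    "select_stage_genes",
    "run_summary",
]


@dataclass(frozen=True)
class ElasticNetConfig:
    """Tuning parameters of the path fit and the selection rule."""

    alpha_mix: float = 0.5
    n_models: int = 50
    coef_threshold: float = 1e-8
    cutoff: int = 20
    lambda_min_ratio: float = 0.05
    max_iter: int = 10_000
    tol: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_mix <= 1.0):
            raise ValueError("alpha_mix must be in (0, 1]")
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if not (0 <= self.cutoff <= self.n_models + 1):
            raise ValueError("cutoff must be between 0 and n_models (+1 allowed to disable)")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if not (0.0 < self.lambda_min_ratio < 1.0):
            raise ValueError("lambda_min_ratio must be in (0, 1)")


@dataclass
class CoefficientPath:
    """Coefficients and objective values along the regularization path."""

    lambdas: np.ndarray  # strictly decreasing, length n_models
    betas: np.ndarray  # n_models x n
    objective: np.ndarray  # objective value at each path point

    @property
    def n_models(self) -> int:
        return len(self.lambdas)


@dataclass
class SelectionProfile:
    """Per-gene selection counts across the path and the cutoff rule."""

    counts: dict[str, int]
    selected: set[str]
    n_models: int
    cutoff: int
    #: largest number of distinct genes selected by any single model
    max_genes_per_model: int = 0


def objective(X: np.ndarray, y: np.ndarray, beta: np.ndarray, lam: float, alpha_mix: float) -> float:
    """The penalized least-squares objective being minimized at one path point."""
    resid = y - X @ beta
    m = X.shape[0]
    penalty = lam * (alpha_mix * np.abs(beta).sum() + (1.0 - alpha_mix) * (beta @ beta))
    return float(resid @ resid / m + penalty)


def lambda_max(X: np.ndarray, y: np.ndarray, alpha_mix: float) -> float:
    """Smallest penalty strength at which beta = 0 is optimal (KKT bound)."""
    m = X.shape[0]
    return float(2.0 / m * np.max(np.abs(X.T @ y)) / alpha_mix)


def _sklearn_params(lam: float, alpha_mix: float) -> tuple[float, float]:
    # sklearn minimizes (1/2m)||y-Xb||^2 + alpha*l1r*|b|_1 + (alpha/2)(1-l1r)|b|_2^2;
    # doubling it and matching terms to our objective gives this mapping
    alpha = lam * (1.0 - alpha_mix / 2.0)
    l1_ratio = alpha_mix / (2.0 - alpha_mix)
    return alpha, l1_ratio


def fit_path(
    X: FeatureMatrix | np.ndarray, y: StageLabelVector | np.ndarray, cfg: ElasticNetConfig
) -> CoefficientPath:
    """Fit the elastic net along the full regularization path.

    Returns exactly ``cfg.n_models`` path points on a log-spaced grid from
    lambda_max down to ``lambda_min_ratio * lambda_max``; at the first point
    every coefficient is exactly zero. Raises on a constant label vector and
    warns (without failing) if the solver hits ``max_iter``.
    """
    Xa = X.X if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    ya = y.y if isinstance(y, StageLabelVector) else np.asarray(y, dtype=float)
    if Xa.ndim != 2 or Xa.shape[0] != ya.shape[0]:
        raise ValueError("X and y have incompatible shapes")
    if np.all(ya == ya[0]):
        raise ValueError("degenerate label: y is constant")

    lam_hi = lambda_max(Xa, ya, cfg.alpha_mix)
    if lam_hi <= 0.0:  # y orthogonal to every column: zero path on a nominal grid
        lam_hi = 1.0
    if cfg.n_models == 1:
        lambdas = np.array([lam_hi])
    else:
        lambdas = np.geomspace(lam_hi, cfg.lambda_min_ratio * lam_hi, cfg.n_models)

    n = Xa.shape[1]
    betas = np.zeros((cfg.n_models, n))
    objs = np.zeros(cfg.n_models)
    est = ElasticNet(fit_intercept=False, warm_start=True, max_iter=cfg.max_iter, tol=cfg.tol)
    unconverged = 0
    for i, lam in enumerate(lambdas):
        alpha, l1_ratio = _sklearn_params(lam, cfg.alpha_mix)
        est.set_params(alpha=alpha, l1_ratio=l1_ratio)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            est.fit(Xa, ya)
            if any(issubclass(w.category, ConvergenceWarning) for w in caught):
                unconverged += 1
        betas[i] = est.coef_
        objs[i] = objective(Xa, ya, betas[i], lam, cfg.alpha_mix)
    if unconverged:
        warnings.warn(
            f"elastic-net solver hit max_iter={cfg.max_iter} at {unconverged} path points",
            RuntimeWarning,
            stacklevel=2,
        )
    return CoefficientPath(lambdas=lambdas, betas=betas, objective=objs)


def count_selections(
    path: CoefficientPath, column_gene: list[str], cfg: ElasticNetConfig
) -> SelectionProfile:
    """Count, per gene, the models in which any of its columns is active.

    A gene's expression and methylation columns count once per model (union,
    not sum). Genes with count >= cutoff are selected.
    """
    if len(column_gene) != path.betas.shape[1]:
        raise ValueError(
            f"column_gene has {len(column_gene)} entries for {path.betas.shape[1]} columns"
        )
    active = np.abs(path.betas) > cfg.coef_threshold  # n_models x n
    genes = sorted(set(column_gene))
    gene_cols = {g: [] for g in genes}
    for j, g in enumerate(column_gene):
        gene_cols[g].append(j)
    # per model, a gene is selected if any of its columns is active
    gene_active = np.stack([active[:, cols].any(axis=1) for g, cols in gene_cols.items()], axis=1)
    counts = {g: int(c) for g, c in zip(gene_cols, gene_active.sum(axis=0))}
    selected = {g for g, c in counts.items() if c >= cfg.cutoff}
    max_per_model = int(gene_active.sum(axis=1).max()) if gene_active.size else 0
    return SelectionProfile(
        counts=counts,
        selected=selected,
        n_models=path.n_models,
        cutoff=cfg.cutoff,
        max_genes_per_model=max_per_model,
    )


def select_stage_genes(
    X: FeatureMatrix, labels: list[StageLabelVector], cfg: ElasticNetConfig
) -> dict[str, SelectionProfile]:
    """Run the path fit and selection rule independently for every stage."""
    profiles: dict[str, SelectionProfile] = {}
    for lab in labels:
        path = fit_path(X, lab, cfg)
        profiles[lab.stage] = count_selections(path, X.column_gene, cfg)
    return profiles


def run_summary(profiles: dict[str, SelectionProfile]) -> pd.DataFrame:
    """Per-stage summary: models fitted, peak genes per model, genes at cutoff."""
    rows = [
        {
            "stage": st,
            "models": p.n_models,
            "max_genes_detected": p.max_genes_per_model,
            "genes_at_cutoff": len(p.selected),
            "cutoff": p.cutoff,
        }
        for st, p in sorted(profiles.items())
    ]
    return pd.DataFrame(rows)


def profile_table(profile: SelectionProfile) -> pd.DataFrame:
    """Per-gene table (gene, count, selected flag), counts descending."""
    rows = [
        {"gene": g, "count": c, "selected": g in profile.selected}
        for g, c in sorted(profile.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows)
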