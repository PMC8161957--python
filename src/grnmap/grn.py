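"""Elastic-net inference of TF -> target-gene regulatory networks.

For each target gene (TG), its expression vector y over cells is regressed on
the expression matrix X of the m candidate TFs — those with motif-supported
wires to the TG in the reference network — by solving

    c* = argmin_c  ||y - Xc||^2 + alpha ||c||_2^2 + beta ||c||_1

over a grid of (alpha, beta). Cells are split once per cell type into
train/test; each grid point is fit on the training cells and the winner is the
one minimizing the held-out mean squared error. Predictors and response are
standardized to unit variance on training statistics, so coefficients are
dimensionless and one |c| cutoff is meaningful across genes.

The objective above is converted to scikit-learn's ElasticNet convention
(which minimizes ``1/(2n)||y-Xc||^2 + a*l1*||c||_1 + a*(1-l1)/2*||c||_2^2``)
via ``a = (beta + 2*alpha) / (2n)`` and ``l1_ratio = beta / (beta + 2*alpha)``;
the round trip is exact and tested.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import ElasticNet, LinearRegression

from .expression import ExpressionMatrix
from .intervals import GenomicInterval, overlaps
from .motifs import ReferenceEdge

log = logging.getLogger(__name__)


def default_grid() -> List[Tuple[float, float]]:
    """(alpha, beta) pairs: L1 fraction beta/(alpha+beta) in {0.1, 0.5, 0.9},
    total penalty alpha+beta log-spaced over 10^-4 .. 10^1 (7 values)."""
    grid = []
    for total in np.logspace(-4, 1, 7):
        for mix in (0.1, 0.5, 0.9):
            grid.append((float((1 - mix) * total), float(mix * total)))
    return grid


def paper_to_sklearn(alpha: float, beta: float, n: int) -> Tuple[float, float]:
    """Convert (L2 weight alpha, L1 weight beta) of the unnormalized objective
    to scikit-learn's (alpha, l1_ratio) at sample size n."""
    if alpha < 0 or beta < 0:
        raise ValueError("penalty weights must be >= 0")
    total = beta + 2.0 * alpha
    if total == 0:
        return 0.0, 1.0
    return total / (2.0 * n), beta / total


def sklearn_to_paper(a: float, l1_ratio: float, n: int) -> Tuple[float, float]:
    """Inverse of :func:`paper_to_sklearn`."""
    beta = a * l1_ratio * 2.0 * n
    alpha = a * (1.0 - l1_ratio) * n
    return alpha, beta


@dataclass
class ElasticNetConfig:
    grid: List[Tuple[float, float]] = field(default_factory=default_grid)
    train_ratio: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.grid:
            raise ValueError("grid must be non-empty")
        if not 0.0 < self.train_ratio < 1.0:
            raise ValueError("train_ratio must be in (0, 1)")


@dataclass
class TargetGeneFit:
    gene_id: str
    tf_names: List[str]
    coefficients: np.ndarray
    chosen_alpha: float
    chosen_beta: float
    test_mse: float

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.tf_names):
            raise ValueError("one coefficient per candidate TF required")
        if not math.isfinite(self.test_mse):
            raise ValueError("test_mse must be finite")


@dataclass(frozen=True)
class GrnEdge:
    """Final network edge: TF -> TG with its coefficient and supporting elements."""

    tf_name: str
    gene_id: str
    coefficient: float
    elements: Tuple[Tuple[GenomicInterval, str], ...]


def split_cells(n_cells: int, train_ratio: float = 0.7, seed: int = 0) -> Tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive, seeded train/test index split with |train| = round(ratio * n)."""
    if n_cells < 4:
        raise ValueError("need at least 4 cells to split")
    n_train = int(math.floor(train_ratio * n_cells + 0.5))
    if n_train == 0 or n_train == n_cells:
        raise ValueError(f"degenerate split: {n_train} train of {n_cells}")
    perm = np.random.default_rng(seed).permutation(n_cells)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


class ElasticNetGridRegressor(BaseEstimator, RegressorMixin):
    """Grid-searched elastic net selected by held-out MSE.

    Parameters use the unnormalized objective's (alpha, beta) weighting; data
    are standardized internally on training statistics and coefficients are
    reported on the standardized scale.

    Attributes (after fit): ``coef_``, ``alpha_``, ``beta_``, ``test_mse_``.
    """

    def __init__(self, grid=None, train_ratio: float = 0.7, seed: int = 0,
                 split: Optional[Tuple[np.ndarray, np.ndarray]] = None):
        self.grid = grid
        self.train_ratio = train_ratio
        self.seed = seed
        self.split = split

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError(f"X {X.shape} and y {y.shape} are inconsistent")
        grid = list(self.grid) if self.grid is not None else default_grid()
        if self.split is not None:
            train_idx, test_idx = (np.asarray(s, dtype=int) for s in self.split)
        else:
            train_idx, test_idx = split_cells(X.shape[0], self.train_ratio, self.seed)
        if len(train_idx) < 2:
            raise ValueError("need at least 2 training samples")
        Xtr, Xte = X[train_idx], X[test_idx]
        ytr, yte = y[train_idx], y[test_idx]

        x_mean, x_sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        y_mean, y_sd = float(ytr.mean()), float(ytr.std())
        self.x_mean_, self.x_sd_, self.y_mean_, self.y_sd_ = x_mean, x_sd, y_mean, y_sd
        self.n_features_in_ = X.shape[1]

        if y_sd == 0.0:
            # constant response on training cells: nothing to learn
            log.warning("constant training response; returning all-zero coefficients")
            self.coef_ = np.zeros(X.shape[1])
            self.alpha_, self.beta_ = grid[0]
            self.test_mse_ = float(np.mean((yte - ytr.mean()) ** 2))
            return self

        sd_safe = np.where(x_sd > 0, x_sd, 1.0)
        Ztr = (Xtr - x_mean) / sd_safe
        Zte = (Xte - x_mean) / sd_safe
        Ztr[:, x_sd == 0] = 0.0
        Zte[:, x_sd == 0] = 0.0
        utr = (ytr - y_mean) / y_sd
        ute = (yte - y_mean) / y_sd

        best = None
        n_train = len(train_idx)
        for alpha, beta in grid:
            a, l1 = paper_to_sklearn(alpha, beta, n_train)
            if a == 0.0:
                model = LinearRegression(fit_intercept=False)
            else:
                model = ElasticNet(alpha=a, l1_ratio=l1, fit_intercept=False, max_iter=10000)
            model.fit(Ztr, utr)
            coef = np.asarray(model.coef_, dtype=float).ravel()
            mse = float(np.mean((ute - Zte @ coef) ** 2))
            if best is None or mse < best[0]:
                best = (mse, alpha, beta, coef)
        self.test_mse_, self.alpha_, self.beta_, self.coef_ = best
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        sd_safe = np.where(self.x_sd_ > 0, self.x_sd_, 1.0)
        Z = (X - self.x_mean_) / sd_safe
        Z[:, self.x_sd_ == 0] = 0.0
        return self.y_mean_ + self.y_sd_ * (Z @ self.coef_)

    def training_objective(self, coef: np.ndarray, Z: np.ndarray, u: np.ndarray,
                           alpha: float, beta: float) -> float:
        """Value of the unnormalized objective at ``coef`` on standardized data."""
        resid = u - Z @ coef
        return float(resid @ resid + alpha * coef @ coef + beta * np.abs(coef).sum())


def candidate_tfs(reference: Sequence[ReferenceEdge], gene_id: str, expressed_tfs: Set[str]) -> List[str]:
    """Distinct TFs wired to the gene in the reference network and present in
    the (filtered) expression matrix, excluding the gene itself, sorted."""
    tfs = {e.tf_name for e in reference if e.gene_id == gene_id}
    tfs &= set(expressed_tfs)
    tfs.discard(gene_id)
    return sorted(tfs)


def fit_target_gene(y: np.ndarray, X: np.ndarray, tf_names: Sequence[str],
                    cfg: ElasticNetConfig, gene_id: str = "",
                    split: Optional[Tuple[np.ndarray, np.ndarray]] = None) -> TargetGeneFit:
    est = ElasticNetGridRegressor(grid=cfg.grid, train_ratio=cfg.train_ratio,
                                  seed=cfg.seed, split=split)
    est.fit(X, y)
    return TargetGeneFit(
        gene_id=gene_id,
        tf_names=list(tf_names),
        coefficients=est.coef_,
        chosen_alpha=est.alpha_,
        chosen_beta=est.beta_,
        test_mse=est.test_mse_,
    )


def select_top_tfs(fit: TargetGeneFit, cutoff_absolute: Optional[float] = None,
                   cutoff_percentage: Optional[float] = None) -> List[str]:
    """TFs passing an |coefficient| cutoff, or the top ceil(p*m) by |coefficient|."""
    if (cutoff_absolute is None) == (cutoff_percentage is None):
        raise ValueError("supply exactly one of cutoff_absolute, cutoff_percentage")
    coefs = np.abs(np.asarray(fit.coefficients, dtype=float))
    if cutoff_absolute is not None:
        return [tf for tf, c in zip(fit.tf_names, coefs) if c >= cutoff_absolute]
    m = len(fit.tf_names)
    k = math.ceil(cutoff_percentage * m)
    order = sorted(range(m), key=lambda i: (-coefs[i], fit.tf_names[i]))
    return [fit.tf_names[i] for i in order[:k]]


def _reference_elements(reference: Sequence[ReferenceEdge]) -> Dict[Tuple[str, str], List[Tuple[GenomicInterval, str]]]:
    index: Dict[Tuple[str, str], List[Tuple[GenomicInterval, str]]] = {}
    for e in reference:
        index.setdefault((e.tf_name, e.gene_id), []).append((e.element, e.role))
    for v in index.values():
        v.sort(key=lambda er: (er[0].key(), er[1]))
    return index


def assemble_grn(
    fits: Iterable[TargetGeneFit],
    reference: Sequence[ReferenceEdge],
    variant: str = "top_percent",
    open_regions: Optional[Sequence[GenomicInterval]] = None,
    mse_max: float = 0.1,
    coef_min: float = 0.01,
    cutoff_percentage: float = 0.10,
) -> List[GrnEdge]:
    """Assemble the cell-type GRN from per-gene fits.

    Target genes with held-out MSE strictly above ``mse_max`` are dropped, as
    are TF-TG pairs with |coefficient| strictly below ``coef_min``. Variant
    ``open_chromatin`` then keeps only edges with at least one enhancer inside
    an accessible region (promoter-only edges are retained); variant
    ``top_percent`` instead keeps the top ``cutoff_percentage`` of each TG's
    candidate TFs by |coefficient|.
    """
    if variant not in ("open_chromatin", "top_percent"):
        raise ValueError(f"unknown variant {variant!r}")
    if variant == "open_chromatin" and open_regions is None:
        raise ValueError("variant 'open_chromatin' requires open_regions")
    elements_of = _reference_elements(reference)
    edges: List[GrnEdge] = []
    for fit in fits:
        if fit.test_mse > mse_max:
            continue
        keep = {tf for tf, c in zip(fit.tf_names, fit.coefficients) if abs(c) >= coef_min}
        if variant == "top_percent":
            keep &= set(select_top_tfs(fit, cutoff_percentage=cutoff_percentage))
        for tf, coef in zip(fit.tf_names, fit.coefficients):
            if tf not in keep:
                continue
            elems = elements_of.get((tf, fit.gene_id))
            if not elems:
                continue  # no motif-supported wire: never emit the edge
            if variant == "open_chromatin":
                enhancers = [iv for iv, role in elems if role == "enhancer"]
                if enhancers and not any(
                    overlaps(iv, reg) for iv in enhancers for reg in open_regions
                ):
                    continue
            edges.append(GrnEdge(tf, fit.gene_id, float(coef), tuple(elems)))
    edges.sort(key=lambda e: (e.gene_id, e.tf_name))
    return edges


def infer_grn(
    reference: Sequence[ReferenceEdge],
    expr: ExpressionMatrix,
    cell_type: str,
    cfg: Optional[ElasticNetConfig] = None,
    variant: str = "top_percent",
    open_regions: Optional[Sequence[GenomicInterval]] = None,
    mse_max: float = 0.1,
    coef_min: float = 0.01,
    cutoff_percentage: float = 0.10,
) -> Tuple[List[GrnEdge], Dict[str, TargetGeneFit]]:
    """Fit every target gene of one cell type and assemble its GRN.

    One seeded cell split is shared across all target genes so held-out MSEs
    are comparable between genes.
    """
    cfg = cfg or ElasticNetConfig()
    cells = expr.cells_of_type(cell_type)
    if not cells:
        raise ValueError(f"no cells of type {cell_type!r}")
    values = expr.values[cells]
    expressed = set(values.index)
    split = split_cells(len(cells), cfg.train_ratio, cfg.seed)
    genes_in_reference = sorted({e.gene_id for e in reference})
    fits: Dict[str, TargetGeneFit] = {}
    for gene in genes_in_reference:
        if gene not in expressed:
            continue
        tfs = candidate_tfs(reference, gene, expressed)
        if not tfs:
            log.info("gene %s: no expressed candidate TFs, skipped", gene)
            continue
        y = values.loc[gene].to_numpy(dtype=float)
        X = values.loc[tfs].to_numpy(dtype=float).T
        fits[gene] = fit_target_gene(y, X, tfs, cfg, gene_id=gene, split=split)
    edges = assemble_grn(
        fits.values(), reference, variant=variant, open_regions=open_regions,
        mse_max=mse_max, coef_min=coef_min, cutoff_percentage=cutoff_percentage,
    )
    return edges, fits


def grn_to_frame(edges: Sequence[GrnEdge], fits: Optional[Dict[str, TargetGeneFit]] = None,
                 variant: str = "") -> pd.DataFrame:
    rows = []
    for e in edges:
        rows.append({
            "tf": e.tf_name,
            "target_gene": e.gene_id,
            "coefficient": e.coefficient,
            "test_mse": fits[e.gene_id].test_mse if fits else float("nan"),
            "elements": ";".join(f"{iv.chrom}:{iv.start}-{iv.end}:{role}" for iv, role in e.elements),
            "variant": variant,
        })
    return pd.DataFrame(rows, columns=["tf", "target_gene", "coefficient", "test_mse", "elements", "variant"])
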