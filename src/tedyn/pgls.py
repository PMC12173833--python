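"""Phylogenetic generalized least squares with Pagel's lambda, AICc model
comparison, and Brownian-motion ancestral state reconstruction.

The regression model is y = X b + e with e ~ N(0, sigma2 * C(lambda)),
where C is the shared-branch-length matrix of the tree and lambda scales
its off-diagonal entries (lambda = 0 reduces to ordinary least squares on
an ultrametric tree, lambda = 1 to full Brownian covariance).  Lambda can
be fixed or estimated by profile maximum likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_formats import PhyloTree

__all__ = [
    "PGLSFit",
    "AncestralReconstruction",
    "fit_pgls",
    "compare_models",
    "ancestral_states",
    "design_matrix",
]


@dataclass
class PGLSFit:
    params: pd.Series
    lam: float
    sigma2: float
    loglik: float
    aicc: float
    fvalue: float
    f_pvalue: float
    n: int
    k: int
    lambda_mode: str
    response_name: str = "y"
    tip_order: tuple[str, ...] = ()
    fitted: pd.Series | None = field(default=None, repr=False)
    _response: np.ndarray | None = field(default=None, repr=False)


@dataclass
class AncestralReconstruction:
    """Per internal node: ML Brownian estimate and its variance."""

    states: pd.DataFrame  # index: internal node labels; columns: estimate, variance
    sigma2: float

    @property
    def root_estimate(self) -> float:
        return float(self.states["estimate"].iloc[0])


def design_matrix(predictors: pd.DataFrame) -> pd.DataFrame:
    """Intercept + numeric columns + dummy-coded categoricals.

    Categorical columns are coded with their first category as reference
    (the trait tables order ``oviposition_site`` as [inside, outside], so
    the dummy is the "outside" offset).
    """
    cols = {"Intercept": np.ones(len(predictors))}
    for name in predictors.columns:
        col = predictors[name]
        if isinstance(col.dtype, pd.CategoricalDtype) or col.dtype == object:
            cats = (
                list(col.cat.categories)
                if isinstance(col.dtype, pd.CategoricalDtype)
                else sorted(col.dropna().unique())
            )
            for level in cats[1:]:
                cols[f"{name}[{level}]"] = (col == level).astype(float).to_numpy()
        else:
            cols[name] = col.to_numpy(dtype=float)
    return pd.DataFrame(cols, index=predictors.index)


def _gls_profile(y: np.ndarray, X: np.ndarray, C: np.ndarray):
    """GLS coefficients and profile log-likelihood pieces for fixed C."""
    n = len(y)
    L = np.linalg.cholesky(C)
    yw = np.linalg.solve(L, y)
    Xw = np.linalg.solve(L, X)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    ssr = float(resid @ resid)
    sigma2 = ssr / n  # ML estimate
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2) + n + logdet)
    return beta, sigma2, loglik, ssr


def fit_pgls(
    tree: PhyloTree,
    response: pd.Series,
    predictors: pd.DataFrame,
    lambda_mode: str | float = "ML",
    k_convention: str = "full",
) -> PGLSFit:
    """Fit a PGLS regression of ``response`` on ``predictors``.

    Parameters
    ----------
    lambda_mode
        ``"ML"`` profiles lambda over [0, 1]; a float fixes it.
    k_convention
        ``"full"`` counts intercept + slopes + sigma2 (+ lambda when
        estimated) in AICc; ``"slopes"`` counts regression coefficients
        only.  The convention changes AICc values but not rankings between
        models fit with the same convention.
    """
    labels = tree.tip_labels
    if set(labels) != set(response.index):
        raise ValueError("response index must match the tree's tip set exactly")
    y = response.reindex(labels).to_numpy(dtype=float)
    Xf = design_matrix(predictors.reindex(labels))
    X = Xf.to_numpy(dtype=float)
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        for j in range(p):
            keep = np.delete(np.arange(p), j)
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                raise ValueError(
                    f"design matrix is rank deficient; column "
                    f"{Xf.columns[j]!r} is aliased"
                )
        raise ValueError("design matrix is rank deficient")
    C1 = tree.cov_matrix(labels)
    jitter = 1e-10 * np.trace(C1) / n * np.eye(n)

    def pieces(lam: float):
        Cl = lam * C1
        np.fill_diagonal(Cl, np.diag(C1))
        return _gls_profile(y, X, Cl + jitter)

    if lambda_mode == "ML":
        res = optimize.minimize_scalar(
            lambda lam: -pieces(lam)[2],
            bounds=(0.0, 1.0),
            method="bounded",
            options={"xatol": 1e-6},
        )
        # guard against boundary optima the bracketing can miss
        candidates = {0.0: -pieces(0.0)[2], 1.0: -pieces(1.0)[2], res.x: res.fun}
        lam = min(candidates, key=candidates.get)
        if lam < 1e-4:
            lam = 0.0
        elif lam > 1 - 1e-4:
            lam = 1.0
        estimated_lambda = True
    else:
        lam = float(lambda_mode)
        if not (0.0 <= lam <= 1.0):
            raise ValueError("fixed lambda must lie in [0, 1]")
        estimated_lambda = False

    beta, sigma2, loglik, ssr = pieces(lam)
    # overall F: GLS regression against the intercept-only model under the same C
    _, _, _, ssr0 = _gls_profile(y, X[:, :1], _lambda_cov(C1, lam) + jitter)
    q = p - 1
    if q > 0 and n - p > 0:
        fvalue = ((ssr0 - ssr) / q) / (ssr / (n - p))
        f_pvalue = float(stats.f.sf(fvalue, q, n - p))
    else:
        fvalue, f_pvalue = np.nan, np.nan
    k = (p + 1 + int(estimated_lambda)) if k_convention == "full" else p
    if n - k - 1 <= 0:
        raise ValueError(
            f"AICc undefined: n - k - 1 = {n - k - 1} (n={n}, k={k})"
        )
    aicc = -2 * loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)
    fitted_vals = X @ beta
    return PGLSFit(
        params=pd.Series(beta, index=Xf.columns),
        lam=float(lam),
        sigma2=float(sigma2),
        loglik=float(loglik),
        aicc=float(aicc),
        fvalue=float(fvalue),
        f_pvalue=f_pvalue,
        n=n,
        k=k,
        lambda_mode="ML" if estimated_lambda else "fixed",
        response_name=response.name or "y",
        tip_order=tuple(labels),
        fitted=pd.Series(fitted_vals, index=labels),
        _response=y,
    )


def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    Cl = lam * C
    np.fill_diagonal(Cl, np.diag(C))
    return Cl


def aicc_from_loglik(loglik: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        raise ValueError("AICc undefined for n - k - 1 <= 0")
    return -2 * loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def compare_models(fits: list[PGLSFit]) -> pd.DataFrame:
    """Rank fits by AICc (ascending) with delta-AICc relative to the best."""
    if not fits:
        raise ValueError("no fits supplied")
    ref = fits[0]
    for f in fits[1:]:
        if f.tip_order != ref.tip_order:
            raise ValueError("fits compare different tip sets")
        if not np.allclose(f._response, ref._response):
            raise ValueError("fits compare different responses")
    table = pd.DataFrame(
        {
            "model": [" + ".join(c for c in f.params.index if c != "Intercept") or "1"
                      for f in fits],
            "lambda": [f.lam for f in fits],
            "loglik": [f.loglik for f in fits],
            "k": [f.k for f in fits],
            "aicc": [f.aicc for f in fits],
        }
    ).sort_values("aicc", kind="stable")
    table["delta_aicc"] = table["aicc"] - table["aicc"].min()
    return table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Ancestral reconstruction
# ---------------------------------------------------------------------------


def _shared_depths(tree: PhyloTree, labels: list[str]):
    """Per internal node: (label, depth, vector of shared depths with tips)."""
    dt = tree.dendropy_tree
    leaves = {leaf.taxon.label: leaf for leaf in dt.leaf_node_iter()}
    tip_anc = {}
    for lab in labels:
        node = leaves[lab]
        anc = {id(node): node.distance_from_root()}
        p = node
        while p.parent_node is not None:
            p = p.parent_node
            anc[id(p)] = p.distance_from_root()
        tip_anc[lab] = anc
    rows = []
    for node in dt.preorder_internal_node_iter():
        anc = {id(node): node.distance_from_root()}
        p = node
        while p.parent_node is not None:
            p = p.parent_node
            anc[id(p)] = p.distance_from_root()
        c = np.array(
            [
                max(v for k, v in anc.items() if k in tip_anc[lab])
                for lab in labels
            ]
        )
        rows.append((node.label, node.distance_from_root(), c))
    return rows


def reconstruction_operator(tree: PhyloTree, labels: list[str] | None = None):
    """Linear operator M with internal-node estimates = M @ tip_values.

    The estimate at node v is mu + c_v' C^-1 (y - mu 1) with mu the GLS
    phylogenetic mean and c_v the vector of root-to-MRCA(v, tip) lengths;
    this coincides with the weighted squared-change parsimony / joint-ML
    Brownian reconstruction.  Returns (M, internal_labels, depths, cvecs,
    Cinv-related pieces) for reuse by variance formulas.
    """
    labels = labels or tree.tip_labels
    C = tree.cov_matrix(labels)
    n = C.shape[0]
    Cinv = np.linalg.inv(C + 1e-12 * np.trace(C) / n * np.eye(n))
    ones = np.ones(n)
    Ci1 = Cinv @ ones
    s = ones @ Ci1
    w = Ci1 / s  # GLS-mean weights
    rows = _shared_depths(tree, labels)
    node_labels = [r[0] for r in rows]
    depths = np.array([r[1] for r in rows])
    cmat = np.vstack([r[2] for r in rows])  # n_internal x n
    A = cmat @ Cinv
    M = A + np.outer(1.0 - A @ ones, w)
    return M, node_labels, depths, cmat, (Cinv, Ci1, s, w)


def edge_change_operator(tree: PhyloTree, labels: list[str] | None = None) -> np.ndarray:
    """Matrix E with one row per branch: |E @ y| summed over rows is the
    total reconstructed state change on the tree for tip values y."""
    labels = labels or tree.tip_labels
    M, node_labels, *_ = reconstruction_operator(tree, labels)
    mrow = dict(zip(node_labels, M))
    tip_row = {lab: np.eye(len(labels))[i] for i, lab in enumerate(labels)}

    def row(node):
        if node.is_leaf():
            return tip_row[node.taxon.label]
        return mrow[node.label]

    rows = []
    for node in tree.dendropy_tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        rows.append(row(node.parent_node) - row(node))
    return np.vstack(rows)


def ancestral_states(
    tree: PhyloTree, tip_values: pd.Series
) -> pd.DataFrame:
    """ML Brownian-motion reconstruction of internal node states.

    Returns a frame indexed by internal node label (preorder; the root
    first) with columns ``estimate`` and ``variance``.  The root estimate
    equals the GLS phylogenetic mean of the tip values.
    """
    labels = tree.tip_labels
    y = tip_values.reindex(labels).to_numpy(dtype=float)
    if np.any(np.isnan(y)):
        raise ValueError("tip_values must cover every tip")
    M, node_labels, depths, cmat, (Cinv, Ci1, s, _w) = reconstruction_operator(
        tree, labels
    )
    est = M @ y
    mu = (Ci1 @ y) / s
    resid = y - mu
    sigma2 = float(resid @ (Cinv @ resid) / len(y))
    var = np.empty(len(node_labels))
    for i, c in enumerate(cmat):
        cc = c @ Cinv @ c
        adj = (1.0 - c @ Ci1) ** 2 / s
        var[i] = sigma2 * max(depths[i] - cc + adj, 0.0)
    return pd.DataFrame(
        {"estimate": est, "variance": var}, index=pd.Index(node_labels, name="node")
    )
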