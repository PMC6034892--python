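"""Granger-causality network inference on BOLD time series.

Fits a multivariate autoregressive (MVAR) model and measures
conditional pairwise Granger causality

    gc(i -> j) = ln( var_reduced(j) / var_full(j) )

where the reduced model omits all lags of node i from node j's equation
while conditioning on every other node.  Significance is assessed with
bootstrap surrogates generated under the reduced (no-causality) model by
residual resampling, followed by Benjamini–Hochberg FDR across all
directed pairs.  Per-node inflow/outflow/netflow degrees over the
significant edges identify the network source (highest outflow and
netflow) and sink (highest inflow).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import TimeSeriesSet
from .stats import fdr_bh

__all__ = [
    "MvarFit",
    "GrangerNetwork",
    "select_order",
    "fit_mvar",
    "granger_matrix",
    "bootstrap_significance",
    "degree_metrics",
    "granger_analysis",
    "remove_nuisance",
]


# ------------------------------------------------------------------- helpers
def _lag_design(X: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Lagged regressor matrix with intercept, and the aligned targets.

    X is time × nodes.  Returns (Z, Y) with Z of shape
    (T - p, n*p + 1): columns are [node0 lag1..lagp, node1 lag1..lagp,
    ..., 1] and Y = X[p:].
    """
    T, n = X.shape
    cols = [X[p - l : T - l, j] for j in range(n) for l in range(1, p + 1)]
    cols.append(np.ones(T - p))
    return np.column_stack(cols), X[p:]


def _node_lag_cols(n: int, p: int, node: int) -> np.ndarray:
    return np.arange(node * p, (node + 1) * p)


def _ols_rss(Z: np.ndarray, y: np.ndarray) -> float:
    coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
    r = y - Z @ coef
    return float(r @ r)


# --------------------------------------------------------------------- types
@dataclass
class MvarFit:
    """Least-squares MVAR(p) fit."""

    order: int
    coeffs: np.ndarray        # (p, n, n): coeffs[l, i, j] = weight of x_j(t-l-1) in x_i(t)
    intercept: np.ndarray     # (n,)
    residuals: np.ndarray     # (T - p, n)
    resid_cov: np.ndarray     # (n, n), ML estimate
    node_labels: tuple[str, ...] = ()

    @property
    def spectral_radius(self) -> float:
        p, n = self.order, self.coeffs.shape[1]
        companion = np.zeros((n * p, n * p))
        companion[:n, :] = np.concatenate(list(self.coeffs), axis=1)
        if p > 1:
            companion[n:, :-n] = np.eye(n * (p - 1))
        return float(np.max(np.abs(np.linalg.eigvals(companion))))

    def log_likelihood(self) -> float:
        """Gaussian ML log-likelihood of the fitted model."""
        t_eff, n = self.residuals.shape
        sign, logdet = np.linalg.slogdet(self.resid_cov)
        if sign <= 0:
            return -np.inf
        return -0.5 * t_eff * (n * np.log(2 * np.pi) + logdet + n)


@dataclass
class GrangerNetwork:
    """Directed causality matrix with significance and degree summaries.

    ``gc[i, j]`` is the causality i -> j (diagonal excluded);
    netflow = outflow - inflow sums to zero over nodes.  ``source`` is
    the node with both the highest outflow and highest netflow (None if
    those disagree; the individual argmaxes are always reported);
    ``sink`` has the highest inflow.
    """

    node_labels: tuple[str, ...]
    gc: np.ndarray
    pvals: np.ndarray
    sig_mask: np.ndarray
    inflow: np.ndarray
    outflow: np.ndarray
    netflow: np.ndarray
    source: str | None
    sink: str | None
    top_outflow: str | None
    top_netflow: str | None
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "node_labels": list(self.node_labels),
            "gc": self.gc.tolist(),
            "pvals": self.pvals.tolist(),
            "sig_mask": self.sig_mask.astype(int).tolist(),
            "inflow": self.inflow.tolist(),
            "outflow": self.outflow.tolist(),
            "netflow": self.netflow.tolist(),
            "source": self.source,
            "sink": self.sink,
            "top_outflow": self.top_outflow,
            "top_netflow": self.top_netflow,
            "meta": self.meta,
        }


# ---------------------------------------------------------------- operations
def remove_nuisance(ts: TimeSeriesSet, confounds: np.ndarray) -> TimeSeriesSet:
    """Regress user-supplied confound columns (plus intercept) out of
    every region's series."""
    C = np.atleast_2d(np.asarray(confounds, float))
    if C.shape[0] != ts.n_time:
        raise ValueError("confound rows must match the series length")
    X = np.column_stack([np.ones(ts.n_time), C])
    beta, *_ = np.linalg.lstsq(X, ts.data.T, rcond=None)
    return ts.copy_with(ts.data - (X @ beta).T, nuisance_removed=C.shape[1])


def fit_mvar(ts: TimeSeriesSet, p: int) -> MvarFit:
    """Least-squares multichannel regression on lagged values."""
    X = ts.data.T
    T, n = X.shape
    if T <= n * p + 1:
        raise ValueError(f"need more than n*p + 1 = {n * p + 1} samples, have {T}")
    Z, Y = _lag_design(X, p)
    coef, _, rank, _ = np.linalg.lstsq(Z, Y, rcond=None)
    if rank < Z.shape[1]:
        raise np.linalg.LinAlgError("singular lag matrix")
    resid = Y - Z @ coef
    # coef rows: node j lag l at index j*p + (l-1); last row intercept
    coeffs = np.empty((p, n, n))
    for j in range(n):
        for l in range(p):
            coeffs[l, :, j] = coef[j * p + l, :]
    intercept = coef[-1, :]
    resid_cov = resid.T @ resid / resid.shape[0]
    return MvarFit(p, coeffs, intercept, resid, resid_cov, ts.region_labels)


def select_order(ts: TimeSeriesSet, max_order: int = 5, criterion: str = "bic") -> int:
    """Model order minimizing BIC (or AIC) over 1..max_order.

    All candidate orders are scored on the common sample starting at
    ``max_order`` so their likelihoods are comparable.
    """
    X = ts.data.T
    T, n = X.shape
    if T <= 10 * max_order * n:
        raise ValueError("insufficient data for order selection")
    t_eff = T - max_order
    scores = []
    for p in range(1, max_order + 1):
        Zf, Yf = _lag_design(X, max_order)
        keep = [j * max_order + l for j in range(n) for l in range(p)] + [n * max_order]
        Z = Zf[:, keep]
        coef, *_ = np.linalg.lstsq(Z, Yf, rcond=None)
        resid = Yf - Z @ coef
        cov = resid.T @ resid / t_eff
        sign, logdet = np.linalg.slogdet(cov)
        k_params = n * (n * p + 1)
        if criterion.lower() == "bic":
            score = logdet + k_params * np.log(t_eff) / t_eff
        elif criterion.lower() == "aic":
            score = logdet + 2.0 * k_params / t_eff
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        scores.append(score)
    return int(np.argmin(scores)) + 1


def granger_matrix(ts: TimeSeriesSet, p: int) -> np.ndarray:
    """Conditional pairwise Granger causality matrix (source × target)."""
    X = ts.data.T
    n = X.shape[1]
    Z, Y = _lag_design(X, p)
    gc = np.zeros((n, n))
    rss_full = np.array([_ols_rss(Z, Y[:, j]) for j in range(n)])
    for j in range(n):
        for i in range(n):
            if i == j:
                continue
            keep = np.setdiff1d(np.arange(Z.shape[1]), _node_lag_cols(n, p, i))
            rss_red = _ols_rss(Z[:, keep], Y[:, j])
            gc[i, j] = np.log(rss_red / rss_full[j])
    return gc


def _reduced_system(fit: MvarFit, X: np.ndarray, p: int, i: int, j: int):
    """Coefficients and residuals of the system in which node j's
    equation omits node i's lags (all other equations stay full)."""
    T, n = X.shape
    Z, Y = _lag_design(X, p)
    keep = np.setdiff1d(np.arange(Z.shape[1]), _node_lag_cols(n, p, i))
    coef_j, *_ = np.linalg.lstsq(Z[:, keep], Y[:, j], rcond=None)
    resid_j = Y[:, j] - Z[:, keep] @ coef_j
    coeffs = fit.coeffs.copy()
    intercept = fit.intercept.copy()
    coeffs[:, j, i] = 0.0
    full_keep = [c for c in keep if c < n * p]
    for pos, c in enumerate(full_keep):
        node, lag = divmod(c, p)
        coeffs[lag, j, node] = coef_j[pos]
    intercept[j] = coef_j[-1]
    residuals = fit.residuals.copy()
    residuals[:, j] = resid_j
    return coeffs, intercept, residuals


def bootstrap_significance(
    ts: TimeSeriesSet,
    p: int,
    n_boot: int = 10_000,
    seed: int | None = 0,
    observed_gc: np.ndarray | None = None,
) -> np.ndarray:
    """Bootstrap-surrogate p-values for every directed pair.

    For each pair (i, j), surrogates are generated under the reduced
    model (node j's equation without node i's lags): residual rows are
    resampled jointly over time — preserving their contemporaneous
    covariance and the null autocorrelation structure — the system is
    re-run forward from the observed initial values, and gc(i -> j) is
    recomputed on each surrogate.  p = (1 + #{surrogate >= observed}) /
    (1 + n_boot), so p is bounded below by 1/(n_boot + 1).
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    X = ts.data.T
    T, n = X.shape
    fit = fit_mvar(ts, p)
    if observed_gc is None:
        observed_gc = granger_matrix(ts, p)
    rng = np.random.default_rng(seed)
    t_eff = T - p
    pvals = np.ones((n, n))
    i_cols_cache = {i: _node_lag_cols(n, p, i) for i in range(n)}
    all_cols = np.arange(n * p + 1)
    for j in range(n):
        for i in range(n):
            if i == j:
                continue
            coeffs, intercept, residuals = _reduced_system(fit, X, p, i, j)
            idx = rng.integers(0, t_eff, size=(n_boot, t_eff))
            E = residuals[idx]  # (n_boot, t_eff, n)
            S = np.empty((n_boot, T, n))
            S[:, :p] = X[:p]
            for t in range(p, T):
                acc = intercept + E[:, t - p]
                for l in range(p):
                    acc = acc + S[:, t - 1 - l] @ coeffs[l].T
                S[:, t] = acc
            # batched gc(i -> j) on surrogates
            Zb = np.empty((n_boot, t_eff, n * p + 1))
            for node in range(n):
                for l in range(1, p + 1):
                    Zb[:, :, node * p + l - 1] = S[:, p - l : T - l, node]
            Zb[:, :, -1] = 1.0
            yb = S[:, p:, j]
            keep = np.setdiff1d(all_cols, i_cols_cache[i])
            rss_full = _batched_rss(Zb, yb)
            rss_red = _batched_rss(Zb[:, :, keep], yb)
            gc_sur = np.log(rss_red / rss_full)
            pvals[i, j] = (1.0 + np.sum(gc_sur >= observed_gc[i, j])) / (1.0 + n_boot)
    return pvals


def _batched_rss(Z: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of OLS fits batched over axis 0."""
    G = np.einsum("btk,btl->bkl", Z, Z)
    b = np.einsum("btk,bt->bk", Z, y)
    # small ridge for numerical safety on near-singular surrogates
    G = G + 1e-10 * np.eye(Z.shape[2])[None]
    coef = np.linalg.solve(G, b[..., None])[..., 0]
    yy = np.einsum("bt,bt->b", y, y)
    return np.maximum(yy - np.einsum("bk,bk->b", b, coef), 1e-300)


def degree_metrics(
    gc: np.ndarray,
    sig_mask: np.ndarray,
    node_labels: tuple[str, ...] | None = None,
    pvals: np.ndarray | None = None,
    weighted: bool = True,
) -> GrangerNetwork:
    """Degree summaries and source/sink labelling over significant edges.

    outflow(k) = sum_j gc(k -> j) * mask, inflow(k) = sum_j gc(j -> k) *
    mask (binary counts when ``weighted`` is false); netflow = outflow -
    inflow.  The source label requires the same node to maximize both
    outflow and netflow; the sink is the highest-inflow node.  With no
    significant edge, degrees are zero and labels undefined.
    """
    gc = np.asarray(gc, float)
    mask = np.asarray(sig_mask, bool)
    if gc.shape != mask.shape or gc.shape[0] != gc.shape[1]:
        raise ValueError("gc and sig_mask must be square and same shape")
    n = gc.shape[0]
    if node_labels is None:
        node_labels = tuple(f"node{k + 1}" for k in range(n))
    mask = mask & ~np.eye(n, dtype=bool)
    W = (gc * mask) if weighted else mask.astype(float)
    outflow = W.sum(axis=1)
    inflow = W.sum(axis=0)
    netflow = outflow - inflow
    if not mask.any():
        source = sink = top_out = top_net = None
    else:
        k_out = int(np.argmax(outflow))
        k_net = int(np.argmax(netflow))
        k_in = int(np.argmax(inflow))
        top_out = node_labels[k_out]
        top_net = node_labels[k_net]
        source = node_labels[k_out] if k_out == k_net else None
        sink = node_labels[k_in]
    return GrangerNetwork(
        node_labels=tuple(node_labels),
        gc=gc,
        pvals=pvals if pvals is not None else np.full_like(gc, np.nan),
        sig_mask=mask,
        inflow=inflow,
        outflow=outflow,
        netflow=netflow,
        source=source,
        sink=sink,
        top_outflow=top_out,
        top_netflow=top_net,
        meta={"weighted": weighted},
    )


def granger_analysis(
    ts: TimeSeriesSet,
    p: int | None = None,
    max_order: int = 5,
    n_boot: int = 10_000,
    q: float = 0.05,
    seed: int | None = 0,
    confounds: np.ndarray | None = None,
    weighted: bool = True,
) -> GrangerNetwork:
    """Full network inference: optional nuisance removal, order
    selection, conditional GC, bootstrap significance, edge-wise FDR at
    level ``q`` over all n(n-1) directed pairs, and degree metrics."""
    if confounds is not None:
        ts = remove_nuisance(ts, confounds)
    if p is None:
        p = select_order(ts, max_order=max_order)
    gc = granger_matrix(ts, p)
    pvals = bootstrap_significance(ts, p, n_boot=n_boot, seed=seed, observed_gc=gc)
    n = gc.shape[0]
    off = ~np.eye(n, dtype=bool)
    reject, _ = fdr_bh(pvals[off], q=q)
    mask = np.zeros_like(off)
    mask[off] = reject
    net = degree_metrics(gc, mask, ts.region_labels, pvals=pvals, weighted=weighted)
    net.meta.update({"order": p, "n_boot": n_boot, "q": q, "seed": seed})
    return net
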