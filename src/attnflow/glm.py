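"""Subject-level GLM with two-gamma HRF convolution and group random effects.

The whole-brain search is emulated at parcel scale: each "region" plays
the role of a voxel.  Subject-level fits are ordinary least squares on a
design of HRF-convolved task predictors plus nuisance regressors and an
intercept; the group analysis is a one-sample t across subjects on a
contrast per region, thresholded with Benjamini–Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .containers import BlockDesign, TimeSeriesSet
from .stats import fdr_bh, one_sample_t

__all__ = [
    "two_gamma_hrf",
    "DesignMatrix",
    "build_design_matrix",
    "GlmFit",
    "fit_glm",
    "group_rfx_contrast",
]

#: Field-standard two-gamma parameters: response peak 6 s, undershoot
#: peak 16 s, dispersions 1, undershoot ratio 1/6, kernel length 32 s.
HRF_DEFAULTS = dict(
    peak_delay=6.0, undershoot_delay=16.0, peak_disp=1.0,
    undershoot_disp=1.0, undershoot_ratio=1.0 / 6.0, length=32.0,
)


def two_gamma_hrf(tr: float, oversampling: int = 16, **params) -> np.ndarray:
    """Canonical two-gamma hemodynamic impulse response, unit sum.

    Sampled on the fine grid ``tr / oversampling``; the kernel covers
    ``length`` seconds (default 32 s).  The difference of two gamma
    densities is normalized so the kernel sums to one, making the
    convolution of a sustained boxcar plateau at the boxcar height.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    p = {**HRF_DEFAULTS, **params}
    dt = tr / oversampling
    t = np.arange(0.0, p["length"] + dt / 2, dt)
    peak = sps.gamma.pdf(t, p["peak_delay"] / p["peak_disp"], scale=p["peak_disp"])
    under = sps.gamma.pdf(
        t, p["undershoot_delay"] / p["undershoot_disp"], scale=p["undershoot_disp"]
    )
    h = peak - p["undershoot_ratio"] * under
    return h / h.sum()


@dataclass
class DesignMatrix:
    """Labeled time × regressor matrix (task, nuisance, intercept columns)."""

    columns: tuple[str, ...]
    values: np.ndarray
    task_columns: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, float))
        if self.values.shape[1] != len(self.columns):
            raise ValueError("column count mismatch")

    @property
    def n_time(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.columns.index(name)]

    def contrast_vector(self, weights: dict[str, float]) -> np.ndarray:
        c = np.zeros(len(self.columns))
        for name, w in weights.items():
            c[self.columns.index(name)] = w
        return c


def build_design_matrix(
    design: BlockDesign,
    hrf: np.ndarray | None = None,
    nuisance: np.ndarray | None = None,
    nuisance_names: list[str] | None = None,
) -> DesignMatrix:
    """[HRF-convolved task columns | nuisance | intercept].

    Task boxcars are convolved with the HRF at microtime resolution and
    then downsampled to the TR grid.  Raises on a rank-deficient result.
    """
    if hrf is None:
        hrf = two_gamma_hrf(design.tr, design.microtime_bins)
    cols: list[np.ndarray] = []
    names: list[str] = []
    for cond in design.condition_names:
        fine = np.convolve(design.boxcar(cond), hrf)[: design.n_fine]
        cols.append(fine[:: design.microtime_bins])
        names.append(cond)
    task = tuple(names)
    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, float))
        if nuisance.shape[0] != design.n_scans:
            raise ValueError(
                f"nuisance has {nuisance.shape[0]} rows; expected {design.n_scans}"
            )
        for k in range(nuisance.shape[1]):
            cols.append(nuisance[:, k])
            names.append(
                nuisance_names[k] if nuisance_names else f"nuisance_{k}"
            )
    cols.append(np.ones(design.n_scans))
    names.append("intercept")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    return DesignMatrix(tuple(names), X, task_columns=task, meta={"hrf": "two-gamma"})


@dataclass
class GlmFit:
    """OLS estimates per region with residual variance and df."""

    region_labels: tuple[str, ...]
    columns: tuple[str, ...]
    betas: np.ndarray          # regions × columns
    sigma2: np.ndarray         # regions
    df: int
    xtx_inv: np.ndarray
    residuals: np.ndarray      # regions × time

    def contrast_t(self, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """t and two-tailed p per region for contrast vector ``c``."""
        c = np.asarray(c, float)
        eff = self.betas @ c
        var = self.sigma2 * float(c @ self.xtx_inv @ c)
        t = eff / np.sqrt(var)
        p = 2.0 * sps.t.sf(np.abs(t), self.df)
        return t, p

    def contrast_value(self, c: np.ndarray) -> np.ndarray:
        return self.betas @ np.asarray(c, float)


def fit_glm(ts: TimeSeriesSet, X: DesignMatrix) -> GlmFit:
    """Ordinary least squares per region; df = T - rank(X)."""
    if X.n_time != ts.n_time:
        raise ValueError(f"design has {X.n_time} rows; series has {ts.n_time}")
    V = X.values
    rank = np.linalg.matrix_rank(V)
    if rank < V.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    xtx_inv = np.linalg.inv(V.T @ V)
    betas = ts.data @ V @ xtx_inv          # (regions × cols)
    resid = ts.data - betas @ V.T
    df = ts.n_time - rank
    sigma2 = (resid**2).sum(axis=1) / df
    return GlmFit(ts.region_labels, X.columns, betas, sigma2, df, xtx_inv, resid)


def group_rfx_contrast(
    subject_contrast_values: np.ndarray,
    q: float = 0.05,
    region_labels: tuple[str, ...] | None = None,
) -> dict:
    """Random-effects group test: one-sample t across subjects per region.

    ``subject_contrast_values`` is subjects × regions.  Regions are
    thresholded with BH-FDR at level ``q``.
    """
    vals = np.atleast_2d(np.asarray(subject_contrast_values, float))
    n_sub, n_reg = vals.shape
    if n_sub < 2:
        raise ValueError("need at least 2 subjects")
    t = np.empty(n_reg)
    p = np.empty(n_reg)
    for r in range(n_reg):
        res = one_sample_t(vals[:, r])
        t[r], p[r] = res.statistic, res.p
    reject, p_adj = fdr_bh(p, q=q)
    return {
        "t": t,
        "p": p,
        "p_fdr": p_adj,
        "significant": reject,
        "df": n_sub - 1,
        "region_labels": region_labels,
    }
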