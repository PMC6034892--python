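"""Bilinear dynamic causal modelling: forward model and Bayesian inversion.

The neural model is the bilinear state equation

    dz/dt = (A + sum_j u_j(t) B_j) z + C u(t)

with intrinsic coupling A (Hz), one modulatory matrix B_j per
experimental input, and driving weights C.  Neural activity z drives a
balloon–Windkessel hemodynamic cascade per region (vasodilatory signal
s, blood flow f, venous volume v, deoxyhemoglobin q) observed through
the standard nonlinear BOLD equation, expressed in percent signal about
zero.

Inversion is a variational-Laplace scheme: a Gaussian posterior over
the free parameters obtained by Fisher-scoring / Gauss–Newton ascent on
a free-energy bound F = accuracy - complexity, with step halving when a
candidate update lowers F and an outer loop re-estimating per-region
observation noise.  F is the per-subject log-evidence approximation
consumed by random-effects Bayesian model selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .containers import ALL_VISUAL, BlockDesign, TimeSeriesSet
from .stats import StatResult, one_sample_t

__all__ = [
    "NeuralParams",
    "HemoParams",
    "DCMSpec",
    "DCMPriors",
    "DCMFit",
    "integrate_dcm",
    "fit_dcm",
    "effective_strength",
    "posterior_edge_test",
    "IntegrationDivergedError",
]

log = logging.getLogger(__name__)

SELF_SCALE = -0.5  # A_ii = SELF_SCALE * exp(theta_self); keeps self-decay negative


class IntegrationDivergedError(RuntimeError):
    pass


# --------------------------------------------------------------------------- types
@dataclass(frozen=True)
class HemoParams:
    """Balloon–Windkessel constants (literature defaults).

    kappa: vasodilatory signal decay rate (1/s); gamma: flow
    autoregulation rate (1/s); tau: venous transit time (s); alpha:
    vessel stiffness exponent; e0: resting oxygen extraction fraction;
    v0: resting venous blood volume fraction.
    """

    kappa: float = 0.64
    gamma: float = 0.32
    tau: float = 2.0
    alpha: float = 0.32
    e0: float = 0.4
    v0: float = 0.04

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma", "tau", "v0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.alpha < 1) or not (0 < self.e0 < 1):
            raise ValueError("alpha and e0 must lie in (0, 1)")


@dataclass(frozen=True)
class DCMSpec:
    """Network structure: regions, input labels, and A/B/C masks.

    ``a_mask[i, j]`` allows intrinsic coupling j -> i (the diagonal is
    implicitly always present as self-decay).  ``b_masks[name][i, j]``
    allows modulation of that edge by input ``name``; ``c_masks[name]``
    marks regions receiving that input as a driving input.  Input names
    refer to design conditions (or :data:`~attnflow.containers.ALL_VISUAL`).
    """

    regions: tuple[str, ...]
    a_mask: np.ndarray
    b_masks: Mapping[str, np.ndarray]
    c_masks: Mapping[str, np.ndarray]
    name: str = ""

    def __post_init__(self) -> None:
        n = len(self.regions)
        a = np.asarray(self.a_mask, bool)
        if a.shape != (n, n):
            raise ValueError("a_mask must be n x n")
        object.__setattr__(self, "a_mask", a)
        b = {}
        for k, m in self.b_masks.items():
            m = np.asarray(m, bool)
            if m.shape != (n, n):
                raise ValueError(f"b_mask for {k!r} must be n x n")
            if np.any(m & ~(a | np.eye(n, dtype=bool))):
                raise ValueError(f"b_mask for {k!r} modulates edges absent from a_mask")
            b[k] = m
        object.__setattr__(self, "b_masks", b)
        c = {}
        for k, v in self.c_masks.items():
            v = np.asarray(v, bool).ravel()
            if v.shape != (n,):
                raise ValueError(f"c_mask for {k!r} must have length n")
            c[k] = v
        object.__setattr__(self, "c_masks", c)
        if not any(v.any() for v in c.values()):
            raise ValueError("spec needs at least one driving input")

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def inputs(self) -> tuple[str, ...]:
        """Ordered union of modulatory and driving input labels."""
        names = list(self.b_masks) + [k for k in self.c_masks if k not in self.b_masks]
        return tuple(names)

    def index(self, region: str) -> int:
        return self.regions.index(region)

    def edge_index(self, edge: tuple[str, str]) -> tuple[int, int]:
        """(row, col) of edge (source, target): A[target, source]."""
        src, dst = edge
        return self.index(dst), self.index(src)

    def to_dict(self) -> dict:
        return {
            "regions": list(self.regions),
            "a": self.a_mask.astype(int).tolist(),
            "b": {k: v.astype(int).tolist() for k, v in self.b_masks.items()},
            "c": {k: v.astype(int).tolist() for k, v in self.c_masks.items()},
            "name": self.name,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DCMSpec":
        return cls(
            regions=tuple(d["regions"]),
            a_mask=np.asarray(d["a"], bool),
            b_masks={k: np.asarray(v, bool) for k, v in d["b"].items()},
            c_masks={k: np.asarray(v, bool) for k, v in d["c"].items()},
            name=d.get("name", ""),
        )


@dataclass(frozen=True)
class NeuralParams:
    """Numeric A/B/C parameters conforming to a :class:`DCMSpec`.

    ``A`` is n x n (Hz) with strictly negative diagonal; ``B`` maps
    input name -> n x n modulatory matrix; ``C`` maps input name ->
    length-n driving weights.
    """

    A: np.ndarray
    B: Mapping[str, np.ndarray]
    C: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        A = np.asarray(self.A, float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("A must be square")
        if np.any(np.diag(A) >= 0):
            raise ValueError("diagonal of A must be strictly negative (self-decay)")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", {k: np.asarray(v, float) for k, v in self.B.items()})
        object.__setattr__(self, "C", {k: np.asarray(v, float).ravel() for k, v in self.C.items()})

    def validate_against(self, spec: DCMSpec) -> None:
        n = spec.n_regions
        offdiag = ~np.eye(n, dtype=bool)
        if np.any((self.A != 0) & offdiag & ~spec.a_mask):
            raise ValueError("A has entries outside the spec a_mask")
        for k, m in self.B.items():
            if np.any((m != 0) & ~spec.b_masks.get(k, np.zeros((n, n), bool))):
                raise ValueError(f"B[{k!r}] has entries outside its mask")
        for k, v in self.C.items():
            if np.any((v != 0) & ~spec.c_masks.get(k, np.zeros(n, bool))):
                raise ValueError(f"C[{k!r}] has entries outside its mask")


# ---------------------------------------------------------------- integration
def _stack_inputs(spec: DCMSpec, design: BlockDesign) -> np.ndarray:
    return design.inputs(spec.inputs)


def _integrate_batch(
    A: np.ndarray,
    B: np.ndarray,
    C: np.ndarray,
    u: np.ndarray,
    dt: float,
    microtime_bins: int,
    hemo: HemoParams,
) -> np.ndarray:
    """Euler-integrate a batch of bilinear DCMs on the fine grid.

    A: (batch, n, n); B: (batch, m, n, n); C: (batch, n, m);
    u: (m, n_fine).  Flow, volume and dHb are integrated in log space
    to preserve positivity.  Returns BOLD (batch, n, n_scans) in
    percent signal about zero, sampled at the start of each TR.
    Non-finite trajectories are returned as NaN rows (the caller
    decides whether to raise).
    """
    batch, n = A.shape[0], A.shape[1]
    m, n_fine = u.shape
    n_scans = n_fine // microtime_bins
    kappa, gamma, tau = hemo.kappa, hemo.gamma, hemo.tau
    ialpha = 1.0 / hemo.alpha
    e0, v0 = hemo.e0, hemo.v0
    k1, k2, k3 = 7.0 * e0, 2.0, 2.0 * e0 - 0.2

    z = np.zeros((batch, n))
    s = np.zeros((batch, n))
    lf = np.zeros((batch, n))
    lv = np.zeros((batch, n))
    lq = np.zeros((batch, n))
    y = np.empty((batch, n, n_scans))
    saturated = np.zeros(batch, bool)

    has_b = bool(m) and np.any(B)

    def deriv(state, ut):
        z, s, lf, lv, lq = state
        if has_b and ut.any():
            Aeff = A + np.tensordot(ut, B, axes=([0], [1]))
            dz = np.einsum("bij,bj->bi", Aeff, z)
        else:
            dz = np.einsum("bij,bj->bi", A, z)
        if m:
            dz = dz + C @ ut
        f = np.exp(lf)
        v = np.exp(lv)
        q = np.exp(lq)
        E = 1.0 - (1.0 - e0) ** (1.0 / f)
        ds = z - kappa * s - gamma * (f - 1.0)
        dlf = s / f
        dlv = (f - v**ialpha) / (tau * v)
        dlq = (f * E / e0 / q - v ** (ialpha - 1.0)) / tau
        return dz, ds, dlf, dlv, dlq

    state = (z, s, lf, lv, lq)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        for i in range(n_fine):
            if i % microtime_bins == 0:
                v = np.exp(state[3])
                q = np.exp(state[4])
                y[:, :, i // microtime_bins] = 100.0 * v0 * (
                    k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v)
                )
            ut = u[:, i]
            ut_next = u[:, i + 1] if i + 1 < n_fine else ut
            # Heun step: Euler predictor, trapezoidal corrector
            d1 = deriv(state, ut)
            pred = tuple(x + dt * dx for x, dx in zip(state, d1))
            d2 = deriv(pred, ut_next)
            state = tuple(
                x + 0.5 * dt * (da + db) for x, da, db in zip(state, d1, d2)
            )
            z, s, lf, lv, lq = state
            # saturation bounds keep runaway trajectories finite; hitting
            # them marks the batch member as diverged
            saturated |= np.abs(z).max(axis=1) >= 50.0
            state = (
                np.clip(z, -50.0, 50.0),
                s,
                np.clip(lf, -4.0, 4.0),
                np.clip(lv, -4.0, 4.0),
                np.clip(lq, -4.0, 4.0),
            )

    bad = saturated | ~np.isfinite(y).all(axis=(1, 2))
    if bad.any():
        y[bad] = np.nan
    return y


def integrate_dcm(
    spec: DCMSpec,
    neural: NeuralParams,
    hemo: HemoParams,
    design: BlockDesign,
) -> TimeSeriesSet:
    """Forward model: neural dynamics + hemodynamics, sampled at TR.

    Output is percent BOLD signal about zero; identically zero when all
    inputs are silent (the rest state is a fixed point).
    """
    neural.validate_against(spec)
    u = _stack_inputs(spec, design)
    inputs = spec.inputs
    n = spec.n_regions
    B = np.stack(
        [neural.B.get(k, np.zeros((n, n))) for k in inputs], axis=0
    ) if inputs else np.zeros((0, n, n))
    C = np.stack(
        [neural.C.get(k, np.zeros(n)) for k in inputs], axis=1
    ) if inputs else np.zeros((n, 0))
    y = _integrate_batch(
        neural.A[None], B[None], C[None], u, design.dt, design.microtime_bins, hemo
    )[0]
    if not np.all(np.isfinite(y)):
        bad = [spec.regions[r] for r in np.where(~np.isfinite(y).all(axis=1))[0]]
        raise IntegrationDivergedError(
            f"integration diverged in region(s) {bad}; check stability of A"
        )
    return TimeSeriesSet(spec.regions, y, design.tr, {"source": "integrate_dcm"})


def unstable_eigenvalues(spec: DCMSpec, neural: NeuralParams) -> bool:
    """True if the effective A has an eigenvalue with positive real part
    for the input-off or any single input-on configuration."""
    n = spec.n_regions
    mats = [neural.A]
    for k in spec.inputs:
        mats.append(neural.A + neural.B.get(k, np.zeros((n, n))))
    return any(np.max(np.linalg.eigvals(Mt).real) > 0 for Mt in mats)


# -------------------------------------------------------------------- priors
@dataclass(frozen=True)
class DCMPriors:
    """Gaussian shrinkage priors on the free parameters.

    Off-diagonal A entries ~ N(0, 1/64); modulatory B and driving C
    entries ~ N(0, 1); log self-decay scalings ~ N(0, 1/4) with
    A_ii = -0.5 exp(theta), so region time constants can range over
    roughly 0.7-5.5 s at two prior sd — wide enough to capture
    heterogeneous intrinsic dynamics (a near-delta prior on the log
    scaling would pin every self-decay at -0.5/s and make regions with
    slow integrative dynamics unrepresentable).  ``overrides`` pins
    individual parameters by label, e.g.
    ``{"b:Same:IFJ->IMT+": (0.0, 0.0)}`` clamps that entry (zero prior
    variance fixes the posterior at the prior mean).
    """

    var_a: float = 1.0 / 64.0
    var_b: float = 1.0
    var_c: float = 1.0
    var_self: float = 0.25
    overrides: Mapping[str, tuple[float, float]] = field(default_factory=dict)


def _param_layout(spec: DCMSpec) -> list[tuple[str, str, tuple]]:
    """Ordered free-parameter labels: (block, label, index-info)."""
    n = spec.n_regions
    layout: list[tuple[str, str, tuple]] = []
    offdiag = spec.a_mask & ~np.eye(n, dtype=bool)
    for i, j in zip(*np.where(offdiag)):
        layout.append(("a", f"a:{spec.regions[j]}->{spec.regions[i]}", (int(i), int(j))))
    for i in range(n):
        layout.append(("self", f"a_self:{spec.regions[i]}", (i, i)))
    for k in spec.inputs:
        mask = spec.b_masks.get(k)
        if mask is None:
            continue
        for i, j in zip(*np.where(mask)):
            layout.append(("b", f"b:{k}:{spec.regions[j]}->{spec.regions[i]}", (k, int(i), int(j))))
    for k in spec.inputs:
        cm = spec.c_masks.get(k)
        if cm is None:
            continue
        for (i,) in zip(*np.where(cm)):
            layout.append(("c", f"c:{k}:{spec.regions[i]}", (k, int(i))))
    return layout


def _theta_to_neural(theta: np.ndarray, spec: DCMSpec, layout) -> NeuralParams:
    n = spec.n_regions
    A = np.zeros((n, n))
    B = {k: np.zeros((n, n)) for k in spec.b_masks}
    C = {k: np.zeros(n) for k in spec.c_masks}
    for val, (block, _label, info) in zip(theta, layout):
        if block == "a":
            A[info] = val
        elif block == "self":
            A[info] = SELF_SCALE * np.exp(val)
        elif block == "b":
            k, i, j = info
            B[k][i, j] = val
        else:
            k, i = info
            C[k][i] = val
    return NeuralParams(A, B, C)


def _batch_mats(thetas: np.ndarray, spec: DCMSpec, layout):
    """Vectorized theta (batch, p) -> stacked A, B, C arrays."""
    batch = thetas.shape[0]
    n = spec.n_regions
    inputs = spec.inputs
    m = len(inputs)
    A = np.zeros((batch, n, n))
    B = np.zeros((batch, m, n, n))
    C = np.zeros((batch, n, m))
    input_pos = {k: idx for idx, k in enumerate(inputs)}
    for col, (block, _label, info) in enumerate(layout):
        vals = thetas[:, col]
        if block == "a":
            A[:, info[0], info[1]] = vals
        elif block == "self":
            A[:, info[0], info[1]] = SELF_SCALE * np.exp(vals)
        elif block == "b":
            k, i, j = info
            B[:, input_pos[k], i, j] = vals
        else:
            k, i = info
            C[:, i, input_pos[k]] = vals
    return A, B, C


@dataclass
class DCMFit:
    """Gaussian posterior over DCM parameters with free-energy evidence."""

    spec: DCMSpec
    param_labels: tuple[str, ...]
    theta: np.ndarray
    cov: np.ndarray
    free_energy: float
    sigma2: np.ndarray
    predicted: np.ndarray
    converged: bool
    n_iter: int
    f_trace: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def neural(self) -> NeuralParams:
        return _theta_to_neural(self.theta, self.spec, _param_layout(self.spec))

    def posterior_mean(self, label: str) -> float:
        return float(self.theta[self.param_labels.index(label)])

    def posterior_sd(self, label: str) -> float:
        i = self.param_labels.index(label)
        return float(np.sqrt(self.cov[i, i]))

    def a_mean(self) -> np.ndarray:
        return self.neural.A

    def b_mean(self, input_label: str) -> np.ndarray:
        return self.neural.B[input_label]

    def modulatory_mean(self, input_label: str, edge: tuple[str, str]) -> float:
        i, j = self.spec.edge_index(edge)
        return float(self.neural.B[input_label][i, j])

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "param_labels": list(self.param_labels),
            "posterior_mean": self.theta.tolist(),
            "posterior_sd": np.sqrt(np.diag(self.cov)).tolist(),
            "free_energy": self.free_energy,
            "sigma2": self.sigma2.tolist(),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "meta": self.meta,
        }


DEFAULT_FIT_OPTIONS = dict(max_iter=128, tol=0.01, fd_step=1e-3, max_halvings=6)


def fit_dcm(
    ts: TimeSeriesSet,
    spec: DCMSpec,
    design: BlockDesign,
    priors: DCMPriors | None = None,
    hemo: HemoParams | None = None,
    options: Mapping | None = None,
) -> DCMFit:
    """Variational-Laplace inversion of a bilinear DCM.

    Gauss–Newton / Fisher-scoring updates on the Laplace free energy
    with step halving on F decrease; per-region observation variance is
    re-estimated in an outer loop.  Convergence when the F improvement
    falls below ``tol`` nats (default 0.01) or after ``max_iter``
    iterations (default 128); non-convergence is flagged, not raised.
    """
    if tuple(ts.region_labels) != tuple(spec.regions):
        raise ValueError("time-series regions must match spec regions")
    priors = priors or DCMPriors()
    hemo = hemo or HemoParams()
    opt = {**DEFAULT_FIT_OPTIONS, **(options or {})}

    layout = _param_layout(spec)
    labels = tuple(lb for _, lb, _ in layout)
    block_var = {"a": priors.var_a, "b": priors.var_b, "c": priors.var_c,
                 "self": priors.var_self}
    mu0 = np.zeros(len(layout))
    var0 = np.array([block_var[b] for b, _, _ in layout])
    for idx, lb in enumerate(labels):
        if lb in priors.overrides:
            mu0[idx], var0[idx] = priors.overrides[lb]
    free = var0 > 0
    p0_diag = np.zeros_like(var0)
    p0_diag[free] = 1.0 / var0[free]

    u = _stack_inputs(spec, design)
    mtb = design.microtime_bins
    dt = design.dt
    Y = ts.data
    n, T = Y.shape

    def forward(thetas: np.ndarray) -> np.ndarray:
        A, B, C = _batch_mats(thetas, spec, layout)
        return _integrate_batch(A, B, C, u, dt, mtb, hemo)

    n_free = int(free.sum())
    free_idx = np.where(free)[0]

    theta = mu0.copy()
    g = forward(theta[None])[0]
    if not np.all(np.isfinite(g)):
        raise IntegrationDivergedError("prior-mean integration diverged")
    resid = Y - g
    sigma2 = np.maximum(resid.var(axis=1), 1e-6)

    def free_energy(resid: np.ndarray, sigma2: np.ndarray, theta: np.ndarray,
                    logdet_h: float | None) -> float:
        acc = -0.5 * np.sum(resid**2 / sigma2[:, None]) - 0.5 * T * np.sum(np.log(sigma2))
        dth = theta - mu0
        comp = 0.5 * np.sum(p0_diag[free] * dth[free] ** 2)
        f = acc - comp
        if logdet_h is not None:
            logdet_p0 = float(np.sum(np.log(p0_diag[free])))
            f += 0.5 * (logdet_p0 - logdet_h)
        return float(f)

    fd = opt["fd_step"]
    F = -np.inf
    f_trace: list[float] = []
    converged = False
    H = np.eye(n_free)
    it = 0
    for it in range(1, opt["max_iter"] + 1):
        # finite-difference Jacobian over the free parameters, batched
        thetas = np.repeat(theta[None], n_free + 1, axis=0)
        for k, idx in enumerate(free_idx):
            thetas[k + 1, idx] += fd
        out = forward(thetas)
        if not np.all(np.isfinite(out[0])):
            raise IntegrationDivergedError("integration diverged during fit")
        g = out[0]
        J = (out[1:] - g[None]) / fd          # (n_free, n, T)
        J[~np.isfinite(J)] = 0.0
        resid = Y - g

        w = 1.0 / sigma2                       # per-region precision
        Jw = J * w[None, :, None]
        Hs = np.einsum("anT,bnT->ab", Jw, J)   # J' Pi J
        grad = np.einsum("anT,nT->a", Jw, resid) - p0_diag[free] * (theta[free] - mu0[free])
        H = Hs + np.diag(p0_diag[free])
        # ridge-repair if ill-conditioned
        jitter = 0.0
        for _ in range(6):
            try:
                L = np.linalg.cholesky(H + jitter * np.eye(n_free))
                break
            except np.linalg.LinAlgError:
                jitter = max(jitter * 10.0, 1e-6)
        else:
            raise np.linalg.LinAlgError("posterior Hessian not positive definite")
        if jitter:
            log.warning("fit_dcm: ridge-repaired Hessian (jitter %.1e)", jitter)
            H = H + jitter * np.eye(n_free)
        logdet_h = 2.0 * float(np.sum(np.log(np.diag(L))))
        step_full = np.linalg.solve(H, grad)

        F_cur = free_energy(resid, sigma2, theta, logdet_h)
        # step-halving line search on F (sigma2 held fixed within the step)
        accepted = False
        cand, g_c, r_c = theta, g, resid
        scale = 1.0
        for _ in range(opt["max_halvings"] + 1):
            cand = theta.copy()
            cand[free] = theta[free] + scale * step_full
            g_c = forward(cand[None])[0]
            if np.all(np.isfinite(g_c)):
                r_c = Y - g_c
                F_c = free_energy(r_c, sigma2, cand, logdet_h)
                if F_c > F_cur or scale <= 2.0 ** (-opt["max_halvings"]):
                    accepted = F_c > F_cur
                    break
            scale *= 0.5
        if accepted:
            theta = cand
            g = g_c
            resid = r_c
        # outer loop: ML update of observation variance (weak floor)
        sigma2 = np.maximum((resid**2).mean(axis=1), 1e-8)
        F_new = free_energy(resid, sigma2, theta, logdet_h)
        f_trace.append(F_new)
        if accepted and abs(F_new - F) < opt["tol"]:
            F = F_new
            converged = True
            break
        if not accepted and it > 2:
            F = F_new
            break
        F = F_new

    cov_free = np.linalg.inv(H)
    cov = np.zeros((len(layout), len(layout)))
    cov[np.ix_(free, free)] = cov_free
    cov[~free, ~free] = var0[~free]
    return DCMFit(
        spec=spec,
        param_labels=labels,
        theta=theta,
        cov=cov,
        free_energy=F,
        sigma2=sigma2,
        predicted=g,
        converged=converged,
        n_iter=it,
        f_trace=f_trace,
        meta={"hemo": vars(hemo) if not isinstance(hemo, HemoParams) else hemo.__dict__,
              "options": dict(opt)},
    )


def effective_strength(fit: DCMFit, edge: tuple[str, str], input_label: str) -> float:
    """Effective connection strength: intrinsic + modulatory posterior means."""
    i, j = fit.spec.edge_index(edge)
    if not fit.spec.a_mask[i, j]:
        raise ValueError(f"edge {edge} not present in the model")
    neural = fit.neural
    b = neural.B.get(input_label)
    if b is None:
        raise ValueError(f"unknown modulatory input {input_label!r}")
    return float(neural.A[i, j] + b[i, j])


def posterior_edge_test(
    fits: Sequence[DCMFit], edge: tuple[str, str], input_label: str
) -> StatResult:
    """One-sample t across subjects on the modulatory posterior means."""
    vals = [f.modulatory_mean(input_label, edge) for f in fits]
    return one_sample_t(np.asarray(vals))
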