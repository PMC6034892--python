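"""Random-effects Bayesian model selection and model averaging.

Treats the model identity as a random effect across subjects: model
frequencies r follow a Dirichlet(alpha) posterior estimated by a
variational scheme from the subjects x models table of log evidences
(free energies).  The exceedance probability of model k is the
posterior probability that r_k is the largest frequency — the
probability that model k is more likely than any competitor to have
generated the data of a randomly selected subject.  Family-level
inference sums frequencies within families (with prior mass equalized
across families), and Bayesian model averaging marginalizes parameter
estimates over models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import betainc, digamma, logsumexp

from .model_space import FamilyPartition

__all__ = [
    "BMSResult",
    "rfx_bms",
    "exceedance_prob",
    "exceedance_prob_exact2",
    "family_inference",
    "bma",
]


@dataclass(frozen=True)
class BMSResult:
    """Dirichlet posterior over model (or family) frequencies."""

    model_ids: tuple[str, ...]
    alpha: np.ndarray
    expected_prob: np.ndarray
    exceedance: np.ndarray
    responsibilities: np.ndarray | None = None  # subjects × models
    meta: dict = field(default_factory=dict)

    def best(self) -> str:
        return self.model_ids[int(np.argmax(self.exceedance))]

    def to_dict(self) -> dict:
        return {
            "model_ids": list(self.model_ids),
            "alpha": self.alpha.tolist(),
            "expected_prob": self.expected_prob.tolist(),
            "exceedance": self.exceedance.tolist(),
            "meta": self.meta,
        }


def exceedance_prob(
    alpha: np.ndarray, n_draws: int = 1_000_000, seed: int | None = 0
) -> np.ndarray:
    """Monte-Carlo exceedance probabilities of a Dirichlet(alpha).

    Fraction of draws in which each component is maximal.  For K = 2 the
    exact Beta-CDF expression (:func:`exceedance_prob_exact2`) is used.
    """
    alpha = np.asarray(alpha, float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be positive")
    k = alpha.size
    if k == 2:
        return exceedance_prob_exact2(alpha)
    rng = np.random.default_rng(seed)
    counts = np.zeros(k)
    chunk = 200_000
    remaining = n_draws
    while remaining > 0:
        m = min(chunk, remaining)
        draws = rng.standard_gamma(alpha, size=(m, k))
        counts += np.bincount(np.argmax(draws, axis=1), minlength=k)
        remaining -= m
    return counts / n_draws


def exceedance_prob_exact2(alpha: np.ndarray) -> np.ndarray:
    """Exact two-model exceedance: P(r1 > 1/2) under Beta(a1, a2)."""
    a1, a2 = np.asarray(alpha, float)
    p2 = betainc(a1, a2, 0.5)  # P(r1 < 1/2)
    return np.array([1.0 - p2, p2])


def _vb_dirichlet(
    log_evidence: np.ndarray, alpha0: np.ndarray, max_iter: int = 500, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """Variational update of Dirichlet concentrations (RFX-BMS).

    Iterates subject-wise posterior model probabilities
    u_nk ∝ exp(logev_nk + psi(alpha_k) - psi(sum alpha)) and
    alpha = alpha0 + sum_n u_nk until max |delta alpha| < tol.
    """
    L = np.asarray(log_evidence, float)
    alpha = alpha0.astype(float).copy()
    for _ in range(max_iter):
        logu = L + (digamma(alpha) - digamma(alpha.sum()))[None, :]
        logu -= logsumexp(logu, axis=1, keepdims=True)
        u = np.exp(logu)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    return alpha, u


def rfx_bms(
    evidence: np.ndarray | Mapping[str, Sequence[float]],
    model_ids: Sequence[str] | None = None,
    alpha0: float | np.ndarray = 1.0,
    n_draws: int = 1_000_000,
    seed: int | None = 0,
) -> BMSResult:
    """Random-effects BMS from a subjects × models log-evidence table."""
    if isinstance(evidence, Mapping):
        model_ids = tuple(evidence)
        L = np.column_stack([np.asarray(evidence[m], float) for m in model_ids])
    else:
        L = np.atleast_2d(np.asarray(evidence, float))
        if model_ids is None:
            model_ids = tuple(str(i + 1) for i in range(L.shape[1]))
        model_ids = tuple(model_ids)
    if L.shape[1] < 2:
        raise ValueError("need at least 2 models")
    if not np.all(np.isfinite(L)):
        raise ValueError("log evidences must be finite")
    a0 = np.full(L.shape[1], alpha0, float) if np.isscalar(alpha0) else np.asarray(alpha0, float)
    alpha, u = _vb_dirichlet(L, a0)
    expected = alpha / alpha.sum()
    xp = exceedance_prob(alpha, n_draws=n_draws, seed=seed)
    return BMSResult(
        model_ids=model_ids,
        alpha=alpha,
        expected_prob=expected,
        exceedance=xp,
        responsibilities=u,
        meta={"alpha0": a0.tolist(), "n_draws": n_draws, "seed": seed},
    )


def family_inference(
    evidence: np.ndarray | Mapping[str, Sequence[float]],
    partition: FamilyPartition,
    model_ids: Sequence[str] | None = None,
    n_draws: int = 1_000_000,
    seed: int | None = 0,
) -> BMSResult:
    """Family-level RFX-BMS with equal prior mass per family.

    Model-level prior concentrations are rescaled to
    K_total / (F * K_family) so each family carries equal prior mass;
    the family exceedance is the Monte-Carlo probability that the
    summed frequency of that family is maximal under the model-level
    Dirichlet posterior.  With singleton families this reduces exactly
    to model-level inference.
    """
    if isinstance(evidence, Mapping):
        model_ids = tuple(evidence)
        L = np.column_stack([np.asarray(evidence[m], float) for m in model_ids])
    else:
        L = np.atleast_2d(np.asarray(evidence, float))
        if model_ids is None:
            model_ids = tuple(str(i + 1) for i in range(L.shape[1]))
        model_ids = tuple(model_ids)
    if not partition.covers(model_ids):
        raise ValueError("partition must cover the evidence table's models exactly")
    fam_names = partition.family_names
    n_fam = len(fam_names)
    k_total = len(model_ids)
    alpha0 = np.empty(k_total)
    for fam in fam_names:
        k_fam = len(partition.families[fam])
        for mid in partition.families[fam]:
            alpha0[model_ids.index(mid)] = k_total / (n_fam * k_fam)
    alpha, u = _vb_dirichlet(L, alpha0)

    # family membership matrix
    member = np.zeros((n_fam, k_total))
    for fi, fam in enumerate(fam_names):
        for mid in partition.families[fam]:
            member[fi, model_ids.index(mid)] = 1.0

    if n_fam == 1:
        fam_xp = np.array([1.0])
    else:
        rng = np.random.default_rng(seed)
        counts = np.zeros(n_fam)
        remaining = n_draws
        while remaining > 0:
            m = min(200_000, remaining)
            draws = rng.standard_gamma(alpha, size=(m, k_total))
            draws /= draws.sum(axis=1, keepdims=True)
            fam_mass = draws @ member.T
            counts += np.bincount(np.argmax(fam_mass, axis=1), minlength=n_fam)
            remaining -= m
        fam_xp = counts / n_draws
    fam_alpha = member @ alpha
    return BMSResult(
        model_ids=fam_names,
        alpha=fam_alpha,
        expected_prob=fam_alpha / fam_alpha.sum(),
        exceedance=fam_xp,
        responsibilities=u @ member.T,
        meta={
            "level": "family",
            "model_alpha": alpha.tolist(),
            "model_ids": list(model_ids),
            "n_draws": n_draws,
            "seed": seed,
        },
    )


def bma(
    fits: Sequence[Mapping[str, object]],
    bms: BMSResult,
    param_labels: Sequence[str] | None = None,
    n_draws: int = 10_000,
    seed: int | None = 0,
) -> dict:
    """Bayesian model averaging over per-subject, per-model DCM fits.

    ``fits[s][model_id]`` is the subject's :class:`~attnflow.dcm.DCMFit`
    for that model.  For each subject, models are drawn from the
    subject's posterior model probabilities (the BMS responsibilities)
    and parameters from the chosen model's Gaussian posterior;
    parameters absent from a model count as zero.  Returns per-subject
    and group mean/sd over the draws for each parameter label.
    """
    if bms.responsibilities is None:
        raise ValueError("BMS result lacks subject responsibilities")
    n_sub = len(fits)
    if bms.responsibilities.shape[0] != n_sub:
        raise ValueError("fits and BMS responsibilities are misaligned")
    if param_labels is None:
        seen: list[str] = []
        for m in bms.model_ids:
            for lb in fits[0][m].param_labels:  # type: ignore[attr-defined]
                if lb not in seen:
                    seen.append(lb)
        param_labels = seen
    param_labels = list(param_labels)
    rng = np.random.default_rng(seed)
    subj_mean = np.zeros((n_sub, len(param_labels)))
    subj_sd = np.zeros((n_sub, len(param_labels)))
    for s in range(n_sub):
        probs = bms.responsibilities[s]
        choices = rng.choice(len(bms.model_ids), size=n_draws, p=probs / probs.sum())
        draws = np.zeros((n_draws, len(param_labels)))
        for mi, mid in enumerate(bms.model_ids):
            idx = np.where(choices == mi)[0]
            if idx.size == 0:
                continue
            fit = fits[s][mid]
            lbs = list(fit.param_labels)  # type: ignore[attr-defined]
            mean = fit.theta  # type: ignore[attr-defined]
            cov = fit.cov  # type: ignore[attr-defined]
            sample = rng.multivariate_normal(mean, cov, size=idx.size, method="svd")
            for pj, lb in enumerate(param_labels):
                if lb in lbs:
                    draws[idx, pj] = sample[:, lbs.index(lb)]
        subj_mean[s] = draws.mean(axis=0)
        subj_sd[s] = draws.std(axis=0, ddof=1)
    return {
        "param_labels": param_labels,
        "subject_mean": subj_mean,
        "subject_sd": subj_sd,
        "group_mean": subj_mean.mean(axis=0),
        "group_sd": subj_mean.std(axis=0, ddof=1) if n_sub > 1 else np.zeros(len(param_labels)),
        "n_draws": n_draws,
        "seed": seed,
    }
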