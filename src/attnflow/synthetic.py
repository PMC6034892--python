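"""Seeded generators for every input the pipeline consumes.

Provides the standard block design (eight 16-s stimulus blocks
interleaved with eight 12-s blanks, TR 2 s), ground-truth DCM-generated
BOLD groups with between-subject parameter variability, block-amplitude
tables for attention-index experiments, and stable VAR realizations for
the Granger-causality stage.  Every generator is a pure function of its
arguments including the seed.

Simulated BOLD is expressed as percent signal about a baseline of 100,
matching the grand-mean-scaling convention of the analysis chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import BlockDesign, TimeSeriesSet, build_block_design
from .dcm import (
    DCMSpec,
    HemoParams,
    NeuralParams,
    integrate_dcm,
    unstable_eigenvalues,
)

__all__ = [
    "NoiseSpec",
    "GroupTruth",
    "standard_design",
    "default_neural_truth",
    "simulate_dcm_bold",
    "simulate_group",
    "simulate_block_amplitudes",
    "simulate_var",
    "noise_sd_for_snr",
]

MAX_SELF_DECAY = -0.0625  # truncation bound keeping every subject stable


@dataclass(frozen=True)
class NoiseSpec:
    """Additive observation noise: white Gaussian, optionally AR(1).

    ``sd`` is the marginal standard deviation in percent-signal units;
    with ``ar_coef`` > 0 innovations are scaled so the marginal sd is
    preserved.  The conventional fMRI autocorrelation approximation
    uses ar_coef = 0.3.
    """

    sd: float = 0.5
    ar_coef: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not (0 <= self.ar_coef < 1):
            raise ValueError("ar_coef must lie in [0, 1)")

    def sample(self, rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
        if self.sd == 0:
            return np.zeros(shape)
        w = rng.standard_normal(shape) * self.sd
        if self.ar_coef == 0:
            return w
        e = np.empty(shape)
        e[:, 0] = w[:, 0]
        scale = np.sqrt(1.0 - self.ar_coef**2)
        for t in range(1, shape[1]):
            e[:, t] = self.ar_coef * e[:, t - 1] + scale * w[:, t]
        return e


@dataclass(frozen=True)
class GroupTruth:
    """Ground-truth parameters and their between-subject spread.

    Subject parameters are the base values plus independent Normal(0,
    sd) draws on each free entry (keys "a", "b", "c" of
    ``between_subject_sd``), applied on the natural parameter scale;
    self-decay entries are perturbed with key "self" and truncated so
    they stay below :data:`MAX_SELF_DECAY`, keeping all subjects
    dynamically stable.
    """

    base_neural: NeuralParams
    hemo: HemoParams = field(default_factory=HemoParams)
    between_subject_sd: Mapping[str, float] = field(
        default_factory=lambda: {"a": 0.05, "b": 0.2, "c": 0.05, "self": 0.05}
    )
    n_subjects: int = 19
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if any(v < 0 for v in self.between_subject_sd.values()):
            raise ValueError("between-subject sd must be >= 0")


def standard_design(
    n_blocks: int = 8,
    block_dur: float = 16.0,
    blank_dur: float = 12.0,
    tr: float = 2.0,
    microtime_bins: int = 16,
    conditions: tuple[str, str] = ("Same", "Different"),
) -> BlockDesign:
    """The standard run: alternating Same/Different stimulus blocks.

    Defaults reproduce the acquisition skeleton — eight 16-s blocks
    interleaved with eight 12-s blanks at TR 2 s (224 s, 112 scans),
    half the blocks per condition.
    """
    sequence = [conditions[k % 2] for k in range(n_blocks)]
    return build_block_design(
        n_blocks, block_dur, blank_dur, sequence, tr=tr, microtime_bins=microtime_bins
    )


#: Self-decay (Hz) and direct visual drive (Hz) per hierarchy stage of the
#: non-visual regions, cycled when there are more than four.  Time
#: constants span roughly 1-5 s: fast sensory-driven parietal dynamics
#: down to a slow prefrontal integrator whose activity ramps across a
#: 16-s block.
FRONTAL_DECAYS = (-0.9, -0.45, -0.2, -0.65)
FRONTAL_DRIVES = (0.45, 0.22, 0.05, 0.3)


def default_neural_truth(
    spec: DCMSpec,
    chain: float = 0.1,
    feedback: float = 0.03,
    visual_decay: float = -0.5,
    b_value: float = 0.5,
    c_value: float = 0.3,
) -> NeuralParams:
    """Plausible generating parameters for an attention-network spec.

    The visual nodes (those receiving a driving input) project to every
    non-visual region; the non-visual regions form a hierarchy in their
    listed order, each stage feeding the next with strength ``chain``
    and sending weak ``feedback`` onto the visual nodes.  Crucially,
    the stages have heterogeneous intrinsic time constants
    (:data:`FRONTAL_DECAYS`), with direct drives scaled so steady-state
    activities stay comparable (:data:`FRONTAL_DRIVES`): a fast region
    plateaus within a couple of seconds of block onset while a slow
    integrator ramps across the whole block.

    That temporal heterogeneity is what makes the origin of a modulated
    connection identifiable.  In a homogeneous network all non-visual
    time courses are near-proportional, every candidate source predicts
    essentially the same modulatory effect, and no analysis could
    attribute the modulation — model comparison would then be decided
    by Occam terms rather than by the data.

    Every modulatory entry allowed by the spec is set to ``b_value``
    and every driving entry to ``c_value``.  All rates in Hz.
    """
    n = spec.n_regions
    visual = np.zeros(n, bool)
    for v in spec.c_masks.values():
        visual |= v
    frontal = [i for i in range(n) if not visual[i]]
    stage = {idx: k for k, idx in enumerate(frontal)}
    A = np.zeros((n, n))
    for i in range(n):
        if visual[i]:
            A[i, i] = visual_decay
        else:
            A[i, i] = FRONTAL_DECAYS[stage[i] % len(FRONTAL_DECAYS)]
    for i in range(n):
        for j in range(n):
            if i == j or not spec.a_mask[i, j]:
                continue
            if visual[j] and not visual[i]:
                A[i, j] = FRONTAL_DRIVES[stage[i] % len(FRONTAL_DRIVES)]
            elif visual[i] and not visual[j]:
                A[i, j] = feedback
            elif not visual[i] and not visual[j] and stage[i] == stage[j] + 1:
                A[i, j] = chain
    B = {k: m.astype(float) * b_value for k, m in spec.b_masks.items()}
    C = {k: v.astype(float) * c_value for k, v in spec.c_masks.items()}
    return NeuralParams(A, B, C)


def simulate_dcm_bold(
    spec: DCMSpec,
    neural: NeuralParams,
    hemo: HemoParams,
    design: BlockDesign,
    noise: NoiseSpec,
    seed: int | None = 0,
    baseline: float = 100.0,
) -> TimeSeriesSet:
    """Ground-truth BOLD: DCM forward model plus additive noise.

    The noiseless component is exactly
    :func:`attnflow.dcm.integrate_dcm` shifted to ``baseline``
    (percent-signal about 100 by default).  An effective coupling
    matrix with a positive-real-part eigenvalue is flagged in
    ``meta['unstable_A']`` rather than raised.
    """
    clean = integrate_dcm(spec, neural, hemo, design)
    rng = np.random.default_rng(seed)
    data = baseline + clean.data + noise.sample(rng, clean.data.shape)
    meta = {
        "source": "simulate_dcm_bold",
        "seed": seed,
        "baseline": baseline,
        "noise_sd": noise.sd,
        "ar_coef": noise.ar_coef,
    }
    if unstable_eigenvalues(spec, neural):
        meta["unstable_A"] = True
    return TimeSeriesSet(spec.regions, data, design.tr, meta)


def _perturb_truth(
    truth: GroupTruth, spec: DCMSpec, rng: np.random.Generator
) -> NeuralParams:
    """One subject's parameters: base + Normal(0, sd) on each free entry.

    Draws are rejected (and redrawn) until every effective coupling
    matrix — A alone and A plus each modulatory matrix — has all
    eigenvalues in the left half plane, so every subject is
    dynamically stable.
    """
    sd = truth.between_subject_sd
    base = truth.base_neural
    n = spec.n_regions
    offdiag = spec.a_mask & ~np.eye(n, dtype=bool)
    for _ in range(200):
        A = base.A.copy()
        A[offdiag] += rng.normal(0.0, sd.get("a", 0.0), int(offdiag.sum()))
        diag = np.diag(A).copy() + rng.normal(0.0, sd.get("self", 0.0), n)
        np.fill_diagonal(A, np.minimum(diag, MAX_SELF_DECAY))
        B = {}
        for k, m in spec.b_masks.items():
            b = base.B.get(k, np.zeros((n, n))).copy()
            b[m] += rng.normal(0.0, sd.get("b", 0.0), int(m.sum()))
            B[k] = b
        C = {}
        for k, v in spec.c_masks.items():
            c = base.C.get(k, np.zeros(n)).copy()
            c[v] += rng.normal(0.0, sd.get("c", 0.0), int(v.sum()))
            C[k] = c
        params = NeuralParams(A, B, C)
        if not unstable_eigenvalues(spec, params):
            return params
    raise RuntimeError(
        "could not draw stable subject parameters; base truth is too close "
        "to instability for the requested between-subject spread"
    )


def simulate_group(
    truth: GroupTruth,
    spec: DCMSpec,
    design: BlockDesign,
    noise: NoiseSpec,
    seed: int | None = None,
) -> list[TimeSeriesSet]:
    """Simulate ``truth.n_subjects`` BOLD runs with parameter variability.

    Per-subject seeds are derived deterministically from the master
    seed via :class:`numpy.random.SeedSequence` spawning, so the same
    master seed reproduces the group bit-identically.
    """
    if seed is None:
        seed = truth.seed if truth.seed is not None else 0
    master = np.random.SeedSequence(seed)
    children = master.spawn(truth.n_subjects)
    out = []
    for s, child in enumerate(children):
        rng = np.random.default_rng(child)
        params = _perturb_truth(truth, spec, rng)
        noise_seed = int(rng.integers(0, 2**31 - 1))
        ts = simulate_dcm_bold(
            spec, params, truth.hemo, design, noise, seed=noise_seed
        )
        ts.meta.update(subject=s, master_seed=seed, true_params=params)
        out.append(ts)
    return out


def simulate_block_amplitudes(
    mu_same: float,
    mu_diff: float,
    sd: float,
    n_subjects: int,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Subject × condition amplitude table: Normal draws around the two
    condition means (percent-signal units).  Drives attention-index
    experiments without a full BOLD simulation."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    same = mu_same + sd * rng.standard_normal(n_subjects)
    diff = mu_diff + sd * rng.standard_normal(n_subjects)
    return pd.DataFrame(
        {"Same": same, "Different": diff},
        index=pd.RangeIndex(n_subjects, name="subject"),
    )


def simulate_var(
    coeffs: np.ndarray,
    n_time: int,
    noise_sd: float = 1.0,
    seed: int | None = 0,
    burn_in: int | None = None,
    node_labels: Sequence[str] | None = None,
    tr: float = 2.0,
) -> TimeSeriesSet:
    """Seeded realization of a stable VAR(p) process.

    ``coeffs`` has shape (p, n, n) with ``coeffs[l, i, j]`` the weight
    of node j at lag l+1 in node i's equation.  Rejects coefficient
    sets whose companion matrix has spectral radius >= 1.  A burn-in of
    at least 10 p samples (default max(10 p, 50)) is discarded.
    """
    coeffs = np.asarray(coeffs, float)
    if coeffs.ndim == 2:
        coeffs = coeffs[None]
    p, n, _ = coeffs.shape
    companion = np.zeros((n * p, n * p))
    companion[:n, :] = np.concatenate(list(coeffs), axis=1)
    if p > 1:
        companion[n:, :-n] = np.eye(n * (p - 1))
    radius = float(np.max(np.abs(np.linalg.eigvals(companion))))
    if radius >= 1.0:
        raise ValueError(f"unstable VAR coefficients (spectral radius {radius:.3f})")
    if burn_in is None:
        burn_in = max(10 * p, 50)
    burn_in = max(burn_in, 10 * p)
    rng = np.random.default_rng(seed)
    total = n_time + burn_in
    E = rng.standard_normal((total, n)) * noise_sd
    X = np.zeros((total, n))
    X[:p] = E[:p]
    for t in range(p, total):
        acc = E[t].copy()
        for l in range(p):
            acc += coeffs[l] @ X[t - 1 - l]
        X[t] = acc
    if node_labels is None:
        node_labels = tuple(f"node{k + 1}" for k in range(n))
    return TimeSeriesSet(
        tuple(node_labels),
        X[burn_in:].T,
        tr,
        {"source": "simulate_var", "seed": seed, "order": p, "spectral_radius": radius},
    )


def noise_sd_for_snr(clean: TimeSeriesSet, snr: float) -> float:
    """Observation-noise sd giving the requested signal-to-noise ratio,
    defined as mean per-region signal sd divided by noise sd."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    return float(np.mean(clean.data.std(axis=1)) / snr)
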