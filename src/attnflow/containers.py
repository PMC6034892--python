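"""Core data containers: experimental block designs and region-by-time BOLD series.

A :class:`BlockDesign` holds condition onsets/durations and the derived
stimulus input functions u_j(t) on a fine ("microtime") grid — the skeleton
of a blocked fMRI experiment.  A :class:`TimeSeriesSet` is the universal
region × time signal container used throughout the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = ["BlockDesign", "TimeSeriesSet", "build_block_design", "ALL_VISUAL"]

#: Label of the derived input row equal to the union of all condition
#: boxcars (the "all visual stimulation" driving input used by the DCM).
ALL_VISUAL = "all_visual"


@dataclass(frozen=True)
class BlockDesign:
    """Condition onsets/durations and fine-grid input functions.

    Parameters
    ----------
    condition_names:
        Ordered unique condition labels.
    onsets, durations:
        Mapping condition -> array of onset / duration times in seconds.
    run_length:
        Total run duration in seconds.
    tr:
        Repetition time (sampling interval of the acquired BOLD), seconds.
    microtime_bins:
        Number of fine-grid subdivisions per TR used for input functions
        and for numerical integration of generative models.
    """

    condition_names: tuple[str, ...]
    onsets: Mapping[str, np.ndarray]
    durations: Mapping[str, np.ndarray]
    run_length: float
    tr: float = 2.0
    microtime_bins: int = 16

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.microtime_bins < 1:
            raise ValueError("microtime_bins must be >= 1")
        if self.run_length < 0:
            raise ValueError("run_length must be nonnegative")
        for name in self.condition_names:
            ons = np.asarray(self.onsets[name], dtype=float)
            dur = np.asarray(self.durations[name], dtype=float)
            if ons.shape != dur.shape:
                raise ValueError(f"onsets/durations shape mismatch for {name!r}")
            if np.any(ons < 0) or np.any(ons >= self.run_length if ons.size else False):
                raise ValueError(f"onsets for {name!r} must lie in [0, run_length)")
            if np.any(dur <= 0):
                raise ValueError(f"durations for {name!r} must be positive")
            object.__setattr__(self, "onsets", {**self.onsets, name: ons})
            object.__setattr__(self, "durations", {**self.durations, name: dur})

    # ------------------------------------------------------------------ grids
    @property
    def dt(self) -> float:
        """Fine-grid step, ``tr / microtime_bins`` (seconds)."""
        return self.tr / self.microtime_bins

    @property
    def n_scans(self) -> int:
        """Number of TR-spaced samples in the run."""
        return int(np.floor(self.run_length / self.tr + 1e-9))

    @property
    def n_fine(self) -> int:
        return self.n_scans * self.microtime_bins

    @property
    def fine_times(self) -> np.ndarray:
        return np.arange(self.n_fine) * self.dt

    @property
    def scan_times(self) -> np.ndarray:
        """Acquisition times of the TR samples (start-of-TR convention)."""
        return np.arange(self.n_scans) * self.tr

    # -------------------------------------------------------------- functions
    def boxcar(self, condition: str) -> np.ndarray:
        """Fine-grid indicator of ``condition``: 1 on [onset, onset+duration)."""
        if condition == ALL_VISUAL:
            if not self.condition_names:
                return np.zeros(self.n_fine)
            rows = [self.boxcar(c) for c in self.condition_names]
            return np.clip(np.sum(rows, axis=0), 0.0, 1.0)
        if condition not in self.condition_names:
            raise KeyError(f"unknown condition {condition!r}")
        t = self.fine_times
        u = np.zeros(self.n_fine)
        for onset, dur in zip(self.onsets[condition], self.durations[condition]):
            u[(t >= onset - 1e-9) & (t < onset + dur - 1e-9)] = 1.0
        return u

    @property
    def input_matrix(self) -> np.ndarray:
        """Conditions × fine-grid boxcar matrix (rows ordered as condition_names)."""
        if not self.condition_names:
            return np.zeros((0, self.n_fine))
        return np.vstack([self.boxcar(c) for c in self.condition_names])

    def inputs(self, labels: Sequence[str]) -> np.ndarray:
        """Stack boxcars for ``labels`` (conditions or :data:`ALL_VISUAL`)."""
        if not labels:
            return np.zeros((0, self.n_fine))
        return np.vstack([self.boxcar(lb) for lb in labels])

    def blocks(self) -> list[tuple[str, float, float]]:
        """All (condition, onset, duration) triples sorted by onset."""
        out: list[tuple[str, float, float]] = []
        for name in self.condition_names:
            for onset, dur in zip(self.onsets[name], self.durations[name]):
                out.append((name, float(onset), float(dur)))
        return sorted(out, key=lambda b: b[1])

    def to_dict(self) -> dict:
        return {
            "condition_names": list(self.condition_names),
            "onsets": {k: np.asarray(v).tolist() for k, v in self.onsets.items()},
            "durations": {k: np.asarray(v).tolist() for k, v in self.durations.items()},
            "run_length": self.run_length,
            "tr": self.tr,
            "microtime_bins": self.microtime_bins,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "BlockDesign":
        return cls(
            condition_names=tuple(d["condition_names"]),
            onsets={k: np.asarray(v, float) for k, v in d["onsets"].items()},
            durations={k: np.asarray(v, float) for k, v in d["durations"].items()},
            run_length=float(d["run_length"]),
            tr=float(d["tr"]),
            microtime_bins=int(d["microtime_bins"]),
        )


def build_block_design(
    n_blocks: int,
    block_dur: float,
    blank_dur: float,
    condition_sequence: Sequence[str],
    tr: float = 2.0,
    microtime_bins: int = 16,
    condition_names: Sequence[str] | None = None,
) -> BlockDesign:
    """Build an alternating stimulus/blank block design.

    The run starts with a stimulus block at t = 0; each block of
    ``block_dur`` seconds is followed by a blank of ``blank_dur`` seconds,
    so ``run_length = n_blocks * (block_dur + blank_dur)``.  The standard
    acquisition uses eight 16-s blocks interleaved with eight 12-s blanks
    at TR 2 s (224 s, 112 scans).

    ``condition_sequence`` assigns a condition label (e.g. "Same" /
    "Different") to each stimulus block in order.
    """
    if n_blocks < 0:
        raise ValueError("n_blocks must be >= 0")
    if n_blocks > 0 and (block_dur <= 0 or blank_dur < 0):
        raise ValueError("block_dur must be positive and blank_dur nonnegative")
    condition_sequence = list(condition_sequence)
    if len(condition_sequence) != n_blocks:
        raise ValueError("condition_sequence length must equal n_blocks")
    if condition_names is None:
        seen: list[str] = []
        for c in condition_sequence:
            if c not in seen:
                seen.append(c)
        condition_names = seen
    else:
        unknown = set(condition_sequence) - set(condition_names)
        if unknown:
            raise ValueError(f"unknown condition label(s) in sequence: {sorted(unknown)}")

    cycle = block_dur + blank_dur
    run_length = n_blocks * cycle
    onsets: dict[str, list[float]] = {c: [] for c in condition_names}
    durations: dict[str, list[float]] = {c: [] for c in condition_names}
    for k, cond in enumerate(condition_sequence):
        onsets[cond].append(k * cycle)
        durations[cond].append(block_dur)
    return BlockDesign(
        condition_names=tuple(condition_names),
        onsets={c: np.asarray(v, float) for c, v in onsets.items()},
        durations={c: np.asarray(v, float) for c, v in durations.items()},
        run_length=run_length,
        tr=tr,
        microtime_bins=microtime_bins,
    )


@dataclass
class TimeSeriesSet:
    """Region × time signal matrix with its sampling interval.

    ``data`` has shape (n_regions, n_time); values are BOLD signal in
    arbitrary units or percent signal.  ``meta`` carries subject/run tags
    and provenance notes.
    """

    region_labels: tuple[str, ...]
    data: np.ndarray
    tr: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.region_labels = tuple(self.region_labels)
        if self.data.shape[0] != len(self.region_labels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but "
                f"{len(self.region_labels)} region labels"
            )
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_time(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_time) * self.tr

    def copy_with(self, data: np.ndarray, **meta_updates) -> "TimeSeriesSet":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return TimeSeriesSet(self.region_labels, np.asarray(data, float), self.tr, meta)

    def region(self, label: str) -> np.ndarray:
        return self.data[self.region_labels.index(label)]
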