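"""Binary adverse-event outcomes over the 5-minute future block.

Each outcome applies an aggregator (min or max) and a strict comparison to
the next five minutes of one target signal:

* hypoxemia       — min SAO2  < 93
* hypocapnia      — min ETCO2 < 35
* hypotension     — min NIBPM < 60
* hypertension    — max NIBPM > 110
* phenylephrine   — max PHENYL == 1
* epinephrine     — max EPINE == 1

Labels are pure functions of the *raw* (un-imputed, un-standardized)
future values: a window whose future block has any missing value of the
target signal is excluded (label undefined) rather than imputed, since an
imputed future would fabricate the outcome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import SampleWindow, WindowSet


@dataclass(frozen=True)
class OutcomeSpec:
    name: str
    target_variable: str
    aggregator: str      # "min" | "max"
    comparator: str      # "<" | ">" | "=="
    threshold: float


OUTCOMES: dict[str, OutcomeSpec] = {
    s.name: s
    for s in (
        OutcomeSpec("hypoxemia", "SAO2", "min", "<", 93.0),
        OutcomeSpec("hypocapnia", "ETCO2", "min", "<", 35.0),
        OutcomeSpec("hypotension", "NIBPM", "min", "<", 60.0),
        OutcomeSpec("hypertension", "NIBPM", "max", ">", 110.0),
        OutcomeSpec("phenylephrine", "PHENYL", "max", "==", 1.0),
        OutcomeSpec("epinephrine", "EPINE", "max", "==", 1.0),
    )
}


def get_outcome(name: str) -> OutcomeSpec:
    try:
        return OUTCOMES[name]
    except KeyError:
        raise KeyError(
            f"unknown outcome {name!r}; known: {sorted(OUTCOMES)}"
        ) from None


def _apply(values: np.ndarray, spec: OutcomeSpec) -> np.ndarray:
    """Vectorized label over the last axis (the 5 future minutes)."""
    agg = values.min(axis=-1) if spec.aggregator == "min" else values.max(axis=-1)
    if spec.comparator == "<":
        return (agg < spec.threshold).astype(float)
    if spec.comparator == ">":
        return (agg > spec.threshold).astype(float)
    if spec.comparator == "==":
        return (agg == spec.threshold).astype(float)
    raise ValueError(f"unknown comparator {spec.comparator!r}")


def label_window(window: SampleWindow, spec: OutcomeSpec) -> int | None:
    """Label one window; ``None`` if any future target value is missing."""
    j = window.variables.index(spec.target_variable)
    fut = window.future[j]
    if np.isnan(fut).any():
        return None
    return int(_apply(fut, spec))


@dataclass
class LabelResult:
    """Per-window labels (NaN = undefined) with the base-rate report."""

    labels: np.ndarray           # (n,) float, NaN where undefined
    base_rate: float             # positives / defined
    n_defined: int
    n_undefined: int

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.labels)


def label_cohort(windows: WindowSet, spec: OutcomeSpec) -> LabelResult:
    """Label every window of a set; windows with missing futures excluded.

    The base rate is positives over *defined* labels only; the number of
    excluded windows is reported since each outcome can have a different
    effective sample size.
    """
    if windows.n == 0:
        raise ValueError("empty window set")
    fut = windows.signal_future(spec.target_variable)
    defined = ~np.isnan(fut).any(axis=1)
    labels = np.full(windows.n, np.nan)
    labels[defined] = _apply(fut[defined], spec)
    n_def = int(defined.sum())
    if n_def == 0:
        raise ValueError(f"no defined labels for outcome {spec.name!r}")
    return LabelResult(
        labels=labels,
        base_rate=float(np.nansum(labels) / n_def),
        n_defined=n_def,
        n_undefined=int(windows.n - n_def),
    )
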