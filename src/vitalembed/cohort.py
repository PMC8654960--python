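"""Stay records, splits, preprocessing, and sliding-window sample construction.

A *stay* is one surgery or ICU admission: six static covariates plus a
minute-by-minute matrix of physiological signals with an explicit
observed/missing mask.  Prediction samples are 60-minute histories paired
with the following 5 minutes, anchored at a minute ``t`` (1-based, matching
the clinical convention that minute 1 is the first recorded minute): the
history covers minutes ``t-59..t`` and the future covers ``t+1..t+5``.
Internally everything is 0-based and half-open; the 1-based anchor is mapped
at the boundary (``i = t - 1``, history ``[i-59, i+1)``, future
``[i+1, i+6)``).
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: The 13 physiological input signals, in the fixed global order used for
#: feature concatenation everywhere in the package.
INPUT_SIGNALS: tuple[str, ...] = (
    "SAO2", "ETCO2", "NIBPS", "NIBPM", "NIBPD", "FIO2", "ETSEV",
    "ECGRATE", "PEAK", "PEEP", "PIP", "RESPRATE", "TEMP1",
)

#: Binary drug-administration channels, recorded but never used as inputs.
DRUG_CHANNELS: tuple[str, ...] = ("PHENYL", "EPINE")

#: All 15 dynamic variables (inputs followed by drug channels).
DYNAMIC_VARIABLES: tuple[str, ...] = INPUT_SIGNALS + DRUG_CHANNELS

#: The six static covariates, in canonical order.
STATIC_FIELDS: tuple[str, ...] = (
    "height", "weight", "asa_code", "asa_emergency", "gender", "age",
)

HISTORY_LEN = 60
FUTURE_LEN = 5


@dataclass
class StaticVector:
    """Static covariates of one stay.

    ``gender`` is coded 1.0 = female, 0.0 = male; ``asa_emergency`` is
    0/1; ``asa_code`` is the ordinal physical-status class (1-5).  Any
    field may be NaN before imputation.
    """

    height: float = np.nan
    weight: float = np.nan
    asa_code: float = np.nan
    asa_emergency: float = np.nan
    gender: float = np.nan
    age: float = np.nan

    def to_array(self) -> np.ndarray:
        return np.array(
            [getattr(self, f) for f in STATIC_FIELDS], dtype=float
        )

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "StaticVector":
        return cls(**{f: float(v) for f, v in zip(STATIC_FIELDS, arr)})


@dataclass
class StayRecord:
    """One stay: static covariates + T x V signal matrix with mask."""

    stay_id: str
    static: StaticVector
    signals: np.ndarray          # (T, V) float, NaN where unobserved
    mask: np.ndarray             # (T, V) bool, True = observed
    hospital_tag: str = ""
    variables: tuple[str, ...] = DYNAMIC_VARIABLES
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.signals.ndim != 2:
            raise ValueError("signals must be a T x V matrix")
        if self.signals.shape != self.mask.shape:
            raise ValueError("signals and mask must share shape")
        if self.signals.shape[0] < 1:
            raise ValueError("a stay must have at least one minute")
        if self.signals.shape[1] != len(self.variables):
            raise ValueError(
                f"signals has {self.signals.shape[1]} columns for "
                f"{len(self.variables)} variables"
            )
        for drug in DRUG_CHANNELS:
            if drug in self.variables:
                col = self.signals[:, self.variables.index(drug)]
                observed = col[~np.isnan(col)]
                if observed.size and not np.isin(observed, (0.0, 1.0)).all():
                    raise ValueError(f"{drug} must be binary where observed")

    @property
    def n_minutes(self) -> int:
        return self.signals.shape[0]

    def var_index(self, name: str) -> int:
        return self.variables.index(name)


@dataclass
class SampleWindow:
    """One sample: per-variable 60-minute history and 5-minute future.

    ``anchor_t`` is the 1-based anchor minute ``t``: the history is
    minutes ``t-59..t`` and the future is ``t+1..t+5``.
    """

    stay_id: str
    anchor_t: int
    history: np.ndarray          # (V, 60)
    future: np.ndarray           # (V, 5)
    static: StaticVector
    variables: tuple[str, ...] = DYNAMIC_VARIABLES

    def __post_init__(self) -> None:
        if self.history.shape[-1] != HISTORY_LEN:
            raise ValueError(f"history must cover {HISTORY_LEN} minutes")
        if self.future.shape[-1] != FUTURE_LEN:
            raise ValueError(f"future must cover {FUTURE_LEN} minutes")


def enumerate_windows(record: StayRecord, stride: int = 1) -> list[SampleWindow]:
    """All admissible sample windows of a stay, in increasing anchor order.

    Anchors are 1-based minutes ``t`` with a full 60-minute history and a
    full 5-minute future inside the stay, i.e. ``t in {60, ..., T-5}``;
    with ``stride`` s only every s-th admissible anchor is emitted.  Stays
    shorter than 65 minutes yield no windows.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    T = record.n_minutes
    out: list[SampleWindow] = []
    for t in range(HISTORY_LEN, T - FUTURE_LEN + 1, stride):
        i = t - 1  # 0-based index of the anchor minute
        out.append(
            SampleWindow(
                stay_id=record.stay_id,
                anchor_t=t,
                history=record.signals[i - 59 : i + 1, :].T.copy(),
                future=record.signals[i + 1 : i + 6, :].T.copy(),
                static=record.static,
                variables=record.variables,
            )
        )
    return out


@dataclass
class WindowSet:
    """A batch of sample windows as dense arrays (the pipeline currency).

    ``history`` is (n, V, 60) and ``future`` is (n, V, 5), both carrying
    raw (un-imputed, un-standardized) values with NaN for missing entries;
    ``static`` is (n, 6) in :data:`STATIC_FIELDS` order.
    """

    history: np.ndarray
    future: np.ndarray
    static: np.ndarray
    stay_ids: np.ndarray
    anchor_ts: np.ndarray
    variables: tuple[str, ...] = DYNAMIC_VARIABLES

    @property
    def n(self) -> int:
        return self.history.shape[0]

    def var_index(self, name: str) -> int:
        return self.variables.index(name)

    def signal_history(self, name: str) -> np.ndarray:
        """(n, 60) history of one variable."""
        return self.history[:, self.var_index(name), :]

    def signal_future(self, name: str) -> np.ndarray:
        """(n, 5) future of one variable."""
        return self.future[:, self.var_index(name), :]

    def subset(self, idx: np.ndarray) -> "WindowSet":
        return WindowSet(
            history=self.history[idx],
            future=self.future[idx],
            static=self.static[idx],
            stay_ids=self.stay_ids[idx],
            anchor_ts=self.anchor_ts[idx],
            variables=self.variables,
        )


def build_window_set(records: Iterable[StayRecord], stride: int = 1) -> WindowSet:
    """Stack the sliding windows of many stays into one :class:`WindowSet`."""
    hist, fut, stat, sids, ats = [], [], [], [], []
    variables: tuple[str, ...] | None = None
    for rec in records:
        if variables is None:
            variables = rec.variables
        elif rec.variables != variables:
            raise ValueError("all records must share a variable list")
        T = rec.n_minutes
        anchors = np.arange(HISTORY_LEN, T - FUTURE_LEN + 1, stride)
        if anchors.size == 0:
            continue
        idx = anchors - 1
        # gather with stride tricks: build index grids once per record
        h_idx = idx[:, None] + np.arange(-59, 1)[None, :]
        f_idx = idx[:, None] + np.arange(1, 6)[None, :]
        hist.append(np.swapaxes(rec.signals[h_idx, :], 1, 2))
        fut.append(np.swapaxes(rec.signals[f_idx, :], 1, 2))
        stat.append(np.tile(rec.static.to_array(), (anchors.size, 1)))
        sids.append(np.repeat(rec.stay_id, anchors.size))
        ats.append(anchors)
    if variables is None or not hist:
        V = len(variables) if variables else len(DYNAMIC_VARIABLES)
        variables = variables or DYNAMIC_VARIABLES
        return WindowSet(
            history=np.empty((0, V, HISTORY_LEN)),
            future=np.empty((0, V, FUTURE_LEN)),
            static=np.empty((0, len(STATIC_FIELDS))),
            stay_ids=np.empty(0, dtype=object),
            anchor_ts=np.empty(0, dtype=int),
            variables=variables,
        )
    return WindowSet(
        history=np.concatenate(hist),
        future=np.concatenate(fut),
        static=np.concatenate(stat),
        stay_ids=np.concatenate(sids),
        anchor_ts=np.concatenate(ats),
        variables=variables,
    )


@dataclass
class NormalizationStats:
    """Per-variable mean/sd (signals) and per-field mean (statics).

    Means and standard deviations are computed over *observed* entries of
    the training split only, with the population (1/N) standard deviation;
    a constant variable's sd is replaced by 1 so standardization is a pure
    shift.  Drug channels are fixed to mean 0 / sd 1: they are imputed to
    zero and never standardized.
    """

    variables: tuple[str, ...]
    mean: np.ndarray             # (V,)
    sd: np.ndarray               # (V,)
    static_mean: np.ndarray      # (6,)

    def for_variable(self, name: str) -> tuple[float, float]:
        i = self.variables.index(name)
        return float(self.mean[i]), float(self.sd[i])


def fit_normalization(
    train_records: Sequence[StayRecord],
    variables: Sequence[str] | None = None,
) -> NormalizationStats:
    """Fit imputation/standardization statistics on the training stays.

    ``variables`` restricts the set of signal variables that must be
    observed (default: all input signals of the records); a restricted
    fit is what an ICU-style dataset with a single usable channel needs.
    A required variable or a static field with no observed value at all
    raises a ``ValueError`` naming it.
    """
    if not train_records:
        raise ValueError("need at least one training record")
    var_list = train_records[0].variables
    required = set(
        variables
        if variables is not None
        else [v for v in var_list if v not in DRUG_CHANNELS]
    )
    V = len(var_list)
    mean = np.zeros(V)
    sd = np.ones(V)
    for j, name in enumerate(var_list):
        if name in DRUG_CHANNELS:
            continue
        vals = np.concatenate(
            [r.signals[r.mask[:, j], j] for r in train_records]
        )
        if vals.size == 0:
            if name in required:
                raise ValueError(f"variable {name!r} never observed in train")
            mean[j] = np.nan
            continue
        mean[j] = vals.mean()
        s = vals.std()  # population sd
        sd[j] = s if s > 0 else 1.0
    stat = np.stack([r.static.to_array() for r in train_records])
    static_mean = np.empty(len(STATIC_FIELDS))
    for k, fname in enumerate(STATIC_FIELDS):
        col = stat[:, k]
        obs = col[~np.isnan(col)]
        if obs.size == 0:
            raise ValueError(f"static field {fname!r} never observed in train")
        static_mean[k] = obs.mean()
    return NormalizationStats(
        variables=var_list, mean=mean, sd=sd, static_mean=static_mean
    )


@dataclass
class DatasetSplit:
    """Stay-level train/val/test partition with train-fitted statistics."""

    train: tuple[str, ...]
    val: tuple[str, ...]
    test: tuple[str, ...]
    normalization_stats: NormalizationStats | None = None

    def part_of(self, stay_id: str) -> str:
        for name in ("train", "val", "test"):
            if stay_id in getattr(self, name):
                return name
        raise KeyError(stay_id)


def split_by_stay(
    records: Sequence[StayRecord],
    fractions: tuple[float, float, float] = (0.7, 0.15, 0.15),
    seed: int = 0,
) -> DatasetSplit:
    """Deterministic stay-level partition (largest-remainder rounding).

    Splitting at the stay level (never the window level) keeps all windows
    of one patient stay inside a single part, preventing leakage of
    overlapping histories between train and test.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    ids = [r.stay_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate stay_ids")
    n = len(ids)
    nonzero = sum(f > 0 for f in fractions)
    if n < nonzero:
        raise ValueError(f"{n} stays cannot fill {nonzero} nonempty parts")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    quotas = np.array(fractions) * n
    counts = np.floor(quotas).astype(int)
    remainders = quotas - counts
    # largest remainder; ties broken by part order (train, val, test)
    for _ in range(n - counts.sum()):
        k = int(np.argmax(remainders))
        counts[k] += 1
        remainders[k] = -1.0
    for frac, cnt in zip(fractions, counts):
        if frac > 0 and cnt == 0:
            raise ValueError("a nonzero split part received no stays")
    shuffled = [ids[i] for i in order]
    a, b = counts[0], counts[0] + counts[1]
    return DatasetSplit(
        train=tuple(shuffled[:a]),
        val=tuple(shuffled[a:b]),
        test=tuple(shuffled[b:]),
    )


def preprocess(
    record: StayRecord,
    stats: "NormalizationStats | DatasetSplit",
    standardize: bool = False,
) -> StayRecord:
    """Impute missing signal entries with the train mean; optionally scale.

    Standardization maps each input signal to zero mean / unit variance
    using the train statistics.  Drug channels are imputed to 0 and never
    standardized.  Static fields are imputed with the train mean.  The
    observation mask is preserved unchanged.  ``stats`` may be a fitted
    :class:`NormalizationStats` or a :class:`DatasetSplit` carrying one.
    """
    if isinstance(stats, DatasetSplit):
        if stats.normalization_stats is None:
            raise ValueError("split has no fitted normalization statistics")
        stats = stats.normalization_stats
    sig = record.signals.copy()
    for j, name in enumerate(record.variables):
        missing = ~record.mask[:, j] | np.isnan(sig[:, j])
        if name in DRUG_CHANNELS:
            sig[missing, j] = 0.0
            continue
        m, s = stats.mean[j], stats.sd[j]
        if np.isnan(m):
            continue  # variable was excluded from the fit; leave as is
        sig[missing, j] = m
        if standardize:
            sig[:, j] = (sig[:, j] - m) / s
    stat_arr = record.static.to_array()
    nanstat = np.isnan(stat_arr)
    stat_arr[nanstat] = stats.static_mean[nanstat]
    return StayRecord(
        stay_id=record.stay_id,
        static=StaticVector.from_array(stat_arr),
        signals=sig,
        mask=record.mask.copy(),
        hospital_tag=record.hospital_tag,
        variables=record.variables,
        meta=dict(record.meta),
    )


# ---------------------------------------------------------------------------
# Cohort I/O: one long signals table + one statics table per dataset.
# Plain-text dialect: UTF-8 CSV with a header row, NaN (empty cell) for
# missing; `minute` is the 1-based minute index.  Parquet is the binary
# columnar alternative (same schema).
# ---------------------------------------------------------------------------

def write_cohort(
    records: Sequence[StayRecord], prefix: str | Path, fmt: str = "csv"
) -> tuple[Path, Path]:
    """Write a cohort as ``<prefix>_signals.{csv,parquet}`` + statics table."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    frames = []
    stat_rows = []
    for rec in records:
        T = rec.n_minutes
        df = pd.DataFrame(
            np.where(rec.mask, rec.signals, np.nan), columns=list(rec.variables)
        )
        df.insert(0, "minute", np.arange(1, T + 1))
        df.insert(0, "stay_id", rec.stay_id)
        frames.append(df)
        row = {"stay_id": rec.stay_id, "hospital_tag": rec.hospital_tag}
        row.update(
            {f: getattr(rec.static, f) for f in STATIC_FIELDS}
        )
        stat_rows.append(row)
    signals = pd.concat(frames, ignore_index=True)
    statics = pd.DataFrame(stat_rows)
    if fmt == "csv":
        sig_path = prefix.with_name(prefix.name + "_signals.csv")
        stat_path = prefix.with_name(prefix.name + "_static.csv")
        signals.to_csv(sig_path, index=False)
        statics.to_csv(stat_path, index=False)
    elif fmt == "parquet":
        sig_path = prefix.with_name(prefix.name + "_signals.parquet")
        stat_path = prefix.with_name(prefix.name + "_static.parquet")
        signals.to_parquet(sig_path, index=False)
        statics.to_parquet(stat_path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return sig_path, stat_path


def read_cohort(prefix: str | Path, fmt: str = "csv") -> list[StayRecord]:
    """Read a cohort written by :func:`write_cohort`."""
    prefix = Path(prefix)
    if fmt == "csv":
        signals = pd.read_csv(prefix.with_name(prefix.name + "_signals.csv"))
        statics = pd.read_csv(prefix.with_name(prefix.name + "_static.csv"))
    elif fmt == "parquet":
        signals = pd.read_parquet(
            prefix.with_name(prefix.name + "_signals.parquet")
        )
        statics = pd.read_parquet(
            prefix.with_name(prefix.name + "_static.parquet")
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")
    variables = tuple(c for c in signals.columns if c not in ("stay_id", "minute"))
    statics = statics.set_index("stay_id")
    records = []
    for sid, grp in signals.groupby("stay_id", sort=False):
        grp = grp.sort_values("minute")
        mat = grp[list(variables)].to_numpy(dtype=float)
        srow = statics.loc[sid]
        records.append(
            StayRecord(
                stay_id=str(sid),
                static=StaticVector(
                    **{f: float(srow[f]) for f in STATIC_FIELDS}
                ),
                signals=mat,
                mask=~np.isnan(mat),
                hospital_tag=str(srow.get("hospital_tag", "")),
                variables=variables,
            )
        )
    return records
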