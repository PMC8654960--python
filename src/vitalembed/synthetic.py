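"""Multi-hospital synthetic vital-sign cohorts.

The generator produces minute-resolution stays with the statistical
structure the forecasting pipeline assumes, so every stage is testable
without restricted clinical data:

* each signal follows a first-order autoregressive (AR(1)) latent process
  around a hospital-specific baseline, plus independent per-minute
  measurement noise;
* adverse episodes are *planted*: a downward (upward, for hypertension)
  baseline drift begins ``lead_time`` minutes before the latent trace
  crosses the outcome threshold, holds below it for ``duration`` minutes,
  then recovers.  Histories therefore carry genuine predictive signal —
  the property the whole embedding-transfer story relies on;
* phenylephrine pulses follow low-blood-pressure episodes with a
  configurable probability, emulating reactive administration;
* missingness is independent per entry and per variable; an ICU-style
  profile makes every channel except SAO2 effectively unobserved;
* hospitals differ through :func:`make_shifted_profile` (covariate shift
  in statics and signal baselines) while the drift-precedes-event
  mechanism stays identical, so cross-hospital transfer is learnable.

Every stay is a pure function of ``(profile.seed, stay_index)`` through a
counter-based seeding scheme, so cohorts are reproducible and
order-independent.
"""

from __future__ import annotations

import copy
import hashlib
from dataclasses import dataclass, field

import numpy as np

from .cohort import (
    DRUG_CHANNELS,
    INPUT_SIGNALS,
    StayRecord,
    StaticVector,
    build_window_set,
)
from .outcomes import OUTCOMES, label_cohort


@dataclass
class SignalParams:
    """AR(1) latent + observation noise for one signal.

    ``baseline`` is the stationary latent mean (clinical units), ``rho``
    the per-minute autocorrelation, ``sd_process`` the AR innovation sd
    and ``sd_obs`` the independent measurement noise sd.

    ``artifact_rate`` adds transient measurement artifacts: with this
    per-minute probability the *observed* value (never the latent state)
    is additionally depressed by Uniform(*artifact_depth*) units — the
    single-minute spurious dips that probe contact loss and motion
    produce on real monitors.  Artifacts corrupt individual minutes of
    the history and of the label-bearing future alike.
    """

    baseline: float
    rho: float = 0.9
    sd_process: float = 0.3
    sd_obs: float = 0.5
    artifact_rate: float = 0.0
    artifact_depth: tuple[float, float] = (2.0, 4.0)

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ValueError("autocorrelation must lie in (-1, 1)")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact rate must lie in [0, 1]")


@dataclass
class EventParams:
    """Planted-episode dynamics for one outcome.

    ``hazard`` is the per-minute probability of starting a new adverse
    episode when none is active; the drift ramps linearly over
    ``lead_time`` minutes to ``margin`` beyond the outcome threshold
    (scaled by a per-episode depth jitter drawn from ``depth_jitter``,
    always >= 1 so a planted episode always crosses), holds for
    ``duration`` minutes, and recovers over ``lead_time``.

    ``dip_hazard`` starts *benign dips*: the same drift shape but with a
    relative depth drawn from ``dip_depth`` (< 1), so the latent trace
    approaches the threshold without crossing it.  Near-miss dips are
    what make forecasting genuinely uncertain — whether an unfolding
    excursion will cross can only be judged from the filtered level and
    trend of the noisy history.
    """

    hazard: float = 0.004
    lead_time: int = 30
    duration: int = 6
    margin: float = 2.0
    depth_jitter: tuple[float, float] = (1.0, 1.35)
    dip_hazard: float = 0.008
    dip_depth: tuple[float, float] = (0.35, 0.85)
    lead_range: tuple[int, int] | None = None   # per-episode onset speed

    def __post_init__(self) -> None:
        if not 0.0 <= self.hazard <= 1.0:
            raise ValueError("hazard must lie in [0, 1]")
        if not 0.0 <= self.dip_hazard <= 1.0:
            raise ValueError("dip_hazard must lie in [0, 1]")
        if self.depth_jitter[0] < 1.0:
            raise ValueError("depth jitter must keep episodes crossing (>= 1)")
        if self.dip_depth[1] >= 1.0:
            raise ValueError("dip depth must stay below the threshold (< 1)")


@dataclass
class StaticDistributions:
    height: tuple[float, float] = (168.0, 10.0)    # cm
    weight: tuple[float, float] = (82.0, 22.0)     # kg
    age: tuple[float, float] = (52.0, 17.0)        # years
    asa_probs: tuple[float, ...] = (0.08, 0.32, 0.42, 0.15, 0.03)
    p_emergency: float = 0.0765
    p_female: float = 0.57


def _default_signal_params() -> dict[str, SignalParams]:
    return {
        "SAO2": SignalParams(98.0, rho=0.97, sd_process=0.15, sd_obs=1.0,
                             artifact_rate=0.05, artifact_depth=(2.0, 5.0)),
        "ETCO2": SignalParams(38.0, rho=0.9, sd_process=0.25, sd_obs=0.6),
        "NIBPS": SignalParams(120.0, rho=0.9, sd_process=1.5, sd_obs=3.0),
        "NIBPM": SignalParams(83.0, rho=0.92, sd_process=1.2, sd_obs=2.5),
        "NIBPD": SignalParams(64.0, rho=0.9, sd_process=1.2, sd_obs=2.5),
        "FIO2": SignalParams(50.0, rho=0.95, sd_process=0.8, sd_obs=1.0),
        "ETSEV": SignalParams(1.8, rho=0.95, sd_process=0.05, sd_obs=0.05),
        "ECGRATE": SignalParams(76.0, rho=0.9, sd_process=1.0, sd_obs=1.5),
        "PEAK": SignalParams(20.0, rho=0.95, sd_process=0.4, sd_obs=0.5),
        "PEEP": SignalParams(5.0, rho=0.97, sd_process=0.1, sd_obs=0.2),
        "PIP": SignalParams(18.0, rho=0.95, sd_process=0.4, sd_obs=0.5),
        "RESPRATE": SignalParams(12.0, rho=0.9, sd_process=0.4, sd_obs=0.5),
        "TEMP1": SignalParams(36.4, rho=0.98, sd_process=0.02, sd_obs=0.05),
    }


def _default_event_params() -> dict[str, EventParams]:
    return {
        "hypoxemia": EventParams(hazard=0.002, dip_hazard=0.004,
                                 dip_depth=(0.5, 0.9)),
        "hypocapnia": EventParams(hazard=0.0025, dip_hazard=0.004,
                                  dip_depth=(0.35, 0.7)),
        "hypotension": EventParams(hazard=0.0035),
        "hypertension": EventParams(hazard=0.0015),
    }


@dataclass
class HospitalProfile:
    """Everything needed to simulate one hospital's cohort."""

    name: str = "OR0"
    n_stays: int = 100
    stay_length_range: tuple[int, int] = (120, 240)
    signals: tuple[str, ...] = INPUT_SIGNALS
    signal_params: dict[str, SignalParams] = field(
        default_factory=_default_signal_params
    )
    event_params: dict[str, EventParams] = field(
        default_factory=_default_event_params
    )
    statics: StaticDistributions = field(default_factory=StaticDistributions)
    missingness: dict[str, float] = field(default_factory=dict)
    missingness_default: float = 0.02
    drug_response: float = 0.7
    keep_latent: bool = False    # stash the noiseless latent path in meta
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stays < 1:
            raise ValueError("n_stays must be >= 1")
        for name, rate in self.missingness.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missingness rate for {name} outside [0, 1]")
        unknown = [s for s in self.signals if s not in self.signal_params]
        if unknown:
            raise ValueError(f"signals without parameters: {unknown}")

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.signals) + DRUG_CHANNELS

    def missing_rate(self, signal: str) -> float:
        return self.missingness.get(signal, self.missingness_default)


def small_profile(
    name: str = "OR0",
    n_stays: int = 100,
    signals: tuple[str, ...] = ("SAO2", "ETCO2", "NIBPM"),
    stay_length_range: tuple[int, int] = (100, 140),
    seed: int = 0,
    **kwargs,
) -> HospitalProfile:
    """A reduced-scale profile (3 signals, shorter stays) for experiments."""
    return HospitalProfile(
        name=name, n_stays=n_stays, signals=signals,
        stay_length_range=stay_length_range, seed=seed, **kwargs,
    )


def icu_profile(name: str = "ICUM", n_stays: int = 100, seed: int = 0,
                **kwargs) -> HospitalProfile:
    """ICU-style profile: only SAO2 is consistently observed.

    Every other channel is set to ~100% missingness, so only the SAO2
    embedding model can be trained from such a cohort.
    """
    missing = {s: 0.998 for s in INPUT_SIGNALS if s != "SAO2"}
    missing["SAO2"] = 0.02
    return HospitalProfile(
        name=name, n_stays=n_stays, missingness=missing, seed=seed, **kwargs
    )


# -- covariate shift ---------------------------------------------------------

def make_shifted_profile(profile: HospitalProfile, shift_spec: dict) -> HospitalProfile:
    """A covariate-shifted copy of a profile; the event mechanism is untouched.

    ``shift_spec`` keys:

    * ``"name"`` — new hospital tag;
    * ``"seed"`` — new seed;
    * ``"static:<field>"`` — new value for a :class:`StaticDistributions`
      field (e.g. ``"static:p_female": 0.38``);
    * ``"baseline:<signal>"`` — additive shift of a signal baseline;
    * ``"sd_obs:<signal>"`` / ``"rho:<signal>"`` — new observation-noise
      sd / autocorrelation for a signal;
    * ``"hazard:<outcome>"`` — new episode hazard;
    * ``"missingness:<signal>"`` — new per-entry missingness rate.

    An empty spec returns an identical profile.
    """
    new = copy.deepcopy(profile)
    for key, value in shift_spec.items():
        if key == "name":
            new.name = value
        elif key == "seed":
            new.seed = value
        elif key.startswith("static:"):
            setattr(new.statics, key.split(":", 1)[1], value)
        elif key.startswith("baseline:"):
            new.signal_params[key.split(":", 1)[1]].baseline += value
        elif key.startswith("sd_obs:"):
            new.signal_params[key.split(":", 1)[1]].sd_obs = value
        elif key.startswith("rho:"):
            new.signal_params[key.split(":", 1)[1]].rho = value
        elif key.startswith("hazard:"):
            new.event_params[key.split(":", 1)[1]].hazard = value
        elif key.startswith("missingness:"):
            new.missingness[key.split(":", 1)[1]] = value
        else:
            raise KeyError(f"unknown shift key {key!r}")
    return new


# -- simulation --------------------------------------------------------------

def _stay_rng(profile: HospitalProfile, stay_index: int) -> np.random.Generator:
    # counter-based: each stay gets an independent stream from (seed, index)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(int(profile.seed), int(stay_index)))
    )


def _plant_offsets(
    T: int, ev: EventParams, distance: float, sign: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[dict]]:
    """Baseline offsets from planted episodes and benign dips + metadata.

    ``distance`` is |baseline - threshold|.  An adverse episode drifts to
    ``jitter * (distance + margin)`` (always beyond the threshold); a
    benign dip only to ``rel * distance`` with ``rel < 1``.
    """
    offsets = np.zeros(T)
    episodes = []
    max_lead = ev.lead_range[1] if ev.lead_range else ev.lead_time
    span = 2 * max_lead + ev.duration

    def episode_shape():
        # per-episode onset speed: fast and slow excursions coexist, so
        # both the smoothed level and the precise recent slope carry signal
        lead = (int(rng.integers(ev.lead_range[0], ev.lead_range[1] + 1))
                if ev.lead_range else ev.lead_time)
        ramp = np.linspace(0.0, 1.0, lead + 1)[1:]
        return lead, np.concatenate([ramp, np.ones(ev.duration), ramp[::-1]])

    t = 0
    while t < T - span:
        u = rng.random()
        if u < ev.hazard:
            lead, shape = episode_shape()
            jitter = rng.uniform(*ev.depth_jitter)
            amplitude = jitter * (distance + ev.margin)
            offsets[t : t + shape.size] += sign * amplitude * shape
            episodes.append(
                {
                    "kind": "event",
                    "start": t,
                    "cross": t + lead,               # latent crossing minute
                    "recover": t + lead + ev.duration,
                    "amplitude": float(amplitude),
                }
            )
            t += 2 * lead + ev.duration
        elif u < ev.hazard + ev.dip_hazard:
            lead, shape = episode_shape()
            amplitude = rng.uniform(*ev.dip_depth) * distance
            offsets[t : t + shape.size] += sign * amplitude * shape
            episodes.append(
                {
                    "kind": "dip",
                    "start": t,
                    "trough": t + lead,
                    "amplitude": float(amplitude),
                }
            )
            t += 2 * lead + ev.duration
        else:
            t += 1
    return offsets, episodes


def simulate_stay(profile: HospitalProfile, stay_index: int) -> StayRecord:
    """Simulate one stay, reproducibly from ``(profile.seed, stay_index)``."""
    rng = _stay_rng(profile, stay_index)
    lo, hi = profile.stay_length_range
    T = int(rng.integers(lo, hi + 1))
    variables = profile.variables
    V = len(variables)
    signals = np.zeros((T, V))
    episodes_meta: dict[str, list[dict]] = {}

    # planted-episode offsets per outcome-bearing signal
    offsets = {s: np.zeros(T) for s in profile.signals}
    for outcome, ev in profile.event_params.items():
        spec = OUTCOMES[outcome]
        target = spec.target_variable
        if target not in profile.signals or ev.hazard <= 0:
            continue
        base = profile.signal_params[target].baseline
        sign = 1.0 if spec.comparator == ">" else -1.0
        distance = abs(base - spec.threshold)
        off, eps = _plant_offsets(T, ev, distance, sign, rng)
        offsets[target] += off
        episodes_meta[outcome] = eps

    latent_store: dict[str, np.ndarray] = {}
    for j, name in enumerate(profile.signals):
        sp = profile.signal_params[name]
        innov = rng.normal(0.0, sp.sd_process, size=T)
        latent = np.empty(T)
        stat_sd = sp.sd_process / np.sqrt(1.0 - sp.rho**2)
        latent[0] = rng.normal(0.0, stat_sd)
        for t in range(1, T):
            latent[t] = sp.rho * latent[t - 1] + innov[t]
        level = sp.baseline + offsets[name] + latent
        if profile.keep_latent:
            latent_store[name] = level.copy()
        obs = level + rng.normal(0.0, sp.sd_obs, size=T)
        if sp.artifact_rate > 0:
            hit = rng.random(T) < sp.artifact_rate
            obs[hit] -= rng.uniform(*sp.artifact_depth, size=int(hit.sum()))
        signals[:, j] = obs
    # physical floors/caps for bounded signals
    if "SAO2" in profile.signals:
        j = variables.index("SAO2")
        signals[:, j] = np.clip(signals[:, j], 0.0, 100.0)

    # drug pulses follow low-blood-pressure episodes
    phenyl = np.zeros(T)
    epine = np.zeros(T)
    for ep in episodes_meta.get("hypotension", []):
        if ep["kind"] != "event":
            continue
        if rng.random() < profile.drug_response:
            start = min(ep["cross"] + int(rng.integers(1, 3)), T - 1)
            phenyl[start : start + 3] = 1.0
            if rng.random() < 0.1:  # epinephrine reserved for severe episodes
                epine[start : start + 2] = 1.0
    signals[:, variables.index("PHENYL")] = phenyl
    signals[:, variables.index("EPINE")] = epine

    mask = np.ones((T, V), dtype=bool)
    for j, name in enumerate(profile.signals):
        rate = profile.missing_rate(name)
        if rate > 0:
            mask[:, j] = rng.random(T) >= rate
    signals = np.where(mask, signals, np.nan)

    st = profile.statics
    static = StaticVector(
        height=float(rng.normal(*st.height)),
        weight=float(rng.normal(*st.weight)),
        asa_code=float(rng.choice(len(st.asa_probs), p=st.asa_probs) + 1),
        asa_emergency=float(rng.random() < st.p_emergency),
        gender=float(rng.random() < st.p_female),
        age=float(np.clip(rng.normal(*st.age), 18.0, 95.0)),
    )
    return StayRecord(
        stay_id=f"{profile.name}-{stay_index:05d}",
        static=static,
        signals=signals,
        mask=mask,
        hospital_tag=profile.name,
        variables=variables,
        meta=(
            {"episodes": episodes_meta, "latent": latent_store}
            if profile.keep_latent
            else {"episodes": episodes_meta}
        ),
    )


def simulate_cohort(
    profile: HospitalProfile, stride: int = 1
) -> tuple[list[StayRecord], dict]:
    """All stays of a profile plus an empirical window-level base-rate report."""
    records = [simulate_stay(profile, i) for i in range(profile.n_stays)]
    windows = build_window_set(records, stride=stride)
    report: dict = {
        "hospital": profile.name,
        "n_stays": len(records),
        "n_windows": int(windows.n),
        "base_rates": {},
        "n_defined": {},
    }
    for name, spec in OUTCOMES.items():
        if spec.target_variable not in windows.variables:
            continue
        try:
            res = label_cohort(windows, spec)
        except ValueError:
            continue
        report["base_rates"][name] = res.base_rate
        report["n_defined"][name] = res.n_defined
    return records, report


def save_profile(profile: HospitalProfile, path) -> None:
    """Write a profile as a YAML config file (the plain-text format)."""
    import yaml

    doc = {
        "name": profile.name,
        "n_stays": profile.n_stays,
        "stay_length_range": list(profile.stay_length_range),
        "signals": list(profile.signals),
        "signal_params": {
            k: {
                "baseline": v.baseline, "rho": v.rho,
                "sd_process": v.sd_process, "sd_obs": v.sd_obs,
                "artifact_rate": v.artifact_rate,
                "artifact_depth": list(v.artifact_depth),
            }
            for k, v in profile.signal_params.items()
        },
        "event_params": {
            k: {
                "hazard": v.hazard, "lead_time": v.lead_time,
                "duration": v.duration, "margin": v.margin,
                "depth_jitter": list(v.depth_jitter),
                "dip_hazard": v.dip_hazard, "dip_depth": list(v.dip_depth),
            }
            for k, v in profile.event_params.items()
        },
        "statics": {
            "height": list(profile.statics.height),
            "weight": list(profile.statics.weight),
            "age": list(profile.statics.age),
            "asa_probs": list(profile.statics.asa_probs),
            "p_emergency": profile.statics.p_emergency,
            "p_female": profile.statics.p_female,
        },
        "missingness": dict(profile.missingness),
        "missingness_default": profile.missingness_default,
        "drug_response": profile.drug_response,
        "seed": profile.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_profile(path) -> HospitalProfile:
    """Read a profile written by :func:`save_profile`."""
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    tup = tuple
    return HospitalProfile(
        name=doc["name"],
        n_stays=doc["n_stays"],
        stay_length_range=tup(doc["stay_length_range"]),
        signals=tup(doc["signals"]),
        signal_params={
            k: SignalParams(
                baseline=v["baseline"], rho=v["rho"],
                sd_process=v["sd_process"], sd_obs=v["sd_obs"],
                artifact_rate=v.get("artifact_rate", 0.0),
                artifact_depth=tup(v.get("artifact_depth", (2.0, 4.0))),
            )
            for k, v in doc["signal_params"].items()
        },
        event_params={
            k: EventParams(
                hazard=v["hazard"], lead_time=v["lead_time"],
                duration=v["duration"], margin=v["margin"],
                depth_jitter=tup(v["depth_jitter"]),
                dip_hazard=v["dip_hazard"], dip_depth=tup(v["dip_depth"]),
            )
            for k, v in doc["event_params"].items()
        },
        statics=StaticDistributions(
            height=tup(doc["statics"]["height"]),
            weight=tup(doc["statics"]["weight"]),
            age=tup(doc["statics"]["age"]),
            asa_probs=tup(doc["statics"]["asa_probs"]),
            p_emergency=doc["statics"]["p_emergency"],
            p_female=doc["statics"]["p_female"],
        ),
        missingness=dict(doc.get("missingness", {})),
        missingness_default=doc.get("missingness_default", 0.02),
        drug_response=doc.get("drug_response", 0.7),
        seed=doc.get("seed", 0),
    )


def cohort_digest(records: list[StayRecord]) -> str:
    """SHA-256 digest over all matrices and statics (reproducibility probe)."""
    h = hashlib.sha256()
    for rec in sorted(records, key=lambda r: r.stay_id):
        h.update(rec.stay_id.encode())
        h.update(np.nan_to_num(rec.signals, nan=-1e30).tobytes())
        h.update(rec.mask.tobytes())
        h.update(rec.static.to_array().tobytes())
    return h.hexdigest()
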