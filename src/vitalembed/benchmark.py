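"""The scaled-down two-hospital synthetic study.

This module pins the study conditions used by the acceptance checks and
by ``scripts/acceptance.py``: two covariate-shifted hospitals (different
gender ratio, emergency fraction, and signal baselines, identical event
mechanism), three signals, 16-dimensional embeddings, and a seeded
protocol for

* the embedding-plan comparison (raw / rand / next / next-transferred
  average precision on the target hospital's held-out stays), and
* the paired fine-tuning-versus-scratch convergence comparison.

Everything is deterministic in the supplied seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import build_window_set, fit_normalization, split_by_stay
from .embeddings import TrainConfig, build_model, fine_tune, task_targets, train_embedding
from .synthetic import HospitalProfile, make_shifted_profile, simulate_cohort, small_profile
from .transfer import ExperimentConfig, run_experiment

#: Covariate shift between the two synthetic hospitals: the gender ratio
#: and emergency fraction move between their two observed values, blood
#: pressure and CO2 baselines shift a few clinical units, and adverse
#: hypoxemic episodes are half again as frequent (a sicker case mix).
#: The signal dynamics and the drift-precedes-event mechanism are shared
#: — the physiology is the same machine — so transfer is learnable while
#: the patient and outcome distributions differ markedly.
HOSPITAL_SHIFT = {
    "static:p_female": 0.38,
    "static:p_emergency": 0.1531,
    "baseline:NIBPM": 3.0,
    "baseline:ETCO2": 1.0,
    "hazard:hypoxemia": 0.003,
}

BENCH_SIGNALS = ("SAO2", "ETCO2", "NIBPM")
BENCH_DIM = 16


def benchmark_profiles(
    seed: int, n_stays: int = 300
) -> tuple[HospitalProfile, HospitalProfile]:
    """The (target, source) hospital pair at a given cohort seed."""
    target = small_profile(name="OR0", n_stays=n_stays, seed=seed,
                           signals=BENCH_SIGNALS)
    source = make_shifted_profile(
        target, {"name": "OR1", "seed": seed + 1000, **HOSPITAL_SHIFT}
    )
    return target, source


def benchmark_config(
    seed: int,
    n_stays: int = 300,
    plans: tuple[str, ...] = ("raw", "rand", "next", "next-transferred"),
    outcome: str = "hypoxemia",
    n_bootstrap: int = 200,
) -> ExperimentConfig:
    target, source = benchmark_profiles(seed, n_stays)
    return ExperimentConfig(
        target_profile=target,
        source_profile=source,
        outcome=outcome,
        plans=plans,
        embedding_dim=BENCH_DIM,
        stride=4,
        upstream_stride=1,
        eval_stride=1,
        train_config=TrainConfig(max_epochs=25, patience=5,
                                 learning_rate=3e-3, seed=seed),
        n_bootstrap=n_bootstrap,
        seed=seed,
    )


def ordering_benchmark(
    seeds: tuple[int, ...] = (11, 23, 37, 51, 68),
    n_stays: int = 300,
    plans: tuple[str, ...] = ("raw", "rand", "next", "next-transferred"),
) -> pd.DataFrame:
    """Per-(seed, target) APs of each plan over both transfer directions.

    For each cohort seed the hospital pair is simulated once, per-signal
    models are trained once per hospital, and every plan is evaluated
    with each hospital as the target in turn — the aggregate-over-targets
    protocol.  The methods comparison reads off the medians over the
    resulting rows: trained self-supervised embeddings should beat the
    raw identity features, untrained random embeddings should not, and
    foreign-trained models applied across the covariate shift should
    transfer their advantage.
    """
    from .transfer import ModelRegistry

    rows = []
    for seed in seeds:
        registry = ModelRegistry()
        target, source = benchmark_profiles(seed, n_stays)
        for tgt, src in ((target, source), (source, target)):
            cfg = benchmark_config(seed, n_stays, plans)
            cfg.target_profile, cfg.source_profile = tgt, src
            result = run_experiment(cfg, registry=registry)
            row = {"seed": seed, "target": tgt.name}
            row.update(dict(zip(result.table["plan"], result.table["ap"])))
            row["base_rate"] = float(result.table["base_rate"].iloc[0])
            rows.append(row)
    return pd.DataFrame(rows).set_index(["seed", "target"])


def seed_median_aps(table: pd.DataFrame) -> pd.Series:
    """Reduce a per-(seed, target) AP table to one median AP per plan.

    Within each cohort seed the two target-hospital rows are averaged
    first — the aggregate-across-targets rule — and the median is then
    taken across seeds.
    """
    return table.groupby(level="seed").mean().median()


@dataclass
class ConvergencePair:
    seed: int
    epochs_fine_tuned: int
    epochs_scratch: int
    val_loss_fine_tuned: float
    val_loss_scratch: float


def _signal_arrays(profile: HospitalProfile, signal: str, seed: int):
    records, _ = simulate_cohort(profile)
    split = split_by_stay(records, seed=seed)
    by_id = {r.stay_id: r for r in records}
    stats = fit_normalization([by_id[s] for s in split.train],
                              variables=(signal,))
    mean, sd = stats.for_variable(signal)

    def std(a):
        a = np.where(np.isnan(a), mean, a)
        return (a - mean) / sd

    out = {}
    for part in ("train", "val"):
        ws = build_window_set([by_id[s] for s in getattr(split, part)])
        h = std(ws.signal_history(signal))
        f = std(ws.signal_future(signal))
        out[part] = (h, task_targets("next", h, futures=f))
    return out, (mean, sd)


def convergence_benchmark(
    seeds: tuple[int, ...] = (3, 5, 7, 11, 13),
    n_stays: int = 120,
    signal: str = "SAO2",
    max_epochs: int = 20,
) -> list[ConvergencePair]:
    """Paired fine-tuning-vs-scratch runs on the shifted hospital pair.

    For each seed: pretrain a next-task model at the source hospital,
    then (a) fine-tune it on the target and (b) train an identical
    architecture on the target from scratch, with the same training
    configuration, and record the epoch of each run's best validation
    checkpoint.  Warm starts are expected to reach their best loss in no
    more epochs than cold starts in most pairs.
    """
    out = []
    for seed in seeds:
        target_profile, source_profile = benchmark_profiles(seed, n_stays)
        src, src_norm = _signal_arrays(source_profile, signal, seed)
        tgt, _ = _signal_arrays(target_profile, signal, seed)
        cfg = TrainConfig(max_epochs=max_epochs, patience=4,
                          learning_rate=3e-3, seed=seed)
        pre = build_model(signal, "next", BENCH_DIM, seed=seed,
                          source_tag=source_profile.name)
        pre.norm = {signal: src_norm}
        pre = train_embedding(pre, *src["train"], *src["val"], cfg)
        tuned = fine_tune(pre, target_profile.name,
                          *tgt["train"], *tgt["val"], cfg)
        scratch = build_model(signal, "next", BENCH_DIM, seed=seed,
                              source_tag=target_profile.name)
        scratch = train_embedding(scratch, *tgt["train"], *tgt["val"], cfg)
        out.append(
            ConvergencePair(
                seed=seed,
                epochs_fine_tuned=tuned.training_meta["best_epoch"],
                epochs_scratch=scratch.training_meta["best_epoch"],
                val_loss_fine_tuned=tuned.training_meta["best_val_loss"],
                val_loss_scratch=scratch.training_meta["best_val_loss"],
            )
        )
    return out
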