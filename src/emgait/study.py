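"""End-to-end synthetic study: simulate -> label -> condition -> train -> score.

This mirrors the reference experimental design at desk scale: a cohort of
synthetic subjects walking overground (WO, with quiet-standing interludes)
and on a treadmill (WT, continuous); MVIC trials per muscle for
normalization; kinematics-driven labeling; cross-subject train/val/test
split with WT test-only; and the three evaluation configurations:

* experiment 1 — train and test on 500 Hz windows (1 s each);
* experiment 2 — the 500 Hz-trained model scored on 1500 Hz windows
  (same 500-sample length, 0.333 s span);
* experiment 3 — experiment 2 after partial retraining on a seeded 30%
  subset of the 1500 Hz overground training windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import (SequenceDataset, augment_minority, make_sequences,
                      resample_labels, split_cross_subject)
from .evaluate import confusion_metrics, per_subject_accuracy
from .labeling import label_session
from .model import (BiLSTMPhaseModel, ModelConfig, TrainConfig, build_model,
                    partial_retrain, train)
from .preprocess import mvic_record_from_trials, preprocess_emg
from .signals import MUSCLES
from .simulate import GaitSimParams, simulate_mvic, simulate_session

# plausible maximal isometric forces (N) for the four test setups
_MVIC_FORCE_N = {"TA": 300.0, "VL": 450.0, "SOL": 500.0, "BF": 250.0}


@dataclass
class StudyConfig:
    """Desk-scale defaults for the seeded synthetic study."""

    n_subjects: int = 14
    n_test_subjects: int = 2
    steps_wo: int = 26
    steps_wt: int = 16
    standing_after_step: int = 13
    standing_duration_s: float = 6.0
    cycle_jitter_cv: float = 0.02
    bi_units: tuple[int, ...] = (32, 16)
    dense_units: tuple[int, ...] = (32, 16)
    dropout: float = 0.30
    epochs: int = 8
    retrain_epochs: int = 3
    batch_size: int = 64
    learning_rate: float = 1e-3
    seq_len: int = 500


def _subject_params(cfg: StudyConfig, seed: int, subject_i: int,
                    scenario: str) -> GaitSimParams:
    wo = scenario == "WO"
    return GaitSimParams(
        n_steps=cfg.steps_wo if wo else cfg.steps_wt,
        standing_interludes=((cfg.standing_after_step,
                              cfg.standing_duration_s),) if wo else (),
        cycle_jitter_cv=cfg.cycle_jitter_cv,
        seed=(seed * 1000 + subject_i * 10 + (0 if wo else 1)) % (2 ** 31),
    )


def prepare_subject(cfg: StudyConfig, seed: int, subject_i: int,
                    scenario: str):
    """Simulate, label and condition one subject session.

    Returns ``(env_500, labels_500, env_1500, labels_1500)`` where the
    envelopes are MVIC-normalized :class:`SignalTrace` objects and the
    labels are the kinematics-derived stance/swing tracks resampled onto
    the corresponding EMG grids.
    """
    params = _subject_params(cfg, seed, subject_i, scenario)
    ha, ka, emg, truth = simulate_session(params)
    refs = {}
    for k, muscle in enumerate(MUSCLES):
        trials = simulate_mvic(
            _MVIC_FORCE_N[muscle],
            GaitSimParams(n_steps=1, seed=(params.seed + 7 * k + 1) % (2 ** 31)),
        )
        refs[muscle] = mvic_record_from_trials(muscle, trials)
    env_1500 = preprocess_emg(emg, refs, rate_out=emg.rate_hz)
    env_500 = preprocess_emg(emg, refs, rate_out=emg.rate_hz / 3)
    _, _, labels = label_session(ha, ka, scenario, seed=params.seed % 10000)
    lab_500 = resample_labels(labels, env_500.rate_hz)
    lab_1500 = resample_labels(labels, env_1500.rate_hz)
    return env_500, lab_500, env_1500, lab_1500


def build_study_datasets(cfg: StudyConfig, seed: int):
    """Assemble the 500 Hz and 1500 Hz cross-subject datasets.

    Training subjects' overground sessions are cut with 50% overlap;
    test subjects' overground and treadmill sessions are cut without
    overlap.  The 500 Hz training split is minority-augmented.
    """
    rng = np.random.default_rng(seed)
    subject_ids = [f"S{i + 1:02d}" for i in range(cfg.n_subjects)]
    test_subjects = set(rng.choice(subject_ids, size=cfg.n_test_subjects,
                                   replace=False).tolist())
    ds_500 = SequenceDataset()
    ds_1500 = SequenceDataset()
    L = cfg.seq_len
    for i, sid in enumerate(subject_ids):
        is_test = sid in test_subjects
        scenarios = ("WO", "WT") if is_test else ("WO",)
        for scenario in scenarios:
            env5, lab5, env15, lab15 = prepare_subject(cfg, seed, i, scenario)
            step = L if is_test else L // 2
            ds_500.extend(make_sequences(env5, lab5, sid, scenario, L, step))
            ds_1500.extend(make_sequences(env15, lab15, sid, scenario, L, step))
    ds_500 = split_cross_subject(ds_500, seed=seed, test_subjects=test_subjects)
    ds_1500 = split_cross_subject(ds_1500, seed=seed, test_subjects=test_subjects)
    ds_500 = augment_minority(ds_500)
    return ds_500, ds_1500, sorted(test_subjects)


def _test_metrics(model: BiLSTMPhaseModel, ds: SequenceDataset, scenario: str):
    seqs = [s for s, sp in zip(ds.sequences, ds.split)
            if sp == "test" and s.scenario == scenario]
    if not seqs:
        raise ValueError(f"no test sequences for scenario {scenario}")
    X = np.stack([s.x for s in seqs])
    Y = np.stack([s.y for s in seqs])
    pred = model.predict_labels(X)
    report = confusion_metrics(pred.ravel(), Y.ravel())
    rows = pd.DataFrame({
        "subject": [s.subject for s in seqs],
        "scenario": [s.scenario for s in seqs],
        "accuracy": [100.0 * float(np.mean(model.predict_labels(s.x) == s.y))
                     for s in seqs],
    })
    return report, rows


def run_synthetic_study(seed: int = 1, cfg: StudyConfig | None = None) -> dict:
    """Run the full desk-scale study; returns the metric summary.

    Keys: ``acc_wo_500`` / ``acc_wt_500`` (experiment 1 pooled per-sample
    accuracies), ``acc_1500_before`` / ``acc_1500_after`` (experiments 2/3
    pooled over WO+WT 1500 Hz test windows), the per-scenario
    :class:`MetricsReport` objects, the per-subject accuracy table and the
    trained model.
    """
    cfg = cfg or StudyConfig()
    ds_500, ds_1500, test_subjects = build_study_datasets(cfg, seed)
    model = build_model(
        ModelConfig(input_dim=len(MUSCLES), seq_len=cfg.seq_len,
                    bi_units=cfg.bi_units, dense_units=cfg.dense_units,
                    dropout=cfg.dropout),
        seed=seed,
    )
    tc = TrainConfig(epochs=cfg.epochs, batch_size=cfg.batch_size,
                     learning_rate=cfg.learning_rate, seed=seed, patience=3)
    train(model, ds_500, tc)

    report_wo, rows_wo = _test_metrics(model, ds_500, "WO")
    report_wt, rows_wt = _test_metrics(model, ds_500, "WT")

    # experiment 2: same weights, 0.333 s windows from the 1500 Hz data
    X15, Y15 = ds_1500.arrays("test")
    acc_before = 100.0 * float(np.mean(model.predict_labels(X15) == Y15))

    # experiment 3: partial retraining on 30% of the 1500 Hz WO train windows
    tc_re = TrainConfig(epochs=cfg.retrain_epochs, batch_size=cfg.batch_size,
                        learning_rate=cfg.learning_rate, seed=seed + 1,
                        retrain_fraction=0.30, patience=3)
    partial_retrain(model, ds_1500, tc_re)
    acc_after = 100.0 * float(np.mean(model.predict_labels(X15) == Y15))

    subject_table = per_subject_accuracy(pd.concat([rows_wo, rows_wt]))
    return {
        "test_subjects": test_subjects,
        "acc_wo_500": report_wo.accuracy,
        "acc_wt_500": report_wt.accuracy,
        "report_wo_500": report_wo,
        "report_wt_500": report_wt,
        "acc_1500_before": acc_before,
        "acc_1500_after": acc_after,
        "per_subject": subject_table,
        "model": model,
        "n_train_sequences": sum(1 for s in ds_500.split if s == "train"),
        "n_test_sequences": sum(1 for s in ds_500.split if s == "test"),
    }
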