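"""Sequence dataset construction for the per-timestep classifier.

Normalized EMG envelopes are cut into fixed-length windows (500 samples;
1 s at 500 Hz, 0.333 s at 1500 Hz) carrying a per-sample stance/swing
label vector.  Training windows use 50% overlap, test windows none.
Windows containing any excluded sample are dropped.  Class imbalance is
countered by duplicating training windows whose swing-sample share exceeds
70%.  Splits are cross-subject: test subjects never contribute training or
validation windows, and treadmill (WT) windows are test-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .labeling import EXCLUDED, PhaseLabelTrack
from .signals import SignalTrace

SEQ_LEN_DEFAULT = 500


@dataclass
class LabeledSequence:
    """One fixed-length window of normalized EMG with per-sample labels."""

    x: np.ndarray          # (L, C) fraction-of-MVIC envelopes
    y: np.ndarray          # (L,) 0 stance / 1 swing
    subject: str
    scenario: str          # "WO" | "WT"
    rate_hz: float
    start_time_s: float

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float32)
        self.y = np.asarray(self.y, dtype=np.int8)
        if self.x.shape[0] != self.y.shape[0]:
            raise ValueError("x and y must have the same length")
        if np.any(self.y == EXCLUDED):
            raise ValueError("sequences must not contain excluded samples")

    @property
    def swing_fraction(self) -> float:
        return float(np.mean(self.y == 1))


@dataclass
class SequenceDataset:
    """Bag of labeled sequences plus a per-sequence split tag."""

    sequences: list[LabeledSequence] = field(default_factory=list)
    split: list[str] = field(default_factory=list)  # train | val | test | ""

    def __post_init__(self) -> None:
        if not self.split:
            self.split = [""] * len(self.sequences)
        if len(self.split) != len(self.sequences):
            raise ValueError("split and sequences length mismatch")

    def __len__(self) -> int:
        return len(self.sequences)

    def subjects(self) -> list[str]:
        return sorted({s.subject for s in self.sequences})

    def subset(self, split: str) -> "SequenceDataset":
        keep = [i for i, s in enumerate(self.split) if s == split]
        return SequenceDataset([self.sequences[i] for i in keep],
                               [split] * len(keep))

    def arrays(self, split: str | None = None):
        """Stack into (N, L, C) float32 and (N, L) int8 arrays."""
        idx = range(len(self)) if split is None else \
            [i for i, s in enumerate(self.split) if s == split]
        seqs = [self.sequences[i] for i in idx]
        if not seqs:
            raise ValueError(f"no sequences in split {split!r}")
        X = np.stack([s.x for s in seqs]).astype(np.float32)
        Y = np.stack([s.y for s in seqs]).astype(np.int64)
        return X, Y

    def extend(self, other: "SequenceDataset") -> None:
        self.sequences.extend(other.sequences)
        self.split.extend(other.split)

    def save(self, path) -> None:
        X = np.stack([s.x for s in self.sequences])
        Y = np.stack([s.y for s in self.sequences])
        np.savez_compressed(
            path, x=X, y=Y,
            subject=np.array([s.subject for s in self.sequences]),
            scenario=np.array([s.scenario for s in self.sequences]),
            rate=np.array([s.rate_hz for s in self.sequences]),
            start=np.array([s.start_time_s for s in self.sequences]),
            split=np.array(self.split),
        )

    @classmethod
    def load(cls, path) -> "SequenceDataset":
        z = np.load(path, allow_pickle=False)
        seqs = [
            LabeledSequence(z["x"][i], z["y"][i], str(z["subject"][i]),
                            str(z["scenario"][i]), float(z["rate"][i]),
                            float(z["start"][i]))
            for i in range(z["x"].shape[0])
        ]
        return cls(seqs, [str(s) for s in z["split"]])


def resample_labels(labels: PhaseLabelTrack, target_rate: float) -> PhaseLabelTrack:
    """Map a label track onto a faster grid by nearest-sample assignment.

    Each target-rate sample takes the label of the nearest source sample,
    with exact midpoints resolved to the earlier one; excluded propagates.
    """
    src_rate = labels.rate_hz
    n_src = labels.n_samples
    n_tgt = int(round(n_src * target_rate / src_rate))
    j = np.arange(n_tgt)
    idx = np.ceil(j * (src_rate / target_rate) - 0.5).astype(int)
    idx = np.clip(idx, 0, max(n_src - 1, 0))
    return PhaseLabelTrack(labels.labels[idx], target_rate)


def make_sequences(channels: SignalTrace, labels: PhaseLabelTrack,
                   subject: str, scenario: str,
                   length: int = SEQ_LEN_DEFAULT,
                   step: int | None = None) -> SequenceDataset:
    """Cut windows inside each contiguous non-excluded segment.

    Within a segment of N samples the window starts are 0, step, 2*step,
    ... giving floor((N - length)/step) + 1 windows for N >= length.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if step is None:
        step = length
    if step <= 0:
        raise ValueError("step must be positive")
    if channels.rate_hz != labels.rate_hz:
        raise ValueError("signal and label rates differ")
    n = min(channels.n_samples, labels.n_samples)
    lab = labels.labels[:n]
    x = channels.values[:n]
    seqs = []
    mask = lab != EXCLUDED
    # contiguous non-excluded runs
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    for i0, i1 in zip(np.nonzero(d == 1)[0], np.nonzero(d == -1)[0]):
        start = i0
        while start + length <= i1:
            seqs.append(LabeledSequence(
                x[start:start + length], lab[start:start + length],
                subject, scenario, channels.rate_hz, start / channels.rate_hz,
            ))
            start += step
    return SequenceDataset(seqs)


def augment_minority(ds: SequenceDataset, threshold: float = 0.70,
                     minority_class: int = 1) -> SequenceDataset:
    """Duplicate once every *training* window dominated by the minority class.

    In the reference protocol swing (class 1) is the minority; windows with
    a minority-sample share strictly above ``threshold`` are replicated and
    the copies appended in order.  Validation/test windows are untouched.
    """
    new = SequenceDataset(list(ds.sequences), list(ds.split))
    for i, (seq, sp) in enumerate(zip(ds.sequences, ds.split)):
        if sp != "train":
            continue
        frac = float(np.mean(seq.y == minority_class))
        if frac > threshold:
            new.sequences.append(seq)
            new.split.append("train")
    return new


def split_cross_subject(ds: SequenceDataset, n_test_subjects: int = 3,
                        val_fraction: float = 0.20, seed: int = 0,
                        test_subjects=None) -> SequenceDataset:
    """Cross-subject train/val/test assignment.

    ``n_test_subjects`` whole subjects (seeded choice, unless given
    explicitly) form the test set.  Of the remaining subjects' overground
    sequences a seeded ``val_fraction`` sample goes to validation and the
    rest to training.  Treadmill (WT) sequences are test-only: WT windows
    of test subjects go to the test split and WT windows of training
    subjects are dropped.
    """
    subjects = ds.subjects()
    if test_subjects is None:
        if len(subjects) < n_test_subjects + 1:
            raise ValueError("too few subjects for the requested split")
        rng = np.random.default_rng(seed)
        test_subjects = set(
            rng.choice(subjects, size=n_test_subjects, replace=False).tolist()
        )
    else:
        test_subjects = set(test_subjects)
        unknown = test_subjects - set(subjects)
        if unknown:
            raise ValueError(f"unknown test subject(s) {sorted(unknown)}")

    rng = np.random.default_rng(seed + 1)
    seqs, split = [], []
    train_pool = []
    for seq in ds.sequences:
        if seq.subject in test_subjects:
            seqs.append(seq)
            split.append("test")
        elif seq.scenario == "WT":
            continue  # treadmill data never trains the model
        else:
            train_pool.append(seq)
    n_val = int(round(val_fraction * len(train_pool)))
    val_idx = set(rng.choice(len(train_pool), size=n_val,
                             replace=False).tolist()) if n_val else set()
    for i, seq in enumerate(train_pool):
        seqs.append(seq)
        split.append("val" if i in val_idx else "train")
    return SequenceDataset(seqs, split)
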