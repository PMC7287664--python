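"""Signal preprocessing and dataset assembly.

Raw accelerometer and reference-angle series are low-pass filtered with a
zero-phase fourth-order Butterworth filter (6 Hz cut-off by default), the
orientation-robust resultant channel ``a_xyz = sqrt(ax^2 + ay^2 + az^2)``
is derived from the filtered axes, and a 600 ms window (60 samples at
100 Hz) slides over the signal at single-sample stride.  Each window of
shape (60, 4) is paired with the reference hip/knee/ankle angles at its
centre sample.  Zero-phase (forward–backward) filtering is used so that
the filtered acceleration and the angle targets stay time-aligned; the
effective magnitude response is the squared fourth-order response.

Splitting supports the two evaluation protocols: an intra-participant
80/20 split performed at the level of whole trials (so overlapping
windows never straddle the train/test boundary) and leave-one-subject-out
folds for the inter-participant protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import warnings

import numpy as np
from scipy import signal as sps

from .simulate import TrialRecord


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth settings (zero-phase by default)."""

    order: int = 4
    cutoff: float = 6.0        # Hz
    sample_rate: float = 100.0  # Hz
    zero_phase: bool = True

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if not 0 < self.cutoff < self.sample_rate / 2:
            raise ValueError("cutoff must lie strictly below the Nyquist frequency")

    def fingerprint(self) -> dict:
        return {"filter_order": self.order, "filter_cutoff": self.cutoff,
                "sample_rate": self.sample_rate, "zero_phase": self.zero_phase}


def lowpass(x: np.ndarray, spec: FilterSpec) -> np.ndarray:
    """Zero-phase Butterworth low-pass along axis 0; preserves length."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    sos = sps.butter(spec.order, spec.cutoff, btype="low", output="sos",
                     fs=spec.sample_rate)
    min_len = max(3 * spec.order, 3 * (2 * spec.order + 1))
    if x.shape[0] <= min_len:
        raise ValueError(f"signal too short for order-{spec.order} filtering "
                         f"(need > {min_len} samples, got {x.shape[0]})")
    if spec.zero_phase:
        return sps.sosfiltfilt(sos, x, axis=0)
    return sps.sosfilt(sos, x, axis=0)


def resultant(accel: np.ndarray) -> np.ndarray:
    """Root-sum-square of the three acceleration axes (orientation-free)."""
    accel = np.asarray(accel, dtype=float)
    if accel.ndim != 2 or accel.shape[1] != 3:
        raise ValueError(f"expected a (T, 3) array, got shape {accel.shape}")
    if not np.all(np.isfinite(accel)):
        raise ValueError("acceleration contains non-finite values")
    return np.sqrt(np.einsum("ij,ij->i", accel, accel))


def filter_trial(trial: TrialRecord, spec: FilterSpec | None = None) -> TrialRecord:
    """Return a copy of the trial with accel, angles and heel height filtered."""
    spec = spec or FilterSpec(sample_rate=trial.sample_rate)
    if abs(spec.sample_rate - trial.sample_rate) > 1e-9:
        spec = replace(spec, sample_rate=trial.sample_rate)
    return replace(
        trial,
        accel=lowpass(trial.accel, spec),
        angles=lowpass(trial.angles, spec),
        heel_height=lowpass(trial.heel_height, spec),
        preprocessing=spec.fingerprint(),
    )


@dataclass
class WindowedDataset:
    """Model-ready windows: X (N, 60, 4), y (N, 3) and per-window provenance.

    Channels are ordered (ax, ay, az, a_xyz); ``center_idx`` is the sample
    index of each window's target within its source trial.
    """

    X: np.ndarray
    y: np.ndarray
    trial_ids: np.ndarray       # (N,) str
    participant_ids: np.ndarray  # (N,) str
    center_idx: np.ndarray      # (N,) int
    window_len: int
    fingerprint: dict = field(default_factory=dict)

    def __post_init__(self):
        N = len(self.X)
        if not (self.y.shape == (N, 3) and len(self.trial_ids) == N
                and len(self.center_idx) == N and len(self.participant_ids) == N):
            raise ValueError("inconsistent window array lengths")
        if N and self.X.shape[1:] != (self.window_len, 4):
            raise ValueError(f"X must be (N, {self.window_len}, 4), got {self.X.shape}")

    def __len__(self) -> int:
        return len(self.X)

    def select(self, mask_or_idx) -> "WindowedDataset":
        return WindowedDataset(
            X=self.X[mask_or_idx], y=self.y[mask_or_idx],
            trial_ids=self.trial_ids[mask_or_idx],
            participant_ids=self.participant_ids[mask_or_idx],
            center_idx=self.center_idx[mask_or_idx],
            window_len=self.window_len, fingerprint=dict(self.fingerprint))

    def for_trials(self, trial_ids) -> "WindowedDataset":
        return self.select(np.isin(self.trial_ids, list(trial_ids)))

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("X", data=self.X, compression="gzip")
            fh.create_dataset("y", data=self.y, compression="gzip")
            str_dt = h5py.string_dtype()
            fh.create_dataset("trial_ids", data=self.trial_ids.astype(object),
                              dtype=str_dt)
            fh.create_dataset("participant_ids",
                              data=self.participant_ids.astype(object), dtype=str_dt)
            fh.create_dataset("center_idx", data=self.center_idx)
            fh.attrs["window_len"] = self.window_len
            for key, val in self.fingerprint.items():
                fh.attrs[f"fp_{key}"] = val

    @classmethod
    def load(cls, path) -> "WindowedDataset":
        import h5py

        with h5py.File(path, "r") as fh:
            fingerprint = {k[3:]: (v.item() if hasattr(v, "item") else v)
                           for k, v in fh.attrs.items() if k.startswith("fp_")}
            return cls(
                X=fh["X"][...], y=fh["y"][...],
                trial_ids=fh["trial_ids"].asstr()[...],
                participant_ids=fh["participant_ids"].asstr()[...],
                center_idx=fh["center_idx"][...],
                window_len=int(fh.attrs["window_len"]),
                fingerprint=fingerprint)


def make_windows(trial: TrialRecord, window_ms: float = 600.0) -> WindowedDataset:
    """Slide a centred window over one trial at single-sample stride.

    The window holds ``L = round(window_ms/1000 * rate)`` samples (60 at the
    defaults), split as ``n = L/2`` past samples (including the centre) and
    ``n`` future samples: a window with centre ``t`` spans samples
    ``t-n+1 .. t+n`` and its target is the angle triple at ``t``.  Windows
    that would cross either trial edge are dropped, so a contiguous trial of
    length T yields ``T - L + 1`` windows.
    """
    L = int(round(window_ms / 1000.0 * trial.sample_rate))
    if L < 2:
        raise ValueError("window too short at this sample rate")
    T = trial.n_samples
    if T < L:
        raise ValueError(f"trial of {T} samples shorter than one {L}-sample window")
    chans = np.column_stack([trial.accel, resultant(trial.accel)])
    # (T, 4) -> (N, 4, L) -> (N, L, 4)
    X = np.lib.stride_tricks.sliding_window_view(chans, L, axis=0)
    X = np.ascontiguousarray(X.transpose(0, 2, 1), dtype=np.float32)
    centers = np.arange(T - L + 1) + (L // 2 - 1)
    fingerprint = dict(trial.preprocessing or {})
    fingerprint.update({"window_len": L, "window_ms": window_ms})
    return WindowedDataset(
        X=X,
        y=trial.angles[centers].astype(np.float32),
        trial_ids=np.full(len(X), trial.trial_id, dtype=object),
        participant_ids=np.full(len(X), trial.participant_id, dtype=object),
        center_idx=centers,
        window_len=L,
        fingerprint=fingerprint)


def concat_windows(datasets) -> WindowedDataset:
    """Concatenate per-trial windowed datasets (fingerprints must agree)."""
    datasets = list(datasets)
    if not datasets:
        raise ValueError("no datasets to concatenate")
    fp = datasets[0].fingerprint
    for ds in datasets[1:]:
        if ds.fingerprint != fp:
            raise ValueError("cannot concatenate datasets with different "
                             f"preprocessing fingerprints: {ds.fingerprint} != {fp}")
    return WindowedDataset(
        X=np.concatenate([ds.X for ds in datasets]),
        y=np.concatenate([ds.y for ds in datasets]),
        trial_ids=np.concatenate([ds.trial_ids for ds in datasets]),
        participant_ids=np.concatenate([ds.participant_ids for ds in datasets]),
        center_idx=np.concatenate([ds.center_idx for ds in datasets]),
        window_len=datasets[0].window_len,
        fingerprint=dict(fp))


@dataclass(frozen=True)
class Fold:
    """One train/test assignment, expressed as trial ids."""

    train_trials: tuple[str, ...]
    test_trials: tuple[str, ...]
    label: str = ""

    def __post_init__(self):
        if set(self.train_trials) & set(self.test_trials):
            raise ValueError("train and test trials overlap")


@dataclass
class SplitPlan:
    """Evaluation split: one fold per participant (both protocols)."""

    mode: str                   # "intra" | "loso"
    folds: list[Fold]
    train_fraction: float | None = None
    seed: int | None = None


def _trials_by_participant(trials) -> dict[str, list[TrialRecord]]:
    groups: dict[str, list[TrialRecord]] = {}
    for trial in trials:
        groups.setdefault(trial.participant_id, []).append(trial)
    return groups


def split_intra(trials, train_fraction: float = 0.8,
                seed: int | None = 0) -> SplitPlan:
    """Per-participant 80/20 split at the whole-trial level.

    Trials of each participant are shuffled (seeded) and assigned to the
    training set until the requested fraction of trials is reached
    (nearest-trial rounding, always leaving at least one test trial).
    Splitting whole trials guarantees that no test window shares samples
    with any training window, since windows never cross trial boundaries.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly inside (0, 1)")
    rng = np.random.default_rng(seed)
    folds = []
    for pid, group in sorted(_trials_by_participant(trials).items()):
        ids = [trial.trial_id for trial in group]
        if len(ids) < 2:
            raise ValueError(
                f"participant {pid} has {len(ids)} trial(s); need >= 2 to split")
        order = rng.permutation(len(ids))
        n_train = int(round(train_fraction * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        shuffled = [ids[i] for i in order]
        folds.append(Fold(train_trials=tuple(shuffled[:n_train]),
                          test_trials=tuple(shuffled[n_train:]),
                          label=pid))
    return SplitPlan(mode="intra", folds=folds,
                     train_fraction=train_fraction, seed=seed)


def split_loso(trials) -> SplitPlan:
    """Leave-one-subject-out folds: each participant is the test set once."""
    groups = _trials_by_participant(trials)
    if len(groups) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 participants")
    all_ids = {pid: tuple(trial.trial_id for trial in group)
               for pid, group in groups.items()}
    folds = []
    for pid in sorted(groups):
        test = all_ids[pid]
        train = tuple(tid for other, ids in sorted(all_ids.items())
                      if other != pid for tid in ids)
        folds.append(Fold(train_trials=train, test_trials=test, label=pid))
    return SplitPlan(mode="loso", folds=folds)


def split_windows_random(dataset: WindowedDataset, train_fraction: float = 0.8,
                         seed: int | None = 0):
    """Per-window random split (the literal reading of 'randomly ... 80%').

    Overlapping windows assigned to opposite sides share up to L-1 of their
    L samples, so this split leaks training information into the test set;
    it is provided only for comparison and warns when used.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly inside (0, 1)")
    warnings.warn("per-window random splitting leaks samples between train "
                  "and test sets; prefer split_intra", stacklevel=2)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(dataset))
    n_train = int(round(train_fraction * len(dataset)))
    return order[:n_train], order[n_train:]
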