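"""Scoring of estimated joint-angle trajectories and discrete gait events.

Continuous trajectories are scored per participant with RMSE (deg), NRMSE
(RMSE as a percentage of that participant's reference angle range) and the
coefficient of determination R^2.  Six discrete gait events are read off
each stride — peak hip flexion, peak hip extension (magnitude), peak knee
flexion during stance, peak ankle dorsiflexion, peak ankle plantarflexion
(magnitude) and the signed ankle angle at initial contact — with strides
delimited by successive initial contacts, themselves detected as the
per-stride minima of heel vertical height.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .simulate import EVENT_NAMES

JOINTS = ("hip", "knee", "ankle")


# ---------------------------------------------------------------------------
# Continuous metrics
# ---------------------------------------------------------------------------

def _check_pair(y, y_hat):
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    if y.size == 0:
        raise ValueError("empty series")
    return y, y_hat


def rmse(y, y_hat) -> float:
    """Root-mean-square error (same units as the inputs)."""
    y, y_hat = _check_pair(y, y_hat)
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def nrmse(y, y_hat) -> float:
    """RMSE normalised by the reference range, in percent."""
    y, y_hat = _check_pair(y, y_hat)
    rng = float(y.max() - y.min())
    if rng <= 0:
        raise ValueError("reference series has zero range")
    return 100.0 * rmse(y, y_hat) / rng


def r2(y, y_hat) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot (can be negative)."""
    y, y_hat = _check_pair(y, y_hat)
    if y.size < 2:
        raise ValueError("need at least 2 samples for R^2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0:
        raise ValueError("reference series is constant; R^2 undefined")
    return 1.0 - float(np.sum((y - y_hat) ** 2)) / ss_tot


# ---------------------------------------------------------------------------
# Gait events
# ---------------------------------------------------------------------------

@dataclass
class GaitEvents:
    """Per-stride values of the six discrete gait events (deg).

    Extension / plantarflexion peaks are magnitudes of negative angles;
    ``ankle_angle_at_ic`` is signed.  ``ic_index`` holds the initial-contact
    sample index opening each stride.
    """

    ic_index: np.ndarray
    hip_peak_flexion: np.ndarray
    hip_peak_extension: np.ndarray
    knee_peak_flexion_stance: np.ndarray
    ankle_peak_dorsiflexion: np.ndarray
    ankle_peak_plantarflexion: np.ndarray
    ankle_angle_at_ic: np.ndarray

    def __post_init__(self):
        n = len(self.ic_index)
        for name in EVENT_NAMES:
            if len(getattr(self, name)) != n:
                raise ValueError(f"event {name} does not have one value per stride")

    @property
    def n_strides(self) -> int:
        return len(self.ic_index)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"ic_index": self.ic_index,
                             **{n: getattr(self, n) for n in EVENT_NAMES}})


def detect_initial_contacts(heel_height: np.ndarray,
                            sample_rate: float) -> np.ndarray:
    """Initial contacts as the per-stride minima of heel vertical height.

    The dominant stride period is estimated from the autocorrelation of the
    mean-removed series (searched over 0.3–2 s lags); local minima are then
    required to be at least half that period apart.  Raises if the series is
    flat, monotone, or shows no usable periodicity.
    """
    h = np.asarray(heel_height, dtype=float).ravel()
    if h.size < 4 or float(np.std(h)) < 1e-9:
        raise ValueError("heel-height series is flat; no strides to detect")
    x = h - h.mean()
    ac = np.correlate(x, x, mode="full")[x.size - 1:]
    ac = ac / ac[0]
    lag_lo = max(2, int(round(0.3 * sample_rate)))
    lag_hi = min(x.size - 1, int(round(2.0 * sample_rate)))
    if lag_hi <= lag_lo:
        raise ValueError("series shorter than one plausible stride")
    window = ac[lag_lo:lag_hi + 1]
    period = lag_lo + int(np.argmax(window))
    if window.max() < 0.2:
        raise ValueError("no stride periodicity detectable in heel height")
    ics, _ = sps.find_peaks(-h, distance=max(1, int(round(0.5 * period))))
    if ics.size == 0:
        raise ValueError("no heel-height minima found")
    return ics


def extract_events(angles: np.ndarray, ic_indices,
                   stance_fraction: float = 0.4) -> GaitEvents:
    """Read the six gait events off each IC-to-IC stride.

    ``angles`` is (T, 3) hip/knee/ankle in degrees, flexion/dorsiflexion
    positive.  The knee flexion peak is searched only within the stance
    window, taken as the first ``stance_fraction`` of the stride after
    initial contact.  Strides are right-exclusive; partial strides at the
    trial edges are discarded by construction.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.ndim != 2 or angles.shape[1] != 3:
        raise ValueError(f"expected (T, 3) angles, got {angles.shape}")
    ics = np.asarray(ic_indices, dtype=int)
    if ics.size < 2:
        raise ValueError("need at least 2 initial contacts (one full stride)")
    if np.any(np.diff(ics) <= 0):
        raise ValueError("initial-contact indices must be strictly increasing")
    if ics[0] < 0 or ics[-1] >= len(angles):
        raise ValueError("initial-contact index outside the trial")

    rows = {name: [] for name in EVENT_NAMES}
    for k in range(ics.size - 1):
        a, b = ics[k], ics[k + 1]
        hip, knee, ankle = (angles[a:b, j] for j in range(3))
        stance_end = a + max(1, int(round(stance_fraction * (b - a))))
        rows["hip_peak_flexion"].append(hip.max())
        rows["hip_peak_extension"].append(abs(hip.min()))
        rows["knee_peak_flexion_stance"].append(angles[a:stance_end, 1].max())
        rows["ankle_peak_dorsiflexion"].append(ankle.max())
        rows["ankle_peak_plantarflexion"].append(abs(ankle.min()))
        rows["ankle_angle_at_ic"].append(angles[a, 2])
    return GaitEvents(ic_index=ics[:-1],
                      **{n: np.asarray(v) for n, v in rows.items()})


def event_errors(reference: GaitEvents, estimated: GaitEvents,
                 max_unmatched_fraction: float = 0.2) -> pd.DataFrame:
    """Stride-matched per-event error summary.

    Strides are paired by initial-contact proximity (within half the median
    stride of the reference); raises if more than ``max_unmatched_fraction``
    of reference strides find no partner.  Returns a DataFrame indexed by
    event with reference/estimated means and SDs, MAE (SD) and the mean
    signed difference (estimated - reference).
    """
    ref_ic = np.asarray(reference.ic_index)
    est_ic = np.asarray(estimated.ic_index)
    if ref_ic.size == 0 or est_ic.size == 0:
        raise ValueError("no strides to compare")
    tol = max(1.0, 0.5 * float(np.median(np.diff(ref_ic)))
              if ref_ic.size > 1 else np.inf)
    pairs = []
    for i, ic in enumerate(ref_ic):
        j = int(np.argmin(np.abs(est_ic - ic)))
        if abs(int(est_ic[j]) - int(ic)) <= tol:
            pairs.append((i, j))
    if len(pairs) < (1 - max_unmatched_fraction) * ref_ic.size:
        raise ValueError(
            f"only {len(pairs)}/{ref_ic.size} strides could be matched")
    ridx = [i for i, _ in pairs]
    eidx = [j for _, j in pairs]
    records = {}
    for name in EVENT_NAMES:
        r = getattr(reference, name)[ridx]
        e = getattr(estimated, name)[eidx]
        ae = np.abs(e - r)
        records[name] = {
            "reference_mean": r.mean(), "reference_sd": r.std(ddof=0),
            "estimated_mean": e.mean(), "estimated_sd": e.std(ddof=0),
            "mae": ae.mean(), "mae_sd": ae.std(ddof=0),
            "mean_difference": (e - r).mean(),
            "n_strides": len(pairs),
        }
    return pd.DataFrame(records).T


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-participant and averaged continuous-metric and event summaries.

    ``per_participant`` has one row per participant with columns
    ``{rmse,nrmse,r2}_{hip,knee,ankle}``; ``summary`` aggregates them as
    mean and SD across participants.  ``events_per_participant`` holds the
    stride-level event summaries per participant; ``events_summary``
    averages the per-participant means (mean and across-participant SD),
    mirroring the usual reference/estimated/MAE table layout.
    """

    scenario: str
    per_participant: pd.DataFrame
    summary: pd.DataFrame
    events_per_participant: pd.DataFrame
    events_summary: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "per_participant": self.per_participant.to_dict(orient="index"),
            "summary": self.summary.to_dict(orient="index"),
            "events_summary": self.events_summary.to_dict(orient="index"),
        }

    def to_json(self, path) -> None:
        import json

        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)

    def to_text(self) -> str:
        lines = [f"Scenario: {self.scenario}", "",
                 "Continuous angles (mean (SD) across participants)"]
        header = f"{'':14s}" + "".join(f"{j:>14s}" for j in JOINTS)
        lines.append(header)
        for metric in ("r2", "rmse", "nrmse"):
            row = f"{metric.upper():14s}"
            for joint in JOINTS:
                m = self.summary.loc[f"{metric}_{joint}", "mean"]
                s = self.summary.loc[f"{metric}_{joint}", "sd"]
                row += f"{m:8.2f} ({s:.2f})"
            lines.append(row)
        lines += ["", "Gait events (deg; mean (SD) across participants)"]
        lines.append(f"{'event':28s}{'Reference':>16s}{'Estimated':>16s}"
                     f"{'MAE':>16s}")
        for name in EVENT_NAMES:
            row = self.events_summary.loc[name]
            lines.append(
                f"{name:28s}"
                f"{row['reference_mean']:8.1f} ({row['reference_sd']:4.1f})"
                f"{row['estimated_mean']:8.1f} ({row['estimated_sd']:4.1f})"
                f"{row['mae']:8.1f} ({row['mae_sd']:4.1f})")
        return "\n".join(lines)


def reconstruct_trajectory(estimator, trial, window_ms: float = 600.0):
    """Predict a trial's angle trajectory from its windows.

    Returns ``(centers, y_ref, y_hat)``: the window-centre sample indices
    and the reference/predicted (N, 3) angle series in time order.  Any
    estimator exposing ``predict_windows(X)`` can stand in for the CNN
    (e.g. reference or baseline predictors).
    """
    from .model import predict
    from .preprocess import make_windows

    ds = make_windows(trial, window_ms=window_ms)
    fp = getattr(estimator, "fingerprint", None)
    if fp and ds.fingerprint != fp:
        raise ValueError(
            "preprocessing fingerprint mismatch between trial and estimator: "
            f"{ds.fingerprint} != {fp}")
    if hasattr(estimator, "predict_windows"):
        y_hat = np.asarray(estimator.predict_windows(ds.X), dtype=float)
    else:
        y_hat = predict(estimator, ds.X)
    return ds.center_idx, np.asarray(ds.y, dtype=float), y_hat


def evaluate(estimator, test_trials, stance_fraction: float = 0.4,
             window_ms: float = 600.0) -> EvalReport:
    """Score an estimator on held-out trials, grouped by participant.

    Continuous metrics pool all test windows of a participant; the NRMSE
    normalisation range comes from that participant's reference angles.
    Events are extracted per trial from the reference and predicted
    trajectories at the shared reference initial contacts (detected from
    heel height), then pooled across the participant's strides.
    """
    by_pid: dict[str, list] = {}
    for trial in test_trials:
        by_pid.setdefault(trial.participant_id, []).append(trial)
    if not by_pid:
        raise ValueError("no test trials")

    metric_rows, event_rows = {}, {}
    for pid, trials in sorted(by_pid.items()):
        refs, preds = [], []
        ref_events, est_events = [], []
        for trial in trials:
            centers, y_ref, y_hat = reconstruct_trajectory(
                estimator, trial, window_ms=window_ms)
            refs.append(y_ref)
            preds.append(y_hat)
            try:
                ics = detect_initial_contacts(trial.heel_height,
                                              trial.sample_rate)
            except ValueError:
                continue
            # Keep strides fully covered by window centres and re-index the
            # angle series to the centre grid (centres are contiguous).
            lo, hi = centers[0], centers[-1]
            ics = ics[(ics >= lo) & (ics <= hi)] - lo
            if ics.size < 2:
                continue
            ref_events.append(extract_events(y_ref, ics, stance_fraction))
            est_events.append(extract_events(y_hat, ics, stance_fraction))
        y_ref = np.concatenate(refs)
        y_hat = np.concatenate(preds)
        row = {}
        for j, joint in enumerate(JOINTS):
            row[f"rmse_{joint}"] = rmse(y_ref[:, j], y_hat[:, j])
            row[f"nrmse_{joint}"] = nrmse(y_ref[:, j], y_hat[:, j])
            row[f"r2_{joint}"] = r2(y_ref[:, j], y_hat[:, j])
        metric_rows[pid] = row
        if ref_events:
            ref_all = _concat_events(ref_events)
            est_all = _concat_events(est_events)
            event_rows[pid] = event_errors(ref_all, est_all)

    per_participant = pd.DataFrame(metric_rows).T
    summary = pd.DataFrame({"mean": per_participant.mean(axis=0),
                            "sd": per_participant.std(axis=0, ddof=0)})
    if event_rows:
        events_pp = pd.concat(event_rows, names=["participant", "event"])
        grouped = events_pp.groupby(level="event", sort=False)
        events_summary = pd.DataFrame({
            "reference_mean": grouped["reference_mean"].mean(),
            "reference_sd": grouped["reference_mean"].std(ddof=0),
            "estimated_mean": grouped["estimated_mean"].mean(),
            "estimated_sd": grouped["estimated_mean"].std(ddof=0),
            "mae": grouped["mae"].mean(),
            "mae_sd": grouped["mae"].std(ddof=0),
            "mean_difference": grouped["mean_difference"].mean(),
        }).reindex(list(EVENT_NAMES))
    else:
        events_pp = pd.DataFrame()
        events_summary = pd.DataFrame(
            index=list(EVENT_NAMES),
            columns=["reference_mean", "reference_sd", "estimated_mean",
                     "estimated_sd", "mae", "mae_sd", "mean_difference"],
            dtype=float)
    return EvalReport(scenario="", per_participant=per_participant,
                      summary=summary, events_per_participant=events_pp,
                      events_summary=events_summary)


def _concat_events(events_list) -> GaitEvents:
    offset, ics = 0, []
    fields = {name: [] for name in EVENT_NAMES}
    for ev in events_list:
        ics.append(np.asarray(ev.ic_index) + offset)
        for name in EVENT_NAMES:
            fields[name].append(getattr(ev, name))
        offset += int(np.asarray(ev.ic_index).max()) + 10_000
    return GaitEvents(ic_index=np.concatenate(ics),
                      **{n: np.concatenate(v) for n, v in fields.items()})
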