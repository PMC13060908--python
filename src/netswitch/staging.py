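"""Arousal staging from eye traces or EEG vigilance ranks.

Eye-based staging: a scan is *alert* when eyes were closed for less than 5% of
the scan, *drowsy* between 50% and 90% (inclusive), *discarded* above 90%
(likely faulty tracking or non-compliance), and *intermediate* otherwise.
EEG-based staging thresholds the scan-mean vigilance rank at 3.5, with a
separate *transition* label for scans that start alert and end drowsy.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .simulate import EyeTrace, VigilanceRankSeries


class ArousalLabel(str, enum.Enum):
    ALERT = "alert"
    DROWSY = "drowsy"
    INTERMEDIATE = "intermediate"
    DISCARD = "discard"
    TRANSITION = "transition"


class UnclassifiableScanError(ValueError):
    """Raised when a scan falls exactly on a strict decision boundary."""


@dataclass
class StagedScan:
    scan_id: str
    label: ArousalLabel
    metric: float  # closure fraction (eye) or mean vigilance rank (eeg)
    provenance: str  # 'eye' or 'eeg'

    def __post_init__(self) -> None:
        if self.provenance == "eye" and not 0 <= self.metric <= 1:
            raise ValueError("closure fraction must lie in [0, 1]")
        if self.provenance == "eeg" and not 2 <= self.metric <= 6:
            raise ValueError("mean vigilance rank must lie in [2, 6]")
        if self.provenance not in ("eye", "eeg"):
            raise ValueError("provenance must be 'eye' or 'eeg'")


def _zero_runs(x: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of zero samples as half-open (start, stop) index pairs."""
    closed = x == 0
    if not closed.any():
        return []
    d = np.diff(closed.astype(int))
    starts = list(np.where(d == 1)[0] + 1)
    stops = list(np.where(d == -1)[0] + 1)
    if closed[0]:
        starts.insert(0, 0)
    if closed[-1]:
        stops.append(len(x))
    return list(zip(starts, stops))


def preprocess_eye_trace(trace: EyeTrace) -> EyeTrace:
    """Synchronize, interpolate sub-second blinks, and zero short open bursts.

    Samples before ``scan_onset_index`` are dropped. Zero runs shorter than
    one second (blinks) are linearly interpolated between the flanking valid
    samples; runs of one second or longer are eye closures and are left as
    zeros. Open runs shorter than 100 ms flanked by long closures are zeroed.
    The result is idempotent under re-application.
    """
    if trace.scan_onset_index >= trace.samples.size:
        raise ValueError("trace is entirely pre-onset; nothing to preprocess")
    fs = trace.sampling_rate
    x = trace.samples[trace.scan_onset_index :].astype(float).copy()
    one_s = fs * 1.0

    # 1. linear interpolation of sub-second blinks (needs both flanks)
    for start, stop in _zero_runs(x):
        if (stop - start) >= one_s:
            continue
        if start == 0 or stop == len(x):
            continue  # no flanking sample on one side: leave as closure
        left, right = x[start - 1], x[stop]
        x[start:stop] = np.interp(
            np.arange(start, stop), [start - 1, stop], [left, right]
        )

    # 2. zero out sub-100 ms open bursts between long-duration closures
    runs = _zero_runs(x)
    for (s0, e0), (s1, e1) in zip(runs[:-1], runs[1:]):
        if (e0 - s0) >= one_s and (e1 - s1) >= one_s and (s1 - e0) < 0.1 * fs:
            x[e0:s1] = 0.0

    return EyeTrace(x, fs, scan_onset_index=0)


def closure_fraction(trace: EyeTrace) -> float:
    """Fraction of samples (from scan onset) at which the eyes are closed."""
    x = trace.samples[trace.scan_onset_index :]
    return float(np.mean(x == 0))


def classify_eye(closure_frac: float) -> ArousalLabel:
    """Map an eye-closure fraction to an arousal label.

    [0, 0.05) alert; [0.05, 0.50) intermediate; [0.50, 0.90] drowsy;
    (0.90, 1] discard. A total partition of [0, 1].
    """
    if not 0 <= closure_frac <= 1:
        raise ValueError("closure fraction must lie in [0, 1]")
    if closure_frac < 0.05:
        return ArousalLabel.ALERT
    if 0.50 <= closure_frac <= 0.90:
        return ArousalLabel.DROWSY
    if closure_frac > 0.90:
        return ArousalLabel.DISCARD
    return ArousalLabel.INTERMEDIATE


def classify_eeg(
    ranks: VigilanceRankSeries,
    *,
    transition_quarter: float = 0.25,
    transition_high: float = 4.0,
    transition_low: float = 3.0,
) -> ArousalLabel:
    """Classify a scan from its per-second vigilance ranks.

    Scans whose first-quarter mean is >= 4 and last-quarter mean is <= 3 are
    *transition* scans (alert decaying into drowsiness; excluded downstream).
    Otherwise the scan-mean rank decides: above 3.5 alert, below 3.5 drowsy;
    exactly 3.5 is unclassifiable because both rules are strict.
    """
    r = ranks.ranks
    q = max(1, int(round(transition_quarter * r.size)))
    if r[:q].mean() >= transition_high and r[-q:].mean() <= transition_low:
        return ArousalLabel.TRANSITION
    mean = r.mean()
    if mean > 3.5:
        return ArousalLabel.ALERT
    if mean < 3.5:
        return ArousalLabel.DROWSY
    raise UnclassifiableScanError(
        "scan-mean vigilance rank is exactly 3.5; the alert/drowsy rules are "
        "both strict inequalities"
    )


def stage_eye_scan(scan_id: str, trace: EyeTrace) -> StagedScan:
    """Preprocess an eye trace and stage the scan (thresholds are applied to
    the post-preprocessing closure fraction)."""
    clean = preprocess_eye_trace(trace)
    frac = closure_fraction(clean)
    return StagedScan(scan_id, classify_eye(frac), frac, "eye")


def stage_eeg_scan(scan_id: str, ranks: VigilanceRankSeries) -> StagedScan:
    return StagedScan(scan_id, classify_eeg(ranks), float(ranks.ranks.mean()), "eeg")
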