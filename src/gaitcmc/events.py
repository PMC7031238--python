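"""Gait event detection from footswitches and temporal gait parameters.

Heel strike is an upward threshold crossing of a heel contact switch,
toe-off a downward crossing of the big-toe switch.  From the per-foot event
times the standard temporal gait parameters are computed: stride time
(successive same-foot heel strikes), step time (heel strike to the next
contralateral heel strike), stance (heel strike to same-foot toe-off),
swing / single support (toe-off to the next same-foot heel strike) and
double support (contralateral heel strike to same-foot toe-off, one value
per step).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import SignalRecord

FEET = ("left", "right")


@dataclass
class FootEvents:
    """Heel-strike and toe-off times (seconds) of one foot."""

    heel_strikes: np.ndarray
    toe_offs: np.ndarray
    heel_valid: np.ndarray = None  # per-heel-strike boolean mask
    toe_valid: np.ndarray = None

    def __post_init__(self) -> None:
        self.heel_strikes = np.asarray(self.heel_strikes, dtype=float)
        self.toe_offs = np.asarray(self.toe_offs, dtype=float)
        if self.heel_valid is None:
            self.heel_valid = np.ones(self.heel_strikes.size, dtype=bool)
        if self.toe_valid is None:
            self.toe_valid = np.ones(self.toe_offs.size, dtype=bool)
        self.heel_valid = np.asarray(self.heel_valid, dtype=bool)
        self.toe_valid = np.asarray(self.toe_valid, dtype=bool)
        for name, arr in (("heel_strikes", self.heel_strikes), ("toe_offs", self.toe_offs)):
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise ValueError(f"{name} must be strictly increasing")

    @property
    def n_valid_heel_strikes(self) -> int:
        return int(self.heel_valid.sum())


@dataclass
class EventSeries:
    """Per-foot gait events defining the gait cycles of one record."""

    left: FootEvents
    right: FootEvents
    warnings: list = field(default_factory=list)

    def foot(self, which: str) -> FootEvents:
        if which not in FEET:
            raise ValueError(f"foot must be one of {FEET}, got {which!r}")
        return self.left if which == "left" else self.right

    def shifted(self, dt: float) -> "EventSeries":
        """Events with a constant time offset added (record cropping etc.)."""

        def _shift(fe: FootEvents) -> FootEvents:
            return FootEvents(
                fe.heel_strikes + dt, fe.toe_offs + dt, fe.heel_valid.copy(), fe.toe_valid.copy()
            )

        return EventSeries(_shift(self.left), _shift(self.right), list(self.warnings))

    def mask_intervals(self, intervals) -> "EventSeries":
        """Mark events falling inside any ``(start, stop)`` interval invalid."""

        def _mask(fe: FootEvents) -> FootEvents:
            hv, tv = fe.heel_valid.copy(), fe.toe_valid.copy()
            for a, b in intervals:
                hv &= ~((fe.heel_strikes >= a) & (fe.heel_strikes <= b))
                tv &= ~((fe.toe_offs >= a) & (fe.toe_offs <= b))
            return FootEvents(fe.heel_strikes, fe.toe_offs, hv, tv)

        return EventSeries(_mask(self.left), _mask(self.right), list(self.warnings))


@dataclass
class GaitParameters:
    """Temporal gait parameters, means (and SDs) over valid cycles, pooled feet."""

    stride_time_s: float
    stride_time_sd_s: float
    step_time_s: float
    step_time_sd_s: float
    stance_s: float
    swing_single_support_s: float
    double_support_s: float
    n_cycles: int
    walking_speed_kmh: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "walking_speed_kmh": self.walking_speed_kmh,
            "stride_time_s": self.stride_time_s,
            "stride_time_sd_s": self.stride_time_sd_s,
            "step_time_s": self.step_time_s,
            "step_time_sd_s": self.step_time_sd_s,
            "stance_s": self.stance_s,
            "swing_single_support_s": self.swing_single_support_s,
            "double_support_s": self.double_support_s,
            "n_cycles": self.n_cycles,
        }


@dataclass
class ValidityReport:
    valid: bool
    n_left: int
    n_right: int
    min_heel_strikes: int
    reasons: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def _crossings(x: np.ndarray, fs: float, threshold: float, rising: bool) -> np.ndarray:
    """Linear-interpolated times of threshold crossings in the given direction."""
    above = x >= threshold
    if rising:
        idx = np.flatnonzero(~above[:-1] & above[1:])
    else:
        idx = np.flatnonzero(above[:-1] & ~above[1:])
    if idx.size == 0:
        return np.empty(0)
    x0, x1 = x[idx], x[idx + 1]
    frac = (threshold - x0) / (x1 - x0)
    return (idx + frac) / fs


def _debounce(times: np.ndarray, min_sep_s: float) -> np.ndarray:
    """Merge crossings closer than ``min_sep_s`` (keep the first of a run)."""
    if times.size == 0:
        return times
    keep = [times[0]]
    for t in times[1:]:
        if t - keep[-1] >= min_sep_s:
            keep.append(t)
    return np.asarray(keep)


def detect_events(
    record: SignalRecord,
    threshold: float = 0.5,
    debounce_ms: float = 50.0,
) -> EventSeries:
    """Detect heel-strike and toe-off events from the four footswitch channels.

    Parameters
    ----------
    record
        Record containing four channels with role ``footswitch`` whose
        ``extra`` metadata carries ``side`` in {left, right} and ``part``
        in {heel, toe}.
    threshold
        Crossing threshold as a fraction of each channel's range, which
        makes the detector invariant to amplitude scaling.
    debounce_ms
        Crossings closer together than this are merged (contact bounce).

    Returns
    -------
    EventSeries
        Heel strike = upward crossing of the heel channel, toe-off =
        downward crossing of the toe channel, in seconds.  A channel with
        no crossings yields an empty list and a warning flag.
    """
    fs = record.sample_rate_hz
    chans: dict[tuple[str, str], np.ndarray] = {}
    for i in record.pick("footswitch"):
        c = record.channels[i]
        key = (c.extra.get("side"), c.extra.get("part"))
        chans[key] = record.data[i]
    warnings = []
    feet = {}
    for side in FEET:
        per_part = {}
        for part, rising in (("heel", True), ("toe", False)):
            if (side, part) not in chans:
                raise KeyError(f"missing footswitch channel for {side} {part}")
            x = chans[(side, part)]
            lo, hi = float(x.min()), float(x.max())
            if hi - lo <= 0:
                warnings.append(f"{side} {part} footswitch is constant; no events detected")
                per_part[part] = np.empty(0)
                continue
            thr = lo + threshold * (hi - lo)
            times = _crossings(x, fs, thr, rising=rising)
            times = _debounce(times, debounce_ms / 1000.0)
            if times.size == 0:
                warnings.append(f"no {part} crossings detected on {side} foot")
            per_part[part] = times
        feet[side] = FootEvents(per_part["heel"], per_part["toe"])
    return EventSeries(feet["left"], feet["right"], warnings)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate_record(events: EventSeries, min_heel_strikes: int = 100) -> ValidityReport:
    """Apply the minimum-trigger-count exclusion rule.

    A record is invalid when either foot has fewer than ``min_heel_strikes``
    valid heel strikes (the rule used to exclude footswitch failures).
    """
    n_l = events.left.n_valid_heel_strikes
    n_r = events.right.n_valid_heel_strikes
    reasons = []
    for side, n in (("left", n_l), ("right", n_r)):
        if n < min_heel_strikes:
            reasons.append(f"{side} foot has {n} valid heel strikes (< {min_heel_strikes})")
    return ValidityReport(not reasons, n_l, n_r, min_heel_strikes, reasons)


# ---------------------------------------------------------------------------
# temporal gait parameters
# ---------------------------------------------------------------------------


def _foot_cycles(own: FootEvents, other: FootEvents):
    """Yield per-cycle (stride, step, stance, swing, double_support) tuples.

    A cycle runs from one valid heel strike of a foot to the next.  Within
    each cycle there must be exactly one same-foot toe-off and one
    contralateral heel strike; otherwise the interleaving invariant is
    violated and an error names the first offending event.
    """
    hs = own.heel_strikes[own.heel_valid]
    to = own.toe_offs[own.toe_valid]
    chs = other.heel_strikes[other.heel_valid]
    for a, b in zip(hs[:-1], hs[1:]):
        my_to = to[(to > a) & (to < b)]
        my_chs = chs[(chs > a) & (chs < b)]
        if my_to.size != 1:
            raise ValueError(
                f"interleaving violated: expected one toe-off between heel strikes at "
                f"{a:.3f}s and {b:.3f}s, found {my_to.size}"
            )
        if my_chs.size != 1:
            raise ValueError(
                f"interleaving violated: expected one contralateral heel strike between "
                f"{a:.3f}s and {b:.3f}s, found {my_chs.size}"
            )
        stride = b - a
        stance = float(my_to[0] - a)
        swing = float(b - my_to[0])
        step = float(my_chs[0] - a)
        ds = float(my_to[0] - my_chs[0])  # contralateral heel strike -> own toe-off
        yield stride, step, stance, swing, ds


def compute_gait_parameters(events: EventSeries) -> GaitParameters:
    """Temporal gait parameters from an event series, pooled over both feet.

    Requires at least two valid heel strikes per foot.  The per-cycle sum
    identity ``stance + swing = stride`` holds exactly by construction of
    the phase definitions.
    """
    if all(events.foot(side).n_valid_heel_strikes < 2 for side in FEET):
        raise ValueError("need >= 2 valid heel strikes on at least one foot")
    strides, steps, stances, swings, dss = [], [], [], [], []
    for side in FEET:
        own = events.foot(side)
        if own.n_valid_heel_strikes < 2:
            continue
        other = events.foot("right" if side == "left" else "left")
        for stride, step, stance, swing, ds in _foot_cycles(own, other):
            strides.append(stride)
            steps.append(step)
            stances.append(stance)
            swings.append(swing)
            dss.append(ds)
    strides = np.asarray(strides)
    steps = np.asarray(steps)
    if np.any(np.asarray(dss) < 0):
        raise ValueError("negative double support; toe-off precedes contralateral heel strike")
    return GaitParameters(
        stride_time_s=float(strides.mean()),
        stride_time_sd_s=float(strides.std(ddof=1)) if strides.size > 1 else 0.0,
        step_time_s=float(steps.mean()),
        step_time_sd_s=float(steps.std(ddof=1)) if steps.size > 1 else 0.0,
        stance_s=float(np.mean(stances)),
        swing_single_support_s=float(np.mean(swings)),
        double_support_s=float(np.mean(dss)),
        n_cycles=int(strides.size),
    )
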