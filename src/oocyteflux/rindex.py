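"""Kovats non-isothermal retention-index calibration from an n-alkane ladder.

Each GC-MS injection carries a co-injected ladder of n-alkanes (C12, C15, C19,
C22, C28, C33, C36). Because the oven program is a single linear temperature
ramp, the retention index is interpolated piecewise-linearly between alkane
anchors: a compound eluting between C_a and C_b at time t is assigned

    RI = 100*a + 100*(b - a) * (t - t_a) / (t_b - t_a)

so that every alkane maps exactly to 100x its carbon number. Outside the
ladder the nearest segment is extrapolated and the result is flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["RICalibration", "fit_ri_map", "assign_ri", "invert_ri"]

_FULL_LADDER = (12, 15, 19, 22, 28, 33, 36)


@dataclass(frozen=True)
class RICalibration:
    """Validated alkane anchor set: (carbon_number, retention_time_s) pairs,
    sorted by carbon number with strictly increasing times."""

    anchors: tuple[tuple[int, float], ...]

    @property
    def carbon_numbers(self) -> tuple[int, ...]:
        return tuple(n for n, _ in self.anchors)

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(t for _, t in self.anchors)

    def to_tsv(self) -> str:
        lines = ["carbon_number\trt_seconds"]
        lines += [f"{n}\t{t:.6f}" for n, t in self.anchors]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "RICalibration":
        rows = [ln.split("\t") for ln in text.strip().splitlines()[1:]]
        return fit_ri_map([(int(n), float(t)) for n, t in rows])


def fit_ri_map(alkane_peaks) -> RICalibration:
    """Build a calibration from detected alkane peaks.

    ``alkane_peaks`` is an iterable of (carbon_number, retention_time_s) in any
    order. A ladder missing intermediate alkanes degrades gracefully (with a
    warning); fewer than two anchors or non-monotone times are hard failures.
    """
    anchors = sorted((int(n), float(t)) for n, t in alkane_peaks)
    if len(anchors) < 2:
        raise ValueError(f"need >= 2 alkane anchors, got {len(anchors)}")
    times = [t for _, t in anchors]
    if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("alkane retention times are not strictly increasing")
    missing = set(_FULL_LADDER) - {n for n, _ in anchors}
    if missing:
        warnings.warn(
            f"alkane ladder incomplete; missing C{sorted(missing)}; "
            "proceeding with remaining anchors", stacklevel=2)
    return RICalibration(anchors=tuple(anchors))


def _segment(calib: RICalibration, t: float) -> int:
    """Index of the anchor segment used for time t (nearest for extrapolation)."""
    times = calib.times
    idx = int(np.searchsorted(times, t, side="right")) - 1
    return min(max(idx, 0), len(times) - 2)


def assign_ri(retention_time: float, calib: RICalibration,
              with_flag: bool = False):
    """Map a retention time (s) to a Kovats retention index.

    Returns the RI, or ``(ri, extrapolated)`` when ``with_flag`` is true.
    Times at an anchor map exactly to 100x its carbon number.
    """
    t = float(retention_time)
    if t <= 0:
        raise ValueError(f"retention time must be positive, got {t}")
    i = _segment(calib, t)
    (na, ta), (nb, tb) = calib.anchors[i], calib.anchors[i + 1]
    ri = 100.0 * na + 100.0 * (nb - na) * (t - ta) / (tb - ta)
    if with_flag:
        extrapolated = t < calib.times[0] or t > calib.times[-1]
        return ri, extrapolated
    return ri


def invert_ri(ri: float, calib: RICalibration) -> float:
    """Retention time (s) at which a compound of the given RI elutes, under the
    same piecewise-linear map (inverse of :func:`assign_ri`)."""
    ris = [100.0 * n for n in calib.carbon_numbers]
    idx = int(np.searchsorted(ris, ri, side="right")) - 1
    idx = min(max(idx, 0), len(ris) - 2)
    (na, ta), (nb, tb) = calib.anchors[idx], calib.anchors[idx + 1]
    return ta + (tb - ta) * (ri - 100.0 * na) / (100.0 * (nb - na))
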