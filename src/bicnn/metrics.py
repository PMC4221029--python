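"""Directional tracking-error metrics and cycle-aligned trace overlays."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RseSeries",
    "rse_by_direction",
    "summarize_repeats",
    "overlay_cycles",
]


@dataclass
class RseSeries:
    """Per-cycle RSE of phi and theta, split by motion direction.

    Cycles touched by a fall hold +inf (the robot is down; error is
    unbounded).  ``repeat`` tags the repetition the series came from.
    """

    forward_phi: np.ndarray
    backward_phi: np.ndarray
    forward_theta: np.ndarray
    backward_theta: np.ndarray
    repeat: int = 0


def _direction_masks(t: np.ndarray, freq: float, phase_shift: float) -> np.ndarray:
    """True where the phase-shifted reference half-wave is positive (forward)."""
    return np.sin(2.0 * math.pi * freq * t + phase_shift) > 0.0


def rse_by_direction(log, phase_shift: float = math.pi / 2) -> RseSeries:
    """Per-cycle directional RSE of a :class:`~bicnn.runner.TrialLog`.

    The default ``phase_shift`` of +pi/2 makes the forward mask the samples
    of positive reference velocity; passing
    ``2 pi freq * 10`` reproduces the literal 10 s shift variant.
    """
    n_cycles = log.n_cycles
    spc = log.steps_per_cycle
    fwd = _direction_masks(log.t, log.freq, phase_shift)

    out = {name: np.full(n_cycles, np.inf) for name in
           ("forward_phi", "backward_phi", "forward_theta", "backward_theta")}
    err_phi = log.phi_ref - log.phi
    err_theta = -log.theta  # theta reference is identically zero
    for c in range(n_cycles):
        lo, hi = c * spc, (c + 1) * spc
        if hi > len(log.t) or (log.fallen_step is not None
                               and log.fallen_step < hi):
            break  # this and later cycles stay +inf
        for name, err in (("phi", err_phi), ("theta", err_theta)):
            for dname, mask in (("forward", fwd[lo:hi]), ("backward", ~fwd[lo:hi])):
                sel = err[lo:hi][mask]
                if len(sel) == 0:
                    continue  # flagged as inf (empty direction mask)
                out[f"{dname}_{name}"][c] = math.sqrt(float(np.mean(sel**2)))
    return RseSeries(repeat=getattr(log, "repeat", 0), **out)


def summarize_repeats(series: list[RseSeries]) -> dict[str, np.ndarray]:
    """Per-cycle mean and sd across repeats for each direction/variable."""
    if not series:
        raise ValueError("need at least one repeat")
    out: dict[str, np.ndarray] = {}
    for name in ("forward_phi", "backward_phi", "forward_theta", "backward_theta"):
        stack = np.stack([getattr(s, name) for s in series])
        out[f"{name}_mean"] = stack.mean(axis=0)
        out[f"{name}_sd"] = stack.std(axis=0)
    return out


def overlay_cycles(log, cycle_range: tuple[int, int]) -> dict[str, np.ndarray]:
    """Cycle-aligned traces, one row per cycle in ``[start, stop)``.

    Returns pd_out, vn_out, bicnn_out and (when logged) the per-hemisphere
    mean Purkinje rates, each shaped (n_cycles, steps_per_cycle).
    """
    start, stop = cycle_range
    spc = log.steps_per_cycle
    if start < 0 or stop > log.n_cycles or start >= stop:
        raise IndexError(f"cycle range {cycle_range} outside log")
    if stop * spc > len(log.t):
        raise IndexError(f"cycle range {cycle_range} truncated by a fall")
    out = {}
    for name in ("pd_out", "vn_out", "bicnn_out", "pk_left", "pk_right"):
        arr = getattr(log, name, None)
        if arr is not None:
            out[name] = arr[start * spc : stop * spc].reshape(stop - start, spc)
    return out
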