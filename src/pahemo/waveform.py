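"""Periodic volumetric flow waveforms.

A :class:`FlowWaveform` samples one cardiac cycle of period ``T`` on a
uniform half-open grid ``t_k = k T / n`` for ``k = 0..n-1`` and is
treated as periodic.  All cycle integrals use the trapezoid rule with
periodic wrap, which on a uniform grid reduces to ``mean(Q) * T``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FlowWaveform", "periodic_trapezoid", "waveform_to_csv", "waveform_from_csv"]

MIN_SAMPLES = 64


def periodic_trapezoid(values: np.ndarray, period: float) -> float:
    """Trapezoid integral over one period of uniformly sampled periodic data.

    The closing segment from the last sample back to the first is
    included, so on a uniform half-open grid the result is exactly
    ``mean(values) * period``.
    """
    values = np.asarray(values, dtype=float)
    return float(values.mean() * period)


@dataclass(frozen=True)
class FlowWaveform:
    """One cardiac cycle of volumetric flow rate.

    Parameters
    ----------
    period : float
        Cycle length T in s.
    flow : numpy.ndarray
        Flow samples Q(t_k) in mL/s on the uniform grid [0, T).
    """

    period: float
    flow: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError(f"period must be > 0, got {self.period}")
        flow = np.asarray(self.flow, dtype=float)
        if flow.ndim != 1 or flow.size < MIN_SAMPLES:
            raise ValueError(f"waveform needs >= {MIN_SAMPLES} samples in one 1-D array")
        if not np.all(np.isfinite(flow)):
            raise ValueError("waveform contains non-finite samples")
        object.__setattr__(self, "flow", flow)

    @property
    def n_samples(self) -> int:
        return self.flow.size

    @property
    def times(self) -> np.ndarray:
        """Sample times on the half-open grid [0, T)."""
        return np.arange(self.n_samples) * (self.period / self.n_samples)

    def mean_flow(self) -> float:
        """Cycle-mean flow in mL/s (net, sign included)."""
        return float(self.flow.mean())

    def cycle_volume(self) -> float:
        """Net volume per cycle in mL."""
        return periodic_trapezoid(self.flow, self.period)

    def interpolate(self, t: np.ndarray | float) -> np.ndarray | float:
        """Periodic linear interpolation of Q at arbitrary times."""
        tt = np.mod(np.asarray(t, dtype=float), self.period)
        tp = np.append(self.times, self.period)
        qp = np.append(self.flow, self.flow[0])
        out = np.interp(tt, tp, qp)
        return float(out) if np.isscalar(t) else out


def waveform_to_csv(waveform: FlowWaveform, path_or_buf) -> None:
    """Write a waveform as two-column CSV (time_s, flow_mL_per_s)."""
    df = pd.DataFrame({"time_s": waveform.times, "flow_mL_per_s": waveform.flow})
    df.to_csv(path_or_buf, index=False)


def waveform_from_csv(path_or_buf) -> FlowWaveform:
    """Read a two-column waveform CSV.

    The period is inferred as ``last sample time + grid spacing`` (the
    half-open sampling convention).
    """
    df = pd.read_csv(path_or_buf)
    expected = ["time_s", "flow_mL_per_s"]
    if list(df.columns) != expected:
        raise ValueError(f"waveform CSV must have columns {expected}, got {list(df.columns)}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("waveform CSV needs at least two samples")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-8, atol=1e-12) or t[0] != 0.0:
        raise ValueError("waveform CSV must be uniformly sampled starting at t=0")
    period = float(t[-1] + dt[0])
    return FlowWaveform(period=period, flow=df["flow_mL_per_s"].to_numpy(dtype=float))
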