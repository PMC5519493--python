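"""Data-quality maps: temporal SNR and fALFF.

tSNR is the per-vertex mean over time divided by the standard deviation
over time.  fALFF is the fraction of spectral amplitude in the
0.01-0.08 Hz band relative to the whole (DC-excluded) spectrum; "power"
is operationalized as amplitude (square root of the periodogram) summed
over bins, with a raw-power option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import MIN_FRAMES, SessionTimeseries

DEFAULT_BAND = (0.01, 0.08)


@dataclass
class QCMap:
    values: np.ndarray           # (V,) float; nan where undefined
    metric_name: str             # 'tsnr' or 'falff'
    undefined: np.ndarray        # (V,) bool
    band_hz: tuple[float, float] | None = None


def tsnr(ts: SessionTimeseries) -> QCMap:
    """Temporal SNR map: mean_t(x) / sd_t(x), sd with denominator T-1.

    Vertices with zero temporal variance are flagged undefined (nan),
    never infinite.
    """
    if ts.n_frames < 2:
        raise ValueError("tSNR needs at least 2 frames")
    mean = ts.data.mean(axis=1)
    sd = ts.data.std(axis=1, ddof=1)
    undefined = sd == 0
    values = np.full(ts.n_vertices, np.nan)
    values[~undefined] = mean[~undefined] / sd[~undefined]
    return QCMap(values=values, metric_name="tsnr", undefined=undefined)


def falff(ts: SessionTimeseries, band_hz: tuple[float, float] = DEFAULT_BAND,
          use_power: bool = False) -> QCMap:
    """Fractional amplitude of low-frequency fluctuations per vertex.

    The series is demeaned, a one-sided periodogram taken, and the
    amplitude (or raw power with ``use_power=True``) summed over
    ``band_hz`` is divided by the sum over all bins in (0, Nyquist].
    Values lie in [0, 1]; zero-variance vertices are undefined.
    """
    if ts.n_frames < MIN_FRAMES:
        raise ValueError(f"fALFF needs >= {MIN_FRAMES} frames")
    lo, hi = band_hz
    nyquist = 0.5 / ts.tr_seconds
    if not (0.0 <= lo < hi <= nyquist):
        raise ValueError(f"band {band_hz} outside (0, Nyquist={nyquist}]")
    x = ts.data - ts.data.mean(axis=1, keepdims=True)
    spec = np.abs(np.fft.rfft(x, axis=1))
    if use_power:
        spec = spec**2
    f = np.fft.rfftfreq(ts.n_frames, d=ts.tr_seconds)
    in_band = (f >= lo) & (f <= hi)
    nonzero = f > 0  # DC excluded from the denominator
    num = spec[:, in_band & nonzero].sum(axis=1)
    den = spec[:, nonzero].sum(axis=1)
    undefined = den == 0
    values = np.full(ts.n_vertices, np.nan)
    values[~undefined] = num[~undefined] / den[~undefined]
    return QCMap(values=values, metric_name="falff", undefined=undefined,
                 band_hz=(lo, hi))


def qc_summary(sessions: list[SessionTimeseries]) -> pd.DataFrame:
    """Per-run summary table: run id, mean tSNR, mean fALFF."""
    rows = []
    for ts in sessions:
        t = tsnr(ts).values
        a = falff(ts).values
        rows.append({
            "subject": ts.subject_id,
            "run": ts.run_id,
            "mean_tsnr": float(np.nanmean(t)),
            "mean_falff": float(np.nanmean(a)),
        })
    return pd.DataFrame(rows)
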