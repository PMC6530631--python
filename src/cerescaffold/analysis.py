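"""Spike-train analysis of scaffold simulations.

Implements the validation analyses of the reference experiments: windowed
firing rates (before / during / after the stimulus), peri-stimulus time
histograms (3 ms bins), excited/inhibited classification by rate doubling
or halving (granule cells additionally need more than one spike during the
stimulus), Purkinje burst-pause detection from the first post-stimulus
inter-spike interval, the center-surround excitatory-inhibitory maps

    EI = FR_con(T2) - FR_inoff(T2)        CS = FR_con(T1) - EI

on a pixel grid over the granular layer, and auto/cross-correlograms of
population spike counts with the coherence index C = sum |A_n| / len(A).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .netsim import SpikeRecord

__all__ = [
    "RateTable",
    "CsMap",
    "Correlogram",
    "psth",
    "rates_in_window",
    "mean_rates",
    "classify_response",
    "detect_burst_pause",
    "compute_EI_CS",
    "binned_counts",
    "correlogram",
]


@dataclass
class RateTable:
    """Per-neuron and per-population rates in the three analysis windows."""

    windows: dict[str, tuple[float, float]]
    per_neuron: dict[str, dict[int, float]]        # window -> id -> Hz
    population: dict[str, tuple[float, float]]     # window -> (mean, sd) Hz


@dataclass
class CsMap:
    """Center-surround map on an (x, z) pixel grid of the granular layer."""

    x_edges: np.ndarray
    z_edges: np.ndarray
    fr_con_t1: np.ndarray
    fr_con_t2: np.ndarray
    fr_inoff_t2: np.ndarray
    EI: np.ndarray
    CS: np.ndarray                 # normalized to [-1, 1]
    center_mask: np.ndarray        # CS > 0.5
    surround_mask: np.ndarray      # CS < -0.5
    center_area: float             # fraction of pixels
    surround_area: float
    normalized: bool = True


@dataclass
class Correlogram:
    """Normalized correlation of two binned spike-count signals."""

    lags: np.ndarray               # ms
    values: np.ndarray
    coherence: float               # C = mean |A_n|
    dominant_frequency: float | None   # Hz, from first non-zero-lag peak


def psth(spikes: SpikeRecord, neuron_ids, bin_ms: float = 3.0,
         t_range: tuple[float, float] | None = None
         ) -> tuple[np.ndarray, np.ndarray]:
    """Population spike counts in left-closed bins [k b, (k+1) b).

    Returns (counts, bin edges)."""
    if bin_ms <= 0:
        raise ValueError("bin width must be > 0")
    t0, t1 = (0.0, spikes.T) if t_range is None else t_range
    edges = np.arange(t0, t1 + bin_ms * 0.5, bin_ms)
    t = spikes.times[np.isin(spikes.ids, neuron_ids)]
    t = t[(t >= t0) & (t < edges[-1])]
    counts, _ = np.histogram(t, bins=edges)
    return counts, edges


def rates_in_window(spikes: SpikeRecord, neuron_ids, t0: float, t1: float
                    ) -> dict[int, float]:
    """Per-neuron firing rate (Hz) over [t0, t1); neurons with no spikes
    get 0."""
    neuron_ids = np.asarray(neuron_ids)
    m = np.isin(spikes.ids, neuron_ids) & (spikes.times >= t0) & (spikes.times < t1)
    ids, counts = np.unique(spikes.ids[m], return_counts=True)
    dur_s = (t1 - t0) / 1000.0
    out = {int(i): 0.0 for i in neuron_ids}
    for i, c in zip(ids, counts):
        out[int(i)] = c / dur_s
    return out


def mean_rates(spikes: SpikeRecord, neuron_ids,
               windows: dict[str, tuple[float, float]]) -> RateTable:
    """Windowed per-neuron and population mean +- sd rates."""
    per, pop = {}, {}
    for name, (t0, t1) in windows.items():
        r = rates_in_window(spikes, neuron_ids, t0, t1)
        per[name] = r
        vals = np.array(list(r.values())) if r else np.zeros(1)
        pop[name] = (float(vals.mean()), float(vals.std()))
    return RateTable(windows=dict(windows), per_neuron=per, population=pop)


def classify_response(spikes: SpikeRecord, neuron_id: int,
                      before: tuple[float, float],
                      during: tuple[float, float],
                      grc_rule: bool = False) -> str:
    """'excited' | 'inhibited' | 'unchanged' for one neuron.

    Rates are normalized by window duration.  Excited: during-rate at least
    double the baseline (granule cells additionally need > 1 spike during
    the stimulus); inhibited: during-rate at most half the baseline.  A
    silent-baseline cell is excited by any qualifying during-activity and
    never inhibited.
    """
    t = spikes.times[spikes.ids == neuron_id]
    nb = int(np.sum((t >= before[0]) & (t < before[1])))
    nd = int(np.sum((t >= during[0]) & (t < during[1])))
    rb = nb / (before[1] - before[0])
    rd = nd / (during[1] - during[0])
    if grc_rule and nd <= 1:
        return "inhibited" if (rb > 0 and rd <= 0.5 * rb) else "unchanged"
    if rb == 0:
        return "excited" if nd >= 1 else "unchanged"
    if rd >= 2.0 * rb:
        return "excited"
    if rd <= 0.5 * rb:
        return "inhibited"
    return "unchanged"


def classify_population(spikes: SpikeRecord, neuron_ids,
                        before: tuple[float, float],
                        during: tuple[float, float],
                        grc_rule: bool = False) -> np.ndarray:
    """Vectorized :func:`classify_response` over a population; returns an
    array of labels aligned with ``neuron_ids``."""
    neuron_ids = np.asarray(neuron_ids)
    def counts(w):
        m = np.isin(spikes.ids, neuron_ids) & (spikes.times >= w[0]) \
            & (spikes.times < w[1])
        ids, c = np.unique(spikes.ids[m], return_counts=True)
        out = np.zeros(len(neuron_ids), dtype=np.int64)
        lookup = {int(i): k for k, i in enumerate(neuron_ids)}
        for i, cc in zip(ids, c):
            out[lookup[int(i)]] = cc
        return out
    nb = counts(before)
    nd = counts(during)
    rb = nb / (before[1] - before[0])
    rd = nd / (during[1] - during[0])
    labels = np.full(len(neuron_ids), "unchanged", dtype=object)
    excited = np.where(rb == 0, nd >= 1, rd >= 2.0 * rb)
    if grc_rule:
        excited &= nd > 1
    inhibited = (rb > 0) & (rd <= 0.5 * rb) & ~excited
    labels[excited] = "excited"
    labels[inhibited] = "inhibited"
    return labels.astype(str)


def detect_burst_pause(spikes: SpikeRecord, pc_id: int, stim_start: float,
                       stim_end: float, pre_window: tuple[float, float]
                       ) -> str:
    """Purkinje response label: 'burst', 'pause', 'burst_and_pause', 'none',
    or 'undetermined' (fewer than 3 pre-stimulus ISIs).

    Pause: the first inter-spike interval starting after the stimulus end
    exceeds mean + 2 sd of the pre-stimulus ISIs (the within-cell criterion;
    the mean term keeps perfectly regular trains from flagging every
    interval).  Burst: the excited classification over the stimulus window.
    """
    t = np.sort(spikes.times[spikes.ids == pc_id])
    pre = t[(t >= pre_window[0]) & (t < pre_window[1])]
    if len(pre) < 4:  # need >= 3 pre-stimulus ISIs
        return "undetermined"
    isi = np.diff(pre)
    thr = isi.mean() + 2.0 * isi.std()
    after = t[t >= stim_end]
    pause = False
    if len(after) >= 1:
        last_before = t[t < stim_end]
        if len(last_before):
            first_isi = after[0] - last_before[-1]
            pause = first_isi > thr
    else:
        pause = spikes.T - stim_end > thr
    burst = classify_response(spikes, pc_id, pre_window,
                              (stim_start, stim_end)) == "excited"
    if burst and pause:
        return "burst_and_pause"
    if burst:
        return "burst"
    if pause:
        return "pause"
    return "none"


def _pixel_rates(positions: np.ndarray, rates: np.ndarray,
                 x_edges: np.ndarray, z_edges: np.ndarray) -> np.ndarray:
    """Mean rate of the cells falling in each (x, z) pixel (0 if empty)."""
    ix = np.clip(np.digitize(positions[:, 0], x_edges) - 1, 0,
                 len(x_edges) - 2)
    iz = np.clip(np.digitize(positions[:, 2], z_edges) - 1, 0,
                 len(z_edges) - 2)
    shape = (len(x_edges) - 1, len(z_edges) - 1)
    s = np.zeros(shape)
    n = np.zeros(shape)
    np.add.at(s, (ix, iz), rates)
    np.add.at(n, (ix, iz), 1.0)
    with np.errstate(invalid="ignore"):
        out = np.where(n > 0, s / np.maximum(n, 1), 0.0)
    return out


def compute_EI_CS(fr_con_t1: np.ndarray, fr_con_t2: np.ndarray,
                  fr_inoff_t2: np.ndarray,
                  x_edges: np.ndarray, z_edges: np.ndarray) -> CsMap:
    """Excitatory-inhibitory balance and center-surround maps.

    EI = FR_con(T2) - FR_inoff(T2); CS = FR_con(T1) - EI, then normalized by
    max |CS|.  Center pixels: CS > 0.5; surround: CS < -0.5; areas are pixel
    fractions.
    """
    shapes = {fr_con_t1.shape, fr_con_t2.shape, fr_inoff_t2.shape}
    if len(shapes) != 1:
        raise ValueError("rate maps must share one grid")
    EI = fr_con_t2 - fr_inoff_t2
    CS = fr_con_t1 - EI
    peak = float(np.max(np.abs(CS)))
    normalized = peak > 0
    CSn = CS / peak if normalized else CS.copy()
    center = CSn > 0.5
    surround = CSn < -0.5
    n_pix = CSn.size
    return CsMap(x_edges=x_edges, z_edges=z_edges,
                 fr_con_t1=fr_con_t1, fr_con_t2=fr_con_t2,
                 fr_inoff_t2=fr_inoff_t2, EI=EI, CS=CSn,
                 center_mask=center, surround_mask=surround,
                 center_area=float(center.sum()) / n_pix,
                 surround_area=float(surround.sum()) / n_pix,
                 normalized=normalized)


def cs_map_from_runs(placement, grc_ids, spikes_con: SpikeRecord,
                     spikes_inoff: SpikeRecord, burst_onset: float,
                     pixel_um: float = 10.0,
                     base: tuple[float, float, float, float] = (0, 400, 0, 400)
                     ) -> CsMap:
    """Build the center-surround map from a control and an inhibition-off
    run: granule cells are assigned to 10 um pixels by soma position and
    their T1/T2 window rates averaged per pixel."""
    from .protocols import CS_T1, CS_T2
    x0, x1, z0, z1 = base
    x_edges = np.arange(x0, x1 + pixel_um * 0.5, pixel_um)
    z_edges = np.arange(z0, z1 + pixel_um * 0.5, pixel_um)
    pos = placement.xyz[grc_ids]
    def window_rates(spk, w):
        r = rates_in_window(spk, grc_ids, burst_onset + w[0], burst_onset + w[1])
        return np.array([r[int(i)] for i in grc_ids])
    con_t1 = _pixel_rates(pos, window_rates(spikes_con, CS_T1), x_edges, z_edges)
    con_t2 = _pixel_rates(pos, window_rates(spikes_con, CS_T2), x_edges, z_edges)
    ino_t2 = _pixel_rates(pos, window_rates(spikes_inoff, CS_T2), x_edges, z_edges)
    return compute_EI_CS(con_t1, con_t2, ino_t2, x_edges, z_edges)


def binned_counts(spikes: SpikeRecord, neuron_ids, bin_ms: float,
                  t_range: tuple[float, float] | None = None) -> np.ndarray:
    """Population spike-count signal on a regular grid (for correlograms)."""
    counts, _ = psth(spikes, neuron_ids, bin_ms=bin_ms, t_range=t_range)
    return counts.astype(float)


def correlogram(a: np.ndarray, b: np.ndarray | None, bin_ms: float,
                max_lag_ms: float) -> Correlogram:
    """Mean-subtracted, normalized correlation of two binned count signals
    (autocorrelation when ``b`` is None or identical to ``a``).

    The coherence index is C = sum |A_n| / len(A) over the reported lag
    range.  The dominant frequency is 1 / (first positive-lag local-maximum
    lag) of the correlogram.
    """
    a = np.asarray(a, dtype=float)
    b = a if b is None else np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty spike-count signal")
    if len(a) != len(b):
        raise ValueError("signals must share the binning grid")
    max_lag = int(round(max_lag_ms / bin_ms))
    max_lag = min(max_lag, len(a) - 1)
    am = a - a.mean()
    bm = b - b.mean()
    denom = np.sqrt(np.sum(am * am) * np.sum(bm * bm))
    full = np.correlate(am, bm, mode="full") / (denom if denom > 0 else 1.0)
    mid = len(a) - 1
    vals = full[mid - max_lag: mid + max_lag + 1]
    lags = np.arange(-max_lag, max_lag + 1) * bin_ms
    C = float(np.mean(np.abs(vals)))
    pos = vals[max_lag:]  # lag >= 0
    peaks, _ = find_peaks(pos, prominence=0.02 * max(pos.max(), 1e-12))
    peaks = peaks[peaks > 0]
    dom = 1000.0 / (peaks[0] * bin_ms) if len(peaks) else None
    return Correlogram(lags=lags, values=vals, coherence=C,
                       dominant_frequency=dom)
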