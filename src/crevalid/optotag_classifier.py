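"""Optogenetic identification ("opto-tagging") of Cre+ units.

A unit is accepted as an identified Cre+ neuron only if it satisfies all
of: (1) evoked spiking within 10 ms of laser onset significant at
p < 0.001 in a stimulus-associated latency test; (2) a z-scored PSTH peak
above 10 during both the 5-ms and the 10-ms pulse blocks; and (3) a
Pearson correlation above 0.9 between the average light-evoked waveform
and the average session-wide waveform.

The latency test here is a seeded window-resampling test: the observed
statistic is the fraction of pulses with at least one spike inside the
post-onset window, and the null re-places the same number of windows at
uniformly random non-stimulus times of the session. The statistic and
null construction are fully specified by this module; other latency tests
can be substituted via the ``latency_fn`` hook of :func:`classify_unit`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import pearsonr


@dataclass
class OptoUnit:
    """Spikes, laser pulses, and waveforms for one recorded unit."""

    unit_id: str
    spike_times: np.ndarray                  # s, sorted ascending
    stim_blocks: dict[float, np.ndarray]     # pulse duration ms -> onsets (s)
    session_waveform: np.ndarray             # (samples, channels)
    spike_waveforms: np.ndarray | None = None  # (n_spikes, samples, channels)
    session_duration: float = 0.0
    sampling_rate: float = 30000.0

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if np.any(np.diff(self.spike_times) < 0):
            raise ValueError("spike_times must be sorted ascending")
        for dur, onsets in self.stim_blocks.items():
            onsets = np.asarray(onsets, dtype=float)
            if np.any(np.diff(onsets) < 0):
                raise ValueError(f"stim onsets for {dur} ms must be sorted")
            self.stim_blocks[dur] = onsets
        if self.session_duration <= 0:
            last = [self.spike_times[-1]] if len(self.spike_times) else [0.0]
            last += [o[-1] for o in self.stim_blocks.values() if len(o)]
            self.session_duration = max(last) + 1.0

    def all_stim_times(self) -> np.ndarray:
        if not self.stim_blocks:
            return np.zeros(0)
        return np.sort(np.concatenate(list(self.stim_blocks.values())))


@dataclass
class TagDecision:
    unit_id: str
    latency_p: float
    z_peak_5ms: float
    z_peak_10ms: float
    waveform_r: float
    tagged: bool
    criteria: dict[str, bool] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def _windows_hit(spikes: np.ndarray, starts: np.ndarray, window_s: float) -> np.ndarray:
    """Boolean per window: does [start, start+window) contain a spike?"""
    lo = np.searchsorted(spikes, starts, side="left")
    hi = np.searchsorted(spikes, starts + window_s, side="left")
    return hi > lo


def latency_test(
    spike_times: np.ndarray,
    stim_times: np.ndarray,
    window: float = 10.0,
    n_resamples: int = 1999,
    seed: int = 0,
    session_duration: float | None = None,
    exclusion_pad: float = 0.02,
) -> tuple[float, list[str]]:
    """Window-resampling latency test; returns (p-value, flags).

    Observed statistic: fraction of pulses with >=1 spike in
    ``[onset, onset + window ms)``. Null: ``n_resamples`` draws of
    equally many windows placed uniformly at random over the session,
    excluding ``exclusion_pad`` s around every real pulse;
    ``p = (1 + #{null >= observed}) / (1 + n_resamples)``.
    """
    spikes = np.asarray(spike_times, dtype=float)
    stims = np.asarray(stim_times, dtype=float)
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    flags: list[str] = []
    if len(stims) == 0:
        return 1.0, ["no_pulses"]
    if len(stims) < 10:
        flags.append("low_power")
    w = window / 1000.0
    observed = float(np.mean(_windows_hit(spikes, stims, w)))
    if len(spikes) == 0:
        return 1.0, flags

    duration = session_duration or max(
        spikes[-1] if len(spikes) else 0.0, stims[-1] + 1.0
    )
    rng = np.random.default_rng(seed)
    n_windows = len(stims)
    need = n_resamples * n_windows
    # rejection-sample all window placements at once (i.i.d. across
    # resamples), excluding the stimulus zones
    placed = np.empty(0)
    while placed.size < need:
        cand = rng.uniform(0.0, duration - w, size=int(need * 1.3) + 64)
        idx = np.searchsorted(stims, cand)
        prev = np.where(idx > 0, cand - stims[np.maximum(idx - 1, 0)], np.inf)
        nxt = np.where(idx < len(stims),
                       stims[np.minimum(idx, len(stims) - 1)] - cand, np.inf)
        ok = (prev >= exclusion_pad + w) & (nxt >= exclusion_pad)
        placed = np.concatenate([placed, cand[ok]])
    hits = _windows_hit(spikes, placed[:need], w)
    null = hits.reshape(n_resamples, n_windows).mean(axis=1)
    p = (1.0 + float(np.sum(null >= observed))) / (1.0 + n_resamples)
    return p, flags


def zscored_psth_peak(
    spike_times: np.ndarray,
    stim_times: np.ndarray,
    bin_ms: float = 1.0,
    peak_window_ms: float = 10.0,
    baseline_window: float = 0.5,
) -> tuple[float, list[str]]:
    """Z-scored PSTH peak in the post-onset window; returns (z, flags).

    The PSTH uses ``bin_ms`` bins over ``[0, peak_window_ms)`` after each
    onset, averaged across pulses and expressed in Hz. The baseline is the
    ``baseline_window`` s preceding each pulse, binned identically and
    pooled; z is (peak rate - baseline mean) / baseline SD of binned rates.
    """
    spikes = np.asarray(spike_times, dtype=float)
    stims = np.asarray(stim_times, dtype=float)
    flags: list[str] = []
    if len(stims) == 0:
        return float("nan"), ["no_pulses"]
    w = bin_ms / 1000.0

    def pooled_rates(edges: np.ndarray) -> np.ndarray:
        # counts per bin offset, summed across pulses, via one searchsorted
        all_edges = (stims[:, None] + edges[None, :]).ravel()
        cum = np.searchsorted(spikes, all_edges).reshape(len(stims), -1)
        return np.diff(cum, axis=1).sum(axis=0) / (len(stims) * w)

    n_bins = int(round(peak_window_ms / bin_ms))
    psth_hz = pooled_rates(np.arange(n_bins + 1) * w)
    n_base = int(round(baseline_window / w))
    base_hz = pooled_rates(-baseline_window + np.arange(n_base + 1) * w)
    sd = float(base_hz.std(ddof=1))
    if sd == 0.0:
        return float("nan"), flags + ["zero_baseline_sd"]
    z = (float(psth_hz.max()) - float(base_hz.mean())) / sd
    return z, flags


def evoked_waveform(unit: OptoUnit, window_ms: float = 10.0) -> np.ndarray | None:
    """Mean waveform of spikes falling within the post-laser window."""
    if unit.spike_waveforms is None or len(unit.spike_times) == 0:
        return None
    stims = unit.all_stim_times()
    if len(stims) == 0:
        return None
    w = window_ms / 1000.0
    idx = np.searchsorted(stims, unit.spike_times, side="right") - 1
    idx = np.clip(idx, 0, len(stims) - 1)
    evoked = (unit.spike_times - stims[idx] >= 0) & (
        unit.spike_times - stims[idx] < w
    )
    if not evoked.any():
        return None
    return unit.spike_waveforms[evoked].mean(axis=0)


def waveform_correlation(
    evoked_mean: np.ndarray, session_mean: np.ndarray
) -> tuple[float, list[str]]:
    """Pearson r between waveforms on the peak-amplitude channel."""
    ev = np.atleast_2d(np.asarray(evoked_mean, dtype=float).T).T
    se = np.atleast_2d(np.asarray(session_mean, dtype=float).T).T
    if ev.shape != se.shape:
        raise ValueError("waveform shapes differ")
    ptp = se.max(axis=0) - se.min(axis=0)
    ch = int(np.argmax(ptp))
    a, b = ev[:, ch], se[:, ch]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan"), ["flat_waveform"]
    return float(pearsonr(a, b).statistic), []


def classify_unit(
    unit: OptoUnit,
    alpha: float = 0.001,
    z_min: float = 10.0,
    r_min: float = 0.9,
    latency_window_ms: float = 10.0,
    n_resamples: int = 1999,
    seed: int = 0,
    latency_fn=None,
) -> TagDecision:
    """Apply the three tagging criteria; tagged only if all pass.

    ``latency_fn(spike_times, stim_times, window, n_resamples, seed,
    session_duration)`` may replace the built-in resampling latency test.
    """
    flags: list[str] = []
    fn = latency_fn or (
        lambda *a, **k: latency_test(*a, **k)
    )
    p, f = fn(
        unit.spike_times,
        unit.all_stim_times(),
        window=latency_window_ms,
        n_resamples=n_resamples,
        seed=seed,
        session_duration=unit.session_duration,
    )
    flags += f

    zs: dict[float, float] = {}
    for dur in (5.0, 10.0):
        if dur not in unit.stim_blocks or len(unit.stim_blocks[dur]) == 0:
            zs[dur] = float("nan")
            flags.append(f"missing_{int(dur)}ms_block")
            continue
        z, f = zscored_psth_peak(unit.spike_times, unit.stim_blocks[dur])
        zs[dur] = z
        flags += f

    ev = evoked_waveform(unit, latency_window_ms)
    if ev is None:
        r = float("nan")
        flags.append("no_evoked_spikes")
    else:
        r, f = waveform_correlation(ev, unit.session_waveform)
        flags += f

    criteria = {
        "latency": bool(p < alpha),
        "z_5ms": bool(zs[5.0] > z_min),
        "z_10ms": bool(zs[10.0] > z_min),
        "waveform": bool(r > r_min),
    }
    return TagDecision(
        unit_id=unit.unit_id,
        latency_p=p,
        z_peak_5ms=zs[5.0],
        z_peak_10ms=zs[10.0],
        waveform_r=r,
        tagged=all(criteria.values()),
        criteria=criteria,
        flags=flags,
    )
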