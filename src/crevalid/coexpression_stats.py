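"""Per-nucleus puncta counting, Poisson background thresholding, and the
co-expression specificity/consistency and R-squared summaries.

A cell is "positive" for a probe when its puncta count strictly exceeds
the 95th-percentile threshold of a Poisson background whose mean is the
field-wide outside-nuclei puncta rate multiplied by that cell's (dilated)
nuclear area. Specificity is the percentage of Cre+ nuclei that are also
target-probe-positive; consistency is the percentage of target-positive
nuclei that are also Cre+. Off-target versions substitute the off-target
probe for the target probe in both ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .nucleus_segmentation import NucleusLabelMap
from .puncta_detection import PunctaSet


@dataclass
class CoexpressionSummary:
    specificity: float                      # % of cre+ that are target+
    consistency: float                      # % of target+ that are cre+
    offtarget_specificity: float
    offtarget_consistency: float
    r2: dict[tuple[str, str], float]
    n_cells: int
    region: str = ""
    genotype: str = ""


def count_puncta_per_nucleus(
    labels: NucleusLabelMap, puncta: dict[str, PunctaSet]
) -> pd.DataFrame:
    """Assign each punctum to the dilated nucleus containing its centroid.

    Returns a cell table (index ``cell_id``) with ``area`` and one count
    column per probe; puncta on background are pooled in the table's
    ``attrs["outside"]`` dict so that total counts are conserved.
    """
    if not puncta:
        raise ValueError("no probe channels provided")
    lab = labels.labels
    n = labels.n_labels
    cells = pd.DataFrame(index=pd.RangeIndex(1, n + 1, name="cell_id"))
    cells["area"] = [labels.areas.get(i, 0) for i in cells.index]
    outside: dict[str, int] = {}
    for probe, pset in puncta.items():
        if pset is None:
            raise KeyError(f"probe channel {probe!r} missing")
        counts = np.zeros(n + 1, dtype=int)
        if len(pset):
            rows = np.clip(np.rint(pset.centroids[:, 0]).astype(int), 0,
                           lab.shape[0] - 1)
            cols = np.clip(np.rint(pset.centroids[:, 1]).astype(int), 0,
                           lab.shape[1] - 1)
            owners = lab[rows, cols]
            counts = np.bincount(owners, minlength=n + 1)
        cells[probe] = counts[1:n + 1] if n else np.zeros(0, dtype=int)
        outside[probe] = int(counts[0])
    cells.attrs["outside"] = outside
    return cells


def background_rate(puncta: PunctaSet, labels: NucleusLabelMap) -> float:
    """Puncta per pixel over the region outside all dilated nuclei."""
    bg = labels.background_mask()
    n_px = int(bg.sum())
    if n_px == 0:
        raise ValueError("no background pixels outside nuclei")
    if len(puncta) == 0:
        return 0.0
    rows = np.clip(np.rint(puncta.centroids[:, 0]).astype(int), 0,
                   labels.labels.shape[0] - 1)
    cols = np.clip(np.rint(puncta.centroids[:, 1]).astype(int), 0,
                   labels.labels.shape[1] - 1)
    n_out = int(np.count_nonzero(labels.labels[rows, cols] == 0))
    return n_out / n_px


def poisson_threshold(rate: float, area: float, percentile: float = 0.95) -> int:
    """Smallest integer k with Poisson CDF(k; rate*area) >= percentile.

    A cell is called positive when its count strictly exceeds k.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if area <= 0:
        raise ValueError("area must be > 0")
    if not 0 < percentile < 1:
        raise ValueError("percentile must be in (0, 1)")
    lam = rate * area
    if lam == 0:
        return 0
    return int(stats.poisson.ppf(percentile, lam))


def call_positive(
    profiles: pd.DataFrame,
    background: dict[str, float],
    percentile: float = 0.95,
    override_threshold: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Attach per-cell, per-probe thresholds and positivity calls.

    Thresholds come from :func:`poisson_threshold` with each cell's own
    dilated area, unless ``override_threshold`` fixes a probe's threshold
    (the high-threshold ">30 puncta/cell" variant). Adds columns
    ``thr_<probe>`` (int) and ``pos_<probe>`` (bool).
    """
    override_threshold = override_threshold or {}
    out = profiles.copy()
    probes = [c for c in profiles.columns if c != "area"]
    for probe in probes:
        if probe not in background and probe not in override_threshold:
            raise KeyError(f"no background rate for probe {probe!r}")
        if probe in override_threshold:
            thr = np.full(len(out), int(override_threshold[probe]))
        else:
            rate = background[probe]
            thr = np.array(
                [poisson_threshold(rate, a, percentile) if a > 0 else 0
                 for a in out["area"]],
                dtype=int,
            )
        out[f"thr_{probe}"] = thr
        out[f"pos_{probe}"] = out[probe].to_numpy() > thr
    out.attrs = dict(profiles.attrs)
    out.attrs["percentile"] = percentile
    out.attrs["override_threshold"] = dict(override_threshold)
    return out


def _ratio_pct(num: int, den: int) -> float:
    return 100.0 * num / den if den else float("nan")


def specificity_consistency(
    profiles: pd.DataFrame,
    cre_probe: str,
    target_probe: str,
    offtarget_probe: str,
    region: str = "",
    genotype: str = "",
) -> CoexpressionSummary:
    """Specificity/consistency of Cre expression, on- and off-target.

    Undefined ratios (zero denominator) are reported as NaN, never as 0.
    """
    cre = profiles[f"pos_{cre_probe}"].to_numpy()
    tgt = profiles[f"pos_{target_probe}"].to_numpy()
    off = profiles[f"pos_{offtarget_probe}"].to_numpy()
    summary = CoexpressionSummary(
        specificity=_ratio_pct(int((cre & tgt).sum()), int(cre.sum())),
        consistency=_ratio_pct(int((tgt & cre).sum()), int(tgt.sum())),
        offtarget_specificity=_ratio_pct(int((cre & off).sum()), int(cre.sum())),
        offtarget_consistency=_ratio_pct(int((off & cre).sum()), int(off.sum())),
        r2={},
        n_cells=len(profiles),
        region=region,
        genotype=genotype,
    )
    for pair in ((cre_probe, target_probe), (cre_probe, offtarget_probe)):
        try:
            summary.r2[pair] = pairwise_r2(profiles, *pair)
        except ValueError:
            summary.r2[pair] = float("nan")
    return summary


def pairwise_r2(profiles: pd.DataFrame, probe_a: str, probe_b: str) -> float:
    """Squared Pearson correlation of raw per-cell puncta counts."""
    a = profiles[probe_a].to_numpy(dtype=float)
    b = profiles[probe_b].to_numpy(dtype=float)
    if len(a) < 3:
        raise ValueError("need at least 3 cells")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in counts; R^2 undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)
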