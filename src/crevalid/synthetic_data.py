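"""Ground-truthed synthetic inputs for every validation stage.

Three generators:

* :func:`simulate_fish_image` — a multichannel FISH field (DAPI + probe
  channels) built from elliptical nuclei, per-cell planted puncta with a
  configurable co-expression structure, a uniform background puncta
  process, multiplicative uneven illumination, and Gaussian camera noise.
* :func:`simulate_insertion_reads` — paired-end alignment records around a
  planted transgene-cassette insertion: concordant genome-only pairs plus
  junction-spanning pairs with one mate on the cassette contig.
* :func:`simulate_opto_units` — photo-responsive ("tagged") and ordinary
  Poisson units with spike times, laser pulse blocks, and spike waveforms.

All generators take an integer seed and are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

DEFAULT_PROBES = ("Drd1a", "Adora2a", "iCre")

State = tuple[int, int, int]


class PlacementError(RuntimeError):
    """Raised when nuclei cannot be placed without overlap in the field."""


# ---------------------------------------------------------------------------
# co-expression structure
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoexpressionSpec:
    """Joint probabilities of the (target+, off-target+, cre+) states.

    ``joint`` maps each of the 8 boolean states (as 0/1 triples ordered like
    ``probes``) to its probability; probabilities must sum to 1.
    """

    joint: Mapping[State, float]
    probes: tuple[str, str, str] = DEFAULT_PROBES

    def __post_init__(self) -> None:
        total = sum(self.joint.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"joint probabilities sum to {total}, not 1")
        if any(p < 0 for p in self.joint.values()):
            raise ValueError("joint probabilities must be non-negative")

    @classmethod
    def from_rates(
        cls,
        p_target: float = 0.5,
        consistency: float = 0.8,
        specificity: float = 0.9,
        p_off_given_target_neg: float = 0.85,
        p_off_given_target_pos: float = 0.02,
        probes: tuple[str, str, str] = DEFAULT_PROBES,
    ) -> "CoexpressionSpec":
        """Build a joint from the planted metrics of interest.

        ``consistency`` is P(cre+ | target+) and ``specificity`` is
        P(target+ | cre+); the off-target probe segregates from the target
        probe, emulating the near-complete separation of direct- and
        indirect-pathway MSN markers in striatum.
        """
        p_tc = consistency * p_target                      # P(t+, c+)
        p_c = p_tc / specificity                           # P(c+)
        p_nc = p_c - p_tc                                  # P(t-, c+)
        if p_nc > 1 - p_target + 1e-12:
            raise ValueError("specificity/consistency/p_target incompatible")
        joint: dict[State, float] = {}
        for t, p_t_branch, p_c_branch in (
            (1, p_target, p_tc),
            (0, 1 - p_target, p_nc),
        ):
            p_off = p_off_given_target_pos if t else p_off_given_target_neg
            for c in (1, 0):
                pc = p_c_branch if c else p_t_branch - p_c_branch
                for o in (1, 0):
                    joint[(t, o, c)] = pc * (p_off if o else 1 - p_off)
        return cls(joint=joint, probes=probes)

    def states(self) -> tuple[np.ndarray, np.ndarray]:
        keys = sorted(self.joint)
        return np.array(keys, dtype=int), np.array([self.joint[k] for k in keys])


# ---------------------------------------------------------------------------
# FISH scene
# ---------------------------------------------------------------------------


@dataclass
class FISHImage:
    """Multichannel 2-D field: channel label -> float32 intensity array."""

    channels: dict[str, np.ndarray]
    pixel_depth: int = 16
    channel_order: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        shapes = {c.shape for c in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError("all channels must share one shape")
        if not self.channel_order:
            self.channel_order = tuple(self.channels)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class FISHTruth:
    """Planted ground truth for one simulated FISH field."""

    nucleus_centers: np.ndarray          # (n, 2) float, (row, col)
    nucleus_axes: np.ndarray             # (n, 2) float semi-axes (a, b) px
    nucleus_angles: np.ndarray           # (n,) radians
    per_cell_counts: pd.DataFrame        # cell x probe planted counts
    positivity: pd.DataFrame             # cell x probe planted boolean state
    background_rate: float               # puncta per px per probe
    coexpression_spec: CoexpressionSpec
    puncta: dict[str, pd.DataFrame] = field(default_factory=dict)
    # per probe: columns row, col, cell (-1 = background punctum)
    touching_pairs: list[tuple[int, int]] = field(default_factory=list)
    dilation_radius: int = 5

    @property
    def n_cells(self) -> int:
        return len(self.nucleus_centers)


def _pair_distance_for_overlap(r: float, overlap: float) -> float:
    """Center distance of two equal circles with given lens/circle area ratio."""
    if overlap <= 0:
        return 2 * r
    area = overlap * math.pi * r * r

    def lens(d: float) -> float:
        return 2 * r * r * math.acos(d / (2 * r)) - 0.5 * d * math.sqrt(
            4 * r * r - d * d
        )

    return brentq(lambda d: lens(d) - area, 1e-6, 2 * r - 1e-9)


def _place_nuclei(
    rng: np.random.Generator,
    n_cells: int,
    shape: tuple[int, int],
    axis_range: tuple[float, float],
    touching_fraction: float,
    pair_overlap: float,
    min_gap: float,
    max_tries: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[tuple[int, int]]]:
    h, w = shape
    centers: list[tuple[float, float]] = []
    axes: list[tuple[float, float]] = []
    angles: list[float] = []
    pairs: list[tuple[int, int]] = []

    def clear(r: float, c: float, rmax: float, skip: set[int]) -> bool:
        margin = rmax + 1
        if not (margin <= r < h - margin and margin <= c < w - margin):
            return False
        if not centers:
            return True
        ctr = np.asarray(centers)
        reach = np.max(np.asarray(axes), axis=1) + rmax + min_gap
        d2 = (ctr[:, 0] - r) ** 2 + (ctr[:, 1] - c) ** 2
        bad = d2 < reach**2
        for j in skip:
            bad[j] = False
        return not bad.any()

    n_pairs = int(round(touching_fraction * n_cells / 2))
    n_single = n_cells - 2 * n_pairs

    for _ in range(n_pairs):
        rad = rng.uniform(*axis_range)
        d = _pair_distance_for_overlap(rad, pair_overlap)
        placed = False
        for _try in range(max_tries):
            r0 = rng.uniform(0, h)
            c0 = rng.uniform(0, w)
            theta = rng.uniform(0, 2 * math.pi)
            r1 = r0 + d * math.sin(theta)
            c1 = c0 + d * math.cos(theta)
            if clear(r0, c0, rad + d, set()) and clear(r1, c1, rad + d, set()):
                i0 = len(centers)
                centers += [(r0, c0), (r1, c1)]
                axes += [(rad, rad), (rad, rad)]
                angles += [0.0, 0.0]
                pairs.append((i0, i0 + 1))
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place touching pair after {max_tries} tries "
                f"(n_cells={n_cells}, shape={shape})"
            )

    for _ in range(n_single):
        a = rng.uniform(*axis_range)
        b = rng.uniform(*axis_range)
        ang = rng.uniform(0, math.pi)
        placed = False
        for _try in range(max_tries):
            r0 = rng.uniform(0, h)
            c0 = rng.uniform(0, w)
            if clear(r0, c0, max(a, b), set()):
                centers.append((r0, c0))
                axes.append((a, b))
                angles.append(ang)
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place nucleus after {max_tries} tries "
                f"(n_cells={n_cells}, shape={shape})"
            )

    return (
        np.asarray(centers, dtype=float).reshape(-1, 2),
        np.asarray(axes, dtype=float).reshape(-1, 2),
        np.asarray(angles, dtype=float),
        pairs,
    )


def _elliptical_radius_sq(
    rr: np.ndarray, cc: np.ndarray, center, axes, angle: float
) -> np.ndarray:
    dr = rr - center[0]
    dc = cc - center[1]
    u = dc * math.cos(angle) + dr * math.sin(angle)
    v = -dc * math.sin(angle) + dr * math.cos(angle)
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2


def nucleus_core_mask(
    shape: tuple[int, int],
    centers: np.ndarray,
    axes: np.ndarray,
    angles: np.ndarray,
) -> np.ndarray:
    """Boolean union of the (undilated) planted ellipse footprints."""
    mask = np.zeros(shape, dtype=bool)
    for (r0, c0), (a, b), ang in zip(centers, axes, angles):
        rmax = int(math.ceil(max(a, b))) + 1
        rlo, rhi = max(0, int(r0) - rmax), min(shape[0], int(r0) + rmax + 1)
        clo, chi = max(0, int(c0) - rmax), min(shape[1], int(c0) + rmax + 1)
        rr, cc = np.mgrid[rlo:rhi, clo:chi]
        mask[rlo:rhi, clo:chi] |= (
            _elliptical_radius_sq(rr, cc, (r0, c0), (a, b), ang) <= 1.0
        )
    return mask


def _sample_in_ellipse(
    rng: np.random.Generator,
    n: int,
    center,
    axes,
    angle: float,
    shape: tuple[int, int],
    min_sep: float,
) -> np.ndarray:
    """Uniform points inside an ellipse, best-effort minimum separation."""
    pts: list[tuple[float, float]] = []
    a, b = axes
    for _ in range(n):
        for _try in range(60):
            u = rng.uniform(-1, 1)
            v = rng.uniform(-1, 1)
            if u * u + v * v > 1:
                continue
            du = u * a * math.cos(angle) - v * b * math.sin(angle)
            dv = u * a * math.sin(angle) + v * b * math.cos(angle)
            r = center[0] + dv
            c = center[1] + du
            if not (0 <= r < shape[0] and 0 <= c < shape[1]):
                continue
            if min_sep > 0 and any(
                math.hypot(r - pr, c - pc) < min_sep for pr, pc in pts[-40:]
            ):
                continue
            pts.append((r, c))
            break
        else:
            # fall back: accept any in-ellipse point to keep the count exact
            while True:
                u = rng.uniform(-1, 1)
                v = rng.uniform(-1, 1)
                if u * u + v * v <= 1:
                    du = u * a * math.cos(angle) - v * b * math.sin(angle)
                    dv = u * a * math.sin(angle) + v * b * math.cos(angle)
                    r = min(max(center[0] + dv, 0), shape[0] - 1)
                    c = min(max(center[1] + du, 0), shape[1] - 1)
                    pts.append((r, c))
                    break
    return np.asarray(pts, dtype=float).reshape(-1, 2)


def _stamp_gaussians(
    img: np.ndarray, points: np.ndarray, amps: np.ndarray, sigma: float
) -> None:
    half = int(math.ceil(4 * sigma))
    h, w = img.shape
    for (r, c), amp in zip(points, amps):
        rlo, rhi = max(0, int(r) - half), min(h, int(r) + half + 1)
        clo, chi = max(0, int(c) - half), min(w, int(c) + half + 1)
        rr, cc = np.mgrid[rlo:rhi, clo:chi]
        img[rlo:rhi, clo:chi] += amp * np.exp(
            -((rr - r) ** 2 + (cc - c) ** 2) / (2 * sigma * sigma)
        )


def simulate_fish_image(
    n_cells: int = 150,
    image_shape: tuple[int, int] = (1024, 1024),
    coexpression_spec: CoexpressionSpec | None = None,
    expression_mean: float = 25.0,
    expression_dispersion: float = 5.0,
    background_rate: float = 5e-5,
    illumination_gradient: float = 0.2,
    noise_sd: float = 4.0,
    touching_fraction: float = 0.0,
    pair_overlap: float = 0.15,
    axis_range: tuple[float, float] = (12.0, 20.0),
    spot_sigma: float = 2.0,
    spot_amplitude: float = 120.0,
    dapi_peak: float = 180.0,
    dapi_background: float = 10.0,
    dilation_radius: int = 5,
    min_gap: float = 4.0,
    seed: int = 0,
) -> tuple[FISHImage, FISHTruth]:
    """Render a DAPI + 3-probe FISH field with full planted ground truth.

    Expressing cells draw planted puncta counts from a negative binomial
    (``expression_mean``, ``expression_dispersion``); non-expressing cells
    receive no planted puncta for that probe. Background puncta fall
    uniformly outside all dilated nucleus footprints at ``background_rate``
    per pixel per probe. A linear multiplicative illumination gradient of
    relative amplitude ``illumination_gradient`` runs across the field, and
    i.i.d. Gaussian noise of ``noise_sd`` is added to every channel.
    """
    if image_shape[0] < 128 or image_shape[1] < 128:
        raise ValueError("image_shape must be at least 128x128")
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    spec = coexpression_spec or CoexpressionSpec.from_rates()
    rng = np.random.default_rng(seed)
    probes = spec.probes

    centers, axes, angles, pairs = _place_nuclei(
        rng, n_cells, image_shape, axis_range, touching_fraction,
        pair_overlap, min_gap, max_tries=400,
    )

    # planted expression states
    state_keys, state_probs = spec.states()
    if n_cells:
        idx = rng.choice(len(state_keys), size=n_cells, p=state_probs)
        states = state_keys[idx]
    else:
        states = np.zeros((0, 3), dtype=int)
    positivity = pd.DataFrame(states.astype(bool), columns=list(probes))
    positivity.index.name = "cell"

    # planted per-cell counts
    nb_n = expression_dispersion
    nb_p = nb_n / (nb_n + expression_mean)
    counts = np.zeros((n_cells, 3), dtype=int)
    for j in range(3):
        pos = states[:, j] == 1
        counts[pos, j] = rng.negative_binomial(nb_n, nb_p, size=int(pos.sum()))
    per_cell_counts = pd.DataFrame(counts, columns=list(probes))
    per_cell_counts.index.name = "cell"

    # puncta placement (cells: inside ellipse grown by the dilation radius,
    # which is a subset of the true disc-dilated footprint)
    puncta: dict[str, list[np.ndarray]] = {p: [] for p in probes}
    owner: dict[str, list[np.ndarray]] = {p: [] for p in probes}
    # keep planted puncta a safe margin inside the dilated footprint so
    # that pixel rounding can never push one outside it
    reach = max(dilation_radius - 2.5, 0.0)
    for i in range(n_cells):
        grown = (axes[i, 0] + reach, axes[i, 1] + reach)
        for j, probe in enumerate(probes):
            k = counts[i, j]
            if k == 0:
                continue
            pts = _sample_in_ellipse(
                rng, k, centers[i], grown, angles[i], image_shape, min_sep=3.0
            )
            puncta[probe].append(pts)
            owner[probe].append(np.full(len(pts), i, dtype=int))

    # background puncta: uniform over pixels outside all dilated footprints
    from scipy.ndimage import binary_dilation
    from skimage.morphology import disk

    core = nucleus_core_mask(image_shape, centers, axes, angles)
    if n_cells:
        outside = ~binary_dilation(core, structure=disk(dilation_radius))
    else:
        outside = np.ones(image_shape, dtype=bool)
    out_idx = np.flatnonzero(outside)
    n_out = out_idx.size
    for probe in probes:
        n_bg = rng.poisson(background_rate * n_out)
        if n_bg and n_out:
            pick = rng.choice(out_idx, size=n_bg, replace=False)
            rr, cc = np.unravel_index(pick, image_shape)
            jitter = rng.uniform(-0.45, 0.45, size=(n_bg, 2))
            pts = np.column_stack([rr + jitter[:, 0], cc + jitter[:, 1]])
            puncta[probe].append(pts)
            owner[probe].append(np.full(n_bg, -1, dtype=int))

    puncta_tables: dict[str, pd.DataFrame] = {}
    for probe in probes:
        if puncta[probe]:
            pts = np.vstack(puncta[probe])
            own = np.concatenate(owner[probe])
        else:
            pts = np.zeros((0, 2))
            own = np.zeros(0, dtype=int)
        puncta_tables[probe] = pd.DataFrame(
            {"row": pts[:, 0], "col": pts[:, 1], "cell": own}
        )

    # --- rendering -----------------------------------------------------
    h, w = image_shape
    dapi = np.full(image_shape, dapi_background, dtype=np.float64)
    for (r0, c0), (a, b), ang in zip(centers, axes, angles):
        bright = rng.uniform(0.75, 1.05)
        rmax = int(math.ceil(max(a, b))) + 2
        rlo, rhi = max(0, int(r0) - rmax), min(h, int(r0) + rmax + 1)
        clo, chi = max(0, int(c0) - rmax), min(w, int(c0) + rmax + 1)
        rr, cc = np.mgrid[rlo:rhi, clo:chi]
        re2 = _elliptical_radius_sq(rr, cc, (r0, c0), (a, b), ang)
        # chromatin fills the nucleus: flat-topped profile, smooth rim
        dome = np.clip(1.0 - re2, 0.0, None) ** 0.25 * dapi_peak * bright
        patch = dapi[rlo:rhi, clo:chi]
        np.maximum(patch, dome + dapi_background, out=patch)

    channels: dict[str, np.ndarray] = {}
    grad = 1.0 + illumination_gradient * (
        2.0 * np.arange(w, dtype=np.float64) / max(w - 1, 1) - 1.0
    )
    channels["DAPI"] = dapi * grad[None, :]
    for probe in probes:
        img = np.zeros(image_shape, dtype=np.float64)
        pts = puncta_tables[probe][["row", "col"]].to_numpy()
        amps = spot_amplitude * rng.uniform(0.7, 1.3, size=len(pts))
        _stamp_gaussians(img, pts, amps, spot_sigma)
        img = (img + 6.0) * grad[None, :]
        channels[probe] = img

    for name in channels:
        arr = channels[name] + rng.normal(0.0, noise_sd, size=image_shape)
        channels[name] = np.clip(arr, 0.0, 65535.0).astype(np.float32)

    image = FISHImage(
        channels=channels, pixel_depth=16, channel_order=("DAPI",) + probes
    )
    truth = FISHTruth(
        nucleus_centers=centers,
        nucleus_axes=axes,
        nucleus_angles=angles,
        per_cell_counts=per_cell_counts,
        positivity=positivity,
        background_rate=background_rate,
        coexpression_spec=spec,
        puncta=puncta_tables,
        touching_pairs=pairs,
        dilation_radius=dilation_radius,
    )
    return image, truth


# ---------------------------------------------------------------------------
# cassette insertion read pairs
# ---------------------------------------------------------------------------


@dataclass
class InsertionTruth:
    """A planted single-copy cassette insertion in a reference genome."""

    genome: dict[str, str]           # contig name -> sequence (incl. cassette)
    cassette_name: str
    insertion_contig: str
    insertion_pos: int               # 1-based
    n_supporting_pairs: int = 24
    fragment_size: int = 500

    def __post_init__(self) -> None:
        if self.cassette_name not in self.genome:
            raise ValueError(f"cassette contig {self.cassette_name!r} not in genome")
        if self.insertion_contig not in self.genome:
            raise ValueError(f"contig {self.insertion_contig!r} not in genome")
        if not 1 <= self.insertion_pos <= len(self.genome[self.insertion_contig]):
            raise ValueError("insertion_pos outside contig")
        if self.n_supporting_pairs < 0:
            raise ValueError("n_supporting_pairs must be >= 0")


@dataclass(frozen=True)
class ReadRecord:
    """One aligned mate of a pair (1-based position, as in SAM)."""

    read_id: str
    contig: str
    pos: int
    aligned_length: int
    is_read1: bool
    is_reverse: bool
    mate_contig: str
    mate_pos: int
    seq: str


def simulate_genome(
    contig_lengths: Mapping[str, int],
    cassette_name: str = "iCre_cassette",
    cassette_length: int = 1500,
    seed: int = 0,
) -> dict[str, str]:
    """Random A/C/G/T contigs plus a cassette contig appended to the set."""
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    genome = {
        name: "".join(rng.choice(bases, size=length))
        for name, length in contig_lengths.items()
    }
    genome[cassette_name] = "".join(rng.choice(bases, size=cassette_length))
    return genome


def simulate_insertion_reads(
    truth: InsertionTruth | Sequence[InsertionTruth],
    read_length: int = 150,
    coverage_pairs: int = 200,
    seed: int = 0,
) -> list[ReadRecord]:
    """Emit concordant genome pairs plus junction-spanning cassette pairs.

    Exactly ``n_supporting_pairs`` pairs per planted insertion have one
    mate fully aligned to the cassette contig and the other mate on the
    insertion contig within one fragment size of the insertion point.
    """
    truths = [truth] if isinstance(truth, InsertionTruth) else list(truth)
    if not truths:
        raise ValueError("at least one InsertionTruth required")
    genome = truths[0].genome
    cassette = truths[0].cassette_name
    for t in truths:
        if t.genome is not genome and t.genome != genome:
            raise ValueError("all truths must share one genome")
        if t.cassette_name != cassette:
            raise ValueError("all truths must share one cassette contig")
        if read_length >= t.fragment_size:
            raise ValueError("read_length must be < fragment_size")

    rng = np.random.default_rng(seed)
    records: list[ReadRecord] = []
    genome_contigs = [c for c in genome if c != cassette]
    lengths = np.array([len(genome[c]) for c in genome_contigs], dtype=float)
    weights = lengths / lengths.sum()
    frag = truths[0].fragment_size

    def subseq(contig: str, pos: int, n: int) -> str:
        return genome[contig][pos - 1 : pos - 1 + n]

    serial = 0
    for _ in range(coverage_pairs):
        contig = genome_contigs[int(rng.choice(len(genome_contigs), p=weights))]
        clen = len(genome[contig])
        span = min(frag, clen)
        p1 = int(rng.integers(1, max(clen - span + 1, 1) + 1))
        p2 = min(p1 + span - read_length, clen - read_length + 1)
        p2 = max(p2, 1)
        rid = f"concordant_{serial}"
        serial += 1
        records.append(
            ReadRecord(rid, contig, p1, read_length, True, False,
                       contig, p2, subseq(contig, p1, read_length))
        )
        records.append(
            ReadRecord(rid, contig, p2, read_length, False, True,
                       contig, p1, subseq(contig, p2, read_length))
        )

    for t in truths:
        clen = len(genome[t.insertion_contig])
        casslen = len(genome[cassette])
        for k in range(t.n_supporting_pairs):
            side = 1 if rng.random() < 0.5 else -1
            offset = int(rng.integers(read_length, frag))
            gpos = t.insertion_pos - offset if side > 0 else t.insertion_pos + offset
            gpos = int(min(max(gpos, 1), clen - read_length + 1))
            cpos = int(rng.integers(1, max(casslen - read_length + 1, 1) + 1))
            rid = f"junction_{t.insertion_contig}_{t.insertion_pos}_{k}"
            records.append(
                ReadRecord(rid, t.insertion_contig, gpos, read_length, True,
                           side < 0, cassette, cpos,
                           subseq(t.insertion_contig, gpos, read_length))
            )
            records.append(
                ReadRecord(rid, cassette, cpos, read_length, False,
                           side > 0, t.insertion_contig, gpos,
                           subseq(cassette, cpos, read_length))
            )
    return records


# ---------------------------------------------------------------------------
# opto-tagging units
# ---------------------------------------------------------------------------


@dataclass
class OptoTruth:
    """Ground-truth labels for a simulated opto-tagging session."""

    unit_labels: list[str]           # "tagged" | "untagged"
    true_latency_ms: float
    baseline_rate_hz: float


def _waveform_template(
    rng: np.random.Generator, n_samples: int, n_channels: int
) -> np.ndarray:
    """Biphasic extracellular spike shape with per-channel amplitude falloff."""
    t = np.arange(n_samples, dtype=float)
    t0 = n_samples * 0.35
    trough = -np.exp(-((t - t0) ** 2) / (2 * 2.0**2))
    hump = 0.45 * np.exp(-((t - t0 - 6.0) ** 2) / (2 * 4.5**2))
    shape = trough + hump
    amps = rng.uniform(0.2, 1.0, size=n_channels)
    amps[rng.integers(n_channels)] = 1.0
    scale = rng.uniform(80.0, 250.0)  # microvolts
    return scale * shape[:, None] * amps[None, :]


def simulate_opto_units(
    n_tagged: int = 1,
    n_untagged: int = 1,
    baseline_rate: float = 5.0,
    latency: float = 2.0,
    reliability: float = 0.9,
    n_pulses: int = 120,
    jitter_ms: float = 0.3,
    pulse_interval: float = 1.0,
    pre_baseline_s: float = 60.0,
    waveform_samples: int = 32,
    waveform_channels: int = 4,
    waveform_noise: float = 0.08,
    seed: int = 0,
):
    """Simulate photo-responsive and ordinary units for one laser session.

    The session has a silent-laser baseline followed by two 1-Hz pulse
    blocks (10-ms pulses, then 5-ms pulses, ``n_pulses`` each). Untagged
    units fire homogeneous-Poisson throughout; tagged units additionally
    fire one spike at ``latency`` ms (Gaussian jitter ``jitter_ms``) after
    each pulse with probability ``reliability``. All spikes of a unit reuse
    that unit's waveform template plus i.i.d. sample noise.

    Returns ``(units, truth)`` where units is a list of
    :class:`~crevalid.optotag_classifier.OptoUnit`.
    """
    if not 0.0 <= reliability <= 1.0:
        raise ValueError("reliability must be in [0, 1]")
    if latency / 1000.0 >= pulse_interval:
        raise ValueError("latency must be shorter than the inter-pulse interval")

    from .optotag_classifier import OptoUnit

    rng = np.random.default_rng(seed)
    block_gap = 10.0
    t10 = pre_baseline_s + np.arange(n_pulses) * pulse_interval
    t5 = t10[-1] + block_gap + np.arange(n_pulses) * pulse_interval if n_pulses else t10
    session_end = (t5[-1] if n_pulses else pre_baseline_s) + 5.0
    stim_blocks = {10.0: t10, 5.0: t5}

    units: list = []
    labels: list[str] = []
    for i in range(n_tagged + n_untagged):
        tagged = i < n_tagged
        spikes = np.sort(
            rng.uniform(0.0, session_end, size=rng.poisson(baseline_rate * session_end))
        )
        if tagged:
            evoked = []
            for onsets in stim_blocks.values():
                fire = rng.random(len(onsets)) < reliability
                jit = rng.normal(0.0, jitter_ms / 1000.0, size=int(fire.sum()))
                evoked.append(onsets[fire] + latency / 1000.0 + jit)
            spikes = np.sort(np.concatenate([spikes] + evoked))
        template = _waveform_template(rng, waveform_samples, waveform_channels)
        noise_sd = waveform_noise * np.abs(template).max()
        spike_waveforms = template[None] + rng.normal(
            0.0, noise_sd, size=(len(spikes), waveform_samples, waveform_channels)
        )
        session_waveform = (
            spike_waveforms.mean(axis=0) if len(spikes) else template.copy()
        )
        units.append(
            OptoUnit(
                unit_id=f"unit_{i:04d}",
                spike_times=spikes,
                stim_blocks={k: v.copy() for k, v in stim_blocks.items()},
                session_waveform=session_waveform,
                spike_waveforms=spike_waveforms,
                session_duration=session_end,
                sampling_rate=30000.0,
            )
        )
        labels.append("tagged" if tagged else "untagged")

    truth = OptoTruth(
        unit_labels=labels, true_latency_ms=latency, baseline_rate_hz=baseline_rate
    )
    return units, truth
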