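"""Cassette insertion localization and cross-line off-target screening.

The cassette is localized from paired-end alignments against a reference
augmented with the cassette as an extra contig: pairs in which one mate
aligns to the cassette (with at least ``min_match`` aligned bases) and the
other mate aligns to the genome anchor the insertion; the genome-side
mates are clustered into loci. A single correct knock-in yields exactly
one locus at the target site.

Predicted off-target sites are screened by comparing variant observations
between the two lines: a change present in both lines is strain background
(shared_strain_variant); a change present only in the line whose sgRNA
predicted the site is a candidate off-target event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MateAlignment:
    contig: str
    pos: int                 # 1-based leftmost aligned position
    aligned_length: int


@dataclass(frozen=True)
class AnchoredPair:
    """A read pair with one mate on the cassette, the other on the genome."""

    read_id: str
    cassette_mate: MateAlignment
    genome_mate: MateAlignment


@dataclass
class InsertionLocus:
    contig: str
    position: float          # median genome-mate coordinate (1-based)
    support: int
    span: int                # bp between first and last supporting mate
    positions: list[int] = field(default_factory=list)


@dataclass
class InsertionVerdict:
    passed: bool
    n_loci: int
    expected: tuple[str, int]
    matched_locus: InsertionLocus | None
    off_site_loci: list[InsertionLocus]

    def __bool__(self) -> bool:
        return self.passed


@dataclass
class OfftargetSite:
    contig: str
    pos: int
    context: str                       # exon | intron | intergenic
    predicted_line: str
    variant_in_line_a: str | None      # normalized allele or None
    variant_in_line_b: str | None
    classification: str = ""           # assigned by classify_offtargets


def _iter_mate_pairs(alignments: Iterable) -> Iterable[tuple]:
    """Group records into mate pairs by read id; orphans are skipped."""
    by_id: dict[str, list] = {}
    n_orphans = 0
    for rec in alignments:
        by_id.setdefault(rec.read_id, []).append(rec)
    for rid, recs in by_id.items():
        if len(recs) != 2:
            n_orphans += 1
            continue
        yield recs[0], recs[1]
    if n_orphans:
        logger.info("skipped %d reads without a usable mate", n_orphans)


def select_anchored_pairs(
    alignments: Iterable, cassette_name: str, min_match: int = 100
) -> list[AnchoredPair]:
    """Keep exactly the pairs with one cassette mate and one genome mate.

    The cassette mate must have an aligned block of at least ``min_match``
    bp; both-genome and both-cassette pairs are excluded. ``alignments``
    may be ReadRecord objects or any records with ``read_id``, ``contig``,
    ``pos`` and ``aligned_length`` attributes.
    """
    out: list[AnchoredPair] = []
    for a, b in _iter_mate_pairs(alignments):
        on_cass = [r.contig == cassette_name for r in (a, b)]
        if sum(on_cass) != 1:
            continue
        cass, gen = (a, b) if on_cass[0] else (b, a)
        if cass.aligned_length < min_match:
            continue
        out.append(
            AnchoredPair(
                read_id=cass.read_id,
                cassette_mate=MateAlignment(cass.contig, cass.pos,
                                            cass.aligned_length),
                genome_mate=MateAlignment(gen.contig, gen.pos,
                                          gen.aligned_length),
            )
        )
    return out


def read_sam_pairs(path: str, cassette_name: str, min_match: int = 100):
    """Load mapped mate pairs from a SAM/BAM file (thin pysam wrapper).

    Unmapped mates are dropped; their mapped partners end up orphaned and
    are skipped with a logged count, matching the selection contract.
    """
    import pysam

    from .synthetic_data import ReadRecord

    records: list[ReadRecord] = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.reference_name is None:
                continue
            records.append(
                ReadRecord(
                    read_id=rec.query_name,
                    contig=rec.reference_name,
                    pos=rec.reference_start + 1,
                    aligned_length=rec.query_alignment_length,
                    is_read1=rec.is_read1,
                    is_reverse=rec.is_reverse,
                    mate_contig=rec.next_reference_name or "*",
                    mate_pos=(rec.next_reference_start or 0) + 1,
                    seq=rec.query_sequence or "",
                )
            )
    return select_anchored_pairs(records, cassette_name, min_match)


def cluster_insertion_loci(
    pairs: Sequence[AnchoredPair], window: int = 1000
) -> list[InsertionLocus]:
    """Single-linkage clustering of genome-mate positions within ``window``.

    One locus per cluster, located at the median genome-mate coordinate;
    loci are sorted by support, descending. Every anchored pair contributes
    to exactly one locus.
    """
    if window <= 0:
        raise ValueError("window must be > 0")
    by_contig: dict[str, list[int]] = {}
    for p in pairs:
        by_contig.setdefault(p.genome_mate.contig, []).append(p.genome_mate.pos)
    loci: list[InsertionLocus] = []
    for contig, positions in by_contig.items():
        positions.sort()
        start = 0
        for i in range(1, len(positions) + 1):
            if i == len(positions) or positions[i] - positions[i - 1] > window:
                group = positions[start:i]
                loci.append(
                    InsertionLocus(
                        contig=contig,
                        position=float(np.median(group)),
                        support=len(group),
                        span=group[-1] - group[0],
                        positions=group,
                    )
                )
                start = i
    loci.sort(key=lambda l: (-l.support, l.contig, l.position))
    return loci


def single_insertion_verdict(
    loci: Sequence[InsertionLocus],
    expected: tuple[str, int],
    tolerance: int = 1000,
) -> InsertionVerdict:
    """PASS iff exactly one locus exists, on the expected contig and within
    ``tolerance`` bp of the expected position."""
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    contig, pos = expected
    matched = None
    off_site: list[InsertionLocus] = []
    for locus in loci:
        if locus.contig == contig and abs(locus.position - pos) <= tolerance:
            matched = locus
        else:
            off_site.append(locus)
    passed = len(loci) == 1 and matched is not None
    return InsertionVerdict(
        passed=passed,
        n_loci=len(loci),
        expected=expected,
        matched_locus=matched,
        off_site_loci=off_site,
    )


# ---------------------------------------------------------------------------
# off-target screen
# ---------------------------------------------------------------------------

SHARED = "shared_strain_variant"
CANDIDATE = "candidate_offtarget"
NO_CHANGE = "no_change"


def _normalize_allele(value) -> str | None:
    """Canonical allele string; missing/blank observations become None."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip().upper()
    return s if s and s not in {".", "-", "NONE", "NO_CHANGE", "REF"} else None


def classify_offtargets(
    sites: pd.DataFrame,
    line_a: str = "D1-Cre",
    line_b: str = "A2a-Cre",
) -> tuple[list[OfftargetSite], pd.DataFrame]:
    """Classify predicted off-target sites from two-line variant calls.

    ``sites`` needs columns ``contig``, ``pos``, ``context``,
    ``predicted_line`` and one variant-observation column per line (named
    after the line); observations are allele strings, with None/NaN/"." for
    no change. Classification per site:

    * same variant allele in both lines -> shared_strain_variant;
    * variant only in the line whose sgRNA predicted the site ->
      candidate_offtarget;
    * variant only in the other line -> shared_strain_variant (line
      background, not attributable to this site's sgRNA);
    * no variant in either line -> no_change.

    Discordant alleles (both lines changed, different alleles) are flagged
    in the ``note`` field and classified shared_strain_variant.

    Returns the per-site classifications and a summary count table indexed
    by (classification, context).
    """
    required = {"contig", "pos", "context", "predicted_line", line_a, line_b}
    missing = required - set(sites.columns)
    if missing:
        raise ValueError(f"sites table missing columns: {sorted(missing)}")

    out: list[OfftargetSite] = []
    rows = []
    for _, row in sites.iterrows():
        va = _normalize_allele(row[line_a])
        vb = _normalize_allele(row[line_b])
        note = ""
        if va is None and vb is None:
            cls = NO_CHANGE
        elif va is not None and vb is not None:
            cls = SHARED
            if va != vb:
                note = "discordant_alleles"
        else:
            changed_line = line_a if va is not None else line_b
            cls = CANDIDATE if changed_line == row["predicted_line"] else SHARED
        site = OfftargetSite(
            contig=row["contig"],
            pos=int(row["pos"]),
            context=row["context"],
            predicted_line=row["predicted_line"],
            variant_in_line_a=va,
            variant_in_line_b=vb,
            classification=cls,
        )
        out.append(site)
        rows.append({"classification": cls, "context": row["context"],
                     "note": note})
    summary = (
        pd.DataFrame(rows)
        .groupby(["classification", "context"])
        .size()
        .rename("n_sites")
        .reset_index()
        if rows
        else pd.DataFrame(columns=["classification", "context", "n_sites"])
    )
    return out, summary
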