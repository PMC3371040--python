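"""Detection of spurious exons from coverage and mapping-quality signatures.

Exons that recurrently accumulate artifactual variant calls — typically
because reads from an unassembled homologous region are forced onto them
— show a characteristic signature: inflated read depth combined with a
low proportion of confidently mapped reads.  Per exon and per sample
this module computes

* ``RPE`` — reads per exon, normalized by exon length and by the
  sample's total exonic read yield, so an average-density exon has
  RPE close to 1 and the same exon is comparable across samples; and
* ``P_HQR`` — the proportion of the exon's reads with MAPQ at or above
  a high-quality threshold (default 40).

Exons falling in the high-coverage / low-quality quadrant
(RPE > 1.5 and P_HQR < 0.4 by default, both strict) are flagged, and a
cross-sample recurrence report ranks exons by the number of samples in
which they are flagged.  The module detects the signature of mismapping;
it does not attempt to locate the homologous region causing it.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .variant_io import AlignedRead, ExonInterval

__all__ = [
    "ExonStat",
    "RecurrenceReport",
    "assign_reads_to_exons",
    "count_reads_per_exon",
    "compute_rpe",
    "compute_phqr",
    "mapq_from_error_prob",
    "exon_stats",
    "flag_spurious",
    "recurrence_report",
]

DEFAULT_MAPQ_MIN = 40
DEFAULT_RPE_MIN = 1.5
DEFAULT_PHQR_MAX = 0.4
DEFAULT_MIN_SAMPLES = 31  # "recurrent in more than 30 samples"


@dataclass(frozen=True)
class ExonStat:
    """Per-exon, per-sample coverage and mapping-quality summary."""

    exon_id: str
    sample_id: str
    gene: str
    read_count: int
    rpe: float
    p_hqr: Optional[float]  # None when the exon has no reads
    flagged: bool = False


@dataclass
class RecurrenceReport:
    """Exons ranked by the number of samples in which they were flagged."""

    rows: list[dict]  # gene, exon_id, n_samples_flagged, samples

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(
            self.rows, columns=["gene", "exon_id", "n_samples_flagged", "samples"]
        )


def _exon_trees(exons: Sequence[ExonInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for i, e in enumerate(exons):
        trees[e.chrom][e.start : e.end] = i
    return trees


def assign_reads_to_exons(
    reads: Sequence[AlignedRead], exons: Sequence[ExonInterval]
) -> dict[str, list[int]]:
    """Map exon_id -> MAPQ values of the reads overlapping it by >= 1 base.

    A read overlapping two exons contributes to both; within one exon a
    read contributes at most once.
    """
    trees = _exon_trees(exons)
    mapqs: dict[str, list[int]] = {e.exon_id: [] for e in exons}
    for read in reads:
        tree = trees.get(read.chrom)
        if tree is None:
            continue
        s, e = read.interval0
        for iv in tree.overlap(s, e):
            mapqs[exons[iv.data].exon_id].append(read.mapq)
    return mapqs


def count_reads_per_exon(
    reads: Sequence[AlignedRead], exons: Sequence[ExonInterval]
) -> dict[str, int]:
    """Absolute number of reads overlapping each exon by at least one base."""
    return {eid: len(v) for eid, v in assign_reads_to_exons(reads, exons).items()}


def compute_rpe(
    counts: Mapping[str, int], exons: Sequence[ExonInterval]
) -> dict[str, float]:
    """Length- and yield-normalized reads per exon.

    ``rpe_e = (count_e / length_e) / (R / L)`` with R the total exonic
    read count and L the total exon length of the sample: the exon's read
    density relative to the sample's mean exonic density.  Satisfies
    ``sum_e rpe_e * length_e == L`` identically.  R = 0 is an error.
    """
    lengths = {e.exon_id: e.length for e in exons}
    unknown = set(counts) - set(lengths)
    if unknown:
        raise KeyError(f"counts refer to unknown exons: {sorted(unknown)[:5]}")
    total_reads = sum(counts.get(eid, 0) for eid in lengths)
    if total_reads == 0:
        raise ValueError("no reads mapped to exon regions; RPE is undefined")
    total_length = sum(lengths.values())
    mean_density = total_reads / total_length
    return {
        eid: (counts.get(eid, 0) / lengths[eid]) / mean_density for eid in lengths
    }


def compute_phqr(mapqs: Sequence[int], mapq_min: int = DEFAULT_MAPQ_MIN) -> float:
    """Proportion of reads with MAPQ >= mapq_min among the reads given."""
    if len(mapqs) == 0:
        raise ValueError("P_HQR is undefined for an exon with zero reads")
    return sum(1 for q in mapqs if q >= mapq_min) / len(mapqs)


def mapq_from_error_prob(p_wrong: float) -> int:
    """MAPQ from the probability that the mapping position is wrong.

    ``round(-10 * log10(p_wrong))`` (half away from zero), capped at 60.
    """
    if not 0 < p_wrong <= 1:
        raise ValueError(f"p_wrong must be in (0, 1], got {p_wrong}")
    q = math.floor(-10.0 * math.log10(p_wrong) + 0.5)
    return min(q, 60)


def exon_stats(
    reads: Sequence[AlignedRead],
    exons: Sequence[ExonInterval],
    sample_id: str,
    mapq_min: int = DEFAULT_MAPQ_MIN,
) -> list[ExonStat]:
    """Per-exon read count, RPE and P_HQR for one sample's alignments."""
    mapqs = assign_reads_to_exons(reads, exons)
    counts = {eid: len(v) for eid, v in mapqs.items()}
    rpe = compute_rpe(counts, exons)
    stats = []
    for e in exons:
        n = counts[e.exon_id]
        stats.append(
            ExonStat(
                exon_id=e.exon_id,
                sample_id=sample_id,
                gene=e.gene,
                read_count=n,
                rpe=rpe[e.exon_id],
                p_hqr=compute_phqr(mapqs[e.exon_id], mapq_min) if n > 0 else None,
            )
        )
    return stats


def flag_spurious(
    stats: Iterable[ExonStat],
    rpe_min: float = DEFAULT_RPE_MIN,
    phqr_max: float = DEFAULT_PHQR_MAX,
) -> list[ExonStat]:
    """Flag exons in the high-coverage / low-mapping-quality quadrant.

    An exon is flagged iff ``rpe > rpe_min`` and ``p_hqr < phqr_max``
    (both strict); exons with undefined P_HQR (no reads) are never
    flagged.
    """
    return [
        replace(
            s,
            flagged=s.p_hqr is not None and s.rpe > rpe_min and s.p_hqr < phqr_max,
        )
        for s in stats
    ]


def recurrence_report(
    stats: Iterable[ExonStat], min_samples: int = DEFAULT_MIN_SAMPLES
) -> RecurrenceReport:
    """Rank exons by the number of distinct samples in which they are flagged.

    Only exons flagged in at least ``min_samples`` samples are reported,
    sorted by descending sample count (ties broken by exon id for a
    stable ordering).
    """
    flagged_samples: dict[str, set[str]] = defaultdict(set)
    genes: dict[str, str] = {}
    for s in stats:
        genes.setdefault(s.exon_id, s.gene)
        if s.flagged:
            flagged_samples[s.exon_id].add(s.sample_id)
    rows = [
        {
            "gene": genes[eid],
            "exon_id": eid,
            "n_samples_flagged": len(samples),
            "samples": ",".join(sorted(samples)),
        }
        for eid, samples in flagged_samples.items()
        if len(samples) >= min_samples
    ]
    rows.sort(key=lambda r: (-r["n_samples_flagged"], r["exon_id"]))
    return RecurrenceReport(rows=rows)
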