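"""Seeded generators for synthetic VCF, truth-table and SAM inputs.

Every analysis in the toolkit is testable without any external data:
the generators here emit files with the statistical structure the
analyses assume —

* variant sets in which experimentally true calls sit in a
  high-QUAL/high-DP region and false calls in a low-QUAL/low-DP region,
  with strand-deficient DP4 patterns strongly enriched among the false
  calls; and
* per-sample alignment sets in which most exons carry baseline coverage
  of confidently mapped reads while designated "spurious" exons carry a
  multiple of the baseline density dominated by low-MAPQ reads.

All generators are pure functions of their parameters: a fixed seed
gives byte-identical output files.  Default compositions follow a
Sanger-validated exome call set of 159 SNVs with 65 true (and 22 indels
with 12 true); distributional defaults are stated per parameter below.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .variant_io import (
    ExonInterval,
    TruthEntry,
    VariantRecord,
    write_truth_table,
    write_vcf,
)

__all__ = [
    "VariantSimParams",
    "AlignmentSimParams",
    "simulate_variant_records",
    "gen_variant_set",
    "gen_alignment_set",
    "PRESETS",
]

_BASES = ("A", "C", "G", "T")


@dataclass(frozen=True)
class VariantSimParams:
    """Parameters of the two-class (true/false) variant generator.

    QUAL is drawn per class from a normal truncated at the class bounds
    (and at zero); DP from a negative-binomial count distribution with
    the given mean and dispersion.  ``zero_support_prob`` is the
    per-variant probability that one uniformly chosen DP4 component is
    zeroed, emulating the strand/allele deficiency seen in artifacts.
    """

    n_true: int = 65
    n_false: int = 94
    qual_true: tuple[float, float] = (45.0, 8.0)  # (location, scale)
    qual_false: tuple[float, float] = (16.0, 6.0)
    dp_true: tuple[float, float] = (30.0, 8.0)  # (mean, dispersion k)
    dp_false: tuple[float, float] = (8.0, 4.0)
    zero_support_prob_true: float = 0.05
    zero_support_prob_false: float = 0.8
    qual_bounds_true: tuple[float, float] = (0.0, np.inf)
    qual_bounds_false: tuple[float, float] = (0.0, np.inf)
    # depth floors default to 4: with fewer than four reads not all four
    # allele/strand classes can be populated, and the depth-bound
    # pre-filter in this workflow removes ultra-shallow sites anyway
    dp_floor_true: int = 4
    dp_floor_false: int = 4
    vtype: str = "SNV"  # or "indel"
    sample_id: str = "S1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true < 0 or self.n_false < 0:
            raise ValueError("class sizes must be non-negative")
        for p in (self.zero_support_prob_true, self.zero_support_prob_false):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"zero_support_prob must be in [0,1], got {p}")
        for loc, scale in (self.qual_true, self.qual_false):
            if scale <= 0:
                raise ValueError("qual scale must be positive")
        for mean, k in (self.dp_true, self.dp_false):
            if mean <= 0 or k <= 0:
                raise ValueError("dp mean and dispersion must be positive")
        if self.vtype not in ("SNV", "indel"):
            raise ValueError(f"vtype must be SNV or indel, got {self.vtype!r}")

    @classmethod
    def planted_separation(
        cls, n_true: int = 100, n_false: int = 100, seed: int = 0, **kw
    ) -> "VariantSimParams":
        """Zero-noise configuration with a hard (QUAL, DP) separation.

        True variants have QUAL in [30, 60] and DP >= 6; false variants
        have QUAL in [0, 25], so any cutoff with qual_min in (25, 30]
        and dp_min in (0, 6] classifies perfectly.
        """
        return cls(
            n_true=n_true,
            n_false=n_false,
            qual_true=(42.0, 6.0),
            qual_false=(15.0, 5.0),
            qual_bounds_true=(30.0, 60.0),
            qual_bounds_false=(0.0, 25.0),
            dp_true=(30.0, 8.0),
            dp_false=(8.0, 4.0),
            dp_floor_true=6,
            dp_floor_false=4,
            seed=seed,
            **kw,
        )


#: Named compositions mirroring the validated call-set shapes.
PRESETS: dict[str, VariantSimParams] = {
    "tier1-snv": VariantSimParams(n_true=65, n_false=94, vtype="SNV"),
    "tier1-indel": VariantSimParams(n_true=12, n_false=10, vtype="indel"),
    "planted": VariantSimParams.planted_separation(),
}


def _draw_qual(
    rng: np.random.Generator, n: int, loc_scale: tuple[float, float], bounds
) -> np.ndarray:
    lo, hi = bounds
    q = rng.normal(loc_scale[0], loc_scale[1], size=n)
    return np.clip(q, max(lo, 0.0), hi)


def _draw_dp(
    rng: np.random.Generator, n: int, mean_k: tuple[float, float], floor: int
) -> np.ndarray:
    mean, k = mean_k
    dp = rng.negative_binomial(k, k / (k + mean), size=n)
    return np.maximum(dp, floor)


def _draw_dp4(
    rng: np.random.Generator, dp: int, zero_support_prob: float
) -> tuple[int, int, int, int]:
    """High-quality allele/strand counts (RF, RR, AF, AR) summing to <= dp.

    With probability ``zero_support_prob`` one uniformly chosen component
    is zeroed; otherwise every component is at least one read (possible
    whenever dp >= 4, which the depth floors guarantee), so the
    lacks-support indicator is exactly Bernoulli(zero_support_prob).
    """
    hq = int(np.clip(rng.binomial(dp, 0.9), min(4, dp), dp))
    if hq >= 4:
        # one read per component, the remainder split ref/alt then by strand
        extra = hq - 4
        ref_extra = int(rng.binomial(extra, 0.5))
        alt_extra = extra - ref_extra
        rf = 1 + int(rng.binomial(ref_extra, 0.5))
        af = 1 + int(rng.binomial(alt_extra, 0.5))
        dp4 = [rf, 2 + ref_extra - rf, af, 2 + alt_extra - af]
    else:
        dp4 = list(rng.multinomial(hq, [0.25] * 4))
    if rng.random() < zero_support_prob:
        dp4[int(rng.integers(0, 4))] = 0
    return tuple(int(x) for x in dp4)  # type: ignore[return-value]


def _alleles(rng: np.random.Generator, vtype: str) -> tuple[str, str]:
    if vtype == "SNV":
        ref = _BASES[int(rng.integers(0, 4))]
        alt = _BASES[(int(_BASES.index(ref)) + int(rng.integers(1, 4))) % 4]
        return ref, alt
    base = _BASES[int(rng.integers(0, 4))]
    ins = _BASES[int(rng.integers(0, 4))]
    if rng.random() < 0.5:
        return base, base + ins  # insertion
    return base + ins, base  # deletion


def simulate_variant_records(
    params: VariantSimParams,
) -> tuple[list[VariantRecord], list[TruthEntry]]:
    """Draw a two-class variant set in memory.

    True variants are labeled ``validated``, false ones ``failed``;
    classes are interleaved along the chromosome by a seeded shuffle.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_true + params.n_false
    labels = np.array([True] * params.n_true + [False] * params.n_false)
    rng.shuffle(labels)
    quals = np.where(
        labels,
        _draw_qual(rng, n, params.qual_true, params.qual_bounds_true),
        _draw_qual(rng, n, params.qual_false, params.qual_bounds_false),
    )
    dps = np.where(
        labels,
        _draw_dp(rng, n, params.dp_true, params.dp_floor_true),
        _draw_dp(rng, n, params.dp_false, params.dp_floor_false),
    )
    records: list[VariantRecord] = []
    truth: list[TruthEntry] = []
    pos = 1000
    for i in range(n):
        ref, alt = _alleles(rng, params.vtype)
        zsp = (
            params.zero_support_prob_true
            if labels[i]
            else params.zero_support_prob_false
        )
        dp = int(dps[i])
        rec = VariantRecord(
            chrom="chr1",
            pos=pos,
            ref=ref,
            alt=alt,
            qual=round(float(quals[i]), 2),
            dp=dp,
            dp4=_draw_dp4(rng, dp, zsp),
            sample_id=params.sample_id,
        )
        records.append(rec)
        truth.append(
            TruthEntry(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=rec.alt,
                sample_id=rec.sample_id,
                status="validated" if labels[i] else "failed",
            )
        )
        pos += int(rng.integers(50, 500))
    return records, truth


def gen_variant_set(
    params: VariantSimParams, out_dir: str | Path, prefix: str = "variants"
) -> tuple[Path, Path, list[VariantRecord], list[TruthEntry]]:
    """Generate a two-class variant set as a VCF plus a truth table.

    Returns ``(vcf_path, truth_path, records, truth_entries)``; the files
    are byte-identical for identical parameters.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, truth = simulate_variant_records(params)
    vcf_path = write_vcf(records, out_dir / f"{prefix}.vcf")
    truth_path = write_truth_table(truth, out_dir / f"{prefix}.truth.tsv")
    return vcf_path, truth_path, records, truth


@dataclass(frozen=True)
class AlignmentSimParams:
    """Parameters of the per-sample exon alignment generator.

    Each exon receives a Poisson number of single-end, gap-free reads
    with mean ``baseline_density * length`` (times ``density_factor``
    for spurious exons).  A read is low-quality with the per-class
    probability, drawing MAPQ uniformly from [0, 39]; otherwise from
    [45, 60].  The 0.5 reads/base baseline corresponds to ~50x depth
    with 100-base reads, typical of a captured exome.
    """

    exons: tuple[ExonInterval, ...]
    baseline_density: float = 0.5  # reads per base
    spurious_exon_ids: tuple[str, ...] = ()
    density_factor: float = 3.0
    low_mapq_fraction: float = 0.8  # in spurious exons
    baseline_low_mapq_fraction: float = 0.05
    read_length: int = 100
    n_samples: int = 36
    seed: int = 0

    def __post_init__(self) -> None:
        if self.density_factor <= 1:
            raise ValueError("density_factor must exceed 1")
        for f in (self.low_mapq_fraction, self.baseline_low_mapq_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fractions must be in [0,1], got {f}")
        if self.baseline_density <= 0 or self.read_length <= 0 or self.n_samples < 1:
            raise ValueError("baseline_density, read_length, n_samples must be positive")
        unknown = set(self.spurious_exon_ids) - {e.exon_id for e in self.exons}
        if unknown:
            raise ValueError(f"spurious_exon_ids not in exon set: {sorted(unknown)}")


def _sample_sam_lines(params: AlignmentSimParams, rng: np.random.Generator) -> list[str]:
    by_chrom: dict[str, int] = {}
    for e in params.exons:
        by_chrom[e.chrom] = max(by_chrom.get(e.chrom, 0), e.end)
    header = ["@HD\tVN:1.6\tSO:unsorted"]
    header += [
        f"@SQ\tSN:{chrom}\tLN:{end + params.read_length + 1000}"
        for chrom, end in sorted(by_chrom.items())
    ]
    lines = header
    seq = "A" * params.read_length
    qual = "I" * params.read_length
    cigar = f"{params.read_length}M"
    idx = 0
    for e in params.exons:
        spurious = e.exon_id in params.spurious_exon_ids
        lam = params.baseline_density * e.length
        low_frac = params.baseline_low_mapq_fraction
        if spurious:
            lam *= params.density_factor
            low_frac = params.low_mapq_fraction
        n_reads = int(rng.poisson(lam))
        for _ in range(n_reads):
            lo = max(0, e.start - params.read_length + 1)
            start0 = int(rng.integers(lo, e.end))
            mapq = (
                int(rng.integers(0, 40))
                if rng.random() < low_frac
                else int(rng.integers(45, 61))
            )
            lines.append(
                f"r{idx:07d}\t0\t{e.chrom}\t{start0 + 1}\t{mapq}\t{cigar}"
                f"\t*\t0\t0\t{seq}\t{qual}"
            )
            idx += 1
    return lines


def gen_alignment_set(
    params: AlignmentSimParams, out_dir: str | Path, prefix: str = "sample"
) -> list[Path]:
    """Generate one SAM file per sample; returns the paths in sample order.

    Per-sample streams are independent, derived from ``(seed, sample
    index)``, so regenerating any one sample is deterministic.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(params.n_samples):
        rng = np.random.default_rng([params.seed, i])
        path = out_dir / f"{prefix}_{i:02d}.sam"
        path.write_text("\n".join(_sample_sam_lines(params, rng)) + "\n")
        paths.append(path)
    return paths
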