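"""Readers for the standard formats the toolkit consumes.

All downstream analyses operate on four light-weight domain types:
:class:`VariantRecord` (one called variant with its QUAL/DP/DP4
annotations), :class:`TruthEntry` (the orthogonal-validation outcome for
one variant), :class:`ExonInterval` (a BED exon used as the unit of the
spurious-locus analysis) and :class:`AlignedRead` (position, span and
mapping quality of one primary alignment).

Coordinate conventions follow the formats themselves: VCF and SAM
positions are 1-based, BED intervals are 0-based half-open, and every
internal interval computation is 0-based half-open.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "TruthEntry",
    "ExonInterval",
    "AlignedRead",
    "VariantKey",
    "VcfParseError",
    "Dp4ExceedsDepthError",
    "TruthTableError",
    "BedIntervalError",
    "read_vcf",
    "read_truth_table",
    "read_exons",
    "read_alignments",
    "write_vcf",
]

VariantKey = tuple[str, int, str, str, str]

VALID_STATUSES = ("validated", "failed")


class VcfParseError(ValueError):
    """A VCF record could not be parsed into a VariantRecord."""


class Dp4ExceedsDepthError(VcfParseError):
    """sum(DP4) > DP: DP4 counts only the high-quality subset of DP."""


class TruthTableError(ValueError):
    """Malformed truth table (duplicate key or unknown status token)."""


class BedIntervalError(ValueError):
    """Malformed BED interval (end <= start)."""


@dataclass(frozen=True)
class VariantRecord:
    """One called variant with the caller annotations used for filtering.

    ``dp4`` is the SAMtools convention (ref-forward, ref-reverse,
    alt-forward, alt-reverse) of high-quality reads actually used in the
    call; it is a subset of ``dp``, the raw site depth.  ``dp`` and
    ``dp4`` are ``None`` when the caller did not emit them, in which case
    the record is excluded from depth- or strand-based operations.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qual: float
    dp: Optional[int] = None
    dp4: Optional[tuple[int, int, int, int]] = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.qual < 0:
            raise ValueError(f"qual must be >= 0, got {self.qual}")
        if self.dp is not None and self.dp < 0:
            raise ValueError(f"dp must be >= 0, got {self.dp}")
        if self.dp4 is not None:
            if len(self.dp4) != 4 or any(x < 0 for x in self.dp4):
                raise ValueError(f"dp4 must be four non-negative ints, got {self.dp4}")
            if self.dp is not None and sum(self.dp4) > self.dp:
                raise Dp4ExceedsDepthError(
                    f"sum(DP4)={sum(self.dp4)} exceeds DP={self.dp} at "
                    f"{self.chrom}:{self.pos}"
                )

    @property
    def vtype(self) -> Literal["SNV", "indel"]:
        return "indel" if len(self.ref) != len(self.alt) else "SNV"

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt, self.sample_id)


@dataclass(frozen=True)
class TruthEntry:
    """Validation outcome (e.g. Sanger sequencing) for one variant key."""

    chrom: str
    pos: int
    ref: str
    alt: str
    sample_id: str
    status: Literal["validated", "failed"]

    def __post_init__(self) -> None:
        if self.status not in VALID_STATUSES:
            raise TruthTableError(f"unknown status token: {self.status!r}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt, self.sample_id)

    @property
    def validated(self) -> bool:
        return self.status == "validated"


@dataclass(frozen=True)
class ExonInterval:
    """An exon as a 0-based half-open interval; the unit of the spurious-locus scan."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    exon_id: str
    gene: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise BedIntervalError(
                f"end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, start0: int, end0: int) -> bool:
        """Overlap with a 0-based half-open interval by at least one base."""
        return start0 < self.end and end0 > self.start


@dataclass(frozen=True)
class AlignedRead:
    """Position, reference span, and mapping quality of one primary alignment.

    MAPQ is -10*log10(Pr(mapping position is wrong)), rounded, in [0, 60].
    """

    chrom: str
    start: int  # leftmost 1-based aligned position
    aligned_span: int  # reference bases covered
    mapq: int

    def __post_init__(self) -> None:
        if not 0 <= self.mapq <= 60:
            raise ValueError(f"mapq must be in [0, 60], got {self.mapq}")

    @property
    def interval0(self) -> tuple[int, int]:
        """Covered reference interval in 0-based half-open coordinates."""
        return self.start - 1, self.start - 1 + self.aligned_span


def _parse_dp4(raw) -> tuple[int, int, int, int]:
    vals = tuple(int(v) for v in raw)
    if len(vals) != 4:
        raise VcfParseError(f"DP4 must have 4 components, got {len(vals)}")
    return vals  # type: ignore[return-value]


def read_vcf(path: str | Path, sample_id: Optional[str] = None) -> list[VariantRecord]:
    """Read a VCF into VariantRecords, one per ALT allele.

    Multi-allelic records are split per ALT, duplicating QUAL/DP/DP4,
    with a logged warning.  Records missing DP (or DP4) get ``dp=None``
    (``dp4=None``); downstream depth/strand operations skip them.

    Parameters
    ----------
    path:
        VCF 4.x file (plain text or bgzipped).
    sample_id:
        Label attached to every record; defaults to the file stem.
    """
    path = Path(path)
    records: list[VariantRecord] = []
    n_multi = n_no_dp = n_no_dp4 = 0
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot read VCF {path}: {exc}") from exc
    with vf:
        label = sample_id
        if label is None:
            # a ##sample_id header line wins over the file stem
            for hrec in vf.header.records:
                if hrec.key == "sample_id" and hrec.value:
                    label = str(hrec.value)
                    break
        if label is None:
            label = path.stem.removesuffix(".vcf")
        for i, rec in enumerate(vf, start=1):
            try:
                alts = rec.alts or ()
                if len(alts) > 1:
                    n_multi += 1
                qual = float(rec.qual) if rec.qual is not None else 0.0
                info = rec.info
                dp = int(info["DP"]) if "DP" in info else None
                dp4 = _parse_dp4(info["DP4"]) if "DP4" in info else None
                if dp is None:
                    n_no_dp += 1
                if dp4 is None:
                    n_no_dp4 += 1
                for alt in alts:
                    records.append(
                        VariantRecord(
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=str(alt),
                            qual=qual,
                            dp=dp,
                            dp4=dp4,
                            sample_id=label,
                        )
                    )
            except Dp4ExceedsDepthError:
                raise
            except (TypeError, ValueError, KeyError) as exc:
                raise VcfParseError(f"malformed VCF record #{i} in {path}: {exc}") from exc
    if n_multi:
        logger.warning("%s: split %d multi-allelic records per ALT", path, n_multi)
    if n_no_dp:
        logger.warning(
            "%s: %d records lack INFO:DP and are excluded from depth-based operations",
            path,
            n_no_dp,
        )
    if n_no_dp4:
        logger.warning(
            "%s: %d records lack INFO:DP4 and are excluded from strand operations",
            path,
            n_no_dp4,
        )
    return records


VCF_HEADER_LINES = (
    "##fileformat=VCFv4.2",
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Raw read depth">',
    '##INFO=<ID=DP4,Number=4,Type=Integer,Description='
    '"High-quality ref-forward, ref-reverse, alt-forward, alt-reverse bases">',
)


def write_vcf(
    records: Sequence[VariantRecord],
    path: str | Path,
    contigs: Optional[Iterable[tuple[str, int]]] = None,
    extra_header_lines: Iterable[str] = (),
    sample_id: Optional[str] = None,
) -> Path:
    """Write VariantRecords as a minimal, valid VCF 4.2 text file.

    QUAL is rendered with 2 decimals; DP/DP4 go to INFO when present.
    When ``sample_id`` is given (or all records share one non-empty
    label) it is recorded as a ``##sample_id=`` header line, which
    :func:`read_vcf` uses to relabel records on re-read.  Emission is
    plain text so identical inputs give byte-identical files.
    """
    path = Path(path)
    if sample_id is None:
        labels = {r.sample_id for r in records}
        if len(labels) == 1 and (only := labels.pop()):
            sample_id = only
    if contigs is None:
        seen: dict[str, int] = {}
        for r in records:
            seen[r.chrom] = max(seen.get(r.chrom, 0), r.pos + len(r.ref) + 1000)
        contigs = sorted(seen.items())
    lines = list(VCF_HEADER_LINES)
    if sample_id is not None:
        lines.append(f"##sample_id={sample_id}")
    lines += [f"##contig=<ID={c},length={ln}>" for c, ln in contigs]
    lines += list(extra_header_lines)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for r in records:
        info_parts = []
        if r.dp is not None:
            info_parts.append(f"DP={r.dp}")
        if r.dp4 is not None:
            info_parts.append("DP4=" + ",".join(str(x) for x in r.dp4))
        info = ";".join(info_parts) if info_parts else "."
        lines.append(
            f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t{r.qual:.2f}\t.\t{info}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


TRUTH_COLUMNS = ["chrom", "pos", "ref", "alt", "sample_id", "status"]


def read_truth_table(path: str | Path) -> list[TruthEntry]:
    """Read a tab-separated truth table (chrom, pos, ref, alt, sample_id, status).

    Status tokens are case-normalized to ``validated`` / ``failed``.
    Duplicate variant keys and unknown status tokens raise TruthTableError.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = [c for c in TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise TruthTableError(f"truth table {path} missing columns: {missing}")
    entries: list[TruthEntry] = []
    seen: set[VariantKey] = set()
    for row in df.itertuples(index=False):
        status = str(row.status).strip().lower()
        if status not in VALID_STATUSES:
            raise TruthTableError(f"unknown status token {row.status!r} in {path}")
        entry = TruthEntry(
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref=str(row.ref),
            alt=str(row.alt),
            sample_id=str(row.sample_id),
            status=status,  # type: ignore[arg-type]
        )
        if entry.key in seen:
            raise TruthTableError(f"duplicate truth key {entry.key} in {path}")
        seen.add(entry.key)
        entries.append(entry)
    return entries


def write_truth_table(entries: Sequence[TruthEntry], path: str | Path) -> Path:
    path = Path(path)
    lines = ["\t".join(TRUTH_COLUMNS)]
    lines += [
        f"{e.chrom}\t{e.pos}\t{e.ref}\t{e.alt}\t{e.sample_id}\t{e.status}"
        for e in entries
    ]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_exons(path: str | Path) -> list[ExonInterval]:
    """Read exon intervals from a BED file with >= 4 columns.

    The name column encodes the exon id and optionally the gene symbol as
    ``GENE|exon_label``; without a ``|`` the whole name is the exon id and
    the gene is empty.
    """
    exons: list[ExonInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedIntervalError(
                    f"{path}:{ln}: BED needs >= 4 columns, got {len(fields)}"
                )
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            if end <= start:
                raise BedIntervalError(f"{path}:{ln}: end <= start ({start}, {end})")
            gene = name.split("|", 1)[0] if "|" in name else ""
            exons.append(ExonInterval(chrom=chrom, start=start, end=end, exon_id=name, gene=gene))
    return exons


def write_exons(exons: Sequence[ExonInterval], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        "".join(f"{e.chrom}\t{e.start}\t{e.end}\t{e.exon_id}\n" for e in exons)
    )
    return path


def read_alignments(path: str | Path) -> list[AlignedRead]:
    """Read mapped primary alignments from SAM/BAM into AlignedReads.

    Unmapped, secondary, supplementary and duplicate-flagged reads are
    skipped; reads with missing MAPQ (255) are excluded with a warning
    since the mapping-quality statistics assume MAPQ in [0, 60].
    """
    reads: list[AlignedRead] = []
    n_missing_mapq = 0
    save = pysam.set_verbosity(0)  # silence missing-index chatter
    try:
        af = pysam.AlignmentFile(str(path), check_sq=False)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read alignments from {path}: {exc}") from exc
    finally:
        pysam.set_verbosity(save)
    with af:
        for aln in af:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary or aln.is_duplicate:
                continue
            if aln.mapping_quality == 255:
                n_missing_mapq += 1
                continue
            span = aln.reference_length or 0
            if span <= 0:
                continue
            reads.append(
                AlignedRead(
                    chrom=aln.reference_name,
                    start=aln.reference_start + 1,
                    aligned_span=span,
                    mapq=min(aln.mapping_quality, 60),
                )
            )
    if n_missing_mapq:
        logger.warning(
            "%s: excluded %d reads with unavailable MAPQ (255)", path, n_missing_mapq
        )
    return reads
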