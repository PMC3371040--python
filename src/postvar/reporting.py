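"""Shared report writers: TSV with a reproducibility header.

Every report starts with comment lines recording the package version,
the seed, and a hash of the effective configuration, so a report can be
traced back to the exact run that produced it and identical runs give
byte-identical files.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__

__all__ = ["config_hash", "repro_header", "write_tsv_report"]


def config_hash(config: Mapping[str, object]) -> str:
    """Stable short hash of a flat configuration mapping."""
    canon = ";".join(f"{k}={config[k]}" for k in sorted(config))
    return hashlib.sha1(canon.encode()).hexdigest()[:12]


def repro_header(config: Mapping[str, object], seed: Optional[int] = None) -> list[str]:
    lines = [f"# postvar v{__version__}"]
    lines.append(f"# config_hash={config_hash(config)}" + (f" seed={seed}" if seed is not None else ""))
    for k in sorted(config):
        lines.append(f"# {k}={config[k]}")
    return lines


def _format_cell(v: object, float_fmt: str) -> str:
    if v is None or (isinstance(v, float) and pd.isna(v)):
        return "NA"
    if isinstance(v, float):
        return format(v, float_fmt)
    return str(v)


def write_tsv_report(
    df: pd.DataFrame,
    path: str | Path,
    config: Mapping[str, object],
    seed: Optional[int] = None,
    float_fmt: str = ".4f",
    extra_comment_lines: Sequence[str] = (),
) -> Path:
    """Write a DataFrame as TSV under a reproducibility comment header."""
    path = Path(path)
    lines = repro_header(config, seed)
    lines += [f"# {ln}" for ln in extra_comment_lines]
    lines.append("\t".join(map(str, df.columns)))
    for row in df.itertuples(index=False):
        lines.append("\t".join(_format_cell(v, float_fmt) for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path
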