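"""Rendering of result tables and run provenance logs.

Human-readable tables mirror the published formatting rules: p-values to
3 significant figures with "a.bc × 10^−n" scientific notation, fold-change
and percentages to one decimal. Machine-readable TSV keeps full precision
with plain e-notation.
"""

from __future__ import annotations

import hashlib
import json
import math
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .enrichment import EnrichmentResult

__all__ = [
    "format_p",
    "format_pct",
    "RunLog",
    "ngs_results_frame",
    "lit_results_frame",
    "render_ngs_table",
    "render_lit_table",
]

_SUPERSCRIPTS = str.maketrans("0123456789-", "⁰¹²³⁴⁵⁶⁷⁸⁹⁻")


def format_p(p: float, sig: int = 3) -> str:
    """Render a p-value to ``sig`` significant figures.

    Values below 1e-4 use the publication-style "a.bc × 10^−n" notation;
    larger values are printed as plain decimals.
    """
    if math.isnan(p):
        return "nan"
    if p == 0.0:
        return "0"
    if p >= 1e-4:
        # round to sig significant figures, then print as decimal
        exponent = math.floor(math.log10(abs(p)))
        return f"{round(p, sig - 1 - exponent):g}"
    mantissa_exp = math.floor(math.log10(p))
    mantissa = p / 10**mantissa_exp
    mantissa = round(mantissa, sig - 1)
    if mantissa >= 10.0:  # rounding carried over
        mantissa /= 10.0
        mantissa_exp += 1
    return f"{mantissa:.{sig - 1}f} × 10^{mantissa_exp}"


def format_pct(x: float) -> str:
    return f"{x:.1f}%"


@dataclass
class RunLog:
    """Provenance for one analysis run: config echo, input hashes, warnings."""

    command: str
    config: dict = field(default_factory=dict)
    input_hashes: dict = field(default_factory=dict)
    row_counts: dict = field(default_factory=dict)
    seed: int | None = None
    warnings: list[str] = field(default_factory=list)
    version: str = __version__
    python: str = platform.python_version()

    def add_input(self, path: str | Path) -> None:
        path = Path(path)
        self.input_hashes[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str) + "\n")


def ngs_results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Full-precision frame for pooled-cohort Poisson results."""
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "count": [r.observed for r in results],
            "p_val": [r.p_raw for r in results],
            "p_adj": [r.p_adj for r in results],
            "fold_change": [r.fc for r in results],
            "enrichment_pct": [r.enrichment_pct for r in results],
            "significant": [r.significant for r in results],
        }
    )


def lit_results_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Full-precision frame for gene-specific literature-cohort results."""
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "n_cp": [r.observed[0] for r in results],
            "n_total": [r.observed[1] for r in results],
            "p_point": [r.p_point for r in results],
            "p_uppertail": [r.p_uppertail for r in results],
            "fold_change": [r.fc for r in results],
            "enrichment_pct": [r.enrichment_pct for r in results],
            "significant": [r.significant for r in results],
        }
    )


def render_ngs_table(results: Sequence[EnrichmentResult], top: int | None = None) -> str:
    """Human-readable pooled-cohort table (gene, count, p, p_adj, fc, enrichment)."""
    rows = ["gene\tcount\tp-val\tp_adj\tfold-change\tenrichment"]
    for r in results[:top]:
        rows.append(
            f"{r.gene}\t{r.observed}\t{format_p(r.p_raw)}\t{format_p(r.p_adj)}"
            f"\t{r.fc:.1f}\t{format_pct(r.enrichment_pct)}"
        )
    return "\n".join(rows)


def render_lit_table(results: Sequence[EnrichmentResult], top: int | None = None) -> str:
    """Human-readable literature-cohort table (gene, total, pval, fc, enrichment)."""
    rows = ["gene\ttotal\tpval\tfold-change\tenrichment"]
    for r in results[:top]:
        x, n = r.observed
        rows.append(
            f"{r.gene}\t{x}/{n} ({100 * x / n:.1f}%)\t{format_p(r.p_point)}"
            f"\t{r.fc:.1f}\t{format_pct(r.enrichment_pct)}"
        )
    return "\n".join(rows)
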