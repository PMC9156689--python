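"""miRNA-target interaction analysis.

Interactions (from target prediction and/or degradome sequencing evidence)
are restricted to cleavage-mode pairs, and the relationship between a miRNA
and its target is summarised by the Pearson correlation of their per-genotype
mean expression — globally across all genotypes, or locally along one
translocation line's dosage series (cis miRNA versus trans target).  P values
are two-sided and deliberately unadjusted for multiple comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InteractionRecord",
    "CorrelationResult",
    "load_interactions",
    "write_interactions",
    "genotype_means",
    "correlate_global",
    "correlate_local",
    "intersect_sources",
]

_SOURCES = {"prediction", "degradome"}
_MODES = {"cleavage", "inhibition"}
MAX_EXPECTATION_SCORE = 3.0  # prediction stringency cutoff


@dataclass(frozen=True)
class InteractionRecord:
    mirna_id: str
    target_id: str
    sources: frozenset[str]
    mode: str = "cleavage"
    expectation_score: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"unknown interaction mode {self.mode!r}")
        bad = self.sources - _SOURCES
        if bad:
            raise ValueError(f"unknown interaction source(s) {sorted(bad)}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.mirna_id, self.target_id)


@dataclass(frozen=True)
class CorrelationResult:
    interaction: InteractionRecord
    scope: str               # "global" or "local:<line_id>"
    r: float
    p: float
    n: int
    significant: bool
    exclusion_reason: str | None = None

    @property
    def excluded(self) -> bool:
        return self.exclusion_reason is not None


def load_interactions(path: str | Path) -> list[InteractionRecord]:
    """Read an interaction TSV (mirna_id, target_id, source, mode, expectation_score).

    Inhibition-mode rows are dropped (expression correlation is only
    interpretable for cleavage); prediction rows with expectation score > 3
    are dropped; duplicate pairs are merged with the union of their sources.
    """
    df = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "target_id": str})
    merged: dict[tuple[str, str], dict] = {}
    for row in df.itertuples():
        mode = str(row.mode)
        if mode not in _MODES:
            raise ValueError(f"unknown mode {mode!r} for pair ({row.mirna_id}, {row.target_id})")
        if mode == "inhibition":
            continue
        score = getattr(row, "expectation_score", None)
        score = None if score is None or pd.isna(score) else float(score)
        source = str(row.source)
        if source not in _SOURCES:
            raise ValueError(f"unknown source {source!r}")
        if source == "prediction" and score is not None and score > MAX_EXPECTATION_SCORE:
            continue
        key = (str(row.mirna_id), str(row.target_id))
        entry = merged.setdefault(key, {"sources": set(), "score": None})
        entry["sources"].add(source)
        if score is not None:
            entry["score"] = score if entry["score"] is None else min(entry["score"], score)
    return [
        InteractionRecord(m, t, frozenset(e["sources"]), "cleavage", e["score"])
        for (m, t), e in merged.items()
    ]


def write_interactions(records: Iterable[InteractionRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        for src in sorted(rec.sources):
            rows.append((rec.mirna_id, rec.target_id, src, rec.mode, rec.expectation_score))
    pd.DataFrame(
        rows, columns=["mirna_id", "target_id", "source", "mode", "expectation_score"]
    ).to_csv(path, sep="\t", index=False)


def genotype_means(
    rpm: pd.DataFrame, sample_genotype: Mapping[str, str]
) -> pd.DataFrame:
    """Collapse replicate columns to per-genotype mean expression (features x genotypes)."""
    groups: dict[str, list[str]] = {}
    for s in rpm.columns:
        groups.setdefault(sample_genotype[s], []).append(s)
    return pd.DataFrame({g: rpm[cols].mean(axis=1) for g, cols in groups.items()})


def _correlate(
    ir: InteractionRecord,
    x: pd.Series,
    y: pd.Series,
    scope: str,
    alpha: float,
) -> CorrelationResult:
    common = x.index.intersection(y.index)
    xv = x.loc[common].astype(float)
    yv = y.loc[common].astype(float)
    defined = xv.notna() & yv.notna()
    xv, yv = xv[defined], yv[defined]
    n = len(xv)
    if n < 3:
        return CorrelationResult(ir, scope, np.nan, np.nan, n, False, "n < 3")
    if xv.nunique() == 1 or yv.nunique() == 1:
        return CorrelationResult(ir, scope, np.nan, np.nan, n, False, "constant series")
    r, p = stats.pearsonr(xv.values, yv.values)
    return CorrelationResult(ir, scope, float(r), float(p), n, bool(p < alpha), None)


def correlate_global(
    ir: InteractionRecord,
    mirna_means: pd.DataFrame,
    target_means: pd.DataFrame,
    genotypes: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> CorrelationResult:
    """Pearson correlation of miRNA vs target genotype-mean expression across
    all available genotypes (two-sided P from the t transform with n-2 df)."""
    if ir.mirna_id not in mirna_means.index or ir.target_id not in target_means.index:
        return CorrelationResult(ir, "global", np.nan, np.nan, 0, False, "filtered expression")
    x = mirna_means.loc[ir.mirna_id]
    y = target_means.loc[ir.target_id]
    if genotypes is not None:
        cols = [g for g in genotypes if g in x.index and g in y.index]
        x, y = x[cols], y[cols]
    return _correlate(ir, x, y, "global", alpha)


def correlate_local(
    ir: InteractionRecord,
    line_id: str,
    series_genotypes: Sequence[str],
    mirna_means: pd.DataFrame,
    target_means: pd.DataFrame,
    alpha: float = 0.05,
) -> CorrelationResult:
    """Correlation restricted to one line's dosage-series genotypes.

    Series with fewer than 3 genotype classes are excluded (no P value can be
    produced), mirroring the treatment of two-point dosage series.
    """
    scope = f"local:{line_id}"
    if ir.mirna_id not in mirna_means.index or ir.target_id not in target_means.index:
        return CorrelationResult(ir, scope, np.nan, np.nan, 0, False, "filtered expression")
    cols = [g for g in series_genotypes if g in mirna_means.columns and g in target_means.columns]
    return _correlate(ir, mirna_means.loc[ir.mirna_id, cols], target_means.loc[ir.target_id, cols], scope, alpha)


def intersect_sources(results: Iterable[CorrelationResult]) -> dict:
    """Interactions significant under both evidence sources, with sign counts.

    An interaction enters the intersection when it is significant and its
    record carries both the prediction and degradome source tags.
    """
    both = [
        res
        for res in results
        if res.significant and res.interaction.sources >= {"prediction", "degradome"}
    ]
    negative = sum(1 for res in both if res.r < 0)
    return {
        "n_both_sources_significant": len(both),
        "n_negative": negative,
        "n_positive": len(both) - negative,
        "interactions": [res.interaction.pair for res in both],
    }
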