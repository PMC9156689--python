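"""Count normalisation, expression filtering, and replicate-level QC.

Counts are normalised to reads per million mapped reads (RPM).  RPM does not
reflect expression per cell — a whole-ploidy series scales transcriptome and
cell size together, so relative (RPM) expression cancels; that behaviour is
deliberate and preserved downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "QCReport",
    "read_counts",
    "read_sample_sheet",
    "rpm_normalize",
    "filter_low_expression",
    "replicate_qc_pca",
    "replicate_qc_pcc",
]


@dataclass
class CountMatrix:
    """Integer read counts, features x samples, with a sample -> genotype map."""

    counts: pd.DataFrame
    sample_genotype: Mapping[str, str]

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        unknown = [s for s in self.counts.columns if s not in self.sample_genotype]
        if unknown:
            raise ValueError(f"samples without genotype assignment: {unknown}")

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def samples_of(self, genotype: str) -> list[str]:
        return [s for s in self.counts.columns if self.sample_genotype[s] == genotype]

    def subset_samples(self, samples: Sequence[str]) -> "CountMatrix":
        return CountMatrix(
            self.counts[list(samples)],
            {s: self.sample_genotype[s] for s in samples},
        )


@dataclass
class NormalizedMatrix:
    """RPM values with the library sizes they were computed from."""

    rpm: pd.DataFrame
    library_sizes: pd.Series
    sample_genotype: Mapping[str, str] = field(default_factory=dict)

    def samples_of(self, genotype: str) -> list[str]:
        return [s for s in self.rpm.columns if self.sample_genotype.get(s) == genotype]


@dataclass
class QCReport:
    pc_scores: pd.DataFrame          # sample x (PC1, PC2)
    outlier_flags: pd.Series         # sample -> bool
    pairwise_pcc: pd.DataFrame       # columns: sample_a, sample_b, r, p, flagged
    warnings: list[str] = field(default_factory=list)


def read_counts(path: str | Path, sample_sheet: str | Path | None = None) -> CountMatrix:
    """Read a count TSV (first column feature_id, remaining columns samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if sample_sheet is None:
        raise ValueError("a sample sheet is required to map samples to genotypes")
    sheet = read_sample_sheet(sample_sheet)
    keep = [s for s in df.columns if sheet.get(s, {}).get("include", True)]
    mapping = {s: sheet[s]["genotype_id"] for s in keep if s in sheet}
    missing = [s for s in keep if s not in sheet]
    if missing:
        raise ValueError(f"samples absent from sample sheet: {missing}")
    return CountMatrix(df[keep].astype(int), mapping)


def read_sample_sheet(path: str | Path) -> dict[str, dict]:
    """Read a sample sheet TSV: sample_id, genotype_id, replicate, include_flag."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, dict] = {}
    for r in df.itertuples():
        include = True
        if hasattr(r, "include_flag") and str(r.include_flag).lower() in ("0", "false", "no"):
            include = False
        out[r.sample_id] = {
            "genotype_id": r.genotype_id,
            "replicate": getattr(r, "replicate", None),
            "include": include,
        }
    return out


def rpm_normalize(
    cm: CountMatrix, library_sizes: Mapping[str, int] | None = None
) -> NormalizedMatrix:
    """Reads-per-million normalisation: count / library_size * 1e6.

    Library sizes default to per-sample column sums of the analysed matrix;
    externally supplied totals (total mapped reads) take precedence.
    """
    if library_sizes is None:
        libs = cm.counts.sum(axis=0)
    else:
        libs = pd.Series({s: library_sizes[s] for s in cm.counts.columns}, dtype=float)
    if (libs <= 0).any():
        bad = list(libs.index[libs <= 0])
        raise ValueError(f"zero or negative library size for samples: {bad}")
    rpm = cm.counts.div(libs, axis=1) * 1e6
    return NormalizedMatrix(rpm, libs.astype(int), dict(cm.sample_genotype))


def filter_low_expression(
    nm: NormalizedMatrix,
    experimental: Sequence[str],
    control: Sequence[str],
    threshold: float = 0.5,
) -> pd.Index:
    """Keep features whose mean RPM across the pooled experimental + control
    replicates is >= threshold (default 0.5; strictly-below means are excluded).

    Filtering is per-comparison: the kept set depends on the two sample groups.
    """
    samples = list(experimental) + list(control)
    if len(samples) < 2:
        raise ValueError("comparison must name at least 2 samples")
    pooled_mean = nm.rpm[samples].mean(axis=1)
    return nm.rpm.index[pooled_mean >= threshold]


def replicate_qc_pca(nm: NormalizedMatrix, samples: Sequence[str]) -> QCReport:
    """PCA-based replicate QC on centred (unscaled) RPM profiles.

    A sample is flagged iff its PC1 or PC2 score lies more than 2 SDs from the
    mean score of the comparison set.  Flagged samples are reported, never
    dropped automatically.
    """
    samples = list(samples)
    warns: list[str] = []
    if len(samples) < 3:
        warns.append(f"QC skipped: only {len(samples)} samples (need >= 3)")
        warnings.warn(warns[-1])
        empty = pd.DataFrame(columns=["PC1", "PC2"])
        return QCReport(empty, pd.Series(dtype=bool), _pcc_table(nm, samples), warns)

    x = nm.rpm[samples].T.values  # samples x features
    if np.allclose(x.std(axis=0), 0):
        warns.append("QC degenerate: zero variance across samples; no flags")
        warnings.warn(warns[-1])
        scores = pd.DataFrame(0.0, index=samples, columns=["PC1", "PC2"])
        flags = pd.Series(False, index=samples)
        return QCReport(scores, flags, _pcc_table(nm, samples), warns)

    n_comp = min(2, len(samples) - 1, x.shape[1])
    pca = PCA(n_components=n_comp)
    pcs = pca.fit_transform(x - x.mean(axis=0))
    scores = pd.DataFrame(0.0, index=samples, columns=["PC1", "PC2"])
    scores.iloc[:, :n_comp] = pcs

    flags = pd.Series(False, index=samples)
    for col in ("PC1", "PC2"):
        v = scores[col]
        sd = v.std(ddof=1)
        if sd > 0:
            flags |= (v - v.mean()).abs() > 2 * sd
    return QCReport(scores, flags, _pcc_table(nm, samples), warns)


def _pcc_table(nm: NormalizedMatrix, samples: Sequence[str]) -> pd.DataFrame:
    rows = []
    for a, b in combinations(samples, 2):
        xa, xb = nm.rpm[a].values, nm.rpm[b].values
        if np.std(xa) == 0 or np.std(xb) == 0:
            rows.append((a, b, np.nan, np.nan, True))
            continue
        r, p = stats.pearsonr(xa, xb)
        rows.append((a, b, float(r), float(p), bool(p >= 0.05)))
    return pd.DataFrame(rows, columns=["sample_a", "sample_b", "r", "p", "flagged"])


def replicate_qc_pcc(nm: NormalizedMatrix, samples: Sequence[str]) -> pd.DataFrame:
    """Pairwise Pearson correlation between replicate expression profiles.

    Pairs with P >= 0.05 (or an undefined R from a constant profile) are
    flagged; the matrix itself is never modified.
    """
    if len(samples) < 2:
        raise ValueError("need at least 2 samples for pairwise correlation")
    return _pcc_table(nm, samples)
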