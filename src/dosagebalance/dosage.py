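"""Dosage-response analysis: expected ratios, trans-ratio trends, response typology.

Varying the copy number d of a chromosomal segment against a control copy
number d_c sets two analytic reference fold changes for expression:

* direct (gene-dosage) ratio d_e/d_c — expression follows DNA copy number;
* inverse ratio d_c/d_e — expression of unvaried (trans) features modulated
  reciprocally to the varied dosage.

Per-feature fold changes across a dosage series are compared against these
references, the medians of trans ratios summarise the genome-wide trend (and
are clustered with an exact 1-D k-means), and each feature's pattern of
significant calls across the series is classified into a response type:
direct/positive dosage effect, negative/inverse dosage effect, dosage
compensation, increased or decreased effect, or a mixed response.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import SegmentDef, cis_count_size_correlation
from .preprocess import NormalizedMatrix

__all__ = [
    "ComparisonSpec",
    "ExpectedRatios",
    "ComparisonEvidence",
    "ResponseCall",
    "expected_ratios",
    "compute_ratios",
    "median_trans_ratio",
    "kmeans_1d",
    "apply_control_exclusion",
    "classify_cis_response",
    "classify_trans_response",
    "dem_size_correlation",
]

_SERIES = {"diploid_aneuploid", "haploid_aneuploid", "ploidy", "b_control"}


@dataclass(frozen=True)
class ComparisonSpec:
    """One experimental-vs-control contrast in the dosage design.

    ``cis_dosage_pair`` is (d_e, d_c): copy number of the varied region in the
    experimental and control groups (for the ploidy series, the ploidy itself).
    """

    name: str
    experimental: tuple[str, ...]
    control: tuple[str, ...]
    cis_dosage_pair: tuple[int, int]
    series: str
    line_id: str | None = None

    def __post_init__(self) -> None:
        if self.series not in _SERIES:
            raise ValueError(f"{self.name}: unknown series {self.series!r}")
        d_e, d_c = self.cis_dosage_pair
        if self.series != "b_control" and (d_e < 1 or d_c < 1):
            raise ValueError(f"{self.name}: dosages must be >= 1")
        if self.series in ("diploid_aneuploid", "haploid_aneuploid") and self.line_id is None:
            raise ValueError(f"{self.name}: aneuploid comparison requires a line_id")


@dataclass(frozen=True)
class ExpectedRatios:
    """Analytic reference fold changes for a comparison (exact rationals inside)."""

    direct: Fraction
    inverse: Fraction
    no_change: float = 1.0

    @property
    def direct_fc(self) -> float:
        """Direct (gene-dosage) reference FC, rounded to 2 decimals as reported."""
        return round(float(self.direct), 2)

    @property
    def inverse_fc(self) -> float:
        """Inverse reference FC, rounded to 2 decimals as reported."""
        return round(float(self.inverse), 2)


def expected_ratios(cmp: ComparisonSpec) -> ExpectedRatios:
    """Reference direct and inverse fold changes d_e/d_c and d_c/d_e.

    Their product is exactly 1.  Rounding to two decimals is presentation
    only; the exact rationals are retained.
    """
    d_e, d_c = cmp.cis_dosage_pair
    if d_e == d_c:
        warnings.warn(f"{cmp.name}: degenerate comparison (equal dosages); both ratios 1.0")
    return ExpectedRatios(Fraction(d_e, d_c), Fraction(d_c, d_e))


def compute_ratios(
    nm: NormalizedMatrix,
    cmp: ComparisonSpec,
    kept_features: Sequence[str],
) -> pd.Series:
    """Per-feature fold change of group-mean RPM, experimental over control.

    Features whose control mean is zero get NaN (undefined) and are excluded
    from downstream medians.  Only expression-filtered features are computed.
    """
    exp_samples = [s for g in cmp.experimental for s in nm.samples_of(g)]
    ctl_samples = [s for g in cmp.control for s in nm.samples_of(g)]
    kept = pd.Index(kept_features)
    if kept.empty:
        return pd.Series(dtype=float, name=cmp.name)
    mean_exp = nm.rpm.loc[kept, exp_samples].mean(axis=1)
    mean_ctl = nm.rpm.loc[kept, ctl_samples].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = mean_exp / mean_ctl
    fc[mean_ctl == 0] = np.nan
    fc.name = cmp.name
    return fc


def median_trans_ratio(ratios: pd.Series, trans_features: Sequence[str]) -> float:
    """Median fold change over defined, trans-labelled features."""
    vals = ratios.reindex(pd.Index(trans_features)).dropna()
    if vals.empty:
        raise ValueError("no defined trans ratios")
    return float(vals.median())


def kmeans_1d(values: Sequence[float], k: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Globally optimal 1-D k-means by dynamic programming on sorted values.

    Optimal 1-D clusters are contiguous in sorted order, so an O(n^2 k) DP
    over split points finds the exact within-cluster sum-of-squares optimum;
    the result is deterministic.  Returns (labels aligned to the input order,
    sorted cluster centers).
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < k:
        raise ValueError(f"need at least k={k} values, got {n}")
    if np.unique(x).size < k:
        raise ValueError("degenerate input: fewer distinct values than clusters")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    csum = np.concatenate([[0.0], np.cumsum(xs)])
    csq = np.concatenate([[0.0], np.cumsum(xs * xs)])

    def sse(i: int, j: int) -> float:
        # within-cluster SSE of xs[i:j]
        m = j - i
        s = csum[j] - csum[i]
        return (csq[j] - csq[i]) - s * s / m

    INF = math.inf
    cost = np.full((k + 1, n + 1), INF)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = INF, c - 1
            for i in range(c - 1, j):
                v = cost[c - 1, i] + sse(i, j)
                if v < best:
                    best, arg = v, i
            cost[c, j] = best
            split[c, j] = arg

    bounds = [n]
    j = n
    for c in range(k, 0, -1):
        j = split[c, j]
        bounds.append(j)
    bounds = bounds[::-1]
    labels_sorted = np.empty(n, dtype=int)
    centers = np.empty(k)
    for c in range(k):
        i, j = bounds[c], bounds[c + 1]
        labels_sorted[i:j] = c
        centers[c] = xs[i:j].mean()
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels, centers


def apply_control_exclusion(
    features: Sequence[str], b_control_dems: Sequence[str]
) -> pd.Index:
    """Drop features differentially expressed in the B-chromosome control pair.

    Features responding to the presence of a B chromosome cannot be attributed
    to dosage of the essential (A-chromosome) segment, so they are removed from
    all aneuploidy interpretation.
    """
    excluded = set(b_control_dems)
    return pd.Index([f for f in features if f not in excluded])


@dataclass(frozen=True)
class ComparisonEvidence:
    """Per-comparison DE evidence for one feature."""

    comparison: str
    d_e: int
    d_c: int
    series: str              # diploid_aneuploid | haploid_aneuploid
    logfc: float
    fdr: float
    fc: float

    @property
    def dosage_sign(self) -> int:
        return int(np.sign(self.d_e - self.d_c))

    @property
    def significant(self) -> bool:
        return self.fdr < 0.05  # overridden by classifier alpha; convenience only


@dataclass(frozen=True)
class ResponseCall:
    feature_id: str
    context: str             # cis | trans
    line_id: str | None
    label: str
    evidence: tuple[ComparisonEvidence, ...] = field(default_factory=tuple)


def _alignment(ev: ComparisonEvidence) -> int:
    """+1 if the change tracks dosage direction, -1 if it opposes it, 0 if flat."""
    return int(np.sign(ev.logfc)) * ev.dosage_sign


def _series_conflict(sig: list[ComparisonEvidence]) -> bool:
    """True when diploid- and haploid-background significant calls disagree in alignment."""
    by_series: dict[str, set[int]] = {}
    for ev in sig:
        by_series.setdefault(ev.series, set()).add(_alignment(ev))
    if "diploid_aneuploid" in by_series and "haploid_aneuploid" in by_series:
        return by_series["diploid_aneuploid"] != by_series["haploid_aneuploid"]
    return False


def classify_cis_response(
    feature_id: str,
    line_id: str | None,
    evidence: Sequence[ComparisonEvidence],
    alpha: float = 0.05,
    compensation_band: float = 1.25,
) -> ResponseCall:
    """Classify a cis feature's dosage response across its line's comparisons.

    With S = comparisons significant at fdr < alpha:
      direct_dosage   — every call in S tracks dosage direction;
      negative_dosage — every call opposes it;
      increased       — all calls up, in both a dosage-decreased and a
                        dosage-increased comparison;
      decreased       — mirror of increased;
      compensation    — S empty and every FC within [1/band, band];
      mixed           — significant calls conflicting between the diploid-
                        and haploid-background series;
      unclassified    — no evidence, or S empty with the FC band violated, or
                        an uninterpretable conflict within one series.
    """
    evs = list(evidence)
    if not evs:
        return ResponseCall(feature_id, "cis", line_id, "unclassified")
    sig = [e for e in evs if e.fdr < alpha and e.dosage_sign != 0]
    label = _classify_pattern(sig, evs, alpha, compensation_band)
    return ResponseCall(
        feature_id,
        "cis",
        line_id,
        _CIS_NAMES.get(label, label),
        tuple(evs),
    )


def classify_trans_response(
    feature_id: str,
    line_id: str | None,
    evidence: Sequence[ComparisonEvidence],
    alpha: float = 0.05,
    max_nonsignificant: int = 1,
) -> ResponseCall:
    """Classify a trans feature's response to another segment's dosage.

    Eligibility: the feature must be significant in all available aneuploidy
    comparisons except at most ``max_nonsignificant`` (when only the
    haploid-background disomy comparison exists, significance there suffices).
    Labels mirror the cis typology with positive_trans / inverse_trans for the
    dosage-tracking and dosage-opposing linear responses; anything else with
    conflicting significant calls is mixed.
    """
    evs = list(evidence)
    if not evs:
        return ResponseCall(feature_id, "trans", line_id, "unclassified")
    sig = [e for e in evs if e.fdr < alpha and e.dosage_sign != 0]
    n_nonsig = len(evs) - len(sig)
    eligible = len(sig) >= 1 and (len(evs) == 1 or n_nonsig <= max_nonsignificant)
    if not eligible:
        return ResponseCall(feature_id, "trans", line_id, "unclassified", tuple(evs))
    label = _classify_pattern(sig, evs, alpha, compensation_band=None)
    return ResponseCall(
        feature_id,
        "trans",
        line_id,
        _TRANS_NAMES.get(label, label),
        tuple(evs),
    )


_CIS_NAMES = {"aligned": "direct_dosage", "opposed": "negative_dosage"}
_TRANS_NAMES = {"aligned": "positive_trans", "opposed": "inverse_trans"}


def _classify_pattern(
    sig: list[ComparisonEvidence],
    evs: list[ComparisonEvidence],
    alpha: float,
    compensation_band: float | None,
) -> str:
    if not sig:
        if compensation_band is None:
            return "unclassified"
        band = (1.0 / compensation_band, compensation_band)
        fcs = [e.fc for e in evs if np.isfinite(e.fc)]
        if fcs and all(band[0] <= fc <= band[1] for fc in fcs):
            return "compensation"
        return "unclassified"

    ups = [e for e in sig if e.logfc > 0]
    downs = [e for e in sig if e.logfc < 0]
    has_dec_dir = any(e.dosage_sign < 0 for e in sig)
    has_inc_dir = any(e.dosage_sign > 0 for e in sig)

    # same-direction change in both dosage-decreased and dosage-increased
    # comparisons is a nonlinear (increased / decreased) effect
    if len(ups) == len(sig) and has_dec_dir and has_inc_dir:
        return "increased"
    if len(downs) == len(sig) and has_dec_dir and has_inc_dir:
        return "decreased"
    if all(_alignment(e) == 1 for e in sig):
        return "aligned"
    if all(_alignment(e) == -1 for e in sig):
        return "opposed"
    if _series_conflict(sig):
        return "mixed"
    return "mixed"


def dem_size_correlation(
    dem_counts: Mapping[str, int], segments: Sequence[SegmentDef]
) -> tuple[float, float, int]:
    """Pearson correlation of per-line trans-DEM counts against segment size."""
    return cis_count_size_correlation(dem_counts, segments)
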