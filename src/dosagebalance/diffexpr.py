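"""Count-based differential expression for two-group comparisons.

Self-contained negative-binomial (NB) exact testing in the style of classic
count-based DE analysis: libraries are equalised by linear scaling to the
geometric-mean library size, a common dispersion is estimated by conditional
maximum likelihood, and significance of a group-abundance shift is assessed
by an exact conditional test on the group totals with minimum-likelihood
two-siding.  P values are adjusted by Benjamini-Hochberg; features with
adjusted P < 0.05 are the differentially expressed set.

The conditional likelihood used for dispersion estimation is the
negative-hypergeometric identity: for n iid NB(mu, phi) observations,
P(y | sum y = z) does not depend on mu, leaving a 1-D likelihood in phi.

A separate two-sample t test on per-replicate log2 ratios handles the one
comparison where the two groups come from different genetic backgrounds and
share a common reference group (tetraploid vs triploid, both over diploid).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .preprocess import CountMatrix, NormalizedMatrix

__all__ = [
    "DispersionEstimate",
    "equalize_libraries",
    "estimate_dispersion",
    "nb_exact_test",
    "bh_adjust",
    "de_test",
    "call_dems",
    "ratio_t_test",
    "replicate_log_ratios",
]

_TIE_REL_TOL = 1e-12
_MIN_DISPERSION = 1e-8


@dataclass
class DispersionEstimate:
    common: float
    tagwise: pd.Series
    shrinkage_weight: float


def equalize_libraries(
    counts: pd.DataFrame, library_sizes: pd.Series | None = None
) -> pd.DataFrame:
    """Scale counts linearly to the (rounded) geometric-mean library size.

    Returns integer pseudo-counts on a common effective library, so that group
    totals are comparable under conditioning.
    """
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    libs = library_sizes.loc[counts.columns].astype(float)
    if (libs <= 0).any():
        raise ValueError("library sizes must be positive")
    target = float(np.exp(np.log(libs).mean()))
    scaled = counts.mul(target / libs, axis=1)
    return scaled.round().astype(np.int64)


def _cond_loglik_group(y: np.ndarray, phi: float) -> np.ndarray:
    """Per-feature NB conditional log-likelihood of replicate counts given their sum.

    y: features x replicates.  Independent of the mean; the basis for common
    dispersion estimation.  phi -> 0 recovers the multinomial (Poisson) limit.
    """
    n = y.shape[1]
    z = y.sum(axis=1)
    if phi < _MIN_DISPERSION:
        # Poisson limit: equiprobable multinomial over replicates
        return (
            gammaln(z + 1)
            - gammaln(y + 1).sum(axis=1)
            - z * np.log(n)
        )
    r = 1.0 / phi
    return (
        gammaln(y + r).sum(axis=1)
        - n * gammaln(r)
        + gammaln(n * r)
        + gammaln(z + 1)
        - gammaln(y + 1).sum(axis=1)
        - gammaln(z + n * r)
    )


def _moment_dispersion(y: np.ndarray) -> np.ndarray:
    """Per-feature method-of-moments dispersion, pooled over groups already split out."""
    m = y.mean(axis=1)
    v = y.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = (v - m) / np.square(m)
    phi = np.where(np.isfinite(phi), phi, 0.0)
    return np.clip(phi, 0.0, None)


def estimate_dispersion(
    cm: CountMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    shrinkage_weight: float = 0.7,
    library_sizes: Mapping[str, int] | None = None,
) -> DispersionEstimate:
    """Estimate a common NB dispersion by conditional ML, plus shrunk tagwise values.

    Counts are first equalised to a common library size; the summed conditional
    log-likelihood over features and both groups is maximised in phi.  Tagwise
    dispersions are per-feature moment estimates shrunk linearly toward the
    common value with weight ``shrinkage_weight`` (1.0 = fully common).
    """
    if not 0.0 <= shrinkage_weight <= 1.0:
        raise ValueError("shrinkage_weight must be in [0, 1]")
    samples = list(group_a) + list(group_b)
    counts = cm.counts[samples]
    if (counts.values == 0).all():
        raise ValueError("all-zero count matrix: dispersion undefined")
    libs = None
    if library_sizes is not None:
        libs = pd.Series({s: library_sizes[s] for s in samples}, dtype=float)
    pseudo = equalize_libraries(counts, libs)
    groups = [g for g in (list(group_a), list(group_b)) if len(g) >= 2]
    if not groups:
        raise ValueError("need >= 2 replicates in at least one group")

    ys = [pseudo[g].values for g in groups]

    def neg_ll(log_phi: float) -> float:
        phi = float(np.exp(log_phi))
        return -sum(_cond_loglik_group(y, phi).sum() for y in ys)

    res = optimize.minimize_scalar(neg_ll, bounds=(np.log(1e-6), np.log(20.0)), method="bounded")
    common = float(np.exp(res.x))
    ll_zero = -sum(_cond_loglik_group(y, 0.0).sum() for y in ys)
    if ll_zero <= res.fun:
        common = 0.0

    moment = np.zeros(len(pseudo))
    weight_n = 0
    for y in ys:
        moment += _moment_dispersion(y) * y.shape[1]
        weight_n += y.shape[1]
    moment /= weight_n
    tagwise_vals = shrinkage_weight * common + (1.0 - shrinkage_weight) * moment
    if len(pseudo) == 1:
        tagwise_vals = np.array([common])
    tagwise = pd.Series(tagwise_vals, index=pseudo.index)
    return DispersionEstimate(common, tagwise, shrinkage_weight)


def _conditional_logpmf(t: int, n_a: int, n_b: int, dispersion: float) -> np.ndarray:
    """Log-probabilities of every split a=0..t of the grand total between groups.

    Group totals of n iid NB(mu, phi) are NB(n*mu, phi/n); conditioning on the
    grand total t, the null mean is estimated as t/(n_a+n_b) per library.
    In the dispersion -> 0 limit this is Binomial(t, n_a/(n_a+n_b)).
    """
    a = np.arange(t + 1)
    if dispersion < _MIN_DISPERSION:
        return stats.binom.logpmf(a, t, n_a / (n_a + n_b))
    mu = t / (n_a + n_b)
    r_a, r_b = n_a / dispersion, n_b / dispersion
    log_fa = stats.nbinom.logpmf(a, r_a, r_a / (r_a + n_a * mu))
    log_fb = stats.nbinom.logpmf(t - a, r_b, r_b / (r_b + n_b * mu))
    log_q = log_fa + log_fb
    return log_q - logsumexp(log_q)


def nb_exact_test(
    counts_a: Sequence[int],
    counts_b: Sequence[int],
    dispersion: float,
    library_sizes: Sequence[int] | None = None,
) -> float:
    """Exact NB conditional test of a group-abundance difference.

    Counts are equalised to a common library size (when sizes are given), the
    group totals are conditioned on their sum, and the two-sided p-value is
    the total probability of all splits at most as probable as the observed
    one (minimum-likelihood two-siding).  dispersion=0 is the Poisson limit,
    equivalent to an exact binomial test of the group-A total.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    a = np.asarray(counts_a, dtype=np.int64)
    b = np.asarray(counts_b, dtype=np.int64)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("counts must be non-negative")
    if library_sizes is not None:
        libs = np.asarray(library_sizes, dtype=float)
        if len(libs) != len(a) + len(b):
            raise ValueError("library_sizes must cover all samples (group A then B)")
        target = float(np.exp(np.log(libs).mean()))
        merged = np.concatenate([a, b]) * (target / libs)
        merged = np.round(merged).astype(np.int64)
        a, b = merged[: len(a)], merged[len(a):]

    s_a, s_b = int(a.sum()), int(b.sum())
    t = s_a + s_b
    if t == 0:
        return 1.0
    log_q = _conditional_logpmf(t, len(a), len(b), dispersion)
    obs = log_q[s_a]
    mask = log_q <= obs + np.log1p(_TIE_REL_TOL)
    p = float(np.exp(logsumexp(log_q[mask])))
    return min(p, 1.0)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, order-preserving."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_test(
    cm: CountMatrix,
    nm: NormalizedMatrix,
    experimental: Sequence[str],
    control: Sequence[str],
    features: Sequence[str] | None = None,
    dispersion: DispersionEstimate | float | None = None,
    dispersion_mode: str = "common",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full two-group DE table: logFC, mean abundance, exact-test p, BH FDR, direction.

    ``features`` restricts testing to the expression-filtered set (so the BH
    family size is the number of features actually tested).  logFC is log2 of
    the ratio of group-mean RPM; direction is up/down at fdr < alpha, else ns.
    """
    exp_s, ctl_s = list(experimental), list(control)
    if features is None:
        features = cm.counts.index
    features = pd.Index(features)
    counts = cm.counts.loc[features]
    libs = nm.library_sizes

    if dispersion is None:
        dispersion = estimate_dispersion(
            cm.subset_samples(exp_s + ctl_s).counts.pipe(
                lambda df: CountMatrix(df.loc[features], {s: cm.sample_genotype[s] for s in exp_s + ctl_s})
            ),
            exp_s,
            ctl_s,
            library_sizes=libs,
        )
    if isinstance(dispersion, DispersionEstimate):
        if dispersion_mode == "common":
            disp_vec = np.full(len(features), dispersion.common)
        elif dispersion_mode == "tagwise":
            disp_vec = dispersion.tagwise.reindex(features).fillna(dispersion.common).values
        else:
            raise ValueError(f"unknown dispersion_mode {dispersion_mode!r}")
    else:
        disp_vec = np.full(len(features), float(dispersion))

    lib_vec = [int(libs[s]) for s in exp_s + ctl_s]
    pvals = np.empty(len(features))
    for i, f in enumerate(features):
        pvals[i] = nb_exact_test(
            counts.loc[f, exp_s].values, counts.loc[f, ctl_s].values, disp_vec[i], lib_vec
        )

    mean_exp = nm.rpm.loc[features, exp_s].mean(axis=1)
    mean_ctl = nm.rpm.loc[features, ctl_s].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logfc = np.log2(mean_exp.values / mean_ctl.values)
    logfc = np.where(
        (mean_exp.values == 0) & (mean_ctl.values == 0), 0.0, logfc
    )
    log_mean = np.log2(nm.rpm.loc[features, exp_s + ctl_s].mean(axis=1).values)

    fdr = bh_adjust(pvals)
    direction = np.where(
        fdr < alpha, np.where(logfc > 0, "up", np.where(logfc < 0, "down", "ns")), "ns"
    )
    return pd.DataFrame(
        {
            "feature_id": features,
            "logFC": logfc,
            "log_mean": log_mean,
            "p": pvals,
            "fdr": fdr,
            "direction": direction,
        }
    ).set_index("feature_id")


def call_dems(results: pd.DataFrame, alpha: float = 0.05) -> tuple[pd.DataFrame, dict]:
    """Differentially expressed features at fdr < alpha, with up/down counts."""
    dems = results[results["fdr"] < alpha]
    counts = {
        "up": int((dems["logFC"] > 0).sum()),
        "down": int((dems["logFC"] < 0).sum()),
        "total": int(len(dems)),
    }
    return dems, counts


def replicate_log_ratios(
    nm: NormalizedMatrix,
    samples: Sequence[str],
    reference_samples: Sequence[str],
    features: Sequence[str],
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Per-replicate log2(replicate RPM / reference-group mean RPM)."""
    ref_mean = nm.rpm.loc[features, list(reference_samples)].mean(axis=1)
    out = {}
    for s in samples:
        with np.errstate(divide="ignore", invalid="ignore"):
            out[s] = np.log2((nm.rpm.loc[features, s] + pseudocount) / (ref_mean + pseudocount))
    return pd.DataFrame(out, index=pd.Index(features))


def ratio_t_test(
    log2_ratios_a: Sequence[float], log2_ratios_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sample two-sided Student's t test on per-replicate log2 ratios.

    Used where the two experimental groups differ in genetic background and
    are each expressed relative to a shared reference group, so the test asks
    whether the mean log2 ratios differ.  Degenerate zero-variance inputs with
    equal means give p = 1.
    """
    a = np.asarray(log2_ratios_a, dtype=float)
    b = np.asarray(log2_ratios_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 replicate ratios")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf"), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
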