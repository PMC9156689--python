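"""Synthetic dosage-series study generator with ground truth.

Emulates the structure of a segmental-dosage sRNA/mRNA expression study:

* a set of translocation lines, each varying one chromosomal segment with
  dosages {1,2,3,4} on a diploid background and {1,2} on a haploid background;
* a whole-genome ploidy series (1X/2X/3X/4X) and a B-chromosome control pair
  (0B/1B);
* negative-binomially distributed feature counts with per-sample library-size
  variation, per-feature baseline abundance on an RPM scale (library sizes are
  external "total mapped reads", of which the feature matrix is a fraction);
* per-feature response archetypes — direct dosage, negative dosage,
  compensation, increased, decreased, mixed (cis), positive and inverse
  trans modulation, plus unresponsive background features and B-responsive
  decoys;
* miRNA-to-target cleavage coupling of tunable sign and strength, with
  uncoupled decoy interactions and both prediction and degradome source tags.

Expected per-genotype means are closed-form: a feature with baseline b (RPM)
and archetype ratio r(d; background) has mean RPM b*r, and whole-ploidy
genotypes leave RPM unchanged (per-cell expression and transcriptome size
scale together and cancel under reads-per-million normalisation).  Every
simulated feature and interaction carries a truth record, and a fixed seed
fully determines all outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    FeatureLocus,
    GenotypeDesign,
    SegmentDef,
    write_genotype_designs,
    write_loci_bed,
)
from .dosage import ComparisonSpec
from .preprocess import CountMatrix

__all__ = [
    "SimConfig",
    "Design",
    "SimulatedStudy",
    "simulate_design",
    "simulate_counts",
    "simulate_targets",
    "simulate_study",
    "standard_comparisons",
    "write_study",
]

CIS_ARCHETYPES = {"direct_dosage", "negative_dosage", "compensation", "mixed"}
TRANS_ARCHETYPES = {"positive_trans", "inverse_trans", "increased", "decreased", "null"}

_DEFAULT_MIX = {
    "direct_dosage": 0.10,
    "negative_dosage": 0.03,
    "compensation": 0.07,
    "mixed": 0.03,
    "positive_trans": 0.10,
    "inverse_trans": 0.25,
    "increased": 0.06,
    "decreased": 0.06,
    "null": 0.30,
}

_CHROM_LEN = 150_000_000
_TRANS_REGION_END = 40_000_000     # trans loci live below every segment start
_SEGMENT_MIN_START = 50_000_000


@dataclass(frozen=True)
class SimConfig:
    """Study-level simulation parameters.

    ``archetype_mix`` proportions must sum to 1.  ``dispersion`` is the NB
    dispersion phi (var = mu + phi mu^2).  Baseline abundances are a lognormal
    mixture on the RPM scale with a low-expression stratum near the 0.5-RPM
    filter so the filtering path is exercised.
    """

    n_lines: int = 5
    n_mirnas: int = 400
    n_genes: int = 300
    replicates: int = 3
    dispersion: float = 0.05
    lib_size_mean: int = 5_000_000
    lib_size_cv: float = 0.2
    archetype_mix: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_MIX))
    effect_increase: float = math.log(1.5)   # delta for increased/decreased
    b_effect: float = math.log(2.0)          # fold effect on B-responsive decoys
    n_b_responsive: int = 2
    coupling_fraction_negative: float = 0.6
    coupling_exponent: float = 0.8
    coupling_fraction_coupled: float = 0.5
    baseline_meanlog: float = math.log(20.0)
    baseline_sdlog: float = 1.0
    low_fraction: float = 0.15
    low_meanlog: float = math.log(0.3)
    low_sdlog: float = 0.5
    gene_baseline_meanlog: float = math.log(30.0)
    include_interstitial: bool = True
    cis_per_line_proportional: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.archetype_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"archetype proportions must sum to 1 (got {total})")
        unknown = set(self.archetype_mix) - (CIS_ARCHETYPES | TRANS_ARCHETYPES)
        if unknown:
            raise ValueError(f"unknown archetypes: {sorted(unknown)}")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass
class Design:
    segments: list[SegmentDef]
    loci: list[FeatureLocus]
    genotypes: dict[str, GenotypeDesign]
    sample_sheet: pd.DataFrame        # sample_id, genotype_id, replicate, include_flag, library_size
    truth: pd.DataFrame               # feature_id, archetype, context, line_id, baseline_rpm

    @property
    def sample_genotype(self) -> dict[str, str]:
        return dict(zip(self.sample_sheet["sample_id"], self.sample_sheet["genotype_id"]))

    @property
    def library_sizes(self) -> dict[str, int]:
        return dict(zip(self.sample_sheet["sample_id"], self.sample_sheet["library_size"]))


@dataclass
class SimulatedStudy:
    config: SimConfig
    design: Design
    mirna_counts: CountMatrix
    mirna_expected_rpm: pd.DataFrame          # features x genotypes, closed-form means
    gene_counts: CountMatrix
    gene_expected_rpm: pd.DataFrame
    gene_loci: list[FeatureLocus]
    interactions: pd.DataFrame                # long TSV form incl. decoys and mode rows
    interaction_truth: pd.DataFrame           # mirna_id, target_id, coupled, sign, exponent


def _genotype_table(cfg: SimConfig, line_ids: Sequence[str]) -> dict[str, GenotypeDesign]:
    g: dict[str, GenotypeDesign] = {}
    g["2D"] = GenotypeDesign("2D", 2)
    g["h1D"] = GenotypeDesign("h1D", 1)
    for line in line_ids:
        for d in (1, 3, 4):
            g[f"{line}_{d}D"] = GenotypeDesign(f"{line}_{d}D", 2, {line: d})
        g[f"{line}_h2D"] = GenotypeDesign(f"{line}_h2D", 1, {line: 2})
    for name, ploidy in (("1X", 1), ("2X", 2), ("3X", 3), ("4X", 4)):
        g[name] = GenotypeDesign(name, ploidy)
    g["0B"] = GenotypeDesign("0B", 2, b_count=0)
    g["1B"] = GenotypeDesign("1B", 2, b_count=1)
    return g


def simulate_design(cfg: SimConfig, rng: np.random.Generator | None = None) -> Design:
    """Build segments, loci, genotype designs, sample sheet, and the truth table.

    Segments are distal intervals of varying size (plus one interstitial line
    spanning a mock centromere when configured); cis-archetype features are
    placed inside their home line's segment, with home lines drawn with
    probability proportional to segment length (so cis counts track size);
    trans features are placed in a region below every segment.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    line_ids = [f"L{i + 1:02d}" for i in range(cfg.n_lines)]
    segments: list[SegmentDef] = []
    for i, line in enumerate(line_ids):
        chrom = f"chr{(i % 10) + 1}"
        interstitial = cfg.include_interstitial and i == cfg.n_lines - 1 and cfg.n_lines > 1
        if interstitial:
            length = int(rng.integers(20_000_000, 60_000_000))
            start = 60_000_000
            seg = SegmentDef(line, chrom, start, start + length - 1, "interstitial")
        else:
            length = int(rng.integers(20_000_000, 100_000_000))
            start = max(_SEGMENT_MIN_START, _CHROM_LEN - length + 1)
            seg = SegmentDef(line, chrom, start, _CHROM_LEN, "distal")
        segments.append(seg)
    seg_by_line = {s.line_id: s for s in segments}
    seg_lengths = np.array([s.interval_end - s.interval_start + 1 for s in segments], dtype=float)

    labels = list(cfg.archetype_mix)
    counts = _apportion(cfg.n_mirnas, [cfg.archetype_mix[l] for l in labels], rng)
    archetypes: list[str] = []
    for lab, k in zip(labels, counts):
        archetypes.extend([lab] * k)
    # B-responsive decoys replace trailing background features
    n_b = min(cfg.n_b_responsive, archetypes.count("null"))
    replaced = 0
    for i in range(len(archetypes) - 1, -1, -1):
        if replaced == n_b:
            break
        if archetypes[i] == "null":
            archetypes[i] = "b_responsive"
            replaced += 1

    if cfg.cis_per_line_proportional:
        line_probs = seg_lengths / seg_lengths.sum()
    else:
        line_probs = np.full(len(segments), 1.0 / len(segments))

    loci: list[FeatureLocus] = []
    truth_rows = []
    baselines = _sample_baselines(cfg, len(archetypes), rng)
    for idx, (arch, base) in enumerate(zip(archetypes, baselines)):
        fid = f"Cluster_{idx + 1:05d}"
        if arch in CIS_ARCHETYPES:
            line = line_ids[int(rng.choice(len(line_ids), p=line_probs))]
            seg = seg_by_line[line]
            start = int(rng.integers(seg.interval_start, seg.interval_end - 200))
            context = "cis"
        else:
            line = line_ids[int(rng.integers(len(line_ids)))]
            chrom_i = int(rng.integers(10)) + 1
            start = int(rng.integers(1, _TRANS_REGION_END - 200))
            seg = None
            context = "trans"
        chrom = seg.chrom if seg is not None else f"chr{chrom_i}"
        loci.append(FeatureLocus(fid, chrom, start, start + int(rng.integers(80, 200))))
        truth_rows.append((fid, arch, context, line, base))
    truth = pd.DataFrame(
        truth_rows, columns=["feature_id", "archetype", "context", "line_id", "baseline_rpm"]
    )

    genotypes = _genotype_table(cfg, line_ids)
    sheet_rows = []
    sdlog = math.sqrt(math.log(1 + cfg.lib_size_cv**2))
    meanlog = math.log(cfg.lib_size_mean) - sdlog**2 / 2
    for g in genotypes:
        for r in range(1, cfg.replicates + 1):
            lib = int(rng.lognormal(meanlog, sdlog))
            sheet_rows.append((f"{g}_r{r}", g, r, 1, lib))
    sheet = pd.DataFrame(
        sheet_rows, columns=["sample_id", "genotype_id", "replicate", "include_flag", "library_size"]
    )
    return Design(segments, loci, genotypes, sheet, truth)


def _apportion(n: int, props: Sequence[float], rng: np.random.Generator) -> list[int]:
    """Largest-remainder apportionment of n features over archetype proportions."""
    raw = np.asarray(props) * n
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(raw - base))
    for i in range(rem):
        base[order[i]] += 1
    return base.tolist()


def _sample_baselines(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    low = rng.random(n) < cfg.low_fraction
    out = np.where(
        low,
        rng.lognormal(cfg.low_meanlog, cfg.low_sdlog, n),
        rng.lognormal(cfg.baseline_meanlog, cfg.baseline_sdlog, n),
    )
    return out


def archetype_ratio(
    archetype: str,
    genotype: GenotypeDesign,
    line_id: str,
    effect_increase: float,
    b_effect: float,
) -> float:
    """Closed-form expected RPM ratio of a feature in a genotype vs its background euploid.

    d is the feature's home-segment dosage, b the background ploidy.  Whole-
    ploidy genotypes have d == b, so every archetype ratio is 1 there: the
    joint scaling of per-cell expression with transcriptome size cancels under
    RPM normalisation.
    """
    d = genotype.dosage_of(line_id)
    b = genotype.background_ploidy
    varied = d != b
    if archetype in ("direct_dosage", "positive_trans"):
        return d / b
    if archetype in ("negative_dosage", "inverse_trans"):
        return b / d if d > 0 else 0.0
    if archetype == "compensation" or archetype == "null":
        return 1.0
    if archetype == "increased":
        return math.exp(effect_increase) if varied else 1.0
    if archetype == "decreased":
        return math.exp(-effect_increase) if varied else 1.0
    if archetype == "mixed":
        # dosage effect on the diploid background, inverse on the haploid one
        if not varied:
            return 1.0
        return d / b if genotype.background_ploidy == 2 else b / d
    if archetype == "b_responsive":
        return math.exp(b_effect) if genotype.b_count > 0 else 1.0
    raise ValueError(f"unknown archetype {archetype!r}")


def expected_rpm_table(cfg: SimConfig, design: Design) -> pd.DataFrame:
    """Per-feature per-genotype expected mean RPM (the generator's closed form)."""
    genos = list(design.genotypes)
    out = np.empty((len(design.truth), len(genos)))
    for j, g in enumerate(genos):
        gd = design.genotypes[g]
        for i, row in enumerate(design.truth.itertuples()):
            out[i, j] = row.baseline_rpm * archetype_ratio(
                row.archetype, gd, row.line_id, cfg.effect_increase, cfg.b_effect
            )
    return pd.DataFrame(out, index=design.truth["feature_id"], columns=genos)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.clip(mean, 1e-12, None)
    if dispersion < 1e-12:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    return rng.negative_binomial(r, r / (r + mean))


def simulate_counts(
    cfg: SimConfig, design: Design, rng: np.random.Generator | None = None
) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw the miRNA count matrix; returns (CountMatrix, expected RPM table).

    count ~ NB(expected_rpm * library_size / 1e6, dispersion); library sizes
    are the sample sheet's external totals (the feature matrix is a small
    fraction of mapped reads, as for miRNA clusters in an sRNA library).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    expected = expected_rpm_table(cfg, design)
    cols = {}
    for row in design.sample_sheet.itertuples():
        mean = expected[row.genotype_id].values * (row.library_size / 1e6)
        cols[row.sample_id] = _nb_draw(rng, mean, cfg.dispersion)
    counts = pd.DataFrame(cols, index=expected.index)
    return CountMatrix(counts, design.sample_genotype), expected


def simulate_targets(
    cfg: SimConfig,
    design: Design,
    mirna_expected: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate target-gene counts coupled to miRNA expression, plus the interaction table.

    A coupled target's per-genotype mean is baseline * (miRNA mean / miRNA
    baseline)^(s*gamma) with sign s in {-1,+1}; uncoupled decoy targets carry
    interaction records but no dependence.  Sources are assigned at random to
    prediction, degradome, or both; a few inhibition-mode and weak-prediction
    rows are included to exercise input filtering.

    Returns (gene counts, gene expected RPM, gene loci, interaction table,
    interaction truth).  Gene loci are placed in the region below every
    segment, so every simulated gene is trans to every line.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    genos = list(mirna_expected.columns)
    truth = design.truth.set_index("feature_id")
    responsive = truth.index[
        truth["archetype"].isin(
            ["direct_dosage", "negative_dosage", "positive_trans", "inverse_trans", "increased", "decreased"]
        )
    ].tolist()
    all_mirnas = truth.index.tolist()

    n_coupled = int(round(cfg.coupling_fraction_coupled * cfg.n_genes))
    gene_ids = [f"Gene_{i + 1:05d}" for i in range(cfg.n_genes)]
    baselines = rng.lognormal(cfg.gene_baseline_meanlog, cfg.baseline_sdlog, cfg.n_genes)

    gene_expected = np.empty((cfg.n_genes, len(genos)))
    inter_rows = []
    truth_rows = []
    for i, gid in enumerate(gene_ids):
        coupled = i < n_coupled and responsive
        if coupled:
            mid = responsive[int(rng.integers(len(responsive)))]
            sign = -1 if rng.random() < cfg.coupling_fraction_negative else 1
            ratio = (
                mirna_expected.loc[mid].values / truth.loc[mid, "baseline_rpm"]
            ) ** (sign * cfg.coupling_exponent)
            gene_expected[i] = baselines[i] * ratio
        else:
            mid = all_mirnas[int(rng.integers(len(all_mirnas)))]
            sign = 0
            gene_expected[i] = baselines[i]
        sources = (("prediction",), ("degradome",), ("prediction", "degradome"))[
            int(rng.integers(3))
        ]
        score = round(float(rng.uniform(0, 3)), 2)
        for src in sources:
            inter_rows.append((mid, gid, src, "cleavage", score if src == "prediction" else ""))
        truth_rows.append((mid, gid, bool(coupled), sign, cfg.coupling_exponent, "+".join(sources)))

    # rows the loader must drop: inhibition mode and weak predictions
    for j in range(3):
        mid = all_mirnas[int(rng.integers(len(all_mirnas)))]
        inter_rows.append((mid, f"Gene_inh{j}", "prediction", "inhibition", 1.0))
        inter_rows.append((mid, f"Gene_weak{j}", "prediction", "cleavage", round(3.5 + j, 2)))

    interactions = pd.DataFrame(
        inter_rows, columns=["mirna_id", "target_id", "source", "mode", "expectation_score"]
    )
    interaction_truth = pd.DataFrame(
        truth_rows, columns=["mirna_id", "target_id", "coupled", "sign", "exponent", "sources"]
    )
    expected = pd.DataFrame(gene_expected, index=gene_ids, columns=genos)

    gene_loci = []
    for gid in gene_ids:
        chrom = f"chr{int(rng.integers(10)) + 1}"
        start = int(rng.integers(1, _TRANS_REGION_END - 5000))
        gene_loci.append(FeatureLocus(gid, chrom, start, start + int(rng.integers(500, 5000)), "gene"))

    cols = {}
    for row in design.sample_sheet.itertuples():
        mean = expected[row.genotype_id].values * (row.library_size / 1e6)
        cols[row.sample_id] = _nb_draw(rng, mean, cfg.dispersion)
    gene_counts = CountMatrix(pd.DataFrame(cols, index=expected.index), design.sample_genotype)
    return gene_counts, expected, gene_loci, interactions, interaction_truth


def simulate_study(cfg: SimConfig) -> SimulatedStudy:
    """Run the full generator under one seed: design, miRNA counts, targets."""
    rng = np.random.default_rng(cfg.seed)
    design = simulate_design(cfg, rng)
    mirna_counts, mirna_expected = simulate_counts(cfg, design, rng)
    gene_counts, gene_expected, gene_loci, interactions, itruth = simulate_targets(
        cfg, design, mirna_expected, rng
    )
    return SimulatedStudy(
        cfg, design, mirna_counts, mirna_expected, gene_counts, gene_expected,
        gene_loci, interactions, itruth,
    )


def standard_comparisons(design: Design) -> list[ComparisonSpec]:
    """The study's contrasts: per line 1D/2D, 3D/2D, 4D/2D, 4D/3D, h2D/h1D;
    ploidy 1X/2X, 3X/2X, 4X/2X, 4X/3X; B control 1B/0B."""
    cmps: list[ComparisonSpec] = []
    lines = sorted({s.line_id for s in design.segments})
    for line in lines:
        cmps.append(
            ComparisonSpec(f"{line}:1D/2D", (f"{line}_1D",), ("2D",), (1, 2), "diploid_aneuploid", line)
        )
        cmps.append(
            ComparisonSpec(f"{line}:3D/2D", (f"{line}_3D",), ("2D",), (3, 2), "diploid_aneuploid", line)
        )
        cmps.append(
            ComparisonSpec(f"{line}:4D/2D", (f"{line}_4D",), ("2D",), (4, 2), "diploid_aneuploid", line)
        )
        cmps.append(
            ComparisonSpec(
                f"{line}:4D/3D", (f"{line}_4D",), (f"{line}_3D",), (4, 3), "diploid_aneuploid", line
            )
        )
        cmps.append(
            ComparisonSpec(
                f"{line}:h2D/h1D", (f"{line}_h2D",), ("h1D",), (2, 1), "haploid_aneuploid", line
            )
        )
    for name, de, dc in (("1X/2X", 1, 2), ("3X/2X", 3, 2), ("4X/2X", 4, 2), ("4X/3X", 4, 3)):
        cmps.append(
            ComparisonSpec(name, (f"{de}X",), (f"{dc}X",), (de, dc), "ploidy")
        )
    cmps.append(ComparisonSpec("1B/0B", ("1B",), ("0B",), (2, 2), "b_control"))
    return cmps


def classification_recovery(
    truth: pd.DataFrame,
    cis_calls: pd.DataFrame,
    trans_calls: pd.DataFrame,
) -> pd.DataFrame:
    """Per-archetype recovery of dosage-response calls against generator truth.

    A feature is evaluated against the call made for its home line.  The
    denominator is the classifiable set: cis features with any evidence, and
    trans features meeting the classifier's eligibility rule (an ineligible
    trans feature is reported 'unclassified' and is not a classification
    error, mirroring the restriction of the trans typology to features
    differentially expressed in nearly all of a line's comparisons).
    Returns a table of archetype, n_classifiable, n_correct, recovery.
    """
    rows = []
    calls = pd.concat([cis_calls, trans_calls], ignore_index=True) if len(cis_calls) or len(trans_calls) else pd.DataFrame(columns=["feature_id", "line_id", "label"])
    merged = truth.merge(
        calls, left_on=["feature_id", "line_id"], right_on=["feature_id", "line_id"], how="left"
    )
    for arch, grp in merged.groupby("archetype"):
        if arch in ("null", "b_responsive"):
            continue
        classified = grp[grp["label"].notna() & (grp["label"] != "unclassified")]
        n_cls = len(classified)
        n_ok = int((classified["label"] == arch).sum())
        rows.append((arch, n_cls, n_ok, n_ok / n_cls if n_cls else float("nan")))
    return pd.DataFrame(rows, columns=["archetype", "n_classifiable", "n_correct", "recovery"])


def infer_comparisons(genotypes: Mapping[str, GenotypeDesign]) -> list[ComparisonSpec]:
    """Reconstruct the standard contrasts from genotype designs alone.

    Works for any design following the generator's structure: per-line
    aneuploids against the euploid background control, a ploidy series of
    euploids at ploidy 1-4, and a B-chromosome pair.  Conventionally named
    controls ('2D', 'h1D', ploidy '<p>X', '0B') are preferred when several
    euploids share a karyotype.
    """

    def euploid_control(ploidy: int, prefer: str) -> str | None:
        cands = [
            g.genotype_id
            for g in genotypes.values()
            if g.is_euploid and g.background_ploidy == ploidy and g.b_count == 0
        ]
        if prefer in cands:
            return prefer
        return cands[0] if cands else None

    cmps: list[ComparisonSpec] = []
    lines = sorted({l for g in genotypes.values() for l in g.segment_dosages})
    ctl_2d = euploid_control(2, "2D")
    ctl_h1d = euploid_control(1, "h1D")
    for line in lines:
        by_dose_dip = {
            g.segment_dosages[line]: g.genotype_id
            for g in genotypes.values()
            if line in g.segment_dosages and g.background_ploidy == 2
        }
        for d in (1, 3, 4):
            if d in by_dose_dip and ctl_2d:
                cmps.append(
                    ComparisonSpec(
                        f"{line}:{d}D/2D", (by_dose_dip[d],), (ctl_2d,), (d, 2),
                        "diploid_aneuploid", line,
                    )
                )
        if 4 in by_dose_dip and 3 in by_dose_dip:
            cmps.append(
                ComparisonSpec(
                    f"{line}:4D/3D", (by_dose_dip[4],), (by_dose_dip[3],), (4, 3),
                    "diploid_aneuploid", line,
                )
            )
        hap = [
            g.genotype_id
            for g in genotypes.values()
            if g.segment_dosages.get(line) == 2 and g.background_ploidy == 1
        ]
        if hap and ctl_h1d:
            cmps.append(
                ComparisonSpec(
                    f"{line}:h2D/h1D", (hap[0],), (ctl_h1d,), (2, 1),
                    "haploid_aneuploid", line,
                )
            )
    ctl_2x = euploid_control(2, "2X")
    ploidy_ids = {p: euploid_control(p, f"{p}X") for p in (1, 3, 4)}
    if ctl_2x:
        for p, gid in ploidy_ids.items():
            if gid:
                cmps.append(
                    ComparisonSpec(f"{p}X/2X", (gid,), (ctl_2x,), (p, 2), "ploidy")
                )
    if ploidy_ids.get(4) and ploidy_ids.get(3):
        cmps.append(
            ComparisonSpec("4X/3X", (ploidy_ids[4],), (ploidy_ids[3],), (4, 3), "ploidy")
        )
    b_pos = [g.genotype_id for g in genotypes.values() if g.b_count > 0 and g.is_euploid]
    b_neg = euploid_control(2, "0B")
    if b_pos and b_neg:
        cmps.append(ComparisonSpec("1B/0B", (b_pos[0],), (b_neg,), (2, 2), "b_control"))
    return cmps


def write_study(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Write the study as the TSV/BED dialects the readers accept."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mirna_counts": outdir / "mirna_counts.tsv",
        "gene_counts": outdir / "gene_counts.tsv",
        "sample_sheet": outdir / "sample_sheet.tsv",
        "segments": outdir / "segments.tsv",
        "loci": outdir / "loci.bed",
        "gene_loci": outdir / "genes.bed",
        "genotypes": outdir / "genotypes.tsv",
        "interactions": outdir / "interactions.tsv",
        "truth": outdir / "feature_truth.tsv",
        "interaction_truth": outdir / "interaction_truth.tsv",
    }
    study.mirna_counts.counts.rename_axis("feature_id").to_csv(paths["mirna_counts"], sep="\t")
    study.gene_counts.counts.rename_axis("feature_id").to_csv(paths["gene_counts"], sep="\t")
    study.design.sample_sheet.to_csv(paths["sample_sheet"], sep="\t", index=False)
    pd.DataFrame(
        [
            (s.line_id, s.chrom, s.interval_start, s.interval_end, s.kind)
            for s in study.design.segments
        ],
        columns=["line_id", "chrom", "interval_start", "interval_end", "kind"],
    ).to_csv(paths["segments"], sep="\t", index=False)
    write_loci_bed(study.design.loci, paths["loci"])
    write_loci_bed(study.gene_loci, paths["gene_loci"])
    write_genotype_designs(study.design.genotypes, paths["genotypes"])
    study.interactions.to_csv(paths["interactions"], sep="\t", index=False)
    study.design.truth.to_csv(paths["truth"], sep="\t", index=False)
    study.interaction_truth.to_csv(paths["interaction_truth"], sep="\t", index=False)
    return paths
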