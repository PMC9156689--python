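"""Pipeline orchestration and report tables.

`run_pipeline` executes the full analysis — replicate QC, per-comparison
expression filtering, NB exact-test differential expression, B-chromosome
control exclusion, cis/trans dosage-response classification, trans-ratio
trend summaries with k-means clustering, and miRNA-target correlation — and
emits per-comparison TSVs plus a run-level summary.  The scatter-plot (MA)
tables mirror the DE calls: magenta = significant up, green = significant
down, black otherwise, with reference lines at the comparison's analytic
direct and inverse fold changes.  The report is a pure function of the
inputs and configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import annotation, diffexpr, dosage, preprocess, targets

__all__ = ["RunConfig", "PipelineError", "PipelineResult", "ma_table", "run_pipeline"]


@dataclass
class RunConfig:
    counts: Path
    sample_sheet: Path
    segments: Path
    loci: Path
    genotypes: Path
    comparisons: Sequence[dosage.ComparisonSpec]
    gene_counts: Path | None = None
    gene_loci: Path | None = None
    interactions: Path | None = None
    alpha: float = 0.05
    filter_threshold: float = 0.5
    dispersion_mode: str = "common"
    compensation_band: float = 1.25
    seed: int = 0
    outdir: Path | None = None

    def provenance(self) -> dict:
        return {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in self.__dict__.items()
            if k != "comparisons"
        } | {"comparisons": [c.name for c in self.comparisons]}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineResult:
    de_tables: dict[str, pd.DataFrame]
    ratio_tables: dict[str, pd.Series]
    kept_features: dict[str, pd.Index]
    dem_counts: pd.DataFrame
    qc: dict[str, preprocess.QCReport]
    labels: dict[str, pd.DataFrame]            # line_id -> cis/trans labels
    b_excluded: list[str]
    trend: pd.DataFrame
    cis_calls: pd.DataFrame
    trans_calls: pd.DataFrame
    correlations: pd.DataFrame
    summary: pd.DataFrame
    config: RunConfig | None = None


def ma_table(de: pd.DataFrame, cmp: dosage.ComparisonSpec) -> pd.DataFrame:
    """Scatter-table of one comparison's DE results.

    x = logFC, y = log2 mean RPM; colour magenta iff fdr < 0.05 and logFC > 0,
    green iff fdr < 0.05 and logFC < 0, else black.  Reference lines are the
    comparison's direct and inverse reference FCs plus no-change (1.0).
    """
    if cmp.series == "b_control":
        lines = [1.0]  # no dosage reference for the B pair
    else:
        ref = dosage.expected_ratios(cmp)
        lines = sorted({ref.direct_fc, ref.inverse_fc, 1.0})
    colour = np.where(
        (de["fdr"] < 0.05) & (de["logFC"] > 0),
        "magenta",
        np.where((de["fdr"] < 0.05) & (de["logFC"] < 0), "green", "black"),
    )
    out = pd.DataFrame(
        {
            "feature_id": de.index,
            "x_logfc": de["logFC"].values,
            "y_log_mean": de["log_mean"].values,
            "color_class": colour,
            "reference_lines": ";".join(f"{v:g}" for v in lines),
        }
    )
    return out


def _evidence_for(
    feature: str,
    line: str,
    comparisons: Sequence[dosage.ComparisonSpec],
    de_tables: Mapping[str, pd.DataFrame],
    ratio_tables: Mapping[str, pd.Series],
) -> list[dosage.ComparisonEvidence]:
    """Collect per-comparison evidence for one feature over a line's dosage series.

    Only comparisons against the background euploid control enter the
    typology (the 4D/3D progressive contrast is reported but not classified).
    """
    evs = []
    for cmp in comparisons:
        if cmp.line_id != line:
            continue
        if cmp.series not in ("diploid_aneuploid", "haploid_aneuploid"):
            continue
        background = 2 if cmp.series == "diploid_aneuploid" else 1
        if cmp.cis_dosage_pair[1] != background:
            continue
        de = de_tables.get(cmp.name)
        if de is None or feature not in de.index:
            continue
        fc = ratio_tables[cmp.name].get(feature, float("nan"))
        row = de.loc[feature]
        evs.append(
            dosage.ComparisonEvidence(
                cmp.name,
                cmp.cis_dosage_pair[0],
                cmp.cis_dosage_pair[1],
                cmp.series,
                float(row["logFC"]),
                float(row["fdr"]),
                float(fc),
            )
        )
    return evs


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute qc -> filter -> de -> exclusion -> classify -> trend -> correlate.

    Any stage failure raises PipelineError naming the stage.  When
    cfg.outdir is set, per-comparison and summary TSVs are written there.
    """
    stage = "read_inputs"
    try:
        cm = preprocess.read_counts(cfg.counts, cfg.sample_sheet)
        sheet = pd.read_csv(cfg.sample_sheet, sep="\t")
        lib_sizes = None
        if "library_size" in sheet.columns:
            lib_sizes = dict(zip(sheet["sample_id"], sheet["library_size"]))
        segments = annotation.read_segments(cfg.segments)
        loci = annotation.read_loci(cfg.loci)
        designs = annotation.read_genotype_designs(cfg.genotypes)
    except Exception as exc:  # noqa: BLE001 - stage attribution contract
        raise PipelineError(stage, str(exc)) from exc

    try:
        stage = "normalize"
        nm = preprocess.rpm_normalize(cm, lib_sizes)

        stage = "partition"
        labels = {
            seg.line_id: annotation.partition_cis_trans(loci, seg) for seg in segments
        }

        stage = "qc"
        qc: dict[str, preprocess.QCReport] = {}
        for cmp in cfg.comparisons:
            samples = [s for g in cmp.experimental + cmp.control for s in nm.samples_of(g)]
            if len(samples) >= 3:
                qc[cmp.name] = preprocess.replicate_qc_pca(nm, samples)

        stage = "filter+de"
        de_tables: dict[str, pd.DataFrame] = {}
        ratio_tables: dict[str, pd.Series] = {}
        kept_features: dict[str, pd.Index] = {}
        for cmp in cfg.comparisons:
            exp_s = [s for g in cmp.experimental for s in nm.samples_of(g)]
            ctl_s = [s for g in cmp.control for s in nm.samples_of(g)]
            kept = preprocess.filter_low_expression(nm, exp_s, ctl_s, cfg.filter_threshold)
            kept_features[cmp.name] = kept
            ratio_tables[cmp.name] = dosage.compute_ratios(nm, cmp, kept)
            if cmp.name.endswith("4X/3X"):
                # different genetic backgrounds: t test on log2 ratios to the shared 2X
                de_tables[cmp.name] = _ratio_ttest_table(nm, cmp, cfg, kept)
            else:
                de_tables[cmp.name] = diffexpr.de_test(
                    cm, nm, exp_s, ctl_s, kept,
                    dispersion_mode=cfg.dispersion_mode, alpha=cfg.alpha,
                )

        stage = "exclusion"
        b_excluded: list[str] = []
        for cmp in cfg.comparisons:
            if cmp.series == "b_control" and cmp.name in de_tables:
                dems, _ = diffexpr.call_dems(de_tables[cmp.name], cfg.alpha)
                b_excluded = list(dems.index)

        stage = "dem_counts"
        dem_rows = []
        for cmp in cfg.comparisons:
            de = de_tables[cmp.name]
            usable = dosage.apply_control_exclusion(de.index, b_excluded) \
                if cmp.series != "b_control" else de.index
            dems, counts = diffexpr.call_dems(de.loc[usable], cfg.alpha)
            cis_n = trans_n = 0
            if cmp.line_id is not None:
                lab = labels[cmp.line_id].set_index("feature_id")["label"]
                in_lab = dems.index.intersection(lab.index)
                cis_n = int((lab.loc[in_lab] == "cis").sum())
                trans_n = int((lab.loc[in_lab] == "trans").sum())
            dem_rows.append(
                (cmp.name, cmp.series, cmp.line_id, counts["total"], counts["up"],
                 counts["down"], cis_n, trans_n, len(de))
            )
        dem_counts = pd.DataFrame(
            dem_rows,
            columns=["comparison", "series", "line_id", "dems", "up", "down",
                     "cis_dems", "trans_dems", "tested"],
        )

        stage = "trend"
        trend = _trend_table(cfg, labels, ratio_tables, b_excluded)

        stage = "classify"
        cis_calls, trans_calls = _classify_all(
            cfg, labels, de_tables, ratio_tables, b_excluded
        )

        stage = "correlate"
        correlations = _correlations(cfg, nm, segments, labels, lib_sizes)

        stage = "summary"
        summary = dem_counts.merge(
            trend[["comparison", "median_trans_fc", "cluster"]], on="comparison", how="left"
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    result = PipelineResult(
        de_tables, ratio_tables, kept_features, dem_counts, qc, labels,
        b_excluded, trend, cis_calls, trans_calls, correlations, summary, cfg,
    )
    if cfg.outdir is not None:
        _write_outputs(result, cfg)
    return result


def _ratio_ttest_table(
    nm: preprocess.NormalizedMatrix,
    cmp: dosage.ComparisonSpec,
    cfg: RunConfig,
    kept: pd.Index,
) -> pd.DataFrame:
    ref = [s for s in nm.rpm.columns if nm.sample_genotype.get(s) == "2X"]
    exp_s = [s for g in cmp.experimental for s in nm.samples_of(g)]
    ctl_s = [s for g in cmp.control for s in nm.samples_of(g)]
    if not ref:
        ref = ctl_s  # no shared euploid reference: ratios to the control group
    ra = diffexpr.replicate_log_ratios(nm, exp_s, ref, kept, pseudocount=0.5)
    rb = diffexpr.replicate_log_ratios(nm, ctl_s, ref, kept, pseudocount=0.5)
    pvals = np.array(
        [diffexpr.ratio_t_test(ra.loc[f].values, rb.loc[f].values)[1] for f in kept]
    )
    mean_exp = nm.rpm.loc[kept, exp_s].mean(axis=1)
    mean_ctl = nm.rpm.loc[kept, ctl_s].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        logfc = np.log2(mean_exp.values / mean_ctl.values)
    fdr = diffexpr.bh_adjust(pvals)
    return pd.DataFrame(
        {
            "feature_id": kept,
            "logFC": logfc,
            "log_mean": np.log2(nm.rpm.loc[kept, exp_s + ctl_s].mean(axis=1).values),
            "p": pvals,
            "fdr": fdr,
            "direction": np.where(
                fdr < cfg.alpha, np.where(logfc > 0, "up", "down"), "ns"
            ),
        }
    ).set_index("feature_id")


def _trend_table(cfg, labels, ratio_tables, b_excluded) -> pd.DataFrame:
    rows = []
    for cmp in cfg.comparisons:
        if cmp.line_id is None:
            continue
        lab = labels[cmp.line_id]
        trans_feats = dosage.apply_control_exclusion(
            lab.loc[lab["label"] == "trans", "feature_id"], b_excluded
        )
        ratios = ratio_tables[cmp.name]
        defined = ratios.reindex(trans_feats).dropna()
        med = float(defined.median()) if len(defined) else float("nan")
        d_e, d_c = cmp.cis_dosage_pair
        rows.append((cmp.name, cmp.series, cmp.line_id, f"{d_e}:{d_c}", med))
    trend = pd.DataFrame(
        rows, columns=["comparison", "series", "line_id", "dosage", "median_trans_fc"]
    )
    trend["cluster"] = -1
    for series, grp in trend.groupby("series"):
        vals = grp["median_trans_fc"].dropna()
        if len(vals) >= 2 and vals.nunique() >= 2:
            lab, _ = dosage.kmeans_1d(vals.values, k=2)
            trend.loc[vals.index, "cluster"] = lab
    return trend


def _classify_all(cfg, labels, de_tables, ratio_tables, b_excluded):
    cis_rows, trans_rows = [], []
    for line, lab in labels.items():
        lab = lab.set_index("feature_id")["label"]
        usable = dosage.apply_control_exclusion(lab.index, b_excluded)
        for feat in usable:
            evs = _evidence_for(feat, line, cfg.comparisons, de_tables, ratio_tables)
            if not evs:
                continue
            if lab.loc[feat] == "cis":
                call = dosage.classify_cis_response(
                    feat, line, evs, cfg.alpha, cfg.compensation_band
                )
                cis_rows.append(_call_row(call))
            else:
                if not any(e.fdr < cfg.alpha for e in evs):
                    continue
                call = dosage.classify_trans_response(feat, line, evs, cfg.alpha)
                trans_rows.append(_call_row(call))
    cols = ["feature_id", "line_id", "context", "label", "n_comparisons", "n_significant"]
    return (
        pd.DataFrame(cis_rows, columns=cols),
        pd.DataFrame(trans_rows, columns=cols),
    )


def _call_row(call: dosage.ResponseCall):
    return (
        call.feature_id,
        call.line_id,
        call.context,
        call.label,
        len(call.evidence),
        sum(1 for e in call.evidence if e.fdr < 0.05),
    )


def _correlations(cfg, nm, segments, labels, lib_sizes) -> pd.DataFrame:
    cols = ["mirna_id", "target_id", "sources", "scope", "r", "p", "n",
            "significant", "exclusion_reason"]
    if cfg.interactions is None or cfg.gene_counts is None:
        return pd.DataFrame(columns=cols)
    records = targets.load_interactions(cfg.interactions)
    gene_cm = preprocess.read_counts(cfg.gene_counts, cfg.sample_sheet)
    gene_nm = preprocess.rpm_normalize(gene_cm, lib_sizes)
    mirna_means = targets.genotype_means(nm.rpm, nm.sample_genotype)
    gene_means = targets.genotype_means(gene_nm.rpm, gene_nm.sample_genotype)

    gene_labels = {}
    if cfg.gene_loci is not None:
        gloci = annotation.read_loci(cfg.gene_loci)
        for seg in segments:
            gl = annotation.partition_cis_trans(gloci, seg)
            gene_labels[seg.line_id] = gl.set_index("feature_id")["label"]

    rows = []
    for rec in records:
        res = targets.correlate_global(rec, mirna_means, gene_means, alpha=cfg.alpha)
        rows.append(_corr_row(rec, res))
        for seg in segments:
            line = seg.line_id
            mlab = labels[line].set_index("feature_id")["label"]
            if rec.mirna_id not in mlab.index or mlab.loc[rec.mirna_id] != "cis":
                continue
            glab = gene_labels.get(line)
            if glab is not None and glab.get(rec.target_id) == "cis":
                continue
            series = [f"{line}_1D", "2D", f"{line}_3D", f"{line}_4D", "h1D", f"{line}_h2D"]
            res = targets.correlate_local(
                rec, line, series, mirna_means, gene_means, alpha=cfg.alpha
            )
            rows.append(_corr_row(rec, res))
    return pd.DataFrame(rows, columns=cols)


def _corr_row(rec, res):
    return (
        rec.mirna_id,
        rec.target_id,
        "+".join(sorted(rec.sources)),
        res.scope,
        res.r,
        res.p,
        res.n,
        res.significant,
        res.exclusion_reason or "",
    )


def _write_outputs(result: PipelineResult, cfg: RunConfig) -> None:
    import json

    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(json.dumps(cfg.provenance(), indent=2, default=str))
    for name, de in result.de_tables.items():
        safe = name.replace("/", "_").replace(":", "_")
        de.to_csv(out / f"de_{safe}.tsv", sep="\t")
        cmp = next(c for c in cfg.comparisons if c.name == name)
        ma_table(de, cmp).to_csv(out / f"ma_{safe}.tsv", sep="\t", index=False)
    result.dem_counts.to_csv(out / "dem_counts.tsv", sep="\t", index=False)
    result.trend.to_csv(out / "trend.tsv", sep="\t", index=False)
    result.cis_calls.to_csv(out / "cis_response_calls.tsv", sep="\t", index=False)
    result.trans_calls.to_csv(out / "trans_response_calls.tsv", sep="\t", index=False)
    result.correlations.to_csv(out / "correlations.tsv", sep="\t", index=False)
    result.summary.to_csv(out / "summary.tsv", sep="\t", index=False)
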