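#!/usr/bin/env python
"""Replicate-level quality control of the simulated study.

For every genotype with >= 3 samples across its comparison set: PCA on
centred RPM with the 2-SD outlier rule, and pairwise Pearson correlation of
replicate profiles.  Writes results/qc_pca.tsv and results/qc_pcc.tsv.
"""

from pathlib import Path

import pandas as pd

from dosagebalance.preprocess import read_counts, replicate_qc_pca, rpm_normalize

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    study = ROOT / "study"
    cm = read_counts(study / "mirna_counts.tsv", study / "sample_sheet.tsv")
    sheet = pd.read_csv(study / "sample_sheet.tsv", sep="\t")
    libs = dict(zip(sheet["sample_id"], sheet["library_size"]))
    nm = rpm_normalize(cm, libs)

    pca_rows, pcc_rows = [], []
    for genotype in sorted(set(cm.sample_genotype.values())):
        samples = cm.samples_of(genotype)
        if len(samples) < 3:
            continue
        rep = replicate_qc_pca(nm, samples)
        for s in samples:
            pca_rows.append(
                (genotype, s, rep.pc_scores.loc[s, "PC1"], rep.pc_scores.loc[s, "PC2"],
                 bool(rep.outlier_flags.get(s, False)))
            )
        pcc = rep.pairwise_pcc.assign(genotype=genotype)
        pcc_rows.append(pcc)

    pca = pd.DataFrame(pca_rows, columns=["genotype", "sample_id", "PC1", "PC2", "outlier"])
    pcc = pd.concat(pcc_rows, ignore_index=True)
    pca.to_csv(ROOT / "qc_pca.tsv", sep="\t", index=False)
    pcc.to_csv(ROOT / "qc_pcc.tsv", sep="\t", index=False)

    n_out = int(pca["outlier"].sum())
    n_flag = int(pcc["flagged"].sum())
    print(f"{len(pca)} samples over {pca['genotype'].nunique()} genotypes: "
          f"{n_out} PCA outliers (2-SD rule), {n_flag}/{len(pcc)} replicate pairs "
          f"not significantly correlated")


if __name__ == "__main__":
    main()
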