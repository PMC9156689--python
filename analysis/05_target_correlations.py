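#!/usr/bin/env python
"""miRNA-target expression correlations and evidence-source intersection.

Summarises the correlation table written by 03: significant global
correlations across all genotypes, local cis-miRNA/trans-target correlations
along single dosage series, exclusions (series too short, constant or
filtered expression), and the intersection of prediction- and
degradome-supported interactions with its sign split.  Scores detected
coupling signs against the generator truth.  Writes
results/correlation_summary.tsv.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    corr = pd.read_csv(ROOT / "run" / "correlations.tsv", sep="\t")
    truth = pd.read_csv(ROOT / "study" / "interaction_truth.tsv", sep="\t")

    rows = []
    for scope, grp in corr.groupby(corr["scope"].str.split(":").str[0]):
        usable = grp[grp["exclusion_reason"].isna() | (grp["exclusion_reason"] == "")]
        sig = usable[usable["significant"] == True]  # noqa: E712
        both = sig[sig["sources"].str.contains(r"\+")]
        rows.append((scope, len(grp), len(usable), len(sig),
                     int((sig["r"] < 0).sum()), len(both), int((both["r"] < 0).sum())))
    summary = pd.DataFrame(rows, columns=[
        "scope", "tested", "usable", "significant", "significant_negative",
        "both_sources_significant", "both_sources_negative"])
    summary.to_csv(ROOT / "correlation_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))

    merged = corr[corr["scope"] == "global"].merge(truth, on=["mirna_id", "target_id"])
    neg = merged[(merged["coupled"]) & (merged["sign"] == -1)]
    if len(neg):
        frac = (neg["r"] < 0).mean()
        print(f"\nnegative couplings with recovered negative R: {frac:.0%} of {len(neg)}")
    decoys = merged[~merged["coupled"]]
    if len(decoys):
        print(f"decoy interactions significant at 0.05: "
              f"{(decoys['significant'] == True).mean():.1%} of {len(decoys)}")


if __name__ == "__main__":
    main()
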