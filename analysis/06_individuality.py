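"""Vocal individuality of snorts and squeals via the nested permuted DFA.

For each call type with enough per-individual data: KMO screening of the
12 features (MSA >= 0.5), PCA (eigenvalue > 1), a descriptive DFA with
individual identity as the grouping factor, and two nested pDFAs — one
with sex and one with location as the restriction factor — reporting the
observed and chance cross-classification and the permutation p-value.

Usage: python analysis/06_individuality.py [--seed 42]
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from zebrarep.features import INDIVIDUALITY_FIELDS
from zebrarep.individuality import dfa, kmo, nested_pdfa, pca_reduce
from zebrarep.workbench import MIN_CALLS_PER_INDIVIDUAL


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--permutations", type=int, default=1000)
    ap.add_argument("--selections", type=int, default=100)
    args = ap.parse_args()

    results = Path("results")
    table = pd.read_csv(results / "02_features.csv")
    report = {}
    rows = []
    for ct in ("snort", "squeal"):
        sub = table[table.call_type == ct]
        ok = sub.groupby("individual_id").call_id.count() >= MIN_CALLS_PER_INDIVIDUAL
        sub = sub[sub.individual_id.isin(ok[ok].index)]
        cols = [c for c in INDIVIDUALITY_FIELDS if sub[c].notna().all()]
        sub = sub.dropna(subset=cols)
        print(f"\n{ct}: {len(sub)} calls from {sub.individual_id.nunique()} "
              f"individuals, {len(cols)} usable features")

        kmo_res = kmo(sub[cols])
        print(f"  KMO overall MSA = {kmo_res.overall_msa:.3f}; "
              f"retained {len(kmo_res.retained)} features")
        pca = pca_reduce(sub[kmo_res.retained])
        print(f"  PCA kept {len(pca.retained_components)} components "
              f"(eigenvalues {np.round(pca.eigenvalues[:4], 2)})")
        model = dfa(pca.scores, sub.individual_id.values,
                    component_names=pca.retained_components)
        top2 = model.percent_variance[:2].sum()
        print(f"  DF1+DF2 carry {top2:.1f}% of discriminative variance")
        model.df_pc_correlation.to_csv(results / f"06_df_pc_corr_{ct}.csv")

        entry = dict(kmo_overall=kmo_res.overall_msa,
                     kmo_retained=kmo_res.retained,
                     pca_components=len(pca.retained_components),
                     df_percent_variance=model.percent_variance.tolist())
        for factor in ("sex", "location"):
            res = nested_pdfa(pca.scores, sub.individual_id.values,
                              sub[factor].values,
                              n_permutations=args.permutations,
                              n_selections=args.selections,
                              seed=args.seed, restriction_name=factor)
            entry[f"pdfa_{factor}"] = dict(
                observed_correct=res.observed_correct,
                expected_correct=res.expected_correct,
                percent_correct=res.percent_correct,
                chance_percent=res.chance_percent,
                p_value=res.p_value)
            rows.append(dict(call_type=ct, restriction=factor,
                             observed=res.observed_correct,
                             expected=res.expected_correct,
                             percent=res.percent_correct,
                             chance=res.chance_percent, p=res.p_value))
            print(f"  pDFA ({factor}): correct {res.percent_correct:.1f}% "
                  f"vs chance {res.chance_percent:.1f}%, p = {res.p_value:.3f}")
        report[ct] = entry

    pd.DataFrame(rows).to_csv(results / "06_pdfa_table.csv", index=False)
    (results / "06_individuality.json").write_text(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
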