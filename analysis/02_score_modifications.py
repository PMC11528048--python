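#!/usr/bin/env python
"""Score rRNA modifications and compare wild type against the mutant.

Reads the profiles written by 01_simulate_study.py, computes MethScore for
every Nm site and PsiScore for every Psi site (3 replicates averaged per
condition), classifies highly modified sites (score > 0.8), runs the
unpaired two-sample Wilcoxon comparison per modification type, and reports
how well the scores recover the planted truth.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from snoridr import SimulationConfig, compare_conditions, score_sites
from snoridr.end_profiles import CleavageProfile, EndCountProfile
from snoridr.mod_scoring import meth_score, norm_u_count, psi_score
from snoridr.synthetic import read_reference_fasta

SIM = Path("results/sim")
OUT = Path("results/scores")
REPLICATES = 3


def load_bonds(path) -> CleavageProfile:
    df = pd.read_csv(path, sep="\t")
    c = np.zeros(len(df) + 1, dtype=np.int64)
    c[df["bond"]] = df["c"]
    return CleavageProfile("ref", c)


def load_ends(path) -> EndCountProfile:
    df = pd.read_csv(path, sep="\t")
    n5 = np.zeros(len(df) + 1, dtype=np.int64)
    n3 = np.zeros(len(df) + 1, dtype=np.int64)
    n5[df["position"]] = df["n5"]
    n3[df["position"]] = df["n3"]
    return EndCountProfile("ref", n5, n3)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig.from_yaml(SIM / "config.yaml")
    ref = read_reference_fasta(SIM / "reference.fasta")
    sites = pd.read_csv(SIM / "sites.tsv", sep="\t")
    truth = {"wt": sites, "mut": pd.read_csv(SIM / "sites_mutant.tsv", sep="\t")}

    meth_reps, psi_reps = {}, {}
    for cond in ("wt", "mut"):
        meth_reps[cond] = []
        psi_reps[cond] = []
        for rep in range(1, REPLICATES + 1):
            bonds = load_bonds(SIM / f"rms_{cond}_rep{rep}.bonds.tsv")
            nm_pos = sites.loc[sites["mod_type"] == "Nm", "position"]
            meth_reps[cond].append(pd.Series({int(p): meth_score(bonds, int(p)).score for p in nm_pos}))
            ends = load_ends(SIM / f"hps_{cond}_rep{rep}.ends.tsv")
            scored = psi_score(norm_u_count(ends, str(ref.seq), offset=cfg.hps_offset))
            psi_reps[cond].append(scored.set_index("position")["score"])

    tables = {}
    for mod, reps in (("Nm", meth_reps), ("Psi", psi_reps)):
        table = score_sites(sites, reps, mod)
        tables[mod] = table
        table.to_csv(OUT / f"scores_{mod.lower()}.tsv", sep="\t", index=False)
        for cond in ("wt", "mut"):
            sub = table[table["condition"] == cond].merge(
                truth[cond][truth[cond]["mod_type"] == mod], on=["position", "mod_type"])
            mae = (sub["score"] - sub["true_fraction"]).abs().mean()
            n_high = int(sub["highly_modified"].sum())
            print(f"{mod} {cond}: {len(sub)} sites, MAE vs truth {mae:.3f}, "
                  f"{n_high} highly modified (>0.8)")

    rows = []
    for mod, table in tables.items():
        wide = table.pivot(index="position", columns="condition", values="score")
        res = compare_conditions(wide["wt"], wide["mut"])
        rows.append({"mod_type": mod, "n_sites": res.summary_a.n,
                     "median_wt": res.summary_a.median, "median_mut": res.summary_b.median,
                     "W": res.statistic, "pvalue": res.pvalue, "stars": res.stars})
        print(f"{mod}: WT median {res.summary_a.median:.2f} vs mutant {res.summary_b.median:.2f}, "
              f"Wilcoxon p = {res.pvalue:.2e} {res.stars}")
    pd.DataFrame(rows).to_csv(OUT / "wt_vs_mutant.tsv", sep="\t", index=False)
    print(f"\nScore tables and comparison written to {OUT}/")


if __name__ == "__main__":
    main()
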