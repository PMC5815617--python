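#!/usr/bin/env python
"""Accuracy tables and pick×measure curves for the synthetic cohort.

Produces, under results/:
  * accuracy_nested_ips.tsv — overall ("All") and per-terrain range
    ("Ind.") accuracy of the best 2..6-signal in-pylon classifiers under
    every evaluation protocol;
  * curve_<method>_pick-<protocol>.tsv — accuracy versus number of signals
    for SFS/SBS rankings picked on LOOCV, Test 1 or Test 2 and measured on
    all three (the pick×measure grid);
  * accuracy_summary.tsv — headline numbers for the informative-signal,
    in-pylon-only and full-inventory classifiers.
"""

import argparse
from pathlib import Path

import pandas as pd

from crossslope.evaluation import evaluate_on_test, loocv
from crossslope.features import build_feature_matrix, restrict_to_signals
from crossslope.gait_data import Dataset, SignalInventory
from crossslope.preprocess import preprocess_trial
from crossslope.selection import EvalProtocol, accuracy_vs_count_curve, sbs, sfs
from crossslope.synthetic import generate_dataset, study_cohort

ROOT = Path(__file__).resolve().parents[1]
INFORMATIVE = ["ankle_inversion_angvel", "foot_vert_velocity", "foot_ml_angvel"]


def evaluate(train, test_or_loocv, signals):
    if isinstance(test_or_loocv, str):
        _, rep = loocv(train, signals=signals)
    else:
        _, rep = evaluate_on_test(train, test_or_loocv, signals=signals)
    return rep


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    inv = SignalInventory.full_with_ips()
    matrices = {}
    for role, conf in study_cohort(args.seed).items():
        ds = generate_dataset(conf, role=role)
        ds = Dataset([preprocess_trial(t) for t in ds.trials], role=role)
        matrices[role] = build_feature_matrix(ds, inv)
    train = matrices["training"]
    protocols = {"loocv": "loocv", "test1": matrices["test1"], "test2": matrices["test2"]}

    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    # --- nested in-pylon classifiers (2..6 signals picked by SFS on LOOCV)
    ips = [n for n in inv.names if n.startswith("ips_")]
    ips_train = restrict_to_signals(train, ips)
    ranking = sfs(ips_train, EvalProtocol("loocv_training")).ranking
    rows = []
    for k in range(2, len(ranking) + 1):
        for proto, target in protocols.items():
            rep = evaluate(train, target, ranking[:k])
            rows.append(
                {
                    "n_signals": k,
                    "signals": ",".join(ranking[:k]),
                    "evaluation": proto,
                    "all": round(rep.overall, 4),
                    "ind_min": round(rep.per_class_range[0], 4),
                    "ind_max": round(rep.per_class_range[1], 4),
                }
            )
    pd.DataFrame(rows).to_csv(results / "accuracy_nested_ips.tsv", sep="\t", index=False)
    print(f"nested IPS classifiers -> accuracy_nested_ips.tsv "
          f"(best 6-signal LOOCV accuracy "
          f"{[r['all'] for r in rows if r['n_signals'] == 6 and r['evaluation'] == 'loocv'][0]:.3f})")

    # --- pick×measure curves on the in-pylon inventory
    for pick, target in protocols.items():
        protocol = (
            EvalProtocol("loocv_training")
            if pick == "loocv"
            else EvalProtocol("fixed_test",
                              pick_matrix=restrict_to_signals(target, ips))
        )
        for method, run in (("sfs", sfs), ("sbs", sbs)):
            trace = run(ips_train, protocol)
            curve = accuracy_vs_count_curve(
                trace, ips_train,
                {p: (t if isinstance(t, str) else restrict_to_signals(t, ips))
                 for p, t in protocols.items()},
            )
            out = results / f"curve_{method}_pick-{pick}.tsv"
            curve.to_csv(out, sep="\t", index=False)
    print("pick x measure curves -> curve_<method>_pick-<protocol>.tsv")

    # --- headline summary
    summary = []
    for name, signals in (
        ("informative_signals", INFORMATIVE),
        ("ips_only", ips),
        ("full_inventory", None),
    ):
        for proto, target in protocols.items():
            rep = evaluate(train, target, signals)
            summary.append(
                {
                    "classifier": name,
                    "evaluation": proto,
                    "all": round(rep.overall, 4),
                    "ind_min": round(rep.per_class_range[0], 4),
                    "ind_max": round(rep.per_class_range[1], 4),
                    "n_windows": rep.n_windows,
                }
            )
    df = pd.DataFrame(summary)
    df.to_csv(results / "accuracy_summary.tsv", sep="\t", index=False)
    print(df.to_string(index=False))


if __name__ == "__main__":
    main()
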