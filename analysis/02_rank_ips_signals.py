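#!/usr/bin/env python
"""Rank the six in-pylon sensor signals by SFS and SBS.

For each evaluation protocol (leave-one-trial-out on the training data,
or accuracy on a fixed test set) both selection methods produce a full
ranking of the in-pylon channels with the classifier accuracy reached at
each step. Rankings are written to results/ranking_ips_<method>_<pick>.tsv.
"""

import argparse
from pathlib import Path

from crossslope.features import build_feature_matrix, restrict_to_signals
from crossslope.gait_data import Dataset, SignalInventory
from crossslope.preprocess import preprocess_trial
from crossslope.selection import EvalProtocol, sbs, sfs
from crossslope.synthetic import generate_dataset, study_cohort

ROOT = Path(__file__).resolve().parents[1]


def conditioned_matrix(conf, role, inventory):
    ds = generate_dataset(conf, role=role)
    ds = Dataset([preprocess_trial(t) for t in ds.trials], role=role)
    return build_feature_matrix(ds, inventory)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    inv = SignalInventory.full_with_ips()
    cohort = study_cohort(args.seed)
    matrices = {
        role: conditioned_matrix(conf, role, inv) for role, conf in cohort.items()
    }
    ips = [n for n in inv.names if n.startswith("ips_")]
    train = restrict_to_signals(matrices["training"], ips)

    protocols = {
        "loocv": EvalProtocol("loocv_training"),
        "test1": EvalProtocol(
            "fixed_test", pick_matrix=restrict_to_signals(matrices["test1"], ips)
        ),
        "test2": EvalProtocol(
            "fixed_test", pick_matrix=restrict_to_signals(matrices["test2"], ips)
        ),
    }

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    for pick, protocol in protocols.items():
        for method, run in (("sfs", sfs), ("sbs", sbs)):
            trace = run(train, protocol)
            out = results / f"ranking_ips_{method}_{pick}.tsv"
            trace.to_frame().to_csv(out, sep="\t", index=False)
            print(f"{method.upper()} (pick={pick}): "
                  f"{' > '.join(trace.ranking)} -> {out.name}")


if __name__ == "__main__":
    main()
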