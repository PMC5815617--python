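#!/usr/bin/env python
"""Generate the synthetic study cohort and write it to disk.

Three datasets mirror the study design: ``training`` (3 subjects,
prescribed prosthesis, slope visible), ``test1`` (1 subject, slope not
visible — emulated as a distribution shift with doubled subject offsets
and slightly weaker anticipatory effects) and ``test2`` (2 subjects on the
prototype prosthesis — effects attenuated 20%). Trial files and manifests
land under scratch/data/<role>/; a summary table goes to results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from crossslope.gait_data import write_manifest, write_trial
from crossslope.synthetic import generate_dataset, study_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "scratch" / "data")
    args = ap.parse_args()

    rows = []
    for role, conf in study_cohort(args.seed).items():
        ds = generate_dataset(conf, role=role)
        ddir = args.out / role
        ddir.mkdir(parents=True, exist_ok=True)
        paths = []
        for trial in ds.trials:
            p = ddir / f"{trial.trial_id}.tsv"
            write_trial(trial, p)
            paths.append(p)
        write_manifest(paths, role, ddir / "manifest.txt")
        rows.append(
            {
                "role": role,
                "subjects": conf.n_subjects,
                "trials": len(ds),
                "trials_per_class_per_subject": conf.trials_per_class,
                "prosthesis": conf.prosthesis,
                "subject_sd": conf.subject_sd,
            }
        )
        print(f"{role}: {len(ds)} trials ({conf.n_subjects} subjects, "
              f"{conf.prosthesis} prosthesis) -> {ddir}")

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(results / "cohort_summary.tsv", sep="\t", index=False)
    print(f"summary -> {results / 'cohort_summary.tsv'}")


if __name__ == "__main__":
    main()
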