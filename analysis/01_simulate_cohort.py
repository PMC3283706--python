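"""Simulate the validation-sized cohort (129 SLE / 15 controls).

Writes the cohort table, the latent-class truth file (kept separate so the
downstream analyses never see it) and the generator configuration used.
"""

import argparse
from pathlib import Path

from seroclust import default_config_from_tables, generate_cohort
from seroclust.synthetic_cohort import write_truth

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = default_config_from_tables(seed=seed)
    cohort, truth = generate_cohort(cfg)
    cfg.to_yaml(RESULTS / "sim_config.yaml")
    cohort.write_csv(RESULTS / "cohort.csv")
    write_truth(truth, RESULTS / "truth.csv")
    counts = truth["latent_class"].value_counts()
    print(f"simulated {cohort.n_sle} SLE patients and {cohort.n_control} controls")
    print(f"latent classes: {counts.to_dict()}")
    print(f"wrote {RESULTS / 'cohort.csv'}, truth and config alongside")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(**vars(ap.parse_args()))
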