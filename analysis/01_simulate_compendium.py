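"""Generate the working synthetic compendium: 13 case/control experiments
(251 cases, 428 controls in total) over a 2,000-gene universe with 20 planted
consistently-dysregulated genes, plus the truth ledger.

Data (matrices, labels, truth) go to scratch/compendium; a small design
summary goes to results/analysis.
"""
from pathlib import Path

import pandas as pd

from egwaskit.synth import CompendiumConfig, generate_compendium, write_compendium

DATA_DIR = Path("scratch/compendium")
RESULTS = Path("results/analysis")

CONFIG = CompendiumConfig(n_genes=2000, n_true=20, seed=1)


def main() -> None:
    experiments, truth = generate_compendium(CONFIG)
    write_compendium(experiments, truth, DATA_DIR)
    RESULTS.mkdir(parents=True, exist_ok=True)
    summary = pd.DataFrame(
        {
            "experiment": [e.experiment_id for e in experiments],
            "cases": [e.n_cases for e in experiments],
            "controls": [e.n_controls for e in experiments],
            "genes_measured": [len(e.genes) for e in experiments],
        }
    )
    summary.to_csv(RESULTS / "01_design.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(
        f"\n{len(experiments)} experiments, "
        f"{summary.cases.sum()} cases / {summary.controls.sum()} controls, "
        f"{CONFIG.n_genes}-gene universe, {CONFIG.n_true} planted genes "
        f"(effect {CONFIG.effect_size} SD, activity {CONFIG.activity_prob})."
    )
    print(f"data -> {DATA_DIR}, summary -> {RESULTS / '01_design.tsv'}")


if __name__ == "__main__":
    main()
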