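"""Fit the seven analysis treatments to one simulated dataset.

Generates a single dataset at delta = -2, 20% missing (a condition where
neither scoring-as-wrong nor latent ignorability matches the generating
process), applies CD, UW, UO, MO2, MM1, IF1 and IF2, links every fit to
the true item parameters, and tabulates the linked mean/SD.  For the
model-based fits it also reports BIC and the Gilula-Haberman penalty.
Writes results/single_dataset_fits.csv.
"""

import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from irtmiss.datagen import DesignCell, generate_dataset
from irtmiss.fitstats import ghp, information_criteria
from irtmiss.linking import link_to_truth
from irtmiss.simstudy import apply_treatment

OUT = Path(__file__).resolve().parents[1] / "results"
MODELS = ("CD", "UW", "UO", "MO2", "MM1", "IF1", "IF2")


def main() -> None:
    cell = DesignCell(delta=-2.0, missing_rate=0.20)
    data, truth, complete = generate_dataset(cell, 2024, return_complete=True)
    print(
        f"dataset: N={data.n_persons}, I={data.n_items}, realized missing "
        f"rate {data.missing_rate():.3f}, calibrated beta {truth.bank.beta[0]:.3f}"
    )
    rows = []
    for model in MODELS:
        t0 = time.time()
        fit = apply_treatment(
            model, data, truth.bank, complete=complete,
            rng=np.random.default_rng(7),
        )
        mean, sd = link_to_truth((fit.discrimination, fit.difficulty), truth.bank)
        row = {
            "model": model,
            "linked_mean": round(mean, 4),
            "linked_sd": round(sd, 4),
            "loglik": round(fit.loglik, 1),
            "seconds": round(time.time() - t0, 1),
        }
        if model in ("MO2", "MM1"):  # information criteria for model-based fits
            aic, bic = information_criteria(fit.loglik, fit.n_params, data.n_persons)
            row["BIC"] = round(bic, 1)
            # three parameters (a, b, beta) attributed per administered item
            row["GHP"] = round(ghp(aic, np.full(data.n_persons, data.n_items), 3), 4)
        rows.append(row)
    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "single_dataset_fits.csv", index=False)
    print(table.to_string(index=False))
    print(
        "\nTruth is mean 0, SD 1. On this dataset the correctly specified "
        "Mislevy-Wu model (MM1) stays near the truth, scoring-as-wrong (UW) "
        "underestimates the mean, and the treatments that ignore missingness "
        "or assume latent ignorability (UO, MO2, IF1, IF2) overestimate it "
        "- the two poles the Mislevy-Wu family interpolates between."
    )


if __name__ == "__main__":
    sys.exit(main())
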