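"""Kinetic characterization of the four bifunctional DHPAAS variants.

Emulates the H2O2-production assay for the wild type (Km 41.7 µM, kcat
6.51 min^-1) at 5% relative noise, fits the Michaelis-Menten law with
outlier elimination and profile-likelihood CIs, and computes the
aldehyde-synthase/decarboxylase partition for all four variants from their
maximal velocities.  Writes the fits and the partition table under results/.
"""

import sys
from pathlib import Path

import pandas as pd

from biapath.enzyme_kinetics import fit_mm, percent_aas
from biapath.synthetic_data import (MMSimSpec, VARIANT_VMAX_PAIRS,
                                    gen_mm_dataset)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    data, truth = gen_mm_dataset(MMSimSpec(noise_cv=0.05, n_replicates=2,
                                           seed=SEED))
    fit = fit_mm(data)
    fit_row = pd.DataFrame([{
        "km_uM": fit.km, "km_lo": fit.km_ci[0], "km_hi": fit.km_ci[1],
        "kcat_per_min": fit.kcat, "kcat_lo": fit.kcat_ci[0],
        "kcat_hi": fit.kcat_ci[1], "n_outliers": int(fit.outlier_flags.sum()),
        "true_km_uM": truth["km"], "true_kcat_per_min": truth["kcat"]}])
    fit_row.to_csv(RESULTS / "mm_fit_wildtype.csv", index=False)
    print(f"wild-type fit: Km {fit.km:.1f} µM "
          f"({fit.km_ci[0]:.1f}-{fit.km_ci[1]:.1f}), "
          f"kcat {fit.kcat:.2f} min^-1 "
          f"({fit.kcat_ci[0]:.2f}-{fit.kcat_ci[1]:.2f}) "
          f"[truth: {truth['km']} µM, {truth['kcat']} min^-1]")

    rows = [{"variant": name, "v_aas": pair[0], "v_ddc": pair[1],
             "pct_aas": percent_aas(*pair)}
            for name, pair in VARIANT_VMAX_PAIRS.items()]
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "variant_partition.csv", index=False)
    print("\n" + table.to_string(index=False))
    print("\nThe partition collapses from 95% synthase flux in the wild type "
          "to 5.9% in the triple variant: the three active-site "
          "substitutions switch the enzyme to a decarboxylase.")


if __name__ == "__main__":
    sys.exit(main())
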