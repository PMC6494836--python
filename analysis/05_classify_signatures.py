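"""Active-site signature classification on a synthetic AAAD family.

Generates a 200-sequence family with planted Phe79/Tyr80/Asn192-type triads
(plus DDC-style and mixed isoform-X2-style motifs) at 5% background
mutation, aligns every sequence to the numbering reference, classifies the
triads, and scores the calls against the planted truth.  Writes the call
table and a confusion summary under results/.
"""

import sys
from pathlib import Path

import pandas as pd

from biapath.residue_signature import classify_record
from biapath.synthetic_data import MotifFamilySpec, gen_motif_family

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    spec = MotifFamilySpec(seed=SEED, mutation_rate=0.05,
                           assignments={"DHPAAS": 80, "DDC": 80, "mixed": 40})
    ref, records, truth = gen_motif_family(spec)
    calls = pd.DataFrame(
        [{"id": c.id, "res79": c.residue_79, "res80": c.residue_80,
          "res192": c.residue_192, "label": c.label, "note": c.note}
         for c in (classify_record(r, ref) for r in records)])
    calls.to_csv(RESULTS / "signature_calls.csv", index=False)

    merged = calls.merge(truth[["id", "expected_label"]], on="id")
    confusion = pd.crosstab(merged["expected_label"], merged["label"])
    confusion.to_csv(RESULTS / "signature_confusion.csv")
    agree = (merged["label"] == merged["expected_label"]).mean()
    print(confusion.to_string())
    print(f"\nagreement with planted truth: {100 * agree:.1f}% "
          f"({len(merged)} sequences, 5% background mutation away from the "
          "triad positions)")


if __name__ == "__main__":
    sys.exit(main())
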