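"""Genotype-level genomic prediction within and across breeding cycles.

Five-fold cross-validation (all cycles pooled) and leave-one-cycle-out
prediction per trait.  The expected pattern: five-fold abilities are high
(sharing families between training and test), while predicting a whole
held-out cycle is harder for most cycles, most visibly for the low-
heritability yield-type trait.
"""

import pandas as pd

from _common import RESULTS, ensure_dirs, get_dataset, get_pheno
from ufcpred import gpred


def main() -> None:
    ensure_dirs()
    ds = get_dataset()
    pheno = get_pheno(ds)
    qc = gpred.marker_qc(ds.dosage_df())
    grm = gpred.compute_grm(qc.X)
    cycles = ds.lines.set_index("id")["cycle"]

    rows = []
    for trait, ph in pheno.items():
        y = ph.blues_across
        r5 = gpred.cross_validate_5fold(y, grm, n_rep=5, seed=1)
        rows.append((trait, "5fold", "all", r5))
        loco = gpred.leave_one_cycle_out(y, grm, cycles)
        for cyc, r in loco.items():
            rows.append((trait, "leave_one_cycle_out", cyc, r))
        print(f"{trait}: r_5fold={r5:.3f}, "
              f"per-cycle r={loco.round(3).to_dict()}")
    out = pd.DataFrame(rows, columns=["trait", "scheme", "cycle", "r"])
    out.to_csv(RESULTS / "prediction_abilities.csv", index=False)


if __name__ == "__main__":
    main()
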