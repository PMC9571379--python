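"""Influence of training-population size on family-level prediction.

Random training subsets (five per size) from the earlier cycles predict the
final cycle's families across a ladder of sizes.  Expected: median abilities
rise then plateau with size, and their spread narrows — the dispersion at
the largest size should sit below the dispersion at 50.
"""

import pandas as pd

from _common import RESULTS, ensure_dirs, get_dataset, get_pheno
from ufcpred import validate


def main() -> None:
    ensure_dirs()
    ds = get_dataset()
    pheno = get_pheno(ds)
    trait = "ear_emergence"
    pool = ds.lines.loc[ds.lines.cycle != ds.cycles[-1], "id"]
    avail = sum(g in pheno[trait].blues_across.index for g in pool)
    sizes = tuple(s for s in (50, 100, 200, 400, 1000) if s <= avail)
    if sizes[-1] < avail:
        sizes = sizes + (avail,)
    config = validate.ScenarioConfig(training_sizes=sizes, n_samples=5, seed=1)
    res = validate.run_scenario_training_size(ds, config, pheno)
    res.to_csv(RESULTS / "training_size.csv", index=False)
    for trait in sorted(res.trait.unique()):
        sub = res[(res.trait == trait) & (res.statistic == "mean")]
        med = sub.groupby("training_size")["r"].median().round(3)
        sd = sub.groupby("training_size")["r"].std().round(3)
        print(f"{trait}: median r(mean) by size {med.to_dict()}")
        print(f"{trait}: spread of r(mean) by size {sd.to_dict()}")


if __name__ == "__main__":
    main()
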