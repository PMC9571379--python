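"""Simulate the synthetic breeding programme and write it out.

Five cycles of DH lines (433/1026/1021/1020/1000 scaled by 0.25) from
2-/3-/4-way crosses of inbred founders, 2898 mapped SNPs on 7 chromosomes,
and unbalanced multi-environment trials for three traits with target
heritabilities 0.84 / 0.77 / 0.49.  Full data files land in scratch/program/
(they are large); a compact structural summary goes to results/.
"""

import pandas as pd

from _common import CONFIG, RESULTS, SCRATCH, SEED, ensure_dirs, get_dataset
from ufcpred import io


def main() -> None:
    ensure_dirs()
    ds = get_dataset()
    io.write_program(SCRATCH / "program", ds, vcf=True)
    io.write_manifest(SCRATCH / "program" / "manifest.json", CONFIG, SEED)

    sizes = ds.lines[~ds.lines.is_founder].groupby("family").size()
    summary = pd.DataFrame([
        ("lines", int((~ds.lines.is_founder).sum())),
        ("founders", int(ds.lines.is_founder.sum())),
        ("families", len(ds.pedigree)),
        ("families_2way", int((ds.pedigree.cross_type == "2-way").sum())),
        ("markers", ds.gmap.n_markers),
        ("trial_records", len(ds.trials)),
        ("environments", ds.trials.environment.nunique()),
        ("median_family_size", float(sizes.median())),
        ("families_with_10plus", int((sizes >= 10).sum())),
    ], columns=["quantity", "value"])
    summary.to_csv(RESULTS / "program_summary.csv", index=False)
    print(summary.to_string(index=False))
    print(f"\nprogramme written to {SCRATCH / 'program'}")


if __name__ == "__main__":
    main()
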