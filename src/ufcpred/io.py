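"""Readers and writers for the pipeline's file formats.

Everything is plain text: CSV for dosage matrices, genetic maps, pedigrees,
trial records and truth tables, VCF (phased GT, biallelic SNPs) for
genotypes, JSON for run manifests and YAML for run configuration.  Map
coordinates are genetic (cM) throughout; when writing VCF the POS field
carries the cM position scaled by 10^4 so it survives the integer contract.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .crossing import CrossSpec, contribution_weights
from .genmap import GeneticMap
from .simdata import ProgramConfig, ProgramDataset, TraitSpec

__all__ = [
    "read_genotypes", "write_dosage_csv", "write_vcf",
    "read_map", "write_map", "read_pedigree", "write_pedigree",
    "read_trials", "write_trials", "write_program", "read_program",
    "write_manifest", "RunConfig",
]

_POS_SCALE = 10_000  # cM -> integer VCF POS


# ---------------------------------------------------------------------------
# genotypes


def write_dosage_csv(path, dosage: pd.DataFrame) -> None:
    """Genotypes x markers dosage matrix; missing values as empty cells."""
    dosage.to_csv(path, index_label="genotype")


def write_vcf(path, dosage: pd.DataFrame, gmap: GeneticMap) -> None:
    """Phased VCF (GT only) for homozygous or phased dosages {0,1,2}."""
    markers = list(gmap.marker)
    missing = [m for m in markers if m not in dosage.columns]
    if missing:
        raise ValueError(f"dosage lacks mapped markers, e.g. {missing[:3]}")
    samples = list(dosage.index)
    gt_of = {0: "0|0", 1: "0|1", 2: "1|1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in gmap.chromosomes:
            sl = gmap.chrom_slices()[c]
            ln = int(gmap.pos_cm[sl][-1] * _POS_SCALE) + 2
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write("##INFO=<ID=CM,Number=1,Type=Float,"
                 'Description="Genetic position in cM">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        D = dosage[markers].to_numpy()
        for j, m in enumerate(markers):
            pos = int(round(gmap.pos_cm[j] * _POS_SCALE)) + 1
            calls = []
            for v in D[:, j]:
                if pd.isna(v):
                    calls.append(".|.")
                else:
                    calls.append(gt_of[int(v)])
            fh.write(f"{gmap.chrom[j]}\t{pos}\t{m}\tA\tT\t.\tPASS\t"
                     f"CM={gmap.pos_cm[j]:.6f}\tGT\t" + "\t".join(calls) + "\n")


def _read_vcf(path) -> pd.DataFrame:
    """Minimal text-VCF reader for GT-only biallelic records (ALT dosage)."""
    samples, rows, markers = None, [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            if samples is None:
                raise ValueError(f"{path}:{lineno}: records before #CHROM header")
            parts = line.split("\t")
            if len(parts) != 9 + len(samples):
                raise ValueError(f"{path}:{lineno}: wrong column count")
            markers.append(parts[2])
            fmt = parts[8].split(":")
            if "GT" not in fmt:
                raise ValueError(f"{path}:{lineno}: no GT field")
            gi = fmt.index("GT")
            row = []
            for cell in parts[9:]:
                gt = cell.split(":")[gi].replace("/", "|")
                if "." in gt:
                    row.append(np.nan)
                else:
                    row.append(float(sum(int(a) for a in gt.split("|"))))
            rows.append(row)
    if len(set(markers)) != len(markers):
        raise ValueError(f"{path}: duplicated marker identifiers")
    if samples is not None and len(set(samples)) != len(samples):
        raise ValueError(f"{path}: duplicated sample identifiers")
    return pd.DataFrame(np.array(rows).T, index=samples, columns=markers)


def read_genotypes(path, format: str | None = None) -> pd.DataFrame:
    """Dosage matrix from VCF or CSV (missing entries as NaN, never zero)."""
    path = Path(path)
    fmt = format or ("vcf" if path.suffix == ".vcf" else "csv")
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "csv":
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        df.index.name = "genotype"
        if df.index.duplicated().any() or df.columns.duplicated().any():
            raise ValueError(f"{path}: duplicated genotype or marker identifiers")
        return df.astype(float)
    raise ValueError(f"unknown genotype format {fmt!r}")


# ---------------------------------------------------------------------------
# map / pedigree / trials


def write_map(path, gmap: GeneticMap) -> None:
    gmap.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_map(path) -> GeneticMap:
    df = pd.read_csv(path, dtype={"marker": str, "chrom": str})
    need = {"marker", "chrom", "pos_cm"}
    if not need.issubset(df.columns):
        raise ValueError(f"map CSV needs columns {sorted(need)}")
    return GeneticMap.from_frame(df)


def write_pedigree(path, pedigree: pd.DataFrame) -> None:
    pedigree.to_csv(path, index=False)


def read_pedigree(path) -> list[CrossSpec]:
    """Cross plan from CSV; cross type inferred from the parent count."""
    df = pd.read_csv(path, dtype=str).fillna("")
    out = []
    for _, row in df.iterrows():
        parents = tuple(
            row[c] for c in ("parent1", "parent2", "parent3", "parent4")
            if c in row.index and row[c]
        )
        out.append(CrossSpec(row["family"], parents,
                             contribution_weights(len(parents))))
    return out


def write_trials(path, trials: pd.DataFrame) -> None:
    # %.17g keeps the float64 values bit-exact through the text round trip
    trials.to_csv(path, index=False, float_format="%.17g")


def read_trials(path, known_genotypes=None) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"genotype": str, "environment": str,
                                  "cycle": str, "replication": str,
                                  "block": str, "trait": str},
                     float_precision="round_trip")
    need = {"genotype", "environment", "replication", "block", "trait", "value"}
    if not need.issubset(df.columns):
        raise ValueError(f"trial CSV needs columns {sorted(need)}")
    if known_genotypes is not None:
        unknown = set(df["genotype"]) - set(known_genotypes)
        if unknown:
            raise ValueError(f"trials reference unknown genotypes: "
                             f"{sorted(unknown)[:5]}")
    return df


# ---------------------------------------------------------------------------
# whole programmes


def write_program(outdir, dataset: ProgramDataset, vcf: bool = True) -> dict:
    """Write a programme as CSV/VCF files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "map": outdir / "map.csv",
        "dosage": outdir / "genotypes.csv",
        "lines": outdir / "lines.csv",
        "pedigree": outdir / "pedigree.csv",
        "trials": outdir / "trials.csv",
    }
    write_map(paths["map"], dataset.gmap)
    write_dosage_csv(paths["dosage"], dataset.dosage_df())
    dataset.lines.to_csv(paths["lines"], index=False)
    write_pedigree(paths["pedigree"], dataset.pedigree)
    write_trials(paths["trials"], dataset.trials)
    if vcf:
        paths["vcf"] = outdir / "genotypes.vcf"
        write_vcf(paths["vcf"], dataset.dosage_df(), dataset.gmap)
    if dataset.truth is not None:
        paths["truth_values"] = outdir / "truth_genetic_values.csv"
        dataset.truth["genetic_values"].to_csv(paths["truth_values"])
        paths["truth_families"] = outdir / "truth_families.csv"
        dataset.truth["family_truth"].to_csv(paths["truth_families"], index=False)
        paths["truth_effects"] = outdir / "truth_marker_effects.csv"
        dataset.truth["marker_effects"].to_csv(paths["truth_effects"])
    return {k: str(v) for k, v in paths.items()}


def read_program(outdir) -> ProgramDataset:
    """Reload a programme written by :func:`write_program` (truth excluded)."""
    outdir = Path(outdir)
    gmap = read_map(outdir / "map.csv")
    dosage_df = read_genotypes(outdir / "genotypes.csv", "csv")
    lines = pd.read_csv(outdir / "lines.csv", dtype={"id": str}).fillna({"family": ""})
    lines["family"] = lines["family"].astype(str).replace("nan", "")
    pedigree = pd.read_csv(outdir / "pedigree.csv", dtype=str).fillna("")
    trials = read_trials(outdir / "trials.csv", known_genotypes=lines["id"])
    dosage = dosage_df.loc[lines["id"], gmap.marker].to_numpy().astype(np.uint8)
    return ProgramDataset(gmap, lines, dosage, pedigree, trials, truth=None)


# ---------------------------------------------------------------------------
# configuration and manifests


@dataclass
class RunConfig:
    """Paths, traits and scenario settings for a pipeline run."""

    outdir: str = "results"
    seed: int = 0
    traits: list = field(default_factory=list)
    simulation: dict = field(default_factory=dict)
    scenario: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**{k: v for k, v in data.items()
                      if k in cls.__dataclass_fields__})

    def program_config(self) -> ProgramConfig:
        sim = dict(self.simulation)
        if "traits" in sim:
            sim["traits"] = tuple(TraitSpec(**t) for t in sim["traits"])
        return ProgramConfig(**sim)


def write_manifest(path, config, seed: int, extra: dict | None = None) -> None:
    """JSON manifest: config, seed, package version and a config hash."""
    from . import __version__

    if hasattr(config, "__dataclass_fields__"):
        cfg = asdict(config)
    else:
        cfg = dict(config) if config else {}
    blob = json.dumps(cfg, sort_keys=True, default=str)
    manifest = {
        "seed": seed,
        "version": __version__,
        "config": json.loads(json.dumps(cfg, default=str)),
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
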