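"""Synthetic doubled-haploid breeding programmes.

This module generates the study system end to end: a genetic map, inbred
founders, multiple breeding cycles of DH families from 2-/3-/4-way crosses
with intentionally unequal family sizes, purely additive multi-trait
architectures, and unbalanced multi-environment trials with replications and
incomplete blocks.  The generating truth (QTL effects, true genetic values,
true family means and variances) is retained so that estimators downstream
can be validated against it.

Default dimensions mirror a commercial winter-barley programme: five cycles
of 433/1026/1021/1020/1000 lines, 347 families, 2898 SNPs on seven
chromosomes, and three traits with broad-sense heritabilities of about
0.84 / 0.77 / 0.49 (an early-flowering-type trait, a height-type trait and a
yield-type trait, in decreasing order of heritability and increasing order
of polygenicity).  A ``scale`` factor shrinks cycle and family counts
proportionally for smaller experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genmap import GeneticMap, build_genetic_map
from .crossing import CrossSpec, PhasedGenotype, make_cross, produce_dh_family

__all__ = [
    "TraitSpec",
    "TraitArchitecture",
    "TrialDesign",
    "ProgramConfig",
    "ProgramDataset",
    "allocate_environments",
    "simulate_trial_phenotypes",
    "simulate_program",
]


# ---------------------------------------------------------------------------
# trait architecture


@dataclass(frozen=True)
class TraitSpec:
    """High-level description of a simulated trait."""

    name: str
    h2: float  # target broad-sense heritability (across environments)
    n_qtl: int
    genetic_var: float = 1.0  # variance of true genetic values, trait units^2
    intercept: float = 0.0


@dataclass
class TraitArchitecture:
    """Additive genetic architecture plus trial noise variances.

    The genetic value of a line is ``intercept + dosage[qtl] @ effects``;
    phenotypes add independent normal environment, genotype-by-environment,
    replication-within-environment, block-within-environment and residual
    deviations with the variances below (trait units squared).
    """

    name: str
    qtl_idx: np.ndarray
    effects: np.ndarray
    intercept: float = 0.0
    var_env: float = 0.0
    var_gxe: float = 0.0
    var_rep: float = 0.0
    var_block: float = 0.0
    var_resid: float = 0.0
    h2_target: float | None = None

    def genetic_values(self, dosage: np.ndarray) -> np.ndarray:
        return self.intercept + dosage[:, self.qtl_idx].astype(float) @ self.effects

    @classmethod
    def calibrated(
        cls,
        name: str,
        qtl_idx: np.ndarray,
        effects: np.ndarray,
        *,
        h2: float,
        genetic_var: float,
        n_envs_mean: float,
        n_reps: int,
        intercept: float = 0.0,
        gxe_share: float = 0.6,
    ) -> "TraitArchitecture":
        """Choose noise variances so the across-environment heritability
        estimator lands near ``h2``.

        With genotype means over ``n_envs_mean`` environments, the stage-2
        residual variance is approximately ``var_gxe`` plus the stage-1 mean
        error ``(var_block + var_resid) / n_reps``; the total needed for the
        target is ``n_envs_mean * genetic_var * (1/h2 - 1)``, split
        ``gxe_share`` to genotype-by-environment and the rest to plot error.
        """
        if not 0 < h2 <= 1:
            raise ValueError("h2 must be in (0, 1]")
        s2_needed = n_envs_mean * genetic_var * (1.0 / h2 - 1.0)
        var_gxe = gxe_share * s2_needed
        plot_total = (1.0 - gxe_share) * s2_needed * n_reps
        var_block = plot_total / 6.0
        var_resid = plot_total * 5.0 / 6.0
        return cls(
            name=name,
            qtl_idx=np.asarray(qtl_idx),
            effects=np.asarray(effects, dtype=float),
            intercept=intercept,
            var_env=genetic_var,
            var_gxe=var_gxe,
            var_rep=0.1 * genetic_var,
            var_block=var_block,
            var_resid=var_resid,
            h2_target=h2,
        )


# ---------------------------------------------------------------------------
# trial design


@dataclass
class TrialDesign:
    """Genotype-to-environment allocation plus replication/block layout.

    ``allocation`` holds one row per (genotype, environment) combination that
    is actually grown; the design is unbalanced whenever genotypes differ in
    their environment sets.  Within each environment x replication, the
    genotypes present are split into consecutive incomplete blocks of
    ``block_size`` after random ordering (an alpha-lattice-like layout;
    resolvability is not enforced because blocks are modelled as random).
    """

    allocation: pd.DataFrame  # columns: genotype, environment
    n_reps: int = 2
    block_size: int = 20
    env_cycle: dict = field(default_factory=dict)  # environment -> cycle label

    def __post_init__(self) -> None:
        need = {"genotype", "environment"}
        if not need.issubset(self.allocation.columns):
            raise ValueError(f"allocation needs columns {sorted(need)}")
        if len(self.allocation) == 0:
            raise ValueError("empty genotype-environment allocation")
        if self.n_reps < 1 or self.block_size < 1:
            raise ValueError("n_reps and block_size must be >= 1")


def allocate_environments(
    genotype_ids,
    environments,
    mean_envs: float,
    rng: int | np.random.Generator = 0,
    min_envs: int = 2,
) -> pd.DataFrame:
    """Random unbalanced allocation with a configured mean environments per
    genotype: each genotype is grown in environment *e* independently with
    probability ``mean_envs / n_envs``, then topped up to ``min_envs``."""
    rng = np.random.default_rng(rng)
    envs = list(environments)
    if not envs:
        raise ValueError("no environments")
    min_envs = min(min_envs, len(envs))
    p = min(1.0, mean_envs / len(envs))
    rows_g, rows_e = [], []
    for g in genotype_ids:
        mask = rng.random(len(envs)) < p
        k = int(mask.sum())
        if k < min_envs:
            extra = rng.choice(np.flatnonzero(~mask), size=min_envs - k, replace=False)
            mask[extra] = True
        for j in np.flatnonzero(mask):
            rows_g.append(g)
            rows_e.append(envs[j])
    return pd.DataFrame({"genotype": rows_g, "environment": rows_e})


def simulate_trial_phenotypes(
    genotype_ids,
    dosage: np.ndarray,
    arch: TraitArchitecture,
    design: TrialDesign,
    rng: int | np.random.Generator = 0,
    cycle_of_genotype: dict | None = None,
) -> pd.DataFrame:
    """Simulate plot-level trial records for one trait.

    value = intercept + genetic value + env + GxE + rep + block + residual,
    all noise terms independent normal.  Returns tidy records with columns
    genotype, environment, cycle, replication, block, trait, value.
    """
    genotype_ids = list(genotype_ids)
    idx = {g: i for i, g in enumerate(genotype_ids)}
    rng = np.random.default_rng(rng)
    g_val = arch.genetic_values(np.asarray(dosage))
    envs = sorted(design.allocation["environment"].unique().tolist())
    env_eff = dict(zip(envs, rng.normal(0.0, np.sqrt(arch.var_env), len(envs))))

    out: dict[str, list] = {k: [] for k in
                            ("genotype", "environment", "cycle", "replication",
                             "block", "trait", "value")}
    by_env = design.allocation.groupby("environment", sort=True)["genotype"]
    for env, members in by_env:
        members = members.tolist()
        gi = np.array([idx[m] for m in members])
        gxe = rng.normal(0.0, np.sqrt(arch.var_gxe), len(members))
        base = g_val[gi] + env_eff[env] + gxe
        cyc = design.env_cycle.get(env, "")
        for rep in range(1, design.n_reps + 1):
            rep_eff = rng.normal(0.0, np.sqrt(arch.var_rep))
            order = rng.permutation(len(members))
            n_blocks = int(np.ceil(len(members) / design.block_size))
            block_eff = rng.normal(0.0, np.sqrt(arch.var_block), n_blocks)
            resid = rng.normal(0.0, np.sqrt(arch.var_resid), len(members))
            for pos, j in enumerate(order):
                b = pos // design.block_size
                out["genotype"].append(members[j])
                out["environment"].append(env)
                out["cycle"].append(cycle_of_genotype.get(members[j], cyc)
                                    if cycle_of_genotype else cyc)
                out["replication"].append(f"R{rep}")
                out["block"].append(f"B{b + 1}")
                out["trait"].append(arch.name)
                out["value"].append(base[j] + rep_eff + block_eff[b] + resid[pos])
    df = pd.DataFrame(out)
    df["value"] = df["value"].astype(float)
    return df


# ---------------------------------------------------------------------------
# whole-programme simulation


_DEFAULT_TRAITS = (
    TraitSpec("ear_emergence", h2=0.84, n_qtl=40, genetic_var=4.0, intercept=55.7),
    TraitSpec("plant_height", h2=0.77, n_qtl=120, genetic_var=25.0, intercept=98.0),
    TraitSpec("grain_yield", h2=0.49, n_qtl=300, genetic_var=36.0, intercept=91.7),
)


@dataclass
class ProgramConfig:
    """Dimensions and rates of the simulated breeding programme."""

    n_chrom: int = 7
    markers_per_chrom: int = 414
    chrom_length_cm: float = 150.0
    n_founders: int = 60
    founder_freq_range: tuple = (0.1, 0.9)
    cycle_sizes: tuple = (433, 1026, 1021, 1020, 1000)
    n_families: int = 347
    scale: float = 1.0
    cross_type_probs: tuple = (0.7, 0.2, 0.1)  # 2-, 3-, 4-way
    family_size_alpha: float = 1.3  # Dirichlet concentration; lower = more unequal
    traits: tuple = _DEFAULT_TRAITS
    n_envs_per_cycle: int = 8
    mean_envs_per_genotype: float = 3.5
    founder_mean_envs: float = 1.5
    n_reps: int = 2
    block_size: int = 20

    def scaled_cycle_sizes(self) -> list[int]:
        return [max(2, round(s * self.scale)) for s in self.cycle_sizes]

    def scaled_family_counts(self) -> list[int]:
        """Families per cycle, proportional to cycle size."""
        sizes = self.scaled_cycle_sizes()
        n_fam = max(len(sizes), round(self.n_families * self.scale))
        total = sum(sizes)
        counts = [max(1, int(n_fam * s / total)) for s in sizes]
        # largest-remainder top-up, never exceeding size//2 families per cycle
        while sum(counts) < n_fam:
            i = int(np.argmax([s / c for s, c in zip(sizes, counts)]))
            counts[i] += 1
        return [min(c, max(1, s // 2)) for c, s in zip(counts, sizes)]


@dataclass
class ProgramDataset:
    """A simulated (or loaded) multi-cycle breeding programme.

    ``lines`` has one row per genotyped line (founders included) with its
    cycle, family and founder flag; ``dosage`` rows align with ``lines``.
    ``truth`` is present only for simulated data.
    """

    gmap: GeneticMap
    lines: pd.DataFrame  # id, cycle, family, is_founder
    dosage: np.ndarray  # (n_lines, n_markers) uint8, homozygous {0,2}
    pedigree: pd.DataFrame  # family, cycle, cross_type, parent1..parent4
    trials: pd.DataFrame
    truth: dict | None = None
    config: ProgramConfig | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.dosage.shape != (len(self.lines), self.gmap.n_markers):
            raise ValueError("dosage shape does not match lines x markers")

    @property
    def line_ids(self) -> np.ndarray:
        return self.lines["id"].to_numpy()

    @property
    def cycles(self) -> list:
        c = self.lines.loc[~self.lines["is_founder"], "cycle"]
        return sorted(c.unique().tolist())

    @property
    def traits(self) -> list:
        return sorted(self.trials["trait"].unique().tolist())

    def dosage_df(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.line_ids,
                            columns=self.gmap.marker, copy=False)

    def genotype(self, line_id: str) -> PhasedGenotype:
        i = int(np.flatnonzero(self.line_ids == line_id)[0])
        return PhasedGenotype.from_dosage(line_id, self.dosage[i])

    def cross_spec(self, family: str) -> CrossSpec:
        row = self.pedigree.set_index("family").loc[family]
        parents = tuple(p for p in row[["parent1", "parent2", "parent3", "parent4"]]
                        if isinstance(p, str) and p)
        return CrossSpec(family, parents)

    def family_members(self, family: str) -> list:
        return self.lines.loc[self.lines["family"] == family, "id"].tolist()


def _family_sizes(n_lines: int, n_fam: int, alpha: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Unequal family sizes summing to n_lines (each >= 1)."""
    w = rng.dirichlet(np.full(n_fam, alpha))
    sizes = rng.multinomial(n_lines - n_fam, w) + 1
    return sizes


def simulate_program(config: ProgramConfig | None = None,
                     seed: int = 0) -> ProgramDataset:
    """Simulate a full multi-cycle DH breeding programme with trials.

    Parents of cycle 1 are external founders; later cycles draw parents from
    founders and all earlier cycles' lines.  Founders receive sparse
    phenotype records in the first cycle's environments, mirroring the thin
    information typically available on parents.
    """
    config = config or ProgramConfig()
    ss = np.random.SeedSequence(seed)
    rng_map, rng_founder, rng_cross, rng_arch, rng_alloc, rng_pheno = (
        np.random.default_rng(s) for s in ss.spawn(6))

    gmap = build_genetic_map(config.n_chrom, config.markers_per_chrom,
                             config.chrom_length_cm, rng_map)
    m = gmap.n_markers

    lo, hi = config.founder_freq_range
    freq = rng_founder.uniform(lo, hi, m)
    founder_ids = [f"F{i + 1:03d}" for i in range(config.n_founders)]
    founder_dosage = (
        (rng_founder.random((config.n_founders, m)) < freq).astype(np.uint8) * 2
    )
    genotypes = {
        fid: PhasedGenotype.from_dosage(fid, founder_dosage[i])
        for i, fid in enumerate(founder_ids)
    }

    cycle_sizes = config.scaled_cycle_sizes()
    fam_counts = config.scaled_family_counts()
    n_way_opts = np.array([2, 3, 4])
    probs = np.asarray(config.cross_type_probs, dtype=float)
    probs = probs / probs.sum()

    line_rows, ped_rows = [], []
    dosages = [founder_dosage]
    for fid in founder_ids:
        line_rows.append((fid, "C0", "", True))
    parent_pool = list(founder_ids)
    fam_no = 0
    for ci, (size, n_fam) in enumerate(zip(cycle_sizes, fam_counts), start=1):
        cycle = f"C{ci}"
        sizes = _family_sizes(size, n_fam, config.family_size_alpha, rng_cross)
        cyc_lines = []
        for fs in sizes:
            fam_no += 1
            fam = f"FAM{fam_no:04d}"
            n_par = int(rng_cross.choice(n_way_opts, p=probs))
            parents = tuple(rng_cross.choice(parent_pool, size=min(n_par, len(parent_pool)),
                                             replace=False).tolist())
            spec = CrossSpec(fam, parents)
            f1 = make_cross(spec, genotypes, gmap, rng_cross)
            dh = produce_dh_family(f1, int(fs), gmap, rng_cross, id_prefix=fam)
            for line in dh:
                line_rows.append((line.id, cycle, fam, False))
                dosages.append(line.dosage[None, :])
                genotypes[line.id] = line
                cyc_lines.append(line.id)
            pad = list(parents) + [""] * (4 - len(parents))
            ped_rows.append((fam, cycle, spec.cross_type, *pad))
        parent_pool.extend(cyc_lines)

    lines = pd.DataFrame(line_rows, columns=["id", "cycle", "family", "is_founder"])
    dosage = np.vstack(dosages).astype(np.uint8)
    pedigree = pd.DataFrame(
        ped_rows,
        columns=["family", "cycle", "cross_type",
                 "parent1", "parent2", "parent3", "parent4"],
    )

    # trait architectures scaled to hit the realised genetic variance target
    dh_mask = ~lines["is_founder"].to_numpy()
    archs = []
    for spec in config.traits:
        qtl = np.sort(rng_arch.choice(m, size=min(spec.n_qtl, m), replace=False))
        eff = rng_arch.normal(0.0, 1.0, qtl.size)
        g_raw = dosage[dh_mask][:, qtl].astype(float) @ eff
        sd = g_raw.std()
        if sd > 0:
            eff *= np.sqrt(spec.genetic_var) / sd
        arch = TraitArchitecture.calibrated(
            spec.name, qtl, eff,
            h2=spec.h2, genetic_var=spec.genetic_var,
            n_envs_mean=config.mean_envs_per_genotype, n_reps=config.n_reps,
        )
        g_now = dosage[dh_mask][:, qtl].astype(float) @ eff
        arch.intercept = spec.intercept - g_now.mean()
        archs.append(arch)

    # environments and allocation: each cycle has its own environment set
    alloc_parts, env_cycle = [], {}
    for ci in range(1, len(cycle_sizes) + 1):
        cycle = f"C{ci}"
        envs = [f"E{ci}{chr(ord('a') + j)}" for j in range(config.n_envs_per_cycle)]
        for e in envs:
            env_cycle[e] = cycle
        ids = lines.loc[lines["cycle"] == cycle, "id"].tolist()
        if ci == 1:
            ids = founder_ids + ids  # sparse parental records in cycle 1
        mean_envs = config.mean_envs_per_genotype
        part = []
        for g in ids:
            n_env = (config.founder_mean_envs if g in set(founder_ids)
                     else mean_envs)
            p = min(1.0, n_env / len(envs))
            mask = rng_alloc.random(len(envs)) < p
            if mask.sum() < min(2, len(envs)):
                extra = rng_alloc.choice(np.flatnonzero(~mask),
                                         size=min(2, len(envs)) - int(mask.sum()),
                                         replace=False)
                mask[extra] = True
            part.extend((g, envs[j]) for j in np.flatnonzero(mask))
        alloc_parts.append(pd.DataFrame(part, columns=["genotype", "environment"]))
    allocation = pd.concat(alloc_parts, ignore_index=True)
    design = TrialDesign(allocation, n_reps=config.n_reps,
                         block_size=config.block_size, env_cycle=env_cycle)

    cycle_of = dict(zip(lines["id"], lines["cycle"]))
    trial_parts = []
    for arch, s in zip(archs, np.random.SeedSequence(seed + 1).spawn(len(archs))):
        trial_parts.append(
            simulate_trial_phenotypes(lines["id"], dosage, arch, design,
                                      np.random.default_rng(s), cycle_of)
        )
    trials = pd.concat(trial_parts, ignore_index=True)

    # retained truth
    gvals = pd.DataFrame(
        {a.name: a.genetic_values(dosage) for a in archs}, index=lines["id"]
    )
    eff_full = pd.DataFrame(0.0, index=gmap.marker, columns=[a.name for a in archs])
    for a in archs:
        eff_full.iloc[a.qtl_idx, eff_full.columns.get_loc(a.name)] = a.effects
    fam_rows = []
    for fam in pedigree["family"]:
        members = lines.loc[lines["family"] == fam, "id"]
        for a in archs:
            v = gvals.loc[members, a.name].to_numpy()
            fam_rows.append((fam, a.name, v.mean(),
                             v.var(ddof=1) if v.size > 1 else 0.0, v.size))
    family_truth = pd.DataFrame(
        fam_rows, columns=["family", "trait", "true_mean", "true_var", "n"]
    )
    truth = {
        "genetic_values": gvals,
        "marker_effects": eff_full,
        "architectures": {a.name: a for a in archs},
        "family_truth": family_truth,
        "founder_freq": freq,
    }
    return ProgramDataset(gmap, lines, dosage, pedigree, trials, truth,
                          config=config, seed=seed)
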