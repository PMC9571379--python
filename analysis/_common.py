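"""Shared setup for the analysis drivers: one quarter-scale programme.

All drivers analyse the same simulated five-cycle barley-like DH programme
(seed 2024, quarter scale: ~1124 lines in ~87 families, 2898 SNPs, three
traits).  Heavy intermediates go to scratch/; summary tables to results/.
"""

from pathlib import Path

from ufcpred import simdata, validate

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
SEED = 2024
CONFIG = simdata.ProgramConfig(scale=0.25)

_cache: dict = {}


def get_dataset() -> simdata.ProgramDataset:
    if "ds" not in _cache:
        _cache["ds"] = simdata.simulate_program(CONFIG, seed=SEED)
    return _cache["ds"]


def get_pheno(dataset=None) -> dict:
    """Two-stage phenotypic analysis, cached on disk-free first use."""
    if "pheno" not in _cache:
        _cache["pheno"] = validate.analyze_phenotypes(dataset or get_dataset())
    return _cache["pheno"]


def ensure_dirs() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
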