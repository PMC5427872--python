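"""Shared settings for the numbered analysis drivers."""

from pathlib import Path

from lipidtrio import sim

STUDY_SEED = 17
ROOT = Path(__file__).resolve().parent.parent
DATA_DIR = ROOT / "results" / "cohort"
RESULTS_DIR = ROOT / "results"


def study_config() -> sim.SimConfig:
    """The study-scale cohort the drivers analyse: 544 families, 158 SNPs,
    ~1.5% non-paternity (the real cohort harboured 5 non-biological fathers
    among 352 genotyped ones) and 1% genotype missingness."""
    return sim.default_study_config(seed=STUDY_SEED, nonpaternity_rate=5 / 352)
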