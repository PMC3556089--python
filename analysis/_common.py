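"""Shared setup for the numbered analysis drivers."""

from pathlib import Path

from dgetag.pipeline import run_pipeline
from dgetag.synthetic_data import SimulationConfig

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def default_run(seed: int = 42):
    """The default synthetic experiment used throughout the analyses:
    2,000 genes, 100 planted DE at |log2|=2, 30 Fer-specific, 10
    Ste-specific, 10 alien genes, depth 5e5 per library."""
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    return run_pipeline(SimulationConfig(seed=seed))
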