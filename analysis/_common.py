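"""Shared constants for the analysis scripts.

One mixed cohort — equal thirds of prompt, monthly and poor uploaders —
simulated once in 01 and reused by every later step through the CSVs
under results/analysis/.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "analysis"

N_MUNICIPALITIES = 150
N_WEEKS = 40
SEED = 42
PROFILES = ("prompt", "monthly", "poor")
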