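"""Shared paths and the study configuration used by the numbered drivers.

The stream emulates the full 77-month observation window (Jan 2013 - May
2019) with the documented class mix, drift, event bursts and duplicate
share, at a reduced base rate of 25 tweets/day (~58k records) so the whole
analysis replays in about a minute on a laptop.
"""

from pathlib import Path

import crisprpulse as cp

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

SEED = 20260

CORPUS_CONFIG = cp.CorpusConfig(base_rate=25.0, seed=SEED)
PREP_CONFIG = cp.PrepConfig(monthly_quota=380, seed=SEED)
QC_CONFIG = cp.QCConfig()
ANNOTATION_JOB = cp.config.AnnotationJobConfig()
ANALYSIS_CONFIG = cp.AnalysisConfig()


def ensure_dirs() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
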