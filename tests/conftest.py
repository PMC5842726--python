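"""Shared fixtures: synthetic smears and cached end-to-end pipeline runs.

The pipeline is the expensive part (~2.5 s per image), so the two scoring
regimes are each run once per session and shared by the integration,
classification and acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from hemoseg import (
    PipelineConfig,
    SmearParams,
    generate_smear,
    match_segments,
    run_pipeline,
)

N_SEEDS = 20


@dataclass
class ScoredRun:
    seed: int
    img: np.ndarray
    gt: object
    result: object  # PipelineResult
    report: object  # EvalReport

    @property
    def labels(self):
        return self.result.segmentation.labels

    def pred_class(self, pid: int) -> str:
        return next(r.cell_class for r in self.result.records if r.label == pid)


def _run_regime(params_for_seed) -> list[ScoredRun]:
    runs = []
    for seed in range(N_SEEDS):
        img, gt = generate_smear(params_for_seed(seed))
        res = run_pipeline(img, PipelineConfig())
        rep = match_segments(res.segmentation.labels, gt)
        runs.append(ScoredRun(seed=seed, img=img, gt=gt, result=res, report=rep))
    return runs


@pytest.fixture(scope="session")
def easy_runs() -> list[ScoredRun]:
    """8 well-separated cells (7 RBC + 1 WBC), zero overlap, 20 seeds."""
    return _run_regime(
        lambda s: SmearParams(n_rbc=7, n_wbc=1, max_overlap_fraction=0.0, seed=s)
    )


@pytest.fixture(scope="session")
def adherent_runs() -> list[ScoredRun]:
    """10 adherent cells (9 RBC + 1 WBC), overlap fraction 0.2, 20 seeds."""
    return _run_regime(
        lambda s: SmearParams(n_rbc=9, n_wbc=1, max_overlap_fraction=0.2, seed=s)
    )


@pytest.fixture(scope="session")
def default_smears():
    """Default-world images with ground truth (no pipeline run), 20 seeds."""
    return [generate_smear(SmearParams(seed=s)) for s in range(N_SEEDS)]
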