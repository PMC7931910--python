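"""Shared fixtures: cohorts and trained pipelines at the reference scale."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from somportrait import (CohortConfig, SOMPortrait, SpotDetector,
                         TypeStratifier, center_genes, generate_cohort,
                         match_modules, quantile_normalize,
                         spot_profile_matrix)


@dataclass
class PipelineRun:
    """One fully analyzed synthetic cohort with its ground truth."""

    seed: int
    config: CohortConfig
    expression: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: object
    X: pd.DataFrame  # preprocessed
    som: SOMPortrait
    spots: list
    stratifier: TypeStratifier
    portraits: pd.DataFrame

    @property
    def assignment(self):
        return self.stratifier.assignment_


def run_reference_pipeline(seed: int) -> PipelineRun:
    """Default study conditions: 2,000 genes x 300 samples, 16x16 map."""
    config = CohortConfig(seed=seed)
    expression, phenotypes, truth = generate_cohort(config)
    X = center_genes(quantile_normalize(expression))
    som = SOMPortrait(grid_rows=16, grid_cols=16, random_state=seed).fit(X)
    spots = SpotDetector().fit(som).spots_
    portraits = som.sample_portrait_matrix()
    strat = TypeStratifier(random_state=seed).fit(
        portraits, spot_profile_matrix(spots))
    return PipelineRun(seed=seed, config=config, expression=expression,
                       phenotypes=phenotypes, truth=truth, X=X, som=som,
                       spots=spots, stratifier=strat, portraits=portraits)


@pytest.fixture(scope="session")
def reference_run() -> PipelineRun:
    return run_reference_pipeline(seed=1)


@pytest.fixture(scope="session")
def multi_seed_runs(reference_run) -> list[PipelineRun]:
    """Five replicate cohorts (seeds 1-5) for median-based recovery checks."""
    return [reference_run] + [run_reference_pipeline(s) for s in (2, 3, 4, 5)]


@pytest.fixture(scope="session")
def small_cohort():
    """A light cohort for unit tests that only need plausible structure."""
    config = CohortConfig(n_genes=400, n_samples=120, n_modules=4,
                          module_size=60, n_types=3, n_subtypes_per_type=1,
                          independent_module=True, seed=7)
    return generate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
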