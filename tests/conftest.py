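"""Shared fixtures: small synthetic cohorts computed once per session."""

from __future__ import annotations

import functools

import numpy as np
import pytest

import envnet as en

ALPHA = en.BandSpec("alpha", 8.0, 13.0)


@functools.lru_cache(maxsize=8)
def effect_cohort(seed: int):
    """A 42+42 cohort (20 nodes, alpha band) with 30 affected edges.

    Returns (edge value matrix on the normalized alpha maps, combined
    maps, is_case, affected edge indices, manifest).  The condition is
    calibrated so the affected-edge effect size is Cohen's d ~ 1.
    """
    cfg = en.SimulationConfig(
        n_per_group=42,
        n_nodes=20,
        bands=(ALPHA,),
        sampling_rate=120.0,
        duration=150.0,
        baseline_corr=0.3,
        affected_edge_count=30,
        effect_delta=0.5,
        leakage_lambda=0.1,
        seed=seed,
    )
    subjects, manifest, affected = en.generate_cohort(cfg)
    rows, combined, is_case = [], [], []
    for s in subjects:
        per_band, comb = en.subject_pipeline(
            s.timecourses["alpha"], bands=[ALPHA]
        )
        rows.append(per_band["alpha"].edge_vector())
        combined.append(comb)
        is_case.append(s.group == "case")
    return (
        np.array(rows),
        combined,
        np.array(is_case),
        affected,
        manifest,
    )


def effect_cohort_data(seed: int) -> tuple[en.CohortData, np.ndarray]:
    values, _, is_case, affected, manifest = effect_cohort(seed)
    cohort = en.CohortData(
        subject_ids=[m["subject_id"] for m in manifest],
        values=values,
        is_case=is_case,
        age=np.array([m["age"] for m in manifest]),
        gender=np.array([m["gender"] for m in manifest]),
        icv=np.array([m["icv"] for m in manifest]),
    )
    return cohort, affected


@pytest.fixture(scope="session")
def small_effect_cohort():
    """One calibrated effect cohort as CohortData plus ground truth."""
    return effect_cohort_data(0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@functools.lru_cache(maxsize=4)
def null_cohort_values(seed: int, n_per_group: int = 10, n_nodes: int = 8):
    """Small no-effect cohort run through the full pipeline."""
    cfg = en.SimulationConfig(
        n_per_group=n_per_group,
        n_nodes=n_nodes,
        bands=(ALPHA,),
        sampling_rate=100.0,
        duration=30.0,
        baseline_corr=0.3,
        affected_edge_count=0,
        effect_delta=0.0,
        leakage_lambda=0.0,
        seed=seed,
    )
    subjects, manifest, _ = en.generate_cohort(cfg)
    rows = []
    is_case = []
    for s in subjects:
        per_band, _ = en.subject_pipeline(
            s.timecourses["alpha"], bands=[ALPHA]
        )
        rows.append(per_band["alpha"].edge_vector())
        is_case.append(s.group == "case")
    return np.array(rows), np.array(is_case), manifest
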