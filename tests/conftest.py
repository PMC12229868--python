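"""Shared fixtures: small synthetic cohorts built programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from synovnet.simulate import SimulationConfig, chain_precision, simulate_npx_dataset


def small_config(seed: int = 3, **overrides) -> SimulationConfig:
    """A 2-panel, 20-assay cohort that keeps unit tests fast: planted
    effects on the first three proteins, a 6-protein chain network with a
    control-only tail, one hook-effect assay and one high-LOD assay."""
    effects = np.zeros(20)
    effects[0], effects[1], effects[2] = 1.0, -2.0, 3.4
    cfg = SimulationConfig(
        panels=(("A", 10), ("B", 10)),
        log2_effects=effects,
        network_idx=np.arange(6),
        control_precision=chain_precision(6, [(i, i + 1) for i in range(5)]),
        case_precision=chain_precision(6, [(0, 1), (1, 2)]),
        bad_assay_ids=("B_010",),
        low_detect_assay_ids=("B_009",),
        seed=seed,
    )
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


@pytest.fixture(scope="session")
def small_cohort():
    cfg = small_config(seed=3)
    npx, samples, truth = simulate_npx_dataset(cfg)
    return cfg, npx, samples, truth


def de_long_table(
    rng: np.random.Generator,
    deltas: np.ndarray,
    n_per_group: int = 12,
    person_sd: float = 0.3,
    residual_sd: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Minimal (long table, samples) pair for differential-abundance
    simulations: planted case-minus-control shifts, no covariate effects."""
    p = deltas.size
    n = 2 * n_per_group
    persons = [f"p{i:03d}" for i in range(n)]
    group = np.array(["control"] * n_per_group + ["OA"] * n_per_group)
    samples = pd.DataFrame(
        {
            "person_id": persons,
            "group": group,
            "age": rng.uniform(55, 80, n).round(1),
            "sex": np.where(rng.random(n) < 0.5, "F", "M"),
            "bmi": rng.normal(27, 4, n).round(1),
        }
    )
    mu = rng.uniform(2, 10, p)
    intercepts = rng.normal(0, person_sd, n)
    values = (
        mu[None, :]
        + np.outer(group == "OA", deltas)
        + intercepts[:, None]
        + rng.normal(0, residual_sd, (n, p))
    )
    long = pd.DataFrame(
        {
            "person_id": np.repeat(persons, p),
            "assay_id": np.tile([f"P{j}" for j in range(p)], n),
            "npx": values.ravel(),
        }
    )
    return long, samples
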