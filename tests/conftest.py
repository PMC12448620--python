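"""Shared fixtures: packaged trial table and random valid parameter draws."""

from __future__ import annotations

import numpy as np
import pytest

from geostoich import GSParameters, load_table1
from geostoich.errors import InfeasibleParametersError


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def table1_by_exp(table1):
    by_exp: dict[str, list] = {}
    for t in table1:
        by_exp.setdefault(t.experiment_id, []).append(t)
    return by_exp


def draw_valid_parameters(rng: np.random.Generator) -> GSParameters:
    """One random parameter set from broad physiological ranges.

    theta_Z is drawn at or above theta_V (homeostasis constraint); SDA is
    kept below the level at which absorption cannot cover it, so reverse
    mode is feasible for almost every draw (the rare leftover infeasible
    combination is re-drawn by the caller).
    """
    theta_v = rng.uniform(3.0, 4.5)
    return GSParameters(
        theta_V=theta_v,
        theta_Z=theta_v * rng.uniform(1.0, 1.8),
        sigma_SDA=rng.uniform(0.0, 0.25),
        r_B=rng.uniform(0.0, 0.01),
        xi_basal=rng.uniform(0.0, 0.01),
        f_V=rng.uniform(0.0, 1.0),
        k_N=rng.uniform(0.3, 1.0),
        phi=rng.uniform(0.0, 1.0),
        beta_V=rng.uniform(0.5, 1.0),
        beta_H=rng.uniform(0.5, 1.0),
    )


def sample_feasible_parameters(n: int, seed: int) -> list[GSParameters]:
    """n parameter sets for which reverse mode is feasible at G=0.02."""
    from geostoich import reverse_mode

    rng = np.random.default_rng(seed)
    out: list[GSParameters] = []
    while len(out) < n:
        p = draw_valid_parameters(rng)
        try:
            reverse_mode(0.02, p)
        except InfeasibleParametersError:
            continue
        out.append(p)
    return out
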