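"""Geometric Stoichiometry consumer model: coupled carbon/nitrogen budgets.

The consumer ingests two macromolecule currencies, protein (carbon intake
``I_V``, with fixed protein C:N ``theta_V``) and a pooled non-nitrogenous
macromolecule (lipid/carbohydrate carbon intake ``I_H``).  The consumer holds
its body C:N at ``theta_Z`` (strict homeostasis), so growing at specific rate
``G`` (day^-1, carbon-specific) requires nitrogen at rate ``G/theta_Z`` and
carbon at rate ``G``.  Energetic costs are specific dynamic action (a
fraction ``sigma_SDA`` of intake carbon respired), basal costs ``xi_basal``
and biomass turnover ``r_B``; a fraction ``f_V`` of the energetic demand is
met by catabolising protein, with a metabolic surcharge ``(1 + phi)`` on the
protein carbon so used.  Net protein synthesis efficiency ``k_N`` inflates
the protein requirement for growth and turnover by ``1/k_N``; the overhead
carbon is respired and its nitrogen excreted.  Absorption efficiencies
``beta_V``/``beta_H`` split ingested from egested material.

Budget equations (reverse mode solves these as a linear 2x2 system in
``I_V``, ``I_H``; forward mode evaluates them with a Liebig minimum rule):

    C_E     = sigma_SDA * (I_V + I_H) + xi_basal            (energetic demand)
    beta_V * I_V = theta_V * (G + r_B) / (theta_Z * k_N)
                   + f_V * (1 + phi) * C_E                  (protein pathway)
    beta_H * I_H = (1 - theta_V/theta_Z) * (G + r_B)
                   + (1 - f_V) * C_E                        (non-protein pathway)

With ``sda_base="absorbed"`` the SDA term is ``sigma_SDA * (beta_V I_V +
beta_H I_H)`` instead.  Every evaluation closes the elemental books exactly:

    C:  I_V + I_H      = G + R + F_C
    N:  I_V / theta_V  = G / theta_Z + U_N + F_N
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import Literal

import numpy as np

from .errors import InfeasibleParametersError, InvalidArgumentError, InvalidParameterError

__all__ = [
    "GSParameters",
    "IntakePair",
    "BudgetLedger",
    "reverse_mode",
    "forward_mode",
    "n_budget",
    "DEFAULT_PARAMETERS",
]

_PARAM_BOUNDS = {
    # name: (low, high, low_open, high_open)
    "theta_V": (0.0, math.inf, True, True),
    "theta_Z": (0.0, math.inf, True, True),
    "sigma_SDA": (0.0, 1.0, False, True),
    "r_B": (0.0, math.inf, False, True),
    "xi_basal": (0.0, math.inf, False, True),
    "f_V": (0.0, 1.0, False, False),
    "k_N": (0.0, 1.0, True, False),
    "phi": (0.0, math.inf, False, True),
    "beta_V": (0.0, 1.0, True, False),
    "beta_H": (0.0, 1.0, True, False),
}


@dataclass(frozen=True)
class GSParameters:
    """All constants and per-feed parameters of the consumer model.

    Defaults: ``theta_V=3.7`` is the framework's default protein C:N;
    ``beta_V=0.69`` is the framework's default protein absorption efficiency
    (used where a feed's digestibility was not measured).  ``theta_Z``,
    ``sigma_SDA``, ``r_B`` and ``xi_basal`` are study-level configuration
    with broadly physiological placeholder values; runs should log them.
    """

    theta_V: float = 3.7       # protein C:N, mol C (mol N)^-1
    theta_Z: float = 4.5       # consumer body C:N, mol C (mol N)^-1
    sigma_SDA: float = 0.1     # fraction of intake C respired as SDA
    r_B: float = 0.001         # biomass turnover, day^-1
    xi_basal: float = 0.002    # other basal costs, mol C (mol C)^-1 day^-1
    f_V: float = 0.0           # fraction of energetic costs met by protein
    k_N: float = 1.0           # net protein synthesis efficiency
    phi: float = 0.0           # metabolic penalty on protein used for energy
    beta_V: float = 0.69       # protein absorption efficiency
    beta_H: float = 0.69       # non-N macromolecule absorption efficiency
    sda_base: Literal["ingested", "absorbed"] = "ingested"

    def __post_init__(self) -> None:
        for name, (lo, hi, lo_open, hi_open) in _PARAM_BOUNDS.items():
            v = getattr(self, name)
            ok = (v > lo if lo_open else v >= lo) and (v < hi if hi_open else v <= hi)
            if not ok:
                raise InvalidParameterError(
                    f"{name}={v} outside admissible range "
                    f"{'(' if lo_open else '['}{lo}, {hi}{')' if hi_open else ']'}"
                )
        if self.theta_Z < self.theta_V:
            raise InvalidParameterError(
                f"theta_Z={self.theta_Z} < theta_V={self.theta_V}: a consumer "
                "more N-rich than protein is outside this model's scope"
            )
        if self.sda_base not in ("ingested", "absorbed"):
            raise InvalidParameterError(f"sda_base={self.sda_base!r}")

    def replace(self, **changes: float) -> "GSParameters":
        """Copy with fields replaced (re-validated)."""
        return replace(self, **changes)


DEFAULT_PARAMETERS = GSParameters()


@dataclass(frozen=True)
class IntakePair:
    """Protein (I_V) and non-nitrogenous (I_H) carbon intake rates."""

    I_V: float
    I_H: float

    def __post_init__(self) -> None:
        if self.I_V < 0 or self.I_H < 0:
            raise InvalidArgumentError(
                f"intakes must be >= 0, got I_V={self.I_V}, I_H={self.I_H}"
            )

    @property
    def total(self) -> float:
        return self.I_V + self.I_H

    def __iter__(self):
        return iter((self.I_V, self.I_H))


@dataclass(frozen=True)
class BudgetLedger:
    """Full C and N budget of one model evaluation.

    Carbon entries are mol C (mol C)^-1 day^-1, nitrogen entries
    mol N (mol C)^-1 day^-1.  ``R`` is total respiration (SDA + basal +
    synthesis overhead + penalty + respired surplus), ``F_C``/``F_N`` faecal
    (egested) carbon/nitrogen, ``U_N`` excreted (metabolic) nitrogen.
    """

    G: float
    C_E: float
    R: float
    F_C: float
    F_N: float
    U_N: float
    mode: Literal["forward", "reverse"]
    limiting: Literal["protein", "non-protein", "balanced"]
    maintenance_deficit: bool = False


def _system(G: float, p: GSParameters):
    """Coefficients of the 2x2 linear intake system  M @ (I_V, I_H) = rhs."""
    a = p.f_V * (1.0 + p.phi)          # protein share of energy, with penalty
    b = 1.0 - p.f_V
    demand = G + p.r_B
    q = p.theta_V * demand / (p.theta_Z * p.k_N) + a * p.xi_basal
    h = (1.0 - p.theta_V / p.theta_Z) * demand + b * p.xi_basal
    s = p.sigma_SDA
    if p.sda_base == "ingested":
        m = np.array([[p.beta_V - a * s, -a * s], [-b * s, p.beta_H - b * s]])
    else:  # SDA charged on absorbed carbon
        m = np.array(
            [
                [p.beta_V * (1.0 - a * s), -a * s * p.beta_H],
                [-b * s * p.beta_V, p.beta_H * (1.0 - b * s)],
            ]
        )
    return m, np.array([q, h])


def _energetic_cost(iv: float, ih: float, p: GSParameters) -> float:
    if p.sda_base == "ingested":
        base = iv + ih
    else:
        base = p.beta_V * iv + p.beta_H * ih
    return p.sigma_SDA * base + p.xi_basal


def _close_ledger(
    iv: float,
    ih: float,
    G: float,
    p: GSParameters,
    mode: str,
    limiting: str,
    deficit: bool = False,
) -> BudgetLedger:
    """Close both elemental budgets around (intakes, growth) by residuals.

    Faecal flows are the unabsorbed fractions; respiration and excretion are
    the exact C and N residuals, so conservation holds to machine precision
    by construction (the model guarantees they are nonnegative).
    """
    f_c = (1.0 - p.beta_V) * iv + (1.0 - p.beta_H) * ih
    f_n = (1.0 - p.beta_V) * iv / p.theta_V
    r = iv + ih - G - f_c
    u_n = iv / p.theta_V - G / p.theta_Z - f_n
    tol = 1e-12 * max(1.0, iv + ih)
    if r < -tol or u_n < -tol / p.theta_V:
        raise InfeasibleParametersError(
            f"negative budget residual (R={r}, U_N={u_n}); "
            "growth exceeds what absorption can supply"
        )
    return BudgetLedger(
        G=G,
        C_E=_energetic_cost(iv, ih, p),
        R=max(r, 0.0),
        F_C=f_c,
        F_N=f_n,
        U_N=max(u_n, 0.0),
        mode=mode,  # type: ignore[arg-type]
        limiting=limiting,  # type: ignore[arg-type]
        maintenance_deficit=deficit,
    )


def reverse_mode(G: float, p: GSParameters) -> tuple[IntakePair, BudgetLedger]:
    """Back-calculate the intakes required to grow at rate ``G``.

    Solves the linear budget system for the unique intake pair at which the
    protein and non-protein pathways exactly meet the growth, turnover and
    energetic demands ("balanced" rails).  Raises
    :class:`~geostoich.errors.InfeasibleParametersError` when the system is
    singular (SDA swallows more carbon than absorption supplies) or a
    negative intake would be required.
    """
    if G < 0:
        raise InvalidArgumentError(f"growth rate must be >= 0, got {G}")
    m, rhs = _system(G, p)
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    if det <= 1e-14:
        raise InfeasibleParametersError(
            "intake system is singular: specific dynamic action plus energy "
            f"routing leaves no net absorbed carbon (det={det:.3e})"
        )
    iv = (rhs[0] * m[1, 1] - m[0, 1] * rhs[1]) / det
    ih = (m[0, 0] * rhs[1] - m[1, 0] * rhs[0]) / det
    if iv < 0 or ih < 0:
        which = "protein (I_V)" if iv < 0 else "non-protein (I_H)"
        raise InfeasibleParametersError(
            f"required {which} intake is negative ({iv:.3e}, {ih:.3e}): the "
            "other pathway already oversupplies this one's demand"
        )
    intake = IntakePair(iv, ih)
    ledger = _close_ledger(iv, ih, G, p, "reverse", "balanced")
    return intake, ledger


def reverse_intakes_grid(
    G: float,
    *,
    theta_V: float,
    theta_Z: float,
    sigma_SDA: float,
    r_B: float,
    xi_basal: float,
    sda_base: str,
    f_V: np.ndarray,
    k_N: np.ndarray,
    phi: np.ndarray,
    beta_V: np.ndarray,
    beta_H: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised reverse-mode intake solve over arrays of feed parameters.

    Same closed form as :func:`reverse_mode`; infeasible entries (singular
    system or negative solution) come back as NaN.  Used by the calibration
    grid search; array arguments broadcast against each other.
    """
    a = f_V * (1.0 + phi)
    b = 1.0 - f_V
    demand = G + r_B
    q = theta_V * demand / (theta_Z * k_N) + a * xi_basal
    h = (1.0 - theta_V / theta_Z) * demand + b * xi_basal
    s = sigma_SDA
    if sda_base == "ingested":
        m00 = beta_V - a * s
        m01 = -a * s * np.ones_like(b)
        m10 = -b * s * np.ones_like(a)
        m11 = beta_H - b * s
    else:
        m00 = beta_V * (1.0 - a * s)
        m01 = -a * s * beta_H
        m10 = -b * s * beta_V
        m11 = beta_H * (1.0 - b * s)
    det = m00 * m11 - m01 * m10
    with np.errstate(divide="ignore", invalid="ignore"):
        iv = (q * m11 - m01 * h) / det
        ih = (m00 * h - m10 * q) / det
    bad = (det <= 1e-14) | (iv < 0) | (ih < 0)
    iv = np.where(bad, np.nan, iv)
    ih = np.where(bad, np.nan, ih)
    return iv, ih


def forward_mode(intake: IntakePair, p: GSParameters) -> BudgetLedger:
    """Compute achievable growth and the waste budget from known intakes.

    Growth is the Liebig minimum of what the protein and non-protein
    pathways can each support after energetic costs; surplus substrate
    carbon is respired and surplus protein nitrogen excreted.  When either
    pathway cannot even cover its share of maintenance the ledger comes back
    with ``G=0`` and ``maintenance_deficit=True`` (not an exception).
    """
    iv, ih = intake.I_V, intake.I_H
    c_e = _energetic_cost(iv, ih, p)
    protein_avail = p.beta_V * iv - p.f_V * (1.0 + p.phi) * c_e
    nonprot_avail = p.beta_H * ih - (1.0 - p.f_V) * c_e
    if protein_avail < 0 or nonprot_avail < 0:
        limiting = "protein" if protein_avail < nonprot_avail else "non-protein"
        return _close_ledger(iv, ih, 0.0, p, "forward", limiting, deficit=True)

    g_v = p.k_N * p.theta_Z * protein_avail / p.theta_V - p.r_B
    x = 1.0 - p.theta_V / p.theta_Z
    if x == 0.0:
        g_h = math.inf  # homeostasis needs no non-protein C beyond energy
    else:
        g_h = nonprot_avail / x - p.r_B

    g = min(g_v, g_h)
    if math.isclose(g_v, g_h, rel_tol=1e-9, abs_tol=1e-15):
        limiting = "balanced"
    elif g_v < g_h:
        limiting = "protein"
    else:
        limiting = "non-protein"
    deficit = g < 0
    return _close_ledger(iv, ih, max(g, 0.0), p, "forward", limiting, deficit=deficit)


def n_budget(
    intake: IntakePair, ledger: BudgetLedger, p: GSParameters
) -> tuple[float, float, float, float]:
    """Nitrogen bookkeeping of one evaluation.

    Returns ``(absorbed_N, retained_N, F_N, U_N)`` with
    ``absorbed_N = beta_V I_V / theta_V`` and ``retained_N = G / theta_Z``;
    the conservation identity ``I_V/theta_V = G/theta_Z + U_N + F_N`` holds
    by construction of the ledger.
    """
    absorbed_n = p.beta_V * intake.I_V / p.theta_V
    retained_n = ledger.G / p.theta_Z
    return absorbed_n, retained_n, ledger.F_N, ledger.U_N
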