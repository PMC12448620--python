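"""Faecal nitrogenous waste: stoichiometric model vs conventional estimator.

Two estimators of faecal N output (mol N (mol C)^-1 day^-1) per feed:

* conventional fixed-ratio bioenergetics: ``I_V * (1 - AD_N) / 3.87`` — the
  undigested share of crude-protein intake divided by the feed-protein C:N
  ratio; needs a measured protein digestibility ``AD_N``;
* the consumer model run forward on the observed intakes with calibrated
  parameters, whose ledger's faecal N is the unabsorbed protein converted at
  the model's protein C:N (default 3.7).

"N waste" here is faecal (egested) N only; metabolically excreted N (U_N)
is tracked separately in the ledger and never folded in, so the two
estimators measure the same stream.  Experiment-level contrasts are percent
differences of per-experiment mean waste, always reported in both
directions because percent change is asymmetric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations
from typing import Mapping, Sequence

import pandas as pd

from .conversions import DEFAULT_CONSTANTS, Constants, TrialRecord
from .errors import InvalidArgumentError
from .model import GSParameters, IntakePair, forward_mode

__all__ = [
    "WasteRecord",
    "conventional_n_waste",
    "gs_n_waste",
    "compare_methods",
    "experiment_contrasts",
    "feed_cn_ratio",
]


@dataclass(frozen=True)
class WasteRecord:
    """One feed's faecal-N estimate under one method."""

    experiment_id: str
    feed_label: str
    method: str  # "gs" | "conventional"
    n_waste: float  # mol N (mol C)^-1 day^-1
    feed_CN: float | None = None  # mol C (mol N)^-1, for plotting axes
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_waste < 0:
            raise InvalidArgumentError(f"n_waste must be >= 0, got {self.n_waste}")


def conventional_n_waste(
    I_V: float,
    AD_N: float | None,
    protein_cn: float = 3.87,
) -> float | None:
    """Fixed-ratio faecal N: ``I_V * (1 - AD_N) / protein_cn``.

    Returns ``None`` (explicitly not computable) when the protein
    digestibility was not measured — the estimator has no stoichiometric
    budget to fall back on.
    """
    if I_V < 0:
        raise InvalidArgumentError(f"I_V must be >= 0, got {I_V}")
    if AD_N is None:
        return None
    if not 0.0 <= AD_N <= 1.0:
        raise InvalidArgumentError(f"AD_N={AD_N} outside [0, 1]")
    return I_V * (1.0 - AD_N) / protein_cn


def gs_n_waste(
    trial: TrialRecord,
    calibrated: GSParameters,
    protein_cn: float | None = None,
) -> WasteRecord:
    """Model faecal N from a forward run on the trial's observed intakes.

    The ledger's faecal N is unabsorbed protein at the model protein C:N
    (``calibrated.theta_V``); pass ``protein_cn`` to restate it on another
    ratio (e.g. 3.87 to share the conventional estimator's denominator).
    A maintenance deficit in the forward run does not suppress the waste
    estimate; it is surfaced in ``flags``.
    """
    ledger = forward_mode(
        IntakePair(trial.protein_intake_IV, trial.lipid_intake_IH), calibrated
    )
    n_waste = ledger.F_N
    flags: list[str] = []
    if protein_cn is not None and protein_cn != calibrated.theta_V:
        n_waste = n_waste * calibrated.theta_V / protein_cn
        flags.append(f"converted-at-CN={protein_cn}")
    if ledger.maintenance_deficit:
        flags.append("maintenance-deficit")
    cn, approx = feed_cn_ratio(trial)
    if approx:
        flags.append("feed-CN-approximate")
    return WasteRecord(
        experiment_id=trial.experiment_id,
        feed_label=trial.feed_label,
        method="gs",
        n_waste=n_waste,
        feed_CN=cn,
        flags=tuple(flags),
    )


def compare_methods(
    trials: Sequence[TrialRecord],
    calibrations: Mapping[str, GSParameters],
    constants: Constants = DEFAULT_CONSTANTS,
) -> tuple[pd.DataFrame, float]:
    """Per-feed GS-vs-conventional comparison and its mean percent difference.

    ``calibrations`` maps feed label to that feed's calibrated parameters.
    Feeds without a measured protein digestibility cannot feed the
    conventional estimator; they are skipped with a warning and excluded
    from the mean.  Percent difference is ``100 * (GS - conv) / conv``.
    """
    rows = []
    for t in trials:
        conv = conventional_n_waste(
            t.protein_intake_IV, t.protein_digestibility_ADN, constants.feed_protein_CN
        )
        if conv is None:
            warnings.warn(
                f"feed {t.feed_label}: no protein digestibility; conventional "
                "estimate not computable, excluded from comparison",
                stacklevel=2,
            )
            continue
        gs = gs_n_waste(t, calibrations[t.feed_label])
        rows.append(
            {
                "experiment": t.experiment_id,
                "feed": t.feed_label,
                "gs_n_waste": gs.n_waste,
                "conventional_n_waste": conv,
                "pct_difference": 100.0 * (gs.n_waste - conv) / conv,
            }
        )
    table = pd.DataFrame(rows)
    mean_pct = float(table["pct_difference"].mean()) if len(table) else float("nan")
    return table, mean_pct


def experiment_contrasts(waste: Sequence[WasteRecord]) -> pd.DataFrame:
    """Pairwise percent contrasts of per-experiment mean waste.

    Every ordered pair (A, B) gets a row with
    ``pct = 100 * (mean_A - mean_B) / mean_B``; both directions are printed
    because the contrast is asymmetric (means 2 vs 1 give +100% one way and
    -50% the other).  Empty experiments are excluded with a warning.
    """
    groups: dict[str, list[float]] = {}
    for w in waste:
        groups.setdefault(w.experiment_id, []).append(w.n_waste)
    means = {}
    for exp, values in groups.items():
        if not values:
            warnings.warn(f"experiment {exp} has no waste records", stacklevel=2)
            continue
        means[exp] = sum(values) / len(values)
    rows = [
        {
            "experiment_a": a,
            "experiment_b": b,
            "mean_a": means[a],
            "mean_b": means[b],
            "pct_a_vs_b": 100.0 * (means[a] - means[b]) / means[b],
        }
        for a, b in permutations(sorted(means), 2)
    ]
    return pd.DataFrame(rows)


def feed_cn_ratio(
    trial: TrialRecord,
    total_c_intake: float | None = None,
    constants: Constants = DEFAULT_CONSTANTS,
) -> tuple[float, bool]:
    """Feed C:N ratio, mol C (mol N)^-1, with an "approximate" flag.

    Feed N is crude-protein N, ``I_V / 3.87``.  When only the two tabulated
    intakes exist the carbon numerator is ``I_V + I_H`` (protein + lipid
    carbon only, so the value underestimates whole-feed C:N and the flag is
    set); pass ``total_c_intake`` when full composition is known.
    """
    if trial.protein_intake_IV == 0:
        raise InvalidArgumentError(
            f"feed {trial.feed_label}: C:N undefined at zero protein intake"
        )
    n_intake = trial.protein_intake_IV / constants.feed_protein_CN
    if total_c_intake is not None:
        return total_c_intake / n_intake, False
    return (trial.protein_intake_IV + trial.lipid_intake_IH) / n_intake, True
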