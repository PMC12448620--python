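"""Unit conversions and trial-table I/O for the Geometric Stoichiometry model.

Feeding-trial measurements arrive in grams and proportions; the consumer
model works in biomass-specific molar carbon units, mol C (mol C)^-1 day^-1.
This module holds the conversion constants, the two intake conversions
(crude-protein carbon and lipid carbon), and a CSV reader/writer for trial
tables.  A table of slipper-lobster (*Thenus australiensis*) feeding trials
covering three experiments (protein sources; phospholipid inclusion; fresh
blue-mussel inclusion) is packaged as a fixture and loaded with
:func:`load_table1`.

Conventions
-----------
* Crude protein mass = nitrogen mass x 6.25.
* 75% of lipid (triglyceride) mass is carbon.
* Feed protein C:N = 3.87 mol C (mol N)^-1 (used for unit conversion and the
  conventional waste estimator; the physiological budget uses the model
  default 3.7, see :mod:`geostoich.model`).
* 1 g of lobster contains 0.41 g carbon.
* Molar masses: N 14.007, C 12.011 g mol^-1.

Missing digestibilities (printed as dashes in the source tables) are carried
as ``None`` and must be handled explicitly downstream, never imputed.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .errors import InvalidArgumentError, ParseError, SchemaError

__all__ = [
    "Constants",
    "TrialRecord",
    "crude_protein_from_nitrogen",
    "consumer_mass_to_molC",
    "compute_protein_intake_IV",
    "compute_lipid_intake_IH",
    "load_trials",
    "write_trials",
    "load_table1",
    "TRIAL_COLUMNS",
]

#: Fixed CSV dialect: these columns, UTF-8, "." decimal. The only accepted schema.
TRIAL_COLUMNS = (
    "experiment",
    "feed",
    "protein_intake",
    "lipid_intake",
    "protein_digestibility",
    "lipid_digestibility",
    "growth_rate",
    "growth_sd",
)

#: Cell values treated as "measurement absent" (the tables print a dash).
_MISSING = {"", "-", "–", "—", "na", "nan", "NA", "NaN"}


@dataclass(frozen=True)
class Constants:
    """Conversion constants between mass-based assays and model currencies.

    All values are overridable (they are configuration, not physics), but a
    change should be logged by the caller; every field must stay positive.
    """

    protein_per_N: float = 6.25        # g crude protein per g nitrogen
    lipid_C_fraction: float = 0.75     # g C per g lipid (triglyceride)
    feed_protein_CN: float = 3.87      # mol C (mol N)^-1 of feed protein
    lobster_C_content: float = 0.41    # g C per g lobster (wet mass as recorded)
    molar_mass_N: float = 14.007       # g mol^-1
    molar_mass_C: float = 12.011       # g mol^-1

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, float)) and v > 0):
                raise InvalidArgumentError(
                    f"Constants.{f.name} must be strictly positive, got {v!r}"
                )

    def with_overrides(self, **overrides: float) -> "Constants":
        """Return a copy with some constants replaced (validated again)."""
        return replace(self, **overrides)


DEFAULT_CONSTANTS = Constants()


@dataclass
class TrialRecord:
    """One feed treatment of a feeding trial (a row of the trial table).

    Intakes are biomass-specific molar carbon rates, mol C (mol C)^-1 day^-1;
    digestibilities are fractions in [0, 1] or ``None`` when not measured;
    growth is the specific growth rate in day^-1.
    """

    experiment_id: str
    feed_label: str
    protein_intake_IV: float
    lipid_intake_IH: float
    protein_digestibility_ADN: float | None = None
    lipid_digestibility: float | None = None
    growth_rate_G: float = 0.0
    growth_sd: float | None = None

    def __post_init__(self) -> None:
        if self.protein_intake_IV < 0 or self.lipid_intake_IH < 0:
            raise InvalidArgumentError(
                f"trial {self.experiment_id}/{self.feed_label}: intakes must be >= 0"
            )
        for name in ("protein_digestibility_ADN", "lipid_digestibility"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise InvalidArgumentError(
                    f"trial {self.experiment_id}/{self.feed_label}: "
                    f"{name}={v} outside [0, 1]"
                )
        g = self.growth_rate_G
        if not (g == g and abs(g) != float("inf")):  # finite check without numpy
            raise InvalidArgumentError(
                f"trial {self.experiment_id}/{self.feed_label}: growth must be finite"
            )


def crude_protein_from_nitrogen(
    n_mass: float, constants: Constants = DEFAULT_CONSTANTS
) -> float:
    """Crude protein mass (g) from nitrogen mass (g): N x 6.25."""
    if n_mass < 0:
        raise InvalidArgumentError(f"nitrogen mass must be >= 0, got {n_mass}")
    return n_mass * constants.protein_per_N


def consumer_mass_to_molC(
    mass_g: float, constants: Constants = DEFAULT_CONSTANTS
) -> float:
    """Consumer body mass (g lobster) to mol C: mass x 0.41 / 12.011."""
    if mass_g < 0:
        raise InvalidArgumentError(f"consumer mass must be >= 0, got {mass_g}")
    return mass_g * constants.lobster_C_content / constants.molar_mass_C


def compute_protein_intake_IV(
    feed_intake: float,
    prop_protein_N: float,
    consumer_mass: float,
    constants: Constants = DEFAULT_CONSTANTS,
    record: str | None = None,
) -> float:
    """Protein (crude protein carbon) intake I_V, mol C (mol C)^-1 day^-1.

    ``feed_intake`` is the apparent feed intake (g day^-1), ``prop_protein_N``
    the fraction of feed mass that is protein nitrogen, and ``consumer_mass``
    the consumer body size in mol C.  The feed-protein C:N ratio (3.87)
    converts protein N to protein C.
    """
    if feed_intake < 0 or prop_protein_N < 0 or consumer_mass < 0:
        raise InvalidArgumentError("intake conversion inputs must be >= 0")
    if consumer_mass == 0:
        raise ZeroDivisionError(
            f"consumer mass is zero{f' for record {record}' if record else ''}"
        )
    mol_n = feed_intake * prop_protein_N / constants.molar_mass_N
    return mol_n * constants.feed_protein_CN / consumer_mass


def compute_lipid_intake_IH(
    feed_intake: float,
    prop_lipid_C: float,
    consumer_mass: float,
    constants: Constants = DEFAULT_CONSTANTS,
    record: str | None = None,
) -> float:
    """Lipid carbon intake I_H, mol C (mol C)^-1 day^-1.

    ``prop_lipid_C`` is the fraction of feed mass that is lipid carbon
    (lipid mass fraction x 0.75 when starting from total lipid).
    """
    if feed_intake < 0 or prop_lipid_C < 0 or consumer_mass < 0:
        raise InvalidArgumentError("intake conversion inputs must be >= 0")
    if consumer_mass == 0:
        raise ZeroDivisionError(
            f"consumer mass is zero{f' for record {record}' if record else ''}"
        )
    return feed_intake * prop_lipid_C / constants.molar_mass_C / consumer_mass


# ---------------------------------------------------------------------------
# Trial-table I/O
# ---------------------------------------------------------------------------

def _parse_cell(value: str, row: int, column: str, required: bool) -> float | None:
    text = value.strip()
    if text in _MISSING:
        if required:
            raise ParseError(f"row {row}, column {column!r}: value is required")
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise ParseError(
            f"row {row}, column {column!r}: cannot parse {value!r} as a number"
        ) from exc


def _records_from_reader(reader: csv.DictReader) -> list[TrialRecord]:
    if reader.fieldnames is None or tuple(reader.fieldnames) != TRIAL_COLUMNS:
        raise SchemaError(
            f"header must be exactly {','.join(TRIAL_COLUMNS)}; "
            f"got {reader.fieldnames}"
        )
    records: list[TrialRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(reader, start=2):  # header is line 1
        exp = row["experiment"].strip()
        feed = row["feed"].strip()
        if not exp or not feed:
            raise SchemaError(f"row {i}: experiment and feed labels are required")
        key = (exp, feed)
        if key in seen:
            raise SchemaError(f"row {i}: duplicate (experiment, feed) pair {key}")
        seen.add(key)
        records.append(
            TrialRecord(
                experiment_id=exp,
                feed_label=feed,
                protein_intake_IV=_parse_cell(row["protein_intake"], i, "protein_intake", True),
                lipid_intake_IH=_parse_cell(row["lipid_intake"], i, "lipid_intake", True),
                protein_digestibility_ADN=_parse_cell(
                    row["protein_digestibility"], i, "protein_digestibility", False
                ),
                lipid_digestibility=_parse_cell(
                    row["lipid_digestibility"], i, "lipid_digestibility", False
                ),
                growth_rate_G=_parse_cell(row["growth_rate"], i, "growth_rate", True),
                growth_sd=_parse_cell(row["growth_sd"], i, "growth_sd", False),
            )
        )
    return records


def load_trials(path: str | Path) -> list[TrialRecord]:
    """Read a trial table (fixed CSV schema) into :class:`TrialRecord` rows.

    Missing digestibility cells (empty or a dash) become ``None``.  Malformed
    numeric cells raise :class:`~geostoich.errors.ParseError` naming row and
    column; duplicated (experiment, feed) pairs raise
    :class:`~geostoich.errors.SchemaError`.
    """
    with open(path, "r", encoding="utf-8", newline="") as fh:
        return _records_from_reader(csv.DictReader(fh))


def _format(value: float | None) -> str:
    if value is None:
        return ""
    return repr(float(value))  # shortest round-trippable decimal


def write_trials(records: Iterable[TrialRecord], path: str | Path) -> None:
    """Write records in the fixed CSV schema; round-trips losslessly."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRIAL_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.experiment_id,
                    r.feed_label,
                    _format(r.protein_intake_IV),
                    _format(r.lipid_intake_IH),
                    _format(r.protein_digestibility_ADN),
                    _format(r.lipid_digestibility),
                    _format(r.growth_rate_G),
                    _format(r.growth_sd),
                ]
            )


def load_table1() -> list[TrialRecord]:
    """Load the packaged slipper-lobster feeding-trial table (17 feeds).

    Experiment 1 compares protein sources (FM, KM, SBM, SWM) and is the only
    experiment with measured protein digestibilities; Experiment 2 (D1-D6)
    varies phosphatidylcholine inclusion with measured lipid digestibility
    only; Experiment 3 (BM0%-BM25%, BMHS) varies fresh blue-mussel inclusion
    with no measured digestibilities.
    """
    text = (
        resources.files("geostoich.data")
        .joinpath("table1_trials.csv")
        .read_text(encoding="utf-8")
    )
    return _records_from_reader(csv.DictReader(io.StringIO(text)))
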