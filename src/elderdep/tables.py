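"""Expert-elicited Contact and Impact probability tables.

The simulator is parameterised by three column-stochastic tables per expert:

* two 5x5 *Contact* tables — the relative importance (in percent) of five
  sources of social support (Spouse, Friends & Children, professional
  Caregiver, Neighbors, Loneliness) at five late-life stages (Retirement,
  Death of spouse, Moving, Functional decline, Institutionalization); one
  table describes the social landscape of a non-depressive/neutral person,
  the other that of a depressive person;
* one 3x5 *Impact* table — the probability (in percent) that a contact with
  each source improves (+1), leaves unchanged (0), or worsens (-1) the
  person's depressive status.

Tables are stored and exchanged in percent (columns summing to 100) and only
converted to probabilities at sampling time.  This module validates raw
questionnaire grids, derives the adjusted tables the scenarios need (a
spouse-free table for singles, a pessimistic table for low socio-economic
status), classifies respondents into the two expert typologies, and
aggregates a panel by cell-wise averaging and interquartile consensus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Row order of Contact tables / column order of the Impact table.
SOURCES = ("Spouse", "FriendsChildren", "Caregiver", "Neighbors", "Loneliness")
#: Column order of Contact tables (the five late-life stages).
STAGES = (
    "Retirement",
    "SpouseDeath",
    "Moving",
    "FunctionalDecline",
    "Institutionalization",
)
#: Row order of the Impact table and the impact value each row encodes.
IMPACT_ROWS = ("Positive", "Neutral", "Negative")
IMPACT_VALUES = (1, 0, -1)

#: Stage columns (0-based) for the three events following the spouse's death.
POST_WIDOWHOOD_COLS = (2, 3, 4)

# questionnaire rounding slack: column sums within this of 100 are silently
# renormalized, larger deviations are renormalized with a WARNING
_SILENT_TOL = 0.5
_SUM_TOL = 1e-9


class TableValidationError(ValueError):
    """Raised when a raw grid cannot form a valid probability table."""


def _check_grid(values: np.ndarray, shape: tuple[int, int], what: str) -> None:
    if values.shape != shape:
        raise TableValidationError(
            f"{what}: expected shape {shape}, got {values.shape}"
        )
    if not np.all(np.isfinite(values)):
        raise TableValidationError(f"{what}: non-finite cell")
    if np.any(values < 0):
        r, c = np.argwhere(values < 0)[0]
        raise TableValidationError(
            f"{what}: negative cell at row {r}, column {c} ({values[r, c]})"
        )
    sums = values.sum(axis=0)
    bad = np.where(np.abs(sums - 100.0) > _SUM_TOL)[0]
    if bad.size:
        raise TableValidationError(
            f"{what}: columns {bad.tolist()} do not sum to 100 (sums "
            f"{sums[bad].tolist()}); use validate_table() to normalize"
        )


@dataclass(frozen=True)
class ContactTable:
    """5x5 column-stochastic table: sources x late-life stages, percent."""

    values: np.ndarray
    mood_context: str = "non_depressive"

    def __post_init__(self) -> None:
        vals = np.array(self.values, dtype=float)
        _check_grid(vals, (5, 5), "ContactTable")
        if self.mood_context not in ("non_depressive", "depressive"):
            raise TableValidationError(
                f"mood_context must be non_depressive or depressive, "
                f"got {self.mood_context!r}"
            )
        vals.flags.writeable = False
        object.__setattr__(self, "values", vals)

    def column(self, stage: int) -> np.ndarray:
        """Percent column for a 1-based stage index."""
        return self.values[:, stage - 1]

    def probabilities(self) -> np.ndarray:
        return self.values / 100.0


@dataclass(frozen=True)
class ImpactTable:
    """3x5 column-stochastic table: impact sign x sources, percent."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.array(self.values, dtype=float)
        _check_grid(vals, (3, 5), "ImpactTable")
        vals.flags.writeable = False
        object.__setattr__(self, "values", vals)

    def column(self, source: int) -> np.ndarray:
        """Percent column for a 1-based source index."""
        return self.values[:, source - 1]

    def probabilities(self) -> np.ndarray:
        return self.values / 100.0


@dataclass
class ExpertRecord:
    """One respondent: profile fields plus the three elicited tables."""

    expert_id: str
    age: float
    occupation: str
    is_healthcare: bool
    years_experience: float
    elderly_contacts_last_week: int
    contact_nondep: ContactTable
    contact_dep: ContactTable
    impact: ImpactTable

    def __post_init__(self) -> None:
        if self.elderly_contacts_last_week < 0:
            raise TableValidationError(
                f"expert {self.expert_id}: negative contact count"
            )
        if self.contact_nondep.mood_context != "non_depressive":
            raise TableValidationError(
                f"expert {self.expert_id}: contact_nondep has wrong mood context"
            )
        if self.contact_dep.mood_context != "depressive":
            raise TableValidationError(
                f"expert {self.expert_id}: contact_dep has wrong mood context"
            )


@dataclass(frozen=True)
class TypologyLabel:
    """Expert typology on two independent axes.

    contact_type: Type1 (no elderly contact last week), Type2 (contact and a
    health-care occupation), Type3 (contact, non-health-care occupation).
    spouse_type: TypeA if the spouse has strictly zero importance in all
    three post-widowhood stages of both Contact tables, else TypeB.
    """

    contact_type: str
    spouse_type: str

    def __post_init__(self) -> None:
        if self.contact_type not in ("Type1", "Type2", "Type3"):
            raise ValueError(f"bad contact_type {self.contact_type!r}")
        if self.spouse_type not in ("TypeA", "TypeB"):
            raise ValueError(f"bad spouse_type {self.spouse_type!r}")


def validate_table(
    raw: Sequence | np.ndarray,
    kind: str,
    mood_context: str = "non_depressive",
) -> ContactTable | ImpactTable:
    """Validate and column-normalize a raw questionnaire grid.

    Each column is rescaled to sum to exactly 100.  Columns whose raw sum
    deviates from 100 by more than 0.5 (beyond questionnaire rounding) are
    logged at WARNING with the rescaling factor.

    Raises
    ------
    TableValidationError
        on a wrong shape, a negative cell, or an all-zero column.
    """
    arr = np.array(raw, dtype=float)
    shape = (5, 5) if kind == "contact" else (3, 5) if kind == "impact" else None
    if shape is None:
        raise ValueError(f"kind must be 'contact' or 'impact', got {kind!r}")
    if arr.shape != shape:
        raise TableValidationError(f"expected {shape} grid, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise TableValidationError("non-finite cell in table")
    if np.any(arr < 0):
        r, c = np.argwhere(arr < 0)[0]
        raise TableValidationError(
            f"negative cell at row {r}, column {c}: {arr[r, c]}"
        )
    sums = arr.sum(axis=0)
    zero = np.where(sums <= 0)[0]
    if zero.size:
        raise TableValidationError(
            f"all-zero column(s) {zero.tolist()}: cannot renormalize"
        )
    for j, s in enumerate(sums):
        if abs(s - 100.0) > _SILENT_TOL:
            logger.warning(
                "column %d sums to %.4f; rescaling by %.6f", j, s, 100.0 / s
            )
    normalized = arr * (100.0 / sums)
    if kind == "contact":
        return ContactTable(normalized, mood_context=mood_context)
    return ImpactTable(normalized)


def derive_single_contact_table(t: ContactTable) -> ContactTable:
    """Spouse-free Contact table for singles.

    The spousal row is zeroed and, per column, the four remaining sources are
    reweighted to constitute 100% of the social landscape.
    """
    spouse = t.values[0]
    if np.any(spouse >= 100.0 - _SUM_TOL):
        j = int(np.argmax(spouse))
        raise TableValidationError(
            f"column {j}: spouse holds the whole column ({spouse[j]}%), "
            "nothing to reweight"
        )
    out = t.values * (100.0 / (100.0 - spouse))
    out[0] = 0.0
    return ContactTable(out, mood_context=t.mood_context)


def derive_ses_impact_table(t: ImpactTable) -> ImpactTable:
    """Impact table for low socio-economic status individuals.

    Per source, a quarter of the positive and of the neutral impact
    probabilities is transferred onto the negative impact; column mass is
    conserved exactly.
    """
    pos, neu, neg = t.values
    return ImpactTable(
        np.vstack([0.75 * pos, 0.75 * neu, neg + 0.25 * pos + 0.25 * neu])
    )


def classify_expert(e: ExpertRecord) -> TypologyLabel:
    """Assign the two typology labels to one respondent.

    Zero elderly contacts in the past week takes precedence over occupation
    (Type1); otherwise health-care professionals are Type2 and the rest
    Type3.  TypeA requires a strictly null spousal importance in the three
    stages following the spouse's death in *both* mood-context tables.
    """
    if e.elderly_contacts_last_week == 0:
        contact_type = "Type1"
    elif e.is_healthcare:
        contact_type = "Type2"
    else:
        contact_type = "Type3"
    cols = list(POST_WIDOWHOOD_COLS)
    spouse_after = np.concatenate(
        [e.contact_nondep.values[0, cols], e.contact_dep.values[0, cols]]
    )
    spouse_type = "TypeA" if np.all(spouse_after <= _SUM_TOL) else "TypeB"
    return TypologyLabel(contact_type=contact_type, spouse_type=spouse_type)


def typology_predicate(label: str) -> Callable[[ExpertRecord], bool]:
    """Predicate selecting experts of one typology ('Type2', 'TypeA', ...).

    'TypeAll' (or 'All') selects every expert.
    """
    if label in ("TypeAll", "All", "all"):
        return lambda e: True
    if label in ("Type1", "Type2", "Type3"):
        return lambda e: classify_expert(e).contact_type == label
    if label in ("TypeA", "TypeB"):
        return lambda e: classify_expert(e).spouse_type == label
    raise ValueError(f"unknown typology label {label!r}")


def average_tables(
    panel: Iterable[ExpertRecord],
    filter: Callable[[ExpertRecord], bool] | str | None = None,
) -> tuple[ContactTable, ContactTable, ImpactTable]:
    """Cell-wise mean of the three tables over a (filtered) expert panel.

    The mean of column-stochastic tables is column-stochastic, so no
    renormalization is applied after averaging.
    """
    if isinstance(filter, str):
        name, filter = filter, typology_predicate(filter)
    else:
        name = getattr(filter, "__name__", repr(filter))
    selected = [e for e in panel if filter is None or filter(e)]
    if not selected:
        raise ValueError(f"no experts match typology filter {name}")
    nondep = np.mean([e.contact_nondep.values for e in selected], axis=0)
    dep = np.mean([e.contact_dep.values for e in selected], axis=0)
    imp = np.mean([e.impact.values for e in selected], axis=0)
    return (
        ContactTable(nondep, mood_context="non_depressive"),
        ContactTable(dep, mood_context="depressive"),
        ImpactTable(imp),
    )


def consensus_iqr(panel: Sequence[ExpertRecord]) -> dict[str, np.ndarray]:
    """Cell-wise interquartile range (Q3 - Q1) over the panel.

    Quartiles use linear interpolation between order statistics (numpy's
    default, the 'type 7' convention).  Returns arrays keyed
    'contact_nondep', 'contact_dep', 'impact'.
    """
    if len(panel) < 2:
        raise ValueError(f"need at least 2 experts for consensus, got {len(panel)}")

    def iqr(stack: np.ndarray) -> np.ndarray:
        q1, q3 = np.percentile(stack, [25, 75], axis=0)
        return q3 - q1

    return {
        "contact_nondep": iqr(np.stack([e.contact_nondep.values for e in panel])),
        "contact_dep": iqr(np.stack([e.contact_dep.values for e in panel])),
        "impact": iqr(np.stack([e.impact.values for e in panel])),
    }


# ---------------------------------------------------------------------------
# CSV layouts
#
# Expert panel tables file: one row per (expert_id, table, row_label) with
# five value columns c1..c5 (stage columns for contact tables, source columns
# for the impact table).  Profile file: one row per expert.
# ---------------------------------------------------------------------------

_TABLE_KEYS = ("contact_nondep", "contact_dep", "impact")
_VALUE_COLS = ["c1", "c2", "c3", "c4", "c5"]


def panel_to_frames(panel: Sequence[ExpertRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expert panel -> (tables frame, profiles frame)."""
    rows = []
    for e in panel:
        grids = {
            "contact_nondep": (e.contact_nondep.values, SOURCES),
            "contact_dep": (e.contact_dep.values, SOURCES),
            "impact": (e.impact.values, IMPACT_ROWS),
        }
        for key, (vals, labels) in grids.items():
            for label, row in zip(labels, vals):
                rows.append([e.expert_id, key, label, *row])
    tables = pd.DataFrame(
        rows, columns=["expert_id", "table", "row_label", *_VALUE_COLS]
    )
    profiles = pd.DataFrame(
        {
            "expert_id": [e.expert_id for e in panel],
            "age": [e.age for e in panel],
            "occupation": [e.occupation for e in panel],
            "is_healthcare": [e.is_healthcare for e in panel],
            "years_experience": [e.years_experience for e in panel],
            "elderly_contacts_last_week": [
                e.elderly_contacts_last_week for e in panel
            ],
        }
    )
    return tables, profiles


def write_panel_csv(
    panel: Sequence[ExpertRecord], tables_path, profiles_path
) -> None:
    tables, profiles = panel_to_frames(panel)
    tables.to_csv(tables_path, index=False)
    profiles.to_csv(profiles_path, index=False)


def _grid_from_rows(sub: pd.DataFrame, labels: Sequence[str], what: str) -> np.ndarray:
    missing = [l for l in labels if l not in set(sub["row_label"])]
    if missing:
        raise TableValidationError(f"{what}: missing row(s) {missing}")
    sub = sub.set_index("row_label")
    try:
        grid = sub.loc[list(labels), _VALUE_COLS].to_numpy(dtype=float)
    except ValueError as err:
        raise TableValidationError(f"{what}: non-numeric cell ({err})") from err
    return grid


def read_panel_csv(tables_path, profiles_path) -> list[ExpertRecord]:
    """Load an expert panel from the two CSV files; validates every table."""
    tables = pd.read_csv(tables_path)
    profiles = pd.read_csv(profiles_path)
    need = {"expert_id", "table", "row_label", *_VALUE_COLS}
    if not need.issubset(tables.columns):
        raise TableValidationError(
            f"tables CSV missing columns {sorted(need - set(tables.columns))}"
        )
    panel = []
    for _, prof in profiles.iterrows():
        eid = prof["expert_id"]
        sub = tables[tables["expert_id"] == eid]
        grids = {}
        for key in _TABLE_KEYS:
            labels = IMPACT_ROWS if key == "impact" else SOURCES
            part = sub[sub["table"] == key]
            if part.empty:
                raise TableValidationError(f"expert {eid}: no {key} rows")
            grids[key] = _grid_from_rows(part, labels, f"expert {eid} {key}")
        panel.append(
            ExpertRecord(
                expert_id=str(eid),
                age=float(prof["age"]),
                occupation=str(prof["occupation"]),
                is_healthcare=bool(prof["is_healthcare"]),
                years_experience=float(prof["years_experience"]),
                elderly_contacts_last_week=int(prof["elderly_contacts_last_week"]),
                contact_nondep=validate_table(grids["contact_nondep"], "contact"),
                contact_dep=validate_table(
                    grids["contact_dep"], "contact", mood_context="depressive"
                ),
                impact=validate_table(grids["impact"], "impact"),
            )
        )
    return panel


def write_tables_csv(
    path, contact_nondep: ContactTable, contact_dep: ContactTable, impact: ImpactTable
) -> None:
    """Write an aggregated (e.g. typology-mean) table set to one CSV."""
    rows = []
    for key, vals, labels in (
        ("contact_nondep", contact_nondep.values, SOURCES),
        ("contact_dep", contact_dep.values, SOURCES),
        ("impact", impact.values, IMPACT_ROWS),
    ):
        for label, row in zip(labels, vals):
            rows.append([key, label, *row])
    pd.DataFrame(rows, columns=["table", "row_label", *_VALUE_COLS]).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_tables_csv(path) -> tuple[ContactTable, ContactTable, ImpactTable]:
    df = pd.read_csv(path)
    need = {"table", "row_label", *_VALUE_COLS}
    if not need.issubset(df.columns):
        raise TableValidationError(
            f"tables CSV missing columns {sorted(need - set(df.columns))}"
        )
    grids = {}
    for key in _TABLE_KEYS:
        labels = IMPACT_ROWS if key == "impact" else SOURCES
        part = df[df["table"] == key]
        if part.empty:
            raise TableValidationError(f"no rows for table {key!r}")
        grids[key] = _grid_from_rows(part, labels, key)
    return (
        validate_table(grids["contact_nondep"], "contact"),
        validate_table(grids["contact_dep"], "contact", mood_context="depressive"),
        validate_table(grids["impact"], "impact"),
    )
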