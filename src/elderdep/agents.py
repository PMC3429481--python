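"""Per-year individual dynamics.

One call to :func:`step_individual` advances one elderly person by one
simulated year:

1. a new widow in her first year of bereavement skips social contact and
   stays depressive (the *historic* flag);
2. otherwise the current life stage selects a column of the Contact table
   (depressive-context table if DS = -1, spouse-free table for singles), a
   contact source is drawn, the Impact table column of that source yields an
   impact in {+1, 0, -1}, and the depressive status is updated by clamped
   addition;
3. age increases by exactly one year.

The depressive status (DS) is a three-state variable: +1 non-depressive,
0 neutral, -1 depressive.  For a person frozen at one stage the yearly DS
process is a three-state Markov chain whose transition matrix
:func:`stage_transition_matrix` builds explicitly; this closed form is the
independent oracle the test-suite checks the sampling path against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tables import (
    ContactTable,
    ImpactTable,
    derive_ses_impact_table,
    derive_single_contact_table,
)

NON_DEPRESSIVE, NEUTRAL, DEPRESSIVE = 1, 0, -1

#: Impact value encoded by each Impact-table row.
_IMPACT_OF_ROW = (1, 0, -1)

WOMAN, MAN = "woman", "man"
SINGLE, MARRIED, WIDOW = "single", "married", "widow"


class AgePath:
    """Ages at which this person's life events occur.

    Events absent from a person's trajectory (spouse death for singles;
    moving/decline/institutionalization for the married before widowhood)
    are ``None``.  Present events are strictly increasing.
    """

    __slots__ = (
        "retirement",
        "spouse_death",
        "moving",
        "functional_decline",
        "institutionalization",
    )

    def __init__(
        self,
        retirement: float,
        spouse_death: float | None = None,
        moving: float | None = None,
        functional_decline: float | None = None,
        institutionalization: float | None = None,
    ):
        self.retirement = retirement
        self.spouse_death = spouse_death
        self.moving = moving
        self.functional_decline = functional_decline
        self.institutionalization = institutionalization

    def events(self) -> list[tuple[int, float]]:
        """(1-based stage column, age) for every scheduled event."""
        out = [(1, self.retirement)]
        for col, age in (
            (2, self.spouse_death),
            (3, self.moving),
            (4, self.functional_decline),
            (5, self.institutionalization),
        ):
            if age is not None:
                out.append((col, age))
        return out

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"AgePath(ret={self.retirement}, widow={self.spouse_death}, "
            f"move={self.moving}, decline={self.functional_decline}, "
            f"inst={self.institutionalization})"
        )


class Person:
    """One elderly individual (ten state variables plus bookkeeping)."""

    __slots__ = (
        "person_id",
        "age",
        "gender",
        "ds",
        "marital_status",
        "spouse",
        "age_path",
        "historic",
        "low_ses",
        "alive",
        "path_finalized",
    )

    def __init__(
        self,
        person_id: int,
        age: int,
        gender: str,
        ds: int,
        marital_status: str,
        age_path: AgePath,
        spouse: "Person | None" = None,
        historic: int = 0,
        low_ses: bool = False,
    ):
        self.person_id = person_id
        self.age = age
        self.gender = gender
        self.ds = ds
        self.marital_status = marital_status
        self.spouse = spouse
        self.age_path = age_path
        self.historic = historic
        self.low_ses = low_ses
        self.alive = True
        # set once a permanent single's moving/decline/institutionalization
        # ages have been drawn (or, scenario 1, at creation)
        self.path_finalized = False

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"Person(id={self.person_id}, age={self.age}, {self.gender}, "
            f"ds={self.ds:+d}, {self.marital_status}, historic={self.historic})"
        )


class TableSet:
    """Sampling bundle: the two Contact tables, the Impact table, and the
    derived spouse-free and low-SES variants, with per-column cumulative
    percentages precomputed for fast inverse-CDF draws."""

    def __init__(
        self,
        contact_nondep: ContactTable,
        contact_dep: ContactTable,
        impact: ImpactTable,
    ):
        self.contact_nondep = contact_nondep
        self.contact_dep = contact_dep
        self.impact = impact
        # spouse-free derivation is impossible when a column is 100% spousal;
        # such a table is still usable for married/widowed persons, so the
        # error is deferred until a single actually samples from it
        try:
            self.single_nondep = derive_single_contact_table(contact_nondep)
            self.single_dep = derive_single_contact_table(contact_dep)
        except Exception as err:  # noqa: BLE001 - re-raised on use
            self.single_nondep = self.single_dep = None
            self._single_error = err
        else:
            self._single_error = None
        self.impact_ses = derive_ses_impact_table(impact)

        def cum(t):
            return tuple(tuple(np.cumsum(t.values[:, j])) for j in range(5))

        class _RaiseOnUse:
            def __init__(self, err):
                self._err = err

            def __getitem__(self, _):
                raise self._err

        # keyed [depressive?][single?] -> per-stage cumulative columns
        self._contact_cum = {
            (False, False): cum(contact_nondep),
            (True, False): cum(contact_dep),
            (False, True): cum(self.single_nondep)
            if self.single_nondep is not None
            else _RaiseOnUse(self._single_error),
            (True, True): cum(self.single_dep)
            if self.single_dep is not None
            else _RaiseOnUse(self._single_error),
        }
        # keyed [low_ses?] -> per-source cumulative columns
        self._impact_cum = {False: cum(impact), True: cum(self.impact_ses)}


def select_stage(p: Person) -> int:
    """1-based Contact-table column for the person's current life period.

    The column of the most recently reached life event applies; before any
    event the retirement column (1) applies, and the institutionalization
    column (5) applies until the end of life.  Events a person never
    experiences (spouse death for singles; post-widowhood events for the
    married until actual bereavement) are simply absent from the age path,
    so singles skip column 2 and married persons stay in column 1 until
    widowhood.
    """
    ap = p.age_path
    a = p.age
    if ap.institutionalization is not None and ap.institutionalization <= a:
        return 5
    if ap.functional_decline is not None and ap.functional_decline <= a:
        return 4
    if ap.moving is not None and ap.moving <= a:
        return 3
    if ap.spouse_death is not None and ap.spouse_death <= a:
        return 2
    return 1


def draw_contact(table: ContactTable, stage: int, rng: np.random.Generator) -> int:
    """Sample a 1-based contact source from the stage column."""
    cum = np.cumsum(table.column(stage))
    u = rng.random() * cum[-1]
    return int(np.searchsorted(cum, u, side="right")) + 1


def draw_impact(table: ImpactTable, source: int, rng: np.random.Generator) -> int:
    """Sample an impact in {+1, 0, -1} from the source column."""
    cum = np.cumsum(table.column(source))
    u = rng.random() * cum[-1]
    return _IMPACT_OF_ROW[int(np.searchsorted(cum, u, side="right"))]


def update_ds(ds: int, impact: int) -> int:
    """Clamped addition: DS values of +2/-2 are set back to +1/-1."""
    new = ds + impact
    if new > 1:
        return 1
    if new < -1:
        return -1
    return new


def step_individual(p: Person, tables: TableSet, rng: np.random.Generator) -> Person:
    """Advance one living person by one year (in place; returns ``p``).

    Draws are consumed in fixed order (contact, then impact) so a seeded
    stream reproduces a trajectory exactly.  First-year widows skip the
    contact/impact draws, keep DS = -1 and merely age.
    """
    if not p.alive:
        raise ValueError(f"cannot step dead person {p.person_id}")
    if p.historic:
        p.historic = 0
        p.age += 1
        return p
    stage = select_stage(p)
    ccum = tables._contact_cum[(p.ds == -1, p.marital_status == SINGLE)][stage - 1]
    u = rng.random() * 100.0
    src = 0
    while src < 4 and u >= ccum[src]:
        src += 1
    icum = tables._impact_cum[p.low_ses][src]
    u = rng.random() * 100.0
    row = 0
    while row < 2 and u >= icum[row]:
        row += 1
    p.ds = update_ds(p.ds, _IMPACT_OF_ROW[row])
    p.age += 1
    return p


def stage_transition_matrix(tables: TableSet, stage: int, low_ses: bool = False) -> np.ndarray:
    """Exact yearly DS transition matrix for a person frozen at one stage.

    Rows/columns are ordered (-1, 0, +1).  From state s the impact
    distribution is the contact-mixture q_s(i) = sum_src C_s(src) I(i|src),
    with C_s the depressive-context column iff s = -1 (spouse-free variants
    are not used here: the frozen person is notionally married), and the
    next state is clamp(s + i).  Used as the independent closed-form oracle
    for the sampling path.
    """
    states = (-1, 0, 1)
    P = np.zeros((3, 3))
    for i, s in enumerate(states):
        contact = tables.contact_dep if s == -1 else tables.contact_nondep
        c = contact.column(stage) / 100.0
        imp = (tables.impact_ses if low_ses else tables.impact).probabilities()
        # q[impact value] = sum over sources of P(source) * P(impact | source)
        q = {val: float(imp[row] @ c) for row, val in enumerate(_IMPACT_OF_ROW)}
        for val, prob in q.items():
            nxt = update_ds(s, val)
            P[i, states.index(nxt)] += prob
    return P


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a small transition matrix by linear solve."""
    n = P.shape[0]
    A = np.vstack([P.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return pi


def time_average_variance(P: np.ndarray, f: np.ndarray) -> float:
    """Asymptotic variance of the time-average of f along the chain.

    The yearly DS indicator is autocorrelated, so the Monte-Carlo standard
    error of a long-run fraction is sqrt(sigma^2 / n) with
    sigma^2 = Var_pi(f) + 2 sum_{t>=1} Cov(f_0, f_t), computed here exactly
    through the Poisson equation (I - P) h = f - mu.
    """
    pi = stationary_distribution(P)
    mu = float(pi @ f)
    ft = f - mu
    n = P.shape[0]
    B = np.vstack([np.eye(n) - P, pi])
    h, *_ = np.linalg.lstsq(B, np.concatenate([ft, [0.0]]), rcond=None)
    return float(pi @ (2.0 * ft * h - ft * ft))
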