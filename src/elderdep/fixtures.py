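"""Synthetic stand-ins for the study's input data, plus loaders.

Three inputs feed the simulator: an expert panel (two Contact tables and
one Impact table per respondent, with profile fields), a mortality-rate
schedule by age, and an empirical prevalence-by-age curve with 95%
confidence intervals.  The generators here produce seed-deterministic
synthetic versions of all three — column-stochastic Dirichlet tables, a
Gompertz-like mortality curve, and a linear-in-age prevalence with Wald
binomial intervals — so the whole pipeline runs and is testable without any
external download.  The loaders ingest CSV transcriptions of the real
extracts when available; synthetic and real inputs share the same layouts.

The synthetic panel is not a statistical imitation of any real expert
sample; it exists so that every downstream stage has valid, informative
inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .agents import TableSet
from .population import PrevalenceCurve
from .tables import (
    ExpertRecord,
    POST_WIDOWHOOD_COLS,
    read_panel_csv,
    validate_table,
)


@dataclass
class FixtureSpec:
    """Parameters of the synthetic input generators.

    ``n_experts`` defaults to 28 (the size of the elicited panel) with 18/28
    of respondents constructed spouse-zero (the TypeA share).  Dirichlet
    concentration 2.0 yields informative, non-degenerate columns.  The
    mortality curve rate(age) = min(1, a e^{b (age-65)}) with a = 0.013,
    b = 0.09 spans roughly 1.4% at 66 to 15% at 92, a realistic elderly
    schedule.  The synthetic survey curve rises linearly from about 12% at
    65 to 25% at 92 with Wald 95% intervals at 200 respondents per age.
    """

    n_experts: int = 28
    table_concentration: float = 2.0
    spouse_zero_fraction: float = 18 / 28
    gompertz_a: float = 0.013
    gompertz_b: float = 0.09
    emp_slope: float = 0.005
    emp_intercept: float = -0.205
    emp_n_per_age: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_experts < 1:
            raise ValueError("n_experts must be >= 1")
        if not 0.0 <= self.spouse_zero_fraction <= 1.0:
            raise ValueError("spouse_zero_fraction must be in [0,1]")
        if self.table_concentration <= 0:
            raise ValueError("table_concentration must be positive")
        if self.gompertz_a <= 0 or self.gompertz_b < 0:
            raise ValueError("gompertz parameters must be positive")
        if self.emp_n_per_age < 50:
            raise ValueError("emp_n_per_age must be >= 50 (survey inclusion rule)")


def _random_grid(rng: np.random.Generator, nrow: int, alpha: float) -> np.ndarray:
    cols = rng.dirichlet(np.full(nrow, alpha), size=5).T * 100.0
    return cols


def gen_expert_panel(spec: FixtureSpec, rng: np.random.Generator | None = None) -> list[ExpertRecord]:
    """Seed-deterministic synthetic expert panel.

    Each table column is a symmetric-Dirichlet draw scaled to percent.  A
    ``spouse_zero_fraction`` subset of experts is constructed TypeA: the
    spousal row is zeroed (and the column renormalized) in the three
    post-widowhood stages of both Contact tables.  Profiles are drawn so
    that all three contact typologies occur in any panel of >= 3.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = spec.n_experts
    n_typea = int(round(spec.spouse_zero_fraction * n))
    typea_idx = set(rng.choice(n, size=n_typea, replace=False).tolist())
    panel = []
    occupations_hc = ("nurse", "geriatrician", "general practitioner")
    occupations_other = ("teacher", "engineer", "social science student")
    for i in range(n):
        grids = {}
        for key in ("contact_nondep", "contact_dep"):
            g = _random_grid(rng, 5, spec.table_concentration)
            if i in typea_idx:
                for c in POST_WIDOWHOOD_COLS:
                    g[0, c] = 0.0
                    g[:, c] *= 100.0 / g[:, c].sum()
            grids[key] = g
        impact_grid = _random_grid(rng, 3, spec.table_concentration)
        # guarantee each contact typology is represented
        if i == 0:
            contacts, healthcare = 0, True
        elif i == 1:
            contacts, healthcare = 1 + int(rng.poisson(4)), True
        elif i == 2:
            contacts, healthcare = 1 + int(rng.poisson(4)), False
        else:
            contacts = int(rng.poisson(4))
            healthcare = bool(rng.random() < 0.5)
        occupation = rng.choice(occupations_hc if healthcare else occupations_other)
        panel.append(
            ExpertRecord(
                expert_id=f"E{i:03d}",
                age=float(np.round(rng.uniform(22, 65), 1)),
                occupation=str(occupation),
                is_healthcare=healthcare,
                years_experience=float(np.round(rng.uniform(0, 30), 1)),
                elderly_contacts_last_week=contacts,
                contact_nondep=validate_table(grids["contact_nondep"], "contact"),
                contact_dep=validate_table(
                    grids["contact_dep"], "contact", mood_context="depressive"
                ),
                impact=validate_table(impact_grid, "impact"),
            )
        )
    return panel


def gen_mortality(spec: FixtureSpec) -> pd.DataFrame:
    """Gompertz-like mortality rates, ages 66-92: columns (age, rate)."""
    ages = np.arange(66, 93)
    rates = np.minimum(
        1.0, spec.gompertz_a * np.exp(spec.gompertz_b * (ages - 65.0))
    )
    return pd.DataFrame({"age": ages, "rate": rates})


def gen_empirical_curve(
    spec: FixtureSpec, rng: np.random.Generator | None = None
) -> PrevalenceCurve:
    """Synthetic survey prevalence curve with Wald 95% binomial intervals.

    The mean is linear in age (clipped to (0, 1)); per-age observed
    proportions are binomial draws at ``emp_n_per_age`` respondents, so the
    curve carries realistic sampling noise around the trend.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    ages = np.arange(65, 93)
    mean = np.clip(spec.emp_intercept + spec.emp_slope * ages, 1e-3, 1 - 1e-3)
    n = spec.emp_n_per_age
    observed = rng.binomial(n, mean) / n
    half = 1.96 * np.sqrt(observed * (1 - observed) / n)
    return PrevalenceCurve(
        ages=ages,
        prevalence=observed,
        ci_low=np.clip(observed - half, 0.0, 1.0),
        ci_high=np.clip(observed + half, 0.0, 1.0),
    )


def fixture_table_set(spec: FixtureSpec, typology: str = "TypeAll") -> TableSet:
    """Panel-mean TableSet for one typology from the synthetic panel."""
    from .tables import average_tables

    panel = gen_expert_panel(spec)
    nondep, dep, imp = average_tables(panel, typology)
    return TableSet(nondep, dep, imp)


# ---------------------------------------------------------------------------
# loaders for (transcribed) supplementary extracts
# ---------------------------------------------------------------------------


def load_mortality(path) -> pd.DataFrame:
    """Mortality CSV with columns (age, rate), ages 66-92 required."""
    df = pd.read_csv(path)
    if not {"age", "rate"}.issubset(df.columns):
        raise ValueError(f"{path}: mortality CSV needs columns age, rate")
    df["age"] = df["age"].astype(int)
    missing = sorted(set(range(66, 93)) - set(df["age"]))
    if missing:
        raise ValueError(f"{path}: mortality CSV missing ages {missing}")
    bad = df[(df["rate"] < 0) | (df["rate"] > 1)]
    if not bad.empty:
        lines = (bad.index + 2).tolist()  # +2: header + 0-based
        raise ValueError(f"{path}: rates outside [0,1] at line(s) {lines}")
    return df[["age", "rate"]].sort_values("age").reset_index(drop=True)


def load_empirical(path) -> PrevalenceCurve:
    """Empirical curve CSV with columns (age, mean|prevalence, ci_low, ci_high)."""
    df = pd.read_csv(path)
    mean_col = "mean" if "mean" in df.columns else "prevalence"
    need = {"age", mean_col, "ci_low", "ci_high"}
    if not need.issubset(df.columns):
        raise ValueError(
            f"{path}: empirical CSV missing columns "
            f"{sorted(need - set(df.columns))}"
        )
    df["age"] = df["age"].astype(int)
    missing = sorted(set(range(65, 93)) - set(df["age"]))
    if missing:
        raise ValueError(f"{path}: empirical CSV missing ages {missing}")
    df = df.sort_values("age")
    df = df[df["age"].between(65, 92)]
    return PrevalenceCurve(
        ages=df["age"].to_numpy(),
        prevalence=df[mean_col].to_numpy(float),
        ci_low=df["ci_low"].to_numpy(float),
        ci_high=df["ci_high"].to_numpy(float),
    )


def load_supplementary(
    expert_tables=None, expert_profiles=None, mortality=None, empirical=None
) -> dict:
    """Load whichever transcribed inputs are provided.

    Returns a dict with keys among 'panel', 'mortality', 'empirical'.
    """
    out = {}
    if expert_tables is not None or expert_profiles is not None:
        if expert_tables is None or expert_profiles is None:
            raise ValueError("panel loading needs both tables and profiles CSVs")
        out["panel"] = read_panel_csv(expert_tables, expert_profiles)
    if mortality is not None:
        out["mortality"] = load_mortality(mortality)
    if empirical is not None:
        out["empirical"] = load_empirical(empirical)
    return out


def write_input_set(spec: FixtureSpec, out_dir) -> dict[str, Path]:
    """Write a complete ready-to-run synthetic input set into a directory."""
    from .tables import write_panel_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expert_tables": out / "expert_tables.csv",
        "expert_profiles": out / "expert_profiles.csv",
        "mortality": out / "mortality.csv",
        "empirical": out / "empirical.csv",
    }
    panel = gen_expert_panel(spec)
    write_panel_csv(panel, paths["expert_tables"], paths["expert_profiles"])
    gen_mortality(spec).to_csv(paths["mortality"], index=False, float_format="%.17g")
    curve = gen_empirical_curve(spec)
    df = curve.to_frame().rename(columns={"prevalence": "mean"})
    df.to_csv(paths["empirical"], index=False, float_format="%.17g")
    return paths
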