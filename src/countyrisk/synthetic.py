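"""Synthetic study generator mirroring the two-stage generative model.

Stage 1 is run generatively: county logit vectors are drawn from the
multivariate normal population distribution, transformed to probabilities,
and binomial shooting counts are drawn against race-specific census
populations.  Counties with no simulated shootings are dropped (the model
only includes counties with at least one incident) and recorded in the
truth object.  Stage 2 is run generatively by drawing county covariates
from log-normal-style marginals and setting the true log risk ratio to a
linear function of the logged covariates plus Gaussian residual noise.

Incident-level records can be materialized from the counts (one record per
count unit) with configurable injection of duplicates, out-of-range years,
and unknown races, so the cleaning stage can be exercised and its drop
counts checked against the injected totals.

Default scale: 100 counties with race populations log-uniform between 1e3
and 1e6 and logit means near -11, putting per-4-year shooting
probabilities in a realistic 1e-6..1e-4 band where partial pooling
matters.
"""

from __future__ import annotations

import dataclasses
import json
import string
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .hierarchical import HyperParams, build_cholesky
from .records import (
    Armed,
    CELLS,
    CELL_COLUMNS,
    COVARIATE_COLUMNS,
    POP_COLUMNS,
    Race,
    ShootingRecord,
)
from .regression import PREDICTORS

__all__ = [
    "SyntheticTruth",
    "InjectionReport",
    "default_hyper",
    "generate_counties",
    "generate_records",
    "generate_covariates",
    "simulate_study",
]


def default_hyper() -> HyperParams:
    """Population-level truth used across fixtures.

    Logit means encode armed-vs-unarmed ratios near 3 and a black/white
    unarmed ratio near e^1.2 ~ 3.3, in the spirit of the study's estimates;
    moderate county scatter (sigma 0.5) and a mild positive correlation tie
    the six cells together.
    """
    mu = np.array([-10.8, -9.8, -11.2, -10.2, -12.0, -10.9])
    sigma = np.full(6, 0.5)
    rho = np.full((6, 6), 0.3)
    np.fill_diagonal(rho, 1.0)
    return HyperParams(mu=mu, sigma=sigma, rho=rho)


@dataclasses.dataclass
class SyntheticTruth:
    """Everything needed to reproduce and score a synthetic dataset."""

    mu: np.ndarray
    sigma: np.ndarray
    rho: np.ndarray
    theta_unc: np.ndarray          # (C, 6) logit-scale truth, kept counties
    fips: list[str]
    populations: np.ndarray        # (C, 3)
    dropped_fips: list[str]
    seed: int
    eco_beta: dict[str, float] | None = None
    eco_sigma: float | None = None
    true_log_rr: np.ndarray | None = None

    def to_json(self, path: str | Path) -> None:
        def _clean(v):
            if isinstance(v, np.ndarray):
                return v.tolist()
            return v

        payload = {k: _clean(v) for k, v in dataclasses.asdict(self).items()}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        for key in ("mu", "sigma", "rho", "theta_unc", "populations", "true_log_rr"):
            if payload.get(key) is not None:
                payload[key] = np.asarray(payload[key], dtype=float)
        return cls(**payload)


@dataclasses.dataclass
class InjectionReport:
    """How many noise records of each kind were injected."""

    duplicates: int = 0
    out_of_range_year: int = 0
    unknown_race: int = 0


def _synthetic_fips(i: int) -> str:
    # synthetic FIPS codes: state 90+ avoids real code ranges
    return f"{90 + i // 1000:02d}{i % 1000:03d}"


def generate_counties(
    hyper: HyperParams | None = None,
    populations: np.ndarray | None = None,
    n_counties: int = 100,
    seed: int = 0,
    drop_empty: bool = True,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw county effects and binomial counts from the stage-1 model.

    Returns the counts frame (schema of :mod:`countyrisk.records`) for
    counties with at least one shooting, and the truth object covering the
    kept counties (dropped all-zero counties are listed separately).
    """
    hyper = hyper or default_hyper()
    rng = np.random.default_rng(seed)
    if populations is None:
        populations = np.round(
            10 ** rng.uniform(3, 6, size=(n_counties, 3))
        ).astype(int)
    populations = np.asarray(populations)
    if np.any(populations <= 0):
        raise ValueError("populations must be positive")
    C = populations.shape[0]

    L = build_cholesky(hyper.sigma, hyper.rho)
    z = rng.standard_normal((C, 6))
    theta_unc = np.asarray(hyper.mu, dtype=float) + z @ L.T
    theta = expit(theta_unc)
    race_of_cell = [0, 0, 1, 1, 2, 2]
    n_cell = populations[:, race_of_cell]
    S = rng.binomial(n_cell, theta)

    keep = S.sum(axis=1) > 0
    if not drop_empty and not keep.all():
        raise ValueError("some counties have zero shootings and drop_empty is off")
    all_fips = [_synthetic_fips(i) for i in range(C)]
    kept_fips = [f for f, k in zip(all_fips, keep) if k]
    dropped = [f for f, k in zip(all_fips, keep) if not k]

    counts = pd.DataFrame({
        "fips": kept_fips,
        **{col: S[keep, d] for d, col in enumerate(CELL_COLUMNS)},
        **{col: populations[keep, r] for r, col in enumerate(POP_COLUMNS)},
    })
    truth = SyntheticTruth(
        mu=np.asarray(hyper.mu, dtype=float),
        sigma=np.asarray(hyper.sigma, dtype=float),
        rho=np.asarray(hyper.rho, dtype=float),
        theta_unc=theta_unc[keep],
        fips=kept_fips,
        populations=populations[keep],
        dropped_fips=dropped,
        seed=int(seed),
    )
    return counts, truth


_RACE_TEXT = {"B": "Black", "H": "Hispanic", "W": "White"}
_ARMED_TEXT = {"A": "Armed", "U": "Unarmed"}


def _random_name(rng: np.random.Generator) -> str:
    letters = rng.choice(list(string.ascii_lowercase), size=12)
    return "".join(letters[:6]).capitalize() + " " + "".join(letters[6:]).capitalize()


def _misspell(name: str, rng: np.random.Generator) -> str:
    chars = list(name)
    pos = int(rng.integers(0, len(chars)))
    if chars[pos] == " ":
        pos = max(pos - 1, 0)
    chars[pos] = rng.choice(list(string.ascii_lowercase))
    return "".join(chars)


def generate_records(
    counts: pd.DataFrame,
    seed: int = 0,
    duplicate_rate: float = 0.0,
    year_noise_rate: float = 0.0,
    unknown_race_rate: float = 0.0,
) -> tuple[list[ShootingRecord], InjectionReport]:
    """Materialize one incident record per count unit, plus optional noise.

    With all noise rates zero, cleaning + deduplication + aggregation of the
    output reproduces ``counts`` exactly.  Noise records are *extra* rows:
    duplicates are misspelled copies sharing (year, age, race, county) with
    a source record; year noise and unknown-race records fail cleaning.
    """
    rng = np.random.default_rng(seed)
    records: list[ShootingRecord] = []
    report = InjectionReport()
    for _, row in counts.iterrows():
        fips = str(row["fips"]).zfill(5)
        for (race, armed), col in zip(CELLS, CELL_COLUMNS):
            for _ in range(int(row[col])):
                records.append(ShootingRecord(
                    victim_name=_random_name(rng),
                    year=int(rng.integers(2011, 2015)),
                    race=Race(race),
                    armed=Armed.ARMED if armed == "A" else Armed.UNARMED,
                    county_fips=fips,
                    age=int(rng.integers(18, 61)),
                ))

    extras: list[ShootingRecord] = []
    for rec in records:
        if rng.uniform() < duplicate_rate:
            extras.append(dataclasses.replace(rec, victim_name=_misspell(rec.victim_name, rng)))
            report.duplicates += 1
        if rng.uniform() < year_noise_rate:
            extras.append(dataclasses.replace(
                rec,
                victim_name=_random_name(rng),
                year=int(rng.choice([2009, 2010, 2015, 2016])),
            ))
            report.out_of_range_year += 1
        if rng.uniform() < unknown_race_rate:
            extras.append(dataclasses.replace(
                rec, victim_name=_random_name(rng), race=Race.UNKNOWN
            ))
            report.unknown_race += 1
    # keep duplicates after their sources so "first occurrence" is a source
    rng.shuffle(extras)
    return records + extras, report


def records_to_csv(records: list[ShootingRecord], path: str | Path) -> None:
    pd.DataFrame([
        {
            "name": r.victim_name,
            "year": r.year,
            "race": _RACE_TEXT.get(r.race.value, r.race.value.lower()),
            "armed": {"ARMED": "armed", "UNARMED": "unarmed"}.get(
                r.armed.value, "unclear"
            ),
            "fips": r.county_fips,
            "age": r.age,
        }
        for r in records
    ]).to_csv(path, index=False)


#: log-scale (meanlog, sdlog) marginals for the positive covariates
_COV_MARGINALS = {
    "pop_total": (11.5, 1.2),
    "pct_black": (2.2, 0.8),        # percent of population
    "median_income": (10.7, 0.35),
    "racism_proxy": (0.0, 0.3),
    "assault_rate_W": (2.7, 0.7),   # arrests per 10,000
    "assault_rate_B": (3.2, 0.7),
    "weapons_rate_W": (1.8, 0.7),
    "weapons_rate_B": (2.3, 0.7),
}


def generate_covariates(
    fips: list[str],
    eco_beta: dict[str, float] | None = None,
    eco_sigma: float = 0.2,
    seed: int = 0,
    missing_rate: float = 0.0,
    missing_columns: tuple[str, ...] = ("assault_rate_W", "assault_rate_B",
                                        "weapons_rate_W", "weapons_rate_B"),
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw county covariates and the implied true log risk ratio.

    ``eco_beta`` maps ``"intercept"`` and predictor keys (``pop``, ``pctb``,
    ``inc``, ``gini``, ``grp``, ``ast_w``, ``ast_b``, ``wps_w``, ``wps_b``)
    to true coefficients; the true log risk ratio is the linear predictor on
    logged covariates plus Normal(0, eco_sigma) residual noise.  Missingness
    (mimicking state-level crime-data gaps) is applied to ``missing_columns``
    at ``missing_rate`` after the outcome is formed.
    """
    eco_beta = dict(eco_beta or {"intercept": 1.2})
    rng = np.random.default_rng(seed)
    n = len(fips)
    cov = pd.DataFrame({"fips": [str(f).zfill(5) for f in fips]})
    for col, (m, s) in _COV_MARGINALS.items():
        cov[col] = np.exp(rng.normal(m, s, size=n))
    cov["gini"] = rng.uniform(0.35, 0.55, size=n)
    cov = cov[["fips", *COVARIATE_COLUMNS]]

    linpred = np.full(n, eco_beta.pop("intercept", 0.0))
    for key, coef in eco_beta.items():
        column = PREDICTORS[key][0]
        linpred = linpred + coef * np.log(cov[column].to_numpy())
    true_log_rr = linpred + rng.normal(0.0, eco_sigma, size=n)

    if missing_rate > 0:
        for col in missing_columns:
            mask = rng.uniform(size=n) < missing_rate
            cov.loc[mask, col] = np.nan
    return cov, true_log_rr


def simulate_study(
    out_dir: str | Path,
    n_counties: int = 100,
    seed: int = 0,
    hyper: HyperParams | None = None,
    eco_beta: dict[str, float] | None = None,
    eco_sigma: float = 0.2,
    duplicate_rate: float = 0.0,
    year_noise_rate: float = 0.0,
    unknown_race_rate: float = 0.0,
    missing_rate: float = 0.0,
) -> SyntheticTruth:
    """Write a full synthetic study (records, census, covariates, truth).

    Produces ``records.csv``, ``census.csv``, ``covariates.csv``, and
    ``truth.json`` under ``out_dir``, using the same CSV schemas the reading
    functions consume.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts, truth = generate_counties(hyper=hyper, n_counties=n_counties, seed=seed)
    records, _ = generate_records(
        counts,
        seed=seed + 1,
        duplicate_rate=duplicate_rate,
        year_noise_rate=year_noise_rate,
        unknown_race_rate=unknown_race_rate,
    )
    records_to_csv(records, out / "records.csv")
    pd.DataFrame({
        "fips": truth.fips,
        "pop_black": truth.populations[:, 0],
        "pop_hispanic": truth.populations[:, 1],
        "pop_white": truth.populations[:, 2],
    }).to_csv(out / "census.csv", index=False)
    cov, true_log_rr = generate_covariates(
        truth.fips, eco_beta=eco_beta, eco_sigma=eco_sigma,
        seed=seed + 2, missing_rate=missing_rate,
    )
    cov.to_csv(out / "covariates.csv", index=False)
    truth.eco_beta = dict(eco_beta or {"intercept": 1.2})
    truth.eco_sigma = float(eco_sigma)
    truth.true_log_rr = true_log_rr
    truth.to_json(out / "truth.json")
    return truth
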