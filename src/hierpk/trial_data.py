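"""Data model and I/O for insulin-profile trial data.

A *profile* is one meal-window time series of plasma insulin concentrations
for a given woman, visit and meal, together with its dosing record and
context (body weight, window times).  Profiles carry a covariate row; the
covariate design matrix standardizes continuous factors and expands the
study and mealtime indicators into four mutually exclusive study-by-mealtime
interaction indicators.

External files are plain delimited text:

observations.csv  profile_id, time_min, concentration_pmol_l
dosing.csv        profile_id, kind {basal,bolus}, start_min,
                  end_min_or_duration, amount (U/h for basal, U for bolus)
profiles.csv      profile_id, woman, visit, meal, weight_kg, t_start, t_end,
                  meal_time
covariates.csv    profile_id, one column per factor
covariate_schema.json   {"continuous": [...], "binary": [...],
                         "study": col, "mealtime": col}
exclusions.csv    profile_id, reason   (optional)
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .pk_model import DosingSchedule, ProfileContext

__all__ = [
    "DINNER",
    "BREAKFAST",
    "ProfileKey",
    "Profile",
    "CovariateDesign",
    "Dataset",
    "build_design",
    "read_dataset",
    "write_dataset",
]

DINNER = 1
BREAKFAST = 2

MU_PER_MIN_PER_U_PER_H = 1000.0 / 60.0  # 1 U/h in mU/min
MU_PER_U = 1000.0

INTERACTION_NAMES = (
    "study1_breakfast",
    "study1_dinner",
    "study2_breakfast",
    "study2_dinner",
)


@dataclass(frozen=True, order=True)
class ProfileKey:
    """Hierarchy position of a profile: woman i, visit j, meal k."""

    woman: int
    visit: int
    meal: int  # DINNER or BREAKFAST

    def __post_init__(self):
        if self.meal not in (DINNER, BREAKFAST):
            raise ValueError(f"meal must be {DINNER} (dinner) or {BREAKFAST} (breakfast)")

    @property
    def id(self) -> str:
        meal = "d" if self.meal == DINNER else "b"
        return f"w{self.woman:02d}v{self.visit}{meal}"

    @staticmethod
    def from_id(pid: str) -> "ProfileKey":
        if not (pid.startswith("w") and "v" in pid):
            raise ValueError(f"malformed profile id {pid!r}")
        woman = int(pid[1:3])
        visit = int(pid[4:-1])
        meal = DINNER if pid[-1] == "d" else BREAKFAST
        return ProfileKey(woman, visit, meal)


@dataclass
class Profile:
    """One meal-window time series with its dosing record and context."""

    key: ProfileKey
    times: np.ndarray  # minutes since midnight day 1, strictly increasing
    concentrations: np.ndarray  # pmol/l
    dosing: DosingSchedule
    context: ProfileContext
    meal_time: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if len(self.times) == 0:
            raise ValueError(f"profile {self.key.id} has no observations")
        if len(self.times) != len(self.concentrations):
            raise ValueError("times and concentrations differ in length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"profile {self.key.id}: non-increasing observation times")

    @property
    def n_obs(self) -> int:
        return len(self.times)


@dataclass
class CovariateDesign:
    """Standardized n x c covariate matrix with per-column group labels.

    Continuous columns are centred and scaled to unit sd (means/sds stored so
    subset refits reuse the full-data scaling); binary columns are 0/1; the
    four interaction columns are mutually exclusive study-by-mealtime
    indicators, exactly one equal to 1 per row.
    """

    X: np.ndarray
    names: list[str]
    groups: list[str]  # per column: continuous | binary | interaction
    profile_ids: list[str]
    center: np.ndarray  # per column; 0 for non-continuous
    scale: np.ndarray  # per column; 1 for non-continuous

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    def columns_of(self, group: str) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.groups) if g == group], dtype=int)

    def rows_for(self, profile_ids) -> np.ndarray:
        index = {pid: i for i, pid in enumerate(self.profile_ids)}
        return self.X[[index[p] for p in profile_ids]]

    def destandardize(self, col: int, value: float) -> float:
        return value * self.scale[col] + self.center[col]


@dataclass
class Dataset:
    """All profiles of a trial plus the covariate design and exclusions."""

    profiles: dict[str, Profile]
    design: CovariateDesign | None = None
    raw_factors: pd.DataFrame | None = None
    schema: dict | None = None
    exclusions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        self.profiles = dict(
            sorted(self.profiles.items(), key=lambda kv: kv[1].key)
        )
        if self.design is not None:
            missing = set(self.profiles) - set(self.design.profile_ids)
            extra = set(self.design.profile_ids) - set(self.profiles)
            if missing or extra:
                raise ValueError(
                    f"covariate rows do not match profiles (missing {sorted(missing)},"
                    f" extra {sorted(extra)})"
                )

    @property
    def included_ids(self) -> list[str]:
        return [p for p in self.profiles if p not in self.exclusions]

    def exclude(self, profile_id: str, reason: str) -> None:
        if profile_id not in self.profiles:
            raise KeyError(profile_id)
        self.exclusions[profile_id] = reason

    def subset(self, profile_ids) -> "Dataset":
        """Dataset restricted to the given profiles; the covariate design
        (and its full-data standardization) is carried over unchanged."""
        keep = set(profile_ids)
        return Dataset(
            profiles={p: v for p, v in self.profiles.items() if p in keep},
            design=self.design
            if self.design is None
            else CovariateDesign(
                X=self.design.rows_for([p for p in self.profiles if p in keep]),
                names=self.design.names,
                groups=self.design.groups,
                profile_ids=[p for p in self.profiles if p in keep],
                center=self.design.center,
                scale=self.design.scale,
            ),
            raw_factors=self.raw_factors,
            schema=self.schema,
            exclusions={p: r for p, r in self.exclusions.items() if p in keep},
        )


def build_design(raw_factors: pd.DataFrame, schema: dict) -> CovariateDesign:
    """Assemble the covariate design matrix from a per-profile factor table.

    ``raw_factors`` has one row per profile, indexed by profile id.  The
    schema declares continuous and binary factor columns and names the study
    and mealtime indicator columns, which are replaced by the four
    study-by-mealtime interaction indicators.  Continuous factors are centred
    and scaled over the supplied profiles; no imputation is performed.
    """
    cont = list(schema.get("continuous", []))
    binary = list(schema.get("binary", []))
    study_col = schema.get("study")
    meal_col = schema.get("mealtime")

    for col in cont + binary + [c for c in (study_col, meal_col) if c]:
        if col not in raw_factors.columns:
            raise ValueError(f"factor {col!r} missing from table")
        bad = raw_factors.index[raw_factors[col].isna()]
        if len(bad):
            raise ValueError(f"missing value for factor {col!r} in profile {bad[0]!r}")

    cols, names, groups, centers, scales = [], [], [], [], []
    for col in cont:
        x = raw_factors[col].to_numpy(dtype=float)
        mu, sd = x.mean(), x.std(ddof=0)
        if sd == 0:
            raise ValueError(f"continuous factor {col!r} is constant; cannot standardize")
        cols.append((x - mu) / sd)
        names.append(col)
        groups.append("continuous")
        centers.append(mu)
        scales.append(sd)
    for col in binary:
        x = raw_factors[col].to_numpy(dtype=float)
        if not np.isin(x, (0.0, 1.0)).all():
            raise ValueError(f"binary factor {col!r} has values outside {{0,1}}")
        cols.append(x)
        names.append(col)
        groups.append("binary")
        centers.append(0.0)
        scales.append(1.0)
    if study_col and meal_col:
        s1 = raw_factors[study_col].to_numpy(dtype=float)  # 1 = study 1
        bk = raw_factors[meal_col].to_numpy(dtype=float)  # 1 = breakfast
        for name, ind in zip(
            INTERACTION_NAMES,
            (s1 * bk, s1 * (1 - bk), (1 - s1) * bk, (1 - s1) * (1 - bk)),
        ):
            cols.append(ind)
            names.append(name)
            groups.append("interaction")
            centers.append(0.0)
            scales.append(1.0)

    X = np.column_stack(cols) if cols else np.zeros((len(raw_factors), 0))
    return CovariateDesign(
        X=X,
        names=names,
        groups=groups,
        profile_ids=list(raw_factors.index),
        center=np.array(centers),
        scale=np.array(scales),
    )


def _dosing_to_rows(pid: str, dosing: DosingSchedule) -> list[dict]:
    rows = []
    for s, e, r in dosing.basal_segments:
        rows.append(
            dict(profile_id=pid, kind="basal", start_min=s, end_min_or_duration=e,
                 amount=r / MU_PER_MIN_PER_U_PER_H)
        )
    for s, d, dose in dosing.bolus_events:
        rows.append(
            dict(profile_id=pid, kind="bolus", start_min=s, end_min_or_duration=d,
                 amount=dose / MU_PER_U)
        )
    return rows


def write_dataset(dataset: Dataset, directory: str | Path) -> None:
    """Write the dataset as the delimited files documented in the module
    docstring (lossless round-trip with :func:`read_dataset`)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    obs, dosing_rows, meta = [], [], []
    for pid, prof in dataset.profiles.items():
        for t, y in zip(prof.times, prof.concentrations):
            obs.append(dict(profile_id=pid, time_min=t, concentration_pmol_l=y))
        dosing_rows.extend(_dosing_to_rows(pid, prof.dosing))
        meta.append(
            dict(
                profile_id=pid,
                woman=prof.key.woman,
                visit=prof.key.visit,
                meal=prof.key.meal,
                weight_kg=prof.context.wt,
                t_start=prof.context.t_start,
                t_end=prof.context.t_end,
                meal_time=prof.meal_time,
            )
        )
    pd.DataFrame(obs).to_csv(directory / "observations.csv", index=False)
    pd.DataFrame(dosing_rows).to_csv(directory / "dosing.csv", index=False)
    pd.DataFrame(meta).to_csv(directory / "profiles.csv", index=False)
    if dataset.raw_factors is not None:
        dataset.raw_factors.rename_axis("profile_id").to_csv(directory / "covariates.csv")
        (directory / "covariate_schema.json").write_text(json.dumps(dataset.schema, indent=1))
    if dataset.exclusions:
        pd.DataFrame(
            [dict(profile_id=p, reason=r) for p, r in dataset.exclusions.items()]
        ).to_csv(directory / "exclusions.csv", index=False)


def read_dataset(directory: str | Path, unit_conversion: float = 6.0) -> Dataset:
    """Read a dataset written by :func:`write_dataset`.

    Observations are ordered deterministically by (woman, visit, meal, time).
    Duplicate (profile, time) rows, dosing for unknown profiles and profiles
    without observations are errors.
    """
    directory = Path(directory)
    obs = pd.read_csv(directory / "observations.csv")
    dosing = pd.read_csv(directory / "dosing.csv")
    meta = pd.read_csv(directory / "profiles.csv")

    dup = obs.duplicated(subset=["profile_id", "time_min"])
    if dup.any():
        row = obs[dup].iloc[0]
        raise ValueError(
            f"duplicated time point: profile {row.profile_id} t={row.time_min}"
        )
    known = set(meta.profile_id)
    unknown = set(dosing.profile_id) - known
    if unknown:
        raise ValueError(f"dosing references unknown profiles: {sorted(unknown)}")

    profiles: dict[str, Profile] = {}
    obs_by = dict(tuple(obs.groupby("profile_id")))
    dos_by = dict(tuple(dosing.groupby("profile_id")))
    for row in meta.itertuples():
        pid = row.profile_id
        if pid not in obs_by:
            raise ValueError(f"profile {pid} has no observations")
        o = obs_by[pid].sort_values("time_min")
        d = dos_by.get(pid)
        basal, bolus = [], []
        if d is not None:
            for r in d.itertuples():
                if r.kind == "basal":
                    basal.append(
                        (r.start_min, r.end_min_or_duration, r.amount * MU_PER_MIN_PER_U_PER_H)
                    )
                elif r.kind == "bolus":
                    bolus.append((r.start_min, r.end_min_or_duration, r.amount * MU_PER_U))
                else:
                    raise ValueError(f"unknown dosing kind {r.kind!r}")
        profiles[pid] = Profile(
            key=ProfileKey(int(row.woman), int(row.visit), int(row.meal)),
            times=o.time_min.to_numpy(),
            concentrations=o.concentration_pmol_l.to_numpy(),
            dosing=DosingSchedule(tuple(basal), tuple(bolus)),
            context=ProfileContext(
                wt=row.weight_kg,
                t_end=row.t_end,
                t_start=row.t_start,
                unit_conversion=unit_conversion,
            ),
            meal_time=row.meal_time,
        )

    raw_factors = schema = design = None
    cov_path = directory / "covariates.csv"
    if cov_path.exists():
        raw_factors = pd.read_csv(cov_path, index_col="profile_id")
        raw_factors = raw_factors.loc[list(profiles)]
        schema = json.loads((directory / "covariate_schema.json").read_text())
        design = build_design(raw_factors, schema)

    exclusions = {}
    exc_path = directory / "exclusions.csv"
    if exc_path.exists():
        for r in pd.read_csv(exc_path).itertuples():
            exclusions[r.profile_id] = r.reason

    return Dataset(
        profiles=profiles,
        design=design,
        raw_factors=raw_factors,
        schema=schema,
        exclusions=exclusions,
    )
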