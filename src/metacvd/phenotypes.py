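"""Phenotype derivation from coded hospital-episode records.

Disease onsets are ascertained from Hospital Episode Statistics-style
records: diagnosis codes (ICD9/ICD10) and procedure codes (OPCS4), one row
per episode with a date. The onset of a disease is the earliest episode
whose code matches any configured prefix for that disease; composite CVD
onset is the earliest across the CAD, IS and HF subtypes.

The survival cohort follows the incident-case rule: follow-up starts at the
earliest T2D onset, a CVD event counts only if it falls at least one day
after T2D onset, and follow-up is censored at the earliest of CVD, death,
or a fixed administrative date (default 2021-02-05). Persons with CVD on or
before their T2D onset are prevalent cases and are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CODE_SYSTEMS",
    "CodeDefinition",
    "DEFAULT_CODE_DEFS",
    "CVD_SUBTYPES",
    "derive_onsets",
    "SurvivalCohort",
    "build_cohort",
]

CODE_SYSTEMS = ("ICD9", "ICD10", "OPCS4")
CVD_SUBTYPES = ("CAD", "IS", "HF")


@dataclass(frozen=True)
class CodeDefinition:
    """Disease label plus its (code system, code prefix) pairs.

    Matching is prefix-based after stripping dots and upper-casing, the
    usual tolerance for ICD dialects ("I21.0" matches prefix "I21").
    """

    disease: str
    codes: tuple[tuple[str, str], ...]

    def __post_init__(self):
        for system, prefix in self.codes:
            if system not in CODE_SYSTEMS:
                raise ValueError(
                    f"unknown code system {system!r} for {self.disease} "
                    f"(expected one of {CODE_SYSTEMS})")
            if not prefix:
                raise ValueError(f"empty code prefix for {self.disease}")

    @classmethod
    def from_dict(cls, disease: str, pairs: Iterable) -> "CodeDefinition":
        return cls(disease=disease,
                   codes=tuple((str(s), str(p)) for s, p in pairs))


def _norm_code(code: str) -> str:
    return str(code).replace(".", "").upper()


# Shipped defaults: configuration, not a transcription of any registry's
# official list. Users supply their own YAML for real analyses.
DEFAULT_CODE_DEFS: dict[str, CodeDefinition] = {
    "T2D": CodeDefinition("T2D", (("ICD10", "E11"), ("ICD9", "250"))),
    "CAD": CodeDefinition("CAD", (
        ("ICD10", "I21"), ("ICD10", "I22"), ("ICD10", "I23"),
        ("ICD10", "I24"), ("ICD10", "I252"), ("ICD9", "410"),
        ("ICD9", "412"), ("OPCS4", "K40"), ("OPCS4", "K41"),
        ("OPCS4", "K42"), ("OPCS4", "K43"), ("OPCS4", "K44"),
        ("OPCS4", "K45"), ("OPCS4", "K46"), ("OPCS4", "K49"),
        ("OPCS4", "K75"))),
    "IS": CodeDefinition("IS", (
        ("ICD10", "I63"), ("ICD9", "433"), ("ICD9", "434"))),
    "HF": CodeDefinition("HF", (
        ("ICD10", "I50"), ("ICD10", "I110"), ("ICD9", "428"))),
}


def load_code_defs(path) -> dict[str, CodeDefinition]:
    """Read code definitions from YAML: ``{disease: [[system, prefix], ...]}``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {d: CodeDefinition.from_dict(d, pairs) for d, pairs in raw.items()}


def dump_code_defs(defs: Mapping[str, CodeDefinition], path) -> None:
    raw = {d: [list(pair) for pair in cd.codes] for d, cd in defs.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh)


def derive_onsets(episodes: pd.DataFrame,
                  code_defs: Mapping[str, CodeDefinition] | None = None
                  ) -> pd.DataFrame:
    """Earliest onset date per person per disease.

    ``episodes`` needs columns ``person_id, system, code, date``. Returns a
    DataFrame indexed by person with one datetime column per disease (NaT
    where the person has no matching episode) plus a ``CVD`` column: the
    earliest across the CAD/IS/HF subtypes.

    Raises on unparseable dates (reporting row indices) and on unknown code
    systems.
    """
    if code_defs is None:
        code_defs = DEFAULT_CODE_DEFS
    req = {"person_id", "system", "code", "date"}
    missing = req - set(episodes.columns)
    if missing:
        raise ValueError(f"episodes missing columns: {sorted(missing)}")
    persons = pd.Index(episodes["person_id"].unique(), name="person_id")
    diseases = list(code_defs)
    if episodes.empty:
        out = pd.DataFrame(index=persons,
                           columns=diseases, dtype="datetime64[ns]")
        out["CVD"] = pd.NaT
        return out
    dates = pd.to_datetime(episodes["date"], errors="coerce",
                           format="mixed")
    bad = dates.isna() & episodes["date"].notna()
    if bad.any():
        rows = list(episodes.index[bad][:10])
        raise ValueError(f"unparseable episode dates at rows {rows}")
    systems = episodes["system"].astype(str)
    unknown = ~systems.isin(CODE_SYSTEMS)
    if unknown.any():
        rows = list(episodes.index[unknown][:10])
        raise ValueError(
            f"unknown code system at rows {rows}: "
            f"{sorted(systems[unknown].unique())}")
    codes = episodes["code"].map(_norm_code)
    out = pd.DataFrame(index=persons, columns=diseases,
                       dtype="datetime64[ns]")
    for disease, cdef in code_defs.items():
        mask = np.zeros(len(episodes), dtype=bool)
        for system, prefix in cdef.codes:
            mask |= (systems == system).to_numpy() & codes.str.startswith(
                _norm_code(prefix)).to_numpy()
        if mask.any():
            first = (pd.DataFrame({
                "person_id": episodes["person_id"][mask],
                "date": dates[mask]})
                .groupby("person_id")["date"].min())
            out.loc[first.index, disease] = first
    subtype_cols = [d for d in CVD_SUBTYPES if d in out.columns]
    out["CVD"] = out[subtype_cols].min(axis=1) if subtype_cols else pd.NaT
    return out


@dataclass
class SurvivalCohort:
    """Per-person follow-up for CVD after T2D onset.

    ``table`` has one row per retained person: ``t2d_onset_date``,
    ``event`` (0/1), ``follow_up_days`` (>= 1), ``cvd_onset_date``,
    ``death_date``, ``age_at_onset`` (fractional years) and any covariate
    columns that were supplied. ``exclusions`` counts persons removed by
    each rule.
    """

    table: pd.DataFrame
    censor_date: pd.Timestamp
    min_follow_up_days: int
    exclusions: dict[str, int] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def n_events(self) -> int:
        return int(self.table["event"].sum())

    @property
    def times(self) -> np.ndarray:
        return self.table["follow_up_days"].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.table["event"].to_numpy(dtype=int)

    @property
    def person_ids(self) -> list[str]:
        return [str(p) for p in self.table.index]

    def covariates(self, names: Iterable[str]) -> pd.DataFrame:
        names = list(names)
        missing = [c for c in names if c not in self.table.columns]
        if missing:
            raise KeyError(f"missing covariate column(s): {missing}")
        return self.table[names]

    def subset(self, mask) -> "SurvivalCohort":
        return SurvivalCohort(
            table=self.table[np.asarray(mask)],
            censor_date=self.censor_date,
            min_follow_up_days=self.min_follow_up_days,
            exclusions=dict(self.exclusions),
        )

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", date_format="%Y-%m-%d")

    @classmethod
    def from_tsv(cls, path, censor_date="2021-02-05",
                 min_follow_up_days: int = 1) -> "SurvivalCohort":
        table = pd.read_csv(path, sep="\t", index_col=0,
                            parse_dates=["t2d_onset_date", "cvd_onset_date",
                                         "death_date"])
        return cls(table=table, censor_date=pd.Timestamp(censor_date),
                   min_follow_up_days=min_follow_up_days)


DEFAULT_CENSOR_DATE = pd.Timestamp("2021-02-05")


def build_cohort(onsets: pd.DataFrame,
                 deaths: pd.DataFrame | pd.Series | None,
                 covariates: pd.DataFrame | None,
                 censor_date=DEFAULT_CENSOR_DATE,
                 min_follow_up_days: int = 1) -> SurvivalCohort:
    """Assemble the T2D survival cohort from derived onsets.

    Keeps persons with a T2D onset before the censor date; excludes
    prevalent CVD (onset on or before T2D onset). ``event = 1`` with
    ``follow_up_days = (CVD - T2D).days`` when CVD precedes both death and
    the censor date; otherwise the person is censored at
    ``min(death, censor_date)``. ``min_follow_up_days`` retains only
    persons with at least that much follow-up (31 reproduces the
    "longer than 30 days" sensitivity filter).

    Death strictly before (or on the day of) T2D onset is corrupt input
    and raises.
    """
    censor_date = pd.Timestamp(censor_date)
    df = onsets[onsets["T2D"].notna()].copy()
    df = df.rename(columns={"T2D": "t2d_onset_date",
                            "CVD": "cvd_onset_date"})
    excl: dict[str, int] = {}

    if deaths is None:
        death = pd.Series(pd.NaT, index=df.index, dtype="datetime64[ns]")
    else:
        if isinstance(deaths, pd.DataFrame):
            deaths = deaths.set_index("person_id")["death_date"]
        death = pd.to_datetime(deaths.reindex(df.index))
    df["death_date"] = death

    bad_death = df["death_date"].notna() & (
        df["death_date"] <= df["t2d_onset_date"])
    if bad_death.any():
        who = list(df.index[bad_death][:5])
        raise ValueError(
            f"death on or before T2D onset for person(s) {who}: corrupt "
            f"input")

    after_censor = df["t2d_onset_date"] >= censor_date
    excl["t2d_after_censor"] = int(after_censor.sum())
    df = df[~after_censor]

    prevalent = df["cvd_onset_date"].notna() & (
        df["cvd_onset_date"] <= df["t2d_onset_date"])
    excl["prevalent_cvd"] = int(prevalent.sum())
    df = df[~prevalent]

    end_censor = df["death_date"].fillna(censor_date).clip(upper=censor_date)
    is_event = df["cvd_onset_date"].notna() & (
        df["cvd_onset_date"] <= end_censor)
    end = df["cvd_onset_date"].where(is_event, end_censor)
    df["event"] = is_event.astype(int)
    df["follow_up_days"] = (end - df["t2d_onset_date"]).dt.days

    if (df["follow_up_days"] <= 0).any():
        bad = df[df["follow_up_days"] <= 0]
        raise ValueError(
            f"internal consistency error: non-positive follow-up for "
            f"{list(bad.index[:5])}")

    short = df["follow_up_days"] < min_follow_up_days
    excl["short_follow_up"] = int(short.sum())
    df = df[~short]

    if covariates is not None:
        cov = covariates.copy()
        if "person_id" in cov.columns:
            cov = cov.set_index("person_id")
        cov.index = cov.index.astype(df.index.dtype, copy=False)
        df = df.join(cov, how="left")
        if "birth_date" in df.columns:
            bd = pd.to_datetime(df["birth_date"])
            df["age_at_onset"] = (
                (df["t2d_onset_date"] - bd).dt.days / 365.25)
        elif "age_at_onset" not in df.columns:
            raise ValueError(
                "covariates must provide birth_date or age_at_onset")

    keep = ["t2d_onset_date", "cvd_onset_date", "death_date", "event",
            "follow_up_days"]
    other = [c for c in df.columns
             if c not in keep and c not in CVD_SUBTYPES and c != "birth_date"]
    df = df[keep + other]
    return SurvivalCohort(table=df, censor_date=censor_date,
                          min_follow_up_days=min_follow_up_days,
                          exclusions=excl)
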