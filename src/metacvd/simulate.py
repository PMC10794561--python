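"""Synthetic biobank-style study generator.

Produces a complete study bundle — genotype dosages, three sets of GWAS
summary statistics (one per CVD subtype: CAD, IS, HF), coded hospital
episodes, death dates and clinical covariates — with the statistical
structure the downstream analysis assumes:

* independent biallelic variants with dosages Binomial(2, EAF), optionally
  arranged in correlated blocks to exercise LD clumping;
* per-variant effect sizes for the three subtypes drawn from a trivariate
  normal whose correlation matrix is the genetic correlation ``rho_g``,
  rescaled so each subtype's polygenic liability has variance exactly
  ``h2[k]`` on the standardized-genotype scale;
* observed GWAS betas = true betas + noise with the standard
  ``1 / (2 N p (1-p))`` sampling variance;
* type 2 diabetes onset ages from a truncated normal, converted to calendar
  dates via simulated birth dates;
* subtype CVD events after T2D onset from an exponential
  proportional-hazards model whose log-hazard combines the standardized
  genetic score (optionally modified by an onset-age interaction) and
  centered clinical covariates;
* every simulated diagnosis emitted as an ICD/OPCS-coded episode record; a
  configurable fraction of subtype events is withheld from the episode
  table and flagged as self-reported only, emulating the interview-based
  labels used for stage-1 candidate selection.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .phenotypes import CVD_SUBTYPES, DEFAULT_CODE_DEFS
from .scoring import Genotypes

__all__ = ["SimConfig", "StudyBundle", "simulate_genotypes",
           "simulate_effects_and_sumstats", "simulate_cohort",
           "simulate_study"]

STUDY_START = pd.Timestamp("1994-04-01")

# Episode codes the generator samples from, per disease. Dots included on
# some ICD10 codes deliberately, to exercise dot-insensitive matching.
DEFAULT_CODE_SAMPLES: dict[str, list[tuple[str, str]]] = {
    "T2D": [("ICD10", "E11.9"), ("ICD10", "E11.2"), ("ICD9", "25000")],
    "CAD": [("ICD10", "I21.0"), ("ICD10", "I21.9"), ("ICD10", "I25.2"),
            ("ICD9", "410"), ("OPCS4", "K401"), ("OPCS4", "K491")],
    "IS": [("ICD10", "I63.9"), ("ICD10", "I63.5"), ("ICD9", "434")],
    "HF": [("ICD10", "I50.0"), ("ICD10", "I50.9"), ("ICD9", "428")],
}

# Clinical covariate distributions (means/SDs chosen to match a white
# British T2D biobank cohort) and their log-hazard effects. Lipid-fraction
# means follow clinical plausibility (HDL ~1.2, LDL ~3.9 mmol/L).
COVARIATE_DISTS: dict[str, tuple[str, float, float]] = {
    "sex": ("bernoulli", 0.60, 0.0),          # 1 = male
    "bmi": ("normal", 30.0, 4.5),
    "smoking": ("bernoulli", 0.57, 0.0),
    "hypertension": ("bernoulli", 0.80, 0.0),
    "tc": ("normal", 5.93, 1.28),
    "ldl_c": ("normal", 3.93, 0.83),
    "hdl_c": ("normal", 1.21, 0.33),
    "tg": ("normal", 2.25, 1.27),
    "lipid_med": ("bernoulli", 0.54, 0.0),
    "glucose": ("normal", 6.64, 2.00),
}

DEFAULT_HAZARD_BETAS: dict[str, float] = {
    "genetic": float(np.log(1.3)),       # per SD of subtype genetic score
    "age_at_onset": float(np.log(1.04)),  # per year
    "sex": float(np.log(1.53)),
    "bmi": float(np.log(1.02)),
    "smoking": float(np.log(1.27)),
    "hypertension": float(np.log(1.37)),
    "lipid_med": float(np.log(1.24)),
    "glucose": float(np.log(1.03)),
    "tc": 0.0,
    "ldl_c": 0.0,
    "hdl_c": 0.0,
    "tg": 0.0,
}

_ALLELE_PAIRS = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
                 ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]


def _default_rho() -> np.ndarray:
    return np.array([[1.0, 0.5, 0.6],
                     [0.5, 1.0, 0.5],
                     [0.6, 0.5, 1.0]])


@dataclass
class SimConfig:
    """Full specification of one synthetic study.

    Defaults describe a cohort of the size and event structure of a UK
    biobank T2D population: ~21k patients, liability heritabilities of
    0.50/0.28/0.30 for CAD/IS/HF, genetic correlations 0.5-0.6, a genetic
    hazard ratio of 1.3 per SD per subtype, clinical hazard effects at the
    magnitudes of the cohort's baseline table, and administrative
    censoring at 2021-02-05.
    """

    n_individuals: int = 21092
    n_variants: int = 2000
    maf_range: tuple[float, float] = (0.01, 0.5)
    h2: tuple[float, float, float] = (0.50, 0.28, 0.30)
    rho_g: np.ndarray = field(default_factory=_default_rho)
    gwas_n: tuple[int, int, int] = (550_000, 520_000, 977_000)
    t2d_onset_mean_sd: tuple[float, float] = (60.0, 8.0)
    hazard_betas: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HAZARD_BETAS))
    genetic_onset_interaction: float = 0.0  # extra log-HR per decade < 55
    baseline_hazard_rate: float = 0.0055    # per subtype, events/person-year
    death_rate: float = 0.015               # events/person-year
    censor_date: pd.Timestamp = pd.Timestamp("2021-02-05")
    birth_range: tuple[str, str] = ("1935-01-01", "1960-01-01")
    missing_rate: float = 0.0
    ld_blocks: tuple[int, float] | None = None  # (block size, pairwise r)
    self_report_frac: float = 0.15
    code_maps: dict[str, list[tuple[str, str]]] = field(
        default_factory=lambda: {k: list(v)
                                 for k, v in DEFAULT_CODE_SAMPLES.items()})
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5]: "
                             f"{self.maf_range}")
        self.rho_g = np.asarray(self.rho_g, dtype=float)
        if self.rho_g.shape != (3, 3) or not np.allclose(
                self.rho_g, self.rho_g.T):
            raise ValueError("rho_g must be a symmetric 3x3 matrix")
        if not np.allclose(np.diag(self.rho_g), 1.0):
            raise ValueError("rho_g must have unit diagonal")
        if np.linalg.eigvalsh(self.rho_g).min() < -1e-10:
            raise ValueError("rho_g must be positive semi-definite")
        if any(not (0 <= h < 1) for h in self.h2):
            raise ValueError(f"h2 entries must lie in [0, 1): {self.h2}")
        if self.n_individuals < 2 or self.n_variants < 1:
            raise ValueError("need n_individuals >= 2 and n_variants >= 1")
        for disease in ("T2D",) + CVD_SUBTYPES:
            if not self.code_maps.get(disease):
                raise ValueError(f"empty code list for {disease}")
        self.censor_date = pd.Timestamp(self.censor_date)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rho_g"] = self.rho_g.tolist()
        d["censor_date"] = str(self.censor_date.date())
        d["code_maps"] = {k: [list(p) for p in v]
                          for k, v in self.code_maps.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("maf_range", "h2", "gwas_n", "t2d_onset_mean_sd",
                    "birth_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("ld_blocks") is not None:
            d["ld_blocks"] = (int(d["ld_blocks"][0]), float(d["ld_blocks"][1]))
        if "rho_g" in d:
            d["rho_g"] = np.asarray(d["rho_g"], dtype=float)
        if "code_maps" in d:
            d["code_maps"] = {k: [tuple(p) for p in v]
                              for k, v in d["code_maps"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass
class StudyBundle:
    """One complete synthetic (or user-supplied) study."""

    genotypes: Genotypes
    sumstats: dict[str, pd.DataFrame]         # subtype -> GWAS table
    true_effects: pd.DataFrame                # per-variant, standardized scale
    true_scores: pd.DataFrame                 # per-person genetic scores
    episodes: pd.DataFrame                    # person_id, system, code, date
    deaths: pd.DataFrame                      # person_id, death_date
    covariates: pd.DataFrame                  # person_id + clinical + PCs
    self_reports: pd.DataFrame                # person_id, disease
    config: SimConfig | None = None

    def write(self, outdir, genotype_format: str = "tsv") -> None:
        """Write the bundle as plain-text files plus a manifest YAML."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        if genotype_format == "vcf":
            self.genotypes.to_vcf(out / "genotypes.vcf")
        else:
            self.genotypes.to_tsv(out / "genotypes.tsv", out / "variants.tsv")
        for k, ss in self.sumstats.items():
            ss.to_csv(out / f"sumstats_{k}.tsv", sep="\t", index=False)
        self.true_effects.to_csv(out / "true_effects.tsv", sep="\t")
        self.true_scores.to_csv(out / "true_scores.tsv", sep="\t")
        self.episodes.to_csv(out / "episodes.csv", index=False)
        self.deaths.to_csv(out / "deaths.csv", index=False)
        self.covariates.to_csv(out / "covariates.tsv", sep="\t", index=False)
        self.self_reports.to_csv(out / "self_reports.csv", index=False)
        if self.config is not None:
            self.config.to_yaml(out / "manifest.yaml")


def _rngs(config: SimConfig, n_children: int = 5):
    ss = np.random.SeedSequence(config.seed)
    return [np.random.default_rng(c) for c in ss.spawn(n_children)]


def simulate_genotypes(config: SimConfig,
                       rng: np.random.Generator | None = None) -> Genotypes:
    """Biallelic dosages ~ Binomial(2, EAF), EAF ~ Uniform(maf_range).

    With ``config.ld_blocks = (B, r)`` variants come in blocks of ``B``
    sharing one EAF, with pairwise allele correlation ``r`` induced by a
    shared latent haplotype indicator per chromosome copy.
    """
    if rng is None:
        rng = _rngs(config)[0]
    n, m = config.n_individuals, config.n_variants
    lo, hi = config.maf_range
    if config.ld_blocks is None:
        eaf = rng.uniform(lo, hi, size=m)
        dos = rng.binomial(2, eaf[None, :], size=(n, m)).astype(float)
    else:
        B, r = config.ld_blocks
        if not (0 <= r <= 1):
            raise ValueError("LD block correlation must be in [0, 1]")
        n_blocks = int(np.ceil(m / B))
        eaf_block = rng.uniform(lo, hi, size=n_blocks)
        eaf = np.repeat(eaf_block, B)[:m]
        s = np.sqrt(r)
        dos = np.zeros((n, m))
        for copy in range(2):  # two haplotypes per person
            latent = rng.random((n, n_blocks)) < eaf_block[None, :]
            latent = np.repeat(latent, B, axis=1)[:, :m]
            fresh = rng.random((n, m)) < eaf[None, :]
            use_latent = rng.random((n, m)) < s
            dos += np.where(use_latent, latent, fresh)
    if config.missing_rate > 0:
        miss = rng.random((n, m)) < config.missing_rate
        dos[miss] = np.nan
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    variants = pd.DataFrame({
        "id": [f"rs{j + 1}" for j in range(m)],
        "chrom": "1",
        "pos": 5000 * (np.arange(m) + 1),
        "counted_allele": [_ALLELE_PAIRS[i][1] for i in pair_idx],
        "other_allele": [_ALLELE_PAIRS[i][0] for i in pair_idx],
        "eaf": eaf,
    })
    persons = [f"P{i + 1:06d}" for i in range(n)]
    return Genotypes(dosages=dos, variants=variants, persons=persons)


def simulate_effects_and_sumstats(
        config: SimConfig, variants: pd.DataFrame,
        rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Correlated per-variant effects and noisy GWAS summary statistics.

    True effects (standardized-genotype scale) are drawn per variant from
    N(0, rho_g) and each subtype's vector is rescaled so the genetic score
    variance equals ``h2[k]`` exactly. Observed per-allele betas add noise
    with variance ``1 / (2 N_k p (1-p))``; the reported ``se`` and ``p``
    are consistent with that noise model.
    """
    if rng is None:
        rng = _rngs(config)[1]
    m = len(variants)
    h2 = np.asarray(config.h2, dtype=float)
    L = np.linalg.cholesky(config.rho_g + 1e-12 * np.eye(3))
    raw = rng.standard_normal((m, 3)) @ L.T
    effects = np.zeros((m, 3))
    for k in range(3):
        norm = np.linalg.norm(raw[:, k])
        if h2[k] > 0 and norm > 0:
            effects[:, k] = raw[:, k] * np.sqrt(h2[k]) / norm
    true_effects = pd.DataFrame(effects, index=variants["id"],
                                columns=list(CVD_SUBTYPES))
    true_effects.index.name = "variant_id"
    p = variants["eaf"].to_numpy(dtype=float)
    scale = np.sqrt(2 * p * (1 - p))  # allele scale <-> standardized scale
    sumstats: dict[str, pd.DataFrame] = {}
    for k, subtype in enumerate(CVD_SUBTYPES):
        b_allele = effects[:, k] / scale
        se = 1.0 / np.sqrt(config.gwas_n[k] * 2 * p * (1 - p))
        beta_hat = b_allele + rng.standard_normal(m) * se
        z = beta_hat / se
        pval = 2.0 * stats.norm.sf(np.abs(z))
        sumstats[subtype] = pd.DataFrame({
            "variant_id": variants["id"].to_numpy(),
            "chrom": variants["chrom"].to_numpy(),
            "pos": variants["pos"].to_numpy(),
            "effect_allele": variants["counted_allele"].to_numpy(),
            "other_allele": variants["other_allele"].to_numpy(),
            "eaf": p,
            "beta": beta_hat,
            "se": se,
            "p": pval,
        })
    return true_effects, sumstats


def true_genetic_scores(genotypes: Genotypes,
                        true_effects: pd.DataFrame) -> pd.DataFrame:
    """Per-person liability scores: standardized dosages @ true effects.

    Standardization uses the configured population EAF, so
    ``Var(score_k) == h2[k]`` under the generative model.
    """
    p = genotypes.variants["eaf"].to_numpy(dtype=float)
    sd = np.sqrt(2 * p * (1 - p))
    d = genotypes.dosages
    if np.isnan(d).any():
        d = np.where(np.isnan(d), (2 * p)[None, :], d)
    z = (d - 2 * p[None, :]) / sd[None, :]
    g = z @ true_effects.to_numpy(dtype=float)
    return pd.DataFrame(g, index=pd.Index(genotypes.persons,
                                          name="person_id"),
                        columns=list(true_effects.columns))


def _draw_covariates(config: SimConfig, rng: np.random.Generator
                     ) -> pd.DataFrame:
    n = config.n_individuals
    persons = [f"P{i + 1:06d}" for i in range(n)]
    cols: dict[str, np.ndarray] = {}
    for name, (kind, a, b) in COVARIATE_DISTS.items():
        if kind == "bernoulli":
            cols[name] = (rng.random(n) < a).astype(float)
        else:
            x = rng.normal(a, b, size=n)
            if name in ("tc", "ldl_c", "hdl_c", "tg", "glucose"):
                x = np.clip(x, 0.1, None)
            cols[name] = x
    for j in range(10):
        cols[f"pc{j + 1}"] = rng.standard_normal(n)
    b0, b1 = (pd.Timestamp(config.birth_range[0]),
              pd.Timestamp(config.birth_range[1]))
    days = rng.integers(0, (b1 - b0).days, size=n)
    birth = b0 + pd.to_timedelta(days, unit="D")
    df = pd.DataFrame(cols)
    df.insert(0, "person_id", persons)
    df.insert(1, "birth_date", birth)
    return df


def simulate_cohort(config: SimConfig, genotypes: Genotypes,
                    true_effects: pd.DataFrame,
                    rng: np.random.Generator | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame,
                               pd.DataFrame]:
    """Simulate onsets, deaths, covariates and the coded episode stream.

    Returns ``(episodes, deaths, covariates, self_reports)``. Every person
    develops T2D at a truncated-normal age; each CVD subtype then has an
    exponential event time with log-hazard
    ``log(baseline) + beta_g(age) * Z_k + sum_c beta_c (x_c - mu_c)`` where
    ``Z_k`` is the subtype's standardized genetic score and ``beta_g(age)``
    optionally grows by ``genetic_onset_interaction`` per decade of onset
    age below 55. Records dated after the censor date (or after death) are
    not emitted — an administrative extract cannot contain them. A fraction
    of subtype events is diverted to the self-report table instead of the
    episode stream.
    """
    if rng is None:
        rng = _rngs(config)[2]
    n = config.n_individuals
    cov = _draw_covariates(config, rng)
    persons = cov["person_id"].to_numpy()

    mean, sd = config.t2d_onset_mean_sd
    a, b = (30.0 - mean) / sd, (80.0 - mean) / sd
    onset_age = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n,
                                    random_state=rng)
    birth = pd.to_datetime(cov["birth_date"])
    t2d_date = birth + pd.to_timedelta(
        np.round(onset_age * 365.25).astype(int), unit="D")

    # standardized genetic scores
    g = true_genetic_scores(genotypes, true_effects)
    h2 = np.asarray(config.h2, dtype=float)
    z = np.zeros((n, 3))
    for k in range(3):
        z[:, k] = g.iloc[:, k] / np.sqrt(h2[k]) if h2[k] > 0 else 0.0

    hb = config.hazard_betas
    clin = 0.0
    for name, (kind, a_, _b) in COVARIATE_DISTS.items():
        beta = hb.get(name, 0.0)
        if beta:
            # a_ is the distribution mean for both kinds; centering keeps
            # baseline_hazard_rate interpretable as the typical-person rate
            clin = clin + beta * (cov[name].to_numpy() - a_)
    beta_age = hb.get("age_at_onset", 0.0)
    if beta_age:
        clin = clin + beta_age * (onset_age - mean)

    bg = hb.get("genetic", float(np.log(1.3)))
    bg_eff = bg + config.genetic_onset_interaction * (55.0 - onset_age) / 10.0

    # T2D episodes
    t2d_codes = config.code_maps["T2D"]
    t2d_code_idx = rng.integers(0, len(t2d_codes), size=n)
    t2d_emit_date = pd.Series(t2d_date).clip(lower=STUDY_START)

    # death times (years after T2D onset)
    if config.death_rate > 0:
        t_death = rng.exponential(1.0 / config.death_rate, size=n)
    else:
        t_death = np.full(n, np.inf)
    death_days = np.maximum(
        np.round(np.minimum(t_death, 200.0) * 365.25).astype(int), 1)
    death_date = t2d_date + pd.to_timedelta(death_days, unit="D")
    death_date = death_date.where(np.isfinite(t_death), pd.NaT)

    # subtype event times
    event_dates = {}
    for k, subtype in enumerate(CVD_SUBTYPES):
        if config.baseline_hazard_rate > 0:
            lam = config.baseline_hazard_rate * np.exp(
                np.clip(bg_eff * z[:, k] + clin, -30, 30))
            t_ev = rng.exponential(1.0 / lam)
        else:
            t_ev = np.full(n, np.inf)
        ev_date = t2d_date + pd.to_timedelta(
            np.round(np.minimum(t_ev, 200.0) * 365.25).astype(int),
            unit="D")
        ev_date = ev_date.where(np.isfinite(t_ev), pd.NaT)
        event_dates[subtype] = ev_date

    self_report_mask = {
        subtype: rng.random(n) < config.self_report_frac
        for subtype in CVD_SUBTYPES
    }
    code_choice = {
        subtype: rng.integers(0, len(config.code_maps[subtype]), size=n)
        for subtype in CVD_SUBTYPES
    }

    censor = config.censor_date
    dd = pd.Series(death_date).to_numpy()
    has_death = ~pd.isna(dd) & (dd <= censor.to_datetime64())
    end = np.where(has_death, dd, censor.to_datetime64())
    emit_t2d = pd.Series(t2d_emit_date).to_numpy()
    # a person whose first (clamped) T2D record would coincide with their
    # death day yields zero follow-up; they are invisible to the extract
    visible = (emit_t2d <= end) & (~has_death | (emit_t2d < dd))

    frames = []
    t2d_sys = np.array([t2d_codes[i][0] for i in t2d_code_idx])
    t2d_code = np.array([t2d_codes[i][1] for i in t2d_code_idx])
    frames.append(pd.DataFrame({
        "person_id": persons[visible],
        "system": t2d_sys[visible],
        "code": t2d_code[visible],
        "date": emit_t2d[visible],
    }))
    self_frames = []
    for subtype in CVD_SUBTYPES:
        ev = pd.Series(event_dates[subtype]).to_numpy()
        occurred = visible & ~pd.isna(ev) & (ev <= end)
        sr = occurred & self_report_mask[subtype]
        coded = occurred & ~self_report_mask[subtype]
        codes = config.code_maps[subtype]
        sysv = np.array([codes[i][0] for i in code_choice[subtype]])
        codev = np.array([codes[i][1] for i in code_choice[subtype]])
        frames.append(pd.DataFrame({
            "person_id": persons[coded],
            "system": sysv[coded],
            "code": codev[coded],
            "date": np.maximum(ev[coded], STUDY_START.to_datetime64()),
        }))
        if sr.any():
            self_frames.append(pd.DataFrame({
                "person_id": persons[sr], "disease": subtype}))

    episodes_df = pd.concat(frames, ignore_index=True)
    episodes_df["date"] = pd.to_datetime(episodes_df["date"])
    episodes_df = episodes_df.sort_values(
        ["person_id", "date"], kind="stable").reset_index(drop=True)
    deaths_df = pd.DataFrame({
        "person_id": persons[has_death],
        "death_date": pd.to_datetime(dd[has_death]),
    })
    self_df = (pd.concat(self_frames, ignore_index=True) if self_frames
               else pd.DataFrame(columns=["person_id", "disease"]))
    return episodes_df, deaths_df, cov, self_df


def simulate_study(config: SimConfig) -> StudyBundle:
    """Run the full generator under one seed and return the bundle."""
    r_geno, r_eff, r_cohort, _, _ = _rngs(config)
    genotypes = simulate_genotypes(config, r_geno)
    true_effects, sumstats = simulate_effects_and_sumstats(
        config, genotypes.variants, r_eff)
    episodes, deaths, covariates, self_reports = simulate_cohort(
        config, genotypes, true_effects, r_cohort)
    scores = true_genetic_scores(genotypes, true_effects)
    return StudyBundle(
        genotypes=genotypes,
        sumstats=sumstats,
        true_effects=true_effects,
        true_scores=scores,
        episodes=episodes,
        deaths=deaths,
        covariates=covariates,
        self_reports=self_reports,
        config=config,
    )
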