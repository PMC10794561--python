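"""Polygenic score computation: allele harmonization, weighted-dosage
scoring, and a reference clumping + thresholding (P+T) weight generator.

A polygenic risk score is the per-person sum of counted-allele dosages
weighted by per-allele effect sizes from GWAS summary statistics. Weight
files follow their own allele convention, so they must be harmonized to the
genotype data's counted allele before scoring: matching alleles keep the
weight, swapped alleles negate it (the constant offset is immaterial once
scores are standardized), strand flips are resolved by complementing, and
strand-ambiguous A/T and C/G variants are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Genotypes",
    "WeightSet",
    "PRSVector",
    "HarmonizeReport",
    "harmonize",
    "score",
    "clump_threshold",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_ambiguous(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


@dataclass
class Genotypes:
    """Dosage matrix plus variant annotation.

    ``dosages`` is persons x variants with values in [0, 2]; missing values
    are NaN. ``variants`` has columns ``id, chrom, pos, counted_allele,
    other_allele, eaf`` where ``eaf`` is the counted-allele frequency (the
    ALT allele when read from VCF).
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    persons: list[str]

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.persons), len(self.variants)):
            raise ValueError("dosage matrix shape does not match "
                             "persons x variants")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if np.any(bad):
            raise ValueError("dosages must lie in [0, 2] or be missing")

    @property
    def n(self) -> int:
        return len(self.persons)

    @property
    def m(self) -> int:
        return len(self.variants)

    def column_index(self) -> pd.Index:
        return pd.Index(self.variants["id"])

    # -- plain-text I/O -------------------------------------------------

    def to_tsv(self, dosage_path, variants_path) -> None:
        """Write the dosage matrix (variants x persons) and its companion
        variant table declaring the counted allele per variant."""
        df = pd.DataFrame(self.dosages.T, index=self.variants["id"],
                          columns=self.persons)
        df.index.name = "variant_id"
        df.to_csv(dosage_path, sep="\t", float_format="%.6g")
        self.variants.to_csv(variants_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, dosage_path, variants_path) -> "Genotypes":
        df = pd.read_csv(dosage_path, sep="\t", index_col=0)
        variants = pd.read_csv(variants_path, sep="\t",
                               dtype={"chrom": str, "id": str})
        variants = variants.set_index("id").loc[df.index]
        variants.index.name = "id"
        variants = variants.reset_index()
        return cls(dosages=df.to_numpy(dtype=float).T, variants=variants,
                   persons=[str(c) for c in df.columns])

    def to_vcf(self, path) -> None:
        """Write a sites+dosage VCF with the dosage in a DS FORMAT field."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                     'Description="Estimated alternate allele dosage">\n')
            for chrom in dict.fromkeys(self.variants["chrom"].astype(str)):
                fh.write(f"##contig=<ID={chrom}>\n")
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.persons) + "\n")
            for j, row in enumerate(self.variants.itertuples(index=False)):
                ds = [
                    "." if np.isnan(d) else f"{d:.4g}"
                    for d in self.dosages[:, j]
                ]
                fh.write(
                    f"{row.chrom}\t{row.pos}\t{row.id}\t{row.other_allele}\t"
                    f"{row.counted_allele}\t.\t.\t.\tDS\t" + "\t".join(ds)
                    + "\n"
                )

    @classmethod
    def from_vcf(cls, path) -> "Genotypes":
        """Read dosages from a VCF via cyvcf2 (DS FORMAT field, or GT as
        fallback).

        The counted allele is ALT, following the dosage convention of
        imputed biobank releases.
        """
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        persons = list(vcf.samples)
        ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
        for var in vcf:
            ds = var.format("DS")
            if ds is not None:
                vals = np.asarray(ds, dtype=float).reshape(-1)
                # cyvcf2 encodes missing FORMAT floats as huge sentinels
                vals = np.where((vals < 0) | (vals > 2) |
                                ~np.isfinite(vals), np.nan, vals)
            else:
                gts = np.asarray(var.gt_types, dtype=float)
                # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
                vals = np.select([gts == 0, gts == 1, gts == 3],
                                 [0.0, 1.0, 2.0], default=np.nan)
            chroms.append(str(var.CHROM))
            poss.append(int(var.POS))
            ids.append(var.ID if var.ID else
                       f"{var.CHROM}:{var.POS}")
            refs.append(var.REF)
            alts.append(var.ALT[0] if var.ALT else ".")
            rows.append(vals)
        vcf.close()
        dos = np.array(rows, dtype=float).T
        eaf = np.nanmean(dos, axis=0) / 2.0
        variants = pd.DataFrame({
            "id": ids, "chrom": chroms, "pos": poss,
            "counted_allele": alts, "other_allele": refs, "eaf": eaf,
        })
        return cls(dosages=dos, variants=variants, persons=persons)


@dataclass
class WeightSet:
    """One candidate PRS: per-variant effect allele and weight.

    ``label`` identifies method x subtype (e.g. ``"pt_5e-08:CAD"``);
    ``method`` tags externally produced weights (ldpred, prscs, ...).
    """

    label: str
    table: pd.DataFrame  # variant_id, effect_allele, other_allele, weight
    method: str = "pt"

    def __post_init__(self):
        req = {"variant_id", "effect_allele", "weight"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"weight table missing columns: {sorted(missing)}")
        if "other_allele" not in self.table.columns:
            self.table = self.table.assign(other_allele=None)
        if self.table["variant_id"].duplicated().any():
            raise ValueError("duplicate variant ids in weight set")
        w = self.table["weight"].to_numpy(dtype=float)
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, label: str | None = None,
                 method: str = "external") -> "WeightSet":
        table = pd.read_csv(path, sep="\t")
        return cls(label=label or Path(path).stem, table=table, method=method)


@dataclass
class HarmonizeReport:
    matched: int = 0
    flipped: int = 0          # effect allele was the non-counted allele
    strand_flipped: int = 0   # resolved by complementing
    ambiguous: int = 0        # A/T or C/G, dropped
    unmatched: int = 0        # id absent or alleles irreconcilable

    @property
    def kept(self) -> int:
        return self.matched + self.flipped + self.strand_flipped

    @property
    def dropped(self) -> int:
        return self.ambiguous + self.unmatched


def harmonize(weights: WeightSet, variants: pd.DataFrame
              ) -> tuple[WeightSet, HarmonizeReport]:
    """Align a weight set to the genotype allele convention.

    Returns a new :class:`WeightSet` whose weights apply directly to the
    counted-allele dosages, plus a per-category drop/flip report. Never
    raises: problems are report-only.
    """
    rep = HarmonizeReport()
    vtab = variants.set_index("id")
    out_rows = []
    for row in weights.table.itertuples(index=False):
        vid = row.variant_id
        if vid not in vtab.index:
            rep.unmatched += 1
            continue
        ea = str(row.effect_allele).upper()
        oa = (None if pd.isna(row.other_allele)
              else str(row.other_allele).upper())
        counted = str(vtab.at[vid, "counted_allele"]).upper()
        other = str(vtab.at[vid, "other_allele"]).upper()
        if _is_ambiguous(counted, other) or (oa and _is_ambiguous(ea, oa)):
            rep.ambiguous += 1
            continue
        w = float(row.weight)
        cea, coa = _COMPLEMENT.get(ea), (_COMPLEMENT.get(oa) if oa
                                         else None)
        if ea == counted and oa in (None, other):
            rep.matched += 1
        elif ea == other and oa in (None, counted):
            rep.flipped += 1
            w = -w
        elif cea == counted and coa in (None, other):
            rep.strand_flipped += 1
        elif cea == other and coa in (None, counted):
            rep.strand_flipped += 1
            w = -w
        else:
            rep.unmatched += 1
            continue
        out_rows.append((vid, counted, other, w))
    table = pd.DataFrame(out_rows, columns=["variant_id", "effect_allele",
                                            "other_allele", "weight"])
    return WeightSet(label=weights.label, table=table,
                     method=weights.method), rep


@dataclass
class PRSVector:
    """Per-person polygenic score with provenance."""

    person_ids: list[str]
    values: np.ndarray
    label: str
    n_variants_used: int
    n_dropped: int
    mean: float | None = None
    sd: float | None = None

    def standardized(self) -> "PRSVector":
        mu = float(np.mean(self.values))
        sd = float(np.std(self.values))
        if sd == 0:
            raise ValueError(f"cannot standardize '{self.label}': SD is 0")
        return PRSVector(
            person_ids=self.person_ids,
            values=(self.values - mu) / sd,
            label=self.label,
            n_variants_used=self.n_variants_used,
            n_dropped=self.n_dropped,
            mean=mu,
            sd=sd,
        )

    def series(self) -> pd.Series:
        return pd.Series(self.values, index=self.person_ids, name=self.label)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame({"person_id": self.person_ids,
                           "score": self.values})
        df.to_csv(path, sep="\t", index=False)


def score(genotypes: Genotypes, weights: WeightSet,
          impute_missing: str = "mean",
          harmonized: bool = False) -> PRSVector:
    """Weighted-dosage polygenic score.

    ``score_i = sum_j w_j * dosage_ij`` over the harmonized weights. Missing
    dosages are imputed with the study's own mean dosage (``2 * EAF``
    estimated from the non-missing calls; ``impute_missing="mean"``) or the
    person is dropped entirely (``"drop"``).
    """
    if not harmonized:
        weights, rep = harmonize(weights, genotypes.variants)
        n_dropped = rep.dropped
    else:
        n_dropped = 0
    if len(weights) == 0:
        raise ValueError(f"empty score: no usable variants for "
                         f"'{weights.label}'")
    col = genotypes.column_index()
    idx = col.get_indexer(weights.table["variant_id"])
    if np.any(idx < 0):  # pragma: no cover - harmonize guarantees presence
        raise ValueError("harmonized weight refers to unknown variant")
    d = genotypes.dosages[:, idx]
    w = weights.table["weight"].to_numpy(dtype=float)
    persons = list(genotypes.persons)
    if np.isnan(d).any():
        if impute_missing == "mean":
            colmean = np.nanmean(d, axis=0)
            colmean = np.where(np.isnan(colmean), 0.0, colmean)
            d = np.where(np.isnan(d), colmean[None, :], d)
        elif impute_missing == "drop":
            keep = ~np.isnan(d).any(axis=1)
            d = d[keep]
            persons = [p for p, k in zip(persons, keep) if k]
        else:
            raise ValueError(f"unknown impute_missing: {impute_missing!r}")
    values = d @ w
    return PRSVector(
        person_ids=persons,
        values=values,
        label=weights.label,
        n_variants_used=len(weights),
        n_dropped=n_dropped,
    )


def _pairwise_r2(genotypes: Genotypes, j: int, k: int) -> float:
    a = genotypes.dosages[:, j]
    b = genotypes.dosages[:, k]
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        return 0.0
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def clump_threshold(sumstats: pd.DataFrame, genotypes: Genotypes,
                    p_max: float = 5e-8, r2_max: float = 0.1,
                    window_kb: float = 250.0,
                    label: str = "pt") -> WeightSet:
    """Greedy clumping + thresholding (P+T) reference implementation.

    Variants are visited by ascending GWAS p-value (ties broken by
    (chrom, pos)); a variant is retained if its p-value passes ``p_max``
    and its squared dosage correlation with every already-retained variant
    within ``window_kb`` on the same chromosome is at most ``r2_max``.
    Retained weights are the GWAS betas. LD is measured on the study's own
    dosages, so no external reference panel is needed.
    """
    req = {"variant_id", "chrom", "pos", "p", "beta"}
    missing = req - set(sumstats.columns)
    if missing:
        raise ValueError(f"sumstats missing columns: {sorted(missing)}")
    ss = sumstats[sumstats["p"] <= p_max].copy()
    ss = ss.sort_values(["p", "chrom", "pos"], kind="stable")
    col = genotypes.column_index()
    window = window_kb * 1000.0
    kept: list[tuple[str, str, float]] = []  # (chrom, pos, col index)
    kept_rows = []
    for row in ss.itertuples(index=False):
        j = col.get_loc(row.variant_id) if row.variant_id in col else None
        if j is None:
            continue
        ok = True
        for (c, pos, k) in kept:
            if c == str(row.chrom) and abs(pos - row.pos) <= window:
                if _pairwise_r2(genotypes, j, k) > r2_max:
                    ok = False
                    break
        if ok:
            kept.append((str(row.chrom), float(row.pos), j))
            kept_rows.append(row)
    if not kept_rows:
        warnings.warn(f"clumping produced an empty weight set "
                      f"(p_max={p_max})", stacklevel=2)
        table = pd.DataFrame(columns=["variant_id", "effect_allele",
                                      "other_allele", "weight"])
        return WeightSet(label=label, table=table)
    table = pd.DataFrame({
        "variant_id": [r.variant_id for r in kept_rows],
        "effect_allele": [
            getattr(r, "effect_allele", None) for r in kept_rows],
        "other_allele": [
            getattr(r, "other_allele", None) for r in kept_rows],
        "weight": [r.beta for r in kept_rows],
    })
    if table["effect_allele"].isna().any():
        v = genotypes.variants.set_index("id")
        table["effect_allele"] = table["effect_allele"].fillna(
            table["variant_id"].map(v["counted_allele"]))
        table["other_allele"] = table["other_allele"].fillna(
            table["variant_id"].map(v["other_allele"]))
    return WeightSet(label=label, table=table.reset_index(drop=True))
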