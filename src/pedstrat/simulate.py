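"""Synthetic admixed extended-pedigree generator.

Emulates the statistical structure of a multigenerational admixed study
sample: several large pedigrees whose founders come from family-specific
admixtures of K ancestral populations (Balding–Nichols allele-frequency
divergence), unlinked genotypes transmitted by gene dropping, and a
quantitative blood-pressure-like trait with medication / sex / age /
sex-by-age fixed effects, per-SNP causal effects, a family random intercept
and an i.i.d. residual.  A genetics-free "null" trait is generated from the
same model with every causal effect set to zero.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so every output is reproducible
byte for byte.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genoio import (
    GenotypeMatrix,
    Pedigree,
    DataError,
    MISSING_PARENT,
    write_ped_map,
    write_vcf,
)

__all__ = [
    "SimulationConfig",
    "AncestryModel",
    "ConfigError",
    "build_pedigree",
    "draw_ancestral_freqs",
    "assign_family_admixture",
    "draw_founder_genotypes",
    "gene_drop",
    "simulate_traits",
    "simulate_dataset",
    "SimulatedData",
    "write_dataset",
]

_BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    """Invalid or impossible simulation configuration."""


@dataclass
class SimulationConfig:
    """Knobs of the generator.  Defaults are the study conditions this
    package analyses: 20 extended families of 22–86 members, 134 causal
    SNPs, three ancestral populations at Fst 0.2 with two planted divergent
    family pairs, and an SBP-like trait (mmHg scale)."""

    seed: int
    n_families: int = 20
    family_size_range: tuple[int, int] = (22, 86)
    n_variants: int = 20_000
    n_causal: int = 134
    causal_beta_sd: float = 0.8
    causal_maf_min: float = 0.05
    # ancestry
    n_pops: int = 3
    fst: float = 0.2
    admixture: str = "distinct"  # "distinct" (per-family Dirichlet) or "shared"
    admixture_concentration: tuple[float, ...] = (5.0, 4.5, 0.5)
    founder_admixture_concentration: float = 10.0
    plant_divergent_pairs: bool = True
    # trait model (fixed effects then variance components)
    beta_intercept: float = 110.0
    beta_medication: float = 5.0
    beta_sex: float = -5.0
    beta_age: float = 0.5
    beta_sex_age: float = 0.1
    beta_ancestry: float = 15.0
    sigma2_family: float = 25.0
    sigma2_resid: float = 100.0
    # covariate distributions
    age_range: tuple[float, float] = (20.0, 80.0)
    medication_rate: float = 0.2

    def validate(self) -> None:
        lo, hi = self.family_size_range
        if not (3 <= lo <= hi <= 200):
            raise ConfigError(f"family_size_range {self.family_size_range} outside [3, 200]")
        if self.n_families < 1:
            raise ConfigError("n_families must be >= 1")
        if self.n_causal > self.n_variants:
            raise ConfigError("n_causal exceeds n_variants")
        if not 0.0 < self.fst < 1.0:
            raise ConfigError(f"fst {self.fst} outside (0, 1)")
        if self.sigma2_family < 0 or self.sigma2_resid < 0:
            raise ConfigError("variance components must be >= 0")
        if self.n_pops < 1:
            raise ConfigError("n_pops must be >= 1")
        if len(self.admixture_concentration) != self.n_pops:
            raise ConfigError("admixture_concentration length must equal n_pops")
        if self.admixture not in ("distinct", "shared"):
            raise ConfigError(f"unknown admixture mode {self.admixture!r}")


@dataclass
class AncestryModel:
    """Balding–Nichols ancestral frequencies plus per-family admixture.

    ``ancestral_freqs`` is (n_variants, K); ``family_admixture`` maps each
    family id to a length-K mixing vector summing to 1.
    """

    n_ancestral_pops: int
    ancestral_freqs: np.ndarray
    fst: float
    family_admixture: pd.DataFrame | None = None  # index fid, K columns

    def validate(self) -> None:
        f = self.ancestral_freqs
        if f.ndim != 2 or f.shape[1] != self.n_ancestral_pops:
            raise ConfigError("ancestral_freqs must be (n_variants, K)")
        if not ((f > 0) & (f < 1)).all():
            raise ConfigError("ancestral frequencies must lie strictly inside (0,1)")
        if not 0.0 < self.fst < 1.0:
            raise ConfigError("fst outside (0,1)")
        if self.family_admixture is not None:
            w = self.family_admixture.to_numpy()
            if (w < 0).any() or np.abs(w.sum(axis=1) - 1.0).max() > 1e-9:
                raise ConfigError("admixture vectors must be non-negative and sum to 1")


# ---------------------------------------------------------------------------
# Pedigree construction
# ---------------------------------------------------------------------------

def _build_one_family(fid: str, target: int, rng: np.random.Generator) -> list[tuple]:
    """Grow one multigeneration pedigree to exactly ``target`` members by
    alternately letting couples reproduce and marrying unrelated founders to
    existing children (no inbreeding by construction)."""
    rows: list[tuple] = []  # (fid, iid, father, mother, sex, founder)
    serial = 0

    def new_person(father: str, mother: str, sex: int) -> str:
        nonlocal serial
        serial += 1
        iid = f"{fid}_{serial}"
        rows.append((fid, iid, father, mother, sex, father == MISSING_PARENT))
        return iid

    # founding couple
    pa = new_person(MISSING_PARENT, MISSING_PARENT, 1)
    ma = new_person(MISSING_PARENT, MISSING_PARENT, 2)
    couples = [(pa, ma)]
    marriageable: list[str] = []

    while len(rows) < target:
        if couples:
            fa, mo = couples.pop(0)
            n_kids = min(int(rng.integers(2, 5)), target - len(rows))
            for _ in range(n_kids):
                kid = new_person(fa, mo, int(rng.integers(1, 3)))
                marriageable.append(kid)
        else:
            kid = marriageable.pop(0)
            kid_sex = next(r[4] for r in rows if r[1] == kid)
            spouse = new_person(MISSING_PARENT, MISSING_PARENT, 3 - kid_sex)
            couples.append((kid, spouse) if kid_sex == 1 else (spouse, kid))
    return rows


def build_pedigree(config: SimulationConfig, rng: np.random.Generator | None = None) -> Pedigree:
    """Generate ``n_families`` extended pedigrees with sizes drawn uniformly
    from ``family_size_range``; deterministic given the config seed."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    lo, hi = config.family_size_range
    rows: list[tuple] = []
    for k in range(config.n_families):
        fid = str(k + 1)
        target = int(rng.integers(lo, hi + 1))
        rows.extend(_build_one_family(fid, target, rng))
    ped = Pedigree(
        pd.DataFrame(rows, columns=["fid", "iid", "father", "mother", "sex", "founder"])
    )
    ped.validate()
    return ped


# ---------------------------------------------------------------------------
# Ancestral frequencies and admixture
# ---------------------------------------------------------------------------

def draw_ancestral_freqs(
    n_variants: int,
    K: int,
    fst: float,
    rng: np.random.Generator,
    p_range: tuple[float, float] = (0.05, 0.95),
) -> np.ndarray:
    """Balding–Nichols population frequencies, shape (n_variants, K).

    A base frequency p ~ Uniform(p_range) per variant, then each population's
    frequency ~ Beta(p(1-Fst)/Fst, (1-p)(1-Fst)/Fst), which has mean p and
    variance Fst·p(1-p).  Variants that come out effectively fixed in every
    population are redrawn.
    """
    if not 0.0 < fst < 1.0:
        raise ConfigError(f"fst {fst} outside (0, 1)")
    eps = 1e-6
    out = np.empty((n_variants, K))
    todo = np.arange(n_variants)
    while todo.size:
        p = rng.uniform(*p_range, size=todo.size)
        a = p * (1 - fst) / fst
        b = (1 - p) * (1 - fst) / fst
        draws = rng.beta(a[:, None], b[:, None], size=(todo.size, K))
        draws = np.clip(draws, eps, 1 - eps)
        out[todo] = draws
        # monomorphic across all populations -> redraw
        fixed = (draws.max(axis=1) <= eps) | (draws.min(axis=1) >= 1 - eps)
        todo = todo[fixed]
    return out


_DIVERGENT = [
    (0.90, 0.05, 0.05),  # PC1 extreme A
    (0.05, 0.90, 0.05),  # PC1 extreme B
    (0.05, 0.05, 0.90),  # PC2 extreme A
    (0.45, 0.45, 0.10),  # PC2 extreme B
]


def assign_family_admixture(
    config: SimulationConfig,
    fids: Sequence[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-family admixture proportions (index fid, one column per ancestral
    population).  ``shared`` mode gives every family the same normalized
    concentration vector (no stratification); ``distinct`` draws Dirichlet
    vectors and optionally plants two divergent family pairs at extreme
    admixture so a pair separates on each of the first two genotype PCs."""
    conc = np.asarray(config.admixture_concentration, dtype=float)
    K = config.n_pops
    if config.admixture == "shared":
        w = np.tile(conc / conc.sum(), (len(fids), 1))
    else:
        w = rng.dirichlet(conc, size=len(fids))
        if config.plant_divergent_pairs:
            if K != 3:
                raise ConfigError("planted divergent pairs require n_pops = 3")
            if len(fids) < 4:
                raise ConfigError("planted divergent pairs require >= 4 families")
            for i, vec in enumerate(_DIVERGENT):
                w[i] = vec
    return pd.DataFrame(w, index=pd.Index(fids, name="fid"), columns=[f"pop{k+1}" for k in range(K)])


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def draw_individual_admixture(
    model: AncestryModel,
    pedigree: Pedigree,
    rng: np.random.Generator,
    concentration: float | None = 30.0,
) -> pd.DataFrame:
    """Per-individual ancestry proportions (index iid, one column per
    ancestral population).

    Founders draw their own admixture from a Dirichlet centered on the family
    vector (``concentration`` controls how tightly; ``None`` pins founders to
    the family vector exactly), and every non-founder's ancestry is the mean
    of its parents'.  This is the within-family ancestry heterogeneity real
    admixed extended pedigrees show: marry-in founders differ in admixture,
    so ancestry varies across members of the same family.
    """
    if model.family_admixture is None:
        raise ConfigError("ancestry model has no family admixture vectors")
    W = model.family_admixture
    rows: dict[str, np.ndarray] = {}
    info = pedigree.table.set_index("iid")
    for iid in pedigree.topological_order():
        r = info.loc[iid]
        if r["founder"]:
            w = W.loc[r["fid"]].to_numpy(float)
            if concentration is None:
                rows[iid] = w
            else:
                rows[iid] = rng.dirichlet(np.maximum(concentration * w, 1e-3))
        else:
            rows[iid] = 0.5 * (rows[r["father"]] + rows[r["mother"]])
    iids = pedigree.iids
    return pd.DataFrame(
        [rows[i] for i in iids], index=pd.Index(iids, name="iid"), columns=W.columns
    )


def _variant_meta(n_variants: int, rng: np.random.Generator) -> pd.DataFrame:
    width = len(str(n_variants))
    ids = [f"snp{str(j + 1).zfill(width)}" for j in range(n_variants)]
    ref_idx = rng.integers(0, 4, size=n_variants)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_variants)) % 4
    return pd.DataFrame(
        {
            "id": ids,
            "chrom": "3",
            "pos": np.arange(1, n_variants + 1) * 1000,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
        }
    )


def draw_founder_genotypes(
    model: AncestryModel,
    pedigree: Pedigree,
    rng: np.random.Generator,
    variants: pd.DataFrame | None = None,
    individual_admixture: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Founder dosages: each of the two alleles is an independent Bernoulli
    draw with success probability equal to the founder's admixture-weighted
    ancestral frequency (the founder's own vector when
    ``individual_admixture`` is given, otherwise the family vector)."""
    model.validate()
    if model.family_admixture is None:
        raise ConfigError("ancestry model has no family admixture vectors")
    founders = pedigree.table[pedigree.table["founder"]]
    missing = set(founders["fid"]) - set(model.family_admixture.index)
    if missing:
        raise ConfigError(f"families without admixture vector: {sorted(missing)[:5]}")
    if individual_admixture is not None:
        W = individual_admixture.loc[founders["iid"]].to_numpy()  # (nf, K)
    else:
        W = model.family_admixture.loc[founders["fid"]].to_numpy()  # (nf, K)
    Q = W @ model.ancestral_freqs.T  # (nf, n_variants)
    dosage = rng.binomial(2, Q).astype(float)
    if variants is None:
        variants = _variant_meta(model.ancestral_freqs.shape[0], rng)
    samples = founders[["fid", "iid"]].reset_index(drop=True)
    return GenotypeMatrix(dosage, variants, samples)


def gene_drop(
    pedigree: Pedigree,
    founder_genotypes: GenotypeMatrix,
    rng: np.random.Generator,
) -> GenotypeMatrix:
    """Drop founder alleles through the pedigree: every non-founder receives
    one allele from each parent, chosen uniformly and independently per
    variant (unlinked loci).  Mendelian-consistent by construction."""
    m = founder_genotypes.n_variants
    order = pedigree.topological_order()
    row_of: dict[str, int] = {iid: i for i, iid in enumerate(order)}
    dosage = np.full((len(order), m), np.nan)

    founder_row = {iid: i for i, iid in enumerate(founder_genotypes.iids)}
    info = pedigree.table.set_index("iid")
    for iid in order:
        r = info.loc[iid]
        if r["founder"]:
            if iid not in founder_row:
                raise DataError(f"founder {iid} has no genotypes")
            dosage[row_of[iid]] = founder_genotypes.dosage[founder_row[iid]]
        else:
            pa = dosage[row_of[r["father"]]]
            ma = dosage[row_of[r["mother"]]]
            a = (rng.random(m) < pa / 2.0).astype(float)
            b = (rng.random(m) < ma / 2.0).astype(float)
            dosage[row_of[iid]] = a + b

    fid_of = pedigree.family_of()
    samples = pd.DataFrame({"fid": [fid_of[i] for i in order], "iid": order})
    return GenotypeMatrix(dosage, founder_genotypes.variants.copy(), samples)


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

def _draw_causal(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    p = np.nanmean(genotypes.dosage, axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    eligible = np.flatnonzero(maf > config.causal_maf_min)
    if eligible.size < config.n_causal:
        raise ConfigError(
            f"only {eligible.size} variants with MAF > {config.causal_maf_min}, "
            f"need {config.n_causal} causal"
        )
    idx = np.sort(rng.choice(eligible, size=config.n_causal, replace=False))
    betas = rng.normal(0.0, config.causal_beta_sd, size=config.n_causal)
    return pd.DataFrame(
        {"variant_id": np.asarray(genotypes.variant_ids)[idx], "beta": betas}
    )


def simulate_traits(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    config: SimulationConfig,
    rng: np.random.Generator,
    causal: pd.DataFrame | None = None,
    ancestry: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantitative trait and genetics-free null trait for every genotyped
    individual.

    trait = b0 + b_med·med + b_sex·sex + b_age·age + b_sexage·sex·age
            + b_anc·(ancestry − mean) + Σ_c β_c·dosage_c + u_family + e,
    with u ~ N(0, σ²_fam) and e ~ N(0, σ²_e).

    ``ancestry`` maps each individual id to its leading admixture
    proportion; ``b_anc`` models environmental exposure that covaries with
    ancestry (diet, socioeconomic factors), the mechanism by which
    population stratification confounds association: it shifts trait means
    along the ancestry axis both between and within families.  The
    between-family part is absorbed by any family intercept, but the
    within-family part (marry-in founders differ in admixture) is not —
    individual-level PC covariates are needed.  The effect enters through
    admixture proportions only, never through genotypes.

    The null trait redraws u and e with all β_c = 0 on the same covariates
    (ancestry effect included), so it retains the family and ancestry
    covariance but has zero dependence on genotype.  Returns
    (trait table, causal table).
    """
    config.validate()
    if causal is None:
        causal = _draw_causal(genotypes, config, rng)
    missing = set(causal["variant_id"]) - set(genotypes.variant_ids)
    if missing:
        raise ConfigError(f"causal variants absent from genotypes: {sorted(missing)[:5]}")

    samples = genotypes.samples
    n = len(samples)
    ped = pedigree.table.set_index("iid")
    sex_code = ped.loc[samples["iid"], "sex"].to_numpy()
    sex = (sex_code == 2).astype(float)  # 1 = female
    age = rng.uniform(*config.age_range, size=n)
    med = (rng.random(n) < config.medication_rate).astype(float)

    g = genotypes.dosage[:, genotypes.variant_indexer(causal["variant_id"])]
    genetic = np.nan_to_num(g) @ causal["beta"].to_numpy()

    fids = samples["fid"].to_numpy()
    fixed = (
        config.beta_intercept
        + config.beta_medication * med
        + config.beta_sex * sex
        + config.beta_age * age
        + config.beta_sex_age * sex * age
    )
    if ancestry is not None and config.beta_ancestry != 0.0:
        anc = ancestry.loc[samples["iid"]].to_numpy(float)
        fixed = fixed + config.beta_ancestry * (anc - anc.mean())

    fam_ids = pd.unique(fids)
    sd_f = np.sqrt(config.sigma2_family)
    sd_e = np.sqrt(config.sigma2_resid)

    def family_effect() -> np.ndarray:
        u = dict(zip(fam_ids, rng.normal(0.0, sd_f, size=len(fam_ids))))
        return np.array([u[f] for f in fids])

    trait = fixed + genetic + family_effect() + rng.normal(0.0, sd_e, size=n)
    null_trait = fixed + family_effect() + rng.normal(0.0, sd_e, size=n)

    table = pd.DataFrame(
        {
            "fid": fids,
            "iid": samples["iid"],
            "trait": trait,
            "null_trait": null_trait,
            "medication": med.astype(int),
            "sex": sex.astype(int),
            "age": age,
        }
    )
    return table, causal


# ---------------------------------------------------------------------------
# One-call dataset
# ---------------------------------------------------------------------------

@dataclass
class SimulatedData:
    config: SimulationConfig
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    traits: pd.DataFrame
    causal: pd.DataFrame
    model: AncestryModel
    ancestry: pd.DataFrame | None = None  # per-individual admixture (iid x K)


def simulate_dataset(config: SimulationConfig) -> SimulatedData:
    """Run the full generator: pedigree -> ancestral frequencies ->
    individual admixture -> founder genotypes -> gene drop -> traits."""
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rngs = [np.random.default_rng(s) for s in streams]

    pedigree = build_pedigree(config, rngs[0])
    freqs = draw_ancestral_freqs(config.n_variants, config.n_pops, config.fst, rngs[1])
    fids_in_order = pd.unique(pedigree.table["fid"]).tolist()
    admix = assign_family_admixture(config, fids_in_order, rngs[1])
    model = AncestryModel(config.n_pops, freqs, config.fst, admix)
    # "shared" mode is the ancestry-homogeneous (no-stratification) condition:
    # founders are pinned to the common vector so no individual varies.
    conc = None if config.admixture == "shared" else config.founder_admixture_concentration
    indiv = draw_individual_admixture(model, pedigree, rngs[2], conc)
    founders = draw_founder_genotypes(model, pedigree, rngs[2], individual_admixture=indiv)
    genotypes = gene_drop(pedigree, founders, rngs[3])
    traits, causal = simulate_traits(
        genotypes, pedigree, config, rngs[4],
        ancestry=indiv.iloc[:, 0],
    )
    return SimulatedData(config, pedigree, genotypes, traits, causal, model, indiv)


def write_dataset(data: SimulatedData, outdir: str | Path, vcf: bool = False) -> dict[str, Path]:
    """Write PED/MAP, FAM, phenotype TSV, causal-variant TSV (and optionally
    VCF) under ``outdir``; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = data.config.seed
    paths: dict[str, Path] = {}

    ped, mp = write_ped_map(data.genotypes, outdir / "genotypes", pedigree=data.pedigree)
    paths["ped"], paths["map"] = ped, mp
    fam = outdir / "genotypes.fam"
    data.pedigree.write_fam(fam)
    paths["fam"] = fam

    pheno = outdir / "phenotypes.tsv"
    with open(pheno, "w") as fh:
        fh.write(f"# seed={seed}\n")
        data.traits.to_csv(fh, sep="\t", index=False)
    paths["phenotypes"] = pheno

    causal = outdir / "causal.tsv"
    with open(causal, "w") as fh:
        fh.write(f"# seed={seed}\n")
        data.causal.to_csv(fh, sep="\t", index=False)
    paths["causal"] = causal

    admix = outdir / "admixture.tsv"
    with open(admix, "w") as fh:
        fh.write(f"# seed={seed}\n")
        data.model.family_admixture.to_csv(fh, sep="\t")
    paths["admixture"] = admix

    if data.ancestry is not None:
        anc = outdir / "ancestry.tsv"
        with open(anc, "w") as fh:
            fh.write(f"# seed={seed}\n")
            data.ancestry.to_csv(fh, sep="\t")
        paths["ancestry"] = anc

    if vcf:
        paths["vcf"] = write_vcf(data.genotypes, outdir / "genotypes.vcf", seed=seed)
    return paths
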