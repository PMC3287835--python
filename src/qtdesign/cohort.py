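"""Seeded synthetic cohorts for trait-dependent sampling experiments.

The generator emulates the structure of a sequencing cohort of unrelated
individuals: a panel of rare SNPs (MAF < 3%) of which a subset is functional,
one common SNP carried only in heterozygous form, covariates (age, sex,
smoking), and a quantitative trait simulated over many replicates either with
genetic effects (``alternative``) or from covariates alone (``null``).

Genotypes are drawn under Hardy-Weinberg equilibrium (two independent
Bernoulli allele draws per individual).  A deterministic 321-individual
reference cohort, :func:`reference_cohort`, reproduces a published rare-allele
count spectrum (252/54/11/4 individuals carrying 0-3 rare alleles) and a
common SNP with 56 heterozygotes (MAF 8.72%, no rare homozygotes).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SnpSpec",
    "Cohort",
    "TraitModel",
    "default_snp_panel",
    "simulate_genotypes",
    "simulate_covariates",
    "simulate_traits",
    "make_cohort",
    "reference_cohort",
    "write_phenotype_csv",
    "read_phenotype_csv",
    "write_genotype_csv",
    "read_genotype_csv",
    "write_vcf",
    "read_vcf",
]

# Reference cohort dimensions: 321 individuals, 18 rare SNPs (6 functional),
# one common SNP at MAF 56/642 = 8.72% with no rare homozygotes.
N_REFERENCE = 321
N_RARE_SNPS = 18
N_FUNCTIONAL = 6
COMMON_MAF = 56 / 642
RARE_SCORE_SPECTRUM = (252, 54, 11, 4)  # individuals with 0,1,2,3 rare alleles


def _rng(seed):
    """Accept an int, SeedSequence, or Generator and return a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SnpSpec:
    """A single SNP: identifier, minor allele frequency, and trait effect.

    ``effect`` is in trait units per minor allele and must be 0 for
    non-functional SNPs.  ``no_rare_homozygote`` forbids dosage-2 genotypes
    (used for the common SNP, observed only in heterozygous carriers).
    """

    snp_id: str
    maf: float
    functional: bool = False
    effect: float = 0.0
    no_rare_homozygote: bool = False

    def __post_init__(self):
        if not (0.0 <= self.maf <= 1.0):
            raise ValueError(f"maf must be in [0, 1], got {self.maf}")
        if not self.functional and self.effect != 0.0:
            raise ValueError("non-functional SNP must have effect 0")


@dataclass
class TraitModel:
    """Generating model for the quantitative trait.

    trait = b_age*age + b_sex*sex + b_smk*smoking
            + common_effect*G_common + sum_j rare_effects[j]*G_j
            + N(0, residual_sd), independently per replicate.

    A null trait sets every genetic effect to zero.
    """

    covariate_effects: tuple[float, float, float] = (0.01, 0.2, 0.3)
    common_effect: float = 1.0
    rare_effects: np.ndarray | None = None  # per rare SNP; None -> from SnpSpec
    residual_sd: float = 1.0
    n_replicates: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class Cohort:
    """Covariates, genotypes, SNP metadata, and replicated trait values."""

    covariates: pd.DataFrame  # columns: age, sex, smoking
    genotypes: np.ndarray  # n x m minor-allele dosage, entries in {0,1,2}
    snps: list[SnpSpec]
    traits: np.ndarray | None = None  # n x R
    trait_kind: str = "null"

    @property
    def n(self) -> int:
        return len(self.covariates)

    @property
    def n_replicates(self) -> int:
        return 0 if self.traits is None else self.traits.shape[1]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def validate(self) -> None:
        if not np.isin(self.genotypes, (0, 1, 2)).all():
            raise ValueError("genotype dosages must be in {0, 1, 2}")
        for j, s in enumerate(self.snps):
            if s.no_rare_homozygote and (self.genotypes[:, j] == 2).any():
                raise ValueError(f"{s.snp_id}: homozygote present but forbidden")
        if self.traits is not None and self.traits.shape[0] != self.n:
            raise ValueError("trait rows must match cohort size")


def default_snp_panel(
    n_rare: int = N_RARE_SNPS,
    n_functional: int = N_FUNCTIONAL,
    rare_effect: float = 0.44,
    common_maf: float = COMMON_MAF,
    common_effect: float = 1.0,
) -> list[SnpSpec]:
    """Rare SNP panel plus one common SNP, mirroring the reference cohort.

    Rare MAFs are spread evenly below 3%; the first ``n_functional`` rare SNPs
    carry ``rare_effect`` trait units per allele.  The common SNP is flagged
    ``no_rare_homozygote``.
    """
    snps = []
    for j in range(n_rare):
        maf = 0.0025 + 0.025 * j / max(n_rare - 1, 1)  # 0.25% .. 2.75%
        functional = j < n_functional
        snps.append(
            SnpSpec(
                snp_id=f"RS{j + 1:02d}",
                maf=maf,
                functional=functional,
                effect=rare_effect if functional else 0.0,
            )
        )
    snps.append(
        SnpSpec(
            snp_id="CS523",
            maf=common_maf,
            functional=common_effect != 0.0,
            effect=common_effect,
            no_rare_homozygote=True,
        )
    )
    return snps


def simulate_genotypes(n: int, snps: list[SnpSpec], seed) -> np.ndarray:
    """Draw an n x m dosage matrix under Hardy-Weinberg equilibrium.

    Each column sums two Bernoulli(maf) allele draws.  For SNPs flagged
    ``no_rare_homozygote``, dosage-2 entries are redrawn until none remain.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    out = np.empty((n, len(snps)), dtype=np.int64)
    for j, s in enumerate(snps):
        col = rng.binomial(1, s.maf, n) + rng.binomial(1, s.maf, n)
        if s.no_rare_homozygote:
            while (mask := col == 2).any():
                k = int(mask.sum())
                col[mask] = rng.binomial(1, s.maf, k) + rng.binomial(1, s.maf, k)
        out[:, j] = col
    return out


def simulate_covariates(
    n: int,
    seed,
    age_range: tuple[float, float] = (30.0, 70.0),
    sex_rate: float = 0.5,
    smoking_rate: float = 0.3,
) -> pd.DataFrame:
    """Draw age ~ Uniform(age_range), sex and smoking ~ Bernoulli."""
    if n < 1:
        raise ValueError("n must be >= 1")
    for name, rate in (("sex_rate", sex_rate), ("smoking_rate", smoking_rate)):
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    rng = _rng(seed)
    return pd.DataFrame(
        {
            "age": rng.uniform(age_range[0], age_range[1], n),
            "sex": rng.binomial(1, sex_rate, n),
            "smoking": rng.binomial(1, smoking_rate, n),
        }
    )


def simulate_traits(cohort: Cohort, model: TraitModel) -> np.ndarray:
    """Simulate an n x R trait matrix from covariates, genotypes, and noise.

    ``model.rare_effects`` overrides the per-SNP effects recorded in the
    cohort's SnpSpecs for the rare (non-``no_rare_homozygote``) SNPs; the
    common-SNP effect is ``model.common_effect``.  For a null trait pass a
    model with all genetic effects zero.
    """
    cov = cohort.covariates
    b_age, b_sex, b_smk = model.covariate_effects
    eta = b_age * cov["age"].to_numpy() + b_sex * cov["sex"].to_numpy() + b_smk * cov[
        "smoking"
    ].to_numpy()

    effects = np.array([s.effect for s in cohort.snps], dtype=float)
    common_mask = np.array([s.no_rare_homozygote for s in cohort.snps])
    if model.rare_effects is not None:
        rare_eff = np.asarray(model.rare_effects, dtype=float)
        if rare_eff.shape != ((~common_mask).sum(),):
            raise ValueError("rare_effects length must match number of rare SNPs")
        effects[~common_mask] = rare_eff
    effects[common_mask] = model.common_effect
    eta = eta + cohort.genotypes @ effects

    rng = _rng(model.seed)
    noise = rng.normal(0.0, model.residual_sd, (cohort.n, model.n_replicates))
    return eta[:, None] + noise


def make_cohort(
    n: int = N_REFERENCE,
    snps: list[SnpSpec] | None = None,
    trait_kind: str = "alternative",
    n_replicates: int = 200,
    seed: int = 0,
    trait_model: TraitModel | None = None,
) -> Cohort:
    """Simulate a complete cohort: genotypes, covariates, and traits.

    ``trait_kind='null'`` zeroes every genetic effect in the trait model;
    the genotypes themselves are unchanged.
    """
    if trait_kind not in ("alternative", "null"):
        raise ValueError("trait_kind must be 'alternative' or 'null'")
    snps = default_snp_panel() if snps is None else snps
    ss = np.random.SeedSequence(seed)
    geno_seed, cov_seed, trait_seed = ss.spawn(3)
    genotypes = simulate_genotypes(n, snps, np.random.default_rng(geno_seed))
    covariates = simulate_covariates(n, np.random.default_rng(cov_seed))
    cohort = Cohort(covariates=covariates, genotypes=genotypes, snps=snps,
                    trait_kind=trait_kind)
    if trait_model is None:
        trait_model = TraitModel(n_replicates=n_replicates)
    trait_model = replace(trait_model, seed=np.random.default_rng(trait_seed))
    if trait_kind == "null":
        n_rare = sum(not s.no_rare_homozygote for s in snps)
        trait_model = replace(
            trait_model, common_effect=0.0, rare_effects=np.zeros(n_rare)
        )
    cohort.traits = simulate_traits(cohort, trait_model)
    cohort.validate()
    return cohort


def _reference_genotypes() -> tuple[np.ndarray, list[SnpSpec]]:
    """Deterministic 321 x 19 dosage matrix with the reference score spectrum.

    Rare alleles are laid out so 54 individuals carry exactly 1 rare allele,
    11 carry 2, and 4 carry 3 (252 carry none); multi-allele carriers hold
    their alleles at distinct SNPs, so no rare dosage exceeds 1.  Alleles are
    assigned to the 18 rare SNPs round-robin, keeping every rare MAF below 3%.
    The final column is the common SNP: 56 heterozygotes, no homozygotes.
    """
    n = N_REFERENCE
    geno = np.zeros((n, N_RARE_SNPS + 1), dtype=np.int64)
    counts = np.repeat([1, 2, 3, 0], RARE_SCORE_SPECTRUM[1:] + (0,))
    # individuals 0..53 score 1, 54..64 score 2, 65..68 score 3, rest 0
    allele = 0
    for i, c in enumerate(counts):
        for _ in range(c):
            geno[i, allele % N_RARE_SNPS] += 1
            allele += 1
    geno[:56, N_RARE_SNPS] = 1  # common SNP heterozygotes
    mafs = geno.sum(axis=0) / (2 * n)
    snps = [
        SnpSpec(f"RS{j + 1:02d}", maf=mafs[j], functional=j < N_FUNCTIONAL,
                effect=0.44 if j < N_FUNCTIONAL else 0.0)
        for j in range(N_RARE_SNPS)
    ]
    snps.append(SnpSpec("CS523", maf=mafs[-1], functional=True, effect=1.0,
                        no_rare_homozygote=True))
    return geno, snps


def reference_cohort(
    trait_kind: str = "null", n_replicates: int = 200, seed: int = 20110929
) -> Cohort:
    """The packaged 321-individual cohort with the exact reference spectrum.

    Genotypes are constructed deterministically (not sampled); covariates and
    traits are simulated from ``seed``.
    """
    genotypes, snps = _reference_genotypes()
    ss = np.random.SeedSequence(seed)
    cov_seed, trait_seed = ss.spawn(2)
    covariates = simulate_covariates(N_REFERENCE, np.random.default_rng(cov_seed))
    cohort = Cohort(covariates=covariates, genotypes=genotypes, snps=snps,
                    trait_kind=trait_kind)
    model = TraitModel(n_replicates=n_replicates,
                       seed=np.random.default_rng(trait_seed))
    if trait_kind == "null":
        model = replace(model, common_effect=0.0, rare_effects=np.zeros(N_RARE_SNPS))
    else:
        model = replace(model, rare_effects=None)
    cohort.traits = simulate_traits(cohort, model)
    cohort.validate()
    return cohort


# ---------------------------------------------------------------------------
# I/O: phenotype/genotype CSV and a minimal unphased VCF


def write_phenotype_csv(cohort: Cohort, path) -> None:
    df = cohort.covariates.copy()
    df.insert(0, "id", [f"IND{i + 1:04d}" for i in range(cohort.n)])
    if cohort.traits is not None:
        for r in range(cohort.n_replicates):
            df[f"trait_r{r + 1}"] = cohort.traits[:, r]
    df.to_csv(path, index=False)


def read_phenotype_csv(path) -> tuple[pd.DataFrame, np.ndarray]:
    """Return (covariate table, n x R trait matrix)."""
    df = pd.read_csv(path)
    trait_cols = sorted(
        (c for c in df.columns if c.startswith("trait_r")),
        key=lambda c: int(c.removeprefix("trait_r")),
    )
    covariates = df[["age", "sex", "smoking"]].copy()
    traits = df[trait_cols].to_numpy() if trait_cols else np.empty((len(df), 0))
    return covariates, traits


def write_genotype_csv(cohort: Cohort, path) -> None:
    df = pd.DataFrame(cohort.genotypes, columns=cohort.snp_ids)
    df.insert(0, "id", [f"IND{i + 1:04d}" for i in range(cohort.n)])
    df.to_csv(path, index=False)


def read_genotype_csv(path) -> pd.DataFrame:
    """Dosage matrix indexed by individual id, one column per SNP."""
    return pd.read_csv(path, index_col="id")


def write_vcf(cohort: Cohort, path) -> None:
    """Minimal unphased VCF (GT only) with one record per SNP."""
    ids = [f"IND{i + 1:04d}" for i in range(cohort.n)]
    gt = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ids) + "\n")
        for j, s in enumerate(cohort.snps):
            calls = "\t".join(gt[int(d)] for d in cohort.genotypes[:, j])
            fh.write(f"1\t{j + 1}\t{s.snp_id}\tA\tT\t.\tPASS\t.\tGT\t{calls}\n")


def read_vcf(path) -> pd.DataFrame:
    """Read a VCF into a dosage DataFrame (individuals x SNPs) via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    cols, ids = {}, vcf.samples
    for rec in vcf:
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt (gts012=False maps 3->hom-alt)
        dosage = np.array([sum(g[:2]) for g in rec.genotypes], dtype=np.int64)
        cols[rec.ID] = dosage
    return pd.DataFrame(cols, index=ids)
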