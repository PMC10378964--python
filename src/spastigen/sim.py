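"""Synthetic pedigreed case-control cohorts.

Generates the statistical structure a kinship-aware binary-trait GWAS
assumes: a multi-generation half-sib pedigree (few sires per generation,
as in AI-bred dairy cattle), gene-dropped SNP genotypes across 29
autosomes, and a liability-threshold disease phenotype driven by a few
QTL plus a pedigree-consistent polygenic background.

Defaults emulate the study cohort this toolkit targets: ~50K-density
markers on 29 autosomes, an underlying-scale heritability of 0.41, a
59.25% case prevalence in a cohort of 265 phenotyped animals split into
a 40-animal training set and a 225-animal test set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .kinship import Pedigree, inbreeding, UNKNOWN
from .io import GenotypeMatrix, MarkerMap, MISSING


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Cohort-simulation parameters.

    The defaults are the study conditions: 29 autosomes at 50K-chip marker
    density (~51.5 kb spacing), a half-sib pedigree deep enough to supply
    265 phenotyped animals, five liability QTL on a polygenic background
    with underlying heritability 0.41, and a 59.25% case prevalence.
    """

    n_chromosomes: int = 29
    snps_per_chromosome: int = 1443
    chromosome_length_bp: int = 86_000_000
    n_founders: int = 50
    n_generations: int = 3
    offspring_per_mating: int = 4
    n_sires_per_generation: int = 4
    n_phenotyped: int = 265
    n_training: int = 40
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtl: int = 5
    qtl_effect_sd: float = 0.35
    h2_underlying: float = 0.41
    prevalence_target: float = 0.5925
    missing_rate: float = 0.0
    crossovers_per_meiosis: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_founders < 2:
            raise ConfigError("n_founders must be >= 2")
        if self.n_generations < 1:
            raise ConfigError("n_generations must be >= 1")
        if self.offspring_per_mating < 1:
            raise ConfigError("offspring_per_mating must be >= 1")
        if not (0.0 <= self.h2_underlying <= 1.0):
            raise ConfigError("h2_underlying must lie in [0, 1]")
        if not (0.0 < self.prevalence_target < 1.0):
            raise ConfigError("prevalence_target must lie in (0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must lie in [0, 1)")
        lo, hi = self.founder_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("founder_maf_range must be within (0, 0.5]")
        if self.n_qtl < 0:
            raise ConfigError("n_qtl must be >= 0")


@dataclass
class PhenotypeTable:
    """Binary disease statuses (1 = affected, 0 = unaffected)."""

    animal_ids: list[str]
    status: np.ndarray
    liability: np.ndarray | None = None
    realized_prevalence: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"animal": self.animal_ids,
                             "status": self.status.astype(int)})

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class CohortBundle:
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    true_qtl: list[tuple[int, float]]
    true_h2_underlying: float
    training_ids: list[str] = field(default_factory=list)
    testing_ids: list[str] = field(default_factory=list)

    @property
    def marker_map(self) -> MarkerMap:
        return self.genotypes.marker_map


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Multi-generation half-sib pedigree.

    Founders have unknown parents; in each later generation every dam of
    the previous generation is mated to one of a handful of sires, which
    induces the large paternal half-sib families typical of AI breeding.
    """
    config.validate()
    rng = np.random.default_rng(_substream(config.seed, 1))
    animal: list[str] = []
    sire: list[str] = []
    dam: list[str] = []
    sex: dict[str, int] = {}  # 0 = male, 1 = female

    males: list[str] = []
    females: list[str] = []
    for i in range(config.n_founders):
        aid = f"F{i + 1}"
        animal.append(aid); sire.append(UNKNOWN); dam.append(UNKNOWN)
        sex[aid] = i % 2
        (males if i % 2 == 0 else females).append(aid)

    counter = 0
    for gen in range(1, config.n_generations + 1):
        if not males or not females:
            raise ConfigError("a generation ran out of sires or dams")
        n_sires = min(config.n_sires_per_generation, len(males))
        gen_sires = list(rng.choice(males, size=n_sires, replace=False))
        new_males: list[str] = []
        new_females: list[str] = []
        for mother in females:
            father = gen_sires[int(rng.integers(len(gen_sires)))]
            for _ in range(config.offspring_per_mating):
                counter += 1
                aid = f"G{gen}_{counter}"
                animal.append(aid); sire.append(father); dam.append(mother)
                s = int(rng.integers(2))
                sex[aid] = s
                (new_males if s == 0 else new_females).append(aid)
        males, females = new_males, new_females
    return Pedigree(animal, sire, dam)


def default_marker_map(config: SimConfig) -> MarkerMap:
    """Evenly spaced biallelic markers (A/B) on each autosome."""
    chrom = np.repeat(np.arange(1, config.n_chromosomes + 1),
                      config.snps_per_chromosome)
    spacing = config.chromosome_length_bp // (config.snps_per_chromosome + 1)
    pos = np.tile((np.arange(config.snps_per_chromosome) + 1) * spacing,
                  config.n_chromosomes)
    ids = [f"SNP{c}_{i + 1}" for c in range(1, config.n_chromosomes + 1)
           for i in range(config.snps_per_chromosome)]
    return MarkerMap(pd.DataFrame({
        "snp_id": ids, "chromosome": chrom, "position_bp": pos,
        "allele_a": "A", "allele_b": "B"}))


def simulate_genotypes(pedigree: Pedigree, marker_map: MarkerMap,
                       config: SimConfig) -> GenotypeMatrix:
    """Gene-dropping with per-chromosome recombination.

    Founder haplotype alleles are Bernoulli draws at per-SNP frequencies
    sampled uniformly from ``founder_maf_range``; descendants inherit one
    recombined haplotype per parent (``crossovers_per_meiosis`` uniformly
    placed crossovers per chromosome per meiosis).  Dosage counts the B
    allele; missing calls are injected completely at random.
    """
    config.validate()
    rng = np.random.default_rng(_substream(config.seed, 2))
    m = len(marker_map)
    n = len(pedigree)
    par = pedigree.parent_indices()
    if np.any((par >= 0).sum(axis=1) == 1):
        bad = [pedigree.animal[i] for i in
               np.nonzero((par >= 0).sum(axis=1) == 1)[0]][:5]
        raise ConfigError(
            f"animals with exactly one known parent unsupported: {bad}")

    freq = rng.uniform(*config.founder_maf_range, size=m)
    chrom = marker_map.df["chromosome"].to_numpy()
    chrom_slices = [np.flatnonzero(chrom == c)
                    for c in np.unique(chrom)]

    hap = np.zeros((n, 2, m), dtype=np.int8)
    for i in range(n):
        s, d = par[i]
        if s < 0 and d < 0:
            hap[i] = rng.random((2, m)) < freq
        else:
            hap[i, 0] = _meiosis(hap[s], chrom_slices, m, rng,
                                 config.crossovers_per_meiosis)
            hap[i, 1] = _meiosis(hap[d], chrom_slices, m, rng,
                                 config.crossovers_per_meiosis)
    dosage = hap.sum(axis=1).astype(np.int8)
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = MISSING
    return GenotypeMatrix(list(pedigree.animal), marker_map, dosage)


def _meiosis(parent_hap: np.ndarray, chrom_slices: list[np.ndarray],
             m: int, rng: np.random.Generator, n_crossovers: int) -> np.ndarray:
    """One gamete: per chromosome, crossover(s) at uniform marker positions."""
    gamete = np.empty(m, dtype=np.int8)
    for idx in chrom_slices:
        k = len(idx)
        cuts = np.sort(rng.integers(0, k + 1, size=n_crossovers))
        current = int(rng.integers(2))
        take = np.empty(k, dtype=np.int8)
        prev = 0
        for cut in list(cuts) + [k]:
            take[prev:cut] = current
            current = 1 - current
            prev = cut
        gamete[idx] = np.where(take == 0, parent_hap[0, idx],
                               parent_hap[1, idx])
    return gamete


def simulate_liability_phenotypes(pedigree: Pedigree,
                                  genotypes: GenotypeMatrix,
                                  config: SimConfig,
                                  animal_ids: list[str] | None = None,
                                  ) -> tuple[PhenotypeTable,
                                             list[tuple[int, float]]]:
    """Liability-threshold phenotypes for a (sub)set of genotyped animals.

    liability = sum_k beta_k g_k  +  u  +  e, with the polygenic effect u
    simulated by the pedigree cascade (founders ~ N(0, s2_u); offspring
    u = (u_s + u_d)/2 + Mendelian-sampling term with variance
    s2_u * (0.5 - 0.25(F_s + F_d))), e ~ N(0, 1), and s2_u chosen so that
    Var(QTL term) + s2_u equals h2/(1-h2) on the unit-residual scale.
    Affection status is assigned by thresholding at the realized
    (1 - prevalence) liability quantile, which guarantees the target case
    count up to integer rounding.
    """
    config.validate()
    rng = np.random.default_rng(_substream(config.seed, 3))
    if animal_ids is None:
        animal_ids = list(genotypes.animal_ids)
    m = len(genotypes.marker_map)

    total_genetic = (config.h2_underlying / (1.0 - config.h2_underlying)
                     if config.h2_underlying < 1.0 else float("inf"))

    qtl_idx = np.sort(rng.choice(m, size=config.n_qtl, replace=False)) \
        if config.n_qtl else np.array([], dtype=int)
    betas = rng.normal(0.0, config.qtl_effect_sd, size=len(qtl_idx))

    pos = {a: i for i, a in enumerate(genotypes.animal_ids)}
    rows = np.array([pos[a] for a in animal_ids])
    g_qtl = genotypes.dosage[np.ix_(rows, qtl_idx)].astype(float) \
        if len(qtl_idx) else np.zeros((len(rows), 0))
    g_qtl[g_qtl == MISSING] = np.nan
    col_mean = np.nanmean(g_qtl, axis=0) if g_qtl.size else np.array([])
    inds = np.where(np.isnan(g_qtl))
    if inds[0].size:
        g_qtl[inds] = np.take(col_mean, inds[1])
    qtl_term = g_qtl @ betas if len(qtl_idx) else np.zeros(len(rows))
    var_qtl = float(np.var(qtl_term)) if len(rows) > 1 else 0.0
    sigma2_u = total_genetic - var_qtl
    if sigma2_u < 0:
        raise ConfigError(
            f"QTL variance {var_qtl:.3f} exceeds the target genetic "
            f"variance {total_genetic:.3f}; lower qtl_effect_sd or n_qtl")

    u = _polygenic_cascade(pedigree, sigma2_u, rng)
    u_named = dict(zip(pedigree.animal, u))
    liability = (qtl_term
                 + np.array([u_named[a] for a in animal_ids])
                 + rng.normal(0.0, 1.0, size=len(animal_ids)))

    n_aff = int(round(config.prevalence_target * len(animal_ids)))
    order = np.argsort(-liability, kind="stable")
    status = np.zeros(len(animal_ids), dtype=int)
    status[order[:n_aff]] = 1
    table = PhenotypeTable(list(animal_ids), status, liability,
                           realized_prevalence=n_aff / len(animal_ids))
    return table, list(zip(qtl_idx.tolist(), betas.tolist()))


def _polygenic_cascade(pedigree: Pedigree, sigma2_u: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Pedigree-cascade polygenic effects, exactly A-consistent."""
    n = len(pedigree)
    par = pedigree.parent_indices()
    F = inbreeding(pedigree).to_numpy()
    u = np.zeros(n)
    sd = np.sqrt(max(sigma2_u, 0.0))
    for i in range(n):
        s, d = par[i]
        if s < 0 and d < 0:
            u[i] = rng.normal(0.0, sd)
        else:
            msv = 0.5 - 0.25 * (F[s] + F[d])
            u[i] = 0.5 * (u[s] + u[d]) + rng.normal(0.0, sd * np.sqrt(msv))
    return u


def simulate_cohort(config: SimConfig | None = None) -> CohortBundle:
    """End-to-end cohort: pedigree, genotypes, phenotypes, train/test split.

    Phenotyped animals are drawn from the final generation (emulating a
    contemporary screened cohort); the first ``n_training`` of a seeded
    shuffle form the training set, the rest the test set.
    """
    config = config or SimConfig()
    config.validate()
    pedigree = simulate_pedigree(config)
    marker_map = default_marker_map(config)
    genotypes = simulate_genotypes(pedigree, marker_map, config)

    rng = np.random.default_rng(_substream(config.seed, 4))
    last_gen = [a for a in pedigree.animal
                if a.startswith(f"G{config.n_generations}_")]
    if len(last_gen) < config.n_phenotyped:
        raise ConfigError(
            f"final generation has {len(last_gen)} animals; "
            f"{config.n_phenotyped} phenotyped requested — increase "
            "n_founders, offspring_per_mating or n_generations")
    chosen = list(rng.choice(last_gen, size=config.n_phenotyped,
                             replace=False))
    phenotypes, true_qtl = simulate_liability_phenotypes(
        pedigree, genotypes, config, animal_ids=chosen)
    shuffled = list(chosen)
    rng.shuffle(shuffled)
    training = sorted(shuffled[:config.n_training])
    testing = sorted(shuffled[config.n_training:])
    return CohortBundle(pedigree, genotypes, phenotypes, true_qtl,
                        config.h2_underlying, training, testing)


def write_cohort(bundle: CohortBundle, out_prefix, gene_halfwidth_bp: int = 250_000,
                 ) -> dict[str, str]:
    """Write the cohort as plain-text analysis inputs.

    Produces PLINK .ped/.map, pedigree and phenotype CSVs, train/test id
    lists, a BED file of synthetic "genes" planted around each QTL, and a
    JSON truth file (QTL indices/effects, true heritability) for harnesses.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    from . import io as gio
    paths = {
        "ped": str(out_prefix) + ".ped",
        "map": str(out_prefix) + ".map",
        "pedigree": str(out_prefix) + ".pedigree.csv",
        "phenotypes": str(out_prefix) + ".phenotypes.csv",
        "train_ids": str(out_prefix) + ".train_ids.txt",
        "test_ids": str(out_prefix) + ".test_ids.txt",
        "genes": str(out_prefix) + ".genes.bed",
        "truth": str(out_prefix) + ".truth.json",
    }
    gio.write_plink_text(bundle.genotypes, paths["ped"], paths["map"])
    bundle.pedigree.write_csv(paths["pedigree"])
    bundle.phenotypes.write_csv(paths["phenotypes"])
    Path(paths["train_ids"]).write_text("\n".join(bundle.training_ids) + "\n")
    Path(paths["test_ids"]).write_text("\n".join(bundle.testing_ids) + "\n")

    mm = bundle.marker_map.df
    with open(paths["genes"], "w") as fh:
        for k, (snp_idx, _effect) in enumerate(bundle.true_qtl):
            chrom = int(mm["chromosome"].iloc[snp_idx])
            pos = int(mm["position_bp"].iloc[snp_idx])
            start0 = max(0, pos - gene_halfwidth_bp - 1)  # BED half-open
            end = pos + gene_halfwidth_bp
            fh.write(f"{chrom}\t{start0}\t{end}\tQTLGENE{k + 1}\n")

    truth = {
        "true_qtl": [{"snp_index": int(i),
                      "snp_id": str(mm["snp_id"].iloc[i]),
                      "effect": float(b)} for i, b in bundle.true_qtl],
        "true_h2_underlying": bundle.true_h2_underlying,
        "realized_prevalence": bundle.phenotypes.realized_prevalence,
        "n_phenotyped": len(bundle.phenotypes.animal_ids),
    }
    Path(paths["truth"]).write_text(json.dumps(truth, indent=2) + "\n")
    return paths


def config_from_dict(d: dict) -> SimConfig:
    known = {f for f in SimConfig.__dataclass_fields__}
    unknown = set(d) - known
    if unknown:
        raise ConfigError(f"unknown simulation config keys: {sorted(unknown)}")
    if "founder_maf_range" in d:
        d = dict(d)
        d["founder_maf_range"] = tuple(d["founder_maf_range"])
    cfg = SimConfig(**d)
    cfg.validate()
    return cfg


def _substream(seed: int, stream: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(stream,))
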