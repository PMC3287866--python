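"""Gene-drop simulation of pedigrees, rare variants, and phenotype replicates.

The simulator is the package's fixture factory and reproduces the
statistical structure the association tests assume:

* founder haplotypes carry each marker's rare allele independently with
  its population MAF (optionally a fixed number of copies can be placed,
  to construct variants private to a chosen family);
* every non-founder receives one allele from each parent, chosen
  uniformly and independently per marker (no within-gene linkage or
  recombination model — rare variants are nearly always on distinct
  haplotypes and the collapsing method does not use LD);
* disease status comes from an additive liability model: liability
  ``L_i = sum_j beta_j * (2 * dosage_ij) + eps_i`` with standard normal
  noise redrawn per replicate, thresholded at the empirical (1 - k)
  quantile so every replicate has exactly ``round(k * n)`` cases.
  Genotypes are held fixed across phenotype replicates, mirroring a
  replicate-phenotype study design.

One global integer seed governs everything through an explicit
``SeedSequence`` spawn-key scheme, so any single replicate can be
regenerated in isolation: ``(0,)`` for the gene drop, ``(1, r)`` for
phenotype replicate ``r``, ``(9,)`` for scenario construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pedigree import Individual, Pedigree, Sex, compute_kinship, write_fam
from .variant_data import (
    GenotypeMatrix,
    PhenotypeReplicates,
    write_annotation,
    write_dosage_tsv,
    write_phenotypes,
)


@dataclass(frozen=True)
class MarkerSpec:
    """One simulated marker.

    ``effect_beta`` is the per-allele effect on the liability scale (an
    individual's liability shifts by ``beta`` per rare allele carried).
    If ``n_founder_copies`` is set, exactly that many rare-allele copies
    are placed on founder haplotypes (within ``carrier_family`` if given)
    instead of Bernoulli draws — the construction used for variants
    private to one family.
    """

    marker_id: str
    gene: str
    population_maf: float
    functional_class: str = "nonsynonymous"
    chromosome: str = "1"
    effect_beta: float = 0.0
    n_founder_copies: int | None = None
    carrier_family: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.population_maf <= 0.5:
            raise ValueError(
                f"marker {self.marker_id}: population_maf must lie in [0, 0.5]"
            )


@dataclass
class SimConfig:
    """Configuration of one simulation scenario."""

    markers: Sequence[MarkerSpec]
    prevalence_k: float
    n_replicates: int = 1
    seed: int = 0
    n_families: int = 8
    children_per_couple: int | Sequence[int] = 4
    pedigree: Pedigree | None = None  # custom template overrides the above

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence_k < 1.0:
            raise ValueError("prevalence_k must lie strictly in (0, 1)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.pedigree is None:
            if self.n_families < 1:
                raise ValueError("n_families must be >= 1")
            counts = self._children_counts()
            if any(c < 1 for c in counts):
                raise ValueError("children_per_couple must be >= 1")
        if not self.markers:
            raise ValueError("at least one marker is required")

    def _children_counts(self) -> list[int]:
        if isinstance(self.children_per_couple, int):
            return [self.children_per_couple] * self.n_families
        counts = list(self.children_per_couple)
        if len(counts) != self.n_families:
            raise ValueError("children_per_couple list must have n_families entries")
        return counts

    def build_pedigree(self) -> Pedigree:
        if self.pedigree is not None:
            return self.pedigree
        return three_generation_pedigree(self.n_families, self._children_counts())


def three_generation_pedigree(
    n_families: int, children_per_couple: int | Sequence[int]
) -> Pedigree:
    """Regular three-generation families.

    Each family: a founder couple with ``c`` children; every child marries
    a founder spouse and each such couple again has ``c`` children, giving
    ``2 + 2c + c^2`` members per family.
    """
    if isinstance(children_per_couple, int):
        counts = [children_per_couple] * n_families
    else:
        counts = list(children_per_couple)
        if len(counts) != n_families:
            raise ValueError("children_per_couple list must have n_families entries")
    individuals: list[Individual] = []
    for f, c in enumerate(counts, start=1):
        fid = f"F{f:02d}"
        individuals.append(Individual(fid, "GP1", sex=Sex.MALE))
        individuals.append(Individual(fid, "GP2", sex=Sex.FEMALE))
        for j in range(1, c + 1):
            child_sex = Sex.MALE if j % 2 else Sex.FEMALE
            spouse_sex = Sex.FEMALE if j % 2 else Sex.MALE
            individuals.append(Individual(fid, f"C{j}", "GP1", "GP2", child_sex))
            individuals.append(Individual(fid, f"S{j}", sex=spouse_sex))
            father = f"C{j}" if child_sex is Sex.MALE else f"S{j}"
            mother = f"S{j}" if child_sex is Sex.MALE else f"C{j}"
            for g in range(1, c + 1):
                individuals.append(
                    Individual(
                        fid, f"G{j}_{g}", father, mother,
                        Sex.MALE if g % 2 else Sex.FEMALE,
                    )
                )
    return Pedigree(individuals)


def _irregular_three_generation(
    rng: np.random.Generator,
    n_families: int,
    children_range: tuple[int, int],
    grandchildren_range: tuple[int, int],
) -> Pedigree:
    """Three-generation families with variable sibship sizes.

    Unlike the regular template, each child couple's sibship size is drawn
    uniformly from ``grandchildren_range``, so some married-in founders
    have few offspring — the configuration in which founder variants can
    fail to be transmitted.
    """
    individuals: list[Individual] = []
    for f in range(1, n_families + 1):
        fid = f"F{f:02d}"
        c = int(rng.integers(children_range[0], children_range[1] + 1))
        individuals.append(Individual(fid, "GP1", sex=Sex.MALE))
        individuals.append(Individual(fid, "GP2", sex=Sex.FEMALE))
        for j in range(1, c + 1):
            child_sex = Sex.MALE if j % 2 else Sex.FEMALE
            spouse_sex = Sex.FEMALE if j % 2 else Sex.MALE
            individuals.append(Individual(fid, f"C{j}", "GP1", "GP2", child_sex))
            individuals.append(Individual(fid, f"S{j}", sex=spouse_sex))
            father = f"C{j}" if child_sex is Sex.MALE else f"S{j}"
            mother = f"S{j}" if child_sex is Sex.MALE else f"C{j}"
            g_n = int(rng.integers(grandchildren_range[0], grandchildren_range[1] + 1))
            for g in range(1, g_n + 1):
                individuals.append(
                    Individual(
                        fid, f"G{j}_{g}", father, mother,
                        Sex.MALE if g % 2 else Sex.FEMALE,
                    )
                )
    return Pedigree(individuals)


# ---------------------------------------------------------------------------
# gene drop
# ---------------------------------------------------------------------------


def _drop_haplotypes(
    ped: Pedigree,
    markers: Sequence[MarkerSpec],
    rng: np.random.Generator,
) -> np.ndarray:
    """(n, 2, M) boolean haplotypes: founder draws + Mendelian transmission."""
    n = ped.n
    m = len(markers)
    mafs = np.asarray([mk.population_maf for mk in markers])
    founder_rows = np.nonzero(ped.founder_mask())[0]
    haps = np.zeros((n, 2, m), dtype=bool)
    haps[founder_rows] = rng.random((founder_rows.size, 2, m)) < mafs
    for j, mk in enumerate(markers):
        if mk.n_founder_copies is None:
            continue
        if mk.carrier_family is None:
            eligible = founder_rows
        else:
            fam = set(int(r) for r in ped.family_rows(mk.carrier_family))
            eligible = np.asarray([r for r in founder_rows if int(r) in fam])
        slots = eligible.size * 2
        if mk.n_founder_copies > slots:
            raise ValueError(
                f"marker {mk.marker_id}: {mk.n_founder_copies} founder copies "
                f"requested but only {slots} founder haplotypes available"
            )
        haps[founder_rows, :, j] = False
        chosen = rng.choice(slots, size=mk.n_founder_copies, replace=False)
        for c in chosen:
            haps[eligible[c // 2], c % 2, j] = True
    cols = np.arange(m)
    for row in ped.topological_order():
        parents = ped.parent_rows(row)
        if parents is None:
            continue
        fa, mo = parents
        haps[row, 0] = haps[fa, rng.integers(0, 2, size=m), cols]
        haps[row, 1] = haps[mo, rng.integers(0, 2, size=m), cols]
    return haps


def gene_drop(cfg: SimConfig) -> tuple[Pedigree, GenotypeMatrix, pd.DataFrame]:
    """Simulate genotypes through the pedigree by Mendelian transmission.

    Returns the pedigree, the half-count dosage matrix, and the marker
    annotation table.  Bit-identical given the same config and seed.
    """
    ped = cfg.build_pedigree()
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0,)))
    haps = _drop_haplotypes(ped, cfg.markers, rng)
    dosages = haps.sum(axis=1) / 2.0
    geno = GenotypeMatrix(dosages, [mk.marker_id for mk in cfg.markers], ped.sample_ids)
    return ped, geno, annotation_frame(cfg.markers)


def gene_drop_batch(
    ped: Pedigree,
    markers: Sequence[MarkerSpec],
    n_datasets: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Many independent gene drops at once: (n_datasets, n, M) dosages.

    Used by calibration studies that redraw genotypes every replicate.
    """
    n, m = ped.n, len(markers)
    mafs = np.asarray([mk.population_maf for mk in markers])
    founder_rows = np.nonzero(ped.founder_mask())[0]
    haps = np.zeros((n_datasets, n, 2, m), dtype=bool)
    haps[:, founder_rows] = rng.random((n_datasets, founder_rows.size, 2, m)) < mafs
    for row in ped.topological_order():
        parents = ped.parent_rows(row)
        if parents is None:
            continue
        fa, mo = parents
        pick_f = rng.integers(0, 2, size=(n_datasets, m))
        pick_m = rng.integers(0, 2, size=(n_datasets, m))
        haps[:, row, 0] = np.where(pick_f == 0, haps[:, fa, 0], haps[:, fa, 1])
        haps[:, row, 1] = np.where(pick_m == 0, haps[:, mo, 0], haps[:, mo, 1])
    return haps.sum(axis=2) / 2.0


def annotation_frame(markers: Sequence[MarkerSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "marker_id": [mk.marker_id for mk in markers],
            "gene": [mk.gene for mk in markers],
            "chromosome": [mk.chromosome for mk in markers],
            "functional_class": [mk.functional_class for mk in markers],
            "population_maf": [mk.population_maf for mk in markers],
        }
    )


# ---------------------------------------------------------------------------
# liability-model phenotypes
# ---------------------------------------------------------------------------


def case_indicator_from_liability(
    liability: np.ndarray, n_cases: int
) -> np.ndarray:
    """1 for the ``n_cases`` largest liabilities, 0 otherwise."""
    z = np.zeros(liability.size)
    z[np.argpartition(-liability, n_cases - 1)[:n_cases]] = 1.0
    return z


def simulate_phenotypes(
    geno: GenotypeMatrix, cfg: SimConfig
) -> PhenotypeReplicates:
    """Replicate affection statuses from the additive liability model.

    Per replicate ``r``: liability = (2 * dosage) @ beta + standard normal
    noise (redrawn each replicate, seed spawn key ``(1, r)``), and the
    ``round(k * n)`` individuals with the highest liability are cases, so
    every replicate has the exact target case fraction.  Genotypes are
    held fixed across replicates.
    """
    n = geno.n_individuals
    n_cases = int(round(cfg.prevalence_k * n))
    if n_cases < 1:
        raise ValueError(
            f"prevalence {cfg.prevalence_k} with n={n} yields no cases"
        )
    if n_cases >= n:
        raise ValueError("prevalence too high: no controls would remain")
    beta = np.asarray([mk.effect_beta for mk in cfg.markers])
    if len(beta) != geno.n_markers:
        raise ValueError("marker specs do not match the genotype matrix")
    base = np.nan_to_num(geno.dosages * 2.0) @ beta
    values = np.empty((n, cfg.n_replicates))
    for r in range(cfg.n_replicates):
        rng = np.random.default_rng(
            np.random.SeedSequence(cfg.seed, spawn_key=(1, r))
        )
        liability = base + rng.standard_normal(n)
        values[:, r] = case_indicator_from_liability(liability, n_cases)
    return PhenotypeReplicates(
        sample_ids=list(geno.sample_ids),
        values=values,
        replicate_names=[f"rep{r + 1}" for r in range(cfg.n_replicates)],
        prevalence=cfg.prevalence_k,
    )


# ---------------------------------------------------------------------------
# canned scenario
# ---------------------------------------------------------------------------


@dataclass
class SimBundle:
    """Everything one scenario produces, ready for the analysis pipeline."""

    config: SimConfig
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    annotation: pd.DataFrame
    phenotypes: PhenotypeReplicates

    @property
    def kinship(self):
        if not hasattr(self, "_kinship"):
            self._kinship = compute_kinship(self.pedigree)
        return self._kinship


def gaw17_like_scenario(seed: int = 0, n_replicates: int = 200) -> SimBundle:
    """An 8-family rare-variant scenario with the study-design features
    the association pipeline is meant to exercise.

    * 8 three-generation families with variable sibship sizes (roughly
      20-60 members each), prevalence k = 0.3, 200 phenotype replicates;
    * one gene (``GENE01``) with three causal rare variants private to
      three different families (the many-mutations-one-gene configuration
      that motivates collapsing), each placed as two founder copies,
      per-allele liability effect beta = 0.8;
    * one gene (``GENE02``) with a single strong causal variant
      (beta = 1.5, three founder copies private to a fourth family, so no
      cross-gene confounding with GENE01) plus twenty neutral rare
      members that dilute its collapsed indicator;
    * one private causal background variant (beta = 1.0) in each family
      not already hosting one, so every family has exactly one private
      causal source — the genetic heterogeneity that makes case status
      cluster within every family;
    * 38 neutral genes of 1-3 rare SNPs with population MAF log-uniform
      in [0.001, 0.008], mixed synonymous/nonsynonymous.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(9,)))
    ped = _irregular_three_generation(
        rng, n_families=8, children_range=(4, 10), grandchildren_range=(1, 5)
    )
    markers: list[MarkerSpec] = []
    for i, fam in enumerate(("F01", "F02", "F03"), start=1):
        markers.append(
            MarkerSpec(
                marker_id=f"PRIV{i}", gene="GENE01", population_maf=0.001,
                functional_class="nonsynonymous", chromosome="6",
                effect_beta=0.8, n_founder_copies=2, carrier_family=fam,
            )
        )
    markers.append(
        MarkerSpec(
            marker_id="DILC", gene="GENE02", population_maf=0.002,
            functional_class="nonsynonymous", chromosome="10",
            effect_beta=1.5, n_founder_copies=3, carrier_family="F05",
        )
    )
    for i in range(1, 21):
        markers.append(
            MarkerSpec(
                marker_id=f"DILN{i:02d}", gene="GENE02", population_maf=0.004,
                functional_class="synonymous" if i % 2 else "nonsynonymous",
                chromosome="10",
            )
        )
    # disease heterogeneity: every family hosts exactly one private causal
    # source, so case status clusters within each family.  F01-F03 already
    # carry GENE01's variants and F05 carries GENE02's causal variant; the
    # remaining families get a private causal variant in a background gene.
    for f in (4, 6, 7, 8):
        markers.append(
            MarkerSpec(
                marker_id=f"BGC{f}", gene=f"GENE{f + 2:02d}", population_maf=0.001,
                functional_class="nonsynonymous", chromosome=str(10 + f),
                effect_beta=1.0, n_founder_copies=2, carrier_family=f"F{f:02d}",
            )
        )
    snp = 0
    for gidx in range(3, 41):
        gene = f"GENE{gidx:02d}"
        chrom = str(int(rng.integers(1, 23)))
        for _ in range(int(rng.integers(1, 4))):
            snp += 1
            maf = float(10 ** rng.uniform(np.log10(0.001), np.log10(0.008)))
            markers.append(
                MarkerSpec(
                    marker_id=f"SNP{snp:03d}", gene=gene, population_maf=maf,
                    functional_class=(
                        "nonsynonymous" if rng.random() < 0.5 else "synonymous"
                    ),
                    chromosome=chrom,
                )
            )
    cfg = SimConfig(
        markers=markers,
        prevalence_k=0.3,
        n_replicates=n_replicates,
        seed=seed,
        pedigree=ped,
    )
    ped, geno, ann = gene_drop(cfg)
    pheno = simulate_phenotypes(geno, cfg)
    return SimBundle(
        config=cfg, pedigree=ped, genotypes=geno, annotation=ann, phenotypes=pheno
    )


# ---------------------------------------------------------------------------
# writers: exactly the formats the readers consume
# ---------------------------------------------------------------------------


def write_bundle(bundle: SimBundle, outdir: str | Path) -> dict[str, Path]:
    """Write a bundle as .fam + dosage TSV + annotation TSV + phenotype TSV
    plus a flat key-value config file; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "pedigree": outdir / "pedigree.fam",
        "genotypes": outdir / "genotypes.tsv",
        "annotation": outdir / "annotation.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
        "config": outdir / "config.txt",
    }
    write_fam(bundle.pedigree, paths["pedigree"])
    write_dosage_tsv(bundle.genotypes, paths["genotypes"])
    write_annotation(bundle.annotation, paths["annotation"])
    write_phenotypes(bundle.phenotypes, paths["phenotypes"])
    cfg = bundle.config
    with paths["config"].open("w") as fh:
        fh.write(f"seed={cfg.seed}\n")
        fh.write(f"prevalence_k={cfg.prevalence_k}\n")
        fh.write(f"n_replicates={cfg.n_replicates}\n")
        fh.write(f"n_families={len(bundle.pedigree.family_ids)}\n")
        fh.write(f"n_individuals={bundle.pedigree.n}\n")
        fh.write(f"n_markers={bundle.genotypes.n_markers}\n")
    return paths
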