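"""Power estimation over phenotype replicates and descriptive family summaries.

Power is the proportion of phenotype replicates in which a unit's test
p-value falls strictly below the significance threshold.  Replicates in
which the unit is untestable count as non-hits (and are reported
alongside, so deflated estimates can be audited).  The module also holds
the descriptive summaries particular to family data: how many families
carry each rare variant, which founder variants were never transmitted,
and the head-to-head comparison of collapsed versus single-marker power
per gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from . import qls
from .collapsing import CollapsedGenotype
from .pedigree import KinshipMatrix, Pedigree, compute_kinship
from .qls import AssocResult
from .simulate import MarkerSpec, gene_drop_batch, three_generation_pedigree
from .variant_data import GenotypeMatrix, PhenotypeReplicates

logger = logging.getLogger(__name__)


@dataclass
class PowerEstimate:
    """Proportion of replicates reaching the significance threshold."""

    unit_id: str
    test: str
    threshold: float
    n_replicates: int
    n_hits: int
    n_untestable: int

    @property
    def power(self) -> float:
        return self.n_hits / self.n_replicates


@dataclass
class FamilyDistribution:
    """How many (and which) families carry a given variant."""

    marker_id: str
    carrier_family_ids: frozenset[str]

    @property
    def n_carrier_families(self) -> int:
        return len(self.carrier_family_ids)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    return alpha / n_tests


def estimate_power(
    results_per_replicate: Sequence[Sequence[AssocResult]],
    threshold: float,
) -> list[PowerEstimate]:
    """Per-unit power over replicates; hits are strict ``p < threshold``.

    Every replicate must have tested the same units in the same order.
    Untestable replicates count as non-hits and are tallied separately.
    """
    if not results_per_replicate:
        raise ValueError("no replicates supplied")
    unit_ids = [r.marker_id for r in results_per_replicate[0]]
    tests = [r.test for r in results_per_replicate[0]]
    n_rep = len(results_per_replicate)
    hits = np.zeros(len(unit_ids), dtype=int)
    untestable = np.zeros(len(unit_ids), dtype=int)
    for rep in results_per_replicate:
        if [r.marker_id for r in rep] != unit_ids:
            raise ValueError("replicates tested different unit sets (or orders)")
        for j, r in enumerate(rep):
            if not r.testable:
                untestable[j] += 1
            elif r.p_value < threshold:
                hits[j] += 1
    return [
        PowerEstimate(
            unit_id=unit_ids[j],
            test=tests[j],
            threshold=threshold,
            n_replicates=n_rep,
            n_hits=int(hits[j]),
            n_untestable=int(untestable[j]),
        )
        for j in range(len(unit_ids))
    ]


def run_association_study(
    g: GenotypeMatrix | Sequence[CollapsedGenotype],
    pheno: PhenotypeReplicates,
    phi: KinshipMatrix,
    test: str = qls.MQLS,
    prevalence: float | None = None,
    replicates: Iterable[int] | None = None,
) -> list[list[AssocResult]]:
    """Run one test over every marker for each replicate."""
    if replicates is None:
        replicates = range(pheno.n_replicates)
    return [
        qls.test_markers(g, pheno, r, phi, test=test, prevalence=prevalence)
        for r in replicates
    ]


def run_power_study(
    g: GenotypeMatrix | Sequence[CollapsedGenotype],
    pheno: PhenotypeReplicates,
    phi: KinshipMatrix,
    threshold: float,
    test: str = qls.MQLS,
    prevalence: float | None = None,
    replicates: Iterable[int] | None = None,
) -> list[PowerEstimate]:
    """Convenience wrapper: association study over replicates, then power."""
    results = run_association_study(g, pheno, phi, test, prevalence, replicates)
    return estimate_power(results, threshold)


def power_table(estimates: Sequence[PowerEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "unit_id": [e.unit_id for e in estimates],
            "test": [e.test for e in estimates],
            "threshold": [e.threshold for e in estimates],
            "n_replicates": [e.n_replicates for e in estimates],
            "n_hits": [e.n_hits for e in estimates],
            "n_untestable": [e.n_untestable for e in estimates],
            "power": [e.power for e in estimates],
        }
    )


def compare_collapsed_vs_single(
    collapsed_powers: Sequence[PowerEstimate],
    single_powers: Sequence[PowerEstimate],
    ann: pd.DataFrame,
) -> pd.DataFrame:
    """Per gene: collapsed power minus the best member-SNP power.

    Both tables must come from identical replicates and threshold.  A
    positive delta means collapsing the gene's rare variants beat every
    one of its single-variant tests.
    """
    single = {e.unit_id: e for e in single_powers}
    members = ann.groupby("gene")["marker_id"].apply(list)
    rows = []
    for est in collapsed_powers:
        gene = est.unit_id
        if gene not in members.index:
            raise ValueError(f"gene {gene!r} absent from the annotation table")
        member_ests = [single[m] for m in members[gene] if m in single]
        if not member_ests:
            raise ValueError(
                f"gene {gene!r} has no member markers in the single-marker table"
            )
        if any(e.threshold != est.threshold for e in member_ests):
            raise ValueError("collapsed and single tables used different thresholds")
        best = max(e.power for e in member_ests)
        rows.append(
            {
                "gene": gene,
                "collapsed_power": est.power,
                "best_single_marker_power": best,
                "delta": est.power - best,
            }
        )
    return pd.DataFrame(rows, columns=[
        "gene", "collapsed_power", "best_single_marker_power", "delta"
    ])


# ---------------------------------------------------------------------------
# descriptive family summaries
# ---------------------------------------------------------------------------

HISTOGRAM_BINS = ("0", "1", "2", "3+")


def family_distribution(
    g: GenotypeMatrix,
    ped: Pedigree,
    markers: Iterable[str] | None = None,
) -> tuple[list[FamilyDistribution], dict[str, int]]:
    """Which families carry each marker, plus the 0 / 1 / 2 / 3+ histogram.

    A family carries a marker iff any member has dosage > 0.  The 0 bin is
    the variants absent from the family data entirely.
    """
    marker_ids = list(markers) if markers is not None else list(g.marker_ids)
    out = []
    hist = {b: 0 for b in HISTOGRAM_BINS}
    for marker in marker_ids:
        y = g.column(marker)
        carriers = frozenset(
            fid
            for fid in ped.family_ids
            if bool(np.any(y[ped.family_rows(fid)] > 0))
        )
        out.append(FamilyDistribution(marker_id=marker, carrier_family_ids=carriers))
        n = len(carriers)
        hist["3+" if n >= 3 else str(n)] += 1
    return out, hist


def render_histogram(hist: Mapping[str, int], width: int = 40) -> str:
    """Plain-text bar rendering of the carrier-family histogram."""
    peak = max(hist.values()) or 1
    lines = []
    for label in HISTOGRAM_BINS:
        count = hist.get(label, 0)
        bar = "#" * int(round(width * count / peak))
        lines.append(f"{label:>2} families | {bar} {count}")
    return "\n".join(lines)


def founder_transmission(
    g: GenotypeMatrix,
    ped: Pedigree,
    markers: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per marker: does it exist in founders, and was it passed to offspring?

    ``transmitted`` is true iff at least one non-founder carries the rare
    allele while at least one founder does.  A variant carried only by
    non-founders is impossible under gene-drop simulation and flagged
    ``inconsistent`` (possible in real data: a Mendelian error or de novo
    variant), with a logged warning.
    """
    marker_ids = list(markers) if markers is not None else list(g.marker_ids)
    fmask = ped.founder_mask()
    rows = []
    for marker in marker_ids:
        y = g.column(marker)
        in_founders = bool(np.any(y[fmask] > 0))
        in_offspring = bool(np.any(y[~fmask] > 0))
        inconsistent = in_offspring and not in_founders
        if inconsistent:
            logger.warning(
                "marker %s carried by non-founders only (Mendelian inconsistency?)",
                marker,
            )
        rows.append(
            {
                "marker_id": marker,
                "present_in_founders": in_founders,
                "transmitted": in_founders and in_offspring,
                "inconsistent": inconsistent,
            }
        )
    return pd.DataFrame(rows, columns=[
        "marker_id", "present_in_founders", "transmitted", "inconsistent"
    ])


def single_family_vs_combined(
    g: GenotypeMatrix,
    pheno: PhenotypeReplicates,
    ped: Pedigree,
    phi: KinshipMatrix,
    marker_id: str,
    family_id: str,
    test: str = qls.MQLS,
    prevalence: float | None = None,
    replicates: Iterable[int] | None = None,
) -> pd.DataFrame:
    """Per replicate, the carrier family's own p-value versus the all-family one.

    Quantifies how much combining families that lack a private risk
    variant dilutes its signal.
    """
    if replicates is None:
        replicates = range(pheno.n_replicates)
    sub = g.subset_markers([marker_id])
    rows_f = ped.family_rows(family_id)
    mask = np.zeros(g.n_individuals, dtype=bool)
    mask[rows_f] = True
    fam_kin = phi.submatrix(mask)
    fam_pheno = PhenotypeReplicates(
        sample_ids=[g.sample_ids[int(r)] for r in rows_f],
        values=pheno.values[rows_f],
        replicate_names=list(pheno.replicate_names),
        prevalence=pheno.prevalence,
    )
    fam_geno = sub.subset_individuals(rows_f)
    records = []
    for r in replicates:
        combined = qls.test_markers(
            sub, pheno, r, phi, test=test, prevalence=prevalence
        )[0]
        single = qls.test_markers(
            fam_geno, fam_pheno, r, fam_kin, test=test, prevalence=prevalence,
            scope=f"family:{family_id}",
        )[0]
        records.append(
            {
                "replicate": r,
                "combined_p": combined.p_value,
                "single_family_p": single.p_value,
                "combined_testable": combined.testable,
                "single_family_testable": single.testable,
            }
        )
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# null calibration study
# ---------------------------------------------------------------------------


@dataclass
class CalibrationResult:
    """Empirical size and null-distribution checks for both tests."""

    n_replicates: int
    alpha: float
    size_mqls_snp: float
    size_wqls_snp: float
    size_mqls_gene: float
    size_wqls_gene: float
    n_testable_snp: int
    n_testable_gene: int
    ks_pvalue_mqls_gene: float
    ks_pvalue_wqls_gene: float
    ks_pvalue_mqls_snp: float
    ks_pvalue_wqls_snp: float


def null_calibration_study(
    seed: int,
    n_replicates: int = 5000,
    alpha: float = 0.05,
    n_families: int = 8,
    children_per_couple: int = 8,
    prevalence: float = 0.3,
    n_snps: int = 12,
    snp_maf: float = 0.0095,
    gene_n_snps: int = 15,
    gene_snp_maf: float = 0.004,
    chunk: int = 250,
) -> CalibrationResult:
    """Type-I error of MQLS/WQLS under the null, on rare SNPs and a collapsed gene.

    Every replicate draws *fresh* gene-drop genotypes and a fresh
    zero-effect phenotype (a uniformly random case set of the exact target
    size), so the pooled null statistics form a smooth mixture over
    genotype configurations — with genotypes held fixed the statistic is
    purely discrete and a distributional check is uninformative.  Single-SNP
    size is pooled over ``n_snps`` markers among testable
    (marker, replicate) pairs; monomorphic draws are untestable and never
    enter the numerator or denominator.
    """
    ped = three_generation_pedigree(n_families, children_per_couple)
    kin = compute_kinship(ped)
    n = ped.n
    n_cases = int(round(prevalence * n))
    markers = [
        MarkerSpec(marker_id=f"NULL{i:02d}", gene="NULLSNPS", population_maf=snp_maf)
        for i in range(1, n_snps + 1)
    ] + [
        MarkerSpec(marker_id=f"GM{i:02d}", gene="NULLGENE", population_maf=gene_snp_maf)
        for i in range(1, gene_n_snps + 1)
    ]
    gene_cols = np.arange(n_snps, n_snps + gene_n_snps)
    snp_cols = np.arange(n_snps)

    w, s_ones = kin.solve_ones()
    factors = {fid: linalg.cho_factor(kin.block(fid), lower=True)
               for fid in kin.family_ids}
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(5,)))

    crit = stats.chi2.isf(alpha, df=1)
    stats_snp_m, stats_snp_w = [], []
    stats_gene_m, stats_gene_w = [], []

    done = 0
    while done < n_replicates:
        r = min(chunk, n_replicates - done)
        done += r
        dos = gene_drop_batch(ped, markers, r, rng)  # (r, n, M)
        eps = rng.standard_normal((r, n))
        # exact-count null phenotypes: top n_cases liabilities are cases
        order = np.argpartition(-eps, n_cases - 1, axis=1)[:, :n_cases]
        z = np.zeros((r, n))
        np.put_along_axis(z, order, 1.0, axis=1)

        y_snp = dos[:, :, snp_cols]                      # (r, n, S)
        y_gene = 0.5 * (dos[:, :, gene_cols] > 0).any(axis=2)  # (r, n)
        y_all = np.concatenate([y_snp, y_gene[:, :, None]], axis=2)

        p = np.einsum("n,rnm->rm", w, y_all) / s_ones
        np.clip(p, 0.0, 1.0, out=p)
        s2 = p * (1.0 - p)

        v = z - prevalence
        vsum = v.sum(axis=1)
        phiv = np.empty_like(v)
        b = np.empty_like(v)
        for fid in kin.family_ids:
            rows = kin.family_rows(fid)
            phiv[:, rows] = v[:, rows] @ kin.block(fid)
            b[:, rows] = linalg.cho_solve(factors[fid], z[:, rows].T).T
        a_m = np.einsum("rn,rn->r", v, phiv) - vsum**2 / s_ones
        bsum = b.sum(axis=1)
        a_w = np.einsum("rn,rn->r", z, b) - bsum**2 / s_ones

        u_m = np.einsum("rn,rnm->rm", v, y_all) - vsum[:, None] * p
        u_w = np.einsum("rn,rnm->rm", b, y_all) - bsum[:, None] * p
        var_m = s2 * a_m[:, None]
        var_w = s2 * a_w[:, None]

        ymax = y_all.max(axis=1)
        ymin = y_all.min(axis=1)
        testable = (ymax > ymin) & (var_m > qls.VARIANCE_RTOL * np.maximum(s2, 1e-300))
        with np.errstate(divide="ignore", invalid="ignore"):
            st_m = np.where(testable, u_m**2 / var_m, np.nan)
            st_w = np.where(testable, u_w**2 / var_w, np.nan)

        snp_mask = testable[:, :-1]
        stats_snp_m.append(st_m[:, :-1][snp_mask])
        stats_snp_w.append(st_w[:, :-1][snp_mask])
        gene_mask = testable[:, -1]
        stats_gene_m.append(st_m[:, -1][gene_mask])
        stats_gene_w.append(st_w[:, -1][gene_mask])

    sm = np.concatenate(stats_snp_m)
    sw = np.concatenate(stats_snp_w)
    gm = np.concatenate(stats_gene_m)
    gw = np.concatenate(stats_gene_w)
    chi2_cdf = stats.chi2(df=1).cdf
    return CalibrationResult(
        n_replicates=n_replicates,
        alpha=alpha,
        size_mqls_snp=float((sm > crit).mean()),
        size_wqls_snp=float((sw > crit).mean()),
        size_mqls_gene=float((gm > crit).mean()),
        size_wqls_gene=float((gw > crit).mean()),
        n_testable_snp=int(sm.size),
        n_testable_gene=int(gm.size),
        ks_pvalue_mqls_gene=float(stats.kstest(gm, chi2_cdf).pvalue),
        ks_pvalue_wqls_gene=float(stats.kstest(gw, chi2_cdf).pvalue),
        ks_pvalue_mqls_snp=float(stats.kstest(sm, chi2_cdf).pvalue),
        ks_pvalue_wqls_snp=float(stats.kstest(sw, chi2_cdf).pvalue),
    )
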