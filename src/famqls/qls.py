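"""Quasi-likelihood score tests for case-control association in pedigrees.

Both tests are score tests that use only the mean and the kinship-implied
covariance of genotypes — no full likelihood.  Writing ``Y`` for the
half-count dosage vector, ``Z`` for the case indicator, ``k`` for the
population prevalence and ``Phi`` for the kinship matrix, the null
covariance of ``Y`` is ``p(1-p) Phi`` and the efficient null estimate of
the allele frequency is the quasi-likelihood weighted mean

    p_hat = (1' Phi^-1 Y) / (1' Phi^-1 1).

MQLS weights individuals by their phenotype contrast against prevalence,
``V = Z - k 1``:

    U   = V' (Y - p_hat 1)
    Var = p_hat (1 - p_hat) [ V' Phi V - (V'1)^2 / (1' Phi^-1 1) ]

WQLS is the score test of the mean model ``E[Y] = p 1 + r Z`` at r = 0:

    U   = Z' Phi^-1 (Y - p_hat 1)
    Var = p_hat (1 - p_hat) [ Z' Phi^-1 Z - (Z' Phi^-1 1)^2 / (1' Phi^-1 1) ]

Either statistic is ``U^2 / Var`` referred to the upper tail of a
chi-square with one degree of freedom.  For unrelated individuals
(``Phi = I/2``) and ``k`` equal to the observed case fraction both reduce
to the classical allelic chi-square test.

All solves go through per-family Cholesky factorizations; the kinship
matrix is never explicitly inverted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .collapsing import CollapsedGenotype, collapsed_matrix
from .pedigree import KinshipMatrix, Pedigree
from .variant_data import GenotypeMatrix, PhenotypeReplicates

logger = logging.getLogger(__name__)

MQLS = "mqls"
WQLS = "wqls"

STATUS_OK = "ok"
STATUS_MONOMORPHIC = "monomorphic"
STATUS_SINGLE_CLASS = "single_class"
STATUS_DEGENERATE = "degenerate_variance"

#: Var(U) below VARIANCE_RTOL * p_hat(1-p_hat) is treated as zero.
VARIANCE_RTOL = 1e-12

#: Below this many analyzed individuals the chi-square approximation is
#: shaky; results are still reported but an advisory is logged.
SMALL_SAMPLE_ADVISORY = 30


@dataclass
class AssocResult:
    """One marker's (or collapsed gene's) score-test result."""

    marker_id: str
    test: str
    scope: str
    n_used: int
    ql_freq: float
    score_u: float
    var_u: float
    statistic: float
    p_value: float
    status: str = STATUS_OK

    @property
    def testable(self) -> bool:
        return self.status == STATUS_OK


def _as_kinship(phi: KinshipMatrix | np.ndarray) -> KinshipMatrix:
    if isinstance(phi, KinshipMatrix):
        return phi
    return KinshipMatrix.from_dense(np.asarray(phi, dtype=float))


def _check_complete(name: str, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.isnan(x).any():
        raise ValueError(
            f"{name} contains missing values; drop incomplete individuals first"
        )
    return x


def ql_allele_freq(y: np.ndarray, phi: KinshipMatrix | np.ndarray) -> float:
    """Quasi-likelihood allele-frequency estimate p_hat = (1'Phi^-1 Y)/(1'Phi^-1 1).

    The kinship-weighted mean downweights clusters of relatives, giving
    the efficient estimator of the allele frequency under the null.  For
    unrelated individuals it reduces to the sample mean dosage.  The
    result is clipped to [0, 1] against floating-point drift.
    """
    y = _check_complete("dosages", y)
    kin = _as_kinship(phi)
    w, s = kin.solve_ones()
    return float(np.clip(w @ y / s, 0.0, 1.0))


def _finish(
    marker_id: str,
    test: str,
    scope: str,
    n: int,
    p: float,
    u: float,
    quad: float,
    y_constant: bool,
    z_constant: bool,
) -> AssocResult:
    s2 = p * (1.0 - p)
    var_u = s2 * quad
    if y_constant or s2 == 0.0:
        status = STATUS_MONOMORPHIC
    elif z_constant:
        status = STATUS_SINGLE_CLASS
    elif var_u <= VARIANCE_RTOL * s2:
        status = STATUS_DEGENERATE
    else:
        status = STATUS_OK
    if status != STATUS_OK:
        return AssocResult(
            marker_id, test, scope, n, p, u, var_u, np.nan, np.nan, status
        )
    statistic = u * u / var_u
    return AssocResult(
        marker_id,
        test,
        scope,
        n,
        p,
        u,
        var_u,
        statistic,
        float(stats.chi2.sf(statistic, df=1)),
        STATUS_OK,
    )


def mqls_statistic(
    y: np.ndarray,
    z: np.ndarray,
    prevalence: float,
    phi: KinshipMatrix | np.ndarray,
    marker_id: str = "marker",
    scope: str = "all_families",
) -> AssocResult:
    """MQLS score test of one marker against case-control status.

    ``prevalence`` is the population disease prevalence k in (0, 1); the
    phenotype contrast V = Z - k1 gives controls negative weight and, with
    k below one half, cases the larger absolute weight.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie strictly between 0 and 1")
    y = _check_complete("dosages", y)
    z = _check_complete("phenotypes", z)
    if y.shape != z.shape:
        raise ValueError("dosage and phenotype vectors differ in length")
    kin = _as_kinship(phi)
    if kin.n != y.size:
        raise ValueError("kinship matrix does not match the number of individuals")
    if y.size < SMALL_SAMPLE_ADVISORY:
        logger.info(
            "MQLS on %d individuals: chi-square approximation may be poor", y.size
        )
    w, s = kin.solve_ones()
    p = float(np.clip(w @ y / s, 0.0, 1.0))
    v = z - prevalence
    u = float(v @ y - p * v.sum())
    quad = float(v @ kin.matvec(v) - v.sum() ** 2 / s)
    return _finish(
        marker_id, MQLS, scope, y.size, p, u, quad,
        y_constant=bool(np.ptp(y) == 0), z_constant=bool(np.ptp(z) == 0),
    )


def wqls_statistic(
    y: np.ndarray,
    z: np.ndarray,
    phi: KinshipMatrix | np.ndarray,
    marker_id: str = "marker",
    scope: str = "all_families",
) -> AssocResult:
    """WQLS score test (no prevalence needed; weights from Phi^-1 Z)."""
    y = _check_complete("dosages", y)
    z = _check_complete("phenotypes", z)
    if y.shape != z.shape:
        raise ValueError("dosage and phenotype vectors differ in length")
    kin = _as_kinship(phi)
    if kin.n != y.size:
        raise ValueError("kinship matrix does not match the number of individuals")
    if y.size < SMALL_SAMPLE_ADVISORY:
        logger.info(
            "WQLS on %d individuals: chi-square approximation may be poor", y.size
        )
    w, s = kin.solve_ones()
    p = float(np.clip(w @ y / s, 0.0, 1.0))
    b = kin.solve(z)
    bsum = float(b.sum())
    u = float(b @ y - p * bsum)
    quad = float(z @ b - bsum**2 / s)
    return _finish(
        marker_id, WQLS, scope, y.size, p, u, quad,
        y_constant=bool(np.ptp(y) == 0), z_constant=bool(np.ptp(z) == 0),
    )


# ---------------------------------------------------------------------------
# batch paths (complete data, many markers / many replicates)
# ---------------------------------------------------------------------------


def _batch_freq(Y: np.ndarray, kin: KinshipMatrix) -> np.ndarray:
    w, s = kin.solve_ones()
    return np.clip(w @ Y / s, 0.0, 1.0)


def _mqls_batch(
    Y: np.ndarray, z: np.ndarray, prevalence: float, kin: KinshipMatrix
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized MQLS over the columns of complete dosage matrix Y."""
    w, s = kin.solve_ones()
    p = np.clip(w @ Y / s, 0.0, 1.0)
    v = z - prevalence
    u = v @ Y - p * v.sum()
    quad = float(v @ kin.matvec(v) - v.sum() ** 2 / s)
    var = p * (1.0 - p) * quad
    return p, u, var


def _wqls_batch(
    Y: np.ndarray, z: np.ndarray, kin: KinshipMatrix
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    w, s = kin.solve_ones()
    p = np.clip(w @ Y / s, 0.0, 1.0)
    b = kin.solve(z)
    bsum = float(b.sum())
    u = b @ Y - p * bsum
    quad = float(z @ b - bsum**2 / s)
    var = p * (1.0 - p) * quad
    return p, u, var


def _batch_results(
    marker_ids: Sequence[str],
    Y: np.ndarray,
    z: np.ndarray,
    test: str,
    prevalence: float | None,
    kin: KinshipMatrix,
    scope: str,
) -> list[AssocResult]:
    n = Y.shape[0]
    if test == MQLS:
        assert prevalence is not None
        p, u, var = _mqls_batch(Y, z, prevalence, kin)
    else:
        p, u, var = _wqls_batch(Y, z, kin)
    y_constant = np.ptp(Y, axis=0) == 0
    z_constant = bool(np.ptp(z) == 0)
    s2 = p * (1.0 - p)
    results = []
    for j, marker in enumerate(marker_ids):
        if y_constant[j] or s2[j] == 0.0:
            status = STATUS_MONOMORPHIC
        elif z_constant:
            status = STATUS_SINGLE_CLASS
        elif var[j] <= VARIANCE_RTOL * s2[j]:
            status = STATUS_DEGENERATE
        else:
            status = STATUS_OK
        if status != STATUS_OK:
            results.append(
                AssocResult(
                    marker, test, scope, n, float(p[j]), float(u[j]),
                    float(var[j]), np.nan, np.nan, status,
                )
            )
        else:
            statistic = float(u[j] ** 2 / var[j])
            results.append(
                AssocResult(
                    marker, test, scope, n, float(p[j]), float(u[j]),
                    float(var[j]), statistic,
                    float(stats.chi2.sf(statistic, df=1)), STATUS_OK,
                )
            )
    return results


def _resolve_genotypes(
    g: GenotypeMatrix | Sequence[CollapsedGenotype],
) -> GenotypeMatrix:
    if isinstance(g, GenotypeMatrix):
        return g
    collapsed = list(g)
    return collapsed_matrix(collapsed, sample_ids=_collapsed_ids(collapsed))


def _collapsed_ids(collapsed: Sequence[CollapsedGenotype]) -> list[tuple[str, str]]:
    n = collapsed[0].indicator.size
    return [("NA", str(i)) for i in range(n)]


def test_markers(
    g: GenotypeMatrix | Sequence[CollapsedGenotype],
    pheno: PhenotypeReplicates,
    replicate: int,
    phi: KinshipMatrix | np.ndarray,
    test: str = MQLS,
    prevalence: float | None = None,
    scope: str = "all_families",
) -> list[AssocResult]:
    """Run one test over every marker (or collapsed gene) for one replicate.

    Untestable markers (monomorphic in the analyzed subset, degenerate
    variance, single phenotype class) are flagged, never silently dropped;
    results come back in input marker order.  Individuals with a missing
    phenotype in this replicate — or a missing genotype at a given marker —
    are dropped listwise for the affected test, with a logged warning, and
    their kinship rows dropped with them.
    """
    if test not in (MQLS, WQLS):
        raise ValueError(f"test must be '{MQLS}' or '{WQLS}', got {test!r}")
    if test == MQLS and prevalence is None:
        raise ValueError("MQLS requires a prevalence")
    geno = _resolve_genotypes(g)
    if not 0 <= replicate < pheno.n_replicates:
        raise IndexError(
            f"replicate {replicate} out of range (0..{pheno.n_replicates - 1})"
        )
    z = pheno.replicate(replicate)
    kin = _as_kinship(phi)
    if kin.n != geno.n_individuals or len(z) != geno.n_individuals:
        raise ValueError("genotypes, phenotypes, and kinship must align")

    keep = ~np.isnan(z)
    if not keep.all():
        logger.warning(
            "replicate %d: dropping %d individuals with missing phenotype",
            replicate, int((~keep).sum()),
        )
        kin = kin.submatrix(keep)
        z = z[keep]
    Y = geno.dosages[keep]

    complete = ~np.isnan(Y).any(axis=0)
    results: dict[int, AssocResult] = {}
    if complete.any():
        ids = [geno.marker_ids[j] for j in np.nonzero(complete)[0]]
        batch = _batch_results(
            ids, Y[:, complete], z, test, prevalence, kin, scope
        )
        for j, res in zip(np.nonzero(complete)[0], batch):
            results[int(j)] = res
    for j in np.nonzero(~complete)[0]:
        yj = Y[:, j]
        sub = ~np.isnan(yj)
        logger.warning(
            "marker %s: dropping %d individuals with missing genotype",
            geno.marker_ids[j], int((~sub).sum()),
        )
        sub_kin = kin.submatrix(sub)
        if test == MQLS:
            res = mqls_statistic(
                yj[sub], z[sub], prevalence, sub_kin, geno.marker_ids[j], scope
            )
        else:
            res = wqls_statistic(yj[sub], z[sub], sub_kin, geno.marker_ids[j], scope)
        results[int(j)] = res
    return [results[j] for j in range(geno.n_markers)]


def per_family_tests(
    g: GenotypeMatrix | Sequence[CollapsedGenotype],
    pheno: PhenotypeReplicates,
    replicate: int,
    ped: Pedigree,
    phi: KinshipMatrix | np.ndarray,
    test: str = MQLS,
    prevalence: float | None = None,
) -> dict[str, list[AssocResult]]:
    """Run the chosen test separately within each family.

    Each family's test uses only its members and its kinship block; the
    quasi-likelihood allele frequency is re-estimated within the family.
    Families where a marker is monomorphic, or with a single phenotype
    class, yield flagged untestable results for the affected markers.
    """
    geno = _resolve_genotypes(g)
    kin = _as_kinship(phi)
    out: dict[str, list[AssocResult]] = {}
    for fid in ped.family_ids:
        rows = ped.family_rows(fid)
        mask = np.zeros(geno.n_individuals, dtype=bool)
        mask[rows] = True
        fam_pheno = PhenotypeReplicates(
            sample_ids=[geno.sample_ids[int(r)] for r in rows],
            values=pheno.values[rows],
            replicate_names=list(pheno.replicate_names),
            prevalence=pheno.prevalence,
        )
        out[fid] = test_markers(
            geno.subset_individuals(rows),
            fam_pheno,
            replicate,
            kin.submatrix(mask),
            test=test,
            prevalence=prevalence,
            scope=f"family:{fid}",
        )
    return out


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

RESULT_COLUMNS = (
    "marker_id", "scope", "test", "n_used", "ql_freq",
    "score_u", "var_u", "statistic", "p_value", "status",
)


def results_to_frame(results: Iterable[AssocResult]) -> pd.DataFrame:
    rows = [
        {
            "marker_id": r.marker_id,
            "scope": r.scope,
            "test": r.test,
            "n_used": r.n_used,
            "ql_freq": r.ql_freq,
            "score_u": r.score_u,
            "var_u": r.var_u,
            "statistic": r.statistic,
            "p_value": r.p_value,
            "status": r.status,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def write_results(results: Iterable[AssocResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False, float_format="%.10g")
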