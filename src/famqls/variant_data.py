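"""Genotypes, variant annotations, and replicate phenotypes.

Genotypes are held as per-individual minor-allele *half-counts*
``Y in {0, 0.5, 1}`` per marker (the scale on which the score tests are
written: a heterozygote contributes 0.5, a rare homozygote 1).  Missing
genotypes are NaN.  Annotations map each marker to a gene, chromosome,
functional class (synonymous / nonsynonymous / unknown), and a population
minor-allele frequency; the rare-variant filter is the strict inequality
``MAF < threshold`` with threshold 0.01 by default.

Phenotype replicates are a wide table: one affection-status column
(1 = case, 0 = control) per replicate, all sharing one pedigree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .pedigree import Pedigree

logger = logging.getLogger(__name__)

FUNCTIONAL_CLASSES = ("synonymous", "nonsynonymous", "unknown")

#: Columns of an annotation table.
ANNOTATION_COLUMNS = (
    "marker_id",
    "gene",
    "chromosome",
    "functional_class",
    "population_maf",
)


class GenotypeFormatError(ValueError):
    """Malformed genotype input (bad dosage values, >2 alleles, ...)."""


class AlignmentError(ValueError):
    """Genotype/phenotype rows do not align with the pedigree."""


_VALID_DOSAGES = np.array([0.0, 0.5, 1.0])


class GenotypeMatrix:
    """Individuals x markers matrix of minor-allele half-counts.

    Entries are 0, 0.5, 1 or NaN (missing).  Row order is the pedigree
    (file) order; ``sample_ids`` are (family_id, person_id) pairs.
    """

    def __init__(
        self,
        dosages: np.ndarray,
        marker_ids: Sequence[str],
        sample_ids: Sequence[tuple[str, str]],
    ):
        dosages = np.asarray(dosages, dtype=float)
        if dosages.ndim != 2:
            raise GenotypeFormatError("dosages must be a 2-D matrix")
        finite = dosages[np.isfinite(dosages)]
        if finite.size and not np.isin(finite, _VALID_DOSAGES).all():
            bad = finite[~np.isin(finite, _VALID_DOSAGES)][:3]
            raise GenotypeFormatError(
                f"dosages must be 0, 0.5, 1 or missing; found {bad}"
            )
        if dosages.shape[1] != len(marker_ids):
            raise GenotypeFormatError("marker_ids length != number of columns")
        if dosages.shape[0] != len(sample_ids):
            raise AlignmentError("sample_ids length != number of rows")
        self.dosages = dosages
        self.marker_ids = list(marker_ids)
        self.sample_ids = [tuple(s) for s in sample_ids]
        self._marker_index = {m: j for j, m in enumerate(self.marker_ids)}
        if len(self._marker_index) != len(self.marker_ids):
            raise GenotypeFormatError("duplicate marker ids")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def marker_index(self, marker_id: str) -> int:
        return self._marker_index[marker_id]

    def column(self, marker_id: str) -> np.ndarray:
        return self.dosages[:, self._marker_index[marker_id]]

    def subset_markers(self, marker_ids: Iterable[str]) -> "GenotypeMatrix":
        ids = list(marker_ids)
        cols = [self._marker_index[m] for m in ids]
        return GenotypeMatrix(self.dosages[:, cols], ids, self.sample_ids)

    def subset_individuals(self, rows: np.ndarray) -> "GenotypeMatrix":
        rows = np.asarray(rows)
        if rows.dtype == bool:
            rows = np.nonzero(rows)[0]
        return GenotypeMatrix(
            self.dosages[rows], self.marker_ids, [self.sample_ids[int(r)] for r in rows]
        )

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(self.sample_ids, names=["FID", "IID"])
        return pd.DataFrame(self.dosages, index=idx, columns=self.marker_ids)


@dataclass
class PhenotypeReplicates:
    """Affection status (1 = case, 0 = control) per individual x replicate.

    ``prevalence`` is the population disease prevalence *k* used by the
    MQLS phenotype contrast; it is user-supplied, never estimated here.
    """

    sample_ids: list[tuple[str, str]]
    values: np.ndarray  # (n, R) float with NaN for missing
    replicate_names: list[str] = field(default_factory=list)
    prevalence: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.shape[0] != len(self.sample_ids):
            raise AlignmentError("phenotype rows != number of sample ids")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and not np.isin(finite, [0.0, 1.0]).all():
            raise ValueError("affection status must be 0, 1 or missing")
        if not self.replicate_names:
            self.replicate_names = [f"rep{r + 1}" for r in range(self.values.shape[1])]

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    def replicate(self, index: int) -> np.ndarray:
        return self.values[:, index]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _align_to_pedigree(
    sample_ids: list[tuple[str, str]], values: np.ndarray, pedigree: Pedigree | None
) -> tuple[list[tuple[str, str]], np.ndarray]:
    if pedigree is None:
        return sample_ids, values
    if len(sample_ids) != pedigree.n or set(sample_ids) != set(pedigree.sample_ids):
        raise AlignmentError(
            f"{len(sample_ids)} genotype/phenotype rows do not match the "
            f"{pedigree.n} pedigree members"
        )
    pos = {key: i for i, key in enumerate(sample_ids)}
    order = np.asarray([pos[key] for key in pedigree.sample_ids], dtype=np.intp)
    return list(pedigree.sample_ids), values[order]


def read_genotypes(
    path: str | Path,
    dialect: str = "tsv_dosage",
    map_path: str | Path | None = None,
    pedigree: Pedigree | None = None,
    minor_alleles: Mapping[str, str] | None = None,
) -> GenotypeMatrix:
    """Read genotypes from a PLINK .ped/.map pair or a TSV dosage matrix.

    ped_map
        ``path`` is the .ped file (FID IID PAT MAT SEX PHENO + two allele
        columns per marker, "0" = missing allele); ``map_path`` defaults to
        the sibling .map file.  The minor allele per marker is taken from
        ``minor_alleles`` if given (e.g. the annotation's reference minor
        allele), otherwise from the observed allele counts, ties broken by
        taking the lexicographically later symbol as minor.
    tsv_dosage
        tab-separated, columns FID, IID, then one integer 0/1/2
        minor-allele count per marker (converted to half-counts; empty =
        missing).
    """
    path = Path(path)
    if dialect == "ped_map":
        return _read_ped_map(path, map_path, pedigree, minor_alleles)
    if dialect == "tsv_dosage":
        return _read_tsv_dosage(path, pedigree)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_ped_map(
    path: Path,
    map_path: str | Path | None,
    pedigree: Pedigree | None,
    minor_alleles: Mapping[str, str] | None,
) -> GenotypeMatrix:
    if map_path is None:
        map_path = path.with_suffix(".map")
    marker_ids: list[str] = []
    with Path(map_path).open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise GenotypeFormatError(
                    f"{Path(map_path).name}:{lineno}: expected >= 2 columns"
                )
            marker_ids.append(fields[1])

    sample_ids: list[tuple[str, str]] = []
    allele_rows: list[list[str]] = []
    n_markers = len(marker_ids)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * n_markers:
                raise GenotypeFormatError(
                    f"{path.name}:{lineno}: expected {6 + 2 * n_markers} columns "
                    f"(6 + 2 alleles x {n_markers} markers), got {len(fields)}"
                )
            sample_ids.append((fields[0], fields[1]))
            allele_rows.append(fields[6:])

    alleles = np.asarray(allele_rows, dtype=object).reshape(len(sample_ids), n_markers, 2)
    dosages = np.full((len(sample_ids), n_markers), np.nan)
    for j, marker in enumerate(marker_ids):
        a = alleles[:, j, :]
        observed = a[a != "0"]
        symbols = sorted(set(observed.tolist()))
        if len(symbols) > 2:
            raise GenotypeFormatError(
                f"marker {marker}: more than two alleles observed: {symbols}"
            )
        if not symbols:
            continue  # entirely missing marker
        if minor_alleles and marker in minor_alleles:
            minor = str(minor_alleles[marker])
        elif len(symbols) == 1:
            minor = symbols[0]
        else:
            counts = {s: int((observed == s).sum()) for s in symbols}
            # minor = least frequent; ties broken lexicographically (later wins)
            minor = min(symbols, key=lambda s: (counts[s], -ord(s[0])))
            if counts[symbols[0]] == counts[symbols[1]]:
                minor = symbols[-1]
        missing = (a == "0").any(axis=1)
        dosages[:, j] = (a == minor).sum(axis=1) / 2.0
        dosages[missing, j] = np.nan
    sample_ids, dosages = _align_to_pedigree(sample_ids, dosages, pedigree)
    return GenotypeMatrix(dosages, marker_ids, sample_ids)


def _read_tsv_dosage(path: Path, pedigree: Pedigree | None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3 or [c.upper() for c in df.columns[:2]] != ["FID", "IID"]:
        raise GenotypeFormatError(
            f"{path.name}: expected columns FID, IID, then marker dosages"
        )
    sample_ids = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
    counts = df.iloc[:, 2:].to_numpy(dtype=float)
    finite = counts[np.isfinite(counts)]
    if finite.size and not np.isin(finite, [0.0, 1.0, 2.0]).all():
        raise GenotypeFormatError(
            f"{path.name}: dosage counts must be 0, 1, 2 or missing"
        )
    sample_ids, counts = _align_to_pedigree(sample_ids, counts, pedigree)
    return GenotypeMatrix(counts / 2.0, list(df.columns[2:]), sample_ids)


def write_dosage_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as an integer 0/1/2 TSV dosage matrix."""
    counts = g.dosages * 2.0
    df = pd.DataFrame(counts, columns=g.marker_ids)
    df = df.astype("Int64")  # nullable ints keep missing as empty cells
    df.insert(0, "IID", [s[1] for s in g.sample_ids])
    df.insert(0, "FID", [s[0] for s in g.sample_ids])
    df.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read and validate a variant annotation TSV.

    Columns: marker_id, gene, chromosome, functional_class, population_maf.
    """
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str, "gene": str, "chromosome": str})
    return validate_annotation(df)


def validate_annotation(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table is missing columns {missing}")
    if df["marker_id"].duplicated().any():
        dup = df.loc[df["marker_id"].duplicated(), "marker_id"].iloc[0]
        raise ValueError(f"duplicate marker_id in annotation: {dup}")
    bad_class = set(df["functional_class"]) - set(FUNCTIONAL_CLASSES)
    if bad_class:
        raise ValueError(f"unknown functional_class values: {sorted(bad_class)}")
    maf = df["population_maf"].to_numpy(dtype=float)
    if ((maf < 0) | (maf > 0.5)).any():
        raise ValueError("population_maf must lie in [0, 0.5]")
    return df


def write_annotation(df: pd.DataFrame, path: str | Path) -> None:
    validate_annotation(df)
    df.to_csv(path, sep="\t", index=False, columns=list(ANNOTATION_COLUMNS))


def read_phenotypes(
    path: str | Path,
    pedigree: Pedigree | None = None,
    prevalence: float | None = None,
) -> PhenotypeReplicates:
    """Read a wide replicate phenotype TSV: FID, IID, one column per replicate."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.shape[1] < 3 or [c.upper() for c in df.columns[:2]] != ["FID", "IID"]:
        raise GenotypeFormatError(
            f"{Path(path).name}: expected columns FID, IID, then replicates"
        )
    sample_ids = list(zip(df.iloc[:, 0], df.iloc[:, 1]))
    values = df.iloc[:, 2:].to_numpy(dtype=float)
    sample_ids, values = _align_to_pedigree(sample_ids, values, pedigree)
    return PhenotypeReplicates(
        sample_ids=sample_ids,
        values=values,
        replicate_names=list(df.columns[2:]),
        prevalence=prevalence,
    )


def write_phenotypes(pheno: PhenotypeReplicates, path: str | Path) -> None:
    df = pd.DataFrame(pheno.values, columns=pheno.replicate_names).astype("Int64")
    df.insert(0, "IID", [s[1] for s in pheno.sample_ids])
    df.insert(0, "FID", [s[0] for s in pheno.sample_ids])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# allele frequencies and the rare filter
# ---------------------------------------------------------------------------


def observed_maf(
    g: GenotypeMatrix,
    subset: str | np.ndarray = "all",
    pedigree: Pedigree | None = None,
) -> np.ndarray:
    """Per-marker observed minor-allele frequency over a subset of individuals.

    ``subset`` is ``"all"``, ``"founders"`` (requires ``pedigree``), or an
    index/boolean array.  The frequency is the mean half-count dosage over
    non-missing entries; markers with every entry missing return NaN.
    Founders approximate a population sample, so founders-only frequencies
    are the default stand-in when no population MAF is supplied.
    """
    if isinstance(subset, str):
        if subset == "all":
            rows = np.arange(g.n_individuals)
        elif subset == "founders":
            if pedigree is None:
                raise ValueError("subset='founders' requires a pedigree")
            rows = np.nonzero(pedigree.founder_mask())[0]
        else:
            raise ValueError(f"unknown subset {subset!r}")
    else:
        rows = np.asarray(subset)
        if rows.dtype == bool:
            rows = np.nonzero(rows)[0]
    if rows.size == 0:
        raise ValueError("empty individual subset")
    sub = g.dosages[rows]
    counts = np.isfinite(sub).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.nansum(sub, axis=0) / counts
    out[counts == 0] = np.nan  # marker entirely missing in the subset
    return out


def rare_filter(
    ann: pd.DataFrame,
    threshold: float = 0.01,
    source: str = "population_maf",
    observed: Mapping[str, float] | None = None,
) -> set[str]:
    """Marker ids whose MAF is strictly below ``threshold``.

    ``source`` selects the population MAF column of the annotation or an
    ``observed`` mapping (marker_id -> frequency) computed from data.
    The inequality is strict: a marker at exactly the threshold is excluded.
    """
    if not 0 < threshold <= 0.5:
        raise ValueError("threshold must lie in (0, 0.5]")
    ann = validate_annotation(ann)
    if source == "population_maf":
        maf = ann.set_index("marker_id")["population_maf"]
    elif source == "observed":
        if observed is None:
            raise ValueError("source='observed' requires an observed MAF mapping")
        maf = pd.Series({m: observed.get(m, np.nan) for m in ann["marker_id"]})
    else:
        raise ValueError(f"unknown MAF source {source!r}")
    return set(maf.index[maf < threshold])
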