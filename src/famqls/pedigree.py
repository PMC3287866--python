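"""Pedigrees and kinship matrices.

A pedigree is an ordered set of individuals with optional parent links.
From it we compute the kinship matrix :math:`\\Phi`, the null covariance
structure of genotypes used by the quasi-likelihood score tests: off the
diagonal :math:`\\Phi_{ij} = \\varphi_{ij}`, the probability that one
allele sampled at random from *i* and one from *j* are identical by
descent; on the diagonal :math:`\\Phi_{ii} = (1 + h_i)/2` where ``h_i``
is the inbreeding coefficient (the kinship of *i*'s parents).

The kinship coefficients follow the standard recursion, with founders
assumed mutually unrelated and non-inbred:

* founder: :math:`\\varphi_{ii} = 1/2`, :math:`\\varphi_{ij} = 0` for
  any *j* that is not a descendant of *i*;
* non-founder *i* with parents *f*, *m*:
  :math:`\\varphi_{ii} = (1 + \\varphi_{fm})/2` and
  :math:`\\varphi_{ij} = (\\varphi_{fj} + \\varphi_{mj})/2` for any *j*
  processed before *i* in a parents-first order.

Individuals from different families have kinship exactly 0, so the
matrix is stored and factored block-diagonally per family.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy import linalg


class PedigreeError(ValueError):
    """Base class for pedigree parsing and validation failures."""


class PedigreeParseError(PedigreeError):
    """Malformed pedigree file (bad column count, duplicate ids, ...)."""


class PedigreeValidationError(PedigreeError):
    """Structurally invalid pedigree (missing parents, cycles, ...)."""


class KinshipNumericalError(np.linalg.LinAlgError):
    """A family's kinship block failed its Cholesky factorization."""


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE}
_SEX_TO_CODE = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father_id`` and ``mother_id`` are either both ``None`` (founder)
    or both present (non-founder); a single recorded parent is invalid.
    Sex is parsed from input files but never used by any computation
    (no X-chromosome handling).
    """

    family_id: str
    person_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: Sex = Sex.UNKNOWN

    def __post_init__(self) -> None:
        if (self.father_id is None) != (self.mother_id is None):
            raise PedigreeValidationError(
                f"individual {self.family_id}:{self.person_id} has exactly one "
                "recorded parent; founders must have neither, non-founders both"
            )

    @property
    def is_founder(self) -> bool:
        return self.father_id is None

    @property
    def key(self) -> tuple[str, str]:
        return (self.family_id, self.person_id)


class Pedigree:
    """Validated, ordered collection of :class:`Individual`.

    Order is preserved from the input (file order).  Validation is
    order-independent: parents may be listed after their children.
    """

    def __init__(self, individuals: Iterable[Individual]):
        self.individuals: list[Individual] = list(individuals)
        self._index: dict[tuple[str, str], int] = {}
        self._family_rows: dict[str, list[int]] = {}
        for row, ind in enumerate(self.individuals):
            if ind.key in self._index:
                raise PedigreeValidationError(
                    f"duplicate individual {ind.family_id}:{ind.person_id}"
                )
            self._index[ind.key] = row
            self._family_rows.setdefault(ind.family_id, []).append(row)
        self._validate_parents()
        self._topo = self._topological_order()

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.individuals)

    def __getitem__(self, row: int) -> Individual:
        return self.individuals[row]

    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def family_ids(self) -> list[str]:
        return list(self._family_rows)

    @property
    def sample_ids(self) -> list[tuple[str, str]]:
        return [ind.key for ind in self.individuals]

    def row(self, family_id: str, person_id: str) -> int:
        return self._index[(family_id, person_id)]

    def family_rows(self, family_id: str) -> np.ndarray:
        return np.asarray(self._family_rows[family_id], dtype=np.intp)

    # -- structure ----------------------------------------------------------

    def founders(self) -> list[Individual]:
        """All individuals with no recorded parents, in pedigree order."""
        return [ind for ind in self.individuals if ind.is_founder]

    def founder_mask(self) -> np.ndarray:
        return np.asarray([ind.is_founder for ind in self.individuals], dtype=bool)

    def parent_rows(self, row: int) -> tuple[int, int] | None:
        """Row indices of (father, mother), or None for a founder."""
        ind = self.individuals[row]
        if ind.is_founder:
            return None
        return (
            self._index[(ind.family_id, ind.father_id)],
            self._index[(ind.family_id, ind.mother_id)],
        )

    def topological_order(self) -> list[int]:
        """Row indices in an order where parents precede children."""
        return list(self._topo)

    # -- validation ---------------------------------------------------------

    def _validate_parents(self) -> None:
        for ind in self.individuals:
            if ind.is_founder:
                continue
            for parent_id in (ind.father_id, ind.mother_id):
                if (ind.family_id, parent_id) not in self._index:
                    raise PedigreeValidationError(
                        f"unknown parent {parent_id} of "
                        f"{ind.family_id}:{ind.person_id}"
                    )

    def _topological_order(self) -> list[int]:
        # Kahn's algorithm on the parent -> child graph; a leftover node
        # means an individual is its own ancestor.
        n = len(self.individuals)
        children: list[list[int]] = [[] for _ in range(n)]
        indegree = np.zeros(n, dtype=int)
        for row in range(n):
            parents = self.parent_rows(row)
            if parents is None:
                continue
            fa, mo = parents
            children[fa].append(row)
            children[mo].append(row)
            indegree[row] = 2
        order = [row for row in range(n) if indegree[row] == 0]
        head = 0
        while head < len(order):
            row = order[head]
            head += 1
            for child in children[row]:
                indegree[child] -= 1
                if indegree[child] == 0:
                    order.append(child)
        if len(order) != n:
            bad = [self.individuals[r].key for r in range(n) if indegree[r] > 0]
            raise PedigreeValidationError(
                f"cycle in parent graph involving {bad[:5]}"
            )
        return order


def read_pedigree(
    path: str | Path,
    dialect: str = "fam",
    missing_parent: str = "0",
) -> Pedigree:
    """Read a LINKAGE/PLINK pedigree file (.fam, or the leading columns of .ped).

    Whitespace-delimited, at least five columns per line:
    ``FID IID PAT MAT SEX [PHENO ...]``.  The phenotype column, if present,
    is ignored here; phenotypes are loaded separately so that replicate
    phenotype tables can be attached to one pedigree.  Parent id equal to
    ``missing_parent`` (default ``"0"``) means no recorded parent.
    """
    if dialect not in ("fam", "ped"):
        raise ValueError(f"unknown pedigree dialect {dialect!r}")
    path = Path(path)
    individuals: list[Individual] = []
    seen: dict[tuple[str, str], int] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 5:
                raise PedigreeParseError(
                    f"{path.name}:{lineno}: expected >= 5 columns "
                    f"(FID IID PAT MAT SEX), got {len(fields)}"
                )
            fid, iid, pat, mat, sex_code = fields[:5]
            if (fid, iid) in seen:
                raise PedigreeParseError(
                    f"{path.name}:{lineno}: duplicate individual {fid}:{iid} "
                    f"(first seen on line {seen[(fid, iid)]})"
                )
            seen[(fid, iid)] = lineno
            try:
                individuals.append(
                    Individual(
                        family_id=fid,
                        person_id=iid,
                        father_id=None if pat == missing_parent else pat,
                        mother_id=None if mat == missing_parent else mat,
                        sex=_SEX_CODES.get(sex_code, Sex.UNKNOWN),
                    )
                )
            except PedigreeValidationError as exc:
                raise PedigreeValidationError(f"{path.name}:{lineno}: {exc}") from exc
    return Pedigree(individuals)


def write_fam(ped: Pedigree, path: str | Path, missing_parent: str = "0") -> None:
    """Write a 6-column .fam file (phenotype column written as 0/missing)."""
    with Path(path).open("w") as fh:
        for ind in ped:
            fh.write(
                f"{ind.family_id} {ind.person_id} "
                f"{ind.father_id or missing_parent} {ind.mother_id or missing_parent} "
                f"{_SEX_TO_CODE[ind.sex]} 0\n"
            )


class KinshipMatrix:
    """Block-diagonal kinship matrix aligned to a pedigree's row order.

    Rows/columns are indexed by (family_id, person_id) in pedigree order;
    entries for individuals in different families are exactly zero and
    never stored.  Linear algebra (solves, quadratic forms) is done per
    family block through Cholesky factorizations; the matrix is never
    explicitly inverted.
    """

    def __init__(
        self,
        ids: Sequence[tuple[str, str]],
        family_ids: Sequence[str],
        blocks: dict[str, np.ndarray],
        rows: dict[str, np.ndarray],
    ):
        self.ids = list(ids)
        self.family_ids = list(family_ids)
        self._blocks = {fid: np.asarray(b, dtype=float) for fid, b in blocks.items()}
        self._rows = {fid: np.asarray(r, dtype=np.intp) for fid, r in rows.items()}
        self.n = len(self.ids)
        self._factors: dict[str, tuple] = {}
        self._ones_cache: tuple[np.ndarray, float] | None = None

    @classmethod
    def from_dense(
        cls,
        values: np.ndarray,
        ids: Sequence[tuple[str, str]] | None = None,
        family_id: str = "ALL",
    ) -> "KinshipMatrix":
        """Wrap a dense symmetric matrix as a single-family kinship matrix."""
        values = np.asarray(values, dtype=float)
        n = values.shape[0]
        if ids is None:
            ids = [(family_id, str(i)) for i in range(n)]
        return cls(ids, [family_id], {family_id: values}, {family_id: np.arange(n)})

    def block(self, family_id: str) -> np.ndarray:
        return self._blocks[family_id]

    def family_rows(self, family_id: str) -> np.ndarray:
        return self._rows[family_id]

    def dense(self) -> np.ndarray:
        out = np.zeros((self.n, self.n))
        for fid in self.family_ids:
            rows = self._rows[fid]
            out[np.ix_(rows, rows)] = self._blocks[fid]
        return out

    def diagonal(self) -> np.ndarray:
        out = np.zeros(self.n)
        for fid in self.family_ids:
            out[self._rows[fid]] = np.diag(self._blocks[fid])
        return out

    def inbreeding(self) -> np.ndarray:
        """Per-individual inbreeding coefficients h_i = 2*Phi_ii - 1."""
        return 2.0 * self.diagonal() - 1.0

    def value(self, i: int, j: int) -> float:
        """Entry Phi_ij by global row indices (0 across families)."""
        for fid in self.family_ids:
            rows = self._rows[fid]
            pos_i = np.nonzero(rows == i)[0]
            pos_j = np.nonzero(rows == j)[0]
            if pos_i.size and pos_j.size:
                return float(self._blocks[fid][pos_i[0], pos_j[0]])
            if pos_i.size or pos_j.size:
                return 0.0
        return 0.0

    def submatrix(self, keep: np.ndarray) -> "KinshipMatrix":
        """Restriction to a subset of rows (bool mask or sorted indices)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.nonzero(keep)[0]
        new_pos = {int(old): new for new, old in enumerate(keep)}
        ids = [self.ids[int(old)] for old in keep]
        family_ids, blocks, rows = [], {}, {}
        for fid in self.family_ids:
            old_rows = self._rows[fid]
            local_keep = [k for k, r in enumerate(old_rows) if int(r) in new_pos]
            if not local_keep:
                continue
            family_ids.append(fid)
            idx = np.asarray(local_keep, dtype=np.intp)
            blocks[fid] = self._blocks[fid][np.ix_(idx, idx)]
            rows[fid] = np.asarray(
                [new_pos[int(old_rows[k])] for k in local_keep], dtype=np.intp
            )
        return KinshipMatrix(ids, family_ids, blocks, rows)

    # -- linear algebra -----------------------------------------------------

    def _factor(self, fid: str):
        if fid not in self._factors:
            try:
                self._factors[fid] = linalg.cho_factor(self._blocks[fid], lower=True)
            except np.linalg.LinAlgError as exc:
                raise KinshipNumericalError(
                    f"kinship block for family {fid!r} is not positive definite"
                ) from exc
        return self._factors[fid]

    def assert_positive_definite(self) -> None:
        """Factor every family block; raises KinshipNumericalError on failure."""
        for fid in self.family_ids:
            self._factor(fid)

    def matvec(self, v: np.ndarray) -> np.ndarray:
        """Phi @ v for a vector (n,) or matrix (n, k)."""
        v = np.asarray(v, dtype=float)
        out = np.zeros_like(v)
        for fid in self.family_ids:
            rows = self._rows[fid]
            out[rows] = self._blocks[fid] @ v[rows]
        return out

    def solve(self, b: np.ndarray) -> np.ndarray:
        """Phi^{-1} b via per-family Cholesky solves."""
        b = np.asarray(b, dtype=float)
        out = np.zeros_like(b)
        for fid in self.family_ids:
            rows = self._rows[fid]
            out[rows] = linalg.cho_solve(self._factor(fid), b[rows])
        return out

    def solve_ones(self) -> tuple[np.ndarray, float]:
        """(w, S) with w = Phi^{-1} 1 and S = 1' Phi^{-1} 1 (cached)."""
        if self._ones_cache is None:
            w = self.solve(np.ones(self.n))
            self._ones_cache = (w, float(w.sum()))
        return self._ones_cache


def compute_kinship(ped: Pedigree) -> KinshipMatrix:
    """Kinship matrix of a validated pedigree by the standard recursion.

    Founders are treated as mutually unrelated and non-inbred.  Individuals
    are processed in a parents-first topological order computed internally,
    so the result does not depend on the order of rows in the input file.
    """
    topo = ped.topological_order()
    family_ids = ped.family_ids
    blocks: dict[str, np.ndarray] = {}
    rows: dict[str, np.ndarray] = {}
    for fid in family_ids:
        fam_rows = ped.family_rows(fid)
        fam_set = set(int(r) for r in fam_rows)
        topo_rows = [r for r in topo if r in fam_set]
        pos = {r: a for a, r in enumerate(topo_rows)}
        f = len(topo_rows)
        k = np.zeros((f, f))
        for a, r in enumerate(topo_rows):
            parents = ped.parent_rows(r)
            if parents is None:
                k[a, a] = 0.5
            else:
                fa, mo = pos[parents[0]], pos[parents[1]]
                k[a, a] = 0.5 * (1.0 + k[fa, mo])
                if a:
                    k[a, :a] = 0.5 * (k[fa, :a] + k[mo, :a])
                    k[:a, a] = k[a, :a]
        # reorder the block from topological order back to file order
        inv = np.asarray([pos[int(r)] for r in fam_rows], dtype=np.intp)
        blocks[fid] = k[np.ix_(inv, inv)]
        rows[fid] = fam_rows
    return KinshipMatrix(ped.sample_ids, family_ids, blocks, rows)
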