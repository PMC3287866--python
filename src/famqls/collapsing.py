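"""Gene-level collapsing of rare variants into a carrier indicator.

A gene's rare variants are replaced by one dichotomous pseudo-marker
``G``: 1 if the individual carries at least one rare allele at any member
SNP of the gene, 0 if every member genotype is homozygous common.
Rare homozygotes count the same as heterozygotes — with variants this
rare the two-rare-allele genotype is vanishingly unlikely and presence is
all the indicator records.

The indicator is coded as a heterozygote-style half-count dosage
(0 or 0.5) so it flows through the same quasi-likelihood score tests as
any SNP, with the variance model on the same scale as a dichotomous
carrier variable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .variant_data import GenotypeMatrix, validate_annotation, write_dosage_tsv

CLASS_FILTERS = {
    "all": set(("synonymous", "nonsynonymous", "unknown")),
    "nonsynonymous_only": set(("nonsynonymous",)),
}


class EmptyGeneError(ValueError):
    """No member marker of the gene survives the rare/class filters."""


@dataclass
class CollapsedGenotype:
    """The collapsed carrier indicator for one gene.

    ``indicator`` is 1/0/NaN per individual; an individual is missing only
    if some member genotype is missing *and* no observed member genotype
    already forces carrier status.  ``pseudo_dosage`` is ``indicator / 2``,
    the half-count coding fed to the score tests.
    """

    gene: str
    member_markers: list[str]
    indicator: np.ndarray

    @property
    def pseudo_dosage(self) -> np.ndarray:
        return self.indicator / 2.0

    @property
    def is_monomorphic(self) -> bool:
        obs = self.indicator[np.isfinite(self.indicator)]
        return obs.size == 0 or bool(np.all(obs == obs[0]))

    @property
    def carrier_count(self) -> int:
        return int(np.nansum(self.indicator == 1.0))


def qualifying_markers(
    ann: pd.DataFrame,
    gene: str,
    class_filter: str = "all",
    rare_set: Iterable[str] | None = None,
) -> list[str]:
    """Member markers of ``gene`` surviving the functional-class and rare filters."""
    if class_filter not in CLASS_FILTERS:
        raise ValueError(
            f"class_filter must be one of {sorted(CLASS_FILTERS)}, got {class_filter!r}"
        )
    ann = validate_annotation(ann)
    classes = CLASS_FILTERS[class_filter]
    sub = ann[(ann["gene"] == gene) & (ann["functional_class"].isin(classes))]
    markers = list(sub["marker_id"])
    if rare_set is not None:
        rare = set(rare_set)
        markers = [m for m in markers if m in rare]
    return markers


def gene_indicator(
    g: GenotypeMatrix,
    ann: pd.DataFrame,
    gene: str,
    class_filter: str = "all",
    rare_set: Iterable[str] | None = None,
) -> CollapsedGenotype:
    """Collapse a gene's qualifying rare variants to the carrier indicator.

    Raises :class:`EmptyGeneError` when no member marker qualifies (callers
    iterating over genes may skip such genes).
    """
    markers = qualifying_markers(ann, gene, class_filter, rare_set)
    if not markers:
        raise EmptyGeneError(
            f"gene {gene!r} has no member markers after class/rare filtering"
        )
    cols = [g.marker_index(m) for m in markers]
    sub = g.dosages[:, cols]
    with np.errstate(invalid="ignore"):
        carrier = np.nansum(sub > 0, axis=1) > 0  # NaN > 0 is False
    any_missing = np.isnan(sub).any(axis=1)
    indicator = np.where(carrier, 1.0, np.where(any_missing, np.nan, 0.0))
    return CollapsedGenotype(gene=gene, member_markers=markers, indicator=indicator)


def collapse_all(
    g: GenotypeMatrix,
    ann: pd.DataFrame,
    class_filter: str = "all",
    rare_set: Iterable[str] | None = None,
) -> list[CollapsedGenotype]:
    """Collapse every gene with at least one qualifying marker.

    Genes emptied by the filters are skipped; genes whose indicator is
    monomorphic are retained (flagged via ``is_monomorphic``) so that
    downstream tests report them as untestable rather than losing them.
    Genes are returned in order of first appearance in the annotation.
    """
    ann = validate_annotation(ann)
    out: list[CollapsedGenotype] = []
    for gene in ann["gene"].drop_duplicates():
        try:
            out.append(gene_indicator(g, ann, gene, class_filter, rare_set))
        except EmptyGeneError:
            continue
    return out


def collapsed_matrix(
    collapsed: Sequence[CollapsedGenotype],
    sample_ids: Sequence[tuple[str, str]],
) -> GenotypeMatrix:
    """Stack collapsed genes into a GenotypeMatrix of pseudo-dosages.

    The result is keyed by gene name and can be fed to the score tests
    exactly like a SNP matrix.
    """
    if not collapsed:
        raise ValueError("no collapsed genes to stack")
    dosages = np.column_stack([c.pseudo_dosage for c in collapsed])
    return GenotypeMatrix(dosages, [c.gene for c in collapsed], sample_ids)


def write_collapsed_tsv(
    collapsed: Sequence[CollapsedGenotype],
    sample_ids: Sequence[tuple[str, str]],
    path: str | Path,
) -> None:
    """Write collapsed indicators as a 0/1 TSV re-loadable as tsv_dosage."""
    write_dosage_tsv(collapsed_matrix(collapsed, sample_ids), path)
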