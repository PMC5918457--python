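"""Shared in-memory containers for genotype, pedigree and relatedness data.

All modules operate on one canonical representation:

* dosages are counts of a designated allele in ``{0, 1, 2}`` stored as
  floats, with ``numpy.nan`` as the missing sentinel (0 is a valid dosage,
  so missingness must be out of band);
* subjects are keyed by ``(family_id, individual_id)`` pairs and every
  matrix-like object carries its own ``subject_order`` so that an explicit
  alignment step can enforce one shared order before analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Missing-genotype sentinel. Always test with numpy.isnan, never equality.
MISSING = np.nan

_TRANSITIONS = {frozenset(("A", "G")), frozenset(("C", "T"))}


@dataclass(frozen=True)
class PedigreeRecord:
    """One 6-column pedigree row (FID IID father mother sex affection).

    ``father_id``/``mother_id`` use "0" for unknown; a subject is a founder
    iff both are "0". Sex is 1=male, 2=female, 0=unknown; affection is
    1=unaffected, 2=affected, 0 or -9 = missing.
    """

    family_id: str
    individual_id: str
    father_id: str = "0"
    mother_id: str = "0"
    sex: int = 0
    affection: int = 0

    @property
    def key(self) -> tuple[str, str]:
        return (self.family_id, self.individual_id)

    @property
    def is_founder(self) -> bool:
        return self.father_id == "0" and self.mother_id == "0"


@dataclass(frozen=True)
class VariantRecord:
    """A bi-allelic variant site with 1-based position."""

    chrom: str
    pos: int
    vid: str
    ref: str = "N"
    alt: str = "X"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.vid}: position must be >= 1")
        if self.ref == self.alt:
            raise ValueError(f"variant {self.vid}: ref == alt ({self.ref})")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and \
            self.ref in "ACGT" and self.alt in "ACGT"

    @property
    def is_transition(self) -> bool:
        return self.is_snv and frozenset((self.ref, self.alt)) in _TRANSITIONS


@dataclass
class GenotypeMatrix:
    """Subjects x variants allele-dosage matrix.

    ``dosage[i, j]`` counts the designated allele of variant ``j`` carried
    by subject ``i`` (ALT allele for VCF input, minor allele for PED input
    after orientation), with NaN for missing.
    """

    dosage: np.ndarray
    subject_order: list[tuple[str, str]]
    variant_order: list[VariantRecord]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.subject_order), len(self.variant_order)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.subject_order)} subjects x {len(self.variant_order)} variants"
            )
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        # fractional dosages (imputed) are allowed as long as they stay in [0, 2]
        frac = (~ok) & (self.dosage >= 0) & (self.dosage <= 2)
        if not np.all(ok | frac):
            raise ValueError("dosage entries must be in [0, 2] or NaN")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_order)

    @property
    def n_variants(self) -> int:
        return len(self.variant_order)

    def subject_index(self) -> dict[tuple[str, str], int]:
        return {k: i for i, k in enumerate(self.subject_order)}

    def variant_index(self) -> dict[str, int]:
        return {v.vid: j for j, v in enumerate(self.variant_order)}

    def subset_subjects(self, keys: Sequence[tuple[str, str]]) -> "GenotypeMatrix":
        idx = self.subject_index()
        rows = [idx[k] for k in keys]
        return GenotypeMatrix(self.dosage[rows], list(keys), list(self.variant_order))

    def subset_variants(self, cols: Sequence[int]) -> "GenotypeMatrix":
        cols = list(cols)
        return GenotypeMatrix(
            self.dosage[:, cols],
            list(self.subject_order),
            [self.variant_order[j] for j in cols],
        )


@dataclass
class RelMatrix:
    """Symmetric subject x subject relatedness matrix.

    ``kind`` is "KCM" (pedigree kinship coefficients), "GRM" (centered,
    frequency-scaled genotype estimator) or "IBS". Note the covariance
    kernel used by the association machinery is ``2 * KCM`` but the KCM
    itself stores kinship coefficients (diagonal 0.5(1+F)).
    """

    values: np.ndarray
    kind: str
    subject_order: list[tuple[str, str]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.subject_order)
        if self.values.shape != (n, n):
            raise ValueError("RelMatrix must be square over subject_order")
        if self.kind not in ("KCM", "GRM", "IBS"):
            raise ValueError(f"unknown RelMatrix kind {self.kind!r}")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and not np.allclose(
            self.values, self.values.T, atol=1e-10, equal_nan=True
        ):
            raise ValueError("RelMatrix must be symmetric")

    @property
    def kernel(self) -> np.ndarray:
        """Covariance kernel: 2*phi for kinship matrices, values otherwise."""
        return 2.0 * self.values if self.kind == "KCM" else self.values

    def subset(self, keys: Sequence[tuple[str, str]]) -> "RelMatrix":
        idx = {k: i for i, k in enumerate(self.subject_order)}
        rows = np.array([idx[k] for k in keys])
        return RelMatrix(self.values[np.ix_(rows, rows)], self.kind, list(keys))


@dataclass
class PhenotypeFrame:
    """Analysis-ready phenotype + covariates for one shared subject order.

    ``phenotype`` holds one column of values (NaN = missing); ``covariates``
    is an (n_subjects, n_covariates) array. ``kind`` is "continuous" or
    "binary" (binary recoded to 0/1).
    """

    subject_order: list[tuple[str, str]]
    phenotype: np.ndarray
    phenotype_name: str
    covariates: np.ndarray = field(default=None)  # type: ignore[assignment]
    covariate_names: list[str] = field(default_factory=list)
    kind: str = "continuous"

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype, dtype=float)
        n = len(self.subject_order)
        if self.phenotype.shape != (n,):
            raise ValueError("phenotype length must match subject_order")
        if self.covariates is None:
            self.covariates = np.empty((n, 0))
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.covariates.shape[0] != n:
            raise ValueError("covariate rows must match subject_order")
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"unknown phenotype kind {self.kind!r}")

    @property
    def complete_mask(self) -> np.ndarray:
        """Subjects with phenotype and every covariate observed."""
        ok = np.isfinite(self.phenotype)
        if self.covariates.shape[1]:
            ok &= np.all(np.isfinite(self.covariates), axis=1)
        return ok

    def drop_incomplete(self) -> "PhenotypeFrame":
        m = self.complete_mask
        keys = [k for k, keep in zip(self.subject_order, m) if keep]
        return PhenotypeFrame(
            keys, self.phenotype[m], self.phenotype_name,
            self.covariates[m], list(self.covariate_names), self.kind,
        )


@dataclass
class GeneSet:
    """Mapping gene name -> ordered variant column indices.

    Indices refer to a specific ``GenotypeMatrix.variant_order``; within a
    gene they follow genomic position. Genes may overlap and may be empty
    (empty genes are dropped later by the gene-inclusion rule).
    """

    genes: dict[str, list[int]]

    def __iter__(self):
        return iter(self.genes.items())

    def __len__(self) -> int:
        return len(self.genes)

    def nonempty(self) -> "GeneSet":
        return GeneSet({g: ix for g, ix in self.genes.items() if ix})


def check_aligned(*orders: Sequence[tuple[str, str]]) -> None:
    """Raise if the given subject orders are not all identical."""
    first = list(orders[0])
    for o in orders[1:]:
        if list(o) != first:
            raise ValueError(
                "subject orders are not aligned; call an alignment step first"
            )
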