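"""Pedigree validation, recursive kinship, and Mendelian-consistency checks.

Kinship coefficients phi follow the classical recursion over a per-family
topological order (parents before offspring):

    phi_ii = 0.5 * (1 + phi_father,mother)
    phi_ij = 0.5 * (phi_father(i),j + phi_mother(i),j)   for j earlier than i

with founders unrelated and non-inbred. The resulting kinship coefficient
matrix (KCM) is block-diagonal across families; the covariance kernel used
by the association machinery is 2*KCM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import GenotypeMatrix, PedigreeRecord, RelMatrix, check_aligned


class PedigreeError(ValueError):
    """Inconsistent pedigree structure."""


@dataclass
class Pedigree:
    """Validated pedigree with per-family topological subject order."""

    records: list[PedigreeRecord]
    #: subject keys in topological order (parents before offspring),
    #: grouped by family in first-appearance order
    topo_order: list[tuple[str, str]] = field(default_factory=list)
    founders: set[tuple[str, str]] = field(default_factory=set)
    #: human-readable notes from validation (synthetic parents added, ...)
    validation_report: list[str] = field(default_factory=list)

    @property
    def subject_keys(self) -> list[tuple[str, str]]:
        return [r.key for r in self.records]

    def record(self, key: tuple[str, str]) -> PedigreeRecord:
        return self._by_key[key]

    def parents(self, key: tuple[str, str]) -> tuple:
        """(father_key or None, mother_key or None)."""
        r = self._by_key[key]
        fa = (r.family_id, r.father_id) if r.father_id != "0" else None
        mo = (r.family_id, r.mother_id) if r.mother_id != "0" else None
        return fa, mo

    def families(self) -> dict[str, list[tuple[str, str]]]:
        """family_id -> member keys in topological order."""
        fams: dict[str, list[tuple[str, str]]] = {}
        for key in self.topo_order:
            fams.setdefault(key[0], []).append(key)
        return fams

    def __post_init__(self):
        self._by_key = {r.key: r for r in self.records}


def build_pedigree(records: list[PedigreeRecord]) -> Pedigree:
    """Validate records and establish a topological order.

    A subject listing exactly one parent gets a synthetic untyped founder
    as the other parent so the kinship recursion is total. Raises
    :class:`PedigreeError` on duplicate ids, parentage cycles, or a listed
    father/mother whose recorded sex contradicts the role.
    """
    report: list[str] = []
    by_key: dict[tuple[str, str], PedigreeRecord] = {}
    for r in records:
        if r.key in by_key:
            raise PedigreeError(f"duplicate individual {r.individual_id} in family {r.family_id}")
        by_key[r.key] = r

    completed: list[PedigreeRecord] = []
    synth_count = 0
    for r in records:
        fa, mo = r.father_id, r.mother_id
        if (fa == "0") != (mo == "0"):
            synth_count += 1
            sid = f"_synth{synth_count}"
            if fa == "0":
                fa = sid
                synth = PedigreeRecord(r.family_id, sid, "0", "0", 1, 0)
            else:
                mo = sid
                synth = PedigreeRecord(r.family_id, sid, "0", "0", 2, 0)
            by_key[synth.key] = synth
            completed.append(synth)
            report.append(
                f"added synthetic founder {sid} as missing parent of "
                f"{r.individual_id} in family {r.family_id}"
            )
            r = PedigreeRecord(r.family_id, r.individual_id, fa, mo, r.sex, r.affection)
        completed.append(r)

    # referenced parents absent from the file become untyped founders too
    for r in list(completed):
        for pid, sex in ((r.father_id, 1), (r.mother_id, 2)):
            if pid != "0" and (r.family_id, pid) not in by_key:
                synth = PedigreeRecord(r.family_id, pid, "0", "0", sex, 0)
                by_key[synth.key] = synth
                completed.append(synth)
                report.append(f"parent {pid} of {r.individual_id} (family {r.family_id}) "
                              "not listed; added as untyped founder")

    for r in completed:
        if r.father_id != "0":
            fa = by_key[(r.family_id, r.father_id)]
            if fa.sex == 2:
                raise PedigreeError(
                    f"family {r.family_id}: father {r.father_id} of "
                    f"{r.individual_id} has sex=2"
                )
        if r.mother_id != "0":
            mo = by_key[(r.family_id, r.mother_id)]
            if mo.sex == 1:
                raise PedigreeError(
                    f"family {r.family_id}: mother {r.mother_id} of "
                    f"{r.individual_id} has sex=1"
                )

    # Kahn topological sort per family, preserving first-appearance order
    fam_order: list[str] = []
    fam_members: dict[str, list[PedigreeRecord]] = {}
    for r in completed:
        if r.family_id not in fam_members:
            fam_order.append(r.family_id)
            fam_members[r.family_id] = []
        fam_members[r.family_id].append(r)

    topo: list[tuple[str, str]] = []
    founders: set[tuple[str, str]] = set()
    for fam in fam_order:
        members = fam_members[fam]
        pending = {r.key: r for r in members}
        placed: set[tuple[str, str]] = set()
        order: list[tuple[str, str]] = []
        while pending:
            progressed = False
            for key in list(pending):
                r = pending[key]
                fa = (fam, r.father_id) if r.father_id != "0" else None
                mo = (fam, r.mother_id) if r.mother_id != "0" else None
                if (fa is None or fa in placed) and (mo is None or mo in placed):
                    order.append(key)
                    placed.add(key)
                    if fa is None and mo is None:
                        founders.add(key)
                    del pending[key]
                    progressed = True
            if not progressed:
                stuck = ", ".join(k[1] for k in pending)
                raise PedigreeError(
                    f"family {fam}: parentage cycle involving {{{stuck}}}"
                )
        topo.extend(order)

    return Pedigree(completed, topo, founders, report)


def kinship_matrix(pedigree: Pedigree, subject_order=None) -> RelMatrix:
    """Kinship coefficient matrix over ``subject_order`` (default: the
    pedigree's original record order, synthetic founders included)."""
    topo = pedigree.topo_order
    pos = {k: i for i, k in enumerate(topo)}
    n = len(topo)
    phi = np.zeros((n, n))
    for key in topo:
        i = pos[key]
        fa, mo = pedigree.parents(key)
        fi = pos[fa] if fa else None
        mi = pos[mo] if mo else None
        # off-diagonals with everyone placed earlier
        for jkey in topo[:i]:
            j = pos[jkey]
            if jkey[0] != key[0]:
                continue  # other family: stays 0
            v = 0.0
            if fi is not None:
                v += 0.5 * phi[fi, j]
            if mi is not None:
                v += 0.5 * phi[mi, j]
            phi[i, j] = phi[j, i] = v
        phi[i, i] = 0.5 if fi is None or mi is None else 0.5 * (1.0 + phi[fi, mi])
    if subject_order is None:
        subject_order = [r.key for r in pedigree.records]
    rows = np.array([pos[k] for k in subject_order])
    return RelMatrix(phi[np.ix_(rows, rows)], "KCM", list(subject_order))


# ---------------------------------------------------------------------------
# Mendelian consistency
# ---------------------------------------------------------------------------

def _transmission_bounds(par: np.ndarray):
    """Min/max alleles a parent dosage vector can transmit (NaN -> 0..1)."""
    lo = np.where(np.isnan(par), 0.0, (par == 2).astype(float))
    hi = np.where(np.isnan(par), 1.0, (par != 0).astype(float))
    return lo, hi


def mendelian_errors(pedigree: Pedigree, genotypes: GenotypeMatrix,
                     check_duos: bool = True):
    """Mendelian-inconsistency rates from parent/offspring transmission.

    For each non-founder with at least one typed parent and a typed own
    genotype, a variant is inconsistent iff the offspring dosage cannot be
    the sum of one allele from each parent (an untyped or absent parent may
    transmit either allele). With ``check_duos=False`` only complete typed
    trios are checked.

    Returns ``(variant_rate, subject_rate, family_counts)``: per-variant and
    per-subject error fractions (NaN where nothing was checked, aligned to
    ``genotypes`` orders) and a family -> error-count dict. An inconsistent
    check increments the variant and each involved member once.
    """
    gidx = genotypes.subject_index()
    m = genotypes.n_variants
    var_err = np.zeros(m)
    var_opp = np.zeros(m)
    n = genotypes.n_subjects
    sub_err = np.zeros(n)
    sub_opp = np.zeros(n)
    fam_counts: dict[str, int] = {}

    for key in pedigree.topo_order:
        if key not in gidx:
            continue
        fa, mo = pedigree.parents(key)
        fa_i = gidx.get(fa) if fa else None
        mo_i = gidx.get(mo) if mo else None
        if fa_i is None and mo_i is None:
            continue
        child = genotypes.dosage[gidx[key]]
        pa = genotypes.dosage[fa_i] if fa_i is not None else np.full(m, np.nan)
        ma = genotypes.dosage[mo_i] if mo_i is not None else np.full(m, np.nan)
        typed_parents = (~np.isnan(pa)).astype(int) + (~np.isnan(ma)).astype(int)
        if not check_duos:
            usable = ~np.isnan(child) & (typed_parents == 2)
        else:
            usable = ~np.isnan(child) & (typed_parents >= 1)
        if not usable.any():
            continue
        lo_f, hi_f = _transmission_bounds(pa)
        lo_m, hi_m = _transmission_bounds(ma)
        bad = usable & ((child < lo_f + lo_m - 1e-9) | (child > hi_f + hi_m + 1e-9))
        var_opp += usable
        var_err += bad
        nbad = int(bad.sum())
        nuse = int(usable.sum())
        members = [gidx[key]] + [i for i in (fa_i, mo_i) if i is not None]
        for i in members:
            sub_opp[i] += nuse
            sub_err[i] += nbad
        if nbad:
            fam_counts[key[0]] = fam_counts.get(key[0], 0) + nbad

    with np.errstate(invalid="ignore", divide="ignore"):
        variant_rate = np.where(var_opp > 0, var_err / np.maximum(var_opp, 1), np.nan)
        subject_rate = np.where(sub_opp > 0, sub_err / np.maximum(sub_opp, 1), np.nan)
    return variant_rate, subject_rate, fam_counts


def trio_consistent(father: float, mother: float, child: float) -> bool:
    """Whether a single trio of dosages is Mendelian-consistent (NaN = untyped)."""
    pa = np.array([father], dtype=float)
    ma = np.array([mother], dtype=float)
    lo_f, hi_f = _transmission_bounds(pa)
    lo_m, hi_m = _transmission_bounds(ma)
    if np.isnan(child):
        return True
    return bool(lo_f[0] + lo_m[0] - 1e-9 <= child <= hi_f[0] + hi_m[0] + 1e-9)


def compare_kcm_grm(kcm: RelMatrix, grm: RelMatrix, threshold: float = 0.2):
    """Flag subject pairs where pedigree-declared and genotype-realized
    relatedness disagree: |2*phi_ij - GRM_ij| > threshold."""
    if kcm.kind != "KCM":
        raise ValueError("first argument must be a KCM")
    check_aligned(kcm.subject_order, grm.subject_order)
    diff = np.abs(kcm.kernel - grm.values)
    iu = np.triu_indices(len(kcm.subject_order), k=1)
    flags = []
    for i, j in zip(*iu):
        if np.isfinite(diff[i, j]) and diff[i, j] > threshold:
            flags.append((kcm.subject_order[i], kcm.subject_order[j], float(diff[i, j])))
    return flags
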