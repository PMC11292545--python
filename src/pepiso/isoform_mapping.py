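"""Peptide sharing classification and protein-group composition.

This is the heart of the pipeline.  Every quantified peptide is classified by
what its accession set says about protein/isoform sharing:

* ``UNIQUE`` — all evidence points to a single-isoform family;
* ``ISOFORM_SPECIFIC`` — a proper subset of one family's isoforms: the
  evidence unit for splicing at the protein level;
* ``SHARED_ISOFORMS`` — common to all cataloged isoforms of one family:
  reports total protein abundance irrespective of splicing;
* ``SHARED_MULTI`` — spans two or more families (gene-level ambiguity).

Peptides with *identical* accession sets form a protein group whose area per
sample is the sum of the member peptide areas observed in that sample; a
group is missing in a sample only when every member is missing there.  Under
the ``EXCLUDE_SHARED`` policy (the whole-protein differential branch),
``SHARED_MULTI`` peptides are dropped before grouping; the isoform branch
keeps them (``INCLUDE_SHARED``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import pandas as pd

from .digest import IsoformCatalog, family_of
from .errors import EmptyInputError, UnknownAccessionError
from .io_formats import PeptideKey

__all__ = [
    "PeptideClass",
    "ProteinGroupKey",
    "ProteinGroupMatrix",
    "classify_peptide",
    "compose_protein_groups",
    "family_of",
    "MULTI_FAMILY",
]

#: Family sentinel for groups whose accessions span more than one family.
MULTI_FAMILY = "MULTI"


class PeptideClass(str, enum.Enum):
    UNIQUE = "UNIQUE"
    ISOFORM_SPECIFIC = "ISOFORM_SPECIFIC"
    SHARED_ISOFORMS = "SHARED_ISOFORMS"
    SHARED_MULTI = "SHARED_MULTI"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def classify_peptide(accessions, catalog: IsoformCatalog) -> PeptideClass:
    """Classify a peptide's accession set against the isoform catalog.

    The four classes partition all classifiable peptides: spanning more than
    one family is ``SHARED_MULTI``; within a single family ``F`` the peptide
    is ``UNIQUE`` if ``F`` has exactly one cataloged isoform,
    ``SHARED_ISOFORMS`` if the set covers all of ``F``'s isoforms (>= 2), and
    ``ISOFORM_SPECIFIC`` for any proper subset.
    """
    accs = frozenset(accessions)
    if not accs:
        raise UnknownAccessionError("empty accession set")
    families = {catalog.family_of_accession(a) for a in accs}
    if len(families) > 1:
        return PeptideClass.SHARED_MULTI
    family = next(iter(families))
    isoforms = set(catalog.isoforms(family))
    if len(isoforms) == 1:
        return PeptideClass.UNIQUE
    if accs == isoforms:
        return PeptideClass.SHARED_ISOFORMS
    return PeptideClass.ISOFORM_SPECIFIC


@dataclass(frozen=True)
class ProteinGroupKey:
    """Stable identifier of a composed protein group."""

    accessions: tuple[str, ...]
    family: str
    pclass: PeptideClass

    @property
    def group_id(self) -> str:
        return ";".join(self.accessions)


@dataclass
class ProteinGroupMatrix:
    """Composed group-by-sample areas plus group metadata.

    ``areas`` is indexed by group_id; ``meta`` carries accessions, family,
    peptide class and member count per group; ``membership`` lists the
    contributing peptide keys; ``log`` records peptide bookkeeping counts.
    """

    areas: pd.DataFrame
    meta: pd.DataFrame
    membership: dict[str, list[PeptideKey]]
    log: dict[str, int]

    @property
    def samples(self) -> list[str]:
        return list(self.areas.columns)

    @property
    def group_ids(self) -> list[str]:
        return list(self.areas.index)

    def to_frame(self) -> pd.DataFrame:
        """Flat TSV-ready view: metadata columns then one column per sample."""
        return pd.concat([self.meta, self.areas], axis=1).reset_index(names="group_id")


def _resolve(pmap, key: PeptideKey):
    hit = pmap.get(key)
    if hit is None and key.modification:
        hit = pmap.get(PeptideKey(key.sequence, ""))
    return hit


def compose_protein_groups(
    areas: pd.DataFrame,
    pmap: dict[PeptideKey, frozenset[str]],
    catalog: IsoformCatalog,
    policy: str = "EXCLUDE_SHARED",
) -> ProteinGroupMatrix:
    """Pool peptides with identical accession sets into protein groups.

    Peptides without a map entry, or whose accession set is empty after
    intersection with the catalog (contaminants, decoys), are excluded and
    counted in ``log``.  Under ``EXCLUDE_SHARED``, ``SHARED_MULTI`` peptides
    are dropped (count logged) before grouping.
    """
    if policy not in ("EXCLUDE_SHARED", "INCLUDE_SHARED"):
        raise ValueError(f"unknown policy {policy!r}")

    known = catalog.accessions
    assignment: dict[PeptideKey, ProteinGroupKey] = {}
    n_unmapped = n_uncataloged = n_shared_excluded = 0
    for key in areas.index:
        pkey = PeptideKey(*key)
        accs = _resolve(pmap, pkey)
        if accs is None:
            n_unmapped += 1
            continue
        accs = frozenset(accs) & known
        if not accs:
            n_uncataloged += 1
            continue
        pclass = classify_peptide(accs, catalog)
        if policy == "EXCLUDE_SHARED" and pclass is PeptideClass.SHARED_MULTI:
            n_shared_excluded += 1
            continue
        if pclass is PeptideClass.SHARED_MULTI:
            family = MULTI_FAMILY
        else:
            family = catalog.family_of_accession(next(iter(accs)))
        assignment[pkey] = ProteinGroupKey(tuple(sorted(accs)), family, pclass)

    if not assignment:
        raise EmptyInputError(
            "no peptide in the area table could be assigned to a protein group"
        )

    group_of = pd.Series(
        {tuple(k): g.group_id for k, g in assignment.items()}, dtype=object
    )
    kept = areas.loc[list(group_of.index)]
    grouped = kept.groupby(group_of.reindex(kept.index).to_numpy(), sort=True).sum(
        min_count=1
    )
    grouped.index.name = "group_id"

    keys = {g.group_id: g for g in assignment.values()}
    membership: dict[str, list[PeptideKey]] = {gid: [] for gid in grouped.index}
    for pkey, gkey in assignment.items():
        membership[gkey.group_id].append(pkey)
    meta = pd.DataFrame(
        {
            "accessions": [";".join(keys[g].accessions) for g in grouped.index],
            "family": [keys[g].family for g in grouped.index],
            "pclass": [keys[g].pclass.value for g in grouped.index],
            "n_peptides": [len(membership[g]) for g in grouped.index],
        },
        index=grouped.index,
    )
    log = {
        "n_peptides_in": len(areas),
        "n_unmapped": n_unmapped,
        "n_uncataloged": n_uncataloged,
        "n_shared_excluded": n_shared_excluded,
        "n_peptides_grouped": len(assignment),
        "n_groups": len(grouped),
    }
    return ProteinGroupMatrix(grouped, meta, membership, log)
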