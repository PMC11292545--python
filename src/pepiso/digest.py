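"""In-silico tryptic digestion and the isoform catalog.

A distinct-peptide summary from a search engine is the natural substrate for
peptide classification, but users who only have an isoform-aware FASTA can
re-create an equivalent peptide -> accession-set map by digesting every entry
with the classical trypsin rule (cleave C-terminal to K or R unless the next
residue is P) and intersecting the resulting peptide sets.

Isoform families follow the UniProt naming convention: isoforms of canonical
accession ``P`` are ``P-1``, ``P-2``, ...; an accession without a terminal
``-<integer>`` suffix is its own canonical.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .errors import AlphabetError, ConfigError, DuplicateKeyError, UnknownAccessionError
from .io_formats import STANDARD_AA, PeptideKey

_ISOFORM_SUFFIX = re.compile(r"^(.*)-(\d+)$")


def family_of(accession: str) -> str:
    """Canonical accession of an isoform: strip one terminal ``-<integer>``.

    ``P68363-2`` -> ``P68363``; ``P68363`` -> ``P68363``; only the final
    suffix segment strips, so ``AB-CD-3`` -> ``AB-CD``.
    """
    if not accession:
        raise ValueError("empty accession")
    m = _ISOFORM_SUFFIX.match(accession)
    return m.group(1) if m else accession


@dataclass(frozen=True)
class DigestParams:
    """Tryptic digestion settings (trypsin is the only enzyme in v1)."""

    enzyme: str = "trypsin"
    missed_cleavages: int = 2
    min_len: int = 6
    max_len: int = 50

    def __post_init__(self) -> None:
        if self.enzyme != "trypsin":
            raise ConfigError(f"unsupported enzyme {self.enzyme!r}")
        if not (0 <= self.missed_cleavages <= 5):
            raise ConfigError("missed_cleavages must be in 0..5")
        if self.min_len > self.max_len or self.min_len < 1:
            raise ConfigError("require 1 <= min_len <= max_len")


@dataclass(frozen=True)
class IsoformCatalog:
    """Accession universe grouped into isoform families.

    ``families`` maps each canonical accession to the tuple of its cataloged
    isoform accessions (a single-isoform family is the canonical itself);
    ``sequences`` optionally carries the amino-acid sequences.
    """

    families: dict[str, tuple[str, ...]]
    sequences: dict[str, str] | None = None
    _acc_to_family: dict[str, str] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        lookup: dict[str, str] = {}
        for fam, isoforms in self.families.items():
            if not isoforms:
                raise ConfigError(f"family {fam!r} has no isoforms")
            for acc in isoforms:
                if acc in lookup:
                    raise DuplicateKeyError(
                        f"accession {acc!r} belongs to more than one family"
                    )
                lookup[acc] = fam
        object.__setattr__(self, "_acc_to_family", lookup)

    @classmethod
    def from_accessions(cls, accessions) -> "IsoformCatalog":
        """Group a flat accession collection into families by canonical root."""
        fams: dict[str, list[str]] = {}
        for acc in sorted(set(accessions)):
            fams.setdefault(family_of(acc), []).append(acc)
        return cls({f: tuple(sorted(a)) for f, a in fams.items()})

    @property
    def accessions(self) -> frozenset[str]:
        return frozenset(self._acc_to_family)

    def family_of_accession(self, accession: str) -> str:
        try:
            return self._acc_to_family[accession]
        except KeyError:
            raise UnknownAccessionError(f"accession {accession!r} not in catalog") from None

    def isoforms(self, family: str) -> tuple[str, ...]:
        return self.families[family]


def _check_alphabet(sequence: str) -> str:
    seq = sequence.strip().upper()
    bad = set(seq) - STANDARD_AA
    if not seq or bad:
        raise AlphabetError(
            f"sequence contains non-standard residue(s) {sorted(bad)}"
            if bad
            else "empty sequence"
        )
    return seq


def tryptic_fragments(sequence: str) -> list[str]:
    """Zero-missed-cleavage fragments, N- to C-terminal, unfiltered.

    Cleaves after K or R except when the following residue is P.  The
    concatenation of the fragments is the input sequence.
    """
    seq = _check_alphabet(sequence)
    fragments: list[str] = []
    start = 0
    for i, residue in enumerate(seq):
        if residue in "KR" and (i + 1 == len(seq) or seq[i + 1] != "P"):
            fragments.append(seq[start : i + 1])
            start = i + 1
    if start < len(seq):
        fragments.append(seq[start:])
    return fragments


def digest_sequence(
    sequence: str, params: DigestParams = DigestParams(), *, return_counts: bool = False
):
    """Fully tryptic peptides of ``sequence`` with up to ``missed_cleavages``
    internal sites, filtered to ``[min_len, max_len]``.

    Returns unique peptides in order of first occurrence; with
    ``return_counts=True`` returns a Counter recording multiplicity within
    the protein.
    """
    frags = tryptic_fragments(sequence)
    counts: Counter[str] = Counter()
    order: list[str] = []
    for i in range(len(frags)):
        pep = ""
        for j in range(i, min(i + params.missed_cleavages + 1, len(frags))):
            pep += frags[j]
            if params.min_len <= len(pep) <= params.max_len:
                if pep not in counts:
                    order.append(pep)
                counts[pep] += 1
    if return_counts:
        return counts
    return order


def _accession_from_header(record_id: str) -> str:
    # UniProt-style "sp|P12345-2|NAME" headers carry the accession in the
    # middle field; otherwise the first whitespace-delimited token is used.
    parts = record_id.split("|")
    if len(parts) >= 3 and parts[1]:
        return parts[1]
    return record_id


def build_peptide_map_from_fasta(
    fasta: str | Path,
    params: DigestParams = DigestParams(),
    *,
    collapse_il: bool = False,
) -> tuple[IsoformCatalog, dict[PeptideKey, frozenset[str]]]:
    """Digest every FASTA entry and build (catalog, peptide -> accession set).

    Each distinct peptide sequence maps to the set of accessions whose digest
    contains it.  ``collapse_il`` treats I and L as indistinguishable when
    matching peptides across proteins (off by default: search engines report
    the sequence as matched).
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(fasta), "fasta"):
        acc = _accession_from_header(record.id)
        if acc in sequences:
            raise DuplicateKeyError(f"duplicate accession {acc!r} in {fasta}")
        sequences[acc] = _check_alphabet(str(record.seq))
    if not sequences:
        raise ConfigError(f"no FASTA records in {fasta}")

    catalog = IsoformCatalog.from_accessions(sequences)
    catalog = IsoformCatalog(catalog.families, sequences)

    def match_key(pep: str) -> str:
        return pep.replace("L", "I") if collapse_il else pep

    by_match: dict[str, set[str]] = {}
    spelling: dict[str, str] = {}
    for acc, seq in sequences.items():
        for pep in digest_sequence(seq, params):
            key = match_key(pep)
            by_match.setdefault(key, set()).add(acc)
            spelling.setdefault(key, pep)
    return catalog, {
        PeptideKey(spelling[key]): frozenset(accs) for key, accs in by_match.items()
    }
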