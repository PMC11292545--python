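"""Readers and writers for the pipeline's tabular files.

All tabular I/O is UTF-8, tab-separated, header mandatory, decimal point ".".
The three input files mirror a typical SWATH/DIA workflow:

* **peptide area table** — rows keyed by (sequence, modification), one column
  per sample, values are summed fragment/peptide areas.  Non-detections are
  conventionally exported as ``0``; by default these are mapped to *missing*
  because a structural zero is absence of evidence, not a measured abundance.
* **distinct peptide summary** — maps each peptide to its ``;``-separated set
  of protein accessions (the protein group the search engine assigned).
* **sample design** — two columns, ``sample_id`` and ``cohort``; cohort labels
  are normalised through an alias table (fertile/control -> A,
  infertile/case -> B).

Result tables are written so that re-reading reproduces every field
(round-trip, 1e-9 relative tolerance on floats).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import pandas as pd
import yaml

from .errors import (
    AlphabetError,
    ConfigError,
    ConflictError,
    DesignError,
    DuplicateKeyError,
    FormatError,
    LabelError,
)

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Cohort alias table; extendable through config, never hard-coded downstream.
DEFAULT_COHORT_ALIASES: dict[str, str] = {
    "a": "A",
    "b": "B",
    "fertile": "A",
    "control": "A",
    "infertile": "B",
    "case": "B",
}

FLOAT_FORMAT = "%.12g"  # preserves >= 3 significant digits through round-trip


class PeptideKey(NamedTuple):
    """Row identifier of the peptide area table: sequence plus modification.

    Search engines report modified peptides as separate quantified entities;
    keeping the modification string in the key preserves that distinction.
    Users deriving the peptide map from a FASTA digest (no modifications)
    still match: lookups fall back to (sequence, "").
    """

    sequence: str
    modification: str = ""


def validate_sequence(sequence: str, *, context: str = "") -> str:
    seq = sequence.strip().upper()
    if not seq:
        raise FormatError(f"empty peptide sequence {context}".strip())
    bad = set(seq) - STANDARD_AA
    if bad:
        raise AlphabetError(
            f"non-standard residue(s) {sorted(bad)} in sequence {seq!r} {context}".strip()
        )
    return seq


@dataclass(frozen=True)
class SampleDesign:
    """Two-cohort sample layout; cohort A is the reference (fertile)."""

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        ids = [s for s, _ in self.entries]
        if len(ids) != len(set(ids)):
            dup = sorted({s for s in ids if ids.count(s) > 1})
            raise DesignError(f"duplicate sample ids: {dup}")
        if any(not s for s in ids):
            raise DesignError("empty sample id")
        for _, c in self.entries:
            if c not in ("A", "B"):
                raise LabelError(f"cohort label {c!r} not in {{A, B}}")
        for cohort in ("A", "B"):
            n = sum(1 for _, c in self.entries if c == cohort)
            if n < 2:
                raise DesignError(f"cohort {cohort} has {n} samples; at least 2 required")

    @property
    def samples(self) -> list[str]:
        return [s for s, _ in self.entries]

    @property
    def samples_a(self) -> list[str]:
        return [s for s, c in self.entries if c == "A"]

    @property
    def samples_b(self) -> list[str]:
        return [s for s, c in self.entries if c == "B"]

    def cohort_of(self, sample_id: str) -> str:
        for s, c in self.entries:
            if s == sample_id:
                return c
        raise KeyError(sample_id)


@dataclass(frozen=True)
class AnalysisThresholds:
    """Statistical thresholds of the two analysis branches.

    p_de / fc_de gate the whole-protein differential-abundance filter
    (p < 0.05 and >= 2-fold); p_iso is the raw-p filter on isoform-specific
    groups (p < 0.01); min_obs_per_group is the per-cohort observation count
    required for a group to be testable; permutations drives the
    permutation-based FDR.
    """

    p_de: float = 0.05
    fc_de: float = 2.0
    p_iso: float = 0.01
    min_obs_per_group: int = 3
    permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_de < 1.0 and 0.0 < self.p_iso < 1.0):
            raise ConfigError("p_de and p_iso must lie strictly between 0 and 1")
        if self.fc_de < 1.0:
            raise ConfigError("fc_de must be >= 1")
        if self.min_obs_per_group < 2:
            raise ConfigError("min_obs_per_group must be >= 2")
        if self.permutations < 1:
            raise ConfigError("permutations must be >= 1")


# ---------------------------------------------------------------------------
# peptide area table
# ---------------------------------------------------------------------------

def read_peptide_area_table(
    path: str | Path, *, zero_as_missing: bool = True
) -> pd.DataFrame:
    """Read a SWATH-style peptide area export.

    Returns a DataFrame indexed by a (sequence, modification) MultiIndex with
    one float column per sample; missing values are NaN.  With the default
    ``zero_as_missing`` policy, literal ``0`` cells become missing.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = list(raw.columns)
    if len(cols) < 3:
        raise FormatError(
            f"{path}: expected sequence, modification and >=1 sample column, got {cols}"
        )
    for i, expected in enumerate(("sequence", "modification")):
        if cols[i].strip().lower() != expected:
            raise FormatError(
                f"{path}: column {i + 1} must be {expected!r}, found {cols[i]!r}"
            )
    sample_cols = cols[2:]
    if len(set(sample_cols)) != len(sample_cols):
        raise FormatError(f"{path}: duplicate sample columns in header")

    sequences = [
        validate_sequence(s, context=f"(row {i})") for i, s in enumerate(raw[cols[0]])
    ]
    modifications = [m.strip() for m in raw[cols[1]]]
    index = pd.MultiIndex.from_arrays(
        [sequences, modifications], names=("sequence", "modification")
    )
    if index.has_duplicates:
        dup = index[index.duplicated()].tolist()
        raise DuplicateKeyError(f"{path}: duplicate peptide key(s) {dup[:5]}")

    values = pd.DataFrame(index=index)
    for col in sample_cols:
        cell = raw[col].str.strip().replace("", None)
        try:
            numeric = pd.to_numeric(cell)
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: non-numeric area in column {col!r}: {exc}") from exc
        values[col] = numeric.to_numpy(dtype=float)
    neg = values.lt(0).any(axis=1)
    if neg.any():
        row = int(neg.to_numpy().argmax())
        raise ValueError(f"{path}: negative area at row {row} ({index[row]})")
    if zero_as_missing:
        values = values.mask(values == 0.0)
    return values


def write_peptide_area_table(table: pd.DataFrame, path: str | Path) -> None:
    out = table.reset_index()
    out.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.8g")


# ---------------------------------------------------------------------------
# distinct peptide summary (peptide -> protein group)
# ---------------------------------------------------------------------------

def read_distinct_peptide_summary(path: str | Path) -> dict[PeptideKey, frozenset[str]]:
    """Read a distinct-peptide summary mapping each peptide to its accession set.

    Identical duplicate rows collapse silently; a peptide listed with two
    different accession sets is a hard conflict (no silent union).
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = {c.strip().lower(): c for c in raw.columns}
    for needed in ("sequence", "modification", "accessions"):
        if needed not in cols:
            raise FormatError(f"{path}: missing column {needed!r}")
    entries: dict[PeptideKey, frozenset[str]] = {}
    for i, row in enumerate(raw.itertuples(index=False)):
        seq = validate_sequence(getattr(row, cols["sequence"]), context=f"(row {i})")
        mod = getattr(row, cols["modification"]).strip()
        accfield = getattr(row, cols["accessions"]).strip()
        accs = frozenset(a.strip() for a in accfield.split(";") if a.strip())
        if not accs:
            raise FormatError(f"{path}: empty accession field at row {i} ({seq})")
        key = PeptideKey(seq, mod)
        if key in entries and entries[key] != accs:
            raise ConflictError(
                f"{path}: peptide {key} listed with conflicting accession sets "
                f"{sorted(entries[key])} vs {sorted(accs)}"
            )
        entries[key] = accs
    return entries


def write_peptide_map(
    entries: Mapping[PeptideKey, frozenset[str]], path: str | Path
) -> None:
    """Write a peptide -> accession-set map in the summary dialect."""
    rows = [
        {
            "sequence": k.sequence,
            "modification": k.modification,
            "accessions": ";".join(sorted(v)),
        }
        for k, v in sorted(entries.items())
    ]
    pd.DataFrame(rows, columns=["sequence", "modification", "accessions"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# sample design
# ---------------------------------------------------------------------------

def read_design(
    path: str | Path, *, aliases: Mapping[str, str] | None = None
) -> SampleDesign:
    alias = dict(DEFAULT_COHORT_ALIASES)
    if aliases:
        alias.update({k.lower(): v for k, v in aliases.items()})
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = {c.strip().lower(): c for c in raw.columns}
    for needed in ("sample_id", "cohort"):
        if needed not in cols:
            raise FormatError(f"{path}: missing column {needed!r}")
    entries = []
    for i, row in raw.iterrows():
        sid = row[cols["sample_id"]].strip()
        label = row[cols["cohort"]].strip().lower()
        if label not in alias:
            raise LabelError(
                f"{path}: unrecognised cohort label {row[cols['cohort']]!r} at row {i}"
            )
        entries.append((sid, alias[label]))
    return SampleDesign(tuple(entries))


def write_design(design: SampleDesign, path: str | Path) -> None:
    pd.DataFrame(design.entries, columns=["sample_id", "cohort"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_results(records: pd.DataFrame, path: str | Path) -> None:
    """Write a results table (differential records or splicing calls) as TSV.

    Column order is preserved; floats keep 12 significant digits so a re-read
    reproduces every numeric field to 1e-9 relative.
    """
    records.to_csv(path, sep="\t", index=False, na_rep="", float_format=FLOAT_FORMAT)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a flat YAML run configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")
    return cfg


def thresholds_from_config(cfg: Mapping) -> AnalysisThresholds:
    block = dict(cfg.get("thresholds", {}))
    try:
        return AnalysisThresholds(**block)
    except TypeError as exc:
        raise ConfigError(f"invalid thresholds block: {exc}") from exc
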