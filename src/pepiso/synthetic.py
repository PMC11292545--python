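"""Truth-bearing synthetic DIA/SWATH dataset generator.

Emulates the structure of a two-cohort sperm-proteome study: 12 vs 11
samples, ~1,400 protein families of which a minority carry 2-3 splice
isoforms, lognormal peptide areas with multiplicative per-sample loading
offsets and missing-at-random dropout, 369 planted whole-protein abundance
shifts (2-8-fold), and a handful of planted isoform-usage shifts in which
only one isoform's specific peptides move (up to ~50-fold) while the
isoform-common peptides stay essentially flat (a compensatory drift capped
at 1.2-fold).

Protein sequences are synthesised tryptic-friendly: each designed peptide is
drawn without K/R/P in its body and terminated by K or R, and proteins are
concatenations of their peptides, so a zero-missed-cleavage digest of the
emitted FASTA reproduces the emitted peptide map exactly.  Every output is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .digest import IsoformCatalog
from .errors import ConfigError
from .io_formats import (
    PeptideKey,
    SampleDesign,
    write_design,
    write_peptide_area_table,
    write_peptide_map,
)

#: residues used inside designed peptides: the 20 standard minus K, R
#: (reserved for termini) and P (would suppress the preceding cleavage).
_BODY_ALPHABET = np.array(list("ACDEFGHILMNQSTVWY"))


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the generator.

    Defaults mirror the emulated study: 12 fertile vs 11 infertile samples,
    1,400 protein families (~10% with 2-3 isoforms), 369 abundance-shifted
    families at 2-8-fold, 6 isoform-usage-shifted families at 6-50-fold,
    lognormal noise with CV 0.3 and 10% missing values.
    """

    n_a: int = 12
    n_b: int = 11
    n_families: int = 1400
    isoform_fraction: float = 0.1
    peptides_min: int = 3
    peptides_max: int = 8
    specific_peptide_rate: float = 0.3
    shared_multi_rate: float = 0.02
    n_de: int = 369
    de_fold_range: tuple[float, float] = (2.0, 8.0)
    n_splice: int = 6
    splice_fold_range: tuple[float, float] = (6.0, 50.0)
    cv: float = 0.3
    missing_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_a < 2 or self.n_b < 2:
            raise ConfigError("each cohort needs at least 2 samples")
        if self.n_de + self.n_splice > self.n_families:
            raise ConfigError("n_de + n_splice exceeds n_families")
        for rate, name in (
            (self.isoform_fraction, "isoform_fraction"),
            (self.specific_peptide_rate, "specific_peptide_rate"),
            (self.shared_multi_rate, "shared_multi_rate"),
            (self.missing_rate, "missing_rate"),
        ):
            if not (0.0 <= rate <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1]")
        for lo, hi in (self.de_fold_range, self.splice_fold_range):
            if not (1.0 <= lo <= hi):
                raise ConfigError("fold ranges must satisfy 1 <= lo <= hi")
        if not (1 <= self.peptides_min <= self.peptides_max):
            raise ConfigError("require 1 <= peptides_min <= peptides_max")
        if self.cv <= 0:
            raise ConfigError("cv must be positive")
        if self.isoform_fraction == 0.0 and (
            self.n_splice > 0 or self.specific_peptide_rate > 0.0
        ):
            raise ConfigError(
                "isoform_fraction = 0 leaves no multi-isoform families; "
                "set n_splice = 0 and specific_peptide_rate = 0"
            )


@dataclass
class _Peptide:
    sequence: str
    family: str
    accessions: set[str]
    specific_for: str | None  # isoform accession, None for common/unique


@dataclass
class _Structure:
    catalog: IsoformCatalog
    peptides: list[_Peptide]
    multi_families: list[str]


@dataclass
class SimulatedDataset:
    """In-memory bundle of everything the generator emits."""

    config: SimConfig
    catalog: IsoformCatalog
    fasta_text: str
    areas: pd.DataFrame
    pmap: dict[PeptideKey, frozenset[str]]
    design: SampleDesign
    truth: pd.DataFrame


def _random_peptide(rng: np.random.Generator, used: set[str]) -> str:
    while True:
        length = int(rng.integers(6, 13))
        body = "".join(rng.choice(_BODY_ALPHABET, size=length - 1))
        pep = body + ("K" if rng.random() < 0.5 else "R")
        if pep not in used:
            used.add(pep)
            return pep


def _build_structure(config: SimConfig, rng: np.random.Generator) -> _Structure:
    used: set[str] = set()
    families: dict[str, tuple[str, ...]] = {}
    member: dict[str, list[str]] = {}
    peptides: list[_Peptide] = []
    multi_families: list[str] = []

    for i in range(config.n_families):
        canonical = f"SP{i:05d}"
        multi = rng.random() < config.isoform_fraction
        n_pep = int(rng.integers(config.peptides_min, config.peptides_max + 1))
        if multi:
            k = 2 if rng.random() < 0.7 else 3
            accs = tuple(f"{canonical}-{j + 1}" for j in range(k))
            multi_families.append(canonical)
            n_spec = max(1, round(config.specific_peptide_rate * n_pep))
            n_common = max(1, n_pep - n_spec)
            common = [_random_peptide(rng, used) for _ in range(n_common)]
            for seq in common:
                peptides.append(_Peptide(seq, canonical, set(accs), None))
            for acc in accs:
                member[acc] = list(common)
                for _ in range(n_spec):
                    seq = _random_peptide(rng, used)
                    peptides.append(_Peptide(seq, canonical, {acc}, acc))
                    member[acc].append(seq)
        else:
            accs = (canonical,)
            member[canonical] = []
            for _ in range(n_pep):
                seq = _random_peptide(rng, used)
                peptides.append(_Peptide(seq, canonical, {canonical}, None))
                member[canonical].append(seq)
        families[canonical] = accs

    # gene-level shared peptides: duplicate a peptide into a second family
    if config.shared_multi_rate > 0 and config.n_families > 1:
        share = rng.random(len(peptides)) < config.shared_multi_rate
        fam_names = list(families)
        for idx in np.flatnonzero(share):
            pep = peptides[idx]
            recipient = fam_names[int(rng.integers(config.n_families))]
            if recipient == pep.family:
                continue
            for acc in families[recipient]:
                member[acc].append(pep.sequence)
                pep.accessions.add(acc)

    sequences = {acc: "".join(member[acc]) for acc in member}
    catalog = IsoformCatalog(families, sequences)
    return _Structure(catalog, peptides, multi_families)


def generate_catalog(config: SimConfig) -> tuple[IsoformCatalog, str]:
    """Isoform catalog plus FASTA text; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    structure = _build_structure(config, rng)
    return structure.catalog, fasta_text(structure.catalog)


def fasta_text(catalog: IsoformCatalog) -> str:
    lines: list[str] = []
    assert catalog.sequences is not None
    for acc in sorted(catalog.sequences):
        lines.append(f">{acc} synthetic")
        seq = catalog.sequences[acc]
        lines.extend(seq[i : i + 60] for i in range(0, len(seq), 60))
    return "\n".join(lines) + "\n"


def generate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate areas, peptide map, design and truth table with planted effects."""
    rng = np.random.default_rng(config.seed)
    structure = _build_structure(config, rng)
    catalog = structure.catalog
    peptides = structure.peptides
    n_pep = len(peptides)

    sample_ids = [f"F{i + 1:02d}" for i in range(config.n_a)] + [
        f"I{i + 1:02d}" for i in range(config.n_b)
    ]
    design = SampleDesign(
        tuple((s, "A") for s in sample_ids[: config.n_a])
        + tuple((s, "B") for s in sample_ids[config.n_a :])
    )

    # choose planted families: splice among multi-isoform, DE among the rest
    if config.n_splice > len(structure.multi_families):
        raise ConfigError(
            f"n_splice = {config.n_splice} exceeds the {len(structure.multi_families)} "
            "multi-isoform families generated; raise isoform_fraction or n_families"
        )
    splice_fams = sorted(
        rng.choice(structure.multi_families, size=config.n_splice, replace=False)
    ) if config.n_splice else []
    remaining = [f for f in catalog.families if f not in set(splice_fams)]
    de_fams = sorted(
        rng.choice(remaining, size=config.n_de, replace=False)
    ) if config.n_de else []

    def _signed_shift(fold_range: tuple[float, float]) -> float:
        lo, hi = np.log2(fold_range[0]), np.log2(fold_range[1])
        sign = 1.0 if rng.random() < 0.5 else -1.0
        return float(sign * rng.uniform(lo, hi))

    de_shift = {f: _signed_shift(config.de_fold_range) for f in de_fams}
    splice_plan = {
        f: (
            str(rng.choice(catalog.isoforms(f))),
            _signed_shift(config.splice_fold_range),
        )
        for f in splice_fams
    }

    # per-peptide cohort-B log2 effect
    effect = np.zeros(n_pep)
    drift_log2 = np.log2(1.1)  # compensatory drift on common peptides, < 1.2-fold
    for i, pep in enumerate(peptides):
        if pep.family in de_shift:
            effect[i] = de_shift[pep.family]
        elif pep.family in splice_plan:
            target, shift = splice_plan[pep.family]
            if pep.specific_for == target:
                effect[i] = shift
            elif pep.specific_for is None:
                effect[i] = np.sign(shift) * drift_log2

    base = rng.normal(20.0, 2.0, size=config.n_families)
    fam_index = {f: i for i, f in enumerate(catalog.families)}
    pep_base = np.array([base[fam_index[p.family]] for p in peptides])
    pep_factor = rng.normal(0.0, 1.0, size=n_pep)
    loading = rng.normal(0.0, 1.0, size=len(sample_ids))
    sigma = np.sqrt(np.log1p(config.cv**2)) / np.log(2.0)

    is_b = np.array([design.cohort_of(s) == "B" for s in sample_ids])
    log2x = (
        (pep_base + pep_factor)[:, None]
        + loading[None, :]
        + np.outer(effect, is_b.astype(float))
        + rng.normal(0.0, sigma, size=(n_pep, len(sample_ids)))
    )
    areas = np.power(2.0, log2x)
    if config.missing_rate > 0:
        areas[rng.random(areas.shape) < config.missing_rate] = np.nan

    index = pd.MultiIndex.from_arrays(
        [[p.sequence for p in peptides], [""] * n_pep],
        names=("sequence", "modification"),
    )
    area_table = pd.DataFrame(areas, index=index, columns=sample_ids)

    pmap = {
        PeptideKey(p.sequence): frozenset(p.accessions) for p in peptides
    }

    truth_rows = []
    for fam in catalog.families:
        if fam in de_shift:
            truth_rows.append((fam, "de", "", de_shift[fam]))
        elif fam in splice_plan:
            target, shift = splice_plan[fam]
            truth_rows.append((fam, "splice", target, shift))
        else:
            truth_rows.append((fam, "null", "", 0.0))
    truth = pd.DataFrame(
        truth_rows, columns=["family", "effect", "target_isoform", "log2_shift"]
    )

    return SimulatedDataset(
        config, catalog, fasta_text(catalog), area_table, pmap, design, truth
    )


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write all generator outputs as the pipeline's input dialects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "areas": out / "peptide_areas.tsv",
        "peptide_map": out / "peptide_map.tsv",
        "design": out / "design.tsv",
        "truth": out / "truth.tsv",
        "fasta": out / "proteins.fasta",
    }
    write_peptide_area_table(dataset.areas, paths["areas"])
    write_peptide_map(dataset.pmap, paths["peptide_map"])
    write_design(dataset.design, paths["design"])
    dataset.truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.8g")
    paths["fasta"].write_text(dataset.fasta_text, encoding="utf-8")
    return paths
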