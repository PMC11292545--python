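"""End-to-end orchestration: simulate/load -> classify -> compose -> normalize
-> test -> call -> report.

A run performs one composition under ``INCLUDE_SHARED`` and one normalization
pass; the whole-protein differential branch is the view of the normalized
matrix without ``SHARED_MULTI`` groups (accession-set grouping guarantees
those peptides never pool with others, so the group structure is identical
to an ``EXCLUDE_SHARED`` composition), which keeps the two branches' records
directly comparable.  Every run writes a manifest with the config hash, the
seed, per-stage counts and output paths, plus a log file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .digest import DigestParams, IsoformCatalog, build_peptide_map_from_fasta
from .differential import (
    call_isoform_discordance,
    differential_abundance,
    pca_qc,
)
from .errors import ConfigError
from .io_formats import (
    AnalysisThresholds,
    SampleDesign,
    load_config,
    read_design,
    read_distinct_peptide_summary,
    read_peptide_area_table,
    thresholds_from_config,
    write_results,
)
from .isoform_mapping import MULTI_FAMILY, compose_protein_groups
from .normalization import normalize
from .synthetic import SimConfig, generate_dataset, write_dataset

logger = logging.getLogger("pepiso")


@dataclass
class RunManifest:
    """Machine-readable record of one pipeline run."""

    version: str
    seed: int
    config_hash: str
    input_checksums: dict[str, str]
    counts: dict[str, int]
    outputs: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> RunManifest:
    """Execute the full analysis described by ``config`` into ``out_dir``.

    The config either names input files (``inputs:`` with ``areas``,
    ``design`` and one of ``peptide_map``/``fasta``) or contains a
    ``simulate:`` block of :class:`SimConfig` fields.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    try:
        thresholds = thresholds_from_config(config)
        cfg_hash = config_hash(config)
        logger.info("pepiso %s run; config hash %s; seed %d",
                    __version__, cfg_hash, thresholds.seed)

        checksums: dict[str, str] = {}
        if "simulate" in config:
            sim_cfg = SimConfig(**{**config["simulate"], "seed": thresholds.seed})
            dataset = generate_dataset(sim_cfg)
            sim_dir = out / "simulated"
            paths = write_dataset(dataset, sim_dir)
            logger.info("simulated dataset written to %s", sim_dir)
            areas, pmap, catalog, design = (
                dataset.areas,
                dataset.pmap,
                dataset.catalog,
                dataset.design,
            )
            checksums = {k: _sha256(p) for k, p in paths.items()}
        elif "inputs" in config:
            inputs = config["inputs"]
            for needed in ("areas", "design"):
                if needed not in inputs:
                    raise ConfigError(f"inputs block missing {needed!r}")
            io_cfg = config.get("io", {})
            areas = read_peptide_area_table(
                inputs["areas"], zero_as_missing=io_cfg.get("zero_as_missing", True)
            )
            design = read_design(inputs["design"], aliases=io_cfg.get("cohort_aliases"))
            if "peptide_map" in inputs:
                pmap = read_distinct_peptide_summary(inputs["peptide_map"])
                catalog = IsoformCatalog.from_accessions(
                    a for accs in pmap.values() for a in accs
                )
            elif "fasta" in inputs:
                digest_cfg = config.get("digest", {})
                catalog, pmap = build_peptide_map_from_fasta(
                    inputs["fasta"], DigestParams(**digest_cfg)
                )
            else:
                raise ConfigError("inputs block needs peptide_map or fasta")
            checksums = {
                k: _sha256(Path(v)) for k, v in inputs.items() if Path(v).is_file()
            }
        else:
            raise ConfigError("config needs a 'simulate' or an 'inputs' block")

        missing_cols = set(areas.columns) - set(design.samples)
        if missing_cols:
            logger.warning("dropping %d sample columns absent from the design",
                           len(missing_cols))
        areas = areas[design.samples]

        composed = compose_protein_groups(areas, pmap, catalog, "INCLUDE_SHARED")
        logger.info("composition: %s", composed.log)
        normalized = normalize(composed)

        # whole-protein branch: SHARED_MULTI groups excluded
        keep = normalized.meta["family"] != MULTI_FAMILY
        de_matrix = type(normalized)(
            normalized.values.loc[keep],
            normalized.meta.loc[keep],
            {g: normalized.membership[g] for g in normalized.values.index[keep]},
            normalized.sample_medians,
        )
        de_records = differential_abundance(de_matrix, design, thresholds)
        iso_records = differential_abundance(normalized, design, thresholds)
        calls = call_isoform_discordance(iso_records, catalog, thresholds)
        pca = pca_qc(de_matrix, design)

        outputs = {
            "differential_abundance": str(out / "differential_abundance.tsv"),
            "splicing_calls": str(out / "splicing_calls.tsv"),
            "pca_scores": str(out / "pca_scores.tsv"),
            "manifest": str(out / "manifest.json"),
            "log": str(log_path),
        }
        write_results(de_records, outputs["differential_abundance"])
        write_results(calls, outputs["splicing_calls"])
        pca.scores.reset_index(names="sample_id").to_csv(
            outputs["pca_scores"], sep="\t", index=False, float_format="%.12g"
        )

        n_testable = int(de_records["testable"].sum())
        n_significant = int(de_records["significant"].sum())
        verdict_counts = calls["verdict"].value_counts().to_dict() if len(calls) else {}
        counts = {
            **composed.log,
            "n_samples_A": len(design.samples_a),
            "n_samples_B": len(design.samples_b),
            "n_groups_testable": n_testable,
            "n_significant": n_significant,
            "n_families_called": len(calls),
            **{f"n_calls_{k}": int(v) for k, v in verdict_counts.items()},
        }
        logger.info("testable groups %d, significant %d, calls %s",
                    n_testable, n_significant, verdict_counts)

        manifest = RunManifest(
            version=__version__,
            seed=thresholds.seed,
            config_hash=cfg_hash,
            input_checksums=checksums,
            counts=counts,
            outputs=outputs,
        )
        Path(outputs["manifest"]).write_text(manifest.to_json() + "\n", encoding="utf-8")
        return manifest
    finally:
        logger.removeHandler(handler)
        handler.close()
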