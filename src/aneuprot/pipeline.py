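"""End-to-end study runs: config, staged analysis, and report bundle.

``run_study`` takes a :class:`StudyConfig` (from YAML or built in code),
loads or generates the study inputs, and emits TSV result tables plus a
JSON summary under the configured output directory: per-strain chromosome
profiles, duplicated/non-duplicated distribution fits, attenuation calls,
complex summaries and enrichment, the consistent-up signature with its
per-strain projection and chromosome-size correlation, and (when a
turnover timecourse is supplied) per-gene slopes with the attenuated
contrast.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import dosage_stats, complex_analysis, signatures, synthetic_data
from .io_tables import (
    GeneAnnotation,
    QuantMatrix,
    read_annotation,
    read_complex_catalog,
    read_quant_matrix,
    strain_duplicated_chromosome,
    write_quant_matrix,
)
from .peptide_quant import normalize_recenter

log = logging.getLogger("aneuprot")


class ConfigurationError(ValueError):
    """The study configuration is incomplete or inconsistent."""


class StageFailure(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class StudyConfig:
    """Paths and parameters for one analysis run.

    With ``synthetic=True`` the inputs are generated (seeded) instead of
    read from disk and the path fields may stay empty.
    """

    out_dir: str = "results"
    synthetic: bool = False
    condition: str = "YEPD"
    protein_path: str | None = None
    mrna_path: str | None = None
    annotation_path: str | None = None
    gene_sets_path: str | None = None
    catalog_path: str | None = None
    turnover_path: str | None = None
    turnover_strain: str | None = None
    duplicated: dict[str, str] = field(default_factory=dict)
    cutoff: float = 0.6
    reference: str = "fixed_expected"
    expected: float = 1.0
    bin_width: float = 0.1
    signature_method: str = "threshold"
    signature_min_log2: float = 0.0
    signature_mean_floor: float = 0.2
    recenter: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ConfigurationError("cutoff must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if self.synthetic:
            return
        for name in ("protein_path", "annotation_path", "catalog_path"):
            value = getattr(self, name)
            if value is None:
                raise ConfigurationError(f"missing required config field: {name}")
            if not Path(value).exists():
                raise ConfigurationError(f"{name} does not exist: {value}")


def _load_inputs(config: StudyConfig):
    if config.synthetic:
        study = synthetic_data.generate_study(
            condition=config.condition, seed=config.seed
        )
        return study.protein, study.mrna, study.annotation, study.catalog, study
    protein = read_quant_matrix(config.protein_path, "protein", config.condition)
    mrna = (
        read_quant_matrix(config.mrna_path, "mRNA", config.condition)
        if config.mrna_path
        else None
    )
    annotation = read_annotation(config.annotation_path, config.gene_sets_path)
    catalog = read_complex_catalog(config.catalog_path)
    return protein, mrna, annotation, catalog, None


def _duplicated_map(config: StudyConfig, matrix: QuantMatrix) -> dict[str, str]:
    if config.duplicated:
        mapping = dict(config.duplicated)
    else:
        mapping = {
            s: c
            for s, c in matrix.duplicated_chromosomes().items()
            if c is not None
        }
    missing = [s for s in matrix.strains if s not in mapping]
    if missing:
        raise ConfigurationError(
            f"strains with unknown duplicated chromosome: {missing}; "
            "name them disomeN or supply a 'duplicated' mapping"
        )
    return mapping


def _fit_to_dict(fit: dosage_stats.GaussianFit) -> dict[str, Any]:
    return {
        "n_components": fit.n_components,
        "means": list(fit.means),
        "sds": list(fit.sds),
        "amplitudes": list(fit.amplitudes),
        "r_squared": fit.r_squared,
        "skewness": fit.skewness,
        "n_values": fit.n_values,
    }


def run_study(config: StudyConfig) -> dict[str, Any]:
    """Run every stage and write the report bundle; returns the summary dict."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {
        "config": {k: v for k, v in asdict(config).items()},
        "stages": {},
    }

    def stage(name):
        def wrap(fn):
            t0 = time.monotonic()
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - report stage and abort
                summary["stages"][name] = {"status": "failed", "error": str(exc)}
                (out / "summary.json").write_text(json.dumps(summary, indent=2))
                raise StageFailure(name, exc) from exc
            dt = time.monotonic() - t0
            summary["stages"][name] = {"status": "ok", "seconds": round(dt, 3)}
            log.info("stage %s finished in %.2fs", name, dt)
            return result

        return wrap

    protein, mrna, annotation, catalog, study = stage("load")(
        lambda: _load_inputs(config)
    )
    duplicated = _duplicated_map(config, protein)

    if config.recenter:
        def do_recenter():
            recentered, factors = normalize_recenter(protein, annotation, duplicated)
            summary["recentering_factors"] = {k: round(v, 6) for k, v in factors.items()}
            return recentered

        protein = stage("recenter")(do_recenter)

    def do_profiles():
        frames = []
        chrom_rows = []
        for strain in protein.strains:
            prof, per_chrom = dosage_stats.chromosome_profile(protein, annotation, strain)
            prof.insert(0, "strain", strain)
            frames.append(prof)
            per_chrom = per_chrom.reset_index()
            per_chrom.insert(0, "strain", strain)
            chrom_rows.append(per_chrom)
        pd.concat(frames).to_csv(out / "chromosome_profiles.tsv", sep="\t", index=False)
        pd.concat(chrom_rows).to_csv(out / "chromosome_means.tsv", sep="\t", index=False)
        return sum(len(f) for f in frames)

    n_profile_rows = stage("profiles")(do_profiles)
    summary["n_profile_rows"] = n_profile_rows

    def do_fits():
        dup_values, nondup_values = [], []
        for strain in protein.strains:
            on_dup = set(annotation.genes_on(duplicated[strain]))
            col = protein.data[strain].dropna()
            dup_values.extend(col[col.index.isin(on_dup)])
            nondup_values.extend(col[~col.index.isin(on_dup)])
        fits = {
            "duplicated_protein_2c": _fit_to_dict(
                dosage_stats.fit_gaussian(dup_values, 2, config.bin_width)
            ),
            "duplicated_protein_1c": _fit_to_dict(
                dosage_stats.fit_gaussian(dup_values, 1, config.bin_width)
            ),
            "non_duplicated_protein_1c": _fit_to_dict(
                dosage_stats.fit_gaussian(nondup_values, 1, config.bin_width)
            ),
        }
        comparison = dosage_stats.compare_models(dup_values, config.bin_width)
        fits["model_comparison"] = {
            "preferred": comparison["preferred"],
            "delta_r2": comparison["delta_r2"],
        }
        if mrna is not None:
            dup_mrna = []
            for strain in (s for s in mrna.strains if s in duplicated):
                on_dup = set(annotation.genes_on(duplicated[strain]))
                col = mrna.data[strain].dropna()
                dup_mrna.extend(col[col.index.isin(on_dup)])
            fits["duplicated_mrna_1c"] = _fit_to_dict(
                dosage_stats.fit_gaussian(dup_mrna, 1, config.bin_width)
            )
        (out / "distribution_fits.json").write_text(json.dumps(fits, indent=2))
        return fits

    summary["distribution_fits"] = stage("distribution_fits")(do_fits)

    def do_calls():
        calls = dosage_stats.call_attenuated(
            protein,
            annotation,
            cutoff=config.cutoff,
            reference=config.reference,
            expected=config.expected,
            duplicated=duplicated,
        )
        calls.calls.to_csv(out / "attenuation_calls.tsv", sep="\t", index=False)
        return calls

    calls = stage("attenuation")(do_calls)
    summary["n_attenuation_rows"] = int(len(calls.calls))
    summary["n_attenuated_genes"] = len(calls.attenuated_genes())

    def do_complexes():
        summaries = complex_analysis.summarize_complexes(
            catalog, {config.condition: calls}, min_subunits=3
        )
        rows = [
            {
                "complex": s.complex_id,
                "n_subunits": s.n_subunits[config.condition],
                "mean": s.means[config.condition],
                "attenuated_complex": s.attenuated_complex,
                "n_attenuated_subunits": len(s.attenuated_subunits),
                "n_stable_subunits": len(s.stable_subunits),
            }
            for s in summaries
        ]
        frame = pd.DataFrame(rows)
        frame.to_csv(out / "complex_summaries.tsv", sep="\t", index=False)
        background = calls.measured_genes()
        members = catalog.members() & background
        enr = complex_analysis.enrichment_test(
            calls.attenuated_genes(), members, background
        )
        enrichment = {
            "k": enr.k, "n": enr.n, "K": enr.K, "N": enr.N, "p_value": enr.p_value,
        }
        (out / "enrichment.json").write_text(json.dumps(enrichment, indent=2))
        return frame, enrichment

    complex_frame, enrichment = stage("complexes")(do_complexes)
    summary["n_complexes"] = int(len(complex_frame))
    summary["n_attenuated_complexes"] = (
        int(complex_frame["attenuated_complex"].sum()) if len(complex_frame) else 0
    )
    summary["enrichment"] = enrichment

    def do_signature():
        weights = signatures.WeightTable.downweight_duplicated(
            protein, annotation, duplicated
        )
        sig = signatures.extract_consistent_up_signature(
            protein,
            weights,
            min_log2=config.signature_min_log2,
            mean_floor=config.signature_mean_floor,
            method=config.signature_method,
        )
        pd.DataFrame({"gene": sig.genes}).to_csv(
            out / "signature_genes.tsv", sep="\t", index=False
        )
        projection = pd.DataFrame(
            {"intensity": sig.intensity, "sem": sig.sem}
        )
        projection.index.name = "strain"
        projection.to_csv(out / "signature_projection.tsv", sep="\t")
        sizes = annotation.chromosome_sizes()
        strain_sizes = {s: sizes[c] for s, c in duplicated.items() if c in sizes}
        result: dict[str, Any] = {"n_genes": len(sig.genes)}
        if len(sig.genes) >= 1 and len(strain_sizes) >= 3:
            corr = signatures.intensity_size_correlation(sig, strain_sizes)
            result["size_correlation"] = corr
        for set_name in ("esr_up", "esr_down"):
            members = annotation.gene_sets.get(set_name, set())
            members = [g for g in members if g in protein.data.index]
            if members:
                proj = signatures.signature_projection(protein, members, set_name)
                frame = pd.DataFrame(
                    {"intensity": proj.intensity, "sem": proj.sem}
                )
                frame.index.name = "strain"
                frame.to_csv(out / f"{set_name}_projection.tsv", sep="\t")
        return sig, result

    sig, sig_result = stage("signature")(do_signature)
    summary["signature"] = sig_result

    if config.turnover_path or (config.synthetic and study is not None):
        def do_turnover():
            strain = config.turnover_strain
            if config.turnover_path:
                timecourse = read_quant_matrix(
                    config.turnover_path, "protein", "turnover"
                )
            else:
                strain = strain or next(iter(study.truths))
                truth = study.truths[strain]
                slopes_truth = synthetic_data.default_turnover_slopes(
                    study.genome, truth
                )
                timecourse = synthetic_data.generate_turnover_truth(
                    study.genome, truth, slopes_truth, seed=config.seed
                )
            slopes = signatures.fit_turnover_slope(timecourse)
            slopes.rename("slope").to_csv(out / "turnover_slopes.tsv", sep="\t")
            per_chrom = signatures.turnover_chromosome_means(slopes, annotation)
            per_chrom.rename("mean_slope").to_csv(
                out / "turnover_chromosome_means.tsv", sep="\t"
            )
            result: dict[str, Any] = {"n_genes": int(slopes.notna().sum())}
            # attenuated-vs-not contrast only makes sense within the
            # timecourse strain's own duplicated chromosome
            if strain is not None and strain in duplicated:
                dup_genes = set(annotation.genes_on(duplicated[strain]))
                contrast = signatures.turnover_group_contrast(
                    slopes, calls.attenuated_genes(), dup_genes
                )
                result["strain"] = strain
                result["contrast"] = contrast
            return result

        summary["turnover"] = stage("turnover")(do_turnover)

    if study is not None:
        write_quant_matrix(protein, out / "protein_recentered.tsv")

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary
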