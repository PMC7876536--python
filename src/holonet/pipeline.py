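"""Config-driven orchestration of the full transkingdom analysis.

Stages: preprocess -> [latent-effect correction] -> network inference per
kingdom -> trait encoding -> integrated heatmap -> [enrichment].  Every
stage consumes and produces files, a manifest records input hashes, the
parameters and the seed, and a rerun with an identical config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import data_io, enrichment, integrate, large_effects, preprocess, synthgen, traits
from .network import NetworkParams, infer_network

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    host_counts: str
    microbe_counts: str
    samples: str
    out_dir: str
    seed: int = 0
    annotation: str | None = None
    # preprocess
    tmm_trim_M: float = 0.30
    tmm_trim_A: float = 0.05
    tmm_pseudocount: float = 0.5
    css_quantile: float = 0.5
    gene_min_expr: float = 1.0
    gene_min_sd: float = 0.15
    otu_min_total_fraction: float = 0.00005
    outlier_height_mad_k: float = 5.0
    apply_outlier_removal: bool = False
    drop_samples: tuple = ()
    # latent-effect correction
    correction: bool = False
    correction_B: int = 100
    correction_alpha: float = 0.05
    # networks (merge cut: 0.5 host / 0.4 microbe)
    host_network: NetworkParams = field(default_factory=lambda: NetworkParams(merge_cut_height=0.5))
    microbe_network: NetworkParams = field(default_factory=lambda: NetworkParams(merge_cut_height=0.4))
    # integration
    row_rule: str = "significant_both"
    make_figure: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("host_network", "microbe_network"):
            if key in raw and isinstance(raw[key], dict):
                params = dict(raw[key])
                if "candidate_powers" in params:
                    params["candidate_powers"] = tuple(params["candidate_powers"])
                raw[key] = NetworkParams(**params)
        if "drop_samples" in raw:
            raw["drop_samples"] = tuple(raw["drop_samples"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        # paths depend on where the run happens; the manifest records input
        # hashes instead, and excluding them keeps reruns byte-identical
        for key in ("out_dir", "host_counts", "microbe_counts", "samples", "annotation"):
            d.pop(key, None)
        return d


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []
    manifest: dict = {
        "seed": config.seed,
        "config": _jsonable(config.to_dict()),
        "inputs": {},
        "stages": stages,
    }
    for name in ("host_counts", "microbe_counts", "samples", "annotation"):
        path = getattr(config, name)
        if path:
            manifest["inputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    current = "start"
    try:
        # ---------------- preprocess ----------------
        current = "preprocess"
        host_raw = data_io.read_omics_table(config.host_counts, "host")
        microbe_raw = data_io.read_omics_table(config.microbe_counts, "microbe")
        samples = data_io.read_sample_table(config.samples)

        def drop(matrix, to_drop):
            keep = [s for s in matrix.sample_ids if s not in to_drop]
            return matrix.subset_samples(keep)

        if config.drop_samples:
            host_raw = drop(host_raw, set(config.drop_samples))
            microbe_raw = drop(microbe_raw, set(config.drop_samples))

        host_outliers = preprocess.detect_outlier_samples(host_raw, config.outlier_height_mad_k)
        microbe_outliers = preprocess.detect_outlier_samples(microbe_raw, config.outlier_height_mad_k)
        if config.apply_outlier_removal:
            host_raw = drop(host_raw, set(host_outliers))
            microbe_raw = drop(microbe_raw, set(microbe_outliers))

        tmm = preprocess.tmm_normalize(
            host_raw, config.tmm_trim_M, config.tmm_trim_A, config.tmm_pseudocount
        )
        host_norm, gene_report = preprocess.filter_genes(
            tmm.matrix, config.gene_min_expr, config.gene_min_sd
        )
        microbe_filtered, otu_report = preprocess.filter_otus(
            microbe_raw, config.otu_min_total_fraction
        )
        css = preprocess.css_normalize(microbe_filtered, config.css_quantile)
        microbe_norm = css.matrix

        data_io.write_omics_table(host_norm, out / "host_normalized.tsv")
        data_io.write_omics_table(microbe_norm, out / "microbe_normalized.tsv")
        _write_filter_report(gene_report, out / "host_filter_report.tsv")
        _write_filter_report(otu_report, out / "microbe_filter_report.tsv")
        (out / "outlier_flags.json").write_text(
            json.dumps({"host": host_outliers, "microbe": microbe_outliers}, indent=2, sort_keys=True)
        )
        stages.append("preprocess")

        # ---------------- optional correction ----------------
        if config.correction:
            current = "correct"
            corrected = {}
            spectra = {}
            for name, mat in (("host", host_norm), ("microbe", microbe_norm)):
                est = large_effects.estimate_num_sv(
                    mat, B=config.correction_B, alpha=config.correction_alpha, seed=config.seed
                )
                corrected[name] = large_effects.remove_latent_pcs(mat, est.n_sv)
                spectra[name] = {
                    "n_sv": est.n_sv,
                    "spectrum": [float(v) for v in est.spectrum[:10]],
                    "null_quantiles": [float(v) for v in est.null_quantiles[:10]],
                }
            host_net_input, microbe_net_input = corrected["host"], corrected["microbe"]
            data_io.write_omics_table(host_net_input, out / "host_corrected.tsv")
            data_io.write_omics_table(microbe_net_input, out / "microbe_corrected.tsv")
            (out / "latent_spectra.json").write_text(json.dumps(spectra, indent=2, sort_keys=True))
            stages.append("correct")
        else:
            host_net_input, microbe_net_input = host_norm, microbe_norm

        # ---------------- networks ----------------
        results = {}
        for name, mat, params in (
            ("host", host_net_input, config.host_network),
            ("microbe", microbe_net_input, config.microbe_network),
        ):
            current = f"network_{name}"
            res = infer_network(mat, params)
            results[name] = res
            data_io.write_module_assignments(
                res.partition, res.kme, res.connectivity, out / f"{name}_modules.tsv"
            )
            res.eigennodes.values.to_csv(
                out / f"{name}_eigennodes.tsv", sep="\t", float_format="%.17g", index_label="module"
            )
            res.fit_table.to_csv(out / f"{name}_soft_threshold.tsv", sep="\t",
                                 float_format="%.17g", index=False)
            stages.append(f"network_{name}")

        # ---------------- traits ----------------
        current = "traits"
        samples_used = samples.subset(
            [s for s in samples.sample_ids if s in host_net_input.values.columns]
        )
        trait_matrix = traits.encode_traits(samples_used)
        trait_matrix.to_csv(out / "traits.tsv", sep="\t", float_format="%.17g", index_label="group_id")
        stages.append("traits")

        # ---------------- integrated heatmap ----------------
        current = "ihahi"
        # eigennodes from both kingdoms restricted to samples shared with the
        # metadata table (kingdom sample sets may differ after outlier removal)
        ih = integrate.build_ihahi(
            results["host"].eigennodes,
            results["microbe"].eigennodes,
            trait_matrix,
            samples_used,
            row_rule=config.row_rule,
        )
        integrate.export_ihahi(ih, out / "ihahi")
        if config.make_figure:
            integrate.plot_ihahi(ih, out / "ihahi.png")
        stages.append("ihahi")

        # ---------------- enrichment ----------------
        if config.annotation:
            current = "enrichment"
            annot = data_io.read_annotation(config.annotation)
            universe = results["host"].partition.labels.index
            tables = []
            for lab in results["host"].partition.module_labels:
                module = results["host"].partition.members(lab)
                table = enrichment.hypergeometric_enrichment(module, annot, universe)
                table.insert(0, "module", lab)
                tables.append(table)
            if tables:
                import pandas as pd

                pd.concat(tables, ignore_index=True).to_csv(
                    out / "enrichment.tsv", sep="\t", float_format="%.17g", index=False
                )
            else:
                (out / "enrichment.tsv").write_text(
                    "module\tterm_id\tdescription\toverlap\tmodule_size\tterm_size\tuniverse_size\tp\n"
                )
            stages.append("enrichment")
    except Exception as exc:
        (out / "failed").write_text(f"stage: {current}\ncause: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {current!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _write_filter_report(report: preprocess.FilterReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tstatus\trule\n")
        for fid in report.kept_ids:
            fh.write(f"{fid}\tkept\t\n")
        for fid in report.removed_ids:
            fh.write(f"{fid}\tremoved\t{report.rule_fired[fid]}\n")


def simulate_to_dir(config: synthgen.SynthConfig, out_dir) -> Path:
    """Write a synthetic dataset (host.tsv, microbe.tsv, samples.tsv,
    truth.json) to a directory; the file set feeds ``run_pipeline``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    host, microbe, samples, truth = synthgen.generate(config)
    data_io.write_omics_table(host, out / "host.tsv")
    data_io.write_omics_table(microbe, out / "microbe.tsv")
    data_io.write_sample_table(samples, out / "samples.tsv")
    (out / "truth.json").write_text(
        json.dumps(
            {
                "host_labels": {k: int(v) for k, v in truth.host_labels.items()},
                "microbe_labels": {k: int(v) for k, v in truth.microbe_labels.items()},
                "realized_couplings": truth.realized_couplings,
            },
            indent=2,
            sort_keys=True,
        )
    )
    return out
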