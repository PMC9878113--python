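"""End-to-end orchestration: simulate/ingest -> preprocess -> differential
expression -> qPCR validation -> network integration -> biomarker panels.

A single YAML (or dict) configuration drives the run; every stage writes
its TSV outputs into the output directory and the run manifest records the
seed, thresholds, per-stage row counts and SHA-256 hashes of every output,
so identical config + seed reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import diffexpr, io, network, preprocess, qpcr, simulate
from .io import FIXTURE_FILES, load_fixture_table

log = logging.getLogger("tgamir")

EXPECTED_FIXTURE_COUNTS = {"T2A": 39, "T2B": 51, "T2C": 101, "T3A": 36, "T3B": 164}

DEFAULT_THRESHOLDS = {
    "alpha": 0.05,
    "fc": 1.5,
    "rho": 0.5,
    "ct_gate": 35.0,
    "detection_rate": 0.5,
    "detection_mode": "any_group",
}


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    simulation: dict[str, Any] = field(default_factory=dict)
    thresholds: dict[str, Any] = field(default_factory=dict)
    contrast: tuple[str, str] = ("TGA_RV", "control")
    qpcr_assays: int = 10  # top-|log2FC| DE miRNAs carried into qPCR emulation

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "contrast" in raw:
            raw["contrast"] = tuple(raw["contrast"])
        return cls(**raw)

    def resolved_thresholds(self) -> dict[str, Any]:
        out = dict(DEFAULT_THRESHOLDS)
        out.update(self.thresholds)
        return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the full synthetic-cohort pipeline; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thr = config.resolved_thresholds()
    manifest: dict[str, Any] = {
        "seed": config.seed,
        "thresholds": thr,
        "contrast": list(config.contrast),
        "stages": {},
        "outputs": {},
    }

    # --- simulate -----------------------------------------------------------
    sim_cfg = simulate.SimulationConfig(seed=config.seed, **config.simulation)
    bundle = simulate.generate_bundle(sim_cfg)
    io.write_expression_matrix(bundle.mirna, outdir / "mirna_raw.tsv")
    io.write_expression_matrix(bundle.mrna, outdir / "mrna_raw.tsv")
    io.write_metadata(bundle.metadata, outdir / "metadata.tsv")
    io.write_binding_sites(bundle.sites, outdir / "binding_sites.tsv")
    pd.DataFrame(
        sorted(bundle.truth.regulatory_pairs), columns=["mirna_id", "mrna_id", "planted_rho"]
    ).to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    manifest["stages"]["simulate"] = {
        "n_mirna": bundle.mirna.shape[0],
        "n_mrna": bundle.mrna.shape[0],
        "n_samples": bundle.mirna.shape[1],
        "n_sites": len(bundle.sites),
    }
    log.info("simulate: %s", manifest["stages"]["simulate"])

    # --- preprocess ---------------------------------------------------------
    norm = {}
    for name, mat in (("mirna", bundle.mirna), ("mrna", bundle.mrna)):
        filtered, report = preprocess.detection_filter(
            mat, bundle.metadata, min_rate=thr["detection_rate"], mode=thr["detection_mode"]
        )
        qn = preprocess.quantile_normalize(filtered)
        logm = preprocess.log2_transform(qn)
        norm[name] = logm
        io.write_expression_matrix(logm, outdir / f"{name}_norm_log2.tsv")
        manifest["stages"][f"preprocess_{name}"] = {
            "kept": len(report.kept_features),
            "dropped": len(report.dropped_features),
        }
        log.info("preprocess %s: %s", name, manifest["stages"][f"preprocess_{name}"])

    # --- differential expression -------------------------------------------
    groups = bundle.metadata.set_index("sample_id")["group"]
    de = {}
    for name in ("mirna", "mrna"):
        mat = norm[name]
        ga = [s for s in mat.sample_ids if groups[s] == config.contrast[0]]
        gb = [s for s in mat.sample_ids if groups[s] == config.contrast[1]]
        records = diffexpr.call_differential(
            mat, ga, gb, fc_threshold=thr["fc"], alpha=thr["alpha"]
        )
        de[name] = records
        frame = diffexpr.records_to_frame(records)
        frame.to_csv(outdir / f"de_{name}.tsv", sep="\t", index=False)
        diffexpr.export_volcano(records).to_csv(
            outdir / f"volcano_{name}.tsv", sep="\t", index=False
        )
        n_called = int((frame["direction"] != diffexpr.NOT_SIGNIFICANT).sum())
        manifest["stages"][f"de_{name}"] = {"tested": len(records), "called": n_called}
        log.info("de %s: %s", name, manifest["stages"][f"de_{name}"])

    # --- qPCR validation ----------------------------------------------------
    called = [r for r in de["mirna"] if r.direction != diffexpr.NOT_SIGNIFICANT]
    called.sort(key=lambda r: -abs(r.log2fc))
    assays = [r.feature_id for r in called[: config.qpcr_assays]]
    if assays:
        ct = simulate.generate_ct_table(
            bundle, assays, ct_noise_sd=0.25, censor_fraction=0.02
        )
        dct = qpcr.compute_delta_ct(ct, gate=thr["ct_gate"])
        ga = [s for s in bundle.mirna.sample_ids if groups[s] == config.contrast[0]]
        gb = [s for s in bundle.mirna.sample_ids if groups[s] == config.contrast[1]]
        results = qpcr.compare_groups_dct(dct, ga, gb, alpha=thr["alpha"])
        results = qpcr.concordance_with_array(results, de["mirna"], alpha=thr["alpha"])
        qframe = qpcr.results_to_frame(results)
        qframe.to_csv(outdir / "qpcr_results.tsv", sep="\t", index=False)
        manifest["stages"]["qpcr"] = {
            "assays": len(assays),
            "significant_same_direction": int(
                (qframe["concordance"] == qpcr.SIGNIFICANT_SAME).sum()
            ),
        }
        log.info("qpcr: %s", manifest["stages"]["qpcr"])

    # --- integration network -----------------------------------------------
    edges, summary = network.build_network(
        norm["mirna"],
        norm["mrna"],
        de["mirna"],
        de["mrna"],
        bundle.sites,
        rho_threshold=thr["rho"],
        alpha=thr["alpha"],
    )
    io.write_network(edges, outdir / "network_edges.tsv")
    io.write_network_graphml(edges, outdir / "network.graphml")
    manifest["stages"]["network"] = asdict(summary)
    log.info("network: %s", manifest["stages"]["network"])

    # --- hashes -------------------------------------------------------------
    for p in sorted(outdir.glob("*.tsv")):
        manifest["outputs"][p.name] = _sha256(p)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def verify_fixtures(
    alpha: float = 0.05, fc_high: float = 1.5, fc_low: float = 0.67
) -> dict[str, dict[str, Any]]:
    """Re-check the packaged printed DE tables against their screening rule.

    For each table, counts the rows passing adjusted P < alpha and fold
    change >= fc_high or <= fc_low (printed 2-decimal precision) and
    compares with the published row count.
    """
    report = {}
    for name in FIXTURE_FILES:
        table = load_fixture_table(name)
        count = diffexpr.count_passing(table, alpha=alpha, fc_high=fc_high, fc_low=fc_low)
        expected = EXPECTED_FIXTURE_COUNTS[name]
        report[name] = {
            "rows": len(table),
            "passing": count,
            "expected": expected,
            "ok": count == expected and len(table) == expected,
        }
    return report
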