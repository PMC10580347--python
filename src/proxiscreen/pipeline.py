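"""End-to-end screen -> rank -> annotate -> report orchestration.

The pipeline composes the independently invokable stages: the network
proximity screen ranks drugs, then optional per-drug annotations are joined
on (binding-energy aggregation, rule-of-five evaluation, count of targets
that pass the differential-expression screen).  Output is a ranked
candidate TSV plus a JSON run manifest (seed, sample counts, input digests)
so a run is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import energy as energy_mod
from . import filters as filters_mod
from .expression import load_expression, screen_expression
from .network import load_gene_set, load_network
from .proximity import load_drug_targets, results_to_frame, screen_drugs

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_screen_pipeline"]


@dataclass
class RunConfig:
    """Paths, thresholds, and sampling parameters of one pipeline run."""

    network: Path
    disease_genes: Path
    drug_targets: Path
    out_dir: Path
    energy_components: Optional[Path] = None
    descriptors: Optional[Path] = None
    expression_matrix: Optional[Path] = None
    expression_groups: Optional[Path] = None
    n_samples: int = 1000
    seed: int = 0
    alpha: float = 0.05
    d_min: float = 0.8
    fel_bins: int = 50
    temperature: float = 310.0

    def __post_init__(self) -> None:
        for name in ("alpha", "d_min", "temperature"):
            v = getattr(self, name)
            if not (v == v and abs(v) != float("inf")):
                raise ValueError(f"threshold {name} must be finite")

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        path_fields = {"network", "disease_genes", "drug_targets", "out_dir",
                       "energy_components", "descriptors",
                       "expression_matrix", "expression_groups"}
        kwargs = {k: (Path(v) if k in path_fields and v is not None else v)
                  for k, v in raw.items()}
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _join_annotation(report: pd.DataFrame, ann: pd.DataFrame, key: str,
                     label: str) -> pd.DataFrame:
    ann = ann.rename(columns={key: "drug_id"})
    matched = report["drug_id"].isin(ann["drug_id"]).sum()
    if matched < len(report):
        logger.warning("%s annotation: %d/%d drugs matched by id",
                       label, matched, len(report))
    return report.merge(ann, on="drug_id", how="left")


def run_screen_pipeline(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Execute the full screen and write ``candidates.tsv`` + ``manifest.json``.

    Returns the ranked candidate table and the manifest.  Raises
    ``ValueError`` if the final table would be empty.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    net = load_network(config.network)
    disease = load_gene_set(config.disease_genes)
    drugs = load_drug_targets(config.drug_targets)
    results, unscorable = screen_drugs(net, disease, drugs,
                                       n_samples=config.n_samples, seed=config.seed)
    report = results_to_frame(results)
    if config.n_samples == 0:
        report = report.drop(columns=["ref_mean", "ref_sd", "z"])

    counts = {
        "network_nodes": net.n_nodes,
        "network_edges": net.n_edges,
        "disease_genes": len(disease),
        "disease_genes_in_network": len(disease.intersect_network(net)),
        "drugs_total": len(drugs),
        "drugs_scored": len(results),
        "drugs_unscorable": len(unscorable),
        "drugs_selected": int(report["selected"].sum()),
    }

    if config.energy_components is not None:
        ann = energy_mod.aggregate_table(config.energy_components)
        report = _join_annotation(report, ann, "complex_id", "energy")
        counts["energy_rows"] = len(ann)
    if config.descriptors is not None:
        ann = filters_mod.ro5_table(config.descriptors)
        report = _join_annotation(report, ann, "compound_id", "descriptor")
        counts["descriptor_rows"] = len(ann)
    if config.expression_matrix is not None and config.expression_groups is not None:
        mat = load_expression(config.expression_matrix, config.expression_groups)
        expr = screen_expression(mat, alpha=config.alpha, d_min=config.d_min)
        de_genes = set(expr.loc[expr["selected"], "gene"])
        by_drug = {d.drug_id: len(d.targets & de_genes) for d in drugs}
        report["n_targets_de"] = report["drug_id"].map(by_drug)
        counts["expression_genes_tested"] = len(expr)
        counts["expression_genes_selected"] = len(de_genes)

    if report.empty:
        raise ValueError("pipeline produced an empty candidate table")

    inputs = {"network": config.network, "disease_genes": config.disease_genes,
              "drug_targets": config.drug_targets,
              "energy_components": config.energy_components,
              "descriptors": config.descriptors,
              "expression_matrix": config.expression_matrix,
              "expression_groups": config.expression_groups}
    manifest = {
        "seed": config.seed,
        "n_samples": config.n_samples,
        "thresholds": {"selection": "distance < 0", "alpha": config.alpha,
                       "d_min": config.d_min},
        "counts": counts,
        "unscorable_drugs": unscorable,
        "input_digests": {k: _sha256(v) for k, v in inputs.items() if v is not None},
    }
    report.to_csv(out_dir / "candidates.tsv", sep="\t", index=False)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline wrote %d candidates to %s", len(report), out_dir)
    return report, manifest
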