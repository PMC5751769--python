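"""End-to-end pipeline: integrate -> reference network -> refine -> validate.

The pipeline is driven by a declarative JSON config.  Either real inputs
are named::

    {
      "methods": {"resnik": {"cc": "...", "mf": "...", "bp": "..."}, ...},
      "ppi": ["hprd.tsv", "biogrid.tsv"],
      "predicted_complexes": "pred.tsv",
      "reference_complexes": "ref.tsv"
    }

or a ``"simulate"`` section gives a fixture spec and all inputs are
generated in-process.  Stage outputs are written as they complete, each
readable by the next stage's reader, and a run manifest with content
digests makes reruns auditable.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import logging
import sys
from pathlib import Path
from typing import Any

from . import __version__, netio
from .complex_eval import evaluate
from .core import OntologyTriple, SimilarityMatrix
from .fixtures import FixtureSpec, make_method_matrices, make_planted_complexes, make_ppi
from .nettopo import best_fit, degree_histogram, topology_summary
from .refine import RefineConfig, refine
from .rgan import RganConfig, build_rgan, ecc_weights, integrate_ppi
from .sim_integrate import build_igfsn

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name for error reporting."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: dict, out_dir: str | Path, *, seed: int | None = None) -> dict:
    """Execute the full pipeline; returns a summary dict of artifact paths.

    Re-running with identical inputs and seed reproduces byte-identical
    artifacts (the manifest's timestamp fields aside).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    input_digests: dict[str, str] = {}

    rgan_cfg = RganConfig(
        alpha_path=float(config.get("alpha", 0.5)),
        normalize=config.get("normalize", "max"),
    )
    refine_cfg = RefineConfig(
        tolerance=float(config.get("tolerance", 0.1)),
        reconnect=bool(config.get("reconnect", True)),
    )
    threshold = float(config.get("match_threshold", 0.25))

    # -- stage: inputs -----------------------------------------------------
    stage = "inputs"
    try:
        if "simulate" in config:
            sim_cfg = dict(config["simulate"])
            if seed is not None:
                sim_cfg["seed"] = seed
            spec = FixtureSpec(**sim_cfg)
            ppi_nets = [make_ppi(spec)]
            triples = make_method_matrices(spec, ppi_nets[0], int(config.get("n_methods", 6)))
            reference, predicted = make_planted_complexes(
                spec,
                n_complexes=int(config.get("n_complexes", 10)),
                overlap=float(config.get("complex_overlap", 0.8)),
                complex_size=int(config.get("complex_size", 10)),
            )
        else:
            triples = []
            for name, files in config["methods"].items():
                mats = {o: netio.read_similarity_matrix(files[o]) for o in ("cc", "mf", "bp")}
                for o in ("cc", "mf", "bp"):
                    input_digests[f"method:{name}:{o}"] = _digest(Path(files[o]))
                triples.append(OntologyTriple(**mats))
            ppi_nets = []
            for p in config["ppi"]:
                ppi_nets.append(netio.read_edge_list(p, has_weights=False))
                input_digests[f"ppi:{p}"] = _digest(Path(p))
            predicted = reference = None
            if config.get("predicted_complexes") and config.get("reference_complexes"):
                predicted = netio.read_complexes(config["predicted_complexes"])
                reference = netio.read_complexes(config["reference_complexes"])
                for key in ("predicted_complexes", "reference_complexes"):
                    input_digests[key] = _digest(Path(config[key]))
        if not triples:
            raise ValueError("no similarity method inputs")
    except (OSError, KeyError, ValueError) as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- stage: integrate --------------------------------------------------
    stage = "integrate"
    try:
        igfsn = build_igfsn(triples)
        netio.write_similarity_matrix(igfsn, out / "igfsn.tsv")
        artifacts["igfsn"] = str(out / "igfsn.tsv")
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- stage: build-rgan -------------------------------------------------
    stage = "build-rgan"
    try:
        universe = set(igfsn.genes)
        integrated = integrate_ppi(ppi_nets, universe)
        weighted = ecc_weights(integrated)
        rgan_full = build_rgan(weighted, rgan_cfg)
        rgan = _align(rgan_full, igfsn.genes)
        netio.write_similarity_matrix(rgan, out / "rgan.tsv")
        artifacts["rgan"] = str(out / "rgan.tsv")
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- stage: refine -----------------------------------------------------
    stage = "refine"
    try:
        rgfsn, report = refine(igfsn, rgan, refine_cfg)
        netio.write_similarity_matrix(rgfsn, out / "rgfsn.tsv")
        _write_json(report.to_dict(), out / "refine_report.json")
        artifacts["rgfsn"] = str(out / "rgfsn.tsv")
        artifacts["refine_report"] = str(out / "refine_report.json")
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc

    # -- stage: validate ---------------------------------------------------
    stage = "validate"
    try:
        graph = rgfsn.to_graph()
        summary = topology_summary(graph)
        _write_json(summary.to_dict(), out / "topology.json")
        hist = degree_histogram(graph)
        fits = [f.to_dict() for f in best_fit(hist)]
        _write_json(fits, out / "degree_fits.json")
        artifacts["topology"] = str(out / "topology.json")
        artifacts["degree_fits"] = str(out / "degree_fits.json")
        if predicted is not None and reference is not None:
            result = evaluate(predicted, reference, threshold)
            _write_json(result.to_dict(), out / "complex_eval.json")
            artifacts["complex_eval"] = str(out / "complex_eval.json")
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc

    manifest = {
        "command_line": sys.argv,
        "config": config,
        "seed": seed,
        "version": __version__,
        "input_digests": input_digests,
        "artifact_digests": {k: _digest(Path(v)) for k, v in sorted(artifacts.items())},
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    _write_json(manifest, out / "manifest.json")
    artifacts["manifest"] = str(out / "manifest.json")
    return artifacts


def _align(sim: SimilarityMatrix, genes: list[str]) -> SimilarityMatrix:
    """Reindex a similarity matrix onto a target gene ordering.

    Genes absent from ``sim`` get zero rows (diagonal 1).
    """
    import numpy as np

    idx = {g: i for i, g in enumerate(sim.genes)}
    vals = np.zeros((len(genes), len(genes)))
    present = [(j, idx[g]) for j, g in enumerate(genes) if g in idx]
    if present:
        tgt, src = map(np.array, zip(*present))
        vals[np.ix_(tgt, tgt)] = sim.values[np.ix_(src, src)]
    return SimilarityMatrix(genes, vals, validate=False)
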