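"""End-to-end pipeline: inputs -> networks -> statistics -> report files.

``run_pipeline`` wires the package together behind a single declarative
config (a YAML/JSON file or an equivalent dict):

.. code-block:: yaml

    inputs:                  # EITHER real matrices ...
      format: wide
      files: {LBA: lba.tsv, TSA50: tsa50.tsv, TSA10: tsa10.tsv}
      metadata: strains.tsv  # optional strain -> phylum table
    simulate:                # ... OR a generator block
      n_species: 21
      seed: 7
    fixture: {seed: 7}       # ... OR the pinned study-scale fixture
    analyses: [metrics, hierarchy, conservation, nulls]
    hierarchy: {k: 4, levels: tertile}
    nulls:
      seed: 17
      tests:
        - {statistic: top_k_share, family: erdos, n_perm: 199, k: 4}
    out_dir: results/run1

Outputs: ``report.json`` (the full machine-readable report), per-strain
``hierarchy.tsv``, ``venn.tsv``, and Cytoscape-ready ``network.sif`` /
``network.graphml``. Every number in the report is recomputable from the
inputs and config; on any stage failure the partially written outputs are
removed and the error re-raised with its stage name.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from importlib import metadata as _im
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import conservation as conservation_mod
from . import hierarchy as hierarchy_mod
from . import matrix_io, metrics, null_models, synthetic
from .errors import ConfigurationError, InhibnetError

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"
DEFAULT_ANALYSES = ("metrics", "hierarchy", "conservation")

try:
    __version__ = _im.version("inhibnet")
except _im.PackageNotFoundError:  # pragma: no cover
    __version__ = "unknown"


@dataclass(frozen=True)
class AnalysisReport:
    provenance: dict
    stats: dict
    hierarchy: dict | None
    conservation: dict | None
    null_tests: list[dict]

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "provenance": self.provenance,
            "stats": self.stats,
            "hierarchy": self.hierarchy,
            "conservation": self.conservation,
            "null_tests": self.null_tests,
        }

    def to_json(self, **kwargs: Any) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2, **kwargs)


def _config_hash(config: Mapping) -> str:
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:16]


def load_config(source: str | Path | Mapping) -> dict:
    if isinstance(source, Mapping):
        return dict(source)
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return loaded


def _resolve_tensor(config: Mapping) -> tuple[matrix_io.InhibitionTensor, dict]:
    sources = [k for k in ("inputs", "simulate", "fixture") if k in config]
    if len(sources) != 1:
        raise ConfigurationError(
            "config must name exactly one of 'inputs', 'simulate', 'fixture'"
        )
    source = sources[0]
    if source == "inputs":
        block = dict(config["inputs"])
        files = {str(c): str(p) for c, p in block["files"].items()}
        for path in files.values():
            if not Path(path).exists():
                raise FileNotFoundError(f"input file not found: {path}")
        phylum = None
        if block.get("metadata"):
            phylum = matrix_io.read_strain_metadata(block["metadata"])
        tensor = matrix_io.read_tensor(
            files,
            format=block.get("format", "wide"),
            delimiter=block.get("delimiter"),
            strains=block.get("strains"),
            phylum=phylum,
        )
        prov = {"source": "files", "files": files}
    elif source == "simulate":
        cfg = synthetic.SyntheticConfig(**config["simulate"])
        tensor, _truth = synthetic.generate(cfg)
        prov = {"source": "simulate", "config": config["simulate"]}
    else:
        seed = int(config["fixture"].get("seed", 0))
        tensor = synthetic.study_scale_fixture(seed)
        prov = {"source": "fixture", "seed": seed}
    return tensor, prov


class StageError(InhibnetError):
    """Wraps a stage failure with the stage name for pipeline reporting."""

    def __init__(self, stage: str, error: Exception) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {error}")
        self.stage = stage
        self.error = error


def run_pipeline(config: str | Path | Mapping,
                 out_dir: str | Path | None = None) -> AnalysisReport:
    """Execute the configured stages and write the report plus exports.

    Returns the in-memory :class:`AnalysisReport`; raises
    :class:`StageError` (after removing partial outputs) if any stage
    fails.
    """
    config = load_config(config)
    analyses = tuple(config.get("analyses", DEFAULT_ANALYSES))
    out_dir = Path(out_dir or config.get("out_dir", "."))
    written: list[Path] = []
    try:
        stage = "inputs"
        tensor, source_prov = _resolve_tensor(config)
        network = matrix_io.union_network(tensor)
        logger.info("network: %d strains, %d union edges over %d conditions",
                    network.n_species, network.n_edges,
                    len(tensor.conditions))

        stage = "metrics"
        stats = metrics.network_stats(network).to_dict()

        hierarchy_block = None
        levels = None
        hres = None
        if "hierarchy" in analyses:
            stage = "hierarchy"
            hcfg = dict(config.get("hierarchy", {}))
            hres = hierarchy_mod.hierarchy_scores(network)
            scheme = hcfg.get("levels", "tertile")
            levels = hierarchy_mod.assign_levels(hres, scheme)
            share = hierarchy_mod.top_k_producer_share(
                network, hres, k=int(hcfg.get("k", 4)))
            hierarchy_block = {
                "table": hres.to_frame(levels).to_dict(orient="records"),
                "top_k": {
                    "k": share.k,
                    "producers": list(share.producers),
                    "edge_count": share.edge_count,
                    "share": share.share,
                    "share_percent": share.share_percent,
                },
            }

        conservation_block = None
        if "conservation" in analyses:
            stage = "conservation"
            conservation_block = conservation_mod.conservation_report(tensor)

        null_blocks: list[dict] = []
        if "nulls" in analyses:
            stage = "nulls"
            ncfg = dict(config.get("nulls", {}))
            base_seed = int(ncfg.get("seed", 0))
            for t, test in enumerate(ncfg.get("tests", [])):
                test = dict(test)
                result = null_models.null_test(
                    network,
                    statistic=test["statistic"],
                    family=test.get("family", "erdos"),
                    n_perm=int(test.get("n_perm", 199)),
                    seed=int(test.get("seed", base_seed + t)),
                    k=int(test.get("k", 4)),
                    direction=test.get("direction"),
                )
                null_blocks.append(
                    result.to_dict(include_sample=bool(
                        ncfg.get("dump_samples", False))))

        stage = "export"
        out_dir.mkdir(parents=True, exist_ok=True)
        provenance = {
            "tool": "inhibnet",
            "version": __version__,
            "schema_version": SCHEMA_VERSION,
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "config_hash": _config_hash(config),
            **source_prov,
        }
        report = AnalysisReport(
            provenance=provenance,
            stats=stats,
            hierarchy=hierarchy_block,
            conservation=conservation_block,
            null_tests=null_blocks,
        )

        path = out_dir / "report.json"
        path.write_text(report.to_json() + "\n", encoding="utf-8")
        written.append(path)

        if hierarchy_block is not None and hres is not None:
            path = out_dir / "hierarchy.tsv"
            hres.to_frame(levels).to_csv(path, sep="\t", index=False)
            written.append(path)
        if conservation_block is not None:
            path = out_dir / "venn.tsv"
            pd.DataFrame(
                list(conservation_block["venn_counts"].items()),
                columns=["conditions", "count"],
            ).to_csv(path, sep="\t", index=False)
            written.append(path)
        written.append(matrix_io.write_sif(network, out_dir / "network.sif"))
        written.append(matrix_io.write_graphml(
            network, out_dir / "network.graphml",
            scores=hres.scores() if hres is not None else None,
            levels=levels,
        ))
        logger.info("wrote %d files to %s", len(written), out_dir)
        return report
    except StageError:
        raise
    except Exception as err:
        for path in written:
            try:
                path.unlink()
            except OSError:  # pragma: no cover
                pass
        raise StageError(stage, err) from err
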