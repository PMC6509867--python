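"""End-to-end orchestration: ingest -> selection -> modules -> pathway network.

A single :class:`RunConfig` points either at the five real-format input
files (expression, methylation, clinical, PPI, GMT) or at a synthetic-data
configuration; :func:`run` executes every stage, writes all per-stage
outputs under the output directory and returns a manifest recording input
hashes, the configuration and the per-stage gene/module/pathway counts.
The manifest contains no timestamps, so identical inputs and seeds yield
byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__, ingest, netmod, pathnet, synthio
from .stagesel import ElasticNetConfig, profile_table, run_summary, select_stage_genes

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run"]

_INPUT_KEYS = ("expression", "methylation", "clinical", "ppi", "gmt")


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Exactly one of ``inputs`` (paths to the five real-format files, keys
    expression/methylation/clinical/ppi/gmt) or ``synth`` must be given.
    """

    outdir: str | Path
    inputs: dict[str, str] | None = None
    synth: synthio.SynthConfig | None = None
    enet: ElasticNetConfig = field(default_factory=ElasticNetConfig)
    fdr: float = 0.05
    min_w: float = 0.0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.synth is None):
            raise ValueError("supply exactly one of real input paths or a synthetic config")
        if self.inputs is not None:
            missing = [k for k in _INPUT_KEYS if k not in self.inputs]
            if missing:
                raise ValueError(f"missing input paths: {missing}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run(cfg: RunConfig) -> dict:
    """Execute the full pipeline and return the run manifest.

    Stages: (1) generate or load inputs, (2) preprocess into the feature
    matrix and label vectors, (3) per-stage elastic-net stability selection,
    (4) PPI giant-component modules with cross-stage tags, (5) enrichment
    and the pathway evolution network. Any stage error propagates with the
    failing stage named.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if cfg.synth is not None:
        synthio.write_inputs(cfg.synth, outdir / "inputs")
        paths = {k: str(outdir / "inputs" / f"{k}.{'gmt' if k == 'gmt' else 'tsv'}") for k in _INPUT_KEYS}
        paths["gmt"] = str(outdir / "inputs" / "pathways.gmt")
    else:
        paths = dict(cfg.inputs)  # type: ignore[arg-type]
    for key in _INPUT_KEYS:
        if not Path(paths[key]).exists():
            raise FileNotFoundError(f"[ingest] missing {key} input: {paths[key]}")

    stage_err = "ingest"
    try:
        import pandas as pd

        expr = ingest.read_omics(paths["expression"], layer="expression")
        meth = ingest.read_omics(paths["methylation"], layer="methylation")
        expr, meth = ingest.intersect_layers(expr, meth)
        clinical = pd.read_csv(paths["clinical"], sep="\t", dtype=str)
        labels = ingest.binarize_stages(clinical)
        # align samples: staged samples present in both omics layers
        staged = [
            s for s in labels[0].sample_ids if s in expr.values.index and s in meth.values.index
        ]
        keep = [i for i, s in enumerate(labels[0].sample_ids) if s in set(staged)]
        labels = [
            ingest.StageLabelVector(stage=l.stage, y=l.y[keep], sample_ids=staged) for l in labels
        ]
        X = ingest.assemble_features(expr, meth, staged)
        ppi = ingest.read_ppi(paths["ppi"])
        gene_sets = ingest.read_gmt(paths["gmt"])

        stage_err = "stagesel"
        profiles = select_stage_genes(X, labels, cfg.enet)
        run_summary(profiles).to_csv(outdir / "run_summary.tsv", sep="\t", index=False)
        for st, prof in profiles.items():
            profile_table(prof).to_csv(outdir / f"selection_{st}.tsv", sep="\t", index=False)

        stage_err = "netmod"
        modules = {
            st: netmod.build_stage_module(st, prof.selected, ppi) for st, prof in profiles.items()
        }
        netmod.annotate_cross_stage(modules)
        for mod in modules.values():
            netmod.write_module(mod, outdir / "modules")

        stage_err = "pathnet"
        universe = set().union(*gene_sets.values()) & X.genes if gene_sets else set()
        results_by_stage: dict[str, list[pathnet.EnrichmentResult]] = {}
        for st, mod in modules.items():
            query = mod.nodes & universe
            if not query:
                logger.warning("stage %s: no module genes in the enrichment universe", st)
                results_by_stage[st] = []
                continue
            res = pathnet.enrich(mod.nodes, gene_sets, universe, stage=st, fdr=cfg.fdr)
            results_by_stage[st] = res
            pathnet.enrichment_table(res, fdr=cfg.fdr).to_csv(
                outdir / f"enrichment_{st}.tsv", sep="\t", index=False
            )
        network = pathnet.build_pathway_network(results_by_stage, gene_sets, cfg.fdr, cfg.min_w)
        import networkx as nx

        nx.write_graphml(network, outdir / "pathway_network.graphml")
        groups = pathnet.group_components(network)
        with open(outdir / "groups.tsv", "w") as fh:
            fh.write("group\tpathways\tstages\n")
            for gid, info in groups.items():
                fh.write(f"{gid}\t{','.join(info['pathways'])}\t{','.join(info['stages'])}\n")
    except Exception as exc:
        raise type(exc)(f"[{stage_err}] {exc}").with_traceback(exc.__traceback__) from None

    manifest = {
        "version": __version__,
        "config": {
            "enet": dataclasses.asdict(cfg.enet),
            "fdr": cfg.fdr,
            "min_w": cfg.min_w,
            "synth": dataclasses.asdict(cfg.synth) if cfg.synth else None,
        },
        "inputs": {k: {"path": Path(paths[k]).name, "sha256": _sha256(Path(paths[k]))} for k in _INPUT_KEYS},
        "n_samples": X.m,
        "n_features": X.n,
        "n_genes": len(X.genes),
        "stages": {
            st: {
                "genes_at_cutoff": len(profiles[st].selected),
                "max_genes_per_model": profiles[st].max_genes_per_model,
                "module_nodes": modules[st].graph.number_of_nodes(),
                "module_edges": modules[st].graph.number_of_edges(),
                "significant_pathways": sum(
                    r.q_value <= cfg.fdr for r in results_by_stage[st]
                ),
            }
            for st in sorted(profiles)
        },
        "pathway_network": {
            "nodes": network.number_of_nodes(),
            "edges": network.number_of_edges(),
            "groups": len(groups),
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
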