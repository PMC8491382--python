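"""Pipeline configuration and the end-to-end run.

A single validated config (YAML/JSON on disk) drives the full pipeline:
load lexicon -> annotate corpus -> aggregate co-mentions -> rank/filter ->
export.  Unknown keys are rejected up front, and every run writes a manifest
(config hash, seeds, versions, stage counts) sufficient to reproduce the
outputs bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError as PydanticValidationError

from . import __version__
from .corpus_io import read_abstract_table, read_pubtator, write_pubtator
from .errors import DataError, UsageError
from .lexicon import ConceptLexicon, parse_mesh_descriptors, build_lookup
from .model import ConceptID
from .nen import annotate_corpus
from .ner import RecognizerConfig
from .network import TargetSet, aggregate_comentions, export_graph, rank_and_filter

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


class NerSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    engine: str = "dictionary"
    max_ngram: int = Field(default=10, ge=1)
    case_sensitive: bool = False


class DdaSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    targets: list[str]
    top_k: int = Field(default=100, ge=1)
    min_target_links: int = Field(default=2, ge=1)
    count_mode: str = "document"
    rank_by: str = "edges"


class CompareSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_shared: int = Field(default=20, ge=1)
    id_map: str | None = None


class PipelineConfig(BaseModel):
    """Schema-validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    corpus: str
    corpus_format: str = "table"  # "table" (TSV id,title,abstract) or "pubtator"
    lexicon: str
    lexicon_format: str = "tsv"  # "tsv" or "mesh-xml"
    ner: NerSettings = NerSettings()
    ddas: DdaSettings
    compare: CompareSettings = CompareSettings()
    seed: int = 0
    output_dir: str = "cominer-out"

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def load_config(path: str | Path) -> PipelineConfig:
    try:
        raw = yaml.safe_load(Path(path).read_text())
        return PipelineConfig.model_validate(raw)
    except PydanticValidationError as exc:
        raise UsageError(f"invalid configuration: {exc}") from exc
    except yaml.YAMLError as exc:
        raise UsageError(f"unreadable configuration file: {exc}") from exc


def _load_lexicon(cfg: PipelineConfig) -> ConceptLexicon:
    path = Path(cfg.lexicon)
    if cfg.lexicon_format == "mesh-xml":
        with path.open("rb") as fh:
            return build_lookup(parse_mesh_descriptors(fh))
    if cfg.lexicon_format == "tsv":
        with path.open() as fh:
            return ConceptLexicon.from_tsv(fh)
    raise UsageError(f"unknown lexicon_format {cfg.lexicon_format!r}")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute annotate -> co-mention network -> export; returns the run
    manifest (also written to the output directory)."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    lexicon = _load_lexicon(cfg)
    corpus_path = Path(cfg.corpus)
    if cfg.corpus_format == "pubtator":
        with corpus_path.open() as fh:
            docs = [d.document for d in read_pubtator(fh)]
    elif cfg.corpus_format == "table":
        with corpus_path.open() as fh:
            docs = read_abstract_table(fh)
    else:
        raise UsageError(f"unknown corpus_format {cfg.corpus_format!r}")

    ner_cfg = RecognizerConfig(
        max_ngram=cfg.ner.max_ngram, case_sensitive=cfg.ner.case_sensitive
    )
    if cfg.ner.engine != "dictionary":
        raise UsageError(f"unknown ner.engine {cfg.ner.engine!r}")
    result = annotate_corpus(docs, lexicon, ner_cfg)
    (out / "annotated.pubtator").write_text(write_pubtator(result.documents))

    edges = aggregate_comentions(result.documents, count_mode=cfg.ddas.count_mode)
    targets = TargetSet.of(*cfg.ddas.targets)
    ranked = rank_and_filter(
        edges,
        targets,
        k=cfg.ddas.top_k,
        min_target_links=cfg.ddas.min_target_links,
        rank_by=cfg.ddas.rank_by,
    )
    (out / "edges_all.tsv").write_text(export_graph(edges, "tsv"))
    (out / "edges_top.tsv").write_text(export_graph(ranked.edges, "tsv"))
    (out / "network_top.graphml").write_text(
        export_graph(ranked.edges, "graphml", lexicon)
    )

    manifest = {
        "tool": "cominer",
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "config": cfg.model_dump(),
        "seed": cfg.seed,
        "counts": {
            **result.summary,
            "edges_total": len(edges),
            "edges_top": len(ranked.edges),
            "target_target_edges": len(ranked.target_target),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
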