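"""End-to-end pipeline: collect -> opposition -> themes -> misinfo ->
top authors -> partition -> comparison table, with a run manifest.

The pipeline is a pure function of (inputs, config, seed): repeated runs are
byte-identical except for wall-clock fields in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import influence, stats, themes, validation
from .corpus import read_posts, write_posts
from .errors import PipelineStageError, VaxwatchError
from .query import compile_query
from .themes import load_rulebook

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

log = logging.getLogger("vaxwatch")


@dataclass
class PipelineConfig:
    """Paths and thresholds for one full run."""

    corpus_path: Path
    rulebook_path: Path
    out_dir: Path
    top_k: int = influence.DEFAULT_TOP_K
    precision_threshold: float = validation.DEFAULT_PRECISION_THRESHOLD
    saturation_threshold: float = themes.SATURATION_THRESHOLD
    sample_total: int = 1000   # sample of the full conversation for manual coding
    sample_theme: int = 100    # per-theme audit sample
    sample_crosscode: int = 200
    seed: int = 0
    deny_list_path: Optional[Path] = None
    corpus_format: Optional[str] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        with path.open("r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        base = path.parent

        def resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        kwargs = {}
        for key in ("corpus_path", "rulebook_path", "out_dir", "deny_list_path"):
            if key in data and data[key] is not None:
                kwargs[key] = resolve(data.pop(key))
            else:
                data.pop(key, None)
        for key in (
            "top_k", "precision_threshold", "saturation_threshold",
            "sample_total", "sample_theme", "sample_crosscode", "seed",
            "corpus_format",
        ):
            if key in data:
                kwargs[key] = data.pop(key)
        if data:
            raise VaxwatchError(f"unknown pipeline config key(s): {sorted(data)}")
        return cls(**kwargs)


@dataclass
class RunManifest:
    """Provenance for one run: input hashes, seed, per-stage counts/timings."""

    config_hashes: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    stages: list[dict] = field(default_factory=list)
    started_at: float = 0.0
    finished_at: float = 0.0

    def record(self, stage: str, n_in: int, n_out: int, seconds: float) -> None:
        self.stages.append(
            {"stage": stage, "n_in": n_in, "n_out": n_out, "seconds": round(seconds, 4)}
        )

    def counts(self) -> dict[str, tuple[int, int]]:
        return {s["stage"]: (s["n_in"], s["n_out"]) for s in self.stages}

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "config_hashes": self.config_hashes,
                    "seed": self.seed,
                    "stages": self.stages,
                    "started_at": self.started_at,
                    "finished_at": self.finished_at,
                },
                fh,
                indent=2,
            )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Stage:
    """Context manager that times a stage and wraps errors with its name."""

    def __init__(self, manifest: RunManifest, name: str):
        self.manifest = manifest
        self.name = name
        self.n_in = 0
        self.n_out = 0

    def __enter__(self):
        log.info("stage %s: start", self.name)
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, exc_type, exc, tb):
        elapsed = time.perf_counter() - self.t0
        if exc is not None:
            if isinstance(exc, PipelineStageError):
                return False
            raise PipelineStageError(self.name, str(exc)) from exc
        self.manifest.record(self.name, self.n_in, self.n_out, elapsed)
        log.info(
            "stage %s: %d -> %d records in %.2fs",
            self.name, self.n_in, self.n_out, elapsed,
        )
        return False


def run_pipeline(config: PipelineConfig | str | Path) -> RunManifest:
    """Execute the full coding-and-comparison flow, writing all artifacts.

    Artifacts written to ``config.out_dir``: the opposition sub-corpus,
    tagged posts (JSONL and long CSV), the top-author registry (CSV + JSON),
    the comparison table (CSV + Markdown), theme counts/saturation/coverage
    (JSON), and ``manifest.json``.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=config.seed, started_at=time.time())
    for name, p in (("corpus", config.corpus_path), ("rulebook", config.rulebook_path)):
        manifest.config_hashes[name] = _sha256(Path(p))

    rulebook = load_rulebook(config.rulebook_path)
    opposition_query = compile_query(rulebook.opposition)
    deny: frozenset[str] = frozenset()
    if config.deny_list_path is not None:
        deny = frozenset(
            line.strip()
            for line in Path(config.deny_list_path).read_text(encoding="utf-8").splitlines()
            if line.strip()
        )

    with _Stage(manifest, "ingest") as st:
        corpus = read_posts(config.corpus_path, format=config.corpus_format)
        st.n_in = st.n_out = len(corpus)
    if len(corpus) == 0:
        raise PipelineStageError("filter_opposition", "input corpus is empty")

    with _Stage(manifest, "filter_opposition") as st:
        st.n_in = len(corpus)
        opposition = themes.filter_opposition(corpus, opposition_query)
        st.n_out = len(opposition)
        write_posts(opposition, out / "opposition.jsonl")
    if len(opposition) == 0:
        raise PipelineStageError(
            "filter_opposition", "no posts match the opposition query"
        )

    with _Stage(manifest, "tag_themes") as st:
        st.n_in = len(opposition)
        tagged = themes.tag_themes(opposition, rulebook.theme_rules)
        st.n_out = len(tagged)

    with _Stage(manifest, "tag_misinformation") as st:
        st.n_in = len(tagged)
        tagged = themes.tag_misinformation(
            tagged, rulebook.misinfo_rules, rulebook.theme_rules
        )
        st.n_out = len(tagged)
        _write_tagged(tagged, out)

    with _Stage(manifest, "theme_summary") as st:
        st.n_in = len(tagged)
        counts = themes.theme_counts(tagged)
        summary = {
            "total_opposition": len(tagged),
            "theme_counts": dict(sorted(counts.items())),
            "coverage": themes.coverage(tagged),
            "saturated": themes.saturation_check(
                counts, len(tagged), config.saturation_threshold
            ),
        }
        (out / "theme_summary.json").write_text(
            json.dumps(summary, indent=2), encoding="utf-8"
        )
        st.n_out = len(counts)

    with _Stage(manifest, "monthly_top_authors") as st:
        st.n_in = len(opposition)
        registry = influence.monthly_top_authors(
            opposition, k=config.top_k, deny_list=deny
        )
        st.n_out = len(registry.union)
        registry.to_csv(out / "top_authors.csv")
        registry.to_json(out / "top_authors.json")

    with _Stage(manifest, "partition") as st:
        st.n_in = len(tagged)
        top, other = influence.partition_by_top_authors(tagged, registry)
        st.n_out = len(top) + len(other)

    with _Stage(manifest, "comparison_table") as st:
        st.n_in = len(top) + len(other)
        table = stats.build_comparison_table(top, other, rulebook.theme_names())
        st.n_out = len(table.rows)
        table.to_csv(out / "comparison.csv")
        (out / "comparison.md").write_text(table.to_markdown() + "\n", encoding="utf-8")

    manifest.finished_at = time.time()
    manifest.save(out / "manifest.json")
    return manifest


def _write_tagged(tagged, out: Path) -> None:
    with (out / "tagged.jsonl").open("w", encoding="utf-8") as fh:
        for tp in tagged:
            fh.write(
                json.dumps(
                    {
                        "post_id": tp.post.post_id,
                        "opposition": tp.opposition,
                        "themes": sorted(tp.themes),
                        "misinfo": sorted(map(list, tp.misinfo)),
                    }
                )
            )
            fh.write("\n")
    with (out / "tagged_long.csv").open("w", encoding="utf-8", newline="") as fh:
        fh.write("post_id,theme\n")
        for tp in tagged:
            for theme in sorted(tp.themes):
                fh.write(f"{tp.post.post_id},{theme}\n")
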