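"""End-to-end orchestration: simulate -> build-index -> transfer -> evaluate,
plus consensus and nu labelling, with a reproducibility manifest.

All randomness flows from the single config seed through named substreams,
and all TSV output uses fixed formatting with LF line endings, so a rerun on
identical inputs is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

import idranno.consensus as cns

from . import __version__
from .compaction import label_table, read_nu_table, write_labeled_table
from .embeddings import read_region_embeddings
from .evaluation import GoldStandard, default_grid, fmax
from .knn import TransferConfig, build_index, predictions_to_table, transfer_all
from .ontology import load_obo
from .simulate import FixtureSpec, write_bundle

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "transfer", "evaluate", "consensus", "label-nu")


@dataclass
class RunConfig:
    """Serialisable description of one pipeline run."""

    outdir: str = "idranno_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    fixture: FixtureSpec = field(default_factory=FixtureSpec)
    transfer: TransferConfig = field(default_factory=TransferConfig)
    consensus: cns.ConsensusConfig = field(default_factory=cns.ConsensusConfig)
    grid_step: float = 0.01
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for stage in self.stages:
            if stage not in ALL_STAGES:
                raise ValueError(f"unknown stage {stage!r}")
        # the fixture inherits the run seed unless set explicitly
        if self.fixture.seed != self.seed:
            self.fixture = dataclasses.replace(self.fixture, seed=self.seed)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        if "fixture" in data:
            data["fixture"] = FixtureSpec.from_json(json.dumps(data["fixture"]))
        if "transfer" in data:
            data["transfer"] = TransferConfig(**data["transfer"])
        if "consensus" in data:
            data["consensus"] = cns.ConsensusConfig(**data["consensus"])
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in dependency order.

    Returns the manifest (also written to ``<outdir>/manifest.json``).  On a
    stage failure a FAILED marker naming the stage is left in the output
    directory and the exception propagates.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    manifest: dict = {
        "version": __version__,
        "config": json.loads(config.to_json()),
        "stages": {},
        "inputs": {},
    }
    (outdir / "config_snapshot.json").write_text(
        config.to_json() + "\n", encoding="utf-8"
    )

    bundle_dir = outdir / "fixtures"
    stage = None
    try:
        if "simulate" in config.stages:
            stage = "simulate"
            files = write_bundle(config.fixture, bundle_dir)
            manifest["stages"]["simulate"] = files
            manifest["inputs"] = {
                name: _sha256(Path(path)) for name, path in sorted(files.items())
            }

        results = None
        gold_by_ns: dict[str, GoldStandard] = {}
        if "transfer" in config.stages:
            stage = "transfer"
            ontology = load_obo(str(bundle_dir / "ontology.obo"))
            annotations = pd.read_csv(
                bundle_dir / "reference_annotations.tsv", sep="\t"
            )
            refs = read_region_embeddings(bundle_dir / "reference_embeddings.tsv")
            queries = read_region_embeddings(bundle_dir / "query_embeddings.tsv")
            index = build_index(annotations, refs, ontology, propagate=True)
            namespaces = tuple(
                ns
                for ns in ("molecular_function", "disorder_function")
                if index.namespace_size(ns)
            )
            results = transfer_all(queries, index, config.transfer, namespaces)
            table = predictions_to_table(results)
            table.to_csv(
                outdir / "predictions.tsv", sep="\t", index=False,
                lineterminator="\n", float_format="%.6f",
            )
            manifest["stages"]["transfer"] = {
                "n_queries": len(queries),
                "n_reference": len(index),
                "namespaces": list(namespaces),
            }

        if "evaluate" in config.stages:
            stage = "evaluate"
            if results is None:
                raise RuntimeError("evaluate requires the transfer stage")
            gold_df = pd.read_csv(bundle_dir / "gold_annotations.tsv", sep="\t")
            for ns, grp in gold_df.groupby("namespace"):
                regions: dict = {}
                for rec in grp.itertuples(index=False):
                    key = (str(rec.accession), int(rec.start), int(rec.end))
                    regions.setdefault(key, set()).add(str(rec.term))
                gold_by_ns[str(ns)] = GoldStandard(
                    namespace=str(ns),
                    regions={k: frozenset(v) for k, v in regions.items()},
                )
            grid = default_grid(config.grid_step)
            report = {}
            for ns, preds in results.items():
                if ns not in gold_by_ns:
                    continue
                res = fmax(preds, gold_by_ns[ns], thresholds=grid)
                report[ns] = {
                    "fmax": round(res.fmax, 6),
                    "optimal_threshold": round(res.optimal_threshold, 6),
                    "n_regions": res.n_regions,
                    "n_predicted": res.n_predicted,
                    "curve": [
                        [round(v, 6) for v in point] for point in res.curve
                    ],
                }
            (outdir / "evaluation.json").write_text(
                json.dumps(report, indent=2, sort_keys=True) + "\n",
                encoding="utf-8",
            )
            manifest["stages"]["evaluate"] = {
                ns: rep["fmax"] for ns, rep in report.items()
            }

        if "consensus" in config.stages:
            stage = "consensus"
            tracks = cns.read_tracks_tsv(bundle_dir / "tracks.tsv")
            sources = [t for t in tracks if t.feature_key != "hidden-truth"]
            by_acc: dict[str, list[cns.DisorderTrack]] = {}
            for t in sources:
                by_acc.setdefault(t.accession, []).append(t)
            out_tracks = []
            for acc in sorted(by_acc):
                votes = cns.VoteMatrix(acc, by_acc[acc])
                for mode in ("merge", "majority", "strict"):
                    cfg = dataclasses.replace(config.consensus, mode=mode)
                    out_tracks.append(cns.consensus(votes, cfg))
            cns.write_tracks_tsv(out_tracks, outdir / "consensus.tsv")
            stats = cns.content_fraction(sources + out_tracks)
            (outdir / "content_stats.tsv").write_text(
                "feature_key\tfraction\tn_proteins\n"
                + "".join(
                    f"{k}\t{v.fraction:.6f}\t{v.n_proteins}\n"
                    for k, v in sorted(stats.items())
                ),
                encoding="utf-8",
            )
            manifest["stages"]["consensus"] = {
                "n_proteins": len(by_acc),
                "modes": ["merge", "majority", "strict"],
            }

        if "label-nu" in config.stages:
            stage = "label-nu"
            preds = read_nu_table(bundle_dir / "nu_table.tsv")
            table, summary = label_table(preds)
            write_labeled_table(table, outdir / "nu_labels.tsv")
            manifest["stages"]["label-nu"] = {
                k: (round(v, 6) if isinstance(v, float) else v)
                for k, v in summary.items()
            }
    except Exception as exc:
        failed_marker.write_text(f"stage {stage} failed: {exc}\n", encoding="utf-8")
        raise

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
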