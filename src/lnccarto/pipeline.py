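"""End-to-end pipeline: simulate -> train -> map -> candidates -> flips -> features.

A single YAML config drives all stages.  Each completed stage writes a
``<stage>.done.json`` marker containing a hash of every config section it
depends on (including its upstream stages' hashes), so re-running with an
unchanged config skips completed stages, while changing, say, the training
section re-runs training and everything downstream but not the simulation.
A run manifest listing every produced artifact with its checksum is written
at the end.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields as dc_fields
from pathlib import Path

import yaml

from .cartography import (
    RegionThresholds,
    WeightingScheme,
    assign_region,
    compute_confidence_variability,
    consensus_candidates,
    plot_map,
    select_misannotation_candidates,
)
from .classifiers import ArchitectureSpec, build_classifier
from .encoding import KmerEmbeddingTable, load_embedding_table
from .features import embed_2d, feature_table, orf_table
from .flips import FlipConfig, run_flip_experiment
from .io import (
    filter_noncoding_min_length,
    read_labeled_fasta,
    truncate_sequences,
)
from .synthetic import SynthConfig, generate_dataset, write_dataset
from .training import EncodedDataset, TrainConfig, TrainingTrace, train_with_recording

log = logging.getLogger("lnccarto.pipeline")

STAGES = ("simulate", "train", "map", "candidates", "flip_experiment", "features")


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    output_dir: str
    seed: int = 7
    stages: tuple[str, ...] = STAGES
    synthetic: SynthConfig | None = None
    input_fasta: str | None = None
    input_manifest: str | None = None
    architectures: tuple[str, ...] = ("cnn",)
    training: TrainConfig = field(default_factory=TrainConfig)
    scheme: WeightingScheme = field(default_factory=WeightingScheme.base)
    thresholds: RegionThresholds = field(default_factory=RegionThresholds)
    flip: FlipConfig = field(default_factory=FlipConfig)
    embedding_path: str | None = None
    embedding_dim: int = 100
    tsne: bool = True

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {list(STAGES)}")
        if self.synthetic is None and not (self.input_fasta and self.input_manifest):
            self.synthetic = SynthConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def take(section: str, dc_type):
            sub = raw.pop(section, None)
            if sub is None:
                return None
            allowed = {f.name for f in dc_fields(dc_type)}
            bad = set(sub) - allowed
            if bad:
                raise ValueError(f"unknown keys {sorted(bad)} in section {section!r}")
            return dc_type(**sub)

        kw: dict = {}
        if "output_dir" not in raw:
            raise ValueError("config requires output_dir")
        kw["output_dir"] = raw.pop("output_dir")
        kw["seed"] = int(raw.pop("seed", 7))
        if "stages" in raw:
            kw["stages"] = tuple(raw.pop("stages"))
        syn = take("synthetic", SynthConfig)
        if syn is not None:
            kw["synthetic"] = syn
        tr = take("training", TrainConfig)
        if tr is not None:
            kw["training"] = tr
        carto = raw.pop("cartography", None)
        if carto:
            carto = dict(carto)
            if "scheme" in carto:
                kw["scheme"] = WeightingScheme.parse(carto.pop("scheme"))
            if "thresholds" in carto:
                kw["thresholds"] = RegionThresholds(**carto.pop("thresholds"))
            if carto:
                raise ValueError(f"unknown keys {sorted(carto)} in section 'cartography'")
        flip = raw.pop("flip", None)
        if flip:
            flip = dict(flip)
            schemes = flip.pop("schemes", None)
            if schemes:
                flip["scheme_grid"] = tuple(WeightingScheme.parse(s) for s in schemes)
            kw["flip"] = FlipConfig(**flip)
        inp = raw.pop("input", None)
        if inp:
            inp = dict(inp)
            kw["input_fasta"] = inp.pop("fasta", None)
            kw["input_manifest"] = inp.pop("manifest", None)
            if inp:
                raise ValueError(f"unknown keys {sorted(inp)} in section 'input'")
        emb = raw.pop("embedding", None)
        if emb:
            emb = dict(emb)
            kw["embedding_path"] = emb.pop("path", None)
            kw["embedding_dim"] = int(emb.pop("dim", 100))
            if emb:
                raise ValueError(f"unknown keys {sorted(emb)} in section 'embedding'")
        if "architectures" in raw:
            kw["architectures"] = tuple(raw.pop("architectures"))
        if "tsne" in raw:
            kw["tsne"] = bool(raw.pop("tsne"))
        if raw:
            raise ValueError(f"unknown top-level config keys {sorted(raw)}")
        return cls(**kw)


def _hash(obj) -> str:
    def default(o):
        if hasattr(o, "__dataclass_fields__"):
            return asdict(o)
        if isinstance(o, (set, frozenset, tuple)):
            return sorted(map(str, o))
        return str(o)

    blob = json.dumps(obj, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _file_checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


class _Stage:
    """Marker/skip bookkeeping for one pipeline stage."""

    def __init__(self, out_dir: Path, name: str, config_hash: str):
        self.name = name
        self.hash = config_hash
        self.marker = out_dir / f"{name}.done.json"

    @property
    def complete(self) -> bool:
        if not self.marker.exists():
            return False
        try:
            saved = json.loads(self.marker.read_text())
        except json.JSONDecodeError:
            return False
        if saved.get("config_hash") != self.hash:
            return False
        return all(Path(p).exists() for p in saved.get("outputs", []))

    def outputs(self) -> list[str]:
        return json.loads(self.marker.read_text())["outputs"]

    def finish(self, outputs: list[Path]) -> None:
        self.marker.write_text(
            json.dumps(
                {"config_hash": self.hash, "outputs": [str(p) for p in outputs]},
                indent=2,
            )
        )


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the run manifest: stage -> {executed, outputs (with checksums)}.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "config_seed": cfg.seed}
    executed: dict[str, bool] = {}
    artifacts: dict[str, list[Path]] = {}

    # -- stage hashes chain upstream hashes in, so invalidation propagates
    hashes: dict[str, str] = {}
    hashes["simulate"] = _hash(
        {"synthetic": cfg.synthetic, "input": (cfg.input_fasta, cfg.input_manifest)}
    )
    hashes["train"] = _hash(
        {
            "up": hashes["simulate"],
            "training": cfg.training,
            "architectures": cfg.architectures,
            "embedding": (cfg.embedding_path, cfg.embedding_dim),
        }
    )
    hashes["map"] = _hash(
        {"up": hashes["train"], "scheme": cfg.scheme, "thresholds": cfg.thresholds}
    )
    hashes["candidates"] = _hash({"up": hashes["map"]})
    hashes["flip_experiment"] = _hash(
        {"up": hashes["train"], "flip": cfg.flip, "thresholds": cfg.thresholds}
    )
    hashes["features"] = _hash({"up": hashes["simulate"], "tsne": cfg.tsne, "seed": cfg.seed})

    stages = {s: _Stage(out, s, hashes[s]) for s in STAGES}
    selected = [s for s in STAGES if s in cfg.stages]

    # lazy state shared between stages
    state: dict = {}

    def sequences():
        if "sequences" not in state:
            fasta = out / "dataset.fasta"
            man = out / "dataset.labels.tsv"
            if cfg.input_fasta:
                fasta, man = Path(cfg.input_fasta), Path(cfg.input_manifest)
            seqs = read_labeled_fasta(fasta, man)
            state["sequences"] = truncate_sequences(filter_noncoding_min_length(seqs))
        return state["sequences"]

    def table():
        if "table" not in state:
            if cfg.embedding_path:
                state["table"] = load_embedding_table(cfg.embedding_path)
            else:
                state["table"] = KmerEmbeddingTable.random(
                    dim=cfg.embedding_dim, seed=cfg.seed
                )
        return state["table"]

    def encoded():
        if "encoded" not in state:
            state["encoded"] = EncodedDataset.from_sequences(sequences(), k=table().k)
        return state["encoded"]

    def run_stage(name: str, fn):
        stage = stages[name]
        if stage.complete:
            log.info("stage %-15s skipped (up to date)", name)
            executed[name] = False
            artifacts[name] = [Path(p) for p in stage.outputs()]
            return
        t0 = time.time()
        outputs = fn()
        stage.finish(outputs)
        executed[name] = True
        artifacts[name] = outputs
        log.info("stage %-15s done in %.1fs (%d artifacts)", name, time.time() - t0, len(outputs))

    # -- stage bodies ------------------------------------------------------

    def do_simulate():
        if cfg.input_fasta:
            return [Path(cfg.input_fasta), Path(cfg.input_manifest)]
        seqs, truth = generate_dataset(cfg.synthetic)
        fasta, man = write_dataset(seqs, truth, out / "dataset")
        return [Path(fasta), Path(man)]

    def do_train():
        outputs = []
        for arch in cfg.architectures:
            handle = build_classifier(arch, table(), seed=cfg.training.seed)
            trace = train_with_recording(handle, encoded(), cfg.training)
            path = out / f"trace_{arch}.tsv"
            trace.to_tsv(path)
            sidecar = out / f"train_{arch}.json"
            sidecar.write_text(
                json.dumps(
                    {"architecture": asdict(ArchitectureSpec(family=arch)),
                     "training": asdict(cfg.training)},
                    indent=2,
                )
            )
            outputs += [path, sidecar]
        return outputs

    def do_map():
        outputs = []
        for arch in cfg.architectures:
            trace = TrainingTrace.from_tsv(out / f"trace_{arch}.tsv")
            stats = assign_region(
                compute_confidence_variability(trace, cfg.scheme), cfg.thresholds
            )
            path = out / f"stats_{arch}.tsv"
            stats.to_tsv(path)
            png = out / f"map_{arch}.png"
            plot_map(stats, path=png)
            outputs += [path, png]
        return outputs

    def do_candidates():
        outputs = []
        cand_lists = {}
        for arch in cfg.architectures:
            trace = TrainingTrace.from_tsv(out / f"trace_{arch}.tsv")
            stats = assign_region(
                compute_confidence_variability(trace, cfg.scheme), cfg.thresholds
            )
            cands = select_misannotation_candidates(stats)
            cand_lists[arch] = cands
            path = out / f"candidates_{arch}.tsv"
            stats.frame.loc[cands].to_csv(path, sep="\t", index_label="sample_id")
            outputs.append(path)
        if len(cand_lists) >= 2:
            consensus = consensus_candidates(cand_lists)
            path = out / "consensus.tsv"
            consensus.membership.to_csv(path, sep="\t")
            outputs.append(path)
            counts = out / "consensus_counts.json"
            counts.write_text(
                json.dumps(
                    {
                        "+".join(sorted(k)): v
                        for k, v in consensus.cell_counts.items()
                    },
                    indent=2, sort_keys=True,
                )
            )
            outputs.append(counts)
        return outputs

    def do_flip():
        baseline = None
        arch = cfg.architectures[0]
        trace_path = out / f"trace_{arch}.tsv"
        if trace_path.exists():
            baseline = TrainingTrace.from_tsv(trace_path)
        result = run_flip_experiment(
            sequences(), arch, cfg.training, cfg.flip,
            table=table(), baseline_trace=baseline, encoded=encoded(),
        )
        path = out / "flip_result.json"
        result.to_json(path)
        return [path]

    def do_features():
        import pandas as pd

        seqs = sequences()
        feats = feature_table(seqs)
        fpath = out / "features.tsv"
        feats.to_csv(fpath, sep="\t")
        opath = out / "orfs.tsv"
        orf_table(seqs).to_csv(opath, sep="\t", index=False)
        outputs = [fpath, opath]
        if cfg.tsne and len(feats) >= 5:
            coords = embed_2d(feats.to_numpy(), seed=cfg.seed)
            tpath = out / "tsne.tsv"
            pd.DataFrame(
                coords, index=feats.index, columns=["tsne_1", "tsne_2"]
            ).to_csv(tpath, sep="\t")
            outputs.append(tpath)
        return outputs

    bodies = {
        "simulate": do_simulate,
        "train": do_train,
        "map": do_map,
        "candidates": do_candidates,
        "flip_experiment": do_flip,
        "features": do_features,
    }
    for name in selected:
        run_stage(name, bodies[name])

    for name in selected:
        manifest["stages"][name] = {
            "executed": executed[name],
            "config_hash": hashes[name],
            "outputs": {
                str(p): _file_checksum(Path(p)) for p in artifacts[name]
            },
        }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
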