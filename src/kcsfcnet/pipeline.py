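"""End-to-end study pipeline on synthetic (or pre-saved) multi-subject data.

``run_pipeline`` executes the whole protocol: simulate or load each
subject's trials, condition them (resample → bandpass → clip), grid-search
the filter count over five shuffled 80/20 cross-validation rounds, build
the six-column score matrix, group subjects by k-means (k=3) with PCA
ordering, then refit each subject's winning model on all trials and run the
interpretation chain — KS connection pruning at α=0.05, Rényi entropy,
channel relevance, 99th-percentile edge lists and a t-SNE layout.  Every
random stage draws its seed from one root seed through named substreams.

All artifacts are written under the output directory as CSV/JSON plus one
machine-readable ``summary.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import (channel_relevance, cluster_subjects, prune_connections,
                       renyi_entropy, top_percentile_edges, tsne_layout)
from .containers import EEGTrialSet
from .evaluation import build_score_matrix, cross_validate, grid_search_nf
from .io import read_trials, save_model, write_trials
from .model import KCSFCnet
from .preprocessing import PreprocessConfig, preprocess
from .synthetic import Coupling, SyntheticSpec, generate_subject

__all__ = ["SimulateConfig", "ModelSettings", "EvaluationSettings",
           "AnalysisSettings", "RunConfig", "run_pipeline", "substream"]

log = logging.getLogger("kcsfcnet")


def substream(root_seed: int, name: str) -> int:
    """Deterministic named sub-seed of a root seed (stable across runs)."""
    return (int(root_seed) * 0x9E3779B1 + zlib.crc32(name.encode())) % (2**31 - 1)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def _from_mapping(cls, data: dict, context: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {context} config keys: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class SimulateConfig:
    """Synthetic cohort: per-subject snr values span weak to strong coupling
    so that performance groups actually differ."""

    n_subjects: int = 6
    n_trials: int = 40
    n_channels: int = 8
    fs: float = 128.0
    duration: float = 3.0
    cue_onset: float = 0.0
    snr: tuple[float, ...] = (0.2, 0.5, 1.0, 1.5, 2.0, 3.0)
    couplings: tuple[tuple, ...] = (((0, 1), 8.0, 13.0, 1), ((2, 3), 18.0, 24.0, 0))

    def spec_for(self, subject_idx: int, seed: int) -> SyntheticSpec:
        snr = self.snr[subject_idx % len(self.snr)]
        return SyntheticSpec(
            n_trials=self.n_trials, n_channels=self.n_channels, fs=self.fs,
            duration=self.duration, cue_onset=self.cue_onset,
            couplings=tuple(Coupling(tuple(c[0]), c[1], c[2], c[3])
                            for c in self.couplings),
            snr=snr, seed=seed,
        )


@dataclass(frozen=True)
class ModelSettings:
    n_filters: int = 4
    kernel_length: int = 64
    n_epochs: int = 150
    learning_rate: float = 1e-3
    dropout_rate: float = 0.5

    def build(self, seed: int | None = None) -> KCSFCnet:
        return KCSFCnet(n_filters=self.n_filters, kernel_length=self.kernel_length,
                        n_epochs=self.n_epochs, learning_rate=self.learning_rate,
                        dropout_rate=self.dropout_rate, random_state=seed)


@dataclass(frozen=True)
class EvaluationSettings:
    n_folds: int = 5
    nf_grid: tuple[int, ...] = (2, 3, 4)
    grid_search: bool = True


@dataclass(frozen=True)
class AnalysisSettings:
    alpha: float = 0.05
    percentile: float = 99.0
    perplexity: float = 10.0
    k: int = 3


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration; unknown YAML keys are rejected."""

    seed: int = 0
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: ModelSettings = field(default_factory=ModelSettings)
    evaluation: EvaluationSettings = field(default_factory=EvaluationSettings)
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)
    input_dir: str | None = None  # read pre-saved trial archives instead of simulating

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict = {}
        for key, sub in (("simulate", SimulateConfig), ("preprocess", PreprocessConfig),
                         ("model", ModelSettings), ("evaluation", EvaluationSettings),
                         ("analysis", AnalysisSettings)):
            if key in raw:
                section = dict(raw[key])
                for fname, val in section.items():  # YAML lists -> tuples
                    if isinstance(val, list):
                        section[fname] = tuple(tuple(v) if isinstance(v, list) else v
                                               for v in val)
                kwargs[key] = _from_mapping(sub, section, key)
        for key in ("seed", "input_dir"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _load_subjects(config: RunConfig, out: Path) -> dict[str, EEGTrialSet]:
    subjects: dict[str, EEGTrialSet] = {}
    if config.input_dir is not None:
        for f in sorted(Path(config.input_dir).glob("*.npz")):
            subjects[f.stem] = read_trials(f)
        if not subjects:
            raise ValueError(f"no trial archives (*.npz) in {config.input_dir}")
        return subjects
    trial_dir = out / "trials"
    for s in range(config.simulate.n_subjects):
        name = f"S{s + 1:02d}"
        spec = config.simulate.spec_for(s, substream(config.seed, f"simulate/{name}"))
        trials = generate_subject(spec)
        write_trials(trial_dir / f"{name}.npz", trials)
        subjects[name] = trials
    return subjects


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full protocol; returns the summary dict (also written
    to ``summary.json``).  Any stage failure aborts with the stage named;
    artifacts of completed stages remain on disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "subjects": {},
    }
    try:
        stage = "simulate/load"
        subjects = _load_subjects(config, out)
        log.info("stage %s: %d subjects", stage, len(subjects))

        stage = "preprocess"
        prepped = {name: preprocess(tr, config.preprocess)
                   for name, tr in subjects.items()}

        stage = "train/evaluate"
        per_subject_folds = {}
        fitted = {}
        for name, tr in prepped.items():
            seed = substream(config.seed, f"cv/{name}")
            base = config.model.build(seed=substream(config.seed, f"init/{name}"))
            if config.evaluation.grid_search and len(config.evaluation.nf_grid) > 0:
                best_nf, means, folds = grid_search_nf(
                    tr.data, tr.labels, base, candidates=config.evaluation.nf_grid,
                    n_folds=config.evaluation.n_folds, seed=seed)
                fold_metrics = folds[best_nf]
            else:
                best_nf = config.model.n_filters
                means = {}
                fold_metrics = cross_validate(
                    tr.data, tr.labels, base, n_folds=config.evaluation.n_folds,
                    seed=seed)
            per_subject_folds[name] = fold_metrics
            final = config.model.build(seed=substream(config.seed, f"init/{name}"))
            final.set_params(n_filters=best_nf)
            final.fit(tr.data, tr.labels)
            save_model(out / "models" / f"{name}.npz", final)
            fitted[name] = final
            summary["subjects"][name] = {
                "best_nf": int(best_nf),
                "grid_mean_accuracy": {str(k): v for k, v in means.items()},
                "folds": [f.as_dict() for f in fold_metrics],
                "n_parameters": int(final.n_parameters_),
            }

        stage = "score matrix"
        scores = build_score_matrix(per_subject_folds)
        scores.rename_axis("subject").to_csv(out / "scores.csv")

        stage = "grouping"
        if len(scores) >= config.analysis.k:
            groups = cluster_subjects(scores, k=config.analysis.k,
                                      seed=substream(config.seed, "kmeans"))
            summary["groups"] = groups.labels
            summary["ordering"] = groups.ordering
            (out / "groups.json").write_text(json.dumps(
                {"labels": groups.labels, "ordering": groups.ordering,
                 "centroids": groups.centroids.tolist()},
                indent=2, sort_keys=True, default=_jsonable))
        else:
            warnings.warn("fewer subjects than clusters: grouping skipped")
            summary["groups"] = None

        stage = "connectivity analysis"
        mean_conn = {}
        pair_index = None
        for name, tr in prepped.items():
            conn = fitted[name].connectivity(tr.data)
            pair_index = conn.pair_index
            pmat = prune_connections(conn, tr.labels, alpha=config.analysis.alpha)
            pd.DataFrame(pmat.p, index=tr.channel_names,
                         columns=tr.channel_names).to_csv(out / f"pvalues_{name}.csv")
            rel_p = channel_relevance("pvalues", pmat)
            rel_w = channel_relevance("weights", fitted[name].readout_weights_,
                                      n_channels=tr.n_channels)
            pd.DataFrame({"channel": tr.channel_names, "rel_pvalues": rel_p,
                          "rel_weights": rel_w}).to_csv(
                out / f"relevance_{name}.csv", index=False)
            mean_conn[name] = conn.values.mean(axis=0)
            summary["subjects"][name].update(
                renyi_entropy_bits=renyi_entropy(pmat),
                n_significant_pairs=int(pmat.mask[np.triu_indices(pmat.n_channels, 1)].sum()),
            )

        stage = "edges"
        edges = top_percentile_edges(mean_conn, pair_index, q=config.analysis.percentile)
        for name, df in edges.items():
            df.to_csv(out / f"edges_{name}.csv", index=False)
            summary["subjects"][name]["n_top_edges"] = int(len(df))

        stage = "t-SNE layout"
        n = len(scores)
        perp = min(config.analysis.perplexity, n - 1)
        if perp < config.analysis.perplexity:
            warnings.warn(f"perplexity reduced to {perp} for {n} subjects")
        if n >= 3:
            emb = tsne_layout(scores, perplexity=perp,
                              seed=substream(config.seed, "tsne"))
            pd.DataFrame(emb, index=scores.index,
                         columns=["x", "y"]).rename_axis("subject").to_csv(out / "tsne.csv")
    except ValueError as exc:
        log.exception("pipeline failed at stage %r", stage)
        raise ValueError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    except Exception as exc:
        log.exception("pipeline failed at stage %r", stage)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_jsonable))
    return summary
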