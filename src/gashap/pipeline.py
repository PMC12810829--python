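"""End-to-end orchestration: data -> classifier -> heatmaps -> GA masks.

Runs the full workflow into a run directory:

1. generate (or load) a cohort with its parcellation atlas;
2. train the 3D CNN and keep the best-validation checkpoint;
3. compute one attribution heatmap per training-split volume;
4. per binning scheme: encode the heatmaps into a chromosome population,
   prune consensus-unimportant regions, evolve masks with the GA;
5. intersect the schemes' selected region sets and write a report.

Every artifact lands as NIfTI or delimited text under the run directory
and carries the seed and a hash of the configuration; re-running with the
same configuration and seed reproduces the outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .attribution import Heatmap, compute_heatmap
from .classifier import CNNSpec, TrainConfig, TrainedClassifier, masked_accuracy, train
from .ga import ClassifierMaskEvaluator, GAConfig, GARunResult, prune_initial_regions, run_ga
from .io import (
    LabelAtlas,
    LabeledDataset,
    Volume,
    read_atlas,
    read_manifest,
    read_volume,
    write_volume,
)
from .morphology import StructuringElement, build_mask
from .scoring import (
    GENE_LABELS,
    GENE_OPERATIONS,
    SCHEME_A,
    SCHEME_B,
    BinningScheme,
    chromosome_table,
    heatmaps_to_population,
    region_scores,
)
from .synthetic import SyntheticSpec, generate_atlas, generate_cohort, write_cohort

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "run_pipeline",
    "make_report",
    "recovery_experiment",
]

SCHEMES = {"A": SCHEME_A, "B": SCHEME_B}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PipelineConfig:
    """Declarative configuration of one full run.

    The default mode is synthetic (``synthetic`` spec used); pointing
    ``manifest`` at a (path, class, split) table plus ``atlas_labels`` /
    ``atlas_names`` switches to preprocessed real volumes.  The GA defaults
    here are desk-scale (small population, few generations) so a complete
    run finishes in minutes on one CPU; the full-scale values live in
    :class:`~gashap.ga.GAConfig` defaults.
    """

    seed: int = 0
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    manifest: str | None = None
    atlas_labels: str | None = None
    atlas_names: str | None = None
    cnn: CNNSpec = field(default_factory=CNNSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    attribution_backend: str = "grad_input"
    attribution_params: dict = field(default_factory=dict)
    correct_only: bool = False  # restrict heatmaps to correctly classified samples
    schemes: tuple[str, ...] = ("A", "B")
    ga: GAConfig = field(default_factory=lambda: GAConfig(population_cap=16, max_generations=12))
    prune_theta: float = 0.5
    se_connectivity: int = 6
    se_iterations: int = 1
    mask_fill: float = 0.0

    def __post_init__(self) -> None:
        if not self.schemes:
            raise ValueError("at least one binning scheme is required")
        for s in self.schemes:
            if s not in SCHEMES:
                raise ValueError(f"unknown scheme {s!r}; choose from {sorted(SCHEMES)}")

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        """Canonical plain-type dict (tuples as lists, numpy scalars native)."""

        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, np.generic):
                return obj.item()
            return obj

        return clean(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (
            ("synthetic", SyntheticSpec),
            ("cnn", CNNSpec),
            ("train", TrainConfig),
            ("ga", GAConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if "schemes" in d:
            d["schemes"] = tuple(d["schemes"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> Path:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return Path(path)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    @property
    def element(self) -> StructuringElement:
        return StructuringElement(self.se_connectivity, self.se_iterations)


def _stage(name: str):
    """Wrap a stage so failures abort with the stage name and cause."""

    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - reported with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        wrapped.__name__ = fn.__name__
        wrapped.__doc__ = fn.__doc__
        return wrapped

    return deco


# ---------------------------------------------------------------------------
# stages


@_stage("synth")
def stage_synth(cfg: PipelineConfig, rundir: Path) -> tuple[LabelAtlas, LabeledDataset, np.ndarray]:
    """Generate or load the cohort + atlas; persist the synthetic one."""
    if cfg.manifest is not None:
        if cfg.atlas_labels is None or cfg.atlas_names is None:
            raise ValueError("manifest mode needs atlas_labels and atlas_names paths")
        ds = read_manifest(cfg.manifest)
        atlas = read_atlas(cfg.atlas_labels, cfg.atlas_names)
        for v in ds.volumes:
            if v.shape != atlas.shape:
                raise ValueError(f"volume shape {v.shape} != atlas shape {atlas.shape}")
        return atlas, ds, np.array([], dtype=np.int64)
    spec = dataclasses.replace(cfg.synthetic, seed=cfg.seed)
    atlas = generate_atlas(spec)
    ds, signal = generate_cohort(atlas, spec)
    write_cohort(atlas, ds, signal, rundir / "data")
    return atlas, ds, signal


@_stage("train")
def stage_train(cfg: PipelineConfig, rundir: Path, ds: LabeledDataset) -> TrainedClassifier:
    cnn = dataclasses.replace(cfg.cnn, input_shape=ds.volumes[0].shape)
    tcfg = dataclasses.replace(cfg.train, seed=cfg.seed + 1)
    clf = train(cnn, ds, tcfg)
    clf.save(rundir / "classifier.npz")
    clf.history.to_csv(rundir / "training_history.csv", index=False)
    return clf


@_stage("explain")
def stage_explain(
    cfg: PipelineConfig,
    rundir: Path,
    clf: TrainedClassifier,
    ds: LabeledDataset,
    atlas: LabelAtlas,
) -> list[Heatmap]:
    """One heatmap per training-split volume (predicted class by default)."""
    xtr, ytr = ds.subset("train")
    keep = np.arange(len(ytr))
    if cfg.correct_only:
        keep = np.flatnonzero(clf.predict(xtr) == ytr)
        if len(keep) == 0:
            raise ValueError("no correctly classified training volumes to explain")
    params = dict(cfg.attribution_params)
    if cfg.attribution_backend == "region_shapley":
        params.setdefault("atlas", atlas)
    hdir = rundir / "heatmaps"
    hdir.mkdir(parents=True, exist_ok=True)
    heatmaps, rows = [], []
    for i in keep:
        h = compute_heatmap(
            clf, Volume(xtr[i]), backend=cfg.attribution_backend,
            seed=cfg.seed + 3, **params,
        )
        heatmaps.append(h)
        rel = f"heatmaps/heatmap{i:04d}.nii.gz"
        write_volume(Volume(h.values.astype(np.float32)), rundir / rel)
        rows.append({"train_index": int(i), "heatmap": rel, "target_class": h.target_class})
    pd.DataFrame(rows).to_csv(rundir / "heatmap_manifest.csv", index=False)
    return heatmaps


@_stage("evolve")
def stage_evolve(
    cfg: PipelineConfig,
    rundir: Path,
    heatmaps: list[Heatmap],
    atlas: LabelAtlas,
    clf: TrainedClassifier,
    ds: LabeledDataset,
) -> dict[str, GARunResult]:
    xtr, ytr = ds.subset("train")
    xte, yte = ds.subset("test")
    train_eval = ClassifierMaskEvaluator(clf, xtr, ytr, fill=cfg.mask_fill)
    test_eval = (
        ClassifierMaskEvaluator(clf, xte, yte, fill=cfg.mask_fill) if len(yte) else None
    )
    results: dict[str, GARunResult] = {}
    for si, name in enumerate(cfg.schemes):
        scheme = SCHEMES[name]
        sdir = rundir / f"scheme_{name}"
        sdir.mkdir(parents=True, exist_ok=True)
        population = heatmaps_to_population(heatmaps, atlas, scheme)
        mean_scores = np.mean([region_scores(h, atlas) for h in heatmaps], axis=0)
        pruned = prune_initial_regions(population, theta=cfg.prune_theta)
        gacfg = dataclasses.replace(cfg.ga, seed=cfg.seed + 10 + si)
        result = run_ga(
            pruned.population,
            train_eval,
            atlas,
            gacfg,
            se=cfg.element,
            active=pruned.active,
            test_evaluator=test_eval,
        )
        result.trajectory.to_csv(sdir / "trajectory.csv", index=False)
        np.savetxt(sdir / "best_chromosome.txt", result.best_genes, fmt="%d")
        write_volume(
            Volume(result.best_mask.mask.astype(np.float32)), sdir / "mask.nii.gz"
        )
        chromosome_table(result.best_genes, atlas, scores=mean_scores).to_csv(
            sdir / "region_table.csv", index=False
        )
        results[name] = result
    return results


@_stage("report")
def stage_report(
    cfg: PipelineConfig,
    rundir: Path,
    results: dict[str, GARunResult],
    atlas: LabelAtlas,
    clf: TrainedClassifier,
    ds: LabeledDataset,
) -> dict:
    from .ga import intersect_runs

    names = list(results)
    summary: dict = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "best_val_accuracy": float(clf.history["val_acc"].max()),
        "schemes": {},
    }
    xte, yte = ds.subset("test")
    if len(yte):
        _, test_acc = masked_accuracy(
            clf, xte, yte, np.ones(atlas.shape, dtype=bool), fill=cfg.mask_fill
        )
        summary["test_accuracy_unmasked"] = float(test_acc)
    for name, res in results.items():
        summary["schemes"][name] = {
            "best_fitness": res.best_record.fitness,
            "best_f1_train": res.best_record.f1,
            "n_regions": res.best_record.n_regions,
            "initial_active_regions": res.initial_active_regions,
            "generations": res.n_generations,
            "selected_region_ids": sorted(
                int(atlas.region_ids[r - 1]) for r in res.selected_regions
            ),
        }
    if len(names) >= 2:
        inter = intersect_runs(results[names[0]], results[names[1]])
        for extra in names[2:]:
            inter &= results[extra].selected_regions
        rows = []
        for r in sorted(inter):
            rows.append(
                {
                    "internal_id": r,
                    "region_id": int(atlas.region_ids[r - 1]),
                    "name": atlas.region_names[r - 1],
                }
            )
        pd.DataFrame(
            rows, columns=["internal_id", "region_id", "name"]
        ).to_csv(rundir / "intersection_table.csv", index=False)
        summary["intersection_region_ids"] = [row["region_id"] for row in rows]
    with open(rundir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def run_pipeline(cfg: PipelineConfig, rundir: str | Path) -> dict:
    """Execute all stages into ``rundir``; returns the summary dict."""
    rundir = Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(rundir / "config.yaml")
    atlas, ds, _signal = stage_synth(cfg, rundir)
    clf = stage_train(cfg, rundir, ds)
    heatmaps = stage_explain(cfg, rundir, clf, ds, atlas)
    results = stage_evolve(cfg, rundir, heatmaps, atlas, clf, ds)
    return stage_report(cfg, rundir, results, atlas, clf, ds)


# ---------------------------------------------------------------------------
# ground-truth recovery experiment


def recovery_experiment(
    seed: int,
    spec: SyntheticSpec | None = None,
    max_generations: int = 60,
    prune_theta: float = 0.5,
) -> dict[str, float]:
    """Measure how well the GA recovers the planted signal regions.

    Builds the synthetic cohort, initializes the population from
    gradient-based heatmaps of the deterministic intensity surrogate (so no
    stochastic training enters the loop), prunes by consensus, and evolves
    against the region-recovery evaluator, whose f1 is the recovered
    fraction of planted regions.  The stop rule is disabled so the
    compactness pressure has the full generation budget to prune false
    positives.  Returns recall/precision of the selected region set against
    the planted truth and the fractional reduction in active regions.
    """
    from .attribution import compute_heatmap as _compute_heatmap
    from .classifier import SurrogateClassifier
    from .ga import PlantedRegionEvaluator

    spec = dataclasses.replace(spec or SyntheticSpec(), seed=seed)
    atlas = generate_atlas(spec)
    ds, planted = generate_cohort(atlas, spec)
    xtr, ytr = ds.subset("train")
    surrogate = SurrogateClassifier().fit_threshold(xtr, ytr)
    heatmaps = [
        _compute_heatmap(surrogate, Volume(x), backend="grad_input", target=1)
        for x in xtr[ytr == 1]
    ]
    population = heatmaps_to_population(heatmaps, atlas, SCHEME_A)
    pruned = prune_initial_regions(population, theta=prune_theta)
    result = run_ga(
        pruned.population,
        PlantedRegionEvaluator(atlas, planted),
        atlas,
        GAConfig(stop_tol=None, max_generations=max_generations, seed=seed),
        active=pruned.active,
    )
    selected = result.selected_regions
    truth = set(int(r) for r in planted)
    return {
        "recall": len(selected & truth) / len(truth),
        "precision": len(selected & truth) / len(selected),
        "region_reduction": 1.0 - result.best_record.n_regions / result.initial_active_regions,
    }


# ---------------------------------------------------------------------------
# reloading artifacts so the CLI verbs compose


def load_cohort(rundir: str | Path) -> tuple[LabelAtlas, LabeledDataset, np.ndarray]:
    """Reload the persisted synthetic cohort from ``rundir/data``."""
    data = Path(rundir) / "data"
    needed = [data / "manifest.csv", data / "atlas_labels.nii.gz", data / "atlas_names.tsv"]
    missing = [str(p) for p in needed if not p.exists()]
    if missing:
        raise PipelineError(f"no cohort in run directory; missing {missing}")
    ds = read_manifest(data / "manifest.csv")
    atlas = read_atlas(data / "atlas_labels.nii.gz", data / "atlas_names.tsv")
    sig_path = data / "signal_regions.txt"
    signal = (
        np.atleast_1d(np.loadtxt(sig_path, dtype=np.int64))
        if sig_path.exists()
        else np.array([], dtype=np.int64)
    )
    return atlas, ds, signal


def load_heatmaps(rundir: str | Path) -> list[Heatmap]:
    """Reload the heatmaps written by the explain stage."""
    rundir = Path(rundir)
    manifest = rundir / "heatmap_manifest.csv"
    if not manifest.exists():
        raise PipelineError(f"no heatmaps in run directory; missing {manifest}")
    df = pd.read_csv(manifest)
    return [
        Heatmap(
            values=read_volume(rundir / row["heatmap"]).data.astype(np.float64),
            target_class=int(row["target_class"]),
        )
        for _, row in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# post-hoc reporting from a completed run directory


def make_report(rundir: str | Path) -> dict[str, Path]:
    """Emit final region tables and trajectory plots from a completed run.

    The region table keeps only selected regions (gene > 0), labelled with
    their importance class (IR/VIR/VVIR) and morphological operation.
    Raises if expected artifacts are missing, listing them.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rundir = Path(rundir)
    cfg = PipelineConfig.from_yaml(rundir / "config.yaml")
    missing = [
        str(p)
        for name in cfg.schemes
        for p in (
            rundir / f"scheme_{name}" / "trajectory.csv",
            rundir / f"scheme_{name}" / "region_table.csv",
        )
        if not p.exists()
    ]
    if missing:
        raise PipelineError(f"incomplete run directory; missing artifacts: {missing}")
    outputs: dict[str, Path] = {}
    for name in cfg.schemes:
        sdir = rundir / f"scheme_{name}"
        table = pd.read_csv(sdir / "region_table.csv")
        final = table[table["gene"] > 0].reset_index(drop=True)
        out = sdir / "final_regions.csv"
        final.to_csv(out, index=False)
        outputs[f"final_regions_{name}"] = out

        traj = pd.read_csv(sdir / "trajectory.csv")
        fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
        axes[0].plot(traj["generation"], traj["best_fitness"], label="best")
        axes[0].plot(traj["generation"], traj["mean_fitness"], label="mean")
        axes[0].set_ylabel("fitness")
        axes[0].legend()
        axes[1].plot(traj["generation"], traj["best_f1_train"], label="train")
        if "best_f1_test" in traj:
            axes[1].plot(traj["generation"], traj["best_f1_test"], label="test")
        axes[1].set_ylabel("masked accuracy")
        axes[1].legend()
        axes[2].plot(traj["generation"], traj["best_n_regions"])
        axes[2].set_ylabel("regions in best mask")
        for ax in axes:
            ax.set_xlabel("generation")
        fig.suptitle(f"scheme {name}")
        fig.tight_layout()
        plot = sdir / "trajectories.png"
        fig.savefig(plot, dpi=110)
        plt.close(fig)
        outputs[f"plot_{name}"] = plot
    return outputs
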