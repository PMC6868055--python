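"""End-to-end experiment drivers.

Three reproducible studies built from the library modules:

* ``run_kinet_radial`` — classify simulated inner-kinetochore images by the
  radial displacement of the Cse4 convergence point (classes 0/25/50/100 nm
  by default) with the CNN.
* ``run_nucleolus_mu`` — classify simulated rDNA-locus images by the mean
  crosslink duration mu (classes 0.09/0.19/1.6 s by default) with the CNN.
* ``run_feature_analysis`` — extract the 13 features from two simulated
  image classes, rank them by PCA importance, and validate the ranking by
  comparing repeated-split SVM accuracy distributions on all / top-2 /
  bottom-2 feature subsets with rank-sum tests.

Each driver consumes an :class:`ExperimentConfig`, derives all randomness
from its master seed, and returns a report carrying the confusion matrix
or statistics plus a manifest sufficient to regenerate it.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import cnn as cnn_mod
from . import features as feat_mod
from . import stats as stats_mod
from .kinet_model import (KinetochoreProteinParams, Nuf2Params, SpindleParams,
                          Spc29Params, build_model)
from .microscope_sim import ImageStack, NoiseParams, OpticsParams, add_noise, render_stack
from .polymer_model import (PolymerParams, rdna_only_params, run_trajectory,
                            snapshot_to_fluorophores)
from .preprocess import process_stack

__all__ = ["ExperimentConfig", "ExperimentReport", "generate_kinet_dataset",
           "generate_nucleolus_dataset", "run_kinet_radial",
           "run_nucleolus_mu", "run_feature_analysis", "classify_external"]

logger = logging.getLogger(__name__)

AUGMENT_FACTOR = 8     # dihedral orientations per source stack


@dataclass
class ExperimentConfig:
    """Shared configuration of the experiment drivers.

    ``classes`` maps class name -> parameter value (radial displacement in
    nm, or mu in s, depending on the experiment). ``images_per_class`` is
    rounded down to a multiple of 8 (the dihedral augmentation factor).
    """

    name: str = "kinet_radial"
    classes: dict = field(default_factory=dict)
    images_per_class: int = 400
    seed: int = 0
    spindle: SpindleParams = field(default_factory=SpindleParams)
    optics: OpticsParams = field(default_factory=OpticsParams)
    noise: NoiseParams = field(default_factory=NoiseParams)
    train: cnn_mod.TrainConfig | None = None
    split: cnn_mod.SplitSpec | None = None

    def __post_init__(self) -> None:
        if self.name not in ("kinet_radial", "nucleolus_mu", "feature_analysis"):
            raise ValueError(f"unknown experiment {self.name!r}")
        if not self.classes:
            self.classes = default_classes(self.name)
        if len(self.classes) < 2:
            raise ValueError("an experiment needs >= 2 classes")
        if self.images_per_class < 10:
            raise ValueError("images_per_class must be >= 10")
        if self.train is None:
            # desk-scale datasets: smaller minibatches keep the number of
            # SGD updates adequate under the fixed 20-epoch cap
            self.train = cnn_mod.TrainConfig(batch_size=32, seed=self.seed)
        if self.split is None:
            self.split = cnn_mod.SplitSpec(seed=self.seed)


def default_classes(name: str) -> dict:
    if name == "nucleolus_mu":
        return {"mu=0.09s": 0.09, "mu=0.19s": 0.19, "mu=1.6s": 1.6}
    if name == "feature_analysis":
        return {"inner": 100.0, "outer": 0.0}
    return {"0nm": 0.0, "25nm": 25.0, "50nm": 50.0, "100nm": 100.0}


@dataclass
class ExperimentReport:
    """Outcome of one driver run, with enough provenance to regenerate it."""

    name: str
    class_names: list
    confusion: cnn_mod.ConfusionMatrix | None
    test_accuracy: float | None
    validation_accuracy: float | None
    per_class_counts: dict
    manifest: dict
    history: dict | None = None
    extras: dict = field(default_factory=dict)


# ----------------------------------------------------------------- generators

def _default_proteins(radial_displacement: float) -> dict:
    return dict(
        nuf2=Nuf2Params(),
        spc29=Spc29Params(),
        kinetochore=KinetochoreProteinParams(
            radial_displacement=radial_displacement),
    )


def generate_kinet_dataset(displacements: dict,
                           images_per_class: int,
                           seed: int,
                           spindle: SpindleParams | None = None,
                           optics: OpticsParams | None = None,
                           noise: NoiseParams | None = None,
                           protein_overrides: dict | None = None,
                           ) -> tuple[np.ndarray, np.ndarray, list]:
    """Simulate, render and preprocess kinetochore images for each class.

    Each model instance yields 8 oriented images, so ``images_per_class``
    is served by ``images_per_class // 8`` independent model draws.
    Returns (images uint16 (n, 50, 50, 3), integer labels, class names).
    """
    spindle = spindle or SpindleParams()
    optics = optics or OpticsParams()
    noise = noise or NoiseParams()
    class_names = list(displacements)
    ss = np.random.SeedSequence(seed)
    class_seeds = ss.spawn(len(class_names))
    images, labels = [], []
    for ci, name in enumerate(class_names):
        n_models = max(images_per_class // AUGMENT_FACTOR, 1)
        model_seeds = class_seeds[ci].spawn(n_models)
        proteins = _default_proteins(displacements[name])
        if protein_overrides:
            proteins.update(protein_overrides.get(name, {}))
        for ms in model_seeds:
            s_model, s_noise = (int(x.generate_state(1)[0] % (2**31 - 1))
                                for x in ms.spawn(2))
            fluors = build_model(spindle, s_model, **proteins)
            fluors = fluors.restrict_channels(optics.channel_names)
            stack = add_noise(render_stack(fluors, optics), noise, s_noise)
            for img in process_stack(stack, source_id=f"{name}/{s_model}"):
                images.append(img.pixels)
                labels.append(ci)
    return np.array(images), np.array(labels), class_names


def generate_nucleolus_dataset(mus: dict,
                               images_per_class: int,
                               seed: int,
                               optics: OpticsParams | None = None,
                               noise: NoiseParams | None = None,
                               rdna_only: bool = True,
                               polymer_overrides: dict | None = None,
                               burn_in_steps: int = 60000,
                               sample_every: int = 2500,
                               snapshots_per_trajectory: int = 2,
                               ) -> tuple[np.ndarray, np.ndarray, list]:
    """Simulate polymer trajectories per mu class and render rDNA images.

    Snapshots are taken ``sample_every`` steps apart after a burn-in, so
    consecutive images within a trajectory are decorrelated by many bead
    relaxation times; multiple independent trajectories supply the class.
    """
    optics = optics or OpticsParams()
    if set(optics.wavelengths) != {"red"}:
        # rDNA beads are the only emitters; rendering (and normalizing) a
        # signal-free channel would just amplify camera noise
        optics = dataclasses.replace(
            optics, wavelengths={"red": optics.wavelengths.get("red", 580.0)})
    noise = noise or NoiseParams()
    class_names = list(mus)
    ss = np.random.SeedSequence(seed)
    class_seeds = ss.spawn(len(class_names))
    images, labels = [], []
    for ci, name in enumerate(class_names):
        n_stacks = max(images_per_class // AUGMENT_FACTOR, 1)
        n_traj = int(np.ceil(n_stacks / snapshots_per_trajectory))
        traj_seeds = class_seeds[ci].spawn(n_traj)
        made = 0
        for ts in traj_seeds:
            s_traj, s_noise_base = (int(x.generate_state(1)[0] % (2**31 - 1))
                                    for x in ts.spawn(2))
            overrides = dict(polymer_overrides or {})
            params = (rdna_only_params(mu=mus[name], **overrides) if rdna_only
                      else PolymerParams(mu=mus[name], **overrides))
            traj = run_trajectory(params,
                                  total_steps=sample_every * snapshots_per_trajectory,
                                  sample_every=sample_every, seed=s_traj,
                                  burn_in_steps=burn_in_steps)
            for k in range(len(traj.times)):
                if made >= n_stacks:
                    break
                fluors = snapshot_to_fluorophores(traj, k)
                stack = add_noise(render_stack(fluors, optics), noise,
                                  (s_noise_base + k) % (2**31 - 1))
                for img in process_stack(stack, source_id=f"{name}/{s_traj}/{k}"):
                    images.append(img.pixels)
                    labels.append(ci)
                made += 1
    return np.array(images), np.array(labels), class_names


# -------------------------------------------------------------------- drivers

def _group_split(labels: np.ndarray, spec: cnn_mod.SplitSpec,
                 group_size: int = AUGMENT_FACTOR) -> tuple:
    """Split whole source stacks: the 8 orientations of one stack are
    near-duplicates, so image-level splits would leak test content into
    training and inflate every accuracy (including the indistinguishable-
    classes control, which must sit at chance)."""
    n = len(labels)
    assert n % group_size == 0, "labels not grouped by source stack"
    group_labels = labels[::group_size]
    g_train, g_val, g_test = cnn_mod.split_dataset(group_labels, spec)
    expand = (lambda g: (g[:, None] * group_size
                         + np.arange(group_size)[None, :]).ravel())
    return expand(g_train), expand(g_val), expand(g_test)


def _train_and_evaluate(images: np.ndarray, labels: np.ndarray,
                        class_names: list, config: ExperimentConfig) -> tuple:
    x = cnn_mod.images_to_tensor(images)
    labels = np.asarray(labels)
    train_idx, val_idx, test_idx = _group_split(labels, config.split)
    model = cnn_mod.build_cnn(
        cnn_mod.CNNConfig(n_classes=len(class_names)), seed=config.seed)
    history = cnn_mod.train_cnn(model, x, labels, (train_idx, val_idx),
                                config.train)
    confusion = cnn_mod.evaluate(model, x[test_idx], labels[test_idx],
                                 class_names)
    return model, history, confusion, labels, (train_idx, val_idx, test_idx)


def _report(name, class_names, confusion, history, labels, config,
            t0, extras=None) -> ExperimentReport:
    counts = {c: int((np.asarray(labels) == i).sum())
              for i, c in enumerate(class_names)}
    manifest = {
        "experiment": name,
        "seed": config.seed,
        "classes": config.classes,
        "images_per_class": config.images_per_class,
        "split": dataclasses.asdict(config.split),
        "train": dataclasses.asdict(config.train),
        "runtime_s": round(time.monotonic() - t0, 2),
    }
    acc = confusion.accuracy if confusion is not None else None
    if acc is not None and acc < 0.70:
        manifest["recommendation"] = ("iterate: classification below the 70% "
                                      "go/no-go gate")
    else:
        manifest["recommendation"] = "proceed"
    return ExperimentReport(
        name=name, class_names=class_names, confusion=confusion,
        test_accuracy=acc,
        validation_accuracy=(history or {}).get("final_validation_accuracy"),
        per_class_counts=counts, manifest=manifest, history=history,
        extras=extras or {})


def run_kinet_radial(config: ExperimentConfig) -> ExperimentReport:
    """Radial-displacement classification study (CNN on simulated images)."""
    t0 = time.monotonic()
    logger.info("generating kinetochore dataset: %s", config.classes)
    images, labels, class_names = generate_kinet_dataset(
        config.classes, config.images_per_class, config.seed,
        spindle=config.spindle, optics=config.optics, noise=config.noise)
    logger.info("training CNN on %d images", len(images))
    model, history, confusion, labels, _ = _train_and_evaluate(
        images, labels, class_names, config)
    return _report("kinet_radial", class_names, confusion, history, labels,
                   config, t0, extras={"model": model})


def run_nucleolus_mu(config: ExperimentConfig,
                     **dataset_kwargs) -> ExperimentReport:
    """Crosslink-duration classification study (CNN on simulated rDNA images)."""
    t0 = time.monotonic()
    logger.info("generating nucleolus dataset: %s", config.classes)
    images, labels, class_names = generate_nucleolus_dataset(
        config.classes, config.images_per_class, config.seed,
        optics=config.optics, noise=config.noise, **dataset_kwargs)
    logger.info("training CNN on %d images", len(images))
    model, history, confusion, labels, _ = _train_and_evaluate(
        images, labels, class_names, config)
    return _report("nucleolus_mu", class_names, confusion, history, labels,
                   config, t0, extras={"model": model})


def run_feature_analysis(config: ExperimentConfig,
                         n_reps: int = 30) -> ExperimentReport:
    """PCA importance ranking + SVM validation on two simulated classes.

    The two classes are kinetochore models whose class value is the
    radial displacement of the inner-kinetochore protein. Images are
    feature-extracted (flagged ones dropped; >50% flagged aborts), the
    features ranked by PCA importance, and SVM accuracy distributions
    compared between all features, the top 2 and the bottom 2.
    """
    t0 = time.monotonic()
    if len(config.classes) != 2:
        raise ValueError("feature analysis compares exactly 2 classes")
    images, labels, class_names = generate_kinet_dataset(
        config.classes, config.images_per_class, config.seed,
        spindle=config.spindle, optics=config.optics, noise=config.noise)
    # one orientation per source stack: the 13 features are invariant
    # under the dihedral orientations, so the other 7 are exact duplicate
    # rows that would leak across SVM train/test splits
    originals = np.arange(0, len(images), AUGMENT_FACTOR)
    images, labels = images[originals], np.asarray(labels)[originals]
    records, kept_labels, n_flagged = [], [], 0
    for img, lab in zip(images, labels):
        rec, flag = feat_mod.extract_features(img)
        if rec is None:
            n_flagged += 1
            logger.debug("flagged image (%s)", flag)
        else:
            records.append(rec)
            kept_labels.append(lab)
    if n_flagged > 0.5 * len(images):
        raise RuntimeError(
            f"{n_flagged}/{len(images)} images flagged during feature "
            f"extraction; the model classes do not produce analyzable foci")
    matrix = np.array([r.as_array() for r in records])
    kept_labels = np.array(kept_labels)
    ranking = stats_mod.pca_importance(matrix, feat_mod.FEATURE_NAMES)
    subsets = {
        "all": list(feat_mod.FEATURE_NAMES),
        "top2": ranking.top(2),
        "bottom2": ranking.bottom(2),
    }
    ss = np.random.SeedSequence(config.seed)
    subset_seeds = {k: int(s.generate_state(1)[0] % (2**31 - 1))
                    for k, s in zip(subsets, ss.spawn(len(subsets)))}
    dists = {k: stats_mod.repeated_accuracy(
        matrix, kept_labels, feature_subset=v,
        feature_names=feat_mod.FEATURE_NAMES, n_reps=n_reps,
        seed=subset_seeds[k]) for k, v in subsets.items()}
    pvals = {
        "all_vs_top2": stats_mod.compare_distributions(dists["all"], dists["top2"]),
        "all_vs_bottom2": stats_mod.compare_distributions(dists["all"],
                                                          dists["bottom2"]),
    }
    extras = {"ranking": ranking, "accuracy_distributions": dists,
              "p_values": pvals, "n_flagged": n_flagged,
              "n_images": len(images)}
    return _report("feature_analysis", class_names, None, None, kept_labels,
                   config, t0, extras=extras)


def classify_external(model: cnn_mod.SimpleCNN, images: np.ndarray,
                      class_names: list) -> dict:
    """Classify user images under the simulated-class model (count summary)."""
    if len(images) == 0:
        return {c: 0 for c in class_names}
    _, counts = cnn_mod.predict(model, images, class_names)
    return counts
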