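"""Sample-level 5-fold partitioning and within-class spectral augmentation.

Spectra are partitioned into folds *by sample* before any augmentation, so
that augmented training spectra can never share source samples with the
validation or test sets (split-then-augment). With the canonical 110-sample
layout and 5 folds, each fold holds 22 samples; one fold serves as the test
set and one as the validation set in each of the five rotations, giving
66 training samples which the default x10 augmentation expands to 660
spectra (and 220 validation / 220 test).

Augmentation generates, for each original spectrum, ``factor`` synthetic
spectra, each a convex combination of three same-group spectra from the same
subset with weights drawn from the uniform Dirichlet on the simplex. Convex
weights keep every augmented spectrum inside the convex hull of its sources,
so the group's spectral distribution is preserved in the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AugmentationError, ConfigError
from .io import Spectrum, SpectrumSet
from .preprocess import minmax_normalize

__all__ = ["FoldPlan", "AugmentConfig", "make_folds", "augment", "build_datasets"]


@dataclass
class FoldPlan:
    """Assignment of samples to folds and of folds to roles per rotation."""

    n_folds: int
    assignments: dict[str, int]
    rotations: list[dict[str, object]] = field(default_factory=list)

    def __post_init__(self) -> None:
        folds = set(self.assignments.values())
        if folds and (min(folds) < 0 or max(folds) >= self.n_folds):
            raise ConfigError("fold index out of range")
        if not self.rotations:
            self.rotations = [
                {
                    "test": r,
                    "val": (r + 1) % self.n_folds,
                    "train": [
                        f
                        for f in range(self.n_folds)
                        if f not in (r, (r + 1) % self.n_folds)
                    ],
                }
                for r in range(self.n_folds)
            ]

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.n_folds
        for f in self.assignments.values():
            sizes[f] += 1
        return sizes

    def samples_in(self, folds) -> set[str]:
        folds = {folds} if isinstance(folds, int) else set(folds)
        return {sid for sid, f in self.assignments.items() if f in folds}


@dataclass
class AugmentConfig:
    factor: int = 10
    n_components: int = 3
    weight_law: str = "dirichlet_uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.factor < 1:
            raise ConfigError("factor must be >= 1")
        if self.n_components < 2:
            raise ConfigError("n_components must be >= 2")
        if self.weight_law not in ("dirichlet_uniform", "degenerate_first"):
            raise ConfigError(f"unknown weight_law {self.weight_law!r}")


def make_folds(
    s: SpectrumSet, n_folds: int = 5, seed: int = 0, stratified: bool = True
) -> FoldPlan:
    """Randomly partition samples into ``n_folds`` folds.

    Stratified partitioning (default) spreads each group across folds as
    evenly as integer counts allow, preserving the 30/30/30/20 balance per
    fold; non-stratified shuffles all samples together. Deterministic given
    ``seed``.
    """
    seen: dict[str, str | None] = {}
    for sp in s:
        seen.setdefault(sp.sample_id, sp.group)
    sample_ids = list(seen)
    if n_folds > len(sample_ids):
        raise ConfigError(f"n_folds {n_folds} exceeds sample count {len(sample_ids)}")
    rng = np.random.default_rng(seed)
    assignments: dict[str, int] = {}
    if stratified:
        groups: dict[str | None, list[str]] = {}
        for sid in sample_ids:
            groups.setdefault(seen[sid], []).append(sid)
        offset = 0
        for g in groups:
            ids = list(groups[g])
            rng.shuffle(ids)
            # round-robin with a rolling start so remainders spread over folds
            for i, sid in enumerate(ids):
                assignments[sid] = (offset + i) % n_folds
            offset += len(ids)
    else:
        ids = list(sample_ids)
        rng.shuffle(ids)
        for i, sid in enumerate(ids):
            assignments[sid] = i % n_folds
    return FoldPlan(n_folds=n_folds, assignments=assignments)


def augment(subset: SpectrumSet, cfg: AugmentConfig | None = None) -> SpectrumSet:
    """Within-class random convex combinations.

    For each original spectrum, emits ``cfg.factor`` synthetic spectra. Each
    is a convex combination of ``n_components`` distinct same-group spectra:
    the original itself plus ``n_components - 1`` others drawn without
    replacement from its group, with Dirichlet(1, ..., 1) weights. Group
    label is inherited. Deterministic given ``cfg.seed``.
    """
    cfg = cfg or AugmentConfig()
    rng = np.random.default_rng(cfg.seed)
    by_group: dict[str | None, list[int]] = {}
    for i, sp in enumerate(subset):
        by_group.setdefault(sp.group, []).append(i)
    for g, idxs in by_group.items():
        if len(idxs) < cfg.n_components:
            raise AugmentationError(
                f"group {g!r} has {len(idxs)} spectra; "
                f"augmentation needs >= {cfg.n_components}"
            )
    X = subset.intensity_matrix()
    out: list[Spectrum] = []
    for i, anchor in enumerate(subset):
        pool = [j for j in by_group[anchor.group] if j != i]
        for k in range(cfg.factor):
            others = rng.choice(pool, size=cfg.n_components - 1, replace=False)
            sources = np.concatenate(([i], others))
            if cfg.weight_law == "degenerate_first":
                w = np.zeros(cfg.n_components)
                w[0] = 1.0
            else:
                w = rng.dirichlet(np.ones(cfg.n_components))
            mix = w @ X[sources]
            out.append(
                Spectrum(
                    subset.axis,
                    mix,
                    f"{anchor.sample_id}+a{k + 1}",
                    None,
                    anchor.group,
                )
            )
    return SpectrumSet(out, subset.axis, subset.class_names)


def build_datasets(
    s: SpectrumSet,
    plan: FoldPlan,
    rotation: int,
    cfg: AugmentConfig | None = None,
    normalize: bool = True,
) -> tuple[SpectrumSet, SpectrumSet, SpectrumSet]:
    """Split at sample level, augment each subset independently, normalise.

    Returns ``(train, val, test)``. No spectrum from one subset enters
    another subset's combinations, by construction. Min-max normalisation is
    applied after augmentation.
    """
    cfg = cfg or AugmentConfig()
    if not 0 <= rotation < plan.n_folds:
        raise ConfigError(f"rotation {rotation} out of range")
    rot = plan.rotations[rotation]
    roles = {
        "train": plan.samples_in(rot["train"]),
        "val": plan.samples_in(rot["val"]),
        "test": plan.samples_in(rot["test"]),
    }
    out = []
    for part, ids in roles.items():
        sub = s.subset([i for i, sp in enumerate(s) if sp.sample_id in ids])
        # distinct sub-streams per role so subsets draw independent weights
        aug = augment(
            sub,
            AugmentConfig(
                cfg.factor,
                cfg.n_components,
                cfg.weight_law,
                seed=(cfg.seed * plan.n_folds + rotation) * 3
                + ("train", "val", "test").index(part),
            ),
        )
        if normalize:
            aug = SpectrumSet(
                [minmax_normalize(sp) for sp in aug], aug.axis, aug.class_names
            )
        out.append(aug)
    return tuple(out)
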