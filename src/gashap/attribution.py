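"""Signed per-voxel attribution heatmaps with a testable Shapley core.

A heatmap assigns every voxel of one input volume a signed influence on the
classifier's output.  The Shapley value of a voxel *group* (an atlas region
or a cubic block) is its average marginal contribution to the model output
over all coalition orderings, where voxels outside the coalition are
replaced by a reference input (default: the all-zeros volume, i.e. the mean
of standardized data).  Two implementations are provided:

* :func:`exact_shapley` — full enumeration over the ``2**M`` coalitions
  with factorial weights; exact, feasible for M <= 20;
* :func:`sampled_shapley` — unbiased permutation-sampling estimate for
  larger M, deterministic for a fixed seed.

These satisfy (and are tested against) the classical axioms: efficiency
(base value plus all attributions equals the model output on the full
input), missingness/dummy (ignored groups get zero), symmetry, and
consistency across models.  Fast network-specific approximations such as
DeepLIFT-based explainers plug in through the ``external`` backend of
:func:`compute_heatmap` and produce the same :class:`Heatmap` type.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np

from .io import LabelAtlas, Volume

__all__ = [
    "Heatmap",
    "FeatureGrouping",
    "ShapleyResult",
    "exact_shapley",
    "sampled_shapley",
    "compute_heatmap",
    "check_consistency",
]

EXACT_LIMIT = 20  # 2**20 coalition evaluations is the ceiling for enumeration


@dataclass
class Heatmap:
    """Signed per-voxel attribution for one volume."""

    values: np.ndarray
    target_class: int
    base_value: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("heatmap must be a 3D grid")
        if not np.isfinite(self.values).all():
            raise ValueError("heatmap contains non-finite values")


class FeatureGrouping:
    """Disjoint voxel groups covering the explained support.

    ``labels`` maps each voxel to a group ``1..M`` (0 = outside the
    support, e.g. atlas background).
    """

    def __init__(self, labels: np.ndarray) -> None:
        labels = np.asarray(labels)
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("group labels must be integers")
        present = np.unique(labels)
        present = present[present != 0]
        self.M = len(present)
        if self.M < 1:
            raise ValueError("grouping must contain at least one group")
        if not np.array_equal(present, np.arange(1, self.M + 1)):
            # compact arbitrary positive IDs to 1..M
            lut = np.zeros(int(present.max()) + 1, dtype=np.int64)
            lut[present] = np.arange(1, self.M + 1)
            labels = lut[labels]
        self.labels = labels
        self._flat = labels.ravel()

    @classmethod
    def from_atlas(cls, atlas: LabelAtlas) -> "FeatureGrouping":
        return cls(atlas.labels)

    @classmethod
    def from_blocks(cls, shape: tuple[int, int, int], block: int = 4) -> "FeatureGrouping":
        """Cubic blocks of side ``block`` (edge blocks may be smaller)."""
        if block < 1:
            raise ValueError("block side must be >= 1")
        idx = np.indices(shape)
        nb = [int(np.ceil(s / block)) for s in shape]
        bi = [np.minimum(idx[d] // block, nb[d] - 1) for d in range(3)]
        labels = (bi[0] * nb[1] + bi[1]) * nb[2] + bi[2] + 1
        return cls(labels.astype(np.int64))

    def group_sizes(self) -> np.ndarray:
        return np.bincount(self._flat, minlength=self.M + 1)[1:]

    def spread_to_voxels(self, phi: np.ndarray) -> np.ndarray:
        """Per-group attribution divided evenly over each group's voxels."""
        per_voxel = np.zeros(self.M + 1, dtype=np.float64)
        per_voxel[1:] = np.asarray(phi, dtype=np.float64) / self.group_sizes()
        return per_voxel[self.labels]


@dataclass
class ShapleyResult:
    phi: np.ndarray  # per-group attribution, model-output units
    phi0: float  # model output at the reference input
    grouping: FeatureGrouping


def _as_data(x) -> np.ndarray:
    return np.asarray(x.data if isinstance(x, Volume) else x, dtype=np.float64)


def _coalition_inputs(
    x: np.ndarray, reference: np.ndarray, grouping: FeatureGrouping, coalitions: np.ndarray
) -> np.ndarray:
    """Stack of inputs: group in coalition -> x voxels, else reference voxels.

    ``coalitions`` is a boolean array of shape (n, M).  Voxels outside every
    group (label 0) always keep the reference value by convention; with the
    default zero reference this matches evaluating the model on the masked
    support alone.
    """
    member = np.concatenate(
        [np.zeros((len(coalitions), 1), dtype=bool), coalitions], axis=1
    )  # prepend background column
    take_x = member[:, _as_flat_labels(grouping)]
    flat_x, flat_ref = x.ravel(), reference.ravel()
    return np.where(take_x, flat_x, flat_ref).reshape(len(coalitions), *x.shape)


def _as_flat_labels(grouping: FeatureGrouping) -> np.ndarray:
    return grouping._flat


def _batched_eval(model_fn, inputs: np.ndarray, batch: int = 256) -> np.ndarray:
    outs = [np.asarray(model_fn(inputs[i : i + batch]), dtype=np.float64)
            for i in range(0, len(inputs), batch)]
    out = np.concatenate([o.reshape(-1) for o in outs])
    if len(out) != len(inputs):
        raise ValueError("model_fn must return one scalar per input volume")
    return out


def exact_shapley(
    model_fn, x, reference, grouping: FeatureGrouping
) -> ShapleyResult:
    """Exact Shapley values by enumeration over all ``2**M`` coalitions.

    ``model_fn`` maps a batch of volumes ``(n, nx, ny, nz)`` to ``n``
    scalar outputs.  Refuses M > 20; use :func:`sampled_shapley` there.
    """
    M = grouping.M
    if M > EXACT_LIMIT:
        raise ValueError(
            f"M={M} groups needs 2^{M} evaluations; use sampled_shapley instead"
        )
    x, reference = _as_data(x), _as_data(reference)
    n_coal = 2**M
    bits = (np.arange(n_coal)[:, None] >> np.arange(M)) & 1  # (2^M, M)
    coalitions = bits.astype(bool)
    values = _batched_eval(model_fn, _coalition_inputs(x, reference, grouping, coalitions))
    sizes = coalitions.sum(axis=1)
    weights = np.array(
        [factorial(s) * factorial(M - 1 - s) / factorial(M) for s in range(M)]
    )
    phi = np.zeros(M)
    for i in range(M):
        without = ~coalitions[:, i]
        idx_wo = np.flatnonzero(without)
        idx_with = idx_wo | (1 << i)  # adding group i flips its bit
        phi[i] = np.sum(weights[sizes[idx_wo]] * (values[idx_with] - values[idx_wo]))
    return ShapleyResult(phi=phi, phi0=float(values[0]), grouping=grouping)


def sampled_shapley(
    model_fn, x, reference, grouping: FeatureGrouping, n_permutations: int, seed: int = 0
) -> ShapleyResult:
    """Permutation-sampling Shapley estimate (unbiased, seed-deterministic).

    Each sampled ordering contributes one marginal-contribution estimate to
    every group, so the per-group standard error shrinks as
    ``1/sqrt(n_permutations)``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    M = grouping.M
    x, reference = _as_data(x), _as_data(reference)
    rng = np.random.default_rng(seed)
    phi = np.zeros(M)
    v_empty = float(_batched_eval(model_fn, reference[None])[0])
    chunk = max(1, 2048 // max(M, 1))
    for start in range(0, n_permutations, chunk):
        n_here = min(chunk, n_permutations - start)
        perms = np.stack([rng.permutation(M) for _ in range(n_here)])
        # coalition after step j of a permutation = first j+1 groups
        coalitions = np.zeros((n_here * M, M), dtype=bool)
        row = 0
        for p in perms:
            for j in range(M):
                coalitions[row, p[: j + 1]] = True
                row += 1
        values = _batched_eval(
            model_fn, _coalition_inputs(x, reference, grouping, coalitions)
        ).reshape(n_here, M)
        prev = np.concatenate(
            [np.full((n_here, 1), v_empty), values[:, :-1]], axis=1
        )
        marginals = values - prev
        for i in range(n_here):
            phi[perms[i]] += marginals[i]
    phi /= n_permutations
    return ShapleyResult(phi=phi, phi0=v_empty, grouping=grouping)


def check_consistency(
    model_f, model_fprime, x, reference, grouping: FeatureGrouping, i: int
) -> bool:
    """Verify the consistency axiom for group ``i`` (0-based).

    First checks by enumeration that ``f'`` has marginal contributions for
    group ``i`` dominating those of ``f`` on every coalition (the axiom's
    premise); raises if the premise fails or cannot be enumerated.  Returns
    whether ``phi_i(f') >= phi_i(f)`` — which the axiom guarantees, so a
    ``False`` return flags an implementation defect.
    """
    M = grouping.M
    if M > EXACT_LIMIT:
        raise ValueError(f"premise not verifiable by enumeration for M={M} > {EXACT_LIMIT}")
    if not 0 <= i < M:
        raise ValueError(f"group index {i} out of range for M={M}")
    x, reference = _as_data(x), _as_data(reference)
    n_coal = 2**M
    coalitions = ((np.arange(n_coal)[:, None] >> np.arange(M)) & 1).astype(bool)
    inputs = _coalition_inputs(x, reference, grouping, coalitions)
    vf = _batched_eval(model_f, inputs)
    vfp = _batched_eval(model_fprime, inputs)
    with_i = np.flatnonzero(coalitions[:, i])
    without_i = with_i & ~(1 << i)
    delta_f = vf[with_i] - vf[without_i]
    delta_fp = vfp[with_i] - vfp[without_i]
    if not np.all(delta_fp >= delta_f - 1e-9):
        raise ValueError("consistency premise does not hold for this model pair")
    phi_f = exact_shapley(model_f, x, reference, grouping).phi[i]
    phi_fp = exact_shapley(model_fprime, x, reference, grouping).phi[i]
    return bool(phi_fp >= phi_f - 1e-9)


# ---------------------------------------------------------------------------
# heatmap backends


def _target_and_fn(clf, vdata: np.ndarray, target):
    """Resolve the explained class and build a scalar model function."""
    if target in (None, "pred"):
        target_class = int(clf.predict(vdata[None])[0])
    else:
        target_class = int(target)

    def model_fn(batch: np.ndarray) -> np.ndarray:
        return clf.predict_proba(batch)[:, target_class]

    return target_class, model_fn


def compute_heatmap(
    clf,
    v: Volume,
    backend: str = "grad_input",
    *,
    target=None,
    atlas: LabelAtlas | None = None,
    block: int = 4,
    n_permutations: int = 64,
    mode: str = "auto",
    seed: int = 0,
    reference: np.ndarray | None = None,
    explain_fn=None,
) -> Heatmap:
    """Voxel heatmap for one volume under the chosen backend.

    Backends
    --------
    ``grad_input``
        Gradient of the target-class logit times the input, voxel-resolved.
        The default: exact for linear models, cheap for the CNN.
    ``block_shapley``
        Sampled Shapley values over cubic blocks of side ``block``; each
        voxel receives its block's value divided by the block size.
    ``region_shapley``
        Shapley values over atlas regions (requires ``atlas``); exact when
        ``mode='exact'`` (or ``'auto'`` with R <= 20), else sampled.
    ``external``
        Adapter contract: ``explain_fn(volume_data) -> voxel array`` from a
        third-party explainer (e.g. a DeepLIFT-style deep explainer),
        wrapped into the same :class:`Heatmap` type.
    """
    vdata = _as_data(v)
    ref = np.zeros_like(vdata) if reference is None else _as_data(reference)
    if backend == "grad_input":
        target_class = (
            int(clf.predict(vdata[None])[0]) if target in (None, "pred") else int(target)
        )
        grad = clf.input_gradient(vdata[None], target_class)[0]
        return Heatmap(values=grad * vdata, target_class=target_class)
    if backend == "block_shapley":
        target_class, model_fn = _target_and_fn(clf, vdata, target)
        grouping = FeatureGrouping.from_blocks(vdata.shape, block=block)
        res = sampled_shapley(model_fn, vdata, ref, grouping, n_permutations, seed=seed)
        return Heatmap(
            values=grouping.spread_to_voxels(res.phi),
            target_class=target_class,
            base_value=res.phi0,
        )
    if backend == "region_shapley":
        if atlas is None:
            raise ValueError("region_shapley requires an atlas")
        target_class, model_fn = _target_and_fn(clf, vdata, target)
        grouping = FeatureGrouping.from_atlas(atlas)
        exact = mode == "exact" or (mode == "auto" and grouping.M <= EXACT_LIMIT)
        if exact:
            res = exact_shapley(model_fn, vdata, ref, grouping)
        else:
            res = sampled_shapley(model_fn, vdata, ref, grouping, n_permutations, seed=seed)
        return Heatmap(
            values=grouping.spread_to_voxels(res.phi),
            target_class=target_class,
            base_value=res.phi0,
        )
    if backend == "external":
        if explain_fn is None:
            raise ValueError("external backend requires explain_fn")
        target_class = (
            int(clf.predict(vdata[None])[0]) if target in (None, "pred") else int(target)
        )
        values = np.asarray(explain_fn(vdata), dtype=np.float64)
        if values.shape != vdata.shape:
            raise ValueError("explain_fn must return a voxel array matching the volume")
        return Heatmap(values=values, target_class=target_class)
    raise ValueError(f"unknown attribution backend {backend!r}")
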