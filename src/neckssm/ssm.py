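"""Point-distribution shape model of the aligned landmark grids.

The model is a standard PCA in landmark space: the mean shape plus an
orthonormal basis of variation modes with per-mode variances.  With n
subjects and d = levels x angles x 3 coordinates (d >> n here), at most
n - 1 modes carry variance; the retained subset is the smallest set of
leading modes whose cumulative variance fraction reaches the retention
threshold (default 0.98).

The decomposition is computed through an SVD of the centered data matrix
for numerical stability; eigendecomposition of the explicitly formed
covariance matrix is kept in the test suite as an independent oracle.
Component signs are fixed so that each mode's largest-magnitude loading is
positive, which makes scores reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from neckssm.errors import InvalidParameterError
from neckssm.parametrization import ParametrizedNeck

__all__ = [
    "ShapeModel",
    "PCScores",
    "GeneralizationResult",
    "build_ssm",
    "project",
    "synthesize",
    "reconstruct",
    "generalization_ability",
    "grid_to_mesh",
]

#: variance below this fraction of the total is treated as numerically zero
_ZERO_VAR_FRACTION = 1e-10


def _as_matrix(landmarks) -> tuple[np.ndarray, tuple[int, int]]:
    """Stack necks/grids into an (n, d) matrix; returns (matrix, grid shape)."""
    grids = []
    for item in landmarks:
        g = item.landmarks if isinstance(item, ParametrizedNeck) else np.asarray(item, dtype=float)
        grids.append(g)
    shapes = {g.shape for g in grids}
    if len(shapes) != 1:
        raise InvalidParameterError(f"inconsistent grid shapes: {shapes}")
    (shape,) = shapes
    X = np.stack([g.reshape(-1) for g in grids])
    if np.isnan(X).any():
        raise InvalidParameterError("landmark grids contain NaNs")
    return X, shape[:2]


@dataclass
class ShapeModel:
    """Mean shape + orthonormal variation modes of a landmark population."""

    mean_shape: np.ndarray  # (d,)
    components: np.ndarray  # (K, d), orthonormal rows
    variances: np.ndarray  # (K,), mm^2, non-increasing
    variance_fraction: np.ndarray  # (K,), sums to 1 over nonzero-variance modes
    n_retained: int
    retention_threshold: float
    grid_shape: tuple[int, int]  # (levels, angles)

    @property
    def n_components(self) -> int:
        return len(self.variances)

    @property
    def n_nonzero(self) -> int:
        total = self.variances.sum()
        if total <= 0:
            return 0
        return int((self.variances > _ZERO_VAR_FRACTION * total).sum())

    def sd(self, k: int) -> float:
        """Standard deviation (mm) of mode k."""
        return float(np.sqrt(self.variances[k]))


@dataclass
class PCScores:
    """Per-subject mode scores (mm), with ids and group labels."""

    scores: np.ndarray  # (n_subjects, K)
    subject_ids: list[str] = field(default_factory=list)
    groups: list[str] = field(default_factory=list)


@dataclass
class GeneralizationResult:
    """Leave-one-out reconstruction errors of the model (mm)."""

    per_subject_error: np.ndarray
    mean_error: float
    ci95: tuple[float, float]
    n_components_used: np.ndarray  # retained count of each leave-one-out model


def build_ssm(landmarks, retention_threshold: float = 0.98) -> ShapeModel:
    """Fit the shape model to aligned landmark grids.

    ``landmarks`` is a sequence of :class:`ParametrizedNeck` or raw
    (levels, angles, 3) arrays, already aligned.  Variances use the n-1
    divisor of the sample covariance.
    """
    X, grid_shape = _as_matrix(landmarks)
    n = len(X)
    if n < 2:
        raise InvalidParameterError("at least 2 subjects are required for a PCA")
    if not (0 < retention_threshold <= 1):
        raise InvalidParameterError("retention_threshold must be in (0, 1]")
    mean = X.mean(axis=0)
    Xc = X - mean
    _, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n - 1, Xc.shape[1])
    svals, Vt = svals[:k], Vt[:k]
    variances = svals**2 / (n - 1)

    # sign convention: largest-|loading| entry of each mode positive
    flip = np.sign(Vt[np.arange(k), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]

    total = variances.sum()
    # scale-aware zero test: variance indistinguishable from fp error on the
    # raw coordinates counts as zero (covers the all-identical-shapes case)
    eps_var = (1e-12 * max(np.linalg.norm(X), 1.0)) ** 2 / (n - 1)
    nonzero = variances > np.maximum(_ZERO_VAR_FRACTION * total, eps_var)
    if nonzero.any():
        fractions = variances / total
        cum = np.cumsum(fractions)
        n_retained = int(np.searchsorted(cum, retention_threshold - 1e-12) + 1)
        n_retained = min(n_retained, int(nonzero.sum()))
    else:  # all shapes identical
        variances = np.zeros_like(variances)
        fractions = np.zeros_like(variances)
        n_retained = 0
    return ShapeModel(
        mean_shape=mean,
        components=Vt,
        variances=variances,
        variance_fraction=fractions,
        n_retained=n_retained,
        retention_threshold=retention_threshold,
        grid_shape=grid_shape,
    )


def _flatten_for(model: ShapeModel, shape) -> np.ndarray:
    g = shape.landmarks if isinstance(shape, ParametrizedNeck) else np.asarray(shape, dtype=float)
    v = g.reshape(-1)
    if v.shape != model.mean_shape.shape:
        raise InvalidParameterError(
            f"shape has {v.size} coordinates, model expects {model.mean_shape.size}"
        )
    return v


def project(shape, model: ShapeModel, n_components: int | None = None) -> np.ndarray:
    """Scores of a shape: inner products of (shape - mean) with each mode.

    By default the retained modes are used; pass ``n_components`` to score
    against a different number of leading modes.
    """
    k = model.n_retained if n_components is None else n_components
    if k > model.n_components:
        raise InvalidParameterError(f"requested {k} components, model has {model.n_components}")
    v = _flatten_for(model, shape)
    return model.components[:k] @ (v - model.mean_shape)


def project_cohort(
    necks: list[ParametrizedNeck], model: ShapeModel, n_components: int | None = None
) -> PCScores:
    """Score every subject of a cohort against the model."""
    scores = np.stack([project(n, model, n_components=n_components) for n in necks])
    return PCScores(
        scores=scores,
        subject_ids=[n.subject_id for n in necks],
        groups=[n.group for n in necks],
    )


def synthesize(model: ShapeModel, pc_index: int, k_sd: float) -> np.ndarray:
    """Grid of the mean shape offset by ``k_sd`` SDs along one mode.

    This is the mean +/- 3 SD visualization primitive: ``k_sd`` in [-3, 3]
    spans the plausible range of the mode.
    """
    if not (0 <= pc_index < model.n_components):
        raise InvalidParameterError(f"pc_index {pc_index} out of range")
    v = model.mean_shape + k_sd * model.sd(pc_index) * model.components[pc_index]
    return v.reshape(model.grid_shape + (3,))


def reconstruct(scores: np.ndarray, model: ShapeModel, n_components: int | None = None) -> np.ndarray:
    """Grid of mean + sum(score_k * mode_k) over the first modes."""
    scores = np.asarray(scores, dtype=float)
    k = len(scores) if n_components is None else n_components
    if k > model.n_components:
        raise InvalidParameterError(f"requested {k} components, model has {model.n_components}")
    v = model.mean_shape + scores[:k] @ model.components[:k]
    return v.reshape(model.grid_shape + (3,))


def reconstruction_error(shape, model: ShapeModel, n_components: int) -> float:
    """Mean point-to-point landmark distance (mm) after projecting a shape
    onto the first ``n_components`` modes and reconstructing it."""
    v = _flatten_for(model, shape)
    s = project(shape, model, n_components=n_components)
    recon = model.mean_shape + s @ model.components[:n_components]
    diff = (v - recon).reshape(-1, 3)
    return float(np.linalg.norm(diff, axis=1).mean())


def generalization_ability(landmarks, retention_threshold: float = 0.98) -> GeneralizationResult:
    """Leave-one-out generalization: how well the model built on n-1
    subjects reconstructs the held-out subject.

    For each subject, the model is refit without it, the retained-mode
    count follows the threshold rule, and the error is the mean Euclidean
    distance over corresponding landmarks.  The 95% CI of the mean is a
    normal approximation over subjects (mean +/- 1.96 sd/sqrt(n)).
    """
    X, grid_shape = _as_matrix(landmarks)
    n = len(X)
    if n < 3:
        raise InvalidParameterError("leave-one-out generalization needs >= 3 subjects")
    errors = np.empty(n)
    used = np.empty(n, dtype=int)
    idx = np.arange(n)
    for i in range(n):
        train = X[idx != i]
        model = build_ssm(train.reshape(n - 1, *grid_shape, 3), retention_threshold)
        errors[i] = reconstruction_error(
            X[i].reshape(*grid_shape, 3), model, model.n_retained
        )
        used[i] = model.n_retained
    mean = float(errors.mean())
    half = 1.96 * errors.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
    return GeneralizationResult(
        per_subject_error=errors,
        mean_error=mean,
        ci95=(mean - half, mean + half),
        n_components_used=used,
    )


def grid_to_mesh(grid: np.ndarray):
    """Triangulate a (levels, angles, 3) landmark grid into a closed tube
    mesh (quad strips between levels, fan caps at both ends)."""
    import trimesh

    L, A, _ = grid.shape
    vertices = grid.reshape(-1, 3)
    faces = []
    for i in range(L - 1):
        base, nxt = i * A, (i + 1) * A
        for k in range(A):
            k1 = (k + 1) % A
            faces.append((base + k, base + k1, nxt + k1))
            faces.append((base + k, nxt + k1, nxt + k))
    top_apex = len(vertices)
    bot_apex = top_apex + 1
    vertices = np.vstack([vertices, grid[0].mean(axis=0), grid[-1].mean(axis=0)])
    last = (L - 1) * A
    for k in range(A):
        k1 = (k + 1) % A
        faces.append((top_apex, (k + 1) % A, k))
        faces.append((bot_apex, last + k, last + k1))
    return trimesh.Trimesh(vertices=vertices, faces=np.asarray(faces), process=False)
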