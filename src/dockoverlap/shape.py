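"""3D shape and pharmacophore similarity against a lead compound.

Compounds are compared to a reference by rigidly superposing them and
scoring three Tanimoto coefficients:

* ``tc_shape`` — hard-sphere volume Tanimoto V∩ / (V_ref + V_probe − V∩),
* ``tc_color`` — Tanimoto over typed pharmacophore feature overlaps
  (donor, acceptor, cation, anion, ring, hydrophobe),
* ``tc_combo`` — their unit-weight sum, in [0, 2].

Alignment maximizes a *Gaussian* volume overlap: each atom is replaced by a
spherical Gaussian whose integral equals its hard-sphere volume
(Grant–Pickup style, fixed amplitude 2.7, first-order pairwise overlaps
only).  The Gaussian surrogate is smooth in the pose parameters and so
optimizable; the reported Tanimoto always uses hard-sphere volumes, keeping
one volume definition across the package.  Only proper rotations are ever
searched — molecules are chiral, so a mirror image must not count as a
match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .structures import MoleculePose
from .volumetrics import (
    DEFAULT_SETTINGS,
    VolumeSettings,
    intersection_volume,
    union_volume,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RigidTransform",
    "FeaturePoint",
    "SimilarityScore",
    "AlignmentResult",
    "gaussian_overlap",
    "align_to_reference",
    "shape_tanimoto",
    "color_tanimoto",
    "derive_features",
    "rank_by_combo",
]

#: Fixed Gaussian amplitude; with the width tied to the vdW radius below,
#: each atom Gaussian integrates to its hard-sphere volume.
GAUSS_AMPLITUDE = 2.7

FEATURE_TYPES = ("donor", "acceptor", "cation", "anion", "ring", "hydrophobe")


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x ↦ R·x + t (rotation 3×3, translation Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise ValueError("rotation is not orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-6):
            raise ValueError("rotation must be proper (det = +1); reflections are not rigid motions of a chiral molecule")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def random(cls, rng: np.random.Generator, max_translation: float = 10.0) -> "RigidTransform":
        R = Rotation.random(rng=rng).as_matrix()
        t = rng.uniform(-max_translation, max_translation, size=3)
        return cls(R, t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation

    def apply_pose(self, pose: MoleculePose) -> MoleculePose:
        return pose.with_coords(self.apply(pose.coords))


@dataclass(frozen=True)
class FeaturePoint:
    """A typed pharmacophore point: type, position (Å) and Gaussian width."""

    type: str
    position: np.ndarray
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.type not in FEATURE_TYPES:
            raise ValueError(f"feature type must be one of {FEATURE_TYPES}, got {self.type!r}")
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))


@dataclass(frozen=True)
class SimilarityScore:
    tc_shape: float
    tc_color: float
    transform: RigidTransform

    @property
    def tc_combo(self) -> float:
        return self.tc_shape + self.tc_color


@dataclass
class AlignmentResult:
    transform: RigidTransform
    aligned: MoleculePose
    score: float                      # Gaussian overlap at the optimum, Å³
    start_scores: list[float] = field(default_factory=list)


def _gauss_params(pose: MoleculePose) -> tuple[np.ndarray, np.ndarray]:
    """Per-atom Gaussian decay constants γ such that A(π/γ)^{3/2} = (4/3)πr³."""
    r = pose.radii
    vol = 4.0 / 3.0 * np.pi * r ** 3
    gamma = np.pi * (GAUSS_AMPLITUDE / vol) ** (2.0 / 3.0)
    return gamma, vol


def _pair_overlap(coords_a, gamma_a, coords_b, gamma_b) -> float:
    d2 = np.sum((coords_a[:, None, :] - coords_b[None, :, :]) ** 2, axis=-1)
    gsum = gamma_a[:, None] + gamma_b[None, :]
    gprod = gamma_a[:, None] * gamma_b[None, :]
    terms = GAUSS_AMPLITUDE ** 2 * (np.pi / gsum) ** 1.5 * np.exp(-gprod / gsum * d2)
    return float(terms.sum())


def gaussian_overlap(a: MoleculePose, b: MoleculePose) -> float:
    """Gaussian volume overlap (Å³) between two poses, pairwise first order.

    Symmetric; maximal over rigid motions of ``b`` when b coincides with a
    copy of itself; decays to 0 as the poses separate.
    """
    ga, _ = _gauss_params(a)
    gb, _ = _gauss_params(b)
    return _pair_overlap(a.coords, ga, b.coords, gb)


def _principal_axes(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decomposition of the centered coordinate covariance.

    Returns (eigenvalues descending, column eigenvector matrix with
    det = +1).
    """
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / max(len(coords), 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if np.linalg.det(vecs) < 0:
        vecs[:, 2] *= -1
    return vals, vecs


#: Sign flips of two principal axes at a time keep the rotation proper; the
#: four combinations cover the axis-ambiguity of an inertial frame.
_AXIS_SIGNS = [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]


def align_to_reference(
    ref: MoleculePose,
    probe: MoleculePose,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> AlignmentResult:
    """Rigidly superpose ``probe`` onto ``ref`` by maximizing Gaussian overlap.

    Strategy: center both molecules on their centroids, seed four proper
    rotations from the principal-axes sign ambiguity, refine each seed by
    quasi-Newton ascent over (rotation-vector, translation), and keep the
    best.  The returned score is never below any seed's score.

    A degenerate probe (all atoms coincident or collinear, where principal
    axes are undefined) falls back to a translation-only alignment with a
    warning.
    """
    ref_c = ref.coords.mean(axis=0)
    probe_c = probe.coords.mean(axis=0)
    gamma_ref, _ = _gauss_params(ref)
    gamma_probe, _ = _gauss_params(probe)
    ref_xyz = ref.coords
    probe_local = probe.coords - probe_c

    vals_p, axes_p = _principal_axes(probe.coords)
    degenerate = probe.n_atoms < 3 or vals_p[1] < 1e-8
    if degenerate:
        logger.warning(
            "probe %r is degenerate (coincident/collinear atoms); translation-only alignment",
            probe.id,
        )
        t = ref_c - probe_c
        transform = RigidTransform(np.eye(3), t)
        aligned = transform.apply_pose(probe)
        score = _pair_overlap(ref_xyz, gamma_ref, aligned.coords, gamma_probe)
        return AlignmentResult(transform, aligned, score, [score])

    _, axes_r = _principal_axes(ref.coords)

    def score_of(rotvec: np.ndarray, t: np.ndarray) -> float:
        R = Rotation.from_rotvec(rotvec).as_matrix()
        moved = probe_local @ R.T + ref_c + t
        return _pair_overlap(ref_xyz, gamma_ref, moved, gamma_probe)

    def negative(params: np.ndarray) -> float:
        return -score_of(params[:3], params[3:])

    start_scores: list[float] = []
    best_params: np.ndarray | None = None
    best_score = -np.inf
    for signs in _AXIS_SIGNS:
        R0 = axes_r @ np.diag(signs) @ axes_p.T
        rotvec0 = Rotation.from_matrix(R0).as_rotvec()
        x0 = np.concatenate([rotvec0, np.zeros(3)])
        start_scores.append(score_of(rotvec0, np.zeros(3)))
        res = minimize(
            negative,
            x0,
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-8},
        )
        final = -res.fun
        # quasi-Newton descent on the negative score can only improve a seed
        final = max(final, start_scores[-1])
        if final > best_score:
            best_score = final
            best_params = res.x if -res.fun >= start_scores[-1] else x0

    assert best_params is not None
    R = Rotation.from_rotvec(best_params[:3]).as_matrix()
    t_local = best_params[3:]
    translation = ref_c + t_local - R @ probe_c
    transform = RigidTransform(R, translation)
    aligned = transform.apply_pose(probe)
    return AlignmentResult(transform, aligned, best_score, start_scores)


def shape_tanimoto(
    ref: MoleculePose,
    probe: MoleculePose,
    align: bool = True,
    settings: VolumeSettings = DEFAULT_SETTINGS,
) -> float:
    """Hard-sphere shape Tanimoto V∩ / (V_ref + V_probe − V∩), in [0, 1].

    With ``align=True`` the probe is first superposed on the reference by
    :func:`align_to_reference`; with ``align=False`` the poses are compared
    in place (symmetric in its arguments).
    """
    if align:
        probe = align_to_reference(ref, probe).aligned
    inter = intersection_volume(ref, probe, settings)
    union = union_volume(ref, settings) + union_volume(probe, settings) - inter
    if union <= 0:
        return 0.0
    return float(np.clip(inter / union, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Pharmacophore features
# ---------------------------------------------------------------------------

def derive_features(pose: MoleculePose, sigma: float = 1.0) -> list[FeaturePoint]:
    """Minimal rule-based pharmacophore typing from geometry and the SDF blocks.

    Rules (a declared simplification of vendor "color" force fields):

    * donor — N or O with at least one hydrogen within 1.2 Å;
    * acceptor — any N or O;
    * cation / anion — atoms with positive / negative formal charge
      (SDF charge block);
    * ring — centroid of each 5- or 6-membered cycle of the bond graph;
    * hydrophobe — carbon with no N or O within 2.0 Å.
    """
    import networkx as nx

    coords = pose.coords
    elements = [e.capitalize() for e in pose.elements]
    features: list[FeaturePoint] = []

    h_idx = [i for i, e in enumerate(elements) if e == "H"]
    no_idx = [i for i, e in enumerate(elements) if e in ("N", "O")]

    for i, e in enumerate(elements):
        if e in ("N", "O"):
            features.append(FeaturePoint("acceptor", coords[i], sigma))
            if h_idx and np.min(np.linalg.norm(coords[h_idx] - coords[i], axis=1)) <= 1.2:
                features.append(FeaturePoint("donor", coords[i], sigma))
        elif e == "C":
            if not no_idx or np.min(np.linalg.norm(coords[no_idx] - coords[i], axis=1)) > 2.0:
                features.append(FeaturePoint("hydrophobe", coords[i], sigma))
        if pose.atoms[i].formal_charge > 0:
            features.append(FeaturePoint("cation", coords[i], sigma))
        elif pose.atoms[i].formal_charge < 0:
            features.append(FeaturePoint("anion", coords[i], sigma))

    if pose.bonds:
        graph = nx.Graph(pose.bonds)
        for cycle in nx.cycle_basis(graph):
            if len(cycle) in (5, 6):
                features.append(FeaturePoint("ring", coords[list(cycle)].mean(axis=0), sigma))
    return features


def _feature_overlap(fa: Sequence[FeaturePoint], fb: Sequence[FeaturePoint]) -> float:
    """Σ over same-type pairs of the Gaussian product integral."""
    total = 0.0
    for ftype in FEATURE_TYPES:
        pa = [f for f in fa if f.type == ftype]
        pb = [f for f in fb if f.type == ftype]
        if not pa or not pb:
            continue
        ca = np.array([f.position for f in pa])
        cb = np.array([f.position for f in pb])
        sa = np.array([f.sigma for f in pa])
        sb = np.array([f.sigma for f in pb])
        d2 = np.sum((ca[:, None, :] - cb[None, :, :]) ** 2, axis=-1)
        s2 = sa[:, None] ** 2 + sb[None, :] ** 2
        total += float(
            np.sum(
                (2 * np.pi * (sa[:, None] * sb[None, :]) ** 2 / s2) ** 1.5
                * np.exp(-d2 / (2 * s2))
            )
        )
    return total


def color_tanimoto(
    ref: MoleculePose,
    probe: MoleculePose,
    ref_features: Sequence[FeaturePoint] | None = None,
    probe_features: Sequence[FeaturePoint] | None = None,
    transform: RigidTransform | None = None,
) -> float:
    """Pharmacophore ("color") Tanimoto in [0, 1].

    Feature points default to :func:`derive_features`; when ``transform`` is
    given (normally the shape-alignment transform), it is applied to the
    probe's features first.  If the two molecules share no feature type the
    score is exactly 0 — the mechanism by which chemically unrelated
    compounds get very low color scores no matter how similar their shapes.
    """
    fa = list(ref_features) if ref_features is not None else derive_features(ref)
    fb = list(probe_features) if probe_features is not None else derive_features(probe)
    if not fa or not fb:
        logger.warning("empty feature set (ref %r: %d, probe %r: %d); color Tanimoto = 0",
                       ref.id, len(fa), probe.id, len(fb))
        return 0.0
    if transform is not None:
        fb = [FeaturePoint(f.type, transform.apply(f.position[None, :])[0], f.sigma) for f in fb]
    o_ab = _feature_overlap(fa, fb)
    if o_ab == 0.0:
        return 0.0
    o_aa = _feature_overlap(fa, fa)
    o_bb = _feature_overlap(fb, fb)
    return float(np.clip(o_ab / (o_aa + o_bb - o_ab), 0.0, 1.0))


def rank_by_combo(
    ref: MoleculePose,
    probes: Sequence[MoleculePose],
    settings: VolumeSettings = DEFAULT_SETTINGS,
    shape_weight: float = 1.0,
    color_weight: float = 1.0,
) -> list[tuple[str, SimilarityScore]]:
    """Rank probes against the reference by descending combo Tanimoto.

    Each probe is aligned once; ``tc_shape`` and ``tc_color`` both use that
    alignment.  Combo is the (by default unit-) weighted sum.  Ties break
    lexicographically by id, so the ranking is deterministic.
    """
    if not probes:
        raise ValueError("need at least one probe")
    ref_features = derive_features(ref)
    scored: list[tuple[str, SimilarityScore]] = []
    for probe in probes:
        result = align_to_reference(ref, probe)
        tc_s = shape_tanimoto(ref, result.aligned, align=False, settings=settings)
        tc_c = color_tanimoto(
            ref, probe,
            ref_features=ref_features,
            probe_features=derive_features(probe),
            transform=result.transform,
        )
        scored.append((probe.id, SimilarityScore(tc_s, tc_c, result.transform)))
    scored.sort(key=lambda item: (-(shape_weight * item[1].tc_shape
                                    + color_weight * item[1].tc_color), item[0]))
    return scored
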