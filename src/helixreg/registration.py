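"""Single-pose image-to-robot registration.

Pipeline
--------
1. Segment fiducials from the CBCT volume (:mod:`helixreg.detection`).
2. Match detected large fiducials to model large fiducials by comparing
   inter-fiducial distance patterns (distances are rigid invariants, so no
   initial pose estimate is needed).
3. Estimate an affine phantom-to-CBCT transform Tp2c from the matched pairs by
   least squares (complete orthogonal decomposition).
4. Project the affine estimate to the nearest rigid transform and refine it
   with a derivative-free direct search minimizing the RMSE between every
   detected fiducial (small and large) and its nearest model fiducial.
5. Chain Tr2c = Tp2c * Te2p * Tr2e(Reg).

The distance-pattern cost for detected fiducial i against model candidate j is

    d_ij = sum_{k=1..m-1} min_{j' != j} | ||f_i - f_{(i+k) mod m}||
                                        - ||f_j - f_j'|| |

where m is the number of detected large fiducials, the inner index wraps
modulo m, and j' ranges over all model large fiducials except j. The absolute
difference makes the cost a proper dissimilarity of the two distance
patterns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import lstsq
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .detection import DetectedFiducial, ThresholdSpec, detect_fiducials
from .errors import (
    AmbiguousCorrespondenceError,
    InsufficientFiducialsError,
    RankDeficiencyError,
)
from .phantom import ModelFiducial
from .transforms import (
    HomogeneousTransform,
    RigidTransform,
    project_to_rigid,
    robot_to_cbct,
)
from .volume import VoxelVolume

__all__ = [
    "Correspondence",
    "RefinementDiagnostics",
    "RegistrationResult",
    "pattern_distance_costs",
    "match_large_fiducials",
    "estimate_affine",
    "refine_registration",
    "compute_fre",
    "register",
    "MIN_LARGE_FIDUCIALS",
    "AMBIGUITY_MARGIN_MM",
]

#: Fewest large fiducials for which the distance pattern is trusted.
MIN_LARGE_FIDUCIALS = 4
#: Required gap (mm) between best and second-best pattern costs.
AMBIGUITY_MARGIN_MM = 0.5

#: Refinement defaults: the three stopping rules of the direct search.
MAX_ITERATIONS = 2000
COST_TOLERANCE_MM = 1e-3
STEP_TOLERANCE_MM = 1e-3
#: Rotation parameters are axis-angle radians scaled by the phantom radius so
#: a unit step moves a surface fiducial about 1 mm, commensurate with the
#: translation parameters.
ROTATION_SCALE_MM = 54.0


def _centers(fiducials: Sequence) -> np.ndarray:
    return np.array([np.asarray(f.center, dtype=float) for f in fiducials]).reshape(-1, 3)


def pattern_distance_costs(
    query_points: np.ndarray, model_points: np.ndarray
) -> np.ndarray:
    """Distance-pattern cost matrix d_ij (mm) between two point sets.

    ``query_points`` are the m detected large-fiducial centroids, and
    ``model_points`` the candidate model positions. Because the inner minimum
    is taken per distance, the cost depends only on the *set* of distances
    from each point to its companions — it is invariant to any rigid motion of
    either set and to the ordering of the query run.
    """
    q = np.asarray(query_points, dtype=float).reshape(-1, 3)
    p = np.asarray(model_points, dtype=float).reshape(-1, 3)
    m, n = len(q), len(p)
    dq = cdist(q, q)
    dp = cdist(p, p)
    costs = np.empty((m, n))
    for i in range(m):
        qi = np.delete(dq[i], i)  # distances to the other detected fiducials
        for j in range(n):
            pj = np.delete(dp[j], j)  # distances to the other model fiducials
            costs[i, j] = np.abs(qi[:, None] - pj[None, :]).min(axis=1).sum()
    return costs


@dataclass(frozen=True)
class Correspondence:
    """An injective assignment of detected large fiducials to model positions.

    ``pairs`` holds ``(cbct_index, model_index)`` positional indices into the
    sequences given to :func:`match_large_fiducials`; ``cost_per_pair`` the
    matched pattern costs d_ij in mm.
    """

    pairs: tuple[tuple[int, int], ...]
    cost_per_pair: tuple[float, ...]

    def __post_init__(self) -> None:
        model_ids = [j for _, j in self.pairs]
        if len(set(model_ids)) != len(model_ids):
            raise AmbiguousCorrespondenceError(
                "correspondence assigns one model fiducial twice"
            )


def match_large_fiducials(
    cbct_large: Sequence[DetectedFiducial],
    model_large: Sequence[ModelFiducial],
    ambiguity_margin: float = AMBIGUITY_MARGIN_MM,
) -> Correspondence:
    """Brute-force distance-pattern matching of detected to model fiducials.

    For each detected fiducial the model candidate minimizing d_ij is chosen;
    the assignment must be injective and each minimum must beat the runner-up
    by ``ambiguity_margin`` mm, otherwise the correspondence is rejected
    loudly rather than silently mis-registered.
    """
    m = len(cbct_large)
    if m < MIN_LARGE_FIDUCIALS:
        raise InsufficientFiducialsError(
            f"{m} large fiducials detected; at least {MIN_LARGE_FIDUCIALS} are "
            "required to identify the helical pattern"
        )
    if len(model_large) < m:
        raise InsufficientFiducialsError(
            f"model has {len(model_large)} large fiducials but {m} were detected"
        )
    costs = pattern_distance_costs(_centers(cbct_large), _centers(model_large))
    pairs = []
    matched_costs = []
    for i in range(m):
        order = np.argsort(costs[i])
        best, second = int(order[0]), int(order[1])
        gap = costs[i, second] - costs[i, best]
        if gap < ambiguity_margin:
            raise AmbiguousCorrespondenceError(
                f"detected fiducial {i}: best ({costs[i, best]:.3f} mm) and "
                f"second-best ({costs[i, second]:.3f} mm) pattern costs are "
                f"within the {ambiguity_margin} mm ambiguity margin"
            )
        pairs.append((i, best))
        matched_costs.append(float(costs[i, best]))
    return Correspondence(pairs=tuple(pairs), cost_per_pair=tuple(matched_costs))


def estimate_affine(
    correspondence: Correspondence,
    cbct_large: Sequence[DetectedFiducial],
    model_large: Sequence[ModelFiducial],
) -> HomogeneousTransform:
    """Least-squares affine Tp2c from matched pairs.

    Solves ``Tp2c * [f(model); 1] = [f(CBCT)]`` in homogeneous form via
    complete orthogonal decomposition (LAPACK ``gelsy``). At least four
    non-coplanar pairs are required.
    """
    if len(correspondence.pairs) < 4:
        raise InsufficientFiducialsError(
            "affine estimation needs at least 4 corresponding pairs"
        )
    model_pts = np.array(
        [np.asarray(model_large[j].center, float) for _, j in correspondence.pairs]
    )
    cbct_pts = np.array(
        [np.asarray(cbct_large[i].center, float) for i, _ in correspondence.pairs]
    )
    a = np.hstack([model_pts, np.ones((len(model_pts), 1))])
    if np.linalg.matrix_rank(a, tol=1e-6) < 4:
        raise RankDeficiencyError(
            "corresponding fiducials are coplanar; affine fit is rank-deficient"
        )
    x, *_ = lstsq(a, cbct_pts, lapack_driver="gelsy")
    matrix = np.eye(4)
    matrix[:3, :] = x.T
    return HomogeneousTransform(matrix, "p", "c")


@dataclass(frozen=True)
class RefinementDiagnostics:
    iterations: int
    termination_reason: str  # max-iterations | cost-tolerance | step-tolerance
    converged: bool
    initial_cost: float
    final_cost: float
    n_evaluations: int


def _nearest_rmse(detected_pts: np.ndarray, model_pts_c: np.ndarray) -> float:
    d = cdist(detected_pts, model_pts_c).min(axis=1)
    return float(np.sqrt(np.mean(d**2)))


def refine_registration(
    init: HomogeneousTransform,
    all_detected: Sequence[DetectedFiducial],
    model: Sequence[ModelFiducial],
    max_iterations: int = MAX_ITERATIONS,
    cost_tolerance: float = COST_TOLERANCE_MM,
    step_tolerance: float = STEP_TOLERANCE_MM,
    initial_step: float = 2.0,
) -> tuple[RigidTransform, RefinementDiagnostics]:
    """Direct-search rigid refinement of Tp2c.

    Starting from ``project_to_rigid(init)``, a compass (pattern) search over
    six rigid parameters — axis-angle rotation scaled by the 54 mm phantom
    radius plus translation in mm — minimizes the RMSE between each detected
    fiducial (any size class) and the nearest model fiducial mapped through
    the current transform. Terminates when the iteration budget is exhausted,
    an accepted step improves the cost by less than ``cost_tolerance`` mm, or
    the search step falls below ``step_tolerance`` mm.
    """
    rigid0 = project_to_rigid(init)
    detected_pts = _centers(all_detected)
    model_pts = _centers(model)
    n_eval = 0

    def cost(params: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        rot = Rotation.from_rotvec(params[:3] / ROTATION_SCALE_MM).as_matrix()
        r = rigid0.rotation @ rot
        t = rigid0.translation + params[3:]
        return _nearest_rmse(detected_pts, model_pts @ r.T + t)

    x = np.zeros(6)
    f = cost(x)
    initial_cost = f
    step = float(initial_step)
    iterations = 0
    reason = "max-iterations"
    while iterations < max_iterations:
        iterations += 1
        best_f, best_x = f, None
        for axis in range(6):
            for sign in (1.0, -1.0):
                trial = x.copy()
                trial[axis] += sign * step
                ft = cost(trial)
                if ft < best_f:
                    best_f, best_x = ft, trial
        if best_x is None:
            step *= 0.5
            if step < step_tolerance:
                reason = "step-tolerance"
                break
        else:
            improvement = f - best_f
            x, f = best_x, best_f
            if improvement < cost_tolerance:
                reason = "cost-tolerance"
                break

    rot = Rotation.from_rotvec(x[:3] / ROTATION_SCALE_MM).as_matrix()
    refined = RigidTransform(rigid0.rotation @ rot, rigid0.translation + x[3:])
    diagnostics = RefinementDiagnostics(
        iterations=iterations,
        termination_reason=reason,
        converged=reason != "max-iterations" and f <= initial_cost + 1e-12,
        initial_cost=initial_cost,
        final_cost=f,
        n_evaluations=n_eval,
    )
    return refined, diagnostics


def compute_fre(
    transform: HomogeneousTransform | RigidTransform,
    detected: Sequence[DetectedFiducial],
    model: Sequence[ModelFiducial],
    pairs: Sequence[tuple[int, int]] | None = None,
) -> float:
    """Fiducial registration error: RMSE of detected-to-model distances (mm).

    Model fiducials are mapped into the CBCT frame by ``transform``. With
    explicit ``pairs`` the RMSE runs over those correspondences; otherwise
    each detected fiducial is paired with its nearest mapped model fiducial.
    """
    if len(detected) == 0:
        raise InsufficientFiducialsError("FRE needs at least one pair")
    detected_pts = _centers(detected)
    model_pts = _centers(model)
    if isinstance(transform, RigidTransform):
        mapped = transform.apply(model_pts)
    else:
        mapped = model_pts @ transform.linear.T + transform.translation
    if pairs is None:
        d = cdist(detected_pts, mapped).min(axis=1)
    else:
        d = np.linalg.norm(
            detected_pts[[i for i, _ in pairs]] - mapped[[j for _, j in pairs]],
            axis=1,
        )
    return float(np.sqrt(np.mean(d**2)))


@dataclass(frozen=True)
class RegistrationResult:
    """Outputs and diagnostics of a single-pose registration."""

    tp2c_initial: HomogeneousTransform  # affine least-squares estimate
    tp2c_refined: RigidTransform
    tr2c: HomogeneousTransform
    fre: float
    n_large_used: int
    n_small_used: int
    converged: bool
    iterations: int
    termination_reason: str
    correspondence: Correspondence
    threshold: float

    def to_dict(self) -> dict:
        return {
            "tp2c_initial": self.tp2c_initial.matrix.tolist(),
            "tp2c_refined": self.tp2c_refined.as_homogeneous("p", "c").matrix.tolist(),
            "tr2c": self.tr2c.matrix.tolist(),
            "fre_mm": self.fre,
            "n_large_used": self.n_large_used,
            "n_small_used": self.n_small_used,
            "converged": self.converged,
            "iterations": self.iterations,
            "termination_reason": self.termination_reason,
            "pairs": list(map(list, self.correspondence.pairs)),
            "threshold": self.threshold,
        }


def register(
    volume: VoxelVolume,
    model: Sequence[ModelFiducial],
    tr2e_reg: HomogeneousTransform,
    te2p: HomogeneousTransform,
    spec: ThresholdSpec | None = None,
) -> RegistrationResult:
    """End-to-end single-pose registration of a phantom CBCT.

    Runs threshold -> component extraction -> size classification -> pattern
    matching -> affine estimation -> rigid refinement, then chains
    ``Tr2c = Tp2c * Te2p * Tr2e(Reg)``. The FRE is the refined nearest-pair
    RMSE over all detected fiducials.
    """
    spec = spec or ThresholdSpec()
    visible = None
    if spec.mode == "expected-volume":
        lo, hi = volume.bounds()
        visible = [
            f
            for f in model
            if np.all(np.asarray(f.center) - f.radius >= lo)
            and np.all(np.asarray(f.center) + f.radius <= hi)
        ]
    detected, tau = detect_fiducials(volume, spec, visible)
    large = [f for f in detected if f.size_class == "large"]
    small = [f for f in detected if f.size_class == "small"]
    model_large = sorted(
        (f for f in model if f.size_class == "large"), key=lambda f: f.index
    )
    correspondence = match_large_fiducials(large, model_large)
    tp2c_initial = estimate_affine(correspondence, large, model_large)
    tp2c_refined, diag = refine_registration(tp2c_initial, detected, model)
    tr2c = robot_to_cbct(tp2c_refined.as_homogeneous("p", "c"), te2p, tr2e_reg)
    fre = compute_fre(tp2c_refined, detected, model)
    return RegistrationResult(
        tp2c_initial=tp2c_initial,
        tp2c_refined=tp2c_refined,
        tr2c=tr2c,
        fre=fre,
        n_large_used=len(large),
        n_small_used=len(small),
        converged=diag.converged,
        iterations=diag.iterations,
        termination_reason=diag.termination_reason,
        correspondence=correspondence,
        threshold=tau,
    )
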