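"""Mutual information expansion: assemble total entropies from marginals.

The configurational entropy of N localized (permutation-reduced) molecules
is expanded as

    S ~= sum_i S_i - sum_{i<j} I2(i,j) + sum_{i<j<k} I3(i,j,k)

truncated at third order, with

    I2(i,j)   = S_i + S_j - S_ij
    I3(i,j,k) = S_i + S_j + S_k - S_ij - S_ik - S_jk + S_ijk

(interaction-information convention; the signs are fixed so that the
truncated expansion is exact for jointly Gaussian molecules). Every
marginal entropy comes from the kNN estimator on the permutation-reduced
coordinates. Pair terms are evaluated for molecule pairs whose
time-averaged minimum-image distance is below a cutoff, triple terms when
all three legs are below a (smaller) cutoff; beyond those distances the MI
of localized molecules is negligible.

Translation-rotation correlation is quantified by
I_tr(j, k) = S(x_j) + S(q_k) - S(x_j, q_k), with the joint term estimated
in the composite space R^3 x SO(3).

The kinetic contribution is analytic: per molecule
S_kin = R (3/2 - 3 ln(lambda / l)) with the thermal de Broglie wavelength
lambda and the arbitrary reference length l that also normalizes the
configurational density; their sum is independent of l.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, replace as dc_replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .constants import GAS_CONSTANT_R, nats_to_molar, thermal_wavelength_nm
from .geometry import CompositeMetricParams
from .knn import EstimatorParams, MatchedRadiusMI, knn_entropy, marginal_entropy
from .model_io import EntropyReport, EntropyValue, ThermoParams
from .orientations import OrientationTrack
from .permutation import PermutedTrajectory

logger = logging.getLogger(__name__)


@dataclass
class CutoffPolicy:
    """Distance cutoffs (nm, on time-averaged minimum-image distances
    between permutation-localized molecules) selecting which MI terms are
    evaluated. Defaults: 1.0 nm for pairs; 0.45 nm suits argon-like
    liquids, 0.33 nm water."""

    pair_cutoff: float = 1.0
    triple_cutoff: float = 0.45

    def __post_init__(self) -> None:
        if self.triple_cutoff > self.pair_cutoff:
            raise ValueError(
                "CutoffPolicy requires triple_cutoff <= pair_cutoff "
                f"(got {self.triple_cutoff} > {self.pair_cutoff})"
            )


def mean_distance_matrix(ptraj: PermutedTrajectory) -> np.ndarray:
    """Pairwise minimum-image distances between mean positions."""
    mp = ptraj.mean_positions
    box = ptraj.box[0]
    d = mp[:, None, :] - mp[None, :, :]
    d -= box * np.round(d / box)
    return np.sqrt(np.einsum("ijk,ijk->ij", d, d))


def select_pairs_triples(
    ptraj: PermutedTrajectory, policy: Optional[CutoffPolicy] = None
) -> Tuple[List[Tuple[int, int]], List[Tuple[int, int, int]]]:
    """Molecule pairs/triples whose MI terms the cutoff policy selects.

    A triple qualifies only if all three pairwise mean distances are below
    the triple cutoff.
    """
    if policy is None:
        policy = CutoffPolicy()
    D = mean_distance_matrix(ptraj)
    N = ptraj.n_molecules
    iu = np.triu_indices(N, k=1)
    close = D[iu] < policy.pair_cutoff
    pairs = [(int(i), int(j)) for i, j in zip(iu[0][close], iu[1][close])]
    tclose = D < policy.triple_cutoff
    triples = []
    for i in range(N):
        nbrs = np.nonzero(tclose[i, i + 1 :])[0] + i + 1
        for a, b in itertools.combinations(nbrs, 2):
            if tclose[a, b]:
                triples.append((i, int(a), int(b)))
    return pairs, triples


def stride_frames(ptraj: PermutedTrajectory, stride: int) -> PermutedTrajectory:
    """Every ``stride``-th frame of a permuted trajectory (views, no copy).

    Mean positions are kept from the full trajectory so cutoff selection is
    unaffected.
    """
    if stride <= 1:
        return ptraj
    return PermutedTrajectory(
        positions=ptraj.positions[::stride],
        box=ptraj.box[::stride],
        times=ptraj.times[::stride],
        molecule_ids=ptraj.molecule_ids,
        site_positions=None if ptraj.site_positions is None
        else ptraj.site_positions[::stride],
        metadata=ptraj.metadata,
        permutations=None if ptraj.permutations is None
        else ptraj.permutations[::stride],
        objectives=None if ptraj.objectives is None else ptraj.objectives[::stride],
        reference=ptraj.reference,
        unwrapped=None if ptraj.unwrapped is None else ptraj.unwrapped[::stride],
        mean_positions=ptraj.mean_positions,
    )


def _molecule_block(ptraj: PermutedTrajectory, m: int) -> np.ndarray:
    coords = ptraj.unwrapped if getattr(ptraj, "unwrapped", None) is not None \
        else ptraj.positions
    return coords[:, m, :]


def _engine_from_params(params: EstimatorParams) -> MatchedRadiusMI:
    return MatchedRadiusMI(
        k=params.k,
        query_subsample=params.query_subsample,
        seed=params.seed,
        duplicate_policy=params.duplicate_policy,
    )


def mutual_information_2(
    ptraj: PermutedTrajectory,
    i: int,
    j: int,
    params: Optional[EstimatorParams] = None,
    S_cache: Optional[Dict[Tuple[int, ...], float]] = None,
    method: str = "ksg",
    engine: Optional[MatchedRadiusMI] = None,
) -> float:
    """Pairwise mutual information I2 = S_i + S_j - S_ij, nats.

    ``method="ksg"`` (default) evaluates the difference with the
    matched-radius estimator, whose leading finite-sample biases cancel;
    ``method="difference"`` subtracts independent marginal-entropy
    estimates (the slower-converging textbook route). Negative estimates
    (noise around zero) are reported as-is. ``S_cache`` memoizes marginal
    entropies across calls of the difference route.
    """
    if params is None:
        params = EstimatorParams()
    if method == "ksg":
        eng = engine if engine is not None else _engine_from_params(params)
        return eng.multi_information(
            [_molecule_block(ptraj, i), _molecule_block(ptraj, j)],
            keys=[("mol", i), ("mol", j)],
        )
    if method != "difference":
        raise ValueError(f"unknown MI method {method!r}")
    cache = S_cache if S_cache is not None else {}
    for key in [(i,), (j,)]:
        if key not in cache:
            cache[key] = marginal_entropy(ptraj, key, params)
    pair = (i, j) if i < j else (j, i)
    if pair not in cache:
        cache[pair] = marginal_entropy(ptraj, pair, params)
    return cache[(i,)] + cache[(j,)] - cache[pair]


def mutual_information_3(
    ptraj: PermutedTrajectory,
    i: int,
    j: int,
    k: int,
    params: Optional[EstimatorParams] = None,
    S_cache: Optional[Dict[Tuple[int, ...], float]] = None,
    method: str = "ksg",
    engine: Optional[MatchedRadiusMI] = None,
    pair_mi: Optional[Dict[Tuple[int, int], float]] = None,
) -> float:
    """Triplewise interaction information
    I3 = S_i + S_j + S_k - S_ij - S_ik - S_jk + S_ijk, nats.

    The matched-radius route uses the identity
    I3 = I2(i,j) + I2(i,k) + I2(j,k) - M3(i,j,k), where M3 is the
    three-block multi-information; ``pair_mi`` supplies already-computed
    pair terms.
    """
    if params is None:
        params = EstimatorParams()
    idx = tuple(sorted((i, j, k)))
    if method == "ksg":
        eng = engine if engine is not None else _engine_from_params(params)
        legs = [tuple(p) for p in itertools.combinations(idx, 2)]
        i2 = {}
        for a, b in legs:
            if pair_mi is not None and (a, b) in pair_mi:
                i2[(a, b)] = pair_mi[(a, b)]
            else:
                i2[(a, b)] = mutual_information_2(
                    ptraj, a, b, params, method="ksg", engine=eng
                )
        m3 = eng.multi_information(
            [_molecule_block(ptraj, m) for m in idx],
            keys=[("mol", m) for m in idx],
        )
        return sum(i2.values()) - m3
    if method != "difference":
        raise ValueError(f"unknown MI method {method!r}")
    cache = S_cache if S_cache is not None else {}
    singles = [(m,) for m in idx]
    pairs = [tuple(p) for p in itertools.combinations(idx, 2)]
    for key in singles + pairs + [idx]:
        if key not in cache:
            cache[key] = marginal_entropy(ptraj, key, params)
    return (
        sum(cache[s] for s in singles)
        - sum(cache[p] for p in pairs)
        + cache[idx]
    )


def trans_rot_mi(
    ptraj: PermutedTrajectory,
    orientations: OrientationTrack,
    pairs: Optional[Sequence[Tuple[int, int]]] = None,
    params: Optional[EstimatorParams] = None,
    metric: Optional[CompositeMetricParams] = None,
    self_only: bool = False,
    policy: Optional[CutoffPolicy] = None,
) -> Dict[Tuple[int, int], float]:
    """Translation-rotation mutual information terms, nats.

    For each (j, k): I = S(x_j) + S(q_k) - S(x_j, q_k), with the joint
    entropy estimated under the composite metric. By default the pair set
    is all self-pairs plus ordered cross pairs within the pair cutoff
    (self-coupling dominates; cross terms decay with distance);
    ``self_only=True`` restricts to j == k.
    """
    if params is None:
        params = EstimatorParams()
    if metric is None:
        metric = CompositeMetricParams()
    if orientations.n_frames != ptraj.n_frames:
        raise ValueError("orientation track and trajectory frame counts differ")
    if orientations.n_molecules != ptraj.n_molecules:
        raise ValueError("orientation track and trajectory molecule counts differ")
    if pairs is None:
        N = ptraj.n_molecules
        pairs = [(j, j) for j in range(N)]
        if not self_only:
            D = mean_distance_matrix(ptraj)
            cut = (policy or CutoffPolicy()).pair_cutoff
            for j in range(N):
                for k in range(N):
                    if j != k and D[j, k] < cut:
                        pairs.append((j, k))

    comp_params = dc_replace(params, space="composite", metric_params=metric)
    trans_params = params
    S_x: Dict[int, float] = {}
    S_q: Dict[int, float] = {}
    out: Dict[Tuple[int, int], float] = {}
    so3_params = dc_replace(params, space="so3")
    coords = ptraj.unwrapped if ptraj.unwrapped is not None else ptraj.positions
    box = ptraj.box[0]
    for j, k in pairs:
        if j not in S_x:
            S_x[j] = marginal_entropy(ptraj, (j,), trans_params)
        if k not in S_q:
            S_q[k] = knn_entropy(orientations.quaternions[:, k, :], so3_params)
        joint = np.hstack([coords[:, j, :], orientations.quaternions[:, k, :]])
        # keep the joint estimate periodicity-consistent with the marginal
        spread = np.abs(coords[:, j, :] - coords[:, j, :].mean(axis=0)).max()
        jp = dc_replace(
            comp_params, periodic_box=box if spread > box.min() / 4.0 else None
        )
        S_joint = knn_entropy(joint, jp)
        out[(j, k)] = S_x[j] + S_q[k] - S_joint
    return out


# ---------------------------------------------------------------------------
# Analytic kinetic terms
# ---------------------------------------------------------------------------


def kinetic_entropy_trans(params: ThermoParams) -> float:
    """Analytic kinetic translational entropy per molecule, J mol^-1 K^-1.

    S_kin = R (3/2 - 3 ln(lambda / l)); the configurational part measured
    in units of l supplies the compensating +3 R ln l dependence.
    """
    lam = thermal_wavelength_nm(params.molecular_mass, params.temperature)
    return GAS_CONSTANT_R * (1.5 - 3.0 * math.log(lam / params.length_unit))


def sackur_tetrode(params: ThermoParams, number_density: float) -> float:
    """Ideal-gas entropy per particle (Stirling limit), J mol^-1 K^-1.

    S/R = ln(1 / (rho lambda^3)) + 5/2, with rho in nm^-3 and lambda the
    thermal wavelength in nm.
    """
    if number_density <= 0:
        raise ValueError("density must be positive")
    lam = thermal_wavelength_nm(params.molecular_mass, params.temperature)
    return GAS_CONSTANT_R * (math.log(1.0 / (number_density * lam**3)) + 2.5)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def assemble_total(report: EntropyReport) -> EntropyReport:
    """Fill in total and per-component molar entropies of a report.

    Translational: kinetic + R (sum S1 - sum I2 + sum I3) / N per molecule.
    Rotational (if present): R sum S1_rot / N, relative to the uniform
    reference. The translation-rotation term enters as -R sum I_tr / N.
    The uncertainty is the standard error across the per-molecule
    decomposition.
    """
    from .spatial import per_molecule_decomposition

    N = report.n_molecules
    S1 = float(np.sum(report.S1_trans))
    sum_I2 = float(sum(report.I2.values()))
    sum_I3 = float(sum(report.I3.values()))
    conf_nats = S1 - sum_I2 + sum_I3
    components = {
        "kinetic": report.kinetic_per_molecule,
        "first_order": report.kinetic_per_molecule + nats_to_molar(S1) / N,
        "second_order": -nats_to_molar(sum_I2) / N,
        "third_order": nats_to_molar(sum_I3) / N,
        "trans_total": report.kinetic_per_molecule + nats_to_molar(conf_nats) / N,
    }
    total = components["trans_total"]
    if report.S1_rot is not None:
        components["rot_first_order"] = nats_to_molar(float(np.sum(report.S1_rot))) / N
        total += components["rot_first_order"]
    if report.I_tr:
        components["trans_rot_mi"] = -nats_to_molar(float(sum(report.I_tr.values()))) / N
        total += components["trans_rot_mi"]
    report.components = components
    dec = per_molecule_decomposition(report)
    stderr = float(np.std(dec["total"], ddof=1) / math.sqrt(N)) if N > 1 else 0.0
    report.total = EntropyValue(value=total, stderr=stderr, basis=conf_nats / N)
    return report


def compute_report(
    ptraj: PermutedTrajectory,
    thermo: ThermoParams,
    policy: Optional[CutoffPolicy] = None,
    params: Optional[EstimatorParams] = None,
    orientations: Optional[OrientationTrack] = None,
    order: int = 3,
    metric: Optional[CompositeMetricParams] = None,
    trans_rot: str = "auto",
    mi_params: Optional[EstimatorParams] = None,
    mi_frame_stride: int = 1,
    mi_method: str = "ksg",
) -> EntropyReport:
    """Run the full expansion on a permutation-reduced trajectory.

    ``order`` truncates the expansion (1, 2 or 3). ``mi_params`` and
    ``mi_frame_stride`` optionally run the pair/triple/I_tr terms with a
    different estimator configuration and on a frame subsample (every
    ``stride``-th frame); all marginals inside one MI difference always use
    the same frames so the estimator biases partially cancel. First-order
    entropies always use ``params`` on all frames. ``trans_rot``: "auto"
    computes I_tr when orientations are given, "off" disables it, "self"
    restricts to self-pairs.
    """
    if policy is None:
        policy = CutoffPolicy()
    if params is None:
        params = EstimatorParams()
    if mi_params is None:
        mi_params = params
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    N = ptraj.n_molecules

    S1 = np.array([marginal_entropy(ptraj, (i,), params) for i in range(N)])
    pairs, triples = select_pairs_triples(ptraj, policy) if order > 1 else ([], [])
    mi_traj = stride_frames(ptraj, mi_frame_stride)
    cache: Dict[Tuple[int, ...], float] = {}
    engine = _engine_from_params(mi_params) if mi_method == "ksg" else None
    I2 = {}
    if order >= 2:
        for i, j in pairs:
            I2[(i, j)] = mutual_information_2(
                mi_traj, i, j, mi_params, cache, method=mi_method, engine=engine
            )
    I3 = {}
    if order >= 3:
        for i, j, k in triples:
            I3[(i, j, k)] = mutual_information_3(
                mi_traj, i, j, k, mi_params, cache,
                method=mi_method, engine=engine, pair_mi=I2,
            )

    S1_rot = None
    I_tr: Dict[Tuple[int, int], float] = {}
    if orientations is not None and trans_rot != "off":
        so3_params = dc_replace(params, space="so3")
        S1_rot = np.array(
            [knn_entropy(orientations.quaternions[:, m, :], so3_params) for m in range(N)]
        )
        mi_orient = OrientationTrack(orientations.quaternions[::mi_frame_stride]) \
            if mi_frame_stride > 1 else orientations
        I_tr = trans_rot_mi(
            mi_traj,
            mi_orient,
            params=mi_params,
            metric=metric,
            self_only=(trans_rot == "self"),
            policy=policy,
        )

    report = EntropyReport(
        molecule_ids=ptraj.molecule_ids,
        S1_trans=S1,
        I2=I2,
        I3=I3,
        S1_rot=S1_rot,
        I_tr=I_tr,
        kinetic_per_molecule=kinetic_entropy_trans(thermo),
        n_f=ptraj.n_frames,
        params={
            "k": params.k,
            "order": order,
            "mi_method": mi_method,
            "pair_cutoff": policy.pair_cutoff,
            "triple_cutoff": policy.triple_cutoff,
            "xi": (metric or CompositeMetricParams()).xi,
            "temperature": thermo.temperature,
            "molecular_mass": thermo.molecular_mass,
            "seed": params.seed,
        },
    )
    return assemble_total(report)
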