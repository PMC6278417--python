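"""Seedable synthetic data: pose tables, judgment matrices, plate reads.

The pose generator emulates a docking campaign at the scale the pipeline is
designed for — by default 10 runs x 30 poses per ligand, criterion values in
the ranges typical of oxime/AChE docking (distance 3.5-6 Å, intermolecular
energy -130 to -70 kcal/mol, H-bond energy -12 to 0 kcal/mol, 1-4 contact
residues).  Controlled fractions of rule-violating poses (positive energies,
no active-site contact) and near-duplicates are injected so screening can be
validated by exact recovery of the injected violators.

The PCM generator builds reciprocal matrices around a random priority vector
w via ``a_ij = (w_i / w_j) * exp(t * e_ij)`` with antisymmetric noise e and
bisects the noise scale t until the consistency ratio hits a requested
target.

All randomness flows from one integer seed through named, spawned
sub-streams (values / violators / duplicates), so adding draws to one stage
does not shift another.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core_io import NumericError, PairwiseComparisonMatrix, PoseRecord
from . import ahp as _ahp

__all__ = [
    "DEFAULT_ACTIVE_SITE",
    "DECOY_RESIDUES",
    "PoseGenSpec",
    "PCMGenSpec",
    "gen_pose_tables",
    "gen_pcm",
    "gen_plate_table",
]

#: Residues lining the AChE active-site gorge (catalytic triad, oxyanion
#: hole, choline-binding and peripheral sites) used as contact labels.
DEFAULT_ACTIVE_SITE: tuple[str, ...] = (
    "Ser203", "His447", "Glu334", "Trp86", "Gly121", "Gly122", "Tyr124",
    "Ser125", "Glu202", "Ala204", "Trp286", "Phe295", "Phe297", "Tyr337",
    "Phe338", "Tyr341", "Asp74", "Tyr72",
)

#: Surface residues far from the gorge, used for no-contact violator poses.
DECOY_RESIDUES: tuple[str, ...] = (
    "Pro232", "Lys348", "Asn533", "Gln413", "Thr436", "Arg296",
)


@dataclass(frozen=True)
class PoseGenSpec:
    """Parameters of a synthetic docking campaign.

    Ranges are (low, high) for uniform sampling or (mean, sd) for normal
    sampling, chosen by ``noise_model``.  ``fraction_fail_rule1/2/3`` and
    ``fraction_duplicates`` are converted to pose counts by rounding to the
    nearest integer.
    """

    n_ligands: int = 3
    n_runs: int = 10
    poses_per_run: int = 30
    distance_range: tuple[float, float] = (3.5, 6.0)
    e_inter_range: tuple[float, float] = (-130.0, -70.0)
    e_hbond_range: tuple[float, float] = (-12.0, 0.0)
    n_residues_range: tuple[int, int] = (1, 4)
    noise_model: str = "uniform"
    fraction_fail_rule1: float = 0.05
    fraction_fail_rule2: float = 0.05
    fraction_fail_rule3: float = 0.05
    fraction_duplicates: float = 0.05
    duplicate_perturbation: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_fail_rule1", "fraction_fail_rule2",
                     "fraction_fail_rule3", "fraction_duplicates"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.poses_per_run < 1:
            raise ValueError("poses_per_run must be >= 1")
        if self.noise_model not in ("uniform", "normal"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    @property
    def n_total(self) -> int:
        return self.n_ligands * self.n_runs * self.poses_per_run


@dataclass(frozen=True)
class PCMGenSpec:
    """Parameters of a synthetic pairwise-comparison matrix."""

    n: int = 4
    target_cr: float = 0.0
    noise: float = 0.1        # initial log-scale sigma for the bisection
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("PCM order must be >= 2")
        if self.target_cr < 0:
            raise ValueError("target_cr must be >= 0")


def _draw(rng: np.random.Generator, rng_pair, size, model: str) -> np.ndarray:
    lo, hi = rng_pair
    if model == "uniform":
        return rng.uniform(lo, hi, size=size)
    mean, sd = (lo + hi) / 2.0, (hi - lo) / 4.0
    return rng.normal(mean, sd, size=size)


def gen_pose_tables(spec: PoseGenSpec) -> list[PoseRecord]:
    """Generate a full synthetic campaign as a flat pose list.

    Poses are emitted ligand-by-ligand, run-by-run, in generation order.
    Clean poses always carry at least one active-site contact and strictly
    negative energies.  Violators are injected on disjoint random index
    sets, each violating exactly one rule; duplicates are near-copies
    (within ``duplicate_perturbation`` on continuous criteria, equal
    residue count) of a randomly chosen clean pose of the same ligand,
    replacing the pose at the chosen index.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_values, rng_viol, rng_dup = (
        np.random.default_rng(s) for s in ss.spawn(3))

    total = spec.n_total
    dist = _draw(rng_values, spec.distance_range, total, spec.noise_model)
    dist = np.clip(dist, 0.5, None)  # distances must stay positive
    e_int = _draw(rng_values, spec.e_inter_range, total, spec.noise_model)
    e_hb = _draw(rng_values, spec.e_hbond_range, total, spec.noise_model)
    e_int = np.minimum(e_int, -1e-6)
    e_hb = np.minimum(e_hb, 0.0)
    n_res = rng_values.integers(max(1, spec.n_residues_range[0]),
                                spec.n_residues_range[1] + 1, size=total)

    poses: list[PoseRecord] = []
    idx = 0
    for lig in range(spec.n_ligands):
        ligand_id = f"ligand{lig + 1}"
        for run in range(1, spec.n_runs + 1):
            for k in range(1, spec.poses_per_run + 1):
                n_r = int(n_res[idx])
                residues = tuple(rng_values.choice(
                    DEFAULT_ACTIVE_SITE, size=n_r, replace=False))
                poses.append(PoseRecord(
                    ligand_id=ligand_id, run_id=run,
                    pose_id=f"run{run}_pose{k}",
                    distance_OP=float(dist[idx]),
                    e_inter=float(e_int[idx]),
                    e_hbond=float(e_hb[idx]),
                    residues=residues))
                idx += 1

    # disjoint violator index sets, sizes rounded to nearest integer
    n1 = round(spec.fraction_fail_rule1 * total)
    n2 = round(spec.fraction_fail_rule2 * total)
    n3 = round(spec.fraction_fail_rule3 * total)
    nd = round(spec.fraction_duplicates * total)
    chosen = rng_viol.choice(total, size=min(total, n1 + n2 + n3 + nd),
                             replace=False)
    i1, i2 = chosen[:n1], chosen[n1:n1 + n2]
    i3, idup = chosen[n1 + n2:n1 + n2 + n3], chosen[n1 + n2 + n3:]

    for i in i1:  # rule 1: positive intermolecular energy
        p = poses[i]
        poses[i] = replace(p, e_inter=float(rng_viol.uniform(0.5, 20.0)))
    for i in i2:  # rule 2: positive H-bond energy, binding still negative
        p = poses[i]
        poses[i] = replace(p, e_hbond=float(rng_viol.uniform(0.1, 5.0)))
    for i in i3:  # rule 3: contacts only decoy residues
        p = poses[i]
        k = min(len(DECOY_RESIDUES), max(1, p.n_residues))
        residues = tuple(rng_viol.choice(DECOY_RESIDUES, size=k,
                                         replace=False))
        poses[i] = replace(p, residues=residues, n_residues=k)

    clean = sorted(set(range(total)) - set(int(c) for c in chosen))
    per_ligand = spec.n_runs * spec.poses_per_run
    for i in idup:  # rule 4: near-duplicate of a clean pose, same ligand
        lig = int(i) // per_ligand
        pool = [c for c in clean
                if c // per_ligand == lig and c != int(i)]
        if not pool:
            continue
        src = poses[pool[int(rng_dup.integers(len(pool)))]]
        jit = spec.duplicate_perturbation
        poses[i] = replace(
            poses[i],
            distance_OP=src.distance_OP + float(rng_dup.uniform(-jit, jit)),
            e_inter=src.e_inter + float(rng_dup.uniform(-jit, jit)),
            e_hbond=src.e_hbond + float(rng_dup.uniform(-jit, jit)),
            residues=src.residues, n_residues=src.n_residues)
    return poses


def gen_pcm(spec: PCMGenSpec, max_bisect: int = 200,
            ) -> PairwiseComparisonMatrix:
    """Generate a reciprocal PCM with a requested consistency ratio.

    A random positive priority vector w defines the consistent skeleton
    ``w_i / w_j``; antisymmetric log-normal noise is added and its scale
    bisected until |CR - target| < 0.005.  ``target_cr = 0`` returns the
    exactly consistent matrix.  Raises :class:`NumericError` if the scale
    cannot be bracketed or bisection fails to converge.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n = spec.n
    w = rng.uniform(0.2, 5.0, size=n)
    eps = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    eps[iu] = rng.normal(0.0, 1.0, size=len(iu[0]))
    eps -= eps.T  # antisymmetric => reciprocity at every noise scale
    labels = tuple(f"c{i + 1}" for i in range(n))
    skeleton = np.log(np.outer(w, 1.0 / w))

    def matrix_at(t: float) -> PairwiseComparisonMatrix:
        a = np.exp(skeleton + t * eps)
        np.fill_diagonal(a, 1.0)
        return PairwiseComparisonMatrix(labels, a)

    if spec.target_cr == 0.0:
        return matrix_at(0.0)

    def cr_at(t: float) -> float:
        return _ahp.consistency_ratio(matrix_at(t))

    lo, hi = 0.0, max(spec.noise, 1e-3)
    for _ in range(max_bisect):
        if cr_at(hi) >= spec.target_cr:
            break
        hi *= 2.0
    else:
        raise NumericError("could not bracket the target consistency ratio")
    for _ in range(max_bisect):
        mid = 0.5 * (lo + hi)
        cr = cr_at(mid)
        if abs(cr - spec.target_cr) < 0.005:
            return matrix_at(mid)
        if cr < spec.target_cr:
            lo = mid
        else:
            hi = mid
    raise NumericError(
        f"bisection failed to reach target CR {spec.target_cr} "
        f"in {max_bisect} steps")


def gen_plate_table(compounds=("oximeA", "oximeB"),
                    concentrations_uM=(10.0, 100.0),
                    times_min=(10.0, 30.0),
                    n_replicates: int = 3,
                    seed: int = 0):
    """Synthetic long-format Ellman plate table as a pandas DataFrame.

    Emulates a triplicate assay: L0 around 0.9 absorbance units, strong
    inhibition (Li around 0.1), and partial reactivation growing with
    concentration and time, with small normal well noise.
    """
    import pandas as pd

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for comp in compounds:
        potency = rng.uniform(0.2, 0.8)
        for conc in concentrations_uM:
            for t in times_min:
                frac = potency * (conc / (conc + 50.0)) * (t / (t + 20.0))
                L0, Li = 0.9, 0.1
                Lr = Li + frac * (L0 - Li)
                for role, mean in (("L0_negative_control", L0),
                                   ("Li_inhibited", Li),
                                   ("Lr_reactivated", Lr)):
                    for rep in range(1, n_replicates + 1):
                        rows.append({
                            "compound": comp,
                            "concentration_uM": conc,
                            "time_min": t,
                            "role": role,
                            "replicate": rep,
                            "absorbance": max(
                                0.0, mean + rng.normal(0.0, 0.01)),
                        })
    return pd.DataFrame(rows)
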