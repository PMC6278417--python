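"""Pre-evaluation screening of docking poses.

A docking campaign of ~10 runs x 30 poses per ligand produces far more
candidates than a pairwise multicriteria evaluation can digest, so poses are
screened before ranking:

1. poses with positive intermolecular energy are discarded;
2. poses with positive H-bond energy are discarded;
3. poses with no contact to any active-site residue are discarded;
4. near-duplicate poses (all four criterion values agreeing within
   per-criterion tolerances) are collapsed to the first occurrence.

Finally, one pose per docking run is pre-selected: the one with the lowest
oxime-O-to-phosphorus distance, ties broken by the lowest intermolecular
energy, so at least one candidate per run reaches the decision matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .core_io import ConfigError, PoseRecord

__all__ = [
    "ReasonCode",
    "SimilarityEps",
    "ScreeningReport",
    "apply_elimination_rules",
    "select_run_best",
    "screen_poses",
    "DEFAULT_SIMILARITY_EPS",
]


class ReasonCode(str, Enum):
    """Why a pose was removed; the first triggered rule is recorded."""

    POSITIVE_E_INTER = "positive_e_inter"
    POSITIVE_E_HBOND = "positive_e_hbond"
    NO_ACTIVE_SITE_CONTACT = "no_active_site_contact"
    SIMILAR_DUPLICATE = "similar_duplicate"
    NOT_RUN_BEST = "not_run_best"


@dataclass(frozen=True)
class SimilarityEps:
    """Per-criterion tolerances under which two poses count as duplicates.

    Units: Å, kcal/mol, kcal/mol, residues. ``n_residues`` defaults to 0,
    i.e. duplicate poses must agree exactly on the contact count.
    """

    distance_OP: float = 0.01
    e_inter: float = 0.01
    e_hbond: float = 0.01
    n_residues: float = 0.0

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.distance_OP, self.e_inter, self.e_hbond,
                self.n_residues)


DEFAULT_SIMILARITY_EPS = SimilarityEps()


@dataclass
class ScreeningReport:
    """Partition of the input poses into kept and removed-with-reason."""

    kept: list[PoseRecord]
    removed: list[tuple[PoseRecord, ReasonCode]]

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.removed)

    def removed_by(self, reason: ReasonCode) -> list[PoseRecord]:
        return [p for p, r in self.removed if r is reason]


def _norm_residue(label: str) -> str:
    return label.strip().casefold()


def _similar(a: PoseRecord, b: PoseRecord,
             eps: tuple[float, float, float, float]) -> bool:
    return all(abs(x - y) <= e for x, y, e in zip(
        a.criterion_values(), b.criterion_values(), eps))


def apply_elimination_rules(
    poses: Sequence[PoseRecord],
    active_site: Iterable[str] | None = None,
    similarity_eps: SimilarityEps = DEFAULT_SIMILARITY_EPS,
) -> ScreeningReport:
    """Apply the four elimination rules in their numbered order.

    ``active_site=None`` disables rule 3 (an empty set is a configuration
    error: rule 3 with nothing to match would remove every pose). Residue
    matching is case-insensitive after whitespace stripping. Each removed
    pose records only the first rule that fired. Rule 4 keeps the first pose
    of every similarity group in input order.
    """
    site: set[str] | None
    if active_site is None:
        site = None
    else:
        site = {_norm_residue(r) for r in active_site}
        if not site:
            raise ConfigError("active_site must be non-empty when rule 3 "
                              "is enabled (pass None to disable)")

    eps = similarity_eps.as_tuple()
    kept: list[PoseRecord] = []
    removed: list[tuple[PoseRecord, ReasonCode]] = []
    for pose in poses:
        if pose.e_inter > 0:
            removed.append((pose, ReasonCode.POSITIVE_E_INTER))
        elif pose.e_hbond > 0:
            removed.append((pose, ReasonCode.POSITIVE_E_HBOND))
        elif site is not None and not site & {
                _norm_residue(r) for r in pose.residues}:
            removed.append((pose, ReasonCode.NO_ACTIVE_SITE_CONTACT))
        elif any(k.ligand_id == pose.ligand_id and _similar(k, pose, eps)
                 for k in kept):
            removed.append((pose, ReasonCode.SIMILAR_DUPLICATE))
        else:
            kept.append(pose)
    return ScreeningReport(kept=kept, removed=removed)


def select_run_best(poses: Sequence[PoseRecord]) -> list[PoseRecord]:
    """Keep one pose per (ligand, run): lowest distance, then lowest energy.

    Selection is lexicographic — minimal ``distance_OP`` first, ties broken
    by minimal ``e_inter``, remaining ties by input order.  Output is ordered
    by (ligand_id first appearance, run_id).
    """
    groups: dict[tuple[str, int], list[tuple[float, float, int, PoseRecord]]] = {}
    ligand_order: dict[str, int] = {}
    for idx, p in enumerate(poses):
        ligand_order.setdefault(p.ligand_id, len(ligand_order))
        groups.setdefault((p.ligand_id, p.run_id), []).append(
            (p.distance_OP, p.e_inter, idx, p))
    ordered_keys = sorted(groups, key=lambda k: (ligand_order[k[0]], k[1]))
    return [min(groups[k])[3] for k in ordered_keys]


def screen_poses(
    poses: Sequence[PoseRecord],
    active_site: Iterable[str] | None = None,
    similarity_eps: SimilarityEps = DEFAULT_SIMILARITY_EPS,
    order: str = "rules_then_best",
) -> ScreeningReport:
    """Full screen: elimination rules plus per-run pre-selection.

    ``order`` selects whether the four rules run before per-run selection
    (default) or after; poses losing the per-run selection are recorded with
    reason ``not_run_best``.
    """
    if order not in ("rules_then_best", "best_then_rules"):
        raise ConfigError(f"unknown screening order {order!r}")
    if order == "rules_then_best":
        report = apply_elimination_rules(poses, active_site, similarity_eps)
        survivors = select_run_best(report.kept)
        chosen = set(id(p) for p in survivors)
        extra = [(p, ReasonCode.NOT_RUN_BEST)
                 for p in report.kept if id(p) not in chosen]
        return ScreeningReport(kept=survivors, removed=report.removed + extra)
    best = select_run_best(poses)
    best_ids = set(id(p) for p in best)
    pre_removed = [(p, ReasonCode.NOT_RUN_BEST)
                   for p in poses if id(p) not in best_ids]
    report = apply_elimination_rules(best, active_site, similarity_eps)
    return ScreeningReport(kept=report.kept,
                           removed=pre_removed + report.removed)
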