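"""Domain types and delimited-text I/O for the pose-ranking pipeline.

The pipeline evaluates docking poses of oxime reactivators inside
paraoxon-inhibited acetylcholinesterase (AChE) on four criteria:

1. ``distance_OP`` — distance from the oxime oxygen to the organophosphate
   phosphorus, in Å (smaller is better: the oxygen must reach the
   phosphylated catalytic serine to trigger reactivation);
2. ``e_inter`` — intermolecular (binding) energy in kcal/mol (more negative
   is better);
3. ``e_hbond`` — hydrogen-bond energy in kcal/mol (more negative is better);
4. ``n_residues`` — number of active-site residues engaged in H-bonds
   (larger is better).

Everything is plain delimited text: pose tables and pairwise-comparison
matrices (PCMs) are CSV/TSV with a mandatory header, residue lists are
semicolon-separated inside one cell, and PCM cells accept exact fraction
literals such as ``1/7`` so that Saaty-scale reciprocity survives parsing.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "PoseRankError",
    "FormatError",
    "ParseError",
    "DataDomainError",
    "ReciprocityError",
    "ConfigError",
    "NumericError",
    "SchemaError",
    "PoseRecord",
    "CriterionSpec",
    "PairwiseComparisonMatrix",
    "DecisionMatrix",
    "PlateMeasurement",
    "CRITERION_FIELDS",
    "DEFAULT_CRITERIA",
    "parse_number",
    "read_pose_table",
    "write_pose_table",
    "read_pcm",
    "write_pcm",
    "read_active_site",
    "build_decision_matrix",
    "fixture_path",
    "load_fixture_poses",
    "load_expert_pcms",
    "load_group_pcm",
    "load_best_pose_summary",
    "verify_fixture_checksums",
]


# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------

class PoseRankError(Exception):
    """Base class for all package errors."""


class FormatError(PoseRankError):
    """Structural problem in an input file (missing column, non-square block)."""


class ParseError(FormatError):
    """A cell could not be parsed; the message carries the row number."""


class DataDomainError(PoseRankError, ValueError):
    """A value lies outside its mathematical domain (e.g. PCM entry <= 0)."""


class ReciprocityError(PoseRankError):
    """Strict-mode reciprocity violation in a pairwise-comparison matrix."""


class ConfigError(PoseRankError):
    """Inconsistent or incomplete run configuration."""


class NumericError(PoseRankError):
    """An iterative numerical procedure failed to converge."""


class SchemaError(PoseRankError):
    """A grouped record set is missing a required role or column."""


# --------------------------------------------------------------------------
# Numeric cell parsing
# --------------------------------------------------------------------------

#: Single-character vulgar fractions occasionally found in typeset tables.
_VULGAR = {
    "¼": "1/4", "½": "1/2", "¾": "3/4",
    "⅓": "1/3", "⅔": "2/3", "⅕": "1/5",
    "⅖": "2/5", "⅗": "3/5", "⅘": "4/5",
    "⅙": "1/6", "⅛": "1/8", "⅑": "1/9",
}

# Typeset minus / dash variants normalised to ASCII hyphen-minus.
_MINUS = str.maketrans({"−": "-", "‒": "-", "–": "-"})


def parse_number(text: str) -> float:
    """Parse one numeric cell, accepting fraction literals.

    Fractions (``1/7``, ``¼``) are evaluated exactly via
    :class:`fractions.Fraction` before the single conversion to float, so a
    Saaty-scale entry and its reciprocal multiply to 1 at machine precision.
    Unicode minus signs are normalised to ASCII.
    """
    s = text.strip().translate(_MINUS)
    s = _VULGAR.get(s, s)
    if not s:
        raise ValueError("empty numeric cell")
    if "/" in s:
        return float(Fraction(s))
    return float(s)


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PoseRecord:
    """One docking pose with its four criterion values and residue contacts.

    ``residues`` may be empty when only the contact *count* is known (as in
    summary tables); in that case ``n_residues`` must be given explicitly.
    """

    ligand_id: str
    run_id: int
    pose_id: str
    distance_OP: float
    e_inter: float
    e_hbond: float
    residues: tuple[str, ...] = ()
    n_residues: int = -1  # -1 sentinel: fill from residues

    def __post_init__(self) -> None:
        if self.run_id < 1:
            raise DataDomainError(f"run_id must be >= 1, got {self.run_id}")
        if not self.distance_OP > 0:
            raise DataDomainError(
                f"distance_OP must be positive, got {self.distance_OP}")
        object.__setattr__(self, "residues", tuple(self.residues))
        if self.n_residues == -1:
            object.__setattr__(self, "n_residues", len(self.residues))
        if self.n_residues < 0:
            raise DataDomainError("n_residues must be >= 0")
        if self.residues and self.n_residues != len(self.residues):
            raise DataDomainError(
                f"n_residues={self.n_residues} inconsistent with "
                f"{len(self.residues)} listed residues")

    def criterion_values(self) -> tuple[float, float, float, float]:
        """The four criterion values in canonical order."""
        return (self.distance_OP, self.e_inter, self.e_hbond,
                float(self.n_residues))


Direction = Literal["benefit", "cost"]


@dataclass(frozen=True)
class CriterionSpec:
    """A named criterion with optimisation direction and optional weight.

    ``direction`` is ``"cost"`` when smaller values are preferred (distance,
    energies) and ``"benefit"`` when larger values are preferred (residue
    count). ``weight`` may be left unset to be supplied later by AHP.
    """

    name: str
    direction: Direction
    weight: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("benefit", "cost"):
            raise DataDomainError(f"unknown direction {self.direction!r}")
        if self.weight is not None and not 0 < self.weight <= 1:
            raise DataDomainError(
                f"weight must lie in (0, 1], got {self.weight}")


#: Mapping from criterion name to the PoseRecord attribute that carries it.
CRITERION_FIELDS: dict[str, str] = {
    "distance_OP": "distance_OP",
    "e_inter": "e_inter",
    "e_hbond": "e_hbond",
    "n_residues": "n_residues",
}

#: The canonical four criteria with their published directions.
DEFAULT_CRITERIA: tuple[CriterionSpec, ...] = (
    CriterionSpec("distance_OP", "cost"),
    CriterionSpec("e_inter", "cost"),
    CriterionSpec("e_hbond", "cost"),
    CriterionSpec("n_residues", "benefit"),
)


@dataclass(frozen=True)
class PairwiseComparisonMatrix:
    """Square positive reciprocal judgment matrix on the Saaty 1-9 scale.

    Entry ``a_ij`` states how much more important criterion *i* is than
    criterion *j*; a consistent judge satisfies ``a_ji == 1/a_ij`` exactly.
    Validation happens in :meth:`validate`; construction only checks shape,
    positivity and a unit diagonal so that rounded published matrices can be
    loaded in lenient mode before symmetrisation.
    """

    labels: tuple[str, ...]
    entries: np.ndarray

    #: relative tolerance on a_ij * a_ji == 1 in strict mode
    STRICT_RTOL = 1e-6
    #: relative tolerance in lenient mode (published matrices are rounded)
    LENIENT_RTOL = 0.05

    def __post_init__(self) -> None:
        a = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", a)
        object.__setattr__(self, "labels", tuple(self.labels))
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise FormatError(f"PCM must be square, got shape {a.shape}")
        if len(self.labels) != a.shape[0]:
            raise FormatError("label count does not match matrix order")
        if not np.all(a > 0):
            raise DataDomainError("PCM entries must be strictly positive")
        if not np.allclose(np.diag(a), 1.0, atol=1e-9):
            raise DataDomainError("PCM diagonal must be 1")

    @property
    def n(self) -> int:
        return self.entries.shape[0]

    def validate(self, mode: Literal["strict", "lenient"] = "strict") -> None:
        """Check reciprocity; raise :class:`ReciprocityError` on violation."""
        rtol = self.STRICT_RTOL if mode == "strict" else self.LENIENT_RTOL
        prod = self.entries * self.entries.T
        bad = np.abs(prod - 1.0) > rtol
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise ReciprocityError(
                f"reciprocity violated at ({i + 1},{j + 1}): "
                f"a_ij={self.entries[i, j]:g}, a_ji={self.entries[j, i]:g} "
                f"(mode={mode})")

    def symmetrized(self) -> "PairwiseComparisonMatrix":
        """Exact-reciprocal copy keeping the upper triangle.

        Used for published matrices whose lower triangle was rounded for
        print: the upper-triangle judgments are kept verbatim and the lower
        triangle is recomputed as exact reciprocals.
        """
        a = self.entries.copy()
        iu = np.triu_indices(self.n, k=1)
        a[(iu[1], iu[0])] = 1.0 / a[iu]
        np.fill_diagonal(a, 1.0)
        return PairwiseComparisonMatrix(self.labels, a)


@dataclass(frozen=True)
class DecisionMatrix:
    """Alternatives x criteria performance table with per-criterion direction."""

    alternatives: tuple[str, ...]
    criteria: tuple[CriterionSpec, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "alternatives", tuple(self.alternatives))
        object.__setattr__(self, "criteria", tuple(self.criteria))
        m, n = len(self.alternatives), len(self.criteria)
        if m < 1 or n < 1:
            raise DataDomainError("decision matrix needs >= 1 row and column")
        if v.shape != (m, n):
            raise FormatError(
                f"values shape {v.shape} does not match {m} alternatives "
                f"x {n} criteria")
        if not np.all(np.isfinite(v)):
            raise DataDomainError("decision matrix has missing values")

    @property
    def directions(self) -> tuple[Direction, ...]:
        return tuple(c.direction for c in self.criteria)

    @property
    def weights(self) -> np.ndarray | None:
        """Weight vector if every criterion carries one, else None."""
        ws = [c.weight for c in self.criteria]
        if any(w is None for w in ws):
            return None
        w = np.array(ws, dtype=float)
        if abs(w.sum() - 1.0) > 1e-9:
            raise DataDomainError(f"criterion weights sum to {w.sum()}, not 1")
        return w


@dataclass(frozen=True)
class PlateMeasurement:
    """One absorbance reading at 412 nm from an Ellman microplate well."""

    role: Literal["L0_negative_control", "Li_inhibited", "Lr_reactivated"]
    replicate: int
    absorbance: float
    compound: str = ""
    concentration_uM: float = float("nan")
    time_min: float = float("nan")

    def __post_init__(self) -> None:
        if self.role not in ("L0_negative_control", "Li_inhibited",
                             "Lr_reactivated"):
            raise DataDomainError(f"unknown plate role {self.role!r}")
        if self.absorbance < 0:
            raise DataDomainError("absorbance must be >= 0")


# --------------------------------------------------------------------------
# Pose table I/O
# --------------------------------------------------------------------------

POSE_COLUMNS = ("ligand_id", "run_id", "pose_id", "distance_OP_A",
                "E_inter_kcalmol", "E_hbond_kcalmol", "residues",
                "n_residues")

RESIDUE_SEP = ";"


def _sniff_delimiter(path: Path) -> str:
    head = path.read_text(encoding="utf-8").splitlines()[0] if path.stat().st_size else ""
    return "\t" if "\t" in head else ","


def read_pose_table(path: str | Path, delimiter: str | None = None,
                    residue_sep: str = RESIDUE_SEP) -> list[PoseRecord]:
    """Read a delimited pose table into :class:`PoseRecord` rows.

    The header must name every column in :data:`POSE_COLUMNS`.  Row order is
    preserved.  Residue lists are ``residue_sep``-separated inside one cell;
    an empty cell means "count only" and ``n_residues`` is taken verbatim.
    """
    path = Path(path)
    delim = delimiter or _sniff_delimiter(path)
    records: list[PoseRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        missing = [c for c in POSE_COLUMNS if c not in header]
        if missing:
            raise FormatError(
                f"{path.name}: missing column(s) {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                residues = tuple(
                    r.strip() for r in (row["residues"] or "").split(residue_sep)
                    if r.strip())
                records.append(PoseRecord(
                    ligand_id=row["ligand_id"].strip(),
                    run_id=int(row["run_id"]),
                    pose_id=row["pose_id"].strip(),
                    distance_OP=parse_number(row["distance_OP_A"]),
                    e_inter=parse_number(row["E_inter_kcalmol"]),
                    e_hbond=parse_number(row["E_hbond_kcalmol"]),
                    residues=residues,
                    n_residues=int(row["n_residues"]),
                ))
            except (ValueError, KeyError) as exc:
                raise ParseError(
                    f"{path.name}, row {lineno}: {exc}") from exc
    return records


def write_pose_table(path: str | Path, poses: Iterable[PoseRecord],
                     delimiter: str = ",",
                     residue_sep: str = RESIDUE_SEP) -> None:
    """Write poses in the dialect :func:`read_pose_table` accepts.

    Floats are written with :func:`repr` so a round trip reproduces values
    to full precision.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(POSE_COLUMNS)
        for p in poses:
            writer.writerow([
                p.ligand_id, p.run_id, p.pose_id,
                repr(p.distance_OP), repr(p.e_inter), repr(p.e_hbond),
                residue_sep.join(p.residues), p.n_residues,
            ])


# --------------------------------------------------------------------------
# PCM I/O
# --------------------------------------------------------------------------

def read_pcm(path: str | Path,
             mode: Literal["strict", "lenient"] = "strict",
             delimiter: str | None = None) -> PairwiseComparisonMatrix:
    """Read a square pairwise-comparison matrix from delimited text.

    Two layouts are accepted: a labelled block (header row + row-label
    column) or a bare numeric block.  Fraction literals are parsed exactly.
    In lenient mode a matrix whose lower triangle is rounded (as published
    group matrices are) is accepted up to 5% relative reciprocity error and
    returned as-is; callers wanting exact reciprocity use
    :meth:`PairwiseComparisonMatrix.symmetrized`.
    """
    path = Path(path)
    delim = delimiter or _sniff_delimiter(path)
    with open(path, newline="", encoding="utf-8") as fh:
        rows = [r for r in csv.reader(fh, delimiter=delim) if any(
            c.strip() for c in r)]
    if not rows:
        raise FormatError(f"{path.name}: empty PCM file")

    def _is_number(cell: str) -> bool:
        try:
            parse_number(cell)
            return True
        except ValueError:
            return False

    if _is_number(rows[0][-1]):  # bare numeric block
        labels = [f"c{i + 1}" for i in range(len(rows))]
        body = rows
        first_col = 0
    else:  # labelled block
        labels = [c.strip() for c in rows[0][1:]]
        body = rows[1:]
        first_col = 1
    n = len(labels)
    if len(body) != n or any(len(r) - first_col != n for r in body):
        raise FormatError(
            f"{path.name}: PCM block is not square ({len(body)} rows, "
            f"{n} labelled columns)")
    entries = np.empty((n, n))
    for i, r in enumerate(body):
        for j, cell in enumerate(r[first_col:]):
            try:
                entries[i, j] = parse_number(cell)
            except ValueError as exc:
                raise ParseError(
                    f"{path.name}, row {i + 1 + first_col}: {exc}") from exc
    pcm = PairwiseComparisonMatrix(tuple(labels), entries)
    pcm.validate(mode)
    return pcm


def write_pcm(path: str | Path, pcm: PairwiseComparisonMatrix,
              delimiter: str = ",") -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["criterion", *pcm.labels])
        for label, row in zip(pcm.labels, pcm.entries):
            writer.writerow([label, *[repr(float(v)) for v in row]])


def read_active_site(path: str | Path) -> set[str]:
    """Read a one-residue-label-per-line active-site file."""
    labels = {ln.strip() for ln in Path(path).read_text(
        encoding="utf-8").splitlines()}
    return {l for l in labels if l and not l.startswith("#")}


# --------------------------------------------------------------------------
# Decision-matrix construction
# --------------------------------------------------------------------------

def build_decision_matrix(poses: Sequence[PoseRecord],
                          criteria: Sequence[CriterionSpec] = DEFAULT_CRITERIA,
                          ) -> DecisionMatrix:
    """Assemble the alternatives x criteria matrix from screened poses.

    Rows follow pose order; columns follow ``criteria`` order, so permuting
    the criteria permutes the columns and nothing else.  Alternative labels
    are the pose ids.
    """
    for c in criteria:
        if c.name not in CRITERION_FIELDS:
            raise ConfigError(
                f"unknown criterion {c.name!r}; expected one of "
                f"{sorted(CRITERION_FIELDS)}")
    values = np.array([
        [float(getattr(p, CRITERION_FIELDS[c.name])) for c in criteria]
        for p in poses])
    labels = tuple(p.pose_id for p in poses)
    return DecisionMatrix(labels, tuple(criteria), values)


# --------------------------------------------------------------------------
# Packaged reference fixtures
# --------------------------------------------------------------------------
# The bundled data reproduce the worked example of the study this package
# emulates: per-run best docking poses of isatin-3-oxime and obidoxime inside
# paraoxon-inhibited AChE, four experts' Saaty-scale judgment matrices, the
# rounded group matrix derived from them, and the per-oxime best-pose summary.

def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    p = resources.files("poserank.data") / name
    return Path(str(p))


def load_fixture_poses(ligand: Literal["obidoxime", "isatin-O"]
                       ) -> list[PoseRecord]:
    fname = {"obidoxime": "obidoxime_poses.csv",
             "isatin-O": "isatin_o_poses.csv"}[ligand]
    return read_pose_table(fixture_path(fname))


def load_expert_pcms() -> list[PairwiseComparisonMatrix]:
    """The four experts' judgment matrices (strict reciprocity)."""
    return [read_pcm(fixture_path(f"expert{k}_pcm.csv")) for k in range(1, 5)]


def load_group_pcm(symmetrize: bool = True) -> PairwiseComparisonMatrix:
    """The rounded group matrix as published.

    With ``symmetrize=True`` (default) the rounded lower triangle is replaced
    by exact reciprocals of the upper triangle.
    """
    pcm = read_pcm(fixture_path("group_pcm.csv"), mode="lenient")
    return pcm.symmetrized() if symmetrize else pcm


def load_best_pose_summary():
    """Per-oxime best-pose summary table as a pandas DataFrame."""
    import pandas as pd

    return pd.read_csv(fixture_path("best_pose_summary.csv"))


def verify_fixture_checksums() -> dict[str, bool]:
    """SHA-256 integrity check of every packaged data file."""
    expected = json.loads(fixture_path("checksums.json").read_text())
    out = {}
    for name, digest in expected.items():
        actual = hashlib.sha256(fixture_path(name).read_bytes()).hexdigest()
        out[name] = actual == digest
    return out
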