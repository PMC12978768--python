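"""Electron-conformational matrices of contiguity (ECMC) and submatrix matching.

An ECMC represents one conformer as an n x n symmetric matrix: the diagonal
a_ii carries an atomic electronic property (default: partial charge, e), the
off-diagonal a_ij carries a bond descriptor (default: bond order) for bonded
pairs and the interatomic Euclidean distance (Å) for nonbonded pairs.
Carbon-hydrogen bonded entries are masked out of all comparisons by default,
since they contribute equally in every compound.

Pharmacophore (ECSA) screening asks whether a k x k reference submatrix can
be embedded in a candidate ECMC: an injective, element-compatible assignment
of reference atoms to candidate atoms under which every unmasked entry agrees
with the reference within a per-element tolerance (inclusive).  The search is
deterministic backtracking (candidate atoms tried in increasing index order;
the first complete assignment wins); a brute-force enumerator over all
injective assignments serves as an independent oracle for small candidates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_formats import ConformerEnsemble, Conformer

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.9872e-3

#: Default temperature (K) for Boltzmann populations.
DEFAULT_TEMPERATURE = 298.15


class PropertyMissingError(ValueError):
    """A required atomic or bond property is absent from the ensemble."""


# ---------------------------------------------------------------------------
# Conformer filtering and Boltzmann populations
# ---------------------------------------------------------------------------

def filter_conformers(ensemble: ConformerEnsemble,
                      energy_window: float = 1.5,
                      max_conformers: int = 100,
                      drop_imaginary: bool = True) -> ConformerEnsemble:
    """Retain low-energy minima: drop imaginary-frequency conformers, keep
    those within ``energy_window`` kcal/mol of the minimum, cap at
    ``max_conformers`` lowest, and re-reference energies to the new minimum.
    """
    kept = list(ensemble.conformers)
    if drop_imaginary:
        kept = [c for c in kept if not c.has_imaginary_freq]
    if kept:
        emin = min(c.rel_energy for c in kept)
        kept = [c for c in kept if c.rel_energy - emin <= energy_window]
    if len(kept) > max_conformers:
        kept = sorted(kept, key=lambda c: (c.rel_energy, c.conformer_id))
        kept = kept[:max_conformers]
    if not kept:
        raise ValueError(
            f"compound {ensemble.compound_id!r}: no conformers survive filtering")
    out = ConformerEnsemble(
        compound_id=ensemble.compound_id, atoms=list(ensemble.atoms),
        bonds=list(ensemble.bonds),
        conformers=[Conformer(c.conformer_id, c.rel_energy, c.has_imaginary_freq,
                              c.coords, c.atomic_charge, dict(c.atomic_props),
                              dict(c.descriptors))
                    for c in kept])
    out.rereference_energies()
    return out


def boltzmann_weights(rel_energies: Sequence[float],
                      T: float = DEFAULT_TEMPERATURE) -> np.ndarray:
    """Normalized populations w_i = exp(-E_i/RT) / sum_j exp(-E_j/RT)."""
    e = np.asarray(rel_energies, dtype=float)
    if e.size == 0:
        raise ValueError("empty energy list")
    if not np.isfinite(e).all():
        raise ValueError("non-finite energy")
    if not T > 0:
        raise ValueError(f"temperature must be positive, got {T}")
    x = -(e - e.min()) / (R_KCAL * T)  # shift for numerical stability
    w = np.exp(x)
    return w / w.sum()


# ---------------------------------------------------------------------------
# ECMC construction
# ---------------------------------------------------------------------------

@dataclass
class ECMC:
    """Electron-conformational matrix of contiguity for one conformer."""

    compound_id: str
    conformer_id: str
    atom_indices: list[int]            # 1-based indices into the source ensemble
    elements: list[str]
    labels: list[Optional[str]]        # skeleton labels where known
    matrix: np.ndarray                 # (n, n) symmetric
    mask: np.ndarray                   # (n, n) bool, True = excluded from comparison

    def __post_init__(self) -> None:
        n = len(self.atom_indices)
        if self.matrix.shape != (n, n) or self.mask.shape != (n, n):
            raise ValueError("ECMC matrix/mask shape mismatch")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("ECMC matrix not symmetric")
        if not (self.mask == self.mask.T).all():
            raise ValueError("ECMC mask not symmetric")

    @property
    def n(self) -> int:
        return len(self.atom_indices)

    def submatrix(self, positions: Sequence[int]) -> "ECMC":
        """ECMC restricted to the given 0-based positions (order preserved)."""
        pos = list(positions)
        return ECMC(
            compound_id=self.compound_id, conformer_id=self.conformer_id,
            atom_indices=[self.atom_indices[p] for p in pos],
            elements=[self.elements[p] for p in pos],
            labels=[self.labels[p] for p in pos],
            matrix=self.matrix[np.ix_(pos, pos)].copy(),
            mask=self.mask[np.ix_(pos, pos)].copy())

    def to_dict(self) -> dict:
        return {
            "compound_id": self.compound_id, "conformer_id": self.conformer_id,
            "atom_indices": self.atom_indices, "elements": self.elements,
            "labels": self.labels, "matrix": self.matrix.tolist(),
            "mask": self.mask.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "ECMC":
        return cls(compound_id=d["compound_id"], conformer_id=d["conformer_id"],
                   atom_indices=list(d["atom_indices"]),
                   elements=list(d["elements"]), labels=list(d["labels"]),
                   matrix=np.asarray(d["matrix"], dtype=float),
                   mask=np.asarray(d["mask"], dtype=bool))


@dataclass
class ToleranceMatrix:
    """Per-element non-negative half-widths (± values) for submatrix matching."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("tolerance matrix must be square")
        if (self.values < 0).any():
            raise ValueError("tolerances must be non-negative")

    @property
    def k(self) -> int:
        return self.values.shape[0]

    @classmethod
    def uniform(cls, k: int, diag: float, offdiag: float) -> "ToleranceMatrix":
        v = np.full((k, k), float(offdiag))
        np.fill_diagonal(v, float(diag))
        return cls(v)


def _atomic_property(conformer: Conformer, name: str, compound_id: str) -> np.ndarray:
    if name == "charge":
        if conformer.atomic_charge is None:
            raise PropertyMissingError(
                f"compound {compound_id!r} conformer {conformer.conformer_id!r}: "
                "atomic charges absent (geometry-only ingest?)")
        return conformer.atomic_charge
    if name in conformer.atomic_props:
        return conformer.atomic_props[name]
    raise PropertyMissingError(
        f"compound {compound_id!r} conformer {conformer.conformer_id!r}: "
        f"atomic property {name!r} absent")


def build_ecmc(ensemble: ConformerEnsemble, conformer_id: str,
               diag_property: str = "charge",
               bonded_property: str = "order",
               mask_ch: bool = True) -> ECMC:
    """Build the ECMC of one conformer.

    ``diag_property`` selects the atomic property on the diagonal ('charge'
    or any key of ``atomic_props``); ``bonded_property`` selects the bond
    descriptor ('order', 'wiberg', 'bond_energy' or 'bond_polarizability')
    for bonded off-diagonal entries; nonbonded entries are Euclidean
    distances in Å.  With ``mask_ch`` the bonded C-H entries are masked.
    """
    conf = ensemble.conformer(conformer_id)
    n = ensemble.n_atoms
    diag = _atomic_property(conf, diag_property, ensemble.compound_id)
    coords = conf.coords
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    matrix = d.copy()
    np.fill_diagonal(matrix, diag)
    mask = np.zeros((n, n), dtype=bool)
    elements = [a.element for a in ensemble.atoms]
    for b in ensemble.bonds:
        value = getattr(b, "order" if bonded_property == "order" else bonded_property)
        if value is None:
            raise PropertyMissingError(
                f"compound {ensemble.compound_id!r}: bond ({b.i},{b.j}) lacks "
                f"property {bonded_property!r}")
        i, j = b.i - 1, b.j - 1
        matrix[i, j] = matrix[j, i] = float(value)
        if mask_ch and {elements[i], elements[j]} == {"C", "H"}:
            mask[i, j] = mask[j, i] = True
    return ECMC(compound_id=ensemble.compound_id, conformer_id=conformer_id,
                atom_indices=[a.index for a in ensemble.atoms],
                elements=elements,
                labels=[a.skeleton_label for a in ensemble.atoms],
                matrix=matrix, mask=mask)


# ---------------------------------------------------------------------------
# Tolerance-bounded submatrix matching
# ---------------------------------------------------------------------------

@dataclass
class MatchResult:
    """Outcome of embedding a reference submatrix into a candidate ECMC."""

    matched: bool
    #: 0-based reference position -> 0-based candidate position (when matched).
    assignment: Optional[dict[int, int]] = None
    #: per-element |deviation| under the matched assignment (NaN where masked).
    deviations: Optional[np.ndarray] = None
    #: (ref_a, ref_b, |deviation|, tolerance) entries that blocked the deepest
    #: partial assignment (when unmatched).
    failing_elements: list[tuple[int, int, float, float]] = field(default_factory=list)

    @property
    def max_abs_deviation(self) -> float:
        if self.deviations is None:
            return math.nan
        finite = self.deviations[np.isfinite(self.deviations)]
        return float(finite.max()) if finite.size else 0.0


def _check_shapes(reference_values: np.ndarray, tolerances: ToleranceMatrix) -> None:
    if reference_values.shape != tolerances.values.shape:
        raise ValueError(
            f"reference {reference_values.shape} and tolerance "
            f"{tolerances.values.shape} shapes differ")
    if reference_values.ndim != 2 or reference_values.shape[0] != reference_values.shape[1]:
        raise ValueError("reference submatrix must be square")


def _deviation_matrix(reference_values: np.ndarray, candidate: ECMC,
                      assignment: dict[int, int]) -> np.ndarray:
    k = reference_values.shape[0]
    dev = np.full((k, k), np.nan)
    for a in range(k):
        for b in range(a, k):
            ca, cb = assignment[a], assignment[b]
            if candidate.mask[ca, cb]:
                continue
            dev[a, b] = dev[b, a] = abs(candidate.matrix[ca, cb]
                                        - reference_values[a, b])
    return dev


def _evaluate_assignment(reference_values: np.ndarray, tol: np.ndarray,
                         candidate: ECMC, assignment: dict[int, int]) -> MatchResult:
    dev = _deviation_matrix(reference_values, candidate, assignment)
    failing = [(a, b, float(dev[a, b]), float(tol[a, b]))
               for a in range(len(assignment)) for b in range(a, len(assignment))
               if np.isfinite(dev[a, b]) and dev[a, b] > tol[a, b]]
    if failing:
        return MatchResult(matched=False, failing_elements=failing)
    return MatchResult(matched=True, assignment=dict(assignment), deviations=dev)


def match_submatrix(reference_values: np.ndarray, tolerances: ToleranceMatrix,
                    candidate: ECMC,
                    reference_elements: Optional[Sequence[str]] = None,
                    fixed_assignment: Optional[dict[int, int]] = None) -> MatchResult:
    """Search for an embedding of the reference submatrix in ``candidate``.

    The embedding must be injective, element-compatible (when
    ``reference_elements`` is given) and satisfy
    ``|candidate - reference| <= tolerance`` elementwise (inclusive) on every
    entry not masked in the candidate.  ``fixed_assignment`` (reference
    position -> candidate position) pins the assignment, as when skeleton
    labels fix the correspondence; otherwise a deterministic backtracking
    search tries candidate atoms in increasing index order and returns the
    first complete assignment.
    """
    reference_values = np.asarray(reference_values, dtype=float)
    _check_shapes(reference_values, tolerances)
    k = reference_values.shape[0]
    tol = tolerances.values
    if reference_elements is not None and len(reference_elements) != k:
        raise ValueError("reference_elements length must equal submatrix size")

    if fixed_assignment is not None:
        if len(fixed_assignment) != k or len(set(fixed_assignment.values())) != k:
            raise ValueError("fixed assignment must be a bijection on reference atoms")
        return _evaluate_assignment(reference_values, tol, candidate,
                                    fixed_assignment)

    # Candidate positions compatible with each reference atom, in index order.
    compatible = []
    for a in range(k):
        if reference_elements is None:
            compatible.append(list(range(candidate.n)))
        else:
            compatible.append([p for p in range(candidate.n)
                               if candidate.elements[p] == reference_elements[a]])

    assignment: dict[int, int] = {}
    used = [False] * candidate.n
    best_depth = -1
    deepest_failures: list[tuple[int, int, float, float]] = []

    def extend_ok(a: int, ca: int) -> bool:
        nonlocal best_depth, deepest_failures
        ok = True
        for b in range(a + 1):
            cb = ca if b == a else assignment[b]
            if candidate.mask[ca, cb]:
                continue
            dev = abs(candidate.matrix[ca, cb] - reference_values[a, b])
            if dev > tol[a, b]:
                if a > best_depth:
                    best_depth, deepest_failures = a, []
                if a == best_depth:
                    deepest_failures.append((min(a, b), max(a, b),
                                             float(dev), float(tol[a, b])))
                ok = False
                break
        return ok

    def backtrack(a: int) -> bool:
        if a == k:
            return True
        for ca in compatible[a]:
            if used[ca]:
                continue
            if extend_ok(a, ca):
                assignment[a] = ca
                used[ca] = True
                if backtrack(a + 1):
                    return True
                used[ca] = False
                del assignment[a]
        return False

    if backtrack(0):
        return MatchResult(matched=True, assignment=dict(assignment),
                           deviations=_deviation_matrix(reference_values,
                                                        candidate, assignment))
    return MatchResult(matched=False, failing_elements=deepest_failures)


def brute_force_match(reference_values: np.ndarray, tolerances: ToleranceMatrix,
                      candidate: ECMC,
                      reference_elements: Optional[Sequence[str]] = None,
                      max_atoms: int = 10) -> MatchResult:
    """Exhaustive-enumeration oracle for :func:`match_submatrix`.

    Enumerates every injective element-compatible assignment (candidates with
    at most ``max_atoms`` atoms) in lexicographic order of candidate
    positions and returns the first match, so a matched verdict carries the
    same assignment the backtracking search finds.
    """
    reference_values = np.asarray(reference_values, dtype=float)
    _check_shapes(reference_values, tolerances)
    if candidate.n > max_atoms:
        raise ValueError(
            f"brute-force guard: candidate has {candidate.n} atoms > {max_atoms}")
    k = reference_values.shape[0]
    if reference_elements is not None and len(reference_elements) != k:
        raise ValueError("reference_elements length must equal submatrix size")
    last_failing: list[tuple[int, int, float, float]] = []
    for perm in itertools.permutations(range(candidate.n), k):
        if reference_elements is not None and any(
                candidate.elements[p] != reference_elements[a]
                for a, p in enumerate(perm)):
            continue
        result = _evaluate_assignment(reference_values, tolerances.values,
                                      candidate, dict(enumerate(perm)))
        if result.matched:
            return result
        last_failing = result.failing_elements
    return MatchResult(matched=False, failing_elements=last_failing)
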