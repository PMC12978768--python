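"""Pharmacophore (ECSA) discovery and screening.

The ECSA — electron-conformational submatrix of activity — is a k x k
fragment of a reference compound's ECMC that is present (within per-element
tolerances) in active compounds and absent in inactive ones.  Discovery
enumerates atom subsets of the reference ECMC by deterministic breadth-first
growth, screens the lowest-energy conformer of every compound under the
initial tolerances, and scores each candidate by the association between
feature presence and the activity class:

    P_a     = (h1 + 1) / (h1 + h2 + 2)
    alpha_a = (h1*h4 - h2*h3) / sqrt(k1*k2*k3*k4)

where h1/h2 count actives with/without the feature, h3/h4 the same for
low-activity compounds, k1 = h1+h2, k2 = h3+h4, k3 = h1+h3, k4 = h2+h4.
alpha_a is a phi-type association coefficient bounded in [-1, 1]; the
square-rooted denominator is the only form with that bound.

Class-wise tolerance matrices (the attained maxima of per-element deviations
over a conformer subset) quantify how tightly each class reproduces the
reference fragment.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import ActivityTable, ConformerEnsemble
from .ecmc_core import (ECMC, MatchResult, ToleranceMatrix, build_ecmc,
                        match_submatrix)


class DegenerateMarginalError(ValueError):
    """A contingency marginal is zero, leaving alpha_a undefined."""


class NoDiscriminatingSubmatrixError(ValueError):
    """No candidate submatrix separates the activity classes (alpha_a <= 0)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ECSA:
    """Pharmacophore submatrix: reference values plus screening tolerances."""

    reference_compound_id: str
    reference_conformer_id: str
    atom_labels: list[str]
    elements: list[str]
    reference_positions: list[int]       # 0-based positions in the reference ECMC
    reference_values: np.ndarray         # (k, k) symmetric
    tolerances: ToleranceMatrix          # screening tolerances
    class_tolerances: dict[str, ToleranceMatrix] = field(default_factory=dict)
    diag_property: str = "charge"
    bonded_property: str = "order"
    mask_ch: bool = True

    def __post_init__(self) -> None:
        self.reference_values = np.asarray(self.reference_values, dtype=float)
        k = len(self.atom_labels)
        if k < 2:
            raise ValueError("ECSA needs at least 2 atoms")
        if self.reference_values.shape != (k, k):
            raise ValueError("reference_values shape must match atom count")
        if not np.allclose(self.reference_values, self.reference_values.T,
                           atol=1e-12):
            raise ValueError("reference_values not symmetric")
        if self.tolerances.k != k:
            raise ValueError("tolerance shape must match atom count")

    @property
    def k(self) -> int:
        return len(self.atom_labels)

    def build_candidate_ecmc(self, ensemble: ConformerEnsemble,
                             conformer_id: str) -> ECMC:
        return build_ecmc(ensemble, conformer_id,
                          diag_property=self.diag_property,
                          bonded_property=self.bonded_property,
                          mask_ch=self.mask_ch)

    def match(self, candidate: ECMC,
              tolerances: Optional[ToleranceMatrix] = None,
              fixed_assignment: Optional[dict[int, int]] = None) -> MatchResult:
        return match_submatrix(self.reference_values,
                               tolerances or self.tolerances, candidate,
                               reference_elements=self.elements,
                               fixed_assignment=fixed_assignment)

    def to_dict(self) -> dict:
        return {
            "reference_compound_id": self.reference_compound_id,
            "reference_conformer_id": self.reference_conformer_id,
            "atom_labels": self.atom_labels,
            "elements": self.elements,
            "reference_positions": self.reference_positions,
            "reference_values": self.reference_values.tolist(),
            "tolerances": self.tolerances.values.tolist(),
            "class_tolerances": {k: v.values.tolist()
                                 for k, v in self.class_tolerances.items()},
            "diag_property": self.diag_property,
            "bonded_property": self.bonded_property,
            "mask_ch": self.mask_ch,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ECSA":
        return cls(
            reference_compound_id=d["reference_compound_id"],
            reference_conformer_id=d["reference_conformer_id"],
            atom_labels=list(d["atom_labels"]), elements=list(d["elements"]),
            reference_positions=list(d["reference_positions"]),
            reference_values=np.asarray(d["reference_values"], dtype=float),
            tolerances=ToleranceMatrix(np.asarray(d["tolerances"], dtype=float)),
            class_tolerances={k: ToleranceMatrix(np.asarray(v, dtype=float))
                              for k, v in d.get("class_tolerances", {}).items()},
            diag_property=d.get("diag_property", "charge"),
            bonded_property=d.get("bonded_property", "order"),
            mask_ch=d.get("mask_ch", True))

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "ECSA":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class MatchTable:
    """Per-conformer pharmacophore presence flags delta_ni with assignments."""

    frame: pd.DataFrame  # columns: compound_id, conformer_id, delta
    assignments: dict[tuple[str, str], Optional[dict[int, int]]] = field(
        default_factory=dict)

    def compound_presence(self) -> dict[str, int]:
        """Compound-level presence: 1 if any retained conformer matches."""
        return {cid: int(g["delta"].max())
                for cid, g in self.frame.groupby("compound_id", sort=False)}

    def delta_vector(self, ensemble: ConformerEnsemble) -> np.ndarray:
        """delta_ni aligned with the ensemble's conformer order."""
        sub = self.frame[self.frame["compound_id"] == ensemble.compound_id]
        lookup = dict(zip(sub["conformer_id"], sub["delta"]))
        try:
            return np.array([lookup[c.conformer_id] for c in ensemble.conformers],
                            dtype=float)
        except KeyError as e:
            raise KeyError(
                f"conformer {e.args[0]!r} of {ensemble.compound_id!r} missing "
                "from match table") from None


@dataclass(frozen=True)
class QualityStats:
    """Contingency counts and the P_a / alpha_a quality estimates."""

    h1: int
    h2: int
    h3: int
    h4: int

    @property
    def k1(self) -> int:
        return self.h1 + self.h2

    @property
    def k2(self) -> int:
        return self.h3 + self.h4

    @property
    def k3(self) -> int:
        return self.h1 + self.h3

    @property
    def k4(self) -> int:
        return self.h2 + self.h4

    @property
    def p_a(self) -> float:
        return (self.h1 + 1) / (self.h1 + self.h2 + 2)

    @property
    def alpha_a(self) -> float:
        denom = self.k1 * self.k2 * self.k3 * self.k4
        if denom == 0:
            raise DegenerateMarginalError(
                f"zero marginal in contingency table h=({self.h1},{self.h2},"
                f"{self.h3},{self.h4}); alpha_a undefined")
        return (self.h1 * self.h4 - self.h2 * self.h3) / math.sqrt(denom)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def quality_stats(presence: dict[str, int], classes: dict[str, str]) -> QualityStats:
    """Contingency counts from compound-level presence flags and classes."""
    missing = set(classes) - set(presence)
    if missing:
        raise ValueError(f"no presence flag for compounds {sorted(missing)}")
    h1 = h2 = h3 = h4 = 0
    for cid, cls in classes.items():
        has = bool(presence[cid])
        if cls == "high":
            h1, h2 = h1 + has, h2 + (not has)
        elif cls == "low":
            h3, h4 = h3 + has, h4 + (not has)
        else:
            raise ValueError(f"unknown activity class {cls!r} for {cid!r}")
    return QualityStats(h1=h1, h2=h2, h3=h3, h4=h4)


def screen(ecsa: ECSA, ensembles: Sequence[ConformerEnsemble],
           tolerances: Optional[ToleranceMatrix] = None,
           lowest_energy_only: bool = False) -> MatchTable:
    """Screen every retained conformer of every compound against the ECSA."""
    rows = []
    assignments: dict[tuple[str, str], Optional[dict[int, int]]] = {}
    for ens in ensembles:
        conformers = ([ens.lowest_energy_conformer()] if lowest_energy_only
                      else ens.conformers)
        for conf in conformers:
            candidate = ecsa.build_candidate_ecmc(ens, conf.conformer_id)
            result = ecsa.match(candidate, tolerances=tolerances)
            rows.append((ens.compound_id, conf.conformer_id, int(result.matched)))
            assignments[(ens.compound_id, conf.conformer_id)] = result.assignment
    frame = pd.DataFrame(rows, columns=["compound_id", "conformer_id", "delta"])
    return MatchTable(frame=frame, assignments=assignments)


def derive_tolerances(ecsa: ECSA,
                      conformer_subset: Iterable[tuple[ConformerEnsemble, str]],
                      screening_tolerances: Optional[ToleranceMatrix] = None
                      ) -> ToleranceMatrix:
    """Attained-maximum tolerances over a conformer subset.

    Every conformer in the subset must match the ECSA under the screening
    tolerances; the returned matrix holds, per element, the maximum absolute
    deviation of the mapped candidate value from the reference (reported as a
    ± half-width).  Entries never compared (masked) stay 0.
    """
    k = ecsa.k
    out = np.zeros((k, k))
    any_conformer = False
    for ens, conformer_id in conformer_subset:
        any_conformer = True
        candidate = ecsa.build_candidate_ecmc(ens, conformer_id)
        result = ecsa.match(candidate, tolerances=screening_tolerances)
        if not result.matched:
            raise ValueError(
                f"conformer {conformer_id!r} of {ens.compound_id!r} does not "
                f"match the ECSA; failing elements: {result.failing_elements}")
        dev = np.where(np.isfinite(result.deviations), result.deviations, 0.0)
        out = np.maximum(out, dev)
    if not any_conformer:
        raise ValueError("empty conformer subset")
    return ToleranceMatrix(out)


def _candidate_subsets(n: int, size_range: tuple[int, int]) -> Iterable[tuple[int, ...]]:
    """Deterministic breadth-first growth: all subsets of each size in
    ascending size order, each size in lexicographic position order (seed
    pairs extended by larger positions)."""
    lo, hi = size_range
    for k in range(max(2, lo), min(n, hi) + 1):
        yield from itertools.combinations(range(n), k)


def find_ecsa(ensembles: Sequence[ConformerEnsemble], activities: ActivityTable,
              reference: str,
              init_tol: tuple[float, float] = (0.25, 1.30),
              size_range: tuple[int, int] = (3, 8),
              diag_property: str = "charge", bonded_property: str = "order",
              mask_ch: bool = True) -> ECSA:
    """Discover the pharmacophore submatrix maximizing alpha_a.

    The reference pattern is the ECMC of the lowest-energy conformer of the
    (high-activity) ``reference`` compound.  Candidate atom subsets within
    ``size_range`` are screened against the lowest-energy conformer of every
    compound under the initial tolerances ``init_tol = (diag, offdiag)``, and
    scored by alpha_a; ties break toward higher P_a, then smaller size, then
    lexicographically earlier atom labels.
    """
    classes = activities.classes()
    class_values = set(classes.values())
    if "high" not in class_values or "low" not in class_values:
        raise ValueError("need at least one high- and one low-activity compound")
    if classes.get(reference) != "high":
        raise ValueError(f"reference {reference!r} is not a high-activity compound")

    by_id = {e.compound_id: e for e in ensembles}
    if reference not in by_id:
        raise KeyError(f"no ensemble for reference compound {reference!r}")
    ref_ens = by_id[reference]
    ref_conf = ref_ens.lowest_energy_conformer()
    ref_ecmc = build_ecmc(ref_ens, ref_conf.conformer_id,
                          diag_property=diag_property,
                          bonded_property=bonded_property, mask_ch=mask_ch)

    # Lowest-energy candidate ECMC per compound (stage-1 screening).
    candidates = {}
    for cid in classes:
        ens = by_id.get(cid)
        if ens is None:
            raise KeyError(f"no ensemble for compound {cid!r}")
        candidates[cid] = build_ecmc(ens, ens.lowest_energy_conformer().conformer_id,
                                     diag_property=diag_property,
                                     bonded_property=bonded_property,
                                     mask_ch=mask_ch)

    diag_tol, offdiag_tol = init_tol
    best: Optional[tuple] = None  # (alpha, p_a, -k, labels, subset, stats)

    for subset in _candidate_subsets(ref_ecmc.n, size_range):
        sub = ref_ecmc.submatrix(subset)
        tol = ToleranceMatrix.uniform(len(subset), diag_tol, offdiag_tol)
        presence = {}
        for cid, cand in candidates.items():
            result = match_submatrix(sub.matrix, tol, cand,
                                     reference_elements=sub.elements)
            presence[cid] = int(result.matched)
        stats = quality_stats(presence, classes)
        try:
            alpha = stats.alpha_a
        except DegenerateMarginalError:
            continue
        # '~' sorts after alphanumerics, so unlabeled atoms lose label ties.
        labels = tuple(lbl if lbl is not None else f"~{idx}"
                       for lbl, idx in zip(sub.labels, sub.atom_indices))
        key = (alpha, stats.p_a, -len(subset))
        if best is None or _better(key, labels, best[0], best[3]):
            best = (key, subset, stats, labels)

    if best is None or best[0][0] <= 0:
        raise NoDiscriminatingSubmatrixError(
            "no discriminating submatrix: no candidate achieves alpha_a > 0")

    _, subset, stats, _ = best
    sub = ref_ecmc.submatrix(subset)
    labels = [lbl if lbl is not None else f"atom{idx}"
              for lbl, idx in zip(sub.labels, sub.atom_indices)]
    return ECSA(reference_compound_id=reference,
                reference_conformer_id=ref_conf.conformer_id,
                atom_labels=labels, elements=list(sub.elements),
                reference_positions=list(subset),
                reference_values=sub.matrix,
                tolerances=ToleranceMatrix.uniform(len(subset), diag_tol,
                                                   offdiag_tol),
                diag_property=diag_property, bonded_property=bonded_property,
                mask_ch=mask_ch)


def _better(key_new: tuple, labels_new: tuple, key_old: tuple,
            labels_old: tuple) -> bool:
    """Candidate ranking: higher alpha_a, then higher P_a, then smaller size,
    then lexicographically earlier atom labels."""
    if key_new != key_old:
        return key_new > key_old
    return labels_new < labels_old


def class_tolerances(ecsa: ECSA, ensembles: Sequence[ConformerEnsemble],
                     activities: ActivityTable,
                     match_table: Optional[MatchTable] = None
                     ) -> dict[str, ToleranceMatrix]:
    """Attained-maximum tolerance matrices per activity class and overall.

    Only conformers that actually carry the pharmacophore (delta = 1) enter
    the maxima; classes with no matching conformer are omitted.
    """
    if match_table is None:
        match_table = screen(ecsa, ensembles)
    classes = activities.classes()
    by_id = {e.compound_id: e for e in ensembles}
    groups: dict[str, list[tuple[ConformerEnsemble, str]]] = {
        "high": [], "low": [], "all": []}
    for row in match_table.frame.itertuples():
        if not row.delta:
            continue
        pair = (by_id[row.compound_id], row.conformer_id)
        groups["all"].append(pair)
        groups[classes[row.compound_id]].append(pair)
    return {name: derive_tolerances(ecsa, members)
            for name, members in groups.items() if members}
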