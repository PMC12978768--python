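"""Seeded synthetic data generators and packaged reference fixtures.

The original conformer ensembles and descriptor panels behind the pyrazole
study are unavailable (they live in proprietary Spartan/Schrödinger
archives), so every pipeline input is emulated by a seeded generator:

* :func:`gen_pharmacophore_set` — conformer ensembles with a *planted*
  pharmacophore submatrix: a k-atom reference fragment embedded (within the
  screening tolerances) in every active compound and geometrically violated
  in every inactive, so the discovery search has a known optimum.
* :func:`gen_activity_data` — per-conformer descriptor panels and activities
  forward-simulated from the Boltzmann-weighted shielding model with known
  kappa, for parameter-recovery and descriptor-selection tests.
* :func:`gen_ml_table` — a nonlinear regression table (smooth term,
  interaction, step) with known signal columns for the ML stack.

Every generator is a pure function of its spec: the same spec yields
byte-identical output.  The printed reference tables (activities and
classes; the reference ECSA and its class-wise tolerance matrices; the
selected descriptors with kappa values; the per-descriptor E column) ship
as checksummed CSV fixtures and are loaded through :func:`load_fixture`.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import (ActivityTable, Atom, Bond, Conformer,
                         ConformerEnsemble, DescriptorPanel,
                         DEFAULT_ACTIVITY_THRESHOLD, classify_activity)
from .ecmc_core import DEFAULT_TEMPERATURE, ToleranceMatrix
from .activity_model import predict_one
from .pharmacophore import MatchTable

#: SHA-256 of each packaged fixture; load_fixture refuses drifted files.
FIXTURE_SHA256 = {
    "table1": "6f5bc7437a1dba4a86c10150df819a25bd8b601bb6b21f20cc7b5e3c59094ebb",
    "table2a": "7bada0379f991e7ada7b45c0b77da31a8bf6572604f7967141ad7d3c9c862e72",
    "table2b": "0c9e8b6e66e8c0bc95ba0545eb8f62bb1672be4cec93c0f1f8bc108d01c1ee9b",
    "table2c": "047eeae04e695ed79a85b46b0e7a92a9a9cbe4366919ba2ce96f2175b20ecbfb",
    "table2d": "88d9650e6e1299f1c711f4e1ed29c25b76040b4a4987d71af05e41f7671a6a29",
    "table3": "58217da76c886ceafa0853cfe9bedef5605830bc8706489e362acd3b53ef8273",
    "table4_E": "13c3c87d2f7ebc5b00e75d886b980482fb6e5ef99637b40c5c1f8d9bb2d218d7",
}


@dataclass
class SyntheticSpec:
    """Conditions for the synthetic generators.

    Defaults reflect the study conditions the pipeline is validated under:
    kappa recovery at n = 40 compounds, 4 signal descriptors among 8 and
    activity noise of 0.05 pIC50 units; pharmacophore sets with 5 actives
    and 5 inactives, conformer energies on a 1 kcal/mol scale, and the
    0.25 / 1.30 diagonal / off-diagonal screening tolerances.
    """

    seed: int
    n_active: int = 20
    n_inactive: int = 20
    pharmacophore_size: int = 3
    tolerance_scale: float = 0.3       # active perturbations, fraction of tol
    n_conformers: int = 5
    energy_scale: float = 1.0          # kcal/mol, mean of conformer energies
    kappa_true: Optional[np.ndarray] = None
    noise_sd: float = 0.05             # pIC50 units
    p_descriptors: int = 8
    signal_indices: Optional[tuple[int, ...]] = None   # 1-based
    n_samples: int = 200               # rows of the ML table
    diag_tol: float = 0.25
    offdiag_tol: float = 1.30
    min_atoms: int = 8
    max_atoms: int = 14
    a0: float = 9.0
    temperature: float = DEFAULT_TEMPERATURE
    zero_delta_compounds: int = 0

    def __post_init__(self) -> None:
        if self.n_active < 1 or self.n_inactive < 1 or self.n_conformers < 1:
            raise ValueError("counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.signal_indices is not None:
            bad = [i for i in self.signal_indices
                   if not 1 <= i <= self.p_descriptors]
            if bad:
                raise ValueError(f"signal indices outside 1..p: {bad}")

    def resolved_signal_indices(self) -> tuple[int, ...]:
        if self.signal_indices is not None:
            return tuple(self.signal_indices)
        return tuple(range(1, min(4, self.p_descriptors) + 1))


# ---------------------------------------------------------------------------
# Planted-pharmacophore ensembles
# ---------------------------------------------------------------------------

_PHARMACOPHORE_ELEMENTS = ["C", "N", "O", "S", "P", "F", "Cl", "B"]


def _reference_geometry(k: int, rng: np.random.Generator,
                        max_tries: int = 2000) -> np.ndarray:
    """k points with pairwise distances in [1.8, 6.0] Å."""
    coords = [np.zeros(3)]
    tries = 0
    while len(coords) < k:
        candidate = rng.uniform(-3.0, 3.0, 3)
        d = [np.linalg.norm(candidate - c) for c in coords]
        if all(1.8 <= x <= 6.0 for x in d):
            coords.append(candidate)
        tries += 1
        if tries > max_tries:
            raise RuntimeError("infeasible pharmacophore geometry")
    return np.vstack(coords)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _jitter(coords: np.ndarray, radius: float,
            rng: np.random.Generator) -> np.ndarray:
    """Displace each point by at most ``radius`` (so no pairwise distance
    changes by more than 2*radius)."""
    direction = rng.normal(size=coords.shape)
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    return coords + direction * rng.uniform(0, radius, (coords.shape[0], 1))


def gen_pharmacophore_set(spec: SyntheticSpec
                          ) -> tuple[list[ConformerEnsemble], ActivityTable]:
    """Ensembles with a planted k-atom pharmacophore.

    The pharmacophore atoms carry distinct elements (decoys are hydrogens),
    so the reference fragment admits exactly one element-compatible
    assignment per conformer.  Decoys sit on a *conserved scaffold*: their
    reference geometry is shared by every compound (jittered within the
    tolerances, like the planted atoms), so no decoy-containing submatrix
    can separate the classes.  Actives reproduce the full reference within
    ``tolerance_scale`` of the screening tolerances in every conformer.
    Each inactive displaces one pharmacophore atom (cycling over the k atoms
    across inactives) far enough that *every* distance involving it deviates
    by more than 3x the off-diagonal tolerance — so a candidate submatrix
    discriminates all inactives only if it contains every planted atom, and
    screening with the generating tolerances yields h2 = h3 = 0 by
    construction.
    """
    k = spec.pharmacophore_size
    if not 2 <= k <= len(_PHARMACOPHORE_ELEMENTS):
        raise ValueError(f"pharmacophore size must be 2..8, got {k}")
    rng = np.random.default_rng(spec.seed)
    elements = _PHARMACOPHORE_ELEMENTS[:k]
    labels = [f"{el}1" for el in elements]
    ref_coords = _reference_geometry(k, rng)
    ref_charges = rng.uniform(-0.4, 0.4, k)
    jitter_radius = spec.tolerance_scale * spec.offdiag_tol / 2.0
    charge_halfwidth = spec.tolerance_scale * spec.diag_tol
    # Conserved decoy scaffold shared by every compound.
    max_decoys = max(spec.max_atoms - k, 2)
    decoy_ref = []
    while len(decoy_ref) < max_decoys:
        candidate = rng.uniform(-6.0, 6.0, 3)
        existing = np.vstack([ref_coords] + decoy_ref) if decoy_ref else ref_coords
        if np.min(np.linalg.norm(existing - candidate, axis=1)) >= 0.8:
            decoy_ref.append(candidate)
    decoy_ref = np.vstack(decoy_ref)
    decoy_charges = rng.uniform(-0.2, 0.2, max_decoys)

    ensembles = []
    activity_rows = []
    n_total = spec.n_active + spec.n_inactive
    # One shared size keeps the conserved scaffold identical across the set.
    n_atoms = max(int(rng.integers(spec.min_atoms, spec.max_atoms + 1)), k + 2)
    for c in range(n_total):
        active = c < spec.n_active
        cid = f"act{c + 1:02d}" if active else f"inact{c - spec.n_active + 1:02d}"
        atoms = [Atom(index=i + 1, element=elements[i], skeleton_label=labels[i])
                 for i in range(k)]
        atoms += [Atom(index=i + 1, element="H") for i in range(k, n_atoms)]
        bonds = [Bond(i=i, j=i + 1, order=1.0)
                 for i in range(k + 1, n_atoms)]

        energies = rng.exponential(spec.energy_scale, spec.n_conformers)
        energies -= energies.min()
        conformers = []
        for j in range(spec.n_conformers):
            pharm = _jitter(ref_coords, jitter_radius, rng)
            charges_k = ref_charges + rng.uniform(-charge_halfwidth,
                                                  charge_halfwidth, k)
            if not active:
                # Push one planted atom radially past twice the fragment
                # diameter: every distance involving it then exceeds its
                # reference value by > 3x the off-diagonal tolerance.
                violated = (c - spec.n_active) % k
                others = np.delete(pharm, violated, axis=0)
                centroid = others.mean(axis=0)
                axis = pharm[violated] - centroid
                norm = np.linalg.norm(axis)
                axis = axis / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
                diffs = ref_coords[:, None, :] - ref_coords[None, :, :]
                diameter = float(np.linalg.norm(diffs, axis=-1).max())
                shift = 2.0 * diameter + 3.0 * spec.offdiag_tol + 1.5
                pharm[violated] = centroid + axis * shift
            n_decoys = n_atoms - k
            decoys = _jitter(decoy_ref[:n_decoys], jitter_radius, rng)
            coords = np.vstack([pharm, decoys])
            rot = _random_rotation(rng)
            coords = coords @ rot.T + rng.uniform(-10, 10, 3)
            charges = np.concatenate([
                charges_k,
                decoy_charges[:n_decoys] + rng.uniform(
                    -charge_halfwidth, charge_halfwidth, n_decoys)])
            conformers.append(Conformer(
                conformer_id=f"conf{j + 1}", rel_energy=float(energies[j]),
                has_imaginary_freq=False, coords=coords,
                atomic_charge=charges))
        ens = ConformerEnsemble(compound_id=cid, atoms=atoms, bonds=bonds,
                                conformers=conformers)
        ens.validate()
        ens.rereference_energies()
        ensembles.append(ens)
        pic50 = float(rng.uniform(7.7, 9.3) if active else rng.uniform(5.0, 7.5))
        activity_rows.append((cid, pic50, classify_activity(pic50), "unassigned"))

    frame = pd.DataFrame(activity_rows,
                         columns=["compound_id", "pic50", "activity_class",
                                  "split"])
    return ensembles, ActivityTable(frame=frame)


# ---------------------------------------------------------------------------
# Forward-simulated activity data (shielding model as generator)
# ---------------------------------------------------------------------------

def gen_activity_data(spec: SyntheticSpec
                      ) -> tuple[list[ConformerEnsemble], MatchTable,
                                 DescriptorPanel, ActivityTable, np.ndarray]:
    """Activities forward-simulated from the ensemble shielding model.

    Per-conformer descriptors are standard normal; the true kappa vector is
    zero outside ``signal_indices``; activities are the model predictions
    plus Gaussian noise of sd ``noise_sd``.  Returns the full-length true
    kappa vector for recovery tests.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.p_descriptors
    signal = spec.resolved_signal_indices()
    if spec.kappa_true is not None:
        kappa_full = np.asarray(spec.kappa_true, dtype=float)
        if kappa_full.shape != (p,):
            raise ValueError(f"kappa_true must have length p={p}")
    else:
        kappa_full = np.zeros(p)
        for i in signal:
            kappa_full[i - 1] = rng.uniform(0.2, 0.8) * rng.choice([-1.0, 1.0])

    n = spec.n_active + spec.n_inactive
    ensembles, panel_rows, match_rows, activity_rows = [], [], [], []
    for c in range(n):
        cid = f"c{c + 1:02d}"
        energies = rng.exponential(spec.energy_scale, spec.n_conformers)
        energies -= energies.min()
        delta = np.ones(spec.n_conformers)
        if c < spec.zero_delta_compounds:
            delta[:] = 0.0
        conformers = []
        descriptors = rng.normal(0.0, 1.0, (spec.n_conformers, p))
        for j in range(spec.n_conformers):
            conformers.append(Conformer(
                conformer_id=f"conf{j + 1}", rel_energy=float(energies[j]),
                has_imaginary_freq=False,
                coords=np.zeros((2, 3)), atomic_charge=np.zeros(2)))
            panel_rows.append((cid, f"conf{j + 1}", *descriptors[j]))
            match_rows.append((cid, f"conf{j + 1}", int(delta[j])))
        ens = ConformerEnsemble(
            compound_id=cid,
            atoms=[Atom(index=1, element="C"), Atom(index=2, element="H")],
            bonds=[], conformers=conformers)
        ens.rereference_energies()
        ensembles.append(ens)
        s = descriptors @ kappa_full
        activity = predict_one(delta, energies, s, spec.a0, spec.temperature)
        activity += rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
        activity_rows.append((cid, float(activity),
                              classify_activity(activity,
                                                DEFAULT_ACTIVITY_THRESHOLD),
                              "train"))

    names = [f"d{j + 1}" for j in range(p)]
    panel = DescriptorPanel(frame=pd.DataFrame(
        panel_rows, columns=["compound_id", "conformer_id", *names]
    ).set_index(["compound_id", "conformer_id"]))
    match = MatchTable(frame=pd.DataFrame(
        match_rows, columns=["compound_id", "conformer_id", "delta"]))
    activities = ActivityTable(frame=pd.DataFrame(
        activity_rows, columns=["compound_id", "pic50", "activity_class",
                                "split"]))
    return ensembles, match, panel, activities, kappa_full


# ---------------------------------------------------------------------------
# Nonlinear ML regression table
# ---------------------------------------------------------------------------

def gen_ml_table(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """Feature table X ~ N(0, 1) of shape (n_samples, p) and a nonlinear
    target built from the signal columns: a smooth sine term, a pairwise
    interaction, a step, and a small linear term on every signal column,
    plus Gaussian noise.  ``signal_indices=()`` yields a pure-noise target.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_samples, spec.p_descriptors
    X = rng.normal(0.0, 1.0, (n, p))
    signal = tuple(spec.signal_indices if spec.signal_indices is not None
                   else spec.resolved_signal_indices())
    y = np.zeros(n)
    if signal:
        cols = [i - 1 for i in signal]
        y += 3.0 * np.sin(X[:, cols[0]])
        if len(cols) >= 3:
            y += 0.5 * X[:, cols[1]] * X[:, cols[2]]
        elif len(cols) == 2:
            y += 0.5 * X[:, cols[0]] * X[:, cols[1]]
        y += 1.5 * (X[:, cols[-1]] > 0)
        y += 1.5 * X[:, cols].sum(axis=1)
    y += rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd > 0 else 0.0
    return X, y


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def _fixture_bytes(name: str) -> bytes:
    ref = resources.files("ecga").joinpath(f"fixtures/{name}.csv")
    data = ref.read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != FIXTURE_SHA256[name]:
        raise RuntimeError(
            f"fixture {name!r} drifted from its documented transcription "
            f"(sha256 {digest})")
    return data


def load_fixture(name: str):
    """Load a packaged reference table by name.

    * ``table1`` -> :class:`ActivityTable` (54 compounds, printed classes
      kept verbatim; the predicted column is available via
      :func:`load_fixture_frame`).
    * ``table2a`` -> ``(labels, values)``: the 6x6 reference ECSA submatrix
      over atoms C1, C7, C9, N1, H9, N2.
    * ``table2b`` / ``table2c`` / ``table2d`` -> ``(labels,
      ToleranceMatrix)``: attained tolerances for the high-activity class,
      the low-activity class, and all 1154 conformers.
    * ``table3`` -> DataFrame of the 12 selected descriptors with kappa.
    * ``table4_E`` -> DataFrame of per-descriptor E statistics.
    """
    if name not in FIXTURE_SHA256:
        raise KeyError(f"unknown fixture {name!r}; "
                       f"choose from {sorted(FIXTURE_SHA256)}")
    frame = load_fixture_frame(name)
    if name == "table1":
        frame = frame.copy()
        frame["compound_id"] = frame["compound_id"].astype(str)
        frame["split"] = "unassigned"
        return ActivityTable(
            frame=frame[["compound_id", "pic50", "activity_class", "split"]])
    if name.startswith("table2"):
        labels = list(frame["label"])
        values = frame[labels].to_numpy(dtype=float)
        if not np.allclose(values, values.T):
            raise RuntimeError(f"fixture {name!r} matrix not symmetric")
        if name == "table2a":
            return labels, values
        return labels, ToleranceMatrix(values)
    return frame


def load_fixture_frame(name: str) -> pd.DataFrame:
    """The raw (checksummed) fixture CSV as a DataFrame."""
    import io

    return pd.read_csv(io.BytesIO(_fixture_bytes(name)))
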