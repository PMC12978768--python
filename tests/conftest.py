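"""Shared fixtures: small synthetic datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import ecga
from ecga import (ActivityDataset, ActivityTable, Atom, Bond, Conformer,
                  ConformerEnsemble, SyntheticSpec)


@pytest.fixture(scope="session")
def planted_set():
    """Ten-compound planted-pharmacophore set (k=3) with its activities."""
    spec = SyntheticSpec(seed=1, n_active=5, n_inactive=5,
                         pharmacophore_size=3, max_atoms=10)
    ensembles, activities = ecga.gen_pharmacophore_set(spec)
    return spec, ensembles, activities


@pytest.fixture(scope="session")
def activity_data():
    """Forward-simulated noiseless activity dataset with known kappa."""
    spec = SyntheticSpec(seed=3, n_active=6, n_inactive=6, noise_sd=0.0,
                         p_descriptors=6, n_conformers=4)
    ensembles, match, panel, activities, kappa_true = ecga.gen_activity_data(spec)
    dataset = ActivityDataset.assemble(ensembles, match, panel, activities,
                                       a0=spec.a0)
    return spec, dataset, kappa_true


def make_simple_ensemble(compound_id: str = "cmp", energies=(0.0, 0.5),
                         charges=(-0.1, 0.2, 0.05)) -> ConformerEnsemble:
    """Tiny 3-atom ensemble (C, N, H; one C-H bond) for unit tests."""
    n = len(charges)
    atoms = [Atom(1, "C", "C1"), Atom(2, "N", "N1"), Atom(3, "H", "H1")][:n]
    coords = np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [0.0, 1.1, 0.0]])[:n]
    conformers = [
        Conformer(conformer_id=f"conf{i + 1}", rel_energy=float(e),
                  has_imaginary_freq=False, coords=coords.copy(),
                  atomic_charge=np.array(charges, dtype=float))
        for i, e in enumerate(energies)]
    ens = ConformerEnsemble(compound_id=compound_id, atoms=atoms,
                            bonds=[Bond(1, 3, order=1.0)] if n == 3 else [],
                            conformers=conformers)
    ens.validate()
    ens.rereference_energies()
    return ens


def table2_scenario(seed: int = 0, n_active: int = 6, n_inactive: int = 6):
    """Synthetic compound set embedding the packaged 6-atom reference ECSA.

    Every pair of the six skeleton atoms (C1, C7, C9, N1, H9, N2) is bonded,
    with the bond descriptor set to the fixture's off-diagonal value and the
    charge to its diagonal, so the reference compound's ECMC reproduces the
    fixture exactly.  Actives perturb each element within the high-activity
    tolerance matrix; each inactive shifts one of three disjoint atom pairs
    by a large offset, so only the full six-atom submatrix separates the
    classes.  Two conserved hydrogen decoys are appended.
    """
    rng = np.random.default_rng(seed)
    labels, ref_values = ecga.load_fixture("table2a")
    _, tol_high = ecga.load_fixture("table2b")
    elements = [lbl[0] for lbl in labels]  # C,C,C,N,H,N
    k = len(labels)
    base_coords = np.array([
        [0.0, 0.0, 0.0], [2.0, 0.0, 0.0], [4.0, 0.5, 0.0],
        [1.0, 2.0, 0.5], [3.0, 2.5, 0.5], [5.0, 2.0, 1.0],
        [0.5, 4.5, 2.0], [4.5, 4.5, 2.0]])
    violated_pairs = [(0, 1), (2, 3), (4, 5)]  # disjoint, none C-H masked

    ensembles, rows = [], []
    for c in range(n_active + n_inactive):
        active = c < n_active
        cid = f"act{c + 1:02d}" if active else f"inact{c - n_active + 1:02d}"
        values = ref_values.copy()
        if c > 0:  # every non-reference compound sits within the tolerances
            jitter = rng.uniform(-1.0, 1.0, (k, k)) * tol_high.values
            jitter = (jitter + jitter.T) / 2.0
            values = values + jitter
        if not active:
            a, b = violated_pairs[(c - n_active) % len(violated_pairs)]
            values[a, b] = values[b, a] = values[a, b] + 5.0
        atoms = [Atom(i + 1, elements[i], labels[i]) for i in range(k)]
        atoms += [Atom(k + 1, "H"), Atom(k + 2, "H")]
        bonds = [Bond(i + 1, j + 1, order=float(values[i, j]))
                 for i in range(k) for j in range(i + 1, k)]
        conf = Conformer(conformer_id="conf1", rel_energy=0.0,
                         has_imaginary_freq=False, coords=base_coords.copy(),
                         atomic_charge=np.concatenate(
                             [np.diag(values), [0.0, 0.0]]))
        ens = ConformerEnsemble(compound_id=cid, atoms=atoms, bonds=bonds,
                                conformers=[conf])
        ens.validate()
        ensembles.append(ens)
        pic50 = float(rng.uniform(8.0, 9.3) if active else rng.uniform(5.0, 7.0))
        rows.append((cid, pic50, "high" if active else "low", "unassigned"))

    activities = ActivityTable(frame=pd.DataFrame(
        rows, columns=["compound_id", "pic50", "activity_class", "split"]))
    return ensembles, activities, labels
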