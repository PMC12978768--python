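"""Boltzmann-weighted conformer-ensemble activity model.

The predicted activity of compound n with retained conformers i = 1..m_n is

    A_n = A0 * [ sum_i delta_ni * exp(-S_ni) * exp(-E_ni/RT) ]
               / [ sum_i exp(-E_ni/RT) ]

where delta_ni flags whether conformer i carries the pharmacophore, E_ni is
its relative energy (kcal/mol), R the gas constant and T the temperature.
A0 is pinned to the experimental pIC50 of the reference (most active)
compound, so a compound whose every conformer carries the pharmacophore with
zero shielding is predicted at exactly A0.  The shielding term

    S_ni = sum_j kappa_j * a_ni^(j)

aggregates the influence of descriptors outside the pharmacophore
(auxiliary groups and anti-pharmacophore shielding); the kappa_j are fitted
by nonlinear least squares on the training compounds.

Descriptor indices are 1-based throughout, matching the descriptor panel's
column-order convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .io_formats import ActivityTable, ConformerEnsemble, DescriptorPanel
from .ecmc_core import DEFAULT_TEMPERATURE, R_KCAL, boltzmann_weights
from .pharmacophore import MatchTable


# ---------------------------------------------------------------------------
# Data assembly
# ---------------------------------------------------------------------------

@dataclass
class CompoundData:
    """Everything the activity formula needs for one compound."""

    compound_id: str
    a_exp: float
    rel_energies: np.ndarray   # (m,) kcal/mol
    delta: np.ndarray          # (m,) pharmacophore flags in {0, 1}
    descriptors: np.ndarray    # (m, p) per-conformer descriptor vectors
    split: str = "train"

    def __post_init__(self) -> None:
        self.rel_energies = np.asarray(self.rel_energies, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        self.descriptors = np.atleast_2d(np.asarray(self.descriptors, dtype=float))
        m = self.rel_energies.size
        if m == 0:
            raise ValueError(f"compound {self.compound_id!r}: no conformers")
        if self.delta.shape != (m,) or self.descriptors.shape[0] != m:
            raise ValueError(
                f"compound {self.compound_id!r}: delta/descriptors misaligned "
                f"with {m} conformers")


@dataclass
class ActivityDataset:
    """Aligned per-compound records plus the model constants A0 and T."""

    compounds: list[CompoundData]
    descriptor_names: list[str]
    a0: float
    temperature: float = DEFAULT_TEMPERATURE

    @property
    def p(self) -> int:
        return len(self.descriptor_names)

    @property
    def n(self) -> int:
        return len(self.compounds)

    def training(self) -> list[CompoundData]:
        train = [c for c in self.compounds if c.split != "test"]
        return train if train else list(self.compounds)

    def subset(self, compounds: Sequence[CompoundData]) -> "ActivityDataset":
        return ActivityDataset(compounds=list(compounds),
                               descriptor_names=self.descriptor_names,
                               a0=self.a0, temperature=self.temperature)

    @classmethod
    def assemble(cls, ensembles: Sequence[ConformerEnsemble],
                 match_table: MatchTable, panel: DescriptorPanel,
                 activities: ActivityTable,
                 a0: Optional[float] = None,
                 temperature: float = DEFAULT_TEMPERATURE) -> "ActivityDataset":
        """Join ensembles, match flags, descriptors and activities by id.

        ``a0`` defaults to the maximum experimental pIC50 (the reference
        compound's activity).
        """
        frame = activities.frame
        compounds = []
        by_id = {e.compound_id: e for e in ensembles}
        for row in frame.itertuples():
            ens = by_id.get(row.compound_id)
            if ens is None:
                raise KeyError(f"no ensemble for compound {row.compound_id!r}")
            conformer_ids = [c.conformer_id for c in ens.conformers]
            compounds.append(CompoundData(
                compound_id=row.compound_id, a_exp=float(row.pic50),
                rel_energies=ens.rel_energies(),
                delta=match_table.delta_vector(ens),
                descriptors=panel.matrix(row.compound_id, conformer_ids),
                split=row.split))
        if a0 is None:
            a0 = float(frame["pic50"].max())
        return cls(compounds=compounds, descriptor_names=panel.descriptor_names,
                   a0=a0, temperature=temperature)


# ---------------------------------------------------------------------------
# Model evaluation
# ---------------------------------------------------------------------------

def _column_indices(descriptor_indices: Sequence[int], p: int) -> np.ndarray:
    idx = np.asarray(descriptor_indices, dtype=int)
    if idx.size == 0:
        raise ValueError("descriptor index list is empty")
    if len(set(idx.tolist())) != idx.size:
        raise ValueError(f"duplicate descriptor indices in {list(idx)}")
    if (idx < 1).any() or (idx > p).any():
        raise ValueError(f"descriptor indices must lie in 1..{p}, got {list(idx)}")
    return idx - 1


def shielding(descriptor_vector: np.ndarray, kappa: np.ndarray,
              descriptor_indices: Sequence[int]) -> np.ndarray:
    """S = sum_j kappa_j * a^(j) over the selected (1-based) descriptors.

    Accepts a single vector (p,) or a per-conformer matrix (m, p); returns a
    scalar or an (m,) vector accordingly.
    """
    a = np.asarray(descriptor_vector, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    cols = _column_indices(descriptor_indices, a.shape[-1])
    if kappa.shape != (cols.size,):
        raise ValueError("kappa length must equal the number of selected indices")
    return a[..., cols] @ kappa


def predict_one(delta: np.ndarray, rel_energies: np.ndarray,
                s_values: np.ndarray, a0: float,
                temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Evaluate the ensemble activity formula for one compound."""
    delta = np.asarray(delta, dtype=float)
    e = np.asarray(rel_energies, dtype=float)
    s = np.asarray(s_values, dtype=float)
    if not (delta.shape == e.shape == s.shape) or e.size == 0:
        raise ValueError("delta, energies and S must be equal-length and non-empty")
    w = boltzmann_weights(e, T=temperature)
    return float(a0 * np.sum(delta * np.exp(-s) * w))


@dataclass
class KappaModel:
    """Fitted shielding coefficients for a selected descriptor subset."""

    a0: float
    temperature: float
    descriptor_indices: list[int]    # 1-based
    kappa: np.ndarray
    fit_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.kappa = np.asarray(self.kappa, dtype=float)
        if self.kappa.shape != (len(self.descriptor_indices),):
            raise ValueError("kappa length must match descriptor_indices")

    def predict(self, compound: CompoundData) -> float:
        s = shielding(compound.descriptors, self.kappa, self.descriptor_indices)
        return predict_one(compound.delta, compound.rel_energies, s,
                           self.a0, self.temperature)


def _predictions(compounds: Sequence[CompoundData], kappa: np.ndarray,
                 cols: np.ndarray, a0: float, temperature: float) -> np.ndarray:
    out = np.empty(len(compounds))
    for n, c in enumerate(compounds):
        w = boltzmann_weights(c.rel_energies, T=temperature)
        s = c.descriptors[:, cols] @ kappa
        out[n] = a0 * np.sum(c.delta * np.exp(-s) * w)
    return out


def fit_kappa(dataset: ActivityDataset, descriptor_indices: Sequence[int],
              a0: Optional[float] = None, temperature: Optional[float] = None,
              seed: int = 0, n_starts: int = 1,
              exclude_unmatched: bool = False,
              ftol: float = 1e-10) -> KappaModel:
    """Fit kappa by trust-region nonlinear least squares.

    Minimizes sum_n (A_n^exp - A_n^calc(kappa))^2 over the training
    compounds, initialized at kappa = 0 (optional seeded multistart adds
    Gaussian starting points).  Compounds with no matching conformer predict
    0 regardless of kappa; they contribute (A_exp - 0)^2 by default (the
    pharmacophore is claimed necessary) or are dropped with
    ``exclude_unmatched=True`` — a warning is emitted either way.
    """
    a0 = dataset.a0 if a0 is None else float(a0)
    temperature = dataset.temperature if temperature is None else float(temperature)
    train = dataset.training()
    cols = _column_indices(descriptor_indices, dataset.p)
    N = cols.size

    unmatched = [c.compound_id for c in train if not c.delta.any()]
    if len(unmatched) == len(train):
        raise ValueError("every training compound lacks a matching conformer")
    if unmatched:
        action = "excluded from" if exclude_unmatched else "kept in"
        warnings.warn(
            f"compounds without a matching conformer {action} the fit: "
            f"{unmatched}", stacklevel=2)
        if exclude_unmatched:
            train = [c for c in train if c.delta.any()]
    if len(train) < N + 1:
        warnings.warn(
            f"only {len(train)} training compounds for {N} parameters",
            stacklevel=2)

    y = np.array([c.a_exp for c in train])
    # Precompute Boltzmann weights and descriptor blocks once per compound.
    weights = [boltzmann_weights(c.rel_energies, T=temperature) for c in train]
    blocks = [c.descriptors[:, cols] for c in train]
    deltas = [c.delta for c in train]

    def residuals(kappa: np.ndarray) -> np.ndarray:
        res = np.empty(len(train))
        for n in range(len(train)):
            s = blocks[n] @ kappa
            res[n] = y[n] - a0 * np.sum(deltas[n] * np.exp(-s) * weights[n])
        return res

    def jacobian(kappa: np.ndarray) -> np.ndarray:
        jac = np.empty((len(train), N))
        for n in range(len(train)):
            s = blocks[n] @ kappa
            g = deltas[n] * np.exp(-s) * weights[n]          # (m,)
            jac[n] = a0 * (g @ blocks[n])                    # d(-A)/dk = +a0*g.a
        return jac

    rng = np.random.default_rng(seed)
    starts = [np.zeros(N)]
    starts += [rng.normal(0.0, 1.0, N) for _ in range(max(0, n_starts - 1))]

    best = None
    for x0 in starts:
        sol = least_squares(residuals, x0, jac=jacobian, method="trf",
                            ftol=ftol, xtol=1e-12, gtol=1e-12)
        if best is None or sol.cost < best.cost:
            best = sol

    kappa0_cost = 0.5 * float(np.sum(residuals(np.zeros(N)) ** 2))
    if best.cost > kappa0_cost + 1e-12:  # descent safeguard; keep init if worse
        best_x, best_cost, converged, nfev = (np.zeros(N), kappa0_cost, False,
                                              best.nfev)
    else:
        best_x, best_cost, converged, nfev = (best.x, float(best.cost),
                                              best.status > 0, best.nfev)

    return KappaModel(
        a0=a0, temperature=temperature,
        descriptor_indices=[int(i) for i in descriptor_indices],
        kappa=best_x,
        fit_report={"objective": 2.0 * best_cost, "n_evaluations": int(nfev),
                    "converged": bool(converged), "seed": int(seed),
                    "n_starts": int(n_starts)})


def loo_predictions(dataset: ActivityDataset,
                    descriptor_indices: Sequence[int],
                    a0: Optional[float] = None,
                    temperature: Optional[float] = None,
                    seed: int = 0, n_starts: int = 1,
                    exclude_unmatched: bool = False) -> pd.DataFrame:
    """Leave-one-out predictions: refit kappa on n-1 compounds, predict the
    held-out one.  Returns a table (compound_id, a_exp, a_calc, split)."""
    train = dataset.training()
    if len(train) < 3:
        raise ValueError(f"LOO needs at least 3 training compounds, got {len(train)}")
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for held in range(len(train)):
            rest = [c for i, c in enumerate(train) if i != held]
            model = fit_kappa(dataset.subset(rest), descriptor_indices, a0=a0,
                              temperature=temperature, seed=seed,
                              n_starts=n_starts,
                              exclude_unmatched=exclude_unmatched)
            c = train[held]
            rows.append((c.compound_id, c.a_exp, model.predict(c), c.split))
    return pd.DataFrame(rows, columns=["compound_id", "a_exp", "a_calc", "split"])


def prediction_table(dataset: ActivityDataset, model: KappaModel) -> pd.DataFrame:
    """Fitted-model predictions for every compound (training and test)."""
    rows = [(c.compound_id, c.a_exp, model.predict(c), c.split)
            for c in dataset.compounds]
    return pd.DataFrame(rows, columns=["compound_id", "a_exp", "a_calc", "split"])


def e_statistics(dataset: ActivityDataset, full_model: KappaModel,
                 seed: int = 0) -> pd.DataFrame:
    """Per-descriptor influence: E_j = PRESS_N(full) / PRESS_{N-1}(drop j).

    Lower E marks a more influential descriptor (dropping it inflates the
    reduced model's PRESS).  E is undefined (NaN) when the reduced model's
    PRESS is 0.
    """
    indices = full_model.descriptor_indices
    if len(indices) < 2:
        raise ValueError("E statistics need a model with at least 2 descriptors")

    def press_of(idx: Sequence[int]) -> float:
        table = loo_predictions(dataset, idx, a0=full_model.a0,
                                temperature=full_model.temperature, seed=seed)
        return float(np.sum((table["a_exp"] - table["a_calc"]) ** 2))

    press_full = press_of(indices)
    rows = []
    for j in indices:
        reduced = [i for i in indices if i != j]
        press_reduced = press_of(reduced)
        e = press_full / press_reduced if press_reduced > 0 else math.nan
        rows.append((j, e, press_reduced))
    return pd.DataFrame(rows, columns=["descriptor_index", "E", "press_reduced"])
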