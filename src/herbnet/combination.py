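"""Dose-matrix combination scoring against highest-single-agent additivity.

Two compounds are tested alone and in all dose combinations on a factorial
grid.  The highest-single-agent (HSA, also "highest single compound")
reference predicts the combination effect at doses (i, j) to be the larger
of the two single-agent effects at the matched doses:

    reference(i, j) = max(effect_a[i], effect_b[j])
    excess(i, j)    = effect_ab[i, j] - reference(i, j)

Positive excess beyond a dead-band tolerance is called synergy, negative
excess antagonism, anything within the band additive.  Responses may be
percent growth or percent inhibition; the arithmetic is identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MODES = ("growth", "inhibition")
CALLS = ("synergy", "additive", "antagonism")


@dataclass
class DoseMatrix:
    """Single-agent and combination responses on a factorial dose grid.

    ``effect_ab[i, j]`` is the response at ``doses_a[i]`` x ``doses_b[j]``.
    """

    doses_a: np.ndarray
    doses_b: np.ndarray
    effect_a: np.ndarray
    effect_b: np.ndarray
    effect_ab: np.ndarray
    mode: str = "inhibition"

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        self.effect_a = np.asarray(self.effect_a, dtype=float)
        self.effect_b = np.asarray(self.effect_b, dtype=float)
        self.effect_ab = np.asarray(self.effect_ab, dtype=float)
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.doses_a.shape != self.effect_a.shape or self.doses_b.shape != self.effect_b.shape:
            raise ValueError("dose vectors and single-agent effects must align")
        if self.effect_ab.shape != (self.doses_a.size, self.doses_b.size):
            raise ValueError(
                f"combination matrix shape {self.effect_ab.shape} does not match "
                f"the {self.doses_a.size}x{self.doses_b.size} dose grid"
            )
        for name, v in (("doses_a", self.doses_a), ("doses_b", self.doses_b)):
            if np.any(np.diff(v) <= 0):
                raise ValueError(f"{name} must be strictly ascending")
        for name, v in (
            ("effect_a", self.effect_a),
            ("effect_b", self.effect_b),
            ("effect_ab", self.effect_ab),
        ):
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} contains non-finite responses")

    def transpose(self) -> "DoseMatrix":
        """Swap the two agents (rows <-> columns)."""
        return DoseMatrix(
            self.doses_b, self.doses_a, self.effect_b, self.effect_a,
            self.effect_ab.T, self.mode,
        )


@dataclass
class ExcessMatrix:
    """Deviation from HSA additivity with per-cell synergy calls."""

    excess: np.ndarray
    calls: np.ndarray
    tol: float

    def n_synergy(self) -> int:
        return int((self.calls == "synergy").sum())

    def n_antagonism(self) -> int:
        return int((self.calls == "antagonism").sum())


def hsa_excess(dm: DoseMatrix, tol: float = 5.0) -> ExcessMatrix:
    """Excess over the highest-single-agent reference, with calls.

    ``tol`` (percentage points) is the dead-band half-width: cells within
    +/- tol of the reference are called additive.
    """
    if tol < 0:
        raise ValueError("tol must be non-negative")
    reference = np.maximum(dm.effect_a[:, None], dm.effect_b[None, :])
    excess = dm.effect_ab - reference
    calls = np.where(
        excess > tol, "synergy", np.where(excess < -tol, "antagonism", "additive")
    )
    return ExcessMatrix(excess=excess, calls=calls, tol=float(tol))


def read_dose_matrix(path: str | Path, mode: str = "inhibition") -> DoseMatrix:
    """Long-format TSV with columns dose_a, dose_b, response.

    Rows with one dose equal to 0 carry the other agent's single-dose
    response; rows with both doses positive fill the combination grid,
    which must be complete.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"dose_a", "dose_b", "response"}
    if not required <= set(df.columns):
        raise ValueError(f"dose matrix TSV needs columns {sorted(required)}")
    singles_a = df[(df.dose_a > 0) & (df.dose_b == 0)].set_index("dose_a")["response"]
    singles_b = df[(df.dose_b > 0) & (df.dose_a == 0)].set_index("dose_b")["response"]
    combos = df[(df.dose_a > 0) & (df.dose_b > 0)]
    doses_a = np.sort(combos["dose_a"].unique())
    doses_b = np.sort(combos["dose_b"].unique())
    if doses_a.size == 0 or doses_b.size == 0:
        raise ValueError("no combination rows (both doses positive) found")
    grid = combos.pivot_table(index="dose_a", columns="dose_b", values="response")
    grid = grid.reindex(index=doses_a, columns=doses_b)
    if grid.isna().any().any():
        raise ValueError("combination dose grid is incomplete")
    try:
        eff_a = singles_a.loc[doses_a].to_numpy()
        eff_b = singles_b.loc[doses_b].to_numpy()
    except KeyError as exc:
        raise ValueError(f"missing single-agent response for dose {exc}") from None
    return DoseMatrix(doses_a, doses_b, eff_a, eff_b, grid.to_numpy(), mode)


def write_excess(
    dm: DoseMatrix, em: ExcessMatrix, path: str | Path
) -> None:
    """Long-format TSV of per-cell excess and calls."""
    rows = []
    for i, da in enumerate(dm.doses_a):
        for j, db in enumerate(dm.doses_b):
            rows.append({
                "dose_a": da, "dose_b": db,
                "response": dm.effect_ab[i, j],
                "excess": em.excess[i, j],
                "call": em.calls[i, j],
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
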