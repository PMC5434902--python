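"""Data container for the two-stage linear model.

The model has a second stage y = X1 b1 + X2 b2 + e with k1 endogenous
regressors X1 and k2 exogenous regressors X2, and a first stage in which
X is regressed on the combined instrument matrix Z = [Z1 X2] (the l1
excluded instruments plus the exogenous regressors, which instrument
themselves).  ``RegressionData`` holds the four blocks with column names
and enforces the identification contracts shared by every estimator.

No intercept is added implicitly anywhere: callers who want one include a
constant column in X2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ContractError,
    IdentificationError,
    InsufficientDataError,
    RoleError,
    UnderIdentifiedError,
)

__all__ = ["RegressionData", "RANK_RTOL"]

#: relative singular-value cutoff for rank decisions
RANK_RTOL = 1e-10


def _as_matrix(a, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if arr.ndim != 2:
        raise ContractError(f"{name} must be 1- or 2-dimensional, got ndim={arr.ndim}")
    return arr


def _numerical_rank(M: np.ndarray) -> tuple[int, np.ndarray]:
    if M.size == 0:
        return 0, np.empty(0)
    s = np.linalg.svd(M, compute_uv=False)
    tol = RANK_RTOL * s[0] if s.size and s[0] > 0 else 0.0
    return int(np.sum(s > tol)), s


def _deficient_columns(M: np.ndarray, names: Sequence[str]) -> list[str]:
    """Heuristically name columns implicated in a rank deficiency.

    Uses column-pivoted QR: the pivots beyond the numerical rank are the
    columns that add (numerically) nothing to the span of the others.
    """
    from scipy.linalg import qr

    rank, _ = _numerical_rank(M)
    if rank >= M.shape[1]:
        return []
    _, _, piv = qr(M, mode="economic", pivoting=True)
    return [names[j] for j in sorted(piv[rank:])]


@dataclass
class RegressionData:
    """The (y, X1, X2, Z1) blocks of a two-stage linear model.

    Parameters
    ----------
    y : array-like, shape (n,)
        Continuous outcome (e.g. a symptom score).
    X1 : array-like, shape (n, k1)
        Endogenous regressors (e.g. number of therapy sessions).
    X2 : array-like, shape (n, k2)
        Exogenous regressors; include a constant column here to fit an
        intercept.  May be empty.
    Z1 : array-like, shape (n, l1)
        Excluded instruments (e.g. randomization and its interactions with
        baseline covariates).  May be empty for pure-OLS use.
    names_X1, names_X2, names_Z1 : sequence of str, optional
        Column names; defaults are generated.  Names must be unique across
        all blocks.
    validate : bool
        If True (default) check all invariants at construction.
    """

    y: np.ndarray
    X1: np.ndarray
    X2: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    Z1: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    names_X1: tuple[str, ...] = ()
    names_X2: tuple[str, ...] = ()
    names_Z1: tuple[str, ...] = ()
    validate: bool = True

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        n = self.y.shape[0]
        self.X1 = _as_matrix(self.X1, "X1")
        self.X2 = (
            _as_matrix(self.X2, "X2") if np.size(self.X2) else np.empty((n, 0))
        )
        self.Z1 = (
            _as_matrix(self.Z1, "Z1") if np.size(self.Z1) else np.empty((n, 0))
        )
        if not self.names_X1:
            self.names_X1 = tuple(f"x1_{j}" for j in range(self.k1))
        if not self.names_X2:
            self.names_X2 = tuple(f"x2_{j}" for j in range(self.k2))
        if not self.names_Z1:
            self.names_Z1 = tuple(f"z1_{j}" for j in range(self.l1))
        self.names_X1 = tuple(self.names_X1)
        self.names_X2 = tuple(self.names_X2)
        self.names_Z1 = tuple(self.names_Z1)
        if self.validate:
            self._check()

    # ---- derived blocks and dimensions -------------------------------

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def k1(self) -> int:
        return self.X1.shape[1]

    @property
    def k2(self) -> int:
        return self.X2.shape[1]

    @property
    def k(self) -> int:
        return self.k1 + self.k2

    @property
    def l1(self) -> int:
        return self.Z1.shape[1]

    @property
    def l(self) -> int:
        return self.l1 + self.k2

    @property
    def X(self) -> np.ndarray:
        """Full design [X1 X2]; coefficient order is endogenous block first."""
        return np.hstack([self.X1, self.X2])

    @property
    def Z(self) -> np.ndarray:
        """Full instrument matrix [Z1 X2]."""
        return np.hstack([self.Z1, self.X2])

    @property
    def names(self) -> tuple[str, ...]:
        return self.names_X1 + self.names_X2

    @property
    def names_Z(self) -> tuple[str, ...]:
        return self.names_Z1 + self.names_X2

    # ---- validation --------------------------------------------------

    def _check(self) -> None:
        n = self.n
        for block, label in ((self.X1, "X1"), (self.X2, "X2"), (self.Z1, "Z1")):
            if block.shape[0] != n:
                raise ContractError(
                    f"{label} has {block.shape[0]} rows but y has {n}"
                )
        if len(self.names_X1) != self.k1 or len(self.names_X2) != self.k2 or len(
            self.names_Z1
        ) != self.l1:
            raise ContractError("column-name lengths do not match block widths")
        all_names = self.names + self.names_Z1
        if len(set(all_names)) != len(all_names):
            dupes = sorted({nm for nm in all_names if all_names.count(nm) > 1})
            raise ContractError(f"duplicate column names across blocks: {dupes}")
        stacked = np.column_stack([self.y[:, None], self.X, self.Z1])
        if not np.all(np.isfinite(stacked)):
            raise ContractError("missing or non-finite entries in y/X1/X2/Z1")
        if self.k1 < 1:
            raise ContractError("X1 must contain at least one endogenous column")
        if n <= self.l:
            raise InsufficientDataError(
                f"need n > l: n={n}, l=l1+k2={self.l}"
            )
        if n <= self.k:
            raise InsufficientDataError(f"need n > k: n={n}, k={self.k}")
        rank_x, _ = _numerical_rank(self.X)
        if rank_x < self.k:
            bad = _deficient_columns(self.X, list(self.names))
            raise IdentificationError(
                f"X = [X1 X2] is rank deficient (rank {rank_x} < k={self.k}); "
                f"offending columns: {bad}"
            )
        if self.l1 > 0:
            if self.l1 < self.k1:
                raise UnderIdentifiedError(
                    f"order condition fails: l1={self.l1} < k1={self.k1}"
                )
            rank_z, _ = _numerical_rank(self.Z)
            if rank_z < self.l:
                bad = _deficient_columns(self.Z, list(self.names_Z))
                raise IdentificationError(
                    f"Z = [Z1 X2] is rank deficient (rank {rank_z} < l={self.l}); "
                    f"offending columns: {bad}"
                )

    # ---- construction from tabular data ------------------------------

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        roles: Mapping[str, Sequence[str] | str],
        validate: bool = True,
    ) -> "RegressionData":
        """Build from a DataFrame and a role map.

        ``roles`` has keys ``outcome`` (one column), ``endogenous``,
        ``exogenous`` and ``instruments`` (lists of columns).  Role lists
        must be disjoint and all columns must exist in the frame.
        """
        roles = dict(roles)
        outcome = roles.get("outcome")
        if isinstance(outcome, (list, tuple)):
            if len(outcome) != 1:
                raise RoleError("exactly one outcome column is required")
            outcome = outcome[0]
        if not outcome:
            raise RoleError("role map must name an outcome column")

        def _lst(key):
            v = roles.get(key, [])
            if isinstance(v, str):
                v = [v]
            return list(v)

        endog, exog, instr = _lst("endogenous"), _lst("exogenous"), _lst("instruments")
        if not endog:
            raise RoleError("role map must name at least one endogenous column")
        groups = [[outcome], endog, exog, instr]
        flat = [c for g in groups for c in g]
        if len(set(flat)) != len(flat):
            dupes = sorted({c for c in flat if flat.count(c) > 1})
            raise RoleError(f"role lists are not disjoint: {dupes}")
        missing = [c for c in flat if c not in frame.columns]
        if missing:
            raise RoleError(f"columns not present in data: {missing}")
        return cls(
            y=frame[outcome].to_numpy(float),
            X1=frame[endog].to_numpy(float),
            X2=frame[exog].to_numpy(float) if exog else np.empty((len(frame), 0)),
            Z1=frame[instr].to_numpy(float) if instr else np.empty((len(frame), 0)),
            names_X1=tuple(endog),
            names_X2=tuple(exog),
            names_Z1=tuple(instr),
            validate=validate,
        )

    def to_frame(self, outcome_name: str = "y") -> pd.DataFrame:
        cols = {outcome_name: self.y}
        for j, nm in enumerate(self.names_X1):
            cols[nm] = self.X1[:, j]
        for j, nm in enumerate(self.names_X2):
            cols[nm] = self.X2[:, j]
        for j, nm in enumerate(self.names_Z1):
            cols[nm] = self.Z1[:, j]
        return pd.DataFrame(cols)

    def resample(self, idx: np.ndarray, validate: bool = False) -> "RegressionData":
        """Row-resampled copy (used by the pairs bootstrap)."""
        return RegressionData(
            y=self.y[idx],
            X1=self.X1[idx],
            X2=self.X2[idx] if self.k2 else np.empty((len(idx), 0)),
            Z1=self.Z1[idx] if self.l1 else np.empty((len(idx), 0)),
            names_X1=self.names_X1,
            names_X2=self.names_X2,
            names_Z1=self.names_Z1,
            validate=validate,
        )
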