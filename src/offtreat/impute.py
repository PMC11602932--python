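"""Sequential monotone multiple imputation with on/off-treatment structure.

Missing outcomes are imputed one timepoint at a time (j = 1..J) and
separately per randomised arm.  At each step an ordinary regression of
the outcome on earlier outcomes (or earlier residuals) plus optional
treatment-status terms is fitted to the patients whose outcome at j is
observed — under monotone missingness their full history is observed —
and parameters are drawn from the standard noninformative
normal-inverse-gamma posterior (proper imputation).  Missing outcomes
are then drawn from the predictive distribution using observed or
previously imputed covariate values.

Eight model structures are supported, differing in which status terms
enter the intercept, whether slopes interact with status, and whether
conditioning uses raw values or residuals about fitted cell means:

========  ==================  ===============  ============
name      intercept basis     slope basis      conditioning
========  ==================  ===============  ============
CICS      common              common           values
OICS      on/off at j         common           values
PICS      pattern up to j     common           values
OIOS      on/off at j         on/off at j      values
PIOS      pattern up to j     on/off history   values
PIPS      final pattern       final pattern    values
OICS_R    on/off at j         common           residuals
PICS_R    pattern up to j     common           residuals
========  ==================  ===============  ============

The pattern-based residual model (PICS_R) spans the same column space as
PICS at every step, so the two are reparameterisations of one another;
the on/off residual model (OICS_R) is genuinely different from OICS
because the residual centring uses the historical status at each earlier
timepoint, which the raw-value model cannot see.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import ARMS, TrialData

__all__ = [
    "MODEL_NAMES",
    "InestimableModelError",
    "ImputationModelSpec",
    "DesignInfo",
    "PosteriorDraw",
    "ResidualBasis",
    "ImputedDataset",
    "build_design",
    "fit_and_draw",
    "compute_residual_basis",
    "sequential_impute",
]

# residual variance floor (mL^2) guarding exact-fit degeneracies
MIN_SIGMA2 = 1e-8

_MODEL_TABLE = {
    "CICS": ("common", "common", "values"),
    "OICS": ("onoff_current", "common", "values"),
    "PICS": ("pattern_current", "common", "values"),
    "OIOS": ("onoff_current", "onoff_current", "values"),
    "PIOS": ("pattern_current", "onoff_history", "values"),
    "PIPS": ("pattern_final", "pattern_final", "values"),
    "OICS_R": ("onoff_current", "common", "residuals"),
    "PICS_R": ("pattern_current", "common", "residuals"),
}

MODEL_NAMES = tuple(_MODEL_TABLE)


class InestimableModelError(RuntimeError):
    """An imputation regression cannot be estimated (or cannot serve the
    patients needing imputation) — e.g. a discontinuation-pattern cell
    with no observed outcomes, or more parameters than observed rows."""

    def __init__(self, message: str, arm: str | None = None,
                 timepoint: int | None = None, model: str | None = None):
        super().__init__(message)
        self.arm = arm
        self.timepoint = timepoint
        self.model = model

    def tagged(self, arm: str, timepoint: int, model: str) -> "InestimableModelError":
        err = InestimableModelError(
            f"{self.args[0]} [model={model}, arm={arm}, timepoint={timepoint}]",
            arm=arm, timepoint=timepoint, model=model,
        )
        return err


@dataclass(frozen=True)
class ImputationModelSpec:
    """Declarative description of one sequential imputation structure."""

    name: str
    intercept_basis: str
    slope_basis: str
    conditioning: str

    def __post_init__(self) -> None:
        if self.name not in _MODEL_TABLE:
            raise ValueError(f"unknown model name {self.name!r}; choose from {MODEL_NAMES}")
        if (self.intercept_basis, self.slope_basis, self.conditioning) != _MODEL_TABLE[self.name]:
            raise ValueError(
                f"model {self.name} implies bases {_MODEL_TABLE[self.name]}, "
                f"got ({self.intercept_basis}, {self.slope_basis}, {self.conditioning})"
            )

    @classmethod
    def from_name(cls, name: str) -> "ImputationModelSpec":
        key = name.strip().upper().replace("-", "_")
        if key not in _MODEL_TABLE:
            raise ValueError(f"unknown model name {name!r}; choose from {MODEL_NAMES}")
        ib, sb, cond = _MODEL_TABLE[key]
        return cls(name=key, intercept_basis=ib, slope_basis=sb, conditioning=cond)


@dataclass(frozen=True)
class PosteriorDraw:
    """One proper-imputation parameter draw."""

    beta: np.ndarray
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")


class DesignInfo:
    """A design matrix built on the fitting (donor) rows, remembering which
    columns were dropped so recipient rows can be transformed consistently."""

    def __init__(self, labels: Sequence[str], columns: Sequence[np.ndarray]):
        keep, dropped, constants = [], [], {}
        for idx, (lab, col) in enumerate(zip(labels, columns)):
            if lab != "intercept" and np.all(col == col[0]):
                dropped.append(lab)
                constants[lab] = float(col[0]) if col.size else 0.0
            else:
                keep.append(idx)
        self.labels = [labels[i] for i in keep]
        self.dropped_columns = dropped
        self._dropped_constants = constants
        self._keep_labels = set(self.labels)
        self.matrix = (
            np.column_stack([columns[i] for i in keep])
            if keep else np.empty((len(columns[0]) if columns else 0, 0))
        )
        n, p = self.matrix.shape
        if n > 0 and np.linalg.matrix_rank(self.matrix) < p:
            raise InestimableModelError(
                f"design matrix is rank deficient after dropping {dropped or 'nothing'} "
                f"(columns: {self.labels})"
            )

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    def transform(self, labels: Sequence[str], columns: Sequence[np.ndarray]) -> np.ndarray:
        """Assemble recipient rows onto the kept columns.

        A column that was dropped in the donor design must take the same
        constant value for every recipient; otherwise the recipients
        belong to a stratum with no donors and the model is inestimable
        for them.
        """
        out = []
        for lab, col in zip(labels, columns):
            if lab in self._keep_labels:
                out.append(col)
            else:
                const = self._dropped_constants.get(lab, 0.0)
                if col.size and not np.all(col == const):
                    raise InestimableModelError(
                        f"term {lab!r} was dropped from the imputation model "
                        "(no variation among fitted patients) but patients "
                        "needing imputation fall in the unrepresented stratum"
                    )
        return np.column_stack(out) if out else np.empty((len(columns[0]), 0))


def _status_current(disc_time: np.ndarray, j: int) -> np.ndarray:
    return ((disc_time >= 1) & (disc_time <= j)).astype(float)


def _pattern(disc_time: np.ndarray, j: int) -> np.ndarray:
    return np.where((disc_time >= 1) & (disc_time <= j), disc_time, 0)


def _raw_columns(
    spec: ImputationModelSpec,
    j: int,
    J: int,
    disc_time: np.ndarray,
    y_prev: np.ndarray,
    resid_basis: "ResidualBasis | None" = None,
) -> tuple[list, list]:
    """Labels and column values of the full (pre-drop) design at step j.

    ``y_prev`` holds the covariate outcomes Y_0..Y_{j-1} for the rows in
    question (observed for donors, observed-or-imputed for recipients).
    """
    labels: list = ["intercept"]
    cols: list = [np.ones(len(disc_time))]

    if spec.intercept_basis == "onoff_current":
        labels.append(f"D{j}")
        cols.append(_status_current(disc_time, j))
    elif spec.intercept_basis == "pattern_current":
        pat = _pattern(disc_time, j)
        for lev in range(1, j + 1):
            labels.append(f"P{j}={lev}")
            cols.append((pat == lev).astype(float))
    elif spec.intercept_basis == "pattern_final":
        for lev in range(1, J + 1):
            labels.append(f"P{J}={lev}")
            cols.append((disc_time == lev).astype(float))

    if spec.conditioning == "residuals":
        if resid_basis is None:
            raise ValueError("residual-conditioning models need a ResidualBasis")
        slope_vals = [resid_basis.residuals(k, y_prev[:, k], disc_time) for k in range(j)]
        slope_labels = [f"R{k}" for k in range(j)]
    else:
        slope_vals = [y_prev[:, k] for k in range(j)]
        slope_labels = [f"Y{k}" for k in range(j)]
    labels.extend(slope_labels)
    cols.extend(slope_vals)

    if spec.slope_basis == "onoff_current":
        dj = _status_current(disc_time, j)
        for k in range(j):
            labels.append(f"D{j}:{slope_labels[k]}")
            cols.append(dj * slope_vals[k])
    elif spec.slope_basis == "onoff_history":
        for k in range(j):
            dk = _status_current(disc_time, k)  # D_0 is identically zero
            labels.append(f"D{k}:{slope_labels[k]}")
            cols.append(dk * slope_vals[k])
    elif spec.slope_basis == "pattern_final":
        # interactions start at Y_1: baseline keeps a common slope
        for lev in range(1, J + 1):
            dummy = (disc_time == lev).astype(float)
            for k in range(1, j):
                labels.append(f"P{J}={lev}:{slope_labels[k]}")
                cols.append(dummy * slope_vals[k])

    return labels, cols


def build_design(
    spec: ImputationModelSpec,
    j: int,
    disc_time: np.ndarray,
    y_prev: np.ndarray,
    J: int,
    resid_basis: "ResidualBasis | None" = None,
) -> DesignInfo:
    """Design matrix for the step-j imputation regression on one arm.

    Rows are the patients used for fitting (outcome at j observed);
    zero-variance columns (for example the off-treatment indicator when
    nobody has discontinued yet) are dropped and recorded.
    """
    if not 1 <= j <= J:
        raise ValueError("timepoint j must lie in 1..J")
    disc_time = np.asarray(disc_time, dtype=int)
    y_prev = np.asarray(y_prev, dtype=float)
    if np.isnan(y_prev[:, :j]).any():
        raise ValueError("covariate outcomes must be fully observed or imputed")
    labels, cols = _raw_columns(spec, j, J, disc_time, y_prev, resid_basis)
    return DesignInfo(labels, cols)


class _OlsFit:
    """QR-based least squares fit reused across imputation copies."""

    def __init__(self, X: np.ndarray, y: np.ndarray):
        n, p = X.shape
        if n <= p:
            raise InestimableModelError(
                f"cannot fit imputation model: {n} observed rows for {p} parameters"
            )
        q, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        if diag.min() <= 1e-10 * max(diag.max(), 1.0):
            raise InestimableModelError("design matrix is numerically singular")
        self.beta = np.linalg.solve(r, q.T @ y)
        resid = y - X @ self.beta
        self.ssr = float(resid @ resid)
        self.dof = n - p
        self.r_inv = np.linalg.solve(r, np.eye(p))

    def draw(self, rng: np.random.Generator) -> PosteriorDraw:
        sigma2 = max(self.ssr / rng.chisquare(self.dof), MIN_SIGMA2)
        beta = self.beta + np.sqrt(sigma2) * (self.r_inv @ rng.standard_normal(self.beta.size))
        return PosteriorDraw(beta=beta, sigma=float(np.sqrt(sigma2)))


def fit_and_draw(
    design: DesignInfo | np.ndarray, y: np.ndarray, rng: np.random.Generator
) -> PosteriorDraw:
    """Fit OLS and draw (beta, sigma) from the noninformative posterior.

    sigma^2 is drawn from its scaled inverse-chi-square posterior with
    n - p degrees of freedom and beta from the conditional multivariate
    normal — the standard monotone-regression proper-imputation draw.
    """
    X = design.matrix if isinstance(design, DesignInfo) else np.asarray(design, dtype=float)
    return _OlsFit(X, np.asarray(y, dtype=float)).draw(rng)


class ResidualBasis:
    """Fitted marginal means per timepoint and status cell, and the
    residuals about them used as covariates by the *_R models.

    For timepoint k the cell is the on/off status D_k (OICS_R) or the
    discontinuation pattern P_k (PICS_R); the cell mean is taken over the
    patients in this arm whose outcome at k is observed.  Baseline (k=0)
    uses the arm mean, every patient being on treatment there.
    """

    def __init__(self, cell_kind: str, mu: dict):
        self.cell_kind = cell_kind  # "onoff" or "pattern"
        self.mu = mu  # {timepoint: {cell code: mean}}

    def cell_codes(self, k: int, disc_time: np.ndarray) -> np.ndarray:
        if k == 0:
            return np.zeros(len(disc_time), dtype=int)
        if self.cell_kind == "onoff":
            return _status_current(disc_time, k).astype(int)
        return _pattern(disc_time, k)

    def mean_for(self, k: int, disc_time: np.ndarray) -> np.ndarray:
        codes = self.cell_codes(k, disc_time)
        table = self.mu[k]
        lut = np.full(max(codes.max(initial=0) + 1, max(table, default=-1) + 2), np.nan)
        for c, v in table.items():
            lut[c] = v
        out = lut[codes]
        if np.isnan(out).any():
            bad = sorted(set(codes[np.isnan(out)].tolist()))
            raise InestimableModelError(
                f"no observed outcomes in status cell(s) {bad} at timepoint {k}: "
                "cannot centre residuals for patients in those cells"
            )
        return out

    def residuals(self, k: int, y_k: np.ndarray, disc_time: np.ndarray) -> np.ndarray:
        return np.asarray(y_k, dtype=float) - self.mean_for(k, disc_time)


def compute_residual_basis(
    spec: ImputationModelSpec,
    disc_time: np.ndarray,
    y_observed: np.ndarray,
    J: int,
) -> ResidualBasis:
    """Cell means of the observed outcomes for a residual-conditioning model.

    ``y_observed`` is the masked (n, J+1) outcome matrix for one arm; the
    mean for each (timepoint, cell) uses the patients with that outcome
    observed, which makes the within-cell mean of the residuals exactly
    zero among them.
    """
    if spec.conditioning != "residuals":
        raise ValueError("residual basis only applies to *_R models")
    kind = "onoff" if spec.intercept_basis == "onoff_current" else "pattern"
    basis = ResidualBasis(kind, {})
    disc_time = np.asarray(disc_time, dtype=int)
    y_observed = np.asarray(y_observed, dtype=float)
    for k in range(J):  # covariate timepoints 0..J-1
        codes = basis.cell_codes(k, disc_time)
        obs = ~np.isnan(y_observed[:, k])
        table = {}
        for c in np.unique(codes):
            cell = obs & (codes == c)
            if cell.any():
                table[int(c)] = float(y_observed[cell, k].mean())
        basis.mu[k] = table
    return basis


class ImputedDataset:
    """m completed copies of a trial; observed cells identical across copies."""

    def __init__(self, trial: TrialData, y_imputed: np.ndarray, model: str):
        self.trial = trial
        self.y = y_imputed  # (m, n, J+1)
        self.m = y_imputed.shape[0]
        self.model = model

    def dataset(self, i: int) -> TrialData:
        return self.trial.with_y(self.y[i])

    def datasets(self) -> list:
        return [self.dataset(i) for i in range(self.m)]

    def stacked(self) -> pd.DataFrame:
        frames = []
        for i in range(self.m):
            d = self.dataset(i).df.copy()
            d.insert(0, "imputation", i + 1)
            frames.append(d)
        return pd.concat(frames, ignore_index=True)


def _check_monotone(y: np.ndarray) -> None:
    if np.isnan(y[:, 0]).any():
        raise ValueError("baseline outcomes must be observed for every patient")
    obs = ~np.isnan(y[:, 1:])
    # once missing, always missing
    if np.any(obs[:, 1:] & ~obs[:, :-1]):
        raise ValueError("missingness must be monotone over timepoints")


def impute_arrays(
    y: np.ndarray,
    disc_time: np.ndarray,
    arm_active: np.ndarray,
    spec: ImputationModelSpec,
    m: int,
    rng: np.random.Generator,
    J: int,
) -> np.ndarray:
    """Array core of :func:`sequential_impute`; returns an (m, n, J+1) stack."""
    if m < 2:
        raise ValueError("at least 2 imputations are required")
    _check_monotone(y)
    out = np.repeat(y[None, :, :], m, axis=0)
    for arm_label, arm_mask in (("C", ~arm_active), ("A", arm_active)):
        rows = np.flatnonzero(arm_mask)
        if rows.size == 0:
            continue
        d_arm = disc_time[rows]
        step = 0
        try:
            basis = (
                compute_residual_basis(spec, d_arm, y[rows], J)
                if spec.conditioning == "residuals" else None
            )
            for j in range(1, J + 1):
                step = j
                observed = ~np.isnan(y[rows, j])
                recipients = rows[~observed]
                if recipients.size == 0:
                    continue
                donors = rows[observed]
                dinfo = build_design(
                    spec, j, disc_time[donors], y[donors, :], J, resid_basis=basis
                )
                fit = _OlsFit(dinfo.matrix, y[donors, j])
                d_rec = disc_time[recipients]
                for i in range(m):
                    draw = fit.draw(rng)
                    labels, cols = _raw_columns(
                        spec, j, J, d_rec, out[i][recipients, :], basis
                    )
                    x_rec = dinfo.transform(labels, cols)
                    out[i][recipients, j] = (
                        x_rec @ draw.beta
                        + draw.sigma * rng.standard_normal(recipients.size)
                    )
        except InestimableModelError as err:
            raise err.tagged(arm_label, err.timepoint or step, spec.name) from err
    return out


def sequential_impute(
    data: TrialData,
    spec: ImputationModelSpec | str,
    m: int,
    rng: np.random.Generator | int,
) -> ImputedDataset:
    """Produce m completed datasets under one imputation model structure.

    Imputation proceeds per arm and per timepoint in order; each copy
    uses a fresh proper posterior draw.  Patients with no missing
    outcomes pass through unchanged, identically in every copy.
    """
    if isinstance(spec, str):
        spec = ImputationModelSpec.from_name(spec)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    y = data.y_matrix()
    stacked = impute_arrays(
        y, data.disc_time, data.arm_active, spec, m, rng, data.J
    )
    return ImputedDataset(trial=data, y_imputed=stacked, model=spec.name)
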