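"""Virtual-trial simulator for treatment-policy estimand studies.

Simulates two-arm parallel-group trials of a continuous repeated outcome
(FEV1 in mL in the motivating setting) in which patients may discontinue
randomised treatment and subsequently withdraw from follow-up.  Each
patient carries a multivariate-normal vector of *potential* outcomes —
baseline, on-treatment values for every post-baseline timepoint and
off-treatment values for the same timepoints — so that the observed
trajectory can switch from the on- to the off-treatment component at the
moment of discontinuation.

Discontinuation is selected by outcome rank ("worst patients
discontinue") under two mechanisms:

* DAR  — discontinuation at random: selection on the most recent
  *observed* on-treatment value.
* DNAR — discontinuation not at random: selection on the *next*
  (unobserved) potential on-treatment value.

Study withdrawal is a single assessment at the point of discontinuation:
a withdrawn patient contributes no off-treatment data, so missingness is
monotone and confined to discontinuers.  Discontinuation and withdrawal
counts are fixed exactly (rank selection / simple random sampling of an
exact count) rather than drawn Bernoulli, so every simulated trial hits
the configured rates.

The true treatment-policy contrast for a scenario (difference in mean
change from baseline at the final timepoint, counting off-treatment
outcomes) is evaluated by a large-sample Monte Carlo oracle that runs
the same generative process without any withdrawal masking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ARMS",
    "MECHANISMS",
    "TRAJECTORIES",
    "BALANCES",
    "SimulationParameters",
    "ScenarioConfig",
    "TrialData",
    "TruthValues",
    "default_covariance",
    "round_half_up",
    "discontinuation_counts",
    "generate_potential_outcomes",
    "select_discontinuations",
    "select_withdrawals",
    "withdrawal_time_rates",
    "simulate_trial",
    "compute_truth",
]

ARMS = ("C", "A")
MECHANISMS = ("DAR", "DNAR")
TRAJECTORIES = ("return_to_baseline", "same_as_active")
BALANCES = ("more_early", "balanced", "more_late")

DEFAULT_CONTROL_MEANS = (2140.0, 2470.0, 2520.0, 2540.0)
DEFAULT_EFFECTS = (0.0, 100.0, 100.0, 100.0)
DEFAULT_SD = 450.0
DEFAULT_SPLIT = (0.5, 0.3, 0.2)

# shift applied to the first-window withdrawal rate in the unbalanced
# ("more early" / "more late") schemes; later windows are adjusted so the
# split-weighted mean withdrawal rate stays at the configured overall rate
UNBALANCE_SHIFT = 0.2


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties going up (0.5 -> 1)."""
    return int(math.floor(x + 0.5))


def default_covariance(
    J: int = 3,
    sd: float = DEFAULT_SD,
    within_corr: float = 0.7,
    cross_corr: float = 0.8,
) -> np.ndarray:
    """Default covariance of the potential-outcome vector.

    Components are ordered (Y0, Y1_on..YJ_on, Y1_off..YJ_off).  All
    components share the same standard deviation ``sd``; correlation
    decays as ``within_corr**lag`` between timepoints within a regime
    (baseline counting as timepoint 0 of either regime) and is damped by
    ``cross_corr`` between the on- and off-treatment regimes.  The on-
    and off-treatment blocks are identical by construction.  If the
    resulting matrix is not positive definite it is projected onto the
    nearest correlation matrix with eigenvalues floored at a small
    positive value.
    """
    d = 2 * J + 1

    def time_of(i: int) -> int:
        return 0 if i == 0 else (i - 1) % J + 1

    def regime(i: int) -> str:
        return "base" if i == 0 else ("on" if i <= J else "off")

    corr = np.eye(d)
    for i in range(d):
        for k in range(i + 1, d):
            lag = abs(time_of(i) - time_of(k))
            ri, rk = regime(i), regime(k)
            rho = within_corr ** lag
            if "base" not in (ri, rk) and ri != rk:
                rho *= cross_corr
            corr[i, k] = corr[k, i] = rho
    eigval, eigvec = np.linalg.eigh(corr)
    if eigval.min() <= 1e-10:
        eigval = np.clip(eigval, 1e-8, None)
        corr = (eigvec * eigval) @ eigvec.T
        scale = np.sqrt(np.diag(corr))
        corr = corr / np.outer(scale, scale)
    return sd * sd * corr


@dataclass(frozen=True)
class SimulationParameters:
    """Design constants of the data-generating model.

    ``mean_control_on`` holds the Control-arm means (mL) for baseline and
    the J on-treatment timepoints; ``effect_on`` the Active-minus-Control
    on-treatment differences at the same timepoints (zero at baseline).
    ``covariance`` is the (2J+1)-dimensional covariance of the potential
    outcomes ordered (Y0, on-treatment 1..J, off-treatment 1..J).
    """

    n_per_arm: int = 375
    mean_control_on: tuple = DEFAULT_CONTROL_MEANS
    effect_on: tuple = DEFAULT_EFFECTS
    off_trajectory: str = "return_to_baseline"
    covariance: np.ndarray | None = None
    J: int = 3

    def __post_init__(self) -> None:
        if self.n_per_arm < 0:
            raise ValueError("n_per_arm must be non-negative")
        if self.J < 1:
            raise ValueError("J must be at least 1")
        if len(self.mean_control_on) != self.J + 1:
            raise ValueError("mean_control_on must have J+1 entries")
        if len(self.effect_on) != self.J + 1:
            raise ValueError("effect_on must have J+1 entries")
        if self.effect_on[0] != 0.0:
            raise ValueError("effect_on[0] must be 0 (no baseline difference)")
        if self.off_trajectory not in TRAJECTORIES:
            raise ValueError(f"off_trajectory must be one of {TRAJECTORIES}")
        cov = self.covariance
        if cov is None:
            cov = default_covariance(self.J)
        cov = np.asarray(cov, dtype=float)
        d = 2 * self.J + 1
        if cov.shape != (d, d):
            raise ValueError(f"covariance must be {d}x{d}")
        if not np.allclose(cov, cov.T, atol=1e-8):
            raise ValueError("covariance matrix is not symmetric")
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"covariance matrix is not positive definite:\n{cov}"
            ) from exc
        on = cov[1 : self.J + 1, 1 : self.J + 1]
        off = cov[self.J + 1 :, self.J + 1 :]
        if not np.allclose(on, off, atol=1e-6):
            raise ValueError(
                "on- and off-treatment covariance sub-blocks must be identical"
            )
        object.__setattr__(self, "covariance", cov)
        object.__setattr__(self, "mean_control_on", tuple(float(v) for v in self.mean_control_on))
        object.__setattr__(self, "effect_on", tuple(float(v) for v in self.effect_on))

    def component_means(self, arm: str) -> np.ndarray:
        """Mean vector (Y0, on 1..J, off 1..J) for one arm."""
        if arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}")
        base = np.asarray(self.mean_control_on, dtype=float)
        eff = np.asarray(self.effect_on, dtype=float)
        on = base + eff if arm == "A" else base.copy()
        if self.off_trajectory == "return_to_baseline":
            off = np.full(self.J, base[0])
        else:  # same_as_active: off-treatment tracks the Active on-treatment means
            off = (base + eff)[1:]
        return np.concatenate([on, off])


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the discontinuation/withdrawal factorial."""

    mechanism: str
    disc_rate_control: float
    disc_rate_active: float
    withdrawal_rate: float
    withdrawal_balance: str
    sim_params: SimulationParameters = field(default_factory=SimulationParameters)
    disc_time_split: tuple = DEFAULT_SPLIT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"mechanism must be one of {MECHANISMS}")
        if self.withdrawal_balance not in BALANCES:
            raise ValueError(f"withdrawal_balance must be one of {BALANCES}")
        for name in ("disc_rate_control", "disc_rate_active", "withdrawal_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        split = tuple(float(s) for s in self.disc_time_split)
        if len(split) != self.sim_params.J:
            raise ValueError("disc_time_split must have one entry per post-baseline timepoint")
        if any(s < 0 for s in split):
            raise ValueError("disc_time_split entries must be non-negative")
        if abs(sum(split) - 1.0) > 1e-12:
            raise ValueError("disc_time_split must sum to 1")
        object.__setattr__(self, "disc_time_split", split)
        # fail early if the balance scheme pushes a per-window rate out of range
        withdrawal_time_rates(self.withdrawal_rate, self.withdrawal_balance, split)

    def disc_rate(self, arm: str) -> float:
        return self.disc_rate_control if arm == "C" else self.disc_rate_active


@dataclass
class TrialData:
    """One simulated (or loaded) trial in wide patient-level format.

    ``df`` has columns ``patient_id, arm, y0..yJ, disc_time, withdrawn``
    with NaN marking missing outcomes.  ``disc_time`` is 0 for patients
    who never discontinue; a value t >= 1 means the outcome at timepoint
    t is the first off-treatment outcome.  ``complete`` (simulator output
    only) holds the same table before withdrawal masking.
    """

    df: pd.DataFrame
    J: int
    complete: pd.DataFrame | None = None

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def y_columns(self) -> list:
        return [f"y{j}" for j in range(self.J + 1)]

    def y_matrix(self, complete: bool = False) -> np.ndarray:
        src = self.complete if complete else self.df
        if src is None:
            raise ValueError("no complete (pre-masking) data attached to this trial")
        return src[self.y_columns].to_numpy(dtype=float)

    @property
    def disc_time(self) -> np.ndarray:
        return self.df["disc_time"].to_numpy(dtype=int)

    @property
    def withdrawn(self) -> np.ndarray:
        return self.df["withdrawn"].to_numpy(dtype=bool)

    @property
    def arm_active(self) -> np.ndarray:
        return (self.df["arm"] == "A").to_numpy()

    def off_treatment(self, j: int) -> np.ndarray:
        """Indicator D_j: off randomised treatment at timepoint j."""
        d = self.disc_time
        return ((d >= 1) & (d <= j)).astype(int)

    def pattern(self, j: int) -> np.ndarray:
        """Discontinuation pattern P_j: 0 = on treatment through j, else the
        discontinuation timepoint (1..j)."""
        d = self.disc_time
        return np.where((d >= 1) & (d <= j), d, 0)

    def validate(self) -> None:
        """Check the structural invariants of simulator output."""
        y = self.y_matrix()
        d = self.disc_time
        w = self.withdrawn
        if np.isnan(y[:, 0]).any():
            raise ValueError("baseline outcome must never be missing")
        if ((d < 0) | (d > self.J)).any():
            raise ValueError("disc_time must lie in 0..J")
        if (w & (d < 1)).any():
            raise ValueError("withdrawal only occurs among discontinuers")
        miss = np.isnan(y)
        for j in range(1, self.J + 1):
            expected = w & (d <= j)
            if not np.array_equal(miss[:, j], expected):
                raise ValueError(
                    "missingness must start exactly at disc_time for withdrawn "
                    "patients and be absent otherwise"
                )

    def with_y(self, y: np.ndarray) -> "TrialData":
        out = self.df.copy()
        out[self.y_columns] = y
        return TrialData(df=out, J=self.J, complete=None)


@dataclass(frozen=True)
class TruthValues:
    """Monte Carlo estimates of the true treatment-policy quantities."""

    mean_change_control: float
    mean_change_active: float
    delta: float
    oracle_mc_se: float
    oracle_n: int

    def __post_init__(self) -> None:
        gap = self.delta - (self.mean_change_active - self.mean_change_control)
        if abs(gap) > 1e-9:
            raise ValueError("delta must equal the difference of the arm means")


def discontinuation_counts(n: int, rate: float, split: Sequence[float]) -> np.ndarray:
    """Exact per-timepoint discontinuation counts.

    The total ``round_half_up(n * rate)`` is apportioned over timepoints by
    the largest-remainder rule applied to ``total * split`` with ties broken
    toward the earliest timepoint.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    split = np.asarray(split, dtype=float)
    if (split < 0).any():
        raise ValueError("split entries must be non-negative")
    if abs(split.sum() - 1.0) > 1e-12:
        raise ValueError("split must sum to 1")
    total = round_half_up(n * rate)
    target = total * split
    counts = np.floor(target).astype(int)
    frac = target - counts
    leftover = total - int(counts.sum())
    if leftover > 0:
        order = np.lexsort((np.arange(split.size), -frac))
        counts[order[:leftover]] += 1
    return counts


def generate_potential_outcomes(
    params: SimulationParameters, arm: str, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n iid potential-outcome vectors (Y0, on 1..J, off 1..J)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    mean = params.component_means(arm)
    chol = np.linalg.cholesky(params.covariance)
    z = rng.standard_normal((n, mean.size))
    return mean + z @ chol.T


def select_discontinuations(
    potentials: np.ndarray,
    mechanism: str,
    counts: Sequence[int],
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Assign discontinuation times by sequential worst-rank selection.

    For each window t = 1..J the ``counts[t-1]`` lowest-scoring patients
    still on treatment are set to discontinue at t.  DAR scores on the
    last observed on-treatment value (baseline for t = 1); DNAR scores on
    the next potential on-treatment value.  Selection is deterministic
    given the potentials (outcomes are continuous, so ties have measure
    zero); ``rng`` is accepted for interface symmetry.
    """
    if mechanism not in MECHANISMS:
        raise ValueError(f"mechanism must be one of {MECHANISMS}")
    potentials = np.asarray(potentials, dtype=float)
    n = potentials.shape[0]
    counts = np.asarray(counts, dtype=int)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    disc = np.zeros(n, dtype=int)
    for t in range(1, counts.size + 1):
        k = int(counts[t - 1])
        pool = np.flatnonzero(disc == 0)
        if k > pool.size:
            raise ValueError(
                f"cannot discontinue {k} patients at window {t}: only {pool.size} remain"
            )
        if k == 0:
            continue
        col = t - 1 if mechanism == "DAR" else t
        scores = potentials[pool, col]
        if k < pool.size:
            worst = np.argpartition(scores, k)[:k]
        else:
            worst = np.arange(pool.size)
        disc[pool[worst]] = t
    return disc


def withdrawal_time_rates(
    rate: float, balance: str, split: Sequence[float] = DEFAULT_SPLIT
) -> np.ndarray:
    """Per-discontinuation-window withdrawal rates (w_1..w_J).

    The rates satisfy sum(split_t * w_t) == rate so the overall share of
    discontinuers withdrawn by the final timepoint equals ``rate``.
    ``more_early`` raises the first-window rate by 0.2 (and lowers the
    later windows to compensate); ``more_late`` does the opposite.
    """
    if balance not in BALANCES:
        raise ValueError(f"balance must be one of {BALANCES}")
    split = np.asarray(split, dtype=float)
    J = split.size
    if rate in (0.0, 1.0) or balance == "balanced":
        w = np.full(J, rate)
    else:
        shift = UNBALANCE_SHIFT if balance == "more_early" else -UNBALANCE_SHIFT
        w = np.empty(J)
        w[0] = rate + shift
        # keep the split-weighted mean at `rate`
        w[1:] = rate - shift * split[0] / (1.0 - split[0])
    if ((w < -1e-12) | (w > 1.0 + 1e-12)).any():
        raise ValueError(
            f"per-window withdrawal rates {w} fall outside [0, 1] for "
            f"rate={rate}, balance={balance}"
        )
    return np.clip(w, 0.0, 1.0)


def select_withdrawals(
    disc_time: np.ndarray,
    withdrawal_rate: float,
    balance: str,
    rng: np.random.Generator,
    split: Sequence[float] = DEFAULT_SPLIT,
) -> np.ndarray:
    """Flag an exact simple random sample of discontinuers as withdrawn."""
    disc_time = np.asarray(disc_time, dtype=int)
    w = withdrawal_time_rates(withdrawal_rate, balance, split)
    withdrawn = np.zeros(disc_time.size, dtype=bool)
    for t in range(1, w.size + 1):
        pool = np.flatnonzero(disc_time == t)
        k = round_half_up(pool.size * w[t - 1])
        if k > 0:
            withdrawn[rng.choice(pool, size=k, replace=False)] = True
    return withdrawn


def _simulate_arm(
    config: ScenarioConfig, arm: str, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Potential outcomes, observed trajectories, disc times and withdrawal."""
    params = config.sim_params
    J = params.J
    pots = generate_potential_outcomes(params, arm, n, rng)
    counts = discontinuation_counts(n, config.disc_rate(arm), config.disc_time_split)
    disc = select_discontinuations(pots, config.mechanism, counts, rng)
    withdrawn = select_withdrawals(
        disc, config.withdrawal_rate, config.withdrawal_balance, rng, config.disc_time_split
    )
    y = pots[:, : J + 1].copy()
    jj = np.arange(1, J + 1)
    off = (disc[:, None] >= 1) & (jj[None, :] >= disc[:, None])
    y[:, 1:][off] = pots[:, J + 1 :][off]
    return pots, y, disc, withdrawn


def simulate_trial(config: ScenarioConfig, seed=None) -> TrialData:
    """Simulate one trial under a scenario configuration.

    ``seed`` may be an int or a numpy SeedSequence; when omitted the
    scenario's own seed is used.  Identical seeds give bit-identical
    trials.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    params = config.sim_params
    J = params.J
    frames = []
    complete_frames = []
    next_id = 1
    for arm in ARMS:
        n = params.n_per_arm
        _, y, disc, withdrawn = _simulate_arm(config, arm, n, rng)
        y_masked = y.copy()
        jj = np.arange(1, J + 1)
        miss = withdrawn[:, None] & (jj[None, :] >= disc[:, None])
        y_masked[:, 1:][miss] = np.nan
        base = {
            "patient_id": np.arange(next_id, next_id + n),
            "arm": arm,
        }
        next_id += n
        ycols = {f"y{j}": y_masked[:, j] for j in range(J + 1)}
        ycols_full = {f"y{j}": y[:, j] for j in range(J + 1)}
        tail = {"disc_time": disc, "withdrawn": withdrawn}
        frames.append(pd.DataFrame({**base, **ycols, **tail}))
        complete_frames.append(pd.DataFrame({**base, **ycols_full, **tail}))
    trial = TrialData(
        df=pd.concat(frames, ignore_index=True),
        J=J,
        complete=pd.concat(complete_frames, ignore_index=True),
    )
    trial.validate()
    return trial


def compute_truth(
    config: ScenarioConfig, oracle_n: int = 2_000_000, seed=None
) -> TruthValues:
    """Monte Carlo oracle for the true treatment-policy estimand.

    Runs the generative process (including rank-based discontinuation,
    which shifts the off-treatment mixture) with ``oracle_n`` patients per
    arm and *no* withdrawal masking, and returns the empirical mean change
    from baseline per arm, their difference, and the Monte Carlo SE of the
    difference.
    """
    if oracle_n < 200:
        raise ValueError("oracle_n must be at least 200")
    if seed is None:
        seed = np.random.SeedSequence([config.seed, 202_406])
    rng = np.random.default_rng(seed)
    params = config.sim_params
    J = params.J
    # Rank-based exact-count selection couples patients, so the naive iid
    # standard error of the mean is invalid.  Run independent blocks and use
    # the empirical spread of the block-level contrasts instead.
    n_blocks = 20 if oracle_n >= 20 * 2000 else max(oracle_n // 1000, 4)
    block_n = oracle_n // n_blocks
    deltas = np.empty(n_blocks)
    arm_means = {arm: np.empty(n_blocks) for arm in ARMS}
    for b in range(n_blocks):
        for arm in ARMS:
            pots = generate_potential_outcomes(params, arm, block_n, rng)
            counts = discontinuation_counts(
                block_n, config.disc_rate(arm), config.disc_time_split
            )
            disc = select_discontinuations(pots, config.mechanism, counts, rng)
            y_final = pots[:, J].copy()
            off = disc >= 1  # disc <= J always: every discontinuer is off at J
            y_final[off] = pots[off, 2 * J]
            arm_means[arm][b] = float((y_final - pots[:, 0]).mean())
        deltas[b] = arm_means["A"][b] - arm_means["C"][b]
    mean_c = float(arm_means["C"].mean())
    mean_a = float(arm_means["A"].mean())
    return TruthValues(
        mean_change_control=mean_c,
        mean_change_active=mean_a,
        delta=mean_a - mean_c,
        oracle_mc_se=float(deltas.std(ddof=1) / math.sqrt(n_blocks)),
        oracle_n=block_n * n_blocks,
    )


def null_scenario(config: ScenarioConfig) -> ScenarioConfig:
    """Return the matched null configuration: no treatment effect and equal
    discontinuation rates (set to the Control rate) in both arms."""
    params = replace(
        config.sim_params, effect_on=tuple(0.0 for _ in config.sim_params.effect_on)
    )
    return replace(
        config,
        sim_params=params,
        disc_rate_active=config.disc_rate_control,
    )
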