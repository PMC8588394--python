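"""Loss-based model comparison: Plackett-Luce ranking, Model Confidence
Set, and Superior Predictive Ability.

All three consume a :class:`LossMatrix` of prediction losses (RMSE per
evaluation unit, rows = fold x patient units, columns = models):

* :func:`pl_ranking` - Bayesian Plackett-Luce model over the per-row
  rankings with a Dirichlet prior on the worth vector; reports each
  model's posterior probability of being the best.
* :func:`mcs` - Hansen/Lunde/Nason iterative elimination with a
  studentized max statistic and a stationary-bootstrap null; returns the
  set of models statistically indistinguishable from the best at level
  alpha, with monotonized p-values.
* :func:`spa` - Hansen's reality-check successor testing whether any
  competitor beats a chosen benchmark; reports the lower, consistent and
  upper p-values produced by the three standard re-centerings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import AlignmentError

__all__ = [
    "LossMatrix",
    "RankingResult",
    "MCSResult",
    "SPAResult",
    "pl_ranking",
    "mcs",
    "spa",
    "multi_horizon",
    "stationary_bootstrap_indices",
]

_EPS = 1e-12


@dataclass
class LossMatrix:
    """Observations x models matrix of non-negative prediction losses."""

    losses: np.ndarray
    model_ids: tuple
    horizon: str = "30"
    unit: str = "per-fold-per-patient"

    def __post_init__(self):
        self.losses = np.asarray(self.losses, dtype=float)
        self.model_ids = tuple(self.model_ids)
        if self.losses.ndim != 2 or self.losses.shape[1] != len(self.model_ids):
            raise AlignmentError("losses must be (observations, models)")
        if self.losses.shape[1] < 2:
            raise ValueError("need at least two models")
        if np.any(~np.isfinite(self.losses)):
            raise ValueError("losses contain missing or non-finite cells")
        if np.any(self.losses < 0):
            raise ValueError("losses must be non-negative")

    @property
    def n_obs(self) -> int:
        return self.losses.shape[0]

    @property
    def n_models(self) -> int:
        return self.losses.shape[1]


def multi_horizon(lm_a: LossMatrix, lm_b: LossMatrix) -> LossMatrix:
    """Row-wise concatenation of two loss matrices over the same models."""
    if lm_a.model_ids != lm_b.model_ids or lm_a.unit != lm_b.unit:
        raise AlignmentError("model sets / units differ between horizons")
    return LossMatrix(
        np.vstack([lm_a.losses, lm_b.losses]),
        lm_a.model_ids,
        horizon=f"{lm_a.horizon}∪{lm_b.horizon}",
        unit=lm_a.unit,
    )


# ------------------------------------------------------------ Plackett-Luce
@dataclass
class RankingResult:
    model_ids: tuple
    p_best: np.ndarray  # posterior mean probability of ranking first
    ci_low: np.ndarray  # 5% posterior quantile
    ci_high: np.ndarray  # 95% posterior quantile
    samples: np.ndarray = field(repr=False)  # (draws, models) of P(best)

    def as_dict(self) -> dict:
        return dict(zip(self.model_ids, self.p_best))


def _rankings_from_losses(losses: np.ndarray, rng) -> np.ndarray:
    """Per-row orderings, lowest loss first; exact ties broken at random."""
    jitter = rng.uniform(0, 1e-9, size=losses.shape)
    return np.argsort(losses + jitter, axis=1)


def pl_ranking(
    loss_matrix: LossMatrix,
    prior_concentration: float = 1.0,
    n_samples: int = 2000,
    seed: int = 0,
    n_chains: int = 4,
    burn_in: int = 500,
) -> RankingResult:
    """Posterior probability of each model being the best.

    Each observation row is reduced to a ranking (magnitudes discarded).
    The Plackett-Luce likelihood with a Dirichlet(prior_concentration)
    prior on the normalized worths is sampled by the latent-exponential
    Gibbs sampler (Gamma conditionals via the data augmentation of Caron
    & Doucet 2012); P(best) for a draw is w_k / sum(w). Rows where all
    models tie carry no ranking information and are dropped.
    """
    if prior_concentration <= 0:
        raise ValueError("prior_concentration must be positive")
    losses = loss_matrix.losses
    tied = np.all(np.isclose(losses, losses[:, :1]), axis=1)
    if tied.any():
        warnings.warn(f"dropping {int(tied.sum())} all-tied observation rows")
        losses = losses[~tied]
    if len(losses) == 0:
        raise ValueError("no informative observations")
    n_obs, k = losses.shape
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    orders = _rankings_from_losses(losses, rng)
    # win counts: each model is "chosen" once per row unless ranked last
    wins = np.zeros(k)
    for j in range(k - 1):
        np.add.at(wins, orders[:, j], 1.0)

    draws = []
    per_chain = max(1, n_samples // n_chains)
    for chain in range(n_chains):
        crng = np.random.default_rng(np.random.SeedSequence([seed, 13, chain]))
        w = crng.gamma(prior_concentration, 1.0, size=k)
        for it in range(burn_in + per_chain):
            # latent rates: sum of worths still in contention at each stage
            w_ord = w[orders]  # (n_obs, k)
            suffix = np.cumsum(w_ord[:, ::-1], axis=1)[:, ::-1]  # (n_obs, k)
            z = crng.exponential(1.0 / suffix[:, : k - 1])  # stages 1..k-1
            # rate accumulated on each model: z_{i,j} applies to models with
            # rank position >= j in row i
            zcum = np.cumsum(z, axis=1)  # (n_obs, k-1)
            rates = np.zeros(k)
            # position 0 contributes z_0; position p contributes sum z_{0..min(p,k-2)}
            contrib = np.concatenate([zcum, zcum[:, -1:]], axis=1)  # (n_obs, k)
            np.add.at(rates, orders, contrib)
            w = crng.gamma(prior_concentration + wins, 1.0 / (1.0 + rates))
            if it >= burn_in:
                draws.append(w / w.sum())
    samples = np.asarray(draws)
    return RankingResult(
        model_ids=loss_matrix.model_ids,
        p_best=samples.mean(axis=0),
        ci_low=np.quantile(samples, 0.05, axis=0),
        ci_high=np.quantile(samples, 0.95, axis=0),
        samples=samples,
    )


# ------------------------------------------------------------------ bootstrap
def stationary_bootstrap_indices(
    n: int, n_replicates: int, expected_block: float, rng
) -> np.ndarray:
    """(n_replicates, n) index matrix from the Politis-Romano scheme.

    Block lengths are geometric with mean ``expected_block``; blocks wrap
    circularly.
    """
    p = 1.0 / max(expected_block, 1.0)
    fresh = rng.random((n_replicates, n)) < p
    fresh[:, 0] = True
    starts = rng.integers(0, n, size=(n_replicates, n))
    idx = np.empty((n_replicates, n), dtype=np.intp)
    idx[:, 0] = starts[:, 0]
    for t in range(1, n):
        idx[:, t] = np.where(fresh[:, t], starts[:, t], (idx[:, t - 1] + 1) % n)
    return idx


# ------------------------------------------------------------------------ MCS
@dataclass
class MCSResult:
    model_ids: tuple
    p_values: dict  # model -> monotonized MCS p-value
    survivors: tuple  # models with p > alpha
    elimination_order: tuple
    alpha: float

    def in_set(self, model_id: str) -> bool:
        return model_id in self.survivors


def mcs(
    loss_matrix: LossMatrix,
    alpha: float = 0.05,
    n_bootstrap: int = 1000,
    block_length: float = 5.0,
    seed: int = 0,
) -> MCSResult:
    """Model Confidence Set by iterative elimination (T_max statistic).

    At each step the studentized per-model statistic t_i = dbar_i /
    se(dbar_i) is computed, where dbar_i is model i's mean loss
    differential against the average of the current set; the null
    distribution of max_i t_i comes from a stationary block bootstrap.
    The worst model is eliminated while the equivalence hypothesis is
    rejected. Eliminated models receive the running maximum of the test
    p-values (monotonization); the last survivor has p-value 1.
    """
    if loss_matrix.n_obs < 10:
        raise ValueError("MCS needs at least 10 observations")
    losses = loss_matrix.losses
    ids = list(loss_matrix.model_ids)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
    boot_idx = stationary_bootstrap_indices(
        losses.shape[0], n_bootstrap, block_length, rng
    )

    current = list(range(len(ids)))
    p_values: dict = {}
    elim_order = []
    running_max = 0.0
    while len(current) > 1:
        sub = losses[:, current]  # (n, m)
        di = sub - sub.mean(axis=1, keepdims=True)  # loss vs set average
        dbar = di.mean(axis=0)  # (m,)
        boot_dbar = di[boot_idx].mean(axis=1)  # (B, m)
        se = np.sqrt(np.mean((boot_dbar - dbar) ** 2, axis=0))
        se = np.maximum(se, _EPS)
        t_obs = dbar / se
        t_boot = (boot_dbar - dbar) / se
        stat = t_obs.max()
        p = float(np.mean(t_boot.max(axis=1) >= stat))
        running_max = max(running_max, p)
        worst = int(np.argmax(t_obs))
        if np.allclose(dbar, 0.0):
            # fully tied set: indistinguishable, everyone survives
            for j in current:
                p_values[ids[j]] = 1.0
            break
        p_values[ids[current[worst]]] = running_max
        elim_order.append(ids[current[worst]])
        current.pop(worst)
    if len(current) == 1:
        p_values[ids[current[0]]] = 1.0
    survivors = tuple(m for m in ids if p_values[m] > alpha)
    if not survivors:  # the best model always survives
        best = max(ids, key=lambda m: p_values[m])
        survivors = (best,)
    return MCSResult(
        model_ids=tuple(ids),
        p_values=p_values,
        survivors=survivors,
        elimination_order=tuple(elim_order),
        alpha=alpha,
    )


# ------------------------------------------------------------------------ SPA
@dataclass
class SPAResult:
    benchmark: str
    p_lower: float
    p_consistent: float
    p_upper: float

    def as_tuple(self):
        return (self.p_lower, self.p_consistent, self.p_upper)


def spa(
    loss_matrix: LossMatrix,
    benchmark: str,
    n_bootstrap: int = 1000,
    block_length: float = 5.0,
    seed: int = 0,
) -> SPAResult:
    """Superior Predictive Ability test of a benchmark model.

    d_k(t) = loss_benchmark(t) - loss_k(t); positive means competitor k
    beat the benchmark at observation t. The studentized max statistic
    over competitors is compared with a stationary-bootstrap null under
    the three standard re-centerings: lower (mu = min(dbar, 0)),
    consistent (mu = dbar where significantly negative, else 0) and upper
    (mu = 0), giving p_lower <= p_consistent <= p_upper. A high
    consistent p-value means no competitor significantly beats the
    benchmark.
    """
    if benchmark not in loss_matrix.model_ids:
        raise KeyError(f"benchmark {benchmark!r} not in model set")
    if loss_matrix.n_models < 2:
        raise ValueError("need at least one competitor")
    ids = list(loss_matrix.model_ids)
    b = ids.index(benchmark)
    others = [j for j in range(len(ids)) if j != b]
    d = loss_matrix.losses[:, [b]] - loss_matrix.losses[:, others]  # (n, k)
    n, k = d.shape
    dbar = d.mean(axis=0)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 19]))
    boot_idx = stationary_bootstrap_indices(n, n_bootstrap, block_length, rng)
    boot_dbar = d[boot_idx].mean(axis=1)  # (B, k)
    omega = np.sqrt(n * np.mean((boot_dbar - dbar) ** 2, axis=0))
    omega = np.maximum(omega, _EPS)

    t_obs = max(0.0, float(np.max(np.sqrt(n) * dbar / omega)))
    mus = {
        "lower": np.minimum(dbar, 0.0),
        "consistent": np.where(
            np.sqrt(n) * dbar / omega <= -np.sqrt(2.0 * np.log(np.log(max(n, 3)))),
            dbar,
            0.0,
        ),
        "upper": np.zeros(k),
    }
    pvals = {}
    for name, mu in mus.items():
        t_boot = np.sqrt(n) * (boot_dbar - dbar + mu) / omega  # (B, k)
        stat_boot = np.maximum(t_boot.max(axis=1), 0.0)
        pvals[name] = float(np.mean(stat_boot >= t_obs))
    return SPAResult(
        benchmark=benchmark,
        p_lower=pvals["lower"],
        p_consistent=pvals["consistent"],
        p_upper=pvals["upper"],
    )
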