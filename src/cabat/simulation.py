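"""Virtual-participant experiments.

Simulated responders draw Bernoulli responses from the response model at a
known true ability, so whole adaptive sessions can be replayed in silico.
The reliability experiment mirrors the validation design: a cohort of
virtual participants (abilities drawn from the standard normal, or
empirical estimates up-sampled by a replication factor) takes the adaptive
test twice, and for each test length k the weighted-likelihood estimate and
its standard error are recomputed from the first k responses.  The outputs
are the mean-SE-versus-length curve and the between-session test-retest
Pearson correlation, with bootstrap confidence bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .adaptive import SessionConfig, interim_wl_curve, run_session
from .item_bank import DifficultyCoefficients, ItemBank, ItemSpec
from .model_core import ResponseModelParams, prob_correct_cabat

__all__ = [
    "VirtualCohort",
    "ReliabilityCurve",
    "simulate_responder",
    "upsample_cohort",
    "reliability_experiment",
]


@dataclass(frozen=True)
class VirtualCohort:
    abilities: tuple[float, ...]
    provenance: str = "unspecified"
    seed: int | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.abilities, dtype=float)
        if arr.size == 0:
            raise ValueError("cohort must be nonempty")
        if not np.isfinite(arr).all():
            raise ValueError("abilities must be finite")

    @classmethod
    def standard_normal(cls, n: int, seed: int | None = 0) -> "VirtualCohort":
        rng = np.random.default_rng(seed)
        return cls(tuple(rng.standard_normal(n)), provenance="sampled N(0,1)", seed=seed)


def simulate_responder(
    true_theta: float,
    coefficients: DifficultyCoefficients,
    rng: np.random.Generator,
) -> Callable[[ItemSpec], int]:
    """A responder answering each item with the model-implied probability."""
    a = coefficients.discrimination

    def responder(item: ItemSpec) -> int:
        p = float(prob_correct_cabat(true_theta, item.difficulty, a))
        return int(rng.random() < p)

    return responder


def upsample_cohort(abilities: Sequence[float], factor: int = 250) -> VirtualCohort:
    """Replicate each ability ``factor`` times (e.g. 52 estimates x 250)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    reps = tuple(float(a) for a in abilities for _ in range(factor))
    return VirtualCohort(reps, provenance=f"up-sampled x{factor}")


@dataclass
class ReliabilityCurve:
    lengths: list[int]
    mean_se: dict[int, float]
    se_band: dict[int, tuple[float, float]]
    retest_r: dict[int, float]
    r_band: dict[int, tuple[float, float]]
    theta_estimates: dict[int, np.ndarray] = field(default_factory=dict, repr=False)
    se_values: dict[int, np.ndarray] = field(default_factory=dict, repr=False)
    degenerate: bool = False


def _bootstrap_band(values: np.ndarray, stat: Callable[[np.ndarray], float],
                    rng: np.random.Generator, n_boot: int, axis_n: int) -> tuple[float, float]:
    reps = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, axis_n, size=axis_n)
        reps[i] = stat(idx)
    return float(np.percentile(reps, 2.5)), float(np.percentile(reps, 97.5))


def reliability_experiment(
    cohort: VirtualCohort,
    bank: ItemBank,
    config: SessionConfig = SessionConfig(),
    n_sessions: int = 2,
    lengths: Sequence[int] | None = None,
    master_seed: int = 0,
    n_bootstrap: int = 1000,
) -> ReliabilityCurve:
    """Simulated test-retest experiment over an adaptive item bank.

    Each participant takes ``n_sessions`` independent adaptive sessions
    (independent response draws, item tie-breaks and stimulus orders, all
    derived deterministically from ``master_seed``).  For each requested
    test length k, the weighted-likelihood estimate and SE are recomputed
    from the first k responses of every session; the curve reports the mean
    SE and the Pearson correlation between the first two sessions'
    estimates, with percentile-bootstrap confidence bands over
    participants.
    """
    if lengths is None:
        lengths = list(range(1, config.test_length + 1))
    lengths = sorted(set(int(k) for k in lengths))
    if lengths[0] < 1 or lengths[-1] > config.test_length:
        raise ValueError("lengths must lie within 1..test_length")
    params = ResponseModelParams(discrimination=bank.coefficients.discrimination)
    n = len(cohort.abilities)
    ss = np.random.SeedSequence(master_seed)
    child_seqs = ss.spawn(n * n_sessions)
    theta_by_k = {k: np.empty((n, n_sessions)) for k in lengths}
    se_by_k = {k: np.empty((n, n_sessions)) for k in lengths}
    for p_idx, theta in enumerate(cohort.abilities):
        for s_idx in range(n_sessions):
            seq = child_seqs[p_idx * n_sessions + s_idx]
            resp_rng = np.random.default_rng(seq)
            session_seed = int(seq.generate_state(1, np.uint32)[0])
            responder = simulate_responder(theta, bank.coefficients, resp_rng)
            cfg = SessionConfig(
                test_length=config.test_length,
                first_item_difficulty_target=config.first_item_difficulty_target,
                randomesque_set_size=config.randomesque_set_size,
                prior_mean=config.prior_mean,
                prior_sd=config.prior_sd,
                seed=session_seed,
            )
            result = run_session(bank, responder, cfg)
            curve = interim_wl_curve(result, params, lengths)
            for k, est in curve.items():
                theta_by_k[k][p_idx, s_idx] = est.theta_hat
                se_by_k[k][p_idx, s_idx] = est.standard_error

    rng = np.random.default_rng(np.random.SeedSequence(master_seed).spawn(n * n_sessions + 1)[-1])
    mean_se, se_band, retest_r, r_band = {}, {}, {}, {}
    degenerate = False
    for k in lengths:
        ses = se_by_k[k]
        mean_se[k] = float(ses.mean())
        se_band[k] = _bootstrap_band(
            ses, lambda idx: float(ses[idx].mean()), rng, n_bootstrap, n
        )
        if n_sessions >= 2:
            t1, t2 = theta_by_k[k][:, 0], theta_by_k[k][:, 1]
            if np.std(t1) == 0 or np.std(t2) == 0:
                retest_r[k] = float("nan")
                r_band[k] = (float("nan"), float("nan"))
                degenerate = True
            else:
                retest_r[k] = float(np.corrcoef(t1, t2)[0, 1])

                def r_stat(idx, t1=t1, t2=t2):
                    if np.std(t1[idx]) == 0 or np.std(t2[idx]) == 0:
                        return float("nan")
                    return float(np.corrcoef(t1[idx], t2[idx])[0, 1])

                r_band[k] = _bootstrap_band(theta_by_k[k], r_stat, rng, n_bootstrap, n)
    return ReliabilityCurve(
        lengths=lengths,
        mean_se=mean_se,
        se_band=se_band,
        retest_r=retest_r,
        r_band=r_band,
        theta_estimates=theta_by_k,
        se_values=se_by_k,
        degenerate=degenerate,
    )
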