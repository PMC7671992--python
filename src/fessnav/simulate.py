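"""Synthetic FESS navigation workflow generator.

No clinical recordings ship with this package, so downstream stages are
exercised on simulated workflows that reproduce the aggregate structure of
annotated FESS data: about 22 procedures with a mean of ~167 navigation
steps, 6-16 unique landmark combinations per procedure, and a heavily
imbalanced landmark marginal distribution centred on the middle nasal
concha (visible in roughly half of all states).

The generator is a first-order Markov chain over landmark-combination
states with zero self-transition probability (consecutive identical
combinations would be merged into one state, so a transition always means a
new combination visit).  The transition matrix is calibrated so that the
chain's stationary distribution, accumulated per landmark, matches the
target observation fractions.  Dwell times are log-normal; they decorate
states but carry no information used by the predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .ontology import (
    NavigationState,
    SpatialOntology,
    default_ontology,
    infer_direction,
    validate_workflow,
)
from .workflow_io import NavigationWorkflow

__all__ = [
    "SimulatorConfig",
    "default_config",
    "default_state_table",
    "simulate_workflow",
    "simulate_corpus",
    "landmark_marginals",
]

# Combination states with target stationary probabilities.  Accumulated per
# landmark these give fractions close to the annotated-data distribution:
# middle_nasal_concha 0.505, middle_nasal_meatus 0.287,
# maxillary_sinus_orifice 0.20, out_of_patient 0.17,
# uncinate_process_of_ethmoid 0.06, ethmoidal_bulla 0.04,
# spheno_ethmoidal_recess 0.013.  The probabilities sum to 1, which a
# combination-state chain requires; the small excesses over the annotated
# fractions (sum 1.20) absorb that normalization.
_DEFAULT_STATES: list[tuple[tuple[str, ...], float]] = [
    (("out_of_patient",), 0.170),
    (("middle_nasal_concha",), 0.230),
    (("middle_nasal_meatus",), 0.157),
    (("maxillary_sinus_orifice",), 0.130),
    (("uncinate_process_of_ethmoid",), 0.015),
    (("ethmoidal_bulla",), 0.015),
    (("spheno_ethmoidal_recess",), 0.008),
    (("middle_nasal_concha", "middle_nasal_meatus"), 0.130),
    (("maxillary_sinus_orifice", "middle_nasal_concha"), 0.070),
    (("middle_nasal_concha", "uncinate_process_of_ethmoid"), 0.045),
    (("ethmoidal_bulla", "middle_nasal_concha"), 0.025),
    (("middle_nasal_concha", "spheno_ethmoidal_recess"), 0.005),
]


@dataclass
class SimulatorConfig:
    """Parameters of the semi-Markov workflow simulator.

    Attributes
    ----------
    states : list of landmark-name tuples
        The combination states of the chain.
    transition_matrix : (C, C) row-stochastic array
        Zero diagonal; row i is the distribution of the next combination.
    dwell_mu, dwell_sigma : float
        Log-normal dwell-time parameters (log-seconds); the default median
        exp(mu) is about 9 s, matching the reported mean landmark
        visibility duration band.
    excursion_prob : float
        Extra per-step probability of an out-of-patient excursion (lens
        cleaning) on top of the chain's own out-of-patient state.
    steps_mean, steps_sd : float
        Truncated-normal parameters of the per-workflow step count.
    steps_min, steps_max : int
        Truncation bounds of the step count.
    n_workflows : int
    seed : int
        Master seed; per-workflow seeds are derived by fixed offset.
    """

    states: list[tuple[str, ...]]
    transition_matrix: np.ndarray
    initial: np.ndarray
    dwell_mu: float = float(np.log(9.0))
    dwell_sigma: float = 0.5
    excursion_prob: float = 0.0
    steps_mean: float = 167.0
    steps_sd: float = 60.0
    steps_min: int = 20
    steps_max: int = 500
    n_workflows: int = 22
    seed: int = 0

    def validate(self) -> None:
        T = np.asarray(self.transition_matrix, dtype=float)
        C = len(self.states)
        if T.shape != (C, C):
            raise ValueError(f"transition matrix shape {T.shape}, expected {(C, C)}")
        if not np.allclose(T.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if (T < 0).any() or (T > 1).any():
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not 0.0 <= self.excursion_prob <= 1.0:
            raise ValueError("excursion_prob must lie in [0, 1]")
        if self.steps_min < 2:
            raise ValueError("workflows need at least 2 steps")


def default_state_table() -> tuple[list[tuple[str, ...]], np.ndarray]:
    states = [tuple(s) for s, _ in _DEFAULT_STATES]
    pi = np.array([p for _, p in _DEFAULT_STATES], dtype=float)
    return states, pi / pi.sum()


def _stationary(T: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (power iteration)."""
    pi = np.full(T.shape[0], 1.0 / T.shape[0])
    for _ in range(10_000):
        nxt = pi @ T
        if np.max(np.abs(nxt - pi)) < 1e-13:
            return nxt / nxt.sum()
        pi = nxt
    return pi / pi.sum()


def _calibrate_transitions(target_pi: np.ndarray, n_iter: int = 200) -> np.ndarray:
    """Zero-diagonal row-stochastic matrix with stationary ~= target_pi.

    Row i is proportional to q restricted to j != i; q is adjusted by
    fixed-point iteration until the stationary distribution matches the
    target (max abs error typically < 1e-10).
    """
    q = target_pi.copy()
    C = len(q)
    T = np.zeros((C, C))
    for _ in range(n_iter):
        T = np.tile(q, (C, 1))
        np.fill_diagonal(T, 0.0)
        T /= T.sum(axis=1, keepdims=True)
        s = _stationary(T)
        q = q * (target_pi / np.maximum(s, 1e-15))
        q = np.clip(q, 1e-12, None)
        q /= q.sum()
    return T


def default_config(seed: int = 0, n_workflows: int = 22) -> SimulatorConfig:
    """Simulator configuration calibrated to the annotated-data statistics."""
    states, pi = default_state_table()
    T = _calibrate_transitions(pi)
    cfg = SimulatorConfig(
        states=states,
        transition_matrix=T,
        initial=pi.copy(),
        n_workflows=n_workflows,
        seed=seed,
    )
    cfg.validate()
    return cfg


def landmark_marginals(
    states: list[tuple[str, ...]], pi: np.ndarray
) -> dict[str, float]:
    """Accumulated per-landmark fractions implied by state probabilities."""
    out: dict[str, float] = {}
    for combo, p in zip(states, pi):
        for name in combo:
            out[name] = out.get(name, 0.0) + float(p)
    return out


def _workflow_seed(master: int, index: int) -> int:
    return (int(master) + 7919 * (index + 1)) % (2**31 - 1)


def simulate_workflow(
    config: SimulatorConfig,
    seed: int,
    workflow_id: str = "sim",
    ontology: SpatialOntology | None = None,
) -> NavigationWorkflow:
    """Draw one navigation workflow from the configured chain.

    Identical seeds give identical workflows.  The returned workflow passes
    structural validation: step counts 1..n, directions consistent with the
    depth-rank ontology, non-decreasing times.
    """
    config.validate()
    ont = ontology or default_ontology()
    rng = np.random.default_rng(seed)
    C = len(config.states)
    reachable = (config.initial > 0) | (config.transition_matrix.sum(axis=0) > 0)
    if not reachable.all():
        bad = [config.states[i] for i in np.flatnonzero(~reachable)]
        raise ValueError(f"unreachable states: {bad}")

    lo = (config.steps_min - config.steps_mean) / config.steps_sd
    hi = (config.steps_max - config.steps_mean) / config.steps_sd
    n_steps = int(
        round(
            stats.truncnorm.rvs(
                lo, hi, loc=config.steps_mean, scale=config.steps_sd,
                random_state=rng,
            )
        )
    )
    try:
        out_idx = config.states.index(("out_of_patient",))
    except ValueError:
        out_idx = -1

    idx = int(rng.choice(C, p=config.initial))
    seq = [idx]
    if C == 1:  # degenerate chain: the single state repeats (all dwell)
        seq = [idx] * n_steps
    while len(seq) < n_steps:
        if (
            config.excursion_prob > 0
            and out_idx >= 0
            and seq[-1] != out_idx
            and rng.random() < config.excursion_prob
        ):
            nxt = out_idx
        else:
            nxt = int(rng.choice(C, p=config.transition_matrix[seq[-1]]))
        if nxt == seq[-1]:  # merged visits never repeat a combination
            continue
        seq.append(nxt)

    t = 0.0
    states: list[NavigationState] = []
    prev: frozenset[str] | None = None
    for step, s_idx in enumerate(seq, start=1):
        combo = frozenset(config.states[s_idx])
        dwell = float(rng.lognormal(config.dwell_mu, config.dwell_sigma))
        rep = ont.representative(combo)
        states.append(
            NavigationState(
                step_count=step,
                cavity=rep.cavity,
                landmark_group=rep.group,
                landmark_combination=combo,
                direction=infer_direction(prev, combo, ont),
                start_s=t,
                end_s=t + dwell,
            )
        )
        prev = combo
        t += dwell
    wf = NavigationWorkflow(workflow_id, states)
    problems = validate_workflow(wf.states, ont)
    if problems:  # pragma: no cover - generator invariant
        raise AssertionError(f"simulated workflow invalid: {problems}")
    return wf


def simulate_corpus(
    config: SimulatorConfig, ontology: SpatialOntology | None = None
) -> tuple[list[NavigationWorkflow], dict]:
    """Simulate ``config.n_workflows`` workflows plus a manifest.

    The manifest records each workflow's derived seed and the corpus summary
    statistics (computed by :func:`fessnav.evaluation.corpus_statistics`, the
    single source of truth for those numbers).
    """
    from .evaluation import corpus_statistics

    ont = ontology or default_ontology()
    workflows = [
        simulate_workflow(
            config, _workflow_seed(config.seed, i), workflow_id=f"wf{i:02d}",
            ontology=ont,
        )
        for i in range(config.n_workflows)
    ]
    summary = corpus_statistics(workflows)
    manifest = {
        "seed": config.seed,
        "workflow_seeds": {
            wf.workflow_id: _workflow_seed(config.seed, i)
            for i, wf in enumerate(workflows)
        },
        "statistics": summary.to_dict(),
    }
    return workflows, manifest
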