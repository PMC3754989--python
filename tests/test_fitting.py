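"""Likelihood replay, grid search, tie-breaking, and parameter recovery.

The reference oracle here is an independent pure-Python replay of the
model (its own softmax, update rule, and quadruple parameter loop),
written without reference to the package's vectorized evaluator.
"""

import math

import numpy as np
import pytest

from gainloss import (
    AgentParams,
    GridSpec,
    TaskConfig,
    build_session,
    grid_fit,
    recovery_experiment,
    session_log_likelihood,
    simulate_agent,
    uniform_grid_sampler,
)
from gainloss.fitting import SessionDataError, grid_log_likelihoods

LOG_HALF = math.log(0.5)


# --- independent oracle -----------------------------------------------------

def oracle_loglik(session, alpha_gain, alpha_loss, beta, r0):
    """Trial-by-trial replay with its own arithmetic (no package calls)."""
    stimuli = list(session.config.stimuli)
    q = {(resp, s): 0.0 for resp in "AB" for s in stimuli}
    total = 0.0
    for rec in session.records:
        s = rec.trial.stimulus
        d = q[("A", s)] - q[("B", s)]
        if beta == 0.0:
            p_a = 1.0 if d > 0 else (0.0 if d < 0 else 0.5)
        else:
            p_a = 1.0 / (1.0 + math.exp(-d / beta))
        p = p_a if rec.response == "A" else 1.0 - p_a
        if p == 0.0:
            return float("-inf")
        total += math.log(p)
        r = {"reward": 1.0, "punishment": -1.0, "none": r0}[rec.feedback]
        pe = r - q[(rec.response, s)]
        rate = alpha_gain if pe > 0 else alpha_loss
        if pe != 0:
            q[(rec.response, s)] += rate * pe
    return total


def oracle_grid_fit(session, grid):
    """Naive quadruple loop in ascending lexicographic order."""
    best, best_ll = None, -math.inf
    for ag in grid.alpha_gain:
        for al in grid.alpha_loss:
            for b in grid.beta:
                for r0 in grid.r0:
                    ll = oracle_loglik(session, ag, al, b, r0)
                    if ll > best_ll:
                        best, best_ll = (ag, al, b, r0), ll
    return best, best_ll


# --- log-likelihood ---------------------------------------------------------

class TestSessionLogLikelihood:
    @pytest.mark.parametrize("beta,r0", [(0.5, 0.0), (0.1, 0.8), (1.0, -0.5)])
    def test_non_learning_closed_form(self, played_session, beta, r0):
        """With both learning rates 0 the expectancies never move, every
        response has probability 0.5, and the LLE is 160 ln(1/2)."""
        params = AgentParams(0.0, 0.0, beta, r0)
        lle = session_log_likelihood(played_session, params)
        assert lle == pytest.approx(160 * LOG_HALF, abs=1e-9)

    def test_certain_response_contributes_zero(self, config):
        """A trial whose response the model deems certain adds ln(1) = 0;
        one the greedy model deems impossible sinks the LLE to -inf."""
        from gainloss.task import Session, Trial, play_session

        trials = (
            Trial(0, 0, "S1", "reward", "A", "A"),
            Trial(1, 0, "S1", "reward", "A", "A"),
        )
        schedule = Session("x", config, trials)
        params = AgentParams(0.5, 0.5, 0.0, 0.0)
        # first trial: tied expectancies, p=0.5; reward pushes Q[A,S1] up,
        # so the second A is certain under beta=0 and contributes 0
        consistent = play_session(schedule, ["A", "A"])
        assert session_log_likelihood(consistent, params) == pytest.approx(
            LOG_HALF, abs=1e-12
        )
        inconsistent = play_session(schedule, ["A", "B"])
        assert session_log_likelihood(inconsistent, params) == -math.inf

    def test_lle_is_nonpositive(self, played_session):
        rng = np.random.default_rng(0)
        for _ in range(10):
            params = AgentParams(*rng.uniform(0, 1, 3), rng.uniform(-1, 1))
            assert session_log_likelihood(played_session, params) <= 0.0

    def test_incomplete_session_rejected(self, schedule):
        with pytest.raises(SessionDataError):
            session_log_likelihood(schedule, AgentParams(0.1, 0.1, 0.5, 0.0))

    def test_reorder_invariance_only_without_learning(self, played_session):
        reordered = played_session.with_records(played_session.records[::-1])
        flat = AgentParams(0.0, 0.0, 0.4, 0.2)
        learning = AgentParams(0.4, 0.3, 0.4, 0.2)
        assert session_log_likelihood(reordered, flat) == pytest.approx(
            session_log_likelihood(played_session, flat), abs=1e-9
        )
        assert session_log_likelihood(reordered, learning) != pytest.approx(
            session_log_likelihood(played_session, learning), abs=1e-6
        )


class TestGridEvaluation:
    def test_default_grid_cardinality(self):
        assert GridSpec.default().cardinality == 21**4

    def test_vectorized_matches_naive_replay(self, played_session):
        grid = GridSpec.default()
        lls = grid_log_likelihoods(played_session, grid)
        rng = np.random.default_rng(1)
        for _ in range(12):
            ia, il, ib, ir = rng.integers([21, 21, 21, 21])
            params = AgentParams(
                float(grid.alpha_gain[ia]), float(grid.alpha_loss[il]),
                float(grid.beta[ib]), float(grid.r0[ir]),
            )
            naive = session_log_likelihood(played_session, params)
            assert lls[ia, il, ib, ir] == pytest.approx(naive, abs=1e-9)

    def test_grid_fit_matches_quadruple_loop_oracle(self, config):
        grid = GridSpec.from_steps(alpha_step=0.25, beta_step=0.25, r0_step=0.5)
        rng = np.random.default_rng(7)
        for i in range(5):
            params = AgentParams(*rng.uniform(0, 1, 3), rng.uniform(-1, 1))
            schedule = build_session(config, seed=100 + i)
            session = simulate_agent(schedule, params, seed=200 + i)
            expected_point, expected_ll = oracle_grid_fit(session, grid)
            result = grid_fit(session, grid)
            got = (
                result.best_params.alpha_gain, result.best_params.alpha_loss,
                result.best_params.beta, result.best_params.r0,
            )
            assert got == pytest.approx(expected_point, abs=1e-12)
            assert result.lle == pytest.approx(expected_ll, abs=1e-9)

    def test_fit_dominates_generating_parameters(self, config):
        grid = GridSpec.default()
        params = AgentParams(0.3, 0.2, 0.3, 0.5)  # grid-node parameters
        schedule = build_session(config, seed=21)
        session = simulate_agent(schedule, params, seed=22)
        result = grid_fit(session, grid)
        assert result.lle >= session_log_likelihood(session, params) - 1e-9

    def test_flat_likelihood_ties_break_lexicographically(self, played_session):
        # with both alphas pinned to 0 every (beta>0, r0) scores identically
        grid = GridSpec(
            alpha_gain=np.array([0.0]), alpha_loss=np.array([0.0]),
            beta=np.array([0.3, 0.6]), r0=np.array([-0.5, 0.0, 0.5]),
        )
        result = grid_fit(played_session, grid)
        assert result.n_ties == 6
        assert result.best_params.beta == 0.3
        assert result.best_params.r0 == -0.5
        assert result.lle == pytest.approx(160 * LOG_HALF, abs=1e-9)

    def test_empty_grid_rejected(self, played_session):
        with pytest.raises(ValueError):
            GridSpec(alpha_gain=np.array([]), alpha_loss=np.array([0.0]),
                     beta=np.array([0.5]), r0=np.array([0.0]))


class TestRecovery:
    def test_same_seed_same_report(self):
        grid = GridSpec.from_steps(0.25, 0.25, 0.5)
        sampler = uniform_grid_sampler(grid)
        a = recovery_experiment(sampler, n_agents=4, seed=3, grid=grid)
        b = recovery_experiment(sampler, n_agents=4, seed=3, grid=grid)
        assert a.table.equals(b.table)

    def test_r0_recovery_rank_correlation(self):
        """Recovered R0 tracks true R0 even on a coarsened grid."""
        grid = GridSpec.from_steps(0.25, 0.25, 0.25)
        report = recovery_experiment(
            uniform_grid_sampler(grid), n_agents=40, seed=11, grid=grid
        )
        rho = report.summary().loc["r0", "spearman_rho"]
        assert rho > 0.3
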