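"""Reference behavioral statistics for the three sensory-environment paradigms.

Grand means (across sessions) of the observed behavior of head-fixed rats in
a whisker-based Go/No-go discrimination task, indexed by the fraction of Go
(S+) trials in a session.  These numbers parameterize the synthetic-session
generator and serve as comparison points for the reward-rate optimization;
they are measured quantities, not outputs of this package.
"""

#: The three Go-stimulus fractions, ordered from most to least Go-rich.
GO_FRACTIONS: tuple[float, float, float] = (0.8, 0.5, 0.2)

#: Grand-mean hit rate per paradigm.
OBSERVED_HIT_RATE: dict[float, float] = {0.8: 0.8574, 0.5: 0.723, 0.2: 0.552}

#: Grand-mean false-alarm rate per paradigm.
OBSERVED_FA_RATE: dict[float, float] = {0.8: 0.7622, 0.5: 0.578, 0.2: 0.398}

#: Grand-mean perceptual sensitivity d' per paradigm (session-wise mean,
#: which is not the d' of the grand-mean rates).
OBSERVED_D_PRIME: dict[float, float] = {0.8: 0.536, 0.5: 0.510, 0.2: 0.518}

#: Grand-mean decision criterion c per paradigm (full 260-session cohort).
OBSERVED_CRITERION: dict[float, float] = {0.8: -1.139, 0.5: -0.483, 0.2: 0.045}

#: Criterion grand means from the subset of sessions entering the
#: optimality comparison; differ from OBSERVED_CRITERION in the third decimal.
OBSERVED_CRITERION_VS_OPTIMAL: dict[float, float] = {
    0.8: -1.137, 0.5: -0.479, 0.2: 0.0636,
}

#: Grand-mean reaction time (s) per paradigm, hit and false-alarm trials only.
OBSERVED_MEAN_RT: dict[float, float] = {0.8: 0.4838, 0.5: 0.594, 0.2: 0.702}

#: Grand-mean fraction of trials with an impulsive (pre-stimulus) lick.
OBSERVED_IMPULSIVE_RATE: dict[float, float] = {0.8: 0.174, 0.5: 0.134, 0.2: 0.062}

#: Mean perceptual sensitivity across the three paradigms; the evidence-mean
#: of the simulated observer in the reward-rate optimization.
MEAN_SENSITIVITY: float = 0.52


def mean_observed_d_prime() -> float:
    """Average of the three per-paradigm grand-mean d' values."""
    return sum(OBSERVED_D_PRIME.values()) / len(OBSERVED_D_PRIME)
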