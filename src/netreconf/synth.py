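"""Seeded synthetic fMRI-like cohort generator.

Emulates the statistical structure the reconfiguration analysis assumes:
multi-subject cohorts with paired rest/task runs in two phase encodings
(LR/RL), planted modular correlation structure whose integration level
differs between states, a ground-truth set of "activated" ROIs whose
task-state signal is locked to a haemodynamic task regressor, plus
low-frequency drift and motion-like nuisance signals.

The signal model for ROI ``i`` in community ``c`` is a latent-factor
construction::

    x_i(t) = a * f_c(t) + b * g(t) + s * eps_i(t)  (+ task, drift, nuisance)

with ``f_c`` a per-community factor, ``g`` a global factor and ``eps_i``
node noise, all unit-variance white Gaussian.  Given target within- and
between-community correlations ``w`` and ``v`` and noise scale ``s``, the
loadings are solved exactly: ``b^2 = v*V``, ``a^2 = (w - v)*V`` with
``V = s^2 / (1 - w)``, so the population correlation of two nodes is ``w``
within a community and ``v`` across communities regardless of ``s``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ConfoundSet, Parcellation, RunSeries

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "Cohort",
    "double_gamma_hrf",
    "make_task_regressor",
    "gen_parcellation",
    "gen_confounds",
    "gen_run",
    "gen_cohort",
]


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults are scaled-down analogues of a resting/task fMRI cohort:
    the task state is both more internally correlated and markedly more
    integrated across communities than rest, which at a fixed network
    density yields the task-state increase in global efficiency and
    decrease in modularity seen empirically in rest-to-task transitions.
    """

    n_subjects: int = 20
    n_roi: int = 60
    n_subnetworks: int = 6
    n_timepoints: int = 400
    tr: float = 0.72
    states: tuple[str, ...] = ("rest", "task")
    encodings: tuple[str, ...] = ("LR", "RL")
    within_corr_rest: float = 0.60
    between_corr_rest: float = 0.02
    within_corr_task: float = 0.65
    between_corr_task: float = 0.30
    act_fraction: float = 0.3
    task_amplitude: float = 2.0
    noise_sd: float = 1.0
    drift_amp: float = 1.0
    corr_jitter: float = 0.12
    seed: int = 0

    def validate(self) -> None:
        errors = []
        for name in ("n_subjects", "n_roi", "n_subnetworks", "n_timepoints"):
            if getattr(self, name) < 1:
                errors.append(f"{name} must be >= 1")
        if self.tr <= 0:
            errors.append("tr must be positive")
        if self.n_subnetworks > self.n_roi:
            errors.append("n_subnetworks cannot exceed n_roi")
        if not self.states or "rest" not in self.states:
            errors.append("states must contain 'rest'")
        if len(self.states) < 2:
            errors.append("states must contain at least one task besides rest")
        if not self.encodings:
            errors.append("at least one encoding is required")
        for tag in ("rest", "task"):
            w = getattr(self, f"within_corr_{tag}")
            v = getattr(self, f"between_corr_{tag}")
            if not (0 <= v < w < 1):
                errors.append(
                    f"need 0 <= between_corr_{tag} < within_corr_{tag} < 1"
                )
        if not (0 < self.act_fraction < 1):
            errors.append("act_fraction must lie in (0, 1)")
        if self.noise_sd < 0 or self.drift_amp < 0 or self.corr_jitter < 0:
            errors.append("noise_sd, drift_amp, corr_jitter must be >= 0")
        if errors:
            raise ValueError("invalid cohort spec: " + "; ".join(errors))

    @property
    def tasks(self) -> tuple[str, ...]:
        return tuple(s for s in self.states if s != "rest")

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(f"sub-{i:03d}" for i in range(self.n_subjects))


@dataclass
class GroundTruth:
    """Planted structure shared by all subjects of a cohort."""

    communities: dict[str, np.ndarray]
    act_mask: dict[str, np.ndarray]
    task_regressors: dict[str, np.ndarray]


@dataclass
class Cohort:
    """A generated cohort: runs, nuisance tables and the planted truth."""

    spec: CohortSpec
    parcellation: Parcellation
    truth: GroundTruth
    runs: list[RunSeries]
    confounds: dict[tuple[str, str, str], ConfoundSet]
    covariates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def run(self, subject: str, state: str, encoding: str) -> RunSeries:
        for r in self.runs:
            if (r.subject, r.state, r.encoding) == (subject, state, encoding):
                return r
        raise KeyError(f"no run for ({subject}, {state}, {encoding})")


def double_gamma_hrf(tr: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled at ``tr``.

    Standard published shape parameters: response peak 6 s, undershoot
    peak 16 s, undershoot ratio 1/6; peak-normalised to 1.
    """
    t = np.arange(0, duration, tr)
    peak = stats.gamma.pdf(t, a=6, scale=1.0)
    undershoot = stats.gamma.pdf(t, a=16, scale=1.0)
    h = peak - undershoot / 6.0
    return h / h.max()


def make_task_regressor(
    n_timepoints: int, tr: float, block_s: float = 20.0
) -> np.ndarray:
    """Boxcar block design (block_s on / block_s off) convolved with the HRF.

    The default 20 s blocks put the task fundamental near 0.025 Hz, inside
    the 0.009-0.08 Hz analysis band, so the task signal survives band-pass
    filtering.  Peak-normalised to 1.
    """
    t = np.arange(n_timepoints) * tr
    boxcar = (np.mod(t, 2 * block_s) < block_s).astype(float)
    reg = np.convolve(boxcar, double_gamma_hrf(tr))[:n_timepoints]
    return reg / np.abs(reg).max()


def gen_parcellation(
    n_roi: int, n_subnetworks: int, seed: int, n_excluded: int = 0
) -> Parcellation:
    """Random balanced assignment of ROIs to labelled subnetworks.

    ``n_excluded`` subnetworks (the last ones by label) are flagged as not
    included in subnetwork-level summaries, mirroring the convention of
    dropping subnetworks without a determined functional role.
    """
    if n_subnetworks > n_roi:
        raise ValueError("n_subnetworks cannot exceed n_roi")
    if not (0 <= n_excluded < n_subnetworks):
        raise ValueError("n_excluded must be in [0, n_subnetworks)")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    # balanced sizes, then shuffled node order
    base = np.repeat(np.arange(n_subnetworks), n_roi // n_subnetworks)
    extra = rng.choice(n_subnetworks, size=n_roi - base.size, replace=False)
    codes = np.concatenate([base, extra])
    rng.shuffle(codes)
    labels = np.array([f"SN{c + 1:02d}" for c in codes])
    excluded_codes = set(range(n_subnetworks - n_excluded, n_subnetworks))
    included = np.array([c not in excluded_codes for c in codes])
    return Parcellation(subnetwork=labels, included=included)


def _run_seed(spec: CohortSpec, subject: str, state: str, encoding: str):
    subj_idx = spec.subjects.index(subject)
    if state not in spec.states:
        raise ValueError(f"unknown state {state!r}; spec states: {spec.states}")
    if encoding not in spec.encodings:
        raise ValueError(
            f"unknown encoding {encoding!r}; spec encodings: {spec.encodings}"
        )
    return (
        subj_idx,
        spec.states.index(state),
        spec.encodings.index(encoding),
    )


def gen_confounds(
    spec: CohortSpec, subject: str, state: str, encoding: str
) -> ConfoundSet:
    """Motion-like nuisance table: 6 AR(1) series + 2 tissue-mean series."""
    subj_idx, state_idx, enc_idx = _run_seed(spec, subject, state, encoding)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), 23, subj_idx, state_idx, enc_idx])
    )
    t = spec.n_timepoints
    cols = np.empty((t, 8))
    for c in range(8):
        phi = 0.95 if c < 6 else 0.8
        e = rng.normal(size=t)
        x = np.empty(t)
        x[0] = e[0]
        for k in range(1, t):
            x[k] = phi * x[k - 1] + np.sqrt(1 - phi**2) * e[k]
        cols[:, c] = x
    names = [f"motion{i + 1}" for i in range(6)] + ["wm_mean", "csf_mean"]
    return ConfoundSet(columns=cols, names=names)


def _state_corr_targets(
    spec: CohortSpec, subject: str, state: str
) -> tuple[float, float]:
    """Within/between correlation targets, with per-subject jitter.

    The between-community target is jittered per (subject, state) to model
    stable inter-individual differences in network integration; the jitter
    is shared across encodings of the same run pair.
    """
    tag = "rest" if state == "rest" else "task"
    within = getattr(spec, f"within_corr_{tag}")
    between = getattr(spec, f"between_corr_{tag}")
    if spec.corr_jitter > 0:
        subj_idx = spec.subjects.index(subject)
        state_idx = spec.states.index(state)
        rng = np.random.default_rng(
            np.random.SeedSequence([int(spec.seed), 37, subj_idx, state_idx])
        )
        # one latent integration trait per subject and state: more integrated
        # individuals have higher between- and lower within-community
        # coupling, so the trait moves segregation and integration together
        u = rng.uniform(-1.0, 1.0)
        between = float(np.clip(between + spec.corr_jitter * u, 0.0, 0.95))
        within = float(np.clip(within - 0.5 * spec.corr_jitter * u, 0.05, 0.97))
        between = min(between, within - 0.02)
    return within, between


def gen_run(
    spec: CohortSpec,
    subject: str,
    state: str,
    encoding: str,
    truth: GroundTruth,
) -> RunSeries:
    """Generate one run's T x N matrix; reproducible from its coordinates."""
    subj_idx, state_idx, enc_idx = _run_seed(spec, subject, state, encoding)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(spec.seed), 41, subj_idx, state_idx, enc_idx])
    )
    t, n = spec.n_timepoints, spec.n_roi
    comm = truth.communities[state]
    within, between = _state_corr_targets(spec, subject, state)

    s = spec.noise_sd
    v_tot = s**2 / (1.0 - within) if s > 0 else 1.0
    b = np.sqrt(between * v_tot)
    a = np.sqrt((within - between) * v_tot)

    global_factor = rng.normal(size=t)
    factors = rng.normal(size=(t, comm.max() + 1))
    noise = rng.normal(size=(t, n))
    data = a * factors[:, comm] + b * global_factor[:, None] + s * noise

    # low-frequency drift: cosines at least an octave below the 0.009 Hz
    # analysis band edge, so band-pass filtering demonstrably removes them;
    # phases are drawn unconditionally to keep the RNG stream independent
    # of drift_amp
    time = np.arange(t) * spec.tr
    for f in (0.002, 0.003, 0.004):
        phase = rng.uniform(0, 2 * np.pi, size=n)
        if spec.drift_amp > 0:
            data += spec.drift_amp * np.cos(2 * np.pi * f * time[:, None] + phase)

    # small nuisance leakage so confound regression has something to remove
    conf = gen_confounds(spec, subject, state, encoding)
    loadings = rng.normal(scale=0.1, size=(conf.n_columns, n))
    data += conf.columns @ loadings

    if state != "rest":
        reg = truth.task_regressors[state]
        mask = truth.act_mask[state]
        data[:, mask] += spec.task_amplitude * reg[:, None]

    return RunSeries(
        data=data, tr=spec.tr, subject=subject, state=state, encoding=encoding
    )


def _make_truth(spec: CohortSpec, parcellation: Parcellation) -> GroundTruth:
    comm = parcellation.integer_labels()
    communities = {state: comm.copy() for state in spec.states}
    n_act = int(round(spec.act_fraction * spec.n_roi))
    act_mask: dict[str, np.ndarray] = {}
    regs: dict[str, np.ndarray] = {}
    for k, task in enumerate(spec.tasks):
        rng = np.random.default_rng(
            np.random.SeedSequence([int(spec.seed), 53, k])
        )
        # task activation concentrates in task-relevant subnetworks: fill the
        # mask community by community (seeded order) up to the target size,
        # so Act/L-Act interactions are dominated by between-community edges
        mask = np.zeros(spec.n_roi, dtype=bool)
        remaining = n_act
        for c in rng.permutation(comm.max() + 1):
            members = np.flatnonzero(comm == c)
            if remaining >= members.size:
                mask[members] = True
                remaining -= members.size
            else:
                mask[rng.choice(members, size=remaining, replace=False)] = True
                remaining = 0
            if remaining == 0:
                break
        act_mask[task] = mask
        regs[task] = make_task_regressor(spec.n_timepoints, spec.tr)
    return GroundTruth(
        communities=communities, act_mask=act_mask, task_regressors=regs
    )


def gen_cohort(spec: CohortSpec) -> Cohort:
    """Generate every subject x state x encoding run plus shared truth."""
    spec.validate()
    parcellation = gen_parcellation(
        spec.n_roi, spec.n_subnetworks, seed=spec.seed
    )
    truth = _make_truth(spec, parcellation)
    runs: list[RunSeries] = []
    confounds: dict[tuple[str, str, str], ConfoundSet] = {}
    for subject in spec.subjects:
        for state in spec.states:
            for encoding in spec.encodings:
                runs.append(gen_run(spec, subject, state, encoding, truth))
                confounds[(subject, state, encoding)] = gen_confounds(
                    spec, subject, state, encoding
                )
    cov_rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 61]))
    covariates = pd.DataFrame(
        {
            "subject": list(spec.subjects),
            "sex": cov_rng.integers(0, 2, size=spec.n_subjects),
            "age": np.round(cov_rng.normal(29.1, 3.5, size=spec.n_subjects), 1),
        }
    )
    return Cohort(
        spec=spec,
        parcellation=parcellation,
        truth=truth,
        runs=runs,
        confounds=confounds,
        covariates=covariates,
    )
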