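"""Model/Results interface to the rest-to-task reconfiguration analysis.

:class:`NetworkReconfiguration` is built from ROI time-series runs plus a
parcellation (statsmodels-style); :meth:`NetworkReconfiguration.fit` runs the
full pipeline — preprocessing, Act/L-Act detection, connectivity network
construction, graph metrics, community statistics and group inference — and
returns a :class:`ReconfigurationResults` carrying the per-subject metric
table, node-level measures, partitions, test results and a ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import activation as act_mod
from . import connectome as conn_mod
from . import graphmetrics as gm
from . import groupstats as gs
from . import modularity as mod_mod
from . import preprocess as pp
from .config import PipelineConfig, validate_config
from .containers import ConfoundSet, Parcellation, RunSeries
from .synth import Cohort

__all__ = ["NetworkReconfiguration", "ReconfigurationResults"]

logger = logging.getLogger(__name__)

#: fractional-modularity variants reported per region mask
QF_VARIANTS = (
    ("both", "pair_count", "both_pairs"),
    ("at_least_one", "pair_count", "one_pairs"),
    ("both", "region_size", "both_size"),
    ("at_least_one", "region_size", "one_size"),
)


def _sub_seed(base: int, *idx: int) -> int:
    ss = np.random.SeedSequence([int(base), *[int(i) for i in idx]])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


@dataclass
class ReconfigurationResults:
    """Fitted pipeline outputs.

    Attributes
    ----------
    metrics : DataFrame
        Tidy per-subject table: subject, state, density, mask_task, metric,
        value.  Global metrics (E_global, Q, n_communities) carry an empty
        mask_task; region metrics (I, E_act, E_lact, Qf_*) are computed with
        a task's Act mask for both that task state and rest.
    node_pc : DataFrame
        Participation coefficient per subject, state, density and ROI.
    subnet_flex : DataFrame
        Mean node flexibility per included subnetwork, subject and task.
    tests : DataFrame
        Group-level inference: paired t, paired permutation, normality of
        paired differences, FDR-adjusted p, ANOVA on Act vs L-Act fractional
        modularity, and the adjusted dI-dE correlation.
    act_masks : dict
        Task -> boolean Act mask used for the region split.
    partitions : dict
        (subject, state, density) -> Partition from best-of-restarts Louvain.
    """

    config: PipelineConfig
    metrics: pd.DataFrame
    node_pc: pd.DataFrame
    flexibility: pd.DataFrame
    subnet_flex: pd.DataFrame
    tests: pd.DataFrame
    act_masks: dict[str, np.ndarray]
    partitions: dict[tuple[str, str, float], mod_mod.Partition]
    activation_maps: dict[str, act_mod.ActivationMap] = field(default_factory=dict)
    consensus: dict[tuple[str, float], mod_mod.Partition] = field(default_factory=dict)

    def metric_pivot(
        self, metric: str, density: float, mask_task: str = ""
    ) -> pd.DataFrame:
        """Wide subject x state table for one metric at one density."""
        sel = self.metrics[
            (self.metrics["metric"] == metric)
            & (self.metrics["density"] == density)
            & (self.metrics["mask_task"] == mask_task)
        ]
        return sel.pivot(index="subject", columns="state", values="value")

    def delta(self, metric: str, task: str, density: float) -> pd.Series:
        """Per-subject task-minus-rest change for one metric."""
        mask_task = "" if metric in ("E_global", "Q", "n_communities") else task
        wide = self.metric_pivot(metric, density, mask_task)
        return wide[task] - wide["rest"]

    def summary(self) -> str:
        """Human-readable report of state means and group tests."""
        lines = ["Rest-to-task network reconfiguration", "=" * 52]
        lines.append(
            f"subjects: {self.metrics['subject'].nunique()}   "
            f"densities: {sorted(self.metrics['density'].unique())}"
        )
        means = (
            self.metrics.groupby(["density", "state", "metric"])["value"]
            .mean()
            .unstack("state")
        )
        lines.append("\nState means (over subjects):")
        lines.append(means.round(4).to_string())
        if len(self.tests):
            cols = [
                c
                for c in (
                    "density", "task", "metric", "test", "statistic",
                    "p", "p_fdr", "n",
                )
                if c in self.tests.columns
            ]
            lines.append("\nGroup tests:")
            lines.append(self.tests[cols].round(6).to_string(index=False))
        return "\n".join(lines)

    def plot_efficiency(self, density: float | None = None, ax=None):
        """Box plot of global efficiency per state (one density)."""
        import matplotlib.pyplot as plt

        if density is None:
            density = sorted(self.metrics["density"].unique())[-1]
        wide = self.metric_pivot("E_global", density)
        if ax is None:
            _, ax = plt.subplots(figsize=(1.5 * wide.shape[1] + 2, 4))
        ax.boxplot([wide[c].dropna() for c in wide.columns], tick_labels=wide.columns)
        ax.set_ylabel("global efficiency")
        ax.set_title(f"Global efficiency by state (density {density:g})")
        return ax


class NetworkReconfiguration:
    """Rest-to-task reconfiguration model over a cohort of ROI runs.

    Parameters
    ----------
    runs : list of RunSeries
        One run per subject x state x encoding.
    parcellation : Parcellation
        ROI -> subnetwork table (defines PC modules and subnetwork averages).
    confounds : dict, optional
        (subject, state, encoding) -> ConfoundSet nuisance tables.
    task_regressors : dict, optional
        task -> length-T regressor; used for activation detection and for
        regressing the mean task activity out of task runs before
        connectivity.
    act_masks : dict, optional
        task -> boolean mask.  When given, activation detection is skipped
        and these masks define the Act/L-Act split.
    covariates : DataFrame, optional
        Per-subject ``subject``, ``sex``, ``age`` used as confounds in the
        adjusted correlations.
    config : PipelineConfig, optional
    """

    def __init__(
        self,
        runs: list[RunSeries],
        parcellation: Parcellation,
        confounds: dict[tuple[str, str, str], ConfoundSet] | None = None,
        task_regressors: dict[str, np.ndarray] | None = None,
        act_masks: dict[str, np.ndarray] | None = None,
        covariates: pd.DataFrame | None = None,
        config: PipelineConfig | None = None,
    ) -> None:
        self.runs = list(runs)
        self.parcellation = parcellation
        self.confounds = confounds or {}
        self.task_regressors = task_regressors or {}
        self.act_masks = act_masks
        self.covariates = covariates
        self.config = config or PipelineConfig()
        errors = validate_config(self.config)
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))
        self.subjects = sorted({r.subject for r in self.runs})
        self.states = sorted(
            {r.state for r in self.runs}, key=lambda s: (s != "rest", s)
        )
        self.tasks = [s for s in self.states if s != "rest"]
        if "rest" not in self.states:
            raise ValueError("cohort must include a rest state")

    @classmethod
    def from_cohort(
        cls,
        cohort: Cohort,
        config: PipelineConfig | None = None,
        use_planted_masks: bool = False,
    ) -> "NetworkReconfiguration":
        """Build the model from a synthetic cohort.

        With ``use_planted_masks`` the planted ground-truth Act masks are
        used directly instead of running the activation GLM (useful when the
        object under study is the metric pipeline, not mask recovery).
        """
        if config is None:
            config = PipelineConfig(cohort=cohort.spec, seed=cohort.spec.seed)
        return cls(
            runs=cohort.runs,
            parcellation=cohort.parcellation,
            confounds=cohort.confounds,
            task_regressors=cohort.truth.task_regressors,
            act_masks=dict(cohort.truth.act_mask) if use_planted_masks else None,
            covariates=cohort.covariates,
            config=config,
        )

    # ------------------------------------------------------------------

    def _clean_runs(self) -> dict[tuple[str, str, str], RunSeries]:
        low, high = self.config.band
        out = {}
        for run in self.runs:
            key = (run.subject, run.state, run.encoding)
            out[key] = pp.preprocess_run(
                run, confounds=self.confounds.get(key), low=low, high=high
            )
        return out

    def _detect_activation(
        self, clean: dict
    ) -> tuple[dict[str, np.ndarray], dict[str, act_mod.ActivationMap]]:
        masks, maps = {}, {}
        for task in self.tasks:
            if task not in self.task_regressors:
                raise ValueError(
                    f"no task regressor for {task!r}; supply act_masks instead"
                )
            # filter the design like the data (zero-phase, same band)
            tr = next(iter(clean.values())).tr
            reg = pp.bandpass_vector(
                self.task_regressors[task], tr, *self.config.band
            )
            z_rows = []
            for subject in self.subjects:
                runs = [
                    clean[k] for k in clean if k[0] == subject and k[1] == task
                ]
                z_rows.append(act_mod.subject_glm(runs, reg))
            amap = act_mod.group_activation(
                np.vstack(z_rows), threshold=self.config.z_threshold, task=task
            )
            masks[task] = amap.act_mask
            maps[task] = amap
        return masks, maps

    def _state_networks(
        self, clean: dict
    ) -> dict[tuple[str, str, float], conn_mod.BinaryNetwork]:
        low, high = self.config.band
        raw = {(r.subject, r.state, r.encoding): r for r in self.runs}
        nets = {}
        for subject in self.subjects:
            for state in self.states:
                keys = sorted(k for k in raw if k[0] == subject and k[1] == state)
                reg = self.task_regressors.get(state) if state != "rest" else None
                runs = [
                    pp.preprocess_run(
                        raw[k],
                        confounds=self.confounds.get(k),
                        task_regressor=reg,
                        low=low,
                        high=high,
                    )
                    for k in keys
                ]
                fc = [conn_mod.correlation_network(r) for r in runs]
                net = (
                    conn_mod.average_encodings(fc[0], fc[1])
                    if len(fc) == 2
                    else fc[0]
                )
                nonneg = conn_mod.zero_negatives(net)
                for density in self.config.densities:
                    nets[(subject, state, density)] = conn_mod.threshold_density(
                        nonneg, density
                    )
        return nets

    # ------------------------------------------------------------------

    def fit(self) -> ReconfigurationResults:
        """Run the pipeline end to end and return the results object."""
        cfg = self.config
        logger.info("preprocessing %d runs", len(self.runs))
        clean = self._clean_runs()
        activation_maps: dict[str, act_mod.ActivationMap] = {}
        if self.act_masks is not None:
            masks = dict(self.act_masks)
        else:
            logger.info("detecting activation (z > %.2f)", cfg.z_threshold)
            masks, activation_maps = self._detect_activation(clean)
        logger.info("building networks at densities %s", list(cfg.densities))
        nets = self._state_networks(clean)

        rows, pc_rows = [], []
        partitions: dict[tuple[str, str, float], mod_mod.Partition] = {}
        labels_int = self.parcellation.integer_labels()
        for si, subject in enumerate(self.subjects):
            for sti, state in enumerate(self.states):
                for di, density in enumerate(cfg.densities):
                    net = nets[(subject, state, density)]
                    part = mod_mod.louvain_best(
                        net,
                        gamma=cfg.gamma,
                        restarts=cfg.restarts,
                        seed=_sub_seed(cfg.seed, 71, si, sti, di),
                    )
                    partitions[(subject, state, density)] = part
                    pc = gm.participation_coefficient(net, labels_int)
                    pc_rows.append(
                        pd.DataFrame(
                            {
                                "subject": subject,
                                "state": state,
                                "density": density,
                                "roi": np.arange(pc.size),
                                "pc": pc,
                            }
                        )
                    )
                    rows += [
                        (subject, state, density, "", "E_global",
                         gm.global_efficiency(net)),
                        (subject, state, density, "", "Q", part.q),
                        (subject, state, density, "", "n_communities",
                         part.n_communities),
                    ]
                    for task in self.tasks:
                        if state not in ("rest", task):
                            continue
                        mask = masks[task]
                        rows += [
                            (subject, state, density, task, "I",
                             gm.interaction_strength(net, mask, ~mask)),
                            (subject, state, density, task, "E_act",
                             gm.areal_efficiency(net, mask)),
                            (subject, state, density, task, "E_lact",
                             gm.areal_efficiency(net, ~mask)),
                        ]
                        for region, rmask in (("act", mask), ("lact", ~mask)):
                            for rule, norm, tag in QF_VARIANTS:
                                rows.append(
                                    (subject, state, density, task,
                                     f"Qf_{region}_{tag}",
                                     mod_mod.fractional_modularity(
                                         net, part.labels, rmask,
                                         pair_rule=rule, normalization=norm,
                                         gamma=cfg.gamma,
                                     ))
                                )
        metrics = pd.DataFrame(
            rows,
            columns=["subject", "state", "density", "mask_task", "metric", "value"],
        )
        node_pc = pd.concat(pc_rows, ignore_index=True)

        flex_rows, subnet_rows = [], []
        pc_wide = node_pc.pivot_table(
            index=["subject", "density", "roi"], columns="state", values="pc"
        )
        for task in self.tasks:
            flex = gm.flexibility(
                pc_wide[task].to_numpy(), pc_wide["rest"].to_numpy()
            )
            f = pc_wide.reset_index()[["subject", "density", "roi"]].copy()
            f["task"] = task
            f["flexibility"] = flex
            flex_rows.append(f)
            for (subject, density), grp in f.groupby(["subject", "density"]):
                sn = gm.subnetwork_flexibility(
                    grp.sort_values("roi")["flexibility"].to_numpy(),
                    self.parcellation,
                )
                for lab, val in sn.items():
                    subnet_rows.append((subject, task, density, lab, val))
        flexibility = (
            pd.concat(flex_rows, ignore_index=True)
            if flex_rows
            else pd.DataFrame()
        )
        subnet_flex = pd.DataFrame(
            subnet_rows,
            columns=["subject", "task", "density", "subnetwork", "flexibility"],
        )

        tests = self._group_inference(metrics)
        consensus: dict[tuple[str, float], mod_mod.Partition] = {}
        if cfg.consensus:
            for sti, state in enumerate(self.states):
                for di, density in enumerate(cfg.densities):
                    parts = [
                        partitions[(s, state, density)] for s in self.subjects
                    ]
                    consensus[(state, density)] = mod_mod.representative_partition(
                        parts,
                        seed=_sub_seed(cfg.seed, 79, sti, di),
                        gamma=cfg.gamma,
                        restarts=cfg.restarts,
                        n_null=cfg.n_null,
                    )

        return ReconfigurationResults(
            config=cfg,
            metrics=metrics,
            node_pc=node_pc,
            flexibility=flexibility,
            subnet_flex=subnet_flex,
            tests=tests,
            act_masks=masks,
            partitions=partitions,
            activation_maps=activation_maps,
            consensus=consensus,
        )

    # ------------------------------------------------------------------

    def _group_inference(self, metrics: pd.DataFrame) -> pd.DataFrame:
        cfg = self.config
        conf = None
        if self.covariates is not None and len(self.covariates):
            cov = (
                self.covariates.set_index("subject")
                .loc[self.subjects, ["sex", "age"]]
                .to_numpy(dtype=float)
            )
            conf = cov
        rows = []
        paired_metrics = ["E_global", "Q", "I", "E_act", "E_lact"]
        for di, density in enumerate(cfg.densities):
            for ti, task in enumerate(self.tasks):
                block = []
                for metric in paired_metrics:
                    mask_task = "" if metric in ("E_global", "Q") else task
                    sel = metrics[
                        (metrics["metric"] == metric)
                        & (metrics["density"] == density)
                        & (metrics["mask_task"] == mask_task)
                        & (metrics["state"].isin(["rest", task]))
                    ]
                    wide = sel.pivot(
                        index="subject", columns="state", values="value"
                    ).dropna()
                    a, b = wide[task].to_numpy(), wide["rest"].to_numpy()
                    t_res = gs.paired_t(a, b)
                    try:
                        perm = gs.paired_permutation(
                            a, b, n_perm=cfg.n_perm,
                            seed=_sub_seed(cfg.seed, 73, di, ti,
                                           paired_metrics.index(metric)),
                        )
                    except ValueError:  # cohorts below the permutation minimum
                        perm = gs.TestResult(
                            statistic=float(np.mean(a - b)), p=np.nan,
                            method="paired_permutation", n=len(wide),
                        )
                    try:
                        ks = gs.ks_normality(a - b)
                        ks_p = ks.p
                    except ValueError:
                        ks_p = np.nan
                    block.append((metric, t_res, perm, ks_p, len(wide)))
                p_raw = [t.p for _, t, _, _, _ in block]
                p_adj = gs.fdr_adjust(np.array(p_raw), method=cfg.fdr_method)
                for (metric, t_res, perm, ks_p, n), padj in zip(block, p_adj):
                    rows.append(
                        dict(density=density, task=task, metric=metric,
                             test="paired_t", statistic=t_res.statistic,
                             p=t_res.p, p_fdr=padj, df=t_res.df, n=n)
                    )
                    rows.append(
                        dict(density=density, task=task, metric=metric,
                             test="paired_permutation",
                             statistic=perm.statistic, p=perm.p,
                             p_fdr=np.nan, df=np.nan, n=n)
                    )
                    rows.append(
                        dict(density=density, task=task, metric=metric,
                             test="ks_normality_diff", statistic=np.nan,
                             p=ks_p, p_fdr=np.nan, df=np.nan, n=n)
                    )
                # adjusted correlation of dI with dE_global
                d_e = self._delta(metrics, "E_global", task, density, "")
                d_i = self._delta(metrics, "I", task, density, task)
                joint = pd.concat([d_e, d_i], axis=1, keys=["dE", "dI"]).dropna()
                if len(joint) >= 5:
                    cc = (
                        conf[[self.subjects.index(s) for s in joint.index]]
                        if conf is not None
                        else None
                    )
                    r, p = gs.adjusted_correlation(
                        joint["dI"].to_numpy(), joint["dE"].to_numpy(), cc
                    )
                    rows.append(
                        dict(density=density, task=task, metric="dI~dE",
                             test="adjusted_correlation", statistic=r, p=p,
                             p_fdr=np.nan, df=np.nan, n=len(joint))
                    )
            # ANOVA: Act vs L-Act fractional modularity over subject x task rows
            for rule, norm, tag in QF_VARIANTS:
                cols = {}
                for region in ("act", "lact"):
                    vals = []
                    for task in self.tasks:
                        sel = metrics[
                            (metrics["metric"] == f"Qf_{region}_{tag}")
                            & (metrics["density"] == density)
                            & (metrics["mask_task"] == task)
                            & (metrics["state"] == task)
                        ].sort_values("subject")
                        vals.append(sel["value"].to_numpy())
                    cols[region] = np.concatenate(vals)
                table = np.column_stack([cols["act"], cols["lact"]])
                try:
                    res = gs.anova_two_way_repeated(
                        table, reps=len(self.subjects)
                    )
                except ValueError:
                    continue
                for effect, tr in res.items():
                    rows.append(
                        dict(density=density, task="all",
                             metric=f"Qf_{tag}", test=f"anova_{effect}",
                             statistic=tr.statistic, p=tr.p, p_fdr=np.nan,
                             df=str(tr.df), n=tr.n)
                    )
        return pd.DataFrame(rows)

    @staticmethod
    def _delta(
        metrics: pd.DataFrame, metric: str, task: str, density: float,
        mask_task: str,
    ) -> pd.Series:
        sel = metrics[
            (metrics["metric"] == metric)
            & (metrics["density"] == density)
            & (metrics["mask_task"] == mask_task)
            & (metrics["state"].isin(["rest", task]))
        ]
        wide = sel.pivot(index="subject", columns="state", values="value")
        return wide[task] - wide["rest"]
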