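"""End-to-end cohort analysis: connectivity -> topology -> statistics -> classification.

The driver follows the model/results idiom: :class:`CohortNetworkAnalysis`
is constructed from a :class:`~phaselink.datatypes.CohortDataset` and a
:class:`~phaselink.datatypes.PipelineConfig`; :meth:`~CohortNetworkAnalysis.fit`
runs the requested stages and returns a :class:`CohortNetworkResults` holding
every intermediate (per-subject connectivity matrices, regional tables,
graph and tree metrics, group-comparison tables, classification reports),
with ``summary()`` and ``save()`` for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as _classify
from . import connectivity as _conn
from . import graph as _graph
from . import mst as _mst
from . import stats as _stats
from .datatypes import CohortDataset, PipelineConfig

__all__ = ["CohortNetworkAnalysis", "CohortNetworkResults", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("connectivity", "graph", "mst", "compare", "classify")

#: Feature-set combinations evaluated by the classify stage.
FEATURE_SET_COMBOS: dict[str, tuple[str, ...]] = {
    "connectivity": ("connectivity",),
    "topology": ("topology",),
    "combined": ("connectivity", "topology", "mmse"),
}

# The topology columns of the per-band metrics table (classical metrics with
# surrogate-normalised clustering/path length, plus the 6 tree metrics).
# Global mean connectivity is deliberately NOT part of this set: the
# topology-vs-connectivity contrast requires the two feature families to be
# disjoint (the connectivity table already carries the global mean).
TOPOLOGY_COLUMNS = (
    "clustering_norm",
    "local_efficiency",
    "global_efficiency",
    "path_length_norm",
    "sigma",
    "mst_leaf_fraction",
    "mst_bc",
    "mst_diameter",
    "mst_k_max",
    "mst_ecc",
    "mst_tree_hierarchy",
)


@dataclass
class CohortNetworkResults:
    """Everything the pipeline computed, stage by stage."""

    config: PipelineConfig
    conditions: tuple[str, ...]
    connectivity: dict = field(default_factory=dict)  # (subject, cond, band) -> ConnectivityMatrix
    regional: pd.DataFrame | None = None  # long: subject, condition, band, region_a, region_b, value
    connectivity_features: dict[str, pd.DataFrame] = field(default_factory=dict)  # cond -> wide
    metrics: pd.DataFrame | None = None  # long: subject, condition, band, <metric columns>
    topology_features: dict[str, pd.DataFrame] = field(default_factory=dict)  # cond -> wide
    labels: pd.Series | None = None
    mmse: pd.Series | None = None
    comparisons: pd.DataFrame | None = None
    percent_change: pd.DataFrame | None = None
    percent_change_comparisons: pd.DataFrame | None = None
    classification: dict[tuple[str, str], _classify.ClassificationReport] = field(default_factory=dict)

    def significant(self) -> pd.DataFrame:
        """FDR-significant rows of the group-comparison table."""
        if self.comparisons is None:
            return pd.DataFrame()
        return self.comparisons[self.comparisons["significant"]]

    def summary(self) -> str:
        lines = ["Cohort network analysis", "=" * 60]
        lines.append(f"conditions: {', '.join(self.conditions)}")
        if self.labels is not None:
            counts = self.labels.value_counts().to_dict()
            lines.append(f"groups: {counts}")
        if self.comparisons is not None:
            sig = self.significant()
            lines.append(f"group comparisons: {len(self.comparisons)} features, "
                         f"{len(sig)} significant after FDR (q={self.config.fdr_q})")
            for _, row in sig.iterrows():
                lines.append(
                    f"  {row['family']}: {row['feature']}  "
                    f"p={row['p']:.4f}  p_adj={row['p_adjusted']:.4f}"
                )
        if self.percent_change_comparisons is not None:
            sig = self.percent_change_comparisons
            sig = sig[sig["significant"]]
            lines.append(f"pre/post percent-change comparisons: {len(sig)} significant")
        for (cond, name), report in self.classification.items():
            lines.append(
                f"classification [{cond}, {name}]: accuracy={report.accuracy:.3f} "
                f"precision={report.precision:.3f} sensitivity={report.sensitivity:.3f} "
                f"F1={report.f1:.3f}"
            )
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        """Write every tabular output as CSV (plus classification JSON)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.regional is not None:
            self.regional.to_csv(outdir / "regional_connectivity.csv", index=False)
        for cond, df in self.connectivity_features.items():
            df.to_csv(outdir / f"connectivity_features_{cond}.csv")
        if self.metrics is not None:
            self.metrics.to_csv(outdir / "metrics.csv", index=False)
        for cond, df in self.topology_features.items():
            df.to_csv(outdir / f"topology_features_{cond}.csv")
        if self.comparisons is not None:
            self.comparisons.to_csv(outdir / "group_comparisons.csv", index=False)
        if self.percent_change is not None:
            self.percent_change.to_csv(outdir / "percent_change.csv")
        if self.percent_change_comparisons is not None:
            self.percent_change_comparisons.to_csv(
                outdir / "percent_change_comparisons.csv", index=False
            )
        for (cond, name), report in self.classification.items():
            report.to_json(outdir / f"classification_{cond}_{name}.json")
            cm = report.confusion
            pd.DataFrame(
                [[cm.tp, cm.fn], [cm.fp, cm.tn]],
                index=["actual_pos", "actual_neg"],
                columns=["pred_pos", "pred_neg"],
            ).to_csv(outdir / f"confusion_{cond}_{name}.csv")
        (outdir / "summary.txt").write_text(self.summary() + "\n")


class CohortNetworkAnalysis:
    """Resting-state functional-network analysis of a two-group cohort.

    Parameters
    ----------
    cohort
        Labeled subjects with per-condition epoched recordings.
    config
        Pipeline settings; defaults follow the study conditions (six bands,
        10% proportional threshold, 50 surrogates, DWPLI).
    """

    def __init__(self, cohort: CohortDataset, config: PipelineConfig | None = None):
        self.cohort = cohort
        self.config = config or PipelineConfig()

    # ------------------------------------------------------------------ fit
    def fit(self, stages: tuple[str, ...] = ALL_STAGES) -> CohortNetworkResults:
        cfg = self.config
        unknown = [s for s in stages if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s) {unknown}")
        conditions = tuple(
            c for c in cfg.conditions if all(c in s.recordings for s in self.cohort)
        )
        if not conditions:
            raise ValueError(
                f"no condition from {cfg.conditions} present for every subject"
            )
        res = CohortNetworkResults(config=cfg, conditions=conditions)
        res.labels = pd.Series(
            {s.subject_id: s.group for s in self.cohort}, name="group"
        )
        res.mmse = pd.Series({s.subject_id: s.mmse for s in self.cohort}, name="mmse")

        self._stage_connectivity(res, conditions)
        if "graph" in stages or "mst" in stages:
            self._stage_metrics(res, conditions, with_graph="graph" in stages,
                                with_mst="mst" in stages)
        if "compare" in stages:
            self._stage_compare(res, conditions)
        if "classify" in stages:
            self._stage_classify(res, conditions)
        return res

    # ------------------------------------------------------------- stages
    def _stage_connectivity(self, res: CohortNetworkResults, conditions) -> None:
        cfg = self.config
        regional_rows = []
        features: dict[str, dict[str, dict[str, float]]] = {c: {} for c in conditions}
        try:
            for subject in self.cohort:
                for cond in conditions:
                    rec = subject.recordings[cond]
                    if cfg.channels is not None:
                        rec = rec.select_channels(cfg.channels)
                    row: dict[str, float] = {}
                    for band in cfg.bands:
                        W = _conn.band_connectivity(
                            rec, band, cfg.estimator, cfg.band_collapse
                        )
                        res.connectivity[(subject.subject_id, cond, band.name)] = W
                        if cfg.roi is not None:
                            reg = _conn.regional_mean(W, cfg.roi)
                            for _, r in reg.table.iterrows():
                                regional_rows.append(
                                    {
                                        "subject": subject.subject_id,
                                        "condition": cond,
                                        "band": band.name,
                                        "region_a": r.region_a,
                                        "region_b": r.region_b,
                                        "value": r.value,
                                    }
                                )
                                row[f"{band.name}|{r.region_a}-{r.region_b}"] = r.value
                        row[f"{band.name}|global"] = W.global_mean()
                    features[cond][subject.subject_id] = row
        except Exception as err:
            raise RuntimeError(f"stage connectivity: {err}") from err
        res.regional = pd.DataFrame(regional_rows)
        res.connectivity_features = {
            cond: pd.DataFrame.from_dict(rows, orient="index").sort_index()
            for cond, rows in features.items()
        }

    def _stage_metrics(self, res, conditions, with_graph: bool, with_mst: bool) -> None:
        cfg = self.config
        rows = []
        try:
            for si, subject in enumerate(self.cohort):
                for ci, cond in enumerate(conditions):
                    for bi, band in enumerate(cfg.bands):
                        W = res.connectivity[(subject.subject_id, cond, band.name)]
                        row = {
                            "subject": subject.subject_id,
                            "condition": cond,
                            "band": band.name,
                        }
                        if with_graph:
                            seed = np.random.default_rng(
                                np.random.SeedSequence([cfg.seed, si, ci, bi])
                            )
                            rec = _graph.graph_metrics_record(
                                W,
                                p=cfg.threshold_prop,
                                n_surrogates=cfg.n_surrogates,
                                seed=seed,
                                variant=cfg.clustering_variant,
                            )
                            row.update(rec.to_dict())
                        if with_mst:
                            tree = _mst.extract_mst(W)
                            row.update(_mst.mst_metrics(tree).to_dict())
                        rows.append(row)
        except Exception as err:
            raise RuntimeError(f"stage graph/mst metrics: {err}") from err
        res.metrics = pd.DataFrame(rows)
        value_cols = [c for c in res.metrics.columns if c not in ("subject", "condition", "band")]
        for cond in conditions:
            sub = res.metrics[res.metrics.condition == cond]
            wide = sub.pivot(index="subject", columns="band", values=value_cols)
            wide.columns = [f"{band}|{metric}" for metric, band in wide.columns]
            topo_cols = [
                f"{b.name}|{m}"
                for b in cfg.bands
                for m in TOPOLOGY_COLUMNS
                if f"{b.name}|{m}" in wide.columns
            ]
            res.topology_features[cond] = wide[topo_cols].sort_index()

    def _stage_compare(self, res, conditions) -> None:
        cfg = self.config
        tables = []
        try:
            for cond in conditions:
                blocks: list[tuple[str, pd.DataFrame]] = []
                if res.connectivity_features.get(cond) is not None:
                    blocks.append(("conn", res.connectivity_features[cond]))
                if res.topology_features.get(cond) is not None:
                    blocks.append(("topo", res.topology_features[cond]))
                for klass, df in blocks:
                    families = {
                        col: f"{cond}|{col.split('|')[0]}|{klass}" for col in df.columns
                    }
                    t = _stats.group_comparison_table(
                        df,
                        res.labels.loc[df.index],
                        q=cfg.fdr_q,
                        groups=("control", "aMCI"),
                        families=families,
                    )
                    t.insert(0, "condition", cond)
                    tables.append(t)
            res.comparisons = pd.concat(tables, ignore_index=True)
            if {"pre", "post"}.issubset(conditions):
                res.percent_change = self._percent_change_table(res)
                families = {
                    col: f"pct|{col.split('|')[0]}" for col in res.percent_change.columns
                }
                res.percent_change_comparisons = _stats.group_comparison_table(
                    res.percent_change,
                    res.labels.loc[res.percent_change.index],
                    q=cfg.fdr_q,
                    groups=("control", "aMCI"),
                    families=families,
                )
        except Exception as err:
            raise RuntimeError(f"stage compare: {err}") from err

    def _percent_change_table(self, res) -> pd.DataFrame:
        """Per-subject [(post - pre)/pre] * 100 for every feature."""
        blocks = []
        for store in (res.connectivity_features, res.topology_features):
            if "pre" in store and "post" in store:
                pre, post = store["pre"], store["post"]
                common = [c for c in pre.columns if c in post.columns]
                pre, post = pre[common], post[common]
                ok = (pre != 0).all(axis=0)
                blocks.append(100.0 * (post.loc[:, ok] - pre.loc[:, ok]) / pre.loc[:, ok])
        return pd.concat(blocks, axis=1)

    def _stage_classify(self, res, conditions) -> None:
        cfg = self.config
        try:
            for cond in conditions:
                tables: dict[str, pd.DataFrame | pd.Series] = {"mmse": res.mmse}
                if res.connectivity_features.get(cond) is not None:
                    tables["connectivity"] = res.connectivity_features[cond]
                if res.topology_features.get(cond) is not None:
                    tables["topology"] = res.topology_features[cond]
                for name, sets in FEATURE_SET_COMBOS.items():
                    if any(s not in tables for s in sets):
                        continue
                    ft = _classify.build_feature_table(tables, res.labels, sets)
                    res.classification[(cond, name)] = _classify.rfe_rf_loocv(
                        ft,
                        seed=cfg.seed,
                        n_trees=cfg.n_trees,
                        n_select=cfg.n_select,
                        rfe_step=cfg.rfe_step,
                        positive_class=cfg.positive_class,
                    )
        except Exception as err:
            raise RuntimeError(f"stage classify: {err}") from err


def run_pipeline(
    cfg: PipelineConfig,
    cohort: CohortDataset,
    outdir: str | Path | None = None,
    stages: tuple[str, ...] = ALL_STAGES,
) -> CohortNetworkResults:
    """Convenience wrapper: fit the full pipeline and optionally write CSVs."""
    results = CohortNetworkAnalysis(cohort, cfg).fit(stages)
    if outdir is not None:
        results.save(outdir)
    return results
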