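"""Ground-truth scoring of DEG calls and the experiment runner.

Calls are scored per (method, cell type) against the injected ground
truth: sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), precision =
TP/(TP+FP), F1 = harmonic mean of precision and sensitivity. Genes in the
evaluated set but absent from a result count as non-calls (the missing-p
rule); for subset analyses all scores are relative to the subset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import stage_seed
from .config import SimConfig
from .deg import DEGResult, bh_adjust, deg_ttest, deg_wilcoxon, filter_dataset, majority_vote, run_deg
from .pipeline import STAGES, build_stages, simulate_tissue
from .singlecell import GroundTruth, SCDataset, SCReference, inflate_sc_baseline

__all__ = [
    "EvalScores",
    "score_calls",
    "sc_baseline_deg",
    "run_experiment",
    "summarize",
    "run_specificity_benchmark",
]


@dataclass
class EvalScores:
    """Confusion counts and derived scores for one method × cell type."""

    tp: int
    fp: int
    tn: int
    fn: int
    degenerate: bool = False  # some score had a zero denominator

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else 0.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def f1(self) -> float:
        s, p = self.sensitivity, self.precision
        return 2 * p * s / (p + s) if p + s else 0.0


def score_calls(
    result: DEGResult | None,
    gt: GroundTruth,
    cell_type: str,
    evaluated_genes: np.ndarray,
) -> EvalScores:
    """Score one result against the ground truth over an evaluated gene set.

    ``evaluated_genes`` must be a subset of the ground-truth genes; genes
    the result did not test are treated as not called.
    """
    gt_index = {g: i for i, g in enumerate(gt.genes)}
    c = int(np.flatnonzero(gt.cell_types == cell_type)[0])
    called = {}
    if result is not None:
        called = dict(zip(result.genes, result.call))
    tp = fp = tn = fn = 0
    for g in evaluated_genes:
        truth = bool(gt.is_de[gt_index[g], c])
        call = bool(called.get(g, False))
        if truth and call:
            tp += 1
        elif truth:
            fn += 1
        elif call:
            fp += 1
        else:
            tn += 1
    degenerate = (tp + fn == 0) or (tn + fp == 0) or (tp + fp == 0)
    return EvalScores(tp, fp, tn, fn, degenerate)


def sc_baseline_deg(
    sc: SCDataset, method: str = "ttest", alpha: float = 0.01
) -> list[DEGResult]:
    """DEG tests directly in single-cell space (per cell type, A vs B)."""
    results = []
    for ct in dict.fromkeys(sc.cell_type):
        a = sc.counts[(sc.cell_type == ct) & (sc.condition == "A")]
        b = sc.counts[(sc.cell_type == ct) & (sc.condition == "B")]
        if method == "ttest":
            p = deg_ttest(a, b)
        elif method == "wilcoxon":
            p = deg_wilcoxon(a, b)
        else:
            raise ValueError(f"unknown SC method {method!r}")
        p_adj = bh_adjust(p)
        results.append(
            DEGResult(method, str(ct), sc.genes, p, p_adj, p_adj <= alpha)
        )
    return results


def _replicate_seed(seed: int, config_idx: int, replicate: int) -> int:
    return int(
        stage_seed(seed, f"replicate:{config_idx}:{replicate}").generate_state(1)[0]
        % (2**31)
    )


def run_experiment(
    prior: SCReference,
    configs: list[SimConfig] | SimConfig,
    n_replicates: int = 1,
    seed: int = 0,
    stages: tuple[str, ...] = STAGES + ("SC",),
    methods: tuple[str, ...] = ("ttest", "wilcoxon", "majority"),
    qc_policy: str = "flag",
    sc_baseline_cells: int = 5000,
) -> pd.DataFrame:
    """Run the benchmark over a configuration grid.

    One tidy row per (config, replicate, stage, method, cell type) with
    confusion counts and scores. ``SC`` as a stage scores the tests run
    directly on a size-matched random subsample of the single-cell pool.
    A replicate whose ground-truth QC fails is flagged (``qc_policy:
    'flag'``, the default) or raises (``'halt'``); a replicate failing for
    any other reason is logged and skipped, and the run continues.
    """
    if isinstance(configs, SimConfig):
        configs = [configs]
    base_methods = tuple(m for m in methods if m != "majority")
    rows = []
    for ci, config in enumerate(configs):
        for rep in range(n_replicates):
            rep_seed = _replicate_seed(seed, ci, rep)
            try:
                sc, gt, qc, st_m = simulate_tissue(prior, config, rep_seed)
                if qc_policy == "halt" and not qc.passed:
                    raise RuntimeError("ground-truth QC failed")
                st_stages = build_stages(
                    st_m, config, rep_seed,
                    tuple(s for s in stages if s != "SC"),
                )
                for stage, ds in st_stages.items():
                    ds_f = filter_dataset(ds)
                    per_method = {
                        m: run_deg(
                            ds_f, m, config.deg.input_mode, config.deg.alpha
                        )
                        for m in base_methods
                    }
                    if "majority" in methods:
                        per_method["majority"] = _majority_results(
                            per_method, config.deg.alpha
                        )
                    for m, results in per_method.items():
                        for res in results:
                            scores = score_calls(res, gt, res.cell_type, ds_f.genes)
                            rows.append(
                                _row(ci, rep, rep_seed, stage, m, res.cell_type, scores, qc)
                            )
                if "SC" in stages:
                    pool = inflate_sc_baseline(
                        sc, min(sc_baseline_cells, sc.n_cells), rep_seed
                    )
                    per_method = {
                        m: sc_baseline_deg(pool, m, config.deg.alpha)
                        for m in base_methods
                    }
                    if "majority" in methods:
                        per_method["majority"] = _majority_results(
                            per_method, config.deg.alpha
                        )
                    for m, results in per_method.items():
                        for res in results:
                            scores = score_calls(res, gt, res.cell_type, gt.genes)
                            rows.append(
                                _row(ci, rep, rep_seed, "SC", m, res.cell_type, scores, qc)
                            )
            except Exception:  # noqa: BLE001 - a failed replicate must not kill the grid
                import logging

                logging.getLogger(__name__).exception(
                    "replicate (config=%d, rep=%d) failed; continuing", ci, rep
                )
                rows.append(
                    {
                        "config": ci,
                        "replicate": rep,
                        "seed": rep_seed,
                        "stage": "",
                        "method": "",
                        "cell_type": "",
                        "failed": True,
                    }
                )
    table = pd.DataFrame(rows)
    if "failed" not in table.columns:
        table["failed"] = False
    table["failed"] = table["failed"].fillna(False).astype(bool)
    return table


def _majority_results(per_method: dict, alpha: float) -> list[DEGResult]:
    """Consensus over the base methods' calls, per cell type."""
    names = list(per_method)
    by_ct: dict[str, list[DEGResult]] = {}
    for m in names:
        for res in per_method[m]:
            by_ct.setdefault(res.cell_type, []).append(res)
    out = []
    for ct, results in by_ct.items():
        calls = np.vstack([r.call for r in results])
        consensus = majority_vote(calls)
        genes = results[0].genes
        p = np.where(consensus, 0.0, 1.0)  # consensus has no native p-value
        out.append(DEGResult("majority", ct, genes, p, p, consensus))
    return out


def _row(ci, rep, rep_seed, stage, method, cell_type, scores: EvalScores, qc):
    return {
        "config": ci,
        "replicate": rep,
        "seed": rep_seed,
        "stage": stage,
        "method": method,
        "cell_type": cell_type,
        "tp": scores.tp,
        "fp": scores.fp,
        "tn": scores.tn,
        "fn": scores.fn,
        "sensitivity": scores.sensitivity,
        "specificity": scores.specificity,
        "precision": scores.precision,
        "f1": scores.f1,
        "degenerate": scores.degenerate,
        "qc_passed": qc.passed,
        "failed": False,
    }


def run_specificity_benchmark(
    prior: SCReference,
    config: SimConfig,
    thresholds: tuple[float, ...] = (0.25, 0.35, 0.45, 0.55),
    seed: int = 0,
    stage: str = "ST-LD",
) -> pd.DataFrame:
    """Benchmark prior-based gene selection against matched random picks.

    One replicate: simulate a tissue, derive the requested artifact stage,
    run the regional t-test on all genes, learn mean-specificity scores
    from the simulated single cells, and for each threshold compare the
    prior-based selection to a random selection of the same size. Both
    selections share the argmax cell-type attribution and the
    subset-restricted BH correction; F1 is relative to each subset
    (mean over attributed cell types).
    """
    from .pipeline import build_stages as _stages
    from .specificity import (
        SpecificityScores,
        matched_baselines,
        mean_specificity,
        prior_selected_deg,
        select_genes,
    )

    sc, gt, qc, st_m = simulate_tissue(prior, config, seed)
    ds = filter_dataset(_stages(st_m, config, seed, (stage,))[stage])
    regional = run_deg(ds, "ttest", "regional", config.deg.alpha)
    p = regional[0].p  # regional groups are identical across cell types

    cts = np.array(list(dict.fromkeys(sc.cell_type)), dtype=object)
    means = np.column_stack([sc.counts[sc.cell_type == ct].mean(axis=0) for ct in cts])
    scores = mean_specificity(means, sc.genes, cts)
    keep = np.isin(scores.genes, ds.genes)
    scores = SpecificityScores(
        scores.genes[keep], scores.cell_types, scores.score[keep],
        scores.metric, scores.unscored[keep],
    )
    attribution = dict(zip(scores.genes, scores.argmax_type))

    rows = []
    for t_i, thr in enumerate(thresholds):
        selection = select_genes(scores, thr)
        if not selection:
            continue
        for kind, sel in (
            ("prior", selection),
            (
                "random",
                {
                    str(g): str(attribution[g])
                    for g in matched_baselines(
                        ds.genes, len(selection), "random",
                        seed=_replicate_seed(seed, 1000 + t_i, 0),
                    )
                },
            ),
        ):
            results = prior_selected_deg(p, ds.genes, sel, config.deg.alpha)
            f1s = [
                score_calls(r, gt, r.cell_type, r.genes).f1 for r in results
            ]
            rows.append(
                {
                    "threshold": thr,
                    "selection": kind,
                    "n_selected": len(sel),
                    "mean_f1": float(np.mean(f1s)) if f1s else 0.0,
                    "seed": seed,
                    "stage": stage,
                }
            )
    return pd.DataFrame(rows)


def summarize(table: pd.DataFrame, baseline_stage: str = "ST-LD") -> pd.DataFrame:
    """Mean ± sd per (stage, method), with deltas against a baseline stage."""
    ok = table[~table["failed"]]
    metrics = ["sensitivity", "specificity", "precision", "f1"]
    agg = ok.groupby(["stage", "method"])[metrics].agg(["mean", "std"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    agg = agg.reset_index()
    base = agg[agg["stage"] == baseline_stage].set_index("method")
    for m in metrics:
        agg[f"delta_{m}"] = agg.apply(
            lambda r: r[f"{m}_mean"] - base.loc[r["method"], f"{m}_mean"]
            if r["method"] in base.index
            else np.nan,
            axis=1,
        )
    return agg
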