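"""Orchestration of the full dimensionality-analysis sequence.

The sequence mirrors the standard workflow for re-appraising a short
ordinal screening scale: (1) a one-factor CFA of the polychoric matrix;
(2) exploratory models of increasing dimension inside the CFA framework,
with geomin rotation, scaled difference tests and modification indices;
(3) a strict congeneric CFA of the retained structure with AVE-based
convergent/discriminant validity; (4) an orthogonal bifactor model with a
variance partition; (5) MAP factor scores against raw scores; and (6)
nonparametric scalability and monotonicity checks of the raw total score.
Every stage lands in a report bundle (CSV + JSON + optional SVG) together
with a decision log that applies the conventional cut-offs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .mokken import mokken_report, severity_ordering
from .polychoric import polychoric_matrix
from .scores import score_table
from .sem import (
    bifactor_spec,
    cfa_spec,
    fit_exploratory,
    fit_model,
    modification_indices,
    one_factor_spec,
    scaled_difference_test,
)
from .synthetic import DEFAULT_SEED, ItemResponseMatrix, epds_spec, generate_responses
from .validity import bootstrap_validity, variance_partition

__all__ = ["PipelineConfig", "PipelineResult", "run_sequence", "read_responses"]

logger = logging.getLogger(__name__)

read_responses = _io.read_responses  # pipeline-level input entry point

RMSEA_CLOSE = 0.06
RMSEA_POOR = 0.10
INCREMENTAL_ADEQUATE = 0.90
TRIVIAL_LOADING = 0.40
DIFF_ALPHA = 0.01


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis-level configuration and the conventional decision constants."""

    input_path: str | None = None
    reversal_map: tuple = ()
    synthetic_model: str = "bifactor"
    threshold_profile: str = "calibrated"
    n: int = 811
    ecfa_range: tuple = (2, 4)
    mi_threshold: float = 10.0
    bootstrap_B: int = 1000
    minsize: int | None = None
    minvi: float = 0.03
    seed: int = DEFAULT_SEED
    output_dir: str | None = None
    make_plots: bool = True

    def validate(self, n_items: int) -> None:
        lo, hi = self.ecfa_range
        if not (1 <= lo <= hi <= n_items):
            raise ValueError("ecfa_range must lie within [1, number of items]")
        if self.bootstrap_B < 50:
            raise ValueError("bootstrap_B must be at least 50")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if "ecfa_range" in payload:
            payload["ecfa_range"] = tuple(payload["ecfa_range"])
        if "reversal_map" in payload:
            payload["reversal_map"] = tuple(payload["reversal_map"])
        return cls(**payload)


@dataclass
class PipelineResult:
    """Bundle of per-stage artifacts plus the decision log."""

    stages: dict = field(default_factory=dict)
    decisions: list = field(default_factory=list)
    failure: dict | None = None

    def decision(self, stage, rule, outcome, **detail):
        entry = {"stage": stage, "rule": rule, "outcome": outcome, **detail}
        self.decisions.append(entry)
        logger.info("decision[%s] %s -> %s", stage, rule, outcome)


def _load_input(config: PipelineConfig) -> ItemResponseMatrix:
    if config.input_path is not None:
        return read_responses(config.input_path, reversal_map=config.reversal_map)
    spec = epds_spec(
        model=config.synthetic_model,
        threshold_profile=config.threshold_profile,
        n=config.n,
        seed=config.seed,
    )
    return generate_responses(spec)


def _fit_summary(label, fi):
    return {
        "model": label,
        "T": fi.T,
        "df": fi.df,
        "p": fi.p_value,
        "rmsea": fi.rmsea,
        "rmsea_lo": fi.rmsea_ci[0],
        "rmsea_hi": fi.rmsea_ci[1],
        "cfi": fi.cfi,
        "tli": fi.tli,
    }


def _rmsea_band(rmsea: float) -> str:
    if rmsea < RMSEA_CLOSE:
        return "close"
    if rmsea <= RMSEA_POOR:
        return "marginal"
    return "poor"


def run_sequence(config: PipelineConfig) -> PipelineResult:
    """Run the full analytic sequence on real or synthetic input.

    Stage failures halt the run with a stage-labelled failure record;
    artifacts of completed stages are preserved (and written when an output
    directory is configured).
    """
    result = PipelineResult()
    stage = "input"
    try:
        matrix = _load_input(config)
        config.validate(matrix.n_items)
        result.stages["input"] = {"n": matrix.n, "n_items": matrix.n_items}
        item_labels = matrix.item_labels

        stage = "polychoric"
        stats = polychoric_matrix(matrix)
        result.stages["polychoric"] = stats

        stage = "one_factor"
        sol_a, fit_a = fit_model(one_factor_spec(item_labels), stats)
        result.stages["one_factor"] = {"solution": sol_a, "fit": fit_a}
        band = _rmsea_band(fit_a.rmsea)
        rejected = fit_a.rmsea >= RMSEA_CLOSE
        result.decision(
            "one_factor",
            f"RMSEA banded at {RMSEA_CLOSE}/{RMSEA_POOR}",
            "rejected" if rejected else "accepted",
            rmsea=fit_a.rmsea,
            band=band,
        )

        chosen_k = 1
        ecfa = {}
        if rejected:
            stage = "ecfa"
            lo, hi = config.ecfa_range
            prev_fit = fit_a
            for k in range(lo, hi + 1):
                try:
                    sol_k, fit_k = fit_exploratory(stats, k, seed=config.seed)
                except Exception as exc:
                    result.decision(
                        "ecfa", f"{k}-factor exploratory model",
                        "not adopted (fit failed)", n_factors=k, error=str(exc),
                    )
                    continue
                if not sol_k.converged:
                    result.decision(
                        "ecfa", f"{k}-factor exploratory model",
                        "not adopted (non-convergence)", n_factors=k,
                        grad_norm=sol_k.grad_norm,
                    )
                    continue
                mis = modification_indices(sol_k, stats)
                flagged = [m for m in mis if m.mi >= config.mi_threshold]
                ecfa[k] = {"solution": sol_k, "fit": fit_k, "mi": flagged}
                stat, ddf, p, neg = scaled_difference_test(fit_k, prev_fit)
                ecfa[k]["diff_vs_previous"] = {
                    "stat": stat, "df": ddf, "p": p, "negative_flag": neg,
                }
                improves = p < DIFF_ALPHA
                weakest = _weakest_factor_strong_loadings(sol_k.loadings)
                trivial = weakest <= 1
                if improves and not trivial:
                    chosen_k = k
                result.decision(
                    "ecfa",
                    f"{k} vs {k - 1} factors: scaled difference at alpha={DIFF_ALPHA}"
                    "; extra factor trivial if <2 loadings >= "
                    f"{TRIVIAL_LOADING}",
                    "accepted" if (improves and not trivial) else "not adopted",
                    n_factors=k,
                    p=p,
                    strong_loadings_on_weakest_factor=int(weakest),
                )
                prev_fit = fit_k
            result.stages["ecfa"] = ecfa

        stage = "cfa"
        item_sets = None
        report_cfa = None
        if chosen_k > 1:
            sol_e = ecfa[chosen_k]["solution"]
            item_sets = _assign_items(sol_e.loadings, item_labels, sol_e.factor_labels)
        if item_sets is None and chosen_k > 1:
            result.decision(
                "cfa", "item assignment from the exploratory solution",
                "collapsed to fewer than two factors; multi-factor CFA skipped",
            )
        if item_sets is not None:
            spec_c = cfa_spec(item_sets, item_labels)
            sol_c, fit_c = fit_model(spec_c, stats)
            mis_c = [m for m in modification_indices(sol_c, stats)
                     if m.mi >= config.mi_threshold]
            report_cfa = {"solution": sol_c, "fit": fit_c, "item_sets": item_sets,
                          "mi": mis_c}
            result.stages["cfa"] = report_cfa
            result.decision(
                "cfa",
                "congeneric CFA of the retained structure",
                _rmsea_band(fit_c.rmsea),
                rmsea=fit_c.rmsea,
                n_factors=chosen_k,
                mi_over_threshold=[m.label for m in mis_c],
            )

            stage = "validity"
            report_v = bootstrap_validity(
                matrix, spec_c, B=config.bootstrap_B, seed=config.seed
            )
            result.stages["validity"] = report_v
            failures = report_v.summary()["discriminant_failures"]
            result.decision(
                "validity",
                "Fornell-Larcker: sqrt(AVE) per factor vs factor correlations",
                "discriminant validity questionable" if failures else "discriminant validity holds",
                failures=failures,
                convergent=report_v.convergent,
            )

        stage = "bifactor"
        bifactor = None
        if item_sets is not None:
            spec_d = bifactor_spec(item_sets, item_labels)
            sol_d, fit_d = fit_model(spec_d, stats)
            stat, ddf, p, neg = scaled_difference_test(fit_d, report_cfa["fit"])
            partition = variance_partition(sol_d)
            bifactor = {
                "solution": sol_d,
                "fit": fit_d,
                "g_test_vs_cfa": {"stat": stat, "df": ddf, "p": p, "negative_flag": neg},
                "partition": partition,
            }
            result.stages["bifactor"] = bifactor
            result.decision(
                "bifactor",
                "general-factor significance and share of explained variance",
                "general factor supported" if p < 0.001 else "general factor uncertain",
                p=p,
                g_share_of_explained=partition.g_share_of_explained,
            )

        stage = "scores"
        scoring_solution = bifactor["solution"] if bifactor else sol_a
        sets_for_scores = item_sets or {"f1": list(item_labels)}
        score_set = score_table(matrix, scoring_solution, sets_for_scores)
        result.stages["scores"] = score_set
        if bifactor:
            r_g_total = score_set.correlations.loc["score_g", "raw_total"]
            result.decision(
                "scores",
                "correlation of MAP general-factor score with raw total",
                "raw total adequate proxy" if r_g_total >= 0.9 else "raw total questionable",
                r=float(r_g_total),
            )

        stage = "nirt"
        report_m = mokken_report(matrix, minsize=config.minsize, minvi=config.minvi)
        result.stages["nirt"] = report_m
        result.decision(
            "nirt",
            "scale H > 0.3; crit bands 40/80",
            "scalable" if report_m.scalability.H > 0.3 else "weak scalability",
            H=report_m.scalability.H,
            mono_crit_max=max(c.crit for c in report_m.monotonicity.items),
            dm_crit_max=max(c.crit for c in report_m.double_monotonicity.items),
        )

        stage = "severity"
        if bifactor:
            g_col = bifactor["solution"].spec.general_col
            sev = severity_ordering(
                np.asarray(stats.thresholds.values),
                loadings=bifactor["solution"].loadings[:, g_col],
                item_labels=item_labels,
            )
        else:
            sev = severity_ordering(
                np.asarray(stats.thresholds.values), item_labels=item_labels
            )
        result.stages["severity"] = sev

    except Exception as exc:  # halt with stage label; keep partial outputs
        logger.exception("pipeline stage %r failed", stage)
        result.failure = {"stage": stage, "error": str(exc)}

    if config.output_dir is not None:
        _write_bundle(result, config)
    return result


def _weakest_factor_strong_loadings(loadings: np.ndarray) -> int:
    strong = (np.abs(loadings) >= TRIVIAL_LOADING).sum(axis=0)
    return int(strong.min())


def _assign_items(loadings, item_labels, factor_labels, min_items=3):
    """Assign each item to the factor with its largest absolute loading.

    Factors left with fewer than ``min_items`` indicators cannot anchor a
    congeneric CFA; they are dissolved and their items move to the
    next-best remaining factor (deterministically, smallest factor first).
    Returns None if fewer than two factors survive.
    """
    absload = np.abs(np.asarray(loadings))
    ranking = np.argsort(-absload, axis=1)
    assign = ranking[:, 0].copy()
    active = set(range(absload.shape[1]))
    while True:
        counts = {k: int(np.sum(assign == k)) for k in sorted(active)}
        small = [k for k, c in counts.items() if 0 < c < min_items]
        empty = [k for k, c in counts.items() if c == 0]
        for k in empty:
            active.discard(k)
        if not small:
            break
        weakest = min(small, key=lambda k: (counts[k], k))
        active.discard(weakest)
        for i in np.where(assign == weakest)[0]:
            for k in ranking[i]:
                if k in active:
                    assign[i] = k
                    break
    if len(active) < 2:
        return None
    return {
        factor_labels[k]: [item_labels[i] for i in np.where(assign == k)[0]]
        for k in sorted(active)
    }


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

def _write_bundle(result: PipelineResult, config: PipelineConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    fit_rows = []
    for label in ("one_factor", "cfa"):
        if label in result.stages and "fit" in result.stages[label]:
            fit_rows.append(_fit_summary(label, result.stages[label]["fit"]))
    for k, entry in result.stages.get("ecfa", {}).items():
        fit_rows.append(_fit_summary(f"ecfa_{k}", entry["fit"]))
    if "bifactor" in result.stages:
        fit_rows.append(_fit_summary("bifactor", result.stages["bifactor"]["fit"]))
    if fit_rows:
        pd.DataFrame(fit_rows).to_csv(out / "fit_indices.csv", index=False)

    for label in ("one_factor", "cfa", "bifactor"):
        entry = result.stages.get(label)
        if entry and "solution" in entry:
            entry["solution"].to_frame().to_csv(out / f"parameters_{label}.csv", index=False)

    if "polychoric" in result.stages:
        stats = result.stages["polychoric"]
        _io.write_polychoric(
            stats, out / "polychoric_R.csv", out / "thresholds.csv", out / "polychoric_acov.csv"
        )
    if "validity" in result.stages:
        result.stages["validity"].to_frame().to_csv(out / "validity.csv", index=False)
        result.stages["validity"].comparisons.to_csv(
            out / "fornell_larcker.csv", index=False
        )
    if "bifactor" in result.stages:
        result.stages["bifactor"]["partition"].table.to_csv(
            out / "variance_partition.csv", index=False
        )
    if "scores" in result.stages:
        score_set = result.stages["scores"]
        score_set.scores.to_csv(out / "scores.csv", index=False)
        score_set.correlations.to_csv(out / "score_correlations.csv")
    if "nirt" in result.stages:
        report_m = result.stages["nirt"]
        report_m.to_frame().to_csv(out / "mokken.csv", index=False)
        report_m.traces.table.to_csv(out / "restscore_traces.csv", index=False)
    if "severity" in result.stages:
        result.stages["severity"].to_csv(out / "severity_ordering.csv", index=False)

    payload = {"decisions": result.decisions, "failure": result.failure}
    (out / "decisions.json").write_text(json.dumps(payload, indent=2, default=float))

    if config.make_plots and result.failure is None:
        _write_plots(result, out)


def _write_plots(result: PipelineResult, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if "severity" in result.stages and "polychoric" in result.stages:
        stats = result.stages["polychoric"]
        labels = list(stats.item_labels)
        tau = np.asarray(stats.thresholds.values)
        fig, ax = plt.subplots(figsize=(7, 4))
        for j, item in enumerate(labels):
            finite = np.isfinite(tau[j])
            ax.plot(tau[j][finite], [j] * int(finite.sum()), "o-", color="tab:blue", alpha=0.7)
        ax.set_yticks(range(len(labels)), labels)
        ax.set_xlabel("threshold location (latent-response scale)")
        ax.set_title("Item thresholds")
        fig.tight_layout()
        fig.savefig(out / "thresholds.svg")
        plt.close(fig)

    if "nirt" in result.stages:
        traces = result.stages["nirt"].traces.table
        fig, ax = plt.subplots(figsize=(7, 4))
        for item, sub in traces.groupby("item"):
            sub = sub.sort_values("group")
            ax.plot(sub["group"], sub["mean"], marker="o", label=item)
        ax.set_xlabel("restscore group")
        ax.set_ylabel("mean item score")
        ax.set_title("Item traces by restscore group")
        ax.legend(ncols=2, fontsize=8)
        fig.tight_layout()
        fig.savefig(out / "restscore_traces.svg")
        plt.close(fig)
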