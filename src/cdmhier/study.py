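"""Replication studies: empirical Type I error, power, accuracy, runtimes.

One *condition* is a design cell (N, K, item quality, hierarchy, attribute
distribution) crossed with a generating regime: under the ``null`` regime the
data honour the hierarchy being tested (rejections are Type I errors), under
the ``alternative`` regime the data come from the saturated model with no
hierarchy (rejections are power).  Per replication the harness generates a
dataset, fits the saturated identity-link model, computes the Wald statistic
with the XPD and/or Obs covariance, optionally fits the restricted model for
the LR test, and records rejections at the nominal level.  Replications that
fail outright are excluded from the denominator and counted.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np

from .em import fit as em_fit
from .em import fit_nested, ModelFit
from .hierarchy import AttributeHierarchy, hierarchy_preset
from .inference import lr_test, wald_test
from .information import covariance, obs_information, score_contributions, xpd_information
from .simulate import SimDesign, gen_attributes, gen_item_params, gen_responses, study_qmatrix

__all__ = ["StudyResult", "run_condition", "rate_ci", "classification_accuracy"]

ALL_METHODS = ("wald-xpd", "wald-obs", "lr")


@dataclass
class StudyResult:
    """Aggregated outcome of one condition."""

    design: SimDesign
    regime: str                                  # "null" | "alternative"
    methods: tuple
    replications_run: int
    rejections: dict = field(default_factory=dict)
    completed: dict = field(default_factory=dict)
    failures: int = 0
    failure_messages: list = field(default_factory=list)
    mean_accuracy: float = float("nan")
    runtimes: dict = field(default_factory=dict)   # mean seconds per stage

    def rate(self, method: str) -> float:
        """Rejection proportion over completed replications."""
        n = self.completed[method]
        return self.rejections[method] / n if n else float("nan")

    def ci(self, method: str) -> tuple[float, float]:
        return rate_ci(self.rate(method), self.completed[method])

    def rows(self) -> list[dict]:
        """Long-format summary, one row per method."""
        d = self.design
        out = []
        for m in self.methods:
            lo, hi = self.ci(m)
            out.append({
                "label": d.label, "regime": self.regime, "N": d.N, "K": d.K,
                "quality": d.quality, "hierarchy": d.hierarchy_name,
                "distribution": d.distribution, "method": m,
                "rate": round(self.rate(m), 3), "ci_low": lo, "ci_high": hi,
                "completed": self.completed[m], "failures": self.failures,
                "mean_accuracy": round(self.mean_accuracy, 3)
                if np.isfinite(self.mean_accuracy) else None,
            })
        return out


def rate_ci(p: float, n: int) -> tuple[float, float]:
    """Normal-approximation 95% interval for an observed rejection rate,
    ``p +/- 1.96 sqrt(p (1 - p) / n)``, clipped to [0, 1] and rounded to
    three decimals."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"rate must be in [0, 1], got {p}")
    if n < 1:
        raise ValueError(f"need n >= 1 replications, got {n}")
    half = 1.96 * np.sqrt(p * (1.0 - p) / n)
    return (round(max(0.0, p - half), 3), round(min(1.0, p + half), 3))


def classification_accuracy(fit: ModelFit, true_positions) -> float:
    """Proportion of examinees whose MAP pattern matches the truth (0-based
    canonical positions; ties break to the lowest position)."""
    true_positions = np.asarray(true_positions)
    mapped = fit.map_patterns()
    if mapped.shape != true_positions.shape:
        raise ValueError("posterior and truth disagree on the number of examinees")
    return float(np.mean(mapped == true_positions))


def run_condition(
    design: SimDesign,
    regime: str = "null",
    methods=ALL_METHODS,
    alpha: float = 0.05,
    track_accuracy: bool = True,
    max_iter: int = 20000,
) -> StudyResult:
    """Run all replications of one condition and aggregate rejection rates.

    Per-replication seeds are spawned deterministically from the design's
    base seed, so any single replication can be reproduced in isolation.  The
    Q-matrix is a fixed test design drawn once per condition.
    """
    if regime not in ("null", "alternative"):
        raise ValueError(f"unknown regime {regime!r}")
    methods = tuple(methods)
    for m in methods:
        if m not in ALL_METHODS:
            raise ValueError(f"unknown method {m!r}")
    if design.replications < 1:
        raise ValueError("need at least one replication")

    hierarchy = hierarchy_preset(design.hierarchy_name, design.K)
    gen_h = hierarchy if regime == "null" else AttributeHierarchy(design.K, name="none")

    root = np.random.SeedSequence(design.base_seed)
    Q = study_qmatrix(design.J, design.K)      # fixed test design per condition
    item_params = gen_item_params(Q, design.quality)
    rep_seeds = root.spawn(design.replications)

    rejections = {m: 0 for m in methods}
    completed = {m: 0 for m in methods}
    failures = 0
    messages: list[str] = []
    accuracies: list[float] = []
    stage_times = {"em": [], "wald-xpd": [], "wald-obs": [], "lr": []}

    # per-fit diagnostics stay on ModelFit.warnings_; don't spam the log
    with warnings.catch_warnings():
      warnings.simplefilter("ignore", RuntimeWarning)
      for r, seed in enumerate(rep_seeds):
        rng = np.random.default_rng(seed)
        try:
            positions = gen_attributes(design.N, gen_h, design.distribution, rng)
            X = gen_responses(positions, Q, item_params, rng)

            t0 = time.perf_counter()
            sat = em_fit(X, Q, link="identity", max_iter=max_iter)
            stage_times["em"].append(time.perf_counter() - t0)

            if track_accuracy:
                accuracies.append(classification_accuracy(sat, positions))

            results = {}
            if "wald-xpd" in methods:
                t0 = time.perf_counter()
                scores = score_contributions(sat, X)
                cov = covariance(xpd_information(scores), "XPD", sat)
                results["wald-xpd"] = wald_test(sat, cov, hierarchy, alpha)
                stage_times["wald-xpd"].append(time.perf_counter() - t0)
            if "wald-obs" in methods:
                t0 = time.perf_counter()
                cov = covariance(obs_information(sat, X), "Obs", sat)
                results["wald-obs"] = wald_test(sat, cov, hierarchy, alpha)
                stage_times["wald-obs"].append(time.perf_counter() - t0)
            if "lr" in methods:
                t0 = time.perf_counter()
                restricted = em_fit(X, Q, link="identity", hierarchy=hierarchy,
                                    max_iter=max_iter)
                if sat.loglik < restricted.loglik:
                    # saturated EM stopped in a local optimum: refit the pair
                    # with the nesting guarantee
                    sat, restricted = fit_nested(X, Q, hierarchy,
                                                 max_iter=max_iter)
                results["lr"] = lr_test(sat, restricted, alpha)
                stage_times["lr"].append(time.perf_counter() - t0)
        except Exception as exc:  # failed replication: log and exclude
            failures += 1
            messages.append(f"replication {r + 1}: {type(exc).__name__}: {exc}")
            continue
        for m, res in results.items():
            completed[m] += 1
            rejections[m] += int(res.reject)

    return StudyResult(
        design=design, regime=regime, methods=methods,
        replications_run=design.replications,
        rejections=rejections, completed=completed,
        failures=failures, failure_messages=messages,
        mean_accuracy=float(np.mean(accuracies)) if accuracies else float("nan"),
        runtimes={k: float(np.mean(v)) for k, v in stage_times.items() if v},
    )
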